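"""Growth traits from per-plant projected-shoot-area time series.

Five traits feed the biostimulant characterization index downstream:

* final projected area (px, mean over the variant's plants),
* relative growth rate, RGR (day⁻¹) — per imaging interval,
  ``[ln A(t_{i+1}) − ln A(t_i)] / (t_{i+1} − t_i)``, averaged over the
  experiment; constant (and exactly recovered) for exponential growth,
* growth-curve slope (px day⁻¹) — ordinary least-squares fit of area vs time,
* coefficient of variance of final areas (%; population homogeneity —
  lower is better),
* survival (%; a plant is alive if its final image holds ≥ 100 green pixels).

Dead plants (final area below the survival threshold) count in survival but
are excluded from the other four traits by default: their near-zero areas
are an artefact of the green criterion, not of growth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

SURVIVAL_THRESHOLD_PX = 100

__all__ = [
    "GrowthSeries",
    "TraitSummary",
    "interval_rgr",
    "mean_rgr",
    "growth_slope",
    "coefficient_of_variance",
    "survival_rate",
    "summarize_variant",
    "SURVIVAL_THRESHOLD_PX",
]


@dataclass
class GrowthSeries:
    """Area time series of one plant (strictly increasing times, in days)."""

    plant_id: str
    variant_id: str
    timestamps: np.ndarray
    areas: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=float)
        a = np.asarray(self.areas, dtype=float)
        if t.size != a.size:
            raise ValueError("timestamps and areas differ in length")
        if t.size < 2:
            raise ValueError("a growth series needs at least two timepoints")
        if not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(a < 0):
            raise ValueError("areas must be non-negative")
        self.timestamps, self.areas = t, a


@dataclass
class TraitSummary:
    """Per-variant aggregate of the five screen traits."""

    variant_id: str
    n_plants: int
    final_area_mean: float
    rgr_mean: float
    cv_final: float
    survival: float
    slope_mean: float

    def __post_init__(self) -> None:
        if self.n_plants <= 0:
            raise ValueError("n_plants must be positive")
        if not (0 <= self.survival <= 100):
            raise ValueError("survival must lie in [0, 100] %")


def interval_rgr(series: GrowthSeries) -> np.ndarray:
    """Per-interval relative growth rates (day⁻¹).

    Intervals touching a non-positive area cannot be log-transformed; they
    are excluded and logged, not propagated as NaN.
    """
    t, a = series.timestamps, series.areas
    valid = (a[:-1] > 0) & (a[1:] > 0)
    n_dropped = int(np.count_nonzero(~valid))
    if n_dropped:
        logger.info(
            "plant %s: dropped %d RGR interval(s) with non-positive area",
            series.plant_id,
            n_dropped,
        )
    dt = np.diff(t)[valid]
    loga = np.log(a, out=np.full_like(a, -np.inf), where=a > 0)
    with np.errstate(invalid="ignore"):
        dlog = np.diff(loga)[valid]
    return dlog / dt


def mean_rgr(series: GrowthSeries) -> float:
    """Arithmetic mean of interval RGRs over the whole period; NaN if no
    interval is computable."""
    rates = interval_rgr(series)
    if rates.size == 0:
        logger.warning("plant %s: RGR undefined (no valid interval)", series.plant_id)
        return math.nan
    return float(np.mean(rates))


def growth_slope(series: GrowthSeries) -> float:
    """OLS slope of area (px) against time (days), using every timepoint.

    Zero areas are legitimate linear observations and are retained.
    """
    t, a = series.timestamps, series.areas
    if np.ptp(t) == 0:
        raise ValueError("degenerate time values: slope undefined")
    slope, _ = np.polyfit(t, a, 1)
    return float(slope)


def coefficient_of_variance(final_areas: Sequence[float]) -> float:
    """CV of final areas in percent: 100 × sample SD (n−1) / mean.

    NaN when fewer than two plants or the mean is not positive.
    """
    a = np.asarray(final_areas, dtype=float)
    if a.size < 2 or a.mean() <= 0:
        logger.warning("CV undefined (n=%d, mean=%.3g)", a.size, a.mean() if a.size else 0)
        return math.nan
    return float(100.0 * a.std(ddof=1) / a.mean())


def survival_rate(
    final_areas: Sequence[float], threshold_px: float = SURVIVAL_THRESHOLD_PX
) -> float:
    """Percent of plants whose final area reaches the survival threshold.

    The threshold is inclusive: a plant at exactly 100 px counts as alive.
    """
    a = np.asarray(final_areas, dtype=float)
    if a.size == 0:
        raise ValueError("survival undefined for an empty population")
    return float(100.0 * np.count_nonzero(a >= threshold_px) / a.size)


def summarize_variant(
    series_set: Sequence[GrowthSeries],
    last_day: float | None = None,
    threshold_px: float = SURVIVAL_THRESHOLD_PX,
    include_dead: bool = False,
) -> TraitSummary:
    """Aggregate one variant's plants into a :class:`TraitSummary`.

    ``last_day`` selects the final timepoint (default: the latest timestamp
    present); every series must include it. Survival uses all plants;
    the other traits use only plants alive at the final timepoint unless
    ``include_dead`` is set.
    """
    if not series_set:
        raise ValueError("empty variant")
    variant_id = series_set[0].variant_id
    if any(s.variant_id != variant_id for s in series_set):
        raise ValueError("series from different variants passed to summarize_variant")

    if last_day is None:
        last_day = max(float(s.timestamps[-1]) for s in series_set)

    finals = []
    for s in series_set:
        idx = np.nonzero(np.isclose(s.timestamps, last_day))[0]
        if idx.size == 0:
            raise ValueError(
                f"plant {s.plant_id} has no observation at the final day {last_day}"
            )
        finals.append(float(s.areas[idx[0]]))
    finals = np.asarray(finals)

    surv = survival_rate(finals, threshold_px)
    alive = finals >= threshold_px
    if include_dead or not alive.any():
        retained = list(series_set)
        retained_finals = finals
        if not alive.any():
            logger.warning(
                "variant %s: no plant above the survival threshold; growth "
                "traits computed on all plants",
                variant_id,
            )
    else:
        retained = [s for s, ok in zip(series_set, alive) if ok]
        retained_finals = finals[alive]
        n_dead = int(np.count_nonzero(~alive))
        if n_dead:
            logger.info(
                "variant %s: excluded %d dead plant(s) from growth traits",
                variant_id,
                n_dead,
            )

    return TraitSummary(
        variant_id=variant_id,
        n_plants=len(series_set),
        final_area_mean=float(np.mean(retained_finals)),
        rgr_mean=float(np.nanmean([mean_rgr(s) for s in retained])),
        cv_final=coefficient_of_variance(retained_finals),
        survival=surv,
        slope_mean=float(np.mean([growth_slope(s) for s in retained])),
    )
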