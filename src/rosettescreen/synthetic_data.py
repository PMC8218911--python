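"""Synthetic plate-screen generator with ground truth.

Emulates the statistical structure the analysis assumes, so every pipeline
stage is testable without any external data:

* 48-well plates (6 × 8) of green rosettes, two plates (96 plants) per
  variant, imaged twice daily (a.m. = day d, p.m. = day d + 0.25) over 7
  days — 15 timepoints;
* exponential area growth A(t) = A0 · exp(r_eff · t), A0 lognormal around a
  configured median, r_eff = growth_rate × effect_multiplier plus a small
  per-plant rate jitter — so the relative growth rate of a noiseless plant
  is exactly the generative rate;
* salt stress as a condition-specific growth-rate reduction plus a daily
  Bernoulli death process; dead rosettes shrink by 50 %/day and switch to a
  brown palette that never satisfies the green criterion, so their measured
  green area is 0;
* rendering that colours exactly the ground-truth number of pixels per
  rosette (a lobed quasi-circular blob), so segmentation recovery can be
  validated pixel-for-pixel.

Everything is driven by one seeded :class:`numpy.random.Generator`; a fixed
seed reproduces identical scenarios, images and manifests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .plate_imaging import PlateImage, WellGrid, build_grid

logger = logging.getLogger(__name__)

__all__ = [
    "VariantSpec",
    "Palette",
    "SyntheticScenario",
    "GroundTruth",
    "simulate_growth",
    "render_plates",
    "write_fixture",
    "default_layout",
    "default_screen_scenario",
    "two_group_scenario",
    "make_transients",
    "SALT_RATE_MULTIPLIER",
    "SALT_DEATH_PROB",
]

# Condition effects used by the scenario builders: moderate salt (75 mM)
# slows growth without killing; severe salt (150 mM) slows it further and
# brings unprimed survival to ~95% over 7 days (0.9928^7 ≈ 0.951).
SALT_RATE_MULTIPLIER = {0: 1.0, 75: 0.70, 150: 0.45}
SALT_DEATH_PROB = {0: 0.0, 75: 0.0, 150: 0.007}


@dataclass
class VariantSpec:
    """Generative parameters of one substance × dose × condition group.

    ``substance=None`` marks the unprimed control. ``growth_rate`` is the
    condition-adjusted base rate (day⁻¹); ``effect_multiplier`` is the
    priming effect on that rate. ``initial_area_sigma`` is the SD of
    ln(A0); together with the rate jitter it yields final-day area CVs in
    the 35–50 % range typical of plate-grown seedlings.
    """

    substance: str | None
    dose: float | None
    condition: float  # mM NaCl; 0 = unstressed
    growth_rate: float = 0.25
    effect_multiplier: float = 1.0
    initial_area_mean: float = 100.0
    initial_area_sigma: float = 0.35
    growth_rate_sd: float = 0.03
    daily_death_prob: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.daily_death_prob <= 1:
            raise ValueError("daily_death_prob must lie in [0, 1]")
        if not np.isfinite(self.growth_rate):
            raise ValueError("growth_rate must be finite")

    @property
    def variant_id(self) -> str:
        name = self.substance if self.substance is not None else "none"
        dose = f"{self.dose:g}" if self.dose else "0"
        return f"{name}_d{dose}_c{self.condition:g}"

    @property
    def r_eff(self) -> float:
        """Expected effective growth rate (before per-plant jitter)."""
        return self.growth_rate * self.effect_multiplier


@dataclass
class Palette:
    """Colour ranges for rendering (inclusive-exclusive integer bounds)."""

    live_r: tuple[int, int] = (20, 91)
    live_g: tuple[int, int] = (130, 211)
    live_b: tuple[int, int] = (20, 91)
    dead_r: tuple[int, int] = (120, 161)
    dead_g: tuple[int, int] = (80, 111)
    dead_b: tuple[int, int] = (40, 71)
    background: tuple[int, int, int] = (205, 200, 190)


def default_layout(pitch: int = 70, n_rows: int = 6, n_cols: int = 8) -> dict:
    """Compact synthetic plate layout: 6 × 8 wells on a square pitch."""
    return {
        "n_rows": n_rows,
        "n_cols": n_cols,
        "pitch_y": pitch,
        "pitch_x": pitch,
        "margin_top": 0,
        "margin_left": 0,
        "image_height": n_rows * pitch,
        "image_width": n_cols * pitch,
    }


@dataclass
class SyntheticScenario:
    variants: list[VariantSpec]
    plates_per_variant: int = 2
    n_days: int = 7
    layout: dict = field(default_factory=default_layout)
    palette: Palette = field(default_factory=Palette)
    rng_seed: int = 0
    round_id: str = "r1"

    def imaging_times(self) -> np.ndarray:
        """Twice-daily cadence: a.m. on days 0..n, p.m. on days 0..n−1."""
        am = np.arange(self.n_days + 1, dtype=float)
        pm = np.arange(self.n_days, dtype=float) + 0.25
        return np.sort(np.concatenate([am, pm]))

    @property
    def wells_per_plate(self) -> int:
        return int(self.layout.get("n_rows", 6)) * int(self.layout.get("n_cols", 8))


@dataclass
class GroundTruth:
    """Simulated truth: per-plant parameters and per-timepoint areas.

    ``plants`` columns: plant_id, variant_id, substance, dose, condition,
    plate_id, row, col, initial_area, r_eff, death_day (NaN if never dies).
    ``areas`` columns: plant_id, plate_id, row, col, time_days, area_px
    (green-visible; 0 once dead), blob_px (physical rosette size, decaying
    after death), alive.
    """

    plants: pd.DataFrame
    areas: pd.DataFrame
    scenario: SyntheticScenario

    def expected_survival(self, variant_id: str) -> float:
        """Closed-form expected survival %: 100 · (1 − p_death)^n_days."""
        spec = next(v for v in self.scenario.variants if v.variant_id == variant_id)
        if spec.condition <= 0:
            return 100.0
        return 100.0 * (1.0 - spec.daily_death_prob) ** self.scenario.n_days


def simulate_growth(
    scenario: SyntheticScenario, rng: np.random.Generator | None = None
) -> GroundTruth:
    """Draw per-plant growth parameters and area trajectories."""
    if rng is None:
        rng = np.random.default_rng(scenario.rng_seed)
    times = scenario.imaging_times()
    n_rows = int(scenario.layout.get("n_rows", 6))
    n_cols = int(scenario.layout.get("n_cols", 8))

    plant_rows, area_rows = [], []
    for spec in scenario.variants:
        for p in range(scenario.plates_per_variant):
            plate_id = f"{spec.variant_id}-p{p + 1}"
            for row in range(n_rows):
                for col in range(n_cols):
                    plant_id = f"{plate_id}:r{row}c{col}"
                    a0 = spec.initial_area_mean * np.exp(
                        rng.normal(0.0, spec.initial_area_sigma)
                    )
                    r_eff = rng.normal(
                        spec.growth_rate * spec.effect_multiplier,
                        spec.growth_rate_sd,
                    )
                    death_day = np.nan
                    if spec.condition > 0 and spec.daily_death_prob > 0:
                        hits = rng.random(scenario.n_days) < spec.daily_death_prob
                        if hits.any():
                            death_day = float(np.argmax(hits) + 1)
                    plant_rows.append(
                        {
                            "plant_id": plant_id,
                            "variant_id": spec.variant_id,
                            "substance": spec.substance,
                            "dose": spec.dose,
                            "condition": spec.condition,
                            "plate_id": plate_id,
                            "row": row,
                            "col": col,
                            "initial_area": a0,
                            "r_eff": r_eff,
                            "death_day": death_day,
                        }
                    )
                    for t in times:
                        if np.isnan(death_day) or t < death_day:
                            blob = a0 * np.exp(r_eff * t)
                            alive = True
                        else:
                            blob = a0 * np.exp(r_eff * death_day) * 0.5 ** (
                                t - death_day
                            )
                            alive = False
                        blob_px = int(round(blob))
                        area_rows.append(
                            {
                                "plant_id": plant_id,
                                "plate_id": plate_id,
                                "row": row,
                                "col": col,
                                "time_days": t,
                                "area_px": blob_px if alive else 0,
                                "blob_px": blob_px,
                                "alive": alive,
                            }
                        )
    return GroundTruth(
        plants=pd.DataFrame(plant_rows),
        areas=pd.DataFrame(area_rows),
        scenario=scenario,
    )


def _draw_blob(
    canvas: np.ndarray,
    box,
    n_px: int,
    rng: np.random.Generator,
    palette: Palette,
    alive: bool,
    plant_id: str,
) -> None:
    """Colour exactly ``n_px`` pixels of the well as a lobed rosette blob.

    Pixels are ranked by a radial score perturbed with a sinusoidal lobe
    term, so the footprint is quasi-circular; the count is exact unless the
    blob would exceed the well box (then clipped and logged).
    """
    if n_px <= 0:
        return
    h, w = box.r1 - box.r0, box.c1 - box.c0
    if n_px > h * w:
        logger.warning(
            "plant %s: rosette of %d px clipped to the %d-px well box",
            plant_id,
            n_px,
            h * w,
        )
        n_px = h * w
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - (h - 1) / 2.0, xx - (w - 1) / 2.0
    theta = np.arctan2(dy, dx)
    lobes = int(rng.integers(3, 7))
    phase = rng.uniform(0, 2 * np.pi)
    score = np.hypot(dy, dx) * (1.0 + 0.12 * np.sin(lobes * theta + phase))
    score += rng.uniform(0, 1e-3, score.shape)  # deterministic tie-break
    order = np.argsort(score, axis=None)[:n_px]
    ys, xs = np.unravel_index(order, (h, w))
    rr, gg, bb = (
        (palette.live_r, palette.live_g, palette.live_b)
        if alive
        else (palette.dead_r, palette.dead_g, palette.dead_b)
    )
    colors = np.stack(
        [
            rng.integers(rr[0], rr[1], n_px),
            rng.integers(gg[0], gg[1], n_px),
            rng.integers(bb[0], bb[1], n_px),
        ],
        axis=1,
    ).astype(np.uint8)
    canvas[box.r0 + ys, box.c0 + xs] = colors


def render_plates(
    truth: GroundTruth,
    grid: WellGrid | None = None,
    rng: np.random.Generator | None = None,
) -> list[PlateImage]:
    """Render every plate × timepoint of a simulation as an RGB image."""
    scenario = truth.scenario
    if grid is None:
        grid = build_grid(scenario.layout)
    if rng is None:
        rng = np.random.default_rng(scenario.rng_seed + 1)
    palette = scenario.palette
    boxes = {(b.row, b.col): b for b in grid.well_boxes}
    img_h = int(scenario.layout["image_height"])
    img_w = int(scenario.layout["image_width"])

    images = []
    for (plate_id, t), group in truth.areas.groupby(["plate_id", "time_days"]):
        canvas = np.empty((img_h, img_w, 3), dtype=np.uint8)
        canvas[:] = palette.background
        for rec in group.itertuples():
            _draw_blob(
                canvas,
                boxes[(rec.row, rec.col)],
                int(rec.blob_px),
                rng,
                palette,
                bool(rec.alive),
                rec.plant_id,
            )
        images.append(
            PlateImage(
                pixels=canvas,
                plate_id=str(plate_id),
                round_id=scenario.round_id,
                time_days=float(t),
            )
        )
    return images


def write_fixture(scenario: SyntheticScenario, out_dir: str | Path) -> dict:
    """Materialize a scenario: PNGs, manifest CSV and ground-truth CSVs.

    Deterministic for a fixed ``rng_seed``: reruns produce byte-identical
    manifests and images. Returns the paths written.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    truth = simulate_growth(scenario)
    images = render_plates(truth)

    manifest_rows = []
    for img in images:
        fname = f"images/{img.plate_id}_t{img.time_days:05.2f}.png"
        Image.fromarray(img.pixels).save(out / fname)
        manifest_rows.append(
            {
                "filename": fname,
                "plate_id": img.plate_id,
                "round_id": img.round_id,
                "time_days": img.time_days,
            }
        )
    manifest = pd.DataFrame(manifest_rows).sort_values(
        ["plate_id", "time_days"], kind="mergesort"
    )
    paths = {
        "manifest": out / "manifest.csv",
        "plants": out / "ground_truth_plants.csv",
        "areas": out / "ground_truth_areas.csv",
        "scenario": out / "scenario.yaml",
    }
    manifest.to_csv(paths["manifest"], index=False)
    truth.plants.to_csv(paths["plants"], index=False)
    truth.areas.to_csv(paths["areas"], index=False)
    cfg = {
        "rng_seed": scenario.rng_seed,
        "plates_per_variant": scenario.plates_per_variant,
        "n_days": scenario.n_days,
        "round_id": scenario.round_id,
        "layout": dict(scenario.layout),
        "variants": [asdict(v) for v in scenario.variants],
    }
    with open(paths["scenario"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}


def two_group_scenario(
    condition: float = 75,
    effect_multiplier: float = 1.3,
    substance: str = "S",
    dose: float = 0.001,
    seed: int = 0,
    include_control_condition: bool = True,
    **variant_kwargs,
) -> SyntheticScenario:
    """Primed-vs-unprimed scenario at one salt level (plus, optionally, the
    unstressed condition) — the minimal design that supports a PBC score."""
    conds = [condition] + ([0] if include_control_condition and condition != 0 else [])
    variants = []
    for cond in conds:
        rate = 0.25 * SALT_RATE_MULTIPLIER.get(cond, 1.0)
        death = SALT_DEATH_PROB.get(cond, 0.0)
        common = dict(
            condition=cond, growth_rate=rate, daily_death_prob=death, **variant_kwargs
        )
        variants.append(
            VariantSpec(
                substance=substance,
                dose=dose,
                effect_multiplier=effect_multiplier if cond > 0 else 1.0,
                **common,
            )
        )
        variants.append(VariantSpec(substance=None, dose=None, **common))
    return SyntheticScenario(variants=variants, rng_seed=seed)


def default_screen_scenario(
    substances: Sequence[str] = ("A", "B"),
    doses: Sequence[float] = (0.001, 0.01, 0.1),
    conditions: Sequence[float] = (0, 75, 150),
    seed: int = 0,
) -> SyntheticScenario:
    """Small screen: every substance × dose × condition plus matched controls.

    Priming effects are substance- and dose-dependent: substance order
    alternates between a mild promoter/alleviator and a high-dose inhibitor,
    mimicking the dose-dependence real screens show.
    """
    variants = []
    for cond in conditions:
        rate = 0.25 * SALT_RATE_MULTIPLIER.get(cond, 1.0)
        death = SALT_DEATH_PROB.get(cond, 0.0)
        variants.append(
            VariantSpec(
                substance=None,
                dose=None,
                condition=cond,
                growth_rate=rate,
                daily_death_prob=death,
            )
        )
        for i, sub in enumerate(substances):
            for dose in doses:
                if i % 2 == 0:
                    mult = 1.25 if dose < 0.1 else 1.1
                else:
                    mult = 1.15 if dose < 0.1 else 0.8
                variants.append(
                    VariantSpec(
                        substance=sub,
                        dose=dose,
                        condition=cond,
                        growth_rate=rate,
                        effect_multiplier=mult,
                        daily_death_prob=death,
                    )
                )
    return SyntheticScenario(variants=variants, rng_seed=seed)


def make_transients(
    n_plants: int = 10,
    rng: np.random.Generator | None = None,
    irradiances: Sequence[int] = (95, 210, 320, 440),
) -> pd.DataFrame:
    """Random valid fluorescence transients for testing the chlf module.

    Dark-adapted Fv/Fm around 0.78–0.83; quenching grows with irradiance so
    Fm′ declines along the light curve while Ft stays below Fm′.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    rows = []
    for i in range(n_plants):
        Fo = rng.uniform(150, 250)
        Fm = Fo / (1.0 - rng.uniform(0.78, 0.83))
        for k, irr in enumerate(irradiances):
            quench = rng.uniform(0.10, 0.20) * (k + 1)
            Fm_prime = Fm / (1.0 + quench)
            Ft = Fm_prime * rng.uniform(0.35, 0.75)
            rows.append(
                {
                    "plant_id": f"plant{i}",
                    "irradiance": irr,
                    "Fo": Fo,
                    "Fm": Fm,
                    "Fm_prime": Fm_prime,
                    "Ft": Ft,
                }
            )
    return pd.DataFrame(rows)
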