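"""Orchestration: plate images → well areas → traits → PBC → reports.

The screen's analysis chain, with the routine statistics (one-way ANOVA,
Tukey HSD groupings, trait correlation matrices) as a thin reporting layer
over scipy/statsmodels — they gate nothing in the index computation.

`run` accepts either a synthetic scenario (everything generated in memory,
optionally through the actual rendering + segmentation path) or a manifest
of PNG plate images plus a layout and an experiment design mapping plates
to variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import pbc_index
from .growth_traits import (
    SURVIVAL_THRESHOLD_PX,
    GrowthSeries,
    TraitSummary,
    growth_slope,
    mean_rgr,
    summarize_variant,
)
from .plate_imaging import (
    PlateImage,
    SegmentationParams,
    build_grid,
    measure_wells,
    records_to_frame,
    segment_green,
)
from .synthetic_data import SyntheticScenario, render_plates, simulate_growth

logger = logging.getLogger(__name__)

__all__ = [
    "RunReport",
    "run",
    "compare_rounds",
    "trait_stats",
    "correlation_matrix",
    "measure_images",
    "series_by_variant",
    "summaries_frame",
    "plot_pbc_heatmap",
]


@dataclass
class RunReport:
    """All tables a screen run produces, plus the exclusion/decision log."""

    well_areas: pd.DataFrame
    trait_summaries: pd.DataFrame
    pbc_table: pd.DataFrame
    classification: pd.DataFrame
    stats: dict = field(default_factory=dict)
    log: list[str] = field(default_factory=list)


def measure_images(
    images: Sequence[PlateImage],
    layout: Mapping,
    seg_params: SegmentationParams | None = None,
) -> pd.DataFrame:
    """Segment and measure a batch of plate images into a long area table."""
    grid = build_grid(layout)
    records = []
    for img in images:
        mask = segment_green(img, seg_params)
        records.extend(measure_wells(mask, grid))
    return records_to_frame(records)


def series_by_variant(
    area_frame: pd.DataFrame, plant_variants: Mapping[str, str]
) -> dict[str, list[GrowthSeries]]:
    """Group the long area table into per-plant series, keyed by variant."""
    out: dict[str, list[GrowthSeries]] = {}
    for plant_id, grp in area_frame.groupby("plant_id"):
        if plant_id not in plant_variants:
            logger.warning("plant %s not in the design; skipped", plant_id)
            continue
        grp = grp.sort_values("time_days")
        series = GrowthSeries(
            plant_id=str(plant_id),
            variant_id=plant_variants[plant_id],
            timestamps=grp["time_days"].to_numpy(),
            areas=grp["area_px"].to_numpy(),
        )
        out.setdefault(series.variant_id, []).append(series)
    return out


def summaries_frame(
    summaries: Mapping[str, TraitSummary], meta: pd.DataFrame
) -> pd.DataFrame:
    """Tabulate TraitSummary objects and join substance/dose/condition."""
    rows = [
        {
            "variant_id": s.variant_id,
            "n_plants": s.n_plants,
            "final_area_mean": s.final_area_mean,
            "rgr_mean": s.rgr_mean,
            "cv_final": s.cv_final,
            "survival": s.survival,
            "slope_mean": s.slope_mean,
        }
        for s in summaries.values()
    ]
    frame = pd.DataFrame(rows)
    return frame.merge(meta, on="variant_id", how="left").sort_values(
        "variant_id", kind="mergesort", ignore_index=True
    )


def _pbc_stage(
    summaries: Mapping[str, TraitSummary],
    meta: pd.DataFrame,
    cv_raw_log2: bool = False,
    epsilon: float = 0.0,
    log: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every primed variant against its condition-matched control."""
    meta_ix = meta.set_index("variant_id")
    controls = {
        row["condition"]: vid
        for vid, row in meta_ix.iterrows()
        if pd.isna(row["substance"]) or row["substance"] is None
    }
    pbc_rows = []
    results_by_group: dict[tuple, dict[float, pbc_index.PBCResult]] = {}
    for vid, row in meta_ix.iterrows():
        sub = row["substance"]
        if pd.isna(sub) or sub is None:
            continue
        cond = float(row["condition"])
        if cond not in controls:
            raise ValueError(f"no unprimed control for condition {cond}")
        res = pbc_index.pbc(
            summaries[vid],
            summaries[controls[cond]],
            condition=cond,
            substance=str(sub),
            dose=float(row["dose"]),
            cv_raw_log2=cv_raw_log2,
        )
        results_by_group.setdefault((res.substance, res.dose), {})[cond] = res
        entry = {
            "substance": res.substance,
            "dose": res.dose,
            "condition": cond,
            "index": res.index,
            "sign": res.sign,
        }
        entry.update({f"contrib_{c.trait}": c.contribution for c in res.contributions})
        pbc_rows.append(entry)
        if log is not None:
            log.append(
                f"PBC {res.substance}@{res.dose:g} {cond:g} mM: index={res.index:+.4f}"
            )
    class_rows = []
    for (sub, dose), by_cond in sorted(results_by_group.items()):
        if not any(c == 0 for c in by_cond):
            msg = (
                f"{sub}@{dose:g}: no unstressed condition in the design; "
                "classification skipped"
            )
            logger.info(msg)
            if log is not None:
                log.append(msg)
            continue
        cls = pbc_index.classify(by_cond, epsilon=epsilon)
        class_rows.append(
            {
                "substance": sub,
                "dose": dose,
                "label": cls.label,
                "condition_signs": ";".join(
                    f"{c:g}:{s}" for c, s in sorted(cls.condition_signs.items())
                ),
                "inhibitory_conditions": ";".join(
                    f"{c:g}" for c in cls.inhibitory_conditions
                ),
            }
        )
    pbc_frame = pd.DataFrame(pbc_rows).sort_values(
        ["substance", "dose", "condition"], kind="mergesort", ignore_index=True
    )
    return pbc_frame, pd.DataFrame(class_rows)


def compare_rounds(mean_round1: float, mean_round2: float) -> tuple[float, int]:
    """Reproducibility headline between experimental rounds.

    Percent difference of the control-group means, with the larger mean as
    denominator: 100 × |A₁ − A₂| / max(A₁, A₂). Returns (exact value,
    nearest-integer percent).
    """
    if mean_round1 <= 0 or mean_round2 <= 0:
        raise ValueError("round means must be positive")
    exact = 100.0 * abs(mean_round1 - mean_round2) / max(mean_round1, mean_round2)
    return exact, int(round(exact))


def _compact_letters(groups: Sequence[str], nonsig_pairs: set[frozenset]) -> dict:
    """Compact letter display: groups that are not significantly different
    share at least one letter (insert–absorb heuristic)."""
    letter_sets: list[set[str]] = []
    for g in groups:
        placed = False
        for s in letter_sets:
            if all(frozenset((g, h)) in nonsig_pairs for h in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    for pair in nonsig_pairs:
        a, b = tuple(pair)
        if not any(a in s and b in s for s in letter_sets):
            letter_sets.append({a, b})
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict[str, str] = {g: "" for g in groups}
    for i, s in enumerate(letter_sets):
        for g in s:
            out[g] += alphabet[i % len(alphabet)]
    return out


def trait_stats(
    per_plant: pd.DataFrame,
    trait_cols: Sequence[str],
    group_col: str = "variant_id",
    alpha: float = 0.05,
) -> dict:
    """One-way ANOVA + Tukey HSD letter groupings for each trait.

    Standard routines only (scipy for the F test, statsmodels for Tukey);
    traits with degenerate groups are skipped with a warning.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    out: dict[str, dict] = {}
    for trait in trait_cols:
        sub = per_plant[[group_col, trait]].dropna()
        groups = [g[trait].to_numpy() for _, g in sub.groupby(group_col)]
        names = [str(n) for n, _ in sub.groupby(group_col)]
        if len(groups) < 2 or any(len(g) < 2 for g in groups):
            logger.warning("trait %s: degenerate groups, skipped", trait)
            continue
        if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
            logger.warning("trait %s: zero variance everywhere, skipped", trait)
            continue
        f, p = sps.f_oneway(*groups)
        tk = pairwise_tukeyhsd(
            sub[trait].to_numpy(), sub[group_col].astype(str).to_numpy(), alpha=alpha
        )
        res = tk.summary().data[1:]
        nonsig = {
            frozenset((str(r[0]), str(r[1]))) for r in res if not r[-1]
        }
        order = (
            sub.groupby(group_col)[trait].mean().sort_values(ascending=False).index
        )
        letters = _compact_letters([str(g) for g in order], nonsig)
        out[trait] = {"anova_F": float(f), "anova_p": float(p), "tukey_letters": letters}
    return out


_STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def correlation_matrix(
    table: pd.DataFrame, cols: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pearson correlations with significance stars (α = .05/.01/.001)."""
    n = len(cols)
    r = pd.DataFrame(np.eye(n), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((n, n)), index=cols, columns=cols)
    stars = pd.DataFrame("", index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j <= i:
                continue
            pair = table[[a, b]].dropna()
            rv, pv = sps.pearsonr(pair[a], pair[b])
            r.loc[a, b] = r.loc[b, a] = rv
            p.loc[a, b] = p.loc[b, a] = pv
            star = next((s for thr, s in _STAR_LEVELS if pv < thr), "")
            stars.loc[a, b] = stars.loc[b, a] = star
    return r, p, stars


def plot_pbc_heatmap(pbc_frame: pd.DataFrame, path: str | Path) -> None:
    """Red/blue heatmap of the index by substance × dose (rows) and
    condition (columns) — the screen's summary figure."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    pivot = pbc_frame.pivot_table(
        index=["substance", "dose"], columns="condition", values="index"
    )
    vmax = max(abs(np.nanmin(pivot.values)), abs(np.nanmax(pivot.values)), 1e-9)
    fig, ax = plt.subplots(figsize=(1.6 + pivot.shape[1], 0.6 + 0.4 * pivot.shape[0]))
    im = ax.imshow(pivot.values, cmap="RdBu", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(pivot.shape[1]))
    ax.set_xticklabels([f"{c:g} mM" for c in pivot.columns])
    ax.set_yticks(range(pivot.shape[0]))
    ax.set_yticklabels([f"{s} @ {d:g}" for s, d in pivot.index])
    for (i, j), v in np.ndenumerate(pivot.values):
        if np.isfinite(v):
            ax.text(j, i, f"{v:.2f}", ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, label="PBC index (log2 units)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _load_manifest_images(manifest_path: str | Path) -> list[PlateImage]:
    from PIL import Image

    manifest = pd.read_csv(manifest_path)
    root = Path(manifest_path).parent
    images = []
    for rec in manifest.itertuples():
        px = np.asarray(Image.open(root / rec.filename).convert("RGB"))
        images.append(
            PlateImage(
                pixels=px,
                plate_id=str(rec.plate_id),
                round_id=str(getattr(rec, "round_id", "")),
                time_days=float(rec.time_days),
            )
        )
    return images


def run(
    scenario: SyntheticScenario | None = None,
    manifest: str | Path | None = None,
    layout: Mapping | None = None,
    design: pd.DataFrame | None = None,
    seg_params: SegmentationParams | None = None,
    render: bool = True,
    cv_raw_log2: bool = False,
    epsilon: float = 0.0,
    out_dir: str | Path | None = None,
) -> RunReport:
    """Execute the full screen: segment → measure → traits → PBC → stats.

    Synthetic mode (``scenario``): the design and ground truth come from the
    generator; with ``render=False`` the imaging stage is bypassed and the
    generator's green-visible areas feed the traits directly (fast path for
    statistical studies — rendering recovery is validated separately).

    Image mode (``manifest`` + ``layout`` + ``design``): PNGs are loaded and
    measured; ``design`` maps plate_id → substance/dose/condition.
    """
    log: list[str] = []
    if scenario is not None:
        truth = simulate_growth(scenario)
        meta = (
            truth.plants[["variant_id", "substance", "dose", "condition"]]
            .drop_duplicates("variant_id")
            .reset_index(drop=True)
        )
        plant_variants = dict(
            zip(truth.plants["plant_id"], truth.plants["variant_id"])
        )
        if render:
            images = render_plates(truth)
            area_frame = measure_images(images, scenario.layout, seg_params)
            log.append(f"measured {len(images)} rendered plate images")
        else:
            area_frame = truth.areas[
                ["plate_id", "row", "col", "plant_id", "time_days", "area_px"]
            ].copy()
            log.append("imaging bypassed: ground-truth green areas used")
    elif manifest is not None:
        if layout is None or design is None:
            raise ValueError("image mode needs manifest, layout and design")
        images = _load_manifest_images(manifest)
        area_frame = measure_images(images, layout, seg_params)
        frame_plates = area_frame["plate_id"]
        d = design.set_index("plate_id")
        missing = set(frame_plates) - set(d.index)
        if missing:
            raise ValueError(f"plates absent from the design: {sorted(missing)}")
        meta = (
            design[["variant_id", "substance", "dose", "condition"]]
            .drop_duplicates("variant_id")
            .reset_index(drop=True)
        )
        plant_variants = {
            f"{pid}:r{r}c{c}": d.loc[pid, "variant_id"]
            for pid, r, c in area_frame[["plate_id", "row", "col"]]
            .drop_duplicates()
            .itertuples(index=False)
        }
    else:
        raise ValueError("provide either a scenario or a manifest")

    by_variant = series_by_variant(area_frame, plant_variants)
    summaries = {vid: summarize_variant(s) for vid, s in by_variant.items()}
    summary_frame = summaries_frame(summaries, meta)
    pbc_frame, class_frame = _pbc_stage(
        summaries, meta, cv_raw_log2=cv_raw_log2, epsilon=epsilon, log=log
    )

    per_plant = _per_plant_traits(by_variant)
    stats_out = trait_stats(per_plant, ["final_area", "rgr", "slope"])

    report = RunReport(
        well_areas=area_frame,
        trait_summaries=summary_frame,
        pbc_table=pbc_frame,
        classification=class_frame,
        stats=stats_out,
        log=log,
    )
    if out_dir is not None:
        _write_report(report, out_dir)
    return report


def _per_plant_traits(by_variant: Mapping[str, Sequence[GrowthSeries]]) -> pd.DataFrame:
    rows = []
    for vid, series_list in by_variant.items():
        for s in series_list:
            final = float(s.areas[-1])
            rows.append(
                {
                    "plant_id": s.plant_id,
                    "variant_id": vid,
                    "final_area": final,
                    "rgr": mean_rgr(s) if final >= SURVIVAL_THRESHOLD_PX else np.nan,
                    "slope": growth_slope(s),
                    "alive": final >= SURVIVAL_THRESHOLD_PX,
                }
            )
    return pd.DataFrame(rows)


def _write_report(report: RunReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.well_areas.to_csv(out / "well_areas.csv", index=False)
    report.trait_summaries.to_csv(out / "trait_summaries.csv", index=False)
    report.pbc_table.to_csv(out / "pbc_table.csv", index=False)
    report.classification.to_csv(out / "classification.csv", index=False)
    if not report.pbc_table.empty:
        plot_pbc_heatmap(report.pbc_table, out / "pbc_heatmap.png")
    with open(out / "run_log.txt", "w") as fh:
        fh.write("\n".join(report.log) + "\n")
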