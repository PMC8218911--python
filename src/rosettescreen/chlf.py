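"""PSII performance parameters from PAM chlorophyll-fluorescence transients.

Works on numeric transient tables (not fluorescence images): per plant a
dark-adapted pair (Fo, Fm) and, for each actinic irradiance of the light
curve (95, 210, 320, 440 µmol m⁻² s⁻¹), a light-adapted pair (Fm′, Ft) with
optional measured Fo′. Standard definitions:

* Fv/Fm   = (Fm − Fo)/Fm       — maximum PSII quantum yield, dark-adapted
* ΦPSII   = (Fm′ − Ft)/Fm′     — effective PSII quantum yield in light
* NPQ     = (Fm − Fm′)/Fm′     — non-photochemical quenching
* Fv′/Fm′ = (Fm′ − Fo′)/Fm′    — maximum PSII efficiency in light

When Fo′ is not measured it is estimated from the Oxborough–Baker relation
Fo′ = Fo / (Fv/Fm + Fo/Fm′), and the output flags the estimate.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LIGHT_CURVE_IRRADIANCES = (95, 210, 320, 440)  # µmol m⁻² s⁻¹

__all__ = [
    "fv_fm",
    "phi_psii",
    "npq",
    "estimate_fo_prime",
    "fvp_fmp",
    "light_curve_table",
    "LIGHT_CURVE_IRRADIANCES",
]


def fv_fm(Fo: float, Fm: float) -> float:
    """Maximum quantum yield of PSII, dark-adapted: (Fm − Fo)/Fm ∈ [0, 1]."""
    if not (Fo > 0 and Fm > 0):
        raise ValueError("Fo and Fm must be positive")
    if Fm < Fo:
        raise ValueError(f"Fm ({Fm}) below Fo ({Fo})")
    return (Fm - Fo) / Fm


def phi_psii(Fm_prime: float, Ft: float) -> float:
    """Effective PSII quantum yield in light: (Fm′ − Ft)/Fm′ ∈ [0, 1]."""
    if not (Fm_prime > 0 and Ft > 0):
        raise ValueError("Fm′ and Ft must be positive")
    if Ft > Fm_prime:
        raise ValueError(f"Ft ({Ft}) above Fm′ ({Fm_prime})")
    return (Fm_prime - Ft) / Fm_prime


def npq(Fm: float, Fm_prime: float) -> float:
    """Non-photochemical quenching: (Fm − Fm′)/Fm′; ≥ 0 whenever Fm ≥ Fm′."""
    if not (Fm > 0 and Fm_prime > 0):
        raise ValueError("Fm and Fm′ must be positive")
    value = (Fm - Fm_prime) / Fm_prime
    if value < 0:
        warnings.warn(
            f"NPQ is negative ({value:.4g}): Fm′ exceeds dark-adapted Fm",
            stacklevel=2,
        )
    return value


def estimate_fo_prime(Fo: float, Fm: float, Fm_prime: float) -> float:
    """Oxborough–Baker estimate of the light-adapted minimal fluorescence:
    Fo′ = Fo / (Fv/Fm + Fo/Fm′)."""
    if not (Fm_prime > 0):
        raise ValueError("Fm′ must be positive")
    return Fo / (fv_fm(Fo, Fm) + Fo / Fm_prime)


def fvp_fmp(
    Fm_prime: float,
    Fo_prime: float | None = None,
    Fo: float | None = None,
    Fm: float | None = None,
) -> float:
    """Maximum PSII efficiency in light: (Fm′ − Fo′)/Fm′.

    Uses measured Fo′ when given; otherwise estimates it from (Fo, Fm, Fm′).
    """
    if Fo_prime is None:
        if Fo is None or Fm is None:
            raise ValueError("need either a measured Fo′ or (Fo, Fm) to estimate it")
        Fo_prime = estimate_fo_prime(Fo, Fm, Fm_prime)
    if not (Fm_prime > 0 and Fo_prime > 0):
        raise ValueError("Fm′ and Fo′ must be positive")
    return (Fm_prime - Fo_prime) / Fm_prime


def light_curve_table(transients: pd.DataFrame) -> pd.DataFrame:
    """Derive per-irradiance PSII parameters for every plant.

    Input columns: plant_id, irradiance, Fo, Fm, Fm_prime, Ft, optional
    Fo_prime (and Fp, read through but unused). Output: one row per plant ×
    irradiance with phi_psii, npq, fvp_fmp, fo_prime_estimated, plus the
    per-plant dark-adapted fv_fm repeated on each of that plant's rows.
    Rows with an irradiance outside the light-curve protocol are kept with a
    warning; rows missing Fm′ or Ft get NaN light-adapted parameters.
    """
    required = {"plant_id", "irradiance", "Fo", "Fm"}
    missing = required - set(transients.columns)
    if missing:
        raise ValueError(f"transient table lacks columns: {sorted(missing)}")
    rows = []
    for _, rec in transients.iterrows():
        irr = rec["irradiance"]
        if irr not in LIGHT_CURVE_IRRADIANCES:
            warnings.warn(
                f"plant {rec['plant_id']}: irradiance {irr} outside the "
                f"light-curve protocol {LIGHT_CURVE_IRRADIANCES}; row kept",
                stacklevel=2,
            )
        out = {
            "plant_id": rec["plant_id"],
            "irradiance": irr,
            "fv_fm": fv_fm(rec["Fo"], rec["Fm"]),
            "phi_psii": np.nan,
            "npq": np.nan,
            "fvp_fmp": np.nan,
            "fo_prime_estimated": False,
        }
        fmp = rec.get("Fm_prime", np.nan)
        ft = rec.get("Ft", np.nan)
        if pd.notna(fmp) and fmp > 0:
            out["npq"] = npq(rec["Fm"], fmp)
            if pd.notna(ft) and ft > 0:
                out["phi_psii"] = phi_psii(fmp, ft)
            fop = rec.get("Fo_prime", np.nan)
            if pd.notna(fop) and fop > 0:
                out["fvp_fmp"] = fvp_fmp(fmp, Fo_prime=fop)
            else:
                out["fvp_fmp"] = fvp_fmp(fmp, Fo=rec["Fo"], Fm=rec["Fm"])
                out["fo_prime_estimated"] = True
        else:
            logger.warning(
                "plant %s @ %s: Fm′ missing; light-adapted parameters flagged NaN",
                rec["plant_id"],
                irr,
            )
        rows.append(out)
    return pd.DataFrame(rows)
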