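"""Plant Biostimulant Characterization (PBC) index.

For each priming substance × dose × growth condition, every trait is scored
as the signed base-2 log ratio of the primed group's value to the matched
unprimed control's value; the index is the sum of those contributions.
Positive contributions mean the priming helped on that trait.

CV is the one *negative* trait (lower is better), so its contribution is
−log2(primed/unprimed). A ``cv_raw_log2`` compatibility switch reports the
raw log2 of the CV ratio instead, without the sign flip — some published
index tables tabulate that raw value.

Survival is a stress-only trait: under the unstressed control condition the
index sums the remaining four traits.

Classification by the sign pattern of the index across conditions:
positive under control only → growth promoter; positive under every salt
condition but not control → stress alleviator; positive everywhere →
promoter and alleviator; negative anywhere → growth inhibitor (flagged per
condition); otherwise neutral.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .growth_traits import TraitSummary

logger = logging.getLogger(__name__)

__all__ = [
    "PBCContribution",
    "PBCResult",
    "SubstanceClassification",
    "trait_contribution",
    "pbc",
    "classify",
    "POSITIVE_TRAITS",
    "NEGATIVE_TRAITS",
]

POSITIVE_TRAITS = ("final_area", "rgr", "survival", "slope")
NEGATIVE_TRAITS = ("cv",)


class UndefinedContributionError(ValueError):
    """A trait ratio cannot be formed (non-positive input)."""


@dataclass
class PBCContribution:
    trait: str
    primed_value: float
    unprimed_value: float
    negative_trait: bool
    contribution: float


@dataclass
class PBCResult:
    substance: str
    dose: float
    condition: float  # mM NaCl; 0 = unstressed control condition
    contributions: list[PBCContribution] = field(default_factory=list)

    @property
    def index(self) -> float:
        return float(sum(c.contribution for c in self.contributions))

    @property
    def sign(self) -> str:
        idx = self.index
        return "positive" if idx > 0 else "negative" if idx < 0 else "zero"


@dataclass
class SubstanceClassification:
    substance: str
    dose: float
    label: str
    condition_signs: dict[float, str] = field(default_factory=dict)
    inhibitory_conditions: list[float] = field(default_factory=list)


def trait_contribution(
    primed: float, unprimed: float, negative_trait: bool = False, trait: str = ""
) -> PBCContribution:
    """Signed log2-ratio contribution of one trait.

    ``contribution = s · log2(primed/unprimed)`` with s = −1 for negative
    traits (lower is better, e.g. CV) and +1 otherwise.
    """
    if not (primed > 0 and unprimed > 0):
        raise UndefinedContributionError(
            f"trait {trait or '?'}: ratio needs positive values, got "
            f"primed={primed!r}, unprimed={unprimed!r}"
        )
    sign = -1.0 if negative_trait else 1.0
    return PBCContribution(
        trait=trait,
        primed_value=float(primed),
        unprimed_value=float(unprimed),
        negative_trait=negative_trait,
        contribution=float(sign * math.log2(primed / unprimed)),
    )


def _floored_survival(value: float, n: int, variant: str) -> float:
    """Floor a 0% survival at 100/(n+1)% so its log ratio stays finite."""
    if value > 0:
        return value
    floored = 100.0 / (n + 1)
    logger.warning(
        "variant %s: survival 0%% floored at %.4g%% (n=%d) for the index",
        variant,
        floored,
        n,
    )
    return floored


def pbc(
    primed: TraitSummary,
    unprimed: TraitSummary,
    condition: float,
    substance: str = "",
    dose: float = float("nan"),
    cv_raw_log2: bool = False,
) -> PBCResult:
    """Score one primed variant against its unprimed control.

    Under salt stress (condition > 0) all five traits contribute; under the
    unstressed control condition survival is omitted (it is defined for the
    stress variants only) and the index sums four traits.
    """
    pairs = [
        ("final_area", primed.final_area_mean, unprimed.final_area_mean, False),
        ("rgr", primed.rgr_mean, unprimed.rgr_mean, False),
        ("cv", primed.cv_final, unprimed.cv_final, not cv_raw_log2),
        ("slope", primed.slope_mean, unprimed.slope_mean, False),
    ]
    if condition > 0:
        pairs.append(
            (
                "survival",
                _floored_survival(primed.survival, primed.n_plants, primed.variant_id),
                _floored_survival(
                    unprimed.survival, unprimed.n_plants, unprimed.variant_id
                ),
                False,
            )
        )
    contributions = []
    for trait, p, u, neg in pairs:
        if p is None or u is None or math.isnan(p) or math.isnan(u):
            raise UndefinedContributionError(f"trait {trait} is missing/undefined")
        contributions.append(trait_contribution(p, u, negative_trait=neg, trait=trait))
    return PBCResult(
        substance=substance, dose=dose, condition=condition, contributions=contributions
    )


def classify(
    results: Sequence[PBCResult] | Mapping[float, PBCResult],
    epsilon: float = 0.0,
) -> SubstanceClassification:
    """Label one substance × dose from its index sign pattern across
    conditions.

    ``epsilon`` widens the zero band: an index in [−epsilon, epsilon] counts
    as neither positive nor negative (default 0, i.e. strict sign).
    """
    if isinstance(results, Mapping):
        by_cond = dict(results)
    else:
        by_cond = {r.condition: r for r in results}
    if not by_cond:
        raise ValueError("no conditions to classify")
    if 0 not in by_cond and 0.0 not in by_cond:
        raise ValueError("the unstressed control condition is required")

    first = next(iter(by_cond.values()))
    signs: dict[float, str] = {}
    for cond, res in sorted(by_cond.items()):
        idx = res.index
        signs[cond] = (
            "positive" if idx > epsilon else "negative" if idx < -epsilon else "zero"
        )
    stress_conds = [c for c in by_cond if c > 0]
    control_pos = signs[0] == "positive" if 0 in signs else signs[0.0] == "positive"
    stress_pos = bool(stress_conds) and all(signs[c] == "positive" for c in stress_conds)
    neg_conds = sorted(c for c, s in signs.items() if s == "negative")

    if control_pos and stress_pos:
        label = "promoter and alleviator"
    elif control_pos:
        label = "growth promoter"
    elif stress_pos:
        label = "stress alleviator"
    elif neg_conds:
        label = "growth inhibitor"
    else:
        label = "neutral"
    return SubstanceClassification(
        substance=first.substance,
        dose=first.dose,
        label=label,
        condition_signs=signs,
        inhibitory_conditions=neg_conds,
    )
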