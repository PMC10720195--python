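"""The conditional probability-ratio statistic for consecutive WGDs.

For a genome that went through two whole-genome duplications separated by
time ``t1``, with time ``t2`` elapsed since the second, the statistic

    p_ratio = P(pair survives t2 | its parent pair survived t1)
              -------------------------------------------------
              P(pair survives t2 | its parent pair was lost in t1)

measures whether retention in the two rounds is sorted.  Under the
independence hypothesis (a single retention category for the whole genome)
the ratio is exactly 1.  Under the gene-duplicability hypothesis the genome
is a mixture of categories with proportions alpha, and conditioning on the
t1 fate shifts the category mixture between numerator and denominator.  The
mutational-opportunity hypothesis nests gene duplicability: a fraction
``beta_switch_mo`` of alternative-functionalization survivors of t1 lose the
ability to alt-functionalize again and behave as chance-retention (non)
genes during t2.

Both conditionals are mixture averages of the category survival curves; the
factor of two from each t1 survivor contributing two pairs at the second
WGD cancels in the normalized conditionals and is therefore absent here (the
simulator honors it in its pair accounting).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .survival import (
    RetentionClassParams,
    SeriesConfig,
    get_profile,
    survival,
)

__all__ = [
    "GenomeComposition",
    "HypothesisSpec",
    "UndefinedConditionalError",
    "MODELS",
    "conditional_survival_given_survived",
    "conditional_survival_given_lost",
    "p_ratio",
]

MODELS = ("independence", "gene_duplicability", "mutational_opportunity")

_SIMPLEX_TOL = 1e-9


class UndefinedConditionalError(ZeroDivisionError):
    """A conditional survival probability has an empty conditioning event."""


@dataclass(frozen=True)
class GenomeComposition:
    """Proportion of the ancestral genome in each retention category.

    The three proportions live on the probability simplex:
    ``alpha_alt_func + alpha_dos + alpha_non = 1``.
    """

    alpha_alt_func: float
    alpha_dos: float
    alpha_non: float

    def __post_init__(self) -> None:
        for name, a in self.as_dict().items():
            if not (0.0 <= a <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {a}")
        total = self.alpha_alt_func + self.alpha_dos + self.alpha_non
        if abs(total - 1.0) > _SIMPLEX_TOL:
            raise ValueError(
                f"composition proportions must sum to 1 (got {total!r})"
            )

    def as_dict(self) -> dict[str, float]:
        return {
            "alt_func": self.alpha_alt_func,
            "dos": self.alpha_dos,
            "non": self.alpha_non,
        }

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.alpha_alt_func, self.alpha_dos, self.alpha_non)


@dataclass(frozen=True)
class HypothesisSpec:
    """Which p_ratio model applies, and its switching fraction.

    ``beta_switch_mo`` is meaningful only under ``mutational_opportunity``;
    for the other models it is forced to 0, so that mutational opportunity
    with beta = 0 is *identical* to gene duplicability (the models are
    nested).
    """

    model: str
    beta_switch_mo: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(
                f"unknown model {self.model!r}; expected one of {MODELS}"
            )
        if not (0.0 <= self.beta_switch_mo <= 1.0):
            raise ValueError(
                f"beta_switch_mo must be in [0, 1], got {self.beta_switch_mo}"
            )
        if self.model != "mutational_opportunity" and self.beta_switch_mo != 0.0:
            object.__setattr__(self, "beta_switch_mo", 0.0)


def _category_survivals(
    profile: Mapping[str, RetentionClassParams],
    t: float,
    series: SeriesConfig | None,
) -> dict[str, float]:
    return {label: survival(p, t, series) for label, p in profile.items()}


def _switched_survivals(
    s_t2: Mapping[str, float], beta: float
) -> dict[str, float]:
    """Post-switch t2 survival per category: only alt_func survivors switch."""
    out = dict(s_t2)
    out["alt_func"] = (1.0 - beta) * s_t2["alt_func"] + beta * s_t2["non"]
    return out


def _effective_composition(
    comp: GenomeComposition, hyp: HypothesisSpec
) -> GenomeComposition:
    """Under independence the genome is a single category; collapse to the
    dominant one (the ratio is 1 regardless of which)."""
    if hyp.model != "independence":
        return comp
    weights = comp.as_dict()
    top = max(weights, key=lambda k: (weights[k], k))
    pure = {"alt_func": 0.0, "dos": 0.0, "non": 0.0}
    pure[top] = 1.0
    return GenomeComposition(pure["alt_func"], pure["dos"], pure["non"])


def conditional_survival_given_survived(
    comp: GenomeComposition,
    t1: float,
    t2: float,
    hyp: HypothesisSpec,
    profile: Mapping[str, RetentionClassParams] | None = None,
    series: SeriesConfig | None = None,
) -> float:
    """P(a second-round pair survives t2 | its parent pair survived t1).

    Mixture form ``sum_i alpha_i S_i(t1) S~_i(t2) / sum_i alpha_i S_i(t1)``
    where ``S~`` applies the mutational-opportunity switch to alt_func.
    """
    if t1 <= 0:
        raise ValueError(f"t1 must be > 0, got {t1}")
    if t2 < 0:
        raise ValueError(f"t2 must be >= 0, got {t2}")
    profile = profile if profile is not None else get_profile()
    comp = _effective_composition(comp, hyp)
    alphas = comp.as_dict()
    s1 = _category_survivals(profile, t1, series)
    s2 = _switched_survivals(
        _category_survivals(profile, t2, series), hyp.beta_switch_mo
    )
    denom = sum(alphas[k] * s1[k] for k in alphas)
    if denom <= 0.0:
        raise UndefinedConditionalError(
            f"no category can survive t1={t1}; conditional undefined"
        )
    num = sum(alphas[k] * s1[k] * s2[k] for k in alphas)
    return num / denom


def conditional_survival_given_lost(
    comp: GenomeComposition,
    t1: float,
    t2: float,
    hyp: HypothesisSpec | None = None,
    profile: Mapping[str, RetentionClassParams] | None = None,
    series: SeriesConfig | None = None,
) -> float:
    """P(the survivor-copy pair survives t2 | the parent pair was lost in t1).

    No switching applies in this branch: only genes that were *retained*
    through alternative functionalization can lose that ability.
    """
    if t1 <= 0:
        raise ValueError(f"t1 must be > 0, got {t1}")
    if t2 < 0:
        raise ValueError(f"t2 must be >= 0, got {t2}")
    profile = profile if profile is not None else get_profile()
    if hyp is not None:
        comp = _effective_composition(comp, hyp)
    alphas = comp.as_dict()
    s1 = _category_survivals(profile, t1, series)
    s2 = _category_survivals(profile, t2, series)
    denom = sum(alphas[k] * (1.0 - s1[k]) for k in alphas)
    if denom <= 0.0:
        raise UndefinedConditionalError(
            f"no pair can be lost by t1={t1}; conditional undefined "
            "(this is why t1 = 0 is outside the statistic's domain)"
        )
    num = sum(alphas[k] * (1.0 - s1[k]) * s2[k] for k in alphas)
    return num / denom


def p_ratio(
    comp: GenomeComposition,
    t1: float,
    t2: float,
    hyp: HypothesisSpec,
    profile: Mapping[str, RetentionClassParams] | None = None,
    series: SeriesConfig | None = None,
) -> float:
    """The probability-ratio statistic at (t1, t2).

    Ratio of the two conditional survival probabilities; 1 means retention
    in the second round carries no memory of the first ("unsorted").
    Strictly positive and finite; ``t1`` and ``t2`` must both be > 0.
    """
    if t1 <= 0 or t2 <= 0:
        raise ValueError(f"p_ratio requires t1 > 0 and t2 > 0, got ({t1}, {t2})")
    num = conditional_survival_given_survived(comp, t1, t2, hyp, profile, series)
    den = conditional_survival_given_lost(comp, t1, t2, hyp, profile, series)
    if den <= 0.0:
        raise UndefinedConditionalError(
            f"denominator conditional is 0 at (t1={t1}, t2={t2})"
        )
    ratio = num / den
    if not math.isfinite(ratio) or ratio <= 0.0:
        raise UndefinedConditionalError(
            f"p_ratio evaluated to {ratio!r} at (t1={t1}, t2={t2})"
        )
    return ratio
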