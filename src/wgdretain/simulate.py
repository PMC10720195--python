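"""Monte-Carlo simulation of duplicate-gene fates through two WGDs.

Each ancestral gene draws a retention category from the genome composition.
Its first-round pair survives the inter-duplication interval t1 with the
category's survival probability.  A t1 survivor enters the second WGD with
two copies, hence contributes two independent second-round pairs; a t1
loser contributes one.  Each second-round pair survives t2 with the
category's survival probability — except that under the mutational
opportunity hypothesis an alt_func gene whose pair survived t1 switches,
once per gene with probability beta, to the chance-retention (non) curve
for t2.

The simulator is both the brute-force oracle for the closed-form statistic
and the synthetic-data generator for composition inference.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .pratio import GenomeComposition, HypothesisSpec
from .survival import RetentionClassParams, SeriesConfig, get_profile, survival

__all__ = [
    "SimulationConfig",
    "RetentionCounts",
    "GeneFates",
    "simulate_retention",
    "empirical_p_ratio",
    "write_counts_json",
    "read_counts_json",
    "write_fates_tsv",
]

#: generator algorithm recorded in metadata; outputs are reproducible across
#: machines for a fixed algorithm and seed
RNG_ALGORITHM = "numpy.random.Generator(PCG64)"

_CATEGORIES = ("alt_func", "dos", "non")


@dataclass(frozen=True)
class SimulationConfig:
    """One simulation run: genome size, seed, times, composition, hypothesis."""

    n_genes: int
    seed: int
    t1: float
    t2: float
    composition: GenomeComposition
    hypothesis: HypothesisSpec

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError(f"n_genes must be >= 1, got {self.n_genes}")
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError(
                f"t1 and t2 must be > 0, got ({self.t1}, {self.t2})"
            )


@dataclass(frozen=True)
class RetentionCounts:
    """2x2 pair-fate table across both duplication rounds.

    ``n11``/``n10``: second-round pairs from t1 *survivors* (two pairs per
    surviving gene) that survived / were lost in t2.  ``n01``/``n00``: the
    single second-round pair of each t1 *loser* that survived / was lost in
    t2.  Totals therefore satisfy
    ``n11 + n10 = 2 * (#t1 survivors)`` and ``n01 + n00 = #t1 losers``.
    """

    n11: int
    n10: int
    n01: int
    n00: int
    t1: float
    t2: float

    def __post_init__(self) -> None:
        for name in ("n11", "n10", "n01", "n00"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")

    @property
    def total_pairs(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    def as_dict(self) -> dict:
        return {
            "n11": int(self.n11), "n10": int(self.n10),
            "n01": int(self.n01), "n00": int(self.n00),
            "t1": self.t1, "t2": self.t2,
        }


@dataclass(frozen=True)
class GeneFates:
    """Per-gene fate table (parallel arrays over genes)."""

    category: np.ndarray        # str labels
    switched: np.ndarray        # bool, MO switch applied for t2
    survived_t1: np.ndarray     # bool
    pair_a_survived_t2: np.ndarray  # bool; valid for every gene
    pair_b_survived_t2: np.ndarray  # bool; valid only where survived_t1


def simulate_retention(
    config: SimulationConfig,
    profile: Mapping[str, RetentionClassParams] | None = None,
    series: SeriesConfig | None = None,
    return_fates: bool = False,
):
    """Simulate per-gene fates; returns RetentionCounts (and optionally fates).

    Fates are Bernoulli draws from the closed-form survival probabilities,
    not hazard-process trajectories.  Randomness is consumed in a fixed
    stage order (category, t1 survival, switch, t2 survival), so identical
    configs give identical outputs.
    """
    profile = profile if profile is not None else get_profile()
    s1 = {k: survival(profile[k], config.t1, series) for k in _CATEGORIES}
    s2 = {k: survival(profile[k], config.t2, series) for k in _CATEGORIES}

    rng = np.random.default_rng(config.seed)
    alphas = np.array(
        [config.composition.as_dict()[k] for k in _CATEGORIES]
    )
    n = config.n_genes
    cat_idx = rng.choice(3, size=n, p=alphas / alphas.sum())

    s1_arr = np.array([s1[k] for k in _CATEGORIES])[cat_idx]
    survived_t1 = rng.random(n) < s1_arr

    beta = config.hypothesis.beta_switch_mo
    switched = np.zeros(n, dtype=bool)
    if config.hypothesis.model == "mutational_opportunity" and beta > 0:
        # one switch draw per gene, applied only to alt_func t1-survivors
        is_alt_survivor = survived_t1 & (cat_idx == 0)
        switched[is_alt_survivor] = rng.random(int(is_alt_survivor.sum())) < beta

    # effective t2 survival per gene: switched genes follow the non curve
    s2_by_cat = np.array([s2[k] for k in _CATEGORIES])
    s2_arr = s2_by_cat[cat_idx]
    s2_arr = np.where(switched, s2["non"], s2_arr)

    # survivors contribute two independent pairs; losers one
    pair_a = rng.random(n) < s2_arr
    pair_b = rng.random(n) < s2_arr  # only meaningful for t1 survivors

    n11 = int(pair_a[survived_t1].sum() + pair_b[survived_t1].sum())
    n10 = int(2 * survived_t1.sum() - n11)
    lost = ~survived_t1
    n01 = int(pair_a[lost].sum())
    n00 = int(lost.sum() - n01)

    counts = RetentionCounts(n11, n10, n01, n00, config.t1, config.t2)
    if not return_fates:
        return counts
    fates = GeneFates(
        category=np.array(_CATEGORIES, dtype=object)[cat_idx],
        switched=switched,
        survived_t1=survived_t1,
        pair_a_survived_t2=pair_a,
        pair_b_survived_t2=pair_b,
    )
    return counts, fates


def empirical_p_ratio(counts: RetentionCounts) -> tuple[float, float]:
    """Empirical statistic and its delta-method standard error.

    Returns ``([n11/(n11+n10)] / [n01/(n01+n00)], SE)`` where the SE treats
    the two conditional survival fractions as independent binomial
    proportions.  The variance estimate uses continuity-adjusted
    proportions ``(x + 1/2)/(n + 1)``: the plug-in estimate is degenerate
    (zero) when a sampled proportion sits on the boundary, which happens
    routinely when one conditioning class is small.  The point estimate
    itself is the unadjusted ratio.
    """
    n1 = counts.n11 + counts.n10
    n2 = counts.n01 + counts.n00
    if n1 == 0 or n2 == 0 or counts.n01 == 0:
        raise ZeroDivisionError(
            "empirical p_ratio undefined: need pairs in both conditioning "
            f"classes and n01 > 0 (got n11+n10={n1}, n01={counts.n01}, "
            f"n01+n00={n2})"
        )
    p1 = counts.n11 / n1
    p2 = counts.n01 / n2
    ratio = p1 / p2
    p1a = (counts.n11 + 0.5) / (n1 + 1.0)
    p2a = (counts.n01 + 0.5) / (n2 + 1.0)
    var_log = (1.0 - p1a) / (n1 * p1a) + (1.0 - p2a) / (n2 * p2a)
    return ratio, ratio * math.sqrt(var_log)


def write_counts_json(counts: RetentionCounts, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(counts.as_dict(), fh, indent=2)
        fh.write("\n")


def read_counts_json(path: str | os.PathLike) -> RetentionCounts:
    with open(path) as fh:
        d = json.load(fh)
    return RetentionCounts(
        int(d["n11"]), int(d["n10"]), int(d["n01"]), int(d["n00"]),
        float(d["t1"]), float(d["t2"]),
    )


def write_fates_tsv(fates: GeneFates, path: str | os.PathLike) -> None:
    """Per-gene fate table: id, category, switched, t1 fate, pair-level t2 fates."""
    with open(path, "w") as fh:
        fh.write("gene_id\tcategory\tswitched\tsurvived_t1\t"
                 "pair_a_survived_t2\tpair_b_survived_t2\n")
        for i in range(len(fates.category)):
            surv1 = bool(fates.survived_t1[i])
            pair_b = bool(fates.pair_b_survived_t2[i]) if surv1 else ""
            fh.write(
                f"g{i}\t{fates.category[i]}\t{int(fates.switched[i])}\t"
                f"{int(surv1)}\t{int(fates.pair_a_survived_t2[i])}\t{pair_b}\n"
            )
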