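"""Maximum-likelihood recovery of genome composition from retention counts.

Given a 2x2 pair-fate table at known (t1, t2) and fixed hazard parameters,
the composition alpha over the three retention categories (and optionally
the mutational-opportunity switching fraction beta) is estimated by
maximizing a multinomial likelihood over the four pair-outcome cells.  The
cell masses mirror the simulator's pair accounting: a gene whose first pair
survived t1 contributes two second-round pairs, one whose pair was lost
contributes one, so the expected number of pairs per gene in category i is
``1 + S_i(t1)``.

The simplex constraint is handled by an additive log-ratio
reparameterization with multi-start L-BFGS-B; the curvature (Hessian
eigenvalues of the negative log-likelihood in the unconstrained
coordinates) is reported so near-flat, weakly identified directions — e.g.
alt_func vs dos at time points where their survival products are similar —
are visible rather than hidden.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import minimize

from .pratio import GenomeComposition, HypothesisSpec
from .simulate import RetentionCounts
from .survival import RetentionClassParams, SeriesConfig, get_profile, survival

__all__ = [
    "FitResult",
    "cell_probabilities",
    "log_likelihood",
    "fit_composition",
    "write_fit_json",
]

_CATEGORIES = ("alt_func", "dos", "non")
_TIME_TOL = 1e-12


@dataclass(frozen=True)
class FitResult:
    """Outcome of a composition fit."""

    composition: GenomeComposition
    beta_switch_mo: float | None
    log_likelihood: float
    converged: bool
    n_restarts: int
    curvature_eigenvalues: tuple[float, ...]

    def as_dict(self) -> dict:
        return {
            "composition": self.composition.as_dict(),
            "beta_switch_mo": self.beta_switch_mo,
            "log_likelihood": self.log_likelihood,
            "converged": self.converged,
            "n_restarts": self.n_restarts,
            "curvature_eigenvalues": list(self.curvature_eigenvalues),
        }


def _survival_pair(
    profile: Mapping[str, RetentionClassParams],
    t1: float,
    t2: float,
    series: SeriesConfig | None,
) -> tuple[np.ndarray, np.ndarray, float]:
    s1 = np.array([survival(profile[k], t1, series) for k in _CATEGORIES])
    s2 = np.array([survival(profile[k], t2, series) for k in _CATEGORIES])
    return s1, s2, s2[2]  # s2_non needed for the switch


def _cell_probs_from_survivals(
    alpha: np.ndarray, beta: float, s1: np.ndarray, s2: np.ndarray, s2_non: float
) -> np.ndarray:
    """(p11, p10, p01, p00) given per-category survivals at t1 and t2."""
    s2_eff = s2.copy()
    s2_eff[0] = (1.0 - beta) * s2[0] + beta * s2_non  # alt_func switch
    m11 = np.sum(alpha * 2.0 * s1 * s2_eff)
    m10 = np.sum(alpha * 2.0 * s1 * (1.0 - s2_eff))
    m01 = np.sum(alpha * (1.0 - s1) * s2)
    m00 = np.sum(alpha * (1.0 - s1) * (1.0 - s2))
    z = np.sum(alpha * (1.0 + s1))
    return np.array([m11, m10, m01, m00]) / z


def cell_probabilities(
    comp: GenomeComposition,
    hyp: HypothesisSpec,
    t1: float,
    t2: float,
    profile: Mapping[str, RetentionClassParams] | None = None,
    series: SeriesConfig | None = None,
) -> np.ndarray:
    """Probabilities of the four pair-outcome cells (11, 10, 01, 00); sum to 1."""
    if t1 <= 0 or t2 < 0:
        raise ValueError(f"need t1 > 0 and t2 >= 0, got ({t1}, {t2})")
    profile = profile if profile is not None else get_profile()
    alpha = np.array([comp.as_dict()[k] for k in _CATEGORIES])
    s1, s2, s2_non = _survival_pair(profile, t1, t2, series)
    return _cell_probs_from_survivals(alpha, hyp.beta_switch_mo, s1, s2, s2_non)


def log_likelihood(
    counts: RetentionCounts,
    comp: GenomeComposition,
    hyp: HypothesisSpec,
    t1: float,
    t2: float,
    profile: Mapping[str, RetentionClassParams] | None = None,
    series: SeriesConfig | None = None,
) -> float:
    """Multinomial log-likelihood of the pair-fate table under (comp, hyp).

    ``-inf`` only when a cell with positive count has probability zero.
    """
    if abs(counts.t1 - t1) > _TIME_TOL or abs(counts.t2 - t2) > _TIME_TOL:
        raise ValueError(
            f"counts were generated at (t1={counts.t1}, t2={counts.t2}) but the "
            f"likelihood was requested at (t1={t1}, t2={t2})"
        )
    probs = cell_probabilities(comp, hyp, t1, t2, profile, series)
    ns = (counts.n11, counts.n10, counts.n01, counts.n00)
    total = 0.0
    for n, p in zip(ns, probs):
        if n == 0:
            continue
        if p <= 0.0:
            return -math.inf
        total += n * math.log(p)
    return total


def _alpha_from_z(z: np.ndarray) -> np.ndarray:
    """Additive log-ratio inverse: alpha = softmax([z0, z1, 0])."""
    w = np.array([z[0], z[1], 0.0])
    w -= w.max()
    e = np.exp(w)
    return e / e.sum()


def _neg_loglik_factory(counts, s1, s2, s2_non, fit_beta, fixed_beta):
    ns = np.array([counts.n11, counts.n10, counts.n01, counts.n00], dtype=float)

    def nll(x: np.ndarray) -> float:
        alpha = _alpha_from_z(x[:2])
        beta = 1.0 / (1.0 + math.exp(-x[2])) if fit_beta else fixed_beta
        probs = _cell_probs_from_survivals(alpha, beta, s1, s2, s2_non)
        with np.errstate(divide="ignore"):
            logp = np.log(probs)
        mask = ns > 0
        if np.any(~np.isfinite(logp[mask])):
            return 1e300
        return -float(np.sum(ns[mask] * logp[mask]))

    return nll


def _fd_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    k = len(x)
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei) - f(x + ej) + f0
            ) / (h * h)
    return H


def fit_composition(
    counts: RetentionCounts,
    hyp_model: str,
    t1: float,
    t2: float,
    fit_beta: bool = False,
    beta_switch_mo: float = 0.0,
    restarts: int = 8,
    seed: int = 0,
    profile: Mapping[str, RetentionClassParams] | None = None,
    series: SeriesConfig | None = None,
) -> FitResult:
    """Maximize the multinomial likelihood over the composition simplex.

    ``fit_beta`` additionally estimates the switching fraction (only
    meaningful for ``hyp_model = 'mutational_opportunity'``); otherwise beta
    is fixed at ``beta_switch_mo`` (default 0, the gene-duplicability
    model).  Multi-start from seeded random simplex points guards against
    multimodality; the best of all restarts is reported, deterministically
    for a given seed.
    """
    profile = profile if profile is not None else get_profile()
    if hyp_model not in ("gene_duplicability", "mutational_opportunity"):
        raise ValueError(
            f"hyp_model must be gene_duplicability or mutational_opportunity, "
            f"got {hyp_model!r}"
        )
    if fit_beta and hyp_model != "mutational_opportunity":
        raise ValueError("fit_beta requires the mutational_opportunity model")
    s1, s2, s2_non = _survival_pair(profile, t1, t2, series)
    if abs(counts.t1 - t1) > _TIME_TOL or abs(counts.t2 - t2) > _TIME_TOL:
        raise ValueError(
            f"counts were generated at (t1={counts.t1}, t2={counts.t2}) but the "
            f"fit was requested at (t1={t1}, t2={t2})"
        )
    fixed_beta = beta_switch_mo if hyp_model == "mutational_opportunity" else 0.0
    nll = _neg_loglik_factory(counts, s1, s2, s2_non, fit_beta, fixed_beta)

    rng = np.random.default_rng(seed)
    k = 3 if fit_beta else 2
    best = None
    any_converged = False
    for r in range(restarts):
        if r == 0:
            x0 = np.zeros(k)  # uniform composition (and beta = 0.5)
        else:
            a0 = rng.dirichlet(np.ones(3))
            x0 = np.empty(k)
            x0[0] = math.log(max(a0[0], 1e-8) / max(a0[2], 1e-8))
            x0[1] = math.log(max(a0[1], 1e-8) / max(a0[2], 1e-8))
            if fit_beta:
                b0 = rng.uniform(0.05, 0.95)
                x0[2] = math.log(b0 / (1.0 - b0))
        res = minimize(nll, x0, method="L-BFGS-B")
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not any_converged:
        raise RuntimeError(
            f"no restart converged after {restarts} attempts; "
            f"last status: {getattr(best, 'message', 'n/a')}"
        )
    alpha = _alpha_from_z(best.x[:2])
    beta_hat = (
        1.0 / (1.0 + math.exp(-best.x[2])) if fit_beta
        else (fixed_beta if hyp_model == "mutational_opportunity" else None)
    )
    # renormalize defensively so the reported alphas are a simplex point
    alpha = alpha / alpha.sum()
    H = _fd_hessian(nll, best.x)
    eig = tuple(float(v) for v in np.linalg.eigvalsh(H))
    return FitResult(
        composition=GenomeComposition(*(float(a) for a in alpha)),
        beta_switch_mo=beta_hat,
        log_likelihood=-float(best.fun),
        converged=any_converged,
        n_restarts=restarts,
        curvature_eigenvalues=eig,
    )


def write_fit_json(result: FitResult, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(result.as_dict(), fh, indent=2)
        fh.write("\n")
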