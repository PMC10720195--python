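"""Category-specific hazard and survival curves for duplicate gene pairs.

After a whole-genome duplication (WGD) every gene pair is at risk of losing
one copy.  The instantaneous per-pair loss rate for a gene category is

    h(t) = d + f * exp(-b * t**c)

where ``d + f`` is the loss rate of a fully redundant pair immediately after
the duplication and ``d`` is the asymptotic rate once the retention process
(sub-/neofunctionalization, dosage balance, or pure drift) has played out.
``b`` and ``c`` shape the transition between the two regimes.  The survival
function follows by integrating the hazard; expanding the exponential in the
integrand term by term gives

    S(t) = exp( -d*t - f * sum_{n>=0} (-b)**n * t**(c*n+1) / (n! * (c*n+1)) )

which is evaluated here with a term recurrence, compensated summation, and a
controlled truncation at ``n_max`` terms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

__all__ = [
    "RetentionClassParams",
    "SeriesConfig",
    "EvaluationDomainError",
    "SeriesConvergenceError",
    "CATEGORY_LABELS",
    "PROFILES",
    "get_profile",
    "hazard",
    "survival",
]

logger = logging.getLogger(__name__)

CATEGORY_LABELS = ("alt_func", "dos", "non")

#: validation domain upper end: hazard nonnegativity is checked on (0, T_CHECK]
T_CHECK_DEFAULT = 2.0

#: exp() argument below which the result underflows to exactly 0.0
_EXP_UNDERFLOW = -745.0
#: exp() argument above which float64 overflows
_EXP_OVERFLOW = 709.0


class EvaluationDomainError(ValueError):
    """The hazard/survival function cannot be evaluated at this point."""


class SeriesConvergenceError(ArithmeticError):
    """The survival series did not converge within ``n_max`` terms."""


@dataclass(frozen=True)
class RetentionClassParams:
    """Hazard parameterization (b, c, d, f) of one gene category.

    Parameters
    ----------
    label : str
        Category name, one of ``alt_func`` (retainable by sub- or
        neofunctionalization), ``dos`` (transient dosage-balance retention),
        or ``non`` (retention only by chance, constant hazard).
    b : float
        Hazard-decay shape parameter (dimensionless).  ``b > 0`` gives a
        decaying excess hazard, ``b < 0`` a growing one, ``b = 0`` a constant
        hazard ``d + f``.
    c : float
        Time exponent (dimensionless, strictly positive).
    d : float
        Asymptotic per-pair loss rate (1/time).  May be negative as long as
        the total hazard stays nonnegative on the validation domain.
    f : float
        Initial excess loss rate of a fully redundant pair (1/time);
        ``d + f`` is the hazard at t = 0.
    t_check : float
        Upper end of the numerical nonnegativity check for the hazard.
    """

    label: str
    b: float
    c: float
    d: float
    f: float
    t_check: float = T_CHECK_DEFAULT

    def __post_init__(self) -> None:
        if self.label not in CATEGORY_LABELS:
            raise ValueError(
                f"unknown category label {self.label!r}; expected one of {CATEGORY_LABELS}"
            )
        if not self.c > 0:
            raise ValueError(f"c must be > 0, got {self.c}")
        if self.d + self.f < 0:
            raise ValueError(
                f"initial hazard d + f must be nonnegative, got {self.d + self.f}"
            )
        if not self.t_check > 0:
            raise ValueError(f"t_check must be > 0, got {self.t_check}")
        # numerical nonnegativity of the hazard on (0, t_check]
        for i in range(1, 201):
            t = self.t_check * i / 200.0
            h = hazard(self, t)
            if h < 0:
                raise ValueError(
                    f"hazard is negative ({h:.6g}) at t={t:.6g} for category "
                    f"{self.label!r}; parameters are invalid on (0, {self.t_check}]"
                )


@dataclass(frozen=True)
class SeriesConfig:
    """Truncation control for the survival series.

    ``n_max`` caps the series index; early termination fires when the running
    term is below ``rel_tol`` times the partial sum on two consecutive terms
    (a single accidentally small term of an alternating series must not stop
    the summation).  If the cap is reached while the final term still exceeds
    ``fail_tol`` times the partial sum, the evaluation fails loudly rather
    than returning a silently truncated value.
    """

    n_max: int = 100
    rel_tol: float = 1e-12
    fail_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.n_max < 1:
            raise ValueError(f"n_max must be >= 1, got {self.n_max}")
        if not (0.0 < self.rel_tol < self.fail_tol < 1.0):
            raise ValueError(
                "tolerances must satisfy 0 < rel_tol < fail_tol < 1, got "
                f"rel_tol={self.rel_tol}, fail_tol={self.fail_tol}"
            )


def hazard(params: RetentionClassParams, t: float) -> float:
    """Instantaneous per-pair loss rate ``d + f*exp(-b*t**c)`` at time ``t >= 0``."""
    if t < 0:
        raise EvaluationDomainError(f"time must be nonnegative, got {t}")
    if t == 0.0:
        return params.d + params.f
    arg = -params.b * t**params.c
    if arg > _EXP_OVERFLOW:
        raise EvaluationDomainError(
            f"hazard overflows at t={t} for category {params.label!r} "
            f"(exp argument {arg:.3g} exceeds float64 range)"
        )
    return params.d + params.f * math.exp(arg)


def _series_sum(params: RetentionClassParams, t: float, series: SeriesConfig) -> float:
    """Sum_{n=0}^{N} (-b)^n t^{cn+1} / (n! (cn+1)) with early termination.

    Uses the term recurrence
        term_{n+1} = term_n * (-b)*t^c * (c*n+1) / ((n+1)*(c*(n+1)+1))
    starting from term_0 = t, so no explicit factorial or power is ever
    formed, and Kahan-compensated summation against the mild cancellation of
    the alternating (b > 0) case.
    """
    b, c = params.b, params.c
    ratio_base = -b * t**c
    term = t
    total = 0.0
    comp = 0.0  # Kahan compensation
    small_streak = 0
    for n in range(series.n_max + 1):
        y = term - comp
        s = total + y
        comp = (s - total) - y
        total = s
        if abs(term) <= series.rel_tol * abs(total):
            small_streak += 1
            if small_streak >= 2:
                return total
        else:
            small_streak = 0
        term *= ratio_base * (c * n + 1.0) / ((n + 1.0) * (c * (n + 1.0) + 1.0))
    # cap reached: the *last added* term is the n_max-th; `term` now holds n_max+1
    if abs(term) > series.fail_tol * abs(total):
        raise SeriesConvergenceError(
            f"survival series did not converge within n_max={series.n_max} terms "
            f"at t={t} for category {params.label!r} "
            f"(b={params.b}, c={params.c}, d={params.d}, f={params.f}); "
            f"final relative term {abs(term) / abs(total):.3g}"
        )
    return total


def survival(
    params: RetentionClassParams,
    t: float,
    series: SeriesConfig | None = None,
) -> float:
    """Probability that a duplicate pair is still retained ``t`` after its WGD.

    Returns ``exp(-d*t - f*Sigma(t))`` with the truncated series ``Sigma``.
    ``survival(params, 0)`` is exactly 1.  Values that stray above 1 by more
    than 1e-9 (a sign of a broken series, not of rounding) raise; a stray of
    at most 1e-9 is clamped.
    """
    if t < 0:
        raise EvaluationDomainError(f"time must be nonnegative, got {t}")
    if t == 0.0:
        return 1.0
    if series is None:
        series = SeriesConfig()
    exponent = -params.d * t - params.f * _series_sum(params, t, series)
    if exponent < _EXP_UNDERFLOW:
        logger.debug(
            "survival underflows to 0 at t=%g for category %r (exponent %g)",
            t, params.label, exponent,
        )
        return 0.0
    if exponent > _EXP_OVERFLOW:
        raise EvaluationDomainError(
            f"survival exponent {exponent:.3g} overflows at t={t} "
            f"for category {params.label!r}"
        )
    s = math.exp(exponent)
    if s > 1.0:
        if s - 1.0 <= 1e-9:
            return 1.0
        raise EvaluationDomainError(
            f"survival evaluated to {s!r} > 1 at t={t} for category "
            f"{params.label!r}; series evaluation is unreliable here"
        )
    return s


def _make_profile(spec: dict[str, tuple[float, float, float, float]]):
    return {
        label: RetentionClassParams(label, *bcdf) for label, bcdf in spec.items()
    }


#: Named parameter profiles, keyed by category label.  The default profile
#: carries the empirically motivated (b, c, d, f) sets for the merged
#: alternative-functionalization category, the dosage-balance category, and
#: the chance-retention (constant hazard) category.
PROFILES: dict[str, dict[str, RetentionClassParams]] = {
    "konrad2011_adjusted": _make_profile(
        {
            "alt_func": (10.0, 2.37, 0.00054, 5.84),
            "dos": (-17.0, 0.2573, -0.000028, 0.000028),
            "non": (0.0, 1.0, 20.0, 5.0),
        }
    ),
}

DEFAULT_PROFILE = "konrad2011_adjusted"


def get_profile(name: str = DEFAULT_PROFILE) -> dict[str, RetentionClassParams]:
    """Return a builtin parameter profile by name."""
    try:
        return PROFILES[name]
    except KeyError:
        raise KeyError(
            f"unknown profile {name!r}; available: {sorted(PROFILES)}"
        ) from None
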