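"""Count-scale control limits for a Poisson mean.

Three constructions of two-sided funnel-plot control limits for an expected
event count ``lam`` (the Poisson mean λ, generically non-integer):

``wald``
    Normal approximation, λ ± z_{1−α/2}·√λ. The lower limit may be negative
    and is stored unclamped.
``exact``
    The classical Poisson/chi-square interval: lower = ½·χ²(α/2; 2λ),
    upper = ½·χ²(1−α/2; 2λ+2). Non-integer degrees of freedom are handled
    by scipy's gamma-based chi-square quantile. The lower limit is strictly
    positive for every λ > 0.
``prediction``
    Probability-based integer limits read off the Poisson CDF itself, so the
    outside-probability of a future in-control observation is controlled by
    construction. Under the conservative tail rule the lower limit L is the
    smallest integer with P(X ≤ L) ≥ α/2 and the upper limit U the largest
    integer with P(X ≥ U) ≥ α/2; consequently P(X < L) < α/2 and
    P(X > U) < α/2.

"Falling outside" always means strictly beyond a limit; an observation
exactly on a limit is inside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.stats import chi2, norm, poisson

__all__ = [
    "NominalLevel",
    "TailRule",
    "LimitPair",
    "METHODS",
    "ALARM",
    "ACTION",
    "as_level",
    "wald_limits",
    "exact_limits",
    "prediction_limits",
    "interpolated_prediction_limits",
    "limits",
    "wald_bounds",
    "exact_bounds",
    "prediction_bounds",
]

METHODS = ("wald", "exact", "prediction")


@dataclass(frozen=True)
class NominalLevel:
    """A two-sided nominal coverage level, e.g. 0.95 ('alarm') or 0.998 ('action').

    ``alpha`` is the total nominal outside-probability 1 − level and
    ``tail_prob`` the per-tail share α/2.
    """

    level: float

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise ValueError(f"level must lie in (0, 1), got {self.level}")

    @property
    def alpha(self) -> float:
        return 1.0 - self.level

    @property
    def tail_prob(self) -> float:
        return self.alpha / 2.0


#: Conventional 95% 'alarm' and 99.8% 'action' limits.
ALARM = NominalLevel(0.95)
ACTION = NominalLevel(0.998)


def as_level(level: "float | NominalLevel") -> NominalLevel:
    """Coerce a float or NominalLevel to a NominalLevel."""
    if isinstance(level, NominalLevel):
        return level
    return NominalLevel(float(level))


class TailRule(str, Enum):
    """How the integer prediction limits treat the nominal per-tail probability.

    Discreteness forces a choice between two adjacent integers in each tail:
    the outer one leaves strictly-outside probability at most α/2, the inner
    one at least α/2. CONSERVATIVE (the primary definition) picks the outer
    integer in both tails; LIBERAL picks the inner integer in both tails
    (e.g. at λ=10, level 0.95 the upper candidates are 16 with tail 0.027
    and 17 with tail 0.014 — conservative takes 17, liberal 16).
    ASYMMETRIC_FUNNELCOMPAR mimics the Stata FUNNELCOMPAR convention:
    conservative below (tail ≤ α/2), liberal above (tail ≥ α/2). All limits
    are stored in the strict-outside convention: an observation is flagged
    only strictly beyond the stored value.
    """

    CONSERVATIVE = "conservative"
    LIBERAL = "liberal"
    ASYMMETRIC_FUNNELCOMPAR = "asymmetric_funnelcompar"


@dataclass(frozen=True)
class LimitPair:
    """Lower/upper control limits on the count scale for one λ, method and level.

    For ``method="prediction"`` the limits are non-negative integers (stored
    as floats). For ``method="wald"`` the lower limit may be negative and is
    not clamped.
    """

    lam: float
    method: str
    level: NominalLevel
    lower: float
    upper: float
    tail_rule: "TailRule | None" = field(default=None)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.lower > self.upper:
            raise ValueError(
                f"lower limit {self.lower} exceeds upper limit {self.upper}"
            )


def _check_lam(lam) -> np.ndarray:
    arr = np.asarray(lam, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0.0):
        raise ValueError("lam (expected events) must be positive and finite")
    return arr


# ---------------------------------------------------------------------------
# vectorised bounds: arrays in, (lower, upper) arrays out


def wald_bounds(lam, level: "float | NominalLevel") -> tuple[np.ndarray, np.ndarray]:
    lam = _check_lam(lam)
    lv = as_level(level)
    z = norm.ppf(1.0 - lv.tail_prob)
    half = z * np.sqrt(lam)
    return lam - half, lam + half


def exact_bounds(lam, level: "float | NominalLevel") -> tuple[np.ndarray, np.ndarray]:
    lam = _check_lam(lam)
    lv = as_level(level)
    lower = 0.5 * chi2.ppf(lv.tail_prob, 2.0 * lam)
    upper = 0.5 * chi2.ppf(1.0 - lv.tail_prob, 2.0 * lam + 2.0)
    return lower, upper


def prediction_bounds(
    lam,
    level: "float | NominalLevel",
    rule: TailRule = TailRule.CONSERVATIVE,
) -> tuple[np.ndarray, np.ndarray]:
    lam = _check_lam(lam)
    lv = as_level(level)
    a2 = lv.tail_prob
    rule = TailRule(rule)
    # smallest integer with CDF >= a2 — exactly scipy's discrete ppf
    lower = poisson.ppf(a2, lam)
    # largest integer U with P(X >= U) >= a2: ppf(1-a2) gives the smallest k
    # with F(k) >= 1-a2, so P(X >= k) > a2 always holds; step up once more
    # when the survival probability at k is still >= a2 (ties included).
    k = poisson.ppf(1.0 - a2, lam)
    upper = np.where(poisson.sf(k, lam) >= a2, k + 1.0, k)
    if rule is TailRule.LIBERAL:
        lower, upper = lower + 1.0, upper - 1.0
    elif rule is TailRule.ASYMMETRIC_FUNNELCOMPAR:
        upper = upper - 1.0
    if np.any(lower > upper):
        raise ValueError(
            "liberal prediction interval is empty at this lam/level "
            "(lam too small for an inner-integer limit in both tails)"
        )
    return lower, upper


# ---------------------------------------------------------------------------
# scalar API returning LimitPair


def wald_limits(lam: float, level: "float | NominalLevel") -> LimitPair:
    """Normal-approximation limits λ ± z_{1−α/2}·√λ (lower unclamped)."""
    lo, up = wald_bounds(lam, level)
    return LimitPair(float(lam), "wald", as_level(level), float(lo), float(up))


def exact_limits(lam: float, level: "float | NominalLevel") -> LimitPair:
    """'Exact' chi-square limits; non-integer 2λ df handled via the gamma form."""
    lo, up = exact_bounds(lam, level)
    return LimitPair(float(lam), "exact", as_level(level), float(lo), float(up))


def prediction_limits(
    lam: float,
    level: "float | NominalLevel",
    rule: TailRule = TailRule.CONSERVATIVE,
) -> LimitPair:
    """Integer probability-based prediction limits under the given tail rule.

    Conservative limits guarantee strictly-outside probability ≤ α/2 in each
    tail; liberal limits (one integer inward) guarantee ≥ α/2. At very small
    λ the two inward steps can cross, leaving no liberal interval — that is
    reported as an error rather than an arbitrary pair.
    """
    lo, up = prediction_bounds(lam, level, rule)
    return LimitPair(
        float(lam), "prediction", as_level(level), float(lo), float(up),
        tail_rule=TailRule(rule),
    )


def interpolated_prediction_limits(
    lam: float, level: "float | NominalLevel"
) -> LimitPair:
    """Real-valued prediction limits for *plotting only*.

    The conservative integer limits produce a step-function funnel; for
    display the steps are smoothed by interpolating linearly in the exceeded
    tail probability between adjacent integers. With T(x) = P(X ≥ x) and
    F the CDF::

        upper* = x_U + (α/2 − T(x_U + 1)) / (T(x_U) − T(x_U + 1))
        lower* = x_L − (F(x_L) − α/2) / (F(x_L) − F(x_L − 1))

    so upper* ∈ [x_U, x_U + 1) and lower* ∈ (x_L − 1, x_L]. Classification
    and coverage computations never use this output — outlier status is
    unaffected by the smoothing.
    """
    lam_arr = _check_lam(lam)
    lv = as_level(level)
    a2 = lv.tail_prob
    xl, xu = prediction_bounds(lam_arr, lv, TailRule.CONSERVATIVE)

    t_u = poisson.sf(xu - 1.0, lam_arr)       # P(X >= x_U) >= a2
    t_u1 = poisson.sf(xu, lam_arr)            # P(X >= x_U + 1) < a2
    upper = xu + (a2 - t_u1) / (t_u - t_u1)

    f_l = poisson.cdf(xl, lam_arr)            # F(x_L) >= a2
    f_l1 = poisson.cdf(xl - 1.0, lam_arr)     # F(x_L - 1) < a2
    lower = xl - (f_l - a2) / (f_l - f_l1)

    return LimitPair(
        float(lam), "prediction", lv, float(lower), float(upper),
        tail_rule=TailRule.CONSERVATIVE,
    )


def limits(
    lam: float,
    method: str,
    level: "float | NominalLevel",
    rule: TailRule = TailRule.CONSERVATIVE,
) -> LimitPair:
    """Dispatch to one of the three limit constructions by name."""
    if method == "wald":
        return wald_limits(lam, level)
    if method == "exact":
        return exact_limits(lam, level)
    if method == "prediction":
        return prediction_limits(lam, level, rule)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
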