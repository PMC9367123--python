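"""ROC-comparison sample-size calculation.

The variance of an estimated ROC area uses the Hanley-McNeil form

    V(A) = [A(1-A) + (n_pos-1)(Q1-A^2) + (n_neg-1)(Q2-A^2)] / (n_pos n_neg)

with Q1 = A/(2-A) and Q2 = 2A^2/(1+A). The required number of positives
for comparing two areas is the smallest n_pos at which the normal-
approximation z-test attains the requested power:

    power = Phi( |A1 - A0| / sqrt(V0 + V1 - 2 rho sqrt(V0 V1)) - z_alpha )

All planning assumptions (alpha sidedness, correlation between the two
area estimates, negative:positive allocation ratio) are explicit fields of
:class:`PowerSpec`. The defaults — two-sided alpha 0.05, correlation 0.15,
equal allocation — are the assumption set under which comparing areas of
0.80 and 0.85 at 80% power requires 463 positives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

_N_CAP = 1_000_000


@dataclass(frozen=True)
class PowerSpec:
    auc_null: float = 0.80
    auc_alt: float = 0.85
    alpha: float = 0.05
    power: float = 0.80
    neg_to_pos_ratio: float = 1.0
    correlation: float = 0.15
    sided: str = "two"  # "one" | "two"

    def __post_init__(self) -> None:
        if not 0.5 <= self.auc_null < 1.0:
            raise ValueError("auc_null must be in [0.5, 1)")
        if not self.auc_alt > self.auc_null:
            raise ValueError("auc_alt must exceed auc_null")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < self.power < 1.0:
            raise ValueError("power must be in (0, 1)")
        if self.neg_to_pos_ratio <= 0:
            raise ValueError("neg_to_pos_ratio must be positive")
        if not 0.0 <= self.correlation < 1.0:
            raise ValueError("correlation must be in [0, 1)")
        if self.sided not in ("one", "two"):
            raise ValueError("sided must be 'one' or 'two'")


def auc_variance(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil variance of an estimated ROC area."""
    if n_pos < 1 or n_neg < 1:
        raise ValueError("n_pos and n_neg must be >= 1")
    a = auc
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    return (
        a * (1.0 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)


def achieved_power(n_pos: int, spec: PowerSpec) -> float:
    """Power of the two-area comparison at ``n_pos`` positives."""
    n_neg = max(1, round(spec.neg_to_pos_ratio * n_pos))
    v0 = auc_variance(spec.auc_null, n_pos, n_neg)
    v1 = auc_variance(spec.auc_alt, n_pos, n_neg)
    var = v0 + v1 - 2.0 * spec.correlation * math.sqrt(v0 * v1)
    z_alpha = norm.ppf(
        1.0 - spec.alpha / (2.0 if spec.sided == "two" else 1.0)
    )
    return float(norm.cdf(abs(spec.auc_alt - spec.auc_null) / math.sqrt(var) - z_alpha))


def required_positives(spec: PowerSpec) -> int:
    """Smallest number of positives attaining the requested power.

    Power is monotone non-decreasing in the number of positives, so the
    answer is found by doubling to bracket and then bisecting.
    """
    lo, hi = 2, 2
    while achieved_power(hi, spec) < spec.power:
        lo, hi = hi, hi * 2
        if hi > _N_CAP:
            raise ValueError(
                f"required sample size exceeds {_N_CAP}: the difference "
                f"{spec.auc_alt - spec.auc_null:.4g} is too small to detect"
            )
    while lo < hi:
        mid = (lo + hi) // 2
        if achieved_power(mid, spec) >= spec.power:
            hi = mid
        else:
            lo = mid + 1
    return hi
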