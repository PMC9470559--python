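"""Exact inference on a binomial response rate after a Simon two-stage design.

Naive binomial inference (x/n with a Clopper–Pearson interval) is biased
after an adaptive two-stage rule because the sampling distribution of the
total response count depends on the interim stopping boundary.  This
module implements design-adjusted inference built on the two-stage tail
probability

    Q(p) = P(reach stage 2 and X1 + X2 >= x | p)          (stage 2 reached)
    Q(p) = P(X1 >= x1 | p)                                 (stopped at stage 1)

which is continuous and strictly increasing in p for x >= 1.  The
design-adjusted p-value is Q(p0); the point estimate is the median-unbiased
root Q(p) = 1/2; confidence bounds invert Q at the tail levels
(Koyama–Chen-style inversion of the stage-wise ordering); and the UMVUE is
the Girshick–Mosteller–Savage ratio of truncated binomial coefficient sums.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy.stats import binom

from .design import TwoStageDesign

__all__ = [
    "TrialOutcome",
    "InferenceResult",
    "pvalue_function",
    "design_pvalue",
    "median_unbiased_estimate",
    "confidence_interval",
    "umvue",
    "infer",
]

_BISECT_TOL = 1e-8
_BISECT_MAX_ITER = 200


@dataclass(frozen=True)
class TrialOutcome:
    """Observed result of a two-stage trial.

    ``total_responses`` is the total number of responders (x); when the
    trial stopped at stage 1, ``stage1_responses`` must be given and equal
    the total.
    """

    total_responses: int
    stopped_stage1: bool = False
    stage1_responses: int | None = None

    def __post_init__(self) -> None:
        if self.total_responses < 0:
            raise ValueError("total_responses must be >= 0")
        if self.stopped_stage1:
            if self.stage1_responses is None:
                raise ValueError("stage1_responses required when stopped_stage1")
            if self.stage1_responses != self.total_responses:
                raise ValueError("stage-1-stopped outcome must have x = x1")

    def validate_against(self, design: TwoStageDesign) -> None:
        x = self.total_responses
        if self.stopped_stage1:
            if self.stage1_responses > design.r1:
                raise ValueError(
                    f"stopped at stage 1 with x1={self.stage1_responses} > r1={design.r1}"
                )
        else:
            if x > design.n:
                raise ValueError(f"x={x} exceeds total sample size n={design.n}")
            if x <= design.r1:
                raise ValueError(
                    f"stage 2 claimed but total x={x} <= r1={design.r1}: stage-2 entry "
                    "requires more than r1 stage-1 responses"
                )


@dataclass(frozen=True)
class InferenceResult:
    """Design-adjusted inference summary for one trial outcome."""

    estimate: float
    umvue: float
    ci_lower: float
    ci_upper: float
    conf_level: float
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_lower <= self.estimate <= self.ci_upper <= 1.0):
            raise ValueError("confidence bounds must bracket the estimate within [0, 1]")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value must lie in [0, 1]")


def pvalue_function(outcome: TrialOutcome, design: TwoStageDesign, p: float) -> float:
    """Tail probability Q(p) of an outcome at least as extreme as observed.

    The stochastic ordering is stage-wise: after stage 2, "at least as
    extreme" means reaching stage 2 with a total at least the observed x;
    after a stage-1 stop it is the stage-1 binomial tail.  The observed
    outcome is included in the tail.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must be in [0, 1], got {p}")
    outcome.validate_against(design)
    if outcome.stopped_stage1:
        return float(binom.sf(outcome.stage1_responses - 1, design.n1, p))
    x = outcome.total_responses
    j = np.arange(design.r1 + 1, design.n1 + 1)
    # P(X2 >= x - j), with the tail = 1 when x - j <= 0
    tail = binom.sf(x - j - 1, design.n2, p)
    return float(np.sum(binom.pmf(j, design.n1, p) * tail))


def design_pvalue(outcome: TrialOutcome, design: TwoStageDesign, p0: float) -> float:
    """Design-adjusted p-value: Q evaluated at the null response rate."""
    return pvalue_function(outcome, design, p0)


def _invert_q(outcome: TrialOutcome, design: TwoStageDesign, target: float) -> float:
    """Solve Q(p) = target for p by bisection; Q is increasing in p."""
    lo, hi = 0.0, 1.0
    for _ in range(_BISECT_MAX_ITER):
        mid = 0.5 * (lo + hi)
        if pvalue_function(outcome, design, mid) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < _BISECT_TOL:
            break
    return 0.5 * (lo + hi)


def median_unbiased_estimate(outcome: TrialOutcome, design: TwoStageDesign) -> float:
    """Median-unbiased response-rate estimate: the root of Q(p) = 1/2.

    Returns 0 by convention when no responses were observed (the tail is
    degenerate: Q is identically 1).
    """
    outcome.validate_against(design)
    if outcome.total_responses == 0:
        return 0.0
    return _invert_q(outcome, design, 0.5)


def confidence_interval(
    outcome: TrialOutcome, design: TwoStageDesign, conf_level: float
) -> tuple[float, float]:
    """Two-sided design-adjusted confidence interval by inverting Q.

    With gamma = (1 - conf_level)/2 the lower bound solves Q(p) = gamma and
    the upper bound solves Q(p) = 1 - gamma; both by bisection.  For x = 0
    the lower bound is 0.
    """
    if not (0.0 < conf_level < 1.0):
        raise ValueError(f"conf_level must be in (0, 1), got {conf_level}")
    outcome.validate_against(design)
    gamma = (1.0 - conf_level) / 2.0
    if outcome.total_responses == 0:
        # Q is identically 1 with zero responses: the tail cannot be
        # inverted, so fall back to the exact (Clopper-Pearson) upper
        # bound for 0/n1 successes
        return (0.0, 1.0 - gamma ** (1.0 / design.n1))
    lower = _invert_q(outcome, design, gamma)
    upper = _invert_q(outcome, design, 1.0 - gamma)
    return (max(0.0, lower), min(1.0, upper))


def umvue(outcome: TrialOutcome, design: TwoStageDesign) -> float:
    """Uniformly minimum-variance unbiased estimate of the response rate.

    After stage 2 this is the ratio of truncated sums

        sum_j C(n1-1, j-1) C(n2, x-j)  /  sum_j C(n1, j) C(n2, x-j)

    over stage-1 counts j compatible with continuation and the observed
    total; after a stage-1 stop the stage-1 MLE x1/n1 is already unbiased.
    """
    outcome.validate_against(design)
    if outcome.stopped_stage1:
        return outcome.stage1_responses / design.n1
    x = outcome.total_responses
    n1, n2, r1 = design.n1, design.n2, design.r1
    j_lo = max(r1 + 1, x - n2)
    j_hi = min(n1, x)
    num = sum(comb(n1 - 1, j - 1) * comb(n2, x - j) for j in range(j_lo, j_hi + 1))
    den = sum(comb(n1, j) * comb(n2, x - j) for j in range(j_lo, j_hi + 1))
    return num / den


def infer(
    outcome: TrialOutcome,
    design: TwoStageDesign,
    p0: float,
    conf_level: float = 0.80,
) -> InferenceResult:
    """Full design-adjusted inference for one observed outcome."""
    lower, upper = confidence_interval(outcome, design, conf_level)
    est = median_unbiased_estimate(outcome, design)
    # bisection can leave the estimate a hair outside the bounds; clamp
    est = min(max(est, lower), upper)
    return InferenceResult(
        estimate=est,
        umvue=umvue(outcome, design),
        ci_lower=lower,
        ci_upper=upper,
        conf_level=conf_level,
        p_value=design_pvalue(outcome, design, p0),
    )
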