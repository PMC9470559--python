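"""Simon two-stage single-arm binomial designs.

A two-stage design ``(r1, n1, r, n)`` enrols ``n1`` patients, stops for
futility if at most ``r1`` of them respond, otherwise enrols ``n - n1``
more and declares success when the total number of responders exceeds
``r``.  The *minimax* design minimises the maximum sample size ``n``
among all designs meeting the type-I/type-II error constraints; the
*optimal* design minimises the expected sample size under the null
response probability.  All operating characteristics here are exact
binomial sums — no normal approximation anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

__all__ = [
    "DesignSpec",
    "TwoStageDesign",
    "DesignProperties",
    "DesignSearchError",
    "reject_probability",
    "prob_early_termination",
    "expected_sample_size",
    "design_properties",
    "search_designs",
]


class DesignSearchError(RuntimeError):
    """No feasible design exists within the search ceiling ``n_max``."""


@dataclass(frozen=True)
class DesignSpec:
    """Error-rate specification for a two-stage design search.

    Parameters
    ----------
    p0
        Unacceptable ("null") response probability.
    p1
        Target response probability under the alternative.
    alpha
        One-sided type-I error bound.
    beta
        Type-II error bound (power bound is ``1 - beta``).
    n_max
        Ceiling on the total sample size searched.
    """

    p0: float
    p1: float
    alpha: float
    beta: float
    n_max: int = 150

    def __post_init__(self) -> None:
        if not (0.0 <= self.p0 < self.p1 <= 1.0):
            raise ValueError(f"require 0 <= p0 < p1 <= 1, got p0={self.p0}, p1={self.p1}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not (0.0 < self.beta < 1.0):
            raise ValueError(f"beta must be in (0, 1), got {self.beta}")
        if self.n_max < 2:
            raise ValueError(f"n_max must be >= 2, got {self.n_max}")


@dataclass(frozen=True)
class TwoStageDesign:
    """Decision rule of a Simon two-stage design.

    Stop at stage 1 when stage-1 responses ``X1 <= r1``; reject the null
    (trial success) when total responses ``X1 + X2 > r``.
    """

    r1: int
    n1: int
    r: int
    n: int

    def __post_init__(self) -> None:
        if not (0 <= self.r1 <= self.n1 < self.n):
            raise ValueError(
                f"require 0 <= r1 <= n1 < n, got r1={self.r1}, n1={self.n1}, n={self.n}"
            )
        if not (self.r1 <= self.r <= self.n):
            raise ValueError(f"require r1 <= r <= n, got r1={self.r1}, r={self.r}, n={self.n}")

    @property
    def n2(self) -> int:
        """Stage-2 sample size."""
        return self.n - self.n1


@dataclass(frozen=True)
class DesignProperties:
    """Exact operating characteristics of a design at (p0, p1)."""

    attained_alpha: float
    attained_power: float
    pet_p0: float
    expected_n_p0: float


def _validate_p(p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"response probability must be in [0, 1], got {p}")


def reject_probability(design: TwoStageDesign, p: float) -> float:
    """Exact probability the design rejects the null at response rate ``p``.

    This is ``P(X1 > r1 and X1 + X2 > r)`` with ``X1 ~ Bin(n1, p)`` and
    ``X2 ~ Bin(n2, p)``, computed by summation over stage-1 outcomes.
    """
    _validate_p(p)
    x1 = np.arange(design.r1 + 1, design.n1 + 1)
    if x1.size == 0:
        return 0.0
    # P(X2 > r - x1) = sf(r - x1) with the convention sf(k) = 1 for k < 0
    tail = binom.sf(design.r - x1, design.n2, p)
    return float(np.sum(binom.pmf(x1, design.n1, p) * tail))


def prob_early_termination(design: TwoStageDesign, p: float) -> float:
    """Probability of stopping for futility at stage 1: ``P(X1 <= r1)``."""
    _validate_p(p)
    return float(binom.cdf(design.r1, design.n1, p))


def expected_sample_size(design: TwoStageDesign, p: float) -> float:
    """Expected number of patients enrolled: ``n1 + (1 - PET(p)) * n2``."""
    pet = prob_early_termination(design, p)
    return design.n1 + (1.0 - pet) * design.n2


def design_properties(design: TwoStageDesign, spec: DesignSpec) -> DesignProperties:
    """Exact operating characteristics of ``design`` under ``spec``."""
    return DesignProperties(
        attained_alpha=reject_probability(design, spec.p0),
        attained_power=reject_probability(design, spec.p1),
        pet_p0=prob_early_termination(design, spec.p0),
        expected_n_p0=expected_sample_size(design, spec.p0),
    )


def _feasible_designs_at_n(n: int, spec: DesignSpec):
    """Yield (design, alpha, power, en0) for every feasible rule with total n.

    For fixed (n1, r1) the rejection probability is non-increasing in r, so
    only the smallest r meeting the alpha bound can also meet the power
    bound; larger r are pruned.
    """
    for n1 in range(1, n):
        n2 = n - n1
        x1 = np.arange(0, n1 + 1)
        pmf0 = binom.pmf(x1, n1, spec.p0)
        pmf1 = binom.pmf(x1, n1, spec.p1)
        # sf_at[k] = P(X2 > k) for k in -1..n2, indexed by k+1
        k = np.arange(-1, n2 + 1)
        sf0 = binom.sf(k, n2, spec.p0)
        sf1 = binom.sf(k, n2, spec.p1)
        for r1 in range(0, n1 + 1):
            cont = np.arange(r1 + 1, n1 + 1)  # stage-1 counts that continue
            if cont.size == 0:
                continue
            w0 = pmf0[cont]
            w1 = pmf1[cont]
            # alpha(r) decreasing in r: find smallest r with alpha <= bound
            lo, hi = r1, n
            # alpha at r = n is 0 (cannot exceed n), always feasible
            while lo < hi:
                mid = (lo + hi) // 2
                a = float(np.sum(w0 * sf0[np.clip(mid - cont, -1, n2) + 1]))
                if a <= spec.alpha:
                    hi = mid
                else:
                    lo = mid + 1
            r = lo
            alpha = float(np.sum(w0 * sf0[np.clip(r - cont, -1, n2) + 1]))
            power = float(np.sum(w1 * sf1[np.clip(r - cont, -1, n2) + 1]))
            if power >= 1.0 - spec.beta:
                design = TwoStageDesign(r1=r1, n1=n1, r=r, n=n)
                pet0 = float(binom.cdf(r1, n1, spec.p0))
                en0 = n1 + (1.0 - pet0) * n2
                yield design, alpha, power, en0


def search_designs(spec: DesignSpec) -> dict[str, tuple[TwoStageDesign, DesignProperties]]:
    """Exhaustively search for the minimax and optimal two-stage designs.

    Returns a dict with keys ``"minimax"`` and ``"optimal"``, each mapping
    to a ``(TwoStageDesign, DesignProperties)`` pair.  Minimax minimises
    total ``n`` (ties broken by expected sample size at ``p0``, then by
    ``n1``); optimal minimises expected sample size at ``p0`` over all
    feasible designs with ``n <= n_max``.

    Raises
    ------
    DesignSearchError
        If no design with ``n <= n_max`` meets both error bounds.
    """
    minimax: tuple | None = None  # key (n, en0, n1) -> (design, alpha, power)
    optimal: tuple | None = None  # key (en0, n, n1)
    for n in range(2, spec.n_max + 1):
        for design, alpha, power, en0 in _feasible_designs_at_n(n, spec):
            key_mm = (design.n, en0, design.n1)
            if minimax is None or key_mm < minimax[0]:
                minimax = (key_mm, design, alpha, power)
            key_opt = (en0, design.n, design.n1)
            if optimal is None or key_opt < optimal[0]:
                optimal = (key_opt, design, alpha, power)
    if minimax is None or optimal is None:
        raise DesignSearchError(
            f"search ceiling exceeded: no feasible two-stage design with n <= {spec.n_max} "
            f"for p0={spec.p0}, p1={spec.p1}, alpha={spec.alpha}, beta={spec.beta}"
        )

    def with_props(entry) -> tuple[TwoStageDesign, DesignProperties]:
        _, design, alpha, power = entry
        return design, DesignProperties(
            attained_alpha=alpha,
            attained_power=power,
            pet_p0=prob_early_termination(design, spec.p0),
            expected_n_p0=expected_sample_size(design, spec.p0),
        )

    return {"minimax": with_props(minimax), "optimal": with_props(optimal)}
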