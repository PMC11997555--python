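"""Bulk-to-transduced-cell VCN adjustment and per-cell VCN distributions.

The bulk VCN averages over every cell in the product, transduced or not,
and so understates the copy load of the cells that actually carry
vector.  Under a Poisson model of integration — each cell receives
k ~ Poisson(lambda) copies, independently and with equal susceptibility
— the bulk VCN estimates lambda, the fraction of transduced cells
(k >= 1) is 1 - e^-lambda, and the mean copy number among transduced
cells is the zero-truncated Poisson mean:

    VCN_adj = VCN_bulk / (1 - e^-VCN_bulk)

with 1 - e^-VCN_bulk the putative transduction efficiency.  VCN_adj is
always >= max(1, VCN_bulk): a transduced cell has at least one copy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "VCNDistribution",
    "adjust_vcn",
    "vcn_distribution",
    "untransduced_fraction_check",
    "UntransducedCheck",
]

_TAIL_TOL = 1e-9  # internal support extension target for normalisation
_DISPLAY_CDF = 0.9999  # default displayed support covers this much mass


@dataclass
class VCNDistribution:
    """Per-cell VCN probability table under the Poisson copy model.

    The all-cells variant (``truncated=False``) uses lambda = VCN_bulk
    and includes VCN = 0 (untransduced cells); the zero-truncated
    variant describes transduced cells only and has mean VCN_adj.
    """

    lam: float
    support_max: int
    pmf: dict[int, float]
    cdf: dict[int, float]
    truncated: bool

    def mean(self) -> float:
        """Mean over the full (internally extended) support."""
        if self.truncated:
            return self.lam / (1.0 - math.exp(-self.lam))
        return self.lam

    def fraction_above(self, k: int) -> float:
        """Fraction of cells with VCN strictly greater than k."""
        if k in self.cdf:
            return 1.0 - self.cdf[k]
        if k < 0:
            return 1.0
        # beyond displayed support: recompute from the exact Poisson tail
        tail = float(stats.poisson.sf(k, self.lam))
        if self.truncated:
            tail /= 1.0 - math.exp(-self.lam)
        return tail


def adjust_vcn(vcn_bulk: float) -> tuple[float, float]:
    """Adjust bulk VCN to per-transduced-cell VCN.

    Returns ``(vcn_adj, transduction_putative)``.  A bulk VCN of zero
    means no vector was detected: the transduced-cell VCN is undefined
    and reported as NaN with transduction 0 (not the mathematical limit
    1 — there is no transduced population to describe).
    """
    if vcn_bulk < 0:
        raise ValueError("vcn_bulk must be non-negative")
    if vcn_bulk == 0:
        return float("nan"), 0.0
    transduction = -math.expm1(-vcn_bulk)  # 1 - e^-x, accurate for small x
    return vcn_bulk / transduction, transduction


def vcn_distribution(
    lam: float, support_max: int | None = None, truncated: bool = False
) -> VCNDistribution:
    """Poisson (or zero-truncated Poisson) pmf and cdf of per-cell VCN.

    ``support_max`` controls the displayed table only; internally the
    support is extended until the cdf reaches 1 - 1e-9 so that
    normalisation is meaningful.  Defaults to the smallest k with
    cdf >= 0.9999.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    if support_max is not None and support_max < 1:
        raise ValueError("support_max must be >= 1")

    norm = -math.expm1(-lam) if truncated else 1.0
    k_full = int(stats.poisson.isf(_TAIL_TOL, lam)) + 2
    ks = np.arange(0, k_full + 1)
    pmf_full = stats.poisson.pmf(ks, lam)
    if truncated:
        pmf_full = pmf_full / norm
        pmf_full[0] = 0.0
    cdf_full = np.cumsum(pmf_full)

    if support_max is None:
        support_max = int(np.searchsorted(cdf_full, _DISPLAY_CDF))
        support_max = max(support_max, 1)
    kmax = min(support_max, k_full)
    return VCNDistribution(
        lam=lam,
        support_max=support_max,
        pmf={int(k): float(pmf_full[k]) for k in range(kmax + 1)},
        cdf={int(k): float(cdf_full[k]) for k in range(kmax + 1)},
        truncated=truncated,
    )


@dataclass
class UntransducedCheck:
    """Poisson-predicted vs flow-measured untransduced (VCN = 0) fractions."""

    theoretical_negative: float
    flow_negative: float
    difference: float  # theoretical - flow
    theory_exceeds_flow: bool  # unexpected direction: assay/flow inconsistency


def untransduced_fraction_check(
    vcn_bulk: float, flow_negative_fraction: float
) -> UntransducedCheck:
    """Compare e^-VCN_bulk with the flow-cytometry negative fraction.

    Vector-containing cells can fail to express detectable marker, so
    the Poisson prediction is expected to sit below the flow value; the
    reverse direction is flagged.
    """
    if vcn_bulk < 0:
        raise ValueError("vcn_bulk must be non-negative")
    if not 0 <= flow_negative_fraction <= 1:
        raise ValueError("flow_negative_fraction must lie in [0, 1]")
    theo = math.exp(-vcn_bulk)
    return UntransducedCheck(
        theoretical_negative=theo,
        flow_negative=flow_negative_fraction,
        difference=theo - flow_negative_fraction,
        theory_exceeds_flow=theo > flow_negative_fraction,
    )
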