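"""Poisson inversion of droplet counts and bulk vector copy number.

With template molecules partitioned independently into droplets of
volume V, the number per droplet is Poisson with rate lambda = c * V,
so the negative-droplet fraction estimates e^-lambda and

    c = -ln(n_negative / n_total) / V        [copies/ul of reaction mix]

The bulk VCN is the target-to-reference concentration ratio scaled by
two reference copies per diploid cell:

    VCN_bulk = 2 * c_WPRE / c_TERT
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ConcentrationEstimate",
    "VCNResult",
    "estimate_concentration",
    "compute_vcn_bulk",
    "aggregate_replicates",
    "SaturationError",
    "ReferenceFailureError",
]

#: Wells with fewer accepted droplets than this are flagged, not rejected.
DEFAULT_MIN_ACCEPTED_DROPLETS = 10000


class SaturationError(ValueError):
    """All droplets positive: concentration unbounded above."""


class ReferenceFailureError(ValueError):
    """Reference channel has zero concentration: no quantifiable genome input."""


@dataclass
class ConcentrationEstimate:
    """Absolute concentration with a 95% CI, in copies/ul of reaction mix."""

    copies_per_ul: float
    ci_low: float
    ci_high: float
    n_accepted: int
    n_negative: int
    droplet_volume_ul: float

    def __post_init__(self) -> None:
        if not self.ci_low <= self.copies_per_ul <= self.ci_high:
            raise ValueError("CI must bracket the point estimate")
        if not 0 <= self.n_negative <= self.n_accepted:
            raise ValueError("negative count must lie in [0, n_accepted]")
        if self.copies_per_ul < 0:
            raise ValueError("concentration must be non-negative")


@dataclass
class VCNResult:
    """Bulk and transduced-cell VCN for one sample (adjustment filled by refine)."""

    sample_id: str
    vcn_bulk: float
    wpre: ConcentrationEstimate | None = None
    tert: ConcentrationEstimate | None = None
    vcn_bulk_ci: tuple[float, float] | None = None
    vcn_adj: float = float("nan")
    transduction_putative: float = float("nan")
    qc_flags: set[str] = field(default_factory=set)
    replicate_sd: float = float("nan")
    replicate_cv_pct: float = float("nan")
    n_replicates: int = 1


def estimate_concentration(
    counts_negative: int,
    counts_total: int,
    droplet_volume_ul: float,
) -> ConcentrationEstimate:
    """Invert the negative-droplet fraction to copies/ul.

    The 95% CI is a Wilson score interval on the negative fraction mapped
    through -ln(.)/V; the map is decreasing, so the endpoints swap.
    """
    if counts_total < 1:
        raise ValueError("empty well: counts_total must be >= 1")
    if not 0 <= counts_negative <= counts_total:
        raise ValueError("counts_negative must lie in [0, counts_total]")
    if droplet_volume_ul <= 0:
        raise ValueError("droplet_volume_ul must be positive")
    if counts_negative == 0:
        raise SaturationError(
            "no negative droplets: concentration is unbounded; dilute the sample"
        )

    p_neg = counts_negative / counts_total
    conc = -math.log(p_neg) / droplet_volume_ul

    p_lo, p_hi = proportion_confint(
        counts_negative, counts_total, alpha=0.05, method="wilson"
    )
    ci_high = -math.log(p_lo) / droplet_volume_ul if p_lo > 0 else math.inf
    ci_low = -math.log(min(p_hi, 1.0)) / droplet_volume_ul
    ci_low = max(ci_low, 0.0)
    return ConcentrationEstimate(
        copies_per_ul=conc,
        ci_low=ci_low,
        ci_high=ci_high,
        n_accepted=counts_total,
        n_negative=counts_negative,
        droplet_volume_ul=droplet_volume_ul,
    )


def compute_vcn_bulk(
    wpre: ConcentrationEstimate,
    tert: ConcentrationEstimate,
    sample_id: str = "",
    lloq: float | None = None,
    min_accepted_droplets: int = DEFAULT_MIN_ACCEPTED_DROPLETS,
) -> VCNResult:
    """VCN_bulk = 2 x WPRE / TERT, with a conservative endpoint-ratio CI."""
    if tert.copies_per_ul == 0:
        raise ReferenceFailureError(
            "reference concentration is zero: no quantifiable genome input"
        )
    vcn = 2.0 * wpre.copies_per_ul / tert.copies_per_ul
    ci = (
        2.0 * wpre.ci_low / tert.ci_high if tert.ci_high > 0 else 0.0,
        2.0 * wpre.ci_high / tert.ci_low if tert.ci_low > 0 else math.inf,
    )
    flags: set[str] = set()
    if lloq is not None and wpre.copies_per_ul < lloq:
        flags.add("below_lloq")
    if min(wpre.n_accepted, tert.n_accepted) < min_accepted_droplets:
        flags.add("low_droplet_count")
    return VCNResult(
        sample_id=sample_id,
        vcn_bulk=vcn,
        wpre=wpre,
        tert=tert,
        vcn_bulk_ci=ci,
        qc_flags=flags,
    )


def aggregate_replicates(results: list[VCNResult]) -> VCNResult:
    """Combine replicate wells of one sample.

    The point estimate is the accepted-droplet-weighted mean of the
    replicate VCN_bulk values (more droplets carry more information);
    dispersion is the unweighted sample SD and CV% across replicates.
    """
    if len(results) == 0:
        raise ValueError("need at least one replicate")
    ids = {r.sample_id for r in results}
    if len(ids) > 1:
        raise ValueError(f"mixed sample ids in replicates: {sorted(ids)}")
    vcns = np.array([r.vcn_bulk for r in results], dtype=float)
    weights = np.array(
        [
            min(r.wpre.n_accepted, r.tert.n_accepted)
            if r.wpre is not None and r.tert is not None
            else 1.0
            for r in results
        ],
        dtype=float,
    )
    mean = float(np.average(vcns, weights=weights))
    flags = set().union(*(r.qc_flags for r in results))
    if len(results) == 1:
        sd = float("nan")
        cv = float("nan")
        flags.add("single_replicate")
    else:
        sd = float(np.std(vcns, ddof=1))
        cv = 100.0 * sd / mean if mean != 0 else float("nan")
    return VCNResult(
        sample_id=results[0].sample_id,
        vcn_bulk=mean,
        qc_flags=flags,
        replicate_sd=sd,
        replicate_cv_pct=cv,
        n_replicates=len(results),
    )
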