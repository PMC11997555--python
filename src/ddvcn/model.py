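"""Model/Results facade over the assay pipeline.

`VCNModel` holds the droplet data for one sample (one or more replicate
wells) and the assay settings; `fit()` runs thresholding, cluster
calling, Poisson inversion and the transduced-cell adjustment, and
returns a `VCNResults` carrying the estimates, their confidence
intervals, QC diagnostics, the per-cell VCN distribution, and a
`summary()` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import calling, quantify, refine
from .calling import DropletWell
from .limits import AssayLimits, flag_below_limits
from .quantify import VCNResult

__all__ = ["VCNModel", "VCNResults"]


class VCNModel:
    """Duplex ddPCR vector-copy-number model for one sample.

    Parameters
    ----------
    wells
        Replicate droplet wells of the same sample.  FAM is the target
        (vector) channel, HEX the diploid reference channel.
    droplet_volume_ul
        Partition volume used for Poisson inversion (default 0.85 nl).
    threshold_method
        "otsu", "midpoint" or "manual" (then fam/hex_threshold required).
    limits
        Optional assay limits; the target concentration of each well is
        flagged against them.
    """

    def __init__(
        self,
        wells: list[DropletWell] | DropletWell,
        droplet_volume_ul: float = 0.00085,
        threshold_method: str = "otsu",
        fam_threshold: float | None = None,
        hex_threshold: float | None = None,
        min_accepted_droplets: int = quantify.DEFAULT_MIN_ACCEPTED_DROPLETS,
        limits: AssayLimits | None = None,
    ):
        if isinstance(wells, DropletWell):
            wells = [wells]
        if len(wells) == 0:
            raise ValueError("need at least one well")
        ids = {w.sample_id for w in wells}
        if len(ids) > 1:
            raise ValueError(f"wells belong to different samples: {sorted(ids)}")
        self.wells = wells
        self.sample_id = wells[0].sample_id
        self.droplet_volume_ul = droplet_volume_ul
        self.threshold_method = threshold_method
        self.fam_threshold = fam_threshold
        self.hex_threshold = hex_threshold
        self.min_accepted_droplets = min_accepted_droplets
        self.limits = limits

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        fam_column: str = "Ch1 Amplitude",
        hex_column: str = "Ch2 Amplitude",
        sample_id: str = "sample",
        **kwargs,
    ) -> "VCNModel":
        """Build from a droplet table with one row per droplet."""
        well = DropletWell(
            well_id=sample_id,
            sample_id=sample_id,
            fam_amplitudes=df[fam_column].to_numpy(dtype=float),
            hex_amplitudes=df[hex_column].to_numpy(dtype=float),
        )
        return cls(well, **kwargs)

    def _thresholds(self, well: DropletWell) -> tuple[float, float]:
        if self.threshold_method == "manual":
            if self.fam_threshold is None or self.hex_threshold is None:
                raise ValueError("manual thresholding needs fam_threshold and hex_threshold")
            return self.fam_threshold, self.hex_threshold
        fam = calling.set_threshold(well.fam_amplitudes, method=self.threshold_method)
        hex_ = calling.set_threshold(well.hex_amplitudes, method=self.threshold_method)
        return fam, hex_

    def fit(self) -> "VCNResults":
        per_well = []
        reps: list[VCNResult] = []
        for well in self.wells:
            fam_t, hex_t = self._thresholds(well)
            counts = calling.classify_droplets(well, fam_t, hex_t)
            wpre = quantify.estimate_concentration(
                counts.n_fam_negative, counts.n_total, self.droplet_volume_ul
            )
            tert = quantify.estimate_concentration(
                counts.n_hex_negative, counts.n_total, self.droplet_volume_ul
            )
            res = quantify.compute_vcn_bulk(
                wpre,
                tert,
                sample_id=well.sample_id,
                lloq=self.limits.lloq if self.limits is not None else None,
                min_accepted_droplets=self.min_accepted_droplets,
            )
            if self.limits is not None:
                res.qc_flags |= flag_below_limits(wpre, self.limits)
            reps.append(res)
            per_well.append(
                {
                    "well_id": well.well_id,
                    "n_accepted": counts.n_total,
                    "fam_threshold": fam_t,
                    "hex_threshold": hex_t,
                    "n_fam_positive": counts.n_fam_positive,
                    "n_hex_positive": counts.n_hex_positive,
                    "wpre_copies_per_ul": wpre.copies_per_ul,
                    "tert_copies_per_ul": tert.copies_per_ul,
                    "vcn_bulk": res.vcn_bulk,
                    "qc_flags": ";".join(sorted(res.qc_flags)),
                }
            )
        combined = quantify.aggregate_replicates(reps) if len(reps) > 1 else reps[0]
        vcn_adj, transduction = refine.adjust_vcn(combined.vcn_bulk)
        combined.vcn_adj = vcn_adj
        combined.transduction_putative = transduction
        distribution = (
            refine.vcn_distribution(combined.vcn_bulk) if combined.vcn_bulk > 0 else None
        )
        return VCNResults(
            model=self,
            result=combined,
            replicates=reps,
            per_well=pd.DataFrame.from_records(per_well),
            distribution=distribution,
        )


@dataclass
class VCNResults:
    """Fitted VCN estimates with diagnostics for one sample."""

    model: VCNModel
    result: VCNResult
    replicates: list[VCNResult]
    per_well: pd.DataFrame
    distribution: refine.VCNDistribution | None

    @property
    def vcn_bulk(self) -> float:
        return self.result.vcn_bulk

    @property
    def vcn_adj(self) -> float:
        return self.result.vcn_adj

    @property
    def transduction_putative(self) -> float:
        return self.result.transduction_putative

    @property
    def qc_flags(self) -> set[str]:
        return self.result.qc_flags

    def transduced_distribution(self, support_max: int | None = None) -> refine.VCNDistribution:
        """Zero-truncated per-cell VCN distribution (transduced cells)."""
        return refine.vcn_distribution(
            self.result.vcn_bulk, support_max=support_max, truncated=True
        )

    def summary(self) -> str:
        r = self.result
        lines = [
            "Duplex ddPCR VCN estimates",
            "=" * 46,
            f"sample:                  {r.sample_id}",
            f"replicate wells:         {r.n_replicates}",
            f"VCN_bulk (copies/cell):  {r.vcn_bulk:.2f}",
        ]
        if r.vcn_bulk_ci is not None:
            lines.append(
                f"  95% CI:                [{r.vcn_bulk_ci[0]:.2f}, {r.vcn_bulk_ci[1]:.2f}]"
            )
        if not math.isnan(r.replicate_cv_pct):
            lines.append(f"  inter-replicate CV%:   {r.replicate_cv_pct:.1f}")
        adj = "undefined (no vector detected)" if math.isnan(r.vcn_adj) else f"{r.vcn_adj:.2f}"
        lines += [
            f"VCN_adj (copies/transduced cell): {adj}",
            f"putative transduction:   {r.transduction_putative:.1%}",
            f"QC flags:                {', '.join(sorted(r.qc_flags)) or 'none'}",
            "-" * 46,
            self.per_well.to_string(index=False),
        ]
        return "\n".join(lines)
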