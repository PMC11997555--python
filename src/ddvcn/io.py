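"""File formats: droplet amplitude CSVs, plate configuration, reports.

Droplet CSVs follow the instrument-export dialect: one row per droplet,
columns "Ch1 Amplitude" (FAM) and "Ch2 Amplitude" (HEX); an optional
cluster column is ignored on read.  Plate configuration is YAML or JSON.
Reports are JSON or CSV with deterministic field order; VCN values are
printed to 2 decimals with full precision kept in a parallel field.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .calling import DropletWell
from .limits import AssayLimits
from .quantify import VCNResult

__all__ = [
    "PlateConfig",
    "WellConfig",
    "read_droplet_csv",
    "write_droplet_csv",
    "read_plate_config",
    "write_report",
]

FAM_COLUMN = "Ch1 Amplitude"
HEX_COLUMN = "Ch2 Amplitude"

_ROLES = {"sample", "ntc", "non_transduced_control"}


@dataclass
class WellConfig:
    well_id: str
    sample_id: str
    role: str = "sample"
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"unknown well role: {self.role!r}")
        if not 0 < self.dilution_factor <= 1:
            raise ValueError("dilution_factor must lie in (0, 1]")


@dataclass
class PlateConfig:
    """Plate layout plus assay-wide settings."""

    wells: list[WellConfig]
    droplet_volume_ul: float = 0.00085
    min_accepted_droplets: int = 10000
    threshold_method: str = "otsu"
    channel_map: dict[str, str] = field(
        default_factory=lambda: {"target": "FAM", "reference": "HEX"}
    )

    def __post_init__(self) -> None:
        ids = [w.well_id for w in self.wells]
        if len(ids) != len(set(ids)):
            raise ValueError("well_ids must be unique")
        if set(self.channel_map.keys()) != {"target", "reference"}:
            raise ValueError("channel_map must name exactly a target and a reference")
        if set(self.channel_map.values()) != {"FAM", "HEX"}:
            raise ValueError("channel_map must assign FAM and HEX")


def read_plate_config(path) -> PlateConfig:
    """Load a PlateConfig from YAML or JSON (by extension)."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    wells = [WellConfig(**w) for w in raw.get("wells", [])]
    assay = raw.get("assay", {})
    kwargs = {}
    for key in ("droplet_volume_ul", "min_accepted_droplets", "threshold_method", "channel_map"):
        if key in assay:
            kwargs[key] = assay[key]
    return PlateConfig(wells=wells, **kwargs)


def read_droplet_csv(
    path,
    well_id: str = "",
    sample_id: str = "",
    dilution_factor: float = 1.0,
    is_blank: bool = False,
    fam_column: str = FAM_COLUMN,
    hex_column: str = HEX_COLUMN,
) -> DropletWell:
    """Read a per-well droplet amplitude CSV into a DropletWell."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty droplet file") from None
    for col in (fam_column, hex_column):
        if col not in df.columns:
            raise ValueError(
                f"{path}: missing amplitude column {col!r} "
                f"(found: {list(df.columns)})"
            )
    if len(df) == 0:
        raise ValueError(f"{path}: no droplet rows")
    fam = pd.to_numeric(df[fam_column], errors="coerce")
    hex_ = pd.to_numeric(df[hex_column], errors="coerce")
    if fam.isna().any() or hex_.isna().any():
        raise ValueError(f"{path}: non-numeric amplitude values")
    return DropletWell(
        well_id=well_id or path.stem,
        sample_id=sample_id or path.stem,
        fam_amplitudes=fam.to_numpy(dtype=float),
        hex_amplitudes=hex_.to_numpy(dtype=float),
        dilution_factor=dilution_factor,
        is_blank=is_blank,
    )


def write_droplet_csv(well: DropletWell, path) -> None:
    """Write a well's amplitudes in the instrument-export dialect."""
    pd.DataFrame(
        {FAM_COLUMN: well.fam_amplitudes, HEX_COLUMN: well.hex_amplitudes}
    ).to_csv(path, index=False, float_format="%.17g")


def _round2(x: float) -> float | None:
    return None if x is None or (isinstance(x, float) and math.isnan(x)) else round(x, 2)


def _result_record(r: VCNResult) -> dict:
    rec = {
        "sample_id": r.sample_id,
        "vcn_bulk": _round2(r.vcn_bulk),
        "vcn_adj": _round2(r.vcn_adj),
        "transduction_putative": _round2(r.transduction_putative),
        "vcn_bulk_full": r.vcn_bulk,
        "vcn_adj_full": None if math.isnan(r.vcn_adj) else r.vcn_adj,
        "transduction_putative_full": None
        if math.isnan(r.transduction_putative)
        else r.transduction_putative,
        "wpre_copies_per_ul": r.wpre.copies_per_ul if r.wpre else None,
        "wpre_ci_low": r.wpre.ci_low if r.wpre else None,
        "wpre_ci_high": r.wpre.ci_high if r.wpre else None,
        "tert_copies_per_ul": r.tert.copies_per_ul if r.tert else None,
        "tert_ci_low": r.tert.ci_low if r.tert else None,
        "tert_ci_high": r.tert.ci_high if r.tert else None,
        "replicate_sd": None if math.isnan(r.replicate_sd) else r.replicate_sd,
        "replicate_cv_pct": None if math.isnan(r.replicate_cv_pct) else r.replicate_cv_pct,
        "n_replicates": r.n_replicates,
        "qc_flags": ";".join(sorted(r.qc_flags)),
    }
    return rec


def write_report(
    results: list[VCNResult],
    path,
    limits: AssayLimits | None = None,
    linearity=None,
    repeatability=None,
    distributions: dict | None = None,
    format: str = "json",
) -> None:
    """Write the per-sample VCN report as JSON or CSV.

    The CSV holds the per-sample table only; the JSON additionally
    carries assay limits, validation reports, and per-sample VCN
    distribution tables when supplied.
    """
    if len(results) == 0:
        raise ValueError("no results to report")
    records = [_result_record(r) for r in results]
    path = Path(path)
    if format == "csv":
        pd.DataFrame.from_records(records).to_csv(path, index=False)
        return
    if format != "json":
        raise ValueError(f"unknown report format: {format!r}")
    doc: dict = {"samples": records}
    if limits is not None:
        doc["limits"] = {
            "lob": limits.lob,
            "llod": limits.llod,
            "lloq": limits.lloq,
            "mean_blank": limits.mean_blank,
            "sd_blank": limits.sd_blank,
            "lowest_dilution_tested": limits.lowest_dilution_tested,
            "n_blanks": limits.n_blanks,
        }
    if linearity is not None:
        doc["linearity"] = {
            "slope": linearity.slope,
            "intercept": linearity.intercept,
            "r_squared": linearity.r_squared,
            "scale": linearity.scale,
            "n_points": linearity.n_points,
        }
    if repeatability is not None:
        doc["repeatability"] = {
            "per_condition_cv": repeatability.per_condition_cv,
            "max_cv": repeatability.max_cv,
            "n_timepoints": repeatability.n_timepoints,
        }
    if distributions is not None:
        doc["distributions"] = {
            sid: {
                "lam": d.lam,
                "truncated": d.truncated,
                "support_max": d.support_max,
                "pmf": {str(k): v for k, v in d.pmf.items()},
                "cdf": {str(k): v for k, v in d.cdf.items()},
            }
            for sid, d in distributions.items()
        }
    path.write_text(json.dumps(doc, indent=2, sort_keys=False) + "\n")
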