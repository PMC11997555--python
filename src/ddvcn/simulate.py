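"""Synthetic droplet wells and cell products with known ground truth.

Stands in for the droplet generator / reader: each droplet receives an
independent Poisson number of target (WPRE, FAM channel) and reference
(TERT, HEX channel) template molecules at rate ``concentration x droplet
volume``, and its channel amplitude is drawn from a positive Gaussian if
it holds at least one copy, a negative Gaussian otherwise.  An optional
"rain" fraction of droplets is drawn uniformly between the two cluster
means instead.  Target and reference occupancy are independent: the
assay digests the genome with EcoRI before partitioning, placing the two
loci on distinct fragments (the target amplicon carries no EcoRI site).

The cell-product generator draws per-cell integrated vector copy numbers
from a Poisson distribution — the model under which the bulk-to-transduced
VCN adjustment is exact — and exposes the template totals a real product
would contribute to a reaction (two reference copies per diploid cell).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .calling import DropletWell

__all__ = [
    "SimConfig",
    "CellProductConfig",
    "CellProduct",
    "simulate_well",
    "simulate_dilution_series",
    "simulate_cell_product",
]

#: QX200 convention; the droplet volume used for Poisson inversion.
DEFAULT_DROPLET_VOLUME_UL = 0.00085


@dataclass
class SimConfig:
    """Parameters for one simulated duplex well.

    Concentrations are in copies/ul of reaction mix; amplitudes are in
    arbitrary fluorescence units.  Defaults give cleanly separated
    clusters (negative mean 1000, positive mean 8000, SD 400).
    """

    wpre_conc: float
    tert_conc: float
    seed: int
    n_droplets: int = 20000
    droplet_volume_ul: float = DEFAULT_DROPLET_VOLUME_UL
    fam_neg_mean: float = 1000.0
    fam_pos_mean: float = 8000.0
    fam_sd: float = 400.0
    hex_neg_mean: float = 1000.0
    hex_pos_mean: float = 8000.0
    hex_sd: float = 400.0
    rain_fraction: float = 0.0
    well_id: str = "A01"
    sample_id: str = "sim"
    dilution_factor: float = 1.0
    is_blank: bool = False

    def __post_init__(self) -> None:
        if self.n_droplets < 1:
            raise ValueError("n_droplets must be >= 1")
        if self.droplet_volume_ul <= 0:
            raise ValueError("droplet_volume_ul must be positive")
        if self.wpre_conc < 0 or self.tert_conc < 0:
            raise ValueError("concentrations must be non-negative")
        if self.fam_pos_mean <= self.fam_neg_mean or self.hex_pos_mean <= self.hex_neg_mean:
            raise ValueError("positive cluster mean must exceed negative cluster mean")
        if not 0 <= self.rain_fraction < 1:
            raise ValueError("rain_fraction must lie in [0, 1)")
        if self.fam_sd <= 0 or self.hex_sd <= 0:
            raise ValueError("amplitude SDs must be positive")


@dataclass
class CellProductConfig:
    """Per-cell copy model: k_i ~ Poisson(lambda_vcn) over n_cells cells."""

    n_cells: int
    lambda_vcn: float
    seed: int

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.lambda_vcn < 0:
            raise ValueError("lambda_vcn must be non-negative")


@dataclass
class CellProduct:
    """A simulated cell product with per-cell ground truth."""

    copies_per_cell: np.ndarray
    transduced_fraction: float
    mean_vcn_transduced: float  # NaN when no cell is transduced
    wpre_total: int
    tert_total: int

    @property
    def n_cells(self) -> int:
        return len(self.copies_per_cell)

    @property
    def mean_vcn_all(self) -> float:
        return float(np.mean(self.copies_per_cell))

    def to_sim_config(self, tert_conc: float, seed: int, **kwargs) -> SimConfig:
        """Reaction-mix concentrations preserving the product's WPRE:TERT ratio.

        The absolute scale is set by the reference concentration (how much
        gDNA was loaded); the target concentration follows from the
        template ratio, which is what the VCN ratio measures.
        """
        wpre_conc = tert_conc * self.wpre_total / self.tert_total
        return SimConfig(wpre_conc=wpre_conc, tert_conc=tert_conc, seed=seed, **kwargs)


def _channel_amplitudes(
    rng: np.random.Generator,
    occupied: np.ndarray,
    neg_mean: float,
    pos_mean: float,
    sd: float,
    rain_fraction: float,
) -> np.ndarray:
    n = len(occupied)
    amps = np.where(
        occupied,
        rng.normal(pos_mean, sd, size=n),
        rng.normal(neg_mean, sd, size=n),
    )
    if rain_fraction > 0:
        rain = rng.random(n) < rain_fraction
        amps[rain] = rng.uniform(neg_mean, pos_mean, size=int(rain.sum()))
    return amps


def simulate_well(config: SimConfig) -> DropletWell:
    """Simulate one duplex well; hidden occupancy kept for testing."""
    rng = np.random.default_rng(config.seed)
    lam_wpre = config.wpre_conc * config.droplet_volume_ul
    lam_tert = config.tert_conc * config.droplet_volume_ul
    k_wpre = rng.poisson(lam_wpre, size=config.n_droplets)
    k_tert = rng.poisson(lam_tert, size=config.n_droplets)
    fam = _channel_amplitudes(
        rng, k_wpre >= 1, config.fam_neg_mean, config.fam_pos_mean,
        config.fam_sd, config.rain_fraction,
    )
    hex_ = _channel_amplitudes(
        rng, k_tert >= 1, config.hex_neg_mean, config.hex_pos_mean,
        config.hex_sd, config.rain_fraction,
    )
    return DropletWell(
        well_id=config.well_id,
        sample_id=config.sample_id,
        fam_amplitudes=fam,
        hex_amplitudes=hex_,
        dilution_factor=config.dilution_factor,
        is_blank=config.is_blank,
        true_fam_counts=k_wpre,
        true_hex_counts=k_tert,
    )


def simulate_dilution_series(
    config: SimConfig, dilution_factors: list[float]
) -> list[DropletWell]:
    """One well per factor: target concentration scaled, reference held.

    Mirrors serial dilution of product gDNA into same-donor PBMC gDNA,
    which dilutes the vector target while keeping the reference genome
    concentration fixed.
    """
    if len(dilution_factors) == 0:
        raise ValueError("dilution_factors must be non-empty")
    wells = []
    for i, f in enumerate(dilution_factors):
        if not 0 < f <= 1:
            raise ValueError("each dilution factor must lie in (0, 1]")
        cfg = replace(
            config,
            wpre_conc=config.wpre_conc * f,
            seed=config.seed + i,
            dilution_factor=f,
            well_id=f"{config.well_id}-D{i}",
        )
        wells.append(simulate_well(cfg))
    return wells


def simulate_cell_product(config: CellProductConfig) -> CellProduct:
    """Draw per-cell VCNs; transduced cells are those with >= 1 copy."""
    rng = np.random.default_rng(config.seed)
    k = rng.poisson(config.lambda_vcn, size=config.n_cells)
    transduced = k >= 1
    n_trans = int(transduced.sum())
    return CellProduct(
        copies_per_cell=k,
        transduced_fraction=n_trans / config.n_cells,
        mean_vcn_transduced=float(k[transduced].mean()) if n_trans else float("nan"),
        wpre_total=int(k.sum()),
        tert_total=2 * config.n_cells,
    )
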