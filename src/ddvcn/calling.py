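"""Droplet classification for the duplex FAM/HEX readout.

A duplex well produces a two-dimensional amplitude cloud with up to four
clusters: double-negative, FAM-only (target, WPRE), HEX-only (reference,
TERT) and double-positive.  Classification is per-channel with a scalar
threshold, matching the single-threshold display of the instrument
software: a droplet is positive on a channel iff its amplitude lies
strictly above the channel threshold (ties are called negative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DropletWell",
    "ClusterCounts",
    "set_threshold",
    "classify_droplets",
]


class DegenerateAmplitudesError(ValueError):
    """Raised when an automatic threshold is requested on non-separable data."""


@dataclass
class DropletWell:
    """Raw two-channel amplitudes for one well plus metadata.

    ``true_fam_counts`` / ``true_hex_counts`` hold the hidden template
    occupancy per droplet when the well was produced by the simulator;
    they are ``None`` for wells read from instrument exports.
    """

    well_id: str
    sample_id: str
    fam_amplitudes: np.ndarray
    hex_amplitudes: np.ndarray
    dilution_factor: float = 1.0
    is_blank: bool = False
    true_fam_counts: np.ndarray | None = None
    true_hex_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.fam_amplitudes = np.asarray(self.fam_amplitudes, dtype=float)
        self.hex_amplitudes = np.asarray(self.hex_amplitudes, dtype=float)
        if self.fam_amplitudes.ndim != 1 or self.hex_amplitudes.ndim != 1:
            raise ValueError("amplitude arrays must be one-dimensional")
        if len(self.fam_amplitudes) != len(self.hex_amplitudes):
            raise ValueError("FAM and HEX amplitude lists must have equal length")
        if len(self.fam_amplitudes) < 1:
            raise ValueError("a well must contain at least one droplet")
        if not (np.isfinite(self.fam_amplitudes).all() and np.isfinite(self.hex_amplitudes).all()):
            raise ValueError("amplitudes must be finite")
        if not 0 < self.dilution_factor <= 1:
            raise ValueError("dilution_factor must lie in (0, 1]")

    @property
    def n_droplets(self) -> int:
        return len(self.fam_amplitudes)


@dataclass
class ClusterCounts:
    """Droplet counts in the four duplex clusters of one well."""

    n_total: int
    n_fam_pos_hex_pos: int
    n_fam_pos_hex_neg: int
    n_fam_neg_hex_pos: int
    n_fam_neg_hex_neg: int
    fam_threshold: float
    hex_threshold: float

    def __post_init__(self) -> None:
        parts = (
            self.n_fam_pos_hex_pos
            + self.n_fam_pos_hex_neg
            + self.n_fam_neg_hex_pos
            + self.n_fam_neg_hex_neg
        )
        if parts != self.n_total:
            raise ValueError("cluster counts must partition n_total")
        if not (np.isfinite(self.fam_threshold) and np.isfinite(self.hex_threshold)):
            raise ValueError("thresholds must be finite")

    @property
    def n_fam_positive(self) -> int:
        return self.n_fam_pos_hex_pos + self.n_fam_pos_hex_neg

    @property
    def n_fam_negative(self) -> int:
        return self.n_total - self.n_fam_positive

    @property
    def n_hex_positive(self) -> int:
        return self.n_fam_pos_hex_pos + self.n_fam_neg_hex_pos

    @property
    def n_hex_negative(self) -> int:
        return self.n_total - self.n_hex_positive


def _two_cluster_split(amplitudes: np.ndarray) -> tuple[float, float]:
    """Optimal 1-D two-group split: centers minimising within-class variance.

    Scans every split point of the sorted sample; equivalent to exact
    (histogram-free) Otsu.  Returns the two cluster means.
    """
    x = np.sort(amplitudes)
    n = len(x)
    csum = np.cumsum(x)
    total = csum[-1]
    sizes_lo = np.arange(1, n)
    mean_lo = csum[:-1] / sizes_lo
    mean_hi = (total - csum[:-1]) / (n - sizes_lo)
    # between-class variance, maximised <=> within-class variance minimised
    w_lo = sizes_lo / n
    between = w_lo * (1 - w_lo) * (mean_lo - mean_hi) ** 2
    k = int(np.argmax(between))
    return float(mean_lo[k]), float(mean_hi[k])


def set_threshold(
    amplitudes,
    method: str = "otsu",
    manual_value: float | None = None,
    n_bins: int = 256,
) -> float:
    """Place the positive/negative threshold on one channel.

    ``otsu`` maximises between-class variance over a fixed-bin histogram,
    ``midpoint`` returns the mean of the two cluster centers from an exact
    1-D two-group split, ``manual`` echoes ``manual_value``.
    """
    if method == "manual":
        if manual_value is None:
            raise ValueError("manual_value is required when method='manual'")
        return float(manual_value)
    if manual_value is not None:
        raise ValueError("manual_value is only accepted with method='manual'")

    x = np.asarray(amplitudes, dtype=float)
    if x.size < 2:
        raise ValueError("automatic threshold methods need at least 2 droplets")
    if not np.isfinite(x).all():
        raise ValueError("amplitudes must be finite")
    if np.ptp(x) == 0:
        raise DegenerateAmplitudesError(
            "all amplitudes identical: no separable positive/negative classes"
        )

    if method == "midpoint":
        lo, hi = _two_cluster_split(x)
        return 0.5 * (lo + hi)
    if method == "otsu":
        counts, edges = np.histogram(x, bins=n_bins)
        centers = 0.5 * (edges[:-1] + edges[1:])
        w = np.cumsum(counts)
        m = np.cumsum(counts * centers)
        w_lo = w[:-1]
        w_hi = w[-1] - w_lo
        valid = (w_lo > 0) & (w_hi > 0)
        if not valid.any():
            raise DegenerateAmplitudesError("histogram collapsed to a single bin")
        mean_lo = np.where(valid, m[:-1] / np.maximum(w_lo, 1), 0.0)
        mean_hi = np.where(valid, (m[-1] - m[:-1]) / np.maximum(w_hi, 1), 0.0)
        between = np.where(valid, w_lo * w_hi * (mean_lo - mean_hi) ** 2, -np.inf)
        k = int(np.argmax(between))
        # cut at the upper edge of the best bin
        return float(edges[k + 1])
    raise ValueError(f"unknown threshold method: {method!r}")


def classify_droplets(
    well: DropletWell, fam_threshold: float, hex_threshold: float
) -> ClusterCounts:
    """Partition a well's droplets into the four duplex clusters.

    Positive iff amplitude strictly exceeds the channel threshold.
    """
    if well.n_droplets == 0:  # DropletWell forbids this, but guard anyway
        raise ValueError("empty well")
    if not (np.isfinite(fam_threshold) and np.isfinite(hex_threshold)):
        raise ValueError("thresholds must be finite")
    fam_pos = well.fam_amplitudes > fam_threshold
    hex_pos = well.hex_amplitudes > hex_threshold
    return ClusterCounts(
        n_total=well.n_droplets,
        n_fam_pos_hex_pos=int(np.sum(fam_pos & hex_pos)),
        n_fam_pos_hex_neg=int(np.sum(fam_pos & ~hex_pos)),
        n_fam_neg_hex_pos=int(np.sum(~fam_pos & hex_pos)),
        n_fam_neg_hex_neg=int(np.sum(~fam_pos & ~hex_pos)),
        fam_threshold=float(fam_threshold),
        hex_threshold=float(hex_threshold),
    )
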