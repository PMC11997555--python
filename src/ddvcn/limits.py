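"""Assay detection limits from blank replicates and a dilution series.

No-template controls define the blank distribution; the standard
parametric limits follow:

    LoB  = mean_blank + 1.645 * SD_blank
    LLoD = max(LoB + 3.3 * SD_blank, lowest dilution tested)
    LLoQ = max(LoB + 10  * SD_blank, lowest dilution tested)

all in copies/ul of reaction mix.  Sample (n-1) SD is used.  The MAX
rule keeps a limit from being claimed below the lowest concentration the
dilution series actually probed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AssayLimits", "compute_limits", "flag_below_limits"]


@dataclass
class AssayLimits:
    """Limit of blank, detection and quantification, copies/ul."""

    lob: float
    llod: float
    lloq: float
    mean_blank: float
    sd_blank: float
    lowest_dilution_tested: float
    n_blanks: int

    def __post_init__(self) -> None:
        if min(self.lob, self.llod, self.lloq) < 0:
            raise ValueError("limits must be non-negative")
        if self.sd_blank >= 0 and not self.lob <= self.llod <= self.lloq:
            raise ValueError("expected ordering LoB <= LLoD <= LLoQ")


def compute_limits(
    blank_measurements, lowest_dilution_tested: float = 0.0
) -> AssayLimits:
    """Compute LoB/LLoD/LLoQ from blank (NTC) concentration measurements."""
    blanks = np.asarray(blank_measurements, dtype=float)
    if blanks.size < 2:
        raise ValueError("need at least 2 blank measurements for a sample SD")
    if (blanks < 0).any():
        raise ValueError("blank measurements must be non-negative")
    if lowest_dilution_tested < 0:
        raise ValueError("lowest_dilution_tested must be non-negative")
    mean = float(blanks.mean())
    sd = float(blanks.std(ddof=1))
    lob = mean + 1.645 * sd
    llod = max(lob + 3.3 * sd, lowest_dilution_tested)
    lloq = max(lob + 10.0 * sd, lowest_dilution_tested)
    return AssayLimits(
        lob=lob,
        llod=llod,
        lloq=lloq,
        mean_blank=mean,
        sd_blank=sd,
        lowest_dilution_tested=float(lowest_dilution_tested),
        n_blanks=int(blanks.size),
    )


def flag_below_limits(estimate, limits: AssayLimits) -> set[str]:
    """QC flags for a concentration estimate against the assay limits.

    Strictly-below flagging: a value equal to a limit is considered
    quantifiable.  Accepts a ConcentrationEstimate or a bare number.
    """
    value = getattr(estimate, "copies_per_ul", estimate)
    flags: set[str] = set()
    if value < limits.lob:
        flags.add("below_lob")
    if value < limits.llod:
        flags.add("below_llod")
    if value < limits.lloq:
        flags.add("below_lloq")
    return flags
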