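"""Sample-level quality control for the cfDNA methylation workflow.

Three metrics guard the pre-analytical steps: recovery of a soybean CPP1
spike-in added before cfDNA extraction (purification efficiency), signal
from a B-cell IGH assay (leucocyte genomic-DNA contamination), and the
before/after ratio of a cytosine-free-region (CF) quantification spanning
bisulfite conversion (conversion recovery).  A sample is excluded when it
shows leucocyte contamination, fewer than 10,000 droplets in any of its
wells, or no measurable CF signal after conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

__all__ = [
    "QCFlag",
    "QCConfig",
    "QCMetrics",
    "QCResult",
    "purification_efficiency",
    "bisulfite_recovery",
    "qc_gate",
]

MIN_DROPLETS = 10_000


class QCFlag(str, Enum):
    leucocyte_contamination = "leucocyte_contamination"
    low_droplets = "low_droplets"
    no_cf_signal = "no_cf_signal"
    incomplete_qc = "incomplete_qc"
    over_recovery = "over_recovery"


@dataclass(frozen=True)
class QCConfig:
    """Exclusion cutoffs.

    ``pbc_fraction_cutoff`` flags leucocyte contamination when PBC-derived
    copies exceed that fraction of the CF-measured copies; a relative cutoff
    is robust to the amount of input DNA.
    """

    min_droplets: int = MIN_DROPLETS
    pbc_fraction_cutoff: float = 0.10


@dataclass
class QCMetrics:
    """Per-sample QC measurements; None marks a missing measurement."""

    sample_id: str
    purification_efficiency: float | None = None  # %
    pbc_copies: float | None = None               # copies (PBC assay)
    cf_before: float | None = None                # copies before conversion
    cf_after: float | None = None                 # copies after conversion
    bisulfite_recovery: float | None = None       # %
    min_droplets: int | None = None               # min over the sample's wells
    flags: set = field(default_factory=set)


@dataclass(frozen=True)
class QCResult:
    sample_id: str
    passed: bool
    reasons: tuple


def purification_efficiency(measured_cpp1: float, spiked_cpp1: float) -> float:
    """Percentage recovery of the CPP1 spike-in after cfDNA extraction."""
    if spiked_cpp1 <= 0:
        raise ValueError("spiked CPP1 amount must be positive")
    if measured_cpp1 < 0:
        raise ValueError("measured CPP1 cannot be negative")
    return 100.0 * measured_cpp1 / spiked_cpp1


def bisulfite_recovery(cf_before: float, cf_after: float) -> float:
    """Percent DNA surviving bisulfite conversion (after / before)."""
    if cf_before <= 0:
        raise ValueError("CF quantity before conversion must be positive")
    if cf_after < 0:
        raise ValueError("CF quantity after conversion cannot be negative")
    return 100.0 * cf_after / cf_before


def qc_gate(metrics: QCMetrics, config: QCConfig | None = None) -> QCResult:
    """Apply the sample exclusion rules; every triggered rule is reported.

    Fails on: PBC copies above ``pbc_fraction_cutoff`` of CF copies
    (leucocyte contamination), any well under ``min_droplets`` droplets, or
    no measurable CF signal after conversion.  A sample with a missing
    metric fails with an ``incomplete_qc`` reason rather than passing by
    default.
    """
    config = config or QCConfig()
    reasons: list[str] = []

    if metrics.min_droplets is None or metrics.pbc_copies is None or metrics.cf_after is None:
        reasons.append(QCFlag.incomplete_qc.value)
    if metrics.min_droplets is not None and metrics.min_droplets < config.min_droplets:
        reasons.append(QCFlag.low_droplets.value)
    if metrics.cf_after is not None and metrics.cf_after <= 0:
        reasons.append(QCFlag.no_cf_signal.value)
    if (
        metrics.pbc_copies is not None
        and metrics.cf_before is not None
        and metrics.cf_before > 0
        and metrics.pbc_copies > config.pbc_fraction_cutoff * metrics.cf_before
    ):
        reasons.append(QCFlag.leucocyte_contamination.value)

    metrics.flags = {QCFlag(r) for r in reasons}
    if metrics.purification_efficiency is not None and metrics.purification_efficiency > 100:
        # reported, not an exclusion: over-recovery of the spike-in
        metrics.flags.add(QCFlag.over_recovery)
    return QCResult(sample_id=metrics.sample_id, passed=not reasons, reasons=tuple(reasons))
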