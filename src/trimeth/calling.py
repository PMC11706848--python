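"""TriMeth sample calling and cohort detection summaries.

A plasma sample is scored on three methylation markers (C9orf50, KCNQ5,
CLIP4).  A marker is positive when more than one droplet is positive
(>= 2 droplets, guarding against single-droplet noise); the sample is
ctDNA positive when at least 2 of the 3 markers are positive.  The overall
TriMeth concentration is the sum of the three marker copies/mL, preserving
total methylated-molecule count.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

from trimeth.ddpcr import TRIMETH_MARKERS, Target

__all__ = [
    "Timepoint",
    "Call",
    "DynamicsGroup",
    "SampleResult",
    "IncompletePanelError",
    "marker_positive",
    "sample_call",
    "trimeth_total",
    "detection_rate",
    "dynamics_group",
    "dynamics_groups",
]

#: Minimum positive droplets for a single marker to count ("> 1 droplet").
MARKER_MIN_DROPLETS = 2
#: Markers that must be individually positive for a positive sample call.
MARKERS_REQUIRED = 2


class Timepoint(str, Enum):
    baseline = "baseline"
    after_1_cycle = "after_1_cycle"
    after_preop_ct = "after_preop_ct"
    post_surgery = "post_surgery"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Call(str, Enum):
    positive = "positive"
    negative = "negative"


class DynamicsGroup(str, Enum):
    neg_to_neg = "neg_to_neg"
    neg_to_pos = "neg_to_pos"
    pos_to_neg = "pos_to_neg"
    pos_to_pos = "pos_to_pos"


class IncompletePanelError(ValueError):
    """A sample is missing one of the three marker measurements."""


@dataclass
class SampleResult:
    """Per-sample marker measurements and the TriMeth call."""

    sample_id: str
    patient_id: str
    timepoint: Timepoint
    marker_droplets: Mapping[Target, tuple[int, int]] = field(default_factory=dict)
    marker_copies_per_ml: Mapping[Target, float] = field(default_factory=dict)
    trimeth_total_copies_per_ml: float = 0.0
    call: Call | None = None
    qc_pass: bool = True


def marker_positive(k_positive: int) -> bool:
    """True when a marker shows more than one positive droplet."""
    if k_positive < 0:
        raise ValueError("droplet count cannot be negative")
    return k_positive >= MARKER_MIN_DROPLETS


def sample_call(marker_droplets: Mapping[Target, tuple[int, int] | int]) -> Call:
    """2-of-3 TriMeth rule: positive iff >= 2 markers are marker-positive.

    Accepts either (k_positive, n_total) pairs or bare positive-droplet
    counts per marker; invariant under marker permutation.
    """
    missing = [t for t in TRIMETH_MARKERS if t not in marker_droplets]
    if missing:
        raise IncompletePanelError(
            f"missing marker measurement(s): {', '.join(str(m) for m in missing)}"
        )
    n_pos = 0
    for t in TRIMETH_MARKERS:
        v = marker_droplets[t]
        k = v[0] if isinstance(v, tuple) else int(v)
        if marker_positive(k):
            n_pos += 1
    return Call.positive if n_pos >= MARKERS_REQUIRED else Call.negative


def trimeth_total(marker_copies_per_ml: Mapping[Target, float]) -> float:
    """Overall TriMeth concentration: sum of the three marker copies/mL."""
    return float(sum(marker_copies_per_ml.get(t, 0.0) for t in TRIMETH_MARKERS))


def detection_rate(
    cohort: Iterable[SampleResult], timepoint: Timepoint
) -> tuple[int, int, int]:
    """(positives, evaluable, percent) at one timepoint.

    Only QC-passed samples with a defined call are evaluable; each patient
    may contribute at most one such sample per timepoint.  Percent is
    rounded to the nearest integer, matching how detection rates are
    conventionally reported.
    """
    timepoint = Timepoint(timepoint)
    seen: set[str] = set()
    n_pos = 0
    n_eval = 0
    for s in cohort:
        if Timepoint(s.timepoint) is not timepoint:
            continue
        if not s.qc_pass or s.call is None:
            continue
        if s.patient_id in seen:
            raise ValueError(
                f"patient {s.patient_id} has more than one evaluable sample at {timepoint}"
            )
        seen.add(s.patient_id)
        n_eval += 1
        if Call(s.call) is Call.positive:
            n_pos += 1
    pct = int(round(100.0 * n_pos / n_eval)) if n_eval else 0
    return n_pos, n_eval, pct


def dynamics_group(call_t1: Call, call_t2: Call) -> DynamicsGroup:
    """Map a pair of serial calls to its ctDNA-transition group."""
    if call_t1 is None or call_t2 is None:
        raise ValueError("both calls must be defined for dynamics grouping")
    a = "pos" if Call(call_t1) is Call.positive else "neg"
    b = "pos" if Call(call_t2) is Call.positive else "neg"
    return DynamicsGroup(f"{a}_to_{b}")


def dynamics_groups(
    cohort: Iterable[SampleResult], t1: Timepoint, t2: Timepoint
) -> tuple[dict[str, DynamicsGroup], list[str]]:
    """Group patients by their ctDNA transition between two timepoints.

    Returns the per-patient group mapping and the list of patients excluded
    because one of the two calls is missing or failed QC.
    """
    t1, t2 = Timepoint(t1), Timepoint(t2)
    calls: dict[str, dict[Timepoint, Call]] = {}
    for s in cohort:
        tp = Timepoint(s.timepoint)
        if tp not in (t1, t2) or not s.qc_pass or s.call is None:
            continue
        calls.setdefault(s.patient_id, {})[tp] = Call(s.call)
    groups: dict[str, DynamicsGroup] = {}
    excluded: list[str] = []
    for pid, c in sorted(calls.items()):
        if t1 in c and t2 in c:
            groups[pid] = dynamics_group(c[t1], c[t2])
        else:
            excluded.append(pid)
    return groups, excluded
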