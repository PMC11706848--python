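"""Droplet digital PCR quantification.

A ddPCR reaction is partitioned into ~20,000 nanolitre-scale droplets; each
droplet either contains template molecules (bright after endpoint PCR) or
does not (dark).  The fraction of positive droplets gives the mean number of
molecules per droplet through the Poisson occupancy relation
``lambda = -ln(1 - k/n)``, which converts to a concentration per microlitre
of reaction via the droplet volume, and finally to copies per millilitre of
plasma via the extraction/elution geometry of the sample.

Thresholding between positive and negative droplets is derived per plate
and channel from the droplet signals of that plate's positive and negative
control wells, so every sample well on the plate is classified with the
same objective cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "Channel",
    "Target",
    "WellRole",
    "DropletWell",
    "ChannelThreshold",
    "MarkerMeasurement",
    "ReactionGeometry",
    "ControlFailure",
    "SaturatedWellError",
    "set_threshold_from_controls",
    "classify_droplets",
    "poisson_concentration",
    "copies_per_ml_plasma",
]


class Channel(str, Enum):
    ch1 = "ch1"
    ch2 = "ch2"


class Target(str, Enum):
    """Assay targets: three methylation markers plus the QC assays."""

    C9orf50 = "C9orf50"
    KCNQ5 = "KCNQ5"
    CLIP4 = "CLIP4"
    CF = "CF"       # cytosine-free region, total-DNA quantification
    CPP1 = "CPP1"   # soybean spike-in, purification efficiency
    PBC = "PBC"     # B-cell IGH locus, leucocyte contamination

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


TRIMETH_MARKERS = (Target.C9orf50, Target.KCNQ5, Target.CLIP4)

#: Duplex plate layout: each well is read on two fluorescence channels,
#: one target per channel.
DUPLEX_LAYOUT = {
    "methylation": {Channel.ch1: Target.C9orf50, Channel.ch2: Target.KCNQ5},
    "methylation_cf": {Channel.ch1: Target.CLIP4, Channel.ch2: Target.CF},
    "qc": {Channel.ch1: Target.CPP1, Channel.ch2: Target.PBC},
}


class WellRole(str, Enum):
    sample = "sample"
    positive_control = "positive_control"
    negative_control = "negative_control"
    no_template_control = "no_template_control"


class ControlFailure(RuntimeError):
    """Raised when a plate's control wells cannot define a threshold."""


class SaturatedWellError(ValueError):
    """Raised when a concentration is requested for an all-positive well."""


@dataclass(frozen=True)
class DropletWell:
    """Raw per-droplet fluorescence amplitudes for one well and channel."""

    well_id: str
    plate_id: str
    channel: Channel
    target: Target
    role: WellRole
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        amp = np.asarray(self.amplitudes, dtype=float)
        object.__setattr__(self, "amplitudes", amp)
        if amp.ndim != 1 or amp.size == 0:
            raise ValueError(f"well {self.well_id}: amplitudes must be a non-empty 1-d array")
        if not np.all(np.isfinite(amp)):
            raise ValueError(f"well {self.well_id}: non-finite amplitude")

    @property
    def n_droplets(self) -> int:
        return int(self.amplitudes.size)


@dataclass(frozen=True)
class ChannelThreshold:
    """Amplitude cutoff for one plate x channel, derived from controls."""

    plate_id: str
    channel: Channel
    threshold: float
    neg_center: float
    pos_center: float
    method_metadata: str = ""

    def __post_init__(self) -> None:
        if not self.neg_center < self.threshold < self.pos_center:
            raise ValueError(
                f"threshold {self.threshold} not between control centers "
                f"({self.neg_center}, {self.pos_center})"
            )


@dataclass(frozen=True)
class ReactionGeometry:
    """Volumes linking droplet counts back to the plasma sample.

    ``droplet_volume`` is the QX200 partition volume (0.85 nL); the reaction
    is assembled to 22 uL from 2-8 uL of a 22 uL bisulfite eluate that
    derives from ``plasma_volume`` mL of plasma.
    """

    droplet_volume: float = 0.00085  # µL
    reaction_volume: float = 22.0    # µL
    template_volume: float = 8.0     # µL loaded into this reaction
    eluate_volume: float = 22.0      # µL total eluate
    plasma_volume: float = 8.0       # mL plasma extracted

    def __post_init__(self) -> None:
        for name in ("droplet_volume", "reaction_volume", "template_volume",
                     "eluate_volume", "plasma_volume"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.template_volume > self.eluate_volume:
            raise ValueError("template_volume cannot exceed eluate_volume")


@dataclass
class MarkerMeasurement:
    """Positive/total droplet counts and derived concentrations for one marker."""

    target: Target
    k_positive: int
    n_total: int
    lam: float = float("nan")
    conc_per_ul_reaction: float = float("nan")
    copies_per_reaction: float = float("nan")
    copies_per_ml_plasma: float = float("nan")
    saturated: bool = False
    threshold: float = float("nan")

    def __post_init__(self) -> None:
        if not 0 <= self.k_positive <= self.n_total:
            raise ValueError(f"need 0 <= k ({self.k_positive}) <= n ({self.n_total})")


def _mad(x: np.ndarray) -> float:
    """Median absolute deviation (raw, unscaled)."""
    return float(np.median(np.abs(x - np.median(x))))


def _two_class_split(amplitudes: np.ndarray, tol: float = 1e-9, max_iter: int = 200):
    """Deterministic 1-d two-means split, centers initialised at min and max.

    Returns (lower_center, upper_center) as medians of the two classes.
    """
    amp = np.asarray(amplitudes, dtype=float)
    lo, hi = float(amp.min()), float(amp.max())
    if hi - lo <= tol:
        # single cluster; both centers coincide
        m = float(np.median(amp))
        return m, m
    c_lo, c_hi = lo, hi
    for _ in range(max_iter):
        cut = 0.5 * (c_lo + c_hi)
        upper = amp > cut
        if not upper.any() or upper.all():
            break
        new_lo = float(amp[~upper].mean())
        new_hi = float(amp[upper].mean())
        if abs(new_lo - c_lo) < tol and abs(new_hi - c_hi) < tol:
            c_lo, c_hi = new_lo, new_hi
            break
        c_lo, c_hi = new_lo, new_hi
    cut = 0.5 * (c_lo + c_hi)
    upper = amp > cut
    if not upper.any() or upper.all():
        m = float(np.median(amp))
        return m, m
    return float(np.median(amp[~upper])), float(np.median(amp[upper]))


def set_threshold_from_controls(
    neg_control: DropletWell, pos_control: DropletWell
) -> ChannelThreshold:
    """Derive the plate/channel amplitude threshold from control wells.

    The negative-cluster center is the median amplitude of the negative
    control; the positive-cluster center is the median of the upper class of
    a deterministic two-class split of the positive control.  The cutoff is

        max(neg + 0.4 * (pos - neg),  neg + 7 * MAD(neg))

    i.e. 40% of the way up the dynamic range, floored well above the
    negative noise band so that rain near the negative cluster is not
    called positive.  One threshold is applied to every sample well on the
    plate/channel.

    Raises
    ------
    ControlFailure
        If the positive control shows no upper cluster separated from the
        negative center by more than four times the negative spread.
    """
    if neg_control.plate_id != pos_control.plate_id or neg_control.channel != pos_control.channel:
        raise ValueError("control wells must share plate and channel")
    neg_amp = neg_control.amplitudes
    neg_center = float(np.median(neg_amp))
    neg_mad = _mad(neg_amp)
    _, pos_center = _two_class_split(pos_control.amplitudes)
    separation = pos_center - neg_center
    if separation <= 4.0 * neg_mad or separation <= 0:
        raise ControlFailure(
            f"plate {neg_control.plate_id} {neg_control.channel.value}: positive control "
            f"upper cluster at {pos_center:.1f} not separated from negative center "
            f"{neg_center:.1f} (MAD {neg_mad:.1f}); plate not analyzable"
        )
    threshold = max(neg_center + 0.4 * separation, neg_center + 7.0 * neg_mad)
    return ChannelThreshold(
        plate_id=neg_control.plate_id,
        channel=neg_control.channel,
        threshold=float(threshold),
        neg_center=neg_center,
        pos_center=pos_center,
        method_metadata=(
            f"interp0.4+7MAD; neg_mad={neg_mad:.4g}; "
            f"neg_well={neg_control.well_id}; pos_well={pos_control.well_id}"
        ),
    )


def classify_droplets(well: DropletWell, thr: ChannelThreshold) -> tuple[int, int]:
    """Count positive droplets (amplitude strictly above the threshold).

    Ties at the threshold count negative, so a single borderline droplet
    cannot create a positive call.
    """
    if well.plate_id != thr.plate_id or well.channel != thr.channel:
        raise ValueError(
            f"well {well.well_id} ({well.plate_id}/{well.channel.value}) does not match "
            f"threshold ({thr.plate_id}/{thr.channel.value})"
        )
    k = int(np.count_nonzero(well.amplitudes > thr.threshold))
    return k, well.n_droplets


def poisson_concentration(
    k_positive: int,
    n_total: int,
    geometry: ReactionGeometry | None = None,
    target: Target = Target.C9orf50,
) -> MarkerMeasurement:
    """Poisson-correct droplet counts into per-reaction copy numbers.

    ``lambda = -ln(1 - k/n)`` is the mean copies per droplet; dividing by
    the droplet volume gives copies/µL of reaction, and multiplying by the
    reaction volume gives total copies in the reaction.  A fully positive
    well (k == n) is marked saturated and its concentrations left undefined.
    """
    geometry = geometry or ReactionGeometry()
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= k_positive <= n_total:
        raise ValueError(f"need 0 <= k ({k_positive}) <= n ({n_total})")
    m = MarkerMeasurement(target=target, k_positive=k_positive, n_total=n_total)
    if k_positive == n_total:
        m.saturated = True
        return m
    m.lam = -math.log1p(-k_positive / n_total)
    m.conc_per_ul_reaction = m.lam / geometry.droplet_volume
    m.copies_per_reaction = m.conc_per_ul_reaction * geometry.reaction_volume
    return m


def copies_per_ml_plasma(m: MarkerMeasurement, geometry: ReactionGeometry) -> float:
    """Scale per-reaction copies back to copies per mL of plasma.

    Only ``template_volume`` of the ``eluate_volume`` µL eluate entered the
    reaction, so reaction copies are scaled by eluate/template and divided
    by the plasma volume the eluate derives from.
    """
    if m.saturated:
        raise SaturatedWellError(
            f"{m.target}: all {m.n_total} droplets positive; concentration undefined "
            "(dilution-aware re-quantification is out of scope)"
        )
    value = m.copies_per_reaction * (geometry.eluate_volume / geometry.template_volume)
    value /= geometry.plasma_volume
    m.copies_per_ml_plasma = float(value)
    return m.copies_per_ml_plasma


def quantify_well(
    well: DropletWell,
    thr: ChannelThreshold,
    geometry: ReactionGeometry,
) -> MarkerMeasurement:
    """Classify, Poisson-correct and scale one sample well to copies/mL."""
    k, n = classify_droplets(well, thr)
    m = poisson_concentration(k, n, geometry, target=well.target)
    m.threshold = thr.threshold
    if not m.saturated:
        copies_per_ml_plasma(m, geometry)
    return m
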