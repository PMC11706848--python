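"""Synthetic droplet plates and clinical cohorts.

The generator emulates the statistical structure the analysis assumes:

* droplet occupancy is Poisson at ~21,000 droplets per well (the observed
  per-well counts have median 20,978, IQR 20,230-21,456);
* fluorescence amplitudes form two Gaussian clusters with sparse "rain" in
  between — a fraction of occupied droplets is displaced into a uniform
  inter-cluster band (partial amplification), and empty droplets carry a
  tiny per-droplet background rain rate, which is what produces the
  occasional single false-positive droplet the >1-droplet marker rule
  guards against;
* spike-in purification efficiency and bisulfite recovery are logit-normal
  around the observed medians (92% and 51%);
* per-timepoint ctDNA positivity follows the observed 56/37/25/15% with a
  Gaussian-copula correlation across timepoints so all four dynamics
  groups occur;
* recurrence hazards are multiplicative in ctDNA status (defaults 2.54
  after one chemotherapy cycle and 6.22 post-surgery on an exponential
  baseline with 30-month median RFS), with death following recurrence
  after an exponential post-recurrence survival.

True marker concentrations refer to the measurable (post-conversion)
copies per mL of plasma, so the droplet model inverts the quantification
pipeline exactly and ground truth is recoverable.  Every output is fully
determined by the seed.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from trimeth.calling import Timepoint, sample_call
from trimeth.ddpcr import Channel, ReactionGeometry, Target, WellRole
from trimeth.survival import DAYS_PER_MONTH, DEFAULT_DATA_CUTOFF

__all__ = [
    "SimulationConfig",
    "PlateData",
    "CohortData",
    "StudyData",
    "simulate_plate",
    "simulate_cohort",
    "simulate_call_table",
    "simulate_study",
]

#: Plate-id suffixes per assay mix.  Every plate carries one duplex mix so
#: the per-plate, per-channel threshold is well-defined; a CF measurement on
#: a ``-CFB`` plate is the before-conversion quantity, CF on the ``-CFM``
#: plate is after conversion.
MET_PLATE_SUFFIX = "-MET"   # C9orf50 (ch1) + KCNQ5 (ch2)
CFM_PLATE_SUFFIX = "-CFM"   # CLIP4 (ch1) + CF after conversion (ch2)
QC_PLATE_SUFFIX = "-QC"     # CPP1 (ch1) + PBC (ch2), before conversion
CFB_PLATE_SUFFIX = "-CFB"   # CF before conversion (ch1)

TIMEPOINTS = (
    Timepoint.baseline,
    Timepoint.after_1_cycle,
    Timepoint.after_preop_ct,
    Timepoint.post_surgery,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters; defaults are the study conditions."""

    seed: int = 0
    n_patients: int = 86

    # droplet counts per well
    droplets_mean: float = 20978.0
    droplets_sd: float = 909.0          # matches the reported IQR width
    low_droplets_value: int = 9000      # injected low-droplet QC failures

    # amplitude model
    neg_amplitude_mean: float = 1000.0
    neg_amplitude_sd: float = 60.0
    pos_amplitude_mean: float = 8000.0
    pos_amplitude_sd: float = 300.0
    rain_fraction: float = 0.05         # of occupied droplets, into the band
    false_rain_rate: float = 1e-5       # per empty droplet

    # control wells
    pos_control_lambda: float = 0.3
    neg_control_cf_lambda: float = 0.5  # unmethylated carrier DNA is CF-positive

    # sample concentration model
    copies_per_ml_median: float = 30.0  # among ctDNA-positive samples
    copies_per_ml_sigma_log: float = 1.0
    marker_sigma_log: float = 0.25      # marker-to-marker variation
    cf_copies_median: float = 3000.0    # per reaction, before conversion
    cf_copies_sigma_log: float = 0.5
    spiked_cpp1_copies: float = 500.0
    purification_logit_mean: float = float(logit(0.92))
    purification_logit_sd: float = 1.0
    bisulfite_logit_mean: float = float(logit(0.51))
    bisulfite_logit_sd: float = 0.366
    contamination_pbc_fraction: float = 0.25

    # cohort structure
    timepoint_positivity: dict = field(
        default_factory=lambda: {
            Timepoint.baseline: 0.56,
            Timepoint.after_1_cycle: 0.37,
            Timepoint.after_preop_ct: 0.25,
            Timepoint.post_surgery: 0.15,
        }
    )
    timepoint_sampling: dict = field(
        default_factory=lambda: {
            Timepoint.baseline: 0.94,
            Timepoint.after_1_cycle: 0.83,
            Timepoint.after_preop_ct: 0.30,
            Timepoint.post_surgery: 0.62,
        }
    )
    status_copula_rho: float = 0.7
    qc_failure_rate: float = 0.05

    # outcome model
    median_rfs_neg: float = 30.0        # months, all-negative patient
    hr_by_timepoint: dict = field(
        default_factory=lambda: {
            Timepoint.after_1_cycle: 2.54,
            Timepoint.post_surgery: 6.22,
        }
    )
    post_recurrence_median: float = 8.0  # months
    follow_up_min: float = 23.5          # months
    follow_up_max: float = 28.5
    data_cutoff: _dt.date = DEFAULT_DATA_CUTOFF

    # geometry
    plasma_volume_ml: float = 8.0
    template_volume_ul: float = 8.0
    geometry: ReactionGeometry = field(default_factory=ReactionGeometry)

    def __post_init__(self) -> None:
        for tp, p in self.timepoint_positivity.items():
            if not 0 <= p <= 1:
                raise ValueError(f"positivity for {tp} outside [0, 1]")
        if not 0 <= self.qc_failure_rate <= 1:
            raise ValueError("qc_failure_rate outside [0, 1]")
        if not 0 <= self.rain_fraction <= 1:
            raise ValueError("rain_fraction outside [0, 1]")


@dataclass
class PlateData:
    droplets: pd.DataFrame      # plate_id, well_id, sample_id, channel, target, role, amplitude
    sample_sheet: pd.DataFrame  # sample_id, patient_id, timepoint, volumes, spike-in
    truth: pd.DataFrame         # per sample x marker true copies/mL and call


@dataclass
class CohortData:
    clinical: pd.DataFrame      # one row per patient
    status_truth: pd.DataFrame  # patient_id, timepoint, true_status, sampled, qc_fail


@dataclass
class StudyData:
    plates: PlateData
    cohort: CohortData


def _n_droplets(cfg: SimulationConfig, rng: np.random.Generator) -> int:
    return int(max(12000, round(rng.normal(cfg.droplets_mean, cfg.droplets_sd))))


def _well_amplitudes(
    cfg: SimulationConfig, rng: np.random.Generator, n: int, lam: float
) -> np.ndarray:
    """Amplitudes for one well/channel at mean occupancy ``lam``."""
    k = int(rng.binomial(n, 1.0 - np.exp(-lam))) if lam > 0 else 0
    amp = np.empty(n, dtype=float)
    n_empty = n - k
    amp[:n_empty] = rng.normal(cfg.neg_amplitude_mean, cfg.neg_amplitude_sd, n_empty)
    band_lo = cfg.neg_amplitude_mean + 6.0 * cfg.neg_amplitude_sd
    band_hi = cfg.pos_amplitude_mean
    # background rain among empty droplets
    n_bg = int(rng.binomial(n_empty, cfg.false_rain_rate)) if n_empty else 0
    if n_bg:
        idx = rng.choice(n_empty, size=n_bg, replace=False)
        amp[idx] = rng.uniform(band_lo, band_hi, n_bg)
    if k:
        n_rain = int(rng.binomial(k, cfg.rain_fraction))
        pos = rng.normal(cfg.pos_amplitude_mean, cfg.pos_amplitude_sd, k - n_rain)
        rain = rng.uniform(band_lo, band_hi, n_rain)
        amp[n_empty:] = np.concatenate([pos, rain])
    return rng.permutation(amp)


def _copies_per_reaction(copies_per_ml: float, g: ReactionGeometry) -> float:
    """Invert the plasma scaling: reaction copies for a given copies/mL."""
    return copies_per_ml * g.plasma_volume / (g.eluate_volume / g.template_volume)


def _lambda_for(copies_per_reaction: float, g: ReactionGeometry) -> float:
    return copies_per_reaction / g.reaction_volume * g.droplet_volume


@dataclass
class SampleSpec:
    """Ground-truth specification of one plasma sample on a plate."""

    sample_id: str
    patient_id: str
    timepoint: Timepoint
    marker_copies_per_ml: dict          # Target -> copies/mL (measurable)
    cf_before: float                    # copies per reaction
    bisulfite_recovery: float           # fraction
    purification_efficiency: float      # fraction
    pbc_copies: float = 0.0             # copies per reaction
    qc_fail_mode: str | None = None     # None | low_droplets | pbc | no_cf


def _draw_sample_specs(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    statuses: pd.DataFrame,
) -> list[SampleSpec]:
    """One SampleSpec per sampled (patient, timepoint) row."""
    specs = []
    for row in statuses.itertuples(index=False):
        if not row.sampled:
            continue
        if row.true_status:
            total = float(np.exp(rng.normal(np.log(cfg.copies_per_ml_median),
                                            cfg.copies_per_ml_sigma_log)))
            marker_copies = {
                t: total * float(np.exp(rng.normal(0.0, cfg.marker_sigma_log)))
                for t in (Target.C9orf50, Target.KCNQ5, Target.CLIP4)
            }
        else:
            marker_copies = {t: 0.0 for t in (Target.C9orf50, Target.KCNQ5, Target.CLIP4)}
        cf_before = float(np.exp(rng.normal(np.log(cfg.cf_copies_median),
                                            cfg.cf_copies_sigma_log)))
        recovery = float(expit(rng.normal(cfg.bisulfite_logit_mean, cfg.bisulfite_logit_sd)))
        efficiency = float(expit(rng.normal(cfg.purification_logit_mean,
                                            cfg.purification_logit_sd)))
        mode = None
        pbc = 0.0
        if row.qc_fail:
            mode = ("low_droplets", "pbc", "no_cf")[int(rng.integers(3))]
            if mode == "pbc":
                pbc = cfg.contamination_pbc_fraction * cf_before
        specs.append(
            SampleSpec(
                sample_id=f"{row.patient_id}-{Timepoint(row.timepoint).value}",
                patient_id=row.patient_id,
                timepoint=Timepoint(row.timepoint),
                marker_copies_per_ml=marker_copies,
                cf_before=cf_before,
                bisulfite_recovery=recovery,
                purification_efficiency=efficiency,
                pbc_copies=pbc,
                qc_fail_mode=mode,
            )
        )
    return specs


def _emit_well(
    rows: list,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    plate_id: str,
    well_id: str,
    sample_id: str,
    role: WellRole,
    channel_targets: dict,
    lambdas: dict,
    n_droplets: int | None = None,
) -> None:
    n = n_droplets if n_droplets is not None else _n_droplets(cfg, rng)
    for channel, target in channel_targets.items():
        amp = _well_amplitudes(cfg, rng, n, lambdas.get(target, 0.0))
        rows.append(
            pd.DataFrame(
                {
                    "plate_id": plate_id,
                    "well_id": well_id,
                    "sample_id": sample_id,
                    "channel": channel.value,
                    "target": target.value,
                    "role": role.value,
                    "amplitude": amp,
                }
            )
        )


def _emit_controls(
    rows: list, cfg: SimulationConfig, rng: np.random.Generator,
    plate_id: str, channel_targets: dict, neg_has_cf: bool,
) -> None:
    """Positive / negative / no-template control wells for one plate.

    The negative control carries unmethylated carrier DNA, so on CF
    channels it shows genuine signal (``neg_has_cf``); the NTC is always
    signal-free.
    """
    pos_l = {t: cfg.pos_control_lambda for t in channel_targets.values()}
    neg_l = {t: (cfg.neg_control_cf_lambda if (neg_has_cf and t is Target.CF) else 0.0)
             for t in channel_targets.values()}
    _emit_well(rows, cfg, rng, plate_id, "POS", "", WellRole.positive_control,
               channel_targets, pos_l)
    _emit_well(rows, cfg, rng, plate_id, "NEG", "", WellRole.negative_control,
               channel_targets, neg_l)
    _emit_well(rows, cfg, rng, plate_id, "NTC", "", WellRole.no_template_control,
               channel_targets, {})


MET_LAYOUT = {Channel.ch1: Target.C9orf50, Channel.ch2: Target.KCNQ5}
CFM_LAYOUT = {Channel.ch1: Target.CLIP4, Channel.ch2: Target.CF}
QC_LAYOUT = {Channel.ch1: Target.CPP1, Channel.ch2: Target.PBC}
CFB_LAYOUT = {Channel.ch1: Target.CF}


def simulate_plate(
    cfg: SimulationConfig,
    seed: int | None = None,
    specs: list[SampleSpec] | None = None,
    batch_id: str = "P1",
    markers_only: bool = False,
) -> PlateData:
    """Simulate the ddPCR plates for a set of samples.

    One plate per duplex mix: a C9orf50+KCNQ5 plate and a CLIP4+CF(after)
    plate for the methylation panel and, unless ``markers_only``, a
    CPP1+PBC plate and a CF-before plate for the pre-conversion QC assays.
    Each plate gets its own positive, negative and no-template control
    wells.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    g = dataclasses.replace(
        cfg.geometry,
        plasma_volume=cfg.plasma_volume_ml,
        template_volume=cfg.template_volume_ul,
    )
    if specs is None:
        statuses = pd.DataFrame(
            {
                "patient_id": [f"PT{i:03d}" for i in range(cfg.n_patients)],
                "timepoint": [Timepoint.baseline.value] * cfg.n_patients,
                "true_status": rng.random(cfg.n_patients)
                < cfg.timepoint_positivity[Timepoint.baseline],
                "sampled": True,
                "qc_fail": rng.random(cfg.n_patients) < cfg.qc_failure_rate,
            }
        )
        specs = _draw_sample_specs(cfg, rng, statuses)

    rows: list[pd.DataFrame] = []
    met_plate = batch_id + MET_PLATE_SUFFIX
    cfm_plate = batch_id + CFM_PLATE_SUFFIX
    qc_plate = batch_id + QC_PLATE_SUFFIX
    cfb_plate = batch_id + CFB_PLATE_SUFFIX

    _emit_controls(rows, cfg, rng, met_plate, MET_LAYOUT, neg_has_cf=False)
    _emit_controls(rows, cfg, rng, cfm_plate, CFM_LAYOUT, neg_has_cf=True)
    if not markers_only:
        _emit_controls(rows, cfg, rng, qc_plate, QC_LAYOUT, neg_has_cf=False)
        _emit_controls(rows, cfg, rng, cfb_plate, CFB_LAYOUT, neg_has_cf=True)

    sheet_rows, truth_rows = [], []
    for s in specs:
        lam_marker = {
            t: _lambda_for(_copies_per_reaction(c, g), g)
            for t, c in s.marker_copies_per_ml.items()
        }
        cf_after = 0.0 if s.qc_fail_mode == "no_cf" else s.cf_before * s.bisulfite_recovery
        lam_cf_after = _lambda_for(cf_after, g)
        low_n = cfg.low_droplets_value if s.qc_fail_mode == "low_droplets" else None
        _emit_well(rows, cfg, rng, met_plate, f"{s.sample_id}-MET", s.sample_id,
                   WellRole.sample, MET_LAYOUT, lam_marker, n_droplets=low_n)
        _emit_well(rows, cfg, rng, cfm_plate, f"{s.sample_id}-CFM", s.sample_id,
                   WellRole.sample, CFM_LAYOUT, {**lam_marker, Target.CF: lam_cf_after})
        if not markers_only:
            lam_qc = {
                Target.CPP1: _lambda_for(cfg.spiked_cpp1_copies * s.purification_efficiency, g),
                Target.PBC: _lambda_for(s.pbc_copies, g),
            }
            _emit_well(rows, cfg, rng, qc_plate, f"{s.sample_id}-QCB", s.sample_id,
                       WellRole.sample, QC_LAYOUT, lam_qc)
            _emit_well(rows, cfg, rng, cfb_plate, f"{s.sample_id}-CFB", s.sample_id,
                       WellRole.sample, CFB_LAYOUT, {Target.CF: _lambda_for(s.cf_before, g)})
        sheet_rows.append(
            {
                "sample_id": s.sample_id,
                "patient_id": s.patient_id,
                "timepoint": s.timepoint.value,
                "plasma_volume_ml": cfg.plasma_volume_ml,
                "template_volume_ul": cfg.template_volume_ul,
                "spiked_cpp1_copies": cfg.spiked_cpp1_copies,
            }
        )
        n_pos_markers = sum(
            1 for c in s.marker_copies_per_ml.values() if c > 0
        )
        for t, c in s.marker_copies_per_ml.items():
            truth_rows.append(
                {
                    "sample_id": s.sample_id,
                    "patient_id": s.patient_id,
                    "timepoint": s.timepoint.value,
                    "target": t.value,
                    "true_copies_per_ml": c,
                    "true_call": "positive" if n_pos_markers >= 2 else "negative",
                    "qc_fail_mode": s.qc_fail_mode or "",
                }
            )

    droplets = pd.concat(rows, ignore_index=True)
    return PlateData(
        droplets=droplets,
        sample_sheet=pd.DataFrame(sheet_rows),
        truth=pd.DataFrame(truth_rows),
    )


# covariate categories and marginal frequencies for the simulated cohort
_COVARIATE_MODEL = {
    "age_group": (("<65", ">=65"), (0.48, 0.52)),
    "sex": (("female", "male"), (0.16, 0.84)),
    "performance_score": (("0", "1-2"), (0.59, 0.41)),
    "tumor_location": (("lower_esophagus", "GEJ", "stomach"), (0.26, 0.62, 0.12)),
    "clinical_T": (("cT1/T2", "cT3/T4"), (0.30, 0.70)),
    "clinical_N": (("cN0", "cN+"), (0.66, 0.34)),
    "HER2": (("normal", "positive"), (0.64, 0.36)),
    "pathological_T": (("ypT1/T2", "ypT3/T4"), (0.40, 0.60)),
    "pathological_N": (("ypN0", "ypN+"), (0.55, 0.45)),
    "TRG": (("TRG1-2", "TRG3-5"), (0.45, 0.55)),
}


def simulate_cohort(cfg: SimulationConfig, seed: int | None = None) -> CohortData:
    """Simulate patients: covariates, serial ctDNA statuses, outcomes.

    Statuses across timepoints share a Gaussian-copula latent (correlation
    ``status_copula_rho``) so marginal positivity is exact per timepoint
    while transitions between timepoints remain stochastic.  The RFS hazard
    is exponential, multiplicative in the true statuses with the configured
    per-timepoint hazard ratios; death follows recurrence after an
    exponential post-recurrence survival; administrative censoring at the
    data cutoff with follow-up uniform in the configured window.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_patients
    pids = [f"PT{i:03d}" for i in range(n)]

    cov = {}
    for name, (levels, probs) in _COVARIATE_MODEL.items():
        cov[name] = rng.choice(levels, size=n, p=np.asarray(probs) / np.sum(probs))

    # Gaussian copula for serial statuses
    z = rng.normal(size=n)
    status = {}
    rho = cfg.status_copula_rho
    for tp in TIMEPOINTS:
        p = cfg.timepoint_positivity[tp]
        x = rho * z + np.sqrt(1 - rho**2) * rng.normal(size=n)
        status[tp] = x > norm.ppf(1 - p) if p > 0 else np.zeros(n, dtype=bool)

    h0 = np.log(2.0) / cfg.median_rfs_neg
    log_hr = np.zeros(n)
    for tp, hr in cfg.hr_by_timepoint.items():
        log_hr += status[Timepoint(tp)] * np.log(hr)
    hazard = h0 * np.exp(log_hr)
    t_rec = rng.exponential(1.0 / hazard)                       # months
    t_death = t_rec + rng.exponential(cfg.post_recurrence_median / np.log(2.0), n)
    follow_up = rng.uniform(cfg.follow_up_min, cfg.follow_up_max, n)

    sampled = {
        tp: rng.random(n) < cfg.timepoint_sampling[tp] for tp in TIMEPOINTS
    }
    qc_fail = {
        tp: sampled[tp] & (rng.random(n) < cfg.qc_failure_rate) for tp in TIMEPOINTS
    }

    cutoff = cfg.data_cutoff
    clin_rows, status_rows = [], []
    for i, pid in enumerate(pids):
        fu_days = round(follow_up[i] * DAYS_PER_MONTH)
        inclusion = cutoff - _dt.timedelta(days=fu_days)
        rec_date, death_date, cause = "", "", ""
        if t_rec[i] <= follow_up[i]:
            # clamp into (inclusion, cutoff]; death strictly after recurrence
            rec_day = min(max(1, round(t_rec[i] * DAYS_PER_MONTH)), fu_days)
            rec_date = (inclusion + _dt.timedelta(days=rec_day)).isoformat()
            if t_death[i] <= follow_up[i]:
                death_day = min(max(rec_day + 1, round(t_death[i] * DAYS_PER_MONTH)), fu_days)
                death_date = (inclusion + _dt.timedelta(days=death_day)).isoformat()
                cause = "cancer"
        clin_rows.append(
            {
                "patient_id": pid,
                "inclusion_date": inclusion.isoformat(),
                "recurrence_date": rec_date,
                "death_date": death_date,
                "death_cause": cause,
                "data_cutoff": cutoff.isoformat(),
                **{name: cov[name][i] for name in _COVARIATE_MODEL},
            }
        )
        for tp in TIMEPOINTS:
            status_rows.append(
                {
                    "patient_id": pid,
                    "timepoint": tp.value,
                    "true_status": bool(status[tp][i]),
                    "sampled": bool(sampled[tp][i]),
                    "qc_fail": bool(qc_fail[tp][i]),
                    "true_rfs_months": float(t_rec[i]),
                    "follow_up_months": float(follow_up[i]),
                }
            )
    return CohortData(
        clinical=pd.DataFrame(clin_rows), status_truth=pd.DataFrame(status_rows)
    )


def simulate_call_table(cfg: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Counts-level fast path: marker droplet counts without amplitudes.

    Shares the cohort (copula statuses, sampling, QC failures) and
    concentration models with the full droplet simulation, but draws the
    positive-droplet count of each marker directly — binomial occupancy at
    the marker's Poisson rate plus a Poisson background of rain false
    positives — skipping per-droplet amplitudes and thresholding.  Suitable
    for large-cohort calibration of the calling rule.

    Returns one row per sampled plasma sample with per-marker k, the
    TriMeth call (2-of-3 rule) for QC-passed samples, and the true status.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    cohort = simulate_cohort(cfg, seed=cfg.seed if seed is None else seed)
    specs = _draw_sample_specs(cfg, rng, cohort.status_truth)
    truth = {
        (r.patient_id, r.timepoint): bool(r.true_status)
        for r in cohort.status_truth.itertuples(index=False)
    }
    g = dataclasses.replace(
        cfg.geometry,
        plasma_volume=cfg.plasma_volume_ml,
        template_volume=cfg.template_volume_ul,
    )
    # half the uniform rain band lies above a mid-band threshold
    bg_rate = cfg.false_rain_rate * 0.5
    rows = []
    for s in specs:
        n = _n_droplets(cfg, rng)
        ks = {}
        for t, c in s.marker_copies_per_ml.items():
            lam = _lambda_for(_copies_per_reaction(c, g), g)
            k = int(rng.binomial(n, 1.0 - np.exp(-lam))) if lam > 0 else 0
            ks[t] = k + int(rng.poisson(n * bg_rate))
        qc_pass = s.qc_fail_mode is None
        call = sample_call(ks).value if qc_pass else ""
        rows.append(
            {
                "sample_id": s.sample_id,
                "patient_id": s.patient_id,
                "timepoint": s.timepoint.value,
                **{f"{t.value}_k_positive": k for t, k in ks.items()},
                "call": call,
                "qc_pass": qc_pass,
                "true_status": truth[(s.patient_id, s.timepoint.value)],
            }
        )
    return pd.DataFrame(rows)


def simulate_study(cfg: SimulationConfig, seed: int | None = None) -> StudyData:
    """Full synthetic study: cohort plus droplet plates for every sample."""
    base = cfg.seed if seed is None else seed
    cohort = simulate_cohort(cfg, seed=base)
    rng = np.random.default_rng(base + 1)
    specs = _draw_sample_specs(cfg, rng, cohort.status_truth)
    plates = simulate_plate(cfg, seed=base + 2, specs=specs, batch_id="P1")
    return StudyData(plates=plates, cohort=cohort)
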