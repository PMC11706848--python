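"""Stage orchestration: quantify -> qc -> call -> survival.

Each stage is a pure function from DataFrames to DataFrames so the stages
can be driven from the command line (CSV in / CSV out) or composed
in memory.  ``run_pipeline`` wires them together, writes per-stage CSVs,
a run-metadata JSON and a human-readable summary.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from trimeth import __version__
from trimeth.calling import (
    Call,
    SampleResult,
    Timepoint,
    detection_rate,
    dynamics_groups,
    sample_call,
    trimeth_total,
)
from trimeth.ddpcr import (
    TRIMETH_MARKERS,
    Channel,
    ChannelThreshold,
    DropletWell,
    ReactionGeometry,
    Target,
    WellRole,
    quantify_well,
    set_threshold_from_controls,
)
from trimeth.io import clinical_to_records, write_csv
from trimeth.qc import QCConfig, QCMetrics, bisulfite_recovery, purification_efficiency, qc_gate
from trimeth.survival import (
    Endpoint,
    build_endpoints,
    cox_univariable,
    km_estimate,
    logrank_test,
    roc_analysis,
)

__all__ = [
    "PipelineError",
    "quantify_stage",
    "qc_stage",
    "call_stage",
    "survival_stage",
    "RunConfig",
    "run_pipeline",
]

#: CF measured on a plate with this suffix is the before-conversion copy
#: number; CF anywhere else is after conversion.
CF_BEFORE_SUFFIX = "-CFB"

#: Targets whose channel is thresholded against the no-template control:
#: the negative (unmethylated DNA) control genuinely carries CF signal.
NTC_REFERENCE_TARGETS = {Target.CF}

LANDMARK_MONTHS = 24.0


class PipelineError(RuntimeError):
    """A stage failed; the message is tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _control_well(
    group: pd.DataFrame, plate: str, channel: str, role: WellRole
) -> DropletWell:
    sub = group[group["role"] == role.value]
    if sub.empty:
        raise PipelineError(
            "quantify", f"plate {plate} {channel}: no {role.value} well"
        )
    well_id = sorted(sub["well_id"].unique())[0]
    w = sub[sub["well_id"] == well_id]
    return DropletWell(
        well_id=well_id,
        plate_id=plate,
        channel=Channel(channel),
        target=Target(w["target"].iloc[0]),
        role=role,
        amplitudes=w["amplitude"].to_numpy(dtype=float),
    )


def plate_thresholds(droplets: pd.DataFrame) -> dict[tuple[str, str], ChannelThreshold]:
    """Control-derived threshold for every plate x channel.

    The positive reference is the positive-control well.  The negative
    reference is the negative-control well, except on channels reading a
    target for which that control carries genuine signal (CF on the
    unmethylated carrier DNA), where the no-template control is used.
    """
    thresholds: dict[tuple[str, str], ChannelThreshold] = {}
    for (plate, channel), group in droplets.groupby(["plate_id", "channel"], sort=True):
        sample_targets = set(group.loc[group["role"] == WellRole.sample.value, "target"])
        use_ntc = bool(sample_targets & {t.value for t in NTC_REFERENCE_TARGETS})
        neg_role = WellRole.no_template_control if use_ntc else WellRole.negative_control
        neg = _control_well(group, plate, channel, neg_role)
        pos = _control_well(group, plate, channel, WellRole.positive_control)
        thresholds[(plate, channel)] = set_threshold_from_controls(neg, pos)
    return thresholds


def quantify_stage(
    droplets: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    geometry: ReactionGeometry | None = None,
) -> pd.DataFrame:
    """Droplet amplitudes -> per-sample, per-target marker measurements.

    Thresholds are derived per plate x channel from that plate's controls;
    sample wells are classified, Poisson-corrected and scaled to copies/mL
    using each sample's plasma and template volumes from the sample sheet.
    """
    base = geometry or ReactionGeometry()
    thresholds = plate_thresholds(droplets)
    sheet = sample_sheet.set_index("sample_id")

    rows = []
    samples = droplets[droplets["role"] == WellRole.sample.value]
    for (plate, well, channel), w in samples.groupby(
        ["plate_id", "well_id", "channel"], sort=True
    ):
        sid = w["sample_id"].iloc[0]
        if sid not in sheet.index:
            raise PipelineError("quantify", f"sample {sid!r} not in sample sheet")
        geom = dataclasses.replace(
            base,
            plasma_volume=float(sheet.loc[sid, "plasma_volume_ml"]),
            template_volume=float(sheet.loc[sid, "template_volume_ul"]),
        )
        dw = DropletWell(
            well_id=well,
            plate_id=plate,
            channel=Channel(channel),
            target=Target(w["target"].iloc[0]),
            role=WellRole.sample,
            amplitudes=w["amplitude"].to_numpy(dtype=float),
        )
        m = quantify_well(dw, thresholds[(plate, channel)], geom)
        rows.append(
            {
                "sample_id": sid,
                "plate_id": plate,
                "well_id": well,
                "channel": channel,
                "target": m.target.value,
                "k_positive": m.k_positive,
                "n_total": m.n_total,
                "threshold": m.threshold,
                "copies_per_reaction": m.copies_per_reaction,
                "copies_per_ml_plasma": m.copies_per_ml_plasma,
                "saturated": m.saturated,
            }
        )
    return pd.DataFrame(rows)


def _sum_or_none(values: pd.Series) -> float | None:
    return float(values.sum()) if len(values) else None


def qc_stage(
    measurements: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    config: QCConfig | None = None,
) -> pd.DataFrame:
    """Per-sample QC metrics and the exclusion gate.

    CPP1 recovery is measured against the spiked amount from the sample
    sheet; CF before conversion is read from the dedicated CF plate
    (``-CFB`` suffix), CF after conversion from the methylation run; the
    droplet minimum applies to every well of the sample.
    """
    config = config or QCConfig()
    rows = []
    by_sample = dict(tuple(measurements.groupby("sample_id", sort=True)))
    for sheet_row in sample_sheet.sort_values("sample_id").itertuples(index=False):
        sid = sheet_row.sample_id
        m = by_sample.get(sid)
        metrics = QCMetrics(sample_id=sid)
        if m is not None and len(m):
            metrics.min_droplets = int(m["n_total"].min())
            cpp1 = m.loc[m["target"] == Target.CPP1.value, "copies_per_reaction"]
            pbc = m.loc[m["target"] == Target.PBC.value, "copies_per_reaction"]
            cf = m[m["target"] == Target.CF.value]
            before = cf.loc[cf["plate_id"].str.endswith(CF_BEFORE_SUFFIX), "copies_per_reaction"]
            after = cf.loc[~cf["plate_id"].str.endswith(CF_BEFORE_SUFFIX), "copies_per_reaction"]
            metrics.pbc_copies = _sum_or_none(pbc)
            metrics.cf_before = _sum_or_none(before)
            metrics.cf_after = _sum_or_none(after)
            if len(cpp1) and sheet_row.spiked_cpp1_copies > 0:
                metrics.purification_efficiency = purification_efficiency(
                    float(cpp1.sum()), float(sheet_row.spiked_cpp1_copies)
                )
            if metrics.cf_before and metrics.cf_before > 0 and metrics.cf_after is not None:
                metrics.bisulfite_recovery = bisulfite_recovery(
                    metrics.cf_before, metrics.cf_after
                )
        result = qc_gate(metrics, config)
        rows.append(
            {
                "sample_id": sid,
                "patient_id": sheet_row.patient_id,
                "timepoint": sheet_row.timepoint,
                "purification_efficiency_pct": metrics.purification_efficiency,
                "bisulfite_recovery_pct": metrics.bisulfite_recovery,
                "pbc_copies": metrics.pbc_copies,
                "cf_before": metrics.cf_before,
                "cf_after": metrics.cf_after,
                "min_droplets": metrics.min_droplets,
                "qc_pass": result.passed,
                "reasons": ";".join(result.reasons),
            }
        )
    return pd.DataFrame(rows)


def call_stage(
    measurements: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    qc_report: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """TriMeth 2-of-3 calls per sample.

    QC-failed samples are carried with ``qc_pass`` False and no call; the
    table mirrors the shape of a per-sample supplementary results file so
    an external per-sample table can be re-scored through the same rule.
    A saturated marker well counts positive (its droplet count equals the
    well size) but contributes no copies/mL to the TriMeth total.
    """
    qc_pass = (
        {r.sample_id: bool(r.qc_pass) for r in qc_report.itertuples(index=False)}
        if qc_report is not None
        else {}
    )
    rows = []
    by_sample = dict(tuple(measurements.groupby("sample_id", sort=True)))
    for sheet_row in sample_sheet.sort_values("sample_id").itertuples(index=False):
        sid = sheet_row.sample_id
        m = by_sample.get(sid, pd.DataFrame(columns=measurements.columns))
        passed = qc_pass.get(sid, True)
        droplets, copies = {}, {}
        for t in TRIMETH_MARKERS:
            sub = m[m["target"] == t.value]
            if len(sub):
                droplets[t] = (int(sub["k_positive"].sum()), int(sub["n_total"].sum()))
                copies[t] = float(sub["copies_per_ml_plasma"].fillna(0.0).sum())
        complete = all(t in droplets for t in TRIMETH_MARKERS)
        call = sample_call(droplets) if (passed and complete) else None
        total = trimeth_total(copies) if complete else float("nan")
        row = {
            "sample_id": sid,
            "patient_id": sheet_row.patient_id,
            "timepoint": sheet_row.timepoint,
        }
        for t in TRIMETH_MARKERS:
            k, n = droplets.get(t, (np.nan, np.nan))
            row[f"{t.value}_k_positive"] = k
            row[f"{t.value}_copies_per_ml"] = copies.get(t, np.nan)
        row["trimeth_total_copies_per_ml"] = total
        row["call"] = call.value if call is not None else ""
        row["qc_pass"] = passed
        rows.append(row)
    return pd.DataFrame(rows)


def call_table_to_results(call_table: pd.DataFrame) -> list[SampleResult]:
    """Rehydrate SampleResult objects from a call table."""
    results = []
    for r in call_table.itertuples(index=False):
        call = Call(r.call) if r.call else None
        results.append(
            SampleResult(
                sample_id=r.sample_id,
                patient_id=r.patient_id,
                timepoint=Timepoint(r.timepoint),
                trimeth_total_copies_per_ml=float(r.trimeth_total_copies_per_ml),
                call=call,
                qc_pass=bool(r.qc_pass),
            )
        )
    return results


@dataclass
class SurvivalBundle:
    endpoints: pd.DataFrame
    detection: pd.DataFrame
    comparisons: pd.DataFrame   # per timepoint x endpoint: HR, CI, p, landmark
    km_tables: dict
    dynamics: pd.DataFrame
    roc: pd.DataFrame


def survival_stage(
    clinical: pd.DataFrame,
    call_table: pd.DataFrame,
    landmark_months: float = LANDMARK_MONTHS,
) -> SurvivalBundle:
    """Prognostic analytics of the ctDNA calls.

    Per timepoint: detection rate, RFS/OS Kaplan-Meier by ctDNA status
    with landmark survival, log-rank test, univariable Cox HR; plus
    dynamics groups (after one chemotherapy cycle -> post-surgery) and ROC
    of the TriMeth copies/mL against recurrence status.
    """
    records = clinical_to_records(clinical)
    eps = {rec.patient_id: build_endpoints(rec) for rec in records}
    results = call_table_to_results(call_table)

    ep_rows = [
        {"patient_id": pid, "endpoint": e.endpoint.value, "time_months": e.time,
         "event": e.event}
        for pid, pair in sorted(eps.items())
        for e in pair
    ]
    endpoints_df = pd.DataFrame(ep_rows)

    det_rows, cmp_rows, km_tables = [], [], {}
    for tp in Timepoint:
        n_pos, n_eval, pct = detection_rate(results, tp)
        det_rows.append(
            {"timepoint": tp.value, "n_positive": n_pos, "n_evaluable": n_eval,
             "percent": pct}
        )
        calls = {
            r.patient_id: Call(r.call)
            for r in results
            if Timepoint(r.timepoint) is tp and r.qc_pass and r.call is not None
        }
        pos_ids = {p for p, c in calls.items() if c is Call.positive}
        neg_ids = set(calls) - pos_ids
        if not pos_ids or not neg_ids:
            continue
        for which, idx in ((Endpoint.RFS, 0), (Endpoint.OS, 1)):
            grp_pos = [eps[p][idx] for p in sorted(pos_ids) if p in eps]
            grp_neg = [eps[p][idx] for p in sorted(neg_ids) if p in eps]
            if not grp_pos or not grp_neg:
                continue
            lr = logrank_test(grp_pos, grp_neg)
            km_pos, km_neg = km_estimate(grp_pos), km_estimate(grp_neg)
            km_tables[(tp.value, which.value, "positive")] = km_pos.event_table
            km_tables[(tp.value, which.value, "negative")] = km_neg.event_table
            s_pos = km_pos.survival_at(landmark_months)
            s_neg = km_neg.survival_at(landmark_months)
            cov = {p: ("positive" if p in pos_ids else "negative")
                   for p in sorted(pos_ids | neg_ids) if p in eps}
            try:
                # reference level = negative (not detected)
                est = cox_univariable(
                    grp_pos + grp_neg, cov, name="ctDNA",
                    levels=["negative", "positive"],
                )[0]
                hr, lo, hi, p_cox, diag = est.hr, est.ci_low, est.ci_high, est.p_value, est.diagnostic
            except ValueError as exc:
                hr = lo = hi = p_cox = float("nan")
                diag = str(exc)
            cmp_rows.append(
                {
                    "timepoint": tp.value,
                    "endpoint": which.value,
                    "n_positive": len(grp_pos),
                    "n_negative": len(grp_neg),
                    "logrank_chi2": lr.statistic,
                    "logrank_p": lr.p_value,
                    "hr": hr,
                    "hr_ci_low": lo,
                    "hr_ci_high": hi,
                    "hr_p": p_cox,
                    "hr_diagnostic": diag,
                    f"landmark_{int(landmark_months)}m_positive": s_pos[0],
                    f"landmark_{int(landmark_months)}m_negative": s_neg[0],
                }
            )

    groups, excluded = dynamics_groups(results, Timepoint.after_1_cycle, Timepoint.post_surgery)
    dyn_rows = [
        {"patient_id": pid, "group": g.value} for pid, g in sorted(groups.items())
    ] + [{"patient_id": pid, "group": "excluded_missing_call"} for pid in excluded]
    dynamics_df = pd.DataFrame(dyn_rows, columns=["patient_id", "group"])

    recurred = {
        rec.patient_id: rec.recurrence_date is not None for rec in records
    }
    roc_rows = []
    for tp in Timepoint:
        scored = [
            (r.trimeth_total_copies_per_ml, recurred.get(r.patient_id, False))
            for r in results
            if Timepoint(r.timepoint) is tp and r.qc_pass and r.call is not None
            and np.isfinite(r.trimeth_total_copies_per_ml)
        ]
        labels = [lab for _, lab in scored]
        if len(set(labels)) == 2:
            _, _, _, auc = roc_analysis([s for s, _ in scored], labels)
            roc_rows.append({"timepoint": tp.value, "n": len(scored), "auc": auc})
    roc_df = pd.DataFrame(roc_rows, columns=["timepoint", "n", "auc"])

    return SurvivalBundle(
        endpoints=endpoints_df,
        detection=pd.DataFrame(det_rows),
        comparisons=pd.DataFrame(cmp_rows),
        km_tables=km_tables,
        dynamics=dynamics_df,
        roc=roc_df,
    )


@dataclass
class RunConfig:
    """File-level configuration of a full pipeline run."""

    droplets: str | Path
    sample_sheet: str | Path
    clinical: str | Path | None = None
    out_dir: str | Path = "trimeth_out"
    geometry: ReactionGeometry = field(default_factory=ReactionGeometry)
    qc: QCConfig = field(default_factory=QCConfig)
    landmark_months: float = LANDMARK_MONTHS
    skip_survival: bool = False
    seed: int = 0


def run_pipeline(config: RunConfig) -> dict:
    """Execute quantify -> qc -> call (-> survival) and write outputs.

    Returns a metadata dict (also written as ``run_metadata.json``); stage
    CSVs and a human-readable summary land in ``out_dir``.  Stage errors
    raise PipelineError with a stage tag; outputs of completed stages are
    retained.
    """
    from trimeth.io import read_clinical, read_droplets, read_sample_sheet

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta: dict = {
        "software": "trimeth",
        "version": __version__,
        "seed": config.seed,
        "started_utc": _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"),
        "inputs": {
            "droplets": str(config.droplets),
            "sample_sheet": str(config.sample_sheet),
            "clinical": str(config.clinical) if config.clinical else None,
        },
    }
    summary_lines = []

    try:
        droplets = read_droplets(config.droplets)
        sheet = read_sample_sheet(config.sample_sheet)
    except Exception as exc:
        raise PipelineError("input", str(exc)) from exc

    try:
        thresholds = plate_thresholds(droplets)
        measurements = quantify_stage(droplets, sheet, config.geometry)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("quantify", str(exc)) from exc
    write_csv(measurements, out / "measurements.csv")
    meta["thresholds"] = {
        f"{p}/{c}": t.threshold for (p, c), t in sorted(thresholds.items())
    }
    meta["droplets_per_well"] = {
        f"{r.plate_id}/{r.well_id}": int(r.n_total)
        for r in measurements.drop_duplicates(["plate_id", "well_id"]).itertuples(index=False)
    }

    try:
        qc_report = qc_stage(measurements, sheet, config.qc)
    except Exception as exc:
        raise PipelineError("qc", str(exc)) from exc
    write_csv(qc_report, out / "qc_report.csv")
    n_fail = int((~qc_report["qc_pass"]).sum())
    meta["qc"] = {
        "n_samples": int(len(qc_report)),
        "n_excluded": n_fail,
        "excluded": sorted(qc_report.loc[~qc_report["qc_pass"], "sample_id"]),
    }
    summary_lines.append(
        f"samples collected: {len(qc_report)}; QC-passed: {len(qc_report) - n_fail}; "
        f"excluded: {n_fail}"
    )

    try:
        calls = call_stage(measurements, sheet, qc_report)
    except Exception as exc:
        raise PipelineError("call", str(exc)) from exc
    write_csv(calls, out / "calls.csv")
    evaluable = calls[calls["qc_pass"] & (calls["call"] != "")]
    summary_lines.append(
        f"evaluable samples: {len(evaluable)}; "
        f"positive: {int((evaluable['call'] == 'positive').sum())}"
    )

    if not config.skip_survival and config.clinical:
        try:
            clinical = read_clinical(config.clinical)
            bundle = survival_stage(clinical, calls, config.landmark_months)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("survival", str(exc)) from exc
        write_csv(bundle.endpoints, out / "endpoints.csv")
        write_csv(bundle.detection, out / "detection_rates.csv")
        write_csv(bundle.comparisons, out / "hazard_ratios.csv")
        write_csv(bundle.dynamics, out / "dynamics_groups.csv")
        write_csv(bundle.roc, out / "roc_auc.csv")
        for (tp, ep, grp), table in bundle.km_tables.items():
            write_csv(table, out / f"km_{tp}_{ep}_{grp}.csv")
        for r in bundle.detection.itertuples(index=False):
            summary_lines.append(
                f"{r.timepoint}: ctDNA detected in {r.percent}% "
                f"({r.n_positive} of {r.n_evaluable})"
            )
        meta["survival"] = {
            "landmark_months": config.landmark_months,
            "n_patients": int(clinical["patient_id"].nunique()),
        }

    meta["finished_utc"] = _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    (out / "summary.txt").write_text("\n".join(summary_lines) + "\n")
    return meta
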