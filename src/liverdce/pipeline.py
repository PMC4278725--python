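"""End-to-end orchestration of the pre-bolus vs main-bolus comparison study.

For every subject the pipeline:

1. converts the pre-bolus aortic signal to concentration (saturation-
   recovery model) and the main-bolus aorta/portal/liver signals to
   concentration (SPGR model);
2. applies the hematocrit plasma correction to the blood pools;
3. reconstructs the full-dose AIF from the pre-bolus response;
4. measures the five shape parameters of both AIF variants;
5. fits the dual-input single-compartment model with each AIF;

and then assembles cohort tables: shape comparison, perfusion agreement
(CV and Bland-Altman limits), and test-retest reproducibility when
replicate acquisitions exist.  Per-subject failures are quarantined with a
reason; the run fails only if every subject fails.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from .aif import reconstruct_aif
from .config import PipelineConfig
from .kinetics import FitResult, fit_dual_input
from .metrics import ShapeParams, detect_trise, shape_parameters
from .signal_model import (
    AcquisitionParams,
    RelaxationParams,
    blood_to_plasma,
    signal_to_concentration,
)
from .stats import PairedMeasurements, bland_altman, test_retest_cv
from .synthetic import SyntheticSubject, generate_cohort
from .timeseries import TimeSeries, read_timeseries, write_timeseries

__all__ = ["SubjectData", "SubjectResult", "CohortReport", "PipelineError",
           "run_pipeline", "process_subject", "write_report"]

log = logging.getLogger("liverdce")

SHAPE_COLS = ["cpeak", "ttp", "upslope", "auc60", "fwhm"]
PERFUSION_COLS = ["fa", "fp", "ft", "art", "pv", "dv", "mtt"]


class PipelineError(RuntimeError):
    """Raised when no subject could be processed."""


@dataclass
class SubjectData:
    """One subject's raw inputs (signal series + per-subject scalars)."""

    subject_id: str
    prebolus_si: TimeSeries
    aorta_si: TimeSeries
    portal_si: TimeSeries
    liver_si: TimeSeries
    hematocrit: float
    t10_liver: float
    replicate: int = 1   # 1 = first visit, 2 = retest


@dataclass
class SubjectResult:
    data: SubjectData
    prebolus_conc: TimeSeries
    aif_prebolus: TimeSeries
    aif_mainbolus: TimeSeries
    portal_conc: TimeSeries
    liver_conc: TimeSeries
    shapes: dict[str, ShapeParams]      # keys: prebolus_aif, mainbolus_aif
    fits: dict[str, FitResult]          # keys: prebolus, mainbolus


@dataclass
class CohortReport:
    shape_df: pd.DataFrame
    perfusion_df: pd.DataFrame
    shape_agreement: pd.DataFrame
    perfusion_agreement: pd.DataFrame
    retest_shape_cv: pd.DataFrame | None
    retest_perfusion_cv: pd.DataFrame | None
    quarantine: pd.DataFrame
    results: list[SubjectResult] = field(default_factory=list)


# ---------------------------------------------------------------------------
# subject-level processing
# ---------------------------------------------------------------------------

def _acquisitions(cfg: PipelineConfig) -> tuple[AcquisitionParams, AcquisitionParams]:
    a = cfg.acquisition
    pre = AcquisitionParams(
        sequence_kind="sat_recovery", tr=a.prebolus_tr, te=a.prebolus_te,
        flip_angle_deg=a.prebolus_flip_deg, recovery_time=a.prebolus_recovery_time,
    )
    main = AcquisitionParams(
        sequence_kind="spgr", tr=a.mainbolus_tr, te=a.mainbolus_te,
        flip_angle_deg=a.mainbolus_flip_deg,
    )
    return pre, main


def process_subject(data: SubjectData, cfg: PipelineConfig) -> SubjectResult:
    """Run the full quantification chain on one subject."""
    acq_pre, acq_main = _acquisitions(cfg)
    relax_blood = RelaxationParams(t10=cfg.relaxation.t10_blood, r1=cfg.relaxation.r1)
    relax_liver = RelaxationParams(t10=data.t10_liver, r1=cfg.relaxation.r1)
    m = cfg.metrics
    protocol = cfg.protocol.to_protocol()

    pre_conc = signal_to_concentration(
        data.prebolus_si, m.n_baseline_pre, acq_pre, relax_blood, m.conc_max
    ).series
    pre_plasma = blood_to_plasma(pre_conc, data.hematocrit)
    aif_pre = reconstruct_aif(pre_plasma, protocol, mode=cfg.fit.reconstruction_mode)

    aif_main = blood_to_plasma(
        signal_to_concentration(
            data.aorta_si, m.n_baseline_main, acq_main, relax_blood, m.conc_max
        ).series,
        data.hematocrit,
    )
    portal = blood_to_plasma(
        signal_to_concentration(
            data.portal_si, m.n_baseline_main, acq_main, relax_blood, m.conc_max
        ).series,
        data.hematocrit,
    )
    liver = signal_to_concentration(
        data.liver_si, m.n_baseline_main, acq_main, relax_liver, m.conc_max
    ).series

    shapes = {}
    for kind, series, nb in (
        ("prebolus_aif", aif_pre, m.n_baseline_pre),
        ("mainbolus_aif", aif_main, m.n_baseline_main),
    ):
        trise = detect_trise(series, nb, m.k_sd)
        shapes[kind] = shape_parameters(series, trise)

    fit_opts = cfg.fit.to_fit_options()
    fits = {
        "prebolus": fit_dual_input(aif_pre, portal, liver, fit_opts),
        "mainbolus": fit_dual_input(aif_main, portal, liver, fit_opts),
    }
    return SubjectResult(
        data=data,
        prebolus_conc=pre_plasma,
        aif_prebolus=aif_pre,
        aif_mainbolus=aif_main,
        portal_conc=portal,
        liver_conc=liver,
        shapes=shapes,
        fits=fits,
    )


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def _shape_row(sid: str, replicate: int, kind: str, p: ShapeParams) -> dict:
    return {
        "subject_id": sid,
        "replicate": replicate,
        "curve_kind": kind,
        "cpeak": p.cpeak,
        "ttp": p.ttp,
        "upslope": p.upslope,
        "auc60": p.auc60,
        "fwhm": p.fwhm,
        "trise": p.trise,
        "tpeak": p.tpeak,
        "auc60_truncated": p.auc60_truncated,
        "fwhm_censored": p.fwhm_left_censored or p.fwhm_right_censored,
    }


def _perfusion_row(sid: str, replicate: int, source: str, fit: FitResult) -> dict:
    k, pf = fit.params, fit.perfusion
    return {
        "subject_id": sid,
        "replicate": replicate,
        "aif_source": source,
        "fa": pf.fa, "fp": pf.fp, "ft": pf.ft, "art": pf.art,
        "pv": pf.pv, "dv": pf.dv, "mtt": pf.mtt,
        "k1a": k.k1a, "k1p": k.k1p, "k2": k.k2,
        "tau_a": k.tau_a, "tau_p": k.tau_p,
        "sse": fit.sse, "converged": fit.converged,
    }


def _paired(df: pd.DataFrame, col: str, a_key: tuple, b_key: tuple, by: str):
    da = df[df[by] == a_key].set_index("subject_id")[col]
    db = df[df[by] == b_key].set_index("subject_id")[col]
    ids = sorted(set(da.index) & set(db.index))
    return ids, da.loc[ids].to_numpy(), db.loc[ids].to_numpy()


def _shape_agreement(shape_df: pd.DataFrame) -> pd.DataFrame:
    first = shape_df[shape_df.replicate == 1]
    rows = []
    for col in SHAPE_COLS:
        ids, pre, main = _paired(first, col, "prebolus_aif", "mainbolus_aif", "curve_kind")
        try:
            pval = float(wilcoxon(pre, main).pvalue) if len(ids) >= 2 else float("nan")
        except ValueError:  # all differences zero
            pval = 1.0
        rows.append({
            "parameter": col,
            "prebolus_mean": float(np.mean(pre)), "prebolus_sd": float(np.std(pre, ddof=1)) if len(pre) > 1 else 0.0,
            "mainbolus_mean": float(np.mean(main)), "mainbolus_sd": float(np.std(main, ddof=1)) if len(main) > 1 else 0.0,
            "wilcoxon_p": pval,
            "n": len(ids),
        })
    return pd.DataFrame(rows)


def _perfusion_agreement(perf_df: pd.DataFrame, ba_mode: str) -> pd.DataFrame:
    first = perf_df[perf_df.replicate == 1]
    rows = []
    for col in PERFUSION_COLS:
        ids, pre, main = _paired(first, col, "prebolus", "mainbolus", "aif_source")
        row = {
            "parameter": col,
            "prebolus_mean": float(np.mean(pre)), "prebolus_sd": float(np.std(pre, ddof=1)) if len(pre) > 1 else 0.0,
            "mainbolus_mean": float(np.mean(main)), "mainbolus_sd": float(np.std(main, ddof=1)) if len(main) > 1 else 0.0,
            "n": len(ids),
        }
        if len(ids) >= 2:
            rep = bland_altman(
                PairedMeasurements(ids, pre, main, label=col), mode=ba_mode
            )
            row.update({
                "mean_cv_pct": rep.mean_cv_pct,
                "bias_pct": rep.bias_pct,
                "loa_low_pct": rep.loa_low_pct,
                "loa_high_pct": rep.loa_high_pct,
            })
            try:
                row["wilcoxon_p"] = float(wilcoxon(pre, main).pvalue)
            except ValueError:
                row["wilcoxon_p"] = 1.0
        rows.append(row)
    return pd.DataFrame(rows)


def _retest_tables(df: pd.DataFrame, cols: list[str], by: str) -> pd.DataFrame:
    """Mean and range of test-retest CVs, per parameter and per AIF method."""
    out = []
    for key in sorted(df[by].unique()):
        sub = df[df[by] == key]
        v1 = sub[sub.replicate == 1][["subject_id"] + cols]
        v2 = sub[sub.replicate == 2][["subject_id"] + cols]
        common = sorted(set(v1.subject_id) & set(v2.subject_id))
        if not common:
            continue
        tab = test_retest_cv(
            v1[v1.subject_id.isin(common)], v2[v2.subject_id.isin(common)],
            id_col="subject_id", param_cols=cols,
        )
        tab.insert(0, by, key)
        out.append(tab)
    return pd.concat(out, ignore_index=True) if out else pd.DataFrame()


def _subject_data_from_synthetic(sub: SyntheticSubject, replicate: int) -> SubjectData:
    return SubjectData(
        subject_id=sub.subject_id,
        prebolus_si=sub.prebolus_si,
        aorta_si=sub.mainbolus_aorta_si,
        portal_si=sub.portal_si,
        liver_si=sub.liver_si,
        hematocrit=sub.truth.hematocrit,
        t10_liver=sub.truth.t10_liver,
        replicate=replicate,
    )


def load_manifest(manifest_path, cfg: PipelineConfig) -> tuple[list[SubjectData], list[dict]]:
    """Read a cohort manifest CSV: one row per subject (and per replicate).

    Required columns: subject_id, prebolus_si, aorta_si, portal_si,
    liver_si, hematocrit.  Optional: t10_liver, replicate.  Rows whose
    files are missing or unreadable are quarantined, not fatal.
    """
    mdir = Path(manifest_path).parent
    df = pd.read_csv(manifest_path)
    subjects, quarantine = [], []
    for _, row in df.iterrows():
        sid = str(row["subject_id"])
        replicate = int(row["replicate"]) if "replicate" in df.columns else 1
        try:
            series = {}
            for key in ("prebolus_si", "aorta_si", "portal_si", "liver_si"):
                path = mdir / str(row[key])
                if not path.exists():
                    raise FileNotFoundError(f"missing input file {path}")
                series[key] = read_timeseries(path)
        except Exception as exc:
            quarantine.append({"subject_id": sid, "replicate": replicate, "reason": str(exc)})
            continue
        subjects.append(
            SubjectData(
                subject_id=sid,
                hematocrit=float(row["hematocrit"]),
                t10_liver=float(row["t10_liver"])
                if "t10_liver" in df.columns else cfg.relaxation.t10_liver,
                replicate=replicate,
                **series,
            )
        )
    return subjects, quarantine


def gather_subjects(cfg: PipelineConfig) -> tuple[list[SubjectData], list[dict]]:
    """Materialise the cohort from the simulate block or the input manifest."""
    if cfg.simulate is not None:
        sim = cfg.simulate
        overrides = {}
        if sim.noise_sd is not None:
            overrides["noise_sd"] = sim.noise_sd
        if sim.inflow_amplitude is not None:
            overrides["inflow_amplitude"] = sim.inflow_amplitude
        subs, retests = generate_cohort(
            sim.n_subjects,
            sim.master_seed,
            retest=sim.retest,
            protocol=cfg.protocol.to_protocol(),
            truth_overrides=overrides or None,
            snap_delays=sim.snap_delays,
        )
        data = [_subject_data_from_synthetic(s, 1) for s in subs]
        data += [_subject_data_from_synthetic(s, 2) for s in retests]
        return data, []
    return load_manifest(cfg.inputs.manifest, cfg)


def run_pipeline(cfg: PipelineConfig, out_dir=None) -> CohortReport:
    """Run the whole study; optionally write all artifacts under ``out_dir``."""
    subjects, quarantine = gather_subjects(cfg)
    shape_rows, perf_rows, results = [], [], []
    for data in subjects:
        tag = f"{data.subject_id}" + ("" if data.replicate == 1 else f"(retest)")
        try:
            log.info("processing %s", tag)
            res = process_subject(data, cfg)
        except Exception as exc:  # quarantine, keep going
            log.warning("quarantined %s: %s", tag, exc)
            quarantine.append(
                {"subject_id": data.subject_id, "replicate": data.replicate,
                 "reason": str(exc)}
            )
            continue
        results.append(res)
        for kind, p in res.shapes.items():
            shape_rows.append(_shape_row(data.subject_id, data.replicate, kind, p))
        for source, fit in res.fits.items():
            perf_rows.append(_perfusion_row(data.subject_id, data.replicate, source, fit))

    if (subjects or quarantine) and not results:
        raise PipelineError("all subjects failed; see quarantine")

    shape_df = pd.DataFrame(shape_rows)
    perf_df = pd.DataFrame(perf_rows)
    has_retest = bool(len(shape_df)) and (shape_df.replicate == 2).any()

    report = CohortReport(
        shape_df=shape_df,
        perfusion_df=perf_df,
        shape_agreement=_shape_agreement(shape_df) if len(shape_df) else pd.DataFrame(),
        perfusion_agreement=_perfusion_agreement(perf_df, cfg.stats.ba_mode) if len(perf_df) else pd.DataFrame(),
        retest_shape_cv=_retest_tables(shape_df, SHAPE_COLS, "curve_kind") if has_retest else None,
        retest_perfusion_cv=_retest_tables(perf_df, PERFUSION_COLS, "aif_source") if has_retest else None,
        quarantine=pd.DataFrame(quarantine, columns=["subject_id", "replicate", "reason"]),
        results=results,
    )
    if out_dir is not None:
        write_report(report, out_dir)
    return report


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def _fit_to_dict(fit: FitResult) -> dict:
    k, pf = fit.params, fit.perfusion
    return {
        "params": {"k1a": k.k1a, "k1p": k.k1p, "k2": k.k2,
                   "tau_a": k.tau_a, "tau_p": k.tau_p},
        "perfusion": {"fa": pf.fa, "fp": pf.fp, "ft": pf.ft, "art": pf.art,
                      "pv": pf.pv, "dv": pf.dv, "mtt": pf.mtt},
        "sse": fit.sse,
        "n_iter": fit.n_iter,
        "converged": fit.converged,
    }


def write_report(report: CohortReport, out_dir) -> None:
    """Write every stage's artifacts: per-subject curves + cohort tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for res in report.results:
        rep_suffix = "" if res.data.replicate == 1 else "_retest"
        sdir = out / "subjects" / f"{res.data.subject_id}{rep_suffix}"
        sdir.mkdir(parents=True, exist_ok=True)
        write_timeseries(res.prebolus_conc, sdir / "prebolus_plasma_conc.csv")
        write_timeseries(res.aif_prebolus, sdir / "aif_prebolus.csv")
        write_timeseries(res.aif_mainbolus, sdir / "aif_mainbolus.csv")
        write_timeseries(res.portal_conc, sdir / "portal_plasma_conc.csv")
        write_timeseries(res.liver_conc, sdir / "liver_conc.csv")
        for source, fit in res.fits.items():
            with open(sdir / f"fit_{source}.json", "w") as fh:
                json.dump(_fit_to_dict(fit), fh, indent=2, sort_keys=True)
                fh.write("\n")
    report.shape_df.to_csv(out / "shape_params.csv", index=False)
    report.perfusion_df.to_csv(out / "perfusion_params.csv", index=False)
    report.shape_agreement.to_csv(out / "shape_agreement.csv", index=False)
    report.perfusion_agreement.to_csv(out / "perfusion_agreement.csv", index=False)
    if report.retest_shape_cv is not None:
        report.retest_shape_cv.to_csv(out / "retest_shape_cv.csv", index=False)
        report.retest_perfusion_cv.to_csv(out / "retest_perfusion_cv.csv", index=False)
    report.quarantine.to_csv(out / "quarantine.csv", index=False)


def write_synthetic_inputs(cfg: PipelineConfig, out_dir) -> Path:
    """Write a simulated cohort as signal CSVs + manifest (simulate stage)."""
    if cfg.simulate is None:
        raise ValueError("config has no simulate block")
    subjects, _ = gather_subjects(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for data in subjects:
        rep_suffix = "" if data.replicate == 1 else "_retest"
        sdir = out / "signals" / f"{data.subject_id}{rep_suffix}"
        sdir.mkdir(parents=True, exist_ok=True)
        files = {}
        for key, series in (
            ("prebolus_si", data.prebolus_si), ("aorta_si", data.aorta_si),
            ("portal_si", data.portal_si), ("liver_si", data.liver_si),
        ):
            rel = f"signals/{data.subject_id}{rep_suffix}/{key}.csv"
            write_timeseries(series, out / rel)
            files[key] = rel
        rows.append({
            "subject_id": data.subject_id, "replicate": data.replicate,
            **files, "hematocrit": data.hematocrit, "t10_liver": data.t10_liver,
        })
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
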