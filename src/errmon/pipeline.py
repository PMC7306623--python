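"""End-to-end orchestration: simulate -> preprocess -> behavior -> ERP ->
decode -> stats, with an inclusion ledger and TSV/HTML report.

Every stage reads and writes the formats in :mod:`errmon.io_formats`, so a
run is resumable and each stage is independently testable.  A fixed seed
and config give a deterministic run; the config is serialized verbatim into
the output directory and its hash is stamped into every result table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import behavior as beh
from . import decoding as dec
from . import erp as erpmod
from . import stats as st
from .behavior import classify_phase
from .io_formats import (read_brainvision, read_config, read_subject_meta,
                         read_trial_table, load_default_montage, write_config)
from .preprocessing import CsdParams, csd_transform, extract_epochs, \
    regress_ocular, reject_artifacts
from .synthetic_data import generate_cohort

__all__ = ["RunConfig", "StageFailure", "run_pipeline", "classify_phase"]

log = logging.getLogger("errmon")


class StageFailure(RuntimeError):
    def __init__(self, stage: str, subject: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for subject {subject!r}: {cause}")
        self.stage, self.subject, self.cause = stage, subject, cause


@dataclass
class RunConfig:
    out_dir: str = "errmon_run"
    seed: int = 1
    n_patients: int = 24
    n_controls: int = 32
    n_trials: int = 360
    sampling_rate: float = 500.0
    write_eeg: bool = True            # False = behavior-only cohort
    stim_window: tuple[float, float] = (-100.0, 800.0)
    resp_window: tuple[float, float] = (-100.0, 600.0)
    decode_window: tuple[float, float] = (-100.0, 300.0)
    baseline: tuple[float, float] = (-100.0, 0.0)
    threshold_uv: float = 150.0
    csd_m: int = 4
    csd_legendre: int = 50
    csd_lambda: float = 1e-5
    csd_head_radius: float = 0.09
    decode_on_csd: bool = True
    folds: int = 10
    repeats: int = 10
    svm_c: float = 1.0
    family_alpha: float = 0.05
    corr_alpha: float = 0.025
    min_erp_trials: int = 6
    min_mvpa_errors: int = 10
    make_plots: bool = False
    stages: tuple[str, ...] = ("simulate", "behavior", "erp", "decode", "stats")

    def to_flat(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            out[f.name] = ",".join(map(str, v)) if isinstance(v, tuple) else v
        return out

    @classmethod
    def from_flat(cls, flat: dict) -> "RunConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in flat:
                continue
            v = flat[f.name]
            if f.name == "stages":
                kwargs[f.name] = tuple(str(v).split(","))
            elif isinstance(v, str) and "," in v:
                kwargs[f.name] = tuple(float(x) for x in v.split(","))
            else:
                kwargs[f.name] = v
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        return cls.from_flat(read_config(path))

    def fingerprint(self) -> str:
        # out_dir is where results land, not what they are: exclude it so
        # identical analyses hash identically wherever they are written
        items = sorted((k, v) for k, v in self.to_flat().items() if k != "out_dir")
        return hashlib.sha256(repr(items).encode()).hexdigest()[:12]

    def csd_params(self) -> CsdParams:
        return CsdParams(self.csd_m, self.csd_legendre, self.csd_lambda,
                         self.csd_head_radius)


def _bf_cell(t: float, n1: int, n2: int) -> str:
    if not math.isfinite(t):
        return ""
    bf = st.jzs_bf_ttest(t, n1, n2)
    if bf.bf10 >= 1.0:
        return f"BF10={bf.bf10:.3g}"
    return f"BF01={bf.bf01:.3g}"


def _group_compare(tab: pd.DataFrame, col: str) -> dict:
    """Independent t + JZS BF for one per-subject variable, patients vs controls."""
    a = tab.loc[tab["group"] == "patient", col].dropna().to_numpy()
    b = tab.loc[tab["group"] == "control", col].dropna().to_numpy()
    if len(a) < 2 or len(b) < 2:
        return {"variable": col, "n_patient": len(a), "n_control": len(b)}
    r = st.t_independent(a, b)
    return {"variable": col,
            "mean_patient": a.mean(), "sem_patient": a.std(ddof=1) / math.sqrt(len(a)),
            "mean_control": b.mean(), "sem_control": b.std(ddof=1) / math.sqrt(len(b)),
            "t": r.t, "df": r.df, "p": r.p,
            "bayes": _bf_cell(r.t, len(a), len(b)),
            "n_patient": len(a), "n_control": len(b)}


def run_pipeline(config: RunConfig, group_profiles: dict | None = None) -> dict:
    """Run all enabled stages; returns the report as a dict of DataFrames.

    Artifacts land under ``config.out_dir``: the dataset, per-subject QC
    logs, the inclusion ledger, behavioral/ERP/decoding/statistics tables as
    TSV, and an HTML digest.  Any stage failure aborts with the stage name
    and subject id; partial outputs stay on disk next to a FAILED sentinel.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    write_config(config.to_flat(), os.path.join(config.out_dir, "run_config.txt"))
    fp = config.fingerprint()
    dataset = os.path.join(config.out_dir, "dataset")
    report: dict = {}
    try:
        return _run(config, dataset, fp, report, group_profiles)
    except Exception:
        with open(os.path.join(config.out_dir, "FAILED"), "w") as f:
            f.write("run aborted; see logs\n")
        raise


def _run(config: RunConfig, dataset: str, fp: str, report: dict,
         group_profiles: dict | None = None) -> dict:
    montage = load_default_montage(config.csd_head_radius)

    if "simulate" in config.stages:
        log.info("stage=simulate n=%d+%d seed=%d",
                 config.n_patients, config.n_controls, config.seed)
        generate_cohort(config.n_patients, config.n_controls, dataset,
                        group_profiles=group_profiles,
                        seed=config.seed, n_trials=config.n_trials,
                        sampling_rate=config.sampling_rate,
                        write_eeg=config.write_eeg, montage=montage)
    meta = read_subject_meta(os.path.join(dataset, "subjects.tsv"))

    ledger_rows, beh_rows = [], []
    erp_rows, curves = [], {"patient": [], "control": []}
    fcz_waves: list[dict] = []   # response-locked FCz averages for the report figure
    decode_grid = dec.WindowGrid(*config.decode_window)
    subj_seeds = np.random.SeedSequence(config.seed + 7).generate_state(len(meta)) % (2 ** 31)

    for k, srow in enumerate(meta.itertuples(index=False)):
        sid, group = srow.subject_id, srow.group
        sdir = os.path.join(dataset, sid)
        try:
            trials = beh.classify_trials(read_trial_table(os.path.join(sdir, "trials.tsv")))
            summary = beh.summarize(trials)
            beh_rows.append({"subject_id": sid, "group": group,
                             **{f"rate_{c}": summary.rates[c] for c in beh.CATEGORIES},
                             "error_detection_rate": summary.error_detection_rate,
                             "baseline_rt": summary.baseline_rt,
                             "error_rt": summary.error_rt,
                             "delta_pes": summary.delta_pes})
            counts = summary.counts
            ok_erp, why_erp = beh.inclusion(counts, "erp", config.min_erp_trials,
                                            config.min_mvpa_errors)
            ok_mvpa, why_mvpa = beh.inclusion(counts, "mvpa", config.min_erp_trials,
                                              config.min_mvpa_errors)
            ledger_rows.append({"subject_id": sid, "group": group,
                                "erp_included": ok_erp, "erp_reason": why_erp,
                                "mvpa_included": ok_mvpa, "mvpa_reason": why_mvpa})
            log.info("stage=behavior subject=%s trials=%d detected=%d",
                     sid, len(trials), counts["detected_error"])
        except Exception as exc:
            raise StageFailure("behavior", sid, exc)

        if not config.write_eeg or not ({"erp", "decode"} & set(config.stages)):
            continue
        try:
            rec = read_brainvision(os.path.join(sdir, sid + ".vhdr"))
            rec = regress_ocular(rec)
            params = config.csd_params()

            def _csd_epochs(window):
                ep = extract_epochs(rec, "stimulus" if window is config.stim_window
                                    else "response", window, trials,
                                    baseline=config.baseline)
                ep = reject_artifacts(ep, config.threshold_uv)
                return ep, csd_transform(ep, montage, params)

            ep_stim, ep_stim_csd = _csd_epochs(config.stim_window)
            ep_resp, ep_resp_csd = _csd_epochs(config.resp_window)
            ep_stim_csd.qc_frame().to_csv(os.path.join(sdir, "qc_stimulus.tsv"),
                                          sep="\t", index=False)
            ep_resp_csd.qc_frame().to_csv(os.path.join(sdir, "qc_response.tsv"),
                                          sep="\t", index=False)
        except Exception as exc:
            raise StageFailure("preprocess", sid, exc)

        if "erp" in config.stages:
            try:
                for comp, cond in [("N2", "correct_go"), ("N2", "correct_withhold"),
                                   ("P3", "correct_go"), ("P3", "correct_withhold")]:
                    avg = erpmod.condition_average(ep_stim_csd, cond)
                    m = erpmod.measure_component(avg, comp)
                    erp_rows.append({"subject_id": sid, "group": group,
                                     "component": comp, "condition": cond,
                                     "amplitude": m.peak_amplitude,
                                     "latency": m.peak_latency, "auc": m.auc})
                if ok_erp:
                    for comp in ("Ne", "CRN", "Pe", "Pc"):
                        _, _, _, _, cond = erpmod.COMPONENT_DEFS[comp]
                        avg = erpmod.condition_average(ep_resp_csd, cond)
                        m = erpmod.measure_component(avg, comp)
                        erp_rows.append({"subject_id": sid, "group": group,
                                         "component": comp, "condition": cond,
                                         "amplitude": m.peak_amplitude,
                                         "latency": m.peak_latency, "auc": m.auc})
                        if comp in ("Ne", "CRN"):
                            fcz = avg.channel_labels.index("FCz")
                            fcz_waves.append({"group": group, "condition": cond,
                                              "times": avg.times,
                                              "wave": avg.data[fcz]})
                log.info("stage=erp subject=%s included=%s", sid, ok_erp)
            except Exception as exc:
                raise StageFailure("erp", sid, exc)

        if "decode" in config.stages and ok_mvpa:
            try:
                ep_dec = extract_epochs(rec, "response", config.decode_window,
                                        trials, baseline=config.baseline)
                ep_dec = reject_artifacts(ep_dec, config.threshold_uv)
                if config.decode_on_csd:
                    ep_dec = csd_transform(ep_dec, montage, config.csd_params())
                curve = dec.decode_subject(ep_dec, sid, decode_grid,
                                           folds=config.folds, repeats=config.repeats,
                                           seed=int(subj_seeds[k]), C=config.svm_c,
                                           min_per_class=config.min_mvpa_errors)
                curves[group].append(curve)
                log.info("stage=decode subject=%s n_per_class=%d", sid, curve.n_per_class)
            except Exception as exc:
                raise StageFailure("decode", sid, exc)

    behavior_table = pd.DataFrame(beh_rows)
    ledger = pd.DataFrame(ledger_rows)
    report["behavior"] = behavior_table
    report["inclusion_ledger"] = ledger

    if "stats" in config.stages:
        rows = [_group_compare(behavior_table, c) for c in
                ("rate_incorrect_go", "rate_miss_go", "rate_detected_error",
                 "rate_undetected_error", "error_detection_rate",
                 "baseline_rt", "error_rt", "delta_pes")]
        err = behavior_table[["subject_id", "group"]].copy()
        err["nogo_error_rate"] = (behavior_table["rate_detected_error"]
                                  + behavior_table["rate_undetected_error"])
        rows.insert(4, _group_compare(err, "nogo_error_rate"))
        report["behavior_group_stats"] = pd.DataFrame(rows)

        if erp_rows:
            erp_table = pd.DataFrame(erp_rows)
            report["erp_measures"] = erp_table
            anova_rows = []
            pairs = [("N2", "correct_withhold", "correct_go"),
                     ("P3", "correct_withhold", "correct_go"),
                     (("Ne", "CRN"), "detected_error", "correct_go"),
                     (("Pe", "Pc"), "detected_error", "correct_go")]
            for comp, lvl1, lvl0 in pairs:
                c1, c0 = (comp, comp) if isinstance(comp, str) else comp
                for qty in ("amplitude", "latency"):
                    wide = _wide(erp_table, c1, lvl1, c0, lvl0, qty)
                    if len(wide) < 4 or wide["group"].nunique() < 2:
                        continue
                    res = st.mixed_anova_2x2(wide[["v0", "v1"]].to_numpy(),
                                             wide["group"].to_numpy())
                    anova_rows.append({"component": c1 if c1 == c0 else f"{c1}/{c0}",
                                       "quantity": qty,
                                       "F_group": res.f_group, "p_group": res.p_group,
                                       "F_response_type": res.f_within,
                                       "p_response_type": res.p_within,
                                       "F_interaction": res.f_interaction,
                                       "p_interaction": res.p_interaction,
                                       "df": f"(1, {res.df_den})",
                                       "gg_epsilon": res.gg_epsilon,
                                       "bayes": "not reproduced (Bayesian RM ANOVA out of scope)"})
            report["erp_anovas"] = pd.DataFrame(anova_rows)
            report["correlations"] = _patient_correlations(
                behavior_table, erp_table, meta, config.corr_alpha)

        if len(curves["patient"]) >= 2 and len(curves["control"]) >= 2:
            report["decoding_group"] = dec.group_analysis(
                curves["patient"], curves["control"], config.family_alpha)
            report["decoding_curves"] = pd.concat(
                [c.frame() for g in ("patient", "control") for c in curves[g]],
                ignore_index=True)

    if config.make_plots:
        from . import plots
        if "decoding_curves" in report:
            merged = report["decoding_curves"].merge(
                meta[["subject_id", "group"]], on="subject_id")
            plots.plot_decoding_curves(
                merged, os.path.join(config.out_dir, "decoding_accuracy.png"))
        if fcz_waves:
            times = fcz_waves[0]["times"]
            waves = {}
            for g in ("patient", "control"):
                for cond in ("correct_go", "detected_error"):
                    sel = [w["wave"] for w in fcz_waves
                           if w["group"] == g and w["condition"] == cond]
                    if sel:
                        waves[f"{g} {cond}"] = np.mean(sel, axis=0)
            plots.plot_erp_waveforms(
                waves, times, os.path.join(config.out_dir, "response_erps.png"),
                electrode="FCz")

    for name, tab in report.items():
        tab = tab.copy()
        tab.attrs["config_fingerprint"] = fp
        path = os.path.join(config.out_dir, f"{name}.tsv")
        with open(path, "w", encoding="utf-8") as f:
            f.write(f"# config={fp}\n")
            tab.to_csv(f, sep="\t", index=False)
    with open(os.path.join(config.out_dir, "report.html"), "w", encoding="utf-8") as f:
        f.write("<html><body><h1>errmon report</h1>")
        f.write(f"<p>config fingerprint: {fp}</p>")
        for name, tab in report.items():
            f.write(f"<h2>{name}</h2>")
            f.write(tab.to_html(index=False))
        f.write("</body></html>")
    return report


def _wide(erp_table: pd.DataFrame, c1: str, lvl1: str, c0: str, lvl0: str,
          qty: str) -> pd.DataFrame:
    a = erp_table[(erp_table["component"] == c0) & (erp_table["condition"] == lvl0)]
    b = erp_table[(erp_table["component"] == c1) & (erp_table["condition"] == lvl1)]
    m = a.merge(b, on=["subject_id", "group"], suffixes=("_0", "_1"))
    return m.rename(columns={f"{qty}_0": "v0", f"{qty}_1": "v1"})[
        ["subject_id", "group", "v0", "v1"]]


def _patient_correlations(behavior_table, erp_table, meta, corr_alpha) -> pd.DataFrame:
    """Clinical covariates vs task variables, patients only (difference
    scores for the neural variables: withhold-correct, error-correct)."""
    pat = behavior_table[behavior_table["group"] == "patient"].copy()
    pat["nogo_error_rate"] = pat["rate_detected_error"] + pat["rate_undetected_error"]
    pat = pat.merge(meta[["subject_id", "lesion_size_cm3", "days_post_stroke"]],
                    on="subject_id")
    deltas = {}
    for comp, lvl1, lvl0, name in [("N2", "correct_withhold", "correct_go", "dN2"),
                                   ("P3", "correct_withhold", "correct_go", "dP3"),
                                   (("Ne", "CRN"), "detected_error", "correct_go", "dNe"),
                                   (("Pe", "Pc"), "detected_error", "correct_go", "dPe")]:
        c1, c0 = (comp, comp) if isinstance(comp, str) else comp
        for qty in ("amplitude", "latency"):
            wide = _wide(erp_table[erp_table["group"] == "patient"],
                         c1, lvl1, c0, lvl0, qty)
            deltas[f"{name}_{qty}"] = wide.assign(delta=wide["v1"] - wide["v0"])[
                ["subject_id", "delta"]].rename(columns={"delta": f"{name}_{qty}"})
    for d in deltas.values():
        pat = pat.merge(d, on="subject_id", how="left")

    task_vars = ["baseline_rt", "nogo_error_rate", "error_detection_rate"] + \
        list(deltas.keys())
    rows = []
    for cov in ("lesion_size_cm3", "days_post_stroke"):
        for var in task_vars:
            sub = pat[[cov, var]].dropna()
            if len(sub) < 3:
                continue
            r, p = st.pearson(sub[cov], sub[var])
            rows.append({"covariate": cov, "variable": var, "n": len(sub),
                         "r": r, "p": p, "significant": p < corr_alpha})
    return pd.DataFrame(rows)
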