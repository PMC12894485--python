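"""End-to-end validation pipeline.

Orchestrates the full study replication: simulate (or load) cohorts, fit
the healthy-reference adjustment, build panel features, train the
classifiers and severity regressor on a training cohort, predict on a
disjoint validation cohort, run ROC inference (pooled, per-center, and
against the conventional CSF markers), evaluate the staging classifier's
independent prognostic value, propagate CSF-predicted severity through
the conversion chain to a predicted follow-up EDSS, and audit
misclassifications.

External-validation discipline is enforced structurally: every model
records the provenance tag of its training cohort, and the pipeline
refuses to evaluate a model on a cohort with the same tag.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from mscsf import features as feat
from mscsf import models as mdl
from mscsf import prognosis as prog
from mscsf import roc
from mscsf import simulate as sim

__all__ = [
    "PipelineConfig",
    "run_full_validation",
    "read_supplementary_results",
    "compare_with_conventional_markers",
    "misclassification_audit",
]

log = logging.getLogger("mscsf.pipeline")

_DIAGNOSIS_ALIASES = {
    "rrms": "RRMS",
    "rms": "RRMS",
    "progms": "ProgMS",
    "ppms": "ProgMS",
    "spms": "ProgMS",
    "oind": "OIND",
    "nind": "NIND",
}

# default column-name candidates for the supplementary results reader
_COLUMN_CANDIDATES = {
    "participant_id": ("participant_id", "id", "sample", "sample_id", "patientcode"),
    "diagnosis": ("diagnosis", "dx", "group", "final_diagnosis", "class"),
    "ms_probability": ("ms_probability", "ms_prob", "prob_ms", "msprobability"),
    "progms_probability": ("progms_probability", "progms_prob", "prob_progms"),
    "msdss_pred": ("msdss_pred", "csf_msdss", "predicted_msdss", "msdss"),
    "center": ("center", "site"),
    "age_at_lp": ("age_at_lp", "age"),
    "baseline_edss": ("baseline_edss", "edss_baseline"),
    "followup_edss": ("followup_edss", "edss_followup", "edss_fu"),
    "interval_years": ("interval_years", "followup_interval", "interval"),
    "ocb_positive": ("ocb_positive", "ocb"),
    "igg_index_elevated": ("igg_index_elevated", "igg_index_abnormal", "igg"),
    "scd27": ("scd27", "cd27"),
    "nfl": ("nfl", "neurofilament"),
}

_MANDATORY = ("participant_id", "diagnosis", "ms_probability")


@dataclass
class PipelineConfig:
    """Configuration of a full validation run.

    Exactly one of the three modes applies: ``simulate`` generates all
    cohorts from :class:`mscsf.simulate.SimConfig`; ``supplementary``
    reads a per-participant results table (model probabilities already
    computed); ``user_data`` reads cohort CSVs written in this package's
    format.
    """

    mode: str = "simulate"
    seed: int = 0
    sim: sim.SimConfig = field(default_factory=sim.SimConfig)
    # training-side cohort sizes (the cohort the classifiers are fitted on)
    train_n_rrms: int = 150
    train_n_progms: int = 80
    train_n_oind: int = 80
    train_n_nind: int = 80
    n_healthy: int = 150
    n_crosssectional: int = 3000
    panels: dict = field(
        default_factory=lambda: {
            "diagnostic": "diagnostic",
            "progms": "progms",
            "severity": "severity",
        }
    )
    n_trees: int = 500
    n_boot: int = 2000
    cutoff: float = 0.5
    scd27_healthy_log_mean: float = float(np.log(30.0))
    scd27_healthy_log_sd: float = 0.5
    supplementary_path: Optional[str] = None
    user_data_dir: Optional[str] = None
    column_map: Optional[dict] = None
    out_dir: Optional[str] = None

    def __post_init__(self):
        if self.mode not in ("simulate", "supplementary", "user_data"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "supplementary" and not self.supplementary_path:
            raise ValueError("supplementary mode needs supplementary_path")
        if self.mode == "user_data" and not self.user_data_dir:
            raise ValueError("user_data mode needs user_data_dir")
        if isinstance(self.sim, dict):
            self.sim = sim.SimConfig(**self.sim)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)


def _sub_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def _format_p(p) -> Optional[str]:
    return None if p is None else f"{p:.2e}"


def _roc_block(result: roc.RocResult) -> dict:
    d = result.to_dict()
    d["p_formatted"] = _format_p(d.get("p_value"))
    return d


def compare_with_conventional_markers(ms_probability, is_ms, ocb, igg) -> dict:
    """AUROCs of the classifier vs OCB, IgG index, and their combination,
    with paired DeLong comparisons, on the subcohort where both markers
    are available.

    The combined marker is the sum of the two binaries (a 3-level score),
    the minimal monotone combination.
    """
    prob = np.asarray(ms_probability, float)
    y = np.asarray(is_ms)
    ocb = np.asarray(ocb, float)
    igg = np.asarray(igg, float)
    keep = ~np.isnan(ocb) & ~np.isnan(igg) & ~np.isnan(prob)
    if not keep.any():
        raise ValueError("no participants with both OCB and IgG index available")
    prob, y, ocb, igg = prob[keep], y[keep], ocb[keep], igg[keep]
    combo = ocb + igg
    out = {
        "n_ms": int(np.sum(y)),
        "n_nonms": int(np.sum(~y.astype(bool))),
        "classifier_auc": roc.auroc(prob, y).auc,
        "ocb_auc": roc.auroc(ocb, y).auc,
        "igg_auc": roc.auroc(igg, y).auc,
        "ocb_plus_igg_auc": roc.auroc(combo, y).auc,
    }
    for name, scores in (("ocb", ocb), ("igg", igg), ("ocb_plus_igg", combo)):
        _, _, z, p = roc.delong_paired_test(prob, scores, y)
        out[f"delong_p_vs_{name}"] = p
        out[f"delong_p_vs_{name}_formatted"] = _format_p(p)
    return out


def misclassification_audit(
    records: pd.DataFrame,
    participants: pd.DataFrame,
    cutoff: float = 0.5,
    scd27_log_mean: float = float(np.log(30.0)),
    scd27_log_sd: float = 0.5,
) -> pd.DataFrame:
    """List misclassified participants with their ancillary CSF markers.

    A participant is misclassified when the dichotomized MS probability
    (score > cutoff) disagrees with the clinical MS/non-MS label. sCD27 is
    flagged as elevated when above the healthy mean + 2 SD bound (on the
    natural-log scale by default).
    """
    df = participants.merge(records, on="participant_id", how="inner")
    is_ms = df["diagnosis"].isin(sim.MS_CLASSES)
    called_ms = df["ms_probability"] > cutoff
    mis = df.loc[is_ms != called_ms].copy()
    bound = float(np.exp(scd27_log_mean + 2.0 * scd27_log_sd))
    rows = []
    for _, r in mis.iterrows():
        rows.append(
            {
                "participant_id": r["participant_id"],
                "diagnosis": r["diagnosis"],
                "ms_probability": r["ms_probability"],
                "direction": "ms_called_nonms" if r["diagnosis"] in sim.MS_CLASSES else "nonms_called_ms",
                "ocb_positive": r.get("ocb_positive"),
                "igg_index_elevated": r.get("igg_index_elevated"),
                "scd27": r.get("scd27"),
                "scd27_elevated": (
                    bool(r["scd27"] > bound) if pd.notna(r.get("scd27")) else None
                ),
                "nfl": r.get("nfl"),
            }
        )
    cols = [
        "participant_id", "diagnosis", "ms_probability", "direction",
        "ocb_positive", "igg_index_elevated", "scd27", "scd27_elevated", "nfl",
    ]
    return pd.DataFrame(rows, columns=cols)


def read_supplementary_results(path, column_map: Optional[dict] = None):
    """Read a per-participant results table (identifier, diagnosis, model
    probabilities, optional EDSS timeline and CSF markers).

    Column names are resolved through ``column_map`` (canonical name ->
    file column) or, failing that, a list of common candidates. Rows whose
    diagnosis label cannot be parsed are rejected with their line numbers
    logged. Returns ``(participants, records)`` DataFrames.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path} contains no rows")
    lower = {c.lower().strip(): c for c in df.columns}
    resolved = {}
    for canon, candidates in _COLUMN_CANDIDATES.items():
        if column_map and canon in column_map:
            if column_map[canon] not in df.columns:
                raise ValueError(f"mapped column {column_map[canon]!r} not in file")
            resolved[canon] = column_map[canon]
            continue
        for cand in candidates:
            if cand in lower:
                resolved[canon] = lower[cand]
                break
    missing = [c for c in _MANDATORY if c not in resolved]
    if missing:
        raise ValueError(
            f"mandatory columns missing: {missing}; columns found: {list(df.columns)}"
        )

    out = pd.DataFrame({canon: df[col] for canon, col in resolved.items()})
    parsed = out["diagnosis"].astype(str).str.strip().str.lower().map(_DIAGNOSIS_ALIASES)
    bad = parsed.isna()
    if bad.any():
        lines = (out.index[bad] + 2).tolist()  # header is line 1
        log.warning(
            "rejected %d rows with unparseable diagnosis labels at lines %s",
            int(bad.sum()), lines,
        )
        out = out.loc[~bad]
        parsed = parsed.loc[~bad]
    out["diagnosis"] = parsed.to_numpy()
    out = out.reset_index(drop=True)
    part_cols = [
        c for c in (
            "participant_id", "diagnosis", "center", "age_at_lp", "baseline_edss",
            "followup_edss", "interval_years", "ocb_positive",
            "igg_index_elevated", "scd27", "nfl",
        ) if c in out.columns
    ]
    rec_cols = [
        c for c in ("participant_id", "ms_probability", "progms_probability", "msdss_pred")
        if c in out.columns
    ]
    return out[part_cols].copy(), out[rec_cols].copy()


def _check_external(model: mdl.DiagnosticModel, cohort_tag: str):
    if model.training_provenance == cohort_tag:
        raise ValueError(
            f"external-validation violation: model trained on {model.training_provenance!r} "
            f"cannot be evaluated on cohort {cohort_tag!r}"
        )


def _diagnostic_section(records, participants, cfg, seeds) -> dict:
    merged = participants.merge(records, on="participant_id")
    y = merged["diagnosis"].isin(sim.MS_CLASSES).to_numpy()
    prob = merged["ms_probability"].to_numpy(float)
    pooled = roc.bootstrap_auc_ci(prob, y, n_boot=cfg.n_boot, seed=seeds[0])
    pooled.p_value = roc.mason_graham_p(prob, y)
    section = {"pooled": _roc_block(pooled)}
    if "center" in merged.columns and merged["center"].notna().any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            per_center = roc.auroc_by_group(prob, y, merged["center"].to_numpy())
        section["per_center"] = {
            str(k): _roc_block(v) for k, v in per_center.items() if k != "pooled"
        }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        section["confusion"] = roc.confusion_at_cutoff(prob, y, cfg.cutoff).to_dict()
    section["median_probability"] = {
        "ms": float(np.median(prob[y])),
        "nonms": float(np.median(prob[~y])),
    }
    try:
        section["conventional_markers"] = compare_with_conventional_markers(
            prob,
            y,
            merged.get("ocb_positive", pd.Series(np.nan, index=merged.index)),
            merged.get("igg_index_elevated", pd.Series(np.nan, index=merged.index)),
        )
    except ValueError as exc:
        section["conventional_markers"] = {"unavailable": str(exc)}
    return section


def _staging_section(records, participants, cfg, seeds) -> dict:
    merged = participants.merge(records, on="participant_id")
    ms = merged[merged["diagnosis"].isin(sim.MS_CLASSES)]
    if "progms_probability" not in ms.columns or ms["progms_probability"].isna().all():
        return {"unavailable": "no progMS probabilities"}
    y = (ms["diagnosis"] == "ProgMS").to_numpy()
    prob = ms["progms_probability"].to_numpy(float)
    if 0 < y.sum() < y.size:
        res = roc.bootstrap_auc_ci(prob, y, n_boot=cfg.n_boot, seed=seeds[1])
        res.p_value = roc.mason_graham_p(prob, y)
        section = {"auroc": _roc_block(res)}
    else:
        return {"unavailable": "staging needs both RRMS and progMS"}
    section["median_probability"] = {
        "progms": float(np.median(prob[y])),
        "rrms": float(np.median(prob[~y])),
    }
    needed = {"baseline_edss", "followup_edss", "age_at_lp"}
    if needed.issubset(ms.columns):
        try:
            rep = prog.multivariate_followup_model(
                ms["baseline_edss"], ms["age_at_lp"], prob, ms["followup_edss"]
            )
            section["multivariate_followup"] = rep.to_dict()
        except ValueError as exc:
            section["multivariate_followup"] = {"unavailable": str(exc)}
    else:
        section["multivariate_followup"] = {"unavailable": "EDSS timeline columns absent"}
    return section


def _prognostic_section(records, participants, conversions, cfg) -> dict:
    merged = participants.merge(records, on="participant_id")
    ms = merged[merged["diagnosis"].isin(sim.MS_CLASSES)]
    if "msdss_pred" not in ms.columns or ms["msdss_pred"].isna().all():
        return {"unavailable": "no CSF-predicted severity scores"}
    if conversions is None:
        return {"unavailable": "no conversion models (supplementary mode provides none)"}
    needed = {"baseline_edss", "followup_edss", "interval_years"}
    if not needed.issubset(ms.columns):
        return {"unavailable": "EDSS timeline columns absent"}
    section = {}
    baselines = {"clinician": "baseline_edss"}
    if "mri_edss_estimate" in ms.columns:
        baselines["mri"] = "mri_edss_estimate"
    for source, col in baselines.items():
        sub = ms.dropna(subset=[col, "followup_edss", "interval_years", "msdss_pred"])
        log.info("prognostic chain (%s baseline): %d of %d MS participants complete",
                 source, len(sub), len(ms))
        if len(sub) < 10:
            section[source] = {"unavailable": f"only {len(sub)} complete cases"}
            continue
        preds = prog.predict_followup_edss(
            sub["msdss_pred"], sub[col], sub["interval_years"], conversions,
            participant_id=sub["participant_id"], baseline_source=source,
        )
        rep = prog.evaluate_prognosis(preds, sub["followup_edss"].to_numpy())
        block = rep.to_dict()
        block["p_gain_formatted"] = _format_p(rep.p_gain)
        section[source] = block
        section[f"{source}_predictions"] = preds
    return section


def run_full_validation(config: PipelineConfig) -> dict:
    """Execute all stages and return the validation report as a dict.

    In simulate mode the report is a pure function of the config (all
    randomness flows from ``config.seed``); rerunning with the same config
    reproduces every number. When ``config.out_dir`` is set, the report
    JSON and intermediate tables are written there.
    """
    seeds = _sub_seeds(config.seed, 10)
    report: dict = {
        "config": {
            "mode": config.mode,
            "seed": config.seed,
            "n_trees": config.n_trees,
            "n_boot": config.n_boot,
            "cutoff": config.cutoff,
        },
        "stage_log": [],
    }
    conversions = None
    intermediates: dict[str, pd.DataFrame] = {}

    if config.mode == "simulate":
        train_cfg = dataclasses.replace(
            config.sim,
            n_rrms=config.train_n_rrms,
            n_progms=config.train_n_progms,
            n_oind=config.train_n_oind,
            n_nind=config.train_n_nind,
            apply_missingness=False,
        )
        healthy = sim.generate_healthy_reference(config.n_healthy, config.sim, seed=seeds[2])
        train = sim.generate_cohort(train_cfg, seed=seeds[3], tag="training")
        calib = sim.generate_training_cohort(train_cfg, seed=seeds[4])
        val = sim.generate_cohort(config.sim, seed=seeds[5], tag="validation")
        report["stage_log"].append(
            f"simulated cohorts: train n={len(train.participants)}, "
            f"calibration n={len(calib.participants)}, validation n={len(val.participants)}, "
            f"healthy n={len(healthy.participants)}"
        )

        ref = feat.fit_healthy_reference(healthy)
        panels = {name: feat.load_panel(src) for name, src in config.panels.items()}

        Xtr = {n: feat.cohort_features(train, p, ref) for n, p in panels.items()}
        Xval = {n: feat.cohort_features(val, p, ref) for n, p in panels.items()}
        Xcal = feat.cohort_features(calib, panels["severity"], ref)

        tr_parts = train.participants
        tr_ms_mask = tr_parts["diagnosis"].isin(sim.MS_CLASSES).to_numpy()
        ms_ids = tr_parts.loc[tr_ms_mask, "participant_id"]

        diag_model = mdl.train_classifier(
            Xtr["diagnostic"], tr_ms_mask, model_kind="ms_vs_nonms",
            n_trees=config.n_trees, seed=seeds[6], training_provenance=train.tag,
        )
        prog_model = mdl.train_classifier(
            Xtr["progms"].loc[ms_ids],
            (tr_parts.loc[tr_ms_mask, "diagnosis"] == "ProgMS").to_numpy(),
            model_kind="rrms_vs_progms", n_trees=config.n_trees, seed=seeds[7],
            training_provenance=train.tag,
        )
        sev_model = mdl.train_severity_regressor(
            Xtr["severity"].loc[ms_ids],
            tr_parts.loc[tr_ms_mask, "msdss_true"].to_numpy(),
            n_trees=config.n_trees, seed=seeds[8], training_provenance=train.tag,
        )
        report["stage_log"].append("trained diagnostic, staging, and severity forests")

        for model in (diag_model, prog_model, sev_model):
            _check_external(model, val.tag)

        records = pd.DataFrame(
            {
                "participant_id": val.participants["participant_id"],
                "ms_probability": mdl.predict_probabilities(
                    diag_model, Xval["diagnostic"]
                ).to_numpy(),
                "progms_probability": mdl.predict_probabilities(
                    prog_model, Xval["progms"]
                ).to_numpy(),
                "msdss_pred": mdl.predict_probabilities(
                    sev_model, Xval["severity"]
                ).to_numpy(),
            }
        )
        participants = val.participants

        # conversion models from the training side
        msdss_cal = mdl.predict_probabilities(sev_model, Xcal)
        conversions = prog.fit_msdss_slope_model(
            msdss_cal.to_numpy(), calib.participants["combiwise_slope_true"].to_numpy()
        )
        xsec = sim.generate_crosssectional_cw_edss(config.n_crosssectional, seed=seeds[9])
        conversions = prog.fit_combiwise_edss_model(
            xsec["combiwise"], xsec["edss"], models=conversions
        )
        report["conversion_models"] = conversions.to_dict()
        report["stage_log"].append(
            f"fitted conversion models: slope=({conversions.a:.3f}, {conversions.b:.3f}), "
            f"quadratic R2={conversions.quadratic_r2:.3f}"
        )
    elif config.mode == "supplementary":
        participants, records = read_supplementary_results(
            config.supplementary_path, config.column_map
        )
        report["stage_log"].append(
            f"read supplementary results: {len(participants)} participants"
        )
    else:  # user_data
        cohort = sim.Cohort.read(config.user_data_dir)
        raise NotImplementedError(
            "user_data mode requires trained models; train via the library API "
            f"(cohort with {len(cohort.participants)} participants was read successfully)"
        )

    n_ms = int(participants["diagnosis"].isin(sim.MS_CLASSES).sum())
    report["cohort"] = {
        "n_total": len(participants),
        "n_ms": n_ms,
        "n_nonms": len(participants) - n_ms,
        "by_class": participants["diagnosis"].value_counts().to_dict(),
    }

    report["diagnostic"] = _diagnostic_section(records, participants, config, seeds)
    report["staging"] = _staging_section(records, participants, config, seeds)
    prognostic = _prognostic_section(records, participants, conversions, config)
    for key in list(prognostic):
        if key.endswith("_predictions"):
            intermediates[f"prognostic_{key}"] = prognostic.pop(key)
    report["prognostic"] = prognostic

    audit = misclassification_audit(
        records, participants, cutoff=config.cutoff,
        scd27_log_mean=config.scd27_healthy_log_mean,
        scd27_log_sd=config.scd27_healthy_log_sd,
    )
    report["misclassification"] = {
        "n_misclassified_ms": int((audit["direction"] == "ms_called_nonms").sum()),
        "n_misclassified_nonms": int((audit["direction"] == "nonms_called_ms").sum()),
        "listing": audit.to_dict(orient="records"),
    }
    intermediates["predictions"] = records
    intermediates["participants"] = participants

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in intermediates.items():
            df.to_csv(out / f"{name}.csv", index=False)
        (out / "report.json").write_text(json.dumps(_jsonify(report), indent=2))
        log.info("report written to %s", out / "report.json")
    report["_intermediates"] = intermediates
    return report


def _jsonify(obj):
    """Round floats and drop non-serializable intermediates for stable
    report diffs."""
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items() if not str(k).startswith("_")}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        if np.isnan(obj):
            return None
        return float(f"{float(obj):.6g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, pd.DataFrame):
        return None
    return obj
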