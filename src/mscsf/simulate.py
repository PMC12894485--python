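"""Seeded synthetic multicenter cohorts for the validation pipeline.

The generator emulates the statistical structure the downstream analysis
assumes: a four-class multicenter cohort (RRMS, progressive MS, other
inflammatory and non-inflammatory controls), SOMAscan-like wide protein
tables in relative fluorescence units (RFU), class-dependent shifts on the
configured protein panels, age/sex effects on protein abundance, a latent
severity that couples severity-panel ratios to the rate of disability
progression, EDSS measured on its clinical half-point grid, ancillary CSF
markers (OCB, IgG index, sCD27, NFL), and per-center heterogeneity.

Signal model. Disease effects enter through scalar latent scores rather
than a uniform shift on panel proteins (a uniform shift would cancel
exactly in log-ratios): a diagnostic score ``u_d ~ N(diag_effect * 1[MS],
1)`` and a staging score ``u_p ~ N(prog_effect * 1[progMS], 1)`` are loaded
onto their panel's proteins with alternating signs, so each chained ratio
carries ``±u`` plus residual noise. All class information flows through
the scalar score, whose two-normal geometry makes the Bayes AUROC of the
downstream task exactly ``analytic_auc(effect)`` — the calibration knob
the pipeline's acceptance checks rely on.

Per-protein assay parameters (baseline log-RFU, age slope, sex offset) are
derived from a hash of the protein identifier, not from the cohort seed, so
a healthy-reference cohort generated under a different seed shares the same
assay-level structure as the disease cohorts it adjusts.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from mscsf.features import (
    DIAGNOSTIC_PROTEINS,
    PROGMS_PROTEINS,
    SEVERITY_PROTEINS,
)

__all__ = [
    "SimConfig",
    "Cohort",
    "generate_cohort",
    "generate_healthy_reference",
    "generate_training_cohort",
    "generate_crosssectional_cw_edss",
    "analytic_auc",
    "effect_for_auc",
    "edss_grid_round",
    "combiwise_to_edss_true",
    "edss_to_combiwise_true",
    "TRUE_CW_EDSS_COEF",
]

MS_CLASSES = ("RRMS", "ProgMS")
CONTROL_CLASSES = ("OIND", "NIND")
ALL_CLASSES = MS_CLASSES + CONTROL_CLASSES

# Ground-truth quadratic mapping CombiWISE (0-100) to EDSS (0-10), strictly
# increasing on [0, 100]: q(cw) = 0.06*cw + 0.0004*cw^2.
TRUE_CW_EDSS_COEF = (0.0, 0.06, 0.0004)

# Class-level demographics: age mean/sd, fraction female, per-center weights.
_DEMOGRAPHICS = {
    "RRMS": {"age": (38.1, 10.7), "f_frac": 44 / 65, "centers": (12, 6, 47)},
    "ProgMS": {"age": (51.0, 10.5), "f_frac": 17 / 31, "centers": (7, 18, 6)},
    "OIND": {"age": (41.3, 13.2), "f_frac": 20 / 30, "centers": (6, 5, 19)},
    "NIND": {"age": (39.7, 12.5), "f_frac": 28 / 34, "centers": (11, 4, 19)},
}

# Class-conditional positivity rates for the conventional CSF markers,
# read from the observed cohort proportions (configurable via SimConfig).
_DEFAULT_OCB_RATES = {"RRMS": 49 / 61, "ProgMS": 23 / 29, "OIND": 5 / 20, "NIND": 0.02}
_DEFAULT_IGG_RATES = {"RRMS": 36 / 61, "ProgMS": 14 / 28, "OIND": 5 / 21, "NIND": 0.02}


def analytic_auc(effect: float) -> float:
    """Expected AUROC of two unit-variance normal score populations
    separated by ``effect``: Phi(effect / sqrt(2))."""
    if not np.isfinite(effect):
        return 1.0 if effect > 0 else 0.0
    return float(norm.cdf(effect / np.sqrt(2.0)))


def effect_for_auc(target_auc: float) -> float:
    """Inverse of :func:`analytic_auc`: the standardized separation whose
    two-normal AUROC equals ``target_auc``."""
    if not 0.0 < target_auc < 1.0:
        raise ValueError("target AUROC must be in (0, 1)")
    return float(np.sqrt(2.0) * norm.ppf(target_auc))


def edss_grid_round(values):
    """Round continuous disability to the clinical EDSS grid.

    Grid: {0} plus half-point steps from 1.0 to 10.0 (the scale has no 0.5
    step below 1.0). Nearest grid point, half-up; NaN passes through.
    """
    v = np.asarray(values, dtype=float)
    out = np.floor(np.clip(v, 0.0, 10.0) * 2.0 + 0.5) / 2.0
    out = np.where(v < 0.5, 0.0, out)
    out = np.where((v >= 0.5) & (v < 1.0), 1.0, out)
    return np.where(np.isnan(v), np.nan, out)


def combiwise_to_edss_true(cw):
    """Generator's ground-truth CombiWISE -> EDSS quadratic."""
    c0, c1, c2 = TRUE_CW_EDSS_COEF
    cw = np.asarray(cw, dtype=float)
    return c0 + c1 * cw + c2 * cw**2


def edss_to_combiwise_true(edss):
    """Inverse of the ground-truth quadratic on [0, 100]."""
    c0, c1, c2 = TRUE_CW_EDSS_COEF
    e = np.asarray(edss, dtype=float)
    disc = c1**2 - 4.0 * c2 * (c0 - e)
    return (-c1 + np.sqrt(np.maximum(disc, 0.0))) / (2.0 * c2)


@dataclass
class SimConfig:
    """Generative knobs for a synthetic multicenter cohort.

    Effect sizes are standardized separations on the latent score scale;
    use :func:`effect_for_auc` to pick them for a target AUROC. Defaults
    reproduce the validation cohort's composition (65/31/30/34 across four
    diagnostic classes, three centers) with diagnostic and staging signals
    calibrated to AUROC 0.94 and 0.76.
    """

    n_rrms: int = 65
    n_progms: int = 31
    n_oind: int = 30
    n_nind: int = 34
    n_centers: int = 3
    diag_effect: float = effect_for_auc(0.94)
    prog_effect: float = effect_for_auc(0.76)
    prog_severity_corr: float = 0.5  # staging score loading on residual severity
    # severity->ratio coupling sized so the CSF-predicted severity score
    # correlates with the true score at r ~ 0.55, the validity scale reported
    # for the severity model's external validation
    severity_coupling: float = 0.03
    age_slope_per_protein: float = 0.005  # SD of per-protein age slopes, log-RFU/yr
    sex_offset_per_protein: float = 0.05  # SD of per-protein M-vs-F offsets, log-RFU
    noise_sd: float = 0.15  # residual log-RFU SD
    interval_mean_years: float = 10.2
    interval_sd_years: float = 5.0
    edss_noise_sd: float = 0.4  # measurement noise on prospective (follow-up) EDSS
    baseline_edss_noise_sd: float = 1.4  # extra noise on retrospective baseline EDSS
    seed: int = 0
    n_noise_proteins: int = 200
    # latent severity -> MS-DSS -> CombiWISE slope chain
    msdss_center: float = 1.0
    msdss_scale: float = 0.5
    slope_intercept: float = 0.2  # CombiWISE units/year at MS-DSS 0
    slope_per_msdss: float = 0.5  # CombiWISE units/year per MS-DSS unit
    slope_noise_sd: float = 0.4  # leaves severity explaining ~30% of slope variance
    nonprogressor_frac: float = 0.2  # fraction with progression slope forced to 0
    # EDSS baseline model
    edss_base_mean: float = 2.0
    edss_per_severity: float = 0.8
    edss_per_year_age: float = 0.03
    # conventional markers
    ocb_rates: dict = field(default_factory=lambda: dict(_DEFAULT_OCB_RATES))
    igg_rates: dict = field(default_factory=lambda: dict(_DEFAULT_IGG_RATES))
    marker_avail_ms: float = 89 / 96
    marker_avail_ctrl: float = 32 / 64
    # attrition among MS participants (counts, capped at cohort size)
    n_missing_baseline_edss: int = 7
    n_missing_followup_edss: int = 5
    n_with_mri: int = 54
    mri_noise_sd: float = 0.7
    apply_missingness: bool = True

    def __post_init__(self):
        for name in ("n_rrms", "n_progms", "n_oind", "n_nind"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_rrms + self.n_progms + self.n_oind + self.n_nind == 0:
            raise ValueError("cohort would be empty")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.edss_noise_sd < 0:
            raise ValueError("edss_noise_sd must be non-negative")
        if self.interval_mean_years <= 0:
            raise ValueError("interval_mean_years must be positive")
        if self.n_centers < 1:
            raise ValueError("need at least one center")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class Cohort:
    """Participant table plus wide protein-abundance table.

    ``participants``: one row per participant (clinical ground truth;
    ``latent_severity`` and any ``*_true`` columns are synthetic-only and
    must not be consumed by analysis stages). ``proteomics``: wide RFU
    table indexed by participant_id. ``provenance`` records the SimConfig,
    seed, and true generative parameters.
    """

    participants: pd.DataFrame
    proteomics: pd.DataFrame
    provenance: dict

    def __post_init__(self):
        ids = self.participants["participant_id"]
        if ids.duplicated().any():
            raise ValueError("duplicate participant ids")
        if set(ids) != set(self.proteomics.index):
            raise ValueError("participants and profiles must match one-to-one")

    def abundance_frame(self) -> pd.DataFrame:
        return self.proteomics

    @property
    def profiles(self) -> dict:
        return {pid: row.to_dict() for pid, row in self.proteomics.iterrows()}

    @property
    def tag(self) -> str:
        return self.provenance.get("tag", "unknown")

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.participants.to_csv(outdir / "participants.csv", index=False)
        self.proteomics.rename_axis("participant_id").to_csv(outdir / "proteomics.csv")
        with open(outdir / "cohort.json", "w") as fh:
            json.dump(self.provenance, fh, indent=2, default=str)

    @classmethod
    def read(cls, indir) -> "Cohort":
        indir = Path(indir)
        parts = pd.read_csv(indir / "participants.csv")
        prot = pd.read_csv(indir / "proteomics.csv", index_col="participant_id")
        prov_path = indir / "cohort.json"
        prov = json.loads(prov_path.read_text()) if prov_path.exists() else {"tag": str(indir)}
        return cls(participants=parts, proteomics=prot, provenance=prov)


def _protein_universe(cfg: SimConfig) -> list[str]:
    seen: dict[str, None] = {}
    for p in DIAGNOSTIC_PROTEINS + PROGMS_PROTEINS + SEVERITY_PROTEINS:
        seen.setdefault(p)
    for i in range(cfg.n_noise_proteins):
        seen.setdefault(f"NOISE{i + 1:03d}")
    return list(seen)


def _protein_params(proteins, cfg: SimConfig) -> pd.DataFrame:
    """Assay-level per-protein parameters, a deterministic function of the
    protein identifier (seed-independent by design)."""
    rows = []
    for p in proteins:
        h = zlib.crc32(p.encode()) & 0x7FFFFFFF
        r = np.random.default_rng(h)
        rows.append(
            {
                "intercept": 7.0 + 0.5 * r.standard_normal(),
                "age_slope": cfg.age_slope_per_protein * r.standard_normal(),
                "sex_offset": cfg.sex_offset_per_protein * r.standard_normal(),
            }
        )
    return pd.DataFrame(rows, index=list(proteins))


def _alternating_loadings(proteins) -> dict[str, float]:
    return {p: (0.5 if i % 2 == 0 else -0.5) for i, p in enumerate(proteins)}


_DIAG_LOADINGS = _alternating_loadings(DIAGNOSTIC_PROTEINS)
_PROG_LOADINGS = _alternating_loadings(PROGMS_PROTEINS)
_SEV_LOADINGS = _alternating_loadings(SEVERITY_PROTEINS)


def _streams(seed: int, names: tuple[str, ...]):
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def _sample_classes(cfg: SimConfig) -> list[str]:
    return (
        ["RRMS"] * cfg.n_rrms
        + ["ProgMS"] * cfg.n_progms
        + ["OIND"] * cfg.n_oind
        + ["NIND"] * cfg.n_nind
    )


def _proteomics_table(
    ids, ages, male, u_diag, u_prog, severity, cfg: SimConfig, rng
) -> pd.DataFrame:
    proteins = _protein_universe(cfg)
    params = _protein_params(proteins, cfg)
    n = len(ids)
    log_abund = (
        params["intercept"].to_numpy()[None, :]
        + np.asarray(ages)[:, None] * params["age_slope"].to_numpy()[None, :]
        + np.asarray(male, float)[:, None] * params["sex_offset"].to_numpy()[None, :]
        + rng.normal(0.0, cfg.noise_sd, size=(n, len(proteins)))
    )
    col = {p: i for i, p in enumerate(proteins)}
    for p, s in _DIAG_LOADINGS.items():
        log_abund[:, col[p]] += s * u_diag
    for p, s in _PROG_LOADINGS.items():
        log_abund[:, col[p]] += s * u_prog
    for p, s in _SEV_LOADINGS.items():
        log_abund[:, col[p]] += s * cfg.severity_coupling * severity
    return pd.DataFrame(np.exp(log_abund), index=list(ids), columns=proteins)


def generate_cohort(config: SimConfig, seed: Optional[int] = None, tag: str = "validation") -> Cohort:
    """Generate a four-class multicenter validation cohort.

    MS participants carry the diagnostic signal (``diag_effect`` on the
    diagnostic-score latent), progressive MS additionally the staging
    signal; latent severity (standard normal, +1 in progressive MS) drives
    severity-panel ratios and the true progression slope; EDSS timelines
    are measured on the clinical grid; OCB/IgG-index positivity is
    Bernoulli with class-dependent rates; controls have no EDSS timeline.
    """
    seed = config.seed if seed is None else seed
    rng = _streams(seed, ("demo", "latent", "prot", "edss", "markers", "missing"))

    classes = _sample_classes(config)
    n = len(classes)
    ids = [f"{tag.upper()[:3]}-{i + 1:04d}" for i in range(n)]

    ages = np.empty(n)
    sexes = np.empty(n, dtype=object)
    centers = np.empty(n, dtype=int)
    for i, cls in enumerate(classes):
        demo = _DEMOGRAPHICS[cls]
        mu, sd = demo["age"]
        ages[i] = float(np.clip(rng["demo"].normal(mu, sd), 18.0, 85.0))
        sexes[i] = "F" if rng["demo"].random() < demo["f_frac"] else "M"
        w = np.asarray(demo["centers"], float)[: config.n_centers]
        centers[i] = 1 + rng["demo"].choice(config.n_centers, p=w / w.sum())

    is_ms = np.isin(classes, MS_CLASSES)
    is_prog = np.asarray(classes) == "ProgMS"
    u_diag = rng["latent"].standard_normal(n) + config.diag_effect * is_ms
    sev_resid = rng["latent"].standard_normal(n)  # severity net of the class shift
    severity = sev_resid + 1.0 * is_prog
    # the staging score shares variance with residual severity (progression
    # biology is continuous), leaving its class-conditional law N(shift, 1)
    c = float(np.clip(config.prog_severity_corr, -1.0, 1.0))
    u_prog = (
        config.prog_effect * is_prog
        + c * sev_resid
        + np.sqrt(max(1.0 - c**2, 0.0)) * rng["latent"].standard_normal(n)
    )

    prot = _proteomics_table(
        ids, ages, np.asarray(sexes) == "M", u_diag, u_prog, severity, config, rng["prot"]
    )

    # EDSS timeline (MS participants only; controls were not followed)
    msdss_true = config.msdss_center + config.msdss_scale * severity
    slope_cw = (
        config.slope_intercept
        + config.slope_per_msdss * msdss_true
        + rng["edss"].normal(0.0, config.slope_noise_sd, n)
    )
    # a configurable fraction are non-progressors (slope floored at 0);
    # everyone else keeps their drawn slope, improvement included
    nonprog = rng["edss"].random(n) < config.nonprogressor_frac
    slope_cw = np.where(nonprog, 0.0, slope_cw)

    # true (latent) baseline disability drives progression; the measured
    # baseline adds retrospective chart-review noise on top — baseline EDSS
    # transcribed from free-text examinations is far less precise than the
    # structured prospective follow-up exam
    true_base = np.clip(
        config.edss_base_mean
        + config.edss_per_severity * severity
        + config.edss_per_year_age * (ages - 40.0)
        + rng["edss"].normal(0.0, 0.5, n),
        0.0,
        9.0,
    )
    interval = np.maximum(
        rng["edss"].normal(config.interval_mean_years, config.interval_sd_years, n), 0.5
    )
    cw_base = edss_to_combiwise_true(true_base)
    cw_follow = np.clip(cw_base + slope_cw * interval, 0.0, 100.0)
    base_meas = np.clip(
        true_base + rng["edss"].normal(0.0, config.baseline_edss_noise_sd, n), 0.0, 10.0
    )
    follow_meas = np.clip(
        combiwise_to_edss_true(cw_follow) + rng["edss"].normal(0.0, config.edss_noise_sd, n),
        0.0,
        10.0,
    )
    baseline_edss = np.where(is_ms, edss_grid_round(base_meas), np.nan)
    followup_edss = np.where(is_ms, edss_grid_round(follow_meas), np.nan)
    interval_years = np.where(is_ms, np.round(interval, 2), np.nan)

    mri_est = np.where(
        is_ms,
        np.clip(true_base + rng["edss"].normal(0.0, config.mri_noise_sd, n), 0.0, 10.0),
        np.nan,
    )

    # conventional markers
    ocb = np.array([rng["markers"].random() < config.ocb_rates[c] for c in classes], float)
    igg = np.array([rng["markers"].random() < config.igg_rates[c] for c in classes], float)
    avail_rate = np.where(is_ms, config.marker_avail_ms, config.marker_avail_ctrl)
    avail = rng["markers"].random(n) < avail_rate
    ocb = np.where(avail, ocb, np.nan)
    igg = np.where(avail, igg, np.nan)

    # sCD27 / NFL (pg/mL): lognormal, elevated in MS
    scd27 = np.exp(
        np.log(30.0) + 1.3 * is_ms + 0.4 * (np.asarray(classes) == "OIND")
        + rng["markers"].normal(0.0, 0.5, n)
    )
    nfl = np.exp(np.log(500.0) + 0.7 * is_ms + 0.4 * severity + rng["markers"].normal(0.0, 0.6, n))

    parts = pd.DataFrame(
        {
            "participant_id": ids,
            "center": centers,
            "diagnosis": classes,
            "age_at_lp": np.round(ages, 1),
            "sex": sexes,
            "baseline_edss": baseline_edss,
            "followup_edss": followup_edss,
            "interval_years": interval_years,
            "ocb_positive": ocb,
            "igg_index_elevated": igg,
            "mri_edss_estimate": np.round(mri_est, 2),
            "scd27": np.round(scd27, 1),
            "nfl": np.round(nfl, 1),
            "latent_severity": severity,
            "msdss_true": msdss_true,
            "combiwise_slope_true": slope_cw,
        }
    )

    if config.apply_missingness:
        ms_idx = parts.index[is_ms].to_numpy()
        miss_rng = rng["missing"]
        k_base = min(config.n_missing_baseline_edss, len(ms_idx))
        k_fu = min(config.n_missing_followup_edss, len(ms_idx))
        if k_base:
            drop = miss_rng.choice(ms_idx, size=k_base, replace=False)
            parts.loc[drop, "baseline_edss"] = np.nan
        if k_fu:
            drop = miss_rng.choice(ms_idx, size=k_fu, replace=False)
            parts.loc[drop, ["followup_edss", "interval_years"]] = np.nan
        k_mri = min(config.n_with_mri, len(ms_idx))
        if k_mri < len(ms_idx):
            no_mri = miss_rng.choice(ms_idx, size=len(ms_idx) - k_mri, replace=False)
            parts.loc[no_mri, "mri_edss_estimate"] = np.nan

    provenance = {
        "tag": tag,
        "seed": seed,
        "config": config.to_dict(),
        "true_cw_edss_coef": list(TRUE_CW_EDSS_COEF),
        "a_true": config.slope_intercept,
        "b_true": config.slope_per_msdss,
    }
    return Cohort(participants=parts, proteomics=prot, provenance=provenance)


def generate_healthy_reference(
    n: int,
    config: SimConfig,
    seed: Optional[int] = None,
    age_range: tuple[float, float] = (20.0, 65.0),
) -> Cohort:
    """Healthy-volunteer reference cohort: age/sex effects plus noise only.

    Used to fit the per-protein adjustment model; requires ``n >= 20`` so
    the per-protein OLS has reasonable degrees of freedom.
    """
    if n < 20:
        raise ValueError(f"healthy reference needs n >= 20 (got {n})")
    seed = config.seed if seed is None else seed
    rng = _streams(seed, ("demo", "prot"))
    ids = [f"HV-{i + 1:04d}" for i in range(n)]
    ages = rng["demo"].uniform(age_range[0], age_range[1], n)
    sexes = np.where(rng["demo"].random(n) < 0.5, "F", "M").astype(object)
    zeros = np.zeros(n)
    prot = _proteomics_table(ids, ages, sexes == "M", zeros, zeros, zeros, config, rng["prot"])
    parts = pd.DataFrame(
        {
            "participant_id": ids,
            "center": 0,
            "diagnosis": "Healthy",
            "age_at_lp": np.round(ages, 1),
            "sex": sexes,
        }
    )
    prov = {"tag": "healthy_reference", "seed": seed, "config": config.to_dict()}
    return Cohort(participants=parts, proteomics=prot, provenance=prov)


def generate_training_cohort(config: SimConfig, seed: Optional[int] = None) -> Cohort:
    """MS-only training cohort with per-participant severity targets.

    ``msdss_true`` is a monotone (affine) function of latent severity and
    ``combiwise_slope_true = a_true + b_true * msdss_true + noise``; the
    true (a, b) are recorded in provenance for recovery tests. Attrition
    masks are not applied: training data are complete by construction.
    """
    train_cfg = dataclasses.replace(
        config, n_oind=0, n_nind=0, apply_missingness=False
    )
    seed = config.seed if seed is None else seed
    cohort = generate_cohort(train_cfg, seed=seed, tag="training")
    if cohort.participants["msdss_true"].nunique() < 2:
        raise ValueError("degenerate training cohort: msdss_true is constant")
    return cohort


def generate_crosssectional_cw_edss(
    n: int = 3000, noise_sd: float = 0.35, seed: int = 0
) -> pd.DataFrame:
    """Cross-sectional (CombiWISE, EDSS) visit pairs from the ground-truth
    quadratic plus measurement noise; used to fit the conversion curve."""
    rng = np.random.default_rng(seed)
    cw = rng.uniform(0.0, 100.0, n)
    edss = np.clip(combiwise_to_edss_true(cw) + rng.normal(0.0, noise_sd, n), 0.0, 10.0)
    return pd.DataFrame({"combiwise": cw, "edss": edss})
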