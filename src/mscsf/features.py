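"""Age/sex-adjusted log-ratio features from CSF protein abundances.

The classifiers never see raw relative fluorescence units (RFU). Each
profile is log-transformed, residualized against a healthy reference
(removing the fitted age slope and sex offset per protein), and collapsed
into the panel's log-ratios: feature("A/B") = adjusted(A) - adjusted(B).
Because a log-ratio subtracts two adjusted log-abundances, any per-sample
multiplicative rescaling of all RFUs cancels exactly — the features are
invariant to global scaling of a sample, which is what makes ratio panels
robust across assay batches.

Panels ship as CSV files (columns panel,numerator,denominator). The
diagnostic and progressive-MS panels carry the published protein lists;
the exact numerator/denominator pairings of the historical models are not
public, so the packaged pairing is a documented deterministic default and
panels are fully user-configurable. Two reagents target protein complexes
("TLR4/LY96 complex", "LTA/LTB"); they are single identifiers here, written
``TLR4_LY96`` and ``LTA_LTB`` so that ``/`` stays reserved for ratio labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProteinPanel",
    "HealthyReference",
    "default_pairing",
    "load_panel",
    "fit_healthy_reference",
    "adjust_profile",
    "compute_ratio_features",
    "DIAGNOSTIC_PROTEINS",
    "PROGMS_PROTEINS",
]

# Published protein lists (complex-targeting reagents renamed: '/' -> '_').
DIAGNOSTIC_PROTEINS = (
    "TNFRSF17", "CD48", "PRTN3", "PLA2G7", "PDCD1LG2", "CCL7", "SLAMF6",
    "TLR4_LY96", "CSF3", "CDKN1B", "TNFRSF6B", "TNC", "CRK", "PGK1",
    "MAPK14", "FLT4", "F9", "CXCL13", "TNFRSF4", "DCTPP1", "MMP7",
)
PROGMS_PROTEINS = (
    "EDA2R", "SELL", "CFD", "SERPING1", "ICOSLG", "LTA_LTB", "IL22",
    "INHBA", "GP6", "EDAR", "PRTN3", "LILRB2", "STX1A", "JAM3", "EPHA5",
    "GZMA", "NTRK3", "IL10", "CLEC1B", "TYRO3", "BOC", "ETHE1", "UNC5C",
    "RGMA",
)
# The severity panel's 75 protein identities are not public; the packaged
# severity panel is synthetic (see severity_panel_synthetic.csv).
SEVERITY_PROTEINS = tuple(f"SEVP{i:03d}" for i in range(1, 76))

_PACKAGED = {
    "diagnostic": "diagnostic_panel.csv",
    "progms": "progms_panel.csv",
    "severity": "severity_panel_synthetic.csv",
}
_EXPECTED = {
    "diagnostic": (20, set(DIAGNOSTIC_PROTEINS)),
    "progms": (21, set(PROGMS_PROTEINS)),
    "severity": (57, set(SEVERITY_PROTEINS)),
}


@dataclass(frozen=True)
class ProteinPanel:
    """An ordered list of (numerator, denominator) protein ratios."""

    name: str
    ratios: tuple[tuple[str, str], ...]

    def __post_init__(self):
        for num, den in self.ratios:
            if num == den:
                raise ValueError(f"ratio {num}/{den}: numerator equals denominator")
        if not self.ratios:
            raise ValueError("panel has no ratios")

    @property
    def protein_list(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for num, den in self.ratios:
            seen.setdefault(num)
            seen.setdefault(den)
        return tuple(seen)

    @property
    def ratio_labels(self) -> tuple[str, ...]:
        return tuple(f"{n}/{d}" for n, d in self.ratios)


def default_pairing(proteins: Sequence[str], n_ratios: int) -> tuple[tuple[str, str], ...]:
    """Deterministic pairing covering every protein with ``n_ratios`` ratios.

    When ``n_ratios >= len(proteins) - 1`` the base is the chain
    p[i]/p[i+1]; otherwise disjoint pairs p[0]/p[1], p[2]/p[3], ... (plus a
    wrap ratio if the count is odd) cover the list. Extra ratios beyond the
    covering set step through wider offsets p[i]/p[i+k], k = 2, 3, ...
    """
    p = list(proteins)
    n = len(p)
    if n < 2:
        raise ValueError("need at least two proteins")
    if n_ratios < math.ceil(n / 2):
        raise ValueError(f"{n_ratios} ratios cannot reference {n} unique proteins")
    used: set[frozenset] = set()
    ratios: list[tuple[str, str]] = []

    def add(a, b):
        key = frozenset((a, b))
        if a != b and key not in used:
            used.add(key)
            ratios.append((a, b))

    if n_ratios >= n - 1:
        for i in range(n - 1):
            add(p[i], p[i + 1])
    else:
        for i in range(0, n - 1, 2):
            add(p[i], p[i + 1])
        if n % 2:
            add(p[n - 1], p[0])
    k = 2
    while len(ratios) < n_ratios and k < n:
        for i in range(n - k):
            if len(ratios) == n_ratios:
                break
            add(p[i], p[i + k])
        k += 1
    if len(ratios) != n_ratios:
        raise ValueError("could not construct requested number of ratios")
    return tuple(ratios)


def load_panel(source) -> ProteinPanel:
    """Load a panel from a CSV path or a packaged panel name.

    ``source`` may be ``"diagnostic"``, ``"progms"``, ``"severity"`` (the
    packaged files) or any path to a CSV with columns
    ``panel,numerator,denominator``. Packaged panels are checked against
    the transcribed protein lists; a user panel reusing one of those names
    gets a warning for unknown proteins rather than an error.
    """
    import warnings

    if isinstance(source, str) and source in _PACKAGED:
        ref = resources.files("mscsf.panels") / _PACKAGED[source]
        df = pd.read_csv(str(ref))
    else:
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(path)
        df = pd.read_csv(path)
    required = {"panel", "numerator", "denominator"}
    if not required.issubset(df.columns):
        raise ValueError(f"panel file needs columns {sorted(required)}, got {list(df.columns)}")
    for i, row in df.iterrows():
        if pd.isna(row["numerator"]) or pd.isna(row["denominator"]):
            raise ValueError(f"malformed panel row at line {i + 2}")
    names = df["panel"].unique()
    if len(names) != 1:
        raise ValueError(f"panel file must describe one panel, found {list(names)}")
    name = str(names[0])
    panel = ProteinPanel(
        name=name,
        ratios=tuple(zip(df["numerator"].astype(str), df["denominator"].astype(str))),
    )
    if name in _EXPECTED:
        n_ratios, known = _EXPECTED[name]
        unknown = set(panel.protein_list) - known
        if unknown:
            warnings.warn(
                f"panel {name!r}: proteins not in the packaged list: {sorted(unknown)}",
                stacklevel=2,
            )
    return panel


@dataclass
class HealthyReference:
    """Per-protein age/sex regression coefficients from a healthy cohort.

    For each protein: log(RFU) ~ intercept + age_slope*age + sex_offset*1[M],
    fitted by OLS, with the residual SD retained.
    """

    coefficients: pd.DataFrame  # index: protein; columns: intercept, age_slope, sex_offset, residual_sd
    n_reference: int

    def __post_init__(self):
        needed = {"intercept", "age_slope", "sex_offset", "residual_sd"}
        if not needed.issubset(self.coefficients.columns):
            raise ValueError(f"reference table needs columns {sorted(needed)}")
        if (self.coefficients["residual_sd"] <= 0).any():
            raise ValueError("residual_sd must be positive for every protein")

    def covers(self, proteins: Iterable[str]) -> bool:
        return set(proteins).issubset(set(self.coefficients.index))


def fit_healthy_reference(reference_cohort, min_n: int = 20) -> HealthyReference:
    """Fit per-protein OLS of log abundance on age and sex.

    ``reference_cohort`` is a :class:`mscsf.simulate.Cohort`. Requires at
    least ``min_n`` profiles, both sexes, and non-constant age, else the
    design is rank-deficient and fitting aborts.
    """
    parts = reference_cohort.participants
    wide = reference_cohort.abundance_frame()
    n = len(parts)
    if n < min_n:
        raise ValueError(f"healthy reference needs >= {min_n} profiles, got {n}")
    age = parts["age_at_lp"].to_numpy(float)
    male = (parts["sex"].to_numpy() == "M").astype(float)
    if np.ptp(age) == 0 or len(np.unique(male)) < 2:
        raise ValueError("degenerate design: reference needs both sexes and varying age")
    X = np.column_stack([np.ones(n), age, male])
    Y = np.log(wide.loc[parts["participant_id"]].to_numpy(float))
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = max(n - 3, 1)
    sd = np.sqrt((resid**2).sum(axis=0) / dof)
    sd = np.maximum(sd, 1e-12)
    coef = pd.DataFrame(
        {
            "intercept": beta[0],
            "age_slope": beta[1],
            "sex_offset": beta[2],
            "residual_sd": sd,
        },
        index=wide.columns,
    )
    return HealthyReference(coefficients=coef, n_reference=n)


def adjust_profile(
    abundances: Mapping[str, float],
    age: float,
    sex: str,
    ref: HealthyReference,
    proteins: Sequence[str] | None = None,
) -> pd.Series:
    """Age/sex-residualized log abundances for one profile.

    adjusted = log(RFU) - age_slope*age - sex_offset*1[sex == M]. The
    reference intercept is deliberately retained: it cancels in every
    ratio, and keeping it makes the adjusted values interpretable as
    log-RFU on a common demographic baseline.
    """
    keys = list(proteins) if proteins is not None else list(abundances)
    out = np.empty(len(keys))
    male = 1.0 if sex == "M" else 0.0
    coef = ref.coefficients
    for i, prot in enumerate(keys):
        if prot not in abundances:
            raise KeyError(f"protein {prot!r} missing from profile")
        if prot not in coef.index:
            raise KeyError(f"protein {prot!r} missing from healthy reference")
        rfu = abundances[prot]
        if not rfu > 0:
            raise ValueError(f"protein {prot!r}: non-positive RFU {rfu!r}")
        row = coef.loc[prot]
        out[i] = math.log(rfu) - row["age_slope"] * age - row["sex_offset"] * male
    return pd.Series(out, index=keys)


def compute_ratio_features(adjusted: pd.DataFrame, panel: ProteinPanel) -> pd.DataFrame:
    """Panel log-ratio features from adjusted log-abundance vectors.

    ``adjusted``: rows = participants, columns = proteins. Returns a frame
    with one column per panel ratio ("NUM/DEN"), in panel order.
    """
    missing = [p for p in panel.protein_list if p not in adjusted.columns]
    if missing:
        raise KeyError(f"panel proteins missing from adjusted matrix: {missing}")
    data = {
        f"{num}/{den}": adjusted[num].to_numpy() - adjusted[den].to_numpy()
        for num, den in panel.ratios
    }
    out = pd.DataFrame(data, index=adjusted.index)
    out.attrs["panel_name"] = panel.name
    if out.isna().any().any():
        raise ValueError("feature matrix contains missing values")
    return out


def cohort_features(cohort, panel: ProteinPanel, ref: HealthyReference) -> pd.DataFrame:
    """Adjust every profile in a cohort and return its panel feature matrix.

    Vectorized equivalent of calling :func:`adjust_profile` per participant
    followed by :func:`compute_ratio_features`.
    """
    parts = cohort.participants.set_index("participant_id")
    wide = cohort.abundance_frame()
    proteins = list(panel.protein_list)
    missing = [p for p in proteins if p not in wide.columns]
    if missing:
        raise KeyError(f"panel proteins missing from cohort profiles: {missing}")
    if not ref.covers(proteins):
        absent = sorted(set(proteins) - set(ref.coefficients.index))
        raise KeyError(f"panel proteins missing from healthy reference: {absent}")
    W = wide[proteins].to_numpy(float)
    if (W <= 0).any():
        raise ValueError("non-positive RFU in cohort profiles")
    age = parts.loc[wide.index, "age_at_lp"].to_numpy(float)
    male = (parts.loc[wide.index, "sex"].to_numpy() == "M").astype(float)
    coef = ref.coefficients.loc[proteins]
    adj = (
        np.log(W)
        - age[:, None] * coef["age_slope"].to_numpy()[None, :]
        - male[:, None] * coef["sex_offset"].to_numpy()[None, :]
    )
    adjusted = pd.DataFrame(adj, index=wide.index, columns=proteins)
    return compute_ratio_features(adjusted, panel)
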