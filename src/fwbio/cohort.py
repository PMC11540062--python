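"""Synthetic longitudinal aging cohorts with known generating parameters.

Emulates the statistical structure of a memory-and-aging study: older
adults (CU or MCI at baseline) seen at a four-visit schedule (baseline,
18 months, 3 years, 5 years) with attrition, nine baseline neuroimaging
biomarkers loading on one latent pathology factor, and seven cognitive
outcomes following a linear mixed model with correlated random intercepts
and age slopes per participant.

Everything the generator draws is parameterised by :class:`CohortTruth`
and a seed, so model-recovery tests can compare estimates against the
exact generating values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "BIOMARKER_COLUMNS",
    "OUTCOME_COLUMNS",
    "COVARIATE_COLUMNS",
    "CohortTruth",
    "make_cohort",
    "make_morphometry",
    "make_variance_partition_dataset",
]

BIOMARKER_COLUMNS = (
    "hippocampal_volume_adj",
    "hippocampal_fw",
    "hippocampal_fa_fwcorr",
    "schwarz_signature",
    "schwarz_fw",
    "schwarz_fa_fwcorr",
    "mcevoy_signature",
    "mcevoy_fw",
    "mcevoy_fa_fwcorr",
)

OUTCOME_COLUMNS = (
    "memory_composite",
    "executive_composite",
    "boston_naming",
    "animal_naming",
    "coding",
    "number_sequencing",
    "hooper",
)

COVARIATE_COLUMNS = ("age", "sex", "education", "race", "apoe4", "diagnosis", "fsrp")


def _default_fixed_effects() -> dict:
    # outcome is on a z-score-like scale; age enters centred at the
    # population mean baseline age (73 y)
    return {
        "intercept": 0.0,
        "biomarker": -0.30,
        "age": -0.045,
        "sex": 0.10,
        "education": 0.04,
        "race": -0.10,
        "apoe4": -0.15,
        "diagnosis": -0.80,
        "fsrp": -0.02,
    }


def _default_loadings() -> dict:
    # sign convention: latent factor = AD-like pathology burden
    return {
        "hippocampal_volume_adj": -0.70,
        "hippocampal_fw": 0.80,
        "hippocampal_fa_fwcorr": -0.55,
        "schwarz_signature": -0.65,
        "schwarz_fw": 0.60,
        "schwarz_fa_fwcorr": -0.45,
        "mcevoy_signature": -0.65,
        "mcevoy_fw": 0.60,
        "mcevoy_fa_fwcorr": -0.45,
    }


@dataclass
class CohortTruth:
    """Generating parameters for :func:`make_cohort`.

    fixed_effects : coefficients of the outcome linear predictor; the
        ``biomarker`` entry multiplies the observed value of
        ``target_biomarker`` (standardised scale).
    biomarker_loadings : loading of each biomarker on the latent pathology
        factor; unique variance is filled to give unit total variance.
    attrition_probs : per-visit retention probabilities, non-increasing.
    """

    fixed_effects: dict = field(default_factory=_default_fixed_effects)
    random_intercept_sd: float = 0.60
    random_age_slope_sd: float = 0.06
    intercept_slope_corr: float = -0.30
    residual_sd: float = 0.35
    biomarker_loadings: dict = field(default_factory=_default_loadings)
    attrition_probs: tuple = (1.0, 0.87, 0.76, 0.44)
    target_biomarker: str = "hippocampal_fw"
    age_mean: float = 73.0
    age_sd: float = 7.0
    age_min: float = 60.0
    sex_male_frac: float = 0.41
    race_minority_frac: float = 0.13
    education_mean: float = 16.0
    education_sd: float = 2.5
    apoe4_frac_cu: float = 0.25
    apoe4_frac_mci: float = 0.40
    fsrp_mean: float = 11.0
    fsrp_sd: float = 4.0
    dropout_mode: str = "mcar"  # or "outcome" (worse memory -> more dropout)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.random_intercept_sd < 0 or self.random_age_slope_sd < 0 or self.residual_sd < 0:
            raise ValueError("variance components must be non-negative")
        if abs(self.intercept_slope_corr) > 1:
            raise ValueError("|intercept_slope_corr| must be <= 1")
        probs = np.asarray(self.attrition_probs, dtype=float)
        if np.any(probs <= 0) or np.any(probs > 1):
            raise ValueError("retention probabilities must lie in (0, 1]")
        if np.any(np.diff(probs) > 1e-12):
            raise ValueError("retention probabilities must be non-increasing")
        unknown = set(self.biomarker_loadings) - set(BIOMARKER_COLUMNS)
        if unknown:
            raise ValueError(f"loadings reference unknown biomarkers: {sorted(unknown)}")
        if self.target_biomarker not in BIOMARKER_COLUMNS:
            raise ValueError(f"unknown target biomarker {self.target_biomarker!r}")
        if self.dropout_mode not in ("mcar", "outcome"):
            raise ValueError("dropout_mode must be 'mcar' or 'outcome'")


def _truncated_normal(rng, mean, sd, low, size):
    out = rng.normal(mean, sd, size=size)
    bad = out < low
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out < low
    return out


def make_cohort(
    n_participants: int,
    visit_schedule=(0.0, 1.5, 3.0, 5.0),
    truth: CohortTruth | None = None,
    diagnosis_fraction_mci: float = 0.40,
    seed: int | None = None,
):
    """Draw a longitudinal cohort and its baseline biomarker table.

    Returns ``(cohort, biomarkers, truth)`` where ``cohort`` is long-format
    (one row per retained participant-visit) and ``biomarkers`` has one row
    per participant.  ``seed`` overrides ``truth.seed`` when given.
    """
    if n_participants < 10:
        raise ValueError("need at least 10 participants")
    schedule = np.asarray(visit_schedule, dtype=float)
    if schedule.size == 0:
        raise ValueError("visit schedule is empty")
    if schedule[0] != 0 or np.any(np.diff(schedule) <= 0):
        raise ValueError("schedule must be strictly increasing and start at 0")
    truth = truth if truth is not None else CohortTruth()
    if len(truth.attrition_probs) != schedule.size:
        raise ValueError("attrition_probs length must match the visit schedule")
    rng = np.random.default_rng(truth.seed if seed is None else seed)

    n = int(n_participants)
    ids = np.array([f"P{i:04d}" for i in range(n)])

    # baseline covariates
    age0 = _truncated_normal(rng, truth.age_mean, truth.age_sd, truth.age_min, n)
    sex = (rng.random(n) < truth.sex_male_frac).astype(int)
    race = (rng.random(n) < truth.race_minority_frac).astype(int)
    education = rng.normal(truth.education_mean, truth.education_sd, n)
    fsrp = _truncated_normal(rng, truth.fsrp_mean, truth.fsrp_sd, 0.0, n)
    n_mci = int(round(diagnosis_fraction_mci * n))
    diagnosis = np.zeros(n, dtype=int)
    diagnosis[rng.permutation(n)[:n_mci]] = 1  # 1 = MCI
    apoe_p = np.where(diagnosis == 1, truth.apoe4_frac_mci, truth.apoe4_frac_cu)
    apoe4 = (rng.random(n) < apoe_p).astype(int)

    # latent pathology factor, elevated in MCI
    factor = rng.normal(0.0, 1.0, n) + 0.8 * diagnosis

    biom = {"participant_id": ids}
    for name in BIOMARKER_COLUMNS:
        lam = float(truth.biomarker_loadings.get(name, 0.0))
        unique_sd = np.sqrt(max(1.0 - lam**2, 0.0))
        biom[name] = lam * factor + rng.normal(0.0, unique_sd, n)
    biomarkers = pd.DataFrame(biom)

    # random effects: correlated intercept and age slope
    cov = np.array(
        [
            [truth.random_intercept_sd**2,
             truth.intercept_slope_corr * truth.random_intercept_sd * truth.random_age_slope_sd],
            [truth.intercept_slope_corr * truth.random_intercept_sd * truth.random_age_slope_sd,
             truth.random_age_slope_sd**2],
        ]
    )
    # matrix square root via eigendecomposition: exact zeros when the
    # variance components are zero, and tolerant of |corr| = 1
    lam, V = np.linalg.eigh(cov)
    L = V * np.sqrt(np.clip(lam, 0.0, None))

    fe = truth.fixed_effects
    target = biomarkers[truth.target_biomarker].to_numpy()

    rows = []
    for o in OUTCOME_COLUMNS:
        re = rng.standard_normal((n, 2)) @ L.T  # per-outcome random effects
        for v, t in enumerate(schedule):
            age = age0 + t
            age_c = age - truth.age_mean
            lp = (
                fe["intercept"]
                + fe["biomarker"] * target
                + fe["age"] * age_c
                + fe["sex"] * sex
                + fe["education"] * education
                + fe["race"] * race
                + fe["apoe4"] * apoe4
                + fe["diagnosis"] * diagnosis
                + fe["fsrp"] * fsrp
            )
            y = lp + re[:, 0] + re[:, 1] * age_c + rng.normal(0.0, truth.residual_sd, n)
            rows.append((o, v, age, y))

    # assemble long format: one row per participant-visit with all outcomes
    visit_frames = []
    for v, t in enumerate(schedule):
        frame = pd.DataFrame(
            {
                "participant_id": ids,
                "visit": v,
                "years_from_baseline": t,
                "age": age0 + t,
                "sex": sex,
                "education": education,
                "race": race,
                "apoe4": apoe4,
                "diagnosis": diagnosis,
                "fsrp": fsrp,
            }
        )
        for o, vv, age, y in rows:
            if vv == v:
                frame[o] = y
        visit_frames.append(frame)
    cohort = pd.concat(visit_frames, ignore_index=True)

    # attrition
    keep = np.ones(len(cohort), dtype=bool)
    probs = np.asarray(truth.attrition_probs, dtype=float)
    for v in range(schedule.size):
        sel = cohort["visit"].to_numpy() == v
        p = np.full(int(sel.sum()), probs[v])
        if truth.dropout_mode == "outcome" and v > 0:
            # worse memory at baseline shifts retention odds down
            base_mem = cohort.loc[cohort["visit"] == 0, ["participant_id", "memory_composite"]]
            mem = cohort.loc[sel, "participant_id"].map(
                base_mem.set_index("participant_id")["memory_composite"]
            ).to_numpy()
            logit = np.log(p / (1 - p + 1e-12)) + 0.5 * (mem - np.nanmean(mem))
            p = 1.0 / (1.0 + np.exp(-logit))
        keep[sel] = rng.random(p.shape) < p
    cohort = cohort.loc[keep].reset_index(drop=True)
    cohort = cohort.sort_values(["participant_id", "visit"]).reset_index(drop=True)

    return cohort, biomarkers, truth


def make_morphometry(participant_ids, seed=0, latent=None,
                     regions=("entorhinal", "fusiform", "inferior_temporal", "middle_temporal")):
    """Synthetic per-participant morphometry: thickness, hippocampal volumes, TIV.

    ``latent`` (optional, one value per participant) thins cortex and
    shrinks the hippocampus, mimicking pathology load.
    """
    ids = list(participant_ids)
    n = len(ids)
    rng = np.random.default_rng(seed)
    latent = np.zeros(n) if latent is None else np.asarray(latent, dtype=float)
    out = {"participant_id": ids}
    for r in regions:
        for side in ("left", "right"):
            out[f"thickness_{r}_{side}"] = np.clip(
                rng.normal(2.8, 0.2, n) - 0.12 * latent, 0.5, 6.0)
    out["hippocampus_left_volume"] = np.clip(rng.normal(3500, 300, n) - 180 * latent, 500, None)
    out["hippocampus_right_volume"] = np.clip(rng.normal(3550, 300, n) - 180 * latent, 500, None)
    out["tiv"] = rng.normal(1400, 120, n)  # cm^3
    return pd.DataFrame(out)


def make_variance_partition_dataset(
    n: int,
    r2_unique: dict,
    r2_covariates: float = 0.50,
    seed: int = 0,
):
    """Cross-sectional dataset with exact population variance shares.

    Covariates (standard normal, using the cohort covariate names) jointly
    explain ``r2_covariates`` of outcome variance; each key of
    ``r2_unique`` becomes a biomarker column explaining its share uniquely
    (orthogonally to covariates and to the other biomarkers); the rest is
    residual.  The population incremental R^2 of biomarker j beyond the
    covariates is exactly ``r2_unique[j]``.
    """
    total = r2_covariates + sum(r2_unique.values())
    if total >= 1:
        raise ValueError("variance shares must sum to < 1")
    rng = np.random.default_rng(seed)
    data = {"participant_id": [f"P{i:04d}" for i in range(n)], "visit": 0}
    C = rng.standard_normal((n, len(COVARIATE_COLUMNS)))
    for j, c in enumerate(COVARIATE_COLUMNS):
        data[c] = C[:, j]
    y = np.sqrt(r2_covariates) * (C.sum(axis=1) / np.sqrt(C.shape[1]))
    for name, share in r2_unique.items():
        u = rng.standard_normal(n)
        data[name] = u
        y = y + np.sqrt(share) * u
    y = y + np.sqrt(1.0 - total) * rng.standard_normal(n)
    data["outcome"] = y
    return pd.DataFrame(data)
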