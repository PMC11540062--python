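"""Unique-variance (incremental adjusted R^2) competitive model analysis.

For each outcome, a covariates-only model and one model per biomarker
(covariates + biomarker) are fit on identical rows.  The biomarker's
unique contribution is

    dR2_adj = R2_adj(covariates + biomarker) - R2_adj(covariates only)

with R2_adj the Ezekiel-adjusted R^2, and, for mixed models, R^2 computed
from fixed-effects predictions only (random effects set to zero).  All
models are refit on bootstrap resamples of participants — longitudinal
data is resampled by participant with all visits (cluster bootstrap) so
within-person correlation is respected — giving bootstrap SDs, a
two-sided test of each biomarker model against the covariates-only model,
and pairwise biomarker comparisons computed on shared resamples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .models import DEFAULT_COVARIATES, _fit_mixedlm

__all__ = [
    "adjusted_r2_ols",
    "adjusted_r2",
    "marginal_r2_lmm",
    "delta_r2",
    "bootstrap_competitive",
    "tertile_trajectories",
    "CompetitiveResult",
    "TertileSummary",
]


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel adjustment: 1 - (1 - R^2)(n - 1)/(n - p - 1).

    ``p`` counts predictors excluding the intercept.  May be negative.
    """
    if n <= p + 1:
        raise ValueError(f"n = {n} must exceed p + 1 = {p + 1}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def adjusted_r2_ols(fit) -> float:
    """Adjusted R^2 of a fitted OLS model (statsmodels RegressionResults)."""
    n = int(fit.nobs)
    p = int(fit.df_model)
    r2 = 1.0 - fit.ssr / fit.centered_tss
    return adjusted_r2(r2, n, p)


def marginal_r2_lmm(fit) -> float:
    """Fixed-effects-only adjusted R^2 of a mixed model.

    R^2 = 1 - SS(y - X*beta_fixed) / SS(y - ybar), random effects at zero,
    then Ezekiel-adjusted with n = observations and p = fixed terms.
    """
    if not fit.converged:
        raise ValueError("mixed model did not converge")
    y = np.asarray(fit.model.endog, dtype=float)
    yhat = np.asarray(fit.model.exog, dtype=float) @ np.asarray(fit.fe_params)
    ss_res = np.sum((y - yhat) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot
    p = len(fit.fe_params) - 1  # exclude intercept
    return adjusted_r2(r2, len(y), p)


def delta_r2(full_r2adj: float, covonly_r2adj: float) -> float:
    """Unique variance: full-model minus covariates-only adjusted R^2."""
    return float(full_r2adj) - float(covonly_r2adj)


def _ols_r2adj(X: np.ndarray, y: np.ndarray) -> tuple:
    """(adjusted R^2, last coefficient) by direct least squares.

    X includes the intercept; the biomarker, when present, is the last
    column, so the second return value is its coefficient.
    """
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot
    return adjusted_r2(r2, X.shape[0], X.shape[1] - 1), float(beta[-1])


def _corrected_two_sided_p(diffs: np.ndarray) -> float:
    """2 * min tail probability with (count + 1)/(B + 1) correction."""
    B = diffs.size
    lo = (np.sum(diffs <= 0) + 1) / (B + 1)
    hi = (np.sum(diffs >= 0) + 1) / (B + 1)
    return float(min(1.0, 2.0 * min(lo, hi)))


def _basic_bootstrap_p(stat_hat: float, stat_star: np.ndarray) -> float:
    """Two-sided basic-bootstrap test of H0: stat = 0.

    The centred replicates ``stat* - stat_hat`` approximate the sampling
    distribution of ``stat_hat`` around its true value; the test asks how
    extreme ``stat_hat`` is against that distribution.  Calibrated for
    regular (asymptotically normal) statistics such as a regression
    coefficient — unlike tail tests on dR2_adj itself, whose null
    distribution is boundary-degenerate.
    """
    T = stat_star - stat_hat
    B = T.size
    lo = (np.sum(T <= stat_hat) + 1) / (B + 1)
    hi = (np.sum(T >= stat_hat) + 1) / (B + 1)
    return float(min(1.0, 2.0 * min(lo, hi)))


@dataclass
class CompetitiveResult:
    """Point estimates, bootstrap SDs and comparison tests for one outcome."""

    outcome: str
    mode: str
    r2adj: dict            # model name -> point estimate
    r2adj_sd: dict         # model name -> bootstrap SD
    delta: dict            # biomarker -> point dR2_adj
    delta_sd: dict         # biomarker -> bootstrap SD
    beats_covariates_p: dict
    pairwise_p: pd.DataFrame
    B: int
    B_dropped: int
    seed: int
    replicates: pd.DataFrame = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"outcome": self.outcome, "model": "covariates_only",
                 "r2adj": self.r2adj["covariates_only"],
                 "r2adj_sd": self.r2adj_sd["covariates_only"],
                 "delta_r2adj": np.nan, "delta_r2adj_sd": np.nan,
                 "beats_covariates_p": np.nan}]
        for bm in self.delta:
            rows.append({"outcome": self.outcome, "model": bm,
                         "r2adj": self.r2adj[bm], "r2adj_sd": self.r2adj_sd[bm],
                         "delta_r2adj": self.delta[bm],
                         "delta_r2adj_sd": self.delta_sd[bm],
                         "beats_covariates_p": self.beats_covariates_p[bm]})
        return pd.DataFrame(rows)


def _lmm_r2adj(rows, outcome, fixed_cols, group_col, coef_col=None):
    fit, _ = _fit_mixedlm(rows, outcome, fixed_cols, group_col, "age_c")
    beta = float(fit.fe_params[coef_col]) if coef_col else np.nan
    return marginal_r2_lmm(fit), beta


def bootstrap_competitive(
    data: pd.DataFrame,
    biomarkers,
    outcome: str,
    mode: str = "baseline_ols",
    B: int = 1000,
    seed: int = 0,
    covariates=DEFAULT_COVARIATES,
    group_col: str = "participant_id",
    age_col: str = "age",
    keep_replicates: bool = True,
) -> CompetitiveResult:
    """Bootstrap the covariates-only and biomarker models on one outcome.

    mode "baseline_ols" uses baseline rows and resamples participants;
    mode "longitudinal_lmm" resamples participants with all their visits
    and refits the mixed model per replicate (markedly slower).  Every
    model within a replicate sees the same resample, so differences of
    dR2_adj between biomarkers are paired.

    ``beats_covariates_p`` tests whether the biomarker model improves on
    the covariates-only model via a basic bootstrap on the biomarker
    coefficient (see :func:`_basic_bootstrap_p`); pairwise biomarker
    comparisons use the two-sided tail test on paired dR2_adj differences.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    biomarkers = list(biomarkers)
    rng = np.random.default_rng(seed)

    if mode == "baseline_ols":
        if "visit" in data.columns:
            data = data[data["visit"] == data["visit"].min()]
        rows = data.dropna(subset=[outcome, *covariates, *biomarkers]).reset_index(drop=True)
        y = rows[outcome].to_numpy(dtype=float)
        C = np.column_stack([np.ones(len(rows)), rows[list(covariates)].to_numpy(dtype=float)])
        Bm = rows[biomarkers].to_numpy(dtype=float)
        n = len(rows)

        def replicate_fit(idx):
            r2_c, _ = _ols_r2adj(C[idx], y[idx])
            r2 = {"covariates_only": r2_c}
            betas = {}
            for j, bm in enumerate(biomarkers):
                X = np.column_stack([C[idx], Bm[idx, j]])
                r2[bm], betas[bm] = _ols_r2adj(X, y[idx])
            return r2, betas

        point_r2, point_beta = replicate_fit(np.arange(n))
        draw = lambda: rng.integers(0, n, size=n)

    elif mode == "longitudinal_lmm":
        covs = [c for c in covariates if c != age_col]
        rows = data.dropna(subset=[outcome, age_col, *covs, *biomarkers]).copy()
        base_age = rows.sort_values(age_col).groupby(group_col)[age_col].first()
        rows["age_c"] = rows[age_col] - base_age.mean()
        rows = rows.reset_index(drop=True)
        pids = rows[group_col].unique()
        by_pid = {pid: np.flatnonzero(rows[group_col].to_numpy() == pid) for pid in pids}

        def fit_all(frame):
            r2_c, _ = _lmm_r2adj(frame, outcome, ["age_c", *covs], group_col)
            r2 = {"covariates_only": r2_c}
            betas = {}
            for bm in biomarkers:
                r2[bm], betas[bm] = _lmm_r2adj(frame, outcome,
                                               [bm, "age_c", *covs], group_col,
                                               coef_col=bm)
            return r2, betas

        def replicate_fit(pid_sample):
            parts = []
            for new_id, pid in enumerate(pid_sample):
                chunk = rows.iloc[by_pid[pid]].copy()
                chunk[group_col] = f"B{new_id}"  # duplicated draws stay distinct clusters
                parts.append(chunk)
            return fit_all(pd.concat(parts, ignore_index=True))

        point_r2, point_beta = fit_all(rows)
        draw = lambda: rng.choice(pids, size=len(pids), replace=True)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    names = ["covariates_only"] + biomarkers
    reps_r2 = []
    reps_beta = []
    dropped = 0
    for b in range(B):
        sample = draw()
        try:
            r2, betas = replicate_fit(sample)
        except (np.linalg.LinAlgError, ValueError, RuntimeError):
            dropped += 1
            continue
        reps_r2.append(r2)
        reps_beta.append(betas)
    if dropped > 0.10 * B:
        raise RuntimeError(
            f"{dropped}/{B} bootstrap replicates failed to fit; "
            "data too unstable for a competitive analysis")

    rep = pd.DataFrame(reps_r2)[names]
    beta_rep = pd.DataFrame(reps_beta)[biomarkers]
    delta_rep = rep[biomarkers].sub(rep["covariates_only"], axis=0)

    delta_point = {bm: delta_r2(point_r2[bm], point_r2["covariates_only"])
                   for bm in biomarkers}
    # significance vs the covariates-only model: basic bootstrap on the
    # biomarker coefficient (regular statistic -> calibrated test); the
    # dR2_adj bootstrap SD quantifies uncertainty of the effect size
    beats = {bm: _basic_bootstrap_p(point_beta[bm], beta_rep[bm].to_numpy())
             for bm in biomarkers}

    pw = pd.DataFrame(np.nan, index=biomarkers, columns=biomarkers)
    for i, bi in enumerate(biomarkers):
        for bj in biomarkers[i + 1:]:
            p = _corrected_two_sided_p((delta_rep[bi] - delta_rep[bj]).to_numpy())
            pw.loc[bi, bj] = p
            pw.loc[bj, bi] = p

    return CompetitiveResult(
        outcome=outcome, mode=mode,
        r2adj={k: float(point_r2[k]) for k in names},
        r2adj_sd={k: float(rep[k].std(ddof=1)) for k in names},
        delta=delta_point,
        delta_sd={bm: float(delta_rep[bm].std(ddof=1)) for bm in biomarkers},
        beats_covariates_p=beats,
        pairwise_p=pw,
        B=B - dropped, B_dropped=dropped, seed=seed,
        replicates=rep if keep_replicates else None,
    )


@dataclass
class TertileSummary:
    """Per-tertile age-slopes of an outcome, split on a baseline biomarker."""

    biomarker: str
    outcome: str
    slopes: dict       # tertile -> fitted age slope
    slope_se: dict
    group_n: dict      # tertile -> number of participants
    assignments: pd.Series  # participant -> tertile label


TERTILE_LABELS = ("low", "middle", "high")


def tertile_trajectories(
    data: pd.DataFrame,
    biomarker: str,
    outcome: str,
    group_col: str = "participant_id",
    age_col: str = "age",
) -> TertileSummary:
    """Split participants by baseline biomarker tertile; fit each group's
    outcome-vs-age slope with a random-intercept mixed model.

    Participants are ordered by (baseline value, participant id) — the id
    breaks ties deterministically — and cut into three groups as equal as
    possible (sizes differ by at most one).
    """
    if "visit" in data.columns:
        base = data[data["visit"] == data["visit"].min()]
    else:
        base = data
    base = base.dropna(subset=[biomarker])
    if base[group_col].nunique() < 9:
        raise ValueError("need at least 9 participants with a baseline biomarker")
    if base[biomarker].nunique() < 3:
        raise ValueError("need at least 3 distinct biomarker values")

    ordered = base.sort_values([biomarker, group_col])[group_col].tolist()
    n = len(ordered)
    cuts = [round(n / 3), round(2 * n / 3)]
    assign = {}
    for i, pid in enumerate(ordered):
        assign[pid] = TERTILE_LABELS[0] if i < cuts[0] else (
            TERTILE_LABELS[1] if i < cuts[1] else TERTILE_LABELS[2])
    assignments = pd.Series(assign, name="tertile")

    rows = data.dropna(subset=[outcome, age_col]).copy()
    rows["age_c"] = rows[age_col] - rows[age_col].mean()
    slopes, ses, ns = {}, {}, {}
    for lab in TERTILE_LABELS:
        pids = [p for p, t in assign.items() if t == lab]
        sub = rows[rows[group_col].isin(pids)]
        ns[lab] = len(pids)
        exog = sm.add_constant(sub[["age_c"]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.MixedLM(sub[outcome], exog, groups=sub[group_col]).fit(reml=True)
        slopes[lab] = float(fit.fe_params["age_c"])
        ses[lab] = float(fit.bse_fe["age_c"])
    return TertileSummary(biomarker=biomarker, outcome=outcome, slopes=slopes,
                          slope_se=ses, group_n=ns, assignments=assignments)
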