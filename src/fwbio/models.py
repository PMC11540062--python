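"""Cross-sectional and longitudinal biomarker-cognition models.

Baseline model (per biomarker x outcome): ordinary least squares of the
cognitive score on the standardized biomarker plus covariates (age, sex,
education, race/ethnicity, APOE-e4 positivity, baseline diagnosis, FSRP).

Longitudinal model: linear mixed-effects regression of the score at every
visit on the baseline biomarker and the same covariates, with correlated
random intercept and random age-slope per participant, fit by REML.  Age
is centred at the baseline-sample mean before entering as covariate and
random-slope variable.  If the correlated-random-effects fit does not
converge the model is refit with uncorrelated random effects, then with a
random intercept only; the fallback level is recorded on the result.

Families of p-values are adjusted with the Benjamini-Hochberg step-up
false-discovery-rate procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "DEFAULT_COVARIATES",
    "ModelResult",
    "standardize_predictors",
    "fit_baseline_model",
    "fit_longitudinal_model",
    "fit_interaction_model",
    "fdr_adjust",
    "biomarker_outcome_grid",
    "results_to_frame",
]

DEFAULT_COVARIATES = ("age", "sex", "education", "race", "apoe4", "diagnosis", "fsrp")


@dataclass
class ModelResult:
    """One fitted biomarker-outcome model."""

    outcome: str
    predictor: str
    beta: float
    se: float
    p: float
    terms: pd.DataFrame  # index = term, columns = beta, se, p
    n_obs: int
    n_participants: int
    kind: str  # "ols" | "lmm"
    converged: bool = True
    p_fdr: float | None = None
    variance_components: dict | None = None
    random_structure: str | None = None  # correlated | uncorrelated | intercept_only
    fit: object = field(default=None, repr=False)


def standardize_predictors(table: pd.DataFrame, columns, visit_col: str = "visit"):
    """Z-score predictor columns using baseline-visit statistics.

    The mean/SD are taken over the earliest visit (one row per participant)
    and applied to every row, so a participant's standardized baseline
    biomarker is constant across visits.  Returns a copy; the transform
    parameters are stored in ``result.attrs['standardization']``.
    """
    out = table.copy()
    if visit_col in out.columns:
        base = out[out[visit_col] == out[visit_col].min()]
    else:
        base = out
    params = {}
    for col in columns:
        mu = float(base[col].mean())
        sd = float(base[col].std(ddof=1))
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"column {col!r} has zero variance at baseline")
        out[col] = (out[col] - mu) / sd
        params[col] = {"mean": mu, "sd": sd}
    out.attrs["standardization"] = params
    return out


def _check_full_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify aliased columns by incremental rank
        aliased = []
        cols = []
        for c in X.columns:
            cols.append(c)
            if np.linalg.matrix_rank(X[cols].to_numpy()) < len(cols):
                aliased.append(c)
                cols.pop()
        raise ValueError(f"design is rank deficient; aliased terms: {aliased}")


def _complete_rows(data: pd.DataFrame, cols) -> pd.DataFrame:
    return data.dropna(subset=[c for c in cols if c in data.columns])


def fit_baseline_model(
    data: pd.DataFrame,
    biomarker: str,
    outcome: str,
    covariates=DEFAULT_COVARIATES,
    extra_terms=(),
) -> ModelResult:
    """OLS of the outcome on biomarker + covariates, baseline rows only."""
    needed = [outcome, biomarker, *covariates, *extra_terms]
    if "visit" in data.columns:
        data = data[data["visit"] == data["visit"].min()]
    rows = _complete_rows(data, needed)
    if len(rows) < 20:
        raise ValueError(f"only {len(rows)} complete rows; need >= 20")
    X = sm.add_constant(rows[[biomarker, *covariates, *extra_terms]])
    _check_full_rank(X)
    fit = sm.OLS(rows[outcome], X).fit()
    terms = pd.DataFrame({"beta": fit.params, "se": fit.bse, "p": fit.pvalues})
    n_part = rows["participant_id"].nunique() if "participant_id" in rows else len(rows)
    return ModelResult(
        outcome=outcome, predictor=biomarker,
        beta=float(fit.params[biomarker]), se=float(fit.bse[biomarker]),
        p=float(fit.pvalues[biomarker]), terms=terms,
        n_obs=int(fit.nobs), n_participants=int(n_part), kind="ols", fit=fit,
    )


def _fit_mixedlm(rows, outcome, fixed_cols, group_col, age_c_col):
    """Fallback ladder: correlated -> uncorrelated -> intercept-only."""
    endog = rows[outcome]
    exog = sm.add_constant(rows[list(fixed_cols)])
    groups = rows[group_col]
    exog_re = sm.add_constant(rows[[age_c_col]])
    last_err = None
    for label in ("correlated", "uncorrelated", "intercept_only"):
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    warnings.simplefilter("ignore", RuntimeWarning)
                    warnings.simplefilter("ignore", UserWarning)
                    if label == "correlated":
                        md = sm.MixedLM(endog, exog, groups=groups, exog_re=exog_re)
                        fit = md.fit(reml=True, method=method)
                    elif label == "uncorrelated":
                        md = sm.MixedLM(endog, exog, groups=groups,
                                        exog_re=exog_re, use_sqrt=False)
                        free = sm.regression.mixed_linear_model.MixedLMParams.from_components(
                            fe_params=np.ones(exog.shape[1]), cov_re=np.eye(2))
                        fit = md.fit(reml=True, free=free, method=method)
                    else:
                        md = sm.MixedLM(endog, exog, groups=groups)
                        fit = md.fit(reml=True, method=method)
                if fit.converged:
                    return fit, label
                last_err = RuntimeError(f"{label}/{method} fit did not converge")
            except (np.linalg.LinAlgError, ValueError, RuntimeError) as err:
                last_err = err
    raise RuntimeError(f"mixed model failed at every fallback level: {last_err}")


def fit_longitudinal_model(
    data: pd.DataFrame,
    predictor: str,
    outcome: str,
    covariates=DEFAULT_COVARIATES,
    group_col: str = "participant_id",
    age_col: str = "age",
    extra_terms=(),
) -> ModelResult:
    """Linear mixed model with random intercept + age slope per participant.

    ``predictor`` is typically a baseline biomarker column merged onto the
    long table; passing a biomarker as ``outcome`` and ``diagnosis`` as
    ``predictor`` yields the diagnosis-to-biomarker longitudinal analysis.
    """
    covs = [c for c in covariates if c != "age"]
    needed = [outcome, predictor, age_col, *covs, *extra_terms, group_col]
    rows = _complete_rows(data, needed).copy()
    n_part = rows[group_col].nunique()
    visits = rows.groupby(group_col).size()
    if (visits >= 2).mean() < 0.30:
        raise ValueError("fewer than 30% of participants have repeated visits")

    # centre age at the baseline-sample mean
    base_age = rows.sort_values(age_col).groupby(group_col)[age_col].first()
    rows["age_c"] = rows[age_col] - base_age.mean()
    fixed = [predictor, "age_c", *covs, *extra_terms]
    _check_full_rank(sm.add_constant(rows[fixed]))

    fit, structure = _fit_mixedlm(rows, outcome, fixed, group_col, "age_c")
    params = fit.fe_params
    bse = fit.bse_fe
    pvals = fit.pvalues[params.index]
    terms = pd.DataFrame({"beta": params, "se": bse, "p": pvals})
    vc = {"group_var": float(fit.cov_re.iloc[0, 0]) if fit.cov_re.size else 0.0,
          "residual_var": float(fit.scale)}
    if fit.cov_re.shape[0] > 1:
        vc["age_slope_var"] = float(fit.cov_re.iloc[1, 1])
        vc["intercept_slope_cov"] = float(fit.cov_re.iloc[0, 1])
    return ModelResult(
        outcome=outcome, predictor=predictor,
        beta=float(params[predictor]), se=float(bse[predictor]),
        p=float(pvals[predictor]), terms=terms,
        n_obs=len(rows), n_participants=int(n_part), kind="lmm",
        converged=bool(fit.converged), variance_components=vc,
        random_structure=structure, fit=fit,
    )


def fit_interaction_model(
    data: pd.DataFrame,
    predictor: str,
    moderator: str,
    outcome: str,
    covariates=DEFAULT_COVARIATES,
    **kwargs,
) -> ModelResult:
    """Parent model plus a predictor x moderator product term.

    The product is formed from the columns as passed (standardize first);
    ``moderator="age"`` fits the longitudinal model with a predictor x
    centred-age term, anything else the baseline OLS model.  The returned
    ``beta``/``se``/``p`` refer to the interaction term.
    """
    data = data.copy()
    if moderator == "age":
        base_age = (data.sort_values("age").groupby("participant_id")["age"].first()
                    if "participant_id" in data.columns else data["age"])
        data["_moderator"] = data["age"] - base_age.mean()
    else:
        if data[moderator].nunique() < 2:
            raise ValueError(f"moderator {moderator!r} is constant")
        data["_moderator"] = data[moderator]
    inter = f"{predictor}_x_{moderator}"
    data[inter] = data[predictor] * data["_moderator"]
    if moderator == "age":
        res = fit_longitudinal_model(data, predictor, outcome,
                                     covariates=covariates,
                                     extra_terms=(inter,), **kwargs)
    else:
        extra = (inter,) if moderator in covariates or moderator == predictor \
            else (moderator, inter)
        res = fit_baseline_model(data, predictor, outcome,
                                 covariates=covariates, extra_terms=extra)
    res.beta = float(res.terms.loc[inter, "beta"])
    res.se = float(res.terms.loc[inter, "se"])
    res.p = float(res.terms.loc[inter, "p"])
    res.predictor = inter
    return res


def fdr_adjust(pvalues, method: str = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method=method)[1]


def biomarker_outcome_grid(
    data: pd.DataFrame,
    biomarkers,
    outcomes,
    mode: str = "baseline",
    covariates=DEFAULT_COVARIATES,
    fdr_family: str = "grid",
    moderator: str | None = None,
    **kwargs,
):
    """Fit every biomarker x outcome pair and FDR-adjust the family.

    mode : "baseline" (OLS), "longitudinal" (LMM) or "interaction"
        (requires ``moderator``)
    fdr_family : "grid" adjusts over all pairs at once; "per_biomarker"
        adjusts each biomarker's column of outcomes separately
    """
    results = []
    for bm in biomarkers:
        for oc in outcomes:
            try:
                if mode == "baseline":
                    res = fit_baseline_model(data, bm, oc, covariates=covariates)
                elif mode == "longitudinal":
                    res = fit_longitudinal_model(data, bm, oc,
                                                 covariates=covariates, **kwargs)
                elif mode == "interaction":
                    res = fit_interaction_model(data, bm, moderator, oc,
                                                covariates=covariates, **kwargs)
                else:
                    raise ValueError(f"unknown mode {mode!r}")
            except (ValueError, RuntimeError) as err:
                raise RuntimeError(f"model failed for ({bm}, {oc}): {err}") from err
            results.append(res)

    if fdr_family == "grid":
        adj = fdr_adjust([r.p for r in results])
        for r, a in zip(results, adj):
            r.p_fdr = float(a)
    elif fdr_family == "per_biomarker":
        for bm in biomarkers:
            group = [r for r in results if r.predictor == bm or r.predictor.startswith(f"{bm}_x_")]
            adj = fdr_adjust([r.p for r in group])
            for r, a in zip(group, adj):
                r.p_fdr = float(a)
    else:
        raise ValueError(f"unknown fdr_family {fdr_family!r}")
    return results


def results_to_frame(results) -> pd.DataFrame:
    """Tidy table of grid results (one row per biomarker x outcome)."""
    return pd.DataFrame(
        [
            {
                "outcome": r.outcome,
                "biomarker": r.predictor,
                "beta": r.beta,
                "se": r.se,
                "p": r.p,
                "p_fdr": r.p_fdr,
                "n_obs": r.n_obs,
                "n_participants": r.n_participants,
                "kind": r.kind,
                "converged": r.converged,
                "random_structure": r.random_structure,
            }
            for r in results
        ]
    )
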