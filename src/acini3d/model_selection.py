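"""Exhaustive AICc logistic model selection over the nine cluster features.

Every subset of the nine features (2^9 = 512 models, intercept-only
included) is fitted by maximum likelihood and scored with the
small-sample-corrected Akaike information criterion

    AICc = -2 logL + 2k + 2k(k+1)/(n - k - 1),

where k counts the intercept.  Models are compared through their AICc
differences delta_i and Akaike weights w_i = exp(-delta_i/2) normalised
over the feasible fits; the confidence set keeps models with delta <= 3.
Relative variable importance is the sum of Akaike weights of the models in
which a feature appears (the literal sum of AICc values is also emitted as
a diagnostic column, but it is not a bounded importance measure).

A random-intercept mixed logistic model (random effect per acinus,
marginal likelihood via the Laplace approximation) complements the fixed
effects analysis.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm

from .errors import AnalysisError
from .feature_extraction import FEATURE_NAMES

logger = logging.getLogger(__name__)

SEPARATION_COEF_BOUND = 15.0  # on standardized predictors
DELTA_WINDOW = 3.0


@dataclass
class ModelFit:
    """One logistic fit: subset, MLEs on the log-odds scale, AICc bookkeeping."""

    subset: tuple[str, ...]
    params: pd.Series | None
    bse: pd.Series | None
    loglik: float
    k: int
    n: int
    aicc: float
    converged: bool
    separation: bool
    feasible: bool
    reason: str = ""

    def odds_ratio_table(self, level: float = 0.95) -> pd.DataFrame:
        """Exponentiated coefficients with Wald confidence intervals."""
        return _odds_ratio_rows(self.params, self.bse, level)


def _odds_ratio_rows(params: pd.Series, bse: pd.Series, level: float) -> pd.DataFrame:
    """Exponentiated coefficients with Wald CIs; divergent fits yield
    infinite interval bounds rather than warnings."""
    z = norm.ppf(0.5 + level / 2.0)
    rows = []
    with np.errstate(over="ignore"):
        for name in params.index:
            coef, se = params[name], bse[name]
            zval = coef / se if se > 0 else np.nan
            rows.append(
                {
                    "term": name,
                    "coef": coef,
                    "se": se,
                    "odds_ratio": np.exp(coef),
                    "ci_low": np.exp(coef - z * se),
                    "ci_high": np.exp(coef + z * se),
                    "p_value": 2 * norm.sf(abs(zval)) if np.isfinite(zval) else np.nan,
                }
            )
    return pd.DataFrame(rows)


def _irls(X: np.ndarray, y: np.ndarray, tol: float = 1e-8, maxiter: int = 100):
    """Newton/IRLS for logistic regression.

    Returns (beta, cov, loglik, converged).  Step-halving guards against
    overshooting; a tiny ridge keeps the Hessian solvable near separation.
    """
    n, p = X.shape
    beta = np.zeros(p)
    ll = _loglik(X, y, beta)
    converged = False
    for _ in range(maxiter):
        eta = X @ beta
        mu = expit(eta)
        grad = X.T @ (y - mu)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(p), grad)
        except np.linalg.LinAlgError:
            break
        # step halving
        for _ in range(30):
            cand = beta + step
            ll_new = _loglik(X, y, cand)
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        beta = beta + step
        ll = _loglik(X, y, beta)
    mu = expit(X @ beta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H + 1e-10 * np.eye(p))
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    return beta, cov, _loglik(X, y, beta), converged


def _loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # log(1 + e^eta) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected AIC; requires n - k - 1 > 0."""
    if n - k - 1 <= 0:
        raise AnalysisError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _fit_design(Xf: np.ndarray, y: np.ndarray, subset: tuple[str, ...]) -> ModelFit:
    """Fit logistic MLE on an already-extracted feature matrix (no intercept
    column); shared by fit_logistic and the subset enumeration."""
    n = len(y)
    k = Xf.shape[1] + 1
    names = ["intercept", *subset]
    X = np.column_stack([np.ones(n), Xf])
    if n - k - 1 <= 0:
        return ModelFit(subset, None, None, np.nan, k, n, np.inf, False, False, False,
                        reason="n - k - 1 <= 0")
    if np.linalg.matrix_rank(X) < k:
        return ModelFit(subset, None, None, np.nan, k, n, np.inf, False, False, False,
                        reason="rank-deficient design")
    beta, cov, ll, converged = _irls(X, y)
    scale = np.ones(k)
    if k > 1:
        sd = Xf.std(axis=0, ddof=1)
        scale[1:] = np.where(sd > 0, sd, 1.0)
    std_coefs = beta * scale
    separation = bool(np.any(np.abs(std_coefs[1:]) > SEPARATION_COEF_BOUND)) or (
        not converged and bool(np.any(np.abs(std_coefs) > SEPARATION_COEF_BOUND / 2))
    )
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    return ModelFit(
        subset=subset,
        params=pd.Series(beta, index=names),
        bse=pd.Series(se, index=names),
        loglik=ll,
        k=k,
        n=n,
        aicc=aicc(ll, k, n),
        converged=converged,
        separation=separation,
        feasible=True,
    )


def fit_logistic(
    features: pd.DataFrame,
    subset: tuple[str, ...] | list[str],
    outcome: str = "outcome",
) -> ModelFit:
    """Fit a logistic regression of tumor outcome on a feature subset.

    The subset may be empty (intercept-only).  Quasi-complete separation is
    flagged when any standardized coefficient exceeds 15 in absolute value,
    or the fit fails to converge while coefficients diverge.  Rank-deficient
    designs and n - k - 1 <= 0 yield an infeasible (unfitted) result.
    """
    subset = tuple(subset)
    y = features[outcome].astype(float).to_numpy()
    if len(np.unique(y)) < 2:
        raise AnalysisError("outcome has a single class; logistic fit degenerate")
    n = len(y)
    Xf = features[list(subset)].to_numpy(dtype=float) if subset else np.empty((n, 0))
    return _fit_design(Xf, y, subset)


@dataclass
class SelectionResult:
    """Cross-model summary of the exhaustive AICc search."""

    models: pd.DataFrame          # one row per candidate subset
    fits: list[ModelFit]
    best: ModelFit
    confidence_set: pd.DataFrame  # models with delta <= DELTA_WINDOW
    importance: pd.DataFrame      # per-feature Akaike-weight sums
    best_or_table: pd.DataFrame
    delta_window: float = DELTA_WINDOW

    def summary_json(self) -> dict:
        return {
            "n_clusters": int(self.best.n),
            "n_models": int(len(self.models)),
            "n_feasible": int(self.models["feasible"].sum()),
            "best_subset": list(self.best.subset),
            "best_aicc": float(self.best.aicc),
            "confidence_set_size": int(len(self.confidence_set)),
            "importance": {
                r.feature: float(r.importance)
                for r in self.importance.itertuples(index=False)
            },
            "best_odds_ratios": self.best_or_table.to_dict(orient="records"),
        }


def all_subsets_selection(
    features: pd.DataFrame,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
    outcome: str = "outcome",
    delta_window: float = DELTA_WINDOW,
) -> SelectionResult:
    """Enumerate all 2^m feature subsets and rank them by AICc.

    Infeasible fits (rank deficiency, n - k - 1 <= 0) are flagged and
    excluded from the Akaike-weight normalisation but retained in the
    output.  Output ordering is deterministic (by delta, then subset).
    """
    y = features[outcome]
    if y.nunique() < 2 or min((y == v).sum() for v in y.unique()) < 2:
        raise AnalysisError("need at least 2 clusters per outcome class")
    yv = y.astype(float).to_numpy()
    col = {f: features[f].to_numpy(dtype=float) for f in feature_names}
    fits: list[ModelFit] = []
    for r in range(len(feature_names) + 1):
        for subset in itertools.combinations(feature_names, r):
            Xf = (
                np.column_stack([col[f] for f in subset])
                if subset
                else np.empty((len(yv), 0))
            )
            fits.append(_fit_design(Xf, yv, subset))
    feasible = [f for f in fits if f.feasible]
    if not feasible:
        raise AnalysisError("no feasible model among the candidates")
    best_aicc = min(f.aicc for f in feasible)
    rows = []
    for f in fits:
        delta = f.aicc - best_aicc if f.feasible else np.nan
        rows.append(
            {
                "subset": "+".join(f.subset) if f.subset else "(intercept)",
                "size": len(f.subset),
                "k": f.k,
                "loglik": f.loglik,
                "aicc": f.aicc if f.feasible else np.nan,
                "delta": delta,
                "feasible": f.feasible,
                "converged": f.converged,
                "separation": f.separation,
                "reason": f.reason,
            }
        )
    models = pd.DataFrame(rows)
    w = np.exp(-0.5 * models["delta"].to_numpy(dtype=float))
    w[~models["feasible"].to_numpy()] = 0.0
    models["weight"] = w / np.nansum(w)
    models = models.sort_values(
        ["feasible", "delta", "subset"], ascending=[False, True, True]
    ).reset_index(drop=True)
    best = min(feasible, key=lambda f: (f.aicc, f.subset))
    confidence = models[models["feasible"] & (models["delta"] <= delta_window)]
    imp_rows = []
    for feat in feature_names:
        mask = models["subset"].str.split("+").apply(lambda s, f=feat: f in s)
        imp_rows.append(
            {
                "feature": feat,
                "importance": float(models.loc[mask, "weight"].sum()),
                "aicc_sum": float(models.loc[mask & models["feasible"], "aicc"].sum()),
            }
        )
    importance = (
        pd.DataFrame(imp_rows)
        .sort_values("importance", ascending=False)
        .reset_index(drop=True)
    )
    return SelectionResult(
        models=models,
        fits=fits,
        best=best,
        confidence_set=confidence.reset_index(drop=True),
        importance=importance,
        best_or_table=best.odds_ratio_table(),
        delta_window=delta_window,
    )


# ---------------------------------------------------------------------------
# Random-intercept mixed logistic model (Laplace approximation)
# ---------------------------------------------------------------------------


@dataclass
class MixedModelFit:
    """Random-intercept logistic GLMM fitted by Laplace-approximated ML."""

    fe_names: list[str]
    fe_params: pd.Series
    fe_bse: pd.Series
    random_intercept_sd: float
    loglik: float
    converged: bool
    n_groups: int
    n_obs: int
    message: str = ""

    def odds_ratio_table(self, level: float = 0.95) -> pd.DataFrame:
        return _odds_ratio_rows(self.fe_params, self.fe_bse, level)


def _laplace_group_loglik(Xg, yg, beta, sigma):
    """Laplace-approximated marginal log-likelihood of one group.

    Inner 1-D Newton maximisation over the group's random intercept b;
    written as  l(b^) - b^2/(2 s^2) - 0.5 log(1 + s^2 sum w)  so the
    s -> 0 limit recovers the ordinary logistic log-likelihood.
    """
    eta0 = Xg @ beta
    b = 0.0
    for _ in range(50):
        mu = expit(eta0 + b)
        g = float(np.sum(yg - mu)) - b / sigma**2
        h = -float(np.sum(mu * (1 - mu))) - 1.0 / sigma**2
        step = -g / h
        b += step
        if abs(step) < 1e-10:
            break
    mu = expit(eta0 + b)
    w = float(np.sum(mu * (1 - mu)))
    ll_data = float(yg @ (eta0 + b) - np.logaddexp(0.0, eta0 + b).sum())
    return ll_data - b**2 / (2 * sigma**2) - 0.5 * np.log1p(sigma**2 * w)


def _mixed_negloglik(theta, X, y, groups_idx):
    beta, log_sigma = theta[:-1], theta[-1]
    sigma = np.exp(log_sigma)
    total = 0.0
    for idx in groups_idx:
        total += _laplace_group_loglik(X[idx], y[idx], beta, sigma)
    return -total


def fit_mixed_logistic(
    features: pd.DataFrame,
    fixed_effects: list[str],
    group: str = "acinus_id",
    outcome: str = "outcome",
    interaction_with: str | None = None,
    fix_sigma: float | None = None,
) -> MixedModelFit:
    """Random-intercept logistic regression via Laplace-approximated ML.

    ``fixed_effects`` enter as main effects; when ``interaction_with`` is a
    column name (e.g. the starting number of normal cells in the acinus) it
    is added as a main effect together with its interactions with each
    fixed effect.  The random intercept is per ``group`` with variance
    bounded at zero (optimised on the log-SD scale).  ``fix_sigma`` pins
    the random-intercept SD instead of estimating it (0 reduces the model
    to ordinary logistic regression).  Non-convergence is reported in the
    result, never raised.
    """
    df = features.copy()
    y = df[outcome].astype(float).to_numpy()
    if len(np.unique(y)) < 2:
        raise AnalysisError("outcome has a single class")
    if df[group].nunique() < 2:
        raise AnalysisError("need at least 2 groups for a random intercept")
    names = ["intercept", *fixed_effects]
    cols = [df[f].to_numpy(dtype=float) for f in fixed_effects]
    if interaction_with is not None:
        base = df[interaction_with].to_numpy(dtype=float)
        names.append(interaction_with)
        cols.append(base)
        for f in fixed_effects:
            names.append(f"{f}:{interaction_with}")
            cols.append(df[f].to_numpy(dtype=float) * base)
    X = np.column_stack([np.ones(len(df)), *cols])
    codes = pd.Categorical(df[group]).codes
    groups_idx = [np.where(codes == g)[0] for g in range(codes.max() + 1)]

    # start from the ordinary logistic fit, small positive sigma
    beta0, _, _, _ = _irls(X, y)
    if fix_sigma is not None and fix_sigma <= 1e-8:
        beta, cov, ll, conv = _irls(X, y)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        return MixedModelFit(
            fe_names=names,
            fe_params=pd.Series(beta, index=names),
            fe_bse=pd.Series(se, index=names),
            random_intercept_sd=0.0,
            loglik=ll,
            converged=conv,
            n_groups=len(groups_idx),
            n_obs=len(y),
            message="sigma fixed to 0 (ordinary logistic fit)",
        )
    if fix_sigma is not None:
        lo = hi = np.log(fix_sigma)
    else:
        lo, hi = np.log(1e-4), np.log(50.0)
    theta0 = np.append(beta0, np.clip(np.log(0.5), lo, hi))
    res = minimize(
        _mixed_negloglik,
        theta0,
        args=(X, y, groups_idx),
        method="L-BFGS-B",
        bounds=[(None, None)] * X.shape[1] + [(lo, hi)],
        options={"maxiter": 500},
    )
    beta = res.x[:-1]
    sigma = float(np.exp(res.x[-1]))
    # Wald SEs for the fixed effects from a numerical Hessian of the
    # marginal negative log-likelihood at the optimum
    se = _numerical_se(res.x, X, y, groups_idx)[: X.shape[1]]
    return MixedModelFit(
        fe_names=names,
        fe_params=pd.Series(beta, index=names),
        fe_bse=pd.Series(se, index=names),
        random_intercept_sd=sigma if sigma > 2e-4 else 0.0,
        loglik=-float(res.fun),
        converged=bool(res.success),
        n_groups=len(groups_idx),
        n_obs=len(y),
        message=str(res.message),
    )


def _numerical_se(theta, X, y, groups_idx, eps: float = 1e-4) -> np.ndarray:
    p = len(theta)
    H = np.zeros((p, p))
    f0 = _mixed_negloglik(theta, X, y, groups_idx)
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = eps
            ej = np.zeros(p); ej[j] = eps
            fpp = _mixed_negloglik(theta + ei + ej, X, y, groups_idx)
            fpm = _mixed_negloglik(theta + ei - ej, X, y, groups_idx)
            fmp = _mixed_negloglik(theta - ei + ej, X, y, groups_idx)
            fmm = _mixed_negloglik(theta - ei - ej, X, y, groups_idx)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps**2)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    _ = f0
    return se
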