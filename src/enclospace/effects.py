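"""Effect summaries from random-intercept models: EMMs, ratios, odds ratios.

Responses are modeled against two fixed factors — housing condition and sex
— with a random intercept per subject.  Proportion responses (behavior,
wall use, feeding outcome) use a binomial model with the visible-scan count
as the binomial total; continuous responses (weight, home-range and
core-area size) use a Gaussian model.

Estimation is delegated: Gaussian models go to ``statsmodels`` MixedLM;
binomial random-intercept models are fitted by Gauss–Hermite-quadrature
maximum likelihood with ``scipy`` optimization (an optional backend routes
them to R's glmmTMB instead, when an R installation is available).  All
downstream quantities — estimated marginal means averaged over the other
factor with equal level weights, EMM ratios with delta-method intervals,
odds ratios from logit-scale contrasts, and VIF screening — are computed
here so they can be tested against closed forms.

Models whose residual skewness exceeds a threshold (|skew| > 1 by default)
are flagged for descriptive reporting instead of model-based summaries.
"""

from __future__ import annotations

import json
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy import stats
from scipy.optimize import minimize
from scipy.special import expit
from statsmodels.tools.numdiff import approx_hess

__all__ = [
    "EffectSummary",
    "FittedConditionModel",
    "ModelSpec",
    "ConvergenceError",
    "InestimableLevelError",
    "UndefinedRatioError",
    "effect_ratio",
    "estimated_marginal_means",
    "fit_condition_model",
    "variance_inflation",
]

Z95 = stats.norm.ppf(0.975)


class ConvergenceError(RuntimeError):
    pass


class InestimableLevelError(ValueError):
    pass


class UndefinedRatioError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Contract for one condition model.

    ``response``: column holding the proportion (binomial) or value
    (gaussian).  ``weights``: column with the binomial total (visible-scan
    count); ignored for gaussian.  ``random`` lists random-intercept
    grouping columns; the date term is honored only by the glmmTMB backend
    (the quadrature backend integrates a single subject intercept).
    """

    response: str
    family: str  # "binomial" | "gaussian"
    fixed: tuple[str, ...] = ("condition", "sex")
    random: tuple[str, ...] = ("subject_id",)
    weights: str | None = None
    reference_levels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in {"binomial", "gaussian"}:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "binomial" and self.weights is None:
            raise ValueError("binomial models need a weights (total) column")


def _design(
    df: pd.DataFrame, fixed: tuple[str, ...], reference: dict
) -> tuple[np.ndarray, list[str], dict[str, list[str]]]:
    """Treatment-coded design matrix with intercept; deterministic levels."""
    cols = [np.ones(len(df))]
    names = ["Intercept"]
    levels: dict[str, list[str]] = {}
    for factor in fixed:
        lv = sorted(df[factor].astype(str).unique())
        ref = reference.get(factor, lv[0])
        if ref in lv:
            lv = [ref] + [x for x in lv if x != ref]
        levels[factor] = lv
        for other in lv[1:]:
            cols.append((df[factor].astype(str) == other).to_numpy(float))
            names.append(f"{factor}[{other}]")
    return np.column_stack(cols), names, levels


@dataclass
class FittedConditionModel:
    """A fitted random-intercept model plus its audit trail."""

    spec: ModelSpec
    params: pd.Series
    cov: pd.DataFrame
    tau: float
    levels: dict[str, list[str]]
    converged: bool
    residuals: np.ndarray
    residual_skew: float
    backend: str
    loglik: float | None = None
    skew_threshold: float = 1.0

    @property
    def descriptive_fallback(self) -> bool:
        """True when residual skew exceeds the threshold and summaries
        should be replaced by descriptive statistics."""
        return abs(self.residual_skew) > self.skew_threshold

    def emm_contrast(self, factor: str, level: str) -> np.ndarray:
        """Row vector giving the link-scale EMM of ``factor == level``,
        averaging over the other fixed factors with equal level weights."""
        if factor not in self.levels or level not in self.levels[factor]:
            raise InestimableLevelError(f"{factor}={level!r} not in the model")
        c = np.zeros(len(self.params))
        names = list(self.params.index)
        c[names.index("Intercept")] = 1.0
        for f, lv in self.levels.items():
            if f == factor:
                if level != lv[0]:
                    c[names.index(f"{f}[{level}]")] = 1.0
            else:
                w = 1.0 / len(lv)
                for other in lv[1:]:
                    c[names.index(f"{f}[{other}]")] = w
        return c


# ---------------------------------------------------------------------------
# binomial random-intercept GLMM by Gauss-Hermite quadrature


def _fit_binomial_ghq(
    df: pd.DataFrame, spec: ModelSpec, n_nodes: int = 25
) -> FittedConditionModel:
    X, names, levels = _design(df, spec.fixed, spec.reference_levels)
    tot = df[spec.weights].to_numpy(float)
    succ = np.round(df[spec.response].to_numpy(float) * tot)
    group_col = spec.random[0]
    groups, sub = np.unique(df[group_col], return_inverse=True)
    n_grp = len(groups)

    nodes, w = hermegauss(n_nodes)
    logw = np.log(w / w.sum())

    def nll(theta: np.ndarray) -> float:
        beta, ltau = theta[:-1], theta[-1]
        tau = np.exp(ltau)
        eta = X @ beta
        acc = None
        for q in range(n_nodes):
            e = eta + tau * nodes[q]
            li = succ * e - tot * np.logaddexp(0, e)
            per = np.bincount(sub, weights=li, minlength=n_grp)
            term = logw[q] + per
            acc = term if acc is None else np.logaddexp(acc, term)
        return -float(acc.sum())

    # start from the pooled GLM solution with a modest intercept spread
    p0 = np.clip((succ.sum() + 0.5) / (tot.sum() + 1.0), 1e-6, 1 - 1e-6)
    theta0 = np.r_[np.log(p0 / (1 - p0)), np.zeros(X.shape[1] - 1), np.log(0.3)]
    res = minimize(nll, theta0, method="L-BFGS-B",
                   options={"maxiter": 500})
    if not res.success:  # pragma: no cover - flat likelihoods
        res = minimize(nll, res.x, method="Nelder-Mead",
                       options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10})
    beta = res.x[:-1]
    tau = float(np.exp(res.x[-1]))
    H = approx_hess(res.x, nll)
    try:
        V_full = np.linalg.inv(H)
        cov = V_full[: len(beta), : len(beta)]
        ok = np.all(np.isfinite(cov)) and np.all(np.diag(cov) > 0)
    except np.linalg.LinAlgError:
        cov = np.full((len(beta), len(beta)), np.nan)
        ok = False

    fitted = expit(X @ beta)
    with np.errstate(divide="ignore", invalid="ignore"):
        pearson = (succ / tot - fitted) / np.sqrt(
            np.maximum(fitted * (1 - fitted) / np.maximum(tot, 1), 1e-12)
        )
    skew = float(stats.skew(pearson[np.isfinite(pearson)]))
    return FittedConditionModel(
        spec=spec,
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        tau=tau,
        levels=levels,
        converged=bool(res.success and ok),
        residuals=pearson,
        residual_skew=skew,
        backend="ghq",
        loglik=-float(res.fun),
    )


# ---------------------------------------------------------------------------
# gaussian random-intercept model via statsmodels MixedLM


def _fit_gaussian_mixedlm(df: pd.DataFrame, spec: ModelSpec) -> FittedConditionModel:
    import statsmodels.api as sm

    X, names, levels = _design(df, spec.fixed, spec.reference_levels)
    y = df[spec.response].to_numpy(float)
    groups = df[spec.random[0]].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups)
        try:
            res = model.fit(reml=True, method="lbfgs")
            converged = bool(res.converged)
        except Exception:  # pragma: no cover - singular fits
            res = model.fit(reml=True, method="nm", maxiter=2000)
            converged = bool(res.converged)
        beta = np.asarray(res.fe_params)
        cov = np.asarray(res.cov_params())[: len(beta), : len(beta)]
        llf = float(res.llf)
    resid = y - X @ beta
    skew = float(stats.skew(resid))
    tau = float(np.sqrt(max(float(np.squeeze(res.cov_re)), 0.0)))
    return FittedConditionModel(
        spec=spec,
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        tau=tau,
        levels=levels,
        converged=converged,
        residuals=resid,
        residual_skew=skew,
        backend="mixedlm",
        loglik=llf,
    )


# ---------------------------------------------------------------------------
# optional glmmTMB backend (requires Rscript + glmmTMB)

_R_TEMPLATE = """
suppressMessages(library(glmmTMB))
d <- read.csv("{csv}")
{factors}
m <- glmmTMB({formula}, data = d, family = {family})
fe <- fixef(m)$cond
V <- as.matrix(vcov(m)$cond)
vc <- VarCorr(m)$cond
tau <- if (!is.null(vc${group})) sqrt(vc${group}[1, 1]) else 0
out <- list(names = names(fe), beta = as.numeric(fe),
            cov = as.numeric(V), tau = tau,
            converged = is.finite(logLik(m)), loglik = as.numeric(logLik(m)))
cat(jsonlite::toJSON(out, auto_unbox = TRUE, digits = 12))
"""


def _fit_glmmtmb(df: pd.DataFrame, spec: ModelSpec) -> FittedConditionModel:
    """Delegate the fit to R glmmTMB (supports crossed random intercepts)."""
    _, names, levels = _design(df, spec.fixed, spec.reference_levels)
    work = df.copy()
    for factor in spec.fixed:
        lv = levels[factor]
        work[factor] = pd.Categorical(work[factor].astype(str), categories=lv)
    rand = " + ".join(f"(1|{g})" for g in spec.random)
    fixed = " + ".join(spec.fixed)
    if spec.family == "binomial":
        work["succ_"] = np.round(work[spec.response] * work[spec.weights])
        work["fail_"] = work[spec.weights] - work["succ_"]
        formula = f"cbind(succ_, fail_) ~ {fixed} + {rand}"
        family = "binomial"
    else:
        formula = f"{spec.response} ~ {fixed} + {rand}"
        family = "gaussian"
    with tempfile.TemporaryDirectory() as tmp:
        csv = Path(tmp) / "data.csv"
        work.to_csv(csv, index=False)
        factor_lines = "\n".join(
            f'd${f} <- factor(d${f}, levels = c({", ".join(repr(x) for x in levels[f])}))'
            for f in spec.fixed
        )
        script = Path(tmp) / "fit.R"
        script.write_text(
            _R_TEMPLATE.format(csv=csv, factors=factor_lines, formula=formula,
                               family=family, group=spec.random[0])
        )
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True
        )
    if proc.returncode != 0:
        raise ConvergenceError(f"glmmTMB backend failed: {proc.stderr[-500:]}")
    out = json.loads(proc.stdout)
    p = len(out["beta"])
    cov = np.asarray(out["cov"], dtype=float).reshape(p, p, order="F")
    beta = np.asarray(out["beta"], dtype=float)
    X, _, _ = _design(df, spec.fixed, spec.reference_levels)
    if spec.family == "binomial":
        tot = df[spec.weights].to_numpy(float)
        fitted = expit(X @ beta)
        resid = (df[spec.response].to_numpy(float) - fitted) / np.sqrt(
            np.maximum(fitted * (1 - fitted) / np.maximum(tot, 1), 1e-12)
        )
    else:
        resid = df[spec.response].to_numpy(float) - X @ beta
    return FittedConditionModel(
        spec=spec,
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        tau=float(out["tau"]),
        levels=levels,
        converged=bool(out["converged"]),
        residuals=resid,
        residual_skew=float(stats.skew(resid)),
        backend="glmmtmb",
        loglik=float(out["loglik"]),
    )


def fit_condition_model(
    df: pd.DataFrame, spec: ModelSpec, backend: str = "auto"
) -> FittedConditionModel:
    """Fit a random-intercept condition model under the ModelSpec contract.

    ``backend``: "auto" picks the quadrature fitter for binomial and
    statsmodels MixedLM for gaussian; "glmmtmb" routes either family to R.
    Non-convergence is flagged on the result (downstream summaries raise).
    """
    for col in spec.fixed + spec.random[:1] + (spec.response,):
        if col not in df.columns:
            raise ValueError(f"data is missing required column {col!r}")
    if df.groupby("condition")["subject_id"].nunique().min() < 2:
        raise ValueError("need both conditions observed for >= 2 subjects")
    if backend == "glmmtmb":
        return _fit_glmmtmb(df, spec)
    if spec.family == "binomial":
        return _fit_binomial_ghq(df, spec)
    return _fit_gaussian_mixedlm(df, spec)


# ---------------------------------------------------------------------------
# EMMs, ratios, odds ratios


@dataclass(frozen=True)
class EffectSummary:
    """Estimated marginal means and pairwise contrasts for one model.

    ``emms``: rows (factor, level, emm, ci_low, ci_high) on the response
    scale.  ``contrasts``: rows (factor, level_a, level_b, kind,
    estimate, ci_low, ci_high) where kind is "odds_ratio" (binomial) or
    "emm_ratio" (gaussian).
    """

    family: str
    emms: pd.DataFrame
    contrasts: pd.DataFrame
    descriptive_fallback: bool


def _require_usable(fit: FittedConditionModel) -> None:
    if not fit.converged:
        raise ConvergenceError(
            "model did not converge; summaries are suppressed"
        )


def estimated_marginal_means(fit: FittedConditionModel) -> EffectSummary:
    """EMMs per factor level with 95% CIs, plus all pairwise contrasts.

    Link-scale EMMs average over the other fixed factor with equal level
    weights and are back-transformed (inverse logit for binomial); CIs come
    from the link-scale standard errors.
    """
    _require_usable(fit)
    V = fit.cov.to_numpy()
    beta = fit.params.to_numpy()
    rows = []
    for factor, lv in fit.levels.items():
        for level in lv:
            c = fit.emm_contrast(factor, level)
            eta = float(c @ beta)
            se = float(np.sqrt(c @ V @ c))
            lo, hi = eta - Z95 * se, eta + Z95 * se
            if fit.spec.family == "binomial":
                eta, lo, hi = expit(eta), expit(lo), expit(hi)
            rows.append({"factor": factor, "level": level, "emm": eta,
                         "ci_low": lo, "ci_high": hi})
    emms = pd.DataFrame(rows)

    contrasts = []
    for factor, lv in fit.levels.items():
        for i in range(len(lv)):
            for j in range(len(lv)):
                if i == j:
                    continue
                contrasts.append(
                    _contrast_row(fit, factor, lv[i], lv[j])
                )
    return EffectSummary(
        family=fit.spec.family,
        emms=emms,
        contrasts=pd.DataFrame(contrasts),
        descriptive_fallback=fit.descriptive_fallback,
    )


def _contrast_row(
    fit: FittedConditionModel, factor: str, level_a: str, level_b: str
) -> dict:
    V = fit.cov.to_numpy()
    beta = fit.params.to_numpy()
    ca = fit.emm_contrast(factor, level_a)
    cb = fit.emm_contrast(factor, level_b)
    if fit.spec.family == "binomial":
        d = ca - cb
        est = float(d @ beta)
        se = float(np.sqrt(d @ V @ d))
        with np.errstate(over="ignore"):  # huge SEs yield an infinite bound
            return {
                "factor": factor, "level_a": level_a, "level_b": level_b,
                "kind": "odds_ratio",
                "estimate": float(np.exp(est)),
                "ci_low": float(np.exp(est - Z95 * se)),
                "ci_high": float(np.exp(est + Z95 * se)),
            }
    ma, mb = float(ca @ beta), float(cb @ beta)
    if mb <= 0 or ma <= 0:
        raise UndefinedRatioError(
            f"EMM ratio undefined for non-positive means ({ma:.3g}, {mb:.3g})"
        )
    ratio = ma / mb
    va = float(ca @ V @ ca)
    vb = float(cb @ V @ cb)
    cab = float(ca @ V @ cb)
    # delta method on log(ratio) keeps the CI positive
    var_log = va / ma**2 + vb / mb**2 - 2 * cab / (ma * mb)
    se_log = float(np.sqrt(max(var_log, 0.0)))
    return {
        "factor": factor, "level_a": level_a, "level_b": level_b,
        "kind": "emm_ratio",
        "estimate": ratio,
        "ci_low": ratio * float(np.exp(-Z95 * se_log)),
        "ci_high": ratio * float(np.exp(Z95 * se_log)),
    }


def effect_ratio(
    fit: FittedConditionModel, factor: str, level_a: str, level_b: str
) -> dict:
    """The level_a : level_b effect ratio (Gaussian) or odds ratio (binomial)
    with its 95% CI."""
    _require_usable(fit)
    return _contrast_row(fit, factor, level_a, level_b)


def variance_inflation(design: pd.DataFrame, cutoff: float = 2.1) -> pd.DataFrame:
    """Variance inflation factors for fixed-factor design columns.

    Each column is regressed on the others (with an intercept);
    VIF = 1/(1 - R^2).  Columns above ``cutoff`` are flagged; perfectly
    collinear columns yield infinite VIF.
    """
    X = design.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 fixed-factor columns")
    rows = []
    n = X.shape[0]
    for j, name in enumerate(design.columns):
        y = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        tss = float(np.sum((y - y.mean()) ** 2))
        rss = float(np.sum(resid**2))
        if tss == 0:
            vif = np.inf
        else:
            r2 = 1 - rss / tss
            vif = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append({"factor": name, "vif": vif, "flagged": bool(vif > cutoff)})
    return pd.DataFrame(rows)
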