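"""Mixed-effects models for the shortstopping analysis.

Three pre-specified model structures are fit (no model selection):

* site-distance LMM: distance_km ~ max_age + temp_anomaly + grain_cover
  + autocov, random intercept of first-use year, REML;
* experience LMM: log_min_prev ~ age with crossed random intercepts for
  individual, year and site, REML;
* shortstop GLMM: binomial/logit, shortstopped ~ age + year with an
  individual random intercept, maximum likelihood with Gauss-Hermite
  quadrature over the random effect.

Fixed-effect p-values are Wald-z (normal approximation).  The LMMs are
fit with statsmodels MixedLM; a self-contained profiled-REML fitter for
the single-random-intercept model (`reml_random_intercept`) backs the
randomization test's inner loop, where thousands of refits are needed,
and is equivalence-tested against MixedLM.  The binomial GLMM likelihood
is integrated with 21-node Gauss-Hermite quadrature, which is exact
enough that the sigma -> 0 limit reproduces plain logistic regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special
from scipy.special import expit, log_expit
from statsmodels.tools.numdiff import approx_hess

__all__ = [
    "ConvergenceError",
    "MixedModelFit",
    "fit_distance_lmm",
    "fit_experience_lmm",
    "fit_shortstop_glmm",
    "bootstrap_prediction_band",
    "partial_residuals",
    "reml_random_intercept",
]

DISTANCE_FIXED_EFFECTS = ["max_age", "temp_anomaly", "grain_cover", "autocov"]

#: optimiser tolerances, fixed for all fits
OPTIM_RTOL = 1e-8
OPTIM_MAXITER = 10_000


class ConvergenceError(RuntimeError):
    """Raised when an optimiser fails; carries its diagnostics message."""


@dataclass
class MixedModelFit:
    """A fitted mixed model in a backend-independent form.

    ``fe_table`` has one row per fixed effect (term, estimate, se, z, p);
    ``random_components`` maps each grouping factor to its intercept
    variance; ``resid`` are conditional residuals (random effects
    subtracted) and ``fitted`` the corresponding fitted values.
    """

    formula: str
    fe_table: pd.DataFrame
    random_components: dict[str, float]
    resid: np.ndarray
    fitted: np.ndarray
    fit_method: str
    converged: bool
    n_obs: int
    n_groups: dict[str, int]
    extra: dict = field(default_factory=dict, repr=False)

    def coef(self, term: str) -> float:
        return float(self.fe_table.set_index("term").loc[term, "estimate"])

    def se(self, term: str) -> float:
        return float(self.fe_table.set_index("term").loc[term, "se"])

    def to_summary_dict(self) -> dict:
        """JSON-serialisable summary of the fit."""
        return {
            "formula": self.formula,
            "fit_method": self.fit_method,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "fixed_effects": self.fe_table.to_dict(orient="records"),
            "random_components": self.random_components,
        }


# ---------------------------------------------------------------------------
# site-distance LMM
# ---------------------------------------------------------------------------

def fit_distance_lmm(rows: pd.DataFrame) -> MixedModelFit:
    """REML fit of the site-distance model.

    ``rows`` needs columns distance_km, max_age, temp_anomaly,
    grain_cover, autocov, first_use_year.  Row order does not affect the
    estimates.  Fit by the profiled-REML backend
    (:func:`reml_random_intercept`); a near-zero year variance triggers
    a singular-fit warning and the fit is still returned.
    """
    rows = rows.reset_index(drop=True)
    endog = rows["distance_km"].to_numpy(dtype=float)
    exog = sm.add_constant(rows[DISTANCE_FIXED_EFFECTS].to_numpy(dtype=float))
    groups = rows["first_use_year"].to_numpy()

    # canonical row order + internal centring: estimates become exactly
    # invariant to input permutation and response shifts
    codes = pd.factorize(groups, sort=True)[0]
    order = np.lexsort(tuple(exog.T[1:]) + (codes,))
    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))
    xm = exog[:, 1:].mean(axis=0)
    ym = endog.mean()
    Xc = exog.copy()
    Xc[:, 1:] -= xm
    res = reml_random_intercept((endog - ym)[order], Xc[order], codes[order])
    # de-centre: shift the intercept and transform its covariance
    k = exog.shape[1]
    T = np.eye(k)
    T[0, 1:] = -xm
    beta = T @ res["beta"]
    beta[0] += ym
    cov = T @ res["cov_beta"] @ T.T
    res["beta"], res["se"] = beta, np.sqrt(np.diag(cov))
    if not res["converged"]:
        raise ConvergenceError("distance LMM failed to converge "
                               f"(REML criterion {res['reml']:.3f})")
    if res["sigma2_u"] < 1e-8 * res["sigma2_e"]:
        warnings.warn("year random-intercept variance is singular (near zero)")

    terms = ["intercept", *DISTANCE_FIXED_EFFECTS]
    fe = pd.DataFrame({"term": terms, "estimate": res["beta"], "se": res["se"]})
    fe["z"] = fe["estimate"] / fe["se"]
    fe["p"] = 2.0 * (1.0 - _norm_cdf(np.abs(fe["z"].to_numpy())))

    marginal = endog - exog @ res["beta"]
    # BLUP of each year intercept: shrunken group mean of marginal residuals
    theta = res["sigma2_u"] / res["sigma2_e"] if res["sigma2_e"] > 0 else 0.0
    re_vec = np.zeros(len(rows))
    for g in pd.unique(groups):
        idx = groups == g
        n_g = int(idx.sum())
        re_vec[idx] = theta / (1.0 + n_g * theta) * marginal[idx].sum()
    resid = marginal - re_vec
    fitted = endog - resid

    return MixedModelFit(
        formula="distance_km ~ max_age + temp_anomaly + grain_cover + autocov"
                " + (1 | first_use_year)",
        fe_table=fe,
        random_components={"first_use_year": float(res["sigma2_u"])},
        resid=resid,
        fitted=fitted,
        fit_method="REML",
        converged=True,
        n_obs=len(rows),
        n_groups={"first_use_year": int(pd.unique(groups).size)},
        extra={
            "scale": float(res["sigma2_e"]),
            "marginal_resid": marginal,
            "exog": exog,
            "terms": terms,
            "groups": groups,
        },
    )


def _norm_cdf(x):
    return 0.5 * (1.0 + special.erf(np.asarray(x, dtype=float) / np.sqrt(2.0)))


def partial_residuals(fit: MixedModelFit, predictor: str) -> pd.DataFrame:
    """Partial residuals for one predictor of the distance LMM.

    Marginal residuals plus the predictor's fixed-effect contribution,
    paired with the predictor values (the display used to show each
    covariate's effect after adjusting for the others).
    """
    terms = fit.extra.get("terms")
    if terms is None or predictor not in terms:
        raise ValueError(f"unknown predictor {predictor!r}; available: {terms}")
    j = terms.index(predictor)
    x = fit.extra["exog"][:, j]
    beta = fit.coef(predictor)
    return pd.DataFrame({
        predictor: x,
        "partial_residual": fit.extra["marginal_resid"] + beta * x,
    })


# ---------------------------------------------------------------------------
# fast profiled REML for the single-random-intercept LMM
# ---------------------------------------------------------------------------

def reml_random_intercept(y: np.ndarray, X: np.ndarray,
                          group_codes: np.ndarray) -> dict:
    """Profiled REML for y = X beta + u_group + eps, one random intercept.

    The REML criterion is profiled down to the variance ratio
    theta = sigma_u^2 / sigma_e^2; V = I + theta Z Z' is inverted in
    closed form per group (Woodbury), so each evaluation is O(n p^2) and
    the whole fit is a 1-D bounded minimisation.  Matches statsmodels
    MixedLM to numerical tolerance, at a fraction of the cost -- used by
    the randomization test's inner loop.

    Returns a dict with beta, se, sigma2_e, sigma2_u, reml (criterion
    value), converged.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"REML needs more observations ({n}) than fixed "
                         f"effects ({p})")
    codes = np.asarray(group_codes)
    order = np.argsort(codes, kind="stable")
    y_s, X_s, codes_s = y[order], X[order], codes[order]
    starts = np.flatnonzero(np.r_[True, codes_s[1:] != codes_s[:-1]])
    counts = np.diff(np.r_[starts, n])

    Sx = np.add.reduceat(X_s, starts, axis=0)          # group sums of X
    Sy = np.add.reduceat(y_s, starts)                  # group sums of y
    XtX = X_s.T @ X_s
    Xty = X_s.T @ y_s
    yty = float(y_s @ y_s)

    def crit(log_theta: float) -> float:
        th = np.exp(log_theta)
        c = th / (1.0 + counts * th)                   # per-group shrinkage
        A = XtX - (Sx.T * c) @ Sx                      # X' V^-1 X
        b = Xty - Sx.T @ (c * Sy)                      # X' V^-1 y
        yVy = yty - float(c @ (Sy * Sy))
        sign, logdetA = np.linalg.slogdet(A)
        beta = np.linalg.solve(A, b)
        rss = yVy - float(b @ beta)
        logdetV = float(np.sum(np.log1p(counts * th)))
        return logdetV + logdetA + (n - p) * np.log(max(rss, 1e-300))

    opt = optimize.minimize_scalar(crit, bounds=(-12.0, 12.0), method="bounded",
                                   options={"xatol": 1e-10})
    th = float(np.exp(opt.x))
    c = th / (1.0 + counts * th)
    A = XtX - (Sx.T * c) @ Sx
    b = Xty - Sx.T @ (c * Sy)
    beta = np.linalg.solve(A, b)
    yVy = yty - float(c @ (Sy * Sy))
    rss = yVy - float(b @ beta)
    sigma2_e = rss / (n - p)
    cov_beta = np.linalg.inv(A) * sigma2_e
    return {
        "beta": beta,
        "se": np.sqrt(np.diag(cov_beta)),
        "cov_beta": cov_beta,
        "sigma2_e": sigma2_e,
        "sigma2_u": th * sigma2_e,
        "reml": float(opt.fun),
        "converged": bool(opt.success),
    }


# ---------------------------------------------------------------------------
# experience LMM (crossed random intercepts)
# ---------------------------------------------------------------------------

def fit_experience_lmm(records: pd.DataFrame,
                       age_grid: np.ndarray | None = None) -> MixedModelFit:
    """REML fit of log prior distance on age with crossed random intercepts.

    ``records`` needs columns log_min_prev, age, bird_id, year, site_id;
    each grouping factor must have at least two levels.  The fit also
    carries mean predictions by age with a 95% confidence band for the
    mean (random effects conditioned at zero) under
    ``extra["prediction"]``.
    """
    df = records.reset_index(drop=True).copy()
    for col in ("bird_id", "year", "site_id"):
        if df[col].nunique() < 2:
            raise ValueError(f"grouping factor {col!r} has fewer than 2 levels")
    df["_g"] = 1
    vc = {"bird": "0 + C(bird_id)", "year": "0 + C(year)", "site": "0 + C(site_id)"}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM.from_formula("log_min_prev ~ age", groups="_g",
                                        vc_formula=vc, re_formula="0", data=df)
        res = model.fit(reml=True, method="lbfgs", maxiter=OPTIM_MAXITER)
    if not res.converged:
        raise ConvergenceError("experience LMM failed to converge")

    vcomp = {name: float(v * res.scale)
             for name, v in zip(model.exog_vc.names, res.vcomp)}

    # fixed-effect covariance by GLS at the estimated variance
    # components (the Hessian-based covariance can lose positive
    # definiteness near a variance boundary)
    n = len(df)
    exog = sm.add_constant(df["age"].to_numpy(dtype=float))
    V = float(res.scale) * np.eye(n)
    factor_cols = {"bird": "bird_id", "year": "year", "site": "site_id"}
    for name, var in vcomp.items():
        Z = pd.get_dummies(df[factor_cols[name]]).to_numpy(dtype=float)
        V += var * Z @ Z.T
    Vi_X = np.linalg.solve(V, exog)
    covb = np.linalg.inv(exog.T @ Vi_X)

    fe = pd.DataFrame({
        "term": ["intercept", "age"],
        "estimate": np.asarray(res.fe_params, dtype=float),
        "se": np.sqrt(np.diag(covb)),
    })
    fe["z"] = fe["estimate"] / fe["se"]
    fe["p"] = 2.0 * (1.0 - _norm_cdf(np.abs(fe["z"].to_numpy())))

    marginal = df["log_min_prev"].to_numpy(dtype=float) - exog @ res.fe_params
    resid = np.asarray(res.resid, dtype=float)

    if age_grid is None:
        age_grid = np.sort(df["age"].unique()).astype(float)
    G = sm.add_constant(age_grid, has_constant="add")
    mean = G @ res.fe_params
    se_mean = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", G, covb, G), 0.0, None))
    pred = pd.DataFrame({
        "age": age_grid,
        "log_pred": mean,
        "log_lo": mean - 1.959963984540054 * se_mean,
        "log_hi": mean + 1.959963984540054 * se_mean,
    })
    pred["pred_km"] = np.exp(pred["log_pred"])

    return MixedModelFit(
        formula="log_min_prev ~ age + (1|bird_id) + (1|year) + (1|site_id)",
        fe_table=fe,
        random_components=vcomp,
        resid=resid,
        fitted=df["log_min_prev"].to_numpy(dtype=float) - resid,
        fit_method="REML",
        converged=bool(res.converged),
        n_obs=len(df),
        n_groups={c: int(df[c].nunique()) for c in ("bird_id", "year", "site_id")},
        extra={"prediction": pred, "marginal_resid": marginal},
    )


# ---------------------------------------------------------------------------
# shortstop GLMM (binomial, logit, individual random intercept)
# ---------------------------------------------------------------------------

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(21)
_GH_LOGW = np.log(_GH_WEIGHTS) - 0.5 * np.log(np.pi)


def _glmm_negloglik(params: np.ndarray, yv: np.ndarray, Xv: np.ndarray,
                    starts: np.ndarray) -> float:
    """Negative marginal log-likelihood, Gauss-Hermite integration.

    Rows must be sorted by individual; ``starts`` are the group offsets.
    """
    beta = params[:-1]
    sigma = np.exp(params[-1])
    eta0 = Xv @ beta
    offs = np.sqrt(2.0) * sigma * _GH_NODES          # (nq,)
    eta = eta0[:, None] + offs[None, :]              # (n, nq)
    ll_obs = np.where(yv[:, None] > 0, log_expit(eta), log_expit(-eta))
    ll_grp = np.add.reduceat(ll_obs, starts, axis=0)  # (n_groups, nq)
    return -float(np.sum(special.logsumexp(ll_grp + _GH_LOGW[None, :], axis=1)))


def fit_shortstop_glmm(records: pd.DataFrame) -> MixedModelFit:
    """ML fit of P(shortstop) ~ age + year with an individual intercept.

    ``records`` needs columns shortstopped (bool/0-1), age, year,
    bird_id.  Year enters centred on its midpoint for optimisation
    stability; the reported coefficient is on the original year scale
    (centring only shifts the intercept).  Predicted probabilities
    (random effect at zero) are returned for the age x year combinations
    present in the data (``extra["prediction"]``).

    Raises
    ------
    ValueError
        If only one outcome class is present, or on complete separation.
    ConvergenceError
        If the optimiser fails.
    """
    df = records.reset_index(drop=True)
    yv = df["shortstopped"].to_numpy(dtype=float)
    if yv.min() == yv.max():
        raise ValueError("both outcome classes must be present")
    year_mid = float(np.mean([df["year"].min(), df["year"].max()]))
    X = np.column_stack([np.ones(len(df)),
                         df["age"].to_numpy(dtype=float),
                         df["year"].to_numpy(dtype=float) - year_mid])

    # quick pooled fit: starting values + complete-separation detection
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            logit0 = sm.Logit(yv, X).fit(disp=0, maxiter=200)
        except Exception as exc:  # PerfectSeparationError and kin
            raise ValueError(
                "complete separation in shortstop data; consider penalisation"
            ) from exc
    if not np.all(np.isfinite(logit0.params)) or np.abs(logit0.params).max() > 30:
        raise ValueError(
            "complete separation in shortstop data; consider penalisation")

    order = np.argsort(df["bird_id"].to_numpy(), kind="stable")
    yv_s, X_s = yv[order], X[order]
    birds_s = df["bird_id"].to_numpy()[order]
    starts = np.flatnonzero(np.r_[True, birds_s[1:] != birds_s[:-1]])

    x0 = np.r_[logit0.params, np.log(0.5)]
    opt = optimize.minimize(_glmm_negloglik, x0, args=(yv_s, X_s, starts),
                            method="BFGS",
                            options={"gtol": 1e-6, "maxiter": OPTIM_MAXITER})
    grad_ok = np.max(np.abs(opt.jac)) < 1e-2
    if not (opt.success or grad_ok):
        raise ConvergenceError(f"shortstop GLMM failed to converge: {opt.message}")

    params = opt.x
    H = approx_hess(params, _glmm_negloglik, args=(yv_s, X_s, starts))
    try:
        cov = np.linalg.inv(H)
        se_all = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se_all = np.full(params.size, np.nan)

    terms = ["intercept", "age", "year"]
    fe = pd.DataFrame({"term": terms, "estimate": params[:3], "se": se_all[:3]})
    fe["z"] = fe["estimate"] / fe["se"]
    fe["p"] = 2.0 * (1.0 - _norm_cdf(np.abs(fe["z"].to_numpy())))
    sigma_u = float(np.exp(params[-1]))

    grid = (df[["age", "year"]].drop_duplicates()
            .sort_values(["year", "age"]).reset_index(drop=True))
    eta_g = (params[0] + params[1] * grid["age"].to_numpy(dtype=float)
             + params[2] * (grid["year"].to_numpy(dtype=float) - year_mid))
    grid["p_shortstop"] = expit(eta_g)

    eta_all = X @ params[:3]
    mu = expit(eta_all)

    return MixedModelFit(
        formula="shortstopped ~ age + year + (1 | bird_id), binomial(logit)",
        fe_table=fe,
        random_components={"bird_id": sigma_u ** 2},
        resid=yv - mu,
        fitted=mu,
        fit_method="ML (Gauss-Hermite, 21 nodes)",
        converged=True,
        n_obs=len(df),
        n_groups={"bird_id": int(df["bird_id"].nunique())},
        extra={
            "prediction": grid,
            "params": params,
            "year_mid": year_mid,
            "data": df[["bird_id", "age", "year", "shortstopped"]].copy(),
            "negloglik": float(opt.fun),
        },
    )


def bootstrap_prediction_band(fit: MixedModelFit, n_reps: int = 1000,
                              seed: int = 0,
                              max_failure_frac: float = 0.05) -> pd.DataFrame:
    """Parametric-bootstrap 95% band for the GLMM prediction grid.

    Each replicate simulates individual intercepts and binary responses
    from the fitted model, refits, and predicts on the same age x year
    grid; the band is the 2.5/97.5 percentile per grid point.
    Deterministic given ``seed``.  Errors if more than
    ``max_failure_frac`` of replicate refits fail.
    """
    df = fit.extra["data"]
    params = fit.extra["params"]
    year_mid = fit.extra["year_mid"]
    sigma_u = float(np.exp(params[-1]))
    X = np.column_stack([np.ones(len(df)),
                         df["age"].to_numpy(dtype=float),
                         df["year"].to_numpy(dtype=float) - year_mid])
    eta0 = X @ params[:3]
    birds = df["bird_id"].to_numpy()
    uniq, inv = np.unique(birds, return_inverse=True)

    grid = fit.extra["prediction"][["age", "year"]].copy()
    Xg = np.column_stack([np.ones(len(grid)),
                          grid["age"].to_numpy(dtype=float),
                          grid["year"].to_numpy(dtype=float) - year_mid])

    rng = np.random.default_rng(seed)
    preds = []
    n_fail = 0
    base = df.copy()
    for _ in range(n_reps):
        u = rng.normal(0.0, sigma_u, size=len(uniq))
        p = expit(eta0 + u[inv])
        ystar = rng.random(len(p)) < p
        if ystar.min() == ystar.max():
            n_fail += 1
            continue
        rep = base.copy()
        rep["shortstopped"] = ystar
        try:
            refit = fit_shortstop_glmm(rep)
        except (ValueError, ConvergenceError):
            n_fail += 1
            continue
        rp = refit.extra["params"]
        preds.append(expit(Xg @ rp[:3]))
    if n_fail > max_failure_frac * n_reps:
        raise ConvergenceError(
            f"{n_fail}/{n_reps} bootstrap replicate refits failed")
    P = np.vstack(preds)
    grid["lo"] = np.percentile(P, 2.5, axis=0)
    grid["hi"] = np.percentile(P, 97.5, axis=0)
    grid["n_ok"] = len(preds)
    return grid
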