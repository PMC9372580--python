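"""Random-intercept models and variance-ratio effect sizes.

Each per-turn outcome is modelled as

    value ~ run + leg + run:leg + (1 | skier-session)

(run only, for cycle-level outcomes such as movement amplitude and run
time). Three response families compete on maximum-likelihood AIC: normal,
lognormal (a normal model on log responses, with the log-transform Jacobian
added back so AICs are comparable on the response scale), and gamma with a
log link. Normal and lognormal fits use ``statsmodels`` MixedLM; the gamma
generalized linear mixed model is fitted here by adaptive Gauss-Hermite
quadrature over the random intercept.

Effect sizes follow the variance-component framework: with random-intercept
variance s2_id, residual (distribution-specific, latent-scale) variance
s2_e and fixed-predictor variance s2_f = Var(X beta) over the observed
design,

    ICC_adj  = s2_id / (s2_id + s2_e)
    ICC_cond = s2_id / (s2_id + s2_e + s2_f)
    R2m = s2_f / (s2_f + s2_id + s2_e),  R2c = (s2_f + s2_id) / (same)

so R2m + ICC_cond = R2c identically. A significant factor whose ICC_cond
(computed with that factor's own predictor variance) stays within ``tau`` of
ICC_adj is classified *negligible* — the fixed effect is too small to move
the denominator; otherwise the adapted agreement cutoffs bucket ICC_cond
into very strong (< 0.5), strong (< 0.75), moderate (< 0.9) and small
(> 0.9) fixed-effect sizes.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

import statsmodels.api as sm

log = logging.getLogger(__name__)

ALPHA = 0.05
ICC_EQUIVALENCE_TAU = 0.01
Z95 = 1.959963984540054
GH_NODES = 25

FAMILIES = ("normal", "lognormal", "gamma")


class FitError(RuntimeError):
    pass


@dataclass
class ModelSpec:
    response: str
    fixed: str = "run*leg"  # "run*leg" or "run"
    family: str = "auto"  # normal | lognormal | gamma | auto

    def terms(self) -> list[str]:
        if self.fixed == "run":
            return ["Intercept", "run"]
        if self.fixed == "run*leg":
            return ["Intercept", "run", "leg", "run:leg"]
        raise FitError(f"unsupported fixed structure {self.fixed!r}")


@dataclass
class EffectClass:
    label: str  # negligible | small | moderate | strong | very strong
    p: float
    icc_adj: float
    icc_cond: float


@dataclass
class CvDecomposition:
    cv_random: float
    cv_intra: float
    cv_syst: float


@dataclass
class MixedFit:
    family: str
    terms: list[str]
    coefficients: dict[str, float]
    cov: np.ndarray
    p_values: dict[str, float]
    var_random: float
    var_residual: float
    var_fixed: float
    var_fixed_terms: dict[str, float]
    aic: float
    llf: float
    n_obs: int
    n_groups: int
    r2m: float
    r2c: float
    icc_adj: float
    icc_cond: float
    singular: bool
    grand_mean: float
    gamma_shape: float | None = None
    emmeans: list[dict] = field(default_factory=list)
    emmean_diffs: list[dict] = field(default_factory=list)
    families_aic: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# effect-size primitives


def icc_adjusted(var_random: float, var_residual: float) -> float:
    """ICC_adj = random variance / (random + residual variance)."""
    denom = var_random + var_residual
    if denom <= 0:
        raise FitError("ICC_adj undefined: zero total variance")
    return var_random / denom


def icc_conditional(var_random: float, var_residual: float, var_fixed: float) -> float:
    """ICC_cond = random variance / (random + residual + fixed variance)."""
    denom = var_random + var_residual + var_fixed
    if denom <= 0:
        raise FitError("ICC_cond undefined: zero total variance")
    return var_random / denom


def icc_cond_from_r2(r2m: float, r2c: float) -> float:
    """ICC_cond recovered from the identity R2m + ICC_cond = R2c."""
    if r2m > r2c:
        raise FitError(f"r2m={r2m} exceeds r2c={r2c}")
    return r2c - r2m


def r2_nakagawa(var_fixed: float, var_random: float, var_residual: float) -> tuple[float, float]:
    """Marginal and conditional R^2 from the three variance components."""
    denom = var_fixed + var_random + var_residual
    if denom <= 0:
        raise FitError("R^2 undefined: zero total variance")
    return var_fixed / denom, (var_fixed + var_random) / denom


def classify_effect(
    p: float,
    icc_adj: float,
    icc_cond: float,
    alpha: float = ALPHA,
    tau: float = ICC_EQUIVALENCE_TAU,
) -> EffectClass:
    """Two-step classification of a fixed effect.

    A non-significant term is negligible. A significant term whose
    conditional ICC barely differs from the adjusted ICC (< tau) is also
    negligible — adding the fixed-effect variance to the denominator did not
    move it. Otherwise ICC_cond buckets the size: the *smaller* ICC_cond,
    the larger the share of variance the fixed effect claims.
    """
    if p >= alpha or abs(icc_adj - icc_cond) < tau:
        label = "negligible"
    elif icc_cond < 0.5:
        label = "very strong"
    elif icc_cond < 0.75:
        label = "strong"
    elif icc_cond <= 0.9:
        label = "moderate"
    else:
        label = "small"
    return EffectClass(label, p, icc_adj, icc_cond)


# ---------------------------------------------------------------------------
# design handling


def _design(table: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    df = table
    if "run" not in df.columns or "session_id" not in df.columns:
        raise FitError("table must have 'run' and 'session_id' columns")
    y = df["value"].to_numpy(dtype=float)
    run = (df["run"].astype(str) == "Last").to_numpy(dtype=float)
    terms = spec.terms()
    cols = [np.ones(len(df)), run]
    if "leg" in terms:
        leg = (df["leg"].astype(str) == "OL").to_numpy(dtype=float)
        cols += [leg, run * leg]
    X = np.column_stack(cols)
    groups = pd.factorize(df["session_id"])[0]
    if len(np.unique(groups)) < 2:
        raise FitError("need at least 2 skier-sessions for the random intercept")
    for j, t in enumerate(terms[1:], start=1):
        if np.ptp(X[:, j]) == 0:
            raise FitError(f"fixed factor {t!r} has a single level in the table")
    return y, X, groups, terms


def _grid_rows(terms: list[str]) -> list[tuple[dict, np.ndarray]]:
    cells = []
    legs = ["IL", "OL"] if "leg" in terms else [""]
    for run_v, run_name in ((0.0, "First"), (1.0, "Last")):
        for leg_name in legs:
            leg_v = 1.0 if leg_name == "OL" else 0.0
            x = [1.0, run_v] + ([leg_v, run_v * leg_v] if "leg" in terms else [])
            cells.append(({"run": run_name, "leg": leg_name}, np.array(x)))
    return cells


# ---------------------------------------------------------------------------
# family fits


def _lmm_loglik(y: np.ndarray, X: np.ndarray, groups: np.ndarray, beta: np.ndarray, vr: float, ve: float) -> float:
    """Exact marginal Gaussian log-likelihood of a random-intercept model.

    Per group, V = ve*I + vr*J; the Woodbury identity gives
    log|V| = n*log(ve) + log(1 + n*vr/ve) and
    r'V^-1 r = (r'r - vr/(ve + n*vr) * (sum r)^2) / ve.
    """
    if ve <= 0:
        return -np.inf
    r = y - X @ beta
    n_g = np.bincount(groups).astype(float)
    rr = np.bincount(groups, weights=r * r)
    rs = np.bincount(groups, weights=r)
    logdet = n_g * math.log(ve) + np.log1p(n_g * vr / ve)
    quad = (rr - vr / (ve + n_g * vr) * rs**2) / ve
    return float(-0.5 * np.sum(n_g * math.log(2.0 * math.pi) + logdet + quad))


def _fit_lmm(y: np.ndarray, X: np.ndarray, groups: np.ndarray, n_fe: int):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups)
        res = model.fit(reml=False)
        vr = float(np.asarray(res.cov_re)[0, 0])
        llf = _lmm_loglik(y, X, groups, np.asarray(res.fe_params, dtype=float), vr, float(res.scale))
        if not np.isfinite(llf) or vr < 1e-10:
            # the default optimizer occasionally collapses onto the boundary
            alt = model.fit(reml=False, method="powell")
            alt_vr = float(np.asarray(alt.cov_re)[0, 0])
            alt_llf = _lmm_loglik(y, X, groups, np.asarray(alt.fe_params, dtype=float), alt_vr, float(alt.scale))
            if np.isfinite(alt_llf) and (not np.isfinite(llf) or alt_llf > llf):
                res, llf = alt, alt_llf
    beta = np.asarray(res.fe_params, dtype=float)
    cov = np.asarray(res.cov_params())[:n_fe, :n_fe]
    var_random = float(np.asarray(res.cov_re)[0, 0])
    var_resid = float(res.scale)
    return beta, cov, var_random, var_resid, llf


def _gamma_nll(theta: np.ndarray, y: np.ndarray, X: np.ndarray, group_ids: np.ndarray, n_groups: int, nodes, weights) -> float:
    p = X.shape[1]
    beta = theta[:p]
    sigma_b = math.exp(theta[p])
    k = math.exp(theta[p + 1])
    eta = X @ beta
    n_g = np.bincount(group_ids, minlength=n_groups).astype(float)
    T_g = np.bincount(group_ids, weights=np.log(y), minlength=n_groups)
    E_g = np.bincount(group_ids, weights=eta, minlength=n_groups)
    S_g = np.bincount(group_ids, weights=y * np.exp(-eta), minlength=n_groups)
    base = n_g * (k * math.log(k) - special.gammaln(k)) + (k - 1.0) * T_g - k * E_g
    c = math.sqrt(2.0) * sigma_b * nodes  # (Q,)
    # ll_g(c_q) = base_g - k*n_g*c_q - k*exp(-c_q)*S_g
    with np.errstate(over="ignore"):
        ll = base[:, None] - k * n_g[:, None] * c[None, :] - k * np.exp(-c)[None, :] * S_g[:, None]
    lw = np.log(weights) - 0.5 * math.log(math.pi)
    group_ll = special.logsumexp(ll + lw[None, :], axis=1)
    return -float(group_ll.sum())


def _numeric_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.empty((n, n))
    hs = eps * (1.0 + np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = hs[i]
            ej = np.zeros(n); ej[j] = hs[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * hs[i] * hs[j])
    return H


def _fit_gamma_glmm(y: np.ndarray, X: np.ndarray, groups: np.ndarray, n_fe: int):
    """ML fit of a log-link gamma GLMM with a random intercept (Gauss-Hermite)."""
    if np.any(y <= 0):
        raise FitError("gamma family requires positive responses")
    n_groups = int(groups.max()) + 1
    nodes, weights = np.polynomial.hermite.hermgauss(GH_NODES)
    # warm start from the lognormal fit
    beta0, _, vr0, ve0, _ = _fit_lmm(np.log(y), X, groups, n_fe)
    k0 = _invert_trigamma(max(ve0, 1e-4))
    theta0 = np.concatenate([beta0, [0.5 * math.log(max(vr0, 1e-6)), math.log(k0)]])
    nll = lambda th: _gamma_nll(th, y, X, groups, n_groups, nodes, weights)
    bounds = [(None, None)] * n_fe + [(-8.0, 4.0), (-4.0, 12.0)]
    res = optimize.minimize(nll, theta0, method="L-BFGS-B", bounds=bounds)
    if not res.success:
        res2 = optimize.minimize(nll, res.x, method="Nelder-Mead", options={"maxiter": 4000, "xatol": 1e-7, "fatol": 1e-8})
        if res2.fun < res.fun:
            res = res2
    theta = res.x
    H = _numeric_hessian(nll, theta)
    try:
        cov_full = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_full = np.linalg.pinv(H)
    beta = theta[:n_fe]
    cov = cov_full[:n_fe, :n_fe]
    var_random = math.exp(theta[n_fe]) ** 2
    shape = math.exp(theta[n_fe + 1])
    llf = -float(res.fun)
    return beta, cov, var_random, shape, llf


def _invert_trigamma(v: float) -> float:
    """Solve trigamma(k) = v for k > 0 (Newton, trigamma is decreasing)."""
    k = 0.5 + 1.0 / v  # standard starting value
    for _ in range(50):
        f = float(special.polygamma(1, k)) - v
        fp = float(special.polygamma(2, k))
        step = f / fp
        k_new = k - step
        if k_new <= 0:
            k_new = k / 2.0
        if abs(k_new - k) < 1e-12 * (1 + k):
            k = k_new
            break
        k = k_new
    return k


# ---------------------------------------------------------------------------
# the front door


def fit_model(table: pd.DataFrame, spec: ModelSpec, alpha: float = ALPHA) -> MixedFit:
    """Fit the random-intercept model and derive the full effect-size summary.

    For ``family="auto"`` the normal, lognormal and gamma candidates are
    fitted and the lowest response-scale AIC wins (lognormal and gamma are
    skipped, with a log message, when responses are not strictly positive).
    A near-zero random-intercept variance is reported via ``singular=True``
    rather than raised.
    """
    df = table[table["metric"] == spec.response] if "metric" in table.columns else table
    if len(df) == 0:
        raise FitError(f"no rows for response {spec.response!r}")
    y, X, groups, terms = _design(df, spec)
    n_fe = X.shape[1]

    candidates = FAMILIES if spec.family == "auto" else (spec.family,)
    fits: dict[str, dict] = {}
    aics: dict[str, float] = {}
    positive = bool(np.all(y > 0))
    for fam in candidates:
        if fam in ("lognormal", "gamma") and not positive:
            log.info("family %s skipped for %s: non-positive responses", fam, spec.response)
            continue
        try:
            if fam == "normal":
                beta, cov, vr, ve, llf = _fit_lmm(y, X, groups, n_fe)
                aic = -2.0 * llf + 2.0 * (n_fe + 2)
                fits[fam] = dict(beta=beta, cov=cov, var_random=vr, var_residual=ve, llf=llf, shape=None)
            elif fam == "lognormal":
                beta, cov, vr, ve, llf_log = _fit_lmm(np.log(y), X, groups, n_fe)
                llf = llf_log - float(np.log(y).sum())  # Jacobian back to the response scale
                aic = -2.0 * llf + 2.0 * (n_fe + 2)
                fits[fam] = dict(beta=beta, cov=cov, var_random=vr, var_residual=ve, llf=llf, shape=None)
            else:
                beta, cov, vr, shape, llf = _fit_gamma_glmm(y, X, groups, n_fe)
                ve = float(special.polygamma(1, shape))  # latent-scale residual variance
                aic = -2.0 * llf + 2.0 * (n_fe + 2)
                fits[fam] = dict(beta=beta, cov=cov, var_random=vr, var_residual=ve, llf=llf, shape=shape)
            aics[fam] = aic
        except (FitError, np.linalg.LinAlgError) as exc:
            log.warning("family %s failed for %s: %s", fam, spec.response, exc)
    if not fits:
        raise FitError(f"no family could be fitted for {spec.response!r}")
    family = min(aics, key=aics.get)
    f = fits[family]
    beta, cov = f["beta"], f["cov"]
    var_random, var_residual = float(f["var_random"]), float(f["var_residual"])

    eta = X @ beta
    var_fixed = float(np.var(eta))
    var_fixed_terms: dict[str, float] = {}
    for term in terms[1:]:
        jset = [j for j, t in enumerate(terms) if t == term or t.startswith(f"{term}:") or t.endswith(f":{term}")]
        contrib = X[:, jset] @ beta[jset]
        var_fixed_terms[term] = float(np.var(contrib))

    r2m, r2c = r2_nakagawa(var_fixed, var_random, var_residual)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    zvals = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    from scipy.stats import norm as _norm

    pvals = {t: float(2.0 * _norm.sf(abs(z))) for t, z in zip(terms, zvals)}

    fit = MixedFit(
        family=family,
        terms=terms,
        coefficients={t: float(b) for t, b in zip(terms, beta)},
        cov=cov,
        p_values=pvals,
        var_random=var_random,
        var_residual=var_residual,
        var_fixed=var_fixed,
        var_fixed_terms=var_fixed_terms,
        aic=float(aics[family]),
        llf=float(f["llf"]),
        n_obs=len(y),
        n_groups=int(groups.max()) + 1,
        r2m=r2m,
        r2c=r2c,
        icc_adj=icc_adjusted(var_random, var_residual),
        icc_cond=icc_conditional(var_random, var_residual, var_fixed),
        singular=var_random < 1e-8,
        grand_mean=float(np.mean(y)),
        gamma_shape=f["shape"],
        families_aic=aics,
    )
    if fit.singular:
        log.warning("singular fit for %s: random-intercept variance ~ 0", spec.response)
    _attach_emmeans(fit)
    return fit


def _backtransform(family: str):
    if family == "normal":
        return lambda m: m
    return math.exp


def _attach_emmeans(fit: MixedFit) -> None:
    """Estimated marginal means on a balanced run(xleg) grid, Wald 95% CI.

    For lognormal/gamma families the means are computed on the link scale
    and back-transformed; Last-First differences on the response scale use
    the delta method.
    """
    terms = fit.terms
    beta = np.array([fit.coefficients[t] for t in terms])
    cov = fit.cov
    g = _backtransform(fit.family)
    cells = _grid_rows(terms)
    if np.linalg.matrix_rank(np.vstack([x for _, x in cells])) < len(terms):
        raise FitError("rank-deficient reference grid")
    fit.emmeans = []
    for labels, x in cells:
        m = float(x @ beta)
        s = float(math.sqrt(max(x @ cov @ x, 0.0)))
        fit.emmeans.append(
            {**labels, "emmean": g(m), "ci_low": g(m - Z95 * s), "ci_high": g(m + Z95 * s)}
        )
    fit.emmean_diffs = []
    legs = ["IL", "OL"] if "leg" in terms else [""]
    for leg in legs:
        xf = next(x for lab, x in cells if lab["run"] == "First" and lab["leg"] == leg)
        xl = next(x for lab, x in cells if lab["run"] == "Last" and lab["leg"] == leg)
        if fit.family == "normal":
            c = xl - xf
            d = float(c @ beta)
            s = float(math.sqrt(max(c @ cov @ c, 0.0)))
            lo, hi = d - Z95 * s, d + Z95 * s
        else:
            mf, ml = float(xf @ beta), float(xl @ beta)
            d = math.exp(ml) - math.exp(mf)
            grad = math.exp(ml) * xl - math.exp(mf) * xf
            s = float(math.sqrt(max(grad @ cov @ grad, 0.0)))
            lo, hi = d - Z95 * s, d + Z95 * s
        fit.emmean_diffs.append({"leg": leg, "diff": d, "ci_low": lo, "ci_high": hi})


def classify_terms(fit: MixedFit, alpha: float = ALPHA, tau: float = ICC_EQUIVALENCE_TAU) -> dict[str, EffectClass]:
    """Classify each fixed factor using its own predictor variance.

    The conditional ICC entering the classification of factor ``f`` adds only
    that factor's systematic variance to the denominator, so a significant
    but tiny effect collapses onto ICC_adj and is called negligible.
    """
    out = {}
    for term in fit.terms[1:]:
        icc_c = icc_conditional(fit.var_random, fit.var_residual, fit.var_fixed_terms[term])
        out[term] = classify_effect(fit.p_values[term], fit.icc_adj, icc_c, alpha=alpha, tau=tau)
    return out


def cv_decomposition(fit: MixedFit) -> CvDecomposition:
    """Coefficients of variation attributing dispersion to its three sources.

    Normal family: 100 * sqrt(variance) / grand mean for each component.
    Lognormal/gamma: random and systematic components live on the log scale
    and map to the response scale via CV = sqrt(exp(var) - 1); the gamma
    within-session CV is 1/sqrt(shape).
    """
    if fit.family == "normal":
        if fit.grand_mean <= 0:
            raise FitError("CV undefined: grand mean <= 0")
        m = fit.grand_mean
        return CvDecomposition(
            cv_random=100.0 * math.sqrt(fit.var_random) / m,
            cv_intra=100.0 * math.sqrt(fit.var_residual) / m,
            cv_syst=100.0 * math.sqrt(fit.var_fixed) / m,
        )
    lat_cv = lambda v: 100.0 * math.sqrt(math.expm1(v))
    if fit.family == "gamma":
        cv_intra = 100.0 / math.sqrt(fit.gamma_shape)
    else:
        cv_intra = lat_cv(fit.var_residual)
    return CvDecomposition(cv_random=lat_cv(fit.var_random), cv_intra=cv_intra, cv_syst=lat_cv(fit.var_fixed))
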