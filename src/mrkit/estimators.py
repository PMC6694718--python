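"""Causal-effect estimators for two-sample Mendelian randomization.

Every method consumes a harmonised dataset of per-SNP effects
(beta_exp, se_exp, beta_out, se_out) and returns a causal estimate of the
exposure on the outcome in the exposure's units (log odds for binary
outcomes; never exponentiated automatically).

Methods and conventions
-----------------------
Wald ratio            beta_out / beta_exp for a single instrument;
                      first-order se = se_out / |beta_exp|; normal p.
IVW                   inverse-variance-weighted combination of Wald
                      ratios, equivalently the zero-intercept weighted
                      regression of beta_out on beta_exp with weights
                      se_out^-2.  Variants: fixed effects ("fe"),
                      multiplicative random effects ("mre", se scaled by
                      the residual dispersion sigma = sqrt(Q/(L-1))), and
                      the default which applies max(1, sigma) so that
                      under-dispersion falls back to fixed effects.
                      Normal p.
MR-Egger              weighted regression with a free intercept after
                      orienting every SNP so beta_exp >= 0; the slope is
                      the causal estimate and the intercept the average
                      directional pleiotropy.  Standard errors use the
                      max(1, sigma) dispersion floor; t p with df = L-2.
                      A parametric bootstrap variant re-estimates the
                      standard errors.
Median                simple / weighted / penalised-weighted interpolated
                      median of the Wald ratios; parametric bootstrap se;
                      normal p.  Consistent when >50% of weight lies on
                      valid instruments.
Mode                  kernel-density mode of the Wald ratios (ZEMPA:
                      valid when the modal pleiotropic bias is zero);
                      simple / weighted, with NOME variants that ignore
                      exposure-side sampling error; bootstrap se; t p with
                      df = L-1.
Maximum likelihood    joint normal likelihood over the true SNP-exposure
                      effects and the causal slope; se from the observed
                      information; normal p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import optimize, stats

__all__ = [
    "MRResult", "PleiotropyResult", "MethodSpec", "wald_ratio", "ivw",
    "egger", "median_estimator", "mode_estimator", "max_likelihood",
    "run_mr", "beta_to_or", "p_value", "DEFAULT_METHODS",
    "method_display_name",
]


@dataclass(frozen=True)
class MRResult:
    """One method's causal estimate.

    ``b`` and ``se`` are on the exposure-unit scale (log odds for binary
    outcomes); ``pvalue_df`` is ``"normal"`` or the integer t degrees of
    freedom used for ``pval``.
    """

    method: str
    nsnp: int
    b: float
    se: float
    pval: float
    pvalue_df: Union[str, int] = "normal"


@dataclass(frozen=True)
class PleiotropyResult:
    """Egger regression intercept: average directional pleiotropic effect."""

    intercept: float
    se: float
    pval: float
    nsnp: int


@dataclass
class MethodSpec:
    """A method request with options and an explicit RNG seed."""

    name: str
    options: dict = field(default_factory=dict)
    seed: int = 0


# internal method keys -> display names used in results tables
_METHOD_NAMES = {
    "wald_ratio": "Wald ratio",
    "ivw": "Inverse variance weighted",
    "ivw_fe": "Inverse variance weighted (fixed effects)",
    "ivw_mre": "Inverse variance weighted (multiplicative random effects)",
    "mr_egger": "MR Egger",
    "mr_egger_bootstrap": "MR Egger (bootstrap)",
    "egger_intercept": "MR Egger intercept",
    "simple_median": "Simple median",
    "weighted_median": "Weighted median",
    "penalised_weighted_median": "Penalised weighted median",
    "simple_mode": "Simple mode",
    "weighted_mode": "Weighted mode",
    "simple_mode_nome": "Simple mode (NOME)",
    "weighted_mode_nome": "Weighted mode (NOME)",
    "max_likelihood": "Maximum likelihood",
}
_DISPLAY_TO_KEY = {v.lower(): k for k, v in _METHOD_NAMES.items()}

#: Default method battery: Wald ratio for single-SNP instruments plus the
#: four standard multi-SNP methods, in results-table order.
DEFAULT_METHODS = ("wald_ratio", "mr_egger", "weighted_median", "ivw", "weighted_mode")

_NORMAL_P = ("wald_ratio", "ivw", "ivw_fe", "ivw_mre", "max_likelihood",
             "simple_median", "weighted_median", "penalised_weighted_median")
_T_DF_MINUS_2 = ("mr_egger", "mr_egger_bootstrap", "egger_intercept")
_T_DF_MINUS_1 = ("simple_mode", "weighted_mode", "simple_mode_nome", "weighted_mode_nome")


def method_display_name(key: str) -> str:
    return _METHOD_NAMES.get(key, key)


def _method_key(name: str) -> str:
    key = name.strip().lower().replace(" ", "_").replace("-", "_")
    if key in _METHOD_NAMES:
        return key
    if name.strip().lower() in _DISPLAY_TO_KEY:
        return _DISPLAY_TO_KEY[name.strip().lower()]
    raise ValueError(f"unknown MR method: {name!r}")


def p_value(b: float, se: float, nsnp: int, method: str) -> float:
    """Two-sided p-value under the per-method distribution convention.

    Wald ratio, IVW, maximum likelihood and the median methods use the
    standard normal; the Egger slope/intercept use t with df = nsnp - 2;
    the mode methods use t with df = nsnp - 1.
    """
    if se <= 0:
        raise ValueError("se must be positive")
    key = _method_key(method)
    z = abs(b / se)
    if key in _NORMAL_P:
        return float(2.0 * stats.norm.sf(z))
    df = nsnp - 2 if key in _T_DF_MINUS_2 else nsnp - 1
    if df < 1:
        raise ValueError(f"t-distribution needs df >= 1 (nsnp={nsnp}, method={method})")
    return float(2.0 * stats.t.sf(z, df))


def beta_to_or(b: float, se: float, level: float = 0.95):
    """Exponentiate a log-odds estimate to an odds ratio with its CI."""
    if se <= 0:
        raise ValueError("se must be positive")
    z = stats.norm.isf((1.0 - level) / 2.0)
    return math.exp(b), math.exp(b - z * se), math.exp(b + z * se)


def _arrays(dataset) -> tuple:
    """Extract kept-SNP effect arrays from a HarmonisedDataset."""
    bx, sx, by, sy = dataset.arrays()
    if np.any(bx == 0):
        raise ValueError("beta_exp of zero gives an undefined Wald ratio")
    return bx, sx, by, sy


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float) -> MRResult:
    """Single-instrument ratio estimate with first-order delta-method se."""
    if beta_exp == 0:
        raise ValueError("undefined ratio: beta_exp is zero")
    b = beta_out / beta_exp
    se = se_out / abs(beta_exp)
    return MRResult("wald_ratio", 1, b, se, p_value(b, se, 1, "wald_ratio"), "normal")


def _ivw_core(bx, by, sy):
    w = sy ** -2.0
    denom = float(np.sum(w * bx * bx))
    b = float(np.sum(w * bx * by)) / denom
    se_fe = denom ** -0.5
    q = float(np.sum(w * (by - b * bx) ** 2))
    return b, se_fe, q


def ivw(dataset, variant: str = "default") -> MRResult:
    """Inverse-variance-weighted estimate (zero-intercept weighted regression).

    ``variant``: "fe" fixed effects, "mre" multiplicative random effects,
    "default" applies the max(1, sigma) dispersion floor.
    """
    bx, sx, by, sy = _arrays(dataset)
    L = bx.size
    if L < 2:
        raise ValueError("ivw needs >= 2 SNPs; use wald_ratio for a single instrument")
    b, se_fe, q = _ivw_core(bx, by, sy)
    sigma = math.sqrt(q / (L - 1))
    if variant == "fe":
        se, key = se_fe, "ivw_fe"
    elif variant == "mre":
        se, key = se_fe * sigma, "ivw_mre"
    elif variant == "default":
        se, key = se_fe * max(1.0, sigma), "ivw"
    else:
        raise ValueError(f"unknown ivw variant: {variant!r}")
    return MRResult(key, L, b, se, p_value(b, se, L, key), "normal")


def _orient(bx, by):
    """Flip SNPs so every exposure effect is positive."""
    sgn = np.where(bx < 0, -1.0, 1.0)
    return bx * sgn, by * sgn


def _egger_wls(bx, by, sy):
    """Weighted regression by = a + b*bx; returns coefficients, unit-weight
    covariance and the residual dispersion sigma (df = L - 2)."""
    w = sy ** -2.0
    X = np.column_stack([np.ones_like(bx), bx])
    xtwx = X.T @ (w[:, None] * X)
    if abs(np.linalg.det(xtwx)) < 1e-300 or np.ptp(bx) == 0:
        raise ValueError("slope unidentifiable: exposure effects collinear after orientation")
    cov_unit = np.linalg.inv(xtwx)
    coef = cov_unit @ (X.T @ (w * by))
    resid = by - X @ coef
    sigma2 = float(np.sum(w * resid ** 2)) / (bx.size - 2)
    return coef, cov_unit, math.sqrt(max(sigma2, 0.0))


def egger(dataset, bootstrap: bool = False, reps: int = 1000, seed: int = 0):
    """MR-Egger regression: (slope MRResult, intercept PleiotropyResult).

    SNPs are oriented so the exposure effect is always positive before the
    fit; standard errors carry the max(1, sigma) dispersion floor; p-values
    are two-sided t with df = L - 2.  With ``bootstrap`` the standard
    errors are replaced by the spread of a parametric bootstrap that
    redraws both betas from their reported sampling errors.
    """
    bx, sx, by, sy = _arrays(dataset)
    L = bx.size
    if L < 3:
        raise ValueError("MR-Egger needs >= 3 SNPs")
    bxo, byo = _orient(bx, by)
    coef, cov_unit, sigma = _egger_wls(bxo, byo, sy)
    infl = max(1.0, sigma)
    se_a = math.sqrt(cov_unit[0, 0]) * infl
    se_b = math.sqrt(cov_unit[1, 1]) * infl
    key = "mr_egger"
    if bootstrap:
        key = "mr_egger_bootstrap"
        rng = np.random.default_rng(seed)
        slopes = np.empty(reps)
        intercepts = np.empty(reps)
        for i in range(reps):
            bxs = rng.normal(bx, sx)
            bys = rng.normal(by, sy)
            bxs, bys = _orient(bxs, bys)
            c, _, _ = _egger_wls(bxs, bys, sy)
            intercepts[i], slopes[i] = c
        se_a = float(np.std(intercepts, ddof=1))
        se_b = float(np.std(slopes, ddof=1))
    slope = MRResult(key, L, float(coef[1]), se_b,
                     p_value(float(coef[1]), se_b, L, key), L - 2)
    intercept = PleiotropyResult(float(coef[0]), se_a,
                                 p_value(float(coef[0]), se_a, L, "egger_intercept"), L)
    return slope, intercept


def _weighted_median(ratios, weights):
    """Interpolated weighted median: the value where the cumulative
    normalized weight crosses 0.5."""
    order = np.argsort(ratios, kind="stable")
    r = np.asarray(ratios, float)[order]
    w = np.asarray(weights, float)[order]
    cum = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] < 0.5:
        return float(r[-1])
    k = int(np.max(np.nonzero(cum < 0.5)[0]))
    return float(r[k] + (r[k + 1] - r[k]) * (0.5 - cum[k]) / (cum[k + 1] - cum[k]))


def _median_point(ratios, w_first, variant, penalty_scale):
    if variant == "simple":
        return _weighted_median(ratios, np.ones_like(ratios))
    if variant == "weighted":
        return _weighted_median(ratios, w_first)
    if variant == "penalised":
        b0 = _weighted_median(ratios, w_first)
        contrib = w_first * (ratios - b0) ** 2
        pen = stats.chi2.sf(contrib, df=1)
        w_pen = w_first * np.minimum(1.0, penalty_scale * pen)
        return _weighted_median(ratios, w_pen)
    raise ValueError(f"unknown median variant: {variant!r}")


def median_estimator(dataset, variant: str = "weighted", reps: int = 1000,
                     seed: int = 0, penalty_scale: float = 20.0) -> MRResult:
    """Median of the per-SNP Wald ratios (simple/weighted/penalised).

    The weighted variants use first-order inverse-variance weights
    se_out^-2 * beta_exp^2; the penalised variant additionally down-weights
    SNPs by the chi^2(1) upper-tail probability of their contribution to
    heterogeneity about the weighted-median fit.  The standard error is a
    seeded parametric bootstrap (default 1000 reps); normal p.
    """
    bx, sx, by, sy = _arrays(dataset)
    L = bx.size
    if L < 3:
        raise ValueError("median methods need >= 3 SNPs")
    ratios = by / bx
    s_first = sy / np.abs(bx)
    w_first = s_first ** -2.0
    b = _median_point(ratios, w_first, variant, penalty_scale)

    rng = np.random.default_rng(seed)
    boots = np.empty(reps)
    for i in range(reps):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        rs = bys / bxs
        ws = (sy / np.abs(bxs)) ** -2.0
        boots[i] = _median_point(rs, ws, variant, penalty_scale)
    se = float(np.std(boots, ddof=1))
    key = {"simple": "simple_median", "weighted": "weighted_median",
           "penalised": "penalised_weighted_median"}[variant]
    return MRResult(key, L, b, se, p_value(b, se, L, key), "normal")


def _silverman_bandwidth(ratios):
    sd = float(np.std(ratios, ddof=1))
    iqr = float(np.subtract(*np.percentile(ratios, [75, 25])))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    return 0.9 * spread * ratios.size ** (-0.2)


def _kde_mode(ratios, weights, h, grid_size=1000):
    """Grid argmax of a weighted Gaussian kernel density over the ratios."""
    h = max(h, 1e-8)
    lo, hi = np.min(ratios) - 3 * h, np.max(ratios) + 3 * h
    grid = np.linspace(lo, hi, grid_size)
    wn = np.asarray(weights, float)
    wn = wn / np.sum(wn)
    dens = np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2) @ wn
    return float(grid[int(np.argmax(dens))])


def mode_estimator(dataset, variant: str = "weighted", nome: bool = False,
                   phi: float = 1.0, reps: int = 1000, seed: int = 0,
                   grid_size: int = 1000) -> MRResult:
    """Kernel-density mode of the Wald ratios (largest-cluster estimate).

    Weights: uniform for the simple variant; inverse ratio variance for the
    weighted variant, using the full delta-method variance
    se_out^2/beta_exp^2 + beta_out^2 se_exp^2/beta_exp^4, or its
    first-order (exposure-error-free) form under NOME.  The bandwidth is
    ``phi`` times the Silverman reference bandwidth of the ratios; the
    estimate is the grid argmax of the smoothed density.  Bootstrap se;
    t p with df = L - 1.
    """
    if phi <= 0:
        raise ValueError("phi must be positive")
    bx, sx, by, sy = _arrays(dataset)
    L = bx.size
    if L < 3:
        raise ValueError("mode methods need >= 3 SNPs")
    ratios = by / bx
    var_first = (sy / np.abs(bx)) ** 2
    var_delta = sy ** 2 / bx ** 2 + (by ** 2) * (sx ** 2) / bx ** 4
    s_ratio = np.sqrt(var_first if nome else var_delta)
    if variant == "simple":
        weights = np.ones(L)
        key = "simple_mode_nome" if nome else "simple_mode"
    elif variant == "weighted":
        weights = 1.0 / (var_first if nome else var_delta)
        key = "weighted_mode_nome" if nome else "weighted_mode"
    else:
        raise ValueError(f"unknown mode variant: {variant!r}")

    h = phi * _silverman_bandwidth(ratios)
    b = _kde_mode(ratios, weights, h, grid_size)

    # parametric bootstrap: redraw the ratios from their sampling errors;
    # the spread is the normal-consistent scaled MAD (the convention for
    # mode estimators, whose bootstrap draws are heavy-tailed)
    rng = np.random.default_rng(seed)
    boots = np.empty(reps)
    for i in range(reps):
        rs = rng.normal(ratios, s_ratio)
        hs = phi * _silverman_bandwidth(rs)
        boots[i] = _kde_mode(rs, weights, hs, grid_size)
    se = float(1.4826 * np.median(np.abs(boots - np.median(boots))))
    return MRResult(key, L, b, se, p_value(b, se, L, key), L - 1)


def max_likelihood(dataset, tol: float = 1e-10) -> MRResult:
    """Joint-likelihood estimate of the causal slope.

    Model: beta_exp_j ~ N(xi_j, se_exp_j^2) and beta_out_j ~
    N(theta*xi_j, se_out_j^2) independently; the likelihood is maximised
    over (xi_1..xi_L, theta).  The per-SNP means have a closed form given
    theta, so theta is found on the profile objective (initialised from
    the IVW estimate); the se comes from the observed information of the
    full parameter vector.
    """
    bx, sx, by, sy = _arrays(dataset)
    L = bx.size
    if L < 2:
        raise ValueError("max_likelihood needs >= 2 SNPs")
    wx, wy = sx ** -2.0, sy ** -2.0

    def xi_hat(theta):
        return (bx * wx + theta * by * wy) / (wx + theta ** 2 * wy)

    def nll(theta):
        xi = xi_hat(theta)
        return 0.5 * float(np.sum(wx * (bx - xi) ** 2) + np.sum(wy * (by - theta * xi) ** 2))

    b0, _, _ = _ivw_core(bx, by, sy)
    span = 5.0 * (1.0 + abs(b0))
    res = optimize.minimize_scalar(nll, bounds=(b0 - span, b0 + span),
                                   method="bounded",
                                   options={"xatol": tol, "maxiter": 500})
    if not res.success:
        raise RuntimeError(f"maximum-likelihood optimisation failed: {res.message}")
    theta = float(res.x)

    # observed information of (theta, xi): se_theta via the Schur complement
    xi = xi_hat(theta)
    info_tt = float(np.sum(wy * xi ** 2))
    cross = (2.0 * theta * xi - by) * wy
    diag = wx + theta ** 2 * wy
    denom = info_tt - float(np.sum(cross ** 2 / diag))
    if denom <= 0:
        raise RuntimeError("observed information not positive definite at the optimum")
    se = denom ** -0.5
    return MRResult("max_likelihood", L, theta, se,
                    p_value(theta, se, L, "max_likelihood"), "normal")


def _run_one(dataset, spec: MethodSpec):
    key = _method_key(spec.name)
    opts = dict(spec.options)
    if key == "wald_ratio":
        bx, sx, by, sy = _arrays(dataset)
        return wald_ratio(bx[0], sx[0], by[0], sy[0])
    if key in ("ivw", "ivw_fe", "ivw_mre"):
        variant = {"ivw": "default", "ivw_fe": "fe", "ivw_mre": "mre"}[key]
        return ivw(dataset, variant)
    if key in ("mr_egger", "mr_egger_bootstrap"):
        slope, _ = egger(dataset, bootstrap=(key == "mr_egger_bootstrap"),
                         reps=opts.get("reps", 1000), seed=spec.seed)
        return slope
    if key in ("simple_median", "weighted_median", "penalised_weighted_median"):
        variant = {"simple_median": "simple", "weighted_median": "weighted",
                   "penalised_weighted_median": "penalised"}[key]
        return median_estimator(dataset, variant, reps=opts.get("reps", 1000),
                                seed=spec.seed,
                                penalty_scale=opts.get("penalty_scale", 20.0))
    if key in ("simple_mode", "weighted_mode", "simple_mode_nome", "weighted_mode_nome"):
        variant = "simple" if key.startswith("simple") else "weighted"
        return mode_estimator(dataset, variant, nome=key.endswith("nome"),
                              phi=opts.get("phi", 1.0), reps=opts.get("reps", 1000),
                              seed=spec.seed, grid_size=opts.get("grid_size", 1000))
    if key == "max_likelihood":
        return max_likelihood(dataset)
    raise ValueError(f"unknown MR method: {spec.name!r}")


_MIN_SNPS = {"wald_ratio": 1, "ivw": 2, "ivw_fe": 2, "ivw_mre": 2,
             "max_likelihood": 2, "mr_egger": 3, "mr_egger_bootstrap": 3,
             "simple_median": 3, "weighted_median": 3,
             "penalised_weighted_median": 3, "simple_mode": 3,
             "weighted_mode": 3, "simple_mode_nome": 3, "weighted_mode_nome": 3}


def run_mr(dataset, methods: Optional[Sequence] = None, seed: int = 0,
           log: Optional[list] = None) -> list:
    """Run a battery of MR methods on a harmonised dataset.

    ``methods`` is a sequence of method names or :class:`MethodSpec`;
    the default battery is Wald ratio, MR-Egger, weighted median, IVW and
    weighted mode.  With exactly one kept SNP only the Wald ratio runs,
    whatever was requested; with several, per-SNP methods are skipped.
    Methods whose minimum SNP count is not met are skipped with a log
    note.  Raises when no SNPs are kept.
    """
    L = dataset.n_kept
    if L == 0:
        raise ValueError("no SNPs kept in the harmonised dataset")
    specs = [m if isinstance(m, MethodSpec) else MethodSpec(str(m), seed=seed)
             for m in (methods if methods is not None else DEFAULT_METHODS)]
    if L == 1:
        return [_run_one(dataset, MethodSpec("wald_ratio", seed=seed))]
    results = []
    for spec in specs:
        key = _method_key(spec.name)
        if key == "wald_ratio":
            continue  # single-instrument method; not applicable to L > 1
        if L < _MIN_SNPS[key]:
            if log is not None:
                log.append(f"skipped {key}: needs >= {_MIN_SNPS[key]} SNPs, have {L}")
            continue
        results.append(_run_one(dataset, spec))
    if not results:
        raise ValueError("no applicable MR method for this dataset")
    return results
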