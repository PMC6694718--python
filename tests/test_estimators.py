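"""Estimator suite: worked-example numbers, independent oracles, and
structural invariants (scale equivariance, orientation, dispersion floor)."""

import numpy as np
import pytest
from scipy import stats

from mrkit import (MethodSpec, beta_to_or, egger, ivw, max_likelihood,
                   median_estimator, mode_estimator, p_value, run_mr,
                   wald_ratio)
from mrkit.estimators import _kde_mode, _silverman_bandwidth, _weighted_median

from conftest import make_dataset


def random_dataset(rng, L, theta=0.5, noise=True):
    bx = rng.uniform(0.05, 0.3, L) * rng.choice([-1, 1], L)
    sx = rng.uniform(0.003, 0.01, L)
    sy = rng.uniform(0.01, 0.08, L)
    by = theta * bx + (rng.normal(0, sy) if noise else 0.0)
    return make_dataset(bx, sx, by, sy)


# ---------------------------------------------------------------- Wald ratio

def test_wald_ratio_unit_exposure():
    res = wald_ratio(1.0, 0.01, 0.5663, 0.0905)
    assert res.b == pytest.approx(0.5663)
    assert res.se == pytest.approx(0.0905)


def test_wald_ratio_scaling():
    res = wald_ratio(2.0, 0.01, 1.0, 0.2)
    assert res.b == pytest.approx(0.5) and res.se == pytest.approx(0.1)


def test_wald_ratio_zero_exposure_is_error():
    with pytest.raises(ValueError, match="undefined ratio"):
        wald_ratio(0.0, 0.01, 0.1, 0.01)


def test_wald_se_against_monte_carlo_ratio_oracle():
    """First-order se agrees with the simulated ratio sd when the
    exposure effect is well measured (se_x/bx small)."""
    bx, sx, by, sy = 0.1, 0.01, 0.02, 0.01
    res = wald_ratio(bx, sx, by, sy)
    rng = np.random.default_rng(0)
    draws = rng.normal(by, sy, 10 ** 6) / rng.normal(bx, sx, 10 ** 6)
    mc_sd = np.std(draws)
    # second-order band: sqrt(sy^2/bx^2 + by^2 sx^2 / bx^4)
    second = np.sqrt(sy ** 2 / bx ** 2 + by ** 2 * sx ** 2 / bx ** 4)
    assert mc_sd == pytest.approx(second, rel=0.05)
    assert res.se == pytest.approx(mc_sd, rel=0.06)


# ----------------------------------------------------------------------- IVW

def test_ivw_two_identical_snps_equal_wald():
    ds = make_dataset([0.1, 0.1], [0.01, 0.01], [0.05, 0.05], [0.02, 0.02])
    assert ivw(ds).b == pytest.approx(0.5)


def test_ivw_matches_wls_oracle(rng):
    import statsmodels.api as sm
    for _ in range(50):
        ds = random_dataset(rng, int(rng.integers(3, 20)))
        bx, sx, by, sy = ds.arrays()
        fit = sm.WLS(by, bx[:, None], weights=sy ** -2).fit()
        res = ivw(ds, "fe")
        assert res.b == pytest.approx(fit.params[0], abs=1e-10)
        # statsmodels' se includes the residual dispersion: rescale to unit
        se_unit = fit.bse[0] / np.sqrt(fit.mse_resid)
        assert res.se == pytest.approx(se_unit, abs=1e-10)


def test_ivw_variants_dispersion_floor(rng):
    for _ in range(20):
        ds = random_dataset(rng, 10)
        default = ivw(ds, "default")
        fe = ivw(ds, "fe")
        mre = ivw(ds, "mre")
        assert default.se >= fe.se - 1e-15  # max(1, sigma) floor
        assert default.se == pytest.approx(max(fe.se, mre.se), abs=1e-15)
        assert default.b == fe.b == mre.b


def test_ivw_single_snp_directs_to_wald():
    ds = make_dataset([0.1], [0.01], [0.05], [0.02])
    with pytest.raises(ValueError, match="wald_ratio"):
        ivw(ds)


# ------------------------------------------------------------------ MR-Egger

def test_egger_exact_fit_recovers_intercept_and_slope():
    bx = np.array([0.05, 0.1, 0.2, 0.3])
    c, theta = 0.02, 0.4
    by = c + theta * bx
    ds = make_dataset(bx, 0.005, by, 0.02)
    slope, intercept = egger(ds)
    assert slope.b == pytest.approx(theta, abs=1e-12)
    assert intercept.intercept == pytest.approx(c, abs=1e-12)


def test_egger_matches_wls_oracle(rng):
    import statsmodels.api as sm
    for _ in range(50):
        ds = random_dataset(rng, int(rng.integers(3, 20)))
        bx, sx, by, sy = ds.arrays()
        sgn = np.where(bx < 0, -1.0, 1.0)
        bxo, byo = bx * sgn, by * sgn
        X = sm.add_constant(bxo)
        fit = sm.WLS(byo, X, weights=sy ** -2).fit()
        slope, intercept = egger(ds)
        assert slope.b == pytest.approx(fit.params[1], abs=1e-10)
        assert intercept.intercept == pytest.approx(fit.params[0], abs=1e-10)
        scale = max(1.0, np.sqrt(fit.mse_resid)) / np.sqrt(fit.mse_resid)
        assert slope.se == pytest.approx(fit.bse[1] * scale, abs=1e-10)


def test_egger_sign_invariance(rng):
    """Negating (beta_exp, beta_out) for any SNP leaves the fit unchanged."""
    ds = random_dataset(rng, 8)
    bx, sx, by, sy = ds.arrays()
    flip = rng.random(8) < 0.5
    s = np.where(flip, -1.0, 1.0)
    ds2 = make_dataset(bx * s, sx, by * s, sy)
    a, b = egger(ds), egger(ds2)
    assert a[0].b == pytest.approx(b[0].b, abs=1e-12)
    assert a[1].intercept == pytest.approx(b[1].intercept, abs=1e-12)


def test_egger_collinear_is_error():
    ds = make_dataset([0.1, 0.1, 0.1], 0.01, [0.05, 0.06, 0.04], 0.02)
    with pytest.raises(ValueError, match="unidentifiable"):
        egger(ds)


def test_egger_min_snps():
    ds = make_dataset([0.1, 0.2], 0.01, [0.05, 0.1], 0.02)
    with pytest.raises(ValueError, match=">= 3"):
        egger(ds)


def test_egger_bootstrap_se_close_to_analytic(rng):
    ds = random_dataset(rng, 30, noise=True)
    analytic, _ = egger(ds)
    boot, _ = egger(ds, bootstrap=True, reps=400, seed=7)
    assert boot.b == analytic.b
    assert boot.se == pytest.approx(analytic.se, rel=0.5)


# -------------------------------------------------------------------- median

def test_simple_median_odd_n():
    ds = make_dataset(np.ones(5), 0.001, [1.0, 2.0, 3.0, 4.0, 5.0], 0.1)
    assert median_estimator(ds, "simple", reps=10).b == pytest.approx(3.0)


def test_weighted_median_weight_concentration():
    ds = make_dataset(np.ones(4), 0.001, [1.0, 2.0, 3.0, 9.0],
                      [100.0, 100.0, 100.0, 1e-4])
    assert median_estimator(ds, "weighted", reps=10).b == pytest.approx(9.0, abs=1e-6)


def _median_scan_oracle(ratios, weights):
    """Independent cumulative-weight scan with linear interpolation."""
    pairs = sorted(zip(ratios, weights))
    total = sum(w for _, w in pairs)
    acc = 0.0
    prev_q, prev_r = None, None
    for r, w in pairs:
        q = (acc + 0.5 * w) / total
        if q >= 0.5:
            if prev_q is None:
                return r
            return prev_r + (r - prev_r) * (0.5 - prev_q) / (q - prev_q)
        acc += w
        prev_q, prev_r = q, r
    return pairs[-1][0]


def test_weighted_median_matches_scan_oracle(rng):
    for _ in range(50):
        L = int(rng.integers(3, 15))
        ratios = rng.normal(size=L)
        weights = rng.uniform(0.1, 5, L)
        assert _weighted_median(ratios, weights) == pytest.approx(
            _median_scan_oracle(list(ratios), list(weights)), abs=1e-12)


def test_penalised_median_downweights_outlier(rng):
    bx = np.full(9, 0.2)
    by = 0.5 * 0.2 + rng.normal(0, 0.002, 9)
    by[0] = 0.2 * 3.0  # gross outlier ratio of 3
    ds = make_dataset(bx, 0.001, by, 0.002)
    pen = median_estimator(ds, "penalised", reps=10, seed=1)
    assert pen.b == pytest.approx(0.5, abs=0.05)


def test_median_min_snps():
    ds = make_dataset([0.1, 0.2], 0.01, [0.05, 0.1], 0.02)
    with pytest.raises(ValueError, match=">= 3"):
        median_estimator(ds)


# ---------------------------------------------------------------------- mode

def test_mode_point_mass_any_phi():
    ds = make_dataset([0.1, 0.2, 0.4], 0.001, [0.05, 0.1, 0.2], 0.01)
    for phi in (0.5, 1.0, 2.0):
        assert mode_estimator(ds, "simple", phi=phi, reps=5).b == pytest.approx(0.5, abs=1e-6)


def _kde_argmax_oracle(ratios, weights, h, grid_size=1000):
    lo, hi = min(ratios) - 3 * h, max(ratios) + 3 * h
    xs = np.linspace(lo, hi, grid_size)
    total = sum(weights)
    best_x, best_d = xs[0], -1.0
    for x in xs:
        d = sum(w / total * np.exp(-0.5 * ((x - r) / h) ** 2)
                for r, w in zip(ratios, weights))
        if d > best_d:
            best_x, best_d = x, d
    return best_x


def test_mode_largest_cluster_wins():
    bx = np.ones(4)
    by = np.array([0.2, 0.2, 0.2, 0.9])
    ds = make_dataset(bx, 0.001, by, 0.05)
    res = mode_estimator(ds, "simple", reps=5)
    ratios = by / bx
    h = _silverman_bandwidth(ratios)
    oracle = _kde_argmax_oracle(list(ratios), [1.0] * 4, h)
    grid_step = (ratios.max() - ratios.min() + 6 * h) / 999
    assert res.b == pytest.approx(oracle, abs=grid_step + 1e-12)
    assert abs(res.b - 0.2) < 3 * grid_step


def test_weighted_mode_follows_weight(rng):
    bx = np.ones(4)
    by = np.array([0.2, 0.2, 0.2, 0.9])
    # nearly all precision on the 0.9 SNP
    sy = np.array([5.0, 5.0, 5.0, 0.001])
    ds = make_dataset(bx, 0.001, by, sy)
    res = mode_estimator(ds, "weighted", reps=5)
    assert res.b == pytest.approx(0.9, abs=0.02)


def test_mode_matches_kde_oracle_random(rng):
    for _ in range(10):
        L = int(rng.integers(4, 12))
        ds = random_dataset(rng, L)
        bx, sx, by, sy = ds.arrays()
        ratios = by / bx
        weights = 1.0 / (sy ** 2 / bx ** 2 + by ** 2 * sx ** 2 / bx ** 4)
        h = _silverman_bandwidth(ratios)
        expected = _kde_argmax_oracle(list(ratios), list(weights), h, 500)
        got = _kde_mode(ratios, weights, h, 500)
        assert got == pytest.approx(expected, abs=1e-12)


def test_mode_bad_phi_is_error(small_dataset):
    with pytest.raises(ValueError, match="phi"):
        mode_estimator(small_dataset, phi=0.0)


# ---------------------------------------------------------- maximum likelihood

def test_ml_recovers_exact_truth():
    bx = np.array([0.1, 0.2, 0.3, 0.15])
    ds = make_dataset(bx, 0.01, 0.4 * bx, 0.02)
    assert max_likelihood(ds).b == pytest.approx(0.4, abs=1e-6)


def test_ml_approaches_ivw_as_exposure_error_vanishes(rng):
    ds = random_dataset(rng, 10)
    bx, sx, by, sy = ds.arrays()
    tiny = make_dataset(bx, 1e-8, by, sy)
    assert max_likelihood(tiny).b == pytest.approx(ivw(tiny, "fe").b, abs=1e-5)


def test_ml_two_snp_matches_grid_search_oracle():
    bx = np.array([0.1, 0.25])
    by = np.array([0.06, 0.11])
    sx, sy = np.array([0.02, 0.02]), np.array([0.03, 0.03])
    ds = make_dataset(bx, sx, by, sy)

    def nll(theta, xi):
        return (np.sum((bx - xi) ** 2 / sx ** 2)
                + np.sum((by - theta * xi) ** 2 / sy ** 2))

    thetas = np.linspace(-1, 2, 601)
    best = None
    for theta in thetas:  # profile xi on a fine inner grid around bx
        xi_grid = [np.linspace(b - 0.1, b + 0.1, 401) for b in bx]
        xi_best = [g[np.argmin((bx[i] - g) ** 2 / sx[i] ** 2
                               + (by[i] - theta * g) ** 2 / sy[i] ** 2)]
                   for i, g in enumerate(xi_grid)]
        val = nll(theta, np.array(xi_best))
        if best is None or val < best[1]:
            best = (theta, val)
    res = max_likelihood(ds)
    assert res.b == pytest.approx(best[0], abs=(thetas[1] - thetas[0]))


# ------------------------------------------------------------------- p-values

@pytest.mark.parametrize("b,se,nsnp,method,expected,rel", [
    # worked-example statistics, printed to 4 significant digits
    (0.5663, 0.0905, 157, "ivw", 3.924e-10, 0.05),
    (0.9711, 0.2917, 157, "mr_egger", 0.001091, 0.05),
    (0.571, 0.07664, 157, "weighted_median", 9.226e-14, 0.05),
    (0.571, 0.1744, 157, "weighted_mode", 0.00131, 0.05),
])
def test_p_value_conventions_reproduce_worked_example(b, se, nsnp, method, expected, rel):
    """The per-method normal/t conventions reproduce the published
    p-values to within the rounding of the printed b and se."""
    assert p_value(b, se, nsnp, method) == pytest.approx(expected, rel=rel)


def test_p_value_zero_beta_is_one():
    assert p_value(0.0, 0.1, 10, "ivw") == pytest.approx(1.0)
    assert p_value(0.0, 0.1, 10, "mr_egger") == pytest.approx(1.0)


def test_p_value_df_guard():
    with pytest.raises(ValueError, match="df"):
        p_value(0.1, 0.1, 2, "mr_egger")  # df = 0


def test_p_value_distribution_families():
    b, se, n = 0.3, 0.1, 12
    assert p_value(b, se, n, "ivw") == pytest.approx(2 * stats.norm.sf(3.0))
    assert p_value(b, se, n, "mr_egger") == pytest.approx(2 * stats.t.sf(3.0, 10))
    assert p_value(b, se, n, "weighted_mode") == pytest.approx(2 * stats.t.sf(3.0, 11))


# ------------------------------------------------------------------ OR scale

@pytest.mark.parametrize("b,se,expected", [
    (0.5663, 0.0905, (1.76, 1.48, 2.10)),
    (0.9711, 0.2917, (2.64, 1.49, 4.68)),
])
def test_beta_to_or_worked_example(b, se, expected):
    or_, lo, hi = beta_to_or(b, se)
    assert round(or_, 2) == pytest.approx(expected[0], abs=0.011)
    assert round(lo, 2) == pytest.approx(expected[1], abs=0.011)
    assert round(hi, 2) == pytest.approx(expected[2], abs=0.011)


def test_beta_to_or_null_symmetric():
    or_, lo, hi = beta_to_or(0.0, 0.25)
    assert or_ == 1.0
    assert lo * hi == pytest.approx(1.0)


# ------------------------------------------------------------ run_mr battery

def test_run_mr_single_snp_forces_wald():
    ds = make_dataset([0.1], [0.01], [0.05], [0.02])
    res = run_mr(ds, methods=["ivw", "mr_egger", "weighted_median"])
    assert len(res) == 1 and res[0].method == "wald_ratio"


def test_run_mr_default_battery(small_dataset):
    res = run_mr(small_dataset, seed=1)
    assert [r.method for r in res] == ["mr_egger", "weighted_median", "ivw",
                                       "weighted_mode"]
    assert all(r.nsnp == small_dataset.n_kept for r in res)


def test_run_mr_methodspec_options(small_dataset):
    spec = MethodSpec("weighted_median", options={"reps": 50}, seed=3)
    res = run_mr(small_dataset, [spec])
    assert res[0].method == "weighted_median"


def test_run_mr_simulation_truth_recovery():
    """On a clean 100-SNP simulated dataset all default multi-SNP methods
    land near the true effect."""
    from mrkit import SimConfig, harmonise_datasets, simulate_two_sample
    exp, out, truth = simulate_two_sample(SimConfig(L=100, seed=11,
                                                    frac_palindromic=0.0))
    ds = harmonise_datasets(exp, out)
    for res in run_mr(ds, seed=11):
        assert res.b == pytest.approx(0.2, abs=4 * res.se)


# ------------------------------------------------------------ equivariance

def test_scale_equivariance(rng):
    ds = random_dataset(rng, 12)
    bx, sx, by, sy = ds.arrays()
    c = 3.5
    scaled_out = make_dataset(bx, sx, c * by, c * sy)
    scaled_exp = make_dataset(c * bx, c * sx, by, sy)
    for variant in ("default", "fe", "mre"):
        base = ivw(ds, variant)
        up = ivw(scaled_out, variant)
        down = ivw(scaled_exp, variant)
        assert up.b == pytest.approx(c * base.b, rel=1e-10)
        assert up.se == pytest.approx(c * base.se, rel=1e-10)
        assert down.b == pytest.approx(base.b / c, rel=1e-10)
    s0, i0 = egger(ds)
    s1, i1 = egger(scaled_out)
    assert s1.b == pytest.approx(c * s0.b, rel=1e-10)
    assert i1.intercept == pytest.approx(c * i0.intercept, rel=1e-10)
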