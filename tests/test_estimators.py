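import numpy as np
import pytest

from covgraph import estimators as est
from covgraph.graphs import make_chain_graph, make_hub_graph, make_scale_free_graph, graph_stats
from covgraph.synthetic import correlation_from_graph, sample_covariance, sample_data


@pytest.fixture(scope="module")
def chain_data():
    g = make_chain_graph(20)
    model = correlation_from_graph(g, w=0.5, eps=0.1)
    X = sample_data(model, 500, seed=77).X
    return g, model, X


# ---------------------------------------------------------------------------
# hard thresholding

def test_threshold_zero_keeps_everything(chain_data):
    _, _, X = chain_data
    S = X.T @ X / len(X)
    rec = est.hard_threshold(S, 0.0)
    assert rec.graph.n_edges == 20 * 19 // 2


def test_threshold_above_max_gives_empty(chain_data):
    _, _, X = chain_data
    S = X.T @ X / len(X)
    iu = np.triu_indices(20, 1)
    rec = est.hard_threshold(S, np.abs(S[iu]).max())
    assert rec.graph.n_edges == 0


def test_threshold_recovers_star_between_magnitudes():
    g = make_hub_graph(3, 1)
    model = correlation_from_graph(g, w=0.7, eps=0.2)
    C = model.C
    hi = min(abs(C[0, 1]), abs(C[0, 2]))
    lo = abs(C[1, 2])
    d = (hi + lo) / 2
    rec = est.hard_threshold(C, d)
    assert np.array_equal(rec.graph.adjacency != 0, g.adjacency != 0)


def test_threshold_monotone_nesting(chain_data):
    _, _, X = chain_data
    S = X.T @ X / len(X)
    e1 = est.hard_threshold(S, 0.1).graph.edge_mask
    e2 = est.hard_threshold(S, 0.3).graph.edge_mask
    assert np.all(e2 <= e1)


def test_threshold_rejects_negative():
    with pytest.raises(ValueError):
        est.hard_threshold(np.eye(3), -0.1)


# ---------------------------------------------------------------------------
# scale-free criterion

def test_power_law_fit_recovers_its_own_model():
    """Degree counts fabricated from P(k) = b k^-2.5 give a perfect fit."""
    ks = np.arange(1, 9)
    counts = np.round(2000 * ks**-2.5).astype(int)  # exact power-law bins
    degrees = np.repeat(ks, counts)
    fit = est._degree_distribution_fit(degrees, 0.0)
    # counts are rounded so the fit is near- but not exactly perfect
    assert fit.R2 > 0.99
    assert fit.gamma_hat == pytest.approx(2.5, abs=0.1)


def test_regular_graph_fit_is_missing():
    degrees = np.full(30, 2)
    fit = est._degree_distribution_fit(degrees, 0.0)
    assert not fit.valid


def test_scale_free_adjacency_fits_power_law():
    hits = 0
    for s in range(10):
        g = make_scale_free_graph(500, seed=s)
        scan = est.scale_free_scan(g.adjacency, [0.5])
        f = scan[0]
        if f.valid and f.gamma_hat > 0 and f.R2 > 0.8:
            hits += 1
    assert hits >= 8


def test_select_threshold_single_qualifier():
    fits = [
        est.ScaleFreeFit(0.2, 0.5, 1.0, 0.0, 3.0, 5),
        est.ScaleFreeFit(0.4, 0.9, 1.5, 0.0, 2.0, 5),
        est.ScaleFreeFit(0.6, 0.7, 1.0, 0.0, 1.0, 5),
    ]
    assert est.select_threshold_scale_free(fits, r2_min=0.8) == 0.4


def test_select_threshold_lowest_mean_degree_ties_to_smallest_d():
    fits = [
        est.ScaleFreeFit(0.3, 0.9, 1.0, 0.0, 2.0, 4),
        est.ScaleFreeFit(0.5, 0.9, 1.0, 0.0, 2.0, 4),
    ]
    assert est.select_threshold_scale_free(fits) == 0.3


def test_select_threshold_no_qualifier_raises():
    fits = [est.ScaleFreeFit(0.3, 0.4, 1.0, 0.0, 2.0, 5)]
    with pytest.raises(ValueError, match="0.4"):
        est.select_threshold_scale_free(fits, r2_min=0.8)


# ---------------------------------------------------------------------------
# lasso regression

def test_lasso_zero_penalty_is_ols(rng):
    Z = rng.standard_normal((50, 5))
    y = Z @ np.array([1.0, -2.0, 0.5, 0.0, 3.0]) + 0.01 * rng.standard_normal(50)
    beta = est.lasso_regression(y, Z, 0.0)
    ols, *_ = np.linalg.lstsq(Z, y, rcond=None)
    assert np.allclose(beta, ols)


def test_lasso_lambda_max_zeroes_solution(rng):
    Z = rng.standard_normal((50, 8))
    y = rng.standard_normal(50)
    lam_max = np.max(np.abs(2 * Z.T @ y / 50))
    beta = est.lasso_regression(y, Z, lam_max * 1.001)
    assert np.all(beta == 0)


def test_lasso_orthonormal_design_soft_threshold(rng):
    n = 400
    Z, _ = np.linalg.qr(rng.standard_normal((n, 6)))
    Z *= np.sqrt(n)  # Z^T Z / n = I
    y = Z @ np.array([2.0, -1.0, 0.5, 0.05, 0.0, -0.3])
    lam = 0.6
    beta = est.lasso_regression(y, Z, lam)
    ols = Z.T @ y / n
    oracle = np.sign(ols) * np.maximum(np.abs(ols) - lam / 2, 0.0)
    assert np.allclose(beta, oracle, atol=1e-10)


def test_lasso_kkt_conditions(rng):
    """|(2/n) Z^T(y - Z beta)| = lam*w on the active set, <= lam*w off it."""
    Z = rng.standard_normal((80, 10))
    y = rng.standard_normal(80)
    lam = 0.2
    beta = est.lasso_regression(y, Z, lam, tol=1e-10)
    grad = 2 * Z.T @ (y - Z @ beta) / 80
    active = beta != 0
    assert np.allclose(np.abs(grad[active]), lam, atol=1e-4)
    assert np.all(np.abs(grad[~active]) <= lam + 1e-4)


def test_weighted_lasso_infinite_weight_forces_zero(rng):
    Z = rng.standard_normal((60, 4))
    y = Z @ np.array([1.0, 1.0, 1.0, 1.0])
    w = np.array([1.0, np.inf, 1.0, 1.0])
    beta = est.lasso_regression(y, Z, 0.1, weights=w)
    assert beta[1] == 0.0
    assert np.any(beta != 0)


def test_weighted_lasso_kkt_with_weights(rng):
    Z = rng.standard_normal((100, 6))
    y = rng.standard_normal(100)
    w = rng.uniform(0.5, 2.0, 6)
    lam = 0.15
    beta = est.lasso_regression(y, Z, lam, weights=w, tol=1e-10)
    grad = 2 * Z.T @ (y - Z @ beta) / 100
    active = beta != 0
    assert np.allclose(np.abs(grad[active]), lam * w[active], atol=1e-4)
    assert np.all(np.abs(grad[~active]) <= lam * w[~active] + 1e-4)


# ---------------------------------------------------------------------------
# nodewise regression

def test_nodewise_coefficients_match_precision_ratios():
    """beta^i_j -> Theta_ij / Theta_ii on large-n data at tiny penalty."""
    g = make_chain_graph(10)
    model = correlation_from_graph(g, w=0.5, eps=0.1)
    X = sample_data(model, 10_000, seed=3).X
    Theta = np.linalg.inv(model.C)
    rec = est.nodewise_lasso(X, 1e-4)
    B = rec.meta["B"]
    for i in range(10):
        for j in range(10):
            if i != j and abs(Theta[i, j]) > 0.05:
                expected = -Theta[i, j] / Theta[i, i]
                assert B[i, j] == pytest.approx(expected, rel=0.05)


def test_nodewise_empty_above_lambda_max(chain_data):
    _, _, X = chain_data
    lam = est.lambda_max_nodewise(X)
    rec = est.nodewise_lasso(X, lam * 1.01)
    assert rec.graph.n_edges == 0


def test_and_rule_nested_in_or_rule(chain_data):
    _, _, X = chain_data
    X30 = X[:30]
    for lam in (0.05, 0.2, 0.5):
        e_and = est.nodewise_lasso(X30, lam, rule="and").graph.edge_mask
        e_or = est.nodewise_lasso(X30, lam, rule="or").graph.edge_mask
        assert np.all(e_and <= e_or)


def test_nodewise_path_matches_single_fits(chain_data):
    _, _, X = chain_data
    grid = np.geomspace(0.02, 0.8, 5)
    B = est.nodewise_lasso_path(X, grid)
    for gi in (0, 4):
        single = est.nodewise_lasso(X, grid[gi]).meta["B"]
        assert np.array_equal(B[gi] != 0, single != 0)


# ---------------------------------------------------------------------------
# covariance lasso

def test_covariance_lasso_zero_penalty_returns_sample_covariance(chain_data):
    _, _, X = chain_data
    S = X.T @ X / len(X)  # p=20 < n=500: PD
    rec = est.covariance_lasso(S, 0.0, n_samples=len(X), n_mm_steps=10, max_inner=3000)
    # the unpenalised minimiser is S itself; first-order solver gets close
    assert np.max(np.abs(rec.estimate - S)) < 5e-3
    obj_S = est._cov_lasso_objective(S, S, 0.0, np.zeros_like(S))
    obj_fit = rec.meta["objective"][-1]
    assert obj_fit <= obj_S + 1e-4


def test_covariance_lasso_large_penalty_is_diagonal(chain_data):
    _, _, X = chain_data
    S = X.T @ X / len(X)
    rec = est.covariance_lasso(S, 10.0, n_samples=len(X))
    off = ~np.eye(20, dtype=bool)
    assert np.all(rec.estimate[off] == 0)


def test_covariance_lasso_mm_objective_monotone(chain_data):
    _, _, X = chain_data
    S = X.T @ X / len(X)
    rec = est.covariance_lasso(S, 0.3, n_samples=len(X), n_mm_steps=8)
    objs = rec.meta["objective"]
    assert len(objs) >= 3
    assert all(b <= a + 1e-9 for a, b in zip(objs, objs[1:]))


def test_covariance_lasso_output_is_pd(chain_data):
    _, _, X = chain_data
    X30 = X[:15]  # p > n regime
    S = X30.T @ X30 / 15
    rec = est.covariance_lasso(S, 0.5, n_samples=15)
    assert np.linalg.eigvalsh(rec.estimate)[0] > 0
    assert rec.meta["s_reg"] > 0  # ridge engaged for rank-deficient input


def test_covariance_lasso_support_contains_true_edges():
    g = make_hub_graph(3, 1)
    model = correlation_from_graph(g, w=0.7, eps=0.2)
    hits = 0
    for s in range(20):
        X = sample_data(model, 500, seed=s).X
        S = X.T @ X / 500
        rec = est.covariance_lasso(S, 0.25, n_samples=500)
        mask = rec.graph.edge_mask
        if mask[0] and mask[1]:  # pairs (0,1) and (0,2) in triu order
            hits += 1
    assert hits >= 18


def test_cv_covariance_lasso_single_grid_point(chain_data):
    _, _, X = chain_data
    lam, curve = est.cv_covariance_lasso(X[:40], np.array([0.3]), K=4, seed=0)
    assert lam == 0.3 and len(curve) == 1


def test_cv_covariance_lasso_deterministic(chain_data):
    _, _, X = chain_data
    grid = np.array([0.2, 0.5, 0.9])
    a = est.cv_covariance_lasso(X[:40], grid, K=4, seed=11)
    b = est.cv_covariance_lasso(X[:40], grid, K=4, seed=11)
    assert a[0] == b[0] and np.allclose(a[1], b[1])


# ---------------------------------------------------------------------------
# graphical lasso

def test_glasso_identity_input_gives_diagonal():
    rec = est.graphical_lasso(np.eye(8), 0.2)
    off = ~np.eye(8, dtype=bool)
    assert np.all(np.abs(rec.estimate[off]) < 1e-10)


def test_glasso_large_penalty_diagonal(chain_data):
    _, _, X = chain_data
    S = X.T @ X / len(X)
    rec = est.graphical_lasso(S, 5.0)
    assert rec.graph.n_edges == 0
    # diagonal stationarity of the penalised likelihood: Sigma_ii = S_ii
    assert np.allclose(np.diag(rec.meta["covariance"]), np.diag(S), rtol=1e-3)


def test_glasso_output_symmetric_pd(chain_data):
    _, _, X = chain_data
    X30 = X[:30]
    S = X30.T @ X30 / 30
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)
    for lam in (0.1, 0.3, 0.6):
        rec = est.graphical_lasso(R, lam)
        assert np.allclose(rec.estimate, rec.estimate.T)
        assert np.linalg.eigvalsh(rec.estimate)[0] > 0


def test_glasso_stationarity_kkt(chain_data):
    """Independent optimality check: Sigma_hat - S acts like lam * sign."""
    _, _, X = chain_data
    S = X.T @ X / len(X)
    lam = 0.15
    rec = est.graphical_lasso(S, lam, tol=1e-8, max_iter=500)
    Theta = rec.estimate
    W = np.linalg.inv(Theta)  # fitted covariance
    grad = W - S  # d/dTheta [logdet - tr(S Theta)] = Theta^-1 - S
    off = ~np.eye(len(S), dtype=bool)
    active = (Theta != 0) & off
    # on active off-diagonals the gradient matches lam * sign(Theta)
    assert np.allclose(grad[active], lam * np.sign(Theta[active]), atol=1e-2)
    inactive = (Theta == 0) & off
    assert np.all(np.abs(grad[inactive]) <= lam + 1e-2)


# ---------------------------------------------------------------------------
# adaptive lasso

@pytest.fixture(scope="module")
def adaptive_fit(chain_data):
    _, _, X = chain_data
    return est.adaptive_lasso(X[:60], K=5, seed=5), X[:60]


def test_adaptive_support_nested_in_stage1(adaptive_fit):
    rec, _ = adaptive_fit
    s1 = rec.meta["graph_stage1"].edge_mask
    s2 = rec.graph.edge_mask
    assert np.all(s2 <= s1)


def test_adaptive_stage1_zero_forces_final_zero(adaptive_fit):
    rec, _ = adaptive_fit
    B1, B2 = rec.meta["B_stage1"], rec.meta["B"]
    assert np.all(B2[B1 == 0] == 0)


def test_adaptive_sparser_than_cv_nodewise(adaptive_fit):
    rec, X = adaptive_fit
    lam1 = rec.meta["lambda_stage1"]
    nodewise_cv = est.nodewise_lasso(X, lam1)
    assert rec.graph.n_edges <= nodewise_cv.graph.n_edges
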