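import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tosccamm import (
    LongitudinalView,
    PairedLongitudinalData,
    TrajectorySpec,
    deflate,
    fit_tosccamm,
    nipals_component,
    soft_threshold_topk,
)

PASS = TrajectorySpec("passthrough")


# ---------------------------------------------------------------------------
# independent oracle: plain sparse-CCA NIPALS loop (no trajectories), coded
# from scratch with its own thresholding
# ---------------------------------------------------------------------------
def _topk_oracle(w, k):
    a = np.abs(w)
    lam = 0.0 if k == len(w) else np.sort(a)[::-1][k]
    out = np.sign(w) * np.clip(a - lam, 0.0, None)
    n = np.sqrt((out**2).sum())
    return out / n if n > 0 else out


def _plain_sparse_cca(X, Y, init, px, qy, tol=1e-6, max_iter=100):
    def unit(v):
        return v / np.linalg.norm(v)

    def cor(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return a @ b / (np.linalg.norm(a) * np.linalg.norm(b))

    wx = unit(np.asarray(init, float))
    rho_prev, rho, n_it = 0.0, 0.0, 0
    for n_it in range(1, max_iter + 1):
        eta = unit(X @ wx)
        wy = _topk_oracle(Y.T @ eta, qy)
        gamma = unit(Y @ wy)
        wx = _topk_oracle(X.T @ gamma, px)
        eta = unit(X @ wx)
        rho = cor(eta, gamma)
        if abs(rho - rho_prev) <= tol:
            break
        rho_prev = rho
    return wx, wy, rho, n_it


class TestSoftThresholdTopk:
    def test_hand_computed_example(self):
        out = soft_threshold_topk(np.array([3.0, -2.0, 1.0, 0.5]), 2)
        np.testing.assert_allclose(out, np.array([2.0, -1.0, 0.0, 0.0]) / np.sqrt(5))

    def test_k_equal_length_keeps_direction(self):
        w = np.array([1.0, -4.0, 2.0])
        out = soft_threshold_topk(w, 3)
        np.testing.assert_allclose(out, w / np.linalg.norm(w))

    def test_zero_vector_flagged(self):
        with pytest.warns(UserWarning, match="degenerate"):
            out = soft_threshold_topk(np.zeros(3), 2)
        np.testing.assert_array_equal(out, np.zeros(3))

    @pytest.mark.parametrize("k", [0, 5])
    def test_invalid_k_rejected(self, k):
        with pytest.raises(ValueError):
            soft_threshold_topk(np.ones(4), k)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 30))
    def test_exact_cardinality_and_unit_norm(self, seed, p):
        # generic (tie-free) input: exactly k nonzeros, unit norm, support =
        # the k largest magnitudes
        rng = np.random.default_rng(seed)
        w = rng.standard_normal(p)
        k = int(rng.integers(1, p))
        out = soft_threshold_topk(w, k)
        assert np.count_nonzero(out) == k
        assert np.linalg.norm(out) == pytest.approx(1.0)
        top = set(np.argsort(-np.abs(w))[:k])
        assert set(np.flatnonzero(out)) == top

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 100.0))
    def test_positive_scale_equivariance(self, seed, c):
        rng = np.random.default_rng(seed)
        w = rng.standard_normal(8)
        np.testing.assert_allclose(
            soft_threshold_topk(c * w, 3), soft_threshold_topk(w, 3), atol=1e-10
        )


class TestDeflate:
    def test_orthogonality_and_idempotence(self):
        rng = np.random.default_rng(1)
        M = rng.standard_normal((15, 6))
        u = rng.standard_normal(15)
        u /= np.linalg.norm(u)
        D = deflate(M, u)
        assert np.max(np.abs(u @ D)) <= 1e-10
        np.testing.assert_allclose(deflate(D, u), D, atol=1e-12)

    def test_zero_matrix(self):
        u = np.array([1.0, 0.0])
        np.testing.assert_array_equal(deflate(np.zeros((2, 3)), u), np.zeros((2, 3)))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            deflate(np.zeros((3, 2)), np.ones(4))


def _pair_from(X, Y, ids, times):
    return PairedLongitudinalData(
        LongitudinalView(ids, times, X), LongitudinalView(ids, times, Y)
    )


class TestNipalsComponent:
    def test_self_correlation_limit(self):
        # X == Y, a single feature following an exact linear mixed model:
        # the component must correlate its two latent views almost perfectly
        rng = np.random.default_rng(0)
        n, m = 25, 6
        ids = np.repeat([f"i{j}" for j in range(n)], m)
        t = np.tile(np.arange(m, dtype=float), n)
        x = rng.normal(0, 1, n)[np.repeat(np.arange(n), m)] + 2.0 * t
        x = (x - x.mean()) / x.std(ddof=1)
        view = x.reshape(-1, 1)
        data = _pair_from(view, view.copy(), ids, t)
        spec = TrajectorySpec("random_intercept_linear")
        comp = nipals_component(data, 1, 1, spec, spec, rng=np.random.default_rng(1))
        assert abs(comp.rho) >= 0.99

    def test_matches_exhaustive_sparse_grid_search(self):
        # 4 individuals, single visit, p=q=2, 1-sparse weights: the optimum
        # over all unit-norm 1-sparse pairs is a finite grid we can enumerate
        rng = np.random.default_rng(6)
        n = 4
        z = rng.standard_normal(n)
        X = np.column_stack([z + 0.05 * rng.standard_normal(n), rng.standard_normal(n)])
        Y = np.column_stack([rng.standard_normal(n), z + 0.05 * rng.standard_normal(n)])
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        Y = (Y - Y.mean(0)) / Y.std(0, ddof=1)
        ids = np.array([f"i{j}" for j in range(n)], dtype=object)
        data = _pair_from(X, Y, ids, np.zeros(n))

        def cor(a, b):
            a = a - a.mean()
            b = b - b.mean()
            return a @ b / (np.linalg.norm(a) * np.linalg.norm(b))

        brute = max(abs(cor(X[:, j], Y[:, l])) for j in range(2) for l in range(2))
        comp = nipals_component(
            data, 1, 1, PASS, PASS, rng=np.random.default_rng(3), n_starts=5
        )
        assert abs(abs(comp.rho) - brute) < 1e-3

    def test_reduces_to_plain_sparse_cca(self):
        # one visit per individual + passthrough trajectories: the
        # longitudinal algorithm IS plain thresholded NIPALS
        rng = np.random.default_rng(8)
        n, p, q = 30, 6, 5
        z = rng.standard_normal(n)
        X = rng.standard_normal((n, p))
        Y = rng.standard_normal((n, q))
        X[:, :2] += 1.5 * z[:, None]
        Y[:, :2] += 1.5 * z[:, None]
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        Y = (Y - Y.mean(0)) / Y.std(0, ddof=1)
        ids = np.array([f"i{j}" for j in range(n)], dtype=object)
        data = _pair_from(X, Y, ids, np.zeros(n))
        init = rng.standard_normal(p)

        comp = nipals_component(data, 2, 2, PASS, PASS, init=init)
        wx_ref, wy_ref, rho_ref, _ = _plain_sparse_cca(X, Y, init, 2, 2)
        np.testing.assert_allclose(comp.wx, wx_ref, atol=1e-8)
        np.testing.assert_allclose(comp.wy, wy_ref, atol=1e-8)
        assert comp.rho == pytest.approx(rho_ref, abs=1e-8)

    def test_empty_view_rejected(self):
        X = np.zeros((0, 2))
        data = PairedLongitudinalData(
            LongitudinalView(np.array([], dtype=object), [], X),
            LongitudinalView(["a"], [0.0], np.ones((1, 2))),
        )
        with pytest.raises(ValueError, match="at least one row"):
            nipals_component(data, 1, 1, PASS, PASS, init=np.ones(2))

    def test_degenerate_zero_data_component(self):
        ids = np.array(["a", "b", "c"], dtype=object)
        data = _pair_from(np.zeros((3, 2)), np.zeros((3, 2)), ids, np.zeros(3))
        comp = nipals_component(data, 1, 1, PASS, PASS, init=np.array([1.0, 0.0]))
        assert comp.rho == 0.0 and not comp.converged

    def test_sparsity_bounds_validated(self):
        rng = np.random.default_rng(0)
        ids = np.array(["a", "b", "c"], dtype=object)
        data = _pair_from(rng.standard_normal((3, 2)), rng.standard_normal((3, 2)), ids, np.zeros(3))
        with pytest.raises(ValueError, match="sparsity"):
            nipals_component(data, 3, 1, PASS, PASS, init=np.ones(2))


class TestFitTosccamm:
    def test_exact_cardinality_on_simulated_signal(self, small_sim, cubic_spec):
        res = fit_tosccamm(small_sim.data, 2, [(10, 5), (7, 4)], cubic_spec, cubic_spec, seed=0)
        assert [np.count_nonzero(c.wx) for c in res.components] == [10, 7]
        assert [np.count_nonzero(c.wy) for c in res.components] == [5, 4]

    def test_latent_orthogonality_across_components(self, small_sim, cubic_spec):
        res = fit_tosccamm(small_sim.data, 3, [(10, 5)] * 3, cubic_spec, cubic_spec, seed=0)
        for a in range(3):
            for b in range(a + 1, 3):
                assert abs(res.components[a].eta @ res.components[b].eta) <= 1e-6
                assert abs(res.components[a].gamma @ res.components[b].gamma) <= 1e-6

    def test_prefix_stability(self, small_sim, cubic_spec):
        one = fit_tosccamm(small_sim.data, 1, [(10, 5)], cubic_spec, cubic_spec, seed=3)
        two = fit_tosccamm(small_sim.data, 2, [(10, 5)] * 2, cubic_spec, cubic_spec, seed=3)
        np.testing.assert_array_equal(one.components[0].wx, two.components[0].wx)
        np.testing.assert_array_equal(one.components[0].wy, two.components[0].wy)

    def test_seed_determinism_bit_for_bit(self, small_sim, cubic_spec):
        a = fit_tosccamm(small_sim.data, 2, [(10, 5)] * 2, cubic_spec, cubic_spec, seed=5)
        b = fit_tosccamm(small_sim.data, 2, [(10, 5)] * 2, cubic_spec, cubic_spec, seed=5)
        for ca, cb in zip(a.components, b.components):
            np.testing.assert_array_equal(ca.wx, cb.wx)
            np.testing.assert_array_equal(ca.wy, cb.wy)
            assert ca.rho == cb.rho

    def test_sequential_reduction_matches_plain_cca(self):
        # two components, single-visit data: sequential extraction with
        # deflation equals the independently coded plain loop run twice
        rng = np.random.default_rng(12)
        n, p, q = 40, 8, 6
        z1, z2 = rng.standard_normal((2, n))
        X = rng.standard_normal((n, p))
        Y = rng.standard_normal((n, q))
        X[:, 0:2] += 2.0 * z1[:, None]
        Y[:, 0:2] += 2.0 * z1[:, None]
        X[:, 4:6] += 1.2 * z2[:, None]
        Y[:, 3:5] += 1.2 * z2[:, None]
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        Y = (Y - Y.mean(0)) / Y.std(0, ddof=1)
        ids = np.array([f"i{j}" for j in range(n)], dtype=object)
        data = _pair_from(X, Y, ids, np.zeros(n))

        seed = 21
        res = fit_tosccamm(
            data, 2, [(2, 2)] * 2, PASS, PASS, seed=seed,
            standardize=False, n_starts=1,
        )
        # oracle: same init draws, plain loop + explicit deflation
        rng_init = np.random.default_rng(seed)
        Xd, Yd = X.copy(), Y.copy()
        for comp in res.components:
            init = rng_init.standard_normal(p)
            init /= np.linalg.norm(init)
            wx_ref, wy_ref, rho_ref, _ = _plain_sparse_cca(Xd, Yd, init, 2, 2)
            np.testing.assert_allclose(comp.wx, wx_ref, atol=1e-8)
            np.testing.assert_allclose(comp.wy, wy_ref, atol=1e-8)
            assert comp.rho == pytest.approx(rho_ref, abs=1e-8)
            eta = Xd @ wx_ref
            eta /= np.linalg.norm(eta)
            gamma = Yd @ wy_ref
            gamma /= np.linalg.norm(gamma)
            Xd = Xd - np.outer(eta, eta @ Xd)
            Yd = Yd - np.outer(gamma, gamma @ Yd)

    def test_result_serialization(self, tmp_path, small_sim, cubic_spec):
        res = fit_tosccamm(small_sim.data, 1, [(10, 5)], cubic_spec, cubic_spec, seed=0)
        res.write(tmp_path, small_sim.data)
        assert (tmp_path / "weights.csv").exists()
        assert (tmp_path / "scores.csv").exists()
        summary = (tmp_path / "summary.json").read_text()
        assert '"rho"' in summary
        wdf = res.weights_frame(
            small_sim.data.x_view.feature_names, small_sim.data.y_view.feature_names
        )
        assert len(wdf) == 15  # 10 + 5 nonzero weights, zeros omitted
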