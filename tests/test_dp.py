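"""Unit and property tests for the minimal-path dynamic programming core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octcap import (
    ControlPoint,
    DPParams,
    InfeasiblePathError,
    InputError,
    backtrack,
    build_cost,
    constrain_cost,
    extract_min_path,
    gradient_image,
    path_cost,
    propagate_front,
)


class TestGradientImage:
    def test_constant_image_has_zero_gradient(self):
        img = np.full((40, 6), 3.7)
        grad = gradient_image(img, sigma_um=9.0, pixel_um=4.5)
        assert np.allclose(grad, 0.0)

    def test_step_peak_at_step_row_and_matches_dense_convolution(self):
        # vertical step: rows >= r0 are bright; the smoothed-derivative
        # maximum must sit on the step row, and the whole interior must
        # match a direct dense convolution with an explicitly sampled
        # Gaussian-derivative kernel
        r0, n_r = 25, 60
        img = np.zeros((n_r, 4))
        img[r0:, :] = 1.0
        sigma_px = 3.0
        grad = gradient_image(img, sigma_um=sigma_px * 4.5, pixel_um=4.5)
        # the discrete edge sits between rows r0-1 and r0: both attain the
        # maximum of the symmetric kernel response
        assert np.allclose(grad[r0, :], grad.max(axis=0))
        assert (np.argmax(grad, axis=0) >= r0 - 1).all()
        assert (np.argmax(grad, axis=0) <= r0).all()

        half = int(np.ceil(4 * sigma_px))
        x = np.arange(-half, half + 1, dtype=float)
        g = np.exp(-(x**2) / (2 * sigma_px**2))
        g /= g.sum()
        gprime = -x / sigma_px**2 * g
        dense = np.convolve(img[:, 0], gprime, mode="same")
        interior = slice(half + 1, n_r - half - 1)
        assert np.allclose(grad[interior, 0], dense[interior], atol=1e-12)

    def test_orientation_flips_sign(self):
        img = np.random.default_rng(0).random((30, 5))
        pos = gradient_image(img, 9.0, 4.5, "positive")
        neg = gradient_image(img, 9.0, 4.5, "negative")
        assert np.allclose(pos, -neg)

    def test_rejects_unresolvable_sigma_and_nonfinite(self):
        img = np.ones((10, 3))
        with pytest.raises(InputError):
            gradient_image(img, sigma_um=1.0, pixel_um=4.5)  # 0.22 px
        bad = img.copy()
        bad[0, 0] = np.nan
        with pytest.raises(InputError):
            gradient_image(bad, sigma_um=9.0, pixel_um=4.5)


class TestBuildCost:
    def test_linear_rescale_of_negated_gradient(self):
        grad = np.array([[-2.0, 0.0, 2.0], [-2.0, 0.0, 2.0]])
        assert np.allclose(build_cost(grad), [[1.0, 0.5, 0.0]] * 2)

    def test_output_spans_unit_interval(self, rng):
        cost = build_cost(rng.normal(size=(17, 9)))
        assert cost.min() == 0.0
        assert cost.max() == 1.0

    def test_constant_gradient_degenerates_to_zeros_with_warning(self):
        with pytest.warns(UserWarning, match="constant gradient"):
            cost = build_cost(np.full((5, 4), 2.5))
        assert np.array_equal(cost, np.zeros((5, 4)))


class TestPropagationAndBacktracking:
    def test_zero_cost_gives_zero_cumulated(self):
        prop = propagate_front(np.zeros((6, 5)), 0.3, 1.5, 2)
        assert np.array_equal(prop.cumulated, np.zeros((6, 5)))

    def test_seed_column_is_zero_and_backpointers_within_reach(self, rng):
        cost = rng.random((8, 7))
        N = 3
        prop = propagate_front(cost, 0.2, 1.8, N)
        assert np.array_equal(prop.cumulated[:, 0], np.zeros(8))
        rows = np.arange(8)[:, None]
        reach = np.abs(prop.backpointers[:, 1:] - rows)
        assert (reach <= N).all()

    @pytest.mark.parametrize(
        "alpha,beta,N", [(0.2, 1.8, 1), (0.0, 1.0, 2), (2.0, 1.0, 1),
                         (0.5, 2.0, 2)]
    )
    def test_matches_exhaustive_enumeration(self, rng, enum_oracle,
                                            alpha, beta, N):
        for _ in range(15):
            cost = rng.random((4, 4))
            prop = propagate_front(cost, alpha, beta, N)
            path = backtrack(prop, cost)
            _, best = enum_oracle(cost, alpha, beta, N)
            assert path.total_cost == pytest.approx(best, abs=1e-9)
            assert path_cost(cost, path.rows, alpha, beta) == pytest.approx(
                best, abs=1e-9
            )

    def test_cumulated_matrix_matches_prefix_enumeration(self, rng):
        # every node of the cumulated matrix, not just the optimum
        cost = rng.random((4, 4))
        alpha, beta, N = 0.2, 1.8, 1
        prop = propagate_front(cost, alpha, beta, N)
        n_r, n_c = cost.shape
        for t in range(1, n_c):
            grids = np.meshgrid(*([np.arange(n_r)] * (t + 1)), indexing="ij")
            prefixes = np.stack([g.ravel() for g in grids], axis=1)
            steps = np.abs(np.diff(prefixes, axis=1))
            prefixes = prefixes[(steps <= N).all(axis=1)]
            for r in range(n_r):
                ending = prefixes[prefixes[:, -1] == r]
                vals = [path_cost(cost[:, : t + 1], p, alpha, beta)
                        for p in ending]
                assert prop.cumulated[r, t] == pytest.approx(
                    min(vals), abs=1e-9
                )

    def test_unpenalized_case_agrees_with_dijkstra(self, rng):
        # alpha = 0 reduces the recursion to a plain shortest path on the
        # neighbor graph with edge weight C(r,t+1) + C(r+d,t)
        import networkx as nx

        cost = rng.random((5, 6))
        N = 2
        G = nx.DiGraph()
        n_r, n_c = cost.shape
        for t in range(n_c - 1):
            for r1 in range(n_r):
                for r2 in range(max(0, r1 - N), min(n_r, r1 + N + 1)):
                    G.add_edge((r1, t), (r2, t + 1),
                               weight=cost[r2, t + 1] + cost[r1, t])
        for r in range(n_r):
            G.add_edge("s", (r, 0), weight=0.0)
            G.add_edge((r, n_c - 1), "e", weight=0.0)
        best = nx.shortest_path_length(G, "s", "e", weight="weight")
        path = backtrack(propagate_front(cost, 0.0, 1.0, N), cost)
        assert path.total_cost == pytest.approx(best, abs=1e-9)

    def test_unique_zero_row_is_the_optimal_path(self):
        cost = np.full((7, 9), 0.8)
        cost[3, :] = 0.0
        path = backtrack(propagate_front(cost, 0.5, 1.8, 2), cost)
        assert np.array_equal(path.rows, np.full(9, 3))
        assert path.total_cost == pytest.approx(0.0)

    def test_direction_independence(self, rng):
        # edge-weight symmetry: the minimal total cost must not depend on
        # whether the front propagates left-to-right or right-to-left
        for _ in range(25):
            cost = rng.random((6, 7))
            fwd = backtrack(propagate_front(cost, 0.3, 1.8, 2), cost)
            rev_cost = cost[:, ::-1].copy()
            rev = backtrack(propagate_front(rev_cost, 0.3, 1.8, 2), rev_cost)
            assert fwd.total_cost == pytest.approx(rev.total_cost, abs=1e-9)

    def test_blocked_column_is_rejected(self):
        cost = np.random.default_rng(1).random((5, 4))
        cost[:, 2] = np.inf
        with pytest.raises(InfeasiblePathError):
            propagate_front(cost, 0.2, 1.8, 1)


class TestExtractMinPath:
    PARAMS = DPParams(alpha=0.2, beta=1.8, sigma_um=13.5, half_neighbors=2,
                      orientation="positive")

    def _band_image(self, boundary_rows, n_r=60):
        img = np.zeros((n_r, boundary_rows.size))
        for j, b in enumerate(boundary_rows):
            img[b:, j] = 1.0
        return img

    def test_recovers_known_boundary_within_one_pixel(self, rng):
        boundary = 25 + np.cumsum(rng.integers(-1, 2, size=24))
        img = self._band_image(boundary)
        path = extract_min_path(img, self.PARAMS, pixel_um=4.5)
        assert np.max(np.abs(path.rows - boundary)) <= 1

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(5)
        boundary = 20 + np.cumsum(rng.integers(-2, 3, size=12))
        img = self._band_image(boundary, n_r=50) + 0.1 * rng.random((50, 12))
        base = extract_min_path(img, self.PARAMS, pixel_um=4.5)
        scaled = extract_min_path(img * scale, self.PARAMS, pixel_um=4.5)
        assert np.array_equal(base.rows, scaled.rows)

    def test_large_alpha_forces_horizontal_path(self, rng, enum_oracle):
        # with strictly positive cost and alpha far above W*max/min, any
        # vertical step is costlier than staying flat the whole way
        cost = 0.2 + 0.8 * rng.random((5, 5))
        alpha = 10 * cost.shape[1] * cost.max() / cost.min()
        prop = propagate_front(cost, alpha, 1.0, 2)
        path = backtrack(prop, cost)
        assert np.ptp(path.rows) == 0
        _, best = enum_oracle(cost, alpha, 1.0, 2)
        assert path.total_cost == pytest.approx(best, abs=1e-6 * best)

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_consecutive_rows_never_exceed_reach(self, seed):
        rng = np.random.default_rng(seed)
        n_r, n_c = int(rng.integers(4, 12)), int(rng.integers(3, 9))
        N = int(rng.integers(1, 4))
        cost = rng.random((n_r, n_c))
        path = backtrack(propagate_front(cost, 0.2, 1.8, N), cost)
        assert np.max(np.abs(np.diff(path.rows))) <= N


class TestConstrainCost:
    def test_empty_point_list_is_identity(self, rng):
        cost = rng.random((6, 6))
        assert constrain_cost(cost, []) is cost

    def test_single_point_forces_path_through_it(self, rng):
        cost = rng.random((8, 9))
        cp = ControlPoint(col=4, row=6)
        constrained = constrain_cost(cost, [cp], half_neighbors=2)
        path = backtrack(propagate_front(constrained, 0.2, 1.8, 2),
                         constrained)
        assert path.rows[4] == 6
        # untouched columns keep their costs
        assert np.array_equal(constrained[:, :4], cost[:, :4])
        assert np.isinf(constrained[:5, 4]).all()
        assert constrained[6, 4] == 0.0

    def test_two_points_in_one_column_rejected(self, rng):
        cost = rng.random((6, 6))
        with pytest.raises(InputError, match="column 2"):
            constrain_cost(
                cost, [ControlPoint(2, 1), ControlPoint(2, 4)]
            )

    def test_mutually_unreachable_points_rejected(self, rng):
        cost = rng.random((10, 8))
        with pytest.raises(InputError, match="unreachable"):
            constrain_cost(
                cost,
                [ControlPoint(2, 0), ControlPoint(3, 9)],
                half_neighbors=2,
            )

    def test_truthful_anchor_reduces_contour_error(self, rng, enum_oracle):
        # corrupt one column of a band image with a bright artifact; a
        # control point on the true boundary must strictly reduce the error
        n_r, n_c = 40, 15
        truth = np.full(n_c, 20)
        img = np.zeros((n_r, n_c))
        for j, b in enumerate(truth):
            img[b:, j] = 1.0
        img[8:10, 7] = 5.0  # artifact pulling the gradient shallow
        params = DPParams(0.05, 1.0, 9.0, 2, "positive")
        free = extract_min_path(img, params, 4.5)
        anchored = extract_min_path(
            img, params, 4.5, control_points=[ControlPoint(7, 20)]
        )
        err_free = np.abs(free.rows - truth).sum()
        err_anch = np.abs(anchored.rows - truth).sum()
        assert anchored.rows[7] == 20
        assert err_anch < err_free
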