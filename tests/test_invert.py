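"""Model inversion: round trips, grid-oracle agreement, noise monotonicity."""

import numpy as np
import pytest

import moxquant as mq


def _well_conditioned_samples(rng, n):
    """Random mixtures inside the region where the mapping is one-to-one.

    Under the reference coefficients the Jacobian determinant vanishes along
    a fold at ethanol ~1-5 ppm (two exact preimages exist on either side of
    it), so unique round-trip recovery is only guaranteed above it.
    """
    return np.column_stack([rng.uniform(6, 20, n), rng.uniform(6, 40, n)])


class TestInvertSample:
    def test_noiseless_round_trip(self, ref, rng):
        c = _well_conditioned_samples(rng, 100)
        s_true = mq.sources_from_concentrations(c, ref.r)
        for s in s_true:
            x = mq.forward_lq(s, ref)
            res = mq.invert_sample(x, ref)
            assert res.converged
            assert np.allclose(res.s_hat, s, rtol=1e-6)

    def test_unit_ratios_give_zero_sources(self, ref):
        res = mq.invert_sample([1.0, 1.0], ref)
        assert np.allclose(res.s_hat, [0.0, 0.0], atol=1e-6)
        assert np.allclose(res.c_hat, [0.0, 0.0], atol=1e-6)

    def test_concentrations_are_back_transformed_sources(self, ref):
        s = mq.sources_from_concentrations([12.0, 30.0], ref.r)
        res = mq.invert_sample(mq.forward_lq(s, ref), ref)
        assert np.allclose(res.c_hat, mq.concentrations_from_sources(res.s_hat, ref.r))

    def test_perturbed_truth_requires_truth(self, ref):
        opts = mq.InversionOptions(init_strategy="perturbed_truth")
        with pytest.raises(ValueError, match="truth"):
            mq.invert_sample([2.0, 2.0], ref, opts)

    def test_fold_gives_two_exact_preimages(self, ref):
        """The quadratic map is two-to-one near its fold (det J = 0 locus).

        At fixed acetone the Jacobian determinant changes sign across the
        low-ethanol band, and a mixture just below the fold shares its exact
        observation pair with a second source vector: inversion ambiguity
        there is a property of the model, not of the solver.
        """
        det = []
        for c2 in (0.5, 10.0):
            s = mq.sources_from_concentrations([12.0, c2], ref.r)
            det.append(np.linalg.det(mq.jacobian_lq(s, ref)))
        assert det[0] * det[1] < 0

        s_true = mq.sources_from_concentrations([12.14, 1.75], ref.r)
        x = mq.forward_lq(s_true, ref)
        res = mq.invert_sample(x, ref)  # mid-range start lands on the twin root
        assert res.residual_norm < 1e-6
        assert not np.allclose(res.s_hat, s_true, rtol=1e-3)

    def test_nonnegative_estimates_with_clipping(self, ref, rng):
        # noisy observations near clean air can pull iterates negative
        for _ in range(20):
            x = np.clip(1.0 + rng.normal(0, 0.5, 2), 0.05, None)
            res = mq.invert_sample(x, ref)
            assert np.all(res.s_hat >= 0)


class TestInvertDataset:
    def test_noiseless_dataset_mse_near_zero(self, ref, rng):
        c = _well_conditioned_samples(rng, 30)
        s = mq.sources_from_concentrations(c, ref.r)
        xs = mq.forward_lq(s, ref)
        results, report = mq.invert_dataset(xs, ref, truths=c)
        assert len(results) == 30
        assert report.mse_mean < 1e-10

    def test_empty_input_gives_empty_output(self, ref):
        results, report = mq.invert_dataset(np.empty((0, 2)), ref)
        assert results == [] and report is None

    def test_mse_nondecreasing_in_noise(self, ref, rng):
        c = _well_conditioned_samples(np.random.default_rng(77), 100)
        s = mq.sources_from_concentrations(c, ref.r)
        x_clean = mq.forward_lq(s, ref)
        mses = []
        for i, var in enumerate([0.01, 1.0, 100.0]):
            noise = np.random.default_rng(100 + i).normal(0, np.sqrt(var), x_clean.shape)
            xs = np.clip(x_clean + noise, 0.05, None)
            _, report = mq.invert_dataset(xs, ref, truths=c)
            mses.append(report.mse_mean)
        assert mses[0] <= mses[1] <= mses[2]


class TestGridOracle:
    def test_recovers_noiseless_on_grid_sources_exactly(self, ref):
        # truths placed on grid nodes: the exhaustive search must return them
        grid = mq.GridSpec(n_per_axis=201)  # steps (0.1, 0.2) ppm
        for c in ([10.0, 20.0], [6.0, 30.0], [15.0, 10.0]):
            s = mq.sources_from_concentrations(c, ref.r)
            x = mq.forward_lq(s, ref)
            s_grid = mq.grid_oracle_invert(x, ref, grid)
            c_grid = mq.concentrations_from_sources(s_grid, ref.r)
            assert np.allclose(c_grid, c, atol=1e-9)

    def test_exhaustive_search_beats_truth_adjacent_node(self, ref, rng):
        # the returned node's cost never exceeds the cost at the node nearest
        # the generating mixture (global argmin on the grid)
        grid = mq.GridSpec(n_per_axis=201)
        axes = [np.linspace(lo, hi, grid.n_per_axis) for lo, hi in grid.ranges]
        for _ in range(5):
            c = np.array([rng.uniform(6, 20), rng.uniform(6, 40)])
            s = mq.sources_from_concentrations(c, ref.r)
            x = mq.forward_lq(s, ref)
            s_grid = mq.grid_oracle_invert(x, ref, grid)
            nearest = np.array([ax[np.argmin(np.abs(ax - ci))] for ax, ci in zip(axes, c)])
            s_near = mq.sources_from_concentrations(nearest, ref.r)
            cost_found = float(np.sum((mq.forward_lq(s_grid, ref) - x) ** 2))
            cost_near = float(np.sum((mq.forward_lq(s_near, ref) - x) ** 2))
            assert cost_found <= cost_near + 1e-12

    def test_argmin_beats_grid_neighbors(self, ref):
        grid = mq.GridSpec(n_per_axis=101)
        x = np.asarray(mq.forward_lq(mq.sources_from_concentrations([10.0, 20.0], ref.r), ref))
        x = x + np.array([0.3, -0.4])

        def cost(c_pair):
            s = mq.sources_from_concentrations(c_pair, ref.r)
            return float(np.sum((mq.forward_lq(s, ref) - x) ** 2))

        s_best = mq.grid_oracle_invert(x, ref, grid)
        c_best = mq.concentrations_from_sources(s_best, ref.r)
        steps = np.array([(hi - lo) / (grid.n_per_axis - 1) for lo, hi in grid.ranges])
        base = cost(c_best)
        for delta in ([1, 0], [-1, 0], [0, 1], [0, -1]):
            neighbor = c_best + steps * delta
            if np.all(neighbor >= 0):
                assert base <= cost(neighbor) + 1e-12

    def test_grid_refinement_never_increases_minimum(self, ref):
        x = np.array([50.0, 40.0])

        def min_cost(n):
            s = mq.grid_oracle_invert(x, ref, mq.GridSpec(n_per_axis=n))
            return float(np.sum((mq.forward_lq(s, ref) - x) ** 2))

        # 101 -> 201 is a nested refinement of linspace grids
        assert min_cost(201) <= min_cost(101) + 1e-12

    def test_lm_matches_oracle_on_noisy_observations(self, ref, rng):
        grid = mq.GridSpec(n_per_axis=201)
        c = _well_conditioned_samples(rng, 25)
        s = mq.sources_from_concentrations(c, ref.r)
        xs = mq.forward_lq(s, ref) + rng.normal(0, 0.5, (25, 2))

        # grid-resolution slack on the cost: one step along each source axis
        for x in xs:
            res = mq.invert_sample(x, ref)
            s_grid = mq.grid_oracle_invert(x, ref, grid)
            cost_lm = res.residual_norm**2
            cost_grid = float(np.sum((mq.forward_lq(s_grid, ref) - x) ** 2))
            assert cost_lm <= cost_grid + 1e-9
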