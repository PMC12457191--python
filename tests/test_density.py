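import numpy as np
import pytest
from scipy import stats

from sffdr.density import (
    SurrogateDensity,
    evaluate_density,
    fit_joint_density,
    make_surrogate,
)


class TestSurrogate:
    def test_ranks_divided_by_m(self):
        sm = make_surrogate([0.98, 0.50, 0.75])
        np.testing.assert_allclose(sm.r, [1.0, 1 / 3, 2 / 3])

    def test_ties_randomly_assigned_and_seed_stable(self):
        a = make_surrogate([0.9, 0.9], seed=5)
        b = make_surrogate([0.9, 0.9], seed=5)
        assert sorted(a.r) == [0.5, 1.0]
        np.testing.assert_array_equal(a.r, b.r)

    def test_output_is_exact_permutation_of_uniform_grid(self):
        rng = np.random.default_rng(0)
        vals = rng.choice([0.2, 0.5, 0.9], size=200)  # heavy ties
        sm = make_surrogate(vals, seed=1)
        np.testing.assert_allclose(np.sort(sm.r), np.arange(1, 201) / 200)

    def test_prediction_is_monotone_and_interpolates(self):
        rng = np.random.default_rng(1)
        vals = rng.random(500)
        sm = make_surrogate(vals, seed=0)
        query = np.linspace(0, 1, 50)
        out = sm.predict(query)
        assert np.all(np.diff(out) >= 0)
        assert np.all((out >= 0) & (out <= 1))

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            make_surrogate([])


@pytest.fixture(scope="module")
def flat_fit():
    rng = np.random.default_rng(2)
    return SurrogateDensity(span=0.02).fit(rng.random(10_000), rng.random(10_000))


class TestJointDensity:
    def test_flat_null_close_to_one(self, flat_fit):
        grid = np.linspace(0.05, 0.95, 19)
        pp, rr = np.meshgrid(grid, grid)
        vals = flat_fit.joint(pp.ravel(), rr.ravel())
        assert np.abs(vals - 1).max() < 0.25

    def test_unit_mass_on_p_r_scale(self, flat_fit):
        from scipy.stats import norm

        gu, gr = flat_fit.grid_p_, flat_fit.grid_r_
        mass = np.trapezoid(
            np.trapezoid(flat_fit.joint_values_ * norm.pdf(gu)[:, None], gr, axis=1), gu
        )
        assert abs(mass - 1) < 0.02

    def test_beta_density_recovered_through_probit_pipeline(self):
        """Jacobian correctness: the probit-scale fit returns the Beta
        density on the original scale with small integrated error."""
        rng = np.random.default_rng(3)
        fit = SurrogateDensity(span=0.1).fit(rng.beta(2, 5, 10_000), rng.random(10_000))
        grid = np.linspace(0.002, 0.998, 400)
        est = fit.joint(grid, np.full_like(grid, 0.5))
        iae = np.trapezoid(np.abs(est - stats.beta.pdf(grid, 2, 5)), grid)
        assert iae < 0.15

    def test_joint_beats_product_of_marginals_when_dependent(self):
        """With a (p, r)-dependent mixture the joint estimate has smaller
        integrated squared error than the independence baseline."""
        rng = np.random.default_rng(4)
        m = 20_000
        r = rng.random(m)
        alt = rng.random(m) < 0.3 * (1 - r)  # signal concentrated at low r
        p = np.where(alt, rng.beta(0.4, 5, m), rng.random(m))
        fit = SurrogateDensity(span=0.1).fit(p, r)
        grid_p = np.linspace(0.01, 0.99, 60)
        grid_r = np.linspace(0.05, 0.95, 30)
        pp, rr = np.meshgrid(grid_p, grid_r, indexing="ij")

        def truth(p_, r_):
            w = 0.3 * (1 - r_)
            return (1 - w) + w * stats.beta.pdf(p_, 0.4, 5)

        est = fit.joint(pp.ravel(), rr.ravel())
        prod = fit.joint(pp.ravel(), np.full(pp.size, 0.5))  # r-independent proxy
        t = truth(pp.ravel(), rr.ravel())
        assert np.mean((est - t) ** 2) < np.mean((prod - t) ** 2)

    def test_span_floor_applied_by_wrapper(self):
        rng = np.random.default_rng(5)
        fit = fit_joint_density(rng.random(2_000), rng.random(2_000), pi0_overall=0.99)
        assert fit.span == 0.02
        with pytest.raises(ValueError):
            fit_joint_density(rng.random(100), rng.random(100), pi0_overall=1.5)

    def test_determinism(self):
        rng = np.random.default_rng(6)
        p, r = rng.random(3_000), rng.random(3_000)
        a = SurrogateDensity(span=0.05).fit(p, r)
        b = SurrogateDensity(span=0.05).fit(p, r)
        np.testing.assert_array_equal(a.joint_values_, b.joint_values_)

    def test_too_few_points_error(self):
        with pytest.raises(ValueError, match="at least"):
            SurrogateDensity().fit(np.full(10, 0.5), np.full(10, 0.5))


class TestEvaluation:
    def test_grid_node_returns_stored_value(self, flat_fit):
        iu, ir = 150, 16
        p_node = stats.norm.cdf(flat_fit.grid_p_[iu])
        r_node = flat_fit.grid_r_[ir]
        joint, _ = evaluate_density(flat_fit, np.array([p_node]), np.array([r_node]))
        np.testing.assert_allclose(joint[0], flat_fit.joint_values_[iu, ir], rtol=1e-6)

    def test_out_of_range_queries_clamp_to_edges(self, flat_fit):
        lo = flat_fit.joint(np.array([1e-300]), np.array([0.5]))
        edge = flat_fit.joint(np.array([stats.norm.cdf(flat_fit.grid_p_[0])]), np.array([0.5]))
        np.testing.assert_allclose(lo, edge, rtol=1e-6)

    def test_floor_contract(self, flat_fit):
        joint, marg = evaluate_density(
            flat_fit, np.array([1e-15, 0.5]), np.array([0.001, 0.999])
        )
        assert np.all(joint >= flat_fit.density_floor)
        assert np.all(marg >= flat_fit.density_floor)


class TestMarginal:
    def test_uniform_r_close_to_flat(self, flat_fit):
        grid = np.linspace(0.05, 0.95, 50)
        assert np.abs(flat_fit.marginal(grid) - 1).max() < 0.1

    def test_integrates_to_one(self, flat_fit):
        grid = flat_fit.marginal_grid_r_
        assert abs(np.trapezoid(flat_fit.marginal_r_values_, grid) - 1) < 0.02

    def test_ld_duplication_shifts_mass(self):
        """Duplicating low-r SNPs three-fold makes f(r) larger at low r."""
        rng = np.random.default_rng(7)
        r = rng.random(5_000)
        r_all = np.concatenate([r, np.repeat(r[r < 0.2], 2)])
        fit = SurrogateDensity(span=0.05).fit(rng.random(5_000), r)
        fit.fit_marginal(r_all)
        low = fit.marginal(np.linspace(0.02, 0.18, 20)).mean()
        high = fit.marginal(np.linspace(0.82, 0.98, 20)).mean()
        assert low > high
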