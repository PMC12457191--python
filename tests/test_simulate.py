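import numpy as np
import pytest
from scipy import stats

from sffdr.ffdr import qf_values
from sffdr.simulate import (
    SimConfig,
    apply_ld_duplication,
    evaluate_metrics,
    oracle_local_fdr,
    simulate_independent,
)


class TestConfig:
    def test_strength_mappings(self):
        cfg = SimConfig(primary_strength="high", informative_strength="low",
                        effect_strength="moderate")
        assert cfg.alpha0 == 0.3
        assert cfg.informative_alpha == 4.0
        assert cfg.effect_a == 0.3
        assert cfg.effect_c == 0.3 / 4

    def test_none_effect_disables_coupling(self):
        cfg = SimConfig(effect_strength="none")
        assert cfg.effect_a == 0.0 and cfg.effect_c == 0.0

    @pytest.mark.parametrize(
        "kwargs", [dict(gamma=0.0), dict(baseline=1.0), dict(primary_strength="huge")]
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


@pytest.fixture(scope="module")
def ds():
    return simulate_independent(SimConfig(m=150_000, seed=42))


class TestGenerator:

    def test_informative_null_proportions_in_stated_range(self, ds):
        assert np.all((ds.pi0_k >= 0.975) & (ds.pi0_k <= 0.9875))

    def test_fully_informative_null_snps_sit_at_baseline_exactly(self, ds):
        all_null = (ds.H_informative == 0).all(axis=1)
        assert all_null.any()
        np.testing.assert_array_equal(ds.pi0_z[all_null], 0.98)

    def test_h_frequency_consistent_with_prior(self, ds):
        expected = (1 - ds.pi0_z).mean()
        se = np.sqrt(expected * (1 - expected) / ds.m)
        assert abs(ds.H.mean() - expected) < 3 * se

    def test_null_informative_p_values_uniform(self, ds):
        for k in range(3):
            null_z = ds.z[ds.H_informative[:, k] == 0, k]
            assert stats.kstest(null_z, "uniform").pvalue > 0.001

    def test_effect_direction_monotone_in_effect_strength(self):
        """Stronger informative coupling pulls the alternative Beta shape
        further below alpha0 at shared alternatives."""
        means = {}
        for eff in ("large", "moderate", "none"):
            d = simulate_independent(SimConfig(m=100_000, seed=7, effect_strength=eff))
            shared = d.H_informative.any(axis=1)
            means[eff] = d.alpha_z[shared].mean()
        assert means["large"] < means["moderate"] < means["none"]
        assert means["none"] == pytest.approx(0.4)

    def test_none_effect_gives_constant_baseline(self):
        d = simulate_independent(SimConfig(m=10_000, seed=3, effect_strength="none"))
        np.testing.assert_array_equal(d.pi0_z, 0.98)
        np.testing.assert_array_equal(d.alpha_z, 0.4)

    def test_determinism_bit_identical(self):
        a = simulate_independent(SimConfig(m=5_000, seed=9))
        b = simulate_independent(SimConfig(m=5_000, seed=9))
        np.testing.assert_array_equal(a.p, b.p)
        np.testing.assert_array_equal(a.z, b.z)
        np.testing.assert_array_equal(a.H, b.H)


class TestOracle:
    def test_pure_null_lambda_is_one(self):
        d = simulate_independent(SimConfig(m=2_000, seed=1, effect_strength="none"))
        d.pi0_z[:] = 1.0
        assert np.allclose(oracle_local_fdr(d)[d.pi0_z == 1.0], 1.0)

    def test_arithmetic_at_unit_alternative_density(self):
        d = simulate_independent(SimConfig(m=1_000, seed=2))
        lam = oracle_local_fdr(d)
        f1 = stats.beta.pdf(d.p, d.alpha_z, 5.0)
        expected = d.pi0_z / (d.pi0_z + (1 - d.pi0_z) * f1)
        np.testing.assert_allclose(lam, expected, rtol=1e-12)
        near_unit = np.isclose(f1, 1.0, atol=0.01) & np.isclose(d.pi0_z, 0.98)
        if near_unit.any():
            np.testing.assert_allclose(lam[near_unit], 0.98, atol=0.01)

    def test_oracle_qf_controls_fdr_over_replicates(self):
        """Thresholding the exact posterior at q_f <= 0.01 keeps the mean
        FDP at or below 0.01 + 2 Monte-Carlo SE (25 replicates)."""
        fdps = []
        for seed in range(25):
            d = simulate_independent(SimConfig(m=50_000, seed=600 + seed))
            q = qf_values(oracle_local_fdr(d))
            sig = q <= 0.01
            R = int(sig.sum())
            fdps.append(np.sum(sig & (d.H == 0)) / max(R, 1))
        fdps = np.array(fdps)
        bound = 0.01 + 2 * fdps.std(ddof=1) / np.sqrt(len(fdps))
        assert fdps.mean() <= bound


class TestLdDuplication:
    def test_duplication_contract(self):
        d = simulate_independent(SimConfig(m=3, seed=5))
        dup = apply_ld_duplication(d, sizes=np.array([2, 1, 3]))
        assert dup.m == 6
        assert list(dup.table["block_id"]) == [0, 0, 1, 2, 2, 2]
        block = dup.table[dup.table["block_id"] == 2]
        assert block["p"].nunique() == 1
        assert dup.table["snp"].is_unique

    def test_all_singletons_is_identity_on_values(self):
        d = simulate_independent(SimConfig(m=100, seed=6))
        dup = apply_ld_duplication(d, sizes=np.ones(100, dtype=int))
        np.testing.assert_array_equal(dup.p, d.p)
        np.testing.assert_array_equal(dup.H, d.H)

    def test_sampled_sizes_seeded_and_capped(self):
        d = simulate_independent(SimConfig(m=2_000, seed=7))
        a = apply_ld_duplication(d, seed=1)
        b = apply_ld_duplication(d, seed=1)
        np.testing.assert_array_equal(a.block_sizes, b.block_sizes)
        assert a.block_sizes.max() <= 50 and a.block_sizes.min() >= 1


class TestMetrics:
    def test_fdp_conventions(self):
        H = np.array([0, 0, 1, 1])
        q = np.array([0.5, 0.5, 0.5, 0.5])
        out = evaluate_metrics(H, qvalues=q, fdr_targets=(0.01,))
        assert out.iloc[0]["discoveries"] == 0 and out.iloc[0]["fdp"] == 0.0

        q = np.array([0.005, 0.5, 0.005, 0.005])
        out = evaluate_metrics(H, qvalues=q, fdr_targets=(0.01,))
        row = out.iloc[0]
        assert row["discoveries"] == 3 and row["false_discoveries"] == 1
        assert row["fdp"] == pytest.approx(1 / 3)

    def test_perfect_classifier(self):
        H = np.array([0, 1, 0, 1])
        q = np.where(H == 1, 1e-6, 1.0)
        p = np.where(H == 1, 1e-12, 1.0)
        out = evaluate_metrics(H, qvalues=q, pvalues=p)
        assert (out[out.statistic == "qvalue"]["power"] == 1.0).all()
        assert (out["fdp"] == 0.0).all()
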