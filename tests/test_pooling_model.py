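import dataclasses

import numpy as np
import pytest
from scipy.stats import norm, spearmanr

from lgnpool import (
    NeuronProfile,
    PoolConfig,
    assign_weights,
    run_experiment,
    sample_pool,
    simulate_trial,
)
from lgnpool.pooling_model import simulate_trials
from lgnpool.synthetic_population import (
    CALIBRATION_FANO,
    _rmax_for_dprime,
    neuron_dprime,
    response_moments,
)


def cell_with_dprime(d, cls="P", uid="n", baseline=15.0, c50=20.0, hill=1.5,
                     transience=0.4, latency=10.0):
    """Build a cell whose d-prime at the calibration conditions is exactly d."""
    rmax = _rmax_for_dprime(
        np.array([d]), np.array([baseline]), np.array([c50]), hill,
        np.array([transience]), latency,
    )[0]
    return NeuronProfile(
        neuron_id=uid, cell_class=cls, polarity="ON", baseline_rate=baseline,
        r_max=rmax, c50=c50, hill_exponent=hill, transience=transience,
        latency_ms=latency,
    )


SMALL_CFG = PoolConfig(n_p=8, n_m=8, n_reps=3, trials_per_contrast=50, seed=0)


class TestSamplePool:
    def test_composition_and_replacement(self, population, rng):
        pool = sample_pool(population, 512, 512, rng)
        assert len(pool) == 1024
        assert (pool.classes == "P").sum() == 512
        assert (pool.classes == "M").sum() == 512
        # 512 draws from 68 P cells must repeat
        assert len(set(pool.indices[:512])) < 512

    def test_pure_class_pools(self, population, rng):
        pool = sample_pool(population, 0, 16, rng)
        assert set(pool.classes) == {"M"}

    def test_determinism(self, population):
        a = sample_pool(population, 10, 5, np.random.default_rng(3))
        b = sample_pool(population, 10, 5, np.random.default_rng(3))
        assert np.array_equal(a.indices, b.indices)

    def test_missing_class_rejected(self, population, rng):
        only_p = [n for n in population if n.cell_class == "P"]
        with pytest.raises(ValueError, match="M"):
            sample_pool(only_p, 4, 4, rng)


class TestAssignWeights:
    def make_pool(self, dprimes_p, dprimes_m):
        from lgnpool.pooling_model import PoolSample

        members = [
            cell_with_dprime(d, "P", f"p{i}") for i, d in enumerate(dprimes_p)
        ] + [cell_with_dprime(d, "M", f"m{i}") for i, d in enumerate(dprimes_m)]
        return PoolSample(
            members=members,
            indices=np.arange(len(members)),
            classes=np.array([m.cell_class for m in members]),
        )

    def test_uniform_weights_all_one(self, population, rng):
        pool = sample_pool(population, 5, 5, rng)
        assert np.all(assign_weights(pool, "uniform", 150, 1.03) == 1.0)

    def test_dprime_joint_proportional_with_unit_max(self):
        pool = self.make_pool([2.0, 1.0], [])
        w = assign_weights(pool, "dprime_joint", 150, CALIBRATION_FANO)
        assert w == pytest.approx([1.0, 0.5], abs=1e-9)

    def test_separate_vs_joint_normalization_groups(self):
        # best P d' = 4, best M d' = 2: separate puts a 1.0 in each class,
        # joint scales M's best to 0.5
        pool = self.make_pool([4.0, 1.0], [2.0, 1.0])
        sep = assign_weights(pool, "dprime_separate", 150, CALIBRATION_FANO)
        joint = assign_weights(pool, "dprime_joint", 150, CALIBRATION_FANO)
        assert sep[:2].max() == pytest.approx(1.0)
        assert sep[2:].max() == pytest.approx(1.0)
        assert joint.max() == pytest.approx(1.0)
        assert joint[2:].max() == pytest.approx(0.5, abs=1e-9)

    def test_separate_equals_joint_when_class_maxima_agree(self):
        pool = self.make_pool([3.0, 1.0], [3.0, 0.5])
        sep = assign_weights(pool, "dprime_separate", 150, CALIBRATION_FANO)
        joint = assign_weights(pool, "dprime_joint", 150, CALIBRATION_FANO)
        assert sep == pytest.approx(joint)

    def test_mean_amp_weights_track_high_contrast_response(self, population, rng):
        pool = sample_pool(population, 6, 6, rng)
        w = assign_weights(pool, "mean_amp_joint", 150, 1.03, 99.0)
        means, _ = response_moments(pool.members, 99.0, 150, 1.03)
        assert w == pytest.approx(means / means.max())

    def test_amp_per_trial_defers(self, population, rng):
        pool = sample_pool(population, 3, 3, rng)
        assert assign_weights(pool, "amp_per_trial", 150, 1.03) is None

    def test_unknown_scheme_rejected(self, population, rng):
        pool = sample_pool(population, 2, 2, rng)
        with pytest.raises(ValueError):
            assign_weights(pool, "bogus", 150, 1.03)


class TestSimulateTrial:
    def test_blank_trial_choice_is_fair(self, population, rng):
        pool = sample_pool(population, 4, 4, rng)
        w = assign_weights(pool, "uniform", 150, 1.03)
        cfg = dataclasses.replace(SMALL_CFG, pooling_noise=0.0)
        choices = [
            simulate_trial(pool, w, 0.0, cfg, rng)[0] for _ in range(400)
        ]
        frac_in = np.mean([c == "in_rf" for c in choices])
        assert frac_in == pytest.approx(0.5, abs=0.07)

    def test_strong_single_neuron_nearly_always_correct(self, rng):
        strong = cell_with_dprime(8.0, "P", "s")
        from lgnpool.pooling_model import PoolSample

        pool = PoolSample([strong], np.array([0]), np.array(["P"]))
        cfg = PoolConfig(
            n_p=1, n_m=0, pooling_noise=0.0, r_within=0.0, r_between=0.0,
            contrasts=(0.0, 99.0), n_reps=1, seed=0,
        )
        choices = [
            simulate_trial(pool, np.ones(1), 99.0, cfg, rng)[0]
            for _ in range(200)
        ]
        assert np.mean([c == "in_rf" for c in choices]) > 0.95

    def test_invalid_correlation_ordering_rejected(self):
        with pytest.raises(ValueError, match="r_between"):
            PoolConfig(r_within=0.01, r_between=0.1)

    def test_unlisted_contrast_rejected(self, population, rng):
        pool = sample_pool(population, 2, 2, rng)
        with pytest.raises(ValueError):
            simulate_trial(pool, np.ones(4), 3.0, SMALL_CFG, rng)

    def test_percent_correct_matches_gaussian_oracle(self, rng):
        # r = 0, p = 0, no clipping, uniform weights: percent correct at
        # contrast c is Phi(sum(dmu) / sqrt(2 sum(var))) analytically
        cells = [cell_with_dprime(1.0, "P", f"c{i}", baseline=40.0)
                 for i in range(32)]
        from lgnpool.pooling_model import PoolSample

        pool = PoolSample(cells, np.arange(32), np.array(["P"] * 32))
        cfg = PoolConfig(
            n_p=32, n_m=0, r_within=0.0, r_between=0.0, pooling_noise=0.0,
            contrasts=(0.0, 8.0), clip_negative=False, n_reps=1, seed=0,
        )
        mu_t, sd_t = response_moments(cells, 8.0, cfg.window, cfg.fano)
        mu_r, sd_r = response_moments(cells, 0.0, cfg.window, cfg.fano)
        choices, _ = simulate_trials(
            mu_t, sd_t, mu_r, sd_r, pool.classes, np.ones(32), cfg, 4000, rng
        )
        expected = norm.cdf(
            (mu_t - mu_r).sum() / np.sqrt((sd_t**2 + sd_r**2).sum())
        )
        assert choices.mean() == pytest.approx(expected, abs=0.02)


class TestRunExperiment:
    def test_bookkeeping_shapes_and_bounds(self, population):
        res = run_experiment(population, SMALL_CFG)
        assert res.thresholds.shape == (3,)
        assert np.all(res.thresholds > 0)
        rec = res.member_records
        assert len(rec) == 3 * 16
        # each member contributes at most one CP per repetition
        assert rec.groupby(["rep", "member"]).size().max() == 1
        ok = rec[~rec.excluded]
        assert ok.cp.between(0, 1).all()

    def test_determinism(self, population):
        a = run_experiment(population, SMALL_CFG)
        b = run_experiment(population, SMALL_CFG)
        assert np.array_equal(a.thresholds, b.thresholds)
        assert a.member_records.equals(b.member_records)

    def test_uncorrelated_noise_free_pool_cp_near_half(self, population):
        # with r = 0 and p = 0 any single member's share of a large pooled
        # decision variable vanishes, so member CPs approach 0.5
        def cp_at(n):
            cfg = PoolConfig(
                n_p=n, n_m=n, r_within=0.0, r_between=0.0, pooling_noise=0.0,
                n_reps=6, seed=1,
            )
            res = run_experiment(population, cfg)
            return res.cp_mean("P"), res.cp_mean("M")

        small, large = cp_at(32), cp_at(512)
        for s, l in zip(small, large):
            assert abs(l - 0.5) < abs(s - 0.5)
            assert l == pytest.approx(0.5, abs=0.015)

    def test_dprime_weighting_couples_dprime_and_cp(self, population):
        cfg = PoolConfig(
            n_p=128, n_m=128, scheme="dprime_separate", n_reps=10, seed=2
        )
        res = run_experiment(population, cfg)
        rec = res.member_records
        ok = rec[~rec.excluded]
        rho, _ = spearmanr(ok.dprime, ok.cp)
        assert rho > 0

    def test_aggregates_recomputable_from_records(self, population):
        res = run_experiment(population, SMALL_CFG)
        rec = res.member_records
        ok = rec[(rec.cell_class == "P") & (~rec.excluded)]
        manual = ok.groupby("rep").cp.mean().mean()
        assert res.cp_mean("P") == pytest.approx(manual)
        assert res.mean_threshold == pytest.approx(res.thresholds.mean())

    def test_result_serialization(self, population, tmp_path):
        res = run_experiment(population, SMALL_CFG)
        res.save(tmp_path)
        assert (tmp_path / "simulation_thresholds.csv").exists()
        assert (tmp_path / "simulation_members.csv").exists()
        assert (tmp_path / "simulation_config.json").exists()
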