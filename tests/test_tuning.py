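import numpy as np
import pytest
from scipy import stats

import shapecode.shapes as sh
from shapecode.neurons import build_noisy_table, lif_rate
from shapecode.tuning import (
    AugmentationSpec,
    TuningCurve,
    augment,
    error_stats,
    fit_cosine_lif,
    levene_test,
    murata_archetypes,
)


@pytest.fixture(scope="module")
def standardized(stimulus_features_36):
    X = stimulus_features_36
    mu, sd = X.mean(0), X.std(0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def plant_neuron(Z, rng):
    """Random cosine-LIF neuron with a usable dynamic range over Z."""
    while True:
        phi = rng.standard_normal(Z.shape[1])
        b = rng.uniform(0.8, 1.6)
        tau = rng.uniform(0.03, 0.15)
        rates = lif_rate(Z @ phi + b, 0.005, tau)
        if rates.max() > 10 and (rates > 0).sum() >= 8:
            return rates


class TestAugment:
    def test_size_invariant_shares_rates_across_sizes(self, stimulus_set):
        tc = augment([10, 20, 30, 40], AugmentationSpec(size_mode="invariant"), stimulus_set)
        for s in range(4):
            for o in set(stimulus_set.orient_id):
                m = (stimulus_set.shape_id == s) & (stimulus_set.orient_id == o)
                if m.sum() > 1:
                    assert np.allclose(tc.rates[m], tc.rates[m][0])

    def test_monotone_rates_increase_with_size(self, stimulus_set):
        tc = augment([10, 20, 30, 40], AugmentationSpec(size_mode="monotone"), stimulus_set)
        for s in range(4):
            for o in set(stimulus_set.orient_id):
                m = (stimulus_set.shape_id == s) & (stimulus_set.orient_id == o)
                if m.any():
                    r = tc.rates[m][np.argsort(stimulus_set.size_id[m])]
                    assert np.all(np.diff(r) >= -1e-12)

    def test_reference_stimuli_reproduce_base_rates(self, stimulus_set):
        base = [12.0, 24.0, 36.0, 48.0]
        spec = AugmentationSpec(size_mode="monotone", orientation_pref=0, baseline=2.0)
        tc = augment(base, spec, stimulus_set)
        ref = (stimulus_set.size_id == 3) & (stimulus_set.orient_id == 0)
        for s in range(4):
            got = tc.rates[ref & (stimulus_set.shape_id == s)]
            assert got == pytest.approx(base[s])

    def test_plate_cylinder_equal_archetype(self, stimulus_set):
        base, spec = murata_archetypes()["plate-cylinder-equal"]
        tc = augment(base, spec, stimulus_set)
        names = stimulus_set.shape_names
        for o in (0, 2):
            for z in range(4):
                mp = (stimulus_set.shape_id == names.index("plate")) & \
                     (stimulus_set.size_id == z) & (stimulus_set.orient_id == o)
                mc = (stimulus_set.shape_id == names.index("cylinder")) & \
                     (stimulus_set.size_id == z) & (stimulus_set.orient_id == o)
                assert tc.rates[mp] == pytest.approx(tc.rates[mc])

    def test_negative_base_rates_rejected(self, stimulus_set):
        with pytest.raises(ValueError):
            augment([-1, 5, 5, 5], AugmentationSpec(), stimulus_set)


class TestFitCosineLIF:
    def test_parameter_recovery_noiseless(self, stimulus_set, stimulus_features_36, standardized):
        rng = np.random.default_rng(0)
        for trial in range(5):
            rates = plant_neuron(standardized, rng)
            fit = fit_cosine_lif(TuningCurve(stimulus_set, rates), stimulus_features_36,
                                 n_restarts=200, seed=trial, stop_sse=(1e-4) ** 2 * 36)
            assert np.sqrt(np.mean(fit.errors**2)) < 1e-3

    def test_constant_curve_fit_bias_only(self, stimulus_set, stimulus_features_36):
        rates = np.full(36, 40.0)
        fit = fit_cosine_lif(TuningCurve(stimulus_set, rates), stimulus_features_36,
                             n_restarts=30, seed=0, stop_sse=1e-10)
        assert fit.error_sd < 1e-3

    def test_all_zero_curve(self, stimulus_set, stimulus_features_36):
        fit = fit_cosine_lif(TuningCurve(stimulus_set, np.zeros(36)), stimulus_features_36,
                             n_restarts=10, seed=0, stop_sse=1e-12)
        assert np.all(fit.model_rates == 0)

    def test_best_of_restarts_monotone(self, stimulus_set, stimulus_features_36, standardized):
        rng = np.random.default_rng(3)
        rates = plant_neuron(standardized, rng)
        curve = TuningCurve(stimulus_set, rates)
        sse = [fit_cosine_lif(curve, stimulus_features_36, n_restarts=n, seed=9).sse
               for n in (1, 5, 25)]
        assert sse[0] >= sse[1] >= sse[2]

    def test_size_invariant_curve_suppresses_size_drive(
            self, stimulus_set, stimulus_features_36):
        """Cosine tuning can express size invariance by shrinking the
        drive from the scale features: fits to size-invariant targets
        show much weaker size modulation than fits to size-selective
        versions of the same profile."""
        X = stimulus_features_36
        stats = {}
        for mode in ("invariant", "monotone"):
            tc = augment([10, 20, 30, 45], AugmentationSpec(size_mode=mode), stimulus_set)
            fit = fit_cosine_lif(tc, X, n_restarts=100, seed=1)
            spreads = [
                np.ptp(fit.model_rates[m])
                for s in range(4)
                for o in set(stimulus_set.orient_id)
                if (m := (stimulus_set.shape_id == s) & (stimulus_set.orient_id == o)).sum() > 1
            ]
            phi = fit.neuron.phi
            stats[mode] = (max(spreads), np.std(X[:, :3] @ phi[:3]), np.ptp(tc.rates))
        inv, mono = stats["invariant"], stats["monotone"]
        assert inv[0] < 0.5 * mono[0]       # size modulation of fitted rates
        assert inv[1] < 0.5 * mono[1]       # drive through the scale features
        assert inv[0] < 0.15 * inv[2]       # near-invariant in absolute terms

    def test_noisy_mode_fits(self, stimulus_set, stimulus_features_36, standardized):
        table = build_noisy_table(I_grid=np.arange(0.0, 4.05, 0.1),
                                  sigma_grid=np.array([1e-6, 0.25, 0.5, 1.0]),
                                  duration=1.0, seed=0)
        rng = np.random.default_rng(1)
        rates = plant_neuron(standardized, rng)
        fit = fit_cosine_lif(TuningCurve(stimulus_set, rates), stimulus_features_36,
                             n_restarts=20, noise_mode="on", table=table, seed=0)
        assert fit.neuron.sigma_noise > 0
        assert np.corrcoef(fit.model_rates, rates)[0, 1] > 0.9

    def test_restart_count_validated(self, stimulus_set, stimulus_features_36):
        with pytest.raises(ValueError):
            fit_cosine_lif(TuningCurve(stimulus_set, np.ones(36)),
                           stimulus_features_36, n_restarts=0)


class TestErrorStats:
    def test_perfect_fit(self, stimulus_set, stimulus_features_36):
        fit = fit_cosine_lif(TuningCurve(stimulus_set, np.zeros(36)),
                             stimulus_features_36, n_restarts=5, stop_sse=1e-12)
        mean, sd = error_stats(fit)
        assert mean == 0 and sd == 0

    def test_hand_arithmetic(self):
        class Dummy:
            errors = np.array([1.0, -1.0])

        mean, sd = error_stats(Dummy())
        assert mean == 0.0
        assert sd == pytest.approx(np.sqrt(2))


class TestLeveneTest:
    def test_identical_groups_zero(self):
        W, p, dfs = levene_test([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert W == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_scipy_oracle(self):
        a = np.array([1.0, 2, 3, 4])
        b = np.array([2.0, 4, 6, 8])
        W, p, dfs = levene_test(a, b)
        ref = stats.levene(a, b, center="mean")
        assert W == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_degrees_of_freedom(self):
        rng = np.random.default_rng(0)
        W, p, dfs = levene_test(rng.normal(0, 1, 456), rng.normal(0, 2, 456))
        assert dfs == (1, 910)

    def test_degenerate_failure(self):
        with pytest.raises(ValueError):
            levene_test([1.0, 1.0, 1.0], [2.0, 2.0])
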