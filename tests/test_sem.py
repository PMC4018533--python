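import numpy as np
import pytest

from phasesync import (
    FrequencyGrid,
    ModelSpec,
    compare_models,
    enumerate_loop_models,
    extract_band_signal,
    fit_loop_model,
    fit_loop_model_cov,
    fit_pairwise,
    morlet_transform,
    rmsea_from_chi2,
    simulate_loop_data,
)
from phasesync.exceptions import ModelSpecError, PhaseSyncError, WindowError

from conftest import make_epochs

CYCLE_1 = {("AC", "vPMC"), ("vPMC", "TPJ"), ("TPJ", "AC")}
CYCLE_2 = {("AC", "TPJ"), ("TPJ", "vPMC"), ("vPMC", "AC")}


def _find(models, edges):
    for m in models:
        if set(m.directed_edges) == edges:
            return m
    raise AssertionError(f"model {edges} not found")


class TestExtractBandSignal:
    def _tf(self, rng, n_trials=4):
        ep = make_epochs(rng.standard_normal((n_trials, 2, 700)), rois=["A", "B"])
        return morlet_transform(ep, FrequencyGrid(14, 26, 3))

    def test_single_bin_is_standardized_real_part(self, rng):
        tf = self._tf(rng)
        out = extract_band_signal(tf, (20, 20), (50, 200))
        fi = np.argmin(np.abs(tf.freqs - 20))
        tmask = (tf.times >= 50) & (tf.times < 200)
        raw = np.real(tf.coefficients[:, :, fi, :][:, :, tmask])
        expected = (raw - raw.mean(axis=2, keepdims=True)) / raw.std(axis=2, keepdims=True)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_unit_variance(self, rng):
        out = extract_band_signal(self._tf(rng), (14, 26), (50, 200))
        np.testing.assert_allclose(out.std(axis=2), 1.0, atol=1e-10)
        np.testing.assert_allclose(out.mean(axis=2), 0.0, atol=1e-10)

    def test_multi_bin_average_oracle(self, rng):
        tf = self._tf(rng)
        out = extract_band_signal(tf, (14, 20), (50, 200))
        fmask = (tf.freqs >= 14) & (tf.freqs <= 20)
        tmask = (tf.times >= 50) & (tf.times < 200)
        raw = np.real(tf.coefficients[:, :, fmask][:, :, :, tmask]).mean(axis=2)
        expected = (raw - raw.mean(axis=2, keepdims=True)) / raw.std(axis=2, keepdims=True)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_empty_range_raises(self, rng):
        tf = self._tf(rng)
        with pytest.raises(WindowError):
            extract_band_signal(tf, (200, 300), (50, 200))
        with pytest.raises(WindowError):
            extract_band_signal(tf, (14, 26), (600, 700))


class TestFitPairwise:
    def _planted(self, rng, n_subjects=20, n_trials=30, n_samples=80, lag=3, beta=0.8):
        a = rng.standard_normal((n_subjects, n_trials, n_samples))
        noise = 0.3 * rng.standard_normal((n_subjects, n_trials, n_samples))
        b = noise.copy()
        b[:, :, lag:] += beta * a[:, :, :-lag]
        return a, b

    def test_planted_coefficient_recovery(self, rng):
        # oracle: B(t) = 0.8 A(t - lag) + noise, A white
        a, b = self._planted(rng)
        res = fit_pairwise(a, b, lag=3, n_boot=200, n_perm=1000, seed=0)
        assert res.beta_ab.mean() == pytest.approx(0.8, abs=0.05)
        assert abs(res.beta_ba.mean()) < 0.1
        assert res.p_value < 0.05
        # bootstrap CIs bracket the planted value for most subjects
        covered = ((res.ci_ab[:, 0] <= 0.8) & (0.8 <= res.ci_ab[:, 1])).mean()
        assert covered >= 0.8

    def test_directionality_power(self, rng):
        # power >= 0.9: correct, significant direction in >= 18/20 replicates
        wins = 0
        for rep in range(20):
            a, b = self._planted(rng, n_subjects=20)
            res = fit_pairwise(a, b, lag=3, n_boot=50, n_perm=500, seed=rep)
            if res.p_value < 0.05 and res.beta_ab.mean() > res.beta_ba.mean():
                wins += 1
        assert wins >= 18

    def test_symmetric_coupling_type_one_rate(self, rng):
        # oracle: shared zero-lag source -> no spurious directionality
        rejections = 0
        n_reps = 50
        for rep in range(n_reps):
            shared = rng.standard_normal((10, 20, 60))
            a = shared + 0.5 * rng.standard_normal((10, 20, 60))
            b = shared + 0.5 * rng.standard_normal((10, 20, 60))
            res = fit_pairwise(a, b, lag=2, n_boot=20, n_perm=300, seed=rep)
            rejections += res.p_value < 0.05
        assert rejections <= 8  # binomial(50, 0.05) upper band

    def test_independent_signals_centered_at_zero(self, rng):
        a = rng.standard_normal((15, 30, 80))
        b = rng.standard_normal((15, 30, 80))
        res = fit_pairwise(a, b, lag=3, n_boot=20, n_perm=200, seed=0)
        assert abs(res.beta_ab.mean()) < 0.05
        assert abs(res.beta_ba.mean()) < 0.05

    def test_zero_variance_regressor_raises(self):
        a = np.zeros((2, 5, 20))
        b = np.ones((2, 5, 20))
        with pytest.raises(PhaseSyncError):
            fit_pairwise(a, b, lag=2, n_boot=10, n_perm=10)

    def test_lag_too_long_raises(self, rng):
        a = rng.standard_normal((2, 5, 20))
        with pytest.raises(WindowError):
            fit_pairwise(a, a, lag=20, n_boot=10, n_perm=10)


class TestEnumerateLoopModels:
    def test_three_nodes_eight_models(self):
        # 3 undirected edges, one direction each -> 2^3 = 8 candidate models
        models = enumerate_loop_models(("AC", "TPJ", "vPMC"))
        assert len(models) == 8
        labels = {frozenset(m.directed_edges) for m in models}
        assert len(labels) == 8

    def test_contains_both_cyclic_orderings(self):
        # both cyclic orderings AC->vPMC->TPJ->AC and AC->TPJ->vPMC->AC appear
        models = enumerate_loop_models(("AC", "TPJ", "vPMC"))
        _find(models, CYCLE_1)
        _find(models, CYCLE_2)

    def test_two_nodes_two_models(self):
        models = enumerate_loop_models(("X", "Y"))
        assert len(models) == 2
        assert {m.directed_edges[0] for m in models} == {("X", "Y"), ("Y", "X")}

    def test_every_edge_single_direction(self):
        for m in enumerate_loop_models(("A", "B", "C")):
            assert len(m.directed_edges) == 3
            undirected = {frozenset(e) for e in m.directed_edges}
            assert len(undirected) == 3

    def test_invalid_edge_rejected(self):
        with pytest.raises(ModelSpecError):
            ModelSpec(nodes=("A", "B"), directed_edges=(("A", "C"),))
        with pytest.raises(ModelSpecError):
            ModelSpec(nodes=("A", "B"), directed_edges=(("A", "A"),))


class TestFitLoopModel:
    def test_rmsea_hand_formula(self):
        # oracle: chi2 = 30, df = 9, n = 120 -> sqrt(21 / (9 * 119))
        assert rmsea_from_chi2(30, 9, 120) == pytest.approx(
            np.sqrt(21 / (9 * 119)), abs=1e-12
        )
        assert rmsea_from_chi2(30, 9, 120) == pytest.approx(0.140028, abs=1e-6)

    def test_chi2_below_df_floors_rmsea_at_zero(self):
        assert rmsea_from_chi2(5.0, 9, 100) == 0.0

    def test_analytic_covariance_oracle(self):
        # oracle: implied-covariance construction -> exact beta recovery
        model = _find(enumerate_loop_models(("A", "B", "C")),
                      {("A", "B"), ("B", "C"), ("C", "A")})
        beta = {("A", "B"): 0.6, ("B", "C"): 0.4, ("C", "A"): 0.5}
        idx = {"A": 0, "B": 1, "C": 2}
        B = np.zeros((3, 3))
        for (s, d), v in beta.items():
            B[idx[d], idx[s]] = v
        phi = np.array([[1.0, 0.2, 0.1], [0.2, 1.5, 0.3], [0.1, 0.3, 0.8]])
        psi = np.diag([1.0, 0.9, 1.1])
        syy = B @ phi @ B.T + psi
        syx = B @ phi
        S = np.block([[syy, syx], [syx.T, phi]])
        fit = fit_loop_model_cov(model, S, n_effective=120)
        for edge, v in beta.items():
            assert fit.beta[edge] == pytest.approx(v, abs=1e-3)
        assert fit.chi_square == pytest.approx(0.0, abs=1e-6)
        assert fit.rmsea == 0.0
        assert fit.df == 9

    def test_generating_model_good_fit(self):
        # RMSEA < 0.07 is the good-fit cutoff
        model = _find(enumerate_loop_models(("AC", "TPJ", "vPMC")), CYCLE_1)
        data = simulate_loop_data(model, beta=0.5, n_trials=500, n_samples=100, lag=5, seed=3)
        fit = fit_loop_model(model, data, lag=5, seed=3)
        assert fit.rmsea <= 0.07
        assert fit.n_effective == 500
        for v in fit.beta.values():
            assert v == pytest.approx(0.5, abs=0.05)

    def test_misdirected_model_misfits(self):
        model = _find(enumerate_loop_models(("AC", "TPJ", "vPMC")), CYCLE_1)
        wrong = _find(enumerate_loop_models(("AC", "TPJ", "vPMC")), CYCLE_2)
        data = simulate_loop_data(model, beta=0.5, n_trials=500, n_samples=100, lag=5, seed=4)
        assert fit_loop_model(wrong, data, lag=5).rmsea > 0.07

    def test_df_always_nine_across_models(self, rng):
        data = rng.standard_normal((50, 3, 60))
        for m in enumerate_loop_models(("A", "B", "C")):
            assert fit_loop_model(m, data, lag=4).df == 9

    def test_json_roundtrip(self):
        import json

        model = _find(enumerate_loop_models(("AC", "TPJ", "vPMC")), CYCLE_1)
        data = simulate_loop_data(model, n_trials=100, n_samples=60, lag=4, seed=0)
        fit = fit_loop_model(model, data, lag=4)
        parsed = json.loads(fit.to_json())
        assert parsed["df"] == 9
        assert len(parsed["beta"]) == 3


class TestCompareModels:
    def test_single_model_passthrough(self):
        model = enumerate_loop_models(("A", "B", "C"))[0]
        data = simulate_loop_data(model, n_trials=100, n_samples=60, lag=4, seed=0)
        fit = fit_loop_model(model, data, lag=4)
        table = compare_models([fit])
        assert len(table) == 1
        assert table["model"].iloc[0] == model.label()

    def test_generating_model_ranks_first(self):
        # Monte-Carlo: >= 9/10 replicates put the generator on top
        models = enumerate_loop_models(("AC", "TPJ", "vPMC"))
        gen = _find(models, CYCLE_1)
        wins = 0
        for rep in range(10):
            data = simulate_loop_data(gen, beta=0.5, n_trials=300, n_samples=80, lag=4, seed=rep)
            fits = [fit_loop_model(m, data, lag=4) for m in models]
            table = compare_models(fits)
            if table["model"].iloc[0] == gen.label():
                wins += 1
        assert wins >= 9

    def test_shared_noise_gives_no_good_fit_flags(self, rng):
        # zero-lag common input violates every directed-lag model
        models = enumerate_loop_models(("A", "B", "C"))
        shared = rng.standard_normal((300, 1, 80))
        data = shared + 0.3 * rng.standard_normal((300, 3, 80))
        fits = [fit_loop_model(m, data, lag=4) for m in models]
        table = compare_models(fits)
        assert not table["good_fit"].any()

    def test_rmsea_shrinks_with_trials_for_generator_only(self):
        models = enumerate_loop_models(("AC", "TPJ", "vPMC"))
        gen = _find(models, CYCLE_1)
        wrong = _find(models, CYCLE_2)
        gen_rmsea, wrong_rmsea = [], []
        for n in (50, 200, 800):
            data = simulate_loop_data(gen, beta=0.5, n_trials=n, n_samples=80, lag=4, seed=7)
            gen_rmsea.append(fit_loop_model(gen, data, lag=4).rmsea)
            wrong_rmsea.append(fit_loop_model(wrong, data, lag=4).rmsea)
        assert gen_rmsea[-1] <= 0.03
        assert all(w > 0.07 for w in wrong_rmsea)
        assert all(g < w for g, w in zip(gen_rmsea, wrong_rmsea))

    def test_multi_subject_mean_and_sd(self):
        model = enumerate_loop_models(("A", "B", "C"))[0]
        fits = []
        for s in range(3):
            data = simulate_loop_data(model, n_trials=150, n_samples=60, lag=4, seed=s)
            fits.append(fit_loop_model(model, data, lag=4))
        table = compare_models([fits])
        assert table["n_subjects"].iloc[0] == 3
        assert table["sd_rmsea"].iloc[0] >= 0.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            compare_models([])
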