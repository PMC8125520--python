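import numpy as np
import pytest

import anthospec as asp
from anthospec.evaluate import (
    FoldAssignment, ModelSpec, absorbance_difference_feature,
    correlation_spectrum, cross_validate, make_folds, prediction_intervals,
    score_predictions,
)
from anthospec.simulate import GeneratorConfig, PigmentPrior, generate_dataset
from anthospec.spectra import (LeafSample, PigmentProfile, SpectralDataset,
                               SpectralGrid)


class TestFolds:
    def test_210_into_10_gives_21_each(self):
        f = make_folds(210, 10, seed=0)
        counts = np.bincount(f.labels)[1:]
        assert list(counts) == [21] * 10

    def test_remainder_rule(self):
        f = make_folds(11, 10, seed=0)
        counts = sorted(np.bincount(f.labels)[1:])
        assert counts == [1] * 9 + [2]

    def test_determinism_and_roundtrip(self, tmp_path):
        a = make_folds(50, 10, seed=3)
        b = make_folds(50, 10, seed=3)
        np.testing.assert_array_equal(a.labels, b.labels)
        p = tmp_path / "folds.json"
        a.to_json(p)
        c = FoldAssignment.from_json(p)
        np.testing.assert_array_equal(a.labels, c.labels)
        assert (c.k, c.seed) == (10, 3)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            make_folds(5, 10, seed=0)

    def test_every_sample_assigned_once(self):
        f = make_folds(47, 10, seed=1)
        covered = np.zeros(47, dtype=int)
        for g in range(1, 11):
            _, te = f.split(g)
            covered += te
        assert np.all(covered == 1)


class TestScoring:
    def test_identity(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        s = score_predictions(y, y)
        assert s.r2 == pytest.approx(1.0)
        assert s.rmse == pytest.approx(0.0)

    def test_constant_offset(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        s = score_predictions(y, y + 1)
        assert s.r2 == pytest.approx(1.0)
        assert s.rmse == pytest.approx(1.0)

    def test_reversal_matches_correlation_oracle(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        pred = y[::-1].copy()
        s = score_predictions(y, pred)
        assert s.r2 == pytest.approx(np.corrcoef(y, pred)[0, 1] ** 2)

    def test_r2_is_symmetric(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=20), rng.normal(size=20)
        assert score_predictions(a, b).r2 == pytest.approx(
            score_predictions(b, a).r2)

    def test_confidence_interval_brackets_slope(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=200)
        s = score_predictions(y, 2 * y + rng.normal(0, 0.1, 200))
        lo, hi = s.slope_ci
        assert lo < 2.0 < hi or abs(s.slope - 2.0) < 0.05

    def test_constant_measured_rejected(self):
        with pytest.raises(ValueError):
            score_predictions(np.ones(5), np.arange(5.0))


def _linear_dataset(n=60, seed=0, noise=0.0):
    """Absorbance dataset whose single channel is exactly linear in content."""
    rng = np.random.default_rng(seed)
    y = rng.uniform(1, 30, n)
    grid = SpectralGrid(np.array([550.0, 700.0]))
    X = np.c_[0.05 * y + rng.normal(0, noise, n), rng.normal(1, 0.1, n)]
    samples = tuple(
        LeafSample(f"s{i}", PigmentProfile(10.0, float(y[i]), 3.0), X[i])
        for i in range(n))
    return SpectralDataset(grid, samples, "absorbance")


class TestCrossValidate:
    @pytest.mark.parametrize("engine,kwargs", [
        ("plsr", {"n_components": 1}),
        ("gpr", {"n_restarts": 1}),
    ])
    def test_noiseless_linear_signal_is_recovered(self, engine, kwargs):
        ds = _linear_dataset()
        folds = make_folds(len(ds), 10, 0)
        spec = ModelSpec(engine, (550.0, 700.0), transform="reflectance",
                         seed=0, **kwargs)
        cv = cross_validate(ds, spec, folds)
        assert cv.mean_val_r2 > 0.999

    def test_permuted_responses_score_near_zero(self):
        # folds of 20: the null expectation of a squared correlation over a
        # k-point fold is 1/(k-1), so tiny folds would not read as ~0
        scores = []
        for seed in range(20):
            ds = _linear_dataset(n=100, seed=seed, noise=0.01)
            rng = np.random.default_rng(seed + 1000)
            perm = rng.permutation(len(ds))
            shuffled = SpectralDataset(
                ds.grid,
                tuple(
                    LeafSample(s.id, ds.samples[perm[i]].profile, s.spectrum)
                    for i, s in enumerate(ds.samples)),
                ds.representation)
            spec = ModelSpec("plsr", (550.0, 700.0), transform="reflectance",
                             n_components=1, seed=seed)
            cv = cross_validate(shuffled, spec, make_folds(len(ds), 5, seed))
            scores.append(cv.mean_val_r2)
        assert np.mean(scores) < 0.1

    def test_determinism(self, default_dataset, default_folds):
        spec = ModelSpec("gpr", (555.0, 705.0), n_restarts=1, seed=5)
        a = cross_validate(default_dataset, spec, default_folds)
        b = cross_validate(default_dataset, spec, default_folds)
        np.testing.assert_array_equal(a.val_r2, b.val_r2)
        np.testing.assert_array_equal(a.predicted, b.predicted)

    def test_each_sample_validated_exactly_once(self):
        ds = _linear_dataset(n=37)
        spec = ModelSpec("plsr", (550.0, 700.0), transform="reflectance",
                         n_components=1)
        cv = cross_validate(ds, spec, make_folds(len(ds), 10, 2))
        assert np.all(np.isfinite(cv.predicted))
        assert cv.predicted.size == len(ds)


class TestCorrelationSpectrum:
    def test_channel_equal_to_content_has_unit_r(self):
        ds = _linear_dataset(noise=0.0)
        wl, r, flags = correlation_spectrum(ds, "reflectance")
        assert r[0] == pytest.approx(1.0)
        assert not flags.any()

    def test_green_peak_on_default_data(self, default_dataset):
        wl, r, _ = correlation_spectrum(default_dataset, "log1r")
        assert 520 <= wl[np.argmax(np.abs(r))] <= 580

    def test_log_transform_flips_sign_at_green_peak(self, default_dataset):
        _, r_refl, _ = correlation_spectrum(default_dataset, "reflectance")
        _, r_abs, _ = correlation_spectrum(default_dataset, "log1r")
        i = default_dataset.grid.index_of(550)
        assert np.sign(r_refl[i]) == -np.sign(r_abs[i])

    def test_constant_channel_flagged(self):
        grid = SpectralGrid(np.array([500.0, 501.0]))
        samples = tuple(
            LeafSample(f"s{i}", PigmentProfile(1.0, float(i + 1), 1.0),
                       np.array([0.5, 0.1 * (i + 1)]))
            for i in range(5))
        ds = SpectralDataset(grid, samples, "reflectance")
        _, r, flags = correlation_spectrum(ds, "reflectance")
        assert flags[0] and r[0] == 0.0


class TestAbsorbanceDifference:
    def test_equal_channels_give_zero(self):
        grid = SpectralGrid.from_range(550, 710, 1.0)
        spec = np.full(len(grid), 0.3)
        ds = SpectralDataset(
            grid, (LeafSample("x", PigmentProfile(1.0, 1.0), spec),),
            "reflectance")
        assert absorbance_difference_feature(ds)[0] == pytest.approx(0.0)

    def test_hand_computed_value(self):
        grid = SpectralGrid(np.array([550.0, 708.0]))
        ds = SpectralDataset(
            grid, (LeafSample("x", PigmentProfile(1.0, 1.0),
                              np.array([0.1, 0.5])),),
            "reflectance")
        assert absorbance_difference_feature(ds)[0] == pytest.approx(
            1.0 - 0.30103, abs=1e-5)

    def test_gpr_beats_linear_fit_on_saturating_feature(self):
        """One-dimensional GPR on the green/red-edge absorbance difference
        outperforms the straight line once absorbance saturates in content."""
        wins = 0
        for seed in range(10):
            ds = generate_dataset(GeneratorConfig(n=120, seed=seed))
            feat = absorbance_difference_feature(ds)
            y = ds.contents("anth")
            folds = make_folds(len(ds), 5, seed)
            rmse_lin, rmse_gpr = [], []
            for g in range(1, 6):
                tr, te = folds.split(g)
                coef = np.polyfit(feat[tr], y[tr], 1)
                rmse_lin.append(np.sqrt(np.mean(
                    (np.polyval(coef, feat[te]) - y[te]) ** 2)))
                m = asp.fit_gpr(feat[tr, None], y[tr], n_restarts=1, seed=seed)
                pred = asp.predict_gpr(m, feat[te, None])
                rmse_gpr.append(np.sqrt(np.mean((pred.mean - y[te]) ** 2)))
            if np.mean(rmse_gpr) < np.mean(rmse_lin):
                wins += 1
        assert wins >= 8


class TestPredictionIntervals:
    def test_training_point_with_tiny_noise_has_tiny_sd(self):
        rng = np.random.default_rng(0)
        S = rng.normal(size=(10, 1))
        z = np.sin(S[:, 0])
        from anthospec.gpr import GPRHyper, fit_gpr
        m = fit_gpr(S, z, init=GPRHyper(1.0, np.array([1.0]), 1e-4),
                    n_restarts=0, max_iter=0, seed=0)
        _, sd = prediction_intervals(m, S)
        assert np.all(sd < 0.05)

    def test_far_query_sd_near_signal_sd(self):
        rng = np.random.default_rng(1)
        S = rng.normal(size=(10, 1))
        z = rng.normal(size=10)
        m = asp.fit_gpr(S, z, n_restarts=1, seed=0)
        _, sd = prediction_intervals(m, np.array([[1e5]]))
        assert sd[0] == pytest.approx(m.hyper.sigma_f, rel=1e-6)
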