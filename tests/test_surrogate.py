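import hashlib

import numpy as np
import pytest

from emuflux.emu import EMU, decompose
from emuflux.fixtures import full_emu_targets
from emuflux.sampling import sample_concentrations, sample_flux_space
from emuflux.surrogate import (
    Standardiser,
    SurrogateEnsemble,
    SurrogateSpec,
    build_training_table,
    simulate_training_set,
    train_ensemble,
    train_surrogate,
    validate_ensemble,
)


@pytest.fixture(scope="module")
def washout_samples(washout_net):
    emu_net = decompose(washout_net, full_emu_targets(washout_net))
    fs = sample_flux_space(washout_net, 2000, seed=41)
    cs = sample_concentrations(washout_net, 2000, seed=42)
    trajs = simulate_training_set(emu_net, fs, cs, [1.0])
    return emu_net, fs, cs, trajs


@pytest.fixture(scope="module")
def toy_ensemble(toy_sc):
    """A small trained ensemble shared by the prediction tests."""
    fs = sample_flux_space(toy_sc.network, 300, seed=51)
    cs = sample_concentrations(toy_sc.network, 300, seed=52)
    trajs = simulate_training_set(toy_sc.emu_network, fs, cs, toy_sc.timepoints)
    spec = SurrogateSpec(epochs=30, seed=5)
    ens = train_ensemble(
        toy_sc.emu_network, fs, cs, toy_sc.timepoints,
        target_emus=toy_sc.measured_emus, spec=spec, trajectories=trajs,
    )
    return ens, fs, cs, trajs


class TestTrainingTable:
    def test_shapes(self, washout_samples):
        emu_net, fs, cs, trajs = washout_samples
        emu = EMU("B[c]", (1,))
        X, Y, _ = build_training_table(fs, cs, trajs, emu, 1.0)
        # inputs: split flux columns then pools; targets: M+0..M+size
        assert X.shape == (2000, 2 + 1)
        assert Y.shape == (2000, 2)

    def test_standardise_round_trip(self, washout_samples):
        emu_net, fs, cs, trajs = washout_samples
        X, _, std = build_training_table(fs, cs, trajs, EMU("B[c]", (1,)), 1.0)
        assert np.allclose(std.inverse(X), std.inverse(std.transform(std.inverse(X))), atol=1e-12)

    def test_zero_variance_feature_is_safe(self):
        X = np.column_stack([np.ones(20), np.arange(20.0)])
        std = Standardiser.fit(X)
        Z = std.transform(X)
        assert np.all(np.isfinite(Z))
        assert np.allclose(std.inverse(Z), X, atol=1e-12)

    def test_missing_timepoint_errors(self, washout_samples):
        emu_net, fs, cs, trajs = washout_samples
        with pytest.raises(KeyError):
            build_training_table(fs, cs, trajs, EMU("B[c]", (1,)), 99.0)


def _weights_hash(surrogate):
    h = hashlib.sha256()
    for w in surrogate.regressor.coefs_ + surrogate.regressor.intercepts_:
        h.update(np.ascontiguousarray(w).tobytes())
    return h.hexdigest()


class TestTraining:
    def test_constant_target_learned_closely(self):
        # minibatch adam leaves interpolation jitter of a few 1e-3, so
        # "learned" here means orders of magnitude below the target scale
        rng = np.random.default_rng(0)
        X = rng.normal(size=(1000, 4))
        Y = np.tile([1.0, 0.0, 0.0], (1000, 1))
        spec = SurrogateSpec(epochs=200, seed=1)
        m = train_surrogate(spec, X, Y, EMU("M", (1, 2)), 1.0, Standardiser.fit(X))
        assert m.holdout_sd < 1e-2
        assert m.final_loss < m.initial_loss

    def test_washout_family_learned_against_closed_form(self, washout_samples):
        # target surface is the closed form 1 - exp(-v t / c); the surrogate
        # must sit far below the signal spread (pool ratios span v/c up to
        # 100, so the surface is steep and 2000 samples leave ~2e-2 error)
        emu_net, fs, cs, trajs = washout_samples
        X, Y, std = build_training_table(fs, cs, trajs, EMU("B[c]", (1,)), 1.0)
        m = train_surrogate(SurrogateSpec(epochs=200, seed=2), X, Y, EMU("B[c]", (1,)), 1.0, std)
        assert m.holdout_sd < 0.025
        assert m.holdout_sd < 0.1 * Y.std()
        assert m.final_loss < m.initial_loss
        # spot check against the closed form itself
        raw = std.inverse(X[:20])
        closed = 1.0 - np.exp(-raw[:, 0] / np.exp(raw[:, 2]))
        pred = m.predict_raw(X[:20])[:, 1]
        assert np.abs(pred - closed).mean() < 0.03

    def test_same_seed_reproduces_identical_weights(self, washout_samples):
        emu_net, fs, cs, trajs = washout_samples
        X, Y, std = build_training_table(fs, cs, trajs, EMU("B[c]", (1,)), 1.0)
        spec = SurrogateSpec(epochs=20, seed=9)
        a = train_surrogate(spec, X, Y, EMU("B[c]", (1,)), 1.0, std)
        b = train_surrogate(spec, X, Y, EMU("B[c]", (1,)), 1.0, std)
        assert _weights_hash(a) == _weights_hash(b)

    def test_too_few_rows_rejected(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError, match="10"):
            train_surrogate(SurrogateSpec(), X, X, EMU("M", (1,)), 0.5, Standardiser.fit(X))


class TestEnsemblePrediction:
    def test_grid_complete_and_sd_table_shape(self, toy_ensemble, toy_sc):
        ens, *_ = toy_ensemble
        table = ens.holdout_sd_table()
        assert len(table) == len(toy_sc.measured_emus) * len(toy_sc.timepoints)
        assert set(ens.grid) == {
            (e.id, t) for e in toy_sc.measured_emus for t in toy_sc.timepoints
        }

    def test_predictions_on_simplex(self, toy_ensemble, toy_sc):
        ens, fs, cs, _ = toy_ensemble
        pred = ens.predict(fs[0].w, cs[0].as_dict())
        for mid in pred.values():
            assert np.all(mid >= 0)
            assert np.isclose(mid.sum(), 1.0)

    def test_in_sample_predictions_close_to_simulation(self, toy_ensemble):
        ens, fs, cs, trajs = toy_ensemble
        hits = total = 0
        for f, c, tr in zip(fs[:50], cs[:50], trajs[:50]):
            pred = ens.predict(f.w, c.as_dict())
            for (emu_id, t), mid in pred.items():
                truth = tr[emu_id].at(t)
                sd = ens.members[(emu_id, t)].holdout_sd
                hits += np.max(np.abs(mid - truth)) <= 4 * max(sd, 1e-3)
                total += 1
        assert hits / total >= 0.95

    def test_out_of_domain_flag(self, toy_ensemble, toy_sc):
        ens, fs, cs, _ = toy_ensemble
        w_out = np.full_like(fs[0].w, 1e4)
        ens.predict(w_out, cs[0].as_dict())
        assert ens.last_out_of_domain
        ens.predict(fs[0].w, cs[0].as_dict())
        assert not ens.last_out_of_domain

    def test_save_load_round_trip(self, toy_ensemble, toy_sc, tmp_path):
        ens, fs, cs, _ = toy_ensemble
        ens.save(tmp_path / "ens.joblib")
        loaded = SurrogateEnsemble.load(tmp_path / "ens.joblib")
        a = ens.predict(fs[0].w, cs[0].as_dict())
        b = loaded.predict(fs[0].w, cs[0].as_dict())
        for key in a:
            assert np.array_equal(a[key], b[key])


class TestValidation:
    def test_fresh_samples_report(self, toy_ensemble, toy_sc):
        ens, *_ = toy_ensemble
        fs = sample_flux_space(toy_sc.network, 40, seed=61)
        cs = sample_concentrations(toy_sc.network, 40, seed=62)
        trajs = simulate_training_set(toy_sc.emu_network, fs, cs, toy_sc.timepoints)
        report = validate_ensemble(ens, fs, cs, trajs)
        assert len(report) == len(ens.grid)
        assert np.all(report["sd"] >= 0)
        assert np.isfinite(report.attrs["median_sd"])

    def test_overlap_with_training_set_rejected(self, toy_ensemble, toy_sc):
        ens, fs, cs, trajs = toy_ensemble
        with pytest.raises(ValueError, match="overlap"):
            validate_ensemble(ens, fs[:3], cs[:3], trajs[:3])

    def test_perfect_predictor_scores_zero_sd(self, toy_sc, toy_oracle):
        # inject the exact simulator as a mock ensemble member set
        class Oracle:
            grid = [(e.id, t) for e in toy_sc.measured_emus for t in toy_sc.timepoints]
            provenance = {}

            def predict(self, w, conc):
                full = toy_oracle.predict(w, conc)
                return {k: full[k] for k in self.grid}

        fs = sample_flux_space(toy_sc.network, 5, seed=71)
        cs = sample_concentrations(toy_sc.network, 5, seed=72)
        trajs = simulate_training_set(toy_sc.emu_network, fs, cs, toy_sc.timepoints)
        report = validate_ensemble(Oracle(), fs, cs, trajs)
        assert np.all(report["sd"] < 1e-12)
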