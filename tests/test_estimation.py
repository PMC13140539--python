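import numpy as np
import pytest

from emuflux.measurements import MeasurementError, MeasurementSet
from emuflux.model import (
    InstMfaModel,
    degrees_of_freedom,
    goodness_of_fit,
    weighted_residuals,
)


class TestWeightedResiduals:
    def _measurements(self):
        rows = [
            ("B[c]:1", 1.0, 0, 0.4, 0.01),
            ("B[c]:1", 1.0, 1, 0.6, 0.01),
        ]
        return MeasurementSet.from_records(rows)

    def test_zero_when_prediction_matches(self):
        meas = self._measurements()
        pred = {("B[c]:1", 1.0): np.array([0.4, 0.6])}
        assert np.allclose(weighted_residuals(pred, meas), 0.0)

    def test_unit_residual_at_one_sd(self):
        meas = MeasurementSet.from_records([("X:1", 1.0, 0, 0.5, 0.02), ("X:1", 1.0, 1, 0.5, 0.02)])
        pred = {("X:1", 1.0): np.array([0.52, 0.5])}
        r = weighted_residuals(pred, meas)
        assert np.allclose(r, [1.0, 0.0])

    def test_record_order_permutes_residuals(self):
        rows = [
            ("X:1", 1.0, 0, 0.3, 0.01),
            ("X:1", 1.0, 1, 0.7, 0.01),
            ("X:1", 2.0, 0, 0.2, 0.02),
            ("X:1", 2.0, 1, 0.8, 0.02),
        ]
        pred = {("X:1", 1.0): np.array([0.35, 0.65]), ("X:1", 2.0): np.array([0.25, 0.75])}
        r1 = weighted_residuals(pred, MeasurementSet.from_records(rows))
        r2 = weighted_residuals(pred, MeasurementSet.from_records(rows[::-1]))
        assert np.allclose(r1, r2[::-1])

    def test_missing_prediction_names_record(self):
        meas = self._measurements()
        with pytest.raises(MeasurementError, match="B\\[c\\]:1"):
            weighted_residuals({}, meas)


class TestMeasurementValidation:
    def test_zero_sd_rejected(self):
        with pytest.raises(MeasurementError, match="sd"):
            MeasurementSet.from_records([("X:1", 1.0, 0, 0.5, 0.0), ("X:1", 1.0, 1, 0.5, 0.01)])

    def test_mid_sum_tolerance(self):
        with pytest.raises(MeasurementError, match="sums to"):
            MeasurementSet.from_records([("X:1", 1.0, 0, 0.5, 0.01), ("X:1", 1.0, 1, 0.6, 0.01)])

    def test_csv_round_trip(self, tmp_path, toy_sc):
        meas = toy_sc.measurements(seed=3)
        meas.to_csv(tmp_path / "m.csv")
        again = MeasurementSet.from_csv(tmp_path / "m.csv")
        assert np.allclose(meas.frame["value"], again.frame["value"])


class TestDegreesOfFreedom:
    def test_headline_bookkeeping(self):
        assert degrees_of_freedom(2040, 853) == 1187

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError, match="dof"):
            degrees_of_freedom(10, 10)

    def test_no_free_parameters(self):
        assert degrees_of_freedom(7, 0) == 7


class TestGoodnessOfFit:
    def test_unit_L_accepted_at_large_dof(self):
        assert goodness_of_fit(1.0, 1000, 0.05).accept

    def test_zero_L_flags_overfit(self):
        g = goodness_of_fit(0.0, 10, 0.05)
        assert not g.accept and g.overfit

    def test_alpha_one_always_rejects(self):
        assert not goodness_of_fit(1.0, 10, 1.0).accept


class TestOracleFit:
    def test_noiseless_recovery_on_toy(self, toy_sc, toy_oracle):
        meas = toy_sc.measurements(seed=1)  # noise_sd stored but we want exact:
        sc = toy_sc
        exact = sc.measurements(seed=1, renormalise=False)
        # rebuild noiseless records from the exact simulation
        import emuflux.fixtures as fx

        noiseless_sc = fx.toy_scenario(seed=sc.seed, noise_sd=0.0)
        meas = noiseless_sc.measurements()
        model = InstMfaModel(
            sc.network, meas, toy_oracle, concentrations=sc.true_conc.as_dict()
        )
        res = model.fit(n_starts=3, seed=2)
        assert res.converged
        assert res.ssr < 1e-6
        assert np.allclose(res.v_hat, sc.true_flux.net, rtol=1e-4)
        # steady state and bounds hold at the optimum
        split = model.split
        assert np.max(np.abs(split.S @ res.w_hat)) < 1e-8
        assert np.all(res.w_hat >= split.lb - 1e-9)
        assert np.all(res.w_hat <= split.ub + 1e-9)

    def test_more_starts_never_worse(self, toy_sc, toy_oracle):
        meas = toy_sc.measurements(seed=4)
        model = InstMfaModel(
            toy_sc.network, meas, toy_oracle, concentrations=toy_sc.true_conc.as_dict()
        )
        starts = model._starts(6, seed=8)
        one = model.fit(start_points=starts[:1])
        many = model.fit(start_points=starts)
        assert many.ssr <= one.ssr + 1e-12

    def test_co_estimating_pools_converges(self, toy_sc, toy_oracle):
        meas = toy_sc.measurements(seed=5)
        model = InstMfaModel(toy_sc.network, meas, toy_oracle, concentrations="estimate")
        res = model.fit(n_starts=3, seed=3)
        assert res.converged
        assert res.dof == meas.n_records - model.n_free_parameters
        for mid, c in res.c_hat.items():
            lo, hi = toy_sc.network.metabolites[mid].pool_bounds
            assert lo - 1e-9 <= c <= hi + 1e-9

    def test_summary_mentions_key_statistics(self, toy_sc, toy_oracle):
        meas = toy_sc.measurements(seed=6)
        model = InstMfaModel(
            toy_sc.network, meas, toy_oracle, concentrations=toy_sc.true_conc.as_dict()
        )
        res = model.fit(n_starts=2, seed=1)
        text = res.summary()
        assert "reduced chi-square" in text
        assert "R1" in text and "R3" in text

    def test_predictor_must_cover_measured_pairs(self, toy_sc, toy_oracle):
        rows = [("Z:1", 1.0, 0, 0.5, 0.01), ("Z:1", 1.0, 1, 0.5, 0.01)]
        meas = MeasurementSet.from_records(rows)
        with pytest.raises(MeasurementError, match="cover"):
            InstMfaModel(toy_sc.network, meas, toy_oracle,
                         concentrations=toy_sc.true_conc.as_dict())

    def test_results_serialise(self, toy_sc, toy_oracle, tmp_path):
        meas = toy_sc.measurements(seed=7)
        model = InstMfaModel(
            toy_sc.network, meas, toy_oracle, concentrations=toy_sc.true_conc.as_dict()
        )
        res = model.fit(n_starts=2, seed=1)
        res.to_json(tmp_path / "fit.json")
        res.fluxes_to_csv(tmp_path / "fluxes.csv")
        import json

        blob = json.loads((tmp_path / "fit.json").read_text())
        assert set(blob["net_fluxes"]) == set(toy_sc.network.reaction_ids)
        assert blob["dof"] == res.dof
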