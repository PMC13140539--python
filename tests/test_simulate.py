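import numpy as np
import pytest

from emuflux.emu import EMU, decompose
from emuflux.fixtures import _tr, full_emu_targets, washout_network
from emuflux.network import Metabolite, Reaction, ReactionNetwork, TracerSpec
from emuflux.sampling import sample_concentrations, sample_flux_space
from emuflux.simulate import (
    SimulationError,
    build_emu_odes,
    simulate_isotopomers_bruteforce,
    simulate_mids,
    trajectories_to_frame,
)


@pytest.fixture(scope="module")
def washout_emu(washout_net):
    return decompose(washout_net, full_emu_targets(washout_net))


class TestWashoutClosedForm:
    def test_labelled_fraction_matches_exponential(self, washout_net, washout_emu):
        times = [0.1, 0.5, 1.0, 2.0, 5.0]
        trajs = simulate_mids(washout_emu, np.array([1.0, 1.0]), {"B[c]": 1.0}, times)
        expected = 1.0 - np.exp(-np.asarray(times))
        assert np.allclose(trajs["B[c]:1"].mids[:, 1], expected, atol=1e-9)

    def test_general_rate_over_pool(self, washout_net, washout_emu):
        v, c = 2.5, 0.4
        trajs = simulate_mids(washout_emu, np.array([v, v]), {"B[c]": c}, [1.0])
        assert np.isclose(trajs["B[c]:1"].mids[0, 1], 1 - np.exp(-v / c), atol=1e-9)

    def test_start_fully_unlabelled(self, washout_emu):
        trajs = simulate_mids(washout_emu, np.array([1.0, 1.0]), {"B[c]": 1.0}, [1e-10, 1.0])
        assert np.allclose(trajs["B[c]:1"].mids[0], [1.0, 0.0], atol=1e-9)


class TestODEAssembly:
    def test_balance_row_sums_vanish(self, toy_sc, rich_sc):
        for sc in (toy_sc, rich_sc):
            system = build_emu_odes(
                sc.emu_network, sc.true_flux.w, sc.true_conc.as_dict()
            )
            assert system.balance_residual() < 1e-10

    def test_drain_is_total_consumption_over_pool(self, toy_sc):
        system = build_emu_odes(toy_sc.emu_network, toy_sc.true_flux.w, toy_sc.true_conc.as_dict())
        v = toy_sc.true_flux.net[0]  # all three fluxes equal in the toy chain
        conc = toy_sc.true_conc.as_dict()
        for emu in toy_sc.emu_network.emus:
            drain = system.drain[system.offsets[emu].start]
            assert np.isclose(drain, v / conc[emu.metabolite_id])

    def test_zero_pool_rejected(self, toy_sc):
        conc = dict(toy_sc.true_conc.as_dict())
        conc["B[c]"] = 0.0
        with pytest.raises(SimulationError, match="positive pool"):
            build_emu_odes(toy_sc.emu_network, toy_sc.true_flux.w, conc)


class TestSimplexAndScaling:
    def test_mids_stay_on_simplex(self, rich_sc):
        trajs = simulate_mids(
            rich_sc.emu_network,
            rich_sc.true_flux.w,
            rich_sc.true_conc.as_dict(),
            [0.1, 1.0, 10.0],
            solver_opts={"keep_raw": True},
        )
        for tr in trajs.values():
            assert np.all(tr.mids >= 0)
            assert np.allclose(tr.mids.sum(axis=1), 1.0, atol=1e-6)
            assert np.all(tr.raw_mids >= -1e-9)

    def test_flux_scaling_compresses_time(self, toy_sc):
        k = 4.2
        base = simulate_mids(
            toy_sc.emu_network, toy_sc.true_flux.w, toy_sc.true_conc.as_dict(), [1.0]
        )
        scaled = simulate_mids(
            toy_sc.emu_network, k * toy_sc.true_flux.w, toy_sc.true_conc.as_dict(), [1.0 / k]
        )
        for emu_id in base:
            assert np.allclose(base[emu_id].mids, scaled[emu_id].mids, atol=1e-9)

    def test_stationary_state_fully_labelled(self, toy_sc):
        system = build_emu_odes(toy_sc.emu_network, toy_sc.true_flux.w, toy_sc.true_conc.as_dict())
        horizon = 50.0 * max(1.0 / system.drain[system.offsets[e].start] for e in system.emus)
        trajs = simulate_mids(
            toy_sc.emu_network, toy_sc.true_flux.w, toy_sc.true_conc.as_dict(), [horizon]
        )
        for emu in toy_sc.emu_network.emus:
            assert trajs[emu.id].mids[0, -1] > 1 - 1e-4


class TestBruteForceOracle:
    def test_one_atom_chain_matches_emu(self, washout_net, washout_emu):
        times = [0.2, 1.0, 3.0]
        w = np.array([1.3, 1.3])
        conc = {"B[c]": 0.7}
        emu_tr = simulate_mids(washout_emu, w, conc, times)
        iso = simulate_isotopomers_bruteforce(washout_net, w, conc, times)
        assert np.allclose(
            emu_tr["B[c]:1"].mids, iso["B[c]"].mid_of(EMU("B[c]", (1,))), atol=1e-8
        )

    def test_isotopomer_fractions_sum_to_one(self, rich_sc):
        iso = simulate_isotopomers_bruteforce(
            rich_sc.network, rich_sc.true_flux.w, rich_sc.true_conc.as_dict(), [0.5, 2.0]
        )
        for tr in iso.values():
            assert np.allclose(tr.fractions.sum(axis=1), 1.0, atol=1e-7)

    def test_condensation_product_rule_at_stationarity(self):
        # T(ab) feeds D(a) and E(b); D + E condense to C. With independent
        # pools at steady labelling, C's M+2 is the product of the labelled
        # fractions of its two source atoms.
        mets = {
            "T": Metabolite("T", "c", 2, (0.1, 10.0), is_boundary=True),
            "D": Metabolite("D", "c", 1, (0.1, 10.0)),
            "E": Metabolite("E", "c", 1, (0.1, 10.0)),
            "C": Metabolite("C", "c", 2, (0.1, 10.0)),
        }
        rxns = [
            Reaction("R1", {"T": -1, "D": 1, "E": 1},
                     atom_transitions=[_tr([("T", "ab")], [("D", "a"), ("E", "b")])]),
            Reaction("R2", {"D": -1, "E": -1, "C": 1},
                     atom_transitions=[_tr([("D", "a"), ("E", "b")], [("C", "ab")])]),
            Reaction("R3", {"C": -1}, atom_transitions=[_tr([("C", "ab")], [])]),
        ]
        net = ReactionNetwork(mets, rxns, TracerSpec("T", label_pattern=(0.7, 0.4)))
        w = np.ones(3)
        conc = {"D": 0.5, "E": 0.7, "C": 0.9}
        iso = simulate_isotopomers_bruteforce(net, w, conc, [200.0])
        mid = iso["C"].mid_of(EMU("C", (1, 2)))[0]
        assert np.isclose(mid[2], 0.7 * 0.4, atol=1e-6)

    def test_state_cap_guard(self, rich_sc):
        with pytest.raises(SimulationError, match="cap"):
            simulate_isotopomers_bruteforce(
                rich_sc.network,
                rich_sc.true_flux.w,
                rich_sc.true_conc.as_dict(),
                [1.0],
                state_cap=4,
            )


def test_emu_equals_marginalised_isotopomers_on_samples(toy_net, rich_net):
    """The EMU reduction's correctness oracle on both fixtures."""
    times = [0.25, 1.0, 3.0]
    for net, seed in ((toy_net, 31), (rich_net, 32)):
        emu_net = decompose(net, full_emu_targets(net))
        f = sample_flux_space(net, 1, seed=seed)[0]
        c = sample_concentrations(net, 1, seed=seed + 1)[0]
        emu_tr = simulate_mids(emu_net, f.w, c.as_dict(), times)
        iso = simulate_isotopomers_bruteforce(net, f.w, c.as_dict(), times)
        for emu in emu_net.emus:
            diff = np.abs(emu_tr[emu.id].mids - iso[emu.metabolite_id].mid_of(emu))
            assert diff.max() < 1e-6


def test_long_format_frame_matches_measurement_schema(toy_sc):
    frame = trajectories_to_frame(toy_sc.exact_trajectories())
    assert list(frame.columns) == ["emu_id", "time", "mass_shift", "fraction"]
    per_cell = frame.groupby(["emu_id", "time"])["fraction"].sum()
    assert np.allclose(per_cell, 1.0, atol=1e-6)
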