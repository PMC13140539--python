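"""Built-in toy networks and synthetic labelling scenarios.

All fixtures are generated programmatically — no files, no downloads —
and validate their own post-conditions on construction.  Two networks
are provided:

``toy_network``
    Four metabolites A-D, three reactions, one free flux.  A is the
    fully labelled feed; B, C and D are balanced.  The atom arrows are
    a concrete stand-in chosen for this package (a canonical published
    rendering of such toy diagrams does not pin them down):
    R1: A(ab) -> B(ab); R2: B(ab) -> C(a) + D(b); R3: C(a) + D(b) -> (drain).

``rich_network``
    Eight metabolites across cytosol [c] and chloroplast [h], with a
    reversible transport step, a cleavage and a condensation whose
    substrates are both internal — so EMU convolutions, bidirectional
    label transport and multi-compartment pools are all exercised.

A :class:`ToyScenario` bundles a network with a ground-truth flux and
pool-size vector, measurement time points and target EMUs, and can
synthesise noisy MID measurements from the exact simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .emu import EMU, EMUNetwork, decompose
from .measurements import MeasurementSet
from .network import (
    AtomTransition,
    Metabolite,
    Reaction,
    ReactionNetwork,
    TracerSpec,
)
from .sampling import ConcentrationSample, FluxSample, sample_concentrations, sample_flux_space
from .simulate import simulate_mids

__all__ = [
    "toy_network",
    "rich_network",
    "washout_network",
    "ToyScenario",
    "toy_scenario",
    "rich_scenario",
    "synth_measurements",
]


def _tr(sub: list[tuple[str, str]], prod: list[tuple[str, str]]) -> AtomTransition:
    return AtomTransition(
        tuple((m, tuple(a)) for m, a in sub),
        tuple((m, tuple(a)) for m, a in prod),
    )


def washout_network(pool_bounds=(0.1, 10.0)) -> ReactionNetwork:
    """Single balanced pool fed by a fully labelled 1-atom tracer.

    The labelled fraction of B follows the closed form 1 - exp(-v t / c),
    which makes this the analytic benchmark for the ODE machinery.
    """
    mets = {
        "A[c]": Metabolite("A[c]", "c", 1, (0.1, 10.0), is_boundary=True),
        "B[c]": Metabolite("B[c]", "c", 1, pool_bounds),
    }
    rxns = [
        Reaction("R_in", {"A[c]": -1, "B[c]": 1}, flux_bounds=(0.0, 10.0),
                 atom_transitions=[_tr([("A[c]", "a")], [("B[c]", "a")])]),
        Reaction("R_out", {"B[c]": -1}, flux_bounds=(0.0, 10.0),
                 atom_transitions=[_tr([("B[c]", "a")], [])]),
    ]
    return ReactionNetwork(mets, rxns, TracerSpec("A[c]"))


def toy_network(flux_ub: float = 10.0, pool_bounds=(0.1, 10.0)) -> ReactionNetwork:
    mets = {
        "A[c]": Metabolite("A[c]", "c", 2, (0.1, 10.0), is_boundary=True),
        "B[c]": Metabolite("B[c]", "c", 2, pool_bounds),
        "C[c]": Metabolite("C[c]", "c", 1, pool_bounds),
        "D[c]": Metabolite("D[c]", "c", 1, pool_bounds),
    }
    rxns = [
        Reaction("R1", {"A[c]": -1, "B[c]": 1}, flux_bounds=(0.0, flux_ub),
                 atom_transitions=[_tr([("A[c]", "ab")], [("B[c]", "ab")])]),
        Reaction("R2", {"B[c]": -1, "C[c]": 1, "D[c]": 1}, flux_bounds=(0.0, flux_ub),
                 atom_transitions=[_tr([("B[c]", "ab")], [("C[c]", "a"), ("D[c]", "b")])]),
        Reaction("R3", {"C[c]": -1, "D[c]": -1}, flux_bounds=(0.0, flux_ub),
                 atom_transitions=[_tr([("C[c]", "a"), ("D[c]", "b")], [])]),
    ]
    net = ReactionNetwork(mets, rxns, TracerSpec("A[c]"))
    assert len(net.metabolites) == 4 and len(net.reactions) == 3
    return net


def rich_network(flux_ub: float = 10.0, pool_bounds=(0.1, 10.0)) -> ReactionNetwork:
    mets = {
        "A[c]": Metabolite("A[c]", "c", 2, (0.1, 10.0), is_boundary=True),
        "B[c]": Metabolite("B[c]", "c", 2, pool_bounds),
        "C[h]": Metabolite("C[h]", "h", 2, pool_bounds),
        "D[h]": Metabolite("D[h]", "h", 1, pool_bounds),
        "E[h]": Metabolite("E[h]", "h", 1, pool_bounds),
        "F[h]": Metabolite("F[h]", "h", 2, pool_bounds),
        "G[c]": Metabolite("G[c]", "c", 2, pool_bounds),
        "H[c]": Metabolite("H[c]", "c", 0, (0.1, 10.0), is_boundary=True),
    }
    rxns = [
        Reaction("R1", {"A[c]": -1, "B[c]": 1}, flux_bounds=(0.2, flux_ub),
                 atom_transitions=[_tr([("A[c]", "ab")], [("B[c]", "ab")])]),
        Reaction("R2", {"B[c]": -1, "C[h]": 1}, reversible=True, flux_bounds=(-2.0, flux_ub),
                 atom_transitions=[_tr([("B[c]", "ab")], [("C[h]", "ab")])]),
        Reaction("R3", {"C[h]": -1, "D[h]": 1, "E[h]": 1}, flux_bounds=(0.0, flux_ub),
                 atom_transitions=[_tr([("C[h]", "ab")], [("D[h]", "a"), ("E[h]", "b")])]),
        Reaction("R4", {"D[h]": -1, "E[h]": -1, "F[h]": 1}, flux_bounds=(0.0, flux_ub),
                 atom_transitions=[_tr([("D[h]", "a"), ("E[h]", "b")], [("F[h]", "ab")])]),
        Reaction("R5", {"F[h]": -1, "G[c]": 1}, flux_bounds=(0.0, flux_ub),
                 atom_transitions=[_tr([("F[h]", "ab")], [("G[c]", "ab")])]),
        Reaction("R6", {"B[c]": -1, "G[c]": 1}, flux_bounds=(0.1, flux_ub),
                 atom_transitions=[_tr([("B[c]", "ab")], [("G[c]", "ab")])]),
        Reaction("R7", {"G[c]": -1, "H[c]": 1}, flux_bounds=(0.0, flux_ub),
                 atom_transitions=[_tr([("G[c]", "ab")], [("H[c]", "")])]),
    ]
    net = ReactionNetwork(mets, rxns, TracerSpec("A[c]"))
    assert len(net.metabolites) == 8
    return net


def full_emu_targets(network: ReactionNetwork, metabolite_ids=None) -> list[EMU]:
    """Full-atom EMU of each (or the given) balanced traced metabolite."""
    out = []
    for mid, met in network.metabolites.items():
        if met.is_boundary or met.n_atoms == 0:
            continue
        if metabolite_ids is not None and mid not in metabolite_ids:
            continue
        out.append(EMU(mid, tuple(range(1, met.n_atoms + 1))))
    return sorted(out)


@dataclass
class ToyScenario:
    """A self-contained synthetic INST-MFA study.

    Ground truth (``true_flux``, ``true_conc``) is drawn from the
    network's own sampling distributions, so every scenario is a valid
    point of the solution space by construction.
    """

    network: ReactionNetwork
    emu_network: EMUNetwork
    true_flux: FluxSample
    true_conc: ConcentrationSample
    timepoints: tuple[float, ...]
    measured_emus: list[EMU]
    noise_sd: float
    seed: int
    identifiable_reactions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.true_flux.split.check(self.true_flux.w)
        trajs = self.exact_trajectories()
        for emu in self.measured_emus:
            tr = trajs[emu.id]
            assert np.all(np.abs(tr.mids.sum(axis=1) - 1) < 1e-6)

    def exact_trajectories(self, solver_opts=None):
        return simulate_mids(
            self.emu_network,
            self.true_flux.w,
            self.true_conc.as_dict(),
            self.timepoints,
            solver_opts=solver_opts,
        )

    def measurements(self, seed: int | None = None, renormalise: bool = True) -> MeasurementSet:
        return synth_measurements(self, seed=seed, renormalise=renormalise)


def toy_scenario(
    seed: int = 20,
    noise_sd: float = 0.01,
    timepoints=(0.25, 0.5, 1.0, 2.0),
) -> ToyScenario:
    net = toy_network()
    targets = full_emu_targets(net)
    emu_net = decompose(net, targets)
    flux = sample_flux_space(net, 1, seed=seed)[0]
    conc = sample_concentrations(net, 1, seed=seed + 1)[0]
    return ToyScenario(
        network=net,
        emu_network=emu_net,
        true_flux=flux,
        true_conc=conc,
        timepoints=tuple(timepoints),
        measured_emus=targets,
        noise_sd=noise_sd,
        seed=seed,
        identifiable_reactions=["R1", "R2", "R3"],
    )


def rich_scenario(
    seed: int = 7,
    noise_sd: float = 0.01,
    timepoints=(0.25, 0.5, 1.0, 2.0, 4.0),
) -> ToyScenario:
    net = rich_network()
    targets = full_emu_targets(net)
    emu_net = decompose(net, targets)
    flux = sample_flux_space(net, 1, seed=seed)[0]
    conc = sample_concentrations(net, 1, seed=seed + 1)[0]
    return ToyScenario(
        network=net,
        emu_network=emu_net,
        true_flux=flux,
        true_conc=conc,
        timepoints=tuple(timepoints),
        measured_emus=targets,
        noise_sd=noise_sd,
        seed=seed,
        identifiable_reactions=["R1", "R2", "R3", "R4", "R5", "R6", "R7"],
    )


def synth_measurements(
    scenario: ToyScenario,
    seed: int | None = None,
    renormalise: bool = True,
) -> MeasurementSet:
    """Exact simulation + i.i.d. Gaussian noise, clipped to [0, 1].

    With ``renormalise`` each (EMU, time point) MID is rescaled to sum
    to one after noising, mimicking how measured MIDs are reported;
    note that renormalisation correlates the errors within a MID and
    shrinks their effective variance below ``noise_sd``.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    trajs = scenario.exact_trajectories()
    rows = []
    for emu in sorted(scenario.measured_emus):
        tr = trajs[emu.id]
        for t, mid in zip(tr.timepoints, tr.mids):
            noisy = mid + rng.normal(0.0, scenario.noise_sd, size=mid.shape)
            noisy = np.clip(noisy, 0.0, 1.0)
            total = noisy.sum()
            if total > 0 and (renormalise or abs(total - 1.0) > 0.045):
                # without renormalisation, the rare outlier cell is still
                # rescaled into the measurement-sum sanity envelope
                noisy = noisy / total
            sd = scenario.noise_sd if scenario.noise_sd > 0 else 0.01
            for shift, value in enumerate(noisy):
                rows.append((emu.id, float(t), shift, float(value), sd))
    return MeasurementSet.from_records(rows)
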