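import numpy as np
import pytest

from emuflux.fixtures import _tr, toy_network
from emuflux.network import (
    AtomTransition,
    Metabolite,
    NetworkError,
    Reaction,
    ReactionNetwork,
    TracerSpec,
    free_flux_basis,
    load_network,
    parse_atom_map,
    stoichiometric_matrix,
    write_atom_map,
    write_sbml,
)
from emuflux.sampling import sample_flux_space


def _met(mid, n, boundary=False):
    return Metabolite(mid, "c", n, (0.1, 10.0), is_boundary=boundary)


def chain_network():
    mets = {"A": _met("A", 1, True), "B": _met("B", 1), "C": _met("C", 1, True)}
    rxns = [
        Reaction("R1", {"A": -1, "B": 1}, atom_transitions=[_tr([("A", "a")], [("B", "a")])]),
        Reaction("R2", {"B": -1, "C": 1}, atom_transitions=[_tr([("B", "a")], [("C", "a")])]),
    ]
    return ReactionNetwork(mets, rxns, TracerSpec("A"))


class TestAtomBalance:
    def test_identity_mapping_passes(self):
        mets = {"A": _met("A", 2, True), "B": _met("B", 2)}
        Reaction("R", {"A": -1, "B": 1}, atom_transitions=[_tr([("A", "ab")], [("B", "ab")])])
        net = ReactionNetwork(
            mets,
            [
                Reaction("R", {"A": -1, "B": 1}, atom_transitions=[_tr([("A", "ab")], [("B", "ab")])]),
                Reaction("Rout", {"B": -1}, atom_transitions=[_tr([("B", "ab")], [])]),
            ],
        )
        assert net.reaction("R").atom_transitions

    def test_dropped_atom_ok_when_product_smaller(self):
        mets = {"A": _met("A", 2, True), "B": _met("B", 1)}
        net = ReactionNetwork(
            mets,
            [
                Reaction("R", {"A": -1, "B": 1}, atom_transitions=[_tr([("A", "ab")], [("B", "a")])]),
                Reaction("Rout", {"B": -1}, atom_transitions=[_tr([("B", "a")], [])]),
            ],
        )
        assert net.metabolites["B"].n_atoms == 1

    def test_pattern_shorter_than_declared_atoms_errors(self):
        mets = {"A": _met("A", 2, True), "B": _met("B", 2)}
        with pytest.raises(NetworkError, match="declares 2"):
            ReactionNetwork(
                mets,
                [Reaction("R", {"A": -1, "B": 1}, atom_transitions=[_tr([("A", "ab")], [("B", "a")])])],
            )

    def test_duplicated_substrate_atom_rejected(self):
        with pytest.raises(NetworkError, match="cannot map to two"):
            AtomTransition((("A", ("a",)), ("B", ("a",))), (("C", ("a",)),))

    def test_unmapped_product_atom_rejected(self):
        with pytest.raises(NetworkError, match="not .*mapped"):
            AtomTransition((("A", ("a",)),), (("C", ("a", "b")),))

    def test_missing_atom_map_for_traced_reaction(self):
        mets = {"A": _met("A", 1, True), "B": _met("B", 1)}
        with pytest.raises(NetworkError, match="no atom map"):
            ReactionNetwork(mets, [Reaction("R", {"A": -1, "B": 1})])


class TestStoichiometry:
    def test_chain_single_balance_row(self):
        S = stoichiometric_matrix(chain_network())
        assert S.shape == (1, 2)
        assert np.array_equal(S, [[1.0, -1.0]])

    def test_toy_rank(self, toy_net):
        S = stoichiometric_matrix(toy_net)
        assert np.linalg.matrix_rank(S) <= 3

    def test_no_internal_metabolites_gives_zero_rows(self):
        mets = {"A": _met("A", 0, True), "B": _met("B", 0, True)}
        net = ReactionNetwork(mets, [Reaction("R", {"A": -1, "B": 1})])
        assert stoichiometric_matrix(net).shape == (0, 1)


class TestFreeFluxBasis:
    def test_chain_basis_spans_equal_fluxes(self):
        v0, K = free_flux_basis(chain_network())
        assert K.shape == (2, 1)
        assert np.allclose(K[0], K[1])
        assert np.isclose(v0[0], v0[1])

    def test_null_space_property(self, toy_net):
        S = stoichiometric_matrix(toy_net)
        v0, K = free_flux_basis(toy_net)
        assert np.max(np.abs(S @ K)) < 1e-10
        assert np.max(np.abs(S @ v0)) < 1e-10
        assert K.shape[1] == len(toy_net.reactions) - np.linalg.matrix_rank(S)

    def test_infeasible_bounds_error(self):
        mets = {"A": _met("A", 0, True), "B": _met("B", 0)}
        rxns = [
            Reaction("R1", {"A": -1, "B": 1}, flux_bounds=(5.0, 10.0)),
            Reaction("R2", {"B": -1}, flux_bounds=(0.0, 1.0)),
        ]
        net = ReactionNetwork(mets, rxns)
        with pytest.raises(NetworkError, match="empty"):
            free_flux_basis(net)


def test_sampled_fluxes_satisfy_steady_state(toy_net, rich_net):
    for net in (toy_net, rich_net):
        S = net.split_system().S
        for s in sample_flux_space(net, 25, seed=9):
            assert np.max(np.abs(S @ s.w)) < 1e-8
            assert np.max(np.abs(stoichiometric_matrix(net) @ s.net)) < 1e-8


class TestAtomMapDialect:
    def test_round_trip(self, toy_net, rich_net):
        for net in (toy_net, rich_net):
            text = write_atom_map(net)
            parsed = parse_atom_map(text)
            for rxn in net.reactions:
                assert parsed[rxn.id] == list(rxn.atom_transitions)

    def test_parse_errors(self):
        with pytest.raises(NetworkError, match="TAB"):
            parse_atom_map("R1 A (a) -> B (a)")
        with pytest.raises(NetworkError, match="->"):
            parse_atom_map("R1\tA (a) = B (a)")


class TestSBMLLoader:
    @pytest.fixture()
    def toy_files(self, tmp_path, toy_net):
        write_sbml(toy_net, tmp_path / "toy.xml")
        (tmp_path / "atoms.tsv").write_text(write_atom_map(toy_net))
        return tmp_path

    def _config(self, **extra):
        cfg = {
            "compartments": ["c"],
            "boundary_metabolites": ["A[c]"],
            "default_pool_bounds": [0.1, 10.0],
            "tracer": {"metabolite": "A[c]"},
        }
        cfg.update(extra)
        return cfg

    def test_loads_toy_model(self, toy_files, toy_net):
        net = load_network(toy_files / "toy.xml", toy_files / "atoms.tsv", self._config())
        assert len(net.metabolites) == 4
        assert len(net.reactions) == 3
        assert net.metabolites["A[c]"].is_boundary
        assert write_atom_map(net) == write_atom_map(toy_net)

    def test_unknown_compartment_rejected(self, toy_files):
        with pytest.raises(NetworkError, match="compartment"):
            load_network(
                toy_files / "toy.xml",
                toy_files / "atoms.tsv",
                self._config(compartments=["h"]),
            )

    def test_config_flux_bounds_win(self, toy_files):
        net = load_network(
            toy_files / "toy.xml",
            toy_files / "atoms.tsv",
            self._config(flux_bounds={"R1": [0.0, 3.5]}),
        )
        assert net.reaction("R1").flux_bounds == (0.0, 3.5)

    def test_missing_atom_map_row_is_hard_error(self, toy_files, toy_net):
        partial = "\n".join(
            line
            for line in write_atom_map(toy_net).splitlines()
            if not line.startswith("R2")
        )
        (toy_files / "partial.tsv").write_text(partial + "\n")
        with pytest.raises(NetworkError, match="R2"):
            load_network(toy_files / "toy.xml", toy_files / "partial.tsv", self._config())
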