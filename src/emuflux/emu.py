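"""Elementary metabolic unit (EMU) decomposition.

An EMU is a specific subset of a metabolite's traced atoms.  Starting
from the EMUs one wants to simulate (the measurement targets), the
decomposition traces atom transitions backwards through every producing
reaction and emits the minimal set of EMUs — stratified by size — whose
balance equations close.  A target whose atoms originate in more than
one substrate molecule yields a *convolution* reaction: its mass
isotopomer distribution is the convolution of the source MIDs.

The resulting :class:`EMUNetwork` is consumed by the labelling
simulator; its correctness oracle is agreement with a brute-force
full-isotopomer simulation marginalised to the same EMUs.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

from .network import NetworkError, ReactionNetwork

__all__ = [
    "EMU",
    "EMUReaction",
    "EMUNetwork",
    "decompose",
    "emu_count_report",
    "emu_network_to_tsv",
    "emu_network_from_tsv",
]


@dataclass(frozen=True, order=True)
class EMU:
    """Atoms ``atom_indices`` (1-based, sorted) of ``metabolite_id``."""

    metabolite_id: str
    atom_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = tuple(sorted(self.atom_indices))
        object.__setattr__(self, "atom_indices", idx)
        if not idx:
            raise NetworkError("an EMU must contain at least one atom")
        if len(set(idx)) != len(idx):
            raise NetworkError(f"duplicate atom index in EMU of {self.metabolite_id}")
        if idx[0] < 1:
            raise NetworkError("atom indices are 1-based")

    @property
    def size(self) -> int:
        return len(self.atom_indices)

    @property
    def id(self) -> str:
        return f"{self.metabolite_id}:{'-'.join(map(str, self.atom_indices))}"

    @classmethod
    def from_id(cls, emu_id: str) -> "EMU":
        met, _, idx = emu_id.rpartition(":")
        if not met:
            raise NetworkError(f"malformed EMU id {emu_id!r}")
        return cls(met, tuple(int(i) for i in idx.split("-")))

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.id


@dataclass(frozen=True)
class EMUReaction:
    """One production route of ``target``: coefficient * flux * (conv of sources)."""

    target: EMU
    sources: tuple[EMU, ...]
    flux_ref: tuple[str, str]  # (reaction id, 'fwd' | 'bwd')
    coefficient: float

    def __post_init__(self) -> None:
        if sum(s.size for s in self.sources) != self.target.size:
            raise NetworkError(
                f"EMU reaction {self.target.id}: source sizes do not add up"
            )
        if self.coefficient <= 0:
            raise NetworkError("EMU reaction coefficient must be positive")


class EMUNetwork:
    """Size-stratified EMU balance network.

    ``emus`` are the unknowns (EMUs of balanced metabolites), ordered by
    (size, metabolite id, atom indices); ``source_emus`` sit on boundary
    metabolites and have known, constant MIDs set by the tracer.
    """

    def __init__(
        self,
        network: ReactionNetwork,
        emus: list[EMU],
        source_emus: list[EMU],
        reactions: list[EMUReaction],
        targets: list[EMU],
    ):
        self.network = network
        self.emus = sorted(set(emus), key=lambda e: (e.size, e.metabolite_id, e.atom_indices))
        self.source_emus = sorted(
            set(source_emus), key=lambda e: (e.size, e.metabolite_id, e.atom_indices)
        )
        self.reactions = sorted(
            reactions,
            key=lambda r: (r.target.size, r.target.id, [s.id for s in r.sources], r.flux_ref),
        )
        self.targets = list(targets)

    @property
    def levels(self) -> dict[int, tuple[list[EMU], list[EMUReaction]]]:
        out: dict[int, tuple[list[EMU], list[EMUReaction]]] = {}
        for e in self.emus:
            out.setdefault(e.size, ([], []))[0].append(e)
        for r in self.reactions:
            out.setdefault(r.target.size, ([], []))[1].append(r)
        return out

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, EMUNetwork)
            and self.emus == other.emus
            and self.source_emus == other.source_emus
            and self.reactions == other.reactions
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<EMUNetwork {len(self.emus)} EMUs, {len(self.source_emus)} sources, "
            f"{len(self.reactions)} EMU reactions>"
        )


def _producing_records(network: ReactionNetwork):
    """Map metabolite -> [(flux_ref, record_weight, substrates, product_entry), ...].

    Reversible reactions contribute both orientations.  Multiple
    transition records of one reaction are equiprobable alternatives
    (molecular symmetry) and carry weight 1/n_records each.
    """
    table: dict[str, list] = {}
    for rxn in network.reactions:
        if not rxn.atom_transitions:
            continue
        orientations = [("fwd", False)]
        if rxn.reversible:
            orientations.append(("bwd", True))
        for direction, flip in orientations:
            weight = 1.0 / len(rxn.atom_transitions)
            for tr in rxn.atom_transitions:
                subs = tr.products if flip else tr.substrates
                prods = tr.substrates if flip else tr.products
                for prod_entry in prods:
                    met_id, _ = prod_entry
                    table.setdefault(met_id, []).append(
                        ((rxn.id, direction), weight, subs, prod_entry)
                    )
    return table


def decompose(network: ReactionNetwork, targets: list[EMU]) -> EMUNetwork:
    """Backward-trace ``targets`` to the minimal closed EMU network."""
    for t in targets:
        met = network.metabolites.get(t.metabolite_id)
        if met is None:
            raise NetworkError(f"target EMU on unknown metabolite {t.metabolite_id}")
        if t.atom_indices[-1] > met.n_atoms:
            raise NetworkError(
                f"target {t.id}: atom index out of range (metabolite has "
                f"{met.n_atoms} traced atoms)"
            )

    producers = _producing_records(network)
    unknown: set[EMU] = set()
    sources: set[EMU] = set()
    # coefficients accumulate over records and product instances
    coeff: dict[tuple[EMU, tuple[EMU, ...], tuple[str, str]], float] = {}

    queue = deque(sorted(set(targets)))
    visited: set[EMU] = set()
    while queue:
        emu = queue.popleft()
        if emu in visited:
            continue
        visited.add(emu)
        met = network.metabolites[emu.metabolite_id]
        if met.is_boundary:
            sources.add(emu)
            continue
        unknown.add(emu)
        for flux_ref, weight, subs, (pmet, pletters) in producers.get(emu.metabolite_id, []):
            if pmet != emu.metabolite_id:
                continue
            needed = {pletters[i - 1] for i in emu.atom_indices}
            parts: list[EMU] = []
            for smet, sletters in subs:
                pos = tuple(
                    i + 1 for i, letter in enumerate(sletters) if letter in needed
                )
                if pos:
                    parts.append(EMU(smet, pos))
            if sum(p.size for p in parts) != emu.size:
                raise NetworkError(
                    f"{flux_ref[0]}: atoms of {emu.id} are not fully mapped "
                    "from substrates"
                )
            src = tuple(sorted(parts, key=lambda e: (e.metabolite_id, e.atom_indices)))
            key = (emu, src, flux_ref)
            coeff[key] = coeff.get(key, 0.0) + weight
            for p in src:
                if p not in visited:
                    queue.append(p)

    reactions = [
        EMUReaction(target=t, sources=s, flux_ref=f, coefficient=c)
        for (t, s, f), c in coeff.items()
    ]
    return EMUNetwork(network, sorted(unknown), sorted(sources), reactions, targets)


def emu_count_report(emu_network: EMUNetwork) -> dict[int, dict[str, int]]:
    """Per-size EMU and EMU-reaction counts (sources included)."""
    report: dict[int, dict[str, int]] = {}
    for size, (emus, rxns) in sorted(emu_network.levels.items()):
        report[size] = {"emus": len(emus), "reactions": len(rxns), "sources": 0}
    for e in emu_network.source_emus:
        entry = report.setdefault(e.size, {"emus": 0, "reactions": 0, "sources": 0})
        entry["emus"] += 1
        entry["sources"] += 1
    return report


# ---------------------------------------------------------------------------
# TSV dump / load (inspection + fixtures)
# ---------------------------------------------------------------------------


def emu_network_to_tsv(emu_network: EMUNetwork) -> str:
    lines = ["target\tsources\treaction\tdirection\tcoefficient"]
    for r in emu_network.reactions:
        src = ",".join(s.id for s in r.sources)
        lines.append(
            f"{r.target.id}\t{src}\t{r.flux_ref[0]}\t{r.flux_ref[1]}\t{r.coefficient:.12g}"
        )
    return "\n".join(lines) + "\n"


def emu_network_from_tsv(network: ReactionNetwork, text: str) -> EMUNetwork:
    reactions: list[EMUReaction] = []
    lines = [ln for ln in text.splitlines() if ln.strip()]
    for line in lines[1:]:
        target, srcs, rid, direction, c = line.split("\t")
        reactions.append(
            EMUReaction(
                target=EMU.from_id(target),
                sources=tuple(EMU.from_id(s) for s in srcs.split(",")),
                flux_ref=(rid, direction),
                coefficient=float(c),
            )
        )
    emus, sources = set(), set()
    for r in reactions:
        for e in (r.target, *r.sources):
            if network.metabolites[e.metabolite_id].is_boundary:
                sources.add(e)
            else:
                emus.add(e)
    return EMUNetwork(network, sorted(emus), sorted(sources), reactions, sorted(emus))
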