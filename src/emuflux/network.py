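"""Compartmentalised reaction networks with atom transitions.

A :class:`ReactionNetwork` couples ordinary stoichiometry (for the
steady-state constraint ``S @ v = 0``) with per-reaction atom transition
maps (for isotope-labelling simulation).  Atom maps use a plain-text TSV
dialect, one row per transition record::

    R1\tA[c] (ab) + B[c] (c) -> C[h] (abc)

Lowercase letters name traced atoms; the same letter on both sides marks
the transition.  Metabolite tokens may carry an integer stoichiometric
prefix, in which case one ``(..)`` group is listed per unit (one
transition record per unit of stoichiometry).  A reaction may have
several rows: the records are treated as equiprobable alternatives,
which is how rotationally symmetric molecules are expressed.

Reversible reactions are split internally into non-negative forward and
backward sub-fluxes (label can flow both ways); the net flux is
``forward - backward``.  The split system is exposed through
:class:`SplitFluxSystem` and consumed by the sampling, simulation and
estimation layers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import null_space
from scipy.optimize import linprog

__all__ = [
    "Metabolite",
    "AtomTransition",
    "Reaction",
    "ReactionNetwork",
    "SplitFluxSystem",
    "NetworkError",
    "load_network",
    "parse_atom_map",
    "write_atom_map",
    "stoichiometric_matrix",
    "free_flux_basis",
]


class NetworkError(ValueError):
    """Raised for invalid networks, atom maps or infeasible bounds."""


@dataclass(frozen=True)
class Metabolite:
    """A compartmentalised species carrying ``n_atoms`` traced atoms."""

    id: str
    compartment: str
    n_atoms: int
    pool_bounds: tuple[float, float] = (0.01, 100.0)
    is_boundary: bool = False

    def __post_init__(self) -> None:
        if self.n_atoms < 0:
            raise NetworkError(f"{self.id}: negative atom count")
        lo, hi = self.pool_bounds
        if lo > hi:
            raise NetworkError(f"{self.id}: pool bounds {self.pool_bounds} inverted")
        if not self.is_boundary and self.n_atoms > 0 and lo <= 0:
            raise NetworkError(
                f"{self.id}: balanced traced metabolite needs a strictly "
                f"positive pool lower bound, got {lo}"
            )


@dataclass(frozen=True)
class AtomTransition:
    """One atom-transition record.

    ``substrates``/``products`` are tuples of ``(metabolite_id, letters)``
    where ``letters`` is a tuple of single-character atom names in atom
    order (1-based position ``i`` carries ``letters[i-1]``).  One entry
    per unit of stoichiometry.
    """

    substrates: tuple[tuple[str, tuple[str, ...]], ...]
    products: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        sub_letters = [a for _, ls in self.substrates for a in ls]
        prod_letters = [a for _, ls in self.products for a in ls]
        if len(set(sub_letters)) != len(sub_letters):
            raise NetworkError(
                f"substrate atom named twice in {self._fmt()} "
                "(one substrate atom cannot map to two product atoms)"
            )
        if len(set(prod_letters)) != len(prod_letters):
            raise NetworkError(f"product atom named twice in {self._fmt()}")
        missing = set(prod_letters) - set(sub_letters)
        if missing:
            raise NetworkError(
                f"product atom(s) {sorted(missing)} of {self._fmt()} are not "
                "mapped from any substrate atom"
            )

    def _fmt(self) -> str:
        def side(entries):
            return " + ".join(f"{m} ({''.join(ls)})" for m, ls in entries)

        return f"{side(self.substrates)} -> {side(self.products)}"


@dataclass
class Reaction:
    """A (possibly reversible) reaction with bounds and atom transitions."""

    id: str
    stoichiometry: dict[str, float]
    reversible: bool = False
    flux_bounds: tuple[float, float] = (0.0, 10.0)
    atom_transitions: list[AtomTransition] = field(default_factory=list)

    def __post_init__(self) -> None:
        lo, hi = self.flux_bounds
        if lo > hi:
            raise NetworkError(f"{self.id}: flux bounds {self.flux_bounds} inverted")
        if not self.reversible and lo < 0:
            raise NetworkError(f"{self.id}: irreversible reaction with lower bound {lo}")

    @property
    def substrate_ids(self) -> list[str]:
        return [m for m, c in self.stoichiometry.items() if c < 0]

    @property
    def product_ids(self) -> list[str]:
        return [m for m, c in self.stoichiometry.items() if c > 0]


@dataclass
class TracerSpec:
    """Labelled-nutrient specification.

    ``label_pattern`` gives the labelled fraction of each atom of the fed
    metabolite (default fully labelled, the indistinguishable-atom case
    of 13CO2 or 15NO3-).  Before ``switch_time`` the feed is unlabelled.
    """

    metabolite_id: str
    label_pattern: tuple[float, ...] | None = None
    switch_time: float = 0.0

    def pattern_for(self, n_atoms: int) -> tuple[float, ...]:
        if self.label_pattern is None:
            return (1.0,) * n_atoms
        if len(self.label_pattern) != n_atoms:
            raise NetworkError(
                f"tracer pattern length {len(self.label_pattern)} != "
                f"{n_atoms} atoms of {self.metabolite_id}"
            )
        if any(not (0.0 <= p <= 1.0) for p in self.label_pattern):
            raise NetworkError("tracer labelled fractions must lie in [0, 1]")
        return self.label_pattern


@dataclass
class ReactionNetwork:
    metabolites: dict[str, Metabolite]
    reactions: list[Reaction]
    tracer: TracerSpec | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        ids = set(self.metabolites)
        seen = set()
        for rxn in self.reactions:
            if rxn.id in seen:
                raise NetworkError(f"duplicate reaction id {rxn.id}")
            seen.add(rxn.id)
            for m in rxn.stoichiometry:
                if m not in ids:
                    raise NetworkError(f"{rxn.id}: unknown metabolite {m}")
            self._check_atom_map(rxn)
        if self.tracer is not None and self.tracer.metabolite_id not in ids:
            raise NetworkError(f"tracer metabolite {self.tracer.metabolite_id} unknown")

    def _check_atom_map(self, rxn: Reaction) -> None:
        traced_subs = [m for m in rxn.substrate_ids if self.metabolites[m].n_atoms > 0]
        traced_prods = [m for m in rxn.product_ids if self.metabolites[m].n_atoms > 0]
        if not traced_subs and not traced_prods:
            return
        if not rxn.atom_transitions:
            raise NetworkError(
                f"reaction {rxn.id} carries traced metabolites but has no atom map"
            )
        for tr in rxn.atom_transitions:
            for side, entries, traced in (
                ("substrate", tr.substrates, traced_subs),
                ("product", tr.products, traced_prods),
            ):
                counts: dict[str, int] = {}
                for met_id, letters in entries:
                    met = self.metabolites.get(met_id)
                    if met is None:
                        raise NetworkError(f"{rxn.id}: atom map names unknown {met_id}")
                    if len(letters) != met.n_atoms:
                        raise NetworkError(
                            f"{rxn.id}: atom pattern ({''.join(letters)}) for "
                            f"{met_id} has {len(letters)} atoms but the "
                            f"metabolite declares {met.n_atoms}"
                        )
                    counts[met_id] = counts.get(met_id, 0) + 1
                for met_id in traced:
                    want = int(round(abs(rxn.stoichiometry[met_id])))
                    if counts.get(met_id, 0) != want:
                        raise NetworkError(
                            f"{rxn.id}: {side} {met_id} appears {counts.get(met_id, 0)} "
                            f"time(s) in the atom map but stoichiometry is {want}"
                        )

    # -- views ---------------------------------------------------------
    @property
    def balanced_metabolites(self) -> list[str]:
        return [m for m in self.metabolites if not self.metabolites[m].is_boundary]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def with_tracer(self, tracer: TracerSpec) -> "ReactionNetwork":
        return ReactionNetwork(dict(self.metabolites), list(self.reactions), tracer)

    def stoichiometric_matrix(self) -> np.ndarray:
        return stoichiometric_matrix(self)

    def split_system(self) -> "SplitFluxSystem":
        return SplitFluxSystem(self)


def stoichiometric_matrix(network: ReactionNetwork) -> np.ndarray:
    """S over balanced metabolites (rows) x reactions (columns, net)."""
    rows = network.balanced_metabolites
    idx = {m: i for i, m in enumerate(rows)}
    S = np.zeros((len(rows), len(network.reactions)))
    for j, rxn in enumerate(network.reactions):
        for m, c in rxn.stoichiometry.items():
            if m in idx:
                S[idx[m], j] = c
    return S


def _interior_point(
    A_eq: np.ndarray, lb: np.ndarray, ub: np.ndarray
) -> np.ndarray:
    """A strictly interior feasible point of {lb<=x<=ub, A_eq x = 0}.

    Maximises the minimum slack to the box faces (capped so unbounded
    directions do not dominate), via one LP.
    """
    n = A_eq.shape[1]
    span = ub - lb
    cap = np.where(np.isfinite(span), span / 2.0, 1.0)
    cap = np.maximum(cap, 1e-9)
    # variables: x (n), s (1); maximise s with x_i - s*1 >= lb_i, x_i + s <= ub_i
    # scaled per-variable so tight boxes do not pin s at ~0 globally.
    c = np.zeros(n + 1)
    c[-1] = -1.0
    A_ub = []
    b_ub = []
    for i in range(n):
        row = np.zeros(n + 1)
        row[i] = -1.0
        row[-1] = cap[i]
        A_ub.append(row)
        b_ub.append(-lb[i])
        row = np.zeros(n + 1)
        row[i] = 1.0
        row[-1] = cap[i]
        A_ub.append(row)
        b_ub.append(ub[i])
    Aeq = np.hstack([A_eq, np.zeros((A_eq.shape[0], 1))])
    res = linprog(
        c,
        A_ub=np.asarray(A_ub),
        b_ub=np.asarray(b_ub),
        A_eq=Aeq,
        b_eq=np.zeros(A_eq.shape[0]),
        bounds=[(None, None)] * n + [(0, 1)],
        method="highs",
    )
    if not res.success or res.x[-1] <= 0:
        raise NetworkError("flux polytope is empty (infeasible bounds)")
    return res.x[:n]


def free_flux_basis(network: ReactionNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Particular solution v0 and null-space basis K with ``S @ K = 0``.

    Any ``v = v0 + K @ u`` satisfies the steady-state constraint exactly;
    ``u`` has dimension ``n_reactions - rank(S)``.
    """
    S = stoichiometric_matrix(network)
    lb = np.array([r.flux_bounds[0] for r in network.reactions], float)
    ub = np.array([r.flux_bounds[1] for r in network.reactions], float)
    v0 = _interior_point(S, lb, ub)
    K = null_space(S) if S.size else np.eye(len(network.reactions))
    return v0, K


class SplitFluxSystem:
    """Direction-split flux space of a network.

    Columns are ``(reaction_id, 'fwd')`` for every reaction plus
    ``(reaction_id, 'bwd')`` for reversible ones; all split fluxes are
    non-negative and the net stoichiometric balance ``S_net @ net(w) = 0``
    becomes ``S_split @ w = 0``.
    """

    def __init__(self, network: ReactionNetwork, exchange_cap: float | None = None):
        self.network = network
        self.columns: list[tuple[str, str]] = []
        lbs, ubs = [], []
        for rxn in network.reactions:
            lo, hi = rxn.flux_bounds
            self.columns.append((rxn.id, "fwd"))
            lbs.append(max(lo, 0.0))
            ubs.append(max(hi, 0.0))
            if rxn.reversible:
                self.columns.append((rxn.id, "bwd"))
                bub = max(-lo, 0.0)
                if exchange_cap is not None:
                    bub = min(bub, exchange_cap)
                lbs.append(0.0)
                ubs.append(bub)
        self.lb = np.asarray(lbs, float)
        self.ub = np.asarray(ubs, float)
        S_net = stoichiometric_matrix(network)
        net_idx = {r.id: j for j, r in enumerate(network.reactions)}
        cols = []
        for rid, direction in self.columns:
            col = S_net[:, net_idx[rid]]
            cols.append(col if direction == "fwd" else -col)
        self.S = np.column_stack(cols) if cols else np.zeros((S_net.shape[0], 0))
        self._basis: tuple[np.ndarray, np.ndarray] | None = None

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    @property
    def dim(self) -> int:
        return self.basis()[1].shape[1]

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """(w0, K) with ``w = w0 + K @ u`` spanning the split null space."""
        if self._basis is None:
            w0 = _interior_point(self.S, self.lb, self.ub)
            K = null_space(self.S) if self.S.size else np.eye(self.n_columns)
            self._basis = (w0, K)
        return self._basis

    def net(self, w: np.ndarray) -> np.ndarray:
        """Net flux per reaction (forward minus backward)."""
        w = np.asarray(w, float)
        out = np.zeros(len(self.network.reactions))
        for k, (rid, direction) in enumerate(self.columns):
            j = self.network.reaction_ids.index(rid)
            out[j] += w[..., k] if direction == "fwd" else -w[..., k]
        return out

    def from_net(self, v_net: np.ndarray, exchange: float = 0.0) -> np.ndarray:
        """Split vector realising net fluxes with a uniform exchange flux."""
        w = np.zeros(self.n_columns)
        net_idx = {r.id: j for j, r in enumerate(self.network.reactions)}
        for k, (rid, direction) in enumerate(self.columns):
            v = v_net[net_idx[rid]]
            if direction == "fwd":
                w[k] = max(v, 0.0) + (exchange if self.network.reaction(rid).reversible else 0.0)
            else:
                w[k] = max(-v, 0.0) + exchange
        return w

    def column_labels(self) -> list[str]:
        return [rid if d == "fwd" else f"{rid}__bwd" for rid, d in self.columns]

    def check(self, w: np.ndarray, tol: float = 1e-8) -> None:
        w = np.asarray(w, float)
        if self.S.size and np.max(np.abs(self.S @ w)) >= tol:
            raise NetworkError("split flux vector violates steady state")
        if np.any(w < self.lb - 1e-9) or np.any(w > self.ub + 1e-9):
            raise NetworkError("split flux vector violates bounds")


def write_sbml(network: ReactionNetwork, path) -> None:
    """Serialise stoichiometry + bounds to SBML L3 (atom maps go to TSV).

    Boundary metabolites get an exchange pseudo-reaction so the flag
    survives the round trip.
    """
    import cobra
    import cobra.io

    model = cobra.Model("emuflux_network")
    cobra_mets = {}
    for met in network.metabolites.values():
        base = met.id.split("[")[0]
        cm = cobra.Metabolite(f"{base}_{met.compartment}", compartment=met.compartment)
        cobra_mets[met.id] = cm
    model.add_metabolites(list(cobra_mets.values()))
    rxns = []
    for rxn in network.reactions:
        cr = cobra.Reaction(rxn.id)
        cr.lower_bound, cr.upper_bound = rxn.flux_bounds
        rxns.append(cr)
    model.add_reactions(rxns)
    for rxn, cr in zip(network.reactions, rxns):
        cr.add_metabolites({cobra_mets[m]: c for m, c in rxn.stoichiometry.items()})
    for met in network.metabolites.values():
        if met.is_boundary:
            ex = cobra.Reaction(f"EX_{cobra_mets[met.id].id}")
            ex.lower_bound, ex.upper_bound = -1000.0, 1000.0
            model.add_reactions([ex])
            ex.add_metabolites({cobra_mets[met.id]: -1.0})
    cobra.io.write_sbml_model(model, str(path))


# ---------------------------------------------------------------------------
# Atom-map TSV dialect
# ---------------------------------------------------------------------------

_TOKEN = re.compile(r"^\s*(?:(\d+)\s+)?(.+?)\s*\(([a-z]*)\)\s*$")


def _parse_side(text: str) -> list[tuple[str, tuple[str, ...]]]:
    entries: list[tuple[str, tuple[str, ...]]] = []
    for token in text.split("+"):
        token = token.strip()
        if not token:
            continue
        m = _TOKEN.match(token)
        if m is None:
            raise NetworkError(f"cannot parse atom-map token {token!r}")
        count = int(m.group(1) or 1)
        met, letters = m.group(2).strip(), tuple(m.group(3))
        if count != 1:
            raise NetworkError(
                f"{token!r}: list one (..) group per unit of stoichiometry "
                "instead of a numeric prefix with a single group"
            )
        entries.append((met, letters))
    return entries


def parse_atom_map(text: str) -> dict[str, list[AtomTransition]]:
    """Parse the TSV dialect into {reaction_id: [AtomTransition, ...]}."""
    out: dict[str, list[AtomTransition]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            rid, eqn = line.split("\t", 1)
        except ValueError as exc:
            raise NetworkError(f"atom map line {lineno}: missing TAB separator") from exc
        if "->" not in eqn:
            raise NetworkError(f"atom map line {lineno}: missing '->'")
        left, right = eqn.split("->", 1)
        try:
            tr = AtomTransition(tuple(_parse_side(left)), tuple(_parse_side(right)))
        except NetworkError as exc:
            raise NetworkError(f"atom map line {lineno} ({rid}): {exc}") from exc
        out.setdefault(rid.strip(), []).append(tr)
    return out


def write_atom_map(network: ReactionNetwork) -> str:
    """Serialise all atom transitions back to the TSV dialect."""
    lines = []
    for rxn in network.reactions:
        for tr in rxn.atom_transitions:
            def side(entries):
                return " + ".join(f"{m} ({''.join(ls)})" for m, ls in entries)

            lines.append(f"{rxn.id}\t{side(tr.substrates)} -> {side(tr.products)}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# SBML + config loader
# ---------------------------------------------------------------------------


def _bracket_id(sid: str, compartment: str) -> str:
    suffix = f"_{compartment}"
    base = sid[: -len(suffix)] if sid.endswith(suffix) else sid
    return f"{base}[{compartment}]"


def load_network(sbml_source, atommap_source, bounds_config: dict) -> ReactionNetwork:
    """Build a validated :class:`ReactionNetwork` from SBML + atom map + config.

    ``bounds_config`` keys (all optional unless noted):

    - ``compartments``: allowed compartment codes (others rejected)
    - ``boundary_metabolites``: ids exempt from the steady-state balance
    - ``untraced_metabolites``: ids carrying no traced atoms
    - ``pool_bounds``: {metabolite_id: [lo, hi]} plus ``default_pool_bounds``
    - ``flux_bounds``: {reaction_id: [lo, hi]} overriding SBML bounds
    - ``tracer``: {metabolite, label_pattern?, switch_time?}
    """
    import cobra.io

    model = cobra.io.read_sbml_model(str(sbml_source))
    with open(atommap_source, encoding="utf-8") as fh:
        atom_maps = parse_atom_map(fh.read())

    allowed = bounds_config.get("compartments")
    boundary = set(bounds_config.get("boundary_metabolites", []))
    untraced = set(bounds_config.get("untraced_metabolites", []))
    default_pool = tuple(bounds_config.get("default_pool_bounds", (0.01, 100.0)))
    pool_overrides = bounds_config.get("pool_bounds", {})
    flux_overrides = bounds_config.get("flux_bounds", {})

    # traced-atom counts inferred from atom-map patterns, checked for agreement
    n_atoms: dict[str, int] = {}
    for rid, trs in atom_maps.items():
        for tr in trs:
            for met, letters in tr.substrates + tr.products:
                prev = n_atoms.setdefault(met, len(letters))
                if prev != len(letters):
                    raise NetworkError(
                        f"{met}: atom map declares both {prev} and {len(letters)} atoms"
                    )

    metabolites: dict[str, Metabolite] = {}
    id_map: dict[str, str] = {}
    for met in model.metabolites:
        comp = met.compartment or ""
        if allowed is not None and comp not in allowed:
            raise NetworkError(
                f"metabolite {met.id} is in unknown compartment {comp!r}; "
                f"allowed: {sorted(allowed)}"
            )
        mid = _bracket_id(met.id, comp)
        id_map[met.id] = mid
        is_bnd = mid in boundary or met.id in boundary or bool(getattr(met, "boundary_condition", False))
        count = n_atoms.get(mid, 0)
        if mid in untraced or met.id in untraced:
            count = 0
        pb = tuple(pool_overrides.get(mid, pool_overrides.get(met.id, default_pool)))
        metabolites[mid] = Metabolite(mid, comp, count, pb, is_bnd)

    reactions: list[Reaction] = []
    for rxn in model.reactions:
        if rxn.boundary:
            # exchange pseudo-reactions: fold into boundary flags, skip
            for met in rxn.metabolites:
                mid = id_map[met.id]
                metabolites[mid] = replace(metabolites[mid], is_boundary=True)
            continue
        stoich = {id_map[m.id]: float(c) for m, c in rxn.metabolites.items()}
        lo, hi = flux_overrides.get(rxn.id, (rxn.lower_bound, rxn.upper_bound))
        trs = atom_maps.get(rxn.id, [])
        traced_touch = any(metabolites[m].n_atoms > 0 for m in stoich)
        if traced_touch and not trs:
            raise NetworkError(
                f"reaction {rxn.id} carries traced metabolites but the atom "
                "map has no row for it (declare it untraced or add a row)"
            )
        reactions.append(
            Reaction(
                id=rxn.id,
                stoichiometry=stoich,
                reversible=lo < 0,
                flux_bounds=(float(lo), float(hi)),
                atom_transitions=trs,
            )
        )

    tracer = None
    tr_cfg = bounds_config.get("tracer")
    if tr_cfg:
        tracer = TracerSpec(
            metabolite_id=tr_cfg["metabolite"],
            label_pattern=tuple(tr_cfg["label_pattern"]) if tr_cfg.get("label_pattern") else None,
            switch_time=float(tr_cfg.get("switch_time", 0.0)),
        )
    return ReactionNetwork(metabolites, reactions, tracer)
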