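"""Time-resolved mass isotopomer distribution (MID) simulation.

The labelling state of every EMU is a probability vector over mass
shifts M+0..M+size.  Stacking all unknown EMUs gives a block-triangular
ODE system

    c  (x)  dX/dt = A(v) . X + B(v) . Y

where Y collects convolution inputs from smaller EMUs and constant
source (tracer/boundary) MIDs.  The system is solved jointly across
size levels.  When no convolution couples two unknown EMUs the system
is affine with constant coefficients and is integrated exactly through
a matrix exponential; otherwise a stiff initial-value solver is used.

A brute-force full-isotopomer simulator (2^n states per metabolite)
serves as the independent correctness oracle for the EMU reduction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .emu import EMU, EMUNetwork
from .network import ReactionNetwork, TracerSpec

__all__ = [
    "TracerSpec",
    "MIDTrajectory",
    "EMUODESystem",
    "build_emu_odes",
    "simulate_mids",
    "simulate_isotopomers_bruteforce",
    "IsotopomerTrajectory",
    "trajectories_to_frame",
    "SimulationError",
]


class SimulationError(RuntimeError):
    pass


@dataclass
class MIDTrajectory:
    """MIDs of one EMU at the requested time points (rows on the simplex)."""

    emu: EMU
    timepoints: np.ndarray  # (T,)
    mids: np.ndarray  # (T, size+1)
    raw_mids: np.ndarray | None = None  # pre clip/renormalise, debug only

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, float)
        self.mids = np.asarray(self.mids, float)
        if np.any(np.diff(self.timepoints) <= 0):
            raise SimulationError("time points must be strictly increasing")
        if self.mids.shape != (len(self.timepoints), self.emu.size + 1):
            raise SimulationError("MID array shape mismatch")

    def at(self, t: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.timepoints - t)))
        if not np.isclose(self.timepoints[i], t, rtol=1e-9, atol=1e-12):
            raise KeyError(f"time point {t} not simulated")
        return self.mids[i]


def _source_mid(emu: EMU, network: ReactionNetwork, tracer: TracerSpec | None) -> np.ndarray:
    """Constant MID of a boundary-metabolite EMU under the tracer feed."""
    met = network.metabolites[emu.metabolite_id]
    if tracer is not None and emu.metabolite_id == tracer.metabolite_id:
        pattern = tracer.pattern_for(met.n_atoms)
        probs = [pattern[i - 1] for i in emu.atom_indices]
    else:
        probs = [0.0] * emu.size
    mid = np.array([1.0])
    for p in probs:
        mid = np.convolve(mid, [1.0 - p, p])
    return mid


class EMUODESystem:
    """Assembled EMU balance ODEs for one (flux, concentration) pair."""

    def __init__(
        self,
        emu_network: EMUNetwork,
        flux: np.ndarray,
        conc: dict[str, float],
        tracer: TracerSpec | None = None,
    ):
        net = emu_network.network
        self.emu_network = emu_network
        self.tracer = tracer if tracer is not None else net.tracer
        split = net.split_system()
        flux = np.asarray(flux, float)
        if flux.shape != (split.n_columns,):
            raise SimulationError(
                f"flux vector has {flux.shape} entries, expected split vector "
                f"of length {split.n_columns}"
            )
        self.split = split
        self.flux = flux
        fluxmap = dict(zip(split.columns, flux))

        # consumption flux per metabolite (drain of every EMU of that pool)
        consumption: dict[str, float] = {m: 0.0 for m in net.metabolites}
        for (rid, direction), v in fluxmap.items():
            rxn = net.reaction(rid)
            for m, coefficient in rxn.stoichiometry.items():
                eaten = -coefficient if direction == "fwd" else coefficient
                if eaten > 0:
                    consumption[m] += eaten * v

        self.emus = emu_network.emus
        self.index = {e: i for i, e in enumerate(self.emus)}
        self.offsets: dict[EMU, slice] = {}
        pos = 0
        for e in self.emus:
            self.offsets[e] = slice(pos, pos + e.size + 1)
            pos += e.size + 1
        self.n_state = pos

        self.source_mids = {
            e: _source_mid(e, net, self.tracer) for e in emu_network.source_emus
        }

        # term list: (target slice, rate, const kernel, [state EMU refs])
        self.terms: list[tuple[slice, float, np.ndarray, list[EMU]]] = []
        self.drain = np.zeros(self.n_state)
        for e in self.emus:
            met = net.metabolites[e.metabolite_id]
            c = conc.get(e.metabolite_id)
            if c is None or c <= 0:
                raise SimulationError(
                    f"metabolite {e.metabolite_id} needs a positive pool size"
                )
            self.drain[self.offsets[e]] = consumption[e.metabolite_id] / c
        for r in emu_network.reactions:
            c = conc[r.target.metabolite_id]
            rate = r.coefficient * fluxmap[r.flux_ref] / c
            kernel = np.array([1.0])
            state_refs: list[EMU] = []
            for s in r.sources:
                if s in self.source_mids:
                    kernel = np.convolve(kernel, self.source_mids[s])
                else:
                    state_refs.append(s)
            self.terms.append((self.offsets[r.target], rate, kernel, state_refs))

        self.is_linear = all(len(refs) <= 1 for _, _, _, refs in self.terms)
        self._linear: tuple[np.ndarray, np.ndarray] | None = None

    # -- diagnostics ---------------------------------------------------
    def balance_residual(self) -> float:
        """max over EMUs of |sum of production fluxes - consumption flux|.

        Zero (to rounding) for any steady-state flux vector: the row sums
        of the assembled [A|B] system vanish EMU-wise.
        """
        net = self.emu_network.network
        fluxmap = dict(zip(self.split.columns, self.flux))
        prod: dict[EMU, float] = {e: 0.0 for e in self.emus}
        for r in self.emu_network.reactions:
            if r.target in prod:
                prod[r.target] += r.coefficient * fluxmap[r.flux_ref]
        eaten: dict[str, float] = {m: 0.0 for m in net.metabolites}
        for (rid, direction), v in fluxmap.items():
            for m, coefficient in net.reaction(rid).stoichiometry.items():
                take = -coefficient if direction == "fwd" else coefficient
                if take > 0:
                    eaten[m] += take * v
        return max(
            (abs(prod[e] - eaten[e.metabolite_id]) for e in self.emus), default=0.0
        )

    # -- right-hand side ----------------------------------------------
    def rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        dx = -self.drain * x
        for sl, rate, kernel, refs in self.terms:
            vec = kernel
            for s in refs:
                vec = np.convolve(vec, x[self.offsets[s]])
            dx[sl] += rate * vec
        return dx

    def linear_system(self) -> tuple[np.ndarray, np.ndarray]:
        """(M, b) with dx/dt = M x + b; only valid when ``is_linear``."""
        if not self.is_linear:
            raise SimulationError("system has unknown-unknown convolutions")
        if self._linear is None:
            M = np.diag(-self.drain)
            b = np.zeros(self.n_state)
            for sl, rate, kernel, refs in self.terms:
                if refs:
                    s = refs[0]
                    ssl = self.offsets[s]
                    for l, kl in enumerate(kernel):
                        if kl == 0.0:
                            continue
                        for j in range(s.size + 1):
                            M[sl.start + j + l, ssl.start + j] += rate * kl
                else:
                    b[sl] += rate * kernel
            self._linear = (M, b)
        return self._linear

    def initial_state(self) -> np.ndarray:
        x0 = np.zeros(self.n_state)
        for e in self.emus:
            x0[self.offsets[e].start] = 1.0  # fully unlabelled: M+0 = 1
        return x0


def build_emu_odes(
    emu_network: EMUNetwork,
    flux: np.ndarray,
    conc: dict[str, float] | np.ndarray,
    tracer: TracerSpec | None = None,
) -> EMUODESystem:
    """Assemble the EMU balance ODE system (see :class:`EMUODESystem`)."""
    conc = _conc_dict(emu_network.network, conc)
    return EMUODESystem(emu_network, flux, conc, tracer)


def _conc_dict(network: ReactionNetwork, conc) -> dict[str, float]:
    if isinstance(conc, dict):
        return conc
    ids = network.balanced_metabolites
    arr = np.asarray(conc, float)
    if arr.shape != (len(ids),):
        raise SimulationError(
            f"concentration vector length {arr.shape} != {len(ids)} balanced metabolites"
        )
    return dict(zip(ids, arr))


def _clip_renormalise(mids: np.ndarray) -> np.ndarray:
    out = np.clip(mids, 0.0, None)
    sums = out.sum(axis=-1, keepdims=True)
    sums[sums == 0] = 1.0
    return out / sums


def simulate_mids(
    emu_network: EMUNetwork,
    flux: np.ndarray,
    conc,
    timepoints,
    tracer: TracerSpec | None = None,
    solver_opts: dict | None = None,
) -> dict[str, MIDTrajectory]:
    """Solve the EMU ODEs; return {emu_id: MIDTrajectory} for all unknowns.

    The initial condition is fully unlabelled (M+0 = 1) at the tracer
    switch time.  Affine systems are propagated exactly with a matrix
    exponential of the augmented generator; systems with
    unknown-unknown convolutions fall back to a stiff IVP solver
    (LSODA, rtol 1e-8 / atol 1e-10 by default, BDF retry on failure).
    """
    opts = {"rtol": 1e-8, "atol": 1e-10, "method": "LSODA"}
    if solver_opts:
        opts.update(solver_opts)
    keep_raw = bool(opts.pop("keep_raw", False))
    force_ivp = bool(opts.pop("force_ivp", False))

    system = build_emu_odes(emu_network, flux, conc, tracer)
    tracer = system.tracer
    t0 = tracer.switch_time if tracer is not None else 0.0
    timepoints = np.asarray(timepoints, float)
    if np.any(timepoints < t0):
        raise SimulationError("time points must not precede the tracer switch time")

    x0 = system.initial_state()
    if system.is_linear and not force_ivp:
        M, b = system.linear_system()
        n = system.n_state
        gen = np.zeros((n + 1, n + 1))
        gen[:n, :n] = M
        gen[:n, n] = b
        z0 = np.append(x0, 1.0)
        X = np.empty((len(timepoints), n))
        for i, t in enumerate(timepoints):
            X[i] = (expm(gen * (t - t0)) @ z0)[:n]
    else:
        X = _solve_ivp_with_retry(system, t0, timepoints, x0, opts)

    out: dict[str, MIDTrajectory] = {}
    for e in system.emus:
        raw = X[:, system.offsets[e]]
        if np.any(raw < -1e-6) or np.any(np.abs(raw.sum(axis=1) - 1.0) > 1e-5):
            raise SimulationError(
                f"EMU {e.id}: solver left the probability simplex; tighten tolerances"
            )
        out[e.id] = MIDTrajectory(
            emu=e,
            timepoints=timepoints,
            mids=_clip_renormalise(raw),
            raw_mids=raw.copy() if keep_raw else None,
        )
    return out


def _solve_ivp_with_retry(system, t0, timepoints, x0, opts):
    method = opts.pop("method", "LSODA")
    attempts = [
        (method, opts["rtol"], opts["atol"]),
        ("BDF", opts["rtol"] * 1e-2, opts["atol"] * 1e-2),
    ]
    last = None
    for meth, rtol, atol in attempts:
        sol = solve_ivp(
            system.rhs,
            (t0, float(timepoints[-1])),
            x0,
            t_eval=timepoints,
            method=meth,
            rtol=rtol,
            atol=atol,
        )
        if sol.success:
            return sol.y.T
        last = sol
    raise SimulationError(f"stiff solver failed: {last.message if last else 'unknown'}")


# ---------------------------------------------------------------------------
# Brute-force full-isotopomer oracle
# ---------------------------------------------------------------------------


@dataclass
class IsotopomerTrajectory:
    metabolite_id: str
    n_atoms: int
    timepoints: np.ndarray
    fractions: np.ndarray  # (T, 2**n_atoms); bit i-1 set <=> atom i labelled

    def mid_of(self, emu: EMU) -> np.ndarray:
        """Marginalise the isotopomer distribution to the EMU's MID."""
        if emu.metabolite_id != self.metabolite_id:
            raise KeyError(emu.metabolite_id)
        n = self.n_atoms
        shifts = np.zeros(2**n, dtype=int)
        for pattern in range(2**n):
            shifts[pattern] = sum(
                1 for i in emu.atom_indices if pattern >> (i - 1) & 1
            )
        mids = np.zeros((len(self.timepoints), emu.size + 1))
        for k in range(emu.size + 1):
            mids[:, k] = self.fractions[:, shifts == k].sum(axis=1)
        return mids


def _marginal_matrix(n_atoms: int, positions: tuple[int, ...]) -> np.ndarray:
    """G with (G @ p)[g] = P(atoms at ``positions`` show bit pattern g)."""
    G = np.zeros((2 ** len(positions), 2**n_atoms))
    for pattern in range(2**n_atoms):
        g = 0
        for k, pos in enumerate(positions):
            if pattern >> (pos - 1) & 1:
                g |= 1 << k
        G[g, pattern] = 1.0
    return G


def simulate_isotopomers_bruteforce(
    network: ReactionNetwork,
    flux: np.ndarray,
    conc,
    timepoints,
    tracer: TracerSpec | None = None,
    state_cap: int = 4096,
    solver_opts: dict | None = None,
) -> dict[str, IsotopomerTrajectory]:
    """Integrate full isotopomer distributions (2^n states per metabolite).

    Exponential in atom counts; guarded by ``state_cap``.  Test oracle
    for the EMU reduction, not a production path.
    """
    opts = {"rtol": 1e-8, "atol": 1e-10}
    if solver_opts:
        opts.update(solver_opts)
    tracer = tracer if tracer is not None else network.tracer
    conc = _conc_dict(network, conc)
    split = network.split_system()
    flux = np.asarray(flux, float)
    fluxmap = dict(zip(split.columns, flux))

    traced = [m for m in network.metabolites.values() if m.n_atoms > 0]
    internal = [m for m in traced if not m.is_boundary]
    n_states = sum(2**m.n_atoms for m in internal)
    if n_states > state_cap:
        raise SimulationError(
            f"{n_states} isotopomer states exceed the cap {state_cap}; "
            "use the EMU simulation instead"
        )

    offsets: dict[str, slice] = {}
    pos = 0
    for m in internal:
        offsets[m.id] = slice(pos, pos + 2**m.n_atoms)
        pos += 2**m.n_atoms

    def boundary_distribution(met) -> np.ndarray:
        p = np.zeros(met.n_atoms)
        if tracer is not None and met.id == tracer.metabolite_id:
            p = np.asarray(tracer.pattern_for(met.n_atoms))
        dist = np.zeros(2**met.n_atoms)
        for pattern in range(2**met.n_atoms):
            pr = 1.0
            for i in range(met.n_atoms):
                pi = p[i]
                pr *= pi if pattern >> i & 1 else (1.0 - pi)
            dist[pattern] = pr
        return dist

    # precompute production terms
    # term: (product met id, rate, groups) with groups = (source kind, G, bit positions in product pattern)
    terms = []
    consumption = {m.id: 0.0 for m in network.metabolites.values()}
    for (rid, direction), v in fluxmap.items():
        rxn = network.reaction(rid)
        for met_id, coefficient in rxn.stoichiometry.items():
            eaten = -coefficient if direction == "fwd" else coefficient
            if eaten > 0:
                consumption[met_id] += eaten * v
        if not rxn.atom_transitions:
            continue
        weight = 1.0 / len(rxn.atom_transitions)
        for tr in rxn.atom_transitions:
            subs = tr.products if direction == "bwd" else tr.substrates
            prods = tr.substrates if direction == "bwd" else tr.products
            for pmet_id, pletters in prods:
                pmet = network.metabolites[pmet_id]
                if pmet.is_boundary or pmet.n_atoms == 0:
                    continue
                letter_to_product_bit = {l: i for i, l in enumerate(pletters)}
                groups = []
                for smet_id, sletters in subs:
                    smet = network.metabolites[smet_id]
                    positions = tuple(
                        i + 1
                        for i, l in enumerate(sletters)
                        if l in letter_to_product_bit
                    )
                    if not positions:
                        continue
                    bits = tuple(
                        letter_to_product_bit[sletters[p - 1]] for p in positions
                    )
                    G = _marginal_matrix(smet.n_atoms, positions)
                    kind = ("const", boundary_distribution(smet)) if (
                        smet.is_boundary
                    ) else ("state", smet_id)
                    groups.append((kind, G, bits))
                if sum(len(g[2]) for g in groups) != pmet.n_atoms:
                    raise SimulationError(
                        f"{rid}: product {pmet_id} atoms not fully mapped"
                    )
                # map: for each product pattern, index into each group's marginal
                npat = 2**pmet.n_atoms
                maps = []
                for kind, G, bits in groups:
                    idx = np.zeros(npat, dtype=int)
                    for pattern in range(npat):
                        g = 0
                        for k, bit in enumerate(bits):
                            if pattern >> bit & 1:
                                g |= 1 << k
                        idx[pattern] = g
                    maps.append((kind, G, idx))
                terms.append((pmet_id, v * weight, maps))

    drain = np.zeros(pos)
    inv_c = np.zeros(pos)
    for m in internal:
        c = conc.get(m.id)
        if c is None or c <= 0:
            raise SimulationError(f"metabolite {m.id} needs a positive pool size")
        drain[offsets[m.id]] = consumption[m.id] / c
        inv_c[offsets[m.id]] = 1.0 / c

    def rhs(t, y):
        dy = -drain * y
        for pmet_id, rate, maps in terms:
            if rate == 0.0:
                continue
            prod = rate
            for kind, G, idx in maps:
                base = G @ (kind[1] if kind[0] == "const" else y[offsets[kind[1]]])
                prod = prod * base[idx]
            dy[offsets[pmet_id]] += prod * inv_c[offsets[pmet_id]]
        return dy

    y0 = np.zeros(pos)
    for m in internal:
        y0[offsets[m.id].start] = 1.0  # pattern 0 = unlabelled
    t0 = tracer.switch_time if tracer is not None else 0.0
    timepoints = np.asarray(timepoints, float)
    sol = solve_ivp(
        rhs,
        (t0, float(timepoints[-1])),
        y0,
        t_eval=timepoints,
        method="LSODA",
        rtol=opts["rtol"],
        atol=opts["atol"],
    )
    if not sol.success:
        raise SimulationError(f"isotopomer solver failed: {sol.message}")
    Y = sol.y.T
    return {
        m.id: IsotopomerTrajectory(m.id, m.n_atoms, timepoints, Y[:, offsets[m.id]])
        for m in internal
    }


# ---------------------------------------------------------------------------
# Long-format CSV (matches the measurement schema)
# ---------------------------------------------------------------------------


def trajectories_to_frame(trajectories: dict[str, MIDTrajectory]) -> pd.DataFrame:
    rows = []
    for emu_id in sorted(trajectories):
        tr = trajectories[emu_id]
        for t, mid in zip(tr.timepoints, tr.mids):
            for shift, frac in enumerate(mid):
                rows.append((emu_id, float(t), shift, float(frac)))
    return pd.DataFrame(rows, columns=["emu_id", "time", "mass_shift", "fraction"])
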