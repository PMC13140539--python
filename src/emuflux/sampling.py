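"""Sampling of steady-state flux distributions and pool-size vectors.

Fluxes are sampled from the polytope ``{w : S_split @ w = 0, lb <= w <= ub}``
of direction-split fluxes, parameterised on its null space so the
steady-state constraint holds exactly for every sample.  The default
sampler is coordinate hit-and-run with ``100 * dim`` warm-up steps and
``dim`` thinning steps; ``corner_mix`` draws Dirichlet mixtures of
polytope vertices instead.  Pool sizes default to log-uniform draws
within their bounds, reflecting that metabolite concentrations span
orders of magnitude.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .network import NetworkError, ReactionNetwork, SplitFluxSystem

__all__ = [
    "FluxSample",
    "ConcentrationSample",
    "sample_flux_space",
    "sample_concentrations",
    "save_samples",
    "load_samples",
]


@dataclass
class FluxSample:
    """One steady-state flux vector.

    ``w`` is the direction-split representation used by the labelling
    simulator; ``net`` the per-reaction net flux (forward - backward).
    """

    w: np.ndarray
    split: SplitFluxSystem

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, float)
        self.split.check(self.w)

    @property
    def net(self) -> np.ndarray:
        return self.split.net(self.w)

    @property
    def labels(self) -> list[str]:
        return self.split.column_labels()


@dataclass
class ConcentrationSample:
    """Strictly positive pool sizes for all balanced metabolites."""

    c: np.ndarray
    metabolite_ids: list[str]

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, float)
        if np.any(self.c <= 0):
            raise NetworkError("pool sizes must be strictly positive")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.metabolite_ids, self.c))


def _chord_interval(w, K, j, lb, ub):
    """Feasible step interval along null-space coordinate j at point w."""
    lo, hi = -np.inf, np.inf
    col = K[:, j]
    for i in range(len(w)):
        k = col[i]
        if abs(k) < 1e-13:
            continue
        a = (lb[i] - w[i]) / k
        b = (ub[i] - w[i]) / k
        lo_i, hi_i = (a, b) if k > 0 else (b, a)
        lo, hi = max(lo, lo_i), min(hi, hi_i)
    return lo, hi


def sample_flux_space(
    network: ReactionNetwork,
    n: int,
    seed: int,
    method: str = "hit_and_run",
    split: SplitFluxSystem | None = None,
    warmup_factor: int = 100,
    thin: int | None = None,
) -> list[FluxSample]:
    """Draw ``n`` steady-state flux samples; bit-reproducible for a seed."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if split is None:
        split = network.split_system()
    w0, K = split.basis()
    dim = K.shape[1]
    rng = np.random.default_rng(seed)
    if n == 0:
        return []
    if dim == 0:
        return [FluxSample(w0.copy(), split) for _ in range(n)]

    if method == "hit_and_run":
        w = w0.copy()
        samples = []
        warmup = warmup_factor * dim
        thin = thin if thin is not None else dim
        step = 0
        while len(samples) < n:
            j = int(rng.integers(dim))
            lo, hi = _chord_interval(w, K, j, split.lb, split.ub)
            if hi > lo:
                delta = rng.uniform(lo, hi)
                w = w + delta * K[:, j]
                # guard against drift out of the box
                w = np.clip(w, split.lb, split.ub)
            step += 1
            if step > warmup and (step - warmup) % thin == 0:
                samples.append(FluxSample(_repair(w, w0, K, split), split))
        return samples
    if method == "corner_mix":
        vertices = _polytope_vertices(split, rng, max(2 * dim + 2, 4))
        samples = []
        for _ in range(n):
            weights = rng.dirichlet(np.ones(len(vertices)))
            w = np.asarray(vertices).T @ weights
            samples.append(FluxSample(_repair(w, w0, K, split), split))
        return samples
    raise ValueError(f"unknown sampling method {method!r}")


def _repair(w, w0, K, split):
    """Project tiny box-clipping drift back onto the steady-state space."""
    u = K.T @ (w - w0)
    return w0 + K @ u


def _polytope_vertices(split, rng, count):
    w0, K = split.basis()
    dim = K.shape[1]
    verts = []
    for _ in range(count):
        c_u = rng.standard_normal(dim) @ np.eye(dim)
        # minimise c_u . u subject to lb <= w0 + K u <= ub
        res = linprog(
            c_u,
            A_ub=np.vstack([K, -K]),
            b_ub=np.concatenate([split.ub - w0, w0 - split.lb]),
            bounds=[(None, None)] * dim,
            method="highs",
        )
        if res.success:
            verts.append(w0 + K @ res.x)
    if not verts:
        raise NetworkError("could not find polytope vertices")
    return verts


def sample_concentrations(
    network: ReactionNetwork,
    n: int,
    seed: int,
    distribution: str = "log_uniform",
) -> list[ConcentrationSample]:
    """Draw pool-size vectors for all balanced metabolites within bounds."""
    if n < 0:
        raise ValueError("n must be non-negative")
    ids = network.balanced_metabolites
    lo = np.array([network.metabolites[m].pool_bounds[0] for m in ids])
    hi = np.array([network.metabolites[m].pool_bounds[1] for m in ids])
    if np.any(lo <= 0):
        raise NetworkError("pool lower bounds must be strictly positive to sample")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        if distribution == "log_uniform":
            c = np.exp(rng.uniform(np.log(lo), np.log(hi)))
        elif distribution == "uniform":
            c = rng.uniform(lo, hi)
        else:
            raise ValueError(f"unknown distribution {distribution!r}")
        out.append(ConcentrationSample(c, ids))
    return out


# ---------------------------------------------------------------------------
# Persistence: CSV + JSON sidecar
# ---------------------------------------------------------------------------


def save_samples(
    path,
    flux_samples: list[FluxSample],
    conc_samples: list[ConcentrationSample],
    meta: dict | None = None,
) -> None:
    path = Path(path)
    flux_cols = flux_samples[0].labels if flux_samples else []
    conc_cols = conc_samples[0].metabolite_ids if conc_samples else []
    data = {}
    for j, col in enumerate(flux_cols):
        data[f"flux:{col}"] = [s.w[j] for s in flux_samples]
    for j, col in enumerate(conc_cols):
        data[f"conc:{col}"] = [s.c[j] for s in conc_samples]
    frame = pd.DataFrame(data)
    frame.to_csv(path, index=False)
    sidecar = dict(meta or {})
    sidecar["columns"] = list(frame.columns)
    sidecar["sha256"] = hashlib.sha256(path.read_bytes()).hexdigest()
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True)
    )


def load_samples(path, network: ReactionNetwork):
    path = Path(path)
    frame = pd.read_csv(path)
    split = network.split_system()
    flux_cols = [f"flux:{c}" for c in split.column_labels()]
    conc_ids = network.balanced_metabolites
    conc_cols = [f"conc:{c}" for c in conc_ids]
    flux_samples = [
        FluxSample(row[flux_cols].to_numpy(float), split) for _, row in frame.iterrows()
    ]
    conc_samples = [
        ConcentrationSample(row[conc_cols].to_numpy(float), conc_ids)
        for _, row in frame.iterrows()
    ]
    return flux_samples, conc_samples
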