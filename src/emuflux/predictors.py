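"""Forward predictors: anything mapping (fluxes, pools) -> measured MIDs.

The estimation layer only requires the :class:`Predictor` contract, so a
trained surrogate ensemble and the exact ODE simulator are drop-in
replacements for one another.  Oracle-mode fits (exact simulator as
predictor) isolate estimation error from surrogate error.
"""

from __future__ import annotations

from typing import Protocol

import numpy as np

from .emu import EMUNetwork
from .simulate import simulate_mids

__all__ = ["Predictor", "SimulatorPredictor"]


class Predictor(Protocol):
    def predict(self, w: np.ndarray, conc: dict[str, float]) -> dict[tuple[str, float], np.ndarray]:
        """MID per (emu_id, time) for a split flux vector and pool dict."""
        ...

    @property
    def grid(self) -> list[tuple[str, float]]:
        """(emu_id, time) pairs this predictor can produce."""
        ...


class SimulatorPredictor:
    """Exact EMU ODE simulation behind the predictor contract."""

    def __init__(self, emu_network: EMUNetwork, timepoints, solver_opts: dict | None = None):
        self.emu_network = emu_network
        self.timepoints = tuple(float(t) for t in sorted(timepoints))
        self.solver_opts = solver_opts or {}

    @property
    def grid(self) -> list[tuple[str, float]]:
        return [
            (e.id, t) for e in self.emu_network.emus for t in self.timepoints
        ]

    def predict(self, w, conc):
        trajs = simulate_mids(
            self.emu_network, w, conc, self.timepoints, solver_opts=dict(self.solver_opts)
        )
        out = {}
        for emu_id, tr in trajs.items():
            for i, t in enumerate(self.timepoints):
                out[(emu_id, t)] = tr.mids[i]
        return out
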