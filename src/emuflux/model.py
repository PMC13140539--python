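"""Flux and pool-size estimation from measured MIDs.

:class:`InstMfaModel` is the modelling entry point: it couples a
reaction network, a measurement set and a forward predictor (exact
simulator or trained surrogate ensemble).  ``fit`` minimises the
reduced chi-square statistic

    L = ssr / dof,   ssr = sum_k ((pred_k - meas_k) / sd_k)^2,
    dof = n_measurements - n_free_parameters

with a multi-start trust-region-reflective least-squares solver.  The
steady-state constraint is enforced by construction: the optimiser
moves in null-space coordinates ``u`` of the direction-split
stoichiometric system (``w = w0 + K u`` gives ``S w = 0`` exactly at
every iterate), with pool sizes co-estimated on a log scale or held
fixed.  Box bounds on the physical fluxes are soft-penalised with a
ramped weight and verified by a final feasibility projection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import null_space
from scipy.optimize import least_squares, minimize

from .measurements import MeasurementError, MeasurementSet
from .network import ReactionNetwork, SplitFluxSystem
from .predictors import Predictor
from .sampling import sample_concentrations, sample_flux_space
from .simulate import SimulationError

__all__ = [
    "InstMfaModel",
    "InstMfaResults",
    "weighted_residuals",
    "degrees_of_freedom",
    "goodness_of_fit",
    "GoodnessOfFit",
]


def weighted_residuals(
    predicted: dict[tuple[str, float], np.ndarray], measurements: MeasurementSet
) -> np.ndarray:
    """r_k = (pred_k - meas_k) / sd_k, one entry per measurement record."""
    frame = measurements.frame
    r = np.empty(len(frame))
    for k, rec in enumerate(frame.itertuples()):
        key = (rec.emu_id, float(rec.time))
        mid = predicted.get(key)
        if mid is None:
            raise MeasurementError(
                f"no prediction for measurement record ({rec.emu_id}, t={rec.time})"
            )
        shift = int(rec.mass_shift)
        if shift >= len(mid):
            raise MeasurementError(
                f"record ({rec.emu_id}, t={rec.time}) asks for M+{shift} but the "
                f"prediction has {len(mid)} mass shifts"
            )
        r[k] = (mid[shift] - rec.value) / rec.sd
    return r


def degrees_of_freedom(n_measurements: int, n_free_parameters: int) -> int:
    dof = n_measurements - n_free_parameters
    if dof <= 0:
        raise ValueError(
            f"{n_measurements} measurements cannot constrain "
            f"{n_free_parameters} free parameters (dof = {dof} <= 0)"
        )
    return dof


@dataclass
class GoodnessOfFit:
    accept: bool
    L: float
    dof: int
    alpha: float
    interval: tuple[float, float]
    overfit: bool = False


def goodness_of_fit(L: float, dof: int, alpha: float = 0.05) -> GoodnessOfFit:
    """Chi-square acceptance test on the reduced statistic.

    Accept iff L lies in ``[chi2_{alpha/2,dof}, chi2_{1-alpha/2,dof}] / dof``.
    ``alpha = 1`` degenerates to an empty interval (always reject).
    """
    if dof < 1:
        raise ValueError("dof must be >= 1")
    lo = stats.chi2.ppf(alpha / 2, dof) / dof
    hi = stats.chi2.ppf(1 - alpha / 2, dof) / dof
    if alpha >= 1:
        return GoodnessOfFit(False, L, dof, alpha, (lo, hi), overfit=False)
    accept = lo <= L <= hi
    return GoodnessOfFit(accept, L, dof, alpha, (lo, hi), overfit=L < lo)


@dataclass
class _StartResult:
    ssr: float
    theta: np.ndarray
    success: bool
    n_out_of_domain: int


class InstMfaModel:
    """Reduced chi-square INST-MFA estimation problem.

    Parameters
    ----------
    network:
        Validated reaction network; provides the flux polytope.
    measurements:
        Measured MIDs; every (EMU, time) pair must be covered by the
        predictor's grid.
    predictor:
        Forward model (exact simulator or surrogate ensemble).
    concentrations:
        ``"estimate"`` (default) co-estimates log pool sizes within
        their bounds; a dict of pool sizes holds them fixed.
    """

    def __init__(
        self,
        network: ReactionNetwork,
        measurements: MeasurementSet,
        predictor: Predictor,
        concentrations: str | dict[str, float] = "estimate",
        exchange_cap: float | None = None,
    ):
        self.network = network
        self.measurements = measurements
        self.predictor = predictor
        self.split = (
            network.split_system()
            if exchange_cap is None
            else SplitFluxSystem(network, exchange_cap)
        )
        self.w0, self.K = self.split.basis()
        self.estimate_conc = concentrations == "estimate"
        if self.estimate_conc:
            self.fixed_conc = None
        else:
            if not isinstance(concentrations, dict):
                raise ValueError("concentrations must be 'estimate' or a dict")
            self.fixed_conc = dict(concentrations)
        self.conc_ids = network.balanced_metabolites
        grid = set(predictor.grid)
        missing = [p for p in measurements.emu_timepoints if p not in grid]
        if missing:
            raise MeasurementError(
                f"predictor does not cover measured pairs {missing[:3]}..."
            )
        self._log_bounds = self._conc_log_bounds()

    # -- parameter vector layout: [u (dim), log c (n_pools)?] ----------
    @property
    def n_free_parameters(self) -> int:
        n = self.K.shape[1]
        if self.estimate_conc:
            n += len(self.conc_ids)
        return n

    def _conc_log_bounds(self):
        lo = np.log([self.network.metabolites[m].pool_bounds[0] for m in self.conc_ids])
        hi = np.log([self.network.metabolites[m].pool_bounds[1] for m in self.conc_ids])
        return lo, hi

    def _unpack(self, theta, w0=None, K=None):
        w0 = self.w0 if w0 is None else w0
        K = self.K if K is None else K
        d = K.shape[1]
        w = w0 + K @ theta[:d]
        if self.estimate_conc:
            conc = dict(zip(self.conc_ids, np.exp(theta[d:])))
        else:
            conc = self.fixed_conc
        return w, conc

    def _residuals(self, theta, penalty_weight, counter, w0=None, K=None):
        w, conc = self._unpack(theta, w0, K)
        span = np.maximum(self.split.ub - self.split.lb, 1.0)
        pen_lo = penalty_weight * np.maximum(self.split.lb - w, 0.0) / span
        pen_hi = penalty_weight * np.maximum(w - self.split.ub, 0.0) / span
        w_eval = np.clip(w, self.split.lb, self.split.ub)
        viol = float(np.max(np.abs(w_eval - w), initial=0.0))
        if viol > 1e-6:
            # clipping this far breaks the steady state the simulator
            # assumes; a flat cliff (no simulation) makes the trust
            # region back off while the penalty terms restore direction
            r = np.full(self.measurements.n_records, 1e3)
        else:
            try:
                pred = self.predictor.predict(w_eval, conc)
                r = weighted_residuals(pred, self.measurements)
            except SimulationError:
                r = np.full(self.measurements.n_records, 1e3)
        if counter is not None and getattr(self.predictor, "last_out_of_domain", False):
            counter[0] += 1
        return np.concatenate([r, pen_lo, pen_hi])

    def _theta_bounds(self, d):
        lo = np.full(d, -np.inf)
        hi = np.full(d, np.inf)
        if self.estimate_conc:
            blo, bhi = self._log_bounds
            lo = np.concatenate([lo, blo])
            hi = np.concatenate([hi, bhi])
        return lo, hi

    def _starts(self, n_starts, seed):
        rng = np.random.SeedSequence(seed)
        s1, s2 = rng.spawn(2)
        fseed = int(s1.generate_state(1)[0] % (2**31))
        cseed = int(s2.generate_state(1)[0] % (2**31))
        # mix interior (hit-and-run) and extreme (vertex-mix) starts so the
        # multi-start sweep also probes low-flux corners of the polytope
        n_corner = n_starts // 2
        flux_starts = sample_flux_space(
            self.network, n_starts - n_corner, seed=fseed, split=self.split
        )
        if n_corner:
            flux_starts += sample_flux_space(
                self.network, n_corner, seed=fseed + 1, split=self.split,
                method="corner_mix",
            )
        conc_starts = sample_concentrations(self.network, n_starts, seed=cseed)
        thetas = []
        for f, c in zip(flux_starts, conc_starts):
            u = self.K.T @ (f.w - self.w0)
            theta = u
            if self.estimate_conc:
                theta = np.concatenate([u, np.log(c.c)])
            thetas.append(theta)
        return thetas

    def _solve_from(self, theta0, solver_opts, w0=None, K=None):
        # diff_step well above the ODE-solver noise floor keeps the
        # finite-difference jacobian clean (rtol 1e-8 simulations)
        opts = {
            "gtol": 1e-10,
            "xtol": 1e-12,
            "ftol": 1e-12,
            "diff_step": 1e-6,
            "max_nfev": None,
        }
        opts.update(solver_opts or {})
        max_nfev = opts.pop("max_nfev")
        d = (K if K is not None else self.K).shape[1]
        lo, hi = self._theta_bounds(d)
        counter = [0]
        theta = np.clip(theta0, lo + 1e-12, hi - 1e-12)
        result = None
        for pw in (1e3, 1e5):
            result = least_squares(
                self._residuals,
                theta,
                bounds=(lo, hi),
                method="trf",
                args=(pw, counter, w0, K),
                max_nfev=max_nfev or 400 * (len(theta) + 1),
                **opts,
            )
            theta = result.x
            w, _ = self._unpack(theta, w0, K)
            viol = max(
                np.max(np.maximum(self.split.lb - w, 0.0), initial=0.0),
                np.max(np.maximum(w - self.split.ub, 0.0), initial=0.0),
            )
            if viol < 1e-8:
                break
        theta = self._project_feasible(theta, w0, K)
        w, conc = self._unpack(theta, w0, K)
        pred = self.predictor.predict(w, conc)
        ssr = float(np.sum(weighted_residuals(pred, self.measurements) ** 2))
        return _StartResult(ssr, theta, bool(result.success), counter[0])

    def _project_feasible(self, theta, w0=None, K=None):
        """Nudge u so the physical fluxes respect their box exactly."""
        w0 = self.w0 if w0 is None else w0
        K = self.K if K is None else K
        d = K.shape[1]
        w = w0 + K @ theta[:d]
        if np.all(w >= self.split.lb - 1e-9) and np.all(w <= self.split.ub + 1e-9):
            return theta
        u0 = theta[:d]
        res = minimize(
            lambda u: float(np.sum((K @ (u - u0)) ** 2)),
            u0,
            jac=lambda u: 2 * (K.T @ (K @ (u - u0))),
            constraints=[
                {"type": "ineq", "fun": lambda u: w0 + K @ u - self.split.lb},
                {"type": "ineq", "fun": lambda u: self.split.ub - (w0 + K @ u)},
            ],
            method="SLSQP",
            options={"maxiter": 200, "ftol": 1e-14},
        )
        out = theta.copy()
        if res.success:
            out[:d] = res.x
        return out

    # -- public fit ----------------------------------------------------
    def fit(
        self,
        n_starts: int = 10,
        seed: int = 0,
        solver_opts: dict | None = None,
        start_points: list[np.ndarray] | None = None,
        polish_top: int = 2,
    ) -> "InstMfaResults":
        """Best-of-``n_starts`` trust-region-reflective fit.

        When starts are drawn internally, every start first runs with a
        capped evaluation budget and only the ``polish_top`` best basins
        are optimised to full tolerance — the cheap sweep locates the
        global basin, the polish nails it.  Explicit ``start_points``
        are all solved at full tolerance.
        """
        if start_points is not None:
            thetas = start_points
            starts = [self._solve_from(t, solver_opts) for t in thetas]
        else:
            thetas = self._starts(n_starts, seed)
            if len(thetas) > polish_top:
                explore_opts = dict(solver_opts or {})
                explore_opts.setdefault(
                    "max_nfev", 40 * (len(thetas[0]) + 1)
                )
                starts = [self._solve_from(t, explore_opts) for t in thetas]
                order = np.argsort([s.ssr for s in starts])
                for idx in order[:polish_top]:
                    polished = self._solve_from(starts[idx].theta, solver_opts)
                    if polished.ssr < starts[idx].ssr:
                        starts[idx] = polished
            else:
                starts = [self._solve_from(t, solver_opts) for t in thetas]
        ssrs = [s.ssr for s in starts]
        best_idx = int(np.argmin(ssrs))
        best = starts[best_idx]
        dof = degrees_of_freedom(self.measurements.n_records, self.n_free_parameters)
        w, conc = self._unpack(best.theta)
        return InstMfaResults(
            model=self,
            theta=best.theta,
            w_hat=w,
            c_hat=dict(conc) if conc else {},
            ssr=best.ssr,
            dof=dof,
            n_starts=len(starts),
            best_start_index=best_idx,
            per_start_ssr=ssrs,
            converged=any(s.success for s in starts),
            n_out_of_domain=sum(s.n_out_of_domain for s in starts),
        )

    # -- constrained refit used by profile confidence intervals --------
    def constrained_basis(self, reaction_id: str, value: float):
        """Null-space basis of {S w = 0, net flux of reaction = value}.

        The null space and the minimum-norm particular solution are
        affine in ``value``, so the expensive factorisations are cached
        per reaction and only combined per pinned value.
        """
        cache = getattr(self, "_cb_cache", None)
        if cache is None:
            cache = self._cb_cache = {}
        entry = cache.get(reaction_id)
        if entry is None:
            a = np.zeros(self.split.n_columns)
            rid_found = False
            for k, (rid, direction) in enumerate(self.split.columns):
                if rid == reaction_id:
                    a[k] = 1.0 if direction == "fwd" else -1.0
                    rid_found = True
            if not rid_found:
                raise KeyError(reaction_id)
            A = np.vstack([self.split.S, a])
            Kc = null_space(A)
            if Kc.size == 0:
                Kc = np.zeros((self.split.n_columns, 0))
            pinv = np.linalg.pinv(A)
            entry = cache[reaction_id] = (pinv[:, -1], Kc)
        direction_col, Kc = entry
        return direction_col * value, Kc

    def refit_with_fixed_flux(
        self,
        reaction_id: str,
        value: float,
        warm_theta: np.ndarray | None = None,
        solver_opts: dict | None = None,
    ):
        """Re-optimise all remaining parameters at a pinned net flux.

        Returns (ssr, theta_in_constrained_coordinates) or None when the
        pinned value is infeasible within the flux bounds.
        """
        w0c, Kc = self.constrained_basis(reaction_id, value)
        if warm_theta is not None:
            w_warm = self.w0 + self.K @ warm_theta[: self.K.shape[1]]
            uc = Kc.T @ (w_warm - w0c) if Kc.shape[1] else np.zeros(0)
            rest = warm_theta[self.K.shape[1]:]
        else:
            uc = np.zeros(Kc.shape[1])
            rest = (
                0.5 * (self._log_bounds[0] + self._log_bounds[1])
                if self.estimate_conc
                else np.zeros(0)
            )
        theta0 = np.concatenate([uc, rest])
        if len(theta0) == 0:
            # fully determined: the unique solution must respect the box
            if np.any(w0c < self.split.lb - 1e-9) or np.any(
                w0c > self.split.ub + 1e-9
            ):
                return None
            pred = self.predictor.predict(
                np.clip(w0c, self.split.lb, self.split.ub), self.fixed_conc
            )
            ssr = float(np.sum(weighted_residuals(pred, self.measurements) ** 2))
            return ssr, theta0
        result = self._solve_from(theta0, solver_opts, w0=w0c, K=Kc)
        w_fit, _ = self._unpack(result.theta, w0c, Kc)
        viol = max(
            np.max(np.maximum(self.split.lb - w_fit, 0.0), initial=0.0),
            np.max(np.maximum(w_fit - self.split.ub, 0.0), initial=0.0),
        )
        if viol > 1e-6:
            return None  # pinned value infeasible within the flux bounds
        return result.ssr, result.theta


@dataclass
class InstMfaResults:
    """Estimates, uncertainty and diagnostics of one INST-MFA fit."""

    model: InstMfaModel
    theta: np.ndarray
    w_hat: np.ndarray
    c_hat: dict[str, float]
    ssr: float
    dof: int
    n_starts: int
    best_start_index: int
    per_start_ssr: list[float]
    converged: bool
    n_out_of_domain: int = 0
    _ci_cache: dict = field(default_factory=dict, repr=False)

    @property
    def v_hat(self) -> np.ndarray:
        """Net flux estimate per reaction (reaction order of the network)."""
        return self.model.split.net(self.w_hat)

    @property
    def L(self) -> float:
        """Reduced chi-square statistic ssr / dof."""
        return self.ssr / self.dof

    def flux_series(self) -> pd.Series:
        return pd.Series(self.v_hat, index=self.model.network.reaction_ids, name="net_flux")

    def goodness_of_fit(self, alpha: float = 0.05) -> GoodnessOfFit:
        return goodness_of_fit(self.L, self.dof, alpha)

    def conf_int(
        self,
        reaction_ids: list[str] | None = None,
        level: float = 0.99,
        opts: dict | None = None,
    ) -> pd.DataFrame:
        """Per-reaction profile confidence intervals (chi-square threshold)."""
        from .profile import profile_ci

        rids = reaction_ids or self.model.network.reaction_ids
        rows = []
        for rid in rids:
            key = (rid, level)
            if key not in self._ci_cache:
                self._ci_cache[key] = profile_ci(
                    self, rid, level=level, **(opts or {})
                )
            ci = self._ci_cache[key]
            rows.append(
                {
                    "reaction_id": rid,
                    "level": level,
                    "estimate": float(self.flux_series()[rid]),
                    "lower": ci.lower,
                    "upper": ci.upper,
                    "censored_low": ci.censored_low,
                    "censored_high": ci.censored_high,
                    "n_profile_points": len(ci.profile),
                }
            )
        return pd.DataFrame(rows)

    def summary(self, alpha: float = 0.05) -> str:
        gof = self.goodness_of_fit(alpha)
        lines = [
            "INST-MFA fit results",
            "=" * 56,
            f"measurements:          {self.model.measurements.n_records}",
            f"free parameters:       {self.model.n_free_parameters}",
            f"degrees of freedom:    {self.dof}",
            f"SSR (weighted):        {self.ssr:.6g}",
            f"reduced chi-square L:  {self.L:.4f}",
            f"chi-square acceptance: [{gof.interval[0]:.3f}, {gof.interval[1]:.3f}]"
            f" at alpha={alpha} -> {'accept' if gof.accept else ('over-fit' if gof.overfit else 'reject')}",
            f"multi-start:           best of {self.n_starts} (index {self.best_start_index})",
            f"converged:             {self.converged}",
            "-" * 56,
            f"{'reaction':<14}{'net flux':>12}  bounds",
        ]
        for rid, v in self.flux_series().items():
            lo, hi = self.model.network.reaction(rid).flux_bounds
            lines.append(f"{rid:<14}{v:>12.4f}  [{lo:g}, {hi:g}]")
        if self.c_hat and self.model.estimate_conc:
            lines.append("-" * 56)
            lines.append(f"{'pool':<14}{'size':>12}")
            for mid, c in self.c_hat.items():
                lines.append(f"{mid:<14}{c:>12.4f}")
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        payload = {
            "net_fluxes": {r: float(v) for r, v in self.flux_series().items()},
            "split_fluxes": dict(
                zip(self.model.split.column_labels(), map(float, self.w_hat))
            ),
            "pool_sizes": {m: float(c) for m, c in self.c_hat.items()},
            "ssr": self.ssr,
            "dof": self.dof,
            "reduced_chi_square": self.L,
            "n_starts": self.n_starts,
            "best_start_index": self.best_start_index,
            "per_start_ssr": [float(s) for s in self.per_start_ssr],
            "converged": self.converged,
            "n_out_of_domain": self.n_out_of_domain,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def fluxes_to_csv(self, path) -> None:
        self.flux_series().rename_axis("reaction_id").reset_index().to_csv(
            path, index=False
        )
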