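"""Neural-network surrogates of the labelling simulator.

One small fully connected regressor — three hidden layers of 216, 36
and 6 nodes — is trained per (EMU, time point) to map the concatenated
(split flux vector, pool-size vector) to that EMU's MID.  A trained
:class:`SurrogateEnsemble` satisfies the same predictor contract as the
exact simulator, so it can replace the ODE solve inside estimation.

Inputs are standardised per feature (pool sizes on a log scale by
default, since they are sampled log-uniformly over orders of
magnitude); outputs use a linear head whose predictions are clipped to
non-negative values and renormalised onto the probability simplex.
Each surrogate records the standard deviation of its held-out
prediction errors (``holdout_sd``), the quantity that must stay below
the measurement noise for the surrogate swap to be harmless.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, replace

import joblib
import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor

from .emu import EMU, EMUNetwork
from .sampling import ConcentrationSample, FluxSample
from .simulate import MIDTrajectory, simulate_mids

__all__ = [
    "SurrogateSpec",
    "Standardiser",
    "TrainedSurrogate",
    "SurrogateEnsemble",
    "build_training_table",
    "train_surrogate",
    "train_ensemble",
    "validate_ensemble",
]


@dataclass(frozen=True)
class SurrogateSpec:
    """Architecture and training recipe for one surrogate.

    Training uses adam with a two-phase step decay: the last
    ``finetune_fraction`` of the epoch budget runs at
    ``learning_rate * finetune_lr_factor``, which removes most of the
    minibatch jitter left by a constant learning rate.
    """

    hidden_sizes: tuple[int, ...] = (216, 36, 6)
    activation: str = "relu"
    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    validation_fraction: float = 0.2
    log_concentrations: bool = True
    finetune_fraction: float = 0.25
    finetune_lr_factor: float = 0.1

    def __post_init__(self) -> None:
        if any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("hidden layer sizes must be positive")
        if not (0.0 < self.validation_fraction < 1.0):
            raise ValueError("validation fraction must be in (0, 1)")
        if not (0.0 <= self.finetune_fraction < 1.0):
            raise ValueError("finetune fraction must be in [0, 1)")


@dataclass(frozen=True)
class Standardiser:
    """Per-feature affine map x -> (x - mean) / scale (zero-variance safe)."""

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardiser":
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        return cls(mean, scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.scale

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        return Z * self.scale + self.mean


def _sample_hash(w: np.ndarray, c: np.ndarray) -> str:
    payload = np.round(np.concatenate([w, c]), 12).tobytes()
    return hashlib.sha256(payload).hexdigest()


def _input_row(w, c, log_concentrations: bool) -> np.ndarray:
    c = np.asarray(c, float)
    return np.concatenate([np.asarray(w, float), np.log(c) if log_concentrations else c])


def build_training_table(
    flux_samples: list[FluxSample],
    conc_samples: list[ConcentrationSample],
    trajectories: list[dict[str, MIDTrajectory]],
    emu: EMU,
    timepoint: float,
    log_concentrations: bool = True,
    standardiser: Standardiser | None = None,
):
    """(standardised inputs, MID targets, standardiser) for one grid cell."""
    if not (len(flux_samples) == len(conc_samples) == len(trajectories)):
        raise ValueError("samples and trajectories must align one-to-one")
    X = np.stack(
        [_input_row(f.w, c.c, log_concentrations) for f, c in zip(flux_samples, conc_samples)]
    )
    Y = np.empty((len(trajectories), emu.size + 1))
    for i, trajs in enumerate(trajectories):
        tr = trajs.get(emu.id)
        if tr is None:
            raise KeyError(f"trajectory set {i} lacks EMU {emu.id}")
        Y[i] = tr.at(timepoint)
    std = standardiser or Standardiser.fit(X)
    return std.transform(X), Y, std


@dataclass
class TrainedSurrogate:
    spec: SurrogateSpec
    emu: EMU
    timepoint: float
    regressor: MLPRegressor
    standardiser: Standardiser
    holdout_sd: float
    input_min: np.ndarray  # training hull, raw input scale
    input_max: np.ndarray
    initial_loss: float
    final_loss: float

    def predict_raw(self, X_std: np.ndarray) -> np.ndarray:
        out = self.regressor.predict(X_std)
        return out.reshape(-1, self.emu.size + 1)


def train_surrogate(
    spec: SurrogateSpec,
    X_std: np.ndarray,
    Y: np.ndarray,
    emu: EMU,
    timepoint: float,
    standardiser: Standardiser,
    input_min: np.ndarray | None = None,
    input_max: np.ndarray | None = None,
) -> TrainedSurrogate:
    """Deterministic (seeded) training with an internal holdout split."""
    if len(X_std) < 10:
        raise ValueError("need at least 10 training rows")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(X_std))
    n_hold = max(1, int(round(spec.validation_fraction * len(X_std))))
    hold, train = order[:n_hold], order[n_hold:]
    n_fine = int(round(spec.finetune_fraction * spec.epochs))
    n_main = max(1, spec.epochs - n_fine)
    reg = MLPRegressor(
        hidden_layer_sizes=spec.hidden_sizes,
        activation=spec.activation,
        solver="adam",
        learning_rate_init=spec.learning_rate,
        batch_size=spec.batch_size,
        max_iter=n_main,
        n_iter_no_change=n_main,  # run the full budget; no early stop
        random_state=spec.seed,
        tol=0.0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        reg.fit(X_std[train], Y[train])
        initial_loss = float(reg.loss_curve_[0])
        if n_fine > 0:
            reg.warm_start = True
            reg.learning_rate_init = spec.learning_rate * spec.finetune_lr_factor
            reg.max_iter = n_fine
            reg.n_iter_no_change = n_fine
            reg.fit(X_std[train], Y[train])
    if not np.all(np.isfinite(reg.loss_curve_)):
        raise RuntimeError(f"non-finite training loss for {emu.id} @ t={timepoint}")
    resid = reg.predict(X_std[hold]).reshape(len(hold), -1) - Y[hold]
    raw = standardiser.inverse(X_std)
    return TrainedSurrogate(
        spec=spec,
        emu=emu,
        timepoint=float(timepoint),
        regressor=reg,
        standardiser=standardiser,
        holdout_sd=float(resid.std()),
        input_min=raw.min(axis=0) if input_min is None else input_min,
        input_max=raw.max(axis=0) if input_max is None else input_max,
        initial_loss=initial_loss,
        final_loss=float(reg.loss_curve_[-1]),
    )


class SurrogateEnsemble:
    """Complete grid of trained surrogates; drop-in forward predictor."""

    def __init__(
        self,
        members: dict[tuple[str, float], TrainedSurrogate],
        input_labels: list[str],
        log_concentrations: bool,
        conc_ids: list[str],
        provenance: dict | None = None,
    ):
        if not members:
            raise ValueError("empty ensemble")
        self.members = dict(members)
        self.input_labels = list(input_labels)
        self.log_concentrations = log_concentrations
        self.conc_ids = list(conc_ids)
        self.provenance = provenance or {}
        self.last_out_of_domain = False

    @property
    def grid(self) -> list[tuple[str, float]]:
        return sorted(self.members)

    def holdout_sd_table(self) -> pd.DataFrame:
        rows = [
            {"emu_id": k[0], "time": k[1], "holdout_sd": m.holdout_sd}
            for k, m in sorted(self.members.items())
        ]
        return pd.DataFrame(rows)

    def predict(self, w, conc) -> dict[tuple[str, float], np.ndarray]:
        c = np.array([conc[m] for m in self.conc_ids], float)
        x = _input_row(w, c, self.log_concentrations)
        out: dict[tuple[str, float], np.ndarray] = {}
        oob = False
        for key, member in self.members.items():
            xs = member.standardiser.transform(x[None, :])
            raw = x  # hull check on the raw input scale
            if np.any(raw < member.input_min - 1e-9) or np.any(
                raw > member.input_max + 1e-9
            ):
                oob = True
            mid = member.predict_raw(xs)[0]
            mid = np.clip(mid, 0.0, None)
            s = mid.sum()
            out[key] = mid / s if s > 0 else np.full_like(mid, 1.0 / len(mid))
        self.last_out_of_domain = oob
        return out

    # -- persistence ---------------------------------------------------
    def save(self, path) -> None:
        joblib.dump(
            {
                "members": self.members,
                "input_labels": self.input_labels,
                "log_concentrations": self.log_concentrations,
                "conc_ids": self.conc_ids,
                "provenance": self.provenance,
            },
            path,
            compress=3,
        )

    @classmethod
    def load(cls, path) -> "SurrogateEnsemble":
        blob = joblib.load(path)
        return cls(
            blob["members"],
            blob["input_labels"],
            blob["log_concentrations"],
            blob["conc_ids"],
            blob["provenance"],
        )


def simulate_training_set(
    emu_network: EMUNetwork,
    flux_samples: list[FluxSample],
    conc_samples: list[ConcentrationSample],
    timepoints,
    solver_opts: dict | None = None,
) -> list[dict[str, MIDTrajectory]]:
    return [
        simulate_mids(emu_network, f.w, c.as_dict(), timepoints, solver_opts=solver_opts)
        for f, c in zip(flux_samples, conc_samples)
    ]


def train_ensemble(
    emu_network: EMUNetwork,
    flux_samples: list[FluxSample],
    conc_samples: list[ConcentrationSample],
    timepoints,
    target_emus: list[EMU] | None = None,
    spec: SurrogateSpec = SurrogateSpec(),
    trajectories: list[dict[str, MIDTrajectory]] | None = None,
) -> SurrogateEnsemble:
    """Train the full (EMU, time point) grid from one shared sample set."""
    network = emu_network.network
    timepoints = [float(t) for t in timepoints]
    targets = target_emus if target_emus is not None else list(emu_network.targets)
    if trajectories is None:
        trajectories = simulate_training_set(
            emu_network, flux_samples, conc_samples, timepoints
        )
    members: dict[tuple[str, float], TrainedSurrogate] = {}
    std: Standardiser | None = None
    for emu in sorted(set(targets)):
        for t in timepoints:
            X_std, Y, std = build_training_table(
                flux_samples,
                conc_samples,
                trajectories,
                emu,
                t,
                log_concentrations=spec.log_concentrations,
                standardiser=std,
            )
            member_spec = replace(
                spec, seed=spec.seed + len(members)  # distinct init per cell
            )
            members[(emu.id, t)] = train_surrogate(
                member_spec, X_std, Y, emu, t, std
            )
    split = network.split_system()
    labels = split.column_labels() + [f"conc:{m}" for m in network.balanced_metabolites]
    provenance = {
        "n_samples": len(flux_samples),
        "sample_hashes": [
            _sample_hash(f.w, c.c) for f, c in zip(flux_samples, conc_samples)
        ],
        "spec_seed": spec.seed,
    }
    return SurrogateEnsemble(
        members, labels, spec.log_concentrations, network.balanced_metabolites, provenance
    )


def validate_ensemble(
    ensemble: SurrogateEnsemble,
    flux_samples: list[FluxSample],
    conc_samples: list[ConcentrationSample],
    trajectories: list[dict[str, MIDTrajectory]],
) -> pd.DataFrame:
    """Per-(EMU, time point) sd of surrogate-vs-simulated MIDs, held out.

    Raises if any validation sample was seen during training (checked
    by sample hash).
    """
    train_hashes = set(ensemble.provenance.get("sample_hashes", []))
    for f, c in zip(flux_samples, conc_samples):
        if _sample_hash(f.w, c.c) in train_hashes:
            raise ValueError("validation sample overlaps the training set")
    errors: dict[tuple[str, float], list[float]] = {k: [] for k in ensemble.grid}
    for f, c, trajs in zip(flux_samples, conc_samples, trajectories):
        pred = ensemble.predict(f.w, c.as_dict())
        for (emu_id, t), mid in pred.items():
            truth = trajs[emu_id].at(t)
            errors[(emu_id, t)].extend((mid - truth).tolist())
    rows = [
        {"emu_id": k[0], "time": k[1], "sd": float(np.std(errs))}
        for k, errs in sorted(errors.items())
    ]
    frame = pd.DataFrame(rows)
    frame.attrs["median_sd"] = float(frame["sd"].median())
    return frame
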