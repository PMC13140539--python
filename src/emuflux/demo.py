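"""End-to-end pipeline: sample -> simulate -> train -> fit -> ci -> evaluate.

Each stage writes its artifacts into the output directory and records
the derived seed plus SHA-256 hashes of everything it wrote in
``manifest.json``.  A failed stage leaves the manifest with the stages
completed so far.  Two runs with the same master seed produce
byte-identical manifests.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import fixtures
from .config import default_config, stage_seeds
from .evaluate import RecoveryReport, recovery_experiment
from .model import InstMfaModel
from .sampling import sample_concentrations, sample_flux_space, save_samples
from .simulate import trajectories_to_frame
from .surrogate import SurrogateSpec, simulate_training_set, train_ensemble

__all__ = ["run_demo", "build_scenario"]


def build_scenario(config: dict, seed: int) -> fixtures.ToyScenario:
    name = config.get("scenario", "toy")
    noise_sd = config["measurements"]["noise_sd"]
    timepoints = tuple(config["simulation"]["timepoints"])
    if name == "toy":
        return fixtures.toy_scenario(seed=seed, noise_sd=noise_sd, timepoints=timepoints)
    if name == "rich":
        return fixtures.rich_scenario(seed=seed, noise_sd=noise_sd, timepoints=timepoints)
    raise ValueError(f"unknown scenario {name!r}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _surrogate_spec(config: dict, seed: int) -> SurrogateSpec:
    s = config["surrogate"]
    return SurrogateSpec(
        hidden_sizes=tuple(s["hidden_sizes"]),
        activation=s["activation"],
        epochs=int(s["epochs"]),
        batch_size=int(s["batch_size"]),
        learning_rate=float(s["learning_rate"]),
        validation_fraction=float(s["validation_fraction"]),
        log_concentrations=bool(s["log_concentrations"]),
        seed=seed,
    )


def run_demo(config: dict | None = None, out_dir="demo_out", master_seed: int | None = None) -> dict:
    """Run the full workflow on the configured scenario; return the manifest."""
    config = config or default_config()
    if master_seed is None:
        master_seed = int(config.get("seed", 1234))
    seeds = stage_seeds(master_seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "master_seed": master_seed,
        "stage_seeds": seeds,
        "scenario": config.get("scenario", "toy"),
        "stages": {},
    }

    def record(stage: str, files: list[Path]) -> None:
        manifest["stages"][stage] = {
            "seed": seeds[stage],
            "files": {f.name: _sha256(f) for f in sorted(files)},
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )

    scenario = build_scenario(config, seeds["scenario"])
    timepoints = list(scenario.timepoints)
    try:
        # 1. sample the solution space
        n = int(config["sampling"]["n_samples"])
        flux_samples = sample_flux_space(
            scenario.network, n, seed=seeds["sample"], method=config["sampling"]["method"]
        )
        conc_samples = sample_concentrations(
            scenario.network, n, seed=seeds["sample"] + 1,
            distribution=config["sampling"]["distribution"],
        )
        save_samples(out / "samples.csv", flux_samples, conc_samples,
                     meta={"seed": seeds["sample"], "method": config["sampling"]["method"]})
        record("sample", [out / "samples.csv", out / "samples.csv.json"])

        # 2. simulate training MIDs + synthetic measurements
        solver_opts = {
            "rtol": float(config["simulation"]["rtol"]),
            "atol": float(config["simulation"]["atol"]),
        }
        trajectories = simulate_training_set(
            scenario.emu_network, flux_samples, conc_samples, timepoints,
            solver_opts=solver_opts,
        )
        frames = []
        for i, trajs in enumerate(trajectories[: min(5, len(trajectories))]):
            frame = trajectories_to_frame(trajs)
            frame.insert(0, "sample", i)
            frames.append(frame)
        pd.concat(frames).to_csv(out / "trajectories_head.csv", index=False)
        measurements = fixtures.synth_measurements(scenario, seed=seeds["simulate"])
        measurements.to_csv(out / "measurements.csv")
        record("simulate", [out / "trajectories_head.csv", out / "measurements.csv"])

        # 3. train the surrogate ensemble
        spec = _surrogate_spec(config, seeds["train"])
        ensemble = train_ensemble(
            scenario.emu_network, flux_samples, conc_samples, timepoints,
            target_emus=scenario.measured_emus, spec=spec, trajectories=trajectories,
        )
        ensemble.save(out / "ensemble.joblib")
        ensemble.holdout_sd_table().to_csv(out / "surrogate_report.csv", index=False)
        record("train", [out / "ensemble.joblib", out / "surrogate_report.csv"])

        # 4. fit fluxes and pools from the measurements
        conc_mode = config["estimation"]["concentrations"]
        model = InstMfaModel(
            scenario.network,
            measurements,
            ensemble,
            concentrations=conc_mode if conc_mode == "estimate" else scenario.true_conc.as_dict(),
        )
        results = model.fit(n_starts=int(config["estimation"]["n_starts"]), seed=seeds["fit"])
        results.to_json(out / "fit.json")
        results.fluxes_to_csv(out / "fluxes.csv")
        (out / "fit_summary.txt").write_text(results.summary() + "\n")
        record("fit", [out / "fit.json", out / "fluxes.csv", out / "fit_summary.txt"])

        # 5. profile confidence intervals
        ci_frame = results.conf_int(
            reaction_ids=list(config["ci"]["reactions"]),
            level=float(config["ci"]["level"]),
        )
        ci_frame.to_csv(out / "ci.csv", index=False)
        record("ci", [out / "ci.csv"])

        # 6. recoverability evaluation
        ev = config["evaluation"]
        true_mat, est_mat, meta = recovery_experiment(
            scenario.network,
            scenario.emu_network,
            int(ev["n_distributions"]),
            timepoints,
            scenario.measured_emus,
            config["measurements"]["noise_sd"],
            seeds["evaluate"],
            ensemble,
            n_starts=int(ev.get("n_starts", 2)),
        )
        report = RecoveryReport.from_experiment(
            scenario.network, true_mat, est_mat, meta, seed=seeds["evaluate"],
            n_permutations=int(ev["n_permutations"]),
            thresholds=tuple(ev["thresholds"]),
        )
        report.to_csv(out / "recovery.csv")
        (out / "recovery_summary.json").write_text(
            json.dumps({"counts": report.counts, "n_distributions": report.n_distributions},
                       indent=2, sort_keys=True)
        )
        record("evaluate", [out / "recovery.csv", out / "recovery_summary.json"])
    except Exception as exc:  # partial progress stays on disk
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise
    return manifest
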