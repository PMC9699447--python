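"""Experiment orchestration: factorial (unit, length, T*, seed) sweeps from a
declarative config, with a manifest, resumability and composition ranking."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import ContactSpec, stem_distribution_frame, sweep_summary
from .forcefield import ForceField
from .integrator import RunProtocol, run_quench
from .io import write_sidecar, write_xyz
from .sequence import build_sequence, parse_repeat_spec

__all__ = ["ExperimentConfig", "ExperimentError", "run_experiment",
           "compare_compositions"]

logger = logging.getLogger("hnpmd.pipeline")

#: Observables emitted into the long-format results table.
_RESULT_OBSERVABLES = (
    "per_bond_stretch", "per_angle", "per_bond_stretch_bend", "per_dihedral",
    "per_bond_nonbonded", "per_bond_total",
    "rg", "rgx", "rgy", "rgz", "order_parameter", "contacts",
)


class ExperimentError(RuntimeError):
    """Raised when one or more runs of an experiment failed."""


@dataclass(frozen=True)
class ExperimentConfig:
    """Declarative description of one factorial simulation experiment."""

    units: tuple[str, ...]
    lengths: tuple[int, ...]
    tstar_grid: tuple[float, ...]
    seeds: tuple[int, ...]
    steps_per_leg: int = 100_000
    init_tstar: float = 1.5
    init_steps: int = 20_000
    equilibration_fraction: float = 0.5
    snapshot_stride: int = 500
    dt_fs: float = 2.5
    tau_fs: float = 25.0
    mass: float = 110.0
    output_dir: str = "experiment_out"
    forcefield: dict = field(default_factory=dict)
    ramp: bool = False  # single continuous cooling ramp instead of independent runs

    def __post_init__(self) -> None:
        if not (self.units and self.lengths and self.tstar_grid and self.seeds):
            raise ValueError("units, lengths, tstar_grid and seeds must be nonempty")
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("seeds must be distinct")
        for tstar in self.tstar_grid:
            if not 0.0 < tstar < 10.0:
                raise ValueError(f"T* must lie in (0, 10), got {tstar}")
        for unit in self.units:
            parse_repeat_spec(unit)  # validates spelling

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "units": list(self.units), "lengths": list(self.lengths),
            "tstar_grid": [float(t) for t in self.tstar_grid],
            "seeds": list(self.seeds),
            "steps_per_leg": self.steps_per_leg,
            "init_tstar": self.init_tstar, "init_steps": self.init_steps,
            "equilibration_fraction": self.equilibration_fraction,
            "snapshot_stride": self.snapshot_stride,
            "dt_fs": self.dt_fs, "tau_fs": self.tau_fs, "mass": self.mass,
            "output_dir": self.output_dir,
            "forcefield": dict(self.forcefield),
            "ramp": self.ramp,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        data = dict(data)
        for key in ("units", "lengths", "tstar_grid", "seeds"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def make_forcefield(self) -> ForceField:
        return ForceField.from_dict(self.forcefield) if self.forcefield else ForceField()

    def run_matrix(self) -> list[dict]:
        """The planned (unit, length, T*, seed) factorial, one dict per run."""
        runs = []
        for unit in self.units:
            for length in self.lengths:
                for tstar in self.tstar_grid:
                    for seed in self.seeds:
                        runs.append({
                            "run_id": f"{unit}_N{length}_T{tstar:g}_s{seed}",
                            "unit": unit, "n_beads": int(length),
                            "tstar": float(tstar), "seed": int(seed),
                            "derived_seed": _derive_seed(unit, length, tstar, seed),
                        })
        return runs


def _derive_seed(unit: str, length: int, tstar: float, seed: int) -> int:
    """Deterministic per-run seed decorrelating the factorial cells."""
    key = f"{unit}|{length}|{tstar:.6g}|{seed}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big")


def _execute_run(cfg: ExperimentConfig, ff: ForceField, run: dict,
                 run_dir: Path) -> None:
    seq = build_sequence(run["unit"], run["n_beads"])
    schedule = [(cfg.init_tstar, cfg.init_steps), (run["tstar"], cfg.steps_per_leg)]
    protocol = RunProtocol(schedule=tuple(schedule), seed=run["derived_seed"],
                           dt_fs=cfg.dt_fs, snapshot_stride=cfg.snapshot_stride,
                           tau_fs=cfg.tau_fs, mass=cfg.mass)
    traj = run_quench(seq, ff, protocol)
    production = traj.at_tstar(run["tstar"])
    table, stem_dists = sweep_summary(
        {run["tstar"]: production},
        equilibration_fraction=cfg.equilibration_fraction,
        bootstrap_seed=run["derived_seed"])

    run_dir.mkdir(parents=True, exist_ok=True)
    write_xyz(traj, run_dir / "traj.xyz")
    write_sidecar(traj, run_dir / "run.yaml", ff)
    table.to_csv(run_dir / "summary.csv", index=False)
    stem_distribution_frame(stem_dists).to_csv(run_dir / "stems.csv", index=False)


def _collect_run(run: dict, run_dir: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    table = pd.read_csv(run_dir / "summary.csv")
    stems = pd.read_csv(run_dir / "stems.csv")
    keys = {"unit": run["unit"], "n_beads": run["n_beads"],
            "tstar": run["tstar"], "seed": run["seed"]}
    records = []
    for name in _RESULT_OBSERVABLES:
        records.append({**keys, "observable": name,
                        "mean": float(table[f"{name}_mean"].iloc[0]),
                        "se": float(table[f"{name}_se"].iloc[0])})
    long = pd.DataFrame(records)
    for col, val in keys.items():
        stems[col] = val
    return long, stems


def run_experiment(config: ExperimentConfig, *, dry_run: bool = False,
                   resume: bool = False) -> dict:
    """Run every (unit, length, T*, seed) cell and aggregate the results.

    Writes per-run trajectories and summaries under ``output_dir/runs/``, a
    merged long-format ``results.csv`` and ``stems.csv``, and a
    ``manifest.json`` recording the config hash and per-run status.  With
    ``resume=True`` runs whose summary already exists are skipped.  Partial
    failures are recorded and the remaining runs continue; an
    :class:`ExperimentError` is raised at the end if any run failed.

    Returns the manifest dict (with a ``"planned"`` key only for dry runs).
    """
    runs = config.run_matrix()
    if dry_run:
        for run in runs:
            logger.info("planned: %s", run["run_id"])
        return {"config_hash": config.config_hash(), "planned": runs}

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ff = config.make_forcefield()
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "hnpmd_version": __version__,
        "numpy_version": np.__version__,
        "runs": [],
    }
    results_parts, stems_parts, failures = [], [], []
    for run in runs:
        run_dir = out / "runs" / run["run_id"]
        entry = dict(run)
        done = (run_dir / "summary.csv").exists()
        if resume and done:
            entry["status"] = "skipped (resume)"
        else:
            logger.info("running %s", run["run_id"])
            try:
                _execute_run(config, ff, run, run_dir)
                entry["status"] = "ok"
            except Exception as exc:  # noqa: BLE001 - record and continue
                entry["status"] = f"failed: {exc}"
                failures.append(run["run_id"])
                logger.error("run %s failed: %s", run["run_id"], exc)
                manifest["runs"].append(entry)
                continue
        try:
            long, stems = _collect_run(run, run_dir)
            results_parts.append(long)
            stems_parts.append(stems)
        except Exception as exc:  # noqa: BLE001
            entry["status"] = f"failed (collect): {exc}"
            failures.append(run["run_id"])
        manifest["runs"].append(entry)

    if results_parts:
        results = pd.concat(results_parts, ignore_index=True)
        results.to_csv(out / "results.csv", index=False)
    if stems_parts:
        stems_all = pd.concat(stems_parts, ignore_index=True)
        stems_all.to_csv(out / "stems.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    if failures:
        raise ExperimentError(
            f"{len(failures)} run(s) failed: {', '.join(failures)}")
    return manifest


def compare_compositions(results: pd.DataFrame, observable: str, tstar: float,
                         *, n_bootstrap: int = 1000, seed: int = 0,
                         atol: float = 1e-9) -> pd.DataFrame:
    """Rank repeat units by an observable's mean at one temperature.

    ``results`` is the long-format table from :func:`run_experiment`.  Means
    are taken over seeds; confidence intervals are 2.5/97.5 percentiles of
    seeded bootstrap resamples over per-seed means (degenerate when only one
    seed is present).  Ties are broken by unit name.
    """
    have_obs = sorted(results["observable"].unique())
    if observable not in have_obs:
        raise KeyError(f"observable {observable!r} not found; available: {have_obs}")
    sub = results[(results["observable"] == observable)
                  & (np.abs(results["tstar"] - tstar) <= atol)]
    if sub.empty:
        have_t = sorted(results["tstar"].unique())
        raise KeyError(f"no rows at T* = {tstar}; available temperatures: {have_t}")
    rng = np.random.default_rng(seed)
    rows = []
    for unit, grp in sub.groupby("unit"):
        vals = grp["mean"].to_numpy(dtype=float)
        mean = float(vals.mean())
        if len(vals) > 1:
            boots = np.array([
                vals[rng.integers(0, len(vals), len(vals))].mean()
                for _ in range(n_bootstrap)])
            lo, hi = np.percentile(boots, [2.5, 97.5])
        else:
            lo = hi = mean
        rows.append({"unit": unit, "mean": mean,
                     "ci_low": float(lo), "ci_high": float(hi),
                     "n_seeds": int(len(vals))})
    table = pd.DataFrame(rows).sort_values(
        ["mean", "unit"], ascending=[False, True], ignore_index=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table
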