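"""Trajectory and metadata I/O: multi-frame XYZ, CA-only PDB, YAML sidecars.

Coordinates are stored in nm (declared in the XYZ comment line, which also
carries the frame time, thermostat target and energy terms so that analysis
round-trips through plain text).
"""

from __future__ import annotations

import numpy as np
import yaml

from .forcefield import ForceField
from .integrator import Trajectory
from .sequence import Sequence

__all__ = ["write_xyz", "read_xyz", "write_pdb", "write_sidecar", "read_sidecar"]


def write_xyz(traj: Trajectory, path) -> None:
    """Write all frames as multi-frame XYZ; element column = residue class."""
    labels = [c.value for c in traj.sequence.classes]
    n = len(labels)
    with open(path, "w") as fh:
        for k in range(traj.n_frames):
            en = traj.energies[k]
            fh.write(f"{n}\n")
            fh.write(
                "units=nm t_ps=%.6f tstar=%.6g "
                "e_kcal=%.10g,%.10g,%.10g,%.10g,%.10g\n"
                % (traj.times[k], traj.tstars[k], en[0], en[1], en[2], en[3], en[4])
            )
            pos = traj.positions[k]
            for i in range(n):
                fh.write("%s %.9f %.9f %.9f\n"
                         % (labels[i], pos[i, 0], pos[i, 1], pos[i, 2]))


def read_xyz(path, *, mass: float = 110.0) -> Trajectory:
    """Read a multi-frame XYZ written by :func:`write_xyz`.

    Velocities are not stored in XYZ and come back as zeros; frame times,
    thermostat targets and energies are recovered from the comment lines
    (zero / NaN when a foreign XYZ lacks them).
    """
    frames: list[np.ndarray] = []
    times: list[float] = []
    tstars: list[float] = []
    energies: list[list[float]] = []
    labels: list[str] | None = None
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            comment = fh.readline()
            meta = dict(
                item.split("=", 1) for item in comment.split() if "=" in item)
            times.append(float(meta.get("t_ps", 0.0)))
            tstars.append(float(meta.get("tstar", "nan")))
            if "e_kcal" in meta:
                energies.append([float(x) for x in meta["e_kcal"].split(",")])
            else:
                energies.append([np.nan] * 5)
            pos = np.empty((n, 3))
            frame_labels = []
            for i in range(n):
                parts = fh.readline().split()
                frame_labels.append(parts[0])
                pos[i] = [float(x) for x in parts[1:4]]
            if labels is None:
                labels = frame_labels
            frames.append(pos)
    if not frames or labels is None:
        raise ValueError(f"{path}: no XYZ frames found")
    seq = Sequence.from_labels(labels)
    n = len(seq)
    positions = np.stack(frames)
    return Trajectory(
        sequence=seq,
        positions=positions,
        velocities=np.zeros_like(positions),
        times=np.asarray(times),
        tstars=np.asarray(tstars),
        energies=np.asarray(energies),
        masses=np.full(n, float(mass)),
    )


def write_pdb(traj: Trajectory, path, *, scale: float = 10.0) -> None:
    """Write frames as CA-only PDB MODEL records (coordinates nm -> Angstrom)."""
    res_names = {"H": "PHB", "N": "NEU", "P": "PHL"}
    with open(path, "w") as fh:
        for k in range(traj.n_frames):
            fh.write(f"MODEL     {k + 1:4d}\n")
            pos = traj.positions[k] * scale
            for i, cls in enumerate(traj.sequence.classes):
                fh.write(
                    "ATOM  %5d  CA  %3s A%4d    %8.3f%8.3f%8.3f  1.00  0.00           C\n"
                    % (i + 1, res_names[cls.value], i + 1,
                       pos[i, 0], pos[i, 1], pos[i, 2])
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_sidecar(traj: Trajectory, path, ff: ForceField | None = None) -> None:
    """YAML sidecar: run metadata plus the force-field parameters."""
    doc = {"run": dict(traj.metadata)}
    if ff is not None:
        doc["forcefield"] = ff.to_dict()
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_sidecar(path) -> tuple[dict, ForceField | None]:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    ff = ForceField.from_dict(doc["forcefield"]) if "forcefield" in doc else None
    return doc.get("run", {}), ff
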