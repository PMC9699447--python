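"""Structural observables: gyration tensor, bond orientational order,
trans/gauche stems, residue contacts, and per-temperature sweep summaries.

Conventions
-----------
* The reference ("z") axis for the order parameter is the gyration-tensor
  principal axis with the largest eigenvalue — the chain's long axis.
* Trans/gauche is a property of the N-3 dihedrals; a stem is a maximal run
  of at least ``min_stem`` (default 4) consecutive trans dihedrals and its
  length is counted in dihedral units, so a fully trans chain of N beads
  carries one stem of length N-3.
* A contact is an unordered bead pair with sequence separation |i-j| > lcut
  and distance <= Rcut.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence as TypingSequence

import numpy as np
import pandas as pd

from .forcefield import ChainState, dihedral_angles
from .integrator import Trajectory

__all__ = [
    "GyrationResult",
    "StemDistribution",
    "ContactSpec",
    "gyration",
    "orientational_order",
    "principal_axes",
    "dihedral_states",
    "stems",
    "stem_distribution",
    "contact_count",
    "sweep_summary",
]

#: Trans iff |phi| <= pi/3 (phi measured from the trans state).
TRANS_THRESHOLD = np.pi / 3.0
#: "More than three consecutive" trans dihedrals: minimum stem length 4.
DEFAULT_MIN_STEM = 4


@dataclass(frozen=True)
class GyrationResult:
    """Radius of gyration and its components along the principal axes.

    Components are sorted ascending so ``rgz`` is along the long axis;
    rg**2 == rgx**2 + rgy**2 + rgz**2 holds exactly.
    """

    rg: float
    rgx: float
    rgy: float
    rgz: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.rg, self.rgx, self.rgy, self.rgz)


@dataclass(frozen=True)
class ContactSpec:
    """Contact definition: distance cutoff (nm) and sequence-separation cutoff."""

    rcut: float = 0.65
    lcut: int = 3


@dataclass(frozen=True)
class StemDistribution:
    """Normalized histogram of stem lengths (dihedral-bond units)."""

    histogram: dict[int, float]
    n_stems_observed: int

    def probability(self, n_tr: int) -> float:
        return self.histogram.get(n_tr, 0.0)

    @property
    def mean_length(self) -> float:
        if not self.histogram:
            return float("nan")
        return sum(k * p for k, p in self.histogram.items())

    @property
    def mode(self) -> int | None:
        if not self.histogram:
            return None
        return max(self.histogram, key=lambda k: (self.histogram[k], -k))


def _gyration_tensor(positions: np.ndarray) -> np.ndarray:
    x = positions - positions.mean(axis=0)
    return (x.T @ x) / len(positions)


def gyration(frame: ChainState | np.ndarray) -> GyrationResult:
    """Radius of gyration (unit masses) with principal-axis components.

    rg is the root-mean-square bead distance from the center of geometry;
    the components are square roots of the gyration-tensor eigenvalues in
    ascending order.
    """
    positions = frame.positions if isinstance(frame, ChainState) else np.asarray(frame)
    s = _gyration_tensor(positions)
    eigvals = np.linalg.eigvalsh(s)  # ascending
    eigvals = np.clip(eigvals, 0.0, None)
    comps = np.sqrt(eigvals)
    return GyrationResult(rg=float(np.sqrt(eigvals.sum())),
                          rgx=float(comps[0]), rgy=float(comps[1]),
                          rgz=float(comps[2]))


def principal_axes(positions: np.ndarray) -> np.ndarray:
    """Gyration-tensor eigenvectors as columns, ascending eigenvalue order
    (column 2 = the chain's long axis)."""
    _, vecs = np.linalg.eigh(_gyration_tensor(np.asarray(positions)))
    return vecs


def orientational_order(frame: ChainState | np.ndarray, *,
                        axis: np.ndarray | None = None,
                        literal_count: bool = False) -> float:
    """Second-Legendre bond alignment P = <(3 cos^2 a - 1)/2> in [-0.5, 1].

    ``a`` is the angle between each bond vector and the reference axis
    (default: the long principal axis of the frame's gyration tensor).  All
    N-1 bonds are averaged; ``literal_count=True`` instead divides the sum
    over the last N-2 bonds by N-2.  Zero-length bonds are skipped.
    """
    positions = frame.positions if isinstance(frame, ChainState) else np.asarray(frame)
    if axis is None:
        axis = principal_axes(positions)[:, 2]
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    bonds = np.diff(positions, axis=0)
    norms = np.linalg.norm(bonds, axis=1)
    ok = norms > 1e-12
    if literal_count:
        ok = ok.copy()
        ok[0] = False  # sum over bonds 2..N-1, prefactor 1/(N-2)
    if not np.any(ok):
        return float("nan")
    cosa = (bonds[ok] @ axis) / norms[ok]
    return float(np.mean(1.5 * cosa * cosa - 0.5))


def dihedral_states(frame: ChainState | np.ndarray) -> np.ndarray:
    """Boolean array over the N-3 dihedrals: True = trans (|phi| <= pi/3).

    Degenerate (collinear) dihedrals have phi defined as 0 and label trans.
    """
    positions = frame.positions if isinstance(frame, ChainState) else np.asarray(frame)
    phi = dihedral_angles(positions)
    return np.abs(phi) <= TRANS_THRESHOLD


def stems(labels: TypingSequence[bool] | np.ndarray,
          min_stem: int = DEFAULT_MIN_STEM) -> list[int]:
    """Lengths of maximal trans runs of at least ``min_stem`` dihedrals."""
    out: list[int] = []
    run = 0
    for lab in labels:
        if lab:
            run += 1
        else:
            if run >= min_stem:
                out.append(run)
            run = 0
    if run >= min_stem:
        out.append(run)
    return out


def stem_distribution(frames: Iterable[ChainState | np.ndarray],
                      min_stem: int = DEFAULT_MIN_STEM) -> StemDistribution:
    """Pool stems over frames and normalize the length histogram to sum 1."""
    counts: dict[int, int] = {}
    total = 0
    for frame in frames:
        for length in stems(dihedral_states(frame), min_stem=min_stem):
            counts[length] = counts.get(length, 0) + 1
            total += 1
    if total == 0:
        return StemDistribution({}, 0)
    hist = {k: c / total for k, c in sorted(counts.items())}
    return StemDistribution(hist, total)


def contact_count(frame: ChainState | np.ndarray,
                  spec: ContactSpec = ContactSpec()) -> int:
    """Number of unordered pairs with |i-j| > lcut and r_ij <= Rcut."""
    positions = frame.positions if isinstance(frame, ChainState) else np.asarray(frame)
    i, j = np.triu_indices(len(positions), k=spec.lcut + 1)
    if i.size == 0:
        return 0
    d = np.linalg.norm(positions[i] - positions[j], axis=1)
    return int(np.count_nonzero(d <= spec.rcut))


# --- sweep aggregation -------------------------------------------------------

_OBSERVABLES = (
    "per_bond_stretch", "per_angle", "per_bond_stretch_bend", "per_dihedral",
    "per_bond_nonbonded", "per_bond_total",
    "rg", "rgx", "rgy", "rgz", "order_parameter", "contacts",
)


def _frame_observables(traj: Trajectory, idx: np.ndarray,
                       contact_spec: ContactSpec) -> dict[str, np.ndarray]:
    n = len(traj.sequence)
    es, eb, et, enb = (traj.energies[idx, k] for k in range(4))
    vals: dict[str, list[float]] = {k: [] for k in ("rg", "rgx", "rgy", "rgz",
                                                    "order_parameter", "contacts")}
    for i in idx:
        pos = traj.positions[i]
        g = gyration(pos)
        vals["rg"].append(g.rg)
        vals["rgx"].append(g.rgx)
        vals["rgy"].append(g.rgy)
        vals["rgz"].append(g.rgz)
        vals["order_parameter"].append(orientational_order(pos))
        vals["contacts"].append(contact_count(pos, contact_spec))
    out = {k: np.asarray(v, dtype=float) for k, v in vals.items()}
    out["per_bond_stretch"] = es / (n - 1)
    out["per_angle"] = eb / (n - 2)
    out["per_bond_stretch_bend"] = out["per_bond_stretch"] + out["per_angle"]
    out["per_dihedral"] = et / (n - 3)
    out["per_bond_nonbonded"] = enb / (n - 1)
    out["per_bond_total"] = (es + eb + et + enb) / (n - 1)
    return out


def sweep_summary(trajectories: Mapping[float, Trajectory], *,
                  equilibration_fraction: float = 0.5,
                  contact_spec: ContactSpec = ContactSpec(),
                  min_stem: int = DEFAULT_MIN_STEM,
                  n_bootstrap: int = 200,
                  bootstrap_seed: int = 0
                  ) -> tuple[pd.DataFrame, dict[float, StemDistribution]]:
    """Per-temperature ensemble averages of every observable.

    ``trajectories`` maps reduced temperature to the trajectory sampled at
    that temperature.  The first ``equilibration_fraction`` of each
    trajectory's frames is discarded; means carry bootstrap standard errors
    (``n_bootstrap`` seeded resamples over production frames).

    Returns a DataFrame (one row per T*, columns ``<obs>_mean``/``<obs>_se``)
    and a dict of per-temperature stem distributions.
    """
    rng = np.random.default_rng(bootstrap_seed)
    rows = []
    stem_dists: dict[float, StemDistribution] = {}
    for tstar in sorted(trajectories):
        traj = trajectories[tstar]
        n_frames = traj.n_frames
        if n_frames == 0:
            continue
        start = int(np.floor(equilibration_fraction * n_frames))
        idx = np.arange(start, n_frames)
        if idx.size == 0:
            idx = np.array([n_frames - 1])
        obs = _frame_observables(traj, idx, contact_spec)
        row: dict[str, float] = {"tstar": tstar, "n_frames": idx.size}
        for name in _OBSERVABLES:
            series = obs[name]
            row[f"{name}_mean"] = float(series.mean())
            if idx.size > 1 and n_bootstrap > 0:
                boots = np.empty(n_bootstrap)
                for b in range(n_bootstrap):
                    pick = rng.integers(0, idx.size, idx.size)
                    boots[b] = series[pick].mean()
                row[f"{name}_se"] = float(boots.std(ddof=1))
            else:
                row[f"{name}_se"] = 0.0
        rows.append(row)
        stem_dists[tstar] = stem_distribution(
            (traj.positions[i] for i in idx), min_stem=min_stem)
    return pd.DataFrame(rows), stem_dists


def stem_distribution_frame(stem_dists: Mapping[float, StemDistribution]) -> pd.DataFrame:
    """Long-format table (tstar, n_tr, probability) of stem histograms."""
    records = [
        {"tstar": tstar, "n_tr": k, "probability": p}
        for tstar, dist in sorted(stem_dists.items())
        for k, p in sorted(dist.histogram.items())
    ]
    return pd.DataFrame(records, columns=["tstar", "n_tr", "probability"])
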