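"""Model self-check targets: analytic force-field properties recovered
numerically from the implemented energy routines.

Each function recomputes one quantity from scratch (numerical minimization,
root finding, or grid search over the package's own kernels), so these serve
as end-to-end checks that the implemented potentials carry the intended
constants.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from . import _kernels
from .analysis import orientational_order, stem_distribution
from .forcefield import ForceField, pair_potential
from .integrator import RunProtocol, run_quench
from .sequence import ResidueClass, build_sequence

__all__ = [
    "bond_length_minimum",
    "bond_angle_minimum",
    "torsion_barrier",
    "hh_well_depth",
    "hh_zero_crossing",
    "parallel_order_parameter",
    "stem_mode_full_scale",
]


def _kernel_energy(pos: np.ndarray, ff: ForceField) -> tuple[float, float, float]:
    """(stretch, bend, torsion) of a bare coordinate array via the kernel."""
    cls = np.zeros(len(pos), dtype=np.int64)
    _, es, eb, et, _, _ = _kernels.forces_and_energies(
        np.ascontiguousarray(pos, dtype=float), cls,
        ff.l0, ff.kd, ff.theta0, ff.ktheta, ff.kphi, ff.sigma, ff.rc,
        ff.epsilon_matrix, ff.lambda_matrix, ff.cutoff_shift_matrix())
    return es, eb, et


def bond_length_minimum(ff: ForceField) -> float:
    """Bond length (nm) minimizing the single-bond stretch energy."""

    def energy(length):
        pos = np.array([[0.0, 0.0, 0.0], [length, 0.0, 0.0]])
        return _kernel_energy(pos, ff)[0]

    res = minimize_scalar(energy, bounds=(0.05, 0.5), method="bounded",
                          options={"xatol": 1e-12})
    return float(res.x)


def bond_angle_minimum(ff: ForceField) -> float:
    """Bond angle (rad) minimizing the single-angle bend energy."""

    def energy(theta):
        pos = np.array([
            [-ff.l0, 0.0, 0.0],
            [0.0, 0.0, 0.0],
            [ff.l0 * np.cos(theta), ff.l0 * np.sin(theta), 0.0],
        ])
        return _kernel_energy(pos, ff)[1]

    res = minimize_scalar(energy, bounds=(1e-3, np.pi - 1e-3), method="bounded",
                          options={"xatol": 1e-12})
    return float(res.x)


def torsion_barrier(ff: ForceField, n_grid: int = 20001) -> float:
    """Maximum of the one-dihedral torsion energy over a dense angle grid."""
    half = ff.theta0 / 2.0
    step = np.array([np.cos(half), np.sin(half), 0.0]) * ff.l0
    base = np.zeros((4, 3))
    for i in range(1, 4):
        s = step.copy()
        s[1] *= (-1.0) ** (i - 1)
        base[i] = base[i - 1] + s
    axis = base[2] - base[1]
    axis /= np.linalg.norm(axis)
    v = base[3] - base[2]
    best = -np.inf
    for phi in np.linspace(-np.pi, np.pi, n_grid):
        c, s = np.cos(phi), np.sin(phi)
        rotated = v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1 - c)
        pos = base.copy()
        pos[3] = base[2] + rotated
        best = max(best, _kernel_energy(pos, ff)[2])
    return float(best)


def hh_well_depth(ff: ForceField) -> float:
    """|minimum| (kcal/mol) of the unshifted H-H pair potential."""
    h = ResidueClass.H
    res = minimize_scalar(
        lambda r: pair_potential(h, h, r, ff, shifted=False),
        bounds=(0.2, ff.rc), method="bounded", options={"xatol": 1e-12})
    return float(abs(res.fun))


def hh_zero_crossing(ff: ForceField) -> float:
    """Distance (nm) where the unshifted H-H pair potential crosses zero."""
    h = ResidueClass.H
    return float(brentq(
        lambda r: pair_potential(h, h, r, ff, shifted=False), 0.2, 0.5,
        xtol=1e-14))


def parallel_order_parameter(ff: ForceField, n_beads: int = 50) -> float:
    """Order parameter of a straight chain measured along its own axis."""
    pos = np.zeros((n_beads, 3))
    pos[:, 2] = ff.l0 * np.arange(n_beads)
    return float(orientational_order(pos, axis=np.array([0.0, 0.0, 1.0])))


def stem_mode_full_scale(ff: ForceField, seed: int, *, n_beads: int = 240,
                         unit: str = "H4N1P1") -> int:
    """Mode of the stem-length histogram after a full-scale low-T quench.

    Order 1e7 MD steps — hours on one CPU; used only by explicit opt-in
    (acceptance --full / HNPMD_FULL_SCALE).
    """
    seq = build_sequence(unit, n_beads)
    schedule = ((1.5, 200_000), (1.0, 500_000), (0.8, 800_000),
                (0.7, 1_000_000), (0.6, 1_500_000), (0.5, 2_000_000),
                (0.45, 2_000_000), (0.4, 4_000_000))
    proto = RunProtocol(schedule=schedule, seed=seed, snapshot_stride=10_000)
    traj = run_quench(seq, ff, proto).at_tstar(0.4)
    production = traj.positions[traj.n_frames // 2:]
    return stem_distribution(production).mode
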