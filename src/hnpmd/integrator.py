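"""Velocity-Verlet dynamics with a single Nose-Hoover thermostat.

The thermostat coupling mass is Q = n_free * kB * T * tau^2 with relaxation
constant tau (default 25 fs); n_free = 3N - 6 because net translation and
rotation are projected out at initialization.  Temperature is specified as
the reduced value T* = kB T / eps_h.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence as TypingSequence

import numpy as np

from . import _kernels
from .forcefield import KB_KCAL, KCAL_TO_KJ, ChainState, ForceField
from .sequence import Sequence

__all__ = [
    "ThermostatState",
    "RunProtocol",
    "Trajectory",
    "IntegrationError",
    "remove_rigid_motion",
    "step",
    "run_leg",
    "run_quench",
]


class IntegrationError(RuntimeError):
    """Raised when the integrator produces non-finite coordinates."""


@dataclass
class ThermostatState:
    """Nose-Hoover chain thermostat (length 2): target T*, frictions (1/ps),
    relaxation constant tau (fs).

    ``xi`` couples to the kinetic energy with mass Q1 = n_free kB T tau^2;
    the auxiliary ``xi2`` thermostats xi with mass Q2 = kB T tau^2, which
    restores ergodic sampling of the stiff bond modes.
    """

    target_tstar: float
    xi: float = 0.0
    xi2: float = 0.0
    tau_fs: float = 25.0

    def __post_init__(self) -> None:
        if self.tau_fs <= 0:
            raise ValueError("thermostat relaxation constant must be positive")

    def coupling_masses(self, n_free: int, eps_h: float) -> tuple[float, float]:
        """(Q1, Q2) in kJ/mol ps^2."""
        kbt_kj = self.target_tstar * eps_h * KCAL_TO_KJ
        tau_ps = self.tau_fs * 1e-3
        return n_free * kbt_kj * tau_ps * tau_ps, kbt_kj * tau_ps * tau_ps


@dataclass(frozen=True)
class RunProtocol:
    """Temperature schedule and bookkeeping for one quench run."""

    schedule: tuple[tuple[float, int], ...]
    seed: int = 0
    dt_fs: float = 2.5
    snapshot_stride: int = 1000
    tau_fs: float = 25.0
    mass: float = 110.0

    def __post_init__(self) -> None:
        if self.dt_fs <= 0:
            raise ValueError("time step must be positive")
        if not self.schedule:
            raise ValueError("schedule must contain at least one leg")
        for tstar, steps in self.schedule:
            if tstar <= 0:
                raise ValueError(f"reduced temperature must be positive, got {tstar}")
            if steps < 1:
                raise ValueError(f"leg step count must be >= 1, got {steps}")
        if self.snapshot_stride < 1:
            raise ValueError("snapshot stride must be >= 1")


@dataclass
class Trajectory:
    """Saved frames of one run: positions, velocities, times, leg T*, energies.

    ``energies`` columns are (stretch, bend, torsion, nonbonded, kinetic) in
    kcal/mol, evaluated at the saved frame.
    """

    sequence: Sequence
    positions: np.ndarray          # (n_frames, N, 3) nm
    velocities: np.ndarray         # (n_frames, N, 3) nm/ps
    times: np.ndarray              # (n_frames,) ps
    tstars: np.ndarray             # (n_frames,) thermostat target at save time
    energies: np.ndarray           # (n_frames, 5) kcal/mol
    masses: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def frame(self, i: int) -> ChainState:
        return ChainState(self.positions[i].copy(), self.velocities[i].copy(),
                          self.masses.copy(), self.sequence, float(self.times[i]))

    def frames(self) -> Iterable[ChainState]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def at_tstar(self, tstar: float, atol: float = 1e-9) -> "Trajectory":
        """Sub-trajectory of frames whose thermostat target equals ``tstar``."""
        mask = np.abs(self.tstars - tstar) <= atol
        return Trajectory(self.sequence, self.positions[mask],
                          self.velocities[mask], self.times[mask],
                          self.tstars[mask], self.energies[mask],
                          self.masses, dict(self.metadata))

    @staticmethod
    def concatenate(parts: TypingSequence["Trajectory"]) -> "Trajectory":
        first = parts[0]
        return Trajectory(
            first.sequence,
            np.concatenate([p.positions for p in parts]),
            np.concatenate([p.velocities for p in parts]),
            np.concatenate([p.times for p in parts]),
            np.concatenate([p.tstars for p in parts]),
            np.concatenate([p.energies for p in parts]),
            first.masses,
            dict(first.metadata),
        )


def remove_rigid_motion(state: ChainState) -> ChainState:
    """Project out net linear and angular momentum about the center of mass.

    Relative internal velocities are minimally perturbed (a projection, not a
    rescale); applying the operation twice equals applying it once.
    """
    pos = state.positions
    vel = state.velocities.copy()
    m = state.masses
    mtot = m.sum()
    # remove center-of-mass velocity
    vcom = (m[:, None] * vel).sum(axis=0) / mtot
    vel -= vcom
    # remove rigid rotation: omega = I^+ L
    com = (m[:, None] * pos).sum(axis=0) / mtot
    x = pos - com
    ang_mom = (m[:, None] * np.cross(x, vel)).sum(axis=0)
    r2 = np.einsum("ij,ij->i", x, x)
    inertia = np.einsum("i,ij,ik->jk", m, x, x)
    inertia = np.diag([np.sum(m * r2)] * 3) - inertia
    omega = np.linalg.pinv(inertia, rcond=1e-12) @ ang_mom
    vel -= np.cross(omega, x)
    return ChainState(pos.copy(), vel, m.copy(), state.sequence, state.time)


def _kernel_args(ff: ForceField):
    return (ff.l0, ff.kd, ff.theta0, ff.ktheta, ff.kphi, ff.sigma, ff.rc,
            ff.epsilon_matrix, ff.lambda_matrix, ff.cutoff_shift_matrix())


def run_leg(state: ChainState, ff: ForceField, n_steps: int, *,
            thermostat: ThermostatState | None = None, dt_fs: float = 2.5,
            snapshot_stride: int = 1000) -> tuple[ChainState, Trajectory]:
    """Advance ``n_steps`` and return the final state plus saved frames."""
    pos = state.positions.copy()
    vel = state.velocities.copy()
    masses = state.masses.copy()
    cls = state.sequence.class_indices
    dt_ps = dt_fs * 1e-3
    n_free = 3 * state.n_beads - 6

    if thermostat is not None:
        kbt = thermostat.target_tstar * ff.eps_h * KCAL_TO_KJ
        kbt_nf = n_free * kbt
        q1, q2 = thermostat.coupling_masses(n_free, ff.eps_h)
        xi, xi2 = thermostat.xi, thermostat.xi2
        use_nh = True
        tstar = thermostat.target_tstar
    else:
        kbt, kbt_nf, q1, q2 = 1.0, 1.0, 1.0, 1.0
        xi, xi2, use_nh, tstar = 0.0, 0.0, False, np.nan

    n_snap_max = n_steps // snapshot_stride
    snap_pos = np.empty((n_snap_max, state.n_beads, 3))
    snap_vel = np.empty_like(snap_pos)
    snap_en = np.empty((n_snap_max, 5))

    xi, xi2, n_snap, bad_step = _kernels.md_run(
        pos, vel, masses, cls, *_kernel_args(ff),
        dt_ps, n_steps, use_nh, kbt_nf, kbt, q1, q2, xi, xi2,
        snapshot_stride, snap_pos, snap_vel, snap_en)
    if bad_step >= 0:
        raise IntegrationError(
            f"non-finite forces or bead overlap at step {bad_step} "
            f"(t = {state.time + bad_step * dt_ps:.3f} ps)"
        )
    if thermostat is not None:
        thermostat.xi = xi
        thermostat.xi2 = xi2

    times = state.time + dt_ps * snapshot_stride * np.arange(1, n_snap + 1)
    traj = Trajectory(state.sequence, snap_pos[:n_snap], snap_vel[:n_snap],
                      times, np.full(n_snap, tstar), snap_en[:n_snap], masses)
    new_state = ChainState(pos, vel, masses, state.sequence,
                           state.time + n_steps * dt_ps)
    return new_state, traj


def step(state: ChainState, ff: ForceField,
         thermostat: ThermostatState | None = None,
         dt_fs: float = 2.5) -> ChainState:
    """One velocity-Verlet step (NVE when ``thermostat`` is None)."""
    new_state, _ = run_leg(state, ff, 1, thermostat=thermostat, dt_fs=dt_fs,
                           snapshot_stride=2)
    return new_state


def run_quench(seq: Sequence, ff: ForceField, protocol: RunProtocol) -> Trajectory:
    """Random high-temperature start, then one thermostatted leg per schedule
    entry with the target retuned at each transition.

    The chain is initialized with :func:`~hnpmd.sequence.initial_configuration`
    at the first leg's temperature; net momenta are removed once at start.
    Identical protocols (same seed) give bit-identical trajectories.
    """
    from .sequence import initial_configuration

    first_tstar = protocol.schedule[0][0]
    state = initial_configuration(seq, protocol.seed, forcefield=ff,
                                  tstar=first_tstar, mass=protocol.mass)
    thermo = ThermostatState(first_tstar, tau_fs=protocol.tau_fs)
    parts: list[Trajectory] = []
    for leg_idx, (tstar, n_steps) in enumerate(protocol.schedule):
        thermo.target_tstar = tstar
        try:
            state, traj = run_leg(state, ff, n_steps, thermostat=thermo,
                                  dt_fs=protocol.dt_fs,
                                  snapshot_stride=protocol.snapshot_stride)
        except IntegrationError as exc:
            raise IntegrationError(
                f"leg {leg_idx} (T* = {tstar}): {exc}") from exc
        parts.append(traj)
    out = Trajectory.concatenate(parts)
    out.metadata = {
        "unit": seq.provenance,
        "n_beads": len(seq),
        "seed": protocol.seed,
        "dt_fs": protocol.dt_fs,
        "tau_fs": protocol.tau_fs,
        "snapshot_stride": protocol.snapshot_stride,
        "schedule": [[float(t), int(s)] for t, s in protocol.schedule],
        "mass": protocol.mass,
    }
    return out
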