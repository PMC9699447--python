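"""Potential-energy terms, interaction matrices and analytic forces.

Four terms act on a chain of beads: harmonic bond stretching, harmonic
bending of the angle between consecutive bond vectors, a threefold torsion
with minima at the trans and both gauche states, and a truncated-and-shifted
12-6 Lennard-Jones potential between beads at least four residues apart.
The LJ strength ``eps`` and attraction switch ``lam`` depend on the residue
classes of the pair: only H-H pairs attract (lam=+1), P-P pairs carry an
inverted (purely repulsive, lam=-1) tail, all remaining pairs are soft
repulsive (lam=0).

Energies are reported in kcal/mol, lengths in nm, angles in rad.  Dihedral
angles are measured from the trans state (phi = 0 <=> trans), so the torsion
term reads (kphi/2)(1 - cos 3 phi) with barrier kphi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .sequence import ResidueClass, Sequence

__all__ = [
    "KB_KCAL",
    "KCAL_TO_KJ",
    "ForceField",
    "ChainState",
    "EnergyBreakdown",
    "SingularConfigurationError",
    "bond_vectors",
    "bond_lengths",
    "bend_angles",
    "dihedral_angles",
    "pair_potential",
    "stretch_energy",
    "bend_energy",
    "torsion_energy",
    "nonbonded_energy",
    "nonbonded_pairs",
    "energy_breakdown",
    "total_energy_and_forces",
]

#: Boltzmann constant, kcal/(mol K).
KB_KCAL = 1.9872e-3
#: kcal -> kJ conversion used when coupling energies to g/mol, nm, ps dynamics.
KCAL_TO_KJ = 4.184

#: Minimum interbead distance (nm) below which configurations are singular.
_OVERLAP_DISTANCE = 1e-4


class SingularConfigurationError(RuntimeError):
    """Raised when beads overlap closely enough for forces to blow up."""


def _default_epsilon_matrix(eps_h: float) -> np.ndarray:
    # index order H=0, N=1, P=2
    return eps_h * np.array([
        [1.0, 2.0 / 3.0, 7.0 / 12.0],
        [2.0 / 3.0, 1.0 / 3.0, 1.0 / 4.0],
        [7.0 / 12.0, 1.0 / 4.0, 1.0 / 6.0],
    ])


def _default_lambda_matrix() -> np.ndarray:
    lam = np.zeros((3, 3))
    lam[0, 0] = 1.0    # H-H attracts
    lam[2, 2] = -1.0   # P-P inverted tail, purely repulsive
    return lam


@dataclass(frozen=True)
class ForceField:
    """All potential constants plus the pairwise eps/lam interaction matrices.

    Defaults: l0 = 0.153 nm, kd = 7e4 kcal/(nm^2 mol), theta0 = 1.231 rad,
    ktheta = 100 kcal/(rad^2 mol), kphi = 2.0 kcal/mol, sigma = 0.3624 nm,
    eps_h = 0.1984 kcal/mol, rc = 0.95 nm.
    """

    l0: float = 0.153
    kd: float = 7.0e4
    theta0: float = 1.231
    ktheta: float = 100.0
    kphi: float = 2.0
    sigma: float = 0.3624
    eps_h: float = 0.1984
    rc: float = 0.95
    epsilon_matrix: np.ndarray = None  # type: ignore[assignment]
    lambda_matrix: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.epsilon_matrix is None:
            object.__setattr__(self, "epsilon_matrix", _default_epsilon_matrix(self.eps_h))
        if self.lambda_matrix is None:
            object.__setattr__(self, "lambda_matrix", _default_lambda_matrix())
        eps = np.asarray(self.epsilon_matrix, dtype=float)
        lam = np.asarray(self.lambda_matrix, dtype=float)
        if eps.shape != (3, 3) or lam.shape != (3, 3):
            raise ValueError("interaction matrices must be 3x3 (H, N, P)")
        if not np.allclose(eps, eps.T) or not np.allclose(lam, lam.T):
            raise ValueError("interaction matrices must be symmetric")
        if np.any(eps <= 0):
            raise ValueError("epsilon values must be positive")
        object.__setattr__(self, "epsilon_matrix", eps)
        object.__setattr__(self, "lambda_matrix", lam)

    def epsilon(self, a: ResidueClass, b: ResidueClass) -> float:
        return float(self.epsilon_matrix[a.index, b.index])

    def lam(self, a: ResidueClass, b: ResidueClass) -> float:
        return float(self.lambda_matrix[a.index, b.index])

    def cutoff_shift(self, a: ResidueClass, b: ResidueClass) -> float:
        """Unshifted pair-potential value at the cutoff for this pair."""
        return float(self.cutoff_shift_matrix()[a.index, b.index])

    def cutoff_shift_matrix(self) -> np.ndarray:
        sr6 = (self.sigma / self.rc) ** 6
        return 4.0 * self.epsilon_matrix * (sr6 * sr6 - self.lambda_matrix * sr6)

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "l0": self.l0, "kd": self.kd,
            "theta0": self.theta0, "ktheta": self.ktheta,
            "kphi": self.kphi,
            "sigma": self.sigma, "eps_h": self.eps_h, "rc": self.rc,
            "epsilon_matrix": [[float(x) for x in row] for row in self.epsilon_matrix],
            "lambda_matrix": [[float(x) for x in row] for row in self.lambda_matrix],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ForceField":
        data = dict(data)
        for key in ("epsilon_matrix", "lambda_matrix"):
            if key in data and data[key] is not None:
                data[key] = np.asarray(data[key], dtype=float)
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"forcefield": self.to_dict()}, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ForceField":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if isinstance(data, dict) and "forcefield" in data:
            data = data["forcefield"]
        return cls.from_dict(data)


@dataclass
class ChainState:
    """Positions/velocities/masses of all beads at one instant.

    positions : (N, 3) nm; velocities : (N, 3) nm/ps; masses : (N,) g/mol.
    """

    positions: np.ndarray
    velocities: np.ndarray
    masses: np.ndarray
    sequence: Sequence
    time: float = 0.0  # ps

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=float)
        self.masses = np.ascontiguousarray(self.masses, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.sequence)
        if self.positions.shape != (n, 3):
            raise ValueError(f"positions must be ({n}, 3), got {self.positions.shape}")
        if self.velocities.shape != (n, 3):
            raise ValueError(f"velocities must be ({n}, 3), got {self.velocities.shape}")
        if self.masses.shape != (n,):
            raise ValueError(f"masses must be ({n},), got {self.masses.shape}")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if not np.all(np.isfinite(self.velocities)):
            raise ValueError("velocities must be finite")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")

    @property
    def n_beads(self) -> int:
        return len(self.sequence)

    def copy(self) -> "ChainState":
        return ChainState(self.positions.copy(), self.velocities.copy(),
                          self.masses.copy(), self.sequence, self.time)

    def kinetic_energy(self) -> float:
        """Kinetic energy in kcal/mol."""
        ke_kj = 0.5 * float(np.sum(self.masses[:, None] * self.velocities ** 2))
        return ke_kj / KCAL_TO_KJ

    def kinetic_tstar(self, eps_h: float = 0.1984, n_free: int | None = None) -> float:
        """Instantaneous kinetic reduced temperature 2*KE / (n_free * kB T / ...)."""
        if n_free is None:
            n_free = 3 * self.n_beads - 6
        kbt = 2.0 * self.kinetic_energy() / n_free  # kcal/mol
        return kbt / eps_h


@dataclass(frozen=True)
class EnergyBreakdown:
    """Per-term potential energies (kcal/mol) with per-bond normalizations."""

    stretch: float
    bend: float
    torsion: float
    nonbonded: float
    n_beads: int

    @property
    def total(self) -> float:
        return self.stretch + self.bend + self.torsion + self.nonbonded

    @property
    def per_bond_stretch_bend(self) -> float:
        """(stretch + bend) normalized: stretch by N-1 bonds, bend by N-2 angles."""
        return self.per_bond_stretch + self.per_angle

    @property
    def per_bond_stretch(self) -> float:
        return self.stretch / (self.n_beads - 1)

    @property
    def per_angle(self) -> float:
        return self.bend / (self.n_beads - 2)

    @property
    def per_dihedral(self) -> float:
        return self.torsion / (self.n_beads - 3)

    @property
    def per_bond_nonbonded(self) -> float:
        return self.nonbonded / (self.n_beads - 1)

    @property
    def per_bond_total(self) -> float:
        return self.total / (self.n_beads - 1)

    def as_dict(self) -> dict:
        return {
            "stretch": self.stretch, "bend": self.bend,
            "torsion": self.torsion, "nonbonded": self.nonbonded,
            "total": self.total,
            "per_bond_stretch": self.per_bond_stretch,
            "per_angle": self.per_angle,
            "per_dihedral": self.per_dihedral,
            "per_bond_nonbonded": self.per_bond_nonbonded,
            "per_bond_total": self.per_bond_total,
        }


# --- internal coordinates ----------------------------------------------------

def bond_vectors(positions: np.ndarray) -> np.ndarray:
    return np.diff(np.asarray(positions, dtype=float), axis=0)


def bond_lengths(positions: np.ndarray) -> np.ndarray:
    return np.linalg.norm(bond_vectors(positions), axis=1)


def bend_angles(positions: np.ndarray) -> np.ndarray:
    """Angle (rad) between consecutive bond vectors, one per interior bead.

    Zero corresponds to collinear bonds; the equilibrium value 1.231 rad is
    the deflection of a tetrahedral backbone.
    """
    b = bond_vectors(positions)
    u, v = b[:-1], b[1:]
    cosang = np.einsum("ij,ij->i", u, v) / (
        np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def dihedral_angles(positions: np.ndarray) -> np.ndarray:
    """Dihedral angles (rad) in (-pi, pi], measured from the trans state.

    phi = 0 for a planar extended (trans) quadruplet; |phi| = pi at the cis
    barrier.  Degenerate (collinear) quadruplets are assigned phi = 0.
    """
    b = bond_vectors(positions)
    b1, b2, b3 = b[:-2], b[1:-1], b[2:]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=1)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b2) / np.where(b2n > 0, b2n, 1.0)
    degenerate = (np.einsum("ij,ij->i", n1, n1) < 1e-18) | (
        np.einsum("ij,ij->i", n2, n2) < 1e-18)
    phi_std = np.arctan2(y, x)
    # shift so trans (phi_std = +/-pi) maps to 0
    phi = np.mod(phi_std + 2.0 * np.pi, 2.0 * np.pi) - np.pi
    phi[degenerate] = 0.0
    return phi


# --- energy terms ------------------------------------------------------------

def stretch_energy(state: ChainState, ff: ForceField) -> float:
    """Sum over N-1 bonds of (kd/2)(l - l0)^2, kcal/mol."""
    dl = bond_lengths(state.positions) - ff.l0
    return float(0.5 * ff.kd * np.sum(dl * dl))


def bend_energy(state: ChainState, ff: ForceField) -> float:
    """Sum over N-2 angles of (ktheta/2)(theta - theta0)^2, kcal/mol."""
    dth = bend_angles(state.positions) - ff.theta0
    return float(0.5 * ff.ktheta * np.sum(dth * dth))


def torsion_energy(state: ChainState, ff: ForceField) -> float:
    """Sum over N-3 dihedrals of (kphi/2)(1 - cos 3 phi), kcal/mol."""
    phi = dihedral_angles(state.positions)
    return float(0.5 * ff.kphi * np.sum(1.0 - np.cos(3.0 * phi)))


def pair_potential(a: ResidueClass, b: ResidueClass, r, ff: ForceField,
                   *, shifted: bool = True):
    """Nonbonded pair energy 4 eps [(sigma/r)^12 - lam (sigma/r)^6], kcal/mol.

    With ``shifted=True`` (the simulation form) the value at the cutoff is
    subtracted for r <= rc and the energy is exactly 0 beyond the cutoff;
    ``shifted=False`` returns the bare truncated potential.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    eps = ff.epsilon(a, b)
    lam = ff.lam(a, b)
    sr6 = (ff.sigma / r) ** 6
    u = 4.0 * eps * (sr6 * sr6 - lam * sr6)
    if shifted:
        u = np.where(r <= ff.rc, u - ff.cutoff_shift(a, b), 0.0)
    else:
        u = np.where(r <= ff.rc, u, 0.0)
    return float(u) if u.ndim == 0 else u


def nonbonded_pairs(n_beads: int, min_separation: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays (i, j), i < j, of all pairs with j - i >= min_separation."""
    i, j = np.triu_indices(n_beads, k=min_separation)
    return i, j


def nonbonded_energy(state: ChainState, ff: ForceField, *, shifted: bool = True) -> float:
    """Sum of the shifted pair potential over all pairs with |j - i| >= 4."""
    idx_i, idx_j = nonbonded_pairs(state.n_beads)
    if idx_i.size == 0:
        return 0.0
    d = state.positions[idx_i] - state.positions[idx_j]
    r = np.linalg.norm(d, axis=1)
    cls = state.sequence.class_indices
    ai, aj = cls[idx_i], cls[idx_j]
    eps = ff.epsilon_matrix[ai, aj]
    lam = ff.lambda_matrix[ai, aj]
    sr6 = (ff.sigma / r) ** 6
    u = 4.0 * eps * (sr6 * sr6 - lam * sr6)
    if shifted:
        u = u - ff.cutoff_shift_matrix()[ai, aj]
    return float(np.sum(u[r <= ff.rc]))


def energy_breakdown(state: ChainState, ff: ForceField) -> EnergyBreakdown:
    """Evaluate all four terms with the plain (numpy) routines."""
    return EnergyBreakdown(
        stretch=stretch_energy(state, ff),
        bend=bend_energy(state, ff),
        torsion=torsion_energy(state, ff),
        nonbonded=nonbonded_energy(state, ff),
        n_beads=state.n_beads,
    )


def total_energy_and_forces(state: ChainState, ff: ForceField
                            ) -> tuple[EnergyBreakdown, np.ndarray]:
    """Energies plus analytic forces (kcal/(mol nm)) from the compiled kernel.

    Raises :class:`SingularConfigurationError` when any nonbonded pair sits
    closer than 0.1 pm.
    """
    from ._kernels import forces_and_energies

    cls = state.sequence.class_indices
    f, es, eb, et, enb, min_r2 = forces_and_energies(
        state.positions, cls,
        ff.l0, ff.kd, ff.theta0, ff.ktheta, ff.kphi,
        ff.sigma, ff.rc,
        ff.epsilon_matrix, ff.lambda_matrix, ff.cutoff_shift_matrix(),
    )
    if min_r2 < _OVERLAP_DISTANCE ** 2:
        raise SingularConfigurationError(
            f"bead overlap: nonbonded pair at distance {np.sqrt(min_r2):.2e} nm"
        )
    breakdown = EnergyBreakdown(stretch=es, bend=eb, torsion=et,
                                nonbonded=enb, n_beads=state.n_beads)
    return breakdown, f
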