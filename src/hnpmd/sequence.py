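"""Chain inputs: residue classes, repeat units, sequences and seeded initial coils.

A chain is specified by a repeat unit such as ``H3N1P1`` (three hydrophobic,
one neutral, one hydrophilic bead) tiled to the requested bead count.  Real
amino-acid sequences can be mapped onto the three-letter H/N/P alphabet with
:func:`classify_amino_acid`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence as TypingSequence

import numpy as np

__all__ = [
    "ResidueClass",
    "RepeatUnit",
    "Sequence",
    "SequenceError",
    "ConfigurationError",
    "parse_repeat_spec",
    "build_sequence",
    "classify_amino_acid",
    "initial_configuration",
    "write_fasta",
    "read_fasta",
    "PAPER_UNITS",
]

#: Repeat units studied in the reference experiments.
PAPER_UNITS = ("H3N1P1", "H4N1P1", "H4N2P2", "H6N2P2", "H8N2P2", "H8N4P4")


class SequenceError(ValueError):
    """Raised for malformed repeat specs, sequences or residue codes."""


class ConfigurationError(RuntimeError):
    """Raised when an initial chain configuration cannot be generated."""


class ResidueClass(Enum):
    """Coarse-grained residue class: hydrophobic, neutral or hydrophilic."""

    H = "H"
    N = "N"
    P = "P"

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.value

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return self.value

    @property
    def index(self) -> int:
        """Stable integer index used by the force-field matrices (H=0, N=1, P=2)."""
        return _CLASS_ORDER.index(self)


_CLASS_ORDER = (ResidueClass.H, ResidueClass.N, ResidueClass.P)

# Residue grouping for the 20 standard amino acids.
_H_RESIDUES = {"PHE", "MET", "ILE", "LEU", "TRP", "VAL", "CYS", "TYR"}
_N_RESIDUES = {"HIS", "ALA", "GLY", "THR"}
_P_RESIDUES = {"LYS", "ASP", "ASN", "GLU", "GLN", "SER", "PRO", "ARG"}

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass(frozen=True)
class RepeatUnit:
    """Ordered blocks of (residue class, count) forming a periodic motif."""

    blocks: tuple[tuple[ResidueClass, int], ...]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise SequenceError("repeat unit must contain at least one block")
        for cls, count in self.blocks:
            if not isinstance(cls, ResidueClass):
                raise SequenceError(f"invalid residue class {cls!r}")
            if count < 1:
                raise SequenceError(f"block count must be >= 1, got {count}")

    @property
    def name(self) -> str:
        """Canonical spelling, e.g. ``H3N1P1``."""
        return "".join(f"{cls.value}{count}" for cls, count in self.blocks)

    def __len__(self) -> int:
        return sum(count for _, count in self.blocks)

    @property
    def classes(self) -> tuple[ResidueClass, ...]:
        """The unit expanded bead by bead."""
        out: list[ResidueClass] = []
        for cls, count in self.blocks:
            out.extend([cls] * count)
        return tuple(out)

    def composition(self) -> dict[ResidueClass, int]:
        comp = {cls: 0 for cls in _CLASS_ORDER}
        for cls, count in self.blocks:
            comp[cls] += count
        return comp


@dataclass(frozen=True)
class Sequence:
    """Ordered residue classes for one chain of N beads."""

    classes: tuple[ResidueClass, ...]
    provenance: str = "explicit"

    def __post_init__(self) -> None:
        if len(self.classes) < 5:
            raise SequenceError(
                f"chain needs at least 5 beads (got {len(self.classes)}): "
                "the first dihedral requires 4 beads and the first nonbonded pair 5"
            )

    def __len__(self) -> int:
        return len(self.classes)

    @property
    def n_beads(self) -> int:
        return len(self.classes)

    @property
    def labels(self) -> str:
        return "".join(cls.value for cls in self.classes)

    @property
    def class_indices(self) -> np.ndarray:
        """Integer class per bead (H=0, N=1, P=2), for numeric kernels."""
        return np.fromiter((c.index for c in self.classes), dtype=np.int64,
                           count=len(self.classes))

    def composition(self) -> dict[ResidueClass, int]:
        comp = {cls: 0 for cls in _CLASS_ORDER}
        for cls in self.classes:
            comp[cls] += 1
        return comp

    @classmethod
    def from_labels(cls, labels: Iterable[str], provenance: str = "explicit") -> "Sequence":
        classes = []
        for i, ch in enumerate(labels):
            try:
                classes.append(ResidueClass(ch.upper()))
            except ValueError:
                raise SequenceError(f"unknown residue class {ch!r} at position {i}") from None
        return cls(tuple(classes), provenance=provenance)


_SPEC_TOKEN = re.compile(r"([A-Za-z])(\d+)")


def parse_repeat_spec(spec: str) -> RepeatUnit:
    """Parse a repeat-unit spec such as ``"H3N1P1"`` into a :class:`RepeatUnit`.

    The spec is a concatenation of (class letter, positive count) pairs over
    the alphabet {H, N, P}.

    >>> parse_repeat_spec("H3N1P1").classes
    (H, H, H, N, P)
    """
    spec = spec.strip()
    if not spec:
        raise SequenceError("empty repeat spec")
    pos = 0
    blocks: list[tuple[ResidueClass, int]] = []
    for match in _SPEC_TOKEN.finditer(spec):
        if match.start() != pos:
            raise SequenceError(
                f"malformed repeat spec {spec!r}: unparsable token at {spec[pos:match.start()]!r}"
            )
        letter, digits = match.group(1), match.group(2)
        try:
            cls = ResidueClass(letter.upper())
        except ValueError:
            raise SequenceError(
                f"malformed repeat spec {spec!r}: unknown class letter {letter!r}"
            ) from None
        count = int(digits)
        if count < 1:
            raise SequenceError(
                f"malformed repeat spec {spec!r}: count for {letter!r} must be positive"
            )
        blocks.append((cls, count))
        pos = match.end()
    if pos != len(spec):
        raise SequenceError(
            f"malformed repeat spec {spec!r}: trailing token {spec[pos:]!r}"
        )
    return RepeatUnit(tuple(blocks))


def build_sequence(unit: RepeatUnit | str, n_beads: int) -> Sequence:
    """Tile ``unit`` in block order and truncate at ``n_beads`` beads."""
    if isinstance(unit, str):
        unit = parse_repeat_spec(unit)
    if n_beads < 5:
        raise SequenceError(f"chain length must be >= 5 beads, got {n_beads}")
    motif = unit.classes
    reps = -(-n_beads // len(motif))
    classes = (motif * reps)[:n_beads]
    return Sequence(tuple(classes), provenance=unit.name)


def classify_amino_acid(code: str) -> ResidueClass:
    """Map a one- or three-letter amino-acid code to its H/N/P class.

    Hydrophobic (H): Phe, Met, Ile, Leu, Trp, Val, Cys, Tyr.
    Neutral (N): His, Ala, Gly, Thr.
    Hydrophilic (P): Lys, Asp, Asn, Glu, Gln, Ser, Pro, Arg.
    """
    raw = code.strip()
    if len(raw) == 1:
        three = _ONE_TO_THREE.get(raw.upper())
        if three is None:
            raise SequenceError(f"unknown one-letter amino-acid code {code!r}")
    elif len(raw) == 3:
        three = raw.upper()
    else:
        raise SequenceError(f"amino-acid code must be 1 or 3 letters, got {code!r}")
    if three in _H_RESIDUES:
        return ResidueClass.H
    if three in _N_RESIDUES:
        return ResidueClass.N
    if three in _P_RESIDUES:
        return ResidueClass.P
    raise SequenceError(f"unknown amino-acid code {code!r}")


def sequence_from_amino_acids(residues: TypingSequence[str] | str,
                              provenance: str = "amino-acid") -> Sequence:
    """Build an H/N/P sequence from amino-acid codes (string of one-letter
    codes or an iterable of one-/three-letter codes)."""
    return Sequence(tuple(classify_amino_acid(r) for r in residues), provenance=provenance)


# --- initial configuration ---------------------------------------------------

def initial_configuration(seq: Sequence, seed: int, *, forcefield=None,
                          tstar: float = 1.5, mass: float = 110.0,
                          max_retries: int = 200):
    """Build a seeded self-avoiding random-coil :class:`~hnpmd.forcefield.ChainState`.

    Beads are placed one bond at a time with every bond length exactly ``l0``;
    a candidate direction is rejected whenever any pair at sequence separation
    >= 4 would come closer than ``0.8 * sigma``.  Velocities are drawn from the
    Maxwell-Boltzmann distribution at reduced temperature ``tstar`` and the
    net linear and angular momenta are projected out.

    Parameters
    ----------
    seq : Sequence
        Residue classes of the chain.
    seed : int
        Seed for the random walk and the velocity draw; identical seeds give
        bit-identical states.
    forcefield : ForceField, optional
        Source of ``l0`` and ``sigma`` (defaults used when omitted).
    tstar : float
        Reduced temperature for the velocity draw.
    mass : float
        Uniform bead mass in g/mol (110 = mean amino-acid residue mass).
    """
    from .forcefield import ChainState, ForceField

    ff = forcefield if forcefield is not None else ForceField()
    n = len(seq)
    rng = np.random.default_rng(seed)
    l0 = ff.l0
    min_sep2 = (0.8 * ff.sigma) ** 2

    pos = np.zeros((n, 3))
    i = 1
    retries = 0
    while i < n:
        # uniform random direction on the unit sphere
        vec = rng.normal(size=3)
        vec /= np.linalg.norm(vec)
        cand = pos[i - 1] + l0 * vec
        prior = pos[: max(i - 3, 0)]  # pairs at |i-j| >= 4
        if prior.size and np.min(np.sum((prior - cand) ** 2, axis=1)) <= min_sep2:
            retries += 1
            if retries > max_retries:
                # back out a few beads and retry from there
                i = max(1, i - 5)
                retries = 0
                if rng.random() < 0.01:
                    raise ConfigurationError(
                        f"failed to place bead {i} after repeated backtracking; "
                        "try a different seed"
                    )
            continue
        pos[i] = cand
        retries = 0
        i += 1

    masses = np.full(n, float(mass))
    kbt_kcal = tstar * ff.eps_h  # k_B T in kcal/mol
    # velocity variance: kB T / m, in nm^2/ps^2 with energies in kJ/mol
    sigma_v = np.sqrt(kbt_kcal * 4.184 / masses)
    vel = rng.normal(size=(n, 3)) * sigma_v[:, None]

    state = ChainState(positions=pos, velocities=vel, masses=masses, sequence=seq)
    from .integrator import remove_rigid_motion

    return remove_rigid_motion(state)


# --- FASTA I/O ---------------------------------------------------------------

def write_fasta(seq: Sequence, path, header: str | None = None) -> None:
    """Write a single-record FASTA over the {H,N,P} alphabet."""
    name = header if header is not None else f"hnp|{seq.provenance}|N={len(seq)}"
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        labels = seq.labels
        for k in range(0, len(labels), 60):
            fh.write(labels[k:k + 60] + "\n")


def read_fasta(path, *, amino_acid: bool = False) -> Sequence:
    """Read a single-record FASTA; residues are H/N/P labels, or one-letter
    amino-acid codes when ``amino_acid=True``."""
    header = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    raise SequenceError(f"{path}: expected a single FASTA record")
                header = line[1:]
                continue
            chunks.append(line)
    if header is None or not chunks:
        raise SequenceError(f"{path}: no FASTA record found")
    letters = "".join(chunks)
    if amino_acid:
        return sequence_from_amino_acids(letters)
    return Sequence.from_labels(letters, provenance="explicit")
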