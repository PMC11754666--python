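"""Shared domain types: atoms, nucleotides, base pairs, duplexes, helix frames.

Coordinates are in Angstroms throughout; angles crossing an API boundary are in
degrees. Base-pair positions use PAM-relative indexing that skips zero:
``..., -2, -1`` are PAM pairs (``-1`` is the last PAM pair) and ``+1, +2, ...``
are protospacer pairs, so the PAM/protospacer boundary sits between ``-1`` and
``+1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "BasePair",
    "BendscanError",
    "DegenerateGeometryError",
    "Duplex",
    "HelixFrame",
    "IncompleteResidueError",
    "Nucleotide",
    "PairingError",
    "ParseError",
    "SegmentationError",
    "UsageError",
    "ValidationError",
    "WATSON_CRICK",
    "frame_atom_names",
    "from_ordinal",
    "ordinal",
    "pam_range",
    "step_count",
    "wrap_angle",
]


class BendscanError(Exception):
    """Base class for all package errors."""


class UsageError(BendscanError, ValueError):
    """Invalid argument or precondition violation by the caller."""


class ParseError(BendscanError):
    """A structure file could not be read."""


class ValidationError(BendscanError):
    """Geometric or chemical validation of a duplex failed."""


class PairingError(BendscanError, LookupError):
    """A referenced residue or reference condition is missing."""


class SegmentationError(BendscanError):
    """A junction definition references pam_index values absent from the duplex."""


class DegenerateGeometryError(BendscanError):
    """Point sets too small or collinear for a unique rigid superposition."""


class IncompleteResidueError(BendscanError):
    """A nucleotide lacks the base-ring/C1' atoms needed for frame fitting."""


# Watson-Crick partners; U is accepted as a T analogue.
WATSON_CRICK = {"A": "T", "T": "A", "G": "C", "C": "G", "U": "A"}

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CTU")

# Base-ring heavy atoms used for frame fitting (plus C1' of each strand).
PURINE_RING = ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4")
PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")


def frame_atom_names(base: str) -> tuple[str, ...]:
    """Atom names entering helix-frame superposition for a given base code."""
    if base in PURINES:
        return PURINE_RING + ("C1'",)
    if base in PYRIMIDINES:
        return PYRIMIDINE_RING + ("C1'",)
    raise UsageError(f"no frame-fitting atom set for base {base!r}")


def ordinal(pam_index: int) -> int:
    """Map a PAM-relative index (no zero) onto consecutive integers.

    ``..., -2 -> -2, -1 -> -1, +1 -> 0, +2 -> 1, ...`` so that differences of
    ordinals count base-pair steps across the PAM/protospacer boundary.
    """
    if pam_index == 0:
        raise UsageError("pam_index 0 does not exist (indexing skips zero)")
    return pam_index if pam_index < 0 else pam_index - 1


def from_ordinal(o: int) -> int:
    """Inverse of :func:`ordinal`: map a consecutive integer back to pam_index."""
    return o if o < 0 else o + 1


def step_count(a: int, b: int) -> int:
    """Number of base-pair steps from pam_index ``a`` to ``b`` (signed)."""
    return ordinal(b) - ordinal(a)


def pam_range(start: int, stop: int) -> tuple[int, ...]:
    """Inclusive run of pam_index values from start to stop, skipping 0."""
    if start == 0 or stop == 0:
        raise UsageError("pam_index 0 does not exist")
    if ordinal(start) > ordinal(stop):
        raise UsageError(f"empty pam_index range {start}..{stop}")
    return tuple(i for i in range(start, stop + 1) if i != 0)


def wrap_angle(deg: float) -> float:
    """Wrap an angle in degrees to the interval (-180, 180]."""
    w = deg % 360.0
    if w > 180.0:
        w -= 360.0
    return w


@dataclass
class Atom:
    name: str
    position: np.ndarray
    element: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise UsageError("atom name must be non-empty")
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise UsageError(f"atom {self.name}: position must be a finite 3-vector")
        if not self.element:
            self.element = self.name.lstrip("0123456789")[0]


@dataclass
class Nucleotide:
    chain_id: str
    residue_number: int
    base: str
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self, names: Iterable[str]) -> np.ndarray:
        """Coordinates for the named atoms, in order; raises if any is missing."""
        out = []
        for name in names:
            a = self.atom(name)
            if a is None:
                raise IncompleteResidueError(
                    f"residue {self.chain_id}/{self.residue_number} ({self.base}) "
                    f"is missing atom {name}"
                )
            out.append(a.position)
        return np.array(out)

    @property
    def is_complete(self) -> bool:
        """True when all base-ring atoms and C1' required for fitting are present."""
        try:
            names = frame_atom_names(self.base)
        except UsageError:
            return False
        return all(self.atom(n) is not None for n in names)

    def __repr__(self) -> str:  # compact, used in error messages
        return f"Nucleotide({self.chain_id}/{self.residue_number} {self.base})"


@dataclass
class BasePair:
    """A Watson-Crick pair: target-strand and non-target-strand nucleotides."""

    ts: Nucleotide
    nts: Nucleotide
    pam_index: int

    def __post_init__(self) -> None:
        ordinal(self.pam_index)  # rejects 0

    def c1_c1_distance(self) -> float:
        a = self.ts.atom("C1'")
        b = self.nts.atom("C1'")
        if a is None or b is None:
            raise IncompleteResidueError(
                f"pair {self.pam_index:+d}: C1' atom missing on one strand"
            )
        return float(np.linalg.norm(a.position - b.position))

    def is_watson_crick(self) -> bool:
        return WATSON_CRICK.get(self.ts.base) == self.nts.base or WATSON_CRICK.get(
            self.nts.base
        ) == self.ts.base


@dataclass
class Duplex:
    """Ordered base pairs with strictly consecutive pam_index values."""

    pairs: list[BasePair]

    def __post_init__(self) -> None:
        self.pairs = sorted(self.pairs, key=lambda p: ordinal(p.pam_index))
        ords = [ordinal(p.pam_index) for p in self.pairs]
        if len(set(ords)) != len(ords):
            dup = [p.pam_index for p in self.pairs]
            raise ValidationError(f"duplicate pam_index in duplex: {dup}")
        for a, b in zip(ords, ords[1:]):
            if b != a + 1:
                raise ValidationError("pam_index values must be consecutive (no gaps)")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(p.pam_index for p in self.pairs)

    def pair(self, pam_index: int) -> BasePair:
        o = ordinal(pam_index)
        for p in self.pairs:
            if ordinal(p.pam_index) == o:
                return p
        raise SegmentationError(f"pam_index {pam_index:+d} not present in duplex")

    def segment(self, indices: Sequence[int]) -> list[BasePair]:
        return [self.pair(i) for i in indices]

    def ts_sequence(self) -> str:
        return "".join(p.ts.base for p in self.pairs)


@dataclass
class HelixFrame:
    """Right-handed orthonormal frame attached to a helix segment.

    ``axes`` columns are the x, y, z unit vectors; z is the local helical axis
    pointing 5'->3' along the target strand.
    """

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        self.validate()

    def validate(self, tol: float = 1e-8) -> None:
        err = np.abs(self.axes.T @ self.axes - np.eye(3)).max()
        if err > tol:
            raise ValidationError(f"frame axes not orthonormal (max dev {err:.2e})")
        det = np.linalg.det(self.axes)
        if abs(det - 1.0) > tol:
            raise ValidationError(f"frame axes not right-handed (det {det:.8f})")

    @property
    def x(self) -> np.ndarray:
        return self.axes[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.axes[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.axes[:, 2]

    @classmethod
    def identity(cls) -> "HelixFrame":
        return cls(np.zeros(3), np.eye(3))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "HelixFrame":
        """This frame carried through a rigid motion x -> R x + t."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float).reshape(3)
        return HelixFrame(R @ self.origin + t, R @ self.axes)
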