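"""Standard base-pair reference geometry.

In-plane coordinates of the base-ring heavy atoms and C1' of each nucleobase,
expressed in the standard nucleic-acid base reference frame (Olson et al. 2001
convention): the base lies in the z = 0 plane, x points into the major groove,
y toward the strand carrying the base. An idealized Watson-Crick pair is built
by placing the target-strand base at its reference coordinates and the
complementary base rotated 180 degrees about x (y -> -y, z -> -z), which for
planar bases reduces to mirroring y. The resulting pair frame is the identity:
origin at (0,0,0), pair normal along +z.
"""

from __future__ import annotations

import numpy as np

from .core import Atom, Nucleotide, UsageError, WATSON_CRICK, frame_atom_names

__all__ = ["BASE_FRAME_COORDS", "complement", "complement_sequence", "pair_nucleotides"]

# (atom name, x, y) in Angstroms; z = 0 for all ring atoms and C1'.
BASE_FRAME_COORDS: dict[str, tuple[tuple[str, float, float], ...]] = {
    "A": (
        ("C1'", -2.479, 5.346),
        ("N9", -1.291, 4.498),
        ("C8", 0.024, 4.897),
        ("N7", 0.877, 3.902),
        ("C5", 0.071, 2.771),
        ("C6", 0.369, 1.398),
        ("N1", -0.668, 0.532),
        ("C2", -1.912, 1.023),
        ("N3", -2.320, 2.290),
        ("C4", -1.267, 3.124),
    ),
    "G": (
        ("C1'", -2.477, 5.399),
        ("N9", -1.289, 4.551),
        ("C8", 0.023, 4.962),
        ("N7", 0.870, 3.969),
        ("C5", 0.071, 2.833),
        ("C6", 0.424, 1.460),
        ("N1", -0.700, 0.641),
        ("C2", -1.999, 1.087),
        ("N3", -2.342, 2.364),
        ("C4", -1.265, 3.177),
    ),
    "C": (
        ("C1'", -2.477, 5.402),
        ("N1", -1.285, 4.542),
        ("C2", -1.472, 3.158),
        ("N3", -0.391, 2.344),
        ("C4", 0.837, 2.868),
        ("C5", 1.056, 4.275),
        ("C6", -0.023, 5.068),
    ),
    "T": (
        ("C1'", -2.481, 5.354),
        ("N1", -1.284, 4.500),
        ("C2", -1.462, 3.135),
        ("N3", -0.298, 2.407),
        ("C4", 0.994, 2.897),
        ("C5", 1.106, 4.338),
        ("C6", -0.024, 5.057),
    ),
}


def complement(base: str) -> str:
    try:
        c = WATSON_CRICK[base]
    except KeyError:
        raise UsageError(f"no Watson-Crick complement for base {base!r}") from None
    return "T" if c == "U" else c


def complement_sequence(sequence: str) -> str:
    """5'->3' complement strand of a 5'->3' sequence (reverse complement)."""
    return "".join(complement(b) for b in reversed(sequence))


def _base_coords(base: str, mirror: bool) -> dict[str, np.ndarray]:
    coords = {}
    for name, x, y in BASE_FRAME_COORDS[base]:
        coords[name] = np.array([x, -y if mirror else y, 0.0])
    return coords


def pair_nucleotides(
    ts_base: str,
    *,
    ts_chain: str = "A",
    nts_chain: str = "B",
    ts_number: int = 1,
    nts_number: int = 1,
) -> tuple[Nucleotide, Nucleotide]:
    """Idealized Watson-Crick pair in the pair reference frame (identity).

    Returns (target-strand, non-target-strand) nucleotides carrying the
    frame-fitting atoms (base ring + C1') only.
    """
    if ts_base not in BASE_FRAME_COORDS:
        raise UsageError(f"sequence may only contain A, C, G, T (got {ts_base!r})")
    nts_base = complement(ts_base)
    ts_coords = _base_coords(ts_base, mirror=False)
    nts_coords = _base_coords(nts_base, mirror=True)
    ts = Nucleotide(
        ts_chain,
        ts_number,
        ts_base,
        [Atom(n, ts_coords[n]) for n in frame_atom_names(ts_base)],
    )
    nts = Nucleotide(
        nts_chain,
        nts_number,
        nts_base,
        [Atom(n, nts_coords[n]) for n in frame_atom_names(nts_base)],
    )
    return ts, nts
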