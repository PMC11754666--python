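"""Idealized B-form DNA construction from a fiber model.

Each base pair is a rigid standard-frame template placed by pure helical twist
(default 36 deg/step) and rise (default 3.38 A/step) along the global z axis.
Propeller, roll, slide and all other step parameters are zero: only the helical
axis frame matters for the inter-helical Euler analysis, so a straight ideal
helix is the cleanest reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Duplex, BasePair, HelixFrame, UsageError, ordinal
from .templates import BASE_FRAME_COORDS, pair_nucleotides

__all__ = ["FiberParams", "build_ideal_duplex", "pair_frame"]


@dataclass(frozen=True)
class FiberParams:
    """Helical step parameters of the fiber model (canonical B-DNA defaults)."""

    twist_per_step: float = 36.0  # degrees
    rise_per_step: float = 3.38  # Angstroms

    def __post_init__(self) -> None:
        if not 0.0 < self.twist_per_step < 360.0:
            raise UsageError("twist_per_step must lie in (0, 360) degrees")
        if self.rise_per_step <= 0.0:
            raise UsageError("rise_per_step must be positive")


def _rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def pair_frame(pair_index: int, params: FiberParams | None = None) -> HelixFrame:
    """Closed-form frame of pair ``pair_index`` (0-based) of an ideal helix.

    Pair k's frame is the global frame rotated by k*twist about z and
    translated by k*rise along z.
    """
    if pair_index < 0:
        raise UsageError("pair_index must be >= 0")
    p = params or FiberParams()
    return HelixFrame(
        np.array([0.0, 0.0, pair_index * p.rise_per_step]),
        _rot_z(pair_index * p.twist_per_step),
    )


def build_ideal_duplex(
    sequence: str,
    params: FiberParams | None = None,
    *,
    first_index: int = -3,
    ts_chain: str = "A",
    nts_chain: str = "B",
) -> Duplex:
    """Idealized B-form duplex for a 5'->3' target-strand sequence.

    pam_index runs from ``first_index`` (default -3, so an 8-mer spans the
    default H1/J/H2 layout -3..+5). Target-strand residues are numbered 1..n in
    sequence order; non-target-strand numbering is mirrored (pair k gets
    residue n-k) so each strand is numbered 1..n in its own 5'->3' direction.
    """
    if len(sequence) < 1:
        raise UsageError("sequence must contain at least one base")
    sequence = sequence.upper()
    bad = set(sequence) - set(BASE_FRAME_COORDS)
    if bad:
        raise UsageError(f"sequence may only contain A, C, G, T (got {sorted(bad)})")
    p = params or FiberParams()
    n = len(sequence)
    start = ordinal(first_index)
    pairs = []
    for k, base in enumerate(sequence):
        frame = pair_frame(k, p)
        ts, nts = pair_nucleotides(
            base,
            ts_chain=ts_chain,
            nts_chain=nts_chain,
            ts_number=k + 1,
            nts_number=n - k,
        )
        for nt in (ts, nts):
            for atom in nt.atoms:
                atom.position = frame.axes @ atom.position + frame.origin
        o = start + k
        pam_index = o if o < 0 else o + 1
        pairs.append(BasePair(ts, nts, pam_index))
    return Duplex(pairs)
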