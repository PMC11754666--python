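"""H1/J/H2 junction segmentation and the bend/underwinding report.

A PAM-indexed duplex is split into an upstream 3-bp helix H1 (default: the
junction-proximal PAM pairs -3..-1), an N-bp junction J (default +1, +2) and a
downstream 3-bp helix H2 (default +3..+5). Ideal B-form 3-bp helices built
with the matching sequences are superposed onto H1 and H2, the relative
rotation of the fitted frames is decomposed into ZYZ Euler angles, and the
underwinding across the junction is N * twist - zeta_h (positive = underwound).

Registration convention: the raw Euler angles between the two central-pair
frames contain the helices' own internal twist. The report therefore re-references
them so that zeta_h measures twist accumulated over exactly N ideal steps
(gamma_h is expressed in the frame of H1's junction-proximal end pair, and H2's
frame is pulled back to the last junction-pair position). For an undistorted
B-form duplex this makes zeta_h = N * twist and underwinding = 0 for every
H1/J/H2 split; the correction is a rotation about each helix's own axis, so
beta_h is untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .core import (
    Duplex,
    SegmentationError,
    UsageError,
    step_count,
    wrap_angle,
)
from .geometry import euler_decompose, fit_helix_frame, relative_rotation, underwinding
from .ideal_helix import FiberParams

__all__ = [
    "BendReport",
    "CONVENTION",
    "JunctionDefinition",
    "analyze_batch",
    "analyze_junction",
    "reports_to_frame",
]

CONVENTION = (
    "active ZYZ Euler decomposition R = Rz(alpha) Ry(beta_h) Rz(gamma); "
    "beta_h = inter-axis angle; gamma_h referenced to H1's junction-proximal "
    "end-pair frame; zeta_h re-referenced to the N junction steps; "
    "underwinding = N x twist - zeta_h; superposition atoms: base ring + C1' "
    "of both strands over 3 bp"
)

#: bend magnitudes below this (degrees) leave the bending direction undefined
DIRECTION_TOL = 1e-3


def _check_consecutive(name: str, idx: tuple[int, ...]) -> None:
    if any(step_count(a, b) != 1 for a, b in zip(idx, idx[1:])):
        raise UsageError(f"{name} indices must be consecutive pam_index values: {idx}")


@dataclass(frozen=True)
class JunctionDefinition:
    """Contiguous H1 / J / H2 split of a PAM-indexed duplex."""

    h1: tuple[int, ...] = (-3, -2, -1)
    j: tuple[int, ...] = (1, 2)
    h2: tuple[int, ...] = (3, 4, 5)

    def __post_init__(self) -> None:
        object.__setattr__(self, "h1", tuple(self.h1))
        object.__setattr__(self, "j", tuple(self.j))
        object.__setattr__(self, "h2", tuple(self.h2))
        if len(self.h1) != 3 or len(self.h2) != 3:
            raise UsageError("H1 and H2 must each contain exactly 3 base pairs")
        if len(self.j) < 1:
            raise UsageError("the junction must contain at least 1 base pair")
        for name, idx in (("H1", self.h1), ("J", self.j), ("H2", self.h2)):
            _check_consecutive(name, idx)
        if step_count(self.h1[-1], self.j[0]) != 1 or step_count(self.j[-1], self.h2[0]) != 1:
            raise UsageError("H1, J and H2 must be contiguous and ordered H1 < J < H2")

    @property
    def n_junction(self) -> int:
        return len(self.j)


@dataclass
class BendReport:
    """Bend/twist geometry of one junction."""

    beta_h: float  # bend magnitude, degrees
    gamma_h: float  # bending direction, degrees
    zeta_h: float  # inter-helical twist across the junction, degrees
    n_junction: int
    underwinding: float  # N x twist - zeta_h, degrees
    h1_fit_rmsd: float  # Angstroms
    h2_fit_rmsd: float
    flags: list[str] = field(default_factory=list)
    convention: str = CONVENTION
    fiber_params: FiberParams = field(default_factory=FiberParams)

    def to_dict(self) -> dict:
        return {
            "beta_h": self.beta_h,
            "gamma_h": self.gamma_h,
            "zeta_h": self.zeta_h,
            "n_junction": self.n_junction,
            "underwinding": self.underwinding,
            "h1_fit_rmsd": self.h1_fit_rmsd,
            "h2_fit_rmsd": self.h2_fit_rmsd,
            "flags": list(self.flags),
            "convention": self.convention,
            "fiber_params": {
                "twist_per_step": self.fiber_params.twist_per_step,
                "rise_per_step": self.fiber_params.rise_per_step,
            },
        }


def analyze_junction(
    duplex: Duplex,
    jdef: JunctionDefinition | None = None,
    params: FiberParams | None = None,
) -> BendReport:
    """Fit H1 and H2 helix frames and report bend, twist and underwinding."""
    jdef = jdef or JunctionDefinition()
    p = params or FiberParams()
    missing = [i for i in (*jdef.h1, *jdef.j, *jdef.h2) if i not in duplex.indices]
    if missing:
        raise SegmentationError(
            f"duplex (pam_index {duplex.indices[0]:+d}..{duplex.indices[-1]:+d}) "
            f"lacks required pam_index values {', '.join(f'{i:+d}' for i in missing)}"
        )
    h1_frame, h1_rmsd = fit_helix_frame(duplex.segment(jdef.h1), params=p)
    h2_frame, h2_rmsd = fit_helix_frame(duplex.segment(jdef.h2), params=p)
    angles = euler_decompose(relative_rotation(h1_frame, h2_frame))

    n = jdef.n_junction
    tau = p.twist_per_step
    # internal-twist corrections: steps from H1's central pair to its end pair,
    # and total non-junction steps between the two central pairs
    theta1 = step_count(jdef.h1[1], jdef.h1[-1]) * tau
    internal = (step_count(jdef.h1[1], jdef.h2[1]) - n) * tau
    zeta = wrap_angle(angles.zeta_h - internal)
    flags: list[str] = []
    if angles.gimbal or angles.beta_h < DIRECTION_TOL:
        gamma = 0.0
        flags.append("direction_undefined")
    else:
        gamma = wrap_angle(angles.gamma_h - theta1)
    uw = underwinding(n, zeta, tau)
    if abs(uw) > 90.0:
        flags.append("large_underwinding")
    return BendReport(
        beta_h=angles.beta_h,
        gamma_h=gamma,
        zeta_h=zeta,
        n_junction=n,
        underwinding=uw,
        h1_fit_rmsd=h1_rmsd,
        h2_fit_rmsd=h2_rmsd,
        flags=flags,
        fiber_params=p,
    )


def analyze_batch(entries: Iterable[Mapping]) -> pd.DataFrame:
    """Run :func:`analyze_junction` over many structures, never aborting.

    Each entry is a mapping with an ``id`` and either a ready ``duplex`` or a
    ``path`` plus pairing ``config`` (see :func:`bendscan.structure_io.
    load_pairing_config` for the keys); optional ``jdef`` and ``params``.
    Failures are recorded in the row's ``error`` column and the batch
    continues. Rows keep input order.
    """
    entries = list(entries)
    if not entries:
        raise UsageError("analyze_batch requires at least one entry")
    from . import structure_io  # deferred: batch over paths only

    rows = []
    for i, entry in enumerate(entries):
        row: dict = {"id": entry.get("id", i)}
        try:
            duplex = entry.get("duplex")
            if duplex is None:
                cfg = entry["config"]
                st = structure_io.read_structure(
                    entry["path"], altloc=cfg.get("altloc")
                )
                duplex = structure_io.select_duplex(
                    st,
                    cfg["ts_chain"],
                    cfg["nts_chain"],
                    cfg["pairs"],
                    modified=cfg.get("modified", ()),
                )
            report = analyze_junction(
                duplex, entry.get("jdef"), entry.get("params")
            )
            row.update(
                beta_h=report.beta_h,
                gamma_h=report.gamma_h,
                zeta_h=report.zeta_h,
                n_junction=report.n_junction,
                underwinding=report.underwinding,
                h1_fit_rmsd=report.h1_fit_rmsd,
                h2_fit_rmsd=report.h2_fit_rmsd,
                flags=",".join(report.flags),
                error=None,
            )
        except Exception as exc:  # record-and-continue batch policy
            row.update(error=f"{type(exc).__name__}: {exc}")
        rows.append(row)
    return pd.DataFrame(rows)


def reports_to_frame(reports: Mapping[str, BendReport]) -> pd.DataFrame:
    """Tabulate named reports (one row each), e.g. for TSV export."""
    rows = []
    for name, r in reports.items():
        d = r.to_dict()
        d.pop("convention")
        d.pop("fiber_params")
        d["flags"] = ",".join(r.flags)
        rows.append({"id": name, **d})
    return pd.DataFrame(rows)
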