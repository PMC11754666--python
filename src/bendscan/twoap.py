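"""2-aminopurine fluorescence normalization with error propagation.

2-AP is a fluorescent adenine analogue whose emission rises when the base is
unstacked from the duplex, reporting base flipping in solution. Replicate
intensities per (condition, probe position) are averaged, and every condition
is normalized to the double-stranded-DNA-only reference measured at the same
probe position. The uncertainty of the ratio r = x/y follows standard
first-order propagation:

    sigma_r = (x/y) * sqrt((sigma_x/x)^2 + (sigma_y/y)^2)

with sample (n-1) standard deviations. Time-point selection from kinetic
reads is handled by the CSV reader (``timepoint=``); the statistics operate on
already-selected readings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .core import PairingError, UsageError

__all__ = [
    "NormalizedSignal",
    "ReplicateSet",
    "normalize",
    "position_profile",
    "read_plate_csv",
    "summarize",
]

DSDNA_CONDITION = "dsDNA"


@dataclass(frozen=True)
class ReplicateSet:
    """Replicate fluorescence readings for one condition and probe position."""

    condition: str
    probe_position: int
    readings: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "readings", tuple(float(r) for r in self.readings))
        if any(r <= 0 for r in self.readings):
            raise UsageError("fluorescence intensities must be positive")


@dataclass(frozen=True)
class NormalizedSignal:
    """Reference-normalized signal ratio with propagated uncertainty."""

    ratio: float
    propagated_sigma: float


def summarize(replicates: ReplicateSet | Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample (n-1) standard deviation of the readings."""
    readings = (
        replicates.readings if isinstance(replicates, ReplicateSet) else tuple(replicates)
    )
    n = len(readings)
    if n < 2:
        raise UsageError("need at least 2 readings for a standard deviation")
    mean = sum(readings) / n
    var = sum((r - mean) ** 2 for r in readings) / (n - 1)
    return mean, math.sqrt(var)


def normalize(
    signal: tuple[float, float], reference: tuple[float, float]
) -> NormalizedSignal:
    """Ratio of (mean, sd) summaries with first-order error propagation."""
    x, sx = signal
    y, sy = reference
    if y == 0:
        raise ZeroDivisionError("reference mean must be non-zero")
    if x <= 0 or y < 0:
        raise UsageError("means must be positive")
    if sx < 0 or sy < 0:
        raise UsageError("standard deviations must be non-negative")
    ratio = x / y
    sigma = ratio * math.sqrt((sx / x) ** 2 + (sy / y) ** 2)
    return NormalizedSignal(ratio, sigma)


def position_profile(
    data: Iterable[ReplicateSet], reference_condition: str = DSDNA_CONDITION
) -> pd.DataFrame:
    """Normalize every (position, condition) against its same-position reference.

    Each probe position must carry a ``reference_condition`` replicate set (its
    own dsDNA-only control sequence). Reference rows normalize to exactly 1,
    with sigma reflecting only the doubled reference variance.
    """
    data = list(data)
    refs: dict[int, tuple[float, float]] = {}
    for rs in data:
        if rs.condition == reference_condition:
            refs[rs.probe_position] = summarize(rs)
    rows = []
    for rs in data:
        try:
            ref = refs[rs.probe_position]
        except KeyError:
            raise PairingError(
                f"no {reference_condition!r} reference at probe position "
                f"{rs.probe_position}"
            ) from None
        mean, sd = summarize(rs)
        ns = normalize((mean, sd), ref)
        rows.append(
            {
                "position": rs.probe_position,
                "condition": rs.condition,
                "mean": mean,
                "sd": sd,
                "ratio": ns.ratio,
                "propagated_sigma": ns.propagated_sigma,
            }
        )
    return pd.DataFrame(rows).sort_values(["position", "condition"]).reset_index(drop=True)


def read_plate_csv(path: str | Path, timepoint: float | None = None) -> list[ReplicateSet]:
    """Read long-format plate data (condition, position, replicate, time_s,
    intensity) into replicate sets, optionally selecting one kinetic time point.
    """
    df = pd.read_csv(path)
    required = {"condition", "position", "intensity"}
    if not required <= set(df.columns):
        raise UsageError(f"{path}: expected columns {sorted(required)}")
    if timepoint is not None:
        if "time_s" not in df.columns:
            raise UsageError(f"{path}: no time_s column to select timepoint from")
        df = df[df["time_s"] == timepoint]
        if df.empty:
            raise UsageError(f"{path}: no readings at time_s == {timepoint}")
    out = []
    for (condition, position), grp in df.groupby(["condition", "position"], sort=True):
        out.append(
            ReplicateSet(str(condition), int(position), tuple(grp["intensity"]))
        )
    return out
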