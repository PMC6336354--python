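"""Per-residue peak-intensity quenching maps for adaptor titrations.

On binding, residues in and around the interacting helix lose peak height
(line broadening from slower effective tumbling and/or exchange) while the
rest of the disordered chain is untouched.  The map is the per-residue
ratio of bound to free peak heights; contiguous stretches of strong
quenching are called as binding segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np


class ResidueStatus(str, Enum):
    OK = "ok"
    OVERLAPPED = "overlapped"
    PROLINE = "proline"
    MISSING = "missing"


@dataclass(frozen=True)
class BindingSegment:
    start_residue: int
    end_residue: int
    mean_ratio: float


@dataclass
class QuenchProfile:
    """I_bound/I_free per residue; flagged residues carry status but no ratio."""

    ratios: dict[int, float]
    statuses: dict[int, ResidueStatus]
    molar_ratio: str = "1:1"

    def __post_init__(self) -> None:
        for r, v in self.ratios.items():
            if self.statuses.get(r) != ResidueStatus.OK:
                raise ValueError(f"residue {r}: ratio present but status is not ok")
            if v < 0:
                raise ValueError(f"residue {r}: negative intensity ratio")


def quench_profile(
    free: dict[int, float],
    bound: dict[int, float],
    statuses: dict[int, ResidueStatus] | None = None,
    molar_ratio: str = "1:1",
    normalize_region: tuple[int, int] | None = None,
) -> QuenchProfile:
    """Compute per-residue bound/free peak-height ratios.

    Ratios are raw by default (no cross-spectrum normalisation).  If
    ``normalize_region`` is given, all ratios are divided by the mean ratio
    over that residue range, which rescales for inter-sample concentration
    differences using a region declared unaffected by binding.
    """
    statuses = dict(statuses or {})
    extra = set(bound) - set(free)
    if extra:
        raise ValueError(f"residues present in bound but absent in free: {sorted(extra)}")
    ratios: dict[int, float] = {}
    out_status: dict[int, ResidueStatus] = {}
    for r in sorted(free):
        st = statuses.get(r, ResidueStatus.OK)
        if st is ResidueStatus.OK and r not in bound:
            st = ResidueStatus.MISSING
        out_status[r] = st
        if st is ResidueStatus.OK:
            if free[r] <= 0:
                raise ValueError(f"residue {r}: nonpositive free intensity with status ok")
            ratios[r] = bound[r] / free[r]
    for r, st in statuses.items():  # flagged residues absent from the tables still appear
        out_status.setdefault(r, st)
    if normalize_region is not None:
        lo, hi = normalize_region
        ref = [v for r, v in ratios.items() if lo <= r <= hi]
        if not ref:
            raise ValueError(f"no ok residues in normalisation region {lo}-{hi}")
        scale = float(np.mean(ref))
        ratios = {r: v / scale for r, v in ratios.items()}
    return QuenchProfile(ratios=ratios, statuses=out_status, molar_ratio=molar_ratio)


def call_binding_segments(
    profile: QuenchProfile,
    threshold: float = 0.5,
    min_length: int = 3,
) -> list[BindingSegment]:
    """Call maximal contiguous runs of quenched residues.

    A residue qualifies when its status is ok and its ratio is at or below
    ``threshold``.  A single flagged (overlapped/proline/missing) residue
    inside a run is bridged; two or more consecutive non-qualifying
    residues, or any ok residue above threshold, break the run.  Runs with
    at least ``min_length`` qualifying residues are reported with the mean
    ratio over those residues.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    residues = sorted(profile.statuses)
    if not residues:
        return []

    def qualifies(r: int) -> bool:
        return profile.statuses.get(r) is ResidueStatus.OK and profile.ratios[r] <= threshold

    def bridgeable(r: int) -> bool:
        return profile.statuses.get(r, ResidueStatus.MISSING) is not ResidueStatus.OK

    segments: list[BindingSegment] = []
    lo, hi = residues[0], residues[-1]
    i = lo
    while i <= hi:
        if not qualifies(i):
            i += 1
            continue
        start = i
        end = i
        j = i + 1
        while j <= hi:
            if qualifies(j):
                end = j
                j += 1
            elif bridgeable(j) and j + 1 <= hi and qualifies(j + 1):
                end = j + 1  # single flagged residue bridged
                j += 2
            else:
                break
        members = [r for r in range(start, end + 1) if qualifies(r)]
        if len(members) >= min_length:
            segments.append(
                BindingSegment(start, end, float(np.mean([profile.ratios[r] for r in members])))
            )
        i = j
    return segments
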