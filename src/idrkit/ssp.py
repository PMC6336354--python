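"""Secondary-structure-propensity (SSP) scoring from backbone chemical shifts.

The score combines the secondary shifts of several backbone nuclei into one
residue-specific number on a scale where +1 is a fully formed alpha helix,
-1 a fully formed beta sheet, and 0 random coil.  Under the two-state
(helix/coil) picture the score is linear in the helical population, so a
segment transiently sampling helix 20% of the time scores about +0.2.

This is a defined SSP variant: per-nucleus normalised propensities are
averaged over a sliding window with weights proportional to the squared
reference secondary shift, and CA/CB shifts can be re-referenced by a
robust (10%-trimmed-mean) chain offset.  Bit-parity with any external SSP
program is not promised; the endpoint and linearity semantics above are
the contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .formats import KNOWN_NUCLEI, ShiftTable, ValidationError

#: soft bound on |score|; values beyond it are flagged, not clipped
SCORE_SOFT_BOUND = 1.5

#: nuclei whose raw secondary shifts are re-referenced by a chain offset
REREFERENCED_NUCLEI = ("CA", "CB")


@dataclass(frozen=True)
class ReferenceShiftLibrary:
    """Random-coil shifts and full-helix / full-sheet secondary shifts.

    Keys are ``(residue_type, nucleus)`` with one-letter residue codes.
    The helix and sheet secondary shifts must be nonzero and of opposite
    sign for every covered pair, which is what makes the normalised
    propensity land on +1 / -1 at the structural endpoints.
    """

    rc: dict[tuple[str, str], float]
    helix: dict[tuple[str, str], float]
    sheet: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        for key in self.rc:
            a, b = self.helix[key], self.sheet[key]
            if a == 0 or b == 0:
                raise ValidationError(f"zero secondary shift in library at {key}")
            if a * b >= 0:
                raise ValidationError(f"helix/sheet secondary shifts share sign at {key}")

    def covers(self, residue_type: str, nucleus: str) -> bool:
        return (residue_type, nucleus) in self.rc


def load_reference_library() -> ReferenceShiftLibrary:
    """Load the packaged random-coil + secondary-shift compilation."""
    with resources.files("idrkit.data").joinpath("reference_shifts.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    rc, helix, sheet = {}, {}, {}
    for row in df.itertuples(index=False):
        key = (row.residue_type, row.nucleus)
        rc[key] = float(row.rc_shift)
        helix[key] = float(row.helix_secondary)
        sheet[key] = float(row.sheet_secondary)
    return ReferenceShiftLibrary(rc=rc, helix=helix, sheet=sheet)


@dataclass
class SecondaryShifts:
    """Per-(residue, nucleus) observed secondary shifts plus applied offsets."""

    values: dict[tuple[int, str], float]          # ppm
    offsets: dict[str, float]                     # ppm, per nucleus
    residue_types: dict[int, str]


def secondary_shifts(
    shifts: ShiftTable,
    sequence: str | None = None,
    library: ReferenceShiftLibrary | None = None,
    rereference: bool = True,
    first_residue: int | None = None,
) -> SecondaryShifts:
    """Compute observed secondary shifts, optionally re-referencing CA/CB.

    The secondary shift is delta_obs - delta_rc - offset(nucleus).  With
    ``rereference`` on, the CA and CB offsets are the 10%-trimmed mean of
    the raw secondary shifts over the whole chain — robust against a couple
    of short structured segments — and all other nuclei get offset 0.

    ``sequence``/``first_residue`` are used only to cross-check residue
    types when provided.
    """
    if library is None:
        library = load_reference_library()
    types = shifts.residue_types()
    if sequence is not None:
        start = first_residue if first_residue is not None else min(types, default=1)
        for resnum, rtype in types.items():
            pos = resnum - start
            if 0 <= pos < len(sequence) and sequence[pos] != rtype:
                raise ValidationError(
                    f"residue {resnum} typed {rtype} in table but {sequence[pos]} in sequence"
                )
    raw: dict[tuple[int, str], float] = {}
    for e in shifts.entries:
        if not library.covers(e.residue_type, e.nucleus):
            raise ValidationError(f"library lacks ({e.residue_type}, {e.nucleus}) for residue {e.residue_number}")
        raw[(e.residue_number, e.nucleus)] = e.shift - library.rc[(e.residue_type, e.nucleus)]
    offsets = {nuc: 0.0 for nuc in KNOWN_NUCLEI}
    if rereference:
        for nuc in REREFERENCED_NUCLEI:
            vals = [v for (_, n), v in raw.items() if n == nuc]
            if vals:
                offsets[nuc] = float(stats.trim_mean(vals, proportiontocut=0.1))
    values = {(r, n): v - offsets[n] for (r, n), v in raw.items()}
    return SecondaryShifts(values=values, offsets=offsets, residue_types=types)


@dataclass
class SSPProfile:
    """Residue-resolved SSP scores (nominal range -1..+1)."""

    scores: dict[int, float]
    n_shifts_used: dict[int, int]
    window: int
    offsets: dict[str, float]
    flagged: list[int] = field(default_factory=list)  # |score| beyond the soft bound

    def to_frame(self) -> pd.DataFrame:
        residues = sorted(self.n_shifts_used)
        return pd.DataFrame(
            {
                "residue": residues,
                "score": [self.scores.get(r, math.nan) for r in residues],
                "n_shifts_used": [self.n_shifts_used[r] for r in residues],
            }
        )


def ssp_profile(
    secondary: SecondaryShifts,
    window: int = 5,
    library: ReferenceShiftLibrary | None = None,
) -> SSPProfile:
    """Combine secondary shifts into windowed residue-specific SSP scores.

    For each available (residue, nucleus): s = sign(helix_ref) * delta_obs,
    and the normalised propensity is p = s/|helix_ref| when s >= 0 (toward
    helix) or s/|sheet_ref| when s < 0 (toward sheet).  The residue score is
    the weighted mean of p over all nuclei of all residues in the centred
    window, with weights proportional to the square of the reference
    secondary shift used in the normalisation.  Missing shifts are simply
    omitted; the window truncates at chain ends.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    if library is None:
        library = load_reference_library()
    half = (window - 1) // 2
    residues = sorted(secondary.residue_types)
    # per-residue lists of (p, weight)
    per_residue: dict[int, list[tuple[float, float]]] = {r: [] for r in residues}
    for (resnum, nuc), dd in secondary.values.items():
        rtype = secondary.residue_types[resnum]
        a = library.helix[(rtype, nuc)]
        b = library.sheet[(rtype, nuc)]
        s = math.copysign(1.0, a) * dd
        ref = abs(a) if s >= 0 else abs(b)
        per_residue[resnum].append((s / ref, ref * ref))
    scores: dict[int, float] = {}
    n_used: dict[int, int] = {}
    flagged: list[int] = []
    for r in residues:
        num = den = 0.0
        count = 0
        for rr in range(r - half, r + half + 1):
            for p, w in per_residue.get(rr, ()):
                num += w * p
                den += w
                count += 1
        n_used[r] = count
        if count:
            score = num / den
            scores[r] = score
            if abs(score) > SCORE_SOFT_BOUND:
                flagged.append(r)
    return SSPProfile(scores=scores, n_shifts_used=n_used, window=window,
                      offsets=dict(secondary.offsets), flagged=flagged)
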