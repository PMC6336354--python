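"""Tabular I/O for the pipeline: chemical-shift tables, long-format series, results.

TSV is the canonical dialect (tab-delimited, ``#`` comments, header row
required).  A minimal NMR-STAR v3 reader covers the ``_Atom_chem_shift``
loop only, which is what BMRB-style chemical-shift deposits contain; no
attempt is made at the full STAR grammar.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

#: Backbone nuclei the pipeline understands.  ``C`` is the carbonyl carbon.
KNOWN_NUCLEI = ("H", "N", "C", "CA", "CB")

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class FormatError(ValueError):
    """Malformed file content (parse failure, schema mismatch)."""


class ValidationError(ValueError):
    """Content parsed but violates a domain invariant."""


@dataclass(frozen=True)
class ShiftEntry:
    residue_number: int
    residue_type: str  # one-letter code
    nucleus: str       # one of KNOWN_NUCLEI
    shift: float       # ppm


@dataclass
class ShiftTable:
    """Residue-resolved chemical shifts, at most one entry per (residue, nucleus)."""

    entries: list[ShiftEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[int, str]] = set()
        last_by_nucleus: dict[str, int] = {}
        for e in self.entries:
            if e.residue_type not in AMINO_ACIDS:
                raise ValidationError(f"unknown residue type {e.residue_type!r} at residue {e.residue_number}")
            if e.nucleus not in KNOWN_NUCLEI:
                raise ValidationError(f"unknown nucleus {e.nucleus!r} at residue {e.residue_number}")
            if not math.isfinite(e.shift):
                raise ValidationError(f"non-finite shift at residue {e.residue_number} {e.nucleus}")
            if e.residue_type == "G" and e.nucleus == "CB":
                raise ValidationError(f"glycine {e.residue_number} cannot carry a CB shift")
            key = (e.residue_number, e.nucleus)
            if key in seen:
                raise ValidationError(f"duplicate assignment for residue {e.residue_number} nucleus {e.nucleus}")
            seen.add(key)
            prev = last_by_nucleus.get(e.nucleus)
            if prev is not None and e.residue_number < prev:
                raise ValidationError(
                    f"residue numbers not non-decreasing within nucleus {e.nucleus} (…{prev}, {e.residue_number})"
                )
            last_by_nucleus[e.nucleus] = e.residue_number

    def __len__(self) -> int:
        return len(self.entries)

    def residues(self) -> list[int]:
        return sorted({e.residue_number for e in self.entries})

    def residue_types(self) -> dict[int, str]:
        out: dict[int, str] = {}
        for e in self.entries:
            prev = out.setdefault(e.residue_number, e.residue_type)
            if prev != e.residue_type:
                raise ValidationError(f"conflicting residue types at residue {e.residue_number}: {prev} vs {e.residue_type}")
        return out

    def by_residue_nucleus(self) -> dict[tuple[int, str], float]:
        return {(e.residue_number, e.nucleus): e.shift for e in self.entries}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.residue_number, e.residue_type, e.nucleus, e.shift) for e in self.entries],
            columns=["residue", "residue_type", "nucleus", "shift"],
        )


@dataclass(frozen=True)
class LongTableSchema:
    """Declares which columns of a long-format file play which role."""

    series_key: str = "series"
    x: str = "x"
    y: str = "y"
    weight: str | None = None
    allow_replicates: bool = False


@dataclass
class LongTable:
    """Long-format (series_key, x, y[, weight]) table, sorted by (series_key, x)."""

    data: pd.DataFrame
    schema: LongTableSchema

    def series_keys(self) -> list[str]:
        return list(dict.fromkeys(self.data["series_key"]))

    def series(self, key: str) -> pd.DataFrame:
        return self.data[self.data["series_key"] == key].reset_index(drop=True)


def _read_tsv(path: Path, sep: str) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=sep, comment="#", dtype=str, skip_blank_lines=True)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse: {exc}") from exc


def read_shift_table(path: str | Path, dialect: str = "tsv") -> ShiftTable:
    """Read a chemical-shift table.

    ``dialect='tsv'`` expects columns ``residue``, ``residue_type``,
    ``nucleus``, ``shift``.  ``dialect='nmrstar'`` reads the single
    ``_Atom_chem_shift`` loop of an NMR-STAR v3 file.  Rows whose nucleus is
    not one of ``H, N, C, CA, CB`` are skipped with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        rows = _shift_rows_from_tsv(path)
    elif dialect == "nmrstar":
        rows = _shift_rows_from_nmrstar(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    entries, skipped = [], 0
    for lineno, resnum, restype, nucleus, shift in rows:
        if nucleus not in KNOWN_NUCLEI:
            skipped += 1
            continue
        try:
            entries.append(ShiftEntry(int(resnum), restype, nucleus, float(shift)))
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: malformed row at line {lineno}: {exc}") from exc
    if skipped:
        logger.info("%s: skipped %d rows with unsupported nuclei", path, skipped)
    return ShiftTable(entries)


def _shift_rows_from_tsv(path: Path):
    df = _read_tsv(path, sep="\t")
    required = {"residue", "residue_type", "nucleus", "shift"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    for i, row in df.iterrows():
        yield i + 2, row["residue"], str(row["residue_type"]).strip(), str(row["nucleus"]).strip(), row["shift"]


def _shift_rows_from_nmrstar(path: Path):
    """Extract (residue, type, atom, value) from the one assigned-shift loop."""
    text = path.read_text()
    lines = text.splitlines()
    loops = []
    i = 0
    while i < len(lines):
        if lines[i].strip() == "loop_":
            tags: list[str] = []
            j = i + 1
            while j < len(lines) and lines[j].strip().startswith("_"):
                tags.append(lines[j].strip())
                j += 1
            body: list[tuple[int, list[str]]] = []
            while j < len(lines) and lines[j].strip() != "stop_":
                stripped = lines[j].strip()
                if stripped and not stripped.startswith("#"):
                    body.append((j + 1, stripped.split()))
                j += 1
            if any(t.startswith("_Atom_chem_shift.") for t in tags):
                loops.append((tags, body))
            i = j + 1
        else:
            i += 1
    if len(loops) != 1:
        raise FormatError(f"{path}: expected exactly one _Atom_chem_shift loop, found {len(loops)}")
    tags, body = loops[0]
    idx = {t.split(".", 1)[1]: k for k, t in enumerate(tags)}
    for col in ("Comp_index_ID", "Comp_ID", "Atom_ID", "Val"):
        if col not in idx:
            raise FormatError(f"{path}: _Atom_chem_shift loop lacks column {col}")
    for lineno, fields in body:
        if len(fields) != len(tags):
            raise FormatError(f"{path}: malformed loop row at line {lineno}")
        comp = fields[idx["Comp_ID"]].upper()
        restype = THREE_TO_ONE.get(comp, comp if comp in AMINO_ACIDS else None)
        if restype is None:
            raise FormatError(f"{path}: unknown residue {comp!r} at line {lineno}")
        yield lineno, fields[idx["Comp_index_ID"]], restype, fields[idx["Atom_ID"]].upper(), fields[idx["Val"]]


def read_long_table(path: str | Path, schema: LongTableSchema, dialect: str = "tsv") -> LongTable:
    """Read a long-format series table and normalise it to (series_key, x, y[, weight])."""
    path = Path(path)
    sep = "\t" if dialect == "tsv" else ","
    df = _read_tsv(path, sep=sep)
    cols = [schema.series_key, schema.x, schema.y] + ([schema.weight] if schema.weight else [])
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    out = pd.DataFrame()
    out["series_key"] = df[schema.series_key].astype(str)
    for role, col in (("x", schema.x), ("y", schema.y)) + ((("weight", schema.weight),) if schema.weight else ()):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            raise FormatError(f"{path}: non-numeric value in column {col!r} at row {int(bad.idxmax()) + 2}")
        out[role] = vals.astype(float)
    if not out["x"].map(math.isfinite).all():
        raise ValidationError(f"{path}: non-finite x values")
    if not schema.allow_replicates:
        dup = out.duplicated(subset=["series_key", "x"])
        if dup.any():
            first = out[dup].iloc[0]
            raise ValidationError(f"{path}: duplicate (series, x) pair ({first['series_key']}, {first['x']})")
    out = out.sort_values(["series_key", "x"], kind="stable").reset_index(drop=True)
    return LongTable(out, schema)


def write_results(records, path: str | Path, format: str = "tsv") -> None:
    """Write keyed result records (list of dicts) as TSV or JSON.

    Numeric values survive a round trip through :func:`read_long_table` to at
    least 12 significant digits (full ``repr`` precision is written).
    """
    path = Path(path)
    records = list(records)
    if not records:
        logger.warning("write_results: empty record set -> header-only file %s", path)
    if format == "json":
        path.write_text(json.dumps(records, indent=2, default=float) + "\n")
        return
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}")
    columns: list[str] = []
    for rec in records:
        for k in rec:
            if k not in columns:
                columns.append(k)
    with open(path, "w") as fh:
        fh.write("\t".join(columns if columns else ["empty"]) + "\n")
        for rec in records:
            cells = []
            for k in columns:
                v = rec.get(k, "")
                if isinstance(v, float):
                    if math.isnan(v):
                        raise ValidationError("NaN in results; drop or flag it before writing")
                    cells.append(repr(v))
                else:
                    cells.append(str(v))
            fh.write("\t".join(cells) + "\n")


@dataclass
class CoverageReport:
    assigned: int
    unassigned: list[int]
    prolines: list[int]


def validate_residue_coverage(table: ShiftTable, sequence: str, offset: int = 0) -> CoverageReport:
    """Partition sequence positions into assigned / unassigned / proline.

    ``offset`` maps sequence position 1 to residue number ``1 + offset``
    (construct-absolute numbering is kept verbatim).
    """
    types = table.residue_types()
    mismatches = []
    for resnum, rtype in types.items():
        pos = resnum - offset
        if 1 <= pos <= len(sequence) and sequence[pos - 1] != rtype:
            mismatches.append((resnum, sequence[pos - 1], rtype))
    if mismatches:
        detail = ", ".join(f"{n} (sequence {s}, table {t})" for n, s, t in mismatches)
        raise ValidationError(f"residue-type mismatch at {detail}")
    assigned = 0
    unassigned: list[int] = []
    prolines: list[int] = []
    for pos, aa in enumerate(sequence, start=1):
        resnum = pos + offset
        if aa == "P":
            prolines.append(resnum)
        elif resnum in types:
            assigned += 1
        else:
            unassigned.append(resnum)
    return CoverageReport(assigned=assigned, unassigned=unassigned, prolines=prolines)
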