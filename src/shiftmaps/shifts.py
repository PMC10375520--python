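"""Shift tables and experimental assignments.

Database structures carry *predicted* chemical shifts (one per ¹H/¹³C
site, with a prediction uncertainty); the query molecule carries
*experimental* assigned shifts.  Both are plain CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import FormatError, ValidationError

__all__ = ["ShiftRecord", "Assignment", "AssignmentTable", "read_shift_table",
           "write_shift_table", "read_assignments"]

SHIFT_COLUMNS = ["structure_id", "site_index", "nucleus", "shift_ppm", "uncertainty_ppm"]


@dataclass(frozen=True)
class ShiftRecord:
    """Predicted shift of one database site (ppm) with its uncertainty."""

    structure_id: str
    site_index: int
    nucleus: str
    predicted_shift: float
    uncertainty: float

    def __post_init__(self) -> None:
        if not self.uncertainty > 0:
            raise ValidationError(
                f"{self.structure_id}/{self.site_index}: uncertainty must be > 0"
            )


def read_shift_table(path: str | Path) -> list[ShiftRecord]:
    """Read a predicted-shift CSV (columns: structure_id, site_index, nucleus,
    shift_ppm, uncertainty_ppm); row order is preserved."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pandas raises several parse error types
        raise FormatError(f"{path}: cannot read CSV: {exc}") from exc
    missing = [c for c in SHIFT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    records = []
    for i, row in df.iterrows():
        try:
            shift = float(row["shift_ppm"])
            unc = float(row["uncertainty_ppm"])
            idx = int(row["site_index"])
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: non-numeric value in row {i}: {exc}") from exc
        records.append(ShiftRecord(str(row["structure_id"]), idx,
                                   str(row["nucleus"]).strip(), shift, unc))
    return records


def write_shift_table(records: list[ShiftRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "structure_id": r.structure_id,
                "site_index": r.site_index,
                "nucleus": r.nucleus,
                "shift_ppm": r.predicted_shift,
                "uncertainty_ppm": r.uncertainty,
            }
            for r in records
        ],
        columns=SHIFT_COLUMNS,
    ).to_csv(path, index=False)


@dataclass(frozen=True)
class Assignment:
    """One assigned experimental shift on the query molecule.

    ``pair_id`` links the ¹³C and ¹H entries of a bonded C–H pair used for
    two-dimensional (HETCOR-style) environment selection.
    """

    site_label: str
    nucleus: str
    experimental_shift: float
    ambiguous: bool = False
    pair_id: str | None = None


@dataclass
class AssignmentTable:
    """The set of assigned experimental shifts for one query molecule."""

    assignments: list[Assignment] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for a in self.assignments:
            if not a.ambiguous:
                key = a.site_label
                if key in seen:
                    raise ValidationError(f"unambiguous site {key!r} assigned twice")
                seen.add(key)

    def __iter__(self):
        return iter(self.assignments)

    def __len__(self) -> int:
        return len(self.assignments)

    def unambiguous(self) -> list[Assignment]:
        return [a for a in self.assignments if not a.ambiguous]

    def pairs(self) -> dict[str, tuple[Assignment, Assignment]]:
        """pair_id -> (¹³C assignment, ¹H assignment) for bonded C–H pairs."""
        grouped: dict[str, list[Assignment]] = {}
        for a in self.assignments:
            if a.pair_id is not None:
                grouped.setdefault(a.pair_id, []).append(a)
        out = {}
        for pid, members in grouped.items():
            if len(members) != 2 or {m.nucleus for m in members} != {"C", "H"}:
                raise ValidationError(
                    f"pair {pid!r} must contain exactly one C and one H assignment"
                )
            c = next(m for m in members if m.nucleus == "C")
            h = next(m for m in members if m.nucleus == "H")
            out[pid] = (c, h)
        return out


def read_assignments(path: str | Path) -> AssignmentTable:
    """Read an assignment CSV (site_label, nucleus, shift_ppm[, ambiguous, pair_id])."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"{path}: cannot read CSV: {exc}") from exc
    required = ["site_label", "nucleus", "shift_ppm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    out = []
    for i, row in df.iterrows():
        try:
            shift = float(row["shift_ppm"])
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: non-numeric shift in row {i}") from exc
        amb = bool(row["ambiguous"]) if "ambiguous" in df.columns and not pd.isna(row.get("ambiguous")) else False
        pid = None
        if "pair_id" in df.columns and not pd.isna(row.get("pair_id")):
            pid = str(row["pair_id"])
        out.append(Assignment(str(row["site_label"]), str(row["nucleus"]).strip(),
                              shift, amb, pid))
    return AssignmentTable(out)
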