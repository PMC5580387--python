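"""Specimen-table I/O and packaged fixture datasets.

Schema (comma-delimited, UTF-8, LF, header required):

==================  =========================================================
column              meaning
==================  =========================================================
specimen_id         unique, non-empty
taxon               free text
age_class           ``adult`` | ``juvenile`` | ``unknown`` (empty = unknown)
locality            free text, quoted when it contains commas
a .. l              character state codes: C (cervical), X (transitional),
                    T (thoracic), ? or empty (missing)
<c>_left, <c>_right optional per-side states for bilateral characters
m_<field>           optional raw measurement columns (floats)
facet_left/right    optional facet size class: none | small | large
facet_position_note optional free text (recorded only when sides differ)
==================  =========================================================

Any other column is carried through verbatim in ``record.metadata``.

Three fixtures ship with the package:

* ``coelodonta_c7`` — 32 Late Pleistocene woolly-rhinoceros last-cervical
  vertebrae (full character detail where recorded; the remainder are
  archetypal C7).
* ``extant_rhino`` — 56 extant rhinocerotid C7 vertebrae from five species,
  all archetypal C7 (no rib facets found).
* ``table4_matrix`` — the 12 fully characterized vertebrae with at least one
  transitional character, including the first-thoracic comparison vertebrae.
"""

from __future__ import annotations

import csv
import hashlib
import io
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

from .characters import (
    BILATERAL_IDS,
    CHARACTER_IDS,
    AgeClass,
    CharacterState,
    MeasurementSet,
    SideStates,
)
from .classifier import FacetSize, SideNotes, VertebraRecord
from .errors import SpecimenTableError

FIXTURE_NAMES = ("coelodonta_c7", "extant_rhino", "table4_matrix")

_BASE_COLUMNS = ("specimen_id", "taxon", "age_class", "locality")
_STATE_BY_CODE = {s.value: s for s in CharacterState}
_MEASUREMENT_FIELDS = tuple(
    f for f in MeasurementSet.__dataclass_fields__ if f != "age_class"
)

#: SHA-256 of the packaged fixture files, pinned at release time.
FIXTURE_SHA256 = {
    "coelodonta_c7": None,  # filled by tests/tooling via fixture_checksum()
    "extant_rhino": None,
    "table4_matrix": None,
}


def _parse_state(code: str, line_no: int, column: str, problems: list[str]):
    code = code.strip()
    if code == "":
        return CharacterState.MISSING
    state = _STATE_BY_CODE.get(code)
    if state is None:
        problems.append(
            f"line {line_no}: unknown state code {code!r} in column {column!r}"
        )
    return state


def _parse_age(raw: str) -> AgeClass:
    raw = raw.strip().lower()
    if raw in ("", "unknown", "n/a", "na", "n.a."):
        return AgeClass.UNKNOWN
    return AgeClass(raw)


def _parse_facet(raw: str, line_no: int, column: str, problems: list[str]):
    raw = raw.strip().lower()
    if raw == "":
        return None
    try:
        return FacetSize(raw)
    except ValueError:
        problems.append(
            f"line {line_no}: unknown facet size {raw!r} in column {column!r}"
        )
        return None


def read_specimen_table(path: Union[str, Path, io.TextIOBase]) -> list[VertebraRecord]:
    """Parse a specimen table; raises SpecimenTableError listing every bad line."""
    if isinstance(path, (str, Path)):
        with open(path, newline="", encoding="utf-8") as fh:
            return read_specimen_table(fh)

    reader = csv.DictReader(path)
    if reader.fieldnames is None or "specimen_id" not in reader.fieldnames:
        raise SpecimenTableError(
            ["line 1: missing header (a 'specimen_id' column is required)"]
        )
    fieldnames = list(reader.fieldnames)

    side_cols = {
        c: (c[:-5], "left") if c.endswith("_left") else (c[:-6], "right")
        for c in fieldnames
        if (c.endswith("_left") or c.endswith("_right"))
        and c.split("_")[0] in CHARACTER_IDS
        and not c.startswith("facet")
    }
    meas_cols = [c for c in fieldnames if c.startswith("m_") and c[2:] in _MEASUREMENT_FIELDS]
    known = (
        set(_BASE_COLUMNS)
        | set(CHARACTER_IDS)
        | set(side_cols)
        | set(meas_cols)
        | {"facet_left", "facet_right", "facet_position_note"}
    )
    extra_cols = [c for c in fieldnames if c not in known]

    records: list[VertebraRecord] = []
    problems: list[str] = []
    seen: set[str] = set()
    for line_no, row in enumerate(reader, start=2):
        sid = (row.get("specimen_id") or "").strip()
        if not sid:
            problems.append(f"line {line_no}: empty specimen_id")
            continue
        if sid in seen:
            problems.append(f"line {line_no}: duplicate specimen id {sid!r}")
            continue
        seen.add(sid)

        try:
            age = _parse_age(row.get("age_class") or "")
        except ValueError:
            problems.append(
                f"line {line_no}: unknown age_class {row.get('age_class')!r}"
            )
            age = AgeClass.UNKNOWN

        profile: dict = {}
        for cid in CHARACTER_IDS:
            if cid in fieldnames:
                state = _parse_state(row.get(cid) or "", line_no, cid, problems)
                if state is not None:
                    profile[cid] = state
        # Per-side columns override the single-state column for that character.
        per_side: dict[str, dict[str, CharacterState]] = {}
        for col, (cid, side) in side_cols.items():
            raw = (row.get(col) or "").strip()
            if raw == "":
                continue
            state = _parse_state(raw, line_no, col, problems)
            if state is not None:
                per_side.setdefault(cid, {})[side] = state
        for cid, sides in per_side.items():
            profile[cid] = SideStates(
                left=sides.get("left", CharacterState.MISSING),
                right=sides.get("right", CharacterState.MISSING),
            )

        measurements = None
        meas_kwargs = {}
        for col in meas_cols:
            raw = (row.get(col) or "").strip()
            if raw == "":
                continue
            try:
                meas_kwargs[col[2:]] = float(raw)
            except ValueError:
                problems.append(
                    f"line {line_no}: non-numeric measurement {raw!r} in {col!r}"
                )
        if meas_kwargs:
            measurements = MeasurementSet(age_class=age, **meas_kwargs)

        side_notes = None
        facet_l = _parse_facet(row.get("facet_left") or "", line_no, "facet_left", problems)
        facet_r = _parse_facet(row.get("facet_right") or "", line_no, "facet_right", problems)
        note = (row.get("facet_position_note") or "").strip()
        if facet_l is not None or facet_r is not None or note:
            side_notes = SideNotes(
                facet_left=facet_l, facet_right=facet_r, position_note=note
            )

        metadata = {c: row.get(c, "") for c in extra_cols if (row.get(c) or "") != ""}
        records.append(
            VertebraRecord(
                specimen_id=sid,
                taxon=(row.get("taxon") or "").strip(),
                age_class=age,
                locality=(row.get("locality") or "").strip(),
                profile=profile,
                measurements=measurements,
                side_notes=side_notes,
                metadata=metadata,
            )
        )

    if problems:
        raise SpecimenTableError(problems)
    return records


def write_specimen_table(
    records: Iterable[VertebraRecord], path: Union[str, Path, io.TextIOBase]
) -> None:
    """Write records in the schema above; read(write(x)) == x."""
    records = list(records)
    if isinstance(path, (str, Path)):
        with open(path, "w", newline="", encoding="utf-8") as fh:
            write_specimen_table(records, fh)
        return

    side_cols: list[str] = []
    meas_fields: list[str] = []
    extra_cols: list[str] = []
    has_notes = False
    for rec in records:
        for cid, entry in rec.profile.items():
            if isinstance(entry, SideStates):
                for suffix in ("_left", "_right"):
                    col = cid + suffix
                    if col not in side_cols:
                        side_cols.append(col)
        if rec.measurements is not None:
            for f in _MEASUREMENT_FIELDS:
                if getattr(rec.measurements, f) is not None and f not in meas_fields:
                    meas_fields.append(f)
        if rec.side_notes is not None:
            has_notes = True
        for key in rec.metadata:
            if key not in extra_cols:
                extra_cols.append(key)

    header = (
        list(_BASE_COLUMNS)
        + list(CHARACTER_IDS)
        + sorted(side_cols)
        + [f"m_{f}" for f in meas_fields]
        + (["facet_left", "facet_right", "facet_position_note"] if has_notes else [])
        + extra_cols
    )
    writer = csv.DictWriter(path, fieldnames=header, lineterminator="\n")
    writer.writeheader()
    for rec in records:
        row = {
            "specimen_id": rec.specimen_id,
            "taxon": rec.taxon,
            "age_class": rec.age_class.value,
            "locality": rec.locality,
        }
        for cid in CHARACTER_IDS:
            entry = rec.profile.get(cid)
            if entry is None:
                row[cid] = "?"
            elif isinstance(entry, SideStates):
                row[cid] = ""
                row[f"{cid}_left"] = entry.left.value
                row[f"{cid}_right"] = entry.right.value
            else:
                row[cid] = entry.value
        if rec.measurements is not None:
            for f in meas_fields:
                v = getattr(rec.measurements, f)
                if v is not None:
                    row[f"m_{f}"] = repr(v)
        if rec.side_notes is not None:
            row["facet_left"] = (
                rec.side_notes.facet_left.value if rec.side_notes.facet_left else ""
            )
            row["facet_right"] = (
                rec.side_notes.facet_right.value if rec.side_notes.facet_right else ""
            )
            row["facet_position_note"] = rec.side_notes.position_note
        for key, value in rec.metadata.items():
            row[key] = value
        writer.writerow(row)


def _fixture_path(name: str):
    if name not in FIXTURE_NAMES:
        raise ValueError(
            f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}"
        )
    return resources.files("ctvert").joinpath("data", f"{name}.csv")


def fixture_checksum(name: str) -> str:
    """SHA-256 hex digest of a packaged fixture file."""
    return hashlib.sha256(_fixture_path(name).read_bytes()).hexdigest()


def load_fixture(name: str) -> list[VertebraRecord]:
    """Load one of the packaged fixture datasets by name."""
    text = _fixture_path(name).read_text(encoding="utf-8")
    return read_specimen_table(io.StringIO(text))
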