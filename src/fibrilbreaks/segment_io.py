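"""Read, validate and write fibril-segment tables.

A *segment* is one boxed sub-image of a fibril, extracted at fixed spacing
along the fibril axis for helical reconstruction; after 3D classification
each segment carries a class label.  Here labels are reduced to the
conformational classes ``A``, ``B`` and ``UNASSIGNED``.

A *fibril* (helical tube) is identified by the pair
``(micrograph_id, tube_id)`` — tube IDs are conventionally numbered per
micrograph and must never be merged across micrographs.

Two on-disk dialects are supported:

* ``tsv`` — a plain tab-separated table with a header row, columns
  ``micrograph_id``, ``tube_id``, ``axial_pos``, ``class_label`` and
  optionally ``coord_x``, ``coord_y``, ``in_final``.
* ``star`` — a STAR particle table in the helical convention
  (``_rlnMicrographName``, ``_rlnHelicalTubeID``, ``_rlnClassNumber``,
  optionally ``_rlnHelicalTrackLengthAngst``/``_rlnHelicalTrackLength``,
  ``_rlnCoordinateX/Y``).  Because class numbering is specific to each
  refinement run, a ``class_map`` from class numbers to ``A``/``B`` must be
  supplied by the caller; unmapped classes become ``UNASSIGNED``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from gemmi import cif

__all__ = [
    "LABEL_A",
    "LABEL_B",
    "LABEL_UNASSIGNED",
    "SegmentRecord",
    "SegmentTable",
    "SegmentTableFormatError",
    "SegmentTableValidationError",
    "read_segment_table",
    "write_segment_table",
    "group_fibrils",
    "label_sequences",
    "parse_class_map",
]

LABEL_A = "A"
LABEL_B = "B"
LABEL_UNASSIGNED = "UNASSIGNED"
_VALID_LABELS = (LABEL_A, LABEL_B, LABEL_UNASSIGNED)

_TSV_MANDATORY = ("micrograph_id", "tube_id", "axial_pos", "class_label")
_STAR_MANDATORY = ("_rlnMicrographName", "_rlnHelicalTubeID", "_rlnClassNumber")


class SegmentTableFormatError(ValueError):
    """File does not parse under the declared dialect (e.g. missing column)."""


class SegmentTableValidationError(ValueError):
    """Parsed rows violate a table invariant (e.g. duplicate axial position)."""


@dataclass(frozen=True)
class SegmentRecord:
    """One picked fibril segment.

    ``axial_pos`` is the position along the fibril axis in Å; coordinates
    are 0-based picking coordinates in pixels and optional.  ``in_final``
    flags segments retained in the final reconstruction subset.
    """

    micrograph_id: str
    tube_id: int
    axial_pos: float
    class_label: str = LABEL_UNASSIGNED
    coord_x: float | None = None
    coord_y: float | None = None
    in_final: bool = False

    def __post_init__(self) -> None:
        if self.tube_id < 1:
            raise SegmentTableValidationError(
                f"tube_id must be a positive integer, got {self.tube_id}"
            )
        if self.axial_pos < 0 or not math.isfinite(self.axial_pos):
            raise SegmentTableValidationError(
                f"axial_pos must be a finite non-negative length, got {self.axial_pos}"
            )
        if self.class_label not in _VALID_LABELS:
            raise SegmentTableValidationError(
                f"class_label must be one of {_VALID_LABELS}, got {self.class_label!r}"
            )

    @property
    def fibril_id(self) -> tuple[str, int]:
        return (self.micrograph_id, self.tube_id)


@dataclass
class SegmentTable:
    """Ordered collection of segments with provenance metadata."""

    records: list[SegmentRecord] = field(default_factory=list)
    provenance: str = ""
    interbox_spacing: float | None = None  # declared spacing, Å

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def validate(self) -> None:
        """Check table-level invariants; raises on duplicate axial positions."""
        seen: set[tuple[str, int, float]] = set()
        for rec in self.records:
            key = (rec.micrograph_id, rec.tube_id, rec.axial_pos)
            if key in seen:
                raise SegmentTableValidationError(
                    f"duplicate axial position {rec.axial_pos} Å on fibril "
                    f"{rec.fibril_id} — axial positions must be distinct within a fibril"
                )
            seen.add(key)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "micrograph_id": [r.micrograph_id for r in self.records],
                "tube_id": [r.tube_id for r in self.records],
                "axial_pos": [r.axial_pos for r in self.records],
                "class_label": [r.class_label for r in self.records],
                "coord_x": [r.coord_x for r in self.records],
                "coord_y": [r.coord_y for r in self.records],
                "in_final": [r.in_final for r in self.records],
            }
        )


def parse_class_map(text: str) -> dict[int, str]:
    """Parse a ``"3:A,5:B"``-style class-map string into ``{3: "A", 5: "B"}``."""
    mapping: dict[int, str] = {}
    for part in text.split(","):
        part = part.strip()
        if not part:
            continue
        try:
            num, label = part.split(":")
            num_i = int(num)
        except ValueError as exc:
            raise SegmentTableFormatError(
                f"bad class-map entry {part!r}; expected NUMBER:LABEL"
            ) from exc
        label = label.strip().upper()
        if label not in (LABEL_A, LABEL_B):
            raise SegmentTableFormatError(
                f"class-map labels must be A or B, got {label!r}"
            )
        mapping[num_i] = label
    return mapping


def _normalize_label(raw: str) -> str:
    up = str(raw).strip().upper()
    return up if up in (LABEL_A, LABEL_B) else LABEL_UNASSIGNED


def _parse_bool(raw) -> bool:
    return str(raw).strip().lower() in ("1", "true", "t", "yes")


def read_segment_table(
    path: str | Path,
    dialect: str = "tsv",
    *,
    class_map: Mapping[int, str] | None = None,
    interbox_spacing: float | None = None,
) -> SegmentTable:
    """Read a segment table from ``path`` under the given dialect.

    Parameters
    ----------
    dialect : str
        ``"tsv"`` or ``"star"``.
    class_map : mapping, optional
        For the STAR dialect: class number → ``"A"``/``"B"``.  Unmapped
        class numbers become ``UNASSIGNED``.
    interbox_spacing : float, optional
        Declared spacing (Å).  For STAR files lacking a track-length
        column, axial positions are synthesized as extraction order ×
        spacing per fibril.

    Raises
    ------
    SegmentTableFormatError
        Missing mandatory column, or unknown dialect.
    SegmentTableValidationError
        Duplicate (fibril, axial position) pair.
    """
    path = Path(path)
    if dialect == "tsv":
        table = _read_tsv(path)
    elif dialect == "star":
        table = _read_star(path, class_map or {}, interbox_spacing)
    else:
        raise SegmentTableFormatError(f"unknown dialect {dialect!r}")
    table.interbox_spacing = interbox_spacing or table.interbox_spacing
    table.validate()
    return table


def _read_tsv(path: Path) -> SegmentTable:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise SegmentTableFormatError(f"{path}: empty file, no header row") from exc
    for col in _TSV_MANDATORY:
        if col not in df.columns:
            raise SegmentTableFormatError(f"{path}: missing mandatory column {col!r}")
    records = []
    for row in df.itertuples(index=False):
        coord_x = getattr(row, "coord_x", "")
        coord_y = getattr(row, "coord_y", "")
        records.append(
            SegmentRecord(
                micrograph_id=str(row.micrograph_id),
                tube_id=int(row.tube_id),
                axial_pos=float(row.axial_pos),
                class_label=_normalize_label(row.class_label),
                coord_x=float(coord_x) if coord_x not in ("", ".") else None,
                coord_y=float(coord_y) if coord_y not in ("", ".") else None,
                in_final=_parse_bool(getattr(row, "in_final", "false")),
            )
        )
    return SegmentTable(records=records, provenance=str(path))


_STAR_TRACK_TAGS = ("_rlnHelicalTrackLengthAngst", "_rlnHelicalTrackLength")
_STAR_IN_FINAL_TAG = "_fibrilbreaksInFinal"


def _read_star(
    path: Path, class_map: Mapping[int, str], interbox_spacing: float | None
) -> SegmentTable:
    doc = cif.read_file(str(path))
    block = None
    for blk in doc:
        if blk.find_loop(_STAR_MANDATORY[0]):
            block = blk
            break
    if block is None:
        # a zero-row table serializes as a bare data block (gemmi drops
        # empty loops); only complain if the file actually carries loop data
        has_any_loop = any(
            item.loop is not None for blk in doc for item in blk
        )
        if not has_any_loop:
            return SegmentTable(records=[], provenance=str(path))
        raise SegmentTableFormatError(
            f"{path}: no block with mandatory column {_STAR_MANDATORY[0]!r}"
        )
    cols: dict[str, list[str]] = {}
    for tag in _STAR_MANDATORY:
        vals = list(block.find_loop(tag))
        if not vals and tag != _STAR_MANDATORY[0]:
            raise SegmentTableFormatError(f"{path}: missing mandatory column {tag!r}")
        cols[tag] = vals
    n = len(cols[_STAR_MANDATORY[0]])

    def optional(tag: str) -> list[str] | None:
        vals = list(block.find_loop(tag))
        return vals if len(vals) == n else None

    track = None
    for tag in _STAR_TRACK_TAGS:
        track = optional(tag)
        if track is not None:
            break
    xs, ys = optional("_rlnCoordinateX"), optional("_rlnCoordinateY")
    finals = optional(_STAR_IN_FINAL_TAG)

    if track is None:
        if interbox_spacing is None:
            raise SegmentTableFormatError(
                f"{path}: no helical track-length column; supply interbox_spacing "
                "to synthesize axial positions from extraction order"
            )
        counters: dict[tuple[str, int], int] = {}

    records = []
    for i in range(n):
        mic = cif.as_string(cols["_rlnMicrographName"][i])
        tube = int(float(cols["_rlnHelicalTubeID"][i]))
        cls = int(float(cols["_rlnClassNumber"][i]))
        if track is not None:
            axial = float(track[i])
        else:
            key = (mic, tube)
            axial = counters.get(key, 0) * interbox_spacing
            counters[key] = counters.get(key, 0) + 1
        records.append(
            SegmentRecord(
                micrograph_id=mic,
                tube_id=tube,
                axial_pos=axial,
                class_label=class_map.get(cls, LABEL_UNASSIGNED),
                coord_x=float(xs[i]) if xs is not None and xs[i] not in (".", "?") else None,
                coord_y=float(ys[i]) if ys is not None and ys[i] not in (".", "?") else None,
                in_final=_parse_bool(finals[i]) if finals is not None else False,
            )
        )
    return SegmentTable(records=records, provenance=str(path))


def write_segment_table(
    table: SegmentTable,
    path: str | Path,
    dialect: str = "tsv",
    *,
    class_map: Mapping[int, str] | None = None,
) -> None:
    """Write ``table`` to ``path``; ``read_segment_table`` inverts this.

    For the STAR dialect, labels are written as class numbers through the
    inverse of ``class_map`` (default ``{1: "A", 2: "B"}``); ``UNASSIGNED``
    is written as class 0.
    """
    table.validate()
    path = Path(path)
    if dialect == "tsv":
        _write_tsv(table, path)
    elif dialect == "star":
        _write_star(table, path, class_map or {1: LABEL_A, 2: LABEL_B})
    else:
        raise SegmentTableFormatError(f"unknown dialect {dialect!r}")


def _write_tsv(table: SegmentTable, path: Path) -> None:
    df = table.to_dataframe()
    df["coord_x"] = df["coord_x"].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    df["coord_y"] = df["coord_y"].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    df["axial_pos"] = df["axial_pos"].map(lambda v: repr(float(v)))
    df["in_final"] = df["in_final"].map(lambda v: "true" if v else "false")
    df.to_csv(path, sep="\t", index=False)


def _write_star(table: SegmentTable, path: Path, class_map: Mapping[int, str]) -> None:
    inverse = {label: num for num, label in class_map.items()}
    if LABEL_A not in inverse or LABEL_B not in inverse:
        raise SegmentTableFormatError("class_map must cover both labels A and B")
    doc = cif.Document()
    block = doc.add_new_block("particles")
    loop = block.init_loop(
        "",
        [
            "_rlnMicrographName",
            "_rlnHelicalTubeID",
            "_rlnHelicalTrackLengthAngst",
            "_rlnCoordinateX",
            "_rlnCoordinateY",
            "_rlnClassNumber",
            _STAR_IN_FINAL_TAG,
        ],
    )
    for rec in table.records:
        loop.add_row(
            [
                cif.quote(rec.micrograph_id),
                str(rec.tube_id),
                repr(float(rec.axial_pos)),
                "." if rec.coord_x is None else repr(float(rec.coord_x)),
                "." if rec.coord_y is None else repr(float(rec.coord_y)),
                str(inverse.get(rec.class_label, 0)),
                "1" if rec.in_final else "0",
            ]
        )
    doc.write_file(str(path))


def group_fibrils(table: SegmentTable) -> dict[tuple[str, int], list[SegmentRecord]]:
    """Group segments into fibrils, each sorted by axial position.

    Returns one entry per distinct ``(micrograph_id, tube_id)`` pair.  The
    result is invariant under permutation of the input rows; keys are sorted
    for reproducible iteration order.
    """
    groups: dict[tuple[str, int], list[SegmentRecord]] = {}
    for rec in table.records:
        groups.setdefault(rec.fibril_id, []).append(rec)
    return {
        fid: sorted(groups[fid], key=lambda r: r.axial_pos)
        for fid in sorted(groups)
    }


def label_sequences(table: SegmentTable) -> dict[tuple[str, int], list[str]]:
    """Axially ordered class-label sequence per fibril."""
    return {
        fid: [rec.class_label for rec in recs]
        for fid, recs in group_fibrils(table).items()
    }
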