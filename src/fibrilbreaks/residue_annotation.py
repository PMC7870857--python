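"""Residue-span annotation of the fibril protein and mutation classification.

The amyloid fibril protein studied here is a 115-residue fragment
(Ser2–Ser116, precursor light-chain numbering) of a λ3 immunoglobulin
light chain.  Within the fibril it folds into two structurally ordered
segments linked by an internal disordered region whose extent differs
between the two coexisting conformations A and B; the N- and C-termini are
disordered in both.  This module provides the interval algebra over those
spans: position classification (ordered core / disordered /
cleaved-or-absent), comparison of two annotations, and classification of
the somatic mutations relative to the germline sequence.

All residue numbering is 1-based inclusive and positional; amino-acid
names attached to span labels are annotations only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "REGION_ORDERED",
    "REGION_DISORDERED",
    "REGION_CLEAVED",
    "ResidueSpan",
    "StructureAnnotation",
    "MutationRecord",
    "span_length",
    "classify_position",
    "diff_annotations",
    "load_default_annotations",
    "spans_to_bed_tsv",
]

REGION_ORDERED = "ordered-core"
REGION_DISORDERED = "disordered"
REGION_CLEAVED = "cleaved-or-absent"


@dataclass(frozen=True, order=True)
class ResidueSpan:
    """Closed interval of residues, 1-based inclusive."""

    start: int
    end: int
    label: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValueError(f"start ({self.start}) must be <= end ({self.end})")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end

    def contains_span(self, other: "ResidueSpan") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "ResidueSpan") -> bool:
        return self.start <= other.end and other.start <= self.end


def span_length(span: ResidueSpan) -> int:
    """Number of residues in a closed span: ``end - start + 1``."""
    return len(span)


@dataclass(frozen=True)
class StructureAnnotation:
    """Ordered/disordered/β-strand spans for one fibril conformation.

    Invariants checked at construction: ordered and disordered spans are
    pairwise disjoint, both lie inside the fibril-protein span, and every
    β-strand lies inside some ordered span.
    """

    conformation: str
    fibril_protein_span: ResidueSpan
    ordered_spans: tuple[ResidueSpan, ...]
    disordered_spans: tuple[ResidueSpan, ...]
    strand_spans: tuple[ResidueSpan, ...]

    def __post_init__(self) -> None:
        for s in (*self.ordered_spans, *self.disordered_spans):
            if not self.fibril_protein_span.contains_span(s):
                raise ValueError(
                    f"span {s.start}-{s.end} ({s.label!r}) outside fibril protein "
                    f"{self.fibril_protein_span.start}-{self.fibril_protein_span.end}"
                )
        spans = [*self.ordered_spans, *self.disordered_spans]
        for i, a in enumerate(spans):
            for b in spans[i + 1:]:
                if a.overlaps(b):
                    raise ValueError(
                        f"overlapping spans {a.start}-{a.end} and {b.start}-{b.end}"
                    )
        for strand in self.strand_spans:
            if not any(o.contains_span(strand) for o in self.ordered_spans):
                raise ValueError(
                    f"strand {strand.label!r} ({strand.start}-{strand.end}) not "
                    "inside any ordered span"
                )


@dataclass(frozen=True)
class MutationRecord:
    """One germline→patient mutation with derived structural-region labels."""

    position: int
    from_aa: str
    to_aa: str
    germline_segment: str
    region_A: str
    region_B: str

    @property
    def name(self) -> str:
        return f"{self.from_aa}{self.position}{self.to_aa}"


def classify_position(position: int, annotation: StructureAnnotation) -> str:
    """Structural region of a residue position under one annotation.

    Returns ``cleaved-or-absent`` for positions outside the fibril-protein
    span (N-terminal residue 1 and everything beyond the C-terminal
    truncation), ``ordered-core`` inside any ordered span, else
    ``disordered``.
    """
    if position < 1:
        raise ValueError(f"position must be >= 1, got {position}")
    if position not in annotation.fibril_protein_span:
        return REGION_CLEAVED
    if any(position in s for s in annotation.ordered_spans):
        return REGION_ORDERED
    return REGION_DISORDERED


def _runs_to_spans(positions: Sequence[int]) -> list[ResidueSpan]:
    """Merge a sorted list of residue positions into maximal intervals."""
    spans: list[ResidueSpan] = []
    for p in positions:
        if spans and p == spans[-1].end + 1:
            spans[-1] = ResidueSpan(spans[-1].start, p)
        else:
            spans.append(ResidueSpan(p, p))
    return spans


def diff_annotations(
    a: StructureAnnotation, b: StructureAnnotation
) -> list[ResidueSpan]:
    """Minimal residue intervals where two annotations disagree.

    A residue differs when its ordered/disordered status differs or when
    the set of named spans (strands) covering it differs.  The comparison
    is per-residue and therefore symmetric; adjacent differing residues are
    merged into maximal intervals.
    """
    if a.fibril_protein_span != b.fibril_protein_span:
        raise ValueError(
            "annotations cover different fibril-protein spans: "
            f"{a.fibril_protein_span} vs {b.fibril_protein_span}"
        )
    fp = a.fibril_protein_span

    def profile(ann: StructureAnnotation, pos: int) -> tuple:
        strands = frozenset(
            s.label for s in ann.strand_spans if pos in s
        )
        return (classify_position(pos, ann), strands)

    differing = [
        pos
        for pos in range(fp.start, fp.end + 1)
        if profile(a, pos) != profile(b, pos)
    ]
    return _runs_to_spans(differing)


def _load_raw(path: str | Path | None = None) -> dict:
    if path is not None:
        return json.loads(Path(path).read_text())
    ref = resources.files("fibrilbreaks.data").joinpath("annotations.json")
    return json.loads(ref.read_text())


def _spans(entries: Iterable[dict]) -> tuple[ResidueSpan, ...]:
    return tuple(ResidueSpan(e["start"], e["end"], e.get("label", "")) for e in entries)


def load_default_annotations(
    path: str | Path | None = None,
) -> tuple[StructureAnnotation, StructureAnnotation, list[MutationRecord]]:
    """Built-in annotations for conformations A and B, plus the mutation list.

    Conformation A carries two extra short strands (between the sixth and
    seventh shared strands) in a segment that is disordered in B, so A has
    14 strands and B has 12.  The seven germline→patient mutations get
    their structural-region labels derived, per conformation, from
    :func:`classify_position`.  Invariants are validated at load.
    """
    raw = _load_raw(path)
    fp = raw["fibril_protein_span"]
    fp_span = ResidueSpan(fp["start"], fp["end"], fp.get("label", ""))

    annotations = {}
    for conf in ("A", "B"):
        c = raw["conformations"][conf]
        annotations[conf] = StructureAnnotation(
            conformation=conf,
            fibril_protein_span=fp_span,
            ordered_spans=_spans(c["ordered_spans"]),
            disordered_spans=_spans(c["disordered_spans"]),
            strand_spans=_spans(c["strand_spans"]),
        )

    mutations = [
        MutationRecord(
            position=m["position"],
            from_aa=m["from_aa"],
            to_aa=m["to_aa"],
            germline_segment=m["germline_segment"],
            region_A=classify_position(m["position"], annotations["A"]),
            region_B=classify_position(m["position"], annotations["B"]),
        )
        for m in raw["mutations"]
    ]
    return annotations["A"], annotations["B"], mutations


def spans_to_bed_tsv(spans: Iterable[ResidueSpan]) -> str:
    """Render spans as a BED-like TSV (1-based inclusive, as documented).

    Columns: start, end, length, label.  Note this deviates from genomic
    BED's 0-based half-open convention; residue annotations in this field
    are conventionally 1-based inclusive.
    """
    lines = ["start\tend\tlength\tlabel"]
    for s in spans:
        lines.append(f"{s.start}\t{s.end}\t{len(s)}\t{s.label}")
    return "\n".join(lines) + "\n"
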