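"""Four-predictor consensus aggregation score.

Sequence-based aggregation predictors (TANGO, FoldAmyloid, Aggrescan,
PASTA 2.0) each emit one numeric value per residue, on incomparable
scales.  The consensus score reduces them to a common 0–4 integer per
residue: the number of predictors that flag the residue as
aggregation-prone under each program's published hit rule:

* TANGO — per-residue β-aggregation percentage above 5;
* FoldAmyloid ("triple hybrid" scale) — the residue belongs to a run of
  at least five consecutive residues each scoring above 21.4;
* PASTA 2.0 — per-residue energy below −2.8 PASTA Energy Units
  (lower = more aggregation-prone);
* Aggrescan — per-residue value above −0.02.

All threshold comparisons are strict: a residue exactly at a cutoff is
not a hit.  The predictors themselves are not reimplemented here; tracks
arrive as per-residue numeric arrays or as two-column TSV files
(``position``, ``value``; header required; positions contiguous from 1).
PASTA natively scores residue pairings — the per-residue energy track
consumed here is assumed to have been projected upstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .residue_annotation import ResidueSpan

__all__ = [
    "TANGO_CUTOFF",
    "FOLDAMYLOID_CUTOFF",
    "FOLDAMYLOID_MIN_RUN",
    "PASTA_CUTOFF",
    "AGGRESCAN_CUTOFF",
    "AggregationTracks",
    "tango_hits",
    "foldamyloid_hits",
    "pasta_hits",
    "aggrescan_hits",
    "consensus_score",
    "max_scoring_window",
    "read_track",
]

TANGO_CUTOFF = 5.0        # percent
FOLDAMYLOID_CUTOFF = 21.4  # triple-hybrid scale units
FOLDAMYLOID_MIN_RUN = 5    # consecutive residues
PASTA_CUTOFF = -2.8        # PASTA Energy Units
AGGRESCAN_CUTOFF = -0.02


def _as_track(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} track must be one-dimensional")
    if arr.size and not np.isfinite(arr).all():
        raise ValueError(f"{name} track contains non-finite values")
    return arr


def tango_hits(track: Sequence[float]) -> np.ndarray:
    """Residues whose TANGO β-aggregation percentage exceeds 5 (strict)."""
    return _as_track(track, "tango") > TANGO_CUTOFF


def foldamyloid_hits(track: Sequence[float]) -> np.ndarray:
    """Residues inside a run of ≥5 consecutive values above 21.4.

    FoldAmyloid's rule is window-based: isolated high scores do not count;
    only residues belonging to some run of at least five consecutive
    above-threshold residues are hits (all residues of the run are hits).
    """
    arr = _as_track(track, "foldamyloid")
    above = arr > FOLDAMYLOID_CUTOFF
    hits = np.zeros(arr.size, dtype=bool)
    run_start = None
    for i, flag in enumerate(above):
        if flag and run_start is None:
            run_start = i
        if (not flag or i == arr.size - 1) and run_start is not None:
            run_end = i + 1 if flag else i  # exclusive
            if run_end - run_start >= FOLDAMYLOID_MIN_RUN:
                hits[run_start:run_end] = True
            run_start = None
    return hits


def pasta_hits(track: Sequence[float]) -> np.ndarray:
    """Residues whose PASTA energy falls below −2.8 PEU (strict)."""
    return _as_track(track, "pasta") < PASTA_CUTOFF


def aggrescan_hits(track: Sequence[float]) -> np.ndarray:
    """Residues whose Aggrescan value exceeds −0.02 (strict)."""
    return _as_track(track, "aggrescan") > AGGRESCAN_CUTOFF


@dataclass(frozen=True)
class AggregationTracks:
    """Aligned per-residue tracks from the four predictors.

    Residue ``i`` (1-based) corresponds to index ``i - 1`` of every array.
    """

    tango: np.ndarray
    foldamyloid: np.ndarray
    pasta: np.ndarray
    aggrescan: np.ndarray

    def __post_init__(self) -> None:
        lengths = {
            "tango": len(self.tango),
            "foldamyloid": len(self.foldamyloid),
            "pasta": len(self.pasta),
            "aggrescan": len(self.aggrescan),
        }
        if len(set(lengths.values())) != 1:
            raise ValueError(f"track lengths differ: {lengths}")

    @property
    def sequence_length(self) -> int:
        return len(self.tango)

    @property
    def consensus(self) -> np.ndarray:
        return consensus_score(self)

    @classmethod
    def from_tsvs(cls, tango: str | Path, foldamyloid: str | Path,
                  pasta: str | Path, aggrescan: str | Path) -> "AggregationTracks":
        return cls(
            tango=read_track(tango),
            foldamyloid=read_track(foldamyloid),
            pasta=read_track(pasta),
            aggrescan=read_track(aggrescan),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(1, self.sequence_length + 1),
                "tango_hit": tango_hits(self.tango).astype(int),
                "foldamyloid_hit": foldamyloid_hits(self.foldamyloid).astype(int),
                "pasta_hit": pasta_hits(self.pasta).astype(int),
                "aggrescan_hit": aggrescan_hits(self.aggrescan).astype(int),
                "consensus": self.consensus,
            }
        )


def consensus_score(tracks: AggregationTracks) -> np.ndarray:
    """Per-residue count of predictors flagging the residue, 0–4."""
    return (
        tango_hits(tracks.tango).astype(np.int8)
        + foldamyloid_hits(tracks.foldamyloid).astype(np.int8)
        + pasta_hits(tracks.pasta).astype(np.int8)
        + aggrescan_hits(tracks.aggrescan).astype(np.int8)
    )


def max_scoring_window(
    consensus: Sequence[int], restrict: ResidueSpan | None = None
) -> ResidueSpan | None:
    """Contiguous region of residues at the maximum consensus score.

    Among maximal runs of residues whose score equals the track's maximum
    (within ``restrict``, if given), returns the longest; ties break to
    the lowest start position.  Returns ``None`` when the maximum is zero
    (no predictor flags anything).
    """
    arr = np.asarray(consensus, dtype=int)
    if arr.size == 0:
        raise ValueError("consensus track is empty")
    lo, hi = 1, arr.size
    if restrict is not None:
        lo, hi = max(lo, restrict.start), min(hi, restrict.end)
        if lo > hi:
            raise ValueError(f"restriction {restrict.start}-{restrict.end} "
                             "does not overlap the track")
    window = arr[lo - 1:hi]
    peak = int(window.max())
    if peak == 0:
        return None
    best: tuple[int, int] | None = None  # (length, -start) maximization
    run_start = None
    at_peak = window == peak
    for i, flag in enumerate(at_peak):
        if flag and run_start is None:
            run_start = i
        if run_start is not None and (not flag or i == window.size - 1):
            run_end = i + 1 if flag else i
            length = run_end - run_start
            if best is None or length > best[0]:
                best = (length, run_start)
            run_start = None
    assert best is not None
    start = lo + best[1]
    return ResidueSpan(start, start + best[0] - 1,
                       label=f"max consensus score {peak}")


def read_track(path: str | Path) -> np.ndarray:
    """Read a per-residue track TSV (columns ``position``, ``value``).

    Positions must be contiguous from 1; the returned array is indexed by
    position − 1.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("position", "value"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")
    positions = df["position"].to_numpy()
    expected = np.arange(1, len(df) + 1)
    if not np.array_equal(positions, expected):
        raise ValueError(f"{path}: positions must be contiguous from 1")
    return df["value"].to_numpy(dtype=float)
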