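"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from fibrilbreaks import SegmentRecord, SegmentTable


def brute_force_runs(labels) -> list[tuple[str, int]]:
    """Single-pass run counter over the classified (A/B) subsequence.

    Deliberately naive: filter, then group consecutive equal labels.
    """
    filtered = [l for l in labels if l in ("A", "B")]
    return [(lab, len(list(grp))) for lab, grp in itertools.groupby(filtered)]


def brute_force_switches(labels) -> int:
    return max(len(brute_force_runs(labels)) - 1, 0)


def exhaustive_clustering_p(labels) -> float:
    """Exact one-sided p for a single fibril by enumerating all label
    placements with the same A/B composition (uniform null)."""
    filtered = [l for l in labels if l in ("A", "B")]
    n = len(filtered)
    k = sum(1 for l in filtered if l == "B")
    observed = brute_force_switches(filtered)
    n_le = 0
    total = 0
    for b_positions in itertools.combinations(range(n), k):
        seq = ["B" if i in b_positions else "A" for i in range(n)]
        total += 1
        if brute_force_switches(seq) <= observed:
            n_le += 1
    return n_le / total


def make_table(sequences: dict, interbox: float = 33.6) -> SegmentTable:
    """Build a SegmentTable from {(mic, tube): [labels]} on a regular grid."""
    records = []
    for (mic, tube), labels in sequences.items():
        for i, lab in enumerate(labels):
            records.append(
                SegmentRecord(
                    micrograph_id=mic,
                    tube_id=tube,
                    axial_pos=i * interbox,
                    class_label=lab,
                )
            )
    return SegmentTable(records=records, interbox_spacing=interbox)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    return make_table(
        {
            ("mic1.mrc", 1): ["A", "A", "A", "B", "B"],
            ("mic1.mrc", 2): ["A", "UNASSIGNED", "B"],
            ("mic2.mrc", 1): ["B", "B"],
        }
    )
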