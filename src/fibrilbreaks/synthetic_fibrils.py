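"""Synthetic segment tables with persistent two-state conformational regions.

The generator emulates the statistical structure observed in segment-level
classification of patient-derived amyloid fibrils: each fibril's true
conformation sequence follows a persistent two-state (A/B) Markov chain
along the fibril axis, the observed class label flips with a small
misclassification probability, and a fraction of segments may be left
unclassified.  Per-fibril B-fractions then span the whole range from 0 to
1 — with mass at both endpoints and in between — and same-conformation
segments cluster into axially contiguous runs.

A symmetric two-state chain is the minimal model consistent with both
proposed break-formation mechanisms (imperfect templating during growth,
or post-assembly conversion of initially disordered segments): the two are
indistinguishable at the level of a label sequence.  This is a modeling
choice of this package, not a claim about mechanism.

Defaults emulate the scale of a typical segment-classification dataset:
fibril lengths geometric with mean 9 segments (about 10^5 segments over
about 10^4 fibrils gives ~9 segments per fibril), switch probability 0.02
per inter-segment step, initial B-probability 0.36 (the overall fraction
of B-classified segments in such datasets), misclassification 0.02, and
inter-box spacing 33.6 Å.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .helical_geometry import axial_positions
from .segment_io import (
    LABEL_A,
    LABEL_B,
    LABEL_UNASSIGNED,
    SegmentRecord,
    SegmentTable,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SwitchRateEstimate",
    "generate",
    "estimate_switch_rate",
]

FIBRILS_PER_MICROGRAPH = 25  # fibrils share micrographs so tube IDs repeat


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the two-state fibril generator.

    ``length_distribution`` is one of ``("fixed", n)``,
    ``("geometric", mean)`` (support starting at 1) or
    ``("empirical", [n1, n2, ...])`` (lengths sampled uniformly with
    replacement from the list).
    """

    n_fibrils: int = 500
    length_distribution: tuple = ("geometric", 9.0)
    p_switch: float = 0.02
    p_B_init: float = 0.36
    epsilon: float = 0.02
    p_unassigned: float = 0.0
    interbox: float = 33.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fibrils < 1:
            raise ValueError(f"n_fibrils must be >= 1, got {self.n_fibrils}")
        for name in ("p_switch", "p_B_init", "epsilon", "p_unassigned"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        if self.interbox <= 0:
            raise ValueError(f"interbox must be positive, got {self.interbox}")
        kind = self.length_distribution[0]
        if kind not in ("fixed", "geometric", "empirical"):
            raise ValueError(f"unknown length distribution kind {kind!r}")


@dataclass
class GroundTruth:
    """True (noise-free) conformations emitted alongside a synthetic table."""

    true_labels: dict[tuple[str, int], list[str]]
    true_switches: dict[tuple[str, int], int]
    config: SyntheticConfig

    @property
    def total_switches(self) -> int:
        return sum(self.true_switches.values())


def _draw_lengths(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    kind, arg = config.length_distribution[0], config.length_distribution[1]
    n = config.n_fibrils
    if kind == "fixed":
        if int(arg) < 1:
            raise ValueError("fixed length must be >= 1")
        return np.full(n, int(arg))
    if kind == "geometric":
        if arg < 1:
            raise ValueError("geometric mean length must be >= 1")
        return rng.geometric(1.0 / float(arg), size=n)
    lengths = np.asarray(arg, dtype=int)
    if lengths.size == 0 or (lengths < 1).any():
        raise ValueError("empirical lengths must be a non-empty list of positives")
    return rng.choice(lengths, size=n, replace=True)


def generate(config: SyntheticConfig) -> tuple[SegmentTable, GroundTruth]:
    """Generate a synthetic segment table and its ground truth.

    Per fibril: the true label sequence starts in B with probability
    ``p_B_init`` and switches state at each step with probability
    ``p_switch``; the observed label differs from the truth with
    probability ``epsilon`` (symmetric flip); independently, each segment
    is reported ``UNASSIGNED`` with probability ``p_unassigned``.  Axial
    positions are the regular extraction grid ``0, interbox, 2*interbox,
    ...``.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    lengths = _draw_lengths(config, rng)

    records: list[SegmentRecord] = []
    true_labels: dict[tuple[str, int], list[str]] = {}
    true_switches: dict[tuple[str, int], int] = {}

    n_micrographs = -(-config.n_fibrils // FIBRILS_PER_MICROGRAPH)
    width = max(4, len(str(n_micrographs)))
    for i, n_seg in enumerate(lengths):
        mic = f"synthetic_{i // FIBRILS_PER_MICROGRAPH + 1:0{width}d}.mrc"
        tube = i % FIBRILS_PER_MICROGRAPH + 1
        fid = (mic, tube)

        # two-state chain: cumulative XOR of i.i.d. switch indicators
        switches = rng.random(n_seg - 1) < config.p_switch if n_seg > 1 else np.empty(0, bool)
        state0 = rng.random() < config.p_B_init
        states = np.concatenate([[state0], switches]).astype(np.int8)
        states = np.bitwise_xor.accumulate(states)

        flips = rng.random(n_seg) < config.epsilon
        observed = np.bitwise_xor(states, flips.astype(np.int8))
        unassigned = rng.random(n_seg) < config.p_unassigned

        truth = [LABEL_B if s else LABEL_A for s in states]
        true_labels[fid] = truth
        true_switches[fid] = int(np.count_nonzero(np.diff(states)))

        pos = axial_positions(int(n_seg), config.interbox)
        for j in range(int(n_seg)):
            label = LABEL_UNASSIGNED if unassigned[j] else (
                LABEL_B if observed[j] else LABEL_A
            )
            records.append(
                SegmentRecord(
                    micrograph_id=mic,
                    tube_id=tube,
                    axial_pos=float(pos[j]),
                    class_label=label,
                )
            )

    table = SegmentTable(
        records=records,
        provenance=f"synthetic two-state generator, seed={config.seed}",
        interbox_spacing=config.interbox,
    )
    return table, GroundTruth(true_labels=true_labels, true_switches=true_switches,
                              config=config)


@dataclass(frozen=True)
class SwitchRateEstimate:
    """Pooled maximum-likelihood switch-rate estimate with binomial SE."""

    p_hat: float
    se: float
    n_switches: int
    n_pairs: int


def estimate_switch_rate(table: SegmentTable) -> SwitchRateEstimate:
    """Estimate the per-step switch probability from observed labels.

    Treats every adjacent pair of classified segments within a fibril as an
    independent Bernoulli trial (switch / no switch); the MLE is the pooled
    ratio ``total switches / total adjacent pairs``, with the usual
    binomial standard error ``sqrt(p(1-p)/n)``.  Note the estimator sees
    *observed* labels: classification noise inflates it (each flip creates
    about two spurious switches), so it is an estimate of the observed
    switch rate, unbiased for the true rate only when noise is negligible.

    Raises
    ------
    InsufficientDataError
        If no fibril contributes an adjacent classified pair.
    """
    from .break_analysis import InsufficientDataError, _labeled_binary

    n_switches = 0
    n_pairs = 0
    from .segment_io import group_fibrils

    for _, recs in group_fibrils(table).items():
        arr = _labeled_binary([r.class_label for r in recs])
        if arr.size >= 2:
            n_pairs += arr.size - 1
            n_switches += int(np.count_nonzero(np.diff(arr)))
    if n_pairs == 0:
        raise InsufficientDataError("no adjacent classified segment pairs")
    p_hat = n_switches / n_pairs
    se = float(np.sqrt(p_hat * (1.0 - p_hat) / n_pairs))
    return SwitchRateEstimate(p_hat=p_hat, se=se, n_switches=n_switches, n_pairs=n_pairs)
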