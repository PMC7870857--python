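"""Helical lattice bookkeeping for fibril reconstructions.

A C1 amyloid fibril is a one-start helix: consecutive subunits are related
by a rotation (*twist*, degrees) and an axial translation (*rise*, Å).  The
*pitch* is the axial distance over which the lattice completes a full 360°
turn, ``pitch = (360 / twist) * rise``.  In projection a C1 helix repeats
every half turn, so the apparent *crossover* spacing seen on micrographs is
half the pitch.

Twist is stored as a magnitude together with an explicit handedness flag;
every quantity computed here is independent of handedness, which for many
fibril reconstructions is an assumption rather than a measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HelicalParams",
    "ExtractionGeometry",
    "pitch_from_twist_rise",
    "crossover_from_pitch",
    "interbox_percentage",
    "axial_positions",
]


def pitch_from_twist_rise(twist: float, rise: float) -> float:
    """Axial length of one full helical turn, in Å.

    Parameters
    ----------
    twist : float
        Rotation between consecutive subunits, degrees (magnitude, > 0).
    rise : float
        Axial translation between consecutive subunits, Å (> 0).
    """
    if not twist > 0:
        raise ValueError(f"twist must be positive, got {twist}")
    if not rise > 0:
        raise ValueError(f"rise must be positive, got {rise}")
    return (360.0 / twist) * rise


def crossover_from_pitch(pitch: float) -> float:
    """Apparent repeat of a C1 helix in projection: half the pitch, in Å."""
    if not pitch > 0:
        raise ValueError(f"pitch must be positive, got {pitch}")
    return pitch / 2.0


def interbox_percentage(interbox: float, box: float) -> float:
    """Inter-box distance as a percentage of the box size.

    Segments for helical reconstruction are extracted as overlapping boxes
    spaced ``interbox`` Å apart along the fibril axis; the spacing expressed
    as a percentage of the box edge is the conventional way to report the
    overlap.  Requires ``0 < interbox <= box``.
    """
    if not interbox > 0:
        raise ValueError(f"interbox must be positive, got {interbox}")
    if not box > 0:
        raise ValueError(f"box must be positive, got {box}")
    if interbox > box:
        raise ValueError(
            f"interbox ({interbox} Å) cannot exceed box size ({box} Å)"
        )
    return 100.0 * interbox / box


def axial_positions(n_segments: int, interbox: float) -> np.ndarray:
    """Axial coordinates (Å) of ``n_segments`` boxes spaced ``interbox`` apart.

    Returns the arithmetic sequence ``0, interbox, ..., (n-1) * interbox``.
    """
    if n_segments < 0:
        raise ValueError(f"n_segments must be >= 0, got {n_segments}")
    if not interbox > 0:
        raise ValueError(f"interbox must be positive, got {interbox}")
    return np.arange(n_segments, dtype=float) * interbox


@dataclass(frozen=True)
class HelicalParams:
    """Twist/rise pair with derived pitch and crossover.

    Attributes
    ----------
    twist : float
        Degrees per subunit, stored as a magnitude.
    rise : float
        Å per subunit.
    handedness : str
        ``"left"`` or ``"right"``.  Only recorded; no derived quantity
        depends on it.
    """

    twist: float
    rise: float
    handedness: str = "left"

    def __post_init__(self) -> None:
        if self.handedness not in ("left", "right"):
            raise ValueError(f"handedness must be 'left' or 'right', got {self.handedness!r}")
        # validates positivity as a side effect
        pitch_from_twist_rise(self.twist, self.rise)

    @property
    def pitch(self) -> float:
        return pitch_from_twist_rise(self.twist, self.rise)

    @property
    def crossover(self) -> float:
        return crossover_from_pitch(self.pitch)

    @property
    def pitch_nm(self) -> float:
        """Pitch in nm, rounded to the nearest nm (reporting convention)."""
        return round(self.pitch / 10.0)

    def to_dict(self) -> dict:
        return {
            "twist_deg": self.twist,
            "rise_A": self.rise,
            "handedness": self.handedness,
            "pitch_A": self.pitch,
            "pitch_nm": self.pitch_nm,
            "crossover_A": self.crossover,
        }


@dataclass(frozen=True)
class ExtractionGeometry:
    """Box-extraction geometry for helical segments.

    ``box_px`` and ``box_angstrom`` describe the extraction box;
    ``interbox_angstrom`` is the spacing between consecutive boxes along the
    fibril axis.  ``overlap_fraction`` is the inter-box spacing as a fraction
    of the box size, in (0, 1].
    """

    box_px: int
    box_angstrom: float
    interbox_angstrom: float

    def __post_init__(self) -> None:
        if self.box_px <= 0:
            raise ValueError(f"box_px must be positive, got {self.box_px}")
        # validates 0 < interbox <= box
        interbox_percentage(self.interbox_angstrom, self.box_angstrom)

    @property
    def overlap_fraction(self) -> float:
        return self.interbox_angstrom / self.box_angstrom

    @property
    def interbox_percent(self) -> float:
        return interbox_percentage(self.interbox_angstrom, self.box_angstrom)

    @property
    def pixel_size(self) -> float:
        """Å per pixel implied by the box sizes."""
        return self.box_angstrom / self.box_px

    def to_dict(self) -> dict:
        return {
            "box_px": self.box_px,
            "box_A": self.box_angstrom,
            "interbox_A": self.interbox_angstrom,
            "interbox_percent": self.interbox_percent,
            "interbox_percent_rounded": round(self.interbox_percent),
            "pixel_size_A": self.pixel_size,
        }
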