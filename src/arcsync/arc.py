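"""Dramatic-arc phase structure.

A six-phase narrative arc (exposition, rising action, crisis, climax,
falling action, denouement) is described by the timestamps at which each
phase starts plus the end of the stimulus.  These boundaries are used both
to synthesise engagement curves and to slice any time-indexed quantity
into per-phase segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical six phase names, in narrative order.
PHASE_NAMES = (
    "exposition",
    "rising_action",
    "crisis",
    "climax",
    "falling_action",
    "denouement",
)

#: Rater-consensus phase starting points (seconds) plus stimulus end.
DEFAULT_BOUNDARIES_S = (0.0, 151.0, 300.0, 345.0, 460.0, 482.0, 506.0)


@dataclass(frozen=True)
class ArcTemplate:
    """Piecewise-constant engagement target over the six arc phases.

    Parameters
    ----------
    phase_names : tuple of str
        Ordered phase labels.
    boundaries_s : tuple of float
        Strictly increasing timestamps: the start of each phase followed by
        the end of the stimulus.  ``len(boundaries_s) == len(phase_names)+1``
        and the first boundary must be 0.
    phase_levels : tuple of float
        Target engagement level per phase (rating-scale units).
    smoothing_s : float
        Duration of the moving-average ramp applied at phase transitions.
    """

    phase_names: tuple = PHASE_NAMES
    boundaries_s: tuple = DEFAULT_BOUNDARIES_S
    phase_levels: tuple = (3.0, 5.0, 6.5, 9.0, 4.0, 2.0)
    smoothing_s: float = 10.0

    def __post_init__(self):
        b = np.asarray(self.boundaries_s, float)
        if b.ndim != 1 or len(b) != len(self.phase_names) + 1:
            raise ValueError("need one boundary per phase start plus the stimulus end")
        if b[0] != 0:
            raise ValueError("first boundary must be 0")
        if not np.all(np.diff(b) > 0):
            raise ValueError("boundaries must be strictly increasing")
        if len(self.phase_levels) != len(self.phase_names):
            raise ValueError("one level per phase required")
        if self.smoothing_s < 0:
            raise ValueError("smoothing_s must be >= 0")

    @property
    def duration_s(self) -> float:
        return float(self.boundaries_s[-1])

    @property
    def durations_s(self) -> np.ndarray:
        """Per-phase durations in seconds."""
        return np.diff(np.asarray(self.boundaries_s, float))

    def segmentation(self) -> "PhaseSegmentation":
        return PhaseSegmentation(
            names=tuple(self.phase_names),
            starts_s=tuple(self.boundaries_s[:-1]),
            end_s=self.duration_s,
        )


@dataclass(frozen=True)
class PhaseSegmentation:
    """Ordered phase boundaries used to slice time-indexed arrays."""

    names: tuple
    starts_s: tuple
    end_s: float

    def __post_init__(self):
        s = np.asarray(self.starts_s, float)
        if len(s) != len(self.names):
            raise ValueError("one start per phase")
        if s[0] != 0:
            raise ValueError("first phase must start at 0")
        if not np.all(np.diff(np.r_[s, self.end_s]) > 0):
            raise ValueError("starts must be strictly increasing and end after last start")

    def slices(self, times_s: np.ndarray) -> dict:
        """Map phase name -> boolean mask over ``times_s`` (seconds)."""
        t = np.asarray(times_s, float)
        edges = np.r_[np.asarray(self.starts_s, float), self.end_s]
        return {
            name: (t >= edges[i]) & (t < edges[i + 1])
            for i, name in enumerate(self.names)
        }


def default_template(**overrides) -> ArcTemplate:
    """The stock six-phase arc with rater-consensus boundaries."""
    return ArcTemplate(**overrides)
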