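"""Shared small pieces: named errors and the grid-valued threshold rule."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence


class NoSignalError(ValueError):
    """Raised when a recording carries no usable signal (all zero / non-finite)."""


class InvalidWindowError(ValueError):
    """Raised when an analysis window selects no samples."""


class UnbalancedDesignError(ValueError):
    """Raised when a repeated-measures table is not a complete subject x level grid."""


class MissingLandmarkError(KeyError):
    """Raised when a required landmark set is absent."""


class DegenerateLandmarkError(ValueError):
    """Raised when landmark geometry is degenerate (e.g. coincident midpoints)."""


@dataclass(frozen=True)
class ThresholdResult:
    """Grid-valued detection threshold.

    ``threshold_db`` is a member of the tested level grid, or ``None`` when the
    criterion is not met at the top of the grid ("not reached").
    """

    threshold_db: float | None
    criterion: float
    rule: Mapping[str, object] = field(default_factory=dict)

    @property
    def reached(self) -> bool:
        return self.threshold_db is not None


def suffix_threshold(levels: Sequence[float], exceeds: Sequence[bool]) -> float | None:
    """Lowest tested level above which the criterion is met at *every* tested level.

    Implements the rule "the intensity above which the response exceeds the
    criterion": a level qualifies when all strictly higher tested levels pass.
    The top level qualifies vacuously, so "not reached" is declared when the
    top level itself fails. Levels need not be passed in sorted order.
    """
    if len(levels) == 0:
        raise ValueError("empty level grid")
    if len(levels) != len(exceeds):
        raise ValueError("levels and exceeds must have equal length")
    order = sorted(range(len(levels)), key=lambda i: levels[i])
    lv = [float(levels[i]) for i in order]
    ok = [bool(exceeds[i]) for i in order]
    if not ok[-1]:
        return None
    # walk down from the top while the suffix above each candidate stays true
    threshold = lv[-1]
    for i in range(len(lv) - 2, -1, -1):
        if not ok[i + 1]:
            break
        threshold = lv[i]
    return threshold
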