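"""Metaphase-anchored nuclear trajectory container.

A :class:`NuclearTrack` holds one nucleus's apico-basal position time
series.  Positions are distances from the apical surface in micrometres
(apical surface = 0, larger = more basal).  Times are in minutes and are
anchored so that the final metaphase frame is ``t = 0``; all earlier
frames are negative.  Sampling must be uniform: mean-squared-displacement
estimation with overlapping pairs assumes a constant frame interval, so
gapped tracks are split or truncated upstream, never interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NuclearTrack", "TrackValidationError"]

#: relative tolerance on frame-interval uniformity
_DT_RTOL = 1e-6
#: absolute tolerance on the metaphase anchor (minutes)
_ANCHOR_ATOL = 1e-9


class TrackValidationError(ValueError):
    """A trajectory violates the track invariants."""


@dataclass
class NuclearTrack:
    """One nucleus's distance-to-apical-surface time series.

    Parameters
    ----------
    track_id:
        Identifier, unique within a cohort.
    times:
        Time stamps in minutes, strictly increasing with constant
        spacing, final entry 0 (final metaphase).
    positions:
        Distance from the apical surface at each time, micrometres,
        finite and non-negative.
    myosin:
        Optional cortical myosin intensity per time point (same length
        as ``times``); raw or normalized depending on provenance.
    disc_id, condition:
        Grouping labels (source disc, experimental condition).
    """

    track_id: str
    times: np.ndarray
    positions: np.ndarray
    myosin: np.ndarray | None = None
    disc_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.myosin is not None:
            self.myosin = np.asarray(self.myosin, dtype=float)

        if self.times.ndim != 1 or self.positions.ndim != 1:
            raise TrackValidationError(
                f"track {self.track_id!r}: times and positions must be 1-D"
            )
        if self.times.size != self.positions.size:
            raise TrackValidationError(
                f"track {self.track_id!r}: times ({self.times.size}) and "
                f"positions ({self.positions.size}) differ in length"
            )
        if self.times.size < 2:
            raise TrackValidationError(
                f"track {self.track_id!r}: need at least 2 time points"
            )
        if not np.all(np.isfinite(self.times)):
            raise TrackValidationError(
                f"track {self.track_id!r}: non-finite time stamps"
            )
        if not np.all(np.isfinite(self.positions)):
            raise TrackValidationError(
                f"track {self.track_id!r}: non-finite positions"
            )
        if np.any(self.positions < 0):
            raise TrackValidationError(
                f"track {self.track_id!r}: negative apical distances"
            )
        diffs = np.diff(self.times)
        if np.any(diffs <= 0):
            raise TrackValidationError(
                f"track {self.track_id!r}: times not strictly increasing"
            )
        dt = float(np.median(diffs))
        if np.any(np.abs(diffs - dt) > _DT_RTOL * dt):
            raise TrackValidationError(
                f"track {self.track_id!r}: non-uniform frame interval "
                "(gapped tracks must be split or truncated, not interpolated)"
            )
        if abs(self.times[-1]) > _ANCHOR_ATOL:
            raise TrackValidationError(
                f"track {self.track_id!r}: not metaphase-anchored "
                f"(final time {self.times[-1]:g}, expected 0)"
            )
        if self.myosin is not None and self.myosin.size != self.times.size:
            raise TrackValidationError(
                f"track {self.track_id!r}: myosin series length mismatch"
            )

    @property
    def n(self) -> int:
        """Number of time points."""
        return int(self.times.size)

    @property
    def dt(self) -> float:
        """Frame interval in minutes."""
        return float(np.median(np.diff(self.times)))

    def index_at(self, time: float) -> int:
        """Index of the frame closest to ``time`` (within half a frame)."""
        idx = int(np.argmin(np.abs(self.times - time)))
        if abs(self.times[idx] - time) > 0.5 * self.dt + _ANCHOR_ATOL:
            raise TrackValidationError(
                f"track {self.track_id!r}: no frame near t = {time:g} min"
            )
        return idx
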