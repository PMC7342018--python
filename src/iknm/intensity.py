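"""Cortical myosin intensity dynamics coupled to nuclear tracks.

Cortical enrichment of myosin-II (e.g. an Sqh-GFP reporter) marks the
onset of mitotic rounding.  Intensity time series are normalized to the
pre-mitotic baseline — the mean of all samples strictly before a
baseline cutoff (default 30 min before metaphase) — and then compared
against the motion-segmentation onset of the paired nuclear track.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .kinetics import PhaseSplit
from .tracks import NuclearTrack

__all__ = [
    "IntensitySeries",
    "normalize_myosin",
    "onset_concordance",
    "cohort_concordance",
    "intensity_distance_table",
]


@dataclass(frozen=True)
class IntensitySeries:
    """Cortical intensity per time point for one tracked nucleus.

    ``source`` records the measurement provenance: ``"membrane"`` for a
    traced lateral membrane, ``"flanking"`` for flanking-line
    measurements taken when the membrane is indistinguishable from
    cytoplasm.
    """

    track_id: str
    times: np.ndarray            # min, metaphase = 0
    raw_intensity: np.ndarray    # arbitrary units, >= 0
    normalized_intensity: np.ndarray | None = None
    source: str = "membrane"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        raw = np.asarray(self.raw_intensity, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "raw_intensity", raw)
        if t.size != raw.size:
            raise ValueError("times and raw_intensity differ in length")
        if t.size < 2:
            raise ValueError("need at least 2 intensity samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(raw)) or np.any(raw < 0):
            raise ValueError("raw intensities must be finite and >= 0")
        if self.normalized_intensity is not None:
            norm = np.asarray(self.normalized_intensity, dtype=float)
            object.__setattr__(self, "normalized_intensity", norm)
            if norm.size != t.size:
                raise ValueError("normalized series length mismatch")


def normalize_myosin(
    series: IntensitySeries, baseline_end: float = -30.0
) -> IntensitySeries:
    """Divide by the mean intensity of samples strictly before
    ``baseline_end`` (half-open baseline window).

    The baseline window's normalized mean is exactly 1; normalization
    is idempotent and invariant to rescaling the raw series.
    """
    mask = series.times < baseline_end
    if mask.sum() < 2:
        raise ValueError(
            f"track {series.track_id!r}: need >= 2 samples before "
            f"t = {baseline_end:g} min, got {int(mask.sum())}"
        )
    baseline = float(series.raw_intensity[mask].mean())
    if baseline <= 0:
        raise ValueError(
            f"track {series.track_id!r}: baseline mean is not positive"
        )
    return replace(
        series, normalized_intensity=series.raw_intensity / baseline
    )


def onset_concordance(
    track: NuclearTrack,
    series: IntensitySeries,
    split: PhaseSplit,
    intensity_threshold: float = 1.2,
) -> float | None:
    """Time offset between myosin enrichment and motion onset.

    Returns ``(first time normalized intensity strictly exceeds the
    threshold) - (motion onset time)``; negative means myosin rises
    first.  ``None`` (a counted missing value) when the intensity never
    crosses.
    """
    if series.normalized_intensity is None:
        raise ValueError("series must be normalized first (normalize_myosin)")
    if series.track_id != track.track_id:
        raise ValueError(
            f"track/series mismatch: {track.track_id!r} vs "
            f"{series.track_id!r}"
        )
    above = np.nonzero(series.normalized_intensity > intensity_threshold)[0]
    if above.size == 0:
        return None
    return float(series.times[above[0]] - split.onset_time)


def cohort_concordance(offsets: list[float | None]) -> dict:
    """Median offset over a cohort; missing crossings are counted."""
    present = np.array([o for o in offsets if o is not None], dtype=float)
    return {
        "n": len(offsets),
        "n_missing": len(offsets) - present.size,
        "median_offset_min": float(np.median(present)) if present.size else None,
    }


def intensity_distance_table(
    tracks: list[NuclearTrack], series: list[IntensitySeries]
) -> pd.DataFrame:
    """Paired per-time summary: mean normalized intensity and mean
    nuclear distance with SEM each, across a cohort.

    Tracks and series are matched by ``track_id``; per-time aggregation
    is a plain mean over whichever cells cover that time point.
    """
    by_id = {t.track_id: t for t in tracks}
    rows = []
    for s in series:
        if s.normalized_intensity is None:
            raise ValueError("all series must be normalized first")
        t = by_id.get(s.track_id)
        if t is None:
            continue
        pos = pd.Series(t.positions, index=np.round(t.times, 6))
        for time, val in zip(s.times, s.normalized_intensity):
            key = round(float(time), 6)
            rows.append(
                {
                    "time_min": key,
                    "intensity": float(val),
                    "distance_um": float(pos.get(key, np.nan)),
                }
            )
    if not rows:
        raise ValueError("no matched track/series pairs")
    df = pd.DataFrame(rows)
    g = df.groupby("time_min")

    def _sem(s: pd.Series) -> float:
        s = s.dropna()
        return float(s.std(ddof=1) / np.sqrt(len(s))) if len(s) > 1 else 0.0

    out = pd.DataFrame(
        {
            "time_min": sorted(g.groups),
            "mean_intensity": g["intensity"].mean().to_numpy(),
            "sem_intensity": g["intensity"].apply(_sem).to_numpy(),
            "mean_distance_um": g["distance_um"].mean().to_numpy(),
            "sem_distance_um": g["distance_um"].apply(_sem).to_numpy(),
            "n_cells": g["intensity"].count().to_numpy(),
        }
    )
    return out
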