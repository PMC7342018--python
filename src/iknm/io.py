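"""CSV/JSON file formats and run configuration.

All tabular data travels as plain UTF-8 CSV (decimal point, comma
separator) because upstream manual-tracking exports are
spreadsheet-shaped; nested summaries travel as JSON.  Units are fixed
at micrometres and minutes throughout — no unit inference.

Track CSV dialect::

    track_id,time_min,apical_distance_um[,myosin_intensity][,disc_id][,condition]

Profile CSV dialect::

    position_um,intensity[,disc_id][,region]

Position CSV dialect::

    disc_id,condition,distance_um[,region_height_um]

Intensity CSV dialect::

    track_id,time_min,raw_intensity[,source]
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .intensity import IntensitySeries
from .morphology import ApicoBasalProfile
from .positioning import MitoticPositionSet
from .tracks import NuclearTrack, TrackValidationError

__all__ = [
    "read_tracks",
    "write_tracks",
    "read_profiles",
    "write_profiles",
    "read_positions",
    "write_positions",
    "read_intensity",
    "write_intensity",
    "write_json",
    "RunConfig",
    "write_resolved_config",
]

_GAP_RTOL = 0.5  # a step > 1.5x the median interval is a gap


def _require(df: pd.DataFrame, cols: tuple[str, ...], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} file missing required column(s): {missing}")


def read_tracks(
    path: str | Path,
    *,
    strict: bool = True,
    allow_unanchored: bool = False,
) -> list[NuclearTrack]:
    """Read a track CSV into validated :class:`NuclearTrack` objects.

    Rows are sorted by time within each track.  Sampling gaps (a time
    step larger than 1.5x the track's median interval) are an error in
    strict mode; in lenient mode the track is truncated to its final
    contiguous run (the metaphase-anchored stretch the analyses use) —
    gaps are never interpolated.  Tracks whose final time is not 0 are
    rejected unless ``allow_unanchored``, which re-anchors them by
    shifting times so the final frame is 0.
    """
    df = pd.read_csv(path)
    _require(df, ("track_id", "time_min", "apical_distance_um"), "track")
    tracks: list[NuclearTrack] = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("time_min")
        times = grp["time_min"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise TrackValidationError(
                f"track {tid!r}: non-monotone or duplicate times"
            )
        dt = float(np.median(np.diff(times)))
        gaps = np.nonzero(np.diff(times) > (1 + _GAP_RTOL) * dt)[0]
        if gaps.size:
            if strict:
                raise TrackValidationError(
                    f"track {tid!r}: sampling gap(s) at t = "
                    f"{times[gaps].tolist()}; re-read with strict=False to "
                    "truncate to the final contiguous run"
                )
            warnings.warn(
                f"track {tid!r}: truncating at sampling gap "
                f"(keeping final {times.size - (gaps[-1] + 1)} frames)",
                stacklevel=2,
            )
            grp = grp.iloc[gaps[-1] + 1:]
            times = grp["time_min"].to_numpy(dtype=float)
        if abs(times[-1]) > 1e-9:
            if not allow_unanchored:
                raise TrackValidationError(
                    f"track {tid!r}: not metaphase-anchored (final time "
                    f"{times[-1]:g}); pass allow_unanchored=True to "
                    "re-anchor at the final frame"
                )
            times = times - times[-1]
        myo = None
        if "myosin_intensity" in grp.columns and grp["myosin_intensity"].notna().all():
            myo = grp["myosin_intensity"].to_numpy(dtype=float)
        tracks.append(
            NuclearTrack(
                track_id=str(tid),
                times=times,
                positions=grp["apical_distance_um"].to_numpy(dtype=float),
                myosin=myo,
                disc_id=str(grp["disc_id"].iloc[0]) if "disc_id" in grp else "",
                condition=str(grp["condition"].iloc[0])
                if "condition" in grp else "",
            )
        )
    if not tracks:
        raise ValueError(f"no tracks found in {path}")
    return tracks


def write_tracks(path: str | Path, tracks: list[NuclearTrack]) -> None:
    """Write tracks in the track CSV dialect."""
    frames = []
    for t in tracks:
        f = pd.DataFrame(
            {
                "track_id": t.track_id,
                "time_min": t.times,
                "apical_distance_um": t.positions,
            }
        )
        if t.myosin is not None:
            f["myosin_intensity"] = t.myosin
        f["disc_id"] = t.disc_id
        f["condition"] = t.condition
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_profiles(path: str | Path) -> list[ApicoBasalProfile]:
    """Read one or more apico-basal profiles (grouped by disc_id)."""
    df = pd.read_csv(path)
    _require(df, ("position_um", "intensity"), "profile")
    if "disc_id" not in df.columns:
        df["disc_id"] = "disc00"
    profiles = []
    for disc, grp in df.groupby("disc_id", sort=True):
        grp = grp.sort_values("position_um")
        profiles.append(
            ApicoBasalProfile(
                positions=grp["position_um"].to_numpy(dtype=float),
                intensity=grp["intensity"].to_numpy(dtype=float),
                disc_id=str(disc),
                region=str(grp["region"].iloc[0]) if "region" in grp else "",
            )
        )
    if not profiles:
        raise ValueError(f"no profiles found in {path}")
    return profiles


def write_profiles(path: str | Path, profiles: list[ApicoBasalProfile]) -> None:
    frames = [
        pd.DataFrame(
            {
                "position_um": p.positions,
                "intensity": p.intensity,
                "disc_id": p.disc_id,
                "region": p.region,
            }
        )
        for p in profiles
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_positions(path: str | Path) -> MitoticPositionSet:
    df = pd.read_csv(path)
    _require(df, ("disc_id", "condition", "distance_um"), "position")
    return MitoticPositionSet(df)


def write_positions(path: str | Path, pset: MitoticPositionSet) -> None:
    pset.data.to_csv(path, index=False)


def read_intensity(path: str | Path) -> list[IntensitySeries]:
    df = pd.read_csv(path)
    _require(df, ("track_id", "time_min", "raw_intensity"), "intensity")
    series = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("time_min")
        series.append(
            IntensitySeries(
                track_id=str(tid),
                times=grp["time_min"].to_numpy(dtype=float),
                raw_intensity=grp["raw_intensity"].to_numpy(dtype=float),
                source=str(grp["source"].iloc[0]) if "source" in grp
                else "membrane",
            )
        )
    if not series:
        raise ValueError(f"no intensity series found in {path}")
    return series


def write_intensity(path: str | Path, series: list[IntensitySeries]) -> None:
    frames = []
    for s in series:
        f = pd.DataFrame(
            {
                "track_id": s.track_id,
                "time_min": s.times,
                "raw_intensity": s.raw_intensity,
            }
        )
        if s.normalized_intensity is not None:
            f["normalized_intensity"] = s.normalized_intensity
        f["source"] = s.source
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# run configuration

_SCHEMA: dict[str, dict | None] = {
    "inputs": {
        "tracks": None,
        "profiles": None,
        "positions": None,
        "intensity": None,
    },
    "output_dir": None,
    "seed": None,
    "verbosity": None,
    "kinetics": {
        "max_lag": None,
        "lag_window": None,
        "margin": None,
        "min_late": None,
        "min_early": None,
        "diffusive_band": None,
        "ballistic_band": None,
        "myosin_threshold": None,
    },
    "morphology": {
        "threshold_frac": None,
        "smooth_window": None,
        "prominence_frac": None,
        "min_sep": None,
    },
    "positioning": {
        "cutoff_um": None,
        "ks_method": None,
    },
    "intensity": {
        "baseline_end": None,
        "intensity_threshold": None,
    },
}


class RunConfig(dict):
    """Validated run configuration (flat keys + per-module sections).

    Unknown keys are rejected, so a typo in a parameter name fails the
    run instead of silently using a default.  Every run writes a
    resolved copy of its configuration next to the outputs.
    """

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if not isinstance(raw, dict):
            raise ValueError("config root must be a mapping")
        unknown = [k for k in raw if k not in _SCHEMA]
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key, sub in _SCHEMA.items():
            if sub is not None and key in raw:
                if not isinstance(raw[key], dict):
                    raise ValueError(f"config section {key!r} must be a mapping")
                bad = [k for k in raw[key] if k not in sub]
                if bad:
                    raise ValueError(
                        f"unknown key(s) in config section {key!r}: "
                        f"{sorted(bad)}"
                    )
        return cls(raw)

    def section(self, name: str) -> dict:
        return dict(self.get(name, {}) or {})


def write_resolved_config(outdir: str | Path, resolved: dict) -> Path:
    """Write the fully resolved configuration next to the outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "resolved_config.yaml"
    path.write_text(yaml.safe_dump(resolved, sort_keys=True))
    return path
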