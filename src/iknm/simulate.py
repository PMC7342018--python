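"""Synthetic ground-truth generators for the migration pipeline.

Three generators emulate the statistical structure of the real inputs:

* :func:`simulate_tracks` — two-phase apico-basal nuclear trajectories:
  an early phase of free (Brownian) or confined (Ornstein--Uhlenbeck)
  diffusion, switching at a known changepoint to a late phase of
  apically directed drift plus diffusion, ending at final metaphase
  (``t = 0``).
* :func:`simulate_profile` — apico-basal nuclear-intensity line
  profiles: a sum of Gaussian nuclear peaks confined to the nuclear
  layer, flanked by an apical proliferative zone and a basal
  nucleus-free zone.
* :func:`simulate_positions` — per-disc mitotic-nucleus distances to
  the apical surface drawn from named distribution families.

Every generator is deterministic given its seed.  Trajectories use one
independent RNG sub-stream per track, keyed by ``(seed, track index)``,
so track ``i`` is identical no matter how many tracks are requested.
Ground truth (changepoint times, zone boundaries, peak counts, family
parameters) is returned alongside the data and can be written to a JSON
sidecar for downstream comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .tracks import NuclearTrack
from .morphology import ApicoBasalProfile
from .positioning import MitoticPositionSet

__all__ = [
    "ConfigError",
    "SimConfig",
    "ProfileConfig",
    "SimulatedCohort",
    "SimulatedProfile",
    "simulate_tracks",
    "simulate_profile",
    "simulate_positions",
    "POSITION_FAMILIES",
]


class ConfigError(ValueError):
    """Invalid generator configuration."""


def _track_rng(seed: int, counter: int) -> np.random.Generator:
    # one sub-stream per track, independent of how many tracks are drawn
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(counter,)))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the two-phase trajectory generator.

    Attributes
    ----------
    seed:
        RNG seed.
    dt:
        Frame interval in minutes.  The imaging interval is a free
        parameter of the acquisition; 1.5 min is a realistic default
        for minute-scale confocal time lapses of nuclear migration.
    n_steps:
        Number of update steps; a track has ``n_steps + 1`` samples.
    d_early:
        Early-phase diffusion constant, um^2/min.
    alpha_early:
        Intended early-phase anomalous exponent, recorded as ground
        truth (1.0 = Brownian; values below 1 arise over intermediate
        lags when ``confinement_k > 0``).  The exponent is emergent
        from the dynamics, not imposed.
    confinement_k:
        Restoring-force rate toward the starting position, 1/min.
        0 gives free Brownian motion; > 0 gives Ornstein--Uhlenbeck
        confined diffusion (MSD plateaus at ``2 d_early / k``).
    v_late:
        Late-phase apical drift speed, um/min (positive = toward the
        apical surface, i.e. positions decrease).
    d_late:
        Late-phase diffusion constant, um^2/min.
    t_onset:
        Changepoint time in minutes before metaphase (negative).  The
        recorded ground-truth onset is this time snapped to the frame
        grid; drift applies to every step starting at or after it.
    p0:
        Starting distance from the apical surface, um.
    meas_noise_sd:
        Additive Gaussian measurement noise on each sample, um.
    n_tracks:
        Number of trajectories.
    """

    seed: int = 0
    dt: float = 1.5
    n_steps: int = 40
    d_early: float = 0.1
    alpha_early: float = 1.0
    confinement_k: float = 0.0
    v_late: float = 0.6
    d_late: float = 0.05
    t_onset: float = -15.0
    p0: float = 20.0
    meas_noise_sd: float = 0.0
    n_tracks: int = 30

    def validate(self) -> None:
        numeric = {
            k: v for k, v in asdict(self).items() if isinstance(v, (int, float))
        }
        bad = [k for k, v in numeric.items() if not math.isfinite(v)]
        if bad:
            raise ConfigError(f"non-finite SimConfig parameters: {bad}")
        if self.dt <= 0:
            raise ConfigError(f"dt must be positive, got {self.dt}")
        if self.n_steps < 4:
            raise ConfigError(f"n_steps must be >= 4, got {self.n_steps}")
        for name in ("d_early", "d_late", "v_late", "confinement_k",
                     "meas_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.p0 < 0:
            raise ConfigError(f"p0 must be >= 0, got {self.p0}")
        span = self.n_steps * self.dt
        if not (-span <= self.t_onset <= 0):
            raise ConfigError(
                f"t_onset {self.t_onset} outside simulated window [-{span}, 0]"
            )
        if self.confinement_k * self.dt >= 1.0:
            raise ConfigError(
                "confinement_k * dt must be < 1 for a stable update "
                f"(got {self.confinement_k * self.dt:g})"
            )
        if self.n_tracks < 1:
            raise ConfigError("n_tracks must be >= 1")


@dataclass
class SimulatedCohort:
    """Tracks plus their generating truth."""

    tracks: list[NuclearTrack]
    truth: pd.DataFrame  # track_id, onset_time, onset_index
    config: SimConfig

    def sidecar(self) -> dict:
        """JSON-serializable ground-truth record."""
        return {
            "generator": "simulate_tracks",
            "config": asdict(self.config),
            "onset_times": dict(
                zip(self.truth["track_id"], self.truth["onset_time"])
            ),
        }


def simulate_tracks(cfg: SimConfig) -> SimulatedCohort:
    """Draw a cohort of two-phase metaphase-anchored trajectories.

    Early phase (``t < t_onset``): Euler--Maruyama update
    ``p += -k (p - p0) dt + sqrt(2 d_early dt) xi`` (pure Brownian when
    ``confinement_k = 0``).  Late phase: ``p += -v_late dt +
    sqrt(2 d_late dt) xi``.  The apical surface at 0 reflects; nuclei
    abut but never cross it.  Measurement noise is added afterwards and
    the result clipped at 0.
    """
    cfg.validate()
    n_pts = cfg.n_steps + 1
    times = (np.arange(n_pts) - cfg.n_steps) * cfg.dt
    # first index at or after the changepoint; drift acts on steps i -> i+1
    # for i >= onset_index, so the noiseless track is flat through onset_index
    onset_index = int(np.ceil((cfg.t_onset - times[0]) / cfg.dt - 1e-9))
    onset_index = min(max(onset_index, 0), cfg.n_steps)
    onset_time = float(times[onset_index])

    sig_early = math.sqrt(2.0 * cfg.d_early * cfg.dt)
    sig_late = math.sqrt(2.0 * cfg.d_late * cfg.dt)

    tracks: list[NuclearTrack] = []
    rows = []
    for i in range(cfg.n_tracks):
        rng = _track_rng(cfg.seed, i)
        xi = rng.standard_normal(cfg.n_steps)
        p = np.empty(n_pts)
        p[0] = cfg.p0
        for j in range(cfg.n_steps):
            if j < onset_index:
                step = -cfg.confinement_k * (p[j] - cfg.p0) * cfg.dt
                step += sig_early * xi[j]
            else:
                step = -cfg.v_late * cfg.dt + sig_late * xi[j]
            p[j + 1] = abs(p[j] + step)  # reflecting apical surface
        if cfg.meas_noise_sd > 0:
            p = p + cfg.meas_noise_sd * rng.standard_normal(n_pts)
        np.clip(p, 0.0, None, out=p)
        tid = f"sim{i:04d}"
        tracks.append(
            NuclearTrack(track_id=tid, times=times.copy(), positions=p,
                         condition="simulated")
        )
        rows.append({"track_id": tid, "onset_time": onset_time,
                     "onset_index": onset_index})
    return SimulatedCohort(tracks=tracks, truth=pd.DataFrame(rows), config=cfg)


# Gaussian peaks fall to 20% of their height 1.794 sigma from center;
# outermost peak centers are inset by this much so the layer's intensity
# envelope decays to background right at the configured boundaries.
_EDGE_FACTOR = math.sqrt(2.0 * math.log(5.0))


@dataclass(frozen=True)
class ProfileConfig:
    """Parameters of the apico-basal intensity-profile generator."""

    seed: int = 0
    epithelial_height: float = 40.0
    apz_height: float = 6.0
    nfz_height: float = 10.0
    n_nuclei: int = 4
    nucleus_sigma: float = 1.5
    sample_spacing: float = 0.5
    noise_sd: float = 0.0

    def validate(self) -> None:
        vals = asdict(self)
        bad = [k for k, v in vals.items() if not math.isfinite(v)]
        if bad:
            raise ConfigError(f"non-finite ProfileConfig parameters: {bad}")
        if self.epithelial_height <= 0 or self.sample_spacing <= 0:
            raise ConfigError("heights and spacing must be positive")
        if self.apz_height < 0 or self.nfz_height < 0:
            raise ConfigError("zone heights must be >= 0")
        if self.apz_height + self.nfz_height >= self.epithelial_height:
            raise ConfigError(
                "apz_height + nfz_height must be smaller than "
                "epithelial_height"
            )
        if self.n_nuclei < 1:
            raise ConfigError("n_nuclei must be >= 1")
        if self.nucleus_sigma <= 0:
            raise ConfigError("nucleus_sigma must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        nl = self.epithelial_height - self.apz_height - self.nfz_height
        if 2.0 * _EDGE_FACTOR * self.nucleus_sigma >= nl:
            raise ConfigError(
                "nuclear layer too thin for the requested nucleus_sigma"
            )

    @property
    def nl_height(self) -> float:
        return self.epithelial_height - self.apz_height - self.nfz_height


@dataclass
class SimulatedProfile:
    """Profile plus its generating truth."""

    profile: ApicoBasalProfile
    truth: dict

    def sidecar(self) -> dict:
        return {"generator": "simulate_profile", **self.truth}


def simulate_profile(cfg: ProfileConfig) -> SimulatedProfile:
    """Sample an apico-basal DAPI-like intensity profile.

    ``n_nuclei`` unit-height Gaussian peaks are stacked evenly through
    the nuclear layer (regular stacking mimics the columnar packing of
    nuclei), inset from the layer boundaries so the summed intensity
    decays to ~20% of a peak right at the configured boundary.  Optional
    Gaussian intensity noise is added and clipped at zero.
    """
    cfg.validate()
    nl_start = cfg.apz_height
    nl_end = cfg.epithelial_height - cfg.nfz_height
    inset = _EDGE_FACTOR * cfg.nucleus_sigma
    if cfg.n_nuclei == 1:
        centers = np.array([(nl_start + nl_end) / 2.0])
    else:
        centers = np.linspace(nl_start + inset, nl_end - inset, cfg.n_nuclei)

    n_samples = int(round(cfg.epithelial_height / cfg.sample_spacing)) + 1
    x = np.arange(n_samples) * cfg.sample_spacing
    intensity = np.zeros_like(x)
    for c in centers:
        intensity += np.exp(-0.5 * ((x - c) / cfg.nucleus_sigma) ** 2)
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        intensity = intensity + cfg.noise_sd * rng.standard_normal(x.size)
        np.clip(intensity, 0.0, None, out=intensity)

    profile = ApicoBasalProfile(positions=x, intensity=intensity,
                                disc_id="sim", region="pouch")
    truth = {
        "config": asdict(cfg),
        "apz_height": cfg.apz_height,
        "nl_height": cfg.nl_height,
        "nfz_height": cfg.nfz_height,
        "nl_start": nl_start,
        "nl_end": nl_end,
        "peak_centers": centers.tolist(),
        "n_peaks": int(cfg.n_nuclei),
    }
    return SimulatedProfile(profile=profile, truth=truth)


POSITION_FAMILIES = ("exponential", "half_normal", "mixture")


def simulate_positions(
    n_per_disc: list[int] | tuple[int, ...],
    dist_family: str,
    params: dict | None = None,
    seed: int = 0,
    *,
    condition: str = "simulated",
    region_height: float | None = None,
) -> MitoticPositionSet:
    """Draw per-disc mitotic-nucleus distances to the apical surface.

    Families
    --------
    ``exponential``
        ``mean`` (um, default 2.0).
    ``half_normal``
        ``sigma`` (um, default 3.0): absolute value of a centred normal.
    ``mixture``
        Apical spike + deep tail: with probability ``tail_weight`` draw
        ``tail_offset + Exponential(tail_scale)``, otherwise a
        half-normal spike of width ``spike_sigma``.  Defaults:
        ``spike_sigma`` 1.0, ``tail_weight`` 0.2, ``tail_offset`` 5.0,
        ``tail_scale`` 5.0.
    """
    if dist_family not in POSITION_FAMILIES:
        raise ValueError(
            f"unsupported distribution family {dist_family!r}; "
            f"supported families: {', '.join(POSITION_FAMILIES)}"
        )
    params = dict(params or {})
    rows = []
    for d, n in enumerate(n_per_disc):
        if n < 0:
            raise ConfigError("per-disc counts must be >= 0")
        rng = _track_rng(seed, d)
        if dist_family == "exponential":
            dist = rng.exponential(params.get("mean", 2.0), size=n)
        elif dist_family == "half_normal":
            dist = np.abs(rng.normal(0.0, params.get("sigma", 3.0), size=n))
        else:
            w = params.get("tail_weight", 0.2)
            if not 0.0 <= w <= 1.0:
                raise ConfigError("tail_weight must lie in [0, 1]")
            is_tail = rng.random(n) < w
            spike = np.abs(
                rng.normal(0.0, params.get("spike_sigma", 1.0), size=n)
            )
            tail = params.get("tail_offset", 5.0) + rng.exponential(
                params.get("tail_scale", 5.0), size=n
            )
            dist = np.where(is_tail, tail, spike)
        frame = pd.DataFrame(
            {
                "disc_id": f"disc{d:02d}",
                "condition": condition,
                "distance_um": dist,
            }
        )
        if region_height is not None:
            frame["region_height_um"] = region_height
        rows.append(frame)
    data = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["disc_id", "condition", "distance_um"]
    )
    pset = MitoticPositionSet(data)
    pset.truth = {
        "generator": "simulate_positions",
        "family": dist_family,
        "params": params,
        "seed": seed,
        "n_per_disc": list(n_per_disc),
    }
    return pset
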