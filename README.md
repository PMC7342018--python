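# iknm

Quantification of mitotic (interkinetic) nuclear migration in
pseudostratified epithelia.

In pseudostratified epithelia — such as the *Drosophila* wing disc —
nuclei are staggered along the apico-basal axis and must translocate to
the apical surface before dividing. This package implements the
trajectory and tissue analyses used to characterize that behavior from
manually tracked, metaphase-anchored nuclear trajectories and from
fixed-tissue measurements, together with synthetic generators that
produce every input with known ground truth. It is aimed at
quantitative cell and developmental biologists analyzing apico-basal
nuclear dynamics.

## What it computes

**Trajectory kinetics** (`iknm.kinetics`). A track is a 1-D time series
p(iδt) of distance to the apical surface (µm), aligned so final
metaphase is t = 0. The overlapping-pair mean squared displacement for
lag Δt = nδt is

    MSD(Δt) = (1/(N−n)) Σ_{i=1..N−n} ( p((n+i)δt) − p(iδt) )²

and motion is characterized through the log-log linearized power law

    ln MSD(Δt) = ln 2D + a ln Δt,

fitted by ordinary least squares: `a` is the anomalous exponent
(a < 1 constrained, a ≈ 1 diffusive, a > 1 directed, a ≈ 2 ballistic)
and D the diffusion constant. Tracks are segmented into an early
(non-directed) and a late (directed apical) phase, either with a
supplied manual onset or automatically by a least-squares changepoint
scan on frame-to-frame displacements; mitotic nuclear velocity is the
net apical displacement from onset to metaphase divided by its
duration, optionally normalized to a control cohort's mean.

**Tissue morphology** (`iknm.morphology`). From apico-basal nuclear
intensity profiles: heights of the apical proliferative zone, nuclear
layer and basal nucleus-free zone via a fractional-intensity threshold;
stacked-nucleus counts via prominence-based peak detection; and nuclear
density as nuclei / (apical area × nuclear-layer height).

**Mitotic positioning** (`iknm.positioning`). Fixed-tissue distances of
mitotic (PH3+) nuclei to the apical surface: per-disc normalization by
nuclear-region height, the percentage of nuclei deeper than a cutoff
(default 5 µm, strict inequality), ECDFs with two-sample
Kolmogorov–Smirnov comparisons (discs pooled per condition), and
classification of mosaic-clone neighborhoods (wt:wt, wt:rnai, rnai:wt,
rnai:rnai) from apical-perimeter composition.

**Myosin dynamics** (`iknm.intensity`). Cortical myosin reporter
series normalized to the pre-mitotic baseline (mean of samples before
−30 min), and the time offset between myosin enrichment and motion
onset.

**Synthetic data** (`iknm.simulate`). Seeded generators for two-phase
trajectories (Brownian or Ornstein–Uhlenbeck-confined early phase,
drift + diffusion late phase, reflecting apical surface), multi-peak
intensity profiles with configured zone geometry, and per-disc mitotic
position samples from named distribution families — each returning its
generating ground truth.

## Worked example

```python
import numpy as np
from iknm import (SimConfig, simulate_tracks, compute_msd, pooled_msd,
                  fit_power_law, classify_motion, segment_phases,
                  mitotic_velocity)

cfg = SimConfig(seed=42, dt=1.0, n_steps=60, d_early=0.1, v_late=0.6,
                d_late=0.05, t_onset=-15.0, p0=20.0, n_tracks=30)
cohort = simulate_tracks(cfg)

splits = [segment_phases(t, "automatic") for t in cohort.tracks]
vels = [mitotic_velocity(t, s)["velocity_um_min"]
        for t, s in zip(cohort.tracks, splits) if s is not None]
onsets = [s.onset_time for s in splits if s is not None]

early = pooled_msd([compute_msd(t.positions[:s.onset_index + 1], dt=cfg.dt)
                    for t, s in zip(cohort.tracks, splits) if s is not None])
late = pooled_msd([compute_msd(t, start_index=s.onset_index)
                   for t, s in zip(cohort.tracks, splits) if s is not None])
fe, fl = fit_power_law(early, lag_window=(1, 20)), fit_power_law(late)

print(f"tracks with a directed phase: {len(vels)}/{cfg.n_tracks}")
print(f"mean onset of apical movement: {np.mean(onsets):.1f} min")
print(f"mean mitotic nuclear velocity: {np.mean(vels):.2f} um/min")
print(f"early-phase exponent a = {fe.slope_a:.2f} "
      f"({classify_motion(fe).label}), D = {fe.diffusion_d:.3f}")
print(f"late-phase  exponent a = {fl.slope_a:.2f} "
      f"({classify_motion(fl).label}), D = {fl.diffusion_d:.3f}")
```

prints

```
tracks with a directed phase: 30/30
mean onset of apical movement: -15.1 min
mean mitotic nuclear velocity: 0.61 um/min
early-phase exponent a = 0.94 (diffusive), D = 0.104
late-phase  exponent a = 1.86 (ballistic), D = 0.240
```

The cohort was generated with a changepoint at −15 min and a late
apical drift of 0.6 µm/min: segmentation recovers the onset (−15.1 min)
and velocity (0.61 µm/min), the early phase fits an exponent near 1
(stochastic diffusion), and the drift-dominated late phase approaches
the ballistic exponent 2.

The same pipeline is scriptable from the shell — `iknm simulate tracks`,
`iknm msd`, `iknm phases`, `iknm velocity`, `iknm zones`,
`iknm density`, `iknm positions`, `iknm myosin`, and `iknm report`
(one JSON/CSV bundle from a YAML config). Run `iknm --help` for the
full surface. Every run writes a resolved-config copy next to its
outputs and is bit-reproducible for a fixed config and seed.

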