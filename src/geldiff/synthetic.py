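"""Synthetic data generators mirroring the study's measurement designs.

Each generator is a pure function of its config (including the mandatory
seed): rerunning with the same config reproduces the output bit for bit.
Alongside every dataset a machine-readable ground-truth record is returned
so that recovery tests can close the loop.

Default parameters reproduce the study conditions:

* **Release** — sampling on days 0, 1, 2, 10, 14, 20, 30 and 35 from a
  1.26 mm gel slab; truth D = 2.5 μm²/s and mobile fraction 0.36 (a
  plateau near 36%); additive Gaussian noise with sd 0.05 fraction units
  (the ±5-percentage-point replicate scatter); 4 replicates.
* **FRAP** — 100 × 100 μm ROI, 25% bleach depth, dextran-scale
  diffusivities (default 64.6 μm²/s), 1% additive intensity noise on a
  0–240 s grid that spans ≥ 90% recovery for the slowest dextran.
* **Tracks** — a two-population ensemble: mobile particles do free 2-D
  Brownian motion (per-axis step sd √(2DΔt)); immobilized ones diffuse
  inside a reflecting disk; isotropic Gaussian localization noise is added
  per frame.  50 frames per track, matching the imaging series length.
* **Probes** — dextran panel with hydrodynamic radii 0.7, 3.0 and 7.95 nm
  (diameters 1.4, 6.0, 15.9 nm), in-gel diffusivities from a chosen
  network model with multiplicative log-normal noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import units
from .exceptions import ValidationError
from .frap import FrapCurve, FrapRoi, rect_frap_recovery
from .gel_network import (GelNetwork, MediumSpec, ProbeSpec, _RATIO_FUNCS,
                          stokes_einstein_d0)
from .release import ReleaseCurve, ReleaseModelParams, predicted_release
from .tracking import Track

__all__ = [
    "ReleaseSimConfig",
    "FrapSimConfig",
    "TrackSimConfig",
    "ProbeSimConfig",
    "generate_release_curve",
    "generate_frap_curve",
    "generate_tracks",
    "generate_probe_dataset",
]


def _check_seed(seed) -> int:
    if seed is None or int(seed) < 0:
        raise ValidationError("a non-negative integer seed is required")
    return int(seed)


@dataclass(frozen=True)
class ReleaseSimConfig:
    seed: int
    d_um2_s: float = 2.5
    f_mob: float = 0.36
    thickness_mm: float = 1.26
    times_days: tuple = (0.0, 1.0, 2.0, 10.0, 14.0, 20.0, 30.0, 35.0)
    noise_sd: float = 0.05
    n_replicates: int = 4


@dataclass(frozen=True)
class FrapSimConfig:
    seed: int
    d_um2_s: float = 64.6
    bleach_depth: float = 0.25
    roi: FrapRoi = field(default_factory=FrapRoi)
    times_s: tuple = tuple(np.linspace(0.0, 240.0, 121))
    noise_sd: float = 0.01


@dataclass(frozen=True)
class TrackSimConfig:
    seed: int
    n_tracks: int = 200
    mobile_fraction: float = 0.4
    d_mobile_um2_s: float = 1.0
    confinement_radius_um: float = 0.3
    d_confined_um2_s: float = 0.5
    n_frames: int = 50
    dt_s: float = 0.5
    localization_noise_um: float = 0.03


@dataclass(frozen=True)
class ProbeSimConfig:
    seed: int
    radii_nm: tuple = (0.7, 3.0, 7.95)
    names: tuple = ("dextran_4kDa", "dextran_70kDa", "dextran_500kDa")
    model_name: str = "ogston_amsden"
    fiber_radius_nm: float = 1.0
    volume_fraction: float = 0.016
    noise_cv: float = 0.05


def generate_release_curve(config: ReleaseSimConfig) -> tuple[ReleaseCurve, dict]:
    """Noisy replicate release curves plus the generating truth record.

    Values are the forward model plus additive Gaussian noise (sd in
    fraction units), clipped at 0; the number of clipped points is recorded
    in the truth sidecar.
    """
    rng = np.random.default_rng(_check_seed(config.seed))
    params = ReleaseModelParams(d_um2_s=config.d_um2_s, f_mob=config.f_mob,
                                thickness_mm=config.thickness_mm)
    t_days = np.asarray(config.times_days, dtype=float)
    t_s = units.days_to_seconds(t_days)
    clean = predicted_release(t_s, params)

    times, values, reps = [], [], []
    n_clipped = 0
    for r in range(config.n_replicates):
        noisy = clean + rng.normal(0.0, config.noise_sd, size=clean.size) if config.noise_sd > 0 else clean.copy()
        n_clipped += int(np.sum(noisy < 0))
        noisy = np.clip(noisy, 0.0, 1.0)
        times.append(t_s)
        values.append(noisy)
        reps.append(np.full(t_s.size, r))
    curve = ReleaseCurve(times_s=np.concatenate(times), values=np.concatenate(values),
                         replicate_ids=np.concatenate(reps), is_fraction=True)
    truth = {"scenario": "release", "seed": config.seed, "d_um2_s": config.d_um2_s,
             "f_mob": config.f_mob, "thickness_mm": config.thickness_mm,
             "noise_sd": config.noise_sd, "n_replicates": config.n_replicates,
             "times_days": list(t_days), "n_clipped": n_clipped}
    return curve, truth


def generate_frap_curve(config: FrapSimConfig) -> tuple[FrapCurve, dict]:
    """Noisy rectangular-ROI recovery curve plus the generating truth."""
    rng = np.random.default_rng(_check_seed(config.seed))
    if not config.d_um2_s > 0:
        raise ValidationError("D must be > 0")
    t = np.asarray(config.times_s, dtype=float)
    clean = rect_frap_recovery(t, config.d_um2_s, config.roi, config.bleach_depth)
    noisy = clean + rng.normal(0.0, config.noise_sd, size=t.size) if config.noise_sd > 0 else clean.copy()
    curve = FrapCurve(times_s=t, intensities=noisy, bleach_depth=config.bleach_depth)
    truth = {"scenario": "frap", "seed": config.seed, "d_um2_s": config.d_um2_s,
             "bleach_depth": config.bleach_depth,
             "roi_um": [config.roi.width_um, config.roi.height_um],
             "noise_sd": config.noise_sd}
    return curve, truth


def _confined_walk(rng, n_frames, step_sd, radius):
    """Brownian walk inside a reflecting disk centred on the start point."""
    xy = np.zeros((n_frames, 2))
    for i in range(1, n_frames):
        pos = xy[i - 1] + rng.normal(0.0, step_sd, size=2) if step_sd > 0 else xy[i - 1].copy()
        if radius > 0:
            r = np.hypot(*pos)
            while r > radius:  # radial mirror reflection back into the disk
                pos = pos * ((2.0 * radius - r) / r)
                r = np.hypot(*pos)
        else:
            pos = np.zeros(2)
        xy[i] = pos
    return xy


def generate_tracks(config: TrackSimConfig) -> tuple[list[Track], dict]:
    """Two-population Brownian track ensemble with per-track truth labels.

    Mobile tracks are free 2-D random walks; immobilized tracks are
    confined to a reflecting disk around their start.  Localization noise
    is added to the reported positions only (the underlying walk is not
    perturbed).
    """
    rng = np.random.default_rng(_check_seed(config.seed))
    if not 0.0 <= config.mobile_fraction <= 1.0:
        raise ValidationError("mobile_fraction must be in [0, 1]")
    n_mobile = int(round(config.n_tracks * config.mobile_fraction))
    labels = np.array(["mobile"] * n_mobile + ["immobile"] * (config.n_tracks - n_mobile))

    t = np.arange(config.n_frames) * config.dt_s
    frames = np.arange(config.n_frames)
    step_mobile = np.sqrt(2.0 * config.d_mobile_um2_s * config.dt_s)
    step_conf = np.sqrt(2.0 * config.d_confined_um2_s * config.dt_s)

    tracks = []
    for i, label in enumerate(labels):
        if label == "mobile":
            steps = rng.normal(0.0, step_mobile, size=(config.n_frames - 1, 2))
            xy = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
        else:
            xy = _confined_walk(rng, config.n_frames, step_conf, config.confinement_radius_um)
        if config.localization_noise_um > 0:
            xy = xy + rng.normal(0.0, config.localization_noise_um, size=xy.shape)
        tracks.append(Track(track_id=f"track_{i:04d}", frames=frames.copy(),
                            times_s=t.copy(), positions_um=xy))
    truth = {"scenario": "tracks", "seed": config.seed, "labels": labels.tolist(),
             **{k: v for k, v in asdict(config).items() if k != "seed"}}
    truth["seed"] = config.seed
    return tracks, truth


def generate_probe_dataset(config: ProbeSimConfig) -> tuple[list[ProbeSpec], dict]:
    """Dextran-like probe panel with model-generated in-gel diffusivities.

    D_g = D_0(R_h) · ratio(R_h) · exp(ε), ε ~ N(0, cv) — multiplicative
    log-normal noise, so noiseless output equals the model exactly and
    noisy values stay positive.
    """
    rng = np.random.default_rng(_check_seed(config.seed))
    network = GelNetwork.from_fiber_and_phi(config.fiber_radius_nm, config.volume_fraction)
    medium = MediumSpec()
    probes = []
    truth_dg = []
    for name, r in zip(config.names, config.radii_nm):
        d0 = stokes_einstein_d0(r, medium)
        dg = d0 * float(_RATIO_FUNCS[config.model_name](r, network))
        truth_dg.append(dg)
        noisy = dg * float(np.exp(rng.normal(0.0, config.noise_cv))) if config.noise_cv > 0 else dg
        probes.append(ProbeSpec(name=name, r_h_nm=float(r),
                                d_gel_um2_s=min(noisy, d0), d_free_um2_s=float(d0)))
    truth = {"scenario": "probes", "seed": config.seed,
             "model_name": config.model_name,
             "fiber_radius_nm": config.fiber_radius_nm,
             "volume_fraction": config.volume_fraction,
             "mesh_radius_nm": network.mesh_radius_nm,
             "noise_cv": config.noise_cv,
             "true_dg_um2_s": truth_dg}
    return probes, truth
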