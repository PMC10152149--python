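"""Seeded generator of synthetic microwell experiments.

Forward-simulates the turnover model under a named condition preset, then
observes the trajectory with multiplicative lognormal measurement noise
and lognormal between-track parameter variability.  Every draw flows from
a single seed, so identical specs produce bit-identical outputs.

Noise magnitudes are calibration knobs of this artifact, not measured
values; they are surfaced in :class:`NoiseModel` and never hard-coded
downstream.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from cometpool.model_core import TurnoverParams, preset_params, simulate
from cometpool.trajectory_analysis import CometTrack, write_tracks_csv

__all__ = [
    "NoiseModel",
    "CohortSpec",
    "Cohort",
    "generate_track",
    "generate_defect_trace",
    "generate_cohort",
    "save_cohort",
]

PRESET_NAMES = ("assembly", "disassembly", "recycling")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement and between-track noise settings.

    observation_cv : lognormal CV applied multiplicatively to observed
        lengths, areas and velocities.
    additive_floor : additive offset on intensity-like observables (a.u.).
    param_cv : lognormal CV of per-track (gamma, k_DT, psi) around the
        preset values.
    """

    observation_cv: float = 0.10
    additive_floor: float = 0.0
    param_cv: float = 0.15
    frame_interval_min: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.observation_cv < 0 or self.param_cv < 0:
            raise ValueError("CVs must be nonnegative")
        if self.frame_interval_min <= 0:
            raise ValueError("frame interval must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """One synthetic condition: preset, cohort size, duration, geometry."""

    preset: str = "recycling"
    n_tracks: int = 16
    duration_h: float = 20.0
    l_max: float = 110.0
    G_bar: float = 3.0
    tail_width_um: float = 2.0  # for area synthesis; not a measured value
    noise: NoiseModel = field(default_factory=NoiseModel)

    def __post_init__(self) -> None:
        if self.preset not in PRESET_NAMES:
            raise ValueError(f"unknown preset {self.preset!r}; choose from {PRESET_NAMES}")
        if self.n_tracks < 1:
            raise ValueError("n_tracks must be >= 1")
        if self.duration_h <= 0:
            raise ValueError("duration must be positive")


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal factors with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    s = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * s * s, sigma=s, size=size)


def _track_params(spec: CohortSpec, rng: np.random.Generator) -> TurnoverParams:
    base = preset_params(spec.preset, l_max=spec.l_max)
    g, kdt, psi = (
        base.gamma * _lognormal_factors(rng, spec.noise.param_cv, None),
        base.k_DT * _lognormal_factors(rng, spec.noise.param_cv, None),
        base.psi * _lognormal_factors(rng, spec.noise.param_cv, None),
    )
    return TurnoverParams(
        k_tilde=base.k_tilde,
        gamma=float(g),
        k_DT=float(kdt),
        psi=float(psi),
        sigma=base.sigma,
        l_max=spec.l_max,
        G_bar=spec.G_bar,
    )


def generate_track(spec: CohortSpec, track_index: int = 0) -> tuple[CometTrack, dict]:
    """Simulate one noisy track; returns the track and its ground-truth record.

    The per-track random stream is derived from ``(seed, track_index)``,
    so tracks are reproducible independently of generation order.
    """
    rng = np.random.default_rng([spec.noise.seed, track_index])
    params = _track_params(spec, rng)

    dt = spec.noise.frame_interval_min
    n = int(round(spec.duration_h * 60.0 / dt))
    t_grid = np.linspace(0.0, n * dt, n + 1)
    traj = simulate(params, t_grid=t_grid)

    cv = spec.noise.observation_cv
    obs_length = traj.l * _lognormal_factors(rng, cv, len(t_grid))
    obs_area = obs_length * spec.tail_width_um * _lognormal_factors(rng, cv, len(t_grid))
    obs_velocity = traj.velocities * _lognormal_factors(rng, cv, len(t_grid))
    intensity = obs_length + spec.noise.additive_floor

    # bead path: integrate the true velocity along a persistent direction
    theta = rng.uniform(0.0, 2.0 * math.pi)
    displacement = np.concatenate(
        ([0.0], np.cumsum(0.5 * (traj.velocities[1:] + traj.velocities[:-1]) * np.diff(t_grid)))
    )
    x = displacement * math.cos(theta)
    y = displacement * math.sin(theta)

    track = CometTrack(
        track_id=f"{spec.preset}_{track_index:03d}",
        time_min=t_grid,
        x_um=x,
        y_um=y,
        comet_length_um=obs_length,
        comet_area_um2=obs_area,
        bead_velocity_um_per_min=obs_velocity,
        actin_intensity_au=intensity,
    )
    truth = {
        "track_id": track.track_id,
        "preset": spec.preset,
        "gamma_per_min": params.gamma,
        "k_DT_per_min": params.k_DT,
        "psi_per_min": params.psi,
        "k_tilde_per_min": params.rate,
        "sigma": params.sigma,
        "l_max_um": params.l_max,
        "seed": spec.noise.seed,
        "track_index": track_index,
    }
    return track, truth


def generate_defect_trace(
    tau_min: float,
    I0: float = 100.0,
    noise_cv: float = 0.0,
    n_points: int = 60,
    dt_min: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic defect-photometry trace ``I(t) = I0 exp(-t/tau)`` with noise.

    Returns ``(time_min, intensity)``.
    """
    if tau_min <= 0 or I0 <= 0 or dt_min <= 0:
        raise ValueError("tau, I0 and dt must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(n_points) * dt_min
    intensity = I0 * np.exp(-t / tau_min) * _lognormal_factors(rng, noise_cv, n_points)
    return t, intensity


@dataclass(frozen=True)
class Cohort:
    spec: CohortSpec
    tracks: list
    manifest: dict


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate ``spec.n_tracks`` tracks plus a ground-truth manifest."""
    tracks, truths = [], []
    for i in range(spec.n_tracks):
        track, truth = generate_track(spec, i)
        tracks.append(track)
        truths.append(truth)
    manifest = {
        "spec": {
            **{k: v for k, v in asdict(spec).items() if k != "noise"},
            "noise": asdict(spec.noise),
        },
        "tracks": truths,
    }
    return Cohort(spec=spec, tracks=tracks, manifest=manifest)


def save_cohort(cohort: Cohort, out_dir) -> tuple[Path, Path]:
    """Write ``tracks.csv`` and ``manifest.json`` under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tracks_path = out / "tracks.csv"
    manifest_path = out / "manifest.json"
    write_tracks_csv(cohort.tracks, tracks_path)
    manifest_path.write_text(json.dumps(cohort.manifest, indent=2))
    return tracks_path, manifest_path
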