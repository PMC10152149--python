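"""Statistics computed from comet tracks.

Operates on per-frame track tables (time, position, comet length/area,
velocity, intensity) of the kind produced by threshold/skeletonize/track
image pipelines.  Image processing itself is out of scope; tracks arrive
as CSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import curve_fit
from scipy.stats import linregress

__all__ = [
    "CometTrack",
    "DecayFit",
    "CycleSeries",
    "read_tracks_csv",
    "write_tracks_csv",
    "instantaneous_velocity",
    "motility_half_life",
    "cumulative_polymerized",
    "cycle_count",
    "consumption_rate",
    "tail_fraction",
    "decay_time_constant",
    "disassembly_speed",
    "estimate_kplus",
]

#: canonical monomer-pool length equivalent, um (mean comet length 63 um
#: divided by the 0.57 polymerized fraction); configurable everywhere it is used
DEFAULT_L_MAX = 110.0

TRACK_COLUMNS = [
    "track_id",
    "frame",
    "time_min",
    "x_um",
    "y_um",
    "comet_length_um",
    "comet_area_um2",
    "bead_velocity_um_per_min",
    "actin_intensity_au",
]


@dataclass(frozen=True)
class CometTrack:
    """One comet's per-frame observables.  Optional fields may be ``None``."""

    track_id: str
    time_min: np.ndarray
    x_um: np.ndarray | None = None
    y_um: np.ndarray | None = None
    comet_length_um: np.ndarray | None = None
    comet_area_um2: np.ndarray | None = None
    bead_velocity_um_per_min: np.ndarray | None = None
    actin_intensity_au: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, dtype=float)
        object.__setattr__(self, "time_min", t)
        if t.ndim != 1 or len(t) < 1:
            raise ValueError("time_min must be a non-empty 1-D array")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time_min must be strictly increasing")
        for name in (
            "x_um",
            "y_um",
            "comet_length_um",
            "comet_area_um2",
            "bead_velocity_um_per_min",
            "actin_intensity_au",
        ):
            value = getattr(self, name)
            if value is None:
                continue
            arr = np.asarray(value, dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != t.shape:
                raise ValueError(f"{name} must match time_min in length")
        for name in ("comet_length_um", "comet_area_um2"):
            arr = getattr(self, name)
            if arr is not None and np.any(arr < 0):
                raise ValueError(f"{name} must be nonnegative")

    @property
    def n_frames(self) -> int:
        return len(self.time_min)

    def to_dataframe(self) -> pd.DataFrame:
        n = self.n_frames
        data = {
            "track_id": [self.track_id] * n,
            "frame": np.arange(n),
            "time_min": self.time_min,
        }
        for name in TRACK_COLUMNS[3:]:
            value = getattr(self, name)
            data[name] = np.full(n, np.nan) if value is None else value
        return pd.DataFrame(data)


def _column_or_none(df: pd.DataFrame, name: str) -> np.ndarray | None:
    if name not in df.columns or df[name].isna().all():
        return None
    return df[name].to_numpy(dtype=float)


def read_tracks_csv(path) -> list[CometTrack]:
    """Read a long-format track table (one row per track per frame)."""
    df = pd.read_csv(path)
    missing = {"track_id", "time_min"} - set(df.columns)
    if missing:
        raise ValueError(f"track CSV missing required columns: {sorted(missing)}")
    tracks = []
    for track_id, group in df.groupby("track_id", sort=True):
        group = group.sort_values("time_min")
        tracks.append(
            CometTrack(
                track_id=str(track_id),
                time_min=group["time_min"].to_numpy(dtype=float),
                x_um=_column_or_none(group, "x_um"),
                y_um=_column_or_none(group, "y_um"),
                comet_length_um=_column_or_none(group, "comet_length_um"),
                comet_area_um2=_column_or_none(group, "comet_area_um2"),
                bead_velocity_um_per_min=_column_or_none(group, "bead_velocity_um_per_min"),
                actin_intensity_au=_column_or_none(group, "actin_intensity_au"),
            )
        )
    return tracks


def write_tracks_csv(tracks: Sequence[CometTrack], path) -> None:
    pd.concat([t.to_dataframe() for t in tracks], ignore_index=True).to_csv(path, index=False)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    # centered, partial windows at the edges
    return (
        pd.Series(x).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def instantaneous_velocity(
    track: CometTrack, window: int = 5, source: str = "auto"
) -> np.ndarray:
    """Per-frame speed (um/min) by central differences plus moving-average smoothing.

    ``source`` selects the underlying signal: ``"position"`` (magnitude of
    the (x, y) displacement rate), ``"length"`` (comet length differences),
    or ``"auto"`` (positions when present, else length).  The smoothing
    window is in frames, must be odd; endpoints use one-sided differences.
    """
    if track.n_frames < 2:
        raise ValueError("velocity needs at least 2 frames")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd number of frames")
    if source == "auto":
        source = "position" if track.x_um is not None else "length"
    if source == "position":
        if track.x_um is None or track.y_um is None:
            raise ValueError("track has no position columns")
        vx = np.gradient(track.x_um, track.time_min)
        vy = np.gradient(track.y_um, track.time_min)
        speed = np.hypot(vx, vy)
    elif source == "length":
        if track.comet_length_um is None:
            raise ValueError("track has no comet_length_um column")
        speed = np.gradient(track.comet_length_um, track.time_min)
    else:
        raise ValueError(f"unknown source {source!r}")
    return _moving_average(speed, window)


@dataclass(frozen=True)
class DecayFit:
    """Single-exponential fit ``A * exp(-rate * t)``; ``ok`` is False for no-fit."""

    ok: bool
    amplitude: float | None = None
    rate: float | None = None
    unit: str = "per_min"
    r_squared: float | None = None
    message: str = ""

    @property
    def tau(self) -> float | None:
        return None if self.rate is None else 1.0 / self.rate

    @property
    def half_life(self) -> float | None:
        return None if self.rate is None else math.log(2.0) / self.rate


def _fit_exponential(time: np.ndarray, values: np.ndarray, unit: str) -> DecayFit:
    mask = values > 0
    if mask.sum() < 5:
        return DecayFit(ok=False, unit=unit, message="fewer than 5 positive points")
    t, v = time[mask], values[mask]
    # log-linear initialization
    slope, intercept = np.polyfit(t, np.log(v), 1)
    span = float(t.max() - t.min())
    # require a non-negligible total decay over the observation window
    if slope * span >= -1e-9:
        return DecayFit(ok=False, unit=unit, message="series is not decaying")
    p0 = (math.exp(intercept), -slope)
    try:
        popt, _ = curve_fit(
            lambda tt, a, lam: a * np.exp(-lam * tt), t, v, p0=p0, maxfev=10000
        )
    except RuntimeError as exc:  # pragma: no cover - pathological data
        return DecayFit(ok=False, unit=unit, message=f"fit failed: {exc}")
    amplitude, rate = float(popt[0]), float(popt[1])
    if rate <= 0:
        return DecayFit(ok=False, unit=unit, message="fitted rate is non-positive")
    pred = amplitude * np.exp(-rate * t)
    ss_res = float(np.sum((v - pred) ** 2))
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return DecayFit(ok=True, amplitude=amplitude, rate=rate, unit=unit, r_squared=r2)


def motility_half_life(
    velocities: np.ndarray, time: np.ndarray, time_unit: str = "min"
) -> DecayFit:
    """Exponential fit to a bead-velocity curve; half-life is ln2 / rate."""
    time = np.asarray(time, dtype=float)
    velocities = np.asarray(velocities, dtype=float)
    if time.shape != velocities.shape:
        raise ValueError("time and velocity series must have the same length")
    return _fit_exponential(time, velocities, unit=f"per_{time_unit}")


@dataclass(frozen=True)
class CycleSeries:
    """Cumulative polymerized length and its pool-cycle conversion."""

    time_min: np.ndarray
    cumulative_length_um: np.ndarray
    cycles: np.ndarray | None = None
    consumption_rate_uM_per_h: np.ndarray | None = None


def cumulative_polymerized(
    velocities: np.ndarray, time: np.ndarray, *, clip_negative: bool = False
) -> CycleSeries:
    """Trapezoidal integral of the velocity curve: cumulative polymerized length.

    Negative velocities (tracking jitter) raise unless ``clip_negative``
    is explicitly set, in which case they are clipped to 0 first.
    """
    time = np.asarray(time, dtype=float)
    v = np.asarray(velocities, dtype=float)
    if time.shape != v.shape:
        raise ValueError("time and velocity series must have the same length")
    if np.any(v < 0):
        if not clip_negative:
            raise ValueError(
                "negative velocities present; pass clip_negative=True to clip them"
            )
        v = np.clip(v, 0.0, None)
    cum = cumulative_trapezoid(v, time, initial=0.0)
    return CycleSeries(time_min=time, cumulative_length_um=cum)


def cycle_count(series: CycleSeries, l_max: float = DEFAULT_L_MAX) -> CycleSeries:
    """Convert cumulative length into monomer-pool cycles (cum / l_max)."""
    if l_max <= 0:
        raise ValueError("l_max must be positive")
    cycles = series.cumulative_length_um / l_max
    return CycleSeries(
        time_min=series.time_min,
        cumulative_length_um=series.cumulative_length_um,
        cycles=cycles,
        consumption_rate_uM_per_h=series.consumption_rate_uM_per_h,
    )


def consumption_rate(
    series: CycleSeries,
    G_bar: float = 3.0,
    l_max: float = DEFAULT_L_MAX,
    window_min: float = 10.0,
) -> CycleSeries:
    """Windowed monomer consumption rate in uM/h.

    The slope of the cumulative length (um/min) is smoothed over a
    centered window of ``window_min`` minutes and converted with
    ``60 * G_bar / l_max``.
    """
    t = series.time_min
    if len(t) < 2:
        raise ValueError("need at least two samples")
    dt = float(np.median(np.diff(t)))
    if window_min < 2 * dt:
        raise ValueError("window must span at least two sample intervals")
    slope = np.gradient(series.cumulative_length_um, t)
    frames = max(1, int(round(window_min / dt)))
    if frames % 2 == 0:
        frames += 1
    smoothed = _moving_average(slope, frames)
    rate = smoothed * 60.0 * G_bar / l_max
    return CycleSeries(
        time_min=t,
        cumulative_length_um=series.cumulative_length_um,
        cycles=series.cycles,
        consumption_rate_uM_per_h=rate,
    )


def tail_fraction(
    comet_intensity: float, total_intensity: float, background: float | tuple = 0.0
) -> float:
    """Fraction of the well's actin in the comet, from background-corrected intensities.

    ``background`` is either one value subtracted from both intensities or
    a ``(bg_comet, bg_total)`` pair.
    """
    if isinstance(background, (tuple, list)):
        bg_comet, bg_total = background
    else:
        bg_comet = bg_total = float(background)
    corrected_total = total_intensity - bg_total
    if corrected_total <= 0:
        raise ValueError("background-corrected total intensity must be positive")
    return (comet_intensity - bg_comet) / corrected_total


def decay_time_constant(intensities: np.ndarray, time_min: np.ndarray) -> DecayFit:
    """Single-exponential fit to a defect-intensity trace; tau in minutes."""
    time_min = np.asarray(time_min, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if time_min.shape != intensities.shape:
        raise ValueError("time and intensity series must have the same length")
    if len(time_min) < 5:
        raise ValueError("need at least 5 points")
    return _fit_exponential(time_min, intensities, unit="per_min")


def disassembly_speed(comet_length_um: float, tau_min: float) -> float:
    """Network disassembly speed: comet length / decay time constant, um/min."""
    if comet_length_um <= 0 or tau_min <= 0:
        raise ValueError("length and tau must be positive")
    return comet_length_um / tau_min


def estimate_kplus(
    filament_lengths_um: np.ndarray,
    time_s: np.ndarray,
    G_uM: float,
    subunit_rise_um: float = 0.0027,
) -> tuple[float, bool]:
    """Barbed-end association rate constant from filament elongation.

    Least-squares slope of length vs time (um/s) divided by
    ``subunit_rise * G`` gives k+ in subunits/(uM * s).  Returns
    ``(k_plus, depolymerizing)`` where the flag marks a negative slope.
    """
    lengths = np.asarray(filament_lengths_um, dtype=float)
    time_s = np.asarray(time_s, dtype=float)
    if len(lengths) < 3:
        raise ValueError("need at least 3 points")
    if G_uM <= 0 or subunit_rise_um <= 0:
        raise ValueError("G and subunit rise must be positive")
    slope = float(linregress(time_s, lengths).slope)
    return slope / (subunit_rise_um * G_uM), slope < 0
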