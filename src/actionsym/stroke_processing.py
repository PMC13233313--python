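"""Touchscreen preprocessing and stroke segmentation.

Raw touch data arrive as (t, x, y, touching) samples at the screen refresh
rate (60 Hz, 33.6 px/cm).  The pipeline upsamples them to a uniform 500 Hz
grid, low-pass filters position at 15 Hz to keep only drawing-related
movement, and cuts the series into strokes at maximal runs of the touching
flag.  Velocity and speed are computed with a five-point finite-difference
stencil after an additional 12.5 Hz low-pass and 25 Hz downsampling step,
then brought back to 500 Hz with a cubic spline.

Coordinate convention: analysis space has y increasing upward; readers of
screen dumps are expected to flip the y axis on ingest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import CubicSpline, interp1d

PX_PER_CM = 33.6
SOURCE_RATE_HZ = 60.0
TARGET_RATE_HZ = 500.0
POSITION_LOWPASS_HZ = 15.0
VELOCITY_LOWPASS_HZ = 12.5
VELOCITY_DOWNSAMPLE_HZ = 25.0


@dataclass
class TouchSeries:
    """Time-stamped touchscreen samples.

    Attributes
    ----------
    t : array of sample times in seconds, strictly increasing.
    x, y : finger position in pixels.
    touching : boolean flag per sample (finger on screen).
    rate_hz : nominal sampling rate.
    px_per_cm : screen resolution conversion.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    touching: np.ndarray
    rate_hz: float = SOURCE_RATE_HZ
    px_per_cm: float = PX_PER_CM

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.touching = np.asarray(self.touching, dtype=bool)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("sample times must be strictly increasing")


@dataclass
class Stroke:
    """One touch-down -> touch-up segment of a drawing.

    Positions are in pixels on the (uniform) sample grid ``t``; velocity and
    speed, when present, are per-sample derivatives in px/s.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    vx: np.ndarray | None = None
    vy: np.ndarray | None = None
    speed: np.ndarray | None = None
    trial_id: int = 0
    stroke_index: int = 0

    @property
    def onset_t(self) -> float:
        return float(self.t[0])

    @property
    def offset_t(self) -> float:
        return float(self.t[-1])

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def path_length(self) -> float:
        """Cumulative distance travelled ("ink"), px."""
        return float(np.sum(np.hypot(np.diff(self.x), np.diff(self.y))))


def _zero_phase_lowpass(values: np.ndarray, cutoff_hz: float, rate_hz: float,
                        order: int = 4) -> np.ndarray:
    """Order-4 Butterworth, applied forward-backward (zero phase).

    Zero-phase filtering avoids onset shifts that would bias stroke timing.
    """
    nyq = rate_hz / 2.0
    if cutoff_hz >= nyq:
        return values
    b, a = signal.butter(order, cutoff_hz / nyq)
    padlen = min(3 * max(len(a), len(b)), len(values) - 1)
    return signal.filtfilt(b, a, values, padlen=padlen)


def preprocess_touch_series(raw: TouchSeries,
                            target_rate_hz: float = TARGET_RATE_HZ,
                            lowpass_hz: float = POSITION_LOWPASS_HZ) -> TouchSeries:
    """Upsample to a uniform 500 Hz grid and low-pass position at 15 Hz.

    Position is linearly interpolated onto the grid before filtering; the
    touching flag is carried through by previous-sample hold so stroke
    boundaries stay aligned with the original touch events.
    """
    if raw.t.size < 4:
        raise ValueError("need at least 4 samples to preprocess")
    dt = 1.0 / target_rate_hz
    grid = np.arange(raw.t[0], raw.t[-1] + dt / 2, dt)
    x = np.interp(grid, raw.t, raw.x)
    y = np.interp(grid, raw.t, raw.y)
    touch_f = interp1d(raw.t, raw.touching.astype(float), kind="previous",
                       bounds_error=False, fill_value=(raw.touching[0], raw.touching[-1]))
    touching = touch_f(grid) > 0.5
    x = _zero_phase_lowpass(x, lowpass_hz, target_rate_hz)
    y = _zero_phase_lowpass(y, lowpass_hz, target_rate_hz)
    return TouchSeries(grid, x, y, touching, rate_hz=target_rate_hz,
                       px_per_cm=raw.px_per_cm)


def differentiate_five_point(values: np.ndarray, h: float) -> np.ndarray:
    """Finite-difference derivative by the five-point stencil.

    Interior points use f'[n] = (f[n-2] - 8 f[n-1] + 8 f[n+1] - f[n+2]) / (12 h),
    exact for polynomials up to degree 4.  The first and last two points fall
    back to one-sided second-order differences.
    """
    f = np.asarray(values, dtype=float)
    if f.size < 5:
        raise ValueError("need at least 5 samples for the five-point stencil")
    d = np.empty_like(f)
    d[2:-2] = (f[:-4] - 8 * f[1:-3] + 8 * f[3:-1] - f[4:]) / (12 * h)
    # one-sided second-order at the edges
    d[0] = (-3 * f[0] + 4 * f[1] - f[2]) / (2 * h)
    d[1] = (-3 * f[1] + 4 * f[2] - f[3]) / (2 * h)
    d[-2] = (3 * f[-2] - 4 * f[-3] + f[-4]) / (2 * h)
    d[-1] = (3 * f[-1] - 4 * f[-2] + f[-3]) / (2 * h)
    return d


def _stroke_velocity(t: np.ndarray, x: np.ndarray, y: np.ndarray,
                     rate_hz: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Velocity via 12.5 Hz low-pass, 25 Hz downsample, stencil, spline back."""
    step = max(1, int(round(rate_hz / VELOCITY_DOWNSAMPLE_HZ)))
    if t.size < 5 * step:
        # short stroke: differentiate on the native grid
        vx = differentiate_five_point(x, 1.0 / rate_hz) if t.size >= 5 else np.gradient(x, t)
        vy = differentiate_five_point(y, 1.0 / rate_hz) if t.size >= 5 else np.gradient(y, t)
        return vx, vy, np.hypot(vx, vy)
    xf = _zero_phase_lowpass(x, VELOCITY_LOWPASS_HZ, rate_hz)
    yf = _zero_phase_lowpass(y, VELOCITY_LOWPASS_HZ, rate_hz)
    td, xd, yd = t[::step], xf[::step], yf[::step]
    hd = step / rate_hz
    vxd = differentiate_five_point(xd, hd)
    vyd = differentiate_five_point(yd, hd)
    vx = CubicSpline(td, vxd)(t)
    vy = CubicSpline(td, vyd)(t)
    return vx, vy, np.hypot(vx, vy)


def segment_strokes(series: TouchSeries, trial_id: int = 0,
                    compute_velocity: bool = True) -> list[Stroke]:
    """Cut a preprocessed series into strokes at maximal touching runs.

    Returns strokes ordered by onset; an empty list if the finger never
    touches.  Runs shorter than two samples are dropped (no extent).
    """
    touching = series.touching.astype(int)
    edges = np.diff(np.concatenate([[0], touching, [0]]))
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)
    strokes: list[Stroke] = []
    for k, (i, j) in enumerate(zip(starts, stops)):
        if j - i < 2:
            continue
        t, x, y = series.t[i:j], series.x[i:j], series.y[i:j]
        vx = vy = sp = None
        if compute_velocity:
            vx, vy, sp = _stroke_velocity(t, x, y, series.rate_hz)
        strokes.append(Stroke(t, x, y, vx, vy, sp,
                              trial_id=trial_id, stroke_index=len(strokes)))
    return strokes


def touch_series_to_frame(series: TouchSeries, trial_id: int = 0) -> pd.DataFrame:
    """Long-format sample table (trial_id, t_s, x_px, y_px, touching_flag)."""
    return pd.DataFrame({
        "trial_id": trial_id,
        "t_s": series.t,
        "x_px": series.x,
        "y_px": series.y,
        "touching_flag": series.touching.astype(int),
    })


def frame_to_touch_series(frame: pd.DataFrame, trial_id: int | None = None,
                          rate_hz: float = SOURCE_RATE_HZ) -> TouchSeries:
    """Inverse of :func:`touch_series_to_frame` for one trial."""
    if trial_id is not None:
        frame = frame[frame["trial_id"] == trial_id]
    return TouchSeries(frame["t_s"].to_numpy(), frame["x_px"].to_numpy(),
                       frame["y_px"].to_numpy(),
                       frame["touching_flag"].to_numpy().astype(bool),
                       rate_hz=rate_hz)
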