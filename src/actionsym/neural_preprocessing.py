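"""Spike-train conversion, unit screening, normalization and time-warping.

Spike times become firing-rate functions by convolution with a 0.025 s
Gaussian kernel evaluated on a 0.01 s grid.  Units are screened for a
minimum rate (80th percentile across trials and bins >= 1 Hz), for
systematic drift over the session (|slope of sqrt-rate vs time in hours| /
mean rate > 0.2), and for large rate fluctuations across contiguous 50-trial
bins.  Surviving rates are square-root transformed and soft z-scored,

    x_norm = (sqrt(x) - mu) / (sigma + C),   C = min_units(mean rate) + 3 Hz,

so high-rate units still contribute somewhat more than low-rate ones.
Finally, single-stroke trials can be linearly time-warped segment by
segment onto a median trial template defined by the anchor events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

logger = logging.getLogger("actionsym")

KERNEL_SD_S = 0.025
BIN_SLIDE_S = 0.01
KERNEL_TRUNCATE_SD = 4.0
LOW_RATE_PERCENTILE = 80.0
LOW_RATE_THRESHOLD_HZ = 1.0
DRIFT_RATIO_THRESHOLD = 0.2
FLUCT_SD_THRESHOLD = 1.15
FLUCT_MEAN_THRESHOLD = 0.65
FLUCT_BIN_TRIALS = 50
SOFT_Z_OFFSET_HZ = 3.0
ANCHOR_SMOOTH_SD_S = 0.0025


# ---------------------------------------------------------------------------
# spikes -> rates
# ---------------------------------------------------------------------------

def spikes_to_rates(spike_times_per_trial, window: tuple[float, float],
                    kernel_sd_s: float = KERNEL_SD_S,
                    bin_slide_s: float = BIN_SLIDE_S) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel firing-rate estimate on a 10 ms grid.

    Each trial's spike times (seconds, trial-aligned) are smoothed with a
    Gaussian of s.d. kernel_sd_s truncated at 4 s.d.; the kernel is
    renormalized within the trial window so a single spike always integrates
    to one spike regardless of its distance from the window edge.  Returns
    (rates [trials x bins] in Hz, bin centres).
    """
    t0, t1 = window
    bins = np.arange(t0, t1 + bin_slide_s / 2, bin_slide_s)
    half = KERNEL_TRUNCATE_SD * kernel_sd_s
    rates = np.zeros((len(spike_times_per_trial), len(bins)))
    for i, spikes in enumerate(spike_times_per_trial):
        for s in np.asarray(spikes, dtype=float):
            lo = max(t0, s - half)
            hi = min(t1, s + half)
            if hi <= lo:
                continue
            u = (bins - s) / kernel_sd_s
            k = np.exp(-0.5 * u * u)
            k[np.abs(u) > KERNEL_TRUNCATE_SD] = 0.0
            area = k.sum() * bin_slide_s
            if area > 0:
                rates[i] += k / area
    return rates, bins


# ---------------------------------------------------------------------------
# unit screening
# ---------------------------------------------------------------------------

@dataclass
class UnitScreen:
    unit_id: int
    low_rate: bool
    drift: bool
    fluctuation: bool
    stats: dict
    fluctuation_skipped: bool = False

    @property
    def passed(self) -> bool:
        return not (self.low_rate or self.drift or self.fluctuation)


def _screen_one(rates: np.ndarray, trial_times_h: np.ndarray,
                unit_id: int) -> UnitScreen:
    pct80 = float(np.percentile(rates, LOW_RATE_PERCENTILE))
    low_rate = pct80 < LOW_RATE_THRESHOLD_HZ

    # drift is assessed wholly on the sqrt scale: slope of sqrt-rate vs time
    # in hours over the mean sqrt-rate, so the ratio is 1/hours
    sqrt_means = np.sqrt(np.clip(rates, 0, None)).mean(axis=1)
    u = float(sqrt_means.mean())
    A = np.column_stack([np.ones_like(trial_times_h), trial_times_h])
    m = float(np.linalg.lstsq(A, sqrt_means, rcond=None)[0][1])
    drift = u > 0 and abs(m) / u > DRIFT_RATIO_THRESHOLD

    n_trials = rates.shape[0]
    fluct = False
    skipped = n_trials < 2 * FLUCT_BIN_TRIALS
    stats = {"m": m, "u": u, "pct80": pct80}
    if not skipped:
        n_bins = n_trials // FLUCT_BIN_TRIALS
        s_vals, u_vals = [], []
        for b in range(n_bins):
            chunk = np.sqrt(np.clip(rates[b * FLUCT_BIN_TRIALS:(b + 1) * FLUCT_BIN_TRIALS], 0, None))
            s_vals.append(chunk.mean(axis=1).std())
            u_vals.append(rates[b * FLUCT_BIN_TRIALS:(b + 1) * FLUCT_BIN_TRIALS].mean())
        s_vals, u_vals = np.array(s_vals), np.array(u_vals)
        stats.update(s_max=float(s_vals.max()), s_min=float(s_vals.min()),
                     s_mean=float(s_vals.mean()), u_max=float(u_vals.max()),
                     u_min=float(u_vals.min()), u_mean=float(u_vals.mean()))
        if s_vals.mean() > 0 and (s_vals.max() - s_vals.min()) / s_vals.mean() > FLUCT_SD_THRESHOLD:
            fluct = True
        if u_vals.mean() > 0 and (u_vals.max() - u_vals.min()) / u_vals.mean() > FLUCT_MEAN_THRESHOLD:
            fluct = True
    return UnitScreen(unit_id, low_rate, drift, fluct, stats, skipped)


def screen_units(rates_per_unit, trial_start_times_h) -> list[UnitScreen]:
    """Apply the three exclusion rules to every unit (order-independent).

    rates_per_unit: sequence of (trials x bins) rate matrices in Hz;
    trial_start_times_h: trial start times in hours from session start.
    Fluctuation rules need at least 100 trials (two 50-trial bins); with
    fewer they are skipped and flagged.
    """
    times = np.asarray(trial_start_times_h, dtype=float)
    return [_screen_one(np.asarray(r, float), times, i)
            for i, r in enumerate(rates_per_unit)]


# ---------------------------------------------------------------------------
# soft z-score
# ---------------------------------------------------------------------------

@dataclass
class NormalizationParams:
    mu: np.ndarray       # per unit, mean of sqrt-rate across trials and bins
    sigma: np.ndarray    # per unit, s.d. of sqrt-rate
    C: float             # softness constant: min over units of mean rate + 3 Hz


def fit_normalization(rates: np.ndarray) -> NormalizationParams:
    """Fit soft z-score parameters on a (trials, units, bins) rate tensor."""
    sq = np.sqrt(np.clip(rates, 0, None))
    mu = sq.mean(axis=(0, 2))
    sigma = sq.std(axis=(0, 2))
    mean_rates = rates.mean(axis=(0, 2))
    C = float(mean_rates.min() + SOFT_Z_OFFSET_HZ)
    return NormalizationParams(mu, sigma, C)


def normalize_rates(rates: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """x_norm = (sqrt(x) - mu) / (sigma + C) per unit."""
    sq = np.sqrt(np.clip(rates, 0, None))
    return (sq - params.mu[None, :, None]) / (params.sigma[None, :, None] + params.C)


def denormalize_rates(norm: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Invert :func:`normalize_rates` (round-trips to numerical precision)."""
    sq = norm * (params.sigma[None, :, None] + params.C) + params.mu[None, :, None]
    return sq**2


# ---------------------------------------------------------------------------
# time-warping to a trial template
# ---------------------------------------------------------------------------

@dataclass
class TrialTemplate:
    anchor_names: tuple
    anchor_times: np.ndarray       # template (median) anchor times, s
    segment_durations: np.ndarray  # median durations per segment
    kept_trials: np.ndarray        # trial indices that warped successfully


def timewarp_to_template(rates: np.ndarray, time: np.ndarray,
                         anchors: pd.DataFrame,
                         anchor_names=None) -> tuple[np.ndarray, TrialTemplate]:
    """Warp each trial's rates onto the median trial, linearly per segment.

    rates: (trials, units, bins) on the absolute time grid `time` (trial
    clock).  anchors: one row per trial of anchor event times.  Each
    inter-anchor segment is linearly rescaled to its median duration;
    resampling changes only timing, not rate levels.  Rates are lightly
    smoothed (2.5 ms Gaussian) after warping to remove joint discontinuities.
    Trials with missing or disordered anchors are dropped and logged.
    """
    if anchor_names is None:
        anchor_names = [c for c in anchors.columns if c != "trial_id"]
    A = anchors[list(anchor_names)].to_numpy(dtype=float)

    valid = np.all(np.isfinite(A), axis=1) & np.all(np.diff(A, axis=1) > 0, axis=1)
    dropped = np.flatnonzero(~valid)
    if dropped.size:
        logger.info("timewarp: dropping %d trial(s) with missing/disordered "
                    "anchors: %s", dropped.size, dropped.tolist())
    A = A[valid]
    kept = np.flatnonzero(valid)

    seg_durs = np.median(np.diff(A, axis=1), axis=0)
    template_anchors = np.concatenate([[0.0], np.cumsum(seg_durs)])

    dt = float(np.median(np.diff(time)))
    template_time = np.arange(0.0, template_anchors[-1] + dt / 2, dt)
    warped = np.empty((len(kept), rates.shape[1], len(template_time)))
    for out_i, tr in enumerate(kept):
        a = A[out_i]
        # map template time -> trial time, linear within each segment
        trial_t = np.interp(template_time, template_anchors, a)
        for u in range(rates.shape[1]):
            warped[out_i, u] = np.interp(trial_t, time, rates[tr, u])
    if ANCHOR_SMOOTH_SD_S > 0:
        sd_bins = ANCHOR_SMOOTH_SD_S / dt
        warped = gaussian_filter1d(warped, sd_bins, axis=2, mode="nearest")
    tmpl = TrialTemplate(tuple(anchor_names), template_anchors, seg_durs, kept)
    return warped, tmpl
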