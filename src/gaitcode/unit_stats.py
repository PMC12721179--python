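"""Single-unit statistics around locomotion.

Four analyses, all operating on one unit's spike times plus the
kinematics-stage outputs:

* smoothed peri-onset firing-rate matrices (25 ms counts, Gaussian
  kernel sd 0.1 s, block-averaged to the requested output bin);
* onset modulation: per-time-bin paired t-test of each unit's rate
  against its baseline rate (-1.0 to -0.9 s), and the fraction of units
  significant per bin;
* speed tuning: mean rate in 20 mm/s speed bins from 50 to 310 mm/s
  during walking, with the squared Pearson correlation (R^2) of rate
  against bin-centre speed;
* spike-gait phase locking: occupancy-normalised rates in 24 15-degree
  phase bins, the circular mean resultant (vector) length r in [0, 1]
  and preferred phase, with significance from a +/-0.15 s spike-time
  jitter null (1000 surrogates, locked if r exceeds the 95th
  percentile).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as spstats

from .kinematics import PhaseSeries

__all__ = [
    "RateMatrix",
    "SpeedTuning",
    "PhaseLocking",
    "estimate_rates",
    "modulated_fraction",
    "speed_tuning",
    "phase_locking",
    "jitter_test",
    "binned_vector_length",
]


@dataclass
class RateMatrix:
    """Trials x time-bins firing rates (Hz) around an event."""

    rates: np.ndarray        # (n_trials, n_bins), Hz
    bin_centers: np.ndarray  # s relative to event
    bin_width: float         # s

    def __post_init__(self) -> None:
        if np.any(self.rates < 0):
            raise ValueError("firing rates must be non-negative")


@dataclass
class SpeedTuning:
    """Speed-binned mean rates and their linear-correlation summary."""

    bin_centers: np.ndarray   # mm/s, occupied bins only
    rates: np.ndarray         # Hz per occupied bin
    r_squared: float
    p_value: float
    valid: bool = True        # False when < 3 speed bins were occupied


@dataclass
class PhaseLocking:
    """Spike-gait phase-coupling summary for one unit and one limb."""

    limb: str
    bin_centers_deg: np.ndarray  # 24 centres
    rates: np.ndarray            # occupancy-normalised rate per bin, Hz
    vector_length: float         # r in [0, 1]
    preferred_phase: float       # deg in [0, 360)
    jitter_null: Optional[np.ndarray] = None  # surrogate r values
    is_locked: Optional[bool] = None
    valid: bool = True           # False when no spikes fell during walking


# ---------------------------------------------------------------------------
# Peri-event rates
# ---------------------------------------------------------------------------

def estimate_rates(
    spike_times: np.ndarray,
    event_times: Sequence[float],
    window: tuple[float, float] = (-1.0, 1.0),
    kernel_sd: float = 0.1,
    base_bin: float = 0.025,
    out_bin: float = 0.1,
) -> RateMatrix:
    """Smoothed peri-event rate matrix.

    Spikes are counted in ``base_bin`` increments on a window padded by
    four kernel widths (so smoothing does not leak mass at the edges of
    the analysis window), convolved with a Gaussian kernel, converted to
    Hz, and block-averaged into ``out_bin`` bins.
    """
    ratio = out_bin / base_bin
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"out_bin {out_bin} must be an integer multiple of base_bin {base_bin}"
        )
    ratio = int(round(ratio))
    lo, hi = window
    pad_bins = int(np.ceil(4 * kernel_sd / base_bin))
    n_base = int(round((hi - lo) / base_bin))
    edges = lo + base_bin * np.arange(-pad_bins, n_base + pad_bins + 1)

    spike_times = np.asarray(spike_times, float)
    counts = np.empty((len(event_times), n_base + 2 * pad_bins))
    for i, ev in enumerate(event_times):
        counts[i] = np.histogram(spike_times - ev, bins=edges)[0]

    half = int(np.ceil(4 * kernel_sd / base_bin))
    x = np.arange(-half, half + 1) * base_bin
    kernel = np.exp(-0.5 * (x / kernel_sd) ** 2)
    kernel /= kernel.sum()
    smoothed = np.apply_along_axis(
        lambda row: np.convolve(row, kernel, mode="same"), 1, counts
    )
    core = smoothed[:, pad_bins : pad_bins + n_base] / base_bin  # Hz
    rates = core.reshape(len(event_times), n_base // ratio, ratio).mean(axis=2)
    centers = lo + out_bin * (np.arange(n_base // ratio) + 0.5)
    return RateMatrix(rates=rates, bin_centers=centers, bin_width=out_bin)


def modulated_fraction(
    rate_matrices: Sequence[RateMatrix],
    baseline_window: tuple[float, float] = (-1.0, -0.9),
    alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fraction of units whose rate differs from baseline at each bin.

    For every unit and time bin, a two-sided paired t-test compares the
    per-trial rate in that bin with the per-trial rate in the baseline
    bin. Zero-variance differences (e.g. the baseline bin against
    itself) count as not modulated (p = 1). No multiple-testing
    correction is applied, matching common practice for this per-bin
    descriptive fraction.

    Returns ``(bin_centers, fraction_significant, p_values)`` where
    ``p_values`` has shape (n_units, n_bins).
    """
    first = rate_matrices[0]
    centers = first.bin_centers
    b_lo, b_hi = baseline_window
    base_idx = int(
        np.argmin(np.abs(centers - 0.5 * (b_lo + b_hi)))
    )
    pvals = np.ones((len(rate_matrices), len(centers)))
    for u, rm in enumerate(rate_matrices):
        if rm.rates.shape[0] < 2:
            continue
        base = rm.rates[:, base_idx]
        for j in range(rm.rates.shape[1]):
            diff = rm.rates[:, j] - base
            if np.allclose(diff, diff[0]):
                continue  # zero-variance differences: not modulated
            pvals[u, j] = spstats.ttest_rel(rm.rates[:, j], base).pvalue
    fraction = np.mean(pvals < alpha, axis=0)
    return centers, fraction, pvals


# ---------------------------------------------------------------------------
# Speed tuning
# ---------------------------------------------------------------------------

def speed_tuning(
    spike_times: np.ndarray,
    speed: np.ndarray,
    walking_mask: np.ndarray,
    frame_rate: float = 80.0,
    edges: tuple[float, float, float] = (50.0, 310.0, 20.0),
) -> SpeedTuning:
    """Mean rate per 20 mm/s speed bin during walking, with R^2.

    Empty speed bins are dropped before the correlation; a unit with
    fewer than 3 occupied bins is returned flagged invalid.
    """
    lo, hi, step = edges
    bin_edges = np.arange(lo, hi + step / 2, step)
    centers = bin_edges[:-1] + step / 2
    n_bins = len(centers)

    walking_mask = np.asarray(walking_mask, bool)
    speed = np.asarray(speed, float)
    frame_bin = np.digitize(speed, bin_edges) - 1
    valid_frame = walking_mask & (frame_bin >= 0) & (frame_bin < n_bins)

    occupancy = np.bincount(frame_bin[valid_frame], minlength=n_bins) / frame_rate
    spike_frames = _spike_frames(
        np.asarray(spike_times, float), len(speed), frame_rate
    )
    spike_frames = spike_frames[spike_frames >= 0]
    sf = spike_frames[valid_frame[spike_frames]]
    counts = np.bincount(frame_bin[sf], minlength=n_bins)

    occupied = occupancy > 0
    if occupied.sum() < 3:
        return SpeedTuning(
            bin_centers=centers[occupied],
            rates=np.zeros(occupied.sum()),
            r_squared=np.nan,
            p_value=np.nan,
            valid=False,
        )
    rates = counts[occupied] / occupancy[occupied]
    if np.allclose(rates, rates[0]):
        r, p = 0.0, 1.0
    else:
        r, p = spstats.pearsonr(centers[occupied], rates)
    return SpeedTuning(
        bin_centers=centers[occupied],
        rates=rates,
        r_squared=float(r**2),
        p_value=float(p),
    )


# ---------------------------------------------------------------------------
# Phase locking
# ---------------------------------------------------------------------------

def binned_vector_length(
    rates: np.ndarray, centers_deg: np.ndarray
) -> tuple[float, float]:
    """Mean resultant length and direction of rate-weighted bin centres.

    ``r = |sum_k w_k e^{i theta_k}| / sum_k w_k`` with weights the
    occupancy-normalised rates: 0 for a uniform phase histogram, 1 when
    all rate is concentrated in a single bin.
    """
    w = np.asarray(rates, float)
    theta = np.radians(np.asarray(centers_deg, float))
    total = w.sum()
    if total <= 0:
        return np.nan, np.nan
    resultant = np.sum(w * np.exp(1j * theta)) / total
    return float(np.abs(resultant)), float(np.degrees(np.angle(resultant)) % 360.0)


def _spike_frames(times: np.ndarray, n_frames: int, frame_rate: float) -> np.ndarray:
    """Video frame containing each spike; -1 for spikes outside the session.

    A spike exactly at the session end belongs to the last frame.
    """
    frames = np.floor(np.asarray(times, float) * frame_rate).astype(int)
    frames[frames == n_frames] = n_frames - 1
    frames[(frames < 0) | (frames >= n_frames)] = -1
    return frames


def _phase_bin_lookup(
    phase_series: PhaseSeries, n_bins: int
) -> np.ndarray:
    """Per-frame phase-bin index; -1 outside walking bouts."""
    lookup = np.full(len(phase_series.phase_deg), -1, dtype=int)
    ok = phase_series.mask & np.isfinite(phase_series.phase_deg)
    lookup[ok] = np.minimum(
        (phase_series.phase_deg[ok] / (360.0 / n_bins)).astype(int), n_bins - 1
    )
    return lookup


def phase_locking(
    spike_times: np.ndarray,
    phase_series: PhaseSeries,
    frame_rate: float = 80.0,
    n_bins: int = 24,
) -> PhaseLocking:
    """Spike-gait phase coupling of one unit to one limb.

    Each spike is assigned the phase of the video frame containing it
    (12.5 ms frames; no sub-frame interpolation). Rates per 15-degree
    bin are normalised by the time spent in that bin, which removes
    locomotor-speed occupancy artefacts, and summarised by the circular
    mean resultant length.
    """
    centers = (np.arange(n_bins) + 0.5) * 360.0 / n_bins
    lookup = _phase_bin_lookup(phase_series, n_bins)
    occupancy = np.bincount(lookup[lookup >= 0], minlength=n_bins) / frame_rate

    frames = _spike_frames(np.asarray(spike_times, float), len(lookup), frame_rate)
    spike_bins = lookup[frames[frames >= 0]]
    spike_bins = spike_bins[spike_bins >= 0]
    if spike_bins.size == 0:
        return PhaseLocking(
            limb=phase_series.limb,
            bin_centers_deg=centers,
            rates=np.zeros(n_bins),
            vector_length=np.nan,
            preferred_phase=np.nan,
            valid=False,
        )
    counts = np.bincount(spike_bins, minlength=n_bins)
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.where(occupancy > 0, counts / np.maximum(occupancy, 1e-300), 0.0)
    r, pref = binned_vector_length(rates, centers)
    return PhaseLocking(
        limb=phase_series.limb,
        bin_centers_deg=centers,
        rates=rates,
        vector_length=r,
        preferred_phase=pref,
    )


def jitter_test(
    spike_times: np.ndarray,
    phase_series: PhaseSeries,
    frame_rate: float = 80.0,
    n_bins: int = 24,
    jitter: float = 0.15,
    n_iter: int = 1000,
    seed: int = 0,
) -> PhaseLocking:
    """Jitter-surrogate significance test of phase locking.

    Each surrogate displaces every spike independently by a uniform
    amount in [-jitter, +jitter] s and recomputes the vector length;
    spikes jittered outside walking frames drop out of that surrogate.
    The unit is locked to this limb if the actual r exceeds the 95th
    percentile of the surrogate distribution.
    """
    actual = phase_locking(spike_times, phase_series, frame_rate, n_bins)
    if not actual.valid:
        actual.jitter_null = np.full(n_iter, np.nan)
        actual.is_locked = False
        return actual

    rng = np.random.default_rng(seed)
    lookup = _phase_bin_lookup(phase_series, n_bins)
    occupancy = np.bincount(lookup[lookup >= 0], minlength=n_bins) / frame_rate
    centers = actual.bin_centers_deg

    times = np.asarray(spike_times, float)
    null = np.empty(n_iter)
    for i in range(n_iter):
        jt = times + rng.uniform(-jitter, jitter, size=times.size)
        frames = _spike_frames(jt, len(lookup), frame_rate)
        bins = lookup[frames[frames >= 0]]
        bins = bins[bins >= 0]
        if bins.size == 0:
            null[i] = 0.0
            continue
        counts = np.bincount(bins, minlength=n_bins)
        # same arithmetic path as phase_locking, so a zero-magnitude
        # jitter reproduces the actual r bit for bit
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(occupancy > 0, counts / np.maximum(occupancy, 1e-300), 0.0)
        null[i], _ = binned_vector_length(w, centers)
    actual.jitter_null = null
    actual.is_locked = bool(actual.vector_length > np.quantile(null, 0.95))
    return actual
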