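"""From tracked coordinates to walking bouts, strides, and limb phase.

The processing chain mirrors standard practice for markerless gait
analysis of freely moving rodents:

1. coordinates are smoothed with a third-order Savitzky-Golay filter;
2. whole-body speed is the RMS of the four limb speeds (frame-difference
   displacement times the frame rate);
3. candidate walking bouts come from a sustained speed threshold; each
   onset is refined to the peak in body acceleration within a 50-frame
   window and the bout is kept only if that peak has prominence above
   1000 mm/s^2, lasts at least 1 s, and is at least 1 s from its
   neighbour;
4. limb positions are projected onto the nose-tail axis and band-pass
   filtered 0.5-8 Hz; minima of the filtered limb-to-nose signal mark
   stance onsets, maxima mark swing onsets;
5. instantaneous limb phase is the analytic-signal angle of the filtered
   signal, re-referenced so stance onset sits at 0 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .session import LIMBS, RunConfig, Session, ValidationError

__all__ = [
    "WalkBout",
    "Stride",
    "PhaseSeries",
    "smooth_positions",
    "body_speed",
    "body_acceleration",
    "detect_bouts",
    "project_limb_to_axis",
    "bandpass_gait",
    "segment_strides",
    "limb_phase",
    "segment_session",
]


@dataclass(frozen=True)
class WalkBout:
    """One accepted walking bout, onset-aligned to the acceleration peak."""

    onset_frame: int
    offset_frame: int
    peak_prominence: float

    def duration(self, frame_rate: float) -> float:
        return (self.offset_frame - self.onset_frame) / frame_rate


@dataclass(frozen=True)
class Stride:
    """One gait cycle of one limb: stance onset -> swing onset -> next stance."""

    limb: str
    stance_onset_frame: int
    swing_onset_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if not (self.stance_onset_frame < self.swing_onset_frame < self.end_frame):
            raise ValidationError(
                f"stride frames must be ordered: {self.stance_onset_frame} < "
                f"{self.swing_onset_frame} < {self.end_frame}"
            )

    def duration(self, frame_rate: float) -> float:
        return (self.end_frame - self.stance_onset_frame) / frame_rate


@dataclass
class PhaseSeries:
    """Per-frame instantaneous gait phase of one limb, degrees in [0, 360).

    ``phase_deg`` has one entry per session frame; it is NaN wherever
    ``mask`` is False (outside walking bouts).
    """

    limb: str
    phase_deg: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.phase_deg = np.asarray(self.phase_deg, float)
        self.mask = np.asarray(self.mask, bool)
        if self.phase_deg.shape != self.mask.shape:
            raise ValidationError("phase and mask must have equal length")


# ---------------------------------------------------------------------------
# Smoothing and speed
# ---------------------------------------------------------------------------

def smooth_positions(
    kinematics: pd.DataFrame,
    window_frames: int = 7,
    polyorder: int = 3,
) -> pd.DataFrame:
    """Savitzky-Golay smooth every coordinate channel.

    Endpoints are handled by fitting the edge polynomial to the last full
    window (scipy's ``interp`` mode), which reproduces any polynomial of
    degree <= ``polyorder`` exactly.
    """
    if window_frames < polyorder + 2:
        raise ValueError(
            f"window_frames={window_frames} too short for polyorder={polyorder}"
        )
    out = kinematics.copy()
    for col in out.columns:
        if col == "frame":
            continue
        out[col] = sps.savgol_filter(
            out[col].to_numpy(float), window_frames, polyorder, mode="interp"
        )
    return out


def body_speed(kinematics: pd.DataFrame, frame_rate: float = 80.0) -> np.ndarray:
    """Whole-body speed: RMS of the four limb speeds, mm/s.

    Per-limb speed is the frame-difference displacement magnitude times
    the frame rate; the first frame repeats the second so the output has
    one value per frame.
    """
    speeds = np.empty((len(kinematics), len(LIMBS)))
    for j, limb in enumerate(LIMBS):
        x = kinematics[f"{limb}_x"].to_numpy(float)
        y = kinematics[f"{limb}_y"].to_numpy(float)
        d = np.hypot(np.diff(x), np.diff(y)) * frame_rate
        speeds[1:, j] = d
        speeds[0, j] = d[0] if len(d) else 0.0
    return np.sqrt(np.mean(speeds**2, axis=1))


def body_acceleration(speed: np.ndarray, frame_rate: float = 80.0) -> np.ndarray:
    """Centered-difference derivative of body speed, mm/s^2."""
    return np.gradient(np.asarray(speed, float)) * frame_rate


# ---------------------------------------------------------------------------
# Bout detection
# ---------------------------------------------------------------------------

def _candidate_windows(
    speed: np.ndarray, threshold: float, min_frames: int
) -> list[tuple[int, int]]:
    """Contiguous runs of speed >= threshold lasting >= min_frames."""
    above = speed >= threshold
    edges = np.diff(above.astype(int), prepend=0, append=0)
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)
    # bridge sub-half-second dips so one bout yields one candidate
    merged: list[tuple[int, int]] = []
    for a, b in zip(starts, stops):
        if merged and a - merged[-1][1] < min_frames:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    return [(a, b) for a, b in merged if b - a >= min_frames]


def detect_bouts(
    speed: np.ndarray,
    frame_rate: float = 80.0,
    config: RunConfig | None = None,
) -> list[WalkBout]:
    """Detect walking bouts from the body-speed trace.

    Candidate episodes are runs where speed stays above the threshold for
    the sustained minimum. Each preliminary onset (threshold crossing) is
    refined to the frame of peak positive body acceleration within the
    centered 50-frame window; candidates whose peak prominence is not
    above 1000 mm/s^2 are discarded, as are bouts shorter than 1 s.  Of
    any two accepted onsets closer than 1 s, the later is dropped.
    """
    cfg = config or RunConfig()
    speed = np.asarray(speed, float)
    accel = body_acceleration(speed, frame_rate)
    pos_accel = np.clip(accel, 0.0, None)
    min_frames = int(round(cfg.min_sustained * frame_rate))
    half_win = cfg.accel_window_frames // 2
    off_frames = int(round(0.25 * frame_rate))

    bouts: list[WalkBout] = []
    for start, stop in _candidate_windows(speed, cfg.speed_threshold, min_frames):
        if bouts and start < bouts[-1].offset_frame:
            continue  # candidate inside an already-accepted bout
        lo = max(0, start - half_win)
        hi = min(len(speed), start + half_win + 1)
        peaks, props = sps.find_peaks(pos_accel[lo:hi], prominence=0.0)
        if peaks.size == 0:
            continue
        best = int(np.argmax(props["prominences"]))
        prominence = float(props["prominences"][best])
        if prominence <= cfg.prominence_threshold:
            continue
        onset = lo + int(peaks[best])
        offset = _bout_offset(speed, onset, stop, cfg.speed_threshold, off_frames)
        if (offset - onset) / frame_rate < cfg.min_bout_duration:
            continue
        bouts.append(WalkBout(onset, offset, prominence))

    # of any pair of bouts separated by less than the minimum, keep the earlier
    kept: list[WalkBout] = []
    min_sep = cfg.min_bout_separation * frame_rate
    for bout in sorted(bouts, key=lambda b: b.onset_frame):
        if kept and bout.onset_frame - kept[-1].offset_frame < min_sep:
            continue
        kept.append(bout)
    return kept


def _bout_offset(
    speed: np.ndarray, onset: int, candidate_stop: int, threshold: float,
    off_frames: int,
) -> int:
    """First frame after onset where speed stays below threshold >= 0.25 s."""
    below = speed[onset:] < threshold
    run = 0
    for i, b in enumerate(below):
        run = run + 1 if b else 0
        if run >= off_frames:
            return onset + i - off_frames + 1
    return max(candidate_stop, onset + 1)


# ---------------------------------------------------------------------------
# Limb-to-nose projection, band-pass, strides, phase
# ---------------------------------------------------------------------------

def project_limb_to_axis(kinematics: pd.DataFrame, limb: str) -> np.ndarray:
    """Limb position along the nose-tail axis, measured back from the nose.

    The signal is small when the limb is closest to the nose (stance
    onset) and large when furthest (swing onset). Units mm.
    """
    nose = kinematics[["nose_x", "nose_y"]].to_numpy(float)
    tail = kinematics[["tail_x", "tail_y"]].to_numpy(float)
    pos = kinematics[[f"{limb}_x", f"{limb}_y"]].to_numpy(float)
    axis = nose - tail
    norm = np.linalg.norm(axis, axis=1)
    norm[norm == 0] = 1.0
    u = axis / norm[:, None]
    return np.einsum("ij,ij->i", nose - pos, u)


def bandpass_gait(
    projected: np.ndarray,
    frame_rate: float = 80.0,
    band: tuple[float, float] = (0.5, 8.0),
    order: int = 2,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass of the projected limb signal.

    A second-order filter applied forward and backward removes DC and
    attenuates content outside the gait band by well over 20 dB while
    leaving stride-frequency components essentially untouched.
    """
    projected = np.asarray(projected, float)
    sos = sps.butter(order, band, btype="bandpass", fs=frame_rate, output="sos")
    # effective FIR-equivalent tap count of one biquad section
    filt_len = 5 * (2 * order + 1)
    if projected.size < 3 * filt_len:
        raise ValueError(
            f"signal of {projected.size} samples shorter than 3 filter lengths "
            f"({3 * filt_len})"
        )
    return sps.sosfiltfilt(sos, projected)


def segment_strides(
    filtered: np.ndarray,
    bout: WalkBout,
    limb: str,
    frame_rate: float = 80.0,
    max_gait_hz: float = 8.0,
) -> list[Stride]:
    """Segment one bout of a filtered limb signal into strides.

    Stance onsets are the local minima of the filtered limb-to-nose
    signal, swing onsets the maxima. A stride runs stance onset ->
    swing onset -> next stance onset; partial cycles at bout edges are
    dropped, as are minima/maxima pairs that do not alternate cleanly.
    """
    seg = np.asarray(filtered, float)[bout.onset_frame : bout.offset_frame]
    if seg.size < 3:
        return []
    min_dist = max(2, int(0.5 * frame_rate / max_gait_hz))
    # small prominence floor rejects tracker-noise wiggles
    floor = 0.1 * np.std(seg)
    minima, _ = sps.find_peaks(-seg, distance=min_dist, prominence=floor)
    maxima, _ = sps.find_peaks(seg, distance=min_dist, prominence=floor)
    strides: list[Stride] = []
    for a, b in zip(minima[:-1], minima[1:]):
        between = maxima[(maxima > a) & (maxima < b)]
        if between.size != 1:
            continue
        strides.append(
            Stride(
                limb=limb,
                stance_onset_frame=bout.onset_frame + int(a),
                swing_onset_frame=bout.onset_frame + int(between[0]),
                end_frame=bout.onset_frame + int(b),
            )
        )
    return strides


def limb_phase(
    filtered: np.ndarray,
    bouts: list[WalkBout],
    limb: str,
) -> PhaseSeries:
    """Instantaneous gait phase from the analytic signal.

    The Hilbert-transform angle of the band-passed limb-to-nose signal is
    shifted by +180 deg so that signal minima (stance onsets) map to
    0 deg, then wrapped to [0, 360). Phase is defined only on frames
    inside accepted bouts.
    """
    filtered = np.asarray(filtered, float)
    if not np.any(filtered):
        raise ValidationError("all-zero signal: phase undefined")
    analytic = sps.hilbert(filtered)
    phase = (np.degrees(np.angle(analytic)) + 180.0) % 360.0
    mask = np.zeros(filtered.size, dtype=bool)
    for bout in bouts:
        mask[bout.onset_frame : bout.offset_frame] = True
    out = np.where(mask, phase, np.nan)
    return PhaseSeries(limb=limb, phase_deg=out, mask=mask)


# ---------------------------------------------------------------------------
# Session-level driver
# ---------------------------------------------------------------------------

@dataclass
class SegmentedSession:
    """All kinematics-stage outputs for one session."""

    session: Session
    smoothed: pd.DataFrame
    speed: np.ndarray
    bouts: list[WalkBout]
    strides: dict[str, list[Stride]]
    phases: dict[str, PhaseSeries]
    filtered: dict[str, np.ndarray]

    @property
    def walking_mask(self) -> np.ndarray:
        mask = np.zeros(len(self.smoothed), dtype=bool)
        for bout in self.bouts:
            mask[bout.onset_frame : bout.offset_frame] = True
        return mask


def segment_session(session: Session, config: RunConfig | None = None) -> SegmentedSession:
    """Run the full kinematics chain on one session."""
    cfg = config or RunConfig()
    fr = session.frame_rate
    smoothed = smooth_positions(
        session.kinematics, cfg.savgol_window, cfg.savgol_polyorder
    )
    speed = body_speed(smoothed, fr)
    bouts = detect_bouts(speed, fr, cfg)
    strides: dict[str, list[Stride]] = {}
    phases: dict[str, PhaseSeries] = {}
    filtered: dict[str, np.ndarray] = {}
    for limb in LIMBS:
        proj = project_limb_to_axis(smoothed, limb)
        filt = bandpass_gait(proj, fr, (cfg.band_low, cfg.band_high))
        filtered[limb] = filt
        strides[limb] = [
            s for bout in bouts for s in segment_strides(filt, bout, limb, fr)
        ]
        if bouts and np.any(filt):
            phases[limb] = limb_phase(filt, bouts, limb)
        else:
            phases[limb] = PhaseSeries(
                limb, np.full(len(filt), np.nan), np.zeros(len(filt), bool)
            )
    return SegmentedSession(
        session=session,
        smoothed=smoothed,
        speed=speed,
        bouts=bouts,
        strides=strides,
        phases=phases,
        filtered=filtered,
    )
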