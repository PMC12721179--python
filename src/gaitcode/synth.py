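"""Synthetic sessions with known ground truth.

The generator emulates the statistical structure the analysis assumes:
80 Hz coordinates of six tracked features in which quiescent epochs
alternate with walking bouts of rhythmic, trot-patterned limb motion,
plus single-unit spike trains produced by an inhomogeneous Poisson
process whose log intensity combines a pre-onset ramp, a body-speed
gain, and von Mises gait-phase tuning.

Everything that the downstream stages try to recover — bout onsets,
per-frame limb phase, body speed, and each unit's tuning parameters —
is returned alongside the data, so parameter-recovery tests can compare
estimate against truth.

Kinematic model
---------------
During a bout the body translates along a slowly turning heading at a
speed following an Ornstein-Uhlenbeck walk inside the configured range;
the bout begins with a raised-cosine speed rise steep enough to exceed
the 1000 mm/s^2 acceleration-prominence filter. Each limb oscillates
along the body axis at the stride frequency with trot phase offsets
(left-fore with right-rear, right-fore with left-rear, the two diagonal
pairs 180 degrees apart). The oscillation amplitude scales with body
speed (a stationary stance limb, a fast swing limb), and all coordinates
carry additive Gaussian tracking noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .session import LIMBS, KINEMATICS_COLUMNS, Session, SpikeTrain, ValidationError, derive_seed

__all__ = [
    "GaitParams",
    "TuningProfile",
    "RegionProfile",
    "CohortSpec",
    "KinematicsTruth",
    "Cohort",
    "M1_LIKE",
    "DMS_LIKE",
    "generate_kinematics",
    "generate_spikes",
    "generate_session",
    "generate_cohort",
]

#: Trot inter-limb phase offsets in degrees relative to the left rear limb.
TROT_OFFSETS = {"lr": 0.0, "rf": 0.0, "lf": 180.0, "rr": 180.0}


@dataclass
class GaitParams:
    """Parameters of the synthetic walking behaviour.

    ``stride_amplitude`` is the limb-oscillation displacement amplitude at
    the reference body speed of 235 mm/s; the effective amplitude scales
    linearly with instantaneous speed so that stance limbs are nearly
    stationary in the lab frame.
    """

    stride_frequency: float = 2.5        # Hz
    stride_amplitude: float = 15.0       # mm at 235 mm/s reference speed
    phase_offsets_deg: dict = field(default_factory=lambda: dict(TROT_OFFSETS))
    bout_duration: float = 4.0           # s, mean; individual bouts 0.5-1.5x
    inter_bout_gap: float = 4.0          # s, mean; min 1 s
    speed_range: tuple[float, float] = (50.0, 310.0)  # mm/s
    frame_rate: float = 80.0             # Hz
    phase_jitter_sd: float = 8.0         # deg, per-limb slow phase jitter
    tracking_noise_sd: float = 0.5       # mm, additive coordinate noise
    stance_fraction: float = 0.55        # fraction of cycle spent in stance
    onset_rise: float = 0.1              # s, raised-cosine speed rise

    def __post_init__(self) -> None:
        if not 0.5 <= self.stride_frequency <= 8.0:
            raise ValidationError(
                "stride_frequency must lie in the 0.5-8 Hz gait band"
            )
        if self.bout_duration < 1.0 or self.inter_bout_gap < 1.0:
            raise ValidationError("bout_duration and inter_bout_gap must be >= 1 s")
        for limb, off in self.phase_offsets_deg.items():
            if not 0 <= off < 360:
                raise ValidationError(f"phase offset for {limb} outside [0,360)")


@dataclass
class TuningProfile:
    """Ground-truth tuning of one synthetic unit.

    The spike intensity is log-linear::

        log lambda(t) = log(baseline_rate) + ramp_amplitude * shape(t)
                        + speed_gain * speed(t)
                        + phase_kappa * cos(phase(t) - preferred_phase)

    where ``shape`` rises linearly from ``ramp_lead`` seconds before each
    bout onset to 1 at onset + 0.1 s and decays exponentially with time
    constant ``ramp_decay``; the speed and phase terms apply during
    walking only. ``ramp_amplitude`` and ``speed_gain`` act on the log
    rate (units: log-rate and log-rate per mm/s), which keeps the
    intensity positive for any parameter values.
    """

    baseline_rate: float = 5.0    # Hz
    ramp_amplitude: float = 0.0   # log-rate units; peak multiplier e^a
    ramp_lead: float = 0.5        # s before onset
    ramp_decay: float = 0.5       # s, exponential decay after the peak
    speed_gain: float = 0.0       # log-rate per (mm/s)
    phase_kappa: float = 0.0      # von Mises concentration
    preferred_phase: float = 0.0  # deg
    preferred_limb: str = "lf"

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise ValidationError("baseline_rate must be > 0")
        if self.phase_kappa < 0:
            raise ValidationError("phase_kappa must be >= 0")
        if self.preferred_limb not in LIMBS:
            raise ValidationError(f"preferred_limb must be one of {LIMBS}")


@dataclass
class KinematicsTruth:
    """Ground truth accompanying a generated kinematics table."""

    bouts: pd.DataFrame                 # onset_frame, offset_frame
    phase_deg: dict[str, np.ndarray]    # per limb, NaN outside bouts
    speed: np.ndarray                   # commanded translation speed, mm/s
    stance_onsets: dict[str, np.ndarray]  # frames of phase-zero crossings
    frame_rate: float


# ---------------------------------------------------------------------------
# Kinematics
# ---------------------------------------------------------------------------

def _bout_schedule(gait: GaitParams, duration: float, rng: np.random.Generator):
    """Alternating (gap, bout) schedule in seconds; bouts >= 1 s."""
    spans = []
    t = max(1.0, gait.inter_bout_gap * rng.uniform(0.5, 1.5))
    while True:
        d = max(1.0, gait.bout_duration * rng.uniform(0.5, 1.5))
        if t + d + 1.0 > duration:
            break
        spans.append((t, t + d))
        t += d + max(1.0, gait.inter_bout_gap * rng.uniform(0.5, 1.5))
    if not spans:
        raise ValidationError(
            f"duration {duration} s too short for one bout plus gaps"
        )
    return spans


def _speed_profile(
    gait: GaitParams, spans, n_frames: int, rng: np.random.Generator
) -> np.ndarray:
    """Commanded translation speed per frame (mm/s)."""
    fr = gait.frame_rate
    dt = 1.0 / fr
    lo, hi = gait.speed_range
    speed = np.zeros(n_frames)
    rise_f = max(2, int(round(gait.onset_rise * fr)))
    fall_f = max(2, int(round(0.2 * fr)))
    for t0, t1 in spans:
        a, b = int(round(t0 * fr)), int(round(t1 * fr))
        b = min(b, n_frames)
        v0 = rng.uniform(120.0, 250.0)
        mu = rng.uniform(lo + 10, hi - 60)
        n = b - a
        v = np.empty(n)
        v[0] = v0
        # OU walk toward mu, clipped to the configured range
        theta, sigma = 1.0, 60.0
        noise = rng.standard_normal(n - 1) if n > 1 else np.empty(0)
        for i in range(1, n):
            v[i] = v[i - 1] + theta * (mu - v[i - 1]) * dt + sigma * np.sqrt(dt) * noise[i - 1]
        v = np.clip(v, lo, hi)
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(min(rise_f, n)) / rise_f))
        v[: len(ramp)] *= ramp
        speed[a:b] = v
        # raised-cosine fall after the bout
        c = min(n_frames, b + fall_f)
        if c > b:
            fall = 0.5 * (1 + np.cos(np.pi * np.arange(c - b) / fall_f))
            speed[b:c] = v[-1] * fall
    return speed


def _warp_phase(phase_rad: np.ndarray, stance_fraction: float) -> np.ndarray:
    """Map true phase to waveform phase: stance (0..2*pi*f_s) -> (0..pi)."""
    p = np.mod(phase_rad, 2 * np.pi)
    split = 2 * np.pi * stance_fraction
    out = np.where(
        p < split,
        p * (np.pi / split),
        np.pi + (p - split) * (np.pi / (2 * np.pi - split)),
    )
    return out


def generate_kinematics(
    gait: GaitParams,
    duration: float,
    seed: int,
) -> tuple[pd.DataFrame, KinematicsTruth]:
    """Generate a six-feature coordinate table with walking bouts.

    Returns the kinematics table (one row per frame, mm) and the ground
    truth: bout spans, per-limb per-frame phase (degrees, NaN outside
    bouts), commanded translation speed, and stance-onset frames.
    """
    rng = np.random.default_rng(seed)
    fr = gait.frame_rate
    n_frames = int(round(duration * fr))
    dt = 1.0 / fr
    spans = _bout_schedule(gait, duration, rng)
    speed = _speed_profile(gait, spans, n_frames, rng)

    # The analysis measures body speed as the RMS of limb speeds, which the
    # stride oscillation inflates relative to pure translation.  The
    # configured speed range refers to that measured quantity, so the body
    # translates at speed / F with F the waveform's analytic inflation
    # factor sqrt(1 + amp^2 E[w'^2]).
    amp_scale = gait.stride_amplitude / 15.0
    pgrid = np.linspace(0, 2 * np.pi, 4096, endpoint=False)
    wgrid = np.cos(_warp_phase(pgrid, gait.stance_fraction))
    wprime = np.gradient(wgrid, pgrid)
    inflation = float(np.sqrt(1.0 + amp_scale**2 * np.mean(wprime**2)))
    v_trans = speed / inflation

    walking = np.zeros(n_frames, dtype=bool)
    for t0, t1 in spans:
        walking[int(round(t0 * fr)) : int(round(t1 * fr))] = True

    # heading: slow random walk while moving
    dtheta = np.where(speed > 1.0, rng.standard_normal(n_frames) * np.radians(20) * np.sqrt(dt), 0.0)
    heading = np.cumsum(dtheta)
    ux, uy = np.cos(heading), np.sin(heading)

    # body centre path
    cx = np.cumsum(v_trans * ux * dt)
    cy = np.cumsum(v_trans * uy * dt)

    # common gait phase advances at the stride frequency during bouts
    omega = 2 * np.pi * gait.stride_frequency
    dphi = np.where(walking, omega * dt, 0.0)
    phi0 = rng.uniform(0, 2 * np.pi)
    phi = phi0 + np.cumsum(dphi)

    # per-limb slow phase jitter (smoothed white noise)
    jitter: dict[str, np.ndarray] = {}
    k = max(1, int(0.25 * fr))
    kernel = np.ones(k) / k
    for limb in LIMBS:
        w = rng.standard_normal(n_frames) * np.radians(gait.phase_jitter_sd) * np.sqrt(k)
        jitter[limb] = np.convolve(w, kernel, mode="same")

    base_amp = amp_scale * v_trans / omega  # stance limb nearly stationary

    body_len = 80.0
    lateral = {"lf": 12.0, "rf": -12.0, "lr": 12.0, "rr": -12.0}
    axial = {"lf": 20.0, "rf": 20.0, "lr": -20.0, "rr": -20.0}

    cols = {"frame": np.arange(n_frames)}
    noise = lambda: rng.standard_normal(n_frames) * gait.tracking_noise_sd
    cols["nose_x"] = cx + 0.5 * body_len * ux + noise()
    cols["nose_y"] = cy + 0.5 * body_len * uy + noise()
    cols["tail_x"] = cx - 0.5 * body_len * ux + noise()
    cols["tail_y"] = cy - 0.5 * body_len * uy + noise()

    phase_deg: dict[str, np.ndarray] = {}
    stance_onsets: dict[str, np.ndarray] = {}
    for limb in LIMBS:
        off = np.radians(gait.phase_offsets_deg[limb])
        p = phi + off + jitter[limb]
        # waveform: +cos of the asymmetrically warped phase, so at phase
        # zero the limb is displaced forward (closest to the nose) and the
        # projected limb-to-nose signal is at its minimum = stance onset
        w = np.cos(_warp_phase(p, gait.stance_fraction))
        osc = base_amp * w
        # lateral offset rotated into the heading frame; oscillation
        # along the heading axis
        px = cx + axial[limb] * ux - lateral[limb] * uy + osc * ux + noise()
        py = cy + axial[limb] * uy + lateral[limb] * ux + osc * uy + noise()
        cols[f"{limb}_x"] = px
        cols[f"{limb}_y"] = py
        deg = np.degrees(np.mod(p, 2 * np.pi))
        deg[~walking] = np.nan
        phase_deg[limb] = deg
        # stance onsets: frames where wrapped phase crosses zero inside a bout
        wrapped = np.mod(p, 2 * np.pi)
        crossing = (np.diff(wrapped) < -np.pi) & walking[1:] & walking[:-1]
        stance_onsets[limb] = np.flatnonzero(crossing) + 1

    kin = pd.DataFrame(cols)[KINEMATICS_COLUMNS]
    bouts = pd.DataFrame(
        {
            "onset_frame": [
                int(round(t0 * fr)) + int(round(gait.onset_rise * fr)) // 2
                for t0, _ in spans
            ],
            "offset_frame": [min(int(round(t1 * fr)), n_frames) for _, t1 in spans],
        }
    )
    truth = KinematicsTruth(
        bouts=bouts,
        phase_deg=phase_deg,
        speed=speed,
        stance_onsets=stance_onsets,
        frame_rate=fr,
    )
    return kin, truth


# ---------------------------------------------------------------------------
# Spikes
# ---------------------------------------------------------------------------

def _intensity_on_grid(
    truth: KinematicsTruth,
    profile: TuningProfile,
    duration: float,
    dt: float = 0.001,
) -> np.ndarray:
    """Piecewise-constant intensity (Hz) on a dt grid."""
    n = int(round(duration / dt))
    t = (np.arange(n) + 0.5) * dt
    fr = truth.frame_rate
    frame_of = np.minimum((t * fr).astype(int), len(truth.speed) - 1)

    log_lam = np.full(n, np.log(profile.baseline_rate))

    if profile.ramp_amplitude != 0.0:
        shape = np.zeros(n)
        for onset_f in truth.bouts["onset_frame"]:
            onset_t = onset_f / fr
            peak_t = onset_t + 0.1
            rise = (t - (onset_t - profile.ramp_lead)) / (profile.ramp_lead + 0.1)
            rise = np.clip(rise, 0.0, 1.0)
            decay = np.exp(-np.clip(t - peak_t, 0.0, None) / profile.ramp_decay)
            shape = np.maximum(shape, np.where(t <= peak_t, rise, decay))
        log_lam += profile.ramp_amplitude * shape

    walking = np.zeros(len(truth.speed), dtype=bool)
    for row in truth.bouts.itertuples(index=False):
        walking[row.onset_frame : row.offset_frame] = True
    walk_t = walking[frame_of]

    if profile.speed_gain != 0.0:
        log_lam += np.where(walk_t, profile.speed_gain * truth.speed[frame_of], 0.0)

    if profile.phase_kappa > 0.0:
        ph = truth.phase_deg[profile.preferred_limb][frame_of]
        term = profile.phase_kappa * np.cos(
            np.radians(ph) - np.radians(profile.preferred_phase)
        )
        log_lam += np.where(walk_t & np.isfinite(term), term, 0.0)

    return np.exp(log_lam)


def generate_spikes(
    truth: KinematicsTruth,
    profile: TuningProfile,
    duration: float,
    seed: int,
    dt: float = 0.001,
) -> np.ndarray:
    """Inhomogeneous-Poisson spike times (s) by thinning.

    The intensity is piecewise constant on a ``dt`` grid (1 ms default),
    for which thinning of a homogeneous process at the grid maximum is
    exact.
    """
    rng = np.random.default_rng(seed)
    lam = _intensity_on_grid(truth, profile, duration, dt)
    lam_max = float(lam.max())
    if lam_max <= 0:
        return np.array([])
    n_cand = rng.poisson(lam_max * duration)
    cand = rng.uniform(0.0, duration, size=n_cand)
    cell = np.minimum((cand / dt).astype(int), len(lam) - 1)
    keep = rng.uniform(0.0, 1.0, size=n_cand) < lam[cell] / lam_max
    return np.sort(cand[keep])


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class RegionProfile:
    """Distribution over tuning profiles for one synthetic region.

    ``ramp_amplitude`` and ``phase_kappa`` are drawn from lognormal /
    gamma families around the stated means so units within a region are
    heterogeneous, as real populations are.
    """

    baseline_median: float = 5.0        # Hz, lognormal median
    baseline_sigma: float = 0.5         # lognormal sigma of baseline
    ramp_amplitude_mean: float = 0.0    # log-rate units
    ramp_lead_range: tuple[float, float] = (0.3, 1.0)   # s
    ramp_decay_range: tuple[float, float] = (0.3, 0.8)  # s
    speed_gain_mean: float = 0.0        # log-rate per mm/s
    speed_gain_sd: float = 0.001
    phase_kappa_mean: float = 0.0
    phase_kappa_shape: float = 4.0      # gamma shape; higher = tighter

    def sample(self, rng: np.random.Generator) -> TuningProfile:
        kappa = (
            rng.gamma(self.phase_kappa_shape, self.phase_kappa_mean / self.phase_kappa_shape)
            if self.phase_kappa_mean > 0
            else 0.0
        )
        ramp = (
            rng.lognormal(np.log(self.ramp_amplitude_mean), 0.3)
            if self.ramp_amplitude_mean > 0
            else 0.0
        )
        return TuningProfile(
            baseline_rate=rng.lognormal(np.log(self.baseline_median), self.baseline_sigma),
            ramp_amplitude=ramp,
            ramp_lead=rng.uniform(*self.ramp_lead_range),
            ramp_decay=rng.uniform(*self.ramp_decay_range),
            speed_gain=rng.normal(self.speed_gain_mean, self.speed_gain_sd),
            phase_kappa=kappa,
            preferred_phase=rng.uniform(0, 360),
            preferred_limb=LIMBS[rng.integers(len(LIMBS))],
        )


#: Strong gait-phase tuning, weak preparatory ramp (motor-cortex-like).
M1_LIKE = RegionProfile(
    ramp_amplitude_mean=0.2,
    ramp_lead_range=(0.2, 0.6),
    speed_gain_mean=0.002,
    phase_kappa_mean=2.0,
)

#: Strong, early preparatory ramp, weak gait-phase tuning
#: (dorsomedial-striatum-like).
DMS_LIKE = RegionProfile(
    ramp_amplitude_mean=1.2,
    ramp_lead_range=(0.6, 1.2),
    speed_gain_mean=0.002,
    phase_kappa_mean=0.3,
)


@dataclass
class CohortSpec:
    """Specification of a synthetic multi-session cohort."""

    regions: dict[str, RegionProfile]   # region label -> profile distribution
    n_units: int = 50                   # per region per session
    n_sessions: int = 1
    session_duration: float = 300.0     # s
    gait: GaitParams = field(default_factory=GaitParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValidationError("n_units must be >= 1")
        bad = [r for r in self.regions if r not in {"M1", "mPFC", "DMS", "DLS"}]
        if bad:
            raise ValidationError(f"unknown region label(s): {bad}")


@dataclass
class Cohort:
    """Generated sessions plus their hidden ground truth."""

    sessions: list[Session]
    truths: list[KinematicsTruth]
    unit_truth: pd.DataFrame  # session_id, unit_id, region + profile fields


def generate_session(
    session_id: str,
    regions: dict[str, RegionProfile],
    n_units: int,
    duration: float,
    gait: GaitParams,
    seed: int,
) -> tuple[Session, KinematicsTruth, pd.DataFrame]:
    """One synthetic session with ``n_units`` units per region."""
    kin, truth = generate_kinematics(gait, duration, derive_seed(seed, "kin"))
    units: list[SpikeTrain] = []
    rows = []
    for region, rprofile in sorted(regions.items()):
        prof_rng = np.random.default_rng(derive_seed(seed, f"profiles:{region}"))
        for i in range(n_units):
            profile = rprofile.sample(prof_rng)
            uid = f"{session_id}_{region}_{i:03d}"
            times = generate_spikes(
                truth, profile, duration, derive_seed(seed, f"spikes:{uid}")
            )
            times = times[times <= duration]
            units.append(SpikeTrain(unit_id=uid, region=region, spike_times=times))
            rows.append(
                {
                    "session_id": session_id,
                    "unit_id": uid,
                    "region": region,
                    "baseline_rate": profile.baseline_rate,
                    "ramp_amplitude": profile.ramp_amplitude,
                    "ramp_lead": profile.ramp_lead,
                    "ramp_decay": profile.ramp_decay,
                    "speed_gain": profile.speed_gain,
                    "phase_kappa": profile.phase_kappa,
                    "preferred_phase": profile.preferred_phase,
                    "preferred_limb": profile.preferred_limb,
                }
            )
    session = Session(
        session_id=session_id,
        kinematics=kin,
        units=units,
        frame_rate=gait.frame_rate,
        duration=duration,
    )
    return session, truth, pd.DataFrame(rows)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate all sessions of a cohort, deterministically under the seed."""
    sessions, truths, tables = [], [], []
    for s in range(spec.n_sessions):
        sid = f"synth{s:02d}"
        sess, truth, table = generate_session(
            sid,
            spec.regions,
            spec.n_units,
            spec.session_duration,
            spec.gait,
            derive_seed(spec.seed, f"session:{s}"),
        )
        sessions.append(sess)
        truths.append(truth)
        tables.append(table)
    return Cohort(
        sessions=sessions,
        truths=truths,
        unit_truth=pd.concat(tables, ignore_index=True),
    )
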