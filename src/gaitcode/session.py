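"""Session container, on-disk layout, and run configuration.

A *session* is one freely-moving recording: an 80 Hz table of tracked
body-feature coordinates (four limbs, nose, tail base; millimetres), a set
of spike-sorted single units with spike times in seconds on the same clock,
and minimal unit metadata (brain-region label, optional sublabel such as a
cortical layer).

On disk a session is a directory of delimited text tables plus a small JSON
header::

    session_dir/
        kinematics.tsv   frame, nose_x, nose_y, tail_x, tail_y,
                         lf_x, lf_y, rf_x, rf_y, lr_x, lr_y, rr_x, rr_y
        spikes.tsv       unit_id, time_s
        units.tsv        unit_id, region, sublabel
        meta.json        session_id, frame_rate, duration

All coordinates are stored in mm, frame indices are 0-based and gapless,
and every time is in seconds from the first video frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "BODY_FEATURES",
    "LIMBS",
    "REGIONS",
    "KINEMATICS_COLUMNS",
    "SchemaError",
    "ValidationError",
    "SpikeTrain",
    "Session",
    "RunConfig",
    "read_session",
    "write_session",
    "load_config",
    "derive_seed",
]

#: Tracked features, in on-disk column order.
BODY_FEATURES = ("nose", "tail", "lf", "rf", "lr", "rr")
#: The four limbs (left/right fore, left/right rear).
LIMBS = ("lf", "rf", "lr", "rr")
#: Closed set of accepted brain-region labels.
REGIONS = frozenset({"M1", "mPFC", "DMS", "DLS"})

KINEMATICS_COLUMNS = ["frame"] + [
    f"{feat}_{ax}" for feat in BODY_FEATURES for ax in ("x", "y")
]

_FLOAT_FMT = "%.10g"


class SchemaError(ValueError):
    """A required column or key is missing or of the wrong type."""


class ValidationError(ValueError):
    """Data violate a session invariant (ordering, bounds, finiteness)."""


@dataclass
class SpikeTrain:
    """Spike times of one sorted single unit.

    Parameters
    ----------
    unit_id
        Unique unit label within the session.
    region
        One of ``M1``, ``mPFC``, ``DMS``, ``DLS``.
    spike_times
        Spike times in seconds, sorted ascending, non-negative.
    sublabel
        Optional finer anatomical label (layer or subregion); purely
        pass-through metadata.
    """

    unit_id: str
    region: str
    spike_times: np.ndarray
    sublabel: Optional[str] = None

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.region not in REGIONS:
            raise ValidationError(
                f"unit {self.unit_id!r}: region {self.region!r} not in "
                f"{sorted(REGIONS)}"
            )
        if self.spike_times.ndim != 1:
            raise ValidationError(f"unit {self.unit_id!r}: spike_times must be 1-D")
        if self.spike_times.size and np.any(np.diff(self.spike_times) < 0):
            raise ValidationError(f"unit {self.unit_id!r}: spike times not sorted")
        if self.spike_times.size and self.spike_times[0] < 0:
            raise ValidationError(f"unit {self.unit_id!r}: negative spike time")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


@dataclass
class Session:
    """One recording: kinematics + spike trains + metadata.

    Invariants (enforced by :meth:`validate`, called on construction):
    frame indices strictly increasing and gapless from 0; all coordinates
    finite; ``duration >= 1`` s; every spike time in ``[0, duration]``.
    """

    session_id: str
    kinematics: pd.DataFrame
    units: list[SpikeTrain] = field(default_factory=list)
    frame_rate: float = 80.0
    duration: Optional[float] = None

    def __post_init__(self) -> None:
        if self.duration is None:
            self.duration = len(self.kinematics) / self.frame_rate
        self.validate()

    def validate(self) -> None:
        missing = [c for c in KINEMATICS_COLUMNS if c not in self.kinematics.columns]
        if missing:
            raise SchemaError(f"kinematics missing column(s): {missing}")
        frames = self.kinematics["frame"].to_numpy()
        if len(frames) == 0:
            raise ValidationError("kinematics table is empty")
        if frames[0] != 0 or (len(frames) > 1 and np.any(np.diff(frames) != 1)):
            raise ValidationError("frame indices must start at 0 and be gapless")
        coords = self.kinematics[KINEMATICS_COLUMNS[1:]].to_numpy(float)
        if not np.all(np.isfinite(coords)):
            raise ValidationError("non-finite coordinate in kinematics")
        if self.frame_rate <= 0:
            raise ValidationError("frame_rate must be positive")
        if self.duration < 1.0:
            raise ValidationError(f"duration {self.duration} s < 1 s minimum")
        bad = [
            u.unit_id
            for u in self.units
            if u.n_spikes and u.spike_times[-1] > self.duration
        ]
        if bad:
            raise ValidationError(
                f"spike time(s) beyond session duration for unit(s): {bad}"
            )

    @property
    def n_frames(self) -> int:
        return len(self.kinematics)

    @property
    def frame_times(self) -> np.ndarray:
        """Time of each frame's start, in seconds."""
        return self.kinematics["frame"].to_numpy() / self.frame_rate


def write_session(session: Session, path: str | Path) -> None:
    """Write a session directory (three TSV tables + ``meta.json``).

    The byte layout is deterministic for identical input: fixed column
    order, fixed float format, sorted JSON keys.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    session.kinematics[KINEMATICS_COLUMNS].to_csv(
        path / "kinematics.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    spikes = pd.DataFrame(
        {
            "unit_id": np.repeat(
                [u.unit_id for u in session.units],
                [u.n_spikes for u in session.units],
            )
            if session.units
            else np.array([], dtype=object),
            "time_s": np.concatenate([u.spike_times for u in session.units])
            if session.units
            else np.array([], dtype=float),
        }
    )
    spikes.to_csv(path / "spikes.tsv", sep="\t", index=False, float_format="%.9f")
    units = pd.DataFrame(
        {
            "unit_id": [u.unit_id for u in session.units],
            "region": [u.region for u in session.units],
            "sublabel": [u.sublabel if u.sublabel is not None else "" for u in session.units],
        }
    )
    units.to_csv(path / "units.tsv", sep="\t", index=False)
    meta = {
        "session_id": session.session_id,
        "frame_rate": session.frame_rate,
        "duration": session.duration,
    }
    (path / "meta.json").write_text(json.dumps(meta, sort_keys=True, indent=1) + "\n")


def read_session(path: str | Path) -> Session:
    """Read and validate a session directory written by :func:`write_session`."""
    path = Path(path)
    for fname in ("kinematics.tsv", "spikes.tsv", "units.tsv", "meta.json"):
        if not (path / fname).exists():
            raise SchemaError(f"session directory {path} missing {fname}")
    meta = json.loads((path / "meta.json").read_text())
    kin = pd.read_csv(path / "kinematics.tsv", sep="\t")
    spikes = pd.read_csv(path / "spikes.tsv", sep="\t")
    units_tab = pd.read_csv(path / "units.tsv", sep="\t", keep_default_na=False)
    for col in ("unit_id", "time_s"):
        if col not in spikes.columns:
            raise SchemaError(f"spikes.tsv missing column {col!r}")
    for col in ("unit_id", "region"):
        if col not in units_tab.columns:
            raise SchemaError(f"units.tsv missing column {col!r}")
    units: list[SpikeTrain] = []
    grouped = (
        dict(iter(spikes.groupby("unit_id"))) if len(spikes) else {}
    )
    for row in units_tab.itertuples(index=False):
        uid = str(row.unit_id)
        times = (
            grouped[uid]["time_s"].to_numpy(float) if uid in grouped else np.array([])
        )
        sublabel = getattr(row, "sublabel", "") or None
        units.append(
            SpikeTrain(unit_id=uid, region=str(row.region), spike_times=times,
                       sublabel=sublabel)
        )
    return Session(
        session_id=str(meta["session_id"]),
        kinematics=kin,
        units=units,
        frame_rate=float(meta["frame_rate"]),
        duration=float(meta["duration"]),
    )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Analysis parameters, defaulting to the published values.

    All randomness in a run flows from ``random_seed`` through
    :func:`derive_seed`, so individual stages can be re-run in isolation
    and still reproduce the full-pipeline result bit for bit.
    """

    random_seed: int = 0

    # peri-event rate estimation
    base_bin: float = 0.025      # s, raw spike-count bin
    kernel_sd: float = 0.1       # s, Gaussian smoothing kernel
    rate_bin: float = 0.1        # s, output bin for modulation analysis
    time_bin: float = 0.2        # s, output bin for decoding
    modulation_window: tuple[float, float] = (-1.0, 1.0)   # s around onset
    decoding_window: tuple[float, float] = (-1.5, 1.5)     # s around onset
    baseline_window: tuple[float, float] = (-1.0, -0.9)    # s, t-test baseline
    alpha: float = 0.05

    # kinematics
    savgol_window: int = 7       # frames
    savgol_polyorder: int = 3
    band_low: float = 0.5        # Hz
    band_high: float = 8.0       # Hz
    speed_threshold: float = 50.0        # mm/s candidate-bout threshold
    min_sustained: float = 0.5           # s above threshold for a candidate
    accel_window_frames: int = 50        # refinement window around onset
    prominence_threshold: float = 1000.0  # mm/s^2
    min_bout_duration: float = 1.0       # s
    min_bout_separation: float = 1.0     # s

    # single-unit statistics
    speed_bin_edges: tuple[float, float, float] = (50.0, 310.0, 20.0)  # lo, hi, step
    n_phase_hist_bins: int = 24
    jitter_window: float = 0.15  # s, +/- spike-time jitter
    n_jitter: int = 1000

    # decoding
    n_time_classes: int = 15
    n_phase_classes: int = 12
    speed_class_edges: tuple[float, ...] = (50.0, 100.0, 150.0, 200.0, 250.0)
    n_units_draw: int = 200
    n_units_draw_speed: int = 100
    n_draws: int = 50
    n_eval_iterations: int = 50
    n_shuffles: int = 50
    trials_per_session_time: int = 50
    trials_per_class_speed: int = 100
    trials_per_session_phase: int = 200

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        return out


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a flat key-value YAML config; unset keys take defaults.

    Unknown keys raise :class:`SchemaError` rather than being silently
    ignored, so typos like ``tim_bin`` surface immediately.
    """
    values: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise SchemaError("config file must be a flat key-value mapping")
        values.update(raw)
    values.update(overrides)
    known = {f.name: f for f in fields(RunConfig)}
    unknown = sorted(set(values) - set(known))
    if unknown:
        raise SchemaError(f"unknown config key(s): {unknown}")
    cfg = RunConfig()
    for key, val in values.items():
        current = getattr(cfg, key)
        if isinstance(current, (int, float)) and not isinstance(current, bool):
            if not isinstance(val, (int, float)):
                raise SchemaError(f"config key {key!r} must be numeric, got {val!r}")
        if isinstance(current, tuple):
            val = tuple(val)
        cfg = replace(cfg, **{key: val})
    _check_config(cfg)
    return cfg


def _check_config(cfg: RunConfig) -> None:
    for key in ("base_bin", "kernel_sd", "rate_bin", "time_bin"):
        if getattr(cfg, key) <= 0:
            raise ValidationError(f"config {key} must be > 0")
    for key in ("modulation_window", "decoding_window", "baseline_window"):
        lo, hi = getattr(cfg, key)
        if lo >= hi:
            raise ValidationError(f"config {key} edges must be ordered")
    if list(cfg.speed_class_edges) != sorted(cfg.speed_class_edges):
        raise ValidationError("speed_class_edges must be increasing")


def derive_seed(master_seed: int, stage: str) -> int:
    """Derive a stage-specific 31-bit seed from the master seed.

    Hashes the stage name together with the master seed (SHA-256, stable
    across processes and platforms) so that each pipeline stage draws from
    an independent, reproducible stream.
    """
    import hashlib

    digest = hashlib.sha256(f"{int(master_seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
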