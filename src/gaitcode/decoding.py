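"""Population decoding of time-around-onset, body speed, and gait phase.

The decoder is a one-against-one multiclass support vector machine with
a radial-basis kernel: one binary classifier per unordered class pair
(105 classifiers for the 15-class time task, 6 for the 4-class speed
task, 66 for the 12-class phase task), each voting for one of its two
candidate classes; the prediction is the majority class. Evaluation
follows a two-level resampling scheme: an outer loop of random draws of
N units (pseudo-population pooled across sessions), and an inner loop of
iterations that each hold out whole trials for testing. Chance level is
estimated empirically by re-running the evaluation on tensors whose
class labels are permuted within trial.

Tasks
-----
time
    15 classes: 0.2 s bins tiling -1.5 to +1.5 s around bout onset; one
    trial is one walking bout.
speed
    4 classes: 50-100, 100-150, 150-200, 200-250 mm/s; one trial is one
    0.2 s walking bin per class.
phase
    12 classes: 30 degree bins of the gait cycle of one limb; one trial
    is one stride.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .kinematics import SegmentedSession
from .session import derive_seed
from .unit_stats import estimate_rates

__all__ = [
    "TrialTensor",
    "DecoderSpec",
    "DecodingResult",
    "OvOModel",
    "build_trials",
    "fit_ovo_svm",
    "predict_vote",
    "evaluate",
    "shuffle_null",
    "error_metrics",
    "prepost_summary",
    "size_sweep",
]

TASKS = ("time", "speed", "phase")

#: Default number of trials held out per evaluation iteration, by task.
HOLDOUT = {"time": 1, "speed": 2, "phase": 4}


@dataclass
class TrialTensor:
    """Trials x units x classes firing-rate array for one decoding task."""

    task: str
    data: np.ndarray           # (n_trials, n_units, n_classes), Hz
    class_values: np.ndarray   # physical class centres (s, mm/s, or deg)
    unit_ids: list[str] = field(default_factory=list)
    session_ids: list[str] = field(default_factory=list)  # per trial

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}")
        if self.data.ndim != 3:
            raise ValueError("data must be trials x units x classes")
        if self.data.shape[2] != len(self.class_values):
            raise ValueError("class_values length must match the class axis")
        if np.any(self.data < 0):
            raise ValueError("firing rates must be non-negative")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_units(self) -> int:
        return self.data.shape[1]

    @property
    def n_classes(self) -> int:
        return self.data.shape[2]


@dataclass
class DecoderSpec:
    """Decoder and resampling configuration.

    Defaults follow the full-scale analysis (200-unit draws, 50 draws,
    50 leave-trial-out iterations); tests and desk-scale runs shrink
    them. ``gamma_grid`` entries are multipliers on the median-distance
    heuristic bandwidth computed from the training features.
    """

    n_units: int = 200
    n_draws: int = 50
    n_eval_iterations: int = 50
    n_holdout: Optional[int] = None      # None -> per-task default
    n_shuffles: int = 50
    c_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    gamma_grid: tuple[float, ...] = (0.1, 0.3, 1.0, 3.0, 10.0)
    max_search: int = 20
    cv_folds: int = 5
    scale_features: bool = True
    tune: bool = True                    # False -> C=1, median-heuristic gamma
    trials_per_session: int = 50         # quota; task-dependent in practice
    seed: int = 0


@dataclass
class DecodingResult:
    """Aggregated decoder performance over draws and iterations."""

    task: str
    confusion: np.ndarray            # (K, K), row-normalised actual x predicted
    per_class_accuracy: np.ndarray   # (K,)
    overall_accuracy: float
    error_metric: float              # RMSE (s or mm/s) or angular MAE (deg)
    error_metric_bins: float         # same error in bin-index units
    per_draw_accuracy: np.ndarray    # (n_draws,)
    per_draw_per_class: np.ndarray   # (n_draws, K)
    class_values: np.ndarray
    n_units: int
    shuffle_band: Optional[dict] = None

    def __post_init__(self) -> None:
        rows = self.confusion.sum(axis=1)
        if not np.allclose(rows[rows > 0], 1.0, atol=1e-9):
            raise ValueError("confusion rows must sum to 1")


# ---------------------------------------------------------------------------
# Trial-tensor construction
# ---------------------------------------------------------------------------

def _session_rate_series(
    spike_times: np.ndarray,
    duration: float,
    base_bin: float = 0.025,
    kernel_sd: float = 0.1,
) -> np.ndarray:
    """Smoothed firing rate (Hz) on the 25 ms session grid."""
    n = int(np.ceil(duration / base_bin))
    counts = np.histogram(spike_times, bins=n, range=(0, n * base_bin))[0].astype(float)
    half = int(np.ceil(4 * kernel_sd / base_bin))
    x = np.arange(-half, half + 1) * base_bin
    kernel = np.exp(-0.5 * (x / kernel_sd) ** 2)
    kernel /= kernel.sum()
    return np.convolve(counts, kernel, mode="same") / base_bin


def build_trials(
    segmented: Sequence[SegmentedSession],
    task: str,
    spec: DecoderSpec,
    limb: str = "lf",
    speed_class_edges: Sequence[float] = (50.0, 100.0, 150.0, 200.0, 250.0),
    window: tuple[float, float] = (-1.5, 1.5),
    time_bin: float = 0.2,
) -> TrialTensor:
    """Build the trials x units x classes tensor for one task.

    Trials are selected per session up to ``spec.trials_per_session``
    (for the speed task, per class); sessions that cannot fill the quota
    are excluded with a warning. Units from the surviving sessions are
    pooled by concatenation into a pseudo-population, with trials from
    different sessions aligned by index after per-session random
    selection.
    """
    rng = np.random.default_rng(derive_seed(spec.seed, f"build:{task}"))
    blocks: list[np.ndarray] = []
    unit_ids: list[str] = []
    kept_sessions: list[str] = []
    quota = spec.trials_per_session

    for seg in segmented:
        if task == "time":
            block, cvals = _time_block(seg, quota, rng, window, time_bin)
        elif task == "speed":
            block, cvals = _speed_block(seg, quota, rng, speed_class_edges, time_bin)
        elif task == "phase":
            block, cvals = _phase_block(seg, quota, rng, limb)
        else:
            raise ValueError(f"unknown task {task!r}")
        if block is None:
            warnings.warn(
                f"session {seg.session.session_id} below the {quota}-trial "
                f"quota for task {task!r}; excluded"
            )
            continue
        class_values = cvals
        blocks.append(block)
        unit_ids.extend(u.unit_id for u in seg.session.units)
        kept_sessions.append(seg.session.session_id)

    if not blocks:
        raise ValueError(f"no session meets the trial quota for task {task!r}")
    data = np.concatenate(blocks, axis=1)
    session_ids = [kept_sessions[0]] * data.shape[0]
    return TrialTensor(
        task=task,
        data=data,
        class_values=class_values,
        unit_ids=unit_ids,
        session_ids=session_ids,
    )


def _time_block(seg, quota, rng, window, time_bin):
    sess = seg.session
    fr = sess.frame_rate
    onsets = np.array(
        [
            b.onset_frame / fr
            for b in seg.bouts
            if b.onset_frame / fr + window[0] >= 0
            and b.onset_frame / fr + window[1] <= sess.duration
        ]
    )
    if len(onsets) < quota:
        return None, None
    chosen = np.sort(rng.choice(len(onsets), size=quota, replace=False))
    events = onsets[chosen]
    per_unit = [
        estimate_rates(u.spike_times, events, window=window, out_bin=time_bin).rates
        for u in sess.units
    ]
    block = np.stack(per_unit, axis=1)  # trials x units x bins
    n_bins = block.shape[2]
    cvals = window[0] + time_bin * (np.arange(n_bins) + 0.5)
    return block, cvals


def _speed_block(seg, quota, rng, edges, time_bin):
    sess = seg.session
    fr = sess.frame_rate
    frames_per = int(round(time_bin * fr))
    mask = seg.walking_mask
    n_classes = len(edges) - 1
    starts_by_class: list[list[int]] = [[] for _ in range(n_classes)]
    for start in range(0, len(mask) - frames_per + 1, frames_per):
        if not mask[start : start + frames_per].all():
            continue
        v = seg.speed[start : start + frames_per].mean()
        cls = np.searchsorted(edges, v, side="right") - 1
        if 0 <= cls < n_classes:
            starts_by_class[cls].append(start)
    if any(len(s) < quota for s in starts_by_class):
        return None, None
    rate_series = {
        u.unit_id: _session_rate_series(u.spike_times, sess.duration)
        for u in sess.units
    }
    base_bin = 0.025
    ratio = int(round(time_bin / base_bin))
    block = np.empty((quota, len(sess.units), n_classes))
    for cls in range(n_classes):
        chosen = rng.choice(len(starts_by_class[cls]), size=quota, replace=False)
        for t, idx in enumerate(chosen):
            b0 = int(round(starts_by_class[cls][idx] / fr / base_bin))
            for j, u in enumerate(sess.units):
                series = rate_series[u.unit_id]
                block[t, j, cls] = series[b0 : b0 + ratio].mean()
    cvals = np.asarray(edges[:-1]) + np.diff(edges) / 2
    return block, cvals


def _phase_block(seg, quota, rng, limb, n_classes: int = 12):
    sess = seg.session
    fr = sess.frame_rate
    phase = seg.phases[limb].phase_deg
    strides = seg.strides[limb]
    rate_series = {
        u.unit_id: _session_rate_series(u.spike_times, sess.duration)
        for u in sess.units
    }
    base_bin = 0.025
    frame_rate_idx = np.minimum(
        (np.arange(len(phase)) / fr / base_bin).astype(int),
        min(len(s) for s in rate_series.values()) - 1 if rate_series else 0,
    )
    usable = []
    for s in strides:
        fr_idx = np.arange(s.stance_onset_frame, s.end_frame)
        ph = phase[fr_idx]
        if not np.all(np.isfinite(ph)):
            continue
        bins = np.minimum((ph / (360.0 / n_classes)).astype(int), n_classes - 1)
        if len(np.unique(bins)) < n_classes:
            continue
        usable.append((fr_idx, bins))
    if len(usable) < quota:
        return None, None
    chosen = rng.choice(len(usable), size=quota, replace=False)
    block = np.empty((quota, len(sess.units), n_classes))
    for t, idx in enumerate(chosen):
        fr_idx, bins = usable[idx]
        rate_idx = frame_rate_idx[fr_idx]
        for j, u in enumerate(sess.units):
            series = rate_series[u.unit_id][rate_idx]
            for c in range(n_classes):
                block[t, j, c] = series[bins == c].mean()
    cvals = (np.arange(n_classes) + 0.5) * 360.0 / n_classes
    return block, cvals


# ---------------------------------------------------------------------------
# One-against-one SVM
# ---------------------------------------------------------------------------

@dataclass
class OvOModel:
    """One binary RBF-SVM per unordered class pair, plus the scaler."""

    classifiers: dict[tuple[int, int], SVC]
    scaler: Optional[StandardScaler]
    n_classes: int
    c: float
    gamma: float


def _median_heuristic_gamma(X: np.ndarray, rng: np.random.Generator) -> float:
    """RBF bandwidth 1/median(squared pairwise distance)."""
    n = X.shape[0]
    idx = rng.choice(n, size=min(n, 300), replace=False)
    sub = X[idx]
    d2 = np.sum((sub[:, None, :] - sub[None, :, :]) ** 2, axis=-1)
    med = np.median(d2[np.triu_indices_from(d2, k=1)])
    return 1.0 / med if med > 0 else 1.0


def fit_ovo_svm(
    X: np.ndarray,
    y: np.ndarray,
    c: float = 1.0,
    gamma_mult: float = 1.0,
    scale_features: bool = True,
    rng: Optional[np.random.Generator] = None,
) -> OvOModel:
    """Fit one binary RBF-SVM per class pair.

    ``X`` is (n_samples, n_units), ``y`` integer class indices. The
    per-unit standardisation and the median-heuristic kernel bandwidth
    are learned on the training data only.
    """
    rng = rng or np.random.default_rng(0)
    classes = np.unique(y)
    for k in classes:
        if np.sum(y == k) < 2:
            raise ValueError(f"class {int(k)} has fewer than 2 training trials")
    scaler = None
    if scale_features:
        scaler = StandardScaler().fit(X)
        X = scaler.transform(X)
    gamma = gamma_mult * _median_heuristic_gamma(X, rng)
    classifiers: dict[tuple[int, int], SVC] = {}
    for a, b in itertools.combinations(classes.tolist(), 2):
        sel = (y == a) | (y == b)
        svc = SVC(C=c, kernel="rbf", gamma=gamma)
        svc.fit(X[sel], y[sel])
        classifiers[(int(a), int(b))] = svc
    return OvOModel(
        classifiers=classifiers,
        scaler=scaler,
        n_classes=len(classes),
        c=c,
        gamma=gamma,
    )


def predict_vote(model: OvOModel, X: np.ndarray) -> np.ndarray:
    """Majority-vote prediction over all binary classifiers.

    Each pair classifier casts one vote. Ties are broken by the summed
    signed decision-function margin accumulated per class; residual ties
    go to the lowest class index, deterministically.
    """
    if model.scaler is not None:
        X = model.scaler.transform(X)
    n = X.shape[0]
    votes = np.zeros((n, model.n_classes))
    margins = np.zeros((n, model.n_classes))
    for (a, b), svc in model.classifiers.items():
        df = svc.decision_function(X)  # >0 -> classes_[1]
        hi = int(svc.classes_[1])
        lo = int(svc.classes_[0])
        pick_hi = df > 0
        votes[pick_hi, hi] += 1
        votes[~pick_hi, lo] += 1
        margins[:, hi] += df
        margins[:, lo] -= df
    # lexicographic: votes, then margin, then lowest index
    out = np.empty(n, dtype=int)
    for i in range(n):
        best = np.flatnonzero(votes[i] == votes[i].max())
        if len(best) > 1:
            m = margins[i, best]
            best = best[m == m.max()]
        out[i] = best[0]
    return out


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def _flatten(tensor_data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(trials, units, K) -> (trials*K, units) samples with class labels."""
    t, u, k = tensor_data.shape
    X = np.transpose(tensor_data, (0, 2, 1)).reshape(t * k, u)
    y = np.tile(np.arange(k), t)
    return X, y


def _tune(
    X: np.ndarray, y: np.ndarray, spec: DecoderSpec, rng: np.random.Generator
) -> tuple[float, float]:
    """Seeded grid search with stratified k-fold CV, capped at max_search."""
    grid = list(itertools.product(spec.c_grid, spec.gamma_grid))[: spec.max_search]
    folds = min(spec.cv_folds, int(np.min(np.bincount(y))))
    if folds < 2:
        return 1.0, 1.0
    skf = StratifiedKFold(
        n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31))
    )
    splits = list(skf.split(X, y))
    best, best_acc = (1.0, 1.0), -1.0
    for c, gm in grid:
        accs = []
        for tr, te in splits:
            model = fit_ovo_svm(X[tr], y[tr], c, gm, spec.scale_features, rng)
            accs.append(np.mean(predict_vote(model, X[te]) == y[te]))
        acc = float(np.mean(accs))
        if acc > best_acc:
            best, best_acc = (c, gm), acc
    return best


def evaluate(tensor: TrialTensor, spec: DecoderSpec) -> DecodingResult:
    """Outer draws of unit subsets, inner leave-trials-out iterations.

    Hyperparameters are tuned once per call on the first draw's unit
    subset (seeded grid search, five-fold cross-validation, capped at 20
    evaluations) and reused across draws; all randomness flows from
    ``spec.seed``.
    """
    rng = np.random.default_rng(derive_seed(spec.seed, f"evaluate:{tensor.task}"))
    k = tensor.n_classes
    n_hold = spec.n_holdout if spec.n_holdout is not None else HOLDOUT[tensor.task]
    if tensor.n_trials <= n_hold + 1:
        raise ValueError(
            f"{tensor.n_trials} trials insufficient for {n_hold} held out"
        )
    n_units = min(spec.n_units, tensor.n_units)

    draw_units = [
        rng.choice(tensor.n_units, size=n_units, replace=False)
        for _ in range(spec.n_draws)
    ]
    if spec.tune:
        Xt, yt = _flatten(tensor.data[:, draw_units[0], :])
        c, gamma_mult = _tune(Xt, yt, spec, rng)
    else:
        c, gamma_mult = 1.0, 1.0

    confusion = np.zeros((k, k))
    per_draw_conf = np.zeros((spec.n_draws, k, k))
    actual_all, pred_all = [], []
    for d, units in enumerate(draw_units):
        sub = tensor.data[:, units, :]
        for _ in range(spec.n_eval_iterations):
            test_trials = rng.choice(tensor.n_trials, size=n_hold, replace=False)
            train_mask = np.ones(tensor.n_trials, bool)
            train_mask[test_trials] = False
            X_tr, y_tr = _flatten(sub[train_mask])
            X_te, y_te = _flatten(sub[test_trials])
            model = fit_ovo_svm(X_tr, y_tr, c, gamma_mult, spec.scale_features, rng)
            pred = predict_vote(model, X_te)
            for a, p in zip(y_te, pred):
                confusion[a, p] += 1
                per_draw_conf[d, a, p] += 1
            actual_all.append(y_te)
            pred_all.append(pred)

    actual = np.concatenate(actual_all)
    pred = np.concatenate(pred_all)
    row_sums = confusion.sum(axis=1, keepdims=True)
    conf_norm = np.divide(confusion, row_sums, out=np.zeros_like(confusion), where=row_sums > 0)
    per_class = np.diag(conf_norm)
    overall = float(np.mean(actual == pred))
    per_draw_per_class = np.zeros((spec.n_draws, k))
    per_draw_acc = np.zeros(spec.n_draws)
    for d in range(spec.n_draws):
        rows = per_draw_conf[d].sum(axis=1)
        per_draw_per_class[d] = np.divide(
            np.diag(per_draw_conf[d]), rows, out=np.zeros(k), where=rows > 0
        )
        per_draw_acc[d] = per_draw_conf[d].trace() / per_draw_conf[d].sum()

    err_phys = error_metrics(
        tensor.class_values[actual], tensor.class_values[pred], tensor.task
    )
    err_bins = error_metrics(
        actual.astype(float), pred.astype(float), "time"
    )
    return DecodingResult(
        task=tensor.task,
        confusion=conf_norm,
        per_class_accuracy=per_class,
        overall_accuracy=overall,
        error_metric=err_phys,
        error_metric_bins=err_bins,
        per_draw_accuracy=per_draw_acc,
        per_draw_per_class=per_draw_per_class,
        class_values=tensor.class_values,
        n_units=n_units,
    )


def shuffle_null(
    tensor: TrialTensor, spec: DecoderSpec, n_shuffles: Optional[int] = None
) -> dict:
    """Empirical chance band from within-trial label permutation.

    Each surrogate permutes the class axis independently within every
    trial (equivalent to reassigning each rate vector to a random class
    label within its trial) and repeats a single-draw evaluation. Returns
    the 2.5/97.5 percentile band per class and overall.
    """
    n_shuffles = n_shuffles or spec.n_shuffles
    rng = np.random.default_rng(derive_seed(spec.seed, f"shuffle:{tensor.task}"))
    k = tensor.n_classes
    overall = np.empty(n_shuffles)
    per_class = np.empty((n_shuffles, k))
    for s in range(n_shuffles):
        shuffled = np.empty_like(tensor.data)
        for t in range(tensor.n_trials):
            shuffled[t] = tensor.data[t][:, rng.permutation(k)]
        sub_spec = replace(
            spec, n_draws=1, seed=derive_seed(spec.seed, f"shufeval:{s}"), tune=False
        )
        res = evaluate(
            TrialTensor(tensor.task, shuffled, tensor.class_values), sub_spec
        )
        overall[s] = res.overall_accuracy
        per_class[s] = res.per_class_accuracy
    return {
        "overall_band": tuple(np.percentile(overall, [2.5, 97.5])),
        "per_class_band": np.percentile(per_class, [2.5, 97.5], axis=0),
        "overall_values": overall,
        "center": float(np.mean(overall)),
    }


# ---------------------------------------------------------------------------
# Metrics and summaries
# ---------------------------------------------------------------------------

def error_metrics(actual: np.ndarray, predicted: np.ndarray, task: str) -> float:
    """RMSE in physical units (time/speed) or mean absolute angular error.

    Angular differences are wrapped to [0, 180] degrees, so e.g. 350 vs
    10 degrees is a 20 degree error.
    """
    actual = np.asarray(actual, float)
    predicted = np.asarray(predicted, float)
    if actual.shape != predicted.shape:
        raise ValueError("actual and predicted must have equal length")
    if task == "phase":
        d = np.abs(actual - predicted) % 360.0
        d = np.minimum(d, 360.0 - d)
        return float(np.mean(d))
    return float(np.sqrt(np.mean((actual - predicted) ** 2)))


def prepost_summary(
    result: DecodingResult,
    pre_window: tuple[float, float] = (-0.9, -0.3),
    post_window: tuple[float, float] = (0.3, 0.9),
) -> dict:
    """Mean accuracy in the preparatory and performance windows.

    Averages the per-class accuracy over the time bins whose centres lie
    strictly inside each window (three 0.2 s bins per window at the
    default geometry). Per-draw means are returned for group statistics.
    """
    if result.task != "time":
        raise ValueError("pre/post summary applies to the time task only")
    centers = result.class_values
    pre = (centers > pre_window[0]) & (centers < pre_window[1])
    post = (centers > post_window[0]) & (centers < post_window[1])
    return {
        "pre": float(result.per_class_accuracy[pre].mean()),
        "post": float(result.per_class_accuracy[post].mean()),
        "pre_bins": int(pre.sum()),
        "post_bins": int(post.sum()),
        "pre_per_draw": result.per_draw_per_class[:, pre].mean(axis=1),
        "post_per_draw": result.per_draw_per_class[:, post].mean(axis=1),
    }


def size_sweep(
    tensor: TrialTensor,
    spec: DecoderSpec,
    sizes: Sequence[int] = (25, 50, 100, 150, 200),
) -> list[dict]:
    """Decoding accuracy as a function of pseudo-population size."""
    usable = [s for s in sizes if s <= tensor.n_units]
    if len(usable) < len(sizes):
        warnings.warn(
            f"only {tensor.n_units} units available; sizes truncated to {usable}"
        )
    out = []
    for size in usable:
        res = evaluate(tensor, replace(spec, n_units=size))
        out.append(
            {
                "n_units": size,
                "mean_accuracy": float(res.per_draw_accuracy.mean()),
                "sd_accuracy": float(res.per_draw_accuracy.std(ddof=1))
                if spec.n_draws > 1
                else 0.0,
            }
        )
    return out
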