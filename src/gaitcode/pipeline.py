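"""End-to-end orchestration and group comparisons across regions.

``run_all`` executes segmentation, single-unit statistics, and the three
decoding tasks for every region label in a cohort, then assembles a JSON
report whose every number recomputes from the per-unit tables. Group
comparisons follow a normality-gated branch: Lilliefors test per group,
then one-way ANOVA with Tukey post hoc if all groups look normal,
otherwise Kruskal-Wallis with Dunn-Sidak post hoc (Friedman for paired
designs, chi-squared with Sidak adjustment for proportions).
"""

from __future__ import annotations

import itertools
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as spstats
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .decoding import (
    DecoderSpec,
    build_trials,
    evaluate,
    prepost_summary,
    shuffle_null,
)
from .kinematics import SegmentedSession, segment_session
from .session import LIMBS, RunConfig, Session, derive_seed
from .unit_stats import estimate_rates, jitter_test, modulated_fraction, speed_tuning

__all__ = ["run_all", "compare_groups", "unit_stats_table"]


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def _dunn_sidak(groups: dict[str, np.ndarray]) -> list[dict]:
    """Dunn's rank-sum post hoc z-tests with Sidak correction.

    No installed package exposes Dunn's test directly, so the standard
    rank-mean z statistic (with tie correction) is computed here and the
    per-pair p-values are Sidak-adjusted for the number of pairs.
    """
    names = list(groups)
    all_vals = np.concatenate([groups[g] for g in names])
    ranks = spstats.rankdata(all_vals)
    n_total = len(all_vals)
    # tie correction term
    _, counts = np.unique(all_vals, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12 * (n_total - 1))
    mean_ranks, sizes = {}, {}
    start = 0
    for g in names:
        n = len(groups[g])
        mean_ranks[g] = ranks[start : start + n].mean()
        sizes[g] = n
        start += n
    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        se = np.sqrt(
            (n_total * (n_total + 1) / 12.0 - tie_term)
            * (1.0 / sizes[a] + 1.0 / sizes[b])
        )
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2 * spstats.norm.sf(abs(z))
        p_adj = 1 - (1 - min(p, 1.0)) ** m
        rows.append(
            {"group_a": a, "group_b": b, "statistic": float(z), "p": float(p_adj)}
        )
    return rows


def compare_groups(
    groups: dict[str, np.ndarray],
    design: str = "independent",
    alpha: float = 0.05,
    lilliefors_alpha: float = 0.05,
) -> dict:
    """Normality-gated omnibus test with post hoc pairwise comparisons.

    Parameters
    ----------
    groups
        Mapping group label -> 1-D sample. For ``design='paired'`` all
        samples must have equal length (rows are matched observations).
    design
        ``'independent'``: one-way ANOVA + Tukey, or Kruskal-Wallis +
        Dunn-Sidak. ``'paired'``: repeated-measures ANOVA, or Friedman +
        Dunn-Sidak. ``'proportions'``: groups are (successes, total)
        pairs, compared by pairwise chi-squared with Sidak adjustment.
    """
    names = [g for g in groups]
    if design == "proportions":
        return _compare_proportions(groups)
    usable = {g: np.asarray(v, float) for g, v in groups.items() if len(v) >= 3}
    dropped = sorted(set(names) - set(usable))
    if len(usable) < 2:
        raise ValueError("need at least two groups with n >= 3")

    normal = True
    for v in usable.values():
        if np.ptp(v) == 0 or len(v) < 4:
            # Lilliefors needs n >= 4; tiny or degenerate groups take the
            # distribution-free branch
            normal = False
            break
        if lilliefors(v, dist="norm")[1] < lilliefors_alpha:
            normal = False
            break

    samples = [usable[g] for g in usable]
    rows: list[dict] = []
    if design == "paired":
        if len({len(v) for v in samples}) != 1:
            raise ValueError("paired design requires equal group sizes")
        if normal:
            test_name = "repeated-measures ANOVA"
            data = np.column_stack(samples)
            stat, p = _rm_anova(data)
        else:
            test_name = "Friedman"
            stat, p = spstats.friedmanchisquare(*samples)
            stat, p = float(stat), float(p)
        rows = _dunn_sidak(usable) if not normal else _tukey_rows(usable)
    elif design == "independent":
        if normal:
            test_name = "one-way ANOVA"
            stat, p = spstats.f_oneway(*samples)
            stat, p = float(stat), float(p)
            if not np.isfinite(p):  # identical groups: F ~ 0/0
                stat, p = max(stat, 0.0), 1.0
            rows = _tukey_rows(usable)
        else:
            test_name = "Kruskal-Wallis"
            stat, p = spstats.kruskal(*samples)
            stat, p = float(stat), float(p)
            rows = _dunn_sidak(usable)
    else:
        raise ValueError(f"unknown design {design!r}")
    return {
        "test": test_name,
        "statistic": stat,
        "p": p,
        "normal_gate": normal,
        "post_hoc": rows,
        "dropped_groups": dropped,
    }


def _rm_anova(data: np.ndarray) -> tuple[float, float]:
    """One-way repeated-measures ANOVA F and p (subjects x conditions)."""
    n, k = data.shape
    grand = data.mean()
    ss_cond = n * np.sum((data.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((data.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((data - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (n - 1) * (k - 1)
    f = (ss_cond / df_cond) / (ss_err / df_err)
    p = spstats.f.sf(f, df_cond, df_err)
    return float(f), float(p)


def _tukey_rows(groups: dict[str, np.ndarray]) -> list[dict]:
    vals = np.concatenate(list(groups.values()))
    labels = np.concatenate([[g] * len(v) for g, v in groups.items()])
    res = pairwise_tukeyhsd(vals, labels)
    rows = []
    for (a, b), p, stat in zip(
        itertools.combinations(res.groupsunique.tolist(), 2),
        res.pvalues,
        res.meandiffs,
    ):
        rows.append(
            {"group_a": a, "group_b": b, "statistic": float(stat), "p": float(p)}
        )
    return rows


def _compare_proportions(groups: dict) -> dict:
    """Pairwise chi-squared on (successes, total) with Sidak adjustment."""
    pairs = list(itertools.combinations(groups, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        sa, na = groups[a]
        sb, nb = groups[b]
        table = np.array([[sa, na - sa], [sb, nb - sb]])
        chi2, p, _, _ = spstats.chi2_contingency(table, correction=False)
        p_adj = 1 - (1 - min(p, 1.0)) ** m
        rows.append(
            {"group_a": a, "group_b": b, "statistic": float(chi2), "p": float(p_adj)}
        )
    return {
        "test": f"pairwise chi-squared (Sidak-adjusted for {m} comparisons)",
        "statistic": None,
        "p": None,
        "normal_gate": None,
        "post_hoc": rows,
        "dropped_groups": [],
    }


# ---------------------------------------------------------------------------
# Per-unit statistics table
# ---------------------------------------------------------------------------

def unit_stats_table(
    segmented: Sequence[SegmentedSession],
    config: RunConfig,
    n_jitter: Optional[int] = None,
) -> pd.DataFrame:
    """Speed-correlation and phase-locking summary for every unit."""
    n_jitter = n_jitter or config.n_jitter
    rows = []
    for seg in segmented:
        sess = seg.session
        mask = seg.walking_mask
        for u in sess.units:
            st = speed_tuning(
                u.spike_times, seg.speed, mask, sess.frame_rate,
                config.speed_bin_edges,
            )
            row = {
                "session_id": sess.session_id,
                "unit_id": u.unit_id,
                "region": u.region,
                "speed_r2": st.r_squared,
                "speed_p": st.p_value,
                "speed_valid": st.valid,
            }
            locked_any = False
            for limb in LIMBS:
                pl = jitter_test(
                    u.spike_times,
                    seg.phases[limb],
                    sess.frame_rate,
                    config.n_phase_hist_bins,
                    config.jitter_window,
                    n_jitter,
                    seed=derive_seed(config.random_seed, f"jitter:{u.unit_id}:{limb}"),
                )
                row[f"r_{limb}"] = pl.vector_length
                row[f"pref_{limb}"] = pl.preferred_phase
                row[f"locked_{limb}"] = bool(pl.is_locked)
                locked_any |= bool(pl.is_locked)
            row["locked_any"] = locked_any
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def _round_floats(obj, ndigits=8):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def run_all(
    sessions: Sequence[Session],
    config: RunConfig,
    decoder_spec: Optional[DecoderSpec] = None,
    tasks: Sequence[str] = ("time", "speed", "phase"),
    out_dir: Optional[str | Path] = None,
    with_shuffle: bool = False,
) -> dict:
    """Run segmentation, unit statistics, and decoding per region.

    Returns (and optionally writes as ``report.json``) a report whose
    decoding section holds one entry per region label per task. The
    group-comparison table operates on draw-level decoding accuracies,
    with the caveat, logged in the report, that draws of overlapping
    unit subsets are not independent samples.
    """
    dspec = decoder_spec or DecoderSpec(seed=config.random_seed)
    report: dict = {"config": config.to_dict(), "regions": {}, "decoding": {}}

    segmented = [segment_session(s, config) for s in sessions]
    report["n_sessions"] = len(sessions)
    report["n_bouts"] = int(sum(len(s.bouts) for s in segmented))

    # --- per-unit statistics, by region
    stats = unit_stats_table(segmented, config)
    regions = sorted(stats["region"].unique())
    for region in regions:
        sub = stats[stats["region"] == region]
        sig_speed = (sub["speed_p"] < config.alpha) & sub["speed_valid"]
        report["regions"][region] = {
            "n_units": int(len(sub)),
            "pct_speed_correlated": float(100.0 * sig_speed.mean()),
            "pct_phase_locked": float(100.0 * sub["locked_any"].mean()),
            "mean_vector_length": float(
                np.nanmean(sub[[f"r_{l}" for l in LIMBS]].to_numpy())
            ),
        }

    # --- modulated fraction per region
    for region in regions:
        mats = []
        for seg in segmented:
            onsets = [
                b.onset_frame / seg.session.frame_rate
                for b in seg.bouts
                if b.onset_frame / seg.session.frame_rate
                + config.modulation_window[0]
                >= 0
                and b.onset_frame / seg.session.frame_rate
                + config.modulation_window[1]
                <= seg.session.duration
            ]
            if len(onsets) < 2:
                continue
            for u in seg.session.units:
                if u.region != region:
                    continue
                mats.append(
                    estimate_rates(
                        u.spike_times,
                        onsets,
                        config.modulation_window,
                        config.kernel_sd,
                        config.base_bin,
                        config.rate_bin,
                    )
                )
        if mats:
            centers, fraction, _ = modulated_fraction(
                mats, config.baseline_window, config.alpha
            )
            report["regions"][region]["modulated_fraction"] = {
                "bin_centers_s": centers.tolist(),
                "fraction": fraction.tolist(),
            }

    # --- decoding per region per task
    draw_samples: dict[str, dict[str, np.ndarray]] = {t: {} for t in tasks}
    for region in regions:
        region_segs = [
            _region_view(seg, region) for seg in segmented
        ]
        report["decoding"][region] = {}
        for task in tasks:
            try:
                tensor = build_trials(region_segs, task, dspec)
            except ValueError as exc:
                report["decoding"][region][task] = {"error": str(exc)}
                continue
            res = evaluate(tensor, dspec)
            entry = {
                "overall_accuracy": res.overall_accuracy,
                "per_class_accuracy": res.per_class_accuracy.tolist(),
                "error_metric": res.error_metric,
                "confusion": res.confusion.tolist(),
                "n_units": res.n_units,
                "per_draw_accuracy": res.per_draw_accuracy.tolist(),
            }
            if task == "time":
                pp = prepost_summary(res)
                entry["pre_start_accuracy"] = pp["pre"]
                entry["post_start_accuracy"] = pp["post"]
            if with_shuffle:
                band = shuffle_null(tensor, dspec)
                entry["shuffle_band"] = list(band["overall_band"])
            report["decoding"][region][task] = entry
            draw_samples[task][region] = res.per_draw_accuracy

    # --- group comparisons on draw-level accuracies
    report["group_comparisons"] = {}
    report["group_comparison_caveat"] = (
        "samples are random unit draws from a fixed population and are "
        "not independent"
    )
    if len(regions) >= 2:
        for task in tasks:
            samples = {r: v for r, v in draw_samples[task].items() if len(v) >= 3}
            if len(samples) >= 2:
                report["group_comparisons"][task] = compare_groups(samples)
    else:
        report["group_comparisons"]["notice"] = (
            "single region: group comparisons skipped"
        )

    report = _round_floats(report)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        stats.to_csv(out_dir / "units_stats.tsv", sep="\t", index=False,
                     float_format="%.8g")
        (out_dir / "report.json").write_text(
            json.dumps(report, sort_keys=True, indent=1) + "\n"
        )
    return report


def _region_view(seg: SegmentedSession, region: str) -> SegmentedSession:
    """A segmented session restricted to one region's units."""
    sess = seg.session
    sub = Session.__new__(Session)  # skip re-validation of shared tables
    sub.session_id = sess.session_id
    sub.kinematics = sess.kinematics
    sub.units = [u for u in sess.units if u.region == region]
    sub.frame_rate = sess.frame_rate
    sub.duration = sess.duration
    return SegmentedSession(
        session=sub,
        smoothed=seg.smoothed,
        speed=seg.speed,
        bouts=seg.bouts,
        strides=seg.strides,
        phases=seg.phases,
        filtered=seg.filtered,
    )
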