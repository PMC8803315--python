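"""Session-level impulsivity metrics, trait splits, and motion-state extraction.

Waiting impulsivity is operationalized as the precue response rate (pokes per
second of precue exposure) and stopping impulsivity as the percentage of
No-Go trials ending in a false alarm.  A compound impulsivity score (mean of
within-cohort fractional ranks of the two metrics) drives the HI/LI trait
split by quartile or median.  The module also carries the cohort-level
statistical utilities used around these metrics (Grubbs outlier screen at a
conservative alpha, pooled two-sample Kolmogorov-Smirnov comparisons) and the
immobility-state extraction from the motion-measure trace (2 s moving
average, 1 s minimum state duration, merging of episodes < 0.5 s apart).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .synthetic import SessionLog

__all__ = [
    "BehaviorMetrics",
    "TraitAssignment",
    "ImmobilityIntervals",
    "classify_trial_outcome",
    "compute_session_metrics",
    "per_trial_precue_rates",
    "apply_inclusion_criteria",
    "assign_trait_groups",
    "grubbs_outlier_test",
    "grubbs_critical_value",
    "compare_pooled_distributions",
    "extract_immobility",
    "interval_jaccard",
    "precue_rate_category",
]


@dataclass(frozen=True)
class BehaviorMetrics:
    """Per-session impulsivity and performance summary.

    ``pct_correct_go`` / ``pct_ng_fa`` are NaN (with ``undefined_percent``
    set) when the session has no completed trials of the relevant type.
    """

    precue_response_rate: float
    pct_correct_go: float
    pct_ng_fa: float
    n_trials: int
    total_licks: int
    distance: float
    undefined_percent: bool = False


@dataclass(frozen=True)
class TraitAssignment:
    animal_id: str
    compound_score: float
    group: str  # HI / LI / Middle / Tied


@dataclass(frozen=True)
class ImmobilityIntervals:
    intervals: tuple[tuple[float, float], ...]
    source_trace_id: str = ""

    def total_duration(self) -> float:
        return float(sum(e - s for s, e in self.intervals))


# ---------------------------------------------------------------------------
# Trial outcomes and session metrics
# ---------------------------------------------------------------------------

def classify_trial_outcome(trial_type: str, cue_window: tuple[float, float],
                           poke_times, abort_window: tuple[float, float]):
    """Classify one trial from raw poke times.

    The first poke inside the abort window (final stretch of the precue
    period) aborts the trial regardless of later pokes.  Otherwise, the
    first poke inside the cue window ends the cue: on a Go trial this is a
    correct response, on a No-Go trial a false alarm; absence of cue pokes
    gives an omission (Go) or a correct withhold (No-Go).

    Returns ``(outcome, response_latency_s)``; the latency is None except
    for CorrectGo / FalseAlarm outcomes.
    """
    poke_times = np.asarray(poke_times, dtype=float)
    if np.any(np.diff(poke_times) < 0):
        raise ValueError("poke_times must be sorted ascending")
    a0, a1 = abort_window
    c0, c1 = cue_window
    if a1 > c0 + 1e-12:
        raise ValueError("abort window must precede the cue window")
    if np.any((poke_times >= a0) & (poke_times < a1)):
        return "Aborted", None
    in_cue = poke_times[(poke_times >= c0) & (poke_times < c1)]
    if trial_type == "Go":
        if len(in_cue):
            return "CorrectGo", float(in_cue[0] - c0)
        return "Omission", None
    if trial_type == "NG":
        if len(in_cue):
            return "FalseAlarm", float(in_cue[0] - c0)
        return "CorrectNoGo", None
    raise ValueError(f"unknown trial type: {trial_type!r}")


def compute_session_metrics(session: SessionLog,
                            include_aborted_exposure: bool = False) -> BehaviorMetrics:
    """Compute the session's impulsivity/performance summary.

    The precue response rate pools pokes and exposure seconds across trials:
    rate = (total precue pokes) / (total precue seconds).  By default trials
    terminated by an abort poke are excluded from both numerator and
    denominator (``include_aborted_exposure=True`` instead counts their
    truncated exposure and pokes).  Percentages use completed trials only:
    ``%correct Go = 100 * CorrectGo / (CorrectGo + Omission)`` and
    ``%NG with FA = 100 * FalseAlarm / (FalseAlarm + CorrectNoGo)``.
    """
    tr = session.trials
    if len(tr) == 0:
        raise ValueError("session has no trials")
    completed = tr[tr["outcome"] != "Aborted"]
    pokes = float(completed["n_precue_pokes"].sum())
    exposure = float(completed["precue_duration_s"].sum())
    if include_aborted_exposure:
        aborted = tr[tr["outcome"] == "Aborted"]
        pokes += float(aborted["n_precue_pokes"].sum())
        # exposure of an aborted trial runs up to the aborting poke
        ev = session.events
        abort_times = ev.loc[ev["event_label"] == "abort_poke"]
        for _, row in abort_times.iterrows():
            onset = float(tr.loc[tr["index"] == row["trial_index"],
                                 "precue_onset_s"].iloc[0])
            exposure += float(row["time_s"]) - onset
    rate = pokes / exposure if exposure > 0 else 0.0

    n_cg = int((tr["outcome"] == "CorrectGo").sum())
    n_om = int((tr["outcome"] == "Omission").sum())
    n_fa = int((tr["outcome"] == "FalseAlarm").sum())
    n_cn = int((tr["outcome"] == "CorrectNoGo").sum())
    undefined = (n_cg + n_om == 0) or (n_fa + n_cn == 0)
    pct_go = 100.0 * n_cg / (n_cg + n_om) if n_cg + n_om else np.nan
    pct_fa = 100.0 * n_fa / (n_fa + n_cn) if n_fa + n_cn else np.nan

    motion = session.motion["motion"].to_numpy(dtype=float)
    # arbitrary-unit path length of the motion measure
    distance = float(np.sum(motion) / session.motion_fs_hz / 100.0)
    return BehaviorMetrics(
        precue_response_rate=float(rate), pct_correct_go=float(pct_go),
        pct_ng_fa=float(pct_fa), n_trials=int(len(tr)),
        total_licks=int(tr["lick_count"].sum()), distance=distance,
        undefined_percent=bool(undefined))


def per_trial_precue_rates(session: SessionLog) -> pd.DataFrame:
    """Per-trial precue poke rate and count for completed trials.

    Used for stratifying unit activity by precue-poke load; the rate is
    pokes / precue seconds of that trial, with the same definition as the
    pooled session rate.
    """
    tr = session.trials
    completed = tr[tr["outcome"] != "Aborted"].copy()
    completed["precue_rate"] = (completed["n_precue_pokes"]
                                / completed["precue_duration_s"])
    return completed[["index", "trial_type", "precue_onset_s", "cue_onset_s",
                      "precue_duration_s", "n_precue_pokes", "precue_rate",
                      "outcome"]]


def precue_rate_category(rate: float, n_pokes: int) -> str:
    """Precue-load category: none / low (<0.15) / mid [0.15, 0.3) / high (>=0.3).

    Boundary values fall in the higher-labelled bin (intervals closed on the
    left); trials with no precue poke are their own category.
    """
    if n_pokes == 0:
        return "none"
    if rate < 0.15:
        return "low"
    if rate < 0.3:
        return "mid"
    return "high"


# ---------------------------------------------------------------------------
# Inclusion criteria and trait split
# ---------------------------------------------------------------------------

def apply_inclusion_criteria(history: pd.DataFrame) -> pd.DataFrame:
    """Apply training and exclusion thresholds to a session history.

    ``history`` needs columns ``pct_correct_go`` and ``pct_ng_fa`` in
    session order.  A session is excluded when %correct Go < 80 or %FA > 60;
    training is passed from the first session that completes three
    consecutive sessions with %correct Go >= 80 and %FA <= 45 (both bounds
    inclusive).  With fewer than 3 sessions the stability criterion is
    undetermined (``training_passed`` all-NA column of dtype object).
    """
    go = history["pct_correct_go"].to_numpy(dtype=float)
    fa = history["pct_ng_fa"].to_numpy(dtype=float)
    out = history.copy()
    out["session_excluded"] = (go < 80.0) | (fa > 60.0)
    ok = (go >= 80.0) & (fa <= 45.0)
    n = len(history)
    passed = np.zeros(n, dtype=bool)
    if n < 3:
        out["training_passed"] = pd.array([pd.NA] * n, dtype="object")
        out.attrs["stability"] = "undetermined"
        return out
    reached = False
    for i in range(n):
        if i >= 2 and ok[i] and ok[i - 1] and ok[i - 2]:
            reached = True
        passed[i] = reached
    out["training_passed"] = passed
    out.attrs["stability"] = "determined"
    return out


def assign_trait_groups(metrics: pd.DataFrame,
                        method: str = "quartile") -> list[TraitAssignment]:
    """Split a cohort into HI/LI trait groups by compound impulsivity score.

    ``metrics`` needs columns ``animal_id``, ``precue_response_rate`` and
    ``pct_ng_fa``.  The compound score is the mean of the within-cohort
    fractional ranks of the two metrics (rank / n, average ranks on ties).
    Method ``"quartile"`` labels scores >= the 75th percentile HI and <= the
    25th percentile LI (others Middle); ``"median"`` labels above-median HI
    and below-median LI.  Scores exactly equal to a median cut, or an
    all-identical cohort, are flagged ``Tied``.
    """
    n = len(metrics)
    if method == "quartile" and n < 4:
        raise ValueError("quartile split needs at least 4 animals")
    if method == "median" and n < 2:
        raise ValueError("median split needs at least 2 animals")
    r1 = stats.rankdata(metrics["precue_response_rate"]) / n
    r2 = stats.rankdata(metrics["pct_ng_fa"]) / n
    score = (r1 + r2) / 2.0
    out: list[TraitAssignment] = []
    if np.allclose(score, score[0]):
        warnings.warn("all compound scores identical; flagging every animal Tied")
        return [TraitAssignment(a, float(s), "Tied")
                for a, s in zip(metrics["animal_id"], score)]
    if method == "quartile":
        lo, hi = np.percentile(score, [25.0, 75.0])
        for a, s in zip(metrics["animal_id"], score):
            if s >= hi:
                grp = "HI"
            elif s <= lo:
                grp = "LI"
            else:
                grp = "Middle"
            out.append(TraitAssignment(a, float(s), grp))
    elif method == "median":
        med = float(np.median(score))
        for a, s in zip(metrics["animal_id"], score):
            if np.isclose(s, med):
                grp = "Tied"  # sits exactly on the cut
            elif s > med:
                grp = "HI"
            else:
                grp = "LI"
            out.append(TraitAssignment(a, float(s), grp))
    else:
        raise ValueError(f"unknown split method: {method!r}")
    return out


# ---------------------------------------------------------------------------
# Cohort statistics
# ---------------------------------------------------------------------------

def grubbs_critical_value(n: int, alpha: float, two_sided: bool = True) -> float:
    """Grubbs critical value from the Student-t quantile.

    ``G_crit = (n-1)/sqrt(n) * sqrt(t^2 / (n - 2 + t^2))`` with ``t`` the
    upper ``alpha/(2n)`` (two-sided) or ``alpha/n`` (one-sided) quantile of
    the t distribution on ``n - 2`` degrees of freedom.
    """
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    q = alpha / (2 * n) if two_sided else alpha / n
    t = stats.t.ppf(1.0 - q, n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def grubbs_outlier_test(values, alpha: float = 1e-4,
                        two_sided: bool = True) -> int | None:
    """Single-outlier Grubbs screen; returns the flagged index or None.

    At most one point is flagged per call: the one with the largest absolute
    deviation from the mean, when ``G = max|x - mean| / sd`` exceeds the
    t-quantile critical value at the given alpha.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("Grubbs test needs a 1-D sample with n >= 3")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    sd = x.std(ddof=1)
    if sd == 0:
        return None
    dev = np.abs(x - x.mean())
    i = int(np.argmax(dev))
    g = dev[i] / sd
    return i if g > grubbs_critical_value(len(x), alpha, two_sided) else None


def compare_pooled_distributions(group_a, group_b):
    """Two-sample Kolmogorov-Smirnov test on trial values pooled per group.

    Returns ``(D, p)``.  Callers pool trials across animals within each
    group before calling.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Immobility extraction
# ---------------------------------------------------------------------------

def _runs(mask: np.ndarray):
    """Start/end sample indices (half-open) of True runs."""
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts, ends))


def extract_immobility(motion, fs_hz: float, window_s: float = 2.0,
                       threshold: float = 80.0, min_duration_s: float = 1.0,
                       merge_gap_s: float = 0.5, merge_first: bool = True,
                       trace_id: str = "") -> ImmobilityIntervals:
    """Extract immobility intervals from a motion-measure trace.

    The trace is smoothed with a centered moving average of ``window_s``;
    a sample is immobile when the smoothed motion measure is at most
    ``100 - threshold`` on the 0-100 scale (the motion measure is low when
    the animal is still, so threshold 80 cuts at motion <= 20).  Immobile
    runs separated by gaps shorter than ``merge_gap_s`` are merged, then
    runs shorter than ``min_duration_s`` are dropped (``merge_first=False``
    reverses the order).
    """
    x = np.asarray(motion, dtype=float)
    win = max(int(round(window_s * fs_hz)), 1)
    if len(x) < win:
        raise ValueError("trace shorter than the smoothing window")
    smoothed = ndimage.uniform_filter1d(x, size=win, mode="nearest")
    mask = smoothed <= (100.0 - threshold)
    iv = [(s / fs_hz, e / fs_hz) for s, e in _runs(mask)]

    def merge(v):
        out = []
        for s, e in v:
            if out and s - out[-1][1] < merge_gap_s:
                out[-1] = (out[-1][0], e)
            else:
                out.append((s, e))
        return out

    def drop_short(v):
        return [(s, e) for s, e in v if e - s >= min_duration_s]

    iv = drop_short(merge(iv)) if merge_first else merge(drop_short(iv))
    return ImmobilityIntervals(intervals=tuple(iv), source_trace_id=trace_id)


def interval_jaccard(a, b) -> float:
    """Jaccard overlap (intersection / union of total covered time) of two
    interval sets; 1.0 when both are empty."""
    def as_arr(v):
        return np.array([(s, e) for s, e in v], dtype=float).reshape(-1, 2)

    ia, ib = as_arr(a), as_arr(b)
    if len(ia) == 0 and len(ib) == 0:
        return 1.0
    edges = np.unique(np.concatenate([ia.ravel(), ib.ravel()]))
    mids = (edges[:-1] + edges[1:]) / 2.0
    lens = np.diff(edges)

    def covered(iv, pts):
        if len(iv) == 0:
            return np.zeros(len(pts), dtype=bool)
        return np.any((pts[:, None] >= iv[None, :, 0])
                      & (pts[:, None] < iv[None, :, 1]), axis=1)

    ca, cb = covered(ia, mids), covered(ib, mids)
    inter = float(lens[ca & cb].sum())
    union = float(lens[ca | cb].sum())
    return inter / union if union > 0 else 1.0
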