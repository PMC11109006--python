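"""Secretion-positivity calling, phenotype classification and group statistics.

The detection limit is anchored to the empty wells of the same dish: their
intensity fluctuations estimate the noise floor, robustly, as
sigma = 1.4826 * MAD.  A well is secretion-positive when its cumulative
signal stays above 3*sigma for at least two frames, tolerating transient
dips below threshold of up to three frames (the cumulative signal is
continuous in time, so an isolated supra-threshold frame is noise, and a
short dip inside a real episode is, too).  Positive wells are split into
slightly-active and hyperactive phenotypes at 50*sigma of maximum signal,
a cut that coincides with the boundary a 2-class k-means finds on the
log-intensity distribution (reported here as a concordance check; the
50*sigma rule is authoritative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .deconvolve import CssTrace

__all__ = [
    "RobustSD",
    "ThresholdSet",
    "SecretionCall",
    "robust_sd",
    "call_positive",
    "classify_activity",
    "kmeans_concordance",
    "ActivationCurve",
    "activation_curve",
    "TestResult",
    "compare_groups",
    "significance_label",
]

MAD_TO_SD = 1.4826  # consistency factor for Gaussian noise


class RobustSD(NamedTuple):
    sigma: float
    degenerate: bool


def robust_sd(values) -> RobustSD:
    """Robust noise SD: 1.4826 x median absolute deviation.

    Returns sigma with a ``degenerate`` flag when the MAD is zero (constant
    data); callers must refuse to call positivity with a degenerate sigma.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 values for a robust SD")
    mad = float(np.median(np.abs(x - np.median(x))))
    return RobustSD(sigma=MAD_TO_SD * mad, degenerate=(mad == 0.0))


@dataclass(frozen=True)
class ThresholdSet:
    """Detection (3 sigma) and hyperactivity (50 sigma) limits for one stratum."""

    sigma: float
    detect_mult: float = 3.0
    hyper_mult: float = 50.0
    channel: str = ""
    stratum: str = ""
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    @property
    def detection_limit(self) -> float:
        return self.detect_mult * self.sigma

    @property
    def hyper_limit(self) -> float:
        return self.hyper_mult * self.sigma


@dataclass
class SecretionCall:
    """Positivity verdict for one well/channel trace."""

    well_id: str
    channel: str
    positive: bool
    onset_frame: int | None
    onset_time: float | None
    episodes: list[tuple[int, int]]
    max_css: float
    thresholds: ThresholdSet
    activity_class: str | None = None
    insufficient_data: bool = False

    def __post_init__(self) -> None:
        if self.positive and self.onset_frame is None:
            raise ValueError("positive call requires an onset")
        if not self.positive and self.onset_frame is not None:
            raise ValueError("negative call cannot carry an onset")


def _episodes(supra: np.ndarray, max_gap: int) -> list[list[int]]:
    """Group supra-threshold frame indices; gaps <= max_gap join an episode."""
    idx = np.flatnonzero(supra)
    groups: list[list[int]] = []
    for i in idx:
        if groups and i - groups[-1][-1] - 1 <= max_gap:
            groups[-1].append(int(i))
        else:
            groups.append([int(i)])
    return groups


def call_positive(
    trace: CssTrace,
    thresholds: ThresholdSet,
    min_run: int = 2,
    max_gap: int = 3,
    well_id: str = "",
) -> SecretionCall:
    """Call secretion positivity on a CSS trace.

    A frame is supra-threshold when its value is >= the detection limit.
    Supra frames separated by at most ``max_gap`` sub-threshold frames
    belong to one episode (the gap allowance may be used repeatedly); the
    trace is positive iff some episode contains at least ``min_run`` supra
    frames.  Onset is the first frame of the first qualifying episode.
    """
    if thresholds.degenerate or thresholds.sigma == 0:
        raise ValueError("cannot call positivity with a degenerate sigma")
    v = trace.values
    if v.size < min_run:
        return SecretionCall(
            well_id=well_id, channel=trace.channel, positive=False,
            onset_frame=None, onset_time=None, episodes=[],
            max_css=float(np.max(v)) if v.size else float("nan"),
            thresholds=thresholds, insufficient_data=True,
        )
    supra = v >= thresholds.detection_limit
    qualifying = [g for g in _episodes(supra, max_gap) if len(g) >= min_run]
    positive = bool(qualifying)
    onset = qualifying[0][0] if positive else None
    return SecretionCall(
        well_id=well_id, channel=trace.channel, positive=positive,
        onset_frame=onset,
        onset_time=None if onset is None else onset * trace.frame_interval,
        episodes=[(g[0], g[-1]) for g in qualifying],
        max_css=float(np.max(v)),
        thresholds=thresholds,
    )


def classify_activity(call: SecretionCall, thresholds: ThresholdSet | None = None) -> str:
    """Assign silent / slightly_active / hyperactive and record it on the call."""
    th = thresholds if thresholds is not None else call.thresholds
    if th.degenerate or th.sigma == 0:
        raise ValueError("cannot classify with a degenerate sigma")
    if not call.positive:
        cls = "silent"
    elif call.max_css >= th.hyper_limit:
        cls = "hyperactive"
    else:
        cls = "slightly_active"
    call.activity_class = cls
    return cls


def kmeans_concordance(
    max_css_positive: Sequence[float],
    thresholds: ThresholdSet,
    seed: int = 0,
) -> dict:
    """2-class k-means on log10(max CSS) of positive wells vs the 50-sigma rule.

    Returns the k-means boundary (in CSS units), per-well k-means labels
    mapped to {slightly_active, hyperactive}, and the fraction agreeing
    with the 50-sigma classification.  Informative only; the threshold
    rule remains the classifier of record.
    """
    x = np.asarray(max_css_positive, dtype=float)
    if x.size < 2 or np.any(x <= 0):
        raise ValueError("need >= 2 positive, strictly positive max CSS values")
    lx = np.log10(x).reshape(-1, 1)
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(lx)
    hi_cluster = int(np.argmax(km.cluster_centers_.ravel()))
    km_hyper = km.labels_ == hi_cluster
    rule_hyper = x >= thresholds.hyper_limit
    lo, hi = sorted(km.cluster_centers_.ravel())
    boundary = 10 ** ((lo + hi) / 2.0)
    return {
        "boundary": float(boundary),
        "kmeans_hyper": km_hyper,
        "rule_hyper": rule_hyper,
        "concordance": float(np.mean(km_hyper == rule_hyper)),
    }


@dataclass
class ActivationCurve:
    """Cumulative fraction of wells that have begun secreting, vs time."""

    times: np.ndarray
    fraction_activated: np.ndarray
    at_risk: np.ndarray
    durations: np.ndarray
    events: np.ndarray


def activation_curve(calls: Sequence[SecretionCall], horizon: float) -> ActivationCurve:
    """Kaplan-Meier style activation curve from onset times.

    The event is secretion onset; wells never called positive are censored
    at ``horizon``.  Fraction activated = 1 - S(t).  The returned
    durations/events are suitable for log-rank comparison.
    """
    if not calls:
        raise ValueError("no calls supplied")
    durations = np.array(
        [c.onset_time if c.positive else horizon for c in calls], dtype=float
    )
    events = np.array([c.positive for c in calls], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    frac = 1.0 - kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = np.array([np.sum(durations >= t) for t in times])
    return ActivationCurve(
        times=times, fraction_activated=frac, at_risk=at_risk,
        durations=durations, events=events,
    )


@dataclass
class TestResult:
    statistic: float
    p_value: float
    p_adjusted: float | None = None
    method: str = ""
    label: str = ""
    tie_warning: bool = False


def _one_test(a, b, method: str) -> TestResult:
    if method == "mannwhitney":
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError("need >= 2 observations per group")
        pooled = np.concatenate([a, b])
        if np.ptp(pooled) == 0:
            return TestResult(statistic=a.size * b.size / 2.0, p_value=1.0,
                              method=method, tie_warning=True)
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                          method=method)
    if method == "logrank":
        da, ea = a
        db, eb = b
        if len(da) < 2 or len(db) < 2:
            raise ValueError("need >= 2 observations per group")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = logrank_test(da, db, event_observed_A=ea, event_observed_B=eb)
        return TestResult(statistic=float(res.test_statistic),
                          p_value=float(res.p_value), method=method)
    raise ValueError(f"unknown method {method!r}")


def compare_groups(
    group_a,
    group_b,
    method: str = "mannwhitney",
    correction: str = "benjamini_hochberg",
) -> list[TestResult]:
    """Compare groups with Mann-Whitney or log-rank, BH-corrected.

    ``group_a``/``group_b`` are either one comparison or parallel lists of
    comparisons (the multiple-testing family).  For ``method="logrank"``
    each group is a (durations, events) pair.  Adjusted p-values are
    computed across the family with the Benjamini-Hochberg step-up
    procedure (``correction=None`` skips adjustment).
    """
    def is_family(g):
        if method == "logrank":
            # family: list of (durations, events) pairs
            return not (len(g) == 2 and np.ndim(g[0]) == 1 and np.ndim(g[1]) == 1
                        and len(g[0]) == len(g[1]))
        return np.ndim(g[0]) != 0

    family = is_family(group_a)
    pairs = list(zip(group_a, group_b)) if family else [(group_a, group_b)]
    results = [_one_test(a, b, method) for a, b in pairs]
    if correction == "benjamini_hochberg":
        ps = [r.p_value for r in results]
        _, p_adj, _, _ = multipletests(ps, method="fdr_bh")
        for r, p in zip(results, p_adj):
            r.p_adjusted = float(p)
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    return results


def significance_label(p: float) -> str:
    """Conventional star labels at 0.05 / 0.01 / 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
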