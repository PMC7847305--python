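"""ΔF% computation and control-calibrated responder calling for dendron ROIs.

Candidate transmitters are puff-applied (20-90 s) onto GnRH neuron distal
dendrons while GCaMP6 fluorescence is frame-scanned at ~0.9 Hz for 500 s.
Control aCSF puffs produce a small movement artifact (mean 4.5%, SD 0.5%
ΔF), so a drug response must (i) exceed the control mean plus two standard
deviations (5.5%) in either direction and (ii) outlast the puff window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import defaults

__all__ = [
    "RoiTrace",
    "DffTrace",
    "ResponseThreshold",
    "ResponseCall",
    "GroupSummary",
    "compute_dff",
    "qc_drift",
    "calibrate_threshold",
    "detect_response",
    "summarize_group",
    "compare_groups",
    "GroupComparison",
]


@dataclass
class RoiTrace:
    roi_id: str
    times: np.ndarray          # s, strictly increasing
    raw_f: np.ndarray          # raw fluorescence, arbitrary units
    frame_rate: float          # Hz
    puff_window: tuple[float, float]  # (start s, end s)
    baseline_frames: int = 20  # F0 frames at the start of the recording

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.raw_f = np.asarray(self.raw_f, dtype=float)
        if self.times.shape != self.raw_f.shape:
            raise ValueError("times and raw_f must have the same length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        start, end = self.puff_window
        if not (self.times[0] <= start < end <= self.times[-1]):
            raise ValueError("puff_window must lie within the recording")
        if not (1 <= self.baseline_frames <= np.searchsorted(self.times, start)):
            raise ValueError("baseline frames must precede the puff")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")


@dataclass
class DffTrace:
    roi_id: str
    times: np.ndarray
    dff: np.ndarray            # % change relative to F0
    drift: float               # % of F0 across the recording
    qc_pass: bool
    puff_window: tuple[float, float]


@dataclass
class ResponseThreshold:
    control_mean: float        # %
    control_sd: float          # %

    @property
    def threshold(self) -> float:
        return self.control_mean + defaults.THRESHOLD_N_SD * self.control_sd


@dataclass
class ResponseCall:
    roi_id: str
    peak_dff: float            # %, signed
    exceeds_threshold: bool
    outlasts_puff: bool

    @property
    def responder(self) -> bool:
        return self.exceeds_threshold and self.outlasts_puff


@dataclass
class GroupSummary:
    n_rois: int
    mean_peak: float           # % of peak ΔF, mean over ROIs
    sem_peak: float
    median_peak: float
    mean_trace: np.ndarray     # per-timepoint mean ΔF%
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    auc: float                 # trapezoidal integral of the mean trace, s·%F
    responder_fraction: float


def compute_dff(
    trace: RoiTrace,
    drift_limit: float = defaults.DRIFT_LIMIT_PCT,
) -> DffTrace:
    """ΔF% = 100·(F − F0)/F0 with F0 the mean of the leading baseline frames.

    Baseline drift is estimated as the difference between the mean ΔF% of a
    trailing window (same length as the baseline) and the leading baseline,
    i.e. the net change in baseline fluorescence across the recording.
    """
    n0 = trace.baseline_frames
    f0 = float(trace.raw_f[:n0].mean())
    if f0 <= 0:
        raise ValueError("baseline fluorescence F0 must be positive")
    dff = 100.0 * (trace.raw_f - f0) / f0
    drift = float(abs(dff[-n0:].mean() - dff[:n0].mean()))
    return DffTrace(
        roi_id=trace.roi_id,
        times=trace.times,
        dff=dff,
        drift=drift,
        qc_pass=drift < drift_limit,
        puff_window=trace.puff_window,
    )


def qc_drift(dff: DffTrace, limit: float = defaults.DRIFT_LIMIT_PCT) -> bool:
    """Accept the recording only when baseline drift is strictly below limit."""
    return dff.drift < limit


def calibrate_threshold(control_changes) -> ResponseThreshold:
    """Response threshold = control mean + 2 x sample SD of control changes."""
    vals = np.asarray(control_changes, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least two control values")
    return ResponseThreshold(
        control_mean=float(vals.mean()),
        control_sd=float(vals.std(ddof=1)),
    )


def detect_response(
    dff: DffTrace,
    threshold: ResponseThreshold,
    min_outlast_frames: int = defaults.OUTLAST_MIN_FRAMES,
) -> ResponseCall:
    """Call a responder: |peak ΔF%| beyond threshold AND outlasting the puff.

    The peak is the signed extremum of ΔF% from puff onset to the end of the
    recording; increases and decreases are both eligible.  "Outlasts" requires
    |ΔF%| to stay above threshold for at least ``min_outlast_frames``
    *consecutive* frames after the puff ends — a lone supra-threshold frame is
    indistinguishable from noise and does not constitute a sustained response.
    """
    start, end = dff.puff_window
    after_onset = dff.times >= start
    seg = dff.dff[after_onset]
    peak = float(seg[np.argmax(np.abs(seg))]) if seg.size else 0.0
    thr = threshold.threshold
    post = np.abs(dff.dff[dff.times > end]) > thr
    exceeds = abs(peak) > thr
    run = best_run = 0
    for v in post:
        run = run + 1 if v else 0
        best_run = max(best_run, run)
    outlasts = best_run >= min_outlast_frames
    return ResponseCall(
        roi_id=dff.roi_id,
        peak_dff=peak,
        exceeds_threshold=exceeds,
        outlasts_puff=outlasts,
    )


def summarize_group(
    dffs: list[DffTrace],
    calls: list[ResponseCall],
    ci: float = 0.95,
) -> GroupSummary:
    """Per-timepoint mean trace with t-based CI across ROIs, peaks and AUC."""
    if not dffs:
        raise ValueError("empty group")
    mat = np.vstack([d.dff for d in dffs])
    times = dffs[0].times
    mean_trace = mat.mean(axis=0)
    n = mat.shape[0]
    if n > 1:
        sem_trace = mat.std(axis=0, ddof=1) / np.sqrt(n)
        tval = stats.t.ppf(0.5 + ci / 2.0, df=n - 1)
    else:
        sem_trace = np.zeros_like(mean_trace)
        tval = 0.0
    peaks = np.array([c.peak_dff for c in calls], dtype=float)
    return GroupSummary(
        n_rois=n,
        mean_peak=float(peaks.mean()) if peaks.size else float("nan"),
        sem_peak=float(peaks.std(ddof=1) / np.sqrt(len(peaks))) if peaks.size > 1 else 0.0,
        median_peak=float(np.median(peaks)) if peaks.size else float("nan"),
        mean_trace=mean_trace,
        ci_lower=mean_trace - tval * sem_trace,
        ci_upper=mean_trace + tval * sem_trace,
        auc=float(np.trapezoid(mean_trace, times)),
        responder_fraction=(
            float(np.mean([c.responder for c in calls])) if calls else float("nan")
        ),
    )


@dataclass
class GroupComparison:
    test: str
    statistic: float
    p_value: float
    degenerate: bool = False
    posthoc: list[tuple[int, int, float]] | None = None  # (i, j, adjusted p)


def _dunn_posthoc(groups: list[np.ndarray]) -> list[tuple[int, int, float]]:
    """Dunn's rank-based pairwise z tests with Bonferroni adjustment."""
    all_vals = np.concatenate(groups)
    ranks = stats.rankdata(all_vals)
    n = len(all_vals)
    # tie correction term
    _, counts = np.unique(all_vals, return_counts=True)
    tie = (counts ** 3 - counts).sum() / (12.0 * (n - 1)) if n > 1 else 0.0
    mean_ranks, sizes = [], []
    i0 = 0
    for g in groups:
        mean_ranks.append(ranks[i0:i0 + len(g)].mean())
        sizes.append(len(g))
        i0 += len(g)
    k = len(groups)
    m = k * (k - 1) // 2
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt((n * (n + 1) / 12.0 - tie) * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p = min(1.0, 2.0 * stats.norm.sf(abs(z)) * m)
            out.append((i, j, float(p)))
    return out


def compare_groups(*groups, design: str = "unpaired") -> GroupComparison:
    """Rank-based group comparison appropriate to the design.

    Two unpaired groups: Mann-Whitney U.  Two paired groups: Wilcoxon
    signed-rank.  k>2 groups: Kruskal-Wallis (unpaired) or Friedman (paired),
    both followed by Dunn's post hoc with Bonferroni adjustment.  Degenerate
    all-tied inputs are reported as p = 1 with a flag rather than an error.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrs):
        raise ValueError("groups must be non-empty")
    if design not in ("paired", "unpaired"):
        raise ValueError("design must be 'paired' or 'unpaired'")
    if design == "paired" and len({a.size for a in arrs}) != 1:
        raise ValueError("paired design requires equal group sizes")
    concat = np.concatenate(arrs)
    if np.all(concat == concat[0]):
        test = "degenerate"
        return GroupComparison(test=test, statistic=0.0, p_value=1.0, degenerate=True)
    if len(arrs) == 2:
        a, b = arrs
        if design == "paired":
            diffs = a - b
            if np.all(diffs == 0):
                return GroupComparison("wilcoxon", 0.0, 1.0, degenerate=True)
            res = stats.wilcoxon(a, b)
            return GroupComparison("wilcoxon", float(res.statistic), float(res.pvalue))
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return GroupComparison("mann-whitney", float(res.statistic), float(res.pvalue))
    if design == "paired":
        res = stats.friedmanchisquare(*arrs)
        name = "friedman"
    else:
        res = stats.kruskal(*arrs)
        name = "kruskal-wallis"
    return GroupComparison(
        name, float(res.statistic), float(res.pvalue), posthoc=_dunn_posthoc(arrs)
    )
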