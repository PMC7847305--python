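"""Fiber-photometry synchronization events and LH pulse coincidence.

Arcuate KNDy (kisspeptin/NKB/dynorphin) neurons fire in episodic population
bursts — synchronization events (SEs) — visible as abrupt peaks in bulk GCaMP
fluorescence recorded in scheduled mode (5 s on / 15 s off).  In intact mice
each SE is followed within minutes by a pulse of luteinizing hormone (LH) in
tail-tip blood; in Kiss1-null mice SEs persist but LH stays flat.  This module
turns scheduled samples into ΔF/F, detects SEs (>10% of the recording maximum
and abrupt), detects LH pulses against ELISA assay noise, and matches the two
event series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from . import defaults

__all__ = [
    "PhotometryTrace",
    "SyncEvent",
    "LHSeries",
    "LHPulse",
    "CoincidenceResult",
    "process_photometry",
    "detect_synchronization_events",
    "detect_lh_pulses",
    "coincidence",
]


@dataclass
class PhotometryTrace:
    times: np.ndarray          # s, one sample per on-burst
    dff: np.ndarray            # %
    schedule: tuple[float, float] = defaults.PHOTOMETRY_SCHEDULE_S

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def max_signal(self) -> float:
        return float(self.dff.max())


@dataclass
class SyncEvent:
    time: float                # s, peak time
    peak_dff: float            # %
    prominence: float          # %
    rise_rate: float           # %/s


@dataclass
class LHSeries:
    times: np.ndarray          # min
    conc: np.ndarray           # ng/mL
    assay_floor: float = defaults.LH_ASSAY_FLOOR_NG_ML
    assay_cv: float = defaults.LH_ASSAY_CV

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if np.any(self.conc < 0):
            raise ValueError("concentrations must be non-negative")


@dataclass
class LHPulse:
    peak_time: float           # min
    peak_conc: float           # ng/mL
    rise_from_nadir: float     # ng/mL


@dataclass
class CoincidenceResult:
    n_se: int
    n_pulses: int
    matched_pairs: list[tuple[float, float]] = field(default_factory=list)
    fraction_pulses_preceded_by_se: float = float("nan")
    fraction_se_followed_by_pulse: float = float("nan")
    window: float = defaults.COINCIDENCE_WINDOW_MIN  # min


def process_photometry(
    times: np.ndarray,
    raw_f: np.ndarray,
    schedule: tuple[float, float] = defaults.PHOTOMETRY_SCHEDULE_S,
    baseline_percentile: float = defaults.BASELINE_PERCENTILE,
    baseline_window: float = defaults.BASELINE_WINDOW_S,
) -> PhotometryTrace:
    """Average each on-burst to one sample and compute ΔF/F (%).

    Scheduled acquisition yields a burst of raw samples every
    ``on + off`` seconds; each burst is collapsed to its mean.  The baseline is
    a running low percentile (default 10th over 30 min) of the burst means,
    robust to the slow drift of long recordings, and
    ΔF/F = 100·(F − baseline)/baseline.
    """
    times = np.asarray(times, dtype=float)
    raw_f = np.asarray(raw_f, dtype=float)
    if times.size == 0:
        raise ValueError("empty photometry input")
    on, off = schedule
    period = on + off
    burst = np.floor(times / period).astype(int)
    ids = np.unique(burst)
    t_out = np.empty(ids.size)
    f_out = np.empty(ids.size)
    for k, b in enumerate(ids):
        sel = burst == b
        t_out[k] = times[sel].mean()
        f_out[k] = raw_f[sel].mean()
    base = _rolling_percentile(t_out, f_out, baseline_window, baseline_percentile)
    with np.errstate(divide="ignore", invalid="ignore"):
        dff = 100.0 * (f_out - base) / base
    dff = np.where(np.isfinite(dff), dff, 0.0)
    return PhotometryTrace(times=t_out, dff=dff, schedule=schedule)


def _rolling_percentile(t: np.ndarray, f: np.ndarray, window: float, q: float) -> np.ndarray:
    half = window / 2.0
    out = np.empty_like(f)
    j0 = 0
    j1 = 0
    n = len(t)
    for i in range(n):
        while t[i] - t[j0] > half:
            j0 += 1
        while j1 < n and t[j1] - t[i] <= half:
            j1 += 1
        out[i] = np.percentile(f[j0:j1], q)
    return out


def detect_synchronization_events(
    trace: PhotometryTrace,
    fraction_of_max: float = defaults.SE_FRACTION_OF_MAX,
    abruptness_s: float = defaults.SE_ABRUPTNESS_S,
    refractory_s: float = defaults.SE_REFRACTORY_S,
    min_peak_dff: float = 0.5,
) -> list[SyncEvent]:
    """Abrupt ΔF/F peaks exceeding 10% of the recording maximum.

    A local maximum qualifies when (i) its height strictly exceeds
    ``fraction_of_max x max_signal`` (and an absolute floor guarding against
    noise-only traces), and (ii) it is abrupt: the signal last crossed the
    10%-of-max level no more than ``abruptness_s`` before the peak.  Peaks
    within the refractory interval are merged, keeping the larger.
    """
    dff = trace.dff
    if dff.size < 3 or trace.max_signal <= 0:
        return []
    level = fraction_of_max * trace.max_signal
    height = max(level, min_peak_dff)
    idx, _ = find_peaks(dff, height=height, prominence=height / 2.0)
    idx = [i for i in idx if dff[i] > level]
    events: list[SyncEvent] = []
    for i in idx:
        # last upward crossing of the 10% level before the peak
        j = i
        while j > 0 and dff[j - 1] > level:
            j -= 1
        rise_time = trace.times[i] - trace.times[j] if j < i else 0.0
        if rise_time > abruptness_s:
            continue
        dt = max(rise_time, np.diff(trace.times).min())
        rate = (dff[i] - level) / dt if dt > 0 else float("inf")
        events.append(
            SyncEvent(
                time=float(trace.times[i]),
                peak_dff=float(dff[i]),
                prominence=float(dff[i] - dff[j]),
                rise_rate=float(rate),
            )
        )
    # merge within refractory interval, keep the larger peak
    merged: list[SyncEvent] = []
    for ev in events:
        if merged and ev.time - merged[-1].time < refractory_s:
            if ev.peak_dff > merged[-1].peak_dff:
                merged[-1] = ev
        else:
            merged.append(ev)
    return merged


def detect_lh_pulses(lh: LHSeries) -> list[LHPulse]:
    """LH pulses: local maxima rising above assay noise from the last nadir.

    A local maximum is a pulse when its rise from the preceding nadir exceeds
    max(2 x assay_CV x nadir, 2 x assay sensitivity).  The paper reports LH
    pulsatility without naming an algorithm; this criterion is an explicit
    stand-in scaled to the stated assay characteristics (sensitivity
    0.04 ng/mL, intra-assay CV 9.3%).
    """
    conc = lh.conc
    if conc.size < 3:
        return []
    peaks, _ = find_peaks(conc)
    # a rising final sample is a peak candidate (recording may truncate a pulse)
    if conc[-1] > conc[-2]:
        peaks = np.append(peaks, conc.size - 1)
    pulses: list[LHPulse] = []
    prev_peak = 0
    for p in peaks:
        nadir = float(conc[prev_peak:p].min()) if p > prev_peak else float(conc[p])
        rise = float(conc[p] - nadir)
        crit = max(2.0 * lh.assay_cv * nadir, 2.0 * lh.assay_floor)
        if rise > crit:
            pulses.append(
                LHPulse(
                    peak_time=float(lh.times[p]),
                    peak_conc=float(conc[p]),
                    rise_from_nadir=rise,
                )
            )
            prev_peak = p
    return pulses


def coincidence(
    ses: list[SyncEvent],
    pulses: list[LHPulse],
    window: float = defaults.COINCIDENCE_WINDOW_MIN,
) -> CoincidenceResult:
    """Greedy one-to-one matching of each LH pulse to the nearest preceding SE.

    SE times are in seconds, LH pulse times in minutes (both from the common
    recording clock).  A pulse matches the closest unmatched SE that precedes
    it by at most ``window`` minutes.  Fractions over either denominator are
    NaN when that denominator is empty.
    """
    se_times = sorted(s.time / 60.0 for s in ses)  # -> min
    pulse_times = sorted(p.peak_time for p in pulses)
    used = [False] * len(se_times)
    pairs: list[tuple[float, float]] = []
    for pt in pulse_times:
        best = None
        for k, st in enumerate(se_times):
            if used[k] or st > pt:
                continue
            if pt - st <= window and (best is None or st > se_times[best]):
                best = k
        if best is not None:
            used[best] = True
            pairs.append((se_times[best], pt))
    return CoincidenceResult(
        n_se=len(se_times),
        n_pulses=len(pulse_times),
        matched_pairs=pairs,
        fraction_pulses_preceded_by_se=(
            len(pairs) / len(pulse_times) if pulse_times else float("nan")
        ),
        fraction_se_followed_by_pulse=(
            len(pairs) / len(se_times) if se_times else float("nan")
        ),
        window=window,
    )
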