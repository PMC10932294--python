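"""Threshold screening of single-channel EEG for electrographic seizures.

A candidate electrographic seizure must (1) last at least 5 s, (2) reach
an amplitude at least three times the background signal, and (3) show an
evolution of amplitude and frequency over its course. This module
implements those three criteria as an automated screener:

* background amplitude is the median RMS over non-overlapping 10-s
  windows, which is robust as long as bursts occupy less than half of
  the windows;
* candidate regions are runs of 1-s sliding-window RMS above
  ``amplitude_ratio ×`` background, merged across sub-second gaps;
* "evolution" is operationalized as a significant monotone trend
  (Spearman rank correlation, p < 0.05) in either the windowed RMS or
  the dominant spectral frequency across the event.

The original screening combined a custom detector with manual
proofreading by blinded experimenters; this implementation is therefore
a screener for candidate events, not a validated seizure detector. All
rejected candidates are logged with the criterion they failed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "EEGTrace",
    "DetectedEvent",
    "background_amplitude",
    "detect_events",
    "events_to_frame",
    "read_trace",
    "seizure_incidence",
]

log = logging.getLogger(__name__)


@dataclass
class EEGTrace:
    """Single-channel sampled trace."""

    samples: np.ndarray
    fs: float  # Hz
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.size < 1:
            raise ValueError("trace must contain at least one sample")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.fs


@dataclass
class DetectedEvent:
    start: float  # s
    end: float  # s
    peak_ratio: float  # peak windowed RMS over background RMS
    evolution: bool
    trend_stat: float  # strongest |Spearman rho| among RMS and frequency trends

    @property
    def duration(self) -> float:
        return self.end - self.start


def read_trace(path: str | Path, channel: int = 0) -> EEGTrace:
    """Load a trace from EDF (needs ``mne``) or two-column time/value text."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        try:
            import mne
        except ImportError as exc:  # pragma: no cover
            raise ImportError("reading EDF requires the optional 'mne' dependency") from exc
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data()[channel]
        return EEGTrace(data, float(raw.info["sfreq"]))
    arr = np.loadtxt(path)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("text trace must have two columns: time, value")
    t, x = arr[:, 0], arr[:, 1]
    dt = np.diff(t)
    if dt.size == 0 or np.any(dt <= 0):
        raise ValueError("time column must be strictly increasing")
    return EEGTrace(x, 1.0 / float(np.median(dt)), start_time=float(t[0]))


# ---------------------------------------------------------------------------
# amplitude statistics
# ---------------------------------------------------------------------------


def _window_rms(x: np.ndarray, win: int, hop: int) -> np.ndarray:
    """RMS over length-``win`` windows hopped by ``hop`` samples."""
    sq = np.square(x)
    csum = np.concatenate([[0.0], np.cumsum(sq)])
    starts = np.arange(0, x.size - win + 1, hop)
    return np.sqrt((csum[starts + win] - csum[starts]) / win)


def background_amplitude(trace: EEGTrace, window_s: float = 10.0) -> float:
    """Median of per-window RMS over non-overlapping windows.

    The median makes the estimate insensitive to high-amplitude bursts
    occupying fewer than half of the windows.
    """
    win = int(round(window_s * trace.fs))
    if trace.samples.size < win:
        raise ValueError(
            f"trace ({trace.duration:.1f} s) shorter than one window ({window_s} s)"
        )
    rms = _window_rms(trace.samples, win, win)
    return float(np.median(rms))


def _dominant_frequency(x: np.ndarray, fs: float) -> float:
    freqs, psd = signal.periodogram(x, fs)
    if psd.size <= 1:
        return 0.0
    return float(freqs[1:][np.argmax(psd[1:])])  # skip DC


def _evolution_trend(seg: np.ndarray, fs: float, p_threshold: float = 0.05):
    """Trend of windowed RMS and dominant frequency across an event.

    Returns ``(significant, strongest |rho|)`` using Spearman rank
    correlation against window index; either an amplitude or a frequency
    trend at p < ``p_threshold`` qualifies.
    """
    win = max(int(0.5 * fs), 8)
    hop = max(win // 2, 1)
    starts = np.arange(0, seg.size - win + 1, hop)
    if starts.size < 5:
        return False, 0.0
    rms = np.array([np.sqrt(np.mean(seg[s : s + win] ** 2)) for s in starts])
    freq = np.array([_dominant_frequency(seg[s : s + win], fs) for s in starts])
    best = 0.0
    significant = False
    for series in (rms, freq):
        if np.allclose(series, series[0]):
            continue
        rho, p = stats.spearmanr(np.arange(series.size), series)
        if np.isnan(rho):
            continue
        if abs(rho) > abs(best):
            best = float(rho)
        if p < p_threshold:
            significant = True
    return significant, abs(best)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def detect_events(
    trace: EEGTrace,
    min_duration_s: float = 5.0,
    amplitude_ratio: float = 3.0,
    require_evolution: bool = True,
    background_window_s: float = 10.0,
    rms_window_s: float = 1.0,
    hop_s: float = 0.1,
    merge_gap_s: float = 1.0,
) -> list[DetectedEvent]:
    """Screen a trace for candidate electrographic seizures.

    Candidates are contiguous stretches where the 1-s sliding-window RMS
    reaches ``amplitude_ratio ×`` the background RMS, merged across gaps
    shorter than ``merge_gap_s``; they are kept iff they last at least
    ``min_duration_s`` and (when ``require_evolution``) show a
    significant amplitude or frequency trend. Rejections are logged with
    the failed criterion. Detections are invariant to rescaling the
    whole trace by a positive constant.
    """
    background = background_amplitude(trace, background_window_s)
    if background <= 0:
        log.info("zero background amplitude: trace treated as event-free")
        return []

    win = max(int(round(rms_window_s * trace.fs)), 1)
    hop = max(int(round(hop_s * trace.fs)), 1)
    if trace.samples.size < win:
        return []
    rms = _window_rms(trace.samples, win, hop)
    t_start = trace.start_time + np.arange(rms.size) * hop / trace.fs  # window starts

    above = rms >= amplitude_ratio * background
    if not above.any():
        return []

    # contiguous runs of above-threshold windows
    edges = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
    runs = [(edges[i], edges[i + 1] - 1) for i in range(0, edges.size, 2)]

    # merge runs separated by less than merge_gap_s
    merged = [list(runs[0])]
    for a, b in runs[1:]:
        prev_end_t = t_start[merged[-1][1]] + rms_window_s
        if t_start[a] - prev_end_t < merge_gap_s:
            merged[-1][1] = b
        else:
            merged.append([a, b])

    events: list[DetectedEvent] = []
    for a, b in merged:
        start = float(t_start[a])
        end = float(t_start[b] + rms_window_s)
        peak = float(rms[a : b + 1].max() / background)
        if end - start < min_duration_s:
            log.info("candidate %.1f–%.1f s rejected: duration < %.1f s", start, end, min_duration_s)
            continue
        i0 = int(round((start - trace.start_time) * trace.fs))
        i1 = int(round((end - trace.start_time) * trace.fs))
        significant, rho = _evolution_trend(trace.samples[i0:i1], trace.fs)
        if require_evolution and not significant:
            log.info("candidate %.1f–%.1f s rejected: no amplitude/frequency evolution", start, end)
            continue
        events.append(DetectedEvent(start, end, peak, significant, rho))
    return events


def events_to_frame(events: list[DetectedEvent]) -> pd.DataFrame:
    """Event table (start, end, duration, peak ratio, evolution statistic)."""
    return pd.DataFrame(
        [
            {
                "start_s": e.start,
                "end_s": e.end,
                "duration_s": e.duration,
                "peak_ratio": e.peak_ratio,
                "evolution": e.evolution,
                "trend_stat": e.trend_stat,
            }
            for e in events
        ],
        columns=["start_s", "end_s", "duration_s", "peak_ratio", "evolution", "trend_stat"],
    )


def seizure_incidence(events_per_animal: dict[str, list[DetectedEvent]]) -> float:
    """Percent of animals with at least one accepted event (rounded integer).

    E.g. 11 epileptic animals in a cohort of 53 gives 21.
    """
    if not events_per_animal:
        raise ValueError("empty cohort")
    n_epileptic = sum(1 for evs in events_per_animal.values() if evs)
    return round(100.0 * n_epileptic / len(events_per_animal))
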