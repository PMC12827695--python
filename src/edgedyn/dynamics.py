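"""Event dynamics on the RSS trace: troughs, peaks, amplitude and TTD.

A trough is a frame strictly below both immediate neighbors (endpoints can
never qualify; plateaus produce no trough under the strict rule).  Between
each pair of consecutive troughs exactly one peak is recorded: the argmax of
the trace on the open interval, ties resolved to the earliest frame.  The
trough-to-trough duration (TTD) is the frame distance between adjacent
troughs; per-subject summaries are arithmetic means, reported in frames by
default or in seconds via the TR.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np

from .ets import RssTrace

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class EventProfile:
    """Trough/peak structure of one subject's RSS trace."""

    trough_frames: np.ndarray
    peak_frames: np.ndarray
    peak_amplitudes: np.ndarray
    ttd_frames: np.ndarray
    tr_seconds: float = 1.0

    @property
    def n_troughs(self) -> int:
        return len(self.trough_frames)

    @property
    def n_peaks(self) -> int:
        return len(self.peak_frames)

    @property
    def mean_peak_amplitude(self) -> float:
        if self.n_peaks == 0:
            return math.nan
        return float(np.mean(self.peak_amplitudes))

    @property
    def mean_ttd(self) -> float:
        if len(self.ttd_frames) == 0:
            return math.nan
        return float(np.mean(self.ttd_frames))


def detect_troughs(rss: RssTrace) -> np.ndarray:
    """Frames t with rss(t) < rss(t-1) and rss(t) < rss(t+1), strictly."""
    x = np.asarray(rss.values, dtype=float)
    if x.size < 3:
        raise ValueError("trough detection requires at least 3 frames")
    interior = (x[1:-1] < x[:-2]) & (x[1:-1] < x[2:])
    return np.flatnonzero(interior) + 1


def detect_peaks(rss: RssTrace, troughs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Peak frame and amplitude for each consecutive trough pair.

    The peak is the argmax of the trace on the open interval between the two
    troughs (earliest frame on ties).  With fewer than 2 troughs the subject
    has no measurable peaks: a warning is logged and empty arrays returned.
    """
    x = np.asarray(rss.values, dtype=float)
    troughs = np.asarray(troughs, dtype=int)
    if troughs.size < 2:
        logger.warning("fewer than 2 troughs; no peaks measurable")
        return np.empty(0, dtype=int), np.empty(0, dtype=float)
    frames = np.empty(troughs.size - 1, dtype=int)
    amps = np.empty(troughs.size - 1, dtype=float)
    for k in range(troughs.size - 1):
        a, b = troughs[k], troughs[k + 1]
        segment = x[a + 1 : b]
        # consecutive strict minima are >= 2 frames apart, so the open
        # interval is never empty
        offset = int(np.argmax(segment))
        frames[k] = a + 1 + offset
        amps[k] = segment[offset]
    return frames, amps


def event_profile(rss: RssTrace) -> EventProfile:
    """Full trough/peak/TTD decomposition of an RSS trace."""
    troughs = detect_troughs(rss)
    peaks, amps = detect_peaks(rss, troughs)
    ttd = np.diff(troughs) if troughs.size >= 2 else np.empty(0, dtype=int)
    return EventProfile(
        trough_frames=troughs,
        peak_frames=peaks,
        peak_amplitudes=amps,
        ttd_frames=ttd,
        tr_seconds=rss.tr_seconds,
    )


def summarize_dynamics(
    profile: EventProfile, tr_seconds: float | None = None, units: str = "frames"
) -> tuple[float, float]:
    """(mean peak amplitude, mean TTD); TTD in frames or seconds.

    An empty profile yields NaN for the missing quantity so the subject can
    be flagged rather than silently dropped.
    """
    if units not in ("frames", "seconds"):
        raise ValueError(f"units must be 'frames' or 'seconds', got {units!r}")
    tr = profile.tr_seconds if tr_seconds is None else tr_seconds
    mean_amp = profile.mean_peak_amplitude
    mean_ttd = profile.mean_ttd
    if math.isnan(mean_amp) or math.isnan(mean_ttd):
        logger.warning("empty event profile; dynamics summary contains NaN")
    if units == "seconds":
        mean_ttd = mean_ttd * tr
    return mean_amp, mean_ttd
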