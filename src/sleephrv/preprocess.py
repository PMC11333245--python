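"""ECG preprocessing: block normalization, non-useful-segment detection
and Pan-Tompkins R-peak detection.

Sleep ECG amplitude drifts with body position and electrode contact, so
the signal is first variance-normalized in non-overlapping 10 s blocks.
Blocks are then screened: after removing the trend, a block is kept as
ECG only when the residual variance lies inside a fixed acceptance band
— too low marks flat-line / lost-contact stretches, too high marks
broadband motion artifact. The first and last 20 minutes of every
recording are always discarded (lights-on transitions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .series import BeatSeries

__all__ = [
    "SegmentMask",
    "normalize_segments",
    "detect_nonuseful",
    "detect_rpeaks",
]

BLOCK_S = 10.0
EDGE_MIN = 20.0  # minutes forced non-useful at each end
VAR_LOW, VAR_HIGH = 0.04, 0.2  # acceptance band for residual variance
TREND_CUTOFF_HZ = 20.0  # morphology/trend vs broadband-noise split


@dataclass
class SegmentMask:
    """Per-10 s-block useful / non-useful labels, half-open in seconds."""

    starts: np.ndarray
    ends: np.ndarray
    useful: np.ndarray  # bool per block

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype=float)
        self.ends = np.asarray(self.ends, dtype=float)
        self.useful = np.asarray(self.useful, dtype=bool)
        if not np.allclose(self.starts[1:], self.ends[:-1]):
            raise ValueError("mask blocks must tile the recording without gaps")

    @property
    def n_blocks(self) -> int:
        return int(self.useful.size)

    def useful_at(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.clip(np.searchsorted(self.ends, t, side="right"), 0, self.n_blocks - 1)
        return self.useful[idx]

    def _intervals(self, value: bool) -> list[tuple[float, float]]:
        out: list[list[float]] = []
        for s, e, u in zip(self.starts, self.ends, self.useful):
            if u != value:
                continue
            if out and out[-1][1] == s:
                out[-1][1] = e
            else:
                out.append([s, e])
        return [(s, e) for s, e in out]

    def useful_intervals(self) -> list[tuple[float, float]]:
        return self._intervals(True)

    def nonuseful_intervals(self) -> list[tuple[float, float]]:
        return self._intervals(False)


def _blocks(n: int, fs: float) -> list[tuple[int, int]]:
    size = int(round(BLOCK_S * fs))
    edges = list(range(0, n, size))
    return [(s, min(s + size, n)) for s in edges]


def normalize_segments(ecg: np.ndarray, fs: float) -> np.ndarray:
    """Divide each non-overlapping 10 s block by its standard deviation.

    Zero-variance blocks are left as zeros (they will fail the variance
    screen downstream). The sampling rate must be known.
    """
    if fs is None or fs <= 0:
        raise ValueError("sampling rate fs must be a positive number")
    ecg = np.asarray(ecg, dtype=float)
    out = np.empty_like(ecg)
    for lo, hi in _blocks(ecg.size, fs):
        block = ecg[lo:hi]
        sd = block.std()
        out[lo:hi] = 0.0 if sd == 0 else block / sd
    return out


def detect_nonuseful(
    normalized: np.ndarray,
    fs: float,
    edge_min: float = EDGE_MIN,
    var_low: float = VAR_LOW,
    var_high: float = VAR_HIGH,
) -> SegmentMask:
    """Screen variance-normalized 10 s blocks for usable ECG.

    Per block, the trend is removed — a linear fit for baseline wander
    plus the smooth morphology component (zero-phase low-pass below
    ``TREND_CUTOFF_HZ``) — and the variance ``v`` of the residual is
    compared against the acceptance band: the block is useful iff
    ``var_low <= v <= var_high`` (bounds inclusive). Flat blocks fall
    below the band, broadband motion artifact above it. The first and
    last ``edge_min`` minutes are forced non-useful. Idempotent: the
    mask is a pure function of its inputs.
    """
    if fs is None or fs <= 0:
        raise ValueError("sampling rate fs must be a positive number")
    normalized = np.asarray(normalized, dtype=float)
    if normalized.size < 2 * edge_min * 60 * fs:
        warnings.warn(
            f"recording shorter than 2 x {edge_min:g} min: "
            "every block is forced non-useful", stacklevel=2,
        )
    sos = sps.butter(4, TREND_CUTOFF_HZ, btype="low", fs=fs, output="sos")
    bounds = _blocks(normalized.size, fs)
    starts = np.array([lo / fs for lo, _ in bounds])
    ends = np.array([hi / fs for _, hi in bounds])
    useful = np.zeros(len(bounds), dtype=bool)
    for k, (lo, hi) in enumerate(bounds):
        block = normalized[lo:hi]
        if block.std() == 0:
            continue
        detrended = sps.detrend(block, type="linear")
        if block.size > 24:  # sosfiltfilt needs enough samples for padding
            resid = detrended - sps.sosfiltfilt(sos, detrended)
        else:
            resid = detrended
        v = resid.var()
        useful[k] = var_low <= v <= var_high
    total = ends[-1]
    useful &= (starts >= edge_min * 60.0) & (ends <= total - edge_min * 60.0)
    return SegmentMask(starts=starts, ends=ends, useful=useful)


def detect_rpeaks(ecg: np.ndarray, fs: float, refractory: float = 0.25) -> BeatSeries:
    """Pan-Tompkins R-peak detection.

    Canonical stages with fixed published parameters: 5-15 Hz band-pass,
    derivative, squaring, 150 ms moving-window integration, adaptive
    signal/noise thresholds with search-back, and a 250 ms refractory
    period. Peak times are refined to the local extremum of the raw
    signal. Returns an empty series (with a warning) when no credible
    peaks are found, e.g. on a flat signal.
    """
    if not 100 <= fs <= 512:
        raise ValueError("sampling rate must lie in [100, 512] Hz")
    ecg = np.asarray(ecg, dtype=float)
    if ecg.size < fs:
        warnings.warn("signal shorter than 1 s: no peaks detected", stacklevel=2)
        return BeatSeries(r_times=np.empty(0))
    if np.ptp(ecg) == 0:
        warnings.warn("flat signal: no R-peaks found", stacklevel=2)
        return BeatSeries(r_times=np.empty(0))

    sos = sps.butter(3, [5.0, 15.0], btype="band", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, ecg)
    deriv = np.gradient(bp)
    squared = deriv**2
    win = max(int(round(0.150 * fs)), 1)
    integ = sps.convolve(squared, np.ones(win) / win, mode="same")

    dist = max(int(round(refractory * fs)), 1)
    cand, _ = sps.find_peaks(integ, distance=dist)
    if cand.size == 0:
        warnings.warn("no candidate peaks in integrated signal", stacklevel=2)
        return BeatSeries(r_times=np.empty(0))

    # Adaptive thresholding (Pan-Tompkins running estimates).
    init = integ[: int(2 * fs)]
    spki = 0.25 * float(init.max())
    npki = 0.5 * float(init.mean())
    accepted: list[int] = []
    rr_hist: list[float] = []

    def threshold() -> float:
        return npki + 0.25 * (spki - npki)

    last = None
    for c in cand:
        level = integ[c]
        if level > threshold():
            if last is not None:
                rr_hist.append((c - last) / fs)
                if len(rr_hist) > 8:
                    rr_hist.pop(0)
            accepted.append(c)
            last = c
            # clamp the update so a motion-artifact burst cannot inflate
            # the running signal estimate and mask the following beats
            spki = 0.125 * min(level, 4.0 * spki) + 0.875 * spki
        else:
            # search-back: if a beat is overdue, accept the best
            # candidate above half threshold
            overdue = (
                last is not None
                and rr_hist
                and (c - last) / fs > 1.66 * float(np.mean(rr_hist))
            )
            if overdue and level > 0.5 * threshold():
                accepted.append(c)
                last = c
                spki = 0.25 * min(level, 4.0 * spki) + 0.75 * spki
            else:
                npki = 0.125 * min(level, 4.0 * npki) + 0.875 * npki
                if overdue:
                    # threshold stranded above the signal (e.g. after a
                    # motion burst): decay geometrically until beats return
                    spki = max(0.5 * spki, npki)

    if not accepted:
        warnings.warn("no peaks passed the adaptive threshold", stacklevel=2)
        return BeatSeries(r_times=np.empty(0))

    # Refine to the raw-signal extremum near each integrated peak.
    w = max(int(round(0.10 * fs)), 1)
    base = np.median(ecg)
    refined = []
    for c in accepted:
        lo, hi = max(c - w, 0), min(c + w + 1, ecg.size)
        refined.append(lo + int(np.argmax(np.abs(ecg[lo:hi] - base))))
    refined = np.unique(refined)

    # Enforce the refractory period after refinement, keeping the taller peak.
    keep: list[int] = []
    for idx in refined:
        if keep and (idx - keep[-1]) < dist:
            if abs(ecg[idx] - base) > abs(ecg[keep[-1]] - base):
                keep[-1] = idx
        else:
            keep.append(idx)
    return BeatSeries(r_times=np.asarray(keep, dtype=float) / fs)
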