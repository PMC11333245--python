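"""Analysis-ready RR and MM series.

From a series of R-peak occurrence times this module excises wake epochs
and non-useful ECG segments, merges the remaining runs onto a continuous
time base, interpolates the RR tachogram on a uniform 4 Hz grid, extracts
the MM fluctuations (series built from the local maxima of the RR
tachogram, suppressing the respiratory high-frequency rhythm) and builds
shuffle surrogates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "BeatSeries",
    "RRSeries",
    "MMSeries",
    "merged_beat_rr",
    "build_rr",
    "local_maxima",
    "extract_mm",
    "shuffle_surrogate",
]

#: uniform resampling rate of RR / MM series, Hz
RESAMPLE_HZ = 4.0

#: minimum retained sleep required for scaling analysis, hours
MIN_HOURS = 5.0


@dataclass
class BeatSeries:
    """R-peak occurrence times in seconds, strictly increasing."""

    r_times: np.ndarray
    source: str = "original"  # original | surrogate

    def __post_init__(self):
        self.r_times = np.asarray(self.r_times, dtype=float)
        if self.r_times.size > 1 and np.any(np.diff(self.r_times) <= 0):
            raise ValueError("R-peak times must be strictly increasing")

    @property
    def n_beats(self) -> int:
        return int(self.r_times.size)

    def rr(self) -> tuple[np.ndarray, np.ndarray]:
        """Beat-level RR intervals and the times of their closing beats."""
        rr = np.diff(self.r_times)
        return self.r_times[1:], rr


@dataclass
class RRSeries:
    """Uniformly resampled (4 Hz) RR tachogram on the merged time base."""

    t: np.ndarray
    rr: np.ndarray
    provenance: str = "original"  # original | surrogate
    fs: float = RESAMPLE_HZ

    @property
    def total_duration_h(self) -> float:
        return self.t.size / self.fs / 3600.0


@dataclass
class MMSeries:
    """MM fluctuations resampled at 4 Hz.

    ``inter_max_interval`` mode carries the time gaps between successive
    local maxima of the RR tachogram (magnitude of a respiratory period);
    ``envelope`` mode carries the RR values at those maxima.
    """

    t: np.ndarray
    mm: np.ndarray
    mode: str = "inter_max_interval"
    fs: float = RESAMPLE_HZ


def _exclusion_intervals(mask=None, hypnogram=None) -> list[tuple[float, float]]:
    """Union of non-useful mask intervals and wake epochs, merged."""
    iv: list[tuple[float, float]] = []
    if mask is not None:
        iv.extend(mask.nonuseful_intervals())
    if hypnogram is not None:
        iv.extend(hypnogram.wake_intervals())
    if not iv:
        return []
    iv.sort()
    merged = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def merged_beat_rr(
    beats: BeatSeries, mask=None, hypnogram=None
) -> tuple[np.ndarray, np.ndarray]:
    """Beat-level RR after excision, on a merged continuous time base.

    An RR interval is retained only when the whole span between its two
    beats lies outside every exclusion interval; beats whose RR spans an
    exclusion boundary are dropped with the segment. Retained intervals
    are concatenated: the returned times are cumulative sums of the kept
    RR values, so excised gaps vanish from the time base.

    Returns
    -------
    (t_merged, rr) : times of the closing beats on the merged base, and
        the RR values (seconds).
    """
    if beats.n_beats < 2:
        return np.empty(0), np.empty(0)
    ends, rr = beats.rr()
    starts = beats.r_times[:-1]
    keep = np.ones(rr.size, dtype=bool)
    for s, e in _exclusion_intervals(mask, hypnogram):
        keep &= (ends <= s) | (starts >= e)
    rr_kept = rr[keep]
    if rr_kept.size == 0:
        return np.empty(0), rr_kept
    # anchor the merged base at zero: the first kept RR sample sits at t=0
    t_merged = np.cumsum(rr_kept) - rr_kept[0]
    return t_merged, rr_kept


def build_rr(
    beats: BeatSeries,
    mask=None,
    hypnogram=None,
    fs: float = RESAMPLE_HZ,
    min_hours: float = MIN_HOURS,
) -> RRSeries:
    """Excise, merge and cubic-spline interpolate RR onto a uniform grid.

    Raises ``ValueError`` when the retained duration falls short of
    ``min_hours`` (default 5 h, the minimum needed to cover at least
    three NREM-REM sleep cycles).
    """
    t_merged, rr_kept = merged_beat_rr(beats, mask, hypnogram)
    retained_h = rr_kept.sum() / 3600.0
    if retained_h < min_hours:
        raise ValueError(
            f"retained duration {retained_h:.2f} h is below the "
            f"{min_hours:g} h minimum required for scaling analysis"
        )
    spline = CubicSpline(t_merged, rr_kept)
    t = np.arange(0.0, rr_kept.sum(), 1.0 / fs)
    return RRSeries(t=t, rr=spline(t), provenance=beats.source, fs=fs)


def local_maxima(values: np.ndarray) -> np.ndarray:
    """Indices of interior local maxima.

    Strict increase on the left, weak decrease on the right
    (``v[i-1] < v[i] >= v[i+1]``), which collapses plateaus to their
    first index — a deterministic tie-break.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        return np.empty(0, dtype=int)
    left = v[1:-1] > v[:-2]
    right = v[1:-1] >= v[2:]
    return np.nonzero(left & right)[0] + 1


def extract_mm(
    rr_times: np.ndarray,
    rr_values: np.ndarray,
    mode: str = "inter_max_interval",
    fs: float = RESAMPLE_HZ,
) -> MMSeries:
    """MM fluctuations from a beat-level RR sequence.

    Parameters
    ----------
    rr_times, rr_values : beat-level RR sequence (times of the closing
        beats, RR in seconds), e.g. from :func:`merged_beat_rr`.
    mode : ``"inter_max_interval"`` (default; gaps in seconds between
        successive RR local maxima, sampled at the later maximum) or
        ``"envelope"`` (RR value at each maximum).

    The (maximum-time, value) pairs are cubic-spline resampled onto the
    uniform ``fs`` grid spanning them.
    """
    if mode not in ("inter_max_interval", "envelope"):
        raise ValueError(f"unknown MM mode: {mode!r}")
    rr_times = np.asarray(rr_times, dtype=float)
    rr_values = np.asarray(rr_values, dtype=float)
    if rr_values.size < 3:
        raise ValueError("need at least 3 beat-level RR values")
    idx = local_maxima(rr_values)
    if idx.size < 2:
        raise ValueError("fewer than 2 RR local maxima: cannot build MM series")
    tm = rr_times[idx]
    if mode == "inter_max_interval":
        pts_t = tm[1:]
        pts_v = np.diff(tm)
    else:
        pts_t = tm
        pts_v = rr_values[idx]
    if pts_t.size < 2:
        raise ValueError("fewer than 2 MM points: cannot resample")
    spline = CubicSpline(pts_t, pts_v)
    t = np.arange(pts_t[0], pts_t[-1], 1.0 / fs)
    return MMSeries(t=t, mm=spline(t), mode=mode, fs=fs)


def beat_mm_values(
    rr_times: np.ndarray, rr_values: np.ndarray, mode: str = "inter_max_interval"
) -> tuple[np.ndarray, np.ndarray]:
    """Beat-level MM points (before resampling): (times, values).

    Used for the time-domain meanMM/sdMM indices, which the quarter-wise
    analysis computes on the raw maxima rather than the 4 Hz series.
    """
    rr_times = np.asarray(rr_times, dtype=float)
    rr_values = np.asarray(rr_values, dtype=float)
    idx = local_maxima(rr_values)
    if idx.size < 2:
        raise ValueError("fewer than 2 RR local maxima")
    tm = rr_times[idx]
    if mode == "inter_max_interval":
        return tm[1:], np.diff(tm)
    return tm, rr_values[idx]


def shuffle_surrogate(beats: BeatSeries, seed) -> BeatSeries:
    """Shuffle surrogate of a beat series.

    The beat-level RR values are uniformly permuted (seeded) and the new
    beat times are cumulative sums of the permuted values, anchored at
    the original first beat. The multiset of RR values — hence mean and
    variance — is preserved exactly, while every temporal correlation is
    destroyed.
    """
    rng = np.random.default_rng(seed)
    rr = np.diff(beats.r_times)
    perm = rng.permutation(rr.size)
    new_times = beats.r_times[0] + np.concatenate([[0.0], np.cumsum(rr[perm])])
    return BeatSeries(r_times=new_times, source="surrogate")
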