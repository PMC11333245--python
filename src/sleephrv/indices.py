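"""Quarter-wise time-domain and spectral HRV indices.

Retained (post-excision, merged) sleep time is partitioned into four
equal contiguous quarters Q1-Q4 and, per quarter, the classical indices
are computed:

* meanRR / sdRR — mean and SD of the beat-level RR intervals (s);
* rmsRR — RMS of successive RR differences (RMSSD, s);
* meanMM / sdMM — mean and SD of the beat-level MM fluctuations (s);
* LFnu / HFnu / LF/HF — Welch-normalized band powers, LF 0.04-0.15 Hz
  and HF 0.15-0.5 Hz, normalized so LFnu + HFnu = 1 (HF tracks vagal /
  respiratory drive, the LF/HF ratio sympathovagal balance);
* alpha — the monofractal DFA exponent H(2) of the 4 Hz RR series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import mfdfa as _mfdfa  # noqa: F401  (submodule import, resolved before package attribute shadowing)
from . import series as _series

__all__ = [
    "WelchConfig",
    "QuarterIndices",
    "partition_quarters",
    "time_domain",
    "spectral_indices",
    "dfa_alpha",
    "analyze_quarters",
]

QUARTERS = ("Q1", "Q2", "Q3", "Q4")


@dataclass(frozen=True)
class WelchConfig:
    """Welch PSD settings: 8 Hamming segments with 50% overlap at 4 Hz."""

    n_segments: int = 8
    overlap: float = 0.5
    window: str = "hamming"
    sample_rate: float = 4.0
    lf_band: tuple[float, float] = (0.04, 0.15)  # [low, high)
    hf_band: tuple[float, float] = (0.15, 0.5)  # [low, high]

    def __post_init__(self):
        nyq = self.sample_rate / 2.0
        if not (0 <= self.lf_band[0] < self.lf_band[1] <= self.hf_band[0] < self.hf_band[1] <= nyq):
            raise ValueError("LF and HF bands must be disjoint and below Nyquist")


@dataclass
class QuarterIndices:
    """All nine indices for one sleep quarter; NaN marks "missing"."""

    quarter: str
    mean_rr: float
    sd_rr: float
    rms_rr: float
    mean_mm: float
    sd_mm: float
    hf_nu: float
    lf_nu: float
    lf_hf: float
    alpha: float

    def as_dict(self) -> dict:
        return {
            "quarter": self.quarter,
            "meanRR": self.mean_rr,
            "sdRR": self.sd_rr,
            "rmsRR": self.rms_rr,
            "meanMM": self.mean_mm,
            "sdMM": self.sd_mm,
            "HFnu": self.hf_nu,
            "LFnu": self.lf_nu,
            "LFHF": self.lf_hf,
            "alpha": self.alpha,
        }


def partition_quarters(n: int) -> list[slice]:
    """Four contiguous, equal-length, half-open quarters of ``n`` samples.

    The remainder (at most 3 samples) is assigned to Q4, so the slices
    are disjoint and their union is the full series.
    """
    if n < 4:
        raise ValueError("cannot partition fewer than 4 samples into quarters")
    base = n // 4
    edges = [0, base, 2 * base, 3 * base, n]
    return [slice(edges[i], edges[i + 1]) for i in range(4)]


def quarter_time_edges(t0: float, t1: float) -> np.ndarray:
    """Quarter boundaries of the retained time span [t0, t1)."""
    return t0 + (t1 - t0) * np.array([0.0, 0.25, 0.5, 0.75, 1.0])


def time_domain(
    quarter_rr: np.ndarray, quarter_mm: np.ndarray | None = None, min_beats: int = 30
) -> dict:
    """Beat-level time-domain indices for one quarter.

    meanRR / sdRR are the mean / SD of the RR values, rmsRR the RMS of
    successive RR differences (RMSSD), meanMM / sdMM the mean / SD of
    the beat-level MM values. With fewer than ``min_beats`` RR values
    the RR indices are NaN ("missing"); likewise for MM with fewer than
    2 values.
    """
    rr = np.asarray(quarter_rr, dtype=float)
    out = {"meanRR": math.nan, "sdRR": math.nan, "rmsRR": math.nan,
           "meanMM": math.nan, "sdMM": math.nan}
    if rr.size >= min_beats:
        out["meanRR"] = float(rr.mean())
        out["sdRR"] = float(rr.std(ddof=1))
        out["rmsRR"] = float(np.sqrt(np.mean(np.diff(rr) ** 2)))
    if quarter_mm is not None:
        mm = np.asarray(quarter_mm, dtype=float)
        if mm.size >= 2:
            out["meanMM"] = float(mm.mean())
            out["sdMM"] = float(mm.std(ddof=1))
    return out


def spectral_indices(rr_4hz: np.ndarray, config: WelchConfig | None = None) -> dict:
    """Normalized LF / HF powers and their ratio from a 4 Hz RR quarter.

    The mean-removed series is split into ``n_segments`` Welch segments
    with 50% overlap and Hamming windows; the averaged periodogram is
    integrated over the LF and HF bands and normalized so that
    LFnu + HFnu = 1 exactly. Indices are NaN when the combined band
    power vanishes.
    """
    if config is None:
        config = WelchConfig()
    x = np.asarray(rr_4hz, dtype=float)
    nperseg = int(2 * x.size / (config.n_segments + 1))
    if nperseg < 8:
        raise ValueError(
            f"quarter too short for {config.n_segments} Welch segments"
        )
    f, psd = sps.welch(
        x,
        fs=config.sample_rate,
        window=config.window,
        nperseg=nperseg,
        noverlap=int(nperseg * config.overlap),
        detrend="constant",
    )
    df = f[1] - f[0]
    lf_mask = (f >= config.lf_band[0]) & (f < config.lf_band[1])
    hf_mask = (f >= config.hf_band[0]) & (f <= config.hf_band[1])
    lf = float(psd[lf_mask].sum() * df)
    hf = float(psd[hf_mask].sum() * df)
    total = lf + hf
    if total == 0:
        return {"LFnu": math.nan, "HFnu": math.nan, "LFHF": math.nan}
    return {"LFnu": lf / total, "HFnu": hf / total,
            "LFHF": lf / hf if hf > 0 else math.inf}


def dfa_alpha(rr_4hz: np.ndarray, detrend_order: int = 1, fs: float = 4.0) -> float:
    """Monofractal DFA exponent of a 4 Hz RR quarter.

    Identical to H(2) of the multifractal module on the same samples:
    windows of 16 s up to min(2048 s, quarter length / 4), linear
    detrending.
    """
    x = np.asarray(rr_4hz, dtype=float)
    scales = _mfdfa.scales_seconds(x.size, fs=fs)
    return _mfdfa.dfa_alpha(x, scales=scales, detrend_order=detrend_order)


def analyze_quarters(
    beats: _series.BeatSeries,
    mask=None,
    hypnogram=None,
    mm_mode: str = "inter_max_interval",
    welch: WelchConfig | None = None,
    min_hours: float = _series.MIN_HOURS,
) -> pd.DataFrame:
    """End-to-end quarter-wise index table for one recording.

    Excises wake / non-useful intervals, merges, builds the 4 Hz RR
    series, extracts beat-level MM points, partitions the retained time
    into quarters and returns one row per quarter with the nine indices.
    """
    t_merged, rr_kept = _series.merged_beat_rr(beats, mask, hypnogram)
    rr_series = _series.build_rr(beats, mask, hypnogram, min_hours=min_hours)
    mm_t, mm_v = _series.beat_mm_values(t_merged, rr_kept, mode=mm_mode)
    slices = partition_quarters(rr_series.t.size)
    rows = []
    for name, sl in zip(QUARTERS, slices):
        t_lo = rr_series.t[sl.start]
        t_hi = rr_series.t[sl.stop - 1] + 1.0 / rr_series.fs
        in_q = (t_merged >= t_lo) & (t_merged < t_hi)
        mm_in_q = (mm_t >= t_lo) & (mm_t < t_hi)
        td = time_domain(rr_kept[in_q], mm_v[mm_in_q])
        spec = spectral_indices(rr_series.rr[sl], welch)
        alpha = dfa_alpha(rr_series.rr[sl])
        rows.append(
            QuarterIndices(
                quarter=name,
                mean_rr=td["meanRR"], sd_rr=td["sdRR"], rms_rr=td["rmsRR"],
                mean_mm=td["meanMM"], sd_mm=td["sdMM"],
                hf_nu=spec["HFnu"], lf_nu=spec["LFnu"], lf_hf=spec["LFHF"],
                alpha=alpha,
            ).as_dict()
        )
    return pd.DataFrame(rows)
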