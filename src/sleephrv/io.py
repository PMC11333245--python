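"""Plain-text readers and writers for the pipeline's data products.

Formats are deliberately simple: two-column CSV for beat and resampled
series (with a comment header carrying sampling rate / mode /
provenance), BED-like half-open interval text for segment masks, one
stage name per line for hypnograms. ECG can be read from a single-column
CSV with a ``# fs=...`` header or, when ``mne`` is available, from an
EDF channel.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import SegmentMask
from .series import BeatSeries, MMSeries, RRSeries
from .synthetic import EPOCH_S, STAGE_CODES, STAGE_NAMES, Hypnogram

__all__ = [
    "write_beats", "read_beats",
    "write_series", "read_series",
    "write_mask", "read_mask",
    "write_hypnogram", "read_hypnogram",
    "write_ecg_csv", "read_ecg_csv", "read_ecg_edf",
]


def write_beats(path, beats: BeatSeries) -> None:
    """Beat series as CSV (time_s, rr_s); the first beat has no RR."""
    t = beats.r_times
    rr = np.concatenate([[np.nan], np.diff(t)])
    with open(path, "w") as fh:
        fh.write(f"# source={beats.source}\n")
        fh.write("time_s,rr_s\n")
        for ti, ri in zip(t, rr):
            fh.write(f"{ti:.6f},{'' if np.isnan(ri) else f'{ri:.6f}'}\n")


def read_beats(path) -> BeatSeries:
    source = "original"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first[1:].split(","):
                key, _, val = token.strip().partition("=")
                if key == "source":
                    source = val
    df = pd.read_csv(path, comment="#")
    return BeatSeries(r_times=df["time_s"].to_numpy(), source=source)


def write_series(path, series: RRSeries | MMSeries) -> None:
    """Uniform 4 Hz series as CSV (t_s, value_s) with a header comment."""
    if isinstance(series, RRSeries):
        meta = f"kind=rr, fs_hz={series.fs:g}, provenance={series.provenance}"
        values = series.rr
    else:
        meta = f"kind=mm, fs_hz={series.fs:g}, mode={series.mode}"
        values = series.mm
    with open(path, "w") as fh:
        fh.write(f"# {meta}\n")
        fh.write("t_s,value_s\n")
        for ti, vi in zip(series.t, values):
            fh.write(f"{ti:.4f},{vi:.6f}\n")


def read_series(path) -> RRSeries | MMSeries:
    meta: dict[str, str] = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first[1:].split(","):
                key, _, val = token.strip().partition("=")
                meta[key] = val
    df = pd.read_csv(path, comment="#")
    t = df["t_s"].to_numpy()
    v = df["value_s"].to_numpy()
    fs = float(meta.get("fs_hz", 4.0))
    if meta.get("kind") == "mm":
        return MMSeries(t=t, mm=v, mode=meta.get("mode", "inter_max_interval"), fs=fs)
    return RRSeries(t=t, rr=v, provenance=meta.get("provenance", "original"), fs=fs)


def write_mask(path, mask: SegmentMask) -> None:
    """Half-open interval text: start_s <TAB> end_s <TAB> label."""
    with open(path, "w") as fh:
        for s, e in mask.useful_intervals():
            fh.write(f"{s:.1f}\t{e:.1f}\tuseful\n")
        for s, e in mask.nonuseful_intervals():
            fh.write(f"{s:.1f}\t{e:.1f}\tnon_useful\n")


def read_mask(path, block_s: float = 10.0) -> SegmentMask:
    intervals = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            s, e, label = line.split("\t")
            intervals.append((float(s), float(e), label.strip() == "useful"))
    intervals.sort()
    end = max(e for _, e, _ in intervals)
    starts = np.arange(0.0, end, block_s)
    ends = np.minimum(starts + block_s, end)
    useful = np.zeros(starts.size, dtype=bool)
    for s, e, u in intervals:
        if u:
            sel = (starts >= s) & (ends <= e)
            useful[sel] = True
    return SegmentMask(starts=starts, ends=ends, useful=useful)


def write_hypnogram(path, hyp: Hypnogram) -> None:
    """One stage name per 30 s epoch per line."""
    with open(path, "w") as fh:
        for st in hyp.stages:
            fh.write(STAGE_NAMES[int(st)] + "\n")


def read_hypnogram(path) -> Hypnogram:
    stages = []
    with open(path) as fh:
        for line in fh:
            name = line.strip()
            if name:
                stages.append(STAGE_CODES[name])
    starts = np.arange(len(stages)) * EPOCH_S
    return Hypnogram(starts=starts, ends=starts + EPOCH_S, stages=np.asarray(stages))


def write_ecg_csv(path, signal: np.ndarray, fs: float) -> None:
    with open(path, "w") as fh:
        fh.write(f"# fs={fs:g}\n")
        fh.write("ecg\n")
        np.savetxt(fh, np.asarray(signal), fmt="%.5f")


def read_ecg_csv(path) -> tuple[np.ndarray, float]:
    fs = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#") and "fs=" in first:
            fs = float(first.split("fs=")[1].strip())
    if fs is None:
        raise ValueError(f"{path}: missing '# fs=...' header with the sampling rate")
    sig = pd.read_csv(path, comment="#")["ecg"].to_numpy(dtype=float)
    return sig, fs


def read_ecg_edf(path, channel: str) -> tuple[np.ndarray, float]:
    """Named ECG channel from an EDF recording (requires ``mne``)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the optional dependency 'mne'") from exc
    raw = mne.io.read_raw_edf(str(path), include=[channel], preload=True, verbose="error")
    data = raw.get_data(picks=[channel])[0]
    return np.asarray(data, dtype=float), float(raw.info["sfreq"])
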