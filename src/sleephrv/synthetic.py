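"""Synthetic sleep RR / ECG generator.

Emulates the statistical structure of sleep heart-rate variability in
non-, early- and middle-pregnancy so the whole analysis pipeline can be
exercised without polysomnography downloads. The instantaneous RR model
is additive:

    RR(t) = baseline + drift * t/T + LF sinusoid (~0.1 Hz)
            + RSA sinusoid (respiratory sinus arrhythmia, period ~4 s,
              amplitude gated by the NREM/REM state)
            + cascade-modulated long-range-correlated noise

The fractal component is synthesised by spectral shaping (power-law
spectrum matched to a target DFA exponent) and multiplied by a smoothed
multiplicative-cascade volatility series; this injects q-dependent
scaling that a random shuffle destroys, i.e. multifractality carried by
long-range correlations rather than by a broad value distribution. The
respiratory period is slowly jittered by a second long-range-correlated
process (stronger in REM, where breathing is less stable) so the spacing
of the RR maxima is neither degenerate-periodic nor white.

Group presets follow the observed first-quarter magnitudes: mean RR
0.90 / 0.83 / 0.78 s with overnight lengthening of +0.09 / +0.06 /
+0.02 s and respiratory periods of 4.0 / 3.7 / 3.7 s for non-, early-
and middle-pregnancy.

Beat times are built iteratively (each beat advances time by the
instantaneous RR), and a synthetic ECG with template QRS complexes plus
injected motion-artifact and flat-line windows allows end-to-end testing
of the R-peak detection and segment-rejection stages against ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

from .series import BeatSeries

__all__ = [
    "STAGE_WAKE",
    "STAGE_NREM",
    "STAGE_REM",
    "STAGE_NAMES",
    "GeneratorConfig",
    "Hypnogram",
    "CascadeSeries",
    "ECGRecording",
    "PRESETS",
    "config_for_group",
    "generate_hypnogram",
    "generate_rr",
    "generate_ecg",
    "binomial_cascade",
    "fractional_noise",
]

STAGE_WAKE, STAGE_NREM, STAGE_REM = 0, 1, 2
STAGE_NAMES = {STAGE_WAKE: "WAKE", STAGE_NREM: "NREM", STAGE_REM: "REM"}
STAGE_CODES = {v: k for k, v in STAGE_NAMES.items()}

EPOCH_S = 30.0

#: group presets: first-quarter mean RR, overnight RR lengthening and
#: respiratory period for non- / early- / middle-pregnancy
PRESETS: dict[str, dict] = {
    "non": dict(baseline_rr=0.90, overnight_drift=0.09, resp_period=4.0, lf_amplitude=0.043),
    "early": dict(baseline_rr=0.83, overnight_drift=0.06, resp_period=3.7, lf_amplitude=0.025),
    "middle": dict(baseline_rr=0.78, overnight_drift=0.02, resp_period=3.7, lf_amplitude=0.028),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic sleep-RR model.

    Amplitudes are in seconds of RR modulation. ``fractal_target_H`` is
    the DFA exponent the 1/f-like component is shaped to;
    ``cascade_asymmetry`` (in (0.5, 1)) sets the strength of the
    multiplicative-cascade volatility and hence of the injected
    multifractality. ``resp_jitter`` is the fractional slow modulation of
    the respiratory period (+/-10% by default).
    """

    group: str = "non"
    duration_h: float = 7.0
    baseline_rr: float = 0.90
    overnight_drift: float = 0.09
    resp_period: float = 4.0
    rsa_amplitude_nrem: float = 0.07
    rsa_amplitude_rem: float = 0.035
    lf_freq: float = 0.1
    lf_amplitude: float = 0.02
    fractal_target_H: float = 1.0
    fractal_amplitude: float = 0.035
    cascade_depth: int = 14
    cascade_asymmetry: float = 0.7
    resp_jitter: float = 0.30
    resp_jitter_H: float = 1.2
    resp_drift: float = 0.04
    rem_resp_instability: float = 2.8
    artifact_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.group not in PRESETS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {list(PRESETS)}")
        if self.baseline_rr <= 0:
            raise ValueError("baseline_rr must be positive")
        if not 0 < self.resp_period < 10:
            raise ValueError("resp_period must lie in (0, 10) s")
        if self.duration_h < 5:
            raise ValueError(
                "duration_h must be at least 5 h: shorter recordings cannot "
                "cover the three NREM-REM cycles required for scaling analysis"
            )
        if not 0.5 < self.cascade_asymmetry < 1:
            raise ValueError("cascade_asymmetry must lie in (0.5, 1)")


def config_for_group(group: str, duration_h: float = 7.0, seed: int = 0, **overrides) -> GeneratorConfig:
    """Preset configuration for a pregnancy group, with optional overrides."""
    params = dict(PRESETS[group])
    params.update(overrides)
    return GeneratorConfig(group=group, duration_h=duration_h, seed=seed, **params)


@dataclass
class Hypnogram:
    """Contiguous half-open 30 s epochs with stages WAKE / NREM / REM."""

    starts: np.ndarray
    ends: np.ndarray
    stages: np.ndarray  # int codes

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype=float)
        self.ends = np.asarray(self.ends, dtype=float)
        self.stages = np.asarray(self.stages, dtype=int)
        if not (np.allclose(self.starts[1:], self.ends[:-1])):
            raise ValueError("epochs must be contiguous and non-overlapping")

    @property
    def n_epochs(self) -> int:
        return int(self.stages.size)

    @property
    def duration_s(self) -> float:
        return float(self.ends[-1] - self.starts[0])

    def stage_at(self, t) -> np.ndarray:
        """Stage code at time(s) ``t`` (half-open epochs)."""
        t = np.asarray(t, dtype=float)
        idx = np.clip(np.searchsorted(self.ends, t, side="right"), 0, self.n_epochs - 1)
        return self.stages[idx]

    def wake_intervals(self) -> list[tuple[float, float]]:
        """Merged (start, end) intervals scored WAKE."""
        out: list[list[float]] = []
        for s, e, st in zip(self.starts, self.ends, self.stages):
            if st != STAGE_WAKE:
                continue
            if out and out[-1][1] == s:
                out[-1][1] = e
            else:
                out.append([s, e])
        return [(s, e) for s, e in out]

    def rem_fraction(self, t0: float, t1: float) -> float:
        inside = (self.starts >= t0) & (self.ends <= t1)
        if not inside.any():
            return 0.0
        return float(np.mean(self.stages[inside] == STAGE_REM))


@dataclass
class CascadeSeries:
    """Multiplicative binomial cascade: positive values of length 2**depth."""

    values: np.ndarray
    a: float
    depth: int


@dataclass
class ECGRecording:
    """Synthetic ECG with ground-truth beats and artifact labels."""

    signal: np.ndarray
    fs: float
    r_times: np.ndarray
    artifacts: list  # (start_s, end_s, kind) with kind in {"motion", "flat"}


def binomial_cascade(a: float, depth: int, rng: np.random.Generator | None = None) -> CascadeSeries:
    """Multiplicative binomial cascade of ``2**depth`` positive values.

    Starting from unit mass, every element splits its mass into fractions
    ``a`` and ``1 - a`` at each level, so total mass is conserved at every
    level of the construction. Without ``rng`` the split is deterministic
    (``a`` to the left child); with ``rng`` the orientation of each split
    is randomised, which randomises the series while keeping its
    multifractal exponents. The deterministic variant has the closed-form
    generalised Hurst exponents

        H(q) = 1/q - ln(a^q + (1-a)^q) / (q ln 2)

    making it an exactly solvable oracle for MF-DFA.
    """
    if not 0.5 < a < 1:
        raise ValueError("cascade multiplier a must lie in (0.5, 1)")
    if depth < 1:
        raise ValueError("cascade depth must be a positive integer")
    values = np.ones(1)
    for _ in range(depth):
        if rng is None:
            left = np.full(values.size, a)
        else:
            left = np.where(rng.random(values.size) < 0.5, a, 1.0 - a)
        nxt = np.empty(values.size * 2)
        nxt[0::2] = values * left
        nxt[1::2] = values * (1.0 - left)
        values = nxt
    return CascadeSeries(values=values, a=a, depth=depth)


def cascade_hurst_closed_form(a: float, q) -> np.ndarray:
    """Closed-form H(q) of the binomial cascade (log-average at q = 0)."""
    q = np.asarray(q, dtype=float)
    b = 1.0 - a
    out = np.empty(q.shape)
    nz = q != 0
    out[nz] = 1.0 / q[nz] - np.log(a ** q[nz] + b ** q[nz]) / (q[nz] * np.log(2))
    out[~nz] = -(np.log(a) + np.log(b)) / (2 * np.log(2))
    return out


def fractional_noise(n: int, target_H: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise spectrally shaped to a target DFA exponent.

    Uses a power-law spectrum S(f) ~ f**(-beta) with ``beta = 2 H - 1``
    (white noise at H = 0.5, 1/f noise at H = 1). Returned with zero mean
    and unit standard deviation.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    beta = 2.0 * target_H - 1.0
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-beta / 2.0)
    x = np.fft.irfft(spec * shape, n)
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def _cascade_volatility(
    n: int,
    a: float,
    depth: int,
    rng: np.random.Generator,
    smooth_samples: float,
    exponent: float = 0.3,
) -> np.ndarray:
    """Positive, mean-one volatility series from a randomised cascade.

    The raw cascade is extremely intermittent (its log-values have SD
    ``sqrt(depth) * |ln(a/(1-a))| / 2``); raising it to a sub-unity
    exponent tempers the tails so the volatility modulates — rather
    than dominates — the component it multiplies, while keeping the
    cascade's scale-invariant structure.
    """
    c = binomial_cascade(a, depth, rng=rng).values
    c = (c / c.mean()) ** exponent
    pos = np.linspace(0.0, 1.0, n)
    v = np.interp(pos, np.linspace(0.0, 1.0, c.size), c)
    v = gaussian_filter1d(v, smooth_samples, mode="nearest")
    return v / v.mean()


def generate_hypnogram(config: GeneratorConfig) -> Hypnogram:
    """Plausible overnight hypnogram on 30 s epochs.

    NREM and REM alternate in roughly 90 min cycles, with the REM portion
    of each successive cycle growing (REM pressure rises across the
    night) and occasional one-epoch awakenings at cycle boundaries. The
    layout is deterministic given the seed.
    """
    if config.duration_h < 5:
        raise ValueError(
            "duration_h must be at least 5 h: shorter recordings cannot "
            "cover the three NREM-REM cycles required for scaling analysis"
        )
    rng = np.random.default_rng([config.seed, 11])
    n_epochs = int(round(config.duration_h * 3600.0 / EPOCH_S))
    stages: list[int] = []
    cycle = 0
    while len(stages) < n_epochs:
        rem_min = min(10 + 6 * cycle, 35) + int(rng.integers(-3, 4))
        nrem_min = max(90 - rem_min + int(rng.integers(-5, 6)), 40)
        stages.extend([STAGE_NREM] * int(nrem_min * 60 / EPOCH_S))
        stages.extend([STAGE_REM] * int(rem_min * 60 / EPOCH_S))
        if rng.random() < 0.5:
            stages.extend([STAGE_WAKE] * int(rng.integers(1, 3)))
        cycle += 1
    stages_arr = np.asarray(stages[:n_epochs], dtype=int)
    starts = np.arange(n_epochs) * EPOCH_S
    return Hypnogram(starts=starts, ends=starts + EPOCH_S, stages=stages_arr)


def _instantaneous_rr(
    config: GeneratorConfig, hypnogram: Hypnogram | None, grid_hz: float = 4.0
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous RR model on a uniform grid; returns (t_grid, rr)."""
    T = config.duration_h * 3600.0
    dt = 1.0 / grid_hz
    n = int(round(T * grid_hz))
    t = np.arange(n) * dt
    rng_fr = np.random.default_rng([config.seed, 1])
    rng_resp = np.random.default_rng([config.seed, 2])
    rng_cas = np.random.default_rng([config.seed, 3])
    rng_ph = np.random.default_rng([config.seed, 4])

    if hypnogram is not None:
        stage = hypnogram.stage_at(t)
    else:
        stage = np.full(n, STAGE_NREM)
    rem = stage == STAGE_REM

    drift = config.overnight_drift * (t / T)
    lf = config.lf_amplitude * np.sin(
        2 * np.pi * config.lf_freq * t + rng_ph.uniform(0, 2 * np.pi)
    )

    # 1/f-like component with cascade volatility: q-dependent scaling
    # that shuffling destroys.
    fractal = np.zeros(n)
    if config.fractal_amplitude > 0:
        fr = fractional_noise(n, config.fractal_target_H, rng_fr)
        vol = _cascade_volatility(
            n, config.cascade_asymmetry, config.cascade_depth, rng_cas,
            smooth_samples=15.0 * grid_hz,
        )
        fr = fr * vol
        fr = gaussian_filter1d(fr, 1.0)
        fr -= fr.mean()
        sd = fr.std()
        if sd > 0:
            fr *= config.fractal_amplitude / sd
        fractal = fr

    # Respiratory sinus arrhythmia: phase integrates a slowly jittered
    # period; jitter shares the cascade-modulated 1/f structure and is
    # amplified in REM where breathing is less stable.
    rsa = np.zeros(n)
    if config.rsa_amplitude_nrem > 0 or config.rsa_amplitude_rem > 0:
        g = fractional_noise(n, config.resp_jitter_H, rng_resp)
        g *= _cascade_volatility(
            n, config.cascade_asymmetry, config.cascade_depth, rng_resp,
            smooth_samples=15.0 * grid_hz, exponent=0.35,
        )
        g = gaussian_filter1d(g, 2.0 * grid_hz)
        # remove wander slower than ~25 min so the record-mean breathing
        # rate stays anchored to the preset
        g -= uniform_filter1d(g, size=int(3000 * grid_hz), mode="nearest")
        sd = g.std()
        if sd > 0:
            g /= sd
        jitter = config.resp_jitter * np.where(rem, config.rem_resp_instability, 1.0) * g
        shape = 1.0 + np.clip(jitter, -0.6, 1.5)
        # inter-maximum gaps sample the period once per cycle, i.e. they
        # estimate its harmonic (number-weighted) mean; normalise so the
        # preset resp_period is that mean rather than the time average
        shape *= np.mean(1.0 / shape)
        period = config.resp_period * (1.0 + config.resp_drift * t / T) * shape
        phase = 2 * np.pi * np.cumsum(dt / period) + rng_ph.uniform(0, 2 * np.pi)
        amp = np.where(rem, config.rsa_amplitude_rem, config.rsa_amplitude_nrem)
        rsa = amp * np.sin(phase)

    rr = config.baseline_rr + drift + lf + rsa + fractal
    if np.any(rr <= 0):
        raise ValueError("generator parameters produce non-positive RR intervals")
    return t, np.clip(rr, 0.3, 2.0)


def generate_rr(config: GeneratorConfig, hypnogram: Hypnogram | None = None) -> BeatSeries:
    """Beat series whose RR intervals follow the instantaneous model.

    Beat times are accumulated iteratively: each beat advances time by
    the instantaneous RR evaluated at the current time. Deterministic
    given the config (seed included).
    """
    t_grid, rr_inst = _instantaneous_rr(config, hypnogram)
    T = config.duration_h * 3600.0
    grid_hz = 1.0 / (t_grid[1] - t_grid[0])
    times = [0.0]
    t = 0.0
    n = rr_inst.size
    while True:
        i = int(t * grid_hz)
        if i >= n:
            i = n - 1
        t += rr_inst[i]
        if t >= T:
            break
        times.append(t)
    return BeatSeries(r_times=np.asarray(times), source="original")


_QRS_SIGMA_S = 0.012
_T_SIGMA_S = 0.05
_T_OFFSET_S = 0.25
_T_AMPLITUDE = 0.2
_NOISE_SD = 0.05
_MOTION_SD = 3.0


def generate_ecg(
    beats: BeatSeries, config: GeneratorConfig, fs: float = 200.0
) -> ECGRecording:
    """Template-based synthetic ECG for the given beat series.

    A Gaussian R wave (unit amplitude) and a smaller T wave are centred
    at each beat time, on top of slow baseline wander and broadband
    sensor noise. Motion-artifact windows (high-variance noise) and
    flat-line windows are injected at ``config.artifact_rate`` events per
    hour, and their ground-truth labels are returned for detector
    validation.
    """
    if not 100 <= fs <= 512:
        raise ValueError("sampling rate must lie in [100, 512] Hz")
    rng = np.random.default_rng([config.seed, 21])
    duration = float(beats.r_times[-1]) + 1.0
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    sig = 0.1 * np.sin(2 * np.pi * 0.3 * t)  # baseline wander
    sig += rng.normal(0.0, _NOISE_SD, n)

    half = int(round(0.08 * fs))
    tpl_t = np.arange(-half, half + 1) / fs
    qrs = np.exp(-0.5 * (tpl_t / _QRS_SIGMA_S) ** 2)
    t_half = int(round(0.18 * fs))
    ttpl_t = np.arange(-t_half, t_half + 1) / fs
    twave = _T_AMPLITUDE * np.exp(-0.5 * (ttpl_t / _T_SIGMA_S) ** 2)

    for rt in beats.r_times:
        c = int(round(rt * fs))
        lo, hi = c - half, c + half + 1
        if lo >= 0 and hi <= n:
            sig[lo:hi] += qrs
        c_t = int(round((rt + _T_OFFSET_S) * fs))
        lo, hi = c_t - t_half, c_t + t_half + 1
        if lo >= 0 and hi <= n:
            sig[lo:hi] += twave

    artifacts: list[tuple[float, float, str]] = []
    if config.artifact_rate > 0:
        n_events = rng.poisson(config.artifact_rate * duration / 3600.0)
        for _ in range(n_events):
            start = rng.uniform(0.0, max(duration - 30.0, 1.0))
            length = rng.uniform(10.0, 30.0)
            end = min(start + length, duration)
            kind = "motion" if rng.random() < 0.5 else "flat"
            lo, hi = int(start * fs), int(end * fs)
            if kind == "motion":
                sig[lo:hi] += rng.normal(0.0, _MOTION_SD, hi - lo)
            else:
                sig[lo:hi] = 0.0
            artifacts.append((start, end, kind))
    artifacts.sort()
    return ECGRecording(signal=sig, fs=fs, r_times=beats.r_times.copy(), artifacts=artifacts)
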