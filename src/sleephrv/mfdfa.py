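"""Multifractal detrended fluctuation analysis (MF-DFA).

MF-DFA generalises detrended fluctuation analysis (DFA) from the second
moment to arbitrary q-order moments of the detrended fluctuations. For a
series ``x`` the profile (cumulative sum of the mean-centred series) is
split into non-overlapping windows of length ``s``; in each window the
residual variance ``F^2(v, s)`` about a least-squares polynomial fit is
computed, and the q-order fluctuation function is

    F_q(s) = { (1 / 2 N_s) sum_v [F^2(v, s)]^(q/2) } ^ (1/q)      (q != 0)
    F_0(s) = exp{ (1 / 4 N_s) sum_v ln F^2(v, s) }                (q == 0)

where windows are taken both from the start and from the end of the
profile (2 N_s windows in total) so that no tail is discarded. If the
series scales, ``F_q(s) ~ s^H(q)`` and the generalised Hurst exponent
H(q) is the log-log slope. ``H(2)`` is the ordinary DFA exponent alpha.

The singularity spectrum follows from the mass exponent
``tau(q) = q H(q) - 1`` via the Legendre transform
``h = dtau/dq``, ``D(h) = q h - tau(q)``. A q-dependent H(q) (equivalently
a D(h) of nonzero width) marks multifractality; shuffle surrogates
distinguish multifractality carried by long-range correlations (destroyed
by shuffling, surrogate H ~ 0.5) from that carried by a broad value
distribution (unchanged by shuffling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_Q_GRID",
    "MFDFAConfig",
    "MultifractalSpectrum",
    "default_scales",
    "scales_seconds",
    "profile",
    "fluctuation_function",
    "hurst_exponents",
    "multifractal_spectrum",
    "mfdfa",
    "dfa_alpha",
    "classify_multifractality",
]

#: q orders used throughout: negative q weights windows with small
#: fluctuations, positive q those with large fluctuations.
DEFAULT_Q_GRID = (-5.0, -3.0, -1.0, 0.0, 1.0, 3.0, 5.0)


def default_scales(n: int, s_min: int = 16, s_max: int = 2048, num: int = 20) -> np.ndarray:
    """Log-spaced integer window sizes in ``[s_min, min(s_max, n // 4)]``.

    The upper end is capped at a quarter of the series length so that at
    least four windows (eight counting both ends) enter every estimate.
    """
    s_max = min(int(s_max), n // 4)
    if s_max < s_min:
        raise ValueError(
            f"series too short for scale range: n={n} gives max scale {s_max} < {s_min}"
        )
    scales = np.unique(np.round(np.geomspace(s_min, s_max, num)).astype(int))
    return scales


def scales_seconds(
    n: int, fs: float = 4.0, s_min_s: float = 16.0, s_max_s: float = 2048.0, num: int = 20
) -> np.ndarray:
    """Log-spaced window sizes covering 16 s to 2048 s of a sampled series.

    For the 4 Hz RR / MM series the physiologically meaningful window
    range runs from a few breathing cycles (16 s) up to a third of a
    sleep cycle (2048 s ~ 34 min); windows shorter than the spacing of
    the underlying beat/maxima samples would mostly measure the
    interpolation, not the signal. Expressed in samples and capped at
    n // 4 like :func:`default_scales`.
    """
    return default_scales(n, int(round(s_min_s * fs)), int(round(s_max_s * fs)), num)


@dataclass(frozen=True)
class MFDFAConfig:
    """Analysis settings: window sizes, q grid and detrending order."""

    scales: tuple[int, ...] | None = None  # None -> default_scales(len(x))
    q_grid: tuple[float, ...] = DEFAULT_Q_GRID
    detrend_order: int = 1
    min_scale_points: int = 6

    def resolve_scales(self, n: int) -> np.ndarray:
        if self.scales is None:
            scales = default_scales(n)
        else:
            scales = np.asarray(sorted(set(int(s) for s in self.scales)))
            scales = scales[scales <= n // 4]
        scales = scales[scales >= self.detrend_order + 2]
        if len(scales) < self.min_scale_points:
            raise ValueError(
                f"only {len(scales)} usable scales for n={n}; "
                f"need at least {self.min_scale_points}"
            )
        return scales


@dataclass
class MultifractalSpectrum:
    """Result container: exponents, spectrum and the two summary indices.

    ``width = max(h) - min(h)`` quantifies multifractality strength and
    ``argmax_h`` (the singularity exponent at the peak of D(h)) its central
    tendency; for a monofractal both collapse to the single exponent H.
    """

    q_grid: np.ndarray
    H: np.ndarray
    tau: np.ndarray
    h: np.ndarray
    D: np.ndarray
    width: float
    argmax_h: float
    fit_r2: np.ndarray | None = None
    reliable: bool = True

    def summary(self) -> dict:
        return {
            "width": float(self.width),
            "argmax_h": float(self.argmax_h),
            "H2": float(np.interp(2.0, self.q_grid, self.H)),
            "reliable": bool(self.reliable),
        }


def profile(x: np.ndarray) -> np.ndarray:
    """Cumulative sum of the mean-centred series.

    The last element is zero up to round-off; a constant input yields the
    all-zero profile (warned, since no scaling can be estimated from it).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("profile expects a 1-D series")
    if x.size and np.ptp(x) == 0:
        warnings.warn("constant series: profile is identically zero", stacklevel=2)
    return np.cumsum(x - x.mean())


def _window_variances(y: np.ndarray, s: int, order: int) -> np.ndarray:
    """Residual variances about per-window polynomial fits.

    Windows of length ``s`` are taken from the start and, reversed in
    position, from the end of the profile: 2 * (N // s) values.
    """
    n = y.size
    ns = n // s
    t = np.arange(s, dtype=float)
    design = np.vander(t, order + 1, increasing=True)
    pinv = np.linalg.pinv(design)
    segs = np.concatenate([y[: ns * s].reshape(ns, s), y[n - ns * s :].reshape(ns, s)])
    coeffs = segs @ pinv.T
    resid = segs - coeffs @ design.T
    return np.mean(resid**2, axis=1)


def fluctuation_function(
    y: np.ndarray,
    scales: np.ndarray,
    q_grid=DEFAULT_Q_GRID,
    detrend_order: int = 1,
) -> np.ndarray:
    """q-order fluctuation functions ``F_q(s)`` from a profile.

    Parameters
    ----------
    y : profile (output of :func:`profile`), not the raw series.
    scales : window sizes (samples).
    q_grid : q orders; 0 uses the logarithmic average.
    detrend_order : order of the per-window polynomial fit (1 = linear).

    Returns
    -------
    F : array of shape (len(scales), len(q_grid)).

    Windows with exactly zero residual variance are excluded for q <= 0
    (with a warning) since they have no finite contribution there.
    """
    y = np.asarray(y, dtype=float)
    scales = np.asarray(scales, dtype=int)
    q_grid = np.asarray(q_grid, dtype=float)
    if np.any(scales < detrend_order + 2):
        raise ValueError("every scale must be at least detrend_order + 2")
    if np.any(scales > y.size // 4):
        raise ValueError("scales above len(y)//4 are not allowed")

    F = np.full((scales.size, q_grid.size), np.nan)
    warned = False
    for i, s in enumerate(scales):
        f2 = _window_variances(y, int(s), detrend_order)
        zero = f2 == 0.0
        for j, q in enumerate(q_grid):
            vals = f2
            if q <= 0 and zero.any():
                if not warned:
                    warnings.warn(
                        "windows with zero residual variance excluded for q <= 0",
                        stacklevel=2,
                    )
                    warned = True
                vals = f2[~zero]
                if vals.size == 0:
                    continue
            if q == 0:
                F[i, j] = np.exp(0.5 * np.mean(np.log(vals)))
            else:
                F[i, j] = np.mean(vals ** (q / 2.0)) ** (1.0 / q)
    return F


def hurst_exponents(
    F: np.ndarray, scales: np.ndarray, q_grid=DEFAULT_Q_GRID
) -> tuple[np.ndarray, np.ndarray]:
    """Per-q OLS slope of log F_q(s) versus log s, with fit R^2.

    Scales where F is non-finite (or zero) are dropped from that q's fit.
    """
    scales = np.asarray(scales, dtype=float)
    q_grid = np.asarray(q_grid, dtype=float)
    if scales.size < 6:
        raise ValueError("at least 6 scales are required for a slope fit")
    H = np.full(q_grid.size, np.nan)
    r2 = np.full(q_grid.size, np.nan)
    logs = np.log(scales)
    for j in range(q_grid.size):
        col = F[:, j]
        ok = np.isfinite(col) & (col > 0)
        if ok.sum() < 3:
            continue
        lx, ly = logs[ok], np.log(col[ok])
        slope, intercept = np.polyfit(lx, ly, 1)
        fit = slope * lx + intercept
        ss_res = np.sum((ly - fit) ** 2)
        ss_tot = np.sum((ly - ly.mean()) ** 2)
        H[j] = slope
        r2[j] = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return H, r2


def multifractal_spectrum(
    H: np.ndarray,
    q_grid=DEFAULT_Q_GRID,
    fit_r2: np.ndarray | None = None,
    concavity_tol: float = 0.05,
) -> MultifractalSpectrum:
    """Mass exponent, singularity exponents and spectrum from H(q).

    tau(q) = q H(q) - 1; h = dtau/dq by centred finite differences on the
    (possibly non-uniform) q grid, one-sided at the endpoints; and
    D(h) = q h - tau(q). tau must be concave for the Legendre transform to
    be single-valued; a violation beyond ``concavity_tol`` (on the
    decrease of successive chord slopes) flags the spectrum unreliable
    rather than raising, because small non-concavities are routine
    estimation noise.
    """
    q = np.asarray(q_grid, dtype=float)
    H = np.asarray(H, dtype=float)
    if not np.all(np.isfinite(H)):
        raise ValueError("H(q) must be finite on the whole q grid")
    tau = q * H - 1.0
    if q.size == 1:  # degenerate single-q case: spectrum collapses to a point
        h = H.copy()
        D = np.ones(1)
        width, argmax_h, reliable = 0.0, float(h[0]), True
        return MultifractalSpectrum(
            q_grid=q, H=H, tau=tau, h=h, D=D,
            width=width, argmax_h=argmax_h, fit_r2=fit_r2, reliable=reliable,
        )
    h = np.gradient(tau, q)
    D = q * h - tau
    width = float(np.max(h) - np.min(h))
    argmax_h = float(h[np.argmax(D)])
    slopes = np.diff(tau) / np.diff(q)
    reliable = bool(np.all(np.diff(slopes) <= concavity_tol))
    return MultifractalSpectrum(
        q_grid=q, H=H, tau=tau, h=h, D=D,
        width=width, argmax_h=argmax_h, fit_r2=fit_r2, reliable=reliable,
    )


def mfdfa(x: np.ndarray, config: MFDFAConfig | None = None) -> MultifractalSpectrum:
    """Full MF-DFA pipeline on a raw series: profile -> F_q(s) -> spectrum."""
    if config is None:
        config = MFDFAConfig()
    x = np.asarray(x, dtype=float)
    if x.size < 64:
        raise ValueError("series too short for MF-DFA (need >= 64 samples)")
    scales = config.resolve_scales(x.size)
    y = profile(x)
    F = fluctuation_function(y, scales, config.q_grid, config.detrend_order)
    H, r2 = hurst_exponents(F, scales, config.q_grid)
    return multifractal_spectrum(H, config.q_grid, fit_r2=r2)


def dfa_alpha(x: np.ndarray, scales: np.ndarray | None = None, detrend_order: int = 1) -> float:
    """Monofractal DFA exponent alpha, identically H(2) of :func:`mfdfa`."""
    x = np.asarray(x, dtype=float)
    if scales is None:
        scales = default_scales(x.size)
    y = profile(x)
    F = fluctuation_function(y, scales, q_grid=(2.0,), detrend_order=detrend_order)
    H, _ = hurst_exponents(F, scales, q_grid=(2.0,))
    return float(H[0])


def classify_multifractality(
    H_orig: np.ndarray,
    H_surr: np.ndarray,
    q_grid=DEFAULT_Q_GRID,
    band: float = 0.1,
    min_width: float = 0.15,
) -> str:
    """Attribute multifractality to correlations, a broad pdf, or neither.

    Parameters
    ----------
    H_orig : H(q) of the original series.
    H_surr : surrogate H(q), shape (n_surrogates, n_q) or (n_q,).
    band : tolerance for "indistinguishable from 0.5" / "coincides with
        the original", applied per q to the surrogate-ensemble mean.
    min_width : singularity-spectrum width below which the original is
        considered effectively monofractal ("none").

    Returns one of ``"correlations"``, ``"broad_pdf"``, ``"none"``.
    """
    q = np.asarray(q_grid, dtype=float)
    H_orig = np.asarray(H_orig, dtype=float)
    H_surr = np.atleast_2d(np.asarray(H_surr, dtype=float))
    if H_orig.shape != (q.size,) or H_surr.shape[1] != q.size:
        raise ValueError("original and surrogate H must share the q grid")
    surr_mean = H_surr.mean(axis=0)
    width_orig = multifractal_spectrum(H_orig, q).width
    width_surr = float(
        np.mean([multifractal_spectrum(row, q).width for row in H_surr])
    )
    if width_orig < min_width:
        return "none"
    white_like = np.all(np.abs(surr_mean - 0.5) <= band)
    coincide = np.all(np.abs(surr_mean - H_orig) <= band)
    if white_like and width_orig > width_surr:
        return "correlations"
    if coincide:
        return "broad_pdf"
    # Ambiguous estimates: attribute to whichever pattern is closer.
    dist_white = float(np.max(np.abs(surr_mean - 0.5)))
    dist_coincide = float(np.max(np.abs(surr_mean - H_orig)))
    return "correlations" if dist_white <= dist_coincide else "broad_pdf"
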