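"""FCS autocorrelation and 2D diffusion fitting; LAURDAN generalized polarization.

The normalized fluctuation autocorrelation
G(τ) = ⟨δF(t)δF(t+τ)⟩ / ⟨F⟩² of an intensity trace from membrane diffusers
under a Gaussian observation profile decays as the single-component 2D model

    G(τ) = G0 / (1 + τ/τ_D),        D = w² / (4 τ_D),

with G0 ≈ 1/⟨N⟩ the inverse mean particle number in the effective
observation area.  No triplet/photophysics term is included.  GP is the
two-channel ratio (I440 − I490)/(I440 + I490) computed per pixel over a
signal mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .core_io import DataError, logger


class FitError(RuntimeError):
    """Raised when the FCS model cannot be fitted to a correlation curve."""


@dataclass
class FCSTrace:
    times: np.ndarray          # s
    intensity: np.ndarray      # counts (a.u.)
    dt: float                  # s

    def __post_init__(self) -> None:
        if len(self.times) != len(self.intensity):
            raise DataError("times and intensity must have equal length")
        if len(self.times) > 1:
            steps = np.diff(self.times)
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
                raise DataError("FCS trace must be uniformly sampled")


@dataclass
class CorrelationCurve:
    lags: np.ndarray           # s
    G: np.ndarray
    zero_variance: bool = False


@dataclass
class FCSFit:
    G0: float
    tau_D: float               # s
    D: float                   # μm²/s
    waist_w: float             # μm
    residual_norm: float


def _linear_acf(df: np.ndarray, max_lag: int) -> np.ndarray:
    """Unbiased ⟨δF(t)δF(t+k)⟩ for k = 0..max_lag via FFT."""
    n = len(df)
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(df, nfft)
    acf = np.fft.irfft(f * np.conj(f), nfft)[: max_lag + 1]
    return acf / (n - np.arange(max_lag + 1))


def _multitau_lags(n: int, points_per_octave: int = 8) -> np.ndarray:
    """Quasi-logarithmic integer lag grid (multi-tau style)."""
    lags = list(range(1, points_per_octave + 1))
    step = 1
    while lags and lags[-1] < n - 1:
        step *= 2
        start = lags[-1] + step
        block = list(range(start, min(start + step * points_per_octave, n), step))
        if not block:
            break
        lags.extend(block)
    return np.array([l for l in lags if l < n], dtype=int)


def autocorrelate(trace: FCSTrace, scheme: str = "multitau",
                  max_lag: Optional[float] = None,
                  points_per_octave: int = 8) -> CorrelationCurve:
    """Normalized fluctuation autocorrelation G(τ) = ⟨δF δF(τ)⟩/⟨F⟩².

    ``scheme='linear'`` returns every lag up to ``max_lag`` (default half
    the trace); ``'multitau'`` returns a quasi-logarithmic grid of 8 points
    per octave, suited to long traces.  A constant trace has zero variance;
    the returned curve is all-zero with ``zero_variance`` set.
    """
    n = len(trace.intensity)
    if n < 1000:
        raise DataError("autocorrelation needs at least 1000 samples")
    mean = trace.intensity.mean()
    df = trace.intensity - mean
    if mean == 0 or np.allclose(df, 0.0, atol=1e-12 * max(1.0, abs(mean))):
        logger.warning("constant intensity trace: correlation undefined")
        lags = np.arange(1, min(n // 2, 64)) * trace.dt
        return CorrelationCurve(lags, np.zeros(len(lags)), zero_variance=True)

    max_k = n // 2 if max_lag is None else min(n - 2, int(round(max_lag / trace.dt)))
    acf = _linear_acf(df, max_k)
    g_all = acf / mean ** 2
    if scheme == "linear":
        ks = np.arange(1, max_k + 1)
    elif scheme == "multitau":
        ks = _multitau_lags(max_k + 1, points_per_octave)
    else:
        raise ValueError("scheme must be 'linear' or 'multitau'")
    return CorrelationCurve(ks * trace.dt, g_all[ks])


def fcs_model_2d(tau: np.ndarray, g0: float, tau_d: float) -> np.ndarray:
    """Single-component 2D diffusion FCS model G(τ) = G0/(1 + τ/τ_D)."""
    return g0 / (1.0 + tau / tau_d)


def fit_fcs(curve: CorrelationCurve, waist_w: float,
            model: str = "2D") -> FCSFit:
    """Nonlinear least-squares fit of the 2D diffusion model to G(τ).

    D = w²/(4 τ_D) with the waist in μm and lags in seconds gives D in
    μm²/s.  A non-decaying curve (or a fit driven to a non-positive τ_D)
    raises :class:`FitError`.
    """
    if model != "2D":
        raise ValueError("only the single-component 2D model is implemented")
    if curve.zero_variance:
        raise FitError("curve has zero variance; nothing to fit")
    lags = np.asarray(curve.lags, dtype=float)
    g = np.asarray(curve.G, dtype=float)
    ok = lags > 0
    lags, g = lags[ok], g[ok]
    if len(lags) < 4:
        raise FitError("too few lag points to fit")

    g0_guess = float(np.median(g[: max(3, len(g) // 50)]))
    if g0_guess <= 0:
        raise FitError("correlation amplitude is non-positive")
    below = np.nonzero(g < g0_guess / 2)[0]
    tau_guess = float(lags[below[0]]) if len(below) else float(lags[len(lags) // 2])
    # iterative refit restricted to lags ≲ 100 τ_D: beyond that the curve is
    # pure noise (slightly negative from mean subtraction) and would bias τ_D
    g0, tau_d = g0_guess, tau_guess
    try:
        for _ in range(3):
            m = lags <= 100.0 * tau_d
            if m.sum() < 4:
                m = np.ones_like(lags, dtype=bool)
            popt, _ = curve_fit(fcs_model_2d, lags[m], g[m],
                                p0=(g0, tau_d),
                                bounds=([0.0, 0.0], [np.inf, np.inf]),
                                maxfev=10000)
            g0, tau_d = (float(v) for v in popt)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"FCS fit did not converge: {exc}") from exc
    if tau_d <= 0 or not np.isfinite(tau_d):
        raise FitError("fitted correlation time is not positive")
    resid = g - fcs_model_2d(lags, g0, tau_d)
    return FCSFit(G0=g0, tau_D=tau_d, D=waist_w ** 2 / (4.0 * tau_d),
                  waist_w=waist_w, residual_norm=float(np.sqrt((resid ** 2).mean())))


# ---------------------------------------------------------------------------
# Generalized polarization
# ---------------------------------------------------------------------------

@dataclass
class GPResult:
    gp: np.ndarray             # per-pixel GP, NaN where masked
    mask: np.ndarray           # True where defined
    mean_gp: float
    I440: np.ndarray
    I490: np.ndarray


def compute_gp(i440: np.ndarray, i490: np.ndarray,
               mask_threshold="auto") -> GPResult:
    """LAURDAN generalized polarization GP = (I440 − I490)/(I440 + I490).

    Pixels whose summed intensity falls at or below ``mask_threshold`` are
    masked (NaN); ``'auto'`` uses 3× the median summed intensity of the
    dimmer half of the image as a background proxy.  The scalar summary is
    the mean GP over the mask.
    """
    i440 = np.asarray(i440, dtype=float)
    i490 = np.asarray(i490, dtype=float)
    if i440.shape != i490.shape:
        raise DataError(f"channel shapes differ: {i440.shape} vs {i490.shape}")
    total = i440 + i490
    if mask_threshold == "auto":
        lower_half = np.sort(total.ravel())[: max(1, total.size // 2)]
        mask_threshold = 3.0 * float(np.median(lower_half))
    mask = total > mask_threshold
    gp = np.full(total.shape, np.nan)
    np.divide(i440 - i490, total, out=gp, where=mask)
    mean_gp = float(np.nanmean(gp[mask])) if mask.any() else float("nan")
    return GPResult(gp, mask, mean_gp, i440, i490)
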