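"""Burg autoregressive spectral estimation and peak-frequency extraction.

The ventilatory frequency of a 5-s segment is estimated as the location of
the maximum of an autoregressive power spectral density fitted with Burg's
method.  Burg's recursion minimizes the summed forward and backward
prediction error at each stage through a reflection coefficient

    k_m = -2 * sum(f_m[t] * b_m[t-1]) / sum(f_m[t]^2 + b_m[t-1]^2),

updates the AR coefficients by the Levinson recursion, and the prediction
error power by E_m = (1 - k_m^2) * E_{m-1}.  Because every |k_m| < 1 the
fitted model is guaranteed stable, and the error sequence E_0 >= E_1 >= ...
is obtained in a single sweep, which makes AIC order selection over
p = 10..50 cheap: AIC(p) = n * ln(E_p) + 2 p.

Coefficient convention: x_t = -sum_k a_k x_{t-k} + e_t, i.e. the AR
polynomial is A(z) = 1 + a_1 z^-1 + ... + a_p z^-p, and the PSD is

    S(f) = sigma^2 / (rate * |A(e^{-i 2 pi f / rate})|^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .errors import DegenerateSegmentError, NoPeakError, OrderError

AR_ORDER_MIN = 10
AR_ORDER_MAX = 50
DEFAULT_N_FREQ = 4096
#: peak search band = the ventilatory filter passband, Hz
DEFAULT_PEAK_BAND = (1.0, 10.0)
#: below this max/min power ratio the in-band spectrum counts as flat
FLATNESS_RATIO = 1.001


@dataclass
class ARModel:
    """Burg-estimated autoregressive model of one segment."""

    order: int
    coefficients: np.ndarray  # a_1..a_p
    residual_variance: float  # E_p, prediction error power
    rate_hz: float
    n_samples: int
    reflection: np.ndarray | None = None  # k_1..k_p from the Burg recursion

    def polynomial(self) -> np.ndarray:
        """Full AR polynomial [1, a_1, ..., a_p]."""
        return np.concatenate(([1.0], self.coefficients))

    def poles(self) -> np.ndarray:
        return np.roots(self.polynomial())

    def is_stable(self) -> bool:
        if self.reflection is not None:
            return bool(np.all(np.abs(self.reflection) < 1.0))
        return bool(np.all(np.abs(self.poles()) < 1.0))


@dataclass
class PsdEstimate:
    """AR power spectral density evaluated on a frequency grid."""

    frequencies_hz: np.ndarray
    power: np.ndarray
    source: ARModel

    def __post_init__(self) -> None:
        if len(self.frequencies_hz) != len(self.power):
            raise ValueError("frequency and power grids must have equal length")


def _burg_sweep(x: np.ndarray, p_max: int):
    """One Burg recursion up to order ``p_max``.

    Returns (coeffs_by_order, errors, reflections) where
    ``coeffs_by_order[m]`` is a_1..a_m, ``errors[m]`` = E_m (errors[0] is
    the sample power) and ``reflections[m-1]`` = k_m.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if p_max < 1:
        raise OrderError("order must be >= 1")
    if p_max >= n / 2:
        raise OrderError(f"order {p_max} too high for {n} samples (need p < n/2)")
    e0 = float(np.dot(x, x)) / n
    if e0 <= 0:
        raise DegenerateSegmentError("zero-energy input")
    f = x.copy()
    b = x.copy()
    a = np.empty(0)
    coeffs = {0: np.empty(0)}
    errors = np.empty(p_max + 1)
    errors[0] = e0
    ks = np.empty(p_max)
    for m in range(1, p_max + 1):
        ff = f[1:]
        bb = b[:-1]
        den = float(np.dot(ff, ff) + np.dot(bb, bb))
        if den <= 0:
            raise DegenerateSegmentError(f"prediction error vanished at order {m}")
        k = -2.0 * float(np.dot(ff, bb)) / den
        ks[m - 1] = k
        a = np.concatenate((a + k * a[::-1], [k]))
        errors[m] = errors[m - 1] * (1.0 - k * k)
        f, b = ff + k * bb, bb + k * ff
        coeffs[m] = a.copy()
    return coeffs, errors, ks


def burg_fit(x: np.ndarray, p: int, rate_hz: float) -> ARModel:
    """Fit a p-order AR model to a (zero-mean) segment by Burg's method."""
    coeffs, errors, ks = _burg_sweep(np.asarray(x, dtype=float), p)
    return ARModel(
        order=p,
        coefficients=coeffs[p],
        residual_variance=float(errors[p]),
        rate_hz=rate_hz,
        n_samples=len(x),
        reflection=ks[:p],
    )


def select_order_aic(
    x: np.ndarray,
    rate_hz: float,
    p_min: int = AR_ORDER_MIN,
    p_max: int = AR_ORDER_MAX,
) -> tuple[int, ARModel]:
    """Choose the AR order in [p_min, p_max] minimizing AIC(p) = n ln E_p + 2p.

    A single Burg sweep to ``p_max`` provides the whole error sequence; ties
    break toward the smaller order.  A 5-s segment comfortably satisfies the
    n > 2 p_max requirement at both 500 Hz (2500 samples) and 100 fps (500).
    """
    x = np.asarray(x, dtype=float)
    if not 1 <= p_min <= p_max:
        raise OrderError(f"need 1 <= p_min <= p_max, got [{p_min}, {p_max}]")
    n = len(x)
    coeffs, errors, ks = _burg_sweep(x, p_max)
    orders = np.arange(p_min, p_max + 1)
    aic = n * np.log(errors[p_min : p_max + 1]) + 2.0 * orders
    best = int(orders[int(np.argmin(aic))])  # argmin returns first minimum -> smaller p
    model = ARModel(
        order=best,
        coefficients=coeffs[best],
        residual_variance=float(errors[best]),
        rate_hz=rate_hz,
        n_samples=n,
        reflection=ks[:best],
    )
    return best, model


def aic_curve(x: np.ndarray, p_min: int = AR_ORDER_MIN, p_max: int = AR_ORDER_MAX):
    """AIC(p) over the order grid, for diagnostics and oracle tests."""
    x = np.asarray(x, dtype=float)
    _, errors, _ = _burg_sweep(x, p_max)
    orders = np.arange(p_min, p_max + 1)
    return orders, len(x) * np.log(errors[p_min : p_max + 1]) + 2.0 * orders


def ar_psd(
    model: ARModel,
    n_freq: int = DEFAULT_N_FREQ,
    band: tuple[float, float] | None = None,
) -> PsdEstimate:
    """Evaluate the AR power spectral density on a uniform grid.

    By default the grid spans [0, Nyquist]; passing ``band`` restricts it
    (used to refine resolution over the peak-search band without a huge
    global grid).
    """
    lo, hi = band if band is not None else (0.0, model.rate_hz / 2)
    freqs = np.linspace(lo, hi, n_freq)
    # |A(e^{-iw})|^2 via freqz on the AR polynomial
    _, h = _signal.freqz(1.0, model.polynomial(), worN=freqs, fs=model.rate_hz)
    power = model.residual_variance / model.rate_hz * np.abs(h) ** 2
    return PsdEstimate(frequencies_hz=freqs, power=power, source=model)


def peak_frequency(
    psd: PsdEstimate, band: tuple[float, float] = DEFAULT_PEAK_BAND
) -> float:
    """Frequency of maximum AR power within the search band.

    The band defaults to the ventilatory filter passband (1–10 Hz), where
    observed peak frequencies fall (1–6 Hz).  Ties break toward the lower
    frequency.  A flat in-band spectrum (max/min power ratio < 1.001, e.g.
    white noise) has no meaningful peak and raises :class:`NoPeakError`.
    """
    lo, hi = band
    f = psd.frequencies_hz
    mask = (f >= lo) & (f <= hi)
    if not mask.any():
        raise NoPeakError(f"band ({lo}, {hi}) Hz not covered by the PSD grid")
    step = np.max(np.diff(f[mask])) if mask.sum() > 1 else np.inf
    if step > 0.02 + 1e-12:
        raise NoPeakError(
            f"PSD grid spacing {step:.4f} Hz too coarse over the band (need <= 0.02 Hz)"
        )
    p = psd.power[mask]
    if p.max() / max(p.min(), 1e-300) < FLATNESS_RATIO:
        raise NoPeakError("spectrum is flat in the search band")
    return float(f[mask][int(np.argmax(p))])


def segment_peak_frequency(
    values: np.ndarray,
    rate_hz: float,
    p_min: int = AR_ORDER_MIN,
    p_max: int = AR_ORDER_MAX,
    band: tuple[float, float] = DEFAULT_PEAK_BAND,
    grid_hz: float = 0.01,
) -> float:
    """Full per-segment chain: AIC-selected Burg fit -> in-band PSD -> peak.

    The PSD is evaluated on a dense local grid over the search band
    (``grid_hz`` spacing) so the peak resolution is independent of a global
    Nyquist-wide grid.
    """
    _, model = select_order_aic(values, rate_hz, p_min=p_min, p_max=p_max)
    n = int(np.ceil((band[1] - band[0]) / grid_hz)) + 1
    psd = ar_psd(model, n_freq=n, band=band)
    return peak_frequency(psd, band=band)
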