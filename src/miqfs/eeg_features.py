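"""Per-band EEG features: C0 complexity, approximate entropy, Higuchi fractal
dimension, Hjorth parameters, and mean power spectral density.

Each epoch channel is decomposed into the five clinical frequency bands with a
six-level discrete wavelet transform, and every feature family is evaluated on
each band-limited reconstruction, giving the channel x band x family layout
(19 channels -> 95 columns per scalar family, 285 for the three Hjorth
parameters, 665 for the full fusion).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numba
import numpy as np
import pywt

from .containers import EpochSet, FeatureMatrix

BAND_NAMES = ("delta", "theta", "alpha", "beta", "gamma")

#: Nominal band edges in Hz at fs = 256 for the 6-level dyadic mapping.
BAND_EDGES_HZ = {
    "delta": (0.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 16.0),
    "beta": (16.0, 32.0),
    "gamma": (32.0, 128.0),
}

# wavedec returns [cA6, cD6, cD5, cD4, cD3, cD2, cD1]; the gamma band keeps
# both D2 and the level-1 residual D1 so the five bands partition the
# coefficient space and band reconstructions sum exactly to the epoch.
_BAND_COEFF_INDEX = {
    "delta": (0, 1),   # A6 + D6, <4 Hz
    "theta": (2,),     # D5, 4-8 Hz
    "alpha": (3,),     # D4, 8-16 Hz
    "beta": (4,),      # D3, 16-32 Hz
    "gamma": (5, 6),   # D2 + D1, >=32 Hz
}

_MIN_EPOCH_LEN = 64  # 2**6 samples needed for six decomposition levels

FAMILY_ORDER = ("CO", "ApEn", "FD", "Hjorth", "PSD")


class DegenerateSignalError(ValueError):
    """Raised when a feature is undefined on a (near-)constant series."""


@dataclass
class BandSignals:
    """Band-limited reconstructions of one epoch, all at the original length."""

    delta: np.ndarray
    theta: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in BAND_NAMES}


def decompose_bands(x: np.ndarray, fs: float = 256.0,
                    wavelet: str = "db8") -> BandSignals:
    """Split an epoch into the five clinical bands via a 6-level DWT.

    One masked set of wavelet coefficients is inverted per band, so each band
    series has the length of the input and the five series sum back to the
    original epoch (perfect reconstruction).

    Parameters
    ----------
    x : 1-D array
        Epoch samples; at least 64 samples are required for six levels.
    fs : float
        Sampling rate. The dyadic band edges above are exact only at 256 Hz.
    wavelet : str
        Mother wavelet (PyWavelets name).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("decompose_bands expects a 1-D series")
    if x.size < _MIN_EPOCH_LEN:
        raise ValueError(
            f"epoch too short for a 6-level DWT: need >= {_MIN_EPOCH_LEN} "
            f"samples, got {x.size}")
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    coeffs = pywt.wavedec(x, wavelet, level=6, mode="periodization")
    out: dict[str, np.ndarray] = {}
    for band, keep in _BAND_COEFF_INDEX.items():
        masked = [c if i in keep else np.zeros_like(c)
                  for i, c in enumerate(coeffs)]
        rec = pywt.waverec(masked, wavelet, mode="periodization")
        out[band] = rec[:x.size]
    return BandSignals(**out)


@numba.njit(cache=False)
def _apen_phi(x: np.ndarray, m: int, r: float) -> float:
    """Mean log of self-inclusive template-match ratios at embedding m."""
    n = x.shape[0]
    cnt = n - m + 1
    total = 0.0
    for i in range(cnt):
        c = 0
        for j in range(cnt):
            d = 0.0
            for k in range(m):
                t = abs(x[i + k] - x[j + k])
                if t > d:
                    d = t
                    if d > r:
                        break
            if d <= r:
                c += 1
        total += np.log(c / cnt)
    return total / cnt


def approximate_entropy(x: np.ndarray, m: int = 2,
                        r: float | None = None) -> float:
    """Approximate entropy ApEn(m, r) of a series.

    Counts Chebyshev-ball template matches (self-matches included) at
    embeddings ``m`` and ``m + 1``; the match ratios are averaged on the
    natural-log scale over the ``N - m + 1`` templates and differenced.
    ``r`` defaults to ``0.2 * SD(x)``, the standard tolerance.
    """
    x = np.asarray(x, dtype=float)
    if m < 1:
        raise ValueError("embedding dimension m must be >= 1")
    if x.size < m + 2:
        raise ValueError(f"series too short for ApEn: need > {m + 1} samples")
    if r is None:
        r = 0.2 * float(np.std(x))
    if r <= 0:
        raise ValueError("tolerance r must be positive")
    return float(_apen_phi(x, m, r) - _apen_phi(x, m + 1, r))


def psd_mean(x: np.ndarray) -> float:
    """Mean periodogram power ``(1/N) sum |DFT(x)|^2`` (equals ``sum x^2``)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("psd_mean requires a nonempty series")
    spec = np.fft.fft(x)
    return float(np.sum(np.abs(spec) ** 2) / x.size)


def hjorth_activity(x: np.ndarray) -> float:
    """Population variance of the series (zero for a constant signal)."""
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValueError("empty series")
    return float(np.var(x))


def hjorth(x: np.ndarray) -> tuple[float, float, float]:
    """Hjorth activity, mobility, and complexity.

    Activity is the population variance; mobility is
    ``sqrt(var(dx) / var(x))`` with ``dx`` the first difference; complexity is
    ``mobility(dx) / mobility(x)``. All variances are population (1/N),
    mean-centered. A signal whose first difference is constant (e.g. a ramp)
    has zero mobility and, by convention, zero complexity; a constant signal
    has no defined mobility at all and raises.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("hjorth requires at least 3 samples")
    v0 = float(np.var(x))
    if v0 == 0.0:
        raise DegenerateSignalError(
            "mobility/complexity undefined for a constant signal")
    d1 = np.diff(x)
    d2 = np.diff(d1)
    v1 = float(np.var(d1))
    v2 = float(np.var(d2))
    mobility = np.sqrt(v1 / v0)
    if v1 == 0.0:
        return v0, 0.0, 0.0
    complexity = np.sqrt(v2 / v1) / mobility
    return v0, float(mobility), float(complexity)


def c0_complexity(x: np.ndarray) -> float:
    """C0 complexity: fraction of energy outside above-mean-power DFT bins.

    Bins whose power does not exceed the mean bin power are zeroed; the
    retained spectrum is inverted and the residual energy ratio
    ``sum |x - y|^2 / sum |x|^2`` is returned, a value in [0, 1]. Regular
    signals concentrate power in few strong bins and score near 0.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    denom = float(np.sum(x ** 2))
    if denom == 0.0:
        raise DegenerateSignalError("C0 undefined for an all-zero series")
    spec = np.fft.fft(x)
    power = np.abs(spec) ** 2
    mean_power = power.mean()
    kept = np.where(power > mean_power, spec, 0.0)
    y = np.fft.ifft(kept)
    num = float(np.sum(np.abs(x - y) ** 2))
    return num / denom


def higuchi_fd(x: np.ndarray, kmax: int = 8) -> float:
    """Higuchi fractal dimension from the log-log curve-length slope.

    For each scale ``T = 1..kmax`` the mean normalized curve length ``L(T)``
    is computed over the ``T`` decimated subseries, and the slope of
    ``ln L(T)`` against ``ln (1/T)`` is the fractal dimension (1 for a smooth
    line, 2 for white noise).
    """
    x = np.asarray(x, dtype=float)
    if kmax < 2:
        raise ValueError("kmax must be >= 2")
    n = x.size
    if n < 10 * kmax:
        raise ValueError(
            f"series too short for kmax={kmax}: need >= {10 * kmax} samples")
    lengths = np.empty(kmax)
    for k in range(1, kmax + 1):
        lk = 0.0
        for m0 in range(k):
            n_steps = (n - 1 - m0) // k
            if n_steps < 1:
                continue
            sub = x[m0::k]
            dist = np.sum(np.abs(np.diff(sub[:n_steps + 1])))
            lk += dist * (n - 1) / (n_steps * k) / k
        lengths[k - 1] = lk / k
    t = np.arange(1, kmax + 1)
    slope = np.polyfit(np.log(1.0 / t), np.log(lengths), 1)[0]
    return float(slope)


def _family_columns(family: str) -> tuple[str, ...]:
    if family == "Hjorth":
        return ("hjorth_activity", "hjorth_mobility", "hjorth_complexity")
    return ({"CO": "c0", "ApEn": "apen", "FD": "fd", "PSD": "psd"}[family],)


def _eval_family(family: str, band_x: np.ndarray, *, m: int,
                 r_factor: float, kmax: int) -> tuple[float, ...]:
    if family == "CO":
        return (c0_complexity(band_x),)
    if family == "ApEn":
        sd = float(np.std(band_x))
        if sd == 0.0:
            raise DegenerateSignalError("ApEn tolerance degenerate (SD = 0)")
        return (approximate_entropy(band_x, m=m, r=r_factor * sd),)
    if family == "FD":
        return (higuchi_fd(band_x, kmax=kmax),)
    if family == "Hjorth":
        return hjorth(band_x)
    if family == "PSD":
        return (psd_mean(band_x),)
    raise ValueError(f"unknown feature family {family!r}")


def extract_feature_matrix(epochs: EpochSet,
                           families: tuple[str, ...] = FAMILY_ORDER,
                           *, wavelet: str = "db8", apen_m: int = 2,
                           apen_r_factor: float = 0.2, fd_kmax: int = 8,
                           on_degenerate: str = "raise") -> FeatureMatrix:
    """Assemble the channel x band x family feature table for an epoch set.

    Columns are grouped family-major in the canonical order
    (CO, ApEn, FD, Hjorth, PSD), then channel-major, then band, and named
    ``"<channel>.<band>.<family>"``. With 19 channels each scalar family
    contributes 95 columns, the three Hjorth parameters 285, and the fusion
    of all five families 665.

    ``on_degenerate`` controls what happens when a feature is undefined on a
    constant band series: ``"raise"`` propagates the error, ``"zero"`` fills
    0.0 and emits a warning.
    """
    if not families:
        raise ValueError("at least one feature family is required")
    bad = [f for f in families if f not in FAMILY_ORDER]
    if bad:
        raise ValueError(f"unknown feature families: {bad}")
    if on_degenerate not in ("raise", "zero"):
        raise ValueError("on_degenerate must be 'raise' or 'zero'")
    families = tuple(f for f in FAMILY_ORDER if f in families)

    names: list[str] = []
    for family in families:
        for ch in epochs.channel_names:
            for band in BAND_NAMES:
                names.extend(f"{ch}.{band}.{col}"
                             for col in _family_columns(family))

    values = np.empty((epochs.n_epochs, len(names)))
    for e in range(epochs.n_epochs):
        bands_per_channel = [
            decompose_bands(epochs.data[e, c], fs=epochs.fs,
                            wavelet=wavelet).as_dict()
            for c in range(epochs.n_channels)
        ]
        col = 0
        for family in families:
            for c in range(epochs.n_channels):
                for band in BAND_NAMES:
                    try:
                        vals = _eval_family(
                            family, bands_per_channel[c][band],
                            m=apen_m, r_factor=apen_r_factor, kmax=fd_kmax)
                    except DegenerateSignalError:
                        if on_degenerate == "raise":
                            raise
                        width = len(_family_columns(family))
                        warnings.warn(
                            f"degenerate {family} on epoch {e}, channel "
                            f"{epochs.channel_names[c]}, band {band}; "
                            "filling 0", stacklevel=2)
                        vals = (0.0,) * width
                    for v in vals:
                        values[e, col] = v
                        col += 1
    return FeatureMatrix(values=values, names=names, labels=epochs.labels)
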