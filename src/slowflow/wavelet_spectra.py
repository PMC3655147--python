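"""Morlet continuous wavelet transform and time-frequency spectral matrices.

The analysis pipeline starts from the complex Morlet CWT W_l(t, f) of each
node's realizations.  Cross-products averaged over realizations give the
Hermitian spectral density matrix

    S_lm(t, f) = c(f) · ⟨ W_l(t, f) W_m(t, f)* ⟩ ,

whose diagonal is the node power and whose normalized off-diagonal
magnitude is the coherence.  The normalization c(f) = √π ω0 / (2π f) is
chosen so that S is a one-sided spectral density: for stationary input the
trapezoid integral of the diagonal over the frequency grid approximates the
sample variance (constant factor 1).

Edge effects are tracked through a per-frequency cone of influence (COI):
cells closer than √2·s(f) seconds to either end of the record (s the wavelet
scale) are flagged and excluded from downstream band averages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.fft import fft, ifft

from .synthetic_data import MultiTrialTimeSeries

__all__ = [
    "TimeFreqGrid",
    "SpectralMatrixSeries",
    "PowerMap",
    "CoherenceMap",
    "default_freq_grid",
    "morlet_cwt",
    "spectral_matrix",
    "power",
    "coherence",
]

logger = logging.getLogger(__name__)

DEFAULT_OMEGA0 = 6.0
DEFAULT_N_VOICES = 40
DEFAULT_FMIN = 0.005


@dataclass(frozen=True)
class TimeFreqGrid:
    """The (t, f) grid on which time-frequency quantities live."""

    times: np.ndarray  # seconds, sample-aligned
    freqs: np.ndarray  # Hz, strictly increasing, within (0, Nyquist]
    sampling_interval: float

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.freqs, dtype=float)
        if np.any(np.diff(f) <= 0):
            raise ValueError("freqs must be strictly increasing")
        nyq = 0.5 / self.sampling_interval
        if f[0] <= 0 or f[-1] > nyq * (1 + 1e-9):
            raise ValueError(f"freqs must lie within (0, Nyquist={nyq:g}]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "freqs", f)

    @property
    def n_time(self) -> int:
        return self.times.size

    @property
    def n_freq(self) -> int:
        return self.freqs.size


def default_freq_grid(
    sampling_interval: float,
    n_voices: int = DEFAULT_N_VOICES,
    fmin: float = DEFAULT_FMIN,
) -> np.ndarray:
    """Log-spaced frequency grid from ``fmin`` to Nyquist (inclusive)."""
    nyq = 0.5 / sampling_interval
    return np.geomspace(fmin, nyq, n_voices)


def _scales(freqs: np.ndarray, omega0: float) -> np.ndarray:
    """Wavelet scale s(f) at which the Morlet passband peaks at f."""
    return omega0 / (2.0 * np.pi * freqs)


def coi_width_seconds(freqs: np.ndarray, omega0: float = DEFAULT_OMEGA0) -> np.ndarray:
    """Cone-of-influence width per frequency: the e-folding time √2·s(f)."""
    return np.sqrt(2.0) * _scales(np.asarray(freqs, dtype=float), omega0)


def coi_mask(
    n_time: int,
    sampling_interval: float,
    freqs: np.ndarray,
    omega0: float = DEFAULT_OMEGA0,
) -> np.ndarray:
    """Boolean (n_time, n_freq) mask, True where the cell is inside the COI
    (contaminated by the record edges)."""
    t = np.arange(n_time) * sampling_interval
    width = coi_width_seconds(freqs, omega0)
    total = (n_time - 1) * sampling_interval
    return (t[:, None] < width[None, :]) | (t[:, None] > total - width[None, :])


def _cwt_batch(
    x: np.ndarray,
    sampling_interval: float,
    freqs: np.ndarray,
    omega0: float,
    max_chunk_elems: int = 8_000_000,
) -> np.ndarray:
    """Morlet CWT of a batch of signals, shape (..., n_time) ->
    (..., n_freq, n_time).

    The analytic Morlet kernel 2·exp(-(sω-ω0)²/2) (ω > 0) is applied in the
    Fourier domain on the even periodic extension [x, reversed x] (circular
    reflection, so no artificial edges enter the convolution).  The factor
    2 restores the amplitude of the discarded negative frequencies, so a
    unit sinusoid at f0 has |W(t, f0)| = 1 away from the record edges,
    independent of f0.
    """
    x = np.asarray(x, dtype=float)
    shape = x.shape
    n = shape[-1]
    if n < 2:
        raise ValueError("signal length must be at least 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite samples in input signal")
    freqs = np.asarray(freqs, dtype=float)
    nyq = 0.5 / sampling_interval
    if np.any(freqs <= 0) or np.any(freqs > nyq * (1 + 1e-9)):
        raise ValueError(f"frequencies must lie within (0, Nyquist={nyq:g}]")
    flat = x.reshape(-1, n)
    # even (whole-sample) extension [x, x reversed]: its periodic
    # continuation is the reflection extension with no discontinuity, so
    # the circular FFT convolution sees no artificial edges anywhere
    xp = np.concatenate([flat, flat[:, ::-1]], axis=-1)
    L = xp.shape[-1]
    s = _scales(freqs, omega0)
    omega = 2.0 * np.pi * np.fft.fftfreq(L, d=sampling_interval)
    kern = 2.0 * np.exp(-0.5 * (s[:, None] * omega[None, :] - omega0) ** 2)
    kern[:, omega <= 0] = 0.0
    out = np.empty((flat.shape[0], freqs.size, n), dtype=complex)
    # chunk the batch to bound the (chunk, n_freq, L) workspace
    chunk = max(1, int(max_chunk_elems // (freqs.size * L)))
    for i in range(0, flat.shape[0], chunk):
        X = fft(xp[i : i + chunk], axis=-1)
        W = ifft(X[:, None, :] * kern[None, :, :], axis=-1)
        out[i : i + chunk] = W[:, :, :n]
    return out.reshape(shape[:-1] + (freqs.size, n))


def morlet_cwt(
    signal: np.ndarray,
    sampling_interval: float,
    freqs: np.ndarray,
    omega0: float = DEFAULT_OMEGA0,
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous Morlet wavelet transform of a single time series.

    Returns ``(W, coi)`` where ``W`` has shape (n_freq, n_time) on the full
    input time grid and ``coi`` gives the per-frequency edge-exclusion width
    in seconds.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("morlet_cwt expects a single 1-D series")
    W = _cwt_batch(signal[None, :], sampling_interval, freqs, omega0)[0]
    return W, coi_width_seconds(np.asarray(freqs, dtype=float), omega0)


def _density_norm(freqs: np.ndarray, omega0: float) -> np.ndarray:
    """c(f) converting ⟨W W*⟩ into a one-sided spectral density."""
    return np.sqrt(np.pi) * omega0 / (2.0 * np.pi * np.asarray(freqs, dtype=float))


@dataclass(frozen=True)
class SpectralMatrixSeries:
    """Hermitian node×node spectral density on a time × frequency grid.

    ``S`` has shape (n_time, n_freq, n_nodes, n_nodes); ``coi_seconds`` is
    the per-frequency edge-exclusion width.  ``flags`` (n_time, n_freq) is
    True inside the cone of influence.
    """

    S: np.ndarray
    grid: TimeFreqGrid
    coi_seconds: np.ndarray
    n_realizations: int
    node_labels: tuple[str, ...] = ()

    @property
    def n_nodes(self) -> int:
        return self.S.shape[-1]

    @property
    def flags(self) -> np.ndarray:
        width = self.coi_seconds
        t = self.grid.times
        total = t[-1] - t[0]
        rel = t - t[0]
        return (rel[:, None] < width[None, :]) | (rel[:, None] > total - width[None, :])

    def time_averaged(self) -> np.ndarray:
        """COI-respecting time average, shape (n_freq, n_nodes, n_nodes).

        Frequencies whose COI swallows every time point fall back to the
        full-record average (flagged upstream by an all-True mask column).
        """
        ok = ~self.flags  # (nt, nf)
        w = ok.astype(float)
        cnt = w.sum(axis=0)
        bad = cnt == 0
        if np.any(bad):
            w[:, bad] = 1.0
            cnt[bad] = self.S.shape[0]
        return np.einsum("tf,tfij->fij", w, self.S) / cnt[:, None, None]


@dataclass(frozen=True)
class PowerMap:
    """Per-node spectral power, shape (n_nodes, n_time, n_freq)."""

    values: np.ndarray
    grid: TimeFreqGrid
    coi_seconds: np.ndarray
    node_labels: tuple[str, ...] = ()

    @property
    def flags(self) -> np.ndarray:
        width = self.coi_seconds
        t = self.grid.times
        rel = t - t[0]
        total = t[-1] - t[0]
        return (rel[:, None] < width[None, :]) | (rel[:, None] > total - width[None, :])


@dataclass(frozen=True)
class CoherenceMap:
    """Pairwise magnitude-squared coherence, (n_nodes, n_nodes, n_time, n_freq)."""

    values: np.ndarray
    grid: TimeFreqGrid
    coi_seconds: np.ndarray
    node_labels: tuple[str, ...] = ()


def spectral_matrix(
    ts: MultiTrialTimeSeries,
    freqs: np.ndarray | None = None,
    omega0: float = DEFAULT_OMEGA0,
) -> SpectralMatrixSeries:
    """Estimate S_lm(t, f) by averaging wavelet cross-products over
    realizations.

    With a single realization the estimate is rank one at every (t, f), so
    raw coherence is identically 1; a warning is logged in that case and at
    least two realizations are recommended for any cross-spectral use.
    """
    if freqs is None:
        freqs = default_freq_grid(ts.sampling_interval)
    freqs = np.asarray(freqs, dtype=float)
    if ts.n_realizations < 2:
        logger.warning(
            "spectral_matrix called with a single realization: cross-spectra "
            "are rank-1 and coherence is degenerate (==1)"
        )
    n_nodes, R, n_time = ts.values.shape
    S = np.zeros((n_time, freqs.size, n_nodes, n_nodes), dtype=complex)
    # accumulate over realization chunks to bound memory
    chunk = max(1, int(4_000_000 // (n_nodes * freqs.size * n_time)))
    for i in range(0, R, chunk):
        W = _cwt_batch(
            ts.values[:, i : i + chunk, :], ts.sampling_interval, freqs, omega0
        )  # (node, r, f, t)
        S += np.einsum("arft,brft->tfab", W, W.conj(), optimize=True)
    S /= R
    S *= _density_norm(freqs, omega0)[None, :, None, None]
    grid = TimeFreqGrid(
        times=ts.times, freqs=freqs, sampling_interval=ts.sampling_interval
    )
    return SpectralMatrixSeries(
        S=S,
        grid=grid,
        coi_seconds=coi_width_seconds(freqs, omega0),
        n_realizations=R,
        node_labels=ts.node_labels,
    )


def power(S: SpectralMatrixSeries) -> PowerMap:
    """Node power: the real diagonal of S(t, f).

    Numerically negative diagonal values are clipped at zero; the count of
    clipped cells is logged.
    """
    diag = np.einsum("tfii->itf", S.S)
    imag_max = np.abs(diag.imag).max() if diag.size else 0.0
    if imag_max > 1e-8 * max(np.abs(diag.real).max(), 1e-300):
        logger.warning("power: non-negligible imaginary diagonal (max %g)", imag_max)
    vals = diag.real.copy()
    n_clip = int((vals < 0).sum())
    if n_clip:
        logger.info("power: clipped %d negative cells at 0", n_clip)
        vals[vals < 0] = 0.0
    return PowerMap(
        values=vals,
        grid=S.grid,
        coi_seconds=S.coi_seconds,
        node_labels=S.node_labels,
    )


def coherence(S: SpectralMatrixSeries) -> CoherenceMap:
    """Magnitude-squared coherence C_lm = |S_lm|² / (S_ll S_mm) ∈ [0, 1].

    Cells where a diagonal power vanishes are undefined and returned as NaN
    (flagged, not silently zero).  Values are clipped into [0, 1]; the clip
    count is logged.
    """
    diag = np.einsum("tfii->tfi", S.S).real
    denom = diag[:, :, :, None] * diag[:, :, None, :]
    num = np.abs(S.S) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        C = num / denom
    undef = denom <= 0
    n_undef = int(undef.sum())
    if n_undef:
        logger.warning("coherence: %d cells undefined (zero power), set NaN", n_undef)
        C[undef] = np.nan
    over = C > 1
    n_clip = int(np.nansum(over) + np.nansum(C < 0))
    if n_clip:
        logger.info("coherence: clipped %d cells into [0, 1]", n_clip)
    C = np.clip(C, 0.0, 1.0)
    idx = np.arange(S.n_nodes)
    C[:, :, idx, idx] = np.where(np.isnan(C[:, :, idx, idx]), np.nan, 1.0)
    return CoherenceMap(
        values=np.ascontiguousarray(C.transpose(2, 3, 0, 1)),
        grid=S.grid,
        coi_seconds=S.coi_seconds,
        node_labels=S.node_labels,
    )
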