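"""Synthetic oscillatory networks with known directed spectral structure.

This module generates multichannel vector-autoregressive (VAR) time series
that emulate slow (< 0.25 Hz) BOLD-like network recordings: a handful of
nodes sampled every ``sampling_interval`` seconds, each carrying a damped
oscillatory resonance, with directed lagged coupling between nodes.  Because
the generative model is a VAR, the spectral density matrix, the transfer
function and the frequency-domain Granger causality all have closed forms,
which downstream estimators are validated against.

The default emulation scale mirrors a resting-state fMRI recording of a
4-node default-mode network: TR = 2 s, 237 samples, with multiple
realizations per node standing in for the voxel time series that are
averaged into one regional spectral estimate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "NetworkSpec",
    "MultiTrialTimeSeries",
    "AmplitudeSchedule",
    "make_default_network_spec",
    "simulate_var",
    "apply_amplitude_schedule",
    "analytic_var_spectrum",
    "analytic_var_gc",
    "synth_fiber_counts",
]

DEFAULT_SAMPLING_INTERVAL = 2.0
DEFAULT_N_TIME = 237
DEFAULT_N_REALIZATIONS = 20


def _companion(ar_coeffs: np.ndarray) -> np.ndarray:
    """Companion matrix of a VAR(p); stable iff all eigenvalues lie inside
    the unit circle (equivalently all characteristic roots outside it)."""
    p, n, _ = ar_coeffs.shape
    top = np.concatenate(list(ar_coeffs), axis=1)
    if p == 1:
        return top
    lower = np.eye(n * (p - 1), n * p)
    return np.vstack([top, lower])


@dataclass(frozen=True)
class NetworkSpec:
    """Ground-truth generative description of a coupled oscillator network.

    Parameters
    ----------
    ar_coeffs : ndarray, shape (n_lags, n_nodes, n_nodes)
        ``ar_coeffs[k-1, i, j]`` is the influence of node ``j`` at lag ``k``
        on node ``i`` (dimensionless).
    noise_cov : ndarray, shape (n_nodes, n_nodes)
        Symmetric positive-definite innovation covariance (signal units²).
    sampling_interval : float
        Seconds per sample (the TR for fMRI-like data).
    fiber_counts : ndarray or None
        Symmetric nonnegative integer matrix of anatomical tract counts with
        zero diagonal; the structural-connectivity ground truth.
    node_labels : tuple of str
    """

    ar_coeffs: np.ndarray
    noise_cov: np.ndarray
    sampling_interval: float = DEFAULT_SAMPLING_INTERVAL
    fiber_counts: np.ndarray | None = None
    node_labels: tuple[str, ...] = ()

    def __post_init__(self):
        A = np.asarray(self.ar_coeffs, dtype=float)
        if A.ndim != 3 or A.shape[1] != A.shape[2]:
            raise ValueError("ar_coeffs must have shape (n_lags, n, n)")
        object.__setattr__(self, "ar_coeffs", A)
        n = A.shape[1]
        C = np.asarray(self.noise_cov, dtype=float)
        if C.shape != (n, n):
            raise ValueError("noise_cov shape does not match node count")
        if not np.allclose(C, C.T, atol=1e-12):
            raise ValueError("noise_cov must be symmetric")
        if np.linalg.eigvalsh(C).min() <= 0:
            raise ValueError("noise_cov must be positive definite")
        object.__setattr__(self, "noise_cov", C)
        if self.fiber_counts is not None:
            F = np.asarray(self.fiber_counts)
            if F.shape != (n, n) or not np.array_equal(F, F.T):
                raise ValueError("fiber_counts must be a symmetric n×n matrix")
            if np.any(np.diag(F) != 0) or np.any(F < 0):
                raise ValueError("fiber_counts needs zero diagonal, nonnegative entries")
            object.__setattr__(self, "fiber_counts", F)
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if not self.node_labels:
            object.__setattr__(
                self, "node_labels", tuple(f"node{i}" for i in range(n))
            )
        elif len(self.node_labels) != n:
            raise ValueError("node_labels length must equal node count")
        # stability gate: largest companion eigenvalue < 1
        eig = np.linalg.eigvals(_companion(A))
        worst = eig[np.argmax(np.abs(eig))]
        if np.abs(worst) >= 1.0 - 1e-10:
            root = 1.0 / worst
            raise ValueError(
                "unstable AR polynomial: characteristic root "
                f"{root:.6g} has modulus {np.abs(root):.6g} <= 1"
            )

    @property
    def n_nodes(self) -> int:
        return self.ar_coeffs.shape[1]

    @property
    def n_lags(self) -> int:
        return self.ar_coeffs.shape[0]

    @property
    def nyquist(self) -> float:
        return 0.5 / self.sampling_interval

    @property
    def stability_margin(self) -> float:
        """1 minus the largest companion eigenvalue modulus (> 0 if stable)."""
        return 1.0 - np.abs(np.linalg.eigvals(_companion(self.ar_coeffs))).max()

    def coupling_magnitude(self) -> np.ndarray:
        """Symmetric pairwise coupling strength: sum over lags and both
        directions of |coefficient|, zero diagonal."""
        m = np.abs(self.ar_coeffs).sum(axis=0)
        c = m + m.T
        np.fill_diagonal(c, 0.0)
        return c

    def to_json(self) -> str:
        d = {
            "ar_coeffs": self.ar_coeffs.tolist(),
            "noise_cov": self.noise_cov.tolist(),
            "sampling_interval": self.sampling_interval,
            "fiber_counts": None
            if self.fiber_counts is None
            else self.fiber_counts.tolist(),
            "node_labels": list(self.node_labels),
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        d = json.loads(text)
        return cls(
            ar_coeffs=np.asarray(d["ar_coeffs"], dtype=float),
            noise_cov=np.asarray(d["noise_cov"], dtype=float),
            sampling_interval=float(d["sampling_interval"]),
            fiber_counts=None
            if d.get("fiber_counts") is None
            else np.asarray(d["fiber_counts"]),
            node_labels=tuple(d.get("node_labels", ())),
        )


@dataclass(frozen=True)
class MultiTrialTimeSeries:
    """Node × realization × time array with one shared sampling grid."""

    values: np.ndarray  # (n_nodes, n_realizations, n_time)
    sampling_interval: float
    node_labels: tuple[str, ...] = ()

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError("values must be (n_nodes, n_realizations, n_time)")
        if v.shape[1] < 1:
            raise ValueError("need at least one realization")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")
        object.__setattr__(self, "values", v)
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if not self.node_labels:
            object.__setattr__(
                self, "node_labels", tuple(f"node{i}" for i in range(v.shape[0]))
            )
        elif len(self.node_labels) != v.shape[0]:
            raise ValueError("node_labels length must equal node count")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_realizations(self) -> int:
        return self.values.shape[1]

    @property
    def n_time(self) -> int:
        return self.values.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Seconds from the first sample."""
        return np.arange(self.n_time) * self.sampling_interval

    def node_mean(self) -> np.ndarray:
        """Realization-averaged series, shape (n_nodes, n_time)."""
        return self.values.mean(axis=1)


@dataclass(frozen=True)
class AmplitudeSchedule:
    """Per-node time-varying gain applied to a band-limited signal component.

    ``gain[t]`` multiplies the component of the node's signal inside
    ``band`` (Hz); ``band=None`` scales the whole signal.  This is the
    device used to plant the kind of nonstationarity seen in resting-state
    recordings, e.g. slow-4 power that varies across time windows.
    """

    node: int
    gain: np.ndarray
    band: tuple[float, float] | None = None

    def __post_init__(self):
        object.__setattr__(self, "gain", np.asarray(self.gain, dtype=float))


def _oscillator_ar2(freq_hz: float, radius: float, dt: float) -> tuple[float, float]:
    """AR(2) coefficients (a1, a2) with a spectral resonance near freq_hz."""
    theta = 2.0 * np.pi * freq_hz * dt
    return 2.0 * radius * np.cos(theta), -radius * radius


def make_default_network_spec(seed: int = 0) -> NetworkSpec:
    """Default 4-node network emulating a PCC-seeded default-mode design.

    Each node is a damped AR(2) oscillator with its resonance inside the
    0.01–0.25 Hz range (three nodes in slow-4, one in slow-3), coupled by a
    unidirectional chain of lag-1 and lag-2 coefficients.  The seed jitters
    oscillation frequencies (±10%) and coupling gains (±20%) so repeated
    draws emulate participant variability; the same seed always returns the
    identical spec.  Fiber counts are assigned monotone in |coupling|.
    """
    rng = np.random.default_rng(seed)
    dt = DEFAULT_SAMPLING_INTERVAL
    labels = ("PCC", "mPFC", "LMTC", "LAG")
    base_freqs = np.array([0.045, 0.055, 0.110, 0.060])  # Hz
    radii = np.array([0.85, 0.80, 0.80, 0.75])
    freqs = base_freqs * rng.uniform(0.9, 1.1, size=4)
    # unidirectional chain PCC -> mPFC -> LMTC plus PCC -> LAG
    couplings = {
        (1, 0): 0.35 * rng.uniform(0.8, 1.2),  # lag 1
        (2, 1): 0.30 * rng.uniform(0.8, 1.2),  # lag 1
        (3, 0): 0.20 * rng.uniform(0.8, 1.2),  # lag 2
    }
    A = np.zeros((2, 4, 4))
    for i in range(4):
        a1, a2 = _oscillator_ar2(freqs[i], radii[i], dt)
        A[0, i, i] = a1
        A[1, i, i] = a2
    A[0, 1, 0] = couplings[(1, 0)]
    A[0, 2, 1] = couplings[(2, 1)]
    A[1, 3, 0] = couplings[(3, 0)]
    spec = NetworkSpec(
        ar_coeffs=A,
        noise_cov=np.eye(4),
        sampling_interval=dt,
        node_labels=labels,
    )
    fibers = synth_fiber_counts(spec, noise_sd=0, seed=seed)
    return replace(spec, fiber_counts=fibers)


def simulate_var(
    spec: NetworkSpec,
    n_time: int = DEFAULT_N_TIME,
    n_realizations: int = DEFAULT_N_REALIZATIONS,
    seed: int = 0,
) -> MultiTrialTimeSeries:
    """Simulate independent realizations of the VAR defined by ``spec``.

    A burn-in of ``100 × n_lags`` samples is discarded so the retained
    segment is (for a stable spec without amplitude schedule) a draw from
    the stationary distribution.  Each realization uses an independent
    random sub-stream spawned from ``seed``.
    """
    p = spec.n_lags
    n = spec.n_nodes
    if n_time < 2 * p:
        raise ValueError("n_time must be at least twice the maximum lag")
    burn = 100 * p
    total = n_time + burn
    L = np.linalg.cholesky(spec.noise_cov)
    children = np.random.SeedSequence(seed).spawn(n_realizations)
    eps = np.empty((n_realizations, total, n))
    for r, child in enumerate(children):
        g = np.random.default_rng(child)
        eps[r] = g.standard_normal((total, n)) @ L.T
    x = np.zeros((n_realizations, total, n))
    A = spec.ar_coeffs
    for t in range(total):
        acc = eps[:, t, :].copy()
        for k in range(1, min(p, t) + 1):
            acc += x[:, t - k, :] @ A[k - 1].T
        x[:, t, :] = acc
    out = x[:, burn:, :]  # (real, time, node)
    return MultiTrialTimeSeries(
        values=np.ascontiguousarray(out.transpose(2, 0, 1)),
        sampling_interval=spec.sampling_interval,
        node_labels=spec.node_labels,
    )


def _bandlimit(x: np.ndarray, dt: float, band: tuple[float, float]) -> np.ndarray:
    """Zero-phase brick-wall band-pass of the last axis via rFFT masking."""
    n = x.shape[-1]
    X = np.fft.rfft(x, axis=-1)
    f = np.fft.rfftfreq(n, d=dt)
    mask = (f >= band[0]) & (f <= band[1])
    return np.fft.irfft(X * mask, n=n, axis=-1)


def apply_amplitude_schedule(
    ts: MultiTrialTimeSeries,
    schedule: AmplitudeSchedule | list[AmplitudeSchedule],
) -> MultiTrialTimeSeries:
    """Multiply the scheduled nodes' (band-limited) component by the gain.

    For a banded schedule the node signal is split into in-band and
    out-of-band parts by a zero-phase brick-wall filter; only the in-band
    part is scaled, then the parts are summed back.  Other nodes are
    untouched.
    """
    schedules = schedule if isinstance(schedule, list) else [schedule]
    v = ts.values.copy()
    for sch in schedules:
        if sch.gain.shape != (ts.n_time,):
            raise ValueError(
                f"schedule gain length {sch.gain.shape} does not match "
                f"n_time={ts.n_time}"
            )
        node = sch.node
        if sch.band is None:
            v[node] = v[node] * sch.gain[None, :]
        else:
            comp = _bandlimit(v[node], ts.sampling_interval, sch.band)
            v[node] = v[node] - comp + comp * sch.gain[None, :]
    return MultiTrialTimeSeries(
        values=v,
        sampling_interval=ts.sampling_interval,
        node_labels=ts.node_labels,
    )


def var_transfer_function(spec: NetworkSpec, freqs: np.ndarray) -> np.ndarray:
    """T(f) = (I − Σ_k A_k e^{-2πi f k dt})^{-1}, shape (n_freq, n, n)."""
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    dt = spec.sampling_interval
    n = spec.n_nodes
    z = np.exp(-2j * np.pi * freqs[:, None] * dt * np.arange(1, spec.n_lags + 1))
    Af = np.tensordot(z, spec.ar_coeffs, axes=(1, 0))  # (n_freq, n, n)
    return np.linalg.inv(np.eye(n)[None] - Af)


def analytic_var_spectrum(spec: NetworkSpec, freqs: np.ndarray) -> np.ndarray:
    """One-sided spectral density matrix S(f) = 2·dt·T(f) Σ T(f)*.

    With this convention the integral of the diagonal over (0, Nyquist]
    equals the stationary process variance per node.  Returns shape
    (n_freq, n, n), Hermitian positive semidefinite at every frequency.
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if np.any(freqs < 0) or np.any(freqs > spec.nyquist + 1e-12):
        raise ValueError("frequencies must lie within [0, Nyquist]")
    T = var_transfer_function(spec, freqs)
    S = 2.0 * spec.sampling_interval * np.einsum(
        "fij,jk,flk->fil", T, spec.noise_cov, T.conj()
    )
    return S


def analytic_var_gc(
    spec: NetworkSpec,
    pair: tuple[int, int],
    freqs: np.ndarray,
) -> np.ndarray:
    """Closed-form Geweke frequency-domain causality for ``pair = (l, m)``,
    the influence of node l on node m, evaluated at ``freqs``.

    For a 2-node spec the VAR transfer function is itself the minimum-phase
    factor, so Eq.-style GC is evaluated directly from T(f) and Σ.  For a
    pair embedded in a larger network the exact 2×2 marginal spectrum is
    factorized numerically (the marginal of a VAR is not a finite-order
    VAR, so no closed form exists).
    """
    l, m = pair
    n = spec.n_nodes
    if not (0 <= l < n and 0 <= m < n) or l == m:
        raise ValueError("pair must be two distinct node indices in range")
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if n == 2:
        T = var_transfer_function(spec, freqs)
        Sig = spec.noise_cov
        S = np.einsum("fij,jk,flk->fil", T, Sig, T.conj())
        Smm = S[:, m, m].real
        sig_cond = Sig[l, l] - Sig[l, m] ** 2 / Sig[m, m]
        den = Smm - sig_cond * np.abs(T[:, m, l]) ** 2
        den = np.maximum(den, np.finfo(float).tiny)
        return np.maximum(np.log(Smm / den), 0.0)
    # embedded pair: factorize the exact bivariate marginal spectrum
    from .causal_flow import _gc_from_uniform_spectra

    return _gc_from_uniform_spectra(spec, (l, m), freqs)


def synth_fiber_counts(
    spec: NetworkSpec, noise_sd: int = 0, seed: int = 0
) -> np.ndarray:
    """Synthetic symmetric tract-count matrix, monotone in coupling strength.

    counts = round(base + gain·|coupling|) plus (for ``noise_sd > 0``)
    integer jitter formed as the difference of two Poisson(noise_sd) draws,
    clipped at zero.  Defaults: base = 5, gain = 120.
    """
    base, gain = 5.0, 120.0
    c = spec.coupling_magnitude()
    counts = np.round(base + gain * c)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        jitter = rng.poisson(noise_sd, size=c.shape) - rng.poisson(
            noise_sd, size=c.shape
        )
        jitter = np.triu(jitter, 1)
        counts = counts + jitter + jitter.T
    counts = np.clip(counts, 0, None).astype(int)
    np.fill_diagonal(counts, 0)
    return counts


def yule_walker_autocov(spec: NetworkSpec, max_lag: int) -> np.ndarray:
    """Stationary autocovariance Γ_0..Γ_max_lag of the VAR via the companion
    discrete Lyapunov equation; shape (max_lag+1, n, n)."""
    from scipy.linalg import solve_discrete_lyapunov

    p, n = spec.n_lags, spec.n_nodes
    comp = _companion(spec.ar_coeffs)
    Q = np.zeros((n * p, n * p))
    Q[:n, :n] = spec.noise_cov
    big = solve_discrete_lyapunov(comp, Q)
    gams = [big[:n, k * n : (k + 1) * n] for k in range(p)]  # Γ_0..Γ_{p-1}
    A = spec.ar_coeffs
    while len(gams) <= max_lag:
        k = len(gams)
        gams.append(sum(A[j - 1] @ gams[k - j] for j in range(1, p + 1)))
    return np.array(gams[: max_lag + 1])
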