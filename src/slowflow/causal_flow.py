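"""Spectral matrix factorization and time-frequency Granger causality.

Directed influence between nodes is obtained nonparametrically from the
spectral density matrix: each time slice S(t, ·) is factorized into a
minimum-phase transfer function H and an innovation covariance Σ by
Wilson's iterative algorithm,

    S(f) = H(f) Σ H(f)*,

and the Geweke frequency-domain causality from node l to node m is

    I_{l→m}(f) = ln [ S_mm / ( S_mm − (Σ_ll − Σ_lm²/Σ_mm) |H_ml|² ) ] ≥ 0.

Summing directed causalities gives the net causal in-out flow of node m,

    F_m(t, f) = Σ_l ( I_{l→m} − I_{m→l} ),   I_{m→m} ≡ 0,

positive where the node is a net sink and negative where it is a net
source; the flows of all nodes cancel exactly at every (t, f).

Causality is computed pairwise (2×2 factorization per node pair), matching
the bivariate causality formula and the pairwise sum in the net flow.

Wilson's algorithm needs the spectrum on a uniform frequency grid covering
[0, Nyquist]; wavelet-grid spectra are linearly interpolated onto that grid
with boundary replication at the ends.  The factor's causal Fourier
coefficients are then used to evaluate H exactly back on the wavelet
frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import fft, ifft

from .synthetic_data import MultiTrialTimeSeries
from .wavelet_spectra import (
    DEFAULT_OMEGA0,
    SpectralMatrixSeries,
    TimeFreqGrid,
    _cwt_batch,
    _density_norm,
    coi_mask,
    default_freq_grid,
)

__all__ = [
    "FactorizationResult",
    "PairwiseGC",
    "CausalityTensor",
    "wilson_factorize",
    "pairwise_gc",
    "net_flow",
    "compute_causality",
    "gc_null_threshold",
]

logger = logging.getLogger(__name__)

DEFAULT_TOL = 1e-7
DEFAULT_MAX_ITER = 100
DEFAULT_N_FACT = 65  # uniform factorization grid points on [0, Nyquist]
PSD_FLOOR_REL = 1e-10


# ---------------------------------------------------------------------------
# batched linear algebra helpers (small matrices)


def _hermitize(S: np.ndarray) -> np.ndarray:
    return 0.5 * (S + np.conj(np.swapaxes(S, -1, -2)))


def _psd_floor(S: np.ndarray, rel: float = PSD_FLOOR_REL) -> tuple[np.ndarray, int]:
    """Raise each matrix's spectrum so the minimum eigenvalue is at least
    ``rel`` times the largest eigenvalue found in its frequency slice.

    Returns the repaired array and the number of floored matrices.
    """
    S = _hermitize(np.asarray(S, dtype=complex))
    if S.shape[-1] == 2:
        tr = (S[..., 0, 0] + S[..., 1, 1]).real
        det = (
            S[..., 0, 0] * S[..., 1, 1] - S[..., 0, 1] * S[..., 1, 0]
        ).real
        disc = np.sqrt(np.maximum(tr * tr - 4.0 * det, 0.0))
        emin = 0.5 * (tr - disc)
        emax = 0.5 * (tr + disc)
    else:
        ev = np.linalg.eigvalsh(S)
        emin = ev[..., 0]
        emax = ev[..., -1]
    # reference scale: largest eigenvalue across the frequency axis (-3)
    ref = np.max(emax, axis=-1, keepdims=True)
    ref = np.maximum(ref, np.finfo(float).tiny)
    floor = rel * ref
    lift = np.maximum(floor - emin, 0.0)
    n_floored = int((lift > 0).sum())
    if n_floored:
        n = S.shape[-1]
        S = S + lift[..., None, None] * np.eye(n)
    return S, n_floored


# ---------------------------------------------------------------------------
# Wilson's algorithm


def _mm(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Matrix product with matrix axes leading: (n,n,...) @ (n,n,...)."""
    return np.einsum("ab...,bc...->ac...", X, Y)


def _hermT(X: np.ndarray) -> np.ndarray:
    return np.conj(np.swapaxes(X, 0, 1))


def _inv_lead(M: np.ndarray) -> np.ndarray:
    """Inverse with matrix axes leading; closed form for 2×2."""
    if M.shape[0] == 2:
        det = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
        out = np.empty_like(M)
        out[0, 0] = M[1, 1]
        out[0, 1] = -M[0, 1]
        out[1, 0] = -M[1, 0]
        out[1, 1] = M[0, 0]
        return out / det
    Mi = np.linalg.inv(np.moveaxis(M, (0, 1), (-2, -1)))
    return np.moveaxis(Mi, (-2, -1), (0, 1))


def _wilson_batch(
    S: np.ndarray,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    check_every: int = 3,
):
    """Wilson minimum-phase factorization of batched spectra.

    Parameters
    ----------
    S : ndarray, shape (..., nf, n, n)
        Hermitian PSD spectral matrices sampled on a *uniform* grid of
        ``nf`` frequencies from 0 to Nyquist inclusive.

    Returns
    -------
    psi : ndarray (n, n, ..., 2(nf-1))
        Minimum-phase factor on the full frequency circle (matrix axes
        leading, frequency last), ψψ* = S.
    A0 : ndarray (n, n, ...)
        Zero-lag causal coefficient of ψ; Σ = A0 A0*.
    residual : ndarray (...)
        Relative Frobenius reconstruction error, max over frequencies.
    n_iter : int
    converged : ndarray of bool (...)
    trajectory : list of float
        Max residual across the batch at each convergence check.
    """
    S = np.asarray(S, dtype=complex)
    nf = S.shape[-3]
    n = S.shape[-1]
    m = nf - 1
    if m < 2:
        raise ValueError("need at least 3 frequency points (0..Nyquist)")
    nfull = 2 * m
    # matrix axes leading, frequency last: (n, n, ..., nf)
    Sw = np.moveaxis(S, (-2, -1), (0, 1))
    # a real process has real spectral matrices at the self-conjugate points
    # f = 0 and f = Nyquist of the frequency circle; enforce before extension
    Sw = Sw.copy()
    Sw[..., 0] = Sw[..., 0].real
    Sw[..., m] = Sw[..., m].real
    # Hermitian extension to the full circle: S(-f) = S(f)^conj
    Sfull = np.concatenate([Sw, np.conj(Sw[..., m - 1 : 0 : -1])], axis=-1)
    Snorm = np.sqrt(np.sum(np.abs(Sfull) ** 2, axis=(0, 1)))  # (..., nfull)
    Snorm = np.maximum(Snorm, np.finfo(float).tiny)

    # initialize with the Cholesky factor of the frequency-averaged spectrum
    M0 = np.moveaxis(Sfull.mean(axis=-1).real, (0, 1), (-2, -1))
    jitter = 0.0
    eye = np.eye(n)
    while True:
        try:
            L0 = np.linalg.cholesky(M0 + jitter * eye)
            break
        except np.linalg.LinAlgError:
            scale = np.max(np.abs(M0))
            jitter = max(2 * jitter, 1e-12 * max(scale, 1e-300))
    psi = np.broadcast_to(
        np.moveaxis(L0, (-2, -1), (0, 1))[..., None].astype(complex), Sfull.shape
    ).copy()
    eye_lead = eye.reshape((n, n) + (1,) * (Sfull.ndim - 2))

    def residuals(psi):
        R = _mm(psi, _hermT(psi)) - Sfull
        err = np.sqrt(np.sum(np.abs(R) ** 2, axis=(0, 1))) / Snorm
        return err.max(axis=-1)  # max over frequencies

    trajectory: list[float] = []
    n_iter = 0
    converged = np.zeros(Sfull.shape[2:-1], dtype=bool)
    for it in range(1, max_iter + 1):
        n_iter = it
        ipsi = _inv_lead(psi)
        g = _mm(_mm(ipsi, Sfull), _hermT(ipsi))
        g += eye_lead
        # causal ("plus") projection along the frequency circle
        gam = ifft(g, axis=-1)
        gam[..., 0] *= 0.5
        gam[..., m] *= 0.5
        gam[..., m + 1 :] = 0.0
        gp = fft(gam, axis=-1)
        psi = _mm(psi, gp)
        if it % check_every == 0 or it == max_iter:
            res = residuals(psi)
            trajectory.append(float(res.max()))
            converged = res <= tol
            if converged.all():
                break
    res = residuals(psi)
    converged = res <= tol
    # zero-lag causal coefficient
    A0 = ifft(psi, axis=-1)[..., 0]
    return psi, A0, res, n_iter, converged, trajectory


def _eval_psi(psi: np.ndarray, freqs: np.ndarray, sampling_interval: float,
              refine: int = 4) -> np.ndarray:
    """Evaluate the minimum-phase factor at arbitrary frequencies.

    ψ (matrix axes leading, frequency circle last) is a causal
    trigonometric polynomial; zero-padding its Fourier coefficients
    evaluates it exactly on a ``refine``-times finer uniform circle, from
    which values at the requested frequencies are linearly interpolated.
    Returns shape ``psi.shape[:-1] + (freqs.size,)``.
    """
    nfull = psi.shape[-1]
    coeffs = ifft(psi, axis=-1)
    nfine = refine * nfull
    pad_shape = list(coeffs.shape)
    pad_shape[-1] = nfine
    cpad = np.zeros(pad_shape, dtype=complex)
    cpad[..., :nfull] = coeffs
    psi_fine = fft(cpad, axis=-1)
    # uniform fine grid from 0 to Nyquist: f_j = j / (nfine * dt)
    f_fine = np.arange(nfine // 2 + 1) / (nfine * sampling_interval)
    half = psi_fine[..., : nfine // 2 + 1]
    idx = np.clip(np.searchsorted(f_fine, freqs) - 1, 0, f_fine.size - 2)
    w = (freqs - f_fine[idx]) / (f_fine[idx + 1] - f_fine[idx])
    w = np.clip(w, 0.0, 1.0)
    return half[..., idx] * (1 - w) + half[..., idx + 1] * w


@dataclass
class FactorizationResult:
    """Outcome of Wilson factorization of one spectral matrix slice."""

    H: np.ndarray  # (nf, n, n) minimum-phase transfer function, H(0) lag-0 = I
    Sigma: np.ndarray  # (n, n) real symmetric, S = H Σ H*
    n_iter: int
    residual: float  # max over frequencies of relative Frobenius error
    converged: bool
    residual_trajectory: list = field(default_factory=list)
    n_floored: int = 0


def wilson_factorize(
    S_slice: np.ndarray,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> FactorizationResult:
    """Factorize S(f) (uniform grid 0..Nyquist, shape (nf, n, n)) into a
    minimum-phase transfer function and noise covariance.

    The returned ``Sigma`` carries the same overall scale as ``S`` (for a
    one-sided density 2·dt·TΣT* of a VAR it equals 2·dt·Σ_innovation);
    Granger-causality ratios are invariant to that scale.  Non-convergence
    is reported in the result object (``converged=False``) together with
    the residual trajectory; singular input spectra are repaired by
    eigenvalue flooring, with the floored count reported.
    """
    S_slice = np.asarray(S_slice, dtype=complex)
    if S_slice.ndim != 3 or S_slice.shape[-1] != S_slice.shape[-2]:
        raise ValueError("S_slice must have shape (nf, n, n)")
    Sf, n_floored = _psd_floor(S_slice)
    if n_floored:
        logger.info("wilson_factorize: floored %d spectral matrices", n_floored)
    psi, A0, res, n_iter, conv, traj = _wilson_batch(Sf, tol, max_iter)
    nf = S_slice.shape[0]
    # psi: (n, n, nfull); A0: (n, n)
    A0inv = _inv_lead(A0)
    H = np.moveaxis(_mm(psi[..., :nf], A0inv[..., None]), (0, 1), (-2, -1))
    Sigma = (A0 @ np.conj(A0.T)).real
    Sigma = 0.5 * (Sigma + Sigma.T)
    return FactorizationResult(
        H=H,
        Sigma=Sigma,
        n_iter=n_iter,
        residual=float(res),
        converged=bool(conv),
        residual_trajectory=traj,
        n_floored=n_floored,
    )


# ---------------------------------------------------------------------------
# pairwise Granger causality


def _interp_to_uniform(
    S_pair: np.ndarray, freqs: np.ndarray, nyquist: float, n_fact: int
) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate (..., nf_wav, n, n) spectra onto a uniform grid
    of ``n_fact`` points spanning [0, Nyquist]; ends replicate boundary
    values (clamped interpolation)."""
    fu = np.linspace(0.0, nyquist, n_fact)
    idx = np.clip(np.searchsorted(freqs, fu) - 1, 0, freqs.size - 2)
    w = (fu - freqs[idx]) / (freqs[idx + 1] - freqs[idx])
    w = np.clip(w, 0.0, 1.0)[:, None, None]
    Su = S_pair[..., idx, :, :] * (1 - w) + S_pair[..., idx + 1, :, :] * w
    return Su, fu


def _gc_bivariate(
    Smm_wav: np.ndarray,
    H_at_wav: np.ndarray,
    Sigma: np.ndarray,
    direction: tuple[int, int],
) -> tuple[np.ndarray, int]:
    """Geweke causality along ``direction=(l, m)`` given the factorization.

    ``Smm_wav``: (..., nf) real target-node auto-spectrum at the output
    frequencies; ``H_at_wav``: (2, 2, ..., nf) with matrix axes leading;
    ``Sigma``: (2, 2, ...).  Returns the clipped nonnegative causality and
    the clip count.
    """
    l, m = direction
    sig_ll = Sigma[l, l].real
    sig_lm = Sigma[l, m].real
    sig_mm = Sigma[m, m].real
    sig_cond = sig_ll - sig_lm**2 / sig_mm
    Hml2 = np.abs(H_at_wav[m, l]) ** 2
    den = Smm_wav - sig_cond[..., None] * Hml2
    tiny = np.finfo(float).tiny
    den = np.maximum(den, 1e-300)
    Smm_safe = np.maximum(Smm_wav, tiny)
    I = np.log(Smm_safe / den)
    n_clip = int((I < 0).sum())
    return np.maximum(I, 0.0), n_clip


def _gc_pair_batch(
    S_pair: np.ndarray,
    freqs: np.ndarray,
    sampling_interval: float,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    n_fact: int = DEFAULT_N_FACT,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Both directed causality spectra for batched 2×2 wavelet spectra.

    ``S_pair``: (..., nf_wav, 2, 2) Hermitian spectra on the (possibly
    log-spaced) wavelet grid ``freqs``.  Returns ``(I_01, I_10, meta)`` with
    shapes (..., nf_wav): I_01 is the causality node0 → node1 of the pair.
    Slices whose factorization fails are returned as NaN and counted.
    """
    S_pair = np.asarray(S_pair, dtype=complex)
    squeeze = S_pair.ndim == 3
    if squeeze:
        S_pair = S_pair[None]
    nyq = 0.5 / sampling_interval
    Su, fu = _interp_to_uniform(S_pair, freqs, nyq, n_fact)
    Su, n_floored = _psd_floor(Su)
    psi, A0, res, n_iter, conv, traj = _wilson_batch(Su, tol, max_iter)
    A0inv = _inv_lead(A0)
    psi_wav = _eval_psi(psi, np.asarray(freqs, dtype=float), sampling_interval)
    H_wav = _mm(psi_wav, A0inv[..., None])  # (2, 2, ..., nf)
    Sigma = _mm(A0, _hermT(A0)).real
    S00 = S_pair[..., 0, 0].real
    S11 = S_pair[..., 1, 1].real
    I01, c1 = _gc_bivariate(S11, H_wav, Sigma, (0, 1))
    I10, c2 = _gc_bivariate(S00, H_wav, Sigma, (1, 0))
    bad = ~conv
    n_failed = int(bad.sum())
    if n_failed:
        logger.warning(
            "pairwise_gc: %d slices failed to converge (max residual %.3g); "
            "flagged as missing",
            n_failed,
            float(res.max()),
        )
        I01 = I01.copy()
        I10 = I10.copy()
        I01[bad] = np.nan
        I10[bad] = np.nan
    meta = {
        "n_iter": n_iter,
        "max_residual": float(res.max()),
        "n_failed_slices": n_failed,
        "n_floored": n_floored,
        "n_clipped": c1 + c2,
        "residual_trajectory": traj,
        "tol": tol,
        "max_iter": max_iter,
        "n_fact": n_fact,
    }
    if squeeze:
        I01, I10 = I01[0], I10[0]
    return I01, I10, meta


@dataclass
class PairwiseGC:
    """Directed causality spectra for one node pair.

    ``I_ab``/``I_ba`` have shape (n_time, n_freq), or (n_freq,) when the
    spectral matrix was averaged over time first.
    """

    pair: tuple[int, int]
    I_ab: np.ndarray
    I_ba: np.ndarray
    grid: TimeFreqGrid
    meta: dict


def pairwise_gc(
    S: SpectralMatrixSeries,
    pair: tuple[int, int],
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    average_time: bool = False,
    n_fact: int = DEFAULT_N_FACT,
) -> PairwiseGC:
    """Time-frequency Granger causality between two nodes, both directions.

    Every time slice of the 2×2 sub-spectral-matrix is factorized
    independently; with ``average_time=True`` the COI-respecting
    time-averaged spectrum is factorized once instead (the stationary
    analysis).  Degenerate slices (e.g. duplicated channels) fail the
    residual tolerance and come back flagged as NaN rather than zero.
    """
    a, b = pair
    if a == b:
        raise ValueError("pair must consist of two distinct nodes")
    sub = S.S[..., [a, b], :][..., [a, b]]
    if average_time:
        ok = ~S.flags
        w = ok.astype(float)
        cnt = np.maximum(w.sum(axis=0), 1.0)
        sub = np.einsum("tf,tfij->fij", w, sub) / cnt[:, None, None]
    I_ab, I_ba, meta = _gc_pair_batch(
        sub, S.grid.freqs, S.grid.sampling_interval, tol, max_iter, n_fact
    )
    return PairwiseGC(pair=(a, b), I_ab=I_ab, I_ba=I_ba, grid=S.grid, meta=meta)


@dataclass
class CausalityTensor:
    """All ordered-pair causalities and the per-node net in-out flow.

    ``I`` maps ordered pairs (l, m) to arrays I_{l→m}; ``F`` has shape
    (n_nodes, ...) where positive values mark net sinks and negative values
    net sources.
    """

    I: dict
    F: np.ndarray
    grid: TimeFreqGrid
    node_labels: tuple[str, ...]
    meta: dict


def net_flow(I: dict, n_nodes: int | None = None) -> np.ndarray:
    """Net causal in-out flow F_m = Σ_l (I_{l→m} − I_{m→l}).

    ``I`` must contain every ordered pair of distinct nodes.  The flows sum
    to zero across nodes at every (t, f) by construction.
    """
    if n_nodes is None:
        n_nodes = len({i for p in I for i in p})
    missing = [
        (l, m)
        for l in range(n_nodes)
        for m in range(n_nodes)
        if l != m and (l, m) not in I
    ]
    if missing:
        raise ValueError(f"missing ordered pairs in causality set: {missing}")
    shape = next(iter(I.values())).shape
    F = np.zeros((n_nodes,) + shape)
    for (l, m), val in I.items():
        F[m] += val
        F[l] -= val
    return F


def compute_causality(
    S: SpectralMatrixSeries,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    average_time: bool = False,
    n_fact: int = DEFAULT_N_FACT,
) -> CausalityTensor:
    """Pairwise causality for all node pairs plus the net flow.

    All pairs (and all time slices) are factorized in one batched Wilson
    call.
    """
    n = S.n_nodes
    pairs = [(a, b) for a in range(n) for b in range(a + 1, n)]
    sub = np.stack([S.S[..., [a, b], :][..., [a, b]] for a, b in pairs])
    if average_time:
        ok = ~S.flags
        w = ok.astype(float)
        cnt = np.maximum(w.sum(axis=0), 1.0)
        sub = np.einsum("tf,ptfij->pfij", w, sub) / cnt[None, :, None, None]
    I_ab, I_ba, meta = _gc_pair_batch(
        sub, S.grid.freqs, S.grid.sampling_interval, tol, max_iter, n_fact
    )
    I = {}
    for k, (a, b) in enumerate(pairs):
        I[(a, b)] = I_ab[k]
        I[(b, a)] = I_ba[k]
    F = net_flow(I, n)
    return CausalityTensor(
        I=I, F=F, grid=S.grid, node_labels=S.node_labels, meta=meta
    )


# ---------------------------------------------------------------------------
# permutation null


def gc_null_threshold(
    ts: MultiTrialTimeSeries,
    n_perm: int = 200,
    quantile: float = 0.95,
    seed: int = 0,
    freqs: np.ndarray | None = None,
    pair: tuple[int, int] = (0, 1),
    omega0: float = DEFAULT_OMEGA0,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    n_fact: int = DEFAULT_N_FACT,
    neighborhood: int = 1,
) -> np.ndarray:
    """Per-frequency significance threshold for time-averaged pairwise GC.

    Surrogates permute the pairing of realizations across the two nodes,
    destroying cross-dependence while preserving each node's marginal
    statistics.  Time-averaged surrogate cross-spectra are assembled from a
    per-frequency realization Gram matrix, so each permutation costs one
    2×2 factorization.

    The surrogate statistic for a frequency cell is the maximum causality
    over the directed-pair family tested at that cell: both directions and
    the ``neighborhood`` adjacent grid voices (adjacent log-grid voices
    share most of their passband, so they constitute one effective test).
    Returns the empirical ``quantile`` of that statistic per wavelet
    frequency.
    """
    if ts.n_realizations < 2:
        raise ValueError("need at least 2 realizations to permute pairings")
    if n_perm < 100 and quantile >= 0.95:
        logger.warning(
            "gc_null_threshold: n_perm=%d is small for quantile %.2f",
            n_perm,
            quantile,
        )
    if freqs is None:
        freqs = default_freq_grid(ts.sampling_interval)
    freqs = np.asarray(freqs, dtype=float)
    a, b = pair
    dt = ts.sampling_interval
    R = ts.n_realizations
    nt = ts.n_time
    ok = ~coi_mask(nt, dt, freqs, omega0)  # (nt, nf)
    cnt = np.maximum(ok.sum(axis=0), 1)
    wmask = ok.astype(float)
    norm = _density_norm(freqs, omega0)

    # Gram matrices over realizations, time-averaged outside the COI
    G = np.zeros((freqs.size, R, R), dtype=complex)
    Saa = np.zeros(freqs.size)
    Sbb = np.zeros(freqs.size)
    chunk = max(1, int(4_000_000 // (freqs.size * nt)))
    Wa = np.empty((R, freqs.size, nt), dtype=complex)
    Wb = np.empty((R, freqs.size, nt), dtype=complex)
    for i in range(0, R, chunk):
        Wa[i : i + chunk] = _cwt_batch(ts.values[a, i : i + chunk], dt, freqs, omega0)
        Wb[i : i + chunk] = _cwt_batch(ts.values[b, i : i + chunk], dt, freqs, omega0)
    for fi in range(freqs.size):
        Wat = Wa[:, fi, :] * wmask[:, fi][None, :]
        G[fi] = (Wat @ np.conj(Wb[:, fi, :].T)) / cnt[fi]
    Saa = (
        np.einsum("rft,tf->f", np.abs(Wa) ** 2, wmask) / (R * cnt) * norm
    )
    Sbb = (
        np.einsum("rft,tf->f", np.abs(Wb) ** 2, wmask) / (R * cnt) * norm
    )
    G *= norm[:, None, None] / R

    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(R) for _ in range(n_perm)])
    ar = np.arange(R)
    # surrogate cross-spectra: mean over r of G[f, r, perm[r]]
    Sab = np.stack([G[:, ar, p].sum(axis=1) for p in perms])  # (n_perm, nf)
    Sp = np.empty((n_perm, freqs.size, 2, 2), dtype=complex)
    Sp[..., 0, 0] = Saa[None, :]
    Sp[..., 1, 1] = Sbb[None, :]
    Sp[..., 0, 1] = Sab
    Sp[..., 1, 0] = np.conj(Sab)
    I01, I10, _ = _gc_pair_batch(Sp, freqs, dt, tol, max_iter, n_fact)
    # per-permutation family maximum: both directions, adjacent voices
    stat = np.fmax(I01, I10)  # (n_perm, nf)
    if neighborhood > 0:
        from scipy.ndimage import maximum_filter1d

        stat = maximum_filter1d(
            stat, size=2 * neighborhood + 1, axis=1, mode="nearest"
        )
    return np.nanquantile(stat, quantile, axis=0)


# ---------------------------------------------------------------------------
# analytic oracle support (embedded pairs)


def _gc_from_uniform_spectra(spec, pair, freqs) -> np.ndarray:
    """Causality for a pair embedded in a larger network, from factorizing
    the exact 2×2 marginal of the analytic spectrum on a dense uniform
    grid.  Used by :func:`slowflow.synthetic_data.analytic_var_gc`."""
    from .synthetic_data import analytic_var_spectrum

    l, m = pair
    n_fact = 257
    fu = np.linspace(0.0, spec.nyquist, n_fact)
    Sfull = analytic_var_spectrum(spec, fu)
    Su = Sfull[:, [l, m], :][:, :, [l, m]]
    Su, _ = _psd_floor(Su)
    psi, A0, res, n_iter, conv, _ = _wilson_batch(Su, tol=1e-9, max_iter=200)
    A0inv = _inv_lead(A0)
    psi_f = _eval_psi(psi, np.asarray(freqs, dtype=float), spec.sampling_interval)
    H = _mm(psi_f, A0inv[..., None])
    Sigma = _mm(A0, _hermT(A0)).real
    S_eval = analytic_var_spectrum(spec, np.asarray(freqs, dtype=float))
    Smm = S_eval[:, m, m].real
    I_lm, _ = _gc_bivariate(Smm, H, Sigma, (0, 1))
    return I_lm
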