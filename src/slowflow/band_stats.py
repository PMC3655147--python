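"""Band integration and the windowed / cross-band / structure statistics.

The 0.01–0.25 Hz range of slow BOLD-like oscillations is partitioned into
four log-spaced bands (Hz):

    slow-5 [0.01, 0.027)   slow-4 [0.027, 0.073)
    slow-3 [0.073, 0.198)  slow-2 [0.198, 0.25]

Band edges are half-open on the right except the final band, so every
in-range frequency belongs to exactly one band.  Band-averaged power or net
flow per node per time point is the unit of all downstream statistics:
one-way ANOVA of power across fixed-length time windows (the within-
participant nonstationarity test), paired window-change tests on pairwise
correlations across participants, peak-matched cross-band correlation of
net flow with lower-band power, and the correlation of slow-3 net in-flow
with anatomical fiber degree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import MultiTrialTimeSeries
from .wavelet_spectra import PowerMap, TimeFreqGrid

__all__ = [
    "BandDefinition",
    "BandSeries",
    "PeakEvent",
    "DEFAULT_BANDS",
    "band_for_frequency",
    "band_integrate",
    "windowed_power_anova",
    "windowed_correlation",
    "window_change_test",
    "find_peak",
    "cross_band_relation",
    "structure_function_corr",
]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_LEN = 19  # samples (38 s at TR = 2 s)


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [lo, hi) (final band closed at the top)."""

    name: str
    lo: float
    hi: float
    closed_hi: bool = False

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError("band requires lo < hi")

    def contains(self, f: np.ndarray) -> np.ndarray:
        f = np.asarray(f, dtype=float)
        if self.closed_hi:
            return (f >= self.lo) & (f <= self.hi)
        return (f >= self.lo) & (f < self.hi)


DEFAULT_BANDS: dict[str, BandDefinition] = {
    "slow-5": BandDefinition("slow-5", 0.010, 0.027),
    "slow-4": BandDefinition("slow-4", 0.027, 0.073),
    "slow-3": BandDefinition("slow-3", 0.073, 0.198),
    "slow-2": BandDefinition("slow-2", 0.198, 0.250, closed_hi=True),
}


def band_for_frequency(f: float) -> str | None:
    """Name of the unique default band containing ``f``, or None."""
    for name, band in DEFAULT_BANDS.items():
        if band.contains(np.asarray(f)):
            return name
    return None


@dataclass(frozen=True)
class BandSeries:
    """Band-averaged power or net flow per node per time point.

    ``values`` has shape (n_nodes, n_time); cells where every in-band
    frequency was edge-flagged are NaN.  ``kind`` is "power" or "net_flow".
    """

    values: np.ndarray
    band: BandDefinition
    times: np.ndarray
    kind: str
    node_labels: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind == "power" and np.nanmin(self.values) < 0:
            raise ValueError("power band series must be nonnegative")


@dataclass(frozen=True)
class PeakEvent:
    """Location and height of the global maximum of a band series."""

    node: int
    time: float
    value: float
    time_index: int


def _trapz_weights(f: np.ndarray) -> np.ndarray:
    """Trapezoid quadrature weights on an (irregular) grid."""
    w = np.zeros_like(f)
    df = np.diff(f)
    w[:-1] += df / 2
    w[1:] += df / 2
    return w


def band_integrate(
    values: np.ndarray,
    grid: TimeFreqGrid,
    band: BandDefinition,
    flags: np.ndarray | None = None,
    kind: str = "power",
    node_labels: tuple[str, ...] = (),
) -> BandSeries:
    """Trapezoid-weighted mean of a (node, time, freq) map over a band.

    ``flags`` (n_time, n_freq), where True, marks cells excluded from the
    average (cone of influence); times with no usable in-band frequency get
    NaN.  Accepts a :class:`PowerMap` in place of the raw array.
    """
    if isinstance(values, PowerMap):
        if flags is None:
            flags = values.flags
        node_labels = node_labels or values.node_labels
        values = values.values
    values = np.asarray(values)
    f = grid.freqs
    inband = band.contains(f)
    if inband.sum() < 2:
        raise ValueError(
            f"band {band.name} [{band.lo}, {band.hi}] covers fewer than 2 "
            "grid frequencies"
        )
    w_f = _trapz_weights(f[inband])
    sub = values[:, :, inband]  # (node, time, fb)
    if flags is None:
        ok = np.ones((values.shape[1], int(inband.sum())), dtype=bool)
    else:
        ok = ~np.asarray(flags)[:, inband]  # (time, fb)
    wmat = ok * w_f[None, :]  # (time, fb)
    denom = wmat.sum(axis=1)  # (time,)
    num = np.einsum("ntf,tf->nt", np.nan_to_num(sub), wmat)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / denom[None, :]
    out[:, denom <= 0] = np.nan
    return BandSeries(
        values=out,
        band=band,
        times=grid.times,
        kind=kind,
        node_labels=node_labels,
    )


def windowed_power_anova(
    bs: BandSeries, window_len: int = DEFAULT_WINDOW_LEN
) -> pd.DataFrame:
    """One-way ANOVA of band power grouped by consecutive fixed-length
    windows, per node (the within-participant power-variation test).

    A trailing incomplete window is dropped.  Returns a tidy frame with
    columns node, F, df1, df2, p, n_windows.  A constant series gives
    F = 0, p = 1.
    """
    vals = bs.values
    n_nodes, n_time = vals.shape
    n_win = n_time // window_len
    if n_win < 2:
        raise ValueError("need at least 2 complete windows")
    rows = []
    for node in range(n_nodes):
        x = vals[node, : n_win * window_len]
        groups = [g[np.isfinite(g)] for g in x.reshape(n_win, window_len)]
        groups = [g for g in groups if g.size >= 2]
        if len(groups) < 2:
            raise ValueError(f"node {node}: fewer than 2 usable windows")
        pooled = np.concatenate(groups)
        df1 = len(groups) - 1
        df2 = pooled.size - len(groups)
        if np.ptp(pooled) == 0:
            F, p = 0.0, 1.0
        else:
            F, p = stats.f_oneway(*groups)
        rows.append(
            {
                "node": bs.node_labels[node] if bs.node_labels else node,
                "F": float(F),
                "df1": df1,
                "df2": df2,
                "p": float(p),
                "n_windows": len(groups),
            }
        )
    return pd.DataFrame(rows)


def windowed_correlation(ts: MultiTrialTimeSeries, n_windows: int = 3) -> pd.DataFrame:
    """Pearson correlation between realization-averaged node series within
    each of ``n_windows`` equal consecutive windows (remainder dropped).

    Returns a tidy frame: window, node_i, node_j, r, n.
    """
    if n_windows < 2:
        raise ValueError("need at least 2 windows")
    wlen = ts.n_time // n_windows
    if wlen < 3:
        raise ValueError("windows shorter than 3 samples")
    series = ts.node_mean()
    rows = []
    for w in range(n_windows):
        seg = series[:, w * wlen : (w + 1) * wlen]
        for i in range(ts.n_nodes):
            for j in range(i + 1, ts.n_nodes):
                r = stats.pearsonr(seg[i], seg[j]).statistic
                rows.append(
                    {
                        "window": w,
                        "node_i": ts.node_labels[i],
                        "node_j": ts.node_labels[j],
                        "r": float(r),
                        "n": wlen,
                    }
                )
    return pd.DataFrame(rows)


def window_change_test(
    correlations: np.ndarray, windows: tuple[int, int] = (0, 1)
) -> dict:
    """Paired two-sided t-test across participants for a change in a pair's
    correlation between two windows.

    ``correlations`` is (n_participants, n_windows) of Pearson r for one
    node pair.  Correlations are Fisher-z transformed before the test (the
    test statistic is computed on the z scale); the reported ``sd`` is the
    standard deviation of the raw correlation differences.  Identical
    columns (no change anywhere) give t = 0, p = 1; a degenerate nonzero
    constant difference is an error.
    """
    corr = np.asarray(correlations, dtype=float)
    if corr.ndim != 2 or corr.shape[0] < 3:
        raise ValueError("need correlations for at least 3 participants")
    i, j = windows
    ri, rj = corr[:, i], corr[:, j]
    diffs = ri - rj
    if np.allclose(diffs.std(ddof=1), 0.0):
        if np.allclose(diffs, 0.0):
            return {"t": 0.0, "p": 1.0, "sd": 0.0, "n": corr.shape[0]}
        raise ValueError("degenerate zero-variance nonzero differences")
    zi = np.arctanh(np.clip(ri, -1 + 1e-12, 1 - 1e-12))
    zj = np.arctanh(np.clip(rj, -1 + 1e-12, 1 - 1e-12))
    t, p = stats.ttest_rel(zi, zj)
    return {
        "t": float(t),
        "p": float(p),
        "sd": float(diffs.std(ddof=1)),
        "n": corr.shape[0],
    }


def find_peak(bs: BandSeries, node: int) -> PeakEvent:
    """Global maximum of a node's band series over non-flagged times; ties
    broken by the earliest time."""
    x = bs.values[node]
    if not np.any(np.isfinite(x)):
        raise ValueError(f"node {node}: all time points flagged")
    idx = int(np.nanargmax(x))  # nanargmax returns the first maximum
    return PeakEvent(
        node=node, time=float(bs.times[idx]), value=float(x[idx]), time_index=idx
    )


def cross_band_relation(
    flow_series: list[BandSeries], power_series: list[BandSeries]
) -> dict:
    """Peak-matched cross-band Pearson correlation pooled over
    participants × nodes.

    For every participant (list element) and node, the peak net-flow value
    is paired with the lower-band power at the same peak time; the pooled
    pairs give one Pearson r with a two-sided p.
    """
    if len(flow_series) != len(power_series):
        raise ValueError("flow and power lists must align over participants")
    flows, powers = [], []
    for fb, pb in zip(flow_series, power_series):
        if fb.values.shape != pb.values.shape:
            raise ValueError("flow and power series must share node/time grids")
        for node in range(fb.values.shape[0]):
            pk = find_peak(fb, node)
            pw = pb.values[node, pk.time_index]
            if np.isfinite(pw):
                flows.append(pk.value)
                powers.append(pw)
    n = len(flows)
    if n < 3:
        raise ValueError("fewer than 3 pooled observations")
    res = stats.pearsonr(flows, powers)
    return {"r": float(res.statistic), "p": float(res.pvalue), "n": n}


def structure_function_corr(
    flow_series: list[BandSeries],
    fiber_counts: np.ndarray | list[np.ndarray],
    node_labels: tuple[str, ...] | None = None,
) -> dict:
    """Pearson correlation between peak net in-flow (slow-3 by design) and
    anatomical fiber degree, pooled over participants × nodes.

    ``fiber_counts`` is one symmetric matrix shared by all participants or
    a per-participant list; a node's fiber degree is the sum of its counts
    to all other nodes.
    """
    n_participants = len(flow_series)
    if isinstance(fiber_counts, np.ndarray):
        fiber_list = [fiber_counts] * n_participants
    else:
        fiber_list = list(fiber_counts)
        if len(fiber_list) != n_participants:
            raise ValueError("need one fiber matrix per participant")
    flows, degrees = [], []
    for fb, fibers in zip(flow_series, fiber_list):
        fibers = np.asarray(fibers)
        n_nodes = fb.values.shape[0]
        if fibers.shape != (n_nodes, n_nodes):
            raise ValueError(
                f"fiber matrix shape {fibers.shape} does not match "
                f"{n_nodes} flow nodes"
            )
        if node_labels is not None and fb.node_labels and tuple(
            fb.node_labels
        ) != tuple(node_labels):
            raise ValueError("node labels of flow series and fiber table differ")
        deg = fibers.sum(axis=1)
        for node in range(n_nodes):
            pk = find_peak(fb, node)
            flows.append(pk.value)
            degrees.append(deg[node])
    n = len(flows)
    if n < 3:
        raise ValueError("fewer than 3 pooled observations")
    res = stats.pearsonr(flows, degrees)
    return {"r": float(res.statistic), "p": float(res.pvalue), "n": n}


def benjamini_hochberg(pvals: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (optional; off by default in
    all pipelines, matching the uncorrected reporting convention)."""
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * p.size / (np.arange(p.size) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(adj)
    out[order] = np.minimum(adj, 1.0)
    return out
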