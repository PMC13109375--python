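"""Nine functional-connectivity metrics and the composite edge score.

A single correlation coefficient captures only linear instantaneous
dependence between two BOLD series; the composite score aggregates nine
complementary similarity measures — Pearson correlation, maximal lagged
cross-correlation, dynamic time warping, Euclidean, Manhattan and
Wasserstein distances, mutual information, spectral coherence and wavelet
coherence — after z-scoring each metric across subjects per edge and
aligning signs so that larger always means stronger coupling.

Standard textbook definitions are used throughout (documented per function).
Distances are computed on z-scored series by default so they measure signal
shape rather than amplitude; a raw mode is available.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
import pywt
from numba import njit
from scipy import signal as sps
from scipy.stats import wasserstein_distance as _scipy_wasserstein

__all__ = [
    "corr_metrics",
    "distance_metrics",
    "wasserstein_distance",
    "mutual_information",
    "spectral_metrics",
    "edge_metric_vector",
    "cohort_metrics",
    "composite_edge_score",
    "METRIC_COLUMNS",
    "DISTANCE_METRICS",
]

METRIC_COLUMNS = (
    "pearson",
    "max_lagged_crosscorr",
    "dtw",
    "euclidean",
    "manhattan",
    "wasserstein",
    "mutual_information",
    "coherence",
    "wavelet_coherence",
)
#: metrics where larger values mean weaker coupling (sign-flipped in the composite)
DISTANCE_METRICS = ("dtw", "euclidean", "manhattan", "wasserstein")


class UndefinedCorrelationError(ValueError):
    """A correlation-type metric is undefined (zero-variance input)."""


def _check_pair(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("inputs must be 1-D")
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed")
    return x, y


def _zscore(v):
    sd = v.std()
    if sd == 0:
        raise UndefinedCorrelationError("zero-variance series")
    return (v - v.mean()) / sd


def corr_metrics(x, y, max_lag: int = 10) -> tuple[float, float]:
    """Pearson correlation and maximal lagged cross-correlation.

    The cross-correlation at lag ``l`` is the mean product of the z-scored
    series over their overlap; the reported value is the one with the
    largest absolute magnitude over lags -max_lag..max_lag, sign retained.
    """
    x, y = _check_pair(x, y)
    n = len(x)
    if max_lag >= n / 4:
        raise ValueError("max_lag must be < length / 4")
    zx, zy = _zscore(x), _zscore(y)
    pearson = float(np.dot(zx, zy) / n)
    best = 0.0
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            c = float(np.dot(zx[: n - lag], zy[lag:]) / (n - lag))
        else:
            c = float(np.dot(zx[-lag:], zy[: n + lag]) / (n + lag))
        if abs(c) > abs(best):
            best = c
    return pearson, best


@njit(cache=False)
def _dtw_cost(x, y):  # pragma: no cover - exercised via dtw wrapper
    n, m = len(x), len(y)
    D = np.empty((n + 1, m + 1))
    D[:, 0] = np.inf
    D[0, :] = np.inf
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            c = abs(x[i - 1] - y[j - 1])
            a = D[i - 1, j - 1]
            b = D[i - 1, j]
            d = D[i, j - 1]
            mn = a
            if b < mn:
                mn = b
            if d < mn:
                mn = d
            D[i, j] = c + mn
    return D[n, m]


def distance_metrics(x, y, zscore: bool = True) -> tuple[float, float, float]:
    """Euclidean, Manhattan, and dynamic-time-warping distances.

    DTW uses the classic dynamic-programming recursion with absolute local
    cost and the symmetric step pattern (match / insertion / deletion), no
    warping window. Series are z-scored first unless ``zscore=False``, so the
    distances measure shape rather than amplitude.
    """
    x, y = _check_pair(x, y)
    if zscore:
        x, y = _zscore(x), _zscore(y)
    euclidean = float(np.linalg.norm(x - y))
    manhattan = float(np.abs(x - y).sum())
    dtw = float(_dtw_cost(np.ascontiguousarray(x), np.ascontiguousarray(y)))
    return euclidean, manhattan, dtw


def wasserstein_distance(x, y) -> float:
    """1-Wasserstein distance between the two empirical amplitude
    distributions (integral of the absolute quantile-function difference)."""
    x, y = _check_pair(x, y)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    return float(_scipy_wasserstein(x, y))


def mutual_information(x, y, n_bins: int | None = None) -> float:
    """Plug-in mutual information (nats) from an equal-width 2-D histogram.

    Default bin count is ``ceil(sqrt(n / 5))`` so the expected cell
    occupancy stays reasonable. Constant input yields MI = 0 with a warning
    rather than an error.
    """
    x, y = _check_pair(x, y)
    n = len(x)
    if n_bins is None:
        n_bins = max(2, math.ceil(math.sqrt(n / 5)))
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if x.std() == 0 or y.std() == 0:
        warnings.warn("constant series: mutual information set to 0", stacklevel=2)
        return 0.0
    H, _, _ = np.histogram2d(x, y, bins=n_bins)
    p = H / H.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    contrib = p[nz] * np.log(p[nz] / (px @ py)[nz])
    # sorted summation makes MI(x, y) == MI(y, x) exact (same term multiset)
    return float(np.sort(contrib).sum())


def _welch_coherence(x, y, fs, band, nperseg=64):
    nperseg = min(nperseg, len(x))
    f, cxy = sps.coherence(x, y, fs=fs, nperseg=nperseg, noverlap=nperseg // 2)
    sel = (f >= band[0]) & (f <= band[1])
    if not sel.any():  # band narrower than the frequency resolution
        sel = slice(1, None)
    return float(np.clip(np.mean(cxy[sel]), 0.0, 1.0))


def _morlet_cwt(v, dt, scales, omega0=6.0):
    # Torrence-Compo Morlet psi(t) ~ e^{i omega0 t} e^{-t^2/2} corresponds to
    # pywt's 'cmorB-C' with B = 2 (variance) and C = omega0 / (2 pi).
    wavelet = f"cmor2.0-{omega0 / (2 * math.pi):.6f}"
    coeffs, freqs = pywt.cwt(v, scales, wavelet, sampling_period=dt)
    return coeffs, freqs


def _smooth(W, scales):
    """Smoothing operator for wavelet coherence: Gaussian in time with width
    proportional to scale, boxcar (width 3) across scales."""
    out = np.empty_like(W)
    n = W.shape[1]
    for k, s in enumerate(scales):
        sigma = max(s, 1.0)
        half = int(min(3 * sigma, (n - 1) // 2))
        t = np.arange(-half, half + 1)
        win = np.exp(-0.5 * (t / sigma) ** 2)
        win /= win.sum()
        out[k] = np.convolve(W[k], win, mode="same")
    if out.shape[0] >= 3:
        box = np.ones(3) / 3.0
        out = np.apply_along_axis(lambda c: np.convolve(c, box, mode="same"), 0, out)
    return out


def wavelet_coherence(x, y, tr: float, band=(0.01, 0.1), omega0: float = 6.0,
                      n_scales: int = 16) -> float:
    """Mean smoothed Morlet wavelet coherence over the band.

    ``R^2 = |S(Wx Wy*)|^2 / (S(|Wx|^2) S(|Wy|^2))`` with S the standard
    time (Gaussian, width ~ scale) and scale (boxcar) smoothing; averaged
    over the in-band scales and all time points. Identical inputs give 1.
    """
    x, y = _check_pair(x, y)
    nyq = 1.0 / (2 * tr)
    f1, f2 = max(band[0], 1.0 / (len(x) * tr)), min(band[1], nyq)
    # scale s maps to frequency C / (s dt); choose scales covering [f1, f2]
    C = omega0 / (2 * math.pi)
    s_min, s_max = C / (f2 * tr), C / (f1 * tr)
    scales = np.geomspace(s_min, s_max, n_scales)
    Wx, _ = _morlet_cwt(x, tr, scales, omega0)
    Wy, _ = _morlet_cwt(y, tr, scales, omega0)
    Sxy = _smooth(Wx * np.conj(Wy), scales)
    Sxx = _smooth(np.abs(Wx) ** 2 + 0j, scales).real
    Syy = _smooth(np.abs(Wy) ** 2 + 0j, scales).real
    denom = Sxx * Syy
    denom[denom <= 0] = np.finfo(float).tiny
    R2 = np.abs(Sxy) ** 2 / denom
    return float(np.clip(R2.mean(), 0.0, 1.0))


def spectral_metrics(x, y, repetition_time: float, band=(0.01, 0.1),
                     nperseg: int = 64) -> tuple[float, float]:
    """Band-averaged magnitude-squared coherence (Welch) and smoothed Morlet
    wavelet coherence, both in [0, 1].

    The band is clipped above at the Nyquist frequency ``1 / (2 TR)``; a band
    entirely outside (0, Nyquist] is an error.
    """
    x, y = _check_pair(x, y)
    nyq = 1.0 / (2 * repetition_time)
    if band[1] <= 0 or band[0] > nyq:
        raise ValueError(f"band {band} lies outside (0, {nyq:.4g}] Hz")
    if band[1] <= band[0]:
        raise ValueError("band upper bound must exceed lower bound")
    band = (max(band[0], 1e-12), min(band[1], nyq))
    coh = _welch_coherence(x, y, fs=1.0 / repetition_time, band=band, nperseg=nperseg)
    wcoh = wavelet_coherence(x, y, repetition_time, band=band)
    return coh, wcoh


def edge_metric_vector(x, y, repetition_time: float, max_lag: int = 10,
                       band=(0.01, 0.1), n_bins: int | None = None) -> dict:
    """All nine metrics for one time-series pair, keyed by METRIC_COLUMNS."""
    pearson, xlag = corr_metrics(x, y, max_lag=max_lag)
    euc, man, dtw = distance_metrics(x, y)
    w = wasserstein_distance(x, y)
    mi = mutual_information(x, y, n_bins=n_bins)
    coh, wcoh = spectral_metrics(x, y, repetition_time, band=band)
    return {
        "pearson": pearson,
        "max_lagged_crosscorr": xlag,
        "dtw": dtw,
        "euclidean": euc,
        "manhattan": man,
        "wasserstein": w,
        "mutual_information": mi,
        "coherence": coh,
        "wavelet_coherence": wcoh,
    }


def cohort_metrics(timeseries: dict, edge_set, repetition_time: float,
                   nodes=None, **kwargs) -> pd.DataFrame:
    """Per-subject, per-edge table of the nine metrics.

    ``timeseries`` maps subject_id -> (10, n_volumes) array ordered as
    ``network.NODES`` (or ``nodes``).
    """
    if nodes is None:
        from .network import NODES

        nodes = NODES
    idx = {n: i for i, n in enumerate(nodes)}
    rows = []
    for sid, ts in timeseries.items():
        for a, b in edge_set.undirected:
            m = edge_metric_vector(ts[idx[a]], ts[idx[b]], repetition_time, **kwargs)
            m["subject_id"] = sid
            m["edge"] = f"{a}-{b}"
            rows.append(m)
    df = pd.DataFrame(rows)
    return df[["subject_id", "edge", *METRIC_COLUMNS]]


def composite_edge_score(metrics: pd.DataFrame, mode: str = "aggregate") -> pd.DataFrame:
    """Combine the nine metrics into a per-subject, per-edge composite.

    Each metric is z-scored across subjects within each edge; the four
    distance-type metrics are sign-flipped so larger composite = stronger
    coupling. ``aggregate`` returns the mean of the nine aligned z-scores
    (one value per edge, as the 20-predictor design requires); ``stacked``
    returns the aligned 9-vector; ``pearson_only`` returns the z-scored
    Pearson column alone (robustness mode).

    Edges where any required metric has zero variance across subjects get an
    undefined (NaN) composite with a warning.
    """
    if mode not in ("aggregate", "stacked", "pearson_only"):
        raise ValueError(f"unknown mode {mode!r}")
    cols = ("pearson",) if mode == "pearson_only" else METRIC_COLUMNS
    missing = [c for c in cols if c not in metrics.columns]
    if missing:
        raise ValueError(f"missing metric columns: {missing}")
    if metrics.subject_id.nunique() < 2:
        raise ValueError("composite scoring needs >= 2 subjects")
    out = metrics[["subject_id", "edge"]].copy()
    zcols = {}
    for c in cols:
        grp = metrics.groupby("edge")[c]
        mu, sd = grp.transform("mean"), grp.transform(lambda v: v.std(ddof=0))
        z = (metrics[c] - mu) / sd
        degenerate = sd == 0
        if degenerate.any():
            bad = sorted(metrics.loc[degenerate, "edge"].unique())
            warnings.warn(
                f"zero variance for metric {c!r} on edges {bad}; composite undefined",
                stacklevel=2,
            )
            z[degenerate] = np.nan
        if c in DISTANCE_METRICS:
            z = -z
        zcols[c] = z
    if mode == "aggregate":
        out["composite"] = pd.concat(zcols, axis=1).mean(axis=1, skipna=False)
    elif mode == "pearson_only":
        out["composite"] = zcols["pearson"]
    else:
        for c in cols:
            out[f"z_{c}"] = zcols[c]
    return out
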