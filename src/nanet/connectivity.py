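"""Functional and spatial adjacency construction.

Functional edges are zero-lag Pearson correlations gated by a surrogate
test: the observed correlation is compared, by a two-sided normal z test, to
its distribution over amplitude-adjusted Fourier transform (AAFT) surrogates
of one trace of the pair. AAFT surrogates share the original's marginal
distribution exactly and its power spectrum approximately, so the test
controls for autocorrelation-induced spurious correlation.

Spatial edges weight node pairs by 1 - d/d_max, with d the Euclidean
centroid distance and d_max the field-of-view diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

from .traces import preprocess_traceset
from .types import Population, TraceSet, as_seedseq


def aaft_surrogates(trace: np.ndarray, n: int, seed=0) -> np.ndarray:
    """Generate ``n`` AAFT surrogates of ``trace`` -> array (n, len(trace)).

    Steps per surrogate: (1) Gaussianize the trace by rank-remapping sorted
    Gaussian noise onto its rank order; (2) randomize Fourier phases of the
    Gaussianized series; (3) rank-remap the original's sorted values onto the
    phase-randomized series. Every surrogate's sorted values therefore equal
    the original's sorted values exactly.
    """
    x = np.asarray(trace, dtype=float)
    if x.ndim != 1 or len(x) < 16:
        raise ValueError("trace must be 1-D with length >= 16")
    if np.ptp(x) == 0:
        raise ValueError("constant trace has no AAFT surrogate")
    if n < 1:
        raise ValueError("need n >= 1 surrogates")
    rng = np.random.default_rng(seed)
    T = len(x)
    order_x = np.argsort(x, kind="stable")
    rank_x = np.empty(T, dtype=np.intp)
    rank_x[order_x] = np.arange(T)
    sorted_x = x[order_x]

    # (1) Gaussianize via normal order statistics (rank-preserving)
    g = stats.norm.ppf((np.arange(1, T + 1) - 0.375) / (T + 0.25))
    y = g[rank_x]

    # (2) phase randomization, independently per surrogate
    Y = np.fft.rfft(y)
    phases = rng.uniform(0, 2 * np.pi, size=(n, len(Y)))
    phases[:, 0] = 0.0
    if T % 2 == 0:
        phases[:, -1] = 0.0
    y_pr = np.fft.irfft(Y[None, :] * np.exp(1j * phases), n=T, axis=1)

    # (3) rank-remap the original amplitudes
    order = np.argsort(y_pr, axis=1)
    out = np.empty((n, T))
    rows = np.arange(n)[:, None]
    out[rows, order] = sorted_x[None, :]
    return out


class EdgeTestResult(NamedTuple):
    significant: bool
    weight: float
    z: float
    p: float


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError("constant vector in correlation")
    return (v - v.mean()) / sd


def edge_test(
    x: np.ndarray,
    y: np.ndarray,
    n_surrogates: int = 100,
    alpha: float = 0.05,
    seed=0,
    surrogates: np.ndarray | None = None,
) -> EdgeTestResult:
    """Surrogate-gated correlation test for one ROI pair.

    ``z = (r_obs - mean(r_surr)) / sd(r_surr)`` with ``r_surr`` the
    correlations of ``x`` against AAFT surrogates of ``y``; two-sided normal
    test at ``alpha``. The edge weight is the observed (signed) correlation
    when significant, else 0. Pre-computed ``surrogates`` of ``y`` may be
    passed to amortize their cost over many pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if n_surrogates < 20:
        raise ValueError("need at least 20 surrogates")
    T = len(x)
    zx = _standardize(x)
    zy = _standardize(y)
    r_obs = float(zx @ zy / T)
    if surrogates is None:
        surrogates = aaft_surrogates(y, n_surrogates, seed=seed)
    s = np.asarray(surrogates, dtype=float)
    s = (s - s.mean(axis=1, keepdims=True)) / s.std(axis=1, keepdims=True)
    r_surr = s @ zx / T
    sd = float(r_surr.std(ddof=1))
    if sd == 0:
        raise ValueError("zero variance of surrogate correlations")
    z = (r_obs - float(r_surr.mean())) / sd
    p = float(2 * stats.norm.sf(abs(z)))
    sig = p < alpha
    return EdgeTestResult(significant=sig, weight=r_obs if sig else 0.0, z=z, p=p)


@dataclass
class FunctionalAdjacency:
    """Surrogate-gated correlation network over the ROIs of one recording."""

    weights: np.ndarray  # symmetric, zero diagonal, signed r where significant
    zscores: np.ndarray
    roi_ids: list[str]
    alpha: float = 0.05
    n_surrogates: int = 100

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if not np.allclose(w, w.T):
            raise ValueError("functional adjacency must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("functional adjacency diagonal must be zero")
        if np.nanmax(np.abs(w), initial=0.0) > 1 + 1e-9:
            raise ValueError("weights must lie in [-1, 1]")

    @property
    def n(self) -> int:
        return self.weights.shape[0]


def build_functional_adjacency(
    traces: TraceSet | np.ndarray,
    n_surrogates: int = 100,
    alpha: float = 0.05,
    seed=0,
    roi_ids: list[str] | None = None,
    preprocess: bool = True,
) -> FunctionalAdjacency:
    """Apply :func:`edge_test` to every unordered ROI pair.

    Surrogates are generated once per ROI (for the higher-index member of
    each pair) from seeds derived deterministically from the master seed.
    ROIs whose processed trace is constant (e.g. silent cells) cannot be
    tested; their edges stay 0 with NaN z-scores.
    """
    if isinstance(traces, TraceSet):
        X = preprocess_traceset(traces) if preprocess else traces.traces
        ids = traces.roi_ids
    else:
        X = np.asarray(traces, dtype=float)
        ids = roi_ids if roi_ids is not None else [f"roi{i}" for i in range(X.shape[1])]
    T, n = X.shape
    if n < 2:
        raise ValueError("need at least 2 ROIs")

    sd = X.std(axis=0)
    testable = sd > 0
    Z = np.zeros_like(X)
    Z[:, testable] = (X[:, testable] - X[:, testable].mean(axis=0)) / sd[testable]
    r_obs = (Z.T @ Z) / T

    roi_seeds = as_seedseq(seed).spawn(n)
    weights = np.zeros((n, n))
    zscores = np.full((n, n), np.nan)
    norm = stats.norm
    for j in range(1, n):
        if not testable[j]:
            continue
        surr = aaft_surrogates(X[:, j], n_surrogates, seed=roi_seeds[j])
        s = (surr - surr.mean(axis=1, keepdims=True)) / surr.std(axis=1, keepdims=True)
        r_surr = s @ Z[:, :j] / T  # (n_surrogates, j)
        mu = r_surr.mean(axis=0)
        sdv = r_surr.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (r_obs[:j, j] - mu) / sdv
        z[~testable[:j]] = np.nan
        p = 2 * norm.sf(np.abs(z))
        sig = p < alpha  # NaN p (untestable pair) compares False
        zscores[:j, j] = z
        zscores[j, :j] = z
        w = np.where(sig, r_obs[:j, j], 0.0)
        weights[:j, j] = w
        weights[j, :j] = w
    np.fill_diagonal(weights, 0.0)
    return FunctionalAdjacency(
        weights=np.clip(weights, -1.0, 1.0),
        zscores=zscores,
        roi_ids=list(ids),
        alpha=alpha,
        n_surrogates=n_surrogates,
    )


@dataclass
class SpatialAdjacency:
    """Proximity network: weight = 1 - d/d_max, zero diagonal by convention."""

    weights: np.ndarray
    roi_ids: list[str]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if not np.allclose(w, w.T):
            raise ValueError("spatial adjacency must be symmetric")
        off = w[~np.eye(w.shape[0], dtype=bool)]
        if off.size and (off.min() < -1e-9 or off.max() > 1 + 1e-9):
            raise ValueError("spatial weights must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.weights.shape[0]


def build_spatial_adjacency(population: Population) -> SpatialAdjacency:
    """Pairwise proximity weights from ROI centroids.

    d_max is the FOV diagonal (the maximum possible distance in the field of
    view), so opposite-corner ROIs get weight 0 and coincident ROIs weight 1.
    """
    xy = population.coords  # Population validates centroids lie in the FOV
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    w = 1.0 - d / population.fov_diagonal
    np.fill_diagonal(w, 0.0)
    return SpatialAdjacency(weights=w, roi_ids=population.roi_ids)
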