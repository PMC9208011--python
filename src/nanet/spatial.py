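"""Dependence of functional connectivity on spatial proximity.

Three views, per connection class (neuron-neuron "NN", astrocyte-astrocyte
"AA", interlayer "NA"): a binned functional-connection-probability curve over
spatial weight, an edge-weight-on-spatial-weight regression, and a 2-D
(elementwise) matrix correlation corrected by a uniform-random-matrix
baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .types import ASTRO, NEURON

PAIR_CLASSES = ("NN", "AA", "NA", "all")


def pair_values(
    A: np.ndarray, layers: np.ndarray | None = None, pair_class: str = "all"
) -> np.ndarray:
    """Upper-triangle values of ``A`` restricted to one connection class."""
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    iu = np.triu_indices(n, 1)
    vals = A[iu]
    if pair_class == "all":
        return vals
    if layers is None:
        raise ValueError("layer labels required for class-restricted pairs")
    layers = np.asarray(layers)
    li, lj = layers[iu[0]], layers[iu[1]]
    if pair_class == "NN":
        mask = (li == NEURON) & (lj == NEURON)
    elif pair_class == "AA":
        mask = (li == ASTRO) & (lj == ASTRO)
    elif pair_class == "NA":
        mask = li != lj
    else:
        raise ValueError(f"unknown pair class {pair_class!r}")
    return vals[mask]


def _pooled_pairs(func, spat, layers, pair_class):
    """Pool class-restricted pair values over one or many dish networks."""
    if isinstance(func, np.ndarray):
        func, spat = [func], [spat]
        layers = [layers]
    fvals, svals = [], []
    for F, S, L in zip(func, spat, layers if layers is not None else [None] * len(func)):
        F, S = np.asarray(F), np.asarray(S)
        if F.shape != S.shape:
            raise ValueError("functional/spatial shape mismatch")
        fvals.append(pair_values(F, L, pair_class))
        svals.append(pair_values(S, L, pair_class))
    return np.concatenate(fvals), np.concatenate(svals)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    r_squared: float
    p_value: float
    n: int

    def ci_covers(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high


def _ols(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    X = sm.add_constant(np.asarray(x, dtype=float))
    fit = sm.OLS(np.asarray(y, dtype=float), X).fit()
    ci = fit.conf_int(alpha=0.05)
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        ci_low=float(ci[1][0]),
        ci_high=float(ci[1][1]),
        r_squared=float(fit.rsquared),
        p_value=float(fit.pvalues[1]),
        n=len(x),
    )


@dataclass
class BinnedProbabilityCurve:
    """Connection probability vs spatial weight in equal-width bins."""

    table: pd.DataFrame  # bin, mean_spatial_weight, n_pairs, n_connected, probability
    regression: RegressionResult
    pair_class: str
    n_bins: int
    n_empty_bins: int

    @property
    def total_pairs(self) -> int:
        return int(self.table["n_pairs"].sum())


def connection_probability_curve(
    func,
    spat,
    layers=None,
    pair_class: str = "all",
    n_bins: int = 30,
) -> BinnedProbabilityCurve:
    """Bin pairs by spatial weight; probability = nonzero edges / pairs per bin.

    ``func``/``spat`` may be single matrices or lists of matched matrices
    (pairs pooled across dishes of a condition). Bins are equal-width over
    the spatial-weight range [0, 1]; empty bins are dropped. The probability
    is regressed on the per-bin mean spatial weight by OLS with a 95% CI on
    the slope.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    f, s = _pooled_pairs(func, spat, layers, pair_class)
    if len(f) == 0:
        raise ValueError(f"no pairs of class {pair_class!r}")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(s, edges) - 1, 0, n_bins - 1)
    rows = []
    n_empty = 0
    for b in range(n_bins):
        mask = idx == b
        total = int(mask.sum())
        if total == 0:
            n_empty += 1
            continue
        connected = int(np.count_nonzero(f[mask]))
        rows.append(
            {
                "bin": b,
                "mean_spatial_weight": float(s[mask].mean()),
                "n_pairs": total,
                "n_connected": connected,
                "probability": connected / total,
            }
        )
    if not rows:
        raise ValueError("all bins empty")
    table = pd.DataFrame(rows)
    reg = _ols(table["mean_spatial_weight"].to_numpy(), table["probability"].to_numpy())
    return BinnedProbabilityCurve(
        table=table,
        regression=reg,
        pair_class=pair_class,
        n_bins=n_bins,
        n_empty_bins=n_empty,
    )


def edge_weight_regression(
    func,
    spat,
    layers=None,
    pair_class: str = "all",
    nonzero_only: bool = False,
) -> RegressionResult:
    """OLS of functional edge weight on spatial edge weight over class pairs.

    By default all pairs enter, zero-weight (absent) edges included — edge
    existence is analyzed separately by the probability curve. Set
    ``nonzero_only`` to restrict to realized edges.
    """
    f, s = _pooled_pairs(func, spat, layers, pair_class)
    if nonzero_only:
        keep = f != 0
        f, s = f[keep], s[keep]
    if len(f) < 3:
        raise ValueError("need at least 3 pairs for a regression")
    if np.ptp(s) == 0:
        raise ValueError("zero spatial-weight variance")
    return _ols(s, f)


def corr2(A: np.ndarray, B: np.ndarray) -> float:
    """Elementwise Pearson correlation of two equal-shape matrices."""
    a = np.asarray(A, dtype=float).ravel()
    b = np.asarray(B, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("matrices must have matching shapes")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant matrix in corr2")
    a = a - a.mean()
    b = b - b.mean()
    return float((a @ b) / np.sqrt((a @ a) * (b @ b)))


def corrected_corr2(
    A_func: np.ndarray, A_spat: np.ndarray, seed=0, n_draws: int = 100
) -> float:
    """2-D correlation minus a uniform-random-matrix baseline.

    The baseline is the mean corr2 over ``n_draws`` pairs of fresh uniform
    random matrices of the same shape, removing the small spurious
    correlation expected at finite matrix size.
    """
    base = corr2(A_func, A_spat)
    rng = np.random.default_rng(seed)
    shape = np.asarray(A_func).shape
    draws = [
        corr2(rng.uniform(size=shape), rng.uniform(size=shape))
        for _ in range(n_draws)
    ]
    return float(base - np.mean(draws))
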