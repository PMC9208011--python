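"""Multilayer (neuron-layer + astrocyte-layer) adjacency assembly.

The multilayer matrix concatenates the neuron-neuron, neuron-astrocyte, and
astrocyte-astrocyte blocks into one symmetric matrix with neurons ordered
first, so single-layer graph machinery applies unchanged while layer labels
preserve block structure for layer-resolved statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import ASTRO, NEURON, Population


@dataclass
class MultilayerAdjacency:
    """Symmetric block matrix over all ROIs with a layer label per node."""

    weights: np.ndarray
    layers: np.ndarray  # "neuron" | "astrocyte_segment" per node
    roi_ids: list[str]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        self.layers = np.asarray(self.layers)
        if w.shape[0] != w.shape[1] or w.shape[0] != len(self.layers):
            raise ValueError("weights/layers dimension mismatch")
        if len(self.roi_ids) != len(self.layers):
            raise ValueError("roi_ids/layers dimension mismatch")
        if not np.allclose(w, w.T):
            raise ValueError("multilayer adjacency must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("multilayer adjacency diagonal must be zero")

    @property
    def n_neurons(self) -> int:
        return int(np.sum(self.layers == NEURON))

    @property
    def n_astro(self) -> int:
        return int(np.sum(self.layers == ASTRO))

    def block(self, a: str, b: str) -> np.ndarray:
        ia = np.flatnonzero(self.layers == a)
        ib = np.flatnonzero(self.layers == b)
        return self.weights[np.ix_(ia, ib)]

    @property
    def neuron_block(self) -> np.ndarray:
        return self.block(NEURON, NEURON)

    @property
    def astro_block(self) -> np.ndarray:
        return self.block(ASTRO, ASTRO)

    @property
    def interlayer_block(self) -> np.ndarray:
        return self.block(NEURON, ASTRO)


def assemble_multilayer(
    A_nn: np.ndarray,
    A_aa: np.ndarray,
    A_na: np.ndarray,
    neuron_ids: list[str] | None = None,
    astro_ids: list[str] | None = None,
) -> MultilayerAdjacency:
    """Concatenate intra- and interlayer blocks (neurons first)."""
    A_nn = np.asarray(A_nn, dtype=float)
    A_aa = np.asarray(A_aa, dtype=float)
    A_na = np.asarray(A_na, dtype=float)
    n, a = A_nn.shape[0], A_aa.shape[0]
    if A_nn.shape != (n, n) or A_aa.shape != (a, a) or A_na.shape != (n, a):
        raise ValueError(
            f"inconsistent block dimensions: nn={A_nn.shape}, aa={A_aa.shape}, "
            f"na={A_na.shape}"
        )
    W = np.block([[A_nn, A_na], [A_na.T, A_aa]])
    np.fill_diagonal(W, 0.0)
    layers = np.array([NEURON] * n + [ASTRO] * a)
    ids = (neuron_ids or [f"n{i}" for i in range(n)]) + (
        astro_ids or [f"a{i}" for i in range(a)]
    )
    return MultilayerAdjacency(weights=W, layers=layers, roi_ids=list(ids))


def multilayer_from_matrix(
    W: np.ndarray, population: Population
) -> MultilayerAdjacency:
    """Reorder a full ROI-ordered adjacency into neuron-first block layout."""
    types = population.cell_types
    order = np.concatenate(
        [np.flatnonzero(types == NEURON), np.flatnonzero(types == ASTRO)]
    )
    ids = [population.roi_ids[i] for i in order]
    return MultilayerAdjacency(
        weights=np.asarray(W, dtype=float)[np.ix_(order, order)],
        layers=types[order],
        roi_ids=ids,
    )


def layer_strengths(M: MultilayerAdjacency) -> pd.DataFrame:
    """Per-node normalized intra- and interlayer strengths (absolute weights).

    Intralayer strength of node i is its within-layer strength divided by
    (own-layer size - 1); interlayer strength is divided by the size of the
    other layer. Nodes in a single-node layer get NaN intralayer strength.
    """
    W = np.abs(M.weights)
    rows = []
    for i, (rid, layer) in enumerate(zip(M.roi_ids, M.layers)):
        same = M.layers == layer
        other = ~same
        n_same = int(same.sum())
        n_other = int(other.sum())
        intra = W[i, same].sum() / (n_same - 1) if n_same > 1 else np.nan
        inter = W[i, other].sum() / n_other if n_other > 0 else np.nan
        rows.append(
            {"roi_id": rid, "layer": layer, "intra_strength": intra,
             "inter_strength": inter}
        )
    return pd.DataFrame(rows)


def layer_strength_means(M: MultilayerAdjacency) -> dict[str, float]:
    """Neuron-layer, astrocyte-layer, and interlayer mean normalized strengths.

    The interlayer mean pools the node-level normalized interlayer strengths
    of both layers (symmetric treatment of the two sides).
    """
    df = layer_strengths(M)
    out: dict[str, float] = {}
    for layer, key in ((NEURON, "neuron"), (ASTRO, "astrocyte")):
        vals = df.loc[df["layer"] == layer, "intra_strength"].dropna()
        out[key] = float(vals.mean()) if len(vals) else float("nan")
    inter = df["inter_strength"].dropna()
    out["interlayer"] = float(inter.mean()) if len(inter) else float("nan")
    return out


def subsample_neurons(M: MultilayerAdjacency, seed=0) -> MultilayerAdjacency:
    """Uniformly subsample the neuron layer down to the astrocyte count.

    Balance control: with dominant neuron counts, whole-network statistics
    track the neuron layer; equalizing layer sizes isolates that effect. The
    astrocyte layer and all incident edges of retained nodes are untouched.
    """
    n_n, n_a = M.n_neurons, M.n_astro
    if n_n < n_a:
        raise ValueError(f"cannot subsample {n_n} neurons down to {n_a}")
    rng = np.random.default_rng(seed)
    neuron_idx = np.flatnonzero(M.layers == NEURON)
    keep_n = np.sort(rng.choice(neuron_idx, size=n_a, replace=False))
    keep = np.concatenate([keep_n, np.flatnonzero(M.layers == ASTRO)])
    return MultilayerAdjacency(
        weights=M.weights[np.ix_(keep, keep)],
        layers=M.layers[keep],
        roi_ids=[M.roi_ids[i] for i in keep],
    )
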