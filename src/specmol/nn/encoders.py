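"""View encoders mapping graphs, fingerprints and peak sets to one space.

* Graph encoder: 3-layer GCN over the normalized adjacency (with self
  loops), mean pooling over nodes, then a 2-layer MLP head.
* Fingerprint encoder: 3-layer MLP on the 1024-bit Morgan vector.
* Spectrum / consensus encoders (identical architecture, independent
  parameters): a 3-layer MLP lifts each 15-dim peak vector to the model
  width, a 2-head transformer encoder mixes the peak set (no positional
  encoding — a peak set has no order), masked mean pooling collapses the set
  and a linear head projects to the embedding dimension.
* Binned encoder: plain 3-layer MLP on the fixed-length binned spectrum,
  used by the binned-representation variant of the model.

Batching of variable-size inputs uses block-diagonal sparse structure
matrices (graphs) and padding with key masking (peak sets); padding cannot
leak into outputs because masked positions receive -1e9 attention bias and
are excluded from pooling averages.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from ..chem import NODE_DIM, MolecularGraph
from ..spectra import PEAK_DIM
from .autodiff import Tensor, const_matmul
from .layers import Dropout, Linear, MLP, ParamStore, TransformerEncoderLayer


def _batch_graphs(graphs: list[MolecularGraph]) -> tuple[np.ndarray, sp.csr_matrix, sp.csr_matrix]:
    """Stack graphs into (node matrix, block normalized adjacency, pooling)."""
    if not graphs:
        raise ValueError("empty graph batch")
    sizes = []
    rows_x = []
    data, ri, ci = [], [], []
    offset = 0
    for g in graphs:
        n = g.node_features.shape[0]
        if n == 0:
            raise ValueError("graph with zero nodes")
        sizes.append(n)
        rows_x.append(g.node_features)
        deg = np.ones(n)  # self loops
        for u, v in g.edge_index:
            deg[u] += 1
            deg[v] += 1
        dinv = 1.0 / np.sqrt(deg)
        for u in range(n):  # self loops
            data.append(dinv[u] * dinv[u])
            ri.append(offset + u)
            ci.append(offset + u)
        for u, v in g.edge_index:
            w = dinv[u] * dinv[v]
            data.extend((w, w))
            ri.extend((offset + u, offset + v))
            ci.extend((offset + v, offset + u))
        offset += n
    X = np.vstack(rows_x)
    A = sp.csr_matrix((data, (ri, ci)), shape=(offset, offset))
    pr, pc, pd = [], [], []
    off = 0
    for i, n in enumerate(sizes):
        pr.extend([i] * n)
        pc.extend(range(off, off + n))
        pd.extend([1.0 / n] * n)
        off += n
    P = sp.csr_matrix((pd, (pr, pc)), shape=(len(sizes), offset))
    return X, A, P


class GraphEncoder:
    def __init__(self, store: ParamStore, name: str, hidden: int, embed_dim: int,
                 n_layers: int, rng: np.random.Generator):
        dims = [NODE_DIM] + [hidden] * n_layers
        self.gcn = [
            Linear(store, f"{name}.gcn{i}", dims[i], dims[i + 1], rng)
            for i in range(n_layers)
        ]
        self.head = MLP(store, f"{name}.head", [hidden, hidden, embed_dim], rng)

    def __call__(self, graphs: list[MolecularGraph],
                 dropout: Dropout | None = None) -> Tensor:
        X, A, P = _batch_graphs(graphs)
        h = Tensor(X)
        for layer in self.gcn:
            h = layer(const_matmul(A, h)).relu()
            if dropout is not None:
                h = dropout(h)
        pooled = const_matmul(P, h)
        return self.head(pooled, dropout)


class FingerprintEncoder:
    def __init__(self, store: ParamStore, name: str, d_in: int, hidden: int,
                 embed_dim: int, rng: np.random.Generator):
        self.mlp = MLP(store, f"{name}.mlp", [d_in, hidden, hidden, embed_dim], rng)

    def __call__(self, fps: np.ndarray, dropout: Dropout | None = None) -> Tensor:
        fps = np.atleast_2d(np.asarray(fps, dtype=np.float64))
        if fps.shape[0] == 0:
            raise ValueError("empty fingerprint batch")
        return self.mlp(Tensor(fps), dropout)


def pad_peak_sets(peak_sets: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Pad (L_i, PEAK_DIM) matrices to a (B, L_max, PEAK_DIM) block + mask."""
    if not peak_sets:
        raise ValueError("empty peak-set batch")
    for m in peak_sets:
        if m.shape[0] == 0:
            raise ValueError("empty peak set in batch")
    L = max(m.shape[0] for m in peak_sets)
    B = len(peak_sets)
    X = np.zeros((B, L, peak_sets[0].shape[1]))
    mask = np.zeros((B, L), dtype=bool)
    for i, m in enumerate(peak_sets):
        X[i, : m.shape[0]] = m
        mask[i, : m.shape[0]] = True
    return X, mask


class SpectrumSetEncoder:
    """Peak-MLP + transformer + masked mean pooling + linear head."""

    def __init__(self, store: ParamStore, name: str, hidden: int, embed_dim: int,
                 heads: int, n_transformer: int, peak_mlp_layers: int,
                 rng: np.random.Generator):
        dims = [PEAK_DIM] + [hidden] * peak_mlp_layers
        self.peak_mlp = MLP(store, f"{name}.peaks", dims, rng)
        self.blocks = [
            TransformerEncoderLayer(store, f"{name}.tr{i}", hidden, heads,
                                    2 * hidden, rng)
            for i in range(n_transformer)
        ]
        self.head = Linear(store, f"{name}.head", hidden, embed_dim, rng)

    def __call__(self, peak_sets: list[np.ndarray],
                 dropout: Dropout | None = None) -> Tensor:
        X, mask = pad_peak_sets(peak_sets)
        h = self.peak_mlp(Tensor(X), dropout)
        h = h * mask[:, :, None]  # zero padded tokens before mixing
        for block in self.blocks:
            h = block(h, mask, dropout)
        counts = mask.sum(axis=1, keepdims=True)
        pooled = (h * mask[:, :, None]).sum(axis=1) * (1.0 / counts)
        return self.head(pooled)


class BinnedEncoder:
    """3-layer MLP over fixed-length binned spectra."""

    def __init__(self, store: ParamStore, name: str, n_bins: int, hidden: int,
                 embed_dim: int, rng: np.random.Generator):
        self.n_bins = n_bins
        self.mlp = MLP(store, f"{name}.mlp", [n_bins, hidden, hidden, embed_dim], rng)

    def __call__(self, binned: np.ndarray, dropout: Dropout | None = None) -> Tensor:
        binned = np.atleast_2d(np.asarray(binned, dtype=np.float64))
        if binned.shape[1] != self.n_bins:
            raise ValueError(
                f"binned spectrum length {binned.shape[1]} does not match "
                f"encoder binning config ({self.n_bins} bins)"
            )
        return self.mlp(Tensor(binned), dropout)
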