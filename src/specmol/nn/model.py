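"""The four-view model: one encoder per view sharing an embedding space."""

from __future__ import annotations

import numpy as np

from ..config import EncoderConfig
from .autodiff import Tensor
from .encoders import (
    BinnedEncoder,
    FingerprintEncoder,
    GraphEncoder,
    SpectrumSetEncoder,
)
from .layers import Dropout, ParamStore

FP_BITS = 1024


class MultiViewModel:
    """Graph, fingerprint, spectrum and consensus encoders with one store.

    All four encoders are always constructed (so checkpoints have a fixed
    parameter manifest); training touches only the encoders of the active
    views, leaving the others at initialization.
    """

    def __init__(self, config: EncoderConfig, seed: int):
        self.config = config
        self.store = ParamStore()
        rng = np.random.default_rng(seed)
        c = config
        self.graph_enc = GraphEncoder(
            self.store, "mol", c.gcn_hidden, c.embed_dim, c.gcn_layers, rng)
        self.fp_enc = FingerprintEncoder(
            self.store, "fp", FP_BITS, c.mlp_hidden, c.embed_dim, rng)
        if c.spectral_representation == "binned":
            self.spec_enc = BinnedEncoder(
                self.store, "s", c.n_bins, c.mlp_hidden, c.embed_dim, rng)
            self.cons_enc = BinnedEncoder(
                self.store, "cs", c.n_bins, c.mlp_hidden, c.embed_dim, rng)
        else:
            self.spec_enc = SpectrumSetEncoder(
                self.store, "s", c.mlp_hidden, c.embed_dim, c.transformer_heads,
                c.transformer_layers, c.peak_mlp_layers, rng)
            self.cons_enc = SpectrumSetEncoder(
                self.store, "cs", c.mlp_hidden, c.embed_dim, c.transformer_heads,
                c.transformer_layers, c.peak_mlp_layers, rng)
        self.dropout = Dropout(c.dropout)

    # -- modes ------------------------------------------------------------

    def train_mode(self, rng: np.random.Generator) -> None:
        self.dropout.training = True
        self.dropout.rng = rng

    def eval_mode(self) -> None:
        self.dropout.training = False
        self.dropout.rng = None

    @property
    def _drop(self) -> Dropout | None:
        return self.dropout if self.dropout.training else None

    # -- encoders ---------------------------------------------------------

    def encode_mol(self, graphs) -> Tensor:
        return self.graph_enc(graphs, self._drop)

    def encode_fp(self, fps) -> Tensor:
        return self.fp_enc(fps, self._drop)

    def encode_spectrum(self, inputs) -> Tensor:
        return self.spec_enc(inputs, self._drop)

    def encode_consensus(self, inputs) -> Tensor:
        return self.cons_enc(inputs, self._drop)

    _VIEW_FN = {
        "mol": "encode_mol",
        "fp": "encode_fp",
        "s": "encode_spectrum",
        "cs": "encode_consensus",
    }

    def embed(self, view: str, inputs) -> np.ndarray:
        """Deterministic evaluation-mode embeddings as a numpy array."""
        if view not in self._VIEW_FN:
            raise ValueError(f"unknown view {view!r}")
        was_training = self.dropout.training
        self.eval_mode()
        try:
            out = getattr(self, self._VIEW_FN[view])(inputs)
        finally:
            self.dropout.training = was_training
        return out.data.copy()
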