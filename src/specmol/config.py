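"""Configuration dataclasses and YAML loading.

Defaults follow the published training recipe (Adam, learning rate 7.0e-5,
1500 epochs, batch 64, contrastive temperature 0.05, 256-dim embeddings);
desk-scale runs override epochs/batch/learning rate explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

VIEWS = ("mol", "fp", "s", "cs")
RANKING_VIEWS = ("mol-s", "fp-s", "mol-cs", "fp-cs")


@dataclass
class EncoderConfig:
    embed_dim: int = 256
    gcn_layers: int = 3
    gcn_hidden: int = 256
    mlp_hidden: int = 256
    transformer_heads: int = 2
    transformer_layers: int = 2
    peak_mlp_layers: int = 3
    dropout: float = 0.1
    active_views: tuple[str, ...] = VIEWS
    spectral_representation: str = "formula"  # formula | binned
    n_bins: int = 10000
    bin_width: float = 0.1

    def __post_init__(self):
        self.active_views = tuple(self.active_views)
        unknown = set(self.active_views) - set(VIEWS)
        if unknown:
            raise ValueError(f"unknown views {sorted(unknown)}")
        if not {"mol", "s"} <= set(self.active_views):
            raise ValueError("active_views must contain at least 'mol' and 's'")
        if self.spectral_representation not in ("formula", "binned"):
            raise ValueError("spectral_representation must be 'formula' or 'binned'")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class LossConfig:
    temperature: float = 0.05
    active_views: tuple[str, ...] = VIEWS

    def __post_init__(self):
        self.active_views = tuple(self.active_views)
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if len(self.active_views) < 2:
            raise ValueError("need at least two active views to contrast")


@dataclass
class TrainConfig:
    epochs: int = 1500
    learning_rate: float = 7.0e-5
    batch_size: int = 64
    temperature: float = 0.05
    seed: int = 0
    adduct_filter: str | None = None  # e.g. "[M+H]+"
    select_best_on_validation: bool = False
    encoder: EncoderConfig = field(default_factory=EncoderConfig)

    def __post_init__(self):
        if isinstance(self.encoder, dict):
            self.encoder = EncoderConfig(**self.encoder)
        for name in ("epochs", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0 or self.temperature <= 0:
            raise ValueError("learning_rate and temperature must be positive")

    @property
    def active_views(self) -> tuple[str, ...]:
        return self.encoder.active_views

    def to_dict(self) -> dict:
        d = asdict(self)
        d["encoder"]["active_views"] = list(self.encoder.active_views)
        return d


@dataclass
class SynthConfig:
    n_molecules: int = 50
    spectra_per_molecule: int = 3
    energies: tuple[float, ...] = (10.0, 20.0, 40.0)
    min_peaks: int = 8
    max_peaks: int = 25
    noise_peak_rate: float = 0.0
    mz_error_ppm: float = 5.0
    intensity_noise_sd: float = 0.5
    candidate_set_size: int = 16
    adduct: str = "[M+H]+"
    seed: int = 0

    def __post_init__(self):
        self.energies = tuple(self.energies)
        if self.n_molecules <= 0 or self.spectra_per_molecule <= 0:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.noise_peak_rate < 1.0:
            raise ValueError("noise_peak_rate must be in [0, 1)")
        if self.min_peaks <= 0 or self.max_peaks < self.min_peaks:
            raise ValueError("invalid peak count range")


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        obj = yaml.safe_load(fh) or {}
    if not isinstance(obj, dict):
        raise ValueError("config YAML must be a mapping")
    return obj
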