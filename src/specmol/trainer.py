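"""End-to-end training: annotation, batching, optimization, checkpointing.

The training contract keeps one spectrum per molecule per batch — a batch of
B distinct molecules, each paired with one uniformly sampled constituent
spectrum and its precomputed split-level consensus — so in-batch negatives
are never spectra of the anchor's own molecule. The element scaler is fit on
the training annotations only and reused unchanged for validation and test
(no statistics leak across splits). Consensus spectra are likewise built
within each split.

Optimization is Adam on the summed pairwise contrastive loss over the active
views; parameters of inactive views never receive gradients and stay at
initialization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .chem import MolecularGraph, MoleculeRecord, featurize_graph, morgan_fingerprint
from .config import LossConfig, TrainConfig
from .contrastive import total_loss_tensor
from .io import Checkpoint
from .nn.model import MultiViewModel
from .nn.optim import Adam
from .spectra import (
    AnnotatedSpectrum,
    ElementScaler,
    RawSpectrum,
    annotate_peaks,
    bin_spectrum,
    build_consensus,
    consensus_to_matrix,
    fit_element_scaler,
    spectrum_to_matrix,
)
from .synthetic import SplitData

logger = logging.getLogger(__name__)


@dataclass
class PreparedDataset:
    """Annotated, vectorized view inputs for one split."""

    molecules: list[MoleculeRecord]
    graphs: list[MolecularGraph]
    fingerprints: np.ndarray                    # (n_mol, 1024)
    annotated: list[list[AnnotatedSpectrum]]    # per molecule
    spectrum_inputs: list[list[np.ndarray]]     # peak matrices or binned vectors
    consensus_inputs: list[np.ndarray]
    scaler: ElementScaler
    representation: str = "formula"
    dropped_molecules: list[str] = field(default_factory=list)

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)


def prepare_split(
    molecules: list[MoleculeRecord],
    spectra_by_mol: dict[str, list[RawSpectrum]],
    scaler: ElementScaler | None = None,
    ppm_tol: float = 20.0,
    max_peaks: int = 60,
    representation: str = "formula",
    bin_width: float = 0.1,
    n_bins: int = 10000,
    adduct_filter: str | None = None,
) -> PreparedDataset:
    """Annotate a split's spectra and assemble per-view model inputs.

    Pass ``scaler=None`` only for the training split (it is fit here);
    validation/test must reuse the training-fit scaler.
    """
    cache: dict = {}
    annotated: list[list[AnnotatedSpectrum]] = []
    kept: list[MoleculeRecord] = []
    kept_raw: list[list[RawSpectrum]] = []
    dropped: list[str] = []
    for mol in molecules:
        raws = spectra_by_mol.get(mol.molecule_id, [])
        if adduct_filter is not None:
            raws = [r for r in raws if r.adduct == adduct_filter]
        anns = [
            a
            for r in raws
            if (a := annotate_peaks(r, mol, ppm_tol, max_peaks, cache)).peaks
        ]
        if not anns:
            dropped.append(mol.molecule_id)
            logger.warning("molecule %s has no annotatable spectra; dropped",
                           mol.molecule_id)
            continue
        kept.append(mol)
        kept_raw.append([r for r in raws])
        annotated.append(anns)
    if not kept:
        raise ValueError("no molecule in this split has annotatable spectra")

    if scaler is None:
        scaler = fit_element_scaler([a for anns in annotated for a in anns])

    graphs = [featurize_graph(m) for m in kept]
    fps = np.stack([morgan_fingerprint(m) for m in kept])

    spectrum_inputs: list[list[np.ndarray]] = []
    consensus_inputs: list[np.ndarray] = []
    if representation == "binned":
        max_mz = bin_width * n_bins
        for raws in kept_raw:
            binned = [bin_spectrum(r, bin_width, max_mz) for r in raws]
            spectrum_inputs.append(binned)
            consensus_inputs.append(np.max(np.stack(binned), axis=0))
    else:
        for anns in annotated:
            spectrum_inputs.append([spectrum_to_matrix(a, scaler) for a in anns])
            consensus_inputs.append(
                consensus_to_matrix(build_consensus(anns), scaler)
            )
    return PreparedDataset(
        kept, graphs, fps, annotated, spectrum_inputs, consensus_inputs,
        scaler, representation, dropped,
    )


def prepare_from_split_data(split: SplitData, scaler: ElementScaler | None = None,
                            **kwargs) -> PreparedDataset:
    return prepare_split(split.molecules, split.spectra, scaler, **kwargs)


def make_batches(
    prep: PreparedDataset, batch_size: int, seed: int, epoch: int
) -> list[list[tuple[int, int]]]:
    """Deterministic epoch batches of (molecule index, spectrum index).

    Molecules are permuted with a generator seeded by (seed, epoch); each
    full batch holds ``batch_size`` distinct molecules with one uniformly
    sampled constituent spectrum each. The trailing partial batch is not
    emitted (a contrastive batch needs its full negative count); permutation
    rotates which molecules sit out each epoch.
    """
    n = prep.n_molecules
    if n < batch_size:
        raise ValueError(
            f"dataset has {n} molecules < batch_size {batch_size}; "
            "use a smaller batch"
        )
    rng = np.random.default_rng([seed, epoch])
    perm = rng.permutation(n)
    batches = []
    for start in range(0, n - batch_size + 1, batch_size):
        idx = perm[start : start + batch_size]
        batch = [
            (int(i), int(rng.integers(len(prep.spectrum_inputs[i])))) for i in idx
        ]
        batches.append(batch)
    return batches


def _batch_views(prep: PreparedDataset, batch, model: MultiViewModel,
                 active_views) -> dict:
    mol_idx = [i for i, _ in batch]
    out = {}
    if "mol" in active_views:
        out["mol"] = model.encode_mol([prep.graphs[i] for i in mol_idx])
    if "fp" in active_views:
        out["fp"] = model.encode_fp(prep.fingerprints[mol_idx])
    if "s" in active_views:
        out["s"] = model.encode_spectrum(
            [prep.spectrum_inputs[i][j] for i, j in batch]
        )
    if "cs" in active_views:
        out["cs"] = model.encode_consensus(
            [prep.consensus_inputs[i] for i in mol_idx]
        )
    return out


def train(
    prep: PreparedDataset,
    config: TrainConfig,
    val_prep: PreparedDataset | None = None,
    log_every: int = 0,
) -> tuple[Checkpoint, list[float]]:
    """Train the four encoders; return a checkpoint and the loss history."""
    model = MultiViewModel(config.encoder, seed=config.seed)
    loss_cfg = LossConfig(config.temperature, config.active_views)
    opt = Adam(model.store, lr=config.learning_rate)
    drop_rng = np.random.default_rng([config.seed, 997])
    history: list[float] = []
    best_val = np.inf
    best_state = None
    for epoch in range(config.epochs):
        batches = make_batches(prep, config.batch_size, config.seed, epoch)
        epoch_losses = []
        for batch in batches:
            model.train_mode(drop_rng)
            embeddings = _batch_views(prep, batch, model, config.active_views)
            loss = total_loss_tensor(embeddings, loss_cfg)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss {loss.data!r} at epoch {epoch}; "
                    "reduce the learning rate or check the inputs"
                )
            model.store.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        model.eval_mode()
        history.append(float(np.mean(epoch_losses)))
        if log_every and epoch % log_every == 0:
            logger.info("epoch %d: loss %.4f", epoch, history[-1])
        if config.select_best_on_validation and val_prep is not None:
            v = evaluate_loss(model, val_prep, config)
            if v < best_val:
                best_val = v
                best_state = model.store.state_dict()
    if best_state is not None:
        model.store.load_state_dict(best_state)
    ckpt = Checkpoint(
        params=model.store.state_dict(),
        scaler=prep.scaler,
        config=config.to_dict(),
        extra={"final_loss": history[-1], "n_epochs": config.epochs},
    )
    return ckpt, history


def evaluate_loss(model: MultiViewModel, prep: PreparedDataset,
                  config: TrainConfig) -> float:
    """Mean contrastive loss over deterministic evaluation batches."""
    model.eval_mode()
    loss_cfg = LossConfig(config.temperature, config.active_views)
    batch_size = min(config.batch_size, prep.n_molecules)
    batches = make_batches(prep, batch_size, seed=0, epoch=0)
    vals = []
    for batch in batches:
        emb = _batch_views(prep, batch, model, config.active_views)
        vals.append(float(total_loss_tensor(emb, loss_cfg).data))
    return float(np.mean(vals))


def model_from_checkpoint(ckpt: Checkpoint) -> MultiViewModel:
    """Rebuild the model (architecture + weights) from a checkpoint."""
    from .config import EncoderConfig

    enc = EncoderConfig(**ckpt.config["encoder"])
    model = MultiViewModel(enc, seed=int(ckpt.config.get("seed", 0)))
    model.store.load_state_dict(ckpt.params)
    model.eval_mode()
    return model
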