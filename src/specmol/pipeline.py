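"""High-level inference: embed queries and candidates, rank, report metrics.

Query spectra are annotated against a parent formula (ground truth during
evaluation; an upstream-assigned formula in production use), embedded with
the spectrum or consensus encoder, and scored against candidate molecule
embeddings under one of the four ranking views.
"""

from __future__ import annotations

import numpy as np

from .chem import MoleculeRecord, featurize_graph, morgan_fingerprint, parse_molecule
from .nn.model import MultiViewModel
from .ranker import RankingTable, ViewEmbedding, rank_candidates
from .spectra import (
    AnnotatedSpectrum,
    ElementScaler,
    build_consensus,
    consensus_to_matrix,
    spectrum_to_matrix,
)
from .trainer import PreparedDataset


def embed_molecules(
    model: MultiViewModel, records: list[MoleculeRecord], view: str
) -> dict[str, ViewEmbedding]:
    """Embed unique molecules under the mol or fp view, keyed by SMILES."""
    if view not in ("mol", "fp"):
        raise ValueError(f"molecular view must be 'mol' or 'fp', got {view!r}")
    unique: dict[str, MoleculeRecord] = {}
    for r in records:
        unique.setdefault(r.smiles, r)
    order = sorted(unique)
    if view == "mol":
        Z = model.embed("mol", [featurize_graph(unique[s]) for s in order])
    else:
        Z = model.embed("fp", np.stack([morgan_fingerprint(unique[s]) for s in order]))
    return {s: ViewEmbedding(Z[i], view) for i, s in enumerate(order)}


def embed_spectrum_query(
    model: MultiViewModel, scaler: ElementScaler, spec: AnnotatedSpectrum
) -> ViewEmbedding:
    Z = model.embed("s", [spectrum_to_matrix(spec, scaler)])
    return ViewEmbedding(Z[0], "s")


def embed_consensus_query(
    model: MultiViewModel, scaler: ElementScaler, spectra: list[AnnotatedSpectrum]
) -> ViewEmbedding:
    cons = build_consensus(spectra)
    Z = model.embed("cs", [consensus_to_matrix(cons, scaler)])
    return ViewEmbedding(Z[0], "cs")


def evaluate_retrieval(
    model: MultiViewModel,
    prep: PreparedDataset,
    candidate_sets: dict[str, list[str]],
    ranking_view: str,
    per_spectrum: bool = False,
) -> list[RankingTable]:
    """Rank every molecule's candidates from its own spectra.

    With a spectral (``*-s``) view and ``per_spectrum=False``, each molecule
    contributes one table per constituent spectrum is avoided by using only
    its first spectrum; ``per_spectrum=True`` yields one table per spectrum
    (the substrate for rank-then-aggregate). Consensus (``*-cs``) views use
    the split-level consensus.
    """
    cand_view, query_view = ranking_view.split("-")
    all_smiles = sorted(
        {s for lst in candidate_sets.values() for s in lst}
    )
    records = [parse_molecule(s) for s in all_smiles]
    cand_emb = embed_molecules(model, records, cand_view)

    tables: list[RankingTable] = []
    for i, mol in enumerate(prep.molecules):
        cands = candidate_sets.get(mol.molecule_id)
        if not cands:
            continue
        cand_list = [(s, cand_emb[parse_molecule(s).smiles]) for s in cands]
        if query_view == "cs":
            queries = [
                (mol.molecule_id,
                 ViewEmbedding(model.embed("cs", [prep.consensus_inputs[i]])[0], "cs"))
            ]
        else:
            mats = prep.spectrum_inputs[i]
            if not per_spectrum:
                mats = mats[:1]
            Z = model.embed("s", mats)
            anns = prep.annotated[i]
            queries = [
                (anns[j].spectrum_id if j < len(anns) else f"{mol.molecule_id}_s{j}",
                 ViewEmbedding(Z[j], "s"))
                for j in range(len(mats))
            ]
        for qid, q in queries:
            tables.append(
                rank_candidates(q, cand_list, ranking_view, query_id=qid,
                                target_smiles=mol.smiles)
            )
    return tables
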