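"""Candidate retrieval: scoring, rank metrics, MCES, and rank aggregation.

A query spectrum (or consensus spectrum) is scored against each candidate
molecule by cosine similarity between their embeddings under one of four
ranking views: mol-s, fp-s, mol-cs, fp-cs (candidate view - query view).
Ranks are 1-based; tied candidates all receive the worst rank of their tie
group, which never flatters the target.

Two paradigms handle multiple spectra of one molecule: aggregate-then-rank
(build the consensus spectrum, rank once) and rank-then-aggregate (rank per
spectrum, then fuse by mean rank or by summed reciprocal rank).

`mces_distance` computes the exact maximum-common-edge-subgraph distance
|E_A| + |E_B| - 2|MCES| by branch-and-bound over edge mappings with strict
label matching (atoms by element, bonds by bond type; aromatic is its own
type). Exact search is exponential, so molecules above `size_cap` heavy
atoms are refused.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .chem import MoleculeRecord, parse_molecule
from .config import RANKING_VIEWS


@dataclass
class ViewEmbedding:
    """An embedding vector tagged with its view of origin."""

    vector: np.ndarray
    view: str  # mol | fp | s | cs

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=np.float64)
        if not np.all(np.isfinite(self.vector)):
            raise ValueError("embedding has non-finite entries")
        if np.linalg.norm(self.vector) == 0:
            raise ValueError("embedding has zero norm")


@dataclass
class RankingTable:
    query_id: str
    ranking_view: str
    entries: list[tuple[str, float, int]]  # (candidate_smiles, score, rank)
    target_smiles: str | None = None

    def rank_of(self, smiles: str) -> int:
        canon = parse_molecule(smiles).smiles
        for cand, _, rank in self.entries:
            if parse_molecule(cand).smiles == canon:
                return rank
        raise KeyError(f"{smiles!r} not in candidate set of query {self.query_id}")

    def target_rank(self) -> int:
        if self.target_smiles is None:
            raise ValueError(f"query {self.query_id} has no target_smiles")
        return self.rank_of(self.target_smiles)


@dataclass
class MetricReport:
    rank_at: dict[int, float]  # k -> percentage in [0, 100]
    mces_at_1: float | None
    n_queries: int


# --- candidate filtering -------------------------------------------------

def filter_candidates_by_mass(
    target_mass: float,
    library: list[MoleculeRecord],
    ppm: float = 10.0,
    cap: int = 256,
) -> list[MoleculeRecord]:
    """Library molecules within ``ppm`` of the target mass, closest first."""
    hits = [
        (abs(m.monoisotopic_mass - target_mass) / target_mass * 1e6, m)
        for m in library
    ]
    hits = [(d, m) for d, m in hits if d <= ppm]
    hits.sort(key=lambda t: (t[0], t[1].smiles))
    return [m for _, m in hits[:cap]]


def filter_candidates_by_formula(
    target_formula: dict[str, int],
    library: list[MoleculeRecord],
    cap: int = 256,
) -> list[MoleculeRecord]:
    """Library molecules whose element-count map equals the target's."""
    target = {e: n for e, n in target_formula.items() if n}
    hits = [m for m in library if {e: n for e, n in m.formula.items() if n} == target]
    hits.sort(key=lambda m: m.smiles)
    return hits[:cap]


# --- scoring -------------------------------------------------------------

def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


def _worst_of_tie_ranks(scores: list[float]) -> list[int]:
    """1-based ranks, descending score; ties share the worst rank."""
    arr = np.asarray(scores)
    return [int(np.sum(arr > s) + np.sum(arr == s)) for s in arr]


def rank_candidates(
    query_embedding: ViewEmbedding,
    candidate_embeddings: list[tuple[str, ViewEmbedding]],
    ranking_view: str,
    query_id: str = "query",
    target_smiles: str | None = None,
) -> RankingTable:
    """Score candidates by cosine similarity under a ranking view."""
    if ranking_view not in RANKING_VIEWS:
        raise ValueError(f"unknown ranking view {ranking_view!r}; use {RANKING_VIEWS}")
    cand_view, query_view = ranking_view.split("-")
    if query_embedding.view != query_view:
        raise ValueError(
            f"ranking view {ranking_view} expects a {query_view!r} query, "
            f"got {query_embedding.view!r}"
        )
    if not candidate_embeddings:
        raise ValueError("empty candidate set")
    for smiles, emb in candidate_embeddings:
        if emb.view != cand_view:
            raise ValueError(
                f"ranking view {ranking_view} expects {cand_view!r} candidates, "
                f"got {emb.view!r} for {smiles}"
            )
    scores = [
        _cosine(query_embedding.vector, emb.vector)
        for _, emb in candidate_embeddings
    ]
    ranks = _worst_of_tie_ranks(scores)
    entries = sorted(
        zip((s for s, _ in candidate_embeddings), scores, ranks),
        key=lambda t: (t[2], t[0]),
    )
    return RankingTable(query_id, ranking_view, list(entries), target_smiles)


# --- metrics -------------------------------------------------------------

def rank_at_k(tables: list[RankingTable], ks: tuple[int, ...] = (1, 5, 20)) -> MetricReport:
    """Percentage of queries whose target ranks within the top k."""
    if not tables:
        raise ValueError("rank_at_k requires at least one ranking table")
    target_ranks = [t.target_rank() for t in tables]
    rank_at = {
        k: 100.0 * sum(r <= k for r in target_ranks) / len(target_ranks) for k in ks
    }
    return MetricReport(rank_at=rank_at, mces_at_1=None, n_queries=len(tables))


def mces_at_1(tables: list[RankingTable], size_cap: int = 20) -> float:
    """Mean MCES distance between each target and its rank-1 candidate."""
    if not tables:
        raise ValueError("mces_at_1 requires at least one ranking table")
    dists = []
    for t in tables:
        if t.target_smiles is None:
            raise ValueError(f"query {t.query_id} has no target_smiles")
        top = parse_molecule(t.entries[0][0])
        dists.append(mces_distance(parse_molecule(t.target_smiles), top, size_cap))
    return float(np.mean(dists))


def normalized_rank_difference(tables_for_one_molecule: list[RankingTable]) -> float:
    """Range of the target's ranks across spectra / number of candidates."""
    if not tables_for_one_molecule:
        raise ValueError("need at least one ranking table")
    n_cand = len(tables_for_one_molecule[0].entries)
    ranks = [t.target_rank() for t in tables_for_one_molecule]
    return (max(ranks) - min(ranks)) / n_cand


# --- rank aggregation ----------------------------------------------------

def _common_candidates(tables: list[RankingTable]) -> list[str]:
    if not tables:
        raise ValueError("no ranking tables to aggregate")
    sets = [frozenset(s for s, _, _ in t.entries) for t in tables]
    if len(set(sets)) != 1:
        raise ValueError("tables must share one candidate set for aggregation")
    return sorted(sets[0])


def aggregate_average_rank(per_spectrum_tables: list[RankingTable]) -> RankingTable:
    """Fuse per-spectrum rankings by ascending mean rank.

    The stored score is the negated mean rank so that, as in every table,
    rank 1 carries the maximal score.
    """
    cands = _common_candidates(per_spectrum_tables)
    rank_maps = [dict((s, r) for s, _, r in t.entries) for t in per_spectrum_tables]
    scores = [-float(np.mean([m[c] for m in rank_maps])) for c in cands]
    ranks = _worst_of_tie_ranks(scores)
    entries = sorted(zip(cands, scores, ranks), key=lambda t: (t[2], t[0]))
    first = per_spectrum_tables[0]
    return RankingTable(first.query_id, first.ranking_view, list(entries),
                        first.target_smiles)


def aggregate_reciprocal_rank(per_spectrum_tables: list[RankingTable]) -> RankingTable:
    """Fuse per-spectrum rankings by summed reciprocal rank (higher better)."""
    cands = _common_candidates(per_spectrum_tables)
    rank_maps = [dict((s, r) for s, _, r in t.entries) for t in per_spectrum_tables]
    scores = [float(sum(1.0 / m[c] for m in rank_maps)) for c in cands]
    ranks = _worst_of_tie_ranks(scores)
    entries = sorted(zip(cands, scores, ranks), key=lambda t: (t[2], t[0]))
    first = per_spectrum_tables[0]
    return RankingTable(first.query_id, first.ranking_view, list(entries),
                        first.target_smiles)


# --- exact MCES ----------------------------------------------------------

def _labeled_edges(smiles: str) -> tuple[list[str], list[tuple[int, int, str]]]:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES {smiles!r}")
    atoms = [a.GetSymbol() for a in mol.GetAtoms()]
    edges = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), str(b.GetBondType()))
        for b in mol.GetBonds()
    ]
    return atoms, edges


def mces_size(
    atoms_a: list[str],
    edges_a: list[tuple[int, int, str]],
    atoms_b: list[str],
    edges_b: list[tuple[int, int, str]],
) -> int:
    """Size (edge count) of the maximum common edge subgraph.

    Branch-and-bound: edges of A are considered in order; each is either
    mapped to an unused, label-compatible edge of B consistently with the
    partial vertex map, or skipped. Prunes when the optimistic bound
    (current + remaining) cannot beat the incumbent.
    """
    if len(edges_a) > len(edges_b):  # recurse on the smaller edge set
        atoms_a, edges_a, atoms_b, edges_b = atoms_b, edges_b, atoms_a, edges_a
    mA = len(edges_a)
    best = 0
    fwd: dict[int, int] = {}
    rev: dict[int, int] = {}
    used_b = [False] * len(edges_b)

    def consistent(a: int, b: int) -> bool:
        if a in fwd:
            return fwd[a] == b
        return b not in rev and atoms_a[a] == atoms_b[b]

    def assign(a: int, b: int) -> bool:
        if a in fwd:
            return False
        fwd[a] = b
        rev[b] = a
        return True

    def search(i: int, count: int) -> None:
        nonlocal best
        if count > best:
            best = count
        if i == mA or count + (mA - i) <= best:
            return
        u, v, lab = edges_a[i]
        for j, (x, y, lab_b) in enumerate(edges_b):
            if used_b[j] or lab != lab_b:
                continue
            for p, q in ((x, y), (y, x)):
                if consistent(u, p) and consistent(v, q) and not (
                    u not in fwd and v not in fwd and p == q
                ):
                    added = []
                    if u not in fwd:
                        assign(u, p)
                        added.append(u)
                    if v not in fwd:
                        if assign(v, q):
                            added.append(v)
                        else:  # u==v impossible; q collided via added u
                            for a in added:
                                rev.pop(fwd.pop(a))
                            continue
                    used_b[j] = True
                    search(i + 1, count + 1)
                    used_b[j] = False
                    for a in added:
                        rev.pop(fwd.pop(a))
        search(i + 1, count)  # skip edge i

    search(0, 0)
    return best


def mces_distance(
    mol_a: MoleculeRecord, mol_b: MoleculeRecord, size_cap: int = 20
) -> int:
    """Exact MCES distance |E_A| + |E_B| - 2|MCES| on small molecules."""
    for m in (mol_a, mol_b):
        if m.heavy_atom_count() > size_cap:
            raise ValueError(
                f"molecule {m.molecule_id} has {m.heavy_atom_count()} heavy atoms "
                f"(> size_cap {size_cap}); exact MCES search is exponential — "
                "use the benchmark's approximate tooling for large molecules"
            )
    atoms_a, edges_a = _labeled_edges(mol_a.smiles)
    atoms_b, edges_b = _labeled_edges(mol_b.smiles)
    common = mces_size(atoms_a, edges_a, atoms_b, edges_b)
    return len(edges_a) + len(edges_b) - 2 * common
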