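"""Ranking, metrics, aggregation, and exact MCES vs exhaustive oracles."""

import itertools

import numpy as np
import pytest

from specmol.chem import parse_molecule
from specmol.ranker import (
    RankingTable,
    ViewEmbedding,
    aggregate_average_rank,
    aggregate_reciprocal_rank,
    filter_candidates_by_formula,
    filter_candidates_by_mass,
    mces_distance,
    normalized_rank_difference,
    rank_at_k,
    rank_candidates,
    _labeled_edges,
)


@pytest.fixture(scope="module")
def library():
    return [parse_molecule(s) for s in
            ("OCC1OC(O)C(O)C(O)C1O",      # glucose C6H12O6
             "OCC1(O)OCC(O)C(O)C1O",      # fructose C6H12O6
             "OCC1OC(O)C(O)C1O",          # C5H10O5
             "CCO", "CC(=O)O")]


class TestCandidateFilters:

    def test_exact_mass_included_11ppm_excluded(self, library):
        target = 180.063388
        hits = filter_candidates_by_mass(target, library, ppm=10)
        assert {m.smiles for m in hits} == {
            parse_molecule("OCC1OC(O)C(O)C(O)C1O").smiles,
            parse_molecule("OCC1(O)OCC(O)C(O)C1O").smiles,
        }
        # a candidate 11 ppm away must be excluded
        shifted = target * (1 + 11e-6)
        assert filter_candidates_by_mass(shifted, library[:1], ppm=10) == []

    def test_cap(self, library):
        many = library[:1] * 300  # 300 qualifying entries
        hits = filter_candidates_by_mass(180.063388, many, ppm=10, cap=256)
        assert len(hits) == 256

    def test_formula_isomers(self, library):
        target = parse_molecule("OCC1OC(O)C(O)C(O)C1O")
        hits = filter_candidates_by_formula(target.formula, library)
        assert {m.smiles for m in hits} == {
            parse_molecule("OCC1OC(O)C(O)C(O)C1O").smiles,
            parse_molecule("OCC1(O)OCC(O)C(O)C1O").smiles,
        }
        assert filter_candidates_by_formula({"C": 6, "H": 12, "O": 5}, library) == []
        assert filter_candidates_by_formula(target.formula, []) == []


def _emb(vec, view):
    return ViewEmbedding(np.asarray(vec, dtype=float), view)


class TestRankCandidates:
    def test_scaled_copy_ranks_first(self):
        q = _emb([1.0, 2.0, 0.5], "s")
        cands = [("A", _emb([2.0, 4.0, 1.0], "mol")),
                 ("B", _emb([-1.0, 0.0, 3.0], "mol"))]
        t = rank_candidates(q, cands, "mol-s")
        assert t.entries[0][0] == "A"
        assert t.entries[0][1] == pytest.approx(1.0)
        assert t.entries[0][2] == 1

    def test_ties_share_worst_rank(self):
        q = _emb([1.0, 0.0], "s")
        cands = [("A", _emb([2.0, 0.0], "mol")), ("B", _emb([5.0, 0.0], "mol"))]
        t = rank_candidates(q, cands, "mol-s")
        assert [e[2] for e in t.entries] == [2, 2]

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(0)
        q = _emb(rng.normal(size=6), "cs")
        cands = [(f"c{i}", _emb(rng.normal(size=6), "fp")) for i in range(5)]
        t = rank_candidates(q, cands, "fp-cs")
        # brute-force oracle: cosine scores, descending sort, worst-of-tie
        qv = q.vector / np.linalg.norm(q.vector)
        scores = {
            s: float(qv @ (e.vector / np.linalg.norm(e.vector))) for s, e in cands
        }
        for smiles, score, rank in t.entries:
            assert score == pytest.approx(scores[smiles], rel=1e-12)
            oracle_rank = sum(v > scores[smiles] for v in scores.values()) + \
                sum(v == scores[smiles] for v in scores.values())
            assert rank == oracle_rank

    def test_view_mismatch_errors(self):
        q = _emb([1.0, 0.0], "s")
        with pytest.raises(ValueError, match="query"):
            rank_candidates(_emb([1.0], "mol"), [("A", _emb([1.0], "mol"))], "mol-s")
        with pytest.raises(ValueError, match="candidates"):
            rank_candidates(q, [("A", _emb([1.0, 0.0], "fp"))], "mol-s")

    def test_rescaling_leaves_ranks_unchanged(self):
        rng = np.random.default_rng(1)
        q = _emb(rng.normal(size=4), "s")
        cands = [(f"c{i}", _emb(rng.normal(size=4), "mol")) for i in range(6)]
        t1 = rank_candidates(q, cands, "mol-s")
        q2 = _emb(q.vector * 11.0, "s")
        cands2 = [(s, _emb(e.vector * (0.1 + i), "mol"))
                  for i, (s, e) in enumerate(cands)]
        t2 = rank_candidates(q2, cands2, "mol-s")
        assert [(s, r) for s, _, r in t1.entries] == [(s, r) for s, _, r in t2.entries]


def _table(qid, ranked_smiles, target=None, view="mol-s"):
    n = len(ranked_smiles)
    entries = [(s, float(n - i), i + 1) for i, s in enumerate(ranked_smiles)]
    return RankingTable(qid, view, entries, target)


class TestRankAtK:
    def test_all_rank_one(self):
        tables = [_table(f"q{i}", ["C", "CC", "CCC"], target="C") for i in range(4)]
        rep = rank_at_k(tables)
        assert rep.rank_at == {1: 100.0, 5: 100.0, 20: 100.0}

    def test_mixed_ranks(self):
        smiles = [f"{'C' * (i + 1)}" for i in range(25)]
        ranks = [1, 6, 21]
        tables = [_table(f"q{r}", smiles, target=smiles[r - 1]) for r in ranks]
        rep = rank_at_k(tables)
        assert rep.rank_at[1] == pytest.approx(100 / 3)
        assert rep.rank_at[5] == pytest.approx(100 / 3)
        assert rep.rank_at[20] == pytest.approx(200 / 3)

    def test_monotone_in_k_and_full_coverage(self):
        rng = np.random.default_rng(2)
        smiles = [f"{'C' * (i + 1)}O" for i in range(10)]
        tables = []
        for i in range(8):
            order = [smiles[j] for j in rng.permutation(10)]
            tables.append(_table(f"q{i}", order, target=smiles[0]))
        rep = rank_at_k(tables, ks=(1, 2, 5, 10))
        vals = [rep.rank_at[k] for k in (1, 2, 5, 10)]
        assert vals == sorted(vals)
        assert rep.rank_at[10] == 100.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            rank_at_k([])


class TestAggregation:
    def test_average_rank_example(self):
        # candidate A ranked [1,3,2] across three spectra -> mean 2.0
        tables = [
            _table("q", order, target="A")
            for order in (["A", "B", "C"], ["B", "C", "A"], ["B", "A", "C"])
        ]
        agg = aggregate_average_rank(tables)
        means = {s: -score for s, score, _ in agg.entries}
        assert means["A"] == pytest.approx(2.0)

    def test_reciprocal_rank_example(self):
        tables = [
            _table("q", order)
            for order in (["A", "B", "C"], ["B", "C", "A"], ["B", "A", "C"])
        ]
        agg = aggregate_reciprocal_rank(tables)
        scores = {s: score for s, score, _ in agg.entries}
        assert scores["A"] == pytest.approx(1 + 1 / 3 + 1 / 2)

    def test_always_first_candidate_wins_reciprocal(self):
        tables = [_table(f"q{i}", ["W", "X", "Y", "Z"]) for i in range(5)]
        agg = aggregate_reciprocal_rank(tables)
        assert agg.entries[0][0] == "W" and agg.entries[0][1] == pytest.approx(5.0)

    @pytest.mark.parametrize("agg_fn",
                             [aggregate_average_rank, aggregate_reciprocal_rank])
    def test_fixed_point_when_all_agree(self, agg_fn):
        tables = [_table(f"q{i}", ["A", "B", "C", "D"]) for i in range(3)]
        agg = agg_fn(tables)
        assert [s for s, _, _ in agg.entries] == ["A", "B", "C", "D"]
        assert [r for _, _, r in agg.entries] == [1, 2, 3, 4]

    @pytest.mark.parametrize("agg_fn,better",
                             [(aggregate_average_rank, min),
                              (aggregate_reciprocal_rank, max)])
    def test_random_instances_match_brute_force(self, agg_fn, better):
        rng = np.random.default_rng(5)
        cands = ["A", "B", "C", "D"]
        for _ in range(10):
            tables = []
            for q in range(3):
                order = [cands[i] for i in rng.permutation(4)]
                tables.append(_table(f"q{q}", order))
            agg = agg_fn(tables)
            rank_maps = [{s: r for s, _, r in t.entries} for t in tables]
            if agg_fn is aggregate_average_rank:
                key = {c: np.mean([m[c] for m in rank_maps]) for c in cands}
                oracle = {c: 1 + sum(key[o] < key[c] for o in cands)
                          + sum(key[o] == key[c] for o in cands) - 1 for c in cands}
            else:
                key = {c: sum(1 / m[c] for m in rank_maps) for c in cands}
                oracle = {c: sum(key[o] > key[c] for o in cands)
                          + sum(key[o] == key[c] for o in cands) for c in cands}
            got = {s: r for s, _, r in agg.entries}
            assert got == oracle

    def test_mismatched_candidate_sets_error(self):
        with pytest.raises(ValueError, match="candidate set"):
            aggregate_average_rank([_table("q", ["A", "B"]), _table("q", ["A", "C"])])


class TestNormalizedRankDifference:
    def test_constant_ranks(self):
        smiles = [f"{'C' * (i + 1)}" for i in range(6)]
        tables = [_table(f"q{i}", smiles, target=smiles[4]) for i in range(3)]
        assert normalized_rank_difference(tables) == 0.0

    def test_range_over_candidates(self):
        smiles = [f"{'C' * (i + 1)}" for i in range(20)]
        t1 = _table("q1", smiles, target=smiles[0])            # rank 1
        order = smiles[1:11] + [smiles[0]] + smiles[11:]       # rank 11
        t2 = _table("q2", order, target=smiles[0])
        assert normalized_rank_difference([t1, t2]) == pytest.approx(0.5)

    def test_single_spectrum_degenerate(self):
        smiles = ["C", "CC"]
        assert normalized_rank_difference([_table("q", smiles, target="C")]) == 0.0


# --- MCES ----------------------------------------------------------------

from tests_support_mces import oracle_mces_size  # noqa: E402

MCES_FIXTURES = [
    "C",            # methane
    "CC",           # ethane
    "CCO",          # ethanol
    "CC=O",         # acetaldehyde
    "CC(=O)O",      # acetic acid
    "CCC",          # propane
    "C1CC1",        # cyclopropane
    "C1CCC1",       # cyclobutane
    "c1ccccc1",     # benzene
    "C1CCOC1",      # THF
    "CC(C)=O",      # acetone
    "NCCO",         # ethanolamine
]


class TestMces:
    def test_identical_molecules_zero(self):
        m = parse_molecule("CC(=O)O")
        assert mces_distance(m, m) == 0

    def test_ethane_vs_ethanol(self):
        # common C-C edge: 1 + 2 - 2*1 = 1
        assert mces_distance(parse_molecule("CC"), parse_molecule("CCO")) == 1

    def test_methane_vs_ethane(self):
        # MCES is empty: 0 + 1 - 0 = 1
        assert mces_distance(parse_molecule("C"), parse_molecule("CC")) == 1

    def test_size_cap_refused(self):
        big = parse_molecule("C" * 25)
        with pytest.raises(ValueError, match="size_cap"):
            mces_distance(big, big, size_cap=20)

    def test_symmetry_and_oracle_on_fixture_pairs(self):
        """Exact search agrees with exhaustive enumeration on all 66 pairs."""
        mols = [parse_molecule(s) for s in MCES_FIXTURES]
        for a, b in itertools.combinations(range(len(mols)), 2):
            d_ab = mces_distance(mols[a], mols[b])
            d_ba = mces_distance(mols[b], mols[a])
            assert d_ab == d_ba
            _, ea = _labeled_edges(mols[a].smiles)
            _, eb = _labeled_edges(mols[b].smiles)
            expected = len(ea) + len(eb) - 2 * oracle_mces_size(
                mols[a].smiles, mols[b].smiles
            )
            assert d_ab == expected, (MCES_FIXTURES[a], MCES_FIXTURES[b])

    def test_zero_iff_isomorphic_labeled_edges(self):
        a = parse_molecule("OCC")   # same molecule, different spelling
        b = parse_molecule("CCO")
        assert mces_distance(a, b) == 0
        c = parse_molecule("CC=O")  # same atoms, different bond label
        assert mces_distance(a, c) > 0
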