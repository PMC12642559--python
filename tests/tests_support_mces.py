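"""Independent exhaustive MCES oracle used by the test suite.

Enumerates edge subsets of the smaller molecule (largest first) and checks
labeled monomorphism into the other molecule with networkx — a completely
different route from the package's branch-and-bound search.
"""

import itertools

import networkx as nx

from specmol.ranker import _labeled_edges


def oracle_mces_size(smiles_a: str, smiles_b: str) -> int:
    atoms_a, edges_a = _labeled_edges(smiles_a)
    atoms_b, edges_b = _labeled_edges(smiles_b)
    if len(edges_a) > len(edges_b):
        atoms_a, edges_a, atoms_b, edges_b = atoms_b, edges_b, atoms_a, edges_a
    G_b = nx.Graph()
    for i, sym in enumerate(atoms_b):
        G_b.add_node(i, elem=sym)
    for u, v, lab in edges_b:
        G_b.add_edge(u, v, bond=lab)
    nm = nx.algorithms.isomorphism.categorical_node_match("elem", None)
    em = nx.algorithms.isomorphism.categorical_edge_match("bond", None)
    for k in range(len(edges_a), 0, -1):
        for subset in itertools.combinations(edges_a, k):
            H = nx.Graph()
            for u, v, lab in subset:
                H.add_node(u, elem=atoms_a[u])
                H.add_node(v, elem=atoms_a[v])
                H.add_edge(u, v, bond=lab)
            gm = nx.algorithms.isomorphism.GraphMatcher(
                G_b, H, node_match=nm, edge_match=em
            )
            if gm.subgraph_is_monomorphic():
                return k
    return 0


def oracle_mces_distance(smiles_a: str, smiles_b: str) -> int:
    _, ea = _labeled_edges(smiles_a)
    _, eb = _labeled_edges(smiles_b)
    return len(ea) + len(eb) - 2 * oracle_mces_size(smiles_a, smiles_b)
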