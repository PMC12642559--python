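"""Molecular views: parsing, graph featurization, Morgan fingerprints.

The element universe is the 14-element set E = {C, H, O, N, P, S, Cl, F, Br,
I, B, As, Si, Se}; molecules containing any other element are rejected up
front because fragment-peak vectors cannot represent them downstream.

The graph feature layout is frozen and versioned (FEATURE_VERSION): node rows
encode atom type (one-hot over E plus an "other" bucket), atomic mass,
valence, ring membership, formal charge, radical electrons, chirality
(one-hot), degree, hydrogen count and aromaticity; edge rows encode bond
type (one-hot), ring membership, conjugation and stereo configuration
(one-hot). Numeric features are min-max scaled by fixed constants so the
featurization is dataset-independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

#: Fixed element order used by peak vectors and the atom-type one-hot block.
ELEMENTS: tuple[str, ...] = (
    "C", "H", "O", "N", "P", "S", "Cl", "F", "Br", "I", "B", "As", "Si", "Se",
)

ELEMENT_INDEX = {e: i for i, e in enumerate(ELEMENTS)}

#: Monoisotopic masses (Da) of the supported elements.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "O": 15.9949146196,
    "N": 14.0030740048,
    "P": 30.97376163,
    "S": 31.97207100,
    "Cl": 34.96885268,
    "F": 18.99840322,
    "Br": 78.9183371,
    "I": 126.904473,
    "B": 11.0093054,
    "As": 74.9215965,
    "Si": 27.9769265325,
    "Se": 79.9165213,
}

#: Ion mass offsets (Da) added to a neutral fragment/molecule mass to get the
#: observed m/z for each supported adduct (proton, sodium-minus-electron).
ADDUCT_MASS: dict[str, float] = {
    "[M+H]+": 1.007276,
    "[M+Na]+": 22.989218,
}

SUPPORTED_ADDUCTS = tuple(ADDUCT_MASS)

FEATURE_VERSION = "graph-feat-v1"


class UnsupportedElementError(ValueError):
    """Molecule contains an element outside the supported 14-element set."""


class MoleculeParseError(ValueError):
    """SMILES string could not be parsed."""


@dataclass(frozen=True)
class MoleculeRecord:
    """A molecule with identity, canonical structure, formula and mass."""

    molecule_id: str
    smiles: str
    formula: dict[str, int]
    monoisotopic_mass: float

    def heavy_atom_count(self) -> int:
        return sum(v for e, v in self.formula.items() if e != "H")


@dataclass
class MolecularGraph:
    """Featurized molecular graph (undirected; hydrogens implicit)."""

    node_features: np.ndarray          # (n_atoms, NODE_DIM)
    edge_index: np.ndarray             # (n_bonds, 2) int
    edge_features: np.ndarray          # (n_bonds, EDGE_DIM)
    feature_version: str = field(default=FEATURE_VERSION)


def formula_mass(formula: dict[str, int]) -> float:
    """Neutral monoisotopic mass (Da) of an element-count map."""
    return float(sum(MONOISOTOPIC_MASS[e] * n for e, n in formula.items()))


def formula_to_string(formula: dict[str, int]) -> str:
    """Hill-order formula string, e.g. {C:2,H:4,O:2} -> 'C2H4O2'."""
    parts = []
    for e in ELEMENTS:
        n = formula.get(e, 0)
        if n > 0:
            parts.append(e if n == 1 else f"{e}{n}")
    return "".join(parts)


def parse_formula(s: str) -> dict[str, int]:
    """Inverse of :func:`formula_to_string` (element symbols then counts)."""
    import re

    out: dict[str, int] = {}
    for sym, num in re.findall(r"([A-Z][a-z]?)(\d*)", s):
        if not sym:
            continue
        if sym not in ELEMENT_INDEX:
            raise UnsupportedElementError(f"element {sym} not in supported set")
        out[sym] = out.get(sym, 0) + (int(num) if num else 1)
    return out


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeParseError(f"unparseable SMILES: {smiles!r}")
    return mol


def parse_molecule(smiles: str, molecule_id: str | None = None) -> MoleculeRecord:
    """Parse a SMILES string into a :class:`MoleculeRecord`.

    The SMILES is canonicalized with RDKit; the formula map is restricted to
    the supported element set and the monoisotopic mass is computed from the
    internal mass table (so peaks and molecules share one mass scale).
    """
    if not smiles:
        raise MoleculeParseError("empty SMILES string")
    mol = _mol_from_smiles(smiles)
    canonical = Chem.MolToSmiles(mol)
    formula: dict[str, int] = {}
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym not in ELEMENT_INDEX:
            raise UnsupportedElementError(
                f"element {sym} not in supported set {{{','.join(ELEMENTS)}}}"
            )
        formula[sym] = formula.get(sym, 0) + 1
        h = atom.GetTotalNumHs()
        if h:
            formula["H"] = formula.get("H", 0) + h
    return MoleculeRecord(
        molecule_id=molecule_id or canonical,
        smiles=canonical,
        formula=formula,
        monoisotopic_mass=formula_mass(formula),
    )


# --- graph featurization -------------------------------------------------

_CHIRALITY = (
    Chem.ChiralType.CHI_UNSPECIFIED,
    Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
    Chem.ChiralType.CHI_OTHER,
)
_BOND_TYPES = (
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
)
_BOND_STEREO = (
    Chem.BondStereo.STEREONONE,
    Chem.BondStereo.STEREOZ,
    Chem.BondStereo.STEREOE,
    Chem.BondStereo.STEREOCIS,
    Chem.BondStereo.STEREOTRANS,
    Chem.BondStereo.STEREOANY,
)

# atom type (14 + other) | mass | valence | in-ring | charge | radicals |
# chirality (4) | degree | num H | aromatic
NODE_DIM = len(ELEMENTS) + 1 + 1 + 1 + 1 + 1 + 1 + len(_CHIRALITY) + 1 + 1 + 1
# bond type (4) | in-ring | conjugated | stereo (6)
EDGE_DIM = len(_BOND_TYPES) + 1 + 1 + len(_BOND_STEREO)

# fixed min-max scaling constants for numeric node features
_MASS_SCALE = 130.0   # heaviest supported element ~127
_VALENCE_SCALE = 8.0
_CHARGE_SHIFT, _CHARGE_SCALE = 2.0, 4.0
_RADICAL_SCALE = 4.0
_DEGREE_SCALE = 6.0
_NUMH_SCALE = 8.0


def _atom_row(atom: Chem.Atom) -> np.ndarray:
    row = np.zeros(NODE_DIM, dtype=np.float64)
    sym = atom.GetSymbol()
    idx = ELEMENT_INDEX.get(sym, len(ELEMENTS))
    row[idx] = 1.0
    o = len(ELEMENTS) + 1
    row[o + 0] = atom.GetMass() / _MASS_SCALE
    row[o + 1] = atom.GetTotalValence() / _VALENCE_SCALE
    row[o + 2] = 1.0 if atom.IsInRing() else 0.0
    row[o + 3] = (atom.GetFormalCharge() + _CHARGE_SHIFT) / _CHARGE_SCALE
    row[o + 4] = atom.GetNumRadicalElectrons() / _RADICAL_SCALE
    chi = o + 5 + _CHIRALITY.index(atom.GetChiralTag())
    row[chi] = 1.0
    o2 = o + 5 + len(_CHIRALITY)
    row[o2 + 0] = atom.GetDegree() / _DEGREE_SCALE
    row[o2 + 1] = atom.GetTotalNumHs() / _NUMH_SCALE
    row[o2 + 2] = 1.0 if atom.GetIsAromatic() else 0.0
    return row


def _bond_row(bond: Chem.Bond) -> np.ndarray:
    row = np.zeros(EDGE_DIM, dtype=np.float64)
    try:
        row[_BOND_TYPES.index(bond.GetBondType())] = 1.0
    except ValueError:
        pass  # exotic bond types leave the one-hot block empty
    row[len(_BOND_TYPES) + 0] = 1.0 if bond.IsInRing() else 0.0
    row[len(_BOND_TYPES) + 1] = 1.0 if bond.GetIsConjugated() else 0.0
    row[len(_BOND_TYPES) + 2 + _BOND_STEREO.index(bond.GetStereo())] = 1.0
    return row


def featurize_graph(mol: MoleculeRecord) -> MolecularGraph:
    """Featurize a molecule as an undirected graph with implicit hydrogens."""
    rdmol = _mol_from_smiles(mol.smiles)
    n = rdmol.GetNumAtoms()
    if n == 0:
        raise MoleculeParseError(f"molecule {mol.molecule_id} has no heavy atoms")
    nodes = np.stack([_atom_row(a) for a in rdmol.GetAtoms()])
    bonds = list(rdmol.GetBonds())
    if bonds:
        edge_index = np.array(
            [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in bonds], dtype=np.int64
        )
        edge_feat = np.stack([_bond_row(b) for b in bonds])
    else:
        edge_index = np.zeros((0, 2), dtype=np.int64)
        edge_feat = np.zeros((0, EDGE_DIM), dtype=np.float64)
    return MolecularGraph(nodes, edge_index, edge_feat)


def morgan_fingerprint(
    mol: MoleculeRecord, nbits: int = 1024, radius: int = 5
) -> np.ndarray:
    """Binary Morgan (circular) fingerprint of the canonical structure.

    Deterministic function of the structure: any SMILES spelling of the same
    molecule yields the identical bit vector.
    """
    rdmol = _mol_from_smiles(mol.smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    fp = gen.GetFingerprint(rdmol)
    arr = np.zeros(nbits, dtype=np.float64)
    for bit in fp.GetOnBits():
        arr[bit] = 1.0
    return arr
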