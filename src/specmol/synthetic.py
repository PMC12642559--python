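"""Synthetic molecule libraries and in-silico fragmentation spectra.

The generator emulates the statistical structure the model assumes: a
library of small C/H/O/N/S molecules, several noisy spectra per molecule at
pseudo-collision-energies, and every true peak carrying a genuine subformula
of its parent. Fragments are sampled as *connected subgraphs* of the
molecular graph — not random subformulas — so spectra carry structural
signal the graph view can exploit. Higher pseudo-energy shifts the fragment
size distribution toward smaller fragments, mimicking harder collisions.

All randomness flows from a single seeded generator per dataset with a
documented draw order (library, then spectra molecule-by-molecule in library
order, energy-by-energy), so fixtures are exactly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .chem import ADDUCT_MASS, MoleculeRecord, formula_mass, parse_molecule
from .config import SynthConfig
from .spectra import RawSpectrum

_CORES = ("", "", "c1ccccc1", "C1CCCCC1", "C1CCOC1", "c1ccncc1", "C1CCNC1")
_ELEM_CHOICES = ("C", "O", "N", "S")
_ELEM_P = (0.60, 0.18, 0.14, 0.08)


def _grow_random_molecule(rng: np.random.Generator) -> str | None:
    """One attempt at a random valid molecule; None if sanitization fails."""
    core = _CORES[int(rng.integers(len(_CORES)))]
    if core:
        rw = Chem.RWMol(Chem.MolFromSmiles(core))
    else:
        rw = Chem.RWMol()
        rw.AddAtom(Chem.Atom("C"))
    rw.UpdatePropertyCache(strict=False)
    n_extra = int(rng.integers(3, 9))
    for _ in range(n_extra):
        sites = [a.GetIdx() for a in rw.GetAtoms() if a.GetTotalNumHs() > 0]
        if not sites:
            break
        i = int(rng.choice(sites))
        sym = str(rng.choice(_ELEM_CHOICES, p=_ELEM_P))
        order = Chem.BondType.SINGLE
        at = rw.GetAtomWithIdx(i)
        if (
            sym == "O"
            and at.GetSymbol() == "C"
            and at.GetTotalNumHs() >= 2
            and rng.random() < 0.25
        ):
            order = Chem.BondType.DOUBLE
        j = rw.AddAtom(Chem.Atom(sym))
        rw.AddBond(i, j, order)
        rw.UpdatePropertyCache(strict=False)
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    if mol.GetNumAtoms() < 4:
        return None
    return Chem.MolToSmiles(mol)


def generate_library(config: SynthConfig) -> list[MoleculeRecord]:
    """Seeded library of unique molecules (>= 4 heavy atoms, C/H/O/N/S)."""
    rng = np.random.default_rng(config.seed)
    seen: set[str] = set()
    records: list[MoleculeRecord] = []
    attempts = 0
    max_attempts = config.n_molecules * 400
    while len(records) < config.n_molecules and attempts < max_attempts:
        attempts += 1
        smi = _grow_random_molecule(rng)
        if smi is None or smi in seen:
            continue
        seen.add(smi)
        records.append(parse_molecule(smi, molecule_id=f"M{len(records):04d}"))
    if len(records) < config.n_molecules:
        raise ValueError(
            f"grammar exhausted after {attempts} attempts: produced "
            f"{len(records)} unique molecules, requested {config.n_molecules}"
        )
    return records


def _connected_fragment(
    neighbors: list[list[int]], size: int, rng: np.random.Generator
) -> list[int]:
    """Uniform-ish random connected subgraph of the given size (frontier growth)."""
    n = len(neighbors)
    start = int(rng.integers(n))
    chosen = {start}
    frontier = set(neighbors[start])
    while len(chosen) < size and frontier:
        nxt = int(rng.choice(sorted(frontier)))
        chosen.add(nxt)
        frontier.discard(nxt)
        frontier.update(v for v in neighbors[nxt] if v not in chosen)
    return sorted(chosen)


def fragment_molecule(
    mol: MoleculeRecord,
    energy: float,
    rng: np.random.Generator,
    config: SynthConfig,
    spectrum_id: str | None = None,
) -> RawSpectrum:
    """Simulate one MS/MS spectrum of a molecule at a pseudo-collision-energy.

    True peaks come from connected heavy-atom subgraphs, so each carries a
    genuine parent subformula; hydrogens are those of the fragment atoms plus
    one per cut bond (clamped to the parent's hydrogen count). m/z error is
    Gaussian in ppm, clipped to ±15 ppm so every true peak stays inside the
    20 ppm annotation window; uniform-m/z noise peaks are added at
    ``noise_peak_rate`` per true peak.
    """
    rdmol = Chem.MolFromSmiles(mol.smiles)
    n = rdmol.GetNumAtoms()
    neighbors = [[b.GetIdx() for b in a.GetNeighbors()] for a in rdmol.GetAtoms()]
    atom_h = [a.GetTotalNumHs() for a in rdmol.GetAtoms()]
    atom_sym = [a.GetSymbol() for a in rdmol.GetAtoms()]
    offset = ADDUCT_MASS[config.adduct]
    parent_h = mol.formula.get("H", 0)
    mean_frac = math.exp(-energy / 40.0)  # harder collisions -> smaller fragments

    from .chem import formula_to_string

    n_true = int(rng.integers(config.min_peaks, config.max_peaks + 1))
    peaks: list[tuple[float, float]] = []
    truth: list[tuple[float, str]] = []  # (mz, generating formula)
    for _ in range(n_true):
        size = 1 + int(rng.binomial(n - 1, mean_frac)) if n > 1 else 1
        frag = _connected_fragment(neighbors, size, rng)
        in_frag = set(frag)
        cuts = sum(
            1 for u in frag for v in neighbors[u] if v not in in_frag
        )
        formula: dict[str, int] = {}
        for u in frag:
            formula[atom_sym[u]] = formula.get(atom_sym[u], 0) + 1
        h = min(parent_h, sum(atom_h[u] for u in frag) + cuts)
        if h:
            formula["H"] = h
        ion_mass = formula_mass(formula) + offset
        ppm_err = float(np.clip(rng.normal(0.0, config.mz_error_ppm), -15.0, 15.0))
        mz = ion_mass * (1.0 + ppm_err * 1e-6)
        intensity = float(rng.lognormal(0.0, config.intensity_noise_sd))
        peaks.append((mz, intensity))
        truth.append((mz, formula_to_string(formula)))

    precursor = mol.monoisotopic_mass + offset
    n_noise = int(rng.poisson(config.noise_peak_rate * n_true))
    for _ in range(n_noise):
        mz = float(rng.uniform(30.0, precursor))
        intensity = 0.3 * float(rng.lognormal(0.0, config.intensity_noise_sd))
        peaks.append((mz, intensity))

    peaks.sort(key=lambda p: p[0])
    # provenance header: generating subformula per true-peak m/z (noise blank)
    truth_map = dict(truth)
    true_formulas = ";".join(truth_map.get(mz, "") for mz, _ in peaks)
    return RawSpectrum(
        spectrum_id=spectrum_id or f"{mol.molecule_id}_e{energy:g}",
        precursor_mz=precursor,
        adduct=config.adduct,
        peaks=tuple(peaks),
        molecule_id=mol.molecule_id,
        smiles=mol.smiles,
        metadata={"TRUE_FORMULAS": true_formulas},
    )


@dataclass
class SplitData:
    molecules: list[MoleculeRecord]
    spectra: dict[str, list[RawSpectrum]]          # molecule_id -> spectra
    candidates_by_mass: dict[str, list[str]]       # molecule_id -> SMILES
    candidates_by_formula: dict[str, list[str]]


@dataclass
class SyntheticDataset:
    train: SplitData
    val: SplitData
    test: SplitData
    library: list[MoleculeRecord]
    config: SynthConfig

    def split(self, name: str) -> SplitData:
        return {"train": self.train, "val": self.val, "test": self.test}[name]


def _scaffold_groups(records: list[MoleculeRecord]) -> dict[str, list[MoleculeRecord]]:
    groups: dict[str, list[MoleculeRecord]] = {}
    for rec in records:
        scaf = MurckoScaffold.MurckoScaffoldSmiles(smiles=rec.smiles)
        groups.setdefault(scaf, []).append(rec)
    return groups


def make_candidate_sets(
    targets: list[MoleculeRecord],
    library: list[MoleculeRecord],
    size: int,
) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """Per target: a mass-neighborhood decoy set and the exact-formula set.

    The by-mass set holds the target plus its ``size - 1`` nearest-mass
    library decoys (a desk-scale proxy for a ppm window over a large
    library); the by-formula set is every library isomer of the target.
    Both always contain the target exactly once.
    """
    by_mass: dict[str, list[str]] = {}
    by_formula: dict[str, list[str]] = {}
    for t in targets:
        decoys = sorted(
            (m for m in library if m.smiles != t.smiles),
            key=lambda m: (abs(m.monoisotopic_mass - t.monoisotopic_mass), m.smiles),
        )[: size - 1]
        by_mass[t.molecule_id] = sorted({t.smiles, *(d.smiles for d in decoys)})
        iso = {m.smiles for m in library if m.formula == t.formula}
        iso.add(t.smiles)
        by_formula[t.molecule_id] = sorted(iso)[:size]
    return by_mass, by_formula


def generate_dataset(config: SynthConfig) -> SyntheticDataset:
    """Library + scaffold-split spectra + candidate sets, fully seeded.

    Molecules are split by Murcko scaffold (no scaffold crosses splits),
    a desk-scale proxy for structure-disjoint benchmark splits. Every
    molecule receives ``spectra_per_molecule`` spectra cycling through the
    configured pseudo-energies, and a by-mass / by-formula candidate set
    containing it.
    """
    library = generate_library(config)
    rng = np.random.default_rng([config.seed, 1])

    groups = list(_scaffold_groups(library).items())
    if len(groups) < 3:
        raise ValueError("too few scaffolds for a 3-way structure-disjoint split")
    groups.sort(key=lambda kv: (-len(kv[1]), kv[0]))
    targets = {"train": 0.7 * len(library), "val": 0.15 * len(library),
               "test": 0.15 * len(library)}
    assigned: dict[str, list[MoleculeRecord]] = {"train": [], "val": [], "test": []}
    for _, members in groups:
        deficit = {k: targets[k] - len(assigned[k]) for k in assigned}
        dest = max(deficit, key=lambda k: deficit[k])
        assigned[dest].extend(members)

    splits: dict[str, SplitData] = {}
    for name in ("train", "val", "test"):
        mols = sorted(assigned[name], key=lambda m: m.molecule_id)
        spectra: dict[str, list[RawSpectrum]] = {}
        for mol in mols:
            specs = []
            for i in range(config.spectra_per_molecule):
                energy = config.energies[i % len(config.energies)]
                specs.append(
                    fragment_molecule(
                        mol, energy, rng, config,
                        spectrum_id=f"{mol.molecule_id}_s{i}_e{energy:g}",
                    )
                )
            spectra[mol.molecule_id] = specs
        by_mass, by_formula = make_candidate_sets(
            mols, library, config.candidate_set_size
        )
        splits[name] = SplitData(mols, spectra, by_mass, by_formula)

    return SyntheticDataset(
        splits["train"], splits["val"], splits["test"], library, config
    )


def write_dataset(dataset: SyntheticDataset, out_dir) -> None:
    """Write MGF + candidate JSON + molecules TSV per split."""
    import json
    from pathlib import Path

    import pandas as pd

    from .io import write_mgf

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for name in ("train", "val", "test"):
        split = dataset.split(name)
        specs = [s for mol in split.molecules for s in split.spectra[mol.molecule_id]]
        write_mgf(specs, out / f"{name}.mgf")
        (out / f"{name}_candidates_by_mass.json").write_text(
            json.dumps(split.candidates_by_mass, indent=1, sort_keys=True)
        )
        (out / f"{name}_candidates_by_formula.json").write_text(
            json.dumps(split.candidates_by_formula, indent=1, sort_keys=True)
        )
        for mol in split.molecules:
            rows.append(
                {
                    "molecule_id": mol.molecule_id,
                    "split": name,
                    "smiles": mol.smiles,
                    "monoisotopic_mass": round(mol.monoisotopic_mass, 6),
                }
            )
    pd.DataFrame(rows).to_csv(out / "molecules.tsv", sep="\t", index=False)
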