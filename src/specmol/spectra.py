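"""Spectral views: subformula peak annotation, consensus spectra, peak vectors.

A tandem mass spectrum is reduced to its most abundant peaks (60 by default);
each retained peak is assigned the subformula of the parent molecule whose
ion mass (neutral monoisotopic mass + adduct offset) matches the observed m/z
within a ppm tolerance (20 by default), choosing the smallest |ppm error| and
breaking ties by the lexicographically smallest formula string. Unassignable
peaks are dropped and the surviving intensities are max-normalized.

A consensus spectrum merges all annotated spectra of one molecule: the peak
set is the union of their formulas and each formula keeps the maximum
normalized intensity observed for it — so every constituent spectrum's
formula set is a subset of the consensus formula set.

Peak vectors are 15-dimensional: the 14 element counts (fixed order C, H, O,
N, P, S, Cl, F, Br, I, B, As, Si, Se) each divided by the highest count of
that element observed in the training annotations (ElementScaler), plus the
normalized intensity. Counts exceeding the training maximum scale above 1 and
are logged, not clipped.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .chem import (
    ADDUCT_MASS,
    ELEMENTS,
    MONOISOTOPIC_MASS,
    MoleculeRecord,
    UnsupportedElementError,
    formula_to_string,
    parse_formula,
)

logger = logging.getLogger(__name__)

PEAK_DIM = len(ELEMENTS) + 1  # 14 scaled element counts + normalized intensity

#: guard against pathological parents in exhaustive subformula enumeration
MAX_SUBFORMULAS = 2_000_000


@dataclass(frozen=True)
class RawSpectrum:
    """An MS/MS spectrum as read from disk (see io module)."""

    spectrum_id: str
    precursor_mz: float
    adduct: str
    peaks: tuple[tuple[float, float], ...]
    molecule_id: str | None = None
    smiles: str | None = None
    metadata: dict = field(default_factory=dict)


@dataclass(frozen=True)
class AnnotatedPeak:
    formula: dict[str, int]
    intensity_norm: float
    ppm_error: float

    @property
    def formula_str(self) -> str:
        return formula_to_string(self.formula)


@dataclass
class AnnotatedSpectrum:
    spectrum_id: str
    molecule_id: str
    adduct: str
    peaks: list[AnnotatedPeak]

    def formula_set(self) -> set[str]:
        return {p.formula_str for p in self.peaks}


@dataclass
class ConsensusSpectrum:
    """Formula-keyed union of all spectra of one molecule (max intensity)."""

    molecule_id: str
    peaks: dict[str, float]  # formula string -> normalized intensity


class ElementScaler:
    """Per-element maximum counts observed in training annotations.

    Frozen after fit; converts formulas to scaled count vectors. Every entry
    is at least 1 so unobserved elements never divide by zero.
    """

    def __init__(self, max_count: dict[str, int]):
        self.max_count = {e: max(1, int(max_count.get(e, 1))) for e in ELEMENTS}

    @classmethod
    def fit(cls, train: list[AnnotatedSpectrum]) -> "ElementScaler":
        if not train:
            raise ValueError("cannot fit ElementScaler on an empty training set")
        mx = {e: 0 for e in ELEMENTS}
        for spec in train:
            for peak in spec.peaks:
                for e, n in peak.formula.items():
                    if n > mx[e]:
                        mx[e] = n
        for e, v in mx.items():
            if v == 0:
                logger.warning("element %s never observed; scaler entry set to 1", e)
        return cls(mx)

    def to_json(self) -> str:
        return json.dumps(self.max_count, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "ElementScaler":
        return cls(json.loads(s))

    def __eq__(self, other) -> bool:
        return isinstance(other, ElementScaler) and self.max_count == other.max_count


def fit_element_scaler(train: list[AnnotatedSpectrum]) -> ElementScaler:
    """Fit per-element maximum counts on training annotations."""
    return ElementScaler.fit(train)


def enumerate_subformulas(
    parent: dict[str, int],
) -> tuple[list[str], list[dict[str, int]], np.ndarray]:
    """All non-empty element-count maps f with 0 <= f_e <= parent_e.

    Returns parallel lists of formula strings and maps plus their neutral
    monoisotopic masses, sorted by formula string so downstream tie-breaking
    is deterministic.
    """
    elems = [e for e in ELEMENTS if parent.get(e, 0) > 0]
    for e in parent:
        if e not in ELEMENTS:
            raise UnsupportedElementError(f"element {e} not in supported set")
    total = 1
    for e in elems:
        total *= parent[e] + 1
    if total > MAX_SUBFORMULAS:
        raise ValueError(
            f"parent formula yields {total} subformulas (> {MAX_SUBFORMULAS}); "
            "too large for exhaustive enumeration"
        )
    ranges = [range(parent[e] + 1) for e in elems]
    strings: list[str] = []
    maps: list[dict[str, int]] = []
    masses: list[float] = []
    for counts in itertools.product(*ranges):
        if not any(counts):
            continue
        f = {e: c for e, c in zip(elems, counts) if c}
        strings.append(formula_to_string(f))
        maps.append(f)
        masses.append(sum(MONOISOTOPIC_MASS[e] * c for e, c in f.items()))
    order = sorted(range(len(strings)), key=lambda i: strings[i])
    return (
        [strings[i] for i in order],
        [maps[i] for i in order],
        np.array([masses[i] for i in order], dtype=np.float64),
    )


def annotate_peaks(
    spec: RawSpectrum,
    parent: MoleculeRecord,
    ppm_tol: float = 20.0,
    max_peaks: int = 60,
    _subformula_cache: dict | None = None,
) -> AnnotatedSpectrum:
    """Assign parent subformulas to the most abundant peaks of a spectrum.

    Every peak is assumed to carry the spectrum's adduct charge, so the
    candidate ion mass for subformula f is mass(f) + adduct offset. Peaks with
    no subformula within ``ppm_tol`` are dropped; surviving intensities are
    divided by their maximum.
    """
    if spec.adduct not in ADDUCT_MASS:
        raise ValueError(
            f"unsupported adduct {spec.adduct!r}; supported: {sorted(ADDUCT_MASS)}"
        )
    key = formula_to_string(parent.formula)
    if _subformula_cache is not None and key in _subformula_cache:
        strings, maps, masses = _subformula_cache[key]
    else:
        strings, maps, masses = enumerate_subformulas(parent.formula)
        if _subformula_cache is not None:
            _subformula_cache[key] = (strings, maps, masses)
    ion_masses = masses + ADDUCT_MASS[spec.adduct]

    # canonical peak order: intensity desc, then m/z asc (deterministic)
    ordered = sorted(spec.peaks, key=lambda p: (-p[1], p[0]))[:max_peaks]

    annotated: list[tuple[dict[str, int], float, float]] = []
    for mz, inten in ordered:
        ppm = (mz - ion_masses) / ion_masses * 1e6
        ok = np.flatnonzero(np.abs(ppm) <= ppm_tol)
        if ok.size == 0:
            continue
        # min |ppm error|, ties by lexicographically smallest formula string
        best = min(ok, key=lambda i: (abs(ppm[i]), strings[i]))
        annotated.append((maps[best], inten, float(ppm[best])))

    if not annotated:
        logger.warning("no peak of spectrum %s could be annotated", spec.spectrum_id)
        return AnnotatedSpectrum(spec.spectrum_id, parent.molecule_id, spec.adduct, [])

    max_int = max(a[1] for a in annotated)
    peaks = [
        AnnotatedPeak(f, inten / max_int if max_int > 0 else 0.0, ppm)
        for f, inten, ppm in annotated
    ]
    return AnnotatedSpectrum(spec.spectrum_id, parent.molecule_id, spec.adduct, peaks)


def peak_to_vector(peak: AnnotatedPeak, scaler: ElementScaler) -> np.ndarray:
    """15-vector: scaled element counts then normalized intensity (no clip)."""
    v = np.zeros(PEAK_DIM, dtype=np.float64)
    for i, e in enumerate(ELEMENTS):
        n = peak.formula.get(e, 0)
        if n:
            v[i] = n / scaler.max_count[e]
            if v[i] > 1.0:
                logger.warning(
                    "element %s count %d exceeds training maximum %d",
                    e, n, scaler.max_count[e],
                )
    v[-1] = peak.intensity_norm
    return v


def spectrum_to_matrix(spec: AnnotatedSpectrum, scaler: ElementScaler) -> np.ndarray:
    """Stack a spectrum's peak vectors into an (n_peaks, 15) matrix."""
    if not spec.peaks:
        raise ValueError(f"spectrum {spec.spectrum_id} has no annotated peaks")
    return np.stack([peak_to_vector(p, scaler) for p in spec.peaks])


def consensus_to_matrix(cons: ConsensusSpectrum, scaler: ElementScaler) -> np.ndarray:
    """Peak-vector matrix for a consensus spectrum (formula-sorted rows)."""
    if not cons.peaks:
        raise ValueError(f"consensus for {cons.molecule_id} has no peaks")
    rows = [
        peak_to_vector(AnnotatedPeak(parse_formula(f), inten, 0.0), scaler)
        for f, inten in sorted(cons.peaks.items())
    ]
    return np.stack(rows)


def build_consensus(spectra: list[AnnotatedSpectrum]) -> ConsensusSpectrum:
    """Merge spectra of one molecule: union of formulas, max intensity each.

    Commutative and associative in its inputs; the consensus of a single
    spectrum is that spectrum's own formula->intensity map (the inference
    fallback when only one measurement exists).
    """
    if not spectra:
        raise ValueError("cannot build consensus from an empty spectrum list")
    mol_ids = {s.molecule_id for s in spectra}
    if len(mol_ids) > 1:
        raise ValueError(f"mixed molecule ids in consensus input: {sorted(mol_ids)}")
    merged: dict[str, float] = {}
    for spec in spectra:
        for peak in spec.peaks:
            key = peak.formula_str
            if key not in merged or peak.intensity_norm > merged[key]:
                merged[key] = peak.intensity_norm
    return ConsensusSpectrum(mol_ids.pop(), merged)


def bin_spectrum(
    spec: RawSpectrum, bin_width: float = 0.1, max_mz: float = 1000.0
) -> np.ndarray:
    """Fixed-length binned representation: summed intensities, max-normalized.

    Peaks beyond ``max_mz`` are dropped with a warning. An empty spectrum
    yields the zero vector.
    """
    n_bins = int(round(max_mz / bin_width))
    v = np.zeros(n_bins, dtype=np.float64)
    for mz, inten in spec.peaks:
        idx = int(mz / bin_width)
        if idx >= n_bins:
            logger.warning("peak at m/z %.4f beyond max_mz %.1f dropped", mz, max_mz)
            continue
        v[idx] += inten
    m = v.max()
    if m > 0:
        v /= m
    return v


def export_annotations_tsv(spectra: list[AnnotatedSpectrum], path) -> None:
    """Write annotated peaks as TSV for inspection."""
    import pandas as pd

    rows = [
        {
            "spectrum_id": s.spectrum_id,
            "formula": p.formula_str,
            "intensity": round(p.intensity_norm, 6),
            "ppm_error": round(p.ppm_error, 4),
        }
        for s in spectra
        for p in s.peaks
    ]
    pd.DataFrame(rows, columns=["spectrum_id", "formula", "intensity", "ppm_error"]).to_csv(
        path, sep="\t", index=False
    )
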