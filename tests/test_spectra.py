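"""Peak annotation, element scaling, consensus algebra, binning."""

import numpy as np
import pytest

from specmol.chem import ADDUCT_MASS, parse_molecule
from specmol.spectra import (
    AnnotatedPeak,
    AnnotatedSpectrum,
    ElementScaler,
    RawSpectrum,
    annotate_peaks,
    bin_spectrum,
    build_consensus,
    enumerate_subformulas,
    fit_element_scaler,
    peak_to_vector,
)

C2H4O2_ION = 60.021130 + 1.007276  # neutral acetic-acid subformula + proton


def _spec(peaks, adduct="[M+H]+", sid="s"):
    return RawSpectrum(sid, 181.0707, adduct, tuple(peaks))


@pytest.fixture(scope="module")
def glucose():
    return parse_molecule("OCC1OC(O)C(O)C(O)C1O", "glucose")


class TestAnnotatePeaks:
    def test_exact_subformula_assignment(self, glucose):
        ann = annotate_peaks(_spec([(61.028406, 1.0)]), glucose)
        assert len(ann.peaks) == 1
        p = ann.peaks[0]
        assert p.formula == {"C": 2, "H": 4, "O": 2}
        assert abs(p.ppm_error) < 0.1
        assert p.intensity_norm == 1.0

    def test_out_of_tolerance_peak_dropped(self, glucose):
        # +25 ppm: no glucose subformula lies within the 20 ppm window
        ann = annotate_peaks(_spec([(61.029932, 1.0)]), glucose)
        assert ann.peaks == []

    @pytest.mark.parametrize("shift_ppm,kept", [(19.0, True), (21.0, False)])
    def test_tolerance_boundary(self, glucose, shift_ppm, kept):
        mz = C2H4O2_ION * (1.0 + shift_ppm * 1e-6)
        ann = annotate_peaks(_spec([(mz, 1.0)]), glucose)
        if kept:
            assert len(ann.peaks) == 1
            assert ann.peaks[0].formula == {"C": 2, "H": 4, "O": 2}
        else:
            assert ann.peaks == []

    def test_top_60_retained_before_matching(self, glucose):
        # 80 copies of an annotatable m/z with distinct intensities
        peaks = [(61.028406, float(i + 1)) for i in range(80)]
        ann = annotate_peaks(_spec(peaks), glucose)
        assert len(ann.peaks) == 60
        assert max(p.intensity_norm for p in ann.peaks) == 1.0

    def test_sodium_adduct_offset(self, glucose):
        mz = 60.021130 + ADDUCT_MASS["[M+Na]+"]
        ann = annotate_peaks(_spec([(mz, 1.0)], adduct="[M+Na]+"), glucose)
        assert ann.peaks[0].formula == {"C": 2, "H": 4, "O": 2}

    def test_shuffle_invariance(self, glucose):
        rng = np.random.default_rng(0)
        peaks = [(61.028406, 0.9), (85.028406, 0.5), (127.039, 0.2), (163.0601, 0.7)]
        ref = annotate_peaks(_spec(peaks), glucose)
        for _ in range(10):
            rng.shuffle(peaks)
            out = annotate_peaks(_spec(list(peaks)), glucose)
            assert [(p.formula_str, p.intensity_norm) for p in out.peaks] == [
                (p.formula_str, p.intensity_norm) for p in ref.peaks
            ]

    def test_unsupported_adduct(self, glucose):
        with pytest.raises(ValueError, match="adduct"):
            annotate_peaks(_spec([(61.0, 1.0)], adduct="[M-H]-"), glucose)

    def test_nothing_annotatable_yields_empty(self, glucose):
        ann = annotate_peaks(_spec([(500.0, 1.0)]), glucose)
        assert ann.peaks == []


class TestSubformulaEnumeration:
    def test_count_and_bounds(self, glucose):
        strings, maps, masses = enumerate_subformulas(glucose.formula)
        assert len(strings) == 7 * 13 * 7 - 1  # all count combos minus empty
        for f in maps:
            for e, n in f.items():
                assert 0 < n <= glucose.formula[e]
        assert strings == sorted(strings)
        assert np.all(masses > 0)


class TestElementScaler:
    def test_fit_takes_elementwise_max(self):
        specs = [
            AnnotatedSpectrum("a", "m", "[M+H]+",
                              [AnnotatedPeak({"C": 2, "H": 4, "O": 2}, 1.0, 0.0)]),
            AnnotatedSpectrum("b", "m", "[M+H]+",
                              [AnnotatedPeak({"C": 6, "H": 12, "O": 6}, 1.0, 0.0)]),
        ]
        scaler = fit_element_scaler(specs)
        assert scaler.max_count["C"] == 6
        assert scaler.max_count["H"] == 12
        assert scaler.max_count["O"] == 6
        assert all(scaler.max_count[e] == 1 for e in ("N", "P", "S", "Se"))

    def test_single_peak(self):
        s = AnnotatedSpectrum("a", "m", "[M+H]+", [AnnotatedPeak({"C": 1}, 1.0, 0.0)])
        scaler = fit_element_scaler([s])
        assert scaler.max_count["C"] == 1
        assert scaler.max_count["H"] == 1

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            fit_element_scaler([])

    def test_json_round_trip(self):
        scaler = ElementScaler({"C": 10, "H": 20})
        assert ElementScaler.from_json(scaler.to_json()) == scaler


class TestPeakToVector:
    def test_scaled_counts_then_intensity(self):
        scaler = ElementScaler({"C": 10, "H": 20, "O": 8})
        v = peak_to_vector(AnnotatedPeak({"C": 6, "H": 12, "O": 6}, 1.0, 0.0), scaler)
        np.testing.assert_allclose(v[:3], [0.6, 0.6, 0.75])
        assert np.all(v[3:14] == 0)
        assert v[14] == 1.0

    def test_empty_formula(self):
        v = peak_to_vector(AnnotatedPeak({}, 0.2, 0.0), ElementScaler({}))
        assert np.all(v[:14] == 0) and v[14] == 0.2

    def test_unseen_count_exceeds_one_not_clipped(self, caplog):
        scaler = ElementScaler({"C": 10})
        with caplog.at_level("WARNING"):
            v = peak_to_vector(AnnotatedPeak({"C": 12}, 0.5, 0.0), scaler)
        assert v[0] == pytest.approx(1.2)
        assert "exceeds training maximum" in caplog.text


class TestConsensus:
    def _aspec(self, sid, peaks):
        return AnnotatedSpectrum(
            sid, "mol", "[M+H]+",
            [AnnotatedPeak(f, i, 0.0) for f, i in peaks],
        )

    def test_max_merge(self):
        a = self._aspec("a", [({"C": 1, "H": 1, "O": 2}, 0.5)])
        b = self._aspec("b", [({"C": 1, "H": 1, "O": 2}, 0.9),
                              ({"C": 2, "H": 2}, 0.3)])
        cons = build_consensus([a, b])
        assert cons.peaks == {"CHO2": 0.9, "C2H2": 0.3}

    def test_idempotence_and_single_spectrum(self):
        a = self._aspec("a", [({"C": 1}, 1.0), ({"C": 2}, 0.4)])
        cons = build_consensus([a])
        assert cons.peaks == {"C": 1.0, "C2": 0.4}
        assert build_consensus([a, a]).peaks == cons.peaks

    def test_order_invariance_commutative_associative(self):
        rng = np.random.default_rng(3)
        specs = [
            self._aspec(f"s{i}", [({"C": int(c), "H": int(h)}, float(rng.random()))
                                  for c, h in rng.integers(1, 5, size=(4, 2))])
            for i in range(4)
        ]
        ref = build_consensus(specs).peaks
        for _ in range(5):
            perm = rng.permutation(len(specs))
            assert build_consensus([specs[i] for i in perm]).peaks == ref
        # associativity: fold pairwise via intermediate consensus spectra
        left = build_consensus(specs[:2])
        right = build_consensus(specs[2:])
        merged = {
            k: max(left.peaks.get(k, 0), right.peaks.get(k, 0))
            for k in {*left.peaks, *right.peaks}
        }
        assert merged == ref

    def test_constituent_subset_property(self):
        specs = [
            self._aspec("a", [({"C": 2, "H": 4}, 0.1), ({"O": 1, "H": 2}, 1.0)]),
            self._aspec("b", [({"C": 3}, 0.7)]),
        ]
        cons = build_consensus(specs)
        for s in specs:
            assert s.formula_set() <= set(cons.peaks)

    def test_mixed_molecules_error(self):
        a = self._aspec("a", [({"C": 1}, 1.0)])
        b = AnnotatedSpectrum("b", "other", "[M+H]+",
                              [AnnotatedPeak({"C": 1}, 1.0, 0.0)])
        with pytest.raises(ValueError, match="mixed"):
            build_consensus([a, b])

    def test_empty_list_error(self):
        with pytest.raises(ValueError):
            build_consensus([])


class TestBinSpectrum:
    def test_single_peak_bin_index(self):
        v = bin_spectrum(RawSpectrum("s", 100.0, "[M+H]+", ((100.05, 1.0),)))
        assert v.shape == (10000,)
        nz = np.flatnonzero(v)
        assert list(nz) == [1000] and v[1000] == 1.0

    def test_same_bin_summed_then_normalized(self):
        v = bin_spectrum(
            RawSpectrum("s", 100.0, "[M+H]+", ((50.01, 1.0), (50.04, 1.0), (70.0, 1.0)))
        )
        assert v[500] == 1.0  # 2.0 summed, then max-normalized
        assert v[700] == 0.5

    def test_empty_and_out_of_range(self):
        v = bin_spectrum(RawSpectrum("s", 100.0, "[M+H]+", ((1500.0, 1.0),)))
        assert np.all(v == 0)
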