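"""Ladder reading, assembly and closure from simulated peak lists."""

import numpy as np
import pytest

from peptaibolkit import chem, reader
from peptaibolkit.chem import PeptaibolSequence
from peptaibolkit.reader import PeakList, SequenceCall
from peptaibolkit.simulate import SpectrumSimConfig, simulate_spectrum


def _spectra(seq, seed=1, **kw):
    return simulate_spectrum(seq, SpectrumSimConfig(seed=seed, **kw))


def _na_precursor(seq):
    return chem.adduct_mz(chem.neutral_mass(seq)[0], "Na", 1)[0]


class TestPeakList:
    def test_sorted_and_validated(self):
        pl = PeakList(np.array([[500.0, 1.0], [100.0, 2.0]]), "full_scan")
        assert list(pl.mz) == [100.0, 500.0]
        with pytest.raises(ValueError):
            PeakList(np.array([[-1.0, 1.0]]), "full_scan")
        with pytest.raises(ValueError):
            PeakList(np.array([[100.0, 1.0]]), "full_scan", tolerance=0.0)


class TestNTerminus:
    def test_reads_r1_to_r13(self, paracelsin_b):
        full, _ = _spectra(paracelsin_b)
        call = reader.read_n_terminus(full)
        truth = paracelsin_b.collapsed().labels
        assert {k: truth[k] for k in range(1, 14)} == call.assignments

    def test_composite_step_crosses_missing_b7(self, by_name):
        """With no b7 peak present (by construction), R7/R8 come from the
        composite Gln-Aib step."""
        seq = by_name["Pept-A-Ia"].seq
        full, _ = _spectra(seq)
        call = reader.read_n_terminus(full)
        assert call.assignments[7] == "Gln"
        assert call.assignments[8] == "Aib"
        assert "composite" in call.provenance[7]
        assert "composite" in call.provenance[8]

    def test_brevicelsin_composite_anchors_vacancy(self, brevicelsin_i):
        full, _ = _spectra(brevicelsin_i)
        call = reader.read_n_terminus(full)
        assert call.vacancy_at == 6
        assert 6 not in call.assignments
        assert call.assignments[7] == "Gln"

    def test_no_b_ions_yields_empty_call(self):
        empty = PeakList(np.empty((0, 2)), "full_scan")
        call = reader.read_n_terminus(empty)
        assert call.assignments == {}
        assert any("no b1" in d for d in call.diagnostics)

    def test_rejects_wrong_level(self, paracelsin_b):
        _, ms2 = _spectra(paracelsin_b)
        with pytest.raises(ValueError):
            reader.read_n_terminus(ms2)

    def test_tolerance_monotonicity(self, all_records):
        """Enlarging the tolerance never removes a correct ladder step."""
        for rec in all_records[::17]:
            full, _ = _spectra(rec.seq, seed=5)
            truth = rec.seq.collapsed().labels
            narrow = reader.read_n_terminus(full)
            full.tolerance = 0.5
            wide = reader.read_n_terminus(full)
            correct_narrow = {k: v for k, v in narrow.assignments.items()
                              if truth.get(k) == v}
            for k, v in correct_narrow.items():
                assert wide.assignments.get(k) == v


class TestCTerminus:
    def test_reads_r14_to_r20(self, paracelsin_b):
        _, ms2 = _spectra(paracelsin_b)
        call = reader.read_c_terminus(ms2)
        truth = paracelsin_b.collapsed().labels
        assert call.assignments == {k: truth[k] for k in range(14, 21)}
        assert call.assignments[14] == "Pro"
        assert call.provenance[20] == "terminal y1 unit mass"

    def test_y7_precursor_matches_printed_selection(self, paracelsin_b):
        _, ms2 = _spectra(paracelsin_b)
        assert chem.floor_to_tenth(ms2.precursor_mz) == 774.4

    def test_empty_ms2_leaves_c_labels_unassigned(self):
        empty = PeakList(np.empty((0, 2)), "ms2_of_y7", precursor_mz=774.45)
        call = reader.read_c_terminus(empty)
        assert call.assignments == {}

    def test_precursor_required(self):
        pl = PeakList(np.array([[152.1, 1.0]]), "ms2_of_y7")
        with pytest.raises(ValueError):
            reader.read_c_terminus(pl)


class TestAssemble:
    def test_complete_round_trip(self, paracelsin_b):
        full, ms2 = _spectra(paracelsin_b)
        call = reader.assemble(reader.read_n_terminus(full),
                               reader.read_c_terminus(ms2),
                               precursor=_na_precursor(paracelsin_b))
        assert call.complete
        assert call.closure_residual < 0.1
        assert call.assignments == paracelsin_b.collapsed().labels

    def test_brevicelsin_round_trip_records_vacancy(self, by_name):
        seq = by_name["Brevicelsin-IV"].seq
        full, ms2 = _spectra(seq)
        call = reader.assemble(reader.read_n_terminus(full),
                               reader.read_c_terminus(ms2),
                               precursor=_na_precursor(seq))
        assert call.complete
        assert call.vacancy_at == 6
        assert call.closure_residual < 0.1
        assert call.assignments == seq.collapsed().labels

    def test_wrong_residue_fails_closure_by_14(self, paracelsin_b, registry):
        """A chain simulated with Aib->Vxx at one site against the true
        precursor misses closure by ~14.02 Da and is flagged incomplete."""
        chain = list(paracelsin_b.chain)
        chain[5] = "Vxx"  # Aib -> Vxx: +14.01565
        mutated = PeptaibolSequence(chain, registry=registry)
        full, ms2 = _spectra(mutated)
        call = reader.assemble(reader.read_n_terminus(full),
                               reader.read_c_terminus(ms2),
                               precursor=_na_precursor(paracelsin_b),
                               precursor_kind="Na")
        assert not call.complete
        assert call.closure_residual == pytest.approx(14.016, abs=0.1)

    def test_identical_overlap_merges_without_conflict(self):
        a = SequenceCall(assignments={1: "Aib"}, provenance={1: "b-ladder"})
        b = SequenceCall(assignments={1: "Aib", 14: "Pro"},
                         provenance={1: "b-ladder", 14: "y-series"})
        merged = reader.assemble(a, b)
        assert merged.assignments[1] == "Aib"

    def test_conflicting_overlap_raises_with_provenances(self):
        a = SequenceCall(assignments={1: "Aib"}, provenance={1: "b-ladder"})
        b = SequenceCall(assignments={1: "Vxx"}, provenance={1: "y-series"})
        with pytest.raises(ValueError, match="b-ladder.*y-series"):
            reader.assemble(a, b)

    def test_precursor_interpretations(self, paracelsin_b):
        """[M+H]+, [M+Na]+ and [M+2Na]2+ precursors all close."""
        m = chem.neutral_mass(paracelsin_b)[0]
        for adduct, charge in [("H", 1), ("Na", 1), ("2Na", 2)]:
            full, ms2 = _spectra(paracelsin_b)
            call = reader.assemble(
                reader.read_n_terminus(full), reader.read_c_terminus(ms2),
                precursor=chem.adduct_mz(m, adduct, charge)[0])
            assert call.complete, adduct


class TestDropoutSafety:
    def test_no_hallucinated_assignments_under_dropout(self, all_records):
        """At 10% peak dropout every assigned position is correct (assigned
        set is a subset of the true labelling) across 100 seeded spectra."""
        rng = np.random.default_rng(11)
        checked = 0
        for _ in range(100):
            rec = all_records[int(rng.integers(0, len(all_records)))]
            cfg = SpectrumSimConfig(seed=int(rng.integers(0, 2 ** 31)),
                                    noise_sigma=0.02, dropout_p=0.1)
            full, ms2 = simulate_spectrum(rec.seq, cfg)
            call = reader.assemble(reader.read_n_terminus(full),
                                   reader.read_c_terminus(ms2),
                                   precursor=_na_precursor(rec.seq))
            truth = rec.seq.collapsed().labels
            for lab, tok in call.assignments.items():
                assert truth.get(lab) == tok, (rec.name, lab)
            checked += 1
        assert checked == 100

    def test_ala_gly_bridge_is_not_read_as_gln(self, by_name, registry):
        """Dropping the b ion between an adjacent Ala-Gly pair leaves a delta
        equal to the Gln residue mass to 1e-5 Da; the reader must stop rather
        than assign a phantom Gln."""
        seq = by_name["Pept-A-IVb"].seq  # Ala at R10, Gly at R11
        from peptaibolkit.simulate import theory_peaks
        full_t, _, _ = theory_peaks(seq)
        b10 = chem.b_ion(seq, 10)[0]
        kept = [mz for mz in full_t if abs(mz - b10) > 1e-6]
        pl = PeakList(np.column_stack([kept, np.ones(len(kept))]),
                      "full_scan")
        call = reader.read_n_terminus(pl)
        truth = seq.collapsed().labels
        for lab, tok in call.assignments.items():
            assert truth[lab] == tok
        assert 10 not in call.assignments
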