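"""Sequence features: frequencies, motif scans, physicochemistry."""

import re

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from thymosig import features as ft
from thymosig.io import Clonotype
from .conftest import make_repertoire

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestResidueFrequencies:
    def test_hand_counts(self):
        r = make_repertoire(["GG", "GA"])
        t = ft.residue_frequencies(r)
        assert t.freqs == {"G": 0.75, "A": 0.25}
        t2 = ft.residue_frequencies(make_repertoire(["CASF"]))
        assert t2.freqs == {c: 0.25 for c in "CASF"}

    def test_per_occurrence_sums_to_one(self, pre_10k):
        t = ft.residue_frequencies(pre_10k)
        assert sum(t.freqs.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(0 <= f <= 1 for f in t.freqs.values())

    def test_presence_weighting_fraction_of_clonotypes(self):
        r = make_repertoire(["GGG", "GA"])
        t = ft.residue_frequencies(r, weighting="per_clonotype_presence")
        assert t.freqs == {"G": 1.0, "A": 0.5}


class TestKmerFrequencies:
    def test_hand_counts(self):
        t = ft.kmer_frequencies(make_repertoire(["GGGG"]), k=3)
        assert t.freqs == {"GGG": 1.0}
        assert t.total == 2
        t2 = ft.kmer_frequencies(make_repertoire(["CASSF"]), k=3)
        assert t2.freqs == {"CAS": pytest.approx(1 / 3), "ASS": pytest.approx(1 / 3),
                            "SSF": pytest.approx(1 / 3)}

    def test_normalization_on_simulated(self, pre_10k):
        t = ft.kmer_frequencies(pre_10k, k=3)
        assert sum(t.freqs.values()) == pytest.approx(1.0, abs=1e-9)

    def test_oversized_k_warns_empty(self):
        with pytest.warns(UserWarning):
            t = ft.kmer_frequencies(make_repertoire(["CAF"]), k=10)
        assert t.freqs == {}


class TestScanSequons:
    def test_basic_hit(self):
        hits = ft.scan_sequons("ANAS")
        assert [(h.pattern, h.position) for h in hits] == [("NAS", 1)]

    def test_proline_x_toggle(self):
        assert ft.scan_sequons("CNPSF", exclude_proline_x=True) == []
        assert len(ft.scan_sequons("CNPSF", exclude_proline_x=False)) == 1

    def test_generic_tra_junction_has_no_sequon(self):
        # N at index 6 is followed by T,G — not a sequon start
        assert ft.scan_sequons("CAGGSSNTGKLIF") == []

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(hst.text(alphabet=AA, min_size=0, max_size=30))
    def test_matches_regex_oracle(self, seq):
        expected = [m.start() for m in re.finditer(r"(?=(N[^P][ST]))", seq)]
        got = [h.position for h in ft.scan_sequons(seq, exclude_proline_x=True)]
        assert got == expected
        expected_all = [m.start() for m in re.finditer(r"(?=(N.[ST]))", seq)]
        got_all = [h.position for h in ft.scan_sequons(seq)]
        assert got_all == expected_all


class TestScanFixedMotifs:
    def test_overlapping_hits(self):
        hits = ft.scan_fixed_motifs("ADDDY", ["DDD", "DDY"])
        assert {(h.pattern, h.position) for h in hits} == {("DDD", 1), ("DDY", 2)}

    def test_default_motif_list(self):
        assert set(ft.SULFATION_MOTIFS) == {"DDD", "DDY", "YYY", "EEE"}

    def test_absence(self):
        assert ft.scan_fixed_motifs("CASSF") == []


class TestAttributeRegion:
    @staticmethod
    def _clonotype(nt, bounds, aa=None):
        from thymosig.simulate import translate
        return Clonotype(aa or translate(nt), "V", "J", 1, cdr3_nt=nt,
                         segment_bounds=bounds)

    def test_codon_fully_inside_ndn(self):
        # aa: C N A S -> codons 0-2 (V), 3-8 (NDN), 9-11 (J)
        nt = "TGT" + "AATGCT" + "AGT"
        c = self._clonotype(nt, ((0, 3), (3, 9), (9, 12)))
        hit = ft.scan_sequons(c.cdr3_aa)[0]
        assert ft.attribute_region(hit, c) == "NDN"

    def test_majority_rule_two_nt_in_v(self):
        # anchor codon spans V/NDN with 2 nt in V
        nt = "TGTAA" + "TGCTAGT"
        c = self._clonotype(nt, ((0, 5), (5, 9), (9, 12)))
        hit = ft.scan_sequons(c.cdr3_aa)[0]  # N at residue 1, codon nt 3..6
        assert ft.attribute_region(hit, c) == "V"

    def test_no_bounds_unknown(self):
        c = Clonotype("CNASF", "V", "J", 1)
        hit = ft.scan_sequons(c.cdr3_aa)[0]
        assert ft.attribute_region(hit, c) == "unknown"

    def test_simulated_knock_in_recovered_from_ground_truth(self, pre_10k):
        """Sequons whose anchor codon lies in the simulator's NDN interval
        are attributed NDN with >= 95% accuracy (exact bounds)."""
        total = correct = 0
        for c in pre_10k:
            (v0, v1), (n0, n1), (j0, j1) = c.segment_bounds
            for hit in ft.scan_sequons(c.cdr3_aa):
                start = 3 * hit.position
                if n0 <= start and start + 3 <= n1:  # truly inserted anchor
                    total += 1
                    correct += ft.attribute_region(hit, c) == "NDN"
        assert total > 20
        assert correct / total >= 0.95


class TestPhyschem:
    def test_single_residue_equals_kidera_row(self):
        p = ft.physchem("A")
        assert np.allclose(p.kidera, ft.KIDERA["A"])
        assert p.length == 1

    def test_charge_monotonicity(self):
        assert ft.physchem("KK").charge > ft.physchem("GG").charge
        assert ft.physchem("DD").charge < ft.physchem("GG").charge

    def test_brute_force_oracle(self):
        seq = "CASSLGETQYF"
        p = ft.physchem(seq)
        kid = sum((ft.KIDERA[c] for c in seq), np.zeros(10)) / len(seq)
        assert np.allclose(p.kidera, kid, atol=1e-9)
        hyd = sum(ft.HYDROPHOBICITY_SCALES["kyte_doolittle"][c] for c in seq) / len(seq)
        assert p.hydrophobicity == pytest.approx(hyd, abs=1e-9)
        q = 0.0
        for c in seq:
            if c in "HKR":
                pka = ft.PKA_SETS["lehninger"][c][0]
                q += 1 / (1 + 10 ** (7.0 - pka))
            elif c in "DECY":
                pka = ft.PKA_SETS["lehninger"][c][0]
                q -= 1 / (1 + 10 ** (pka - 7.0))
        assert p.charge == pytest.approx(q, abs=1e-9)

    def test_kidera_additive_by_mean(self):
        s1, s2 = "CASS", "GETQYF"
        p1, p2, p12 = ft.physchem(s1), ft.physchem(s2), ft.physchem(s1 + s2)
        combined = (p1.kidera * len(s1) + p2.kidera * len(s2)) / len(s1 + s2)
        assert np.allclose(p12.kidera, combined, atol=1e-12)

    def test_unknown_residue_named_in_error(self):
        with pytest.raises(ValueError, match="X"):
            ft.physchem("CAXF")

    def test_kyte_doolittle_matches_biopython(self):
        from Bio.SeqUtils.ProtParamData import kd

        for aa in AA:
            assert ft.HYDROPHOBICITY_SCALES["kyte_doolittle"][aa] == pytest.approx(kd[aa])


class TestPositionalMarginals:
    def test_identity_gives_zeros(self, pre_10k):
        m = ft.positional_marginals(pre_10k, pre_10k, length=14)
        assert np.allclose(m.to_numpy(), 0.0)

    def test_absent_from_both_is_zero(self):
        post = make_repertoire(["CAAF", "CAAF"])
        pre = make_repertoire(["CAAF", "CADF"])
        m = ft.positional_marginals(post, pre, length=4)
        assert m.loc[0, "W"] == 0.0  # W occurs nowhere
        assert m.loc[2, "D"] < 0.0   # D knocked out of post at position 2

    def test_sequon_knockout_shows_negative_n_logodds(self, pre_10k):
        from thymosig.simulate import SelectionSpec, apply_selection

        post = apply_selection(
            pre_10k, SelectionSpec(motif_penalties={"N[^P][ST]": 0.0}), seed=2)
        m = ft.positional_marginals(post, pre_10k, length=14)
        # N depleted overall at interior positions where sequons are feasible
        assert m.loc[4:10, "N"].mean() < 0
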