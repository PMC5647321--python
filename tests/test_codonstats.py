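"""Codon alignment, four-fold site identification and 4dTv statistics."""

import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_codon_pair_sequences
from paleoploid.codonstats import (
    CodonPairAlignment,
    align_pair_codon_aware,
    classify_substitution,
    compute_4dtv,
    compute_aa_distance,
    fourdtv_table,
    identify_fourfold_sites,
)

TOY_A = "GGTCTAGCCACGTTTATG"
TOY_B = "GGACTGGCGACGTTCATG"


class TestAlignment:
    def test_identical_cds_align_gapless(self):
        cds = "ATGGCTGGTTGCTAA"
        aln = align_pair_codon_aware(cds, cds)
        assert aln.aln_a == aln.aln_b == cds

    def test_single_synonymous_difference(self):
        aln = align_pair_codon_aware("ATGGGTTAA", "ATGGGATAA")
        assert len(aln.aln_a) == 9
        assert "-" not in aln.aln_a + aln.aln_b

    def test_codon_deletion_yields_one_triplet_gap(self):
        cds_a = "ATGGCTAAAGGTTGCTAA"
        cds_b = "ATGGCTGGTTGCTAA"  # AAA codon removed
        aln = align_pair_codon_aware(cds_a, cds_b)
        assert "-" not in aln.aln_a
        assert aln.aln_b.count("-") == 3
        gap_start = aln.aln_b.index("-")
        assert gap_start % 3 == 0
        assert aln.aln_b[gap_start:gap_start + 3] == "---"

    def test_internal_stop_is_aligned_not_rejected(self):
        aln = align_pair_codon_aware("ATGTAAGGTTAA", "ATGTGCGGTTAA")
        assert len(aln.aln_a) == len(aln.aln_b) == 12

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_pair_codon_aware("", "ATGTAA")


class TestFourfoldSites:
    @pytest.mark.parametrize("ca,cb,counted", [
        ("GGT", "GGC", True),    # glycine family
        ("ATG", "ATG", False),   # Met is not four-fold
        ("AGA", "AGG", False),   # AGR arginine is two-fold; only CGN counts
        ("GGT", "GCT", False),   # first-two mismatch
        ("CGA", "CGT", True),    # CGN arginine
        ("GG-", "GGT", False),   # gapped codon excluded
        ("GGN", "GGT", False),   # ambiguity excluded
    ])
    def test_site_counting_rules(self, ca, cb, counted):
        aln = CodonPairAlignment("a", "b", ca, cb)
        sites = identify_fourfold_sites(aln)
        assert (sites == [2]) == counted

    def test_matches_brute_force_codon_table(self):
        """Four-fold classification agrees with direct genetic-code enumeration
        on every sense-codon pair."""
        from Bio.Seq import Seq

        bases = "ACGT"
        sense = [a + b + c for a in bases for b in bases for c in bases
                 if str(Seq(a + b + c).translate()) != "*"]
        assert len(sense) == 61

        def brute_fourfold(codon):
            aas = {str(Seq(codon[:2] + b).translate()) for b in bases}
            return len(aas) == 1

        for ca, cb in itertools.product(sense, repeat=2):
            aln = CodonPairAlignment("a", "b", ca, cb)
            expect = brute_fourfold(ca) and brute_fourfold(cb) and ca[:2] == cb[:2]
            assert (identify_fourfold_sites(aln) == [2]) == expect, (ca, cb)


class TestClassifySubstitution:
    @pytest.mark.parametrize("a,b,kind", [
        ("A", "G", "transition"), ("G", "A", "transition"),
        ("C", "T", "transition"), ("T", "C", "transition"),
        ("A", "T", "transversion"), ("A", "C", "transversion"),
        ("G", "T", "transversion"), ("C", "G", "transversion"),
        ("C", "C", "identical"),
    ])
    def test_classification(self, a, b, kind):
        assert classify_substitution(a, b) == kind

    def test_ambiguous_base_rejected(self):
        with pytest.raises(ValueError):
            classify_substitution("N", "A")


class TestCompute4dTv:
    def test_identical_sequences_give_zero(self):
        aln = CodonPairAlignment("a", "b", "GGTCCC", "GGTCCC")
        res = compute_4dtv(aln)
        assert res.n_4d_sites == 2
        assert res.fourdtv == 0.0

    def test_hand_counted_toy_alignment(self):
        res = compute_4dtv(CodonPairAlignment("a", "b", TOY_A, TOY_B))
        assert res.n_4d_sites == 4
        assert res.n_transversions == 2
        assert res.n_transitions == 1
        assert res.fourdtv == 0.5

    def test_no_fourfold_sites_is_undefined(self):
        res = compute_4dtv(CodonPairAlignment("a", "b", "ATGTGG", "ATGTGG"))
        assert not res.defined
        assert res.fourdtv is None

    def test_symmetry_in_pair_order(self):
        a, b = random_codon_pair_sequences(200, 0.3, 2.0, seed=41)
        fwd = compute_4dtv(CodonPairAlignment("a", "b", a, b))
        rev = compute_4dtv(CodonPairAlignment("b", "a", b, a))
        assert fwd == rev

    def test_simulated_pair_recovers_deep_ortholog_level(self):
        # a pair evolved to the deep divergence level must read back 0.27
        from paleoploid.simulate import tau_for_target_4dtv

        tau = tau_for_target_4dtv(0.27)
        # at this divergence only ~14% of codons stay countable four-fold
        # sites, so 400k codons are needed for >= 50k sites
        a, b = random_codon_pair_sequences(400_000, tau, 2.0, seed=13)
        res = compute_4dtv(CodonPairAlignment("a", "b", a, b))
        assert res.n_4d_sites >= 50_000
        se = math.sqrt(0.27 * 0.73 / res.n_4d_sites)
        assert res.fourdtv == pytest.approx(0.27, abs=3 * se)

    def test_mean_4dtv_nondecreasing_in_tau(self):
        import numpy as np

        means = []
        for tau in (0.01, 0.05, 0.12, 0.25, 0.5):
            vals = []
            for s in range(100):
                a, b = random_codon_pair_sequences(60, tau, 2.0, seed=1000 + s)
                r = compute_4dtv(CodonPairAlignment("a", "b", a, b))
                if r.defined:
                    vals.append(r.fourdtv)
            means.append(np.mean(vals))
        assert all(m2 >= m1 for m1, m2 in zip(means, means[1:]))

    def test_corrected_variant_expands_raw_value(self):
        # three 4d sites, one transversion: raw q = 1/3
        res = compute_4dtv(CodonPairAlignment("a", "b", "GGTCTAACG", "GGACTGACG"),
                           correct=True)
        assert res.fourdtv == pytest.approx(-0.5 * math.log(1 - 2 / 3), abs=1e-12)

    def test_correction_undefined_at_saturation(self):
        res = compute_4dtv(CodonPairAlignment("a", "b", TOY_A, TOY_B), correct=True)
        assert res.fourdtv is None  # raw q = 0.5 saturates the correction


class TestAADistance:
    def test_identical_proteins(self):
        d = compute_aa_distance("MKV", "MKV")
        assert d.p_distance == 0.0
        assert d.poisson_corrected == 0.0

    def test_one_mismatch_in_ten(self):
        d = compute_aa_distance("MKVLAWGHIE", "MKVLAWGHID")
        assert d.p_distance == pytest.approx(0.1)
        assert d.poisson_corrected == pytest.approx(0.10536, abs=1e-5)

    def test_saturated_distance_flagged(self):
        d = compute_aa_distance("AA", "VV")
        assert d.p_distance == 1.0
        assert d.poisson_corrected is None

    def test_all_gap_columns_undefined(self):
        d = compute_aa_distance("--", "AA")
        assert not d.defined

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30))
    @settings(max_examples=30, deadline=None)
    def test_poisson_correction_dominates_p(self, prot):
        mutated = ("A" if prot[0] != "A" else "V") + prot[1:]
        d = compute_aa_distance(prot, mutated)
        if d.poisson_corrected is not None:
            assert d.poisson_corrected >= d.p_distance


def test_fourdtv_table_schema_and_missing_id():
    cds = {"x": "ATGGGTTAA", "y": "ATGGGATAA"}
    df = fourdtv_table(cds, [("x", "y")])
    assert list(df.columns) == ["id_a", "id_b", "n_4d_sites", "n_transversions",
                                "fourdtv", "p_distance"]
    assert len(df) == 1
    with pytest.raises(KeyError):
        fourdtv_table(cds, [("x", "zzz")])
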