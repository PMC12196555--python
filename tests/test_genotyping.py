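import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zfnkit.genotyping import (
    AlignScores,
    EditCall,
    PairwiseAlignment,
    apply_edits,
    call_edits,
    classify_consequence,
    genotype_clones,
    global_align,
    percent_identity,
    summarize_spectrum,
)
from zfnkit.seqio import SequenceRecord

NEG = float("-inf")


def oracle_score(ref: str, alt: str, p: AlignScores = AlignScores()) -> float:
    """Quadratic-space Gotoh DP, affine gaps (length L costs open + (L-1)*extend)."""
    n, m = len(ref), len(alt)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in alt
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in ref
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = p.gap_open + (i - 1) * p.gap_extend
    for j in range(1, m + 1):
        Y[0][j] = p.gap_open + (j - 1) * p.gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = p.match if ref[i - 1] == alt[j - 1] else p.mismatch
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(
                M[i - 1][j] + p.gap_open,
                X[i - 1][j] + p.gap_extend,
                Y[i - 1][j] + p.gap_open,
            )
            Y[i][j] = max(
                M[i][j - 1] + p.gap_open,
                X[i][j - 1] + p.gap_open,
                Y[i][j - 1] + p.gap_extend,
            )
    for i in range(1, n + 1):
        X[i][m] = max(X[i][m], M[i - 1][m] + p.gap_open, X[i - 1][m] + p.gap_extend)
    for j in range(1, m + 1):
        Y[n][j] = max(Y[n][j], M[n][j - 1] + p.gap_open, Y[n][j - 1] + p.gap_extend)
    return max(M[n][m], X[n][m], Y[n][m])


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


# ---------------------------------------------------------------- alignment

class TestGlobalAlign:
    def test_identical_sequences(self):
        aln = global_align("ACGTACGT", "ACGTACGT")
        assert "-" not in aln.ref_aligned + aln.alt_aligned
        assert aln.score == 2.0 * 8

    def test_single_deletion(self):
        aln = global_align("ACGT", "AGT")
        assert aln.alt_aligned.count("-") == 1
        assert aln.ref_aligned.count("-") == 0
        assert aln.score == oracle_score("ACGT", "AGT") == 2.0  # A + gap + G + T

    def test_all_mismatch_beats_gapping(self):
        aln = global_align("ACGT", "TGCA")
        assert "-" not in aln.ref_aligned + aln.alt_aligned
        assert aln.score == oracle_score("ACGT", "TGCA") == -4.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACGT")

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_score_matches_dp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ref = random_seq(rng, int(rng.integers(1, 31)))
        alt = random_seq(rng, int(rng.integers(1, 31)))
        assert global_align(ref, alt).score == pytest.approx(oracle_score(ref, alt))

    def test_no_all_gap_columns_allowed(self):
        with pytest.raises(ValueError):
            PairwiseAlignment("A-C", "A-C", 0.0)


# ---------------------------------------------------------------- edit calling

class TestCallEdits:
    def test_identical_gives_no_calls(self):
        assert call_edits(global_align("ACGTACGT", "ACGTACGT")) == []

    def test_single_substitution(self):
        aln = PairwiseAlignment("ACGT", "ACTT", 0.0)
        assert call_edits(aln) == [EditCall("SNV", 3, "G", "T")]

    def test_two_column_gap_is_one_deletion(self):
        aln = PairwiseAlignment("ACGTT", "A--TT", 0.0)
        (call,) = call_edits(aln)
        assert call.kind == "deletion"
        assert (call.ref_pos, call.ref_allele) == (2, "CG")

    def test_deletion_left_aligned_in_homopolymer(self):
        # deleting any one A of the run is the same sequence; call the leftmost
        aln = global_align("CAAAAG", "CAAAG")
        (call,) = call_edits(aln)
        assert call.kind == "deletion"
        assert call.ref_pos == 2 and call.ref_allele == "A"

    def test_insertion_left_aligned_and_anchored(self):
        aln = global_align("CATG", "CAATG")
        (call,) = call_edits(aln)
        assert call.kind == "insertion"
        assert call.ref_pos == 1 and call.alt_allele == "A"

    def test_mixed_run_is_complex(self):
        aln = PairwiseAlignment("ACGT", "AT-T", 0.0)
        (call,) = call_edits(aln)
        assert call.kind == "complex"
        assert (call.ref_pos, call.ref_allele, call.alt_allele) == (2, "CG", "T")

    def test_adjacent_substitutions_merge_to_complex(self):
        aln = PairwiseAlignment("ACGT", "ATTT", 0.0)
        (call,) = call_edits(aln)
        assert call.kind == "complex"

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_roundtrip_reconstructs_alternate(self, seed):
        rng = np.random.default_rng(seed)
        ref = random_seq(rng, 80)
        # random perturbation: point changes plus one indel
        alt = list(ref)
        for _ in range(int(rng.integers(0, 4))):
            i = int(rng.integers(0, len(alt)))
            alt[i] = str(rng.choice(list("ACGT")))
        i = int(rng.integers(1, 70))
        if rng.random() < 0.5:
            del alt[i : i + int(rng.integers(1, 4))]
        else:
            alt[i:i] = list(random_seq(rng, int(rng.integers(1, 4))))
        alt = "".join(alt)
        aln = global_align(ref, alt)
        assert apply_edits(ref, call_edits(aln)) == alt


# ---------------------------------------------------------------- consequences

def make_cds_with_codon(codon_idx: int, codon: str, n_codons: int = 300) -> str:
    """A CDS of GCA codons with ``codon`` at the given 1-based index."""
    codons = ["ATG"] + ["GCA"] * (n_codons - 2) + ["TAA"]
    codons[codon_idx - 1] = codon
    return "".join(codons)


class TestClassifyConsequence:
    def test_missense_reported_as_codon_ref_alt(self):
        # codon 231 GCT (Ala); C-to-T at CDS position 692 makes GTT (Val)
        cds = make_cds_with_codon(231, "GCT")
        cons = classify_consequence([EditCall("SNV", 692, "C", "T")], cds)
        assert cons.consequence_class == "missense"
        assert cons.aa_change == "231A>V"
        assert cons.first_affected_codon == 231
        assert cons.last_intact_codon == 230

    def test_synonymous_substitution(self):
        cds = make_cds_with_codon(50, "GCT")
        cons = classify_consequence([EditCall("SNV", 150, "T", "C")], cds)
        assert cons.consequence_class == "synonymous"

    def test_single_base_deletion_is_frameshift(self):
        cds = make_cds_with_codon(50, "GCT")
        cons = classify_consequence([EditCall("deletion", 148, "G", "")], cds)
        assert cons.consequence_class == "frameshift" and cons.frameshift

    def test_codon_aligned_triplet_deletion_in_frame(self):
        cds = make_cds_with_codon(50, "GCT")
        cons = classify_consequence([EditCall("deletion", 148, "GCT", "")], cds)
        assert cons.consequence_class == "in_frame_indel"
        assert not cons.frameshift

    def test_nonsense_snv_is_premature_stop(self):
        cds = make_cds_with_codon(40, "TAC")  # Tyr; TAC -> TAA by C>A
        cons = classify_consequence([EditCall("SNV", 120, "C", "A")], cds)
        assert cons.consequence_class == "premature_stop"
        assert cons.premature_stop

    def test_no_edits_is_none(self):
        cds = make_cds_with_codon(10, "GCT")
        assert classify_consequence([], cds).consequence_class == "none"

    def test_edit_outside_cds_rejected(self):
        cds = make_cds_with_codon(10, "GCT", n_codons=20)
        with pytest.raises(ValueError):
            classify_consequence([EditCall("SNV", 100, "A", "T")], cds)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_frameshift_flag_equals_net_indel_mod3(self, seed):
        rng = np.random.default_rng(seed)
        cds = make_cds_with_codon(5, "GCT", n_codons=60)
        edits = []
        pos = 10
        while pos < 150 and len(edits) < 3:
            kind = rng.choice(["insertion", "deletion", "SNV"])
            if kind == "insertion":
                edits.append(EditCall("insertion", pos, "", random_seq(rng, int(rng.integers(1, 5)))))
            elif kind == "deletion":
                ln = int(rng.integers(1, 5))
                edits.append(EditCall("deletion", pos, cds[pos - 1 : pos - 1 + ln], ""))
            else:
                ref = cds[pos - 1]
                alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[ref]
                edits.append(EditCall("SNV", pos, ref, alt))
            pos += int(rng.integers(8, 20))
        net = sum(e.net_length for e in edits)
        cons = classify_consequence(edits, cds)
        assert cons.frameshift == (net % 3 != 0)


# ---------------------------------------------------------------- identity

class TestPercentIdentity:
    def test_identical(self):
        aln = global_align("A" * 100, "A" * 100)
        assert percent_identity(aln) == 100.0

    def test_one_mismatch_in_hundred(self):
        ref = "ACGT" * 25
        alt = ref[:50] + ("A" if ref[50] != "A" else "C") + ref[51:]
        assert percent_identity(global_align(ref, alt)) == pytest.approx(99.0)

    def test_gap_columns_in_denominator(self):
        ref = "A" * 102
        cols_ref = ref + "--"
        cols_alt = "C" * 2 + "A" * 100 + "GG"
        aln = PairwiseAlignment(cols_ref, cols_alt, 0.0)
        assert percent_identity(aln) == pytest.approx(100 * 100 / 104)

    def test_hundred_iff_identical(self):
        aln = global_align("ACGTA", "ACGTT")
        assert percent_identity(aln) < 100.0


# ---------------------------------------------------------------- spectrum

def _cons(frameshift=False, stop=False):
    from zfnkit.genotyping import ConsequenceCall

    cls = "frameshift" if frameshift else ("premature_stop" if stop else "missense")
    return ConsequenceCall(cls, 1, 0, frameshift=frameshift, premature_stop=stop)


class TestSummarizeSpectrum:
    def test_direct_counts(self):
        per_clone = [
            ([EditCall("SNV", 5, "A", "T")], _cons()),
            ([EditCall("SNV", 9, "C", "G")], _cons()),
            ([EditCall("deletion", 5, "A", "")], _cons(frameshift=True)),
            ([EditCall("complex", 5, "ACG", "T")], _cons(frameshift=True)),
        ]
        s = summarize_spectrum(per_clone)
        assert (s.pct_snv, s.pct_indel, s.pct_complex) == (50.0, 25.0, 25.0)
        assert s.pct_snv + s.pct_indel + s.pct_complex == pytest.approx(100.0)
        assert s.pct_frameshift == 50.0

    def test_category_precedence_complex_over_indel_over_snv(self):
        edits = [
            EditCall("SNV", 5, "A", "T"),
            EditCall("deletion", 9, "C", ""),
            EditCall("complex", 20, "AC", "G"),
        ]
        s = summarize_spectrum([(edits, _cons(frameshift=True))])
        assert s.pct_complex == 100.0

    def test_per_mutation_counting(self):
        edits = [EditCall("SNV", 5, "A", "T"), EditCall("deletion", 9, "C", "")]
        s = summarize_spectrum([(edits, _cons(frameshift=True))], counting="per_mutation")
        assert s.pct_snv == s.pct_indel == 50.0

    def test_unedited_clones_error_or_report(self):
        per_clone = [([], _cons()), ([EditCall("SNV", 5, "A", "T")], _cons())]
        with pytest.raises(ValueError):
            summarize_spectrum(per_clone)
        s = summarize_spectrum(per_clone, on_unedited="report")
        assert s.n_unedited == 1 and s.n_sequences == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_spectrum([])


# ---------------------------------------------------------------- pipeline

def test_genotype_clones_identical_to_reference(reference_cds):
    clones = [SequenceRecord(f"c{i}", reference_cds) for i in range(3)]
    table, spectrum = genotype_clones(reference_cds, clones)
    assert (table["kind"] == "none").all()
    assert (table["identity"] == 100.0).all()
    assert spectrum.n_unedited == 3
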