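"""Aligner and fingerprinting correctness against independent oracles."""

import itertools

import numpy as np
import pytest
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from sexscan import dupfinger as dup
from sexscan.marker import revcomp
from sexscan.models import FixtureConfig, GeneStructure, ValidationError
from sexscan import synth

from .oracles import enumerate_global_affine, recursive_global_affine

MATCH, MISMATCH, GAP_OPEN, GAP_EXT = 5.0, -4.0, 10.0, 0.5


def biopython_score(a, b, mode, protein=False):
    """Independent affine-gap optimum from Biopython's C aligner."""
    al = PairwiseAligner()
    al.mode = mode
    if protein:
        al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    else:
        al.match_score, al.mismatch_score = MATCH, MISMATCH
    al.open_gap_score = -(GAP_OPEN + GAP_EXT)
    al.extend_gap_score = -GAP_EXT
    return al.score(a, b)


class TestAlignPair:
    def test_identity_local_alignment(self):
        aln = dup.align_pair("ACGT", "ACGT", mode="local")
        assert aln.aligned_a == aln.aligned_b == "ACGT"
        assert aln.score == 4 * MATCH

    def test_global_score_matches_independent_recursion(self):
        aln = dup.align_pair("ACGTACGT", "ACGAACGT", mode="global")
        expected = recursive_global_affine(
            "ACGTACGT", "ACGAACGT", MATCH, MISMATCH, GAP_OPEN, GAP_EXT
        )
        assert aln.score == pytest.approx(expected)

    def test_all_short_AC_pairs_match_enumeration_oracle(self):
        """Exhaustive small-instance equivalence over the {A,C} alphabet."""
        strings = [
            "".join(p)
            for n in range(1, 5)
            for p in itertools.product("AC", repeat=n)
        ]
        for a in strings:
            for b in strings:
                got = dup.align_pair(a, b, mode="global").score
                want = enumerate_global_affine(a, b, MATCH, MISMATCH, GAP_OPEN, GAP_EXT)
                assert got == pytest.approx(want), (a, b)

    @given(
        st.text(alphabet="AC", min_size=1, max_size=8),
        st.text(alphabet="AC", min_size=1, max_size=8),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_longer_AC_pairs_match_memoized_recursion(self, a, b):
        got = dup.align_pair(a, b, mode="global").score
        want = recursive_global_affine(a, b, MATCH, MISMATCH, GAP_OPEN, GAP_EXT)
        assert got == pytest.approx(want)

    @given(
        st.text(alphabet="ACGT", min_size=1, max_size=30),
        st.text(alphabet="ACGT", min_size=1, max_size=30),
        st.sampled_from(["local", "global"]),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_scores_match_biopython_aligner(self, a, b, mode):
        got = dup.align_pair(a, b, mode=mode).score
        assert got == pytest.approx(biopython_score(a, b, mode))

    def test_gapless_recovery_of_inputs(self):
        aln = dup.align_pair("ACGTTT", "AGGTTT", mode="global")
        assert aln.aligned_a.replace("-", "") == "ACGTTT"
        assert aln.aligned_b.replace("-", "") == "AGGTTT"

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            dup.align_pair("", "ACGT")

    def test_fixture_gene_pair_has_exactly_two_intron4_gap_runs(self, genes):
        aln = dup.align_pair(genes.amha_seq, genes.amhy_seq, mode="global")
        calls = dup.localize_indels(aln, genes.amha_struct)
        assert sorted(c.length for c in calls) == [131, 166]
        assert all(c.feature == ("intron", 4) and c.carrier == "B" for c in calls)


class TestPercentIdentity:
    def test_identical_sequences_100(self):
        aln = dup.align_pair("A" * 100, "A" * 100, mode="global")
        assert dup.percent_identity(aln) == 100.0

    def test_eight_mismatches_in_100_columns(self):
        """Column-tally convention: 92 identical of 100 columns -> 92.0%."""
        rng = np.random.default_rng(4)
        a = "".join(rng.choice(list("ACGT"), 100))
        b = list(a)
        for pos in rng.choice(100, size=8, replace=False):
            b[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[pos]]
        aln = dup.PairwiseAlignment(
            aligned_a=a, aligned_b="".join(b), score=0.0, mode="global",
            a_span=(0, 100), b_span=(0, 100),
        )
        assert dup.percent_identity(aln) == pytest.approx(92.0)

    @given(
        st.text(alphabet="ACGT", min_size=5, max_size=40),
        st.text(alphabet="ACGT", min_size=5, max_size=40),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_symmetry_and_revcomp_invariance(self, a, b):
        pid = dup.percent_identity(dup.align_pair(a, b, mode="global"))
        swapped = dup.percent_identity(dup.align_pair(b, a, mode="global"))
        rc = dup.percent_identity(
            dup.align_pair(revcomp(a), revcomp(b), mode="global")
        )
        assert pid == pytest.approx(swapped)
        assert pid == pytest.approx(rc)


class TestExonwiseIdentity:
    def test_identical_genes_all_100(self, genes):
        t = dup.exonwise_identity(
            genes.amha_seq, genes.amha_seq, genes.amha_struct, genes.amha_struct
        )
        assert (t["identity_pct"] == 100.0).all()

    def test_single_mutated_exon_against_mismatch_oracle(self):
        rates = [0.0] * 7
        rates[1] = 0.05  # exon 2
        cfg = FixtureConfig(per_exon_divergence=tuple(rates), insertion_lengths=())
        g = synth.build_fixture_genes(cfg)
        t = dup.exonwise_identity(g.amha_seq, g.amhy_seq, g.amha_struct, g.amhy_struct)
        s, e = g.amha_struct.exon_spans[1]
        mism = sum(x != y for x, y in zip(g.amha_seq[s:e], g.amhy_seq[s:e]))
        expected = 100.0 * (e - s - mism) / (e - s)
        # local alignment may clip terminal mismatches, never drop below
        assert t["identity_pct"].iloc[1] >= expected - 1e-9
        assert t["identity_pct"].iloc[1] == pytest.approx(expected, abs=1.0)
        assert (t["identity_pct"].drop(index=1) == 100.0).all()

    def test_default_fixture_identities_span_printed_range(self, genes):
        t = dup.exonwise_identity(
            genes.amha_seq, genes.amhy_seq, genes.amha_struct, genes.amhy_struct
        )
        assert t["identity_pct"].min() >= 91.8 - 0.5
        assert t["identity_pct"].max() <= 97.3 + 0.5

    def test_exon_count_mismatch_raises(self, genes):
        other = GeneStructure(
            gene_id="x", scaffold="s", gene_span=(0, 400), strand="+",
            exon_spans=((0, 100), (200, 400)), cds_span=(0, 99),
        )
        with pytest.raises(ValidationError, match="exon count"):
            dup.exonwise_identity(genes.amha_seq, "A" * 400, genes.amha_struct, other)


class TestLocalizeIndels:
    def test_identical_sequences_no_calls(self, genes):
        aln = dup.align_pair(genes.amha_seq, genes.amha_seq, mode="global")
        assert dup.localize_indels(aln, genes.amha_struct) == []

    def test_planted_intron2_insertion_recovered_exactly(self, genes):
        rng = np.random.default_rng(5)
        s2, e2 = genes.amha_struct.intron_spans[1]
        pos = int(rng.integers(s2 + 5, e2 - 5))
        ins = "".join(rng.choice(list("ACGT"), 50))
        mutated = genes.amha_seq[:pos] + ins + genes.amha_seq[pos:]
        aln = dup.align_pair(genes.amha_seq, mutated, mode="global")
        calls = dup.localize_indels(aln, genes.amha_struct)
        assert len(calls) == 1
        c = calls[0]
        assert (c.carrier, c.length, c.feature) == ("B", 50, ("intron", 2))
        # the called block really is what sits at that position in B
        assert mutated[c.position_in_carrier : c.position_in_carrier + c.length] == c.sequence

    def test_swap_symmetry(self, genes):
        ab = dup.localize_indels(
            dup.align_pair(genes.amha_seq, genes.amhy_seq, mode="global"),
            genes.amha_struct,
        )
        ba = dup.localize_indels(
            dup.align_pair(genes.amhy_seq, genes.amha_seq, mode="global"),
            genes.amhy_struct,
        )
        assert sorted(c.length for c in ab) == sorted(c.length for c in ba)
        assert {c.carrier for c in ab} == {"B"} and {c.carrier for c in ba} == {"A"}

    def test_insertion_lengths_sum_to_gene_length_difference(self, genes):
        aln = dup.align_pair(genes.amha_seq, genes.amhy_seq, mode="global")
        calls = dup.localize_indels(aln, genes.amha_struct, min_indel_length=1)
        assert sum(c.length for c in calls) == len(genes.amhy_seq) - len(genes.amha_seq)


class TestTranslateCds:
    def test_simple_orf(self):
        tr = dup.translate_cds("ATGAAATAA")
        assert tr.protein == "MK"
        assert not tr.premature_stop

    def test_fixture_cds_gives_530_residues(self, genes):
        tr = dup.translate_cds(genes.amha_struct.spliced_cds(genes.amha_seq))
        assert len(tr.protein) == 530

    def test_matches_biopython_translation(self):
        rng = np.random.default_rng(2)
        seq = "ATG" + "".join(
            rng.choice(["AAA", "CCC", "GGT", "TGC", "GAT", "CTG", "TTT"], 299)
        ) + "TAA"
        tr = dup.translate_cds(seq)
        assert tr.protein == str(Seq(seq).translate(to_stop=True))

    def test_non_acgt_codon_names_position(self):
        with pytest.raises(ValidationError, match="position 4"):
            dup.translate_cds("ATGANATAA")

    def test_internal_stop_flagged_premature(self):
        tr = dup.translate_cds("ATGTAAAAATAA")
        assert tr.protein == "M"
        assert tr.premature_stop


class TestDomainIdentity:
    def test_identical_proteins_all_100(self):
        p = "MKV" * 50
        t = dup.domain_identity(p, p, [("D1", (10, 40))])
        assert (t["identity_pct"] == 100.0).all()

    def test_five_substitutions_in_93_residue_domain(self):
        rng = np.random.default_rng(8)
        p = "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), 120))
        q = list(p)
        # five substitutions inside residues 11..103 (a 93-residue domain)
        for pos, repl in zip((20, 40, 60, 80, 100), "WWWWW"):
            q[pos] = repl if p[pos] != repl else "Y"
        q = "".join(q)
        t = dup.domain_identity(p, q, [("D", (11, 103))]).set_index("label")
        assert t.loc["D", "identity_pct"] == pytest.approx(100 * 88 / 93)

    def test_fixture_protein_identity_near_printed_value(self, genes):
        pa = dup.translate_cds(genes.amha_struct.spliced_cds(genes.amha_seq)).protein
        pb = dup.translate_cds(genes.amhy_struct.spliced_cds(genes.amhy_seq)).protein
        t = dup.domain_identity(pa, pb, genes.domains).set_index("label")
        assert t.loc["full", "identity_pct"] == pytest.approx(92.1, abs=2.0)

    def test_out_of_range_domain_raises(self):
        with pytest.raises(ValidationError):
            dup.domain_identity("MKV", "MKV", [("D", (1, 10))])


class TestClassifyTranscriptVariant:
    def test_fixture_truncated_isoform(self, default_config, genes):
        rep = dup.classify_transcript_variant(
            genes.transcripts["amha-truncated"],
            genes.transcripts["amha-full"],
            genes.amha_struct,
            genes.domains,
            transcript_id="amha-truncated",
        )
        ins_seq, ins_exon = default_config.truncating_insertion
        assert rep.insertion is not None
        seq, length, exon = rep.insertion
        assert length == len(ins_seq) == 5
        assert exon == ins_exon == 7
        assert rep.frameshift and rep.premature_stop
        assert "TGF-beta" in rep.lost_domains
        assert rep.predicted_protein_length < 438

    def test_detected_insertion_reconstructs_variant(self, genes):
        """Alignment may slide the gap; the call must still rebuild the variant."""
        full = genes.transcripts["amha-full"]
        trunc = genes.transcripts["amha-truncated"]
        rep = dup.classify_transcript_variant(
            trunc, full, genes.amha_struct, genes.domains
        )
        seq, length, _ = rep.insertion
        rebuilt = [
            full[:k] + seq + full[k:] for k in range(len(full) + 1)
        ]
        assert trunc in rebuilt

    def test_identical_transcript_clean_report(self, genes):
        rep = dup.classify_transcript_variant(
            genes.transcripts["amha-full"],
            genes.transcripts["amha-full"],
            genes.amha_struct,
            genes.domains,
        )
        assert rep.insertion is None
        assert not rep.frameshift and not rep.premature_stop
        assert rep.lost_domains == []
        assert rep.predicted_protein_length == 530

    def test_in_frame_insertion_extends_protein(self, genes):
        """A 6-base exon-5 insertion: no frameshift, protein two residues longer."""
        full = genes.transcripts["amha-full"]
        s5, _ = genes.amha_struct.exon_spans[4]
        tpos = genes.amha_struct.gene_to_transcript(s5) + 30
        cds_lo, _ = genes.amha_struct.cds_span_in_transcript
        tpos = cds_lo + 3 * ((tpos - cds_lo) // 3)  # codon boundary
        variant = full[:tpos] + "GCTGCT" + full[tpos:]
        rep = dup.classify_transcript_variant(
            variant, full, genes.amha_struct, genes.domains
        )
        assert not rep.frameshift
        assert not rep.premature_stop
        assert rep.predicted_protein_length == 532
        assert rep.insertion[2] == 5
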