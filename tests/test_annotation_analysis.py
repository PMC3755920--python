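"""ORF scanning, coding-potential cascade, NTR calling, junction sets and the
two-condition comparison, each against independent oracles."""

import re

import numpy as np
import pytest
from Bio.Seq import Seq
from scipy import stats

from excluseq.annotation_analysis import (
    CodingThresholds,
    call_ntrs,
    classify_coding,
    compare_conditions,
    compare_junctions,
    find_orfs,
    quant_from_counts,
)
from excluseq.assembly import Contig
from excluseq.homology import ScoringScheme, SubjectIndex
from excluseq.io_formats import SequenceRecord, TranscriptModel
from excluseq.mapping_quant import QuantRecord

from conftest import random_dna

_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


def orf_oracle(seq):
    """Brute-force six-frame scanner: first ATG after each stop, to the next
    stop (or sequence end), via Biopython translation and string splitting."""
    out = set()
    rc = str(Seq(seq).reverse_complement())
    for frame in (1, 2, 3, -1, -2, -3):
        src = seq if frame > 0 else rc
        off = abs(frame) - 1
        coding = src[off : off + 3 * ((len(src) - off) // 3)]
        aa = str(Seq(coding).translate())
        for segment in aa.split("*"):
            m = segment.find("M")
            if m >= 0:
                out.add((frame, segment[m:]))
    return out


class TestFindOrfs:
    def test_minimal_orf(self):
        (orf,) = find_orfs("ATGGCCTAA")
        assert orf.frame == 1 and orf.peptide == "MA" and orf.length_aa == 2
        assert (orf.start, orf.end) == (0, 9)
        assert orf.stop_terminated

    def test_no_atg_no_orfs(self):
        assert find_orfs("CCCCCCGGGGGGCCCGGG") == []

    def test_reverse_frame_coordinates(self):
        from excluseq._kmers import revcomp_str

        seq = "TT" + revcomp_str("ATGGCCTAA") + "GG"
        (orf,) = find_orfs(seq, min_aa=2)
        assert orf.frame < 0 and orf.peptide == "MA"
        assert seq[orf.start : orf.end] == revcomp_str("ATGGCCTAA")

    def test_open_ended_orf_flag(self):
        seq = "ATGGCCGCA"  # no stop codon
        (orf,) = find_orfs(seq, allow_open=True)
        assert not orf.stop_terminated and orf.peptide == "MAA"
        assert find_orfs(seq, allow_open=False) == []

    def test_matches_bruteforce_oracle_on_random_sequences(self, rng):
        for _ in range(100):
            seq = random_dna(rng, 600)
            got = {(o.frame, o.peptide) for o in find_orfs(seq)}
            assert got == orf_oracle(seq)

    def test_sorted_by_length_descending(self, rng):
        seq = random_dna(rng, 600)
        lens = [o.length_aa for o in find_orfs(seq)]
        assert lens == sorted(lens, reverse=True)


def make_quant(fpkm_a, fpkm_b):
    qa = QuantRecord("c", 10, 1.0, fpkm_a, 1000, "a", 1000)
    qb = QuantRecord("c", 10, 1.0, fpkm_b, 1000, "b", 1000)
    return (qa, qb)


def orf_free_dna(rng, n, max_aa=30):
    while True:
        s = random_dna(rng, n)
        orfs = find_orfs(s)
        if not orfs or orfs[0].length_aa <= max_aa:
            return s


class TestClassifyCoding:
    def test_noncoding_candidate_rule(self, rng):
        seq = orf_free_dna(rng, 1000)
        cls = classify_coding(Contig("c", seq, 1.0, 21), None, make_quant(12.0, 0.0))
        assert cls == "noncoding_candidate"

    def test_length_floor(self, rng):
        seq = orf_free_dna(rng, 150)
        assert classify_coding(Contig("c", seq, 1, 21), None, make_quant(50, 50)) == "below_expression"

    @pytest.mark.parametrize(
        "n_aa,expected",
        [(199, "noncoding_candidate"), (200, "noncoding_candidate"), (201, "coding_orf")],
    )
    def test_orf_length_boundary(self, rng, n_aa, expected):
        pep = "M" + "".join(np.array(list("ACDEFGHIKLNPQRSTVWY"))[rng.integers(0, 19, n_aa - 1)])
        cds = "".join(_CODON[a] for a in pep) + "TAA"
        cls = classify_coding(Contig("c", cds, 1, 21), None, make_quant(20, 20))
        assert cls == expected

    @pytest.mark.parametrize(
        "length,expected",
        [(199, "below_expression"), (200, "noncoding_candidate"), (201, "noncoding_candidate")],
    )
    def test_length_boundary(self, rng, length, expected):
        seq = orf_free_dna(rng, length, max_aa=60)
        assert classify_coding(Contig("c", seq, 1, 21), None, make_quant(15, 0)) == expected

    @pytest.mark.parametrize(
        "fpkm,expected", [(9.99, "below_expression"), (10.0, "noncoding_candidate")]
    )
    def test_fpkm_boundary(self, rng, fpkm, expected):
        seq = orf_free_dna(rng, 500)
        assert classify_coding(Contig("c", seq, 1, 21), None, make_quant(fpkm, 0)) == expected

    def test_planted_homolog_is_coding(self, rng):
        prot = "".join(np.array(list(_CODON))[rng.integers(0, 20, 120)])
        cds = "".join(_CODON[a] for a in prot)
        idx = SubjectIndex([SequenceRecord("p", prot)], ScoringScheme.translated_default())
        cls = classify_coding(Contig("c", cds, 1, 21), idx, make_quant(0, 0))
        assert cls == "coding_homology"


def tm(chrom, strand, exons, tid, gid=None):
    return TranscriptModel(chrom, strand, tuple(exons), gid or tid, tid)


class TestCallNtrs:
    def test_identical_chain_is_known(self):
        ann = [tm("c1", "+", [(100, 500), (700, 900)], "t1")]
        asm = [tm("c1", "+", [(100, 500), (700, 900)], "a1")]
        calls, bp = call_ntrs(asm, ann)
        assert calls[0].ntr_class == "known" and bp == 0

    def test_intergenic_transcript_is_ntr(self):
        ann = [tm("c1", "+", [(100, 500)], "t1")]
        asm = [tm("c1", "+", [(10_000, 10_800)], "a1")]
        calls, bp = call_ntrs(asm, ann)
        assert calls[0].ntr_class == "ntr"
        assert calls[0].novel_exons == 1
        assert bp == 800

    def test_overlapping_different_chain_is_new_isoform(self):
        ann = [tm("c1", "+", [(100, 500), (700, 900)], "t1")]
        asm = [tm("c1", "+", [(100, 500), (800, 900)], "a1")]
        calls, _ = call_ntrs(asm, ann)
        assert calls[0].ntr_class == "new_isoform"
        assert calls[0].novel_junctions == 1

    def test_strand_awareness_toggle(self):
        ann = [tm("c1", "+", [(100, 500)], "t1")]
        asm = [tm("c1", "-", [(200, 400)], "a1")]
        stranded, _ = call_ntrs(asm, ann, strand_aware=True)
        unstranded, _ = call_ntrs(asm, ann, strand_aware=False)
        assert stranded[0].ntr_class == "ntr"
        assert unstranded[0].ntr_class == "new_isoform"

    def test_gene_span_option_counts_intronic_overlap(self):
        ann = [tm("c1", "+", [(100, 200), (800, 900)], "t1")]
        asm = [tm("c1", "+", [(400, 600)], "a1")]  # inside the intron
        exon_level, _ = call_ntrs(asm, ann, gene_span=False)
        span_level, _ = call_ntrs(asm, ann, gene_span=True)
        assert exon_level[0].ntr_class == "ntr"
        assert span_level[0].ntr_class == "new_isoform"

    def test_novel_bp_unions_overlapping_ntr_exons(self):
        ann = []
        asm = [
            tm("c1", "+", [(100, 300)], "a1"),
            tm("c1", "+", [(200, 400)], "a2"),
        ]
        calls, bp = call_ntrs(asm, ann)
        assert all(c.ntr_class == "ntr" for c in calls)
        assert bp == 300  # union of [100,300) and [200,400)

    def test_out_of_bounds_rejected(self):
        asm = [tm("c1", "+", [(100, 5000)], "a1")]
        with pytest.raises(ValueError):
            call_ntrs(asm, [], chrom_sizes={"c1": 1000})

    def test_planted_novel_loci_recovered(self, small_dataset):
        cfg, genome, annotation, truth, _ = small_dataset
        assembled = [truth.models[t.transcript_id] for t in truth.transcripts
                     if t.chrom != "chrB"]
        calls, bp = call_ntrs(assembled, annotation)
        ntr_ids = {c.transcript.transcript_id for c in calls if c.ntr_class == "ntr"}
        novel_ids = {t.transcript_id for t in truth.by_label("novel")}
        assert ntr_ids == novel_ids
        assert bp == sum(t.length for t in truth.by_label("novel"))
        assert all(c.ntr_class == "known" for c in calls
                   if c.transcript.transcript_id not in novel_ids)


class TestCompareJunctions:
    def test_identity(self):
        models = [tm("c1", "+", [(0, 10), (20, 30), (40, 50)], "t1")]
        confirmed, novel, total = compare_junctions(models, models)
        assert (confirmed, novel, total) == (2, 0, 2)

    def test_single_exon_inputs(self):
        a = [tm("c1", "+", [(0, 10)], "t1")]
        assert compare_junctions(a, a) == (0, 0, 0)

    def test_duplicate_junctions_collapse(self):
        asm = [
            tm("c1", "+", [(0, 10), (20, 30)], "a1"),
            tm("c1", "+", [(2, 10), (20, 28)], "a2"),  # same (10, 20) junction
        ]
        confirmed, novel, total = compare_junctions(asm, [])
        assert (confirmed, novel, total) == (0, 1, 0)


class TestCompareConditions:
    def test_identity_gives_unit_correlation_and_no_calls(self, rng):
        counts = rng.integers(1, 500, 50)
        qa = quant_from_counts([f"f{i}" for i in range(50)], [1000] * 50, counts, "a")
        qb = quant_from_counts([f"f{i}" for i in range(50)], [1000] * 50, counts, "b")
        r, calls = compare_conditions(qa, qb)
        assert r == pytest.approx(1.0)
        assert all(c.direction == "ns" for c in calls)

    def test_strong_feature_flagged_with_hypergeom_oracle(self):
        n = 200
        ids = [f"f{i}" for i in range(n)]
        ca = np.full(n, 5000); cb = np.full(n, 5000)
        ca[0], cb[0] = 100, 10
        qa = quant_from_counts(ids, [1000] * n, ca, "a")
        qb = quant_from_counts(ids, [1000] * n, cb, "b")
        r, calls = compare_conditions(qa, qb)
        c0 = calls[0]
        # independent oracle: conditional (hypergeometric) 2x2 tail
        table = [[c0.count_a, c0.total_a - c0.count_a], [c0.count_b, c0.total_b - c0.count_b]]
        oracle_p = stats.fisher_exact(table)[1]
        assert oracle_p < 1e-15
        assert c0.p_value == pytest.approx(oracle_p)
        assert c0.direction == "over"
        assert all(c.direction == "ns" for c in calls[1:])

    def test_label_swap_flips_directions_preserves_pvalues(self, rng):
        n = 100
        ids = [f"f{i}" for i in range(n)]
        w = rng.lognormal(0, 1, n); w /= w.sum()
        ca = rng.multinomial(100_000, w)
        cb = rng.multinomial(100_000, w)
        ca[:5] = ca[:5] * 6  # planted asymmetry
        qa = quant_from_counts(ids, [1000] * n, ca, "a")
        qb = quant_from_counts(ids, [1000] * n, cb, "b")
        r1, calls1 = compare_conditions(qa, qb)
        r2, calls2 = compare_conditions(qb, qa)
        flip = {"over": "under", "under": "over", "ns": "ns"}
        for x, y in zip(calls1, calls2):
            assert y.p_value == pytest.approx(x.p_value)
            assert y.direction == flip[x.direction]
        assert r1 == pytest.approx(r2)

    def test_mismatched_feature_sets_rejected(self):
        qa = quant_from_counts(["a"], [100], [10], "a")
        qb = quant_from_counts(["b"], [100], [10], "b")
        with pytest.raises(ValueError):
            compare_conditions(qa, qb)

    def test_planted_de_recovered_on_simulated_counts(self, small_dataset):
        cfg, genome, annotation, truth, _ = small_dataset
        tested = [t for t in truth.transcripts if t.chrom != "chrB"]
        ids = [t.transcript_id for t in tested]
        lens = [t.length for t in tested]
        qa = quant_from_counts(ids, lens, [t.count_carrier for t in tested], "carrier")
        qb = quant_from_counts(ids, lens, [t.count_wt for t in tested], "wt")
        r, calls = compare_conditions(qa, qb)
        de_ids = {t.transcript_id for t in truth.transcripts if t.label in ("de_up", "de_down")}
        flagged = {c.feature_id for c in calls if c.direction != "ns"}
        assert len(flagged & de_ids) >= int(0.8 * len(de_ids))
        assert len(flagged - de_ids) <= 1
        up = {c.feature_id for c in calls if c.direction == "over"}
        assert up & {t.transcript_id for t in truth.by_label("de_up")}
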