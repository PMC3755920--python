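"""Annotation-side analyses: ORFs and coding potential, novel transcribed
regions (NTRs) against a GTF, exon-junction comparison, and the two-condition
expression comparison (log-FPKM correlation plus per-feature exact tests).

The coding-potential call is a rule cascade: translated homology at
E < 0.01, then longest ORF > 200 aa, then the long-noncoding criteria
(>= 200 bp and FPKM >= 10 in at least one sample). The differential test is
an exact conditional 2x2 test (Fisher) with Benjamini-Hochberg correction —
a deliberately simple stand-in for a dispersion-modelling DE engine, adequate
for a two-library comparison with no replicates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .homology import ScoringScheme, SubjectIndex, search_translated
from .io_formats import SequenceRecord, TranscriptModel
from .mapping_quant import QuantRecord

logger = logging.getLogger(__name__)

_CODON = {}


def _codon_table():
    if not _CODON:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON[stop] = "*"
    return _CODON


# ---------------------------------------------------------------------------
# ORF finding and coding potential
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ORF:
    """An ATG..stop span; coordinates are on the forward strand of the input."""

    frame: int  # +1,+2,+3,-1,-2,-3
    start: int  # 0-based half-open, forward coordinates; includes the stop codon
    end: int
    peptide: str
    length_aa: int
    stop_terminated: bool


def find_orfs(seq: str, min_aa: int = 1, allow_open: bool = True) -> list[ORF]:
    """Six-frame ORF scan: first ATG after each stop, through the next stop.

    Open-ended ORFs (running off the sequence end without a stop) are
    reported when ``allow_open``. Sorted by peptide length descending, then
    (frame order, start) for determinism.
    """
    from ._kmers import revcomp_str

    seq = seq.upper()
    table = _codon_table()
    L = len(seq)
    orfs: list[ORF] = []
    for frame in (1, 2, 3, -1, -2, -3):
        src = seq if frame > 0 else revcomp_str(seq)
        off = abs(frame) - 1
        codons = [src[i : i + 3] for i in range(off, len(src) - 2, 3)]
        aa = [table.get(c, "X") for c in codons]
        i = 0
        n = len(aa)
        while i < n:
            if aa[i] != "M":
                i += 1
                continue
            j = i
            while j < n and aa[j] != "*":
                j += 1
            stop_terminated = j < n
            if not stop_terminated and not allow_open:
                break
            pep = "".join(aa[i:j])
            if len(pep) >= min_aa:
                nt_start = off + 3 * i
                nt_end = off + 3 * (j + 1 if stop_terminated else j)
                if frame > 0:
                    span = (nt_start, nt_end)
                else:
                    span = (L - nt_end, L - nt_start)
                orfs.append(
                    ORF(
                        frame=frame,
                        start=span[0],
                        end=span[1],
                        peptide=pep,
                        length_aa=len(pep),
                        stop_terminated=stop_terminated,
                    )
                )
            # next ORF starts after this stop (nested starts are not re-reported)
            i = j + 1
    frame_rank = {f: r for r, f in enumerate((1, 2, 3, -1, -2, -3))}
    orfs.sort(key=lambda o: (-o.length_aa, frame_rank[o.frame], o.start))
    return orfs


@dataclass
class CodingThresholds:
    max_evalue: float = 0.01
    min_orf_aa: int = 200  # strict: coding requires ORF > this
    min_length_bp: int = 200  # lncRNA candidates must be at least this long
    min_fpkm: float = 10.0  # ... and expressed at least this much in one sample


def classify_coding(
    contig,
    proteins: SubjectIndex | None,
    quant_pair: tuple[QuantRecord, QuantRecord] | None,
    thresholds: CodingThresholds | None = None,
    scheme: ScoringScheme | None = None,
) -> str:
    """Rule cascade -> {coding_homology, coding_orf, noncoding_candidate,
    below_expression}."""
    t = thresholds or CodingThresholds()
    seq = contig.seq
    cid = contig.id
    if proteins is not None and len(proteins):
        scheme = scheme or ScoringScheme.translated_default()
        hits = search_translated(SequenceRecord(cid, seq), proteins, scheme, t.max_evalue)
        if hits:
            return "coding_homology"
    orfs = find_orfs(seq, min_aa=1, allow_open=True)
    if orfs and orfs[0].length_aa > t.min_orf_aa:
        return "coding_orf"
    fpkm_max = max(q.fpkm for q in quant_pair) if quant_pair else 0.0
    if len(seq) >= t.min_length_bp and fpkm_max >= t.min_fpkm:
        return "noncoding_candidate"
    return "below_expression"


# ---------------------------------------------------------------------------
# Novel transcribed regions
# ---------------------------------------------------------------------------


@dataclass
class NtrCall:
    transcript: TranscriptModel
    ntr_class: str  # known | new_isoform | ntr
    novel_exons: int
    novel_junctions: int


def _merged_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    cur_s = cur_e = None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def call_ntrs(
    assembled: list[TranscriptModel],
    annotation: list[TranscriptModel],
    strand_aware: bool = True,
    gene_span: bool = False,
    chrom_sizes: dict[str, int] | None = None,
) -> tuple[list[NtrCall], int]:
    """Classify genome-placed transcripts against an annotation.

    ``known`` = identical exon chain; ``new_isoform`` = >= 1 bp exon overlap
    with an annotated transcript but a different chain; ``ntr`` = no overlap
    at all. With ``gene_span`` the overlap test uses annotated gene spans
    (first-to-last exon) instead of exons. Returns the calls plus the total
    novel transcribed bp (union of ntr exon intervals, strand-collapsed).
    """
    if chrom_sizes is not None:
        for m in assembled:
            if m.chrom not in chrom_sizes or m.span[1] > chrom_sizes[m.chrom]:
                raise ValueError(f"{m.transcript_id}: coordinates beyond {m.chrom} bounds")
    trees: dict = {}
    chains = set()
    for m in annotation:
        key = (m.chrom, m.strand) if strand_aware else m.chrom
        tree = trees.setdefault(key, IntervalTree())
        if gene_span:
            tree.addi(m.span[0], m.span[1])
        else:
            for s, e in m.exons:
                tree.addi(s, e)
        chains.add((m.chrom, m.strand, m.exons))
    annotated_junctions = {j for m in annotation for j in m.junctions}
    calls = []
    novel_intervals: list[tuple[str, int, int]] = []
    for m in assembled:
        key = (m.chrom, m.strand) if strand_aware else m.chrom
        if (m.chrom, m.strand, m.exons) in chains:
            calls.append(NtrCall(m, "known", 0, 0))
            continue
        tree = trees.get(key)
        overlaps = tree is not None and any(tree.overlap(s, e) for s, e in m.exons)
        if overlaps:
            novel_j = sum(1 for j in m.junctions if j not in annotated_junctions)
            calls.append(NtrCall(m, "new_isoform", 0, novel_j))
        else:
            calls.append(NtrCall(m, "ntr", len(m.exons), len(m.junctions)))
            novel_intervals.extend((m.chrom, s, e) for s, e in m.exons)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in novel_intervals:
        by_chrom.setdefault(chrom, []).append((s, e))
    novel_bp = sum(_merged_length(iv) for iv in by_chrom.values())
    return calls, novel_bp


def compare_junctions(
    assembled: list[TranscriptModel], annotation: list[TranscriptModel]
) -> tuple[int, int, int]:
    """Set comparison of splice junctions: (confirmed, novel, annotated_total)."""
    asm = {j for m in assembled for j in m.junctions}
    ann = {j for m in annotation for j in m.junctions}
    return len(asm & ann), len(asm - ann), len(ann)


# ---------------------------------------------------------------------------
# Two-condition expression comparison
# ---------------------------------------------------------------------------


@dataclass
class DiffCall:
    feature_id: str
    count_a: int
    count_b: int
    total_a: int
    total_b: int
    p_value: float
    q_value: float
    direction: str  # over | under | ns


def fisher_2x2_pvalue(count_a: int, count_b: int, total_a: int, total_b: int) -> float:
    """Two-sided exact conditional test of two binomial proportions."""
    table = [[count_a, total_a - count_a], [count_b, total_b - count_b]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def _median_ratio_totals(ca, cb, ta, tb, min_features=10):
    """Swap-symmetric effective library sizes via the median log count ratio.

    Multinomial read sampling makes every null feature's raw proportion shift
    when other features change (compositional distortion), so the 2x2 tables
    use effective totals chosen so the median expressed feature has equal
    adjusted proportions. With fewer than ``min_features`` co-expressed
    features no normalisation is applied.
    """
    both = (ca > 0) & (cb > 0)
    if both.sum() < min_features:
        return ta, tb
    logm = float(np.median(np.log(ca[both]) - np.log(cb[both])))
    g = math.sqrt(ta * tb)
    return int(round(g * math.exp(logm / 2))), int(round(g * math.exp(-logm / 2)))


def compare_conditions(
    quant_a: list[QuantRecord],
    quant_b: list[QuantRecord],
    alpha: float = 0.05,
    normalize: bool = True,
) -> tuple[float, list[DiffCall]]:
    """Pearson r on log2(FPKM+1) plus per-feature exact tests with BH control.

    Feature sets must match. The correlation is computed over features with a
    nonzero count in at least one sample; directions are assigned at
    q < alpha. With ``normalize`` (default) the test totals are effective
    library sizes from median-ratio normalisation; the normalisation is
    symmetric, so swapping the samples transposes every table and preserves
    every p-value exactly.
    """
    ids_a = [q.feature_id for q in quant_a]
    ids_b = [q.feature_id for q in quant_b]
    if ids_a != ids_b:
        if sorted(ids_a) != sorted(ids_b):
            raise ValueError("mismatched feature sets")
        by_id = {q.feature_id: q for q in quant_b}
        quant_b = [by_id[i] for i in ids_a]
    ca = np.array([q.count for q in quant_a], dtype=np.int64)
    cb = np.array([q.count for q in quant_b], dtype=np.int64)
    ta = quant_a[0].total_mapped if quant_a else 0
    tb = quant_b[0].total_mapped if quant_b else 0
    if ta <= 0 or tb <= 0:
        raise ValueError("sample totals must be > 0")
    if normalize:
        ta, tb = _median_ratio_totals(ca, cb, ta, tb)
    fa = np.log2(np.array([q.fpkm for q in quant_a]) + 1.0)
    fb = np.log2(np.array([q.fpkm for q in quant_b]) + 1.0)
    expressed = (ca > 0) | (cb > 0)
    if expressed.sum() >= 2 and (np.std(fa[expressed]) > 0 and np.std(fb[expressed]) > 0):
        pearson_r = float(np.corrcoef(fa[expressed], fb[expressed])[0, 1])
    else:
        pearson_r = 1.0 if np.allclose(fa[expressed], fb[expressed]) else float("nan")
    pvals = np.array(
        [fisher_2x2_pvalue(int(a), int(b), ta, tb) for a, b in zip(ca, cb)]
    )
    if len(pvals):
        qvals = multipletests(pvals, method="fdr_bh")[1]
    else:
        qvals = pvals
    calls = []
    for i, fid in enumerate(ids_a):
        pa = ca[i] / ta
        pb = cb[i] / tb
        if qvals[i] < alpha and pa > pb:
            direction = "over"
        elif qvals[i] < alpha and pa < pb:
            direction = "under"
        else:
            direction = "ns"
        calls.append(
            DiffCall(
                feature_id=fid,
                count_a=int(ca[i]),
                count_b=int(cb[i]),
                total_a=int(ta),
                total_b=int(tb),
                p_value=float(pvals[i]),
                q_value=float(qvals[i]),
                direction=direction,
            )
        )
    return pearson_r, calls


def quant_from_counts(
    feature_ids, lengths, counts, sample: str = ""
) -> list[QuantRecord]:
    """Build QuantRecords straight from a count vector (total = sum of counts)."""
    from .mapping_quant import quantify

    total = int(np.sum(counts))
    return quantify(counts, lengths, total, feature_ids=feature_ids, sample=sample)
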