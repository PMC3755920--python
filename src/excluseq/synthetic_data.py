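"""Ground-truthed two-condition RNA-seq simulator.

Emulates the wild-type vs B-chromosome-carrier testis design: two samples
share a set of transcripts at correlated expression, a minority of genes are
differentially expressed, some transcribed loci are missing from the
annotation ("novel"), and the carrier sample additionally expresses loci on
an extra, unannotated B chromosome. Every transcript carries a class label
and realised per-condition read counts so each pipeline stage can be tested
against known truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from ._kmers import KmerCodec, decode_seq, revcomp_codes
from .io_formats import ReadSet, SequenceRecord, TranscriptModel

logger = logging.getLogger(__name__)

CLASS_LABELS = ("shared", "exclusive", "novel", "de_up", "de_down")


class GenerationError(RuntimeError):
    """Raised when transcripts cannot be placed on the configured chromosomes."""


@dataclass
class SimulationConfig:
    """Parameters of the simulated study design (defaults: desk-scale testis regime)."""

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 500_000
    b_chrom_length: int = 100_000
    n_shared_transcripts: int = 200
    n_exclusive_transcripts: int = 9
    n_novel_loci: int = 25
    n_de_genes: int = 20
    fold_change: float = 5.0
    transcript_length_range: tuple[int, int] = (500, 1500)
    exons_per_transcript: tuple[int, int] = (1, 1)
    intron_length_range: tuple[int, int] = (60, 400)
    read_length: int = 100
    fragment_length_mean: float = 250.0
    fragment_length_sd: float = 30.0
    n_read_pairs: int = 100_000
    n_read_pairs_wt: int | None = None  # None = same depth as carrier
    error_rate: float = 0.0
    expression_sigma: float = 1.0
    # exclusive transcripts emulate the "abundantly expressed" regime: their
    # expression draw is boosted until this many fragments are expected
    exclusive_min_expected_pairs: int = 200
    # resample the genome until no canonical k-mer of this size repeats within
    # the transcriptome (None disables the check)
    enforce_unique_kmers: int | None = None

    def __post_init__(self):
        counts = (
            self.n_chromosomes,
            self.n_shared_transcripts,
            self.n_exclusive_transcripts,
            self.n_novel_loci,
            self.n_de_genes,
            self.n_read_pairs,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.n_de_genes > self.n_shared_transcripts:
            raise ValueError("n_de_genes cannot exceed n_shared_transcripts")
        if self.transcript_length_range[0] < self.read_length:
            raise ValueError("minimum transcript length must be >= read length")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.exons_per_transcript[0] < 1:
            raise ValueError("transcripts need at least one exon")

    @property
    def pairs_for(self):
        return {
            "carrier": self.n_read_pairs,
            "wt": self.n_read_pairs_wt if self.n_read_pairs_wt is not None else self.n_read_pairs,
        }


@dataclass
class TranscriptTruth:
    transcript_id: str
    label: str
    chrom: str
    strand: str
    length: int
    expr_wt: float
    expr_carrier: float
    count_wt: int = 0
    count_carrier: int = 0

    def expr(self, condition: str) -> float:
        return self.expr_carrier if condition == "carrier" else self.expr_wt


@dataclass
class GroundTruth:
    """Per-transcript class labels, expression levels and realised counts."""

    transcripts: list[TranscriptTruth]
    models: dict[str, TranscriptModel] = field(default_factory=dict)

    def __post_init__(self):
        for t in self.transcripts:
            if t.label not in CLASS_LABELS:
                raise ValueError(f"unknown class label {t.label!r}")
            if t.label == "exclusive" and t.expr_wt != 0:
                raise ValueError("exclusive transcripts must have zero WT expression")

    def by_label(self, label: str) -> list[TranscriptTruth]:
        return [t for t in self.transcripts if t.label == label]

    def get(self, transcript_id: str) -> TranscriptTruth:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "transcript_id": t.transcript_id,
                    "label": t.label,
                    "chrom": t.chrom,
                    "strand": t.strand,
                    "length": t.length,
                    "expr_wt": t.expr_wt,
                    "expr_carrier": t.expr_carrier,
                    "count_wt": t.count_wt,
                    "count_carrier": t.count_carrier,
                }
                for t in self.transcripts
            ]
        )


# ---------------------------------------------------------------------------
# Genome + annotation generation
# ---------------------------------------------------------------------------


def _partition(rng: np.random.Generator, total: int, parts: int, minimum: int) -> np.ndarray:
    """Split `total` into `parts` pieces, each >= minimum, multinomially."""
    spare = total - parts * minimum
    if spare < 0:
        raise GenerationError("region too short to partition")
    return rng.multinomial(spare, np.full(parts, 1.0 / parts)) + minimum


def _place_on_chrom(rng, chrom_len: int, spans: list[int], chrom: str) -> list[int]:
    """Non-overlapping start coordinates for genomic spans, in order, with random gaps."""
    free = chrom_len - sum(spans)
    if free < len(spans) + 1:
        raise GenerationError(
            f"cannot place {len(spans)} loci ({sum(spans)} bp) on {chrom} "
            f"({chrom_len} bp); increase chrom_length"
        )
    gaps = rng.multinomial(free, np.full(len(spans) + 1, 1.0 / (len(spans) + 1)))
    starts, pos = [], 0
    for i, span in enumerate(spans):
        pos += gaps[i]
        starts.append(pos)
        pos += span
    return starts


def _transcriptome_kmers_unique(models, genome_codes, k: int) -> bool:
    """True when no canonical k-mer repeats across the transcriptome and none
    is its own reverse complement (self-palindromic k-mers act like repeats
    in a bidirected assembly graph)."""
    codec = KmerCodec(k)
    chunks_a, chunks_b = [], []
    for m in models:
        seq = m.extract_codes(genome_codes)
        a, b, _, _ = codec.roll(seq[None, :])
        ra, rb = codec.revcomp(a, b)
        if codec.split:
            if bool(((a == ra) & (b == rb)).any()):
                return False
        elif bool((a == ra).any()):
            return False
        ca, cb = codec.canonical(a, b)
        chunks_a.append(ca)
        if cb is not None:
            chunks_b.append(cb)
    a = np.concatenate(chunks_a)
    b = np.concatenate(chunks_b) if chunks_b else None
    _, _, counts = codec.sort_unique(a, b)
    return bool((counts == 1).all())


def simulate_genome(config: SimulationConfig):
    """Generate (genome records, public annotation, ground truth).

    Shared and differentially expressed transcripts live on the normal
    chromosomes and appear in the annotation. Novel loci live on normal
    chromosomes but are left out of the annotation; exclusive loci live on the
    extra B chromosome, which is present in the genome but never annotated.
    """
    for attempt in range(20):
        rng = np.random.default_rng([config.seed, 17, attempt])
        genome_codes = {}
        for c in range(config.n_chromosomes):
            genome_codes[f"chr{c + 1}"] = rng.integers(
                0, 4, config.chrom_length, dtype=np.uint8
            )
        if config.n_exclusive_transcripts:
            genome_codes["chrB"] = rng.integers(
                0, 4, config.b_chrom_length, dtype=np.uint8
            )

        # class labels: DE genes are drawn from the shared pool
        labels = (
            ["shared"] * (config.n_shared_transcripts - config.n_de_genes)
            + ["de_up"] * (config.n_de_genes // 2 + config.n_de_genes % 2)
            + ["de_down"] * (config.n_de_genes // 2)
            + ["novel"] * config.n_novel_loci
            + ["exclusive"] * config.n_exclusive_transcripts
        )
        n_total = len(labels)
        lo, hi = config.transcript_length_range
        lengths = rng.integers(lo, hi + 1, n_total)
        strands = np.where(rng.random(n_total) < 0.5, "+", "-")
        elo, ehi = config.exons_per_transcript
        n_exons = rng.integers(elo, ehi + 1, n_total)

        # assign transcripts to chromosomes (exclusive -> chrB) and build exon
        # structures; placement is per-chromosome, in label order
        per_chrom: dict[str, list[int]] = {c: [] for c in genome_codes}
        normal = [f"chr{c + 1}" for c in range(config.n_chromosomes)]
        for i, lab in enumerate(labels):
            chrom = "chrB" if lab == "exclusive" else normal[i % len(normal)]
            per_chrom[chrom].append(i)

        models: list[TranscriptModel] = []
        truth_rows: list[TranscriptTruth] = []
        try:
            tx_info: dict[int, tuple[str, int]] = {}
            for chrom, idxs in per_chrom.items():
                spans = []
                exon_plans = []
                for i in idxs:
                    parts = _partition(rng, int(lengths[i]), int(n_exons[i]), 60)
                    if n_exons[i] > 1:
                        ilo, ihi = config.intron_length_range
                        introns = rng.integers(ilo, ihi + 1, int(n_exons[i]) - 1)
                    else:
                        introns = np.empty(0, dtype=int)
                    exon_plans.append((parts, introns))
                    spans.append(int(parts.sum() + introns.sum()))
                starts = _place_on_chrom(rng, len(genome_codes[chrom]), spans, chrom)
                for i, start, (parts, introns) in zip(idxs, starts, exon_plans):
                    exons = []
                    pos = start
                    for e, elen in enumerate(parts):
                        exons.append((pos, pos + int(elen)))
                        pos += int(elen) + (int(introns[e]) if e < len(introns) else 0)
                    tx_info[i] = (chrom, start)
                    models.append(
                        TranscriptModel(
                            chrom=chrom,
                            strand=str(strands[i]),
                            exons=tuple(exons),
                            gene_id=f"g{i:05d}",
                            transcript_id=f"tx{i:05d}",
                        )
                    )
        except GenerationError:
            raise

        models.sort(key=lambda m: m.transcript_id)

        # expression: log-normal; DE classes differ by fold_change; exclusive
        # transcripts are boosted to the abundant regime the carrier-specific
        # discovery targets
        base = rng.lognormal(0.0, config.expression_sigma, n_total)
        expr_wt = base.copy()
        expr_carrier = base.copy()
        for i, lab in enumerate(labels):
            if lab == "exclusive":
                expr_wt[i] = 0.0
            elif lab == "de_up":
                expr_carrier[i] = base[i] * config.fold_change
            elif lab == "de_down":
                expr_wt[i] = base[i] * config.fold_change
        if config.n_exclusive_transcripts and config.exclusive_min_expected_pairs:
            excl = np.array([lab == "exclusive" for lab in labels])
            target = float(config.exclusive_min_expected_pairs)
            n_pairs = config.pairs_for["carrier"]
            for _ in range(6):
                w = expr_carrier * lengths
                w = w / w.sum()
                expected = n_pairs * w
                low = excl & (expected < target)
                if not low.any():
                    break
                expr_carrier[low] *= (target * 1.2) / np.maximum(expected[low], 1e-9)

        for i, lab in enumerate(labels):
            truth_rows.append(
                TranscriptTruth(
                    transcript_id=f"tx{i:05d}",
                    label=lab,
                    chrom=tx_info[i][0],
                    strand=str(strands[i]),
                    length=int(lengths[i]),
                    expr_wt=float(expr_wt[i]),
                    expr_carrier=float(expr_carrier[i]),
                )
            )

        if config.enforce_unique_kmers is not None and models:
            if not _transcriptome_kmers_unique(
                models, genome_codes, config.enforce_unique_kmers
            ):
                logger.info("repeated %d-mer in transcriptome; resampling genome", config.enforce_unique_kmers)
                continue

        truth = GroundTruth(
            transcripts=truth_rows, models={m.transcript_id: m for m in models}
        )
        annotation = [
            m
            for m in models
            if truth.get(m.transcript_id).label in ("shared", "de_up", "de_down")
        ]
        genome = [
            SequenceRecord(chrom, decode_seq(codes))
            for chrom, codes in genome_codes.items()
        ]
        return genome, annotation, truth
    raise GenerationError(
        "could not generate a transcriptome without repeated k-mers; "
        "reduce transcript count or k"
    )


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def _genome_codes(genome) -> dict[str, np.ndarray]:
    if isinstance(genome, dict):
        return genome
    from ._kmers import encode_seq

    return {rec.id: encode_seq(rec.seq) for rec in genome}


def simulate_reads(
    genome,
    truth: GroundTruth,
    condition: str,
    config: SimulationConfig,
    with_ids: bool = False,
):
    """Draw paired-end reads for one condition; realised counts land in `truth`.

    Fragments are multinomial over expression x length, positions uniform
    within the transcript, mate 2 reverse-complemented, substitution errors
    i.i.d. at ``error_rate``. Returns ``(reads1, reads2)`` as :class:`ReadSet`.
    """
    if condition not in ("wt", "carrier"):
        raise ValueError("condition must be 'wt' or 'carrier'")
    rng = np.random.default_rng([config.seed, 29, 0 if condition == "wt" else 1])
    codes = _genome_codes(genome)
    rl = config.read_length
    n_pairs = config.pairs_for[condition]

    usable = []
    for t in truth.transcripts:
        if t.length < rl:
            logger.warning("transcript %s shorter than read length; skipped", t.transcript_id)
            continue
        usable.append(t)
    weights = np.array([t.expr(condition) * t.length for t in usable], dtype=float)
    total_w = weights.sum()
    if total_w <= 0:
        raise GenerationError(f"no expressed transcripts in condition {condition!r}")
    counts = rng.multinomial(n_pairs, weights / total_w)

    r1_parts, r2_parts, id_parts = [], [], []
    ar = np.arange(rl)
    for t, c in zip(usable, counts):
        if condition == "wt":
            t.count_wt = int(c)
        else:
            t.count_carrier = int(c)
        if c == 0:
            continue
        tseq = truth.models[t.transcript_id].extract_codes(codes)
        L = len(tseq)
        flen = np.rint(
            rng.normal(config.fragment_length_mean, config.fragment_length_sd, c)
        ).astype(np.int64)
        flen = np.clip(flen, rl, L)
        starts = (rng.random(c) * (L - flen + 1)).astype(np.int64)
        ends = starts + flen
        r1 = tseq[starts[:, None] + ar]
        r2 = tseq[(ends - rl)[:, None] + ar][:, ::-1]
        r2 = np.array([3, 2, 1, 0, 4], dtype=np.uint8)[r2]
        r1_parts.append(r1)
        r2_parts.append(r2)
        if with_ids:
            id_parts.extend(
                f"{condition}:{t.transcript_id}:{j}" for j in range(int(c))
            )
    if r1_parts:
        m1 = np.vstack(r1_parts)
        m2 = np.vstack(r2_parts)
    else:
        m1 = np.empty((0, rl), dtype=np.uint8)
        m2 = np.empty((0, rl), dtype=np.uint8)

    if config.error_rate > 0 and len(m1):
        for m in (m1, m2):
            mask = rng.random(m.shape) < config.error_rate
            shift = rng.integers(1, 4, m.shape, dtype=np.uint8)
            m[mask] = (m[mask] + shift[mask]) % 4

    ids1 = [i + "/1" for i in id_parts] if with_ids else None
    ids2 = [i + "/2" for i in id_parts] if with_ids else None
    return ReadSet(m1, ids1), ReadSet(m2, ids2)


def tile_reads(transcripts: Iterable[SequenceRecord], read_length: int, stride: int) -> ReadSet:
    """Error-free forward-strand reads tiling each transcript at fixed stride.

    Every position including the final window is covered, so assemblers see
    every k-mer of the source; per-base coverage is ~read_length/stride.
    """
    rows, ids = [], []
    from ._kmers import encode_seq

    for rec in transcripts:
        seq = encode_seq(rec.seq) if isinstance(rec, SequenceRecord) else np.asarray(rec)
        name = rec.id if isinstance(rec, SequenceRecord) else "seq"
        L = len(seq)
        if L < read_length:
            logger.warning("transcript %s shorter than read length; skipped", name)
            continue
        starts = list(range(0, L - read_length + 1, stride))
        if starts[-1] != L - read_length:
            starts.append(L - read_length)
        for j, s in enumerate(starts):
            rows.append(seq[s : s + read_length])
            ids.append(f"{name}:tile{j}")
    if not rows:
        return ReadSet(np.empty((0, read_length), dtype=np.uint8), [])
    return ReadSet(np.vstack(rows), ids)


# ---------------------------------------------------------------------------
# Truth manifest I/O
# ---------------------------------------------------------------------------

_MANIFEST_COLUMNS = (
    "transcript_id",
    "label",
    "chrom",
    "strand",
    "length",
    "expr_wt",
    "expr_carrier",
    "count_wt",
    "count_carrier",
)


def write_truth_manifest(truth: GroundTruth, path) -> None:
    """One tab-separated row per transcript; floats are written round-trippably."""
    with open(path, "w") as fh:
        fh.write("\t".join(_MANIFEST_COLUMNS) + "\n")
        for t in truth.transcripts:
            fh.write(
                f"{t.transcript_id}\t{t.label}\t{t.chrom}\t{t.strand}\t{t.length}\t"
                f"{t.expr_wt!r}\t{t.expr_carrier!r}\t{t.count_wt}\t{t.count_carrier}\n"
            )


def read_truth_manifest(path) -> GroundTruth:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _MANIFEST_COLUMNS:
            raise ValueError("not a truth manifest")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            rows.append(
                TranscriptTruth(
                    transcript_id=f[0],
                    label=f[1],
                    chrom=f[2],
                    strand=f[3],
                    length=int(f[4]),
                    expr_wt=float(f[5]),
                    expr_carrier=float(f[6]),
                    count_wt=int(f[7]),
                    count_carrier=int(f[8]),
                )
            )
    return GroundTruth(transcripts=rows)


def simulate_dataset(config: SimulationConfig):
    """Full dataset bundle: genome, annotation, truth and reads for both conditions."""
    genome, annotation, truth = simulate_genome(config)
    reads = {
        cond: simulate_reads(genome, truth, cond, config)
        for cond in ("wt", "carrier")
    }
    return genome, annotation, truth, reads
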