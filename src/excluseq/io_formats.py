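"""Strictly validated readers/writers for FASTA, FASTQ (Phred+33) and GTF.

All downstream modules operate on the in-memory types defined here:
:class:`SequenceRecord`, :class:`TranscriptModel` and the packed
:class:`ReadSet` container. Internal coordinates are 0-based half-open on the
forward strand; GTF I/O converts to/from the 1-based inclusive convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._kmers import decode_seq, encode_seq, revcomp_str

DNA_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class SequenceRecord:
    """A named nucleotide or peptide sequence with optional Phred qualities."""

    id: str
    seq: str
    description: str = ""
    quality: list[int] | None = None

    def __post_init__(self):
        if not self.id:
            raise FormatError("sequence record with empty id")
        if self.quality is not None and len(self.quality) != len(self.seq):
            raise FormatError(
                f"record {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SequenceRecord":
        qual = self.quality[::-1] if self.quality is not None else None
        return SequenceRecord(self.id, revcomp_str(self.seq), self.description, qual)


def _check_alphabet(rec_id: str, seq: str, alphabet: str) -> None:
    if alphabet == "dna":
        allowed = DNA_ALPHABET
    elif alphabet == "protein":
        allowed = PROTEIN_ALPHABET
    else:  # auto: nucleotide first, then peptide
        if set(seq) <= DNA_ALPHABET or set(seq) <= PROTEIN_ALPHABET:
            return
        allowed = DNA_ALPHABET | PROTEIN_ALPHABET
    bad = set(seq) - allowed
    if bad:
        raise FormatError(
            f"record {rec_id!r} contains illegal character(s) {sorted(bad)!r} "
            f"for alphabet {alphabet!r}"
        )


def read_fasta(path, alphabet: str = "auto") -> Iterator[SequenceRecord]:
    """Stream records from a FASTA file, enforcing unique ids and alphabet."""
    seen: set[str] = set()
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            parts = title.split(None, 1)
            rec_id = parts[0] if parts else ""
            desc = parts[1] if len(parts) > 1 else ""
            if rec_id in seen:
                raise FormatError(f"duplicate sequence id {rec_id!r}")
            seen.add(rec_id)
            seq = seq.upper()
            _check_alphabet(rec_id, seq, alphabet)
            yield SequenceRecord(rec_id, seq, desc)


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_fastq(path) -> Iterator[SequenceRecord]:
    """Stream 4-line Phred+33 FASTQ records; truncation or length mismatch raises."""
    seen: set[str] = set()
    with open(path) as fh:
        it = FastqGeneralIterator(fh)
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:  # Biopython flags truncated/mismatched records
                raise FormatError(str(exc)) from exc
            rec_id = title.split(None, 1)[0] if title else ""
            if rec_id in seen:
                raise FormatError(f"duplicate sequence id {rec_id!r}")
            seen.add(rec_id)
            seq = seq.upper()
            _check_alphabet(rec_id, seq, "dna")
            phred = [ord(c) - 33 for c in qual]
            if any(q < 0 for q in phred):
                raise FormatError(f"record {rec_id!r}: quality character below '!'")
            yield SequenceRecord(rec_id, seq, quality=phred)


def write_fastq(records: Iterable[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            qual = rec.quality if rec.quality is not None else [40] * len(rec.seq)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{''.join(chr(q + 33) for q in qual)}\n")


# ---------------------------------------------------------------------------
# Transcript models and GTF
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded multi-exon transcript. Exons are 0-based half-open, sorted."""

    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    gene_id: str
    transcript_id: str

    def __post_init__(self):
        if self.strand not in "+-":
            raise FormatError(f"{self.transcript_id}: strand must be + or -")
        if not self.exons:
            raise FormatError(f"{self.transcript_id}: transcript with no exons")
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        prev_end = -1
        for start, end in self.exons:
            if start >= end:
                raise FormatError(
                    f"{self.transcript_id}: exon ({start},{end}) has start >= end"
                )
            if start < prev_end:
                raise FormatError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = end

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def junctions(self) -> tuple[tuple[str, str, int, int], ...]:
        """Splice junctions as (chrom, strand, donor_end, acceptor_start)."""
        return tuple(
            (self.chrom, self.strand, self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    def extract_codes(self, genome: dict[str, np.ndarray]) -> np.ndarray:
        """Spliced transcript sequence (base codes, 5'->3' on its own strand)."""
        chrom = genome[self.chrom]
        parts = [chrom[s:e] for s, e in self.exons]
        seq = np.concatenate(parts) if len(parts) > 1 else parts[0].copy()
        if self.strand == "-":
            from ._kmers import revcomp_codes

            seq = revcomp_codes(seq)
        return seq


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf(path) -> list[TranscriptModel]:
    """Parse exon features of a GTF into TranscriptModels (internal coordinates).

    Only ``exon`` features are interpreted; other feature types and unknown
    attributes are ignored. Transcripts are returned in order of first
    appearance with exons sorted by start.
    """
    by_tx: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"line {lineno}: expected 9 tab-separated fields")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            attr = dict(_ATTR_RE.findall(attrs))
            if "transcript_id" not in attr:
                raise FormatError(f"line {lineno}: exon missing transcript_id")
            start_i, end_i = int(start), int(end)
            if start_i > end_i:
                raise FormatError(f"line {lineno}: exon start > end")
            tid = attr["transcript_id"]
            entry = by_tx.setdefault(
                tid,
                {"chrom": chrom, "strand": strand, "gene_id": attr.get("gene_id", tid), "exons": []},
            )
            if entry["chrom"] != chrom or entry["strand"] != strand:
                raise FormatError(f"transcript {tid!r}: exons on multiple chromosomes/strands")
            entry["exons"].append((start_i - 1, end_i))  # 1-based incl -> 0-based half-open
            if len(entry["exons"]) == 1:
                order.append(tid)
    models = []
    for tid in order:
        entry = by_tx[tid]
        exons = sorted(entry["exons"])
        models.append(
            TranscriptModel(
                chrom=entry["chrom"],
                strand=entry["strand"],
                exons=tuple(exons),
                gene_id=entry["gene_id"],
                transcript_id=tid,
            )
        )
    return models


def write_gtf(models: Sequence[TranscriptModel], path) -> None:
    """Write exon features in GTF v2.2 attribute syntax; round-trips read_gtf."""
    with open(path, "w") as fh:
        fh.write("# GTF exported by excluseq\n")
        for m in models:
            for start, end in m.exons:
                attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
                fh.write(
                    f"{m.chrom}\texcluseq\texon\t{start + 1}\t{end}\t.\t{m.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# Packed read container
# ---------------------------------------------------------------------------


@dataclass
class ReadSet:
    """Fixed-length reads packed as a (n_reads, read_length) uint8 code matrix."""

    codes: np.ndarray
    ids: list[str] | None = None

    def __post_init__(self):
        self.codes = np.ascontiguousarray(self.codes, dtype=np.uint8)
        if self.codes.ndim != 2:
            raise ValueError("ReadSet codes must be a 2-D matrix")

    def __len__(self) -> int:
        return self.codes.shape[0]

    @property
    def read_length(self) -> int:
        return self.codes.shape[1]

    def record_ids(self) -> list[str]:
        if self.ids is not None:
            return self.ids
        return [f"read{i}" for i in range(len(self))]

    @classmethod
    def from_records(cls, records: Iterable[SequenceRecord]) -> "ReadSet":
        ids, rows = [], []
        length = None
        for rec in records:
            if length is None:
                length = len(rec.seq)
            elif len(rec.seq) != length:
                raise ValueError("ReadSet requires uniform read length")
            ids.append(rec.id)
            rows.append(encode_seq(rec.seq))
        if length is None:
            return cls(np.empty((0, 0), dtype=np.uint8), [])
        return cls(np.vstack(rows), ids)

    @classmethod
    def from_fastq(cls, path) -> "ReadSet":
        return cls.from_records(read_fastq(path))

    def iter_records(self) -> Iterator[SequenceRecord]:
        ids = self.record_ids()
        for i in range(len(self)):
            yield SequenceRecord(ids[i], decode_seq(self.codes[i]))

    def to_fastq(self, path) -> None:
        ids = self.record_ids()
        qual = "I" * self.read_length
        with open(path, "w") as fh:
            for i in range(len(self)):
                fh.write(f"@{ids[i]}\n{decode_seq(self.codes[i])}\n+\n{qual}\n")


def as_read_matrices(reads) -> list[np.ndarray]:
    """Normalise reads (ReadSet, record iterable, or FASTQ path) to code matrices.

    Variable-length record collections are grouped by length so vectorised
    consumers always see rectangular matrices.
    """
    if isinstance(reads, ReadSet):
        return [reads.codes] if len(reads) else []
    if isinstance(reads, (str, Path)):
        reads = read_fastq(reads)
    elif isinstance(reads, (list, tuple)):
        if all(isinstance(r, np.ndarray) for r in reads):
            return list(reads)
        if all(isinstance(r, ReadSet) for r in reads):
            return [r.codes for r in reads if len(r)]
    groups: dict[int, list[np.ndarray]] = {}
    for rec in reads:
        groups.setdefault(len(rec.seq), []).append(encode_seq(rec.seq))
    return [np.vstack(rows) for _, rows in sorted(groups.items())]
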