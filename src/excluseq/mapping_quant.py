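"""Exact-match read mapping with report/suppression caps, plus RPM/FPKM.

The mapper reproduces the short-read-aligner semantics the discovery pipeline
depends on: a read's placements are all exact full-length occurrences on
either strand across all features; a read with more than ``suppress_cap``
placements is discarded entirely (it counts nowhere and is excluded from the
mapped total), otherwise it increments each distinct feature among its first
``report_cap`` placements once. Optional mismatch tolerance is Hamming-only
(seed-and-verify), matching a -v style contract; there are no indels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._kmers import KmerCodec, encode_seq, revcomp_codes
from .io_formats import ReadSet, SequenceRecord, as_read_matrices

logger = logging.getLogger(__name__)


class QuantError(ValueError):
    pass


@dataclass
class MappingPolicy:
    """-v/-k/-m style policy: mismatches, report cap, suppression cap."""

    max_mismatches: int = 0
    report_cap: int | None = 50  # None = report all
    suppress_cap: int | None = 50  # None = never suppress

    def __post_init__(self):
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if self.report_cap is not None and self.report_cap < 1:
            raise ValueError("report_cap must be >= 1")
        if (
            self.suppress_cap is not None
            and self.report_cap is not None
            and self.suppress_cap < self.report_cap
        ):
            raise ValueError("suppress_cap must be >= report_cap")


@dataclass
class QuantRecord:
    """Per-feature counts and abundance for one sample."""

    feature_id: str
    count: int
    rpm: float
    fpkm: float
    feature_length: int
    sample: str = ""
    total_mapped: int = 0


@dataclass
class MappingResult:
    feature_ids: list[str]
    counts: np.ndarray
    total_mapped: int
    n_unmapped: int
    n_discarded: int
    n_reads: int
    placements: list | None = None  # per-read [(feature_id, offset, strand)] when kept

    def count_of(self, feature_id: str) -> int:
        return int(self.counts[self.feature_ids.index(feature_id)])


class ExactIndex:
    """Seed-word index supporting exact full-length occurrence queries."""

    def __init__(self, features, k_index: int = 20):
        features = list(features)
        if not features:
            raise ValueError("feature set is empty")
        if not 1 <= k_index <= 32:
            raise ValueError("k_index must be in [1, 32]")
        self.ids = [f.id for f in features]
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate feature id")
        self.k_index = k_index
        self.seqs = [
            encode_seq(f.seq) if isinstance(f, SequenceRecord) else encode_seq(f.seq)
            for f in features
        ]
        self.seq_bytes = [s.tobytes() for s in self.seqs]
        self.lengths = np.array([len(s) for s in self.seqs], dtype=np.int64)
        codec = KmerCodec(k_index)
        words, feats, poss = [], [], []
        for fi, codes in enumerate(self.seqs):
            a, _b, cols = codec.roll_1d(codes)
            words.append(a)
            feats.append(np.full(len(a), fi, dtype=np.int64))
            poss.append(cols)
        w = np.concatenate(words)
        f = np.concatenate(feats)
        p = np.concatenate(poss)
        order = np.lexsort((p, f, w))
        self.words = w[order]
        self.feat = f[order]
        self.pos = p[order]

    def __len__(self) -> int:
        return len(self.ids)

    def occurrences(self, probe: np.ndarray, max_mismatches: int = 0):
        """All placements (feature_idx, offset, strand) of a probe, both strands."""
        out = []
        for strand, pv in (("+", probe), ("-", revcomp_codes(probe))):
            out.extend(
                (fi, off, strand) for fi, off in self._forward_occurrences(pv, max_mismatches)
            )
        # distinct placements, deterministic order
        out = sorted(set(out), key=lambda t: (self.ids[t[0]], t[1], t[2]))
        return out

    def _forward_occurrences(self, probe: np.ndarray, v: int):
        L = len(probe)
        k = self.k_index
        if L < k or (probe >= 4).any():
            return []
        n_seeds = 1 if v == 0 else min(v + 1, L // k)
        found = set()
        for s in range(n_seeds):
            off = s * k
            word = 0
            for c in probe[off : off + k]:
                word = (word << 2) | int(c)
            word = np.uint64(word)
            lo = int(np.searchsorted(self.words, word, side="left"))
            hi = int(np.searchsorted(self.words, word, side="right"))
            for t in range(lo, hi):
                fi = int(self.feat[t])
                start = int(self.pos[t]) - off
                if start < 0 or start + L > int(self.lengths[fi]):
                    continue
                if (fi, start) in found:
                    continue
                if v == 0:
                    if self.seq_bytes[fi][start : start + L] == probe.tobytes():
                        found.add((fi, start))
                else:
                    seg = self.seqs[fi][start : start + L]
                    if int((seg != probe).sum()) <= v:
                        found.add((fi, start))
        return sorted(found)


def build_index(features, k_index: int = 20) -> ExactIndex:
    """Index a feature set for exact-occurrence lookup of probes >= k_index bp."""
    return ExactIndex(features, k_index)


def _first_word_codes(matrix: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed first-k-mer of each read and of its reverse complement."""
    n, L = matrix.shape
    fwd = np.zeros(n, dtype=np.uint64)
    rc = np.zeros(n, dtype=np.uint64)
    bad_f = np.zeros(n, dtype=bool)
    bad_r = np.zeros(n, dtype=bool)
    for j in range(k):
        cf = matrix[:, j]
        cr = matrix[:, L - 1 - j]
        bad_f |= cf >= 4
        bad_r |= cr >= 4
        fwd = (fwd << np.uint64(2)) | (cf & np.uint8(3)).astype(np.uint64)
        rc = (rc << np.uint64(2)) | ((3 - (cr & np.uint8(3))) % 4).astype(np.uint64)
    return np.where(bad_f, np.uint64(0xFFFFFFFFFFFFFFFF), fwd), np.where(
        bad_r, np.uint64(0xFFFFFFFFFFFFFFFF), rc
    )


def map_reads(
    reads,
    index: ExactIndex,
    policy: MappingPolicy | None = None,
    keep_placements: bool = False,
) -> MappingResult:
    """Map reads to the indexed feature set under the policy.

    With ``max_mismatches == 0`` (the default contract) a vectorised
    first-word screen discards the bulk of non-matching reads before any
    per-read work.
    """
    policy = policy or MappingPolicy()
    matrices = as_read_matrices(reads)
    counts = np.zeros(len(index), dtype=np.int64)
    total_mapped = unmapped = discarded = n_reads = 0
    placements_out: list = [] if keep_placements else None
    k = index.k_index
    for matrix in matrices:
        n, L = matrix.shape
        n_reads += n
        if L < k:
            logger.warning("%d reads shorter than index word (%d bp): unmapped", n, k)
            unmapped += n
            if keep_placements:
                placements_out.extend([[] for _ in range(n)])
            continue
        if policy.max_mismatches == 0:
            fwd, rc = _first_word_codes(matrix, k)
            cand = np.zeros(n, dtype=bool)
            for codes in (fwd, rc):
                pos = np.searchsorted(index.words, codes, side="left")
                pos_c = np.minimum(pos, len(index.words) - 1)
                cand |= (pos < len(index.words)) & (index.words[pos_c] == codes)
            candidates = np.nonzero(cand)[0]
        else:
            candidates = np.arange(n)
        if keep_placements:
            hit_rows = set(candidates.tolist())
            row_iter = range(n)
        else:
            unmapped += n - len(candidates)
            hit_rows = None
            row_iter = candidates.tolist()
        for i in row_iter:
            if hit_rows is not None and i not in hit_rows:
                unmapped += 1
                placements_out.append([])
                continue
            pl = index.occurrences(matrix[i], policy.max_mismatches)
            if keep_placements:
                placements_out.append(
                    [(index.ids[fi], off, strand) for fi, off, strand in pl]
                )
            if not pl:
                unmapped += 1
            elif policy.suppress_cap is not None and len(pl) > policy.suppress_cap:
                discarded += 1
            else:
                total_mapped += 1
                reported = pl if policy.report_cap is None else pl[: policy.report_cap]
                for fi in {fi for fi, _off, _strand in reported}:
                    counts[fi] += 1
    return MappingResult(
        feature_ids=list(index.ids),
        counts=counts,
        total_mapped=total_mapped,
        n_unmapped=unmapped,
        n_discarded=discarded,
        n_reads=n_reads,
        placements=placements_out,
    )


def quantify(
    counts,
    feature_lengths,
    total_mapped: int,
    feature_ids=None,
    sample: str = "",
) -> list[QuantRecord]:
    """RPM and FPKM per feature (zero-count features included).

    rpm = count / total_mapped * 1e6;
    fpkm = count / ((length/1e3) * (total_mapped/1e6)).
    """
    if total_mapped <= 0:
        raise QuantError("total_mapped must be > 0 for quantification")
    if isinstance(counts, MappingResult):
        feature_ids = counts.feature_ids
        counts = counts.counts
    counts = np.asarray(counts, dtype=np.int64)
    lengths = np.asarray(feature_lengths, dtype=np.int64)
    if feature_ids is None:
        feature_ids = [f"feature{i}" for i in range(len(counts))]
    records = []
    for fid, c, ln in zip(feature_ids, counts.tolist(), lengths.tolist()):
        rpm = c / total_mapped * 1e6
        fpkm = c / ((ln / 1e3) * (total_mapped / 1e6))
        records.append(
            QuantRecord(
                feature_id=fid,
                count=int(c),
                rpm=rpm,
                fpkm=fpkm,
                feature_length=int(ln),
                sample=sample,
                total_mapped=int(total_mapped),
            )
        )
    return records


def quantify_sample(reads, index: ExactIndex, policy=None, sample: str = ""):
    """Convenience: map then quantify; returns (records, MappingResult)."""
    res = map_reads(reads, index, policy)
    if res.total_mapped == 0:
        raise QuantError("no reads mapped; cannot quantify")
    return quantify(res, index.lengths, res.total_mapped, sample=sample), res


def quantify_feature_set(
    reads, features, k_index: int = 20, sample: str = ""
):
    """Report-all quantification against an arbitrary feature set (TEs, repeats).

    Returns (records, mapped_fraction) where mapped_fraction = mapped reads /
    total reads — the statistic behind repeat-expression comparisons. A zero
    mapped total yields zero-count records rather than an error.
    """
    index = features if isinstance(features, ExactIndex) else ExactIndex(features, k_index)
    policy = MappingPolicy(max_mismatches=0, report_cap=None, suppress_cap=None)
    res = map_reads(reads, index, policy)
    mapped_fraction = res.total_mapped / res.n_reads if res.n_reads else 0.0
    if res.total_mapped == 0:
        records = [
            QuantRecord(fid, 0, 0.0, 0.0, int(ln), sample, 0)
            for fid, ln in zip(index.ids, index.lengths.tolist())
        ]
    else:
        records = quantify(res, index.lengths, res.total_mapped, sample=sample)
    return records, mapped_fraction


def write_quant_tsv(records, path) -> None:
    with open(path, "w") as fh:
        fh.write("feature_id\tlength\tcount\trpm\tfpkm\tsample\n")
        for r in records:
            fh.write(
                f"{r.feature_id}\t{r.feature_length}\t{r.count}\t{r.rpm:.6g}\t"
                f"{r.fpkm:.6g}\t{r.sample}\n"
            )
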