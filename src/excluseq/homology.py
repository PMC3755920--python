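"""Seed-and-extend local alignment with Karlin-Altschul e-value scoring.

Two modes: nucleotide-nucleotide (word size 11, match/mismatch scoring) and
translated (all six reading frames of a DNA query against a protein set, word
size 4, BLOSUM62). Hits are gapped local alignments grown from exact seed
words: seeds are grouped per diagonal, extended ungapped first (exact maximum
subarray along the diagonal), then the best seed regions get a gapped
Gotoh extension. Pairs small enough for a full dynamic-programming matrix are
aligned exactly, so reported scores on desk-scale instances equal the
Smith-Waterman optimum; larger pairs use a window around the seed diagonal.

E-values use published ungapped Karlin-Altschul parameters applied to gapped
scores — an approximation that is permissive at the cutoffs the subtraction
pipeline uses (0.1 and 0.01).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from ._kmers import KmerCodec, encode_seq, revcomp_codes
from .io_formats import SequenceRecord

logger = logging.getLogger(__name__)

# full dynamic-programming matrix below this many cells (exact scores there)
_FULL_DP_CELLS = 300_000
_WINDOW_PAD = 50
_MAX_GAPPED_CANDIDATES = 32
_MAX_DIAGONALS = 256

_AA_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_INDEX = {c: i for i, c in enumerate(_AA_ALPHABET)}


def _blosum62_matrix() -> np.ndarray:
    m = substitution_matrices.load("BLOSUM62")
    n = len(_AA_ALPHABET)
    out = np.full((n, n), -4, dtype=np.int32)
    for i, a in enumerate(_AA_ALPHABET):
        for j, b in enumerate(_AA_ALPHABET):
            try:
                out[i, j] = int(m[a, b])
            except (KeyError, IndexError):
                pass
    return out


@dataclass
class ScoringScheme:
    """Alignment scoring plus the (lambda, K) pair used for e-values."""

    mode: str  # "nucleotide" | "translated"
    match: int = 1
    mismatch: int = -2
    gap_open: int = 5
    gap_extend: int = 2
    word_size: int = 28
    lam: float = 1.28
    K: float = 0.46
    matrix_name: str | None = None

    def __post_init__(self):
        if self.mode not in ("nucleotide", "translated"):
            raise ValueError("mode must be 'nucleotide' or 'translated'")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")

    @classmethod
    def nucleotide_default(cls) -> "ScoringScheme":
        # ungapped Karlin-Altschul values for +1/-2 scoring; megablast-like
        # 28-nt seed word (chance seeds are effectively impossible, which the
        # subtraction stage relies on)
        return cls(mode="nucleotide")

    @classmethod
    def translated_default(cls) -> "ScoringScheme":
        # ungapped BLOSUM62 values
        return cls(
            mode="translated",
            gap_open=11,
            gap_extend=1,
            word_size=4,
            lam=0.3176,
            K=0.134,
            matrix_name="BLOSUM62",
        )

    def bitscore(self, raw: int) -> float:
        return (self.lam * raw - math.log(self.K)) / math.log(2)

    def evalue(self, raw: int, m: int, n: int) -> float:
        return self.K * m * n * math.exp(-self.lam * raw)


@dataclass
class AlignmentHit:
    """A gapped local alignment between a query and one subject."""

    query_id: str
    subject_id: str
    q_span: tuple[int, int]
    s_span: tuple[int, int]
    strand: str  # '+'/'-' (nucleotide) — frame carries the detail in translated mode
    frame: int | None
    raw_score: int
    bitscore: float
    evalue: float
    identity: float
    align_length: int


# ---------------------------------------------------------------------------
# Gotoh local alignment (vectorised rows, exact)
# ---------------------------------------------------------------------------


def _local_dp(sub_rows: np.ndarray, gap_open: int, gap_extend: int):
    """Smith-Waterman/Gotoh with affine gaps given a (m, n) substitution grid.

    Returns (H matrix (m+1, n+1), best score, best cell). Horizontal gap
    chains are resolved exactly by a running-maximum scan, so the score is the
    true local-alignment optimum of the grid.
    """
    m, n = sub_rows.shape
    NEG = -(10**9)
    go = gap_open + gap_extend  # cost of a length-1 gap
    ge = gap_extend
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    F = np.full(n, NEG, dtype=np.int64)  # vertical-gap state for columns 1..n
    colext = np.arange(1, n + 1, dtype=np.int64) * ge
    for i in range(1, m + 1):
        prev = H[i - 1]
        F = np.maximum(F - ge, prev[1:] - go)
        Htmp = np.maximum(prev[:-1] + sub_rows[i - 1], F)
        np.maximum(Htmp, 0, out=Htmp)
        # horizontal gaps enter from a diag/vertical/zero cell: a chain of
        # horizontal moves is one affine gap, captured by a running max of
        # Htmp[j'] + ge*j', so the row is exact despite vectorisation
        run = np.maximum.accumulate(Htmp + colext)
        row = H[i]
        row[1:] = Htmp
        if n > 1:
            row[2:] = np.maximum(row[2:], run[:-1] - go - colext[:-1])
    best_cell = np.unravel_index(int(np.argmax(H)), H.shape)
    return H, int(H[best_cell]), best_cell


def _traceback(H, sub_rows, gap_open, gap_extend, end):
    """Recover one optimal path ending at `end` by score recomputation.

    Tie-break order: diagonal, then vertical (gap in subject), then
    horizontal. Returns (i_start, j_start, matches, columns) with matches
    counted as positive-substitution... matches counted where the grid equals
    its maximum attainable per-pair score is not known here, so the caller
    passes an identity grid separately.
    """
    go = gap_open + gap_extend
    ge = gap_extend
    i, j = end
    cols = 0
    path = []
    while i > 0 and j > 0 and H[i, j] > 0:
        h = H[i, j]
        if h == H[i - 1, j - 1] + sub_rows[i - 1, j - 1]:
            path.append((i - 1, j - 1, "d"))
            i, j = i - 1, j - 1
            cols += 1
            continue
        moved = False
        g = 1
        while i - g >= 0:  # vertical gap of length g
            if h == H[i - g, j] - go - ge * (g - 1):
                for t in range(g):
                    path.append((i - 1 - t, j, "u"))
                i -= g
                cols += g
                moved = True
                break
            g += 1
            if g > i:
                break
        if moved:
            continue
        g = 1
        while j - g >= 0:  # horizontal gap
            if h == H[i, j - g] - go - ge * (g - 1):
                for t in range(g):
                    path.append((i, j - 1 - t, "l"))
                j -= g
                cols += g
                moved = True
                break
            g += 1
            if g > j:
                break
        if not moved:  # defensive: should not happen
            break
    return i, j, path[::-1], cols


def _align_window(qv: np.ndarray, sv: np.ndarray, scheme: ScoringScheme, subst):
    """Exact local alignment of two (small) vectors; returns hit geometry."""
    is_nt = scheme.mode == "nucleotide"
    if is_nt:
        grid = np.where(
            (qv[:, None] == sv[None, :]) & (qv[:, None] < 4),
            np.int64(scheme.match),
            np.int64(scheme.mismatch),
        )
    else:
        grid = subst[qv[:, None], sv[None, :]].astype(np.int64)
    H, score, end = _local_dp(grid, scheme.gap_open, scheme.gap_extend)
    if score <= 0:
        return 0, (0, 0), (0, 0), 0.0, 0
    i0, j0, path, cols = _traceback(H, grid, scheme.gap_open, scheme.gap_extend, end)
    matches = sum(
        1
        for (pi, pj, mv) in path
        if mv == "d" and qv[pi] == sv[pj] and (not is_nt or qv[pi] < 4)
    )
    identity = matches / cols if cols else 0.0
    return score, (i0, end[0]), (j0, end[1]), identity, cols


# ---------------------------------------------------------------------------
# Subject indexing
# ---------------------------------------------------------------------------


def _aa_encode(seq: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(c, _AA_INDEX["X"]) for c in seq], dtype=np.int64)


def _aa_words(codes: np.ndarray, w: int):
    """Protein word keys (base-24 packed) and their positions."""
    W = len(codes) - w + 1
    if W <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    key = np.zeros(W, dtype=np.int64)
    for j in range(w):
        key = key * 24 + codes[j : j + W]
    return key, np.arange(W, dtype=np.int64)


def _nt_words(codes: np.ndarray, w: int):
    codec = KmerCodec(w)
    a, _b, pos = codec.roll_1d(codes)
    return a.astype(np.int64), pos


class SubjectIndex:
    """Sorted exact seed-word index over a subject sequence set."""

    def __init__(self, records, scheme: ScoringScheme):
        records = list(records)
        self.scheme = scheme
        self.ids = [r.id for r in records]
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate subject id")
        self.word_size = scheme.word_size
        if scheme.mode == "nucleotide":
            if not 1 <= self.word_size <= 32:
                raise ValueError("nucleotide word size must be in [1, 32]")
            self.seqs = [encode_seq(r.seq) for r in records]
            word_fn = _nt_words
        else:
            self.seqs = [_aa_encode(r.seq) for r in records]
            word_fn = _aa_words
        keys, feats, poss = [], [], []
        for si, codes in enumerate(self.seqs):
            kk, pp = word_fn(codes, self.word_size)
            keys.append(kk)
            feats.append(np.full(len(kk), si, dtype=np.int64))
            poss.append(pp)
        if keys:
            k = np.concatenate(keys)
            f = np.concatenate(feats)
            p = np.concatenate(poss)
            order = np.lexsort((p, f, k))
            self.wkeys, self.wfeat, self.wpos = k[order], f[order], p[order]
        else:
            self.wkeys = np.empty(0, dtype=np.int64)
            self.wfeat = np.empty(0, dtype=np.int64)
            self.wpos = np.empty(0, dtype=np.int64)
        self.total_length = sum(len(s) for s in self.seqs)
        self.max_len = max((len(s) for s in self.seqs), default=0)

    def __len__(self) -> int:
        return len(self.ids)


def _kadane(scores: np.ndarray):
    """Best-scoring contiguous run: (score, start, end half-open)."""
    c = np.concatenate([[0], np.cumsum(scores)])
    run_min = np.minimum.accumulate(c[:-1])
    gains = c[1:] - run_min
    end = int(np.argmax(gains))
    best = int(gains[end])
    start = int(np.argmin(c[: end + 1]))
    return best, start, end + 1


def _ungapped_on_diagonal(qv, sv, diag, scheme, subst):
    """Exact best ungapped segment on one diagonal (q_pos - s_pos = diag)."""
    qs = max(0, diag)
    ss = qs - diag
    n = min(len(qv) - qs, len(sv) - ss)
    if n <= 0:
        return 0, 0, 0
    q = qv[qs : qs + n]
    s = sv[ss : ss + n]
    if scheme.mode == "nucleotide":
        sc = np.where((q == s) & (q < 4), scheme.match, scheme.mismatch)
    else:
        sc = subst[q, s]
    best, a, b = _kadane(sc.astype(np.int64))
    return best, qs + a, qs + b  # query coords of the segment


def _collect_diagonals(qv, index: SubjectIndex, scheme) -> dict:
    """Seed counts grouped by (subject, diagonal = q_pos - s_pos)."""
    word_fn = _nt_words if scheme.mode == "nucleotide" else _aa_words
    qwords, qpos = word_fn(qv, scheme.word_size)
    if len(qwords) == 0 or len(index.wkeys) == 0:
        return {}
    lo = np.searchsorted(index.wkeys, qwords, side="left")
    hi = np.searchsorted(index.wkeys, qwords, side="right")
    cnt = hi - lo
    tot = int(cnt.sum())
    if tot == 0:
        return {}
    start = np.repeat(lo, cnt)
    within = np.arange(tot) - np.repeat(np.cumsum(cnt) - cnt, cnt)
    idx = start + within
    feat = index.wfeat[idx]
    diag = np.repeat(qpos, cnt) - index.wpos[idx]
    offset = index.max_len + 1
    key = feat * (offset + len(qv) + 1) + (diag + offset)
    uniq, counts = np.unique(key, return_counts=True)
    span = offset + len(qv) + 1
    seeds = {}
    for u, c in zip(uniq.tolist(), counts.tolist()):
        seeds[(u // span, (u % span) - offset)] = c
    return seeds


def _search_oriented(qv, index, scheme, subst, max_evalue, m_len, short_circuit):
    """Seed/extend one query orientation; returns (hits, short_circuited)."""
    seeds = _collect_diagonals(qv, index, scheme)
    if not seeds:
        return [], False
    ranked = sorted(seeds.items(), key=lambda kv: (-kv[1], kv[0]))[:_MAX_DIAGONALS]
    cands = []
    for (si, diag), _count in ranked:
        score_u, qa, qb = _ungapped_on_diagonal(qv, index.seqs[si], diag, scheme, subst)
        if score_u <= 0:
            continue
        if short_circuit and scheme.evalue(score_u, m_len, index.total_length) <= max_evalue:
            return [
                _FastHit(si, diag, score_u, qa, qb)
            ], True
        cands.append((score_u, si, diag, qa, qb))
    cands.sort(key=lambda t: (-t[0], t[1], t[2]))
    best_per_subject: dict[int, tuple] = {}
    for score_u, si, diag, qa, qb in cands[:_MAX_GAPPED_CANDIDATES]:
        sv = index.seqs[si]
        if len(qv) * len(sv) <= _FULL_DP_CELLS:
            q0 = s0 = 0
            qw, sw = qv, sv
        else:
            q0 = max(0, qa - _WINDOW_PAD)
            q1 = min(len(qv), qb + _WINDOW_PAD)
            s0 = max(0, qa - diag - _WINDOW_PAD)
            s1 = min(len(sv), qb - diag + _WINDOW_PAD)
            qw, sw = qv[q0:q1], sv[s0:s1]
        score, (i0, i1), (j0, j1), ident, cols = _align_window(qw, sw, scheme, subst)
        if score <= 0:
            continue
        hit = (score, (q0 + i0, q0 + i1), (s0 + j0, s0 + j1), ident, cols)
        old = best_per_subject.get(si)
        if old is None or hit[0] > old[0] or (hit[0] == old[0] and hit[2] < old[2]):
            best_per_subject[si] = hit
    hits = []
    for si, (score, qsp, ssp, ident, cols) in best_per_subject.items():
        ev = scheme.evalue(score, m_len, index.total_length)
        if ev <= max_evalue:
            hits.append((si, qsp, ssp, score, ev, ident, cols))
    return hits, False


@dataclass
class _FastHit:
    subject_idx: int
    diag: int
    score: int
    q_start: int
    q_end: int


def search(
    query: SequenceRecord,
    subjects: SubjectIndex,
    scheme: ScoringScheme | None = None,
    max_evalue: float = 0.1,
) -> list[AlignmentHit]:
    """Gapped local hits of a nucleotide query against an indexed subject set.

    Both strands are searched; hits are sorted by ascending e-value, then
    descending score, then (subject_id, s_start).
    """
    scheme = scheme or subjects.scheme
    if scheme.mode != "nucleotide":
        raise ValueError("search() is nucleotide mode; use search_translated()")
    qcodes = encode_seq(query.seq)
    if len(qcodes) < scheme.word_size:
        logger.warning("query %s shorter than word size; no hits", query.id)
        return []
    m_len = len(qcodes)
    hits: list[AlignmentHit] = []
    for strand, qv in (("+", qcodes), ("-", revcomp_codes(qcodes))):
        raw, _ = _search_oriented(qv, subjects, scheme, None, max_evalue, m_len, False)
        for si, qsp, ssp, score, ev, ident, cols in raw:
            if strand == "-":
                qsp = (m_len - qsp[1], m_len - qsp[0])
            hits.append(
                AlignmentHit(
                    query_id=query.id,
                    subject_id=subjects.ids[si],
                    q_span=qsp,
                    s_span=ssp,
                    strand=strand,
                    frame=None,
                    raw_score=score,
                    bitscore=scheme.bitscore(score),
                    evalue=ev,
                    identity=ident,
                    align_length=cols,
                )
            )
    hits.sort(key=lambda h: (h.evalue, -h.raw_score, h.subject_id, h.s_span[0]))
    return hits


def has_hit(
    query: SequenceRecord,
    subjects: SubjectIndex,
    scheme: ScoringScheme | None = None,
    max_evalue: float = 0.1,
) -> bool:
    """True iff the query has >= 1 hit at the cutoff; short-circuits on the
    first seed region whose ungapped score already clears the e-value (the
    gapped score can only be higher, so the shortcut is sound)."""
    scheme = scheme or subjects.scheme
    qcodes = encode_seq(query.seq)
    if len(qcodes) < scheme.word_size or len(subjects) == 0:
        return False
    m_len = len(qcodes)
    for qv in (qcodes, revcomp_codes(qcodes)):
        raw, fast = _search_oriented(qv, subjects, scheme, None, max_evalue, m_len, True)
        if raw:
            return True
    return False


# ---------------------------------------------------------------------------
# Translated (blastx-style) search
# ---------------------------------------------------------------------------


def _six_frame_segments(seq: str):
    """(frame, nt_offset_of_segment_start_in_frame_orientation, peptide) with
    peptides split at stop codons."""
    rc = str(Seq(seq).reverse_complement())
    for frame in (1, 2, 3, -1, -2, -3):
        src = seq if frame > 0 else rc
        off = abs(frame) - 1
        coding = src[off : off + 3 * ((len(src) - off) // 3)]
        pep = str(Seq(coding).translate())
        start = 0
        for segment in pep.split("*"):
            if segment:
                yield frame, off + 3 * start, segment
            start += len(segment) + 1


def search_translated(
    query: SequenceRecord,
    proteins: SubjectIndex,
    scheme: ScoringScheme | None = None,
    max_evalue: float = 0.01,
) -> list[AlignmentHit]:
    """All six reading frames of a DNA query against an indexed protein set."""
    scheme = scheme or proteins.scheme
    if scheme.mode != "translated":
        raise ValueError("search_translated() needs a translated-mode scheme")
    subst = _blosum62_matrix()
    qlen = len(query.seq)
    m_len = max(qlen // 3, 1)
    hits: list[AlignmentHit] = []
    for frame, nt_off, pep in _six_frame_segments(query.seq.upper()):
        if len(pep) < scheme.word_size:
            continue
        qv = np.array([_AA_INDEX.get(c, _AA_INDEX["X"]) for c in pep], dtype=np.int64)
        raw, _ = _search_oriented(qv, proteins, scheme, subst, max_evalue, m_len, False)
        for si, (a0, a1), ssp, score, ev, ident, cols in raw:
            # aa span -> nt span in frame orientation, then to forward coords
            nt0 = nt_off + 3 * a0
            nt1 = nt_off + 3 * a1
            q_span = (nt0, nt1) if frame > 0 else (qlen - nt1, qlen - nt0)
            hits.append(
                AlignmentHit(
                    query_id=query.id,
                    subject_id=proteins.ids[si],
                    q_span=q_span,
                    s_span=ssp,
                    strand="+" if frame > 0 else "-",
                    frame=frame,
                    raw_score=score,
                    bitscore=scheme.bitscore(score),
                    evalue=ev,
                    identity=ident,
                    align_length=cols,
                )
            )
    hits.sort(key=lambda h: (h.evalue, -h.raw_score, h.subject_id, h.s_span[0]))
    return hits


def write_hits_tsv(hits, path) -> None:
    """Conventional tabular hit layout (no mismatch/gap columns)."""
    with open(path, "w") as fh:
        fh.write(
            "query\tsubject\tpident\tlength\tq_start\tq_end\ts_start\ts_end\tevalue\tbitscore\n"
        )
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{100 * h.identity:.2f}\t{h.align_length}\t"
                f"{h.q_span[0]}\t{h.q_span[1]}\t{h.s_span[0]}\t{h.s_span[1]}\t"
                f"{h.evalue:.3g}\t{h.bitscore:.1f}\n"
            )
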