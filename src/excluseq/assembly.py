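"""Simplified de novo assembler: canonical de Bruijn graph + unitig extraction.

This is a deliberately minimal stand-in for a full transcriptome assembler:
unitigs (maximal non-branching paths) only — no bubble popping, scaffolding or
isoform resolution. At desk scale with low error rates, unitigs reconstruct
planted transcripts exactly, which is all the subtraction pipeline needs.
Multi-k assembly unions the per-k unitig sets and deduplicates by strand-aware
containment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._kmers import KmerCodec, PyKmerOps, revcomp_str
from .io_formats import as_read_matrices

logger = logging.getLogger(__name__)

_CHUNK_ROWS = 262144


@dataclass
class Contig:
    """An assembled unitig with its mean k-mer multiplicity."""

    id: str
    seq: str
    mean_coverage: float
    k: int

    def __len__(self) -> int:
        return len(self.seq)


# ---------------------------------------------------------------------------
# Graph backends
# ---------------------------------------------------------------------------


class _NumpyBackend:
    """Packed-limb backend for k <= 63."""

    def __init__(self, k: int, ua, ub, counts):
        self.codec = KmerCodec(k)
        self.k = k
        self.ua = ua
        self.ub = ub
        self.counts = counts
        self._adj = None

    @classmethod
    def from_matrices(cls, matrices, k: int) -> "_NumpyBackend":
        codec = KmerCodec(k)
        parts_a, parts_b = [], []
        for m in matrices:
            if m.shape[1] < k:
                logger.info("%d reads shorter than k=%d contribute no k-mers", m.shape[0], k)
                continue
            for lo in range(0, m.shape[0], _CHUNK_ROWS):
                a, b, _, _ = codec.roll(m[lo : lo + _CHUNK_ROWS])
                ca, cb = codec.canonical(a, b)
                parts_a.append(ca)
                if cb is not None:
                    parts_b.append(cb)
        if parts_a:
            a = np.concatenate(parts_a)
            b = np.concatenate(parts_b) if codec.split else None
        else:
            a, b = np.empty(0, dtype=np.uint64), None
        ua, ub, counts = codec.sort_unique(a, b)
        return cls(k, ua, ub, counts)

    @property
    def n(self) -> int:
        return len(self.ua)

    def adjacency(self):
        """(succ, sori, outdeg): successor node index / orientation per
        (orientation, base, node); -1 where the extension k-mer is absent."""
        if self._adj is not None:
            return self._adj
        codec, n = self.codec, self.n
        if n == 0:
            z = np.empty((2, 4, 0), dtype=np.int64)
            self._adj = (z, z.astype(np.uint8), np.empty((2, 0), dtype=np.int64))
            return self._adj
        ra, rb = codec.revcomp(self.ua, self.ub)
        orient_kmers = [(self.ua, self.ub), (ra, rb)]
        q_a, q_b, q_is_fwd = [], [], []
        for ori in range(2):
            xa, xb = orient_kmers[ori]
            rxa, rxb = orient_kmers[1 - ori]
            for base in range(4):
                ya, yb = codec.shift_append(xa, xb, base)
                rya, ryb = codec.shift_prepend(rxa, rxb, 3 - base)
                if codec.split:
                    fwd_is_canon = (ya < rya) | ((ya == rya) & (yb <= ryb))
                    ca = np.where(fwd_is_canon, ya, rya)
                    cb = np.where(fwd_is_canon, yb, ryb)
                else:
                    fwd_is_canon = ya <= rya
                    ca = np.minimum(ya, rya)
                    cb = None
                q_a.append(ca)
                q_b.append(cb)
                q_is_fwd.append(fwd_is_canon)
        qa = np.concatenate(q_a)
        qb = np.concatenate(q_b) if codec.split else None
        idx = codec.find(qa, qb, self.ua, self.ub).reshape(2, 4, n)
        sori = (~np.concatenate(q_is_fwd)).astype(np.uint8).reshape(2, 4, n)
        outdeg = (idx >= 0).sum(axis=1)
        self._adj = (idx, sori, outdeg)
        return self._adj

    def kmer_string(self, i: int, ori: int) -> str:
        s = self.codec.to_str(self.ua[i], self.ub[i] if self.codec.split else None)
        return s if ori == 0 else revcomp_str(s)

    def last_bases(self):
        """Per-node last base character in each orientation (for path strings)."""
        if self.codec.split:
            lb_f = (self.ub & np.uint64(3)).astype(np.uint8)
            # last base of the rc = complement of the first base of the leading limb
            lb_r = (3 - (self.ua >> np.uint64(62)).astype(np.uint8)) & np.uint8(3)
        else:
            lb_f = (self.ua & np.uint64(3)).astype(np.uint8)
            top = np.uint64(2 * (self.k - 1))
            lb_r = (3 - (self.ua >> top).astype(np.uint8)) & np.uint8(3)
        return lb_f, lb_r

    def lookup(self, kmer: str) -> int:
        c = min(kmer, revcomp_str(kmer))
        a, b = self.codec.from_str(c)
        idx = self.codec.find(
            np.array([a]), None if not self.codec.split else np.array([b]),
            self.ua, self.ub,
        )
        return int(idx[0])

    def subset(self, keep: np.ndarray) -> "_NumpyBackend":
        ub = self.ub[keep] if self.codec.split else None
        return _NumpyBackend(self.k, self.ua[keep], ub, self.counts[keep])


class _PyBackend:
    """Arbitrary-precision fallback for k > 63 (functional, not fast)."""

    def __init__(self, k: int, kmers: list, counts: np.ndarray):
        self.k = k
        self.ops = PyKmerOps(k)
        self.kmers = kmers  # sorted canonical values
        self.counts = counts
        self._index = {v: i for i, v in enumerate(kmers)}
        self._adj = None

    @classmethod
    def from_matrices(cls, matrices, k: int) -> "_PyBackend":
        ops = PyKmerOps(k)
        tally: dict[int, int] = {}
        for m in matrices:
            if m.shape[1] < k:
                logger.info("%d reads shorter than k=%d contribute no k-mers", m.shape[0], k)
                continue
            for row in m:
                for _, fwd, rc in ops.roll_seq(row):
                    tally[min(fwd, rc)] = tally.get(min(fwd, rc), 0) + 1
        kmers = sorted(tally)
        counts = np.array([tally[v] for v in kmers], dtype=np.int64)
        return cls(k, kmers, counts)

    @property
    def n(self) -> int:
        return len(self.kmers)

    def adjacency(self):
        if self._adj is not None:
            return self._adj
        k, n = self.k, self.n
        succ = np.full((2, 4, n), -1, dtype=np.int64)
        sori = np.zeros((2, 4, n), dtype=np.uint8)
        rc_of = [self._rc(v) for v in self.kmers]
        for i, v in enumerate(self.kmers):
            for ori in range(2):
                x = v if ori == 0 else rc_of[i]
                rx = rc_of[i] if ori == 0 else v
                for base in range(4):
                    y, ry = self.ops.shift_append(x, rx, base)
                    c = min(y, ry)
                    j = self._index.get(c, -1)
                    succ[ori, base, i] = j
                    sori[ori, base, i] = 0 if c == y else 1
        outdeg = (succ >= 0).sum(axis=1)
        self._adj = (succ, sori, outdeg)
        return self._adj

    def _rc(self, v: int) -> int:
        r = 0
        for _ in range(self.k):
            r = (r << 2) | (3 - (v & 3))
            v >>= 2
        return r

    def kmer_string(self, i: int, ori: int) -> str:
        s = self.ops.to_str(self.kmers[i])
        return s if ori == 0 else revcomp_str(s)

    def last_bases(self):
        n = self.n
        lb_f = np.array([v & 3 for v in self.kmers], dtype=np.uint8)
        top = 2 * (self.k - 1)
        lb_r = np.array([3 - ((v >> top) & 3) for v in self.kmers], dtype=np.uint8)
        return lb_f, lb_r

    def lookup(self, kmer: str) -> int:
        val = 0
        for c in kmer:
            val = (val << 2) | "ACGT".index(c)
        return self._index.get(min(val, self._rc(val)), -1)

    def subset(self, keep: np.ndarray) -> "_PyBackend":
        kmers = [v for v, kp in zip(self.kmers, keep) if kp]
        return _PyBackend(self.k, kmers, self.counts[keep])


class DeBruijnGraph:
    """Canonical k-mer multiplicity graph; nodes are (k-1)-mer overlaps."""

    def __init__(self, k: int, backend):
        self.k = k
        self._backend = backend

    @property
    def n_kmers(self) -> int:
        return self._backend.n

    def multiplicity(self, kmer: str) -> int:
        """Multiplicity of a k-mer (canonicalized); 0 when absent."""
        i = self._backend.lookup(kmer)
        return int(self._backend.counts[i]) if i >= 0 else 0


def build_graph(reads, k: int) -> DeBruijnGraph:
    """Count canonical k-mers of a read set (k odd; N-containing k-mers skipped)."""
    if k % 2 == 0 or not 3 <= k <= 127:
        raise ValueError("k must be odd and in [3, 127]")
    matrices = as_read_matrices(reads)
    if k <= 63:
        backend = _NumpyBackend.from_matrices(matrices, k)
    else:
        backend = _PyBackend.from_matrices(matrices, k)
    return DeBruijnGraph(k, backend)


# ---------------------------------------------------------------------------
# Unitig extraction
# ---------------------------------------------------------------------------


def _unitig_paths(backend):
    """Maximal non-branching paths as (nodes, orientations, appended_bases).

    Paths are enumerated from the lexicographically smallest canonical k-mer;
    each k-mer lands in exactly one path.
    """
    n = backend.n
    if n == 0:
        return []
    succ, sori, outdeg = backend.adjacency()
    # a state (node, orientation) is mergeable into its successor when it has
    # exactly one extension and that successor has in-degree one (equivalently
    # its reverse orientation has out-degree one)
    has_one = outdeg == 1
    first = np.argmax(succ >= 0, axis=1)  # (2, n): the single extension's base
    usucc = np.take_along_axis(succ, first[:, None, :], axis=1)[:, 0, :]
    uori = np.take_along_axis(sori, first[:, None, :], axis=1)[:, 0, :]
    one_l = has_one.tolist()
    usucc_l = usucc.tolist()
    uori_l = uori.tolist()
    visited = bytearray(n)
    paths = []
    for i in range(n):
        if visited[i]:
            continue
        visited[i] = 1
        # walk backward: forward steps in the reverse orientation
        back_nodes, back_oris = [], []
        j, o = i, 1
        while one_l[o][j]:
            t = usucc_l[o][j]
            to = uori_l[o][j]
            if not one_l[1 - to][t] or visited[t]:
                break
            visited[t] = 1
            back_nodes.append(t)
            back_oris.append(to)
            j, o = t, to
        nodes = back_nodes[::-1] + [i]
        oris = [1 - o for o in back_oris[::-1]] + [0]
        j, o = i, 0
        while one_l[o][j]:
            t = usucc_l[o][j]
            to = uori_l[o][j]
            if not one_l[1 - to][t] or visited[t]:
                break
            visited[t] = 1
            nodes.append(t)
            oris.append(to)
            j, o = t, to
        paths.append((nodes, oris))
    return paths


def _path_sequence(backend, nodes, oris, lb) -> str:
    lb_f, lb_r = lb  # per-node last base ("ACGT" code) in each orientation
    seq = backend.kmer_string(nodes[0], oris[0])
    tail = "".join(
        "ACGT"[lb_f[j] if o == 0 else lb_r[j]] for j, o in zip(nodes[1:], oris[1:])
    )
    return seq + tail


def extract_unitigs(
    graph: DeBruijnGraph, min_coverage: int = 3, min_length: int = 200,
    condition: str = "asm",
) -> list[Contig]:
    """Unitigs after tip removal, filtered by coverage and length.

    Tips — dead-end paths no longer than 2k with mean multiplicity below
    ``min_coverage`` — are removed first, then unitigs are re-extracted.
    Output is deterministic: paths enumerated from the lexicographically
    smallest canonical k-mer.
    """
    backend = graph._backend
    k = graph.k
    for _round in range(10):
        paths = _unitig_paths(backend)
        if not paths:
            return []
        _, _, outdeg = backend.adjacency()
        tip_kmers = []
        for nodes, oris in paths:
            first, ofirst = nodes[0], oris[0]
            last, olast = nodes[-1], oris[-1]
            dead_end = outdeg[1 - ofirst][first] == 0 or outdeg[olast][last] == 0
            length = k + len(nodes) - 1
            mean_cov = float(backend.counts[nodes].mean())
            if dead_end and length <= 2 * k and mean_cov < min_coverage:
                tip_kmers.extend(nodes)
        if not tip_kmers:
            break
        keep = np.ones(backend.n, dtype=bool)
        keep[tip_kmers] = False
        backend = backend.subset(keep)
    contigs = []
    serial = 0
    lb_f, lb_r = backend.last_bases()
    lb = (lb_f.tolist(), lb_r.tolist())
    for nodes, oris in paths:
        mean_cov = float(backend.counts[nodes].mean())
        seq = _path_sequence(backend, nodes, oris, lb)
        seq = min(seq, revcomp_str(seq))
        if len(seq) < min_length or mean_cov < min_coverage:
            continue
        contigs.append(Contig(f"{condition}|k{k}|u{serial}", seq, mean_cov, k))
        serial += 1
    return contigs


def multi_k_assemble(
    reads,
    k_values=(21, 31, 41),
    min_coverage: int = 3,
    min_length: int = 200,
    condition: str = "asm",
) -> list[Contig]:
    """Union of per-k unitig sets, deduplicated by strand-aware containment.

    A contig identical to — or an exact substring of — a longer retained
    contig on either strand is dropped. The retained set is sorted by length
    descending, then id.
    """
    if not k_values:
        raise ValueError("at least one k value required")
    matrices = as_read_matrices(reads)
    contigs: list[Contig] = []
    for k in k_values:
        graph = build_graph(matrices, k)
        contigs.extend(extract_unitigs(graph, min_coverage, min_length, condition))
    contigs.sort(key=lambda c: (-len(c.seq), c.id))
    retained: list[Contig] = []
    haystack = ""
    for c in contigs:
        if haystack and (c.seq in haystack or revcomp_str(c.seq) in haystack):
            continue
        retained.append(c)
        haystack += "#" + c.seq
    return retained
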