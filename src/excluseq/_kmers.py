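"""Bit-packed k-mer primitives shared by the assembler and the exact-match mapper.

Bases are encoded A=0, C=1, G=2, T=3, N=4. A k-mer is packed two bits per
base into either one 64-bit limb (k <= 32) or two limbs (32 < k <= 63): limb
``a`` holds the leading 32 bases (full width), limb ``b`` the trailing k-32
bases right-aligned. Lexicographic order of the base string equals numeric
order of (a, b). Complementation is bitwise NOT of the 2-bit code.

k-mers longer than 63 bases fall back to arbitrary-precision Python integers
(:class:`PyKmerOps`); that path is functional, not fast.
"""

from __future__ import annotations

import numpy as np

U64 = np.uint64

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGTN"):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

_M2 = U64(0x3333333333333333)
_M4 = U64(0x0F0F0F0F0F0F0F0F)


def encode_seq(seq: str) -> np.ndarray:
    """Encode a DNA string (ACGTN, case-insensitive) to uint8 codes."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE[raw]
    if codes.max(initial=0) == 255:
        bad = chr(raw[int(np.argmax(codes == 255))])
        raise ValueError(f"illegal DNA character {bad!r}")
    return codes


def decode_seq(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes[::-1]]


def revcomp_str(seq: str) -> str:
    return decode_seq(revcomp_codes(encode_seq(seq)))


def _rev32(x: np.ndarray) -> np.ndarray:
    """Reverse-complement a full 32-base limb (complement + 2-bit group reversal)."""
    x = np.invert(x)
    x = ((x >> U64(2)) & _M2) | ((x & _M2) << U64(2))
    x = ((x >> U64(4)) & _M4) | ((x & _M4) << U64(4))
    return x.byteswap()


class KmerCodec:
    """Vectorised packed-k-mer operations for 1 <= k <= 63."""

    def __init__(self, k: int):
        if not 1 <= k <= 63:
            raise ValueError("KmerCodec supports 1 <= k <= 63")
        self.k = k
        self.split = k > 32
        self.hb = k - 32 if self.split else 0  # trailing-limb base count
        if self.split:
            self.bmask = U64((1 << (2 * self.hb)) - 1)
            self.amask = U64(0xFFFFFFFFFFFFFFFF)
        else:
            self.amask = U64((1 << (2 * k)) - 1) if k < 32 else U64(0xFFFFFFFFFFFFFFFF)
            self.bmask = U64(0)

    # -- rolling extraction ------------------------------------------------

    def roll(self, codes: np.ndarray):
        """All valid k-windows of a (n_reads, L) code matrix.

        Returns ``(a, b, rows, cols)`` flattened over valid windows; windows
        containing N are dropped. ``b`` is None for k <= 32.
        """
        if codes.ndim == 1:
            codes = codes[None, :]
        n, L = codes.shape
        k = self.k
        W = L - k + 1
        if W <= 0 or n == 0:
            e = np.empty(0, dtype=U64)
            ei = np.empty(0, dtype=np.int64)
            return e, (e if self.split else None), ei, ei
        a = np.zeros(n, dtype=U64)
        b = np.zeros(n, dtype=U64) if self.split else None
        last_n = np.full(n, -1, dtype=np.int64)
        out_a = np.empty((W, n), dtype=U64)
        out_b = np.empty((W, n), dtype=U64) if self.split else None
        valid = np.empty((W, n), dtype=bool)
        two = U64(2)
        for j in range(L):
            col = codes[:, j]
            isn = col >= 4
            if isn.any():
                last_n[isn] = j
            base = (col & np.uint8(3)).astype(U64)
            if self.split:
                carry = b >> U64(2 * (self.hb - 1)) if self.hb > 1 else b
                a = (a << two) | carry
                b = ((b << two) | base) & self.bmask
            else:
                a = ((a << two) | base) & self.amask
            if j >= k - 1:
                w = j - k + 1
                out_a[w] = a
                if self.split:
                    out_b[w] = b
                valid[w] = (j - last_n) >= k
        # flatten in (row, col) order so positions are deterministic
        valid_t = valid.T
        rows, cols = np.nonzero(valid_t)
        fa = out_a.T[valid_t]
        fb = out_b.T[valid_t] if self.split else None
        return fa, fb, rows, cols

    def roll_1d(self, codes: np.ndarray):
        """All valid k-windows of one 1-D sequence: (a, b, positions).

        Iterates over the k window offsets instead of sequence positions, so
        it is fast for long single sequences (the matrix `roll` is fast for
        many short rows).
        """
        codes = np.asarray(codes, dtype=np.uint8)
        L = len(codes)
        k = self.k
        W = L - k + 1
        if W <= 0:
            e = np.empty(0, dtype=U64)
            return e, (e if self.split else None), np.empty(0, dtype=np.int64)
        isn = (codes >= 4).astype(np.int64)
        cs = np.concatenate([[0], np.cumsum(isn)])
        good = (cs[k : k + W] - cs[0:W]) == 0
        val = (codes & np.uint8(3)).astype(U64)
        if not self.split:
            a = np.zeros(W, dtype=U64)
            for j in range(k):
                a = (a << U64(2)) | val[j : j + W]
            a &= self.amask
            pos = np.nonzero(good)[0]
            return a[good], None, pos
        lead = 32
        a = np.zeros(W, dtype=U64)
        for j in range(lead):
            a = (a << U64(2)) | val[j : j + W]
        b = np.zeros(W, dtype=U64)
        for j in range(lead, k):
            b = (b << U64(2)) | val[j : j + W]
        b &= self.bmask
        pos = np.nonzero(good)[0]
        return a[good], b[good], pos

    # -- limb arithmetic ---------------------------------------------------

    def revcomp(self, a, b):
        a = np.asarray(a, dtype=U64)
        if not self.split:
            return _rev32(a) >> U64(64 - 2 * self.k), None
        b = np.asarray(b, dtype=U64)
        hb = self.hb
        rb = _rev32(b) >> U64(64 - 2 * hb)
        ra = _rev32(a)
        na = (rb << U64(64 - 2 * hb)) | (ra >> U64(2 * hb))
        nb = ra & self.bmask
        return na, nb

    def canonical(self, a, b):
        """Elementwise min of a k-mer and its reverse complement."""
        ra, rb = self.revcomp(a, b)
        if not self.split:
            return np.minimum(a, ra), None
        take = (a < ra) | ((a == ra) & (b <= rb))
        return np.where(take, a, ra), np.where(take, b, rb)

    def shift_append(self, a, b, base):
        base = U64(base) if np.isscalar(base) else np.asarray(base, dtype=U64)
        if not self.split:
            return ((a << U64(2)) | base) & self.amask, None
        hb = self.hb
        carry = (b >> U64(2 * (hb - 1))) if hb > 1 else b
        na = (a << U64(2)) | carry
        nb = ((b << U64(2)) | base) & self.bmask
        return na, nb

    def shift_prepend(self, a, b, base):
        base = U64(base) if np.isscalar(base) else np.asarray(base, dtype=U64)
        if not self.split:
            return (base << U64(2 * (self.k - 1))) | (a >> U64(2)), None
        hb = self.hb
        nb = ((a & U64(3)) << U64(2 * (hb - 1))) | (b >> U64(2))
        na = (base << U64(62)) | (a >> U64(2))
        return na, nb

    # -- set operations ----------------------------------------------------

    def sort_unique(self, a, b):
        """Sorted distinct k-mers with multiplicities."""
        if len(a) == 0:
            e = np.empty(0, dtype=U64)
            return e, (e if self.split else None), np.empty(0, dtype=np.int64)
        if not self.split:
            ua, counts = np.unique(a, return_counts=True)
            return ua, None, counts
        order = np.lexsort((b, a))
        sa, sb = a[order], b[order]
        new = np.empty(len(sa), dtype=bool)
        new[0] = True
        new[1:] = (sa[1:] != sa[:-1]) | (sb[1:] != sb[:-1])
        idx = np.nonzero(new)[0]
        counts = np.diff(np.append(idx, len(sa)))
        return sa[idx], sb[idx], counts

    def find(self, qa, qb, ka, kb):
        """Indices of query k-mers in a sorted distinct key set (-1 when absent)."""
        if not self.split:
            pos = np.searchsorted(ka, qa)
            pos_c = np.minimum(pos, len(ka) - 1) if len(ka) else pos
            hit = (pos < len(ka)) & (ka[pos_c] == qa) if len(ka) else np.zeros(len(qa), bool)
            return np.where(hit, pos, -1)
        nk, nq = len(ka), len(qa)
        if nk == 0:
            return np.full(nq, -1, dtype=np.int64)
        alla = np.concatenate([ka, qa])
        allb = np.concatenate([kb, qb])
        is_q = np.zeros(nk + nq, dtype=np.uint8)
        is_q[nk:] = 1
        order = np.lexsort((is_q, allb, alla))  # keys precede equal queries
        oa, ob = alla[order], allb[order]
        start = np.empty(nk + nq, dtype=bool)
        start[0] = True
        start[1:] = (oa[1:] != oa[:-1]) | (ob[1:] != ob[:-1])
        grp = np.cumsum(start) - 1
        first = np.nonzero(start)[0]
        first_orig = order[first]
        grp_key = np.where(first_orig < nk, first_orig, -1)
        res = np.full(nq, -1, dtype=np.int64)
        qpos = np.nonzero(is_q[order])[0]
        res[order[qpos] - nk] = grp_key[grp[qpos]]
        return res

    # -- scalar/string helpers --------------------------------------------

    def to_str(self, a, b) -> str:
        a = int(a)
        if not self.split:
            return "".join("ACGT"[(a >> (2 * (self.k - 1 - i))) & 3] for i in range(self.k))
        b = int(b)
        lead = "".join("ACGT"[(a >> (62 - 2 * i)) & 3] for i in range(32))
        trail = "".join("ACGT"[(b >> (2 * (self.hb - 1 - i))) & 3] for i in range(self.hb))
        return lead + trail

    def from_str(self, s: str):
        codes = encode_seq(s)
        if len(codes) != self.k or (codes >= 4).any():
            raise ValueError("bad k-mer string")
        val = 0
        for c in codes:
            val = (val << 2) | int(c)
        if not self.split:
            return U64(val), None
        return U64(val >> (2 * self.hb)), U64(val & int(self.bmask))


class PyKmerOps:
    """Arbitrary-precision scalar k-mer operations for k > 63 (slow path)."""

    def __init__(self, k: int):
        self.k = k
        self.mask = (1 << (2 * k)) - 1

    def roll_seq(self, codes: np.ndarray):
        """Yield (position, fwd, rc) for each valid window of one sequence."""
        k, mask = self.k, self.mask
        top = 2 * (k - 1)
        fwd = rc = 0
        last_n = -1
        lst = codes.tolist()
        for j, c in enumerate(lst):
            if c >= 4:
                last_n = j
                c = 0
            fwd = ((fwd << 2) | c) & mask
            rc = (rc >> 2) | ((3 - c) << top)
            if j >= k - 1 and (j - last_n) >= k:
                yield j - k + 1, fwd, rc

    def shift_append(self, fwd: int, rc: int, base: int):
        nf = ((fwd << 2) | base) & self.mask
        nr = (rc >> 2) | ((3 - base) << (2 * (self.k - 1)))
        return nf, nr

    def to_str(self, val: int) -> str:
        return "".join("ACGT"[(val >> (2 * (self.k - 1 - i))) & 3] for i in range(self.k))
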