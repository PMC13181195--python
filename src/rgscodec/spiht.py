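"""Set Partitioning in Hierarchical Trees coder with exact bit-budget control.

Implements the classical list dynamics (LIP / LIS / LSP) over the spatial
orientation tree of a Mallat-layout integer coefficient plane: per bitplane a
sorting pass emits significance (and sign) decisions, a refinement pass emits
one magnitude bit for every coefficient found significant at an earlier
plane, and the plane index n is decremented until n < 0 or the bit budget is
hit, at which point the stream is truncated exactly at the budget.

The decoder mirrors the list dynamics bit for bit. A coefficient that turns
significant at plane n is reconstructed at +/-1.5*2^n and every refinement
bit halves its uncertainty interval; when the stream covers all planes down
to n = 0 the midpoint estimates are exactly magnitude + 0.5 and the final
rounding recovers the integers losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import BudgetExhausted, MalformedStream
from .wavelet import IntCoeffPlane

_TYPE_A = 0
_TYPE_B = 1


@dataclass
class BitStream:
    """Ordered 0/1 sequence with an optional write budget and a read cursor."""

    budget: int | None = None
    bits: bytearray = field(default_factory=bytearray)
    cursor: int = 0

    def __len__(self) -> int:
        return len(self.bits)

    def write(self, bit: int) -> None:
        if self.budget is not None and len(self.bits) >= self.budget:
            raise BudgetExhausted
        self.bits.append(1 if bit else 0)

    def read(self) -> int:
        if self.cursor >= len(self.bits):
            raise BudgetExhausted
        b = self.bits[self.cursor]
        self.cursor += 1
        return b

    def to_bytes(self) -> bytes:
        """Pack MSB-first, zero-padded to a byte boundary."""
        out = bytearray((len(self.bits) + 7) // 8)
        for k, b in enumerate(self.bits):
            if b:
                out[k >> 3] |= 0x80 >> (k & 7)
        return bytes(out)

    @classmethod
    def from_bytes(cls, data: bytes, bit_count: int) -> "BitStream":
        if bit_count > 8 * len(data):
            raise MalformedStream(
                f"recorded bit count {bit_count} exceeds payload of {8 * len(data)} bits"
            )
        bits = bytearray(
            (data[k >> 3] >> (7 - (k & 7))) & 1 for k in range(bit_count)
        )
        return cls(budget=None, bits=bits)


@dataclass
class SpihtState:
    LIP: list
    LIS: list
    LSP: list
    n: int
    b_max: int


def max_bitplane(plane: IntCoeffPlane) -> int:
    """floor(log2(max magnitude)); -1 for an all-zero plane."""
    m = int(plane.magnitudes.max()) if plane.magnitudes.size else 0
    return int(m).bit_length() - 1 if m > 0 else -1


def is_significant(coords, n: int, plane: IntCoeffPlane) -> int:
    """1 iff any coefficient in ``coords`` has magnitude >= 2^n; empty set -> 0."""
    thr = 1 << n
    mags = plane.magnitudes
    return int(any(mags[i, j] >= thr for i, j in coords))


def offspring(coord, dims, levels: int) -> list[tuple[int, int]]:
    """Children of ``coord`` in the spatial orientation tree.

    Inside the coarsest LL the top-left member of each 2x2 group is rootless;
    the other three root the same-level HL / LH / HH trees: group (a, b)
    member with offset (oi, oj) has its four children in the 2x2 block at
    (oi*llh + 2a, oj*llw + 2b). Every coefficient outside the LL has children
    at the doubled coordinates when these fall inside the plane (for a 2x2
    LL both rules coincide).
    """
    i, j = coord
    h, w = dims
    llh, llw = h >> levels, w >> levels
    if i < llh and j < llw:
        oi, oj = i % 2, j % 2
        if oi == 0 and oj == 0:
            return []
        r0 = oi * llh + 2 * (i // 2)
        c0 = oj * llw + 2 * (j // 2)
    else:
        r0, c0 = 2 * i, 2 * j
    cands = ((r0, c0), (r0, c0 + 1), (r0 + 1, c0), (r0 + 1, c0 + 1))
    return [(r, c) for r, c in cands if r < h and c < w]


def _descendant_maxima(mags: np.ndarray, levels: int):
    """maxdesc[c] = max magnitude over all descendants of c (excluding c);
    maxgrand[c] = same excluding the direct offspring. Zero where no such set."""
    h, w = mags.shape
    maxdesc = np.zeros_like(mags)
    maxgrand = np.zeros_like(mags)
    dims = (h, w)

    def visit(c):
        md = 0
        mg = 0
        for o in offspring(c, dims, levels):
            visit(o)
            md = max(md, int(mags[o]), int(maxdesc[o]))
            mg = max(mg, int(maxdesc[o]))
        maxdesc[c] = md
        maxgrand[c] = mg

    llh, llw = h >> levels, w >> levels
    for i in range(llh):
        for j in range(llw):
            if not (i % 2 == 0 and j % 2 == 0):
                visit((i, j))
    return maxdesc, maxgrand


def _has_grand(coord, dims, levels: int) -> bool:
    return any(offspring(o, dims, levels) for o in offspring(coord, dims, levels))


def _initial_lists(dims, levels: int):
    h, w = dims
    llh, llw = h >> levels, w >> levels
    LIP = [(i, j) for i in range(llh) for j in range(llw)]
    LIS = [
        ((i, j), _TYPE_A)
        for i in range(llh)
        for j in range(llw)
        if not (i % 2 == 0 and j % 2 == 0)
    ]
    return LIP, LIS


def encode(plane: IntCoeffPlane, budget_bits: int | None = None) -> BitStream:
    """Encode an integer coefficient plane into an embedded bitstream.

    ``budget_bits=None`` means unlimited (code down to plane 0, lossless).
    On budget exhaustion the stream is truncated exactly at ``budget_bits``.
    """
    mags = plane.magnitudes
    signs = plane.signs
    dims = mags.shape
    levels = plane.levels
    stream = BitStream(budget=budget_bits)
    b_max = max_bitplane(plane)
    if b_max < 0 or budget_bits == 0:
        return stream
    maxdesc, maxgrand = _descendant_maxima(mags, levels)
    LIP, LIS = _initial_lists(dims, levels)
    LSP: list[tuple[tuple[int, int], int]] = []
    n = b_max
    try:
        while n >= 0:
            thr = 1 << n
            # --- sorting pass: LIP
            still_insig = []
            for c in LIP:
                sig = mags[c] >= thr
                stream.write(sig)
                if sig:
                    stream.write(signs[c] < 0)
                    LSP.append((c, n))
                else:
                    still_insig.append(c)
            LIP = still_insig
            # --- sorting pass: LIS (grows while being processed)
            k = 0
            while k < len(LIS):
                entry = LIS[k]
                if entry is None:
                    k += 1
                    continue
                c, typ = entry
                if typ == _TYPE_A:
                    sig = maxdesc[c] >= thr
                    stream.write(sig)
                    if sig:
                        for o in offspring(c, dims, levels):
                            osig = mags[o] >= thr
                            stream.write(osig)
                            if osig:
                                stream.write(signs[o] < 0)
                                LSP.append((o, n))
                            else:
                                LIP.append(o)
                        LIS[k] = None
                        if _has_grand(c, dims, levels):
                            LIS.append((c, _TYPE_B))
                else:  # _TYPE_B
                    sig = maxgrand[c] >= thr
                    stream.write(sig)
                    if sig:
                        LIS[k] = None
                        for o in offspring(c, dims, levels):
                            LIS.append((o, _TYPE_A))
                k += 1
            LIS = [e for e in LIS if e is not None]
            # --- refinement pass
            for c, born in LSP:
                if born > n:
                    stream.write((int(mags[c]) >> n) & 1)
            n -= 1
    except BudgetExhausted:
        pass
    return stream


def decode(
    bits: BitStream, dims: tuple[int, int], levels: int, b_max: int
) -> np.ndarray:
    """Mirror the encoder's list dynamics, consuming bits until exhaustion.

    Returns the real-valued Mallat-plane reconstruction. If the stream covers
    every plane down to n = 0, the midpoint estimates are rounded to the
    exact integers.
    """
    h, w = dims
    rec = np.zeros((h, w), dtype=np.float64)
    if b_max < 0:
        return rec
    LIP, LIS = _initial_lists(dims, levels)
    LSP: list[tuple[tuple[int, int], int]] = []
    bits.cursor = 0
    n = b_max
    completed = False
    try:
        while n >= 0:
            step = float(1 << n)
            # --- sorting pass: LIP
            still_insig = []
            for c in LIP:
                if bits.read():
                    sign = -1.0 if bits.read() else 1.0
                    rec[c] = sign * 1.5 * step
                    LSP.append((c, n))
                else:
                    still_insig.append(c)
            LIP = still_insig
            # --- sorting pass: LIS
            k = 0
            while k < len(LIS):
                entry = LIS[k]
                if entry is None:
                    k += 1
                    continue
                c, typ = entry
                if typ == _TYPE_A:
                    if bits.read():
                        for o in offspring(c, dims, levels):
                            if bits.read():
                                sign = -1.0 if bits.read() else 1.0
                                rec[o] = sign * 1.5 * step
                                LSP.append((o, n))
                            else:
                                LIP.append(o)
                        LIS[k] = None
                        if _has_grand(c, dims, levels):
                            LIS.append((c, _TYPE_B))
                else:
                    if bits.read():
                        LIS[k] = None
                        for o in offspring(c, dims, levels):
                            LIS.append((o, _TYPE_A))
                k += 1
            LIS = [e for e in LIS if e is not None]
            # --- refinement pass: halve the uncertainty interval
            half = step / 2.0
            for c, born in LSP:
                if born > n:
                    if bits.read():
                        rec[c] += np.sign(rec[c]) * half
                    else:
                        rec[c] -= np.sign(rec[c]) * half
            n -= 1
        completed = True
    except BudgetExhausted:
        pass
    if completed:
        rec = np.trunc(rec)
    return rec
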