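"""Canonical byte-wise Huffman coder for the SPIHT bitstream.

Symbols are the 8-bit chunks of the SPIHT output (the final partial byte is
zero-padded; the true SPIHT bit count travels in the container framing).
Code lengths come from the classical lowest-probability merge with
deterministic tie-breaking, and are turned into canonical codes so the
packet header only needs (symbol, length) pairs.

Packet layout (big-endian): u16 symbol_count; symbol_count x (u8 symbol,
u8 length); u32 payload_bit_count; payload bits MSB-first, zero-padded to a
byte boundary.
"""

from __future__ import annotations

import heapq
import struct
from dataclasses import dataclass

from .errors import EmptyInput, MalformedPacket


@dataclass
class HuffmanTable:
    """Canonical code table: (symbol, code_length) pairs sorted canonically."""

    entries: list[tuple[int, int]]  # (symbol, length), sorted by (length, symbol)

    def codes(self) -> dict[int, tuple[int, int]]:
        """symbol -> (code value, length), canonical assignment."""
        out: dict[int, tuple[int, int]] = {}
        code = 0
        prev_len = 0
        for sym, length in self.entries:
            code <<= length - prev_len
            out[sym] = (code, length)
            code += 1
            prev_len = length
        return out

    def kraft_sum(self) -> float:
        return sum(2.0 ** -length for _, length in self.entries)


@dataclass
class HuffmanPacket:
    table: HuffmanTable
    payload_bit_count: int
    payload: bytes

    def to_bytes(self) -> bytes:
        head = struct.pack(">H", len(self.table.entries))
        head += b"".join(struct.pack(">BB", s, l) for s, l in self.table.entries)
        return head + struct.pack(">I", self.payload_bit_count) + self.payload

    @classmethod
    def from_bytes(cls, data: bytes) -> "HuffmanPacket":
        if len(data) < 2:
            raise MalformedPacket("packet shorter than its symbol-count field")
        (n_sym,) = struct.unpack(">H", data[:2])
        off = 2
        entries = []
        for _ in range(n_sym):
            if off + 2 > len(data):
                raise MalformedPacket("truncated symbol table")
            s, l = struct.unpack(">BB", data[off : off + 2])
            if l == 0 or l > 32:
                raise MalformedPacket(f"invalid code length {l}")
            entries.append((s, l))
            off += 2
        if off + 4 > len(data):
            raise MalformedPacket("missing payload bit count")
        (bit_count,) = struct.unpack(">I", data[off : off + 4])
        off += 4
        payload = data[off:]
        if bit_count > 8 * len(payload):
            raise MalformedPacket("payload shorter than its recorded bit count")
        table = HuffmanTable(entries=sorted(entries, key=lambda e: (e[1], e[0])))
        if n_sym > 0 and table.kraft_sum() > 1.0 + 1e-12 and n_sym > 1:
            raise MalformedPacket("code lengths violate the Kraft inequality")
        return cls(table=table, payload_bit_count=bit_count, payload=payload)


def build_table(freqs: dict[int, int]) -> HuffmanTable:
    """Optimal prefix-code lengths by Huffman merging, in canonical order.

    Tie-breaking is deterministic: lowest count first, then smallest symbol
    value for leaves, then earliest creation order for merged nodes. A
    single-symbol alphabet gets the degenerate length-1 code.
    """
    items = sorted((s, c) for s, c in freqs.items() if c > 0)
    if not items:
        raise EmptyInput("no symbol has a positive count")
    if len(items) == 1:
        return HuffmanTable(entries=[(items[0][0], 1)])
    # heap keys: (count, order); leaves ordered by symbol value (< 256),
    # internal nodes by creation order (>= 256)
    heap = [(count, sym, [sym]) for sym, count in items]
    heapq.heapify(heap)
    depth = {sym: 0 for sym, _ in items}
    order = 256
    while len(heap) > 1:
        c1, _, leaves1 = heapq.heappop(heap)
        c2, _, leaves2 = heapq.heappop(heap)
        for s in leaves1 + leaves2:
            depth[s] += 1
        heapq.heappush(heap, (c1 + c2, order, leaves1 + leaves2))
        order += 1
    entries = sorted(depth.items(), key=lambda e: (e[1], e[0]))
    return HuffmanTable(entries=[(s, l) for s, l in entries])


def encode_bytes(data: bytes) -> HuffmanPacket:
    """Huffman-pack a byte sequence; empty data yields a header-only packet."""
    data = bytes(data)
    if not data:
        return HuffmanPacket(table=HuffmanTable(entries=[]), payload_bit_count=0, payload=b"")
    freqs: dict[int, int] = {}
    for b in data:
        freqs[b] = freqs.get(b, 0) + 1
    table = build_table(freqs)
    codes = table.codes()
    nbits = sum(freqs[s] * codes[s][1] for s in freqs)
    out = bytearray((nbits + 7) // 8)
    pos = 0
    for b in data:
        code, length = codes[b]
        for k in range(length - 1, -1, -1):
            if (code >> k) & 1:
                out[pos >> 3] |= 0x80 >> (pos & 7)
            pos += 1
    return HuffmanPacket(table=table, payload_bit_count=nbits, payload=bytes(out))


def decode_bytes(packet: HuffmanPacket) -> bytes:
    """Exact inverse of encode_bytes."""
    if not packet.table.entries:
        if packet.payload_bit_count:
            raise MalformedPacket("payload bits but no symbol table")
        return b""
    codes = packet.table.codes()
    # prefix-free: walk bit by bit through a code->symbol map
    lookup = {v: s for s, v in codes.items()}  # (code, length) -> symbol
    out = bytearray()
    code = 0
    length = 0
    payload = packet.payload
    for pos in range(packet.payload_bit_count):
        bit = (payload[pos >> 3] >> (7 - (pos & 7))) & 1
        code = (code << 1) | bit
        length += 1
        sym = lookup.get((code, length))
        if sym is not None:
            out.append(sym)
            code = 0
            length = 0
        elif length > 32:
            raise MalformedPacket("undecodable bit sequence")
    if length:
        raise MalformedPacket("payload ends mid-codeword")
    return bytes(out)
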