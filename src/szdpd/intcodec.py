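"""Reversible compression of sorted unsigned-integer arrays.

Pipeline: delta-encode the sorted array (first value + non-negative gaps),
pack the gaps with a patched frame-of-reference (PFor) bit-packing codec, and
wrap the result in a zlib (RFC 1950) stream.  Sorted quantized m/z axes have
small, repetitive gaps, which is exactly the regime where frame-of-reference
packing shines.

PFor variant
------------
The array is cut into miniblocks of 128 values.  Each miniblock chooses the
bit width ``b`` (0..32) that minimizes its serialized size: every value is
stored in ``b`` low bits, and values ``>= 2**b`` additionally record their
high bits as *exceptions* — (varint position delta, varint high bits) pairs
appended after the packed area.  Bits are packed LSB-first into a
little-endian byte stream; the final partial miniblock is zero-padded to 128
slots and truncated on decode using the element count in the header.

The full byte-level layout is documented in ``docs/format.md``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, InvalidInputError, RangeError, UnsortedInputError

__all__ = [
    "DeltaArray",
    "delta_encode",
    "delta_decode",
    "pfor_encode",
    "pfor_decode",
    "encode_sorted_array",
    "decode_sorted_array",
]

MINIBLOCK = 128
PFOR_MAGIC = b"SPF1"
PFOR_VERSION = 1
ZLIB_LEVEL = 6
_U32_LIMIT = 1 << 32


# ---------------------------------------------------------------- varints

def encode_varint(x: int) -> bytes:
    """Unsigned LEB128."""
    if x < 0:
        raise InvalidInputError(f"varint requires a non-negative integer, got {x}")
    out = bytearray()
    while True:
        byte = x & 0x7F
        x >>= 7
        if x:
            out.append(byte | 0x80)
        else:
            out.append(byte)
            return bytes(out)


def decode_varint(buf: bytes, offset: int) -> tuple[int, int]:
    """Return (value, new_offset); raises FormatError on truncation."""
    x = 0
    shift = 0
    while True:
        if offset >= len(buf):
            raise FormatError(f"truncated varint at byte offset {offset}")
        byte = buf[offset]
        offset += 1
        x |= (byte & 0x7F) << shift
        if not byte & 0x80:
            return x, offset
        shift += 7
        if shift > 70:
            raise FormatError(f"varint longer than 10 bytes at offset {offset}")


def _varint_len(x: int) -> int:
    return max(1, (int(x).bit_length() + 6) // 7)


# ---------------------------------------------------------------- delta stage

@dataclass
class DeltaArray:
    """First value plus non-negative gaps of a sorted array."""

    first: int | None
    deltas: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.uint64))

    def __len__(self) -> int:
        return 0 if self.first is None else 1 + len(self.deltas)


def _as_u64_sorted(v, who: str) -> np.ndarray:
    a = np.asarray(v)
    if a.ndim != 1:
        raise InvalidInputError(f"{who}: expected a 1-D array, got shape {a.shape}")
    if a.size and a.dtype.kind not in "ui":
        if not np.all(np.equal(np.mod(a, 1), 0)) or np.any(a < 0):
            raise InvalidInputError(f"{who}: values must be non-negative integers")
    elif a.size and a.dtype.kind == "i" and (a < 0).any():
        raise InvalidInputError(f"{who}: values must be non-negative")
    a = a.astype(np.uint64)
    if a.size > 1 and np.any(a[1:] < a[:-1]):
        i = int(np.argmax(a[1:] < a[:-1]))
        raise UnsortedInputError(f"{who}: array decreases at index {i + 1}")
    return a


def delta_encode(v) -> DeltaArray:
    """Sorted unsigned array -> first value + gaps."""
    a = _as_u64_sorted(v, "delta_encode")
    if a.size == 0:
        return DeltaArray(first=None)
    return DeltaArray(first=int(a[0]), deltas=np.diff(a))


def delta_decode(d: DeltaArray) -> np.ndarray:
    """Inverse of :func:`delta_encode` (cumulative sum)."""
    if d.first is None:
        return np.empty(0, dtype=np.uint64)
    out = np.empty(len(d.deltas) + 1, dtype=np.uint64)
    out[0] = d.first
    np.cumsum(np.asarray(d.deltas, dtype=np.uint64), out=out[1:])
    out[1:] += np.uint64(d.first)
    return out


# ---------------------------------------------------------------- pFor stage

def _bit_lengths(v: np.ndarray) -> np.ndarray:
    nb = np.zeros(v.size, dtype=np.int64)
    nz = v > 0
    if nz.any():
        nb[nz] = np.floor(np.log2(v[nz].astype(np.float64))).astype(np.int64) + 1
    return nb


def _choose_width(vals: np.ndarray) -> int:
    """Brute-force minimal-byte bit width for one miniblock (ties -> smaller b)."""
    nb = _bit_lengths(vals)
    hist = np.bincount(nb, minlength=33)
    best_b, best_cost = 0, None
    for b in range(33):
        cost = (MINIBLOCK * b + 7) // 8
        for k in range(b + 1, 33):
            if hist[k]:
                cost += hist[k] * (1 + (k - b + 6) // 7)
        if best_cost is None or cost < best_cost:
            best_b, best_cost = b, cost
    return best_b


def _pack_bits_lsb(vals: np.ndarray, b: int, slots: int) -> bytes:
    """Pack ``vals`` (low ``b`` bits each) LSB-first into ``slots`` slots."""
    if b == 0:
        return b""
    padded = np.zeros(slots, dtype=np.uint64)
    padded[: vals.size] = vals & np.uint64((1 << b) - 1)
    bits = (
        (padded[:, None] >> np.arange(b, dtype=np.uint64)) & np.uint64(1)
    ).astype(np.uint8)
    return np.packbits(bits.reshape(-1), bitorder="little").tobytes()


def _unpack_bits_lsb(buf: bytes, b: int, slots: int) -> np.ndarray:
    if b == 0:
        return np.zeros(slots, dtype=np.uint64)
    bits = np.unpackbits(np.frombuffer(buf, dtype=np.uint8), bitorder="little")
    bits = bits[: slots * b].reshape(slots, b).astype(np.uint64)
    return (bits << np.arange(b, dtype=np.uint64)).sum(axis=1, dtype=np.uint64)


def pfor_encode(v) -> bytes:
    """Encode an unsigned-integer array (< 2**32 each) to a self-delimiting payload."""
    a = np.asarray(v)
    if a.ndim != 1:
        raise InvalidInputError(f"pfor_encode: expected 1-D array, got shape {a.shape}")
    if a.size and a.dtype.kind == "i" and (a < 0).any():
        raise InvalidInputError("pfor_encode: values must be non-negative")
    a = a.astype(np.uint64)
    if a.size and (a >= _U32_LIMIT).any():
        i = int(np.argmax(a >= _U32_LIMIT))
        raise RangeError(
            f"pfor_encode: value {int(a[i])} at index {i} exceeds 32-bit range"
        )
    out = bytearray(PFOR_MAGIC)
    out.append(PFOR_VERSION)
    out += encode_varint(a.size)
    for start in range(0, a.size, MINIBLOCK):
        block = a[start : start + MINIBLOCK]
        b = _choose_width(block)
        exc_pos = (
            np.nonzero(block >= np.uint64(1 << b))[0]
            if b < 32
            else np.empty(0, dtype=np.int64)
        )
        out.append(b)
        out += encode_varint(exc_pos.size)
        out += _pack_bits_lsb(block, b, MINIBLOCK)
        prev = 0
        for p in exc_pos:
            out += encode_varint(int(p) - prev)
            out += encode_varint(int(block[p]) >> b)
            prev = int(p)
    return bytes(out)


def pfor_decode_stream(buf: bytes, offset: int = 0) -> tuple[np.ndarray, int]:
    """Decode one pFor payload starting at ``offset``; return (values, end offset)."""
    if buf[offset : offset + 4] != PFOR_MAGIC:
        raise FormatError(
            f"bad pFor magic at byte offset {offset}: {buf[offset:offset + 4]!r}"
        )
    offset += 4
    if offset >= len(buf):
        raise FormatError("truncated pFor payload: missing version byte")
    version = buf[offset]
    offset += 1
    if version != PFOR_VERSION:
        raise FormatError(f"unsupported pFor payload version {version}")
    count, offset = decode_varint(buf, offset)
    values = np.empty(count, dtype=np.uint64)
    done = 0
    while done < count:
        if offset >= len(buf):
            raise FormatError(f"truncated pFor payload at byte offset {offset}")
        b = buf[offset]
        offset += 1
        if b > 32:
            raise FormatError(f"invalid bit width {b} at byte offset {offset - 1}")
        n_exc, offset = decode_varint(buf, offset)
        packed_len = (MINIBLOCK * b + 7) // 8
        if offset + packed_len > len(buf):
            raise FormatError(f"truncated packed area at byte offset {offset}")
        block = _unpack_bits_lsb(buf[offset : offset + packed_len], b, MINIBLOCK)
        offset += packed_len
        pos = 0
        for _ in range(n_exc):
            dpos, offset = decode_varint(buf, offset)
            high, offset = decode_varint(buf, offset)
            pos += dpos
            if pos >= MINIBLOCK:
                raise FormatError(f"exception position {pos} out of miniblock range")
            block[pos] |= np.uint64(high) << np.uint64(b)
        take = min(MINIBLOCK, count - done)
        values[done : done + take] = block[:take]
        done += take
    return values, offset


def pfor_decode(payload: bytes) -> np.ndarray:
    """Inverse of :func:`pfor_encode`; the payload must contain nothing else."""
    values, end = pfor_decode_stream(payload, 0)
    if end != len(payload):
        raise FormatError(
            f"{len(payload) - end} trailing bytes after pFor payload (offset {end})"
        )
    return values


# ---------------------------------------------------------------- composition

def encode_sorted_array(v) -> bytes:
    """Sorted unsigned array -> zlib(varint count | varint first | pFor(gaps)).

    The first value is stored as an unbounded varint so 64-bit quantized m/z
    (6 decimal places, m/z above ~4294 Da) round-trips; the gaps themselves
    must fit 32 bits — a larger gap would mean a >4000 Da hole at 6 dp and is
    rejected as a range error.
    """
    d = delta_encode(v)
    body = bytearray(encode_varint(len(d)))
    if d.first is not None:
        body += encode_varint(d.first)
        if d.deltas.size and (d.deltas >= _U32_LIMIT).any():
            raise RangeError("gap between adjacent sorted values exceeds 32 bits")
        body += pfor_encode(d.deltas)
    return zlib.compress(bytes(body), ZLIB_LEVEL)


def decode_sorted_array(payload: bytes) -> np.ndarray:
    """Inverse of :func:`encode_sorted_array`."""
    try:
        body = zlib.decompress(payload)
    except zlib.error as e:
        raise FormatError(f"zlib inflate failed: {e}") from None
    count, offset = decode_varint(body, 0)
    if count == 0:
        if offset != len(body):
            raise FormatError("trailing bytes after empty sorted-array payload")
        return np.empty(0, dtype=np.uint64)
    first, offset = decode_varint(body, offset)
    deltas, offset = pfor_decode_stream(body, offset)
    if offset != len(body):
        raise FormatError("trailing bytes after sorted-array payload")
    if deltas.size != count - 1:
        raise FormatError(
            f"sorted-array payload count mismatch: header {count}, gaps {deltas.size}"
        )
    return delta_decode(DeltaArray(first=first, deltas=deltas))
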