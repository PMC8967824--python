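"""Stacked compression of groups of spectra (the stacked-ZDPD core).

Up to ``2**n`` same-level spectra (for MS2: same isolation window) are merged
into one globally sorted quantized m/z array.  Adjacent spectra from the same
chromatographic neighbourhood share many near-identical centroids, so the
merged array's gaps are smaller and more repetitive than any single
spectrum's — exactly what the delta/PFor/zlib codec rewards.  To undo the
merge, an *n-bit tag per peak* records which layer (spectrum) each merged
element came from; the tag stream is bit-packed and zlib-compressed.
Intensities travel in merged order so one permutation serves both arrays and
an m/z window is a contiguous slice for chromatogram extraction.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    CapacityError,
    FormatError,
    InvalidInputError,
    RangeError,
)
from .intcodec import ZLIB_LEVEL, decode_sorted_array, encode_sorted_array
from .quantization import PrecisionConfig, dequantize_mz, quantize_mz

__all__ = [
    "Spectrum",
    "EncodedStack",
    "merge_spectra",
    "scatter",
    "pack_tag_bits",
    "unpack_tag_bits",
    "pack_tags",
    "unpack_tags",
    "encode_stack",
    "decode_stack",
]

DEFAULT_LAYER_EXPONENT = 8  # 256 spectra per stack
MAX_TAG_BITS = 16


@dataclass
class Spectrum:
    """One scan: retention time, MS level, optional precursor window, peak lists."""

    rt: float
    ms_level: int
    mz: np.ndarray
    intensity: np.ndarray
    precursor_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise InvalidInputError(
                f"mz/intensity shape mismatch: {self.mz.shape} vs {self.intensity.shape}"
            )
        if self.rt < 0:
            raise InvalidInputError(f"negative retention time {self.rt}")
        if self.ms_level not in (1, 2):
            raise InvalidInputError(f"ms_level must be 1 or 2, got {self.ms_level}")
        if self.ms_level == 2 and self.precursor_window is None:
            raise InvalidInputError("MS2 spectrum requires a precursor window")
        if self.mz.size > 1 and np.any(np.diff(self.mz) < 0):
            raise InvalidInputError("spectrum m/z array must be non-decreasing")

    def __len__(self) -> int:
        return self.mz.size


@dataclass
class EncodedStack:
    """Compressed unit: merged m/z payload, packed tags, merged-order intensities."""

    layer_exponent: int
    spectrum_count: int
    peaks_per_layer: list[int]
    mz_payload: bytes
    tag_payload: bytes
    intensity_payload: bytes
    intensity_width: int = 32  # bits per stored intensity (32 or 64)

    @property
    def layer_capacity(self) -> int:
        return 1 << self.layer_exponent

    @property
    def total_peaks(self) -> int:
        return sum(self.peaks_per_layer)


# ---------------------------------------------------------------- merge / scatter

def merge_spectra(quantized_mz_per_layer):
    """Merge sorted per-spectrum integer arrays into one sorted array plus tags.

    Returns ``(merged, tags, permutation)``: ``tags[i]`` is the source layer of
    ``merged[i]`` (ties broken by ascending layer, stable within a layer), and
    ``permutation`` maps positions of the concatenated input to positions in
    the merged array — the alignment used to carry intensities along.
    """
    if len(quantized_mz_per_layer) < 1:
        raise InvalidInputError("merge_spectra requires at least one layer")
    arrays = []
    for li, arr in enumerate(quantized_mz_per_layer):
        a = np.asarray(arr, dtype=np.uint64)
        if a.size > 1 and np.any(a[1:] < a[:-1]):
            raise InvalidInputError(f"layer {li} is not sorted")
        arrays.append(a)
    concat = (
        np.concatenate(arrays) if arrays else np.empty(0, dtype=np.uint64)
    )
    layer_ids = np.repeat(
        np.arange(len(arrays), dtype=np.int64), [a.size for a in arrays]
    )
    order = np.argsort(concat, kind="stable")
    merged = concat[order]
    tags = layer_ids[order]
    permutation = np.empty(order.size, dtype=np.int64)
    permutation[order] = np.arange(order.size, dtype=np.int64)
    return merged, tags, permutation


def scatter(merged, tags, spectrum_count: int):
    """Inverse of :func:`merge_spectra` on the m/z side: per-layer sorted arrays."""
    merged = np.asarray(merged, dtype=np.uint64)
    tags = np.asarray(tags, dtype=np.int64)
    if merged.size != tags.size:
        raise FormatError(
            f"merged/tags length mismatch: {merged.size} vs {tags.size}"
        )
    if tags.size and (tags.min() < 0 or tags.max() >= spectrum_count):
        raise FormatError(
            f"tag out of range [0, {spectrum_count}): {int(tags.min())}..{int(tags.max())}"
        )
    return [merged[tags == layer] for layer in range(spectrum_count)]


# ---------------------------------------------------------------- tag packing

def pack_tag_bits(tags, n: int) -> bytes:
    """Bit-pack tags LSB-first, n bits each -> exactly ceil(len*n/8) bytes (pre-zlib)."""
    tags = np.asarray(tags, dtype=np.uint64)
    if not 0 <= n <= MAX_TAG_BITS:
        raise InvalidInputError(f"tag bit width must be in 0..{MAX_TAG_BITS}, got {n}")
    if tags.size and n < 64 and (tags >= np.uint64(1 << n)).any():
        raise RangeError(f"tag value exceeds {n}-bit range")
    if n == 0 or tags.size == 0:
        return b""
    bits = (
        (tags[:, None] >> np.arange(n, dtype=np.uint64)) & np.uint64(1)
    ).astype(np.uint8)
    return np.packbits(bits.reshape(-1), bitorder="little").tobytes()


def unpack_tag_bits(packed: bytes, count: int, n: int) -> np.ndarray:
    """Inverse of :func:`pack_tag_bits`: recover exactly ``count`` tags."""
    if n == 0 or count == 0:
        return np.zeros(count, dtype=np.int64)
    need = (count * n + 7) // 8
    if len(packed) < need:
        raise FormatError(
            f"tag stream too short: {len(packed)} bytes, need {need} for {count} tags"
        )
    bits = np.unpackbits(np.frombuffer(packed, dtype=np.uint8), bitorder="little")
    bits = bits[: count * n].reshape(count, n).astype(np.uint64)
    return (bits << np.arange(n, dtype=np.uint64)).sum(axis=1, dtype=np.uint64).astype(
        np.int64
    )


def pack_tags(tags, n: int) -> bytes:
    """Bit-pack then zlib-compress the tag stream; empty stream -> empty payload."""
    packed = pack_tag_bits(tags, n)
    return zlib.compress(packed, ZLIB_LEVEL) if packed else b""


def unpack_tags(payload: bytes, count: int, n: int) -> np.ndarray:
    """Inflate and unpack a tag payload to exactly ``count`` tag values."""
    if n == 0 or count == 0:
        return np.zeros(count, dtype=np.int64)
    try:
        packed = zlib.decompress(payload)
    except zlib.error as e:
        raise FormatError(f"tag payload inflate failed: {e}") from None
    return unpack_tag_bits(packed, count, n)


# ---------------------------------------------------------------- stack encode/decode

def _intensity_dtype(width: int) -> np.dtype:
    if width == 32:
        return np.dtype("<f4")
    if width == 64:
        return np.dtype("<f8")
    raise InvalidInputError(f"intensity width must be 32 or 64, got {width}")


def encode_stack(
    spectra,
    cfg: PrecisionConfig,
    n: int = DEFAULT_LAYER_EXPONENT,
    intensity_width: int = 32,
) -> EncodedStack:
    """Compress up to ``2**n`` homogeneous spectra into one :class:`EncodedStack`.

    All spectra must share the MS level and (for MS2) the precursor window.
    m/z is quantized per ``cfg`` (lossy within half a quantum); intensities are
    narrowed to 32-bit floats unless ``intensity_width=64``.
    """
    spectra = list(spectra)
    if not spectra:
        raise InvalidInputError("encode_stack requires at least one spectrum")
    if len(spectra) > (1 << n):
        raise CapacityError(
            f"{len(spectra)} spectra exceed layer capacity 2**{n} = {1 << n}"
        )
    level = spectra[0].ms_level
    window = spectra[0].precursor_window
    for i, s in enumerate(spectra):
        if s.ms_level != level:
            raise InvalidInputError(f"mixed MS levels in stack (spectrum {i})")
        if level == 2 and s.precursor_window != window:
            raise InvalidInputError(f"mixed precursor windows in stack (spectrum {i})")
    quantized = [quantize_mz(s.mz, cfg) for s in spectra]
    merged, tags, permutation = merge_spectra(quantized)
    dtype = _intensity_dtype(intensity_width)
    concat_intensity = (
        np.concatenate([s.intensity for s in spectra])
        if merged.size
        else np.empty(0, dtype=np.float64)
    )
    merged_intensity = np.empty(merged.size, dtype=np.float64)
    merged_intensity[permutation] = concat_intensity
    return EncodedStack(
        layer_exponent=n,
        spectrum_count=len(spectra),
        peaks_per_layer=[len(s) for s in spectra],
        mz_payload=encode_sorted_array(merged),
        tag_payload=pack_tags(tags, n),
        intensity_payload=zlib.compress(
            merged_intensity.astype(dtype).tobytes(), ZLIB_LEVEL
        ),
        intensity_width=intensity_width,
    )


def decode_stack(
    es: EncodedStack,
    cfg: PrecisionConfig,
    rts=None,
    ms_level: int = 1,
    precursor_window: tuple[float, float] | None = None,
) -> list[Spectrum]:
    """Losslessly invert :func:`encode_stack` at the quantized-integer level.

    ``rts``/``ms_level``/``precursor_window`` restore scan metadata the stack
    payload itself does not carry (the container keeps them in its JSON index).
    """
    merged = decode_sorted_array(es.mz_payload)
    total = int(merged.size)
    if total != es.total_peaks:
        raise FormatError(
            f"mz payload holds {total} peaks but descriptor says {es.total_peaks}"
        )
    if es.spectrum_count < 1 or es.spectrum_count > es.layer_capacity:
        raise FormatError(
            f"spectrum_count {es.spectrum_count} outside 1..{es.layer_capacity}"
        )
    tags = unpack_tags(es.tag_payload, total, es.layer_exponent)
    if total and (tags.min() < 0 or tags.max() >= es.spectrum_count):
        raise FormatError("decoded tag exceeds spectrum count")
    counts = np.bincount(tags, minlength=es.spectrum_count) if total else np.zeros(
        es.spectrum_count, dtype=np.int64
    )
    if list(counts[: es.spectrum_count]) != list(es.peaks_per_layer):
        raise FormatError("tag distribution disagrees with peaks_per_layer")
    try:
        raw = zlib.decompress(es.intensity_payload)
    except zlib.error as e:
        raise FormatError(f"intensity payload inflate failed: {e}") from None
    dtype = _intensity_dtype(es.intensity_width)
    if len(raw) != total * dtype.itemsize:
        raise FormatError(
            f"intensity payload holds {len(raw)} bytes, expected {total * dtype.itemsize}"
        )
    merged_intensity = np.frombuffer(raw, dtype=dtype).astype(np.float64)
    if rts is None:
        rts = [0.0] * es.spectrum_count
    if len(rts) != es.spectrum_count:
        raise FormatError(
            f"{len(rts)} retention times for {es.spectrum_count} spectra"
        )
    # group merged positions by layer; stable sort keeps per-layer m/z order
    order = np.argsort(tags, kind="stable")
    bounds = np.cumsum(counts)[:-1]
    mz_groups = np.split(merged[order], bounds)
    int_groups = np.split(merged_intensity[order], bounds)
    return [
        Spectrum(
            rt=float(rts[layer]),
            ms_level=ms_level,
            mz=dequantize_mz(mz_groups[layer], cfg),
            intensity=int_groups[layer],
            precursor_window=precursor_window,
        )
        for layer in range(es.spectrum_count)
    ]
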