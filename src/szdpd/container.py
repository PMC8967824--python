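"""The mini-Aird on-disk layout: a human-readable JSON index plus a binary file.

A run is stored as two files, ``<stem>.mini-aird.json`` and
``<stem>.mini-aird.bin``.  The JSON carries everything needed to navigate the
run — precision, acquisition mode, block/stack descriptors with byte offsets,
retention times, spectrum ids — so listing time points or locating a spectrum
never touches the binary.  The binary is the bare concatenation of each
stack's three payload segments (merged m/z | packed tags | intensities) in
descriptor order; there is no in-band framing, the JSON is authoritative.

Spectra are grouped into blocks by MS level and (for DIA MS2) isolation
window, so an extracted ion chromatogram touches exactly one block and, per
stack, one contiguous slice of the merged sorted m/z array.
"""

from __future__ import annotations

import json
import os
import zlib
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    EntityLookupError,
    FormatError,
    InvalidInputError,
    UnsupportedVersionError,
)
from .intcodec import decode_sorted_array
from .quantization import PrecisionConfig
from .stack_codec import EncodedStack, Spectrum, decode_stack, unpack_tags

__all__ = [
    "FORMAT_VERSION",
    "StackEntry",
    "Block",
    "RunMetadata",
    "write_run",
    "read_metadata",
    "read_stack",
    "read_spectrum",
    "extract_xic",
]

FORMAT_VERSION = "mini-aird-1"
JSON_SUFFIX = ".mini-aird.json"
BIN_SUFFIX = ".mini-aird.bin"
WINDOW_DECIMALS = 4  # isolation windows are keyed after rounding to 4 decimals


@dataclass
class StackEntry:
    """One encoded stack plus the scan metadata the payloads do not carry."""

    encoded: EncodedStack
    rts: list[float]
    spectrum_ids: list[int]
    precursor_window: tuple[float, float] | None = None


@dataclass
class Block:
    """Ordered stacks of one MS level (and, for MS2, one grouping key)."""

    ms_level: int
    layer_exponent: int
    stacks: list[StackEntry] = field(default_factory=list)
    precursor_window: tuple[float, float] | None = None


def round_window(window):
    """Canonical isolation-window key: rounded to 4 decimals, as a tuple."""
    if window is None:
        return None
    return (round(float(window[0]), WINDOW_DECIMALS), round(float(window[1]), WINDOW_DECIMALS))


# ---------------------------------------------------------------- writing

def write_run(
    blocks: list[Block],
    path_stem: str,
    cfg: PrecisionConfig,
    mode: str,
    source: dict | None = None,
) -> tuple[str, str]:
    """Serialize encoded blocks to the two-file layout; returns (json, bin) paths.

    The binary is written to a temporary name and renamed only after the JSON
    serializes cleanly, so a failure never leaves a partial pair behind.
    """
    if mode not in ("DDA", "DIA"):
        raise InvalidInputError(f"acquisition mode must be DDA or DIA, got {mode!r}")
    json_path = path_stem + JSON_SUFFIX
    bin_path = path_stem + BIN_SUFFIX
    offset = 0
    segments: list[bytes] = []
    block_docs = []
    total_spectra = 0
    for bi, block in enumerate(blocks):
        stack_docs = []
        for entry in block.stacks:
            es = entry.encoded
            if len(entry.rts) != es.spectrum_count or len(entry.spectrum_ids) != es.spectrum_count:
                raise FormatError(
                    f"block {bi}: rt/id list lengths disagree with spectrum_count"
                )
            seg_lens = (len(es.mz_payload), len(es.tag_payload), len(es.intensity_payload))
            stack_docs.append(
                {
                    "offset": offset,
                    "mz_bytes": seg_lens[0],
                    "tag_bytes": seg_lens[1],
                    "intensity_bytes": seg_lens[2],
                    "layer_exponent": es.layer_exponent,
                    "spectrum_count": es.spectrum_count,
                    "peaks_per_layer": list(map(int, es.peaks_per_layer)),
                    "intensity_width": es.intensity_width,
                    "rt": [float(t) for t in entry.rts],
                    "spectrum_ids": list(map(int, entry.spectrum_ids)),
                    "precursor_window": list(round_window(entry.precursor_window))
                    if entry.precursor_window is not None
                    else None,
                }
            )
            segments += [es.mz_payload, es.tag_payload, es.intensity_payload]
            offset += sum(seg_lens)
            total_spectra += es.spectrum_count
        rts_concat = [t for s in stack_docs for t in s["rt"]]
        if any(t2 <= t1 for t1, t2 in zip(rts_concat, rts_concat[1:])):
            raise FormatError(
                f"block {bi}: concatenated retention times are not strictly increasing"
            )
        block_docs.append(
            {
                "block_id": bi,
                "ms_level": block.ms_level,
                "layer_exponent": block.layer_exponent,
                "precursor_window": list(round_window(block.precursor_window))
                if block.precursor_window is not None
                else None,
                "stacks": stack_docs,
            }
        )
    doc = {
        "format_version": FORMAT_VERSION,
        "precision": {"decimal_places": cfg.decimal_places, "scale": cfg.scale},
        "acquisition_mode": mode,
        "source": source or {},
        "total_spectra": total_spectra,
        "binary_file": os.path.basename(bin_path),
        "blocks": block_docs,
    }
    payload = json.dumps(doc, indent=1, sort_keys=False) + "\n"
    tmp_bin = bin_path + ".tmp"
    with open(tmp_bin, "wb") as fh:
        for seg in segments:
            fh.write(seg)
    try:
        with open(json_path, "w", encoding="utf-8") as fh:
            fh.write(payload)
    except Exception:
        os.unlink(tmp_bin)
        raise
    os.replace(tmp_bin, bin_path)
    return json_path, bin_path


# ---------------------------------------------------------------- reading

_REQUIRED_TOP = (
    "format_version",
    "precision",
    "acquisition_mode",
    "total_spectra",
    "blocks",
)
_REQUIRED_STACK = (
    "offset",
    "mz_bytes",
    "tag_bytes",
    "intensity_bytes",
    "layer_exponent",
    "spectrum_count",
    "peaks_per_layer",
    "rt",
    "spectrum_ids",
)


@dataclass
class RunMetadata:
    """Parsed, validated JSON index of a run; knows where its binary lives."""

    doc: dict
    json_path: str
    bin_path: str
    _spectrum_index: dict | None = None

    @property
    def precision(self) -> PrecisionConfig:
        return PrecisionConfig(self.doc["precision"]["decimal_places"])

    @property
    def mode(self) -> str:
        return self.doc["acquisition_mode"]

    @property
    def blocks(self) -> list[dict]:
        return self.doc["blocks"]

    @property
    def total_spectra(self) -> int:
        return self.doc["total_spectra"]

    def spectrum_index(self) -> dict:
        """global id -> (block_id, stack_index, layer)."""
        if self._spectrum_index is None:
            idx = {}
            for b in self.blocks:
                for si, s in enumerate(b["stacks"]):
                    for layer, gid in enumerate(s["spectrum_ids"]):
                        idx[int(gid)] = (b["block_id"], si, layer)
            self._spectrum_index = idx
        return self._spectrum_index


def read_metadata(json_path: str) -> RunMetadata:
    """Load and schema-check a run index; failures name the offending field."""
    with open(json_path, encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise FormatError(f"metadata is not valid JSON: {e}") from None
    for key in _REQUIRED_TOP:
        if key not in doc:
            raise FormatError(f"metadata missing required field {key!r}")
    if doc["format_version"] != FORMAT_VERSION:
        raise UnsupportedVersionError(
            f"unsupported format version {doc['format_version']!r}, "
            f"this reader handles {FORMAT_VERSION!r}"
        )
    if "decimal_places" not in doc["precision"]:
        raise FormatError("metadata missing required field 'precision.decimal_places'")
    prev_end = 0
    for b in doc["blocks"]:
        for key in ("block_id", "ms_level", "layer_exponent", "stacks"):
            if key not in b:
                raise FormatError(f"block descriptor missing field {key!r}")
        for s in b["stacks"]:
            for key in _REQUIRED_STACK:
                if key not in s:
                    raise FormatError(f"stack descriptor missing field {key!r}")
            if s["offset"] < prev_end:
                raise FormatError(
                    f"stack offset {s['offset']} overlaps previous segment end {prev_end}"
                )
            if len(s["rt"]) != s["spectrum_count"]:
                raise FormatError("stack field 'rt' length disagrees with spectrum_count")
            prev_end = s["offset"] + s["mz_bytes"] + s["tag_bytes"] + s["intensity_bytes"]
    bin_path = os.path.join(
        os.path.dirname(os.path.abspath(json_path)),
        doc.get("binary_file", os.path.basename(json_path)[: -len(JSON_SUFFIX)] + BIN_SUFFIX),
    )
    return RunMetadata(doc=doc, json_path=json_path, bin_path=bin_path)


def _stack_doc(meta: RunMetadata, block_id: int, stack_index: int) -> tuple[dict, dict]:
    for b in meta.blocks:
        if b["block_id"] == block_id:
            if not 0 <= stack_index < len(b["stacks"]):
                raise EntityLookupError(
                    f"stack index {stack_index} out of range for block {block_id}"
                )
            return b, b["stacks"][stack_index]
    raise EntityLookupError(f"no block with id {block_id}")


def _read_segments(meta: RunMetadata, s: dict) -> tuple[bytes, bytes, bytes]:
    total = s["mz_bytes"] + s["tag_bytes"] + s["intensity_bytes"]
    with open(meta.bin_path, "rb") as fh:
        fh.seek(s["offset"])
        buf = fh.read(total)
    if len(buf) != total:
        raise FormatError(
            f"binary file truncated: wanted {total} bytes at offset {s['offset']}"
        )
    a = s["mz_bytes"]
    b = a + s["tag_bytes"]
    return buf[:a], buf[a:b], buf[b:]


def _entry_window(b: dict, s: dict):
    w = s.get("precursor_window") or b.get("precursor_window")
    return tuple(w) if w is not None else None


def read_stack(meta: RunMetadata, block_id: int, stack_index: int) -> list[Spectrum]:
    """Decode exactly one stack (seek + bounded read of its three segments)."""
    b, s = _stack_doc(meta, block_id, stack_index)
    mz_seg, tag_seg, int_seg = _read_segments(meta, s)
    es = EncodedStack(
        layer_exponent=s["layer_exponent"],
        spectrum_count=s["spectrum_count"],
        peaks_per_layer=list(s["peaks_per_layer"]),
        mz_payload=mz_seg,
        tag_payload=tag_seg,
        intensity_payload=int_seg,
        intensity_width=s.get("intensity_width", 32),
    )
    return decode_stack(
        es,
        meta.precision,
        rts=s["rt"],
        ms_level=b["ms_level"],
        precursor_window=_entry_window(b, s),
    )


def read_spectrum(meta: RunMetadata, global_spectrum_id: int) -> Spectrum:
    """Resolve a global spectrum id via the index and decode only its stack."""
    try:
        block_id, stack_index, layer = meta.spectrum_index()[int(global_spectrum_id)]
    except (KeyError, TypeError, ValueError):
        raise EntityLookupError(
            f"no spectrum with global id {global_spectrum_id!r}"
        ) from None
    return read_stack(meta, block_id, stack_index)[layer]


def iter_spectra(meta: RunMetadata):
    """Yield (global id, Spectrum) for the whole run in block/stack order."""
    for b in meta.blocks:
        for si, s in enumerate(b["stacks"]):
            spectra = read_stack(meta, b["block_id"], si)
            for gid, sp in zip(s["spectrum_ids"], spectra):
                yield int(gid), sp


# ---------------------------------------------------------------- XIC

def _select_blocks(meta: RunMetadata, ms_level: int, window):
    if ms_level == 1:
        return [b for b in meta.blocks if b["ms_level"] == 1]
    if meta.mode == "DIA" and window is None:
        raise InvalidInputError(
            "an MS2 chromatogram on a DIA run needs a precursor m/z or isolation window"
        )
    out = []
    for b in meta.blocks:
        if b["ms_level"] != 2:
            continue
        bw = b.get("precursor_window")
        if window is None:
            out.append(b)
        elif isinstance(window, (tuple, list)):
            if bw is not None and tuple(bw) == round_window(window):
                out.append(b)
        else:  # precursor m/z: any block whose window contains it
            if bw is not None and bw[0] <= float(window) <= bw[1]:
                out.append(b)
    return out


def extract_xic(
    meta: RunMetadata,
    mz_center: float,
    tol_ppm: float,
    rt_range: tuple[float, float] | None = None,
    ms_level: int = 1,
    window=None,
) -> list[tuple[float, float]]:
    """Extracted ion chromatogram: (rt, summed intensity) per selected spectrum.

    The m/z window is ``mz_center * (1 ± tol_ppm * 1e-6)``.  Per stack, the
    matching peaks are found by binary search in the merged sorted m/z array
    and attributed to spectra through the tag stream — individual spectra are
    never materialized.  Spectra with no matching peak contribute zero at
    their retention time.
    """
    if tol_ppm <= 0:
        raise InvalidInputError(f"tol_ppm must be positive, got {tol_ppm}")
    cfg = meta.precision
    lo = mz_center * (1.0 - tol_ppm * 1e-6)
    hi = mz_center * (1.0 + tol_ppm * 1e-6)
    points: list[tuple[float, float]] = []
    for b in _select_blocks(meta, ms_level, window):
        for s in b["stacks"]:
            rts = s["rt"]
            if rt_range is not None:
                keep = [rt_range[0] <= t <= rt_range[1] for t in rts]
                if not any(keep):
                    continue
            else:
                keep = [True] * len(rts)
            mz_seg, tag_seg, int_seg = _read_segments(meta, s)
            merged = decode_sorted_array(mz_seg)
            total = merged.size
            qlo = max(int(np.ceil(lo * cfg.scale)) - 1, 0)
            qhi = int(np.floor(hi * cfg.scale)) + 1
            i0 = int(np.searchsorted(merged, np.uint64(qlo), side="left"))
            i1 = int(np.searchsorted(merged, np.uint64(qhi), side="right"))
            sums = np.zeros(s["spectrum_count"], dtype=np.float64)
            if i1 > i0:
                slab = merged[i0:i1].astype(np.float64) / cfg.scale
                mask = (slab >= lo) & (slab <= hi)
                if mask.any():
                    tags = unpack_tags(tag_seg, total, s["layer_exponent"])
                    try:
                        raw = zlib.decompress(int_seg)
                    except zlib.error as e:
                        raise FormatError(f"intensity payload inflate failed: {e}") from None
                    width = s.get("intensity_width", 32)
                    dtype = np.dtype("<f4") if width == 32 else np.dtype("<f8")
                    intensity = np.frombuffer(raw, dtype=dtype).astype(np.float64)
                    sel = np.arange(i0, i1)[mask]
                    sums = np.bincount(
                        tags[sel],
                        weights=intensity[sel],
                        minlength=s["spectrum_count"],
                    )
            for layer, t in enumerate(rts):
                if keep[layer]:
                    points.append((float(t), float(sums[layer])))
    points.sort(key=lambda p: p[0])
    return points
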