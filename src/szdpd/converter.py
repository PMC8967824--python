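"""mzML -> mini-Aird conversion: read, reorder into blocks, encode, write.

Reading supports a deliberate subset of mzML 1.1, parsed directly with lxml:
centroid or profile spectra with 32/64-bit float m/z and intensity arrays,
zlib or no compression, MS levels 1 and 2.  Numpress-encoded arrays are
rejected with a clear message naming the CV term.

Block organization follows the acquisition mode.  MS1 spectra always form one
stacked block in retention-time order.  In DIA, MS2 spectra are grouped per
isolation window (windows keyed after rounding to 4 decimals) and stacked
like MS1.  In DDA, the precursor set changes every cycle, so MS2 spectra are
grouped under their triggering MS1 scan and stored unstacked (layer exponent
0 — the plain single-spectrum codec path).
"""

from __future__ import annotations

import base64
import logging
import os
import zlib
from collections import Counter, OrderedDict
from dataclasses import dataclass

import numpy as np
from lxml import etree

from .container import Block, StackEntry, round_window, write_run
from .errors import (
    InvalidInputError,
    ParseError,
    UnsupportedFeatureError,
)
from .quantization import PrecisionConfig, sort_spectrum
from .stack_codec import DEFAULT_LAYER_EXPONENT, Spectrum, encode_stack

__all__ = [
    "read_mzml",
    "detect_mode",
    "organize_blocks",
    "convert",
    "PlannedBlock",
]

log = logging.getLogger(__name__)

_NS = "{http://psi.hupo.org/ms/mzml}"

# CV accessions this reader understands
_ACC_MS_LEVEL = "MS:1000511"
_ACC_SCAN_START = "MS:1000016"
_ACC_ISO_TARGET = "MS:1000827"
_ACC_ISO_LOWER = "MS:1000828"
_ACC_ISO_UPPER = "MS:1000829"
_ACC_SELECTED_MZ = "MS:1000744"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_NOCOMP = "MS:1000576"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_UNSUPPORTED_BINARY = {
    "MS:1000522": "64-bit integer",
    "MS:1000519": "32-bit integer",
    "MS:1002312": "MS-Numpress linear prediction compression",
    "MS:1002313": "MS-Numpress positive integer compression",
    "MS:1002314": "MS-Numpress short logged float compression",
    "MS:1002746": "MS-Numpress linear prediction compression followed by zlib",
    "MS:1002747": "MS-Numpress positive integer compression followed by zlib",
    "MS:1002748": "MS-Numpress short logged float compression followed by zlib",
}
_MINUTE_UNITS = {"UO:0000031", "minute"}


# ---------------------------------------------------------------- mzML reading

def _cv_params(element) -> dict[str, dict]:
    """accession -> {'value':..., 'unit':...} for direct cvParam children."""
    out = {}
    for cv in element.findall(_NS + "cvParam"):
        out[cv.get("accession")] = {
            "value": cv.get("value"),
            "unit": cv.get("unitAccession") or cv.get("unitName"),
        }
    return out


def _decode_binary_array(bda, index: int) -> tuple[str, np.ndarray]:
    params = _cv_params(bda)
    for acc in params:
        if acc in _UNSUPPORTED_BINARY:
            raise UnsupportedFeatureError(
                f"spectrum {index}: unsupported binary encoding {acc} "
                f"({_UNSUPPORTED_BINARY[acc]}); only 32/64-bit floats with "
                "zlib or no compression are handled"
            )
    if _ACC_F64 in params:
        dtype = np.dtype("<f8")
    elif _ACC_F32 in params:
        dtype = np.dtype("<f4")
    else:
        raise UnsupportedFeatureError(
            f"spectrum {index}: binary array without a recognized precision CV term"
        )
    if _ACC_MZ_ARRAY in params:
        kind = "mz"
    elif _ACC_INT_ARRAY in params:
        kind = "intensity"
    else:
        kind = "other"
    node = bda.find(_NS + "binary")
    raw = base64.b64decode((node.text or "").encode("ascii")) if node is not None else b""
    if _ACC_ZLIB in params:
        try:
            raw = zlib.decompress(raw)
        except zlib.error as e:
            raise ParseError(f"spectrum {index}: zlib inflate of binary array failed: {e}") from None
    elif _ACC_NOCOMP not in params and raw:
        # absent compression term: treat as uncompressed (tolerated, logged)
        log.debug("spectrum %d: binary array lacks a compression CV term", index)
    if len(raw) % dtype.itemsize:
        raise ParseError(
            f"spectrum {index}: binary array length {len(raw)} not a multiple of {dtype.itemsize}"
        )
    return kind, np.frombuffer(raw, dtype=dtype).astype(np.float64)


def _parse_spectrum(element, index: int) -> Spectrum:
    params = _cv_params(element)
    if _ACC_MS_LEVEL not in params:
        raise InvalidInputError(f"spectrum {index}: no MS level CV term")
    level = int(params[_ACC_MS_LEVEL]["value"])
    if level not in (1, 2):
        raise UnsupportedFeatureError(
            f"spectrum {index}: MS level {level} outside the supported 1-2"
        )
    rt = None
    scan_list = element.find(_NS + "scanList")
    if scan_list is not None:
        for scan in scan_list.findall(_NS + "scan"):
            p = _cv_params(scan)
            if _ACC_SCAN_START in p:
                rt = float(p[_ACC_SCAN_START]["value"])
                if (p[_ACC_SCAN_START]["unit"] or "") in _MINUTE_UNITS:
                    rt *= 60.0
                break
    if rt is None:
        raise InvalidInputError(f"spectrum {index}: no scan start time")
    window = None
    if level == 2:
        prec = element.find(f"{_NS}precursorList/{_NS}precursor")
        if prec is not None:
            iso = prec.find(_NS + "isolationWindow")
            p = _cv_params(iso) if iso is not None else {}
            if _ACC_ISO_TARGET in p:
                target = float(p[_ACC_ISO_TARGET]["value"])
                lower = float(p.get(_ACC_ISO_LOWER, {"value": 0.0})["value"])
                upper = float(p.get(_ACC_ISO_UPPER, {"value": 0.0})["value"])
                window = (target - lower, target + upper)
            else:
                sel = prec.find(f"{_NS}selectedIonList/{_NS}selectedIon")
                ps = _cv_params(sel) if sel is not None else {}
                if _ACC_SELECTED_MZ in ps:
                    target = float(ps[_ACC_SELECTED_MZ]["value"])
                    window = (target - 0.5, target + 0.5)
        if window is None:
            raise InvalidInputError(
                f"spectrum {index}: MS2 spectrum without precursor information"
            )
    arrays: dict[str, np.ndarray] = {}
    for bda in element.findall(f"{_NS}binaryDataArrayList/{_NS}binaryDataArray"):
        kind, values = _decode_binary_array(bda, index)
        if kind in ("mz", "intensity"):
            arrays[kind] = values
    if "mz" not in arrays:
        raise InvalidInputError(f"spectrum {index}: missing m/z array")
    if "intensity" not in arrays:
        raise InvalidInputError(f"spectrum {index}: missing intensity array")
    if arrays["mz"].size != arrays["intensity"].size:
        raise InvalidInputError(
            f"spectrum {index}: m/z and intensity arrays differ in length"
        )
    mz, intensity = sort_spectrum(arrays["mz"], arrays["intensity"])
    return Spectrum(
        rt=rt, ms_level=level, mz=mz, intensity=intensity, precursor_window=window
    )


def read_mzml(path: str) -> tuple[list[Spectrum], dict]:
    """Parse an mzML file into acquisition-ordered spectra plus provenance."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    spectra: list[Spectrum] = []
    try:
        context = etree.iterparse(path, events=("end",), tag=_NS + "spectrum")
        for _, element in context:
            spectra.append(_parse_spectrum(element, len(spectra)))
            element.clear(keep_tail=True)
    except etree.XMLSyntaxError as e:
        raise ParseError(f"malformed mzML: {e}") from None
    source = {"path": os.path.basename(path), "n_spectra": len(spectra)}
    return spectra, source


# ---------------------------------------------------------------- mode detection

def detect_mode(spectra) -> str:
    """Classify a run as DIA (fixed cycling window set) or DDA.

    DIA requires a small set of distinct isolation windows, each observed at
    least three times, repeating cyclically; everything else (including
    MS1-only runs) is treated as DDA.
    """
    windows = [
        round_window(s.precursor_window) for s in spectra if s.ms_level == 2
    ]
    if not windows:
        log.info("no MS2 spectra; defaulting to a DDA plan with no MS2 blocks")
        return "DDA"
    counts = Counter(windows)
    distinct = list(OrderedDict.fromkeys(windows))
    u = len(distinct)
    if u > 64 or min(counts.values()) < 3:
        log.info("detect_mode: %d distinct windows, min repeat %d -> DDA",
                 u, min(counts.values()))
        return "DDA"
    cyclic = all(w == distinct[i % u] for i, w in enumerate(windows))
    log.info("detect_mode: %d windows, cyclic=%s -> %s", u, cyclic,
             "DIA" if cyclic else "DDA")
    return "DIA" if cyclic else "DDA"


# ---------------------------------------------------------------- block planning

@dataclass
class PlannedBlock:
    """Spectra (by global id) routed to one output block, split into stacks."""

    ms_level: int
    layer_exponent: int
    stack_ids: list[list[int]]
    precursor_window: tuple[float, float] | None = None
    stacked: bool = True


def _chunk(ids: list[int], size: int) -> list[list[int]]:
    return [ids[i : i + size] for i in range(0, len(ids), size)]


def organize_blocks(
    spectra, mode: str, n: int = DEFAULT_LAYER_EXPONENT
) -> list[PlannedBlock]:
    """Partition acquisition-ordered spectra into the block/stack layout.

    Global ids are 0-based positions in the input (acquisition) order; every
    spectrum lands in exactly one stack of exactly one block.
    """
    ms1_ids = [i for i, s in enumerate(spectra) if s.ms_level == 1]
    ms2_ids = [i for i, s in enumerate(spectra) if s.ms_level == 2]
    missing = [i for i in ms2_ids if spectra[i].precursor_window is None]
    if missing:
        raise InvalidInputError(
            f"MS2 spectra without precursor information: ids {missing}"
        )
    ms1_ids.sort(key=lambda i: spectra[i].rt)
    blocks = [
        PlannedBlock(ms_level=1, layer_exponent=n, stack_ids=_chunk(ms1_ids, 1 << n))
    ]
    if mode == "DIA":
        groups: dict[tuple, list[int]] = {}
        for i in ms2_ids:
            groups.setdefault(round_window(spectra[i].precursor_window), []).append(i)
        for w in sorted(groups):
            ids = sorted(groups[w], key=lambda i: spectra[i].rt)
            blocks.append(
                PlannedBlock(
                    ms_level=2,
                    layer_exponent=n,
                    stack_ids=_chunk(ids, 1 << n),
                    precursor_window=w,
                )
            )
    else:  # DDA: group under the most recent preceding MS1 scan, unstacked
        groups2: dict[int, list[int]] = {}
        last_ms1 = -1
        for i, s in enumerate(spectra):
            if s.ms_level == 1:
                last_ms1 = i
            else:
                groups2.setdefault(last_ms1, []).append(i)
        for trigger in sorted(groups2):
            ids = groups2[trigger]
            blocks.append(
                PlannedBlock(
                    ms_level=2,
                    layer_exponent=0,
                    stack_ids=[[i] for i in ids],
                    stacked=False,
                )
            )
    return blocks


# ---------------------------------------------------------------- conversion

def encode_planned_blocks(
    spectra,
    planned: list[PlannedBlock],
    cfg: PrecisionConfig,
    intensity_width: int = 32,
) -> list[Block]:
    """Encode every planned stack; returns container-ready blocks."""
    out = []
    for pb in planned:
        blk = Block(
            ms_level=pb.ms_level,
            layer_exponent=pb.layer_exponent,
            precursor_window=pb.precursor_window,
        )
        for ids in pb.stack_ids:
            members = [spectra[i] for i in ids]
            es = encode_stack(
                members, cfg, n=pb.layer_exponent, intensity_width=intensity_width
            )
            blk.stacks.append(
                StackEntry(
                    encoded=es,
                    rts=[s.rt for s in members],
                    spectrum_ids=list(ids),
                    precursor_window=(
                        members[0].precursor_window
                        if pb.ms_level == 2 and pb.precursor_window is None
                        else None
                    ),
                )
            )
        out.append(blk)
    return out


def convert(
    mzml_path: str,
    out_stem: str,
    cfg: PrecisionConfig | None = None,
    n: int = DEFAULT_LAYER_EXPONENT,
    intensity_width: int = 32,
    mode: str | None = None,
) -> dict:
    """Full pipeline: mzML -> blocks -> encoded stacks -> mini-Aird file pair.

    Returns a conversion report: input/output byte counts, per-block segment
    byte shares, and reduction ratios against the raw in-memory array bytes.
    """
    cfg = cfg or PrecisionConfig()
    spectra, source = read_mzml(mzml_path)
    if mode is None:
        mode = detect_mode(spectra)
    planned = organize_blocks(spectra, mode, n)
    blocks = encode_planned_blocks(spectra, planned, cfg, intensity_width)
    json_path, bin_path = write_run(
        blocks, out_stem, cfg, mode, source=dict(source, layer_exponent=n)
    )
    n_peaks = int(sum(len(s) for s in spectra))
    report = {
        "mode": mode,
        "n_spectra": len(spectra),
        "n_peaks": n_peaks,
        "mzml_bytes": os.path.getsize(mzml_path),
        "raw_array_bytes": n_peaks * (8 + intensity_width // 8),
        "json_bytes": os.path.getsize(json_path),
        "bin_bytes": os.path.getsize(bin_path),
        "blocks": [],
        "json_path": json_path,
        "bin_path": bin_path,
    }
    for bi, blk in enumerate(blocks):
        report["blocks"].append(
            {
                "block_id": bi,
                "ms_level": blk.ms_level,
                "mz_bytes": sum(len(s.encoded.mz_payload) for s in blk.stacks),
                "tag_bytes": sum(len(s.encoded.tag_payload) for s in blk.stacks),
                "intensity_bytes": sum(
                    len(s.encoded.intensity_payload) for s in blk.stacks
                ),
                "n_stacks": len(blk.stacks),
            }
        )
    total = report["json_bytes"] + report["bin_bytes"]
    report["total_bytes"] = total
    raw = report["raw_array_bytes"]
    report["reduction_vs_raw_pct"] = (
        100.0 * (raw - total) / raw if raw else 0.0
    )
    report["reduction_vs_mzml_pct"] = (
        100.0 * (report["mzml_bytes"] - total) / report["mzml_bytes"]
        if report["mzml_bytes"]
        else 0.0
    )
    return report
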