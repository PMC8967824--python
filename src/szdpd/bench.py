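"""Desk-scale benchmarks: layer-count sweep and compression decomposition.

``layer_sweep`` encodes one homogeneous block of spectra at several layer
exponents n and reports the byte split between the merged m/z payload, the
tag stream and the intensities — the curve that shows stacking pays until
tag entropy outgrows the m/z savings.  Every size is verified by a full
decode round trip first; configurations that fail to round-trip are flagged
and their sizes withheld.

``compression_report`` compares, on one run, the raw in-memory array bytes
against three encodings: plain zlib of the arrays, the single-spectrum codec
(n = 0), and the stacked codec as stored on disk.  Ratios follow
``(raw - encoded) / raw * 100``.  Wall-clock encode/decode times are logged
but deliberately never asserted anywhere — they are hardware facts, not
codec properties.
"""

from __future__ import annotations

import io
import csv
import logging
import time
import zlib
from dataclasses import dataclass, asdict

import numpy as np

from .container import Block, StackEntry, _read_segments, read_metadata
from .converter import encode_planned_blocks, organize_blocks
from .errors import SzdpdError
from .intcodec import ZLIB_LEVEL
from .quantization import PrecisionConfig, quantize_mz
from .stack_codec import EncodedStack, decode_stack, encode_stack

__all__ = ["SweepRow", "layer_sweep", "compression_report", "rows_to_csv"]

log = logging.getLogger(__name__)


@dataclass
class SweepRow:
    n: int
    mz_bytes: int
    tag_bytes: int
    intensity_bytes: int
    total_bytes: int
    ratio_vs_raw: float
    ratio_vs_n0: float
    encode_ok: bool
    decode_ok: bool


def _stack_sizes(stacks) -> tuple[int, int, int]:
    return (
        sum(len(s.mz_payload) for s in stacks),
        sum(len(s.tag_payload) for s in stacks),
        sum(len(s.intensity_payload) for s in stacks),
    )


def _roundtrip_ok(spectra, stacks, cfg: PrecisionConfig) -> bool:
    pos = 0
    for es in stacks:
        decoded = decode_stack(es, cfg, ms_level=1)
        for orig, dec in zip(spectra[pos : pos + es.spectrum_count], decoded):
            if not np.array_equal(quantize_mz(orig.mz, cfg), quantize_mz(dec.mz, cfg)):
                return False
            stored = orig.intensity.astype(np.float32).astype(np.float64)
            if not np.array_equal(stored, dec.intensity):
                return False
        pos += es.spectrum_count
    return True


def layer_sweep(block, cfg: PrecisionConfig, n_values) -> list[SweepRow]:
    """Encode ``block`` at each layer exponent; one verified row per n.

    The block must be homogeneous (one MS level, one window).  Raw bytes are
    counted as stored: 8 bytes per m/z plus 4 per (32-bit) intensity.
    """
    spectra = list(block)
    n_peaks = sum(len(s) for s in spectra)
    raw_bytes = n_peaks * 12

    def encode_at(n: int):
        stacks = []
        for i in range(0, len(spectra), 1 << n):
            stacks.append(encode_stack(spectra[i : i + (1 << n)], cfg, n=n))
        return stacks

    base_stacks = encode_at(0)
    base_total = sum(_stack_sizes(base_stacks))
    rows = []
    for n in sorted(set(int(v) for v in n_values)):
        try:
            t0 = time.perf_counter()
            stacks = encode_at(n) if n else base_stacks
            t1 = time.perf_counter()
            ok = _roundtrip_ok(spectra, stacks, cfg)
            t2 = time.perf_counter()
            log.info("n=%d encode %.3fs decode+verify %.3fs", n, t1 - t0, t2 - t1)
        except SzdpdError as e:
            log.warning("layer sweep failed at n=%d: %s", n, e)
            rows.append(SweepRow(n, 0, 0, 0, 0, float("nan"), float("nan"), False, False))
            continue
        if not ok:
            rows.append(SweepRow(n, 0, 0, 0, 0, float("nan"), float("nan"), True, False))
            continue
        mz_b, tag_b, int_b = _stack_sizes(stacks)
        total = mz_b + tag_b + int_b
        rows.append(
            SweepRow(
                n=n,
                mz_bytes=mz_b,
                tag_bytes=tag_b,
                intensity_bytes=int_b,
                total_bytes=total,
                ratio_vs_raw=total / raw_bytes if raw_bytes else float("nan"),
                ratio_vs_n0=total / base_total if base_total else float("nan"),
                encode_ok=True,
                decode_ok=True,
            )
        )
    return rows


def rows_to_csv(rows: list[SweepRow]) -> str:
    buf = io.StringIO()
    writer = csv.DictWriter(buf, fieldnames=list(asdict(rows[0]).keys()))
    writer.writeheader()
    for r in rows:
        writer.writerow(asdict(r))
    return buf.getvalue()


# ---------------------------------------------------------------- report

def _report_from_blocks(blocks, cfg: PrecisionConfig) -> dict:
    """Raw / zlib-only / unstacked / stacked byte totals for encoded blocks.

    All baselines are computed from the *stored* representation (quantized
    m/z, narrowed intensity) so a report regenerated from the files matches
    a report taken at conversion time byte for byte.
    """
    raw = zlib_only = zdpd = szdpd = 0
    n_spectra = n_peaks = 0
    for blk in blocks:
        for si, entry in enumerate(blk.stacks):
            es = entry.encoded
            szdpd += len(es.mz_payload) + len(es.tag_payload) + len(es.intensity_payload)
            decoded = decode_stack(
                es,
                cfg,
                rts=entry.rts,
                ms_level=blk.ms_level,
                precursor_window=entry.precursor_window or blk.precursor_window,
            )
            width_bytes = es.intensity_width // 8
            for sp in decoded:
                n_spectra += 1
                n_peaks += len(sp)
                raw += len(sp) * (8 + width_bytes)
                dtype = "<f4" if es.intensity_width == 32 else "<f8"
                zlib_only += len(zlib.compress(sp.mz.astype("<f8").tobytes(), ZLIB_LEVEL))
                zlib_only += len(
                    zlib.compress(sp.intensity.astype(dtype).tobytes(), ZLIB_LEVEL)
                )
                single = encode_stack([sp], cfg, n=0, intensity_width=es.intensity_width)
                zdpd += (
                    len(single.mz_payload)
                    + len(single.tag_payload)
                    + len(single.intensity_payload)
                )
    def ratio(x):
        return 100.0 * (raw - x) / raw if raw else 0.0

    return {
        "n_spectra": n_spectra,
        "n_peaks": n_peaks,
        "raw_array_bytes": raw,
        "zlib_only_bytes": zlib_only,
        "zdpd_bytes": zdpd,
        "szdpd_bytes": szdpd,
        "ratio_zlib_only_pct": ratio(zlib_only),
        "ratio_zdpd_pct": ratio(zdpd),
        "ratio_szdpd_pct": ratio(szdpd),
    }


def compression_report(json_path: str) -> dict:
    """Regenerate the byte decomposition from a mini-Aird file pair alone."""
    meta = read_metadata(json_path)
    blocks = []
    for b in meta.blocks:
        blk = Block(
            ms_level=b["ms_level"],
            layer_exponent=b["layer_exponent"],
            precursor_window=tuple(b["precursor_window"]) if b.get("precursor_window") else None,
        )
        for si, s in enumerate(b["stacks"]):
            mz_seg, tag_seg, int_seg = _read_segments(meta, s)
            blk.stacks.append(
                StackEntry(
                    encoded=EncodedStack(
                        layer_exponent=s["layer_exponent"],
                        spectrum_count=s["spectrum_count"],
                        peaks_per_layer=list(s["peaks_per_layer"]),
                        mz_payload=mz_seg,
                        tag_payload=tag_seg,
                        intensity_payload=int_seg,
                        intensity_width=s.get("intensity_width", 32),
                    ),
                    rts=s["rt"],
                    spectrum_ids=s["spectrum_ids"],
                    precursor_window=tuple(s["precursor_window"])
                    if s.get("precursor_window")
                    else None,
                )
            )
        blocks.append(blk)
    return _report_from_blocks(blocks, meta.precision)


def compression_report_from_spectra(
    spectra,
    cfg: PrecisionConfig,
    mode: str,
    n: int = 8,
    intensity_width: int = 32,
) -> dict:
    """Same decomposition computed in memory, before or without writing files."""
    planned = organize_blocks(spectra, mode, n)
    blocks = encode_planned_blocks(spectra, planned, cfg, intensity_width)
    return _report_from_blocks(blocks, cfg)
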