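"""Seeded generator of TOF-like synthetic runs and minimal mzML fixtures.

The stacked codec pays off when adjacent spectra share many near-identical
centroids — the signature of time-of-flight instruments cycling quickly over
a stable ion population.  The generator models exactly that: a fixed table of
``base_peak_count`` centroid positions per block, each present in a given
scan with probability ``presence_probability`` and jittered by a small
Gaussian (``mz_jitter_sd``), plus a Poisson number of uniform decoy peaks
that create tag-stream entropy.  Intensities are log-normal.  Everything is
keyed off one seed: per-scan substreams are derived from (seed, scan index),
so the same configuration always yields the same run, bit for bit.

The mzML writer emits a deliberately small dialect of mzML 1.1 — centroid
spectra, 32/64-bit float arrays, zlib or no compression — sufficient for
the package's own reader and for external mzML tooling.
"""

from __future__ import annotations

import base64
import json
import zlib
from dataclasses import dataclass, asdict

import numpy as np

from .errors import ConfigError
from .quantization import sort_spectrum
from .stack_codec import Spectrum

__all__ = ["GeneratorConfig", "generate_run", "write_mzml_fixture"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic acquisition.

    Defaults describe a small DIA (SWATH-style) run: 256 cycles over four
    isolation windows, ~500 peaks per spectrum (450 shared base peaks plus
    ~50 decoys), 0.2 mDa centroid jitter — the high-similarity regime the
    stacked codec targets.
    """

    mode: str = "DIA"
    n_ms1_spectra: int = 256
    mz_range: tuple[float, float] = (400.0, 1200.0)
    base_peak_count: int = 500
    presence_probability: float = 0.9
    mz_jitter_sd: float = 2e-4
    extra_peak_rate: float = 50.0
    intensity_ln_mean: float = 6.0
    intensity_ln_sd: float = 1.5
    cycle_time: float = 1.0
    dia_window_count: int = 4
    dda_top_n: int = 5
    fragment_mz_low: float = 100.0
    seed: int = 42

    def validate(self) -> None:
        if self.mode not in ("DDA", "DIA"):
            raise ConfigError(f"mode must be DDA or DIA, got {self.mode!r}")
        if not 0.0 <= self.presence_probability <= 1.0:
            raise ConfigError(
                f"presence_probability must lie in [0, 1], got {self.presence_probability}"
            )
        if self.mz_range[0] >= self.mz_range[1] or self.mz_range[0] < 0:
            raise ConfigError(f"degenerate mz_range {self.mz_range}")
        if self.n_ms1_spectra < 0 or self.base_peak_count < 0:
            raise ConfigError("spectrum and peak counts must be non-negative")
        if self.extra_peak_rate < 0 or self.mz_jitter_sd < 0:
            raise ConfigError("rates and standard deviations must be non-negative")
        if self.mode == "DIA" and self.dia_window_count < 1:
            raise ConfigError("DIA needs at least one isolation window")
        if self.mode == "DDA" and self.dda_top_n < 0:
            raise ConfigError("dda_top_n must be non-negative")


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _base_table(cfg: GeneratorConfig, table_id: int, low: float, high: float) -> np.ndarray:
    rng = _rng(cfg.seed, 0, table_id)
    return np.sort(rng.uniform(low, high, cfg.base_peak_count))


def _draw_spectrum(
    cfg: GeneratorConfig,
    scan_index: int,
    base: np.ndarray,
    low: float,
    high: float,
) -> tuple[np.ndarray, np.ndarray]:
    rng = _rng(cfg.seed, 1, scan_index)
    present = rng.random(base.size) < cfg.presence_probability
    mz = base[present] + rng.normal(0.0, cfg.mz_jitter_sd, int(present.sum()))
    n_extra = rng.poisson(cfg.extra_peak_rate)
    extras = rng.uniform(low, high, n_extra)
    mz = np.clip(np.concatenate([mz, extras]), 0.0, None)
    intensity = rng.lognormal(cfg.intensity_ln_mean, cfg.intensity_ln_sd, mz.size)
    return sort_spectrum(mz, intensity)


def generate_run(cfg: GeneratorConfig) -> tuple[list[Spectrum], dict]:
    """Produce (acquisition-ordered spectra, ground-truth record)."""
    cfg.validate()
    low, high = cfg.mz_range
    ms1_base = _base_table(cfg, 0, low, high)
    spectra: list[Spectrum] = []
    truth: dict = {
        "mode": cfg.mode,
        "config": asdict(cfg),
        "base_mz": [float(x) for x in ms1_base],
        "windows": [],
    }
    if cfg.mode == "DIA":
        span = (high - low) / cfg.dia_window_count
        windows = [
            (round(low + j * span, 4), round(low + (j + 1) * span, 4))
            for j in range(cfg.dia_window_count)
        ]
        truth["windows"] = [list(w) for w in windows]
        frag_bases = {
            j: _base_table(cfg, 1 + j, cfg.fragment_mz_low, high)
            for j in range(cfg.dia_window_count)
        }
        scans_per_cycle = 1 + cfg.dia_window_count
        scan = 0
        for cycle in range(cfg.n_ms1_spectra):
            rt = scan * cfg.cycle_time / scans_per_cycle
            mz, inten = _draw_spectrum(cfg, scan, ms1_base, low, high)
            spectra.append(Spectrum(rt=rt, ms_level=1, mz=mz, intensity=inten))
            scan += 1
            for j, w in enumerate(windows):
                rt = scan * cfg.cycle_time / scans_per_cycle
                mz, inten = _draw_spectrum(
                    cfg, scan, frag_bases[j], cfg.fragment_mz_low, high
                )
                spectra.append(
                    Spectrum(
                        rt=rt, ms_level=2, mz=mz, intensity=inten, precursor_window=w
                    )
                )
                scan += 1
    else:  # DDA: per cycle, top-N precursors chosen anew -> unique window sets
        frag_cache: dict[int, np.ndarray] = {}
        scans_per_cycle = 1 + cfg.dda_top_n
        scan = 0
        for cycle in range(cfg.n_ms1_spectra):
            rt = scan * cfg.cycle_time / scans_per_cycle
            mz, inten = _draw_spectrum(cfg, scan, ms1_base, low, high)
            spectra.append(Spectrum(rt=rt, ms_level=1, mz=mz, intensity=inten))
            scan += 1
            chooser = _rng(cfg.seed, 2, cycle)
            picks = (
                chooser.choice(ms1_base.size, size=min(cfg.dda_top_n, ms1_base.size), replace=False)
                if ms1_base.size
                else np.empty(0, dtype=np.int64)
            )
            for p in picks:
                precursor = float(ms1_base[p])
                w = (round(precursor - 0.35, 4), round(precursor + 0.35, 4))
                if int(p) not in frag_cache:
                    frag_cache[int(p)] = _base_table(
                        cfg, 1000 + int(p), cfg.fragment_mz_low, high
                    )
                rt = scan * cfg.cycle_time / scans_per_cycle
                mz, inten = _draw_spectrum(
                    cfg, scan, frag_cache[int(p)], cfg.fragment_mz_low, high
                )
                spectra.append(
                    Spectrum(
                        rt=rt, ms_level=2, mz=mz, intensity=inten, precursor_window=w
                    )
                )
                scan += 1
    truth["n_spectra"] = len(spectra)
    return spectra, truth


# ---------------------------------------------------------------- mzML writing

_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
 <cvList count="2">
  <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  <cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>
 </cvList>
 <fileDescription>
  <fileContent>
   <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
  </fileContent>
 </fileDescription>
 <run id="synthetic_run">
  <spectrumList count="{count}">
"""

_MZML_FOOTER = """  </spectrumList>
 </run>
</mzML>
"""


def _binary_array(values: np.ndarray, kind: str, bits: int, compress: bool) -> str:
    dtype = {32: "<f4", 64: "<f8"}[bits]
    raw = np.asarray(values, dtype=dtype).tobytes()
    if compress:
        raw = zlib.compress(raw)
    b64 = base64.b64encode(raw).decode("ascii")
    float_cv = (
        '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
        if bits == 64
        else '<cvParam cvRef="MS" accession="MS:1000521" name="32-bit float" value=""/>'
    )
    comp_cv = (
        '<cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>'
        if compress
        else '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
    )
    kind_cv = (
        '<cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>'
        if kind == "mz"
        else '<cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>'
    )
    return (
        f'     <binaryDataArray encodedLength="{len(b64)}">\n'
        f"      {float_cv}\n      {comp_cv}\n      {kind_cv}\n"
        f"      <binary>{b64}</binary>\n"
        f"     </binaryDataArray>\n"
    )


def write_mzml_fixture(
    spectra,
    path: str,
    mz_bits: int = 64,
    intensity_bits: int = 32,
    compress: bool = True,
) -> str:
    """Write spectra as a minimal centroid mzML 1.1 file; returns the path."""
    parts = [_MZML_HEADER.format(count=len(spectra))]
    for i, s in enumerate(spectra):
        parts.append(
            f'   <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{len(s)}">\n'
            f'    <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{s.ms_level}"/>\n'
            f'    <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>\n'
            f'    <scanList count="1">\n     <scan>\n'
            f'      <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{s.rt!r}" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>\n'
            f"     </scan>\n    </scanList>\n"
        )
        if s.ms_level == 2 and s.precursor_window is not None:
            lo, hi = s.precursor_window
            target = 0.5 * (lo + hi)
            parts.append(
                f'    <precursorList count="1">\n     <precursor>\n'
                f"      <isolationWindow>\n"
                f'       <cvParam cvRef="MS" accession="MS:1000827" name="isolation window target m/z" value="{target!r}"/>\n'
                f'       <cvParam cvRef="MS" accession="MS:1000828" name="isolation window lower offset" value="{target - lo!r}"/>\n'
                f'       <cvParam cvRef="MS" accession="MS:1000829" name="isolation window upper offset" value="{hi - target!r}"/>\n'
                f"      </isolationWindow>\n"
                f'      <selectedIonList count="1">\n       <selectedIon>\n'
                f'        <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{target!r}"/>\n'
                f"       </selectedIon>\n      </selectedIonList>\n"
                f"      <activation/>\n     </precursor>\n    </precursorList>\n"
            )
        parts.append('    <binaryDataArrayList count="2">\n')
        parts.append(_binary_array(s.mz, "mz", mz_bits, compress))
        parts.append(_binary_array(s.intensity, "intensity", intensity_bits, compress))
        parts.append("    </binaryDataArrayList>\n   </spectrum>\n")
    parts.append(_MZML_FOOTER)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("".join(parts))
    return path


def write_ground_truth(truth: dict, path: str) -> str:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1)
        fh.write("\n")
    return path
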