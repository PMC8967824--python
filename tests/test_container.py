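"""Container: write/read round trips, random access, XIC oracle equivalence."""

import json

import numpy as np
import pytest

from szdpd.container import (
    Block,
    StackEntry,
    extract_xic,
    iter_spectra,
    read_metadata,
    read_spectrum,
    read_stack,
    write_run,
)
from szdpd.errors import (
    EntityLookupError,
    FormatError,
    InvalidInputError,
    UnsupportedVersionError,
)
from szdpd.quantization import quantize_mz
from szdpd.stack_codec import Spectrum, encode_stack


def build_run(spectra, cfg, n, tmpdir, stem="run", mode="DIA"):
    """Encode MS1 spectra into one block of stacks and write the pair."""
    blk = Block(ms_level=1, layer_exponent=n)
    for i in range(0, len(spectra), 1 << n):
        chunk = spectra[i : i + (1 << n)]
        blk.stacks.append(
            StackEntry(
                encoded=encode_stack(chunk, cfg, n=n),
                rts=[s.rt for s in chunk],
                spectrum_ids=list(range(i, i + len(chunk))),
            )
        )
    return write_run([blk], str(tmpdir / stem), cfg, mode)


@pytest.fixture
def ms1_spectra(rng):
    out = []
    for i in range(40):
        n_peaks = int(rng.integers(0, 100))
        mz = np.sort(rng.uniform(400, 1200, n_peaks))
        out.append(
            Spectrum(rt=float(i), ms_level=1, mz=mz, intensity=rng.lognormal(5, 1, n_peaks))
        )
    return out


class TestWriteRead:
    def test_empty_run(self, tmp_path, cfg5):
        json_path, bin_path = write_run([], str(tmp_path / "empty"), cfg5, "DDA")
        meta = read_metadata(json_path)
        assert meta.blocks == [] and meta.total_spectra == 0
        assert (tmp_path / "empty.mini-aird.bin").stat().st_size == 0
        assert extract_xic(meta, 500.0, 20.0) == []

    def test_full_round_trip(self, tmp_path, cfg5, ms1_spectra):
        json_path, _ = build_run(ms1_spectra, cfg5, 3, tmp_path)
        meta = read_metadata(json_path)
        assert meta.total_spectra == len(ms1_spectra)
        decoded = dict(iter_spectra(meta))
        assert sorted(decoded) == list(range(len(ms1_spectra)))
        for gid, orig in enumerate(ms1_spectra):
            dec = decoded[gid]
            assert np.array_equal(
                quantize_mz(dec.mz, cfg5), quantize_mz(orig.mz, cfg5)
            )
            assert dec.rt == orig.rt and dec.ms_level == 1

    def test_offsets_match_segment_length_sums(self, tmp_path, cfg5, ms1_spectra):
        json_path, bin_path = build_run(ms1_spectra, cfg5, 3, tmp_path)
        doc = json.load(open(json_path))
        running = 0
        for b in doc["blocks"]:
            for s in b["stacks"]:
                assert s["offset"] == running
                running += s["mz_bytes"] + s["tag_bytes"] + s["intensity_bytes"]
        import os

        assert running == os.path.getsize(bin_path)

    def test_byte_determinism(self, tmp_path, cfg5, ms1_spectra):
        j1, b1 = build_run(ms1_spectra, cfg5, 3, tmp_path, stem="a")
        j2, b2 = build_run(ms1_spectra, cfg5, 3, tmp_path, stem="b")
        assert open(b1, "rb").read() == open(b2, "rb").read()
        d1 = open(j1).read().replace('"a.mini-aird.bin"', '"X"')
        d2 = open(j2).read().replace('"b.mini-aird.bin"', '"X"')
        assert d1 == d2

    def test_non_monotone_rt_rejected_at_write(self, tmp_path, cfg5, rng):
        spectra = [
            Spectrum(rt=1.0, ms_level=1, mz=[500.0], intensity=[1.0]),
            Spectrum(rt=0.5, ms_level=1, mz=[500.0], intensity=[1.0]),
        ]
        with pytest.raises(FormatError):
            build_run(spectra, cfg5, 1, tmp_path)


class TestMetadataValidation:
    def _write(self, tmp_path, cfg5, ms1_spectra):
        return build_run(ms1_spectra, cfg5, 3, tmp_path)[0]

    def test_missing_field_named(self, tmp_path, cfg5, ms1_spectra):
        path = self._write(tmp_path, cfg5, ms1_spectra)
        doc = json.load(open(path))
        del doc["precision"]
        bad = tmp_path / "bad.mini-aird.json"
        bad.write_text(json.dumps(doc))
        with pytest.raises(FormatError, match="precision"):
            read_metadata(str(bad))

    def test_version_mismatch_explicit(self, tmp_path, cfg5, ms1_spectra):
        path = self._write(tmp_path, cfg5, ms1_spectra)
        doc = json.load(open(path))
        doc["format_version"] = "mini-aird-99"
        bad = tmp_path / "bad.mini-aird.json"
        bad.write_text(json.dumps(doc))
        with pytest.raises(UnsupportedVersionError):
            read_metadata(str(bad))

    def test_not_json_rejected(self, tmp_path):
        bad = tmp_path / "bad.mini-aird.json"
        bad.write_text("not json at all {")
        with pytest.raises(FormatError):
            read_metadata(str(bad))


class TestRandomAccess:
    def test_every_stack_equals_full_decode_slice(self, tmp_path, cfg5, ms1_spectra):
        json_path, _ = build_run(ms1_spectra, cfg5, 3, tmp_path)
        meta = read_metadata(json_path)
        full = dict(iter_spectra(meta))
        for b in meta.blocks:
            for si, s in enumerate(b["stacks"]):
                got = read_stack(meta, b["block_id"], si)
                for gid, dec in zip(s["spectrum_ids"], got):
                    ref = full[gid]
                    assert np.array_equal(dec.mz, ref.mz)
                    assert np.array_equal(dec.intensity, ref.intensity)

    def test_every_spectrum_reachable_by_id(self, tmp_path, cfg5, ms1_spectra):
        json_path, _ = build_run(ms1_spectra, cfg5, 3, tmp_path)
        meta = read_metadata(json_path)
        for gid, orig in enumerate(ms1_spectra):
            dec = read_spectrum(meta, gid)
            assert len(dec) == len(orig) and dec.rt == orig.rt

    def test_out_of_range_lookups(self, tmp_path, cfg5, ms1_spectra):
        json_path, _ = build_run(ms1_spectra, cfg5, 3, tmp_path)
        meta = read_metadata(json_path)
        with pytest.raises(EntityLookupError):
            read_stack(meta, 0, 999)
        with pytest.raises(EntityLookupError):
            read_stack(meta, 42, 0)
        with pytest.raises(EntityLookupError):
            read_spectrum(meta, -1)
        with pytest.raises(EntityLookupError):
            read_spectrum(meta, len(ms1_spectra))


class TestXic:
    def brute_force_xic(self, meta, mz_center, tol_ppm, ms_level=1, rt_range=None):
        lo = mz_center * (1 - tol_ppm * 1e-6)
        hi = mz_center * (1 + tol_ppm * 1e-6)
        points = []
        for _, sp in iter_spectra(meta):
            if sp.ms_level != ms_level:
                continue
            if rt_range and not (rt_range[0] <= sp.rt <= rt_range[1]):
                continue
            mask = (sp.mz >= lo) & (sp.mz <= hi)
            points.append((sp.rt, float(sp.intensity[mask].sum())))
        points.sort()
        return points

    def test_equals_brute_force_over_random_queries(self, converted_run, rng):
        meta = read_metadata(converted_run["json"])
        base = converted_run["truth"]["base_mz"]
        for _ in range(40):
            center = float(rng.choice(base)) if rng.random() < 0.7 else float(
                rng.uniform(400, 1200)
            )
            tol = float(rng.uniform(5, 200))
            fast = extract_xic(meta, center, tol, ms_level=1)
            slow = self.brute_force_xic(meta, center, tol)
            assert len(fast) == len(slow)
            for (rt_f, i_f), (rt_s, i_s) in zip(fast, slow):
                assert rt_f == rt_s
                assert i_f == pytest.approx(i_s, rel=1e-9, abs=1e-6)

    def test_ms2_window_query_equals_brute_force(self, converted_run):
        meta = read_metadata(converted_run["json"])
        window = tuple(converted_run["truth"]["windows"][0])
        center = 600.0
        fast = extract_xic(meta, center, 50.0, ms_level=2, window=window)
        lo, hi = window
        slow = []
        for _, sp in iter_spectra(meta):
            if sp.ms_level == 2 and sp.precursor_window == window:
                mask = (sp.mz >= center * (1 - 5e-5)) & (sp.mz <= center * (1 + 5e-5))
                slow.append((sp.rt, float(sp.intensity[mask].sum())))
        slow.sort()
        assert len(fast) == len(slow)
        for (rt_f, i_f), (rt_s, i_s) in zip(fast, slow):
            assert rt_f == rt_s and i_f == pytest.approx(i_s, rel=1e-9, abs=1e-6)

    def test_widening_tolerance_never_decreases_points(self, converted_run):
        meta = read_metadata(converted_run["json"])
        center = float(converted_run["truth"]["base_mz"][3])
        narrow = extract_xic(meta, center, 10.0, ms_level=1)
        wide = extract_xic(meta, center, 100.0, ms_level=1)
        for (rt_n, i_n), (rt_w, i_w) in zip(narrow, wide):
            assert rt_n == rt_w and i_w >= i_n

    def test_rt_range_filters_points(self, converted_run):
        meta = read_metadata(converted_run["json"])
        center = float(converted_run["truth"]["base_mz"][3])
        pts = extract_xic(meta, center, 20.0, ms_level=1, rt_range=(5.0, 10.0))
        assert pts and all(5.0 <= rt <= 10.0 for rt, _ in pts)

    def test_dia_ms2_without_window_rejected(self, converted_run):
        meta = read_metadata(converted_run["json"])
        with pytest.raises(InvalidInputError):
            extract_xic(meta, 500.0, 20.0, ms_level=2)

    def test_nonpositive_tolerance_rejected(self, converted_run):
        meta = read_metadata(converted_run["json"])
        with pytest.raises(InvalidInputError):
            extract_xic(meta, 500.0, 0.0)
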