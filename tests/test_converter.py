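"""Converter: mzML subset reading, mode detection, block planning, end-to-end."""

import numpy as np
import pytest

from szdpd.container import read_metadata, iter_spectra
from szdpd.converter import (
    convert,
    detect_mode,
    organize_blocks,
    read_mzml,
)
from szdpd.errors import InvalidInputError, ParseError, UnsupportedFeatureError
from szdpd.quantization import PrecisionConfig
from szdpd.stack_codec import Spectrum
from szdpd.synthetic import GeneratorConfig, generate_run, write_mzml_fixture


class TestReadMzml:
    def test_round_trip_via_fixture(self, tmp_path, small_dia_run):
        spectra, _ = small_dia_run
        path = str(tmp_path / "run.mzML")
        write_mzml_fixture(spectra, path)
        back, source = read_mzml(path)
        assert source["n_spectra"] == len(spectra)
        for a, b in zip(spectra, back):
            assert a.ms_level == b.ms_level
            assert a.rt == pytest.approx(b.rt, abs=1e-9)
            assert np.allclose(a.mz, b.mz, atol=0)
            assert np.allclose(a.intensity, b.intensity, rtol=1e-6)
            if a.ms_level == 2:
                assert b.precursor_window == pytest.approx(a.precursor_window)

    def test_compressed_and_uncompressed_arrays_identical(self, tmp_path, small_dia_run):
        spectra, _ = small_dia_run
        pz = str(tmp_path / "z.mzML")
        pn = str(tmp_path / "n.mzML")
        write_mzml_fixture(spectra, pz, compress=True)
        write_mzml_fixture(spectra, pn, compress=False)
        a, _ = read_mzml(pz)
        b, _ = read_mzml(pn)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.mz, sb.mz)
            assert np.array_equal(sa.intensity, sb.intensity)

    def test_32_bit_mz_decodes_with_float32_fidelity(self, tmp_path, small_dia_run):
        spectra, _ = small_dia_run
        path = str(tmp_path / "f32.mzML")
        write_mzml_fixture(spectra[:3], path, mz_bits=32)
        back, _ = read_mzml(path)
        for a, b in zip(spectra, back):
            assert np.array_equal(np.sort(a.mz.astype(np.float32).astype(np.float64)), b.mz)

    def test_minute_rt_units_converted_to_seconds(self, tmp_path):
        s = Spectrum(rt=120.0, ms_level=1, mz=[500.0], intensity=[1.0])
        path = str(tmp_path / "m.mzML")
        write_mzml_fixture([s], path)
        text = open(path).read().replace(
            'value="120.0" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"',
            'value="2.0" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"',
        )
        open(path, "w").write(text)
        back, _ = read_mzml(path)
        assert back[0].rt == pytest.approx(120.0)

    def test_missing_intensity_array_named(self, tmp_path):
        s = Spectrum(rt=0.0, ms_level=1, mz=[500.0], intensity=[1.0])
        path = str(tmp_path / "broken.mzML")
        write_mzml_fixture([s], path)
        text = open(path).read().replace('accession="MS:1000515"', 'accession="MS:1000999"')
        open(path, "w").write(text)
        with pytest.raises(InvalidInputError, match="intensity"):
            read_mzml(path)

    def test_numpress_rejected_by_name(self, tmp_path):
        s = Spectrum(rt=0.0, ms_level=1, mz=[500.0], intensity=[1.0])
        path = str(tmp_path / "np.mzML")
        write_mzml_fixture([s], path, compress=False)
        text = open(path).read().replace(
            'accession="MS:1000576" name="no compression"',
            'accession="MS:1002312" name="MS-Numpress linear prediction compression"',
            1,
        )
        open(path, "w").write(text)
        with pytest.raises(UnsupportedFeatureError, match="MS:1002312"):
            read_mzml(path)

    def test_malformed_xml_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.mzML"
        path.write_text("<mzML><spectrum oops")
        with pytest.raises(ParseError):
            read_mzml(str(path))

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_mzml(str(tmp_path / "nope.mzML"))


class TestDetectMode:
    def test_synthetic_dia_detected(self, small_dia_run):
        assert detect_mode(small_dia_run[0]) == "DIA"

    def test_synthetic_dda_detected(self):
        spectra, _ = generate_run(
            GeneratorConfig(mode="DDA", n_ms1_spectra=10, base_peak_count=50, seed=5)
        )
        assert detect_mode(spectra) == "DDA"

    def test_ms1_only_run_defaults_to_dda(self):
        spectra = [
            Spectrum(rt=float(i), ms_level=1, mz=[500.0], intensity=[1.0])
            for i in range(5)
        ]
        assert detect_mode(spectra) == "DDA"


class TestOrganizeBlocks:
    def test_600_ms1_spectra_three_stacks(self):
        spectra = [
            Spectrum(rt=float(i), ms_level=1, mz=[500.0], intensity=[1.0])
            for i in range(600)
        ]
        blocks = organize_blocks(spectra, "DDA", n=8)
        assert len(blocks) == 1
        assert [len(ids) for ids in blocks[0].stack_ids] == [256, 256, 88]

    def test_dia_four_windows_five_blocks(self, medium_dia_run):
        spectra, _ = medium_dia_run
        blocks = organize_blocks(spectra, "DIA", n=8)
        assert len(blocks) == 5
        assert blocks[0].ms_level == 1
        assert sorted(b.precursor_window for b in blocks[1:]) == [
            tuple(w) for w in medium_dia_run[1]["windows"]
        ]

    def test_every_spectrum_placed_exactly_once(self, medium_dia_run):
        spectra, _ = medium_dia_run
        blocks = organize_blocks(spectra, "DIA", n=4)
        placed = [i for b in blocks for ids in b.stack_ids for i in ids]
        assert sorted(placed) == list(range(len(spectra)))

    def test_dda_ms2_groups_unstacked_under_trigger(self):
        spectra, _ = generate_run(
            GeneratorConfig(mode="DDA", n_ms1_spectra=6, base_peak_count=50, seed=5)
        )
        blocks = organize_blocks(spectra, "DDA", n=8)
        ms2_blocks = [b for b in blocks if b.ms_level == 2]
        assert len(ms2_blocks) == 6  # one per triggering MS1 scan
        for b in ms2_blocks:
            assert b.layer_exponent == 0 and not b.stacked
            assert all(len(ids) == 1 for ids in b.stack_ids)

    def test_ms2_without_precursor_lists_ids(self):
        good = Spectrum(rt=0.0, ms_level=1, mz=[500.0], intensity=[1.0])
        blocks_input = [good]
        # bypass Spectrum validation to simulate a reader bug upstream
        bad = Spectrum(rt=1.0, ms_level=2, mz=[500.0], intensity=[1.0], precursor_window=(1, 2))
        bad.precursor_window = None
        blocks_input.append(bad)
        with pytest.raises(InvalidInputError, match=r"\[1\]"):
            organize_blocks(blocks_input, "DIA", n=2)


class TestConvert:
    def test_end_to_end_identity_within_quantization(self, converted_run, cfg5):
        meta = read_metadata(converted_run["json"])
        spectra = converted_run["spectra"]
        decoded = dict(iter_spectra(meta))
        assert len(decoded) == len(spectra)
        for gid, orig in enumerate(spectra):
            dec = decoded[gid]
            assert dec.ms_level == orig.ms_level
            assert dec.rt == pytest.approx(orig.rt, abs=1e-9)
            assert np.max(np.abs(dec.mz - orig.mz), initial=0.0) <= 0.5e-5 + 1e-11
            assert np.array_equal(
                dec.intensity,
                orig.intensity.astype(np.float32).astype(np.float64),
            )

    def test_report_segments_sum_to_binary_size(self, converted_run):
        import os

        rep = converted_run["report"]
        seg_sum = sum(
            b["mz_bytes"] + b["tag_bytes"] + b["intensity_bytes"] for b in rep["blocks"]
        )
        assert seg_sum == os.path.getsize(converted_run["bin"]) == rep["bin_bytes"]

    def test_empty_mzml_gives_valid_empty_run(self, tmp_path):
        path = str(tmp_path / "empty.mzML")
        write_mzml_fixture([], path)
        rep = convert(path, str(tmp_path / "empty"))
        assert rep["n_spectra"] == 0
        meta = read_metadata(rep["json_path"])
        assert meta.total_spectra == 0

    def test_dda_ms2_path_equals_single_spectrum_codec(self, tmp_path, cfg5):
        from szdpd.stack_codec import encode_stack

        spectra, _ = generate_run(
            GeneratorConfig(mode="DDA", n_ms1_spectra=4, base_peak_count=60, seed=9)
        )
        path = str(tmp_path / "dda.mzML")
        write_mzml_fixture(spectra, path)
        rep = convert(path, str(tmp_path / "dda"), cfg=cfg5)
        assert rep["mode"] == "DDA"
        meta = read_metadata(rep["json_path"])
        read_back, _ = read_mzml(path)
        with open(rep["bin_path"], "rb") as fh:
            blob = fh.read()
        for b in meta.blocks:
            if b["ms_level"] != 2:
                continue
            for s in b["stacks"]:
                assert s["layer_exponent"] == 0 and s["spectrum_count"] == 1
                gid = s["spectrum_ids"][0]
                ref = encode_stack([read_back[gid]], cfg5, n=0)
                start = s["offset"]
                assert blob[start : start + s["mz_bytes"]] == ref.mz_payload
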