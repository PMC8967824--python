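import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from szdpd.quantization import PrecisionConfig
from szdpd.synthetic import GeneratorConfig, generate_run

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg5() -> PrecisionConfig:
    return PrecisionConfig(5)


@pytest.fixture(scope="session")
def small_dia_run():
    """8 DIA cycles x 2 windows, ~120 peaks/spectrum: fast but structurally full."""
    cfg = GeneratorConfig(
        mode="DIA",
        n_ms1_spectra=8,
        dia_window_count=2,
        base_peak_count=120,
        extra_peak_rate=10.0,
        seed=7,
    )
    return generate_run(cfg)


@pytest.fixture(scope="session")
def medium_dia_run():
    """32 DIA cycles x 4 windows at default similarity; used for file-level tests."""
    cfg = GeneratorConfig(
        mode="DIA", n_ms1_spectra=32, base_peak_count=200, extra_peak_rate=20.0, seed=11
    )
    return generate_run(cfg)


@pytest.fixture(scope="session")
def converted_run(tmp_path_factory, medium_dia_run):
    """The medium run written to mzML, converted to mini-Aird at n=4."""
    from szdpd.converter import convert
    from szdpd.synthetic import write_mzml_fixture

    spectra, truth = medium_dia_run
    root = tmp_path_factory.mktemp("run")
    mzml = str(root / "run.mzML")
    write_mzml_fixture(spectra, mzml)
    report = convert(mzml, str(root / "run"), n=4)
    return {
        "spectra": spectra,
        "truth": truth,
        "mzml": mzml,
        "report": report,
        "json": report["json_path"],
        "bin": report["bin_path"],
    }


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
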