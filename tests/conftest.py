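import pytest

from cif2smiles.cif import parse_cif
from cif2smiles.fixtures import build_fixture, catalog
from cif2smiles.pipeline import ConversionError, run_entry


@pytest.fixture(scope="session")
def fixture_set():
    """All synthetic fixtures, built once."""
    return {name: build_fixture(name) for name in catalog()}


@pytest.fixture(scope="session")
def entries(fixture_set):
    return {name: parse_cif(fx.cif_text)[0]
            for name, fx in fixture_set.items()}


@pytest.fixture(scope="session")
def pipeline_results(entries, fixture_set):
    """End-to-end conversion of every fixture (errors kept as values)."""
    out = {}
    for name, entry in entries.items():
        try:
            out[name] = run_entry(entry)
        except ConversionError as exc:
            out[name] = exc
    return out
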