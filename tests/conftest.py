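import numpy as np
import pytest

from compilite.simulate import (
    SimulationParams,
    build_from_records,
    generate_proteins,
    simulate_run,
)
from compilite.store import (
    DigestionParams,
    ProteinRecord,
    SQLiteBackend,
    append_decoys,
    build_index,
)


@pytest.fixture
def open_digestion():
    """No length/mass filters, no mods: hand-checkable digestion."""
    return DigestionParams(
        max_missed_cleavages=0,
        min_length=1,
        max_length=10_000,
        min_mass=0.0,
        max_mass=1e9,
        static_modifications={},
    )


@pytest.fixture
def mkrpa_index(open_digestion):
    """Index of the single protein MKRPA plus its reversal APRKM."""
    backend = SQLiteBackend()
    records = [ProteinRecord(0, "p1", "MKRPA")]
    build_index(append_decoys(records), open_digestion, backend)
    return backend


@pytest.fixture(scope="session")
def small_search_setup():
    """50-protein proteome, clean 100-scan run, built index; shared by
    the scoring tests that only read from it."""
    params = SimulationParams(
        seed=42, n_proteins=50, n_spectra=100,
        noise_peaks=0, peak_dropout=0.0, mass_jitter_ppm=0.0,
    )
    records = generate_proteins(params)
    backend = build_from_records(records)
    spectra, truth = simulate_run(records, params)
    return records, backend, spectra, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
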