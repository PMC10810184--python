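import numpy as np
import pytest

from dbrmeta import (
    Dataset,
    Label,
    ProteinRecord,
    SimConfig,
    Source,
    generate_dataset,
    simulate_tracks,
    DEFAULT_TRACKS,
)


def labels_from_string(s: str) -> np.ndarray:
    """'..DO.' -> labels with D=DNA, O=OTHER, .=NONE."""
    table = {".": Label.NONE, "O": Label.OTHER, "D": Label.DNA}
    return np.array([table[c] for c in s], dtype=np.int8)


@pytest.fixture
def toy_dataset() -> Dataset:
    """Four tiny proteins covering both classes and both sources."""
    ds = Dataset()
    specs = [
        ("d_s", "MKVLANREWQ", "..DD...O..", Source.STRUCTURE),
        ("d_d", "ACDEFGHIKL", "D....OO...", Source.DISORDER),
        ("o_s", "PQRSTVWYAC", "...OO.....", Source.STRUCTURE),
        ("o_d", "GHIKLMNPQR", "O........O", Source.DISORDER),
    ]
    for pid, seq, lab, src in specs:
        ds.add_protein(ProteinRecord(pid, seq, labels_from_string(lab), src))
    return ds


@pytest.fixture(scope="session")
def medium_dataset() -> Dataset:
    """Mid-sized labeled dataset with binormal tracks, reused across tests."""
    config = SimConfig(
        n_dna_proteins=30, n_other_proteins=60, length_median=120,
        length_sigma=0.3, seed=7,
    )
    ds = generate_dataset(config)
    simulate_tracks(ds, list(DEFAULT_TRACKS), seed=8)
    return ds
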