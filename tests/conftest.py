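import numpy as np
import pytest

from indelbarcode import (
    GenotypeMatrix,
    GenotypeProfile,
    SelectionConfig,
    SyntheticPanelConfig,
    generate_panel,
)


def make_profile(accession_id, calls):
    return GenotypeProfile(accession_id, tuple(calls))


def make_matrix(rows, marker_ids=None, reference_id=None):
    """rows: dict accession -> call string, e.g. {'x': 'aab'}"""
    n = len(next(iter(rows.values())))
    if marker_ids is None:
        marker_ids = [f"TB{i + 1}" for i in range(n)]
    profiles = [make_profile(a, calls) for a, calls in rows.items()]
    return GenotypeMatrix(list(marker_ids), profiles, reference_id)


@pytest.fixture(scope="session")
def small_panel():
    """Compact synthetic bundle shared by read-only tests."""
    cfg = SyntheticPanelConfig(
        n_accessions=15, n_markers=8, n_decoy_variants=60, rng_seed=42
    )
    return generate_panel(cfg)


@pytest.fixture(scope="session")
def default_cfg():
    return SelectionConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
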