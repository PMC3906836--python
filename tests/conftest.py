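import numpy as np
import pytest

from orthoprimer import Alignment, load_study_tables
from orthoprimer.synthetic import SimConfig


@pytest.fixture(scope="session")
def tables():
    return load_study_tables()


@pytest.fixture
def rng():
    return np.random.default_rng(20130715)


@pytest.fixture
def tiny_dna_alignment():
    return Alignment(
        names=["a", "b", "c", "d"],
        rows=["ACGTACGT", "ACGTACGT", "ACGAACGT", "ACGTACTT"],
        kind="dna",
    )


@pytest.fixture(scope="session")
def marker_case():
    """One marker alignment with its planted truth (canonical study config)."""
    from orthoprimer import make_marker_alignment

    cfg = SimConfig(seed=0)
    return make_marker_alignment(cfg), cfg


@pytest.fixture(scope="session")
def strain_case():
    from orthoprimer import make_strain_panel

    return make_strain_panel(SimConfig(seed=0))
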