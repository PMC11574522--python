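import pytest

from burstkit.synthetic import StudyConfig, generate_study

#: frozen seed of the reference synthetic study used across the suite
STUDY_SEED = 11

#: the (a, b, lam) grid over which the two stationary-distribution
#: implementations are required to agree
ORACLE_GRID = [
    (a, b, lam)
    for a in (0.1, 1.0, 10.0)
    for b in (0.1, 1.0, 10.0)
    for lam in (0.1, 1.0, 10.0, 50.0)
]


@pytest.fixture(scope="session")
def default_study():
    """The default-scale two-condition synthetic study (312 genes, 2 x 3000 cells)."""
    return generate_study(StudyConfig(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def tiny_study():
    """A small study for fast I/O and filtering tests."""
    return generate_study(
        StudyConfig(
            seed=5, n_background=10, n_signature=4, n_cells=150, n_mito_genes=3
        )
    )
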