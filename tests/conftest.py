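import pytest

from nanoconj import (
    BindingModelSpec,
    ParticleBatch,
    ProteinSpec,
    SyntheticExperiment,
)


@pytest.fixture
def gold_batch() -> ParticleBatch:
    """The studied colloid: 24 nm gold spheres, 0.05 g/L, 5x enrichment."""
    return ParticleBatch(diameter_nm=24.0)


@pytest.fixture
def bsa() -> ProteinSpec:
    return ProteinSpec("BSA", 66.0)


@pytest.fixture
def igg() -> ProteinSpec:
    return ProteinSpec("IgG", 150.0)


@pytest.fixture
def bsa_experiment(gold_batch, bsa) -> SyntheticExperiment:
    """Default BSA scenario: one-class sites, Kd 6 nM, N 90, 1% CV noise."""
    return SyntheticExperiment(
        model=BindingModelSpec.langmuir(6.0, 90.0),
        particle=gold_batch,
        protein=bsa,
        noise_cv=0.01,
        seed=1,
    )


@pytest.fixture
def noise_free_bsa(bsa_experiment) -> SyntheticExperiment:
    from dataclasses import replace

    return replace(bsa_experiment, noise_cv=0.0)


@pytest.fixture
def igg_two_class(gold_batch, igg) -> SyntheticExperiment:
    """Two site classes at the IgG scale: Kd 4/30 nM, 26+26 sites."""
    return SyntheticExperiment(
        model=BindingModelSpec.two_class(4.0, 26.0, 30.0, 26.0),
        particle=gold_batch,
        protein=igg,
        noise_cv=0.01,
        seed=1,
    )
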