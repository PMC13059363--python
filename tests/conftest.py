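import pytest

from methexp import pipeline
from methexp.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def tiny_study():
    """Small complete study with the default planted-effect layout."""
    cfg = SimulationConfig(seed=7, n_genes=60, chrom_length=120_000)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def null_study():
    """Same scale, zero planted effects: every call downstream is noise."""
    cfg = SimulationConfig(
        seed=11,
        n_genes=60,
        chrom_length=120_000,
        planted_dmr_spec=[],
        planted_deg_spec=[],
        planted_negreg_spec=[],
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def tiny_results(tiny_study):
    """Both phenotype groups run through DMR + DE stages plus integration."""
    res = {
        grp: pipeline.run_group_pipeline(tiny_study, grp)
        for grp in ("sensitive", "tolerant")
    }
    integ = pipeline.run_integration(tiny_study, res)
    return res, integ
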