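import numpy as np
import pytest

from svasm import discovery as disc
from svasm.simdata import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def study():
    """The default synthetic population study (~1,000 planted variants,
    ten trios)."""
    return simulate_study(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_study():
    """A reduced study for fast structural tests."""
    return simulate_study(
        SimulationConfig(
            seed=3,
            chrom_length=150_000,
            trio_count=2,
            n_snp=40,
            n_small_indel=30,
            n_tei_del=5,
            n_tei_ins=5,
            n_vntr=5,
            n_ccc=6,
            n_nahr=3,
            n_nhr=8,
            n_inversion=4,
            n_block_substitution=6,
            n_replacement=6,
        )
    )


@pytest.fixture(scope="session")
def discovered(study):
    """Per-individual discovery plus the merged population call set over
    the full default study."""
    per_ind = {}
    for sample in study.samples:
        blocks = study.alignment_blocks(sample)
        scaffolds = study.scaffold_records(sample)
        variants, segments, gaps = disc.discover_individual(
            blocks, study.reference, scaffolds, sample
        )
        per_ind[sample] = variants
    records = disc.merge_population(per_ind)
    return per_ind, records


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
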