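import numpy as np
import pandas as pd
import pytest

from stratascan.model import Chromosome, GenomeLayout, SampleInfo, ScaffoldPlacement
from stratascan.simulate import (
    PopulationSpec,
    SimSpec,
    StratumSpec,
    default_layout,
)


@pytest.fixture
def tiny_layout() -> GenomeLayout:
    """Two autosomes and a sex chromosome with a handful of scaffolds."""
    return GenomeLayout(
        chromosomes=[
            Chromosome("chr1", 3000),
            Chromosome("chr2", 2000),
            Chromosome("chrX", 4000, is_sex_chromosome=True),
        ],
        scaffolds=[
            ScaffoldPlacement("s1", "chr1", 1, 1000),
            ScaffoldPlacement("s2", "chr1", 1001, 3000),
            ScaffoldPlacement("s3", "chr2", 1, 2000),
            ScaffoldPlacement("sx1", "chrX", 1, 2000),
            ScaffoldPlacement("sx2", "chrX", 2001, 4000),
        ],
    )


@pytest.fixture
def lab_samples() -> list[SampleInfo]:
    return [
        SampleInfo("lab_M1", "male", "lab"),
        SampleInfo("lab_M2", "male", "lab"),
        SampleInfo("lab_F1", "female", "lab"),
        SampleInfo("lab_F2", "female", "lab"),
    ]


def small_spec(seed: int = 0, **overrides) -> SimSpec:
    """A fast spec on the default genome shape: used where statistical
    structure, not scale, is under test."""
    defaults = dict(
        layout=default_layout(n_autosomes=2, scaffold_kb=500.0),
        strata=[
            StratumSpec(22_000_000, 25_000_000, y_loss=0.5, xy_divergence=0.005,
                        name="stratum1"),
            StratumSpec(15_000_000, 22_000_000, y_loss=0.0, xy_divergence=0.005,
                        name="stratum2"),
        ],
        populations=[PopulationSpec("lab"),
                     PopulationSpec("Yarra_up", divergence_multiplier=2.0),
                     PopulationSpec("Yarra_down")],
        sites_per_scaffold=30,
        n_per_sex=2,
    )
    defaults.update(overrides)
    return SimSpec(seed=seed, **defaults)


def make_counts(rows):
    """Site-count frame from (scaffold, pos, sample, A, C, G, T) tuples."""
    return pd.DataFrame(rows, columns=["scaffold", "pos", "sample", "A", "C", "G", "T"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
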