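import numpy as np
import pandas as pd
import pytest

from venomkit.pipeline import RunConfig, run_all
from venomkit.simulate import GeneratorConfig, build_reference

SMALL_PROFILE = {"3FTx": 0.6, "CRISP": 0.2, "SVMPIII": 0.15, "CTL": 0.05}
SMALL_COUNTS = {"3FTx": 4, "CRISP": 2, "SVMPIII": 3, "CTL": 2}


def small_generator_config(**overrides) -> GeneratorConfig:
    params = dict(
        seed=11,
        family_profile=dict(SMALL_PROFILE),
        family_counts=dict(SMALL_COUNTS),
        n_nontoxins=20,
        n_individuals=3,
    )
    params.update(overrides)
    return GeneratorConfig(**params)


@pytest.fixture
def small_config() -> GeneratorConfig:
    return small_generator_config()


@pytest.fixture
def small_reference(small_config):
    return build_reference(small_config)


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run under generator defaults, shared by the
    end-to-end acceptance checks (chimera screen operating characteristics
    and truth recovery are read off the same run)."""
    return run_all(RunConfig(generator=GeneratorConfig(seed=20210506)))


def locus_of(contig_id: str) -> str:
    """Map a synthetic contig id back to its truth locus (reference id)."""
    tid = contig_id.split(".", 2)[2].removesuffix(".dup")
    return tid.removesuffix(".a").removesuffix(".b")


def truth_family_proportions(result) -> pd.DataFrame:
    cols = []
    for t in result.truths:
        cols.append((t.tpm.groupby(pd.Series(t.family)).sum() / 1e6).rename(t.individual))
    return pd.concat(cols, axis=1).fillna(0.0)


def estimated_family_proportions(result) -> pd.DataFrame:
    fams = pd.Series(result.consensus_family)
    return result.expression.tpm.groupby(fams).sum() / 1e6
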