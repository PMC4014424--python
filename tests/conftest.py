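"""Shared fixtures: one small synthetic bundle generated once per session."""

from pathlib import Path

import pytest

from nrpeak.synthetic_data import Bundle, SimulationConfig, generate


def small_config(**overrides) -> SimulationConfig:
    cfg = SimulationConfig(
        n_chromosomes=2,
        chromosome_length=1_200_000,
        genes_per_chromosome=12,
        gene_cluster=(60_000, 700_000),
        strata={"D8": 120},
        n_extra_genes=400,
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory) -> Path:
    outdir = tmp_path_factory.mktemp("bundle")
    generate(small_config(), seed=3, outdir=outdir)
    return outdir


@pytest.fixture(scope="session")
def bundle() -> Bundle:
    return generate(small_config(), seed=3)
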