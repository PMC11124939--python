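"""Shared fixtures: small simulated worlds reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from bulkscan import (
    SimulationConfig,
    build_bulks,
    filter_informative,
    simulate_f2,
    simulate_pool_reads,
)


@pytest.fixture(scope="session")
def small_config():
    """Fast single-chromosome world with a strong QTL."""
    return SimulationConfig(
        chrom_length_bp=50_000_000,
        n_markers=1500,
        n_f2=240,
        qtl_position=("chr1", 30_000_000),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_population(small_config):
    return simulate_f2(small_config)


@pytest.fixture(scope="session")
def small_bulks(small_population):
    return build_bulks(small_population)


@pytest.fixture(scope="session")
def small_sites(small_population, small_bulks, small_config):
    return simulate_pool_reads(small_population, small_bulks, small_config)


@pytest.fixture(scope="session")
def small_filtered(small_sites):
    filtered, _ = filter_informative(small_sites)
    return filtered


def make_site(
    chrom="chr1",
    pos=100,
    ref="A",
    alt="T",
    site_type="SNP",
    gp05=(20, 0),
    pp05=(0, 25),
    green=(15, 15),
    purple=(15, 15),
):
    """One hand-constructed variant record."""
    return {
        "chrom": chrom,
        "pos": pos,
        "ref": ref,
        "alt": alt,
        "site_type": site_type,
        "gp05_ref": gp05[0],
        "gp05_alt": gp05[1],
        "pp05_ref": pp05[0],
        "pp05_alt": pp05[1],
        "green_ref": green[0],
        "green_alt": green[1],
        "purple_ref": purple[0],
        "purple_alt": purple[1],
    }


@pytest.fixture
def site_builder():
    return make_site


def sites_frame(rows):
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(20240516)
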