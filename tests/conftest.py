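"""Shared fixtures: simulated plates reused across the suite.

Session scope keeps the expensive simulate → QC → normalize → cluster chain
to one execution; tests must not mutate these objects.
"""

import warnings

import pytest

from scplate import (
    compute_size_factors,
    default_config,
    normalize_counts,
    simulate_experiment,
)
from scplate.cluster import cluster_cells
from scplate.qc import run_qc


@pytest.fixture(scope="session")
def immune():
    """Standard 7-type immune fixture: three 384-well plates.

    TCR constant genes are left out so the planted types are the only
    population structure (T cells otherwise split into real alpha/beta vs
    gamma/delta subpopulations).
    """
    cfg = default_config(n_plates=3, seed=11, include_tcr=False,
                         n_ambient_genes=30)
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def immune_nx(immune):
    x, truth = immune
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        filtered, report = run_qc(x, n_permutations=100, seed=3)
    sf = compute_size_factors(filtered, method="spike_total")
    return normalize_counts(filtered, sf), truth, report


@pytest.fixture(scope="session")
def immune_clusters(immune_nx):
    nx, truth, _ = immune_nx
    return cluster_cells(nx, seed=5)


@pytest.fixture(scope="session")
def tcr_sim():
    """One plate with TCR constant-region expression planted in T cells."""
    cfg = default_config(n_plates=1, seed=7, include_tcr=True)
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def tcr_nx(tcr_sim):
    x, truth = tcr_sim
    sub = x.subset(well_mask=~x.empty_mask)
    sf = compute_size_factors(sub, method="spike_total")
    return normalize_counts(sub, sf), truth
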