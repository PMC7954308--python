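"""Shared fixtures: genetic codes, small trees, and simulated datasets."""

from dataclasses import replace

import numpy as np
import pytest

from multihit import (
    FitSettings,
    fit_hierarchy,
    load_code,
    run_tests,
    simulate_alignment,
)
from multihit.simulate import uniform_params
from multihit.tree import PhyloTree, random_tree


@pytest.fixture(scope="session")
def universal():
    return load_code(1)


@pytest.fixture(scope="session")
def mito():
    return load_code(2)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240811)


@pytest.fixture(scope="session")
def three_taxon_tree():
    return PhyloTree.from_newick("(A:0.2,B:0.35,C:0.15);")


@pytest.fixture(scope="session")
def rich_params(universal):
    """Generic full-rate parameter set used by matrix/likelihood tests."""
    from multihit import PositionalFrequencies

    return replace(
        uniform_params(
            universal,
            omega=np.array([0.1, 0.6, 1.8]),
            weights=np.array([0.5, 0.3, 0.2]),
            delta=0.3,
            psi_s=2.0,
            psi=0.4,
            theta=np.array([1.2, 1.0, 0.7, 0.9, 2.0, 0.5]),
        ),
        pi=PositionalFrequencies(
            pi=np.array(
                [
                    [0.30, 0.20, 0.30, 0.20],
                    [0.25, 0.25, 0.25, 0.25],
                    [0.10, 0.40, 0.20, 0.30],
                ]
            )
        ),
    )


@pytest.fixture(scope="session")
def small_mh_dataset(universal):
    """8-taxon alignment simulated with real double- and triple-hit rates."""
    rng = np.random.default_rng(1905)
    tree = random_tree(8, rng, total_length=2.5)
    params = replace(
        uniform_params(
            universal,
            omega=np.array([0.2, 1.0]),
            weights=np.array([0.7, 0.3]),
            delta=0.5,
            psi_s=4.0,
            psi=0.5,
        ),
        branch_lengths=tree.branch_lengths(),
    )
    aln, truth = simulate_alignment(params, "3H+", tree, 300, universal, rng)
    return {"aln": aln, "tree": tree, "params": params, "truth": truth}


@pytest.fixture(scope="session")
def hierarchy_fits(small_mh_dataset):
    """Full five-model warm-started ladder on the simulated MH dataset."""
    settings = FitSettings(n_omega_classes=2, maxiter=200)
    fits = fit_hierarchy(
        small_mh_dataset["aln"], small_mh_dataset["tree"], settings=settings
    )
    return fits


@pytest.fixture(scope="session")
def hierarchy_report(hierarchy_fits):
    return run_tests(hierarchy_fits, alpha=0.01)
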