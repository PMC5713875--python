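"""Shared fixtures: the seeded synthetic decoy study set and small helpers.

The default DecoyGenSpec is the reference study condition for the whole
suite (4-helix up-down bundle, 80 core decoys at 0.5 A noise with a 4x
loop/terminal multiplier, 20 shuffled-topology outliers at 5 A noise,
seed 0); it is built once per session because clustering and the ensemble
sweep dominate the suite's runtime.
"""

import numpy as np
import pytest

from helixmr.clustering import cluster_decoys, top_cluster
from helixmr.decoys import DecoyGenSpec, generate_decoy_set, generate_ground_truth
from helixmr.ensembler import generate_ensembles
from helixmr.helices import build_ideal_helix


@pytest.fixture(scope="session")
def study_spec():
    return DecoyGenSpec()


@pytest.fixture(scope="session")
def ground_truth(study_spec):
    return generate_ground_truth(study_spec)


@pytest.fixture(scope="session")
def decoy_set(study_spec):
    return generate_decoy_set(study_spec)


@pytest.fixture(scope="session")
def clusters(decoy_set):
    return cluster_decoys(decoy_set)


@pytest.fixture(scope="session")
def capped_top_cluster(clusters):
    return top_cluster(clusters)


@pytest.fixture(scope="session")
def ensembles(decoy_set, clusters):
    return generate_ensembles(decoy_set, clusters=clusters)


@pytest.fixture()
def helix20():
    return build_ideal_helix(20)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
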