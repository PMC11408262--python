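import numpy as np
import pandas as pd
import pytest

import personet as pn


@pytest.fixture
def tiny_cfg():
    """A seconds-scale synthetic configuration used across unit tests."""
    return pn.SynthConfig(
        n_subjects=30,
        profile_sizes={"creative": 8, "organized": 15, "unregulated": 7},
        n_genes=120, n_responsive=60, n_biclusters=3,
        bicluster_genes=15, bicluster_subjects=10,
        n_regions=6,
        n_personality_genes=30,
        signature_counts={"M1": 4, "M2": 3, "M3": 3, "M4": 8,
                          "M5": 12, "M6": 5, "M7": 6},
        n_pseudogenes=2, n_other_ncrna=2,
        protein_mirna_clusters=(3, 2, 4), n_ppi_partners=3,
        n_personality_in_network=6, n_switch_genes=6,
        n_personality_lncrnas=4, n_lnc_interactions=8,
        n_ext_mirnas=7, n_ext_other_ncrna=2,
        rng_seed=0)


@pytest.fixture
def expression_bundle(tiny_cfg):
    matrix, labels, truth = pn.gen_expression(tiny_cfg)
    return matrix, labels, truth


@pytest.fixture
def interaction_bundle(tiny_cfg):
    interactions, lnc_edges, truth = pn.gen_interactions(tiny_cfg)
    return interactions, lnc_edges, truth


def make_edge_table(rows):
    return pd.DataFrame(rows, columns=["source", "target", "layer"])


@pytest.fixture
def star_interactions():
    """Seed s with three PPI neighbours a, b, c plus one miRNA edge."""
    edges = make_edge_table([
        ("s", "a", "ppi"), ("s", "b", "ppi"), ("s", "c", "ppi"),
        ("m1", "s", "mirna_gene"),
    ])
    return pn.InteractionTable.from_edges(
        edges, node_types={"m1": "mirna", "s": "protein_coding"})


@pytest.fixture
def rng():
    return np.random.default_rng(20240301)
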