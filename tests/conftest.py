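import random

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import coverphylo.simulate as csim
import coverphylo.tree as ctree
from coverphylo.community import CommunityTable

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[
        HealthCheck.too_slow,
        HealthCheck.function_scoped_fixture,
    ],
)
settings.load_profile("ci")


@pytest.fixture
def cherry_tree():
    """((A:1,B:1):1,C:2); — 3-tip ultrametric tree of depth 2."""
    return ctree.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star3_tree():
    return ctree.parse_newick("(A:1,B:1,C:1);")


def random_tree(n_tips: int, seed: int) -> ctree.PhyloTree:
    """Random binary ultrametric tree (Yule), depth 1."""
    return csim.simulate_yule_tree(n_tips, seed=seed)


def random_polytomous_tree(n_tips: int, seed: int) -> ctree.PhyloTree:
    """Random tree with polytomies, made by collapsing internal edges."""
    tree = random_tree(n_tips, seed)
    rng = random.Random(seed + 1)
    dtree = tree.dendropy_tree
    internal = [
        n
        for n in dtree.preorder_internal_node_iter()
        if n is not dtree.seed_node
    ]
    for node in internal:
        if rng.random() < 0.5:
            # contract the edge: children keep their lengths, the removed
            # edge's length is added to them so tip depths are preserved
            parent = node.parent_node
            extra = node.edge.length
            for child in list(node.child_nodes()):
                child.edge.length += extra
                node.remove_child(child)
                parent.add_child(child)
            parent.remove_child(node)
    return ctree.PhyloTree(dtree)


def make_table(rows) -> CommunityTable:
    """CommunityTable from (site, year, block, plot, treatment, taxon, role, biomass) tuples."""
    df = pd.DataFrame(
        rows,
        columns=[
            "site",
            "year",
            "block",
            "plot",
            "treatment",
            "taxon",
            "role",
            "biomass",
        ],
    )
    return CommunityTable(df)


def naive_interspecific_mpd(D, abundances) -> float:
    """Independent double-loop oracle for abundance-weighted interspecific MPD."""
    taxa = [t for t, b in abundances.items() if b > 0]
    total = sum(abundances[t] for t in taxa)
    num = den = 0.0
    for i in taxa:
        for j in taxa:
            if i == j:
                continue
            pi = abundances[i] / total
            pj = abundances[j] / total
            num += pi * pj * D.loc(i, j)
            den += pi * pj
    return num / den


@pytest.fixture
def rng():
    return np.random.default_rng(0)
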