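"""Shared fixtures: tiny hand-built graphs and one mid-size synthetic world.

The "world" fixture bundles a correlated network pair with its preprocessed
cores, landmark set (20% of surviving true correspondences), held-out true
pairs, and the joint embedding — several test modules and the acceptance
suite reuse it, so it is session-scoped.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pytest

from munk import (
    LandmarkList,
    Network,
    joint_embedding,
    preprocess_network,
    to_dissimilarity,
)
from munk.graph_io import HomologPairs
from munk.synthetic import make_network_pair


def net_from_edges(edges, species_tag="test", extra_nodes=()):
    g = nx.Graph()
    g.add_edges_from(edges)
    g.add_nodes_from(extra_nodes)
    return Network(species_tag, g)


@pytest.fixture
def single_edge_net():
    return net_from_edges([("a", "b")])


@pytest.fixture
def triangle_net():
    return net_from_edges([("a", "b"), ("b", "c"), ("c", "a")])


@dataclass
class SyntheticWorld:
    pair: object
    core1: Network
    core2: Network
    true_pairs: list[tuple[str, str]]  # correspondences surviving both cores
    landmarks: LandmarkList
    held_out: list[tuple[str, str]]
    c1: object
    c2hat: object
    scores: object
    dissim: object

    @property
    def held_out_homologs(self) -> HomologPairs:
        return HomologPairs(tuple(self.held_out))


def build_world(seed: int, landmark_fraction: float = 0.2) -> SyntheticWorld:
    pair = make_network_pair(seed=seed)
    core1 = preprocess_network(pair.net1)
    core2 = preprocess_network(pair.net2)
    in1, in2 = set(core1.graph.nodes), set(core2.graph.nodes)
    true_pairs = sorted(
        (a, b) for a, b in pair.truth.items() if a in in1 and b in in2
    )
    rng = np.random.default_rng(seed)
    n_lm = int(landmark_fraction * len(true_pairs))
    idx = set(int(i) for i in rng.choice(len(true_pairs), size=n_lm, replace=False))
    landmarks = LandmarkList(tuple(true_pairs[i] for i in sorted(idx)))
    held_out = [p for i, p in enumerate(true_pairs) if i not in idx]
    c1, c2hat, scores = joint_embedding(core1, core2, landmarks)
    return SyntheticWorld(
        pair, core1, core2, true_pairs, landmarks, held_out,
        c1, c2hat, scores, to_dissimilarity(scores),
    )


@pytest.fixture(scope="session")
def world() -> SyntheticWorld:
    return build_world(seed=0)
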