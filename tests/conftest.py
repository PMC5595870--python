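import itertools

import numpy as np
import pandas as pd
import pytest

from preclone import phylogeny as ph
from preclone import signatures as sigs
from preclone import synthetic as syn


@pytest.fixture(scope="session")
def reference_sigs():
    return sigs.reference_signatures()


@pytest.fixture(scope="session")
def small_tree():
    return syn.simulate_clone_tree(4, 10, 5, seed=11)


@pytest.fixture(scope="session")
def small_regions(small_tree):
    return syn.simulate_regions(small_tree, 4, seed=12)


@pytest.fixture(scope="session")
def small_reads(small_tree, small_regions):
    return syn.simulate_reads(small_tree, small_regions, mean_depth=80, seed=13)


def parsimony_oracle(X: np.ndarray) -> int:
    """Independent minimal-changes oracle: enumerate every rooted topology
    and, per topology, every internal-state assignment (root fixed to the
    germline state 0).  Deliberately brute force."""
    n = X.shape[0]
    best = None
    for topo in ph.enumerate_topologies(n):
        nodes = []          # postorder: (id, left, right) or (id, leaf)
        counter = itertools.count()

        def build(t):
            nid = next(counter)
            if isinstance(t, int):
                nodes.append((nid, t, None))
            else:
                l = build(t[0])
                r = build(t[1])
                nodes.append((nid, l, r))
            return nid

        root = build(topo)
        internal = [nid for nid, l, r in nodes if r is not None]
        leaf_of = {nid: l for nid, l, r in nodes if r is None}
        edges = []
        for nid, l, r in nodes:
            if r is not None:
                edges.append((nid, l))
                edges.append((nid, r))
        n_int = len(internal)
        score = 0
        for char in range(X.shape[1]):
            best_char = None
            for bits in range(2 ** n_int):
                state = {}
                for k, nid in enumerate(internal):
                    state[nid] = (bits >> k) & 1
                for nid, leaf in leaf_of.items():
                    state[nid] = int(X[leaf, char])
                changes = int(state[root] != 0)  # germline root state is 0
                for a, b in edges:
                    changes += state[a] != state[b]
                if best_char is None or changes < best_char:
                    best_char = changes
            score += best_char
        if best is None or score < best:
            best = score
    return best
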