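"""Trunk/shared/private classification and maximum-parsimony sample trees.

Mutations of a multi-region patient are 'trunk' when detected in every
sample, 'private' when specific to one sample and 'shared' otherwise.
Trees over samples are built from the binary presence/absence character
matrix by maximum parsimony with the germline (all-absent) state as the
root: for small patients every rooted binary topology is scored exhaustively
with the Fitch small-parsimony algorithm; larger patients use seeded
nearest-neighbor-interchange hill climbing from a neighbor-joining start
with random restarts.  Mutations are assigned to edges by Fitch
backtracking, branch lengths equal the number of assigned mutations, and
characters needing more than one state change are reported as homoplasy
(mutations that "do not fit" the tree).  Ties between equally parsimonious
topologies resolve to the lexicographically smallest canonical encoding.

Characters are binary presence/absence rather than flanking-sequence
snippets; for variants embedded in otherwise-identical flanks the two
encodings induce the same parsimony ranking, and presence/absence keeps the
character matrix explicit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CharacterMatrix", "PhyloEdge", "PhyloTree",
    "classify_trunk_shared_private", "trunk_proportion",
    "enumerate_topologies", "fitch_changes", "build_parsimony_tree",
    "annotate_drivers",
]

Topology = int | tuple  # leaf index or (left, right)


@dataclass
class CharacterMatrix:
    """Samples x mutations binary presence; germline is the implicit all-zero root."""

    presence: pd.DataFrame  # bool, index = samples, columns = mutation ids

    def __post_init__(self) -> None:
        if self.presence.index.duplicated().any():
            raise ValueError("duplicate sample ids in character matrix")
        empty = ~self.presence.any(axis=0)
        if empty.any():
            raise ValueError(
                f"all-absent mutation columns: {list(self.presence.columns[empty])}"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.presence.index)

    @property
    def mutations(self) -> list[str]:
        return list(self.presence.columns)


@dataclass
class PhyloEdge:
    parent: str
    child: str
    gained: list[str]
    lost: list[str]
    category: str        # trunk | shared | private

    @property
    def length(self) -> int:
        return len(self.gained) + len(self.lost)


@dataclass
class PhyloTree:
    leaves: list[str]
    newick: str
    edges: list[PhyloEdge]
    score: int
    homoplasy: list[str]                      # mutations with > 1 state change
    driver_labels: dict[str, list[str]] = field(default_factory=dict)  # child node -> labels


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_trunk_shared_private(matrix: CharacterMatrix) -> pd.Series:
    """Per-mutation category: trunk (all samples), private (one), shared (else)."""
    pres = matrix.presence
    if len(pres.index) < 2:
        raise ValueError("trunk/shared/private undefined for a single-sample patient")
    counts = pres.sum(axis=0)
    cat = pd.Series("shared", index=pres.columns, name="category")
    cat[counts == len(pres.index)] = "trunk"
    cat[counts == 1] = "private"
    return cat


def trunk_proportion(matrix: CharacterMatrix) -> float:
    """|trunk mutations| / |all mutations| for one patient."""
    cat = classify_trunk_shared_private(matrix)
    if len(cat) == 0:
        raise ValueError("no mutations")
    return float((cat == "trunk").mean())


# ---------------------------------------------------------------------------
# topology enumeration and Fitch scoring
# ---------------------------------------------------------------------------

def enumerate_topologies(n_leaves: int):
    """All rooted binary topologies over leaves 0..n-1 ((2n-3)!! of them)."""
    if n_leaves < 1:
        return
    trees: list[Topology] = [0]
    for leaf in range(1, n_leaves):
        nxt: list[Topology] = []
        for t in trees:
            nxt.extend(_insert_everywhere(t, leaf))
        trees = nxt
    yield from trees


def _insert_everywhere(t: Topology, leaf: int) -> list[Topology]:
    out: list[Topology] = [(t, leaf)]
    if isinstance(t, tuple):
        left, right = t
        out.extend((nl, right) for nl in _insert_everywhere(left, leaf))
        out.extend((left, nr) for nr in _insert_everywhere(right, leaf))
    return out


def _canonical(t: Topology) -> str:
    if isinstance(t, int):
        return str(t)
    a, b = _canonical(t[0]), _canonical(t[1])
    return f"({a},{b})" if a < b else f"({b},{a})"


def fitch_changes(topology: Topology, X: np.ndarray) -> np.ndarray:
    """Per-character minimal state changes with the root fixed to 0 (germline).

    ``X`` is (n_leaves, n_characters) boolean.  State sets are bitmasks
    (1 = {0}, 2 = {1}, 3 = both); a union step costs one change, and one
    extra change is added when the root set excludes the germline state.
    """
    n_char = X.shape[1]

    def rec(t: Topology) -> tuple[np.ndarray, np.ndarray]:
        if isinstance(t, int):
            return np.where(X[t], 2, 1).astype(np.uint8), np.zeros(n_char, dtype=np.int32)
        (sl, cl) = rec(t[0])
        (sr, cr) = rec(t[1])
        inter = sl & sr
        disjoint = inter == 0
        s = np.where(disjoint, sl | sr, inter)
        return s.astype(np.uint8), cl + cr + disjoint.astype(np.int32)

    root_set, changes = rec(topology)
    return changes + ((root_set & 1) == 0).astype(np.int32)


def _refine(topology: Topology, X: np.ndarray):
    """Fitch backtracking: per-edge gained/lost characters, root state 0.

    Yields (parent_name, child_name, gains_mask, losses_mask, leaves_below)
    with internal nodes named by their canonical encoding; the edge from the
    germline root to the topology's top node is included.
    """
    n_char = X.shape[1]
    sets: dict[int, np.ndarray] = {}
    children: dict[int, tuple[int, int]] = {}
    names: dict[int, str] = {}
    below: dict[int, list[int]] = {}
    counter = itertools.count()

    def up(t: Topology) -> int:
        nid = next(counter)
        if isinstance(t, int):
            sets[nid] = np.where(X[t], 2, 1).astype(np.uint8)
            names[nid] = f"leaf{t}"
            below[nid] = [t]
            return nid
        l, r = up(t[0]), up(t[1])
        inter = sets[l] & sets[r]
        sets[nid] = np.where(inter == 0, sets[l] | sets[r], inter).astype(np.uint8)
        children[nid] = (l, r)
        names[nid] = _canonical(t)
        below[nid] = below[l] + below[r]
        return nid

    root = up(topology)
    states: dict[int, np.ndarray] = {}
    # germline ancestor has state 0 everywhere
    root_state = np.where((sets[root] & 1) != 0, 0, 1).astype(np.uint8)
    states[root] = root_state
    edges = [("germline", root, np.zeros(n_char, np.uint8), root_state)]
    order = [root]
    while order:
        nid = order.pop()
        if nid in children:
            for ch in children[nid]:
                parent_state = states[nid]
                mask = 1 << parent_state  # bit of parent's state
                keep = (sets[ch] & mask) != 0
                child_state = np.where(keep, parent_state,
                                       np.where((sets[ch] & 1) != 0, 0, 1)).astype(np.uint8)
                states[ch] = child_state
                edges.append((names[nid], ch, states[nid], child_state))
                order.append(ch)
    for pname, ch, ps, cs in edges:
        if isinstance(pname, str) and pname == "germline":
            parent_name = "germline"
        else:
            parent_name = pname
        gains = (ps == 0) & (cs == 1)
        losses = (ps == 1) & (cs == 0)
        yield parent_name, names[ch], gains, losses, below[ch]


# ---------------------------------------------------------------------------
# search
# ---------------------------------------------------------------------------

def _nj_topology(X: np.ndarray) -> Topology:
    """Neighbor-joining start tree from Hamming distances, rooted at germline.

    The germline all-zero profile joins the distance matrix as an extra
    taxon; the tree is rooted on its edge and the germline leaf dropped.
    """
    n = X.shape[0]
    profiles = np.vstack([X.astype(int), np.zeros((1, X.shape[1]), dtype=int)])
    m = n + 1
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            D[i, j] = D[j, i] = np.sum(profiles[i] != profiles[j])
    nodes: list[Topology] = list(range(n)) + ["germline"]
    active = list(range(m))
    Dm = D.copy()
    while len(active) > 2:
        r = len(active)
        tot = {i: sum(Dm[i, j] for j in active if j != i) for i in active}
        best = None
        for ii, i in enumerate(active):
            for j in active[ii + 1:]:
                q = (r - 2) * Dm[i, j] - tot[i] - tot[j]
                if best is None or q < best[0]:
                    best = (q, i, j)
        _, i, j = best
        new_idx = Dm.shape[0]
        Dm = np.pad(Dm, ((0, 1), (0, 1)))
        for k in active:
            if k not in (i, j):
                Dm[new_idx, k] = Dm[k, new_idx] = 0.5 * (Dm[i, k] + Dm[j, k] - Dm[i, j])
        nodes.append((nodes[i], nodes[j]))
        active = [k for k in active if k not in (i, j)] + [new_idx]
    a, b = active
    top: Topology = (nodes[a], nodes[b])
    return _root_at_germline(top)


def _root_at_germline(t: Topology) -> Topology:
    """Drop the 'germline' leaf, rooting the tree at its attachment point."""

    def strip(t: Topology) -> Topology | None:
        if isinstance(t, tuple):
            l = strip(t[0])
            r = strip(t[1])
            if l is None:
                return r
            if r is None:
                return l
            return (l, r)
        return None if t == "germline" else t

    out = strip(t)
    if out is None:
        raise ValueError("tree contained only the germline leaf")
    return out


def _nni_neighbors(t: Topology) -> list[Topology]:
    """All rooted trees one NNI or local rotation away."""
    out: list[Topology] = []

    def rec(t: Topology, wrap) -> None:
        if not isinstance(t, tuple):
            return
        l, r = t
        if isinstance(l, tuple):
            a, b = l
            out.append(wrap(((a, r), b)))
            out.append(wrap(((b, r), a)))
        if isinstance(r, tuple):
            a, b = r
            out.append(wrap((b, (a, l))))
            out.append(wrap((a, (b, l))))
        rec(l, lambda s: wrap((s, r)))
        rec(r, lambda s: wrap((l, s)))

    rec(t, lambda s: s)
    return out


def _random_topology(n: int, rng: np.random.Generator) -> Topology:
    order = [int(x) for x in rng.permutation(n)]
    t: Topology = order[0]
    for leaf in order[1:]:
        choices = _insert_everywhere(t, leaf)
        t = choices[rng.integers(len(choices))]
    return t


def _search_topology(X: np.ndarray, exhaustive_max: int, restarts: int,
                     seed: int) -> tuple[Topology, int]:
    n = X.shape[0]
    if n <= exhaustive_max:
        best_t, best_s, best_key = None, None, None
        for t in enumerate_topologies(n):
            s = int(fitch_changes(t, X).sum())
            key = _canonical(t)
            if best_s is None or s < best_s or (s == best_s and key < best_key):
                best_t, best_s, best_key = t, s, key
        return best_t, best_s
    rng = np.random.default_rng(seed)
    starts = [_nj_topology(X)] + [_random_topology(n, rng) for _ in range(restarts)]
    best_t, best_s, best_key = None, None, None
    for start in starts:
        t = start
        s = int(fitch_changes(t, X).sum())
        improved = True
        while improved:
            improved = False
            for nb in _nni_neighbors(t):
                ns = int(fitch_changes(nb, X).sum())
                if ns < s:
                    t, s, improved = nb, ns, True
                    break
        key = _canonical(t)
        if best_s is None or s < best_s or (s == best_s and key < best_key):
            best_t, best_s, best_key = t, s, key
    return best_t, best_s


def build_parsimony_tree(
    matrix: CharacterMatrix,
    exhaustive_max: int = 8,
    nni_restarts: int = 10,
    seed: int = 0,
) -> PhyloTree:
    """Maximum-parsimony rooted tree over a patient's samples.

    Exhaustive topology enumeration up to ``exhaustive_max`` leaves,
    NNI hill climbing with restarts beyond; Fitch backtracking assigns each
    mutation's gains and losses to edges.
    """
    samples = matrix.samples
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    X = matrix.presence.to_numpy(dtype=bool)
    muts = np.array(matrix.mutations)
    topo, score = _search_topology(X, exhaustive_max, nni_restarts, seed)

    changes = fitch_changes(topo, X)
    homoplasy = list(muts[changes > 1])

    edges: list[PhyloEdge] = []
    for parent_name, child_name, gains, losses, leaves_below in _refine(topo, X):
        if len(leaves_below) == len(samples):
            category = "trunk"
        elif len(leaves_below) == 1:
            category = "private"
        else:
            category = "shared"
        edges.append(
            PhyloEdge(
                parent=str(parent_name),
                child=child_name if not child_name.startswith("leaf")
                else samples[int(child_name[4:])],
                gained=list(muts[gains]),
                lost=list(muts[losses]),
                category=category,
            )
        )

    def to_newick(t: Topology) -> str:
        if isinstance(t, int):
            length = next(
                (e.length for e in edges if e.child == samples[t]), 0
            )
            return f"{samples[t]}:{length}"
        name = _canonical(t)
        length = next((e.length for e in edges if e.child == name), 0)
        return f"({to_newick(t[0])},{to_newick(t[1])}):{length}"

    newick = f"({to_newick(topo)})germline;"
    # rename internal canonical ids to stable n1, n2, ...
    internal = sorted({e.child for e in edges if e.child not in samples}
                      | {e.parent for e in edges} - {"germline"})
    rename = {name: f"n{i + 1}" for i, name in enumerate(internal)}
    for e in edges:
        e.parent = rename.get(e.parent, e.parent)
        e.child = rename.get(e.child, e.child)
    return PhyloTree(leaves=samples, newick=newick, edges=edges,
                     score=score, homoplasy=homoplasy)


def annotate_drivers(
    tree: PhyloTree,
    driver_info: dict[str, tuple[str, str]],
) -> PhyloTree:
    """Label edges with their driver genes.

    ``driver_info`` maps mutation id -> (gene, protein change).  A gene hit
    more than once in the patient is labeled with its amino-acid change so
    repeated, independently acquired mutations stay distinguishable.
    """
    gene_counts: dict[str, int] = {}
    for mut, (gene, _) in driver_info.items():
        gene_counts[gene] = gene_counts.get(gene, 0) + 1
    labels: dict[str, list[str]] = {}
    for edge in tree.edges:
        for mut in edge.gained:
            if mut in driver_info:
                gene, aa = driver_info[mut]
                label = f"{gene} {aa}" if gene_counts[gene] > 1 and aa else gene
                labels.setdefault(edge.child, []).append(label)
    tree.driver_labels = labels
    return tree
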