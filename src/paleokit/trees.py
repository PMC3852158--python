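"""Unrooted binary phylogenetic trees: construction, Newick I/O, neighborhoods.

Parsimony scores are properties of the unrooted topology, so trees are
manipulated unrooted throughout: leaves ``0..n-1`` map onto an ordered taxon
tuple, internal nodes have degree 3, and a tree is identified by its set of
nontrivial bipartitions.  A display root (e.g. a designated outgroup) only
affects how Newick output is written, never any score.

Newick reading and writing go through dendropy; small-instance topology
enumeration (3, 15, 105, ... trees), random topologies, and subtree
prune-regraft (SPR) neighborhoods are provided for searches and for
brute-force oracles.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Iterator, Sequence

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "enumerate_topologies",
    "random_topology",
]


class PhyloTree:
    """An unrooted binary tree over an ordered taxon set.

    ``adj`` maps node id -> sorted list of neighbor ids; leaves are
    ``0..n-1`` (indexing ``taxa``), internal nodes are higher ids.  Optional
    ``edge_lengths`` (keyed by frozenset pairs) are carried for simulation
    only and are ignored by all scoring code.
    """

    __slots__ = ("taxa", "adj", "edge_lengths")

    def __init__(
        self,
        taxa: Sequence[str],
        adj: dict[int, list[int]],
        edge_lengths: dict[frozenset, float] | None = None,
    ):
        self.taxa = tuple(taxa)
        self.adj = {u: sorted(vs) for u, vs in adj.items()}
        self.edge_lengths = dict(edge_lengths) if edge_lengths else None
        self._validate()

    def _validate(self) -> None:
        n = len(self.taxa)
        if len(set(self.taxa)) != n:
            raise ValueError("duplicate taxon names")
        for u, vs in self.adj.items():
            for v in vs:
                if u not in self.adj.get(v, ()):
                    raise ValueError(f"adjacency not symmetric at edge ({u}, {v})")
        # a tree may be partial (stepwise addition): only present leaves checked
        for leaf in range(n):
            if leaf in self.adj and n > 1 and len(self.adj[leaf]) != 1:
                raise ValueError(f"leaf {leaf} must have degree 1")
        for u in self.internal_nodes():
            if len(self.adj[u]) != 3 and n > 2:
                raise ValueError(f"internal node {u} must have degree 3 (unrooted binary)")

    # -- basics ------------------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def internal_nodes(self) -> list[int]:
        return [u for u in self.adj if u >= self.n_taxa]

    def edges(self) -> list[tuple[int, int]]:
        return [(u, v) for u in self.adj for v in self.adj[u] if u < v]

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.taxa, {u: list(vs) for u, vs in self.adj.items()},
                         self.edge_lengths)

    # -- traversal ---------------------------------------------------------

    def postorder(self, root: int | None = None) -> list[tuple[int, list[int]]]:
        """Postorder (node, children) pairs, rooted at ``root`` (default leaf 0)."""
        if root is None:
            root = 0 if 0 in self.adj else min(self.adj)
        out: list[tuple[int, list[int]]] = []
        stack = [(root, -1, False)]
        while stack:
            node, parent, expanded = stack.pop()
            children = [v for v in self.adj[node] if v != parent]
            if expanded or not children:
                out.append((node, children))
            else:
                stack.append((node, parent, True))
                for c in children:
                    stack.append((c, node, False))
        return out

    def bipartitions(self) -> frozenset[frozenset[int]]:
        """Nontrivial splits, each encoded as the leaf-id side not containing leaf 0."""
        n = len([u for u in self.adj if u < self.n_taxa])
        splits: set[frozenset[int]] = set()
        below: dict[int, set[int]] = {}
        for node, children in self.postorder():
            if node < n:
                below[node] = {node}
            else:
                below[node] = set().union(*(below[c] for c in children))
            if 1 < len(below[node]) < n - 1:
                splits.add(frozenset(below[node]))
        return frozenset(splits)

    def clades(self) -> frozenset[frozenset[str]]:
        """Bipartitions by taxon name (side not containing the first taxon)."""
        return frozenset(
            frozenset(self.taxa[i] for i in side) for side in self.bipartitions()
        )

    def topology_key(self) -> frozenset[frozenset[int]]:
        return self.bipartitions()

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PhyloTree)
            and self.taxa == other.taxa
            and self.bipartitions() == other.bipartitions()
        )

    def __hash__(self) -> int:
        return hash((self.taxa, self.bipartitions()))

    # -- Newick ------------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, taxa: Sequence[str] | None = None) -> "PhyloTree":
        """Parse a Newick string (branch lengths kept if present, never scored).

        ``taxa`` fixes the leaf order; by default leaves are ordered by name.
        Rooted inputs (degree-2 root) are unrooted automatically.
        """
        dt = dendropy.Tree.get(data=newick, schema="newick")
        labels = [lf.taxon.label for lf in dt.leaf_node_iter()]
        if taxa is None:
            taxa = sorted(labels)
        if set(labels) != set(taxa):
            raise ValueError(
                f"tree taxa {sorted(labels)} do not match expected {sorted(taxa)}"
            )
        index = {name: i for i, name in enumerate(taxa)}
        adj: dict[int, list[int]] = {}
        lengths: dict[frozenset, float] = {}
        next_id = len(taxa)
        node_id: dict = {}

        def get_id(nd) -> int:
            nonlocal next_id
            if nd in node_id:
                return node_id[nd]
            if nd.is_leaf():
                node_id[nd] = index[nd.taxon.label]
            else:
                node_id[nd] = next_id
                next_id += 1
            return node_id[nd]

        has_lengths = False
        for edge in dt.preorder_edge_iter():
            if edge.tail_node is None:
                continue
            u, v = get_id(edge.tail_node), get_id(edge.head_node)
            adj.setdefault(u, []).append(v)
            adj.setdefault(v, []).append(u)
            if edge.length is not None:
                has_lengths = True
            lengths[frozenset((u, v))] = edge.length if edge.length is not None else 0.0

        # suppress a degree-2 display root
        degree2 = [u for u, vs in adj.items() if u >= len(taxa) and len(vs) == 2]
        for u in degree2:
            a, b = adj[u]
            adj[a].remove(u)
            adj[b].remove(u)
            adj[a].append(b)
            adj[b].append(a)
            la = lengths.pop(frozenset((u, a)), 0.0)
            lb = lengths.pop(frozenset((u, b)), 0.0)
            lengths[frozenset((a, b))] = (la or 0.0) + (lb or 0.0)
            del adj[u]
        return cls(taxa, adj, lengths if has_lengths else None)

    def to_newick(self, display_root: str | None = None) -> str:
        """Write Newick, optionally rooted for display on an outgroup taxon."""
        if self.n_taxa == 2:
            return f"({self.taxa[0]},{self.taxa[1]});"
        root_leaf = 0 if display_root is None else self.taxa.index(display_root)
        anchor = self.adj[root_leaf][0]

        def write(node: int, parent: int) -> str:
            children = [v for v in self.adj[node] if v != parent]
            label = self.taxa[node] if node < self.n_taxa else ""
            body = label if not children else (
                "(" + ",".join(write(c, node) for c in children) + ")" + label
            )
            if self.edge_lengths is not None and parent >= 0:
                body += f":{self.edge_lengths.get(frozenset((node, parent)), 0.0):g}"
            return body

        inner = write(anchor, root_leaf)
        return f"({self.taxa[root_leaf]},{inner});"

    # -- editing and neighborhoods ------------------------------------------

    def _next_id(self) -> int:
        return max(self.adj) + 1

    def insert_leaf(self, leaf: int, edge: tuple[int, int]) -> "PhyloTree":
        """New tree with ``leaf`` attached by subdividing ``edge``."""
        u, v = edge
        t = self.copy()
        mid = t._next_id() if t.adj else leaf + 1
        t.adj[u] = [x for x in t.adj[u] if x != v] + [mid]
        t.adj[v] = [x for x in t.adj[v] if x != u] + [mid]
        t.adj[mid] = [u, v, leaf]
        t.adj[leaf] = [mid]
        t.edge_lengths = None
        return PhyloTree(t.taxa, t.adj)

    def spr_neighbors(self) -> list["PhyloTree"]:
        """All distinct trees one subtree-prune-regraft move away.

        Every directed edge (v -> u) defines a pruned subtree rooted at u;
        it is reattached onto every edge of the remaining tree.  The SPR
        neighborhood contains the NNI neighborhood.
        """
        out: dict[frozenset, PhyloTree] = {}
        me = self.topology_key()
        for v, u in [(a, b) for a, b in itertools.chain(
            ((x, y) for x, y in self.edges()), ((y, x) for x, y in self.edges())
        )]:
            if len(self.adj[v]) != 3:
                continue  # pruning must leave a contractible degree-2 node
            # subtree = component containing u after removing edge (u, v)
            sub = self._component(u, banned=v)
            t = self.copy()
            w1, w2 = [x for x in t.adj[v] if x != u]
            # detach: remove v, reconnect w1-w2
            t.adj[w1] = [x for x in t.adj[w1] if x != v] + [w2]
            t.adj[w2] = [x for x in t.adj[w2] if x != v] + [w1]
            t.adj[u] = [x for x in t.adj[u] if x != v]
            del t.adj[v]
            rest_edges = [
                (a, b) for a, b in t.edges() if a not in sub and b not in sub
            ]
            for a, b in rest_edges:
                # note: reattaching on the closing edge (w1, w2) restores the
                # original topology; the key filter below drops it
                nt = {x: list(ys) for x, ys in t.adj.items()}
                nt[a] = [x for x in nt[a] if x != b] + [v]
                nt[b] = [x for x in nt[b] if x != a] + [v]
                nt[v] = [a, b, u]
                nt[u] = nt[u] + [v]
                cand = PhyloTree(self.taxa, nt)
                key = cand.topology_key()
                if key != me:
                    out[key] = cand
        return list(out.values())

    def _component(self, start: int, banned: int) -> set[int]:
        seen = {start}
        stack = [start]
        while stack:
            x = stack.pop()
            for y in self.adj[x]:
                if y != banned and y not in seen:
                    seen.add(y)
                    stack.append(y)
        return seen


# ---------------------------------------------------------------------------
# topology generation


def _three_taxon(taxa: Sequence[str]) -> PhyloTree:
    n = len(taxa)
    hub = n
    adj = {0: [hub], 1: [hub], 2: [hub], hub: [0, 1, 2]}
    return PhyloTree(taxa, adj)


def enumerate_topologies(taxa: Sequence[str]) -> Iterator[PhyloTree]:
    """Yield every unrooted binary topology ((2n-5)!! trees) by leaf insertion."""
    taxa = tuple(taxa)
    n = len(taxa)
    if n < 3:
        if n == 2:
            yield PhyloTree(taxa, {0: [1], 1: [0]})
            return
        raise ValueError("need at least 2 taxa")

    def grow(tree: PhyloTree, k: int) -> Iterator[PhyloTree]:
        if k == n:
            yield tree
            return
        for edge in tree.edges():
            yield from grow(tree.insert_leaf(k, edge), k + 1)

    yield from grow(_three_taxon(taxa), 3)


def random_topology(taxa: Sequence[str], rng: np.random.Generator) -> PhyloTree:
    """Uniform random unrooted binary topology by random sequential addition."""
    taxa = tuple(taxa)
    n = len(taxa)
    if n == 2:
        return PhyloTree(taxa, {0: [1], 1: [0]})
    tree = _three_taxon(taxa)
    for k in range(3, n):
        edges = tree.edges()
        u, v = edges[int(rng.integers(len(edges)))]
        tree = tree.insert_leaf(k, (u, v))
    return tree


def with_random_branch_lengths(
    tree: PhyloTree, rng: np.random.Generator, mean: float = 0.3
) -> PhyloTree:
    """Attach exponential branch lengths (simulation use only)."""
    lengths = {frozenset(e): float(rng.exponential(mean)) for e in tree.edges()}
    return PhyloTree(tree.taxa, tree.adj, lengths)
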