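"""Equal-weights parsimony scoring and desk-scale tree search.

Tree length for a mixed morphological matrix is the weighted sum of
per-character minimum change counts on a fixed unrooted binary topology:

* unordered discrete characters are scored with the Fitch set
  intersection/union down-pass (missing cells carry the full observed
  alphabet and never add length);
* continuous characters are treated as additive and scored with the Farris
  interval down-pass: each internal node takes the intersection of its
  children's intervals, or, when they are disjoint, adds the gap between
  them to the length and takes the between-interval closure.

The consistency index CI = sum(min)/L and retention index
RI = (sum(max) - L)/(sum(max) - sum(min)) compare the realized length with
the per-character floor (any tree) and ceiling (star tree).

Search is a random-addition-sequence + steepest-descent SPR hill climb,
adequate for desk-scale matrices; it makes no attempt to replicate
driven-search heuristics of dedicated parsimony programs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .characters import CharacterMatrix, ContinuousColumn, DiscreteColumn
from .trees import PhyloTree, random_topology

__all__ = [
    "ParsimonyScore",
    "fitch_length",
    "continuous_length",
    "tree_length",
    "ci_ri",
    "hill_climb_search",
]


@dataclass(frozen=True)
class ParsimonyScore:
    """Tree length with per-character breakdown and homoplasy indices.

    ``sum_min``/``sum_max`` are the weighted sums of per-character floors and
    star-tree ceilings; ``ri`` is ``None`` when ``sum_max == sum_min`` (no
    character can vary, RI undefined).
    """

    total_length: float
    per_character: tuple[float, ...]
    min_lengths: tuple[float, ...] = ()
    max_lengths: tuple[float, ...] = ()
    weights: tuple[float, ...] = ()

    @property
    def sum_min(self) -> float:
        return float(sum(w * m for w, m in zip(self.weights, self.min_lengths)))

    @property
    def sum_max(self) -> float:
        return float(sum(w * m for w, m in zip(self.weights, self.max_lengths)))

    @property
    def ci(self) -> float:
        if self.total_length == 0:
            return 1.0
        return self.sum_min / self.total_length

    @property
    def ri(self) -> float | None:
        denom = self.sum_max - self.sum_min
        if denom <= 0:
            return None
        return (self.sum_max - self.total_length) / denom


# ---------------------------------------------------------------------------
# prepared scoring context


class _Prepared:
    """Leaf-level encodings of a matrix, reusable across many topologies."""

    def __init__(self, matrix: CharacterMatrix):
        self.matrix = matrix
        self.n_taxa = matrix.n_taxa
        disc_idx, cont_idx = [], []
        for k, col in enumerate(matrix.columns):
            (disc_idx if isinstance(col, DiscreteColumn) else cont_idx).append(k)
        self.disc_idx = disc_idx
        self.cont_idx = cont_idx
        self.w_disc = np.array([matrix.weights[k] for k in disc_idx])
        self.w_cont = np.array([matrix.weights[k] for k in cont_idx])

        # discrete cells as bitmasks; missing = full observed alphabet
        masks = np.zeros((matrix.n_taxa, len(disc_idx)), dtype=np.int64)
        for j, k in enumerate(disc_idx):
            col = matrix.columns[k]
            sets = col.state_sets()
            for i in range(matrix.n_taxa):
                m = 0
                for s in sets[i]:
                    m |= 1 << s
                masks[i, j] = m
        self.masks = masks

        lo = np.full((matrix.n_taxa, len(cont_idx)), -np.inf)
        hi = np.full((matrix.n_taxa, len(cont_idx)), np.inf)
        for j, k in enumerate(cont_idx):
            col = matrix.columns[k]
            for i, cell in enumerate(col.cells):
                if cell is not None:
                    lo[i, j], hi[i, j] = cell
        self.lo = lo
        self.hi = hi

    def score_tree(self, tree: PhyloTree) -> tuple[float, np.ndarray, np.ndarray]:
        """(weighted total, per-discrete lengths, per-continuous lengths).

        Works on partial trees (only leaves present in the adjacency are
        scored), which is what stepwise addition needs.
        """
        leaves = [u for u in tree.adj if u < self.n_taxa]
        if len(leaves) == 1:
            return 0.0, np.zeros(len(self.disc_idx)), np.zeros(len(self.cont_idx))
        root = min(leaves)
        anchor = tree.adj[root][0]
        disc = np.zeros(len(self.disc_idx))
        cont = np.zeros(len(self.cont_idx))
        if len(leaves) == 2:
            o = self.masks[root] & self.masks[anchor]
            disc += o == 0
            gap = np.maximum(self.lo[root], self.lo[anchor]) - np.minimum(
                self.hi[root], self.hi[anchor]
            )
            cont += np.maximum(gap, 0.0)
            total = float(disc @ self.w_disc) + float(cont @ self.w_cont)
            return total, disc, cont

        mask_of: dict[int, np.ndarray] = {}
        lo_of: dict[int, np.ndarray] = {}
        hi_of: dict[int, np.ndarray] = {}

        # postorder rooted on the edge (root leaf, anchor)
        stack: list[tuple[int, int, bool]] = [(anchor, root, False)]
        order: list[tuple[int, list[int]]] = []
        while stack:
            node, parent, expanded = stack.pop()
            children = [v for v in tree.adj[node] if v != parent]
            if expanded or not children:
                order.append((node, children))
            else:
                stack.append((node, parent, True))
                for c in children:
                    stack.append((c, node, False))

        for node, children in order:
            if not children:
                mask_of[node] = self.masks[node]
                lo_of[node] = self.lo[node]
                hi_of[node] = self.hi[node]
                continue
            c1, c2 = children
            inter = mask_of[c1] & mask_of[c2]
            empty = inter == 0
            mask_of[node] = np.where(empty, mask_of[c1] | mask_of[c2], inter)
            disc += empty

            nlo = np.maximum(lo_of[c1], lo_of[c2])
            nhi = np.minimum(hi_of[c1], hi_of[c2])
            gap = nlo - nhi
            cont += np.maximum(gap, 0.0)
            lo_of[node] = np.minimum(nlo, nhi)
            hi_of[node] = np.maximum(nlo, nhi)

        # close the root edge
        inter = mask_of[anchor] & self.masks[root]
        disc += inter == 0
        gap = np.maximum(lo_of[anchor], self.lo[root]) - np.minimum(
            hi_of[anchor], self.hi[root]
        )
        cont += np.maximum(gap, 0.0)

        total = float(disc @ self.w_disc) + float(cont @ self.w_cont)
        return total, disc, cont


def _check_taxa(tree: PhyloTree, matrix: CharacterMatrix) -> None:
    if tree.taxa != matrix.taxa:
        only_tree = set(tree.taxa) - set(matrix.taxa)
        only_matrix = set(matrix.taxa) - set(tree.taxa)
        if only_tree or only_matrix:
            raise ValueError(
                f"taxon mismatch: only in tree {sorted(only_tree)}, "
                f"only in matrix {sorted(only_matrix)}"
            )
        raise ValueError("tree and matrix taxa are ordered differently")


# ---------------------------------------------------------------------------
# public scoring API


def fitch_length(tree: PhyloTree, column: DiscreteColumn) -> int:
    """Unordered (Fitch) parsimony length of one discrete character."""
    matrix = CharacterMatrix(tree.taxa, (column,))
    _, disc, _ = _Prepared(matrix).score_tree(tree)
    return int(disc[0])


def continuous_length(tree: PhyloTree, column: ContinuousColumn) -> float:
    """Additive (Farris interval) parsimony length of one continuous character."""
    matrix = CharacterMatrix(tree.taxa, (column,))
    _, _, cont = _Prepared(matrix).score_tree(tree)
    return float(cont[0])


def tree_length(tree: PhyloTree, matrix: CharacterMatrix) -> ParsimonyScore:
    """Weighted parsimony length of the whole matrix on a fixed topology."""
    _check_taxa(tree, matrix)
    prep = _Prepared(matrix)
    total, disc, cont = prep.score_tree(tree)
    per: list[float] = []
    di = ci = 0
    for col in matrix.columns:
        if isinstance(col, DiscreteColumn):
            per.append(float(disc[di]))
            di += 1
        else:
            per.append(float(cont[ci]))
            ci += 1
    return ParsimonyScore(total, tuple(per), weights=matrix.weights)


def _discrete_min(col: DiscreteColumn) -> int:
    """Smallest state count hitting every non-missing cell, minus one."""
    cells = [c for c in col.cells if c is not None]
    if not cells:
        return 0
    alphabet = sorted(frozenset().union(*cells))
    for size in range(1, len(alphabet) + 1):
        for combo in itertools.combinations(alphabet, size):
            s = set(combo)
            if all(s & c for c in cells):
                return size - 1
    return len(alphabet) - 1


def _discrete_max(col: DiscreteColumn) -> int:
    """Star-tree length: non-missing cells minus the best-covered state."""
    cells = [c for c in col.cells if c is not None]
    if not cells:
        return 0
    alphabet = frozenset().union(*cells)
    best = max(sum(1 for c in cells if s in c) for s in alphabet)
    return len(cells) - best


def _continuous_min(col: ContinuousColumn) -> float:
    cells = [c for c in col.cells if c is not None]
    if not cells:
        return 0.0
    return max(0.0, max(lo for lo, _ in cells) - min(hi for _, hi in cells))


def _continuous_max(col: ContinuousColumn) -> float:
    """Star-tree length: min over centers of summed interval distances."""
    cells = [c for c in col.cells if c is not None]
    if not cells:
        return 0.0
    candidates = sorted({v for cell in cells for v in cell})

    def cost(c: float) -> float:
        return sum(max(lo - c, c - hi, 0.0) for lo, hi in cells)

    return min(cost(c) for c in candidates)


def ci_ri(matrix: CharacterMatrix, tree: PhyloTree) -> ParsimonyScore:
    """Score a tree and attach per-character floors/ceilings, CI and RI."""
    base = tree_length(tree, matrix)
    mins: list[float] = []
    maxs: list[float] = []
    for col in matrix.columns:
        if isinstance(col, DiscreteColumn):
            mins.append(float(_discrete_min(col)))
            maxs.append(float(_discrete_max(col)))
        else:
            mins.append(_continuous_min(col))
            maxs.append(_continuous_max(col))
    return ParsimonyScore(
        base.total_length, base.per_character, tuple(mins), tuple(maxs), matrix.weights
    )


# ---------------------------------------------------------------------------
# search


def _stepwise_addition(
    prep: _Prepared, order: np.ndarray, taxa: tuple[str, ...]
) -> PhyloTree:
    """Greedy stepwise addition in the given taxon order."""
    first = [int(x) for x in order[:3]]
    n = len(taxa)
    hub = n
    adj = {first[0]: [hub], first[1]: [hub], first[2]: [hub], hub: list(first)}
    tree = PhyloTree(taxa, adj)
    for leaf in order[3:]:
        leaf = int(leaf)
        best = None
        for edge in tree.edges():
            cand = tree.insert_leaf(leaf, edge)
            score, _, _ = prep.score_tree(cand)
            if best is None or score < best[0]:
                best = (score, cand)
        tree = best[1]
    return tree


def _steepest_descent(
    prep: _Prepared, tree: PhyloTree, visit=None
) -> tuple[PhyloTree, float]:
    score, _, _ = prep.score_tree(tree)
    if visit is not None:
        visit(tree, score)
    while True:
        best_move = None
        for nb in tree.spr_neighbors():
            s, _, _ = prep.score_tree(nb)
            if visit is not None:
                visit(nb, s)
            if s < score - 1e-12 and (best_move is None or s < best_move[0] - 1e-12):
                best_move = (s, nb)
        if best_move is None:
            return tree, score
        score, tree = best_move


def hill_climb_search(
    matrix: CharacterMatrix,
    n_starts: int = 10,
    seed: int = 0,
    *,
    _visit=None,
) -> tuple[list[PhyloTree], float]:
    """Random-addition starts plus steepest-descent SPR swapping.

    Returns all distinct best-scoring trees found and their length.  The
    same seed and parameters reproduce the same output exactly.
    """
    if matrix.n_taxa < 4:
        raise ValueError("search needs at least 4 taxa")
    rng = np.random.default_rng(seed)
    prep = _Prepared(matrix)
    best_len = np.inf
    best: dict[frozenset, PhyloTree] = {}
    for _ in range(n_starts):
        start = _stepwise_addition(prep, rng.permutation(matrix.n_taxa), matrix.taxa)
        tree, score = _steepest_descent(prep, start, visit=_visit)
        if score < best_len - 1e-12:
            best_len = score
            best = {tree.topology_key(): tree}
        elif abs(score - best_len) <= 1e-12:
            best.setdefault(tree.topology_key(), tree)
    return list(best.values()), float(best_len)


def exhaustive_search(matrix: CharacterMatrix) -> tuple[list[PhyloTree], float]:
    """Score every topology (tiny n only); oracle for the hill climb."""
    from .trees import enumerate_topologies

    if matrix.n_taxa > 8:
        raise ValueError("exhaustive search limited to 8 taxa")
    prep = _Prepared(matrix)
    best_len = np.inf
    best: list[PhyloTree] = []
    for tree in enumerate_topologies(matrix.taxa):
        s, _, _ = prep.score_tree(tree)
        if s < best_len - 1e-12:
            best_len, best = s, [tree]
        elif abs(s - best_len) <= 1e-12:
            best.append(tree)
    return best, float(best_len)
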