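"""Clade support: symmetric resampling frequencies and Bremer decay.

Symmetric resampling perturbs each character independently with probability
``p`` — doubling or zeroing its weight with equal chance — and re-runs the
search on the perturbed weights; unlike bootstrap or jackknife the expected
weight of every character is unchanged, so the measure is not distorted by
uninformative characters.  Bremer decay asks how many extra steps of tree
length are needed before a clade disappears from the near-optimal set; it is
estimated here from a seeded pool of suboptimal trees collected during hill
climbs (every tree evaluated within the length threshold is retained, and
duplicates are removed before tallying).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .characters import CharacterMatrix
from .parsimony import _Prepared, _stepwise_addition, _steepest_descent, hill_climb_search
from .trees import PhyloTree

__all__ = ["SupportTable", "symmetric_resampling", "bremer_decay"]


@dataclass(frozen=True)
class SupportTable:
    """Per-clade support values plus the run parameters that produced them.

    Clades are taxon-name frozensets (the side of the bipartition not
    containing the reference tree's first taxon).  ``frequency`` is percent
    of replicates; ``decay`` is extra length, with ``None`` meaning the clade
    persisted in every collected tree (decay > ``max_extra_steps``).
    """

    clades: tuple[frozenset, ...]
    frequency: dict = field(default_factory=dict)
    decay: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        max_extra = self.params.get("max_extra_steps")
        for clade in self.clades:
            decay = self.decay.get(clade)
            rows.append({
                "clade": "+".join(sorted(clade)),
                "frequency_pct": self.frequency.get(clade),
                "decay": f"> {max_extra}" if decay is None and self.decay else decay,
            })
        return pd.DataFrame(rows)


def symmetric_resampling(
    matrix: CharacterMatrix,
    reference_tree: PhyloTree,
    replicates: int = 100,
    p: float = 0.33,
    seed: int = 0,
    n_starts: int = 2,
) -> SupportTable:
    """Clade frequencies of the reference tree under symmetric resampling.

    Each replicate perturbs every character weight independently with
    probability ``p`` (x2 or x0, equal chance), searches on the perturbed
    matrix, and counts a reference clade as recovered when it appears in the
    strict consensus of that replicate's best trees.
    """
    if not 0 < p < 1:
        raise ValueError(f"perturbation probability must be in (0, 1), got {p}")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    ref_clades = tuple(sorted(reference_tree.clades(), key=sorted))
    counts = {c: 0 for c in ref_clades}
    base = np.asarray(matrix.weights, dtype=float)
    for _ in range(replicates):
        perturb = rng.random(matrix.n_char) < p
        updown = rng.integers(0, 2, size=matrix.n_char)  # 1 -> x2, 0 -> x0
        factors = np.where(perturb, np.where(updown == 1, 2.0, 0.0), 1.0)
        rep_matrix = matrix.with_weights(base * factors)
        best, _ = hill_climb_search(
            rep_matrix, n_starts=n_starts, seed=int(rng.integers(2**31))
        )
        consensus = frozenset.intersection(*(t.clades() for t in best))
        for c in ref_clades:
            if c in consensus:
                counts[c] += 1
    freq = {c: 100.0 * counts[c] / replicates for c in ref_clades}
    return SupportTable(
        clades=ref_clades,
        frequency=freq,
        params={
            "replicates": replicates,
            "p": p,
            "seed": seed,
            "n_starts": n_starts,
        },
    )


def bremer_decay(
    matrix: CharacterMatrix,
    best_trees: list[PhyloTree],
    max_extra_steps: float = 3.0,
    seed: int = 0,
    n_starts: int = 20,
) -> SupportTable:
    """Decay indices from a seeded pool of near-optimal trees.

    Hill climbs from random-addition starts retain every evaluated tree
    whose length is within ``max_extra_steps`` of the best known length
    (duplicate topologies removed).  The decay of a clade of the (first)
    best tree is the minimum extra length among pool trees lacking it, or
    ``None`` if every collected tree contains it.
    """
    if not best_trees:
        raise ValueError("best_trees must be non-empty")
    rng = np.random.default_rng(seed)
    prep = _Prepared(matrix)
    best_len = min(prep.score_tree(t)[0] for t in best_trees)
    threshold = best_len + max_extra_steps

    pool: dict[frozenset, float] = {}

    def visit(tree: PhyloTree, score: float) -> None:
        if score <= threshold + 1e-9:
            key = tree.clades()
            if key not in pool or score < pool[key]:
                pool[key] = score

    for t in best_trees:
        visit(t, prep.score_tree(t)[0])
    for _ in range(n_starts):
        start = _stepwise_addition(prep, rng.permutation(matrix.n_taxa), matrix.taxa)
        _steepest_descent(prep, start, visit=visit)

    ref_clades = tuple(sorted(best_trees[0].clades(), key=sorted))
    decay: dict = {}
    for clade in ref_clades:
        extras = [s - best_len for k, s in pool.items() if clade not in k]
        decay[clade] = min(extras) if extras else None
    return SupportTable(
        clades=ref_clades,
        decay=decay,
        params={
            "max_extra_steps": max_extra_steps,
            "seed": seed,
            "n_starts": n_starts,
            "pool_size": len(pool),
            "best_length": best_len,
        },
    )
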