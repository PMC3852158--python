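"""TNT parsing, Fitch/Farris scoring, CI/RI, and tree search."""

import itertools

import numpy as np
import pytest

from paleokit.characters import (
    CharacterMatrix,
    ContinuousColumn,
    DiscreteColumn,
    TntParseError,
    parse_tnt,
    write_tnt,
)
from paleokit.parsimony import (
    ci_ri,
    continuous_length,
    exhaustive_search,
    fitch_length,
    hill_climb_search,
    tree_length,
)
from paleokit.trees import PhyloTree, enumerate_topologies, random_topology

from conftest import cont, disc


# ---------------------------------------------------------------------------
# independent oracles


def sankoff_length(tree: PhyloTree, column: DiscreteColumn) -> int:
    """Uniform-cost dynamic program over explicit state assignments."""
    states = sorted(column.alphabet)
    cells = column.state_sets()
    root = tree.adj[0][0]
    INF = 10**9

    def down(node, parent):
        if node < tree.n_taxa:
            return {s: (0 if s in cells[node] else INF) for s in states}
        children = [v for v in tree.adj[node] if v != parent]
        tables = [down(c, node) for c in children]
        out = {}
        for s in states:
            total = 0
            for tab in tables:
                total += min(tab[t] + (0 if t == s else 1) for t in states)
            out[s] = total
        return out

    tab = down(root, 0)
    leaf_costs = {s: (0 if s in cells[0] else INF) for s in states}
    return min(
        tab[s] + leaf_costs[t] + (0 if s == t else 1)
        for s in states for t in states
    )


def l1_steiner_length(tree: PhyloTree, column: ContinuousColumn) -> float:
    """Brute force: internal values restricted to tip values (valid for L1)."""
    tips = [c[0] for c in column.cells if c is not None]
    internals = tree.internal_nodes()
    best = np.inf
    for combo in itertools.product(tips, repeat=len(internals)):
        val = {u: v for u, v in zip(internals, combo)}
        for leaf in range(tree.n_taxa):
            cell = column.cells[leaf]
            val[leaf] = cell[0] if cell is not None else None
        total = 0.0
        ok = True
        for u, v in tree.edges():
            if val[u] is None or val[v] is None:
                continue
            total += abs(val[u] - val[v])
        best = min(best, total)
    return best


# ---------------------------------------------------------------------------
# TNT parsing


TNT_MIXED = """
xread 'mixed example'
5 3
&[continuous]
alpha  1.230 0.500-0.700
beta   1.100 ?
gamma  0.900 0.600
&[num]
alpha  01?
beta   0[01]1
gamma  110
;
"""


class TestParseTnt:
    def test_inline_discrete_matrix(self, tmp_path):
        p = tmp_path / "m.tnt"
        p.write_text("xread\n2 3\nA 00\nB 01\nC 11\n;\n")
        m = parse_tnt(p)
        assert m.n_taxa == 3 and m.n_char == 2
        assert all(isinstance(c, DiscreteColumn) for c in m.columns)

    def test_mixed_blocks_polymorphism_and_missing(self, tmp_path):
        p = tmp_path / "m.tnt"
        p.write_text(TNT_MIXED)
        m = parse_tnt(p)
        assert m.n_char == 5
        assert len(m.continuous_columns) == 2 and len(m.discrete_columns) == 3
        poly = m.discrete_columns[1]
        assert poly.cells[1] == frozenset({0, 1})  # beta's [01]
        assert m.discrete_columns[2].cells[0] is None  # alpha's ?
        assert m.continuous_columns[1].cells[0] == (0.5, 0.7)
        assert m.continuous_columns[1].cells[1] is None

    def test_missing_cell_resolves_to_full_alphabet(self):
        col = disc(0, 2, None)
        assert col.state_sets()[2] == frozenset({0, 2})

    def test_dimension_mismatch_rejected(self, tmp_path):
        p = tmp_path / "m.tnt"
        p.write_text("xread\n3 3\nA 00\nB 01\nC 11\n;\n")
        with pytest.raises(TntParseError, match="3 characters"):
            parse_tnt(p)

    def test_unknown_symbol_reported_with_line(self, tmp_path):
        p = tmp_path / "m.tnt"
        p.write_text("xread\n2 3\nA 00\nB 0x\nC 11\n;\n")
        with pytest.raises(TntParseError, match="line 4"):
            parse_tnt(p)

    def test_ccode_weights_applied(self, tmp_path):
        p = tmp_path / "m.tnt"
        p.write_text("xread\n2 3\nA 00\nB 01\nC 11\n;\nccode /2 1;\n")
        m = parse_tnt(p)
        assert m.weights == (1.0, 2.0)


# ---------------------------------------------------------------------------
# scoring


class TestFitch:
    def test_invariant_column_is_free(self, quartet_tree):
        assert fitch_length(quartet_tree, disc(0, 0, 0, 0)) == 0

    def test_single_split_one_step(self, quartet_tree):
        # exhaustive check over both internal nodes gives exactly one change
        assert fitch_length(quartet_tree, disc(0, 0, 1, 1)) == 1

    def test_conflicting_split_two_steps(self, conflicting_quartet):
        assert fitch_length(conflicting_quartet, disc(0, 0, 1, 1)) == 2

    def test_missing_cells_never_add_length(self, quartet_tree):
        assert fitch_length(quartet_tree, disc(0, None, 1, None)) == 1
        assert fitch_length(quartet_tree, disc(None, None, None, None)) == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_sankoff_oracle_on_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        taxa = tuple(f"t{i}" for i in range(n))
        tree = random_topology(taxa, rng)
        cells = tuple(
            None if rng.random() < 0.15 else frozenset({int(rng.integers(3))})
            for _ in range(n)
        )
        col = DiscreteColumn(cells)
        assert fitch_length(tree, col) == sankoff_length(tree, col)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dendropy_fitch(self, seed):
        import dendropy
        from dendropy.model.parsimony import fitch_down_pass

        rng = np.random.default_rng(seed)
        taxa = tuple(f"t{i}" for i in range(6))
        tree = random_topology(taxa, rng)
        states = [int(rng.integers(2)) for _ in taxa]
        col = disc(*states)

        ns = dendropy.TaxonNamespace()
        fasta = "\n".join(f">{t}\n{s}" for t, s in zip(taxa, states))
        chars = dendropy.StandardCharacterMatrix.get(
            data=fasta, schema="fasta", taxon_namespace=ns
        )
        dt = dendropy.Tree.get(
            data=tree.to_newick(), schema="newick", taxon_namespace=ns
        )
        score = fitch_down_pass(
            list(dt.postorder_node_iter()),
            taxon_state_sets_map=chars.taxon_state_sets_map(gaps_as_missing=True),
        )
        assert fitch_length(tree, col) == score


class TestContinuous:
    def test_two_taxa_absolute_difference(self):
        tree = PhyloTree(("A", "B"), {0: [1], 1: [0]})
        assert continuous_length(tree, cont(0.3, 0.75)) == pytest.approx(0.45)

    def test_quartet_interval_gaps(self, quartet_tree):
        # gaps 0.1 (A,B) + 0.4 (C,D) + 0.3 (across) = 0.8
        col = cont(0.1, 0.2, 0.5, 0.9)
        assert continuous_length(quartet_tree, col) == pytest.approx(0.8)
        assert l1_steiner_length(quartet_tree, col) == pytest.approx(0.8)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_l1_steiner_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 5
        taxa = tuple(f"t{i}" for i in range(n))
        tree = random_topology(taxa, rng)
        col = cont(*(round(float(rng.random()), 3) for _ in range(n)))
        assert continuous_length(tree, col) == pytest.approx(
            l1_steiner_length(tree, col)
        )

    def test_span_lower_bound_and_caterpillar_equality(self):
        # any topology >= max - min; a value-ordered caterpillar attains it
        values = [0.1, 0.25, 0.4, 0.7, 0.95]
        taxa = tuple(f"t{i}" for i in range(5))
        col = cont(*values)
        span = max(values) - min(values)
        lengths = [
            continuous_length(t, col) for t in enumerate_topologies(taxa)
        ]
        assert min(lengths) == pytest.approx(span)
        caterpillar = PhyloTree.from_newick("(t0,(t1,(t2,(t3,t4))));", taxa=taxa)
        assert continuous_length(caterpillar, col) == pytest.approx(span)

    def test_missing_values_contribute_nothing(self, quartet_tree):
        assert continuous_length(quartet_tree, cont(0.5, None, 0.5, None)) == 0.0


class TestTreeLength:
    def _random_mixed(self, seed, n=5):
        rng = np.random.default_rng(seed)
        taxa = tuple(f"t{i}" for i in range(n))
        tree = random_topology(taxa, rng)
        cols = []
        for _ in range(4):
            cols.append(
                DiscreteColumn(tuple(frozenset({int(rng.integers(2))}) for _ in range(n)))
            )
        for _ in range(2):
            cols.append(
                ContinuousColumn(tuple((float(v), float(v)) for v in rng.random(n)))
            )
        return tree, CharacterMatrix(taxa, tuple(cols))

    def test_identical_rows_score_zero(self, quartet_tree):
        m = CharacterMatrix(quartet_tree.taxa, (disc(1, 1, 1, 1), cont(2.5, 2.5, 2.5, 2.5)))
        assert tree_length(quartet_tree, m).total_length == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_total_is_sum_of_per_character_oracles(self, seed):
        tree, m = self._random_mixed(seed)
        score = tree_length(tree, m)
        expected = sum(
            sankoff_length(tree, c) if isinstance(c, DiscreteColumn)
            else l1_steiner_length(tree, c)
            for c in m.columns
        )
        assert score.total_length == pytest.approx(expected)
        assert score.total_length == pytest.approx(sum(score.per_character))

    @pytest.mark.parametrize("seed", range(4))
    def test_invariant_under_rerooting(self, seed):
        tree, m = self._random_mixed(seed)
        base = tree_length(tree, m).total_length
        for taxon in m.taxa:
            rerooted = PhyloTree.from_newick(
                tree.to_newick(display_root=taxon), taxa=m.taxa
            )
            assert tree_length(rerooted, m).total_length == pytest.approx(base)

    def test_all_missing_column_changes_nothing(self, seed=0):
        tree, m = self._random_mixed(seed)
        base = tree_length(tree, m).total_length
        extra = CharacterMatrix(
            m.taxa, m.columns + (DiscreteColumn((None,) * 5), ContinuousColumn((None,) * 5))
        )
        assert tree_length(tree, extra).total_length == pytest.approx(base)

    def test_doubling_weights_doubles_length_not_ci_ri(self, seed=1):
        tree, m = self._random_mixed(seed)
        doubled = m.with_weights([2.0 * w for w in m.weights])
        s1, s2 = ci_ri(m, tree), ci_ri(doubled, tree)
        assert s2.total_length == pytest.approx(2 * s1.total_length)
        assert s2.ci == pytest.approx(s1.ci)
        if s1.ri is not None:
            assert s2.ri == pytest.approx(s1.ri)

    def test_continuous_affine_invariance(self, quartet_tree):
        col = cont(0.1, 0.2, 0.5, 0.9)
        shifted = cont(10.1, 10.2, 10.5, 10.9)
        scaled = cont(0.3, 0.6, 1.5, 2.7)
        base = continuous_length(quartet_tree, col)
        assert continuous_length(quartet_tree, shifted) == pytest.approx(base)
        assert continuous_length(quartet_tree, scaled) == pytest.approx(3 * base)

    def test_taxon_mismatch_listed(self, quartet_tree):
        m = CharacterMatrix(("A", "B", "C", "E"), (disc(0, 0, 1, 1),))
        with pytest.raises(ValueError, match="E"):
            tree_length(quartet_tree, m)


class TestCiRi:
    def test_perfectly_congruent_matrix_ci_one(self, quartet_tree):
        m = CharacterMatrix(
            quartet_tree.taxa, (disc(0, 0, 1, 1), disc(1, 1, 0, 0))
        )
        score = ci_ri(m, quartet_tree)
        assert score.ci == pytest.approx(1.0)
        assert score.ri == pytest.approx(1.0)

    def test_conflicting_character_bounds(self, conflicting_quartet):
        m = CharacterMatrix(conflicting_quartet.taxa, (disc(0, 0, 1, 1),))
        score = ci_ri(m, conflicting_quartet)
        assert score.sum_min == 1.0
        assert score.sum_max == 2.0
        assert score.total_length == 2.0
        assert score.ci == pytest.approx(0.5)
        assert score.ri == pytest.approx(0.0)

    def test_undefined_ri_reported_as_none(self, quartet_tree):
        m = CharacterMatrix(quartet_tree.taxa, (disc(0, 0, 0, 0),))
        assert ci_ri(m, quartet_tree).ri is None

    @pytest.mark.parametrize("seed", range(5))
    def test_per_character_bounds_hold(self, seed):
        rng = np.random.default_rng(seed)
        taxa = tuple(f"t{i}" for i in range(6))
        tree = random_topology(taxa, rng)
        cols = tuple(
            DiscreteColumn(tuple(frozenset({int(rng.integers(3))}) for _ in range(6)))
            for _ in range(6)
        ) + tuple(
            ContinuousColumn(tuple((float(v), float(v)) for v in rng.random(6)))
            for _ in range(2)
        )
        m = CharacterMatrix(taxa, cols)
        score = ci_ri(m, tree)
        for lo, mid, hi in zip(score.min_lengths, score.per_character, score.max_lengths):
            assert lo <= mid + 1e-9
            assert mid <= hi + 1e-9


# ---------------------------------------------------------------------------
# search


class TestSearch:
    def test_four_taxa_matches_exhaustive(self):
        taxa = ("A", "B", "C", "D")
        m = CharacterMatrix(taxa, (disc(0, 0, 1, 1), disc(0, 0, 1, 1), disc(0, 1, 0, 1)))
        best, length = hill_climb_search(m, n_starts=3, seed=0)
        ebest, elength = exhaustive_search(m)
        assert length == pytest.approx(elength)
        assert {t.clades() for t in best} == {t.clades() for t in ebest}

    def test_same_seed_identical_output(self):
        from paleokit.synthetic import CharacterSimConfig, simulate_characters

        m, _ = simulate_characters(
            CharacterSimConfig(n_taxa=6, n_discrete=30, n_continuous=3), 5
        )
        r1 = hill_climb_search(m, n_starts=4, seed=9)
        r2 = hill_climb_search(m, n_starts=4, seed=9)
        assert r1[1] == r2[1]
        assert [t.clades() for t in r1[0]] == [t.clades() for t in r2[0]]

    def test_too_few_taxa_rejected(self):
        m = CharacterMatrix(("A", "B", "C"), (disc(0, 1, 1),))
        with pytest.raises(ValueError, match="4 taxa"):
            hill_climb_search(m)
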