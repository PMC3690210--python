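import itertools
from collections import Counter

import numpy as np
import pytest

from famevol.evodist import DistanceMatrix
from famevol.grouping import (
    GeneGroup,
    classify_group,
    complex_subtype,
    group_stats,
    species_paralog_stats,
    split_tree,
    summarize_groups,
)
from famevol.phylo import Tree, TreeNode
from famevol.seq_io import SPECIES_CODES


def _matrix(ids, close_pairs=(), near=0.05, far=0.6):
    """Distance matrix where listed id-pairs are close and the rest far."""
    n = len(ids)
    vals = np.full((n, n), far)
    np.fill_diagonal(vals, 0.0)
    close = {frozenset(p) for p in close_pairs}
    for i, j in itertools.combinations(range(n), 2):
        if frozenset((ids[i], ids[j])) in close:
            vals[i, j] = vals[j, i] = near
    return DistanceMatrix(ids=list(ids), values=vals)


def _clade(names, support=None, length=0.01):
    return TreeNode(
        support=support,
        length=length,
        children=[TreeNode(name=n, length=length) for n in names],
    )


class TestSplitTree:
    def test_supported_tight_clade_accepted(self):
        names = [f"g{i}" for i in range(7)]
        tree = Tree(
            root=TreeNode(
                children=[_clade(names[:4], support=95), _clade(names[4:], support=96)]
            )
        )
        pairs = itertools.chain(
            itertools.combinations(names[:4], 2), itertools.combinations(names[4:], 2)
        )
        D = _matrix(names, close_pairs=list(pairs))
        groups, singles = split_tree(tree, D)
        assert sorted(len(g) for g in groups) == [3, 4]
        assert singles == []

    def test_low_support_descends_into_children(self):
        # outer clade support 79 (not > 80) -> recurse; inner pair qualifies
        inner = _clade(["a", "b"], support=99)
        outer = TreeNode(support=79, length=0.01, children=[inner, TreeNode(name="c", length=0.3)])
        tree = Tree(root=TreeNode(children=[outer, TreeNode(name="d", length=0.4)]))
        D = _matrix(["a", "b", "c", "d"], close_pairs=[("a", "b"), ("a", "c"), ("b", "c")])
        groups, singles = split_tree(tree, D)
        assert [g.members for g in groups] == [["a", "b"]]
        assert singles == ["c", "d"]

    def test_boundary_support_80_is_rejected(self):
        clade = _clade(["a", "b"], support=80)
        tree = Tree(root=TreeNode(children=[clade, TreeNode(name="c", length=0.3)]))
        D = _matrix(["a", "b", "c"], close_pairs=[("a", "b")])
        groups, singles = split_tree(tree, D)
        assert groups == [] and singles == ["a", "b", "c"]

    def test_divergent_star_yields_all_singletons(self):
        names = list("abcd")
        tree = Tree(root=TreeNode(children=[TreeNode(name=n, length=0.3) for n in names]))
        D = _matrix(names)  # all pairs far
        groups, singles = split_tree(tree, D)
        assert groups == [] and singles == names

    def test_leaf_matrix_mismatch_rejected(self):
        tree = Tree(root=_clade(["a", "b"]))
        with pytest.raises(ValueError, match="disagree"):
            split_tree(tree, _matrix(["a", "x"]))

    def test_accepted_groups_partition_disjointly(self, family, codon_aln, d_matrix):
        from famevol.phylo import bootstrap_tree

        tree = bootstrap_tree(codon_aln, "d", n_reps=50, seed=0)
        groups, singles = split_tree(tree, d_matrix)
        seen = [g for grp in groups for g in grp.members]
        assert len(seen) == len(set(seen))
        assert set(seen) | set(singles) == set(d_matrix.ids)

    def test_agrees_with_exhaustive_clade_enumeration(self):
        """Top-down acceptance equals the maximal elements of the set of
        all qualifying clades (brute-force oracle on a small tree)."""
        rng = np.random.default_rng(4)
        names = [f"g{i}" for i in range(8)]
        inner1 = _clade(names[:3], support=95)
        inner2 = _clade(names[3:5], support=85)
        mid = TreeNode(support=90, length=0.02, children=[inner1, inner2])
        tree = Tree(
            root=TreeNode(children=[mid, _clade(names[5:], support=70, length=0.3)])
        )
        vals = rng.uniform(0.01, 0.25, size=(8, 8))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0)
        D = DistanceMatrix(ids=names, values=vals)
        groups, _ = split_tree(tree, D, max_divergence=0.2, min_support=80)
        got = {frozenset(g.members) for g in groups}

        qualifying = []
        for node, leaves in Tree(root=tree.root).clades():
            if node.is_leaf or len(leaves) < 2:
                continue
            sup_ok = node.support is None or node.support > 80
            dmax = float(np.nanmax(D.pair_values(sorted(leaves))))
            if sup_ok and dmax < 0.2:
                qualifying.append(leaves)
        maximal = {
            s for s in qualifying if not any(s < t for t in qualifying)
        }
        assert got == maximal


class TestClassifyGroup:
    def _group(self, counts):
        members, species_of = [], {}
        k = 0
        for sp, c in zip(SPECIES_CODES, counts):
            for _ in range(c):
                members.append(f"m{k}")
                species_of[f"m{k}"] = sp
                k += 1
        return GeneGroup(group_id="g", members=members), species_of

    def test_one_per_species_is_orthologous(self):
        g, sp = self._group((1, 1, 1, 1, 1, 1, 1))
        assert classify_group(g, sp) == "orthologous"

    @pytest.mark.parametrize("counts", [(3, 4, 2, 1, 0, 0, 0), (0, 0, 0, 0, 0, 0, 6)])
    def test_multicopy_or_missing_species_is_complex(self, counts):
        g, sp = self._group(counts)
        assert classify_group(g, sp) == "complex"

    def test_unknown_species_rejected(self):
        g = GeneGroup(group_id="g", members=["x", "y"])
        with pytest.raises(ValueError, match="unknown species"):
            classify_group(g, {"x": "Hsa", "y": "Rat"})


class TestComplexSubtype:
    def _complex(self, counts, mean_d):
        g = GeneGroup(group_id="g", members=["m"] * sum(counts))
        g.gtype = "complex"
        g.species_counts = Counter(
            {sp: c for sp, c in zip(SPECIES_CODES, counts) if c}
        )
        g.mean_d = mean_d
        return g

    def test_within_species_duplicates_mean_recent_duplication(self):
        g = self._complex((1, 1, 2, 1, 1, 1, 1), mean_d=0.03)
        assert complex_subtype(g) == "recent_duplication"

    def test_missing_species_low_divergence_is_lineage_loss(self):
        g = self._complex((1, 1, 1, 1, 0, 1, 1), mean_d=0.05)
        assert complex_subtype(g) == "lineage_loss"

    def test_missing_species_high_divergence(self):
        g = self._complex((0, 1, 1, 1, 0, 0, 0), mean_d=0.23)
        assert complex_subtype(g) == "high_divergence"


class TestGroupStats:
    def _mats(self, ids, d, ka, ks):
        def dm(v):
            n = len(ids)
            vals = np.full((n, n), v, dtype=float)
            np.fill_diagonal(vals, 0)
            return DistanceMatrix(ids=list(ids), values=vals)

        return dm(d), dm(ka), dm(ks)

    def test_ratio_of_means_matches_published_rounding(self):
        ids = ["a", "b"]
        g = GeneGroup(group_id="g", members=ids)
        group_stats(g, *self._mats(ids, 0.035, 0.0364, 0.0305))
        assert g.kaks_ratio == pytest.approx(0.0364 / 0.0305)
        assert round(g.kaks_ratio, 4) == 1.1934

    def test_zero_ka_gives_zero_ratio(self):
        ids = ["a", "b"]
        g = GeneGroup(group_id="g", members=ids)
        group_stats(g, *self._mats(ids, 0.0149, 0.0, 0.0642))
        assert g.kaks_ratio == 0.0

    def test_identical_members_all_zero(self):
        ids = ["a", "b", "c"]
        g = GeneGroup(group_id="g", members=ids)
        group_stats(g, *self._mats(ids, 0.0, 0.0, 0.0))
        assert (g.mean_d, g.mean_Ka, g.mean_Ks, g.kaks_ratio) == (0, 0, 0, 0)

    def test_undefined_ratio_flagged_none(self):
        ids = ["a", "b"]
        g = GeneGroup(group_id="g", members=ids)
        group_stats(g, *self._mats(ids, 0.01, 0.02, 0.0))
        assert g.kaks_ratio is None

    def test_too_small_group_rejected(self):
        g = GeneGroup(group_id="g", members=["a"])
        with pytest.raises(ValueError, match="2 members"):
            group_stats(g, *self._mats(["a"], 0, 0, 0))


class TestSpeciesParalogStats:
    def test_direction_of_paralog_contrast(self, family, d_matrix):
        """Within-species paralog divergence far exceeds within-group
        divergence (different groups are deep splits)."""
        from famevol.evodist import distance_matrix

        aln = family.true_alignment()
        ka = distance_matrix(aln, "Ka")
        ks = distance_matrix(aln, "Ks")
        table = species_paralog_stats(family.gene_set, d_matrix, ka, ks)
        assert len(table) == 7
        within_group = []
        for members in family.true_groups.values():
            if len(members) >= 2:
                within_group.append(np.nanmean(d_matrix.pair_values(sorted(members))))
        assert table["d"].mean() > 3 * np.mean(within_group)

    def test_species_average_is_mean_of_species_rows(self, family, d_matrix):
        from famevol.evodist import distance_matrix

        aln = family.true_alignment()
        ka = distance_matrix(aln, "Ka")
        ks = distance_matrix(aln, "Ks")
        table = species_paralog_stats(family.gene_set, d_matrix, ka, ks)
        # the "average for all species" aggregation rule: plain mean of rows
        assert table["d"].mean() == pytest.approx(np.mean(table["d"].to_numpy()))


class TestSummarizeGroups:
    def _ortho_groups(self, k):
        out = []
        for i in range(k):
            g = GeneGroup(group_id=f"o{i}", members=[f"o{i}m{j}" for j in range(7)])
            g.gtype = "orthologous"
            g.species_counts = Counter({sp: 1 for sp in SPECIES_CODES})
            out.append(g)
        return out

    def test_orthologous_gene_count(self):
        s = summarize_groups(self._ortho_groups(14))
        assert s.genes_in_orthologous == 98

    def test_percentages(self):
        groups = self._ortho_groups(14)
        for i in range(20):
            g = GeneGroup(group_id=f"c{i}", members=[f"c{i}m{j}" for j in range(6)])
            g.gtype = "complex"
            g.species_counts = Counter({"Cja": 6})
            groups.append(g)
        # 98 ortho + 120 complex genes + 15 singletons = 233
        s = summarize_groups(groups, singletons=[f"s{i}" for i in range(15)])
        assert s.total_genes == 233
        assert s.pct_genes_orthologous == pytest.approx(100 * 98 / 233, abs=1e-9)
        assert s.pct_clades_orthologous == pytest.approx(100 * 14 / 34, abs=1e-9)

    def test_empty_input(self):
        s = summarize_groups([])
        assert s.total_genes == 0 and len(s.counts) == 0

    def test_grand_total_equals_member_sum(self, family, codon_aln, d_matrix):
        from famevol.phylo import bootstrap_tree

        tree = bootstrap_tree(codon_aln, "d", n_reps=50, seed=0)
        groups, singles = split_tree(tree, d_matrix)
        species_of = family.species_of()
        for g in groups:
            classify_group(g, species_of)
        s = summarize_groups(groups, singles)
        assert s.counts["total"].sum() == sum(len(g) for g in groups)
        assert s.total_genes == len(family.gene_set)
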