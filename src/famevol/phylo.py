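"""Neighbor-joining trees with bootstrap support.

The gene tree is built by Saitou & Nei's neighbor-joining (NJ) algorithm
from a pairwise distance matrix (here Jukes–Cantor divergence on the codon
alignment).  Clade stability is assessed by the nonparametric bootstrap:
alignment columns (codon columns, for codon alignments) are resampled with
replacement, a replicate tree is built from each resample, and each
internal edge of the original tree is annotated with the percentage of
replicate trees containing the same bipartition of the leaves.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import dendropy
import numpy as np

from .codon_alignment import Alignment
from .evodist import DistanceMatrix, _encode_rows, distance_matrix

logger = logging.getLogger(__name__)


class NewickError(ValueError):
    pass


@dataclass
class TreeNode:
    """Node of a (rooted-for-traversal) phylogenetic tree.

    ``length`` is the branch above the node; ``support`` (percent of
    bootstrap replicates) is defined only for internal edges.
    """

    name: str | None = None
    length: float | None = None
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def traverse(self) -> Iterator["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.traverse()

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.traverse() if n.is_leaf]


@dataclass
class Tree:
    """NJ topology with branch lengths and bootstrap supports.

    Unrooted; stored with an arbitrary root (the final NJ join) for
    traversal.
    """

    root: TreeNode

    @property
    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each canonicalised to the side that
        excludes the lexicographically smallest leaf."""
        all_leaves = frozenset(self.leaf_names)
        ref = min(all_leaves)
        out = set()
        for node in self.root.traverse():
            if node is self.root or node.is_leaf:
                continue
            side = frozenset(node.leaf_names())
            if ref in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                out.add(side)
        return out

    def clades(self) -> list[tuple[TreeNode, frozenset[str]]]:
        """Every node with its descendant leaf set (root included)."""
        return [(n, frozenset(n.leaf_names())) for n in self.root.traverse()]

    def path_distances(self) -> DistanceMatrix:
        """Leaf-to-leaf distances along the tree."""
        leaves = self.leaf_names
        idx = {name: i for i, name in enumerate(leaves)}
        n = len(leaves)
        vals = np.zeros((n, n))

        def walk(node: TreeNode) -> dict[int, float]:
            if node.is_leaf:
                below = {idx[node.name]: 0.0}
            else:
                child_maps = []
                for child in node.children:
                    m = walk(child)
                    length = child.length or 0.0
                    child_maps.append({k: v + length for k, v in m.items()})
                for a in range(len(child_maps)):
                    for b in range(a + 1, len(child_maps)):
                        for i, di in child_maps[a].items():
                            for j, dj in child_maps[b].items():
                                vals[i, j] = vals[j, i] = di + dj
                below = {k: v for m in child_maps for k, v in m.items()}
            return below

        walk(self.root)
        return DistanceMatrix(ids=leaves, values=vals, kind="path")


def nj_tree(D: DistanceMatrix) -> Tree:
    """Neighbor-joining (Saitou & Nei 1987) from a complete distance matrix.

    Iteratively joins the pair minimising
    ``Q(i,j) = (n-2) D(i,j) - sum_k D(i,k) - sum_k D(j,k)``; ties are broken
    by the lexicographically smallest index pair, so the result is
    deterministic.  Negative branch lengths are clamped to zero and the
    deficit logged.
    """
    n = len(D.ids)
    if n < 3:
        raise ValueError("neighbor-joining needs at least 3 taxa")
    if np.isnan(D.values).any():
        iu = np.triu_indices(n, k=1)
        bad = [
            (D.ids[i], D.ids[j])
            for i, j in zip(*iu)
            if np.isnan(D.values[i, j])
        ]
        raise ValueError(f"missing distances for pairs: {bad[:10]}")

    mat = D.values.astype(float).copy()
    nodes = [TreeNode(name=name) for name in D.ids]
    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        row_sums = mat.sum(axis=1)
        q = (m - 2) * mat - row_sums[:, None] - row_sums[None, :]
        q = np.minimum(q, q.T)  # enforce exact symmetry (float addition order)
        np.fill_diagonal(q, np.inf)
        # lexicographically smallest (i, j) among the minima
        ties = np.argwhere(q == q.min())
        i, j = min((int(min(a, b)), int(max(a, b))) for a, b in ties)
        dij = mat[i, j]
        li = 0.5 * dij + (row_sums[i] - row_sums[j]) / (2 * (m - 2))
        lj = dij - li
        new = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = clamp(li)
        nodes[j].length = clamp(lj)
        du = 0.5 * (mat[i] + mat[j] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        new_mat = np.zeros((m - 1, m - 1))
        new_mat[1:, 1:] = mat[np.ix_(keep, keep)]
        new_mat[0, 1:] = new_mat[1:, 0] = du[keep]
        mat = new_mat
        nodes = [new] + [nodes[k] for k in keep]

    a, b, c = nodes
    dab, dac, dbc = mat[0, 1], mat[0, 2], mat[1, 2]
    a.length = clamp(0.5 * (dab + dac - dbc))
    b.length = clamp(0.5 * (dab + dbc - dac))
    c.length = clamp(0.5 * (dac + dbc - dab))
    if deficit > 0:
        logger.debug("NJ clamped negative branch lengths; total deficit %.6g", deficit)
    # the topology is unrooted; midpoint rooting gives a deterministic
    # traversal root that never falls inside a tight cluster
    return midpoint_root(Tree(root=TreeNode(children=[a, b, c])))


def _parent_map(root: TreeNode) -> dict[int, TreeNode]:
    parents: dict[int, TreeNode] = {}
    for node in root.traverse():
        for child in node.children:
            parents[id(child)] = node
    return parents


def midpoint_root(tree: Tree) -> Tree:
    """Reroot at the midpoint of the longest leaf-to-leaf path."""
    leaves = [n for n in tree.root.traverse() if n.is_leaf]
    if len(leaves) < 3:
        return tree
    dm = tree.path_distances()
    vals = dm.values
    i, j = np.unravel_index(np.argmax(vals), vals.shape)
    diameter = float(vals[i, j])
    if diameter <= 0:
        return tree
    by_name = {n.name: n for n in leaves}
    a, b = by_name[dm.ids[i]], by_name[dm.ids[j]]

    # explicit b -> LCA -> a node path (the unrooted path between them)
    parents = _parent_map(tree.root)
    anc_a = [a]
    while parents.get(id(anc_a[-1])) is not None:
        anc_a.append(parents[id(anc_a[-1])])
    ids_a = {id(n): k for k, n in enumerate(anc_a)}
    chain_b = [b]
    while id(chain_b[-1]) not in ids_a:
        chain_b.append(parents[id(chain_b[-1])])
    lca_idx = ids_a[id(chain_b[-1])]
    path = chain_b + list(reversed(anc_a[:lca_idx]))  # b ... lca ... a

    half = diameter / 2.0
    cum = 0.0
    for u, v in zip(path, path[1:]):
        if parents.get(id(u)) is v:  # climbing: edge stored on u
            edge, child = (u.length or 0.0), u
            offset_from_child = half - cum  # u is the b-side (child) end
        else:  # descending: edge stored on v
            edge, child = (v.length or 0.0), v
            offset_from_child = edge - (half - cum)
        if cum + edge >= half - 1e-15:
            return _reroot_on_edge(tree, child, offset_from_child)
        cum += edge
    return tree  # numerically unreachable


def _reroot_on_edge(tree: Tree, child: TreeNode, dist_from_child: float) -> Tree:
    """Insert a new root on the edge above ``child``."""
    parents = _parent_map(tree.root)
    par = parents.get(id(child))
    if par is None:
        return tree
    edge = child.length or 0.0
    dist_from_child = min(max(dist_from_child, 0.0), edge)
    # chain from par up to the old root
    chain = [par]
    while parents.get(id(chain[-1])) is not None:
        chain.append(parents[id(chain[-1])])
    edge_lengths = [n.length or 0.0 for n in chain[:-1]]  # edge above each chain node
    supports = [n.support for n in chain[:-1]]
    # detach path edges
    par.children.remove(child)
    for lower, upper in zip(chain, chain[1:]):
        upper.children.remove(lower)
    # flip: each upper becomes a child of its former child
    for i, (lower, upper) in enumerate(zip(chain, chain[1:])):
        lower.children.append(upper)
        upper.length = edge_lengths[i]
        upper.support = supports[i]
    # splice out a degenerate old root (it kept a single child)
    old_root = chain[-1]
    if len(old_root.children) == 1 and len(chain) >= 2:
        below = chain[-2]
        only = old_root.children[0]
        below.children.remove(old_root)
        only.length = (only.length or 0.0) + (old_root.length or 0.0)
        below.children.append(only)
    child.length = dist_from_child
    par.length = edge - dist_from_child
    par.support = child.support
    new_root = TreeNode(children=[child, par])
    return Tree(root=new_root)


def _resample_columns(rng: np.random.Generator, n_units: int) -> np.ndarray:
    return rng.integers(0, n_units, size=n_units)


def _jc_from_encoded(enc: np.ndarray) -> np.ndarray:
    n = enc.shape[0]
    vals = np.zeros((n, n))
    valid = enc >= 0
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        sites = both.sum(axis=1).astype(float)
        diffs = ((enc[i] != enc[i + 1 :]) & both).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(sites > 0, diffs / np.maximum(sites, 1), np.nan)
            d = np.where(p < 0.75, -0.75 * np.log1p(-(4.0 / 3.0) * p), np.nan)
        vals[i, i + 1 :] = d
        vals[i + 1 :, i] = d
    return vals


def bootstrap_tree(
    aln: Alignment,
    kind: str = "d",
    n_reps: int = 1000,
    seed: int = 0,
) -> Tree:
    """NJ tree with bootstrap supports on its internal edges.

    Columns (codon columns for codon alignments) are resampled with
    replacement ``n_reps`` times; the support of each internal edge of the
    original-data tree is the percentage of replicate trees containing the
    same bipartition.  Replicates yielding saturated/missing distances are
    dropped and counted.  Replicate ``r`` uses an RNG substream derived
    from ``(seed, r)``, so results are reproducible and order-independent.
    """
    original = nj_tree(distance_matrix(aln, kind))
    if n_reps <= 0:
        return original

    unit = 3 if aln.alphabet == "codon" else 1
    n_units = aln.n_columns // unit
    counts: dict[frozenset[str], int] = {bp: 0 for bp in original.bipartitions()}
    dropped = 0
    use_fast = kind == "d"
    enc = _encode_rows(aln.rows) if use_fast else None
    if use_fast:
        enc = enc.reshape(len(aln.ids), n_units, unit)
    used = 0
    for r in range(n_reps):
        rng = np.random.default_rng([seed, r])
        cols = _resample_columns(rng, n_units)
        if use_fast:
            vals = _jc_from_encoded(enc[:, cols, :].reshape(len(aln.ids), -1))
            if np.isnan(vals).any():
                dropped += 1
                continue
            dm = DistanceMatrix(ids=list(aln.ids), values=vals, kind="d")
        else:
            rows = [
                "".join(row[c * unit : (c + 1) * unit] for c in cols)
                for row in aln.rows
            ]
            rep_aln = Alignment(ids=list(aln.ids), rows=rows, alphabet=aln.alphabet)
            dm = distance_matrix(rep_aln, kind)
            if np.isnan(dm.values).any():
                dropped += 1
                continue
        rep_bips = nj_tree(dm).bipartitions()
        used += 1
        for bp in counts:
            if bp in rep_bips:
                counts[bp] += 1
    if dropped:
        logger.info("bootstrap: dropped %d/%d replicates (saturation)", dropped, n_reps)
    all_leaves = frozenset(original.leaf_names)
    ref = min(all_leaves)
    for node in original.root.traverse():
        if node is original.root or node.is_leaf:
            continue
        side = frozenset(node.leaf_names())
        if ref in side:
            side = all_leaves - side
        if side in counts and used > 0:
            node.support = 100.0 * counts[side] / used
    return original


def _to_newick(node: TreeNode) -> str:
    if node.is_leaf:
        body = node.name or ""
    else:
        inner = ",".join(_to_newick(c) for c in node.children)
        label = "" if node.support is None else f"{node.support:.0f}"
        body = f"({inner}){label}"
    if node.length is not None:
        body += f":{node.length:.6f}"
    return body


def write_newick(tree: Tree, path: str | Path | None = None) -> str:
    """Serialise to Newick; supports become internal node labels."""
    s = _to_newick(tree.root) + ";"
    if path is not None:
        Path(path).write_text(s + "\n")
    return s


def read_newick(source: str | Path) -> Tree:
    """Parse a Newick string or file; internal node labels are read as
    bootstrap supports when numeric."""
    if isinstance(source, Path) or (isinstance(source, str) and Path(source).exists()):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        dtree = dendropy.Tree.get(
            file=io.StringIO(text), schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickError(f"malformed newick: {exc}") from exc

    def convert(dnode) -> TreeNode:
        children = [convert(c) for c in dnode.child_nodes()]
        if children:
            label = dnode.label
            support = None
            if label is not None:
                try:
                    support = float(label)
                except ValueError:
                    support = None
            return TreeNode(
                length=dnode.edge.length, support=support, children=children
            )
        name = dnode.taxon.label if dnode.taxon else dnode.label
        return TreeNode(name=name, length=dnode.edge.length)

    root = convert(dtree.seed_node)
    root.support = None
    return Tree(root=root)
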