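"""Splitting the gene tree into groups and classifying them.

A multigene family's tree decomposes into *orthologous groups* (clades
with exactly one copy from each study species — the signature of
single-copy conservation since the species' common ancestor) and *complex
groups* (clades where some species contributes no copy or several — the
signature of lineage-specific duplication and loss).  Groups are accepted
top-down as maximal clades satisfying a bootstrap-support threshold and a
within-clade divergence ceiling; leaves belonging to no accepted clade
remain singletons.

Complex groups subdivide further by mechanism:

* ``recent_duplication`` — some species contributes two or more copies
  (duplication after speciation);
* ``high_divergence`` — no within-species duplicates but unusually deep
  divergence (faster evolution or older origin);
* ``lineage_loss`` — one-per-species structure except that some species
  lost (or pseudogenised) their copy.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evodist import DistanceMatrix
from .phylo import Tree
from .seq_io import SPECIES_CODES, GeneSet


@dataclass
class GeneGroup:
    group_id: str
    members: list[str]
    gtype: str = "complex"  # orthologous | complex | singleton
    subtype: str = "none"  # recent_duplication | high_divergence | lineage_loss | none
    support: float | None = None
    mean_d: float | None = None
    mean_Ka: float | None = None
    mean_Ks: float | None = None
    kaks_ratio: float | None = None
    n_skipped_pairs: int = 0
    species_counts: Counter = field(default_factory=Counter)

    def __len__(self) -> int:
        return len(self.members)


def split_tree(
    tree: Tree,
    D: DistanceMatrix,
    max_divergence: float = 0.30,
    min_support: float = 80.0,
    min_size: int = 2,
) -> tuple[list[GeneGroup], list[str]]:
    """Decompose the tree into maximal acceptable clades plus singletons.

    A clade is accepted when its bootstrap support is strictly above
    ``min_support`` (edges without a support value — the root — pass
    vacuously), the maximum pairwise divergence among its members is
    strictly below ``max_divergence``, and it has at least ``min_size``
    leaves.  Acceptance is top-down: an accepted clade's descendants are
    not considered, so accepted groups are disjoint and maximal.
    """
    leaves = set(tree.leaf_names)
    if leaves != set(D.ids):
        raise ValueError("tree leaves and distance-matrix ids disagree")

    groups: list[GeneGroup] = []
    singletons: list[str] = []

    def max_pairwise(names: list[str]) -> float:
        vals = D.pair_values(names)
        return float(np.nanmax(vals)) if len(vals) else 0.0

    def visit(node) -> None:
        if node.is_leaf:
            singletons.append(node.name)
            return
        names = node.leaf_names()
        support_ok = node.support is None or node.support > min_support
        pair_vals = D.pair_values(names)
        has_missing = bool(np.isnan(pair_vals).any())
        div_ok = (not has_missing) and max_pairwise(names) < max_divergence
        if len(names) >= min_size and support_ok and div_ok:
            groups.append(
                GeneGroup(
                    group_id=f"group_{len(groups) + 1}",
                    members=sorted(names),
                    support=node.support,
                )
            )
            return
        for child in node.children:
            visit(child)

    visit(tree.root)
    return groups, sorted(singletons)


def classify_group(
    group: GeneGroup,
    species_of: Mapping[str, str],
    species: Sequence[str] = SPECIES_CODES,
) -> str:
    """``orthologous`` iff the members are exactly one per study species."""
    counts = Counter()
    for gid in group.members:
        sp = species_of[gid]
        if sp not in species:
            raise ValueError(f"{gid}: unknown species tag '{sp}'")
        counts[sp] += 1
    group.species_counts = counts
    if len(group.members) == 1:
        group.gtype = "singleton"
    elif all(counts.get(sp, 0) == 1 for sp in species):
        group.gtype = "orthologous"
    else:
        group.gtype = "complex"
    return group.gtype


def complex_subtype(group: GeneGroup, high_div_threshold: float = 0.10) -> str:
    """Assign the duplication/divergence/loss subtype of a complex group."""
    if group.gtype != "complex":
        raise ValueError("subtype is defined for complex groups only")
    if any(c >= 2 for c in group.species_counts.values()):
        group.subtype = "recent_duplication"
    elif group.mean_d is not None and group.mean_d >= high_div_threshold:
        group.subtype = "high_divergence"
    else:
        group.subtype = "lineage_loss"
    return group.subtype


def _pair_means(
    names: list[str],
    D_d: DistanceMatrix,
    D_Ka: DistanceMatrix,
    D_Ks: DistanceMatrix,
) -> tuple[float, float, float, float | None, int]:
    """Means over unordered pairs; saturated (NaN) pairs are skipped and
    counted.  The Ka/Ks ratio is the ratio of the means, not the mean of
    per-pair ratios (robust to pairs with Ks = 0)."""
    vals = {k: m.pair_values(names) for k, m in (("d", D_d), ("Ka", D_Ka), ("Ks", D_Ks))}
    skipped = int(max(np.isnan(v).sum() for v in vals.values()))

    def skipmean(v: np.ndarray) -> float:
        v = v[~np.isnan(v)]
        return float(v.mean()) if v.size else float("nan")

    mean_d = skipmean(vals["d"])
    mean_ka = skipmean(vals["Ka"])
    mean_ks = skipmean(vals["Ks"])
    if mean_ks > 0:
        ratio: float | None = mean_ka / mean_ks
    else:
        ratio = 0.0 if mean_ka == 0 else None  # undefined: Ka>0 with Ks=0
    return mean_d, mean_ka, mean_ks, ratio, skipped


def group_stats(
    group: GeneGroup,
    D_d: DistanceMatrix,
    D_Ka: DistanceMatrix,
    D_Ks: DistanceMatrix,
) -> GeneGroup:
    """Fill ``mean_d``, ``mean_Ka``, ``mean_Ks`` and the Ka/Ks ratio."""
    if len(group.members) < 2:
        raise ValueError(f"{group.group_id}: need at least 2 members for statistics")
    (
        group.mean_d,
        group.mean_Ka,
        group.mean_Ks,
        group.kaks_ratio,
        group.n_skipped_pairs,
    ) = _pair_means(group.members, D_d, D_Ka, D_Ks)
    return group


def species_paralog_stats(
    genes: GeneSet,
    D_d: DistanceMatrix,
    D_Ka: DistanceMatrix,
    D_Ks: DistanceMatrix,
) -> pd.DataFrame:
    """Within-species all-pairs means (the paralog contrast).

    One row per species with >= 2 copies: mean d, Ka, Ks over all
    unordered within-species pairs, plus the ratio of means.  Species with
    fewer than two copies are skipped with a note column absent from the
    output (they simply do not appear).
    """
    rows = []
    for sp in SPECIES_CODES:
        names = [r.gene_id for r in genes.by_species(sp) if r.gene_id in D_d.ids]
        if len(names) < 2:
            continue
        mean_d, mean_ka, mean_ks, ratio, skipped = _pair_means(names, D_d, D_Ka, D_Ks)
        rows.append(
            {
                "species": sp,
                "n_genes": len(names),
                "d": mean_d,
                "Ka": mean_ka,
                "Ks": mean_ks,
                "KaKs": ratio,
                "n_skipped_pairs": skipped,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class GroupSummary:
    """Copy-number bookkeeping across groups (the count matrix)."""

    counts: pd.DataFrame  # group x species, plus 'total' column
    n_orthologous: int
    n_complex: int
    n_singletons: int
    genes_in_orthologous: int
    genes_in_complex: int
    total_genes: int
    pct_genes_orthologous: float
    pct_clades_orthologous: float


def summarize_groups(
    groups: Sequence[GeneGroup], singletons: Sequence[str] = ()
) -> GroupSummary:
    """Count matrix and headline fractions over classified groups."""
    recs = []
    for g in groups:
        row = {"group": g.group_id, "gtype": g.gtype}
        row.update({sp: g.species_counts.get(sp, 0) for sp in SPECIES_CODES})
        row["total"] = len(g)
        recs.append(row)
    counts = pd.DataFrame(
        recs, columns=["group", "gtype", *SPECIES_CODES, "total"]
    )
    n_ortho = sum(1 for g in groups if g.gtype == "orthologous")
    n_complex = sum(1 for g in groups if g.gtype == "complex")
    genes_ortho = sum(len(g) for g in groups if g.gtype == "orthologous")
    genes_complex = sum(len(g) for g in groups if g.gtype == "complex")
    total_genes = sum(len(g) for g in groups) + len(singletons)
    n_clades = n_ortho + n_complex
    return GroupSummary(
        counts=counts,
        n_orthologous=n_ortho,
        n_complex=n_complex,
        n_singletons=len(singletons),
        genes_in_orthologous=genes_ortho,
        genes_in_complex=genes_complex,
        total_genes=total_genes,
        pct_genes_orthologous=100.0 * genes_ortho / total_genes if total_genes else 0.0,
        pct_clades_orthologous=100.0 * n_ortho / n_clades if n_clades else 0.0,
    )


def groups_table(groups: Sequence[GeneGroup]) -> pd.DataFrame:
    """Per-group statistics table (one row per group, 4-decimal style)."""
    rows = []
    for g in groups:
        rows.append(
            {
                "group": g.group_id,
                "gtype": g.gtype,
                "subtype": g.subtype,
                "n_members": len(g),
                "support": g.support,
                "d": g.mean_d,
                "Ka": g.mean_Ka,
                "Ks": g.mean_Ks,
                "KaKs": g.kaks_ratio,
            }
        )
    return pd.DataFrame(rows)
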