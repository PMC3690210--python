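"""End-to-end orchestration: from a gene set to the summary tables.

``run_all`` chains every stage — inclusion filter, codon alignment,
distances, bootstrap NJ tree, group splitting and classification, group
and per-species statistics, RSCU variation contrast, expression CV
contrast, pseudogene calls — and writes one output file per product.  All
arithmetic lives in the stage modules; this layer only sequences them and
serialises results (rounding happens at serialisation only: 4 decimals
for statistics, 3 for P-values).

``replay_tables`` drives the aggregation/testing layer directly from a
table of per-group statistics (for example the packaged published
reference rows), so the headline averages and Welch tests can be
reproduced without sequence data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import codon_usage, expression, grouping, pseudogene, reference_tables
from .codon_alignment import Alignment, backtranslate, read_alignment, restrict_to_domain
from .evodist import distance_matrix, pairwise_table
from .phylo import bootstrap_tree, write_newick
from .seq_io import GeneSet, filter_by_domain_length, read_gene_set
from .stats import welch_t_test

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Thresholds and switches of a full run."""

    seed: int = 0
    min_aa: int = 160
    max_divergence: float = 0.30
    min_support: float = 80.0
    min_size: int = 2
    high_div_threshold: float = 0.10
    min_len_pseudogene: int = 450
    n_bootstrap: int = 1000
    run_rscu: bool = True
    run_expression: bool = True
    run_pseudogene: bool = True

    def __post_init__(self) -> None:
        if min(self.min_aa, self.min_len_pseudogene, self.min_size) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class RunResult:
    """In-memory bundle of everything a run produced."""

    gene_set: GeneSet
    codon_aln: Alignment
    tree: object
    groups: list
    singletons: list[str]
    summary: grouping.GroupSummary
    group_table: pd.DataFrame
    species_table: pd.DataFrame
    comparisons: pd.DataFrame
    rscu_comparison: pd.DataFrame | None = None
    cv_contrast: pd.DataFrame | None = None
    pseudogene_calls: list = field(default_factory=list)
    paths: dict[str, Path] = field(default_factory=dict)


def _comparisons_table(group_table: pd.DataFrame) -> pd.DataFrame:
    """Welch tests of complex vs orthologous groups on d, Ka, Ks, Ka/Ks."""
    cx = group_table[group_table["gtype"] == "complex"]
    ortho = group_table[group_table["gtype"] == "orthologous"]
    rows = []
    for col in ("d", "Ka", "Ks", "KaKs"):
        x = cx[col].dropna().to_numpy()
        y = ortho[col].dropna().to_numpy()
        if len(x) < 2 or len(y) < 2:
            rows.append({"column": col, "skipped": True})
            continue
        res = welch_t_test(x, y)
        rows.append(
            {
                "column": col,
                "mean_complex": res.mean_x,
                "mean_orthologous": res.mean_y,
                "n_complex": res.n_x,
                "n_orthologous": res.n_y,
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "skipped": False,
            }
        )
    return pd.DataFrame(rows)


def analyze_gene_set(
    genes: GeneSet,
    protein_aln: Alignment,
    cfg: RunConfig,
) -> RunResult:
    """Run the sequence-level stages on an in-memory gene set."""
    filtered = filter_by_domain_length(genes, cfg.min_aa)
    keep = [g for g in protein_aln.ids if g in set(filtered.gene_ids)]
    protein_aln = protein_aln.subset(keep)
    codon_aln = backtranslate(protein_aln, {r.gene_id: r.cds for r in filtered})
    codon_aln = restrict_to_domain(
        codon_aln, {r.gene_id: r.domain_span for r in filtered}
    )

    d_mat = distance_matrix(codon_aln, "d")
    ka_mat = distance_matrix(codon_aln, "Ka")
    ks_mat = distance_matrix(codon_aln, "Ks")

    tree = bootstrap_tree(codon_aln, kind="d", n_reps=cfg.n_bootstrap, seed=cfg.seed)
    groups, singletons = grouping.split_tree(
        tree,
        d_mat,
        max_divergence=cfg.max_divergence,
        min_support=cfg.min_support,
        min_size=cfg.min_size,
    )
    species_of = {r.gene_id: r.species for r in filtered}
    for g in groups:
        grouping.classify_group(g, species_of)
        grouping.group_stats(g, d_mat, ka_mat, ks_mat)
        if g.gtype == "complex":
            grouping.complex_subtype(g, cfg.high_div_threshold)
    summary = grouping.summarize_groups(groups, singletons)
    group_table = grouping.groups_table(groups)
    species_table = grouping.species_paralog_stats(filtered, d_mat, ka_mat, ks_mat)
    comparisons = _comparisons_table(group_table)

    result = RunResult(
        gene_set=filtered,
        codon_aln=codon_aln,
        tree=tree,
        groups=groups,
        singletons=singletons,
        summary=summary,
        group_table=group_table,
        species_table=species_table,
        comparisons=comparisons,
    )

    if cfg.run_rscu:
        profiles = [
            codon_usage.rscu_profile(r.domain_cds, r.gene_id) for r in filtered
        ]
        grouped_ids = {g for grp in groups for g in grp.members}
        group_partition = {
            gid: grp.group_id for grp in groups for gid in grp.members
        }
        species_partition = {r.gene_id: r.species for r in filtered}
        gtab = codon_usage.variation_by_partition(
            [p for p in profiles if p.gene_id in grouped_ids], group_partition
        )
        stab = codon_usage.variation_by_partition(profiles, species_partition)
        result.rscu_comparison = codon_usage.compare_partitions(gtab, stab)
    return result


def run_all(indir: str | Path, outdir: str | Path, cfg: RunConfig) -> RunResult:
    """Run every enabled stage on an input directory and write outputs.

    Expects the file layout produced by :func:`famevol.simulate.emit_inputs`
    (or equivalently-shaped real data): ``cds.fasta``, ``metadata.tsv``,
    ``protein_alignment.fasta`` and optionally ``expression.tsv``,
    ``hits.tsv``, ``live_loci.tsv``.
    """
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genes = read_gene_set(indir / "cds.fasta", indir / "metadata.tsv")
    protein_aln = read_alignment(indir / "protein_alignment.fasta", "protein")
    result = analyze_gene_set(genes, protein_aln, cfg)

    if cfg.run_expression and (indir / "expression.tsv").exists():
        raw = pd.read_csv(indir / "expression.tsv", sep="\t")
        expr = expression.aggregate_probes(raw)
        groups_map = {g.group_id: g.members for g in result.groups}
        species_map = {r.gene_id: r.species for r in result.gene_set}
        contrast, cv_records = expression.cv_contrast(expr, groups_map, species_map)
        result.cv_contrast = contrast
        cv_records.to_csv(outdir / "cv_records.tsv", sep="\t", index=False, float_format="%.4f")
        contrast.to_csv(outdir / "cv_contrast.tsv", sep="\t", index=False, float_format="%.4f")

    if cfg.run_pseudogene and (indir / "hits.tsv").exists():
        hits = pseudogene.read_hit_table(indir / "hits.tsv")
        live_df = pd.read_csv(indir / "live_loci.tsv", sep="\t")
        live = [
            pseudogene.GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand)
            for r in live_df.itertuples(index=False)
        ]
        calls = pseudogene.call_pseudogenes(hits, live, min_len=cfg.min_len_pseudogene)
        result.pseudogene_calls = calls
        pseudogene.write_bed(calls, outdir / "pseudogenes.bed")

    _write_tables(result, outdir, cfg)
    return result


def _fmt(df: pd.DataFrame, path: Path, pcols: tuple[str, ...] = ("p",)) -> None:
    df = df.copy()
    for col in df.columns:
        if df[col].dtype.kind == "f":
            digits = 3 if col in pcols else 4
            df[col] = df[col].round(digits)
    df.to_csv(path, sep="\t", index=False)


def _write_tables(result: RunResult, outdir: Path, cfg: RunConfig) -> None:
    paths = result.paths
    # table1: per-group rows, average rows, per-species rows, species average
    gt = result.group_table.copy()

    def avg_row(label: str, gtype: str, sub: pd.DataFrame) -> pd.DataFrame:
        row = {c: np.nan for c in sub.columns}
        row.update(sub[["d", "Ka", "Ks", "KaKs"]].mean().to_dict())
        row["group"], row["gtype"] = label, gtype
        if "subtype" in sub.columns:
            row["subtype"] = ""
        return pd.DataFrame([row], columns=sub.columns)

    blocks = []
    for gtype in ("orthologous", "complex"):
        sub = gt[gt["gtype"] == gtype]
        if len(sub):
            blocks.append(sub)
            blocks.append(avg_row(f"Average for {gtype} groups", gtype, sub))
    st = result.species_table.copy()
    if len(st):
        st = st.rename(columns={"species": "group"})
        st["gtype"] = "species"
        blocks.append(st)
        blocks.append(avg_row("Average for all species", "species", st))
    if blocks:
        cols = list(dict.fromkeys(c for b in blocks for c in b.columns))
        rows = [rec for b in blocks for rec in b.to_dict("records")]
        table1 = pd.DataFrame(rows, columns=cols)
    else:
        table1 = pd.DataFrame()
    _fmt(table1, outdir / "table1.tsv")
    paths["table1"] = outdir / "table1.tsv"

    # table2: complex-group count matrix with totals
    counts = result.summary.counts
    cx = counts[counts["gtype"] == "complex"].drop(columns=["gtype"])
    if len(cx):
        totals = cx.drop(columns=["group"]).sum()
        cx = pd.concat(
            [cx, pd.DataFrame([{"group": "Total", **totals.to_dict()}])],
            ignore_index=True,
        )
    cx.to_csv(outdir / "table2.tsv", sep="\t", index=False)
    paths["table2"] = outdir / "table2.tsv"

    _fmt(result.comparisons, outdir / "comparisons.tsv")
    paths["comparisons"] = outdir / "comparisons.tsv"

    if result.rscu_comparison is not None:
        _fmt(result.rscu_comparison, outdir / "rscu_variation.tsv")
        paths["rscu_variation"] = outdir / "rscu_variation.tsv"

    write_newick(result.tree, outdir / "tree.nwk")
    paths["tree"] = outdir / "tree.nwk"

    rows = [
        {"gene_id": gid, "group": g.group_id, "gtype": g.gtype, "subtype": g.subtype}
        for g in result.groups
        for gid in g.members
    ] + [
        {"gene_id": gid, "group": "", "gtype": "singleton", "subtype": "none"}
        for gid in result.singletons
    ]
    pd.DataFrame(rows).to_csv(outdir / "groups.tsv", sep="\t", index=False)
    paths["groups"] = outdir / "groups.tsv"

    log = {"config": asdict(cfg)}
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    paths["log"] = outdir / "run_log.json"


def replay_tables(
    groups_tsv: str | Path | None = None,
) -> dict[str, object]:
    """Aggregate a per-group statistics table and run the four Welch tests.

    With no argument, the packaged published reference rows are used.  The
    table needs columns ``name/group, block/gtype, d, Ka, Ks, KaKs``.
    Returns the block means (``DataFrame``) and the test results.
    """
    if groups_tsv is None:
        t1 = reference_tables.load_reference_table1()
    else:
        t1 = pd.read_csv(groups_tsv, sep="\t")
        t1 = t1.rename(columns={"group": "name", "gtype": "block"})
    means = reference_tables.replay_block_means(t1)
    tests = reference_tables.replay_welch_tests(t1)
    return {"means": means, "tests": tests}
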