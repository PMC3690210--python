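"""Synthetic gene families with known ground truth.

The generator emulates the statistical structure a multigene-family
analysis assumes, so every pipeline stage can be exercised — and its
recovery measured — without genome downloads:

* a fixed seven-primate species tree (human, chimpanzee, gorilla,
  orangutan, gibbon, rhesus monkey, marmoset) with configurable branch
  lengths;
* *orthologous* groups: one gene per species, evolving along the species
  tree under strong purifying selection (low omega);
* *complex* groups: a birth–death process of duplication and loss inside
  the species tree, evolving under relaxed selection (higher omega);
* deep splits between groups: every group root descends from one family
  ancestor, is recoded with group-specific synonymous-codon preferences
  (group-structured RSCU) and then diverged along a deep branch — so
  between-group divergence is far above the within-group level but below
  Jukes–Cantor saturation;
* pseudogenised copies: complex-group tips that are dropped from the live
  gene set, given a frameshifting 1–2 bp deletion or a premature stop,
  and planted in the homology hit table;
* group-structured tissue expression for the two species with array data
  (human, chimpanzee): log-normal group-by-tissue baselines with small
  within-group scatter, yielding low ortholog CVs and high paralog CVs.

Sequence evolution is a proposal/acceptance scheme: single-base changes
are proposed uniformly over sites (transitions weighted by kappa),
stop-creating changes are rejected, synonymous changes always accepted,
nonsynonymous ones accepted with probability omega.  Branch lengths are
therefore in *mutation-opportunity* units (expected proposals per site);
realised divergence is lower under selection.  This matches the
assumptions of the Nei–Gojobori estimator by construction, which is what
makes the generator a fair null for estimator-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .codon_alignment import Alignment
from .evodist import CODON_TO_AA, SENSE_CODONS, STOP_CODONS
from .phylo import Tree, TreeNode, read_newick
from .pseudogene import GenomicInterval, HitRecord
from .seq_io import SPECIES_CODES, GeneRecord, GeneSet, translate_cds, write_fasta, write_metadata

#: Seven-taxon species tree; branch lengths in mutation-opportunity units.
DEFAULT_SPECIES_TREE = (
    "((((((Hsa:0.015,Ptr:0.015):0.010,Ggo:0.025):0.015,Ppy:0.040):0.010,"
    "Nle:0.050):0.015,Mmu:0.065):0.015,Cja:0.080);"
)

_AA_BY_CODON = CODON_TO_AA
_SYN_FAMILY: dict[str, list[str]] = {}
for _c in SENSE_CODONS:
    _SYN_FAMILY.setdefault(_AA_BY_CODON[_c], []).append(_c)
_AMINO_ACIDS = sorted(_SYN_FAMILY)


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults define the standard test family."""

    seed: int = 0
    species_tree: str = DEFAULT_SPECIES_TREE
    n_ortho_groups: int = 5
    n_complex_groups: int = 5
    dup_rate: float = 8.0  # duplications per lineage per unit branch length
    loss_rate: float = 4.0
    length_codons: int = 376  # a typical actin-fold domain length
    omega_ortho: float = 0.1
    omega_complex: float = 0.4
    omega_deep: float = 0.8  # relaxed selection on the deep between-group branches
    kappa: float = 1.0  # ts/tv proposal bias; 1 = pathway-uniform
    deep_branch_length: float = 0.25  # family ancestor -> each group root
    pseudogene_prob: float = 0.15  # per complex-group tip
    codon_pref_alpha: float = 0.3  # Dirichlet concentration of group codon preferences
    expression_species: tuple[str, ...] = ("Hsa", "Ptr")
    expression_base_level: float = 100.0
    expression_between_group_sd: float = 1.5  # log-scale
    expression_within_group_sd: float = 0.15  # log-scale
    expression_noise_sd: float = 0.05
    n_samples_per_tissue: int = 3
    max_retries: int = 200

    def __post_init__(self) -> None:
        if self.length_codons < 50:
            raise ValueError("length_codons must be >= 50")
        if min(self.dup_rate, self.loss_rate) < 0:
            raise ValueError("rates must be non-negative")
        for w in (self.omega_ortho, self.omega_complex, self.omega_deep):
            if not 0 < w:
                raise ValueError("omega must be positive")


@dataclass
class SimulatedFamily:
    """A generated family plus everything needed to score recovery."""

    config: SimulationConfig
    gene_set: GeneSet
    true_groups: dict[str, list[str]]  # group id -> live member gene ids
    true_types: dict[str, str]  # group id -> orthologous|complex|singleton
    true_trees: dict[str, Tree]
    event_log: list[dict]
    expression_long: pd.DataFrame
    hit_records: list[HitRecord]
    live_loci: list[GenomicInterval]
    pseudogene_seqs: dict[str, str]
    pseudogene_loci: dict[str, GenomicInterval]

    def true_alignment(self) -> Alignment:
        """The true (indel-free) codon alignment of the live genes."""
        return Alignment(
            ids=[r.gene_id for r in self.gene_set],
            rows=[r.cds for r in self.gene_set],
            alphabet="codon",
        )

    def species_of(self) -> dict[str, str]:
        return {r.gene_id: r.species for r in self.gene_set}


# ---------------------------------------------------------------------------
# sequence evolution


def random_codon_seq(
    n_codons: int,
    rng: np.random.Generator,
    codon_weights: dict[str, np.ndarray] | None = None,
    protein: str | None = None,
) -> list[str]:
    """Draw a stop-free codon sequence.

    If ``protein`` is given, codons are drawn per residue; otherwise the
    protein is drawn uniformly over amino acids first.  ``codon_weights``
    maps amino acid -> probability vector over its synonymous codons.
    """
    if protein is None:
        protein = "".join(rng.choice(_AMINO_ACIDS, size=n_codons))
    codons = []
    for aa in protein:
        fam = _SYN_FAMILY[aa]
        if codon_weights is not None:
            codons.append(str(rng.choice(fam, p=codon_weights[aa])))
        else:
            codons.append(str(rng.choice(fam)))
    return codons


def evolve_codon_seq(
    codons: list[str],
    t: float,
    omega: float,
    kappa: float,
    rng: np.random.Generator,
) -> list[str]:
    """Evolve a codon sequence for branch length ``t`` (proposals/site).

    Proposal: uniform site, alternative base with transition weight
    ``kappa`` and transversion weight 1.  Stop-creating proposals are
    rejected; synonymous ones accepted; nonsynonymous accepted with
    probability ``omega``.
    """
    transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
    bases = "ACGT"
    seq = list(codons)
    n_sites = 3 * len(seq)
    n_prop = rng.poisson(t * n_sites)
    for _ in range(n_prop):
        site = int(rng.integers(n_sites))
        ci, pos = divmod(site, 3)
        old_codon = seq[ci]
        old_base = old_codon[pos]
        alts = [b for b in bases if b != old_base]
        weights = np.array([kappa if transitions[old_base] == b else 1.0 for b in alts])
        new_base = str(rng.choice(alts, p=weights / weights.sum()))
        new_codon = old_codon[:pos] + new_base + old_codon[pos + 1 :]
        if new_codon in STOP_CODONS:
            continue
        if _AA_BY_CODON[new_codon] != _AA_BY_CODON[old_codon]:
            if rng.random() >= omega:
                continue
        seq[ci] = new_codon
    return seq


def simulate_omega_pair(
    n_codons: int, t: float, omega: float, seed: int, kappa: float = 1.0
) -> tuple[str, str]:
    """Two sequences diverged from a common ancestor by ``t`` per branch.

    A minimal fixture for estimator-recovery checks.
    """
    rng = np.random.default_rng(seed)
    anc = random_codon_seq(n_codons, rng)
    a = evolve_codon_seq(anc, t, omega, kappa, rng)
    b = evolve_codon_seq(anc, t, omega, kappa, rng)
    return "".join(a), "".join(b)


def evolve_jc(seq: str, t: float, rng: np.random.Generator) -> str:
    """Neutral Jukes–Cantor evolution of a plain nucleotide sequence
    (expected ``t`` substitutions per site; multiple hits allowed)."""
    bases = "ACGT"
    arr = list(seq)
    n_sub = rng.poisson(t * len(arr))
    for _ in range(n_sub):
        site = int(rng.integers(len(arr)))
        arr[site] = str(rng.choice([b for b in bases if b != arr[site]]))
    return "".join(arr)


# ---------------------------------------------------------------------------
# gene-tree simulation


def _sim_gene_subtree(
    sp_node: TreeNode,
    remaining: float,
    dup_rate: float,
    loss_rate: float,
    rng: np.random.Generator,
    events: list[str],
) -> TreeNode | None:
    """One gene lineage entering a species-tree branch with ``remaining``
    time left on it.  Returns the surviving gene subtree or ``None``."""
    elapsed = 0.0
    while True:
        total = dup_rate + loss_rate
        wait = rng.exponential(1.0 / total) if total > 0 else np.inf
        if wait >= remaining:
            break
        remaining -= wait
        elapsed += wait
        if rng.random() < dup_rate / total:
            events.append("duplication")
            left = _sim_gene_subtree(sp_node, remaining, dup_rate, loss_rate, rng, events)
            right = _sim_gene_subtree(sp_node, remaining, dup_rate, loss_rate, rng, events)
            kids = [k for k in (left, right) if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                kids[0].length = (kids[0].length or 0.0) + elapsed
                return kids[0]
            return TreeNode(length=elapsed, children=kids)
        events.append("loss")
        return None
    # reached the end of the species branch
    if sp_node.is_leaf:
        return TreeNode(name=sp_node.name, length=elapsed + remaining)
    kids = []
    for child in sp_node.children:
        sub = _sim_gene_subtree(
            child, child.length or 0.0, dup_rate, loss_rate, rng, events
        )
        if sub is not None:
            kids.append(sub)
    if not kids:
        return None
    if len(kids) == 1:
        kids[0].length = (kids[0].length or 0.0) + elapsed + remaining
        return kids[0]
    return TreeNode(length=elapsed + remaining, children=kids)


def _tip_species_counts(root: TreeNode) -> dict[str, int]:
    counts: dict[str, int] = {}
    for node in root.traverse():
        if node.is_leaf:
            counts[node.name] = counts.get(node.name, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# the generator


def simulate_family(cfg: SimulationConfig) -> SimulatedFamily:
    """Generate a family; deterministic for a fixed ``cfg.seed``.

    Named RNG substreams (trees / sequences / pseudogenes / expression)
    keep the stages independently reproducible.
    """
    rng_trees = np.random.default_rng([cfg.seed, 1])
    rng_seq = np.random.default_rng([cfg.seed, 2])
    rng_pseudo = np.random.default_rng([cfg.seed, 3])
    rng_expr = np.random.default_rng([cfg.seed, 4])

    species_tree = read_newick(cfg.species_tree)
    events_log: list[dict] = []

    # family ancestor protein shared by all groups (they are homologs)
    anc_protein = "".join(rng_seq.choice(_AMINO_ACIDS, size=cfg.length_codons))

    group_specs: list[tuple[str, str]] = [
        (f"og{i + 1}", "orthologous") for i in range(cfg.n_ortho_groups)
    ] + [(f"cg{i + 1}", "complex") for i in range(cfg.n_complex_groups)]

    records: list[GeneRecord] = []
    true_groups: dict[str, list[str]] = {}
    true_types: dict[str, str] = {}
    true_trees: dict[str, Tree] = {}
    pseudo_seqs: dict[str, str] = {}
    pseudo_parent_group: dict[str, str] = {}

    for group_id, gtype in group_specs:
        is_complex = gtype == "complex"
        dup = cfg.dup_rate if is_complex else 0.0
        loss = cfg.loss_rate if is_complex else 0.0
        omega = cfg.omega_complex if is_complex else cfg.omega_ortho

        # topology: retry until the realised family is usable (and, for
        # complex groups, actually complex)
        root = None
        for _ in range(cfg.max_retries):
            events: list[str] = []
            cand = _sim_gene_subtree(
                species_tree.root, 0.0, dup, loss, rng_trees, events
            )
            if cand is None:
                continue
            counts = _tip_species_counts(cand)
            n_tips = sum(counts.values())
            if not is_complex:
                root = cand
                break
            one_per_species = all(counts.get(sp, 0) == 1 for sp in SPECIES_CODES)
            if n_tips >= 2 and not one_per_species:
                root = cand
                break
        if root is None:
            raise RuntimeError(
                f"{group_id}: no usable gene tree after {cfg.max_retries} tries "
                "(rates extinguish every lineage?)"
            )
        events_log.append(
            {
                "group": group_id,
                "gtype": gtype,
                "n_duplications": events.count("duplication"),
                "n_losses": events.count("loss"),
            }
        )

        # unique tip labels per group
        seen: dict[str, int] = {}
        for node in root.traverse():
            if node.is_leaf:
                sp = node.name
                seen[sp] = seen.get(sp, 0) + 1
                node.name = f"{group_id}_{sp}" + (
                    f"_{seen[sp]}" if is_complex else ""
                )
        true_trees[group_id] = Tree(root=root)

        # group root sequence: group-specific codon preferences on the
        # shared ancestral protein, then a deep divergent branch
        weights = {
            aa: rng_seq.dirichlet(np.full(len(fam), cfg.codon_pref_alpha))
            for aa, fam in _SYN_FAMILY.items()
        }
        group_root = random_codon_seq(
            cfg.length_codons, rng_seq, codon_weights=weights, protein=anc_protein
        )
        group_root = evolve_codon_seq(
            group_root, cfg.deep_branch_length, cfg.omega_deep, cfg.kappa, rng_seq
        )

        # evolve down the gene tree
        tip_seqs: dict[str, list[str]] = {}

        def down(node: TreeNode, seq: list[str]) -> None:
            seq = evolve_codon_seq(seq, node.length or 0.0, omega, cfg.kappa, rng_seq)
            if node.is_leaf:
                tip_seqs[node.name] = seq
            else:
                for child in node.children:
                    down(child, seq)

        down(root, group_root)

        members: list[str] = []
        for gid in sorted(tip_seqs):
            cds_codons = tip_seqs[gid]
            if is_complex and rng_pseudo.random() < cfg.pseudogene_prob:
                pseudo_seqs[gid] = _disable(cds_codons, rng_pseudo, events_log, gid)
                pseudo_parent_group[gid] = group_id
                continue
            cds = "".join(cds_codons)
            sp = gid.split("_")[1]
            records.append(
                GeneRecord(
                    gene_id=gid,
                    species=sp,
                    cds=cds,
                    protein=translate_cds(cds),
                    domain_span=(0, cfg.length_codons),
                )
            )
            members.append(gid)
        if members:
            true_groups[group_id] = members
            if len(members) == 1:
                true_types[group_id] = "singleton"
            else:
                counts = {}
                for gid in members:
                    sp = gid.split("_")[1]
                    counts[sp] = counts.get(sp, 0) + 1
                one_each = all(counts.get(sp, 0) == 1 for sp in SPECIES_CODES)
                true_types[group_id] = "orthologous" if one_each else "complex"

    gene_set = GeneSet(records=records, provenance=f"simulate_family(seed={cfg.seed})")

    live_loci, hit_records, pseudo_loci = _layout_genome(
        gene_set, pseudo_seqs, pseudo_parent_group, cfg, rng_pseudo
    )
    expression = _simulate_expression(gene_set, true_groups, cfg, rng_expr)

    return SimulatedFamily(
        config=cfg,
        gene_set=gene_set,
        true_groups=true_groups,
        true_types=true_types,
        true_trees=true_trees,
        event_log=events_log,
        expression_long=expression,
        hit_records=hit_records,
        live_loci=live_loci,
        pseudogene_seqs=pseudo_seqs,
        pseudogene_loci=pseudo_loci,
    )


def _disable(
    codons: list[str], rng: np.random.Generator, log: list[dict], gid: str
) -> str:
    """Inject a pseudogenising lesion: 1–2 bp deletion or premature stop."""
    seq = "".join(codons)
    if rng.random() < 0.5:
        k = int(rng.integers(1, 3))  # 1 or 2 bp
        pos = int(rng.integers(3, len(seq) - 3 - k))
        seq = seq[:pos] + seq[pos + k :]
        log.append({"group": gid, "gtype": "pseudogene", "lesion": f"del{k}bp"})
    else:
        ci = int(rng.integers(1, len(codons) - 1))
        stop = str(rng.choice(sorted(STOP_CODONS)))
        seq = seq[: 3 * ci] + stop + seq[3 * ci + 3 :]
        log.append({"group": gid, "gtype": "pseudogene", "lesion": "premature_stop"})
    return seq


def _layout_genome(
    gene_set: GeneSet,
    pseudo_seqs: dict[str, str],
    pseudo_parent_group: dict[str, str],
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[GenomicInterval], list[HitRecord], dict[str, GenomicInterval]]:
    """Place live genes and pseudogenes on one synthetic contig per
    species and fabricate the homology hit table the pseudogene stage
    consumes: self-hits at live loci, full-length hits at pseudogene loci,
    and sub-450 bp spurious fragments in intergenic space."""
    gap = 1000
    cursors: dict[str, int] = {sp: gap for sp in SPECIES_CODES}
    live_loci: list[GenomicInterval] = []
    hits: list[HitRecord] = []
    locus_of: dict[str, GenomicInterval] = {}
    for rec in gene_set:
        chrom = f"chr{rec.species}"
        start = cursors[rec.species]
        iv = GenomicInterval(chrom, start, start + len(rec.cds), "+")
        cursors[rec.species] = iv.end + gap
        live_loci.append(iv)
        locus_of[rec.gene_id] = iv
        hits.append(HitRecord(query_id=rec.gene_id, interval=iv))

    pseudo_loci: dict[str, GenomicInterval] = {}
    for gid in sorted(pseudo_seqs):
        sp = gid.split("_")[1]
        chrom = f"chr{sp}"
        start = cursors[sp]
        strand = "+" if rng.random() < 0.5 else "-"
        iv = GenomicInterval(chrom, start, start + len(pseudo_seqs[gid]), strand)
        cursors[sp] = iv.end + gap
        pseudo_loci[gid] = iv
        # a pseudogene is found by its closest live relatives
        group = pseudo_parent_group[gid]
        queries = [r.gene_id for r in gene_set if r.gene_id.startswith(group + "_")]
        query = queries[0] if queries else gene_set.gene_ids[0]
        hits.append(HitRecord(query_id=query, interval=iv, identity=90.0))

    # spurious short fragments, below any sensible length threshold
    for sp in SPECIES_CODES:
        for _ in range(2):
            start = cursors[sp]
            frag = int(rng.integers(60, 449))
            iv = GenomicInterval(f"chr{sp}", start, start + frag, "+")
            cursors[sp] = iv.end + gap
            hits.append(HitRecord(query_id=gene_set.gene_ids[0], interval=iv, identity=85.0))
    return live_loci, hits, pseudo_loci


def _simulate_expression(
    gene_set: GeneSet,
    true_groups: dict[str, list[str]],
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Long (gene, probe, sample, tissue, value) table for the expression
    species, with log-normal group baselines and within-group scatter."""
    from .expression import TISSUES

    group_of = {g: gid for gid, members in true_groups.items() for g in members}
    baselines: dict[tuple[str, str], float] = {}
    rows = []
    for rec in gene_set:
        if rec.species not in cfg.expression_species:
            continue
        gid = group_of.get(rec.gene_id)
        if gid is None:
            continue
        n_probes = int(rng.integers(1, 3))
        for tissue in TISSUES:
            key = (gid, tissue)
            if key not in baselines:
                baselines[key] = cfg.expression_base_level * float(
                    np.exp(rng.normal(0.0, cfg.expression_between_group_sd))
                )
            gene_mean = baselines[key] * float(
                np.exp(rng.normal(0.0, cfg.expression_within_group_sd))
            )
            for probe in range(n_probes):
                for sample in range(cfg.n_samples_per_tissue):
                    value = gene_mean * float(
                        np.exp(rng.normal(0.0, cfg.expression_noise_sd))
                    )
                    rows.append(
                        {
                            "gene": rec.gene_id,
                            "probe": f"{rec.gene_id}_p{probe + 1}",
                            "sample": f"{tissue}_s{sample + 1}",
                            "tissue": tissue,
                            "value": value,
                        }
                    )
    return pd.DataFrame(rows, columns=["gene", "probe", "sample", "tissue", "value"])


def emit_inputs(fam: SimulatedFamily, outdir: str | Path) -> dict[str, Path]:
    """Write every input file the analysis modules consume, plus truth.

    Returns a name -> path map.  All formats are the plain-text ones the
    rest of the package reads back (FASTA / TSV).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def p(name: str) -> Path:
        paths[name] = outdir / name
        return paths[name]

    write_fasta(((r.gene_id, r.cds) for r in fam.gene_set), p("cds.fasta"))
    write_fasta(((r.gene_id, r.protein) for r in fam.gene_set), p("protein.fasta"))
    write_metadata(fam.gene_set, p("metadata.tsv"))
    # live genes are indel-free, so the true protein alignment is ungapped
    write_fasta(
        ((r.gene_id, r.protein) for r in fam.gene_set), p("protein_alignment.fasta")
    )
    fam.expression_long.to_csv(p("expression.tsv"), sep="\t", index=False)

    hit_rows = [
        {
            "query": h.query_id,
            "chrom": h.interval.chrom,
            "start": h.interval.start,
            "end": h.interval.end,
            "strand": h.interval.strand,
            "identity": h.identity,
            "bit_score": h.bit_score,
        }
        for h in fam.hit_records
    ]
    pd.DataFrame(hit_rows).to_csv(p("hits.tsv"), sep="\t", index=False)
    live_rows = [
        {"chrom": iv.chrom, "start": iv.start, "end": iv.end, "strand": iv.strand}
        for iv in fam.live_loci
    ]
    pd.DataFrame(live_rows).to_csv(p("live_loci.tsv"), sep="\t", index=False)
    if fam.pseudogene_seqs:
        write_fasta(sorted(fam.pseudogene_seqs.items()), p("pseudogenes.fasta"))

    truth_rows = []
    for gid, members in fam.true_groups.items():
        for g in members:
            truth_rows.append(
                {"gene_id": g, "true_group": gid, "true_type": fam.true_types[gid]}
            )
    for g in fam.pseudogene_seqs:
        truth_rows.append({"gene_id": g, "true_group": "", "true_type": "pseudogene"})
    pd.DataFrame(truth_rows).to_csv(p("truth.tsv"), sep="\t", index=False)
    return paths
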