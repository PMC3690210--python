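"""Relative synonymous codon usage (RSCU) and its variation contrast.

RSCU for codon *j* of amino acid *i* is the observed count divided by the
count expected if all of that amino acid's codons were used equally:
``RSCU_ij = x_ij * n_i / sum_k x_ik``.  Values below/above 1 mark codons
used less/more than average.  The single-codon amino acids (ATG/Met,
TGG/Trp) and the three stop codons are uninformative, leaving 59 relevant
codons.

Codon-usage *pattern* similarity is compared between two partitions of the
same genes — tree groups (orthologs across species) versus genomes
(paralogs within species) — by computing, per codon, the variation of the
RSCU values within each partition cell and contrasting the two sets of
cell variations with a Welch t-test.  Low within-group variation with high
within-species variation indicates that codon usage tracks gene identity
across species rather than genome-wide mutational pressure.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evodist import CODON_TO_AA, SENSE_CODONS
from .stats import welch_t_test

#: The 59 informative codons: sense codons minus the single-codon amino
#: acids ATG (Met) and TGG (Trp).
RSCU_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if c not in ("ATG", "TGG")
)

_SYN_FAMILY: dict[str, list[str]] = {}
for _c in SENSE_CODONS:
    _SYN_FAMILY.setdefault(CODON_TO_AA[_c], []).append(_c)


@dataclass
class RSCUProfile:
    """Per-gene RSCU vector over the 59 informative codons.

    Codons of amino acids absent from the gene are ``NaN`` (missing), not
    zero: absence carries no usage-bias signal.
    """

    gene_id: str
    values: pd.Series  # indexed by RSCU_CODONS, NaN = missing


def rscu_profile(cds: str, gene_id: str = "") -> RSCUProfile:
    """RSCU values for one (domain-restricted) CDS.

    Codons containing non-ACGT characters and stop codons are ignored in
    the counts.  For every amino acid present, the mean RSCU over its
    codons is exactly 1.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    counts: Counter[str] = Counter(
        cds[i : i + 3] for i in range(0, len(cds), 3)
    )
    values = {}
    for aa, codons in _SYN_FAMILY.items():
        if aa in ("M", "W"):
            continue
        total = sum(counts.get(c, 0) for c in codons)
        n_i = len(codons)
        for c in codons:
            values[c] = counts.get(c, 0) * n_i / total if total > 0 else np.nan
    series = pd.Series(values).reindex(list(RSCU_CODONS))
    return RSCUProfile(gene_id=gene_id, values=series)


def rscu_matrix(profiles: Sequence[RSCUProfile]) -> pd.DataFrame:
    """Genes x 59-codon matrix of RSCU values."""
    return pd.DataFrame(
        {p.gene_id: p.values for p in profiles}
    ).T.reindex(columns=list(RSCU_CODONS))


def variation_by_partition(
    profiles: Sequence[RSCUProfile],
    partition: Mapping[str, str],
    measure: str = "variance",
) -> pd.DataFrame:
    """Per-cell, per-codon variation of RSCU values.

    ``partition`` maps every gene id to its cell label (a group id or a
    species tag).  The variation measure is the sample variance (default)
    or sample SD; cells with fewer than two present values at a codon are
    missing there.  Returns a cells x codons frame.
    """
    if measure not in ("variance", "sd"):
        raise ValueError("measure must be 'variance' or 'sd'")
    mat = rscu_matrix(profiles)
    unassigned = [g for g in mat.index if g not in partition]
    if unassigned:
        raise ValueError(f"genes missing from partition: {unassigned[:5]}")
    cells = mat.groupby(pd.Series({g: partition[g] for g in mat.index}))
    var = cells.var(ddof=1)  # pandas: NaN when fewer than 2 present values
    counts = cells.count()
    var = var.where(counts >= 2)
    return np.sqrt(var) if measure == "sd" else var


def compare_partitions(
    groups_table: pd.DataFrame, species_table: pd.DataFrame
) -> pd.DataFrame:
    """Per-codon Welch test: species-cell variations vs group-cell ones.

    For each of the 59 codons, the collection of per-species variation
    values is tested against the collection of per-group values
    (two-tailed).  Codons with fewer than two usable cells on either side
    are skipped.  Returns one row per codon with the two means, t, df, P.
    """
    rows = []
    for codon in RSCU_CODONS:
        gv = groups_table[codon].dropna().to_numpy() if codon in groups_table else np.array([])
        sv = species_table[codon].dropna().to_numpy() if codon in species_table else np.array([])
        if len(gv) < 2 or len(sv) < 2:
            rows.append(
                {
                    "codon": codon,
                    "amino_acid": CODON_TO_AA[codon],
                    "mean_groups": np.nan,
                    "mean_species": np.nan,
                    "t": np.nan,
                    "df": np.nan,
                    "p": np.nan,
                    "skipped": True,
                }
            )
            continue
        res = welch_t_test(sv, gv)
        rows.append(
            {
                "codon": codon,
                "amino_acid": CODON_TO_AA[codon],
                "mean_groups": float(gv.mean()),
                "mean_species": float(sv.mean()),
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "skipped": False,
            }
        )
    return pd.DataFrame(rows)
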