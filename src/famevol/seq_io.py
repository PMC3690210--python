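"""Sequence I/O and the gene-inclusion filter.

A gene family analysis starts from per-species coding sequences (CDS),
their protein translations, and the span of the shared conserved domain
within each protein.  This module reads/writes FASTA, joins sequences with
a metadata table (species tag + domain span), enforces CDS/protein
consistency, and applies the domain-length inclusion filter: copies whose
conserved domain is shorter than 160 aa carry too little alignable signal
and are excluded before any comparative analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Three-letter tags for the seven study species (human, chimpanzee,
#: gorilla, orangutan, gibbon, rhesus monkey, marmoset).
SPECIES_CODES = ("Hsa", "Ptr", "Ggo", "Ppy", "Nle", "Mmu", "Cja")

SPECIES_NAMES = {
    "Hsa": "Homo sapiens",
    "Ptr": "Pan troglodytes",
    "Ggo": "Gorilla gorilla",
    "Ppy": "Pongo pygmaeus abelii",
    "Nle": "Nomascus leucogenys",
    "Mmu": "Macaca mulatta",
    "Cja": "Callithrix jacchus",
}

_IUPAC_DNA = set("ACGTRYSWKMBDHVN")
_AA = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*")


class FastaFormatError(ValueError):
    """Malformed FASTA input (bad header, empty record, duplicate id...)."""


class TranslationError(ValueError):
    """CDS cannot be translated cleanly."""

    def __init__(self, message: str, codon_index: int | None = None):
        super().__init__(message)
        self.codon_index = codon_index


def read_fasta(path: str | Path, alphabet: str = "dna") -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]``.

    Line wrapping and surrounding whitespace are normalised away; ids and
    sequence content are otherwise preserved verbatim.  Duplicate ids,
    empty records and non-IUPAC characters raise :class:`FastaFormatError`
    naming the offending record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    allowed = _IUPAC_DNA if alphabet == "dna" else _AA
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id == "":
            raise FastaFormatError(f"{path}: record with empty header")
        if not seq:
            raise FastaFormatError(f"{path}: record '{rec.id}' has an empty sequence")
        bad = set(seq.replace("-", "")) - allowed
        if bad:
            raise FastaFormatError(
                f"{path}: record '{rec.id}' contains non-IUPAC characters {sorted(bad)}"
            )
        if rec.id in seen:
            raise FastaFormatError(f"{path}: duplicate record id '{rec.id}'")
        seen.add(rec.id)
        out.append((rec.id, seq))
    if not out:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    """Write ``(id, sequence)`` pairs as wrapped FASTA."""
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")
    _ = width  # Biopython wraps at 60; parameter kept for interface stability


def translate_cds(cds: str) -> str:
    """Translate a CDS with the standard genetic code.

    A trailing stop codon is dropped; an internal stop raises
    :class:`TranslationError` carrying the 0-based codon index (a premature
    stop is the signature of pseudogene-like input).  Codons containing
    ambiguous bases translate to ``X``.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise TranslationError(
            f"CDS length {len(cds)} is not divisible by 3", codon_index=None
        )
    protein = str(Seq(cds).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        idx = protein.index("*")
        raise TranslationError(f"internal stop codon at codon {idx}", codon_index=idx)
    return protein


@dataclass(frozen=True)
class GeneRecord:
    """One gene copy: species tag, CDS, protein, and conserved-domain span.

    ``domain_span`` is a half-open amino-acid interval ``(start, end)``
    within ``protein``.
    """

    gene_id: str
    species: str
    cds: str
    protein: str
    domain_span: tuple[int, int]

    def __post_init__(self) -> None:
        if self.species not in SPECIES_CODES:
            raise ValueError(
                f"{self.gene_id}: unknown species tag '{self.species}' "
                f"(expected one of {SPECIES_CODES})"
            )
        start, end = self.domain_span
        if not (0 <= start < end <= len(self.protein)):
            raise ValueError(
                f"{self.gene_id}: domain span {self.domain_span} outside protein "
                f"of length {len(self.protein)}"
            )
        if translate_cds(self.cds) != self.protein:
            raise ValueError(f"{self.gene_id}: CDS does not translate to the given protein")

    @property
    def domain_length(self) -> int:
        start, end = self.domain_span
        return end - start

    @property
    def domain_protein(self) -> str:
        start, end = self.domain_span
        return self.protein[start:end]

    @property
    def domain_cds(self) -> str:
        start, end = self.domain_span
        return self.cds[3 * start : 3 * end]


@dataclass
class GeneSet:
    """An ordered collection of gene copies with unique ids."""

    records: list[GeneRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.gene_id for r in self.records]
        dupes = {g for g in ids if ids.count(g) > 1}
        if dupes:
            raise ValueError(f"duplicate gene ids: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, gene_id: str) -> GeneRecord:
        for r in self.records:
            if r.gene_id == gene_id:
                return r
        raise KeyError(gene_id)

    @property
    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.records]

    def by_species(self, species: str) -> list[GeneRecord]:
        return [r for r in self.records if r.species == species]


def read_gene_set(
    cds_fasta: str | Path,
    metadata_tsv: str | Path,
    protein_fasta: str | Path | None = None,
    provenance: str = "",
) -> GeneSet:
    """Assemble a :class:`GeneSet` from a CDS FASTA and a metadata TSV.

    The metadata table carries columns ``gene_id, species, domain_start,
    domain_end`` (0-based half-open, amino-acid coordinates).  Species tags
    come from this table, not from FASTA headers, so any header dialect
    works.  If ``protein_fasta`` is omitted, proteins are obtained by
    translating the CDSs.
    """
    cds_map = dict(read_fasta(cds_fasta, alphabet="dna"))
    meta = pd.read_csv(metadata_tsv, sep="\t", dtype={"gene_id": str, "species": str})
    required = {"gene_id", "species", "domain_start", "domain_end"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"{metadata_tsv}: missing metadata columns {sorted(missing)}")
    prot_map = (
        dict(read_fasta(protein_fasta, alphabet="protein")) if protein_fasta else None
    )
    records = []
    for row in meta.itertuples(index=False):
        gid = row.gene_id
        if gid not in cds_map:
            raise ValueError(f"metadata gene '{gid}' absent from {cds_fasta}")
        cds = cds_map[gid]
        protein = prot_map[gid] if prot_map else translate_cds(cds)
        records.append(
            GeneRecord(
                gene_id=gid,
                species=row.species,
                cds=cds,
                protein=protein,
                domain_span=(int(row.domain_start), int(row.domain_end)),
            )
        )
    return GeneSet(records=records, provenance=provenance or str(cds_fasta))


def filter_by_domain_length(genes: GeneSet, min_aa: int = 160) -> GeneSet:
    """Drop gene copies whose conserved domain is shorter than ``min_aa``.

    The inequality is strict: a copy with a domain of exactly ``min_aa``
    residues is retained.  Order is preserved; excluded ids are logged.
    """
    kept, excluded = [], []
    for rec in genes.records:
        (kept if rec.domain_length >= min_aa else excluded).append(rec)
    if excluded:
        logger.info(
            "domain-length filter (<%d aa) excluded %d gene(s): %s",
            min_aa,
            len(excluded),
            ", ".join(r.gene_id for r in excluded),
        )
    return GeneSet(records=[replace(r) for r in kept], provenance=genes.provenance)


def write_metadata(genes: GeneSet, path: str | Path) -> None:
    """Write the metadata TSV consumed by :func:`read_gene_set`."""
    rows = [
        {
            "gene_id": r.gene_id,
            "species": r.species,
            "domain_start": r.domain_span[0],
            "domain_end": r.domain_span[1],
        }
        for r in genes.records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
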