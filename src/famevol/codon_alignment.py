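"""Codon alignments by back-translation of a guide protein alignment.

Protein alignments are far more reliable than nucleotide alignments for
divergent coding sequences, so the standard practice is to align the
proteins first and then project that alignment back onto the CDSs: every
aligned amino acid expands to its source codon and every gap to ``---``.
The result is a codon-aware nucleotide alignment whose reading frame is
intact in every row, the required substrate for synonymous/nonsynonymous
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .seq_io import read_fasta, translate_cds, write_fasta


class BacktranslationError(ValueError):
    """Protein row and CDS disagree."""


@dataclass
class Alignment:
    """A rectangular gapped sequence block.

    ``alphabet`` is ``"protein"`` or ``"codon"``; codon alignments have
    length divisible by 3 and gaps in whole-codon units.
    """

    ids: list[str]
    rows: list[str]
    alphabet: str = "protein"

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("alignment ids are not unique")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        if self.alphabet == "codon" and self.rows and len(self.rows[0]) % 3 != 0:
            raise ValueError("codon alignment length not divisible by 3")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, name: str) -> str:
        return self.rows[self.ids.index(name)]

    def subset(self, names: list[str]) -> "Alignment":
        return Alignment(
            ids=list(names), rows=[self.row(n) for n in names], alphabet=self.alphabet
        )


def read_alignment(path: str | Path, alphabet: str = "protein") -> Alignment:
    pairs = read_fasta(path, alphabet="dna" if alphabet == "codon" else "protein")
    return Alignment(ids=[p[0] for p in pairs], rows=[p[1] for p in pairs], alphabet=alphabet)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    write_fasta(zip(aln.ids, aln.rows), path)


def backtranslate(protein_aln: Alignment, cds_by_id: Mapping[str, str]) -> Alignment:
    """Expand a guide protein alignment into a codon alignment.

    For each row the ungapped protein must equal the translation of its
    CDS (trailing stop ignored); otherwise :class:`BacktranslationError`
    names the row and the first mismatching residue.  Ungapping any output
    row recovers its CDS minus any trailing stop.
    """
    out_rows = []
    for name, prow in zip(protein_aln.ids, protein_aln.rows):
        try:
            cds = cds_by_id[name]
        except KeyError:
            raise BacktranslationError(f"no CDS provided for alignment row '{name}'")
        cds = cds.upper()
        translated = translate_cds(cds)
        ungapped = prow.replace("-", "")
        if translated != ungapped:
            pos = next(
                (i for i, (a, b) in enumerate(zip(translated, ungapped)) if a != b),
                min(len(translated), len(ungapped)),
            )
            raise BacktranslationError(
                f"'{name}': CDS translation disagrees with protein row "
                f"at residue {pos} (translation has {len(translated)} aa, "
                f"row has {len(ungapped)})"
            )
        codons = [cds[3 * i : 3 * i + 3] for i in range(len(translated))]
        it = iter(codons)
        out_rows.append("".join("---" if aa == "-" else next(it) for aa in prow))
    return Alignment(ids=list(protein_aln.ids), rows=out_rows, alphabet="codon")


def restrict_to_domain(
    aln: Alignment, domain_spans: Mapping[str, tuple[int, int]]
) -> Alignment:
    """Keep only alignment columns overlapping every row's domain span.

    ``domain_spans`` maps row id to a half-open interval in that row's
    *ungapped* residue (protein) or codon coordinates.  A column is kept
    when, for every row, it is either a gap or falls inside the row's
    span.  Used to restrict analysis to the shared conserved domain.
    """
    unit = 3 if aln.alphabet == "codon" else 1
    ncol = aln.n_columns // unit
    keep = []
    for col in range(ncol):
        ok = True
        for name, row in zip(aln.ids, aln.rows):
            chunk = row[col * unit : (col + 1) * unit]
            if set(chunk) == {"-"}:
                continue
            # ungapped index of this residue within its row
            prefix = row[: col * unit]
            idx = (len(prefix) - prefix.count("-")) // unit
            start, end = domain_spans[name]
            if not (start <= idx < end):
                ok = False
                break
        if ok:
            keep.append(col)
    rows = [
        "".join(row[c * unit : (c + 1) * unit] for c in keep) for row in aln.rows
    ]
    return Alignment(ids=list(aln.ids), rows=rows, alphabet=aln.alphabet)
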