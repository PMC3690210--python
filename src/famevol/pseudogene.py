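"""Pseudogene calling from homology hit tables.

Genomic homology searches with a family's coding sequences return hits at
both live gene loci and decayed copies.  Pseudogene candidates are the
hits that (i) do not overlap any annotated live locus, and (ii) are at
least 450 bp long — short hits are uninformative fragments.  Overlapping
same-strand hits (e.g. from multiple query sequences) are merged into one
locus so a pseudogene is not double-counted.  Candidate sequences can then
be screened for the molecular hallmarks of pseudogenisation: premature
stop codons and frameshifting indels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .evodist import STOP_CODONS


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a chromosome/contig."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand '{self.strand}'")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Any shared base, strand-ignored."""
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class HitRecord:
    """One homology hit: the query gene and its location on the subject."""

    query_id: str
    interval: GenomicInterval
    identity: float = 100.0
    bit_score: float = 0.0


def read_hit_table(path: str | Path) -> list[HitRecord]:
    """Read a tabular (outfmt-6-style) hit table.

    Expected columns: ``query, chrom, start, end, strand, identity,
    bit_score`` (header required; 0-based half-open coordinates).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"query", "chrom", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: hit table missing columns {sorted(missing)}")
    hits = []
    for row in df.itertuples(index=False):
        hits.append(
            HitRecord(
                query_id=str(row.query),
                interval=GenomicInterval(
                    chrom=str(row.chrom),
                    start=int(row.start),
                    end=int(row.end),
                    strand=str(row.strand),
                ),
                identity=float(getattr(row, "identity", 100.0)),
                bit_score=float(getattr(row, "bit_score", 0.0)),
            )
        )
    return hits


def merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping same-strand intervals into maximal ones."""
    out: list[GenomicInterval] = []
    by_key: dict[tuple[str, str], list[GenomicInterval]] = {}
    for iv in intervals:
        by_key.setdefault((iv.chrom, iv.strand), []).append(iv)
    for (chrom, strand), ivs in by_key.items():
        ivs.sort()
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start < cur_end:  # strict overlap, abutting intervals stay separate
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end, strand))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end, strand))
    return sorted(out)


def call_pseudogenes(
    hits: list[HitRecord],
    live_loci: list[GenomicInterval],
    min_len: int = 450,
) -> list[GenomicInterval]:
    """Filter and merge homology hits into pseudogene calls.

    Hits overlapping any live locus (>= 1 bp, strand-ignored) are dropped;
    hits shorter than ``min_len`` are dropped (strictly: a 450 bp hit
    passes a 450 bp threshold); the survivors are merged per strand and
    returned sorted.  Merged loci shorter than ``min_len`` cannot occur
    because merging never shortens.
    """
    survivors = []
    for hit in hits:
        iv = hit.interval
        if iv.length < min_len:
            continue
        if any(iv.overlaps(live) for live in live_loci):
            continue
        survivors.append(iv)
    return merge_intervals(survivors)


@dataclass
class DisablementReport:
    """Descriptive flags for a candidate pseudogene sequence."""

    premature_stops: dict[int, list[int]]  # frame -> 0-based codon indices
    best_frame: int
    frameshift: bool  # length deviates from frame-0 multiple of 3 vs query
    intact: bool


def flag_disablements(
    call_seq: str, query_length: int | None = None
) -> DisablementReport:
    """Scan a called sequence for premature stops and frameshift signals.

    All three forward frames are scanned for internal stop codons; the
    best frame is the one with the fewest.  A frameshift is flagged when
    the sequence length is not congruent modulo 3 with the query length
    (if given) or not a multiple of 3 (if not).  Labels are descriptive —
    no call is removed on their account.
    """
    seq = call_seq.upper().replace("-", "")
    stops: dict[int, list[int]] = {}
    for frame in range(3):
        idxs = []
        ncod = (len(seq) - frame) // 3
        for k in range(ncod - 1):  # trailing codon never counts as premature
            codon = seq[frame + 3 * k : frame + 3 * k + 3]
            if codon in STOP_CODONS:
                idxs.append(k)
        stops[frame] = idxs
    best_frame = min(stops, key=lambda f: (len(stops[f]), f))
    if query_length is not None:
        frameshift = (len(seq) % 3) != (query_length % 3)
    else:
        frameshift = len(seq) % 3 != 0
    intact = not frameshift and not stops[best_frame]
    return DisablementReport(
        premature_stops=stops,
        best_frame=best_frame,
        frameshift=frameshift,
        intact=intact,
    )


def write_bed(calls: list[GenomicInterval], path: str | Path) -> None:
    """Write calls as 6-column BED (0-based half-open, native)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(calls, start=1):
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tpseudogene_{i}\t0\t{iv.strand}\n"
            )


def calls_to_table(calls: list[GenomicInterval], one_based: bool = True) -> pd.DataFrame:
    """Tabular view of the calls; 1-based inclusive by default."""
    return pd.DataFrame(
        {
            "chrom": [c.chrom for c in calls],
            "start": [c.start + 1 if one_based else c.start for c in calls],
            "end": [c.end for c in calls],
            "strand": [c.strand for c in calls],
            "length": [c.length for c in calls],
        }
    )
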