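"""Pairwise evolutionary distances for coding sequences.

Three quantities drive the comparative analysis of a gene family:

* **p-distance** — the proportion of differing nucleotide sites between two
  aligned sequences, with pairwise deletion of gapped/ambiguous columns.
* **Jukes–Cantor divergence** ``d = -(3/4) ln(1 - (4/3) p)`` — the
  multiple-hit-corrected number of substitutions per site under the
  one-parameter model.  Undefined at saturation (``p >= 3/4``).
* **Nei–Gojobori (1986) Ka/Ks** — substitutions per nonsynonymous and per
  synonymous site.  Synonymous/nonsynonymous *site* counts come from
  enumerating all nine single-base mutants of each codon (mutants creating
  stop codons are excluded from the denominator at that position);
  *difference* counts for codon pairs differing at several positions are
  averaged over all orderings of single-base steps, excluding pathways
  that pass through a stop codon.  ``pS = Sd/S`` and ``pN = Nd/N`` are then
  Jukes–Cantor corrected to give Ks and Ka.

A Ka/Ks ratio well below 1 indicates purifying selection; above 1,
positive selection.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .codon_alignment import Alignment

STOP_CODONS = frozenset(standard_dna_table.stop_codons)
CODON_TO_AA = dict(standard_dna_table.forward_table)
SENSE_CODONS = tuple(sorted(CODON_TO_AA))
_BASES = "ACGT"


class SaturationError(ValueError):
    """Observed divergence too large for the correction to be defined."""


class DistanceError(ValueError):
    pass


def p_distance(row_i: str, row_j: str) -> tuple[float, int]:
    """Proportion of differing sites with pairwise deletion.

    Columns where either row carries a gap or a non-ACGT base are excluded.
    Returns ``(p, sites_compared)``; raises :class:`DistanceError` if no
    column is comparable.
    """
    if len(row_i) != len(row_j):
        raise DistanceError("rows differ in length")
    sites = 0
    diffs = 0
    for a, b in zip(row_i.upper(), row_j.upper()):
        if a in _BASES and b in _BASES:
            sites += 1
            if a != b:
                diffs += 1
    if sites == 0:
        raise DistanceError("no comparable (ungapped, unambiguous) sites")
    return diffs / sites, sites


def jc_distance(p: float) -> float:
    """Jukes–Cantor correction of a p-distance."""
    if not 0.0 <= p < 0.75:
        raise SaturationError(f"p={p} outside [0, 0.75): correction undefined")
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


@lru_cache(maxsize=None)
def ng86_site_counts(codon: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts ``(s, n)`` for one codon.

    At each position the three single-base mutants are classified;
    mutants that would create a stop codon are dropped from that
    position's denominator.  ``n = 3 - s``.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site counts")
    if codon not in CODON_TO_AA:
        raise ValueError(f"ambiguous or invalid codon '{codon}'")
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            valid += 1
            if CODON_TO_AA[mutant] == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


@lru_cache(maxsize=None)
def pathway_diff_counts(codon1: str, codon2: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous difference counts ``(sd, nd)`` for a codon pair.

    For codons differing at ``k`` positions, every one of the ``k!``
    orderings of single-base steps is a pathway; pathways passing through
    a stop codon are excluded and the rest are weighted equally.  If every
    pathway is blocked by a stop (possible only for some 3-difference
    pairs), all pathways are used as a fallback so the differences are
    still counted.
    """
    diff_pos = [i for i in range(3) if codon1[i] != codon2[i]]
    if not diff_pos:
        return 0.0, 0.0
    valid_paths = []
    all_paths = []
    for order in itertools.permutations(diff_pos):
        cur = codon1
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + codon2[pos] + cur[pos + 1 :]
            steps.append((cur, nxt))
            if nxt in STOP_CODONS and nxt != codon2:
                blocked = True
            cur = nxt
        all_paths.append(steps)
        if not blocked:
            valid_paths.append(steps)
    paths = valid_paths or all_paths

    def classify(a: str, b: str) -> tuple[float, float]:
        aa_a = CODON_TO_AA.get(a, "*")
        aa_b = CODON_TO_AA.get(b, "*")
        return (1.0, 0.0) if aa_a == aa_b and aa_a != "*" else (0.0, 1.0)

    sd = nd = 0.0
    for steps in paths:
        for a, b in steps:
            ds, dn = classify(a, b)
            sd += ds
            nd += dn
    return sd / len(paths), nd / len(paths)


@dataclass
class NGCounts:
    """Nei–Gojobori counts and rates for one aligned sequence pair.

    ``S``/``N`` are the average synonymous/nonsynonymous site counts of
    the two sequences over compared codons; ``Sd``/``Nd`` the pathway-
    averaged difference counts.  ``Ka``/``Ks`` are ``None`` when the
    corresponding proportion is saturated (``>= 0.75``).
    """

    S: float
    N: float
    Sd: float
    Nd: float
    codons_compared: int
    Ka: float | None
    Ks: float | None

    @property
    def pS(self) -> float:
        return self.Sd / self.S if self.S > 0 else 0.0

    @property
    def pN(self) -> float:
        return self.Nd / self.N if self.N > 0 else 0.0

    @property
    def saturated(self) -> bool:
        return self.Ka is None or self.Ks is None


def _iter_codon_pairs(row_i: str, row_j: str):
    if len(row_i) != len(row_j):
        raise DistanceError("rows differ in length")
    if len(row_i) % 3 != 0:
        raise DistanceError("codon rows must have length divisible by 3")
    for k in range(0, len(row_i), 3):
        c1, c2 = row_i[k : k + 3].upper(), row_j[k : k + 3].upper()
        if set(c1) <= set(_BASES) and set(c2) <= set(_BASES):
            if c1 not in STOP_CODONS and c2 not in STOP_CODONS:
                yield c1, c2


def ng86_pair(row_i: str, row_j: str) -> NGCounts:
    """Nei–Gojobori Ka/Ks for one codon-aligned sequence pair.

    Codon columns with gaps, ambiguous bases, or a stop codon in either
    sequence are skipped.  Site counts are computed per sequence and
    averaged; difference counts use pathway averaging.
    """
    S = N = Sd = Nd = 0.0
    ncod = 0
    for c1, c2 in _iter_codon_pairs(row_i, row_j):
        s1, n1 = ng86_site_counts(c1)
        s2, n2 = ng86_site_counts(c2)
        S += (s1 + s2) / 2
        N += (n1 + n2) / 2
        ds, dn = pathway_diff_counts(c1, c2)
        Sd += ds
        Nd += dn
        ncod += 1
    if ncod == 0:
        raise DistanceError("no comparable codons")

    def corrected(num: float, den: float) -> float | None:
        if den <= 0:
            return 0.0 if num == 0 else None
        try:
            return jc_distance(num / den)
        except SaturationError:
            return None

    ka = corrected(Nd, N)
    ks = corrected(Sd, S)
    return NGCounts(S=S, N=N, Sd=Sd, Nd=Nd, codons_compared=ncod, Ka=ka, Ks=ks)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with ``NaN`` marking saturated pairs."""

    ids: list[str]
    values: np.ndarray
    kind: str = "d"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        if not np.array_equal(np.isnan(v), np.isnan(v.T)) or not np.allclose(
            np.nan_to_num(v), np.nan_to_num(v.T)
        ):
            raise ValueError("matrix must be symmetric")
        self.values = v

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    @property
    def n_missing_pairs(self) -> int:
        iu = np.triu_indices(len(self.ids), k=1)
        return int(np.isnan(self.values[iu]).sum())

    def submatrix(self, names: list[str]) -> "DistanceMatrix":
        idx = [self.ids.index(n) for n in names]
        return DistanceMatrix(
            ids=list(names), values=self.values[np.ix_(idx, idx)], kind=self.kind
        )

    def pair_values(self, names: list[str] | None = None) -> np.ndarray:
        """Upper-triangle values (unordered pairs), NaNs included."""
        m = self.submatrix(names) if names is not None else self
        iu = np.triu_indices(len(m.ids), k=1)
        return m.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def _encode_rows(rows: list[str]) -> np.ndarray:
    """Map rows to int codes: A,C,G,T -> 0..3, anything else -> -1."""
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(_BASES):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    arr = np.frombuffer("".join(rows).encode(), dtype=np.uint8)
    return lut[arr].reshape(len(rows), -1)


def jc_matrix(aln: Alignment) -> DistanceMatrix:
    """Jukes–Cantor divergence ``d`` for all pairs (vectorised).

    Saturated or incomparable pairs become ``NaN``.
    """
    enc = _encode_rows(aln.rows)
    n = len(aln.ids)
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
    return DistanceMatrix(ids=list(aln.ids), values=vals, kind="d")


def distance_matrix(aln: Alignment, kind: str = "d") -> DistanceMatrix:
    """All-pairs distances of the requested ``kind`` ("d", "Ka" or "Ks").

    Saturated components are reported as ``NaN``, never clamped; callers
    can query :attr:`DistanceMatrix.n_missing_pairs` for the skip count.
    """
    if len(aln.ids) < 2:
        raise DistanceError("need at least two rows")
    if kind == "d":
        return jc_matrix(aln)
    if kind not in ("Ka", "Ks"):
        raise ValueError(f"unknown distance kind '{kind}'")
    n = len(aln.ids)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            counts = ng86_pair(aln.rows[i], aln.rows[j])
            v = counts.Ka if kind == "Ka" else counts.Ks
            vals[i, j] = vals[j, i] = np.nan if v is None else v
    return DistanceMatrix(ids=list(aln.ids), values=vals, kind=kind)


def pairwise_table(aln: Alignment) -> pd.DataFrame:
    """Long-format table of d, Ka, Ks for every unordered pair."""
    dm_d = distance_matrix(aln, "d")
    rows = []
    for i in range(len(aln.ids)):
        for j in range(i + 1, len(aln.ids)):
            counts = ng86_pair(aln.rows[i], aln.rows[j])
            rows.append(
                {
                    "gene_1": aln.ids[i],
                    "gene_2": aln.ids[j],
                    "d": dm_d.values[i, j],
                    "Ka": np.nan if counts.Ka is None else counts.Ka,
                    "Ks": np.nan if counts.Ks is None else counts.Ks,
                }
            )
    return pd.DataFrame(rows)


def write_pairwise_table(aln: Alignment, path: str | Path) -> None:
    pairwise_table(aln).to_csv(path, sep="\t", index=False, float_format="%.6f")
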