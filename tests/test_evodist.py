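"""Distance estimators, checked against independent brute-force oracles.

The Nei–Gojobori oracle here is written from scratch on top of
Biopython's translation machinery (not the package's codon tables): site
counts by direct mutant enumeration, difference counts by recursive
enumeration of substitution orderings with stop-codon pathways excluded.
"""

import itertools
import math

import numpy as np
import pytest
from Bio.Seq import Seq

from famevol.codon_alignment import Alignment
from famevol.evodist import (
    DistanceError,
    SaturationError,
    distance_matrix,
    jc_distance,
    ng86_pair,
    ng86_site_counts,
    p_distance,
    pathway_diff_counts,
)
from famevol.simulate import evolve_jc, random_codon_seq, simulate_omega_pair

SENSE = [
    "".join(c)
    for c in itertools.product("ACGT", repeat=3)
    if str(Seq("".join(c)).translate()) != "*"
]


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_site_counts(codon):
    s = 0.0
    for pos in range(3):
        mutants = [
            codon[:pos] + b + codon[pos + 1 :] for b in "ACGT" if b != codon[pos]
        ]
        live = [m for m in mutants if _aa(m) != "*"]
        if live:
            s += sum(_aa(m) == _aa(codon) for m in live) / len(live)
    return s, 3.0 - s


def oracle_pathway_counts(c1, c2):
    """Average syn/nonsyn steps over stop-free substitution orderings."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    results = []
    blocked_results = []
    for order in itertools.permutations(diff):
        cur, sd, nd, blocked = c1, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _aa(nxt) == "*" and nxt != c2:
                blocked = True
            if _aa(cur) == _aa(nxt) and _aa(cur) != "*":
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked_results if blocked else results).append((sd, nd))
    use = results or blocked_results
    return (
        sum(r[0] for r in use) / len(use),
        sum(r[1] for r in use) / len(use),
    )


class TestPDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGT", "ACGT", (0.0, 4)),
            ("ACGT", "ACGA", (0.25, 4)),
            ("AC-T", "ACGT", (0.0, 3)),  # pairwise deletion of the gap column
            ("ACNT", "ACGT", (0.0, 3)),  # ambiguity excluded the same way
        ],
    )
    def test_examples(self, a, b, expected):
        assert p_distance(a, b) == expected

    def test_no_comparable_sites(self):
        with pytest.raises(DistanceError):
            p_distance("--", "AA")


class TestJukesCantor:
    def test_zero_iff_identical(self):
        assert jc_distance(0.0) == 0.0

    def test_closed_form_value(self):
        assert jc_distance(0.05) == pytest.approx(0.05174, abs=5e-6)

    def test_saturation_boundary(self):
        with pytest.raises(SaturationError):
            jc_distance(0.75)

    def test_monotone_and_first_order_near_zero(self):
        grid = np.linspace(0.0, 0.74, 200)
        vals = [jc_distance(p) for p in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert jc_distance(0.01) == pytest.approx(0.01, rel=0.05)

    def test_correction_never_below_p(self):
        for p in np.linspace(0.01, 0.7, 50):
            assert jc_distance(p) >= p


class TestNG86SiteCounts:
    def test_phenylalanine_third_position(self):
        s, n = ng86_site_counts("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(3 - 1 / 3)

    def test_methionine_has_no_synonymous_sites(self):
        assert ng86_site_counts("ATG")[0] == 0.0

    @pytest.mark.parametrize("codon", SENSE)
    def test_all_sense_codons_match_oracle(self, codon):
        s, n = ng86_site_counts(codon)
        es, en = oracle_site_counts(codon)
        assert s == pytest.approx(es, abs=1e-12)
        assert s + n == pytest.approx(3.0)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            ng86_site_counts("TAA")


class TestPathwayCounts:
    def test_all_codon_pairs_match_exhaustive_oracle(self):
        for c1, c2 in itertools.product(SENSE, SENSE):
            got = pathway_diff_counts(c1, c2)
            want = oracle_pathway_counts(c1, c2)
            assert got == pytest.approx(want, abs=1e-12), (c1, c2)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            c1, c2 = rng.choice(SENSE, size=2)
            f = pathway_diff_counts(str(c1), str(c2))
            r = pathway_diff_counts(str(c2), str(c1))
            assert f == pytest.approx(r, abs=1e-12)


class TestNG86Pair:
    def test_identical_sequences(self):
        seq = "".join(random_codon_seq(50, np.random.default_rng(0)))
        counts = ng86_pair(seq, seq)
        assert counts.Ka == 0.0 and counts.Ks == 0.0
        assert counts.S + counts.N == pytest.approx(3 * counts.codons_compared)

    def test_jc_correction_of_ps(self):
        # pS = 0.25 corresponds to Ks ~ 0.30410 under Jukes-Cantor
        assert jc_distance(0.25) == pytest.approx(0.30410, abs=5e-6)

    def test_two_position_codon_matches_oracle(self):
        base = random_codon_seq(20, np.random.default_rng(5))
        other = list(base)
        other[4] = "TTA" if base[4] != "TTA" else "CTG"  # ensure >=1 diff
        # force a two-position difference on a known codon
        base[4] = "TCG"
        other[4] = "TAT"
        a, b = "".join(base), "".join(other)
        counts = ng86_pair(a, b)
        sd, nd = oracle_pathway_counts("TCG", "TAT")
        assert counts.Sd == pytest.approx(sd)
        assert counts.Nd == pytest.approx(nd)

    def test_symmetric_in_arguments(self):
        a, b = simulate_omega_pair(100, 0.2, 0.3, seed=9)
        x, y = ng86_pair(a, b), ng86_pair(b, a)
        assert x.Ka == pytest.approx(y.Ka)
        assert x.Ks == pytest.approx(y.Ks)

    def test_gap_and_stop_codons_skipped(self):
        counts = ng86_pair("ATG---TGAAAA", "ATGCCCTGAAAA")
        assert counts.codons_compared == 2  # ATG and AAA only

    def test_biopython_cross_check(self):
        """Coarse agreement with Bio.codonalign's NG86 (which handles
        stop-adjacent codons by a different convention)."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        a, b = simulate_omega_pair(2000, 0.15, 0.3, seed=21)
        counts = ng86_pair(a, b)
        dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
        assert counts.Ka == pytest.approx(dn, rel=0.05)
        # Ks drifts more between the two stop-codon conventions: excluding
        # stop mutants from site denominators (here) yields more synonymous
        # sites than counting them as nonsynonymous (Biopython)
        assert counts.Ks == pytest.approx(ds, rel=0.10)

    def test_omega_recovery_small(self):
        """Mean Ka/Ks over replicate pairs recovers the simulated omega."""
        for omega in (0.1, 0.5):
            ratios = []
            for rep in range(3):
                a, b = simulate_omega_pair(3000, 0.1, omega, seed=100 + rep)
                c = ng86_pair(a, b)
                ratios.append(c.Ka / c.Ks)
            assert np.mean(ratios) == pytest.approx(omega, rel=0.2)


class TestDistanceMatrix:
    def test_identical_rows_zero_matrix(self):
        aln = Alignment(["a", "b"], ["ATGAAA", "ATGAAA"], alphabet="codon")
        dm = distance_matrix(aln, "d")
        assert np.allclose(dm.values, 0.0)

    def test_three_rows_symmetric(self, codon_aln):
        sub = Alignment(
            ids=codon_aln.ids[:3], rows=codon_aln.rows[:3], alphabet="codon"
        )
        for kind in ("d", "Ka", "Ks"):
            dm = distance_matrix(sub, kind)
            assert np.allclose(dm.values, dm.values.T, equal_nan=True)
            assert np.allclose(np.diag(dm.values), 0.0)

    def test_simulated_jc_depth_recovered(self):
        rng = np.random.default_rng(17)
        anc = "".join(rng.choice(list("ACGT"), size=2000))
        rows = [evolve_jc(anc, 0.05, rng) for _ in range(6)]  # pairwise depth 0.1
        aln = Alignment([f"s{i}" for i in range(6)], rows, alphabet="dna")
        dm = distance_matrix(aln, "d")
        mean_d = float(np.nanmean(dm.pair_values()))
        assert mean_d == pytest.approx(0.1, rel=0.15)

    def test_saturated_pair_reported_missing(self):
        rng = np.random.default_rng(2)
        a = "".join(rng.choice(list("ACGT"), size=3000))
        b = a.translate(str.maketrans("ACGT", "CGTA"))  # p = 1: saturated
        c = evolve_jc(a, 0.01, rng)
        aln = Alignment(["a", "b", "c"], [a, b, c], alphabet="dna")
        dm = distance_matrix(aln, "d")
        assert dm.n_missing_pairs >= 1
        assert not math.isnan(dm.get("a", "c"))
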