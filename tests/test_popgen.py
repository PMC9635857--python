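import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

from gh1kit.popgen import (
    HKAData, HKALocus, LocusAlignment, _codon_pair_differences,
    _codon_site_fractions, classify_coding_sites, diversity_stats, harmonic,
    hka_fit, hka_test, mean_pairwise_differences, nucleotide_diversity,
    segregating_sites, snp_effect, tajima_d, variant_density, watterson_theta,
)
from gh1kit.seqio import VariantRecord
from gh1kit.synthetic_data import gen_coding_population, gen_hka_counts

# ---------------------------------------------------------------------------
# exact-rational oracles (independent of the implementation path)


def oracle_columns(haps):
    return [c for c in range(len(haps[0]))
            if all(h[c] != "-" for h in haps)]


def oracle_s(haps):
    return sum(
        1 for c in oracle_columns(haps)
        if len({h[c] for h in haps}) >= 2
    )


def oracle_pi_count(haps):
    cols = oracle_columns(haps)
    n = len(haps)
    total = 0
    for i, j in itertools.combinations(range(n), 2):
        total += sum(haps[i][c] != haps[j][c] for c in cols)
    return Fraction(total, math.comb(n, 2))


def oracle_tajima_d(haps):
    n = len(haps)
    s = oracle_s(haps)
    if s == 0 or n < 3:
        return None
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2, n) / a1 + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    var = e1 * s + e2 * s * (s - 1)
    if var <= 0:
        return None
    numerator = oracle_pi_count(haps) - Fraction(s) / a1  # exact rational
    return float(numerator) / math.sqrt(float(var))


def random_alignment(rng, with_gaps=False):
    n = rng.integers(2, 7)
    length = rng.integers(5, 31)
    alphabet = "ACGT-" if with_gaps else "ACGT"
    p = [0.3, 0.3, 0.15, 0.15, 0.1] if with_gaps else [0.4, 0.3, 0.15, 0.15]
    haps = tuple(
        "".join(rng.choice(list(alphabet), p=p, size=length))
        for _ in range(n)
    )
    # guarantee at least one fully ungapped column
    haps = tuple("A" + h[1:] for h in haps)
    return LocusAlignment(locus_id="L", haplotypes=haps)


# ---------------------------------------------------------------------------


class TestSegregatingSites:
    def test_identical_pair(self):
        aln = LocusAlignment("L", ("ACGT", "ACGT"))
        assert segregating_sites(aln) == 0

    def test_three_varying_positions(self):
        haps = ("AAAAA", "AAAAT", "ACAAT", "ACGAT")
        aln = LocusAlignment("L", haps)
        assert segregating_sites(aln) == oracle_s(haps) == 3

    def test_gap_column_excluded(self):
        aln = LocusAlignment("L", ("AA", "AA", "-A", "TA"))
        assert segregating_sites(aln) == 0


class TestNucleotideDiversity:
    def test_single_pair(self):
        haps = ("A" * 97 + "TTT", "A" * 97 + "AAA")
        aln = LocusAlignment("L", haps)
        assert nucleotide_diversity(aln) == pytest.approx(0.03)

    def test_identical_haplotypes(self):
        aln = LocusAlignment("L", ("ACGT",) * 4)
        assert nucleotide_diversity(aln) == 0.0

    def test_five_haplotype_pairwise_oracle(self):
        rng = np.random.default_rng(42)
        haps = tuple(
            "".join(rng.choice(list("ACGT"), size=50)) for _ in range(5)
        )
        aln = LocusAlignment("L", haps)
        expected = oracle_pi_count(haps) / Fraction(50)
        assert nucleotide_diversity(aln) == pytest.approx(float(expected))

    def test_pi_equals_thetaw_for_n2(self):
        rng = np.random.default_rng(1)
        for seed in range(20):
            aln = random_alignment(np.random.default_rng(seed))
            if aln.n != 2:
                continue
            cols = len(oracle_columns(aln.haplotypes))
            s = segregating_sites(aln)
            assert nucleotide_diversity(aln) == pytest.approx(
                watterson_theta(s, 2, cols)
            )

    def test_haplotype_order_invariance(self):
        rng = np.random.default_rng(7)
        aln = random_alignment(rng)
        shuffled = LocusAlignment("L", tuple(reversed(aln.haplotypes)))
        assert nucleotide_diversity(aln) == nucleotide_diversity(shuffled)
        assert segregating_sites(aln) == segregating_sites(shuffled)


class TestWattersonTheta:
    def test_pair(self):
        assert watterson_theta(3, 2, 100) == pytest.approx(0.03)

    def test_zero_sites(self):
        assert watterson_theta(0, 10, 500) == 0.0

    def test_n5(self):
        # a1 = 1 + 1/2 + 1/3 + 1/4 = 25/12
        assert watterson_theta(10, 5, 1000) == pytest.approx(
            10 / (25 / 12 * 1000)
        )
        assert watterson_theta(10, 5, 1000) == pytest.approx(0.0048)


class TestTajimaD:
    def test_all_singletons_negative(self):
        haps = []
        for i in range(10):
            row = ["A"] * 20
            if i < 9:
                row[i] = "T"  # each of 9 variants private to one haplotype
            haps.append("".join(row))
        aln = LocusAlignment("L", tuple(haps))
        d = tajima_d(aln)
        assert d is not None and d < 0
        assert d == pytest.approx(oracle_tajima_d(tuple(haps)))

    def test_balanced_configuration_positive(self):
        haps = ("AAAATTTT",) * 5 + ("TTTTAAAA",) * 5
        aln = LocusAlignment("L", haps)
        d = tajima_d(aln)
        assert d is not None and d > 0
        assert d == pytest.approx(oracle_tajima_d(haps))

    def test_no_segregating_sites_undefined(self):
        aln = LocusAlignment("L", ("ACGT",) * 5)
        assert tajima_d(aln) is None

    def test_rational_oracle_battery(self):
        checked = 0
        for seed in range(120):
            rng = np.random.default_rng(seed)
            aln = random_alignment(rng, with_gaps=bool(seed % 3 == 0))
            expected = oracle_tajima_d(aln.haplotypes)
            got = tajima_d(aln)
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected, abs=1e-12)
                checked += 1
        assert checked > 40


class TestCodingSites:
    def test_ttt_site_fractions(self):
        # enumerate all 9 single-base changes of TTT (Phe)
        assert _codon_site_fractions("TTT") == (0.0, 0.0, pytest.approx(1 / 3))

    def test_fractions_sum_to_three(self):
        rng = np.random.default_rng(0)
        from gh1kit.popgen import _CODON_TO_AA

        for _ in range(30):
            codon = "".join(rng.choice(list("ACGT"), size=3))
            if _CODON_TO_AA[codon] == "*":
                continue
            f = _codon_site_fractions(codon)
            assert sum(f) + sum(1 - x for x in f) == pytest.approx(3.0)

    def test_synonymous_call(self):
        ann = classify_coding_sites("TTA", [(1, 3)])
        assert snp_effect(ann, 3, "G") == "synonymous"  # TTA->TTG, Leu

    def test_nonsynonymous_call(self):
        ann = classify_coding_sites("AAA", [(1, 3)])
        assert snp_effect(ann, 2, "G") == "nonsynonymous"  # AAA->AGA, Lys->Arg

    def test_noncoding_call(self):
        ann = classify_coding_sites("GGGTTA", [(4, 6)])
        assert snp_effect(ann, 2, "A") == "noncoding"

    def test_partial_codon_is_error(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            classify_coding_sites("AAAA", [(1, 4)])

    def test_internal_stop_warns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            classify_coding_sites("TAAAAA", [(1, 6)])
        assert "stop codon" in caplog.text

    def test_codon_pair_pathway_average(self):
        # TTT (F) vs GTA (V): two differing positions, two pathways
        #  TTT -> GTT (F->V, nonsyn) -> GTA (V->V, syn)
        #  TTT -> TTA (F->L, nonsyn) -> GTA (L->V, nonsyn)
        sd, nd = _codon_pair_differences("TTT", "GTA")
        assert (sd, nd) == (0.5, 1.5)

    def test_identical_codons(self):
        assert _codon_pair_differences("ATG", "ATG") == (0.0, 0.0)


class TestDiversityStats:
    def test_silent_pools_noncoding_and_synonymous(self):
        pop = gen_coding_population(120, 6, 4, 4, 0, seed=5)
        stats = diversity_stats(pop.alignment, pop.annotation)
        assert stats.pi_sil is not None and stats.pi_syn is not None
        assert stats.s == len(pop.variants)
        assert stats.pi_total > 0

    def test_nonsyn_to_syn_ratio_flag(self):
        pop = gen_coding_population(300, 8, 2, 25, 0, seed=6)
        stats = diversity_stats(pop.alignment, pop.annotation)
        assert stats.pi_nonsyn > stats.pi_syn

    def test_zero_class_flagged(self):
        # no noncoding part, no synonymous variants planted
        pop = gen_coding_population(60, 4, 0, 0, 0, seed=8)
        haps = tuple(h[90:150] for h in pop.alignment.haplotypes)
        aln = LocusAlignment("L", haps)
        ann = classify_coding_sites(pop.reference[90:150], [(1, 60)])
        stats = diversity_stats(aln, ann)
        assert stats.pi_total == 0.0


class TestVariantDensity:
    def test_paper_scale_counts(self):
        variants = (
            [VariantRecord("L", i + 1, "A", "C", allele_counts=(1, 1))
             for i in range(196)]
            + [VariantRecord("L", 500 + i, "AT", "A", allele_counts=(1, 1))
               for i in range(40)]
        )
        bp_snp, bp_indel = variant_density(variants, 31872)
        assert bp_snp == 162.6
        assert bp_indel == 796.8

    def test_zero_snps_absent(self):
        variants = [VariantRecord("L", 1, "AT", "A", allele_counts=(1, 1))]
        bp_snp, bp_indel = variant_density(variants, 100)
        assert bp_snp is None
        assert bp_indel == 100.0

    def test_single_snp(self):
        variants = [VariantRecord("L", 1, "A", "T", allele_counts=(1, 1))]
        assert variant_density(variants, 100)[0] == 100.0


class TestHKA:
    def test_saturated_single_locus_recovery(self):
        # S = a(n) theta*, D = (T*+1) theta* exactly: expected = observed
        data = HKAData(
            loci=(HKALocus("A", s=5, d=10, n=2),
                  HKALocus("B", s=5, d=10, n=2)),
        )
        fit = hka_fit(data, "neutral")
        assert fit.theta_hat["A"] == pytest.approx(5.0, rel=1e-6)
        assert fit.t_hat == pytest.approx(1.0, rel=1e-5)

    def test_nested_identity_k1(self):
        # counts fixed at the k = 1 expectation (theta=30, T=2, n=2):
        # S = theta * a(2) = 30, D = theta * (T+1) = 90 at every locus
        data = HKAData(
            loci=tuple(HKALocus(f"L{i}", s=30, d=90, n=2) for i in range(4)),
            focal_id="L0",
        )
        result = hka_test(data)
        assert result.k_hat == pytest.approx(1.0, rel=1e-3)
        assert result.lrt == pytest.approx(0.0, abs=1e-6)
        assert result.p_value == pytest.approx(1.0, abs=1e-4)

    def test_selection_lnl_at_least_neutral(self):
        for seed in range(5):
            counts = gen_hka_counts([20] * 5, 1.0, 2.0, [12] * 5, seed=seed)
            result = hka_test(counts.to_hka_data())
            assert result.lnl_selection >= result.lnl_neutral - 1e-8
            assert result.lrt >= 0

    def test_k_recovery_single_draw(self):
        counts = gen_hka_counts([100] * 6, 2.0, 3.0, [20] * 6, seed=12)
        result = hka_test(counts.to_hka_data())
        assert 2.0 < result.k_hat < 4.0

    def test_lrt_chi2_critical_value(self):
        from scipy.stats import chi2

        assert chi2.sf(3.841, 1) == pytest.approx(0.05, abs=1e-3)

    def test_zero_count_locus_flagged(self):
        data = HKAData(
            loci=(HKALocus("dead", s=0, d=0, n=4),
                  HKALocus("B", s=6, d=8, n=4),
                  HKALocus("C", s=5, d=9, n=4)),
        )
        fit = hka_fit(data, "neutral")
        assert "dead" in fit.boundary_loci
        assert fit.theta_hat["dead"] == 0.0

    def test_selection_requires_focal(self):
        data = HKAData(loci=(HKALocus("A", 3, 4, 4), HKALocus("B", 5, 6, 4)))
        with pytest.raises(ValueError, match="focal"):
            hka_fit(data, "selection")

    def test_two_loci_minimum(self):
        with pytest.raises(ValueError, match="2 loci"):
            HKAData(loci=(HKALocus("A", 3, 4, 4),))
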