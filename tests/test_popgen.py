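"""Genotype container, allele frequencies, HWE chi-squared and D'/LOD."""

import math

import numpy as np
import pytest

from promsat.popgen import (
    GenotypeFormatError,
    GenotypeTable,
    Individual,
    InsufficientDataError,
    allele_frequencies,
    dprime_from_counts,
    hwe_chisq,
    load_genotypes,
    locus_stats,
    minor_allele_frequency,
    pairwise_dprime,
    parse_call,
)


def table_from_genotypes(genotypes, locus="L"):
    """Build a single-locus table from a list of allele pairs."""
    individuals, calls = [], {}
    for k, pair in enumerate(genotypes):
        ind = Individual(id=f"i{k}")
        individuals.append(ind)
        calls[ind.id] = {locus: tuple(sorted(pair)) if pair else None}
    return GenotypeTable(individuals, [locus], calls)


class TestAlleleFrequencies:
    def test_all_homozygous_reference(self):
        table = table_from_genotypes([("REF", "REF")] * 10)
        assert allele_frequencies(table, "L") == {"REF": 1.0}

    def test_hand_counted_frequencies(self):
        table = table_from_genotypes(
            [("REF", "REF")] * 7 + [("REF", "ALT")] * 2 + [("ALT", "ALT")]
        )
        assert allele_frequencies(table, "L") == {"ALT": 0.2, "REF": 0.8}

    def test_missing_calls_excluded_from_denominator(self):
        table = table_from_genotypes([("A", "A"), ("A", "T"), None])
        freqs = allele_frequencies(table, "L")
        assert freqs == {"A": 0.75, "T": 0.25}

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(11)
        genotypes = [
            tuple(rng.choice(["A", "C", "G"], size=2)) for _ in range(100)
        ]
        freqs = allele_frequencies(table_from_genotypes(genotypes), "L")
        assert math.isclose(sum(freqs.values()), 1.0, abs_tol=1e-12)

    def test_empty_stratum_rejected(self):
        table = table_from_genotypes([None, None])
        with pytest.raises(InsufficientDataError):
            allele_frequencies(table, "L")

    def test_sampling_recovers_generating_frequency(self):
        # binomial bound: 2000 diploids at ALT frequency 0.3
        rng = np.random.default_rng(42)
        n = 2000
        draws = rng.random((n, 2)) < 0.3
        genotypes = [
            tuple("ALT" if hit else "REF" for hit in row) for row in draws
        ]
        freqs = allele_frequencies(table_from_genotypes(genotypes), "L")
        se = math.sqrt(0.3 * 0.7 / (2 * n))
        assert abs(freqs["ALT"] - 0.3) < 3 * se

    def test_multiallelic_maf_is_one_minus_max(self):
        table = table_from_genotypes(
            [("16*1", "16*1")] * 6 + [("16*1", "17")] * 2 + [("17", "11")]
        )
        freqs = allele_frequencies(table, "L")
        assert minor_allele_frequency(table, "L") == pytest.approx(
            1 - max(freqs.values())
        )


class TestHWE:
    def test_exact_proportions_give_zero(self):
        table = table_from_genotypes(
            [("A", "A")] * 25 + [("A", "a")] * 50 + [("a", "a")] * 25
        )
        result = hwe_chisq(table, "L")
        assert result.chi2 == pytest.approx(0.0)
        assert result.df == 1

    def test_hand_calculated_statistic(self):
        table = table_from_genotypes(
            [("A", "A")] * 30 + [("A", "a")] * 40 + [("a", "a")] * 30
        )
        result = hwe_chisq(table, "L")
        assert result.chi2 == pytest.approx(4.0)
        assert result.df == 1

    def test_monomorphic_flagged_non_testable(self):
        table = table_from_genotypes([("A", "A")] * 10)
        result = hwe_chisq(table, "L")
        assert (result.chi2, result.df) == (0.0, 0)
        assert not result.testable

    def test_relabeling_invariance(self):
        genotypes = [("A", "A")] * 12 + [("A", "a")] * 30 + [("a", "a")] * 8
        relabeled = [
            tuple("X" if allele == "a" else "Y" for allele in pair)
            for pair in genotypes
        ]
        chi_1 = hwe_chisq(table_from_genotypes(genotypes), "L").chi2
        chi_2 = hwe_chisq(table_from_genotypes(relabeled), "L").chi2
        assert chi_1 == pytest.approx(chi_2)

    def test_multiallelic_df(self):
        table = table_from_genotypes(
            [("A", "B")] * 10 + [("B", "C")] * 10 + [("A", "C")] * 10
            + [("A", "A"), ("B", "B"), ("C", "C")]
        )
        result = hwe_chisq(table, "L")
        assert result.df == 3  # k = 3 -> k(k-1)/2

    def test_small_expected_counts_flagged(self):
        table = table_from_genotypes(
            [("A", "A")] * 30 + [("A", "a")] * 2
        )
        assert hwe_chisq(table, "L").small_counts


def brute_force_dprime(n_ab, n_aB, n_Ab, n_AB):
    """Independent |D|/Dmax via direct evaluation over the 2x2 table."""
    n = n_ab + n_aB + n_Ab + n_AB
    p_a = (n_ab + n_aB) / n
    p_b = (n_ab + n_Ab) / n
    d = n_ab / n - p_a * p_b
    # largest |D| attainable with the same margins, scanned numerically
    best = 0.0
    for k in range(0, n + 1):
        p11 = k / n
        if (
            p11 <= min(p_a, p_b) + 1e-12
            and p11 >= max(0.0, p_a + p_b - 1) - 1e-12
        ):
            cand = p11 - p_a * p_b
            if (cand >= 0) == (d >= 0):
                best = max(best, abs(cand))
    return 0.0 if best == 0 else abs(d) / best


class TestLinkageDisequilibrium:
    def test_complete_association(self):
        result = dprime_from_counts({("A", "B"): 50, ("a", "b"): 50})
        assert result.dprime == pytest.approx(1.0)
        assert result.lod > 3

    def test_independence(self):
        result = dprime_from_counts(
            {("A", "B"): 25, ("A", "b"): 25, ("a", "B"): 25, ("a", "b"): 25}
        )
        assert result.dprime == pytest.approx(0.0)
        assert result.lod == pytest.approx(0.0)

    def test_matches_brute_force_maximisation(self):
        counts = {("A", "B"): 40, ("A", "b"): 10, ("a", "B"): 10, ("a", "b"): 40}
        result = dprime_from_counts(counts)
        assert result.dprime == pytest.approx(brute_force_dprime(40, 10, 10, 40))

    @pytest.mark.parametrize("counts", [
        {("A", "B"): 30, ("A", "b"): 20, ("a", "B"): 5, ("a", "b"): 45},
        {("A", "B"): 3, ("A", "b"): 55, ("a", "B"): 40, ("a", "b"): 2},
    ])
    def test_dprime_bounded_and_brute_force_consistent(self, counts):
        result = dprime_from_counts(counts)
        assert 0.0 <= result.dprime <= 1.0
        oracle = brute_force_dprime(
            counts[("A", "B")], counts[("A", "b")],
            counts[("a", "B")], counts[("a", "b")],
        )
        assert result.dprime == pytest.approx(oracle, abs=1e-9)

    def test_monomorphic_locus_undefined(self):
        result = dprime_from_counts({("A", "B"): 50, ("A", "b"): 50})
        assert not result.defined

    def test_symmetry_and_relabeling_from_phased_diplotypes(self, make_spec):
        from promsat.haplotypes import clark_phase
        from promsat.synthetic_data import generate_population

        sim = generate_population(make_spec(n=150, seed=3))
        phased = clark_phase(sim.table)
        ab = pairwise_dprime(sim.table, "c.-185", "c.-46", phased.diplotypes)
        ba = pairwise_dprime(sim.table, "c.-46", "c.-185", phased.diplotypes)
        assert ab.dprime == pytest.approx(ba.dprime)
        assert ab.lod == pytest.approx(ba.lod)
        assert 0.0 <= ab.dprime <= 1.0


class TestGenotypeIO:
    def test_parse_call(self):
        assert parse_call("A/T") == ("A", "T")
        assert parse_call("./.") is None
        with pytest.raises(GenotypeFormatError):
            parse_call("A/T/G")

    def test_toy_file_round_trip(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text(
            "id\tspecies\tbreed\tsex\tc.-46\tmsat\n"
            "d1\tdog\tBoxer\tF\tT/T\t16*1/17\n"
            "d2\tdog\tBeagle\tM\tT/C\t17/17\n"
            "d3\tdog\tBoxer\tF\t./.\t16*1/16*1\n"
        )
        table = load_genotypes(path)
        assert len(table) == 3
        assert table.calls["d1"]["msat"] == ("16*1", "17")
        assert table.calls["d3"]["c.-46"] is None
        stats = locus_stats(table, "msat")
        assert stats.allele_counts == {"16*1": 3, "17": 3}

    def test_unknown_repeat_allele_rejected(self, tmp_path, registry):
        path = tmp_path / "g.tsv"
        path.write_text(
            "id\tspecies\tbreed\tsex\tmsat\n"
            "d1\tdog\tBoxer\tF\t16*9/17\n"
        )
        with pytest.raises(GenotypeFormatError, match="16\\*9"):
            load_genotypes(path, repeat_locus="msat", registry=registry)

    def test_non_diploid_cell_reports_row_and_column(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text(
            "id\tspecies\tbreed\tsex\tc.-46\n"
            "d1\tdog\tBoxer\tF\tT\n"
        )
        with pytest.raises(GenotypeFormatError, match="row 1.*c.-46"):
            load_genotypes(path)

    def test_stratum_subsetting(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text(
            "id\tspecies\tbreed\tsex\tc.-46\n"
            "d1\tdog\tBoxer\tF\tT/T\n"
            "w1\twolf\t\tM\tC/C\n"
        )
        table = load_genotypes(path)
        assert allele_frequencies(table, "c.-46", species="wolf") == {"C": 1.0}
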