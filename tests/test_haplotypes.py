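"""Clark-style phasing, haplotype nomenclature and diversity statistics."""

import math

import pytest

from promsat.haplotypes import (
    Haplotype,
    HaplotypeNameRegistry,
    breed_haplotype_table,
    clark_phase,
    haplotype_diversity,
    haplotype_diversity_truncated,
    name_haplotype,
    shared_haplotypes,
)
from promsat.popgen import GenotypeTable, Individual
from promsat.synthetic_data import generate_population


def table_from_calls(rows, loci, breeds=None):
    individuals, calls = [], {}
    for k, row in enumerate(rows):
        ind = Individual(
            id=f"i{k}", breed=(breeds or {}).get(k, "")
        )
        individuals.append(ind)
        calls[ind.id] = {
            locus: tuple(sorted(pair)) if pair else None
            for locus, pair in zip(loci, row)
        }
    return GenotypeTable(individuals, list(loci), calls)


LOCI = ("c.-185", "c.-46", "msat")


class TestClarkPhase:
    def test_fully_homozygous_population_read_directly(self):
        rows = [
            [("T", "T"), ("T", "T"), ("17", "17")],
            [("T", "T"), ("C", "C"), ("16*1", "16*1")],
        ]
        result = clark_phase(table_from_calls(rows, LOCI))
        assert {h.states for h in result.haplotypes} == {
            ("T", "T", "17"), ("T", "C", "16*1"),
        }
        assert all(h.support == "observed_in_homozygote"
                   for h in result.haplotypes)
        assert all(d.resolution == "direct" for d in result.diplotypes)

    def test_single_heterozygous_locus_resolved_directly(self):
        rows = [[("T", "T"), ("C", "T"), ("17", "17")]]
        result = clark_phase(table_from_calls(rows, LOCI))
        assert {h.states for h in result.haplotypes} == {
            ("T", "C", "17"), ("T", "T", "17"),
        }
        assert result.diplotypes[0].resolution == "direct"

    def test_subtraction_resolves_double_heterozygote(self):
        rows = [
            [("T", "T"), ("T", "T"), ("17", "17")],   # seeds T|T|17
            [("T", "-"), ("T", "C"), ("17", "17")],   # ambiguous alone
        ]
        result = clark_phase(table_from_calls(rows, LOCI))
        assert result.unresolved == []
        inferred = [h for h in result.haplotypes if h.support == "inferred"]
        assert [h.states for h in inferred] == [("-", "C", "17")]

    def test_inconsistent_individual_left_unresolved(self):
        rows = [
            [("T", "T"), ("T", "T"), ("17", "17")],
            [("T", "-"), ("T", "C"), ("11", "16*1")],  # 3-fold heterozygote
        ]
        result = clark_phase(table_from_calls(rows, LOCI))
        assert result.unresolved == ["i1"]
        assert len(result.diplotypes) == 1

    def test_missing_calls_never_phased(self):
        rows = [[("T", "T"), None, ("17", "17")]]
        result = clark_phase(table_from_calls(rows, LOCI))
        assert result.unresolved == ["i0"]

    def test_emitted_diplotypes_consistent_with_genotypes(self, make_spec):
        sim = generate_population(make_spec(n=120, seed=9))
        result = clark_phase(sim.table)
        for dip in result.diplotypes:
            genotype = [
                sim.table.calls[dip.individual.id][locus]
                for locus in sim.table.loci
            ]
            assert dip.consistent_with(genotype)

    def test_recovery_on_synthetic_population(self, make_spec):
        sim = generate_population(make_spec(n=200, seed=1))
        result = clark_phase(sim.table)
        truth = sim.true_frequencies()
        assert {h.states for h in result.haplotypes} == set(truth)
        est = {h.states: f for h, f in result.frequencies().items()}
        n_chrom = 2 * len(sim.table)
        for states, p in truth.items():
            se = math.sqrt(p * (1 - p) / n_chrom)
            assert abs(est[states] - p) <= 3 * se + 1e-12

    def test_input_order_invariance(self, make_spec):
        sim = generate_population(make_spec(n=100, seed=4))
        table = sim.table
        reversed_table = GenotypeTable(
            individuals=list(reversed(table.individuals)),
            loci=list(table.loci),
            calls=table.calls,
        )
        a = clark_phase(table)
        b = clark_phase(reversed_table)
        assert [h.states for h in a.haplotypes] == [h.states for h in b.haplotypes]
        assert a.counts == b.counts


def study_registry(loci=LOCI, repeat_locus="msat"):
    reference = {"c.-185": "T", "c.-46": "T"}
    return HaplotypeNameRegistry.from_reference(
        loci, repeat_locus, reference,
        extra_numbers={frozenset({("c.-185", "-")}): 3},
    )


class TestNomenclature:
    def test_reference_pattern_is_1A(self):
        hap = Haplotype(("T", "T", "17"))
        assert name_haplotype(hap, study_registry()) == "*1A(17)"

    def test_deletion_pattern_is_3A(self):
        hap = Haplotype(("-", "T", "11"))
        assert name_haplotype(hap, study_registry()) == "*3A(11)"

    def test_internal_snp_changes_letter_not_number(self):
        registry = study_registry()
        name_haplotype(Haplotype(("T", "T", "17")), registry)
        assert name_haplotype(
            Haplotype(("T", "C", "17")), registry
        ) == "*1B(17)"

    def test_novel_upstream_pattern_allocates_next_free_number(self):
        registry = study_registry()
        # 2 is free (1 and 3 are reserved); repeat length from allele name
        assert name_haplotype(
            Haplotype(("A", "T", "16*2")), registry
        ) == "*2A(16)"

    def test_same_stem_different_repeat_lengths_are_distinct(self):
        registry = study_registry()
        n17 = name_haplotype(Haplotype(("T", "T", "17")), registry)
        n18 = name_haplotype(Haplotype(("T", "T", "18")), registry)
        assert (n17, n18) == ("*1A(17)", "*1A(18)")

    def test_missing_state_rejected(self):
        with pytest.raises(ValueError):
            name_haplotype(Haplotype(("T", "", "17")), study_registry())


class TestDiversity:
    def test_monomorphic_is_zero(self):
        assert haplotype_diversity({"*1A(17)": 1.0}, 556) == 0.0

    def test_two_equal_haplotypes_small_sample_correction(self):
        assert haplotype_diversity([0.5, 0.5], 556) == pytest.approx(
            0.5009, abs=5e-5
        )

    def test_splitting_mass_strictly_increases_diversity(self):
        base = haplotype_diversity([0.5, 0.5], 100)
        split = haplotype_diversity([0.5, 0.25, 0.25], 100)
        assert split > base

    def test_frequencies_must_sum_to_one(self):
        with pytest.raises(ValueError):
            haplotype_diversity([0.5, 0.4], 100)

    def test_truncated_table_lumps_residual_as_singletons(self):
        # visible mass 0.9 over 100 chromosomes -> 10 singletons of 1/100
        h = haplotype_diversity_truncated([0.6, 0.3], 100)
        expected = 100 / 99 * (1 - (0.36 + 0.09 + 10 * 0.0001))
        assert h == pytest.approx(expected)


class TestCohortTables:
    def test_single_breed_single_haplotype(self):
        rows = [[("T", "T"), ("T", "T"), ("17", "17")]] * 6
        table = table_from_calls(rows, LOCI, breeds={k: "Boxer" for k in range(6)})
        result = clark_phase(table)
        freq, diversity = breed_haplotype_table(result.diplotypes)
        assert list(freq.index) == ["Boxer"]
        assert freq.iloc[0, 0] == 1.0
        assert diversity["Boxer"] == 0.0

    def test_small_breeds_excluded(self):
        rows = [[("T", "T"), ("T", "T"), ("17", "17")]] * 7
        breeds = {k: ("Husky" if k < 5 else "Chow") for k in range(7)}
        table = table_from_calls(rows, LOCI, breeds=breeds)
        result = clark_phase(table)
        freq, _ = breed_haplotype_table(result.diplotypes, min_breed_n=5)
        assert list(freq.index) == ["Husky"]

    def test_disjoint_breed_pools_give_block_structure(self, make_spec):
        spec = make_spec(
            n=120, seed=2,
            breeds={"A": 0.5, "B": 0.5},
            breed_frequencies={
                "A": [0.5, 0.5, 0.0, 0.0, 0.0],
                "B": [0.0, 0.0, 0.4, 0.3, 0.3],
            },
        )
        sim = generate_population(spec)
        result = clark_phase(sim.table)
        freq, _ = breed_haplotype_table(result.diplotypes)
        a_haps = set(freq.columns[freq.loc["A"] > 0])
        b_haps = set(freq.columns[freq.loc["B"] > 0])
        assert a_haps and b_haps and not (a_haps & b_haps)

    def test_per_breed_frequencies_sum_to_one(self, make_spec):
        sim = generate_population(
            make_spec(n=80, seed=6, breeds={"A": 0.6, "B": 0.4})
        )
        result = clark_phase(sim.table)
        freq, _ = breed_haplotype_table(result.diplotypes, min_breed_n=5)
        assert freq.sum(axis=1).round(12).eq(1.0).all()


class TestSharedHaplotypes:
    def test_disjoint_sets_share_nothing(self):
        _, sharing = shared_haplotypes({
            "dog": {"*1A(17)": 1.0},
            "coyote": {"*1C(10)": 1.0},
        })
        assert sharing[("dog", "coyote")] == 0

    def test_identical_tables_share_everything(self):
        freqs = {"*1A(17)": 0.5, "*3A(11)": 0.5}
        _, sharing = shared_haplotypes({"dog": freqs, "wolf": dict(freqs)})
        assert sharing[("dog", "wolf")] == 2

    def test_species_table_sharing_counts(self, species_freqs):
        tables = {
            species: species_freqs[f"freq_{species}"].to_dict()
            for species in ("dog", "wolf", "coyote")
        }
        presence, sharing = shared_haplotypes(tables)
        # visible rows of the species table only (the printed table is
        # truncated below frequency 0.05)
        assert sharing[("dog", "wolf")] == 4
        assert sharing[("dog", "coyote")] == 3
        assert sharing[("wolf", "coyote")] == 3
        assert presence.loc["*1A(17)"].all()
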