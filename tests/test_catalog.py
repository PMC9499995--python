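"""Catalog combinatorics, sequence generation and design screens."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medipspike.catalog import (
    DesignError,
    FragmentSpec,
    GenerationError,
    build_catalog,
    cpg_count_for,
    equimolar_amounts,
    generate_sequence,
    molecular_mass_ds,
    n_property_combinations,
    read_catalog_tsv,
    reference_kmer_set,
    reverse_complement,
    screen_genome_match,
    screen_secondary_structure,
    write_catalog_tsv,
)


class TestCombinatorics:
    def test_property_grid_has_27_combinations(self):
        assert n_property_combinations() == 27

    def test_full_design_has_54_fragments(self):
        assert len(build_catalog(include_failed=True)) == 54

    def test_synthesis_failures_leave_52(self):
        assert len(build_catalog(include_failed=False)) == 52

    @pytest.mark.parametrize("length", [80, 160, 320])
    def test_18_fragments_per_length_class(self, length):
        c = build_catalog(include_failed=True)
        assert sum(1 for f in c if f.length_bp == length) == 18

    def test_two_statuses_per_combination(self):
        c = build_catalog(include_failed=True)
        combos = {}
        for f in c:
            key = (f.length_bp, f.gc_content, f.cpg_fraction,
                   f.alternative_index)
            combos.setdefault(key, set()).add(f.methylation_status)
        assert all(v == {"methylated", "unmethylated"}
                   for v in combos.values())

    def test_no_high_gc_320_and_three_alternates(self):
        c = build_catalog(include_failed=True)
        assert not any(
            f.length_bp == 320 and f.gc_content == 0.65 for f in c
        )
        alts = {
            (f.gc_content, f.cpg_fraction)
            for f in c
            if f.length_bp == 320 and f.alternative_index == 2
        }
        assert alts == {(0.35, 1 / 80), (0.50, 1 / 40), (0.50, 1 / 20)}

    def test_failed_fragments_are_the_160_35_1in20_pair(self):
        c = build_catalog(include_failed=True)
        failed = [f for f in c if not f.synthesis_ok]
        assert len(failed) == 2
        assert all(
            (f.length_bp, f.gc_content, f.cpg_fraction)
            == (160, 0.35, 1 / 20)
            for f in failed
        )


class TestCpGCount:
    @pytest.mark.parametrize(
        "length,frac,expected",
        [(80, 1 / 80, 1), (80, 1 / 40, 2), (80, 1 / 20, 4),
         (160, 1 / 80, 2), (160, 1 / 40, 4), (160, 1 / 20, 8),
         (320, 1 / 20, 16)],
    )
    def test_designed_counts(self, length, frac, expected):
        assert cpg_count_for(length, frac) == expected

    def test_non_integral_product_rejected(self):
        with pytest.raises(DesignError):
            cpg_count_for(90, 1 / 80)


class TestSequenceGeneration:
    def test_exact_composition(self):
        spec = FragmentSpec("t", 80, 0.35, 1 / 80, "methylated")
        seq = generate_sequence(spec, seed=5)
        assert len(seq) == 80
        assert sum(seq.count(b) for b in "GC") == 28
        assert seq.count("CG") == 1

    def test_deterministic_given_seed(self):
        spec = FragmentSpec("t", 160, 0.50, 1 / 40, "methylated")
        assert generate_sequence(spec, seed=7) == generate_sequence(
            spec, seed=7
        )

    def test_infeasible_spec_raises(self):
        # 8 CpGs need 16 G/C bases but gc=0.05 allows only 4
        spec = FragmentSpec("t", 80, 0.05, 1 / 10, "methylated")
        with pytest.raises(GenerationError):
            generate_sequence(spec, seed=0)

    def test_catalog_sequences_validate(self, catalog52):
        for f in catalog52:
            f.validate_sequence()

    def test_alternates_have_distinct_sequences(self, catalog52):
        seqs = [f.sequence for f in catalog52]
        assert len(set(seqs)) == len(seqs)


def stem_oracle(seq, min_loop=3):
    """Brute force over all arm pairs: longest s such that seq[i:i+s]
    is the reverse complement of seq[j:j+s] with loop j-(i+s) >=
    min_loop."""
    n = len(seq)
    best = 0
    for s in range(1, n // 2 + 1):
        for i in range(n - s + 1):
            for j in range(i + s + min_loop, n - s + 1):
                if seq[i:i + s] == reverse_complement(seq[j:j + s]):
                    best = max(best, s)
    return best


class TestSecondaryStructureScreen:
    def test_homopolymer_has_no_stem(self):
        ok, stem = screen_secondary_structure("A" * 80)
        assert ok and stem == 0

    def test_constructed_hairpin_fails(self):
        arm = "ACGTACGTAC"
        seq = arm + "TTTT" + reverse_complement(arm)
        ok, stem = screen_secondary_structure(seq, stem_threshold=10)
        assert not ok
        assert stem >= 10

    def test_loop_shorter_than_minimum_not_a_stem(self):
        # perfect palindrome with zero loop: usable stem is limited by
        # the loop requirement
        seq = "AAACGCGTTT"  # revcomp of itself
        _, stem = screen_secondary_structure(seq, min_loop=3)
        assert stem == stem_oracle(seq)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=4, max_size=28))
    def test_matches_bruteforce_oracle(self, seq):
        _, stem = screen_secondary_structure(seq)
        assert stem == stem_oracle(seq)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            screen_secondary_structure("")


class TestGenomeMatchScreen:
    def test_verbatim_copy_fails(self, rng):
        ref = "".join(rng.choice(list("ACGT"), size=1000))
        assert not screen_genome_match(ref[100:180], ref, k=25)

    def test_disjoint_alphabet_passes(self):
        ref = "A" * 500
        assert screen_genome_match("CT" * 20, ref, k=25)

    def test_k_longer_than_sequence_rejected(self):
        with pytest.raises(ValueError):
            screen_genome_match("ACGT", "ACGT" * 100, k=25)

    def test_equals_naive_scan(self, rng):
        ref = "".join(rng.choice(list("ACGT"), size=2000))
        kmers = reference_kmer_set(ref, k=12)
        for _ in range(20):
            query = "".join(rng.choice(list("ACGT"), size=30))
            naive = not any(
                query[i:i + 12] in ref
                or query[i:i + 12] in reverse_complement(ref)
                for i in range(len(query) - 11)
            )
            from medipspike.catalog import screen_genome_match_kmers

            assert screen_genome_match_kmers(query, kmers, k=12) == naive


class TestEquimolar:
    def test_equal_masses_get_equal_split(self, catalog52):
        two = catalog52.subset(catalog52.ids()[:1] + catalog52.ids()[26:27])
        amounts = equimolar_amounts(two, total_mass_ng=2.0, scheme="global")
        vals = list(amounts.values())
        assert vals[0] == pytest.approx(vals[1], rel=1e-12)

    def test_mass_conservation_global(self, catalog52):
        amounts = equimolar_amounts(catalog52, 9.99, scheme="global")
        total = sum(
            amounts[f.id] * f.molecular_mass * 1e-3 for f in catalog52
        )
        assert total == pytest.approx(9.99, rel=1e-9)

    def test_mass_conservation_and_equality_per_pool(self, catalog52):
        amounts = equimolar_amounts(catalog52, 9.99,
                                    scheme="per-length-pool")
        total = sum(
            amounts[f.id] * f.molecular_mass * 1e-3 for f in catalog52
        )
        assert total == pytest.approx(9.99, rel=1e-9)
        for L in (80, 160, 320):
            pool = {amounts[f.id] for f in catalog52 if f.length_bp == L}
            assert max(pool) == pytest.approx(min(pool), rel=1e-12)

    def test_moles_equal_masses_proportional(self, catalog52):
        # global scheme: equal moles, masses proportional to M
        amounts = equimolar_amounts(catalog52, 3.0, scheme="global")
        vals = set(np.round(list(amounts.values()), 20))
        assert len(vals) == 1

    def test_missing_sequence_errors(self):
        c = build_catalog(include_failed=False)
        with pytest.raises(DesignError):
            equimolar_amounts(c, 1.0)


class TestMassAndIO:
    def test_molecular_mass_scales_with_length(self):
        assert molecular_mass_ds("AT" * 80) == pytest.approx(
            2 * molecular_mass_ds("AT" * 40) + 2 * 61.96, rel=1e-6
        )

    def test_mass_strand_symmetric(self):
        s = "ACGTTGCA"
        assert molecular_mass_ds(s) == pytest.approx(
            molecular_mass_ds(reverse_complement(s))
        )

    def test_catalog_tsv_roundtrip(self, catalog52, tmp_path):
        p = tmp_path / "cat.tsv"
        write_catalog_tsv(catalog52, p)
        back = read_catalog_tsv(p)
        assert back.ids() == catalog52.ids()
        assert back.known_amounts.keys() == catalog52.known_amounts.keys()
        f0 = back.fragments[0]
        assert f0.length_bp == catalog52.fragments[0].length_bp
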