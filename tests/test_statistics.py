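import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import matesim as ms
from matesim import stats as S
from matesim.fixtures import _oracle_wang
from matesim.population import make_founder_population, make_offspring


def _diverse_pop(layout, n=8, k=12, seed=0, gens=4):
    rng = np.random.default_rng(seed)
    pop = make_founder_population(layout, n, k, k)
    for _ in range(gens):
        pop = ms.wright_fisher_generation(pop, n, rng)
    return pop


# ---------------------------------------------------------------------------
# per-individual statistics
# ---------------------------------------------------------------------------

class TestHeterozygosityAndCOI:
    def test_counting_definition(self, tiny_layout):
        pop = make_founder_population(tiny_layout, 4, 4, 4)
        ind = pop.individual(0)
        ind.haplotypes[0, :] = 0
        ind.haplotypes[1, :] = 0
        ind.haplotypes[1, :3] = 1          # heterozygous at exactly 3 loci
        loci = np.arange(10)
        assert S.observed_heterozygosity(ind, loci) == pytest.approx(0.3)

    def test_empty_locus_set_rejected(self, tiny_layout):
        pop = make_founder_population(tiny_layout, 4, 4, 4)
        with pytest.raises(ValueError):
            S.observed_heterozygosity(pop.individual(0), [])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**16))
    def test_coi_complements_block_heterozygosity(self, tiny_layout, seed):
        pop = _diverse_pop(tiny_layout, seed=seed)
        for ind in pop:
            het = S.observed_heterozygosity(ind, tiny_layout.block_loci)
            assert S.coefficient_of_inbreeding(ind) + het == pytest.approx(1.0)

    def test_coi_half_when_half_blocks_homozygous(self, tiny_layout):
        pop = make_founder_population(tiny_layout, 4, 4, 4)
        ind = pop.individual(0)
        blocks = tiny_layout.block_loci
        ind.haplotypes[:, :] = 0
        ind.haplotypes[1, blocks[: len(blocks) // 2]] = 1
        assert S.coefficient_of_inbreeding(ind) == pytest.approx(0.5)


class TestRichness:
    def test_threshold_filter(self, tiny_layout):
        pop = make_founder_population(tiny_layout, 10, 4, 4)
        # engineer frequencies 0.9 / 0.06 / 0.04 at locus 0 (50 gene copies)
        pop25 = make_founder_population(tiny_layout, 25, 2, 2)
        copies = pop25.genotypes[:, :, 0].reshape(-1)
        copies[:] = 0
        copies[:3] = 1
        copies[3:5] = 2
        pop25.genotypes[:, :, 0] = copies.reshape(25, 2)
        assert S.allelic_richness(pop25, 0) == 3
        assert S.allelic_richness(pop25, 0, min_freq=0.05) == 2

    def test_monomorphic_and_present_allele_sets(self, tiny_layout):
        pop = make_founder_population(tiny_layout, 6, 1, 1)
        assert S.allelic_richness(pop, 0) == 1
        pop.genotypes[0, 0, 0] = 3
        pop.genotypes[1, 0, 0] = 7
        pop.genotypes[2, 1, 0] = 9
        assert S.allelic_richness(pop, 0) == 4

    def test_vectorised_matches_scalar(self, tiny_layout):
        pop = _diverse_pop(tiny_layout, seed=3)
        rich = S.richness_per_locus(pop)
        rich05 = S.richness_per_locus(pop, min_freq=0.05)
        for locus in range(tiny_layout.n_loci):
            assert rich[locus] == S.allelic_richness(pop, locus)
            assert rich05[locus] == S.allelic_richness(pop, locus, 0.05)


class TestAlleleFrequencies:
    def test_simple_counts(self, tiny_layout):
        pop = make_founder_population(tiny_layout, 2, 1, 1)
        pop.genotypes[:, :, 0] = [[1, 1], [1, 2]]
        table = S.allele_frequencies(pop, [0])
        assert table[0] == {1: 0.75, 2: 0.25}

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**16))
    def test_frequencies_sum_to_one(self, tiny_layout, seed):
        pop = _diverse_pop(tiny_layout, seed=seed)
        table = S.allele_frequencies(pop, np.arange(tiny_layout.n_loci))
        assert np.allclose(table.freq.sum(axis=1), 1.0)


# ---------------------------------------------------------------------------
# pair statistics
# ---------------------------------------------------------------------------

class TestExpectedOffspringHeterozygosity:
    def test_single_locus_shared_pair_is_half(self, tiny_layout):
        pop = make_founder_population(tiny_layout, 4, 4, 4)
        a, b = pop.individual(0), pop.individual(1)
        a.haplotypes[:, 0] = [0, 1]
        b.haplotypes[:, 0] = [0, 1]
        # gametic pairs (0,0),(0,1),(1,0),(1,1) -> het 0, 1, 1, 0
        assert S.expected_offspring_heterozygosity(a, b, [0]) == pytest.approx(0.5)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**16))
    def test_matches_monte_carlo_offspring(self, tiny_layout, seed):
        pop = _diverse_pop(tiny_layout, seed=seed)
        rng = np.random.default_rng(seed + 1)
        p1, p2 = pop.individual(0), pop.individual(1)
        loci = np.arange(tiny_layout.n_loci)
        exact = S.expected_offspring_heterozygosity(p1, p2, loci)
        n = 400
        hets = [
            S.observed_heterozygosity(
                make_offspring(p1, p2, tiny_layout, rng, id=1000 + i), loci
            )
            for i in range(n)
        ]
        se = np.std(hets, ddof=1) / np.sqrt(n)
        assert abs(np.mean(hets) - exact) < 4 * se + 1e-9


class TestInternalRelatedness:
    def test_guaranteed_heterozygote_equal_freqs(self, tiny_layout):
        # single locus, f_a = f_b = 0.5: IR = -1
        pop = make_founder_population(tiny_layout, 2, 2, 2)
        loci = [int(tiny_layout.marker_loci[0])]
        table = S.AlleleFrequencyTable(
            loci=np.asarray(loci), freq=np.array([[0.5, 0.5]])
        )
        a, b = pop.individual(0), pop.individual(1)
        a.haplotypes[:, loci[0]] = [0, 0]
        b.haplotypes[:, loci[0]] = [1, 1]
        assert S.internal_relatedness_pair(a, b, loci, table) == pytest.approx(-1.0)

    def test_guaranteed_heterozygote_rare_alleles(self, tiny_layout):
        pop = make_founder_population(tiny_layout, 2, 2, 2)
        loci = [int(tiny_layout.marker_loci[0])]
        table = S.AlleleFrequencyTable(
            loci=np.asarray(loci), freq=np.array([[0.1, 0.1, 0.8]])
        )
        a, b = pop.individual(0), pop.individual(1)
        a.haplotypes[:, loci[0]] = [0, 0]
        b.haplotypes[:, loci[0]] = [1, 1]
        # -(0.1 + 0.1) / (2 - 0.2)
        assert S.internal_relatedness_pair(a, b, loci, table) == pytest.approx(
            -0.2 / 1.8
        )

    def test_shared_homozygotes_give_one(self, tiny_layout):
        pop = make_founder_population(tiny_layout, 4, 1, 1)
        markers = tiny_layout.marker_loci
        freqs = S.allele_frequencies(pop, markers)
        v = S.internal_relatedness_pair(
            pop.individual(0), pop.individual(1), markers, freqs
        )
        assert v == 1.0

    def test_missing_allele_rejected(self, tiny_layout):
        pop = make_founder_population(tiny_layout, 4, 4, 4)
        markers = tiny_layout.marker_loci
        freqs = S.allele_frequencies(pop, markers)
        intruder = pop.individual(0)
        intruder.haplotypes[0, markers[0]] = 200
        with pytest.raises(KeyError):
            S.internal_relatedness_pair(
                intruder, pop.individual(1), markers, freqs
            )


class TestWangRelatedness:
    def test_matches_independent_oracle(self, tiny_layout):
        rng = np.random.default_rng(5)
        markers = tiny_layout.marker_loci
        for trial in range(20):
            pop = _diverse_pop(tiny_layout, seed=trial, gens=3)
            freqs = S.allele_frequencies(pop, markers)
            fd = {int(l): freqs[int(l)] for l in markers}
            i, j = rng.choice(pop.size, 2, replace=False)
            for weights in ("wang", "uniform"):
                mine = S.wang_relatedness(
                    pop.individual(int(i)), pop.individual(int(j)),
                    markers, freqs, locus_weights=weights,
                )
                oracle = _oracle_wang(
                    pop.genotypes[i], pop.genotypes[j],
                    [int(l) for l in markers], fd, locus_weights=weights,
                )
                assert mine == pytest.approx(oracle, abs=1e-12)

    def test_monomorphic_loci_dropped_and_all_monomorphic_errors(
        self, tiny_layout
    ):
        pop = make_founder_population(tiny_layout, 4, 1, 1)
        markers = tiny_layout.marker_loci
        freqs = S.allele_frequencies(pop, markers)
        with pytest.raises(ValueError, match="monomorphic"):
            S.wang_relatedness(
                pop.individual(0), pop.individual(1), markers, freqs
            )

    def test_unbiased_for_unrelated_pairs(self):
        layout = ms.build_genome_layout(1, 10, 500_000, [10])
        markers = layout.marker_loci
        rng = np.random.default_rng(77)
        F = np.vstack([rng.dirichlet(np.ones(6)) for _ in markers])
        table = S.AlleleFrequencyTable(loci=markers, freq=F)
        est = S.WangEstimator(table)
        n = 3000
        draw = lambda: np.stack(
            [rng.choice(6, size=(n, 2), p=F[i]) for i in range(len(markers))],
            axis=2,
        )
        r = est.relatedness(draw(), draw())
        se = r.std(ddof=1) / np.sqrt(n)
        assert abs(r.mean()) < 4 * se


class TestGenomewideRelatedness:
    def test_identical_homozygous_pair_is_one(self, tiny_layout):
        pop = make_founder_population(tiny_layout, 4, 1, 1)
        loci = np.arange(tiny_layout.n_loci)
        assert S.genomewide_relatedness(
            pop.individual(0), pop.individual(1), loci
        ) == pytest.approx(1.0)

    def test_allele_disjoint_pair_is_zero(self, tiny_layout):
        pop = make_founder_population(tiny_layout, 10, 20, 20)
        loci = np.arange(tiny_layout.n_loci)
        for normalize in (True, False):
            assert S.genomewide_relatedness(
                pop.individual(0), pop.individual(4), loci, normalize=normalize
            ) == 0.0

    def test_full_sibs_average_half(self, tiny_layout):
        rng = np.random.default_rng(9)
        pop = make_founder_population(tiny_layout, 10, 20, 20)
        loci = np.arange(tiny_layout.n_loci)
        vals = []
        for i in range(300):
            s1 = make_offspring(pop.individual(0), pop.individual(1),
                                tiny_layout, rng, id=100 + 2 * i)
            s2 = make_offspring(pop.individual(0), pop.individual(1),
                                tiny_layout, rng, id=101 + 2 * i)
            vals.append(S.genomewide_relatedness(s1, s2, loci))
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 0.5) < 4 * se


class TestPedigreeRelatedness:
    def test_standard_path_counting_values(self):
        for name, pair, value in [
            ("full_sib_trio", None, 0.5),
            ("half_sib_trio", None, 0.25),
        ]:
            fx = ms.make_fixture(name)
            exp = fx.expected[0]
            assert exp.value == value
            sib1 = fx.population.individual(exp.subjects[0])
            sib2 = fx.population.individual(exp.subjects[1])
            assert S.pedigree_relatedness(sib1, sib2) == value

    def test_disjoint_pedigrees_are_unrelated(self, tiny_layout):
        pop = make_founder_population(tiny_layout, 4, 4, 4)
        assert S.pedigree_relatedness(pop.individual(0), pop.individual(1)) == 0.0

    def test_first_cousins(self, tiny_layout, rng):
        pop = make_founder_population(tiny_layout, 8, 16, 16)
        layout = tiny_layout
        a = make_offspring(pop.individual(0), pop.individual(1), layout, rng, 10)
        b = make_offspring(pop.individual(0), pop.individual(1), layout, rng, 11)
        spouse_a = make_offspring(pop.individual(2), pop.individual(3), layout, rng, 12)
        spouse_b = make_offspring(pop.individual(4), pop.individual(5), layout, rng, 13)
        cousin1 = make_offspring(a, spouse_a, layout, rng, 20)
        cousin2 = make_offspring(b, spouse_b, layout, rng, 21)
        assert S.pedigree_relatedness(cousin1, cousin2) == pytest.approx(0.125)

    def test_shared_parent_paths_not_double_counted(self, tiny_layout, rng):
        # full sibs whose parents have known parents: grandparent paths run
        # through the shared parents and must be excluded
        pop = make_founder_population(tiny_layout, 8, 16, 16)
        layout = tiny_layout
        father = make_offspring(pop.individual(0), pop.individual(1), layout, rng, 10)
        mother = make_offspring(pop.individual(2), pop.individual(3), layout, rng, 11)
        s1 = make_offspring(father, mother, layout, rng, 20)
        s2 = make_offspring(father, mother, layout, rng, 21)
        assert S.pedigree_relatedness(s1, s2) == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# invariance properties shared by the pair statistics
# ---------------------------------------------------------------------------

def _relabel(pop, freqs, perm):
    """Apply an allele-id permutation to genotypes and frequency table."""
    relabelled = pop.copy()
    relabelled.genotypes = perm[pop.genotypes.astype(np.intp)].astype(np.uint16)
    ncol = freqs.freq.shape[1]
    new_freq = np.zeros((freqs.freq.shape[0], len(perm)))
    new_freq[:, perm[:ncol]] = freqs.freq
    return relabelled, S.AlleleFrequencyTable(loci=freqs.loci, freq=new_freq)


@settings(max_examples=15, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**16))
def test_pair_statistics_are_symmetric(tiny_layout, seed):
    pop = _diverse_pop(tiny_layout, seed=seed)
    markers = tiny_layout.marker_loci
    loci = np.arange(tiny_layout.n_loci)
    freqs = S.allele_frequencies(pop, markers)
    a, b = pop.individual(0), pop.individual(2)
    assert S.expected_offspring_heterozygosity(a, b, loci) == pytest.approx(
        S.expected_offspring_heterozygosity(b, a, loci), abs=1e-14
    )
    assert S.internal_relatedness_pair(a, b, markers, freqs) == pytest.approx(
        S.internal_relatedness_pair(b, a, markers, freqs), abs=1e-14
    )
    assert S.wang_relatedness(a, b, markers, freqs) == pytest.approx(
        S.wang_relatedness(b, a, markers, freqs), abs=1e-12
    )
    assert S.genomewide_relatedness(a, b, loci) == pytest.approx(
        S.genomewide_relatedness(b, a, loci), abs=1e-14
    )
    assert S.pedigree_relatedness(a, b) == S.pedigree_relatedness(b, a)


@settings(max_examples=15, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**16))
def test_ir_and_wang_invariant_to_allele_relabelling(tiny_layout, seed):
    pop = _diverse_pop(tiny_layout, seed=seed, k=8)
    markers = tiny_layout.marker_loci
    freqs = S.allele_frequencies(pop, markers)
    perm_rng = np.random.default_rng(seed + 1)
    n_ids = max(int(pop.genotypes.max()) + 1, freqs.freq.shape[1])
    perm = perm_rng.permutation(n_ids)
    pop2, freqs2 = _relabel(pop, freqs, perm)
    a1, b1 = pop.individual(0), pop.individual(1)
    a2, b2 = pop2.individual(0), pop2.individual(1)
    assert S.internal_relatedness_pair(
        a1, b1, markers, freqs
    ) == pytest.approx(
        S.internal_relatedness_pair(a2, b2, markers, freqs2), abs=1e-12
    )
    assert S.wang_relatedness(a1, b1, markers, freqs) == pytest.approx(
        S.wang_relatedness(a2, b2, markers, freqs2), abs=1e-12
    )


def test_classical_ir_variant_against_hand_computation(tiny_layout):
    pop = make_founder_population(tiny_layout, 4, 4, 4)
    markers = [int(l) for l in tiny_layout.marker_loci]
    ind = pop.individual(0)
    ind.haplotypes[0, markers] = [0, 0, 1]
    ind.haplotypes[1, markers] = [0, 1, 2]
    table = S.AlleleFrequencyTable(
        loci=np.asarray(markers),
        freq=np.array([[0.5, 0.3, 0.2]] * 3),
    )
    # H = 1 homozygous locus of N = 3; sum f over carried alleles
    sf = (0.5 + 0.5) + (0.5 + 0.3) + (0.3 + 0.2)
    expected = (2 * 1 - sf) / (2 * 3 - sf)
    assert S.internal_relatedness_individual(
        ind, markers, table, method="classical"
    ) == pytest.approx(expected)
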