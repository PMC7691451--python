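import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chisquare

import matesim as ms
from matesim import stats as S
from matesim.mate_choice import (
    MateChoiceParams,
    MatingDeadlockError,
    _GenerationContext,
    _pair_scores,
    choose_mate,
    run_mate_choice_generation,
    sample_first_parent,
    sample_mating_pool,
)
from matesim.population import make_founder_population


def _diverse_pop(layout, n=12, k=12, seed=0, gens=4):
    rng = np.random.default_rng(seed)
    pop = make_founder_population(layout, n, k, k)
    for _ in range(gens):
        pop = ms.wright_fisher_generation(pop, n, rng)
    return pop


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(model="NOT_A_MODEL"),
            dict(mating_pool_size=0),
            dict(maximum_number_of_matings=0),
            dict(proportion_for_layered=0.0),
            dict(proportion_for_layered=1.5),
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MateChoiceParams(**kwargs)


class TestFirstParent:
    def test_only_unmated_individual_is_selected(self, tiny_layout, rng):
        pop = make_founder_population(tiny_layout, 6, 4, 4)
        params = MateChoiceParams(maximum_number_of_matings=2)
        pop.matings[:] = 2
        pop.matings[4] = 1
        for _ in range(10):
            assert sample_first_parent(pop, params, rng).id == 4

    def test_cap_at_population_size_allows_anyone(self, tiny_layout, rng):
        pop = make_founder_population(tiny_layout, 6, 4, 4)
        params = MateChoiceParams(maximum_number_of_matings=6)
        seen = {sample_first_parent(pop, params, rng).id for _ in range(200)}
        assert seen == set(range(6))

    def test_uniformity_over_eligible_set(self, tiny_layout, rng):
        pop = make_founder_population(tiny_layout, 8, 4, 4)
        params = MateChoiceParams(maximum_number_of_matings=3)
        pop.matings[:4] = 3                      # half the population capped
        draws = [sample_first_parent(pop, params, rng).id for _ in range(10_000)]
        counts = np.bincount(draws, minlength=8)
        assert (counts[:4] == 0).all()
        stat, p = chisquare(counts[4:])
        assert p > 1e-4

    def test_deadlock_when_everyone_capped(self, tiny_layout, rng):
        pop = make_founder_population(tiny_layout, 4, 4, 4)
        params = MateChoiceParams(maximum_number_of_matings=1)
        pop.matings[:] = 1
        with pytest.raises(MatingDeadlockError, match="generation"):
            sample_first_parent(pop, params, rng)


class TestMatingPool:
    def test_pool_is_everyone_else_when_large(self, tiny_layout, rng):
        pop = make_founder_population(tiny_layout, 6, 4, 4)
        params = MateChoiceParams(mating_pool_size=10)
        first = pop.individual(2)
        pool = sample_mating_pool(pop, first, params, rng)
        assert sorted(c.id for c in pool) == [0, 1, 3, 4, 5]

    def test_pool_never_contains_first_parent(self, tiny_layout, rng):
        pop = make_founder_population(tiny_layout, 10, 4, 4)
        params = MateChoiceParams(mating_pool_size=4)
        first = pop.individual(7)
        for _ in range(50):
            pool = sample_mating_pool(pop, first, params, rng)
            assert len(pool) == 4
            assert all(c.id != 7 for c in pool)

    def test_fresh_pool_per_event(self, tiny_layout, rng):
        pop = make_founder_population(tiny_layout, 20, 4, 4)
        params = MateChoiceParams(mating_pool_size=5)
        first = pop.individual(0)
        pools = {
            tuple(sorted(c.id for c in sample_mating_pool(pop, first, params, rng)))
            for _ in range(30)
        }
        # 30 draws of 5 from 19 collide with overwhelmingly low probability
        assert len(pools) > 10

    def test_resampled_until_eligible_member_present(self, tiny_layout, rng):
        pop = make_founder_population(tiny_layout, 10, 4, 4)
        params = MateChoiceParams(mating_pool_size=2, maximum_number_of_matings=1)
        pop.matings[:] = 1
        pop.matings[9] = 0                      # single eligible mate
        first = pop.individual(0)
        for _ in range(10):
            pool = sample_mating_pool(pop, first, params, rng)
            assert any(c.id == 9 for c in pool)

    def test_deadlock_when_no_eligible_mate_exists(self, tiny_layout, rng):
        pop = make_founder_population(tiny_layout, 6, 4, 4)
        params = MateChoiceParams(maximum_number_of_matings=1)
        pop.matings[:] = 1
        pop.matings[0] = 0                      # only the first parent is free
        with pytest.raises(MatingDeadlockError, match="no eligible mate"):
            sample_mating_pool(pop, pop.individual(0), params, rng)


class TestChooseMate:
    def test_single_eligible_candidate_wins_under_every_model(
        self, tiny_layout, rng
    ):
        pop = _diverse_pop(tiny_layout)
        freqs = S.allele_frequencies(pop, tiny_layout.marker_loci)
        first = pop.individual(0)
        lone = pop.individual(3)
        for model in ms.MODELS:
            params = MateChoiceParams(model=model)
            assert choose_mate(first, [lone], params, freqs, rng).id == lone.id

    def test_gw_het_prefers_allele_disjoint_candidate(self, tiny_layout, rng):
        pop = make_founder_population(tiny_layout, 10, 20, 20)
        first = pop.individual(0)
        clones = []
        for i in (1, 2, 3):
            c = pop.individual(i)
            c.haplotypes[:] = first.haplotypes   # identical to first
            clones.append(c)
        disjoint = pop.individual(5)             # private founder alleles
        params = MateChoiceParams(model="GW_HET")
        chosen = choose_mate(first, clones + [disjoint], params, None, rng)
        assert chosen.id == disjoint.id

    def test_ineligible_candidates_are_excluded(self, tiny_layout, rng):
        pop = _diverse_pop(tiny_layout)
        params = MateChoiceParams(model="RANDOM", maximum_number_of_matings=2)
        pop.matings[1] = 2
        pop.matings[2] = 2
        pool = [pop.individual(i) for i in (1, 2, 3)]
        free = pop.individual(3).id
        for _ in range(10):
            assert choose_mate(pop.individual(0), pool, params, None, rng).id == free

    def test_empty_eligible_pool_deadlocks(self, tiny_layout, rng):
        pop = _diverse_pop(tiny_layout)
        params = MateChoiceParams(model="RANDOM", maximum_number_of_matings=1)
        pop.matings[1] = 1
        pool = [pop.individual(1)]
        with pytest.raises(MatingDeadlockError):
            choose_mate(pop.individual(0), pool, params, None, rng)

    def test_ties_are_broken_uniformly(self, tiny_layout):
        pop = make_founder_population(tiny_layout, 6, 1, 1)  # everyone identical
        params = MateChoiceParams(model="MS33_HET")
        first = pop.individual(0)
        pool = [pop.individual(i) for i in (1, 2, 3)]
        rng = np.random.default_rng(0)
        seen = {choose_mate(first, pool, params, None, rng).id for _ in range(100)}
        assert seen == {1, 2, 3}

    def test_layered_choice_reproduces_fixture_expectation(self, rng):
        fx = ms.make_fixture("layered_choice_4candidates")
        exp = next(
            e for e in fx.expected if e.statistic == "choose_mate_layered"
        )
        params = MateChoiceParams(
            model="MS33_IR_AGR",
            proportion_for_layered=exp.kwargs["proportion_for_layered"],
        )
        first = fx.population.individual(exp.subjects[0])
        pool = [fx.population.individual(i) for i in exp.subjects[1:]]
        for _ in range(5):
            assert choose_mate(first, pool, params, fx.freqs, rng).id == exp.value


@settings(max_examples=10, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**16))
def test_vectorised_scores_match_reference_pair_functions(tiny_layout, seed):
    pop = _diverse_pop(tiny_layout, seed=seed)
    freqs = S.allele_frequencies(pop, tiny_layout.marker_loci)
    cand_idx = np.array([1, 3, 5, 7, 9])
    cands = [pop.individual(int(i)) for i in cand_idx]
    first = pop.individual(0)
    for model in ("MS33_HET", "GW_HET", "MS33_IR", "MS33_AGR", "GW_REL",
                  "PEDIGREE"):
        ctx = _GenerationContext(pop, MateChoiceParams(model=model))
        fast, hi_fast = ctx.scores(pop, 0, cand_idx, model)
        slow, hi_slow = _pair_scores(first, cands, model, freqs)
        assert hi_fast == hi_slow
        assert np.allclose(fast, slow, atol=1e-12)


class TestPairScore:
    def test_labels_and_orientation(self, tiny_layout):
        from matesim.mate_choice import pair_score

        pop = _diverse_pop(tiny_layout)
        freqs = S.allele_frequencies(pop, tiny_layout.marker_loci)
        a, b = pop.individual(0), pop.individual(1)
        expectations = {
            "GW_HET": ("HET", True),
            "MS33_IR": ("IR", False),
            "MS33_AGR": ("AGR", False),
            "GW_REL": ("REL", False),
            "PEDIGREE": ("PEDIGREE", False),
        }
        for model, (name, higher) in expectations.items():
            score = pair_score(a, b, model, freqs)
            assert score.statistic_name == name
            assert score.higher_is_better == higher
        with pytest.raises(ValueError):
            pair_score(a, b, "RANDOM")


class TestGeneration:
    def test_offspring_count_and_counter_reset(self, tiny_layout, rng):
        pop = _diverse_pop(tiny_layout)
        params = MateChoiceParams(model="RANDOM")
        nxt = run_mate_choice_generation(pop, params, 15, rng)
        assert nxt.size == 15
        assert (nxt.matings == 0).all()
        assert nxt.generation == pop.generation + 1

    def test_mating_cap_is_never_exceeded(self, tiny_layout, rng):
        pop = _diverse_pop(tiny_layout, n=20)
        params = MateChoiceParams(model="RANDOM", maximum_number_of_matings=5)
        audit = []
        nxt = run_mate_choice_generation(pop, params, 40, rng, audit=audit)
        parent_events = np.concatenate(
            [[a[1] for a in audit], [a[2] for a in audit]]
        )
        counts = np.bincount(parent_events.astype(int))
        assert counts.max() <= 5
        assert len(audit) == 40
        # both parents of every offspring are recorded
        assert nxt.size == 40

    def test_cap_binds_under_small_cap_and_large_target(self, tiny_layout, rng):
        pop = _diverse_pop(tiny_layout, n=20)
        params = MateChoiceParams(model="MS33_HET", maximum_number_of_matings=5)
        nxt = run_mate_choice_generation(pop, params, 40, rng)
        assert (pop.matings <= 5).all()
        assert pop.matings.sum() == 2 * 40
        assert nxt.size == 40

    def test_audit_records_score_per_event(self, tiny_layout, rng):
        pop = _diverse_pop(tiny_layout)
        params = MateChoiceParams(model="GW_HET")
        audit = []
        run_mate_choice_generation(pop, params, 5, rng, audit=audit)
        for gen, first_id, mate_id, score in audit:
            assert first_id != mate_id
            assert 0.0 <= score <= 1.0

    def test_offspring_pedigree_links_to_chosen_parents(self, tiny_layout, rng):
        pop = _diverse_pop(tiny_layout)
        params = MateChoiceParams(model="RANDOM")
        audit = []
        nxt = run_mate_choice_generation(pop, params, 8, rng, audit=audit)
        for k, (_, first_id, mate_id, _) in enumerate(audit):
            assert tuple(nxt.parents[k]) == (first_id, mate_id)
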