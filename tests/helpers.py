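"""Shared evaluation harness: recompute a fixture's expected statistics."""

import numpy as np

import matesim as ms
from matesim import stats as S


def resolve_locus_set(fixture, kwargs):
    name = kwargs.get("locus_set", "markers")
    layout = fixture.layout
    return {
        "markers": layout.marker_loci,
        "blocks": layout.block_loci,
        "all": np.arange(layout.n_loci),
    }[name]


def evaluate_expected(fixture, exp):
    """Recompute one ExpectedStatistic through the public API."""
    pop = fixture.population
    st, sub, kw = exp.statistic, exp.subjects, dict(exp.kwargs)
    if st == "observed_heterozygosity":
        return S.observed_heterozygosity(
            pop.individual(sub[0]), resolve_locus_set(fixture, kw)
        )
    if st == "coefficient_of_inbreeding":
        return S.coefficient_of_inbreeding(pop.individual(sub[0]))
    if st == "allelic_richness":
        return S.allelic_richness(pop, sub[0], kw.get("min_freq"))
    if st == "allele_frequencies":
        return S.allele_frequencies(pop, [sub[0]])[sub[0]]
    if st == "expected_offspring_heterozygosity":
        return S.expected_offspring_heterozygosity(
            pop.individual(sub[0]), pop.individual(sub[1]),
            resolve_locus_set(fixture, kw),
        )
    if st == "internal_relatedness_pair":
        return S.internal_relatedness_pair(
            pop.individual(sub[0]), pop.individual(sub[1]),
            fixture.layout.marker_loci, fixture.freqs,
        )
    if st == "internal_relatedness_individual":
        return S.internal_relatedness_individual(
            pop.individual(sub[0]), fixture.layout.marker_loci, fixture.freqs
        )
    if st == "wang_relatedness":
        return S.wang_relatedness(
            pop.individual(sub[0]), pop.individual(sub[1]),
            fixture.layout.marker_loci, fixture.freqs,
            locus_weights=kw.get("locus_weights", "wang"),
        )
    if st == "genomewide_relatedness":
        return S.genomewide_relatedness(
            pop.individual(sub[0]), pop.individual(sub[1]),
            resolve_locus_set(fixture, kw), normalize=kw.get("normalize", True),
        )
    if st == "pedigree_relatedness":
        return S.pedigree_relatedness(
            pop.individual(sub[0]), pop.individual(sub[1])
        )
    if st == "choose_mate_layered":
        params = ms.MateChoiceParams(
            model="MS33_IR_AGR",
            proportion_for_layered=kw["proportion_for_layered"],
        )
        first = pop.individual(sub[0])
        pool = [pop.individual(i) for i in sub[1:]]
        chosen = ms.choose_mate(
            first, pool, params, fixture.freqs, np.random.default_rng(0)
        )
        return chosen.id
    raise AssertionError(f"no evaluator for statistic {st!r}")


def compare_expected(fixture, exp, tol=1e-12):
    actual = evaluate_expected(fixture, exp)
    if isinstance(exp.value, dict):
        assert set(actual) == set(exp.value)
        for k in exp.value:
            assert abs(actual[k] - exp.value[k]) <= tol
    else:
        assert abs(float(actual) - float(exp.value)) <= tol, (
            f"{fixture.name}/{exp.statistic}{exp.subjects}: "
            f"{actual} != {exp.value}"
        )
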