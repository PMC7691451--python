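"""Tiny synthetic populations with analytically known statistics.

Every shipped scenario bundles a small population (emitted in the same
genotype-table format the population module reads), an allele-frequency
table, and a list of expected statistic values.  Expected values are never
hand-typed: they are computed at fixture-build time by the brute-force
oracles in this module, which are independent scalar transcriptions
(explicit loops, explicit matrix adjugates) of each statistic's definition
and share no code with :mod:`matesim.stats`.

Scenarios
    monomorphic                 one allele everywhere
    max_diverse_founders        every founder gene copy a distinct allele
    full_sib_trio               two founders and two full sibs
    half_sib_trio               three founders, two half sibs
    layered_choice_4candidates  hand-built pool where the layered (IR then
                                Wang) rule picks the candidate that is
                                second-best by IR but best by Wang among the
                                IR-selected half
    wang_oracle_10locus         fixed 10-locus genotype pair with a declared
                                frequency table covering every similarity
                                category
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np

from .genome import GenomeLayout, build_genome_layout
from .population import Population
from .stats import AlleleFrequencyTable

__all__ = ["CATALOGUE", "Fixture", "ExpectedStatistic", "make_fixture"]

CATALOGUE = (
    "monomorphic",
    "max_diverse_founders",
    "full_sib_trio",
    "half_sib_trio",
    "layered_choice_4candidates",
    "wang_oracle_10locus",
)


@dataclasses.dataclass(frozen=True)
class ExpectedStatistic:
    """One oracle-computed expectation for a statistic on fixture subjects."""

    statistic: str
    subjects: tuple
    value: object
    kwargs: dict = dataclasses.field(default_factory=dict)


@dataclasses.dataclass
class Fixture:
    name: str
    layout: GenomeLayout
    population: Population
    freqs: AlleleFrequencyTable
    expected: "list[ExpectedStatistic]"


# ---------------------------------------------------------------------------
# brute-force oracles (scalar, loop-based, independent of matesim.stats)
# ---------------------------------------------------------------------------

def _oracle_het(hap_a, hap_b, loci) -> float:
    n_het = sum(1 for l in loci if hap_a[l] != hap_b[l])
    return n_het / len(loci)


def _oracle_richness(genotypes, locus, min_freq=None) -> int:
    copies = [int(g[h][locus]) for g in genotypes for h in (0, 1)]
    count = {}
    for a in copies:
        count[a] = count.get(a, 0) + 1
    if min_freq is None:
        return len(count)
    need = min_freq * len(copies)
    return sum(1 for v in count.values() if v >= need - 1e-12)


def _oracle_frequencies(genotypes, locus) -> "dict[int, float]":
    copies = [int(g[h][locus]) for g in genotypes for h in (0, 1)]
    out: "dict[int, float]" = {}
    for a in copies:
        out[a] = out.get(a, 0.0) + 1.0 / len(copies)
    return out


def _oracle_eoh(g1, g2, loci) -> float:
    total = 0.0
    for i in (0, 1):
        for j in (0, 1):
            total += sum(1 for l in loci if g1[i][l] == g2[j][l]) / len(loci)
    return 1.0 - total / 4.0


def _single_locus_ir(a, b, freq) -> float:
    if a == b:
        return 1.0
    s = freq[a] + freq[b]
    return -s / (2.0 - s)


def _oracle_ir_pair(g1, g2, loci, freq_of) -> float:
    per_locus = []
    for l in loci:
        vals = [
            _single_locus_ir(int(g1[i][l]), int(g2[j][l]), freq_of[l])
            for i in (0, 1)
            for j in (0, 1)
        ]
        per_locus.append(sum(vals) / 4.0)
    return sum(per_locus) / len(per_locus)


def _oracle_ir_individual(g, loci, freq_of) -> float:
    vals = [_single_locus_ir(int(g[0][l]), int(g[1][l]), freq_of[l]) for l in loci]
    return sum(vals) / len(vals)


def _oracle_gw_rel(g1, g2, loci, normalize=True) -> float:
    fbar = 0.0
    for i in (0, 1):
        for j in (0, 1):
            fbar += sum(1 for l in loci if g1[i][l] == g2[j][l]) / len(loci)
    fbar /= 4.0
    if not normalize:
        return 2.0 * fbar
    F1 = sum(1 for l in loci if g1[0][l] == g1[1][l]) / len(loci)
    F2 = sum(1 for l in loci if g2[0][l] == g2[1][l]) / len(loci)
    return 2.0 * fbar / math.sqrt((1.0 + F1) * (1.0 + F2))


def _wang_category(a1, a2, b1, b2) -> int:
    """Similarity category: 1 identical, 2 hom-het sharing, 3 het-het one
    shared, 4 no shared allele."""
    ga, gb = sorted((a1, a2)), sorted((b1, b2))
    shared = len({a1, a2} & {b1, b2})
    if ga == gb:
        return 1
    hom1, hom2 = a1 == a2, b1 == b2
    if shared and hom1 != hom2:
        return 2
    if shared and not hom1 and not hom2:
        return 3
    return 4


def _invert3(m):
    """Explicit 3x3 inverse via the adjugate."""
    (a, b, c), (d, e, f), (g, h, i) = m
    det = a * (e * i - f * h) - b * (d * i - f * g) + c * (d * h - e * g)
    adj = [
        [e * i - f * h, c * h - b * i, b * f - c * e],
        [f * g - d * i, a * i - c * g, c * d - a * f],
        [d * h - e * g, b * g - a * h, a * e - b * d],
    ]
    return [[x / det for x in row] for row in adj]


def _oracle_wang(g1, g2, loci, freq_of, locus_weights="wang") -> float:
    """Independent transcription of the Wang (2002) GLS moment estimator."""
    usable = [l for l in loci if len(freq_of[l]) > 1]
    if not usable:
        raise ValueError("no polymorphic locus available")
    coef = []
    for l in usable:
        ps = list(freq_of[l].values())
        a2 = sum(p**2 for p in ps)
        a3 = sum(p**3 for p in ps)
        a4 = sum(p**4 for p in ps)
        b = 2 * a2**2 - a4
        c = a2 - b
        d = 4 * (a3 - a4)
        e = 2 * (a2 - a3) - d
        f = 4 * (a2 - a2**2 - 2 * a3 + 2 * a4)
        g = (1 - 3 * a2 + 2 * a3) - f
        u = 2 * a2 - a3
        coef.append((b, c, d, e, f, g, u))
    if locus_weights == "wang":
        inv_u = [1.0 / t[6] for t in coef]
        w = [v / sum(inv_u) for v in inv_u]
    else:
        w = [1.0 / len(coef)] * len(coef)

    P = [0.0, 0.0, 0.0]
    for wl, l in zip(w, usable):
        cat = _wang_category(int(g1[0][l]), int(g1[1][l]), int(g2[0][l]), int(g2[1][l]))
        if cat <= 3:
            P[cat - 1] += wl
    bb = sum(wl * t[0] for wl, t in zip(w, coef))
    cb = sum(wl * t[1] for wl, t in zip(w, coef))
    db = sum(wl * t[2] for wl, t in zip(w, coef))
    eb = sum(wl * t[3] for wl, t in zip(w, coef))
    fb = sum(wl * t[4] for wl, t in zip(w, coef))
    gb = sum(wl * t[5] for wl, t in zip(w, coef))

    X = [[cb, 1.0 - bb], [eb, -db], [gb, -fb]]
    p = [bb, db, fb]
    cov = [
        [p[i] * (1.0 - p[i]) if i == j else -p[i] * p[j] for j in range(3)]
        for i in range(3)
    ]
    W = _invert3(cov)
    y = [P[0] - bb, P[1] - db, P[2] - fb]
    # normal equations A @ (phi, delta) = rhs, solved by 2x2 determinant
    A = [[0.0, 0.0], [0.0, 0.0]]
    rhs = [0.0, 0.0]
    for r in range(2):
        for s in range(2):
            A[r][s] = sum(
                X[i][r] * W[i][j] * X[j][s] for i in range(3) for j in range(3)
            )
        rhs[r] = sum(X[i][r] * W[i][j] * y[j] for i in range(3) for j in range(3))
    det = A[0][0] * A[1][1] - A[0][1] * A[1][0]
    phi = (rhs[0] * A[1][1] - rhs[1] * A[0][1]) / det
    delta = (A[0][0] * rhs[1] - A[1][0] * rhs[0]) / det
    return phi / 2.0 + delta


def _oracle_pedigree(ped1, ped2) -> float:
    """Path counting from (id, parents, grandparents) records."""

    def paths(ped):
        out = []
        for k, pid in enumerate(ped["parents"]):
            if pid is not None:
                out.append((pid, 1, set()))
            for gid in ped["grandparents"][2 * k : 2 * k + 2]:
                if gid is not None:
                    out.append((gid, 2, set() if pid is None else {pid}))
        return out

    r = 0.0
    p1, p2 = paths(ped1), paths(ped2)
    for a1, d1, v1 in p1:
        if a1 == ped2["id"]:
            r += 0.5**d1
        for a2, d2, v2 in p2:
            if a1 == a2 and not (v1 & v2):
                r += 0.5 ** (d1 + d2)
    for a2, d2, _ in p2:
        if a2 == ped1["id"]:
            r += 0.5**d2
    return r


# ---------------------------------------------------------------------------
# fixture construction helpers
# ---------------------------------------------------------------------------

_NONE = -1


def _tiny_layout() -> GenomeLayout:
    return build_genome_layout(2, 5, 500_000, [1, 1])


def _build_population(
    layout: GenomeLayout,
    genotypes: np.ndarray,
    parents: Optional[np.ndarray] = None,
    grandparents: Optional[np.ndarray] = None,
) -> Population:
    n = genotypes.shape[0]
    return Population(
        layout,
        genotypes.astype(np.uint8),
        ids=np.arange(n, dtype=np.int64),
        parents=(
            np.full((n, 2), _NONE, dtype=np.int64) if parents is None else parents
        ),
        grandparents=(
            np.full((n, 4), _NONE, dtype=np.int64)
            if grandparents is None
            else grandparents
        ),
    )


def _empirical_freqs(pop: Population, loci: np.ndarray) -> AlleleFrequencyTable:
    freq_of = {int(l): _oracle_frequencies(pop.genotypes, int(l)) for l in loci}
    n_alleles = max(max(d) for d in freq_of.values()) + 1
    mat = np.zeros((loci.size, n_alleles))
    for row, l in enumerate(loci):
        for a, f in freq_of[int(l)].items():
            mat[row, a] = f
    return AlleleFrequencyTable(loci=np.asarray(loci, dtype=np.intp), freq=mat)


def _declared_freqs(loci: np.ndarray, per_locus: "list[dict[int, float]]") -> AlleleFrequencyTable:
    n_alleles = max(max(d) for d in per_locus) + 1
    mat = np.zeros((len(loci), n_alleles))
    for row, d in enumerate(per_locus):
        for a, f in d.items():
            mat[row, a] = f
    return AlleleFrequencyTable(loci=np.asarray(loci, dtype=np.intp), freq=mat)


def _freq_dicts(freqs: AlleleFrequencyTable) -> "dict[int, dict[int, float]]":
    return {int(l): freqs[int(l)] for l in freqs.loci}


def _ped_record(pop: Population, idx: int) -> dict:
    ind = pop.individual(idx)
    return {
        "id": ind.id,
        "parents": ind.parent_ids,
        "grandparents": ind.grandparent_ids,
    }


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

def _monomorphic() -> Fixture:
    layout = _tiny_layout()
    G = np.zeros((4, 2, layout.n_loci), dtype=np.uint8)
    pop = _build_population(layout, G)
    loci = np.arange(layout.n_loci)
    freqs = _empirical_freqs(pop, layout.marker_loci)
    fd = _freq_dicts(freqs)
    markers = [int(l) for l in layout.marker_loci]
    blocks = [int(l) for l in layout.block_loci]
    expected = [
        ExpectedStatistic(
            "observed_heterozygosity", (0,), _oracle_het(G[0][0], G[0][1], blocks),
            {"locus_set": "blocks"},
        ),
        ExpectedStatistic(
            "coefficient_of_inbreeding", (0,),
            1.0 - _oracle_het(G[0][0], G[0][1], blocks),
        ),
        ExpectedStatistic(
            "allelic_richness", (int(loci[0]),),
            _oracle_richness(G, int(loci[0])),
        ),
        ExpectedStatistic(
            "allele_frequencies", (markers[0],),
            _oracle_frequencies(G, markers[0]),
        ),
        ExpectedStatistic(
            "internal_relatedness_individual", (1,),
            _oracle_ir_individual(G[1], markers, fd),
        ),
        ExpectedStatistic(
            "internal_relatedness_pair", (0, 1),
            _oracle_ir_pair(G[0], G[1], markers, fd),
        ),
        ExpectedStatistic(
            "expected_offspring_heterozygosity", (0, 1),
            _oracle_eoh(G[0], G[1], blocks + markers),
            {"locus_set": "all"},
        ),
        ExpectedStatistic(
            "genomewide_relatedness", (0, 1),
            _oracle_gw_rel(G[0], G[1], blocks + markers),
            {"locus_set": "all"},
        ),
    ]
    return Fixture("monomorphic", layout, pop, freqs, expected)


def _max_diverse_founders() -> Fixture:
    layout = _tiny_layout()
    n = 10
    copies = np.arange(2 * n, dtype=np.uint8).reshape(n, 2)
    G = np.repeat(copies[:, :, None], layout.n_loci, axis=2)
    pop = _build_population(layout, G)
    freqs = _empirical_freqs(pop, layout.marker_loci)
    fd = _freq_dicts(freqs)
    markers = [int(l) for l in layout.marker_loci]
    blocks = [int(l) for l in layout.block_loci]
    expected = [
        ExpectedStatistic(
            "observed_heterozygosity", (0,), _oracle_het(G[0][0], G[0][1], blocks),
            {"locus_set": "blocks"},
        ),
        ExpectedStatistic(
            "coefficient_of_inbreeding", (0,),
            1.0 - _oracle_het(G[0][0], G[0][1], blocks),
        ),
        ExpectedStatistic(
            "allelic_richness", (blocks[0],), _oracle_richness(G, blocks[0])
        ),
        ExpectedStatistic(
            "allelic_richness", (blocks[0],),
            _oracle_richness(G, blocks[0], min_freq=0.06),
            {"min_freq": 0.06},
        ),
        ExpectedStatistic(
            "allele_frequencies", (markers[0],), _oracle_frequencies(G, markers[0])
        ),
        ExpectedStatistic(
            "expected_offspring_heterozygosity", (0, 1),
            _oracle_eoh(G[0], G[1], blocks + markers),
            {"locus_set": "all"},
        ),
        ExpectedStatistic(
            "genomewide_relatedness", (0, 1),
            _oracle_gw_rel(G[0], G[1], blocks + markers),
            {"locus_set": "all"},
        ),
        ExpectedStatistic(
            "internal_relatedness_pair", (0, 1),
            _oracle_ir_pair(G[0], G[1], markers, fd),
        ),
        ExpectedStatistic(
            "wang_relatedness", (0, 1),
            _oracle_wang(G[0], G[1], markers, fd),
        ),
        ExpectedStatistic(
            "pedigree_relatedness", (0, 1),
            _oracle_pedigree(_ped_record(pop, 0), _ped_record(pop, 1)),
        ),
    ]
    return Fixture("max_diverse_founders", layout, pop, freqs, expected)


def _sib_fixture(half: bool) -> Fixture:
    layout = _tiny_layout()
    L = layout.n_loci
    if half:
        # founders A,B,C; X = A x B, Y = A x C
        n = 5
        parents = np.array(
            [[_NONE, _NONE]] * 3 + [[0, 1], [0, 2]], dtype=np.int64
        )
        sib_pair = (3, 4)
    else:
        # founders A,B; X = A x B, Y = A x B
        n = 4
        parents = np.array(
            [[_NONE, _NONE]] * 2 + [[0, 1], [0, 1]], dtype=np.int64
        )
        sib_pair = (2, 3)
    grandparents = np.full((n, 4), _NONE, dtype=np.int64)
    copies = np.arange(2 * n, dtype=np.uint8).reshape(n, 2)
    G = np.repeat(copies[:, :, None], L, axis=2)
    # sibs inherit their parents' first haplotypes (free of recombination)
    for row in range(len(parents)):
        pa, pb = parents[row]
        if pa != _NONE:
            G[row, 0, :] = G[pa, 0, :]
            G[row, 1, :] = G[pb, 0, :]
    pop = _build_population(layout, G, parents, grandparents)
    founders = (0, 1) if not half else (1, 2)
    expected = [
        ExpectedStatistic(
            "pedigree_relatedness", sib_pair,
            _oracle_pedigree(_ped_record(pop, sib_pair[0]), _ped_record(pop, sib_pair[1])),
        ),
        ExpectedStatistic(
            "pedigree_relatedness", (0, sib_pair[0]),
            _oracle_pedigree(_ped_record(pop, 0), _ped_record(pop, sib_pair[0])),
        ),
        ExpectedStatistic(
            "pedigree_relatedness", founders,
            _oracle_pedigree(_ped_record(pop, founders[0]), _ped_record(pop, founders[1])),
        ),
    ]
    name = "half_sib_trio" if half else "full_sib_trio"
    freqs = _empirical_freqs(pop, layout.marker_loci)
    return Fixture(name, layout, pop, freqs, expected)


def _layered_choice() -> Fixture:
    layout = build_genome_layout(1, 8, 500_000, [4])
    markers = [int(l) for l in layout.marker_loci]
    L = layout.n_loci
    base = {0: 0.30, 1: 0.25, 2: 0.20, 3: 0.15, 4: 0.06, 5: 0.04}
    freqs = _declared_freqs(np.asarray(markers), [dict(base) for _ in markers])
    fd = _freq_dicts(freqs)

    G = np.zeros((5, 2, L), dtype=np.uint8)

    def set_markers(ind, genotype_per_locus):
        for l, (a, b) in zip(markers, genotype_per_locus):
            G[ind, 0, l] = a
            G[ind, 1, l] = b

    set_markers(0, [(0, 1)] * 4)                       # first parent
    set_markers(1, [(0, 2)] + [(2, 3)] * 3)            # shares one allele once
    set_markers(2, [(4, 5)] * 4)                       # rare, fully disjoint
    set_markers(3, [(0, 1)] * 4)                       # identical to first
    set_markers(4, [(0, 0)] * 4)                       # homozygous common
    pop = _build_population(layout, G)

    ir = [_oracle_ir_pair(G[0], G[c], markers, fd) for c in (1, 2, 3, 4)]
    order = sorted(range(4), key=lambda i: ir[i])
    top2 = [order[0] + 1, order[1] + 1]
    agr = {c: _oracle_wang(G[0], G[c], markers, fd) for c in top2}
    chosen = min(top2, key=lambda c: agr[c])
    # the scenario is only useful if the layered rule overturns the IR rank
    assert chosen == top2[1], "layered fixture lost its defining property"

    expected = [
        ExpectedStatistic("internal_relatedness_pair", (0, c), ir[c - 1])
        for c in (1, 2, 3, 4)
    ] + [
        ExpectedStatistic("wang_relatedness", (0, c), agr[c]) for c in top2
    ] + [
        ExpectedStatistic(
            "choose_mate_layered", (0, 1, 2, 3, 4), chosen,
            {"proportion_for_layered": 0.5},
        )
    ]
    return Fixture("layered_choice_4candidates", layout, pop, freqs, expected)


def _wang_oracle_10locus() -> Fixture:
    layout = build_genome_layout(1, 10, 500_000, [10])
    markers = [int(l) for l in layout.marker_loci]
    L = layout.n_loci
    per_locus = [
        {0: 0.35, 1: 0.25, 2: 0.20, 3: 0.12, 4: 0.08},
        {0: 0.50, 1: 0.30, 2: 0.20},
        {0: 0.40, 1: 0.40, 2: 0.10, 3: 0.10},
        {0: 0.25, 1: 0.25, 2: 0.25, 3: 0.25},
        {0: 0.60, 1: 0.25, 2: 0.15},
        {0: 0.45, 1: 0.30, 2: 0.15, 3: 0.10},
        {0: 0.70, 1: 0.20, 2: 0.10},
        {0: 0.30, 1: 0.30, 2: 0.20, 3: 0.20},
        {0: 0.55, 1: 0.25, 2: 0.12, 3: 0.08},
        {0: 0.80, 1: 0.12, 2: 0.08},
    ]
    freqs = _declared_freqs(np.asarray(markers), per_locus)
    fd = _freq_dicts(freqs)

    # one locus per similarity configuration, cycling through the categories
    geno1 = [(0, 0), (0, 1), (0, 1), (0, 0), (1, 2), (0, 1), (0, 0), (2, 3), (0, 1), (1, 2)]
    geno2 = [(0, 0), (0, 1), (0, 2), (0, 1), (0, 1), (2, 3), (1, 1), (2, 3), (1, 2), (0, 0)]
    G = np.zeros((2, 2, L), dtype=np.uint8)
    for l, (ga, gb) in zip(markers, zip(geno1, geno2)):
        G[0, :, l] = ga
        G[1, :, l] = gb
    pop = _build_population(layout, G)

    expected = [
        ExpectedStatistic(
            "wang_relatedness", (0, 1), _oracle_wang(G[0], G[1], markers, fd)
        ),
        ExpectedStatistic(
            "wang_relatedness", (0, 1),
            _oracle_wang(G[0], G[1], markers, fd, locus_weights="uniform"),
            {"locus_weights": "uniform"},
        ),
        ExpectedStatistic(
            "internal_relatedness_pair", (0, 1),
            _oracle_ir_pair(G[0], G[1], markers, fd),
        ),
        ExpectedStatistic(
            "expected_offspring_heterozygosity", (0, 1),
            _oracle_eoh(G[0], G[1], markers),
            {"locus_set": "markers"},
        ),
        ExpectedStatistic(
            "genomewide_relatedness", (0, 1),
            _oracle_gw_rel(G[0], G[1], markers, normalize=False),
            {"locus_set": "markers", "normalize": False},
        ),
    ]
    return Fixture("wang_oracle_10locus", layout, pop, freqs, expected)


_BUILDERS = {
    "monomorphic": _monomorphic,
    "max_diverse_founders": _max_diverse_founders,
    "full_sib_trio": lambda: _sib_fixture(half=False),
    "half_sib_trio": lambda: _sib_fixture(half=True),
    "layered_choice_4candidates": _layered_choice,
    "wang_oracle_10locus": _wang_oracle_10locus,
}


def make_fixture(scenario: str) -> Fixture:
    """Build a shipped scenario; unknown names raise with the catalogue."""
    try:
        builder = _BUILDERS[scenario]
    except KeyError:
        raise ValueError(
            f"unknown scenario {scenario!r}; catalogue: {', '.join(CATALOGUE)}"
        ) from None
    return builder()
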