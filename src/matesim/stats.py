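"""Genetic statistics for mate ranking and diversity reporting.

Per-individual statistics
    observed heterozygosity, coefficient of inbreeding (COI, the homozygous
    fraction of the block genome), internal relatedness (IR) of an individual's
    own genotype.

Per-pair statistics (all symmetric in the two individuals)
    expected offspring heterozygosity (exact, by enumerating the four gametic
    pairs), pairwise IR (Amos et al.), Wang's (2002) moment estimator of
    relatedness for small marker panels, whole-genome relatedness with the
    Hedrick & Lacy inbreeding normalisation, and shallow-pedigree relatedness
    by path counting over parents and grandparents.

Per-population statistics
    empirical allele frequencies and allelic richness (optionally restricted
    to alleles at or above a frequency threshold).

Scalar (per-pair) functions operate on :class:`~matesim.population.Individual`
views; module-private ``*_scores`` helpers provide vectorised equivalents over
candidate arrays for the mate-choice inner loop, and are property-tested
against the scalar forms.

Wang (2002) estimator
---------------------
At a locus with allele-frequency power sums ``a_m = sum_i p_i**m``, the
probabilities that a pair of genotypes falls in similarity category 1
(identical), 2 (one homozygote sharing an allele with a heterozygote) or 3
(two heterozygotes sharing exactly one allele) are linear in the pair's IBD
coefficients ``phi`` (probability of exactly one IBD pair of genes) and
``delta`` (both pairs IBD)::

    E[P1] = b + c*phi + (1 - b)*delta
    E[P2] = d + e*phi - d*delta
    E[P3] = f + g*phi - f*delta

with ``b = 2*a2**2 - a4``, ``c = a2 - b``, ``d = 4*(a3 - a4)``,
``e = 2*(a2 - a3) - d``, ``f = 4*(a2 - a2**2 - 2*a3 + 2*a4)`` and
``g = (1 - 3*a2 + 2*a3) - f``.  The estimator solves this overdetermined
system by generalised least squares under the multinomial covariance of
``(P1, P2, P3)`` at unrelatedness, and reports ``r = phi/2 + delta``.
Loci are combined with weights proportional to ``1 / (2*a2 - a3)`` (Wang's
locus weighting; uniform weighting is available), applied to both the
category indicators and the mixing coefficients, which keeps the estimator
exactly unbiased.  Loci monomorphic in the reference table carry no
information and are excluded.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from .population import Individual, Population

__all__ = [
    "AlleleFrequencyTable",
    "PairScore",
    "WangEstimator",
    "allele_frequencies",
    "observed_heterozygosity",
    "coefficient_of_inbreeding",
    "allelic_richness",
    "richness_per_locus",
    "expected_offspring_heterozygosity",
    "internal_relatedness_pair",
    "internal_relatedness_individual",
    "wang_relatedness",
    "genomewide_relatedness",
    "pedigree_relatedness",
]


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AlleleFrequencyTable:
    """Per-locus empirical allele frequencies in a reference population.

    ``freq[row, allele]`` holds the frequency of ``allele`` at ``loci[row]``;
    absent alleles have frequency zero.  Frequencies at each locus sum to one.
    """

    loci: np.ndarray          # locus indices, in row order
    freq: np.ndarray          # shape (len(loci), max_allele + 1)

    def __post_init__(self) -> None:
        sums = self.freq.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("allele frequencies must sum to 1 at every locus")
        self._row = {int(l): i for i, l in enumerate(self.loci)}

    def row_of(self, locus: int) -> int:
        return self._row[int(locus)]

    def freq_of(self, locus: int, allele: int) -> float:
        """Frequency of ``allele`` at ``locus``; error if absent."""
        f = float(self.freq[self.row_of(locus), int(allele)])
        if f <= 0.0:
            raise KeyError(f"allele {allele} at locus {locus} absent from table")
        return f

    def __getitem__(self, locus: int) -> "dict[int, float]":
        row = self.freq[self.row_of(locus)]
        return {int(a): float(f) for a, f in enumerate(row) if f > 0}

    def n_alleles(self, locus: int) -> int:
        return int((self.freq[self.row_of(locus)] > 0).sum())


def allele_frequencies(pop: Population, locus_set: Sequence[int]) -> AlleleFrequencyTable:
    """Empirical gene-copy frequencies at ``locus_set`` in ``pop``."""
    if pop.size == 0:
        raise ValueError("population is empty")
    loci = np.asarray(locus_set, dtype=np.intp)
    if loci.size == 0:
        raise ValueError("locus_set is empty")
    sub = pop.genotypes[:, :, loci].reshape(-1, loci.size)  # (2n, m)
    n_alleles = int(sub.max()) + 1
    counts = np.zeros((loci.size, n_alleles), dtype=np.int64)
    offset = sub.astype(np.int64) + np.arange(loci.size) * n_alleles
    flat = np.bincount(offset.reshape(-1), minlength=loci.size * n_alleles)
    counts = flat.reshape(loci.size, n_alleles)
    return AlleleFrequencyTable(loci=loci, freq=counts / (2 * pop.size))


# ---------------------------------------------------------------------------
# per-individual statistics
# ---------------------------------------------------------------------------

def observed_heterozygosity(ind: Individual, locus_set: Sequence[int]) -> float:
    """Fraction of the given loci at which the two allele ids differ."""
    loci = np.asarray(locus_set, dtype=np.intp)
    if loci.size == 0:
        raise ValueError("locus_set is empty")
    return float(
        (ind.haplotypes[0, loci] != ind.haplotypes[1, loci]).mean()
    )


def coefficient_of_inbreeding(ind: Individual) -> float:
    """Fraction of the block genome that is homozygous.

    Every block has the same physical length, so the length-weighted
    definition (homozygous blocks x block length / genome length) reduces to
    the homozygous fraction of block loci, and
    ``COI + observed_heterozygosity(ind, block_loci) == 1``.
    """
    blocks = ind.layout.block_loci
    return float((ind.haplotypes[0, blocks] == ind.haplotypes[1, blocks]).mean())


def internal_relatedness_individual(
    ind: Individual,
    marker_set: Sequence[int],
    freqs: AlleleFrequencyTable,
    method: str = "per_locus",
) -> float:
    """Internal relatedness (Amos et al.) of one individual's genotype.

    ``method='per_locus'`` evaluates the single-locus IR (1 for a homozygote,
    ``-(f_a + f_b) / (2 - f_a - f_b)`` for a heterozygote) and averages across
    loci.  ``method='classical'`` is the original multi-locus ratio of sums
    ``(2H - sum f) / (2N - sum f)``.
    """
    loci = np.asarray(marker_set, dtype=np.intp)
    a = ind.haplotypes[0, loci]
    b = ind.haplotypes[1, loci]
    fa = _lookup(freqs, loci, a)
    fb = _lookup(freqs, loci, b)
    hom = a == b
    if method == "per_locus":
        with np.errstate(divide="ignore", invalid="ignore"):
            per = np.where(hom, 1.0, -(fa + fb) / (2.0 - fa - fb))
        return float(per.mean())
    if method == "classical":
        n = loci.size
        sf = float((fa + fb).sum())
        return float((2.0 * hom.sum() - sf) / (2.0 * n - sf))
    raise ValueError(f"unknown IR method {method!r}")


# ---------------------------------------------------------------------------
# per-population statistics
# ---------------------------------------------------------------------------

def allelic_richness(
    pop: Population, locus: int, min_freq: Optional[float] = None
) -> int:
    """Number of distinct alleles at ``locus`` (>= ``min_freq`` if given)."""
    if pop.size == 0:
        raise ValueError("population is empty")
    alleles = pop.genotypes[:, :, locus].reshape(-1)
    counts = np.bincount(alleles.astype(np.int64))
    if min_freq is None:
        return int((counts > 0).sum())
    return int((counts >= min_freq * alleles.size - 1e-12).sum())


def richness_per_locus(
    pop: Population, min_freq: Optional[float] = None
) -> np.ndarray:
    """Vectorised allelic richness at every locus."""
    n2 = 2 * pop.size
    L = pop.layout.n_loci
    flat = pop.genotypes.reshape(n2, L).astype(np.int64)
    n_alleles = int(flat.max()) + 1
    offset = flat + np.arange(L) * n_alleles
    counts = np.bincount(offset.reshape(-1), minlength=L * n_alleles)
    counts = counts.reshape(L, n_alleles)
    if min_freq is None:
        return (counts > 0).sum(axis=1)
    return (counts >= min_freq * n2 - 1e-12).sum(axis=1)


def mean_observed_heterozygosity(pop: Population, locus_set: Sequence[int]) -> float:
    """Population mean of per-individual observed heterozygosity."""
    loci = np.asarray(locus_set, dtype=np.intp)
    return float(
        (pop.genotypes[:, 0, loci] != pop.genotypes[:, 1, loci]).mean()
    )


# ---------------------------------------------------------------------------
# pair statistics
# ---------------------------------------------------------------------------

def expected_offspring_heterozygosity(
    p1: Individual, p2: Individual, locus_set: Sequence[int]
) -> float:
    """Exact expected offspring heterozygosity under free transmission.

    One minus the mean, over the four ordered parental haplotype pairs, of the
    fraction of loci at which the two transmitted alleles would be identical.
    Recombination does not enter: the expectation is per locus and transmission
    within a locus is fair regardless of linkage.
    """
    loci = np.asarray(locus_set, dtype=np.intp)
    h1 = p1.haplotypes[:, loci]
    h2 = p2.haplotypes[:, loci]
    identity = (h1[:, None, :] == h2[None, :, :]).mean()
    return float(1.0 - identity)


def _lookup(
    freqs: AlleleFrequencyTable, loci: np.ndarray, alleles: np.ndarray
) -> np.ndarray:
    """Frequencies of ``alleles`` (shape ``(..., len(loci))``) at ``loci``."""
    rows = np.asarray([freqs.row_of(l) for l in loci], dtype=np.intp)
    ids = alleles.astype(np.intp)
    if (ids >= freqs.freq.shape[1]).any():
        raise KeyError(
            "an allele carried at one of the loci is absent from the "
            "frequency table"
        )
    f = freqs.freq[rows, ids]
    if (f <= 0).any():
        raise KeyError(
            "an allele carried at one of the loci is absent from the "
            "frequency table"
        )
    return f


def internal_relatedness_pair(
    p1: Individual,
    p2: Individual,
    marker_set: Sequence[int],
    freqs: AlleleFrequencyTable,
    method: str = "per_locus",
) -> float:
    """Mean IR of the four prospective-offspring gametic pairs.

    For each marker locus and each ordered pair of parental alleles (a, b):
    1 if ``a == b`` else ``-(f_a + f_b) / (2 - f_a - f_b)``; averaged over the
    four gametic pairs and then across loci (``method='per_locus'``, the
    mate-ranking form).  ``method='classical'`` applies the original
    multi-locus ratio of sums to each gametic pair before averaging the four.
    Lower values indicate a preferred (less inbred-offspring) mate.
    """
    loci = np.asarray(marker_set, dtype=np.intp)
    h1 = p1.haplotypes[:, loci]      # (2, m)
    h2 = p2.haplotypes[:, loci]
    f1 = _lookup(freqs, loci, h1)                  # (2, m)
    f2 = _lookup(freqs, loci, h2)
    eq = h1[:, None, :] == h2[None, :, :]             # (2, 2, m)
    fsum = f1[:, None, :] + f2[None, :, :]
    if method == "per_locus":
        with np.errstate(divide="ignore", invalid="ignore"):
            per = np.where(eq, 1.0, -fsum / (2.0 - fsum))
        return float(per.mean())
    if method == "classical":
        m = loci.size
        sf = fsum.sum(axis=2)                          # (2, 2)
        ir = (2.0 * eq.sum(axis=2) - sf) / (2.0 * m - sf)
        return float(ir.mean())
    raise ValueError(f"unknown IR method {method!r}")


def genomewide_relatedness(
    p1: Individual,
    p2: Individual,
    locus_set: Sequence[int],
    normalize: bool = True,
) -> float:
    """Whole-genome relatedness (Hedrick & Lacy form).

    ``r = 2 * fbar / sqrt((1 + F1) * (1 + F2))`` where ``fbar`` is the mean
    allele-identity indicator over the four gametic pairs and all loci (the
    kinship analogue) and ``F_i`` is individual ``i``'s homozygous fraction
    over the same loci.  ``normalize=False`` returns the unnormalised
    ``2 * fbar``.  Lower values indicate a preferred mate.
    """
    loci = np.asarray(locus_set, dtype=np.intp)
    h1 = p1.haplotypes[:, loci]
    h2 = p2.haplotypes[:, loci]
    fbar = float((h1[:, None, :] == h2[None, :, :]).mean())
    if not normalize:
        return 2.0 * fbar
    F1 = float((h1[0] == h1[1]).mean())
    F2 = float((h2[0] == h2[1]).mean())
    return 2.0 * fbar / float(np.sqrt((1.0 + F1) * (1.0 + F2)))


# ---------------------------------------------------------------------------
# Wang (2002) relatedness
# ---------------------------------------------------------------------------

def _wang_locus_coefficients(freq_rows: np.ndarray):
    """Mixing coefficients b..g and locus weights u for each frequency row."""
    a2 = (freq_rows ** 2).sum(axis=1)
    a3 = (freq_rows ** 3).sum(axis=1)
    a4 = (freq_rows ** 4).sum(axis=1)
    b = 2 * a2 ** 2 - a4
    c = a2 - b
    d = 4 * (a3 - a4)
    e = 2 * (a2 - a3) - d
    f = 4 * (a2 - a2 ** 2 - 2 * a3 + 2 * a4)
    g = (1 - 3 * a2 + 2 * a3) - f
    u = 2 * a2 - a3
    return b, c, d, e, f, g, u


class WangEstimator:
    """Precomputed Wang (2002) estimator for one reference frequency table.

    Building the estimator once per generation amortises the locus-coefficient
    and GLS algebra across all candidate pairs scored in that generation.
    """

    def __init__(
        self, freqs: AlleleFrequencyTable, locus_weights: str = "wang"
    ) -> None:
        poly = (freqs.freq > 0).sum(axis=1) > 1
        if not poly.any():
            raise ValueError(
                "all loci are monomorphic in the reference table; the Wang "
                "estimator is undefined"
            )
        self.loci = freqs.loci[poly]
        self.rows = np.flatnonzero(poly)
        self.freq = freqs.freq
        b, c, d, e, f, g, u = _wang_locus_coefficients(freqs.freq[poly])
        if locus_weights == "wang":
            w = (1.0 / u) / (1.0 / u).sum()
        elif locus_weights == "uniform":
            w = np.full(b.size, 1.0 / b.size)
        else:
            raise ValueError(f"unknown locus_weights {locus_weights!r}")
        self.w = w
        self.b = float(w @ b)
        self.d = float(w @ d)
        self.f = float(w @ f)
        cbar, ebar, gbar = float(w @ c), float(w @ e), float(w @ g)
        X = np.array(
            [[cbar, 1.0 - self.b], [ebar, -self.d], [gbar, -self.f]]
        )
        p = np.array([self.b, self.d, self.f])
        cov = np.diag(p) - np.outer(p, p)  # multinomial cov at unrelatedness
        W = np.linalg.inv(cov)
        self.M = np.linalg.solve(X.T @ W @ X, X.T @ W)  # (2, 3) solve matrix

    def _categories(self, g1: np.ndarray, g2: np.ndarray):
        """Similarity-category indicators for genotype arrays.

        ``g1``/``g2`` have shape ``(..., 2, m)`` (two alleles per usable
        locus); returns boolean arrays ``(P1, P2, P3)`` of shape ``(..., m)``.
        """
        a1, a2 = g1[..., 0, :], g1[..., 1, :]
        b1, b2 = g2[..., 0, :], g2[..., 1, :]
        s11, s12 = a1 == b1, a1 == b2
        s21, s22 = a2 == b1, a2 == b2
        hom1, hom2 = a1 == a2, b1 == b2
        identical = (hom1 & hom2 & s11) | (
            ~hom1 & ~hom2 & ((s11 & s22) | (s12 & s21))
        )
        shares = s11 | s12 | s21 | s22
        p2 = (hom1 & ~hom2 & shares) | (hom2 & ~hom1 & shares)
        p3 = ~hom1 & ~hom2 & shares & ~identical
        return identical, p2, p3

    def relatedness(self, g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
        """Relatedness ``phi/2 + delta`` for broadcastable genotype arrays."""
        p1, p2, p3 = self._categories(g1, g2)
        P = np.stack(
            [p1 @ self.w, p2 @ self.w, p3 @ self.w], axis=-1
        ) - np.array([self.b, self.d, self.f])
        phi_delta = P @ self.M.T
        return phi_delta[..., 0] / 2.0 + phi_delta[..., 1]


def wang_relatedness(
    p1: Individual,
    p2: Individual,
    marker_set: Sequence[int],
    freqs: AlleleFrequencyTable,
    locus_weights: str = "wang",
) -> float:
    """Wang (2002) moment estimate of pairwise relatedness over a marker panel.

    Symmetric in its arguments; unbiased at the reference frequencies; loci
    monomorphic in the reference table are excluded (all excluded is an
    error).  Lower values indicate a preferred mate.
    """
    loci = np.asarray(marker_set, dtype=np.intp)
    rows = np.asarray([freqs.row_of(l) for l in loci], dtype=np.intp)
    sub = AlleleFrequencyTable(loci=loci, freq=freqs.freq[rows])
    est = WangEstimator(sub, locus_weights=locus_weights)
    keep = np.asarray([np.flatnonzero(loci == l)[0] for l in est.loci])
    g1 = p1.haplotypes[:, loci[keep]]
    g2 = p2.haplotypes[:, loci[keep]]
    return float(est.relatedness(g1, g2))


# ---------------------------------------------------------------------------
# pedigree relatedness
# ---------------------------------------------------------------------------

def _ancestor_paths(ind: Individual):
    """Paths (ancestor_id, depth, intermediates) over tracked generations."""
    paths = []
    for pi, pid in enumerate(ind.parent_ids):
        if pid is not None:
            paths.append((pid, 1, frozenset()))
        for gid in ind.grandparent_ids[2 * pi : 2 * pi + 2]:
            if gid is not None:
                via = frozenset() if pid is None else frozenset([pid])
                paths.append((gid, 2, via))
    return paths


def pedigree_relatedness(i1: Individual, i2: Individual) -> float:
    """Relatedness by path counting over parents and grandparents.

    Sums ``0.5 ** (d1 + d2)`` over every pair of connecting paths to a shared
    ancestor id, excluding path pairs that reuse an intermediate individual
    (so grandparent paths routed through a shared parent are not double
    counted).  Untracked ancestors are treated as unrelated and non-inbred;
    missing pedigree fields contribute nothing.  Direct ancestry (one
    individual appearing in the other's pedigree) contributes ``0.5 ** d``.
    """
    paths1 = _ancestor_paths(i1)
    paths2 = _ancestor_paths(i2)
    r = 0.0
    for a1, d1, via1 in paths1:
        if a1 == i2.id:
            r += 0.5 ** d1
        for a2, d2, via2 in paths2:
            if a1 == a2 and not (via1 & via2):
                r += 0.5 ** (d1 + d2)
    for a2, d2, _ in paths2:
        if a2 == i1.id:
            r += 0.5 ** d2
    return r


# ---------------------------------------------------------------------------
# pair-score plumbing and vectorised candidate scoring
# ---------------------------------------------------------------------------

_STATISTIC_NAMES = ("HET", "IR", "AGR", "REL", "PEDIGREE")


@dataclasses.dataclass(frozen=True)
class PairScore:
    """A scored prospective pairing; ``higher_is_better`` fixes the ranking."""

    value: float
    statistic_name: str
    higher_is_better: bool

    def __post_init__(self) -> None:
        if self.statistic_name not in _STATISTIC_NAMES:
            raise ValueError(f"unknown statistic {self.statistic_name!r}")


def _identity_scores(
    G: np.ndarray, first_idx: int, cand_idx: np.ndarray, loci: Optional[np.ndarray]
) -> np.ndarray:
    """Mean allele identity over the 4 gametic pairs, per candidate."""
    if loci is None:
        pool = G[cand_idx]                     # (k, 2, L)
        first = G[first_idx]
    else:
        pool = G[np.ix_(cand_idx, np.arange(2), loci)]
        first = G[first_idx][:, loci]
    k, L = pool.shape[0], pool.shape[2]
    acc = np.zeros(k)
    for i in range(2):
        for j in range(2):
            acc += (pool[:, i, :] == first[j]).sum(axis=1)
    return acc / (4.0 * L)


def _homozygosity_per_individual(G: np.ndarray, loci: Optional[np.ndarray]) -> np.ndarray:
    if loci is None:
        return (G[:, 0, :] == G[:, 1, :]).mean(axis=1)
    return (G[:, 0, loci] == G[:, 1, loci]).mean(axis=1)


def _ir_scores(
    Gm: np.ndarray, first_idx: int, cand_idx: np.ndarray, freq: np.ndarray
) -> np.ndarray:
    """Per-locus-averaged pair IR per candidate.

    ``Gm`` is the marker-restricted genotype array ``(n, 2, m)`` and ``freq``
    the matching frequency matrix ``(m, n_alleles)``.
    """
    m = Gm.shape[2]
    cols = np.arange(m)
    first = Gm[first_idx]                           # (2, m)
    pool = Gm[cand_idx]                             # (k, 2, m)
    f_first = freq[cols, first.astype(np.intp)]     # (2, m)
    f_pool = freq[cols, pool.astype(np.intp)]       # (k, 2, m)
    eq = pool[:, :, None, :] == first[None, None, :, :]        # (k, 2, 2, m)
    fsum = f_pool[:, :, None, :] + f_first[None, None, :, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        per = np.where(eq, 1.0, -fsum / (2.0 - fsum))
    return per.mean(axis=(1, 2, 3))
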