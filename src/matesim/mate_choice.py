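"""The non-Wright-Fisher life cycle: constrained pairwise mate choice.

Each offspring is produced by (1) sampling a first parent uniformly among
individuals that have not yet reached the per-generation mating cap,
(2) sampling a mating pool uniformly without replacement from the rest of the
population (resampled from scratch until it contains at least one eligible
candidate -- a fresh pool per event, even for a repeated first parent), and
(3) choosing the mate from the pool's eligible members according to the active
mate-choice model.  Both chosen parents' mating counters increment by one per
event, and the strict cap applies to both roles: an individual may mate at
most ``maximum_number_of_matings`` times per generation.

Models
    RANDOM        uniform among eligible pool members
    PEDIGREE      lowest shallow-pedigree relatedness
    MS33_HET      highest expected offspring heterozygosity, marker panel
    GW_HET        highest expected offspring heterozygosity, genome-wide
    MS33_IR       lowest pairwise internal relatedness, marker panel
    MS33_AGR      lowest Wang (2002) relatedness, marker panel
    GW_REL        lowest whole-genome (Hedrick & Lacy) relatedness
    MS33_IR_AGR   layered: best fraction by IR, then lowest Wang among them

All ties are broken by a uniform random draw.  Allele frequencies used by the
IR and Wang statistics are computed once per generation from the full parental
population (offspring join the next generation only).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import numpy as np

from .population import Individual, Population, _next_generation
from . import stats as _stats

__all__ = [
    "MODELS",
    "MS33_MODELS",
    "GW_MODELS",
    "MateChoiceParams",
    "MatingDeadlockError",
    "pair_score",
    "sample_first_parent",
    "sample_mating_pool",
    "choose_mate",
    "run_mate_choice_generation",
]

MODELS = (
    "RANDOM",
    "PEDIGREE",
    "MS33_HET",
    "GW_HET",
    "MS33_IR",
    "MS33_AGR",
    "GW_REL",
    "MS33_IR_AGR",
)
MS33_MODELS = ("MS33_HET", "MS33_IR", "MS33_AGR", "MS33_IR_AGR")
GW_MODELS = ("GW_HET", "GW_REL")


class MatingDeadlockError(RuntimeError):
    """No eligible parent or mate exists; the life cycle cannot continue."""


@dataclasses.dataclass(frozen=True)
class MateChoiceParams:
    """Mate-choice knobs for one simulation configuration.

    ``mating_pool_size`` models limited mate access; the cap
    ``maximum_number_of_matings`` bounds any individual's parental
    contributions per generation; ``proportion_for_layered`` is the fraction
    of the pool kept by the first statistic in the layered model.
    """

    model: str = "RANDOM"
    mating_pool_size: int = 50
    maximum_number_of_matings: int = 200
    proportion_for_layered: float = 0.5

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; choose from {MODELS}")
        if self.mating_pool_size < 1:
            raise ValueError("mating_pool_size must be >= 1")
        if self.maximum_number_of_matings < 1:
            raise ValueError("maximum_number_of_matings must be >= 1")
        if not 0.0 < self.proportion_for_layered <= 1.0:
            raise ValueError("proportion_for_layered must be in (0, 1]")


# ---------------------------------------------------------------------------
# sampling steps
# ---------------------------------------------------------------------------

def _eligible_mask(pop: Population, cap: int) -> np.ndarray:
    return pop.matings < cap


def _sample_first_idx(
    pop: Population, params: MateChoiceParams, rng: np.random.Generator
) -> int:
    eligible = np.flatnonzero(_eligible_mask(pop, params.maximum_number_of_matings))
    if eligible.size == 0:
        raise MatingDeadlockError(
            f"generation {pop.generation}: every individual has reached the "
            f"mating cap ({params.maximum_number_of_matings})"
        )
    return int(eligible[rng.integers(eligible.size)])


def sample_first_parent(
    pop: Population, params: MateChoiceParams, rng: np.random.Generator
) -> Individual:
    """Uniform draw among individuals below the mating cap."""
    return pop.individual(_sample_first_idx(pop, params, rng))


def _sample_pool_idx(
    pop: Population,
    first_idx: int,
    params: MateChoiceParams,
    rng: np.random.Generator,
) -> np.ndarray:
    if pop.size < 2:
        raise ValueError("population must contain more than one individual")
    others = np.delete(np.arange(pop.size), first_idx)
    elig = _eligible_mask(pop, params.maximum_number_of_matings)
    if not elig[others].any():
        raise MatingDeadlockError(
            f"generation {pop.generation}: no eligible mate exists for "
            f"individual {int(pop.ids[first_idx])} "
            f"(cap {params.maximum_number_of_matings})"
        )
    size = min(params.mating_pool_size, others.size)
    while True:
        pool = rng.choice(others, size=size, replace=False)
        if elig[pool].any():
            return pool


def sample_mating_pool(
    pop: Population,
    first: Individual,
    params: MateChoiceParams,
    rng: np.random.Generator,
) -> "list[Individual]":
    """Fresh uniform mating pool excluding the first parent.

    Resampled from scratch until at least one member is mating-eligible; a
    new pool is drawn for every first-parent event.
    """
    first_idx = int(np.flatnonzero(pop.ids == first.id)[0])
    return [pop.individual(i) for i in _sample_pool_idx(pop, first_idx, params, rng)]


# ---------------------------------------------------------------------------
# mate selection
# ---------------------------------------------------------------------------

def _argbest(
    scores: np.ndarray, higher_is_better: bool, rng: np.random.Generator
) -> int:
    best = scores.max() if higher_is_better else scores.min()
    ties = np.flatnonzero(scores == best)
    return int(ties[rng.integers(ties.size)])


def _pair_scores(
    first: Individual,
    candidates: "list[Individual]",
    model: str,
    freqs: Optional[_stats.AlleleFrequencyTable],
) -> "tuple[np.ndarray, bool]":
    """Reference (scalar) scoring of candidates under one model."""
    layout = first.layout
    markers = layout.marker_loci
    gw = np.arange(layout.n_loci)
    if model == "MS33_HET":
        vals = [
            _stats.expected_offspring_heterozygosity(first, c, markers)
            for c in candidates
        ]
        return np.asarray(vals), True
    if model == "GW_HET":
        vals = [
            _stats.expected_offspring_heterozygosity(first, c, gw)
            for c in candidates
        ]
        return np.asarray(vals), True
    if model == "MS33_IR":
        vals = [
            _stats.internal_relatedness_pair(first, c, markers, freqs)
            for c in candidates
        ]
        return np.asarray(vals), False
    if model == "MS33_AGR":
        vals = [
            _stats.wang_relatedness(first, c, markers, freqs)
            for c in candidates
        ]
        return np.asarray(vals), False
    if model == "GW_REL":
        vals = [
            _stats.genomewide_relatedness(first, c, gw) for c in candidates
        ]
        return np.asarray(vals), False
    if model == "PEDIGREE":
        vals = [_stats.pedigree_relatedness(first, c) for c in candidates]
        return np.asarray(vals), False
    raise ValueError(f"model {model!r} has no pair score")


_STATISTIC_OF_MODEL = {
    "MS33_HET": "HET",
    "GW_HET": "HET",
    "MS33_IR": "IR",
    "MS33_AGR": "AGR",
    "GW_REL": "REL",
    "PEDIGREE": "PEDIGREE",
}


def pair_score(
    first: Individual,
    candidate: Individual,
    model: str,
    freqs: Optional[_stats.AlleleFrequencyTable] = None,
) -> _stats.PairScore:
    """Score one prospective pairing under a (non-random, non-layered) model."""
    if model not in _STATISTIC_OF_MODEL:
        raise ValueError(f"model {model!r} has no single pair statistic")
    values, higher = _pair_scores(first, [candidate], model, freqs)
    return _stats.PairScore(
        value=float(values[0]),
        statistic_name=_STATISTIC_OF_MODEL[model],
        higher_is_better=higher,
    )


def _layered_subset_size(proportion: float, n: int) -> int:
    return max(1, math.ceil(proportion * n))


def choose_mate(
    first: Individual,
    pool: "list[Individual]",
    params: MateChoiceParams,
    freqs: Optional[_stats.AlleleFrequencyTable],
    rng: np.random.Generator,
) -> Individual:
    """Select the mate from the pool's eligible members under ``params.model``.

    Ineligible pool members are excluded before scoring; ties are broken
    uniformly at random.  ``freqs`` (reference allele frequencies at the
    marker loci) is required by the IR- and Wang-based models.
    """
    eligible = [
        c for c in pool
        if c.matings_this_generation < params.maximum_number_of_matings
    ]
    if not eligible:
        raise MatingDeadlockError("no mating-eligible candidate in the pool")
    if params.model == "RANDOM":
        return eligible[rng.integers(len(eligible))]
    if params.model == "MS33_IR_AGR":
        ir, _ = _pair_scores(first, eligible, "MS33_IR", freqs)
        m = _layered_subset_size(params.proportion_for_layered, len(eligible))
        order = np.lexsort((rng.random(len(eligible)), ir))
        kept = [eligible[i] for i in order[:m]]
        agr, _ = _pair_scores(first, kept, "MS33_AGR", freqs)
        return kept[_argbest(agr, False, rng)]
    scores, higher = _pair_scores(first, eligible, params.model, freqs)
    return eligible[_argbest(scores, higher, rng)]


# ---------------------------------------------------------------------------
# fast per-generation context and vectorised scoring
# ---------------------------------------------------------------------------

class _GenerationContext:
    """Per-generation precomputation shared by all mating events."""

    def __init__(self, pop: Population, params: MateChoiceParams) -> None:
        layout = pop.layout
        model = params.model
        self.model = model
        self.markers = layout.marker_loci
        self.freqs: Optional[_stats.AlleleFrequencyTable] = None
        self.Gm: Optional[np.ndarray] = None
        self.freq_matrix: Optional[np.ndarray] = None
        self.wang: Optional[_stats.WangEstimator] = None
        self.Gw: Optional[np.ndarray] = None
        self.F: Optional[np.ndarray] = None
        if model in ("MS33_IR", "MS33_AGR", "MS33_IR_AGR"):
            self.freqs = _stats.allele_frequencies(pop, self.markers)
            self.Gm = np.ascontiguousarray(pop.genotypes[:, :, self.markers])
            self.freq_matrix = self.freqs.freq
        if model in ("MS33_AGR", "MS33_IR_AGR"):
            self.wang = _stats.WangEstimator(self.freqs)
            self.Gw = np.ascontiguousarray(pop.genotypes[:, :, self.wang.loci])
        if model == "MS33_HET":
            self.Gm = np.ascontiguousarray(pop.genotypes[:, :, self.markers])
        if model == "GW_REL":
            self.F = _stats._homozygosity_per_individual(pop.genotypes, None)

    def scores(
        self, pop: Population, first_idx: int, cand_idx: np.ndarray, model: str
    ) -> "tuple[np.ndarray, bool]":
        G = pop.genotypes
        if model == "MS33_HET":
            ident = _stats._identity_scores(self.Gm, first_idx, cand_idx, None)
            return 1.0 - ident, True
        if model == "GW_HET":
            ident = _stats._identity_scores(G, first_idx, cand_idx, None)
            return 1.0 - ident, True
        if model == "GW_REL":
            ident = _stats._identity_scores(G, first_idx, cand_idx, None)
            denom = np.sqrt((1.0 + self.F[first_idx]) * (1.0 + self.F[cand_idx]))
            return 2.0 * ident / denom, False
        if model == "MS33_IR":
            return (
                _stats._ir_scores(self.Gm, first_idx, cand_idx, self.freq_matrix),
                False,
            )
        if model == "MS33_AGR":
            r = self.wang.relatedness(self.Gw[cand_idx], self.Gw[first_idx])
            return np.atleast_1d(r), False
        if model == "PEDIGREE":
            first = pop.individual(first_idx)
            vals = [
                _stats.pedigree_relatedness(first, pop.individual(int(i)))
                for i in cand_idx
            ]
            return np.asarray(vals), False
        raise ValueError(f"model {model!r} has no vectorised score")


def _choose_mate_idx(
    pop: Population,
    first_idx: int,
    pool_idx: np.ndarray,
    params: MateChoiceParams,
    ctx: _GenerationContext,
    rng: np.random.Generator,
) -> "tuple[int, float]":
    elig = pool_idx[_eligible_mask(pop, params.maximum_number_of_matings)[pool_idx]]
    if elig.size == 0:
        raise MatingDeadlockError("no mating-eligible candidate in the pool")
    if params.model == "RANDOM":
        return int(elig[rng.integers(elig.size)]), math.nan
    if params.model == "MS33_IR_AGR":
        ir, _ = ctx.scores(pop, first_idx, elig, "MS33_IR")
        m = _layered_subset_size(params.proportion_for_layered, elig.size)
        order = np.lexsort((rng.random(elig.size), ir))
        kept = elig[order[:m]]
        agr, _ = ctx.scores(pop, first_idx, kept, "MS33_AGR")
        j = _argbest(agr, False, rng)
        return int(kept[j]), float(agr[j])
    scores, higher = ctx.scores(pop, first_idx, elig, params.model)
    j = _argbest(scores, higher, rng)
    return int(elig[j]), float(scores[j])


# ---------------------------------------------------------------------------
# one full mate-choice generation
# ---------------------------------------------------------------------------

def run_mate_choice_generation(
    pop: Population,
    params: MateChoiceParams,
    target_size: int,
    rng: np.random.Generator,
    audit: Optional[list] = None,
) -> Population:
    """Produce ``target_size`` offspring by repeated constrained mate choice.

    Mating counters increment for both parents per event and are fresh (zero)
    in the returned offspring generation.  If ``audit`` is a list, one record
    ``(generation, first_id, mate_id, score)`` is appended per mating event
    (score is NaN under RANDOM).
    """
    if pop.size < 2:
        raise ValueError("population must contain at least two individuals")
    if target_size < 1:
        raise ValueError(f"target_size must be >= 1, got {target_size}")
    ctx = _GenerationContext(pop, params)
    firsts = np.empty(target_size, dtype=np.int64)
    mates = np.empty(target_size, dtype=np.int64)
    for k in range(target_size):
        fi = _sample_first_idx(pop, params, rng)
        pool = _sample_pool_idx(pop, fi, params, rng)
        mi, score = _choose_mate_idx(pop, fi, pool, params, ctx, rng)
        pop.matings[fi] += 1
        pop.matings[mi] += 1
        firsts[k] = fi
        mates[k] = mi
        if audit is not None:
            audit.append(
                (pop.generation, int(pop.ids[fi]), int(pop.ids[mi]), score)
            )
    assert (pop.matings <= params.maximum_number_of_matings).all(), (
        "mating cap violated"
    )
    return _next_generation(pop, firsts, mates, rng)
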