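"""Individuals, populations, founder construction and Wright-Fisher drift.

A population is stored column-oriented for speed: one genotype array of shape
``(n, 2, n_loci)`` (two haplotypes of integer allele ids per individual) plus
pedigree-id and mating-counter arrays.  :class:`Individual` is a lightweight
view used by the per-pair statistics and the public mating operations.

There is no mutation: allele ids exist only at founding and are thereafter
shuffled by recombination and lost by drift, so the allele set at any locus
can only shrink over time.
"""

from __future__ import annotations

import dataclasses
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .genome import ConfigurationError, GenomeLayout

__all__ = [
    "Individual",
    "Population",
    "make_founder_population",
    "make_gamete",
    "make_offspring",
    "wright_fisher_generation",
    "to_genotype_table",
    "from_genotype_table",
]

_NONE = -1  # sentinel for an unknown pedigree id


@dataclasses.dataclass
class Individual:
    """View of one individual: two haplotypes plus shallow pedigree."""

    id: int
    haplotypes: np.ndarray  # shape (2, n_loci), integer allele ids
    parent_ids: "tuple[Optional[int], Optional[int]]"
    grandparent_ids: "tuple[Optional[int], Optional[int], Optional[int], Optional[int]]"
    matings_this_generation: int
    layout: GenomeLayout

    def __post_init__(self) -> None:
        if self.haplotypes.shape != (2, self.layout.n_loci):
            raise ValueError("haplotype shape does not match layout")


def _ids_to_tuple(row: np.ndarray) -> tuple:
    return tuple(None if v == _NONE else int(v) for v in row)


class Population:
    """Ordered collection of individuals sharing one :class:`GenomeLayout`."""

    def __init__(
        self,
        layout: GenomeLayout,
        genotypes: np.ndarray,
        ids: np.ndarray,
        parents: np.ndarray,
        grandparents: np.ndarray,
        matings: Optional[np.ndarray] = None,
        generation: int = 0,
        next_id: Optional[int] = None,
    ) -> None:
        n = genotypes.shape[0]
        if genotypes.shape != (n, 2, layout.n_loci):
            raise ValueError("genotypes must have shape (n, 2, n_loci)")
        if len(np.unique(ids)) != n:
            raise ValueError("individual ids must be unique within a population")
        self.layout = layout
        self.genotypes = genotypes
        self.ids = np.asarray(ids, dtype=np.int64)
        self.parents = np.asarray(parents, dtype=np.int64)
        self.grandparents = np.asarray(grandparents, dtype=np.int64)
        self.matings = (
            np.zeros(n, dtype=np.int32) if matings is None
            else np.asarray(matings, dtype=np.int32)
        )
        self.generation = int(generation)
        self.next_id = int(self.ids.max()) + 1 if next_id is None else int(next_id)

    @property
    def size(self) -> int:
        return self.genotypes.shape[0]

    def __len__(self) -> int:
        return self.size

    def individual(self, index: int) -> Individual:
        return Individual(
            id=int(self.ids[index]),
            haplotypes=self.genotypes[index],
            parent_ids=_ids_to_tuple(self.parents[index]),
            grandparent_ids=_ids_to_tuple(self.grandparents[index]),
            matings_this_generation=int(self.matings[index]),
            layout=self.layout,
        )

    def __iter__(self) -> Iterator[Individual]:
        return (self.individual(i) for i in range(self.size))

    def copy(self) -> "Population":
        return Population(
            self.layout,
            self.genotypes.copy(),
            self.ids.copy(),
            self.parents.copy(),
            self.grandparents.copy(),
            self.matings.copy(),
            self.generation,
            self.next_id,
        )


def _allele_dtype(n_alleles: int) -> np.dtype:
    if n_alleles <= np.iinfo(np.uint8).max + 1:
        return np.dtype(np.uint8)
    if n_alleles <= np.iinfo(np.uint16).max + 1:
        return np.dtype(np.uint16)
    return np.dtype(np.uint32)


def make_founder_population(
    layout: GenomeLayout,
    n_individuals: int,
    n_block_alleles: int,
    n_marker_alleles: int,
    rng_seed: int = 0,
) -> Population:
    """Found a population with alleles distributed evenly across gene copies.

    At every locus the ``2 * n_individuals`` founder gene copies carry allele
    ids ``0..k-1`` assigned in round-robin order (``k`` = the allele count for
    the locus type), so per-locus allele counts differ by at most one copy.
    The assignment is deterministic; ``rng_seed`` is accepted for interface
    stability but the round-robin scheme draws nothing from it.
    """
    if n_individuals < 2:
        raise ConfigurationError("n_individuals must be at least 2")
    for name, k in (("n_block_alleles", n_block_alleles),
                    ("n_marker_alleles", n_marker_alleles)):
        if k < 1:
            raise ConfigurationError(f"{name} must be >= 1, got {k}")
        if k > 2 * n_individuals:
            raise ConfigurationError(
                f"{name}={k} exceeds the {2 * n_individuals} founder gene "
                "copies; cannot place every allele"
            )

    dtype = _allele_dtype(max(n_block_alleles, n_marker_alleles))
    copies = np.arange(2 * n_individuals, dtype=np.int64)
    G = np.empty((n_individuals, 2, layout.n_loci), dtype=dtype)
    G[:, :, ~layout.is_marker] = (copies % n_block_alleles).reshape(
        n_individuals, 2, 1
    ).astype(dtype)
    G[:, :, layout.is_marker] = (copies % n_marker_alleles).reshape(
        n_individuals, 2, 1
    ).astype(dtype)

    n = n_individuals
    return Population(
        layout,
        G,
        ids=np.arange(n, dtype=np.int64),
        parents=np.full((n, 2), _NONE, dtype=np.int64),
        grandparents=np.full((n, 4), _NONE, dtype=np.int64),
        generation=0,
    )


def _make_gametes(
    haplotypes: np.ndarray,
    parent_rows: np.ndarray,
    layout: GenomeLayout,
    rng: np.random.Generator,
) -> np.ndarray:
    """Form one recombinant gamete per entry of ``parent_rows``.

    ``haplotypes`` has shape ``(n, 2, L)``; the source haplotype switches
    between consecutive loci with the interval's recombination probability and
    the starting haplotype is chosen uniformly.  Returns ``(k, L)`` alleles.
    """
    k = parent_rows.shape[0]
    L = layout.n_loci
    u = rng.random((k, L - 1), dtype=np.float32)
    switches = (u < layout.recombination_prob.astype(np.float32)).astype(np.uint8)
    source = np.empty((k, L), dtype=np.uint8)
    source[:, 0] = 0
    # uint8 cumsum wraps mod 256, which preserves parity
    np.cumsum(switches, axis=1, dtype=np.uint8, out=source[:, 1:])
    source += rng.integers(0, 2, (k, 1), dtype=np.uint8)
    source &= 1
    flat = haplotypes.reshape(-1, L)
    rows = parent_rows[:, None] * 2 + source
    return flat[rows, np.arange(L)[None, :]]


def make_gamete(
    parent: Individual, layout: GenomeLayout, rng: np.random.Generator
) -> np.ndarray:
    """Recombinant gamete (1-D allele vector) from one parent.

    Markers travel with their host block because the block-marker interval has
    zero recombination probability.
    """
    return _make_gametes(
        parent.haplotypes[None, :, :], np.zeros(1, dtype=np.int64), layout, rng
    )[0]


def make_offspring(
    p1: Individual,
    p2: Individual,
    layout: GenomeLayout,
    rng: np.random.Generator,
    id: int,
) -> Individual:
    """One offspring carrying one gamete from each parent.

    Grandparent ids are copied from the parents' parent ids; the mating
    counter starts at zero.  Selfing (``p1.id == p2.id``) is an error.
    """
    if p1.id == p2.id:
        raise ValueError(f"selfing attempt: both parents have id {p1.id}")
    haps = np.stack([make_gamete(p1, layout, rng), make_gamete(p2, layout, rng)])
    return Individual(
        id=int(id),
        haplotypes=haps,
        parent_ids=(p1.id, p2.id),
        grandparent_ids=(*p1.parent_ids, *p2.parent_ids),
        matings_this_generation=0,
        layout=layout,
    )


def _sample_distinct_pairs(
    n: int, k: int, rng: np.random.Generator
) -> "tuple[np.ndarray, np.ndarray]":
    """k pairs of distinct indices in [0, n), uniform with replacement."""
    a = rng.integers(0, n, k)
    b = rng.integers(0, n - 1, k)
    b += b >= a
    return a, b


def _next_generation(
    pop: Population,
    mother_rows: np.ndarray,
    father_rows: np.ndarray,
    rng: np.random.Generator,
) -> Population:
    """Build the offspring population for given parent-row pairs."""
    k = mother_rows.shape[0]
    gam_a = _make_gametes(pop.genotypes, mother_rows, pop.layout, rng)
    gam_b = _make_gametes(pop.genotypes, father_rows, pop.layout, rng)
    G = np.stack([gam_a, gam_b], axis=1)
    ids = pop.next_id + np.arange(k, dtype=np.int64)
    parents = np.stack(
        [pop.ids[mother_rows], pop.ids[father_rows]], axis=1
    )
    grandparents = np.concatenate(
        [pop.parents[mother_rows], pop.parents[father_rows]], axis=1
    )
    return Population(
        pop.layout,
        G,
        ids=ids,
        parents=parents,
        grandparents=grandparents,
        generation=pop.generation + 1,
        next_id=int(ids[-1]) + 1,
    )


def wright_fisher_generation(
    pop: Population, target_size: int, rng: np.random.Generator
) -> Population:
    """One neutral Wright-Fisher generation.

    Each of ``target_size`` offspring draws two parents uniformly at random
    with replacement (distinct within a pair, i.e. no selfing) and receives
    one recombinant gamete from each.
    """
    if pop.size == 0:
        raise ValueError("population is empty")
    if target_size < 1:
        raise ValueError(f"target_size must be >= 1, got {target_size}")
    a, b = _sample_distinct_pairs(pop.size, target_size, rng)
    return _next_generation(pop, a, b, rng)


def to_genotype_table(pop: Population) -> pd.DataFrame:
    """Long-format genotype table (individual_id, locus_index, allele_a, allele_b)."""
    n, L = pop.size, pop.layout.n_loci
    return pd.DataFrame(
        {
            "individual_id": np.repeat(pop.ids, L),
            "locus_index": np.tile(np.arange(L), n),
            "allele_a": pop.genotypes[:, 0, :].reshape(-1),
            "allele_b": pop.genotypes[:, 1, :].reshape(-1),
        }
    )


def from_genotype_table(
    table: pd.DataFrame,
    layout: GenomeLayout,
    parents: Optional[Sequence] = None,
    grandparents: Optional[Sequence] = None,
    generation: int = 0,
) -> Population:
    """Rebuild a population from a genotype table (pedigree optional).

    The table must contain every locus for every individual; pedigree ids not
    supplied are recorded as unknown.
    """
    ids = table["individual_id"].unique()
    n, L = len(ids), layout.n_loci
    sorted_t = table.sort_values(["individual_id", "locus_index"], kind="stable")
    if len(sorted_t) != n * L:
        raise ValueError("genotype table must cover all loci for all individuals")
    max_allele = int(max(sorted_t["allele_a"].max(), sorted_t["allele_b"].max()))
    dtype = _allele_dtype(max_allele + 1)
    G = np.empty((n, 2, L), dtype=dtype)
    G[:, 0, :] = sorted_t["allele_a"].to_numpy().reshape(n, L)
    G[:, 1, :] = sorted_t["allele_b"].to_numpy().reshape(n, L)
    ids_sorted = np.sort(ids)

    def _fill(rows, width):
        out = np.full((n, width), _NONE, dtype=np.int64)
        if rows is not None:
            for i, row in enumerate(rows):
                out[i] = [(_NONE if v is None else v) for v in row]
        return out

    return Population(
        layout,
        G,
        ids=ids_sorted,
        parents=_fill(parents, 2),
        grandparents=_fill(grandparents, 4),
        generation=generation,
    )
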