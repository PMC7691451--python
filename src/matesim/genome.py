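"""Block-haplotype genome model with an embedded small marker panel.

The genome is modelled as a grid of non-recombining, multi-allelic haplotype
blocks: 38 chromosomes x 120 blocks of 0.5 Mb each (2.28 Gb total), which is a
coarse approximation of the canine genome.  A panel of 33 microsatellite-like
multi-allelic loci ("markers") is embedded in the grid: 3 on chromosome 1,
2 each on chromosomes 2-7, 1 each on chromosomes 8-25, none on 26-38.  Each
marker is co-located with a host block (zero recombination between the two),
mirroring how a dense multi-allelic map and a sparse typed panel coexist on
one genetic map.

Recombination is uniform: probability 0.5 between chromosomes and
``block_length x 1e-8`` (0.005 for 0.5 Mb blocks, i.e. ~1 cM/Mb) between
adjacent blocks within a chromosome.

Loci are indexed 0-based in a single genome-wide order with markers inserted
immediately after their host block; physical positions are block midpoints and
distances are reported in Mb.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "GenomeLayout",
    "UNLINKED",
    "CROSSOVER_RATE_PER_BP",
    "DEFAULT_MARKER_COUNTS",
    "build_genome_layout",
    "default_genome_layout",
    "nearest_marker_distance",
    "export_layout_table",
]

#: probability of crossover per base pair (~1 cM/Mb average in dogs)
CROSSOVER_RATE_PER_BP = 1e-8

#: recombination probability across a chromosome boundary (free recombination)
INTERCHROMOSOME_RECOMBINATION = 0.5

#: sentinel distance for loci on chromosomes that carry no marker
UNLINKED = math.inf

DEFAULT_N_CHROMOSOMES = 38
DEFAULT_BLOCKS_PER_CHROMOSOME = 120
DEFAULT_BLOCK_LENGTH = 500_000

#: marker counts per chromosome for the 33-marker panel
DEFAULT_MARKER_COUNTS = (3,) + (2,) * 6 + (1,) * 18 + (0,) * 13


class ConfigurationError(ValueError):
    """Raised when a layout or parameter configuration is invalid."""


@dataclasses.dataclass(frozen=True)
class GenomeLayout:
    """Immutable description of the block/marker grid.

    Attributes
    ----------
    n_chromosomes, blocks_per_chromosome, block_length
        Grid geometry; ``block_length`` in bases.
    chromosome_of_locus
        0-based chromosome index per locus (combined block+marker order).
    is_marker
        Boolean mask over loci; True for panel markers.
    position_bp
        Physical midpoint of each locus in bases (genome-wide coordinate);
        a marker shares the midpoint of its host block.
    recombination_prob
        Crossover probability for each of the ``n_loci - 1`` inter-locus
        intervals: 0.0 between a block and its co-located marker,
        ``block_length * 1e-8`` within a chromosome, 0.5 across a boundary.
    """

    n_chromosomes: int
    blocks_per_chromosome: int
    block_length: int
    chromosome_of_locus: np.ndarray
    is_marker: np.ndarray
    position_bp: np.ndarray
    recombination_prob: np.ndarray

    @property
    def n_loci(self) -> int:
        """Total locus count (blocks plus markers)."""
        return self.chromosome_of_locus.shape[0]

    @property
    def block_loci(self) -> np.ndarray:
        """Indices of the haplotype-block loci (the genome-wide set)."""
        return np.flatnonzero(~self.is_marker)

    @property
    def marker_loci(self) -> np.ndarray:
        """Indices of the panel marker loci, in genome order."""
        return np.flatnonzero(self.is_marker)

    @property
    def n_blocks(self) -> int:
        return int((~self.is_marker).sum())

    @property
    def n_markers(self) -> int:
        return int(self.is_marker.sum())

    @property
    def genome_length_bp(self) -> int:
        """Implied physical genome length (blocks only)."""
        return self.n_blocks * self.block_length

    @property
    def within_chromosome_recombination(self) -> float:
        return self.block_length * CROSSOVER_RATE_PER_BP

    def marker_counts_per_chromosome(self) -> np.ndarray:
        counts = np.zeros(self.n_chromosomes, dtype=int)
        np.add.at(counts, self.chromosome_of_locus[self.is_marker], 1)
        return counts


def _validate_positive(name: str, value: int) -> None:
    if not isinstance(value, (int, np.integer)) or value < 1:
        raise ConfigurationError(f"{name} must be a positive integer, got {value!r}")


def build_genome_layout(
    n_chromosomes: int = DEFAULT_N_CHROMOSOMES,
    blocks_per_chromosome: int = DEFAULT_BLOCKS_PER_CHROMOSOME,
    block_length: int = DEFAULT_BLOCK_LENGTH,
    marker_counts: "tuple[int, ...] | list[int] | np.ndarray" = DEFAULT_MARKER_COUNTS,
) -> GenomeLayout:
    """Construct the block/marker grid.

    Markers are spaced evenly across the blocks of their chromosome, at block
    indices ``floor(B * (k + 0.5) / m)`` for ``k = 0..m-1`` (``B`` blocks,
    ``m`` markers) -- deterministic given the layout.

    Raises
    ------
    ConfigurationError
        If any count is invalid, ``marker_counts`` has the wrong length, or a
        chromosome is assigned more markers than it has blocks.
    """
    _validate_positive("n_chromosomes", n_chromosomes)
    _validate_positive("blocks_per_chromosome", blocks_per_chromosome)
    _validate_positive("block_length", block_length)
    marker_counts = np.asarray(marker_counts, dtype=int)
    if marker_counts.shape != (n_chromosomes,):
        raise ConfigurationError(
            f"marker_counts must have length n_chromosomes={n_chromosomes}, "
            f"got length {marker_counts.shape[0]}"
        )
    if (marker_counts < 0).any():
        raise ConfigurationError("marker_counts entries must be non-negative")
    if (marker_counts > blocks_per_chromosome).any():
        bad = int(np.flatnonzero(marker_counts > blocks_per_chromosome)[0])
        raise ConfigurationError(
            f"marker_counts[{bad}] exceeds blocks_per_chromosome="
            f"{blocks_per_chromosome}"
        )

    chrom: list[int] = []
    is_marker: list[bool] = []
    position: list[int] = []
    for c in range(n_chromosomes):
        m = int(marker_counts[c])
        marker_blocks = {
            int(blocks_per_chromosome * (k + 0.5) // m) for k in range(m)
        } if m else set()
        for b in range(blocks_per_chromosome):
            midpoint = (
                (c * blocks_per_chromosome + b) * block_length + block_length // 2
            )
            chrom.append(c)
            is_marker.append(False)
            position.append(midpoint)
            if b in marker_blocks:
                chrom.append(c)
                is_marker.append(True)
                position.append(midpoint)

    chrom_arr = np.asarray(chrom, dtype=np.int32)
    marker_arr = np.asarray(is_marker, dtype=bool)
    pos_arr = np.asarray(position, dtype=np.int64)

    within = block_length * CROSSOVER_RATE_PER_BP
    recomb = np.full(len(chrom_arr) - 1, within, dtype=float)
    if recomb.size:
        same_pos = pos_arr[1:] == pos_arr[:-1]
        recomb[same_pos] = 0.0  # marker rides with its host block
        boundary = chrom_arr[1:] != chrom_arr[:-1]
        recomb[boundary] = INTERCHROMOSOME_RECOMBINATION

    return GenomeLayout(
        n_chromosomes=int(n_chromosomes),
        blocks_per_chromosome=int(blocks_per_chromosome),
        block_length=int(block_length),
        chromosome_of_locus=chrom_arr,
        is_marker=marker_arr,
        position_bp=pos_arr,
        recombination_prob=recomb,
    )


def default_genome_layout() -> GenomeLayout:
    """The 38 x 120 block, 33-marker dog-genome layout."""
    return build_genome_layout()


def nearest_marker_distance(layout: GenomeLayout, locus: int) -> float:
    """Distance in Mb from ``locus`` to the nearest marker on its chromosome.

    Returns 0.0 for markers themselves (and their host blocks, which share a
    midpoint), and the :data:`UNLINKED` sentinel (``inf``) for loci on
    chromosomes that carry no marker.
    """
    if not 0 <= locus < layout.n_loci:
        raise IndexError(f"locus {locus} out of range [0, {layout.n_loci})")
    if layout.n_markers == 0:
        raise ConfigurationError("layout has no markers")
    chrom = layout.chromosome_of_locus[locus]
    markers = layout.marker_loci
    same = markers[layout.chromosome_of_locus[markers] == chrom]
    if same.size == 0:
        return UNLINKED
    d = np.abs(layout.position_bp[same] - layout.position_bp[locus]).min()
    return float(d) / 1e6


def nearest_marker_distances(layout: GenomeLayout) -> np.ndarray:
    """Vectorised :func:`nearest_marker_distance` for every locus."""
    out = np.full(layout.n_loci, UNLINKED, dtype=float)
    markers = layout.marker_loci
    for c in range(layout.n_chromosomes):
        on_c = layout.chromosome_of_locus == c
        mk = markers[layout.chromosome_of_locus[markers] == c]
        if mk.size == 0:
            continue
        pos = layout.position_bp[on_c][:, None]
        out[on_c] = np.abs(pos - layout.position_bp[mk][None, :]).min(axis=1) / 1e6
    return out


def export_layout_table(layout: GenomeLayout) -> pd.DataFrame:
    """Four-column inspection table (locus_index, chromosome, position_bp, is_marker)."""
    return pd.DataFrame(
        {
            "locus_index": np.arange(layout.n_loci),
            "chromosome": layout.chromosome_of_locus,
            "position_bp": layout.position_bp,
            "is_marker": layout.is_marker,
        }
    )
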