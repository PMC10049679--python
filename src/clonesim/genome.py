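"""GRCh37 autosome coordinates used for random variant placement.

Variants are placed on chromosomes 1-22 only; positions are 1-based
inclusive, as in VCF.
"""

from __future__ import annotations

import numpy as np

# GRCh37/hg19 autosome lengths (bp).
GRCH37_CHROM_LENGTHS: dict[int, int] = {
    1: 249250621,
    2: 243199373,
    3: 198022430,
    4: 191154276,
    5: 180915260,
    6: 171115067,
    7: 159138663,
    8: 146364022,
    9: 141213431,
    10: 135534747,
    11: 135006516,
    12: 133851895,
    13: 115169878,
    14: 107349540,
    15: 102531392,
    16: 90354753,
    17: 81195210,
    18: 78077248,
    19: 59128983,
    20: 63025520,
    21: 48129895,
    22: 51304566,
}

AUTOSOMES: tuple[int, ...] = tuple(GRCH37_CHROM_LENGTHS)

_CHROMS = np.array(AUTOSOMES)
_LENGTHS = np.array([GRCH37_CHROM_LENGTHS[c] for c in AUTOSOMES], dtype=np.int64)
_WEIGHTS = _LENGTHS / _LENGTHS.sum()


def random_chromosome(rng: np.random.Generator, length_weighted: bool = True) -> int:
    """Draw an autosome, by default weighted by chromosome length so that
    positions are uniform over the autosomal genome."""
    if length_weighted:
        return int(rng.choice(_CHROMS, p=_WEIGHTS))
    return int(rng.choice(_CHROMS))


def random_position(rng: np.random.Generator) -> tuple[int, int]:
    """Uniform random (chrom, pos) over the GRCh37 autosomes, 1-based."""
    chrom = random_chromosome(rng)
    pos = int(rng.integers(1, GRCH37_CHROM_LENGTHS[chrom] + 1))
    return chrom, pos


def random_interval(rng: np.random.Generator, max_length: int) -> tuple[int, int, int]:
    """Uniform random (chrom, start, end), 1-based inclusive, with
    length drawn uniformly on [1, max_length] and the interval fitting
    entirely on the chromosome."""
    chrom = random_chromosome(rng)
    chrom_len = GRCH37_CHROM_LENGTHS[chrom]
    length = int(rng.integers(1, max_length + 1))
    start = int(rng.integers(1, chrom_len - length + 2))
    return chrom, start, start + length - 1
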