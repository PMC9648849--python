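"""Small reproducible fixtures: corner-case genomes and seeded landscapes.

Everything here regenerates identically from recorded seeds, so tests
and examples need no stored data files.
"""

from __future__ import annotations

from .genomes import Genome
from .landscapes import NeighbourhoodModel, NKLandscape

#: corner cases at N = 4: both uniform genomes (maximal accessible-mutant
#: count) and the alternating genome (whose mutant set famously misses 1001)
STANDARD_GENOME_STRINGS = ("0000", "0101", "1111")

DEFAULT_FIXTURE_SEEDS = (11, 23, 42)


def fixture_genomes(topology: str = "circular") -> list[Genome]:
    return [Genome.from_string(s, topology) for s in STANDARD_GENOME_STRINGS]


def fixture_landscapes(
    N: int = 6,
    Ks: tuple[int, ...] = (0, 2),
    model: NeighbourhoodModel = "adjacent",
    seeds: tuple[int, ...] = DEFAULT_FIXTURE_SEEDS,
) -> dict[tuple[int, int], NKLandscape]:
    """Seeded small landscapes keyed by (K, seed)."""
    return {
        (K, seed): NKLandscape(N, K, model=model, seed=seed)
        for K in Ks
        for seed in seeds
    }


def generate_fixtures(
    N: int = 6,
    Ks: tuple[int, ...] = (0, 2),
    model: NeighbourhoodModel = "adjacent",
    seeds: tuple[int, ...] = DEFAULT_FIXTURE_SEEDS,
) -> dict:
    """The standard fixture bundle used by the test-suite."""
    return {
        "genomes": fixture_genomes(),
        "landscapes": fixture_landscapes(N, Ks, model, seeds),
    }
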