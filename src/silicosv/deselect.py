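"""Differential-evolution selection of band pairs to test.

Testing all 51,040 major-band pairs is computationally prohibitive, and
sampling pairs purely by observed breakpoint frequency would over-test
well-known hotspots (centromeres, the Philadelphia chromosome) while never
testing rarely reported bands.  A small differential-evolution (DE) loop
therefore evolves a population of candidate band pairs under an objective
that combines frequency-informed fitness with population diversity:

* individual fitness: product of the two bands' smoothed breakpoint
  probabilities (bands are treated as independent marginals);
* diversity: Shannon entropy of the band-usage distribution across the
  population, normalized by log(#bands) so it lies in [0, 1];
* population objective: mean fitness + lambda * diversity.

Each generation every individual is crossed (probability ``CR``: exchange one
partner band with a random other individual) and mutated (probability ``F``
per slot: replace the band with a frequency-weighted random band); the
candidate replaces its parent only if the population objective does not
decrease.  The loop stops when diversity reaches ``diversity_target`` or
``max_generations`` is hit.  Everything is driven by one seeded RNG, so a
given config and frequency table always yields the same population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .karyoband import BandTable, BreakpointFrequencyTable

__all__ = [
    "Individual",
    "DEConfig",
    "DEPopulation",
    "initialize_population",
    "evolve",
    "pair_fitness",
    "population_diversity",
]


class DEConfigError(ValueError):
    pass


@dataclass(frozen=True)
class Individual:
    """One candidate recombination: an unordered pair of distinct band labels."""

    pair: frozenset[str]
    fitness: float = 0.0

    def __post_init__(self) -> None:
        if len(self.pair) != 2:
            raise DEConfigError(f"individual must hold two distinct bands, got {set(self.pair)}")


@dataclass
class DEConfig:
    population_size: int = 278
    CR: float = 0.5
    F: float = 0.1
    max_generations: int = 50
    diversity_target: float = 0.8
    diversity_weight: float = 1.0
    seed: int = 0
    inter_chromosomal_only: bool = True

    def validate(self) -> None:
        if self.population_size < 1:
            raise DEConfigError("population_size must be >= 1")
        if not (0.0 <= self.CR <= 1.0 and 0.0 <= self.F <= 1.0):
            raise DEConfigError("CR and F must lie in [0, 1]")
        if not (0.0 <= self.diversity_target <= 1.0):
            raise DEConfigError("diversity_target must lie in [0, 1]")
        if self.max_generations < 0:
            raise DEConfigError("max_generations must be >= 0")


@dataclass
class DEPopulation:
    individuals: list[Individual]
    generation: int = 0
    diversity: float = 0.0

    def __len__(self) -> int:
        return len(self.individuals)

    def unique_pairs(self) -> list[frozenset[str]]:
        """Deduplicated pairs, first-seen order (used for output)."""
        seen: dict[frozenset[str], None] = {}
        for ind in self.individuals:
            seen.setdefault(ind.pair, None)
        return list(seen)

    def mean_fitness(self) -> float:
        return float(np.mean([ind.fitness for ind in self.individuals]))


def pair_fitness(pair, freqs: BreakpointFrequencyTable) -> float:
    """Fitness of a band pair: product of its band probabilities (symmetric)."""
    a, b = sorted(pair)
    return freqs.probability(a) * freqs.probability(b)


def population_diversity(pairs, n_bands: int) -> float:
    """Normalized Shannon entropy of band usage across the population.

    Each pair contributes its two bands to the usage distribution, so the
    entropy H ranges from ln 2 (every individual reuses one pair) to
    ln(n_bands) (usage uniform over all bands).  The score is rescaled to
    [0, 1] over that range: a population of identical pairs has diversity
    exactly 0, uniform band usage gives 1.
    """
    if n_bands < 3:
        return 0.0
    usage: dict[str, int] = {}
    for pair in pairs:
        for band in pair:
            usage[band] = usage.get(band, 0) + 1
    total = sum(usage.values())
    entropy = -sum((c / total) * math.log(c / total) for c in usage.values())
    lo, hi = math.log(2), math.log(n_bands)
    return max(0.0, (entropy - lo) / (hi - lo))


class _Sampler:
    """Frequency-weighted band sampling with a fixed label order."""

    def __init__(self, freqs: BreakpointFrequencyTable, table: BandTable):
        self.labels = list(freqs.band_labels)
        probs = np.array([freqs.probability(b) for b in self.labels], dtype=float)
        self.probs = probs / probs.sum()
        self.chrom = {b.label: b.chrom for b in table}

    def draw_band(self, rng: np.random.Generator) -> str:
        return self.labels[int(rng.choice(len(self.labels), p=self.probs))]

    def draw_pair(self, rng: np.random.Generator, inter_only: bool) -> frozenset[str]:
        while True:
            a = self.draw_band(rng)
            b = self.draw_band(rng)
            if a == b:
                continue
            if inter_only and self.chrom[a] == self.chrom[b]:
                continue
            return frozenset((a, b))


def _objective(pairs, freqs, cfg: DEConfig, n_bands: int) -> float:
    mean_fit = float(np.mean([pair_fitness(p, freqs) for p in pairs]))
    return mean_fit + cfg.diversity_weight * population_diversity(pairs, n_bands)


def initialize_population(
    freqs: BreakpointFrequencyTable, table: BandTable, cfg: DEConfig
) -> DEPopulation:
    """Seeded initial population of frequency-weighted valid band pairs."""
    cfg.validate()
    sampler = _Sampler(freqs, table)
    if len(sampler.labels) < 2:
        raise DEConfigError("need >= 2 bands to form pairs")
    rng = np.random.default_rng(cfg.seed)
    pairs = [sampler.draw_pair(rng, cfg.inter_chromosomal_only) for _ in range(cfg.population_size)]
    individuals = [Individual(p, pair_fitness(p, freqs)) for p in pairs]
    return DEPopulation(
        individuals=individuals,
        generation=0,
        diversity=population_diversity(pairs, len(sampler.labels)),
    )


def _valid(pair: frozenset[str], sampler: _Sampler, inter_only: bool) -> bool:
    if len(pair) != 2:
        return False
    a, b = tuple(pair)
    return not (inter_only and sampler.chrom[a] == sampler.chrom[b])


def evolve(
    pop: DEPopulation,
    freqs: BreakpointFrequencyTable,
    table: BandTable,
    cfg: DEConfig,
) -> DEPopulation:
    """Run the DE loop from ``pop`` until diversity target or generation cap."""
    cfg.validate()
    sampler = _Sampler(freqs, table)
    n_bands = len(sampler.labels)
    rng = np.random.default_rng(cfg.seed + 1)
    pairs = [ind.pair for ind in pop.individuals]
    generation = pop.generation
    diversity = population_diversity(pairs, n_bands)

    while diversity < cfg.diversity_target and generation < cfg.max_generations:
        objective = _objective(pairs, freqs, cfg, n_bands)
        for i in range(len(pairs)):
            candidate = list(pairs[i])
            changed = False
            # crossover: exchange one partner band with a random other individual
            if len(pairs) > 1 and rng.random() < cfg.CR:
                j = int(rng.integers(len(pairs) - 1))
                j = j if j < i else j + 1
                donor = list(pairs[j])
                candidate[int(rng.integers(2))] = donor[int(rng.integers(2))]
                changed = True
            # mutation: each slot independently replaced by a frequency-weighted band
            for slot in range(2):
                if rng.random() < cfg.F:
                    candidate[slot] = sampler.draw_band(rng)
                    changed = True
            if not changed:
                continue
            cand_pair = frozenset(candidate)
            if not _valid(cand_pair, sampler, cfg.inter_chromosomal_only):
                continue
            trial = pairs[i]
            pairs[i] = cand_pair
            new_objective = _objective(pairs, freqs, cfg, n_bands)
            if new_objective >= objective:
                objective = new_objective
            else:
                pairs[i] = trial
        generation += 1
        diversity = population_diversity(pairs, n_bands)

    individuals = [Individual(p, pair_fitness(p, freqs)) for p in pairs]
    return DEPopulation(individuals=individuals, generation=generation, diversity=diversity)


def write_selection_tsv(pop: DEPopulation, table: BandTable, path) -> None:
    """Selected-region TSV consumed by the reference builder (deduplicated)."""
    with open(path, "w") as fh:
        fh.write("band_a\tband_b\tfitness\n")
        for pair in pop.unique_pairs():
            a, b = sorted(pair)
            fit = next(ind.fitness for ind in pop.individuals if ind.pair == pair)
            fh.write(f"{a}\t{b}\t{fit:.8g}\n")
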