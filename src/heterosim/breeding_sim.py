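"""Crosses, truncation selection, inbreeding lineages and hybrid schedules.

All mating operations draw from an explicit :class:`numpy.random.Generator`
and are reproducible bit-for-bit from (model, config, seed). Alleles are
transmitted randomly, independently across loci and unaltered — no linkage,
no mutation — so every allele in every generation traces back to a founder.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, StructuralError
from .genetics_layer import (
    Genotype,
    GenotypeEvaluator,
    Phenotype,
    homozygosity_fraction,
    sample_founder_genotype,
)


@dataclass
class Individual:
    """One simulated organism; the phenotype is evaluated lazily and cached."""

    id: str
    genotype: Genotype
    evaluator: GenotypeEvaluator
    parent_ids: tuple[str, str] | None = None
    line_id: str = "line0"
    generation_index: int = 0
    _phenotype: Phenotype | None = field(default=None, repr=False, compare=False)

    @property
    def phenotype(self) -> Phenotype:
        if self._phenotype is None:
            self._phenotype = self.evaluator.evaluate(self.genotype)
        return self._phenotype

    @property
    def biomass_rate(self) -> float:
        return self.phenotype.biomass_rate

    @property
    def homozygosity(self) -> float:
        return homozygosity_fraction(self.genotype)

    @property
    def selfed(self) -> bool:
        return self.parent_ids is not None and self.parent_ids[0] == self.parent_ids[1]


@dataclass
class Population:
    """One generation of individuals with lineage and RNG provenance."""

    individuals: list[Individual]
    generation_index: int = 0
    line_id: str = "line0"
    rng_seed: int | str | None = None

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals)

    def mean_biomass(self) -> float:
        return float(np.mean([ind.biomass_rate for ind in self.individuals]))

    def max_biomass(self) -> float:
        return float(np.max([ind.biomass_rate for ind in self.individuals]))

    def mean_homozygosity(self) -> float:
        return float(np.mean([ind.homozygosity for ind in self.individuals]))

    def summary(self) -> dict:
        return {
            "line_id": self.line_id,
            "generation": self.generation_index,
            "size": len(self),
            "mean_biomass": self.mean_biomass(),
            "max_biomass": self.max_biomass(),
            "mean_homozygosity": self.mean_homozygosity(),
        }

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "id": ind.id,
                "parent_a": ind.parent_ids[0] if ind.parent_ids else "",
                "parent_b": ind.parent_ids[1] if ind.parent_ids else "",
                "line_id": ind.line_id,
                "generation": ind.generation_index,
                "biomass_rate": ind.biomass_rate,
                "homozygosity": ind.homozygosity,
            }
            for ind in self.individuals
        ]
        return pd.DataFrame(rows)


@dataclass
class SelectionConfig:
    """Knobs of the inbreeding/selection regime."""

    population_size: int = 500
    selection_fraction: float = 0.05
    generations: int = 50
    f1_parent_sample_fraction: float = 0.30
    allow_selfing: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.selection_fraction <= 1.0:
            raise ConfigError(
                f"selection_fraction must lie in (0, 1], got {self.selection_fraction}"
            )
        if self.population_size < 1:
            raise ConfigError("population_size must be >= 1")
        if self.generations < 0:
            raise ConfigError("generations must be >= 0")
        if not 0.0 < self.f1_parent_sample_fraction <= 1.0:
            raise ConfigError("f1_parent_sample_fraction must lie in (0, 1]")
        survivors = math.ceil(self.population_size * self.selection_fraction)
        if survivors < 2 and not self.allow_selfing:
            raise ConfigError(
                f"selection keeps {survivors} parent(s) but selfing is disallowed"
            )


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def cross(
    parent_a: Individual, parent_b: Individual, rng: np.random.Generator
) -> Genotype:
    """Mendelian cross: at each locus, one uniformly chosen allele from each
    parent, independently across loci. Offspring slot 0 holds the allele
    from ``parent_a``, slot 1 the allele from ``parent_b``."""
    ga, gb = parent_a.genotype, parent_b.genotype
    if set(ga.alleles) != set(gb.alleles) or ga.ploidy != gb.ploidy:
        raise StructuralError(
            f"parents {parent_a.id!r} and {parent_b.id!r} do not share a "
            f"locus structure"
        )
    half = ga.ploidy // 2
    loci = list(ga.alleles)
    picks_a = rng.integers(0, ga.ploidy, size=(len(loci), half))
    picks_b = rng.integers(0, gb.ploidy, size=(len(loci), half))
    alleles = {}
    for k, locus in enumerate(loci):
        va, vb = ga.alleles[locus], gb.alleles[locus]
        alleles[locus] = tuple(va[i] for i in picks_a[k]) + tuple(
            vb[i] for i in picks_b[k]
        )
    return Genotype(alleles, ga.ploidy)


def truncation_select(population: Population, fraction: float) -> list[Individual]:
    """Top ``ceil(fraction * size)`` individuals by biomass rate; ties broken
    by individual id so the outcome is deterministic."""
    if not 0.0 < fraction <= 1.0:
        raise ConfigError(f"fraction must lie in (0, 1], got {fraction}")
    if fraction == 1.0:
        return list(population.individuals)
    n = math.ceil(fraction * len(population))
    ranked = sorted(
        population.individuals, key=lambda ind: (-ind.biomass_rate, ind.id)
    )
    return ranked[:n]


def make_offspring_generation(
    parents: Sequence[Individual],
    size: int,
    allow_selfing: bool,
    rng: np.random.Generator,
    line_id: str | None = None,
    generation_index: int | None = None,
) -> Population:
    """``size`` offspring from uniformly drawn parent pairs.

    Pairs are distinct unless ``allow_selfing``; with a single parent and
    selfing enabled every offspring is selfed from it.
    """
    if len(parents) == 0:
        raise ConfigError("no parents supplied")
    if len(parents) < 2 and not allow_selfing:
        raise ConfigError("need >= 2 parents when selfing is disallowed")
    line = line_id if line_id is not None else parents[0].line_id
    gen = (
        generation_index
        if generation_index is not None
        else parents[0].generation_index + 1
    )
    evaluator = parents[0].evaluator
    offspring = []
    for i in range(size):
        ia = int(rng.integers(len(parents)))
        if allow_selfing:
            ib = int(rng.integers(len(parents)))
        else:
            ib = int(rng.integers(len(parents) - 1))
            if ib >= ia:
                ib += 1
        pa, pb = parents[ia], parents[ib]
        offspring.append(
            Individual(
                id=f"{line}-g{gen}-{i}",
                genotype=cross(pa, pb, rng),
                evaluator=evaluator,
                parent_ids=(pa.id, pb.id),
                line_id=line,
                generation_index=gen,
            )
        )
    return Population(offspring, generation_index=gen, line_id=line)


def found_population(
    evaluator: GenotypeEvaluator,
    allele_space: Mapping[str, np.ndarray],
    size: int,
    rng: np.random.Generator,
    line_id: str = "line0",
    ploidy: int = 2,
) -> Population:
    """Founders: random heterozygous genotypes drawn from the allele space."""
    individuals = [
        Individual(
            id=f"{line_id}-g0-{i}",
            genotype=sample_founder_genotype(allele_space, ploidy, rng),
            evaluator=evaluator,
            line_id=line_id,
            generation_index=0,
        )
        for i in range(size)
    ]
    return Population(individuals, generation_index=0, line_id=line_id)


# ---------------------------------------------------------------------------
# multi-generation schedules
# ---------------------------------------------------------------------------


def run_inbreeding(
    founders: Population, config: SelectionConfig, rng: np.random.Generator
) -> list[Population]:
    """Iterate truncation selection + offspring production for
    ``config.generations`` generations; returns the full lineage, founders
    first."""
    lineage = [founders]
    current = founders
    for _ in range(config.generations):
        parents = truncation_select(current, config.selection_fraction)
        gen_rng = rng.spawn(1)[0]
        current = make_offspring_generation(
            parents,
            config.population_size,
            config.allow_selfing,
            gen_rng,
            line_id=founders.line_id,
            generation_index=current.generation_index + 1,
        )
        lineage.append(current)
    return lineage


def _sample_parents(
    population: Population, fraction: float, rng: np.random.Generator
) -> list[Individual]:
    n = max(1, round(fraction * len(population)))
    idx = rng.choice(len(population), size=n, replace=False)
    return [population.individuals[i] for i in sorted(idx)]


def produce_f1(
    line_a: Population,
    line_b: Population,
    n: int,
    sample_fraction: float,
    rng: np.random.Generator,
) -> Population:
    """F1 hybrids: each offspring crosses one parent sampled (without
    replacement) from 30% of each line; parent pairs may repeat."""
    if line_a.line_id == line_b.line_id:
        raise ConfigError(
            f"F1 parents must come from distinct lines, got {line_a.line_id!r} twice"
        )
    sample_a = _sample_parents(line_a, sample_fraction, rng)
    sample_b = _sample_parents(line_b, sample_fraction, rng)
    line = f"{line_a.line_id}x{line_b.line_id}"
    gen = max(line_a.generation_index, line_b.generation_index) + 1
    evaluator = sample_a[0].evaluator
    individuals = []
    for i in range(n):
        pa = sample_a[int(rng.integers(len(sample_a)))]
        pb = sample_b[int(rng.integers(len(sample_b)))]
        individuals.append(
            Individual(
                id=f"{line}-f1-{i}",
                genotype=cross(pa, pb, rng),
                evaluator=evaluator,
                parent_ids=(pa.id, pb.id),
                line_id=line,
                generation_index=gen,
            )
        )
    return Population(individuals, generation_index=gen, line_id=line)


def produce_f2(
    f1_pop: Population,
    n: int,
    rng: np.random.Generator,
    sample_fraction: float = 0.30,
) -> Population:
    """F2: crosses between distinct F1 parents sampled from 30% of the F1
    population; no selfing."""
    sample = _sample_parents(f1_pop, sample_fraction, rng)
    if n > 0 and len(sample) < 2:
        raise ConfigError(
            f"F2 production sampled {len(sample)} F1 parent(s); need >= 2"
        )
    gen = f1_pop.generation_index + 1
    individuals = []
    for i in range(n):
        ia = int(rng.integers(len(sample)))
        ib = int(rng.integers(len(sample) - 1))
        if ib >= ia:
            ib += 1
        pa, pb = sample[ia], sample[ib]
        individuals.append(
            Individual(
                id=f"{f1_pop.line_id}-f2-{i}",
                genotype=cross(pa, pb, rng),
                evaluator=pa.evaluator,
                parent_ids=(pa.id, pb.id),
                line_id=f1_pop.line_id,
                generation_index=gen,
            )
        )
    return Population(individuals, generation_index=gen, line_id=f1_pop.line_id)


def pairwise_cross_schedule(
    lines: Sequence[Population] | Sequence[str],
) -> list[tuple[str, str]]:
    """All unordered pairs of distinct line ids, in deterministic order."""
    ids = [p.line_id if isinstance(p, Population) else str(p) for p in lines]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise StructuralError(f"duplicate line ids: {dupes}")
    if len(ids) < 2:
        raise ConfigError("need at least two lines to schedule crosses")
    return list(itertools.combinations(ids, 2))


# ---------------------------------------------------------------------------
# recurrent-selection fixation experiment
# ---------------------------------------------------------------------------


@dataclass
class FixationConfig:
    """Parameters of the heterosis-fixation experiment (defaults mirror the
    full-scale run: 1000 F2, 10 founders per arm, 500 per generation, 2%
    selected and selfed, through generation 11)."""

    n_f2: int = 1000
    founders_per_arm: int = 10
    population_size: int = 500
    selection_fraction: float = 0.02
    last_generation: int = 11
    seed: int = 0

    def __post_init__(self) -> None:
        if self.last_generation < 2:
            raise ConfigError("last_generation must be >= 2")
        n_sel = max(1, round(self.selection_fraction * self.population_size))
        if n_sel < 1:
            raise ConfigError("selection keeps no individuals")


@dataclass
class FixationResult:
    f1: Individual
    f2: Population
    arms: dict[str, list[list[Population]]]  # arm -> lineages -> [F3..Fn]

    @property
    def generation_indices(self) -> list[int]:
        last = max(
            (pop.generation_index for lin in self.arms["selected"] for pop in lin),
            default=self.f2.generation_index,
        )
        return list(range(2, last + 1))

    def biomass_table(self) -> pd.DataFrame:
        rows = [
            {
                "arm": arm,
                "lineage": li,
                "generation": pop.generation_index,
                "mean_biomass": pop.mean_biomass(),
                "max_biomass": pop.max_biomass(),
                "mean_homozygosity": pop.mean_homozygosity(),
            }
            for arm, lineages in self.arms.items()
            for li, lineage in enumerate(lineages)
            for pop in lineage
        ]
        return pd.DataFrame(rows)

    def allele_frequency_table(self, arm: str) -> pd.DataFrame:
        """Per-generation, per-locus frequency of the two F1 parental
        alleles, pooled over lineages. Rows sum to 1."""
        pools: dict[int, list[Individual]] = {2: list(self.f2.individuals)}
        for lineage in self.arms[arm]:
            for pop in lineage:
                pools.setdefault(pop.generation_index, []).extend(pop.individuals)
        rows = []
        f1_alleles = self.f1.genotype.alleles
        for gen in sorted(pools):
            individuals = pools[gen]
            for locus, (a_val, b_val) in f1_alleles.items():
                n_a = n_b = 0
                for ind in individuals:
                    for v in ind.genotype.alleles[locus]:
                        if v == a_val:
                            n_a += 1
                        elif v == b_val:
                            n_b += 1
                total = n_a + n_b
                rows.append(
                    {
                        "generation": gen,
                        "locus": locus,
                        "freq_parent_a": n_a / total,
                        "freq_parent_b": n_b / total,
                    }
                )
        return pd.DataFrame(rows)


def _self_progeny(
    parents: Sequence[Individual],
    size: int,
    rng: np.random.Generator,
    line_id: str,
    generation_index: int,
) -> Population:
    """Self each parent; offspring counts split as evenly as possible."""
    per = [size // len(parents)] * len(parents)
    for k in range(size - sum(per)):
        per[k] += 1
    individuals = []
    i = 0
    for parent, count in zip(parents, per):
        for _ in range(count):
            individuals.append(
                Individual(
                    id=f"{line_id}-g{generation_index}-{i}",
                    genotype=cross(parent, parent, rng),
                    evaluator=parent.evaluator,
                    parent_ids=(parent.id, parent.id),
                    line_id=line_id,
                    generation_index=generation_index,
                )
            )
            i += 1
    return Population(individuals, generation_index, line_id)


def population_to_dict(population: Population) -> dict:
    """JSON-serialisable archive of a population (genotypes + lineage)."""
    return {
        "line_id": population.line_id,
        "generation_index": population.generation_index,
        "rng_seed": population.rng_seed,
        "individuals": [
            {
                "id": ind.id,
                "parent_ids": list(ind.parent_ids) if ind.parent_ids else None,
                "generation_index": ind.generation_index,
                "ploidy": ind.genotype.ploidy,
                "alleles": {l: list(v) for l, v in ind.genotype.alleles.items()},
            }
            for ind in population.individuals
        ],
    }


def population_from_dict(data: Mapping, evaluator: GenotypeEvaluator) -> Population:
    individuals = [
        Individual(
            id=rec["id"],
            genotype=Genotype(
                {l: tuple(v) for l, v in rec["alleles"].items()},
                int(rec["ploidy"]),
            ),
            evaluator=evaluator,
            parent_ids=tuple(rec["parent_ids"]) if rec["parent_ids"] else None,
            line_id=data["line_id"],
            generation_index=int(rec["generation_index"]),
        )
        for rec in data["individuals"]
    ]
    return Population(
        individuals,
        generation_index=int(data["generation_index"]),
        line_id=data["line_id"],
        rng_seed=data.get("rng_seed"),
    )


def fixation_experiment(f1: Individual, config: FixationConfig) -> FixationResult:
    """Recurrent selection under selfing, starting from one F1.

    The F1 is selfed into ``n_f2`` F2 individuals. Two arms of
    ``founders_per_arm`` F2 founders are taken (top-biomass vs random); each
    founder seeds a selfing lineage of ``population_size`` individuals per
    generation in which ``selection_fraction`` are selected (top-biomass or
    random, per arm) and selfed, through generation ``last_generation``.
    """
    rng = np.random.default_rng(config.seed)
    f2_pop = _self_progeny(
        [f1], config.n_f2, rng.spawn(1)[0], f"{f1.line_id}-fix", 2
    )
    ranked = sorted(
        f2_pop.individuals, key=lambda ind: (-ind.biomass_rate, ind.id)
    )
    top = ranked[: config.founders_per_arm]
    rand_idx = rng.choice(
        len(f2_pop), size=config.founders_per_arm, replace=False
    )
    randoms = [f2_pop.individuals[i] for i in sorted(rand_idx)]

    arms: dict[str, list[list[Population]]] = {"selected": [], "random": []}
    for arm, founders in (("selected", top), ("random", randoms)):
        for li, founder in enumerate(founders):
            line_id = f"{f1.line_id}-fix-{arm}-{li}"
            lineage: list[Population] = []
            parents = [founder]
            for gen in range(3, config.last_generation + 1):
                gen_rng = rng.spawn(1)[0]
                pop = _self_progeny(
                    parents, config.population_size, gen_rng, line_id, gen
                )
                lineage.append(pop)
                n_sel = max(1, round(config.selection_fraction * len(pop)))
                if arm == "selected":
                    parents = sorted(
                        pop.individuals,
                        key=lambda ind: (-ind.biomass_rate, ind.id),
                    )[:n_sel]
                else:
                    idx = gen_rng.choice(len(pop), size=n_sel, replace=False)
                    parents = [pop.individuals[i] for i in sorted(idx)]
            arms[arm].append(lineage)
    return FixationResult(f1=f1, f2=f2_pop, arms=arms)
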