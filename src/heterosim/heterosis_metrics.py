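"""Quantification and decomposition of hybrid vigour.

Mid-parent ratios, per-locus substitution scans, the single-/multi-locus
decomposition (on the absolute biomass-deviation scale, where additivity is
exact), flux-heterosis correlations, efficiency profiles and the three-set
reaction classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .breeding_sim import Individual, Population
from .exceptions import (
    StatisticalError,
    StructuralError,
    UndefinedRatioError,
)
from .genetics_layer import GenotypeEvaluator, derive_constraints, evaluate_individual

#: |r| threshold defining the heterosis-correlated reaction set
CORRELATION_THRESHOLD = 0.90
#: across-individual variance threshold defining the contributing set
CONTRIBUTION_VARIANCE_THRESHOLD = 1e-8
#: efficiency above which a reaction counts as near-maximally used
HIGH_EFFICIENCY = 0.95


@dataclass
class HeterosisRecord:
    f1_id: str
    parent_a_id: str
    parent_b_id: str
    midparent_ratio: float
    absolute_deviation: float


@dataclass
class LocusContribution:
    """Effect of making one F1 locus homozygous for either parental allele.

    ``deltas`` holds biomass(substituted) - biomass(F1) per parental slot;
    ``direct_contribution`` is biomass(F1) minus the mean substituted
    biomass, i.e. the heterosis attributable to heterozygosity at this locus
    alone.
    """

    locus: str
    deltas: tuple[float, float]
    direct_contribution: float


@dataclass
class DecompositionResult:
    overall: float
    single_locus_sum: float
    multi_locus: float


def midparent_heterosis(
    f1: Individual, parent_a: Individual, parent_b: Individual
) -> HeterosisRecord:
    """F1 biomass over the mean of the two parental biomasses."""
    parent_mean = 0.5 * (parent_a.biomass_rate + parent_b.biomass_rate)
    if parent_mean <= 0.0:
        raise UndefinedRatioError(
            f"parents of {f1.id!r} have zero mean biomass; ratio undefined"
        )
    f1_rate = f1.biomass_rate
    return HeterosisRecord(
        f1_id=f1.id,
        parent_a_id=parent_a.id,
        parent_b_id=parent_b.id,
        midparent_ratio=f1_rate / parent_mean,
        absolute_deviation=f1_rate - parent_mean,
    )


def locus_substitution_scan(
    f1: Individual,
    evaluator: GenotypeEvaluator | None = None,
    renormalise: bool = True,
) -> list[LocusContribution]:
    """Make each locus homozygous for each parental allele in turn.

    Slot order of the F1 genotype carries parental origin (slot 0 from the
    first parent, slot 1 from the second), so only diploids are scanned.
    With ``renormalise`` (default) every substituted genotype re-derives its
    constraints from scratch, including the capacity normalisation factor;
    otherwise the F1's factor is frozen.
    """
    genotype = f1.genotype
    if genotype.ploidy != 2:
        raise StructuralError(
            "substitution scan requires diploid genotypes with tracked "
            f"parental slots; got ploidy {genotype.ploidy}"
        )
    evaluator = evaluator if evaluator is not None else f1.evaluator
    f1_biomass = evaluator.evaluate(genotype).biomass_rate
    frozen_lam = None
    if not renormalise:
        frozen_lam = derive_constraints(genotype, evaluator.rfd).normalisation_factor

    contributions = []
    for locus, alleles in genotype.alleles.items():
        if alleles[0] == alleles[1]:
            contributions.append(LocusContribution(locus, (0.0, 0.0), 0.0))
            continue
        subs = []
        for value in alleles:
            sub_genotype = genotype.with_homozygous_locus(locus, value)
            if renormalise:
                phenotype = evaluator.evaluate(sub_genotype)
            else:
                constraints = derive_constraints(
                    sub_genotype, evaluator.rfd, lam_override=frozen_lam
                )
                phenotype = evaluate_individual(evaluator.model, constraints)
            subs.append(phenotype.biomass_rate)
        deltas = (subs[0] - f1_biomass, subs[1] - f1_biomass)
        direct = f1_biomass - 0.5 * (subs[0] + subs[1])
        contributions.append(LocusContribution(locus, deltas, direct))
    return contributions


def decompose_heterosis(
    record: HeterosisRecord, contributions: Sequence[LocusContribution]
) -> DecompositionResult:
    """Split the heterotic deviation into single-locus and residual
    multi-locus parts; overall = singles + multi holds exactly."""
    single = math.fsum(c.direct_contribution for c in contributions)
    return DecompositionResult(
        overall=record.absolute_deviation,
        single_locus_sum=single,
        multi_locus=record.absolute_deviation - single,
    )


def flux_heterosis_correlation(
    f1_pop: Population, records: Sequence[HeterosisRecord]
) -> dict[str, float]:
    """Pearson r between each reaction's computed flux and the mid-parent
    ratio across F1 individuals; zero-variance reactions are omitted."""
    ratio_by_id = {r.f1_id: r.midparent_ratio for r in records}
    individuals = [ind for ind in f1_pop if ind.id in ratio_by_id]
    if len(individuals) < 3:
        raise StatisticalError(
            f"need >= 3 matched individuals, got {len(individuals)}"
        )
    ratios = np.array([ratio_by_id[ind.id] for ind in individuals])
    if np.std(ratios) == 0.0:
        raise StatisticalError("no variance in heterosis across individuals")
    reaction_ids = list(individuals[0].phenotype.computed_flux)
    flux = np.array(
        [
            [ind.phenotype.computed_flux[r] for r in reaction_ids]
            for ind in individuals
        ]
    )
    out: dict[str, float] = {}
    centred_ratio = ratios - ratios.mean()
    denom_r = float(np.sqrt((centred_ratio**2).sum()))
    for k, rxn in enumerate(reaction_ids):
        col = flux[:, k]
        centred = col - col.mean()
        denom_f = float(np.sqrt((centred**2).sum()))
        if denom_f == 0.0:
            continue  # reported as missing, not 0
        out[rxn] = float((centred @ centred_ratio) / (denom_f * denom_r))
    return out


def correlated_reactions(
    correlations: Mapping[str, float], threshold: float = CORRELATION_THRESHOLD
) -> set[str]:
    return {r for r, v in correlations.items() if abs(v) > threshold}


@dataclass
class EfficiencyProfile:
    values: np.ndarray
    tail_fraction: float
    histogram: tuple[np.ndarray, np.ndarray]

    @property
    def mean(self) -> float:
        return float(self.values.mean()) if self.values.size else float("nan")


def efficiency_profile(
    population: Population, bins: int = 20
) -> EfficiencyProfile:
    """Pooled per-reaction efficiencies (|computed flux| / capacity) with the
    fraction above the near-maximal threshold. Zero-capacity loci carry no
    efficiency and are excluded upstream."""
    pooled = [
        eff
        for ind in population
        for eff in ind.phenotype.efficiency.values()
    ]
    values = np.array(pooled)
    if values.size == 0:
        return EfficiencyProfile(values, float("nan"), (np.zeros(bins), np.linspace(0, 1, bins + 1)))
    tail = float((values > HIGH_EFFICIENCY).mean())
    hist = np.histogram(values, bins=bins, range=(0.0, max(1.0, values.max())))
    return EfficiencyProfile(values, tail, hist)


def contribution_matrix(
    scans: Mapping[str, Sequence[LocusContribution]]
) -> pd.DataFrame:
    """Individuals x loci matrix of direct contributions."""
    return pd.DataFrame(
        {
            f1_id: {c.locus: c.direct_contribution for c in contribs}
            for f1_id, contribs in scans.items()
        }
    ).T.sort_index()


def contributing_reactions(
    scans: Mapping[str, Sequence[LocusContribution]],
    threshold: float = CONTRIBUTION_VARIANCE_THRESHOLD,
) -> set[str]:
    """Loci whose direct contribution varies across individuals."""
    matrix = contribution_matrix(scans)
    variances = matrix.var(axis=0, ddof=0)
    return set(variances.index[variances > threshold])


@dataclass
class ClassificationResult:
    membership: pd.DataFrame
    region_counts: dict[str, int]

    def counts_tuple(self) -> tuple[int, ...]:
        keys = (
            "coupled_only",
            "correlated_only",
            "contributing_only",
            "coupled_correlated",
            "coupled_contributing",
            "correlated_contributing",
            "all_three",
        )
        return tuple(self.region_counts[k] for k in keys)


def classify_reactions(
    coupled: set[str], correlated: set[str], contributing: set[str]
) -> ClassificationResult:
    """Three-set membership table and the seven Venn-region counts."""
    union = sorted(coupled | correlated | contributing)
    membership = pd.DataFrame(
        {
            "reaction": union,
            "coupled": [r in coupled for r in union],
            "correlated": [r in correlated for r in union],
            "contributing": [r in contributing for r in union],
        }
    ).set_index("reaction")
    counts = {
        "coupled_only": len(coupled - correlated - contributing),
        "correlated_only": len(correlated - coupled - contributing),
        "contributing_only": len(contributing - coupled - correlated),
        "coupled_correlated": len((coupled & correlated) - contributing),
        "coupled_contributing": len((coupled & contributing) - correlated),
        "correlated_contributing": len((correlated & contributing) - coupled),
        "all_three": len(coupled & correlated & contributing),
    }
    return ClassificationResult(membership, counts)
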