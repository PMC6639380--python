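"""Genotype-to-constraint mapping and individual phenotype evaluation.

Alleles are flux capacities drawn from a discrete uniform distribution over
the flux-variability envelope of each internal reaction. Per locus the
allele values are averaged (additive action), the per-locus means are scaled
down by a common factor so their sum never exceeds the total flux of the
reference distribution, and the resulting enzyme capacities tighten the
reaction bound in the reference flux direction. The constrained model is
then solved by parsimonious FBA.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .exceptions import InfeasibleError, StructuralError, ValidationError
from .metabolic_core import (
    COMPARISON_TOL,
    FluxDistribution,
    FluxEnvelope,
    MetabolicModel,
    run_pfba,
)

logger = logging.getLogger(__name__)

#: capacities below this are treated as zero when computing efficiencies
CAPACITY_TOL = 1e-12


@dataclass(frozen=True)
class Allele:
    """One allele: a non-negative flux capacity attached to a reaction."""

    locus: str
    value: float


@dataclass(frozen=True)
class Genotype:
    """Per-locus allele tuples for one individual.

    ``alleles`` maps each constrained locus (every reaction that is neither
    an exchange nor the biomass sink) to exactly ``ploidy`` capacity values.
    For offspring of a cross, slot order records parental origin: slot 0
    came from the first parent, slot 1 from the second.
    """

    alleles: Mapping[str, tuple[float, ...]]
    ploidy: int = 2

    def __post_init__(self) -> None:
        if self.ploidy < 2:
            raise ValidationError("ploidy must be >= 2")
        for locus, values in self.alleles.items():
            if len(values) != self.ploidy:
                raise ValidationError(
                    f"locus {locus!r} carries {len(values)} alleles, "
                    f"expected {self.ploidy}"
                )

    @property
    def constrained_loci(self) -> tuple[str, ...]:
        return tuple(self.alleles)

    def with_homozygous_locus(self, locus: str, value: float) -> "Genotype":
        """Copy of this genotype made homozygous for ``value`` at ``locus``."""
        if locus not in self.alleles:
            raise StructuralError(f"unknown locus {locus!r}")
        new = dict(self.alleles)
        new[locus] = (value,) * self.ploidy
        return Genotype(new, self.ploidy)


@dataclass
class ConstraintSet:
    """Per-reaction enzyme capacities derived from one genotype."""

    capacity: dict[str, float]
    normalisation_factor: float
    direction: dict[str, int]  # sign of the reference flux at each locus


@dataclass
class Phenotype:
    """Outcome of optimising one constrained individual."""

    biomass_rate: float
    computed_flux: dict[str, float]
    efficiency: dict[str, float]
    feasible: bool = True
    total_flux: float = 0.0


def build_reference(model: MetabolicModel) -> FluxDistribution:
    """Parsimonious FBA on the unconstrained model: the lineage-wide
    reference flux distribution (directionality + normalisation budget)."""
    return run_pfba(model)


def build_allele_space(
    model: MetabolicModel,
    envelope: FluxEnvelope,
    rfd: FluxDistribution,
    levels: int = 101,
) -> dict[str, np.ndarray]:
    """Candidate allele values per constrained locus.

    For each locus, ``levels`` evenly spaced capacities spanning the
    absolute-flux range of its envelope restricted to the reference flux
    direction, endpoints included. A degenerate envelope yields a
    single-valued (monomorphic) locus.
    """
    if levels < 1:
        raise ValidationError("levels must be >= 1")
    space: dict[str, np.ndarray] = {}
    for locus in model.constrained_loci:
        env_lo, env_hi = envelope[locus]
        ref = rfd.flux[locus]
        if ref >= COMPARISON_TOL:
            lo, hi = max(env_lo, 0.0), max(env_hi, 0.0)
        elif ref <= -COMPARISON_TOL:
            lo, hi = max(-env_hi, 0.0), max(-env_lo, 0.0)
        else:
            # no reference direction: span of attainable |flux|
            hi = max(abs(env_lo), abs(env_hi))
            lo = 0.0 if env_lo <= 0.0 <= env_hi else min(abs(env_lo), abs(env_hi))
        if hi - lo <= COMPARISON_TOL:
            logger.warning("locus %s is monomorphic (envelope %.6g)", locus, lo)
            space[locus] = np.array([lo])
        else:
            space[locus] = np.linspace(lo, hi, levels)
    return space


def sample_founder_genotype(
    allele_space: Mapping[str, np.ndarray],
    ploidy: int,
    rng: np.random.Generator,
) -> Genotype:
    """Independent uniform draws (with replacement) at every locus."""
    alleles = {}
    for locus, values in allele_space.items():
        idx = rng.integers(0, len(values), size=ploidy)
        alleles[locus] = tuple(float(values[i]) for i in idx)
    return Genotype(alleles, ploidy)


def derive_constraints(
    genotype: Genotype,
    rfd: FluxDistribution,
    lam_override: float | None = None,
) -> ConstraintSet:
    """Average alleles per locus and normalise total capacity.

    The normalisation factor is ``min(1, T_rfd / T_raw)`` where ``T_rfd`` is
    the total absolute reference flux and ``T_raw`` the sum of the per-locus
    allele means: capacities are capped, never scaled up. ``lam_override``
    freezes the factor (used by the substitution scan's frozen-lambda mode).
    """
    means = {
        locus: math.fsum(values) / len(values)
        for locus, values in genotype.alleles.items()
    }
    if lam_override is None:
        t_rfd = math.fsum(abs(v) for v in rfd.flux.values())
        t_raw = math.fsum(means.values())
        lam = 1.0 if t_raw <= t_rfd or t_raw == 0.0 else t_rfd / t_raw
    else:
        lam = lam_override
    direction = {}
    for locus in means:
        ref = rfd.flux[locus]
        if ref >= COMPARISON_TOL:
            direction[locus] = 1
        elif ref <= -COMPARISON_TOL:
            direction[locus] = -1
        else:
            direction[locus] = 0
    capacity = {locus: lam * mean for locus, mean in means.items()}
    return ConstraintSet(capacity, lam, direction)


def _apply_constraints(
    model: MetabolicModel, constraints: ConstraintSet
) -> tuple[np.ndarray, np.ndarray]:
    lb, ub = model.bounds_arrays()
    for locus, cap in constraints.capacity.items():
        j = model.index(locus)
        d = constraints.direction[locus]
        if d >= 0:
            ub[j] = min(ub[j], cap)
        if d <= 0:
            lb[j] = max(lb[j], -cap)
    return lb, ub


def evaluate_individual(
    model: MetabolicModel, constraints: ConstraintSet
) -> Phenotype:
    """Tighten bounds by the enzyme capacities and run parsimonious FBA.

    An infeasible constrained model signals a non-viable genotype and is
    returned as a zero-biomass phenotype rather than raised.
    """
    lb, ub = _apply_constraints(model, constraints)
    try:
        sol = run_pfba(model, lb, ub)
    except InfeasibleError:
        zero = {r: 0.0 for r in model.reaction_ids}
        return Phenotype(
            biomass_rate=0.0,
            computed_flux=zero,
            efficiency={
                l: 0.0
                for l, c in constraints.capacity.items()
                if c > CAPACITY_TOL
            },
            feasible=False,
        )
    efficiency = {
        locus: abs(sol.flux[locus]) / cap
        for locus, cap in constraints.capacity.items()
        if cap > CAPACITY_TOL
    }
    return Phenotype(
        biomass_rate=sol.objective_value,
        computed_flux=dict(sol.flux),
        efficiency=efficiency,
        feasible=True,
        total_flux=sol.total_flux,
    )


def homozygosity_fraction(genotype: Genotype) -> float:
    """Fraction of constrained loci whose allele values are all identical."""
    loci = genotype.alleles
    if not loci:
        return 1.0
    n_hom = sum(
        1 for values in loci.values() if all(v == values[0] for v in values)
    )
    return n_hom / len(loci)


class GenotypeEvaluator:
    """Evaluates genotypes against one (model, reference) pair.

    Phenotypes depend only on the derived capacities, so results are cached
    on the capacity vector; inbred populations converge to few distinct
    genotypes and hit the cache heavily. Evaluation is pure: identical
    genotypes always produce identical phenotypes.
    """

    def __init__(self, model: MetabolicModel, rfd: FluxDistribution) -> None:
        self.model = model
        self.rfd = rfd
        self._cache: dict[tuple, Phenotype] = {}

    def evaluate(self, genotype: Genotype) -> Phenotype:
        constraints = derive_constraints(genotype, self.rfd)
        key = tuple(sorted(constraints.capacity.items()))
        hit = self._cache.get(key)
        if hit is None:
            hit = evaluate_individual(self.model, constraints)
            self._cache[key] = hit
        return hit


# ---------------------------------------------------------------------------
# JSON schema for genotypes / constraint sets:
#   {"ploidy": 2, "alleles": {"R1": [4.0, 6.0], ...}}
#   {"normalisation_factor": 1.0, "capacity": {...}, "direction": {...}}
# ---------------------------------------------------------------------------


def genotype_to_dict(genotype: Genotype) -> dict:
    return {
        "ploidy": genotype.ploidy,
        "alleles": {l: list(v) for l, v in genotype.alleles.items()},
    }


def genotype_from_dict(data: Mapping) -> Genotype:
    return Genotype(
        {l: tuple(v) for l, v in data["alleles"].items()},
        int(data["ploidy"]),
    )


def save_genotype(genotype: Genotype, path: str | Path) -> None:
    Path(path).write_text(json.dumps(genotype_to_dict(genotype), sort_keys=True))


def load_genotype(path: str | Path) -> Genotype:
    return genotype_from_dict(json.loads(Path(path).read_text()))


def constraints_to_dict(constraints: ConstraintSet) -> dict:
    return {
        "normalisation_factor": constraints.normalisation_factor,
        "capacity": dict(constraints.capacity),
        "direction": dict(constraints.direction),
    }
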