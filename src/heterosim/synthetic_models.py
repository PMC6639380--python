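"""Small constraint-based models with known analytic optima.

Every topology produces a model that passes :class:`MetabolicModel`
validation, is feasible and bounded, and has a strictly positive optimum.
Capacities default to values whose flux-variability envelopes at fraction
0.95 are non-degenerate, so allele spaces built on them have room to vary:

* ``chain`` — a single linear pathway; envelope of every internal reaction
  is ``[0.95 * input, input]``.
* ``parallel_paths`` — paths of configurable length and capacity between a
  shared substrate and the biomass precursor.
* ``bottleneck_pair`` — a serial pathway (default 4 internal steps) on which
  two complementary low-capacity parents exhibit F1 hybrid vigour.
* ``futile_cycle`` — a chain plus a two-reaction cycle detached from
  biomass; parsimonious FBA must leave the cycle at zero flux.
* ``branched`` — two parallel two-step routes of unequal capacity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .exceptions import ValidationError
from .metabolic_core import (
    MetabolicModel,
    Metabolite,
    Reaction,
    write_model,  # re-exported: fixture files are written through this
)

__all__ = ["ToySpec", "make_toy_model", "write_model"]

TOPOLOGIES = ("chain", "parallel_paths", "bottleneck_pair", "futile_cycle", "branched")


@dataclass
class ToySpec:
    """Declarative description of a toy network.

    ``capacities`` are the upper bounds of internal reactions. For serial
    topologies one value per internal step (a single value is broadcast);
    for parallel topologies one value per path.
    """

    topology: str = "chain"
    n_internal: int = 1
    capacities: Sequence[float] | float = 10.0
    path_lengths: Sequence[int] | None = None
    input_bound: float = 10.0
    cycle_bound: float = 10.0

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValidationError(
                f"unknown topology {self.topology!r}; expected one of {TOPOLOGIES}"
            )
        if self.input_bound <= 0:
            raise ValidationError("input_bound must be positive")
        if self.topology in ("chain", "bottleneck_pair", "futile_cycle"):
            if self.n_internal < 1:
                raise ValidationError("need at least one internal reaction")
        if self.topology in ("parallel_paths", "branched"):
            caps = self.capacity_list()
            if len(caps) < 2:
                raise ValidationError("parallel topologies need >= 2 paths")

    def capacity_list(self) -> list[float]:
        if isinstance(self.capacities, (int, float)):
            n = (
                self.n_internal
                if self.topology in ("chain", "bottleneck_pair", "futile_cycle")
                else 2
            )
            return [float(self.capacities)] * n
        return [float(c) for c in self.capacities]

    def analytic_optimum(self) -> float:
        caps = self.capacity_list()
        if self.topology in ("chain", "bottleneck_pair", "futile_cycle"):
            return min([self.input_bound] + caps)
        return min(self.input_bound, sum(caps))


def _serial_reactions(
    met_ids: list[str], caps: list[float], prefix: str = "R"
) -> list[Reaction]:
    out = []
    for i in range(len(met_ids) - 1):
        out.append(
            Reaction(
                id=f"{prefix}{i + 1}",
                stoichiometry={met_ids[i]: -1.0, met_ids[i + 1]: 1.0},
                lower_bound=0.0,
                upper_bound=caps[i],
            )
        )
    return out


def make_toy_model(spec: ToySpec) -> MetabolicModel:
    """Build the deterministic model described by ``spec``.

    The analytic optimum (where known) is attached as
    ``model.expected_optimum``.
    """
    caps = spec.capacity_list()
    reactions: list[Reaction] = []
    metabolites: list[Metabolite] = []

    if spec.topology in ("chain", "bottleneck_pair", "futile_cycle"):
        if len(caps) != spec.n_internal:
            raise ValidationError(
                f"{spec.n_internal} internal steps but {len(caps)} capacities"
            )
        met_ids = [f"M{i + 1}" for i in range(spec.n_internal + 1)]
        metabolites = [Metabolite(m) for m in met_ids]
        reactions.append(
            Reaction("EX_M1", {met_ids[0]: 1.0}, 0.0, spec.input_bound)
        )
        reactions.extend(_serial_reactions(met_ids, caps))
        reactions.append(Reaction("BIO", {met_ids[-1]: -1.0}, 0.0, 1e6))
        if spec.topology == "futile_cycle":
            metabolites += [Metabolite("X"), Metabolite("Y")]
            reactions.append(
                Reaction("CYC1", {"X": -1.0, "Y": 1.0}, 0.0, spec.cycle_bound)
            )
            reactions.append(
                Reaction("CYC2", {"Y": -1.0, "X": 1.0}, 0.0, spec.cycle_bound)
            )
    else:  # parallel_paths / branched
        lengths = list(spec.path_lengths) if spec.path_lengths else (
            [2, 2] if spec.topology == "branched" else [1] * len(caps)
        )
        if len(lengths) != len(caps):
            raise ValidationError(
                f"{len(caps)} paths but {len(lengths)} path lengths"
            )
        metabolites = [Metabolite("A"), Metabolite("Z")]
        reactions.append(Reaction("EX_A", {"A": 1.0}, 0.0, spec.input_bound))
        for p, (cap, length) in enumerate(zip(caps, lengths), start=1):
            if length < 1:
                raise ValidationError("path length must be >= 1")
            mids = ["A"] + [f"P{p}M{k}" for k in range(1, length)] + ["Z"]
            metabolites += [Metabolite(m) for m in mids[1:-1]]
            reactions.extend(
                _serial_reactions(mids, [cap] * length, prefix=f"P{p}R")
            )
        reactions.append(Reaction("BIO", {"Z": -1.0}, 0.0, 1e6))

    model = MetabolicModel(
        reactions, metabolites, objective_id="BIO", name=f"toy_{spec.topology}"
    )
    model.expected_optimum = spec.analytic_optimum()
    return model
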