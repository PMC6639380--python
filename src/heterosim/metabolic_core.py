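"""Constraint-based model container and the linear programs built on it.

The model is a thin, validated stoichiometric structure; all optimisation
(FBA, parsimonious FBA, flux variability, biomass coupling) is expressed as
linear programs solved with HiGHS through :func:`scipy.optimize.linprog`.
SBML (level 3 + FBC) and COBRA-style JSON serialisations are delegated to
:mod:`cobra`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .exceptions import (
    FormatError,
    InfeasibleError,
    UnboundedError,
    ValidationError,
)

#: LP feasibility/optimality tolerance (HiGHS primal/dual tolerances).
FEASIBILITY_TOL = 1e-9
#: Tolerance used when comparing fluxes and objectives.
COMPARISON_TOL = 1e-6

#: Reaction classes.
CLASS_INTERNAL = "internal"
CLASS_EXCHANGE = "exchange"
CLASS_BIOMASS = "biomass"


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str = "c"


@dataclass
class Reaction:
    """One reaction: a stoichiometry map plus flux bounds and a class tag."""

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float
    upper_bound: float
    rclass: str = CLASS_INTERNAL

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0


class MetabolicModel:
    """Validated stoichiometric model with a single biomass objective.

    Parameters
    ----------
    reactions:
        Ordered reaction records. Classes are inferred when left as
        ``internal``: a reaction touching exactly one metabolite is an
        exchange, and the objective reaction is the biomass sink.
    metabolites:
        Ordered metabolite records.
    objective_id:
        Id of the biomass reaction (coefficient 1 in the objective).
    """

    def __init__(
        self,
        reactions: Sequence[Reaction],
        metabolites: Sequence[Metabolite],
        objective_id: str,
        name: str = "model",
    ) -> None:
        self.reactions = list(reactions)
        self.metabolites = list(metabolites)
        self.objective_id = objective_id
        self.name = name
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._infer_classes()
        self.validate()
        self._S: np.ndarray | None = None

    # -- structure ---------------------------------------------------------

    def _infer_classes(self) -> None:
        for rxn in self.reactions:
            if rxn.id == self.objective_id:
                rxn.rclass = CLASS_BIOMASS
            elif rxn.rclass == CLASS_INTERNAL and len(rxn.stoichiometry) == 1:
                rxn.rclass = CLASS_EXCHANGE

    def validate(self) -> None:
        if len(self._rxn_index) != len(self.reactions):
            raise ValidationError("duplicate reaction ids")
        if len(self._met_index) != len(self.metabolites):
            raise ValidationError("duplicate metabolite ids")
        if self.objective_id not in self._rxn_index:
            raise ValidationError(
                f"objective reaction {self.objective_id!r} not in model"
            )
        n_biomass = sum(1 for r in self.reactions if r.rclass == CLASS_BIOMASS)
        if n_biomass != 1:
            raise ValidationError(
                f"exactly one biomass reaction required, found {n_biomass}"
            )
        for rxn in self.reactions:
            if rxn.lower_bound > rxn.upper_bound:
                raise ValidationError(
                    f"reaction {rxn.id!r}: lower bound {rxn.lower_bound} "
                    f"exceeds upper bound {rxn.upper_bound}"
                )
            for met in rxn.stoichiometry:
                if met not in self._met_index:
                    raise ValidationError(
                        f"reaction {rxn.id!r} references undeclared "
                        f"metabolite {met!r}"
                    )
            if rxn.rclass == CLASS_EXCHANGE and len(rxn.stoichiometry) != 1:
                raise ValidationError(
                    f"exchange reaction {rxn.id!r} must touch exactly one "
                    f"metabolite"
                )

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    def index(self, rxn_id: str) -> int:
        return self._rxn_index[rxn_id]

    @property
    def constrained_loci(self) -> list[str]:
        """Reaction ids that carry alleles: everything except exchanges and
        the biomass sink."""
        return [r.id for r in self.reactions if r.rclass == CLASS_INTERNAL]

    def stoichiometric_matrix(self) -> np.ndarray:
        if self._S is None:
            S = np.zeros((len(self.metabolites), len(self.reactions)))
            for j, rxn in enumerate(self.reactions):
                for met, coef in rxn.stoichiometry.items():
                    S[self._met_index[met], j] = coef
            self._S = S
        return self._S

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    def objective_vector(self) -> np.ndarray:
        c = np.zeros(len(self.reactions))
        c[self._rxn_index[self.objective_id]] = 1.0
        return c

    def structurally_equal(self, other: "MetabolicModel") -> bool:
        if self.objective_id != other.objective_id:
            return False
        if self.reaction_ids != other.reaction_ids:
            return False
        if sorted(m.id for m in self.metabolites) != sorted(
            m.id for m in other.metabolites
        ):
            return False
        for a, b in zip(self.reactions, other.reactions):
            if a.rclass != b.rclass:
                return False
            if not math.isclose(a.lower_bound, b.lower_bound, abs_tol=1e-9):
                return False
            if not math.isclose(a.upper_bound, b.upper_bound, abs_tol=1e-9):
                return False
            if set(a.stoichiometry) != set(b.stoichiometry):
                return False
            for met, coef in a.stoichiometry.items():
                if not math.isclose(coef, b.stoichiometry[met], abs_tol=1e-9):
                    return False
        return True


@dataclass
class FluxDistribution:
    """One steady-state flux vector with its objective and total flux."""

    flux: dict[str, float]
    objective_value: float
    total_flux: float

    def as_array(self, model: MetabolicModel) -> np.ndarray:
        return np.array([self.flux[r] for r in model.reaction_ids])


@dataclass
class FluxEnvelope:
    """Per-reaction (min, max) flux attainable at near-optimal biomass."""

    ranges: dict[str, tuple[float, float]]
    fraction: float

    def __getitem__(self, rxn_id: str) -> tuple[float, float]:
        return self.ranges[rxn_id]


# ---------------------------------------------------------------------------
# LP solvers
# ---------------------------------------------------------------------------

_LINPROG_OPTS = {
    "presolve": True,
    "primal_feasibility_tolerance": FEASIBILITY_TOL,
    "dual_feasibility_tolerance": FEASIBILITY_TOL,
}


def _solve(c, A_eq, b_eq, bounds, A_ub=None, b_ub=None):
    return linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options=_LINPROG_OPTS,
    )


def _raise_lp_failure(status: int, model: MetabolicModel) -> None:
    if status == 2:
        raise InfeasibleError(f"model {model.name!r}: no feasible flux vector")
    if status == 3:
        unbounded = [
            r.id
            for r in model.reactions
            if math.isinf(r.upper_bound) or math.isinf(r.lower_bound)
        ]
        raise UnboundedError(
            f"model {model.name!r}: objective unbounded "
            f"(reactions with infinite bounds: {unbounded or 'none declared'})"
        )
    raise RuntimeError(f"LP solver failed with status {status}")


def run_fba(
    model: MetabolicModel,
    lb: np.ndarray | None = None,
    ub: np.ndarray | None = None,
) -> FluxDistribution:
    """Maximise the biomass flux subject to steady state and bounds."""
    mlb, mub = model.bounds_arrays()
    lb = mlb if lb is None else lb
    ub = mub if ub is None else ub
    S = model.stoichiometric_matrix()
    c = model.objective_vector()
    res = _solve(-c, S, np.zeros(S.shape[0]), np.column_stack([lb, ub]))
    if res.status != 0:
        _raise_lp_failure(res.status, model)
    flux = dict(zip(model.reaction_ids, res.x))
    return FluxDistribution(
        flux=flux,
        objective_value=float(c @ res.x),
        total_flux=float(np.abs(res.x).sum()),
    )


def run_pfba(
    model: MetabolicModel,
    lb: np.ndarray | None = None,
    ub: np.ndarray | None = None,
) -> FluxDistribution:
    """Two-stage parsimonious FBA.

    First the biomass flux is maximised; every reversible reaction is then
    split into a non-negative forward/reverse pair and the total (split) flux
    is minimised while holding biomass at its optimum. The merged flux vector
    is returned.
    """
    mlb, mub = model.bounds_arrays()
    lb = mlb if lb is None else np.asarray(lb, dtype=float)
    ub = mub if ub is None else np.asarray(ub, dtype=float)
    fba = run_fba(model, lb, ub)
    v_opt = fba.objective_value

    S = model.stoichiometric_matrix()
    m, n = S.shape
    bio = model.index(model.objective_id)

    # variables: [v_plus (n), v_minus (n)], v = v_plus - v_minus
    A_eq = np.zeros((m + 1, 2 * n))
    A_eq[:m, :n] = S
    A_eq[:m, n:] = -S
    A_eq[m, bio] = 1.0
    A_eq[m, n + bio] = -1.0
    b_eq = np.zeros(m + 1)
    b_eq[m] = v_opt

    plus_bounds = np.column_stack([np.maximum(lb, 0.0), np.maximum(ub, 0.0)])
    minus_bounds = np.column_stack([np.maximum(-ub, 0.0), np.maximum(-lb, 0.0)])
    bounds = np.vstack([plus_bounds, minus_bounds])

    res = _solve(np.ones(2 * n), A_eq, b_eq, bounds)
    if res.status != 0:
        _raise_lp_failure(res.status, model)
    v = res.x[:n] - res.x[n:]
    flux = dict(zip(model.reaction_ids, v))
    return FluxDistribution(
        flux=flux,
        objective_value=v_opt,
        total_flux=float(np.abs(v).sum()),
    )


def run_fva(
    model: MetabolicModel,
    fraction: float = 0.95,
    lb: np.ndarray | None = None,
    ub: np.ndarray | None = None,
    reactions: Iterable[str] | None = None,
) -> FluxEnvelope:
    """Per-reaction flux ranges at biomass >= ``fraction`` x optimum."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    mlb, mub = model.bounds_arrays()
    lb = mlb if lb is None else lb
    ub = mub if ub is None else ub
    fba = run_fba(model, lb, ub)
    S = model.stoichiometric_matrix()
    c = model.objective_vector()
    b_eq = np.zeros(S.shape[0])
    # biomass >= fraction * optimum, expressed as -c.v <= -fraction*opt
    A_ub = -c[np.newaxis, :]
    b_ub = np.array([-fraction * fba.objective_value])
    bounds = np.column_stack([lb, ub])

    ids = list(reactions) if reactions is not None else model.reaction_ids
    ranges: dict[str, tuple[float, float]] = {}
    obj = np.zeros(len(model.reactions))
    for rxn_id in ids:
        j = model.index(rxn_id)
        obj[j] = 1.0
        lo_res = _solve(obj, S, b_eq, bounds, A_ub, b_ub)
        hi_res = _solve(-obj, S, b_eq, bounds, A_ub, b_ub)
        obj[j] = 0.0
        lo = -math.inf if lo_res.status == 3 else float(lo_res.x[j])
        hi = math.inf if hi_res.status == 3 else float(hi_res.x[j])
        if lo_res.status not in (0, 3) or hi_res.status not in (0, 3):
            _raise_lp_failure(max(lo_res.status, hi_res.status), model)
        # snap solver noise to exact zero and keep lo <= hi
        if abs(lo) < FEASIBILITY_TOL * 10:
            lo = 0.0
        if abs(hi) < FEASIBILITY_TOL * 10:
            hi = 0.0
        if lo > hi:
            lo, hi = hi, lo
        ranges[rxn_id] = (lo, hi)
    return FluxEnvelope(ranges=ranges, fraction=fraction)


def compute_biomass_coupling(
    model: MetabolicModel,
    fraction: float = 0.95,
    tolerance: float = COMPARISON_TOL,
) -> set[str]:
    """Reactions that must carry flux to sustain near-optimal biomass.

    A reaction is coupled when the minimum of |v_j| over the feasible set
    restricted to biomass >= fraction * optimum exceeds ``tolerance``.
    """
    envelope = run_fva(model, fraction)
    coupled: set[str] = set()
    for rxn_id, (lo, hi) in envelope.ranges.items():
        min_abs = 0.0 if lo <= 0.0 <= hi else min(abs(lo), abs(hi))
        if min_abs > tolerance:
            coupled.add(rxn_id)
    return coupled


# ---------------------------------------------------------------------------
# serialisation (delegated to cobra)
# ---------------------------------------------------------------------------


def _to_cobra(model: MetabolicModel):
    import cobra

    cm = cobra.Model(model.name)
    mets = {
        m.id: cobra.Metabolite(m.id, compartment=m.compartment)
        for m in model.metabolites
    }
    for rxn in model.reactions:
        cr = cobra.Reaction(rxn.id)
        cr.lower_bound = rxn.lower_bound
        cr.upper_bound = rxn.upper_bound
        cm.add_reactions([cr])
        cr.add_metabolites(
            {mets[met]: coef for met, coef in rxn.stoichiometry.items()}
        )
    cm.objective = model.objective_id
    return cm


def _from_cobra(cm, name: str | None = None) -> MetabolicModel:
    from cobra.util.solver import linear_reaction_coefficients

    coeffs = linear_reaction_coefficients(cm)
    if not coeffs:
        raise ValidationError(
            f"model {cm.id!r} declares no objective reaction"
        )
    if len(coeffs) > 1:
        raise ValidationError(
            f"model {cm.id!r} declares multiple objective reactions: "
            f"{sorted(r.id for r in coeffs)}"
        )
    objective_id = next(iter(coeffs)).id
    metabolites = [
        Metabolite(m.id, m.compartment or "c") for m in cm.metabolites
    ]
    reactions = []
    for cr in cm.reactions:
        reactions.append(
            Reaction(
                id=cr.id,
                stoichiometry={m.id: coef for m, coef in cr.metabolites.items()},
                lower_bound=float(cr.lower_bound),
                upper_bound=float(cr.upper_bound),
            )
        )
    return MetabolicModel(
        reactions, metabolites, objective_id, name=name or cm.id or "model"
    )


def load_model(path: str | Path, dialect: str = "json") -> MetabolicModel:
    """Read a model from SBML (level 3 + FBC) or COBRA-style JSON."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"model file not found: {path}")
    if dialect not in ("json", "sbml"):
        raise ValueError(f"unknown dialect {dialect!r}")
    import cobra.io

    if dialect == "json":
        # pre-scan so inverted bounds are reported with the reaction id
        # (cobra rejects them without naming the offending element)
        try:
            raw = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"could not parse {path} as json: {exc}") from exc
        for rxn in raw.get("reactions", []):
            lo = rxn.get("lower_bound", 0.0)
            hi = rxn.get("upper_bound", 0.0)
            if lo > hi:
                raise ValidationError(
                    f"reaction {rxn.get('id')!r}: lower bound {lo} exceeds "
                    f"upper bound {hi}"
                )
    try:
        if dialect == "json":
            cm = cobra.io.load_json_model(str(path))
        else:
            cm = cobra.io.read_sbml_model(str(path))
    except ValidationError:
        raise
    except ValueError as exc:
        raise ValidationError(f"invalid model in {path}: {exc}") from exc
    except Exception as exc:  # parse errors from json/libsbml
        raise FormatError(f"could not parse {path} as {dialect}: {exc}") from exc
    return _from_cobra(cm, name=path.stem)


def write_model(
    model: MetabolicModel, path: str | Path, dialect: str = "json"
) -> Path:
    """Serialise a model; round-trips losslessly through :func:`load_model`."""
    path = Path(path)
    if str(path) == "" or path.is_dir():
        raise OSError(f"invalid output path: {path!r}")
    import cobra.io

    cm = _to_cobra(model)
    if dialect == "json":
        cobra.io.save_json_model(cm, str(path))
    elif dialect == "sbml":
        cobra.io.write_sbml_model(cm, str(path))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path
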