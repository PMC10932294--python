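"""Constraint-based metabolic modelling: FBA with expression-derived bounds.

The model is a standard stoichiometric network: metabolites with
compartment tags (``c`` cytosol, ``m`` mitochondrion, ``i`` inner
mitochondrial membrane, …), reactions with bounds and a single designated
biomass-maintenance objective. Flux balance analysis (FBA) maximizes the
objective flux subject to steady state (``S·v = 0``) and the bounds, as a
linear program; because FBA optima are generically degenerate, a second
LP minimizes total absolute flux at the fixed optimal objective so
reported flux vectors are reproducible across solvers.

The disease condition is modelled by re-bounding reactions with measured
protein fold changes anchored at the optimized solution
(:func:`apply_fold_change_constraints`) and re-solving the same
objective; :func:`compare_fluxes` and :func:`metabolite_production` then
quantify per-reaction flux shifts and per-metabolite production changes
(e.g. inner-membrane proton output as a proxy for electron-transport
-chain pumping).

Two on-disk dialects are supported: BiGG-schema JSON and a minimal
one-reaction-per-line TSV (id, equation with compartment-suffixed
metabolites, bounds, regulating proteins).
"""

from __future__ import annotations

import copy
import json
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linprog

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "FluxSolution",
    "FluxComparison",
    "ProductionChange",
    "ModelFormatError",
    "read_model",
    "write_model",
    "fba_optimize",
    "apply_fold_change_constraints",
    "compare_fluxes",
    "metabolite_production",
    "production_change",
]

FEASIBILITY_TOL = 1e-9
COMPARISON_TOL = 1e-8


class ModelFormatError(ValueError):
    """Malformed model file or inconsistent model record."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float
    upper_bound: float
    gpr: str = ""  # boolean AND/OR rule over protein ids; "" = unregulated

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def proteins(self) -> set[str]:
        return set(re.findall(r"[\w.\-]+", self.gpr)) - {"and", "or", "AND", "OR"}


@dataclass
class MetabolicModel:
    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]
    objective: str

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.objective not in self.reactions:
            raise ModelFormatError(f"objective reaction {self.objective!r} not in model")
        for rxn in self.reactions.values():
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelFormatError(
                    f"reaction {rxn.id!r}: lower bound {rxn.lower_bound} exceeds "
                    f"upper bound {rxn.upper_bound}"
                )
            for met in rxn.stoichiometry:
                if met not in self.metabolites:
                    raise ModelFormatError(
                        f"reaction {rxn.id!r} references undeclared metabolite {met!r}"
                    )

    # -- structure --------------------------------------------------------
    @property
    def reaction_ids(self) -> list[str]:
        return list(self.reactions)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.metabolites)

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S (metabolites × reactions)."""
        met_index = {m: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions.values()):
            for met, coeff in rxn.stoichiometry.items():
                S[met_index[met], j] = coeff
        return S

    def regulation_map(self) -> dict[str, set[str]]:
        """protein id → ids of reactions whose GPR mentions it."""
        out: dict[str, set[str]] = {}
        for rxn in self.reactions.values():
            for prot in rxn.proteins():
                out.setdefault(prot, set()).add(rxn.id)
        return out

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)


@dataclass
class FluxSolution:
    fluxes: pd.Series  # indexed by reaction id
    objective_value: float
    status: str  # optimal | infeasible | unbounded

    def steady_state_residual(self, model: MetabolicModel) -> float:
        v = self.fluxes.loc[model.reaction_ids].to_numpy()
        return float(np.abs(model.stoichiometric_matrix() @ v).max())


@dataclass
class ProductionChange:
    metabolite: str
    optimized: float
    dysregulated: float
    percent: float  # NaN when undefined (no baseline production)

    @property
    def percent_truncated(self) -> int | None:
        return None if math.isnan(self.percent) else math.trunc(self.percent)


@dataclass
class FluxComparison:
    reactions: pd.DataFrame  # optimized, dysregulated, abs_change, rel_change
    metabolites: pd.DataFrame  # production/consumption totals in both conditions
    objective_optimized: float = field(default=np.nan)
    objective_dysregulated: float = field(default=np.nan)


# ---------------------------------------------------------------------------
# model I/O
# ---------------------------------------------------------------------------

_ARROWS = ("<=>", "<->", "⇌", "-->", "->")


def _parse_side(text: str, sign: float, stoich: dict[str, float]) -> None:
    text = text.strip()
    if not text:
        return
    for term in text.split("+"):
        term = term.strip()
        if not term:
            continue
        m = re.match(r"^(?:(\d+(?:\.\d+)?)\s+)?([\w\-]+)$", term)
        if m is None:
            raise ModelFormatError(f"cannot parse equation term {term!r}")
        coeff = float(m.group(1)) if m.group(1) else 1.0
        met = m.group(2)
        stoich[met] = stoich.get(met, 0.0) + sign * coeff


def parse_equation(equation: str) -> tuple[dict[str, float], bool]:
    """Parse ``"a_c + 2 b_m -> c_c"`` into a stoichiometry map.

    Returns the map and whether the arrow was reversible. An empty side
    denotes exchange with the environment.
    """
    for arrow in _ARROWS:
        if arrow in equation:
            left, right = equation.split(arrow, 1)
            reversible = arrow in ("<=>", "<->", "⇌")
            stoich: dict[str, float] = {}
            _parse_side(left, -1.0, stoich)
            _parse_side(right, +1.0, stoich)
            return stoich, reversible
    raise ModelFormatError(f"no reaction arrow in equation {equation!r}")


def format_equation(stoich: dict[str, float], reversible: bool) -> str:
    def side(items):
        return " + ".join(
            (f"{abs(c):g} {m}" if abs(c) != 1 else m) for m, c in items
        )

    left = [(m, c) for m, c in stoich.items() if c < 0]
    right = [(m, c) for m, c in stoich.items() if c > 0]
    arrow = "<=>" if reversible else "->"
    return f"{side(left)} {arrow} {side(right)}".strip()


def _compartment_of(met_id: str) -> str:
    m = re.search(r"_([a-z])$", met_id)
    return m.group(1) if m else "c"


def read_model(path: str | Path) -> MetabolicModel:
    """Read a model from BiGG-schema JSON (``.json``) or native TSV."""
    path = Path(path)
    if path.suffix == ".json":
        return _read_json(path)
    return _read_tsv(path)


def _read_json(path: Path) -> MetabolicModel:
    data = json.loads(path.read_text())
    mets = {
        m["id"]: Metabolite(m["id"], m.get("compartment") or _compartment_of(m["id"]))
        for m in data["metabolites"]
    }
    rxns: dict[str, Reaction] = {}
    objective = None
    for r in data["reactions"]:
        if "lower_bound" not in r or "upper_bound" not in r:
            raise ModelFormatError(f"reaction {r.get('id')!r} is missing bounds")
        rxns[r["id"]] = Reaction(
            id=r["id"],
            stoichiometry={k: float(v) for k, v in r["metabolites"].items()},
            lower_bound=float(r["lower_bound"]),
            upper_bound=float(r["upper_bound"]),
            gpr=r.get("gene_reaction_rule", ""),
        )
        if r.get("objective_coefficient", 0):
            objective = r["id"]
    if objective is None:
        raise ModelFormatError(f"{path.name}: no reaction has a nonzero objective coefficient")
    return MetabolicModel(mets, rxns, objective)


def _read_tsv(path: Path) -> MetabolicModel:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"reaction", "equation", "lower_bound", "upper_bound"}
    if not required <= set(df.columns):
        raise ModelFormatError(f"{path.name}: missing columns {required - set(df.columns)}")
    mets: dict[str, Metabolite] = {}
    rxns: dict[str, Reaction] = {}
    objective = None
    for _, row in df.iterrows():
        stoich, reversible = parse_equation(row["equation"])
        for met in stoich:
            mets.setdefault(met, Metabolite(met, _compartment_of(met)))
        rxns[row["reaction"]] = Reaction(
            id=row["reaction"],
            stoichiometry=stoich,
            lower_bound=float(row["lower_bound"]),
            upper_bound=float(row["upper_bound"]),
            gpr="" if pd.isna(row.get("proteins")) else str(row.get("proteins", "")),
        )
        if str(row.get("objective", "")).strip() in {"1", "1.0", "True", "true"}:
            objective = row["reaction"]
    if objective is None:
        raise ModelFormatError(f"{path.name}: no reaction marked as objective")
    return MetabolicModel(mets, rxns, objective)


def write_model(model: MetabolicModel, path: str | Path) -> None:
    """Write a model as native TSV (``.tsv``) or BiGG-schema JSON (``.json``)."""
    path = Path(path)
    if path.suffix == ".json":
        data = {
            "metabolites": [
                {"id": m.id, "compartment": m.compartment}
                for m in model.metabolites.values()
            ],
            "reactions": [
                {
                    "id": r.id,
                    "metabolites": r.stoichiometry,
                    "lower_bound": r.lower_bound,
                    "upper_bound": r.upper_bound,
                    "gene_reaction_rule": r.gpr,
                    "objective_coefficient": 1.0 if r.id == model.objective else 0.0,
                }
                for r in model.reactions.values()
            ],
            "genes": [
                {"id": g} for g in sorted(model.regulation_map())
            ],
            "id": "blastpte_model",
        }
        path.write_text(json.dumps(data, indent=1))
        return
    rows = [
        {
            "reaction": r.id,
            "equation": format_equation(r.stoichiometry, r.reversible),
            "lower_bound": r.lower_bound,
            "upper_bound": r.upper_bound,
            "proteins": r.gpr,
            "objective": 1 if r.id == model.objective else 0,
        }
        for r in model.reactions.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def fba_optimize(model: MetabolicModel, parsimonious: bool = True) -> FluxSolution:
    """Maximize the objective flux subject to S·v = 0 and the bounds.

    With ``parsimonious=True`` (default) a second LP minimizes Σ|v| at
    the fixed optimal objective, which selects a unique representative
    among degenerate optima; the primary objective value is preserved to
    within 1e-8 by construction.
    """
    rids = model.reaction_ids
    n = len(rids)
    S = model.stoichiometric_matrix()
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions.values()]
    c = np.zeros(n)
    c[rids.index(model.objective)] = -1.0

    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        return FluxSolution(pd.Series(dtype=float), np.nan, status)
    objective = -res.fun
    v = res.x

    if parsimonious:
        # minimize sum t, with t_j >= |v_j|, S v = 0, v_obj fixed at optimum
        c2 = np.concatenate([np.zeros(n), np.ones(n)])
        A_eq = np.hstack([S, np.zeros_like(S)])
        obj_row = np.zeros(2 * n)
        obj_row[rids.index(model.objective)] = 1.0
        A_eq = np.vstack([A_eq, obj_row])
        b_eq = np.concatenate([np.zeros(S.shape[0]), [objective]])
        I = np.eye(n)
        A_ub = np.vstack([np.hstack([I, -I]), np.hstack([-I, -I])])
        b_ub = np.zeros(2 * n)
        bounds2 = bounds + [(0, None)] * n
        res2 = linprog(
            c2, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds2, method="highs"
        )
        if res2.status == 0:
            v = res2.x[:n]

    fluxes = pd.Series(v, index=rids)
    return FluxSolution(fluxes, float(fluxes[model.objective]), "optimal")


# ---------------------------------------------------------------------------
# fold-change constraints
# ---------------------------------------------------------------------------


def _eval_gpr(tokens: list[str], fcs: dict[str, float], policy: str) -> float | None:
    """Evaluate a boolean GPR over available fold changes.

    AND → min of member values, OR → max (standard gene–reaction
    convention); proteins without a measurement are skipped. ``policy``
    applies when a rule-less reaction is hit by several proteins:
    ``"geometric_mean"`` (default), ``"and"`` (min) or ``"or"`` (max).
    """

    def parse_or(pos: int) -> tuple[float | None, int]:
        val, pos = parse_and(pos)
        while pos < len(tokens) and tokens[pos].lower() == "or":
            rhs, pos = parse_and(pos + 1)
            vals = [x for x in (val, rhs) if x is not None]
            val = max(vals) if vals else None
        return val, pos

    def parse_and(pos: int) -> tuple[float | None, int]:
        val, pos = parse_atom(pos)
        while pos < len(tokens) and tokens[pos].lower() == "and":
            rhs, pos = parse_atom(pos + 1)
            vals = [x for x in (val, rhs) if x is not None]
            val = min(vals) if vals else None
        return val, pos

    def parse_atom(pos: int) -> tuple[float | None, int]:
        tok = tokens[pos]
        if tok == "(":
            val, pos = parse_or(pos + 1)
            return val, pos + 1  # skip ')'
        return fcs.get(tok), pos + 1

    if not any(t.lower() in ("and", "or") for t in tokens):
        vals = [fcs[t] for t in tokens if t in fcs]
        if not vals:
            return None
        if policy == "and":
            return min(vals)
        if policy == "or":
            return max(vals)
        return float(np.exp(np.mean(np.log(vals))))
    val, _ = parse_or(0)
    return val


def combined_fold_change(
    rxn: Reaction, fold_changes: dict[str, float], policy: str = "geometric_mean"
) -> float | None:
    """Combined linear fold change acting on a reaction, or None if unmeasured."""
    tokens = re.findall(r"\(|\)|[\w.\-]+", rxn.gpr)
    if not tokens:
        return None
    return _eval_gpr(tokens, fold_changes, policy)


def apply_fold_change_constraints(
    model: MetabolicModel,
    baseline: FluxSolution,
    fold_changes: dict[str, float],
    combine: str = "geometric_mean",
    flux_tol: float = COMPARISON_TOL,
) -> MetabolicModel:
    """Re-bound regulated reactions by protein fold changes.

    For a reaction with combined fold change *f* and baseline flux *v**:
    if *v** > 0 the upper bound becomes *f·v** (and the lower bound drops
    to 0 if it would exceed the new upper bound); if *v** < 0 the lower
    bound becomes *f·v** (mirrored guard on the upper bound); a reaction
    idle at baseline keeps its bounds. Unregulated and unmeasured
    reactions are untouched.
    """
    bad = {p: f for p, f in fold_changes.items() if f <= 0}
    if bad:
        raise ValueError(f"fold changes must be positive linear ratios, got {bad}")
    regulated = model.regulation_map()
    orphans = [p for p in fold_changes if p not in regulated]
    if orphans:
        warnings.warn(f"{len(orphans)} measured proteins map to no reaction: {orphans[:5]}")

    out = model.copy()
    for rxn in out.reactions.values():
        f = combined_fold_change(rxn, fold_changes, combine)
        if f is None:
            continue
        v = float(baseline.fluxes.get(rxn.id, 0.0))
        if v > flux_tol:
            rxn.upper_bound = f * v
            if rxn.lower_bound > rxn.upper_bound:
                rxn.lower_bound = 0.0
        elif v < -flux_tol:
            rxn.lower_bound = f * v
            if rxn.upper_bound < rxn.lower_bound:
                rxn.upper_bound = 0.0
    out.validate()
    return out


# ---------------------------------------------------------------------------
# comparison & production
# ---------------------------------------------------------------------------


def metabolite_production(
    model: MetabolicModel,
    solution: FluxSolution,
    metabolite: str,
    direction: str = "production",
) -> float:
    """Total production (or consumption) flux of one metabolite.

    Production sums ``max(0, coefficient × flux)`` over reactions;
    consumption sums the negative parts analogously.
    """
    if metabolite not in model.metabolites:
        raise KeyError(f"unknown metabolite {metabolite!r}")
    total = 0.0
    for rxn in model.reactions.values():
        coeff = rxn.stoichiometry.get(metabolite)
        if coeff is None:
            continue
        rate = coeff * float(solution.fluxes.get(rxn.id, 0.0))
        if direction == "production":
            total += max(0.0, rate)
        else:
            total += max(0.0, -rate)
    return total


def production_change(
    model: MetabolicModel,
    optimized: FluxSolution,
    dysregulated: FluxSolution,
    metabolite: str,
) -> ProductionChange:
    """Percent reduction in a metabolite's production between conditions.

    ``100 × (1 − dysregulated/optimized)``; undefined (NaN percent) when
    the optimized condition produces none of the metabolite.
    """
    opt = metabolite_production(model, optimized, metabolite)
    dys = metabolite_production(model, dysregulated, metabolite)
    pct = float("nan") if opt <= 0 else 100.0 * (1.0 - dys / opt)
    return ProductionChange(metabolite, opt, dys, pct)


def compare_fluxes(
    model: MetabolicModel,
    optimized: FluxSolution,
    dysregulated: FluxSolution,
) -> FluxComparison:
    """Per-reaction flux deltas and per-metabolite production totals.

    Relative change is reported as NaN where the optimized flux is zero.
    """
    rids = model.reaction_ids
    if set(optimized.fluxes.index) != set(rids) or set(dysregulated.fluxes.index) != set(rids):
        raise ValueError("solutions must cover exactly the model's reaction set")
    opt = optimized.fluxes.loc[rids].astype(float)
    dys = dysregulated.fluxes.loc[rids].astype(float)
    abs_change = dys - opt
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(np.abs(opt) > COMPARISON_TOL, abs_change / opt, np.nan)
    reactions = pd.DataFrame(
        {
            "optimized": opt,
            "dysregulated": dys,
            "abs_change": abs_change,
            "rel_change": rel,
        },
        index=rids,
    )
    met_rows = {}
    for met in model.metabolite_ids:
        met_rows[met] = {
            "production_optimized": metabolite_production(model, optimized, met),
            "production_dysregulated": metabolite_production(model, dysregulated, met),
            "consumption_optimized": metabolite_production(model, optimized, met, "consumption"),
            "consumption_dysregulated": metabolite_production(
                model, dysregulated, met, "consumption"
            ),
        }
    metabolites = pd.DataFrame(met_rows).T
    return FluxComparison(
        reactions,
        metabolites,
        objective_optimized=optimized.objective_value,
        objective_dysregulated=dysregulated.objective_value,
    )
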