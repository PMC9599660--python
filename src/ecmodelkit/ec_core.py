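"""The enzyme-constrained linear program.

Flux balance analysis maximizes a linear objective ``Z = c^T v`` over the
steady-state polytope ``S v = 0``, ``lb <= v <= ub``.  The enzyme
constraint adds one aggregate row on top of the stoichiometric ones:

    sum_i  v_i * MW_i / (sigma_i * kcat_i)  <=  Ptotal * f

where ``MW_i`` is the catalyzing enzyme's complex weight (kDa), ``kcat_i``
its turnover (1/h), ``sigma_i`` the average in-vivo saturation, ``Ptotal``
the cell's protein content (g/gDCW, default 0.56) and ``f`` the mass
fraction of that protein covered by model enzymes.  No pseudo-metabolites
or pseudo-reactions are introduced; the stoichiometric matrix is left
untouched and the pool is a single extra inequality.

All programs are solved with the HiGHS simplex solver through
``scipy.optimize.linprog`` at 1e-9 feasibility/optimality tolerances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .errors import EcModelKitError, SolverError
from .enzyme_params import EnzymeEntry
from .gem_io import ModelDocument

FEASIBILITY_TOL = 1e-9

DEFAULT_PTOTAL = 0.56  # g protein / gDCW, typical microbial protein content


@dataclass
class ECModel:
    """A fully split model plus the single enzyme-pool constraint."""

    base: ModelDocument
    enzymes: list[EnzymeEntry]
    ptotal: float = DEFAULT_PTOTAL
    f: float = 1.0

    def __post_init__(self):
        rxn_ids = self.base.reaction_ids()
        for e in self.enzymes:
            if e.reaction_id not in rxn_ids:
                raise EcModelKitError(f"enzyme entry references unknown reaction {e.reaction_id!r}")
        if not (0 < self.f <= 1):
            raise EcModelKitError(f"f must be in (0, 1], got {self.f}")
        if self.pool_bound <= 0:
            raise EcModelKitError("pool bound must be positive")

    @property
    def pool_bound(self) -> float:
        return self.ptotal * self.f

    def pool_coefficients(self) -> dict[str, float]:
        return {e.reaction_id: e.pool_coefficient for e in self.enzymes}

    def copy(self) -> "ECModel":
        return ECModel(self.base.copy(), list(self.enzymes), self.ptotal, self.f)


def build_ec_model(
    model_split: ModelDocument,
    enzyme_table: list[EnzymeEntry],
    f: float,
    ptotal: float = DEFAULT_PTOTAL,
) -> ECModel:
    return ECModel(base=model_split, enzymes=list(enzyme_table), ptotal=ptotal, f=f)


@dataclass
class FluxSolution:
    status: str  # "optimal" | "infeasible" | "unbounded" | "failed"
    objective_value: float
    fluxes: dict[str, float] = field(default_factory=dict)
    enzyme_usage: float = 0.0

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]


# ---------------------------------------------------------------------------
# LP assembly
# ---------------------------------------------------------------------------


def _doc_of(model) -> ModelDocument:
    return model.base if isinstance(model, ECModel) else model


def _pool_row(model, rxn_index: dict[str, int], n: int):
    if not isinstance(model, ECModel) or not model.enzymes:
        return None, None
    row = np.zeros(n)
    for e in model.enzymes:
        row[rxn_index[e.reaction_id]] += e.pool_coefficient
    return row, model.pool_bound


def _solve(
    model,
    objective: dict[str, float],
    direction: str = "max",
    bound_overrides: dict[str, tuple[float, float]] | None = None,
    extra_ub: list[tuple[np.ndarray, float]] | None = None,
    extra_eq: list[tuple[np.ndarray, float]] | None = None,
    minimize_vector: np.ndarray | None = None,
    include_pool: bool = True,
) -> tuple[FluxSolution, np.ndarray | None, dict[str, int]]:
    doc = _doc_of(model)
    rxns = doc.reactions
    n = len(rxns)
    idx = {r.id: i for i, r in enumerate(rxns)}
    met_idx = {m.id: i for i, m in enumerate(doc.metabolites)}

    rows, cols, vals = [], [], []
    for j, r in enumerate(rxns):
        for m, coeff in r.stoichiometry.items():
            rows.append(met_idx[m])
            cols.append(j)
            vals.append(coeff)
    S = sparse.csr_matrix((vals, (rows, cols)), shape=(len(met_idx), n))

    lb = np.array([r.lower_bound for r in rxns], dtype=float)
    ub = np.array([r.upper_bound for r in rxns], dtype=float)
    if bound_overrides:
        for rid, (lo, hi) in bound_overrides.items():
            if rid not in idx:
                raise EcModelKitError(f"bound override on unknown reaction {rid!r}")
            lb[idx[rid]], ub[idx[rid]] = lo, hi

    if minimize_vector is not None:
        c = minimize_vector.copy()
        sense = 1.0
    else:
        c = np.zeros(n)
        for rid, coeff in objective.items():
            if rid not in idx:
                raise EcModelKitError(f"objective references unknown reaction {rid!r}")
            c[idx[rid]] = coeff
        sense = -1.0 if direction == "max" else 1.0

    A_ub_rows, b_ub = [], []
    pool_row, pool_bound = (_pool_row(model, idx, n) if include_pool else (None, None))
    if pool_row is not None:
        A_ub_rows.append(pool_row)
        b_ub.append(pool_bound)
    if extra_ub:
        for row, rhs in extra_ub:
            A_ub_rows.append(row)
            b_ub.append(rhs)

    A_eq_rows = [S]
    b_eq = [np.zeros(S.shape[0])]
    if extra_eq:
        for row, rhs in extra_eq:
            A_eq_rows.append(sparse.csr_matrix(row.reshape(1, -1)))
            b_eq.append(np.array([rhs]))
    A_eq = sparse.vstack(A_eq_rows, format="csr")
    b_eq_v = np.concatenate(b_eq)

    res = linprog(
        sense * c,
        A_ub=np.vstack(A_ub_rows) if A_ub_rows else None,
        b_ub=np.array(b_ub) if A_ub_rows else None,
        A_eq=A_eq,
        b_eq=b_eq_v,
        bounds=list(zip(lb, ub)),
        method="highs",
        options={
            "presolve": True,
            "primal_feasibility_tolerance": FEASIBILITY_TOL,
            "dual_feasibility_tolerance": FEASIBILITY_TOL,
        },
    )
    if res.status == 2:
        return FluxSolution("infeasible", math.nan), None, idx
    if res.status == 3:
        return FluxSolution("unbounded", math.inf), None, idx
    if not res.success:
        raise SolverError(f"LP solver failed: {res.message}")
    v = res.x
    fluxes = {r.id: float(v[idx[r.id]]) for r in rxns}
    usage = 0.0
    if isinstance(model, ECModel):
        usage = float(sum(e.pool_coefficient * fluxes[e.reaction_id] for e in model.enzymes))
    obj_val = float(sum(coeff * fluxes[rid] for rid, coeff in objective.items())) if objective else float(sense * res.fun)
    return FluxSolution("optimal", obj_val, fluxes, usage), v, idx


# ---------------------------------------------------------------------------
# public solves
# ---------------------------------------------------------------------------


def fba(
    model,
    objective: dict[str, float] | None = None,
    direction: str = "max",
    bound_overrides: dict[str, tuple[float, float]] | None = None,
) -> FluxSolution:
    """Flux balance analysis on a :class:`ModelDocument` or :class:`ECModel`.

    ``objective`` defaults to the model's own objective.  Infeasible or
    unbounded programs are reported in ``status``, never as silent zeros.
    """
    doc = _doc_of(model)
    obj = doc.objective if objective is None else objective
    if not obj:
        raise EcModelKitError("no objective given and model has none")
    sol, _, _ = _solve(model, obj, direction, bound_overrides)
    return sol


def pfba(
    model,
    objective: dict[str, float] | None = None,
    bound_overrides: dict[str, tuple[float, float]] | None = None,
    fraction_of_optimum: float = 1.0,
) -> FluxSolution:
    """Parsimonious FBA: fix the primary objective at its optimum, then
    minimize total flux.

    Two-stage LP.  Stage one maximizes the objective; stage two constrains
    ``c^T v`` to at least ``fraction_of_optimum`` of that optimum (with a
    1e-6-relative numeric slack) and minimizes the sum of absolute fluxes.
    On a fully split model all enzymatic fluxes are nonnegative, so only
    exchange reactions need absolute-value handling; those get auxiliary
    variables internally.
    """
    doc = _doc_of(model)
    obj = doc.objective if objective is None else objective
    first = fba(model, obj, "max", bound_overrides)
    if first.status != "optimal":
        return first

    rxns = doc.reactions
    n = len(rxns)
    idx = {r.id: i for i, r in enumerate(rxns)}
    c_primary = np.zeros(n)
    for rid, coeff in obj.items():
        c_primary[idx[rid]] = coeff
    floor = fraction_of_optimum * first.objective_value
    floor -= 1e-9 * max(1.0, abs(floor))
    # c^T v >= floor  <=>  -c^T v <= -floor
    extra_ub = [(-c_primary, -floor)]

    lb = np.array([r.lower_bound for r in rxns], dtype=float)
    if bound_overrides:
        for rid, (lo, _) in bound_overrides.items():
            lb[idx[rid]] = lo
    neg_idx = [i for i in range(n) if lb[i] < 0]

    if not neg_idx:
        sol, _, _ = _solve(model, obj, bound_overrides=bound_overrides,
                           extra_ub=extra_ub, minimize_vector=np.ones(n))
        return sol

    # Auxiliary t_i >= |v_i| for variables that can run negative; solved on
    # an augmented LP assembled here rather than in _solve to keep the
    # common path simple.
    sol = _pfba_with_abs(model, obj, bound_overrides, extra_ub, neg_idx)
    return sol


def _pfba_with_abs(model, obj, bound_overrides, extra_ub, neg_idx):
    doc = _doc_of(model)
    rxns = doc.reactions
    n = len(rxns)
    k = len(neg_idx)
    idx = {r.id: i for i, r in enumerate(rxns)}
    met_idx = {m.id: i for i, m in enumerate(doc.metabolites)}

    rows, cols, vals = [], [], []
    for j, r in enumerate(rxns):
        for m, coeff in r.stoichiometry.items():
            rows.append(met_idx[m]); cols.append(j); vals.append(coeff)
    S = sparse.csr_matrix((vals, (rows, cols)), shape=(len(met_idx), n + k))

    lb = np.array([r.lower_bound for r in rxns], dtype=float)
    ub = np.array([r.upper_bound for r in rxns], dtype=float)
    if bound_overrides:
        for rid, (lo, hi) in bound_overrides.items():
            lb[idx[rid]], ub[idx[rid]] = lo, hi
    bounds = list(zip(lb, ub)) + [(0.0, None)] * k

    c = np.zeros(n + k)
    for i in range(n):
        c[i] = 0.0 if i in set(neg_idx) else 1.0
    c[n:] = 1.0

    A_ub_rows, b_ub = [], []
    pool_row, pool_bound = _pool_row(model, idx, n)
    if pool_row is not None:
        A_ub_rows.append(np.concatenate([pool_row, np.zeros(k)]))
        b_ub.append(pool_bound)
    for row, rhs in extra_ub:
        A_ub_rows.append(np.concatenate([row, np.zeros(k)]))
        b_ub.append(rhs)
    for a, i in enumerate(neg_idx):
        r1 = np.zeros(n + k); r1[i] = 1.0; r1[n + a] = -1.0   # v - t <= 0
        r2 = np.zeros(n + k); r2[i] = -1.0; r2[n + a] = -1.0  # -v - t <= 0
        A_ub_rows.extend([r1, r2]); b_ub.extend([0.0, 0.0])

    res = linprog(
        c, A_ub=np.vstack(A_ub_rows), b_ub=np.array(b_ub),
        A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs",
        options={"primal_feasibility_tolerance": FEASIBILITY_TOL,
                 "dual_feasibility_tolerance": FEASIBILITY_TOL},
    )
    if res.status == 2:
        return FluxSolution("infeasible", math.nan)
    if not res.success:
        raise SolverError(f"pFBA stage-two LP failed: {res.message}")
    v = res.x[:n]
    fluxes = {r.id: float(v[i]) for r, i in zip(rxns, range(n))}
    usage = 0.0
    if isinstance(model, ECModel):
        usage = float(sum(e.pool_coefficient * fluxes[e.reaction_id] for e in model.enzymes))
    obj_val = float(sum(coeff * fluxes[rid] for rid, coeff in obj.items()))
    return FluxSolution("optimal", obj_val, fluxes, usage)


def min_enzyme(
    model: ECModel,
    fixed_fluxes: dict[str, float] | None = None,
    bound_overrides: dict[str, tuple[float, float]] | None = None,
) -> FluxSolution:
    """Minimum total enzyme mass (Emin, g/gDCW) supporting a flux state.

    Minimizes ``sum_i v_i MW_i / (sigma_i kcat_i)`` subject to steady
    state, bounds, the pool bound, and any fixed fluxes.  The objective
    value and ``enzyme_usage`` coincide.
    """
    if not isinstance(model, ECModel):
        raise EcModelKitError("min_enzyme requires an ECModel")
    overrides = dict(bound_overrides or {})
    for rid, val in (fixed_fluxes or {}).items():
        overrides[rid] = (val, val)
    doc = model.base
    n = len(doc.reactions)
    idx = {r.id: i for i, r in enumerate(doc.reactions)}
    cvec = np.zeros(n)
    for e in model.enzymes:
        cvec[idx[e.reaction_id]] += e.pool_coefficient
    sol, _, _ = _solve(model, {}, bound_overrides=overrides, minimize_vector=cvec)
    if sol.status == "infeasible":
        raise EcModelKitError("min_enzyme: fixed fluxes are infeasible")
    sol.objective_value = sol.enzyme_usage
    return sol


def flux_range(
    model,
    reaction_id: str,
    bound_overrides: dict[str, tuple[float, float]] | None = None,
) -> tuple[float, float]:
    """[min, max] flux of one reaction under the current constraints."""
    lo = fba(model, {reaction_id: 1.0}, "min", bound_overrides)
    hi = fba(model, {reaction_id: 1.0}, "max", bound_overrides)
    if lo.status != "optimal" or hi.status != "optimal":
        raise SolverError(f"FVA subproblem for {reaction_id} not optimal: {lo.status}/{hi.status}")
    return lo.objective_value, hi.objective_value


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_ec_model(model: ECModel, path) -> None:
    """Single bundled JSON: base model + enzyme table + pool header."""
    import json

    from .gem_io import model_to_json_dict

    doc = {
        "model": model_to_json_dict(model.base),
        "enzymes": [
            {
                "reaction_id": e.reaction_id,
                "genes": e.genes,
                "mw_kda": e.mw_kda,
                "kcat_per_h": e.kcat_per_h,
                "sigma": e.sigma,
                "kcat_source": e.kcat_source,
                "flags": list(e.flags),
            }
            for e in model.enzymes
        ],
        "ptotal": model.ptotal,
        "f": model.f,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_ec_model(path) -> ECModel:
    import json

    from .gem_io import _model_from_json_dict

    with open(path) as fh:
        doc = json.load(fh)
    enzymes = [
        EnzymeEntry(
            reaction_id=e["reaction_id"],
            genes={g: int(n) for g, n in e["genes"].items()},
            mw_kda=float(e["mw_kda"]),
            kcat_per_h=float(e["kcat_per_h"]),
            sigma=float(e["sigma"]),
            kcat_source=e.get("kcat_source", ""),
            flags=tuple(e.get("flags", [])),
        )
        for e in doc["enzymes"]
    ]
    return ECModel(
        base=_model_from_json_dict(doc["model"]),
        enzymes=enzymes,
        ptotal=float(doc["ptotal"]),
        f=float(doc["f"]),
    )
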