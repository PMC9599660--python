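"""Downstream analyses of enzyme-constrained models.

Four computations, each comparing or exploiting the proteome pool:

* **comparative FVA** — flux variability of every reaction at a fixed
  growth rate, aggregated back onto the original (pre-split) network:
  isozyme copies contribute the widest member range, and for reversible
  pairs the reverse range is subtracted from the forward range;
* **phenotype phase plane (PhPP)** — parsimonious-FBA growth over a
  glucose x oxygen uptake grid;
* **overflow scan** — growth, byproduct secretion, biomass yield and
  enzyme-usage efficiency as the substrate uptake rate rises, exposing the
  substrate-limited / switching / overflow phases;
* **enzyme-cost target discovery** — per-reaction enzyme costs under a
  high-growth-low-product (HGLP) and a low-growth-high-product (LGHP)
  scenario; reactions whose cost fold change exceeds a threshold are
  proposed as enhancement or attenuation targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import EcModelKitError
from .ec_core import ECModel, FluxSolution, fba, flux_range, min_enzyme, pfba
from .model_expansion import SplitMap, SplitOrigin

GLUCOSE_MW = 0.18016  # g/mmol

ACTIVE_FLUX_TOL = 1e-6
FULL_VARIABILITY_FRACTION = 0.999


# ---------------------------------------------------------------------------
# comparative FVA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FvaRange:
    reaction_id: str  # original, pre-split id
    member_ranges: dict[str, tuple[float, float]]
    fv: float
    review: bool = False  # reverse range exceeded forward range


@dataclass
class FvaReport:
    ranges: list[FvaRange]
    fraction_fully_variable: float
    n_active: int


def _growth_fix(model, fixed_growth: float) -> dict[str, tuple[float, float]]:
    doc = model.base if isinstance(model, ECModel) else model
    if len(doc.objective) != 1:
        raise EcModelKitError("growth fixing requires a single-reaction objective")
    (biomass_rid,) = doc.objective
    return {biomass_rid: (fixed_growth, fixed_growth)}


def _uptake_overrides(uptake_fix: dict[str, float] | None) -> dict[str, tuple[float, float]]:
    """Exchange fixes: an uptake of u mmol/gDCW/h pins the exchange flux at -u."""
    out = {}
    for rid, u in (uptake_fix or {}).items():
        out[rid] = (-abs(u), -abs(u))
    return out


def fva_at_growth(
    model,
    fixed_growth: float,
    uptake_fix: dict[str, float] | None = None,
    split_map: SplitMap | None = None,
    reference: FluxSolution | None = None,
) -> FvaReport:
    """Per-original-reaction flux variability at a fixed growth rate.

    ``split_map`` maps split members back to original reactions (identity
    when absent).  For each original reaction, forward isozyme copies are
    aggregated by the widest member range, reverse copies likewise, and
    the reported variability is forward range minus reverse range; a
    negative result is emitted verbatim with ``review=True`` rather than
    clipped.  The report also carries the fraction of active reactions
    (|v| > 1e-6 in the parsimonious reference solution) whose range spans
    at least 99.9% of the bound span.
    """
    doc = model.base if isinstance(model, ECModel) else model
    overrides = _growth_fix(model, fixed_growth)
    overrides.update(_uptake_overrides(uptake_fix))
    check = fba(model, doc.objective, "max", overrides)
    if check.status != "optimal":
        raise EcModelKitError(f"model {doc.id!r}: infeasible at growth {fixed_growth}")
    if reference is None:
        reference = pfba(model, doc.objective, bound_overrides=overrides)

    if split_map is None:
        split_map = SplitMap({r.id: SplitOrigin(r.id, "fwd") for r in doc.reactions})

    member_range: dict[str, tuple[float, float]] = {}
    for r in doc.reactions:
        member_range[r.id] = flux_range(model, r.id, overrides)

    by_original: dict[str, dict[str, list[tuple[str, tuple[float, float]]]]] = {}
    for sid, origin in split_map.origin.items():
        if sid not in member_range:
            continue
        group = by_original.setdefault(origin.original_id, {"fwd": [], "rev": []})
        group[origin.direction].append((sid, member_range[sid]))

    ranges: list[FvaRange] = []
    for oid in sorted(by_original):
        group = by_original[oid]
        fwd = max(((hi - lo) for _, (lo, hi) in group["fwd"]), default=0.0)
        rev = max(((hi - lo) for _, (lo, hi) in group["rev"]), default=0.0)
        fv = fwd - rev
        members = {sid: rng for d in ("fwd", "rev") for sid, rng in group[d]}
        ranges.append(FvaRange(oid, members, fv, review=fv < 0))

    bounds = {r.id: (r.lower_bound, r.upper_bound) for r in doc.reactions}
    n_active = 0
    n_full = 0
    for r in doc.reactions:
        if abs(reference.fluxes.get(r.id, 0.0)) <= ACTIVE_FLUX_TOL:
            continue
        n_active += 1
        lo, hi = member_range[r.id]
        blo, bhi = bounds[r.id]
        span = bhi - blo
        if span > 0 and (hi - lo) >= FULL_VARIABILITY_FRACTION * span:
            n_full += 1
    frac = (n_full / n_active) if n_active else 0.0
    return FvaReport(ranges=ranges, fraction_fully_variable=frac, n_active=n_active)


def comparative_fva(
    model_a,
    model_b,
    fixed_growth: float,
    uptake_fix: dict[str, float] | None = None,
    split_map_a: SplitMap | None = None,
    split_map_b: SplitMap | None = None,
) -> tuple[FvaReport, FvaReport]:
    """FVA of two models (e.g. base vs enzyme-constrained) at the same growth."""
    rep_a = fva_at_growth(model_a, fixed_growth, uptake_fix, split_map_a)
    rep_b = fva_at_growth(model_b, fixed_growth, uptake_fix, split_map_b)
    return rep_a, rep_b


def fva_cumulative_table(report: FvaReport):
    """Sorted variability values with cumulative fraction, for distribution plots."""
    import pandas as pd

    vals = sorted(r.fv for r in report.ranges)
    n = len(vals)
    return pd.DataFrame(
        {"fv": vals, "cumulative_fraction": [(i + 1) / n for i in range(n)]}
    )


# ---------------------------------------------------------------------------
# phenotype phase plane
# ---------------------------------------------------------------------------


@dataclass
class PhppGrid:
    glucose_axis: list[float]
    oxygen_axis: list[float]
    growth: list[list[float]]  # growth[i][j]: glucose_axis[i] x oxygen_axis[j]
    infeasible: list[tuple[int, int]] = field(default_factory=list)


def phpp(
    model,
    glucose_exchange: str,
    oxygen_exchange: str,
    glucose_grid: list[float] | None = None,
    oxygen_grid: list[float] | None = None,
) -> PhppGrid:
    """Parsimonious growth over a glucose x oxygen uptake grid (0-10 mmol/gDCW/h).

    Each grid point caps the two uptake rates (lower bound ``-u`` on the
    exchange), maximizes biomass and resolves degeneracy by pFBA.
    Infeasible points are recorded as zero growth and flagged.
    """
    doc = model.base if isinstance(model, ECModel) else model
    for rid in (glucose_exchange, oxygen_exchange):
        if rid not in doc.reaction_ids():
            raise EcModelKitError(f"missing exchange reaction {rid!r}")
    if glucose_grid is None:
        glucose_grid = [0.5 * i for i in range(21)]
    if oxygen_grid is None:
        oxygen_grid = [0.5 * i for i in range(21)]
    growth: list[list[float]] = []
    infeasible: list[tuple[int, int]] = []
    for i, g in enumerate(glucose_grid):
        row = []
        for j, o in enumerate(oxygen_grid):
            overrides = {
                glucose_exchange: (-g, 0.0),
                oxygen_exchange: (-o, 0.0),
            }
            sol = pfba(model, doc.objective, bound_overrides=overrides)
            if sol.status != "optimal":
                infeasible.append((i, j))
                row.append(0.0)
            else:
                row.append(max(0.0, sol.objective_value))
        growth.append(row)
    return PhppGrid(list(glucose_grid), list(oxygen_grid), growth, infeasible)


def phpp_table(grid: PhppGrid):
    import pandas as pd

    rows = []
    for i, g in enumerate(grid.glucose_axis):
        for j, o in enumerate(grid.oxygen_axis):
            rows.append({"glucose_uptake": g, "oxygen_uptake": o, "growth": grid.growth[i][j]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# overflow scan
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OverflowRow:
    uptake: float
    growth: float
    byproduct_fluxes: dict[str, float]
    biomass_yield: float  # gDCW per g substrate
    enzyme_usage_efficiency: float  # growth per g enzyme
    emin: float
    phase: str  # "substrate-limited" | "overflow"


def overflow_scan(
    model: ECModel,
    uptake_values: list[float],
    glucose_exchange: str,
    byproduct_exchanges: list[str],
    substrate_mw: float = GLUCOSE_MW,
) -> list[OverflowRow]:
    """Growth/yield/efficiency along increasing substrate uptake.

    Per uptake value ``u``: bound the substrate exchange at ``-u``,
    maximize biomass by pFBA, take biomass yield as
    ``v_biomass / (v_glc * MW_glc)``, compute the minimum enzyme demand
    Emin at the achieved growth, and enzyme-usage efficiency as
    ``v_biomass / Emin``.  Rows are classified into the substrate-limited
    and overflow phases by the first uptake with nonzero byproduct
    secretion.
    """
    doc = model.base
    (biomass_rid,) = doc.objective
    rows: list[OverflowRow] = []
    for u in uptake_values:
        overrides = {glucose_exchange: (-u, 0.0)}
        sol = pfba(model, doc.objective, bound_overrides=overrides)
        if sol.status != "optimal":
            raise EcModelKitError(f"overflow scan infeasible at uptake {u}")
        growth = sol.objective_value
        consumed = -sol.fluxes[glucose_exchange]
        byp = {rid: sol.fluxes.get(rid, 0.0) for rid in byproduct_exchanges}
        if growth <= ACTIVE_FLUX_TOL:
            yield_, eff, emin = 0.0, 0.0, 0.0
        else:
            yield_ = growth / (consumed * substrate_mw) if consumed > 0 else 0.0
            emin_sol = min_enzyme(model, fixed_fluxes={biomass_rid: growth}, bound_overrides=overrides)
            emin = emin_sol.enzyme_usage
            eff = growth / emin if emin > 0 else 0.0
        rows.append(OverflowRow(u, growth, byp, yield_, eff, emin, phase=""))
    onset = next(
        (r.uptake for r in rows if any(v > ACTIVE_FLUX_TOL for v in r.byproduct_fluxes.values())),
        math.inf,
    )
    return [
        OverflowRow(
            r.uptake, r.growth, r.byproduct_fluxes, r.biomass_yield,
            r.enzyme_usage_efficiency, r.emin,
            phase="overflow" if r.uptake >= onset else "substrate-limited",
        )
        for r in rows
    ]


def overflow_table(rows: list[OverflowRow]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "uptake": r.uptake,
                "growth": r.growth,
                **{f"byproduct_{k}": v for k, v in r.byproduct_fluxes.items()},
                "biomass_yield": r.biomass_yield,
                "enzyme_usage_efficiency": r.enzyme_usage_efficiency,
                "emin": r.emin,
                "phase": r.phase,
            }
            for r in rows
        ]
    )


# ---------------------------------------------------------------------------
# enzyme cost and target discovery
# ---------------------------------------------------------------------------


def enzyme_cost(solution: FluxSolution, enzymes) -> dict[str, float]:
    """Per-reaction enzyme cost ``v MW / (sigma kcat)`` (g/gDCW).

    The costs sum to the solution's total enzyme usage.
    """
    if solution.status != "optimal":
        raise EcModelKitError("enzyme_cost requires an optimal solution")
    return {
        e.reaction_id: solution.fluxes.get(e.reaction_id, 0.0) * e.pool_coefficient
        for e in enzymes
    }


def scenario_fluxes(
    model: ECModel,
    product_exchange: str,
    growth_hglp: float = 0.46,
    growth_lghp: float = 0.1,
    uptake_fix: dict[str, float] | None = None,
) -> tuple[FluxSolution, FluxSolution]:
    """Deterministic flux states for the HGLP and LGHP scenarios.

    Per scenario: fix growth, maximize the product exchange, then resolve
    the remaining degeneracy by minimizing total enzyme at the product
    optimum — giving a unique, enzyme-minimal flux state to read costs
    from.
    """
    out = []
    for name, g in (("HGLP", growth_hglp), ("LGHP", growth_lghp)):
        overrides = _growth_fix(model, g)
        overrides.update(_uptake_overrides(uptake_fix))
        sol = fba(model, {product_exchange: 1.0}, "max", overrides)
        if sol.status != "optimal":
            raise EcModelKitError(f"scenario {name}: growth fix {g} infeasible")
        prod = sol.objective_value
        overrides[product_exchange] = (prod, prod)
        out.append(min_enzyme(model, bound_overrides=overrides))
    return out[0], out[1]


@dataclass(frozen=True)
class TargetRow:
    reaction_id: str
    cost_lghp: float
    cost_hglp: float
    fold_change: float  # LGHP / HGLP (inf when HGLP cost is 0 and LGHP > 0)
    log2_fold_change: float
    classification: str  # "enhance" | "weaken" | "neutral"
    flagged_infinite: bool = False


def find_targets(
    cost_lghp: dict[str, float],
    cost_hglp: dict[str, float],
    fold: float = 1.5,
) -> list[TargetRow]:
    """Classify reactions by enzyme-cost fold change between scenarios.

    ``enhance`` when cost_LGHP / cost_HGLP >= fold (the product-favoring
    state spends more enzyme there — overexpression candidate);
    ``weaken`` when cost_HGLP / cost_LGHP >= fold.  A zero denominator
    with a positive numerator classifies at infinite fold and is flagged;
    both-zero reactions are neutral.
    """
    if set(cost_lghp) != set(cost_hglp):
        raise EcModelKitError("target tables cover different reaction sets")
    rows: list[TargetRow] = []
    for rid in sorted(cost_lghp):
        lo, hi = cost_lghp[rid], cost_hglp[rid]
        flagged = False
        if lo == 0.0 and hi == 0.0:
            ratio, cls = 1.0, "neutral"
        elif hi == 0.0:
            ratio, cls, flagged = math.inf, "enhance", True
        elif lo == 0.0:
            ratio, cls, flagged = 0.0, "weaken", True
        else:
            ratio = lo / hi
            if ratio >= fold:
                cls = "enhance"
            elif 1.0 / ratio >= fold:
                cls = "weaken"
            else:
                cls = "neutral"
        log2fc = math.log2(ratio) if 0 < ratio < math.inf else (math.inf if ratio == math.inf else -math.inf)
        if lo == 0.0 and hi == 0.0:
            log2fc = 0.0
        rows.append(TargetRow(rid, lo, hi, ratio, log2fc, cls, flagged))
    return rows


def targets_table(rows: list[TargetRow]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "reaction_id": r.reaction_id,
                "cost_lghp": r.cost_lghp,
                "cost_hglp": r.cost_hglp,
                "fold_change": r.fold_change,
                "log2_fold_change": r.log2_fold_change,
                "classification": r.classification,
                "flagged_infinite": r.flagged_infinite,
            }
            for r in rows
        ]
    )
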