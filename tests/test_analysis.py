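import math

import numpy as np
import pytest

from ecmodelkit import (
    ECModel,
    enzyme_cost,
    fba,
    find_targets,
    fva_at_growth,
    overflow_scan,
    pfba,
    phpp,
    scenario_fluxes,
)
from ecmodelkit.analysis import FvaRange, _growth_fix
from ecmodelkit.errors import EcModelKitError
from ecmodelkit.ec_core import flux_range
from ecmodelkit.model_expansion import SplitMap, SplitOrigin


# ---------------------------------------------------------------------------
# FVA aggregation rules
# ---------------------------------------------------------------------------


def test_fva_single_member_is_plain_range(toy):
    growth = 0.5 * fba(toy.ec_model).objective_value
    report = fva_at_growth(toy.ec_model, growth, split_map=toy.split_map)
    by_id = {r.reaction_id: r for r in report.ranges}
    resp = by_id["RESP"]
    lo, hi = resp.member_ranges["RESP"]
    assert resp.fv == pytest.approx(hi - lo)


def test_fva_isozymes_take_widest_member(toy):
    growth = 0.5 * fba(toy.ec_model).objective_value
    report = fva_at_growth(toy.ec_model, growth, split_map=toy.split_map)
    by_id = {r.reaction_id: r for r in report.ranges}
    ferm = by_id["FERM"]
    widths = [hi - lo for (lo, hi) in ferm.member_ranges.values()]
    assert ferm.fv == pytest.approx(max(widths))


def test_fva_reversible_pair_subtracts_reverse_range(toy):
    growth = 0.5 * fba(toy.ec_model).objective_value
    report = fva_at_growth(toy.ec_model, growth, split_map=toy.split_map)
    by_id = {r.reaction_id: r for r in report.ranges}
    act = by_id["ACt"]
    fwd = act.member_ranges["ACt"]
    rev = act.member_ranges["ACt_reverse"]
    assert act.fv == pytest.approx((fwd[1] - fwd[0]) - (rev[1] - rev[0]))
    assert act.review == (act.fv < 0)


def test_fva_infeasible_growth_raises(toy):
    with pytest.raises(EcModelKitError):
        fva_at_growth(toy.ec_model, 1e3)


def test_ec_ranges_contained_in_base_ranges(toy):
    """Enzyme constraints can only shrink flux variability."""
    growth = 0.5 * fba(toy.ec_model).objective_value
    base_fix = _growth_fix(toy.base_model, growth)
    ec_fix = _growth_fix(toy.ec_model, growth)
    for r in toy.base_model.reactions:
        blo, bhi = flux_range(toy.base_model, r.id, base_fix)
        members = toy.split_map.members(r.id)
        obj = {
            sid: (-1.0 if toy.split_map.origin[sid].direction == "rev" else 1.0)
            for sid in members
        }
        elo = fba(toy.ec_model, obj, "min", ec_fix).objective_value
        ehi = fba(toy.ec_model, obj, "max", ec_fix).objective_value
        assert blo - 1e-6 <= elo and ehi <= bhi + 1e-6


# ---------------------------------------------------------------------------
# phenotype phase plane
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def small_grids():
    return [0.0, 2.0, 5.0, 10.0], [0.0, 2.0, 5.0, 10.0]


def test_phpp_zero_glucose_means_zero_growth(toy, small_grids):
    gg, og = small_grids
    grid = phpp(toy.base_model, toy.truth.glucose_exchange, toy.truth.oxygen_exchange, gg, og)
    assert all(g == pytest.approx(0.0, abs=1e-9) for g in grid.growth[0])


def test_phpp_base_monotone_in_each_axis(toy, small_grids):
    gg, og = small_grids
    grid = phpp(toy.base_model, toy.truth.glucose_exchange, toy.truth.oxygen_exchange, gg, og)
    arr = np.array(grid.growth)
    assert (np.diff(arr, axis=0) >= -1e-8).all()  # more glucose never hurts
    assert (np.diff(arr, axis=1) >= -1e-8).all()  # more oxygen never hurts


def test_phpp_ec_below_base_pointwise(toy, small_grids):
    gg, og = small_grids
    t = toy.truth
    base = np.array(phpp(toy.base_model, t.glucose_exchange, t.oxygen_exchange, gg, og).growth)
    ec = np.array(phpp(toy.ec_model, t.glucose_exchange, t.oxygen_exchange, gg, og).growth)
    assert (ec <= base + 1e-8).all()


def test_phpp_missing_exchange_raises(toy):
    with pytest.raises(EcModelKitError):
        phpp(toy.base_model, "EX_ghost", toy.truth.oxygen_exchange)


# ---------------------------------------------------------------------------
# overflow scan
# ---------------------------------------------------------------------------


def test_biomass_yield_arithmetic():
    # growth 0.45 at glucose uptake 5.05: 0.45 / (5.05 * 0.18016) gDCW/g
    assert 0.45 / (5.05 * 0.18016) == pytest.approx(0.4946, abs=2e-4)


def test_overflow_three_phase_structure(toy):
    t = toy.truth
    uptakes = list(np.linspace(1.0, 1.5 * t.u_star, 15))
    rows = overflow_scan(toy.ec_model, uptakes, t.glucose_exchange, [t.byproduct_exchange])
    phases = [r.phase for r in rows]
    k = phases.count("substrate-limited")
    # substrate-limited prefix, overflow suffix, no relapse
    assert phases == ["substrate-limited"] * k + ["overflow"] * (len(phases) - k)
    limited = [r for r in rows if r.phase == "substrate-limited"]
    over = [r for r in rows if r.phase == "overflow"]
    assert limited and over
    for r in limited:
        assert r.byproduct_fluxes[t.byproduct_exchange] == pytest.approx(0.0, abs=1e-6)
        assert r.growth == pytest.approx(t.y1 * r.uptake, rel=1e-6)
    for r in over:
        assert r.byproduct_fluxes[t.byproduct_exchange] > 1e-6
        assert r.emin <= toy.ec_model.pool_bound + 1e-6


def test_overflow_yield_efficiency_tradeoff(toy):
    t = toy.truth
    uptakes = list(np.linspace(0.5 * t.u_star, 2.0 * t.u_star, 12))
    rows = overflow_scan(toy.ec_model, uptakes, t.glucose_exchange, [t.byproduct_exchange])
    past = [r for r in rows if r.uptake > t.u_star * (1 + 1e-9)]
    yields = [r.biomass_yield for r in past]
    effs = [r.enzyme_usage_efficiency for r in past]
    assert all(b < a - 1e-9 for a, b in zip(yields, yields[1:]))  # strictly decreasing
    assert all(b >= a - 1e-9 for a, b in zip(effs, effs[1:]))  # non-decreasing


def test_overflow_zero_growth_convention(toy):
    t = toy.truth
    ec = toy.ec_model.copy()
    # block biomass: conventions 0/0 -> 0 must hold
    rows = overflow_scan(
        ECModel(ec.base.replace_reaction(
            "BIOMASS", type(ec.base.get_reaction("BIOMASS"))(
                id="BIOMASS", stoichiometry=ec.base.get_reaction("BIOMASS").stoichiometry,
                lower_bound=0.0, upper_bound=0.0)),
            list(ec.enzymes), ec.ptotal, ec.f),
        [2.0], t.glucose_exchange, [t.byproduct_exchange],
    )
    assert rows[0].biomass_yield == 0.0
    assert rows[0].enzyme_usage_efficiency == 0.0


# ---------------------------------------------------------------------------
# enzyme cost and targets
# ---------------------------------------------------------------------------


def test_enzyme_cost_values_and_conservation(toy):
    sol = pfba(toy.ec_model)
    costs = enzyme_cost(sol, toy.ec_model.enzymes)
    assert sum(costs.values()) == pytest.approx(sol.enzyme_usage, abs=1e-9)
    for e in toy.ec_model.enzymes:
        v = sol.fluxes[e.reaction_id]
        assert costs[e.reaction_id] == pytest.approx(v * e.mw_kda / (e.sigma * e.kcat_per_h))


def test_enzyme_cost_arithmetic_example():
    from ecmodelkit import EnzymeEntry, FluxSolution

    sol = FluxSolution("optimal", 0.0, {"R": 1.0}, 0.0)
    entry = EnzymeEntry("R", {}, mw_kda=100.0, kcat_per_h=3600.0, sigma=0.5)
    assert enzyme_cost(sol, [entry])["R"] == pytest.approx(100.0 / 1800.0)  # 0.0556


def test_scenario_product_tradeoff(toy):
    t = toy.truth
    ec_max = fba(toy.ec_model).objective_value
    hglp, lghp = scenario_fluxes(
        toy.ec_model, t.product_exchange, growth_hglp=0.7 * ec_max, growth_lghp=0.1 * ec_max
    )
    # resource freed from growth goes to product
    assert lghp.fluxes[t.product_exchange] >= hglp.fluxes[t.product_exchange]
    for sol in (hglp, lghp):
        assert sol.enzyme_usage <= toy.ec_model.pool_bound + 1e-6


def test_scenario_at_max_growth_leaves_no_product(toy):
    t = toy.truth
    ec_max = fba(toy.ec_model).objective_value
    hglp, _ = scenario_fluxes(
        toy.ec_model, t.product_exchange, growth_hglp=ec_max, growth_lghp=0.1
    )
    assert hglp.fluxes[t.product_exchange] == pytest.approx(0.0, abs=1e-6)


def test_scenario_infeasible_growth_raises(toy):
    with pytest.raises(EcModelKitError, match="HGLP"):
        scenario_fluxes(toy.ec_model, toy.truth.product_exchange, growth_hglp=1e3)


def test_find_targets_boundary_and_conventions():
    lghp = {"a": 1.5, "b": 1.0, "c": 0.01, "d": 0.0, "e": 0.0}
    hglp = {"a": 1.0, "b": 1.0, "c": 0.0, "d": 0.02, "e": 0.0}
    rows = {r.reaction_id: r for r in find_targets(lghp, hglp)}
    assert rows["a"].classification == "enhance"  # ratio exactly 1.5 included
    assert rows["b"].classification == "neutral"
    assert rows["c"].classification == "enhance" and rows["c"].flagged_infinite
    assert rows["d"].classification == "weaken" and rows["d"].flagged_infinite
    assert rows["e"].classification == "neutral"
    assert math.isinf(rows["c"].fold_change)


def test_targets_swap_under_table_exchange():
    lghp = {"a": 3.0, "b": 0.5, "c": 1.2}
    hglp = {"a": 1.0, "b": 1.0, "c": 1.0}
    fwd = {r.reaction_id: r.classification for r in find_targets(lghp, hglp)}
    rev = {r.reaction_id: r.classification for r in find_targets(hglp, lghp)}
    swap = {"enhance": "weaken", "weaken": "enhance", "neutral": "neutral"}
    assert rev == {rid: swap[cls] for rid, cls in fwd.items()}


def test_targets_classes_disjoint(toy):
    t = toy.truth
    ec_max = fba(toy.ec_model).objective_value
    hglp, lghp = scenario_fluxes(
        toy.ec_model, t.product_exchange, growth_hglp=0.7 * ec_max, growth_lghp=0.1 * ec_max
    )
    rows = find_targets(
        enzyme_cost(lghp, toy.ec_model.enzymes), enzyme_cost(hglp, toy.ec_model.enzymes)
    )
    for r in rows:
        assert r.classification in ("enhance", "weaken", "neutral")
    enh = {r.reaction_id for r in rows if r.classification == "enhance"}
    weak = {r.reaction_id for r in rows if r.classification == "weaken"}
    assert not (enh & weak)


def test_targets_mismatched_sets_raise():
    with pytest.raises(EcModelKitError):
        find_targets({"a": 1.0}, {"b": 1.0})
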