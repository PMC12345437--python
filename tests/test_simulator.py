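"""Projection engine: single-step operations, invariants, full runs."""

import numpy as np
import pytest

from catpop.policies import PolicyPlan, get_plan
from catpop.simulator import (
    CatastropheSpec,
    Cohort,
    FlowSpec,
    MortalitySchedule,
    SimConfig,
    abandonment_allocation,
    age_up,
    apply_flows,
    apply_mortality,
    apply_sterilization,
    births,
    default_stratum_params,
    enforce_capacity,
    initialize_state,
    run_scenario,
)
from catpop.stratification import SCENARIO_CODES, BaselineTable

KU, KS, AU, AS = (int(c) for c in Cohort)


def make_baseline(**cats):
    full = {c: 0 for c in SCENARIO_CODES}
    full.update(cats)
    return BaselineTable(cats=full, colonies={c: 0 for c in SCENARIO_CODES})


def int_state(**strata):
    counts = np.zeros((8, 4), dtype=np.int64)
    for code, row in strata.items():
        counts[SCENARIO_CODES.index(code)] = row
    return counts


# ---------------------------------------------------------------- initialize


def test_initialize_splits_half_up():
    state = initialize_state(make_baseline(RL=700_056), SimConfig())
    i = SCENARIO_CODES.index("RL")
    assert state.counts[i, AS] == 140_011
    assert state.counts[i, AU] == 560_045
    assert state.counts[i, [KU, KS]].sum() == 0


@pytest.mark.parametrize("frac,ster,unster", [(0.0, 0, 1000), (1.0, 1000, 0)])
def test_initialize_extreme_fractions(frac, ster, unster):
    cfg = SimConfig(initial_sterilized_fraction=frac)
    state = initialize_state(make_baseline(UM=1000), cfg)
    i = SCENARIO_CODES.index("UM")
    assert state.counts[i, AS] == ster and state.counts[i, AU] == unster


# -------------------------------------------------------------------- births


def test_no_unsterilized_adults_no_births():
    params = default_stratum_params()
    counts = int_state(RVH=[0, 0, 0, 5000])
    rng = np.random.default_rng(0)
    assert births(counts, params, rng).sum() == 0


def test_expected_value_births_match_closed_form():
    """1000 RVH females: 1000 * (3 * 0.7225) * 4.5283 kittens."""
    params = default_stratum_params()
    counts = int_state(RVH=[0, 0, 2000, 0]).astype(float)
    out = births(counts, params)
    i = SCENARIO_CODES.index("RVH")
    assert out[i] == pytest.approx(1000 * 2.1675 * 4.5283, rel=1e-4)
    assert out.sum() == pytest.approx(out[i])


def test_stochastic_births_mean_matches_expectation():
    params = default_stratum_params()
    counts = np.broadcast_to(int_state(RVH=[0, 0, 2000, 0]), (1000, 8, 4)).copy()
    rng = np.random.default_rng(11)
    draws = births(counts, params, rng).sum(axis=-1)
    se = draws.std(ddof=1) / np.sqrt(draws.size)
    assert abs(draws.mean() - 1000 * 2.1675 * 4.5283) < 3 * se


# ----------------------------------------------------------------- mortality


def test_expected_value_mortality_rates():
    counts = int_state(UL=[0, 0, 100, 0]).astype(float)
    out, deaths = apply_mortality(counts, MortalitySchedule())
    i = SCENARIO_CODES.index("UL")
    assert out[i, AU] == pytest.approx(85.0)
    assert deaths.sum() == pytest.approx(15.0)


def test_catastrophe_multiplies_kitten_mortality():
    counts = int_state(UL=[100, 0, 0, 0]).astype(float)
    out, _ = apply_mortality(
        counts, MortalitySchedule(), CatastropheSpec(), catastrophe_active=True
    )
    # 0.65 * 1.3 = 0.845 -> 15.5 survivors
    assert out[SCENARIO_CODES.index("UL"), KU] == pytest.approx(15.5)


def test_additive_catastrophe_mode_and_cap():
    counts = int_state(UL=[100, 0, 0, 0]).astype(float)
    spec = CatastropheSpec(mode="additive", mortality_multiplier=1.5)
    out, _ = apply_mortality(counts, MortalitySchedule(), spec, catastrophe_active=True)
    assert out[SCENARIO_CODES.index("UL"), KU] == pytest.approx(100 * (1 - min(0.65 + 0.5, 1))), \
        "additive bump capped at full mortality"


def test_certain_mortality_empties_cohorts():
    counts = int_state(RM=[50, 50, 50, 50])
    rng = np.random.default_rng(1)
    out, deaths = apply_mortality(
        counts, MortalitySchedule(kitten_mortality=1.0, adult_mortality=1.0), rng=rng
    )
    assert out.sum() == 0 and deaths.sum() == 200


# -------------------------------------------------------------------- age up


def test_age_up_bookkeeping():
    counts = int_state(RH=[50, 20, 10, 5])
    out = age_up(counts)
    i = SCENARIO_CODES.index("RH")
    assert list(out[i]) == [0, 0, 60, 25]
    assert age_up(np.zeros((8, 4), dtype=np.int64)).sum() == 0
    assert out.sum() == counts.sum()


# --------------------------------------------------------------------- flows


def test_abandonment_proportional_allocation():
    flows = FlowSpec()
    initial = np.zeros(8, dtype=np.int64)
    initial[SCENARIO_CODES.index("RL")] = 900
    initial[SCENARIO_CODES.index("UL")] = 100
    alloc = abandonment_allocation(flows, initial)
    assert alloc.sum() == 109_000
    assert alloc[SCENARIO_CODES.index("UL")].sum() == 10_900
    # unsterilized only, half kittens
    assert alloc[:, [KS, AS]].sum() == 0
    assert alloc[:, KU].sum() == pytest.approx(alloc.sum() / 2, abs=8)


def test_adoption_from_empty_population_is_noop():
    counts = np.zeros((8, 4), dtype=np.int64)
    out, added, removed = apply_flows(counts, FlowSpec(), do_abandonment=False)
    assert out.sum() == 0 and removed == 0 and added == 0


def test_zero_flows_leave_state_unchanged():
    counts = int_state(RL=[10, 20, 30, 40])
    flows = FlowSpec(national_abandonment=0, national_adoption=0)
    out, added, removed = apply_flows(counts, flows, np.zeros((8, 4), dtype=np.int64))
    assert np.array_equal(out, counts) and added == 0 and removed == 0


def test_adoption_removes_exact_harvest_proportionally():
    counts = int_state(RL=[0, 0, 8000, 2000])
    flows = FlowSpec(national_abandonment=0, national_adoption=1000)
    out, _, removed = apply_flows(counts, flows, do_abandonment=False)
    assert removed == 1000
    assert counts.sum() - out.sum() == 1000
    i = SCENARIO_CODES.index("RL")
    assert out[i, AU] == 7200 and out[i, AS] == 1800


# ------------------------------------------------------------- sterilization


def test_sterilization_already_met_no_transfer():
    counts = int_state(UM=[0, 0, 80, 20])
    out, moved = apply_sterilization(counts, 0.20)
    assert moved.sum() == 0 and np.array_equal(out, counts)


def test_sterilization_transfer_arithmetic():
    counts = int_state(UM=[0, 0, 800, 200])
    out, moved = apply_sterilization(counts, 0.50)
    i = SCENARIO_CODES.index("UM")
    assert moved.sum() == 300
    assert out[i, AS] == 500 and out[i, AU] == 500
    assert out.sum() == counts.sum(), "sterilization never changes the total"


def test_sterilization_full_coverage_moves_everyone():
    counts = int_state(RVH=[100, 0, 900, 0])
    out, moved = apply_sterilization(counts, 1.0)
    i = SCENARIO_CODES.index("RVH")
    assert moved.sum() == 1000
    assert out[i, KU] == 0 and out[i, AU] == 0
    assert out[i, KS] == 100 and out[i, AS] == 900


def test_sterilization_annual_rate_mode():
    counts = int_state(RVH=[0, 0, 1000, 0])
    out, moved = apply_sterilization(counts, 0.30, mode="annual_rate")
    i = SCENARIO_CODES.index("RVH")
    assert moved.sum() == 300 and out[i, AS] == 300


# ------------------------------------------------------------------ capacity


def test_capacity_scales_down_to_exact_k():
    counts = int_state(RL=[0, 0, 2_080_000, 520_000])
    capacity = np.full(8, 2_500_000, dtype=np.int64)
    out, removed = enforce_capacity(counts, capacity)
    i = SCENARIO_CODES.index("RL")
    assert out[i].sum() == 2_500_000
    assert removed == 100_000
    # proportions preserved within 1
    assert out[i, AU] == pytest.approx(2_500_000 * 0.8, abs=1)


def test_capacity_under_k_unchanged_and_zero_k_empties():
    counts = int_state(RL=[10, 10, 10, 10])
    out, removed = enforce_capacity(counts, np.full(8, 100, dtype=np.int64))
    assert np.array_equal(out, counts) and removed == 0
    out, removed = enforce_capacity(counts, np.zeros(8, dtype=np.int64))
    assert out.sum() == 0 and removed == 40


# ----------------------------------------------------------------- full runs


def test_all_zero_state_is_fixed_point(quiet_config):
    cfg = quiet_config(engine="expected_value", horizon=5)
    res = run_scenario(make_baseline(), get_plan("baseline20"), cfg)
    assert res.national.mean.sum() == 0


def test_one_year_hand_computation(quiet_config):
    """Spreadsheet oracle for one expected-value year of a toy RVH stratum.

    1000 cats, 20% sterilized: births 400 * 2.1675 * 4.5283 = 3926.53;
    survivors: adults 850, kittens 1374.29; no flows; coverage already met.
    """
    cfg = quiet_config(engine="expected_value", horizon=1)
    res = run_scenario(make_baseline(RVH=1000), get_plan("baseline20"), cfg)
    kittens = 400 * 3 * 0.7225 * 4.528357
    expected = 1000 * 0.85 + kittens * 0.35
    assert res.national.mean[1] == pytest.approx(expected, rel=1e-4)


def test_expected_value_engine_is_deterministic(quiet_config, baseline):
    cfg = quiet_config(engine="expected_value", horizon=8)
    a = run_scenario(baseline, get_plan("pacf"), cfg)
    b = run_scenario(baseline, get_plan("pacf"), cfg)
    assert np.array_equal(a.national_total, b.national_total)


def test_stochastic_engine_reproducible_under_seed(baseline):
    cfg = SimConfig(horizon=5, iterations=20, seed=99)
    a = run_scenario(baseline, get_plan("pacf"), cfg)
    b = run_scenario(baseline, get_plan("pacf"), cfg)
    assert np.array_equal(a.national_total, b.national_total)
    c = run_scenario(baseline, get_plan("pacf"), cfg.model_copy(update={"seed": 100}))
    assert not np.array_equal(a.national_total, c.national_total)


def test_full_coverage_no_flows_gives_decay_law(quiet_config, baseline):
    """total(t) = total(0) * 0.85^t with everyone sterilized and no inflow."""
    cfg = quiet_config(
        engine="expected_value", horizon=15, initial_sterilized_fraction=1.0
    )
    res = run_scenario(baseline, PolicyPlan.uniform("all", 1.0), cfg)
    expected = baseline.national_total * 0.85 ** np.arange(16)
    assert np.allclose(res.national.mean, expected, rtol=1e-9)


def test_total_never_exceeds_capacity(baseline):
    cfg = SimConfig(horizon=12, iterations=30, seed=5)
    res = run_scenario(baseline, get_plan("baseline20"), cfg)
    k_total = 2.5 * baseline.rural_total + 3.0 * baseline.urban_total
    assert (res.national_total <= k_total + 0.5).all()
    # per-stratum bound too
    initial = np.array([baseline.cats[c] for c in SCENARIO_CODES], dtype=float)
    mult = np.array([3.0 if c.startswith("U") else 2.5 for c in SCENARIO_CODES])
    per_k = np.round(mult * initial)
    assert (res.stratum_totals <= per_k[None, :, None] + 0.5).all()


def test_year25_total_monotone_in_coverage(baseline):
    """Final mean population is non-increasing in the coverage target."""
    finals = []
    for cov in (0.2, 0.4, 0.5, 0.6, 0.7, 0.8, 1.0):
        cfg = SimConfig(horizon=25, iterations=40, seed=2024)
        res = run_scenario(baseline, PolicyPlan.uniform(f"c{cov}", cov), cfg)
        finals.append(res.national.mean[-1])
    assert all(a >= b - 1e-6 for a, b in zip(finals, finals[1:]))


def test_stochastic_mean_matches_expected_value_engine(baseline, quiet_config):
    """Engine cross-validation: 1000 iterations agree within 3 SE."""
    kwargs = dict(horizon=6, initial_sterilized_fraction=0.2)
    ev = run_scenario(
        baseline, PolicyPlan.uniform("c9", 0.9), quiet_config(engine="expected_value", **kwargs)
    )
    st = run_scenario(
        baseline,
        PolicyPlan.uniform("c9", 0.9),
        quiet_config(engine="stochastic", iterations=1000, **kwargs),
    )
    final = st.national_total[:, -1]
    se = final.std(ddof=1) / np.sqrt(final.size)
    assert abs(final.mean() - ev.national.mean[-1]) < 3 * se


def test_conservation_ledger_holds_each_year(baseline):
    # run_scenario raises if the integer ledger ever fails to balance
    cfg = SimConfig(horizon=10, iterations=25, seed=3)
    res = run_scenario(baseline, get_plan("pacf"), cfg, check_conservation=True)
    assert len(res.ledgers) == 10


def test_percentiles_bracket_mean(baseline):
    cfg = SimConfig(horizon=8, iterations=60, seed=17)
    res = run_scenario(baseline, get_plan("ideal80"), cfg)
    nat = res.national
    assert (nat.lo <= nat.mean + 1e-9).all()
    assert (nat.mean <= nat.hi + 1e-9).all()


def test_event_order_is_configurable_and_validated(baseline, quiet_config):
    order = ("mortality", "births", "age_up", "abandonment", "adoption",
             "sterilization", "capacity")
    cfg = quiet_config(engine="expected_value", horizon=3, event_order=order)
    res = run_scenario(baseline, get_plan("baseline20"), cfg)
    default = run_scenario(
        baseline, get_plan("baseline20"), quiet_config(engine="expected_value", horizon=3)
    )
    assert not np.allclose(res.national.mean[1:], default.national.mean[1:])
    with pytest.raises(ValueError):
        SimConfig(event_order=("births",))


def test_horizon_zero_returns_baseline(baseline):
    cfg = SimConfig(horizon=0, iterations=5, seed=0)
    res = run_scenario(baseline, get_plan("pacf"), cfg)
    assert res.national.mean[0] == baseline.national_total
    assert res.years.tolist() == [0]
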