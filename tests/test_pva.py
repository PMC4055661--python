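"""Monte Carlo PVA: elementary draws, fixtures with closed forms, waiting
times, and the seed/monotonicity contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from florisk.classes import RateClass, SizeClass
from florisk.pva import (
    ExtinctionRiskModel,
    ScenarioConfig,
    draw_initial_size,
    draw_rate,
    expected_extinction_time,
    select_pool,
    simulate_taxon,
)
from florisk.records import (
    ChangeEntity,
    PopulationRecord,
    RatePools,
    build_rate_pools,
)


def rng(seed=0):
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# elementary draws
# ---------------------------------------------------------------------------


def test_open_class_always_gives_point_value():
    cls = SizeClass.parse(">=1000", "first")
    draws = draw_initial_size(cls, rng(), size=100)
    assert np.all(draws == 1000)


def test_log_uniform_draw_has_geometric_mean_of_bounds():
    cls = SizeClass.parse("100-999", "first")
    draws = draw_initial_size(cls, rng(1), size=100_000)
    gm = np.exp(np.mean(np.log(draws)))
    assert gm == pytest.approx(np.sqrt(100 * 999), rel=0.01)
    assert draws.min() >= 100 and draws.max() <= 999


def test_forced_extinction_rate_is_exact():
    ent = ChangeEntity("forced_extinction")
    assert draw_rate(ent, rng()) == 1.0 / 10_000


def test_point_valued_class_pair_rate_is_deterministic():
    ent = ChangeEntity(
        "class_pair",
        SizeClass.parse(">=1000", "first"),
        SizeClass.parse(">=10000", "second"),
    )
    assert all(draw_rate(ent, rng()) == 10.0 for _ in range(10))


def test_decline_score_rate_geometric_mean():
    ent = ChangeEntity("decline_score", rate_class=RateClass.parse("1/100-1/10"))
    g = rng(2)
    draws = np.array([draw_rate(ent, g) for _ in range(20_000)])
    gm = np.exp(np.mean(np.log(draws)))
    assert gm == pytest.approx(np.sqrt(0.01 * 0.1), rel=0.02)


def test_extinct_class_cannot_seed_a_population():
    with pytest.raises(ValueError):
        draw_initial_size(SizeClass.parse("extinct", "second"), rng())


# ---------------------------------------------------------------------------
# pool selection and fallback
# ---------------------------------------------------------------------------


def _entity():
    return ChangeEntity("decline_score", rate_class=RateClass.parse("1/2-1"))


def test_pool_choice_and_fallback_chain():
    pools = RatePools(
        pool1={"taxA": [_entity()]},
        pool2={"c1": [_entity(), _entity()]},
        global_pool=[_entity()] * 3,
    )
    cfg1 = ScenarioConfig(p_pool1=1.0)
    assert select_pool("taxA", "c1", pools, cfg1, rng()) is pools.pool1["taxA"]
    cfg0 = ScenarioConfig(p_pool1=0.0)
    assert select_pool("taxA", "c1", pools, cfg0, rng()) is pools.pool2["c1"]
    # chosen pool empty -> other pool; both empty -> global
    assert select_pool("taxB", "c1", pools, cfg1, rng()) is pools.pool2["c1"]
    assert select_pool("taxB", "c9", pools, cfg1, rng()) is pools.global_pool
    empty = RatePools()
    with pytest.raises(ValueError):
        select_pool("taxA", "c1", empty, cfg1, rng())


# ---------------------------------------------------------------------------
# fixtures with closed-form CDFs
# ---------------------------------------------------------------------------


def _fit(worked_records, **kw):
    cfg = ScenarioConfig(p_pool1=1.0, n_replications=1000, seed=42, **kw)
    return ExtinctionRiskModel(worked_records, config=cfg).fit()


def test_observed_extinction_is_certain_by_first_decade(worked_records):
    res = _fit(worked_records)
    assert np.all(res.trajectories["doomed"].cum_prob == 1.0)
    assert res.trajectories["doomed"].t_expected == 10.0


def test_pure_growth_never_goes_extinct(worked_records):
    res = _fit(worked_records)
    traj = res.trajectories["always_grows"]
    assert np.all(traj.cum_prob == 0.0)
    assert traj.t_expected == 500.0  # the waiting-time horizon


def test_coinflip_pool_follows_geometric_law(worked_records):
    res = _fit(worked_records)
    cum = res.trajectories["coinflip"].cum_prob
    t = np.arange(1, 11)
    expected = 1.0 - 0.5**t
    se = np.sqrt(expected * (1 - expected) / 1000)
    assert np.all(np.abs(cum - expected) <= 3 * np.maximum(se, 1e-3))


def test_loss_curve_sums_taxon_cdfs(worked_records):
    res = _fit(worked_records)
    total = sum(tr.cum_prob[-1] for tr in res.trajectories.values())
    assert res.loss_curve[-1] == pytest.approx(total)
    # doomed + shareds certain, coinflip nearly certain, grower safe
    assert res.loss_curve[-1] == pytest.approx(4.0, abs=0.01)


def test_threatened_classification(worked_records):
    res = _fit(worked_records)
    assert "coinflip" in res.threatened
    assert "always_grows" not in res.threatened


def test_unsimulatable_taxon_is_flagged():
    # a decline score alone gives no starting size anywhere
    recs = [
        PopulationRecord(
            "ghost", "c1", decline_score=RateClass.parse("1/2-1")
        ),
        PopulationRecord(
            "ok", "c2", size_second=SizeClass.parse("1-9", "second"),
            decline_score=RateClass.parse(">1"),
        ),
    ]
    res = ExtinctionRiskModel(
        recs, config=ScenarioConfig(n_replications=50, seed=0)
    ).fit()
    assert res.unsimulated == ["ghost"]
    assert "ok" in res.trajectories


def test_first_census_only_cells_run_one_extra_decade():
    # a first-census start with an always-lethal pool dies in the burn-in
    # step, i.e. is already extinct at decade 1
    recs = [
        PopulationRecord(
            "t", "c1", size_first=SizeClass.parse("1-9", "first"),
            decline_score=RateClass.parse("<1/100"),
        )
    ]
    res = ExtinctionRiskModel(
        recs, config=ScenarioConfig(n_replications=200, seed=0)
    ).fit()
    assert res.trajectories["t"].cum_prob[0] == 1.0


# ---------------------------------------------------------------------------
# contracts
# ---------------------------------------------------------------------------


def test_seed_contract_bit_identical(worked_records):
    a = _fit(worked_records)
    b = _fit(worked_records)
    for tid in a.trajectories:
        assert np.array_equal(a.trajectories[tid].cum_prob, b.trajectories[tid].cum_prob)


def test_cum_prob_monotone_on_synthetic_data():
    from florisk.synthetic import SyntheticScenario, generate_dataset

    records, _, _ = generate_dataset(SyntheticScenario(n_taxa=25, n_cells=15, seed=9))
    cfg = ScenarioConfig(p_pool1=0.5, n_replications=100, seed=9)
    res = ExtinctionRiskModel(records, config=cfg).fit()
    for traj in res.trajectories.values():
        assert np.all(np.diff(traj.cum_prob) >= 0)
        assert np.all((0 <= traj.cum_prob) & (traj.cum_prob <= 1))


def test_smaller_rates_never_decrease_risk(worked_pools, worked_records):
    """Stochastic dominance: degrading every pool entity raises the CDF."""
    cfg = ScenarioConfig(p_pool1=1.0, n_replications=1000, seed=7)
    base = simulate_taxon(
        [r for r in worked_records if r.taxon_id == "coinflip"],
        worked_pools,
        cfg,
        np.random.default_rng(7),
    )
    # replace the guaranteed-survival entity with a mild decline
    worse_pools = build_rate_pools(
        [
            PopulationRecord(
                "coinflip", "c3",
                size_second=SizeClass.parse("1-9", "second"),
                decline_score=RateClass.parse("1/2-1"),
            ),
            PopulationRecord(
                "coinflip", "c4",
                size_second=SizeClass.parse("extinct", "second"),
            ),
        ]
    )
    worse = simulate_taxon(
        [r for r in worked_records if r.taxon_id == "coinflip"],
        worse_pools,
        cfg,
        np.random.default_rng(7),
    )
    assert np.all(worse.cum_prob >= base.cum_prob - 1e-12)


# ---------------------------------------------------------------------------
# expected waiting time to extinction
# ---------------------------------------------------------------------------


def test_immediate_extinction_waits_one_decade():
    assert expected_extinction_time([1.0] + [1.0] * 9) == 10.0


def test_constant_hazard_half_gives_twenty_years():
    t = np.arange(1, 11)
    cum = 1.0 - 0.5**t
    cfg = ScenarioConfig(waiting_time_horizon=1e9)
    assert expected_extinction_time(cum, cfg) == pytest.approx(20.0)


def test_zero_risk_returns_horizon():
    assert expected_extinction_time(np.zeros(10)) == 500.0


@settings(max_examples=200, deadline=None)
@given(
    st.lists(st.floats(0, 1), min_size=10, max_size=10),
    st.lists(st.floats(0, 1), min_size=10, max_size=10),
)
def test_waiting_time_monotone_in_risk(u, v):
    """Pointwise-higher cumulative risk never lengthens the expected wait."""
    lo = np.maximum.accumulate(np.minimum(u, v))
    hi = np.maximum.accumulate(np.maximum(u, v))
    t_lo = expected_extinction_time(lo)
    t_hi = expected_extinction_time(hi)
    assert t_hi <= t_lo + 1e-9
    assert 0 < t_hi <= 500.0
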