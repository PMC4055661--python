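"""Local-extinction databases, the product-form taxon CDF, RER, and the
greedy / comparator site selectors."""

import numpy as np
import pytest

from florisk.classes import RateClass, SizeClass
from florisk.prioritize import (
    LocalExtinctionDB,
    PASelection,
    build_local_extinction_db,
    build_local_extinction_dbs,
    complementarity_select,
    compute_rer,
    evaluate_selection,
    greedy_select,
    hotspot_select,
    random_select,
    taxon_extinction_cdf,
)
from florisk.pva import ScenarioConfig, simulate_taxon
from florisk.records import PopulationRecord, build_rate_pools


def _rec(taxon, cell, sf=None, ss=None, dc=None):
    return PopulationRecord(
        taxon,
        cell,
        size_first=SizeClass.parse(sf, "first") if sf else None,
        size_second=SizeClass.parse(ss, "second") if ss else None,
        decline_score=RateClass.parse(dc) if dc else None,
    )


CFG = ScenarioConfig(p_pool1=1.0, n_replications=1000, seed=13)


# ---------------------------------------------------------------------------
# database construction
# ---------------------------------------------------------------------------


def test_db_requires_taxonwise_pooling(worked_records):
    with pytest.raises(ValueError, match="p_pool1"):
        build_local_extinction_db(
            worked_records, None, ScenarioConfig(p_pool1=0.5), 0.5
        )
    with pytest.raises(ValueError, match="effectiveness"):
        build_local_extinction_db(worked_records, None, CFG, 1.5)


def test_protection_never_increases_local_risk(worked_records):
    db = build_local_extinction_db(worked_records, None, CFG, 0.5)
    for key, unprot in db.unprotected.items():
        prot = db.protected[key]
        assert np.all(prot <= unprot + 1e-12)
        assert np.all(np.diff(unprot) >= 0) and np.all(np.diff(prot) >= 0)


def test_zero_effectiveness_is_a_noop(worked_records):
    db = build_local_extinction_db(worked_records, None, CFG, 0.0)
    for key in db.unprotected:
        assert np.array_equal(db.unprotected[key], db.protected[key])


def test_full_effectiveness_cancels_all_declines():
    # a pool made entirely of declining entities: protection at 1.0 leaves
    # no drawn rate below 1, so the protected vector is identically zero
    recs = [_rec("s", "c1", sf="100-999", ss="1-9")]
    db = build_local_extinction_db(recs, None, CFG, 1.0)
    assert np.all(db.unprotected[("s", "c1")] == 1.0)
    assert np.all(db.protected[("s", "c1")] == 0.0)


def test_coinflip_protection_halves_the_hazard(worked_records):
    # effectiveness 0.5 cancels half of the forced-extinction draws:
    # per-decade hazard drops from 1/2 to 1/4
    db = build_local_extinction_db(worked_records, None, CFG, 0.5)
    prot = db.protected[("coinflip", "c3")]
    t = np.arange(1, 11)
    expected = 1.0 - 0.75**t
    se = np.sqrt(expected * (1 - expected) / CFG.n_replications)
    assert np.all(np.abs(prot - expected) <= 3 * np.maximum(se, 1e-3))


def test_observed_extinctions_stay_extinct_under_protection(worked_records):
    db = build_local_extinction_db(worked_records, None, CFG, 1.0)
    assert np.all(db.unprotected[("doomed", "c1")] == 1.0)
    assert np.all(db.protected[("doomed", "c1")] == 1.0)


# ---------------------------------------------------------------------------
# product-form taxon CDF
# ---------------------------------------------------------------------------


def _fake_db(entries, effectiveness=1.0, cfg=CFG):
    db = LocalExtinctionDB(effectiveness, cfg)
    for (taxon, cell), (unprot, prot) in entries.items():
        db.unprotected[(taxon, cell)] = np.asarray(unprot, float)
        db.protected[(taxon, cell)] = np.asarray(prot, float)
        db.taxon_cells.setdefault(taxon, []).append(cell)
    return db


def test_single_cell_taxon_cdf_is_local_cdf():
    vec = 1.0 - 0.5 ** np.arange(1, 11)
    db = _fake_db({("s", "c1"): (vec, vec * 0.5)})
    assert np.array_equal(taxon_extinction_cdf(db, "s", ()), vec)
    assert np.array_equal(taxon_extinction_cdf(db, "s", {"c1"}), vec * 0.5)
    with pytest.raises(KeyError):
        taxon_extinction_cdf(db, "nope", ())


def test_two_independent_cells_multiply():
    half = np.full(10, 0.5)
    db = _fake_db({("s", "c1"): (half, half), ("s", "c2"): (half, half)})
    assert np.allclose(taxon_extinction_cdf(db, "s", ()), 0.25)


def test_product_form_matches_joint_simulation():
    # three cells, identical decline pools, taxon-wise pooling: the product
    # of single-cell CDFs must agree with directly simulating all cells
    recs = [_rec("tri", c, ss="10-49", dc="1/10-1/2") for c in ("d1", "d2", "d3")]
    pools = build_rate_pools(recs)
    db = build_local_extinction_db(recs, pools, CFG, 0.5)
    product = taxon_extinction_cdf(db, "tri", ())
    joint = simulate_taxon(recs, pools, CFG, np.random.default_rng(99)).cum_prob
    se = np.sqrt(
        np.maximum(product * (1 - product), joint * (1 - joint))
        / CFG.n_replications
    )
    assert np.all(np.abs(product - joint) <= 3 * np.maximum(se, 2e-3) + 0.01)


# ---------------------------------------------------------------------------
# RER
# ---------------------------------------------------------------------------


def test_rer_of_empty_set_is_zero(worked_records):
    db = build_local_extinction_db(worked_records, None, CFG, 1.0)
    assert compute_rer(db, ()).value == 0.0


def test_rer_of_doubled_waiting_time_is_half():
    t = np.arange(1, 11)
    unprot = 1.0 - 0.5**t  # T = 20 years
    prot = 1.0 - 0.75**t  # T = 40 years
    db = _fake_db({("s", "c1"): (unprot, prot)})
    rer = compute_rer(db, {"c1"})
    assert rer.value == pytest.approx(0.5, abs=1e-6)
    assert rer.per_taxon["s"] == pytest.approx(0.5, abs=1e-6)


def test_unnormalized_rer_is_waiting_time_gain():
    t = np.arange(1, 11)
    db = _fake_db({("s", "c1"): (1.0 - 0.5**t, 1.0 - 0.75**t)})
    rer = compute_rer(db, {"c1"}, normalized=False)
    assert rer.value == pytest.approx(20.0, abs=1e-3)


# ---------------------------------------------------------------------------
# greedy selection
# ---------------------------------------------------------------------------


def test_greedy_targets_the_only_declining_taxon():
    recs = [
        _rec("faller", "c1", sf="100-999", ss="1-9"),
        _rec("stable_b", "c2", ss="10-49", dc=">1"),
        _rec("stable_c", "c3", ss="10-49", dc=">1"),
    ]
    db = build_local_extinction_db(recs, None, CFG, 1.0)
    sel = greedy_select(db, 2)
    assert sel.ordered_cells[0] == "c1"
    assert np.all(np.diff(np.concatenate([[0.0], sel.rer_curve])) >= -1e-12)


def test_budget_bounds(worked_records):
    db = build_local_extinction_db(worked_records, None, CFG, 1.0)
    assert greedy_select(db, 0).ordered_cells == []
    with pytest.raises(ValueError):
        greedy_select(db, 99)


def test_full_protection_at_full_effectiveness_saves_everything(worked_records):
    # without the already-extinct taxon, every decline is cancellable:
    # protecting every cell renders no taxon threatened
    recs = [r for r in worked_records if r.taxon_id != "doomed"]
    db = build_local_extinction_db(recs, None, CFG, 1.0)
    sel = greedy_select(db, len(db.cells))
    assert sel.remaining_threatened[-1] == 0


def test_remaining_threatened_monotone_in_effectiveness():
    from florisk.synthetic import SyntheticScenario, generate_dataset

    records, _, _ = generate_dataset(SyntheticScenario(n_taxa=25, n_cells=12, seed=3))
    cfg = ScenarioConfig(p_pool1=1.0, n_replications=300, seed=3)
    dbs = build_local_extinction_dbs(records, None, cfg, [0.2, 0.5, 0.8, 1.0])
    budget = 6
    sel = greedy_select(dbs[1.0], budget)
    remaining = [
        evaluate_selection(dbs[e], sel.ordered_cells)[1][-1]
        for e in (0.2, 0.5, 0.8, 1.0)
    ]
    assert remaining == sorted(remaining, reverse=True)


# ---------------------------------------------------------------------------
# comparator selectors
# ---------------------------------------------------------------------------


def test_complementarity_prefers_richer_disjoint_cell():
    recs = [
        _rec("a", "c1", ss="1-9"),
        _rec("b", "c1", ss="1-9"),
        _rec("c", "c2", ss="1-9"),
    ]
    sel = complementarity_select(recs, 2)
    assert sel.ordered_cells == ["c1", "c2"]


def test_complementarity_matches_brute_force_set_cover():
    # 4 cells x 4 species incidence with a known greedy solution
    incidence = {
        "c1": {"s1", "s2", "s3"},
        "c2": {"s3", "s4"},
        "c3": {"s1", "s4"},
        "c4": {"s2"},
    }
    recs = [
        _rec(s, c, ss="1-9") for c, ss_ in incidence.items() for s in sorted(ss_)
    ]
    sel = complementarity_select(recs, 4)
    # greedy cover: c1 (3 new), c2 (1 new, ties broken by id) -> all covered;
    # second pass: c3 lifts two species to level 2, then c4
    assert sel.ordered_cells == ["c1", "c2", "c3", "c4"]


def test_complementarity_deepens_after_full_coverage():
    recs = [
        _rec("a", "c1", ss="1-9"),
        _rec("b", "c1", ss="1-9"),
        _rec("a", "c2", ss="1-9"),
        _rec("b", "c3", ss="1-9"),
    ]
    sel = complementarity_select(recs, 3)
    assert sel.ordered_cells[0] == "c1"  # covers everything at once
    assert set(sel.ordered_cells[1:]) == {"c2", "c3"}


def test_hotspot_ranks_by_distinct_richness():
    recs = (
        [_rec(f"s{i}", "c1", ss="1-9") for i in range(3)]
        + [_rec("s0", "c2", ss="1-9")]
        + [_rec(f"s{i}", "c3", ss="1-9") for i in range(2)]
    )
    sel = hotspot_select(recs, 3)
    assert sel.ordered_cells == ["c1", "c3", "c2"]


def test_hotspot_ties_break_by_cell_id():
    recs = [_rec("a", "c2", ss="1-9"), _rec("b", "c1", ss="1-9")]
    assert hotspot_select(recs, 2).ordered_cells == ["c1", "c2"]


def test_random_ensemble_terminal_rer_equals_full_protection(worked_records):
    db = build_local_extinction_db(worked_records, None, CFG, 1.0)
    cells = sorted({r.cell_id for r in worked_records})
    ens = random_select(
        worked_records, len(cells), n_repeats=5, seed=1, db=db
    )
    full = compute_rer(db, db.cells).value
    for sel in ens.selections:
        assert sel.rer_curve[-1] == pytest.approx(full, abs=1e-9)
    assert np.all(np.diff(ens.rer_mean) >= -1e-12)


def test_selection_rejects_duplicates():
    with pytest.raises(ValueError):
        PASelection("x", ["c1", "c1"], 2)
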