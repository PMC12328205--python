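import numpy as np
import pytest

from biogeoclim.areas import FIVE_REGIONS
from biogeoclim.dec import BiogeoParams, EpochSchedule
from biogeoclim.niche import extract_climate
from biogeoclim.simulate import (SimulationConfig, generate_climate_grid,
                                 generate_climate_stack, sample_occurrences,
                                 simulate_dec_history, simulate_tree)
from biogeoclim.statespace import build_state_space


# ------------------------------------------------------------------ trees

def test_pure_birth_tree_is_ultrametric_with_exact_tip_count():
    cfg = SimulationConfig(seed=2, birth_rate=0.2, death_rate=0.0, n_tips=50)
    t = simulate_tree(cfg)
    assert t.n_tips == 50
    assert np.allclose(t.ages[: t.n_tips], 0.0)


def test_same_seed_same_newick():
    cfg = SimulationConfig(seed=9, n_tips=25)
    assert simulate_tree(cfg).to_newick() == simulate_tree(cfg).to_newick()


def test_pure_birth_mean_root_age_matches_closed_form():
    lam, n, reps = 0.2, 20, 200
    expected = sum(1.0 / (lam * k) for k in range(2, n + 1))
    ages = []
    for s in range(reps):
        cfg = SimulationConfig(seed=s, birth_rate=lam, death_rate=0.0, n_tips=n)
        ages.append(simulate_tree(cfg).root_age)
    assert np.mean(ages) == pytest.approx(expected, rel=0.15)


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(birth_rate=0.1, death_rate=0.2)
    with pytest.raises(ValueError):
        simulate_tree(SimulationConfig(n_tips=1))


# ------------------------------------------------------------ DEC histories

def test_zero_rates_copy_root_range_everywhere(small_tree, space5):
    rng = np.random.default_rng(4)
    hist = simulate_dec_history(small_tree, BiogeoParams(d=0.0, e=0.0),
                                space5, rng=rng)
    ranges = set(hist.tip_ranges.values())
    assert len(ranges) == 1
    assert len(next(iter(ranges))) == 1


def test_history_reproducible_and_consistent(small_tree, space5):
    h1 = simulate_dec_history(small_tree, BiogeoParams(d=0.05, e=0.01), space5,
                              rng=np.random.default_rng(6))
    h2 = simulate_dec_history(small_tree, BiogeoParams(d=0.05, e=0.01), space5,
                              rng=np.random.default_rng(6))
    assert h1.tip_ranges == h2.tip_ranges
    assert (h1.node_states == h2.node_states).all()
    # no tip carries the null range
    assert all(len(v) > 0 for v in h1.tip_ranges.values())


def test_barrier_epochs_suppress_crossings(space5):
    """Dispersal into penalized pairs concentrates in open epochs."""
    k = space5.k
    m_pen = np.full((k, k), 0.01)
    cfg = SimulationConfig(seed=14, n_tips=12)
    tree = simulate_tree(cfg)
    half = tree.root_age / 2
    sched = EpochSchedule(k=k, breaks=(half,),
                          multipliers=(np.ones((k, k)), m_pen))
    open_events = closed_events = 0
    open_time = tree.root_age - half
    for rep in range(100):
        rng = np.random.default_rng([55, rep])
        h = simulate_dec_history(tree, BiogeoParams(d=0.05, e=0.005), space5,
                                 schedule=sched, rng=rng)
        for ev in h.branch_events:
            if ev["kind"] != "dispersal":
                continue
            if ev["age"] > half:
                open_events += 1
            else:
                closed_events += 1
    assert open_events > 5 * max(closed_events, 1)


def test_event_log_matches_node_states(small_tree, space5):
    rng = np.random.default_rng(21)
    h = simulate_dec_history(small_tree, BiogeoParams(d=0.05, e=0.02), space5,
                             rng=rng)
    # replay: each branch's event chain connects parent-side start state to
    # the recorded child state
    starts = {}
    for ev in h.clado_events:
        kids = small_tree.children[ev["node"]]
        starts[kids[0]] = ev["left_state"]
        starts[kids[1]] = ev["right_state"]
    chains = {}
    for ev in h.branch_events:
        chains.setdefault(ev["branch_child"], []).append(ev)
    for child, evs in chains.items():
        evs.sort(key=lambda e: -e["age"])
        assert evs[0]["from_state"] == starts.get(child, evs[0]["from_state"])
        assert evs[-1]["to_state"] == h.node_states[child]


# ---------------------------------------------------------------- climate

def test_noise_free_equator_value_exact():
    cfg = SimulationConfig(seed=1, mat_noise_sd=0.0)
    grids = generate_climate_grid(cfg, "middle Norian", 222.4, land_mask="all")
    mat = grids["MAT"]
    eq_row = int(np.argmin(np.abs(mat.lats)))
    assert np.max(mat.values[eq_row]) <= cfg.equator_mat_c
    assert mat.values[eq_row].max() == pytest.approx(
        cfg.equator_mat_c - cfg.mat_gradient_c_per_deg * abs(mat.lats[eq_row]))


def test_arid_band_trough_depth():
    cfg = SimulationConfig(seed=2, map_noise_sd=10.0)
    grids = generate_climate_grid(cfg, "middle Norian", 222.4, land_mask="all")
    mapg = grids["MAP"]
    lats = mapg.lats
    lo, hi = cfg.arid_band
    inside = mapg.values[(lats >= lo) & (lats <= hi)]
    outside = mapg.values[(lats < lo) | (lats > hi)]
    depth = outside.mean() - inside.mean()
    assert depth == pytest.approx(cfg.arid_trough_mm, rel=0.1)


def test_same_seed_identical_grids():
    cfg = SimulationConfig(seed=5)
    a = generate_climate_stack(cfg)
    b = generate_climate_stack(cfg)
    for sl in a:
        for var in a[sl]:
            assert np.array_equal(a[sl][var].values, b[sl][var].values)
            assert np.array_equal(a[sl][var].land, b[sl][var].land)


def test_grid_spacing_must_divide():
    cfg = SimulationConfig(seed=1, grid_spacing_deg=7.0)
    with pytest.raises(ValueError, match="spacing"):
        generate_climate_grid(cfg, "Rhaetian", 204.9)


# ------------------------------------------------------------- occurrences

def test_niche_centred_sampling_stays_in_band():
    cfg = SimulationConfig(seed=8, mat_noise_sd=0.2, map_noise_sd=10.0)
    # niche matching the arid band's climate: MAP near base - trough
    cfg.niche_truth = {"lagerpetid": (
        cfg.equator_mat_c - 0.45 * 20, 2.0,
        cfg.map_base_mm - cfg.arid_trough_mm, 60.0)}
    stack = {"middle Norian": generate_climate_grid(
        cfg, "middle Norian", 222.4, land_mask="all")}
    recs = sample_occurrences(stack, cfg, {"lagerpetid": 100})
    lo, hi = cfg.arid_band
    inside = sum(lo <= r.palaeolat <= hi for r in recs)
    assert inside > 80


def test_extraction_recovers_niche_mean(mimic_grids):
    cfg = SimulationConfig(seed=3)
    stack = generate_climate_stack(cfg, land_mask="all")
    recs = sample_occurrences(stack, cfg, {"pterosaur": 150})
    df = extract_climate(recs, stack)
    mu, sd = cfg.niche_truth["pterosaur"][0], cfg.niche_truth["pterosaur"][1]
    se = sd / np.sqrt(len(df))
    # sampling weights x available climate: mean within a few SE of truth
    assert abs(df["MAT"].mean() - mu) < 4 * se


def test_zero_occurrences_rejected():
    cfg = SimulationConfig(seed=1)
    stack = {"Rhaetian": generate_climate_grid(cfg, "Rhaetian", 204.9,
                                               land_mask="all")}
    with pytest.raises(ValueError, match=">= 1"):
        sample_occurrences(stack, cfg, {"pterosaur": 0})


def test_occurrence_sampling_reproducible():
    cfg = SimulationConfig(seed=6)
    stack = generate_climate_stack(cfg, land_mask="all")
    r1 = sample_occurrences(stack, cfg, {"pterosaur": 10},
                            rng=np.random.default_rng(1))
    r2 = sample_occurrences(stack, cfg, {"pterosaur": 10},
                            rng=np.random.default_rng(1))
    assert [r.palaeolat for r in r1] == [r.palaeolat for r in r2]
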