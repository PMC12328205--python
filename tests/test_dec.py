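import math

import numpy as np
import pytest
from scipy.linalg import expm

from biogeoclim.areas import AreaScheme, CONTINENTAL_AREAS
from biogeoclim.dec import (BiogeoParams, EpochSchedule, anagenetic_rate_matrix,
                            ancestral_ranges, cladogenesis_table, fit_ml,
                            tree_loglik, DECModel)
from biogeoclim.statespace import build_state_space
from biogeoclim.trees import parse_newick

from _oracles import dense_loglik_and_marginals


# ---------------------------------------------------------------- state space

def test_state_space_counts_and_order(space5):
    assert space5.n_states == 32  # 2^5 including the null range
    sizes = [len(s) for s in space5.states]
    assert sizes == sorted(sizes)
    assert space5.states[0] == frozenset()


def test_state_space_cap():
    space = build_state_space(CONTINENTAL_AREAS, max_range_size=2)
    assert space.n_states == 1 + 7 + 21
    with pytest.raises(ValueError):
        build_state_space(CONTINENTAL_AREAS, max_range_size=0)


def test_state_space_refuses_explosion():
    big = AreaScheme(labels=tuple(f"a{i}" for i in range(13)))
    with pytest.raises(ValueError, match="force"):
        build_state_space(big)
    assert build_state_space(big, force=True).n_states == 2 ** 13


# ---------------------------------------------------------------- rate matrix

def test_rate_matrix_basic_entries(space2):
    params = BiogeoParams(d=0.1, e=0.03)
    Q = anagenetic_rate_matrix(space2, params)
    i1 = space2.index("A")
    i12 = space2.index(["A", "B"])
    assert Q[i1, i12] == pytest.approx(0.1)
    assert Q[i1, 0] == pytest.approx(0.03)
    assert np.allclose(Q.sum(axis=1), 0.0)
    assert np.all(Q[0] == 0.0)


def test_rate_matrix_three_area_expansion_sum(space3):
    # R = {A, B} gaining C collects d from both sources: 2 * 0.2 = 0.4
    params = BiogeoParams(d=0.2, e=0.05)
    Q = anagenetic_rate_matrix(space3, params)
    r = space3.index(["A", "B"])
    full = space3.index(["A", "B", "C"])
    assert Q[r, full] == pytest.approx(0.4)
    assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)


def test_zero_multipliers_leave_only_contraction(space2):
    Q = anagenetic_rate_matrix(space2, BiogeoParams(d=0.1, e=0.03),
                               np.zeros((2, 2)))
    i1 = space2.index("A")
    assert Q[i1, space2.index(["A", "B"])] == 0.0
    assert Q[i1, 0] == pytest.approx(0.03)


def test_exponentials_are_stochastic(space3, rng):
    Q = anagenetic_rate_matrix(space3, BiogeoParams(d=0.31, e=0.17))
    for t in (0.01, 1.0, 25.0):
        P = expm(Q * t)
        assert np.all(P >= -1e-12)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-8)


# ---------------------------------------------------------------- cladogenesis

def test_dec_singleton_identity(space2):
    table = cladogenesis_table(space2, BiogeoParams(d=0.1, e=0.1)).as_dict()
    i1 = space2.index("A")
    assert table[i1] == [(i1, i1, 1.0)]


def test_dec_two_area_parent_six_events(space2):
    table = cladogenesis_table(space2, BiogeoParams(d=0.1, e=0.1)).as_dict()
    events = table[space2.index(["A", "B"])]
    assert len(events) == 6
    assert all(w == pytest.approx(1 / 6) for _, _, w in events)


def test_bayarealike_copies_range(space3):
    params = BiogeoParams(d=0.1, e=0.1, model="BAYAREALIKE")
    table = cladogenesis_table(space3, params).as_dict()
    for pi in range(1, space3.n_states):
        assert table[pi] == [(pi, pi, 1.0)]


def test_divalike_vicariance_only_for_widespread(space3):
    params = BiogeoParams(d=0.1, e=0.1, model="DIVALIKE")
    table = cladogenesis_table(space3, params).as_dict()
    full = space3.index(["A", "B", "C"])
    events = table[full]
    # 2^3 - 2 = 6 ordered bipartitions of a 3-area range
    assert len(events) == 6
    for l, r, _ in events:
        assert space3.states[l] | space3.states[r] == space3.states[full]
        assert not space3.states[l] & space3.states[r]


def test_founder_weight_and_normalization(space2):
    params = BiogeoParams(d=0.1, e=0.1, j=0.5)
    table = cladogenesis_table(space2, params).as_dict()
    i1 = space2.index("A")
    events = table[i1]
    # identity (weight 1) + two ordered jumps into B (weight j each)
    assert len(events) == 3
    total = 1.0 + 2 * 0.5
    probs = sorted(w for _, _, w in events)
    assert probs == pytest.approx(sorted([1 / total, 0.5 / total, 0.5 / total]))
    for pi, evs in table.items():
        assert sum(w for _, _, w in evs) == pytest.approx(1.0)


# ---------------------------------------------------------------- likelihood

def test_single_branch_persistence_closed_form():
    scheme = AreaScheme(labels=("A",))
    space = build_state_space(scheme)
    tree = parse_newick("A:10;", root_age=10)
    lnl = tree_loglik(tree, {"A": "A"}, space, BiogeoParams(d=0.7, e=0.1))
    assert lnl == pytest.approx(-1.0, abs=1e-10)


def test_no_events_possible_root_averaging(tree2, space2):
    # d = e = 0, both tips in A: only root {A} survives the averaging
    lnl = tree_loglik(tree2, {"x": "A", "y": "A"}, space2,
                      BiogeoParams(d=0.0, e=0.0))
    assert lnl == pytest.approx(math.log(1 / 3), abs=1e-12)


def test_missing_tip_rejected(tree2, space2):
    with pytest.raises(KeyError, match="zz"):
        tree_loglik(tree2, {"x": "A", "zz": "B"}, space2, BiogeoParams(d=0.1, e=0.1))


CASES = [
    ("(x:4,y:7);", 7.0, {"x": "A", "y": "B"}, dict(d=0.05, e=0.02, j=0.0), 2, None),
    ("(x:4,y:7);", 7.0, {"x": "A", "y": "A"}, dict(d=0.11, e=0.06, j=0.8), 2, None),
    ("((x:2,y:2):3,z:5);", 5.0, {"x": "A", "y": "B", "z": "C"},
     dict(d=0.07, e=0.03, j=0.0), 3, None),
    ("((x:2,y:2):3,z:5);", 5.0, {"x": "A", "y": "A", "z": "B"},
     dict(d=0.2, e=0.1, j=1.5), 3, None),
    ("((x:2,y:2):3,z:5);", 5.0, {"x": "C", "y": "B", "z": "B"},
     dict(d=0.07, e=0.03, j=0.0), 3, "epochs"),
]


@pytest.mark.parametrize("nwk,root_age,tips,pars,k,sched", CASES)
def test_pruning_matches_dense_enumeration(nwk, root_age, tips, pars, k, sched):
    scheme = AreaScheme(labels=("A", "B", "C")[:k])
    space = build_state_space(scheme)
    tree = parse_newick(nwk, root_age=root_age)
    params = BiogeoParams(model="DEC", **pars)
    schedule = None
    if sched == "epochs":
        m = np.ones((k, k)); m[0, 1] = m[1, 0] = 0.2
        schedule = EpochSchedule(k=k, breaks=(3.5, 1.5),
                                 multipliers=(np.ones((k, k)), m, np.ones((k, k))))
    lnl = tree_loglik(tree, tips, space, params, schedule)
    oracle_lnl, oracle_marg = dense_loglik_and_marginals(
        tree, tips, space, params, schedule)
    assert lnl == pytest.approx(oracle_lnl, abs=1e-8)
    marg = ancestral_ranges(tree, tips, space, params, schedule)
    assert np.max(np.abs(marg - oracle_marg)) < 1e-8
    assert np.allclose(marg.sum(axis=1), 1.0, atol=1e-9)


def test_marginals_limit_case(space2):
    tree = parse_newick("(x:5,y:5);", root_age=5)
    marg = ancestral_ranges(tree, {"x": "A", "y": "A"}, space2,
                            BiogeoParams(d=1e-9, e=1e-9))
    assert marg[tree.root, space2.index("A")] == pytest.approx(1.0, abs=1e-6)


def test_marginals_invariant_to_child_swap(space2):
    t1 = parse_newick("(x:5,y:5);", root_age=5)
    t2 = parse_newick("(y:5,x:5);", root_age=5)
    params = BiogeoParams(d=0.08, e=0.02)
    m1 = ancestral_ranges(t1, {"x": "A", "y": "B"}, space2, params)
    m2 = ancestral_ranges(t2, {"x": "A", "y": "B"}, space2, params)
    assert np.allclose(m1[t1.root], m2[t2.root], atol=1e-12)


# ---------------------------------------------------------------- ML fitting

def test_nested_j_never_hurts(tree3, space3):
    tips = {"x": "A", "y": "B", "z": "C"}
    plain = fit_ml(tree3, tips, space3, compute_marginals=False)
    plus_j = fit_ml(tree3, tips, space3, founder=True, compute_marginals=False)
    assert plus_j.loglik >= plain.loglik - 1e-6
    assert plus_j.aic == pytest.approx(2 * 3 - 2 * plus_j.loglik)


def test_identical_tips_drive_d_to_lower_bound():
    scheme = AreaScheme(labels=("A", "B"))
    space = build_state_space(scheme)
    nwk = "((a:1,b:1):1,(c:1,d:1):1);"
    tree = parse_newick(nwk, root_age=2)
    fit = fit_ml(tree, {t: "A" for t in "abcd"}, space, compute_marginals=False)
    # flat likelihood near zero: the optimizer parks d at a negligible rate
    assert fit.params.d < 1e-4


def test_constrained_schedule_never_beats_free(small_tree, space5):
    from biogeoclim.simulate import SimulationConfig, simulate_dec_history

    rng = np.random.default_rng(9)
    hist = simulate_dec_history(small_tree, BiogeoParams(d=0.03, e=0.01),
                                space5, rng=rng)
    free = fit_ml(small_tree, hist.tip_ranges, space5, compute_marginals=False)
    k = space5.k
    m = np.full((k, k), 0.05)
    sched = EpochSchedule(k=k, breaks=(), multipliers=(m,))
    constrained = fit_ml(small_tree, hist.tip_ranges, space5, schedule=sched,
                         compute_marginals=False)
    assert constrained.loglik <= free.loglik + 1e-6


def test_estimator_interface(small_tree, space5):
    from biogeoclim.simulate import simulate_dec_history

    rng = np.random.default_rng(4)
    hist = simulate_dec_history(small_tree, BiogeoParams(d=0.03, e=0.01),
                                space5, rng=rng)
    est = DECModel().fit(small_tree, hist.tip_ranges)
    assert est.d_ > 0
    assert est.node_marginals_.shape == (small_tree.n_nodes, space5.n_states)
    assert np.allclose(est.node_marginals_.sum(axis=1), 1.0, atol=1e-9)
    assert "scheme" in est.get_params()
    payload = est.fit_result_.to_json()
    assert '"loglik"' in payload


def test_aic_prefers_founder_on_jump_heavy_data(space5):
    """Model selection recovers '+j' when founder events dominate."""
    from biogeoclim.simulate import SimulationConfig, simulate_dec_history, simulate_tree

    wins = 0
    n_rep = 20
    for rep in range(n_rep):
        cfg = SimulationConfig(seed=500 + rep, n_tips=40)
        tree = simulate_tree(cfg)
        rng = np.random.default_rng([77, rep])
        hist = simulate_dec_history(
            tree, BiogeoParams(d=0.005, e=0.005, j=2.5), space5, rng=rng)
        plain = fit_ml(tree, hist.tip_ranges, space5, compute_marginals=False)
        withj = fit_ml(tree, hist.tip_ranges, space5, founder=True,
                       compute_marginals=False)
        wins += withj.aic < plain.aic
    assert wins >= 0.8 * n_rep
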