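import numpy as np
import pytest
from scipy import stats as sps

from biogeoclim.climate import ClimateGrid
from biogeoclim.niche import (ClimateNichePCA, NicheError, assign_niche_groups,
                              distribution_diagnostics, extract_climate,
                              pairwise_wilcoxon, permutation_manova,
                              raincloud_summary, run_pca)
from biogeoclim.occurrences import OccurrenceRecord
from biogeoclim.simulate import SimulationConfig, generate_climate_stack


def _grid(values, var="MAT", land=None, slice_name="middle Norian"):
    values = np.asarray(values, dtype=float)
    lats = np.arange(-80, 90, 20.0)[: values.shape[0]]
    lons = np.arange(-160, 180, 20.0)[: values.shape[1]]
    if land is None:
        land = np.ones_like(values, dtype=bool)
    return ClimateGrid(var, slice_name, 222.4, lats, lons, values, land)


def _rec(i, lat, lon, early="middle Norian", late=None, clade="pterosaur"):
    return OccurrenceRecord(
        specimen_id=f"N{i}", taxon=f"tax{i}", clade=clade, locality_id=f"L{i}",
        palaeolat=lat, palaeolon=lon, stage_early=early,
        stage_late=late or early,
    ).validate()


def _stack_for(slices, base):
    out = {}
    for k, (sl, val) in enumerate(slices.items()):
        per = {}
        for v, off in (("MAT", 0), ("MAP", 1000), ("TSEAS", 3), ("PSEAS", 40)):
            per[v] = _grid(np.full((9, 17), val + off), var=v, slice_name=sl)
        out[sl] = per
    return out


# ------------------------------------------------------------- extraction

def test_nearest_cell_identity_lookup():
    stack = _stack_for({"middle Norian": 25.0}, 0)
    df = extract_climate([_rec(1, -80.0, -160.0)], stack)
    assert df.loc[0, "MAT"] == pytest.approx(25.0)


def test_two_stage_record_gets_mean_of_slices():
    stack = _stack_for({"middle Norian": 20.0, "late Norian": 30.0}, 0)
    rec = _rec(1, 0.0, 0.0, early="middle Norian", late="late Norian")
    df = extract_climate([rec], stack)
    assert df.loc[0, "MAT"] == pytest.approx(25.0)
    assert df.loc[0, "n_slices"] == 2


def test_sea_cell_falls_back_to_nearest_land():
    vals = np.arange(9 * 17, dtype=float).reshape(9, 17)
    land = np.ones((9, 17), bool)
    land[4, 8] = False  # the cell nearest to (0, 0)
    per = {v: _grid(vals, var=v, land=land) for v in ("MAT", "MAP", "TSEAS", "PSEAS")}
    df = extract_climate([_rec(1, 0.0, 0.0)], {"middle Norian": per})
    # nearest land neighbours are at grid distance 1; deterministic pick
    assert df.loc[0, "MAT"] in {vals[3, 8], vals[5, 8], vals[4, 7], vals[4, 9]}
    land[:, :] = False
    with pytest.raises(NicheError, match="no land cell"):
        extract_climate([_rec(1, 0.0, 0.0)], {"middle Norian": per}, strict=True)


def test_gradient_grid_extraction_recovers_generator_slope():
    cfg = SimulationConfig(seed=5, mat_noise_sd=0.0, map_noise_sd=0.0,
                           tseas_noise_sd=0.0, pseas_noise_sd=0.0)
    stack = generate_climate_stack(cfg, land_mask="all")
    recs = [_rec(i, lat, 10.0) for i, lat in enumerate(np.arange(-60, 61, 5.0))]
    df = extract_climate(recs, stack)
    slope = np.polyfit(np.abs(df["palaeolat"]), df["MAT"], 1)[0]
    assert slope == pytest.approx(-cfg.mat_gradient_c_per_deg, rel=0.05)


def test_group_labels_and_boundary_straddlers(mimic_collapsed, mimic_grids):
    df = extract_climate(mimic_collapsed, mimic_grids)
    grouped = assign_niche_groups(df)
    sizes = grouped.groupby("group").size().to_dict()
    assert sizes == {"pterosaur": 23, "pre-Norian lagerpetid": 9,
                     "Norian-Rhaetian lagerpetid": 17}
    assert len(df) - len(grouped) == 4  # the Carnian/Norian straddlers


# ------------------------------------------------------------------- PCA

def test_pca_standardization_and_reconstruction(rng):
    X = rng.normal(size=(40, 4)) @ rng.normal(size=(4, 4))
    ord_ = run_pca(X)
    assert np.allclose(ord_.standardized.mean(axis=0), 0, atol=1e-9)
    assert np.allclose(ord_.standardized.std(axis=0, ddof=1), 1, atol=1e-9)
    assert np.allclose(ord_.loadings.T @ ord_.loadings, np.eye(4), atol=1e-9)
    recon = ord_.scores @ ord_.loadings.T
    assert np.max(np.abs(recon - ord_.standardized)) < 1e-8
    assert ord_.explained_variance.sum() == pytest.approx(4.0)
    # eigenvalue 1 equals the variance of PC1 scores
    assert np.var(ord_.scores[:, 0], ddof=1) == pytest.approx(
        ord_.explained_variance[0])


def test_pca_scores_invariant_to_affine_rescaling(rng):
    X = rng.normal(size=(30, 4))
    a = run_pca(X)
    Y = X * np.array([3.0, 0.5, 10.0, 1.0]) + np.array([5, -2, 0, 100.0])
    b = run_pca(Y)
    assert np.allclose(a.scores, b.scores, atol=1e-8)


def test_pca_correlated_pair_loads_on_first_component(rng):
    z = rng.normal(size=50)
    X = np.column_stack([z, z * 2 + 1e-9 * rng.normal(size=50),
                         rng.normal(size=50), rng.normal(size=50)])
    ord_ = run_pca(X)
    assert ord_.explained_variance[0] == pytest.approx(2.0, abs=0.35)


def test_pca_matches_svd_oracle_up_to_sign(rng):
    X = rng.normal(size=(4, 4)) + 2.0
    ord_ = run_pca(X)
    Z = (X - X.mean(0)) / X.std(0, ddof=1)
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    oracle = U * s
    for k in range(oracle.shape[1]):
        assert (np.allclose(ord_.scores[:, k], oracle[:, k], atol=1e-8)
                or np.allclose(ord_.scores[:, k], -oracle[:, k], atol=1e-8))


def test_pca_rejects_constant_column(rng):
    X = rng.normal(size=(10, 4))
    X[:, 2] = 7.0
    with pytest.raises(NicheError, match="zero variance"):
        ClimateNichePCA().fit(X)


# ---------------------------------------------------------------- MANOVA

def test_manova_requires_seed_and_groups(rng):
    X = rng.normal(size=(12, 4))
    g = np.array(["a"] * 6 + ["b"] * 6)
    with pytest.raises(NicheError, match="seed"):
        permutation_manova(X, g)
    with pytest.raises(NicheError, match="99"):
        permutation_manova(X, g, n_perm=50, seed=1)


def test_manova_detects_large_shift(rng):
    X = rng.normal(size=(30, 4))
    X[15:] += 5.0  # 5-SD mean shift
    g = np.array(["a"] * 15 + ["b"] * 15)
    res = permutation_manova(X, g, n_perm=999, seed=2)
    assert res.p_value <= 0.01


def test_manova_reproducible_under_seed(rng):
    X = rng.normal(size=(24, 4))
    g = np.array(["a", "b", "c"] * 8)
    r1 = permutation_manova(X, g, n_perm=199, seed=42, pairwise=True)
    r2 = permutation_manova(X, g, n_perm=199, seed=42, pairwise=True)
    assert r1.p_value == r2.p_value
    assert (r1.pairwise["p_adjusted"] == r2.pairwise["p_adjusted"]).all()
    assert len(r1.pairwise) == 3


def test_manova_null_p_values_uniform():
    """Under exchangeable groups the permutation p-value is ~ Uniform."""
    rng = np.random.default_rng(7)
    ps = []
    for _ in range(200):
        X = rng.normal(size=(24, 4))
        g = np.array(["a"] * 12 + ["b"] * 12)
        ps.append(permutation_manova(X, g, n_perm=199,
                                     seed=int(rng.integers(2**31))).p_value)
    ks = sps.kstest(ps, "uniform")
    assert ks.pvalue > 0.01


def test_manova_wilks_option(rng):
    X = rng.normal(size=(20, 4))
    g = np.array(["a"] * 10 + ["b"] * 10)
    res = permutation_manova(X, g, n_perm=199, seed=3, stat="wilks")
    assert 0.0 < res.p_value <= 1.0


# -------------------------------------------------------------- Wilcoxon

def test_wilcoxon_exact_small_sample():
    df = pairwise_wilcoxon(np.array([1, 2, 3, 4, 5, 6.0]),
                           np.array(["a"] * 3 + ["b"] * 3))
    assert df.loc[0, "p"] == pytest.approx(0.1)


def test_wilcoxon_identical_groups():
    vals = np.array([1.0, 2, 3, 1, 2, 3])
    df = pairwise_wilcoxon(vals, np.array(["a"] * 3 + ["b"] * 3))
    assert df.loc[0, "p"] == pytest.approx(1.0)


def test_wilcoxon_all_tied_warns():
    with pytest.warns(UserWarning, match="tied"):
        df = pairwise_wilcoxon(np.ones(8), np.array(["a"] * 4 + ["b"] * 4))
    assert df.loc[0, "p"] == 1.0


def test_wilcoxon_null_calibration():
    rng = np.random.default_rng(11)
    ps = []
    for _ in range(200):
        vals = rng.normal(size=60)
        ps.append(pairwise_wilcoxon(vals, np.array(["a"] * 30 + ["b"] * 30),
                                    adjust=None).loc[0, "p"])
    assert sps.kstest(ps, "uniform").pvalue > 0.01


# ------------------------------------------------------------ diagnostics

def test_shapiro_normal_and_skewed():
    rng = np.random.default_rng(3)
    d = distribution_diagnostics(rng.normal(size=500))
    assert d["shapiro_w"] > 0.98
    rejections = 0
    for k in range(100):
        x = np.random.default_rng(k).exponential(size=100)
        rejections += distribution_diagnostics(x)["shapiro_p"] < 0.05
    assert rejections >= 95


def test_diagnostics_input_guards():
    with pytest.raises(NicheError):
        distribution_diagnostics([1.0, 2.0])
    with pytest.raises(NicheError, match="constant"):
        distribution_diagnostics(np.ones(10))


# -------------------------------------------------------------- raincloud

def test_raincloud_quartiles_and_extreme_whiskers():
    vals = np.arange(1.0, 11.0)
    out = raincloud_summary(vals, np.array(["g"] * 10))["g"]
    assert out["median"] == pytest.approx(5.5)
    assert out["q1"] == pytest.approx(3.25)
    assert out["q3"] == pytest.approx(7.75)
    assert out["whisker_low"] == 1.0 and out["whisker_high"] == 10.0
    assert out["kde"] is not None


def test_raincloud_single_value_and_group_order():
    out = raincloud_summary(np.array([4.0]), np.array(["g"]))["g"]
    assert len({out["median"], out["q1"], out["q3"], out["whisker_low"],
                out["whisker_high"]}) == 1
    two = raincloud_summary(np.array([1.0, 2, 9, 10]),
                            np.array(["a", "a", "b", "b"]))
    assert list(two) == ["a", "b"]
    assert two["a"]["median"] == pytest.approx(1.5)
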