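"""Design matrices, OLS fits, stepwise selection, distances, MDS."""

import numpy as np
import pandas as pd
import pytest

import srnfshape as ss
from srnfshape.regression_models import DistanceMatrix, model_table
from srnfshape.synthetic_data import base_surface, make_mode_fields


@pytest.fixture(scope="module")
def planted_table():
    rng = np.random.default_rng(0)
    n = 200
    scores = {
        "hippocampus": rng.normal(size=(n, 15)),
        "amygdala": rng.normal(size=(n, 15)),
        "putamen": rng.normal(size=(n, 15)),
    }
    coeffs = {
        "PSS": {
            "intercept": 15.0,
            "BDI": 0.25,
            ("PS", "amygdala", 4): 3.0,
            ("PS", "hippocampus", 2): 2.5,
            ("PSxage", "putamen", 1): 0.08,
        },
        "CTQTOT": {"intercept": 60.0, "age": 0.2, ("PS", "putamen", 2): -4.0},
    }
    table, _ = ss.simulate_clinical(scores, coeffs, noise_sd=3.0, seed=1)
    return table


def test_design_covariates_only(planted_table):
    design, y = ss.build_design(planted_table, model_table()[3])
    assert list(design.columns) == ["intercept", "age", "BDI"]
    assert y.name == "PSS"


def test_design_scores_only_has_45_score_columns(planted_table):
    design, _ = ss.build_design(planted_table, model_table()[4])
    assert design.shape[1] == 1 + 45  # intercept + 15 scores x 3 structures


def test_design_interactions_superset(planted_table):
    d1, _ = ss.build_design(planted_table, model_table()[1])
    d2, _ = ss.build_design(planted_table, model_table()[2])
    assert set(d2.columns) <= set(d1.columns)
    # 2 moderators x 5 scores x 3 structures extra columns
    assert d1.shape[1] - d2.shape[1] == 30


def test_design_missing_column_raises():
    table = pd.DataFrame({"age": [1.0], "PSS": [2.0]})
    with pytest.raises(KeyError):
        ss.build_design(table, model_table()[3])


def test_fit_exact_linear_model_r2_one(planted_table):
    design, _ = ss.build_design(planted_table, model_table()[3])
    y = 2.0 + 0.5 * design["age"] - 0.25 * design["BDI"]
    fit = ss.fit_ols(design, y)
    assert fit.adjusted_r2 > 1 - 1e-10
    assert np.abs(fit.model.resid).max() < 1e-8


def test_adjusted_r2_identity(planted_table):
    design, y = ss.build_design(planted_table, model_table()[2])
    fit = ss.fit_ols(design, y)
    expect = 1 - (1 - fit.r2) * (fit.n - 1) / (fit.n - fit.p - 1)
    assert np.isclose(fit.adjusted_r2, expect)
    assert fit.adjusted_r2 <= fit.r2
    assert fit.p_values.between(0, 1).all()


def test_null_design_adjusted_r2_near_zero():
    vals = []
    for s in range(20):
        rng = np.random.default_rng(s)
        design = pd.DataFrame(
            {"intercept": 1.0, "a": rng.normal(size=200), "b": rng.normal(size=200)}
        )
        y = pd.Series(rng.normal(size=200))
        vals.append(ss.fit_ols(design, y).adjusted_r2)
    assert -0.05 < np.mean(vals) < 0.05


def test_model_ordering_interactions_main_covariates(planted_table):
    fits = {}
    for m in (1, 2, 3):
        design, y = ss.build_design(planted_table, model_table()[m])
        fits[m] = ss.fit_ols(design, y).adjusted_r2
    assert fits[1] > fits[2] > fits[3]


def test_icv_addition_leaves_fit_unchanged(planted_table):
    base, y = ss.build_design(planted_table, model_table()[1])
    with_icv, _ = ss.build_design(planted_table, model_table()[9])
    r1 = ss.fit_ols(base, y).adjusted_r2
    r9 = ss.fit_ols(with_icv, y).adjusted_r2
    assert round(r1, 2) == round(r9, 2)


def test_bh_adjustment_never_decreases_pvalues(planted_table):
    design, y = ss.build_design(planted_table, model_table()[2])
    raw = ss.fit_ols(design, y)
    adj = ss.fit_ols(design, y, bh_adjust=True)
    terms = [t for t in raw.p_values.index if t != "intercept"]
    assert (adj.p_values[terms] >= raw.p_values[terms] - 1e-15).all()


def test_stepwise_selects_huge_effect_first():
    rng = np.random.default_rng(2)
    x = rng.normal(size=(100, 5))
    q, _ = np.linalg.qr(x)
    design = pd.DataFrame(q, columns=[f"x{i}" for i in range(5)])
    design.insert(0, "intercept", 1.0)
    y = pd.Series(50.0 * design["x2"] + rng.normal(scale=0.1, size=100))
    fit = ss.stepwise_select(design, y)
    assert "x2" in fit.selected_terms


def test_stepwise_recovers_planted_predictors():
    rng = np.random.default_rng(4)
    x = pd.DataFrame(rng.normal(size=(300, 23)), columns=[f"x{i}" for i in range(23)])
    x.insert(0, "intercept", 1.0)
    y = pd.Series(
        2.0 * x["x0"] - 1.5 * x["x1"] + 1.0 * x["x2"] + rng.normal(size=300)
    )
    fit = ss.stepwise_select(x, y)
    assert {"x0", "x1", "x2"} <= set(fit.selected_terms)


def test_stepwise_pvalue_variant_stricter_on_noise():
    rng = np.random.default_rng(8)
    x = pd.DataFrame(rng.normal(size=(300, 10)), columns=[f"x{i}" for i in range(10)])
    x.insert(0, "intercept", 1.0)
    y = pd.Series(rng.normal(size=300))
    fit = ss.stepwise_select(x, y, criterion="pvalue")
    assert len(fit.selected_terms) <= 2


def test_distance_matrix_identical_surfaces(grid32):
    mu = ss.center_and_scale(base_surface(grid32))
    d = ss.pairwise_distance_matrix([mu, mu.copy(), mu.copy()], mode="raw-L2")
    assert np.all(d.D == 0)


def test_distance_matrix_line_proportional(grid32):
    mu = ss.center_and_scale(base_surface(grid32))
    v1 = make_mode_fields(grid32, 1, seed=5, base=mu)[0].reshape(-1)
    line = ss.simulate_pc_line(mu, v1, seed=0)
    sub = line.surfaces[:6]
    d = ss.pairwise_distance_matrix(sub, mode="raw-L2")
    gaps = np.abs(line.x[:6, None] - line.x[None, :6])
    ratio = d.D[gaps > 0] / gaps[gaps > 0]
    assert ratio.std() / ratio.mean() < 1e-8


def test_elastic_distances_undo_planted_reparameterization(grid32):
    """Elastic registration undoes a planted reparameterization: the
    elastic distances of scrambled surfaces fall far below their raw
    unregistered distances and preserve the planted line ordering."""
    mu = ss.center_and_scale(base_surface(grid32))
    v1 = make_mode_fields(grid32, 1, seed=5, base=mu)[0]
    coeffs = (-0.6, 0.0, 0.6)
    aligned = [
        ss.center_and_scale(ss.GridSurface(grid32, mu.f + c * v1)) for c in coeffs
    ]
    scrambled = []
    for i, s in enumerate(aligned):
        gam = ss.random_diffeomorphism(grid32, amplitude=0.25, seed=40 + i)
        scrambled.append(ss.center_and_scale(ss.apply_reparam(s, gam)))
    d_raw = ss.pairwise_distance_matrix(scrambled, mode="raw-L2")
    d_elastic = ss.pairwise_distance_matrix(scrambled, mode="elastic")
    # registration recovers most of the parameterization-confounded distance
    for i in range(3):
        for j in range(i + 1, 3):
            assert d_elastic.D[i, j] < 0.25 * d_raw.D[i, j]
    # the widest planted gap remains the largest distance
    assert d_elastic.D[0, 2] > d_elastic.D[0, 1]
    assert d_elastic.D[0, 2] > d_elastic.D[1, 2]


def test_classical_mds_three_points_on_line():
    d = DistanceMatrix(np.array([[0.0, 1, 2], [1, 0, 1], [2, 1, 0]]), ["a", "b", "c"])
    emb = ss.classical_mds(d, 1)
    coords = np.sort(emb[:, 0])
    assert np.allclose(np.diff(coords), 1.0, atol=1e-10)
    assert abs(emb.mean()) < 1e-10


def test_two_medoids_separates_two_blobs():
    pts = np.concatenate([np.zeros(10), np.ones(10) * 5.0])
    d = DistanceMatrix(np.abs(pts[:, None] - pts[None, :]), list(range(20)))
    labels = ss.two_medoids(d)
    truth = np.concatenate([np.zeros(10), np.ones(10)])
    assert ss.clustering_accuracy(labels, truth) == 1.0
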