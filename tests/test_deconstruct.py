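import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import edconjoint as ec

from .oracles import normal_equations_ols, ols_inference


# ---------------------------------------------------------------------------
# binarization


@pytest.mark.parametrize("rating,expected", [
    (1, 0.0), (6, 0.0), (7, 100.0), (8, 100.0), (9, 100.0),
])
def test_binarize_top_three_boxes(rating, expected):
    assert ec.binarize(rating) == expected


def test_binarize_monotone_over_scale():
    vals = [ec.binarize(r) for r in range(1, 10)]
    assert vals == sorted(vals)
    assert set(vals) == {0.0, 100.0}


@pytest.mark.parametrize("bad", [0, 10, 5.5, -3])
def test_binarize_rejects_out_of_range(bad):
    with pytest.raises(ec.ModelError):
        ec.binarize(bad)


# ---------------------------------------------------------------------------
# individual OLS


def test_constant_response_exact_fit(small_book):
    X = ec.design_matrix(small_book, "r001")
    y = np.full(48, 100.0)
    m = ec.fit_respondent_model(X, y, "r001")
    assert m.constant == pytest.approx(100.0, abs=1e-9)
    assert all(abs(b) < 1e-9 for b in m.coefficients.values())
    assert m.residual_se == pytest.approx(0.0, abs=1e-9)


def test_noiseless_single_message_effect_recovered(small_book):
    """y = 20 + 30*presence(A1) recovers (20, 30, 0...) and agrees with the
    from-scratch normal-equations oracle."""
    X = ec.design_matrix(small_book, "r001")
    y = 20.0 + 30.0 * X["A1"].to_numpy()
    m = ec.fit_respondent_model(X, y, "r001")
    assert m.constant == pytest.approx(20.0, abs=1e-8)
    assert m.coefficients["A1"] == pytest.approx(30.0, abs=1e-8)
    others = [b for mid, b in m.coefficients.items() if mid != "A1"]
    assert np.allclose(others, 0.0, atol=1e-8)
    oracle = normal_equations_ols(X.to_numpy().tolist(), y.tolist())
    assert m.constant == pytest.approx(oracle[0], abs=1e-8)


def test_matches_normal_equations_oracle_on_noisy_data(small_book):
    rng = np.random.default_rng(21)
    X = ec.design_matrix(small_book, "r002")
    y = 100.0 * (rng.random(48) < 0.5)
    m = ec.fit_respondent_model(X, y, "r002")
    oracle = normal_equations_ols(X.to_numpy().tolist(), y.tolist())
    got = [m.constant] + [m.coefficients[c] for c in X.columns]
    assert np.allclose(got, oracle, atol=1e-8)


def test_linearity_in_response(small_book):
    rng = np.random.default_rng(3)
    X = ec.design_matrix(small_book, "r001")
    y = rng.random(48) * 100
    m1 = ec.fit_respondent_model(X, y)
    m2 = ec.fit_respondent_model(X, 2.5 * y)
    assert m2.constant == pytest.approx(2.5 * m1.constant)
    for mid in m1.coefficients:
        assert m2.coefficients[mid] == pytest.approx(2.5 * m1.coefficients[mid])


def test_residuals_orthogonal_to_design(small_book):
    """OLS conservation: y decomposes into fitted + residual with residuals
    orthogonal to every design column (so fitted + residual == y exactly)."""
    rng = np.random.default_rng(8)
    X = ec.design_matrix(small_book, "r003")
    y = 100.0 * (rng.random(48) < 0.4)
    m = ec.fit_respondent_model(X, y)
    beta = np.concatenate([[m.constant],
                           [m.coefficients[c] for c in X.columns]])
    A = np.hstack([np.ones((48, 1)), X.to_numpy()])
    resid = y - A @ beta
    assert np.allclose(A.T @ resid, 0.0, atol=1e-8)
    assert np.allclose(A @ beta + resid, y, atol=1e-10)


def test_rank_deficient_design_refused():
    X = np.zeros((10, 3))
    X[:, 0] = 1.0  # collinear with the intercept
    with pytest.raises(ec.ModelError, match="rank deficient"):
        ec.fit_respondent_model(X, np.zeros(10))


# ---------------------------------------------------------------------------
# group OLS


def test_group_recovers_shared_noiseless_profile(small_book, profiles):
    beta = profiles[1].utility_vector(small_book.instrument.message_ids)
    pairs = []
    for rid in small_book.respondent_ids:
        X = ec.design_matrix(small_book, rid)
        y = profiles[1].constant + X.to_numpy() @ beta
        pairs.append((X, y))
    gm = ec.fit_group_model(pairs, label="noiseless")
    assert gm.constant == pytest.approx(56.0, abs=1e-8)
    assert gm.coefficients["E3"] == pytest.approx(9.0, abs=1e-8)
    assert gm.coefficients["B6"] == pytest.approx(0.0, abs=1e-8)


def test_group_inference_matches_textbook_oracle():
    """coefficient, SE and t on a 10-row toy system against hand-rolled OLS
    inference; p is the matching two-sided t tail."""
    rng = np.random.default_rng(17)
    X = (rng.random((10, 3)) < 0.5).astype(float)
    X[0, 0] = 1 - X[0, 0]  # guard against constant columns
    y = rng.normal(50, 10, 10)
    gm = ec.fit_group_model([(X, y)], label="toy")
    beta, se, t = ols_inference(X.tolist(), y.tolist())
    names = ["x1", "x2", "x3"]
    assert gm.constant == pytest.approx(beta[0], abs=1e-8)
    for j, nm in enumerate(names, start=1):
        assert gm.coefficients[nm] == pytest.approx(beta[j], abs=1e-8)
        assert gm.std_errors[nm] == pytest.approx(se[j], abs=1e-8)
        assert gm.t_values[nm] == pytest.approx(t[j], abs=1e-8)
        p = 2 * stats.t.sf(abs(t[j]), df=10 - 4)
        assert gm.p_values[nm] == pytest.approx(p, abs=1e-8)
        assert gm.t_values[nm] == pytest.approx(
            gm.coefficients[nm] / gm.std_errors[nm])


def test_group_report_table_shape(standard_panel):
    frame = standard_panel["total"].to_frame()
    assert len(frame) == 37
    assert frame.iloc[0]["term"] == "Additive constant"
    body = frame.iloc[1:]
    assert list(body.coefficient) == sorted(body.coefficient, reverse=True)
    assert set(body.term) == set(standard_panel["book"].instrument.message_ids)


def test_empty_group_rejected():
    with pytest.raises(ec.ModelError, match="empty group"):
        ec.fit_group_model([], label="none")


@given(scale=st.floats(min_value=0.1, max_value=5.0))
def test_group_model_linearity(scale):
    rng = np.random.default_rng(1)
    X = (rng.random((12, 2)) < 0.5).astype(float)
    X[:3] = np.array([[1, 0], [0, 1], [1, 1]])
    y = rng.normal(0, 1, 12)
    g1 = ec.fit_group_model([(X, y)])
    g2 = ec.fit_group_model([(X, scale * y)])
    assert g2.constant == pytest.approx(scale * g1.constant, rel=1e-9, abs=1e-9)
    for nm in g1.coefficients:
        assert g2.coefficients[nm] == pytest.approx(
            scale * g1.coefficients[nm], rel=1e-9, abs=1e-9)
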