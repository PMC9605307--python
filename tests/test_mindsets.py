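import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import edconjoint as ec

from .conftest import make_models_from_vectors
from .oracles import oneway_anova_F, pearson_r


MSG_IDS = ec.default_instrument().message_ids


def _profile_vectors(profiles):
    return np.array([p.utility_vector(MSG_IDS) for p in profiles])


# ---------------------------------------------------------------------------
# correlation distance


def test_identical_vectors_distance_zero():
    u = np.arange(36, dtype=float)
    assert ec.correlation_distance(u, u) == pytest.approx(0.0, abs=1e-12)


def test_anticorrelated_vectors_distance_two():
    u = np.arange(36, dtype=float)
    assert ec.correlation_distance(u, -u) == pytest.approx(2.0, abs=1e-12)


def test_matches_from_scratch_pearson_oracle():
    rng = np.random.default_rng(2)
    u, v = rng.normal(size=36), rng.normal(size=36)
    expect = 1.0 - pearson_r(u.tolist(), v.tolist())
    assert ec.correlation_distance(u, v) == pytest.approx(expect, abs=1e-12)


def test_zero_variance_vector_rejected():
    with pytest.raises(ec.MindsetError, match="zero-variance"):
        ec.correlation_distance(np.ones(36), np.arange(36.0))


# ---------------------------------------------------------------------------
# clustering


@pytest.fixture(scope="module")
def separable_models(profiles):
    """30 respondents whose coefficient vectors duplicate the three
    published profiles exactly (10 each)."""
    V = _profile_vectors(profiles)
    vectors = np.repeat(V, 10, axis=0)
    return make_models_from_vectors(vectors, MSG_IDS), [g for g in range(3)
                                                        for _ in range(10)]


@pytest.mark.parametrize("seed", range(10))
def test_perfect_recovery_on_separable_profiles(separable_models, seed):
    models, truth = separable_models
    sol = ec.cluster_respondents(models, k=3, seed=seed, restarts=20)
    labels = [sol.assignment[m.respondent_id] for m in models]
    assert adjusted_rand_score(truth, labels) == 1.0
    assert sorted(sol.base_sizes) == [10, 10, 10]


def test_scale_invariance_of_assignment(separable_models):
    models, _ = separable_models
    sol1 = ec.cluster_respondents(models, k=3, seed=0, restarts=20)
    scaled = [ec.RespondentModel(
        respondent_id=m.respondent_id, constant=m.constant,
        coefficients={k: 10.0 * v for k, v in m.coefficients.items()},
        residual_se=m.residual_se) if m.respondent_id == "r001" else m
        for m in models]
    sol2 = ec.cluster_respondents(scaled, k=3, seed=0, restarts=20)
    # same partition (cluster indices may relabel): compare co-membership
    l1 = [sol1.assignment[m.respondent_id] for m in models]
    l2 = [sol2.assignment[m.respondent_id] for m in models]
    assert adjusted_rand_score(l1, l2) == 1.0


def test_k_bounds_rejected(separable_models):
    models, _ = separable_models
    with pytest.raises(ec.MindsetError):
        ec.cluster_respondents(models, k=1)
    with pytest.raises(ec.MindsetError):
        ec.cluster_respondents(models[:2], k=3)


# ---------------------------------------------------------------------------
# k selection


def test_two_separated_profiles_select_two():
    rng = np.random.default_rng(4)
    a = rng.normal(size=36) * 5
    b = -a
    vectors = np.vstack([np.tile(a, (15, 1)), np.tile(b, (15, 1))])
    vectors += rng.normal(0, 0.3, vectors.shape)
    models = make_models_from_vectors(vectors, MSG_IDS)
    chosen, profile = ec.select_k(models, range(2, 7), seed=0, restarts=20)
    assert chosen == 2
    assert profile[2] > 0.5


def test_homogeneous_noise_warns_low_separation():
    rng = np.random.default_rng(9)
    vectors = rng.normal(size=(40, 36))
    models = make_models_from_vectors(vectors, MSG_IDS)
    with pytest.warns(UserWarning, match="low cluster separation"):
        chosen, profile = ec.select_k(models, range(2, 7), seed=0, restarts=10)
    assert max(profile.values()) < 0.25


# ---------------------------------------------------------------------------
# ANOVA / Tukey comparison


def _manual_solution(vectors_by_group, ids):
    vectors = np.vstack(vectors_by_group)
    models = make_models_from_vectors(vectors, ids)
    assignment, sizes = {}, []
    i = 0
    for g, grp in enumerate(vectors_by_group):
        sizes.append(len(grp))
        for _ in grp:
            assignment[models[i].respondent_id] = g
            i += 1
    profiles = [ec.MindsetProfile(label=f"G{g + 1}", constant=50.0,
                                  utilities={})
                for g in range(len(vectors_by_group))]
    base = ec.solution_from_profiles(profiles, ids, sizes)
    base.assignment = assignment
    base.respondent_models = models
    return base


def test_identical_groups_give_null_anova(profiles):
    V = _profile_vectors(profiles)[0]
    groups = [np.tile(V, (4, 1)) for _ in range(3)]
    sol = _manual_solution(groups, MSG_IDS)
    out = ec.compare_mindsets(sol)
    assert (out.F == 0.0).all()
    assert (out.p == 1.0).all()
    assert not out.significant.any()
    assert out.degenerate.all()


def test_anova_matches_sum_of_squares_oracle():
    """3 groups x 3 respondents on two messages, checked against the textbook
    one-way ANOVA decomposition."""
    ids = ["A1", "B1"]
    g1 = np.array([[1.0, 5.0], [2.0, 6.0], [3.0, 4.0]])
    g2 = np.array([[4.0, 5.5], [5.0, 6.5], [6.0, 4.5]])
    g3 = np.array([[7.0, 5.2], [8.0, 6.2], [9.0, 4.2]])
    sol = _manual_solution([g1, g2, g3], ids)
    out = ec.compare_mindsets(sol).set_index("message")
    for j, mid in enumerate(ids):
        F_oracle, _, _ = oneway_anova_F([g[:, j].tolist() for g in (g1, g2, g3)])
        assert out.loc[mid, "F"] == pytest.approx(F_oracle, rel=1e-10)
    assert out.loc["A1", "significant"]
    # Tukey adjusted p-values present for every pair
    for c in ("tukey_p_1v2", "tukey_p_1v3", "tukey_p_2v3"):
        assert 0.0 <= out.loc["A1", c] <= 1.0
    assert out.loc["A1", "tukey_p_1v3"] < 0.05


# ---------------------------------------------------------------------------
# reliability


def test_noiseless_homogeneous_panel_fully_reliable():
    rng = np.random.default_rng(11)
    vec = rng.normal(size=36)
    models = make_models_from_vectors(np.tile(vec, (20, 1)), MSG_IDS)
    r1, r2 = ec.split_half_reliability(models, seed=0)
    assert r1 == pytest.approx(1.0, abs=1e-12)
    assert r2 == pytest.approx(1.0, abs=1e-12)


def test_reliability_deterministic_and_bounded(standard_panel):
    models = list(standard_panel["models"].values())
    r1 = ec.split_half_reliability(models, seed=3)
    r2 = ec.split_half_reliability(models, seed=3)
    assert r1 == r2
    assert all(-1.0 <= r <= 1.0 for r in r1)


# ---------------------------------------------------------------------------
# profile matching


def test_hungarian_matching_recovers_permuted_profiles(profiles):
    shuffled = [profiles[2], profiles[0], profiles[1]]
    sol = ec.solution_from_profiles(shuffled, MSG_IDS, [36, 38, 38])
    match = ec.match_to_profiles(sol, profiles, MSG_IDS)
    assert match == {0: 1, 1: 2, 2: 0}
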