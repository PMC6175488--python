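import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from beakrates import morpho, simulate
from beakrates.morpho import (
    CURVE_DISORDER,
    EDGE_INVERSION,
    USER_DISCREPANCY,
    LandmarkConfiguration,
    ShapeSpace,
    average_markups,
    bending_energy,
    bending_energy_matrix,
    gpa,
    pca,
    ppca,
    procrustes_distance,
    qc_markups,
    select_axes,
    slide_semilandmarks,
)

RNG = np.random.default_rng(42)

# printed planar triangles; oracle value computed by an independent
# brute-force optimizer over rotations and scale (equals sin 15 degrees)
EQUILATERAL = np.array([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]], float)
RIGHT_ISO = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float)
TRIANGLE_DISTANCE_ORACLE = 0.25881904510252074


def random_similarity(rng):
    R, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(R) < 0:
        R[:, 0] *= -1
    return rng.uniform(0.3, 3.0), R, rng.standard_normal(3)


# ------------------------------------------------------- procrustes distance
def test_procrustes_distance_zero_for_identical_and_similar_shapes():
    assert procrustes_distance(EQUILATERAL, EQUILATERAL) == pytest.approx(0, abs=1e-12)
    s, R, t = random_similarity(RNG)
    assert procrustes_distance(EQUILATERAL, s * EQUILATERAL @ R.T + t) < 1e-9


def test_procrustes_distance_matches_bruteforce_rotation_oracle():
    assert procrustes_distance(EQUILATERAL, RIGHT_ISO) == pytest.approx(
        TRIANGLE_DISTANCE_ORACLE, abs=1e-9
    )


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_procrustes_distance_is_a_pseudometric(seed):
    rng = np.random.default_rng(seed)
    a, b, c = (rng.standard_normal((6, 3)) for _ in range(3))
    dab, dba = procrustes_distance(a, b), procrustes_distance(b, a)
    assert dab == pytest.approx(dba, abs=1e-9)
    assert dab >= 0
    dac, dbc = procrustes_distance(a, c), procrustes_distance(b, c)
    assert dab <= dac + dbc + 1e-6


# ----------------------------------------------------------------------- GPA
def test_gpa_fixed_point_on_aligned_inputs(template):
    m, _ = simulate.simulate_markups(template, 4, 0.01, seed=0)
    aligned, cons, _ = gpa(list(m.users.values()))
    again, cons2, _ = gpa(list(aligned))
    np.testing.assert_allclose(again, aligned, atol=1e-6)


def test_gpa_collapses_similarity_copies_to_zero_ss(template):
    rng = np.random.default_rng(1)
    configs = []
    for _ in range(10):
        s, R, t = random_similarity(rng)
        configs.append(s * template.coords @ R.T + t)
    aligned, cons, ss = gpa(configs)
    assert ss < 1e-10
    for x in aligned:
        np.testing.assert_allclose(x, aligned[0], atol=1e-6)


def test_two_shape_gpa_matches_pairwise_superimposition_oracle():
    aligned, cons, ss = gpa([EQUILATERAL, RIGHT_ISO])
    # 2-shape GPA reduces to pairwise superimposition of unit-size shapes with
    # inner product cos(g) = sqrt(1 - d^2); the residual against the
    # unit-normalized consensus is 4 - 2*sqrt(2 + 2 cos g)
    cosg = np.sqrt(1 - TRIANGLE_DISTANCE_ORACLE**2)
    assert ss == pytest.approx(4 - 2 * np.sqrt(2 + 2 * cosg), rel=1e-3)


def test_gpa_invariant_to_input_order_and_pretransforms(template):
    rng = np.random.default_rng(2)
    m, _ = simulate.simulate_markups(template, 4, 0.02, seed=3)
    configs = [c.coords for c in m.users.values()]
    _, cons1, ss1 = gpa(configs)
    shuffled = [configs[i] for i in (2, 0, 3, 1)]
    s, R, t = random_similarity(rng)
    shuffled[0] = s * shuffled[0] @ R.T + t
    _, cons2, ss2 = gpa(shuffled)
    assert ss1 == pytest.approx(ss2, abs=1e-8)
    assert procrustes_distance(cons1, cons2) < 1e-6


def test_gpa_alignment_properties(template):
    m, _ = simulate.simulate_markups(template, 5, 0.02, seed=4)
    aligned, cons, _ = gpa(list(m.users.values()))
    for x in aligned:
        np.testing.assert_allclose(x.mean(axis=0), 0, atol=1e-9)
        assert np.sqrt((x**2).sum()) == pytest.approx(1.0, abs=1e-9)


def test_gpa_rejects_degenerate_input():
    with pytest.raises(ValueError, match="degenerate|coincide"):
        gpa([np.zeros((5, 3)), np.ones((5, 3))])


# ------------------------------------------------------------------ averaging
def test_average_of_single_user_is_identity(template):
    assert average_markups([template]) is template


def test_average_of_symmetric_pair_recovers_template(template):
    delta = 1e-4 * np.sin(np.arange(template.k))[:, None] * np.array([[1, -1, 0.5]])
    a = template.with_coords(template.coords + delta)
    b = template.with_coords(template.coords - delta)
    avg = average_markups([a, b])
    assert procrustes_distance(avg, template) < 1e-6


def test_average_of_noisy_users_is_closer_than_the_noise(template):
    noise_sd = 0.01
    m, _ = simulate.simulate_markups(template, 5, noise_sd, seed=6)
    avg = average_markups(list(m.users.values()))
    d_avg = procrustes_distance(avg, template)
    d_users = [procrustes_distance(u, template) for u in m.users.values()]
    assert d_avg < np.mean(d_users)


# ------------------------------------------------------------------------- QC
def test_qc_accepts_identical_users(template):
    m, _ = simulate.simulate_markups(template, 3, 0.0, seed=0)
    rep = qc_markups(m)
    assert all(v == "accept" for v in rep.verdicts.values())
    assert rep.measurement_error == pytest.approx(0, abs=1e-6)


def test_qc_flags_swapped_tomial_edges(template):
    m, _ = simulate.simulate_markups(
        template, 3, 0.004, [{"mode": "swap_tomial_edges", "user": 2}], seed=1
    )
    rep = qc_markups(m)
    assert EDGE_INVERSION in rep.reasons["user2"]
    assert rep.verdicts["user0"] == rep.verdicts["user1"] == "accept"


def test_qc_flags_shuffled_curve(template):
    m, _ = simulate.simulate_markups(
        template, 3, 0.004, [{"mode": "shuffle_curve_order", "user": 0}], seed=2
    )
    rep = qc_markups(m)
    assert CURVE_DISORDER in rep.reasons["user0"]


def test_qc_flags_discrepant_user_at_threshold(template):
    m, _ = simulate.simulate_markups(
        template, 3, 0.004, [{"mode": "outlier_user", "user": 1}],
        seed=3, outlier_distance=0.25,
    )
    rep = qc_markups(m, d_max=0.2)
    assert USER_DISCREPANCY in rep.reasons["user1"]
    assert rep.verdicts["user0"] == rep.verdicts["user2"] == "accept"
    # measurement error excludes the rejected user
    assert rep.measurement_error < 0.1


def test_qc_single_user_skips_discrepancy(template):
    m, _ = simulate.simulate_markups(template, 1, 0.01, seed=4)
    rep = qc_markups(m)
    assert rep.verdicts["user0"] == "accept"
    assert any("skipped" in n for n in rep.notes)


# -------------------------------------------------------------------- sliding
def test_sliding_leaves_consensus_configurations_unmoved(template):
    X = np.stack([template.coords, template.coords.copy()])
    X = np.stack([x - x.mean(0) for x in X])
    X = X / np.sqrt((X[0] ** 2).sum())
    before = X.copy()
    out, cons, hist = slide_semilandmarks(X, template, n_iter=1)
    np.testing.assert_allclose(out, before, atol=1e-8)


def test_sliding_decreases_bending_energy(template):
    tree = simulate.simulate_tree(10, 1.0, seed=1)
    shapes, _ = simulate.simulate_species_shapes(tree, template, seed=2)
    aligned, _, _ = gpa(list(shapes.values()))
    _, _, hist = slide_semilandmarks(aligned, template, n_iter=3)
    for before, after in hist:
        assert after <= before + 1e-12


def test_sliding_displacement_matches_1d_line_search_oracle(template):
    """Single free semi-landmark: closed form vs numeric scan of the energy."""
    rng = np.random.default_rng(5)
    shape = template.coords + 0.01 * rng.standard_normal(template.coords.shape)
    consensus = template.coords - template.coords.mean(0)
    consensus = consensus / np.sqrt((consensus**2).sum())
    shape = shape - shape.mean(0)
    shape = shape / np.sqrt((shape**2).sum())
    B = bending_energy_matrix(consensus)
    from beakrates.morpho import _tangents

    semis, T, caps = _tangents(shape, template)
    j = 10  # one semi-landmark, all others frozen
    lm, t = semis[j], T[j]

    def energy(d):
        x = shape.copy()
        x[lm] += d * t
        return bending_energy(x - consensus, B)

    grid = np.linspace(-0.02, 0.02, 4001)
    vals = [energy(d) for d in grid]
    d_oracle = grid[int(np.argmin(vals))]
    # closed form for the 1-D restriction: d = -t'B(y)_lm / (t' B_ll t)
    y = shape - consensus
    d_closed = -float(t @ (B @ y)[lm]) / float(B[lm, lm] * (t @ t))
    assert d_closed == pytest.approx(d_oracle, abs=2e-5)
    assert energy(d_closed) <= energy(0.0)


# ----------------------------------------------------------------------- PCA
def test_pca_recovers_planted_spectrum():
    rng = np.random.default_rng(8)
    k = 10
    modes = np.linalg.qr(rng.standard_normal((3 * k, 3)))[0]
    planted = np.array([1.0, 0.5, 0.1])
    scores = rng.standard_normal((40, 3)) * np.sqrt(planted)
    scores -= scores.mean(0)
    # orthogonalize realized scores so the sample spectrum is exactly planted
    q, _ = np.linalg.qr(scores)
    scores = q * np.sqrt(planted * 39)
    X = (scores @ modes.T).reshape(40, k, 3)
    space = pca([f"s{i}" for i in range(40)], X)
    np.testing.assert_allclose(space.eigenvalues[:3], planted, rtol=1e-6)
    assert space.variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)


def test_pca_scores_centered_and_reconstruct_data(template):
    m, _ = simulate.simulate_markups(template, 6, 0.02, seed=9)
    aligned, _, _ = gpa(list(m.users.values()))
    space = pca(list(m.users), aligned)
    np.testing.assert_allclose(space.scores.mean(axis=0), 0, atol=1e-9)
    recon = space.scores @ space.eigenvectors.T + space.consensus.ravel()
    np.testing.assert_allclose(recon, aligned.reshape(6, -1), atol=1e-9)


def test_pca_single_variation_direction_gives_unit_fraction():
    base = np.zeros((5, 4, 3))
    direction = np.arange(12).reshape(4, 3) / 12
    X = np.stack([base[0] + w * direction for w in (-2, -1, 0, 1, 2)])
    space = pca(list("abcde"), X)
    assert space.variance_fraction[0] == pytest.approx(1.0)
    assert len(space.eigenvalues) == 1


# ---------------------------------------------------------------------- pPCA
def test_ppca_on_star_tree_equals_pca_up_to_sign(star8):
    rng = np.random.default_rng(10)
    X = rng.standard_normal((8, 6, 3)) * 0.1
    labels = star8.tip_labels()
    sp_p = pca(labels, X)
    sp_pp = ppca(labels, X, star8)
    np.testing.assert_allclose(sp_pp.consensus.ravel(), X.reshape(8, -1).mean(0), atol=1e-10)
    k = min(sp_p.scores.shape[1], sp_pp.scores.shape[1])
    for j in range(k):
        a, b = sp_p.scores[:, j], sp_pp.scores[:, j]
        assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8


def test_ppca_with_identity_covariance_is_exactly_pca(star8):
    rng = np.random.default_rng(11)
    X = rng.standard_normal((8, 5, 3))
    labels = star8.tip_labels()
    sp_p = pca(labels, X)
    sp_pp = ppca(labels, X, star8, C=np.eye(8))
    np.testing.assert_allclose(sp_pp.eigenvalues, sp_p.eigenvalues, rtol=1e-10)


def test_ppca_matches_dense_gls_oracle():
    rng = np.random.default_rng(12)
    tree = simulate.simulate_tree(8, 1.0, seed=12)
    labels = tree.tip_labels()
    X = rng.standard_normal((8, 3, 3))
    space = ppca(labels, X, tree)
    C = tree.vcv(order=labels)
    Ci = np.linalg.inv(C)
    one = np.ones(8)
    Xv = X.reshape(8, -1)
    a = (one @ Ci @ Xv) / (one @ Ci @ one)
    R = (Xv - a).T @ Ci @ (Xv - a) / 7
    np.testing.assert_allclose(space.consensus.ravel(), a, atol=1e-10)
    ev = np.sort(np.linalg.eigvalsh(R))[::-1]
    np.testing.assert_allclose(space.eigenvalues, ev[: len(space.eigenvalues)], atol=1e-10)


# ---------------------------------------------------------------- select_axes
def make_space(fractions):
    fractions = np.asarray(fractions, float)
    scores = np.zeros((3, fractions.size))
    return ShapeSpace(
        labels=list("abc"), aligned=np.zeros((3, 2, 3)), consensus=np.zeros((2, 3)),
        eigenvalues=fractions, eigenvectors=np.eye(fractions.size),
        variance_fraction=fractions, scores=scores,
    )


@pytest.mark.parametrize(
    "fractions,cum_var,expected_k",
    [
        ((0.5, 0.3, 0.15, 0.04, 0.01), 0.99, 4),
        ((0.5, 0.3, 0.15, 0.04, 0.01), 1.0, 5),
        ((1.0,), 0.5, 1),
        ((1.0,), 1.0, 1),
    ],
)
def test_select_axes_cumulative_threshold(fractions, cum_var, expected_k):
    assert select_axes(make_space(fractions), cum_var).shape[1] == expected_k
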