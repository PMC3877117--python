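import numpy as np
import pytest
from numpy.polynomial import legendre as npleg
from scipy.special import eval_legendre

from bcmoments import (
    BCMSet,
    composition_moments,
    compute_distance_matrix,
    decompose,
    feature_schema,
    featurize,
    legendre_feature_block,
    legendre_moment,
    legendre_polynomial,
    make_domain,
)
from bcmoments.moments import DEFAULT_MOMENT_ORDERS
from bcmoments.synthetic_structures import SyntheticSpec


def _bcms_from(h=None, p=None, a=None, o=None, n=10):
    zero = np.zeros((n, n), dtype=int)
    return BCMSet(
        H=zero if h is None else h,
        P=zero if p is None else p,
        A=zero if a is None else a,
        O=zero if o is None else o,
    )


def _symmetric_ones(n):
    return np.ones((n, n), dtype=int)


class TestCompositionMoments:
    def test_full_upper_triangle_is_one(self):
        cm = composition_moments(_bcms_from(h=_symmetric_ones(10), n=10))
        assert cm.c_H == pytest.approx(1.0)
        assert cm.area == 45

    def test_all_zero(self):
        cm = composition_moments(_bcms_from(n=10))
        assert cm.as_tuple() == (0.0, 0.0, 0.0, 0.0)

    def test_single_contact_pair(self):
        m = np.zeros((5, 5), dtype=int)
        m[1, 3] = m[3, 1] = 1
        assert composition_moments(_bcms_from(a=m, n=5)).c_A == pytest.approx(0.1)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            composition_moments(_bcms_from(n=1))


class TestLegendrePolynomial:
    def test_degree_zero(self):
        assert legendre_polynomial(0, 0.3) == 1.0

    @pytest.mark.parametrize("n", range(6))
    def test_unit_at_one(self, n):
        assert legendre_polynomial(n, 1.0) == pytest.approx(1.0)

    def test_odd_degree_vanishes_at_zero(self):
        assert legendre_polynomial(3, 0.0) == pytest.approx(0.0)

    @pytest.mark.parametrize("n", range(6))
    def test_matches_scipy(self, n):
        x = np.linspace(-1, 1, 17)
        np.testing.assert_allclose(legendre_polynomial(n, x), eval_legendre(n, x), atol=1e-12)

    def test_degree_out_of_range(self):
        with pytest.raises(ValueError):
            legendre_polynomial(6, 0.5)


def _geometric_moment_oracle(image: np.ndarray, p: int, q: int) -> float:
    """lambda_pq via geometric moments and expanded Legendre coefficients."""
    n = image.shape[0]
    x = -1.0 + 2.0 * np.arange(n) / (n - 1)
    cp = npleg.leg2poly([0.0] * p + [1.0])
    cq = npleg.leg2poly([0.0] * q + [1.0])
    total = 0.0
    for a, ca in enumerate(cp):
        for b, cb in enumerate(cq):
            if ca == 0.0 or cb == 0.0:
                continue
            m_ab = sum(
                x[i] ** a * x[j] ** b * image[i, j] for i in range(n) for j in range(n)
            )
            total += ca * cb * m_ab
    return (2 * p + 1) * (2 * q + 1) / n**2 * total


class TestLegendreMoment:
    def test_zero_image(self):
        img = np.zeros((12, 12))
        for p, q in DEFAULT_MOMENT_ORDERS:
            assert legendre_moment(img, p, q) == 0.0

    def test_lambda00_of_ones(self):
        assert legendre_moment(np.ones((32, 32)), 0, 0) == pytest.approx(1.0, abs=1e-9)

    def test_lambda10_of_row_mirror_image(self):
        rng = np.random.default_rng(3)
        half = rng.integers(0, 2, size=(5, 10))
        img = np.vstack([half, half[::-1]])  # f(i, j) == f(N-1-i, j)
        assert abs(legendre_moment(img, 1, 0)) < 1e-12

    def test_matches_geometric_moment_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            img = rng.integers(0, 2, size=(20, 20)).astype(float)
            for p, q in [(0, 0), (0, 3), (1, 2), (2, 3), (0, 5)]:
                expected = _geometric_moment_oracle(img, p, q)
                got = legendre_moment(img, p, q)
                assert got == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_symmetry_on_symmetric_images(self):
        rng = np.random.default_rng(7)
        m = rng.integers(0, 2, size=(15, 15))
        img = (m | m.T).astype(float)
        for p, q in DEFAULT_MOMENT_ORDERS:
            assert legendre_moment(img, p, q) == pytest.approx(
                legendre_moment(img, q, p), abs=1e-12
            )

    def test_linearity(self):
        rng = np.random.default_rng(9)
        f = rng.normal(size=(10, 10))
        g = rng.normal(size=(10, 10))
        for p, q in [(1, 2), (0, 4)]:
            assert legendre_moment(f + g, p, q) == pytest.approx(
                legendre_moment(f, p, q) + legendre_moment(g, p, q), abs=1e-12
            )

    def test_translation_sensitivity_along_rows(self):
        # shifting a blob toward larger row index strictly increases lambda_10
        values = []
        for top in (2, 8, 14):
            img = np.zeros((20, 20))
            img[top : top + 4, 8:12] = 1.0
            values.append(legendre_moment(img, 1, 0))
        assert values[0] < values[1] < values[2]

    def test_order_violation(self):
        with pytest.raises(ValueError):
            legendre_moment(np.ones((5, 5)), 3, 3)


class TestFeatureBlock:
    def test_zero_bcms_give_log_length_and_zeros(self):
        block = legendre_feature_block(_bcms_from(n=50))
        assert block.shape == (45,)
        assert block[0] == pytest.approx(np.log(50))
        np.testing.assert_array_equal(block[1:], 0.0)

    def test_swapping_h_and_p_permutes_slices(self):
        rng = np.random.default_rng(13)
        m1 = rng.integers(0, 2, size=(12, 12))
        m1 = (m1 | m1.T).astype(int)
        m2 = rng.integers(0, 2, size=(12, 12))
        m2 = (m2 | m2.T).astype(int)
        np.fill_diagonal(m1, 0)
        np.fill_diagonal(m2, 0)
        a = legendre_feature_block(_bcms_from(h=m1, p=m2, n=12))
        b = legendre_feature_block(_bcms_from(h=m2, p=m1, n=12))
        np.testing.assert_allclose(a[1:12], b[12:23])
        np.testing.assert_allclose(a[12:23], b[1:12])
        np.testing.assert_allclose(a[23:], b[23:])


class TestFeaturize:
    def test_vector_has_49_named_features(self):
        trace = make_domain(SyntheticSpec("alpha_beta", 60, 0.1, 4))
        vec = featurize(trace)
        assert vec.values.shape == (49,)
        assert vec.schema == feature_schema()
        assert np.all(np.isfinite(vec.values))
        assert sum(name.startswith("comp_") for name in vec.schema) == 4

    def test_all_alpha_is_helix_dominated(self):
        vec = featurize(make_domain(SyntheticSpec("all_alpha", 60, 0.0, 1))).as_dict()
        assert vec["comp_H"] > vec["comp_P"]
        assert vec["comp_H"] > vec["comp_A"]

    def test_deterministic(self):
        trace = make_domain(SyntheticSpec("all_beta_parallel", 50, 0.2, 8))
        np.testing.assert_array_equal(featurize(trace).values, featurize(trace).values)

    def test_rigid_body_invariance(self):
        trace = make_domain(SyntheticSpec("alpha_beta", 60, 0.1, 4))
        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = type(trace)(trace.residue_ids, trace.coords @ q.T + [10.0, -4.0, 2.5])
        np.testing.assert_allclose(
            featurize(trace).values, featurize(moved).values, atol=1e-9
        )


def test_reconstruction_error_non_increasing_with_order():
    n = 24
    img = np.zeros((n, n))
    img[:, 10:14] = 1.0  # vertical strip
    x = -1.0 + 2.0 * np.arange(n) / (n - 1)
    table = np.stack([np.asarray(legendre_polynomial(d, x)) for d in range(6)])
    errors = []
    for kmax in range(6):
        recon = np.zeros_like(img)
        for p in range(kmax + 1):
            for q in range(kmax + 1 - p):
                lam = legendre_moment(img, p, q)
                recon += lam * np.outer(table[p], table[q])
        errors.append(((img - recon) ** 2).sum())
    assert all(e2 <= e1 + 1e-9 for e1, e2 in zip(errors, errors[1:]))
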