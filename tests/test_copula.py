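"""Checkerboard copula construction and the q / a / m measures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecoqad.copula import (
    CheckerboardCopula,
    build_ecbc,
    d1_distance,
    monotonicity_m,
    q_directed,
    qad_estimate,
    rank_transform,
    reference_copula,
    resolution,
)


def random_checkerboard(rng, N, n=200):
    """Checkerboard of a random sample (guarantees uniform margins)."""
    x = rng.normal(size=n)
    y = rng.normal(size=n) + rng.choice([0, 1]) * x
    return build_ecbc(rank_transform(x, y), N)


class TestRankTransform:
    def test_untied_monotone_sample_gets_equal_spans(self):
        rp = rank_transform([10, 20, 30], [1, 2, 3])
        assert np.allclose(rp.u_lo, [0, 1 / 3, 2 / 3])
        assert np.allclose(rp.u_hi, [1 / 3, 2 / 3, 1])
        assert np.allclose(rp.v_lo, rp.u_lo) and np.allclose(rp.v_hi, rp.u_hi)

    def test_tied_observations_share_their_rank_interval(self):
        rp = rank_transform([5, 5, 9], [1, 2, 3])
        assert np.allclose(rp.u_lo[:2], 0.0) and np.allclose(rp.u_hi[:2], 2 / 3)
        assert rp.u_lo[2] == pytest.approx(2 / 3) and rp.u_hi[2] == 1.0

    def test_invariant_under_strictly_monotone_transforms(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        a, b = rank_transform(x, y), rank_transform(np.exp(3 * x), y**3)
        assert np.array_equal(a.u_lo, b.u_lo) and np.array_equal(a.u_hi, b.u_hi)

    @pytest.mark.parametrize("x, y, match", [
        ([1, 2], [1, 2, 3], "length mismatch"),
        ([1], [2], "at least 2"),
        ([1, np.nan], [1, 2], "finite"),
    ])
    def test_rejects_malformed_input(self, x, y, match):
        with pytest.raises(ValueError, match=match):
            rank_transform(x, y)


@pytest.mark.parametrize("n, expected", [(16, 4), (24, 4), (25, 5), (4, 2), (2, 2)])
def test_resolution_is_floor_sqrt_with_minimum_2(n, expected):
    assert resolution(n) == expected


def test_resolution_rejects_tiny_samples():
    with pytest.raises(ValueError):
        resolution(1)


class TestBuildEcbc:
    def test_diagonal_sample_yields_diagonal_checkerboard(self):
        x = np.arange(16.0)
        C = build_ecbc(rank_transform(x, x), 4)
        assert np.allclose(C.mass, np.eye(4) / 4)

    def test_one_point_per_cell_yields_independence_checkerboard(self):
        k = np.arange(16)
        y_rank = (k % 4) * 4 + k // 4 + 1
        C = build_ecbc(rank_transform(k + 1.0, y_rank.astype(float)), 4)
        assert np.allclose(C.mass, 1 / 16)

    def test_resolution_out_of_range_rejected(self):
        rp = rank_transform([1, 2, 3], [3, 1, 2])
        for N in (1, 4):
            with pytest.raises(ValueError):
                build_ecbc(rp, N)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(5, 120),
           tie=st.booleans())
    def test_margins_are_uniform_with_and_without_ties(self, seed, n, tie):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        if tie:
            x = np.round(x)  # heavy ties
        C = build_ecbc(rank_transform(x, y), resolution(n))
        assert np.max(np.abs(C.mass.sum(axis=0) - 1 / C.N)) < 1e-12
        assert np.max(np.abs(C.mass.sum(axis=1) - 1 / C.N)) < 1e-12


class TestReferenceCopulas:
    def test_patterns(self):
        assert np.allclose(reference_copula("M", 2).mass, [[0.5, 0], [0, 0.5]])
        W3 = reference_copula("W", 3).mass
        assert np.allclose(W3, np.eye(3)[::-1] / 3)
        assert np.allclose(reference_copula("pi", 4).mass, 1 / 16)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            reference_copula("X", 3)


class TestD1:
    def test_identity(self, rng):
        C = random_checkerboard(rng, 5)
        assert d1_distance(C, C) == 0.0

    @pytest.mark.parametrize("N", [2, 4, 8])
    def test_comonotone_vs_countermonotone_is_half_for_even_N(self, N):
        assert d1_distance(reference_copula("M", N),
                           reference_copula("W", N)) == pytest.approx(0.5)

    def test_comonotone_vs_independence_at_N4(self):
        assert d1_distance(reference_copula("M", 4),
                           reference_copula("pi", 4)) == pytest.approx(7 / 24)

    def test_symmetry_and_triangle_inequality(self, rng):
        A, B, C = (random_checkerboard(rng, 6) for _ in range(3))
        assert d1_distance(A, B) == pytest.approx(d1_distance(B, A))
        assert d1_distance(A, C) <= d1_distance(A, B) + d1_distance(B, C) + 1e-12

    def test_resolution_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            d1_distance(reference_copula("M", 3), reference_copula("M", 4))


class TestDirectedDependence:
    def test_independence_checkerboard_has_q_zero(self):
        assert q_directed(reference_copula("pi", 4)) == 0.0

    def test_comonotone_N4(self):
        assert q_directed(reference_copula("M", 4)) == pytest.approx(0.875)

    @pytest.mark.parametrize("N", [2, 4, 8])
    def test_closed_form_diagonal_checkerboard(self, N):
        # q(M_N) = 1 - 1/(2N): approaches 1 (complete dependence) as N grows
        assert q_directed(reference_copula("M", N)) == pytest.approx(1 - 1 / (2 * N))

    def test_symmetric_mass_gives_zero_asymmetry(self):
        est = qad_estimate(np.arange(16.0), np.arange(16.0))
        assert est.a == 0.0

    def test_transpose_contract(self, rng):
        C = random_checkerboard(rng, 6)
        est_q_yx = q_directed(C.transpose())
        assert est_q_yx == pytest.approx(3 * d1_distance(
            CheckerboardCopula(C.N, C.mass.T), reference_copula("pi", C.N)))


class TestMonotonicity:
    def test_anchor_values(self):
        assert monotonicity_m(reference_copula("M", 4)) == pytest.approx(1.0)
        assert monotonicity_m(reference_copula("W", 4)) == pytest.approx(-1.0)
        assert monotonicity_m(reference_copula("pi", 6)) == pytest.approx(0.0)

    @pytest.mark.parametrize("N", [3, 5, 7])
    def test_anchors_hold_at_odd_resolutions(self, N):
        assert monotonicity_m(reference_copula("M", N)) == pytest.approx(1.0)
        assert monotonicity_m(reference_copula("W", N)) == pytest.approx(-1.0)

    def test_reflection_antisymmetry(self, rng):
        C = random_checkerboard(rng, 6)
        R = CheckerboardCopula(C.N, C.mass[:, ::-1])  # reverse the y axis
        assert monotonicity_m(R) == pytest.approx(-monotonicity_m(C))
        assert q_directed(R) == pytest.approx(q_directed(C))


class TestQadEstimate:
    def test_perfect_monotone_samples(self):
        x = np.arange(1.0, 401.0)  # n = 400 is a multiple of N = 20
        up = qad_estimate(x, x)
        assert (up.m_xy, up.a, up.N) == (pytest.approx(1.0), 0.0, 20)
        down = qad_estimate(x, -x)
        assert down.m_xy == pytest.approx(-1.0)

    def test_scale_free_in_both_margins(self, rng):
        x = rng.normal(size=80)
        y = rng.normal(size=80) + x
        a = qad_estimate(x, y)
        b = qad_estimate(np.exp(x), 5 * y - 3)
        assert (a.q_xy, a.q_yx, a.m_xy, a.m_yx) == (b.q_xy, b.q_yx, b.m_xy, b.m_yx)

    def test_dependence_shrinks_with_sample_size_under_independence(self):
        rng = np.random.default_rng(7)
        qs = []
        for n in (32, 2048):
            est = qad_estimate(rng.normal(size=n), rng.normal(size=n))
            qs.append(max(est.q_xy, est.q_yx))
        assert qs[1] < qs[0]

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(16, 200))
    def test_bounds_hold_for_arbitrary_samples(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = np.sin(3 * x) + rng.normal(size=n)
        est = qad_estimate(x, y)
        assert 0 <= est.q_xy <= 1 and 0 <= est.q_yx <= 1
        assert abs(est.m_xy) <= 1 and abs(est.m_yx) <= 1
        assert est.a == est.q_xy - est.q_yx
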