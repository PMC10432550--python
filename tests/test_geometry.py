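"""Unit-ring parameterization: site construction, symmetry expansion,
inversion, and the lateral/axial decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import npcfusion as nf
from npcfusion.geometry import (InvalidParameterError, PairingError,
                                wrap_angle, wrap_axis_angle)


def params_strategy():
    return st.builds(
        nf.UnitRingParams.from_polar,
        R=st.floats(30.0, 80.0),
        psi=st.floats(-np.pi, np.pi),
        c1z=st.floats(-40.0, 40.0),
        d=st.floats(5.0, 20.0),
        theta=st.floats(0.05, np.pi / 2 - 0.05),
        phi=st.floats(-np.pi + 1e-6, np.pi),
    )


class TestUnitSites:
    def test_reference_geometry_example(self):
        # independent hand evaluation of the two-site construction at the
        # cryo-EM reference: offset = (d/2)(−sinθ sinφ', sinθ cosφ', cosθ)
        p = nf.UnitRingParams.from_polar(R=54.2, psi=0.0, c1z=0.0, d=11.8,
                                         theta=np.radians(76.8), phi=0.0)
        s11, s12 = nf.unit_sites(p)
        np.testing.assert_allclose(s11, [54.2, 5.744, 1.347], atol=5e-4)
        np.testing.assert_allclose(s12, [54.2, -5.744, -1.347], atol=5e-4)

    @settings(deadline=None, max_examples=60)
    @given(p=params_strategy())
    def test_construction_invariants(self, p):
        s11, s12 = nf.unit_sites(p)
        mid = np.array([p.R * np.cos(p.psi), p.R * np.sin(p.psi), p.c1z])
        np.testing.assert_allclose(s11 + s12, 2 * mid, atol=1e-9)
        assert np.linalg.norm(s11 - s12) == pytest.approx(p.d, abs=1e-9)

    def test_planar_unit_has_no_axial_offset(self):
        p = nf.UnitRingParams.from_polar(R=50, psi=0.3, c1z=5.0, d=10,
                                         theta=np.pi / 2, phi=1.0)
        s11, s12 = nf.unit_sites(p)
        assert s11[2] == pytest.approx(5.0, abs=1e-12)
        assert s12[2] == pytest.approx(5.0, abs=1e-12)

    @pytest.mark.parametrize("bad", [
        dict(d=-1.0), dict(d=0.0), dict(theta=-0.2), dict(theta=2.0),
    ])
    def test_invalid_parameters_rejected(self, bad):
        kw = dict(c1x=54.0, c1y=0.0, c1z=0.0, d=11.8, theta=1.3, phi=0.0)
        kw.update(bad)
        with pytest.raises(InvalidParameterError):
            nf.UnitRingParams(**kw)


class TestExpandEightfold:
    @settings(deadline=None, max_examples=40)
    @given(p=params_strategy())
    def test_balanced_rotation_set(self, p):
        ss = nf.expand_eightfold(p)
        flat = ss.flat
        assert flat.shape == (16, 3)
        np.testing.assert_allclose(flat[:, :2].sum(0), 0.0, atol=1e-8)
        mids = ss.midpoints()
        np.testing.assert_allclose(np.hypot(mids[:, 0], mids[:, 1]), p.R,
                                   atol=1e-9)
        np.testing.assert_allclose(mids[:, 2], p.c1z, atol=1e-9)
        # z takes exactly the two values c1z +/- (d/2) cos theta
        zs = np.unique(np.round(flat[:, 2], 9))
        expected = np.round(np.sort([p.c1z - p.d / 2 * np.cos(p.theta),
                                     p.c1z + p.d / 2 * np.cos(p.theta)]), 9)
        np.testing.assert_allclose(np.sort(zs), expected, atol=1e-8)

    def test_quarter_turn_set_invariance(self, reference_nr_params):
        ss = nf.expand_eightfold(reference_nr_params)
        c, s = np.cos(np.pi / 4), np.sin(np.pi / 4)
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        rotated = ss.flat @ R.T
        d = np.linalg.norm(rotated[:, None] - ss.flat[None], axis=-1)
        assert d.min(axis=1).max() < 1e-9

    def test_within_unit_distances_preserved(self, reference_nr_params):
        ss = nf.expand_eightfold(reference_nr_params)
        d = np.linalg.norm(ss.sites[:, 0] - ss.sites[:, 1], axis=1)
        np.testing.assert_allclose(d, 11.8, atol=1e-9)


class TestExtractUnitParams:
    @settings(deadline=None, max_examples=40)
    @given(p=params_strategy())
    def test_roundtrip_inverse(self, p):
        q = nf.extract_unit_params(nf.expand_eightfold(p))
        assert q.R == pytest.approx(p.R, abs=1e-8)
        assert q.d == pytest.approx(p.d, abs=1e-8)
        assert q.theta == pytest.approx(p.theta, abs=1e-8)
        assert wrap_angle(q.phi - p.phi) == pytest.approx(0.0, abs=1e-8)
        assert q.c1z == pytest.approx(p.c1z, abs=1e-8)
        # psi recovered up to unit re-indexing (mod pi/4)
        assert abs(wrap_angle((q.psi - p.psi) * 8)) < 1e-6

    def test_noisy_recovery_tolerance(self, reference_nr_params):
        # Monte-Carlo oracle: with iid sigma=0.1 nm site noise the averaged
        # parameters stay within 0.3 nm / 1 degree of the truth
        rng = np.random.default_rng(0)
        truth = reference_nr_params
        flat = nf.expand_eightfold(truth).flat
        for _ in range(100):
            q = nf.extract_unit_params(flat + rng.standard_normal((16, 3)) * 0.1)
            assert abs(q.R - truth.R) < 0.3
            assert abs(q.d - truth.d) < 0.3
            assert abs(q.theta - truth.theta) < np.radians(1.0)
            assert abs(wrap_angle(q.phi - truth.phi)) < np.radians(1.0)

    def test_unconstrained_kind_gets_paired(self, reference_nr_params):
        flat = nf.expand_eightfold(reference_nr_params).flat
        perm = np.random.default_rng(1).permutation(16)
        q = nf.extract_unit_params(flat[perm])
        assert q.R == pytest.approx(reference_nr_params.R, abs=1e-8)
        assert q.d == pytest.approx(reference_nr_params.d, abs=1e-8)

    def test_ambiguous_pairing_raises(self):
        # 4 points on a square: every point equidistant to two neighbours
        sq = np.array([[1, 0, 0], [0, 1, 0], [-1, 0, 0], [0, -1, 0.0]])
        pts = np.concatenate([sq, sq + [10, 10, 10], sq + [20, 0, 0],
                              sq + [0, 20, 5]])
        with pytest.raises(PairingError):
            nf.extract_unit_params(pts)

    def test_vertical_unit_flags_phi(self):
        p = nf.UnitRingParams.from_polar(R=50, psi=0, c1z=0, d=10,
                                         theta=0.0, phi=0.0)
        q = nf.extract_unit_params(nf.expand_eightfold(p))
        assert q.phi == 0.0
        assert not q.phi_defined


class TestLateralAxialSplit:
    def test_reference_lateral_value(self, reference_nr_params):
        lat, axi = nf.lateral_axial_split(reference_nr_params)
        assert round(lat, 1) == 11.5
        assert lat ** 2 + axi ** 2 == pytest.approx(11.8 ** 2, rel=1e-12)

    @pytest.mark.parametrize("theta,expected", [
        (np.pi / 2, (10.0, 0.0)),
        (1e-12, (0.0, 10.0)),
    ])
    def test_degenerate_angles(self, theta, expected):
        p = nf.UnitRingParams.from_polar(R=50, psi=0, c1z=0, d=10.0,
                                         theta=theta, phi=0.0)
        lat, axi = nf.lateral_axial_split(p)
        assert lat == pytest.approx(expected[0], abs=1e-9)
        assert axi == pytest.approx(expected[1], abs=1e-9)


def test_angle_wrapping_helpers():
    assert wrap_angle(np.pi) == pytest.approx(np.pi)
    assert wrap_angle(-np.pi) == pytest.approx(np.pi)
    assert wrap_angle(3 * np.pi / 2) == pytest.approx(-np.pi / 2)
    assert wrap_axis_angle(np.pi / 2 + 0.1) == pytest.approx(-np.pi / 2 + 0.1)
    assert wrap_axis_angle(-np.pi / 2) == pytest.approx(np.pi / 2)


def test_parameter_serialization_roundtrip(reference_nr_params):
    d = reference_nr_params.to_dict()
    assert d["theta_deg"] == pytest.approx(76.8)
    q = nf.UnitRingParams.from_dict(d)
    assert q == reference_nr_params
    # polar form too
    q2 = nf.UnitRingParams.from_dict(
        {k: v for k, v in d.items() if k not in ("c1x_nm", "c1y_nm")})
    assert q2.R == pytest.approx(reference_nr_params.R)
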