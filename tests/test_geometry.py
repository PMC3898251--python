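"""Geometry kernel: torsions, C-beta reconstruction, S-gamma kinematics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ssbridge.geometry import (
    DegenerateGeometryError,
    IdealParams,
    bond_angle,
    construct_cbeta,
    dihedral,
    place_atom,
    place_sgamma,
)

from conftest import random_rigid_transform


def rotation_matrix_dihedral(p1, p2, p3, p4):
    """Independent torsion oracle: rotate into a frame where the p2->p3 bond
    is +z and p1's perpendicular component points along -y; the torsion is
    then the plane angle of p4's perpendicular component."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    ez = p3 - p2
    ez = ez / np.linalg.norm(ez)
    u = p1 - p2
    u_perp = u - np.dot(u, ez) * ez
    ey = -u_perp / np.linalg.norm(u_perp)
    ex = np.cross(ey, ez)
    v = p4 - p3
    v_perp = v - np.dot(v, ez) * ez
    # angle from the -y axis (p1 side), positive toward +x (clockwise looking
    # down p2->p3)
    ang = np.degrees(np.arctan2(np.dot(v_perp, ex), -np.dot(v_perp, ey)))
    return float(ang)


class TestDihedral:
    @pytest.mark.parametrize(
        "points,expected",
        [
            (((0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)), 0.0),
            (((0, 0, 0), (1, 0, 0), (1, 1, 0), (2, 1, 0)), 180.0),
            (((0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)), 90.0),
        ],
    )
    def test_reference_values(self, points, expected):
        assert dihedral(*points) == pytest.approx(expected, abs=1e-9)

    def test_sign_convention_matches_rotation_matrix_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            pts = rng.normal(scale=3.0, size=(4, 3))
            try:
                d = dihedral(*pts)
            except DegenerateGeometryError:
                continue
            assert d == pytest.approx(rotation_matrix_dihedral(*pts), abs=1e-9)

    def test_invariant_under_point_order_reversal(self):
        # the torsion angle reads the same from either end of the chain
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.normal(scale=2.0, size=(4, 3))
            assert dihedral(*p) == pytest.approx(dihedral(*p[::-1]), abs=1e-9)

    def test_rigid_body_invariance(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            pts = rng.normal(scale=3.0, size=(4, 3))
            rot, trans = random_rigid_transform(rng)
            moved = pts @ rot.T + trans
            assert dihedral(*moved) == pytest.approx(dihedral(*pts), abs=1e-9)
            a, b = bond_angle(*moved[:3]), bond_angle(*pts[:3])
            assert a == pytest.approx(b, abs=1e-9)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(DegenerateGeometryError):
            dihedral((0, 0, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0))
        with pytest.raises(DegenerateGeometryError):
            dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


class TestConstructCbeta:
    def test_distance_and_angles_by_construction(self):
        rng = np.random.default_rng(5)
        params = IdealParams()
        for _ in range(20):
            # realistic backbone: N-CA-C angle in a range compatible with a
            # tetrahedral branch
            ca = rng.normal(scale=2.0, size=3)
            u = _rand_unit(rng)
            ang = np.radians(rng.uniform(95.0, 130.0))
            perp = np.cross(u, _rand_unit(rng))
            perp /= np.linalg.norm(perp)
            v = np.cos(ang) * u + np.sin(ang) * perp
            n = ca + 1.458 * u
            c = ca + 1.525 * v
            cb = construct_cbeta(n, ca, c, params)
            assert np.linalg.norm(cb - ca) == pytest.approx(params.d_ca_cb, abs=1e-9)
            assert bond_angle(n, ca, cb) == pytest.approx(params.ang_n_ca_cb, abs=1e-6)
            assert bond_angle(c, ca, cb) == pytest.approx(params.ang_n_ca_cb, abs=1e-6)
            # L-amino-acid side
            assert dihedral(n, ca, c, cb) > 0

    def test_recovers_fixture_ground_truth_cbeta(self, bridge_model):
        # the fixture's ALA C-beta was stored before "deletion": rebuilding
        # from backbone must reproduce it
        for res in bridge_model.residues:
            cb_ref = res.coord("CB")
            cb = construct_cbeta(res.coord("N"), res.coord("CA"), res.coord("C"))
            assert np.linalg.norm(cb - cb_ref) < 1e-6

    def test_close_to_independently_built_cbeta(self):
        # independent route: place CB from the N-C-CA chain by the improper
        # torsion (+122.5 deg) instead of the double-angle construction
        rng = np.random.default_rng(8)
        for _ in range(10):
            ca = rng.normal(scale=5.0, size=3)
            n = ca + 1.458 * _rand_unit(rng)
            c = place_atom(n + rng.normal(scale=0.1, size=3), n, ca, 1.525, 111.0,
                           float(rng.uniform(-180, 180)))
            cb_ref = place_atom(n, c, ca, 1.53, 110.6, 122.5)
            if dihedral(n, ca, c, cb_ref) < 0:
                cb_ref = place_atom(n, c, ca, 1.53, 110.6, -122.5)
            cb = construct_cbeta(n, ca, c)
            assert np.linalg.norm(cb - cb_ref) < 0.05

    def test_collinear_backbone_raises(self):
        with pytest.raises(DegenerateGeometryError):
            construct_cbeta((0, 0, 0), (1, 0, 0), (2, 0, 0))


def _rand_unit(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def rodrigues_sgamma(n, ca, cb, chi1, params=IdealParams()):
    """Brute-force oracle: build the chi1 = 0 (N-eclipsed) SG and rotate it
    about the CA->CB axis with an explicit Rodrigues rotation."""
    n, ca, cb = (np.asarray(p, float) for p in (n, ca, cb))
    axis = cb - ca
    axis = axis / np.linalg.norm(axis)
    u = ca - cb
    u = u / np.linalg.norm(u)
    perp = (n - ca) - np.dot(n - ca, axis) * axis
    perp = perp / np.linalg.norm(perp)
    ang = np.radians(params.ang_ca_cb_sg)
    sg0 = cb + params.d_cb_sg * (np.cos(ang) * u + np.sin(ang) * perp)
    # right-hand rotation about the CA->CB axis increases the torsion
    t = np.radians(chi1)
    v = sg0 - cb
    k = axis
    rotated = (v * np.cos(t) + np.cross(k, v) * np.sin(t)
               + k * np.dot(k, v) * (1 - np.cos(t)))
    return cb + rotated


class TestPlaceSgamma:
    def setup_method(self):
        rng = np.random.default_rng(17)
        self.frames = []
        for _ in range(10):
            ca = rng.normal(scale=5.0, size=3)
            n = ca + 1.458 * _rand_unit(rng)
            cb = ca + 1.53 * _rand_unit(rng)
            if abs(np.dot((n - ca) / 1.458, (cb - ca) / 1.53)) > 0.9:
                continue
            self.frames.append((n, ca, cb))

    def test_internal_coordinates_roundtrip(self):
        params = IdealParams()
        for n, ca, cb in self.frames:
            for chi1 in (-60.0, 0.0, 97.3, 180.0):
                sg = place_sgamma(n, ca, cb, chi1, params)
                assert np.linalg.norm(sg - cb) == pytest.approx(params.d_cb_sg,
                                                                abs=1e-9)
                assert bond_angle(ca, cb, sg) == pytest.approx(
                    params.ang_ca_cb_sg, abs=1e-6)
                measured = dihedral(n, ca, cb, sg)
                circ = (measured - chi1 + 180.0) % 360.0 - 180.0
                assert abs(circ) < 1e-6

    def test_periodicity(self):
        n, ca, cb = self.frames[0]
        for chi1 in (-120.0, 33.3):
            a = place_sgamma(n, ca, cb, chi1)
            b = place_sgamma(n, ca, cb, chi1 + 360.0)
            assert np.linalg.norm(a - b) < 1e-9

    def test_matches_rodrigues_sweep_oracle(self):
        n, ca, cb = self.frames[0]
        sweep = np.linspace(-180.0, 180.0, 721)
        rng = np.random.default_rng(23)
        chis = np.concatenate([sweep, rng.uniform(-180, 180, size=10)])
        worst = max(
            np.linalg.norm(place_sgamma(n, ca, cb, chi)
                           - rodrigues_sgamma(n, ca, cb, chi))
            for chi in chis
        )
        assert worst < 1e-6

    def test_equivariant_under_rigid_transforms(self):
        rng = np.random.default_rng(29)
        n, ca, cb = self.frames[1]
        for _ in range(10):
            rot, trans = random_rigid_transform(rng)
            chi1 = float(rng.uniform(-180, 180))
            moved = place_sgamma(rot @ n + trans, rot @ ca + trans,
                                 rot @ cb + trans, chi1)
            direct = rot @ place_sgamma(n, ca, cb, chi1) + trans
            assert np.linalg.norm(moved - direct) < 1e-9


@given(st.floats(-180, 180), st.floats(-180, 180))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_dihedral_of_placed_atom_roundtrips(angle_deg, torsion_deg):
    if not 5.0 < angle_deg < 175.0:
        return
    a, b, c = np.array([0.0, 1.3, 0.2]), np.zeros(3), np.array([1.5, 0.0, 0.0])
    d = place_atom(a, b, c, 1.8, angle_deg, torsion_deg)
    assert bond_angle(b, c, d) == pytest.approx(angle_deg, abs=1e-6)
    expected = torsion_deg if torsion_deg > -180.0 else torsion_deg + 360.0
    if expected <= -180.0:
        expected += 360.0
    assert dihedral(a, b, c, d) == pytest.approx(expected, abs=1e-6)


def test_ideal_params_validation():
    with pytest.raises(ValueError):
        IdealParams(d_ss=-1.0)
    with pytest.raises(ValueError):
        IdealParams(ang_cb_s_s=190.0)
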