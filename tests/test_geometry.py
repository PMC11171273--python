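"""Canonical frames, feature extraction, and rigid-motion invariance."""

import numpy as np
import pytest

from dmguess.geometry import (
    FE_O_EQUILIBRIUM,
    DegenerateGeometryError,
    FrameTransform,
    FrameViolationError,
    InvalidMoleculeError,
    MolecularGeometry,
    apply_inverse_frame,
    build_hexaaqua,
    canonical_frame,
    equilibrium_geometry,
    features,
    random_rigid_transform,
)


def test_canonical_pose_is_identity():
    g = equilibrium_geometry("h2o")
    gc, tf = canonical_frame(g, "h2o")
    assert np.allclose(tf.translation, 0.0, atol=1e-12)
    assert np.allclose(tf.rotation, np.eye(3), atol=1e-10)
    assert np.allclose(gc.coords, g.coords, atol=1e-12)


@pytest.mark.parametrize("molecule", ["h2o", "s2o", "fe_hexaaqua"])
def test_rigid_motion_roundtrip_and_feature_invariance(molecule):
    """1000 random rigid motions: features invariant to <1e-8 A, frames
    proper, and the inverse transform recovers the input coordinates."""
    g = equilibrium_geometry(molecule)
    if molecule == "fe_hexaaqua":
        g = build_hexaaqua(FE_O_EQUILIBRIUM * np.array(
            [1.03, 0.98, 1.01, 0.95, 1.06, 0.99]))
    else:
        gc0 = g.with_coords(g.coords * 1.0)
    f0 = features(canonical_frame(g, molecule)[0], molecule)
    rng = np.random.default_rng(42)
    n = 1000 if molecule == "h2o" else 150
    for _ in range(n):
        tf = random_rigid_transform(rng)
        moved = g.with_coords(tf.invert(g.coords))
        gc, tfm = canonical_frame(moved, molecule)
        assert np.max(np.abs(features(gc, molecule) - f0)) < 1e-8
        R = tfm.rotation
        assert np.linalg.norm(R.T @ R - np.eye(3)) < 1e-10
        assert np.linalg.det(R) > 0
        back = tfm.invert(tfm.apply(moved.coords))
        assert np.max(np.abs(back - moved.coords)) < 1e-10


def test_s2o_anchor_is_central_sulfur():
    g = equilibrium_geometry("s2o")
    rng = np.random.default_rng(3)
    moved = g.with_coords(random_rigid_transform(rng).invert(g.coords))
    gc, _ = canonical_frame(moved, "s2o")
    # central S (bonded to O) at the origin, terminal S on the negative x axis
    assert np.linalg.norm(gc.coords[0]) < 1e-10
    assert gc.coords[1][0] < 0
    assert abs(gc.coords[1][1]) < 1e-10 and abs(gc.coords[1][2]) < 1e-10


def test_triatomic_features_match_trigonometry():
    d1, d2, theta = 0.95, 1.02, np.deg2rad(108.0)
    coords = np.array([
        [0.0, 0.0, 0.0],
        [-d1, 0.0, 0.0],
        [d2 * np.cos(np.pi - theta), d2 * np.sin(np.pi - theta), 0.0]])
    g = MolecularGeometry(["O", "H", "H"], coords, name="h2o")
    f = features(g, "h2o")
    assert f[0] == pytest.approx(-d1, abs=1e-12)
    assert np.hypot(f[1], f[2]) == pytest.approx(d2, abs=1e-12)
    ang = np.arccos(-f[1] / np.hypot(f[1], f[2]))
    assert ang == pytest.approx(theta, abs=1e-12)


def test_collinear_triatomic_raises():
    coords = np.array([[0.0, 0, 0], [-0.95, 0, 0], [0.97, 1e-9, 0]])
    g = MolecularGeometry(["O", "H", "H"], coords, name="h2o")
    with pytest.raises(DegenerateGeometryError):
        canonical_frame(g, "h2o")


def test_composition_mismatch_raises():
    g = equilibrium_geometry("h2o")
    with pytest.raises(InvalidMoleculeError):
        canonical_frame(g, "s2o")


def test_frame_violation_detected():
    g = equilibrium_geometry("h2o")
    shifted = g.with_coords(g.coords + np.array([0.5, 0.0, 0.0]))
    with pytest.raises(FrameViolationError):
        features(shifted, "h2o")


def test_hexaaqua_equilibrium_features():
    g = build_hexaaqua(np.full(6, FE_O_EQUILIBRIUM))
    f = features(g, "fe_hexaaqua")
    assert np.allclose(f, FE_O_EQUILIBRIUM, atol=1e-12)


def test_hexaaqua_roundtrip_and_bounds():
    rng = np.random.default_rng(0)
    for _ in range(20):
        bl = FE_O_EQUILIBRIUM * (1.0 + 0.1 * rng.uniform(-1, 1, 6))
        assert np.all(bl >= 1.84725 - 1e-9) and np.all(bl <= 2.25775 + 1e-9)
        g = build_hexaaqua(bl)
        assert np.allclose(features(g, "fe_hexaaqua"), bl, atol=1e-12)
    with pytest.raises(InvalidMoleculeError):
        build_hexaaqua([-1.0] + [2.0] * 5)


def test_apply_inverse_frame_properties():
    rng = np.random.default_rng(7)
    tf = random_rigid_transform(rng)
    vecs = rng.normal(size=(3, 3))
    out = apply_inverse_frame(vecs, tf)
    # covariant back-rotation: norms preserved, translation ignored
    assert np.allclose(np.linalg.norm(out, axis=1),
                       np.linalg.norm(vecs, axis=1), atol=1e-12)
    ident = FrameTransform(np.zeros(3), np.eye(3))
    assert np.allclose(apply_inverse_frame(vecs, ident), vecs)
    # undoes the forward rotation
    assert np.allclose(apply_inverse_frame(tf.rotate_vectors(vecs), tf), vecs,
                       atol=1e-12)


def test_xyz_roundtrip():
    g = equilibrium_geometry("s2o")
    g2 = MolecularGeometry.from_xyz(g.to_xyz("test"), name="s2o")
    assert g2.elements == g.elements
    assert np.allclose(g2.coords, g.coords, atol=1e-9)


def test_transform_yaml_roundtrip():
    tf = random_rigid_transform(np.random.default_rng(1))
    tf2 = FrameTransform.from_yaml(tf.to_yaml())
    assert np.allclose(tf2.rotation, tf.rotation, atol=1e-12)
    assert np.allclose(tf2.translation, tf.translation, atol=1e-12)


def test_distance_floor_enforced():
    with pytest.raises(InvalidMoleculeError):
        MolecularGeometry(["H", "H"], [[0, 0, 0], [0.1, 0, 0]])
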