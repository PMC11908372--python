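"""Warp, displacement regularizer and Jacobian diagnostics.

The trilinear warp is checked against an independent per-voxel
triple-interpolation oracle written as explicit scalar loops.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphldm.spatial import (DisplacementField, Volume,
                              displacement_regularizer, identity_field,
                              jacobian_determinant, warp)


def trilinear_oracle(vol: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Scalar-loop trilinear sampling with border clamping."""
    D, H, W = vol.shape
    out = np.zeros_like(vol, dtype=float)
    for i in range(D):
        for j in range(H):
            for k in range(W):
                x = min(max(i + u[0, i, j, k], 0.0), D - 1)
                y = min(max(j + u[1, i, j, k], 0.0), H - 1)
                z = min(max(k + u[2, i, j, k], 0.0), W - 1)
                x0, y0, z0 = int(np.floor(x)), int(np.floor(y)), int(np.floor(z))
                x1, y1, z1 = min(x0 + 1, D - 1), min(y0 + 1, H - 1), min(z0 + 1, W - 1)
                fx, fy, fz = x - x0, y - y0, z - z0
                c00 = vol[x0, y0, z0] * (1 - fx) + vol[x1, y0, z0] * fx
                c01 = vol[x0, y0, z1] * (1 - fx) + vol[x1, y0, z1] * fx
                c10 = vol[x0, y1, z0] * (1 - fx) + vol[x1, y1, z0] * fx
                c11 = vol[x0, y1, z1] * (1 - fx) + vol[x1, y1, z1] * fx
                c0 = c00 * (1 - fy) + c10 * fy
                c1 = c01 * (1 - fy) + c11 * fy
                out[i, j, k] = c0 * (1 - fz) + c1 * fz
    return out


def test_identity_field_leaves_volume_unchanged(rng):
    vol = Volume(rng.random((5, 6, 7)))
    out = warp(vol, identity_field((5, 6, 7)))
    assert np.allclose(out.intensities, vol.intensities, atol=1e-12)
    out_n = warp(vol, identity_field((5, 6, 7)), interpolation="nearest")
    assert np.array_equal(out_n.intensities, vol.intensities)


def test_integer_shift_matches_array_reindexing(rng):
    vol = Volume(rng.random((4, 4, 4)))
    u = np.zeros((3, 4, 4, 4))
    u[0] = 1.0  # sample from p + (1,0,0)
    out = warp(vol, DisplacementField(u), padding_mode="zeros")
    manual = np.zeros((4, 4, 4))
    manual[:3] = vol.intensities[1:]
    assert np.array_equal(out.intensities, manual)


@pytest.mark.parametrize("seed", range(20))
def test_warp_matches_trilinear_oracle(seed):
    rng = np.random.default_rng(seed)
    shape = tuple(rng.integers(3, 9, size=3))
    vol = rng.random(shape)
    u = rng.normal(0, 1.0, size=(3,) + shape)
    ours = warp(Volume(vol), DisplacementField(u)).intensities
    assert np.max(np.abs(ours - trilinear_oracle(vol, u))) < 1e-6


def test_warp_is_linear_in_the_sampled_volume(rng):
    shape = (6, 6, 6)
    x, y = rng.random(shape), rng.random(shape)
    u = rng.normal(0, 0.7, size=(3,) + shape)
    fld = DisplacementField(u)
    lhs = warp(Volume(2.0 * x + 3.0 * y), fld).intensities
    rhs = (2.0 * warp(Volume(x), fld).intensities
           + 3.0 * warp(Volume(y), fld).intensities)
    assert np.allclose(lhs, rhs, atol=1e-10)


def test_warp_shape_mismatch_raises(rng):
    with pytest.raises(ValueError, match="match"):
        warp(Volume(rng.random((4, 4, 4))), identity_field((5, 5, 5)))


def test_regularizer_zero_field_is_zero():
    r = displacement_regularizer(identity_field((6, 6, 6)), alpha=3, beta=7)
    assert r["total"] == 0.0


def test_regularizer_constant_unit_field_analytic():
    u = np.zeros((3, 4, 4, 4))
    u[0] = 1.0
    r = displacement_regularizer(DisplacementField(u), alpha=5.0, beta=1.0)
    assert r["total"] == pytest.approx(5.0)
    assert r["magnitude"] == pytest.approx(1.0)
    assert r["gradient"] == 0.0


def test_regularizer_step_field_gradient_hand_count():
    # single axis-0 step of height h: (#step voxels) forward differences
    # of h^2 spread over #voxels
    u = np.zeros((3, 4, 4, 4))
    h = 2.0
    u[0, 2:] = h
    r = displacement_regularizer(DisplacementField(u), alpha=0.0, beta=1.0)
    assert r["gradient"] == pytest.approx(h ** 2 * 16 / 64)


@pytest.mark.parametrize("c", [0.5, 2.0, 3.0])
def test_regularizer_scales_quadratically(rng, c):
    u = rng.normal(size=(3, 5, 5, 5))
    base = displacement_regularizer(DisplacementField(u), 2.0, 3.0)
    scaled = displacement_regularizer(DisplacementField(c * u), 2.0, 3.0)
    assert scaled["magnitude"] == pytest.approx(c ** 2 * base["magnitude"])
    assert scaled["gradient"] == pytest.approx(c ** 2 * base["gradient"])


def test_regularizer_gradient_term_translation_invariant(rng):
    u = rng.normal(size=(3, 5, 5, 5))
    shifted = u + np.array([1.7, -0.3, 2.2]).reshape(3, 1, 1, 1)
    a = displacement_regularizer(DisplacementField(u), 1.0, 1.0)
    b = displacement_regularizer(DisplacementField(shifted), 1.0, 1.0)
    assert b["gradient"] == pytest.approx(a["gradient"])


@settings(max_examples=25, deadline=None, derandomize=True)
@given(c=st.floats(0.1, 5.0), alpha=st.floats(0.0, 10.0),
       beta=st.floats(0.0, 10.0), seed=st.integers(0, 1000))
def test_regularizer_homogeneity_property(c, alpha, beta, seed):
    """R is homogeneous of degree 2 in the displacement for any weights."""
    u = np.random.default_rng(seed).normal(size=(3, 4, 4, 4))
    base = displacement_regularizer(DisplacementField(u), alpha, beta)
    scaled = displacement_regularizer(DisplacementField(c * u), alpha, beta)
    assert scaled["total"] == pytest.approx(c ** 2 * base["total"], rel=1e-9)


def test_regularizer_rejects_negative_weights():
    with pytest.raises(ValueError):
        displacement_regularizer(identity_field((4, 4, 4)), alpha=-1.0)


def test_jacobian_identity_and_translation_are_one(rng):
    jd = jacobian_determinant(identity_field((6, 6, 6)))
    assert np.allclose(jd["determinant"], 1.0)
    assert jd["fraction_nonpositive"] == 0.0
    const = np.broadcast_to(
        np.array([1.2, -0.7, 0.4]).reshape(3, 1, 1, 1), (3, 6, 6, 6)).copy()
    jd2 = jacobian_determinant(DisplacementField(const))
    assert np.allclose(jd2["determinant"], 1.0)


def test_jacobian_uniform_expansion_closed_form():
    shape = (12, 12, 12)
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                        indexing="ij")
    center = 5.5
    u = np.stack([0.1 * (g - center) for g in grids])
    det = jacobian_determinant(DisplacementField(u))["determinant"]
    interior = det[2:-2, 2:-2, 2:-2]
    assert np.allclose(interior, 1.1 ** 3, atol=1e-9)
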