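"""Differentiable array operations for 3D volumes.

Contains the two structured ops the tensor module does not cover pointwise:
a strided 3D convolution (im2col via ``sliding_window_view`` + einsum, with
an exact scatter-style backward) and a trilinear grid-sampler differentiable
with respect to both the sampled volume and the displacement field.

Array layout convention is channels-first: volumes are ``(N, C, D, H, W)``,
displacement fields ``(N, 3, D, H, W)`` with channel d holding displacement
along axis d in voxel units.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, as_tensor

__all__ = ["conv3d", "upsample_nearest", "grid_sample", "grid_sample_numpy"]


def conv3d(x, w, b=None, stride: int = 1, padding: int = 0) -> Tensor:
    """3D convolution (cross-correlation) with isotropic stride and padding.

    x: (N, Cin, D, H, W); w: (Cout, Cin, k, k, k); b: (Cout,) or None.
    """
    x, w = as_tensor(x), as_tensor(w)
    if b is not None:
        b = as_tensor(b)
    N, Cin, D, H, W = x.data.shape
    Cout, Cin_w, k, _, _ = w.data.shape
    if Cin != Cin_w:
        raise ValueError(f"conv3d channel mismatch: input {Cin}, weight {Cin_w}")
    p, s = padding, stride
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x.data
    # windows: (N, Cin, Do, Ho, Wo, k, k, k)
    win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))[:, :, ::s, ::s, ::s]
    out_data = np.einsum("ncdhwijk,ocijk->nodhw", win, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None, None]
    Do, Ho, Wo = out_data.shape[2:]
    req = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)
    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        if w.requires_grad:
            gw = np.einsum("ncdhwijk,nodhw->ocijk", win, g, optimize=True)
            Tensor._accum(w, gw)
        if b is not None and b.requires_grad:
            Tensor._accum(b, g.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            # scatter per kernel offset: 27 strided adds
            for i in range(k):
                for j in range(k):
                    for l in range(k):
                        contrib = np.einsum(
                            "nodhw,oc->ncdhw", g, w.data[:, :, i, j, l], optimize=True
                        )
                        gxp[:, :, i : i + Do * s : s, j : j + Ho * s : s,
                            l : l + Wo * s : s] += contrib
            gx = gxp[:, :, p : p + D, p : p + H, p : p + W] if p else gxp
            Tensor._accum(x, gx)

    return Tensor(out_data, req, parents, bw)


def upsample_nearest(x, factor: int = 2) -> Tensor:
    """Nearest-neighbour upsampling of the three spatial axes."""
    x = as_tensor(x)
    f = factor
    out_data = x.data.repeat(f, axis=2).repeat(f, axis=3).repeat(f, axis=4)
    N, C, D, H, W = x.data.shape

    def bw(g):
        g6 = g.reshape(N, C, D, f, H, f, W, f)
        Tensor._accum(x, g6.sum(axis=(3, 5, 7)))

    return Tensor(out_data, x.requires_grad, (x,), bw)


def _corner_gather(vol: np.ndarray, I, J, K) -> np.ndarray:
    """vol (N,C,D,H,W), integer index grids (N,D,H,W) -> (N,C,D,H,W)."""
    N = vol.shape[0]
    out = np.empty((N, vol.shape[1]) + I.shape[1:], dtype=vol.dtype)
    for n in range(N):
        out[n] = vol[n][:, I[n], J[n], K[n]]
    return out


def grid_sample(volume, displacement, padding_mode: str = "border") -> Tensor:
    """Warp `volume` by `displacement` with trilinear interpolation.

    output(p) = volume(p + u(p)); differentiable w.r.t. both inputs.
    padding_mode 'border' clamps sample positions to the volume extent;
    'zeros' treats out-of-bounds samples as zero intensity.
    """
    volume, displacement = as_tensor(volume), as_tensor(displacement)
    vol, u = volume.data, displacement.data
    N, C, D, H, W = vol.shape
    if u.shape != (N, 3, D, H, W):
        raise ValueError(
            f"displacement shape {u.shape} does not match volume {vol.shape}"
        )
    if padding_mode not in ("border", "zeros"):
        raise ValueError(f"unknown padding_mode {padding_mode!r}")

    idg = np.meshgrid(
        np.arange(D, dtype=vol.dtype),
        np.arange(H, dtype=vol.dtype),
        np.arange(W, dtype=vol.dtype),
        indexing="ij",
    )
    pos = [idg[d][None] + u[:, d] for d in range(3)]  # each (N,D,H,W)
    dims = (D, H, W)

    if padding_mode == "zeros":
        inside = np.ones(pos[0].shape, dtype=bool)
        for d in range(3):
            inside &= (pos[d] >= 0.0) & (pos[d] <= dims[d] - 1)

    clamped, lo, frac, hi = [], [], [], []
    interior = []  # where the position is strictly inside (gradient flows)
    for d in range(3):
        pc = np.clip(pos[d], 0.0, dims[d] - 1)
        f0 = np.floor(pc)
        i0 = f0.astype(np.intp)
        i1 = np.minimum(i0 + 1, dims[d] - 1)
        clamped.append(pc)
        lo.append(i0)
        hi.append(i1)
        frac.append(pc - f0)
        interior.append((pos[d] > 0.0) & (pos[d] < dims[d] - 1))

    fx, fy, fz = frac
    corners = []  # (index grids, weight)
    for cx, wx in ((lo[0], 1.0 - fx), (hi[0], fx)):
        for cy, wy in ((lo[1], 1.0 - fy), (hi[1], fy)):
            for cz, wz in ((lo[2], 1.0 - fz), (hi[2], fz)):
                corners.append((cx, cy, cz, wx * wy * wz))

    gathered = [_corner_gather(vol, cx, cy, cz) for cx, cy, cz, _ in corners]
    weights = [wgt for *_, wgt in corners]
    if padding_mode == "zeros":
        weights = [wgt * inside for wgt in weights]
    out_data = sum(gth * wgt[:, None] for gth, wgt in zip(gathered, weights))

    req = volume.requires_grad or displacement.requires_grad

    def bw(g):
        if volume.requires_grad:
            gvol = np.zeros_like(vol)
            flat = gvol.reshape(N, C, -1)
            for (cx, cy, cz, _), wgt in zip(corners, weights):
                lin = (cx * H + cy) * W + cz  # (N,D,H,W)
                contrib = (g * wgt[:, None]).reshape(N, C, -1)
                for n in range(N):
                    np.add.at(flat[n], (slice(None), lin[n].ravel()),
                              contrib[n])
            Tensor._accum(volume, gvol)
        if displacement.requires_grad:
            # d out / d pos_d: trilinear weight derivative; zero where clamped
            wx0, wx1 = 1.0 - fx, fx
            wy0, wy1 = 1.0 - fy, fy
            wz0, wz1 = 1.0 - fz, fz
            # gather all 8 corners (already done)
            c000, c001, c010, c011, c100, c101, c110, c111 = gathered
            if padding_mode == "zeros":
                m = inside[:, None]
                c000, c001, c010, c011 = c000 * m, c001 * m, c010 * m, c011 * m
                c100, c101, c110, c111 = c100 * m, c101 * m, c110 * m, c111 * m
            ddx = ((c100 - c000) * (wy0 * wz0)[:, None]
                   + (c101 - c001) * (wy0 * wz1)[:, None]
                   + (c110 - c010) * (wy1 * wz0)[:, None]
                   + (c111 - c011) * (wy1 * wz1)[:, None])
            ddy = ((c010 - c000) * (wx0 * wz0)[:, None]
                   + (c011 - c001) * (wx0 * wz1)[:, None]
                   + (c110 - c100) * (wx1 * wz0)[:, None]
                   + (c111 - c101) * (wx1 * wz1)[:, None])
            ddz = ((c001 - c000) * (wx0 * wy0)[:, None]
                   + (c011 - c010) * (wx0 * wy1)[:, None]
                   + (c101 - c100) * (wx1 * wy0)[:, None]
                   + (c111 - c110) * (wx1 * wy1)[:, None])
            gu = np.empty_like(u)
            gu[:, 0] = (g * ddx).sum(axis=1) * interior[0]
            gu[:, 1] = (g * ddy).sum(axis=1) * interior[1]
            gu[:, 2] = (g * ddz).sum(axis=1) * interior[2]
            Tensor._accum(displacement, gu)

    return Tensor(out_data, req, (volume, displacement), bw)


def grid_sample_numpy(vol: np.ndarray, u: np.ndarray,
                      interpolation: str = "trilinear",
                      padding_mode: str = "border") -> np.ndarray:
    """Non-differentiable sampler on plain arrays (3D, single item).

    vol: (D,H,W); u: (3,D,H,W). `nearest` is intended for label maps.
    """
    if interpolation == "trilinear":
        out = grid_sample(vol[None, None], u[None], padding_mode=padding_mode)
        return out.data[0, 0]
    if interpolation != "nearest":
        raise ValueError(f"unknown interpolation {interpolation!r}")
    D, H, W = vol.shape
    idg = np.meshgrid(np.arange(D), np.arange(H), np.arange(W), indexing="ij")
    dims = (D, H, W)
    pos = [idg[d] + u[d] for d in range(3)]
    idx = [np.clip(np.rint(pos[d]), 0, dims[d] - 1).astype(np.intp)
           for d in range(3)]
    out = vol[idx[0], idx[1], idx[2]]
    if padding_mode == "zeros":
        inside = np.ones(pos[0].shape, dtype=bool)
        for d in range(3):
            inside &= (pos[d] >= -0.5) & (pos[d] <= dims[d] - 0.5)
        out = np.where(inside, out, 0)
    return out
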