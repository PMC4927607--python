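"""Numba ray-tracing kernels.

Line integrals are evaluated by fixed-step sampling with trilinear
interpolation; the backprojector applies the exact transpose weights, so the
forward/back pair passes a dot-product (adjointness) test to float64
round-off.  Sample positions depend only on the ray endpoints and the step,
never on the volume, which keeps the operator linear.

Out-of-volume samples contribute zero (vacuum outside the reconstructed
cylinder); the volume grid is centred on the physical origin.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["line_integrals", "back_line_integrals"]


@njit(cache=True, fastmath=True)
def _trilinear_fetch(vol, fx, fy, fz):
    nx, ny, nz = vol.shape
    ix = int(np.floor(fx))
    iy = int(np.floor(fy))
    iz = int(np.floor(fz))
    dx = fx - ix
    dy = fy - iy
    dz = fz - iz
    acc = 0.0
    for cx in range(2):
        jx = ix + cx
        if jx < 0 or jx >= nx:
            continue
        wx = dx if cx == 1 else 1.0 - dx
        for cy in range(2):
            jy = iy + cy
            if jy < 0 or jy >= ny:
                continue
            wy = dy if cy == 1 else 1.0 - dy
            for cz in range(2):
                jz = iz + cz
                if jz < 0 or jz >= nz:
                    continue
                wz = dz if cz == 1 else 1.0 - dz
                acc += vol[jx, jy, jz] * wx * wy * wz
    return acc


@njit(cache=True, fastmath=True)
def line_integrals(vol, px, py, pz, a, b, step):
    """Integral of ``vol`` along each segment a[i] -> b[i] (units x mm)."""
    n_rays = a.shape[0]
    nx, ny, nz = vol.shape
    cx = (nx - 1) / 2.0
    cy = (ny - 1) / 2.0
    cz = (nz - 1) / 2.0
    out = np.zeros(n_rays)
    for i in range(n_rays):
        dxr = b[i, 0] - a[i, 0]
        dyr = b[i, 1] - a[i, 1]
        dzr = b[i, 2] - a[i, 2]
        length = np.sqrt(dxr * dxr + dyr * dyr + dzr * dzr)
        if length <= 0.0:
            continue
        nsteps = int(np.ceil(length / step))
        if nsteps < 1:
            nsteps = 1
        dt = length / nsteps
        acc = 0.0
        for k in range(nsteps):
            t = (k + 0.5) / nsteps
            x = a[i, 0] + t * dxr
            y = a[i, 1] + t * dyr
            z = a[i, 2] + t * dzr
            fx = x / px + cx
            fy = y / py + cy
            fz = z / pz + cz
            if fx < -1.0 or fx > nx or fy < -1.0 or fy > ny or fz < -1.0 or fz > nz:
                continue
            acc += _trilinear_fetch(vol, fx, fy, fz)
        out[i] = acc * dt
    return out


@njit(cache=True, fastmath=True)
def back_line_integrals(vol_out, px, py, pz, a, b, step, weights):
    """Transpose of :func:`line_integrals`: smear weights[i] along each ray."""
    n_rays = a.shape[0]
    nx, ny, nz = vol_out.shape
    cx = (nx - 1) / 2.0
    cy = (ny - 1) / 2.0
    cz = (nz - 1) / 2.0
    for i in range(n_rays):
        w = weights[i]
        if w == 0.0:
            continue
        dxr = b[i, 0] - a[i, 0]
        dyr = b[i, 1] - a[i, 1]
        dzr = b[i, 2] - a[i, 2]
        length = np.sqrt(dxr * dxr + dyr * dyr + dzr * dzr)
        if length <= 0.0:
            continue
        nsteps = int(np.ceil(length / step))
        if nsteps < 1:
            nsteps = 1
        dt = length / nsteps
        wv = w * dt
        for k in range(nsteps):
            t = (k + 0.5) / nsteps
            x = a[i, 0] + t * dxr
            y = a[i, 1] + t * dyr
            z = a[i, 2] + t * dzr
            fx = x / px + cx
            fy = y / py + cy
            fz = z / pz + cz
            if fx < -1.0 or fx > nx or fy < -1.0 or fy > ny or fz < -1.0 or fz > nz:
                continue
            ix = int(np.floor(fx))
            iy = int(np.floor(fy))
            iz = int(np.floor(fz))
            ddx = fx - ix
            ddy = fy - iy
            ddz = fz - iz
            for ax in range(2):
                jx = ix + ax
                if jx < 0 or jx >= nx:
                    continue
                wx = ddx if ax == 1 else 1.0 - ddx
                for ay in range(2):
                    jy = iy + ay
                    if jy < 0 or jy >= ny:
                        continue
                    wy = ddy if ay == 1 else 1.0 - ddy
                    for az in range(2):
                        jz = iz + az
                        if jz < 0 or jz >= nz:
                            continue
                        wz = ddz if az == 1 else 1.0 - ddz
                        vol_out[jx, jy, jz] += wv * wx * wy * wz
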