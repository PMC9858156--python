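"""Compiled trajectory tracer for spatial sensitivity maps.

Shares the elementary physics helpers with the main engine; the extra cost
over plain transport is a per-photon vertex buffer so that a detected
trajectory can be rotated to azimuth zero and rasterised into the x–z grid.
Segments are subdivided to half the bin pitch before deposition.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .transport import _fresnel, _hg_cos_theta, _rotate_direction

_MAX_VERTICES = 200_000


@njit(cache=True)
def _deposit(grid, x_edges, z_edges, x0, z0, x1, z1, amount):
    """Spread a segment's deposit over sub-steps of <= half a bin pitch."""
    seg = math.sqrt((x1 - x0) * (x1 - x0) + (z1 - z0) * (z1 - z0))
    if seg <= 0.0:
        return
    dx_bin = x_edges[1] - x_edges[0]
    dz_bin = z_edges[1] - z_edges[0]
    sub = 0.5 * min(dx_bin, dz_bin)
    n_sub = int(seg / sub) + 1
    frac = amount / n_sub
    for k in range(n_sub):
        t = (k + 0.5) / n_sub
        xs = x0 + t * (x1 - x0)
        zs = z0 + t * (z1 - z0)
        ix = int((xs - x_edges[0]) / dx_bin)
        iz = int((zs - z_edges[0]) / dz_bin)
        if 0 <= ix < len(x_edges) - 1 and 0 <= iz < len(z_edges) - 1:
            grid[ix, iz] += frac


@njit(cache=True)
def trace_sensitivity(
    n_photons,
    seed,
    z_top,
    z_bot,
    mua,
    mus,
    g_arr,
    n_arr,
    n_ambient,
    sample_total,
    fresnel_on,
    extend_bottom,
    roulette_threshold,
    roulette_survival,
    max_path,
    r_lo,
    r_hi,
    x_edges,
    z_edges,
):
    np.random.seed(seed)
    n_layers = len(mua)
    grid = np.zeros((len(x_edges) - 1, len(z_edges) - 1))
    verts = np.zeros((_MAX_VERTICES, 3))
    n_detected = 0

    if fresnel_on:
        r_sp = _fresnel(1.0, n_ambient, n_arr[0])
    else:
        r_sp = 0.0

    for _ in range(n_photons):
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        layer = 0
        w = 1.0 - r_sp
        total_path = 0.0
        nv = 1
        verts[0, 0] = 0.0
        verts[0, 1] = 0.0
        verts[0, 2] = 0.0
        overflow = False
        alive = True
        detected = False

        while alive:
            s = -math.log(np.random.random())
            while True:
                if sample_total:
                    mu_samp = mua[layer] + mus[layer]
                else:
                    mu_samp = mus[layer]
                step = s / mu_samp
                if uz > 0.0:
                    if extend_bottom and layer == n_layers - 1:
                        db = 1e30
                    else:
                        db = (z_bot[layer] - z) / uz
                elif uz < 0.0:
                    db = (z_top[layer] - z) / uz
                else:
                    db = 1e30
                move = step if step < db else db
                x += move * ux
                y += move * uy
                z += move * uz
                total_path += move
                if nv < _MAX_VERTICES:
                    verts[nv, 0] = x
                    verts[nv, 1] = y
                    verts[nv, 2] = z
                    nv += 1
                else:
                    overflow = True
                if total_path > max_path:
                    alive = False
                    break
                if step < db:
                    break
                s -= db * mu_samp
                if uz < 0.0:
                    z = z_top[layer]
                    if layer == 0:
                        cos_i = -uz
                        refl = _fresnel(cos_i, n_arr[0], n_ambient) if fresnel_on else 0.0
                        if refl < 1.0 and np.random.random() >= refl:
                            r = math.sqrt(x * x + y * y)
                            if r_lo <= r < r_hi and not overflow:
                                detected = True
                            alive = False
                            break
                        uz = -uz
                    else:
                        n1 = n_arr[layer]
                        n2 = n_arr[layer - 1]
                        if fresnel_on and n1 != n2:
                            cos_i = -uz
                            refl = _fresnel(cos_i, n1, n2)
                            if np.random.random() < refl:
                                uz = -uz
                            else:
                                ratio = n1 / n2
                                sin_t2 = ratio * ratio * (1.0 - cos_i * cos_i)
                                cos_t = math.sqrt(max(0.0, 1.0 - sin_t2))
                                ux *= ratio
                                uy *= ratio
                                uz = -cos_t
                                layer -= 1
                        else:
                            layer -= 1
                else:
                    z = z_bot[layer]
                    if layer == n_layers - 1:
                        alive = False
                        break
                    n1 = n_arr[layer]
                    n2 = n_arr[layer + 1]
                    if fresnel_on and n1 != n2:
                        cos_i = uz
                        refl = _fresnel(cos_i, n1, n2)
                        if np.random.random() < refl:
                            uz = -uz
                        else:
                            ratio = n1 / n2
                            sin_t2 = ratio * ratio * (1.0 - cos_i * cos_i)
                            cos_t = math.sqrt(max(0.0, 1.0 - sin_t2))
                            ux *= ratio
                            uy *= ratio
                            uz = cos_t
                            layer += 1
                    else:
                        layer += 1
            if not alive:
                if detected:
                    # rotate trajectory so the exit azimuth is zero
                    phi = math.atan2(y, x)
                    c = math.cos(-phi)
                    sn = math.sin(-phi)
                    n_detected += 1
                    for k in range(nv - 1):
                        x0 = verts[k, 0] * c - verts[k, 1] * sn
                        z0 = verts[k, 2]
                        x1 = verts[k + 1, 0] * c - verts[k + 1, 1] * sn
                        z1 = verts[k + 1, 2]
                        seg = math.sqrt(
                            (verts[k + 1, 0] - verts[k, 0]) ** 2
                            + (verts[k + 1, 1] - verts[k, 1]) ** 2
                            + (verts[k + 1, 2] - verts[k, 2]) ** 2
                        )
                        _deposit(grid, x_edges, z_edges, x0, z0, x1, z1, w * seg)
                break

            mu_a = mua[layer]
            mu_s = mus[layer]
            dw = w * mu_a / (mu_a + mu_s)
            w -= dw
            cost = _hg_cos_theta(g_arr[layer], np.random.random())
            phi2 = 2.0 * math.pi * np.random.random()
            ux, uy, uz = _rotate_direction(ux, uy, uz, cost, phi2)
            if roulette_threshold > 0.0 and w < roulette_threshold:
                if np.random.random() < roulette_survival:
                    w /= roulette_survival
                else:
                    break

    return grid, n_detected
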