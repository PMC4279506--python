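"""Numba-compiled photon-transport kernel and its single-photon primitives.

The kernel follows the standard variance-reduced random walk for layered
turbid media: exponential step sampling in dimensionless optical depth,
partial weight deposition mu_a/mu_t at each interaction, Henyey-Greenstein
scattering, unpolarised Fresnel reflection / Snell refraction at layer
boundaries (with the residual optical depth carried across, rescaled by the
new layer's mu_t), and Russian roulette termination of low-weight photons.

All tallies are accumulated in cylindrical (r, z) bins with one overflow bin
per axis.  ``crossing`` records each photon's *first* downward crossing of
every tally z-plane, radially resolved at the crossing point; this is the
basis of the energy-versus-depth curves and detector capture fractions.

Roulette conserves energy only in expectation, so the kernel also returns
``roulette_net`` (weight destroyed minus weight injected by survival
boosts); including it closes the per-run energy budget to float precision.

The primitives are importable and used directly by the Python-level engine
API, so unit tests exercise exactly the arithmetic the full runs execute.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

#: Direction cosines closer to vertical than this are treated as normal
#: incidence in the Fresnel formula (avoids 0/0 in the angle form).
_COS_NEARLY_NORMAL = 1.0 - 1e-12


@njit(cache=True)
def step_from_xi(xi: float, mu_t: float) -> float:
    """Free-path length s = -ln(xi)/mu_t for a uniform deviate xi in (0, 1]."""
    return -math.log(xi) / mu_t


@njit(cache=True)
def hg_cos_from_xi(g: float, xi: float) -> float:
    """Sample cos(theta) from the Henyey-Greenstein phase function."""
    if abs(g) < 1e-8:
        return 2.0 * xi - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
    cost = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if cost > 1.0:
        cost = 1.0
    elif cost < -1.0:
        cost = -1.0
    return cost


@njit(cache=True)
def fresnel_unpolarized(n1: float, n2: float, cos_i: float) -> tuple[float, float]:
    """Unpolarised Fresnel reflectance and transmitted cosine.

    Returns ``(R, cos_t)``; beyond the critical angle R = 1 and cos_t = 0.
    """
    if n1 == n2:
        return 0.0, cos_i
    if cos_i > _COS_NEARLY_NORMAL:
        r = (n1 - n2) / (n1 + n2)
        return r * r, 1.0
    sin_i = math.sqrt(max(0.0, 1.0 - cos_i * cos_i))
    sin_t = n1 / n2 * sin_i
    if sin_t >= 1.0:
        return 1.0, 0.0
    cos_t = math.sqrt(1.0 - sin_t * sin_t)
    # sin/cos of (theta_i -/+ theta_t) via addition formulas
    s_m = sin_i * cos_t - cos_i * sin_t
    s_p = sin_i * cos_t + cos_i * sin_t
    c_m = cos_i * cos_t + sin_i * sin_t
    c_p = cos_i * cos_t - sin_i * sin_t
    r = 0.5 * (s_m * s_m) * (c_m * c_m + c_p * c_p) / (s_p * s_p * c_m * c_m)
    return r, cos_t


@njit(cache=True)
def rotate_direction(
    ux: float, uy: float, uz: float, cos_t: float, phi: float
) -> tuple[float, float, float]:
    """Deflect a unit vector by scattering angle theta and azimuth phi."""
    sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    cos_p = math.cos(phi)
    sin_p = math.sin(phi)
    if abs(uz) > 0.99999:
        nux = sin_t * cos_p
        nuy = sin_t * sin_p
        nuz = cos_t if uz >= 0.0 else -cos_t
    else:
        tmp = math.sqrt(1.0 - uz * uz)
        nux = sin_t * (ux * uz * cos_p - uy * sin_p) / tmp + ux * cos_t
        nuy = sin_t * (uy * uz * cos_p + ux * sin_p) / tmp + uy * cos_t
        nuz = -sin_t * cos_p * tmp + uz * cos_t
    norm = math.sqrt(nux * nux + nuy * nuy + nuz * nuz)
    return nux / norm, nuy / norm, nuz / norm


@njit(cache=True)
def _tally_crossing(
    crossing: np.ndarray,
    x0: float,
    y0: float,
    z0: float,
    x1: float,
    y1: float,
    z1: float,
    w: float,
    deepest: int,
    dr: float,
    dz: float,
    nr: int,
    nz: int,
) -> int:
    """Record first downward crossings of tally planes along one straight move."""
    if z1 <= z0:
        return deepest
    p_target = int(z1 / dz)
    if p_target > nz:
        p_target = nz
    while deepest < p_target:
        p = deepest + 1
        zp = p * dz
        t = (zp - z0) / (z1 - z0)
        xc = x0 + t * (x1 - x0)
        yc = y0 + t * (y1 - y0)
        ir = int(math.sqrt(xc * xc + yc * yc) / dr)
        if ir > nr:
            ir = nr
        crossing[ir, p] += w
        deepest = p
    return deepest


@njit(cache=True)
def run_photons(
    n_photons: int,
    seed: int,
    beam_radius: float,
    dr: float,
    dz: float,
    nr: int,
    nz: int,
    w_threshold: float,
    p_survival: float,
    z_bounds: np.ndarray,
    mu_a: np.ndarray,
    mu_s: np.ndarray,
    g: np.ndarray,
    n_layer: np.ndarray,
    n_above: float,
    n_below: float,
):
    """Transport ``n_photons`` through the stack; return raw weight tallies.

    Lengths in mm, coefficients in mm^-1.  ``beam_radius <= 0`` selects a
    pencil beam on the axis; otherwise launch positions are uniform over the
    disk.  Returns (specular, refl_r, trans_r, absorb_rz, per_layer,
    crossing_rz, roulette_net); index nr / nz of each radial / depth axis is
    the overflow bin, and crossing plane p sits at depth p*dz.
    """
    np.random.seed(seed)
    n_lay = mu_a.shape[0]
    refl = np.zeros(nr + 1)
    trans = np.zeros(nr + 1)
    absorb = np.zeros((nr + 1, nz + 1))
    per_layer = np.zeros(n_lay)
    crossing = np.zeros((nr + 1, nz + 1))
    specular = 0.0
    roulette_net = 0.0

    r_sp = (n_above - n_layer[0]) / (n_above + n_layer[0])
    r_sp = r_sp * r_sp

    for _ in range(n_photons):
        if beam_radius > 0.0:
            rr = beam_radius * math.sqrt(np.random.random())
            phi = 2.0 * math.pi * np.random.random()
            x = rr * math.cos(phi)
            y = rr * math.sin(phi)
        else:
            x = 0.0
            y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        layer = 0
        w = 1.0 - r_sp
        specular += r_sp

        ir0 = int(math.sqrt(x * x + y * y) / dr)
        if ir0 > nr:
            ir0 = nr
        crossing[ir0, 0] += w
        deepest = 0

        step = 0.0  # residual dimensionless optical depth
        alive = True
        while alive:
            mt = mu_a[layer] + mu_s[layer]
            if step <= 0.0:
                xi = np.random.random()
                if xi <= 0.0:
                    xi = 1e-12
                step = -math.log(xi)
            s = step / mt
            if uz > 0.0:
                db = (z_bounds[layer + 1] - z) / uz
            elif uz < 0.0:
                db = (z_bounds[layer] - z) / uz
            else:
                db = 1.0e30

            if db <= s:
                # advance to the boundary, keep leftover optical depth
                xn = x + ux * db
                yn = y + uy * db
                zn = z + uz * db
                deepest = _tally_crossing(
                    crossing, x, y, z, xn, yn, zn, w, deepest, dr, dz, nr, nz
                )
                step -= db * mt
                x, y, z = xn, yn, zn

                going_down = uz > 0.0
                n1 = n_layer[layer]
                if going_down:
                    n2 = n_below if layer == n_lay - 1 else n_layer[layer + 1]
                else:
                    n2 = n_above if layer == 0 else n_layer[layer - 1]
                r_f, cos_t = fresnel_unpolarized(n1, n2, abs(uz))
                if np.random.random() < r_f:
                    uz = -uz
                else:
                    scale = n1 / n2
                    ux *= scale
                    uy *= scale
                    uz = cos_t if going_down else -cos_t
                    if going_down:
                        if layer == n_lay - 1:
                            ir = int(math.sqrt(x * x + y * y) / dr)
                            if ir > nr:
                                ir = nr
                            trans[ir] += w
                            alive = False
                        else:
                            layer += 1
                    else:
                        if layer == 0:
                            ir = int(math.sqrt(x * x + y * y) / dr)
                            if ir > nr:
                                ir = nr
                            refl[ir] += w
                            alive = False
                        else:
                            layer -= 1
            else:
                # interaction inside the current layer
                xn = x + ux * s
                yn = y + uy * s
                zn = z + uz * s
                deepest = _tally_crossing(
                    crossing, x, y, z, xn, yn, zn, w, deepest, dr, dz, nr, nz
                )
                x, y, z = xn, yn, zn
                step = 0.0

                dw = w * mu_a[layer] / mt
                ir = int(math.sqrt(x * x + y * y) / dr)
                if ir > nr:
                    ir = nr
                iz = int(z / dz)
                if iz > nz:
                    iz = nz
                absorb[ir, iz] += dw
                per_layer[layer] += dw
                w -= dw

                if w <= 0.0:
                    alive = False
                else:
                    cos_sc = hg_cos_from_xi(g[layer], np.random.random())
                    phi_sc = 2.0 * math.pi * np.random.random()
                    ux, uy, uz = rotate_direction(ux, uy, uz, cos_sc, phi_sc)
                    if w < w_threshold:
                        if np.random.random() < p_survival:
                            injected = w * (1.0 / p_survival - 1.0)
                            w += injected
                            roulette_net -= injected
                        else:
                            roulette_net += w
                            alive = False

    return specular, refl, trans, absorb, per_layer, crossing, roulette_net
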