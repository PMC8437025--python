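"""Numba kernels for layered photon transport.

Transport scheme: steps are sampled against the scattering coefficient only,
while absorption attenuates the photon weight continuously along each
segment (exp(-mu_a s)).  With a track-length fluence tally this makes the
per-bin absorbed weight identically mu_a times the tallied fluence and the
global weight balance exact per realization, and renders a purely absorbing
slab a zero-variance Beer-Lambert problem.

Each photon owns a counter-based splitmix64 stream derived from (seed,
photon index), so runs with the same seed are bit-identical and runs that
differ only in one layer's coefficients stay tightly correlated (common
random numbers).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit, uint64

_GAMMA = uint64(0x9E3779B97F4A7C15)
_MIX1 = uint64(0xBF58476D1CE4E5B9)
_MIX2 = uint64(0x94D049BB133111EB)

#: Russian-roulette weight threshold and survival probability.
ROULETTE_THRESHOLD = 1e-4
ROULETTE_SURVIVAL = 0.1


@njit(cache=True, inline="always")
def _rng_next(state):
    state = state + _GAMMA
    z = state
    z = (z ^ (z >> uint64(30))) * _MIX1
    z = (z ^ (z >> uint64(27))) * _MIX2
    z = z ^ (z >> uint64(31))
    # strictly inside (0, 1): never 0 so -log(u) is finite
    u = (np.float64(z >> uint64(11)) + 0.5) * (1.0 / 9007199254740992.0)
    return state, u


@njit(cache=True, inline="always")
def _photon_stream(seed, idx):
    state = uint64(seed) ^ (uint64(idx) * _MIX1 + _GAMMA)
    state, _ = _rng_next(state)
    state, _ = _rng_next(state)
    return state


@njit(cache=True, inline="always")
def hg_cos_scalar(g, u):
    """Inverse-CDF sample of the Henyey-Greenstein deflection cosine."""
    if abs(g) < 1e-6:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    cost = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if cost > 1.0:
        cost = 1.0
    elif cost < -1.0:
        cost = -1.0
    return cost


@njit(cache=True, inline="always")
def fresnel_scalar(n1, n2, cosi):
    """Unpolarized Fresnel reflectance; 1.0 under total internal reflection."""
    if n1 == n2:
        return 0.0
    sini2 = 1.0 - cosi * cosi
    if sini2 < 0.0:
        sini2 = 0.0
    r = n1 / n2
    sint2 = r * r * sini2
    if sint2 >= 1.0:
        return 1.0
    cost = math.sqrt(1.0 - sint2)
    rs = (n1 * cosi - n2 * cost) / (n1 * cosi + n2 * cost)
    rp = (n1 * cost - n2 * cosi) / (n1 * cost + n2 * cosi)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def transport_kernel(z_edges, bin_layer, mu_a, mu_s, g_lay, n_lay,
                     n_photons, seed, w_threshold, p_survival):
    """Trace photons through the layered slab; return the track-length tally.

    Returns (fluence, reflected, transmitted, roulette_killed,
    roulette_gain, lost).  ``fluence`` is the weight-integrated path length
    per z-bin (m); divide by n_photons and the bin thickness to normalize to
    the incident irradiance.
    """
    nz = bin_layer.shape[0]
    fluence = np.zeros(nz)
    reflected = 0.0
    transmitted = 0.0
    killed = 0.0
    gain = 0.0
    lost = 0.0
    eps_dir = 1e-12

    for idx in range(n_photons):
        state = _photon_stream(seed, idx)
        z = z_edges[0]
        b = 0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = 1.0
        state, u = _rng_next(state)
        tau = -math.log(u)

        while True:
            lay = bin_layer[b]
            mua = mu_a[lay]
            mus = mu_s[lay]

            if uz > eps_dir:
                d_edge = (z_edges[b + 1] - z) / uz
                exit_down = True
            elif uz < -eps_dir:
                d_edge = (z_edges[b] - z) / uz
                exit_down = False
            else:
                d_edge = math.inf
                exit_down = False
            d_scat = tau / mus if mus > 0.0 else math.inf
            d = d_scat if d_scat < d_edge else d_edge

            if not math.isfinite(d):
                lost += w  # horizontal flight in a collisionless medium
                break

            if mua > 0.0:
                att = math.exp(-mua * d)
                fluence[b] += w * (-math.expm1(-mua * d)) / mua
                w *= att
            else:
                fluence[b] += w * d

            if d_scat <= d_edge:
                z += d * uz
                tau_used = True
                # scatter: HG polar angle, uniform azimuth
                state, u = _rng_next(state)
                cost = hg_cos_scalar(g_lay[lay], u)
                sint = math.sqrt(max(0.0, 1.0 - cost * cost))
                state, u = _rng_next(state)
                phi = 2.0 * math.pi * u
                cosp = math.cos(phi)
                sinp = math.sin(phi)
                if abs(uz) > 0.99999:
                    ux = sint * cosp
                    uy = sint * sinp
                    uz = cost if uz > 0.0 else -cost
                else:
                    den = math.sqrt(1.0 - uz * uz)
                    nx = sint * (ux * uz * cosp - uy * sinp) / den + ux * cost
                    ny = sint * (uy * uz * cosp + ux * sinp) / den + uy * cost
                    nzdir = -sint * cosp * den + uz * cost
                    norm = math.sqrt(nx * nx + ny * ny + nzdir * nzdir)
                    ux = nx / norm
                    uy = ny / norm
                    uz = nzdir / norm
                state, u = _rng_next(state)
                tau = -math.log(u)
            else:
                if mus > 0.0:
                    tau -= mus * d
                if exit_down:
                    z = z_edges[b + 1]
                    if b == nz - 1:
                        # domain bottom: Fresnel interface to exterior air
                        refl = fresnel_scalar(n_lay[lay], 1.0, abs(uz))
                        state, u = _rng_next(state)
                        if u < refl:
                            uz = -uz
                            continue
                        transmitted += w
                        break
                    nb = b + 1
                else:
                    z = z_edges[b]
                    if b == 0:
                        # domain top: Fresnel interface to exterior air
                        refl = fresnel_scalar(n_lay[lay], 1.0, abs(uz))
                        state, u = _rng_next(state)
                        if u < refl:
                            uz = -uz
                            continue
                        reflected += w
                        break
                    nb = b - 1
                lay2 = bin_layer[nb]
                if lay2 != lay and n_lay[lay2] != n_lay[lay]:
                    cosi = abs(uz)
                    refl = fresnel_scalar(n_lay[lay], n_lay[lay2], cosi)
                    state, u = _rng_next(state)
                    if u < refl:
                        uz = -uz  # specular reflection, stay in current bin
                    else:
                        r = n_lay[lay] / n_lay[lay2]
                        ux *= r
                        uy *= r
                        s2 = 1.0 - r * r * (1.0 - cosi * cosi)
                        newuz = math.sqrt(s2) if s2 > 0.0 else 0.0
                        uz = newuz if uz > 0.0 else -newuz
                        b = nb
                else:
                    b = nb

            if w < w_threshold:
                state, u = _rng_next(state)
                if u < p_survival:
                    gain += w * (1.0 / p_survival - 1.0)
                    w /= p_survival
                else:
                    killed += w
                    break

    return fluence, reflected, transmitted, killed, gain, lost
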