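"""Monte Carlo photon transport through the layered coral slab.

Photons at a single wavelength (636 nm, inside the chlorophyll absorption
window of the symbionts) are launched as a collimated, normally incident
beam at the top of the air layer, scattered with the Henyey-Greenstein
phase function, refracted/reflected at refractive-index mismatches
(probabilistic unpolarized Fresnel), and attenuated by absorption.  Scalar
irradiance (fluence rate) is tallied with a track-length estimator on the
z-grid; because the slab, the beam and the lateral boundaries are all
invariant in x and y, the z-tally is the exact lateral average of the 3D
field and equals the mid-slice the 2D transport stage consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import constants
from scipy.ndimage import gaussian_filter1d

from . import _kernels
from .grid import DEFAULT_DZ, SimGrid, build_grid
from .scenarios import ConfigError, DomainSpec, LayerSpec, umol_to_mol

__all__ = [
    "LightField",
    "sample_step",
    "sample_hg_cos",
    "fresnel_reflectance",
    "run_photon_mc",
    "smooth_light_field",
    "mid_slice",
    "photon_energy_J_per_mol",
]


def photon_energy_J_per_mol(wavelength_nm: float) -> float:
    """Energy of one mole of photons, N_A h c / lambda (J mol^-1)."""
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    return constants.N_A * constants.h * constants.c / (wavelength_nm * 1e-9)


def sample_step(mu_t: float, u: float) -> float:
    """Free path length -ln(u)/mu_t (m); ballistic (inf) for mu_t <= 0."""
    if mu_t <= 0.0:
        return math.inf
    return -math.log(u) / mu_t


def sample_hg_cos(g, u):
    """Henyey-Greenstein deflection cosine(s) by CDF inversion.

    Vectorized over ``u``; the mean over uniform deviates equals g.
    """
    g = np.asarray(g, dtype=float)
    u = np.asarray(u, dtype=float)
    iso = np.abs(g) < 1e-6
    g_safe = np.where(iso, 0.5, g)
    tmp = (1.0 - g_safe**2) / (1.0 - g_safe + 2.0 * g_safe * u)
    cost = np.where(iso, 2.0 * u - 1.0, (1.0 + g_safe**2 - tmp**2) / (2.0 * g_safe))
    return np.clip(cost, -1.0, 1.0)[()]


def fresnel_reflectance(n1: float, n2: float, cos_incident: float) -> float:
    """Unpolarized Fresnel reflectance at a planar interface (1 under TIR)."""
    return float(_kernels.fresnel_scalar(n1, n2, cos_incident))


@dataclass
class LightField:
    """Gridded MC light field (x-invariant; arrays indexed by z-cell).

    ``normalized_fluence`` is scalar irradiance divided by the incident
    downwelling irradiance; the absorbed photon/power densities are the
    volumetric absorption rates driving photosynthesis and heating.
    """

    z_edges_m: np.ndarray
    x_centers_m: np.ndarray
    cell_layer: np.ndarray
    layer_names: tuple[str, ...]
    normalized_fluence: np.ndarray            # (nz,) dimensionless
    fluence_umol_m2_s: np.ndarray             # (nz,) photon scalar irradiance
    absorbed_photons_mol_m3_s: np.ndarray     # (nz,)
    absorbed_power_W_m3: np.ndarray           # (nz,)
    tallies: dict
    n_photons: int
    seed: int

    @property
    def z_centers_m(self) -> np.ndarray:
        return 0.5 * (self.z_edges_m[:-1] + self.z_edges_m[1:])

    @property
    def conservation_residual(self) -> float:
        t = self.tallies
        return abs(t["launched"] - t["reflected"] - t["transmitted"] - t["absorbed"]) / t["launched"]

    def as_2d(self, name: str) -> np.ndarray:
        """Broadcast a per-z quantity to the (nz, nx) PDE grid."""
        col = getattr(self, name)
        return np.repeat(col[:, None], self.x_centers_m.shape[0], axis=1)


def run_photon_mc(
    stack: Sequence[LayerSpec],
    domain: DomainSpec,
    n_photons: int = 1_000_000,
    seed: int = 0,
    grid: SimGrid | None = None,
    dz: float = DEFAULT_DZ,
) -> LightField:
    """Run the layered MC transport and tally the light field.

    Deterministic for a fixed seed.  The weight balance
    launched = reflected + transmitted + absorbed closes to float roundoff
    (the net Russian-roulette adjustment is folded into ``absorbed`` and
    also reported separately).
    """
    if n_photons < 1:
        raise ConfigError("n_photons must be >= 1")
    if grid is None:
        grid = build_grid(stack, domain, dz=dz)
    if grid.z_edges[-1] <= 0:
        raise ConfigError("stack has zero total thickness")

    mu_a = np.asarray(grid.props["mu_a_per_m"], dtype=float)
    mu_s = np.asarray(grid.props["mu_s_per_m"], dtype=float)
    g_lay = np.asarray(grid.props["g"], dtype=float)
    n_lay = np.asarray(grid.props["n"], dtype=float)

    raw, refl, trans, killed, gain, lost = _kernels.transport_kernel(
        grid.z_edges, grid.cell_layer, mu_a, mu_s, g_lay, n_lay,
        n_photons, seed, _kernels.ROULETTE_THRESHOLD, _kernels.ROULETTE_SURVIVAL,
    )
    deposited = float(np.sum(mu_a[grid.cell_layer] * raw))
    tallies = {
        "launched": float(n_photons),
        "reflected": refl,
        "transmitted": trans,
        "absorbed": deposited + killed + lost - gain,
        "absorbed_deposited": deposited,
        "roulette_killed": killed,
        "roulette_gain": gain,
        "lost": lost,
    }

    normalized = raw / (n_photons * grid.dz)
    fluence = normalized * domain.I_id_umol_m2_s
    absorbed_photons = umol_to_mol(mu_a[grid.cell_layer] * fluence)
    e_mol = photon_energy_J_per_mol(domain.wavelength_nm)
    return LightField(
        z_edges_m=grid.z_edges.copy(),
        x_centers_m=grid.x_centers,
        cell_layer=grid.cell_layer.copy(),
        layer_names=grid.layer_names,
        normalized_fluence=normalized,
        fluence_umol_m2_s=fluence,
        absorbed_photons_mol_m3_s=absorbed_photons,
        absorbed_power_W_m3=absorbed_photons * e_mol,
        tallies=tallies,
        n_photons=n_photons,
        seed=seed,
    )


def smooth_light_field(light: LightField, kernel_width_m: float | None = None) -> LightField:
    """Conservative within-layer Gaussian smoothing of the tallied field.

    Each per-z quantity is filtered layer by layer with reflecting ends, so
    the layer-integrated content (total absorbed power in particular) is
    preserved to float roundoff and no absorption leaks across material
    boundaries.  ``kernel_width_m`` is the Gaussian sigma; the default is
    two cell widths.
    """
    dz = np.diff(light.z_edges_m)
    if kernel_width_m is None:
        kernel_width_m = 2.0 * float(dz.min())
    if kernel_width_m < float(dz.min()):
        raise ValueError("kernel width must be at least one cell")

    def smooth(col: np.ndarray) -> np.ndarray:
        out = col.copy()
        for lay in range(len(light.layer_names)):
            sel = light.cell_layer == lay
            if sel.sum() < 2:
                continue
            sigma_cells = kernel_width_m / float(dz[sel][0])
            out[sel] = gaussian_filter1d(col[sel], sigma_cells, mode="reflect")
        return out

    return LightField(
        z_edges_m=light.z_edges_m,
        x_centers_m=light.x_centers_m,
        cell_layer=light.cell_layer,
        layer_names=light.layer_names,
        normalized_fluence=smooth(light.normalized_fluence),
        fluence_umol_m2_s=smooth(light.fluence_umol_m2_s),
        absorbed_photons_mol_m3_s=smooth(light.absorbed_photons_mol_m3_s),
        absorbed_power_W_m3=smooth(light.absorbed_power_W_m3),
        tallies=dict(light.tallies),
        n_photons=light.n_photons,
        seed=light.seed,
    )


def resample_light_field(light: LightField, grid) -> LightField:
    """Conservatively rebin the light field onto another grid's z-edges.

    Piecewise-constant rebinning via the cumulative depth integral: the
    integral of every per-z quantity over any span shared by both grids
    (layer interfaces in particular) is preserved exactly, so the PDE stage
    can be run on a coarser or finer mesh than the tally without changing
    the deposited power.
    """
    src = light.z_edges_m
    dst = grid.z_edges
    if not (abs(src[0] - dst[0]) < 1e-12 and abs(src[-1] - dst[-1]) < 1e-12):
        raise ValueError("grids must span the same slab")

    def rebin(col: np.ndarray) -> np.ndarray:
        cum = np.concatenate([[0.0], np.cumsum(col * np.diff(src))])
        on_dst = np.interp(dst, src, cum)
        return np.diff(on_dst) / np.diff(dst)

    return LightField(
        z_edges_m=dst.copy(),
        x_centers_m=grid.x_centers,
        cell_layer=grid.cell_layer.copy(),
        layer_names=grid.layer_names,
        normalized_fluence=rebin(light.normalized_fluence),
        fluence_umol_m2_s=rebin(light.fluence_umol_m2_s),
        absorbed_photons_mol_m3_s=rebin(light.absorbed_photons_mol_m3_s),
        absorbed_power_W_m3=rebin(light.absorbed_power_W_m3),
        tallies=dict(light.tallies),
        n_photons=light.n_photons,
        seed=light.seed,
    )


def mid_slice(values: np.ndarray) -> np.ndarray:
    """x-z slice through the middle of the domain.

    1D (already laterally averaged / 2D-equivalent) input is returned as is;
    for a (nz, nx) or (nz, nx, ny) array the central lateral index is taken.
    """
    arr = np.asarray(values)
    if arr.ndim == 1 or arr.ndim == 2:
        return arr if arr.ndim == 1 else arr
    if arr.ndim == 3:
        return arr[:, :, arr.shape[2] // 2]
    raise ValueError("expected a 1D, 2D or 3D field")
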