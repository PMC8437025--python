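"""Steady flow, heat and O2 transport in the coral slab microenvironment.

The absorbed light field drives two coupled steady problems on the shared
rectilinear grid:

* heat:   rho*Cp*u dT/dx = div(k grad T) + q,   q from photon absorption
* oxygen: u dc/dx = div(D grad c) + P - R_max*c/(K_O2 + c)

Flow is the laminar, unidirectional channel flow of the water layer
(no-slip at the coral surface, shear-free at the air-water interface); for
the flat slab the steady Stokes problem reduces exactly to this 1D profile
(Re ~ 9 at the baseline velocity, inertia negligible).  Both scalars are
discretized finite-volume with harmonic-mean diffusive conductances and
first-order upwind advection, and solved with a sparse direct factorization;
the Monod sink is handled by damped Picard iteration.

Boundary conditions (flow-chamber configuration): ambient temperature at
the top of the air layer and on the water inlet; inlet O2 concentration on
the water inlet; advective outflow on the right face; zero flux at the
skeleton bottom, at the lateral faces of solid layers, and (for O2) at the
air-water interface.  O2 is not solved in air.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import constants, sparse
from scipy.sparse.linalg import spsolve

from .grid import DEFAULT_DX, DEFAULT_DZ, SimGrid, build_grid
from .photon_mc import LightField, mid_slice, run_photon_mc, smooth_light_field
from .scenarios import ConfigError, DomainSpec, LayerSpec, umol_to_mol

__all__ = [
    "SourceFields",
    "FieldSolution",
    "SolverError",
    "photon_to_energy_flux",
    "build_sources",
    "solve_flow",
    "solve_heat",
    "solve_oxygen",
    "run_pipeline",
]


class SolverError(RuntimeError):
    """Raised when a steady solve fails to converge; carries residuals."""

    def __init__(self, message: str, residuals: list[float] | None = None):
        super().__init__(message)
        self.residuals = residuals or []


def photon_to_energy_flux(photon_irradiance_umol_m2_s: float, wavelength_nm: float) -> float:
    """Convert photon irradiance (umol photons m^-2 s^-1) to W m^-2."""
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    e_mol = constants.N_A * constants.h * constants.c / (wavelength_nm * 1e-9)
    return umol_to_mol(photon_irradiance_umol_m2_s) * e_mol


@dataclass
class SourceFields:
    """Volumetric sources per z-cell (x-invariant, like the light field)."""

    heat_W_m3: np.ndarray
    photosynthesis_mol_m3_s: np.ndarray
    respiration_capacity_mol_m3_s: np.ndarray


@dataclass
class FieldSolution:
    """Steady velocity, temperature and O2 fields with solver diagnostics."""

    grid: SimGrid
    velocity_m_s: np.ndarray        # (nz,) streamwise u; zero outside water
    elevation_K: np.ndarray         # (nz, nx) temperature elevation T - T0
    temperature_C: np.ndarray       # (nz, nx)
    oxygen_mol_m3: np.ndarray       # (nz, nx); NaN in the air layer
    residuals: dict = field(default_factory=dict)
    balances: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)


def build_sources(light: LightField, grid: SimGrid, domain: DomainSpec) -> SourceFields:
    """Partition absorbed light into heat and photosynthesis sources.

    In the symbiont-bearing gastrodermis a fraction f_ps of the absorbed
    energy is diverted into photochemistry, so only f_heat dissipates as
    heat there; absorption everywhere else is fully thermalized.  The
    photosynthetic O2 source is Q (mol O2 per mol photons) times the local
    volumetric photon absorption rate.
    """
    if light.z_edges_m.shape != grid.z_edges.shape or not np.allclose(
        light.z_edges_m, grid.z_edges
    ):
        raise ValueError("light field and grid are not congruent")
    gastro = grid.mask("oral_gastrodermis", "aboral_gastrodermis")
    heat = light.absorbed_power_W_m3 * np.where(gastro, domain.f_heat, 1.0)
    ps = grid.cell_prop("Q") * light.absorbed_photons_mol_m3_s
    return SourceFields(
        heat_W_m3=heat,
        photosynthesis_mol_m3_s=ps,
        respiration_capacity_mol_m3_s=grid.cell_prop("R_max"),
    )


def solve_flow(grid: SimGrid, domain: DomainSpec) -> np.ndarray:
    """Steady laminar streamwise velocity u(z) in the water layer (m/s).

    Solves eta*u'' = G with no-slip at the coral surface and zero shear at
    the air-water interface, with G scaled so the depth-averaged velocity is
    v0 (the fully developed half-Poiseuille profile).  Returns a full-domain
    per-z-cell array, zero outside the water layer.
    """
    u_full = np.zeros(grid.nz)
    v0 = domain.v0_cm_s * 1e-2
    if v0 == 0.0:
        return u_full
    iw = np.nonzero(grid.mask("water"))[0]
    if iw.size == 0:
        raise ConfigError("no water layer present")
    n = iw.size
    # uniform spacing within the layer; rows ordered top (free surface) to
    # bottom (coral wall)
    main = np.full(n, -2.0)
    lower = np.ones(n - 1)
    upper = np.ones(n - 1)
    main[0] = -1.0        # zero-shear ghost at the free surface
    main[-1] = -3.0       # u = 0 at the wall face (linear ghost)
    A = sparse.diags([lower, main, upper], [-1, 0, 1], format="csc")
    u = spsolve(A, -np.ones(n))     # unit forcing; profile shape only
    u *= v0 / u.mean()
    u_full[iw] = u
    return u_full


def _face_conductance_z(grid: SimGrid, coeff: np.ndarray) -> np.ndarray:
    """Harmonic-mean conductance per unit area between vertically adjacent
    cells (W m^-2 K^-1 or m s^-1 scale depending on ``coeff``)."""
    dz = grid.dz
    d1 = 0.5 * dz[:-1]
    d2 = 0.5 * dz[1:]
    with np.errstate(divide="ignore"):
        return 1.0 / (d1 / coeff[:-1] + d2 / coeff[1:])


def _assemble_advection_diffusion(
    dz: np.ndarray,
    dx: float,
    nx: int,
    coeff: np.ndarray,
    flow: np.ndarray,
    source: np.ndarray,
    top_dirichlet: float | None,
    left_dirichlet: np.ndarray,
    extra_diag: np.ndarray | None = None,
):
    """Build the FV system for one scalar on a (nz_local, nx) block.

    ``coeff`` is the diffusive coefficient per z-row, ``flow`` the advective
    face flow per z-row (coefficient * u * dz, >= 0), ``left_dirichlet`` a
    per-row boundary value (NaN marks a zero-flux left face).  Returns
    (A, b, bookkeeping) with bookkeeping needed for flux balances.
    """
    nz = dz.shape[0]
    N = nz * nx

    d1 = 0.5 * dz[:-1]
    d2 = 0.5 * dz[1:]
    Gz = dx / (d1 / coeff[:-1] + d2 / coeff[1:])          # (nz-1,)
    Gx = coeff * dz / dx                                   # (nz,)
    Gleft = coeff * dz / (0.5 * dx)                        # Dirichlet half-cell
    Gtop = coeff[0] * dx / (0.5 * dz[0]) if top_dirichlet is not None else 0.0

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    b = np.zeros(N)

    def add(r, c, v):
        rows.append(np.asarray(r, dtype=np.int64))
        cols.append(np.asarray(c, dtype=np.int64))
        vals.append(np.asarray(v, dtype=float))

    idx = np.arange(N).reshape(nz, nx)

    # vertical diffusion
    for i in range(nz - 1):
        a = idx[i]
        c = idx[i + 1]
        g = np.full(nx, Gz[i])
        add(a, a, g); add(a, c, -g)
        add(c, c, g); add(c, a, -g)

    # horizontal diffusion + upwind advection (u >= 0, inflow at j=0)
    for i in range(nz):
        a = idx[i, :-1]
        c = idx[i, 1:]
        g = np.full(nx - 1, Gx[i])
        add(a, a, g); add(a, c, -g)
        add(c, c, g); add(c, a, -g)
        if flow[i] > 0.0:
            f = np.full(nx - 1, flow[i])
            add(a, a, f)       # advective outflow of cell j through right face
            add(c, a, -f)      # inflow into cell j+1
            add([idx[i, nx - 1]], [idx[i, nx - 1]], [flow[i]])  # outlet

    # top Dirichlet
    if top_dirichlet is not None:
        a = idx[0]
        add(a, a, np.full(nx, Gtop))
        b[a] += Gtop * top_dirichlet

    # left boundary
    for i in range(nz):
        if np.isnan(left_dirichlet[i]):
            continue
        a = idx[i, 0]
        add([a], [a], [Gleft[i]])
        b[a] += Gleft[i] * left_dirichlet[i]
        if flow[i] > 0.0:
            b[a] += flow[i] * left_dirichlet[i]

    # volumetric source
    b += np.repeat(source * dz * dx, nx)

    if extra_diag is not None:
        a = idx.ravel()
        add(a, a, extra_diag.ravel())

    A = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(N, N),
    ).tocsc()
    book = {"Gtop": Gtop, "Gleft": Gleft, "idx": idx}
    return A, b, book


def solve_heat(
    grid: SimGrid,
    velocity: np.ndarray,
    sources: SourceFields,
    domain: DomainSpec,
) -> tuple[np.ndarray, dict]:
    """Steady temperature elevation field dT(z, x) = T - T0 (K).

    Solved in elevation form, so the ambient Dirichlet value is 0 and the
    solution is exactly linear in the source (and hence in the incident
    irradiance).  Returns (elevation, info) with the linear-solve residual
    and the discrete energy balance (source vs. boundary efflux).
    """
    k = grid.cell_prop("k")
    rhocp = grid.cell_prop("rho") * grid.cell_prop("cp")
    flow = rhocp * velocity * grid.dz
    left = np.where(grid.mask("water"), 0.0, np.nan)  # inlet at ambient
    A, b, book = _assemble_advection_diffusion(
        grid.dz, grid.dx, grid.nx, k, flow, sources.heat_W_m3,
        top_dirichlet=0.0, left_dirichlet=left,
    )
    sol = spsolve(A, b)
    res = np.linalg.norm(A @ sol - b) / max(np.linalg.norm(b), 1e-300)
    if not np.all(np.isfinite(sol)):
        raise SolverError("heat solve produced non-finite temperatures", [res])
    dT = sol.reshape(grid.nz, grid.nx)

    # discrete energy balance: integrated source vs. net boundary efflux
    source_total = float(np.sum(sources.heat_W_m3 * grid.dz) * grid.dx * grid.nx)
    efflux = float(np.sum(book["Gtop"] * dT[0]))
    gl = book["Gleft"]
    water = grid.mask("water")
    efflux += float(np.sum(gl[water] * dT[water, 0]))
    efflux += float(np.sum(flow * dT[:, -1]))
    denom = max(abs(source_total), 1e-300)
    info = {
        "linear_residual": float(res),
        "balance_residual": abs(source_total - efflux) / denom,
        "source_total_W_per_m": source_total,
    }
    return dT, info


def solve_oxygen(
    grid: SimGrid,
    velocity: np.ndarray,
    sources: SourceFields,
    domain: DomainSpec,
    tol: float = 1e-8,
    damping: float = 0.8,
    max_iter: int = 100,
) -> tuple[np.ndarray, dict]:
    """Steady O2 concentration (mol m^-3) below the air-water interface.

    The Monod sink R_max*c/(K_O2 + c) is resolved by Newton linearization
    about the previous iterate (damped over the first iterations); the
    Jacobian contribution R'(c) >= 0 preserves the M-matrix structure, and
    the converged field is clipped at zero against roundoff-scale
    undershoot.  Air cells are excluded (zero flux at the air-water
    interface) and filled with NaN.
    """
    sub = ~grid.mask("air")
    i0 = int(np.argmax(sub))            # air is the contiguous top block
    dz = grid.dz[i0:]
    D = grid.cell_prop("D_O2")[i0:]
    flow = (velocity * grid.dz)[i0:]
    P = sources.photosynthesis_mol_m3_s[i0:]
    Rmax = sources.respiration_capacity_mol_m3_s[i0:]
    K = grid.cell_prop("K_O2")[i0:]
    nz, nx = dz.shape[0], grid.nx
    water = grid.mask("water")[i0:]
    left = np.where(water, domain.c0_mol_m3, np.nan)
    vol = dz[:, None] * grid.dx

    c = np.full((nz, nx), domain.c0_mol_m3)
    history: list[float] = []
    for it in range(max_iter):
        cp = np.maximum(c, 0.0)
        denom_m = K[:, None] + cp
        # Newton linearization of the Monod sink:
        #   R(c) ~ R(cp) + R'(cp) (c - cp),  R'(cp) = Rmax K / (K + cp)^2
        dR = Rmax[:, None] * K[:, None] / denom_m**2
        rhs_corr = (dR * cp - Rmax[:, None] * cp / denom_m) * vol
        A, b, book = _assemble_advection_diffusion(
            dz, grid.dx, nx, D, flow, P,
            top_dirichlet=None, left_dirichlet=left, extra_diag=dR * vol,
        )
        b += rhs_corr.ravel()
        c_new = spsolve(A, b).reshape(nz, nx)
        c_next = (1.0 - damping) * c + damping * c_new if it < 3 else c_new
        change = float(np.max(np.abs(c_next - c)) / max(np.max(np.abs(c_next)), 1e-300))
        history.append(change)
        c = c_next
        if change < tol:
            break
    else:
        raise SolverError("Newton iteration for O2 did not converge", history)
    c = np.maximum(c, 0.0)

    # nonlinear residual of the converged state
    sink = (Rmax[:, None] / (K[:, None] + c)) * vol
    A, b, book = _assemble_advection_diffusion(
        dz, grid.dx, nx, D, flow, P,
        top_dirichlet=None, left_dirichlet=left, extra_diag=sink,
    )
    res = float(np.linalg.norm(A @ c.ravel() - b) / max(np.linalg.norm(b), 1e-300))

    consumption = float(np.sum(Rmax[:, None] * c / (K[:, None] + c) * vol))
    production = float(np.sum(P * dz) * grid.dx * nx)
    gl = book["Gleft"]
    influx = float(np.sum(gl[water] * (domain.c0_mol_m3 - c[water, 0])))
    influx += float(np.sum(flow * domain.c0_mol_m3))
    outflux = float(np.sum(flow * c[:, -1]))
    net_prod = production - consumption
    denom = max(abs(production) + abs(consumption) + abs(influx), 1e-300)
    info = {
        "picard_iterations": len(history),
        "picard_history": history,
        "nonlinear_residual": res,
        "balance_residual": abs(net_prod - (outflux - influx)) / denom,
        "areal_gross_photosynthesis_mol_m2_s": float(np.sum(P * dz)),
        "areal_respiration_mol_m2_s": float(
            np.sum(Rmax[:, None] * c / (K[:, None] + c) * dz[:, None]) / nx
        ),
    }

    full = np.full((grid.nz, grid.nx), np.nan)
    full[i0:] = c
    return full, info


def run_pipeline(
    stack: Sequence[LayerSpec],
    domain: DomainSpec,
    n_photons: int = 1_000_000,
    seed: int = 0,
    dz: float = DEFAULT_DZ,
    dx: float = DEFAULT_DX,
    smooth_width_m: float | None = None,
    light: LightField | None = None,
) -> tuple[LightField, FieldSolution]:
    """Full MC -> smooth -> slice -> flow -> heat -> O2 pipeline.

    Deterministic for a fixed seed.  An existing ``light`` field (congruent
    with the grid) can be supplied to reuse an MC run, e.g. when only the
    PDE stage changes.
    """
    grid = build_grid(stack, domain, dz=dz, dx=dx)
    if light is None:
        raw = run_photon_mc(stack, domain, n_photons=n_photons, seed=seed, grid=grid)
        light = smooth_light_field(raw, smooth_width_m)
    sources = build_sources(light, grid, domain)
    u = solve_flow(grid, domain)
    dT, heat_info = solve_heat(grid, u, sources, domain)
    c, o2_info = solve_oxygen(grid, u, sources, domain)

    gastro = grid.mask("oral_gastrodermis", "aboral_gastrodermis")
    gross_p = o2_info["areal_gross_photosynthesis_mol_m2_s"]
    resp = o2_info["areal_respiration_mol_m2_s"]
    solution = FieldSolution(
        grid=grid,
        velocity_m_s=u,
        elevation_K=dT,
        temperature_C=domain.T0_C + dT,
        oxygen_mol_m3=c,
        residuals={
            "heat_linear": heat_info["linear_residual"],
            "o2_nonlinear": o2_info["nonlinear_residual"],
            "o2_picard_iterations": o2_info["picard_iterations"],
            "mc_conservation": light.conservation_residual,
        },
        balances={
            "heat": heat_info["balance_residual"],
            "o2": o2_info["balance_residual"],
        },
        diagnostics={
            "areal_gross_photosynthesis_mol_m2_s": gross_p,
            "areal_respiration_mol_m2_s": resp,
            "PR_ratio": gross_p / resp if resp > 0 else np.inf,
            "gastrodermis_cells": int(gastro.sum()),
        },
    )
    return light, solution
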