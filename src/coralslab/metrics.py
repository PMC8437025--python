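"""Depth profiles and derived microenvironment metrics.

Profiles are mid-domain vertical transects with the depth datum z = 0 at
the coral (mucus) surface, positive into the coral and negative into the
water column — the orientation in which microsensor profiles are read.
Derived quantities: normalized scalar irradiance, surface light
enhancement, maximum temperature elevation, thermal/diffusive boundary
layer (TBL/DBL) thickness, O2 peak locations and the bleaching power law.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .photon_mc import LightField
from .solvers import FieldSolution

__all__ = [
    "DepthProfile",
    "BoundaryLayerMetrics",
    "extract_profile",
    "normalize_irradiance",
    "boundary_layer_thickness",
    "max_temperature_elevation",
    "surface_enhancement",
    "fit_power_law",
    "o2_peak_locations",
]


@dataclass
class DepthProfile:
    """Mid-domain vertical transect of one quantity."""

    z_mm: np.ndarray                 # strictly increasing; 0 at coral surface
    value: np.ndarray
    quantity_kind: str               # irradiance | temperature | oxygen
    layer_of: np.ndarray             # layer name per node
    markers_mm: dict = field(default_factory=dict)  # name -> (top, bottom)

    def __post_init__(self):
        if not np.all(np.diff(self.z_mm) > 0):
            raise ValueError("profile depth coordinates must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"z_mm": self.z_mm, "value": self.value,
             "quantity": self.quantity_kind, "layer": self.layer_of}
        )

    def interp(self, z_mm: float) -> float:
        return float(np.interp(z_mm, self.z_mm, self.value))


@dataclass
class BoundaryLayerMetrics:
    """Thickness of the water film across which a scalar relaxes to ambient."""

    thickness_mm: float
    criterion: float
    surface_value: float
    ambient_value: float
    degenerate: bool = False


def _markers(cell_layer: np.ndarray, layer_names: tuple[str, ...],
             z_edges_m: np.ndarray, surface_m: float) -> dict:
    out = {}
    for i, name in enumerate(layer_names):
        cells = np.nonzero(cell_layer == i)[0]
        if cells.size:
            out[name] = (
                (z_edges_m[cells[0]] - surface_m) * 1e3,
                (z_edges_m[cells[-1] + 1] - surface_m) * 1e3,
            )
    return out


def extract_profile(obj: LightField | FieldSolution, quantity: str) -> DepthProfile:
    """Mid-x transect of irradiance, temperature (elevation) or oxygen."""
    if isinstance(obj, LightField):
        if quantity not in ("irradiance", "normalized_irradiance"):
            raise ValueError("a LightField only provides irradiance profiles")
        cell_layer, names, z_edges = obj.cell_layer, obj.layer_names, obj.z_edges_m
        surface = z_edges[np.argmax(cell_layer == names.index("mucus"))]
        value = (obj.normalized_fluence if quantity == "normalized_irradiance"
                 else obj.fluence_umol_m2_s).copy()
        kind = "irradiance"
    else:
        grid = obj.grid
        cell_layer, names, z_edges = grid.cell_layer, grid.layer_names, grid.z_edges
        surface = grid.tissue_surface_m
        j = grid.nx // 2
        if quantity == "temperature":
            value = obj.temperature_C[:, j].copy()
        elif quantity == "temperature_elevation":
            value = obj.elevation_K[:, j].copy()
        elif quantity == "oxygen":
            value = obj.oxygen_mol_m3[:, j].copy()
        else:
            raise ValueError(f"unknown quantity {quantity!r}")
        kind = "temperature" if quantity.startswith("temperature") else "oxygen"

    z_centers = 0.5 * (z_edges[:-1] + z_edges[1:])
    z_mm = (z_centers - surface) * 1e3
    layer_of = np.asarray(names)[cell_layer]
    keep = np.isfinite(value)
    return DepthProfile(
        z_mm=z_mm[keep],
        value=np.asarray(value)[keep],
        quantity_kind=kind,
        layer_of=layer_of[keep],
        markers_mm=_markers(cell_layer, tuple(names), z_edges, surface),
    )


def normalize_irradiance(profile: DepthProfile, I_id: float) -> DepthProfile:
    """Divide an irradiance profile by the incident downwelling irradiance."""
    if I_id <= 0:
        raise ValueError("incident irradiance must be positive to normalize")
    return DepthProfile(
        z_mm=profile.z_mm.copy(),
        value=profile.value / I_id,
        quantity_kind=profile.quantity_kind,
        layer_of=profile.layer_of.copy(),
        markers_mm=dict(profile.markers_mm),
    )


def boundary_layer_thickness(
    profile: DepthProfile,
    ambient_value: float,
    criterion: float = 0.90,
) -> BoundaryLayerMetrics:
    """Boundary-layer thickness above the coral surface.

    The thickness is the distance above z = 0 at which the deviation from
    ambient has relaxed to (1 - criterion) of the surface deviation,
    linearly interpolated between profile nodes.  Invariant under affine
    rescaling of the profile values.
    """
    if not 0.0 < criterion < 1.0:
        raise ValueError("criterion must be in (0, 1)")
    surface_value = profile.interp(0.0)
    dev_surface = abs(surface_value - ambient_value)
    scale = max(abs(surface_value), abs(ambient_value), 1e-300)
    if dev_surface <= 1e-12 * scale:
        return BoundaryLayerMetrics(0.0, criterion, surface_value, ambient_value, True)

    above = profile.z_mm < 0
    z = np.concatenate([profile.z_mm[above], [0.0]])
    v = np.concatenate([profile.value[above], [surface_value]])
    # march upward from the surface
    z, v = z[::-1], v[::-1]
    dev = np.abs(v - ambient_value) / dev_surface
    target = 1.0 - criterion
    below = np.nonzero(dev <= target)[0]
    if below.size == 0:
        # never relaxes inside the water column: report the full span
        return BoundaryLayerMetrics(float(-z[-1]), criterion, surface_value,
                                    ambient_value, False)
    i = below[0]
    if i == 0:
        return BoundaryLayerMetrics(0.0, criterion, surface_value, ambient_value, False)
    frac = (dev[i - 1] - target) / max(dev[i - 1] - dev[i], 1e-300)
    z_hit = z[i - 1] + frac * (z[i] - z[i - 1])
    return BoundaryLayerMetrics(float(-z_hit), criterion, surface_value,
                                ambient_value, False)


def max_temperature_elevation(solution: FieldSolution) -> float:
    """Maximum T - T0 over the coral (tissue plus skeleton) cells (K)."""
    grid = solution.grid
    coral = ~grid.mask("air", "water")
    return float(np.max(solution.elevation_K[coral, :]))


def surface_enhancement(light: LightField, read_depth_mm: float = 0.0) -> float:
    """Normalized scalar irradiance at the coral surface (or a given depth).

    The read-out depth is a parameter because light enhancement can be
    quoted at the tissue surface or within the tissue; the default is the
    surface itself.
    """
    profile = extract_profile(light, "normalized_irradiance")
    return profile.interp(read_depth_mm)


def fit_power_law(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Least-squares fit of y = a * x**b in log-log space.

    Returns (amplitude, exponent, R^2 of the log-log regression).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points for a power-law fit")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires strictly positive data")
    lx, ly = np.log(x), np.log(y)
    b, la = np.polyfit(lx, ly, 1)
    pred = la + b * lx
    ss_res = float(np.sum((ly - pred) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(np.exp(la)), float(b), r2


def o2_peak_locations(
    profile: DepthProfile, prominence_fraction: float = 0.01
) -> list[tuple[float, float, str]]:
    """Interior local maxima of an O2 (or any) profile.

    Peaks must rise above ``prominence_fraction`` of the profile's dynamic
    range; each is returned as (z_mm, value, containing layer).
    """
    rng = float(np.ptp(profile.value))
    if rng == 0.0:
        return []
    idx, _ = find_peaks(profile.value, prominence=prominence_fraction * rng)
    return [
        (float(profile.z_mm[i]), float(profile.value[i]), str(profile.layer_of[i]))
        for i in idx
    ]
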