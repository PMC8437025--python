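"""Shared rectilinear simulation grid for the MC tally and the PDE stage.

z runs from 0 at the top of the air layer downwards through the skeleton;
x runs along the flow direction.  Cells are uniform within each layer so
layer interfaces always coincide with cell faces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .scenarios import DomainSpec, LayerSpec, mm_to_m, stack_si_arrays

__all__ = ["SimGrid", "build_grid"]

#: Default vertical resolution (m); profiles are grid-independent below 20 um.
DEFAULT_DZ = 10e-6
#: Default horizontal resolution (m).
DEFAULT_DX = 100e-6


@dataclass(frozen=True)
class SimGrid:
    """Cell-centred rectilinear grid with per-cell layer assignment."""

    z_edges: np.ndarray          # (nz+1,) m
    x_edges: np.ndarray          # (nx+1,) m
    cell_layer: np.ndarray       # (nz,) index into the layer stack
    layer_names: tuple[str, ...]
    props: dict = field(repr=False)  # per-layer SI property arrays

    @property
    def nz(self) -> int:
        return self.cell_layer.shape[0]

    @property
    def nx(self) -> int:
        return self.x_edges.shape[0] - 1

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def dz(self) -> np.ndarray:
        return np.diff(self.z_edges)

    @property
    def dx(self) -> float:
        return float(self.x_edges[1] - self.x_edges[0])

    def cell_prop(self, key: str) -> np.ndarray:
        """Per-z-cell values of a per-layer property array."""
        return np.asarray(self.props[key], dtype=float)[self.cell_layer]

    def mask(self, *names: str) -> np.ndarray:
        """Boolean z-cell mask for the named layers."""
        idx = [self.layer_names.index(n) for n in names]
        return np.isin(self.cell_layer, idx)

    def layer_top_m(self, name: str) -> float:
        """Depth of the top face of a layer (m from top of air)."""
        i = self.layer_names.index(name)
        cells = np.nonzero(self.cell_layer == i)[0]
        return float(self.z_edges[cells[0]])

    @property
    def tissue_surface_m(self) -> float:
        """Depth of the coral (mucus) surface."""
        return self.layer_top_m("mucus")


def build_grid(
    stack: Sequence[LayerSpec],
    domain: DomainSpec,
    dz: float = DEFAULT_DZ,
    dx: float = DEFAULT_DX,
    min_cells_per_layer: int = 5,
) -> SimGrid:
    """Build a grid with at least ``min_cells_per_layer`` cells in each layer.

    Within each layer the spacing is uniform and no larger than ``dz``, so
    thin layers (e.g. a 0.05 mm mucus sheet) are always resolved.
    """
    props = stack_si_arrays(stack)
    z_edges = [0.0]
    cell_layer: list[int] = []
    for i, L in enumerate(props["thickness_m"]):
        ncell = max(min_cells_per_layer, math.ceil(L / dz - 1e-9))
        top = z_edges[-1]
        z_edges.extend((top + L * (j + 1) / ncell) for j in range(ncell))
        cell_layer.extend([i] * ncell)
    Lx = mm_to_m(domain.Lx_mm)
    nx = max(2, round(Lx / dx))
    x_edges = np.linspace(0.0, Lx, nx + 1)
    return SimGrid(
        z_edges=np.asarray(z_edges),
        x_edges=x_edges,
        cell_layer=np.asarray(cell_layer, dtype=np.int64),
        layer_names=tuple(str(n) for n in props["name"]),
        props=props,
    )
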