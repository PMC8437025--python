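"""Layered coral-slab parameterization and acclimation/stress scenarios.

The model organism is a thick-tissue faviid-type coral represented as a
stratified slab: air and flowing seawater on top, a mucus-covered
multi-layered tissue (epidermis with scattering host pigments, mesoglea,
symbiont-bearing oral gastrodermis, water-filled gastric cavity, aboral
gastrodermis, aboral mesoglea) and the aragonite skeleton (calicoblast layer
merged into it) at the bottom.  Every layer carries optical (636 nm),
thermal and O2-transport/kinetic properties.

Scenario transformations are pure functions: they return a new stack and
leave every layer they do not name untouched.
"""

from __future__ import annotations

import math
from typing import Iterable, Literal, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = [
    "ConfigError",
    "OpticalProps",
    "ThermalProps",
    "TransportKinetics",
    "LayerSpec",
    "DomainSpec",
    "BleachingLevel",
    "LAYER_ORDER",
    "TISSUE_LAYERS",
    "GASTRODERMIS_LAYERS",
    "PIGMENT_DENSITY_SWEEP_PER_CM",
    "MUCUS_SWEEP_MM",
    "BLEACHING_SERIES_CELLS_PER_CM2",
    "BASELINE_SYMBIONT_DENSITY",
    "WATER_MU_A_PER_CM",
    "baseline_stack",
    "apply_pigment_distribution",
    "apply_pigment_density",
    "apply_tissue_state",
    "apply_mucus_thickness",
    "apply_bleaching",
    "validate_stack",
    "load_config",
    "save_config",
    "stack_si_arrays",
    "per_cm_to_per_m",
    "per_m_to_per_cm",
    "mm_to_m",
    "m_to_mm",
    "umol_to_mol",
    "mol_to_umol",
]


class ConfigError(ValueError):
    """Raised for invalid scenario configurations."""


LayerName = Literal[
    "air",
    "water",
    "mucus",
    "epidermis",
    "mesoglea",
    "oral_gastrodermis",
    "gastric_cavity",
    "aboral_gastrodermis",
    "aboral_mesoglea",
    "skeleton",
]

#: Canonical top-to-bottom layer order of the slab.
LAYER_ORDER: tuple[str, ...] = (
    "air",
    "water",
    "mucus",
    "epidermis",
    "mesoglea",
    "oral_gastrodermis",
    "gastric_cavity",
    "aboral_gastrodermis",
    "aboral_mesoglea",
    "skeleton",
)

#: Coral tissue compartment (everything between the water column and the
#: skeleton); its summed thickness is 1.7 mm in the contracted baseline.
TISSUE_LAYERS: tuple[str, ...] = (
    "mucus",
    "epidermis",
    "mesoglea",
    "oral_gastrodermis",
    "gastric_cavity",
    "aboral_gastrodermis",
    "aboral_mesoglea",
)

#: Symbiont-bearing layers (photosynthesis + symbiont respiration).
GASTRODERMIS_LAYERS: tuple[str, ...] = ("oral_gastrodermis", "aboral_gastrodermis")

#: Epidermal scattering-coefficient sweep emulating host-pigment density (cm^-1).
PIGMENT_DENSITY_SWEEP_PER_CM: tuple[float, ...] = (0.126, 1.26, 12.6, 126.0, 1260.0)

#: Mucus-layer thickness sweep (mm).
MUCUS_SWEEP_MM: tuple[float, ...] = (0.05, 0.1, 0.15)

#: Symbiont areal densities of the bleaching series (cells cm^-2).
BLEACHING_SERIES_CELLS_PER_CM2: tuple[float, ...] = (2.17e6, 1.09e6, 0.54e6, 0.0)

#: Healthy-coral areal symbiont density (cells cm^-2).
BASELINE_SYMBIONT_DENSITY: float = 2.7e6

#: Absorption coefficient of (sea)water at 636 nm, used as the fully
#: bleached background absorption of the gastrodermis (cm^-1).
WATER_MU_A_PER_CM: float = 3.6e-3


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class OpticalProps(_Model):
    """Single-layer inherent optical properties at 636 nm."""

    mu_a_per_cm: float = Field(ge=0.0, description="absorption coefficient (cm^-1)")
    mu_s_per_cm: float = Field(ge=0.0, description="scattering coefficient (cm^-1)")
    g: float = Field(ge=-1.0, le=1.0, description="scattering anisotropy (mean cosine)")
    n: float = Field(ge=1.0, description="refractive index")


class ThermalProps(_Model):
    """Density, heat conductivity and heat capacity."""

    rho_kg_per_m3: float = Field(gt=0.0)
    k_W_per_m_K: float = Field(gt=0.0)
    cp_J_per_kg_K: float = Field(gt=0.0)


class TransportKinetics(_Model):
    """O2 diffusivity plus photosynthetic/respiratory kinetics.

    Q is the photosynthetic quantum efficiency (mol O2 per mol photons
    absorbed; 0 in non-photosynthetic layers).  R_max is the Monod maximum
    volumetric O2 consumption rate, K_O2 its half-saturation constant.
    """

    D_O2_m2_per_s: float = Field(ge=0.0)
    Q_mol_per_mol: float = Field(ge=0.0, le=1.0)
    R_max_mol_per_m3_s: float = Field(ge=0.0)
    K_O2_mol_per_m3: float = Field(gt=0.0)


class LayerSpec(_Model):
    """One slab layer, ordered top (air) to bottom (skeleton)."""

    name: LayerName
    thickness_mm: float = Field(gt=0.0)
    optical: OpticalProps
    thermal: ThermalProps
    kinetics: TransportKinetics
    is_fluid: bool = False


class DomainSpec(_Model):
    """Global run conditions for the slab (flow-chamber style)."""

    Lx_mm: float = Field(gt=0.0, description="slab width along the flow")
    Ly_mm: float = Field(gt=0.0, description="slab length (lateral)")
    I_id_umol_m2_s: float = Field(ge=0.0, description="incident downwelling photon irradiance")
    wavelength_nm: float = Field(gt=0.0)
    v0_cm_s: float = Field(ge=0.0, description="depth-averaged water velocity")
    T0_C: float = Field(description="ambient (inlet/bath) temperature")
    c0_mol_m3: float = Field(ge=0.0, description="inlet O2 concentration")
    f_heat: float = Field(ge=0.0, le=1.0, description="fraction of absorbed light to heat")
    f_ps: float = Field(ge=0.0, le=1.0, description="fraction of absorbed light to photosynthesis")
    eta_wat_Pa_s: float = Field(gt=0.0, description="water dynamic viscosity")
    PR: float = Field(gt=0.0, description="diagnostic gross P:R ratio in the gastrodermis")

    @model_validator(mode="after")
    def _partition_closes(self) -> "DomainSpec":
        if abs(self.f_heat + self.f_ps - 1.0) > 1e-9:
            raise ValueError("f_heat + f_ps must equal 1")
        return self


class BleachingLevel(_Model):
    """Areal symbiont density relative to the healthy baseline."""

    symbiont_density_cells_per_cm2: float = Field(ge=0.0)
    baseline_density_cells_per_cm2: float = Field(gt=0.0, default=BASELINE_SYMBIONT_DENSITY)

    @model_validator(mode="after")
    def _bounded(self) -> "BleachingLevel":
        if self.symbiont_density_cells_per_cm2 > self.baseline_density_cells_per_cm2:
            raise ValueError("symbiont density exceeds baseline density")
        return self

    @property
    def fraction(self) -> float:
        return self.symbiont_density_cells_per_cm2 / self.baseline_density_cells_per_cm2


# --------------------------------------------------------------------------
# Baseline parameterization
# --------------------------------------------------------------------------

_WATER_THERMAL = ThermalProps(rho_kg_per_m3=997.0, k_W_per_m_K=0.6, cp_J_per_kg_K=4183.0)
_TISSUE_THERMAL = ThermalProps(rho_kg_per_m3=1109.0, k_W_per_m_K=0.37, cp_J_per_kg_K=3391.0)
_SKEL_THERMAL = ThermalProps(rho_kg_per_m3=2930.0, k_W_per_m_K=1.5, cp_J_per_kg_K=811.0)
# Air thermal properties at 25 degC (not tabulated with the coral values;
# the air layer only conducts towards the Dirichlet bath condition on top).
_AIR_THERMAL = ThermalProps(rho_kg_per_m3=1.184, k_W_per_m_K=0.026, cp_J_per_kg_K=1005.0)

_K_O2 = 3.13e-3          # mol m^-3
_R_SYM = 1.2e-2          # mol m^-3 s^-1, symbiont light respiration
_R_SKEL = 3.75e-5        # mol m^-3 s^-1, endolith/skeleton respiration
_D_WAT = 2e-9            # m^2 s^-1
_D_TIS = 1e-9
_D_SKEL = 2e-11


def _kin(D: float, Q: float = 0.0, R: float = 0.0) -> TransportKinetics:
    return TransportKinetics(
        D_O2_m2_per_s=D, Q_mol_per_mol=Q, R_max_mol_per_m3_s=R, K_O2_mol_per_m3=_K_O2
    )


def baseline_stack() -> tuple[list[LayerSpec], DomainSpec]:
    """Return the contracted healthy-coral parameterization.

    Total tissue thickness (mucus through aboral mesoglea) is 1.7 mm.  The
    aboral mesoglea (0.1 mm, same properties as the oral mesoglea) closes
    that total; the calicoblast layer is merged into the skeleton.
    """

    def layer(name, L, mu_a, mu_s, g, n, thermal, kinetics, fluid=False):
        return LayerSpec(
            name=name,
            thickness_mm=L,
            optical=OpticalProps(mu_a_per_cm=mu_a, mu_s_per_cm=mu_s, g=g, n=n),
            thermal=thermal,
            kinetics=kinetics,
            is_fluid=fluid,
        )

    stack = [
        layer("air", 1.0, 1e-4, 1e-5, 1.0, 1.0, _AIR_THERMAL, _kin(0.0)),
        layer("water", 2.0, 3.6e-3, 1e-5, 1.0, 1.33, _WATER_THERMAL, _kin(_D_WAT), fluid=True),
        layer("mucus", 0.1, 3.6e-3, 1.15, 0.93, 1.36, _TISSUE_THERMAL, _kin(_D_TIS)),
        layer("epidermis", 0.1, 3.6e-3, 126.0, 0.34, 1.38, _TISSUE_THERMAL, _kin(_D_TIS)),
        layer("mesoglea", 0.1, 1.6e-3, 150.0, 0.68, 1.45, _TISSUE_THERMAL, _kin(_D_TIS)),
        layer("oral_gastrodermis", 0.2, 75.95, 97.65, 0.98, 1.42, _TISSUE_THERMAL,
              _kin(_D_TIS, Q=0.060, R=_R_SYM)),
        # the gastrovascular cavity is assumed to be pure (still) water
        layer("gastric_cavity", 0.6, 3.6e-3, 1e-5, 1.0, 1.33, _WATER_THERMAL, _kin(_D_WAT)),
        layer("aboral_gastrodermis", 0.5, 30.1, 38.7, 0.98, 1.42, _TISSUE_THERMAL,
              _kin(_D_TIS, Q=0.102, R=_R_SYM)),
        layer("aboral_mesoglea", 0.1, 1.6e-3, 150.0, 0.68, 1.45, _TISSUE_THERMAL, _kin(_D_TIS)),
        layer("skeleton", 3.0, 0.01, 34.0, 0.9, 1.66, _SKEL_THERMAL, _kin(_D_SKEL, R=_R_SKEL)),
    ]
    domain = DomainSpec(
        Lx_mm=10.0,
        Ly_mm=2.5,
        I_id_umol_m2_s=320.0,
        wavelength_nm=636.0,
        v0_cm_s=0.4,
        T0_C=25.0,
        c0_mol_m3=0.25,
        f_heat=0.96,
        f_ps=0.04,
        eta_wat_Pa_s=9e-4,
        PR=3.5,
    )
    return stack, domain


# --------------------------------------------------------------------------
# Scenario transformations (pure; untouched layers are returned unchanged)
# --------------------------------------------------------------------------

def _replace_layer(stack: Sequence[LayerSpec], name: str, **updates) -> list[LayerSpec]:
    if not any(lay.name == name for lay in stack):
        raise ConfigError(f"stack has no layer named {name!r}")
    return [lay.model_copy(update=updates) if lay.name == name else lay for lay in stack]


def apply_pigment_distribution(
    stack: Sequence[LayerSpec], mode: Literal["granular", "diffuse"]
) -> list[LayerSpec]:
    """Set the epidermal anisotropy for granular (g=0.34, near-isotropic)
    or diffuse (g=0.96, forward-peaked) host-pigment distributions."""
    g = {"granular": 0.34, "diffuse": 0.96}.get(mode)
    if g is None:
        raise ConfigError(f"unknown pigment distribution mode {mode!r}")
    ep = _get_layer(stack, "epidermis")
    return _replace_layer(stack, "epidermis", optical=ep.optical.model_copy(update={"g": g}))


def apply_pigment_density(stack: Sequence[LayerSpec], mu_s_ep_per_cm: float) -> list[LayerSpec]:
    """Set the epidermal scattering coefficient (host-pigment density proxy)."""
    if mu_s_ep_per_cm < 0:
        raise ConfigError("epidermal scattering coefficient must be >= 0")
    ep = _get_layer(stack, "epidermis")
    return _replace_layer(
        stack, "epidermis",
        optical=ep.optical.model_copy(update={"mu_s_per_cm": mu_s_ep_per_cm}),
    )


def apply_tissue_state(
    stack: Sequence[LayerSpec], state: Literal["contracted", "expanded"]
) -> list[LayerSpec]:
    """Contracted keeps baseline thicknesses; sideways expansion halves every
    tissue layer thickness (volumetric coefficients unchanged, so areal
    pigment and symbiont amounts halve with the 1.7 -> 0.85 mm total)."""
    if state == "contracted":
        return list(stack)
    if state != "expanded":
        raise ConfigError(f"unknown tissue state {state!r}")
    return [
        lay.model_copy(update={"thickness_mm": lay.thickness_mm * 0.5})
        if lay.name in TISSUE_LAYERS
        else lay
        for lay in stack
    ]


def apply_mucus_thickness(stack: Sequence[LayerSpec], L_muc_mm: float) -> list[LayerSpec]:
    """Set the mucus layer thickness (stress-dependent mucus production)."""
    if L_muc_mm <= 0:
        raise ConfigError("mucus thickness must be positive")
    return _replace_layer(stack, "mucus", thickness_mm=L_muc_mm)


def apply_bleaching(stack: Sequence[LayerSpec], level: BleachingLevel) -> list[LayerSpec]:
    """Scale gastrodermal absorption (and quantum efficiency) with symbiont loss.

    mu_a interpolates linearly between the seawater background (full bleaching,
    virtually no tissue absorption) and the healthy value; Q scales with the
    same density fraction so a fully bleached coral produces no O2 from the
    residual water absorption.
    """
    f = level.fraction
    out: list[LayerSpec] = []
    for lay in stack:
        if lay.name in GASTRODERMIS_LAYERS:
            mu_a = WATER_MU_A_PER_CM + (lay.optical.mu_a_per_cm - WATER_MU_A_PER_CM) * f
            out.append(
                lay.model_copy(
                    update={
                        "optical": lay.optical.model_copy(update={"mu_a_per_cm": mu_a}),
                        "kinetics": lay.kinetics.model_copy(
                            update={"Q_mol_per_mol": lay.kinetics.Q_mol_per_mol * f}
                        ),
                    }
                )
            )
        else:
            out.append(lay)
    return out


# --------------------------------------------------------------------------
# Validation and config I/O
# --------------------------------------------------------------------------

def validate_stack(stack: Sequence[LayerSpec]) -> None:
    """Check canonical layer order/completeness and the fluid invariant."""
    problems: list[str] = []
    names = [lay.name for lay in stack]
    if names != list(LAYER_ORDER):
        missing = [n for n in LAYER_ORDER if n not in names]
        extra = [n for n in names if n not in LAYER_ORDER]
        if missing:
            problems.append(f"missing layers: {missing}")
        if extra:
            problems.append(f"unknown layers: {extra}")
        if not missing and not extra:
            problems.append(f"layers out of canonical order: {names}")
    fluid = [lay.name for lay in stack if lay.is_fluid]
    if fluid != ["water"]:
        problems.append(f"exactly the water layer must be fluid, got {fluid}")
    for lay in stack:
        if lay.name != "air" and lay.kinetics.D_O2_m2_per_s <= 0:
            problems.append(f"{lay.name}: O2 diffusivity must be positive")
    if problems:
        raise ConfigError("; ".join(problems))


def save_config(stack: Sequence[LayerSpec], domain: DomainSpec) -> str:
    """Serialize a validated configuration to YAML (units in key names)."""
    doc = {
        "domain": domain.model_dump(),
        "layers": [lay.model_dump() for lay in stack],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def load_config(text: str) -> tuple[list[LayerSpec], DomainSpec]:
    """Parse and validate a YAML configuration document.

    Unknown keys, invariant violations and missing layers raise
    :class:`ConfigError` naming the offending keys.
    """
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # pragma: no cover - malformed YAML
        raise ConfigError(f"not valid YAML: {exc}") from exc
    if not isinstance(doc, dict) or set(doc) - {"domain", "layers"}:
        raise ConfigError("config must be a mapping with keys 'domain' and 'layers'")
    try:
        domain = DomainSpec.model_validate(doc.get("domain", {}))
        stack = [LayerSpec.model_validate(entry) for entry in doc.get("layers", [])]
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc
    validate_stack(stack)
    return stack, domain


def _get_layer(stack: Sequence[LayerSpec], name: str) -> LayerSpec:
    for lay in stack:
        if lay.name == name:
            return lay
    raise ConfigError(f"stack has no layer named {name!r}")


# --------------------------------------------------------------------------
# Named scenario presets
# --------------------------------------------------------------------------

def _bleach(density: float):
    def make(stack):
        return apply_bleaching(
            stack, BleachingLevel(symbiont_density_cells_per_cm2=density)
        )
    return make


_SCENARIOS: dict[str, tuple[str, object]] = {
    "baseline": ("healthy contracted faviid-type coral, default parameters", lambda s: list(s)),
    "pigment_granular": (
        "granular host pigments in the epidermis (g_ep = 0.34)",
        lambda s: apply_pigment_distribution(s, "granular"),
    ),
    "pigment_diffuse": (
        "diffuse host pigments in the epidermis (g_ep = 0.96)",
        lambda s: apply_pigment_distribution(s, "diffuse"),
    ),
    "tissue_contracted": (
        "contracted tissue, 1.7 mm total",
        lambda s: apply_tissue_state(s, "contracted"),
    ),
    "tissue_expanded": (
        "sideways-expanded tissue, 0.85 mm total",
        lambda s: apply_tissue_state(s, "expanded"),
    ),
}
for _L in MUCUS_SWEEP_MM:
    _SCENARIOS[f"mucus_{_L:g}mm"] = (
        f"mucus layer thickness {_L:g} mm",
        (lambda L: lambda s: apply_mucus_thickness(s, L))(_L),
    )
for _d in BLEACHING_SERIES_CELLS_PER_CM2:
    _SCENARIOS[f"bleaching_{_d:.3g}"] = (
        f"bleaching stage, {_d:.3g} symbiont cells cm^-2",
        _bleach(_d),
    )
for _m in PIGMENT_DENSITY_SWEEP_PER_CM:
    _SCENARIOS[f"pigment_density_{_m:g}"] = (
        f"epidermal scattering coefficient {_m:g} cm^-1",
        (lambda m: lambda s: apply_pigment_density(s, m))(_m),
    )


def scenario_names() -> list[str]:
    return list(_SCENARIOS)


def make_scenario(name: str) -> tuple[list[LayerSpec], DomainSpec, str]:
    """Build a named scenario as a pure transformation of the baseline."""
    if name not in _SCENARIOS:
        raise ConfigError(
            f"unknown scenario {name!r}; available: {', '.join(_SCENARIOS)}"
        )
    stack, domain = baseline_stack()
    desc, transform = _SCENARIOS[name]
    return transform(stack), domain, desc


# --------------------------------------------------------------------------
# Unit bridges (exact scale factors; round-trips are lossless)
# --------------------------------------------------------------------------

def per_cm_to_per_m(x): return np.multiply(x, 100.0)
def per_m_to_per_cm(x): return np.divide(x, 100.0)
def mm_to_m(x): return np.multiply(x, 1e-3)
def m_to_mm(x): return np.divide(x, 1e-3)
def umol_to_mol(x): return np.multiply(x, 1e-6)
def mol_to_umol(x): return np.divide(x, 1e-6)


def stack_si_arrays(stack: Sequence[LayerSpec]) -> dict[str, np.ndarray]:
    """Per-layer property arrays in SI units, ordered top to bottom."""
    validate_stack(stack)
    get = lambda f: np.array([f(lay) for lay in stack], dtype=float)
    return {
        "name": np.array([lay.name for lay in stack]),
        "thickness_m": get(lambda l: mm_to_m(l.thickness_mm)),
        "mu_a_per_m": get(lambda l: per_cm_to_per_m(l.optical.mu_a_per_cm)),
        "mu_s_per_m": get(lambda l: per_cm_to_per_m(l.optical.mu_s_per_cm)),
        "g": get(lambda l: l.optical.g),
        "n": get(lambda l: l.optical.n),
        "rho": get(lambda l: l.thermal.rho_kg_per_m3),
        "k": get(lambda l: l.thermal.k_W_per_m_K),
        "cp": get(lambda l: l.thermal.cp_J_per_kg_K),
        "D_O2": get(lambda l: l.kinetics.D_O2_m2_per_s),
        "Q": get(lambda l: l.kinetics.Q_mol_per_mol),
        "R_max": get(lambda l: l.kinetics.R_max_mol_per_m3_s),
        "K_O2": get(lambda l: l.kinetics.K_O2_mol_per_m3),
        "is_fluid": np.array([lay.is_fluid for lay in stack], dtype=bool),
    }
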