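"""Inertial-focusing force model for spiral microchannels.

In a curved rectangular microchannel a suspended particle feels two
competing hydrodynamic forces: the net inertial lift ``F_L`` (shear-gradient
lift against wall lift) and the drag exerted by the secondary Dean
recirculation ``F_D``.  Their ratio scales with the cube of particle size,
which is what lets a spiral channel place 17 µm CTC-like and 10 µm WBC-like
particles on distinct equilibrium streaks:

    F_L = 2 ρ U_avg² a⁴ c_L / D_H²
    F_D = 3 π µ U_D a
    F_L / F_D ∝ a³

All quantities here are SI (metres, m/s, Pa·s, newtons); the geometry layer
works in micrometres and converts at the call site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

from .exceptions import SpiralfoilError

__all__ = [
    "FluidProps",
    "LiftContext",
    "DeanContext",
    "ParticleSpec",
    "WATER",
    "net_lift_force",
    "dean_drag_force",
    "force_ratio",
    "dimensionless_numbers",
    "dean_velocity",
    "wall_shear_stress",
    "evaluate_design_rules",
]

UL_MIN_TO_M3_S = 1e-9 / 60.0  # µL/min -> m³/s


@dataclass(frozen=True)
class FluidProps:
    """Carrier-fluid density (kg/m³) and dynamic viscosity (Pa·s)."""

    density: float = 1000.0
    viscosity: float = 1e-3

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise SpiralfoilError("fluid properties must be positive")


WATER = FluidProps()


@dataclass(frozen=True)
class LiftContext:
    """Average axial velocity, lift coefficient, hydraulic diameter (SI)."""

    u_avg: float
    lift_coefficient: float = 0.5  # literature midrange; never fixed by data
    hydraulic_diameter: float = 150e-6

    def __post_init__(self) -> None:
        if self.u_avg < 0:
            raise SpiralfoilError("average velocity cannot be negative")
        if self.hydraulic_diameter <= 0:
            raise SpiralfoilError("hydraulic diameter must be positive")


@dataclass(frozen=True)
class DeanContext:
    """Curvature radius, Dean number and mean Dean-vortex velocity (SI)."""

    curvature_radius: float
    dean_number: float = 0.0
    dean_velocity: float = 0.0

    def __post_init__(self) -> None:
        if self.curvature_radius <= 0:
            raise SpiralfoilError("curvature radius must be positive")
        if self.dean_number < 0 or self.dean_velocity < 0:
            raise SpiralfoilError("Dean number/velocity cannot be negative")


@dataclass(frozen=True)
class ParticleSpec:
    """Spherical particle of diameter ``a`` metres with a class label."""

    diameter: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise SpiralfoilError("particle diameter must be positive")


def net_lift_force(fluid: FluidProps, ctx: LiftContext, particle: ParticleSpec) -> float:
    """Net inertial lift F_L = 2 ρ U_avg² a⁴ c_L / D_H² (N)."""
    return (
        2.0
        * fluid.density
        * ctx.u_avg**2
        * particle.diameter**4
        * ctx.lift_coefficient
        / ctx.hydraulic_diameter**2
    )


def dean_drag_force(fluid: FluidProps, ctx: DeanContext, particle: ParticleSpec) -> float:
    """Stokes drag of the Dean recirculation, F_D = 3 π µ U_D a (N)."""
    return 3.0 * math.pi * fluid.viscosity * ctx.dean_velocity * particle.diameter


def force_ratio(
    fluid: FluidProps,
    lift_ctx: LiftContext,
    dean_ctx: DeanContext,
    particle: ParticleSpec,
) -> float:
    """F_L / F_D for one particle; between two particles the ratio of these
    ratios is exactly (a₁/a₂)³."""
    f_d = dean_drag_force(fluid, dean_ctx, particle)
    if f_d == 0.0:
        raise SpiralfoilError("force ratio undefined at zero Dean velocity")
    return net_lift_force(fluid, lift_ctx, particle) / f_d


def dimensionless_numbers(
    fluid: FluidProps,
    metrics: dict[str, float],
    flow_rate_ul_min: float,
    *,
    width_um: float = 300.0,
    depth_um: float = 100.0,
    curvature_radius_um: float | None = None,
) -> dict[str, float]:
    """Channel Reynolds and Dean numbers plus the mean axial velocity.

    ``metrics`` is the output of :func:`spiralfoil.geometry.spiral_metrics`
    (micrometre units).  ``curvature_radius_um`` defaults to the spiral's
    mid radius when not given; pass ``math.inf`` for a straight channel.
    """
    q = flow_rate_ul_min * UL_MIN_TO_M3_S
    w = width_um * 1e-6
    h = depth_um * 1e-6
    d_h = metrics["hydraulic_diameter"] * 1e-6
    u_avg = q / (w * h)
    re = fluid.density * u_avg * d_h / fluid.viscosity
    if curvature_radius_um is None:
        curvature_radius_um = metrics.get("mid_radius_um", 2000.0)
    r_c = curvature_radius_um * 1e-6
    de = 0.0 if math.isinf(r_c) else re * math.sqrt(d_h / (2.0 * r_c))
    return {"Re": re, "De": de, "U_avg": u_avg}


def dean_velocity(de: float, *, prefactor: float = 1.8e-4, exponent: float = 1.63) -> float:
    """Mean Dean-vortex velocity U_D = 1.8e-4 · De^1.63 m/s.

    The power law is the literature convention for rectangular spiral
    channels; both coefficients are pluggable.
    """
    if de < 0:
        raise SpiralfoilError("Dean number cannot be negative")
    return prefactor * de**exponent


def wall_shear_stress(
    fluid: FluidProps,
    flow_rate_ul_min: float,
    width_um: float,
    depth_um: float,
) -> dict[str, float]:
    """Wall shear stress of a wide-slot channel, τ = 6 µ Q / (w h²).

    Returned in both Pa and dyn/cm² (1 Pa = 10 dyn/cm²).
    """
    q = flow_rate_ul_min * UL_MIN_TO_M3_S
    w = width_um * 1e-6
    h = depth_um * 1e-6
    tau = 6.0 * fluid.viscosity * q / (w * h**2)
    return {"Pa": tau, "dyn_cm2": tau * 10.0}


def evaluate_design_rules(
    r_upstream: float,
    r_downstream: float,
    *,
    upstream_band: float = 0.5,
    downstream_min: float = 10.0,
) -> dict[str, object]:
    """Score a design against the two-stage separation design rules.

    Stage 1 (spiral pre-focusing) should deliver a stream resolution of
    about 1; stage 2 (hydrofoil) should push the downstream resolution to
    10 or larger.  The upstream rule is reported as a distance from 1 with
    a configurable advisory band, the downstream rule as a hard threshold.
    """
    if r_upstream < 0 or r_downstream < 0:
        raise SpiralfoilError("resolutions cannot be negative")
    upstream_distance = abs(r_upstream - 1.0)
    return {
        "upstream_resolution": r_upstream,
        "upstream_distance_from_1": upstream_distance,
        "upstream_within_band": upstream_distance <= upstream_band,
        "downstream_resolution": r_downstream,
        "downstream_rule_met": r_downstream >= downstream_min,
        "all_rules_met": (upstream_distance <= upstream_band)
        and (r_downstream >= downstream_min),
    }
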