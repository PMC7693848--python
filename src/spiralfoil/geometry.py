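"""Parametric chip geometry.

Builds the three solids of the downstream separation region of a spiral
CTC-enrichment chip — the NACA 4-digit hydrofoil, the half-elliptic
separation wall with its straight divider, and the rectangular channel
segment that contains them — together with the global metrics of the
upstream Archimedean spiral (hydraulic diameter, centerline length).

Coordinate convention
---------------------
2D, distances in micrometres.  ``x`` runs along the flow, ``y`` across the
channel with ``y = 0`` at the *reference wall*: the channel wall nearest
the large-particle (CTC) equilibrium position.  The CTC outlet passage is
the gap between the reference wall and the separation wall; the waste
passage lies on the far side.  A positive hydrofoil attack angle rotates
the trailing edge away from the reference wall, which is the orientation
that deflects the CTC stream toward that wall.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.integrate import quad
from shapely import contains_xy
from shapely.geometry import Polygon

from .exceptions import GeometryError, PlacementError

__all__ = [
    "SpiralSpec",
    "HydrofoilSpec",
    "SeparationWallSpec",
    "DownstreamDomain",
    "naca4_camber",
    "naca4_profile",
    "place_hydrofoil",
    "build_downstream_domain",
    "spiral_metrics",
]


# --------------------------------------------------------------------------- #
# specifications
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class SpiralSpec:
    """Archimedean spiral focusing channel (rectangular cross-section).

    Defaults are the reference chip: 4 loops, 300 µm wide, 100 µm deep,
    150 µm spacing between loops.
    """

    width: float = 300.0          # µm, across the channel
    depth: float = 100.0          # µm, out of plane
    loops: int = 4
    gap: float = 150.0            # µm between successive loops
    start_radius: float = 1000.0  # µm, innermost centerline radius

    def __post_init__(self) -> None:
        if self.width <= 0 or self.depth <= 0:
            raise GeometryError("channel width and depth must be positive")
        if self.loops < 1:
            raise GeometryError("a spiral needs at least one loop")
        if self.gap < 0:
            raise GeometryError("loop gap cannot be negative")
        if self.start_radius <= 0:
            raise GeometryError("start radius must be positive")

    @property
    def pitch(self) -> float:
        """Centerline pitch per turn (µm)."""
        return self.width + self.gap


def spiral_metrics(spec: SpiralSpec) -> dict[str, float]:
    """Hydraulic diameter, centerline length and pitch of the spiral.

    The centerline is ``r(θ) = r0 + (pitch / 2π) θ``; its length is the
    arc-length integral over ``loops`` full turns.
    """
    w, h = spec.width, spec.depth
    d_h = 2.0 * w * h / (w + h)
    b = spec.pitch / (2.0 * math.pi)

    def ds(theta: float) -> float:
        r = spec.start_radius + b * theta
        return math.hypot(r, b)

    length, _ = quad(ds, 0.0, 2.0 * math.pi * spec.loops, limit=200)
    return {
        "hydraulic_diameter": d_h,
        "centerline_length": length,
        "pitch": spec.pitch,
    }


@dataclass(frozen=True)
class HydrofoilSpec:
    """A NACA 4-digit hydrofoil placed in the channel.

    ``anchor`` is the leading-edge position in channel coordinates (µm);
    ``attack_angle`` (degrees) rotates the trailing edge away from the
    reference wall.
    """

    naca_code: str = "9730"
    chord: float = 300.0
    attack_angle: float = 30.0
    anchor: tuple[float, float] = (250.0, 62.0)
    n_points: int = 120

    def __post_init__(self) -> None:
        if self.chord <= 0:
            raise GeometryError("chord must be positive")
        parse_naca4(self.naca_code)  # validates

    def polygon(self, channel_width: float | None = None) -> np.ndarray:
        """Closed vertex array of the placed foil."""
        prof = naca4_profile(self.naca_code, self.chord, self.n_points)
        return place_hydrofoil(prof, self, channel_width=channel_width)


@dataclass(frozen=True)
class SeparationWallSpec:
    """Half-elliptic separation wall splitting the channel into two outlets.

    The leading tip is the nose of a half-ellipse (semi-minor axis across
    the channel = ``minor_diameter / 2``); downstream of the ellipse the
    wall continues as a straight divider of constant ``minor_diameter``
    width to the outlet boundary.  ``center_offset`` is the distance of the
    wall centerline from the reference wall; ``axial_position`` the x of
    the nose tip.
    """

    minor_diameter: float = 50.0
    center_offset: float = 100.0
    axial_position: float = 640.0
    semi_major: float = 50.0  # streamwise semi-axis of the nose ellipse

    def __post_init__(self) -> None:
        if self.minor_diameter <= 0:
            raise GeometryError("wall minor diameter must be positive")
        if self.semi_major <= 0:
            raise GeometryError("wall nose semi-major axis must be positive")

    @property
    def lower_edge(self) -> float:
        return self.center_offset - self.minor_diameter / 2.0

    @property
    def upper_edge(self) -> float:
        return self.center_offset + self.minor_diameter / 2.0

    def polygon(self, domain_length: float, n_arc: int = 40) -> np.ndarray:
        """Closed vertex array: elliptic nose plus straight divider."""
        a, b = self.semi_major, self.minor_diameter / 2.0
        cx = self.axial_position + a
        cy = self.center_offset
        if cx > domain_length:
            raise GeometryError("wall nose does not fit inside the domain")
        theta = np.linspace(0.5 * np.pi, 1.5 * np.pi, n_arc)
        arc = np.column_stack([cx + a * np.cos(theta), cy + b * np.sin(theta)])
        pts = np.vstack([
            [domain_length, cy + b],
            arc,
            [domain_length, cy - b],
        ])
        return np.vstack([pts, pts[:1]])


# --------------------------------------------------------------------------- #
# NACA 4-digit construction
# --------------------------------------------------------------------------- #

def parse_naca4(code: str) -> tuple[float, float, float]:
    """Parse MPXX into (max camber m, camber position p, thickness t).

    All three are fractions of chord.  Raises :class:`GeometryError` for
    malformed codes or out-of-range parameters.
    """
    if not (isinstance(code, str) and len(code) == 4 and code.isdigit()):
        raise GeometryError(f"malformed NACA 4-digit code: {code!r}")
    m = int(code[0]) / 100.0
    p = int(code[1]) / 10.0
    t = int(code[2:]) / 100.0
    if m > 0.095:
        raise GeometryError(f"camber {m:.3f} out of range [0, 0.095]")
    if m > 0 and not (0.0 < p < 1.0):
        raise GeometryError("cambered section needs camber position in (0,1)")
    if not (0.0 < t < 0.4):
        raise GeometryError(f"thickness {t:.3f} out of range (0, 0.4)")
    return m, p, t


def naca4_camber(code: str, chord: float, x: np.ndarray) -> np.ndarray:
    """Camber-line height at chordwise stations ``x`` (same units as chord)."""
    m, p, _ = parse_naca4(code)
    x = np.asarray(x, dtype=float)
    xc = x / chord
    if m == 0.0:
        return np.zeros_like(x)
    yc = np.where(
        xc < p,
        m / p**2 * (2.0 * p * xc - xc**2),
        m / (1.0 - p) ** 2 * ((1.0 - 2.0 * p) + 2.0 * p * xc - xc**2),
    )
    return yc * chord


def _camber_slope(code: str, chord: float, x: np.ndarray) -> np.ndarray:
    m, p, _ = parse_naca4(code)
    xc = np.asarray(x, dtype=float) / chord
    if m == 0.0:
        return np.zeros_like(xc)
    return np.where(
        xc < p,
        2.0 * m / p**2 * (p - xc),
        2.0 * m / (1.0 - p) ** 2 * (p - xc),
    )


def naca4_thickness(code: str, chord: float, x: np.ndarray) -> np.ndarray:
    """Half-thickness distribution with the closed-trailing-edge polynomial."""
    _, _, t = parse_naca4(code)
    xc = np.clip(np.asarray(x, dtype=float) / chord, 0.0, 1.0)
    # last coefficient -0.1036 closes the trailing edge exactly
    yt = 5.0 * t * (
        0.2969 * np.sqrt(xc)
        - 0.1260 * xc
        - 0.3516 * xc**2
        + 0.2843 * xc**3
        - 0.1036 * xc**4
    )
    return yt * chord


def naca4_profile(code: str, chord: float, n_points: int = 100) -> np.ndarray:
    """Closed surface polygon of a NACA 4-digit section.

    Camber line per the standard piecewise-quadratic formula, thickness
    applied perpendicular to the camber line, cosine-spaced stations.
    Returns an ``(N, 2)`` array whose first and last vertices coincide;
    vertices run from the trailing edge over the upper surface to the
    leading edge and back along the lower surface.
    """
    parse_naca4(code)
    if n_points < 20:
        raise GeometryError("n_points must be at least 20 for a sane polygon")
    beta = np.linspace(0.0, np.pi, n_points)
    x = 0.5 * chord * (1.0 - np.cos(beta))  # cosine clustering at LE/TE
    yt = naca4_thickness(code, chord, x)
    yc = naca4_camber(code, chord, x)
    theta = np.arctan(_camber_slope(code, chord, x))
    xu = x - yt * np.sin(theta)
    yu = yc + yt * np.cos(theta)
    xl = x + yt * np.sin(theta)
    yl = yc - yt * np.cos(theta)
    upper = np.column_stack([xu, yu])[::-1]          # TE -> LE
    lower = np.column_stack([xl, yl])[1:-1]          # LE -> TE, skip dup LE/TE
    poly = np.vstack([upper, lower])
    poly = np.vstack([poly, poly[:1]])               # close at the TE
    if not Polygon(poly).is_valid:
        raise GeometryError("degenerate (self-intersecting) NACA polygon")
    return poly


def place_hydrofoil(
    profile: np.ndarray,
    spec: HydrofoilSpec,
    channel_width: float | None = None,
) -> np.ndarray:
    """Rigidly place a foil profile: rotate about the leading edge by the
    attack angle (trailing edge away from the reference wall), translate
    the leading edge to ``spec.anchor``.

    Raises :class:`PlacementError` if the placed foil leaves the channel.
    """
    pts = np.asarray(profile, dtype=float)
    alpha = math.radians(spec.attack_angle)
    rot = np.array([
        [math.cos(alpha), -math.sin(alpha)],
        [math.sin(alpha), math.cos(alpha)],
    ])
    placed = pts @ rot.T + np.asarray(spec.anchor, dtype=float)
    if channel_width is not None:
        ymin, ymax = placed[:, 1].min(), placed[:, 1].max()
        if ymin <= 0.0 or ymax >= channel_width:
            raise PlacementError(
                f"hydrofoil spans y ∈ [{ymin:.1f}, {ymax:.1f}] µm, outside the "
                f"open channel (0, {channel_width:g})"
            )
    return placed


# --------------------------------------------------------------------------- #
# assembled domain
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class DownstreamDomain:
    """The 2D simulation region just downstream of the spiral.

    Rectangle ``[0, length] × [0, width]`` with up to two solids (hydrofoil,
    separation wall).  Boundary labels: inlet at ``x = 0``; at ``x = length``
    the CTC outlet spans ``(0, ctc_width)`` and the waste outlet
    ``(width - waste_width, width)``; everything else is solid wall.
    """

    length: float
    width: float
    depth: float
    foil_polygon: np.ndarray | None
    wall_polygon: np.ndarray | None
    foil: HydrofoilSpec | None
    wall: SeparationWallSpec | None
    spiral: SpiralSpec = field(default_factory=SpiralSpec)

    @property
    def ctc_width(self) -> float:
        return self.wall.lower_edge if self.wall is not None else self.width

    @property
    def waste_width(self) -> float:
        return self.width - self.wall.upper_edge if self.wall is not None else 0.0

    @property
    def outlet_partition(self) -> tuple[float, float, float]:
        """(CTC passage, wall, waste passage) widths; sums to channel width."""
        wall_w = self.wall.minor_diameter if self.wall is not None else 0.0
        return (self.ctc_width, wall_w, self.waste_width)

    def solids(self) -> list[np.ndarray]:
        return [p for p in (self.foil_polygon, self.wall_polygon) if p is not None]

    def solid_mask(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Boolean mask: True where points (x, y) fall inside a solid."""
        xx = np.asarray(x, dtype=float)
        yy = np.asarray(y, dtype=float)
        mask = np.zeros(xx.shape, dtype=bool)
        for poly in self.solids():
            mask |= contains_xy(Polygon(poly), xx, yy)
        return mask

    # ---------------------------------------------------------------- export
    def export(self, outdir: str | Path) -> list[Path]:
        """Write per-solid vertex CSVs and a JSON descriptor; return paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        names = {"hydrofoil": self.foil_polygon, "separation_wall": self.wall_polygon}
        for name, poly in names.items():
            if poly is None:
                continue
            path = outdir / f"{name}.csv"
            np.savetxt(path, poly, delimiter=",", header="x_um,y_um", comments="")
            written.append(path)
        desc = {
            "length_um": self.length,
            "width_um": self.width,
            "depth_um": self.depth,
            "outlet_partition_um": list(self.outlet_partition),
            "boundary_labels": {
                "inlet": "x=0",
                "ctc_outlet": f"x={self.length:g}, y in (0, {self.ctc_width:g})",
                "waste_outlet": (
                    f"x={self.length:g}, "
                    f"y in ({self.width - self.waste_width:g}, {self.width:g})"
                ),
                "solid": "channel walls, hydrofoil, separation wall",
            },
        }
        jpath = outdir / "domain.json"
        jpath.write_text(json.dumps(desc, indent=2))
        written.append(jpath)
        return written


def build_downstream_domain(
    spiral: SpiralSpec | None = None,
    foil: HydrofoilSpec | None = None,
    wall: SeparationWallSpec | None = None,
    length: float = 800.0,
    include_foil: bool = True,
    include_wall: bool = True,
    wall_in_flow: bool = True,
) -> DownstreamDomain:
    """Assemble the labelled downstream domain.

    ``include_foil=False`` builds the no-hydrofoil reference geometry;
    ``include_wall=False`` leaves a single outlet spanning the full width.
    ``wall_in_flow=False`` keeps the wall as outlet partition and
    classifier but leaves it out of the hydrodynamic solve (the wall acts
    as a downstream collector), which is the reference-configuration
    treatment.  With the default configuration the outlet section
    partitions as 75 µm (CTC) : 50 µm (wall) : 175 µm (waste).
    """
    spiral = spiral or SpiralSpec()
    width = spiral.width
    if include_foil and foil is None:
        foil = HydrofoilSpec()
    if not include_foil:
        foil = None

    foil_poly = foil.polygon(channel_width=width) if foil is not None else None

    wall_poly = None
    if include_wall and wall is None:
        wall = SeparationWallSpec()
    if not include_wall:
        wall = None
    if wall is not None:
        if not (0.0 < wall.center_offset < width):
            raise GeometryError("wall centerline must lie inside the channel")
        if wall.lower_edge <= 0.0 or wall.upper_edge >= width:
            raise GeometryError("separation wall touches a channel wall")
        if wall_in_flow:
            wall_poly = wall.polygon(length)

    if foil_poly is not None and wall_poly is not None:
        if Polygon(foil_poly).buffer(0).intersects(Polygon(wall_poly).buffer(0)):
            raise GeometryError("hydrofoil and separation wall overlap")
    for poly in (foil_poly, wall_poly):
        if poly is not None and not Polygon(poly).is_valid:
            raise GeometryError("solid polygon is not simple")

    return DownstreamDomain(
        length=length,
        width=width,
        depth=spiral.depth,
        foil_polygon=foil_poly,
        wall_polygon=wall_poly,
        foil=foil,
        wall=wall,
        spiral=spiral,
    )
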