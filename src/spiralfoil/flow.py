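"""Steady incompressible 2D flow in the downstream separation region.

A pseudo-transient fractional-step (projection) solver for the
incompressible Navier–Stokes equations on a staggered (MAC) grid with the
hydrofoil and separation wall represented as an immersed solid mask.
Inertia is retained: at the operating point (channel Reynolds number
≈ 100 on the hydraulic diameter) the routing of flow between the CTC and
waste passages depends on the momentum of the jet leaving the hydrofoil,
not only on passage resistances, so a Stokes approximation is not
adequate.  The 100 µm channel depth enters only through the flux
normalization (depth-averaged 2D model).

Boundary conditions: prescribed parabolic inflow carrying the 2D flux
Q/depth, no-slip on channel walls and immersed solids (staircase mask),
and a common zero reference pressure on both outlet passages so the
CTC/waste flow split is an emergent quantity of the solve.  Each time step
ends in an exact discrete projection, so the flux through every
cross-section matches the inlet flux to solver precision.

Internally SI units; the public surface speaks µm and µL/min.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import distance_transform_edt
from scipy.sparse import csc_matrix
from scipy.sparse.linalg import splu

from .exceptions import FlowSolverError, OutOfDomainError
from .geometry import DownstreamDomain

__all__ = ["FlowConfig", "FlowField", "solve_flow", "velocity_at", "flux_across"]

logger = logging.getLogger(__name__)

UL_MIN_TO_M3_S = 1e-9 / 60.0


@dataclass(frozen=True)
class FlowConfig:
    """Flow-rate, fluid and discretization settings.

    ``resolution`` is the grid cell size in µm; keep it at or below 5 µm
    for production runs (a warning is emitted above that).
    """

    flow_rate_ul_min: float = 1200.0
    density: float = 1000.0        # kg/m³
    viscosity: float = 1e-3        # Pa·s
    resolution: float = 3.0        # µm per cell
    cfl: float = 0.35
    max_steps: int = 60000
    check_every: int = 200
    steady_tol: float = 2e-3       # relative field change per check window
    fail_tol: float = 0.05

    def __post_init__(self) -> None:
        if self.flow_rate_ul_min <= 0:
            raise FlowSolverError("flow rate must be positive")
        if self.density <= 0 or self.viscosity <= 0:
            raise FlowSolverError("fluid properties must be positive")
        if self.resolution <= 0:
            raise FlowSolverError("grid resolution must be positive")
        if self.resolution > 5.0:
            warnings.warn(
                "grid resolution above 5 µm; use ≤ 5 µm for production runs",
                RuntimeWarning,
                stacklevel=2,
            )


@dataclass
class FlowField:
    """Discrete steady velocity field, queryable at arbitrary points.

    Cell-centered velocities (m/s) on a uniform grid; ``u_faces`` keeps the
    staggered axial component for exact flux integrals.  Velocities are
    zero on solid cells.
    """

    x: np.ndarray                 # cell centers, µm
    y: np.ndarray
    u: np.ndarray                 # (ny, nx) m/s, cell centered
    v: np.ndarray
    u_faces: np.ndarray           # (ny, nx+1) m/s
    fluid: np.ndarray             # (ny, nx) bool
    h: float                      # µm
    q2d: float                    # inlet flux per unit depth, m²/s
    domain: DownstreamDomain
    density: float = 1000.0       # carrier fluid, kg/m³
    viscosity: float = 1e-3       # Pa·s
    steps: int = 0
    residual: float = float("nan")
    converged: bool = True
    residual_history: list = field(default_factory=list)
    _interp_u: RegularGridInterpolator | None = None
    _interp_v: RegularGridInterpolator | None = None
    _edt: RegularGridInterpolator | None = None

    # ------------------------------------------------------------------ query
    def _build_interpolators(self) -> None:
        w, L = self.domain.width, self.domain.length
        ye = np.concatenate([[0.0], self.y, [w]])
        xe = np.concatenate([[0.0], self.x, [L]])

        def extend(a: np.ndarray, zero_walls: bool) -> np.ndarray:
            out = np.zeros((a.shape[0] + 2, a.shape[1] + 2))
            out[1:-1, 1:-1] = a
            out[1:-1, 0] = a[:, 0]      # inlet column: nearest value
            out[1:-1, -1] = a[:, -1]    # outlet column
            if not zero_walls:
                out[0, :] = out[1, :]
                out[-1, :] = out[-2, :]
            return out

        self._interp_u = RegularGridInterpolator(
            (ye, xe), extend(self.u, zero_walls=True), method="linear"
        )
        self._interp_v = RegularGridInterpolator(
            (ye, xe), extend(self.v, zero_walls=True), method="linear"
        )

    def velocity_at(self, point) -> np.ndarray:
        """Bilinear velocity (m/s) at a point (x, y) in µm."""
        return velocity_at(self, point)

    def solid_at(self, point) -> bool:
        xq, yq = float(point[0]), float(point[1])
        i = min(max(int(xq / self.h), 0), self.fluid.shape[1] - 1)
        j = min(max(int(yq / self.h), 0), self.fluid.shape[0] - 1)
        return not self.fluid[j, i]

    def distance_to_solid(self) -> RegularGridInterpolator:
        """Interpolator of distance (µm) to the nearest solid or channel wall."""
        if self._edt is None:
            free = self.fluid.astype(np.uint8)
            d = distance_transform_edt(free) * self.h
            d = np.minimum(d, self.y[:, None])
            d = np.minimum(d, self.domain.width - self.y[:, None])
            self._edt = RegularGridInterpolator(
                (self.y, self.x), d, method="linear",
                bounds_error=False, fill_value=0.0,
            )
        return self._edt

    # ------------------------------------------------------------------ fluxes
    def flux_across(self, x_um: float, y_range: tuple[float, float] | None = None) -> float:
        """Flux per unit depth (m²/s) of axial velocity through a section."""
        return flux_across(self, x_um, y_range)

    def ctc_split(self) -> float:
        """Fraction of the total flux leaving through the CTC passage."""
        if self.domain.wall is None:
            return 1.0
        lo = (0.0, self.domain.wall.lower_edge)
        return self.flux_across(self.domain.length, lo) / self.q2d


def velocity_at(fld: FlowField, point) -> np.ndarray:
    xq, yq = float(point[0]), float(point[1])
    if not (0.0 <= xq <= fld.domain.length and 0.0 <= yq <= fld.domain.width):
        raise OutOfDomainError(f"point ({xq:g}, {yq:g}) outside the domain")
    if fld.solid_at((xq, yq)):
        raise OutOfDomainError(f"point ({xq:g}, {yq:g}) lies in a solid")
    if fld._interp_u is None:
        fld._build_interpolators()
    q = np.array([[yq, xq]])
    return np.array([fld._interp_u(q)[0], fld._interp_v(q)[0]])


def flux_across(fld: FlowField, x_um: float, y_range=None) -> float:
    """Integrate axial velocity over a vertical section (µm coordinates).

    Solid cells contribute nothing; if the interval intersects a solid a
    partial-section warning is issued and only fluid cells are integrated.
    """
    ny, nx = fld.fluid.shape
    i = int(round(x_um / fld.h))
    i = min(max(i, 0), nx)
    col = fld.u_faces[:, i]
    cell_i = min(i, nx - 1)
    fluid_col = fld.fluid[:, cell_i] if i == 0 else fld.fluid[:, i - 1]
    if y_range is None:
        lo, hi = 0.0, fld.domain.width
    else:
        lo, hi = y_range
    edges_lo = fld.y - fld.h / 2.0
    edges_hi = fld.y + fld.h / 2.0
    overlap = np.clip(np.minimum(edges_hi, hi) - np.maximum(edges_lo, lo), 0.0, fld.h)
    if np.any((overlap > 0) & ~fluid_col):
        warnings.warn(
            "section intersects a solid; integrating fluid cells only",
            RuntimeWarning,
            stacklevel=2,
        )
    return float(np.sum(col * overlap * 1e-6 * fluid_col))


# --------------------------------------------------------------------------- #
# solver
# --------------------------------------------------------------------------- #

def _inlet_profile(yc_um: np.ndarray, width_um: float, q2d: float) -> np.ndarray:
    """Plane-Poiseuille inflow carrying flux q2d (per depth)."""
    w = width_um * 1e-6
    u_mean = q2d / w
    yy = yc_um * 1e-6
    return 6.0 * u_mean * (yy / w) * (1.0 - yy / w)


def _build_poisson(fluid: np.ndarray, u_solid: np.ndarray, v_solid: np.ndarray):
    """Sparse pressure-Poisson operator over fluid cells.

    Neumann on walls, solids and the inlet; zero-Dirichlet ghost behind
    both outlet passages (the common reference pressure).
    """
    ny, nx = fluid.shape
    idx = -np.ones((ny, nx), dtype=np.int64)
    idx[fluid] = np.arange(int(fluid.sum()))
    n = int(fluid.sum())

    rows, cols, vals = [], [], []
    diag = np.zeros(n)

    jj, ii = np.nonzero(fluid)
    k = idx[jj, ii]

    # east neighbor through face (j, i+1)
    east_open = (ii < nx - 1) & ~u_solid[jj, np.minimum(ii + 1, nx)]
    en = east_open & fluid[jj, np.minimum(ii + 1, nx - 1)]
    rows.append(k[en]); cols.append(idx[jj[en], ii[en] + 1]); vals.append(np.ones(en.sum()))
    diag[k[en]] -= 1.0
    # outlet Dirichlet ghost east of the last column
    outlet = (ii == nx - 1) & ~u_solid[jj, nx]
    diag[k[outlet]] -= 1.0

    # west neighbor through face (j, i); i=0 is the inlet (Neumann)
    west_open = (ii > 0) & ~u_solid[jj, ii]
    wn = west_open & fluid[jj, np.maximum(ii - 1, 0)]
    rows.append(k[wn]); cols.append(idx[jj[wn], ii[wn] - 1]); vals.append(np.ones(wn.sum()))
    diag[k[wn]] -= 1.0

    # north neighbor through face (j+1, i)
    north_open = (jj < ny - 1) & ~v_solid[np.minimum(jj + 1, ny), ii]
    nn = north_open & fluid[np.minimum(jj + 1, ny - 1), ii]
    rows.append(k[nn]); cols.append(idx[jj[nn] + 1, ii[nn]]); vals.append(np.ones(nn.sum()))
    diag[k[nn]] -= 1.0

    # south neighbor through face (j, i)
    south_open = (jj > 0) & ~v_solid[jj, ii]
    sn = south_open & fluid[np.maximum(jj - 1, 0), ii]
    rows.append(k[sn]); cols.append(idx[jj[sn] - 1, ii[sn]]); vals.append(np.ones(sn.sum()))
    diag[k[sn]] -= 1.0

    rows.append(np.arange(n)); cols.append(np.arange(n)); vals.append(diag)
    A = csc_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return splu(A), idx


def solve_flow(domain: DownstreamDomain, config: FlowConfig | None = None) -> FlowField:
    """March the 2D Navier–Stokes equations to a steady state.

    Raises :class:`FlowSolverError` if the geometry blocks the channel or
    the residual fails to fall below the failure threshold within the step
    budget; warns if the field is only approximately steady (e.g. a weakly
    unsteady wake).
    """
    config = config or FlowConfig()
    h_um = config.resolution
    nx = int(round(domain.length / h_um))
    ny = int(round(domain.width / h_um))
    h = h_um * 1e-6
    nu = config.viscosity / config.density
    q = config.flow_rate_ul_min * UL_MIN_TO_M3_S
    q2d = q / (domain.depth * 1e-6)

    xc = (np.arange(nx) + 0.5) * h_um
    yc = (np.arange(ny) + 0.5) * h_um
    XX, YY = np.meshgrid(xc, yc)
    solid = domain.solid_mask(XX, YY)
    fluid = ~solid
    if np.any(solid.all(axis=0)):
        raise FlowSolverError("a solid blocks the entire channel width")

    u_solid = np.zeros((ny, nx + 1), dtype=bool)
    u_solid[:, 1:nx] = solid[:, :-1] | solid[:, 1:]
    u_solid[:, 0] = solid[:, 0]
    u_solid[:, nx] = solid[:, -1]
    v_solid = np.ones((ny + 1, nx), dtype=bool)
    v_solid[1:ny, :] = solid[:-1, :] | solid[1:, :]

    lu, idx = _build_poisson(fluid, u_solid, v_solid)

    u_in = _inlet_profile(yc, domain.width, q2d)
    u_in[~fluid[:, 0]] = 0.0
    q2d_disc = float(np.sum(u_in * h))

    u = np.tile(u_in[:, None], (1, nx + 1))
    u[u_solid] = 0.0
    v = np.zeros((ny + 1, nx))

    inv_h = 1.0 / h
    # 2D advective CFL uses |u|+|v| (TVD-safe for the limited scheme)
    dt = config.cfl * min(
        h / max(np.abs(u).max() + np.abs(v).max(), 1e-12),
        h * h / (4.0 * nu),
    )
    u_prev = u.copy()
    residual = np.inf
    history: list[tuple[int, float]] = []
    converged = False
    step = 0

    int_u = ~u_solid[:, 1:nx]
    int_v = ~v_solid[1:ny, :]

    def _harmonic(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
        """van Leer (harmonic-mean) limited slope from adjacent differences."""
        prod = lo * hi
        s = np.zeros_like(prod)
        pos = prod > 0
        s[pos] = 2.0 * prod[pos] / (lo + hi)[pos]
        return s

    def _tend_u(u: np.ndarray, v: np.ndarray) -> np.ndarray:
        """MUSCL advection + viscous tendency for interior u faces."""
        uc = u[:, 1:-1]
        upad = np.vstack([-u[:1], u, -u[-1:]])       # wall ghosts
        # x slopes at u nodes
        dx = np.diff(u, axis=1)
        sx = np.zeros_like(u)
        sx[:, 1:-1] = _harmonic(dx[:, :-1], dx[:, 1:])
        # uu-fluxes at cell centers (between u nodes)
        ua = 0.5 * (u[:, :-1] + u[:, 1:])
        ul = u[:, :-1] + 0.5 * sx[:, :-1]
        ur = u[:, 1:] - 0.5 * sx[:, 1:]
        fx = ua * np.where(ua > 0, ul, ur)
        dfx = np.diff(fx, axis=1)                    # (ny, nx-1)
        # y slopes using wall ghosts
        dy = np.diff(upad, axis=0)                   # (ny+1, nx+1)
        sy = _harmonic(dy[:-1, :], dy[1:, :])        # (ny, nx+1)
        # vu-fluxes at corners, rows j=1..ny-1 (walls carry zero flux)
        va = np.zeros((ny - 1, nx + 1))
        va[:, 1:nx] = 0.5 * (v[1:ny, :-1] + v[1:ny, 1:])
        va[:, nx] = v[1:ny, -1]
        ub = u[:-1, :] + 0.5 * sy[:-1, :]
        ut = u[1:, :] - 0.5 * sy[1:, :]
        fy = np.zeros((ny + 1, nx + 1))
        fy[1:ny] = va * np.where(va > 0, ub, ut)
        dfy = np.diff(fy, axis=0)                    # (ny, nx+1)
        lap = (
            u[:, 2:] - 2 * uc + u[:, :-2]
            + upad[2:, 1:-1] - 2 * uc + upad[:-2, 1:-1]
        ) * inv_h * inv_h
        return -(dfx + dfy[:, 1:-1]) * inv_h + nu * lap

    def _tend_v(u: np.ndarray, v: np.ndarray) -> np.ndarray:
        """MUSCL advection + viscous tendency for interior v faces."""
        vc = v[1:-1, :]
        vpad = np.hstack([-v[:, :1], v, v[:, -1:]])  # inlet/outlet ghosts
        # x slopes on the padded array
        dx = np.diff(vpad, axis=1)                   # (ny+1, nx+1)
        sxp = np.zeros_like(vpad)
        sxp[:, 1:-1] = _harmonic(dx[:, :-1], dx[:, 1:])
        # uv-fluxes at corners, all columns i=0..nx
        ua = np.zeros((ny + 1, nx + 1))
        ua[1:ny, :] = 0.5 * (u[:-1, :] + u[1:, :])
        vl = vpad[:, :-1] + 0.5 * sxp[:, :-1]
        vr = vpad[:, 1:] - 0.5 * sxp[:, 1:]
        fx = ua * np.where(ua > 0, vl, vr)
        dfx = np.diff(fx, axis=1)                    # (ny+1, nx)
        # y slopes at v nodes
        dyv = np.diff(v, axis=0)                     # (ny, nx)
        sy = np.zeros_like(v)
        sy[1:-1, :] = _harmonic(dyv[:-1, :], dyv[1:, :])
        # vv-fluxes at cell centers
        va = 0.5 * (v[:-1, :] + v[1:, :])
        vb = v[:-1, :] + 0.5 * sy[:-1, :]
        vt = v[1:, :] - 0.5 * sy[1:, :]
        fy = va * np.where(va > 0, vb, vt)
        dfy = np.diff(fy, axis=0)                    # (ny-1, nx)
        lapv = (
            vpad[1:-1, 2:] - 2 * vc + vpad[1:-1, :-2]
            + v[2:, :] - 2 * vc + v[:-2, :]
        ) * inv_h * inv_h
        return -(dfx[1:ny, :] + dfy) * inv_h + nu * lapv

    visc_dt = h * h / (4.0 * nu)
    while step < config.max_steps:
        for _ in range(config.check_every):
            adv = float(np.abs(u).max() + np.abs(v).max())
            dt = config.cfl * min(h / max(adv, 1e-12), visc_dt)
            u_new = u[:, 1:-1] + dt * _tend_u(u, v)
            v_new = v[1:-1, :] + dt * _tend_v(u, v)
            u[:, 1:-1] = np.where(int_u, u_new, 0.0)
            v[1:-1, :] = np.where(int_v, v_new, 0.0)
            u[:, 0] = u_in
            u[:, -1] = np.where(u_solid[:, nx], 0.0, u[:, -2])

            # ---------------- projection
            div = (u[:, 1:] - u[:, :-1] + v[1:, :] - v[:-1, :]) * inv_h
            rhs = (div * h * h)[fluid]
            psi = lu.solve(rhs)
            P = np.zeros((ny, nx))
            P[fluid] = psi

            gx = (P[:, 1:] - P[:, :-1]) * inv_h
            u[:, 1:-1] = np.where(int_u, u[:, 1:-1] - gx, 0.0)
            out_ok = ~u_solid[:, nx]
            u[out_ok, -1] -= (0.0 - P[out_ok, -1]) * inv_h
            gy = (P[1:, :] - P[:-1, :]) * inv_h
            v[1:-1, :] = np.where(int_v, v[1:-1, :] - gy, 0.0)

            step += 1

        umax = max(float(np.abs(u).max()), 1e-12)
        if not np.isfinite(umax):
            raise FlowSolverError(
                f"flow solve diverged (non-finite field) after {step} steps"
            )
        residual = float(np.max(np.abs(u - u_prev))) / umax
        history.append((step, residual))
        u_prev = u.copy()
        if residual < config.steady_tol:
            converged = True
            break

    if not converged:
        if residual > config.fail_tol:
            raise FlowSolverError(
                f"flow solve did not converge: residual {residual:.3e} after "
                f"{step} steps (history tail {history[-3:]})"
            )
        warnings.warn(
            f"flow only approximately steady (residual {residual:.3e}); "
            "proceeding with the final field",
            RuntimeWarning,
            stacklevel=2,
        )

    u_c = 0.5 * (u[:, :-1] + u[:, 1:])
    v_c = 0.5 * (v[:-1, :] + v[1:, :])
    u_c[solid] = 0.0
    v_c[solid] = 0.0

    fld = FlowField(
        x=xc, y=yc, u=u_c, v=v_c, u_faces=u.copy(), fluid=fluid,
        h=h_um, q2d=q2d_disc, domain=domain,
        density=config.density, viscosity=config.viscosity,
        steps=step, residual=residual, converged=converged,
        residual_history=history,
    )
    if domain.wall is not None:
        split = fld.ctc_split()
        logger.info(
            "flow solved: %d steps, residual %.2e, CTC-side flow split %.3f",
            step, residual, split,
        )
    else:
        logger.info("flow solved: %d steps, residual %.2e", step, residual)
    return fld


def export_field_csv(fld: FlowField, path) -> None:
    """Write the cell-centered field as CSV (x_um, y_um, u_mps, v_mps)."""
    XX, YY = np.meshgrid(fld.x, fld.y)
    data = np.column_stack(
        [XX.ravel(), YY.ravel(), fld.u.ravel(), fld.v.ravel()]
    )
    header = (
        f"# domain: length={fld.domain.length} width={fld.domain.width} "
        f"depth={fld.domain.depth} (um); q2d={fld.q2d} m^2/s\n"
        "x_um,y_um,u_mps,v_mps"
    )
    np.savetxt(path, data, delimiter=",", header=header, comments="")
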