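"""Time-averaged electrostatic potential maps from smeared charges.

Each atom's point charge is replaced by a spherical Gaussian of inverse
width β (default 0.25 Å⁻¹, grid spacing 1 Å), the Poisson equation
∇²φ = −4πρ is solved spectrally under periodic boundary conditions with
tinfoil (zero-mean) gauge and uniform-background neutralisation, and maps
are averaged over trajectory windows.  The applied transmembrane voltage is
carried as an analytic linear-ramp component: a ramp is not periodic, so
baking it into the node array would corrupt wrap-around interpolation — it
is instead added exactly at probe time (and sampled onto nodes only when
exporting to OpenDX).

Units: charges in e, lengths in Å, potentials in mV.  The maps are smeared
potentials (no point-charge short-range correction) and the dielectric is
implicit — vacuum-like Poisson on the smeared density.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .core import E_PER_ANGSTROM_TO_MV, Topology, Trajectory, TopologyError

__all__ = [
    "PotentialGrid", "spread_charges", "solve_poisson_periodic",
    "add_external_potential", "time_average_maps", "probe", "probe_plane",
    "write_dx", "read_dx", "DEFAULT_BETA", "DEFAULT_SPACING",
]

DEFAULT_BETA = 0.25      # Å^-1, inverse Gaussian width
DEFAULT_SPACING = 1.0    # Å


@dataclass
class PotentialGrid:
    """Periodic scalar field on a regular orthorhombic grid.

    ``values`` holds the solved (periodic, zero-mean) potential in mV;
    ``external`` optionally carries an analytic applied-voltage ramp
    ``(voltage_mV, z_lo, z_hi)`` added at probe time.
    """

    origin: np.ndarray           # Å, position of node (0,0,0)
    spacing: np.ndarray          # Å per axis
    values: np.ndarray           # (nx, ny, nz), mV
    beta: float = DEFAULT_BETA
    frames_averaged: int = 1
    external: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.atleast_1d(np.asarray(self.spacing, dtype=float))
        if self.spacing.size == 1:
            self.spacing = np.repeat(self.spacing, 3)
        if (self.spacing <= 0).any():
            raise ValueError("grid spacing must be positive")
        if min(self.values.shape) < 2:
            raise ValueError("grid needs at least 2 nodes per axis")

    @property
    def dimensions(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def box(self) -> np.ndarray:
        return self.spacing * np.asarray(self.values.shape)

    def external_potential(self, z) -> np.ndarray:
        """Analytic applied-voltage component at height(s) z, mV."""
        if self.external is None:
            return np.zeros_like(np.asarray(z, dtype=float))
        v, z_lo, z_hi = self.external
        return v * np.clip((np.asarray(z, dtype=float) - z_lo)
                           / (z_hi - z_lo), 0.0, 1.0)


def _grid_shape(box: Sequence[float], spacing: float) -> np.ndarray:
    n = np.maximum(np.round(np.asarray(box, dtype=float) / spacing), 2)
    return n.astype(int)


def spread_charges(frame: np.ndarray, topology: Topology,
                   box: Sequence[float], spacing: float = DEFAULT_SPACING,
                   beta: float = DEFAULT_BETA,
                   origin: Sequence[float] | None = None) -> PotentialGrid:
    """Accumulate the Gaussian-smeared charge density on a periodic grid.

    ρ(r) = Σ_i q_i (β/√π)³ exp(−β²|r − r_i|²) with periodic wrapping; atoms
    outside the box are wrapped internally, never an error.  The returned
    grid's ``values`` hold charge density in e/Å³; its integral equals the
    total charge to quadrature tolerance.
    """
    box = np.asarray(box, dtype=float)
    shape = _grid_shape(box, spacing)
    h = box / shape  # exact per-axis spacing commensurate with the box
    org = (np.zeros(3) if origin is None else np.asarray(origin, dtype=float))
    rho = np.zeros(shape)
    # stencil radius: exp(-(beta r)^2) < 3e-14 beyond beta*r = 5.6
    r_cut = 5.6 / beta
    nstep = np.ceil(r_cut / h).astype(int)
    pref = (beta / np.sqrt(np.pi)) ** 3
    x = np.asarray(frame, dtype=float)
    charges = topology.charges
    for i in range(topology.n_atoms):
        q = charges[i]
        if q == 0.0:
            continue
        rel = (x[i] - org) / h  # fractional node coordinates
        base = np.floor(rel).astype(int)
        axes_idx, axes_g = [], []
        for d in range(3):
            offs = np.arange(base[d] - nstep[d], base[d] + nstep[d] + 2)
            dist = (offs - rel[d]) * h[d]
            axes_idx.append(np.mod(offs, shape[d]))
            axes_g.append(np.exp(-(beta * dist) ** 2))
        gx, gy, gz = axes_g
        block = q * pref * gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
        np.add.at(rho, np.ix_(axes_idx[0], axes_idx[1], axes_idx[2]), block)
    return PotentialGrid(org, h, rho, beta=beta)


def solve_poisson_periodic(density: PotentialGrid) -> PotentialGrid:
    """Spectral solve of ∇²φ = −4πρ on the periodic grid.

    Non-neutral cells are handled by uniform-background subtraction (the k=0
    mode is dropped), which also fixes the zero-mean potential gauge.  Output
    in mV.
    """
    rho = density.values
    if not np.any(rho):
        return replace(density, values=np.zeros_like(rho))
    shape = np.asarray(rho.shape)
    h = density.spacing
    k = [2.0 * np.pi * np.fft.fftfreq(n, d=d) for n, d in zip(shape, h)]
    kx, ky, kz = np.meshgrid(*k, indexing="ij")
    k2 = kx ** 2 + ky ** 2 + kz ** 2
    rho_k = np.fft.fftn(rho)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_k = np.where(k2 > 0, 4.0 * np.pi * rho_k / k2, 0.0)
    phi = np.fft.ifftn(phi_k).real * E_PER_ANGSTROM_TO_MV
    return replace(density, values=phi)


def add_external_potential(grid: PotentialGrid, voltage: float,
                           membrane_span: tuple[float, float] | None = None
                           ) -> PotentialGrid:
    """Attach the applied-voltage ramp to a potential grid.

    With ``membrane_span=None`` the constant-field convention is used — the
    potential rises linearly by ``voltage`` across the whole box along z
    (E = V/L_z).  A ``(z_lo, z_hi)`` span instead gives the piecewise profile
    0 below the membrane, linear within, ``voltage`` above.  Adding a ramp of
    −V undoes a ramp of +V.
    """
    if membrane_span is None:
        z_lo = float(grid.origin[2])
        z_hi = z_lo + float(grid.box[2])
    else:
        z_lo, z_hi = map(float, membrane_span)
        if not z_lo < z_hi:
            raise ValueError("membrane_span must satisfy z_lo < z_hi")
    if grid.external is None:
        ext = (float(voltage), z_lo, z_hi)
    else:
        v0, a, b = grid.external
        if (a, b) != (z_lo, z_hi):
            raise ValueError("cannot combine ramps over different spans")
        ext = (v0 + float(voltage), z_lo, z_hi)
    if abs(ext[0]) < 1e-12:
        ext = None
    return replace(grid, external=ext)


def electrostatic_map(frame: np.ndarray, topology: Topology,
                      box: Sequence[float], spacing: float = DEFAULT_SPACING,
                      beta: float = DEFAULT_BETA,
                      origin: Sequence[float] | None = None) -> PotentialGrid:
    """Single-frame smeared-charge potential map (spread + solve)."""
    return solve_poisson_periodic(
        spread_charges(frame, topology, box, spacing=spacing, beta=beta,
                       origin=origin))


def time_average_maps(traj: Trajectory, topology: Topology,
                      window: tuple[int, int] | None = None,
                      spacing: float = DEFAULT_SPACING,
                      beta: float = DEFAULT_BETA,
                      origin: Sequence[float] | None = None) -> PotentialGrid:
    """Arithmetic mean of per-frame potential maps over a frame window."""
    traj.check_compatible(topology)
    lo, hi = (0, traj.n_frames) if window is None else window
    if not (0 <= lo < hi <= traj.n_frames):
        raise ValueError(f"window ({lo}, {hi}) empty or outside trajectory")
    acc = None
    for f in range(lo, hi):
        g = electrostatic_map(traj.coordinates[f], topology, traj.box[f],
                              spacing=spacing, beta=beta, origin=origin)
        acc = g.values if acc is None else acc + g.values
    return replace(g, values=acc / (hi - lo), frames_averaged=hi - lo)


# --------------------------------------------------------------------------- #
# probing
# --------------------------------------------------------------------------- #


def probe(grid: PotentialGrid, points: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of the potential at Cartesian points (mV).

    Periodic wrapping is applied to the solved field; the analytic external
    ramp, when present, is evaluated at the unwrapped z.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    rel = (pts - grid.origin) / grid.spacing
    base = np.floor(rel).astype(int)
    frac = rel - base
    shape = np.asarray(grid.values.shape)
    out = np.zeros(len(pts))
    for cx in (0, 1):
        for cy in (0, 1):
            for cz in (0, 1):
                idx = np.mod(base + [cx, cy, cz], shape)
                w = (np.where(cx, frac[:, 0], 1 - frac[:, 0])
                     * np.where(cy, frac[:, 1], 1 - frac[:, 1])
                     * np.where(cz, frac[:, 2], 1 - frac[:, 2]))
                out += w * grid.values[idx[:, 0], idx[:, 1], idx[:, 2]]
    out = out + grid.external_potential(pts[:, 2])
    return out if np.asarray(points).ndim > 1 else float(out[0])


def probe_plane(grid: PotentialGrid, point: Sequence[float],
                normal: Sequence[float], extent: float = 30.0,
                resolution: float = 1.0
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Potential on a plane through ``point`` with the given normal.

    Returns (u, v, values): in-plane coordinates and the interpolated 2-D
    slice.  The in-plane basis is built by Gram–Schmidt against the normal;
    a zero normal is a degenerate basis and raises.
    """
    n = np.asarray(normal, dtype=float)
    if np.linalg.norm(n) < 1e-12:
        raise ValueError("degenerate plane normal")
    n = n / np.linalg.norm(n)
    trial = np.array([1.0, 0.0, 0.0])
    if abs(n @ trial) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    e1 = trial - (trial @ n) * n
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    u = np.arange(-extent, extent + 0.5 * resolution, resolution)
    uu, vv = np.meshgrid(u, u, indexing="ij")
    pts = (np.asarray(point, dtype=float)[None, :]
           + uu.ravel()[:, None] * e1 + vv.ravel()[:, None] * e2)
    vals = probe(grid, pts).reshape(uu.shape)
    return u, u.copy(), vals


# --------------------------------------------------------------------------- #
# OpenDX exchange
# --------------------------------------------------------------------------- #


def write_dx(path: str, grid: PotentialGrid) -> None:
    """Write the grid in OpenDX scalar format (external ramp baked into the
    node values)."""
    from gridData import Grid

    vals = grid.values
    if grid.external is not None:
        z = grid.origin[2] + np.arange(vals.shape[2]) * grid.spacing[2]
        vals = vals + grid.external_potential(z)[None, None, :]
    Grid(vals, origin=grid.origin, delta=grid.spacing).export(path, "dx")


def read_dx(path: str, beta: float = DEFAULT_BETA) -> PotentialGrid:
    """Read an OpenDX scalar grid."""
    from gridData import Grid

    g = Grid(path)
    delta = np.asarray(g.delta, dtype=float)
    if delta.ndim == 2:
        delta = np.diag(delta)
    return PotentialGrid(np.asarray(g.origin, dtype=float), delta,
                         np.asarray(g.grid, dtype=float), beta=beta)
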