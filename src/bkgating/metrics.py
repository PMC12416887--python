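"""Per-frame structural, hydration and permeation observables.

Covers the trajectory metrics used to characterise voltage activation of a
channel: charged-group z-displacements, helix center-of-mass displacement and
tilt, backbone RMSD to a reference state, residue contact maps (5 Å / 75%
occupancy rule), HOLE-style pore radius profiles, pore-water counting,
permeation-event counting with a double-crossing criterion, conductance
estimation, membrane thickness and 2-D free-energy surfaces.

Per-residue series are averaged over the four subunits when chains share
residue numbers (per-chain series are emitted alongside).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import (R_KCAL, Selection, Topology, Trajectory, SelectionError,
                   TopologyError, select)

__all__ = [
    "TimeSeries", "PoreProfile", "FreeEnergySurface2D",
    "charged_group_z_displacement", "helix_com_displacement",
    "helix_tilt_angle", "backbone_rmsd", "residue_contact_map",
    "pore_radius_profile", "count_pore_waters", "count_permeation_events",
    "estimate_conductance", "membrane_thickness", "free_energy_surface_2d",
    "kabsch_superpose",
]

#: sentinel pore radius where a z-slice has no atoms nearby (bulk region)
PORE_RADIUS_CAP = 15.0


# --------------------------------------------------------------------------- #
# containers
# --------------------------------------------------------------------------- #


@dataclass
class TimeSeries:
    """A labelled per-frame series; ``per_chain`` optionally holds the
    chain-resolved values averaged into ``values``."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""
    per_chain: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape[0] != self.values.shape[0]:
            raise ValueError("times and values must have equal length")

    def running_average(self, window: int = 50) -> np.ndarray:
        """Centered moving average; shrinks the window at the edges."""
        if window < 1:
            raise ValueError("averaging window must be >= 1")
        half = window // 2
        out = np.empty_like(self.values, dtype=float)
        n = len(self.values)
        for i in range(n):
            lo, hi = max(0, i - half), min(n, i + half + 1)
            out[i] = self.values[lo:hi].mean()
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_ns": self.times, "value": self.values})
        df["label"] = self.label
        return df


@dataclass
class PoreProfile:
    """Pore radius along the channel axis with the refined center path."""

    z_grid: np.ndarray
    radius: np.ndarray
    axis_path: np.ndarray  # (n_z, 2) refined (x, y) centers

    def __post_init__(self) -> None:
        self.z_grid = np.asarray(self.z_grid, dtype=float)
        if not (np.diff(self.z_grid) > 0).all():
            raise ValueError("z_grid must be strictly increasing")
        if (np.asarray(self.radius) < 0).any():
            raise ValueError("pore radii must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"z_A": self.z_grid, "radius_A": self.radius})


@dataclass
class FreeEnergySurface2D:
    """-RT ln P(x, y) on a regular grid, min-shifted to zero; empty bins are
    +inf."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    free_energy: np.ndarray  # kcal/mol
    temperature: float

    def to_frame(self) -> pd.DataFrame:
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        xx, yy = np.meshgrid(xc, yc, indexing="ij")
        return pd.DataFrame({"x_A": xx.ravel(), "y_A": yy.ravel(),
                             "F_kcal_mol": self.free_energy.ravel()})


# --------------------------------------------------------------------------- #
# displacements, tilt, RMSD
# --------------------------------------------------------------------------- #


def charged_group_z_displacement(traj: Trajectory, topology: Topology,
                                 residues: Sequence[int],
                                 reference_frame: int = 0
                                 ) -> dict[int, TimeSeries]:
    """Δz(t) of each residue's charged-group atom relative to a reference
    frame, averaged over the chains sharing that residue number."""
    traj.check_compatible(topology)
    out: dict[int, TimeSeries] = {}
    for res in residues:
        chains = sorted(set(
            topology.chain_ids[topology.residue_numbers == res].tolist()))
        if not chains:
            raise SelectionError(f"residue {res} not in topology")
        idx = [topology.charged_group_index(res, c) for c in chains]
        z = traj.coordinates[:, idx, 2]
        dz = z - z[reference_frame]
        per_chain = pd.DataFrame(dz, columns=[str(c) for c in chains])
        per_chain.insert(0, "time_ns", traj.times)
        out[res] = TimeSeries(traj.times, dz.mean(axis=1),
                              label=f"dz_res{res}", per_chain=per_chain)
    return out


def _com(coords: np.ndarray, weights: np.ndarray | None) -> np.ndarray:
    if weights is None:
        return coords.mean(axis=-2)
    w = weights / weights.sum()
    return np.einsum("...ij,i->...j", coords, w)


def helix_com_displacement(traj: Trajectory, topology: Topology, helix: str,
                           reference_frame: int = 0, axis: str = "z",
                           mass_weighted: bool = False,
                           chain: str | None = None) -> TimeSeries:
    """Center-of-mass displacement of a named helix along z, or its lateral
    (x, y) displacement magnitude for ``axis='xy'``."""
    if helix not in topology.helix_definitions:
        raise SelectionError(f"helix {helix!r} not defined in topology")
    lo, hi = topology.helix_definitions[helix]
    mask = (topology.residue_numbers >= lo) & (topology.residue_numbers <= hi)
    if chain is not None:
        mask &= topology.chain_ids == chain
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        raise SelectionError(f"helix {helix} selection is empty")
    weights = topology.masses[idx] if mass_weighted else None
    com = _com(traj.coordinates[:, idx], weights)
    d = com - com[reference_frame]
    if axis == "z":
        vals = d[:, 2]
    elif axis == "xy":
        vals = np.linalg.norm(d[:, :2], axis=1)
    else:
        raise ValueError("axis must be 'z' or 'xy'")
    return TimeSeries(traj.times, vals, label=f"{helix}_com_{axis}")


def helix_tilt_angle(traj: Trajectory, topology: Topology, helix: str,
                     residue_subset: tuple[int, int] | None = None,
                     chain: str | None = None) -> TimeSeries:
    """Angle between the helix axis and the membrane normal.

    The axis is estimated from the Cα trace of the (optionally restricted)
    residue range as the smallest-variance principal direction of the second
    differences of consecutive Cα positions: for an ideal helix those
    difference vectors lie exactly in the plane perpendicular to the axis,
    so the estimate is free of the phase bias that principal components of
    the raw coordinates carry on short discrete helices.  The axis is
    oriented N→C and the angle folded into [0°, 90°].
    """
    if helix not in topology.helix_definitions:
        raise SelectionError(f"helix {helix!r} not defined in topology")
    lo, hi = topology.helix_definitions[helix]
    if residue_subset is not None:
        lo, hi = residue_subset
    mask = ((topology.residue_numbers >= lo) & (topology.residue_numbers <= hi)
            & (topology.names == "CA"))
    if chain is not None:
        mask &= topology.chain_ids == chain
    idx = np.nonzero(mask)[0]
    if len(idx) < 4:
        raise SelectionError(
            f"tilt needs >=4 CA atoms, got {len(idx)} for {helix} {lo}-{hi}")
    order = np.argsort(topology.residue_numbers[idx], kind="stable")
    idx = idx[order]
    vals = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        x = traj.coordinates[f, idx]
        d2 = x[2:] - 2.0 * x[1:-1] + x[:-2]
        _, _, vt = np.linalg.svd(d2, full_matrices=True)
        axis = vt[-1]  # direction the second differences do not explore
        if np.dot(axis, x[-1] - x[0]) < 0:  # orient N -> C
            axis = -axis
        cosang = abs(axis[2]) / np.linalg.norm(axis)
        vals[f] = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return TimeSeries(traj.times, vals, label=f"{helix}_tilt_deg")


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares superposition (Kabsch, SVD): returns the transformed
    mobile coordinates plus the rotation matrix and translation used."""
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    P = mobile - mc
    Q = reference - rc
    V, S, Wt = np.linalg.svd(P.T @ Q)
    d = np.sign(np.linalg.det(V @ Wt))
    D = np.diag([1.0, 1.0, d])
    R = (V @ D @ Wt).T
    moved = (R @ P.T).T + rc
    return moved, R, rc - R @ mc


def backbone_rmsd(traj: Trajectory, topology: Topology, selection: Selection,
                  reference_coordinates: np.ndarray,
                  superpose: bool = True) -> TimeSeries:
    """RMSD of a selection to reference coordinates, after optimal rigid-body
    superposition unless ``superpose=False``."""
    idx = selection.require_nonempty()
    ref = np.asarray(reference_coordinates, dtype=float)
    if ref.shape != (len(idx), 3):
        raise TopologyError(
            f"reference has shape {ref.shape}, expected ({len(idx)}, 3)")
    vals = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        x = traj.coordinates[f, idx]
        if superpose:
            x, _, _ = kabsch_superpose(x, ref)
        vals[f] = np.sqrt(((x - ref) ** 2).sum(axis=1).mean())
    return TimeSeries(traj.times, vals, label="rmsd_A")


# --------------------------------------------------------------------------- #
# contacts
# --------------------------------------------------------------------------- #


def _residue_groups(topology: Topology, sel: Selection) -> tuple[list, list]:
    """Group a selection's heavy-atom indices by (chain, resid)."""
    idx = sel.require_nonempty()
    heavy = topology.heavy_mask()
    idx = idx[heavy[idx]]
    if len(idx) == 0:
        raise SelectionError("selection contains no heavy atoms")
    keys: dict[tuple[str, int], list[int]] = {}
    for i in idx:
        keys.setdefault((str(topology.chain_ids[i]),
                         int(topology.residue_numbers[i])), []).append(int(i))
    labels = sorted(keys)
    return labels, [np.array(keys[k]) for k in labels]


def residue_contact_map(traj: Trajectory, topology: Topology,
                        selection_a: Selection, selection_b: Selection,
                        cutoff: float = 5.0, occupancy: float = 0.75
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Residue contact matrix from the minimum heavy-atom distance rule.

    A residue pair is in contact in a frame when its minimum heavy-atom
    distance is ≤ ``cutoff`` (5 Å); the contact is retained when the fraction
    of frames in contact is ≥ ``occupancy`` (75%).  Returns (contact, occupancy)
    DataFrames indexed by (chain, resid) labels.
    """
    labels_a, groups_a = _residue_groups(topology, selection_a)
    labels_b, groups_b = _residue_groups(topology, selection_b)
    counts = np.zeros((len(labels_a), len(labels_b)))
    for f in range(traj.n_frames):
        x = traj.coordinates[f]
        trees_b = [cKDTree(x[g]) for g in groups_b]
        for a, ga in enumerate(groups_a):
            ta = cKDTree(x[ga])
            for b, tb in enumerate(trees_b):
                if labels_a[a] == labels_b[b]:
                    counts[a, b] += 1  # self-pairs trivially in contact
                    continue
                hits = ta.query_ball_tree(tb, cutoff)
                if any(hits):
                    counts[a, b] += 1
    occ = counts / traj.n_frames
    names_a = [f"{c}:{r}" for c, r in labels_a]
    names_b = [f"{c}:{r}" for c, r in labels_b]
    occ_df = pd.DataFrame(occ, index=names_a, columns=names_b)
    return occ_df >= occupancy, occ_df


# --------------------------------------------------------------------------- #
# pore geometry and hydration
# --------------------------------------------------------------------------- #


def _slice_radius(x: np.ndarray, r_vdw: np.ndarray, center: np.ndarray,
                  z: float) -> float:
    d = np.sqrt(((x[:, :2] - center) ** 2).sum(axis=1) + (x[:, 2] - z) ** 2)
    return float((d - r_vdw).min())


def pore_radius_profile(frame: np.ndarray, topology: Topology,
                        axis_hint: tuple[float, float] = (0.0, 0.0),
                        z_range: tuple[float, float] = (-25.0, 15.0),
                        dz: float = 0.5, search_radius: float = 5.0,
                        coarse_step: float = 0.25,
                        cap: float = PORE_RADIUS_CAP) -> PoreProfile:
    """HOLE-style pore radius profile of a single frame.

    Per z-slice the pore radius is the largest sphere radius
    ``max_c min_i (|c - x_i| - r_i)`` over candidate in-plane centers c,
    found by a coarse xy grid (``coarse_step``) around the (per-slice,
    adaptively carried) axis hint followed by two levels of local grid
    refinement.  Slices with no atoms within a slab are reported at the bulk
    cap.  vdW radii must be assigned.
    """
    if np.isnan(topology.radii).any():
        raise TopologyError("vdW radii are not assigned; read a parameter table")
    x = np.asarray(frame, dtype=float)
    if x.shape != (topology.n_atoms, 3):
        raise TopologyError("frame shape does not match topology")
    zs = np.arange(z_range[0], z_range[1] + 0.5 * dz, dz)
    radii = np.empty(len(zs))
    centers = np.empty((len(zs), 2))
    hint = np.asarray(axis_hint, dtype=float)
    slab = cap + float(topology.radii.max())
    for k, z in enumerate(zs):
        near = np.abs(x[:, 2] - z) <= slab
        if not near.any():
            radii[k] = cap
            centers[k] = hint
            continue
        xa, ra = x[near], topology.radii[near]
        best_c, best_r = hint, _slice_radius(xa, ra, hint, z)
        step, span = coarse_step, search_radius
        for _level in range(3):  # coarse grid, then 5x and 25x refinement
            g = np.arange(-span, span + 0.5 * step, step)
            gx, gy = np.meshgrid(g, g)
            cand = np.c_[gx.ravel(), gy.ravel()] + best_c
            d2 = ((xa[:, None, :2] - cand[None]) ** 2).sum(axis=2)
            d = np.sqrt(d2 + (xa[:, 2:3] - z) ** 2)
            rr = (d - ra[:, None]).min(axis=0)
            j = int(np.argmax(rr))
            # deterministic tie-break: smallest index of the max
            best_c, best_r = cand[j], float(rr[j])
            span, step = step, step / 5.0
        radii[k] = min(max(best_r, 0.0), cap)
        centers[k] = best_c
        hint = best_c  # carry the refined center to the next slice
    return PoreProfile(zs, radii, centers)


def _boundary_plane(traj: Trajectory, topology: Topology, resid: int,
                    atom_name: str = "CA") -> np.ndarray:
    mask = (topology.residue_numbers == resid) & (topology.names == atom_name)
    chains = set(topology.chain_ids[mask].tolist())
    if len(chains) < 4:
        raise SelectionError(
            f"boundary residue {resid} not present in all four chains")
    idx = np.nonzero(mask)[0]
    return traj.coordinates[:, idx].mean(axis=1)  # per-frame ring COM (x,y,z)


def count_pore_waters(traj: Trajectory, topology: Topology,
                      water_selection: Selection,
                      lower_residue: int = 312, upper_residue: int = 320,
                      lateral_radius: float = 10.0) -> TimeSeries:
    """Waters inside the inner pore cavity per frame.

    The cavity is bounded below by the COM of the lower boundary ring
    (L312 Cα by default), above by the plane through the COM of the upper
    ring (P320), and laterally by ``lateral_radius`` around the pore axis
    (the mean of the two ring centers).  Water positions are taken as the
    selected atoms (oxygens).
    """
    widx = water_selection.require_nonempty()
    lo = _boundary_plane(traj, topology, lower_residue)
    hi = _boundary_plane(traj, topology, upper_residue)
    counts = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        w = traj.coordinates[f, widx]
        axis_xy = 0.5 * (lo[f, :2] + hi[f, :2])
        in_z = (w[:, 2] >= lo[f, 2]) & (w[:, 2] <= hi[f, 2])
        lat = np.linalg.norm(w[:, :2] - axis_xy, axis=1) <= lateral_radius
        counts[f] = int((in_z & lat).sum())
    return TimeSeries(traj.times, counts, label="pore_waters")


# --------------------------------------------------------------------------- #
# permeation and conductance
# --------------------------------------------------------------------------- #


def unwrap_z(z: np.ndarray, box_z: np.ndarray) -> np.ndarray:
    """Remove periodic jumps from a per-frame z series (minimum image)."""
    z = np.asarray(z, dtype=float)
    dz = np.diff(z)
    shift = np.cumsum(np.round(dz / box_z[1:]) * box_z[1:])
    out = z.copy()
    out[1:] -= shift
    return out


def count_permeation_events(traj: Trajectory, ion_selection: Selection,
                            plane_lower: float, plane_upper: float,
                            direction: str = "both"
                            ) -> tuple[list[dict], int]:
    """Count full permeation events with a double-crossing criterion.

    An event is one ion excursion that enters below ``plane_lower`` and exits
    above ``plane_upper`` (or the reverse) without returning past its entry
    plane in between.  z-coordinates are unwrapped across periodic images
    before analysis, so an ion recycled by periodic boundaries counts once
    per physical crossing.
    """
    if not plane_lower < plane_upper:
        raise ValueError("plane_lower must be below plane_upper")
    half = traj.box[:, 2].min() / 2.0
    if abs(plane_lower) > half or abs(plane_upper) > half:
        raise ValueError("counting planes lie outside the box")
    if direction not in ("up", "down", "both"):
        raise ValueError("direction must be 'up', 'down' or 'both'")
    Lz = float(traj.box[0, 2])
    events: list[dict] = []
    for ion in ion_selection.require_nonempty():
        z = unwrap_z(traj.coordinates[:, ion, 2], traj.box[:, 2])
        # Along the unwrapped axis the counting region repeats every box
        # length: inside_m = [lower + m·Lz, upper + m·Lz], separated by gaps.
        # A completed event is a move from one gap to another; the number of
        # inside regions traversed is the number of full double crossings.
        last_gap: int | None = None
        for f in range(len(z)):
            m = np.floor((z[f] - plane_lower) / Lz)
            frac = z[f] - m * Lz  # in [plane_lower, plane_lower + Lz)
            if frac <= plane_upper:
                continue  # inside a counting region
            gap = int(m)  # gap above inside_m
            if last_gap is not None and gap != last_gap:
                step = 1 if gap > last_gap else -1
                for _ in range(abs(gap - last_gap)):
                    events.append({"ion": int(ion), "frame": f,
                                   "direction": "up" if step > 0 else "down"})
            last_gap = gap
    if direction != "both":
        events = [e for e in events if e["direction"] == direction]
    events.sort(key=lambda e: (e["frame"], e["ion"]))
    return events, len(events)


def estimate_conductance(event_count: int, duration_ns: float,
                         voltage_mV: float, charge_per_ion: float = 1.0
                         ) -> float:
    """Single-channel conductance g = N·q / (T·V) in picosiemens."""
    if duration_ns <= 0:
        raise ValueError("duration must be positive")
    if voltage_mV == 0:
        raise ValueError("voltage must be nonzero")
    e_C = 1.602176634e-19
    current_A = event_count * charge_per_ion * e_C / (duration_ns * 1e-9)
    return current_A / (voltage_mV * 1e-3) * 1e12


# --------------------------------------------------------------------------- #
# membrane and free-energy surfaces
# --------------------------------------------------------------------------- #


def membrane_thickness(traj: Trajectory, topology: Topology,
                       headgroup_selection: Selection) -> TimeSeries:
    """|mean z(upper leaflet) − mean z(lower leaflet)| per frame.

    Leaflets are split about the per-frame mean z of the headgroup selection,
    making the measure invariant under rigid translation of the system.
    """
    idx = headgroup_selection.require_nonempty()
    vals = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        z = traj.coordinates[f, idx, 2]
        center = z.mean()
        upper, lower = z[z > center], z[z <= center]
        if len(upper) == 0 or len(lower) == 0:
            raise SelectionError(
                "headgroup selection covers only one leaflet")
        vals[f] = abs(upper.mean() - lower.mean())
    return TimeSeries(traj.times, vals, label="membrane_thickness_A")


def free_energy_surface_2d(samples_xy: np.ndarray, temperature: float = 300.0,
                           bin_width: float = 0.5,
                           x_range: tuple[float, float] | None = None,
                           y_range: tuple[float, float] | None = None
                           ) -> FreeEnergySurface2D:
    """F(x, y) = −RT ln P(x, y), min-shifted to zero (empty bins +inf)."""
    xy = np.asarray(samples_xy, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2 or len(xy) == 0:
        raise ValueError("samples must be a non-empty (n, 2) array")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")

    def edges(vals, rng):
        lo, hi = rng if rng is not None else (vals.min(), vals.max())
        n = max(1, int(np.ceil((hi - lo) / bin_width)))
        return lo + np.arange(n + 1) * bin_width

    xe = edges(xy[:, 0], x_range)
    ye = edges(xy[:, 1], y_range)
    H, _, _ = np.histogram2d(xy[:, 0], xy[:, 1], bins=(xe, ye))
    P = H / H.sum()
    with np.errstate(divide="ignore"):
        F = -R_KCAL * temperature * np.log(P)
    F -= F[np.isfinite(F)].min()
    return FreeEnergySurface2D(xe, ye, F, temperature)
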