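"""Synthetic desk-scale systems with analytic ground truth.

Three generators stand in for multi-microsecond membrane-protein MD when
exercising the analysis stack end to end:

* :func:`sample_elastic_network` — i.i.d. Gaussian fluctuation frames drawn
  from the covariance implied by an anisotropic elastic network (spring
  Hessian pseudo-inverse at temperature T), optionally with a planted
  community structure.  The exact covariance used for sampling is returned so
  correlation/network estimators can be checked against ground truth.
* :func:`build_slab_system` — point charges in a membrane slab under a linear
  transmembrane potential.  Each charge's fractional electrical distance
  (the fraction of the applied voltage it senses) is known in closed form, so
  gating-charge recovery can be tested exactly.
* :func:`script_pore_trajectory` — scripted ion z(t) paths and pore-water
  placements with crossing counts and per-frame occupancies known by
  construction, for permeation and hydration counters.

All generators take explicit integer seeds and are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core import (KB_KCAL, Selection, Topology, Trajectory, TopologyError)

__all__ = [
    "ElasticNetworkSpec", "ElasticNetworkEnsemble", "sample_elastic_network",
    "SlabCharge", "SlabSystemSpec", "SlabSystem", "build_slab_system",
    "PoreScriptSpec", "PoreScriptResult", "script_pore_trajectory",
    "make_crossing_path", "make_retreating_path",
    "two_block_spec", "linear_chain_coordinates",
]


# --------------------------------------------------------------------------- #
# elastic network
# --------------------------------------------------------------------------- #


@dataclass
class ElasticNetworkSpec:
    """Anisotropic elastic network: Cα beads joined by Hookean springs.

    spring constants in kcal mol^-1 Å^-2, temperature in K.  The planted
    partition labels are carried through verbatim as community ground truth.
    """

    equilibrium_coordinates: np.ndarray  # (n, 3) Å
    springs: Sequence[tuple[int, int, float]]  # (i, j, k)
    temperature: float = 300.0
    planted_partition: dict[int, int] | None = None
    seed: int = 0
    box: tuple[float, float, float] = (200.0, 200.0, 200.0)

    def __post_init__(self) -> None:
        self.equilibrium_coordinates = np.asarray(
            self.equilibrium_coordinates, dtype=float)
        if self.equilibrium_coordinates.ndim != 2 or \
                self.equilibrium_coordinates.shape[1] != 3:
            raise ValueError("equilibrium_coordinates must be (n, 3)")

    @property
    def n_residues(self) -> int:
        return self.equilibrium_coordinates.shape[0]


@dataclass
class ElasticNetworkEnsemble:
    """Sampled trajectory plus the exact ground truth used to generate it."""

    topology: Topology
    trajectory: Trajectory
    covariance: np.ndarray          # (3n, 3n) Cartesian covariance, Å²
    residue_correlation: np.ndarray  # (n, n) normalized C_ij
    partition: dict[int, int] | None


def _anm_hessian(spec: ElasticNetworkSpec) -> np.ndarray:
    n = spec.n_residues
    H = np.zeros((3 * n, 3 * n))
    for i, j, k in spec.springs:
        if i == j:
            raise ValueError("self-spring")
        d = spec.equilibrium_coordinates[j] - spec.equilibrium_coordinates[i]
        r = np.linalg.norm(d)
        if r == 0:
            raise ValueError(f"coincident residues {i}, {j}")
        nvec = d / r
        K = k * np.outer(nvec, nvec)
        si, sj = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
        H[si, si] += K
        H[sj, sj] += K
        H[si, sj] -= K
        H[sj, si] -= K
    return H


def _check_connected(spec: ElasticNetworkSpec) -> None:
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(spec.n_residues))
    g.add_edges_from((i, j) for i, j, _ in spec.springs)
    if spec.n_residues and not nx.is_connected(g):
        raise ValueError("spring graph is disconnected")


def residue_correlation_from_covariance(cov: np.ndarray) -> np.ndarray:
    """Normalized residue-residue correlation from a 3n×3n Cartesian covariance.

    C_ij = tr(cov_ij) / sqrt(tr(cov_ii) tr(cov_jj)); the trace contracts the
    3×3 displacement-vector blocks to the scalar <Δr_i·Δr_j>.
    """
    n = cov.shape[0] // 3
    blocks = cov.reshape(n, 3, n, 3)
    inner = np.einsum("iaja->ij", blocks)
    diag = np.diag(inner).copy()
    if (diag <= 0).any():
        raise ValueError("zero-variance residue in covariance")
    return inner / np.sqrt(np.outer(diag, diag))


def _ca_topology(n: int, partition: dict[int, int] | None = None) -> Topology:
    return Topology(
        atom_ids=np.arange(1, n + 1),
        names=np.array(["CA"] * n, dtype=object),
        residue_numbers=np.arange(1, n + 1),
        residue_names=np.array(["GLY"] * n, dtype=object),
        chain_ids=np.array(["A"] * n, dtype=object),
        elements=np.array(["C"] * n, dtype=object),
        charges=np.zeros(n),
        radii=np.full(n, 1.7),
    )


def sample_elastic_network(spec: ElasticNetworkSpec,
                           n_frames: int) -> ElasticNetworkEnsemble:
    """Draw i.i.d. Gaussian frames from the elastic-network covariance.

    The covariance is k_B T times the pseudo-inverse of the spring Hessian,
    with rigid-body (zero-frequency) modes removed by a relative eigenvalue
    threshold — six modes for a generic 3-D network, fewer for degenerate
    geometries such as a single spring.  At T = 0 every frame equals the
    equilibrium coordinates.
    """
    _check_connected(spec)
    H = _anm_hessian(spec)
    w, v = np.linalg.eigh(H)
    tol = max(w.max(), 1.0) * 1e-10
    soft = w > tol
    kBT = KB_KCAL * spec.temperature
    inv_w = np.where(soft, 1.0 / np.where(soft, w, 1.0), 0.0)
    cov = kBT * (v * inv_w) @ v.T
    n = spec.n_residues
    rng = np.random.default_rng(spec.seed)
    if kBT == 0:
        disp = np.zeros((n_frames, 3 * n))
    else:
        z = rng.standard_normal((n_frames, int(soft.sum())))
        amp = np.sqrt(kBT * inv_w[soft])
        disp = (z * amp) @ v[:, soft].T
    coords = spec.equilibrium_coordinates[None] + disp.reshape(n_frames, n, 3)
    traj = Trajectory(coords, np.asarray(spec.box, dtype=float))
    corr = (residue_correlation_from_covariance(cov) if kBT > 0
            else np.eye(n))
    return ElasticNetworkEnsemble(
        topology=_ca_topology(n),
        trajectory=traj,
        covariance=cov,
        residue_correlation=corr,
        partition=dict(spec.planted_partition) if spec.planted_partition else None,
    )


def linear_chain_coordinates(n: int, spacing: float = 3.8) -> np.ndarray:
    """Cα positions of a straight chain along x (spacing in Å)."""
    xyz = np.zeros((n, 3))
    xyz[:, 0] = np.arange(n) * spacing
    return xyz


def two_block_spec(n_per_block: int = 12, k_intra: float = 5.0,
                   k_inter: float = 0.05, temperature: float = 300.0,
                   seed: int = 0) -> ElasticNetworkSpec:
    """Planted two-community elastic network: two densely sprung blocks
    joined by a single weak spring."""
    n = 2 * n_per_block
    rng = np.random.default_rng(seed)
    xyz = np.zeros((n, 3))
    xyz[:n_per_block] = rng.normal(scale=4.0, size=(n_per_block, 3))
    xyz[n_per_block:] = rng.normal(scale=4.0, size=(n_per_block, 3)) + \
        np.array([30.0, 0.0, 0.0])
    springs: list[tuple[int, int, float]] = []
    for block in (range(n_per_block), range(n_per_block, n)):
        ids = list(block)
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                springs.append((ids[a], ids[b], k_intra))
    springs.append((n_per_block - 1, n_per_block, k_inter))
    partition = {i: (0 if i < n_per_block else 1) for i in range(n)}
    return ElasticNetworkSpec(xyz, springs, temperature=temperature,
                              planted_partition=partition, seed=seed)


# --------------------------------------------------------------------------- #
# voltage slab
# --------------------------------------------------------------------------- #


@dataclass
class SlabCharge:
    """A point charge in the slab; mobile charges carry two positions."""

    q: float                       # e
    position: tuple[float, float, float]           # resting position, Å
    activated_position: tuple[float, float, float] | None = None

    def pos(self, state: str) -> np.ndarray:
        if state == "activated" and self.activated_position is not None:
            return np.asarray(self.activated_position, dtype=float)
        return np.asarray(self.position, dtype=float)


@dataclass
class SlabSystemSpec:
    """Membrane slab [z_lo, z_hi] under an applied voltage, with point charges.

    The transmembrane potential is the constant-field profile confined to the
    slab: 0 below z_lo, rising linearly to the full applied voltage at z_hi.
    """

    membrane_span: tuple[float, float]   # Å
    applied_voltage: float               # mV
    charges: Sequence[SlabCharge] = field(default_factory=list)
    box: tuple[float, float, float] = (60.0, 60.0, 120.0)

    def __post_init__(self) -> None:
        z_lo, z_hi = self.membrane_span
        if not z_lo < z_hi:
            raise ValueError("membrane_span must satisfy z_lo < z_hi")
        half = np.asarray(self.box) / 2.0
        for c in self.charges:
            for state in ("resting", "activated"):
                p = c.pos(state)
                if (np.abs(p) > half).any():
                    raise ValueError(f"charge at {p} outside box {self.box}")


@dataclass
class SlabSystem:
    """Built slab system with exact electrical distances per charge/state."""

    spec: SlabSystemSpec
    topology: Topology
    resting: Trajectory
    activated: Trajectory
    electrical_distance: dict[str, np.ndarray]  # state -> f per charge

    def fraction(self, z: float | np.ndarray) -> np.ndarray:
        """Analytic fraction of the applied potential at height z."""
        z_lo, z_hi = self.spec.membrane_span
        return np.clip((np.asarray(z, dtype=float) - z_lo) / (z_hi - z_lo),
                       0.0, 1.0)


def build_slab_system(spec: SlabSystemSpec) -> SlabSystem:
    """Materialise the slab: topology, one-frame state trajectories, exact f."""
    n = len(spec.charges)
    if n == 0:
        raise ValueError("slab system needs at least one charge")
    topo = Topology(
        atom_ids=np.arange(1, n + 1),
        names=np.array([f"Q{i + 1}" for i in range(n)], dtype=object),
        residue_numbers=np.arange(1, n + 1),
        residue_names=np.array(["CHG"] * n, dtype=object),
        chain_ids=np.array(["A"] * n, dtype=object),
        elements=np.array([""] * n, dtype=object),
        charges=np.array([c.q for c in spec.charges], dtype=float),
        radii=np.full(n, 2.0),
    )
    box = np.asarray(spec.box, dtype=float)
    rest = Trajectory(np.stack([c.pos("resting") for c in spec.charges])[None],
                      box)
    act = Trajectory(np.stack([c.pos("activated") for c in spec.charges])[None],
                     box)
    z_lo, z_hi = spec.membrane_span

    def f_of(state: str) -> np.ndarray:
        z = np.array([c.pos(state)[2] for c in spec.charges])
        return np.clip((z - z_lo) / (z_hi - z_lo), 0.0, 1.0)

    return SlabSystem(spec, topo, rest, act,
                      {"closed": f_of("resting"), "open": f_of("activated")})


# --------------------------------------------------------------------------- #
# scripted pore trajectories
# --------------------------------------------------------------------------- #


def make_crossing_path(n_frames: int, z_start: float, z_end: float) -> np.ndarray:
    """Monotone ion path from z_start to z_end (one full crossing when the
    endpoints bracket both counting planes)."""
    return np.linspace(z_start, z_end, n_frames)


def make_retreating_path(n_frames: int, z_start: float, z_peak: float) -> np.ndarray:
    """Ion path that advances to z_peak and retreats to its start (no crossing)."""
    half = n_frames // 2
    up = np.linspace(z_start, z_peak, half)
    down = np.linspace(z_peak, z_start, n_frames - half)
    return np.concatenate([up, down])


@dataclass
class PoreScriptSpec:
    """Scripted pore trajectory: waters and ions with known ground truth.

    ``ion_paths`` are per-ion z(t) arrays; ``expected_crossings`` records the
    crossing count each path was constructed to perform (ground truth by
    construction, never measured).  ``n_pore_waters`` may be an int or a
    per-frame sequence; that many water beads are placed inside the pore
    volume each frame, with ``n_bulk_waters`` more scattered outside it.
    """

    frames: int
    pore_z: tuple[float, float] = (-15.0, 5.0)
    pore_radius: float = 5.0
    n_pore_waters: int | Sequence[int] = 30
    n_bulk_waters: int = 20
    ion_paths: Sequence[np.ndarray] = field(default_factory=list)
    expected_crossings: int = 0
    box: tuple[float, float, float] = (60.0, 60.0, 100.0)
    wrap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for p in self.ion_paths:
            if len(p) != self.frames:
                raise ValueError("ion path length must equal frames")
        half_z = self.box[2] / 2.0
        if not self.wrap:
            for p in self.ion_paths:
                if (np.abs(np.asarray(p)) > half_z).any():
                    raise ValueError(
                        "ion path leaves the box along z; set wrap=True to "
                        "fold it through periodic images")


@dataclass
class PoreScriptResult:
    topology: Topology
    trajectory: Trajectory
    ground_truth_crossings: int
    ground_truth_pore_waters: np.ndarray  # per frame
    water_indices: np.ndarray
    ion_indices: np.ndarray
    boundary_lower_z: float
    boundary_upper_z: float

    def ground_truth_json(self) -> str:
        return json.dumps({
            "crossings": int(self.ground_truth_crossings),
            "pore_waters_per_frame": self.ground_truth_pore_waters.tolist(),
        })


def script_pore_trajectory(spec: PoreScriptSpec) -> PoreScriptResult:
    """Assemble the scripted system.

    The topology contains, in order: four LEU 312 CA beads (lower boundary
    ring), four PRO 320 CA beads (upper boundary ring), the water oxygens, and
    the ions — so the residue-based pore-water counter is exercisable exactly
    as on a real channel.
    """
    rng = np.random.default_rng(spec.seed)
    z_lo, z_hi = spec.pore_z
    n_ion = len(spec.ion_paths)
    occupancy = np.asarray(
        [spec.n_pore_waters] * spec.frames
        if np.isscalar(spec.n_pore_waters) else spec.n_pore_waters, dtype=int)
    if len(occupancy) != spec.frames:
        raise ValueError("per-frame water counts must match frames")
    n_wat = int(occupancy.max()) + spec.n_bulk_waters

    names, resnames, resids, chains, elements = [], [], [], [], []
    ring_coords = []
    ring_r = spec.pore_radius + 3.0
    for resid, z in ((312, z_lo), (320, z_hi)):
        for c, ang in zip("ABCD", np.arange(4) * np.pi / 2):
            names.append("CA")
            resnames.append("LEU" if resid == 312 else "PRO")
            resids.append(resid)
            chains.append(c)
            elements.append("C")
            ring_coords.append([ring_r * np.cos(ang), ring_r * np.sin(ang), z])
    for i in range(n_wat):
        names.append("OW")
        resnames.append("HOH")
        resids.append(1000 + i)
        chains.append("W")
        elements.append("O")
    for i in range(n_ion):
        names.append("K")
        resnames.append("K")
        resids.append(2000 + i)
        chains.append("I")
        elements.append("K")

    n_atoms = len(names)
    topo = Topology(
        atom_ids=np.arange(1, n_atoms + 1),
        names=np.array(names, dtype=object),
        residue_numbers=np.array(resids),
        residue_names=np.array(resnames, dtype=object),
        chain_ids=np.array(chains, dtype=object),
        elements=np.array(elements, dtype=object),
        charges=np.zeros(n_atoms),
        radii=np.full(n_atoms, 1.5),
    )

    coords = np.zeros((spec.frames, n_atoms, 3))
    coords[:, :8] = np.asarray(ring_coords)
    w0 = 8
    margin = 0.5
    box = np.asarray(spec.box, dtype=float)
    for f in range(spec.frames):
        k = occupancy[f]
        # in-pore waters: uniform in the counting cylinder (with margin)
        r = (spec.pore_radius - margin) * np.sqrt(rng.random(k))
        th = 2 * np.pi * rng.random(k)
        zz = rng.uniform(z_lo + margin, z_hi - margin, k)
        coords[f, w0:w0 + k] = np.c_[r * np.cos(th), r * np.sin(th), zz]
        # remaining waters: bulk, strictly above the upper boundary
        m = n_wat - k
        coords[f, w0 + k:w0 + n_wat] = np.c_[
            rng.uniform(-box[0] / 4, box[0] / 4, m),
            rng.uniform(-box[1] / 4, box[1] / 4, m),
            rng.uniform(z_hi + 5.0, box[2] / 2 - 2.0, m)]
    for i, path in enumerate(spec.ion_paths):
        z = np.asarray(path, dtype=float)
        if spec.wrap:
            z = (z + box[2] / 2.0) % box[2] - box[2] / 2.0
        coords[:, w0 + n_wat + i, 2] = z
    traj = Trajectory(coords, box)
    return PoreScriptResult(
        topology=topo, trajectory=traj,
        ground_truth_crossings=spec.expected_crossings,
        ground_truth_pore_waters=occupancy,
        water_indices=np.arange(w0, w0 + n_wat),
        ion_indices=np.arange(w0 + n_wat, w0 + n_wat + n_ion),
        boundary_lower_z=z_lo, boundary_upper_z=z_hi)
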