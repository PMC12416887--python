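"""Structure, trajectory and parameter I/O plus atom selection.

Coordinate conventions used throughout the package:

* distances in Å, times in ns, charges in elementary charge units (e);
* the membrane normal is +z with z = 0 at the membrane center and the
  extracellular side at positive z (activation moves S4 charges to larger z);
* residue numbering is the 1-based author numbering of the input PDB
  (human BK numbering); no internal renumbering is ever performed;
* only orthorhombic periodic boxes are supported.

PDB parsing/writing and the selection grammar are delegated to MDAnalysis;
the lightweight :class:`Topology`/:class:`Trajectory` containers defined here
are what every analysis routine consumes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("bkgating")

# --------------------------------------------------------------------------- #
# constants shared across modules
# --------------------------------------------------------------------------- #

#: Boltzmann constant, kcal mol^-1 K^-1
KB_KCAL = 1.987204259e-3
#: gas constant, kcal mol^-1 K^-1 (identical to KB_KCAL in molar units)
R_KCAL = KB_KCAL
#: 1 e·mV in kcal/mol (1 eV = 23.060548 kcal/mol)
E_MV_TO_KCAL = 23.060548e-3
#: Coulomb potential prefactor: potential of 1 e at 1 Å, in mV
E_PER_ANGSTROM_TO_MV = 14399.64548

#: Transmembrane helix spans (author numbering, inclusive) of the human BK
#: Core-MT construct.  S6 covers only the segment below the glycine hinge.
DEFAULT_HELICES: dict[str, tuple[int, int]] = {
    "S1": (109, 135),
    "S2": (148, 170),
    "S3": (181, 199),
    "S4": (205, 225),
    "S5": (230, 259),
    "S6": (313, 324),
}

#: Representative "charged group" atom per charged residue type: guanidinium
#: carbon for Arg, side-chain carboxyl carbon for Asp/Glu.
CHARGED_GROUP_ATOMS: dict[str, str] = {
    "ARG": "CZ",
    "ASP": "CG",
    "GLU": "CD",
    "LYS": "NZ",
    "HIS": "NE2",
}

_ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "K": 39.098, "CL": 35.45, "NA": 22.990, "": 0.0,
}


class ParseError(ValueError):
    """Raised for malformed structure / parameter files."""


class SelectionError(ValueError):
    """Raised for invalid selection expressions or misuse of empty selections."""


class TopologyError(ValueError):
    """Raised for inconsistent topologies (duplicate atoms, bad boxes ...)."""


# --------------------------------------------------------------------------- #
# domain types
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class Atom:
    """A single atom record (author numbering preserved)."""

    atom_id: int
    name: str
    residue_number: int
    residue_name: str
    chain_id: str
    element: str = ""
    partial_charge: float = 0.0
    vdw_radius: float = float("nan")


@dataclass
class Topology:
    """Ordered atom table plus helix and charged-group conventions.

    Parallel numpy arrays are the primary storage; :meth:`atoms` materialises
    :class:`Atom` records on demand.
    """

    atom_ids: np.ndarray
    names: np.ndarray
    residue_numbers: np.ndarray
    residue_names: np.ndarray
    chain_ids: np.ndarray
    elements: np.ndarray
    charges: np.ndarray
    radii: np.ndarray
    helix_definitions: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_HELICES)
    )
    charged_group_atoms: dict[str, str] = field(
        default_factory=lambda: dict(CHARGED_GROUP_ATOMS)
    )

    def __post_init__(self) -> None:
        n = len(self.names)
        for arr in (self.atom_ids, self.residue_numbers, self.residue_names,
                    self.chain_ids, self.elements, self.charges, self.radii):
            if len(arr) != n:
                raise TopologyError("topology arrays have inconsistent lengths")
        keys = list(zip(self.residue_numbers.tolist(), self.chain_ids.tolist(),
                        self.names.tolist()))
        if len(set(keys)) != n:
            seen, dups = set(), []
            for k in keys:
                if k in seen:
                    dups.append(k)
                seen.add(k)
            raise TopologyError(f"duplicate atom keys (resid, chain, name): {dups[:5]}")
        self._universe = None  # lazy MDAnalysis Universe for selections

    def __len__(self) -> int:
        return len(self.names)

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def atoms(self) -> list[Atom]:
        return [
            Atom(int(self.atom_ids[i]), str(self.names[i]),
                 int(self.residue_numbers[i]), str(self.residue_names[i]),
                 str(self.chain_ids[i]), str(self.elements[i]),
                 float(self.charges[i]), float(self.radii[i]))
            for i in range(self.n_atoms)
        ]

    @property
    def masses(self) -> np.ndarray:
        """Atomic masses from a small element table (0 for unknown elements)."""
        return np.array([_ELEMENT_MASSES.get(str(e).upper(), 0.0)
                         for e in self.elements])

    def heavy_mask(self) -> np.ndarray:
        """Boolean mask excluding hydrogens (by element, falling back to name)."""
        out = np.ones(self.n_atoms, dtype=bool)
        for i in range(self.n_atoms):
            el = str(self.elements[i]).strip().upper()
            if el == "H" or (el == "" and str(self.names[i]).lstrip("0123456789").upper().startswith("H")):
                out[i] = False
        return out

    def charged_group_index(self, residue_number: int, chain_id: str) -> int:
        """Index of the representative charged-group atom of one residue."""
        mask = (self.residue_numbers == residue_number) & (self.chain_ids == chain_id)
        if not mask.any():
            raise SelectionError(
                f"residue {residue_number} chain {chain_id} not in topology")
        resname = str(self.residue_names[mask][0]).upper()
        if resname not in self.charged_group_atoms:
            raise SelectionError(
                f"residue {residue_number} ({resname}) has no charged-group convention")
        want = self.charged_group_atoms[resname]
        idx = np.nonzero(mask & (self.names == want))[0]
        if len(idx) == 0:
            raise SelectionError(
                f"residue {residue_number} chain {chain_id}: representative atom "
                f"{want} missing")
        return int(idx[0])

    # -- MDAnalysis bridge ----------------------------------------------------

    def to_universe(self, coordinates: np.ndarray | None = None,
                    box: np.ndarray | None = None):
        """Build an MDAnalysis Universe mirroring this topology."""
        import MDAnalysis as mda

        n = self.n_atoms
        # residues defined by (chain, resid) runs in atom order
        res_keys: list[tuple[str, int]] = []
        atom_resindex = np.empty(n, dtype=int)
        for i in range(n):
            key = (str(self.chain_ids[i]), int(self.residue_numbers[i]))
            if not res_keys or res_keys[-1] != key:
                res_keys.append(key)
            atom_resindex[i] = len(res_keys) - 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe.empty(
                n, n_residues=len(res_keys), atom_resindex=atom_resindex,
                residue_segindex=np.zeros(len(res_keys), dtype=int),
                trajectory=True)
            u.add_TopologyAttr("name", self.names.tolist())
            u.add_TopologyAttr("resid", [k[1] for k in res_keys])
            resnames = []
            for i, k in enumerate(res_keys):
                first = int(np.nonzero(atom_resindex == i)[0][0])
                resnames.append(str(self.residue_names[first]))
            u.add_TopologyAttr("resname", resnames)
            u.add_TopologyAttr("chainIDs", [str(c) for c in self.chain_ids])
            u.add_TopologyAttr("elements", [str(e) for e in self.elements])
            u.add_TopologyAttr("id", [int(i) for i in self.atom_ids])
            u.add_TopologyAttr("occupancies", np.ones(n))
            u.add_TopologyAttr("tempfactors", np.zeros(n))
        if coordinates is not None:
            u.atoms.positions = np.asarray(coordinates, dtype=np.float64)
        if box is not None:
            u.dimensions = [float(box[0]), float(box[1]), float(box[2]),
                            90.0, 90.0, 90.0]
        return u

    def _selection_universe(self):
        if self._universe is None:
            self._universe = self.to_universe(
                coordinates=np.zeros((self.n_atoms, 3)))
        return self._universe


@dataclass
class Trajectory:
    """Cartesian coordinate frames over an orthorhombic periodic box.

    coordinates: (n_frames, n_atoms, 3) in Å; box: (n_frames, 3) box edge
    lengths in Å; time_step: ns between stored frames.
    """

    coordinates: np.ndarray
    box: np.ndarray
    time_step: float = 1.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise TopologyError("coordinates must have shape (n_frames, n_atoms, 3)")
        self.box = np.asarray(self.box, dtype=float)
        if self.box.ndim == 1:
            self.box = np.tile(self.box, (self.n_frames, 1))
        if self.box.shape != (self.n_frames, 3):
            raise TopologyError("box must have shape (n_frames, 3)")
        if not (self.box > 0).all():
            raise TopologyError("box lengths must be positive")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.time_step

    def check_compatible(self, topology: Topology) -> None:
        if self.n_atoms != topology.n_atoms:
            raise TopologyError(
                f"trajectory has {self.n_atoms} atoms but topology has "
                f"{topology.n_atoms}")


@dataclass
class Selection:
    """A resolved atom selection (strictly increasing indices)."""

    expression: str
    resolved_indices: np.ndarray

    def __post_init__(self) -> None:
        self.resolved_indices = np.asarray(self.resolved_indices, dtype=int)
        if len(self.resolved_indices) > 1 and not (
                np.diff(self.resolved_indices) > 0).all():
            raise SelectionError("selection indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.resolved_indices)

    def require_nonempty(self) -> np.ndarray:
        if len(self.resolved_indices) == 0:
            raise SelectionError(f"selection {self.expression!r} matched no atoms")
        return self.resolved_indices


# --------------------------------------------------------------------------- #
# operations
# --------------------------------------------------------------------------- #


def _check_orthorhombic(dimensions) -> np.ndarray | None:
    if dimensions is None:
        return None
    dims = np.asarray(dimensions, dtype=float)
    if not np.all(dims[:3] > 0):
        return None
    if not np.allclose(dims[3:6], 90.0, atol=1e-3):
        raise TopologyError(
            f"triclinic boxes are unsupported (angles {dims[3:6]})")
    return dims[:3]


def _topology_from_universe(u) -> Topology:
    atoms = u.atoms
    n = len(atoms)

    def _attr(name, default):
        try:
            return np.asarray(getattr(atoms, name)).astype(object)
        except Exception:
            return np.array([default] * n, dtype=object)

    elements = _attr("elements", "")
    if (elements == "").all():
        # fall back to the PDB convention: element = first alphabetic character
        elements = np.array(
            [str(nm).lstrip("0123456789")[:1].upper() for nm in atoms.names],
            dtype=object)
    chain = _attr("chainIDs", "")
    if (chain == "").all():
        chain = _attr("segids", "A")
    return Topology(
        atom_ids=np.asarray(_attr("ids", 0), dtype=int) if hasattr(atoms, "ids")
        else np.arange(1, n + 1),
        names=np.asarray(atoms.names, dtype=object),
        residue_numbers=np.asarray(atoms.resids, dtype=int),
        residue_names=np.asarray(atoms.resnames, dtype=object),
        chain_ids=np.asarray(chain, dtype=object),
        elements=np.asarray(elements, dtype=object),
        charges=np.zeros(n),
        radii=np.full(n, np.nan),
    )


def read_structure(path: str) -> tuple[Topology, Trajectory]:
    """Read a PDB file into a Topology plus its (single-frame) Trajectory.

    Author residue numbers, chain identifiers and coordinates are preserved
    exactly as stored; partial charges and vdW radii are left unassigned until
    :func:`read_parameter_table` supplies them.
    """
    import MDAnalysis as mda

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(path)
    except Exception as exc:  # noqa: BLE001 - surface parser context
        raise ParseError(f"failed to parse {path!r}: {exc}") from exc
    topo = _topology_from_universe(u)
    box = _check_orthorhombic(u.dimensions)
    coords = np.asarray(u.atoms.positions, dtype=float)[None, :, :]
    boxes = box[None, :] if box is not None else np.full((1, 3), np.nan)
    if np.isnan(boxes).any():
        boxes = np.full((1, 3), 1.0)  # placeholder; caller may override
    return topo, Trajectory(coords, boxes)


def read_trajectory(path: str, topology: Topology | None = None,
                    box: Sequence[float] | None = None,
                    time_step: float = 1.0) -> Trajectory:
    """Read a multi-model PDB (or any MDAnalysis-readable trajectory).

    The per-frame box is taken from the file when present, otherwise from the
    ``box`` argument.
    """
    import MDAnalysis as mda

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(path)
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"failed to parse {path!r}: {exc}") from exc
    if topology is not None and len(u.atoms) != topology.n_atoms:
        raise TopologyError(
            f"trajectory {path!r} has {len(u.atoms)} atoms but topology has "
            f"{topology.n_atoms}")
    frames, boxes = [], []
    for _ in u.trajectory:
        frames.append(np.asarray(u.atoms.positions, dtype=float))
        dims = _check_orthorhombic(u.dimensions)
        if dims is not None:
            boxes.append(dims)
        elif box is not None:
            boxes.append(np.asarray(box, dtype=float))
        else:
            raise TopologyError(
                f"{path!r} stores no box information; pass box= explicitly")
    return Trajectory(np.stack(frames), np.stack(boxes), time_step=time_step)


def write_structure(path: str, topology: Topology, trajectory: Trajectory) -> None:
    """Write a Topology + Trajectory as a (multi-model if >1 frame) PDB."""
    import MDAnalysis as mda

    trajectory.check_compatible(topology)
    u = topology.to_universe(coordinates=trajectory.coordinates[0],
                             box=trajectory.box[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(path, multiframe=trajectory.n_frames > 1,
                        n_atoms=topology.n_atoms) as w:
            for f in range(trajectory.n_frames):
                u.atoms.positions = trajectory.coordinates[f]
                u.dimensions = list(trajectory.box[f]) + [90.0, 90.0, 90.0]
                w.write(u.atoms)


write_trajectory = write_structure  # same contract; name for symmetry


def read_parameter_table(path: str, topology: Topology) -> Topology:
    """Assign partial charges and vdW radii from a CSV parameter table.

    The table has header ``residue,atom,charge_e,radius_A`` and is matched by
    (residue_name, atom_name); a ``*`` residue row is a wildcard.  Matching is
    first-match-wins in file order; rows shadowed by an earlier identical key
    are reported with a warning.  Atoms with no matching row raise
    :class:`ParseError` listing them.
    """
    table = pd.read_csv(path, skipinitialspace=True)
    required = {"residue", "atom", "charge_e", "radius_A"}
    if not required.issubset(table.columns):
        raise ParseError(
            f"parameter table must have columns {sorted(required)}, "
            f"got {list(table.columns)}")
    rules: dict[tuple[str, str], tuple[float, float]] = {}
    for _, row in table.iterrows():
        key = (str(row["residue"]).strip().upper(), str(row["atom"]).strip().upper())
        if key in rules:
            logger.warning("parameter row shadowed (first match wins): %s", key)
            continue
        rules[key] = (float(row["charge_e"]), float(row["radius_A"]))
    charges = np.zeros(topology.n_atoms)
    radii = np.full(topology.n_atoms, np.nan)
    missing = []
    for i in range(topology.n_atoms):
        rn = str(topology.residue_names[i]).upper()
        an = str(topology.names[i]).upper()
        hit = rules.get((rn, an)) or rules.get(("*", an))
        if hit is None:
            missing.append(f"{rn} {an}")
            continue
        charges[i], radii[i] = hit
        if radii[i] <= 0:
            raise ParseError(f"non-positive vdW radius for {rn} {an}")
    if missing:
        raise ParseError(
            "atoms with no matching parameter row: "
            + ", ".join(sorted(set(missing))))
    topology.charges = charges
    topology.radii = radii
    return topology


def select(topology: Topology, expression: str) -> Selection:
    """Resolve a selection expression against a topology.

    The grammar is MDAnalysis's: residue ranges (``resid 205-225``), atom
    names (``name CA``), chains (``chainID A``) and ``and``/``or``/``not``
    combinations.  The result is deterministic and order-preserving; an empty
    result is legal here and only errors at use sites.
    """
    import MDAnalysis.exceptions as mde

    u = topology._selection_universe()
    try:
        group = u.select_atoms(expression)
    except (mde.SelectionError, Exception) as exc:  # noqa: BLE001
        raise SelectionError(
            f"invalid selection {expression!r}: {exc}") from exc
    return Selection(expression, np.sort(group.indices.astype(int)))
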