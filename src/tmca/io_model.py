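"""Topology/trajectory data model and periodic-distance primitives.

File parsing is delegated to MDAnalysis; this module wraps the results in
small immutable containers so that downstream analyses operate on plain
NumPy arrays with coordinates in Å and orthorhombic periodic boxes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import MDAnalysis as mda
from MDAnalysis.lib import distances as mdadist

__all__ = [
    "Topology",
    "Trajectory",
    "Selection",
    "TopologyError",
    "ResolutionError",
    "load_topology",
    "load_trajectory",
    "select",
    "pairwise_min_image_distance",
    "write_multimodel_pdb",
    "write_xtc",
]

# Masses in Da; BB covers MARTINI-style coarse-grained backbone beads.
_ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "BB": 72.0,
}


class TopologyError(ValueError):
    """Raised for malformed or inconsistent structural input."""


class ResolutionError(TypeError):
    """Raised when an analysis needs atoms the input resolution lacks
    (e.g. hydrogen-bond geometry on a coarse-grained backbone-bead model)."""


def _infer_element(name: str) -> str:
    """Element from an atom name (protein/CG naming conventions).

    Backbone beads ('BB') are kept as their own pseudo-element so that
    resolution checks can distinguish coarse-grained input.
    """
    if name.upper() in ("BB", "SC1", "SC2", "SC3", "SC4"):
        return "BB"
    stripped = name.lstrip("0123456789")
    if not stripped:
        raise TopologyError(f"cannot infer element from atom name {name!r}")
    first = stripped[0].upper()
    if first in "HCNOSP":
        return first
    return stripped[:2].capitalize()


@dataclass(frozen=True)
class Topology:
    """Atom-level description of the system.

    Residue numbering is taken verbatim from the input file (author
    numbering such as K186 or D50) and never renumbered.
    """

    atom_ids: np.ndarray          # (N,) int, unique, ascending
    atom_names: np.ndarray        # (N,) str
    elements: np.ndarray          # (N,) str
    residue_ids: np.ndarray       # (N,) int, author numbering
    residue_names: np.ndarray     # (N,) 3-letter str
    chain_ids: np.ndarray         # (N,) str
    masses: np.ndarray            # (N,) float, Da
    _universe: mda.Universe = field(repr=False, compare=False)

    def __post_init__(self):
        ids = self.atom_ids
        if len(ids) == 0:
            raise TopologyError("topology contains zero atoms")
        if len(np.unique(ids)) != len(ids) or np.any(np.diff(ids) <= 0):
            raise TopologyError("atom_ids must be unique and ascending")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_ids)

    @property
    def chains(self) -> list[str]:
        """Distinct chain identifiers in file order."""
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(str(c), None)
        return list(seen)

    def residue_keys(self, indices: np.ndarray | None = None) -> list[tuple[str, int]]:
        """Ordered distinct (chain_id, residue_id) pairs for the given atoms."""
        idx = np.arange(self.n_atoms) if indices is None else np.asarray(indices)
        seen: dict[tuple[str, int], None] = {}
        for i in idx:
            seen.setdefault((str(self.chain_ids[i]), int(self.residue_ids[i])), None)
        return list(seen)


@dataclass(frozen=True)
class Trajectory:
    """Ordered coordinate frames with per-frame orthorhombic box and time.

    Coordinates are in Å; times in ns; box lengths (Lx, Ly, Lz) in Å.
    """

    coordinates: np.ndarray   # (T, N, 3) float
    box: np.ndarray           # (T, 3) float, Å
    times: np.ndarray         # (T,) float, ns

    def __post_init__(self):
        c, b, t = self.coordinates, self.box, self.times
        if c.ndim != 3 or c.shape[2] != 3:
            raise ValueError("coordinates must have shape (T, N, 3)")
        if b.shape != (c.shape[0], 3):
            raise ValueError("box must have shape (T, 3)")
        if np.any(b <= 0):
            raise ValueError("box lengths must be strictly positive")
        if t.shape != (c.shape[0],) or np.any(np.diff(t) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def __iter__(self):
        for i in range(self.n_frames):
            yield self.coordinates[i]


@dataclass(frozen=True)
class Selection:
    """A set of atom indices plus the expression that produced it."""

    indices: np.ndarray       # positional indices into the Topology
    expression: str

    def __len__(self) -> int:
        return len(self.indices)


# ---------------------------------------------------------------------------
# loading

def _check_orthorhombic(dimensions) -> None:
    if dimensions is None:
        return
    angles = np.asarray(dimensions[3:6], dtype=float)
    if np.any(np.abs(angles - 90.0) > 1e-3):
        raise TopologyError(
            "only orthorhombic periodic boxes are supported; "
            f"got box angles {angles}"
        )


def _assign_chains(universe: mda.Universe) -> np.ndarray:
    """Chain id per atom: use the file's chain/segment field when present;
    otherwise split chains where the residue numbering restarts (common for
    GRO/coarse-grained files that carry no chain record)."""
    atoms = universe.atoms
    raw = None
    if hasattr(atoms, "chainIDs"):
        raw = np.asarray(atoms.chainIDs, dtype=str)
    if raw is None or np.all((raw == "") | (raw == " ")):
        segids = np.asarray(atoms.segids, dtype=str)
        blank = {"", " ", "SYSTEM", "seg_0_SYSTEM"}
        if not np.all(np.isin(segids, list(blank))) and len(set(segids)) > 1:
            raw = segids
    if raw is not None and not np.all((raw == "") | (raw == " ")):
        return raw
    # residue-number restart heuristic
    resids = np.asarray(atoms.resids)
    labels = np.empty(len(resids), dtype="U4")
    chain = 0
    labels[0] = chr(ord("A"))
    for i in range(1, len(resids)):
        if resids[i] < resids[i - 1]:
            chain += 1
        labels[i] = chr(ord("A") + chain)
    return labels


def topology_from_universe(universe: mda.Universe) -> Topology:
    """Build the package Topology from an MDAnalysis Universe."""
    atoms = universe.atoms
    if len(atoms) == 0:
        raise TopologyError("input contains zero atoms")
    names = np.asarray(atoms.names, dtype=str)
    if hasattr(atoms, "elements") and not np.all(np.asarray(atoms.elements) == ""):
        elements = np.asarray([e if e else _infer_element(n)
                               for e, n in zip(atoms.elements, names)], dtype=str)
    else:
        elements = np.asarray([_infer_element(n) for n in names], dtype=str)
    chain_ids = _assign_chains(universe)
    masses = np.asarray([_ELEMENT_MASSES.get(e, 12.011) for e in elements])
    # make selection-by-element and chain selections work downstream
    for attr, values in (("elements", elements), ("chainIDs", chain_ids),
                         ("masses", masses)):
        if hasattr(atoms, attr):
            setattr(atoms, attr, values)
        else:
            universe.add_TopologyAttr(attr, values)
    return Topology(
        atom_ids=np.arange(1, len(atoms) + 1),
        atom_names=names,
        elements=elements,
        residue_ids=np.asarray(atoms.resids, dtype=int),
        residue_names=np.asarray(atoms.resnames, dtype=str),
        chain_ids=np.asarray(chain_ids, dtype=str),
        masses=masses,
        _universe=universe,
    )


def load_topology(path: str | Path, format: str | None = None) -> Topology:
    """Load a PDB or GRO topology.

    GRO coordinates (nm) are converted to Å on read by the backend; all
    coordinates in this package are Å.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("pdb", "gro"):
        raise ValueError(f"unsupported topology format {fmt!r} (use pdb or gro)")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            universe = mda.Universe(str(path), format=fmt)
    except Exception as exc:  # noqa: BLE001 - reraise with context
        raise TopologyError(f"could not parse {path} as {fmt}: {exc}") from exc
    _check_orthorhombic(universe.dimensions)
    return topology_from_universe(universe)


def load_trajectory(
    top: Topology,
    paths: str | Path | Sequence[str | Path],
    format: str | None = None,
    default_box: tuple[float, float, float] | None = None,
    time_unit_ns: float = 1e-3,
) -> Trajectory:
    """Load coordinate frames (XTC/DCD/TRR/multi-model PDB) against ``top``.

    Multiple files are concatenated in the given order; frame times are made
    strictly increasing across file boundaries by offsetting each file by the
    end time of the previous one. ``time_unit_ns`` converts the reader's
    native time unit (ps for the supported formats) to ns.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    paths = [str(p) for p in paths]
    for p in paths:
        if not Path(p).exists():
            raise FileNotFoundError(p)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            universe = mda.Universe(top._universe._topology, paths, format=format)
    except ValueError as exc:
        raise TopologyError(
            f"trajectory does not match topology ({top.n_atoms} atoms): {exc}"
        ) from exc
    if len(universe.atoms) != top.n_atoms:
        raise TopologyError(
            f"trajectory atom count {len(universe.atoms)} does not match "
            f"topology atom count {top.n_atoms}"
        )
    coords, boxes, times = [], [], []
    prev_t = -np.inf
    offset = 0.0
    warnings.filterwarnings("ignore", message="Reader has no dt information")
    for ts in universe.trajectory:
        _check_orthorhombic(ts.dimensions)
        coords.append(ts.positions.astype(np.float64).copy())
        top_dims = top._universe.dimensions
        if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
            boxes.append(np.asarray(ts.dimensions[:3], dtype=float))
        elif default_box is not None:
            boxes.append(np.asarray(default_box, dtype=float))
        elif top_dims is not None and np.all(top_dims[:3] > 0):
            # multi-model PDB carries one CRYST1 record; fall back to it
            boxes.append(np.asarray(top_dims[:3], dtype=float))
        else:
            raise TopologyError("frame has no box dimensions and no default_box given")
        t = float(ts.time) * time_unit_ns
        if t + offset <= prev_t:  # concatenated file restarting its clock
            offset = prev_t + time_unit_ns - t
        prev_t = t + offset
        times.append(prev_t)
    return Trajectory(
        coordinates=np.asarray(coords),
        box=np.asarray(boxes),
        times=np.asarray(times),
    )


# ---------------------------------------------------------------------------
# selections

_ALIASES = {"chain ": "chainID "}


def select(top: Topology, expression: str) -> Selection:
    """Resolve an atom selection expression against a topology.

    The grammar is MDAnalysis's selection language (by chain, residue id
    ranges, residue name, atom name, element, with and/or/not), with
    ``chain X`` accepted as an alias for ``chainID X``.
    """
    expr = expression
    for alias, repl in _ALIASES.items():
        expr = expr.replace(alias, repl)
    try:
        group = top._universe.select_atoms(expr)
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"selection parse error in {expression!r}: {exc}") from exc
    if len(group) == 0:
        warnings.warn(f"selection {expression!r} matched no atoms", stacklevel=2)
    return Selection(indices=group.ix.astype(int), expression=expression)


def selection_from_indices(indices: Iterable[int], label: str = "<indices>") -> Selection:
    return Selection(indices=np.asarray(sorted(indices), dtype=int), expression=label)


# ---------------------------------------------------------------------------
# distances

def pairwise_min_image_distance(
    coords_a: np.ndarray, coords_b: np.ndarray, box: Sequence[float]
) -> np.ndarray:
    """M×K minimum-image Euclidean distances under orthorhombic periodicity."""
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box lengths must be positive")
    dims = np.array([box[0], box[1], box[2], 90.0, 90.0, 90.0])
    a = np.ascontiguousarray(np.asarray(coords_a, dtype=np.float32).reshape(-1, 3))
    b = np.ascontiguousarray(np.asarray(coords_b, dtype=np.float32).reshape(-1, 3))
    return mdadist.distance_array(a, b, box=dims).astype(float)


def min_image_displacement(
    vec: np.ndarray, box: Sequence[float], axes: slice | Sequence[int] = slice(None)
) -> np.ndarray:
    """Wrap displacement components into [-L/2, L/2) along the given axes."""
    vec = np.array(vec, dtype=float)
    box = np.asarray(box, dtype=float)
    idx = np.arange(3)[axes] if isinstance(axes, slice) else np.asarray(axes)
    for ax in idx:
        L = box[ax]
        vec[..., ax] -= L * np.round(vec[..., ax] / L)
    return vec


# ---------------------------------------------------------------------------
# writers (used by the synthetic generator)

def _universe_with_frames(top: Topology, traj: Trajectory) -> mda.Universe:
    u = top._universe
    u.load_new(
        traj.coordinates.astype(np.float32),
        format="memory",
        dimensions=np.hstack([traj.box, np.full((traj.n_frames, 3), 90.0)]),
    )
    return u


def write_multimodel_pdb(top: Topology, traj: Trajectory, path: str | Path) -> None:
    u = _universe_with_frames(top, traj)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), multiframe=True, n_atoms=top.n_atoms) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


def write_pdb(top: Topology, coordinates: np.ndarray,
              box: Sequence[float], path: str | Path) -> None:
    """Write a single-frame PDB (topology + reference coordinates)."""
    u = top._universe
    u.load_new(
        coordinates.astype(np.float32)[None, :, :],
        format="memory",
        dimensions=np.array([[box[0], box[1], box[2], 90.0, 90.0, 90.0]]),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_gro(top: Topology, coordinates: np.ndarray,
              box: Sequence[float], path: str | Path) -> None:
    """Write a single-frame GRO file (coordinates converted to nm by the
    backend)."""
    u = top._universe
    u.load_new(
        coordinates.astype(np.float32)[None, :, :],
        format="memory",
        dimensions=np.array([[box[0], box[1], box[2], 90.0, 90.0, 90.0]]),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_xtc(top: Topology, traj: Trajectory, path: str | Path) -> None:
    u = _universe_with_frames(top, traj)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=top.n_atoms) as w:
            for i, _ in enumerate(u.trajectory):
                u.trajectory.ts.time = traj.times[i] * 1e3  # ns -> ps
                w.write(u.atoms)
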