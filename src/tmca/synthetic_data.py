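"""Ground-truth-labeled synthetic helix-bundle trajectories.

Emulates the statistical structure of a three-helix transmembrane complex
(one receptor helix + an adaptor dimer) so every analysis stage is testable
without MD data: ideal α-helices in a slab geometry, metastable
conformational states with Markov switching, planted residue–residue
interaction geometries on deterministic occupancy schedules, isotropic
positional jitter, and a dissociation scenario in which the receptor helix
translates laterally, sinks along the membrane normal, and tilts toward
horizontal while the adaptor dimer stays vertical.

Two resolutions are emitted:

* ``cg`` — one backbone bead (``BB``) per residue, the coarse-grained
  analogue of Cα, for contact/positioning/clustering analyses;
* ``aa-lite`` — backbone N/H/CA/C/O plus the named side-chain pseudo-atoms
  the geometric classifiers read (Lys NZ+HZ*, Arg NE/NH1/NH2, Asp OD1/OD2,
  Glu OE1/OE2, aromatic ring atoms, side-chain carbons). Full rotamers are
  not modelled: every classifier is a distance/angle rule over named atoms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import MDAnalysis as mda

from .io_model import Topology, Trajectory, topology_from_universe

__all__ = [
    "StateSpec",
    "PlantedInteraction",
    "SyntheticSpec",
    "GroundTruth",
    "build_ideal_helix",
    "simulate",
    "dissociation_scenario",
    "interaction_showcase",
    "clustering_scenario",
    "contact_schedule_scenario",
    "schedule_categories",
]

AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# default three-helix system: receptor-like TM helix (author numbering
# 181–219, with K186 / W194 / E202 motif positions) and two identical
# adaptor-like helices (41–75, with D50 / Y62 / R66)
DEFAULT_SEQUENCES = (
    "LVAILKLAVLFIAWLVAILVLEAILVALIVALIVALIVL",   # chain A, resid 181..219
    "VILAVLIAVDLAVILAVLIAVYLAIRLVAILVAIL",        # chain B, resid 41..75
    "VILAVLIAVDLAVILAVLIAVYLAIRLVAILVAIL",        # chain C, resid 41..75
)
DEFAULT_FIRST_RESIDS = (181, 41, 41)


# ---------------------------------------------------------------------------
# side-chain templates
#
# offsets are expressed in a per-residue local frame (u_r radially out of the
# helix, u_t tangential, z along the helix axis); only names and rough
# geometry matter for the classifiers.

def _chain(names: Sequence[str], step: float = 1.3, start: float = 1.5):
    return [(n, (start + step * i, 0.0, 0.15 * (i % 2))) for i, n in enumerate(names)]


def _ring_template_6(start_x: float) -> list[tuple[str, tuple[float, float, float]]]:
    """Benzene ring (Phe/Tyr naming) in the (u_r, z) plane, CG nearest CA."""
    c = start_x + 1.39
    pts = {
        "CG": 180.0, "CD1": 120.0, "CE1": 60.0, "CZ": 0.0, "CE2": -60.0, "CD2": -120.0,
    }
    return [(n, (c + 1.39 * np.cos(np.radians(a)), 0.0, 1.39 * np.sin(np.radians(a))))
            for n, a in pts.items()]


def _ring_template_his(start_x: float):
    c = start_x + 1.16
    pts = {"CG": 180.0, "ND1": 108.0, "CE1": 36.0, "NE2": -36.0, "CD2": -108.0}
    return [(n, (c + 1.16 * np.cos(np.radians(a)), 0.0, 1.16 * np.sin(np.radians(a))))
            for n, a in pts.items()]


def _ring_template_trp(start_x: float):
    """Fused 5–6 indole ring in the (u_r, z) plane."""
    c5 = np.array([start_x + 1.16, 0.0])
    five = {"CG": 180.0, "CD1": 108.0, "NE1": 36.0, "CE2": -36.0, "CD2": -108.0}
    pos = {n: c5 + 1.16 * np.array([np.cos(np.radians(a)), np.sin(np.radians(a))])
           for n, a in five.items()}
    # hexagon fused on the CD2–CE2 edge, extending away from the 5-ring
    e2, d2 = pos["CE2"], pos["CD2"]
    mid = 0.5 * (e2 + d2)
    edge = d2 - e2
    perp = np.array([edge[1], -edge[0]])
    perp /= np.linalg.norm(perp)
    if np.dot(perp, mid - c5) < 0:
        perp = -perp
    r6 = np.linalg.norm(edge)
    c6 = mid + perp * (r6 * np.sqrt(3) / 2)
    ang_e2 = np.arctan2(*(e2 - c6)[::-1])
    for k, name in enumerate(["CZ2", "CH2", "CZ3", "CE3"], start=1):
        a = ang_e2 - k * np.pi / 3
        pos[name] = c6 + r6 * np.array([np.cos(a), np.sin(a)])
    return [(n, (p[0], 0.0, p[1])) for n, p in pos.items()]


def _sidechain_template(res1: str) -> list[tuple[str, tuple[float, float, float]]]:
    t: list[tuple[str, tuple[float, float, float]]] = []
    if res1 == "G":
        return t
    t.append(("CB", (1.5, 0.0, 0.0)))
    if res1 == "A":
        pass
    elif res1 == "V":
        t += [("CG1", (2.6, 0.8, 0.2)), ("CG2", (2.6, -0.8, 0.2))]
    elif res1 == "L":
        t += [("CG", (2.8, 0.0, 0.1)), ("CD1", (3.9, 0.8, 0.3)), ("CD2", (3.9, -0.8, 0.3))]
    elif res1 == "I":
        t += [("CG1", (2.6, 0.8, 0.2)), ("CG2", (2.6, -0.8, 0.2)), ("CD1", (3.9, 0.8, 0.4))]
    elif res1 == "M":
        t += _chain(["CG", "SD", "CE"], start=2.8)
    elif res1 == "S":
        t += [("OG", (2.7, 0.0, 0.2))]
    elif res1 == "T":
        t += [("OG1", (2.6, 0.8, 0.2)), ("CG2", (2.6, -0.8, 0.2))]
    elif res1 == "C":
        t += [("SG", (2.9, 0.0, 0.2))]
    elif res1 == "N":
        t += [("CG", (2.8, 0.0, 0.1)), ("OD1", (3.8, 0.7, 0.3)), ("ND2", (3.8, -0.7, 0.3))]
    elif res1 == "Q":
        t += [("CG", (2.8, 0.0, 0.1)), ("CD", (4.1, 0.0, 0.2)),
              ("OE1", (5.1, 0.7, 0.4)), ("NE2", (5.1, -0.7, 0.4))]
    elif res1 == "P":
        t += [("CG", (2.4, 0.9, 0.2)), ("CD", (1.6, 1.6, 0.1))]
    elif res1 == "K":
        t += _chain(["CG", "CD", "CE", "NZ"], start=2.8)
        nz_x = 2.8 + 1.3 * 3
        t += [("HZ1", (nz_x + 0.95, 0.3, 0.0)), ("HZ2", (nz_x + 0.95, -0.3, 0.0)),
              ("HZ3", (nz_x, 0.0, 1.0))]
    elif res1 == "R":
        t += _chain(["CG", "CD", "NE", "CZ"], start=2.8)
        cz_x = 2.8 + 1.3 * 3
        t += [("NH1", (cz_x + 1.1, 0.8, 0.0)), ("NH2", (cz_x + 1.1, -0.8, 0.0)),
              ("HE", (2.8 + 1.3 * 2, 0.0, 1.0)),
              ("HH11", (cz_x + 2.0, 1.0, 0.0)), ("HH21", (cz_x + 2.0, -1.0, 0.0))]
    elif res1 == "D":
        t += [("CG", (2.8, 0.0, 0.1)), ("OD1", (3.8, 0.7, 0.3)), ("OD2", (3.8, -0.7, 0.3))]
    elif res1 == "E":
        t += [("CG", (2.8, 0.0, 0.1)), ("CD", (4.1, 0.0, 0.2)),
              ("OE1", (5.1, 0.7, 0.4)), ("OE2", (5.1, -0.7, 0.4))]
    elif res1 == "H":
        t += _ring_template_his(2.6)
    elif res1 == "F":
        t += _ring_template_6(2.6)
    elif res1 == "Y":
        t += _ring_template_6(2.6)
        t += [("OH", (2.6 + 1.39 + 2.78 + 1.36, 0.0, 0.0))]
    elif res1 == "W":
        t += _ring_template_trp(2.6)
    else:
        raise ValueError(f"invalid residue code {res1!r}")
    return t


# ---------------------------------------------------------------------------
# helix construction

CA_RADIUS = 2.3  # Å, Cα distance from helix axis


def build_ideal_helix(
    sequence: str,
    rise: float = 1.5,
    twist: float = 100.0,
    resolution: str = "aa-lite",
    first_resid: int = 1,
) -> tuple[np.ndarray, list[tuple[str, int, str]]]:
    """Ideal α-helix along z (rise Å/residue, twist °/residue ≈ 3.6 res/turn).

    Returns coordinates (N, 3) centred on the helix axis at z ∈
    [0, (n-1)·rise], and an atom table of (atom_name, residue_id,
    residue_name_3letter). ``cg`` resolution emits one BB bead per residue
    at the Cα position; ``aa-lite`` adds backbone N/H/C/O and classifier
    side-chain atoms.
    """
    if not sequence:
        raise ValueError("sequence must be nonempty")
    for c in sequence:
        if c not in AA3:
            raise ValueError(f"invalid residue code {c!r}")
    if resolution not in ("cg", "aa-lite"):
        raise ValueError(f"unknown resolution {resolution!r}")
    coords: list[np.ndarray] = []
    table: list[tuple[str, int, str]] = []
    for i, res1 in enumerate(sequence):
        theta = np.radians(i * twist)
        u_r = np.array([np.cos(theta), np.sin(theta), 0.0])
        u_t = np.array([-np.sin(theta), np.cos(theta), 0.0])
        uz = np.array([0.0, 0.0, 1.0])
        ca = CA_RADIUS * u_r + uz * (i * rise)
        resid = first_resid + i
        resname = AA3[res1]
        if resolution == "cg":
            coords.append(ca)
            table.append(("BB", resid, resname))
            continue
        n = ca - 0.8 * u_t - 1.2 * uz
        atoms = [("N", n), ("H", n + 1.0 * u_r), ("CA", ca),
                 ("C", ca + 0.8 * u_t + 1.2 * uz)]
        atoms.append(("O", atoms[-1][1] + 1.23 * u_r))
        for name, (dr, dt, dz) in _sidechain_template(res1):
            atoms.append((name, ca + dr * u_r + dt * u_t + dz * uz))
        for name, pos in atoms:
            coords.append(pos)
            table.append((name, resid, resname))
    return np.asarray(coords), table


def _assemble_topology(
    sequences: Sequence[str],
    first_resids: Sequence[int],
    resolution: str,
    chain_ids: Sequence[str] = ("A", "B", "C"),
) -> tuple[Topology, np.ndarray, list[np.ndarray]]:
    """Build the multi-chain Topology; returns (topology, base_coords,
    per-chain atom index arrays). Base coordinates have every helix on the
    z axis centred at the origin (posing is done per frame)."""
    all_coords, names, resids, resnames, chains = [], [], [], [], []
    chain_slices = []
    for seq, fr, cid in zip(sequences, first_resids, chain_ids):
        xyz, table = build_ideal_helix(seq, resolution=resolution, first_resid=fr)
        xyz = xyz - xyz.mean(axis=0)  # centre each helix at the origin
        start = len(names)
        for (name, resid, resname), pos in zip(table, xyz):
            names.append(name)
            resids.append(resid)
            resnames.append(resname)
            chains.append(cid)
            all_coords.append(pos)
        chain_slices.append(np.arange(start, len(names)))
    n_atoms = len(names)
    reskeys = list(dict.fromkeys(zip(chains, resids)))
    res_index = {k: i for i, k in enumerate(reskeys)}
    atom_resindex = np.array([res_index[(c, r)] for c, r in zip(chains, resids)])
    seg_index = {c: i for i, c in enumerate(dict.fromkeys(chains))}
    res_chain = [k[0] for k in reskeys]
    u = mda.Universe.empty(
        n_atoms, n_residues=len(reskeys), n_segments=len(seg_index),
        atom_resindex=atom_resindex,
        residue_segindex=np.array([seg_index[c] for c in res_chain]),
        trajectory=True,
    )
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("resids", [k[1] for k in reskeys])
    u.add_TopologyAttr("resnames", [resnames[np.where(atom_resindex == i)[0][0]]
                                    for i in range(len(reskeys))])
    u.add_TopologyAttr("segids", list(seg_index))
    u.add_TopologyAttr("chainIDs", chains)
    top = topology_from_universe(u)
    return top, np.asarray(all_coords), chain_slices


# ---------------------------------------------------------------------------
# schedules

def schedule_categories(n_frames: int, fractions: Sequence[float]) -> np.ndarray:
    """Deterministic per-frame category assignment with exact counts.

    Counts follow largest-remainder rounding of ``fractions``·n (so a
    fraction with integral count is hit exactly); frames are spread through
    the trajectory by a low-discrepancy (golden-ratio) ordering so schedules
    decorrelate from state switching.
    """
    fr = np.asarray(fractions, dtype=float)
    if np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be nonnegative and sum to 1")
    raw = fr * n_frames
    counts = np.floor(raw + 1e-9).astype(int)
    rem = raw - counts
    for _ in range(n_frames - counts.sum()):
        i = int(np.argmax(rem))
        counts[i] += 1
        rem[i] = -1
    order = np.argsort((np.arange(n_frames) * 0.618033988749895) % 1.0, kind="stable")
    cats = np.empty(n_frames, dtype=int)
    pos = 0
    for cat, cnt in enumerate(counts):
        cats[order[pos:pos + cnt]] = cat
        pos += cnt
    return cats


def schedule_binary(n_frames: int, occupancy: float) -> np.ndarray:
    return schedule_categories(n_frames, [1.0 - occupancy, occupancy]).astype(bool)


# ---------------------------------------------------------------------------
# spec dataclasses

@dataclass
class StateSpec:
    """Pose of the receptor helix relative to the adaptor dimer."""
    xy_separation: float = 6.0   # Å, COM distance in the membrane plane
    z_offset: float = 0.0        # Å, COM depth relative to the membrane midplane
    tilt_deg: float = 10.0       # ° from the membrane normal (z)


@dataclass
class PlantedInteraction:
    """A residue–residue interaction toggled on a deterministic schedule.

    ``kind``: contact | saltbridge | hbond | hbond_pair | pipi | hydrophobic.
    ``occupancy`` drives binary kinds; ``fractions`` drives categorical kinds
    (hbond_pair: none/one/both; pipi: none/parallel/t_shaped).
    """
    kind: str
    res_a: tuple[str, int]
    res_b: tuple[str, int]
    occupancy: float = 0.0
    fractions: tuple[float, ...] = ()
    res_b2: tuple[str, int] | None = None  # second acceptor chain for hbond_pair


@dataclass
class SyntheticSpec:
    sequences: tuple[str, str, str] = DEFAULT_SEQUENCES
    first_resids: tuple[int, int, int] = DEFAULT_FIRST_RESIDS
    resolution: str = "cg"
    n_frames: int = 2000
    jitter_sigma: float = 0.5      # Å per axis, isotropic, uncorrelated
    states: list[StateSpec] = field(default_factory=lambda: [StateSpec()])
    transition: np.ndarray | None = None  # k×k row-stochastic; default stay 0.8
    interactions: list[PlantedInteraction] = field(default_factory=list)
    seed: int = 0
    box: tuple[float, float, float] = (90.0, 90.0, 100.0)
    dimer_gap: float = 9.6         # Å between adaptor helix axes
    dt_ns: float = 1.0

    def transition_matrix(self) -> np.ndarray:
        k = len(self.states)
        if self.transition is not None:
            t = np.asarray(self.transition, dtype=float)
            if t.shape != (k, k) or np.any(t < 0) or np.any(np.abs(t.sum(1) - 1) > 1e-9):
                raise ValueError("transition must be k×k row-stochastic")
            return t
        if k == 1:
            return np.ones((1, 1))
        stay = 0.8
        t = np.full((k, k), (1 - stay) / (k - 1))
        np.fill_diagonal(t, stay)
        return t


@dataclass
class GroundTruth:
    """Per-frame truth emitted alongside the coordinates."""
    state_labels: np.ndarray                 # (T,) int
    interaction_states: dict[str, np.ndarray]  # key -> (T,) int (binary or category)
    com: dict[str, np.ndarray]               # chain group -> (T, 3) pre-jitter COM
    xy_separation: np.ndarray                # (T,) receptor↔dimer lateral distance
    tilt_deg: np.ndarray                     # (T,) receptor tilt from z
    state_specs: list[StateSpec]

    def to_json(self, path: str | Path) -> None:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            return x
        payload = {
            "state_labels": self.state_labels.tolist(),
            "interaction_states": {k: v.tolist() for k, v in self.interaction_states.items()},
            "com": {k: v.tolist() for k, v in self.com.items()},
            "xy_separation": self.xy_separation.tolist(),
            "tilt_deg": self.tilt_deg.tolist(),
            "state_specs": [asdict(s) for s in self.state_specs],
        }
        Path(path).write_text(json.dumps(payload))


# ---------------------------------------------------------------------------
# simulation

def _pose_state(base: np.ndarray, chain_idx: list[np.ndarray], masses: np.ndarray,
                state: StateSpec, box: np.ndarray, dimer_gap: float) -> np.ndarray:
    """Rigidly place the three helices for one state; COM placement is exact
    (mass-weighted) so planted separations/offsets are ground truth."""
    centre = box / 2.0
    out = base.copy()
    a, b, c = chain_idx
    # receptor: tilt about x (helix leans along ±y), then set COM exactly
    th = np.radians(state.tilt_deg)
    rot = np.array([[1, 0, 0],
                    [0, np.cos(th), -np.sin(th)],
                    [0, np.sin(th), np.cos(th)]])
    xyz_a = base[a] @ rot.T
    target_a = centre + np.array([state.xy_separation, 0.0, state.z_offset])
    w_a = masses[a][:, None]
    xyz_a += target_a - (xyz_a * w_a).sum(0) / w_a.sum()
    out[a] = xyz_a
    # adaptor dimer: vertical, combined COM at the box centre
    for idx, dy in ((b, -dimer_gap / 2), (c, +dimer_gap / 2)):
        w = masses[idx][:, None]
        com = (base[idx] * w).sum(0) / w.sum()
        out[idx] = base[idx] + (centre + np.array([0.0, dy, 0.0]) - com)
    bc = np.concatenate([b, c])
    w = masses[bc][:, None]
    out[bc] += centre - (out[bc] * w).sum(0) / w.sum()
    return out


_BASIC_ATOMS = {"LYS": ["NZ"], "ARG": ["NE", "NH1", "NH2"],
                "HSP": ["ND1", "NE2"], "HIP": ["ND1", "NE2"]}
_ACIDIC_ATOMS = {"ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"]}
_RING_NAMES = {
    "PHE": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TYR": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "HIS": [["CG", "ND1", "CD2", "CE1", "NE2"]],
    "TRP": [["CG", "CD1", "NE1", "CE2", "CD2"],
            ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"]],
}


class _ResIndex:
    def __init__(self, top: Topology):
        self._by_res: dict[tuple[str, int], np.ndarray] = {}
        for i, (c, r) in enumerate(zip(top.chain_ids, top.residue_ids)):
            self._by_res.setdefault((str(c), int(r)), []).append(i)  # type: ignore
        self._by_res = {k: np.asarray(v) for k, v in self._by_res.items()}
        self.names = top.atom_names
        self.resnames = top.residue_names

    def atoms(self, res: tuple[str, int], names: Sequence[str]) -> np.ndarray:
        idx = self._by_res[res]
        sel = [i for i in idx for n in names if self.names[i] == n]
        return np.asarray(sel, dtype=int)

    def resname(self, res: tuple[str, int]) -> str:
        return str(self.resnames[self._by_res[res][0]])

    def anchor(self, res: tuple[str, int]) -> np.ndarray:
        a = self.atoms(res, ["CA", "BB"])
        return self._by_res[res] if len(a) == 0 else a


def _spread(n: int) -> np.ndarray:
    """Small perpendicular offsets so co-placed atoms do not coincide."""
    return np.linspace(-0.4 * (n - 1), 0.4 * (n - 1), n)


def _apply_interaction(coords: np.ndarray, ridx: _ResIndex, pi: PlantedInteraction,
                       state_code: int) -> None:
    """Override the minimal atom set of a planted interaction, in place.

    Geometries are placed along the line between the two residues' anchor
    atoms with margins well inside/outside the classifier cutoffs.
    """
    pa = coords[ridx.anchor(pi.res_a)].mean(0)
    pb = coords[ridx.anchor(pi.res_b)].mean(0)
    u = pb - pa
    u /= np.linalg.norm(u)
    mid = 0.5 * (pa + pb)
    w = np.array([u[1], -u[0], 0.0])
    nw = np.linalg.norm(w)
    w = np.array([1.0, 0.0, 0.0]) if nw < 1e-8 else w / nw
    on = bool(state_code)

    if pi.kind in ("contact", "hydrophobic"):
        name_a = "CB" if pi.kind == "hydrophobic" else None
        atoms_a = ridx.atoms(pi.res_a, [name_a]) if name_a else ridx.anchor(pi.res_a)[:1]
        atoms_b = ridx.atoms(pi.res_b, ["CB"]) if name_a else ridx.anchor(pi.res_b)[:1]
        d = {"contact": (2.5, 8.0), "hydrophobic": (4.0, 7.0)}[pi.kind][0 if on else 1]
        coords[atoms_a[0]] = mid - (d / 2) * u
        coords[atoms_b[0]] = mid + (d / 2) * u
    elif pi.kind == "saltbridge":
        basic = ridx.atoms(pi.res_a, _BASIC_ATOMS[ridx.resname(pi.res_a)])
        acidic = ridx.atoms(pi.res_b, _ACIDIC_ATOMS[ridx.resname(pi.res_b)])
        d = 2.9 if on else 5.0
        for k, i in enumerate(basic):
            coords[i] = mid - (d / 2) * u + _spread(len(basic))[k] * w
        for k, i in enumerate(acidic):
            coords[i] = mid + (d / 2) * u + _spread(len(acidic))[k] * w
    elif pi.kind == "hbond":
        dn = ridx.atoms(pi.res_a, ["NZ", "N"])[:1]
        hy = ridx.atoms(pi.res_a, ["HZ1", "H"])[:1]
        ac = ridx.atoms(pi.res_b, ["OD1", "OE1", "O"])[:1]
        d = 2.8 if on else 5.0
        coords[dn[0]] = mid - (d / 2) * u
        coords[hy[0]] = coords[dn[0]] + 1.0 * u
        coords[ac[0]] = coords[dn[0]] + d * u
    elif pi.kind == "hbond_pair":
        # donor bonded to neither / one / both acceptor chains (codes 0/1/2)
        dn = ridx.atoms(pi.res_a, ["NZ", "N"])[0]
        h1 = ridx.atoms(pi.res_a, ["HZ1", "H"])[0]
        h2 = ridx.atoms(pi.res_a, ["HZ2"])
        ac1 = ridx.atoms(pi.res_b, ["OD1", "OE1", "O"])[0]
        ac2 = ridx.atoms(pi.res_b2, ["OD1", "OE1", "O"])[0]
        v1 = u
        v2 = 0.5 * u + 0.866 * w
        coords[dn] = mid
        coords[h1] = mid + 1.0 * v1
        if len(h2):
            coords[h2[0]] = mid + 1.0 * v2
        coords[ac1] = mid + (2.8 if state_code >= 1 else 5.0) * v1
        coords[ac2] = mid + (2.8 if state_code == 2 else 5.0) * v2
    elif pi.kind == "pipi":
        # codes: 0 none, 1 parallel, 2 t_shaped
        rings_a = _RING_NAMES[ridx.resname(pi.res_a)]
        rings_b = _RING_NAMES[ridx.resname(pi.res_b)]
        sep = {0: 9.0, 1: 3.8, 2: 5.0}[state_code]
        v = np.cross(u, w)
        for res, names_list, centre, normal in (
            (pi.res_a, rings_a[0], mid - (sep / 2) * u, u),
            (pi.res_b, rings_b[0], mid + (sep / 2) * u, u if state_code != 2 else w),
        ):
            e1 = w if abs(np.dot(w, normal)) < 0.9 else v
            e1 = e1 - np.dot(e1, normal) * normal
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(normal, e1)
            idx = ridx.atoms(res, names_list)
            k = len(idx)
            for j, i in enumerate(idx):
                a = 2 * np.pi * j / k
                coords[i] = centre + 1.39 * (np.cos(a) * e1 + np.sin(a) * e2)
    else:
        raise ValueError(f"unknown planted interaction kind {pi.kind!r}")


def _interaction_key(pi: PlantedInteraction) -> str:
    return f"{pi.kind}:{pi.res_a[0]}{pi.res_a[1]}-{pi.res_b[0]}{pi.res_b[1]}"


def simulate(spec: SyntheticSpec) -> tuple[Topology, Trajectory, GroundTruth]:
    """Emit (Topology, Trajectory, GroundTruth) for a synthetic spec.

    Per frame: the conformational state is sampled from the seeded Markov
    chain; helices are rigidly posed at that state's separation/depth/tilt
    (COM placement exact pre-jitter); planted interaction geometries are
    toggled per their deterministic schedules; isotropic Gaussian jitter is
    added last.
    """
    for s in spec.states:
        if s.xy_separation < 3.0:
            raise ValueError("infeasible geometry: helices would overlap "
                             f"(xy_separation {s.xy_separation} Å)")
    top, base, chain_idx = _assemble_topology(
        spec.sequences, spec.first_resids, spec.resolution)
    masses = top.masses
    box = np.asarray(spec.box, dtype=float)
    rng = np.random.default_rng(spec.seed)
    k = len(spec.states)
    tmat = spec.transition_matrix()

    labels = np.empty(spec.n_frames, dtype=int)
    s = 0
    for t in range(spec.n_frames):
        labels[t] = s
        s = rng.choice(k, p=tmat[s])

    posed = [_pose_state(base, chain_idx, masses, st, box, spec.dimer_gap)
             for st in spec.states]

    ridx = _ResIndex(top)
    schedules: dict[str, np.ndarray] = {}
    for pi in spec.interactions:
        key = _interaction_key(pi)
        if pi.kind in ("hbond_pair", "pipi") and pi.fractions:
            schedules[key] = schedule_categories(spec.n_frames, pi.fractions)
        else:
            schedules[key] = schedule_binary(spec.n_frames, pi.occupancy).astype(int)

    a, b, c = chain_idx
    bc = np.concatenate([b, c])
    com_a = np.empty((spec.n_frames, 3))
    com_bc = np.empty((spec.n_frames, 3))
    frames = np.empty((spec.n_frames, top.n_atoms, 3))
    for t in range(spec.n_frames):
        xyz = posed[labels[t]].copy()
        for pi in spec.interactions:
            _apply_interaction(xyz, ridx, pi, int(schedules[_interaction_key(pi)][t]))
        wa = masses[a][:, None]
        wbc = masses[bc][:, None]
        com_a[t] = (xyz[a] * wa).sum(0) / wa.sum()
        com_bc[t] = (xyz[bc] * wbc).sum(0) / wbc.sum()
        if spec.jitter_sigma > 0:
            xyz = xyz + rng.normal(0.0, spec.jitter_sigma, xyz.shape)
        frames[t] = xyz

    traj = Trajectory(
        coordinates=frames,
        box=np.tile(box, (spec.n_frames, 1)),
        times=(np.arange(spec.n_frames) + 1.0) * spec.dt_ns,
    )
    truth = GroundTruth(
        state_labels=labels,
        interaction_states=schedules,
        com={"A": com_a, "BC": com_bc},
        xy_separation=np.linalg.norm((com_a - com_bc)[:, :2], axis=1),
        tilt_deg=np.array([spec.states[l].tilt_deg for l in labels], dtype=float),
        state_specs=list(spec.states),
    )
    return top, traj, truth


# ---------------------------------------------------------------------------
# presets

def dissociation_scenario(**overrides) -> SyntheticSpec:
    """Two-state dissociation: a bound pose decays irreversibly into a
    laterally displaced, nearly horizontal pose sunk toward the lower
    leaflet (the truncation-mutant signature)."""
    spec = SyntheticSpec(
        resolution="cg",
        n_frames=2000,
        jitter_sigma=0.5,
        states=[
            StateSpec(xy_separation=6.0, z_offset=0.0, tilt_deg=10.0),
            StateSpec(xy_separation=11.2, z_offset=-8.0, tilt_deg=80.0),
        ],
        transition=np.array([[0.98, 0.02], [0.0, 1.0]]),
        seed=7,
    )
    for k, v in overrides.items():
        setattr(spec, k, v)
    return spec


def interaction_showcase(n_frames: int = 2000, seed: int = 11,
                         jitter_sigma: float = 0.0) -> SyntheticSpec:
    """Single bound state, aa-lite, with the canonical planted interactions:
    a 70%-occupancy salt bridge (E202-like to R66-like), a bimodal
    receptor→both-adaptor-chains hydrogen bond (10/40/50 none/one/both),
    and a π–π pair at 30% parallel / 10% T-shaped."""
    return SyntheticSpec(
        resolution="aa-lite",
        n_frames=n_frames,
        jitter_sigma=jitter_sigma,
        states=[StateSpec(xy_separation=14.0, tilt_deg=0.0)],
        interactions=[
            PlantedInteraction("saltbridge", res_a=("B", 66), res_b=("A", 202),
                               occupancy=0.70),
            PlantedInteraction("hbond_pair", res_a=("A", 186), res_b=("B", 50),
                               res_b2=("C", 50), fractions=(0.10, 0.40, 0.50)),
            PlantedInteraction("pipi", res_a=("A", 194), res_b=("B", 62),
                               fractions=(0.60, 0.30, 0.10)),
        ],
        seed=seed,
    )


def contact_schedule_scenario(n_frames: int = 2000, seed: int = 3) -> SyntheticSpec:
    """Well-separated helices (no incidental contacts) with three planted
    residue contacts at 35/61/95% occupancy — exercises the persistence
    tiers none/interacting/important."""
    return SyntheticSpec(
        resolution="cg",
        n_frames=n_frames,
        jitter_sigma=0.0,
        states=[StateSpec(xy_separation=20.0, tilt_deg=0.0)],
        interactions=[
            PlantedInteraction("contact", res_a=("A", 186), res_b=("B", 50), occupancy=0.35),
            PlantedInteraction("contact", res_a=("A", 202), res_b=("B", 66), occupancy=0.61),
            PlantedInteraction("contact", res_a=("A", 194), res_b=("C", 62), occupancy=0.95),
        ],
        seed=seed,
    )


def clustering_scenario(k: int = 2, n_frames: int = 2000, seed: int = 5,
                        jitter_sigma: float = 0.5) -> SyntheticSpec:
    """k ∈ {1,2,3} metastable states with distinct separations/tilts for the
    conformational-state pipeline (CG resolution, BB features)."""
    poses = [
        StateSpec(xy_separation=6.0, z_offset=0.0, tilt_deg=5.0),
        StateSpec(xy_separation=10.0, z_offset=-3.0, tilt_deg=30.0),
        StateSpec(xy_separation=14.0, z_offset=3.0, tilt_deg=55.0),
    ]
    if not 1 <= k <= 3:
        raise ValueError("k must be 1, 2 or 3")
    return SyntheticSpec(
        resolution="cg", n_frames=n_frames, jitter_sigma=jitter_sigma,
        states=poses[:k], seed=seed,
    )
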