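"""Geometric interaction classifiers and trajectory occupancy statistics.

Per-frame rules (all distances in Å, angles in degrees):

* hydrogen bond — donor–acceptor distance ≤ 3.0 and donor–H–acceptor angle
  ≥ 150° for some hydrogen covalently bonded to the donor (bond inferred
  geometrically at ≤ 1.2 Å when the topology has no bond table);
* π–π stacking — ring-centroid distance ≤ 6.5 with interplanar angle ≤ 30°
  (parallel-displaced) or ≥ 60° after folding to [0, 90] (T-shaped; the
  unfolded criterion is 60–120°);
* hydrophobic contact — any side-chain carbon–carbon pair (backbone N, Cα,
  C, O excluded) at ≤ 4.5;
* salt bridge — minimum N···O distance ≤ 3.2 between basic-group nitrogens
  (Lys NZ, Arg NH1/NH2/NE, protonated His ND1/NE2, N-terminal N) and acidic
  oxygens (Asp OD1/OD2, Glu OE1/OE2, C-terminal O/OXT).

All four classifiers need atom-resolved (or "aa-lite") input; coarse-grained
backbone-bead models raise :class:`~tmca.io_model.ResolutionError`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_model import (
    ResolutionError,
    Topology,
    Trajectory,
    min_image_displacement,
    pairwise_min_image_distance,
)

__all__ = [
    "HBondCriteria",
    "PiPiGeometry",
    "find_hbonds",
    "hbond_occupancy",
    "hbond_partner_histogram",
    "ring_plane",
    "classify_pipi",
    "pipi_occupancy",
    "hydrophobic_contact",
    "salt_bridge",
    "interaction_profile",
    "aggregate_replicas",
    "RING_ATOMS",
]

AROMATIC = ("PHE", "TYR", "TRP", "HIS", "HSD", "HSE", "HSP", "HIP", "HIE", "HID")
RING_ATOMS: dict[str, list[list[str]]] = {
    "PHE": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TYR": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TRP": [["CG", "CD1", "NE1", "CE2", "CD2"],
            ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"]],
    "HIS": [["CG", "ND1", "CD2", "CE1", "NE2"]],
}
for _alias in ("HSD", "HSE", "HSP", "HIP", "HIE", "HID"):
    RING_ATOMS[_alias] = RING_ATOMS["HIS"]

BASIC_ATOMS = {"LYS": ("NZ",), "ARG": ("NH1", "NH2", "NE"),
               "HSP": ("ND1", "NE2"), "HIP": ("ND1", "NE2")}
ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BACKBONE_NAMES = ("N", "CA", "C", "O", "OXT", "H", "HA", "BB")


@dataclass(frozen=True)
class HBondCriteria:
    d_da_max: float = 3.0        # Å donor–acceptor
    angle_dha_min: float = 150.0  # ° donor–hydrogen–acceptor

    def __post_init__(self):
        if self.d_da_max <= 0 or not 0 < self.angle_dha_min <= 180:
            raise ValueError("invalid hydrogen-bond criteria")


@dataclass(frozen=True)
class PiPiGeometry:
    centroid_distance: float
    interplanar_angle: float   # folded to [0, 90]
    cls: str                   # parallel | t_shaped | none


# ---------------------------------------------------------------------------
# residue bookkeeping

class ResidueIndex:
    """Fast lookup of atoms by (chain, resid) with chain-terminus flags."""

    def __init__(self, top: Topology):
        self.top = top
        by_res: dict[tuple[str, int], list[int]] = {}
        for i, (c, r) in enumerate(zip(top.chain_ids, top.residue_ids)):
            by_res.setdefault((str(c), int(r)), []).append(i)
        self.by_res = {k: np.asarray(v) for k, v in by_res.items()}
        self.first_in_chain: dict[str, int] = {}
        self.last_in_chain: dict[str, int] = {}
        for (c, r) in self.by_res:
            self.first_in_chain[c] = min(self.first_in_chain.get(c, r), r)
            self.last_in_chain[c] = max(self.last_in_chain.get(c, r), r)

    def atoms(self, res: tuple[str, int]) -> np.ndarray:
        key = (str(res[0]), int(res[1]))
        if key not in self.by_res:
            raise KeyError(f"residue {key} not in topology")
        return self.by_res[key]

    def named(self, res, names: Sequence[str]) -> np.ndarray:
        idx = self.atoms(res)
        return idx[np.isin(self.top.atom_names[idx], names)]

    def resname(self, res) -> str:
        return str(self.top.residue_names[self.atoms(res)[0]])

    def require_atomistic(self, res, analysis: str) -> None:
        idx = self.atoms(res)
        if np.all(self.top.elements[idx] == "BB"):
            raise ResolutionError(
                f"{analysis} needs atom-resolved input; residue "
                f"{res} carries only coarse-grained backbone beads"
            )


def bonded_hydrogens(top: Topology, frame: np.ndarray,
                     box: Sequence[float], max_bond: float = 1.2
                     ) -> dict[int, np.ndarray]:
    """Map each N/O heavy atom to its covalently bonded hydrogens,
    inferred geometrically (H within ``max_bond`` Å of the heavy atom)."""
    h_idx = np.where(top.elements == "H")[0]
    heavy = np.where(np.isin(top.elements, ("N", "O")))[0]
    out: dict[int, list[int]] = {int(i): [] for i in heavy}
    if len(h_idx) == 0 or len(heavy) == 0:
        return {k: np.asarray(v, dtype=int) for k, v in out.items()}
    d = pairwise_min_image_distance(frame[heavy], frame[h_idx], box)
    nearest = np.argmin(d, axis=0)
    for j, hi in enumerate(h_idx):
        if d[nearest[j], j] <= max_bond:
            out[int(heavy[nearest[j]])].append(int(hi))
    return {k: np.asarray(v, dtype=int) for k, v in out.items()}


# ---------------------------------------------------------------------------
# hydrogen bonds

def _dha_angle(frame: np.ndarray, d: int, h: int, a: int,
               box: Sequence[float]) -> float:
    v1 = min_image_displacement(frame[d] - frame[h], box)
    v2 = min_image_displacement(frame[a] - frame[h], box)
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def find_hbonds(
    frame: np.ndarray,
    top: Topology,
    donors: np.ndarray,
    acceptors: np.ndarray,
    box: Sequence[float],
    crit: HBondCriteria = HBondCriteria(),
    hydrogen_map: dict[int, np.ndarray] | None = None,
) -> list[tuple[int, int]]:
    """Hydrogen-bond events (donor_atom, acceptor_atom) in one frame."""
    if hydrogen_map is None:
        hydrogen_map = bonded_hydrogens(top, frame, box)
    donors = np.asarray(donors, dtype=int)
    acceptors = np.asarray(acceptors, dtype=int)
    events = []
    if len(donors) == 0 or len(acceptors) == 0:
        return events
    dmat = pairwise_min_image_distance(frame[donors], frame[acceptors], box)
    for i, dn in enumerate(donors):
        hyds = hydrogen_map.get(int(dn), np.empty(0, dtype=int))
        if len(hyds) == 0:
            warnings.warn(f"donor atom {dn} has no bonded hydrogen; skipped")
            continue
        for j, ac in enumerate(acceptors):
            if ac == dn or dmat[i, j] > crit.d_da_max:
                continue
            for h in hyds:
                if _dha_angle(frame, int(dn), int(h), int(ac), box) >= crit.angle_dha_min:
                    events.append((int(dn), int(ac)))
                    break
    return events


def _donor_acceptor_atoms(ridx: ResidueIndex, donor_res, acceptor_res):
    top = ridx.top
    d_idx = ridx.atoms(donor_res)
    a_idx = ridx.atoms(acceptor_res)
    d_no = d_idx[np.isin(top.elements[d_idx], ("N", "O"))]
    a_no = a_idx[np.isin(top.elements[a_idx], ("N", "O"))]
    return d_no, a_no


def hbond_occupancy(traj: Trajectory, top: Topology,
                    donor_res: tuple[str, int], acceptor_res: tuple[str, int],
                    crit: HBondCriteria = HBondCriteria(),
                    ridx: ResidueIndex | None = None) -> tuple[float, np.ndarray]:
    """Fraction of frames with ≥1 hydrogen bond between two residues
    (donor side fixed); returns (occupancy, per-frame boolean series)."""
    ridx = ridx or ResidueIndex(top)
    ridx.require_atomistic(donor_res, "hydrogen-bond analysis")
    ridx.require_atomistic(acceptor_res, "hydrogen-bond analysis")
    donors, acceptors = _donor_acceptor_atoms(ridx, donor_res, acceptor_res)
    series = np.zeros(traj.n_frames, dtype=bool)
    for t in range(traj.n_frames):
        frame, box = traj.coordinates[t], traj.box[t]
        hmap = bonded_hydrogens(top, frame, box)
        # protonated donor atoms only; hydrogen-less N/O are acceptors here
        d_prot = np.asarray([d for d in donors if len(hmap.get(int(d), ())) > 0],
                            dtype=int)
        series[t] = bool(find_hbonds(frame, top, d_prot, acceptors, box, crit, hmap))
    return float(series.mean()), series


def hbond_partner_histogram(
    traj: Trajectory, top: Topology,
    donor_res: tuple[str, int],
    acceptor_resid: int,
    acceptor_chains: tuple[str, str],
    crit: HBondCriteria = HBondCriteria(),
) -> tuple[float, float, float]:
    """Distribution over {0, 1, 2} adaptor chains hydrogen-bonded to the
    donor residue per frame (the bimodal receptor→dimer bond statistic).

    Returns (p_none, p_one, p_both); any-bond occupancy = p_one + p_both.
    """
    if len(acceptor_chains) != 2:
        raise ValueError("exactly two acceptor chains required")
    ridx = ResidueIndex(top)
    counts = np.zeros(traj.n_frames, dtype=int)
    for chain in acceptor_chains:
        _, series = hbond_occupancy(traj, top, donor_res,
                                    (chain, acceptor_resid), crit, ridx)
        counts += series
    p = np.bincount(counts, minlength=3)[:3] / traj.n_frames
    return float(p[0]), float(p[1]), float(p[2])


# ---------------------------------------------------------------------------
# pi-pi stacking

def ring_plane(ring_coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ring centroid (mean of ring atoms) and unit plane normal defined by
    the first three noncollinear atoms."""
    xyz = np.asarray(ring_coords, dtype=float)
    if len(xyz) < 3:
        raise ValueError("ring needs at least 3 atoms")
    centroid = xyz.mean(axis=0)
    p0 = xyz[0]
    for i in range(1, len(xyz) - 1):
        for j in range(i + 1, len(xyz)):
            n = np.cross(xyz[i] - p0, xyz[j] - p0)
            norm = np.linalg.norm(n)
            if norm > 1e-6:
                return centroid, n / norm
    raise ValueError("degenerate ring: all atoms collinear")


def classify_pipi(
    ring_a: np.ndarray, ring_b: np.ndarray, box: Sequence[float],
    d_max: float = 6.5, parallel_max: float = 30.0, tshaped_min: float = 60.0,
) -> PiPiGeometry:
    """Classify one ring pair as parallel-displaced, T-shaped or none.

    The interplanar angle is folded to [0, 90] (normals are sign-ambiguous),
    mapping the 60–120° T-shaped band to ≥ 60°; 30–60° within range is none.
    """
    ca, na = ring_plane(ring_a)
    cb, nb = ring_plane(ring_b)
    sep = min_image_displacement(cb - ca, box)
    dist = float(np.linalg.norm(sep))
    angle = float(np.degrees(np.arccos(np.clip(abs(np.dot(na, nb)), 0.0, 1.0))))
    cls = "none"
    if dist <= d_max:
        if angle <= parallel_max:
            cls = "parallel"
        elif angle >= tshaped_min:
            cls = "t_shaped"
    return PiPiGeometry(dist, angle, cls)


_PIPI_PRECEDENCE = {"parallel": 2, "t_shaped": 1, "none": 0}


def classify_pipi_residues(frame: np.ndarray, ridx: ResidueIndex,
                           res_a, res_b, box) -> PiPiGeometry:
    """Best-scoring ring-pair classification between two aromatic residues
    (Trp contributes both its 5- and 6-membered rings); precedence
    parallel > t_shaped > none."""
    for res in (res_a, res_b):
        ridx.require_atomistic(res, "π–π analysis")
        if ridx.resname(res) not in RING_ATOMS:
            raise ValueError(f"residue {res} ({ridx.resname(res)}) is not aromatic")
    best: PiPiGeometry | None = None
    for names_a in RING_ATOMS[ridx.resname(res_a)]:
        ia = ridx.named(res_a, names_a)
        if len(ia) < 3:
            continue
        for names_b in RING_ATOMS[ridx.resname(res_b)]:
            ib = ridx.named(res_b, names_b)
            if len(ib) < 3:
                continue
            g = classify_pipi(frame[ia], frame[ib], box)
            if best is None or _PIPI_PRECEDENCE[g.cls] > _PIPI_PRECEDENCE[best.cls] \
                    or (_PIPI_PRECEDENCE[g.cls] == _PIPI_PRECEDENCE[best.cls]
                        and g.centroid_distance < best.centroid_distance):
                best = g
    if best is None:
        raise ValueError("no complete ring found on one of the residues")
    return best


def pipi_occupancy(traj: Trajectory, top: Topology,
                   res_a: tuple[str, int], res_b: tuple[str, int]
                   ) -> tuple[float, float, float]:
    """(parallel, t_shaped, none) frame fractions for an aromatic pair."""
    ridx = ResidueIndex(top)
    tally = {"parallel": 0, "t_shaped": 0, "none": 0}
    for t in range(traj.n_frames):
        g = classify_pipi_residues(traj.coordinates[t], ridx, res_a, res_b,
                                   traj.box[t])
        tally[g.cls] += 1
    n = traj.n_frames
    return tally["parallel"] / n, tally["t_shaped"] / n, tally["none"] / n


# ---------------------------------------------------------------------------
# hydrophobic contacts and salt bridges

def _sidechain_carbons(ridx: ResidueIndex, res) -> np.ndarray:
    idx = ridx.atoms(res)
    top = ridx.top
    keep = (top.elements[idx] == "C") & ~np.isin(top.atom_names[idx], BACKBONE_NAMES)
    return idx[keep]


def hydrophobic_contact(frame: np.ndarray, top_or_ridx, res_a, res_b,
                        box: Sequence[float], cutoff: float = 4.5) -> bool:
    """True iff any side-chain carbon–carbon pair is within the cutoff
    (backbone N/Cα/C/O excluded). Glycine has no side-chain carbon and is
    defined False with a warning."""
    ridx = top_or_ridx if isinstance(top_or_ridx, ResidueIndex) else ResidueIndex(top_or_ridx)
    for res in (res_a, res_b):
        ridx.require_atomistic(res, "hydrophobic-contact analysis")
    ca_idx = _sidechain_carbons(ridx, res_a)
    cb_idx = _sidechain_carbons(ridx, res_b)
    if len(ca_idx) == 0 or len(cb_idx) == 0:
        warnings.warn(f"no side-chain carbons on {res_a} or {res_b} "
                      "(glycine?); hydrophobic contact defined False")
        return False
    d = pairwise_min_image_distance(frame[ca_idx], frame[cb_idx], box)
    return bool(d.min() <= cutoff)


def _charged_atoms(ridx: ResidueIndex, res, table: dict, terminus: str) -> np.ndarray:
    resname = ridx.resname(res)
    names = list(table.get(resname, ()))
    chain, resid = str(res[0]), int(res[1])
    if terminus == "N" and resid == ridx.first_in_chain[chain]:
        names.append("N")
    if terminus == "C" and resid == ridx.last_in_chain[chain]:
        names += ["O", "OXT"]
    return ridx.named(res, names)


def salt_bridge(frame: np.ndarray, top_or_ridx, basic_res, acidic_res,
                box: Sequence[float], cutoff: float = 3.2) -> bool:
    """True iff the minimum N···O distance between the basic-group nitrogens
    and acidic-group oxygens is ≤ cutoff (any listed pair suffices)."""
    ridx = top_or_ridx if isinstance(top_or_ridx, ResidueIndex) else ResidueIndex(top_or_ridx)
    for res in (basic_res, acidic_res):
        ridx.require_atomistic(res, "salt-bridge analysis")
    n_idx = _charged_atoms(ridx, basic_res, BASIC_ATOMS, terminus="N")
    o_idx = _charged_atoms(ridx, acidic_res, ACIDIC_ATOMS, terminus="C")
    if len(n_idx) == 0:
        raise ValueError(f"residue {basic_res} ({ridx.resname(basic_res)}) has "
                         "no basic nitrogen atoms")
    if len(o_idx) == 0:
        raise ValueError(f"residue {acidic_res} ({ridx.resname(acidic_res)}) has "
                         "no acidic oxygen atoms")
    d = pairwise_min_image_distance(frame[n_idx], frame[o_idx], box)
    return bool(d.min() <= cutoff)


# ---------------------------------------------------------------------------
# profiles

def interaction_profile(
    traj: Trajectory, top: Topology,
    pairs: Sequence[tuple[str, tuple[str, int], tuple[str, int]]],
    report_floor: float = 0.0,
) -> pd.DataFrame:
    """Occupancy table for a list of (type, residue A, residue B) requests.

    Types: hbond | pipi | hydrophobic | saltbridge. π–π rows carry parallel
    and T-shaped subclass occupancies; rows with total occupancy below
    ``report_floor`` are omitted.
    """
    ridx = ResidueIndex(top)
    rows = []
    for kind, res_a, res_b in pairs:
        rec = {"type": kind,
               "chain_a": res_a[0], "res_a": res_a[1], "resname_a": ridx.resname(res_a),
               "chain_b": res_b[0], "res_b": res_b[1], "resname_b": ridx.resname(res_b),
               "parallel": np.nan, "t_shaped": np.nan}
        if kind == "hbond":
            rec["occupancy"], _ = hbond_occupancy(traj, top, res_a, res_b, ridx=ridx)
        elif kind == "pipi":
            p, t, _ = pipi_occupancy(traj, top, res_a, res_b)
            rec.update(occupancy=p + t, parallel=p, t_shaped=t)
        elif kind == "hydrophobic":
            series = [hydrophobic_contact(traj.coordinates[t], ridx, res_a, res_b,
                                          traj.box[t]) for t in range(traj.n_frames)]
            rec["occupancy"] = float(np.mean(series))
        elif kind == "saltbridge":
            series = [salt_bridge(traj.coordinates[t], ridx, res_a, res_b,
                                  traj.box[t]) for t in range(traj.n_frames)]
            rec["occupancy"] = float(np.mean(series))
        else:
            raise ValueError(f"unknown interaction type {kind!r}")
        if rec["occupancy"] >= report_floor:
            rows.append(rec)
    cols = ["type", "chain_a", "res_a", "resname_a", "chain_b", "res_b",
            "resname_b", "occupancy", "parallel", "t_shaped"]
    return pd.DataFrame(rows, columns=cols)


def aggregate_replicas(profiles: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Mean ± SD of occupancies across independent replicas (averaged per
    replica first, then across replicas)."""
    key = ["type", "chain_a", "res_a", "chain_b", "res_b"]
    stacked = pd.concat(profiles, keys=range(len(profiles)), names=["replica"])
    g = stacked.groupby(key)["occupancy"]
    out = g.agg(occupancy_mean="mean", occupancy_sd="std", n_replicas="count")
    return out.reset_index()
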