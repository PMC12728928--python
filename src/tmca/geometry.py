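"""Flexibility and membrane-positioning metrics.

RMSF is the square root of the time-averaged squared displacement of each
atom about its mean position, RMSF_i = sqrt( (1/T) Σ_t ‖r_i(t) − ⟨r_i⟩‖² ),
computed on Cα (or BB) atoms after least-squares rigid-body alignment to a
reference selection. Positioning metrics are mass-weighted center-of-mass
traces: depth along the membrane normal (z) relative to the bilayer
midplane, lateral (x–y) separation between helix groups, and helix tilt
from the membrane normal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .io_model import Selection, Topology, Trajectory, min_image_displacement

__all__ = [
    "RMSFProfile",
    "COMTrace",
    "align",
    "rmsf",
    "rmsf_replicas",
    "com_z_trace",
    "xy_com_separation",
    "helix_tilt",
]


@dataclass(frozen=True)
class RMSFProfile:
    residue_ids: np.ndarray
    chain_ids: np.ndarray
    rmsf: np.ndarray            # Å, per residue (or per atom)
    reference: str              # alignment selection expression

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chain": self.chain_ids, "resid": self.residue_ids,
                             "rmsf": self.rmsf})


@dataclass(frozen=True)
class COMTrace:
    """Per-frame mass-weighted COM of each chain group, with z reported
    relative to the membrane midplane."""
    com: dict[str, np.ndarray]        # group -> (T, 3) Å
    z_offset: dict[str, np.ndarray]   # group -> (T,) Å relative to midplane
    midplane_z: np.ndarray            # (T,)
    times: np.ndarray


def _kabsch(mobile: np.ndarray, ref: np.ndarray) -> tuple[Rotation, np.ndarray, np.ndarray]:
    mc = mobile.mean(axis=0)
    rc = ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - rc, mobile - mc)
    return rot, mc, rc


def align(traj: Trajectory, top: Topology, reference_sel: Selection,
          reference_frame: int = 0) -> Trajectory:
    """Rigid-body (Kabsch) superposition of every frame onto the reference
    frame, minimizing the RMSD of ``reference_sel``. Assumes the selection
    is whole (not split across the periodic boundary)."""
    idx = np.asarray(reference_sel.indices)
    if len(idx) < 3:
        raise ValueError("alignment needs at least 3 reference atoms")
    ref = traj.coordinates[reference_frame][idx]
    out = np.empty_like(traj.coordinates)
    for t in range(traj.n_frames):
        rot, mc, rc = _kabsch(traj.coordinates[t][idx], ref)
        out[t] = rot.apply(traj.coordinates[t] - mc) + rc
    return Trajectory(coordinates=out, box=traj.box.copy(), times=traj.times.copy())


def rmsf(traj: Trajectory, top: Topology, sel: Selection,
         group_by_residue: bool = True, reference: str = "") -> RMSFProfile:
    """Per-atom RMSF over an (already aligned) trajectory; with
    ``group_by_residue`` the per-residue value is its Cα/BB atom's value."""
    if traj.n_frames < 2:
        raise ValueError("RMSF undefined for a single frame")
    idx = np.asarray(sel.indices)
    if group_by_residue:
        keep = np.isin(top.atom_names[idx], ("CA", "BB"))
        if keep.any():
            idx = idx[keep]
    xyz = traj.coordinates[:, idx, :]
    # mean relative to frame 0: avoids cancellation, exact 0 for static input
    disp = xyz - xyz[0]
    dev = disp - disp.mean(axis=0)
    val = np.sqrt(np.mean(np.sum(dev ** 2, axis=2), axis=0))
    return RMSFProfile(
        residue_ids=top.residue_ids[idx].copy(),
        chain_ids=top.chain_ids[idx].copy(),
        rmsf=val,
        reference=reference or sel.expression,
    )


def rmsf_replicas(profiles: Sequence[RMSFProfile]) -> pd.DataFrame:
    """Replica mean ± SD per residue (the shaded-envelope aggregation)."""
    frames = [p.to_frame().assign(replica=i) for i, p in enumerate(profiles)]
    df = pd.concat(frames)
    g = df.groupby(["chain", "resid"])["rmsf"]
    return g.agg(rmsf_mean="mean", rmsf_sd="std").reset_index()


def _mass_com(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    total = masses.sum()
    if total <= 0:
        raise ValueError("zero total mass in COM group")
    return (coords * masses[:, None]).sum(axis=-2) / total


def com_z_trace(traj: Trajectory, top: Topology,
                groups: dict[str, Selection],
                membrane_ref: str | float = "box-center") -> COMTrace:
    """Mass-weighted COM per group per frame; the z offset is reported
    relative to the membrane midplane (box z-center for slab systems, or an
    explicit z when lipid positions are known)."""
    if isinstance(membrane_ref, str):
        if membrane_ref != "box-center":
            raise ValueError("membrane_ref must be 'box-center' or a z value")
        mid = traj.box[:, 2] / 2.0
    else:
        mid = np.full(traj.n_frames, float(membrane_ref))
    com, zoff = {}, {}
    for name, sel in groups.items():
        idx = np.asarray(sel.indices)
        if len(idx) == 0:
            raise ValueError(f"empty COM group {name!r}")
        c = _mass_com(traj.coordinates[:, idx, :], top.masses[idx])
        com[name] = c
        zoff[name] = c[:, 2] - mid
    return COMTrace(com=com, z_offset=zoff, midplane_z=mid, times=traj.times.copy())


def xy_com_separation(traj: Trajectory, top: Topology,
                      group_a: Selection, group_b: Selection
                      ) -> tuple[np.ndarray, float]:
    """Lateral (x–y plane) COM separation per frame, minimum-image in x and
    y; returns (per-frame separations, time mean)."""
    ca = _mass_com(traj.coordinates[:, group_a.indices, :], top.masses[group_a.indices])
    cb = _mass_com(traj.coordinates[:, group_b.indices, :], top.masses[group_b.indices])
    sep = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        d = min_image_displacement(cb[t] - ca[t], traj.box[t], axes=[0, 1])
        sep[t] = np.hypot(d[0], d[1])
    return sep, float(sep.mean())


def helix_tilt(traj: Trajectory, top: Topology, helix_sel: Selection
               ) -> np.ndarray:
    """Per-frame angle (°, folded to [0, 90]) between the principal axis of
    the selection and the membrane normal (z)."""
    idx = np.asarray(helix_sel.indices)
    if len(idx) < 4:
        raise ValueError("helix tilt needs at least 4 atoms")
    tilt = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        xyz = traj.coordinates[t][idx]
        centred = xyz - xyz.mean(axis=0)
        _, s, vh = np.linalg.svd(centred, full_matrices=False)
        if s[0] < 1e-6 or (len(s) > 1 and s[1] / s[0] > 0.99):
            tilt[t] = np.nan  # degenerate (near-spherical) selection
            continue
        axis = vh[0]
        tilt[t] = np.degrees(np.arccos(np.clip(abs(axis[2]), 0.0, 1.0)))
    if np.isnan(tilt).any():
        import warnings
        warnings.warn("degenerate selection in some frames; tilt undefined there")
    return tilt
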