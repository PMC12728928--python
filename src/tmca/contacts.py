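"""Residue–residue contact-frequency maps and persistence tiers.

A contact is any heavy-atom pair between two residues within the cutoff
(default 3.0 Å); accumulating the binary per-frame matrix over the
trajectory gives per-pair contact frequencies, which are then classified
into persistence tiers: contacts held >60% of frames are "interacting" and
those held >90% are "important" (with intermediate 70%/80% tiers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_model import Selection, Topology, Trajectory, pairwise_min_image_distance

__all__ = [
    "ContactMap",
    "PersistenceLabels",
    "frame_contacts",
    "contact_frequency",
    "classify_persistence",
    "overlay_maps",
    "DEFAULT_THRESHOLDS",
    "TIER_NAMES",
]

DEFAULT_THRESHOLDS = (0.6, 0.7, 0.8, 0.9)
TIER_NAMES = ("none", "interacting", "t70", "t80", "important")


def _mode_filter(top: Topology, sel: Selection, mode: str) -> np.ndarray:
    idx = np.asarray(sel.indices)
    if len(idx) == 0:
        raise ValueError(f"empty atom group from selection {sel.expression!r}")
    if mode == "heavy":
        keep = top.elements[idx] != "H"
    elif mode == "calpha":
        keep = np.isin(top.atom_names[idx], ("CA", "BB"))
    else:
        raise ValueError(f"unknown contact mode {mode!r} (use heavy or calpha)")
    idx = idx[keep]
    if len(idx) == 0:
        raise ValueError(f"no atoms left in {sel.expression!r} under mode {mode!r}")
    return idx


def _residue_blocks(top: Topology, idx: np.ndarray):
    """Atom indices grouped/ordered by (chain, resid); returns (ordered atom
    index array, reduceat offsets, residue keys)."""
    keys = [(str(top.chain_ids[i]), int(top.residue_ids[i])) for i in idx]
    uniq = list(dict.fromkeys(keys))
    pos = {k: j for j, k in enumerate(uniq)}
    order = np.argsort([pos[k] for k in keys], kind="stable")
    ordered = idx[order]
    counts = np.bincount([pos[k] for k in keys], minlength=len(uniq))
    offsets = np.concatenate([[0], np.cumsum(counts)[:-1]])
    return ordered, offsets, uniq


@dataclass(frozen=True)
class ContactMap:
    """Contact frequencies between two residue groups."""
    rows: list          # (chain, resid) of group A
    cols: list          # (chain, resid) of group B
    frequency: np.ndarray   # (len(rows), len(cols)) fractions in [0, 1]
    n_frames: int
    cutoff: float
    mode: str

    def transpose(self) -> "ContactMap":
        return ContactMap(self.cols, self.rows, self.frequency.T,
                          self.n_frames, self.cutoff, self.mode)

    def merge_chains(self, axis: int = 1) -> "ContactMap":
        """Merge the column (default) chains by residue id, taking the max
        frequency over chains — the single-axis view used for adaptor dimers."""
        keys = self.cols if axis == 1 else self.rows
        resids = sorted({r for _, r in keys})
        pos = {r: j for j, r in enumerate(resids)}
        freq = self.frequency if axis == 1 else self.frequency.T
        merged = np.zeros((freq.shape[0], len(resids)))
        for j, (_, r) in enumerate(keys):
            merged[:, pos[r]] = np.maximum(merged[:, pos[r]], freq[:, j])
        new_keys = [("*", r) for r in resids]
        if axis == 1:
            return ContactMap(self.rows, new_keys, merged, self.n_frames,
                              self.cutoff, self.mode)
        return ContactMap(new_keys, self.cols, merged.T, self.n_frames,
                          self.cutoff, self.mode)

    def to_frame(self, labels: "PersistenceLabels | None" = None) -> pd.DataFrame:
        rec = []
        for i, (ca, ra) in enumerate(self.rows):
            for j, (cb, rb) in enumerate(self.cols):
                rec.append({"res_a": ra, "chain_a": ca, "res_b": rb, "chain_b": cb,
                            "frequency": self.frequency[i, j]})
        df = pd.DataFrame(rec)
        if labels is not None:
            df["tier"] = labels.tiers.ravel()
        return df


@dataclass(frozen=True)
class PersistenceLabels:
    """Per-pair persistence tier; tiers are nested (important ⊂ t80 ⊂ t70 ⊂
    interacting)."""
    rows: list
    cols: list
    tiers: np.ndarray       # (R, C) array of tier names
    thresholds: tuple

    def pairs_at(self, tier: str) -> list[tuple]:
        """Residue pairs at or above the given tier."""
        rank = {t: k for k, t in enumerate(TIER_NAMES)}
        want = rank[tier]
        out = []
        for i in range(len(self.rows)):
            for j in range(len(self.cols)):
                if rank[str(self.tiers[i, j])] >= want:
                    out.append((self.rows[i], self.cols[j]))
        return out


def frame_contacts(
    frame: np.ndarray,
    top: Topology,
    group_a: Selection,
    group_b: Selection,
    box: Sequence[float],
    cutoff: float = 3.0,
    mode: str = "heavy",
    _blocks=None,
) -> np.ndarray:
    """Binary residue-pair contact matrix for one frame.

    Entry (i, j) is True iff the minimum distance between any mode-filtered
    atom of residue i (group A) and residue j (group B) is ≤ cutoff.
    """
    if _blocks is None:
        _blocks = _prepare_blocks(top, group_a, group_b, mode)
    (ia, offa, _), (ib, offb, _) = _blocks
    d = pairwise_min_image_distance(frame[ia], frame[ib], box)
    # two-stage min-reduction over residue blocks
    d = np.minimum.reduceat(d, offa, axis=0)
    d = np.minimum.reduceat(d, offb, axis=1)
    return d <= cutoff


def _prepare_blocks(top, group_a, group_b, mode):
    ia = _mode_filter(top, group_a, mode)
    ib = _mode_filter(top, group_b, mode)
    if np.intersect1d(ia, ib).size:
        raise ValueError("contact groups must be disjoint")
    return _residue_blocks(top, ia), _residue_blocks(top, ib)


def contact_frequency(
    traj: Trajectory,
    top: Topology,
    group_a: Selection,
    group_b: Selection,
    cutoff: float = 3.0,
    mode: str = "heavy",
) -> ContactMap:
    """Per-pair mean of the binary contact matrix over all frames."""
    if traj.n_frames < 1:
        raise ValueError("trajectory has no frames")
    blocks = _prepare_blocks(top, group_a, group_b, mode)
    (_, _, rows), (_, _, cols) = blocks
    acc = np.zeros((len(rows), len(cols)), dtype=float)
    for t in range(traj.n_frames):
        acc += frame_contacts(traj.coordinates[t], top, group_a, group_b,
                              traj.box[t], cutoff, mode, _blocks=blocks)
    return ContactMap(rows=rows, cols=cols, frequency=acc / traj.n_frames,
                      n_frames=traj.n_frames, cutoff=cutoff, mode=mode)


def classify_persistence(
    cm: ContactMap, thresholds: Sequence[float] = DEFAULT_THRESHOLDS
) -> PersistenceLabels:
    """Assign each pair the highest tier whose threshold it strictly exceeds.

    Comparisons are strict ("over 60%", "above 90%"): a frequency exactly at
    a threshold falls below that tier.
    """
    th = tuple(thresholds)
    if len(th) != 4 or any(b <= a for a, b in zip(th, th[1:])) or \
            th[0] <= 0 or th[-1] >= 1:
        raise ValueError("thresholds must be 4 strictly increasing fractions in (0,1)")
    tiers = np.full(cm.frequency.shape, "none", dtype="U12")
    for t, name in zip(th, TIER_NAMES[1:]):
        tiers[cm.frequency > t] = name
    return PersistenceLabels(cm.rows, cm.cols, tiers, th)


def overlay_maps(cm_a: ContactMap, cm_b: ContactMap) -> np.ndarray:
    """Signed difference cm_a − cm_b (entries in [−1, 1]) for overlay plots
    comparing two systems on the same residue axes."""
    if cm_a.rows != cm_b.rows or cm_a.cols != cm_b.cols:
        raise ValueError("contact maps have mismatched residue axes")
    if cm_a.mode != cm_b.mode or cm_a.cutoff != cm_b.cutoff:
        warnings.warn("overlaying maps computed with different parameters")
    return cm_a.frequency - cm_b.frequency
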