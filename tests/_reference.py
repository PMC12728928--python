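"""Independent brute-force reference implementations used as oracles.

Everything here is deliberately naive (explicit loops, 27-image periodic
enumeration) and shares no code with the package's vectorized paths.
"""

import numpy as np

SHIFTS = np.array([(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                   for k in (-1, 0, 1)], dtype=float)


def brute_min_image_dist(a, b, box):
    """Minimum distance between two points over all 27 periodic images
    (points first wrapped into the primary cell)."""
    box = np.asarray(box, dtype=float)
    a = np.mod(np.asarray(a, dtype=float), box)
    b = np.mod(np.asarray(b, dtype=float), box)
    best = np.inf
    for s in SHIFTS:
        d = np.linalg.norm(a - b + s * box)
        best = min(best, d)
    return best


def brute_min_image_vec(a, b, box):
    """Displacement a−b realized by the nearest periodic image."""
    box = np.asarray(box, dtype=float)
    aw = np.mod(np.asarray(a, dtype=float), box)
    bw = np.mod(np.asarray(b, dtype=float), box)
    best, vec = np.inf, None
    for s in SHIFTS:
        v = aw - bw + s * box
        n = np.linalg.norm(v)
        if n < best:
            best, vec = n, v
    return vec


def residue_atoms(top, chain, resid, names=None):
    idx = [i for i in range(top.n_atoms)
           if top.chain_ids[i] == chain and top.residue_ids[i] == resid]
    if names is not None:
        idx = [i for i in idx if top.atom_names[i] in names]
    return idx


def brute_residue_contact(top, frame, box, res_a, res_b, cutoff, mode):
    ia = residue_atoms(top, *res_a)
    ib = residue_atoms(top, *res_b)
    if mode == "heavy":
        ia = [i for i in ia if top.elements[i] != "H"]
        ib = [i for i in ib if top.elements[i] != "H"]
    else:
        ia = [i for i in ia if top.atom_names[i] in ("CA", "BB")]
        ib = [i for i in ib if top.atom_names[i] in ("CA", "BB")]
    return any(brute_min_image_dist(frame[i], frame[j], box) <= cutoff
               for i in ia for j in ib)


def brute_hbond(top, frame, box, donor_res, acceptor_res,
                d_max=3.0, angle_min=150.0):
    """Any-H-bond decision between two residues, donor side first."""
    h_atoms = [i for i in range(top.n_atoms) if top.elements[i] == "H"]
    no_all = [i for i in range(top.n_atoms) if top.elements[i] in ("N", "O")]

    def hydrogens_of(d):
        out = []
        for h in h_atoms:
            dist = brute_min_image_dist(frame[d], frame[h], box)
            if dist <= 1.2 and all(
                    brute_min_image_dist(frame[o], frame[h], box) >= dist
                    for o in no_all if o != d):
                out.append(h)
        return out

    donors = [i for i in residue_atoms(top, *donor_res)
              if top.elements[i] in ("N", "O")]
    acceptors = [i for i in residue_atoms(top, *acceptor_res)
                 if top.elements[i] in ("N", "O")]
    for d in donors:
        for h in hydrogens_of(d):
            for a in acceptors:
                if brute_min_image_dist(frame[d], frame[a], box) > d_max:
                    continue
                v1 = brute_min_image_vec(frame[d], frame[h], box)
                v2 = brute_min_image_vec(frame[a], frame[h], box)
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= angle_min:
                    return True
    return False


RINGS = {
    "PHE": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TYR": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TRP": [["CG", "CD1", "NE1", "CE2", "CD2"],
            ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"]],
    "HIS": [["CG", "ND1", "CD2", "CE1", "NE2"]],
}


def brute_pipi_class(top, frame, box, res_a, res_b):
    """Best ring-pair class, precedence parallel > t_shaped > none."""
    def classify(ring_a, ring_b):
        ca, cb = frame[ring_a].mean(0), frame[ring_b].mean(0)
        na = np.cross(frame[ring_a[1]] - frame[ring_a[0]],
                      frame[ring_a[2]] - frame[ring_a[0]])
        nb = np.cross(frame[ring_b[1]] - frame[ring_b[0]],
                      frame[ring_b[2]] - frame[ring_b[0]])
        na, nb = na / np.linalg.norm(na), nb / np.linalg.norm(nb)
        dist = brute_min_image_dist(ca, cb, box)
        ang = np.degrees(np.arccos(np.clip(abs(np.dot(na, nb)), 0, 1)))
        if dist <= 6.5 and ang <= 30:
            return "parallel"
        if dist <= 6.5 and ang >= 60:
            return "t_shaped"
        return "none"

    rn_a = top.residue_names[residue_atoms(top, *res_a)[0]]
    rn_b = top.residue_names[residue_atoms(top, *res_b)[0]]
    results = []
    for names_a in RINGS[rn_a]:
        ra = residue_atoms(top, *res_a, names=names_a)
        for names_b in RINGS[rn_b]:
            rb = residue_atoms(top, *res_b, names=names_b)
            if len(ra) >= 3 and len(rb) >= 3:
                results.append(classify(ra, rb))
    order = {"parallel": 2, "t_shaped": 1, "none": 0}
    return max(results, key=lambda c: order[c])


def brute_hydrophobic(top, frame, box, res_a, res_b, cutoff=4.5):
    backbone = ("N", "CA", "C", "O", "OXT", "H", "HA", "BB")
    ca = [i for i in residue_atoms(top, *res_a)
          if top.elements[i] == "C" and top.atom_names[i] not in backbone]
    cb = [i for i in residue_atoms(top, *res_b)
          if top.elements[i] == "C" and top.atom_names[i] not in backbone]
    return any(brute_min_image_dist(frame[i], frame[j], box) <= cutoff
               for i in ca for j in cb)


def brute_salt_bridge(top, frame, box, basic_res, acidic_res, cutoff=3.2):
    basic_names = {"LYS": ["NZ"], "ARG": ["NH1", "NH2", "NE"],
                   "HSP": ["ND1", "NE2"], "HIP": ["ND1", "NE2"]}
    acidic_names = {"ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"]}
    rn_b = top.residue_names[residue_atoms(top, *basic_res)[0]]
    rn_a = top.residue_names[residue_atoms(top, *acidic_res)[0]]
    ni = residue_atoms(top, *basic_res, names=basic_names.get(rn_b, []))
    oi = residue_atoms(top, *acidic_res, names=acidic_names.get(rn_a, []))
    return any(brute_min_image_dist(frame[i], frame[j], box) <= cutoff
               for i in ni for j in oi)
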