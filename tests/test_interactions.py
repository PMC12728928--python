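import numpy as np
import pytest

from tmca import interactions as ia
from tmca import io_model as io
from tmca import synthetic_data as sd

from _reference import (
    brute_hbond,
    brute_hydrophobic,
    brute_pipi_class,
    brute_salt_bridge,
)

BOX = (60.0, 60.0, 60.0)


def _hexagon(center, normal, radius=1.39):
    normal = np.asarray(normal, dtype=float)
    normal /= np.linalg.norm(normal)
    ref = np.array([1.0, 0, 0]) if abs(normal[0]) < 0.9 else np.array([0, 1.0, 0])
    e1 = np.cross(normal, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    ang = np.linspace(0, 2 * np.pi, 7)[:-1]
    return np.asarray(center) + radius * (np.outer(np.cos(ang), e1)
                                          + np.outer(np.sin(ang), e2))


class TestHBondGeometry:
    """Constructed donor–H–acceptor geometries at the classifier boundaries."""

    def _frame(self, d_da, angle_deg):
        # donor N at origin, H at 1.0 Å along x; acceptor placed so that the
        # D–H–A angle at H equals angle_deg and |D-A| = d_da
        d = np.array([5.0, 5.0, 5.0])
        h = d + [1.0, 0, 0]
        # numerically solve for acceptor on the x-y plane
        theta = np.radians(angle_deg)
        # direction from H making angle theta with H->D direction (-x)
        direction = np.array([-np.cos(theta), np.sin(theta), 0.0])
        # distance along it so |d - a| == d_da
        from scipy.optimize import brentq
        f = lambda s: np.linalg.norm(h + s * direction - d) - d_da
        s = brentq(f, 1e-6, 10)
        return d, h, h + s * direction

    @pytest.mark.parametrize("d_da,angle,expected", [
        (2.9, 175.0, True),
        (2.9, 149.0, False),
        (2.9, 151.0, True),
        (3.05, 180.0, False),
    ])
    def test_boundaries(self, d_da, angle, expected):
        d, h, a = self._frame(d_da, angle)
        frame = np.vstack([d, h, a])
        top = _toy_topology(["N", "H", "O"])
        events = ia.find_hbonds(frame, top, donors=[0], acceptors=[2], box=BOX,
                                hydrogen_map={0: np.array([1])})
        assert bool(events) is expected

    def test_donor_without_hydrogen_warns_and_skips(self):
        top = _toy_topology(["N", "O"])
        frame = np.array([[5.0, 5, 5], [7.5, 5, 5]])
        with pytest.warns(UserWarning, match="no bonded hydrogen"):
            events = ia.find_hbonds(frame, top, donors=[0], acceptors=[1],
                                    box=BOX, hydrogen_map={})
        assert events == []


def _toy_topology(elements):
    """Minimal single-residue topology for classifier unit tests."""
    import MDAnalysis as mda
    from tmca.io_model import topology_from_universe
    n = len(elements)
    u = mda.Universe.empty(n, n_residues=1, atom_resindex=[0] * n,
                           trajectory=True)
    u.add_TopologyAttr("names", elements)
    u.add_TopologyAttr("resids", [1])
    u.add_TopologyAttr("resnames", ["ALA"])
    u.add_TopologyAttr("segids", ["A"])
    return topology_from_universe(u)


class TestRingPlane:
    def test_hexagon_centroid_and_normal(self):
        ring = _hexagon([2.0, 3.0, 4.0], [0, 0, 1])
        centroid, normal = ia.ring_plane(ring)
        assert centroid == pytest.approx([2.0, 3.0, 4.0], abs=1e-9)
        assert abs(normal[2]) == pytest.approx(1.0, abs=1e-9)

    def test_translation_equivariance(self):
        ring = _hexagon([0, 0, 0], [0, 1, 1])
        c0, n0 = ia.ring_plane(ring)
        c1, n1 = ia.ring_plane(ring + [10.0, -4.0, 2.5])
        assert c1 - c0 == pytest.approx([10.0, -4.0, 2.5], abs=1e-9)
        assert abs(np.dot(n0, n1)) == pytest.approx(1.0, abs=1e-12)

    def test_normal_orthogonal_to_svd_plane(self, rng):
        # random planar ring: normal must match the SVD plane fit
        normal_true = rng.normal(size=3)
        normal_true /= np.linalg.norm(normal_true)
        ring = _hexagon(rng.uniform(0, 10, 3), normal_true)
        ring += rng.normal(0, 1e-10, ring.shape)
        _, normal = ia.ring_plane(ring)
        centred = ring - ring.mean(axis=0)
        _, _, vh = np.linalg.svd(centred)
        assert abs(np.dot(normal, vh[2])) == pytest.approx(1.0, abs=1e-8)

    def test_collinear_ring_rejected(self):
        line = np.outer(np.arange(5), [1.0, 0, 0])
        with pytest.raises(ValueError, match="collinear"):
            ia.ring_plane(line)


class TestPiPiClassification:
    @pytest.mark.parametrize("dist,angle,expected", [
        (3.8, 0.0, "parallel"),
        (5.0, 90.0, "t_shaped"),
        (6.6, 0.0, "none"),     # beyond centroid cutoff
        (6.4, 0.0, "parallel"),
        (6.4, 29.0, "parallel"),
        (6.4, 31.0, "none"),    # gap between bands
        (6.4, 59.0, "none"),
        (6.4, 61.0, "t_shaped"),
    ])
    def test_boundary_geometries(self, dist, angle, expected):
        ring_a = _hexagon([10.0, 10, 10], [0, 0, 1])
        th = np.radians(angle)
        ring_b = _hexagon([10.0 + dist, 10, 10], [np.sin(th), 0, np.cos(th)])
        geom = ia.classify_pipi(ring_a, ring_b, BOX)
        assert geom.cls == expected
        assert geom.interplanar_angle == pytest.approx(angle, abs=1e-6)

    def test_angle_folding_maps_120_band(self):
        # 120° between normals folds to 60° -> still T-shaped
        ring_a = _hexagon([10.0, 10, 10], [0, 0, 1])
        th = np.radians(119.0)
        ring_b = _hexagon([14.0, 10, 10], [np.sin(th), 0, np.cos(th)])
        geom = ia.classify_pipi(ring_a, ring_b, BOX)
        assert geom.cls == "t_shaped"
        assert geom.interplanar_angle == pytest.approx(61.0, abs=1e-6)

    def test_planted_subclass_schedule(self, showcase):
        top, traj, _ = showcase
        p, t, none = ia.pipi_occupancy(traj, top, ("A", 194), ("B", 62))
        assert (p, t, none) == pytest.approx((0.30, 0.10, 0.60))
        assert p + t + none == pytest.approx(1.0)

    def test_nonaromatic_residue_rejected(self, showcase):
        top, traj, _ = showcase
        with pytest.raises(ValueError, match="not aromatic"):
            ia.pipi_occupancy(traj, top, ("A", 186), ("B", 62))  # Lys


class TestSaltBridgeAndHydrophobic:
    def test_salt_bridge_boundaries(self, showcase):
        top, traj, _ = showcase
        ridx = ia.ResidueIndex(top)
        frame = traj.coordinates[0].copy()
        nz = ridx.named(("B", 66), ["NH1", "NH2", "NE"])
        od = ridx.named(("A", 202), ["OE1", "OE2"])
        frame[nz] = [80.0, 80.0, 10.0]   # park basic and acidic groups far
        frame[od] = [10.0, 80.0, 80.0]   # away, and far from each other
        for d, expected in [(3.1, True), (3.3, False)]:
            frame[nz[0]] = [20.0, 20.0, 20.0]
            frame[od[0]] = [20.0 + d, 20.0, 20.0]
            assert ia.salt_bridge(frame, top, ("B", 66), ("A", 202),
                                  traj.box[0]) is expected

    def test_any_listed_pair_suffices(self, showcase):
        top, traj, _ = showcase
        ridx = ia.ResidueIndex(top)
        frame = traj.coordinates[0].copy()
        arg_n = ridx.named(("B", 66), ["NE", "NH1", "NH2"])
        glu_o = ridx.named(("A", 202), ["OE1", "OE2"])
        frame[arg_n] = [80.0, 80, 10]
        frame[glu_o] = [10.0, 80, 80]
        ne = ridx.named(("B", 66), ["NE"])[0]
        frame[ne] = [20.0, 20, 20]
        frame[glu_o[1]] = [23.1, 20, 20]   # NE–OE2 at 3.1 Å, others far
        assert ia.salt_bridge(frame, top, ("B", 66), ("A", 202), traj.box[0])

    def test_missing_charged_atoms_raise(self, showcase):
        top, traj, _ = showcase
        with pytest.raises(ValueError, match="no basic nitrogen"):
            # non-terminal Leu: no basic group (terminal N would count)
            ia.salt_bridge(traj.coordinates[0], top, ("A", 185), ("A", 202),
                           traj.box[0])

    def test_hydrophobic_boundaries_and_backbone_exclusion(self, showcase):
        top, traj, _ = showcase
        ridx = ia.ResidueIndex(top)
        frame = traj.coordinates[0].copy()
        # two Leu side chains: move every side-chain carbon far, then place
        # one CD1–CB pair at a controlled distance
        la = ridx.atoms(("A", 181))
        lb = ridx.atoms(("B", 41))
        frame[la] = [5.0, 5.0, 5.0]
        frame[lb] = [45.0, 45.0, 60.0]
        cd1 = ridx.named(("A", 181), ["CD1"])[0]
        cb = ridx.named(("B", 41), ["CB"])[0]
        for d, expected in [(4.4, True), (4.6, False)]:
            frame[cd1] = [30.0, 30, 30]
            frame[cb] = [30.0 + d, 30, 30]
            assert ia.hydrophobic_contact(frame, top, ("A", 181), ("B", 41),
                                          traj.box[0]) is expected
        # backbone CA–CA proximity alone must not count
        ca_a = ridx.named(("A", 181), ["CA"])[0]
        ca_b = ridx.named(("B", 41), ["CA"])[0]
        frame[cd1] = [5.0, 5, 5]
        frame[cb] = [45.0, 45, 60]
        frame[ca_a] = [40.0, 40, 40]
        frame[ca_b] = [44.0, 40, 40]
        assert not ia.hydrophobic_contact(frame, top, ("A", 181), ("B", 41),
                                          traj.box[0])

    def test_glycine_defined_false_with_warning(self):
        spec = sd.SyntheticSpec(n_frames=1, jitter_sigma=0.0,
                                sequences=("GL", "GL", "GL"),
                                first_resids=(1, 1, 1), resolution="aa-lite",
                                states=[sd.StateSpec(xy_separation=5.0)])
        top, traj, _ = sd.simulate(spec)
        with pytest.warns(UserWarning, match="hydrophobic contact defined False"):
            result = ia.hydrophobic_contact(traj.coordinates[0], top,
                                            ("A", 1), ("B", 1), traj.box[0])
        assert result is False


class TestOracleAgreement:
    """Every classifier decision matches the naive 27-image brute force on
    random jittered frames."""

    def test_salt_bridge(self, oracle_system):
        top, traj, _ = oracle_system
        for t in range(traj.n_frames):
            assert ia.salt_bridge(traj.coordinates[t], top, ("A", 2), ("B", 8),
                                  traj.box[t]) == \
                brute_salt_bridge(top, traj.coordinates[t], traj.box[t],
                                  ("A", 2), ("B", 8))

    def test_hydrophobic(self, oracle_system):
        top, traj, _ = oracle_system
        for t in range(traj.n_frames):
            assert ia.hydrophobic_contact(traj.coordinates[t], top,
                                          ("A", 1), ("B", 4), traj.box[t]) == \
                brute_hydrophobic(top, traj.coordinates[t], traj.box[t],
                                  ("A", 1), ("B", 4))

    def test_pipi(self, oracle_system):
        top, traj, _ = oracle_system
        ridx = ia.ResidueIndex(top)
        for t in range(traj.n_frames):
            got = ia.classify_pipi_residues(traj.coordinates[t], ridx,
                                            ("A", 9), ("B", 7), traj.box[t])
            assert got.cls == brute_pipi_class(top, traj.coordinates[t],
                                               traj.box[t], ("A", 9), ("B", 7))

    def test_hbond(self, oracle_system):
        top, traj, _ = oracle_system
        _, series = ia.hbond_occupancy(traj, top, ("A", 2), ("B", 2))
        for t in range(traj.n_frames):
            assert series[t] == brute_hbond(top, traj.coordinates[t],
                                            traj.box[t], ("A", 2), ("B", 2))

    def test_hbond_donor_acceptor_asymmetry(self, oracle_system):
        # H-bond criteria depend on donor/acceptor roles; the two directions
        # need not agree (unlike the symmetric classifiers)
        top, traj, _ = oracle_system
        occ_fwd, s_fwd = ia.hbond_occupancy(traj, top, ("A", 2), ("B", 2))
        occ_rev, s_rev = ia.hbond_occupancy(traj, top, ("B", 2), ("A", 2))
        assert not np.array_equal(s_fwd, s_rev)

    def test_symmetric_classifiers(self, oracle_system):
        top, traj, _ = oracle_system
        t = 7
        assert ia.salt_bridge(traj.coordinates[t], top, ("A", 2), ("B", 8),
                              traj.box[t]) == \
            brute_salt_bridge(top, traj.coordinates[t], traj.box[t],
                              ("A", 2), ("B", 8))
        assert ia.hydrophobic_contact(traj.coordinates[t], top, ("A", 1),
                                      ("B", 4), traj.box[t]) == \
            ia.hydrophobic_contact(traj.coordinates[t], top, ("B", 4),
                                   ("A", 1), traj.box[t])


class TestCoarseGrainedRefusal:
    @pytest.mark.parametrize("call", ["hbond", "pipi", "hydrophobic", "saltbridge"])
    def test_cg_input_raises_resolution_error(self, static_system, call):
        top, traj, _ = static_system  # CG: BB beads only
        frame, box = traj.coordinates[0], traj.box[0]
        with pytest.raises(io.ResolutionError, match="atom-resolved"):
            if call == "hbond":
                ia.hbond_occupancy(traj, top, ("A", 186), ("B", 50))
            elif call == "pipi":
                ia.pipi_occupancy(traj, top, ("A", 194), ("B", 62))
            elif call == "hydrophobic":
                ia.hydrophobic_contact(frame, top, ("A", 181), ("B", 41), box)
            else:
                ia.salt_bridge(frame, top, ("A", 186), ("B", 50), box)


class TestPartnerHistogram:
    def test_planted_none_one_both_schedule(self, showcase):
        top, traj, _ = showcase
        p = ia.hbond_partner_histogram(traj, top, ("A", 186), 50, ("B", "C"))
        assert p == pytest.approx((0.10, 0.40, 0.50))
        assert sum(p) == pytest.approx(1.0)

    def test_out_of_range_acceptors_all_none(self, showcase):
        top, traj, _ = showcase
        # W194 is not an H-bond landing site for the K186 donor schedule
        p = ia.hbond_partner_histogram(traj, top, ("A", 219), 75, ("B", "C"))
        assert p == (1.0, 0.0, 0.0)

    def test_requires_two_chains(self, showcase):
        top, traj, _ = showcase
        with pytest.raises(ValueError, match="two acceptor chains"):
            ia.hbond_partner_histogram(traj, top, ("A", 186), 50, ("B",))


class TestProfile:
    def test_planted_salt_bridge_occupancy(self, showcase):
        top, traj, _ = showcase
        df = ia.interaction_profile(traj, top,
                                    [("saltbridge", ("B", 66), ("A", 202))])
        assert df.loc[0, "occupancy"] == pytest.approx(0.70)

    def test_empty_pair_list(self, showcase):
        top, traj, _ = showcase
        assert ia.interaction_profile(traj, top, []).empty

    def test_invariant_under_frame_shuffle(self, showcase):
        top, traj, _ = showcase
        perm = np.random.default_rng(3).permutation(traj.n_frames)
        shuffled = io.Trajectory(coordinates=traj.coordinates[perm],
                                 box=traj.box[perm], times=traj.times.copy())
        pairs = [("saltbridge", ("B", 66), ("A", 202)),
                 ("pipi", ("A", 194), ("B", 62))]
        df1 = ia.interaction_profile(traj, top, pairs)
        df2 = ia.interaction_profile(shuffled, top, pairs)
        assert np.allclose(df1["occupancy"], df2["occupancy"])

    def test_replica_aggregation(self, showcase):
        top, traj, _ = showcase
        df = ia.interaction_profile(traj, top,
                                    [("saltbridge", ("B", 66), ("A", 202))])
        agg = ia.aggregate_replicas([df, df, df])
        assert agg.loc[0, "occupancy_mean"] == pytest.approx(0.70)
        assert agg.loc[0, "occupancy_sd"] == pytest.approx(0.0)
        assert agg.loc[0, "n_replicas"] == 3
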