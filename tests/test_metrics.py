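"""Conformation, hydration and permeation metrics against constructed
geometries and brute-force oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from bkgating.core import R_KCAL, Selection, Trajectory, select
from bkgating.metrics import (backbone_rmsd, charged_group_z_displacement,
                              count_permeation_events, count_pore_waters,
                              estimate_conductance, free_energy_surface_2d,
                              helix_com_displacement, helix_tilt_angle,
                              kabsch_superpose, membrane_thickness,
                              pore_radius_profile, residue_contact_map,
                              PORE_RADIUS_CAP, TimeSeries)
from bkgating.synthetic import (PoreScriptSpec, make_crossing_path,
                                make_retreating_path, script_pore_trajectory)

from conftest import bead_topology, single_frame


# --------------------------------------------------------------------------- #
# displacements
# --------------------------------------------------------------------------- #


def _arg_four_chains():
    topo = bead_topology(["CZ"] * 4, [210] * 4, resnames=["ARG"] * 4,
                         chains=list("ABCD"))
    base = np.array([[0.0, 0, 0], [10, 0, 0], [0, 10, 0], [10, 10, 0]])
    return topo, base


class TestChargedGroupDisplacement:
    def test_reference_frame_gives_zero(self):
        topo, base = _arg_four_chains()
        traj = Trajectory(np.stack([base, base]), np.array([50.0, 50, 50]))
        ts = charged_group_z_displacement(traj, topo, [210])[210]
        np.testing.assert_array_equal(ts.values, [0.0, 0.0])

    def test_scripted_8A_shift_all_chains(self):
        topo, base = _arg_four_chains()
        shifted = base + np.array([0, 0, 8.0])
        traj = Trajectory(np.stack([base, shifted]), np.array([50.0, 50, 50]))
        ts = charged_group_z_displacement(traj, topo, [210])[210]
        assert ts.values[1] == pytest.approx(8.0)

    def test_chain_average_is_hand_mean(self):
        topo, base = _arg_four_chains()
        moved = base.copy()
        moved[:, 2] += [7.0, 8.0, 9.0, 8.0]
        traj = Trajectory(np.stack([base, moved]), np.array([50.0, 50, 50]))
        ts = charged_group_z_displacement(traj, topo, [210])[210]
        assert ts.values[1] == pytest.approx(8.0)
        np.testing.assert_allclose(
            ts.per_chain.iloc[1, 1:].to_numpy(dtype=float), [7, 8, 9, 8])

    def test_missing_representative_atom_names_residue(self):
        topo = bead_topology(["CB"], [210], resnames=["ARG"])
        traj = single_frame(topo, np.zeros((1, 3)))
        with pytest.raises(Exception, match="210"):
            charged_group_z_displacement(traj, topo, [210])


class TestHelixCOM:
    def _s4_topo(self, n=8):
        return bead_topology(["CA"] * n, list(range(205, 205 + n)),
                             elements=["C"] * n)

    def test_rigid_z_translation(self):
        topo = self._s4_topo()
        base = np.random.default_rng(0).normal(size=(8, 3))
        traj = Trajectory(np.stack([base, base + [0, 0, 3.0]]),
                          np.array([50.0, 50, 50]))
        ts = helix_com_displacement(traj, topo, "S4")
        assert ts.values[1] == pytest.approx(3.0)

    def test_pure_rotation_about_com_is_zero(self):
        topo = self._s4_topo()
        base = np.random.default_rng(1).normal(size=(8, 3))
        com = base.mean(axis=0)
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        rot = (base - com) @ R.T + com
        traj = Trajectory(np.stack([base, rot]), np.array([50.0, 50, 50]))
        assert helix_com_displacement(traj, topo, "S4").values[1] == \
            pytest.approx(0.0, abs=1e-12)
        assert helix_com_displacement(traj, topo, "S4", axis="xy").values[1] \
            == pytest.approx(0.0, abs=1e-12)

    def test_mass_weighted_vs_geometric_offset(self):
        # two atoms C and S at x=0 and x=2: geometric COM at 1,
        # mass COM at 2*32.06/(12.011+32.06)
        topo = bead_topology(["C1", "S1"], [230, 231],
                             elements=["C", "S"])
        topo.helix_definitions = {"S5": (230, 231)}
        base = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        moved = base + [0, 0, 1.0]
        traj = Trajectory(np.stack([base, moved]), np.array([50.0, 50, 50]))
        # displacement identical, but COM positions differ by hand value
        geo = base.mean(axis=0)[0]
        mw = (12.011 * 0 + 32.06 * 2) / (12.011 + 32.06)
        assert geo == pytest.approx(1.0)
        assert mw == pytest.approx(2 * 32.06 / 44.071)
        for mass_weighted in (False, True):
            ts = helix_com_displacement(traj, topo, "S5",
                                        mass_weighted=mass_weighted)
            assert ts.values[1] == pytest.approx(1.0)

    def test_empty_helix_selection_errors(self):
        topo = self._s4_topo()
        with pytest.raises(Exception, match="S6"):
            helix_com_displacement(
                single_frame(topo, np.zeros((8, 3))), topo, "S6")


def _ideal_helix(n, tilt_deg, rise=1.5, radius=2.3):
    phase = np.arange(n) * np.radians(100.0)
    pts = np.c_[radius * np.cos(phase), radius * np.sin(phase),
                rise * np.arange(n)]
    t = np.radians(tilt_deg)
    R = np.array([[np.cos(t), 0, np.sin(t)], [0, 1, 0],
                  [-np.sin(t), 0, np.cos(t)]])
    return pts @ R.T


class TestTilt:
    def _topo(self, n=12):
        return bead_topology(["CA"] * n, list(range(313, 313 + n)))

    @pytest.mark.parametrize("tilt", [0.0, 90.0, 25.0])
    def test_constructed_tilt_recovered(self, tilt):
        n = 12
        traj = single_frame(self._topo(n), _ideal_helix(n, tilt))
        ts = helix_tilt_angle(traj, self._topo(n), "S6")
        assert ts.values[0] == pytest.approx(tilt, abs=0.5)

    def test_too_few_ca_rejected(self):
        topo = bead_topology(["CA"] * 3, [313, 314, 315])
        with pytest.raises(Exception, match=">=4"):
            helix_tilt_angle(single_frame(topo, np.zeros((3, 3))), topo, "S6")


def _quaternion_rmsd(mobile, ref):
    """Independent superposition oracle (Kearsley quaternion method)."""
    x = mobile - mobile.mean(axis=0)
    y = ref - ref.mean(axis=0)
    sm, sp = x - y, x + y
    K = np.zeros((4, 4))
    K[0, 0] = (sm ** 2).sum()
    K[1, 1] = (sm[:, 0] ** 2 + sp[:, 1] ** 2 + sp[:, 2] ** 2).sum()
    K[2, 2] = (sp[:, 0] ** 2 + sm[:, 1] ** 2 + sp[:, 2] ** 2).sum()
    K[3, 3] = (sp[:, 0] ** 2 + sp[:, 1] ** 2 + sm[:, 2] ** 2).sum()
    K[0, 1] = K[1, 0] = (sp[:, 1] * sm[:, 2] - sm[:, 1] * sp[:, 2]).sum()
    K[0, 2] = K[2, 0] = (sm[:, 0] * sp[:, 2] - sp[:, 0] * sm[:, 2]).sum()
    K[0, 3] = K[3, 0] = (sp[:, 0] * sm[:, 1] - sm[:, 0] * sp[:, 1]).sum()
    K[1, 2] = K[2, 1] = (sm[:, 0] * sm[:, 1] - sp[:, 0] * sp[:, 1]).sum()
    K[1, 3] = K[3, 1] = (sm[:, 0] * sm[:, 2] - sp[:, 0] * sp[:, 2]).sum()
    K[2, 3] = K[3, 2] = (sm[:, 1] * sm[:, 2] - sp[:, 1] * sp[:, 2]).sum()
    lam = np.linalg.eigvalsh(K)[0]
    return np.sqrt(max(lam, 0.0) / len(mobile))


class TestRMSD:
    def _setup(self, coords, ref):
        n = len(ref)
        topo = bead_topology(["CA"] * n, list(range(1, n + 1)))
        traj = single_frame(topo, coords)
        sel = Selection("all", np.arange(n))
        return traj, topo, sel

    def test_identical_coordinates_zero(self, rng):
        ref = rng.normal(size=(10, 3))
        traj, topo, sel = self._setup(ref, ref)
        assert backbone_rmsd(traj, topo, sel, ref).values[0] == \
            pytest.approx(0.0, abs=1e-12)

    def test_rigid_transform_removed_by_superposition(self, rng):
        ref = rng.normal(size=(10, 3))
        th = 1.1
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        moved = ref @ R.T + [5, -3, 2]
        traj, topo, sel = self._setup(moved, ref)
        assert backbone_rmsd(traj, topo, sel, ref,
                             superpose=True).values[0] < 1e-6
        assert backbone_rmsd(traj, topo, sel, ref,
                             superpose=False).values[0] > 1.0

    def test_matches_quaternion_oracle(self, rng):
        for _ in range(5):
            ref = rng.normal(size=(10, 3)) * 3
            mob = ref + rng.normal(size=(10, 3))
            traj, topo, sel = self._setup(mob, ref)
            got = backbone_rmsd(traj, topo, sel, ref).values[0]
            assert got == pytest.approx(_quaternion_rmsd(mob, ref), abs=1e-6)


# --------------------------------------------------------------------------- #
# contacts
# --------------------------------------------------------------------------- #


class TestContactMap:
    def _system(self, rng, n_res=5, frames=10):
        names, resids, resnames, chains, elements = [], [], [], [], []
        for r in range(1, n_res + 1):
            for nm, el in (("CA", "C"), ("CB", "C"), ("HB", "H")):
                names.append(nm)
                resids.append(r)
                resnames.append("ALA")
                chains.append("A")
                elements.append(el)
        topo = bead_topology(names, resids, resnames, chains,
                             elements=elements)
        coords = rng.uniform(0, 12, size=(frames, len(names), 3))
        return topo, Trajectory(coords, np.array([50.0, 50, 50]))

    def test_occupancy_rule_boundary(self):
        # residues within 5 Å in 8/10 frames -> contact; 7/10 -> none
        topo = bead_topology(["CA", "CA"], [1, 2], elements=["C", "C"])
        for hits, expect in ((8, True), (7, False)):
            coords = np.zeros((10, 2, 3))
            coords[:, 1, 0] = 4.0
            coords[hits:, 1, 0] = 9.0  # beyond cutoff in the remaining frames
            traj = Trajectory(coords, np.array([50.0, 50, 50]))
            sel = Selection("all", np.arange(2))
            contact, occ = residue_contact_map(traj, topo, sel, sel)
            assert occ.loc["A:1", "A:2"] == pytest.approx(hits / 10)
            assert bool(contact.loc["A:1", "A:2"]) is expect

    def test_against_brute_force_distance_scan(self, rng):
        topo, traj = self._system(rng)
        sel = Selection("all", np.arange(topo.n_atoms))
        contact, occ = residue_contact_map(traj, topo, sel, sel)
        heavy = topo.heavy_mask()
        resids = sorted(set(topo.residue_numbers.tolist()))
        for a in resids:
            for b in resids:
                if a == b:
                    continue
                ia = np.nonzero((topo.residue_numbers == a) & heavy)[0]
                ib = np.nonzero((topo.residue_numbers == b) & heavy)[0]
                n_in = sum(
                    cdist(traj.coordinates[f, ia],
                          traj.coordinates[f, ib]).min() <= 5.0
                    for f in range(traj.n_frames))
                assert occ.loc[f"A:{a}", f"A:{b}"] == \
                    pytest.approx(n_in / traj.n_frames)


# --------------------------------------------------------------------------- #
# pore geometry
# --------------------------------------------------------------------------- #


def _cylinder_system(R=8.0, r_bead=1.5, z_lo=-10, z_hi=10):
    coords = []
    for z in np.arange(z_lo, z_hi + 0.5, 1.0):
        for ang in np.arange(0, 2 * np.pi, np.pi / 8):
            coords.append([R * np.cos(ang), R * np.sin(ang), z])
    coords = np.array(coords)
    n = len(coords)
    topo = bead_topology([f"C{i}" for i in range(n)], list(range(1, n + 1)),
                         elements=["C"] * n, radii=np.full(n, r_bead))
    return topo, coords


class TestPoreProfile:
    def test_bead_cylinder_radius(self):
        topo, coords = _cylinder_system()
        prof = pore_radius_profile(coords, topo, axis_hint=(0.4, -0.3),
                                   z_range=(-5, 5), dz=1.0)
        np.testing.assert_allclose(prof.radius, 6.5, atol=0.05)

    def test_empty_slice_reports_cap(self):
        topo, coords = _cylinder_system(z_lo=-5, z_hi=5)
        prof = pore_radius_profile(coords, topo, z_range=(40, 42), dz=1.0)
        assert (prof.radius == PORE_RADIUS_CAP).all()

    def test_matches_fine_grid_oracle(self, rng):
        n = 25
        coords = rng.uniform(-6, 6, size=(n, 3))
        radii = rng.uniform(1.0, 2.0, size=n)
        topo = bead_topology([f"C{i}" for i in range(n)],
                             list(range(1, n + 1)), elements=["C"] * n,
                             radii=radii)
        z = 0.0
        prof = pore_radius_profile(coords, topo, z_range=(z, z + 0.1), dz=1.0,
                                   search_radius=4.0)
        # oracle: exhaustive 0.05 Å xy grid
        g = np.arange(-4, 4.001, 0.05)
        gx, gy = np.meshgrid(g, g)
        cand = np.c_[gx.ravel(), gy.ravel()]
        d = np.sqrt(((coords[:, None, :2] - cand[None]) ** 2).sum(axis=2)
                    + (coords[:, 2:3] - z) ** 2)
        oracle = (d - radii[:, None]).min(axis=0).max()
        assert prof.radius[0] == pytest.approx(min(max(oracle, 0),
                                                   PORE_RADIUS_CAP), abs=0.1)

    def test_removing_atom_never_shrinks_radius(self, rng):
        n = 20
        coords = rng.uniform(-6, 6, size=(n, 3))
        topo = bead_topology([f"C{i}" for i in range(n)],
                             list(range(1, n + 1)), elements=["C"] * n,
                             radii=np.full(n, 1.5))
        full = pore_radius_profile(coords, topo, z_range=(-2, 2), dz=1.0)
        topo2 = bead_topology([f"C{i}" for i in range(n - 1)],
                              list(range(1, n)), elements=["C"] * (n - 1),
                              radii=np.full(n - 1, 1.5))
        part = pore_radius_profile(coords[:-1], topo2, z_range=(-2, 2), dz=1.0)
        assert (part.radius >= full.radius - 1e-6).all()


class TestPoreWaters:
    def test_scripted_occupancy_counted_exactly(self):
        res = script_pore_trajectory(
            PoreScriptSpec(frames=5, n_pore_waters=30, seed=8))
        ts = count_pore_waters(res.trajectory, res.topology,
                               select(res.topology, "name OW"))
        np.testing.assert_array_equal(ts.values,
                                      res.ground_truth_pore_waters)

    def test_all_waters_above_upper_plane_zero(self):
        res = script_pore_trajectory(
            PoreScriptSpec(frames=3, n_pore_waters=0, n_bulk_waters=15,
                           seed=8))
        ts = count_pore_waters(res.trajectory, res.topology,
                               select(res.topology, "name OW"))
        np.testing.assert_array_equal(ts.values, 0)

    def test_against_point_in_cylinder_oracle(self, rng):
        res = script_pore_trajectory(
            PoreScriptSpec(frames=4, n_pore_waters=12, n_bulk_waters=25,
                           seed=13))
        ts = count_pore_waters(res.trajectory, res.topology,
                               select(res.topology, "name OW"),
                               lateral_radius=10.0)
        for f in range(4):
            w = res.trajectory.coordinates[f, res.water_indices]
            inside = ((w[:, 2] >= res.boundary_lower_z)
                      & (w[:, 2] <= res.boundary_upper_z)
                      & (np.hypot(w[:, 0], w[:, 1]) <= 10.0))
            assert ts.values[f] == inside.sum()


# --------------------------------------------------------------------------- #
# permeation & conductance
# --------------------------------------------------------------------------- #


def _oracle_events(z, lo, hi):
    """Brute-force double-crossing state machine on an unwrapped track."""
    events = 0
    state = None  # 'below' | 'above' | ('inside', came_from)
    for v in z:
        if v < lo:
            if state == ("inside", "above"):
                events += 1
            state = "below"
        elif v > hi:
            if state == ("inside", "below"):
                events += 1
            state = "above"
        else:
            if state in ("below", "above"):
                state = ("inside", state)
    return events


class TestPermeation:
    def _run(self, paths, expected=None, frames=None):
        frames = frames or len(paths[0])
        res = script_pore_trajectory(
            PoreScriptSpec(frames=frames, ion_paths=paths,
                           expected_crossings=expected or 0, seed=4))
        sel = select(res.topology, "name K")
        return count_permeation_events(res.trajectory, sel, -15.0, 5.0)

    def test_single_full_crossing(self):
        _, n = self._run([make_crossing_path(50, -30, 30)], 1)
        assert n == 1

    def test_oscillation_between_planes_not_counted(self):
        t = np.linspace(0, 6 * np.pi, 80)
        path = -5.0 + 8.0 * np.sin(t)  # oscillates inside/below, never exits up
        path = np.clip(path, -14.0, 4.0)
        _, n = self._run([path])
        assert n == 0

    def test_random_walk_matches_state_machine_oracle(self, rng):
        paths = [np.clip(np.cumsum(rng.normal(0, 4.0, 300)) - 25.0,
                         -45.0, 45.0) for _ in range(10)]
        events, n = self._run(paths, frames=300)
        oracle = sum(_oracle_events(p, -15.0, 5.0) for p in paths)
        assert n == oracle

    def test_time_reversal_symmetry(self, rng):
        paths = [np.clip(np.cumsum(rng.normal(0.5, 3.0, 200)) - 30.0,
                         -45.0, 45.0) for _ in range(5)]
        _, fwd = self._run(paths, frames=200)
        _, rev = self._run([p[::-1].copy() for p in paths], frames=200)
        assert fwd == rev

    def test_periodic_recycling_counts_each_crossing(self):
        # ion crosses, is wrapped back by the periodic box, crosses again
        z = np.concatenate([np.linspace(-30, 30, 40),
                            np.linspace(-30, 30, 40)])
        _, n = self._run([z], frames=80)
        assert n == 2


class TestConductance:
    def test_hand_value(self):
        # 10 events in 1 us at 750 mV: g = 10 e / (1 us * 750 mV) ≈ 2.14 pS
        assert estimate_conductance(10, 1000.0, 750.0) == \
            pytest.approx(2.136, abs=0.001)

    def test_zero_events(self):
        assert estimate_conductance(0, 1000.0, 750.0) == 0.0

    def test_doubling_duration_halves_g(self):
        g1 = estimate_conductance(7, 500.0, 300.0)
        g2 = estimate_conductance(7, 1000.0, 300.0)
        assert g2 == pytest.approx(g1 / 2)

    def test_zero_voltage_rejected(self):
        with pytest.raises(ValueError):
            estimate_conductance(1, 100.0, 0.0)


# --------------------------------------------------------------------------- #
# membrane & free-energy surfaces
# --------------------------------------------------------------------------- #


class TestMembraneThickness:
    def _sheets(self, rng=None, z=19.0, n=30, noise=0.0):
        coords = np.zeros((1, 2 * n, 3))
        coords[0, :n, 2] = z
        coords[0, n:, 2] = -z
        if rng is not None and noise:
            coords[0, :, 2] += rng.normal(0, noise, 2 * n)
        topo = bead_topology(["P"] * 2 * n, list(range(1, 2 * n + 1)),
                             elements=["P"] * 2 * n)
        return topo, Trajectory(coords, np.array([100.0, 100, 100]))

    def test_flat_sheets(self):
        topo, traj = self._sheets()
        sel = Selection("all", np.arange(topo.n_atoms))
        assert membrane_thickness(traj, topo, sel).values[0] == \
            pytest.approx(38.0)

    def test_translation_invariance(self):
        topo, traj = self._sheets()
        sel = Selection("all", np.arange(topo.n_atoms))
        t0 = membrane_thickness(traj, topo, sel).values[0]
        traj2 = Trajectory(traj.coordinates + np.array([0, 0, 11.0]),
                           traj.box[0])
        assert membrane_thickness(traj2, topo, sel).values[0] == \
            pytest.approx(t0)

    def test_noisy_sheets_match_hand_means(self, rng):
        topo, traj = self._sheets(rng, noise=1.5)
        sel = Selection("all", np.arange(topo.n_atoms))
        z = traj.coordinates[0, :, 2]
        hand = abs(z[z > z.mean()].mean() - z[z <= z.mean()].mean())
        assert membrane_thickness(traj, topo, sel).values[0] == \
            pytest.approx(hand)


class TestFreeEnergySurface:
    def test_single_occupied_bin(self):
        fes = free_energy_surface_2d(np.zeros((50, 2)), bin_width=1.0)
        assert fes.free_energy.min() == 0.0
        finite = np.isfinite(fes.free_energy)
        assert finite.sum() == 1

    def test_two_bin_delta_f_closed_form(self):
        # counts 100 and 10 at 300 K -> ΔF = RT ln 10 ≈ 1.37 kcal/mol
        xy = np.concatenate([np.tile([0.25, 0.25], (100, 1)),
                             np.tile([1.25, 0.25], (10, 1))])
        fes = free_energy_surface_2d(xy, temperature=300.0, bin_width=1.0,
                                     x_range=(0, 2), y_range=(0, 1))
        finite = fes.free_energy[np.isfinite(fes.free_energy)]
        assert sorted(finite) == pytest.approx(
            [0.0, R_KCAL * 300 * np.log(10)])

    def test_count_scaling_invariance(self, rng):
        xy = rng.normal(size=(200, 2))
        a = free_energy_surface_2d(xy, bin_width=0.5, x_range=(-3, 3),
                                   y_range=(-3, 3))
        b = free_energy_surface_2d(np.repeat(xy, 2, axis=0), bin_width=0.5,
                                   x_range=(-3, 3), y_range=(-3, 3))
        np.testing.assert_allclose(a.free_energy, b.free_energy)


def test_running_average_centered_window():
    ts = TimeSeries(np.arange(5.0), np.array([0.0, 1, 2, 3, 4]))
    np.testing.assert_allclose(ts.running_average(3),
                               [0.5, 1.0, 2.0, 3.0, 3.5])
    with pytest.raises(ValueError):
        ts.running_average(0)
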