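"""Tryptophan inventory, neighbor counts, SASA, and quencher screening."""

import numpy as np
import pytest

from unfoldscope import simulate, structure
from unfoldscope.errors import IncompleteResidueError, ResidueLookupError
from unfoldscope.structure import (
    DomainDefinition,
    ProteinStructure,
    assign_secondary_structure,
    compute_sasa,
    count_neighbors,
    find_tryptophans,
    microenv_report,
    relative_sasa,
    screen_quenchers,
    secondary_structure_fraction,
    select_other_subunit,
    select_polar,
)


def single_atoms(specs, chain_roles=None, ss=None):
    """Structure from (chain, resname, resnum, atom, element, xyz) tuples."""
    return ProteinStructure(
        chain=np.array([s[0] for s in specs], dtype=object),
        residue_name=np.array([s[1] for s in specs], dtype=object),
        residue_number=np.array([s[2] for s in specs], dtype=int),
        atom_name=np.array([s[3] for s in specs], dtype=object),
        element=np.array([s[4] for s in specs], dtype=object),
        coords=np.array([[s[5] for s in specs]], dtype=float),
        chain_roles=chain_roles,
        secondary_structure=ss,
    )


def trp_with_neighbor(distance, element="C", resname="GLY", atom="CA",
                      chain="B"):
    """A toy indole plus one foreign atom at an exact minimum distance."""
    ring = simulate.indole_template()
    specs = [("A", "TRP", 1, name, "N" if name.startswith("N") else "C",
              ring[name]) for name in ring]
    # place the foreign atom along +x from the ring atom nearest to +x
    outer = max(ring.values(), key=lambda v: v[0])
    specs.append((chain, resname, 2, atom, element,
                  outer + np.array([distance, 0.0, 0.0])))
    return single_atoms(specs)


class TestFindTryptophans:
    def test_sequence_position(self):
        assert find_tryptophans("ACDW") == [("A", 4)]

    def test_empty_sequence(self):
        assert find_tryptophans("") == []

    def test_multi_chain_mapping_ordered(self):
        hits = find_tryptophans({"B": "WAW", "A": "AWA"})
        assert hits == [("A", 2), ("B", 1), ("B", 3)]

    def test_unknown_residue_code_warns_and_skips(self):
        with pytest.warns(UserWarning):
            hits = find_tryptophans("AXW")
        assert hits == [("A", 3)]

    def test_structure_lookup(self, toy_pair):
        assert find_tryptophans(toy_pair) == [("A", 1), ("A", 2)]


class TestCountNeighbors:
    def test_boundary_inside_and_outside_cutoff(self):
        assert count_neighbors(trp_with_neighbor(6.9), ("A", 1), 7.0) == 1
        assert count_neighbors(trp_with_neighbor(7.1), ("A", 1), 7.0) == 0

    def test_own_residue_atoms_never_counted(self):
        st = trp_with_neighbor(100.0)
        assert count_neighbors(st, ("A", 1), 7.0) == 0

    def test_missing_residue_raises(self, toy_pair):
        with pytest.raises(ResidueLookupError):
            count_neighbors(toy_pair, ("A", 99))

    def test_matches_all_pairs_oracle_on_random_structures(self):
        for seed in range(10):
            st = simulate.build_toy_structure(simulate.ToyStructureSpec(
                n_background_atoms=150, seed=seed, placement_box=25.0,
            ))
            fast = count_neighbors(st, ("A", 1), 7.0)
            own = st.residue_mask("A", 1)
            xyz = st.coords[0]
            dmat = np.linalg.norm(
                xyz[~own][:, None, :] - xyz[own][None, :, :], axis=2
            )
            brute = int((dmat.min(axis=1) <= 7.0).sum())
            assert fast == brute

    def test_polar_subset_never_exceeds_total(self):
        for seed in range(5):
            st = simulate.build_toy_structure(simulate.ToyStructureSpec(
                n_background_atoms=100, seed=seed, placement_box=20.0,
            ))
            n_sigma = count_neighbors(st, ("A", 1), 7.0)
            n_pol = count_neighbors(st, ("A", 1), 7.0, selection=select_polar)
            assert 0 <= n_pol <= n_sigma

    def test_other_subunit_selection_uses_chain_roles(self):
        st = trp_with_neighbor(5.0)  # neighbor on chain B
        st.chain_roles = {"A": "alpha", "B": "beta"}
        n = count_neighbors(st, ("A", 1), 7.0,
                            reference="sidechain_atoms",
                            selection=select_other_subunit("A"))
        assert n == 1


class TestSasa:
    def test_isolated_atom_matches_analytic_sphere(self):
        # spec'd example: radius 1.9 A atom via the default-radius fallback
        st = single_atoms([("A", "UNK", 1, "X1", "XX", np.zeros(3))])
        with pytest.warns(UserWarning):
            per_atom, _ = compute_sasa(st, probe=1.4, default_radius=1.9)
        assert per_atom[0] == pytest.approx(4 * np.pi * 3.3**2, rel=0.01)

    def test_caged_atom_is_fully_buried(self):
        # carbon at origin enclosed by a tight icosahedral-ish cage
        pts = structure._sphere_points(64) * 2.2
        specs = [("A", "GLY", 1, "CA", "C", np.zeros(3))]
        specs += [("A", "GLY", 2 + i, "CA", "C", p)
                  for i, p in enumerate(pts)]
        per_atom, _ = compute_sasa(single_atoms(specs))
        assert per_atom[0] == 0.0

    def test_two_sphere_overlap_matches_dense_sampling_oracle(self):
        specs = [("A", "GLY", 1, "CA", "C", np.zeros(3)),
                 ("A", "GLY", 2, "CA", "C", np.array([2.5, 0.0, 0.0]))]
        st = single_atoms(specs)
        coarse, _ = compute_sasa(st, n_points=960)
        dense, _ = compute_sasa(st, n_points=20000)
        np.testing.assert_allclose(coarse, dense, rtol=0.02)

    def test_atom_never_exceeds_isolated_sphere(self):
        st = simulate.build_toy_structure(simulate.ToyStructureSpec(
            n_background_atoms=80, seed=2, placement_box=15.0,
        ))
        per_atom, _ = compute_sasa(st)
        radii = np.array([structure.VDW_RADII[e] for e in st.element]) + 1.4
        assert np.all(per_atom <= 4 * np.pi * radii**2 + 1e-9)

    def test_total_area_decreases_as_atoms_added(self):
        base = [("A", "TRP", 1, n, "N" if n.startswith("N") else "C", v)
                for n, v in simulate.indole_template().items()]
        areas = []
        extra = [np.array([3.0, 0, 0]), np.array([-3.0, 0, 0]),
                 np.array([0, 3.0, 0])]
        for k in range(len(extra) + 1):
            specs = base + [("A", "GLY", 10 + i, "CA", "C", extra[i])
                            for i in range(k)]
            _, per_res = compute_sasa(single_atoms(specs))
            areas.append(per_res[("A", 1)])
        assert np.all(np.diff(areas) < 0)

    def test_agrees_with_biotite_reference(self):
        biotite_struc = pytest.importorskip("biotite.structure")
        st = simulate.build_toy_structure(simulate.ToyStructureSpec(
            n_background_atoms=60, seed=5, placement_box=15.0,
        ))
        per_atom, _ = compute_sasa(st, n_points=4000)
        arr = biotite_struc.AtomArray(st.n_atoms)
        arr.coord = st.coords[0].astype(np.float32)
        arr.chain_id = st.chain.astype("U2")
        arr.res_id = st.residue_number
        arr.res_name = st.residue_name.astype("U3")
        arr.atom_name = st.atom_name.astype("U4")
        arr.element = st.element.astype("U2")
        ref = biotite_struc.sasa(
            arr, probe_radius=1.4, point_number=4000,
            vdw_radii="Single"  # element-based radii, as we use
        )
        # both are quadratures with differing vdW tables; compare loosely
        np.testing.assert_allclose(per_atom.sum(), ref.sum(), rtol=0.05)

    def test_relative_sasa_bounded_and_burial_ordering(self):
        # bare indole: fully exposed; the same indole inside a cage: buried
        ring = simulate.indole_template()
        base = [("A", "TRP", 1, n, "N" if n.startswith("N") else "C", v)
                for n, v in ring.items()]
        _, rel_free = relative_sasa(single_atoms(base), ("A", 1))
        cage = structure._sphere_points(128) * 5.0
        caged = base + [("A", "GLY", 10 + i, "CA", "C", p)
                        for i, p in enumerate(cage)]
        _, rel_caged = relative_sasa(single_atoms(caged), ("A", 1))
        assert 0.0 <= rel_caged <= 100.0
        assert rel_free == pytest.approx(100.0, abs=1e-6)
        assert rel_caged < 17.0 < 40.0 <= rel_free  # buried vs exposed


class TestRigidBodyInvariance:
    def test_descriptors_invariant_under_rotation_translation(self):
        from scipy.spatial.transform import Rotation

        st = simulate.build_toy_structure(simulate.ToyStructureSpec(
            n_background_atoms=120, seed=4, placement_box=20.0,
        ))
        rot = Rotation.from_euler("xyz", [31.0, -47.0, 112.0],
                                  degrees=True).as_matrix()
        moved = st.transformed(rot, np.array([11.0, -3.0, 7.5]))
        for s in (st, moved):
            s.chain_roles = {"A": "alpha"}
        assert count_neighbors(st, ("A", 1), 7.0) == count_neighbors(
            moved, ("A", 1), 7.0
        )
        a0, r0 = relative_sasa(st, ("A", 1))
        a1, r1 = relative_sasa(moved, ("A", 1))
        assert a1 == pytest.approx(a0, rel=0.02)
        assert r1 == pytest.approx(r0, abs=1.0)


class TestSecondaryStructure:
    def test_fraction_matches_hand_count_with_annotations(self):
        st = trp_with_neighbor(5.0)
        st2 = ProteinStructure(
            st.chain, st.residue_name, st.residue_number, st.atom_name,
            st.element, st.coords,
            secondary_structure={("B", 2): "H"},
        )
        # the single neighbor is in a helix: 1/1 -> 100%
        assert secondary_structure_fraction(st2, ("A", 1)) == 100.0

    def test_no_annotation_fallback_disabled_gives_missing(self):
        st = trp_with_neighbor(5.0)
        with pytest.warns(UserWarning):
            out = secondary_structure_fraction(st, ("A", 1), fallback=False)
        assert np.isnan(out)

    def test_mixed_labels_counted_exactly(self):
        ring = simulate.indole_template()
        specs = [("A", "TRP", 1, n, "N" if n.startswith("N") else "C", v)
                 for n, v in ring.items()]
        specs += [("A", "ALA", 2, "CA", "C", np.array([3.0, 0, 0])),
                  ("A", "ALA", 3, "CA", "C", np.array([-3.0, 0, 0])),
                  ("A", "ALA", 4, "CA", "C", np.array([0, 3.0, 0]))]
        st = single_atoms(specs, ss={("A", 2): "H", ("A", 3): "E"})
        # 2 of 3 neighbors in helix/strand
        assert secondary_structure_fraction(st, ("A", 1)) == pytest.approx(
            200.0 / 3.0
        )

    @staticmethod
    def _backbone_from_torsions(n_res, phi, psi):
        """Poly-ALA backbone from ideal internal coordinates (NeRF)."""

        def place(a, b, c, bond, angle_deg, torsion_deg):
            e1 = (c - b) / np.linalg.norm(c - b)
            n_vec = np.cross(b - a, e1)
            e3 = n_vec / np.linalg.norm(n_vec)
            e2 = np.cross(e3, e1)
            # this frame measures torsions offset by pi from the IUPAC
            # convention; compensate so callers pass IUPAC phi/psi
            theta = np.radians(angle_deg)
            tau = np.radians(torsion_deg + 180.0)
            return c + bond * (
                -np.cos(theta) * e1
                + np.sin(theta) * (np.cos(tau) * e2 + np.sin(tau) * e3)
            )

        atoms = {(1, "N"): np.zeros(3), (1, "CA"): np.array([1.458, 0, 0])}
        atoms[(1, "C")] = place(
            np.array([0, 1.0, 0]), atoms[(1, "N")], atoms[(1, "CA")],
            1.525, 111.2, 0.0,
        )
        for i in range(1, n_res):
            atoms[(i + 1, "N")] = place(atoms[(i, "N")], atoms[(i, "CA")],
                                        atoms[(i, "C")], 1.329, 116.2, psi)
            atoms[(i + 1, "CA")] = place(atoms[(i, "CA")], atoms[(i, "C")],
                                         atoms[(i + 1, "N")], 1.458, 121.7,
                                         180.0)
            atoms[(i + 1, "C")] = place(atoms[(i, "C")], atoms[(i + 1, "N")],
                                        atoms[(i + 1, "CA")], 1.525, 111.2,
                                        phi)
        return single_atoms([
            ("A", "ALA", i, name, "N" if name == "N" else "C", xyz)
            for (i, name), xyz in atoms.items()
        ])

    def test_dihedral_fallback_labels_ideal_helix_and_strand(self):
        helix = self._backbone_from_torsions(10, phi=-60.0, psi=-45.0)
        labels = assign_secondary_structure(helix)
        interior = [("A", i) for i in range(3, 9)]
        assert all(labels.get(k) == "H" for k in interior)
        strand = self._backbone_from_torsions(10, phi=-120.0, psi=130.0)
        labels = assign_secondary_structure(strand)
        assert all(labels.get(k) == "E" for k in interior)


class TestQuenchers:
    def test_carboxyl_oxygen_contact_reported(self):
        st = trp_with_neighbor(4.0, element="O", resname="ASP", atom="OD1")
        contacts = screen_quenchers(st, ("A", 1))
        assert len(contacts) == 1
        assert contacts[0].mechanism == "electron-transfer-carboxyl"
        assert contacts[0].distance == pytest.approx(4.0, abs=0.01)

    def test_cysteine_sulfur_at_4p4_reported(self):
        st = trp_with_neighbor(4.4, element="S", resname="CYS", atom="SG")
        contacts = screen_quenchers(st, ("A", 1))
        assert [c.mechanism for c in contacts] == ["electron-transfer-sulfur"]
        assert contacts[0].distance == pytest.approx(4.4, abs=0.01)

    def test_atoms_beyond_cutoff_ignored(self):
        st = trp_with_neighbor(6.0, element="O", resname="ASP", atom="OD1")
        assert screen_quenchers(st, ("A", 1), cutoff=5.5) == []

    def test_backbone_carbonyl_measured_from_ce3(self):
        ring = simulate.indole_template()
        specs = [("A", "TRP", 1, n, "N" if n.startswith("N") else "C", v)
                 for n, v in ring.items()]
        carbonyl = ring["CE3"] + np.array([0.0, -3.6, 0.0])
        specs.append(("A", "GLY", 2, "C", "C", carbonyl))
        contacts = screen_quenchers(single_atoms(specs), ("A", 1))
        assert [c.mechanism for c in contacts] == ["backbone-carbonyl"]
        assert contacts[0].distance == pytest.approx(3.6, abs=1e-6)

    def test_missing_ring_raises(self):
        st = single_atoms([("A", "TRP", 1, "CA", "C", np.zeros(3))])
        with pytest.raises(IncompleteResidueError):
            screen_quenchers(st, ("A", 1))


class TestMicroenvReport:
    def test_full_report_columns_and_multi_model_summary(self, toy_pair):
        traj = simulate.simulate_trajectory(toy_pair, 3, 0.05, seed=9)
        traj.chain_roles = {"A": "alpha"}
        rep = microenv_report(traj, domain=DomainDefinition("A", 1, 1),
                              n_points=240)
        assert set(rep.table.columns) >= {
            "n_sigma", "n_pol", "sasa_abs_A2", "sasa_rel_pct", "n_cterm",
            "n_sec_pct", "n_beta_sub",
        }
        assert len(rep.table) == 2 * 3  # two tryptophans, three models
        summary = rep.summary()
        assert len(summary) == 2
        assert "sasa_abs_A2_mean" in summary.columns
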