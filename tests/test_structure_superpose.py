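"""Monomer extraction, Kabsch superposition vs a quaternion oracle, clustering."""

import numpy as np
import pytest
import gemmi

from kinoprofile.structure_superpose import (
    AnchorSpec,
    ANCHOR_PRESETS,
    KinaseMonomer,
    RigidTransform,
    anchors_for,
    apply_transform,
    aromatic_centroids,
    centroid_clusters,
    ensemble_rmsd,
    extract_monomers,
    kabsch,
    superpose,
    write_pdb,
)
from kinoprofile.synthetic_data import simulate_superposition_set

ANCHORS = AnchorSpec((1, 4), (10, 30))


def quaternion_superpose(moving, reference):
    """Independent oracle: Horn's quaternion method for optimal rotation."""
    mc = moving - moving.mean(axis=0)
    rc = reference - reference.mean(axis=0)
    M = mc.T @ rc
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    vals, vecs = np.linalg.eigh(K)
    q = vecs[:, np.argmax(vals)]
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    moved = mc @ R.T
    return float(np.sqrt(((moved - rc) ** 2).sum(axis=1).mean()))


def rotation_z(deg):
    a = np.deg2rad(deg)
    return np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])


class TestExtraction:
    def test_two_chain_fixture_gives_two_monomers(self, tmp_path, rng):
        ref, members, _ = simulate_superposition_set(n_structures=1, n_atoms=12, seed=1)
        # write both as separate chains of one file
        st = gemmi.Structure()
        model = gemmi.Model("1")
        for cname, mono in (("A", ref), ("B", members[0])):
            chain = gemmi.Chain(cname)
            for r in mono.residues:
                res = gemmi.Residue()
                res.name = r.name
                res.seqid = gemmi.SeqId(r.seqid, " ")
                for a in r.atoms:
                    at = gemmi.Atom()
                    at.name = a.name
                    at.element = gemmi.Element(a.element)
                    at.pos = gemmi.Position(*a.pos)
                    res.add_atom(at)
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
        st.setup_entities()
        path = tmp_path / "two.pdb"
        st.write_pdb(str(path))
        monomers = extract_monomers(path)
        assert len(monomers) == 2
        assert all(len(m.residues) == 12 for m in monomers)

    def test_altloc_highest_occupancy_retained(self, tmp_path):
        pdb = (
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40 10.00           C\n"
            "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.60 10.00           C\n"
            "ATOM      3  CA  ALA A   2       1.000   1.000   1.000  1.00 10.00           C\n"
            "ATOM      4  CA  ALA A   3       2.000   1.000   1.000  1.00 10.00           C\n"
            "END\n"
        )
        path = tmp_path / "alt.pdb"
        path.write_text(pdb)
        (mono,) = extract_monomers(path)
        ca = mono.residue(1).atom("CA")
        assert ca.pos[0] == pytest.approx(5.0)  # altloc B, occ 0.6 wins
        assert ca.altloc == "B"

    def test_altloc_tie_goes_to_a(self, tmp_path):
        pdb = (
            "ATOM      1  CA BALA A   1       5.000   0.000   0.000  0.50 10.00           C\n"
            "ATOM      2  CA AALA A   1       0.000   0.000   0.000  0.50 10.00           C\n"
            "END\n"
        )
        path = tmp_path / "tie.pdb"
        path.write_text(pdb)
        (mono,) = extract_monomers(path)
        assert mono.residue(1).atom("CA").altloc == "A"

    def test_pdb_and_mmcif_renderings_identical(self, tmp_path):
        ref, _, _ = simulate_superposition_set(n_structures=1, n_atoms=10, seed=2)
        pdb_path = tmp_path / "m.pdb"
        write_pdb(ref, pdb_path)
        st = gemmi.read_structure(str(pdb_path))
        st.setup_entities()
        cif_path = tmp_path / "m.cif"
        st.make_mmcif_document().write_file(str(cif_path))
        (from_pdb,) = extract_monomers(pdb_path)
        (from_cif,) = extract_monomers(cif_path)
        assert [r.seqid for r in from_pdb.residues] == [r.seqid for r in from_cif.residues]
        np.testing.assert_allclose(from_pdb.all_coords(), from_cif.all_coords(), atol=1e-3)

    def test_waters_excluded_ligands_annotated(self, tmp_path):
        pdb = (
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00 10.00           C\n"
            "HETATM    2  O   HOH A 101       9.000   9.000   9.000  1.00 10.00           O\n"
            "HETATM    3  C1  STU A 201       3.000   3.000   3.000  1.00 10.00           C\n"
            "END\n"
        )
        path = tmp_path / "lig.pdb"
        path.write_text(pdb)
        (mono,) = extract_monomers(path)
        assert len(mono.residues) == 1
        assert mono.ligands == ["STU"]

    def test_unreadable_file_errors(self, tmp_path):
        with pytest.raises(IOError):
            extract_monomers(tmp_path / "missing.pdb")


class TestSuperpose:
    def test_self_superposition_is_identity(self):
        ref, _, _ = simulate_superposition_set(n_structures=1, n_atoms=40, seed=3)
        tr, rmsd = superpose(ref, ref, ANCHORS, ANCHORS)
        assert rmsd < 1e-10
        assert np.allclose(tr.rotation, np.eye(3), atol=1e-8)
        assert np.allclose(tr.translation, 0, atol=1e-8)

    def test_exact_rigid_recovery(self):
        ref, _, _ = simulate_superposition_set(n_structures=1, n_atoms=40, seed=4)
        known = RigidTransform(rotation_z(37.0), np.array([5.0, -3.0, 2.0]))
        moved = apply_transform(ref, known)
        tr, rmsd = superpose(moved, ref, ANCHORS, ANCHORS)
        assert rmsd < 1e-6
        # recovered transform inverts the applied one
        assert np.allclose(tr.rotation @ known.rotation, np.eye(3), atol=1e-8)

    def test_rotation_always_proper(self, rng):
        for _ in range(20):
            a = rng.normal(size=(10, 3))
            b = rng.normal(size=(10, 3))
            tr = kabsch(a, b)
            assert np.linalg.det(tr.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_near_reflective_configuration_stays_proper(self, rng):
        # flat (planar) point sets invite reflection solutions
        a = rng.normal(size=(12, 3))
        a[:, 2] = 0.0
        b = a.copy()
        b[:, 0] *= -1
        tr = kabsch(a, b)
        assert np.linalg.det(tr.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_rmsd_matches_quaternion_oracle_under_noise(self, rng):
        ref, _, _ = simulate_superposition_set(n_structures=1, n_atoms=40, seed=5)
        anchor_ref = ANCHORS.ca_coords(ref)  # 4 + 21 = 25 Cα
        for _ in range(100):
            noisy = anchor_ref + rng.normal(scale=0.2, size=anchor_ref.shape)
            tr = kabsch(noisy, anchor_ref)
            moved = tr.apply(noisy)
            rmsd = float(np.sqrt(((moved - anchor_ref) ** 2).sum(axis=1).mean()))
            oracle = quaternion_superpose(noisy, anchor_ref)
            assert rmsd == pytest.approx(oracle, abs=1e-8)

    def test_rmsd_invariant_under_rigid_pretransform(self, rng):
        ref, members, _ = simulate_superposition_set(n_structures=1, n_atoms=40,
                                                     noise_sd=0.3, seed=6)
        _, rmsd0 = superpose(members[0], ref, ANCHORS, ANCHORS)
        pre = RigidTransform(rotation_z(61.0), np.array([8.0, 1.0, -4.0]))
        _, rmsd1 = superpose(apply_transform(members[0], pre), ref, ANCHORS, ANCHORS)
        assert rmsd0 == pytest.approx(rmsd1, abs=1e-8)

    def test_rmsd_symmetric(self, rng):
        ref, members, _ = simulate_superposition_set(n_structures=1, n_atoms=40,
                                                     noise_sd=0.3, seed=7)
        _, ab = superpose(members[0], ref, ANCHORS, ANCHORS)
        _, ba = superpose(ref, members[0], ANCHORS, ANCHORS)
        assert ab == pytest.approx(ba, abs=1e-8)

    def test_too_few_anchor_atoms_errors(self):
        ref, _, _ = simulate_superposition_set(n_structures=1, n_atoms=40, seed=8)
        tiny = KinaseMonomer(source_id="t", residues=ref.residues[:2])
        with pytest.raises(ValueError):
            superpose(tiny, ref, ANCHORS, ANCHORS)


class TestEnsemble:
    def test_identical_copies_all_zero(self):
        ref, members, _ = simulate_superposition_set(n_structures=3, n_atoms=40,
                                                     noise_sd=0.0, seed=9)
        table, mean, superposed = ensemble_rmsd(members, ref, ANCHORS)
        assert np.allclose(table["anchor_rmsd_A"], 0.0, atol=1e-6)
        assert mean == pytest.approx(0.0, abs=1e-6)
        assert len(superposed) == 3

    def test_rmsd_ranking_follows_noise_level(self):
        ref, _, _ = simulate_superposition_set(n_structures=1, n_atoms=60, seed=10)
        rng = np.random.default_rng(10)
        members = []
        for noise in (0.05, 0.3, 1.0):
            coords = {r.seqid: r.atoms[0].pos + rng.normal(scale=noise, size=3)
                      for r in ref.residues}
            mem = apply_transform(ref, RigidTransform.identity())
            for r in mem.residues:
                r.atoms[0].pos = coords[r.seqid]
            mem.source_id = f"n{noise}"
            members.append(mem)
        table, mean, _ = ensemble_rmsd(members, ref, ANCHORS)
        assert list(table.sort_values("anchor_rmsd_A")["structure"]) == ["n0.05", "n0.3", "n1.0"]
        assert mean == pytest.approx(table["anchor_rmsd_A"].mean())


class TestCentroids:
    def test_ideal_ring_centroid_is_atom_mean(self):
        sites = [np.array([0.0, 0.0, 0.0])]
        ref, _, _ = simulate_superposition_set(n_structures=1, n_atoms=10,
                                               planted_centroid_sites=sites, seed=11)
        table = aromatic_centroids([ref], [1000])
        assert len(table) == 1
        ring = ref.residue(1000)
        mean = np.mean([a.pos for a in ring.atoms], axis=0)
        np.testing.assert_allclose(table[["x", "y", "z"]].to_numpy()[0], mean, atol=1e-12)

    def test_missing_residue_produces_no_row(self, caplog):
        ref, _, _ = simulate_superposition_set(n_structures=1, n_atoms=10, seed=12)
        with caplog.at_level("WARNING"):
            table = aromatic_centroids([ref], [999])
        assert table.empty

    def test_planted_sites_recovered_within_half_angstrom(self):
        sites = [np.array([0.0, 0.0, 0.0]), np.array([10.0, 0.0, 0.0])]
        ref, members, _ = simulate_superposition_set(
            n_structures=4, n_atoms=30, noise_sd=0.1, planted_centroid_sites=sites, seed=13
        )
        superposed = []
        for m in members:
            tr, _ = superpose(m, ref, ANCHORS, ANCHORS)
            superposed.append(apply_transform(m, tr))
        table = aromatic_centroids([ref] + superposed, [1000, 1001])
        for k, site in enumerate(sites):
            sub = table[table["residue"] == 1000 + k][["x", "y", "z"]].to_numpy()
            assert np.linalg.norm(sub - site, axis=1).max() < 0.5

    def test_two_planted_clusters_found_at_cutoff(self):
        sites = [np.array([0.0, 0.0, 0.0]), np.array([10.0, 0.0, 0.0])]
        ref, members, _ = simulate_superposition_set(
            n_structures=5, n_atoms=20, noise_sd=0.1, planted_centroid_sites=sites, seed=14
        )
        superposed = [apply_transform(m, superpose(m, ref, ANCHORS, ANCHORS)[0])
                      for m in members]
        table = aromatic_centroids([ref] + superposed, [1000, 1001])
        labels = centroid_clusters(table[["x", "y", "z"]].to_numpy(), cutoff=2.0)
        assert len(set(labels)) == 2
        by_site = table["residue"].to_numpy()
        assert len(set(labels[by_site == 1000])) == 1
        assert len(set(labels[by_site == 1001])) == 1

    def test_large_cutoff_single_cluster(self, rng):
        pts = rng.normal(size=(8, 3))
        assert len(set(centroid_clusters(pts, cutoff=1e6))) == 1

    def test_matches_connected_components_oracle(self, rng):
        import networkx as nx

        for _ in range(5):
            pts = rng.uniform(-5, 5, size=(20, 3))
            cutoff = 2.0
            labels = centroid_clusters(pts, cutoff)
            g = nx.Graph()
            g.add_nodes_from(range(20))
            for i in range(20):
                for j in range(i + 1, 20):
                    if np.linalg.norm(pts[i] - pts[j]) <= cutoff:
                        g.add_edge(i, j)
            components = {frozenset(c) for c in nx.connected_components(g)}
            ours = {frozenset(np.flatnonzero(labels == lab)) for lab in set(labels)}
            assert ours == components

    def test_labels_deterministic_lowest_member_first(self, rng):
        pts = np.array([[0, 0, 0], [100, 0, 0], [0.5, 0, 0], [100.5, 0, 0]])
        labels = centroid_clusters(pts, cutoff=2.0)
        assert labels[0] == 0 and labels[2] == 0
        assert labels[1] == 1 and labels[3] == 1


class TestAnchorPresets:
    def test_hinge_window_must_span_four_residues(self):
        with pytest.raises(ValueError):
            AnchorSpec((1196, 1200), (1308, 1324))
        with pytest.raises(ValueError):
            AnchorSpec((100, 103), (101, 120))  # overlap

    def test_presets_match_published_ranges(self):
        alk = ANCHOR_PRESETS["ALK"][0]
        assert alk.hinge_range == (1196, 1199) and alk.af_helix_range == (1308, 1324)
        met = ANCHOR_PRESETS["MET"][0]
        assert met.hinge_range == (1158, 1161) and met.af_helix_range == (1262, 1278)
        assert [s.hinge_range for s in ANCHOR_PRESETS["EGFR"]] == [(766, 769), (790, 793)]

    def test_egfr_numbering_convention_selected_by_presence(self):
        # monomer numbered in the precursor convention (790-793 hinge)
        from kinoprofile.structure_superpose import Atom, Residue

        def res(seqid):
            return Residue(seqid=seqid, icode="", name="ALA",
                           atoms=[Atom("CA", "C", np.zeros(3))])

        mono = KinaseMonomer(
            source_id="x_A",
            residues=[res(i) for i in range(790, 794)] + [res(i) for i in range(893, 910)],
        )
        spec = anchors_for("EGFR", mono)
        assert spec.hinge_range == (790, 793)
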