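"""Structure I/O, residue correspondence, and Kabsch superposition."""

import numpy as np
import pytest

from oracles import brute_force_min_rmsd, quaternion_superpose
from qtysol.structure import (
    Atom,
    Chain,
    CorrespondenceMap,
    DegenerateGeometryError,
    Residue,
    StructureModel,
    build_correspondence,
    kabsch,
    kabsch_superpose,
    read_structure,
    rmsd_report,
    superpose_points,
    write_pdb,
)
from qtysol.synth import make_helix, rotation_about_axis


def _tiny_model(numbers_names, chain_id="A", offset=0.0):
    residues = [
        Residue(num, name, [
            Atom("N", "N", [offset + 3.8 * i, 0.2, 0.0]),
            Atom("CA", "C", [offset + 3.8 * i + 1.0, 0.0, 0.5]),
            Atom("C", "C", [offset + 3.8 * i + 2.0, 0.3, 0.0]),
            Atom("O", "O", [offset + 3.8 * i + 2.2, 1.4, 0.0]),
        ])
        for i, (num, name) in enumerate(numbers_names)
    ]
    return StructureModel("tiny", [Chain(chain_id, residues)], source="synthetic")


class TestReadWrite:
    def test_pdb_round_trip_bit_exact(self, tmp_path, helix30):
        path = tmp_path / "helix.pdb"
        write_pdb(helix30, path)
        back = read_structure(path, fmt="pdb")
        assert back.chain_ids() == ["A"]
        assert len(back.chain("A")) == 30
        for res_a, res_b in zip(helix30.chain("A").residues, back.chain("A").residues):
            assert res_a.number == res_b.number and res_a.name == res_b.name
            assert np.array_equal(res_a.ca.xyz, res_b.ca.xyz)

    def test_mmcif_and_pdb_give_identical_models(self, tmp_path, helix30):
        import gemmi

        pdb_path = tmp_path / "m.pdb"
        write_pdb(helix30, pdb_path)
        st = gemmi.read_structure(str(pdb_path))
        st.setup_entities()
        cif_path = tmp_path / "m.cif"
        st.make_mmcif_document().write_file(str(cif_path))

        from_pdb = read_structure(pdb_path, fmt="pdb")
        from_cif = read_structure(cif_path, fmt="mmcif")
        for ca, cb in zip(from_pdb.chains, from_cif.chains):
            assert len(ca) == len(cb)
            for ra, rb in zip(ca.residues, cb.residues):
                assert (ra.number, ra.name) == (rb.number, rb.name)
                assert np.allclose(ra.ca.xyz, rb.ca.xyz)

    def test_altloc_resolved_to_highest_occupancy(self, tmp_path):
        lines = [
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N",
            "ATOM      2  CA AALA A   1       1.000   0.000   0.000  0.40  0.00           C",
            "ATOM      3  CA BALA A   1       2.000   0.000   0.000  0.60  0.00           C",
            "ATOM      4  C   ALA A   1       3.000   0.000   0.000  1.00  0.00           C",
            "END",
        ]
        path = tmp_path / "altloc.pdb"
        path.write_text("\n".join(lines) + "\n")
        model = read_structure(path, fmt="pdb")
        res = model.chain("A").residues[0]
        cas = [a for a in res.atoms if a.name == "CA"]
        assert len(cas) == 1
        assert cas[0].xyz[0] == pytest.approx(2.0)  # occupancy-major conformer

    def test_waters_and_ligands_excluded(self, tmp_path):
        lines = [
            "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C",
            "ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C",
            "HETATM    3  O   HOH A 101      10.000   0.000   0.000  1.00  0.00           O",
            "HETATM    4  FE  HEM A 201      12.000   0.000   0.000  1.00  0.00          FE",
            "END",
        ]
        path = tmp_path / "het.pdb"
        path.write_text("\n".join(lines) + "\n")
        model = read_structure(path, fmt="pdb")
        assert len(model.chain("A")) == 2

    def test_malformed_file_raises(self, tmp_path):
        path = tmp_path / "bad.cif"
        path.write_text("this is not a structure\n")
        with pytest.raises(ValueError):
            read_structure(path, fmt="mmcif")


class TestCorrespondence:
    def test_loop_gaps_dropped_from_model(self):
        names = [(i, "GLY") for i in range(1, 11)]
        reference = _tiny_model([(n, m) for n, m in names if n not in (5, 6)])
        model = _tiny_model(names)
        corr = build_correspondence(reference, model)
        assert len(corr.pairs) == 8
        assert corr.dropped_b == [("A", 5), ("A", 6)]
        assert corr.dropped_a == []

    def test_identical_models_fully_paired(self, helix30):
        corr = build_correspondence(helix30, helix30)
        assert len(corr.pairs) == 30
        assert corr.dropped_a == [] and corr.dropped_b == []

    def test_qty_substituted_residues_still_pair(self):
        reference = _tiny_model([(1, "LEU"), (2, "ILE"), (3, "VAL"), (4, "PHE")])
        model = _tiny_model([(1, "GLN"), (2, "THR"), (3, "THR"), (4, "TYR")])
        corr = build_correspondence(reference, model)
        assert len(corr.pairs) == 4

    def test_incompatible_identity_dropped(self):
        reference = _tiny_model([(1, "LEU"), (2, "TRP")])
        model = _tiny_model([(1, "GLN"), (2, "GLY")])
        corr = build_correspondence(reference, model)
        assert len(corr.pairs) == 1
        assert ("A", 2) in corr.dropped_a and ("A", 2) in corr.dropped_b

    def test_no_common_residues_is_an_error(self):
        reference = _tiny_model([(i, "GLY") for i in range(1, 5)])
        model = _tiny_model([(i, "GLY") for i in range(10, 14)])
        with pytest.raises(ValueError, match="no common residues"):
            build_correspondence(reference, model)

    def test_duplicate_residue_numbers_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            _tiny_model([(1, "GLY"), (1, "ALA")])


class TestKabsch:
    def test_identity_superposition(self, helix30):
        corr = build_correspondence(helix30, helix30)
        result = kabsch_superpose(corr, helix30, helix30)
        assert result.rmsd == pytest.approx(0.0, abs=1e-9)
        assert result.n_pairs == 30
        assert np.linalg.det(result.rotation) == pytest.approx(1.0, abs=1e-6)

    def test_rigid_transform_recovered(self, helix30):
        rot = rotation_about_axis((0, 0, 1), 90.0)
        moved = helix30.transformed(rot, np.array([5.0, 0.0, 0.0]))
        corr = build_correspondence(helix30, moved)
        result = kabsch_superpose(corr, helix30, moved)
        assert result.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(result.rotation @ result.rotation.T, np.eye(3), atol=1e-9)
        # recovered transform is the inverse of the applied one
        assert np.allclose(result.rotation, rot.T, atol=1e-9)

    def test_matches_quaternion_oracle_on_noisy_helix(self, rng):
        helix = make_helix(30)
        noisy = make_helix(30)
        for res in noisy.chains[0].residues:
            for atom in res.atoms:
                atom.xyz = atom.xyz + rng.normal(0.0, 0.5, 3)
        corr = build_correspondence(helix, noisy)
        result = kabsch_superpose(corr, helix, noisy)
        mov = np.array([r.ca.xyz for r in noisy.chains[0].residues])
        tgt = np.array([r.ca.xyz for r in helix.chains[0].residues])
        _, _, oracle_rmsd = quaternion_superpose(mov, tgt)
        assert result.rmsd == pytest.approx(oracle_rmsd, abs=1e-6)

    def test_rmsd_symmetry_and_rigid_invariance(self, rng):
        p = rng.normal(size=(20, 3))
        q = p + rng.normal(0.0, 0.4, (20, 3))
        _, _, ab = superpose_points(p, q)
        _, _, ba = superpose_points(q, p)
        assert ab == pytest.approx(ba, abs=1e-9)
        rot = rotation_about_axis((1, 1, 0), 37.0)
        _, _, pre = superpose_points(p @ rot.T + np.array([1, -2, 3]), q)
        assert pre == pytest.approx(ab, abs=1e-9)

    def test_small_point_sets_match_oracles(self, rng):
        p = rng.normal(size=(5, 3))
        q = p @ rotation_about_axis((0, 1, 0), 25.0).T + rng.normal(0, 0.2, (5, 3))
        _, _, kab = superpose_points(p, q)
        _, _, quat = quaternion_superpose(p, q)
        assert kab == pytest.approx(quat, abs=1e-6)
        # an exhaustive rotation grid can approach but never beat the optimum
        assert brute_force_min_rmsd(p, q, n_grid=24) >= kab - 1e-9

    def test_too_few_or_degenerate_points(self):
        two = _tiny_model([(1, "GLY"), (2, "GLY")])
        corr = build_correspondence(two, two)
        with pytest.raises(ValueError, match=">= 3"):
            kabsch_superpose(corr, two, two)
        collinear = _tiny_model([(i, "GLY") for i in range(1, 6)])
        for res in collinear.chain("A").residues:  # flatten CAs onto a line
            res.atom("CA").xyz = np.array([float(res.number), 0.0, 0.0])
        corr = build_correspondence(collinear, collinear)
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(corr, collinear, collinear)

    def test_outlier_rejection_drops_displaced_residue(self, helix30):
        import copy

        bent = copy.deepcopy(helix30)
        bent.chain("A").residues[0].atom("CA").xyz = np.array([50.0, 50.0, 50.0])
        corr = build_correspondence(helix30, bent)
        plain = kabsch_superpose(corr, helix30, bent)
        trimmed = kabsch_superpose(corr, helix30, bent, outlier_rejection=(2.0, 5))
        assert trimmed.rmsd < plain.rmsd
        assert ("A", 1) in trimmed.rejected
        assert trimmed.n_pairs == 29

    def test_removing_a_pair_never_increases_residual_sum(self, rng):
        p = rng.normal(size=(15, 3))
        q = p + rng.normal(0.0, 0.6, (15, 3))
        rot, trans = kabsch(p, q)
        full_ss = float(np.sum((p @ rot.T + trans - q) ** 2))
        for drop in range(15):
            keep = [i for i in range(15) if i != drop]
            rot_s, trans_s = kabsch(p[keep], q[keep])
            sub_ss = float(np.sum((p[keep] @ rot_s.T + trans_s - q[keep]) ** 2))
            assert sub_ss <= full_ss + 1e-9


class TestRmsdReport:
    def _result(self, rmsd):
        return type("R", (), {"rmsd": rmsd, "n_pairs": 10, "rejected": []})()

    def test_summary_rows(self):
        df = rmsd_report({
            "S1": self._result(0.3), "S2": self._result(0.5), "S3": self._result(1.3),
        })
        summary = df.set_index("subunit")["rmsd"]
        assert summary["min"] == pytest.approx(0.3)
        assert summary["median"] == pytest.approx(0.5)
        assert summary["max"] == pytest.approx(1.3)

    def test_single_result(self):
        df = rmsd_report({"only": self._result(0.7)})
        summary = df.set_index("subunit")["rmsd"]
        assert summary["min"] == summary["max"] == summary["median"] == pytest.approx(0.7)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rmsd_report({})
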