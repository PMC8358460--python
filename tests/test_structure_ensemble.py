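import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from shiftbind import structure_ensemble as se
from shiftbind import synthetic_data as syn
from oracles import oracle_superpose_rmsd


def _model(coords: dict):
    """Build a Model from {(res, atom): (resname, xyz)}."""
    atoms = {
        key: se.AtomRecord(1, "A", key[0], resname, key[1], tuple(map(float, xyz)))
        for key, (resname, xyz) in coords.items()
    }
    return se.Model(atoms)


def _rigid(xyz, angle_deg=37.0, axis=(1.0, 2.0, 0.5), trans=(3.0, -2.0, 7.0)):
    rot = Rotation.from_rotvec(
        np.deg2rad(angle_deg) * np.asarray(axis) / np.linalg.norm(axis)
    ).as_matrix()
    return np.asarray(xyz) @ rot.T + np.asarray(trans)


class TestSuperpose:
    def test_identity_for_identical_coordinates(self):
        xyz = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        rot, trans, rmsd = se.superpose(xyz, xyz)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(rot, np.eye(3), atol=1e-10)

    def test_recovers_applied_rigid_motion(self):
        rng = np.random.default_rng(0)
        xyz = rng.normal(size=(10, 3))
        moved = _rigid(xyz)
        rot, trans, rmsd = se.superpose(moved, xyz)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(moved @ rot.T + trans, xyz, atol=1e-9)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_matches_bruteforce_search_on_toys(self):
        """Four-point toys with one displaced atom: closed-form Kabsch RMSD
        equals a rotation-vector numerical search to 1e-6."""
        rng = np.random.default_rng(1)
        for k in range(4):
            ref = rng.normal(size=(4 + k, 3)) * 3.0
            mob = ref.copy()
            mob[0] += rng.normal(size=3)  # ~1 A displacement
            mob = _rigid(mob, angle_deg=20.0 + 10 * k)
            _, _, rmsd = se.superpose(mob, ref)
            assert rmsd == pytest.approx(
                oracle_superpose_rmsd(mob, ref, seed=k), abs=1e-6
            )

    def test_rejects_too_few_or_collinear_points(self):
        with pytest.raises(ValueError, match="at least 3"):
            se.superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(ValueError, match="collinear"):
            se.superpose(line, line)


class TestMeanCoordinateRmsd:
    def test_identical_models_give_zero(self):
        base = {
            (i, "CA"): ("ALA", (i * 1.8, (i % 3) * 1.1, math.sin(i)))
            for i in range(1, 8)
        }
        ens = se.ModelEnsemble([_model(base), _model(base), _model(base)])
        mean, sd = se.mean_coordinate_rmsd(ens, selection=lambda a: True)
        assert mean == pytest.approx(0.0, abs=1e-9)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_two_model_case_matches_independent_recomputation(self):
        """Two models differing in one atom: compare against an independent
        iteration built on scipy's align_vectors."""
        rng = np.random.default_rng(5)
        xyz1 = rng.normal(size=(12, 3)) * 4.0
        xyz2 = xyz1.copy()
        xyz2[3] += np.array([1.2, -0.4, 0.8])
        m1 = {(i + 1, "CA"): ("ALA", xyz1[i]) for i in range(12)}
        m2 = {(i + 1, "CA"): ("ALA", xyz2[i]) for i in range(12)}
        ens = se.ModelEnsemble([_model(m1), _model(m2)])
        mean, sd = se.mean_coordinate_rmsd(ens, selection=lambda a: True)

        # independent oracle iteration
        coords = [xyz1.copy(), xyz2.copy()]
        ref = coords[0].copy()
        for _ in range(200):
            fitted = []
            for c in coords:
                rot, rssd = Rotation.align_vectors(
                    ref - ref.mean(0), c - c.mean(0)
                )
                fitted.append(rot.apply(c - c.mean(0)) + ref.mean(0))
            new_ref = np.mean(fitted, axis=0)
            if np.abs(new_ref - ref).max() < 1e-9:
                ref = new_ref
                break
            ref = new_ref
            coords = fitted
        rmsds = [np.sqrt(((c - ref) ** 2).sum(1).mean()) for c in coords]
        assert mean == pytest.approx(np.mean(rmsds), abs=1e-6)
        assert sd == pytest.approx(np.std(rmsds, ddof=1), abs=1e-6)

    def test_invariant_under_common_rigid_motion(self, toy_ensemble):
        mean0, sd0 = se.mean_coordinate_rmsd(toy_ensemble)
        moved_models = []
        for m in toy_ensemble.models:
            atoms = {
                k: se.AtomRecord(
                    a.model_index, a.chain, a.res_num, a.res_name, a.atom_name,
                    tuple(_rigid(np.array(a.xyz), 63.0, (0.2, 1, 3), (11, -5, 2))),
                )
                for k, a in m.atoms.items()
            }
            moved_models.append(se.Model(atoms))
        mean1, sd1 = se.mean_coordinate_rmsd(se.ModelEnsemble(moved_models))
        assert mean1 == pytest.approx(mean0, abs=1e-9)
        assert sd1 == pytest.approx(sd0, abs=1e-9)

    def test_requires_two_models(self, toy_ensemble):
        with pytest.raises(ValueError, match="at least 2"):
            se.mean_coordinate_rmsd(se.ModelEnsemble(toy_ensemble.models[:1]))


class TestDetectDisulfides:
    def test_constructed_pairs_detected_exactly(self):
        coords = {
            (1, "SG"): ("CYS", (0.0, 0.0, 0.0)),
            (4, "SG"): ("CYS", (2.05, 0.0, 0.0)),
            (7, "SG"): ("CYS", (10.0, 0.0, 0.0)),
            (9, "SG"): ("CYS", (10.0, 2.05, 0.0)),
        }
        topo = se.detect_disulfides(_model(coords))
        assert topo.pairs == ((1, 4), (7, 9))
        assert topo.framework == "1-2,3-4"

    def test_no_cysteines_gives_empty_topology(self):
        topo = se.detect_disulfides(_model({(1, "CA"): ("ALA", (0, 0, 0))}))
        assert topo.pairs == () and topo.framework == ""

    def test_atom_order_invariance(self):
        coords = {
            (5, "SG"): ("CYS", (0.0, 0.0, 0.0)),
            (2, "SG"): ("CYS", (2.05, 0.0, 0.0)),
        }
        a = se.detect_disulfides(_model(coords))
        b = se.detect_disulfides(_model(dict(reversed(list(coords.items())))))
        assert a.pairs == b.pairs == ((2, 5),)

    def test_ambiguous_geometry_flagged_not_assigned(self):
        # SG2 closest to SG3, SG3 closest to SG4: SG2 has a sub-cutoff
        # partner but no mutual nearest
        coords = {
            (2, "SG"): ("CYS", (0.0, 0.0, 0.0)),
            (3, "SG"): ("CYS", (2.2, 0.0, 0.0)),
            (4, "SG"): ("CYS", (4.2, 0.0, 0.0)),
        }
        with pytest.raises(ValueError, match="ambiguous"):
            se.detect_disulfides(_model(coords))

    def test_toy_ensemble_realizes_native_framework(self, toy_ensemble):
        topo = se.detect_disulfides(toy_ensemble.models[0])
        assert topo.pairs == ((2, 19), (5, 28), (16, 33), (20, 35))
        assert topo.framework == "1-4,2-6,3-7,5-8"


class TestClassifyRestraints:
    def test_reported_category_counts_give_16_7_per_residue(self):
        restraints = []
        for count, sep in ((147, 0), (154, 1), (134, 3), (98, 7)):
            for k in range(count):
                i = 1 + (k % (36 - sep))
                restraints.append(se.RestraintRecord(i, i + sep))
        restraints += [
            se.RestraintRecord(2, 19, category="disulfide") for _ in range(12)
        ]
        restraints += [se.RestraintRecord(5, 5, category="dihedral") for _ in range(57)]
        stats = se.classify_restraints(restraints, 36)
        assert (stats.intra, stats.sequential, stats.medium, stats.long) == (
            147, 154, 134, 98,
        )
        assert stats.total_distance == 533
        assert round(stats.restraints_per_residue, 1) == 16.7

    def test_empty_list_gives_zeros(self):
        stats = se.classify_restraints([], 36)
        assert stats.total_distance == 0 and stats.restraints_per_residue == 0.0

    def test_random_lists_match_bruteforce_recount(self):
        rng = np.random.default_rng(13)
        restraints = []
        for _ in range(500):
            i, j = rng.integers(1, 37, size=2)
            cat = rng.choice(["distance", "distance", "disulfide", "dihedral"])
            restraints.append(se.RestraintRecord(int(i), int(j), category=str(cat)))
        stats = se.classify_restraints(restraints, 36)
        # exhaustive per-record recount
        bins = {"intra": 0, "sequential": 0, "medium": 0, "long": 0,
                "disulfide": 0, "dihedral": 0}
        for r in restraints:
            if r.category != "distance":
                bins[r.category] += 1
                continue
            s = abs(r.res_i - r.res_j)
            bins["intra" if s == 0 else "sequential" if s == 1
                 else "medium" if s < 5 else "long"] += 1
        assert (stats.intra, stats.sequential, stats.medium, stats.long) == (
            bins["intra"], bins["sequential"], bins["medium"], bins["long"],
        )
        assert stats.intra + stats.sequential + stats.medium + stats.long == (
            stats.total_distance
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            se.classify_restraints([se.RestraintRecord(1, 40)], 36)


class TestFindPatches:
    def _two_triplets(self, gap=25.0):
        coords = {}
        for i, off in enumerate(((0, 0, 0), (6, 0, 0), (3, 5, 0))):
            coords[(10 + i, "NZ")] = ("LYS", off)
        for i, off in enumerate(((0, 0, 0), (6, 0, 0), (3, 5, 0))):
            x, y, z = off
            coords[(20 + i, "CZ")] = ("ARG", (x + gap, y, z))
        return _model(coords)

    def test_two_separated_triplets_found(self):
        patches = se.find_patches(self._two_triplets(), "basic", link_cutoff=10.0)
        assert [p.members for p in patches] == [(10, 11, 12), (20, 21, 22)]

    def test_cutoff_below_all_distances_gives_no_patches(self):
        patches = se.find_patches(self._two_triplets(), "basic", link_cutoff=1.0)
        assert patches == []

    def test_shrinking_gap_merges_without_splitting(self):
        patches = se.find_patches(self._two_triplets(gap=8.0), "basic", link_cutoff=10.0)
        assert [p.members for p in patches] == [(10, 11, 12, 20, 21, 22)]

    def test_toy_ensemble_basic_and_hydrophobic_patches(self, toy_ensemble):
        model = toy_ensemble.models[0]
        basic = se.find_patches(model, "basic")
        assert [p.members for p in basic] == [(14, 15, 23), (25, 27, 36)]
        hydro = se.find_patches(model, "hydrophobic")
        assert [p.members for p in hydro] == [(6, 7, 8, 10)]

    def test_membership_invariant_to_residue_order(self):
        m = self._two_triplets()
        rev = se.Model(dict(reversed(list(m.atoms.items()))))
        assert [p.members for p in se.find_patches(m, "basic")] == [
            p.members for p in se.find_patches(rev, "basic")
        ]


class TestPdbIO:
    def test_three_model_fixture_reads_as_three(self, toy_ensemble):
        assert len(toy_ensemble) == 3

    def test_file_without_model_records_is_single_model(self, tmp_path):
        pdb = tmp_path / "single.pdb"
        pdb.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00"
            "           C\n"
            "ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00"
            "           C\nEND\n"
        )
        ens = se.read_pdb_ensemble(pdb)
        assert len(ens) == 1
        assert set(ens.models[0].atoms) == {(1, "CA"), (2, "CA")}

    def test_inconsistent_atom_sets_rejected(self):
        m1 = _model({(1, "CA"): ("ALA", (0, 0, 0)), (2, "CA"): ("ALA", (1, 0, 0))})
        m2 = _model({(1, "CA"): ("ALA", (0, 0, 0))})
        with pytest.raises(ValueError, match="differs"):
            se.ModelEnsemble([m1, m2])

    def test_restraint_tsv_round_trip(self, tmp_path):
        rs = [
            se.RestraintRecord(1, 5, "HA", "HN", 1.8, 5.0, "distance"),
            se.RestraintRecord(2, 19, "SG", "SG", 2.0, 2.1, "disulfide"),
        ]
        path = tmp_path / "r.tsv"
        se.write_restraint_tsv(rs, path)
        assert se.read_restraint_tsv(path) == rs
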