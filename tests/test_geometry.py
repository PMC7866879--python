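import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import random_rotation
from varimpact.geometry import (
    buried_surface,
    kabsch,
    load_radii,
    local_perturbation,
    rmsd_between,
    sasa,
)
from varimpact.structure_io import Atom, ResidueKey, Selection, Structure
from varimpact.synthetic_data import make_structure, make_variant_structure, VariantEffectSpec


def _atom(name, coords, element=None, serial=1, hetero=False):
    return Atom(serial=serial, name=name, element=element or name[0], coords=coords,
                is_hetero=hetero)


class TestKabsch:
    def test_rigid_motion_gives_zero_rmsd(self):
        rng = np.random.default_rng(0)
        ref = rng.standard_normal((10, 3))
        rot = Rotation.from_euler("z", 37, degrees=True).as_matrix()
        mobile = ref @ rot.T + np.array([5.0, -2.0, 1.0])
        res = kabsch(mobile, ref)
        assert res.rmsd < 1e-8
        assert abs(np.linalg.det(res.rotation) - 1.0) < 1e-8

    def test_identity_on_equal_inputs(self):
        pts = np.random.default_rng(1).standard_normal((6, 3))
        res = kabsch(pts, pts)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(res.translation, 0.0, atol=1e-10)

    def test_matches_scipy_align_vectors_oracle(self):
        """Independent closed-form oracle on a displaced tetrahedron."""
        ref = np.array([[0, 0, 0], [1, 0, 0], [0.5, 1, 0], [0.5, 0.5, 1.0]], dtype=float)
        mobile = ref.copy()
        mobile[3] += [0, 0, 1.0]
        res = kabsch(mobile, ref)
        rot, rssd = Rotation.align_vectors(
            ref - ref.mean(axis=0), mobile - mobile.mean(axis=0)
        )
        oracle_rmsd = rssd / np.sqrt(len(ref))
        assert res.rmsd == pytest.approx(oracle_rmsd, abs=1e-3)
        # no random rotation does better than the optimum
        rng = np.random.default_rng(2)
        mob_c = mobile - mobile.mean(axis=0)
        ref_c = ref - ref.mean(axis=0)
        for _ in range(200):
            r = random_rotation(rng)
            trial = np.sqrt(np.mean(np.sum((mob_c @ r.T - ref_c) ** 2, axis=1)))
            assert trial >= res.rmsd - 1e-9

    def test_degenerate_inputs_raise(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        with pytest.raises(ValueError, match="collinear"):
            kabsch(line, line + 1.0)
        with pytest.raises(ValueError):
            kabsch(line[:2], line[:2])

    def test_reflection_not_allowed(self):
        pts = np.random.default_rng(3).standard_normal((8, 3))
        mirrored = pts * np.array([1, 1, -1.0])
        res = kabsch(mirrored, pts)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)
        assert res.rmsd > 0.1


class TestRmsdBetween:
    def test_identical_is_zero(self, helix):
        assert rmsd_between(helix, helix) == 0.0

    def test_uniform_shift(self, helix):
        shifted = helix.with_coords(helix.coords + [1.0, 0, 0])
        assert rmsd_between(helix, shifted) == pytest.approx(1.0, abs=1e-12)
        assert rmsd_between(helix, shifted, superpose=True) == pytest.approx(0.0, abs=1e-8)

    def test_symmetry_and_triangle_bound(self, helix):
        rng = np.random.default_rng(4)
        b = helix.with_coords(helix.coords + 0.3 * rng.standard_normal((len(helix), 3)))
        c = helix.with_coords(helix.coords + 0.3 * rng.standard_normal((len(helix), 3)))
        assert rmsd_between(helix, b) == pytest.approx(rmsd_between(b, helix))
        assert rmsd_between(helix, c) <= rmsd_between(helix, b) + rmsd_between(b, c) + 1e-12

    def test_direct_sum_oracle(self, helix):
        rng = np.random.default_rng(5)
        disp = rng.standard_normal((len(helix), 3)) * 0.2
        b = helix.with_coords(helix.coords + disp)
        sel = Selection.backbone()
        idx = sel.indices(helix)
        expect = np.sqrt(np.mean(np.sum(disp[idx] ** 2, axis=1)))
        assert rmsd_between(helix, b, sel) == pytest.approx(expect, abs=1e-12)

    def test_mutated_side_chain_excluded(self, helix):
        variant = make_variant_structure(
            helix, VariantEffectSpec(label="v", site_resseq=3, new_resname="TRP")
        )
        # resname differs at 3 but backbone-only matching still works
        assert rmsd_between(helix, variant, Selection.backbone()) == pytest.approx(0.0)


class TestLocalPerturbation:
    def test_identical_structures_zero(self, helix):
        site = helix.find_residue("A", 6)
        res = local_perturbation(helix, helix, site, radius=10.0)
        assert res["rmsd"] == 0.0 and res["mean_disp"] == 0.0
        assert res["n_residues"] > 0

    def test_closed_form_single_residue_shift(self):
        """One shell residue shifted 0.5 Å among 10 -> RMSD = 0.5/sqrt(10)."""
        big = make_structure(30, "helix")
        site = big.find_residue("A", 15)
        from varimpact.structure_io import residues_within

        shell = sorted(residues_within(big, site, 10.0), key=lambda k: k.resseq)
        assert len(shell) >= 10
        shell = shell[:10]
        # restrict the universe to the site + exactly 10 shell residues
        wanted = {site.position} | {k.position for k in shell}
        idx = [i for i, k in enumerate(big.residue_keys) if k.position in wanted]
        small = Structure([big.atoms[i] for i in idx], [big.residue_keys[i] for i in idx])
        coords = small.coords.copy()
        moved = shell[0]
        for i, k in enumerate(small.residue_keys):
            if k.position == moved.position:
                coords[i] += [0.3, 0.4, 0.0]  # |d| = 0.5
        variant = small.with_coords(coords)
        res = local_perturbation(small, variant, site, radius=10.0)
        assert res["n_residues"] == 10
        assert res["rmsd"] == pytest.approx(0.5 / np.sqrt(10), abs=1e-6)
        assert res["mean_disp"] == pytest.approx(0.5 / 10, abs=1e-6)

    def test_empty_shell_raises(self, helix):
        site = helix.find_residue("A", 6)
        with pytest.raises(ValueError, match="radius"):
            local_perturbation(helix, helix, site, radius=0.01)


class TestSasa:
    def test_isolated_atom_closed_form(self):
        s = Structure([_atom("C", [0, 0, 0], "C")], [ResidueKey("A", 1, "", "ALA")])
        rep = sasa(s, probe=1.4, sphere_points=960)
        expect = 4 * np.pi * (1.70 + 1.4) ** 2
        assert rep.total == pytest.approx(expect, rel=0.01)
        assert rep.nonpolar == rep.total and rep.polar == 0.0

    def test_coincident_atoms(self):
        keys = [ResidueKey("A", 1, "", "ALA")] * 2
        s = Structure([_atom("C", [0, 0, 0]), _atom("C", [0, 0, 0], serial=2)], keys)
        one = sasa(Structure([_atom("C", [0, 0, 0])], keys[:1])).total
        assert sasa(s).total == pytest.approx(one, rel=0.01)

    def test_distant_atoms_additive(self):
        keys = [ResidueKey("A", 1, "", "ALA"), ResidueKey("A", 2, "", "ALA")]
        s = Structure([_atom("C", [0, 0, 0]), _atom("N", [50, 0, 0], "N", 2)], keys)
        rep = sasa(s)
        expect = 4 * np.pi * ((1.70 + 1.4) ** 2 + (1.55 + 1.4) ** 2)
        assert rep.total == pytest.approx(expect, rel=0.01)
        assert rep.polar == pytest.approx(4 * np.pi * (1.55 + 1.4) ** 2, rel=0.01)

    def test_total_is_polar_plus_nonpolar(self, helix):
        rep = sasa(helix)
        assert rep.total == pytest.approx(rep.polar + rep.nonpolar, abs=1e-6)

    def test_rigid_motion_invariance(self, helix):
        base = sasa(helix).total
        rot = Rotation.from_euler("xyz", [20, 40, 60], degrees=True).as_matrix()
        moved = helix.with_coords(helix.coords @ rot.T + [3.0, -1.0, 2.0])
        assert sasa(moved).total == pytest.approx(base, rel=0.005)

    def test_against_biopython_shrake_rupley(self, helix, tmp_path):
        """Independent Shrake-Rupley oracle with the same radii table."""
        bp = pytest.importorskip("Bio.PDB")
        from Bio.PDB.SASA import ShrakeRupley
        from varimpact.structure_io import write_pdb

        path = tmp_path / "helix.pdb"
        write_pdb(helix, path)
        structure = bp.PDBParser(QUIET=True).get_structure("s", str(path))
        sr = ShrakeRupley(probe_radius=1.4, n_points=960,
                          radii_dict={"C": 1.70, "N": 1.55, "O": 1.52})
        sr.compute(structure, level="S")
        oracle = structure.sasa
        mine = sasa(helix, radii=load_radii()).total
        assert mine == pytest.approx(oracle, rel=0.02)

    def test_unknown_element_without_default(self):
        s = Structure([_atom("XX", [0, 0, 0], "Xx")], [ResidueKey("A", 1, "", "UNK")])
        with pytest.raises(KeyError):
            sasa(s, radii={"C": 1.7})


class TestBuriedSurface:
    def two_part_complex(self, gap):
        keys = [ResidueKey("A", 1, "", "ALA"), ResidueKey("B", 1, "", "GLY")]
        atoms = [_atom("C", [0, 0, 0]), _atom("N", [gap, 0, 0], "N", 2)]
        s = Structure(atoms, keys)
        a = Selection(chains=frozenset({"A"}))
        b = Selection(chains=frozenset({"B"}))
        return s, a, b

    def test_no_contact_zero(self):
        s, a, b = self.two_part_complex(gap=50.0)
        res = buried_surface(s, a, b, convention="total")
        assert res["buried"] == pytest.approx(0.0, abs=1e-6)

    def test_total_is_twice_per_side(self):
        s, a, b = self.two_part_complex(gap=3.0)
        total = buried_surface(s, a, b, convention="total")
        per_side = buried_surface(s, a, b, convention="per_side")
        assert total["buried"] == pytest.approx(2 * per_side["buried"])
        assert total["polar"] == pytest.approx(2 * per_side["polar"])

    def test_recomputation_oracle(self):
        """Buried area equals three independently recomputed SASA terms."""
        s, a, b = self.two_part_complex(gap=3.0)
        res = buried_surface(s, a, b, convention="total")
        sasa_a = sasa(s.select(a)).total
        sasa_b = sasa(s.select(b)).total
        sasa_ab = sasa(s).total
        assert res["buried"] == pytest.approx(sasa_a + sasa_b - sasa_ab, abs=1e-9)
        assert res["buried"] > 10.0  # the contact actually buries surface
        assert res["polar"] + res["nonpolar"] == pytest.approx(res["buried"], abs=1e-6)

    def test_overlapping_selections_rejected(self, helix):
        sel = Selection.heavy()
        with pytest.raises(ValueError, match="overlap"):
            buried_surface(helix, sel, sel)
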