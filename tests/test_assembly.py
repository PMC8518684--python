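"""Isomer enumeration and 3D cage assembly."""

import itertools

import numpy as np
import pytest

import cagescreen as cs
from cagescreen.errors import SiteDetectionError, ValidationError


def orbit_oracle(n):
    """Exhaustive orbit computation over the 2^n U/D assignments under
    n-gon rotations, reflections and the global U<->D flip."""
    flip = {"U": "D", "D": "U"}

    def orbit(p):
        out = set()
        for q in (p, tuple(flip[c] for c in p)):
            for r in range(n):
                rot = q[r:] + q[:r]
                out.add(rot)
                out.add(rot[::-1])
        return out

    remaining = set(itertools.product("UD", repeat=n))
    count = 0
    while remaining:
        count += 1
        remaining -= orbit(next(iter(sorted(remaining))))
    return count


class TestIsomerEnumeration:
    def test_four_isomers_with_expected_patterns(self):
        specs = cs.enumerate_isomer_specs(cs.LigandSpec.from_id("5B4"))
        assert len(specs) == 4
        patterns = {s.orientation_pattern for s in specs}
        assert patterns == {
            ("U", "U", "U", "U"),
            ("U", "U", "U", "D"),
            ("U", "U", "D", "D"),
            ("U", "D", "U", "D"),
        }
        assert {s.isomer.value for s in specs} == {
            "all_up", "three_up_one_down", "cis", "trans",
        }

    @pytest.mark.parametrize("n", range(1, 7))
    def test_class_count_matches_brute_force_orbits(self, n):
        assert len(cs.orientation_classes(n)) == orbit_oracle(n)

    def test_sixteen_patterns_reduce_to_four_classes(self):
        reps = cs.orientation_classes(4)
        assert len(reps) == 4 == orbit_oracle(4)

    def test_symmetric_ligand_rejected(self):
        with pytest.raises(ValidationError):
            cs.LigandSpec("4", "B", "4")


class TestAssembleCage:
    def test_atom_count_is_conserved(self, ligand_5b4):
        spec = cs.enumerate_isomer_specs(ligand_5b4.spec)[0]
        cage = cs.assemble_cage(ligand_5b4, spec)
        assert cage.n_atoms == 2 + 4 * ligand_5b4.n_atoms
        assert [cage.atoms[i] for i in cage.pd_indices] == ["Pd", "Pd"]

    def test_all_up_puts_all_donor_a_on_one_pd(self, ligand_5b4):
        spec = cs.CageSpec(ligand_5b4.spec, cs.Isomer.ALL_UP)
        cage = cs.assemble_cage(ligand_5b4, spec)
        top = cage.sites[0]
        # each copy's donor_a is at offset 2 + k*nlig + donor_a
        nlig = ligand_5b4.n_atoms
        expected = tuple(2 + k * nlig + ligand_5b4.donor_a for k in range(4))
        assert top.nitrogens == expected

    def test_cis_flipped_ligands_are_adjacent(self, ligand_5b4):
        spec = cs.CageSpec(ligand_5b4.spec, cs.Isomer.CIS)
        assert spec.orientation_pattern == ("U", "U", "D", "D")
        cage = cs.assemble_cage(ligand_5b4, spec)
        nlig = ligand_5b4.n_atoms
        bottom = set(cage.sites[1].nitrogens)
        # copies 2 and 3 (cyclically adjacent) contribute donor_a down
        for k in (2, 3):
            assert 2 + k * nlig + ligand_5b4.donor_a in bottom

    def test_each_ligand_contributes_one_n_to_each_site(self, ligand_5b4):
        for iso in cs.Isomer:
            cage = cs.assemble_cage(ligand_5b4, cs.CageSpec(ligand_5b4.spec, iso))
            for sl in cage.ligand_slices:
                for site in cage.sites:
                    assert sum(1 for n in site.nitrogens if n in sl) == 1

    def test_assembly_is_deterministic(self, ligand_5b4):
        spec = cs.CageSpec(ligand_5b4.spec, cs.Isomer.TRANS)
        a = cs.assemble_cage(ligand_5b4, spec)
        b = cs.assemble_cage(ligand_5b4, spec)
        assert np.array_equal(a.coords, b.coords)

    def test_global_ud_flip_is_a_rigid_flip(self, ligand_5b4):
        """Relabelling every ligand end U<->D gives a cage superimposable
        on the original by a rigid flip (checked over dihedral copy
        permutations with exact atom correspondence)."""
        lig = ligand_5b4
        orig = cs.assemble_cage(lig, cs.CageSpec(lig.spec, cs.Isomer.CIS))
        flipped_pat = tuple("D" if o == "U" else "U" for o in ("U", "U", "D", "D"))
        flipped = cs.assemble_cage(
            lig, cs.CageSpec(lig.spec, cs.Isomer.CIS, flipped_pat)
        )
        nlig = lig.n_atoms

        def kabsch_rmsd(p, q):
            pc, qc = p - p.mean(0), q - q.mean(0)
            u, s, vt = np.linalg.svd(pc.T @ qc)
            d = np.sign(np.linalg.det(vt.T @ u.T))
            rot = vt.T @ np.diag([1, 1, d]) @ u.T
            return float(np.sqrt(np.mean(np.sum((qc - pc @ rot.T) ** 2, axis=1))))

        best = np.inf
        for rot_k in range(4):
            for refl in (False, True):
                perm_pd = [0, 1]
                order = [(k * (1 if not refl else -1) + rot_k) % 4 for k in range(4)]
                idx = perm_pd + [
                    2 + order[k] * nlig + a for k in range(4) for a in range(nlig)
                ]
                best = min(best, kabsch_rmsd(orig.coords, flipped.coords[idx]))
                idx_swapped = [1, 0] + idx[2:]
                best = min(best, kabsch_rmsd(orig.coords, flipped.coords[idx_swapped]))
        assert best < 1e-6

    def test_expanded_cage_donors_sit_at_bond_distance(self, ligand_5b4):
        cage = cs.assemble_cage(ligand_5b4, cs.CageSpec(ligand_5b4.spec, cs.Isomer.CIS))
        for site in cage.sites:
            pd = cage.coords[site.pd]
            for n in site.nitrogens:
                np.testing.assert_allclose(
                    np.linalg.norm(cage.coords[n] - pd), 2.05, atol=1e-8
                )


class TestIdentifySites:
    def test_round_trip_matches_assembly_bookkeeping(self, ligand_5b4):
        cage = cs.assemble_cage(ligand_5b4, cs.CageSpec(ligand_5b4.spec, cs.Isomer.CIS))
        found = cs.identify_pdn4_sites(cage)
        by_pd = {s.pd: set(s.nitrogens) for s in found}
        for site in cage.sites:
            assert by_pd[site.pd] == set(site.nitrogens)

    def test_ideal_fixture_sites(self, ideal):
        found = cs.identify_pdn4_sites(ideal.atoms, ideal.coords)
        assert [len(s.nitrogens) for s in found] == [4, 4]
        assert set(found[0].nitrogens).isdisjoint(found[1].nitrogens)

    def test_wrong_pd_count_raises(self, ideal):
        atoms = ["C" if a == "Pd" else a for a in ideal.atoms[:1]] + ideal.atoms[1:]
        with pytest.raises(SiteDetectionError):
            cs.identify_pdn4_sites(atoms, ideal.coords)

    def test_too_few_nitrogens_raises(self):
        atoms = ["Pd", "Pd", "N", "N"]
        coords = np.array([[0, 0, 0], [0, 0, 5], [2, 0, 0], [0, 2, 5.0]])
        with pytest.raises(SiteDetectionError):
            cs.identify_pdn4_sites(atoms, coords)
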