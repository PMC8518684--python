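"""Structural descriptors: plane fit, D_i, q_sqp, Pd-Pd, anisotropy, pore."""

import numpy as np
import pytest

import cagescreen as cs
from cagescreen.errors import ValidationError

from conftest import random_rigid_motion, tls_plane_oracle, transform_cage


class TestFitPlane:
    def test_coplanar_points_have_zero_residual(self):
        pts = np.array([[0, 0, 1], [1, 0, 1], [0, 1, 1], [1, 1, 1], [0.3, 0.7, 1.0]])
        plane = cs.fit_plane(pts)
        np.testing.assert_allclose(plane.distance(pts), 0.0, atol=1e-12)
        np.testing.assert_allclose(np.abs(plane.normal), [0, 0, 1], atol=1e-12)

    def test_matches_independent_tls_oracle_on_random_sets(self, rng):
        for _ in range(100):
            pts = rng.normal(scale=3.0, size=(5, 3))
            plane = cs.fit_plane(pts)
            _, _, rss_oracle = tls_plane_oracle(pts)
            rss = float(np.sum(plane.distance(pts) ** 2))
            assert abs(rss - rss_oracle) < 1e-10

    def test_square_plus_apex_plane_height(self):
        """4 square corners at z=0 and an apex at height h: the TLS plane
        is parallel to the square at h/5 (centroid property)."""
        h = 1.0
        pts = np.array([[1, 1, 0], [-1, 1, 0], [-1, -1, 0], [1, -1, 0], [0, 0, h]])
        plane = cs.fit_plane(pts)
        np.testing.assert_allclose(np.abs(plane.normal), [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(plane.offset / plane.normal[2], h / 5, atol=1e-12)

    def test_collinear_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValidationError):
            cs.fit_plane(pts)


def ideal_site(r=2.05):
    pd = np.zeros(3)
    ns = np.array([[r, 0, 0], [0, r, 0], [-r, 0, 0], [0, -r, 0.0]])
    return pd, ns


class TestPlaneDeviation:
    def test_planar_site_is_exactly_zero(self):
        pd, ns = ideal_site()
        assert cs.plane_deviation(pd, ns) == pytest.approx(0.0, abs=1e-12)

    def test_displaced_n_matches_svd_oracle(self):
        pd, ns = ideal_site()
        ns = ns.copy()
        ns[0, 2] += 0.10
        pts = np.vstack([ns, pd])
        normal, c, _ = tls_plane_oracle(pts)
        oracle = float(np.sum(np.abs((pts - c) @ normal)))
        assert cs.plane_deviation(pd, ns) == pytest.approx(oracle, abs=1e-10)

    def test_zero_iff_coplanar(self, rng):
        pd, ns = ideal_site()
        assert cs.plane_deviation(pd, ns) < 1e-12
        ns2 = ns.copy()
        ns2[1, 2] += 1e-3
        assert cs.plane_deviation(pd, ns2) > 1e-4


class TestSquarePlanarOrder:
    def test_ideal_square_planar_is_one(self):
        pd, ns = ideal_site()
        assert cs.square_planar_order(pd, ns) == 1.0

    def test_tetrahedral_site_value(self):
        """All six inter-donor angles are arccos(-1/3): direct evaluation
        of the order parameter gives 13/18."""
        pd = np.zeros(3)
        ns = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1.0]])
        assert cs.square_planar_order(pd, ns) == pytest.approx(13.0 / 18.0, abs=1e-12)

    def test_invariant_under_permutation_and_rotation(self, rng):
        pd, ns = ideal_site()
        ns = ns + rng.normal(scale=0.1, size=ns.shape)
        q0 = cs.square_planar_order(pd, ns)
        for _ in range(5):
            perm = rng.permutation(4)
            rot, trans = random_rigid_motion(rng)
            q = cs.square_planar_order(pd @ rot.T + trans, ns[perm] @ rot.T + trans)
            assert abs(q - q0) < 1e-12

    def test_strictly_decreases_towards_axial(self):
        """Rotating one N from in-plane toward the axial position
        monotonically degrades the square-planar order."""
        pd = np.zeros(3)
        r = 2.05
        values = []
        for ang in np.linspace(0, np.pi / 2, 20):
            ns = np.array(
                [
                    [r * np.cos(ang), 0, r * np.sin(ang)],
                    [0, r, 0],
                    [-r, 0, 0],
                    [0, -r, 0.0],
                ]
            )
            values.append(cs.square_planar_order(pd, ns))
        assert values[0] == 1.0
        assert all(b < a for a, b in zip(values, values[1:]))

    def test_coincident_n_rejected(self):
        pd, ns = ideal_site()
        ns = ns.copy()
        ns[0] = pd
        with pytest.raises(ValidationError):
            cs.square_planar_order(pd, ns)


class TestCageLevelMetrics:
    def test_pd_pd_distance(self):
        cage = cs.ideal_cage(cs.FixtureParams(pd_pd=10.0))
        assert cs.pd_pd_distance(cage) == pytest.approx(10.0, abs=1e-12)
        cage2 = cs.ideal_cage(cs.FixtureParams(pd_pd=11.3))
        assert cs.pd_pd_distance(cage2) == pytest.approx(11.3, abs=1e-12)

    def test_anisotropy_zero_for_collinear_normals(self, ideal):
        assert cs.anisotropy(ideal) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("tilt", [5.0, 10.0, 20.0])
    def test_anisotropy_matches_trigonometry_on_tilted_fixture(self, tilt):
        """One site tilted by alpha: its lateral contribution is
        |Pd-Pd| sin(alpha); the mean over both sites halves it."""
        p = cs.FixtureParams(pd_pd=10.0, tilt_angles=(tilt, 0.0))
        cage = cs.distorted_cage(p)
        expected = 10.0 * np.sin(np.deg2rad(tilt)) / 2.0
        assert cs.anisotropy(cage) == pytest.approx(expected, abs=1e-9)
        assert cs.anisotropy(cage, reduce="max") == pytest.approx(
            10.0 * np.sin(np.deg2rad(tilt)), abs=1e-9
        )

    def test_anisotropy_nonnegative(self, rng):
        for _ in range(10):
            p = cs.FixtureParams(
                tilt_angles=(float(rng.uniform(0, 30)), float(rng.uniform(0, 30))),
                lateral_offset=float(rng.uniform(0, 2)),
            )
            assert cs.anisotropy(cs.distorted_cage(p)) >= 0.0

    def test_pore_diameter_closed_form_shell(self):
        """8 identical atoms at radius R from their centroid: pore
        diameter is exactly 2 (R - vdW)."""
        from cagescreen.assembly import CageStructure, Site

        R = 5.0
        dirs = np.array(
            [[0.6, 0.0, 0.8], [0.0, 0.6, 0.8], [0.48, -0.6, 0.64], [1.0, 0.0, 0.0]]
        )
        dirs /= np.linalg.norm(dirs, axis=1)[:, None]
        # antipodal pairs: centroid exactly at the origin, all atoms at R
        pts = R * np.vstack([dirs, -dirs])
        cage = CageStructure(
            atoms=["C"] * 8, coords=pts, pd_indices=(0, 1), sites=[]
        )
        # bypass site checks: pore_diameter only needs atoms+coords
        assert cs.pore_diameter(cage) == pytest.approx(2 * (R - 1.70), abs=1e-9)

    def test_atom_at_centroid_floors_pore_at_zero(self, ideal):
        cage = ideal.copy()
        cage.atoms = cage.atoms + ["C"]
        cage.coords = np.vstack([cage.coords, cage.coords.mean(axis=0)])
        assert cs.pore_diameter(cage) == 0.0

    def test_missing_vdw_radius_names_element(self, ideal):
        cage = ideal.copy()
        cage.atoms[-1] = "Og"
        with pytest.raises(ValidationError, match="Og"):
            cs.pore_diameter(cage)


class TestComputeMetrics:
    def test_ideal_fixture_endpoints(self, ideal):
        rep = cs.compute_metrics(ideal)
        assert rep.q_sqp_min == 1.0
        assert rep.d_max == pytest.approx(0.0, abs=1e-12)
        assert rep.delta_pd == pytest.approx(0.0, abs=1e-12)
        assert rep.q_sqp_min == min(rep.q_sqp)
        assert rep.d_max == max(rep.d_i)

    def test_all_fields_finite_on_relaxed_assembly(self, ligand_5b4):
        cage = cs.assemble_cage(ligand_5b4, cs.CageSpec(ligand_5b4.spec, cs.Isomer.CIS))
        relaxed, _ = cs.toy_relax(cage, max_iter=10)
        rep = cs.compute_metrics(relaxed)
        for v in rep.as_dict().values():
            assert np.isfinite(v)

    def test_all_metrics_rigid_motion_invariant(self, rng):
        p = cs.FixtureParams(tilt_angles=(7.0, 3.0), n_out_of_plane=0.15,
                             lateral_offset=0.5)
        cage = cs.distorted_cage(p)
        rep0 = cs.compute_metrics(cage)
        for _ in range(5):
            rot, trans = random_rigid_motion(rng)
            rep = cs.compute_metrics(transform_cage(cage, rot, trans))
            for k, v in rep.as_dict().items():
                assert abs(v - rep0.as_dict()[k]) < 1e-9, k

    def test_distorted_fixture_matches_per_metric_oracles(self):
        p = cs.FixtureParams(pd_pd=10.0, tilt_angles=(10.0, 0.0), n_out_of_plane=0.2)
        cage = cs.distorted_cage(p)
        rep = cs.compute_metrics(cage)
        # D on the distorted site against the independent TLS oracle
        site = cage.sites[0]
        pts = np.vstack([cage.coords[list(site.nitrogens)], cage.coords[site.pd]])
        normal, c, _ = tls_plane_oracle(pts)
        assert rep.d_max == pytest.approx(float(np.sum(np.abs((pts - c) @ normal))),
                                          abs=1e-10)
        assert rep.pd_pd == pytest.approx(10.0, abs=1e-12)
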