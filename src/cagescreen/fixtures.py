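"""Parametric synthetic cage geometries with analytically known metrics.

These structures are chemically meaningless scaffolds whose distortions
are applied in closed form, so every structural metric has an exact
hand-computable value. They let the metric and ranking layers be tested
without any 3D embedder or external optimizer; their energetics carry
no chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assembly import CageStructure, Site


@dataclass
class FixtureParams:
    """Geometry of a synthetic Pd2(N4)2 fixture cage.

    ``tilt_angles`` rotates each site's N square (about the x axis
    through its Pd) so the site plane normal tilts off the Pd-Pd axis;
    ``n_out_of_plane`` displaces the first N of site 0 along z;
    ``lateral_offset`` shifts the second Pd along x.
    """

    pd_pd: float = 10.0
    pd_n_bond: float = 2.05
    tilt_angles: tuple[float, float] = (0.0, 0.0)  # degrees per site
    n_out_of_plane: float = 0.0  # Å
    lateral_offset: float = 0.0  # Å
    seed: int = 42
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.pd_pd <= 0 or self.pd_n_bond <= 0:
            raise ValueError("pd_pd and pd_n_bond must be positive")


def _rot_x(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def ideal_cage(params: FixtureParams | None = None) -> CageStructure:
    """Geometrically perfect fixture: both PdN4 sites are exact squares
    perpendicular to the Pd-Pd axis.

    Eight carbon scaffold atoms at the equator stand in for ligand
    backbones so centroid/pore computations are non-degenerate.
    """
    p = params or FixtureParams()
    half = p.pd_pd / 2.0
    atoms = ["Pd", "Pd"]
    coords = [np.array([0.0, 0.0, half]), np.array([0.0, 0.0, -half])]
    site_ns: list[list[int]] = [[], []]
    for s, z in ((0, half), (1, -half)):
        for k in range(4):
            ang = np.pi / 2 * k
            coords.append(
                np.array([p.pd_n_bond * np.cos(ang), p.pd_n_bond * np.sin(ang), z])
            )
            site_ns[s].append(len(atoms))
            atoms.append("N")
    scaffold_r = p.pd_n_bond + 2.5
    for k in range(8):
        ang = np.pi / 4 * k
        coords.append(np.array([scaffold_r * np.cos(ang), scaffold_r * np.sin(ang), 0.0]))
        atoms.append("C")
    cage = CageStructure(
        atoms=atoms,
        coords=np.asarray(coords),
        pd_indices=(0, 1),
        sites=[Site(0, tuple(site_ns[0])), Site(1, tuple(site_ns[1]))],
        spec=None,
        provenance="expanded",
        # one all-atom group: scaffold repulsion is not part of the game
        ligand_slices=[range(2, len(atoms))],
    )
    return cage


def distorted_cage(params: FixtureParams) -> CageStructure:
    """Ideal fixture plus controlled distortions, recorded in provenance.

    * ``tilt_angles[i]`` rotates site i's four N about the x axis
      through its Pd — the fitted plane normal then makes that angle
      with the Pd-Pd axis, so the anisotropy contribution of that site
      is exactly ``pd_pd * sin(tilt)``.
    * ``n_out_of_plane`` lifts the first N of site 0 along z.
    * ``lateral_offset`` shifts the bottom Pd along x.

    All distortion magnitudes are stored in ``params.provenance`` so
    tests can compute oracle values analytically.
    """
    cage = ideal_cage(params)
    coords = cage.coords
    for s, tilt in enumerate(params.tilt_angles):
        if tilt:
            R = _rot_x(tilt)
            pd = coords[cage.sites[s].pd]
            ns = list(cage.sites[s].nitrogens)
            coords[ns] = (coords[ns] - pd) @ R.T + pd
    if params.n_out_of_plane:
        coords[cage.sites[0].nitrogens[0], 2] += params.n_out_of_plane
    if params.lateral_offset:
        coords[1, 0] += params.lateral_offset
    params.provenance.update(
        tilt_angles=params.tilt_angles,
        n_out_of_plane=params.n_out_of_plane,
        lateral_offset=params.lateral_offset,
    )
    cage.coords = coords
    return cage
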