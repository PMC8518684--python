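"""Structural descriptors of Pd2L4 cages.

Two of these quantify how square-planar-like the most strained Pd(II)
centre is — the geometric-stability heuristics of the screen:

* ``D_i`` — for one PdN4 site, the sum of the unsigned perpendicular
  distances of the four N atoms and the Pd from their common
  least-squares plane; ``D_max`` is the larger of the two sites
  (0.0 Å = no deviation).
* ``q_sqp`` — square-planar order parameter built from the six pairwise
  angles between the four unit Pd->N vectors: the two largest angles are
  the trans pairs (ideal 180 deg), the remaining four the cis pairs
  (ideal 90 deg), and

      q_sqp = 1 - 1/2 [ 1/2 * sum_trans (cos t + 1)^2
                        + 1/4 * sum_cis  cos^2 t ]

  which is exactly 1 for a perfect square-planar site; ``q_sqp,min`` is
  the smaller of the two sites.

The remaining descriptors characterize cage shape and anisotropy:
Pd...Pd distance, the anisotropy ``Delta_Pd`` (lateral displacement of
each Pd from the axis through the other Pd along its PdN4 plane normal,
0 Å when both plane normals are collinear with the Pd-Pd vector), and
the pore diameter of a spherical probe centred at the atom centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assembly import CageStructure, Site, identify_pdn4_sites
from .errors import ValidationError
from .vdw import vdw_radius


@dataclass(frozen=True)
class Plane:
    """A plane in Hessian normal form: unit normal and signed offset."""

    normal: np.ndarray
    offset: float

    def distance(self, points: np.ndarray) -> np.ndarray:
        """Unsigned perpendicular distances of points to the plane."""
        return np.abs(np.asarray(points) @ self.normal - self.offset)


@dataclass
class MetricsReport:
    q_sqp: tuple[float, float]
    q_sqp_min: float
    d_i: tuple[float, float]
    d_max: float
    pd_pd: float
    delta_pd: float
    pore_diameter: float

    def as_dict(self) -> dict[str, float]:
        return {
            "q_sqp_1": self.q_sqp[0],
            "q_sqp_2": self.q_sqp[1],
            "q_sqp_min": self.q_sqp_min,
            "d_1": self.d_i[0],
            "d_2": self.d_i[1],
            "d_max": self.d_max,
            "pd_pd": self.pd_pd,
            "delta_pd": self.delta_pd,
            "pore_diameter": self.pore_diameter,
        }


def fit_plane(points: np.ndarray) -> Plane:
    """Total-least-squares plane through >= 3 points.

    Minimizes the sum of squared perpendicular distances (the plane
    passes through the centroid; the normal is the smallest principal
    axis of the centred coordinates). The normal sign is fixed by
    requiring a positive z component (then y, then x as tie-breaks).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 3:
        raise ValidationError("plane fit needs >= 3 points in 3D")
    centroid = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centroid)
    if s[1] < 1e-10:
        raise ValidationError("points are collinear; plane is undefined")
    normal = vt[2]
    for comp in (normal[2], normal[1], normal[0]):
        if abs(comp) > 1e-12:
            if comp < 0:
                normal = -normal
            break
    return Plane(normal=normal, offset=float(normal @ centroid))


def _site_coords(cage: CageStructure, site: Site) -> tuple[np.ndarray, np.ndarray]:
    pd = cage.coords[site.pd]
    ns = cage.coords[list(site.nitrogens)]
    return pd, ns


def plane_deviation(pd: np.ndarray, nitrogens: np.ndarray) -> float:
    """D_i: summed unsigned deviations of 4 N + Pd from their mean plane."""
    pts = np.vstack([nitrogens, pd])
    if pts.shape[0] != 5:
        raise ValidationError("a PdN4 site has exactly 4 N and 1 Pd")
    plane = fit_plane(pts)
    return float(plane.distance(pts).sum())


def square_planar_order(pd: np.ndarray, nitrogens: np.ndarray) -> float:
    """q_sqp of one PdN4 site (1.0 = ideal square planar), clamped to [0, 1]."""
    vecs = np.asarray(nitrogens, dtype=float) - np.asarray(pd, dtype=float)
    norms = np.linalg.norm(vecs, axis=1)
    if np.any(norms < 1e-8):
        raise ValidationError("N coincides with Pd; angles undefined")
    vecs = vecs / norms[:, None]
    cos = np.array(
        [np.clip(vecs[i] @ vecs[j], -1.0, 1.0) for i in range(4) for j in range(i + 1, 4)]
    )
    order = np.argsort(cos)  # two smallest cosines = two largest angles = trans
    trans, cis = cos[order[:2]], cos[order[2:]]
    q = 1.0 - 0.5 * (0.5 * np.sum((trans + 1.0) ** 2) + 0.25 * np.sum(cis**2))
    return float(np.clip(q, 0.0, 1.0))


def pd_pd_distance(cage: CageStructure) -> float:
    """Euclidean Pd...Pd distance (Å)."""
    i, j = cage.pd_indices
    return float(np.linalg.norm(cage.coords[i] - cage.coords[j]))


def anisotropy(cage: CageStructure, reduce: str = "mean") -> float:
    """Delta_Pd: displacement of the Pd centres from mutual perpendicular
    alignment with the PdN4 planes.

    For each site, an axis is dropped through its Pd along its fitted
    plane normal and the lateral (perpendicular) distance of the *other*
    Pd from that axis is measured; ``reduce`` selects the mean (default)
    or max of the two. Zero for an ideal symmetric cage.
    """
    if len(cage.sites) != 2:
        raise ValidationError("anisotropy needs both PdN4 sites")
    laterals = []
    for site, other in (cage.sites, cage.sites[::-1]):
        pd, ns = _site_coords(cage, site)
        normal = fit_plane(np.vstack([ns, pd])).normal
        rel = cage.coords[other.pd] - pd
        lateral = rel - normal * (rel @ normal)
        laterals.append(float(np.linalg.norm(lateral)))
    if reduce == "mean":
        return float(np.mean(laterals))
    if reduce == "max":
        return float(np.max(laterals))
    raise ValidationError(f"unknown reduction {reduce!r}")


def pore_diameter(cage: CageStructure, vdw_table: dict[str, float] | None = None) -> float:
    """Diameter of the largest spherical probe centred at the atom
    centroid that touches no atom's vdW sphere (floored at 0)."""
    coords = cage.coords
    centre = coords.mean(axis=0)
    radii = np.array([vdw_radius(el, vdw_table) for el in cage.atoms])
    gaps = np.linalg.norm(coords - centre, axis=1) - radii
    return float(max(0.0, 2.0 * gaps.min()))


def compute_metrics(
    cage: CageStructure, vdw_table: dict[str, float] | None = None
) -> MetricsReport:
    """All seven descriptors of one cage."""
    if len(cage.sites) != 2:
        cage.sites = identify_pdn4_sites(cage)
    q = []
    d = []
    for site in cage.sites:
        pd, ns = _site_coords(cage, site)
        q.append(square_planar_order(pd, ns))
        d.append(plane_deviation(pd, ns))
    return MetricsReport(
        q_sqp=(q[0], q[1]),
        q_sqp_min=min(q),
        d_i=(d[0], d[1]),
        d_max=max(d),
        pd_pd=pd_pd_distance(cage),
        delta_pd=anisotropy(cage),
        pore_diameter=pore_diameter(cage, vdw_table),
    )
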