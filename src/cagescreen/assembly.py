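"""Pd2L4 cage isomer enumeration and 3D assembly.

A lantern-type Pd2L4 cage has two square-planar Pd(II) centres on a
common axis, bridged by four ditopic ligands at the equator. When the
ligand's two ends are inequivalent, each ligand independently points one
end "up" (U) and one "down" (D). The 2^4 orientation patterns collapse,
under the square's rotations/reflections and the global up-down flip,
into exactly four configurational isomers: all-up (UUUU),
three-up-one-down (UUUD), cis (UUDD, flipped ligands adjacent) and trans
(UDUD, alternating).

Assembly places the two Pd ions on the z axis and four rigid copies of
the embedded ligand at equatorial positions 90 degrees apart, each
rotated about its own donor-donor axis so the nitrogen lone pairs point
at their target Pd. The result is an expanded, pre-optimization
structure; only subsequent relaxation gives chemically meaningful
geometry.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import SiteDetectionError, ValidationError
from .library import LigandSpec, LigandStructure

PD_N_BOND = 2.05  # typical Pd(II)-N(pyridyl) bond length, Å


class Isomer(str, Enum):
    ALL_UP = "all_up"
    THREE_UP_ONE_DOWN = "three_up_one_down"
    CIS = "cis"
    TRANS = "trans"


#: Canonical orientation pattern for each isomer (cyclic order around the
#: equator; cis has its two D ligands at adjacent positions).
PATTERN_BY_ISOMER: dict[Isomer, tuple[str, ...]] = {
    Isomer.ALL_UP: ("U", "U", "U", "U"),
    Isomer.THREE_UP_ONE_DOWN: ("U", "U", "U", "D"),
    Isomer.CIS: ("U", "U", "D", "D"),
    Isomer.TRANS: ("U", "D", "U", "D"),
}

ISOMER_BY_PATTERN = {p: iso for iso, p in PATTERN_BY_ISOMER.items()}


@dataclass(frozen=True)
class CageSpec:
    """One isomer of one ligand: the orientation pattern of its 4 ligands."""

    ligand: LigandSpec
    isomer: Isomer
    orientation_pattern: tuple[str, ...] = None

    def __post_init__(self):
        if self.orientation_pattern is None:
            object.__setattr__(
                self, "orientation_pattern", PATTERN_BY_ISOMER[self.isomer]
            )
        if any(o not in ("U", "D") for o in self.orientation_pattern):
            raise ValidationError("orientation pattern must be over {U, D}")

    @property
    def name(self) -> str:
        return f"{self.ligand.id}_{self.isomer.value}"


@dataclass
class Site:
    """A PdN4 coordination site: the Pd atom index and its 4 donor N."""

    pd: int
    nitrogens: tuple[int, int, int, int]


@dataclass
class CageStructure:
    """An assembled (or relaxed) 3D Pd2L4 structure."""

    atoms: list[str]
    coords: np.ndarray
    pd_indices: tuple[int, int]
    sites: list[Site]
    spec: CageSpec | None = None
    provenance: str = "expanded"
    #: per-ligand-copy atom index ranges (used for non-bonded exclusions
    #: and torsion moves); fixtures use a single all-atom group
    ligand_slices: list[range] = field(default_factory=list)
    #: rotatable bonds in cage indexing: (i, j, side-atom indices)
    rotors: list[tuple[int, int, tuple[int, ...]]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def copy(self) -> "CageStructure":
        return CageStructure(
            atoms=list(self.atoms),
            coords=self.coords.copy(),
            pd_indices=self.pd_indices,
            sites=[Site(s.pd, tuple(s.nitrogens)) for s in self.sites],
            spec=self.spec,
            provenance=self.provenance,
            ligand_slices=list(self.ligand_slices),
            rotors=list(self.rotors),
            warnings=list(self.warnings),
        )


def orientation_classes(n: int = 4) -> list[tuple[str, ...]]:
    """Symmetry-distinct U/D orientation patterns for an MnL(2n)-type ring.

    Patterns over {U, D}^n are grouped under the dihedral group of the
    n-gon (rotations + reflections) combined with the global U<->D flip;
    one lexicographically smallest representative per orbit is returned
    (U sorts before D).
    """
    if n < 1:
        raise ValidationError("need at least one ligand position")

    def orbit(p: tuple[str, ...]):
        flip = {"U": "D", "D": "U"}
        out = set()
        for q in (p, tuple(flip[c] for c in p)):
            for r in range(n):
                rot = q[r:] + q[:r]
                out.add(rot)
                out.add(rot[::-1])
        return out

    order = {"U": 0, "D": 1}
    seen: set[tuple[str, ...]] = set()
    reps = []
    for bits in sorted(
        itertools.product("UD", repeat=n), key=lambda p: [order[c] for c in p]
    ):
        if bits not in seen:
            reps.append(bits)
            seen |= orbit(bits)
    return reps


def enumerate_isomer_specs(ligand: LigandSpec) -> list[CageSpec]:
    """The four cage isomers of an unsymmetrical ligand.

    Raises if the ligand is symmetrical (identical arms), in which case
    all orientation patterns are equivalent and there is nothing to rank.
    """
    if ligand.coord_a == ligand.coord_b:
        raise ValidationError(
            f"ligand {ligand.id} is symmetrical; its cage has a single isomer"
        )
    reps = orientation_classes(4)
    assert len(reps) == 4
    return [CageSpec(ligand, ISOMER_BY_PATTERN[p], p) for p in reps]


def _rotation_to(v: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking unit vector v onto unit target."""
    c = float(np.dot(v, target))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        # 180 degrees about any axis perpendicular to v
        axis = np.cross(v, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(v, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return _axis_rotation(axis, np.pi)
    axis = np.cross(v, target)
    s = np.linalg.norm(axis)
    axis /= s
    return _axis_rotation(axis, float(np.arctan2(s, c)))


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    k = np.asarray(axis, dtype=float)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def assemble_cage(
    ligand: LigandStructure,
    spec: CageSpec,
    radius_scale: float = 1.0,
    pd_n_bond: float = PD_N_BOND,
) -> CageStructure:
    """Place Pd ions and 4 aligned ligand copies on the Pd2L4 topology.

    The Pd-Pd separation is ``radius_scale`` times the ligand's
    donor-donor distance; each ligand copy sits with its donor-donor
    axis vertical at equatorial radius ``pd_n_bond`` (so the initial
    donor-Pd distance is about one Pd-N bond length) and is spun about
    that axis so the donor lone pairs point at their Pd. Assembly is
    fully deterministic.
    """
    pat = spec.orientation_pattern
    if len(pat) != 4:
        raise ValidationError("Pd2L4 assembly requires a 4-position pattern")
    pa = ligand.coords[ligand.donor_a]
    pb = ligand.coords[ligand.donor_b]
    d = float(np.linalg.norm(pb - pa))
    if d < 1e-6:
        raise ValidationError("coincident donor atoms")
    h = radius_scale * d
    pd_top = np.array([0.0, 0.0, h / 2])
    pd_bottom = np.array([0.0, 0.0, -h / 2])

    atoms: list[str] = ["Pd", "Pd"]
    coords: list[np.ndarray] = [pd_top, pd_bottom]
    slices: list[range] = []
    rotors: list[tuple[int, int, tuple[int, ...]]] = []
    top_ns: list[int] = []
    bottom_ns: list[int] = []
    warnings: list[str] = []

    mid = 0.5 * (pa + pb)
    nlig = ligand.n_atoms
    for k, orient in enumerate(pat):
        theta = np.pi / 2 * k
        radial = np.array([np.cos(theta), np.sin(theta), 0.0])
        up_idx, dn_idx = (
            (ligand.donor_a, ligand.donor_b)
            if orient == "U"
            else (ligand.donor_b, ligand.donor_a)
        )
        # 1) orient donor-donor axis along z (up donor towards +z)
        u = (ligand.coords[dn_idx] - ligand.coords[up_idx]) / d
        rot0 = _rotation_to(u, np.array([0.0, 0.0, -1.0]))
        local = (ligand.coords - mid) @ rot0.T
        va = ligand.donor_vector_a @ rot0.T
        vb = ligand.donor_vector_b @ rot0.T
        vecs = {ligand.donor_a: va, ligand.donor_b: vb}
        # 2) translate donor axis to the equatorial position
        pos = local + radial * pd_n_bond
        # 3) spin about the (vertical) donor-donor axis so the lone
        #    pairs point at the Pd ions; a weak term pushing the ligand
        #    centroid outward breaks the tie for linear donor vectors.
        #    The objective is A cos(phi) + B sin(phi): maximized analytically.
        zax = np.array([0.0, 0.0, 1.0])
        A = B = 0.0
        for idx, target_pd in ((up_idx, pd_top), (dn_idx, pd_bottom)):
            t = target_pd - pos[idx]
            tn = np.linalg.norm(t)
            t = t / tn if tn > 1e-9 else -radial
            v = vecs[idx]
            v_par = zax * np.dot(zax, v)
            A += float(np.dot(v - v_par, t))
            B += float(np.dot(np.cross(zax, v), t))
        centroid = pos.mean(axis=0) - radial * pd_n_bond
        c_par = zax * np.dot(zax, centroid)
        c_perp = centroid - c_par
        cn = np.linalg.norm(c_perp)
        if cn > 1e-9:
            w = 1e-2
            A += w * float(np.dot(c_perp / cn, radial))
            B += w * float(np.dot(np.cross(zax, c_perp / cn), radial))
        phi = float(np.arctan2(B, A)) if (abs(A) > 1e-12 or abs(B) > 1e-12) else 0.0
        spin = _axis_rotation(zax, phi)
        pivot = radial * pd_n_bond
        pos = (pos - pivot) @ spin.T + pivot

        # alignment residual: mean misalignment of lone pairs with Pd
        resid = 0.0
        for idx, target_pd in ((up_idx, pd_top), (dn_idx, pd_bottom)):
            t = target_pd - pos[idx]
            t /= max(np.linalg.norm(t), 1e-9)
            v = spin @ vecs[idx]
            resid += 0.5 * (1.0 - float(np.dot(v, t)))
        if resid > 0.5:
            warnings.append(
                f"ligand copy {k}: donor alignment residual {resid:.2f}; "
                "relying on relaxation"
            )

        offset = len(atoms)
        atoms.extend(ligand.atoms)
        coords.extend(pos)
        slices.append(range(offset, offset + nlig))
        for i, j, side in ligand.rotatable_bonds:
            rotors.append((i + offset, j + offset, tuple(s + offset for s in side)))
        top_ns.append(offset + up_idx)
        bottom_ns.append(offset + dn_idx)

    return CageStructure(
        atoms=atoms,
        coords=np.asarray(coords, dtype=float),
        pd_indices=(0, 1),
        sites=[Site(0, tuple(top_ns)), Site(1, tuple(bottom_ns))],
        spec=spec,
        provenance="expanded",
        ligand_slices=slices,
        rotors=rotors,
        warnings=warnings,
    )


def identify_pdn4_sites(
    atoms: list[str] | CageStructure,
    coords: np.ndarray | None = None,
    cutoff: float = 2.6,
) -> list[Site]:
    """Locate the two PdN4 sites of a structure by distance.

    For each Pd, its site is the 4 nitrogen atoms within ``cutoff`` Å,
    falling back to the 4 nearest N for strained geometries; the two
    sites are forced to be disjoint by greedy nearest-first assignment.
    Accepts a :class:`CageStructure` or raw (atoms, coords).
    """
    if isinstance(atoms, CageStructure):
        coords = atoms.coords
        atoms = atoms.atoms
    coords = np.asarray(coords, dtype=float)
    pds = [i for i, el in enumerate(atoms) if el == "Pd"]
    if len(pds) != 2:
        raise SiteDetectionError(f"expected exactly 2 Pd atoms, found {len(pds)}")
    ns = [i for i, el in enumerate(atoms) if el == "N"]
    if len(ns) < 8:
        raise SiteDetectionError(f"expected at least 8 N atoms, found {len(ns)}")
    pairs = sorted(
        (float(np.linalg.norm(coords[n] - coords[pd])), n, pd)
        for pd in pds
        for n in ns
    )
    assigned: dict[int, list[int]] = {pd: [] for pd in pds}
    used: set[int] = set()
    for dist, n, pd in pairs:
        if n in used or len(assigned[pd]) == 4:
            continue
        assigned[pd].append(n)
        used.add(n)
        if all(len(v) == 4 for v in assigned.values()):
            break
    for pd in pds:
        if len(assigned[pd]) < 4:
            raise SiteDetectionError(
                f"Pd atom {pd}: fewer than 4 N atoms available for its site"
            )
    # the cutoff is advisory: for strained geometries the nearest 4 stand
    return [Site(pd, tuple(assigned[pd])) for pd in pds]
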