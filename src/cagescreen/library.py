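"""Building blocks and the combinatorial ligand library.

An unsymmetrical ditopic cage ligand ``i-j-k`` is assembled from three
fragments: two inequivalent monodentate N-donor arms (*coordinating*
building blocks, e.g. pyridyl or isoquinolyl) joined to the two ends of a
ditopic spacer (*core* building block). Connection points are marked in
the SMILES of each fragment with a dummy atom (``*``); joining forms a
single bond between the dummy's neighbour on the core and the dummy's
neighbour on the arm.

Because the two arms differ, the ligand has no bilateral symmetry and a
Pd2L4 cage built from it can form four configurational isomers — the
motivation for the whole screen.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .errors import EmbeddingError, ParseError, ValidationError

_DONOR_PROP = "cagescreen_donor_end"

#: Default coordinating building blocks: six aromatic N-donor arms
#: (pyridyl, quinolyl, isoquinolyl and substituted-pyridyl variants)
#: commonly used in metallo-supramolecular chemistry. One dummy atom
#: marks the bond to the core; the ring nitrogen is the Pd-binding donor.
DEFAULT_COORDINATING: dict[str, str] = {
    "1": "*c1ccncc1",            # pyridin-4-yl
    "2": "*c1cccnc1",            # pyridin-3-yl
    "3": "*c1cncc(C)c1",         # 5-methylpyridin-3-yl
    "4": "*c1cncc(OC)c1",        # 5-methoxypyridin-3-yl
    "5": "*c1cnc2ccccc2c1",      # quinolin-3-yl
    "6": "*c1cncc2ccccc12",      # isoquinolin-4-yl
}

#: Default core building blocks: four ditopic aromatic spacers with the
#: two connection points marked by dummy atoms.
DEFAULT_CORES: dict[str, str] = {
    "A": "*c1ccc2cc(*)ccc2c1",       # naphthalene-2,6-diyl
    "B": "*c1ccc(*)cc1",             # 1,4-phenylene
    "C": "*c1cccc(*)c1",             # 1,3-phenylene
    "D": "*C#Cc1ccc(C#C*)cc1",       # 1,4-bis(ethynyl)phenylene
}


@dataclass(frozen=True)
class BuildingBlock:
    """A SMILES-defined fragment with marked connection points.

    ``role`` is ``"coordinating"`` (one connection point, one aromatic
    ring-N donor) or ``"core"`` (two connection points, no donors).
    """

    label: str
    smiles: str
    role: str
    donor_atoms: tuple[int, ...]
    n_connections: int
    mol: Chem.Mol = field(repr=False, compare=False, hash=False, default=None)


@dataclass(frozen=True, order=True)
class LigandSpec:
    """Combinatorial identity of a ligand: arm / core / arm labels.

    The canonical id places the higher-sorting arm label first
    (``"5B4"``, never ``"4B5"``), so each unordered arm pair appears
    exactly once.
    """

    coord_a: str
    core: str
    coord_b: str

    def __post_init__(self):
        if self.coord_a == self.coord_b:
            raise ValidationError(
                f"ligand arms must differ (got {self.coord_a!r} twice); "
                "symmetrical ligands are outside the screen"
            )
        if self.coord_a < self.coord_b:  # canonicalize under arm swap
            a, b = self.coord_a, self.coord_b
            object.__setattr__(self, "coord_a", b)
            object.__setattr__(self, "coord_b", a)

    @property
    def id(self) -> str:
        return f"{self.coord_a}{self.core}{self.coord_b}"

    @classmethod
    def from_id(cls, lig_id: str) -> "LigandSpec":
        if len(lig_id) != 3:
            raise ValidationError(f"cannot parse ligand id {lig_id!r}")
        return cls(lig_id[0], lig_id[1], lig_id[2])


@dataclass
class LigandStructure:
    """An embedded 3D ditopic ligand with its two N-donor ends.

    ``donor_vector_a``/``b`` are unit vectors along each nitrogen's
    lone-pair (binding) direction: the external bisector of the two ring
    bonds at the N.
    """

    atoms: list[str]
    coords: np.ndarray
    donor_a: int
    donor_b: int
    donor_vector_a: np.ndarray
    donor_vector_b: np.ndarray
    spec: LigandSpec | None = None
    mol: Chem.Mol | None = field(default=None, repr=False)
    rotatable_bonds: list[tuple[int, int, tuple[int, ...]]] = field(
        default_factory=list, repr=False
    )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def donor_donor_distance(self) -> float:
        return float(np.linalg.norm(self.coords[self.donor_b] - self.coords[self.donor_a]))


def parse_building_block(smiles: str, role: str, label: str) -> BuildingBlock:
    """Parse a fragment SMILES into a validated :class:`BuildingBlock`.

    Connection points are dummy atoms (``*``). A coordinating block must
    carry exactly one connection point and exactly one pyridine-type
    donor (an aromatic ring nitrogen bearing no H that is not itself a
    connection point); a core block carries exactly two connection
    points and no donor.
    """
    if role not in ("coordinating", "core"):
        raise ValidationError(f"unknown building-block role {role!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"invalid SMILES for block {label!r}: {smiles!r}")
    dummies = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
    expected = 1 if role == "coordinating" else 2
    if len(dummies) != expected:
        raise ValidationError(
            f"block {label!r} ({role}): expected {expected} connection "
            f"point(s), found {len(dummies)}"
        )
    donors: tuple[int, ...] = ()
    if role == "coordinating":
        donors = tuple(
            a.GetIdx()
            for a in mol.GetAtoms()
            if a.GetAtomicNum() == 7
            and a.GetIsAromatic()
            and a.IsInRing()
            and a.GetTotalNumHs() == 0
        )
        if len(donors) != 1:
            raise ValidationError(
                f"block {label!r}: expected exactly 1 aromatic ring-N donor, "
                f"found {len(donors)}"
            )
    return BuildingBlock(
        label=label,
        smiles=smiles,
        role=role,
        donor_atoms=donors,
        n_connections=len(dummies),
        mol=mol,
    )


def default_blocks() -> tuple[list[BuildingBlock], list[BuildingBlock]]:
    """The built-in 6-arm x 4-core block library (60 ligands)."""
    coords = [
        parse_building_block(s, "coordinating", lab)
        for lab, s in DEFAULT_COORDINATING.items()
    ]
    cores = [parse_building_block(s, "core", lab) for lab, s in DEFAULT_CORES.items()]
    return coords, cores


def read_smi(path) -> list[tuple[str, str]]:
    """Read a ``.smi`` file: one ``SMILES<TAB>label`` record per line."""
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 'SMILES<TAB>label', got {line!r}"
                )
            records.append((parts[0], parts[1]))
    return records


def load_blocks(path, role: str) -> list[BuildingBlock]:
    return [parse_building_block(smi, role, lab) for smi, lab in read_smi(path)]


def enumerate_ligand_specs(
    coordinating: list[BuildingBlock], cores: list[BuildingBlock]
) -> list[LigandSpec]:
    """All unordered pairs of distinct arms x all cores.

    Count is ``C(n_arms, 2) * n_cores``; output order is deterministic
    (sorted by core label, then arm pair).
    """
    labels = [b.label for b in coordinating] + [b.label for b in cores]
    if len(set(labels)) != len(labels):
        raise ValidationError("building-block labels must be unique")
    if len(coordinating) < 2:
        raise ValidationError("need at least 2 coordinating blocks")
    if not cores:
        raise ValidationError("need at least 1 core block")
    specs = [
        LigandSpec(a.label, core.label, b.label)
        for core in sorted(cores, key=lambda b: b.label)
        for a, b in itertools.combinations(
            sorted(coordinating, key=lambda b: b.label), 2
        )
    ]
    return sorted(specs, key=lambda s: (s.core, s.coord_a, s.coord_b))


def _zip_fragments(core: BuildingBlock, arm_a: BuildingBlock, arm_b: BuildingBlock) -> Chem.Mol:
    """Join arm-core-arm through their dummy atoms with single bonds."""
    core_mol = Chem.RWMol(core.mol)
    dummies = [a for a in core_mol.GetAtoms() if a.GetAtomicNum() == 0]
    dummies[0].SetAtomMapNum(1)
    dummies[1].SetAtomMapNum(2)
    arms = []
    for block, tag, mapnum in ((arm_a, "a", 1), (arm_b, "b", 2)):
        m = Chem.RWMol(block.mol)
        for atom in m.GetAtoms():
            if atom.GetAtomicNum() == 0:
                atom.SetAtomMapNum(mapnum)
        m.GetAtomWithIdx(block.donor_atoms[0]).SetProp(_DONOR_PROP, tag)
        arms.append(m)
    combined = Chem.CombineMols(Chem.CombineMols(core_mol, arms[0]), arms[1])
    zipped = Chem.molzip(combined)
    Chem.SanitizeMol(zipped)
    return zipped


def _donor_vector(mol: Chem.Mol, coords: np.ndarray, donor: int) -> np.ndarray:
    """Lone-pair direction: external bisector of the ring bonds at the N."""
    nbrs = [
        n.GetIdx()
        for n in mol.GetAtomWithIdx(donor).GetNeighbors()
        if n.GetAtomicNum() > 1
    ]
    v = np.zeros(3)
    for n in nbrs:
        b = coords[n] - coords[donor]
        v -= b / np.linalg.norm(b)
    norm = np.linalg.norm(v)
    if norm < 1e-8:
        raise ValidationError("degenerate donor environment: bisector undefined")
    return v / norm


_ROTATABLE = Chem.MolFromSmarts("[!$(*#*)&!D1]-&!@[!$(*#*)&!D1]")


def _rotatable_bonds(mol: Chem.Mol) -> list[tuple[int, int, tuple[int, ...]]]:
    """Rotatable bonds as (i, j, atoms-on-the-j-side) triples."""
    adj: dict[int, list[int]] = {a.GetIdx(): [] for a in mol.GetAtoms()}
    for b in mol.GetBonds():
        adj[b.GetBeginAtomIdx()].append(b.GetEndAtomIdx())
        adj[b.GetEndAtomIdx()].append(b.GetBeginAtomIdx())
    rotors = []
    for i, j in mol.GetSubstructMatches(_ROTATABLE):
        seen = {i, j}
        stack = [j]
        side = []
        while stack:
            cur = stack.pop()
            for nxt in adj[cur]:
                if nxt not in seen:
                    seen.add(nxt)
                    side.append(nxt)
                    stack.append(nxt)
        rotors.append((i, j, tuple(sorted(side))))
    return rotors


def build_ligand_structure(
    spec: LigandSpec,
    blocks: dict[str, BuildingBlock],
    seed: int = 42,
    max_retries: int = 5,
) -> LigandStructure:
    """Join the three fragments and embed a relaxed 3D conformer.

    Distance-geometry embedding (ETKDGv3) with the given random seed,
    cleaned up with MMFF94 (UFF fallback). The same seed always yields
    identical coordinates.
    """
    try:
        arm_a, core, arm_b = blocks[spec.coord_a], blocks[spec.core], blocks[spec.coord_b]
    except KeyError as e:
        raise ValidationError(f"ligand {spec.id}: unknown block label {e.args[0]!r}") from None
    if core.role != "core" or arm_a.role != "coordinating" or arm_b.role != "coordinating":
        raise ValidationError(f"ligand {spec.id}: block roles do not match positions")

    mol = Chem.AddHs(_zip_fragments(core, arm_a, arm_b))
    params = AllChem.ETKDGv3()
    conf_id = -1
    for attempt in range(max_retries):
        params.randomSeed = int(seed) + attempt
        conf_id = AllChem.EmbedMolecule(mol, params)
        if conf_id >= 0:
            break
    if conf_id < 0:
        raise EmbeddingError(f"3D embedding failed for ligand {spec.id}")
    if AllChem.MMFFHasAllMoleculeParams(mol):
        AllChem.MMFFOptimizeMolecule(mol, maxIters=1000)
    else:
        AllChem.UFFOptimizeMolecule(mol, maxIters=1000)

    coords = np.array(mol.GetConformer().GetPositions(), dtype=float)
    donors = {
        a.GetProp(_DONOR_PROP): a.GetIdx()
        for a in mol.GetAtoms()
        if a.HasProp(_DONOR_PROP)
    }
    if set(donors) != {"a", "b"}:
        raise ValidationError(
            f"ligand {spec.id}: expected 2 donor atoms after assembly, found {len(donors)}"
        )
    return LigandStructure(
        atoms=[a.GetSymbol() for a in mol.GetAtoms()],
        coords=coords,
        donor_a=donors["a"],
        donor_b=donors["b"],
        donor_vector_a=_donor_vector(mol, coords, donors["a"]),
        donor_vector_b=_donor_vector(mol, coords, donors["b"]),
        spec=spec,
        mol=mol,
        rotatable_bonds=_rotatable_bonds(mol),
    )


def ligand_smiles(spec: LigandSpec, blocks: dict[str, BuildingBlock]) -> str:
    """Canonical SMILES of the assembled (H-implicit) ligand."""
    zipped = _zip_fragments(blocks[spec.core], blocks[spec.coord_a], blocks[spec.coord_b])
    return Chem.MolToSmiles(zipped)
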