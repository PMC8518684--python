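"""Plain-text structure I/O (XYZ, optional SDF) with metadata comments.

The XYZ comment line carries ``key=value`` metadata (ligand id, isomer,
provenance) so a structure round-trips its identity alongside its
coordinates.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdmolfiles

from .assembly import CageSpec, CageStructure, Isomer, identify_pdn4_sites
from .errors import XYZFormatError
from .library import LigandSpec, LigandStructure


def _format_comment(meta: dict[str, str]) -> str:
    return " ".join(f"{k}={v}" for k, v in meta.items())


def parse_comment(comment: str) -> dict[str, str]:
    meta = {}
    for token in comment.split():
        if "=" in token:
            k, _, v = token.partition("=")
            meta[k] = v
    return meta


def write_xyz(path, atoms: list[str], coords: np.ndarray, meta: dict | None = None) -> None:
    coords = np.asarray(coords, dtype=float)
    lines = [str(len(atoms)), _format_comment({k: str(v) for k, v in (meta or {}).items()})]
    lines += [
        f"{el} {x:.8f} {y:.8f} {z:.8f}" for el, (x, y, z) in zip(atoms, coords)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path) -> tuple[list[str], np.ndarray, dict[str, str]]:
    """Read one XYZ frame; malformed files raise with a line number."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise XYZFormatError(f"{path}: empty file", line=1)
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise XYZFormatError(f"{path}: first line must be the atom count", line=1)
    if len(lines) < n + 2:
        raise XYZFormatError(
            f"{path}: declared {n} atoms but file ends early", line=len(lines)
        )
    meta = parse_comment(lines[1] if len(lines) > 1 else "")
    atoms, coords = [], []
    for i, ln in enumerate(lines[2 : 2 + n], start=3):
        parts = ln.split()
        if len(parts) < 4:
            raise XYZFormatError(f"{path}: expected 'El x y z'", line=i)
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError:
            raise XYZFormatError(f"{path}: unparseable coordinates", line=i)
        atoms.append(parts[0])
        coords.append(xyz)
    return atoms, np.asarray(coords, dtype=float), meta


def write_cage_xyz(path, cage: CageStructure) -> None:
    meta = {"provenance": cage.provenance}
    if cage.spec is not None:
        meta = {
            "id": cage.spec.ligand.id,
            "isomer": cage.spec.isomer.value,
            **meta,
        }
    write_xyz(path, cage.atoms, cage.coords, meta)


def read_cage_xyz(path) -> CageStructure:
    """Load a cage and (re)identify its PdN4 sites from geometry."""
    atoms, coords, meta = read_xyz(path)
    sites = identify_pdn4_sites(atoms, coords)
    spec = None
    if "id" in meta and "isomer" in meta:
        try:
            spec = CageSpec(LigandSpec.from_id(meta["id"]), Isomer(meta["isomer"]))
        except Exception:
            spec = None
    return CageStructure(
        atoms=atoms,
        coords=coords,
        pd_indices=(sites[0].pd, sites[1].pd),
        sites=sites,
        spec=spec,
        provenance=meta.get("provenance", "external"),
        ligand_slices=[range(0, len(atoms))],
    )


def write_ligand_xyz(path, lig: LigandStructure) -> None:
    meta = {"donor_a": lig.donor_a, "donor_b": lig.donor_b}
    if lig.spec is not None:
        meta["id"] = lig.spec.id
    write_xyz(path, lig.atoms, lig.coords, meta)


def write_ligand_sdf(path, lig: LigandStructure) -> None:
    if lig.mol is None:
        raise XYZFormatError("ligand has no bond graph; cannot write SDF")
    rdmolfiles.MolToMolFile(Chem.Mol(lig.mol), str(path))
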