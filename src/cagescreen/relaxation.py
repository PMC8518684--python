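"""Optimizer / energy backends under one contract.

Cage energies drive the isomer ranking, so every backend reports
kJ/mol under a method tag; energies are only comparable within a tag.

Three backends are provided:

* ``toy`` — a built-in, fully deterministic force field used for
  pipeline plumbing and testing. Its energy is

      E = k_bond * sum_sites sum_N (|Pd-N| - r0)^2          r0 = 2.05 Å
        + k_plane * sum_sites D_i^2
        + eps * sum_nonbonded (sigma_ij / r_ij)^12          sigma = vdW contact

  with k_bond = 500 kJ/mol/Å^2, k_plane = 100 kJ/mol/Å^2 and
  eps = 1 kJ/mol (so the repulsion equals eps exactly at vdW contact).
  It keeps a cage assembled and unclashed; it carries no chemistry and
  is never used for scientific ranking.
* ``xtb-gfn2`` — adapter to an external ``xtb`` executable (GFN2-xTB),
  run with total charge +4 for [Pd2L4]4+ and implicit DMSO solvation;
  Hartree outputs are converted at 2625.499639 kJ/mol per Hartree.
* ``gulp-uff4mof`` — adapter to an external GULP build with UFF4MOF,
  the force-field stage of the full-fidelity protocol.

Missing executables raise :class:`BackendUnavailableError` — there is
never a silent fallback between backends.
"""

from __future__ import annotations

import os
import re
import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .assembly import CageStructure
from .errors import BackendUnavailableError, CageScreenError, ValidationError
from .metrics import plane_deviation
from .vdw import vdw_radius

HARTREE_TO_KJ_MOL = 2625.499639

K_BOND = 500.0   # kJ/mol/Å^2, harmonic Pd-N
R0_PD_N = 2.05   # Å
K_PLANE = 100.0  # kJ/mol/Å^2, harmonic site-planarity on D_i
EPS_REP = 1.0    # kJ/mol at vdW contact
REP_CUTOFF = 2.0  # in units of sigma; (1/2)^12 ~ 2.4e-4 kJ/mol beyond


@dataclass
class EnergyResult:
    energy: float  # kJ/mol
    method: str
    converged: bool = True
    components: dict[str, float] = field(default_factory=dict)


@dataclass
class BackendConfig:
    """Settings for an optimizer/energy backend."""

    backend: str = "toy"  # toy | xtb-gfn2 | gulp-uff4mof
    charge: int = 4       # [Pd2L4]4+
    solvent: str = "dmso"
    n_conformers: int = 40
    seed: int = 42
    executable: str | None = None
    max_iter: int = 200   # toy relaxation steps
    workdir: str | None = None


def _nonbonded_pairs(cage: CageStructure) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs for soft-sphere repulsion.

    Pairs within one ligand copy are excluded (covalent structure is the
    embedder's business, not the cage force field's), as are the dative
    Pd-N pairs of the two sites.
    """
    n = cage.n_atoms
    group = np.full(n, -1)
    for g, sl in enumerate(cage.ligand_slices):
        group[list(sl)] = g
    ii, jj = np.triu_indices(n, k=1)
    same_ligand = (group[ii] >= 0) & (group[ii] == group[jj])
    bonded = set()
    for site in cage.sites:
        for nn in site.nitrogens:
            bonded.add((min(site.pd, nn), max(site.pd, nn)))
    is_bonded = np.array([(a, b) in bonded for a, b in zip(ii, jj)])
    keep = ~(same_ligand | is_bonded)
    return ii[keep], jj[keep]


class ToyForceField:
    """Deterministic cage force field (see module docstring)."""

    def __init__(self, cage: CageStructure, vdw_table: dict[str, float] | None = None):
        self.cage = cage
        self.ii, self.jj = _nonbonded_pairs(cage)
        radii = np.array([vdw_radius(el, vdw_table) for el in cage.atoms])
        self.sigma = radii[self.ii] + radii[self.jj]
        self.site_atoms = [
            np.array([s.pd, *s.nitrogens]) for s in cage.sites
        ]

    def components(self, coords: np.ndarray) -> dict[str, float]:
        e_bond = 0.0
        e_plane = 0.0
        for site in self.cage.sites:
            r = np.linalg.norm(coords[list(site.nitrogens)] - coords[site.pd], axis=1)
            e_bond += K_BOND * float(np.sum((r - R0_PD_N) ** 2))
            d_i = plane_deviation(coords[site.pd], coords[list(site.nitrogens)])
            e_plane += K_PLANE * d_i**2
        e_rep = 0.0
        if len(self.ii):
            r = np.linalg.norm(coords[self.ii] - coords[self.jj], axis=1)
            mask = r < REP_CUTOFF * self.sigma
            if mask.any():
                e_rep = EPS_REP * float(
                    np.sum((self.sigma[mask] / np.maximum(r[mask], 1e-3)) ** 12)
                )
        return {"bond": e_bond, "planarity": e_plane, "repulsion": e_rep}

    def energy(self, coords: np.ndarray) -> float:
        return sum(self.components(coords).values())

    def gradient(self, coords: np.ndarray) -> np.ndarray:
        grad = np.zeros_like(coords)
        # harmonic Pd-N (analytic)
        for site in self.cage.sites:
            ns = list(site.nitrogens)
            dv = coords[ns] - coords[site.pd]
            r = np.linalg.norm(dv, axis=1)
            f = (2.0 * K_BOND * (r - R0_PD_N) / np.maximum(r, 1e-9))[:, None] * dv
            grad[ns] += f
            grad[site.pd] -= f.sum(axis=0)
        # planarity (central differences on the 5 site atoms; D_i is a
        # cheap 5-point SVD, so this stays exact enough and simple)
        h = 1e-6
        for site in self.cage.sites:
            idx = [site.pd, *site.nitrogens]
            for a in idx:
                for ax in range(3):
                    orig = coords[a, ax]
                    coords[a, ax] = orig + h
                    dp = plane_deviation(coords[site.pd], coords[list(site.nitrogens)])
                    coords[a, ax] = orig - h
                    dm = plane_deviation(coords[site.pd], coords[list(site.nitrogens)])
                    coords[a, ax] = orig
                    grad[a, ax] += K_PLANE * (dp**2 - dm**2) / (2 * h)
        # soft-sphere repulsion (analytic)
        if len(self.ii):
            dv = coords[self.ii] - coords[self.jj]
            r = np.linalg.norm(dv, axis=1)
            mask = r < REP_CUTOFF * self.sigma
            if mask.any():
                rr = np.maximum(r[mask], 1e-3)
                mag = -12.0 * EPS_REP * (self.sigma[mask] ** 12) / rr**13
                f = (mag / rr)[:, None] * dv[mask]
                np.add.at(grad, self.ii[mask], f)
                np.subtract.at(grad, self.jj[mask], f)
        return grad


def toy_energy(cage: CageStructure) -> EnergyResult:
    """Evaluate the toy force field on a cage (no optimization)."""
    ff = ToyForceField(cage)
    comp = ff.components(cage.coords)
    return EnergyResult(
        energy=sum(comp.values()), method="toy", converged=True, components=comp
    )


def toy_relax(
    cage: CageStructure,
    max_iter: int = 200,
    gtol: float = 1.0,
    return_trajectory: bool = False,
):
    """Steepest-descent relaxation under the toy force field.

    Backtracking line search guarantees a monotonically non-increasing
    energy trajectory; the result is deterministic for a given input.
    """
    ff = ToyForceField(cage)
    x = cage.coords.copy()
    e = ff.energy(x)
    traj = [e]
    alpha = 1e-4
    for _ in range(max_iter):
        g = ff.gradient(x)
        gmax = float(np.abs(g).max())
        if gmax < gtol:
            break
        step = alpha
        accepted = False
        for _ in range(40):
            x_new = x - step * g
            e_new = ff.energy(x_new)
            if e_new <= e:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        x, e = x_new, e_new
        traj.append(e)
        alpha = min(step * 1.5, 1e-2)
    relaxed = cage.copy()
    relaxed.coords = x
    relaxed.provenance = "relaxed"
    result = EnergyResult(
        energy=e, method="toy", converged=True, components=ff.components(x)
    )
    if return_trajectory:
        return relaxed, result, traj
    return relaxed, result


def _apply_torsions(cage: CageStructure, rng: np.random.Generator, max_angle: float) -> CageStructure:
    """Randomly twist each rotatable bond by up to ±max_angle radians."""
    out = cage.copy()
    coords = out.coords
    for i, j, side in cage.rotors:
        angle = float(rng.uniform(-max_angle, max_angle))
        axis = coords[j] - coords[i]
        norm = np.linalg.norm(axis)
        if norm < 1e-8 or not side:
            continue
        axis = axis / norm
        k = axis
        K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
        sel = list(side)
        coords[sel] = (coords[sel] - coords[j]) @ R.T + coords[j]
    return out


def conformer_search(
    cage: CageStructure,
    n_conformers: int = 40,
    seed: int = 42,
    backend: str = "toy",
    config: BackendConfig | None = None,
    max_angle_deg: float = 60.0,
) -> tuple[CageStructure, EnergyResult]:
    """Relax ``n_conformers`` torsion-perturbed variants, keep the lowest.

    The first conformer is always the unperturbed input, so a search
    with ``n_conformers=1`` is a plain optimize call and the returned
    energy never exceeds the relaxed input energy. A fixed seed makes
    the winner reproducible.
    """
    if n_conformers < 1:
        raise ValidationError("n_conformers must be >= 1")
    config = config or BackendConfig(backend=backend, n_conformers=n_conformers, seed=seed)
    rng = np.random.default_rng(seed)
    best: tuple[CageStructure, EnergyResult] | None = None
    failures: list[str] = []
    for c in range(n_conformers):
        trial = cage if c == 0 else _apply_torsions(cage, rng, np.deg2rad(max_angle_deg))
        try:
            if backend == "toy":
                relaxed, result = toy_relax(trial, max_iter=config.max_iter)
            else:
                relaxed, result = run_external_backend(trial, config)
        except BackendUnavailableError:
            raise
        except CageScreenError as exc:  # pragma: no cover - defensive
            failures.append(f"conformer {c}: {exc}")
            continue
        if best is None or result.energy < best[1].energy:
            best = (relaxed, result)
    if best is None:
        raise CageScreenError(
            "all conformers failed: " + "; ".join(failures[:3])
        )
    return best


def kj_mol_from_hartree(e_h: float) -> float:
    return e_h * HARTREE_TO_KJ_MOL


def hartree_from_kj_mol(e: float) -> float:
    return e / HARTREE_TO_KJ_MOL


def _write_xyz(path: Path, cage: CageStructure, comment: str) -> None:
    lines = [str(cage.n_atoms), comment]
    lines += [
        f"{el} {x:.8f} {y:.8f} {z:.8f}"
        for el, (x, y, z) in zip(cage.atoms, cage.coords)
    ]
    path.write_text("\n".join(lines) + "\n")


def run_external_backend(
    cage: CageStructure, config: BackendConfig
) -> tuple[CageStructure, EnergyResult]:
    """Dispatch to a backend; external programs run in an audit directory.

    ``toy`` routes to the built-in force field and never needs an
    executable. External backends require their program on PATH (or an
    explicit ``executable``); raw inputs/outputs are kept under
    ``config.workdir`` for audit.
    """
    if config.backend == "toy":
        relaxed, result = toy_relax(cage, max_iter=config.max_iter)
        return relaxed, result
    if config.backend == "xtb-gfn2":
        return _run_xtb(cage, config)
    if config.backend == "gulp-uff4mof":
        return _run_gulp(cage, config)
    raise ValidationError(f"unknown backend {config.backend!r}")


def _require_exe(name: str, config: BackendConfig) -> str:
    exe = config.executable or name
    path = shutil.which(exe)
    if path is None:
        raise BackendUnavailableError(
            f"backend {config.backend!r} requires the {name!r} executable, "
            "which is not installed or not on PATH"
        )
    return path


def _run_dir(config: BackendConfig, tag: str) -> Path:
    base = Path(config.workdir or "cagescreen_runs")
    d = base / tag
    d.mkdir(parents=True, exist_ok=True)
    return d


def _run_xtb(cage: CageStructure, config: BackendConfig) -> tuple[CageStructure, EnergyResult]:
    exe = _require_exe("xtb", config)
    tag = cage.spec.name if cage.spec else "cage"
    rundir = _run_dir(config, f"xtb_{tag}")
    _write_xyz(rundir / "input.xyz", cage, tag)
    cmd = [
        exe, "input.xyz", "--opt", "--gfn", "2",
        "--chrg", str(config.charge), "--alpb", config.solvent,
    ]
    proc = subprocess.run(
        cmd, cwd=rundir, capture_output=True, text=True,
        env={**os.environ, "OMP_NUM_THREADS": "1"},
    )
    (rundir / "xtb.log").write_text(proc.stdout + proc.stderr)
    match = None
    for line in proc.stdout.splitlines():
        m = re.search(r"TOTAL ENERGY\s+(-?\d+\.\d+)\s+Eh", line)
        if m:
            match = float(m.group(1))
    converged = "GEOMETRY OPTIMIZATION CONVERGED" in proc.stdout
    if match is None:
        raise CageScreenError(f"xtb produced no total energy (see {rundir}/xtb.log)")
    opt = rundir / "xtbopt.xyz"
    relaxed = cage.copy()
    if opt.exists():
        lines = opt.read_text().splitlines()
        n = int(lines[0].split()[0])
        relaxed.coords = np.array(
            [[float(v) for v in ln.split()[1:4]] for ln in lines[2 : 2 + n]]
        )
    relaxed.provenance = "relaxed"
    return relaxed, EnergyResult(
        energy=kj_mol_from_hartree(match),
        method=f"gfn2-xtb/{config.solvent.upper()}",
        converged=converged,
    )


def _run_gulp(cage: CageStructure, config: BackendConfig) -> tuple[CageStructure, EnergyResult]:
    exe = _require_exe("gulp", config)
    tag = cage.spec.name if cage.spec else "cage"
    rundir = _run_dir(config, f"gulp_{tag}")
    lines = ["opti conj noautobond fix molmec cartesian", "cartesian"]
    lines += [
        f"{el} core {x:.6f} {y:.6f} {z:.6f}"
        for el, (x, y, z) in zip(cage.atoms, cage.coords)
    ]
    lines += ["library uff4mof", "output xyz optimized"]
    (rundir / "gulp.gin").write_text("\n".join(lines) + "\n")
    with open(rundir / "gulp.gin") as fin, open(rundir / "gulp.got", "w") as fout:
        proc = subprocess.run([exe], stdin=fin, stdout=fout, stderr=subprocess.STDOUT,
                              cwd=rundir, text=True)
    out = (rundir / "gulp.got").read_text()
    m = None
    for mm in re.finditer(r"Final energy\s*=\s*(-?\d+\.\d+)\s*eV", out):
        m = float(mm.group(1))
    if m is None:
        raise CageScreenError(f"GULP produced no final energy (see {rundir}/gulp.got)")
    relaxed = cage.copy()
    opt = rundir / "optimized.xyz"
    if opt.exists():
        olines = opt.read_text().splitlines()
        n = int(olines[0].split()[0])
        relaxed.coords = np.array(
            [[float(v) for v in ln.split()[1:4]] for ln in olines[2 : 2 + n]]
        )
    relaxed.provenance = "relaxed"
    return relaxed, EnergyResult(
        energy=m * 96.48533212, method="uff4mof", converged=proc.returncode == 0
    )
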