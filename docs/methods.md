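# Methods

## Scope and model

`cagescreen` screens unsymmetrical ditopic N-donor ligands for their
likelihood of self-assembling with Pd(II) into a single *cis*-Pd₂L₄
lantern cage. The screen deliberately bypasses the (expensive) question
of whether Pd₂L₄ is the preferred topology at all: the working
assumption is that if the Pd₂L₄ cage is geometrically unstrained it is,
as the smallest PdₙL₂ₙ assembly, the entropically favoured product.
Anion and solvent templation, free-energy corrections and synthetic
feasibility are out of scope.

## Ligand construction

A ligand is three fragments joined through dummy-atom (`*`) connection
points: coordinating arm — core — coordinating arm, single bonds formed
between each dummy's neighbours. The donor of a coordinating arm is its
unique aromatic ring nitrogen bearing no hydrogen; arms with zero or
several such nitrogens are rejected (a screen over monodentate
pyridine-type donors needs exactly one).

3D conformers come from RDKit distance-geometry embedding (ETKDGv3,
seed default 42, bounded retries with incremented seeds) followed by an
MMFF94 cleanup (UFF fallback). This is a generic embedding protocol —
adequate because cage assembly only needs an unentangled ligand with
identified donors, and all chemically meaningful geometry comes from
the relaxation backend. The donor binding direction is defined as the
external bisector of the two ring bonds at the N (the lone-pair
direction); nothing else about the embedding enters the assembly.

Ligand ids follow the printed convention of the field: the
higher-sorting arm label first (`5B4`, never `4B5`), making each
unordered arm pair appear exactly once without an alias table.

## Isomer enumeration

Orientation patterns over {U, D}⁴ are reduced under the dihedral group
of the square combined with the global U↔D relabelling; exactly four
orbits survive, with canonical representatives UUUU (all-up), UUUD
(three-up-one-down), UUDD (*cis*; the two flipped ligands cyclically
adjacent) and UDUD (*trans*). The reduction is implemented for general
ring size *n* and is tested against an exhaustive orbit computation for
n ≤ 6. Symmetrical ligands (identical arms) are rejected: all their
patterns are equivalent and there is nothing to rank.

## Cage assembly geometry

The two Pd sit on the z axis separated by `radius_scale ×` (ligand
donor–donor distance), default scale 1.0. Each ligand copy is placed
with its donor–donor axis vertical at equatorial radius 2.05 Å (a
typical Pd(II)–N(pyridyl) bond length), at azimuths 0°, 90°, 180°,
270°, with its U end toward the top Pd. The residual degree of freedom —
spin about the ligand's own donor–donor axis — is fixed analytically:
the alignment objective (donor lone pairs toward their Pd, plus a
weak 10⁻² term pushing the ligand centroid radially outward to break
ties for linear ligands) has the form A cos φ + B sin φ, so the optimal
spin is atan2(B, A). Assembly is therefore deterministic and exactly
symmetric under the global U↔D flip (the flipped cage superimposes on a
rigid flip of the original to < 10⁻⁶ Å RMSD). Poor lone-pair alignment
is recorded as a warning, not an error — the expanded structure only
needs to be unentangled, and relaxation does the rest.

Site bookkeeping is carried through assembly; for structures read from
external coordinate files, PdN₄ sites are re-identified by greedy
nearest-N assignment (advisory 2.6 Å cutoff, falling back to the four
nearest nitrogens for strained geometries, sites forced disjoint).

## Structural metrics

* **Plane fit** — total least squares through all 5 site atoms
  (4 N + Pd): the plane through the centroid normal to the smallest
  principal axis. Fitting all five atoms (rather than the N only)
  follows from the deviation metric being defined over all five; the
  N-only alternative would change D_i only in the third decimal for
  near-planar sites.
* **D_i / D_max** — sum of unsigned perpendicular distances of the five
  site atoms from that plane; D_max is the per-cage maximum.
* **q_sqp** — from the six pairwise angles of the unit Pd→N vectors,
  the two largest assigned *trans* (ideal 180°), the rest *cis* (ideal
  90°): `q = 1 − ½[½ Σ_trans (cos θ + 1)² + ¼ Σ_cis cos² θ]`, clamped
  to [0, 1]. The exact functional form of the literature order
  parameter is not printed where it is cited; this explicit angle-based
  form is adopted instead. It reproduces the documented endpoints
  (1.0 for the ideal square plane, monotonically lower under
  distortion, 13/18 for a tetrahedral site) but numeric agreement with
  the literature parameter at intermediate distortions is not claimed —
  published intermediate q values should be treated as approximate
  cross-checks only.
* **Δ_Pd** — per site, the lateral distance of the *other* Pd from the
  axis through this site's Pd along its fitted plane normal; reported
  as the mean of the two sites (a `max` reduction is exposed as an
  option). Zero exactly when both normals are collinear with the Pd–Pd
  vector, as for cages of symmetrical ligands.
* **Pore diameter** — twice the smallest (|r_atom − c| − vdW_atom) over
  all atoms, floored at zero, with c the all-atom centroid (the Pd–Pd
  midpoint is a reasonable alternative centre but the centroid follows
  the common toolkit convention). vdW radii are Bondi's set with
  1.63 Å for Pd; an unknown element is an error naming the element.

All metrics are rigid-motion invariant (tested to 10⁻⁹) and independent
of site/atom ordering.

## Energy backends

Energies are always reported in kJ/mol under a method tag and are only
comparable within one tag (Hartree outputs converted at
2625.499639 kJ/mol per Hartree).

The **toy force field** exists so the whole pipeline can run and be
tested deterministically with no external programs: harmonic Pd–N bonds
(k = 500 kJ mol⁻¹ Å⁻², r₀ = 2.05 Å), a harmonic site-planarity term
k_plane·D_i² (k_plane = 100 kJ mol⁻¹ Å⁻²), and a purely repulsive
soft-sphere term ε(σ/r)¹² between atoms of different ligands
(ε = 1 kJ/mol at vdW contact σ, cutoff 2σ). The constants are arbitrary
but fixed and documented; toy energies are never used for scientific
ranking. Relaxation is steepest descent with a backtracking line
search (monotone non-increasing energy by construction); bond and
repulsion gradients are analytic, the planarity gradient uses central
differences over the ten site atoms (each evaluation is a 5-point SVD,
so cost is negligible).

**Conformer search** perturbs each rotatable ligand bond by a uniform
random torsion (±60°), relaxes each variant with the active backend and
keeps the lowest; conformer 0 is always the unperturbed input, so
`n_conformers=1` is a plain optimization and the selected energy never
exceeds the relaxed input energy. Fixed seed ⇒ bit-reproducible winner.
The default is 40 conformers for force-field backends; the `run-all`
toy profile defaults to 1, since toy-backend searches only exercise
plumbing and extra conformers add cost without meaning.

**External adapters** (GFN2-xTB via `xtb`; UFF4MOF via `gulp`) write
plain-text inputs into a per-cage audit directory, invoke the
executable with total charge +4 ([Pd₂L₄]⁴⁺, counter-ions never
modelled) and implicit DMSO, and parse optimized coordinates and
energy. A missing executable raises `BackendUnavailableError` — never a
silent fallback — and non-convergence is flagged on the result.
Electronic energies, not free energies, are the comparator throughout.

## Ranking

Per ligand: `delta_e` = second-lowest − lowest isomer energy;
`delta_e_cis` = lowest non-*cis* − *cis* (positive iff *cis* strictly
lowest; equal to `delta_e` in that case). Thresholds: energy pass at
ΔE_cis ≥ 6.0 kJ/mol (inclusive, per "at least"); geometry pass at
D_max < 0.1 Å and q_sqp,min > 0.95 (both strict). Verdict precedence:
`non_cis` (minimum isn't *cis*), then `energy_fail`, then
`geometry_fail`, then `candidate`. Geometry is read from each ligand's
lowest-energy structure. The report orders candidates first, then by
ΔE_cis descending, ties broken by q_sqp,min descending, D_max
ascending, ligand id — deterministic and diff-stable. The 6 kJ/mol
default carries the tight-binding method tag; a DFT-calibrated
threshold of ~10 kJ/mol is a one-line config change.

## Synthetic fixtures

The fixture generator builds chemically meaningless but geometrically
exact Pd₂(N₄)₂ scaffolds (default Pd–Pd 10 Å, Pd–N 2.05 Å, eight
equatorial carbon placeholders so centroid/pore computations are
non-degenerate). Distortions — site tilt, single-N out-of-plane
displacement, lateral Pd offset — are applied in closed form and
recorded, so every metric has an analytic oracle (e.g. one site tilted
by α gives Δ_Pd = |Pd–Pd|·sin α / 2 under the mean reduction). Fixtures
emulate *geometry only*: they say nothing about real cage energetics,
flexibility, or whether a given ligand can realise a given geometry, so
fixture-based tests validate the metric and ranking mathematics, not
chemical predictions.

## Problem sizes and numerical choices

The end-to-end library screen in the test suite runs the built-in
6 × 4 block library (60 ligands, 240 cages) with the toy backend,
single-conformer searches and 40 descent steps per cage — enough for
the counts, determinism and totality properties it asserts, and chosen
so the whole suite runs on a laptop-class single CPU in about a minute.
Full-fidelity energetics (UFF4MOF conformer search + GFN2-xTB
optimization per cage) require the external executables and hours of
compute per ligand, and are exercised only through the backend
contract.

Degenerate inputs are errors, not silent results: collinear points in a
plane fit, coincident N/Pd, symmetric ligands, missing isomer energies,
duplicate ligand ids, unknown vdW radii. Plane-normal sign is fixed by
the first nonzero of (z, y, x) components; trans/cis angle assignment
uses the two smallest cosines, which is permutation-stable.

## Known limitations

* The toy backend's verdicts are meaningless by design; scientific
  rankings require the external tight-binding backend.
* The embedding protocol is a generic stand-in; a dedicated conformer
  pipeline for the free ligand could change expanded-structure details
  (never the enumeration or metrics).
* q_sqp matches the literature parameter only at the ideal endpoints by
  construction (see above).
* Heuristics ignore templation, ligand flexibility entropy and
  counter-ions; experimentally these can flip outcomes near the energy
  threshold.
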