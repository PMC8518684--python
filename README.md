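# cagescreen

High-throughput computational screening of reduced-symmetry **Pd₂L₄
lantern cages** built from unsymmetrical ditopic ligands.

Unsymmetrical N-donor ligands (two chemically inequivalent binding ends)
give Pd₂L₄ cages with anisotropic cavities — attractive for selective
guest binding — but self-assembly can scramble into four configurational
isomers (*all-up*, *three-up-one-down*, *cis*, *trans*). `cagescreen` is
for supramolecular/metallo-organic chemists who want to narrow a
combinatorial ligand search space *before* synthesis: it constructs
candidate ligands from SMILES building blocks, assembles all four cage
isomers in 3D, and ranks ligands by their likelihood of self-sorting
exclusively into the *cis* isomer.

## Model

A ligand *ijk* is assembled from three fragments — two coordinating arms
*i*, *k* (each one dummy-atom connection point and one pyridine-type N
donor) and a ditopic core *j* (two connection points). With *n* arms and
*m* cores the library holds C(*n*, 2)·*m* unsymmetrical ligands (the
built-in 6 × 4 library gives 60 ligands, hence 240 cages).

Each cage is scored by three computationally cheap heuristics:

- **ΔE / ΔE_cis** (kJ mol⁻¹) — the energy gap between the two
  lowest-energy isomers, and its signed variant (positive iff *cis* is
  strictly the most stable). A gap of **≥ 6 kJ mol⁻¹** at the
  semi-empirical tight-binding level is taken as sufficient to drive
  exclusive formation of one isomer (≈ 10 kJ mol⁻¹ if energies come from
  DFT; the threshold is configurable and method-tagged).
- **D_max** (Å) — for each PdN₄ site, *Dᵢ* is the sum of perpendicular
  distances of the 4 N and the Pd from their common least-squares plane;
  *D_max* is the larger of the two sites (0.0 Å = no strain). Pass:
  **D_max < 0.1 Å**.
- **q_sqp,min** — square-planar order parameter from the six angles θ
  between the four unit Pd→N vectors (two *trans* pairs, ideal 180°; four
  *cis* pairs, ideal 90°):

  q_sqp = 1 − ½ [ ½ Σ_trans (cos θ + 1)² + ¼ Σ_cis cos² θ ]

  1.0 = perfect square plane; *q_sqp,min* is the worse of the two Pd
  sites. Pass: **q_sqp,min > 0.95**.

A ligand is a **candidate** when its *cis* isomer is the minimum with
ΔE_cis ≥ 6 kJ mol⁻¹ and the *cis* structure passes both geometry
thresholds. Cage shape is further characterised by the Pd⋯Pd distance,
the anisotropy **Δ_Pd** (lateral offset of each Pd from the axis through
the other Pd along its PdN₄ plane normal; 0 Å for a symmetric cage) and
the spherical-probe **pore diameter** at the atom centroid.

Energetics go through a uniform backend contract: a built-in
deterministic toy force field (pipeline plumbing and tests only — it
carries no chemistry), plus adapters for external GFN2-xTB (`xtb`,
charge +4, implicit DMSO) and UFF4MOF-via-GULP executables for
full-fidelity runs. Missing executables fail loudly; there is no silent
fallback.

## Worked example

Ranking five ligands from their computed *cis*-isomer properties
(q_sqp,min, D_max / Å, ΔE / kJ mol⁻¹):

```python
import cagescreen as cs

props = {
    "5B4": (0.973, 0.023, 18.5),
    "5A1": (0.985, 0.003, 15.0),
    "4B1": (0.982, 0.020, 7.0),
    "4B3": (0.988, 0.030, 5.8),
    "5A3": (0.996, 0.005, 2.9),
}
records = [
    cs.classify(lig, de, de, "cis", q_sqp_min=q, d_max=d)
    for lig, (q, d, de) in props.items()
]
df = cs.rank_library(records)
print(df[["rank", "ligand", "delta_e_cis", "q_sqp_min", "d_max", "verdict"]]
      .to_string(index=False))
```

prints

```
 rank ligand  delta_e_cis  q_sqp_min  d_max     verdict
    1    5B4         18.5      0.973  0.023   candidate
    2    5A1         15.0      0.985  0.003   candidate
    3    4B1          7.0      0.982  0.020   candidate
    4    4B3          5.8      0.988  0.030 energy_fail
    5    5A3          2.9      0.996  0.005 energy_fail
```

The three candidates clear every threshold; `4B3` and `5A3` have *cis*
minima but energy gaps below 6 kJ mol⁻¹, so exclusive self-sorting is
not predicted (`energy_fail`).

The same workflow end-to-end from the command line:

```sh
cagescreen enumerate --out ligands.json            # 60 ligands -> ligands.json
cagescreen build --ligand 5B4 --isomer cis         # expanded cage XYZ
cagescreen analyze structures/cage_5B4_cis.xyz     # metrics for any XYZ
cagescreen run-all --backend toy --out screen_out  # full pipeline
```

`run-all` chains enumerate → build → relax → analyze → rank and writes
`cages.csv` (240 rows: energy + 7 metrics per cage), `ranking.csv`
(60 rows) and `summary.json`. Outputs are deterministic for a given
seed.

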