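"""Energy separations, threshold classification and library ranking.

A ligand is a promising *cis*-selective candidate when (i) its cis cage
isomer is the energetic minimum by a sufficient margin and (ii) that cis
structure is geometrically unstrained:

* ``delta_e``      — unsigned gap between the two lowest isomer energies.
* ``delta_e_cis``  — signed cis stability: (lowest non-cis energy) -
  (cis energy). Positive iff cis is strictly the most stable isomer.
* energy threshold — ``delta_e_cis >= 6 kJ/mol`` (inclusive), the
  empirical margin needed to drive exclusive self-assembly of one
  isomer at the semi-empirical tight-binding level (about 10 kJ/mol if
  energies come from DFT — the threshold is configurable and
  method-tagged for that reason).
* geometry threshold — ``D_max < 0.1 Å`` and ``q_sqp,min > 0.95``
  (strict) on the lowest-energy structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .assembly import Isomer
from .errors import ValidationError

ISOMERS = [i.value for i in Isomer]


@dataclass
class Thresholds:
    delta_e: float = 6.0      # kJ/mol, inclusive
    d_max: float = 0.1        # Å, strict
    q_sqp_min: float = 0.95   # dimensionless, strict
    method: str = "gfn2-xtb"

    def __post_init__(self):
        if self.delta_e <= 0 or self.d_max <= 0 or self.q_sqp_min <= 0:
            raise ValidationError("thresholds must be positive")


@dataclass
class IsomerEnergies:
    ligand_id: str
    energies: dict[str, float]  # isomer name -> kJ/mol
    method: str = "toy"

    def __post_init__(self):
        missing = [i for i in ISOMERS if i not in self.energies]
        if missing:
            raise ValidationError(
                f"ligand {self.ligand_id}: missing isomer energies {missing}"
            )


@dataclass
class RankingRecord:
    ligand_id: str
    delta_e: float
    delta_e_cis: float
    lowest_isomer: str
    q_sqp_min: float
    d_max: float
    passes_energy: bool = False
    passes_geometry: bool = False
    verdict: str = "non_cis"
    method: str = "toy"
    extras: dict = field(default_factory=dict)


def energy_separations(e: IsomerEnergies) -> tuple[float, float, str]:
    """(delta_e, delta_e_cis, lowest_isomer) from one ligand's 4 energies.

    ``delta_e`` = second lowest - lowest (always >= 0);
    ``delta_e_cis`` = lowest non-cis - cis, positive iff cis is strictly
    the most stable isomer, negative when it is beaten, zero on a tie.
    """
    vals = {k: float(v) for k, v in e.energies.items() if k in ISOMERS}
    for k, v in vals.items():
        if not (v == v and abs(v) != float("inf")):
            raise ValidationError(f"ligand {e.ligand_id}: non-finite energy for {k}")
    ordered = sorted(vals.items(), key=lambda kv: (kv[1], kv[0]))
    lowest_isomer = ordered[0][0]
    delta_e = ordered[1][1] - ordered[0][1]
    e_cis = vals[Isomer.CIS.value]
    lowest_non_cis = min(v for k, v in vals.items() if k != Isomer.CIS.value)
    delta_e_cis = lowest_non_cis - e_cis
    return delta_e, delta_e_cis, lowest_isomer


def classify(
    ligand_id: str,
    delta_e: float,
    delta_e_cis: float,
    lowest_isomer: str,
    q_sqp_min: float,
    d_max: float,
    thresholds: Thresholds | None = None,
    method: str = "toy",
) -> RankingRecord:
    """Apply the energy and geometry thresholds to one ligand.

    Verdict precedence: a ligand whose minimum isn't cis is ``non_cis``;
    otherwise an insufficient energy gap gives ``energy_fail``, a
    strained cis structure ``geometry_fail``, and ``candidate`` needs
    all three conditions.
    """
    thr = thresholds or Thresholds()
    passes_energy = delta_e_cis >= thr.delta_e
    passes_geometry = d_max < thr.d_max and q_sqp_min > thr.q_sqp_min
    if lowest_isomer != Isomer.CIS.value or delta_e_cis <= 0:
        verdict = "non_cis" if lowest_isomer != Isomer.CIS.value else "energy_fail"
    elif not passes_energy:
        verdict = "energy_fail"
    elif not passes_geometry:
        verdict = "geometry_fail"
    else:
        verdict = "candidate"
    return RankingRecord(
        ligand_id=ligand_id,
        delta_e=delta_e,
        delta_e_cis=delta_e_cis,
        lowest_isomer=lowest_isomer,
        q_sqp_min=q_sqp_min,
        d_max=d_max,
        passes_energy=passes_energy,
        passes_geometry=passes_geometry,
        verdict=verdict,
        method=method,
    )


def rank_library(records: list[RankingRecord]) -> pd.DataFrame:
    """Deterministic ranked report over the whole ligand library.

    Candidates first; within each group sort by delta_e_cis descending,
    then q_sqp,min descending, then D_max ascending, then ligand id.
    The frame carries summary counts as ``DataFrame.attrs``.
    """
    if not records:
        raise ValidationError("no records to rank")
    ids = [r.ligand_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate ligand ids: {dupes}")
    rows = sorted(
        records,
        key=lambda r: (
            0 if r.verdict == "candidate" else 1,
            -r.delta_e_cis,
            -r.q_sqp_min,
            r.d_max,
            r.ligand_id,
        ),
    )
    df = pd.DataFrame(
        {
            "rank": range(1, len(rows) + 1),
            "ligand": [r.ligand_id for r in rows],
            "delta_e": [r.delta_e for r in rows],
            "delta_e_cis": [r.delta_e_cis for r in rows],
            "lowest_isomer": [r.lowest_isomer for r in rows],
            "q_sqp_min": [r.q_sqp_min for r in rows],
            "d_max": [r.d_max for r in rows],
            "passes_energy": [r.passes_energy for r in rows],
            "passes_geometry": [r.passes_geometry for r in rows],
            "verdict": [r.verdict for r in rows],
            "method": [r.method for r in rows],
        }
    )
    df.attrs["summary"] = {
        "n_ligands": len(rows),
        "n_pass_energy": int(sum(r.passes_energy for r in rows)),
        "n_candidates": int(sum(r.verdict == "candidate" for r in rows)),
        "n_cis_lowest": int(
            sum(r.lowest_isomer == Isomer.CIS.value for r in rows)
        ),
    }
    return df
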