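"""Packaged desk-scale fixtures.

* ``table1`` — the published per-genome quality table of the winery-WWTP
  Patescibacteria/CPR study (27 SAGs + 4 CAGs): CheckM completeness and
  contamination, paralog-corrected contamination, MIMAG/MISAG tier,
  assembly and predicted sizes, GC and taxonomy.  Values are carried
  verbatim as printed (tier case normalised to lq/mq); one SAG row
  (S4_F15) prints a corrected contamination of 0.9 with a CheckM
  contamination of 0, which cannot arise from the correction formula —
  it is kept as printed, not repaired.
* ``funnel_wells`` — a deterministic reconstruction of the study's
  sorting funnel: 880 sorted cells across five half 384-well plates with
  16 negative controls each, of which 717 amplified, 420 gave 16S PCR
  products and 359 gave interpretable Sanger reads.
* ``cag_pairwise`` — pairwise 16S/ANI matrices whose qualifying edges
  encode exactly the CAG memberships of the table (components of sizes
  2, 3, 3 and 8; every other pair below both thresholds).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from ..cluster import PairwiseMatrix
from ..funnel import WellRecord
from ..qc import AssemblyRecord

__all__ = [
    "table1",
    "table1_records",
    "cag_members",
    "funnel_wells",
    "cag_pairwise",
    "FUNNEL_COUNTS",
]

#: Published funnel counts: sorted, MDA-positive, PCR-positive, Sanger-ok.
FUNNEL_COUNTS = (880, 717, 420, 359)


def table1() -> pd.DataFrame:
    """The per-genome quality table as a DataFrame, rows in print order."""
    with resources.files(__package__).joinpath("table1.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return df


def _derive_sh(c: float, corrected: float) -> float:
    """Invert corrected = C·(1 − SH/100); SH is 0 when C is 0."""
    if c <= 0:
        return 0.0
    return max(0.0, min(100.0, 100.0 * (1.0 - corrected / c)))


def table1_records(kinds: tuple[str, ...] = ("SAG", "CAG")) -> list[AssemblyRecord]:
    """Table rows as assembly records.

    Strain heterogeneity is derived by inverting the paralog-correction
    formula where CheckM contamination is positive; the printed corrected
    value is attached verbatim so QC reproduces the table even for the
    one row where the printed value is not formula-consistent.
    """
    records = []
    for row in table1().itertuples():
        if row.kind not in kinds:
            continue
        records.append(
            AssemblyRecord(
                genome_id=row.genome_id,
                kind=row.kind,
                size_mb=row.size_mb,
                checkm_completeness=row.completeness,
                checkm_contamination=row.checkm_contamination,
                strain_heterogeneity=_derive_sh(
                    row.checkm_contamination, row.corrected_contamination
                ),
                gc=row.gc,
                corrected_contamination=row.corrected_contamination,
            )
        )
    return records


def cag_members() -> dict[str, list[str]]:
    """CAG id → member SAG ids, from the table's membership column."""
    members: dict[str, list[str]] = {}
    for row in table1().itertuples():
        if row.kind == "SAG" and isinstance(row.cag, str) and row.cag:
            members.setdefault(row.cag, []).append(row.genome_id)
    return members


def funnel_wells() -> list[WellRecord]:
    """The 880-cell sorting run with its published stage outcomes.

    Wells are assigned deterministically: the first 717 cells are
    MDA-positive, the first 420 of those PCR-positive, the first 359 of
    those Sanger-interpretable.  Cq/RFU values are schematic (positives
    amplify early and high; negatives and the 80 control wells never
    amplify, with a small deterministic baseline spread so control
    statistics are well-defined).
    """
    n_sorted, n_mda, n_pcr, n_sanger = FUNNEL_COUNTS
    wells: list[WellRecord] = []
    per_plate = 176  # 880 cells over five half-384 plates
    for i in range(n_sorted):
        plate = f"P{i // per_plate + 1}"
        mda = i < n_mda
        pcr = i < n_pcr
        sanger = i < n_sanger
        wells.append(
            WellRecord(
                plate_id=plate,
                well_id=f"{plate}_W{i % per_plate + 1:03d}",
                n_cells_detected=1,
                cq=25.0 if mda else None,
                endpoint_rfu=5000.0 if mda else 100.0,
                mda_positive=mda,
                pcr_positive=pcr,
                sanger_ok=sanger,
            )
        )
    for p in range(5):
        plate = f"P{p + 1}"
        for c in range(16):
            wells.append(
                WellRecord(
                    plate_id=plate,
                    well_id=f"{plate}_NC{c + 1:02d}",
                    n_cells_detected=0,
                    is_negative_control=True,
                    cq=None,
                    endpoint_rfu=90.0 + 2.0 * (c % 11),
                )
            )
    return wells


def cag_pairwise(
    within_ani: float = 99.5,
    between_ani: float = 85.0,
    within_16s: float = 100.0,
    between_16s: float = 95.0,
) -> tuple[list[str], PairwiseMatrix, PairwiseMatrix]:
    """(ids, 16S matrix, ANI matrix) encoding the table's CAG membership."""
    df = table1()
    ids = [row.genome_id for row in df.itertuples() if row.kind == "SAG"]
    group_of = {
        row.genome_id: (row.cag if isinstance(row.cag, str) and row.cag else row.genome_id)
        for row in df.itertuples()
        if row.kind == "SAG"
    }
    ani = PairwiseMatrix("ANI")
    id16s = PairwiseMatrix("ID16S")
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            same = group_of[a] == group_of[b]
            ani.set(a, b, within_ani if same else between_ani)
            id16s.set(a, b, within_16s if same else between_16s)
    return ids, id16s, ani
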