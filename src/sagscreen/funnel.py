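"""Single-cell sorting → MDA → 16S PCR → Sanger funnel accounting.

Each dispensed cell sits in one well of a (half) 384-well plate; a few
wells per plate receive no cell and serve as negative controls.  Whole
genome amplification (MDA) is monitored in real time, and a well is
called MDA-positive when its amplification both starts clearly earlier
than the earliest negative control (Cq margin) and ends clearly higher
(endpoint RFU several control standard deviations up).  MDA-positive
wells are screened by 16S rRNA gene PCR, and PCR-positive wells by
Sanger sequencing; the funnel is monotone (Sanger ⇒ PCR ⇒ MDA).

Stage percentages follow the field's reporting convention: MDA success
over sorted cells, PCR and Sanger success both over MDA-positive wells.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from statistics import mean, stdev

from .abundance import AbundanceProfile
from .qc import round_half_away
from .taxonomy import RankConfig, TaxonPath

__all__ = [
    "WellRecord",
    "FunnelReport",
    "call_mda_positive",
    "funnel_stats",
    "taxon_proportions",
]


@dataclass
class WellRecord:
    """One well of a sorted plate and its screening outcomes."""

    plate_id: str
    well_id: str
    n_cells_detected: int = 1
    is_negative_control: bool = False
    cq: float | None = None
    endpoint_rfu: float = 0.0
    mda_positive: bool = False
    pcr_positive: bool = False
    sanger_ok: bool = False
    taxon: TaxonPath | None = None

    def __post_init__(self) -> None:
        if self.n_cells_detected < 0:
            raise ValueError("n_cells_detected must be >= 0")
        if self.endpoint_rfu < 0:
            raise ValueError("endpoint_rfu must be >= 0")
        if self.is_negative_control and self.n_cells_detected != 0:
            raise ValueError(
                f"negative control {self.well_id} must have n_cells_detected = 0"
            )

    def validate_monotone(self) -> None:
        if self.sanger_ok and not self.pcr_positive:
            raise ValueError(f"well {self.well_id}: sanger_ok without pcr_positive")
        if self.pcr_positive and not self.mda_positive:
            raise ValueError(f"well {self.well_id}: pcr_positive without mda_positive")


def call_mda_positive(
    well: WellRecord,
    controls: list[WellRecord],
    margin_cycles: float = 5.0,
    rfu_sigma: float = 3.0,
) -> bool:
    """Call a positive MDA reaction against the plate's negative controls.

    Positive iff the well amplified at all (Cq present), at least
    ``margin_cycles`` cycles before the earliest control (controls that
    never amplify count as Cq = +inf), and its endpoint RFU is at least
    ``rfu_sigma`` control standard deviations above the control mean.
    Needs ≥ 3 controls with endpoint RFU measurements.
    """
    rfus = [c.endpoint_rfu for c in controls]
    if len(rfus) < 3:
        raise ValueError("insufficient controls: need at least 3 negative-control wells")
    if well.cq is None:
        return False
    min_ctrl_cq = min((c.cq for c in controls if c.cq is not None), default=float("inf"))
    rfu_cutoff = mean(rfus) + rfu_sigma * stdev(rfus)
    return well.cq <= min_ctrl_cq - margin_cycles and well.endpoint_rfu >= rfu_cutoff


@dataclass(frozen=True)
class FunnelReport:
    """Stage counts and percentages (negative controls excluded)."""

    n_sorted: int
    n_mda_positive: int
    n_pcr_positive: int
    n_sanger_ok: int
    pct_mda_of_sorted: float
    pct_pcr_of_mda: float
    pct_sanger_of_mda: float


def funnel_stats(wells: list[WellRecord]) -> FunnelReport:
    """Stage-wise funnel counts and the standard reporting percentages.

    MDA is reported over sorted cells; PCR and Sanger over MDA-positive
    wells.  Percentages are one decimal, half away from zero, and
    reproduce exactly from the integer counts.
    """
    cells = [w for w in wells if not w.is_negative_control]
    if not cells:
        raise ValueError("no sorted wells")
    for w in cells:
        w.validate_monotone()
    n_sorted = len(cells)
    n_mda = sum(w.mda_positive for w in cells)
    n_pcr = sum(w.pcr_positive for w in cells)
    n_sanger = sum(w.sanger_ok for w in cells)

    def pct(num: int, den: int) -> float:
        return round_half_away(100.0 * num / den, 1) if den else 0.0

    return FunnelReport(
        n_sorted=n_sorted,
        n_mda_positive=n_mda,
        n_pcr_positive=n_pcr,
        n_sanger_ok=n_sanger,
        pct_mda_of_sorted=pct(n_mda, n_sorted),
        pct_pcr_of_mda=pct(n_pcr, n_mda),
        pct_sanger_of_mda=pct(n_sanger, n_mda),
    )


def taxon_proportions(
    wells: list[WellRecord],
    rank: str = "phylum",
    cfg: RankConfig | None = None,
) -> AbundanceProfile:
    """Taxon composition of the cells with interpretable Sanger reads.

    Fractions are over the classified Sanger-positive wells; the share of
    Sanger-positive wells without a classification is reported as the
    unclassified fraction (so both denominators are recoverable).
    """
    cfg = cfg or RankConfig()
    depth = cfg.depth_of(rank) + 1
    sanger = [w for w in wells if w.sanger_ok and not w.is_negative_control]
    counts: Counter[TaxonPath] = Counter()
    n_unclassified = 0
    for w in sanger:
        if w.taxon is not None and len(w.taxon) >= depth:
            counts[w.taxon.truncate(depth)] += 1
        else:
            n_unclassified += 1
    if not counts:
        raise ValueError("no classified wells")
    n_classified = sum(counts.values())
    return AbundanceProfile(
        rank=rank,
        fractions={t: n / n_classified for t, n in counts.items()},
        n_markers=n_classified,
        unclassified_fraction=n_unclassified / len(sanger),
    )
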