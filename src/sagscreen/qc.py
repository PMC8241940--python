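"""Genome-level quality metrics and MIMAG/MISAG tier assignment.

CheckM reports duplicated-marker "contamination" (C) and the fraction of
duplicates that are near-identical copies, "strain heterogeneity" (SH).
Near-identical duplicates almost certainly reflect within-strain paralogy
or MDA/assembly artefacts rather than cross-species contamination, so the
paralog-corrected contamination is C − (SH/100)·C = C·(1 − SH/100).

Predicted genome size extrapolates the assembly size by the fraction of
the genome actually recovered: size / ((completeness − corrected
contamination)/100).  Subtracting corrected contamination removes the
contribution of foreign/duplicated sequence to the assembly size before
extrapolating; at zero contamination this is plain size/completeness.

Tiers follow the MIMAG/MISAG standard, with contamination judged on the
paralog-corrected value: high needs >90% completeness, <5% contamination
and full-length rRNAs (an explicit flag here — rRNA detection is upstream);
medium needs ≥50% completeness and <10% contamination; everything else is
low.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "AssemblyRecord",
    "QCReport",
    "QCSummary",
    "paralog_corrected_contamination",
    "predicted_genome_size",
    "mimag_tier",
    "qc_report",
    "summarize_qc",
    "n50",
    "round_half_away",
]

TIERS = ("high", "medium", "low")


@dataclass
class AssemblyRecord:
    """Genome-level inputs: one SAG, CAG, MAG or reference assembly."""

    genome_id: str
    kind: str  # SAG | CAG | MAG | REF
    size_mb: float
    checkm_completeness: float
    checkm_contamination: float
    strain_heterogeneity: float = 0.0
    gc: float | None = None
    contig_lengths: list[int] | None = None
    #: A published paralog-corrected contamination value, used verbatim when
    #: set.  CheckM's SH is often not reported alongside a corrected value,
    #: and occasionally (transcription errors in source tables) the printed
    #: value is not derivable from C and SH at all; carrying it explicitly
    #: keeps such rows verbatim instead of silently "fixing" them.
    corrected_contamination: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("SAG", "CAG", "MAG", "REF"):
            raise ValueError(f"unknown assembly kind {self.kind!r}")
        if self.size_mb <= 0:
            raise ValueError("size_mb must be positive")
        if not 0 <= self.checkm_completeness <= 100:
            raise ValueError("completeness must be in [0,100]")
        if self.checkm_contamination < 0:
            raise ValueError("contamination must be >= 0")
        if not 0 <= self.strain_heterogeneity <= 100:
            raise ValueError("strain heterogeneity must be in [0,100]")


@dataclass(frozen=True)
class QCReport:
    """Derived per-genome quality metrics."""

    genome_id: str
    corrected_contamination: float
    predicted_size_mb: float
    tier: str


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (0.75 → 0.8, −0.75 → −0.8)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def paralog_corrected_contamination(c: float, sh: float) -> float:
    """C·(1 − SH/100): contamination net of near-identical duplicate markers."""
    if c < 0:
        raise ValueError("contamination must be >= 0")
    if not 0 <= sh <= 100:
        raise ValueError(f"strain heterogeneity must be in [0,100], got {sh}")
    return c * (1.0 - sh / 100.0)


def predicted_genome_size(
    size_mb: float,
    completeness: float,
    corrected_contamination: float = 0.0,
) -> float:
    """Extrapolated full genome size in Mb.

    size / ((completeness − corrected_contamination)/100).  Undefined when
    the effective completeness is not positive.
    """
    effective = completeness - corrected_contamination
    if effective <= 0:
        raise ValueError("undefined prediction: effective completeness must be > 0")
    return size_mb / (effective / 100.0)


def mimag_tier(
    completeness: float,
    corrected_contamination: float,
    rna_complete: bool = False,
) -> str:
    """MIMAG/MISAG quality tier from completeness and corrected contamination."""
    if completeness > 90 and corrected_contamination < 5 and rna_complete:
        return "high"
    if completeness >= 50 and corrected_contamination < 10:
        return "medium"
    return "low"


def qc_report(record: AssemblyRecord, rna_complete: bool = False) -> QCReport:
    if record.corrected_contamination is not None:
        corrected = record.corrected_contamination
    else:
        corrected = paralog_corrected_contamination(
            record.checkm_contamination, record.strain_heterogeneity
        )
    return QCReport(
        genome_id=record.genome_id,
        corrected_contamination=corrected,
        predicted_size_mb=predicted_genome_size(
            record.size_mb, record.checkm_completeness, corrected
        ),
        tier=mimag_tier(record.checkm_completeness, corrected, rna_complete),
    )


@dataclass(frozen=True)
class QCSummary:
    """Cross-genome summary; means rounded to one decimal, half away from zero."""

    n: int
    mean_completeness: float
    mean_corrected_contamination: float
    size_range_mb: tuple[float, float]
    completeness_range: tuple[float, float]
    corrected_contamination_range: tuple[float, float]
    tier_counts: dict[str, int]


def summarize_qc(records: list[AssemblyRecord], rna_complete: bool = False) -> QCSummary:
    """Summarise a set of assemblies (means, ranges, tier counts)."""
    if not records:
        raise ValueError("cannot summarize an empty record list")
    reports = [qc_report(r, rna_complete) for r in records]
    comp = [r.checkm_completeness for r in records]
    corr = [r.corrected_contamination for r in reports]
    sizes = [r.size_mb for r in records]
    counts = Counter(r.tier for r in reports)
    return QCSummary(
        n=len(records),
        mean_completeness=round_half_away(sum(comp) / len(comp), 1),
        mean_corrected_contamination=round_half_away(sum(corr) / len(corr), 1),
        size_range_mb=(min(sizes), max(sizes)),
        completeness_range=(min(comp), max(comp)),
        corrected_contamination_range=(min(corr), max(corr)),
        tier_counts={t: counts.get(t, 0) for t in TIERS},
    )


def n50(contig_lengths: list[int]) -> int:
    """Largest length L with contigs ≥ L covering at least half the assembly."""
    if not contig_lengths:
        raise ValueError("n50 of an empty assembly is undefined")
    if any(l <= 0 for l in contig_lengths):
        raise ValueError("contig lengths must be positive")
    half = sum(contig_lengths) / 2.0
    running = 0
    for length in sorted(contig_lengths, reverse=True):
        running += length
        if running >= half:
            return length
    raise AssertionError("unreachable")
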