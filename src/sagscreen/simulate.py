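"""Seeded synthetic-data generators with known ground truth.

These generators emulate, table by table, the inputs the pipeline
consumes in a real study — a multi-taxon community assembled into
fragmented contigs with universal single-copy markers and rRNA genes,
cross-taxon contaminant contigs of controlled identity (mimicking
reagent-borne and co-sorted free DNA), a well-plate sorting/MDA/PCR
funnel with negative controls, and pairwise identity matrices with a
planted strain partition.  Every generator is deterministic under its
seed and records the planted truth alongside the observations, so each
downstream module can be tested for parameter recovery without any
sequencing data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import PairwiseMatrix
from .funnel import WellRecord
from .screen import ContigRecord, MarkerHit
from .taxonomy import TaxonPath

__all__ = [
    "TaxonSpec",
    "CommunitySpec",
    "ContaminationSpec",
    "FunnelSpec",
    "simulate_community",
    "inject_contamination",
    "simulate_sort_run",
    "simulate_sag_replicates",
]


@dataclass(frozen=True)
class TaxonSpec:
    """One community member: lineage, abundance and genome layout."""

    taxon: TaxonPath
    abundance: float
    genome_size_bp: int = 1_000_000
    n_scg_markers: int = 40
    n_rrna: int = 1


@dataclass(frozen=True)
class CommunitySpec:
    """A coverage-proportional community with contig fragmentation.

    Per-taxon sequencing depth is ``depth_scale × abundance``; per-contig
    coverage multiplies that by lognormal noise with log-scale sigma
    ``coverage_sigma`` (multiplicative, loosely mimicking MDA/assembly
    coverage unevenness).  Contig lengths are lognormal around
    ``mean_contig_bp`` with log-scale dispersion ``contig_dispersion``.
    """

    taxa: tuple[TaxonSpec, ...]
    mean_contig_bp: int = 20_000
    contig_dispersion: float = 0.5
    depth_scale: float = 100.0
    coverage_sigma: float = 0.0
    marker_identity: tuple[float, float] = (90.0, 100.0)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(t.abundance for t in self.taxa)
        if not np.isclose(total, 1.0):
            raise ValueError(f"abundances must sum to 1, got {total}")
        for t in self.taxa:
            if t.genome_size_bp <= 0 or t.n_scg_markers < 0 or t.n_rrna < 0:
                raise ValueError("genome sizes and marker counts must be positive")
        if self.mean_contig_bp > min(t.genome_size_bp for t in self.taxa):
            raise ValueError("mean contig length exceeds the smallest genome")


def _fragment_genome(rng: np.random.Generator, size_bp: int, mean_bp: int, sigma: float) -> list[int]:
    """Partition a genome into contig lengths (lognormal draws, remainder last)."""
    lengths: list[int] = []
    remaining = size_bp
    mu = np.log(mean_bp) - sigma**2 / 2.0
    while remaining > 0:
        draw = int(rng.lognormal(mu, sigma)) if sigma > 0 else mean_bp
        draw = max(200, min(draw, remaining))
        # avoid a trailing sliver shorter than anything realistic
        if remaining - draw < 200:
            draw = remaining
        lengths.append(draw)
        remaining -= draw
    return lengths


def simulate_community(spec: CommunitySpec) -> tuple[list[ContigRecord], pd.DataFrame]:
    """Generate contigs with marker hits for one community.

    Returns the contig records (with hits attached) and a truth table of
    one row per taxon (true abundance, depth, genome size, marker count).
    Markers land on contigs with probability proportional to contig
    length, one contig per marker (single-copy).
    """
    rng = np.random.default_rng(spec.seed)
    contigs: list[ContigRecord] = []
    truth_rows = []
    for ti, taxon_spec in enumerate(spec.taxa):
        depth = spec.depth_scale * taxon_spec.abundance
        genome_id = f"G{ti:03d}"
        lengths = _fragment_genome(
            rng, taxon_spec.genome_size_bp, spec.mean_contig_bp, spec.contig_dispersion
        )
        records = []
        for ci, length in enumerate(lengths):
            noise = rng.lognormal(0.0, spec.coverage_sigma) if spec.coverage_sigma > 0 else 1.0
            records.append(
                ContigRecord(
                    contig_id=f"{genome_id}_c{ci:04d}",
                    genome_id=genome_id,
                    length_bp=length,
                    mean_coverage=depth * noise,
                )
            )
        probs = np.array(lengths, dtype=float)
        probs /= probs.sum()
        lo, hi = spec.marker_identity
        n_markers = taxon_spec.n_scg_markers + taxon_spec.n_rrna
        homes = rng.choice(len(records), size=n_markers, p=probs)
        for mi, home in enumerate(homes):
            marker_class = "SCG" if mi < taxon_spec.n_scg_markers else "RRNA"
            records[home].hits.append(
                MarkerHit(
                    gene_id=f"{genome_id}_m{mi:03d}",
                    contig_id=records[home].contig_id,
                    marker_class=marker_class,
                    taxon=taxon_spec.taxon,
                    percent_identity=float(rng.uniform(lo, hi)),
                )
            )
        contigs.extend(records)
        truth_rows.append(
            {
                "genome_id": genome_id,
                "taxon_path": str(taxon_spec.taxon),
                "true_abundance": taxon_spec.abundance,
                "depth": depth,
                "genome_size_bp": taxon_spec.genome_size_bp,
                "n_markers": n_markers,
                "n_contigs": len(records),
            }
        )
    return contigs, pd.DataFrame(truth_rows)


@dataclass(frozen=True)
class ContaminationSpec:
    """Planted cross-taxon contaminant contigs.

    ``rate`` is the fraction of the *final* contig table that is
    contaminant; identities of the contaminants' supporting hits are
    drawn uniformly from ``identity_range``.  Emulates reagent-borne DNA
    and free environmental DNA co-sorted with cells.
    """

    rate: float
    source_taxon: TaxonPath
    identity_range: tuple[float, float] = (50.0, 70.0)
    contig_length_bp: int = 5_000
    coverage: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.rate < 1:
            raise ValueError("contamination rate must be in [0,1)")
        lo, hi = self.identity_range
        if not (0 <= lo <= hi <= 100):
            raise ValueError("identity range must lie within [0,100]")


def inject_contamination(
    contigs: list[ContigRecord],
    spec: ContaminationSpec,
) -> tuple[list[ContigRecord], pd.DataFrame]:
    """Add contaminant contigs so they make up ``spec.rate`` of the table.

    Returns the augmented contig list (host contigs unchanged) and a
    truth table flagging every contig as contaminant or not.
    """
    rng = np.random.default_rng(spec.seed)
    n_host = len(contigs)
    n_cont = int(round(n_host * spec.rate / (1.0 - spec.rate)))
    genome_id = contigs[0].genome_id if contigs else "G000"
    lo, hi = spec.identity_range
    out = list(contigs)
    for i in range(n_cont):
        contig_id = f"{genome_id}_x{i:04d}"
        contig = ContigRecord(
            contig_id=contig_id,
            genome_id=genome_id,
            length_bp=spec.contig_length_bp,
            mean_coverage=spec.coverage,
        )
        contig.hits.append(
            MarkerHit(
                gene_id=f"{contig_id}_p000",
                contig_id=contig_id,
                marker_class="PROT",
                taxon=spec.source_taxon,
                percent_identity=float(rng.uniform(lo, hi)),
            )
        )
        out.append(contig)
    truth = pd.DataFrame(
        {
            "contig_id": [c.contig_id for c in out],
            "is_contaminant": [c.contig_id.rsplit("_", 1)[-1].startswith("x") for c in out],
        }
    )
    return out, truth


@dataclass(frozen=True)
class FunnelSpec:
    """A sorted-plate run with per-stage Bernoulli success probabilities.

    Defaults mirror a five half-384-well-plate run: 880 sorted cells, 16
    empty negative-control wells per plate, and conditional stage success
    probabilities (MDA | sorted, PCR | MDA, Sanger | PCR) of 0.815, 0.586
    and 0.854.  Positive wells emit Cq ~ Normal(mu_pos, sd) and a high
    endpoint RFU; failed reactions and controls never cross threshold
    (no Cq) and emit baseline RFU.
    """

    n_wells: int = 880
    n_plates: int = 5
    controls_per_plate: int = 16
    p_mda: float = 0.815
    p_pcr: float = 0.586
    p_sanger: float = 0.854
    taxon_probs: tuple[tuple[str, float], ...] = (
        ("Bacteria;Patescibacteria", 0.145),
        ("Bacteria;Proteobacteria", 0.35),
        ("Bacteria;Bacteroidetes", 0.25),
        ("Bacteria;Chloroflexi", 0.15),
        ("Bacteria;Firmicutes", 0.105),
    )
    cq_positive_mean: float = 25.0
    cq_positive_sd: float = 2.0
    rfu_positive_mean: float = 5000.0
    rfu_positive_sd: float = 300.0
    rfu_baseline_mean: float = 100.0
    rfu_baseline_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_mda, self.p_pcr, self.p_sanger):
            if not 0 <= p <= 1:
                raise ValueError("stage probabilities must be in [0,1]")
        if abs(sum(p for _, p in self.taxon_probs) - 1.0) > 1e-9:
            raise ValueError("taxon probabilities must sum to 1")


def simulate_sort_run(spec: FunnelSpec) -> tuple[list[WellRecord], pd.DataFrame]:
    """Generate a plate run honouring funnel monotonicity.

    Returns well records (cells + negative controls) and a per-well truth
    table of the stage outcomes.
    """
    rng = np.random.default_rng(spec.seed)
    wells: list[WellRecord] = []
    rows = []
    taxa = [TaxonPath.parse(t) for t, _ in spec.taxon_probs]
    probs = np.array([p for _, p in spec.taxon_probs])
    per_plate = -(-spec.n_wells // spec.n_plates)  # cells per plate, last may be short
    for i in range(spec.n_wells):
        plate = f"P{i // per_plate + 1}"
        well_id = f"{plate}_W{i % per_plate + 1:03d}"
        mda = bool(rng.random() < spec.p_mda)
        pcr = bool(mda and rng.random() < spec.p_pcr)
        sanger = bool(pcr and rng.random() < spec.p_sanger)
        taxon = taxa[rng.choice(len(taxa), p=probs)] if sanger else None
        if mda:
            cq = float(rng.normal(spec.cq_positive_mean, spec.cq_positive_sd))
            rfu = max(0.0, float(rng.normal(spec.rfu_positive_mean, spec.rfu_positive_sd)))
        else:
            cq = None
            rfu = max(0.0, float(rng.normal(spec.rfu_baseline_mean, spec.rfu_baseline_sd)))
        wells.append(
            WellRecord(
                plate_id=plate,
                well_id=well_id,
                n_cells_detected=1,
                cq=cq,
                endpoint_rfu=rfu,
                mda_positive=mda,
                pcr_positive=pcr,
                sanger_ok=sanger,
                taxon=taxon,
            )
        )
        rows.append(
            {
                "well_id": well_id,
                "true_mda": mda,
                "true_pcr": pcr,
                "true_sanger": sanger,
                "taxon_path": str(taxon) if taxon else "",
            }
        )
    for p in range(spec.n_plates):
        plate = f"P{p + 1}"
        for c in range(spec.controls_per_plate):
            rfu = max(0.0, float(rng.normal(spec.rfu_baseline_mean, spec.rfu_baseline_sd)))
            wells.append(
                WellRecord(
                    plate_id=plate,
                    well_id=f"{plate}_NC{c + 1:02d}",
                    n_cells_detected=0,
                    is_negative_control=True,
                    cq=None,
                    endpoint_rfu=rfu,
                )
            )
    return wells, pd.DataFrame(rows)


def simulate_sag_replicates(
    group_sizes: list[int],
    n_singletons: int = 0,
    within_ani: tuple[float, float] = (98.5, 100.0),
    between_ani: tuple[float, float] = (70.0, 90.0),
    within_16s: tuple[float, float] = (100.0, 100.0),
    between_16s: tuple[float, float] = (85.0, 97.0),
    seed: int = 0,
) -> tuple[list[str], PairwiseMatrix, PairwiseMatrix, list[frozenset[str]]]:
    """Pairwise matrices with a planted strain partition.

    ``group_sizes`` gives the replicate count of each multi-SAG strain;
    singleton SAGs are added on top.  Within-strain identities are drawn
    from ``within_ani``/``within_16s`` and between-strain from the
    ``between_*`` ranges; construction is refused when the ranges
    overlap, as the partition would then be ambiguous.  Returns (ids,
    16S matrix, ANI matrix, true partition).
    """
    if within_ani[0] <= between_ani[1]:
        raise ValueError("ambiguous construction: ANI ranges overlap")
    if within_16s[0] <= between_16s[1]:
        raise ValueError("ambiguous construction: 16S ranges overlap")
    rng = np.random.default_rng(seed)
    groups: list[list[str]] = []
    counter = 0
    for size in group_sizes:
        if size < 2:
            raise ValueError("group sizes must be >= 2; use n_singletons for singletons")
        groups.append([f"S{counter + j:03d}" for j in range(size)])
        counter += size
    for _ in range(n_singletons):
        groups.append([f"S{counter:03d}"])
        counter += 1
    ids = [g for group in groups for g in group]
    ani = PairwiseMatrix("ANI")
    id16s = PairwiseMatrix("ID16S")
    member_of = {g: gi for gi, group in enumerate(groups) for g in group}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            same = member_of[a] == member_of[b]
            ani_rng = within_ani if same else between_ani
            s16_rng = within_16s if same else between_16s
            ani.set(a, b, float(rng.uniform(*ani_rng)))
            id16s.set(a, b, float(rng.uniform(*s16_rng)))
    truth = [frozenset(g) for g in groups]
    return ids, id16s, ani, truth
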