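"""Pipeline configuration and the umbrella runner.

``run_pipeline`` executes whichever stages the input directory supports —
contamination screen + abundance (contigs.tsv + marker_hits.tsv), genome
QC (genomes.tsv), SAG grouping (pairwise.tsv), funnel accounting
(wells.tsv) — and writes every report as a TSV plus a provenance log
recording the exact thresholds applied.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .abundance import contig_based_abundance, marker_based_abundance
from .cluster import group_sags
from .funnel import funnel_stats, taxon_proportions
from .io import (
    SCHEMAS,
    read_contigs,
    read_genomes,
    read_pairwise,
    read_wells,
    write_table,
)
from .qc import qc_report, summarize_qc
from .screen import classify_contigs, dominant_taxon, flag_contaminants, filter_assembly
from .taxonomy import DEFAULT_RANKS, RankConfig

logger = logging.getLogger("sagscreen")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Every threshold the pipeline applies, in one serialisable place."""

    ranks: tuple[str, ...] = DEFAULT_RANKS
    contradiction_rank: str = "phylum"
    reporting_rank: str = "phylum"
    identity_threshold: float = 40.0
    t16s: float = 100.0
    tani: float = 98.4
    abundance_method: str = "marker"  # marker | contig
    mda_margin_cycles: float = 5.0
    mda_rfu_sigma: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for value in (self.identity_threshold, self.t16s, self.tani):
            if not 0 <= value <= 100:
                raise ValueError(f"thresholds must be within [0,100], got {value}")
        if self.abundance_method not in ("marker", "contig"):
            raise ValueError("abundance_method must be 'marker' or 'contig'")

    @property
    def rank_config(self) -> RankConfig:
        return RankConfig(ranks=tuple(self.ranks), contradiction_rank=self.contradiction_rank)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["ranks"] = list(self.ranks)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "ranks" in data:
            data["ranks"] = tuple(data["ranks"])
        return cls(**data)


def _screen_stage(config: PipelineConfig, contigs, out: Path) -> None:
    cfg = config.rank_config
    by_genome: dict[str, list] = {}
    for c in contigs:
        by_genome.setdefault(c.genome_id, []).append(c)
    screen_rows, retained_rows, flagged_rows = [], [], []
    for genome_id, group in sorted(by_genome.items()):
        classifications = classify_contigs(group)
        dominant = dominant_taxon(classifications, group, cfg)
        flags = flag_contaminants(classifications, dominant, config.identity_threshold, cfg)
        retained, report = filter_assembly(group, flags)
        screen_rows.append(
            {
                "genome_id": genome_id,
                "dominant_taxon": str(dominant),
                "n_contigs": report.n_contigs,
                "n_flagged": report.n_flagged,
                "total_bp": report.total_bp,
                "flagged_bp": report.flagged_bp,
                "fraction_removed_by_count": report.fraction_removed_by_count,
                "fraction_removed_by_length": report.fraction_removed_by_length,
            }
        )
        retained_rows += [
            {
                "genome_id": c.genome_id,
                "contig_id": c.contig_id,
                "length_bp": c.length_bp,
                "mean_coverage": c.mean_coverage,
            }
            for c in retained
        ]
        flagged_rows += [
            {
                "genome_id": genome_id,
                "contig_id": f.contig_id,
                "selected_class": f.selected_class,
                "lca_taxon": str(f.lca_taxon),
                "mean_identity": f.mean_identity,
                "reason": (
                    f"contradicts {dominant} at {config.contradiction_rank} "
                    f"with identity {f.mean_identity:.1f} > {config.identity_threshold}"
                ),
            }
            for f in flags
        ]
        logger.info(
            "screen %s: %d/%d contigs flagged (identity > %.1f, rank %s)",
            genome_id, report.n_flagged, report.n_contigs,
            config.identity_threshold, config.contradiction_rank,
        )
    write_table(pd.DataFrame(screen_rows), out / "screen_report.tsv")
    write_table(
        pd.DataFrame(retained_rows, columns=list(SCHEMAS["contigs"].columns[i].name for i in range(4))),
        out / "retained_contigs.tsv",
    )
    write_table(
        pd.DataFrame(
            flagged_rows,
            columns=["genome_id", "contig_id", "selected_class", "lca_taxon", "mean_identity", "reason"],
        ),
        out / "flagged_contigs.tsv",
    )


def _abundance_stage(config: PipelineConfig, contigs, out: Path) -> None:
    cfg = config.rank_config
    if config.abundance_method == "marker":
        profile = marker_based_abundance(contigs, config.reporting_rank, cfg)
    else:
        profile = contig_based_abundance(
            contigs, classify_contigs(contigs), config.reporting_rank, cfg
        )
    rows = [
        {"taxon_path": str(t), "fraction": frac}
        for t, frac in sorted(profile.fractions.items(), key=lambda kv: -kv[1])
    ]
    df = pd.DataFrame(rows, columns=["taxon_path", "fraction"])
    df["n_markers_total"] = profile.n_markers
    df["unclassified_fraction"] = profile.unclassified_fraction
    write_table(df, out / "abundance.tsv")


def _qc_stage(config: PipelineConfig, genomes, out: Path) -> None:
    rows = []
    for record in genomes:
        report = qc_report(record)
        rows.append(
            {
                "genome_id": record.genome_id,
                "kind": record.kind,
                "checkm_completeness": record.checkm_completeness,
                "checkm_contamination": record.checkm_contamination,
                "corrected_contamination": report.corrected_contamination,
                "predicted_size_mb": report.predicted_size_mb,
                "tier": report.tier,
            }
        )
    write_table(pd.DataFrame(rows), out / "qc_report.tsv")
    sags = [g for g in genomes if g.kind == "SAG"] or genomes
    summary = summarize_qc(sags)
    write_table(
        pd.DataFrame(
            [
                {
                    "n": summary.n,
                    "mean_completeness": summary.mean_completeness,
                    "mean_corrected_contamination": summary.mean_corrected_contamination,
                    "size_min_mb": summary.size_range_mb[0],
                    "size_max_mb": summary.size_range_mb[1],
                    "n_high": summary.tier_counts["high"],
                    "n_medium": summary.tier_counts["medium"],
                    "n_low": summary.tier_counts["low"],
                }
            ]
        ),
        out / "qc_summary.tsv",
    )


def _group_stage(config: PipelineConfig, matrices, out: Path) -> None:
    ids = sorted(
        {g for m in matrices.values() for a, b, _ in m.pairs() for g in (a, b)}
    )
    result = group_sags(
        ids,
        id16s=matrices.get("ID16S"),
        ani=matrices.get("ANI"),
        t16s=config.t16s,
        tani=config.tani,
    )
    rows = [
        {"genome_id": member, "group": result.labels[comp], "group_size": len(comp)}
        for comp in result.components
        for member in sorted(comp)
    ]
    write_table(pd.DataFrame(rows, columns=["genome_id", "group", "group_size"]), out / "groups.tsv")
    logger.info(
        "grouping: %d entities (%d CAGs, %d singletons) at 16S >= %.1f / ANI > %.1f",
        result.n_entities, len(result.cag_components), len(result.singletons),
        config.t16s, config.tani,
    )


def _funnel_stage(config: PipelineConfig, wells, out: Path) -> None:
    report = funnel_stats(wells)
    write_table(
        pd.DataFrame(
            [
                {
                    "n_sorted": report.n_sorted,
                    "n_mda_positive": report.n_mda_positive,
                    "n_pcr_positive": report.n_pcr_positive,
                    "n_sanger_ok": report.n_sanger_ok,
                    "pct_mda_of_sorted": report.pct_mda_of_sorted,
                    "pct_pcr_of_mda": report.pct_pcr_of_mda,
                    "pct_sanger_of_mda": report.pct_sanger_of_mda,
                }
            ]
        ),
        out / "funnel_report.tsv",
    )
    try:
        profile = taxon_proportions(wells, config.reporting_rank, config.rank_config)
    except ValueError:
        return
    write_table(
        pd.DataFrame(
            [
                {"taxon_path": str(t), "fraction": f}
                for t, f in sorted(profile.fractions.items(), key=lambda kv: -kv[1])
            ],
            columns=["taxon_path", "fraction"],
        ),
        out / "sorted_taxa.tsv",
    )


def run_pipeline(config: PipelineConfig, input_dir: str | Path, out_dir: str | Path) -> list[str]:
    """Run every stage whose inputs are present; returns the stages run.

    Raises ``FileNotFoundError`` before any stage runs if the input
    directory contains none of the recognised tables.
    """
    input_dir, out = Path(input_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[tuple[str, callable]] = []
    contigs_path, hits_path = input_dir / "contigs.tsv", input_dir / "marker_hits.tsv"
    if contigs_path.exists():
        contigs = read_contigs(contigs_path, hits_path if hits_path.exists() else None)
        stages.append(("screen", lambda: _screen_stage(config, contigs, out)))
        if hits_path.exists():
            stages.append(("abundance", lambda: _abundance_stage(config, contigs, out)))
    if (input_dir / "genomes.tsv").exists():
        genomes = read_genomes(input_dir / "genomes.tsv")
        stages.append(("qc", lambda: _qc_stage(config, genomes, out)))
    if (input_dir / "pairwise.tsv").exists():
        matrices = read_pairwise(input_dir / "pairwise.tsv")
        stages.append(("group", lambda: _group_stage(config, matrices, out)))
    if (input_dir / "wells.tsv").exists():
        wells = read_wells(input_dir / "wells.tsv")
        stages.append(("funnel", lambda: _funnel_stage(config, wells, out)))
    if not stages:
        raise FileNotFoundError(
            f"no recognised input tables (contigs/genomes/pairwise/wells) in {input_dir}"
        )
    ran = []
    for name, stage in stages:
        try:
            stage()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        ran.append(name)
    provenance = {
        "sagscreen_version": __version__,
        "stages": ran,
        "config": {**asdict(config), "ranks": list(config.ranks)},
    }
    (out / "provenance.yaml").write_text(yaml.safe_dump(provenance, sort_keys=False))
    return ran
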