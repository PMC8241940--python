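"""Community abundance from metagenome marker genes.

Two estimators over the same contig/marker tables:

* **marker-based** — each universal marker gene (single-copy protein or
  rRNA) independently contributes its contig's mean coverage to its own
  taxon.  Because every genome carries the same universal markers
  regardless of how it assembled, the estimate is invariant to contig
  fragmentation: splitting a contig redistributes markers but preserves
  the coverage each marker reports.
* **contig-based** (legacy) — each classified contig contributes its
  coverage once, no matter how many markers it encodes.  Fragmented
  genomes then gain weight (many small one-marker contigs beat one large
  multi-marker contig), inflating poorly assembling taxa relative to
  small, cleanly assembling ones.

Markers or contigs not resolved to the reporting rank go into an explicit
"unclassified" bucket and, by default, are excluded from the simplex
normalisation (reported as a separate fraction of the grand total).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .screen import ContigClassification, ContigRecord
from .taxonomy import RankConfig, TaxonPath

__all__ = [
    "AbundanceProfile",
    "marker_based_abundance",
    "contig_based_abundance",
    "compare_profiles",
]

#: Marker classes counted by the marker-based estimator.
UNIVERSAL_CLASSES = ("RRNA", "SCG")


@dataclass(frozen=True)
class AbundanceProfile:
    """Relative abundances at a fixed reporting rank.

    ``fractions`` sum to 1 over classified taxa; ``unclassified_fraction``
    is the share of total weight not resolved to the reporting rank (it is
    outside the simplex unless the profile was built with
    ``include_unclassified=True``, in which case it appears under the root
    path as well).
    """

    rank: str
    fractions: dict[TaxonPath, float]
    n_markers: int
    unclassified_fraction: float = 0.0

    def fraction_of(self, taxon: TaxonPath | str) -> float:
        """Fraction for ``taxon``, truncated to the profile's reporting depth."""
        if isinstance(taxon, str):
            taxon = TaxonPath.parse(taxon)
        if self.fractions:
            depth = max(len(t) for t in self.fractions)
            if len(taxon) > depth:
                taxon = taxon.truncate(depth)
        return self.fractions.get(taxon, 0.0)


def _normalise(
    weights: dict[TaxonPath, float],
    unclassified: float,
    rank: str,
    n_markers: int,
    include_unclassified: bool,
) -> AbundanceProfile:
    grand = sum(weights.values()) + unclassified
    if include_unclassified:
        fractions = {t: w / grand for t, w in weights.items()}
        if unclassified > 0:
            fractions[TaxonPath()] = unclassified / grand
    else:
        total = sum(weights.values())
        if total == 0:
            raise ValueError("empty profile: no weight at the reporting rank")
        fractions = {t: w / total for t, w in weights.items()}
    return AbundanceProfile(
        rank=rank,
        fractions=fractions,
        n_markers=n_markers,
        unclassified_fraction=(unclassified / grand) if grand else 0.0,
    )


def marker_based_abundance(
    contigs: list[ContigRecord],
    rank: str = "phylum",
    cfg: RankConfig | None = None,
    include_unclassified: bool = False,
) -> AbundanceProfile:
    """Quantify each taxon by the coverage of its universal marker genes."""
    cfg = cfg or RankConfig()
    depth = cfg.depth_of(rank) + 1
    weights: dict[TaxonPath, float] = defaultdict(float)
    unclassified = 0.0
    n_markers = 0
    for contig in contigs:
        for hit in contig.hits:
            if hit.marker_class not in UNIVERSAL_CLASSES:
                continue
            n_markers += 1
            if len(hit.taxon) >= depth:
                weights[hit.taxon.truncate(depth)] += contig.mean_coverage
            else:
                unclassified += contig.mean_coverage
    if n_markers == 0:
        raise ValueError("empty profile: no universal marker genes")
    return _normalise(dict(weights), unclassified, rank, n_markers, include_unclassified)


def contig_based_abundance(
    contigs: list[ContigRecord],
    classifications: list[ContigClassification],
    rank: str = "phylum",
    cfg: RankConfig | None = None,
    include_unclassified: bool = False,
) -> AbundanceProfile:
    """Legacy estimator: each classified contig contributes its coverage once."""
    cfg = cfg or RankConfig()
    depth = cfg.depth_of(rank) + 1
    coverage = {c.contig_id: c.mean_coverage for c in contigs}
    weights: dict[TaxonPath, float] = defaultdict(float)
    unclassified = 0.0
    n_classified = 0
    for cl in classifications:
        if cl.selected_class == "NONE":
            continue
        n_classified += 1
        cov = coverage.get(cl.contig_id, 0.0)
        if len(cl.lca_taxon) >= depth:
            weights[cl.lca_taxon.truncate(depth)] += cov
        else:
            unclassified += cov
    if n_classified == 0:
        raise ValueError("empty profile: no classified contigs")
    return _normalise(dict(weights), unclassified, rank, n_classified, include_unclassified)


def compare_profiles(p1: AbundanceProfile, p2: AbundanceProfile) -> pd.DataFrame:
    """Per-taxon difference table (p1 − p2), sorted by |difference| descending."""
    if p1.rank != p2.rank:
        raise ValueError(f"reporting rank mismatch: {p1.rank!r} vs {p2.rank!r}")
    taxa = sorted(set(p1.fractions) | set(p2.fractions))
    rows = [
        {
            "taxon": str(t),
            "fraction_1": p1.fractions.get(t, 0.0),
            "fraction_2": p2.fractions.get(t, 0.0),
            "difference": p1.fractions.get(t, 0.0) - p2.fractions.get(t, 0.0),
        }
        for t in taxa
    ]
    df = pd.DataFrame(rows, columns=["taxon", "fraction_1", "fraction_2", "difference"])
    return df.reindex(
        df["difference"].abs().sort_values(ascending=False, kind="stable").index
    ).reset_index(drop=True)
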