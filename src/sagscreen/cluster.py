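"""Grouping SAGs into co-assembly candidates and related genome comparisons.

SAGs sorted from the same population should be re-assembled together: two
SAGs qualify for the same co-assembled genome (CAG) when their 16S rRNA
genes are identical (100%) and/or their average nucleotide identity (ANI)
exceeds a strain-level threshold (98.4% by default; 95% is a common
species-level alternative and both appear in practice — the threshold is
plain config here).  Grouping is the transitive closure of qualifying
pairs, i.e. connected components of the qualifying-edge graph.

Also here: the admission filter for public reference genomes (N50 >
35 kb, completeness > 70%, corrected contamination < 5%), agreement
checking across independent classification methods (16S, marker-gene
taxonomy, MLSA), a threshold-based taxonomic-novelty rank against the
nearest admitted reference, and interval arithmetic for the genome
regions a SAG/CAG holds that its matching metagenome bin lacks.

ANI/AAI/16S identity values are *inputs* (computed upstream by OrthoANI,
aai.rb, ARB, ...).  ``naive_fragment_identity`` is a deliberately simple
fragment-identity estimator for synthetic FASTA fixtures only; it is not
OrthoANI-equivalent and must not be used for real genome comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .taxonomy import TaxonPath, lca

__all__ = [
    "PairwiseMatrix",
    "GroupingResult",
    "ReferenceMeta",
    "NoveltyThresholds",
    "group_sags",
    "reference_filter",
    "concordance_check",
    "ConcordanceReport",
    "novelty_rank",
    "unique_region_summary",
    "UniqueRegionSummary",
    "naive_fragment_identity",
]

METRICS = ("ANI", "AAI", "ID16S")


class PairwiseMatrix:
    """Sparse symmetric matrix of percent identities between genomes.

    Missing pairs are allowed (e.g. no full-length 16S in one SAG); the
    diagonal, when present, must be 100.
    """

    def __init__(self, metric: str, values: Mapping[tuple[str, str], float] | None = None):
        if metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
        self.metric = metric
        self._values: dict[frozenset[str] | tuple[str, str], float] = {}
        if values:
            for (a, b), v in values.items():
                self.set(a, b, v)

    @staticmethod
    def _key(a: str, b: str):
        return (a, a) if a == b else frozenset((a, b))

    def set(self, a: str, b: str, value: float) -> None:
        if not 0 <= value <= 100:
            raise ValueError(f"identity must be in [0,100], got {value}")
        if a == b and value != 100:
            raise ValueError(f"diagonal entry ({a},{a}) must be 100, got {value}")
        key = self._key(a, b)
        existing = self._values.get(key)
        if existing is not None and existing != value:
            raise ValueError(
                f"asymmetric matrix: ({a},{b}) given as both {existing} and {value}"
            )
        self._values[key] = value

    def get(self, a: str, b: str, default: float | None = None) -> float | None:
        if a == b:
            return 100.0
        return self._values.get(self._key(a, b), default)

    def pairs(self) -> Iterable[tuple[str, str, float]]:
        for key, v in self._values.items():
            if isinstance(key, frozenset):
                a, b = sorted(key)
            else:
                a, b = key
            yield a, b, v

    def __len__(self) -> int:
        return len(self._values)


@dataclass(frozen=True)
class GroupingResult:
    """Partition of genome ids into CAG components and singleton SAGs."""

    components: tuple[frozenset[str], ...]
    #: (a, b) → which criteria fired, subset of {"16S", "ANI"}
    edges: dict[tuple[str, str], tuple[str, ...]]
    #: component → label; multi-member components get CAG1, CAG2, ...
    labels: dict[frozenset[str], str]

    @property
    def n_entities(self) -> int:
        return len(self.components)

    @property
    def cag_components(self) -> tuple[frozenset[str], ...]:
        return tuple(c for c in self.components if len(c) > 1)

    @property
    def singletons(self) -> tuple[str, ...]:
        return tuple(sorted(next(iter(c)) for c in self.components if len(c) == 1))


def group_sags(
    ids: Sequence[str],
    id16s: PairwiseMatrix | None = None,
    ani: PairwiseMatrix | None = None,
    t16s: float = 100.0,
    tani: float = 98.4,
) -> GroupingResult:
    """Group SAGs whose 16S identity ≥ t16s and/or ANI > tani (strict).

    Components are the transitive closure of qualifying edges; order of
    ``ids`` and of matrix entries does not affect the partition.  CAG
    labels are assigned in order of each component's smallest member id.
    """
    if not (0 < t16s <= 100) or not (0 < tani <= 100):
        raise ValueError("thresholds must be in (0,100]")
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    known = set(ids)

    def qualifying(matrix: PairwiseMatrix | None, fires) -> None:
        if matrix is None:
            return
        for a, b, v in matrix.pairs():
            if a in known and b in known and a != b and fires(v):
                key = (min(a, b), max(a, b))
                crit = "16S" if matrix.metric == "ID16S" else matrix.metric
                existing = set(edge_criteria.get(key, ()))
                existing.add(crit)
                edge_criteria[key] = tuple(sorted(existing))
                graph.add_edge(a, b)

    edge_criteria: dict[tuple[str, str], tuple[str, ...]] = {}
    qualifying(id16s, lambda v: v >= t16s)
    qualifying(ani, lambda v: v > tani)

    components = tuple(
        sorted((frozenset(c) for c in nx.connected_components(graph)), key=lambda c: min(c))
    )
    labels: dict[frozenset[str], str] = {}
    cag_n = 0
    for comp in components:
        if len(comp) > 1:
            cag_n += 1
            labels[comp] = f"CAG{cag_n}"
        else:
            labels[comp] = next(iter(comp))
    return GroupingResult(components=components, edges=edge_criteria, labels=labels)


@dataclass(frozen=True)
class ReferenceMeta:
    """Assembly metadata of a candidate reference genome."""

    genome_id: str
    n50_bp: int
    completeness: float
    corrected_contamination: float


def reference_filter(meta: ReferenceMeta) -> bool:
    """Admit a reference iff N50 > 35 kb, completeness > 70, contamination < 5.

    All three comparisons are strict.
    """
    return (
        meta.n50_bp > 35_000
        and meta.completeness > 70.0
        and meta.corrected_contamination < 5.0
    )


@dataclass(frozen=True)
class ConcordanceReport:
    """Agreement of independent classification methods per genome."""

    #: genome → (n_methods, agreement depth, total agreement at common depth)
    per_genome: dict[str, tuple[int, int, bool]]
    n_genomes: int
    n_total_agreement: int          # genomes where all available methods agree
    n_full_method_agreement: int    # ... among genomes with >= 3 methods
    n_partial_methods: int          # genomes assessed by fewer than 3 methods


def concordance_check(
    assignments: Mapping[str, Mapping[str, TaxonPath]],
) -> ConcordanceReport:
    """Compare per-genome classifications from multiple methods.

    A genome is in *total agreement* when all its available methods yield
    identical paths down to their common depth (the shallowest method's
    depth).  The reported agreement depth is the length of the methods'
    LCA, i.e. the deepest rank where all agree.
    """
    per_genome: dict[str, tuple[int, int, bool]] = {}
    n_total = n_full = n_partial = 0
    for genome, methods in assignments.items():
        paths = list(methods.values())
        if not paths:
            raise ValueError(f"genome {genome!r} has no classifications")
        common_depth = min(len(p) for p in paths)
        total = all(p.truncate(common_depth) == paths[0].truncate(common_depth) for p in paths)
        depth = len(lca(paths))
        per_genome[genome] = (len(paths), depth, total)
        if total:
            n_total += 1
            if len(paths) >= 3:
                n_full += 1
        if len(paths) < 3:
            n_partial += 1
    return ConcordanceReport(
        per_genome=per_genome,
        n_genomes=len(per_genome),
        n_total_agreement=n_total,
        n_full_method_agreement=n_full,
        n_partial_methods=n_partial,
    )


@dataclass(frozen=True)
class NoveltyThresholds:
    """Literature-conventional identity thresholds for rank boundaries."""

    species_ani: float = 95.0
    genus_aai: float = 65.0
    family_aai: float = 45.0


def novelty_rank(
    ani: float | None = None,
    aai: float | None = None,
    id16s: float | None = None,
    thresholds: NoveltyThresholds | None = None,
    insufficient_data: bool = False,
) -> str:
    """Coarse taxonomic novelty from identity to the nearest admitted reference.

    Descending rule: ANI at/above the species threshold → same_species;
    else AAI at/above the genus threshold → novel_species (same genus);
    else AAI at/above the family threshold → novel_genus; else (including
    no usable metric) → novel_family.  ``insufficient_data`` short-circuits
    to indeterminate (e.g. the genome is too incomplete to compare).
    """
    t = thresholds or NoveltyThresholds()
    if insufficient_data:
        return "indeterminate"
    if ani is None and aai is None and id16s is None:
        raise ValueError("at least one identity metric is required")
    if ani is not None and ani >= t.species_ani:
        return "same_species"
    if aai is not None and aai >= t.genus_aai:
        return "novel_species"
    if aai is not None and aai >= t.family_aai:
        return "novel_genus"
    return "novel_family"


@dataclass(frozen=True)
class UniqueRegionSummary:
    """Accounting of genome sequence absent from an aligned partner genome."""

    unshared_bp: int
    unshared_fraction: float
    n_regions: int
    min_region_bp: int
    max_region_bp: int


def _merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def unique_region_summary(
    genome_length_bp: int,
    aligned_intervals: Sequence[tuple[int, int]],
    min_region_bp: int = 200,
) -> UniqueRegionSummary:
    """Summarise the genome regions NOT covered by alignments.

    Intervals are 0-based half-open and may overlap; they are merged, and
    the complement within [0, genome_length) gives the unshared regions.
    Regions shorter than ``min_region_bp`` are dropped before counting
    and summing (set 0 for the exact complement).
    """
    if genome_length_bp <= 0:
        raise ValueError("genome length must be positive")
    for start, end in aligned_intervals:
        if not (0 <= start < end <= genome_length_bp):
            raise ValueError(
                f"interval [{start},{end}) out of bounds for length {genome_length_bp}"
            )
    merged = _merge_intervals(list(aligned_intervals))
    gaps: list[tuple[int, int]] = []
    cursor = 0
    for start, end in merged:
        if start > cursor:
            gaps.append((cursor, start))
        cursor = end
    if cursor < genome_length_bp:
        gaps.append((cursor, genome_length_bp))
    regions = [(s, e) for s, e in gaps if e - s >= min_region_bp]
    sizes = [e - s for s, e in regions]
    total = sum(sizes)
    return UniqueRegionSummary(
        unshared_bp=total,
        unshared_fraction=total / genome_length_bp,
        n_regions=len(regions),
        min_region_bp=min(sizes) if sizes else 0,
        max_region_bp=max(sizes) if sizes else 0,
    )


def naive_fragment_identity(
    seq_a: str,
    seq_b: str,
    fragment_bp: int = 1020,
    k: int = 16,
) -> float:
    """Fixture-grade whole-genome identity estimate from FASTA sequences.

    Chops each sequence into non-overlapping fragments; each fragment is
    placed on the partner sequence at its best shared-k-mer anchor offset
    and scored by ungapped identity; fragments with no anchor score 0.
    The result averages both directions.  This is NOT OrthoANI and exists
    only so synthetic end-to-end grouping tests can start from sequence.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if min(len(seq_a), len(seq_b)) < fragment_bp:
        raise ValueError(f"sequences must be at least {fragment_bp} bp")

    def kmer_index(seq: str) -> dict[str, list[int]]:
        index: dict[str, list[int]] = {}
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append(i)
        return index

    def one_direction(query: str, target: str) -> list[float]:
        index = kmer_index(target)
        identities = []
        for fstart in range(0, len(query) - fragment_bp + 1, fragment_bp):
            frag = query[fstart : fstart + fragment_bp]
            offsets = set()
            for i in range(0, fragment_bp - k + 1, k):
                for pos in index.get(frag[i : i + k], ()):
                    offsets.add(pos - i)
            best = 0.0
            for off in offsets:
                if off < 0 or off + fragment_bp > len(target):
                    continue
                window = target[off : off + fragment_bp]
                matches = sum(x == y for x, y in zip(frag, window))
                best = max(best, 100.0 * matches / fragment_bp)
            identities.append(best)
        return identities

    scores = one_direction(seq_a, seq_b) + one_direction(seq_b, seq_a)
    return sum(scores) / len(scores)
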