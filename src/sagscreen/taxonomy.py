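"""Taxonomic lineages and the lowest-common-ancestor (LCA) classifier.

Lineages are SILVA-style semicolon-delimited name paths ("Bacteria;
Patescibacteria;Saccharibacteria").  A path may be truncated at any depth
(an unclassified tail) but never skips an intermediate rank, so the rank of
each name is positional and LCA reduces to the longest common prefix —
well-defined without a reference tree.

Two lineages *contradict* each other only when both are resolved down to a
configurable evaluation rank (phylum by default) and diverge at or above
it.  A truncated path is indeterminate, never contradicting: a contig
classified only as "Bacteria" carries no evidence against any bacterial
host genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "TaxonPath",
    "RankConfig",
    "DEFAULT_RANKS",
    "RANKS_WITH_SUPERPHYLUM",
    "lca",
    "contradicts",
]

#: Canonical rank order, domain downward.
DEFAULT_RANKS: tuple[str, ...] = (
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

#: Variant with the optional superphylum slot between domain and phylum,
#: for communities annotated with CPR-style superphyla (Parcubacteria,
#: Microgenomates, ...).
RANKS_WITH_SUPERPHYLUM: tuple[str, ...] = (
    "domain",
    "superphylum",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)


@dataclass(frozen=True, order=True)
class TaxonPath:
    """An ordered lineage of taxon names, domain downward.

    The empty path is the root (fully unclassified).  Names are compared
    verbatim; rank labels live in :class:`RankConfig` and are positional.
    """

    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in self.names:
            if not isinstance(name, str) or not name:
                raise ValueError(f"taxon names must be non-empty strings, got {name!r}")

    @classmethod
    def parse(cls, text: str, sep: str = ";") -> "TaxonPath":
        """Parse a semicolon-delimited lineage; blank/whitespace → root."""
        text = (text or "").strip()
        if not text:
            return cls()
        return cls(tuple(part.strip() for part in text.split(sep)))

    def __str__(self) -> str:
        return ";".join(self.names)

    def __len__(self) -> int:
        return len(self.names)

    def __bool__(self) -> bool:
        return bool(self.names)

    @property
    def is_root(self) -> bool:
        return not self.names

    def truncate(self, depth: int) -> "TaxonPath":
        """Prefix of the path with at most ``depth`` ranks."""
        if depth < 0:
            raise ValueError("depth must be non-negative")
        return TaxonPath(self.names[:depth])

    def is_prefix_of(self, other: "TaxonPath") -> bool:
        return self.names == other.names[: len(self.names)]

    def name_at(self, depth: int) -> str | None:
        """Name at 0-based ``depth``, or None if the path is shorter."""
        return self.names[depth] if depth < len(self.names) else None


#: The root (zero-length) path.
ROOT = TaxonPath()


@dataclass(frozen=True)
class RankConfig:
    """Canonical rank labels and the rank at which contradictions are judged."""

    ranks: tuple[str, ...] = DEFAULT_RANKS
    contradiction_rank: str = "phylum"

    def __post_init__(self) -> None:
        if len(set(self.ranks)) != len(self.ranks):
            raise ValueError("rank labels must be unique")
        if self.contradiction_rank not in self.ranks:
            raise ValueError(
                f"contradiction rank {self.contradiction_rank!r} not in {self.ranks}"
            )

    def depth_of(self, rank: str) -> int:
        """0-based depth of ``rank`` in the canonical order."""
        try:
            return self.ranks.index(rank)
        except ValueError:
            raise ValueError(f"unknown rank {rank!r}") from None

    @property
    def contradiction_depth(self) -> int:
        return self.depth_of(self.contradiction_rank)

    def truncate_to_rank(self, path: TaxonPath, rank: str) -> TaxonPath:
        """Prefix of ``path`` through ``rank`` (inclusive)."""
        return path.truncate(self.depth_of(rank) + 1)

    def rank_of_depth(self, depth: int) -> str | None:
        """Rank label for 0-based ``depth``, None past the canonical list."""
        return self.ranks[depth] if 0 <= depth < len(self.ranks) else None


def lca(paths: Iterable[TaxonPath]) -> TaxonPath:
    """Lowest common ancestor: the longest prefix shared by all paths.

    Raises ``ValueError`` on an empty collection ("no classifications").
    Idempotent and order-invariant; the result is a prefix of every input.
    """
    it = iter(paths)
    try:
        first = next(it)
    except StopIteration:
        raise ValueError("no classifications") from None
    common = list(first.names)
    for path in it:
        depth = 0
        for a, b in zip(common, path.names):
            if a != b:
                break
            depth += 1
        del common[depth:]
        if not common:
            break
    return TaxonPath(tuple(common))


def contradicts(a: TaxonPath, b: TaxonPath, cfg: RankConfig | None = None) -> bool:
    """True iff ``a`` and ``b`` disagree at the contradiction rank.

    Both paths must be resolved to at least the contradiction rank;
    otherwise the comparison is indeterminate and returns False (a prefix
    relation is never a contradiction).  Symmetric and irreflexive.
    """
    cfg = cfg or RankConfig()
    depth = cfg.contradiction_depth
    if len(a) <= depth or len(b) <= depth:
        return False
    return a.names[: depth + 1] != b.names[: depth + 1]
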