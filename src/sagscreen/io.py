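"""TSV readers/writers with schema validation.

One tabular dialect everywhere: tab-separated, header row, UTF-8, '.'
decimal, empty field = absent value.  Percentages are on the 0–100 scale
in every table; fractions appear only inside abundance profiles.
Validation errors name the offending column and 1-based data row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import pandas as pd

from .cluster import METRICS, PairwiseMatrix, ReferenceMeta
from .funnel import WellRecord
from .qc import AssemblyRecord
from .screen import MARKER_PRECEDENCE, ContigRecord, MarkerHit
from .taxonomy import TaxonPath

__all__ = [
    "Column",
    "Schema",
    "SchemaError",
    "read_table",
    "write_table",
    "SCHEMAS",
    "read_contigs",
    "write_contigs",
    "read_genomes",
    "write_genomes",
    "read_wells",
    "write_wells",
    "read_pairwise",
    "write_pairwise",
    "read_references",
]


class SchemaError(ValueError):
    """A table violated its schema (missing column, bad type, bad value)."""


@dataclass(frozen=True)
class Column:
    name: str
    kind: str  # "str" | "int" | "float" | "bool"
    required: bool = True          # column must be present
    allow_missing: bool = False    # empty cells permitted
    check: Callable[[object], bool] | None = None
    check_msg: str = ""


@dataclass(frozen=True)
class Schema:
    name: str
    columns: tuple[Column, ...]


def _coerce(value, col: Column, row: int):
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        if col.allow_missing:
            return None
        raise SchemaError(f"{col.name!r} missing in row {row}")
    try:
        if col.kind == "int":
            out = int(value)
        elif col.kind == "float":
            out = float(value)
        elif col.kind == "bool":
            if isinstance(value, bool):
                out = value
            else:
                text = str(value).strip().lower()
                if text in ("true", "1", "yes"):
                    out = True
                elif text in ("false", "0", "no"):
                    out = False
                else:
                    raise ValueError(text)
        else:
            out = str(value)
    except (TypeError, ValueError):
        raise SchemaError(
            f"{col.name!r} in row {row}: cannot read {value!r} as {col.kind}"
        ) from None
    if col.check is not None and not col.check(out):
        raise SchemaError(f"{col.name!r} in row {row}: value {out!r} {col.check_msg}")
    return out


def read_table(path: str | Path, schema: Schema) -> pd.DataFrame:
    """Read and validate a TSV against ``schema``.

    Returns a DataFrame with coerced values; absent optional values are
    None.  Raises :class:`SchemaError` naming the first offending cell.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[])
    for col in schema.columns:
        if col.required and col.name not in df.columns:
            raise SchemaError(f"table {schema.name}: missing column {col.name!r} in {path}")
    out: dict[str, list] = {}
    for col in schema.columns:
        if col.name not in df.columns:
            out[col.name] = [None] * len(df)
            continue
        out[col.name] = [
            _coerce(v, col, i + 1) for i, v in enumerate(df[col.name].tolist())
        ]
    # object dtype for nullable columns keeps absent values as None, not NaN
    return pd.DataFrame(
        {
            name: (
                pd.Series(vals, dtype=object)
                if any(c.name == name and c.allow_missing for c in schema.columns)
                else vals
            )
            for name, vals in out.items()
        }
    )


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame as the standard TSV dialect (None → empty field)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep="")


def _nonneg(x) -> bool:
    return x >= 0


def _pct(x) -> bool:
    return 0 <= x <= 100


SCHEMAS: dict[str, Schema] = {
    "contigs": Schema(
        "contigs",
        (
            Column("genome_id", "str"),
            Column("contig_id", "str"),
            Column("length_bp", "int", check=lambda x: x >= 1, check_msg="must be >= 1"),
            Column("mean_coverage", "float", check=_nonneg, check_msg="must be >= 0"),
        ),
    ),
    "marker_hits": Schema(
        "marker_hits",
        (
            Column("genome_id", "str"),
            Column("contig_id", "str"),
            Column("gene_id", "str"),
            Column(
                "marker_class",
                "str",
                check=lambda x: x in MARKER_PRECEDENCE,
                check_msg=f"must be one of {MARKER_PRECEDENCE}",
            ),
            Column("taxon_path", "str", allow_missing=True),
            Column("percent_identity", "float", check=_pct, check_msg="must be in [0,100]"),
        ),
    ),
    "genomes": Schema(
        "genomes",
        (
            Column("genome_id", "str"),
            Column(
                "kind",
                "str",
                check=lambda x: x in ("SAG", "CAG", "MAG", "REF"),
                check_msg="must be SAG|CAG|MAG|REF",
            ),
            Column("size_mb", "float", check=lambda x: x > 0, check_msg="must be > 0"),
            Column("checkm_completeness", "float", check=_pct, check_msg="must be in [0,100]"),
            Column("checkm_contamination", "float", check=_nonneg, check_msg="must be >= 0"),
            Column("strain_heterogeneity", "float", check=_pct, check_msg="must be in [0,100]"),
            Column("gc", "float", required=False, allow_missing=True),
            Column("corrected_contamination", "float", required=False, allow_missing=True),
        ),
    ),
    "pairwise": Schema(
        "pairwise",
        (
            Column("id_a", "str"),
            Column("id_b", "str"),
            Column(
                "metric", "str", check=lambda x: x in METRICS, check_msg=f"must be one of {METRICS}"
            ),
            Column("value", "float", check=_pct, check_msg="must be in [0,100]"),
        ),
    ),
    "references": Schema(
        "references",
        (
            Column("genome_id", "str"),
            Column("n50_bp", "int", check=_nonneg, check_msg="must be >= 0"),
            Column("completeness", "float", check=_pct, check_msg="must be in [0,100]"),
            Column("contamination", "float", check=_nonneg, check_msg="must be >= 0"),
        ),
    ),
    "wells": Schema(
        "wells",
        (
            Column("plate_id", "str"),
            Column("well_id", "str"),
            Column("n_cells", "int", check=_nonneg, check_msg="must be >= 0"),
            Column("is_negative_control", "bool"),
            Column("cq", "float", allow_missing=True),
            Column("endpoint_rfu", "float", check=_nonneg, check_msg="must be >= 0"),
            Column("mda_positive", "bool"),
            Column("pcr_positive", "bool"),
            Column("sanger_ok", "bool"),
            Column("taxon_path", "str", allow_missing=True),
        ),
    ),
}


# ---------------------------------------------------------------------------
# typed record conversions

def read_contigs(contigs_path: str | Path, hits_path: str | Path | None = None) -> list[ContigRecord]:
    """Load contigs.tsv (+ optional marker_hits.tsv) into contig records."""
    df = read_table(contigs_path, SCHEMAS["contigs"])
    records = {
        row.contig_id: ContigRecord(
            contig_id=row.contig_id,
            genome_id=row.genome_id,
            length_bp=row.length_bp,
            mean_coverage=row.mean_coverage,
        )
        for row in df.itertuples()
    }
    if hits_path is not None:
        hits = read_table(hits_path, SCHEMAS["marker_hits"])
        for i, row in enumerate(hits.itertuples(), start=1):
            if row.contig_id not in records:
                raise SchemaError(
                    f"marker_hits row {i}: unknown contig {row.contig_id!r}"
                )
            records[row.contig_id].hits.append(
                MarkerHit(
                    gene_id=row.gene_id,
                    contig_id=row.contig_id,
                    marker_class=row.marker_class,
                    taxon=TaxonPath.parse(row.taxon_path or ""),
                    percent_identity=row.percent_identity,
                )
            )
    return list(records.values())


def write_contigs(
    contigs: list[ContigRecord],
    contigs_path: str | Path,
    hits_path: str | Path | None = None,
) -> None:
    write_table(
        pd.DataFrame(
            {
                "genome_id": [c.genome_id for c in contigs],
                "contig_id": [c.contig_id for c in contigs],
                "length_bp": [c.length_bp for c in contigs],
                "mean_coverage": [c.mean_coverage for c in contigs],
            }
        ),
        contigs_path,
    )
    if hits_path is not None:
        rows = [
            {
                "genome_id": c.genome_id,
                "contig_id": h.contig_id,
                "gene_id": h.gene_id,
                "marker_class": h.marker_class,
                "taxon_path": str(h.taxon),
                "percent_identity": h.percent_identity,
            }
            for c in contigs
            for h in c.hits
        ]
        write_table(
            pd.DataFrame(
                rows,
                columns=[
                    "genome_id",
                    "contig_id",
                    "gene_id",
                    "marker_class",
                    "taxon_path",
                    "percent_identity",
                ],
            ),
            hits_path,
        )


def read_genomes(path: str | Path) -> list[AssemblyRecord]:
    df = read_table(path, SCHEMAS["genomes"])
    return [
        AssemblyRecord(
            genome_id=row.genome_id,
            kind=row.kind,
            size_mb=row.size_mb,
            checkm_completeness=row.checkm_completeness,
            checkm_contamination=row.checkm_contamination,
            strain_heterogeneity=row.strain_heterogeneity,
            gc=row.gc,
            corrected_contamination=row.corrected_contamination,
        )
        for row in df.itertuples()
    ]


def write_genomes(records: list[AssemblyRecord], path: str | Path) -> None:
    write_table(
        pd.DataFrame(
            {
                "genome_id": [r.genome_id for r in records],
                "kind": [r.kind for r in records],
                "size_mb": [r.size_mb for r in records],
                "checkm_completeness": [r.checkm_completeness for r in records],
                "checkm_contamination": [r.checkm_contamination for r in records],
                "strain_heterogeneity": [r.strain_heterogeneity for r in records],
                "gc": [r.gc for r in records],
                "corrected_contamination": [r.corrected_contamination for r in records],
            }
        ),
        path,
    )


def read_wells(path: str | Path) -> list[WellRecord]:
    df = read_table(path, SCHEMAS["wells"])
    return [
        WellRecord(
            plate_id=row.plate_id,
            well_id=row.well_id,
            n_cells_detected=row.n_cells,
            is_negative_control=row.is_negative_control,
            cq=row.cq,
            endpoint_rfu=row.endpoint_rfu,
            mda_positive=row.mda_positive,
            pcr_positive=row.pcr_positive,
            sanger_ok=row.sanger_ok,
            taxon=TaxonPath.parse(row.taxon_path) if row.taxon_path else None,
        )
        for row in df.itertuples()
    ]


def write_wells(wells: list[WellRecord], path: str | Path) -> None:
    write_table(
        pd.DataFrame(
            {
                "plate_id": [w.plate_id for w in wells],
                "well_id": [w.well_id for w in wells],
                "n_cells": [w.n_cells_detected for w in wells],
                "is_negative_control": [w.is_negative_control for w in wells],
                "cq": [w.cq for w in wells],
                "endpoint_rfu": [w.endpoint_rfu for w in wells],
                "mda_positive": [w.mda_positive for w in wells],
                "pcr_positive": [w.pcr_positive for w in wells],
                "sanger_ok": [w.sanger_ok for w in wells],
                "taxon_path": [str(w.taxon) if w.taxon else "" for w in wells],
            }
        ),
        path,
    )


def read_pairwise(path: str | Path) -> dict[str, PairwiseMatrix]:
    """Load pairwise.tsv into one matrix per metric present."""
    df = read_table(path, SCHEMAS["pairwise"])
    matrices: dict[str, PairwiseMatrix] = {}
    for row in df.itertuples():
        matrices.setdefault(row.metric, PairwiseMatrix(row.metric)).set(
            row.id_a, row.id_b, row.value
        )
    return matrices


def write_pairwise(matrices: dict[str, PairwiseMatrix], path: str | Path) -> None:
    rows = [
        {"id_a": a, "id_b": b, "metric": metric, "value": v}
        for metric, m in matrices.items()
        for a, b, v in m.pairs()
    ]
    write_table(pd.DataFrame(rows, columns=["id_a", "id_b", "metric", "value"]), path)


def read_references(path: str | Path) -> list[ReferenceMeta]:
    df = read_table(path, SCHEMAS["references"])
    return [
        ReferenceMeta(
            genome_id=row.genome_id,
            n50_bp=row.n50_bp,
            completeness=row.completeness,
            corrected_contamination=row.contamination,
        )
        for row in df.itertuples()
    ]
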