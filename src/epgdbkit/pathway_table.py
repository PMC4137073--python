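"""Long-form pathway-prediction tables: I/O, QC filtering, normalization.

The exchange format is a flat TSV, one row per (sample, pathway), modelled on
the tables exported from pathway/genome databases by annotation pipelines:

    sample  pathway_id  pathway_name  n_reactions  n_covered  n_cds  cds_taxa

``n_reactions`` is the number of reactions in the pathway's reference
definition, ``n_covered`` the number with at least one mapped coding sequence,
``n_cds`` the number of mapped coding sequences (ORFs), and ``cds_taxa`` the
semicolon-separated top-hit taxon label of each CDS.  Lines starting with
``#`` are comments.  Per-sample total ORF counts live in a separate two-column
TSV (``sample  total_orfs``) and drive normalization to relative abundances.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Iterable

import pandas as pd

from .errors import ConfigurationError, DomainError, ParseError, SchemaError

REQUIRED_COLUMNS = ("sample", "pathway_id", "n_reactions", "n_covered", "n_cds")
ALL_COLUMNS = ("sample", "pathway_id", "pathway_name", "n_reactions", "n_covered", "n_cds", "cds_taxa")


@dataclass(frozen=True)
class PathwayRecord:
    sample: str
    pathway: str
    n_reactions: int
    n_covered: int
    n_cds: int
    pathway_name: str = ""
    cds_taxa: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_reactions < 1:
            raise SchemaError(f"{self.sample}/{self.pathway}: n_reactions must be positive")
        if self.n_covered > self.n_reactions:
            raise SchemaError(f"{self.sample}/{self.pathway}: n_covered exceeds n_reactions")
        if min(self.n_covered, self.n_cds) < 0:
            raise SchemaError(f"{self.sample}/{self.pathway}: negative count")
        if self.cds_taxa and len(self.cds_taxa) != self.n_cds:
            raise SchemaError(
                f"{self.sample}/{self.pathway}: {len(self.cds_taxa)} CDS taxa for n_cds={self.n_cds}"
            )


@dataclass
class PathwayTable:
    """Collection of pathway records plus per-sample total ORF counts."""

    records: list[PathwayRecord]
    total_orfs: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for r in self.records:
            key = (r.sample, r.pathway)
            if key in seen:
                raise SchemaError(f"duplicate (sample, pathway) pair {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def samples(self) -> list[str]:
        return sorted({r.sample for r in self.records})

    @property
    def pathways(self) -> set[str]:
        return {r.pathway for r in self.records}

    def with_totals(self, total_orfs: dict[str, int]) -> "PathwayTable":
        return PathwayTable(list(self.records), dict(total_orfs))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": [r.sample for r in self.records],
                "pathway_id": [r.pathway for r in self.records],
                "pathway_name": [r.pathway_name for r in self.records],
                "n_reactions": [r.n_reactions for r in self.records],
                "n_covered": [r.n_covered for r in self.records],
                "n_cds": [r.n_cds for r in self.records],
                "cds_taxa": [";".join(r.cds_taxa) for r in self.records],
            }
        )


def read_pathway_table(source: IO[str] | str) -> PathwayTable:
    """Parse the pathway-table TSV dialect.

    Raises a schema error for a missing required column or a duplicate
    (sample, pathway) row, and a parse error for non-numeric counts.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    df = pd.read_csv(source, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"pathway table is missing required column(s): {missing}")
    records = []
    for idx, row in df.iterrows():
        counts = {}
        for col in ("n_reactions", "n_covered", "n_cds"):
            try:
                counts[col] = int(row[col])
            except ValueError as exc:
                raise ParseError(f"row {idx + 2}: non-numeric {col}: {row[col]!r}") from exc
        taxa = tuple(t.strip() for t in str(row.get("cds_taxa", "")).split(";") if t.strip())
        records.append(
            PathwayRecord(
                sample=row["sample"],
                pathway=row["pathway_id"],
                pathway_name=str(row.get("pathway_name", "")),
                cds_taxa=taxa,
                **counts,
            )
        )
    return PathwayTable(records)


def write_pathway_table(table: PathwayTable, sink: IO[str]) -> None:
    table.to_frame().to_csv(sink, sep="\t", index=False)


def read_totals(source: IO[str] | str) -> dict[str, int]:
    """Parse the two-column ``sample  total_orfs`` TSV."""
    if isinstance(source, str):
        source = io.StringIO(source)
    df = pd.read_csv(source, sep="\t", comment="#", dtype={"sample": str})
    if "sample" not in df.columns or "total_orfs" not in df.columns:
        raise SchemaError("totals file needs columns 'sample' and 'total_orfs'")
    return {str(s): int(t) for s, t in zip(df["sample"], df["total_orfs"])}


def write_totals(totals: dict[str, int], sink: IO[str]) -> None:
    pd.DataFrame(
        {"sample": sorted(totals), "total_orfs": [totals[s] for s in sorted(totals)]}
    ).to_csv(sink, sep="\t", index=False)


def qc_filter(table: PathwayTable, min_cds: int = 10) -> PathwayTable:
    """Keep only records with at least ``min_cds`` mapped coding sequences.

    The default of 10 drops the low-evidence tail: pathways supported by nine
    or fewer CDS in a sample are removed, each sample judged independently.
    """
    if min_cds < 1:
        raise DomainError("min_cds must be a positive integer")
    return PathwayTable(
        [r for r in table.records if r.n_cds >= min_cds], dict(table.total_orfs)
    )


def normalize_counts(table: PathwayTable) -> pd.DataFrame:
    """Relative CDS abundance per pathway, as percent of each sample's total ORFs.

    Returns a tidy frame with columns ``sample``, ``pathway_id``,
    ``relative_abundance_pct`` where the value is ``100 * n_cds /
    total_orfs[sample]``.
    """
    for s in {r.sample for r in table.records}:
        if s not in table.total_orfs:
            raise ConfigurationError(f"no total_orfs entry for sample {s!r}")
        if table.total_orfs[s] <= 0:
            raise DomainError(f"total_orfs for sample {s!r} must be positive")
    return pd.DataFrame(
        {
            "sample": [r.sample for r in table.records],
            "pathway_id": [r.pathway for r in table.records],
            "relative_abundance_pct": [
                100.0 * r.n_cds / table.total_orfs[r.sample] for r in table.records
            ],
        }
    )


def presence_sets(table: PathwayTable) -> dict[str, set[str]]:
    """Per-sample sets of predicted pathway identifiers."""
    out: dict[str, set[str]] = {}
    for r in table.records:
        out.setdefault(r.sample, set()).add(r.pathway)
    return out


def merge_tables(tables: Iterable[PathwayTable]) -> PathwayTable:
    """Concatenate tables over disjoint (sample, pathway) keys."""
    records: list[PathwayRecord] = []
    totals: dict[str, int] = {}
    for t in tables:
        records.extend(t.records)
        totals.update(t.total_orfs)
    return PathwayTable(records, totals)
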