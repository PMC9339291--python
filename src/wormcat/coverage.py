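"""Annotation-coverage reports per category.

Tabulates, for every category at a chosen level, how many genes carry a GO
term, a predicted human ortholog, or a lineage-specificity call, from a
frozen per-gene attribute table.  The attribute table is a snapshot (e.g. a
Biomart/BLASTP export); the module never queries live services, so reports
are reproducible.  Also computes Venn-style region counts for arbitrary
boolean predicates within a category.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from itertools import product
from pathlib import Path
from typing import Callable, Mapping, Sequence

import pandas as pd

from .annotation import AnnotationList, CategoryPath, category_counts

__all__ = [
    "read_attribute_table",
    "CoverageTable",
    "coverage_breakdown",
    "overlap_counts",
]

FLAG_COLUMNS = ("has_go_term", "has_human_ortholog", "lineage_specific")


def read_attribute_table(source) -> pd.DataFrame:
    """Read a per-gene attribute CSV into a frame indexed by gene_id.

    Boolean flag columns accept 0/1, true/false, yes/no; numeric columns
    (bitscore, evalue) pass through.  Gene IDs must be unique.
    """
    df = pd.read_csv(source)
    if "gene_id" not in df.columns:
        raise ValueError("attribute table needs a gene_id column")
    df["gene_id"] = df["gene_id"].astype(str).str.strip()
    if df["gene_id"].duplicated().any():
        dupes = sorted(df.loc[df["gene_id"].duplicated(), "gene_id"].unique())
        raise ValueError(f"duplicate gene_id(s) in attribute table: {dupes}")
    df = df.set_index("gene_id")
    truthy = {"1", "1.0", "true", "yes", "t"}
    for col in df.columns:
        if col in FLAG_COLUMNS:
            if df[col].dtype == bool:
                continue
            if pd.api.types.is_numeric_dtype(df[col]):
                df[col] = df[col].fillna(0) != 0
            else:
                df[col] = df[col].astype(str).str.strip().str.lower().isin(truthy)
    return df


def _pct(n: int, total: int) -> float:
    """Percentage to one decimal, rounding half-up (3.25 -> 3.3)."""
    if total == 0:
        return 0.0
    return float(
        (Decimal(100 * n) / Decimal(total)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )


@dataclass
class CoverageTable:
    table: pd.DataFrame  # one row per category at the level
    uncovered: list[str]  # annotation genes absent from the attribute table

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False, float_format="%.1f")


def coverage_breakdown(
    annotation: AnnotationList,
    attrs: pd.DataFrame,
    level: int,
    coding_only: bool = True,
) -> CoverageTable:
    """Per-category coverage counts and percentages at one level.

    Genes in the annotation but missing from the attribute table are counted
    with every flag False and listed in ``uncovered`` — absence of evidence is
    reported, not dropped.  ``coding_only`` restricts the tally to
    protein-coding genes, the convention for GO/ortholog coverage figures.
    """
    genes = [r for r in annotation if (r.coding or not coding_only)]
    uncovered = sorted({r.gene_id for r in genes} - set(attrs.index))

    flags = {c: attrs[c] if c in attrs.columns else None for c in FLAG_COLUMNS}
    rows = []
    per_cat: dict[CategoryPath, dict[str, int]] = {}
    for rec in genes:
        prefix = rec.path.truncate(level)
        if prefix is None:
            continue
        tally = per_cat.setdefault(
            prefix, {"n_total": 0, "n_with_go": 0, "n_with_ortholog": 0, "n_lineage_specific": 0}
        )
        tally["n_total"] += 1
        if rec.gene_id in attrs.index:
            for col, key in (
                ("has_go_term", "n_with_go"),
                ("has_human_ortholog", "n_with_ortholog"),
                ("lineage_specific", "n_lineage_specific"),
            ):
                series = flags[col]
                if series is not None and bool(series.loc[rec.gene_id]):
                    tally[key] += 1
    for cat in sorted(per_cat):
        t = per_cat[cat]
        rows.append(
            {
                "category": cat.label,
                "n_total": t["n_total"],
                "n_with_go": t["n_with_go"],
                "n_with_ortholog": t["n_with_ortholog"],
                "n_lineage_specific": t["n_lineage_specific"],
                "pct_with_go": _pct(t["n_with_go"], t["n_total"]),
                "pct_with_ortholog": _pct(t["n_with_ortholog"], t["n_total"]),
                "pct_lineage_specific": _pct(t["n_lineage_specific"], t["n_total"]),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "category",
            "n_total",
            "n_with_go",
            "n_with_ortholog",
            "n_lineage_specific",
            "pct_with_go",
            "pct_with_ortholog",
            "pct_lineage_specific",
        ],
    )
    return CoverageTable(table=table, uncovered=uncovered)


Predicate = Callable[[pd.Series], bool]


def overlap_counts(
    annotation: AnnotationList,
    attrs: pd.DataFrame,
    category: CategoryPath,
    predicates: Mapping[str, str | Predicate],
    coding_only: bool = True,
) -> dict[tuple[bool, ...], int]:
    """Venn-style region counts for boolean predicates within one category.

    ``predicates`` maps a name to either an attribute column name or a
    callable taking the gene's attribute row.  The result maps each
    truth-assignment tuple (ordered as the predicates) to the number of
    category genes in that region; the regions partition the category, so the
    counts always sum to the category size.  Genes absent from the attribute
    table evaluate every predicate False.
    """
    level = category.depth
    members = [
        r
        for r in annotation
        if (r.coding or not coding_only) and r.path.truncate(level) == category
    ]
    names = list(predicates)
    counts: dict[tuple[bool, ...], int] = {
        combo: 0 for combo in product([True, False], repeat=len(names))
    }
    empty_row = pd.Series(dtype=object)
    for rec in members:
        row = attrs.loc[rec.gene_id] if rec.gene_id in attrs.index else empty_row
        key = []
        for name in names:
            pred = predicates[name]
            if callable(pred):
                key.append(bool(pred(row)) if not row.empty else False)
            else:
                key.append(bool(row.get(pred, False)) if not row.empty else False)
        counts[tuple(key)] += 1
    return counts
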