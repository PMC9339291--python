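"""Nested three-level gene-annotation lists.

The annotation model is a whole-genome table mapping each gene to exactly one
category path ``Cat1 -> Cat2 -> Cat3``.  Cat1 is always present; Cat2 and Cat3
may be absent (a gene is then counted only at the levels it carries).  The
full path tuple — not the leaf label — is the identity used for counting, so
the same leaf name under two different parents is two distinct categories.

The list doubles as the background universe for enrichment testing, which is
why genes with no functional information are retained under an explicit
UNASSIGNED category instead of being dropped.
"""

from __future__ import annotations

import csv
import io
import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "CategoryPath",
    "AnnotationRecord",
    "AnnotationList",
    "ValidationIssue",
    "ValidationReport",
    "ReassignmentReport",
    "AnnotationError",
    "DEFAULT_COLUMNS",
    "DEFAULT_NONCODING_CAT1",
    "read_annotation",
    "write_annotation",
    "validate_annotation",
    "derive_background",
    "category_counts",
    "diff_annotation_lists",
]


class AnnotationError(ValueError):
    """Fatal problem with an annotation list or its source file."""


@dataclass(frozen=True, order=True)
class CategoryPath:
    """A category path prefix: ``cat1`` alone, ``cat1:cat2`` or ``cat1:cat2:cat3``."""

    cat1: str
    cat2: str | None = None
    cat3: str | None = None

    def __post_init__(self) -> None:
        if not self.cat1 or not self.cat1.strip():
            raise AnnotationError("cat1 label must be a non-empty string")
        if self.cat3 is not None and self.cat2 is None:
            raise AnnotationError(f"cat3 {self.cat3!r} present without a cat2")

    @property
    def depth(self) -> int:
        return 1 if self.cat2 is None else (2 if self.cat3 is None else 3)

    def truncate(self, level: int) -> "CategoryPath | None":
        """Path prefix at ``level`` (1-3), or None if the gene has no label there."""
        if level == 1:
            return CategoryPath(self.cat1)
        if level == 2:
            return CategoryPath(self.cat1, self.cat2) if self.cat2 is not None else None
        if level == 3:
            return self if self.cat3 is not None else None
        raise ValueError(f"level must be 1, 2 or 3, got {level}")

    def as_tuple(self) -> tuple[str, ...]:
        return tuple(x for x in (self.cat1, self.cat2, self.cat3) if x is not None)

    @property
    def label(self) -> str:
        return ": ".join(self.as_tuple())

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return self.label


@dataclass(frozen=True)
class AnnotationRecord:
    gene_id: str
    path: CategoryPath
    sequence_name: str | None = None
    coding: bool = True


#: Header of the published annotation CSV shape; a column-mapping dialect can
#: rename any of these.  "Coding" is optional — when absent the flag is derived
#: from the non-coding Cat1 labels (see DEFAULT_NONCODING_CAT1).
DEFAULT_COLUMNS: Mapping[str, str] = {
    "gene_id": "Wormbase ID",
    "sequence_name": "Sequence ID",
    "cat1": "Category 1",
    "cat2": "Category 2",
    "cat3": "Category 3",
    "coding": "Coding",
}

#: Cat1 labels whose genes are treated as non-coding when no explicit coding
#: column is present (the ORF-only background drops these).
DEFAULT_NONCODING_CAT1: frozenset[str] = frozenset({"NON-CODING RNA", "PSEUDOGENE"})


@dataclass
class AnnotationList:
    """An ordered collection of :class:`AnnotationRecord` with unique gene IDs."""

    records: list[AnnotationRecord]
    version_tag: str = ""

    def __post_init__(self) -> None:
        dupes = [g for g, k in Counter(r.gene_id for r in self.records).items() if k > 1]
        if dupes:
            raise AnnotationError(f"duplicate gene_id(s): {sorted(dupes)}")
        self._by_gene = {r.gene_id: r for r in self.records}
        self._by_seq: dict[str, AnnotationRecord] = {}
        for r in self.records:
            if r.sequence_name:
                self._by_seq.setdefault(r.sequence_name.casefold(), r)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AnnotationRecord]:
        return iter(self.records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_gene

    def get(self, gene_id: str) -> AnnotationRecord | None:
        return self._by_gene.get(gene_id)

    def resolve(self, identifier: str) -> AnnotationRecord | None:
        """Resolve an input identifier: exact gene_id first, then sequence name
        (case-insensitive)."""
        rec = self._by_gene.get(identifier)
        if rec is None:
            rec = self._by_seq.get(identifier.casefold())
        return rec

    @property
    def gene_ids(self) -> set[str]:
        return set(self._by_gene)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [r.gene_id for r in self.records],
                "sequence_name": [r.sequence_name for r in self.records],
                "cat1": [r.path.cat1 for r in self.records],
                "cat2": [r.path.cat2 for r in self.records],
                "cat3": [r.path.cat3 for r in self.records],
                "coding": [r.coding for r in self.records],
            }
        )


@dataclass(frozen=True)
class ValidationIssue:
    kind: str  # duplicate_id | empty_label | nesting | normalized_child
    message: str
    gene_id: str | None = None


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def by_kind(self, kind: str) -> list[ValidationIssue]:
        return [i for i in self.issues if i.kind == kind]

    def to_json(self) -> str:
        return json.dumps(
            [
                {"kind": i.kind, "message": i.message, "gene_id": i.gene_id}
                for i in self.issues
            ],
            indent=2,
        )

    def to_text(self) -> str:
        if self.ok:
            return "annotation list: no violations\n"
        return "".join(f"[{i.kind}] {i.message}\n" for i in self.issues)


def _clean(cell: object) -> str | None:
    if cell is None:
        return None
    s = str(cell).strip()
    if not s or s.lower() in {"nan", "na", "none"}:
        return None
    return s


def read_annotation(
    source: str | Path | io.TextIOBase,
    dialect: Mapping[str, str] | None = None,
    version_tag: str = "",
    noncoding_cat1: frozenset[str] = DEFAULT_NONCODING_CAT1,
) -> AnnotationList:
    """Read an annotation CSV into an :class:`AnnotationList`.

    ``dialect`` maps the logical column names (``gene_id``, ``sequence_name``,
    ``cat1``..``cat3``, ``coding``) to the headers actually present in the
    file; it defaults to the published file shape (:data:`DEFAULT_COLUMNS`).

    A Cat2 (Cat3) cell repeating its parent's label is normalized to absent,
    as some published lists pad shallow paths that way.  Rows with an empty
    gene identifier or an empty Cat1 are rejected with their line numbers.
    """
    cols = dict(DEFAULT_COLUMNS)
    if dialect:
        cols.update(dialect)
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    missing = [cols[k] for k in ("gene_id", "cat1") if cols[k] not in df.columns]
    if missing:
        raise AnnotationError(f"missing required column(s): {missing}")

    has_seq = cols["sequence_name"] in df.columns
    has_coding = cols["coding"] in df.columns
    has_c2 = cols["cat2"] in df.columns
    has_c3 = cols["cat3"] in df.columns

    records: list[AnnotationRecord] = []
    bad_rows: list[str] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        row_d = dict(zip(df.columns, row))
        gid = _clean(row_d[cols["gene_id"]])
        c1 = _clean(row_d[cols["cat1"]])
        if gid is None or c1 is None:
            bad_rows.append(f"line {idx}: empty {'gene id' if gid is None else 'Category 1'}")
            continue
        c2 = _clean(row_d[cols["cat2"]]) if has_c2 else None
        c3 = _clean(row_d[cols["cat3"]]) if has_c3 else None
        if c2 is not None and c2 == c1:
            c2 = None
        if c3 is not None and (c2 is None or c3 == c2):
            # a Cat3 repeating its parent, or orphaned by a normalized Cat2,
            # is treated as absent
            c3 = None
        seq = _clean(row_d[cols["sequence_name"]]) if has_seq else None
        if has_coding:
            coding = str(row_d[cols["coding"]]).strip().lower() in {"1", "true", "yes", "t"}
        else:
            coding = c1 not in noncoding_cat1
        records.append(
            AnnotationRecord(gene_id=gid, sequence_name=seq, path=CategoryPath(c1, c2, c3), coding=coding)
        )
    if bad_rows:
        raise AnnotationError("malformed rows: " + "; ".join(bad_rows))
    dupes = [g for g, k in Counter(r.gene_id for r in records).items() if k > 1]
    if dupes:
        raise AnnotationError(f"duplicate gene_id(s): {sorted(dupes)}")
    return AnnotationList(records=records, version_tag=version_tag)


def write_annotation(ann: AnnotationList, dest: str | Path | io.TextIOBase) -> None:
    """Write an annotation list back to the default CSV shape (round-trip safe)."""
    close = False
    if isinstance(dest, (str, Path)):
        fh: io.TextIOBase = open(dest, "w", newline="")
        close = True
    else:
        fh = dest
    try:
        w = csv.writer(fh)
        w.writerow(["Wormbase ID", "Sequence ID", "Category 1", "Category 2", "Category 3", "Coding"])
        for r in ann.records:
            w.writerow(
                [
                    r.gene_id,
                    r.sequence_name or "",
                    r.path.cat1,
                    r.path.cat2 or "",
                    r.path.cat3 or "",
                    "1" if r.coding else "0",
                ]
            )
    finally:
        if close:
            fh.close()


def validate_annotation(ann: AnnotationList) -> ValidationReport:
    """Check the structural invariants; reports, never raises.

    Violations reported: duplicate gene IDs (only reachable when records were
    constructed outside :class:`AnnotationList`), empty labels, a Cat2 leaf
    label appearing under more than one Cat1 parent, and a Cat3 leaf under
    more than one (Cat1, Cat2) parent.
    """
    report = ValidationReport()
    seen: Counter[str] = Counter(r.gene_id for r in ann.records)
    for gid, k in sorted(seen.items()):
        if k > 1:
            report.issues.append(
                ValidationIssue("duplicate_id", f"gene_id {gid} appears {k} times", gid)
            )
    cat2_parents: dict[str, set[str]] = defaultdict(set)
    cat3_parents: dict[str, set[tuple[str, str]]] = defaultdict(set)
    for r in ann.records:
        p = r.path
        for lab in p.as_tuple():
            if not lab.strip():
                report.issues.append(
                    ValidationIssue("empty_label", f"gene {r.gene_id} has a blank label", r.gene_id)
                )
        if p.cat2 is not None:
            cat2_parents[p.cat2].add(p.cat1)
        if p.cat3 is not None:
            cat3_parents[p.cat3].add((p.cat1, p.cat2))  # type: ignore[arg-type]
    for leaf, parents in sorted(cat2_parents.items()):
        if len(parents) > 1:
            report.issues.append(
                ValidationIssue(
                    "nesting",
                    f"Cat2 label {leaf!r} appears under {len(parents)} Cat1 parents: {sorted(parents)}",
                )
            )
    for leaf, parents in sorted(cat3_parents.items()):
        if len(parents) > 1:
            report.issues.append(
                ValidationIssue(
                    "nesting",
                    f"Cat3 label {leaf!r} appears under {len(parents)} (Cat1, Cat2) parents: {sorted(parents)}",
                )
            )
    return report


def derive_background(
    ann: AnnotationList,
    mode: str = "whole",
    gene_ids: Iterable[str] | None = None,
) -> tuple[AnnotationList, list[str]]:
    """Derive a background universe from the whole-genome list.

    Modes: ``whole`` (identity — RNA-seq/ChIP-seq), ``orf_only`` (protein-coding
    records only — proteomics), ``subset`` (intersection with ``gene_ids`` —
    e.g. an RNAi-library universe).  Returns the derived list plus a list of
    warnings (subset IDs absent from the source list).

    Raises :class:`AnnotationError` if the resulting universe is empty.
    """
    warnings: list[str] = []
    if mode == "whole":
        out = ann.records
    elif mode == "orf_only":
        out = [r for r in ann.records if r.coding]
    elif mode == "subset":
        if gene_ids is None:
            raise AnnotationError("subset mode requires gene_ids")
        wanted = set(gene_ids)
        unknown = sorted(wanted - ann.gene_ids)
        warnings.extend(f"subset id not in annotation list: {g}" for g in unknown)
        out = [r for r in ann.records if r.gene_id in wanted]
    else:
        raise AnnotationError(f"unknown background mode {mode!r}")
    if not out:
        raise AnnotationError(f"background mode {mode!r} produced an empty universe")
    return AnnotationList(records=list(out), version_tag=ann.version_tag), warnings


def category_counts(ann: AnnotationList, level: int) -> dict[CategoryPath, int]:
    """Gene counts per category path prefix at ``level`` (1-3).

    Each gene is counted once, and only if it carries a label at that level;
    the counts therefore sum to the number of records labeled at the level.
    """
    counts: Counter[CategoryPath] = Counter()
    for r in ann.records:
        prefix = r.path.truncate(level)
        if prefix is not None:
            counts[prefix] += 1
    return dict(sorted(counts.items()))


@dataclass
class ReassignmentReport:
    """Gene-level diff between two annotation versions keyed on gene_id."""

    changes: pd.DataFrame  # gene_id, old_cat1..3, new_cat1..3
    matrix: pd.DataFrame  # old Cat1 x new Cat1 counts over changed genes
    n_changed: int
    added: list[str]  # gene IDs only in the new list
    removed: list[str]  # gene IDs only in the old list

    def to_csv(self, changes_path: str | Path, matrix_path: str | Path) -> None:
        self.changes.to_csv(changes_path, index=False)
        self.matrix.to_csv(matrix_path)


def diff_annotation_lists(old: AnnotationList, new: AnnotationList) -> ReassignmentReport:
    """Compare two annotation versions; a change is any difference in path."""
    shared = sorted(old.gene_ids & new.gene_ids)
    rows = []
    mat: Counter[tuple[str, str]] = Counter()
    for gid in shared:
        po = old.get(gid).path  # type: ignore[union-attr]
        pn = new.get(gid).path  # type: ignore[union-attr]
        if po != pn:
            rows.append(
                {
                    "gene_id": gid,
                    "old_cat1": po.cat1,
                    "old_cat2": po.cat2 or "",
                    "old_cat3": po.cat3 or "",
                    "new_cat1": pn.cat1,
                    "new_cat2": pn.cat2 or "",
                    "new_cat3": pn.cat3 or "",
                }
            )
            mat[(po.cat1, pn.cat1)] += 1
    changes = pd.DataFrame(
        rows,
        columns=["gene_id", "old_cat1", "old_cat2", "old_cat3", "new_cat1", "new_cat2", "new_cat3"],
    )
    old_labels = sorted({k[0] for k in mat})
    new_labels = sorted({k[1] for k in mat})
    matrix = pd.DataFrame(0, index=old_labels, columns=new_labels, dtype=int)
    for (o, n), k in mat.items():
        matrix.loc[o, n] = k
    matrix.index.name = "old_cat1"
    return ReassignmentReport(
        changes=changes,
        matrix=matrix,
        n_changed=len(rows),
        added=sorted(new.gene_ids - old.gene_ids),
        removed=sorted(old.gene_ids - new.gene_ids),
    )
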