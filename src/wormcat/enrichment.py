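"""Category-enrichment testing of regulated gene sets (RGS).

An input gene list is mapped onto the annotation universe, a 2x2 contingency
table is built per category (RGS membership x category membership over the
whole universe), and a one-sided Fisher's exact test gives the probability of
seeing at least the observed overlap under the hypergeometric null.  P-values
are adjusted for multiple testing separately within each category level
(Cat1, Cat2, Cat3), Benjamini-Hochberg by default.

Testing Cat2/Cat3 categories against the full universe (not the parent
category) keeps the three levels independently interpretable: a Cat3 row
answers "is this leaf over-represented in my gene set relative to the genome",
not "relative to its parent".
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .annotation import AnnotationList, AnnotationError, CategoryPath, category_counts

__all__ = [
    "RegulatedGeneSet",
    "ContingencyTable",
    "EnrichmentRow",
    "EnrichmentResult",
    "EnrichmentConfig",
    "BatchResult",
    "MappingError",
    "read_gene_list",
    "map_genes",
    "build_contingency",
    "fisher_enrichment_p",
    "bh_adjust",
    "run_enrichment",
    "batch_run",
]

LEVELS = (1, 2, 3)


class MappingError(ValueError):
    """No input gene could be resolved against the selected universe."""

    def __init__(self, message: str, unmapped: list[str]):
        super().__init__(message)
        self.unmapped = unmapped


@dataclass
class RegulatedGeneSet:
    """A user gene list resolved against a universe.

    ``mapped`` holds universe gene_ids; ``unmapped`` the input identifiers that
    resolved to nothing, verbatim.  ``|mapped| + |unmapped| + duplicates_removed
    == |raw_ids|``.
    """

    name: str
    raw_ids: list[str]
    mapped: set[str]
    unmapped: list[str]
    duplicates_removed: int


def read_gene_list(source: str | Path | io.TextIOBase, column: str = "Wormbase ID") -> list[str]:
    """Read a single-column gene-ID CSV, preserving order.

    Accepts a headerless single column too; blank lines are skipped and
    whitespace stripped.  Duplicates are kept (deduplication happens during
    mapping, where aliases can first be resolved).
    """
    df = pd.read_csv(source, dtype=str, keep_default_na=False, header=None)
    col0 = df.iloc[:, 0] if df.shape[1] else pd.Series(dtype=str)
    ids = [s for s in (str(v).strip() for v in col0) if s]
    if ids and ids[0] == column:
        ids = ids[1:]
    if not ids:
        raise AnnotationError("gene list is empty")
    return ids


def map_genes(ids: Sequence[str], universe: AnnotationList, name: str = "rgs") -> RegulatedGeneSet:
    """Resolve input identifiers against the universe.

    Resolution tries the primary gene_id first (exact, case-sensitive —
    WBGene-style IDs have fixed case), then the sequence name
    (case-insensitive).  Identifiers resolving to the same gene are collapsed
    and counted in ``duplicates_removed``; unresolved identifiers are kept
    verbatim.  Zero resolved genes is fatal.
    """
    mapped: set[str] = set()
    unmapped: list[str] = []
    duplicates = 0
    for ident in ids:
        rec = universe.resolve(ident)
        if rec is None:
            unmapped.append(ident)
        elif rec.gene_id in mapped:
            duplicates += 1
        else:
            mapped.add(rec.gene_id)
    if not mapped:
        raise MappingError(
            f"none of the {len(ids)} input identifiers mapped to the universe", unmapped
        )
    return RegulatedGeneSet(
        name=name,
        raw_ids=list(ids),
        mapped=mapped,
        unmapped=unmapped,
        duplicates_removed=duplicates,
    )


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: RGS membership x category membership over the universe.

    a: in RGS and in category; b: in RGS, not in category;
    c: in category, not in RGS; d: in neither.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"negative contingency cell: {self}")

    @property
    def universe_size(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def category_size(self) -> int:
        return self.a + self.c

    @property
    def rgs_size(self) -> int:
        return self.a + self.b


def build_contingency(
    rgs: RegulatedGeneSet,
    category: CategoryPath,
    level: int,
    universe: AnnotationList,
) -> ContingencyTable:
    """Count the four cells for one category at one level.

    A gene with no label at this level counts as "not in category" — it stays
    in the universe so the background size is the same for every category at
    the level.
    """
    in_cat = {
        r.gene_id for r in universe if r.path.truncate(level) == category
    }
    if not in_cat:
        raise AnnotationError(f"category {category.label!r} not present in universe at level {level}")
    n_universe = len(universe)
    a = len(rgs.mapped & in_cat)
    b = len(rgs.mapped) - a
    c = len(in_cat) - a
    d = n_universe - a - b - c
    return ContingencyTable(a, b, c, d)


def fisher_enrichment_p(t: ContingencyTable) -> float:
    """One-sided (enrichment, upper tail) Fisher's exact test p-value.

    P(X >= a) for X ~ Hypergeometric(N, K, n) with N the universe size,
    K the category size and n the RGS size.  Always in (0, 1].
    """
    return float(hypergeom.sf(t.a - 1, t.universe_size, t.category_size, t.rgs_size))


def bh_adjust(pvalues: Sequence[float], method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment, returned in the original input order.

    ``bh``: Benjamini-Hochberg step-up, ``q_(i) = min_{j>=i} p_(j) * m / j``
    clipped to 1.  ``bonferroni``: ``min(1, p * m)``.  Adjusted values are
    always >= the raw ones.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method != "bh":
        raise ValueError(f"unknown adjustment method {method!r}")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adj
    return out


@dataclass(frozen=True)
class EnrichmentRow:
    level: int
    category: CategoryPath
    rgs_count: int
    universe_count: int
    p: float
    p_adjusted: float
    significant: bool


@dataclass
class EnrichmentConfig:
    fdr_threshold: float = 0.05
    min_count: int = 1
    adjust_method: str = "bh"  # or "bonferroni"
    #: display bins for plot coloring (adjusted-p cutoffs, strictly decreasing)
    significance_bins: tuple[float, ...] = (0.05, 0.01, 0.001)


@dataclass
class EnrichmentResult:
    rgs: RegulatedGeneSet
    universe_tag: str
    rows: dict[int, list[EnrichmentRow]]  # level -> rows sorted by ascending p
    gene_annotations: pd.DataFrame  # mapped input genes with their paths
    config: EnrichmentConfig = field(default_factory=EnrichmentConfig)

    def level_frame(self, level: int) -> pd.DataFrame:
        rows = self.rows[level]
        return pd.DataFrame(
            {
                "category": [r.category.label for r in rows],
                "rgs_count": [r.rgs_count for r in rows],
                "universe_count": [r.universe_count for r in rows],
                "p": [r.p for r in rows],
                "p_adjusted": [r.p_adjusted for r in rows],
                "significant": [r.significant for r in rows],
            }
        )

    def significant_rows(self, level: int) -> list[EnrichmentRow]:
        return [r for r in self.rows[level] if r.significant]

    def write(self, outdir: str | Path) -> None:
        """Write the standard per-run CSV set (stable float formatting, so the
        same result always produces byte-identical files)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.gene_annotations.to_csv(outdir / "rgs_and_categories.csv", index=False)
        for level in LEVELS:
            self.level_frame(level).to_csv(
                outdir / f"cat{level}.csv", index=False, float_format="%.6g"
            )


def _sort_key(row: EnrichmentRow):
    # ascending p, ties broken by descending RGS count then label, so output
    # order is deterministic
    return (row.p, -row.rgs_count, row.category.as_tuple())


def run_enrichment(
    rgs: RegulatedGeneSet,
    universe: AnnotationList,
    config: EnrichmentConfig | None = None,
) -> EnrichmentResult:
    """Full three-level enrichment of one mapped gene set.

    Every category present in the universe is tested (a category with zero RGS
    genes scores p = 1); the BH family at each level is therefore all
    categories at that level, stable across gene sets run against the same
    universe.  The ``significant`` flag requires adjusted p below the FDR
    threshold AND at least ``min_count`` RGS genes in the category.
    """
    config = config or EnrichmentConfig()
    mapped = rgs.mapped
    rows: dict[int, list[EnrichmentRow]] = {}
    for level in LEVELS:
        counts = category_counts(universe, level)
        rgs_counts: dict[CategoryPath, int] = {c: 0 for c in counts}
        for gid in mapped:
            prefix = universe.get(gid).path.truncate(level)  # type: ignore[union-attr]
            if prefix is not None and prefix in rgs_counts:
                rgs_counts[prefix] += 1
        cats = list(counts)
        n_universe = len(universe)
        n_rgs = len(mapped)
        pvals = [
            fisher_enrichment_p(
                ContingencyTable(
                    a := rgs_counts[c],
                    n_rgs - a,
                    counts[c] - a,
                    n_universe - n_rgs - counts[c] + a,
                )
            )
            for c in cats
        ]
        adj = bh_adjust(pvals, method=config.adjust_method)
        level_rows = [
            EnrichmentRow(
                level=level,
                category=c,
                rgs_count=rgs_counts[c],
                universe_count=counts[c],
                p=p,
                p_adjusted=q,
                significant=bool(q < config.fdr_threshold and rgs_counts[c] >= config.min_count),
            )
            for c, p, q in zip(cats, pvals, adj)
        ]
        rows[level] = sorted(level_rows, key=_sort_key)

    ann_rows = []
    for gid in sorted(mapped):
        rec = universe.get(gid)
        ann_rows.append(
            {
                "gene_id": gid,
                "sequence_name": rec.sequence_name or "",  # type: ignore[union-attr]
                "cat1": rec.path.cat1,  # type: ignore[union-attr]
                "cat2": rec.path.cat2 or "",  # type: ignore[union-attr]
                "cat3": rec.path.cat3 or "",  # type: ignore[union-attr]
            }
        )
    gene_annotations = pd.DataFrame(
        ann_rows, columns=["gene_id", "sequence_name", "cat1", "cat2", "cat3"]
    )
    return EnrichmentResult(
        rgs=rgs,
        universe_tag=universe.version_tag,
        rows=rows,
        gene_annotations=gene_annotations,
        config=config,
    )


@dataclass
class BatchResult:
    results: list[EnrichmentResult]  # in input order; failed sets absent
    combined: pd.DataFrame  # long format keyed (dataset, level, category)
    log: list[str]  # per-set success/failure messages

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for res in self.results:
            res.write(outdir / res.rgs.name)
        self.combined.to_csv(outdir / "combined.csv", index=False, float_format="%.6g")
        (outdir / "batch_log.txt").write_text("".join(s + "\n" for s in self.log))


def batch_run(
    gene_sets: Iterable[tuple[str, Sequence[str]]],
    universe: AnnotationList,
    config: EnrichmentConfig | None = None,
) -> BatchResult:
    """Run several named gene lists against one universe in a single call.

    Each set is processed exactly as an individual :func:`run_enrichment`; a
    set that fails (e.g. nothing maps) is recorded in the log and skipped
    without aborting the rest.  The combined long-format table holds every
    dataset's rows at every level, datasets in input order.
    """
    gene_sets = list(gene_sets)
    if not gene_sets:
        raise ValueError("batch requires at least one gene set")
    results: list[EnrichmentResult] = []
    log: list[str] = []
    frames: list[pd.DataFrame] = []
    for name, ids in gene_sets:
        try:
            rgs = map_genes(ids, universe, name=name)
            res = run_enrichment(rgs, universe, config)
        except (MappingError, AnnotationError, ValueError) as exc:
            log.append(f"FAILED {name}: {exc}")
            continue
        results.append(res)
        log.append(
            f"OK {name}: mapped={len(rgs.mapped)} unmapped={len(rgs.unmapped)} "
            f"duplicates_removed={rgs.duplicates_removed}"
        )
        for level in LEVELS:
            frame = res.level_frame(level)
            frame.insert(0, "level", level)
            frame.insert(0, "dataset", name)
            frames.append(frame)
    combined = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=["dataset", "level", "category", "rgs_count", "universe_count", "p", "p_adjusted", "significant"]
        )
    )
    return BatchResult(results=results, combined=combined, log=log)
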