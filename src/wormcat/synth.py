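"""Synthetic annotation lists and gene sets with known ground truth.

Emulates the structure of a whole-genome three-level annotation — nested
categories of uneven size, a fraction of genes labeled only to Cat1 or Cat2
depth, a non-coding fraction — plus regulated gene sets with an optionally
planted enriched category, so the enrichment pipeline can be exercised and
power-tested end to end without any real data.

Everything is driven by a single integer seed through one
``numpy.random.Generator``; the same spec and seed always produce the same
files.  Synthetic gene IDs use the reserved ``SYNG`` prefix, which can never
collide with real WormBase ``WBGene`` identifiers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .annotation import AnnotationList, AnnotationRecord, CategoryPath, write_annotation

__all__ = ["PlantedSignal", "SyntheticSpec", "generate_annotation_list", "generate_rgs", "write_fixture"]


@dataclass(frozen=True)
class PlantedSignal:
    """A Cat1 category deliberately over-represented in the generated RGS.

    ``fold`` multiplies the category's universe proportion: at fold 1 the RGS
    is an unbiased uniform draw; at fold f the expected in-category fraction
    of the RGS is ``f * category_size / n_genes``.
    """

    cat1: str
    category_size: int  # exact number of universe genes in the planted Cat1
    rgs_size: int
    fold: float

    def __post_init__(self) -> None:
        if self.category_size <= 0 or self.rgs_size <= 0:
            raise ValueError("planted category and RGS sizes must be positive")
        if self.fold < 1:
            raise ValueError("fold enrichment must be >= 1")


@dataclass(frozen=True)
class SyntheticSpec:
    """Shape parameters for a synthetic universe.

    Defaults give a 2,000-gene universe with 20 Cat1 groups of uneven
    (Dirichlet-weighted) size — large enough for stable enrichment statistics,
    small enough that hundreds of replicates run in seconds.  The default
    planted signal (fold 5, RGS 50, category 100/2,000) is the standard
    recovery condition used throughout the test suite.
    """

    seed: int
    n_genes: int = 2000
    n_cat1: int = 20
    cat2_per_cat1: int = 3
    cat3_per_cat2: int = 2
    dirichlet_alpha: float = 5.0  # larger = more even Cat1 sizes
    noncoding_fraction: float = 0.1
    #: fraction of genes whose path stops at Cat1 / at Cat2 (rest get 3 levels)
    depth_fractions: tuple[float, float] = (0.1, 0.2)
    planted: PlantedSignal | None = None

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_cat1 <= 0:
            raise ValueError("n_genes and n_cat1 must be positive")
        if self.n_cat1 > self.n_genes:
            raise ValueError("more Cat1 categories than genes is infeasible")
        if self.planted and self.planted.category_size > self.n_genes:
            raise ValueError("planted category larger than the universe")
        if not 0 <= self.noncoding_fraction < 1:
            raise ValueError("noncoding_fraction must be in [0, 1)")


def _cat1_label(i: int) -> str:
    return f"SYNCAT {i + 1:02d}"


def generate_annotation_list(spec: SyntheticSpec) -> AnnotationList:
    """Generate a validated synthetic annotation list, deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    labels = [_cat1_label(i) for i in range(spec.n_cat1)]
    planted_idx: int | None = None
    if spec.planted is not None:
        if spec.planted.cat1 not in labels:
            raise ValueError(f"planted cat1 {spec.planted.cat1!r} is not a generated label")
        planted_idx = labels.index(spec.planted.cat1)

    weights = rng.dirichlet(np.full(spec.n_cat1, spec.dirichlet_alpha))
    if planted_idx is None:
        sizes = rng.multinomial(spec.n_genes - spec.n_cat1, weights) + 1
    else:
        others = [i for i in range(spec.n_cat1) if i != planted_idx]
        w = weights[others] / weights[others].sum()
        rest = spec.n_genes - spec.planted.category_size  # type: ignore[union-attr]
        if rest < len(others):
            raise ValueError("planted category leaves too few genes for the other categories")
        sizes = np.zeros(spec.n_cat1, dtype=int)
        sizes[others] = rng.multinomial(rest - len(others), w) + 1
        sizes[planted_idx] = spec.planted.category_size  # type: ignore[union-attr]

    records: list[AnnotationRecord] = []
    gid = 0
    p1, p2 = spec.depth_fractions
    for i, label in enumerate(labels):
        for _ in range(int(sizes[i])):
            gid += 1
            gene_id = f"SYNG{gid:08d}"
            seq = f"synT{gid}.1"
            u = rng.random()
            if u < p1:
                path = CategoryPath(label)
            else:
                c2 = f"{label.lower()} c2-{rng.integers(1, spec.cat2_per_cat1 + 1)}"
                if u < p1 + p2:
                    path = CategoryPath(label, c2)
                else:
                    c3 = f"{c2} c3-{rng.integers(1, spec.cat3_per_cat2 + 1)}"
                    path = CategoryPath(label, c2, c3)
            coding = bool(rng.random() >= spec.noncoding_fraction)
            records.append(
                AnnotationRecord(gene_id=gene_id, sequence_name=seq, path=path, coding=coding)
            )
    return AnnotationList(records=records, version_tag=f"synthetic-seed{spec.seed}")


def generate_rgs(
    spec: SyntheticSpec,
    universe: AnnotationList,
    rng: np.random.Generator | None = None,
) -> tuple[list[str], dict]:
    """Draw a gene set from the universe, optionally enriched for the planted
    category.

    At fold 1 the draw is plain uniform sampling without replacement.  At
    fold f, planted-category genes get sampling weight f against 1 for the
    rest (weighted sampling without replacement), so the category's expected
    representation is about f times its universe proportion.  Returns the
    gene IDs and a ground-truth record (planted path, sizes, fold, seed).

    Raises if the requested enrichment is infeasible (expected in-category
    draw exceeding the category size) or the RGS size is not positive.
    """
    if spec.planted is None:
        raise ValueError("spec has no planted signal; nothing to draw")
    planted = spec.planted
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    ids = np.array([r.gene_id for r in universe])
    n = len(ids)
    if planted.rgs_size > n:
        raise ValueError("RGS larger than the universe")
    in_cat = np.array([r.path.cat1 == planted.cat1 for r in universe])
    k = int(in_cat.sum())
    if k == 0:
        raise ValueError(f"planted category {planted.cat1!r} absent from universe")
    expected = planted.fold * k / n * planted.rgs_size
    if expected > k:
        raise ValueError(
            f"infeasible enrichment: expected {expected:.1f} planted genes but the "
            f"category only has {k}"
        )
    if planted.fold == 1:
        chosen = rng.choice(ids, size=planted.rgs_size, replace=False)
    else:
        w = np.where(in_cat, planted.fold, 1.0)
        chosen = rng.choice(ids, size=planted.rgs_size, replace=False, p=w / w.sum())
    chosen_list = [str(g) for g in chosen]
    planted_ids = {str(g) for g, m in zip(ids, in_cat) if m}
    truth = {
        "planted_cat1": planted.cat1,
        "category_size": k,
        "universe_size": n,
        "rgs_size": planted.rgs_size,
        "fold": planted.fold,
        "n_planted_drawn": len(planted_ids & set(chosen_list)),
        "seed": spec.seed,
    }
    return chosen_list, truth


def write_fixture(spec: SyntheticSpec, outdir: str | Path) -> dict[str, Path]:
    """Emit annotation CSV, RGS CSV and truth JSON for a spec; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    universe = generate_annotation_list(spec)
    paths = {"annotation": outdir / "annotation.csv"}
    write_annotation(universe, paths["annotation"])
    if spec.planted is not None:
        ids, truth = generate_rgs(spec, universe)
        paths["rgs"] = outdir / "rgs.csv"
        paths["rgs"].write_text("Wormbase ID\n" + "".join(g + "\n" for g in ids))
        paths["truth"] = outdir / "truth.json"
        paths["truth"].write_text(json.dumps(truth, indent=2) + "\n")
    return paths
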