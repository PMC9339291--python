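from __future__ import annotations

import pytest

from wormcat.annotation import AnnotationList, AnnotationRecord, CategoryPath
from wormcat.synth import PlantedSignal, SyntheticSpec, generate_annotation_list


def make_ann(rows, version_tag: str = "test") -> AnnotationList:
    """Build an AnnotationList from (gene_id, cat1[, cat2[, cat3[, coding]]]) tuples."""
    records = []
    for row in rows:
        gene_id, cat1 = row[0], row[1]
        cat2 = row[2] if len(row) > 2 else None
        cat3 = row[3] if len(row) > 3 else None
        coding = row[4] if len(row) > 4 else True
        records.append(
            AnnotationRecord(
                gene_id=gene_id,
                sequence_name=f"seq-{gene_id}",
                path=CategoryPath(cat1, cat2, cat3),
                coding=coding,
            )
        )
    return AnnotationList(records=records, version_tag=version_tag)


@pytest.fixture(scope="session")
def planted_spec() -> SyntheticSpec:
    """The standard recovery condition: fold 5, RGS 50, category 100/2,000."""
    return SyntheticSpec(
        seed=11,
        planted=PlantedSignal(cat1="SYNCAT 01", category_size=100, rgs_size=50, fold=5.0),
    )


@pytest.fixture(scope="session")
def synthetic_universe(planted_spec):
    return generate_annotation_list(planted_spec)
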