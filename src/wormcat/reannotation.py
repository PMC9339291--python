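"""Membrane/signal reclassification rules and ortholog-call thresholds.

Consensus transmembrane (TM) topology predictions — the number of algorithms
in a six-member suite that predict at least one TM segment — plus transporter-
domain and signal-peptide flags drive a deterministic reassignment of poorly
annotated genes:

1. unanimous TM consensus (6/6) with a transporter-associated domain
   -> TRANSMEMBRANE TRANSPORT;
2. unanimous TM consensus without one -> TRANSMEMBRANE DOMAIN;
3. sub-unanimous TM consensus (1-5) -> UNASSIGNED: Unassigned:
   membrane-spanning domain (lower-confidence call, kept visible but
   unassigned);
4. no TM consensus but a predicted signal peptide -> EXTRACELLULAR MATERIAL:
   Secreted protein;
5. otherwise no change.

Exactly one rule fires per gene; the transporter check precedes the generic
TM rule, and the signal-peptide rule applies only when no algorithm predicts
a TM segment.  Human-ortholog calls from BLASTP hits use strict thresholds:
bitscore > 40 and e-value < 0.01 (both configurable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .annotation import (
    AnnotationList,
    AnnotationRecord,
    CategoryPath,
    ReassignmentReport,
    diff_annotation_lists,
)

__all__ = [
    "TMPrediction",
    "ReassignmentDecision",
    "classify_membrane",
    "apply_reannotation",
    "call_orthologs",
    "read_predictions",
    "PATH_TM_TRANSPORT",
    "PATH_TM_DOMAIN",
    "PATH_LOW_CONF_TM",
    "PATH_SECRETED",
]

PATH_TM_TRANSPORT = CategoryPath("TRANSMEMBRANE TRANSPORT")
PATH_TM_DOMAIN = CategoryPath("TRANSMEMBRANE DOMAIN")
PATH_LOW_CONF_TM = CategoryPath("UNASSIGNED", "Unassigned", "membrane-spanning domain")
PATH_SECRETED = CategoryPath("EXTRACELLULAR MATERIAL", "Secreted protein")

N_TM_ALGORITHMS = 6


@dataclass(frozen=True)
class TMPrediction:
    gene_id: str
    tm_consensus: int  # 0..6 algorithms predicting >=1 TM segment
    has_transporter_domain: bool
    has_signal_peptide: bool
    current_path: CategoryPath | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.tm_consensus <= N_TM_ALGORITHMS:
            raise ValueError(
                f"tm_consensus must be 0..{N_TM_ALGORITHMS}, got {self.tm_consensus} "
                f"for {self.gene_id}"
            )


@dataclass(frozen=True)
class ReassignmentDecision:
    gene_id: str
    new_path: CategoryPath | None  # None only for NO_CHANGE with unknown current path
    rule_id: str  # TRANSPORT | TM_DOMAIN | LOW_CONF_TM | SECRETED | NO_CHANGE
    rationale: str


def classify_membrane(p: TMPrediction) -> ReassignmentDecision:
    """Apply the rule cascade to one prediction; first match wins."""
    if p.tm_consensus == N_TM_ALGORITHMS and p.has_transporter_domain:
        return ReassignmentDecision(
            p.gene_id,
            PATH_TM_TRANSPORT,
            "TRANSPORT",
            "TM segment in all 6 consensus algorithms and a transporter-associated domain",
        )
    if p.tm_consensus == N_TM_ALGORITHMS:
        return ReassignmentDecision(
            p.gene_id,
            PATH_TM_DOMAIN,
            "TM_DOMAIN",
            "TM segment in all 6 consensus algorithms, no transporter-associated domain",
        )
    if 1 <= p.tm_consensus <= N_TM_ALGORITHMS - 1:
        return ReassignmentDecision(
            p.gene_id,
            PATH_LOW_CONF_TM,
            "LOW_CONF_TM",
            f"TM segment in {p.tm_consensus}/6 algorithms: lower-confidence membrane call",
        )
    if p.has_signal_peptide:
        return ReassignmentDecision(
            p.gene_id,
            PATH_SECRETED,
            "SECRETED",
            "predicted signal sequence with no TM segment",
        )
    return ReassignmentDecision(
        p.gene_id, p.current_path, "NO_CHANGE", "no TM segment, no signal sequence"
    )


def apply_reannotation(
    predictions: Iterable[TMPrediction],
    annotation: AnnotationList,
) -> tuple[AnnotationList, ReassignmentReport, list[str]]:
    """Substitute rule-decided paths into an annotation list.

    Only genes present in the prediction table are touched; NO_CHANGE
    decisions leave the record as-is.  Prediction gene IDs absent from the
    annotation list are warned about, never fatal.  Returns the new list, the
    old-vs-new diff, and the warnings.
    """
    decisions: dict[str, ReassignmentDecision] = {}
    warnings: list[str] = []
    for p in predictions:
        if p.gene_id not in annotation:
            warnings.append(f"prediction for unknown gene: {p.gene_id}")
            continue
        decisions[p.gene_id] = classify_membrane(p)
    new_records: list[AnnotationRecord] = []
    for rec in annotation:
        dec = decisions.get(rec.gene_id)
        if dec is None or dec.rule_id == "NO_CHANGE" or dec.new_path is None:
            new_records.append(rec)
        else:
            new_records.append(
                AnnotationRecord(
                    gene_id=rec.gene_id,
                    sequence_name=rec.sequence_name,
                    path=dec.new_path,
                    coding=rec.coding,
                )
            )
    new_list = AnnotationList(records=new_records, version_tag=annotation.version_tag)
    report = diff_annotation_lists(annotation, new_list)
    return new_list, report, warnings


def read_predictions(source) -> list[TMPrediction]:
    """Read a prediction CSV: gene_id, tm_consensus, has_transporter_domain,
    has_signal_peptide."""
    df = pd.read_csv(source)
    truthy = {"1", "true", "yes", "t"}
    return [
        TMPrediction(
            gene_id=str(r["gene_id"]).strip(),
            tm_consensus=int(r["tm_consensus"]),
            has_transporter_domain=str(r["has_transporter_domain"]).strip().lower() in truthy,
            has_signal_peptide=str(r["has_signal_peptide"]).strip().lower() in truthy,
        )
        for _, r in df.iterrows()
    ]


def call_orthologs(
    hits: pd.DataFrame,
    min_bitscore: float = 40.0,
    max_evalue: float = 0.01,
) -> pd.DataFrame:
    """Flag BLASTP hits as ortholog calls.

    ``called`` is True iff bitscore strictly exceeds ``min_bitscore`` AND
    e-value is strictly below ``max_evalue``.  Input needs columns gene_id,
    bitscore, evalue; the output adds the boolean ``called`` column.
    """
    required = {"gene_id", "bitscore", "evalue"}
    missing = required - set(hits.columns)
    if missing:
        raise ValueError(f"ortholog-hit table missing column(s): {sorted(missing)}")
    if (hits["bitscore"] < 0).any() or (hits["evalue"] < 0).any():
        raise ValueError("bitscore and evalue must be non-negative")
    out = hits.copy()
    out["called"] = (out["bitscore"] > min_bitscore) & (out["evalue"] < max_evalue)
    return out
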