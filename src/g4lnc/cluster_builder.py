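"""Gene-level lncRNA clusters.

A gene can be transcribed into several splice variants; the pipeline treats
a gene together with all its transcript variants as one *lncRNA cluster*
and summarizes PQS content at that level (how many isoforms carry a PQS,
and the maximal G-score seen in the cluster).

Deduplication is by exact sequence identity within a gene.  When one
transcript_id arrives from two sources with *different* sequences, both
copies are dropped as low-confidence (conflicting sequence architecture)
and the conflict is logged.  Near-duplicate merging by alignment is
deliberately not attempted: exact identity keeps the behavior
deterministic and oracle-checkable.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .core_io import ExpressionLabel, TranscriptRecord, logger
from .pqs_scanner import PqsHit


@dataclass
class LncRnaCluster:
    """A gene plus all its transcript variants, with PQS summary fields."""

    gene_symbol: str
    members: list[TranscriptRecord]
    pqs_isoform_count: int = 0
    max_g_score: int | None = None
    expression: ExpressionLabel | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster needs at least one member")
        genes = {m.gene_symbol for m in self.members}
        if genes != {self.gene_symbol}:
            raise ValueError(
                f"cluster {self.gene_symbol}: mixed gene symbols {genes}"
            )


def collapse_identical(
    records: list[TranscriptRecord],
) -> list[TranscriptRecord]:
    """Merge exact-duplicate sequences within a gene; drop id conflicts.

    Identical (gene, sequence) pairs collapse into the first-seen record
    with unioned source_tags.  A transcript_id observed with two different
    sequences is removed entirely (every copy) and logged.
    """
    seqs_by_id: dict[str, set[str]] = defaultdict(set)
    for r in records:
        seqs_by_id[r.transcript_id].add(r.sequence)
    conflicted = {tid for tid, seqs in seqs_by_id.items() if len(seqs) > 1}
    for tid in sorted(conflicted):
        logger.warning("collapse_identical: conflicting sequences for %s; "
                       "dropping all copies", tid)

    kept: dict[tuple[str, str], TranscriptRecord] = {}
    for r in records:
        if r.transcript_id in conflicted:
            continue
        key = (r.gene_symbol, r.sequence)
        if key in kept:
            kept[key].source_tags |= r.source_tags
        else:
            kept[key] = TranscriptRecord(r.transcript_id, r.gene_symbol,
                                         r.sequence, set(r.source_tags))
    out = list(kept.values())
    logger.info("collapse_identical: %d records in -> %d out "
                "(%d conflicts dropped)", len(records), len(out),
                len(conflicted))
    return out


def build_clusters(records: list[TranscriptRecord]) -> list[LncRnaCluster]:
    """One cluster per gene symbol, sorted by gene; member order kept."""
    by_gene: dict[str, list[TranscriptRecord]] = defaultdict(list)
    for r in records:
        by_gene[r.gene_symbol].append(r)
    clusters = [LncRnaCluster(g, members)
                for g, members in sorted(by_gene.items())]
    logger.info("build_clusters: %d records in -> %d clusters out",
                len(records), len(clusters))
    return clusters


def summarize_cluster(
    cluster: LncRnaCluster,
    hits: list[PqsHit],
    labels: dict[str, ExpressionLabel] | None = None,
) -> LncRnaCluster:
    """Attach PQS counts, max G-score and expression label to a cluster."""
    member_ids = {m.transcript_id for m in cluster.members}
    mine = [h for h in hits if h.transcript_id in member_ids]
    with_hits = {h.transcript_id for h in mine}
    cluster.pqs_isoform_count = len(with_hits)
    cluster.max_g_score = max((h.g_score for h in mine), default=None)
    if labels is not None:
        if cluster.gene_symbol in labels:
            cluster.expression = labels[cluster.gene_symbol]
        else:
            logger.warning("summarize_cluster: no expression label for %s",
                           cluster.gene_symbol)
            cluster.expression = None
    return cluster
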