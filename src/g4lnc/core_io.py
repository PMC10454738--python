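"""Readers, writers and validation for the formats the pipeline touches.

Transcript sequences travel as FASTA; every evidence table (interaction
scores, RPIseq classifier outputs, compartment assignments, cytoplasmic/
nuclear expression, expression matrices, gel band intensities) is a
tab-separated file with a registered header schema.  Sequences are
normalized to the DNA alphabet {A,C,G,T}: the scanner is alphabet-agnostic
over G-runs, so RNA input (U) is mapped to T and RNA-ness is retained only
as metadata.

Coordinate convention: internal coordinates are 0-based half-open; all
reports are 1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("g4lnc")

VALID_BASES = frozenset("ACGT")

#: Closed vocabulary for differential-expression labels.
EXPRESSION_LABELS = frozenset({"upregulated", "downregulated", "differential"})


class AlphabetError(ValueError):
    """A sequence character outside {A,C,G,T,U, whitespace} was seen."""


class SchemaError(ValueError):
    """A TSV file does not match its registered schema."""


@dataclass
class TranscriptRecord:
    """One transcript: id, owning gene, normalized sequence, provenance."""

    transcript_id: str
    gene_symbol: str
    sequence: str
    source_tags: set[str] = field(default_factory=set)

    @property
    def length_nt(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.transcript_id}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise AlphabetError(
                f"{self.transcript_id}: non-normalized characters {sorted(bad)}"
            )


@dataclass(frozen=True)
class ExpressionLabel:
    gene_symbol: str
    label: str

    def __post_init__(self) -> None:
        if self.label not in EXPRESSION_LABELS:
            raise ValueError(
                f"label {self.label!r} not in {sorted(EXPRESSION_LABELS)}"
            )


@dataclass
class PipelineConfig:
    """Flat bag of pipeline settings; CLI flags override file values."""

    max_length: int = 45
    min_g_group: int = 3
    loop_min: int = 1
    loop_max: int = 14
    score_threshold: int = 60
    rpi_threshold: float = 0.5
    rpi_mode: str = "both"
    neutral_band: float = 0.5
    pseudocount: float = 0.01
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")


def normalize_alphabet(raw_sequence: str) -> str:
    """Uppercase, map U->T, strip whitespace; reject anything else.

    IUPAC ambiguity codes are rejected rather than guessed at: the scanner's
    G-run logic is meaningless on ambiguous positions.
    """
    out = []
    pos = 0
    for ch in raw_sequence:
        if ch.isspace():
            continue
        pos += 1
        up = ch.upper()
        if up == "U":
            up = "T"
        if up not in VALID_BASES:
            raise AlphabetError(
                f"invalid character {ch!r} at position {pos} (1-based, "
                "whitespace excluded)"
            )
        out.append(up)
    return "".join(out)


def _parse_header(header: str, gene_map: dict[str, str] | None) -> tuple[str, str]:
    """Header convention: ``transcript_id|gene_symbol``.

    FASTA has no gene field, but the pipeline groups transcripts by gene, so
    the gene symbol rides in the header; a mapping TSV (transcript_id ->
    gene_symbol) overrides, and a bare header falls back to
    gene_symbol = transcript_id.
    """
    first = header.split()[0]
    if "|" in first:
        tid, gene = first.split("|", 1)
    else:
        tid, gene = first, first
    if gene_map and tid in gene_map:
        gene = gene_map[tid]
    return tid, gene


def read_fasta(
    path: str | Path,
    gene_map: dict[str, str] | None = None,
    source_tag: str | None = None,
) -> list[TranscriptRecord]:
    """Read transcripts from FASTA, normalizing sequences.

    Empty file -> empty list.  Malformed entries raise a ValueError naming
    the offending record.
    """
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        try:
            seq = normalize_alphabet(str(entry.seq))
        except AlphabetError as exc:
            raise AlphabetError(f"{path}:{entry.id}: {exc}") from exc
        tid, gene = _parse_header(entry.description or entry.id, gene_map)
        tags = {source_tag} if source_tag else set()
        if not seq:
            raise ValueError(f"{path}:{entry.id}: empty sequence")
        records.append(TranscriptRecord(tid, gene, seq, tags))
    logger.info("read_fasta: %s -> %d records", path, len(records))
    return records


def write_fasta(records: list[TranscriptRecord], path: str | Path) -> None:
    """Write records with ``transcript_id|gene_symbol`` headers."""
    out = [
        SeqRecord(Seq(r.sequence), id=f"{r.transcript_id}|{r.gene_symbol}",
                  description="")
        for r in records
    ]
    SeqIO.write(out, str(path), "fasta")


def read_gene_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV transcript_id<TAB>gene_symbol escape hatch."""
    df = pd.read_csv(path, sep="\t", header=None, names=["transcript_id",
                                                         "gene_symbol"],
                     dtype=str)
    return dict(zip(df.transcript_id, df.gene_symbol))


def read_expression_labels(path: str | Path) -> dict[str, ExpressionLabel]:
    df = read_table(path, "expression_labels")
    return {
        row.gene_symbol: ExpressionLabel(row.gene_symbol, row.label)
        for row in df.itertuples()
    }


# --- TSV schemas -----------------------------------------------------------

#: registered schemas: name -> (required columns, numeric columns)
TABLE_SCHEMAS: dict[str, tuple[list[str], list[str]]] = {
    "interaction_scores": (
        ["lncrna", "protein", "protein_transcript", "score", "cancer_type"],
        ["score"],
    ),
    "rpi_scores": (["lncrna", "protein", "rf_score", "svm_score"],
                   ["rf_score", "svm_score"]),
    "compartments": (["symbol", "compartments"], []),
    "cn_expression": (["symbol", "cytoplasmic", "nuclear"],
                      ["cytoplasmic", "nuclear"]),
    "expression_matrix": ([], []),  # gene column + one column per sample
    "band_intensities": (
        ["lane", "condition", "full_length_intensity", "stop_intensity"],
        ["full_length_intensity", "stop_intensity"],
    ),
    "expression_labels": (["gene_symbol", "label"], []),
    "tht_replicates": (["group", "replicate", "intensity_488"],
                       ["intensity_488"]),
}


def read_table(path: str | Path, schema_name: str) -> pd.DataFrame:
    """Read a TSV against a registered schema.

    Missing columns raise SchemaError listing the expected header; numeric
    cells that fail to parse raise SchemaError with the (1-based, header
    excluded) row number.  Row order is preserved.
    """
    if schema_name not in TABLE_SCHEMAS:
        raise SchemaError(f"unknown schema {schema_name!r}")
    required, numeric = TABLE_SCHEMAS[schema_name]
    df = pd.read_csv(path, sep="\t", dtype=str)

    if schema_name == "expression_matrix":
        if df.shape[1] < 2:
            raise SchemaError(
                f"{path}: expression_matrix needs a gene column plus >=1 "
                "sample column"
            )
        required = [df.columns[0]]
        numeric = list(df.columns[1:])

    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing column(s) {missing}; expected header "
            f"{required + [c for c in numeric if c not in required]}"
        )
    for col in numeric:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise SchemaError(
                f"{path}: unparseable numeric cell in column {col!r}, "
                f"row {row}"
            )
        df[col] = parsed
    logger.info("read_table[%s]: %s -> %d rows", schema_name, path, len(df))
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Gene-by-sample numeric matrix, genes as the index."""
    df = read_table(path, "expression_matrix")
    return df.set_index(df.columns[0]).astype(float)
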