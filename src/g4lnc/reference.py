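"""Published reference inputs bundled with the package.

Six benchmark RNA oligonucleotides (printed in the DNA alphabet; the
scanner is alphabet-agnostic) with their published G-scores, plus the
published interaction-score and RPIseq evidence tables and compartment
assignments for the four experimentally characterized lncRNA clusters.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .core_io import TABLE_SCHEMAS, SchemaError

#: benchmark oligos: name -> (sequence 5'->3', published G-score)
REFERENCE_OLIGOS: dict[str, tuple[str, int]] = {
    "TERRA": ("GGGTTAGGGTTAGGGTTAGGG", 72),
    "SNHG20": ("GGGTTTGGGCTGGGGCCTGGG", 72),
    "MEG3": ("GGGAAATTCTCAGGAGGGGGACCTGGGCCAAGGG", 64),
    "LINP1": ("GGGGTAGGAGAGGGTATGGGGACCAGGGCACTCTGTAAGGG", 69),
    "CRNDE R1": ("GGGCTAGGGCCTGGGCCTCGGG", 71),
    "CRNDE R2": ("GGGTGTCGGGGTTCGGGGCGGG", 72),
}


def _load(name: str, schema: str) -> pd.DataFrame:
    ref = resources.files("g4lnc.data").joinpath(name)
    with resources.as_file(ref) as path:
        required, numeric = TABLE_SCHEMAS[schema]
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"{name}: missing columns {missing}")
        for col in numeric:
            df[col] = pd.to_numeric(df[col])
        return df


def interaction_scores() -> pd.DataFrame:
    """Published lncRNA-protein interaction scores (top-down channel)."""
    return _load("interaction_scores.tsv", "interaction_scores")


def rpi_scores() -> pd.DataFrame:
    """Published RF/SVM classifier score pairs (bottom-up channel)."""
    return _load("rpi_scores.tsv", "rpi_scores")


def compartments(which: str) -> dict[str, set[str]]:
    """Published compartment sets, ``which`` in {'lnc', 'protein'}."""
    df = _load(f"{which}_compartments.tsv", "compartments")
    return {row.symbol: set(row.compartments.split(";"))
            for row in df.itertuples()}
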