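"""Protein-partner nomination for G4-bearing lncRNAs.

Two independent evidence channels are integrated:

* **top-down** — database-style lncRNA–protein interaction scores, ranked
  descending (scores are treated as ordinal; their units are not
  interpreted);
* **bottom-up** — per-pair random-forest and SVM classifier probabilities
  from an RNA–protein interaction predictor; a pair passes when its scores
  exceed 0.5 (strictly), by default for *both* classifiers.

A third channel — subcellular colocalization — requires the lncRNA's and
the protein's compartment sets to intersect after sub-compartments are
mapped to their parents (nucleoplasm/nucleoli -> nucleus, cytosol/
perinuclear -> cytoplasm).  Expression covariation between a lncRNA and a
candidate partner is quantified by Pearson correlation (the linear
association the covariation heatmaps display).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import logger

#: controlled compartment vocabulary, child -> parent
COMPARTMENT_PARENT = {
    "nucleus": "nucleus",
    "nucleoplasm": "nucleus",
    "nucleoli": "nucleus",
    "cytoplasm": "cytoplasm",
    "cytosol": "cytoplasm",
    "perinuclear": "cytoplasm",
}


@dataclass(frozen=True)
class InteractionScore:
    lncrna: str
    protein: str
    protein_transcript: str
    score: float
    cancer_type: str = ""

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("interaction score must be >= 0")


@dataclass(frozen=True)
class RpiScorePair:
    lncrna: str
    protein: str
    rf_score: float
    svm_score: float

    def __post_init__(self) -> None:
        for s in (self.rf_score, self.svm_score):
            if not 0.0 <= s <= 1.0:
                raise ValueError("classifier scores must lie in [0, 1]")


@dataclass(frozen=True)
class CovariationResult:
    gene_a: str
    gene_b: str
    r: float
    n: int


@dataclass
class PartnerCall:
    lncrna: str
    protein: str
    topdown_score: float | None
    bottomup_pass: bool
    colocalized: bool | None

    @property
    def evidence_count(self) -> int:
        return (int(self.topdown_score is not None)
                + int(self.bottomup_pass)
                + int(bool(self.colocalized)))


def rank_topdown(scores: list[InteractionScore]) -> list[InteractionScore]:
    """Descending by score; (lncrna, protein) lexicographic on ties;
    duplicate (lncrna, protein, score) rows collapse to one."""
    unique = {(s.lncrna, s.protein, s.score): s for s in scores}
    return sorted(unique.values(),
                  key=lambda s: (-s.score, s.lncrna, s.protein))


def filter_bottomup(
    pairs: list[RpiScorePair], threshold: float = 0.5, mode: str = "both",
) -> list[RpiScorePair]:
    """Retain pairs with classifier scores strictly above the threshold.

    mode="both" (default) requires rf AND svm to pass; mode="either"
    accepts one.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if mode not in ("both", "either"):
        raise ValueError("mode must be 'both' or 'either'")
    comb = all if mode == "both" else any
    out = [p for p in pairs
           if comb(s > threshold for s in (p.rf_score, p.svm_score))]
    logger.info("filter_bottomup[%s>%g]: %d pairs in -> %d out", mode,
                threshold, len(pairs), len(out))
    return out


def covariation(
    matrix: pd.DataFrame, gene_a: str, gene_b: str,
) -> CovariationResult:
    """Pearson r between two genes' expression over shared samples.

    Genes are rows of ``matrix``.  Zero variance raises rather than
    silently returning 0 — an undefined correlation should be visible.
    """
    for g in (gene_a, gene_b):
        if g not in matrix.index:
            raise KeyError(f"gene {g!r} absent from expression matrix")
    a = matrix.loc[gene_a].to_numpy(dtype=float)
    b = matrix.loc[gene_b].to_numpy(dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if len(a) < 3:
        raise ValueError("need >= 3 shared finite samples")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError(
            f"zero variance for {gene_a if np.std(a) == 0 else gene_b!r}: "
            "correlation undefined"
        )
    r = float(stats.pearsonr(a, b).statistic)
    return CovariationResult(gene_a, gene_b, r, int(len(a)))


def parent_compartments(compartments: set[str]) -> set[str]:
    """Map sub-compartments onto {nucleus, cytoplasm}."""
    unknown = {c for c in compartments if c not in COMPARTMENT_PARENT}
    if unknown:
        raise ValueError(f"unknown compartment(s) {sorted(unknown)}")
    return {COMPARTMENT_PARENT[c] for c in compartments}


def colocalization_filter(
    pairs: list[tuple[str, str]],
    lnc_compartments: dict[str, set[str]],
    protein_compartments: dict[str, set[str]],
) -> dict[tuple[str, str], bool | None]:
    """Annotate (lncrna, protein) pairs with parent-level convergence.

    Pairs whose lncRNA or protein has no compartment entry get None (a
    warning is logged) and are excluded from downstream evidence counting.
    """
    out: dict[tuple[str, str], bool | None] = {}
    for lnc, prot in pairs:
        if lnc not in lnc_compartments or prot not in protein_compartments:
            logger.warning("colocalization_filter: unknown symbol in pair "
                           "(%s, %s)", lnc, prot)
            out[(lnc, prot)] = None
            continue
        lp = parent_compartments(lnc_compartments[lnc])
        pp = parent_compartments(protein_compartments[prot])
        out[(lnc, prot)] = bool(lp & pp)
    return out


def call_partners(
    topdown: list[InteractionScore],
    bottomup_filtered: list[RpiScorePair],
    colocalization: dict[tuple[str, str], bool | None],
) -> list[PartnerCall]:
    """Union of pairs across channels, with per-pair evidence flags.

    Sorted by (evidence_count desc, topdown_score desc, lncrna, protein);
    pairs without a top-down score sort after scored ones at equal
    evidence count.
    """
    td = {(s.lncrna, s.protein): s.score for s in rank_topdown(topdown)}
    bu = {(p.lncrna, p.protein) for p in bottomup_filtered}
    pairs = set(td) | bu | {p for p, v in colocalization.items()
                            if v is not None}
    calls = [
        PartnerCall(
            lncrna=lnc, protein=prot,
            topdown_score=td.get((lnc, prot)),
            bottomup_pass=(lnc, prot) in bu,
            colocalized=colocalization.get((lnc, prot)),
        )
        for lnc, prot in pairs
    ]
    calls.sort(key=lambda c: (
        -c.evidence_count,
        -(c.topdown_score if c.topdown_score is not None else -np.inf),
        c.lncrna, c.protein,
    ))
    logger.info("call_partners: %d pairs across channels", len(calls))
    return calls
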