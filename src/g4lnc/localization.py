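"""Subcellular localization of lncRNAs from compartment expression.

The cytoplasmic/nuclear relative concentration index (RCI) is the log2
ratio of cytoplasmic to nuclear expression,

    RCI = log2((cyt + p) / (nuc + p)),

with a small pseudocount ``p`` (default 0.01) so the index is defined at
zero expression.  Negative RCI means nuclear enrichment.  Compartments are
assigned with a neutral band (default 0.5 log2 units): transcripts inside
the band are treated as dual-resident in nucleus and cytoplasm, which
keeps near-balanced transcripts visible to the colocalization filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass
class CompartmentProfile:
    symbol: str
    rci: float | None
    compartments: set[str]
    source: str = "computed"  # or "asserted"


def compute_rci(
    cytoplasmic_expr: float, nuclear_expr: float, pseudocount: float = 0.01,
) -> float:
    """log2((cyt + pseudocount) / (nuc + pseudocount))."""
    if cytoplasmic_expr < 0 or nuclear_expr < 0:
        raise ValueError("expression values must be >= 0")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return math.log2((cytoplasmic_expr + pseudocount)
                     / (nuclear_expr + pseudocount))


def assign_compartment(
    symbol: str, rci: float, neutral_band: float = 0.5,
) -> CompartmentProfile:
    """Sign of RCI picks the compartment; |RCI| <= band -> dual-resident."""
    if neutral_band < 0:
        raise ValueError("neutral_band must be >= 0")
    if rci < -neutral_band:
        comps = {"nucleus"}
    elif rci > neutral_band:
        comps = {"cytoplasm"}
    else:
        comps = {"nucleus", "cytoplasm"}
    return CompartmentProfile(symbol, rci, comps)


def profile_from_expression(
    symbol: str,
    cytoplasmic_expr: float,
    nuclear_expr: float,
    pseudocount: float = 0.01,
    neutral_band: float = 0.5,
) -> CompartmentProfile:
    rci = compute_rci(cytoplasmic_expr, nuclear_expr, pseudocount)
    return assign_compartment(symbol, rci, neutral_band)
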