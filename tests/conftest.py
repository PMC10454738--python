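from __future__ import annotations

import numpy as np
import pytest

from g4lnc.pqs_scanner import ScanParams


@pytest.fixture(scope="session")
def paper_params() -> ScanParams:
    """The published scanning parameters: max 45 nt, G-groups >= 3,
    loops 1-14, score threshold 60."""
    return ScanParams(max_length=45, min_g_group=3, loop_min=1,
                      loop_max=14, score_threshold=60)


def random_sequence(rng: np.random.Generator, length: int,
                    g_weight: float = 0.4) -> str:
    """Random DNA with elevated G content so QGRS parses actually occur."""
    other = (1.0 - g_weight) / 3.0
    return "".join(rng.choice(list("ACGT"),
                              p=[other, other, g_weight, other],
                              size=length))
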