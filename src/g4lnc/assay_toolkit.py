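"""Desk-scale analytics for the biophysical G4 assays.

Operates on exported numeric tables, not instrument files: circular
dichroism (CD) wavelength/ellipticity traces, Thioflavin T (ThT)
fluorescence replicate tables and reverse-transcriptase (RT) stop gel
band intensities.

CD topology
-----------
A parallel G4 shows a positive CD band near 265 nm and a negative band
near 240 nm; an antiparallel G4 a positive band near 295 nm with a
negative band near 260 nm.  Classification uses +/-5 nm windows around
those positions and a noise floor of 3x the median absolute deviation of
the structure-free 330-350 nm tail, so uniform rescaling of a spectrum
cannot change the verdict.

Significance stars follow the convention * p <= 0.05, ** p <= 0.001,
*** p <= 0.0001 (unpaired t-test; Welch by default since replicate
variances are rarely equal or even reported).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

_PARALLEL_MAX = (260.0, 270.0)
_PARALLEL_MIN = (235.0, 245.0)
_ANTIPARALLEL_MAX = (290.0, 300.0)
_ANTIPARALLEL_MIN = (255.0, 265.0)
#: extrema are sought inside the structured region of the spectrum
_ANALYSIS_BAND = (230.0, 310.0)
_NOISE_TAIL = (330.0, 350.0)


@dataclass
class Spectrum:
    """A wavelength-indexed intensity trace with ionic-condition metadata."""

    wavelengths: np.ndarray  # nm, strictly increasing
    intensities: np.ndarray  # mdeg (CD) or a.u. (fluorescence)
    condition: str = "no_ion"  # no_ion | K | Li
    ion_mM: float = 0.0
    kind: str = "cd"  # cd | fluorescence_emission | fluorescence_excitation

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.shape != self.intensities.shape:
            raise ValueError("wavelength and intensity grids differ in size")
        if self.wavelengths.size < 2:
            raise ValueError("spectrum needs >= 2 points")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")


@dataclass
class FoldEnhancement:
    sample_mean: float
    blank_mean: float
    fold: float
    sample_replicates: tuple[float, ...]
    blank_replicates: tuple[float, ...]


@dataclass
class ComparisonResult:
    t_statistic: float
    p_value: float
    stars: str  # ns | * | ** | ***


@dataclass
class StopAssayResult:
    lane: str
    condition: str
    full_length_intensity: float
    stop_intensity: float
    stop_fraction: float


def _window(spec: Spectrum, lo: float, hi: float) -> np.ndarray:
    mask = (spec.wavelengths >= lo) & (spec.wavelengths <= hi)
    return spec.intensities[mask]


def _noise_floor(spec: Spectrum) -> float:
    tail = _window(spec, *_NOISE_TAIL)
    if tail.size >= 3:
        return 3.0 * float(np.median(np.abs(tail - np.median(tail))))
    return 0.0


def classify_cd_topology(spec: Spectrum) -> str:
    """Classify a CD spectrum as parallel / antiparallel / mixed / none."""
    lo, hi = spec.wavelengths[0], spec.wavelengths[-1]
    if lo > 230.0 or hi < 300.0:
        raise ValueError("CD spectrum must cover at least 230-300 nm")
    floor = _noise_floor(spec)

    band = (spec.wavelengths >= _ANALYSIS_BAND[0]) \
        & (spec.wavelengths <= _ANALYSIS_BAND[1])
    wl, iy = spec.wavelengths[band], spec.intensities[band]
    wl_max = wl[int(np.argmax(iy))]
    wl_min = wl[int(np.argmin(iy))]

    def sig(max_win: tuple[float, float], min_win: tuple[float, float]) -> bool:
        pk = _window(spec, *max_win)
        tr = _window(spec, *min_win)
        return (pk.size > 0 and tr.size > 0
                and float(pk.max()) > floor and float(tr.min()) < -floor)

    par = sig(_PARALLEL_MAX, _PARALLEL_MIN)
    anti = sig(_ANTIPARALLEL_MAX, _ANTIPARALLEL_MIN)

    if par and anti:
        return "mixed"
    if par and _PARALLEL_MAX[0] <= wl_max <= _PARALLEL_MAX[1] \
            and _PARALLEL_MIN[0] <= wl_min <= _PARALLEL_MIN[1]:
        return "parallel"
    if anti and _ANTIPARALLEL_MAX[0] <= wl_max <= _ANTIPARALLEL_MAX[1] \
            and _ANTIPARALLEL_MIN[0] <= wl_min <= _ANTIPARALLEL_MIN[1]:
        return "antiparallel"
    return "none"


def fold_enhancement(
    sample_replicates: list[float], blank_replicates: list[float],
) -> FoldEnhancement:
    """fold = mean(sample) / mean(blank); replicates kept for testing."""
    if not sample_replicates or not blank_replicates:
        raise ValueError("need >= 1 replicate per group")
    s = float(np.mean(sample_replicates))
    b = float(np.mean(blank_replicates))
    if b <= 0:
        raise ValueError("blank mean must be > 0")
    return FoldEnhancement(s, b, s / b, tuple(sample_replicates),
                           tuple(blank_replicates))


def stars_for_p(p: float) -> str:
    if p <= 0.0001:
        return "***"
    if p <= 0.001:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def compare_conditions(
    group_a: list[float], group_b: list[float], equal_var: bool = False,
) -> ComparisonResult:
    """Two-sided unpaired t-test (Welch unless equal_var=True)."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 replicates per group")
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            # degenerate but well-posed: no evidence of any difference
            return ComparisonResult(0.0, 1.0, "ns")
        return ComparisonResult(float("inf") if a.mean() > b.mean()
                                else float("-inf"), 0.0, "***")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return ComparisonResult(float(t), float(p), stars_for_p(float(p)))


def stop_fraction(
    lanes: list[tuple[str, str, float, float]],
) -> list[StopAssayResult]:
    """Per-lane stop / (stop + full-length) product fractions.

    ``lanes`` rows are (lane_id, condition, full_length_intensity,
    stop_intensity).  A lane whose two intensities are both zero has an
    undefined fraction and raises.
    """
    out = []
    for lane, condition, full, stop in lanes:
        if full < 0 or stop < 0:
            raise ValueError(f"lane {lane}: negative band intensity")
        total = full + stop
        if total == 0:
            raise ValueError(f"lane {lane}: both bands zero, fraction "
                             "undefined")
        out.append(StopAssayResult(lane, condition, full, stop,
                                   stop / total))
    return out
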