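"""Seeded generators for every input the pipeline consumes.

All generators are pure functions of (spec, seed).  One global seed fans
out to per-generator child seeds through ``numpy.random.SeedSequence``
spawning, so each fixture file is reproducible on its own.

Planted transcripts use G-free flanks (alphabet {A,C,T}) by default, which
makes the planted parse provably the unique QGRS-admissible region; a
hostile mode adds decoy G-runs for stress tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import TranscriptRecord
from .pqs_scanner import ScanParams, _score

_GFREE = np.array(list("ACT"))
_FULL = np.array(list("ACGT"))


def child_rng(seed: int, *spawn_key: int) -> np.random.Generator:
    """Deterministic per-generator stream: SeedSequence(seed).spawn-style."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=spawn_key)
    )


@dataclass(frozen=True)
class PlantedPqsSpec:
    """Recipe for one transcript with a known best parse planted in it."""

    tetrad_size: int = 3
    loops: tuple[int, int, int] = (1, 1, 1)
    flank_length: int = 50
    hostile: bool = False  # add decoy G-runs in the flanks

    def validate(self, params: ScanParams) -> None:
        if self.tetrad_size < params.min_g_group:
            raise ValueError("tetrad_size below min_g_group")
        for l in self.loops:
            if not params.loop_min <= l <= params.loop_max:
                raise ValueError(f"loop length {l} outside "
                                 f"[{params.loop_min}, {params.loop_max}]")
        if self.span() > params.max_length:
            raise ValueError("planted span exceeds max_length")
        if self.flank_length < 0:
            raise ValueError("flank_length must be >= 0")

    def span(self) -> int:
        return 4 * self.tetrad_size + sum(self.loops)

    def motif(self, rng: np.random.Generator) -> str:
        g = "G" * self.tetrad_size
        parts = [g]
        for l in self.loops:
            parts.append("".join(rng.choice(_GFREE, size=l)))
            parts.append(g)
        return "".join(parts)


def gen_transcript(
    spec: PlantedPqsSpec,
    seed: int,
    params: ScanParams = ScanParams(),
    transcript_id: str = "SYN1",
    gene_symbol: str = "SYNGENE",
) -> tuple[TranscriptRecord, dict]:
    """Build a transcript with the planted parse and its ground truth.

    Returns (record, truth) where truth records the planted 0-based group
    starts, loops, tetrad size and expected G-score.
    """
    spec.validate(params)
    rng = child_rng(seed, 0)
    motif = spec.motif(rng)
    left = "".join(rng.choice(_GFREE, size=spec.flank_length))
    right = "".join(rng.choice(_GFREE, size=spec.flank_length))
    if spec.hostile:
        # two decoy runs too far from each other (and the plant) to combine
        # into a competitive parse at the planted score
        decoy = "G" * spec.tetrad_size
        if spec.flank_length >= 2 * spec.tetrad_size + 2:
            left = decoy + left[len(decoy):]
            right = right[:-len(decoy)] + decoy
    sequence = left + motif + right
    offset = len(left)
    t = spec.tetrad_size
    starts = [offset]
    for l in spec.loops:
        starts.append(starts[-1] + t + l)
    truth = {
        "group_starts": tuple(starts),
        "tetrad_size": t,
        "loops": spec.loops,
        "start_0based": offset,
        "end_0based": offset + spec.span(),
        "g_score": _score(t, spec.loops),
    }
    rec = TranscriptRecord(transcript_id, gene_symbol, sequence)
    return rec, truth


def gen_transcript_set(
    n_genes: int,
    seed: int,
    params: ScanParams = ScanParams(),
    isoforms_per_gene: int = 1,
) -> tuple[list[TranscriptRecord], dict]:
    """A small cohort of planted transcripts across ``n_genes`` genes."""
    rng = child_rng(seed, 1)
    records, truths = [], {}
    for g in range(n_genes):
        gene = f"LNC{g:03d}"
        for i in range(isoforms_per_gene):
            loops = tuple(int(x) for x in rng.integers(
                params.loop_min, min(params.loop_max, 7) + 1, size=3))
            spec = PlantedPqsSpec(tetrad_size=3, loops=loops,
                                  flank_length=int(rng.integers(20, 60)))
            sub = int(rng.integers(0, 2**31 - 1))
            rec, truth = gen_transcript(spec, sub, params,
                                        transcript_id=f"{gene}.{i + 1}",
                                        gene_symbol=gene)
            records.append(rec)
            truths[rec.transcript_id] = truth
    return records, truths


def gen_evidence_tables(
    n_lnc: int, n_prot: int, seed: int,
) -> dict[str, pd.DataFrame | dict]:
    """Schema-valid interaction / RPI / compartment / CN-expression tables.

    A recorded subset of pairs (``truth['all_channel_pairs']``) is
    constructed to pass all three evidence channels: high interaction
    score, both classifier scores > 0.5, and convergent compartments.
    One pair per lncRNA is additionally planted with rf = 0.3 so it must
    fail the bottom-up filter.
    """
    if n_lnc < 1 or n_prot < 1:
        raise ValueError("sizes must be >= 1")
    rng = child_rng(seed, 2)
    lncs = [f"LNC{i:03d}" for i in range(n_lnc)]
    prots = [f"PROT{j:03d}" for j in range(n_prot)]

    inter_rows, rpi_rows, truth_pairs, fail_pairs = [], [], [], []
    lnc_comp, prot_comp, cn_rows = {}, {}, []

    for j, p in enumerate(prots):
        prot_comp[p] = {"nucleoplasm"} if j % 2 == 0 else {"cytosol"}

    for i, lnc in enumerate(lncs):
        nuclear = i % 2 == 0
        lnc_comp[lnc] = {"nucleus"} if nuclear else {"cytoplasm"}
        cyt, nuc = (1.0, 8.0) if nuclear else (8.0, 1.0)
        cn_rows.append({"symbol": lnc, "cytoplasmic": cyt, "nuclear": nuc})

        # the planted all-channel partner shares the parent compartment
        matching = [p for p in prots
                    if ("nucleoplasm" in prot_comp[p]) == nuclear]
        planted = matching[i % len(matching)] if matching else prots[0]
        truth_pairs.append((lnc, planted))

        for p in prots:
            score = float(rng.uniform(100, 340))
            inter_rows.append({"lncrna": lnc, "protein": p,
                               "protein_transcript": f"{p}-001",
                               "score": round(score, 2),
                               "cancer_type": "CSCC"})
            if p == planted:
                rf, svm = rng.uniform(0.7, 0.99), rng.uniform(0.7, 0.99)
            else:
                rf, svm = rng.uniform(0.51, 0.99), rng.uniform(0.51, 0.99)
            rpi_rows.append({"lncrna": lnc, "protein": p,
                             "rf_score": round(float(rf), 3),
                             "svm_score": round(float(svm), 3)})
        # one guaranteed bottom-up failure per lncRNA
        loser = prots[(i + 1) % n_prot]
        for row in rpi_rows:
            if row["lncrna"] == lnc and row["protein"] == loser \
                    and (lnc, loser) not in truth_pairs:
                row["rf_score"] = 0.3
                fail_pairs.append((lnc, loser))
                break

    tables = {
        "interaction_scores": pd.DataFrame(inter_rows),
        "rpi_scores": pd.DataFrame(rpi_rows),
        "lnc_compartments": pd.DataFrame(
            [{"symbol": k, "compartments": ";".join(sorted(v))}
             for k, v in lnc_comp.items()]),
        "protein_compartments": pd.DataFrame(
            [{"symbol": k, "compartments": ";".join(sorted(v))}
             for k, v in prot_comp.items()]),
        "cn_expression": pd.DataFrame(cn_rows),
        "truth": {"all_channel_pairs": truth_pairs,
                  "bottomup_fail_pairs": fail_pairs},
    }
    return tables


def gen_expression_matrix(
    gene_pairs: list[tuple[str, str, float]], n_samples: int, seed: int,
) -> pd.DataFrame:
    """Gene-by-sample matrix with prescribed pairwise correlations.

    Each (gene_a, gene_b, rho) triple yields a bivariate normal pair of
    rows with population correlation rho.
    """
    rng = child_rng(seed, 3)
    rows, index = [], []
    for a, b, rho in gene_pairs:
        cov = np.array([[1.0, rho], [rho, 1.0]])
        xy = rng.multivariate_normal([0.0, 0.0], cov, size=n_samples)
        rows.extend([xy[:, 0], xy[:, 1]])
        index.extend([a, b])
    return pd.DataFrame(rows, index=index,
                        columns=[f"S{k + 1}" for k in range(n_samples)])


def gen_spectrum(
    topology: str, noise_sd: float, seed: int, amplitude: float = 10.0,
) -> "Spectrum":
    """Synthetic CD trace: Gaussian bands at the canonical G4 positions.

    parallel: +265 nm / -240 nm; antiparallel: +295 nm / -260 nm; none:
    flat.  noise_sd is in the same mdeg units as ``amplitude``; the
    classifier recovers the topology reliably for noise_sd <= 10% of
    amplitude.
    """
    from .assay_toolkit import Spectrum

    if topology not in ("parallel", "antiparallel", "none"):
        raise ValueError(f"unknown topology {topology!r}")
    rng = child_rng(seed, 4)
    wl = np.arange(220.0, 351.0, 1.0)
    iy = np.zeros_like(wl)

    def band(center: float, sign: float, width: float = 8.0) -> None:
        nonlocal iy
        iy = iy + sign * amplitude * np.exp(-0.5 * ((wl - center) / width) ** 2)

    if topology == "parallel":
        band(265.0, +1.0)
        band(240.0, -0.8)
    elif topology == "antiparallel":
        band(295.0, +1.0)
        band(260.0, -0.8)
    if noise_sd > 0:
        iy = iy + rng.normal(0.0, noise_sd, size=wl.size)
    return Spectrum(wl, iy, kind="cd")
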