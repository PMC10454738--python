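# Methods

## The PQS model

A putative quadruplex sequence (PQS) is modelled as a *parse*: four
G-groups of exactly `t` consecutive guanines (`t >= min_g_group`, default
3) separated by three loops of `l1, l2, l3` nucleotides each in
`[loop_min, loop_max]` (default 1–14), with total span at most
`max_length` (default 45 nt). Groups may start at any position carrying
`t` consecutive Gs; loops may themselves contain guanines, and a long
G-run may host more than one group. Zero-length loops are excluded
(`loop_min = 1`). All four groups share one tetrad size; mixed group
sizes are not candidates. Intramolecular parses only: no multimeric G4
modelling, no thermodynamic competition with other secondary structure,
and no antisense-strand scanning (transcripts are single-stranded RNA;
sequences are held in the DNA alphabet with U mapped to T, since the
G-run logic is alphabet-agnostic).

## G-score

Each parse receives the integer score

    g_score = 24 * t - (max(l1,l2,l3) - min(l1,l2,l3)),

24 points per stacked G-quartet minus the loop-length imbalance. The
formula honours the usual quadruplex-stability heuristics — more tetrads
dominate everything else (one extra quartet outweighs the worst possible
loop imbalance of 13), and unequal loops are penalized — and was
calibrated so the benchmark oligo set used to validate the scanner is
reproduced exactly: the telomeric TERRA repeat (loops 3,3,3) scores 72,
the SNHG20 PQS 72, MEG3 64, LINP1 69 and CRNDE-R1 71, and a six-tetrad
equal-loop parse scores 144, the published cluster maximum for H19. The
calibration is forced once those anchors are accepted: all parses of the
MEG3 oligo share the same total loop length, which rules out any
mean-loop term, and the five anchor scores then pin the penalty to
`max - min` and the per-tetrad weight to 24. One published anchor cannot
be reproduced by *any* scoring that prefers shorter and more equal loops:
the CRNDE-R2 oligo (reported 72) admits only parses whose loop multisets
are strictly worse than TERRA's {3,3,3}, and the reported cluster-level
maximum for CRNDE (71) contradicts the per-oligo figure anyway; the
scanner computes 70 for it. The formula lives in one function
(`pqs_scanner._score`) so recalibration stays local.

## Non-overlap selection

The reported hit set maximizes *total* G-score over pairwise-disjoint
threshold-passing parses (weighted interval scheduling), not a greedy
highest-first sweep: exact selection is what the brute-force oracle in
the test suite computes, and greedy selection provably differs on
adversarial candidate layouts (a high scorer bridging two slightly lower
scorers). Among equally scoring selections the canonically earliest set
is chosen — candidates ordered by (start, span, larger tetrad, group
layout), take preferred on ties — making the output deterministic.
Thresholding (score strictly greater than 60) happens before selection.

Long transcripts are scanned in sliding windows of `2*max_length` with
step `max_length`; every admissible parse (span <= max_length) lies
wholly inside at least one window, duplicates across seams are merged by
coordinates, and selection runs once on the merged candidate set, so a
windowed scan equals a global scan exactly.

## Canonical-motif cross-check

Reported motifs carry a boolean from a second, stricter validation layer:
presence of the canonical pattern `G{t} N(1-7) G{t} N(1-7) G{t} N(1-7)
G{t}`, t >= 3 — a tighter loop bound than the scanner's 1–14. It is an
annotation, not a filter; scanner-admissible motifs with any loop longer
than 7 nt (e.g. the MEG3 benchmark oligo, forced first loop 12 nt) fail
it by construction. The pass criterion of the external database the
check stands in for is not published, so this surrogate is deliberately
simple and documented.

## Clustering

Transcript variants are deduplicated by exact sequence identity within a
gene (union of provenance tags); a transcript id seen with two different
sequences is dropped entirely as low-confidence. Alignment-based
near-duplicate merging is deliberately excluded — exact identity keeps
the operation idempotent, deterministic and countable by an oracle.
Clusters are one per gene symbol; the physiological-isoform designation
is an input label, not an inference, since it derives from literature.

## Partner evidence

* Top-down interaction scores are ordinal: ranked descending with
  lexicographic tie-breaks, duplicates collapsed. No unit interpretation.
* Bottom-up RF/SVM probabilities pass at strictly `> 0.5`, and by default
  *both* classifiers must pass (`mode="either"` is available); the
  classifiers themselves are consumed, never trained.
* Covariation is Pearson's r (the linear-correlation quantity the
  heatmap displays), requiring >= 3 shared finite samples; zero variance
  raises instead of returning 0.
* Colocalization is evaluated at parent-compartment level
  (nucleoplasm/nucleoli -> nucleus; cytosol/perinuclear -> cytoplasm)
  because published compartment annotations mix granularities. Unknown
  symbols yield `None` and do not count as evidence.
* A PartnerCall's `evidence_count` (0–3) counts present channels; calls
  sort by evidence count, then top-down score.

## Localization

RCI = log2((cyt + p)/(nuc + p)) with pseudocount p = 0.01 (units: log2
ratio of compartment expression). The pseudocount defines the index at
zero expression; antisymmetry under swapping the compartments is exact.
Compartment assignment uses a neutral band of 0.5 log2 units: |RCI| <=
band is dual-resident. The band is this package's choice — the source
tool reports compartments qualitatively, and dual residency (e.g.
cytoplasmic plus perinuclear lncRNAs) argues against a binary cut. Both
band and pseudocount are configurable. No cell-line-specific multi-track
aggregation is attempted.

## Assay analytics

* **CD topology**: parallel requires the global maximum (within the
  structured 230–310 nm region) in 265±5 nm and the global minimum in
  240±5 nm; antiparallel uses 295±5 / 260±5. Both signatures present ->
  mixed; neither -> none. Amplitudes must exceed a noise floor of 3x the
  median absolute deviation of the structure-free 330–350 nm tail, which
  makes the verdict invariant under uniform rescaling. Window widths and
  the MAD floor are this package's choices; the source classifies
  topology by expert inspection.
* **ThT fold enhancement**: mean(sample)/mean(blank), replicates
  retained. Significance by unpaired t-test, Welch by default (replicate
  variances unreported; pooled mode available), stars at p <= 0.05 (*),
  <= 0.001 (**), <= 0.0001 (***). Two constant equal groups give t = 0,
  p = 1 rather than NaN.
* **RT-stop**: per-lane stop/(stop + full-length) band-intensity
  fraction; densitometry itself is out of scope — any imaging software's
  band table is accepted.

## Synthetic data

Generators are pure functions of (spec, seed); one global seed fans out
per generator through `numpy.random.SeedSequence(entropy=seed,
spawn_key=...)`. Planted transcripts use G-free flanks and G-free loops,
which makes the planted parse provably the unique admissible one (a
hostile mode adds decoy G-runs). Evidence tables plant, per lncRNA, one
pair passing all three channels and one pair failing the bottom-up
filter (rf = 0.3). Synthetic CD spectra are Gaussian bands (sd 8 nm) at
the canonical positions with seeded white noise. The generators emulate
the *shape* of real inputs — paper-shape preset: 4 lncRNAs x 8 proteins,
the dimensions of the published evidence tables — but not real lncRNA
base composition, splice structure, heteroscedastic instrument noise or
database incompleteness; passing tests therefore demonstrate
correctness of the computations, not recall on real transcriptomes.

## Problem sizes and numerics

The oracle-equivalence property runs 500 random sequences of <= 60 nt
(G-weighted so parses actually occur) against an independent brute-force
enumeration plus exact optimal selection, and 100 planted fixtures; the
covariation check uses n = 500 samples at rho = -0.6 with a +/-0.1
acceptance band (the Fisher-z 95% half-width at this n is ~0.06); the CD
Monte Carlo uses 200 seeds at 5% band-amplitude noise with a 95% recovery
bar. Internal coordinates are 0-based half-open; every report is 1-based
inclusive. Score ties anywhere are broken deterministically as described
above, so repeated runs are byte-identical.

## Known limitations

* The G-score is a calibrated integer heuristic, not a thermodynamic
  model; it ignores loop composition and flanking context.
* Exact-identity deduplication will keep trivially different isoforms
  (single-nucleotide variants) separate.
* The colocalization vocabulary is closed; compartments outside it
  (mitochondrion, ER) are rejected rather than mapped.
* Scanning is transcript-space only; no genome coordinates, no liftover.
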