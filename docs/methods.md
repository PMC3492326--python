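# Methods

## The competition-assay model

Two copies of a proteome microarray are probed with a fluorescent
lectin; one probe mix additionally contains an excess of free glycan
competitor. Binding to a protein spot decomposes into a glycan-dependent
component, abolished by competitor, and a nonspecific component, which
is not. The pipeline quantifies each scan at spot level, aggregates to
proteins, and compares conditions:

1. **Spot SNR** — foreground median over local background median of the
   configured wavelength (default 635 nm). The ratio is scale-free, so
   global intensity changes (laser power, PMT gain) cancel; this is
   enforced as a tested invariant and is the reason no between-array
   normalization is applied by default (a normalizer hook exists but the
   default is identity).
2. **Protein SNR** — arithmetic mean of spot SNRs over usable replicate
   spots. A spot is unusable if its GenePix flag is negative or its
   background median is zero (a zero background median is a
   quantification artifact; assigning it infinite SNR would be worse
   than dropping it). When one of two duplicates is dropped, the mean is
   over the surviving spot. Proteins with no usable spot are reported in
   an exclusion list, never silently dropped. Positive-control spots
   (histone-like features) and empty buffer spots are quantified for QC
   display but never enter candidate calling.
3. **Calling Score** — SNR(−)/SNR(+), the fold-suppression by
   competitor. When SNR(+) is exactly zero the score is undefined
   (`None`): the result is treated as passing the score cutoff — zero
   residual signal is the strongest possible suppression — but flagged
   `complete_suppression` so it is visible, since in practice a zero
   background-corrected signal indicates an artifact.
4. **Candidate call** — inclusive dual filter, SNR(−) ≥ 3 and
   Calling Score ≥ 2.5 by default. Inclusive (≥, not >) comparisons
   matter: the published table's weakest rows sit exactly on 2.57 and
   2.60. Output is sorted by SNR(−) descending, ties broken by protein
   identifier.

## Precision and rounding

All internal comparisons use full floating-point precision; rounding
(half-up, matching how score tables are printed, implemented via
`decimal`) happens only at the reporting layer. One deliberate
exception: when the *input itself* is a printed table whose SNR columns
are 2-decimal roundings, `call_candidates(..., score_precision=2)`
thresholds the score at the table's printed precision. This is what
makes thresholding self-consistent on printed data — a row whose score
prints as 2.60 passes an inclusive 2.6 cutoff, while its unrounded
ratio (2.5995) would not. Freshly quantified scans always use the
default full precision.

The packaged 23-row table preserves the published values bit-for-bit,
including the "EentC" identifier typo (with a normalized `alias`
column, "EntC", for joins) and the two rows printed out of SNR(−)
order. Recomputing scores from the printed SNR columns reproduces
21/23 printed scores exactly; DeoA (5.00 vs 5.01) and TalB (12.07 vs
12.08) differ by 0.01 because the original scores were evidently
computed from unrounded SNRs. Tests assert |recomputed − printed| ≤
0.01 for all 23 rows rather than guessing the unrounded inputs.

## GPR/ATF I/O

The reader accepts the ATF dialect GenePix emits: `ATF<tab>1.0`, a
record-count line, optional quoted header records, a column-header row,
then data rows. Required columns are Block/Row/Column, "Name" or "ID"
(Name preferred when both are present), the per-wavelength foreground
and background medians, and Flags. Files with duplicate grid
coordinates are rejected, never repaired. Flagged spots are retained by
the reader and excluded by scoring — parsing and policy are separate
layers. The probing condition and competitor identity are metadata the
file format cannot carry, so they are supplied explicitly (CLI flag or
sidecar), never guessed from content. Encodings other than ASCII/UTF-8
are rejected. Intensities are serialized with `repr`, so write → read
round-trips every field exactly.

The 635 nm default follows the channel the screen's SNR was defined on;
the wavelength is configurable for arrays scanned on other channels
(the published reagent list and results name different dye conjugates —
Cy3 vs Cy5 — so the reader takes the channel as configuration rather
than resolving that discrepancy).

## The synthetic assay generator

The generator emulates the screen's design so the caller's operating
characteristics are measurable with no external data. Defaults are the
study's conditions:

| parameter | default | rationale |
|---|---|---|
| `n_proteins` | 4256 | array scale of the screen |
| `n_replicates` | 2 | each protein spotted twice |
| `frac_glyco` | 0.005 | ≈ 23/4256, the observed hit rate |
| `frac_nonspecific` | 0.01 | nonspecific binders plausibly outnumber hits ~2:1 |
| `glyco_snr_range` | [20, 160] | spans the observed SNR(−) 20.33–152.91 |
| `suppression_range` | [2.5, 13] | spans the observed scores 2.57–12.08 |
| `nonspecific_snr_range` | [5, 50] | bright but competitor-insensitive |
| `background_mean` | 500 counts | mid-range scanner background |
| `spot_cv` | 0.15 | assumed replicate variability (no published estimate) |

Latent classes: glycoprotein (true SNR under competition is
SNR(−)/suppression), nonspecific binder (suppression exactly 1),
non-binder (true SNR 1, i.e. at background). Effect sizes are drawn
uniformly over the ranges above — reproducing the observed spread
without asserting an unobserved distribution. Noise is multiplicative
log-normal on background and (independently) on foreground, with
σ² = ln(1 + CV²) and mean exactly 1 so intensities are unbiased;
scanner intensities are positive and heteroscedastic, which a
log-normal captures with one parameter. Background is i.i.d. across
spots — no spatial gradient (a documented extension point). Positive
controls are simulated as strong competitor-insensitive features;
two empty buffer spots are included.

All randomness flows through one numpy PCG64 generator; the draw
sequence (class permutation → effect sizes → suppressions → per-scan
background then foreground noise, minus scan first) is fixed, so a seed
determines scans, truth, and emitted files bit-for-bit. With
`spot_cv = 0` every noise factor is exactly 1.0 and the measured values
equal the generative ones, which the noise-free oracle tests exploit:
the called set must equal the brute-force enumeration of glycoproteins
whose latent parameters pass both cutoffs.

What the generator does **not** emulate — and hence what passing tests
do not show about real arrays: spatial background gradients and edge
effects, scanner saturation at high intensity, dye- and
probe-concentration chemistry, correlated replicate noise from print
tips, and carrier-protein cross-contamination. The simulation measures
the calling rule's statistical behaviour under its stated noise model,
not scanner physics.

## Evaluation

A call is a true positive iff the protein is flagged a candidate and
its latent class is glycoprotein. Proteins that were never evaluable
(unpaired between scans, or with every replicate excluded) are left out
of the confusion matrix and reported separately. Precision is undefined
(`None`) when no calls are made; recall over zero glycoproteins reports
0. Threshold sweeps quantify SNRs once and re-threshold per grid point.
Category summaries use per-assignment proportions: a candidate with two
annotation labels contributes two assignments of weight one, so
proportions sum to 1 over assignments while counts may exceed the
number of candidates; unannotated candidates count under
"unclassified".

## Problem sizes

The test suite simulates mostly 25–200-protein arrays; the noise-free
oracle and the noisy operating-characteristics checks run at the full
4,256-protein scale, which takes a few seconds. The analysis drivers
run the full-scale assay (seed 17) and a 42-point threshold sweep.

## Known limitations

- Single-lectin, single-channel analysis only; multi-lectin panels are
  out of scope.
- Calls are fixed-threshold, as in the original screen; no p-values or
  FDR machinery is provided, and none should be inferred.
- Control-spot SNRs are reported but never gate calling; the screen
  did not specify a gating rule and inventing one would change calls.
- Annotation categories are whatever map the caller supplies; no
  external classification service is queried.
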