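# Methods

## Coordinates and containers

All genomic coordinates are 0-based, half-open `[start, end)` — the
native convention of BED and bedGraph — so widths are `end - start` and
adjacent intervals share no base. A quantitative track is a sorted,
non-overlapping list of intervals with non-negative values; bases not
covered by any interval carry signal 0 (coverage-style semantics:
absence means no signal, not missing data). The bedGraph writer emits 6
decimal places so write-then-read round trips are exact.

## Peak response model

The response of a peak to treatment is the ratio of its track area
(signal x bp) between arms. Every treatment replicate is compared to
every vehicle replicate (the full cross): for treatment replicate *i*,

    r_i = mean_j log2( (A_Ti + eps) / (A_Vj + eps) )

and the peak's response is `mean_i r_i` with the unbiased sample
variance of the `r_i` retained for the downstream variance gate. The
pseudocount `eps` (default 1.0 signal*bp, applied to both arms) guards
zero-coverage peaks while preserving the arm-swap antisymmetry and the
scaling identity (multiplying the treatment track by *c* shifts every
response by log2 *c* in the small-`eps` limit).

Consensus peaks are connected components of any-base overlap across
replicate peak sets; a component is conserved when it contains peaks
from at least `min_replicates` distinct sets (default: all sets, the
conservative choice; the flag exposes the ≥2-of-3 alternative). The
consensus interval is the union span of the component — the paper-style
conservation rule does not dictate union vs intersection, and the union
keeps downstream widths well defined and never truncates a
replicate's evidence.

## Differential calling and shape classes

Calling is deterministic thresholding, not hypothesis testing: gain iff
mean log2FC >= gain threshold, loss iff <= loss threshold, all
comparisons inclusive (the thresholds are published as >=/<=). The
acetyl-mark default is +0.585 / -1.0 (a 1.5-fold gain, 2-fold loss);
the monomethyl default is +/-0.5 with an additional replicate-variance
ceiling of 1 — that mark's replicate variance is generally high, and a
peak whose replicate means disagree more than the ceiling is never
called regardless of effect size. The variance is computed over
replicate means, not raw pairings, because the gate is about
between-replicate agreement.

Peak shapes are modelled as a two-component Gaussian mixture on log10
width: quantitative ChIP width distributions show a dense mode of short
(~350 bp) peaks plus a tail of broad domains, and widths are strictly
positive and right-skewed, so the log scale is the natural choice. EM
is initialised from the exact two-means split of the sorted log-widths
(found by scanning all n-1 split points), which makes the fit a pure
function of the data — the seed argument only feeds the library RNG and
cannot change the result. Component order is normalised so the
smaller-mean component is "narrow"; a peak is narrow when its narrow
posterior is >= 0.5, with the tie at exactly 0.5 documented as narrow.
Populations with fewer than 10 widths or without 2 distinct values are
rejected as degenerate with instructions to fall back to a single
class.

## Chromatin-state enrichment

Fold enrichment is base-pair weighted: `fold(s) = (peak bp in s / total
peak bp) / (state bp / genome bp)`. A peak straddling several states
contributes its bases to each exactly; no single-assignment is made.
States with zero genomic coverage have undefined fold and are excluded
from the bias denominator. Enrichment bias rescales one peak set's
folds to percentages of their sum ("total enrichment" is read as the
sum of folds; summing overlap bp instead is a trivially different
normalisation the caller can compute from the reported columns). The
18-state-to-4-category condensation map (Promoter, Enhancer, Genic,
Repressive) ships as the default and is overridable.

## Two-mark integration

Linking measures the signed edge-to-edge distance from each A-peak to
its nearest B-peak (0 when overlapping, positive downstream); a pair is
emitted when that distance is within the +/- window (10 kb for
gain-centred analyses, 20 kb for loss-centred, both caller-supplied).
Edge-to-edge rather than centre-to-centre is the default because a
"within 10 kb" statement about broad domains most naturally bounds the
gap; ties between equidistant B-peaks go to the smaller start for
determinism.

The clustering feature is the mean second-mark signal in a fixed +/-
window around the A-peak midpoint (raw efficiency units; a fixed window
is used rather than the nearest peak's mean so that unlinked signal
shoulders count). k-means (k = 3) is initialised with a deterministic
farthest-point sweep over the 1-D features (the two extremes, then the
most isolated remaining point), run for at most 50 Lloyd iterations,
and the clusters are relabelled low/intermediate/high by ascending
centroid, making tier labels a pure function of the data. An
all-identical feature vector is returned as a flagged degenerate
assignment instead of an arbitrary split.

Profile matrices mirror the reference-point / scale-regions matrix
idioms: reference-point mode tiles `[centre - flank, centre + flank)`
with fixed bins (midpoint reference, floor division); scale-regions
mode adds `body_bins` bins of width `region/body_bins`, with fractional
bin bounds integrated exactly against the step-function track. Cells
are base-pair-weighted means; bins extending past chromosome bounds are
NaN and excluded from column means (zero-filling would fabricate signal
at chromosome edges).

## DMR criterion

Per-probe delta-beta is the difference of group mean betas (treated
minus vehicle). The scan finds maximal runs of consecutive probes with
the same non-zero sign whose neighbours are at most `max_gap` apart
(default 1,000 bp — array probes are sparse and an unbounded gap would
merge unrelated loci), and admits a run as a DMR when it has >= 5
probes and run-mean |delta| >= 0.20. The stricter per-probe reading
(every member probe's |delta| >= 0.20) is available as a flag. Runs
separated by a single sign flip are never merged. Maximality is with
respect to sign/gap extendability: a qualifying run is reported exactly
once, with its probe boundaries.

One consequence of run-maximality worth knowing: with noisy background,
probes flanking a true DMR whose noise happens to share its sign join
the run and dilute its mean; a planted run is therefore recovered with
exact probe boundaries only when background deltas are exactly zero.
The tests verify exact-boundary recovery in the noise-free setting and
verify the scan against a quadratic brute-force enumeration (which
checks every sub-run for admissibility and non-extendability) in the
noisy setting.

## Screen model

The well score is `max(RLU - background, 0) / confluency`; wells with
non-positive confluency are invalid. Two exclusion filters precede
scoring: genes with CPM below 100 in *every* provided expression
condition (a gene expressed in any condition is kept; genes absent from
the CPM table count as 0), and wells whose confluency is more than
`sd_mult` (default 1) SDs below the mean of all valid wells. Z-scores
use the mean and unbiased SD of the retained scores — computed after
filtering, over the whole screen rather than per batch (per-batch is an
option) — and a hit requires Z strictly greater than 4.

## Synthetic data: what it emulates and what it does not

Every generator is a pure function of (config, seed); per-generator
RNG streams are derived from the master seed so stages are independent.

- **Annotation**: chromosomes tiled with 200-bp bins assigned states
  i.i.d. at configured proportions (default: an 18-label composition
  dominated by quiescent chromatin), then merged. This preserves exact
  tiling and approximate proportions but has no spatial autocorrelation
  beyond bin merging — enrichment results on it test arithmetic, not
  biology.
- **Tracks**: rectangular peaks (constant height over width) placed
  with a minimum separation, heights uniform in 0.5-1.5x baseline,
  widths drawn on the log10 scale from a narrow (~350 bp) / broad
  (~2,000 bp) mixture, background 0.05 outside peaks. Vehicle heights
  are baseline x unit-mean lognormal noise (default CV 10%); treatment
  heights are additionally multiplied by the planted fold-change
  (default 2.0 gains, 0.4 losses, 20% each), with 2 replicates per arm
  by default and 3 for monomethyl-style designs. Rectangular shapes
  make area ratios analytically exact (CV 0 realises fold-changes
  exactly), at the cost of realistic peak profiles, read-level noise,
  and position-dependent background.
- **Beta matrices**: per-probe background methylation Beta(2,2), probe
  spacing uniform 50-500 bp, 3 samples per arm, Gaussian technical
  noise (default SD 0.02), values clipped to [0,1]; planted runs shift
  the treated group's probe means by delta before noise and clipping.
  No probe-type chemistry, detection p-values, or correlated
  neighbourhood structure.
- **Screen**: ~18,000 genes; healthy confluency N(80, 2), null scores
  N(20, 2), hits shifted by +8 null SDs, toxic knockdowns collapsed to
  10-40% confluency. Severe toxicity is deliberate: the viability
  filter thresholds at mean - 1 SD of the *observed* confluency
  distribution, and in a real screen that SD is dominated by the long
  left tail of lethal knockdowns, which places the cutoff well below
  the healthy range. Had healthy noise and toxic effects been on the
  same scale, the 1-SD filter would discard ~16% of healthy wells —
  including true hits — which is not how such screens behave. No plate
  or edge effects are modelled.

Passing tests on these generators demonstrate the statistics and the
interval arithmetic, not robustness to alignment artefacts, copy-number
bias, probe chemistry, or batch structure in real data.

## Problem sizes and numerical choices

The shipped tests and the acceptance script use desk-scale problems
chosen to make the statistical assertions sharp: 2 Mb chromosomes with
200 planted peaks for differential recovery, 1,000 widths for the
mixture, 200 probes for DMR oracle equivalence, 5,000 random peaks on 5
Mb for the enrichment null, and 10,000-well screens. The uniform-peak
enrichment check runs against the condensed 4-category annotation:
its rarest category covers >= 3% of the genome, so 5,000 random peaks
give every category enough intersections for a +/-0.2 fold band to be a
meaningful test, whereas the rarest raw states (0.5%) would be measured
from only ~25 peak hits and fluctuate beyond that band by sampling
noise alone.

Other numerical defaults: pseudocount 1.0 signal*bp; EM `reg_covar`
1e-9 with variance floors 1e-6 on the split initialisation; mixture and
k-means seeds are recorded but do not affect results (deterministic
initialisation); demo peak segmentation threshold 0.2 (4x the simulated
background, well below the weakest typical peak — though a minimal
height loss peak at fold 0.4 can dip below it, which is a detection
limit, not a defect); manifest hashes are SHA-256 over file bytes and
contain no timestamps, so identical (config, seed) reruns are
byte-identical.

## Known limitations

- Thresholds are published constants, not estimated error rates; no
  FDR or permutation machinery is provided by design.
- The absolute-scaling constant of quantitative ChIP is assumed already
  applied to the input tracks.
- Region-gene assignment is simple proximity linking; regulatory-domain
  models are out of scope.
- DMR calling implements the stated region criterion only, not the
  kernel-smoothed statistics of array-specific callers.
- bigWig ingestion is not implemented; tracks are exchanged as
  bedGraph.
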