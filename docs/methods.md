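# Methods

`replidyn` analyzes deep-sequencing coverage of total DNA taken during a
lytic phage infection of a bacterial host that carries a replicating
phage satellite. The observable is simple — how many reads land on each
replicon, and where — but it encodes copy-number dynamics, replication
origins, replication mode and even the packaging biology of the phage.
This note records the models, the estimators, the numerical choices and
what the synthetic benchmark does and does not establish.

## Abundance: genomes per million (GPM)

Raw read fractions conflate copy number with replicon length: a 126 kb
phage at one copy draws seven times the reads of an 18 kb satellite at
one copy. GPM removes the length factor the same way transcripts per
million does for RNA-seq:

    rate_i = reads_i / length_i
    GPM_i  = 10^6 * rate_i / sum_j rate_j

GPM is proportional to per-cell genome copy number, sums to 10^6 by
construction, and is invariant to sequencing depth. Copy ratios between
replicons are ratios of GPM (equivalently of rates). The package treats
the GPM formula as fixed; no alternative normalizations are offered.

## Coverage profiles

Reads are counted in 0-based, half-open bins (defaults: 1000 bp for the
phage-scale replicons, 150 bp for the 18 kb satellite; the final bin may
be short and its true width is carried along). Per-bin counts are
normalized to percent of the sample's total mapped reads *before*
replicate averaging — the averaged quantity is then depth-free — and the
mean and sample standard deviation (n−1 denominator) are reported per
bin. The SD is a sample SD, not an SEM; with triplicates the two differ
by √3 and the choice is recorded here because plots shading "the SD" are
ambiguous on this point.

GC skew is (G−C)/(G+C) per sliding window (default 1000 bp, step
window/10) computed on the annotated plus strand, with circular wrap for
circular replicons. Windows without any G or C are flagged missing
rather than propagated as NaN. The cumulative skew curve is provided as
a companion statistic: its global minimum and maximum are candidate
origin and terminus, because skew typically changes sign at both.

## Replication shapes

In an asynchronously replicating population, the expected coverage at a
position is proportional to the fraction of cells in which that position
has already been duplicated, so coverage decays with replication-fork
distance from the origin. The generator (and the classifier's mental
model) uses two idealized shapes on a circular genome of length L:

* **theta (bidirectional)** — log2 density declines linearly with
  circular distance d(x) from the origin, with a total peak-to-trough
  log2 range of log2(ptr):

      density(x) ∝ ptr^(−d(x) / (L/2))

* **rolling circle (unidirectional)** — density decays exponentially
  with the distance d̃(x) from the origin measured once around the
  circle against the direction of replication (replication is fixed as
  increasing coordinate, so "upstream" means decreasing coordinate):

      density(x) ∝ exp(−rc_decay · d̃(x)),   d̃(x) = (ori − x) mod L

  This produces the characteristic signature: a gradual decline on the
  upstream flank and a cliff immediately downstream of the peak.

* **mixed** — a per-timepoint convex combination of the two, used to
  model a theta-to-rolling-circle transition over the infection.

These functional forms are this package's formalization; the literature
describing expected marker-frequency shapes for the two modes does so
verbally, without committing to formulas. Everything downstream
(classification thresholds, recovery rates) is stated against these
forms.

## Origin detection

The coarse origin estimate is the argmax of the circularly smoothed
profile (moving average, default 5 bins), ties to the lowest coordinate,
optionally outside an exclusion mask. Two failure modes of the plain
argmax motivated a refinement step:

1. moving-average smoothing displaces the peak of a one-sided
   (rolling-circle) shape upstream by roughly half the smoothing window;
2. near the top of a theta peak adjacent bins differ by ~1%, so at
   realistic depth the argmax wanders a few bins.

The refinement scores every candidate bin within two smoothing widths of
the argmax by the residual of a least-squares regression of
log2(coverage + pseudocount) on distance-from-candidate, using both the
theta (circular min-distance) and rolling-circle (anti-replication
distance) templates and keeping the better of the two. The slope is
constrained to be non-positive: an unconstrained theta template is
exactly degenerate between the origin and the terminus (the circular
distance regressors are linear complements), and the constraint breaks
the tie in the origin's favor. The refined estimate is exact on
noiseless profiles of both shapes at every placement, and in simulation
at depth 10^5 (peak-to-trough 2, 126 bins) it localizes the origin
within ±2 bins essentially always, where the raw smoothed argmax sits at
~95%.

Flatness is decided two ways. A smoothed max/min ratio below 1.1 is
static. When replicate SDs are available, a variance test is applied as
well: the between-bin variance of the replicate mean is compared with
the mean squared replicate SD divided by the replicate count; a ratio
below 1.5 means the profile's structure is indistinguishable from its
own sampling noise and the call is static. The second test is what keeps
multi-megabase host chromosomes — whose smoothed max/min over thousands
of bins exceeds 1.1 on noise alone — from receiving spurious origins.

Confidence intervals come from resampling replicate profiles with
replacement (default 200 resamples) and taking percentile bounds on the
circular deviation of the re-estimated origin.

## Mode classification

Around the called origin, least-squares lines are fit to log2(smoothed
coverage + pseudocount) over w bins (default 10) on each flank.
Two statistics drive the label:

* **asymmetry** — the ratio of the smaller to the larger flank *decline
  rate*, where a decline is max(−slope, 0) measured away from the peak.
  Clipping at zero matters: the downstream flank of a wrapped
  rolling-circle exponential *rises* away from the peak with the same
  absolute slope as the upstream decline, so a naive |slope| ratio would
  score a textbook rolling circle as perfectly symmetric. With clipping,
  theta ≈ 1 and rolling circle ≈ 0. If both declines vanish the profile
  is flat and asymmetry is defined as 1.
* **drop_ratio** — mean coverage of the w gradual-flank bins divided by
  the mean of the w bins immediately across the peak; ≈ 1 for theta,
  large for rolling circle.

Labels: static if the peak-to-trough ratio is below 1.1 (or the variance
test fails); theta if asymmetry ≥ τ_sym and drop_ratio < τ_drop;
rolling_circle if asymmetry < τ_sym and drop_ratio ≥ τ_drop; otherwise
indeterminate. Genuine 50/50 theta/rolling-circle mixtures at moderate
decay land in the indeterminate region by design, and the
theta-to-rolling-circle transition over an infection is reported as the
sequence of per-timepoint labels, never as a single statistic.

τ_sym = 0.4 and τ_drop = 3.0 were calibrated by a simulation ROC at the
generator's default noise (peak-to-trough 2, depth 10^5, 126 bins,
multinomial sampling): theta accuracy 0.995, rolling-circle accuracy
1.0, and 50/50 mixtures at decay 2×10^-5 /bp classified indeterminate
in every replicate. They live in `CLASSIFY_DEFAULTS` and in the run
configuration, not in code paths. The pseudocount before the log2
transform is 0.5 reads, which keeps empty bins finite; with percent-
scale inputs the count-scale replicate mean is preferred whenever the
profile carries one.

## Transient terminus spike

Injected phage particles whose genomes have not yet circularized leave a
library-preparation bias: a narrow coverage spike at the packaging
terminus, present at the earliest timepoint and gone once replication
begins. A bin is called a transient spike when its early coverage
exceeds k (default 3) times the circular local median (window 2w+1,
default 7 bins) while its late coverage stays at or below k/2 times the
late local median. Contiguous calls are merged (across the coordinate
wrap if needed), bins enriched at both timepoints are reported
separately as persistent candidates (a persistent peak is a candidate
origin, not a terminus), and the transient bins feed the exclusion mask
of early-timepoint origin calls, replacing the by-eye exclusion a human
analyst would perform.

## Pac-site localization

Headful packaging initiates at a fixed pac sequence, which appears in
sequencing of particle DNA as a strand-specific spike of read starts.
Per strand, the candidate is the histogram argmax (ties to the lowest
coordinate, flagged); it is called when it exceeds z (default 10) times
the genome-wide mean *and* carries at least z reads. The absolute-
support guard exists because on a sparse uniform background (mean well
below one read per position) the Poisson maximum over 10^5 positions
exceeds any multiple of the mean without being a site. This is
deliberately not a reimplementation of full phage-termini statistical
frameworks: no cos/DTR/headful taxonomy, no coverage-model p-values —
just spike localization plus a transient check (called early, absent in
a late or particle-free pileup), which is the part the downstream
analysis needs.

## qPCR-style fold replication

Fold copy increase is modeled at the copy level:

    fold = (target_t / reference_t) / (target_t0 / reference_t0)

with a single-copy host locus as the conventional reference, so template
and depth effects cancel. Measurements carry multiplicative lognormal
noise (sd 0.1 by default), the natural error model for a ratio assay.
Relative replication efficiency is 100 × fold_test / fold_control.
Ct-level processing (standard curves, ΔΔCt, efficiency correction) is
out of scope; the copy-level definition is the package's choice and is
the level at which the simulator injects truth.

Condition contrasts use the ratio of median folds — robust at triplicate
scale — with a smoothed percentile bootstrap on the log scale (Gaussian
kernel, bandwidth sd·n^(−1/5), default 10,000 resamples, seeded). The
plain percentile bootstrap was measured at 0.874 coverage for a nominal
0.95 interval at n=3 (a ratio of medians of three values has only 27
distinct resamples per arm); the smoothed variant restores 0.954.

## The synthetic generator

The generator emulates the study conditions as its defaults, so that
"run the simulator, run the analysis, compare to truth" is a meaningful
benchmark:

* four replicons: a 2.9 Mb large and a 1.07 Mb small host chromosome
  (static on infection time scales, pre-infection copy skew 1.3:1 in the
  large chromosome's favor, reflecting the small chromosome's delayed
  replication initiation), a 126 kb phage and an 18 kb satellite;
* timepoints 4, 8, 12, 16 minutes; triplicates; 10^6 reads per sample;
* copy trajectories N(t) = n0·2^((t−onset)/doubling_time), flat before
  onset and truncated at n0·cap: the satellite (onset 4 min, doubling
  1.2 min) saturates at 1000-fold, the phage (onset 6 min, doubling
  1.4 min) at 125-fold — so at 16 minutes the satellite outnumbers the
  phage 8-fold, the headline copy-ratio observation;
* the phage replicates by theta from an origin at 60 kb early and is
  fully rolling-circle by 16 minutes (mix weights 0, 0, 0.5, 1 across
  the four timepoints; rc_decay 10^-4 /bp); the satellite replicates by
  theta from an origin placed at 5 kb, inside its noncoding region — the
  published map locates the origin in that region without giving a
  coordinate, so the position here is a choice, not a measurement;
* a 1.3 kb terminus spike (10× at 4 minutes, absent later) at the end
  of the phage genome, and pac positions 431 (+) / 891 (−);
* reads are allocated in one multinomial per sample over all
  (replicon, bin) cells with probabilities ∝ copies × bin length ×
  shape density; overdispersion multiplies cell weights by gamma
  variates (mean 1, variance = `dispersion`, default 0.02), which
  preserves the exact per-sample total, unlike per-bin negative-binomial
  draws;
* per-(replicate, timepoint) random substreams derive from one master
  seed via fixed spawn keys, so any subset of samples is reproducible.

Reference sequences are random with an imposed replichore skew: G over C
by `bias` from origin to terminus, C over G on the return arc, A/T
unbiased — enough structure for the skew stage to recover origin and
terminus from cumulative-skew extrema, and nothing else.

What the generator does **not** emulate, and therefore what passing
recovery tests do not establish: real read-level artifacts (mappability,
GC amplification bias, soft-clipping at termini), host DNA degradation
during infection, partial cell synchrony, the gene-sized fine structure
of real coverage, or Ct-level qPCR behavior. Recovery here demonstrates
estimator correctness under the stated model, not robustness to every
bias of real libraries — the analysis consumes whatever counts an
upstream aligner produces, and those biases are upstream concerns.

## Problem sizes and determinism

The shipped benchmark sizes are chosen to make the statistics stable at
desk scale: 10^6-read samples for abundance recovery (20 seeds),
10^5-read profiles for origin/mode work (100 seeds per class),
10^5-read pileups for pac recovery (50 seeds). Every stochastic step
takes an explicit seed; the command-line pipeline writes a config digest
and reproduces byte-identical outputs for identical config and seed.

## Known limitations

* The two-sided flank logic assumes a single dominant origin; multiple
  simultaneously active origins yield indeterminate labels rather than a
  multi-origin decomposition.
* The rolling-circle template fixes the replication direction as
  increasing coordinate; a genome annotated in the opposite orientation
  should be reverse-complemented upstream (the classifier would still
  fire, but slope signs in the report would read mirrored).
* At the earliest timepoint, before meaningful replication, the shape
  signal is weak by construction and calls there are frequently
  indeterminate; that is a faithful reflection of the data, not a bug.
* Pac calls are per strand and intentionally not reconciled into a
  single packaging model; the geometric relationship between the two
  strand-specific coordinates is reported as-is.
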