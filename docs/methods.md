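# Methods

This note records the models, conventions and numerical choices behind
`nedomains`, and what the synthetic benchmarks do and do not establish.

## Signal model and normalization

A DamID probe value is a log2 ratio of tethered-Dam methylation over a
freely diffusing Dam control. We model the raw per-probe value as

    y = µ(locus) + β·(GC − L/2) + ε,

where µ is the latent association level (0 outside envelope-associated
regions), β a linear GC hybridization bias over probe GC count (probe
length L), and ε AR(1) Gaussian noise along the probe order.

`gc_normalize` standardizes probes within GC strata by the stratum
median and 1.4826×MAD. The MAD constant makes the scale estimate
unbiased for Gaussian noise; strata with fewer than `min_probes_per_bin`
members (default 10) merge with their nearest stratum, and a zero-MAD
stratum falls back to a unit divisor so constant strata map to zero
rather than NaN. Because location and scale are estimated per stratum,
any bias that is a function of GC alone — in particular the linear bias
above — is removed exactly in expectation; the acceptance checks verify
|corr(score, GC)| ≤ 0.05 on simulated null tracks.

Median smoothing uses a window of ±150 bp around each probe **start**
(one fixed convention; with 50-bp probes the difference from
midpoint-anchoring is sub-probe). Quantile normalization maps each score
vector onto the mean of the across-vector order statistics, ties
receiving the mean of the reference values across their shared rank
span, so ties stay tied and re-application is a fixed point.

**Normalization pool.** Quantile normalization is applied jointly across
the replicates of the strains being compared (both Dam-fusion strains in
a run). The control self-comparison dataset is processed by the
identical per-track chain (GC standardization, smoothing, replicate
averaging) but is not entered into the cross-strain pool: its role is
to supply an empirical null for the *sign-based* window statistic,
which is invariant to any monotone per-column map, while pooling a
structureless null track with signal tracks would shrink the signal
tracks' score scale and distort the score-unit thresholds used by the
element rules.

## Domain calling and FDR calibration

Scores are binarized: > 0 → +1, ≤ 0 → −1 (an exact zero carries no
evidence of association and conservatively counts as negative). Windows
of 200 probes, sliding one probe, never cross chromosome ends; a
chromosome shorter than one window contributes no windows. The window
value is the mean of its signs.

The empirical FDR at threshold θ is the positive-window fraction of the
null track divided by that of the signal track, capped at 1. The
selection rule: if the default θ = 0.8 satisfies the ceiling (5%), it is
used; otherwise the smallest grid value passing the ceiling is selected.
This keeps the operating point at the conventional, boundary-sharp
threshold whenever the data allow it, rather than drifting to a
permissive threshold merely because the empirical-null FDR happens to be
tiny there. The full FDR(θ) table is always written out.

Positive windows are converted to spans from their first probe's start
to their last probe's end and merged when they share ≥ 1 bp. Domain
edges therefore carry an uncertainty of up to ~(1−θ)/2 of a window span
on each side — with defaults, ±≈1 kb — which is the main contributor to
the ~0.92 recovery Jaccard observed on planted domains rather than 1.0.
Chromosome termini are not gaps; gaps are intervals strictly between two
domains on one chromosome. Occupancy regressions are fitted over
autosomes only (the X chromosome follows a different spatial pattern and
is reported but excluded).

## Exclusive elements and detached regions

A probe qualifies as "A only" when its A score is ≥ 1 and its B score is
< 0 on the replicate-averaged tracks. Qualifying probes chain while
consecutive start-to-start distances are ≤ 500 bp (start-to-start is
well defined even for overlapping probes); intervening non-qualifying
probes do not break a chain — only spacing does. Chains with ≥ 10
qualifying probes are elements spanning first probe start to last probe
end.

Detached regions reuse the identical chaining rule on the WT − mutant
difference track with the own-score minimum acting as the detachment
threshold and no second-track condition; this is a documented stand-in
convention, chosen to keep a single defensible rule, and is fully
configurable. Swapping the argument order detects regions gained in the
mutant.

## Annotation statistics

Probe classification uses the fixed precedence promoter > exon > intron
(promoter = up to 3 kb upstream of the TSS, strand-aware). Background
fractions are computed over the probe universe, not raw bp, because the
tested units are probes. Enrichment p-values are exact binomial tails
(upper tail for enrichment, lower for depletion, chosen by the sign of
observed − expected); they match rational-arithmetic tail sums to 1e−10
for n ≤ 500. Rank-sum comparisons use full enumeration of label
assignments for combined n ≤ 16 (exact under ties), SciPy's exact
method for tie-free samples below 20 per group, and the tie-corrected
normal approximation otherwise. Gene occupancy is the mean of probes
overlapping the TSS–TES span by ≥ 1 bp, hence strand-invariant; genes
without probes are flagged missing rather than zero.

## Expression and SAM selection

Exon expression is the median per-base coverage over the exon; the exon
table is quantile-normalized across samples and locus expression is the
median over the locus's exons. The order matters: quantile
normalization can inflate the top-ranked values of a sample that lacks
truly elevated loci, and the across-exon median absorbs such single-exon
rank artifacts, which materially improves selection recall.

The SAM statistic is d = (x̄_b − x̄_a)/(s + s₀) with s the pooled
standard error, computed on log2(x+1): coverage noise is multiplicative,
and the fudge-factor machinery assumes scatter independent of level.
s₀ defaults to the 5th percentile of {s_i} (the original SAM choice);
the automatic rule — minimizing the CV of windowed MADs of d across
s-quantile bins — is implemented (`s0_rule="auto"`) but is degenerate on
quantile-normalized log coverage, where {s_i} is nearly flat with
artifact tails and the CV is minimized at the 100th percentile,
collapsing the d scale. Expected order statistics are averaged over all
distinct label assignments (enumerated exhaustively at the replicate
counts used here, e.g. C(5,2)=10; a seeded random subset above
`max_permutations`). Cutoffs follow the SAM rule: the least extreme
ordered d whose deviation from its expectation exceeds Δ (default 4)
sets the cut on each side, and every locus beyond a cut is significant.

Fold changes are ratios of group means with min/max over per-replicate
pairings; a zero wild-type mean flags the locus undefined.

## Synthetic study conditions

The generator emulates the structure that makes each stage non-trivial,
at desk scale:

* genome: two chromosomes (3.0 and 2.4 Mb by default), 50-bp probes at
  50-bp spacing (~105k probes);
* architecture: arms = outer 25% of each chromosome end; domain bp
  density 0.6 on arms, 0.05 in centers; domain lengths lognormal with
  23-kb median (σ_log 0.45), clipped at 15 kb so every planted domain
  exceeds one calling-window span; planted level 1.5 score units.
  Realized genome coverage lands near one third, matching the regime the
  method operates in on real worm data;
* both factors share one latent domain set (their in vivo profiles are
  strongly correlated); exclusive elements are 750-bp intervals inside
  one factor's domain where the other factor's domain is interrupted
  with a 100-bp margin, planted at own level 1.5 / other level −0.5;
  detached intervals are 5-kb interior segments of wild-type domains
  whose mutant level drops to 0;
* noise: AR(1) Gaussian, marginal sd 1.0 (0.5 in the element and
  detachment benchmarks), lag-1 correlation 0.5 (0.8 in the FDR
  stress test), GC bias 0.02 score units per GC count, 3 replicates;
* expression: 3 exons per gene, baseline coverage 20, gamma
  multiplicative noise with CV² = dispersion (0.05 default; 0.01 in the
  selection benchmarks, i.e. 10% coverage CV; dispersion 0 is the exact
  noise-free limit), de-repression fold 4 in non-control groups for
  genes overlapping detached intervals, groups wt:3 / double:2.

What the synthetic data does **not** emulate: real sequence composition,
probe dropout and coverage holes, array saturation, accessibility
structure in the Dam control, partial or cell-type-mixture detachment,
and correlated biological replicate effects. Passing benchmarks
therefore demonstrate correctness of the algorithms and calibration
machinery under the stated noise model, not performance on any
particular organism's arrays.

## Numerical conventions

All coordinates are 0-based half-open internally and in BED output.
Reference arm/center coordinates for the worm genome are shipped
1-based-converted in `workflow_io.CELEGANS_ARMS`. Interval merging
treats end-to-start touching intervals as mergeable. Window-score
computation uses a cumulative-sum identity; the test suite proves it
bit-identical to explicit window enumeration on random tracks. Every
stochastic stage takes an explicit seed, and pipeline outputs are
checksummed in a manifest; two runs from the same configuration are
byte-identical.

## Problem sizes

The bundled benchmarks run at ~105k probes for domain calling (one
seed), ~70k probes × 10 seeds for element recovery, and 1,000 loci × 21
simulations for the selection tests — sizes chosen so the full suite
exercises every stage at meaningful depth while remaining quick to run
on a laptop.
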