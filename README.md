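# nedomains

Analysis of DamID tiling-array profiles of chromatin association with
nuclear-envelope proteins — domain calling with empirical-null FDR
calibration, factor-exclusive element detection, genotype comparisons,
annotation statistics, and differential-expression screening — plus a
synthetic-data generator with planted ground truth so the whole chain is
testable end to end.

## The problem

In *C. elegans* (as in other metazoans), large chromosomal segments are
tethered to the nuclear envelope through lamin (LMN-1) and inner-membrane
proteins such as emerin (EMR-1). DamID measures these contacts: a Dam
methyltransferase fused to the envelope protein methylates adenines in
DNA it touches, and each ~50-bp tiling-array probe reports the log2 ratio
of fusion-methylated over freely diffusing Dam control. From such probe
tracks this package answers:

* Which intervals are **continuously associated** with each factor
  (lamin-associated domains, LADs; emerin-associated domains, EADs)?
* Which short elements bind **one factor exclusively** even though the
  two profiles are otherwise strongly correlated?
* Which regions **detach** from the envelope when one factor is mutated?
* Do released regions become **transcriptionally de-repressed**?

## The method

1. **Normalization** (`nedomains.normalize`): per-replicate robust
   standardization of probe scores within GC strata,
   `(x − median) / (1.4826·MAD)`, removing GC-dependent hybridization
   bias; 300-bp running-median smoothing; quantile normalization across
   strains; replicate averaging. The result is the per-probe score used
   everywhere downstream.
2. **Domain calling** (`nedomains.domains`): scores are binarized to
   signs (+1/−1), averaged in 200-probe windows sliding one probe, and a
   window is *positive* when its mean w ≥ θ (default θ = 0.8).
   The same procedure applied to a control self-comparison track gives an
   empirical null, and

   FDR(θ) = P₀(w ≥ θ) / P(w ≥ θ)

   is required to stay below 5%. Overlapping positive windows are joined
   into domains; gap statistics and chromosome-occupancy regressions
   follow.
3. **Exclusive elements** (`nedomains.elements`): probes with own-factor
   score ≥ 1 and other-factor score < 0, chained while consecutive
   qualifying probes are ≤ 500 bp apart; chains of ≥ 10 probes are
   elements. The same machinery on a wild-type − mutant difference track
   yields *detached regions*.
4. **Annotation** (`nedomains.annotate`): boundary metaprofiles of any
   secondary signal, span-based gene occupancy, one-sided exact binomial
   promoter/exon/intron enrichment, Wilcoxon rank-sum gene-set
   comparisons, track correlations.
5. **Expression** (`nedomains.expression`): exon expression = median
   per-base coverage; exon table quantile-normalized across samples;
   locus expression = median of its exons; differential loci selected by
   a SAM-style permutation statistic d = (x̄_b − x̄_a)/(s + s₀)
   with significance at deviation Δ > 4 from permutation-expected order
   statistics.
6. **Synthetic data** (`nedomains.synth`): worm-like probe tilings,
   arm-enriched planted domain architectures shared between two factors,
   planted exclusive elements and detached intervals, AR(1) probe noise
   with GC bias, a null control, and exon coverage with planted
   de-repression — every generator a pure function of its seed.

## Worked example

```sh
nedomains run --seed 11 --out runs/demo
```

prints

```
domains A/B: 57/57; coverage 0.341; elements A/B: 1/0; significant loci: 5
```

meaning: on a 5.4-Mb synthetic genome with arm density 0.6 and center
density 0.05, the caller found 57 domains per factor covering 34.1% of
the genome at the calibrated threshold θ = 0.8 (the run directory
contains the full FDR(θ) table, domain/element BED files, the SAM table
and a checksummed manifest). One factor-A-exclusive element survived the
probe-count rule at this noise level (sd 1), and 5 of the 6 genes planted
in detached intervals were selected as significantly de-repressed at
Δ > 4. The same analyses are available as library calls; see the
docstrings in `nedomains.domains` and `nedomains.expression`.

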