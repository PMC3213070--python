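# Methods

## The problem

In qPCR the cycle threshold Ct is the cycle at which a gene's
amplification signal crosses detection; at 100% efficiency one cycle is a
doubling, so Ct is −log2 of template abundance up to a per-sample offset.
Relative quantification subtracts a reference gene's signal (ΔCt) to
remove sample-level technical variation — RNA input, reverse-transcription
yield, loading. The method is only as good as the reference: if the
reference itself moves over the experimental conditions, every target
gene's normalized profile acquires the mirror image of that movement.
This package evaluates candidate reference genes in a time-course design
and quantifies the damage done by a drifting one.

## Data model and pre-analytic pipeline

The unit of analysis is a genes × samples Ct matrix; each sample is one
array (one animal) annotated with its time point. Recorded Ct values lie
in (0, 40], 40 being the instrument's last cycle; non-detections are
missing values.

Missing cells are classified before anything else:

* **biological** — the gene is undetected in *all* replicates over a
  contiguous run of time points touching the start or end of the time
  course. That pattern is consistent with the transcript genuinely absent
  before induction or after resolution. These cells are assigned Ct 40
  (the detection ceiling).
* **technical** — any other missing cell. It is imputed with the mean Ct
  of the detected replicates of the same gene at the same time point
  (never across time points).

Genes with ≥ 2 technical missing cells are removed before imputation;
biological cells never count toward removal. Ordering filtering before
imputation makes imputation total: a gene whose time point has *no*
detected replicate necessarily carries ≥ 3 technical missing cells and is
already gone. The classification rule is a config-overridable default,
and a sidecar annotation file (gene, sample, class) can override single
cells, standing in for the expert judgment a rule cannot encode.

The analysis scale is x = 41 − Ct: a reflection so that larger means more
expressed, plus a one-cycle pseudocount so Ct 40 maps to x = 1 rather
than 0. The transform is affine, so spread statistics (SD, MAD) are
identical on the Ct and x scales, and differences of x are log2 fold
changes.

A small QC statistic supports manual exclusions: the Pearson correlation
of one gene's Ct with the per-sample mean Ct of the *other* genes. A gene
reflecting global signal tracks that mean; a gene with array-specific
defects (the batch-artifact archetype) does not. The mean is
leave-one-out because on small panels a gene's own large excursions
otherwise contaminate the array mean and inflate the correlation. The
exclusion decision itself is configuration (a named gene list), matching
how such genes are handled in practice.

## Testing and normalization

Time points are independent groups (3–4 animals each; no repeated
measures, so no autocorrelation structure). Per gene:

* one-way fixed-effects ANOVA and Kruskal–Wallis across all time points,
  on the x scale, where residuals are closest to Gaussian;
* Benjamini–Hochberg adjustment of the ANOVA p-values across the genes of
  one normalization condition (one family per condition);
* fold change FC(t) = 2^(x̄ₜ − x̄₀) against the earliest time point;
* the time of greatest change maximizes max(FC, 1/FC) — change in either
  direction — with ties broken toward the earlier point; a two-sided
  pooled-variance t test compares that group with baseline (Welch is a
  config option; with group sizes 3–4 the pooled variant is the default);
* a gene is *regulated* when max(FC, 1/FC) ≥ 1.5 and BH-adjusted
  ANOVA p < 0.05.

Normalization schemes are declarative: none, single reference
(x′ = x − x_ref per sample), or multi-reference, implemented as the
arithmetic mean of reference x values — exactly division by the geometric
mean of the linear abundances, the standard multi-reference practice. A
literal geometric-mean-of-Ct-numbers variant is available behind a flag
for fidelity experiments; it is numerically eccentric and not the
default. Every scheme is a per-sample shift, so within-sample gene
rankings are preserved, and a re-centering constant (the across-sample
mean of the subtracted signal) keeps the output scale comparable; it
cancels in all fold changes and test statistics.

## Stability screening

Candidates are the genes the non-normalized ANOVA did **not** call
regulated (BH p ≥ 0.05). Screening after normalization would circularly
favour genes resembling the chosen reference, which is why the screen is
tied to the non-normalized results.

* **MAD screen**: candidates ranked by raw median absolute deviation from
  the median of their x values across all samples (ties broken by p
  descending). No 1.4826 consistency factor is applied — the values are
  reported as raw cycle-scale spreads, not SD estimates.
* **geNorm M**: for candidate i, M(i) is the mean over other candidates j
  of the sample SD (n − 1 denominator) of x(i,·) − x(j,·). Genes tracking
  the shared signal have small pairwise-difference SDs. The stepwise
  ranking repeatedly removes the highest-M gene (recomputing M each
  round); the final two genes have equal M by construction and share
  rank 1. Reported M values are the full-candidate-set ones, with the
  stepwise rank as a separate column. Candidates with more than 2 imputed
  or assigned cells are excluded up front (geNorm's excess-missing rule).
  The conventional cutoff M < 0.5 (strict) marks potentially usable
  references.

The two screens are methodologically independent (robust marginal spread
vs pairwise co-stability), so their agreement on the top candidates is
itself evidence; the replicate-simulation experiments measure exactly
that agreement.

## The synthetic-data generator

No public Ct matrix accompanies this study design, so a generator
produces matrices with the design's structure and known truth. The
generative model for gene g on sample s at time t is

    Ct(g,s) = baseline_ct(g) − log2_trajectory(g,t) − array_effect(s)
              + batch_shift(g,s) + N(0, noise_sd(g))

Positive log2 fold change lowers Ct (more template, earlier detection);
efficiency is fixed at 2 (one cycle = 2-fold), the conventional
assumption. Values above a gene's dropout threshold become missing;
values between the threshold and cycle 40 read as 40. The array effect
is an additive shift shared by all genes of a sample (default sd 0); the
batch-artifact archetype instead gets +4 cycles on 3 randomly chosen
arrays, emulating a manufacturing defect on specific arrays.

Default design: 7 time points (0, 1, 4, 9, 18, 27, 50 h) with
(3, 4, 4, 3, 3, 3, 3) replicates — 23 samples. Default panel (96 genes):

| archetype       | n  | trajectory                              | noise sd |
|-----------------|----|------------------------------------------|----------|
| stable          | 3  | flat                                     | 0.25     |
| spike           | 1  | +7.70 log2 at 4 h (≈208-fold), decaying  | 0.5      |
| drift           | 1  | rise to +1.49 log2 at 18 h (≈2.8-fold)   | 0.3      |
| batch_artifact  | 1  | flat + array-specific +4 cycle shifts    | 0.3      |
| dropout         | 10 | flat at baseline Ct 39.8, threshold 40   | 0.6      |
| null            | 80 | flat                                     | 1.0      |

The noise levels are design choices (the emulated study reports none).
Stable candidates are tight (0.25 cycles ≈ 19% CV in linear abundance);
flat "null" genes carry 1.0 cycle of animal-to-animal variability — a
2-fold spread, ordinary for inflammation-related transcripts in tissue,
and the very property that makes a statistically not-regulated gene a
poor reference. The ~4× spread ratio is what produces an unambiguous
top 3 in the screens, the structure the emulated study observed; with 80
flat competitors and 23 samples, an order-statistics argument shows a
smaller ratio would let the minimum of 80 null MADs undercut the maximum
of 3 stable MADs too often for the screen to be reliable. A `regulated`
mix key (moderate spikes, log2 amplitudes ≥ 1.5, varied peaks and
directions) lets users simulate signal-rich panels; it is 0 by default
because many strong true signals make the BH threshold adaptive-lenient,
and chance sub-threshold p-values then evict a genuinely stable gene from
the candidate pool in ~10% of runs — a property of BH screening worth
knowing about, demonstrated by flipping that key.

What the generator does *not* model: amplification-efficiency variation
between assays, inter-plate calibrators, probe chemistry, melt behaviour,
correlated biological co-regulation between genes, and non-Gaussian
heavy-tailed replicate noise. Passing tests therefore show that the
pipeline recovers planted structure under idealized independent Gaussian
noise — they do not certify behaviour on real arrays with correlated or
heavy-tailed variation.

## Replicate-simulation experiments

Three canned experiments (also run by `scripts/acceptance.py`) derive
per-replicate seeds from one base seed via `numpy.random.SeedSequence`:

* **Stable-gene recovery** (100 seeds, default panel): fraction of seeds
  in which the MAD screen's top 3 and the geNorm stepwise top 3 are
  exactly the planted stable genes, and in which the two top-3 sets
  coincide.
* **Drift artifact** (100 seeds): a dedicated panel (3 stable, 1 spike,
  the 1.49-log2 drifting reference, 25 flat genes at noise 0.3) tested
  under no normalization vs drift normalization. Measures the fraction of
  seeds with at least one truth-null gene called regulated *only* under
  drift normalization, and — selecting the focal gene among those
  spurious calls, as an analyst illustrating the artifact would — the
  fraction in which the focal gene shows apparent down-regulation with
  the sign-discordance flag set. The low flat-gene noise isolates the
  artifact mechanism: the mirrored drift is then the dominant source of
  time structure.
* **Global null** (500 seeds, 85 flat genes at noise 0.3): mean number of
  regulated calls per run; BH keeps it far below 1.

## Numerical and degenerate-input choices

* Sample SD uses the n − 1 denominator throughout (geNorm's published
  convention); MAD is raw.
* ANOVA/Kruskal–Wallis on all-identical values, t tests between two
  zero-variance groups, correlations of constant vectors and empty MAD
  inputs raise explicit degenerate-statistic errors in the scalar API; in
  the vectorized per-table path such genes get NaN p-values and are never
  called regulated. Zero within-group variance with different means gives
  p = 0 (perfect separation), which is what makes noise-free planted
  tests exact.
* Fold-change tie-breaks go to the earlier time point, deterministically.
* The stepwise geNorm tie-break removes the last of equal-M genes in the
  current (stable-sorted) order, deterministically.
* Sign discordance in the cross-scheme report: per scheme a gene's
  direction is up/down at its maximal-change point if that scheme calls
  it regulated, else none; the flag is set when at least one scheme sees
  a material change and the directions are not all equal. This covers
  both up-vs-down flips and regulated-vs-flat disagreement — the form the
  drift artifact actually takes for a flat gene, which shows *no*
  material change without normalization.
* All pipeline randomness flows from one integer seed through
  `numpy.random.default_rng`; `run_all` output files are byte-identical
  across invocations with the same config and seed (fixed float
  formatting, sorted JSON keys).

## Known limitations

* The biological/technical missing-value rule is a formalization of what
  is, in practice, expert judgment; the sidecar override exists precisely
  because edge cases (e.g. sporadic detection near the threshold at an
  edge time point) are genuinely ambiguous.
* BH families are per normalization condition; no cross-condition
  multiplicity control is attempted.
* geNorm's pairwise-variation V(n/n+1) statistic for choosing the number
  of reference genes is not computed; multi-reference choices are instead
  compared through the regulated-set Venn machinery.
* The ANOVA groups include the baseline with all later time points in one
  omnibus test; an alternative reading (baseline-vs-each contrasts) is
  not implemented, and for strongly peaked trajectories the omnibus test
  is the more powerful of the two.
* Normalized tables can in principle leave the x > 0 range for extreme
  reference/target combinations; the re-centering constant makes this
  rare and it does not affect any downstream statistic, so it is not
  enforced post-normalization.
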