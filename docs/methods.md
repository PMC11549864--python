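# Methods

## The regression model

The MRL regressor maps a one-hot encoded 50-nt 5'UTR (L×4, column order
A, C, G, T) to a scalar mean ribosome load. The architecture is the
published Optimus-5-Prime design: three 1-D convolutional layers with 120
filters each, kernel size 8, length-preserving zero padding and ReLU
activations, followed by flattening, a 40-unit ReLU dense layer with
dropout 0.2, and a linear output (474,681 trainable parameters).
Training uses Adam (learning rate 1e-3), batch size 128, squared-error
loss, and 3 epochs by default. Kernel size, padding, activation,
dropout, optimizer and batch size are not fixed by the architecture
description itself; the values above are the published training settings
of that model family, and all are config-overridable.

The network is implemented directly in numpy (float32, im2col +
BLAS matmuls, hand-written backprop). This keeps the dependency
footprint small, makes input-gradient computation for attribution a
first-class operation, and is fast enough on one CPU core (roughly 1 ms
per sequence-epoch of training at batch 128).

Targets are standardized with the training split's own mean/sd before
fitting, and predictions are inverse-transformed back to the MRL scale
(the train/test sets are deliberately scaled *separately*, replicating
the published preprocessing even though it is unconventional). All
reported performance is r² = 1 − SSres/SStot on the *untransformed* MRL
scale, so the scaling choice cannot inflate scores. The last 5% of the
training split (by stored order) is held out for per-epoch
validation-loss monitoring. Training with zero target variance raises
rather than silently producing a degenerate scaler.

Determinism: initialization (Glorot uniform), epoch shuffling and
dropout masks all draw from one seeded `numpy.random.Generator`, so a
(seed, data) pair reproduces weights, history and predictions exactly.

## Upstream ORF classification

A uAUG at 0-based index `p` of a length-`L` UTR has TIS-relative
position `p − L` and frame offset `(L − p) mod 3`. With exactly one
uAUG, codons `p, p+3, …` are scanned while the full codon lies inside
the UTR; the first of TAA/TGA/TAG terminates an upstream ORF (IF_UORF if
in frame with the CDS, OOF_UORF otherwise); with no in-UTR stop the call
is NTE (in frame: an N-terminal protein extension) or OUORF (out of
frame: translation overlaps into the CDS). Zero uAUGs is CONTROL;
two or more are EXCLUDED as ambiguous. A stop codon straddling the
UTR/CDS boundary is *not* counted as within the UTR: the reporter's
downstream CDS is fixed and invisible to the classifier, and an
overlapping uORF is precisely one whose translation continues past the
boundary.

## The synthetic MPRA simulator

The simulator emulates the two MPRA designs the modeling work targets: a
"random" library (i.i.d. uniform A/C/G/T per position) and a
"human-like" library (positions drawn with total G/C probability
`gc_target` = 0.6; sequences containing a uAUG retained with probability
`uaug_keep_prob`, emulating the uAUG depletion of native 5'UTRs).

The planted ground-truth MRL of a sequence is

```
mrl = base_mrl
    + kozak_bonus · 1[base at −3 ∈ {A, G}]
    + effect_by_class[class] · w(p)
    − gc_coef · GC_fraction
```

with defaults `base_mrl` 5.0 ribosomes/mRNA, `kozak_bonus` +0.8,
class effects IF_UORF −1.5, OOF_UORF/OUORF −2.5, NTE +0.2, CONTROL 0,
and GC coefficient 2.0 per unit GC fraction (a crude stand-in for
secondary-structure repression). The position weight `w(p)` is 1 when
the uAUG starts inside the TIS-relative window [−47, −32] — the region
where uORFs repress most strongly — and 0.5 outside it. Multi-uAUG
(EXCLUDED) sequences get the sum of their per-uAUG effects (each uAUG
classified as if alone, position-weighted), floored at −4.0: a
deterministic, monotone rule that no recovery test depends on.
Observations add Gaussian noise (sd 0.3) and Poisson read counts
(mean 200); read counts feed only the read-count split, never the MRL.

What the simulator does *not* model: polysome-fraction-level readout
(MRL is generated directly), PCR/sequencing error, RNA secondary
structure beyond the linear GC term, near-cognate starts, or the
empirical MRL distribution of any real library. Passing recovery tests
therefore demonstrates that the pipeline machinery — training,
attribution, occlusion, transfer — behaves correctly on data whose
regulatory grammar is known, not that the planted effect sizes match
biology. The noise level and MRL scale are chosen to be plausible
(observed r² ceilings around 0.85–0.9 resemble published MPRA fits)
since no measured values are available for them.

## Attribution

Integrated gradients with a null-matrix baseline: the gradient of the
scalar output is averaged along the straight path from 0 to the input at
midpoint interpolants `(k − ½)/steps, k = 1..steps` (50 steps by
default), then multiplied element-wise by the input. The midpoint rule
was chosen over an endpoint Riemann sum after measuring both: on a ReLU
network the path function is piecewise linear, and the endpoint sum
needs several thousand steps to push worst-case completeness error below
1% on inputs whose prediction barely differs from the baseline's, while
the midpoint rule is an order of magnitude more accurate at the same
step count. For one-hot inputs
this zeroes all non-observed bases, so a map reads as per-position
importance of the actual sequence. Gradients are taken on the
standardized-target scale; inverse target scaling is affine with
positive slope, so signs and rankings are unaffected and magnitudes are
comparable only within one model. The completeness diagnostic
`|Σ IG − (f(x) − f(0))| / |f(x) − f(0)|` quantifies Riemann-sum error;
it is exactly zero for linear models and below 1% for the trained CNN at
500 steps.

Meta-attribution maps average the maps of a population (element-wise
mean, n recorded). Populations are stratified by *predicted* MRL
(top/bottom decile), matching how the attribution figures are defined.

## Workflows

**Subgroup effects** classifies every reporter, drops EXCLUDED, and
tabulates observed and predicted MRL per class with deltas vs CONTROL
and unpaired two-tailed t-tests vs CONTROL. Welch's form (unequal
variances) is the default because class variances genuinely differ;
a pooled-variance switch exists. Classes with n < 2 get NaN p-values
rather than failing.

**Iterative occlusion** retrains from scratch (fresh seeded
initialization) on the full library, then after removing all
uAUG-containing reporters (−uAUG), then additionally removing reporters
beginning with the dinucleotide TG (−uAUG−UG, an adapter-context
artifact filter), recording test r² and decile meta maps each time. On
the simulator the random library loses most of its signal variance with
the uAUG reporters, so its r² drops; the uAUG-depleted human-like
library barely changes — the qualitative signature of interest.

**Transfer learning** continues training the random-library model on
the human-like train split (targets re-standardized on that split, fresh
optimizer state, all layers trainable) for every epoch count in a 1–15
grid, selecting the candidate with the best r² on the designated
selection split; ties go to the smallest epoch count for
reproducibility. The search is implemented as a single seeded run of
max(grid) epochs with per-epoch weight snapshots — step-for-step
identical to running each candidate independently, because training is
sequential and later epochs cannot affect earlier ones.

## TE link

Translation efficiency of a native transcript is log2(ORFspM/tpm),
computed after keeping only records with both counts strictly above 1
and, within each gene, the single ORF with the highest ORFspM (ties to
the first transcript id). Reporters are matched to native 5'UTRs by
glocal pairwise alignment (Biopython `PairwiseAligner`, match +1,
mismatch 0, gap −1, free end gaps on the native flanks) and kept when
identity over the 50-nt reporter is ≥ 0.9; each reporter keeps its
best-scoring native. The alignment scoring and threshold are package
decisions (the source pipeline did not state them) and are
config-exposed. Real GEO/GENCODE ingestion is an optional adapter fed
by pre-exported TSV/FASTA; the test suite uses synthetic fixtures with
planted correlations.

## Numerical and design choices

* DNA alphabet internally (T, not U); readers canonicalize U→T and
  uppercase. Sequences with N or other ambiguity codes are rejected at
  encoding — both reporter designs are unambiguous at 50 nt.
* Even-kernel "same" padding puts the extra column on the right.
* Read-count splits break ties by stored order; stratification by
  prediction breaks ties by stored order; `fine_tune` ties break toward
  fewer epochs.
* The EXCLUDED floor (−4.0) keeps multi-uAUG effects bounded so the
  simulated dynamic range stays realistic.
* float32 throughout the network; attribution maps are accumulated and
  stored in float64.

## Problem sizes

Tests and the acceptance script run everything at single-CPU desk scale,
chosen as the smallest sizes at which the qualitative effects are stable
across seeds: reference model 20,000 reporters (3 epochs), motif
recovery 50,000 with a 10,000-reporter test split (deciles of 1,000 maps
at 50 IG steps), occlusion 5,000 train / 1,250 test per library across 3
seeds, transfer pretrain 12,000 / fine-tune 4,000 across 3 seeds with
the full 1–15 epoch grid, TE fixtures ~120–150 transcripts. The
acceptance script uses the same or slightly smaller sizes with one seed.

## Known limitations

* The input window is fixed at 50 nt; native 5'UTRs are mostly longer,
  and nothing here addresses longer contexts.
* The simulator's linear GC term is not a structure model; attribution
  signatures of real structural motifs will differ.
* Attribution magnitudes are model-relative (see above); only signs and
  within-model comparisons are meaningful.
* The classifier is AUG-only; near-cognate starts are out of scope.
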