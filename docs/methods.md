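# Methods

## The similarity coefficient

For a pathway with gene set `G` and a population of samples, let `P` be the
`|G| × n` expression matrix. The off-diagonal Gram `P0 = P Pᵀ − Diag(P Pᵀ)`
collects pairwise gene–gene inner products; deleting the diagonal removes
the per-gene "energy" terms that grow with sample count, which is what
makes the comparison insensitive to population size. The TSC of two
populations on the same ordered gene list is the cosine similarity of the
two off-diagonal Grams (Frobenius inner product over the product of
Frobenius norms). Consequences used throughout:

* |TSC| ≤ 1 (Cauchy–Schwarz); self-comparison gives exactly 1.
* Duplicating every sample of a population multiplies `P0` by 2 and leaves
  the cosine unchanged — exactly, not approximately.
* Rescaling a population by any nonzero scalar is invisible.
* With exactly 2 genes every off-diagonal Gram is a multiple of the same
  2×2 pattern, so any defined 2-gene TSC is ±1; pathways therefore need
  ≥ 2 genes for the statistic to exist and ≥ 3 to be informative.

**Undefined values.** When either off-diagonal Gram is all-zero the
denominator vanishes and the TSC is undefined. The package represents this
as `nan` — an explicit marker, never silently 0, since 0 is a meaningful
similarity. Callers decide: the classifier drops undefined pathways before
taking medians (a draw with > 50% undefined pathways on either side
abstains), the biomarker ranking drops undefined entries pairwise and
excludes fully-undefined columns.

**Numerics.** Gene order is canonicalized to lexicographic over the
intersected gene set before Gram construction, making outputs independent
of GMT file order and byte-stable. The quotient is clipped to [−1, 1] to
absorb last-ulp rounding overshoot of the analytic bound. No centering,
scaling, or rank transform is applied inside the TSC; expression values
are consumed as given, with an explicit optional `log2(x+1)` preprocessing
flag (default off) for linear-scale matrices.

## Gene-set handling

Gene sets arrive as GMT (the standard carrier for GO C5 collections). The
size filter keeps sets whose membership, **after** intersection with the
measured genes, lies in the inclusive window [10, 30] — the similarity can
only use measured genes, so counting before intersection would admit sets
that are effectively smaller. Bounds are inclusive by plain reading of
"10 to 30". Genes absent from the matrix are dropped silently per set with
one summary log line; nothing is imputed. The filter is idempotent.

## Classification

**Delta-TSC profile.** For each sample `s` and pathway: TSC(`s`,
responders \ {s}) − TSC(`s`, non-responders \ {s}), the scored sample
always excluded from both references. Defined entries lie in [−2, 2]. This
full-population leave-one-out delta is the biomarker feature; the
subsampled draws below are reserved for the classifier.

**Majority-vote classifier.** For each held-out sample, `n_draws` (default
100) times: draw `draw_size` (default 5) responders and as many
non-responders without replacement, both excluding the sample; compute the
per-pathway TSC of the sample against each draw; reduce each side to its
median over pathways; vote responder iff the responder-side median is
strictly higher. "The median over pathways" is computed separately for the
responder-side and non-responder-side TSC vectors and the two medians
compared (`aggregate = median_each_side`); this is the explicit resolution
of an otherwise ambiguous reduction and is equivalent in spirit to
comparing the median delta against 0.

Tie handling is deterministic and conservative toward the clinically
default no-pCR class: median ties vote non-responder, and a 50/50 vote
split predicts non-responder. When exactly one side's TSC is undefined the
vote follows the defined side. A class smaller than the draw size falls
back to sampling with replacement and logs loudly. One global seed spawns
per-sample substreams indexed by sample rank (`SeedSequence(seed,
spawn_key=(rank,))`), so one sample's draws never leak into another's.

## Biomarker evaluation

The C-index of a score vector against binary response is computed from
midranks (Mann–Whitney U), equal to the mean over all
(responder, non-responder) pairs with ties counting 0.5 — the standard AUC
convention. Significance is the fraction of label permutations whose
C-index strictly exceeds the observed one (one-sided toward high C-index).
Exhaustive enumeration of distinct labelings replaces Monte-Carlo sampling
whenever there are ≤ 10,000 of them; the Monte-Carlo default is 1000
permutations. Because the permutation fraction per feature is not a
multiplicity-adjusted quantity, rankings report it raw **and** attach a
separate Benjamini–Hochberg-adjusted column. Profile comparisons across
(arm, ER) groups use Spearman rank correlation over shared pathways
(undefined below 3 shared), with Ward clustering of the pairwise matrix
available for ≥ 3 groups.

## Unsupervised analysis

Sample similarity is Spearman correlation of expression profiles (midranks
for ties); a sample constant across genes is a named hard error.
Hierarchical clustering uses Ward's minimum-variance method on Euclidean
distances **between rows of the similarity matrix** — the literal reading
of clustering "on the similarity matrix using Euclidean distance". The
alternative correlation-as-distance reading, `sqrt(2(1 − ρ))`, is exposed
as `distance="one-minus-cor"`. Dendrograms serialize to Newick; agreement
with response labels is the adjusted Rand index.

## Synthetic cohorts

The generator emulates a three-arm neoadjuvant trial: per-arm Bernoulli
pCR labels at rates defaulting to the printed 24.7% (lapatinib), 29.5%
(trastuzumab) and 51.3% (combination); independent ER+/ER− strata
(default fraction 0.5). Expression follows a latent-factor Gaussian model,
chosen for analytic control of pairwise correlation:

* a gene baseline `sqrt(ρ)·μ_g` shared by all samples (ρ =
  `baseline_correlation`, default 0.96) plus idiosyncratic noise of
  variance 1 − ρ: this drives inter-sample Pearson correlation to
  ρ / (total per-gene variance), near 0.93–0.95 at defaults, so that the
  emulated property "> 90% of sample pairs with r > 0.9" holds — the
  generator checks this on every cohort up to 1000 samples and records the
  result in the ground-truth echo, warning when unmet;
* per-pathway class-independent factors with small loadings (scale 0.15),
  giving every pathway some co-expression structure;
* for each of `n_signal_pathways` (default 10 of 100) signal pathways,
  disjoint gene blocks load on a latent factor through **class-specific
  unit-norm loading patterns** scaled by `effect_size` (default 1.0):
  responders and non-responders differ in gene–gene covariance, not in
  gene means, which is the structure the TSC reads and univariate gene
  statistics cannot. An optional `mean_shift` adds responder mean offsets
  on signal genes for exercising the gene-level pipeline; a log-normal
  output flag exponentiates values to mimic abundance scales.

Pathway sizes are uniform in [10, 30]; null pathways draw only non-signal
genes, so class signal is provably local to the designated sets. Cohorts
are byte-identical given (config, seed).

**Known trade-off.** The planted covariance signal adds per-gene variance
`effect_size²/|set|` on signal genes, which dilutes the shared-baseline
correlation; at `effect_size` ≈ 3 with few genes the r > 0.9 calibration
can drop below target (the generator reports this). Default conditions
(effect 1.0, 2000 genes) satisfy both properties simultaneously.

**What the generator does not emulate:** RNA-seq count noise and
library-size artifacts, batch effects, gene-length or GC biases,
arm-specific expression differences, and the marginal distributions of any
real cohort. Passing tests therefore demonstrate correctness of the
machinery and recoverability of covariance-borne signal under the stated
model — not clinical performance.

## Null behaviour of the classifier

With no class-linked signal the per-draw votes are independent of the true
label, so expected accuracy equals the class prior, not the empirical
majority fraction (which exceeds 0.5 at finite n by √-law fluctuation).
The null calibration test therefore runs at a balanced generating pCR rate
of 0.5, where chance rate and majority prior coincide at 0.5, and checks
the replicate mean against it within 3 standard errors.

## Problem sizes

Simulation-backed tests use reduced but structurally faithful conditions
chosen once: null-calibration and effect-trend cohorts of 40 samples with
30 pathways (6 signal, 600 genes) and 30 draws per sample over 50 and
3 × 20 replicates respectively; biomarker-ranking cohorts of 60 samples
(~30 per class) with 100 pathways (10 signal, 2000 genes) over 20
replicates; permutation-uniformity screens of 200 replicates at 300
permutations each. The acceptance sweep uses 10,000 random population
pairs and a 10,000-sample arm for rate calibration.

## Known limitations

* The TSC is computed dense; the [10, 30] size filter keeps Grams tiny, so
  no streamed or approximate variant is provided for large gene sets.
* Vote fractions are not calibrated probabilities; no multivariate
  combination of pathway deltas is attempted.
* Survival-time (censored) concordance is out of scope; response must be
  binary.
* GO hierarchy traversal is out of scope: gene sets are taken as given in
  the GMT.
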