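# Methods

`sposekit` implements a complete pipeline for learning and validating
interpretable similarity embeddings from triplet odd-one-out judgments:
experiment design, crowdsourcing quality control, the sparse positive
similarity embedding (SPoSE) model, hyperparameter selection, dimension
interpretation with a rating-based validation, and the stimulus-curation
steps that precede such an experiment.  Because the package is developed
and tested without any behavioral data, a synthetic-data generator that
emulates the assumed choice process is a first-class component: every
downstream stage is exercised against data whose generating truth is known.

## The choice model

Each stimulus $i$ has a non-negative weight vector $w_i \in
\mathbb{R}^K_{\ge 0}$ (a row of the embedding matrix $W$).  Similarity is
the dot product $s_{ij} = w_i \cdot w_j$.  In a trial showing $\{i, j,
k\}$, the odd one out is the item left over once the most similar pair is
picked, so the probability that $k$ is odd is the softmax weight of the
*opposite* pair:

$$p(\text{odd}=k) = \frac{e^{s_{ij}}}{e^{s_{ij}} + e^{s_{ik}} + e^{s_{jk}}}.$$

All probability computations shift scores by the row maximum before
exponentiating (exact for a softmax) and use log-sum-exp for the
cross-entropy, so underflow cannot produce `-inf` losses.

## Experiment design

`design.build_design` assembles three blocks: an *exhaustive* block
enumerating all triplets of a small subset one or more times, a *repeat*
block showing a fixed random sample of triplets many times (the basis of
the consistency estimate), and a *main* block in which every unordered
stimulus pair appears in `pair_coverage` triplets, each completed by a
distinct third stimulus drawn uniformly from the remainder.  Trials are
randomly interleaved, the on-screen order of each triplet is drawn
uniformly from the six permutations without positional balancing, and the
sequence is packed into consecutive sets of `set_size` (default 32)
trials.  If the total is not divisible by `set_size`, the final set is
short and a warning is emitted.  Repeated triplets re-randomize their
screen positions on every showing.

At full scale (768 stimuli; 48-stimulus exhaustive subset twice; 1,000
triplets repeated 40 times; pair coverage 4; sets of 32) the plan
comprises $2\binom{48}{3} + 40{,}000 + 4\binom{768}{2} = 1{,}252{,}704$
trials in 39,147 sets.

## Synthetic data generation

`synthetic.generate_ground_truth` draws the planted embedding: nonzero
entries are exponential with mean `scale` (default 1.0) and each entry is
zeroed independently with probability `sparsity` (default 0.5); all-zero
rows are redrawn.  The exponential/Bernoulli construction yields positive,
sparse, scale-controllable targets resembling trained embeddings, whose
columns have many near-zero and a few large loadings.  With these
defaults, pairwise dot products spread over roughly 0–6, making simulated
choices informative but far from deterministic.

Simulated workers come in three profiles.  *Compliant* workers sample
from the model's choice distribution, with a uniform random lapse on 5% of
trials (crowd workers are not perfectly attentive, and a modest lapse rate
keeps simulated consistency away from its ceiling); their reaction times
are log-normal with median 2,000 ms and log-sd 0.35, comfortably above the
filters' thresholds.  *Speeders* behave identically but respond with a
600 ms median — nearly every set trips the fast-set rule.
*Position-biased* workers click one fixed screen position with probability
0.8 and otherwise follow the model.  Sets are assigned to workers
round-robin, so cohort size controls sets-per-worker; simulations default
to a handful of sets per worker, as in a large crowdsourced cohort.

What the generator does *not* emulate: worker-specific ability or drift,
context effects between trials within a set, stimulus-level perceptual
noise, and any semantic content of the stimuli (ids are opaque).  Passing
tests therefore demonstrate that the algorithms are implemented correctly
and that the pipeline recovers planted structure under its own model
assumptions — not that the model is true of human judgments.

## Quality control

A set of trials is *fast* when at least 12.5% of its responses are under
900 ms **and** at least 50% are under 1,200 ms (both thresholds
inclusive).  A worker is excluded with at least three fast sets, or with
at least six sets in which one screen position received at least half of
the responses.  "Choosing one option" is read as screen position: stimulus
identities change every trial, so position is the only thing a worker can
be deterministic about.  After worker exclusion, individual trials with
RT strictly below 900 ms are dropped (a 900 ms response survives).

Choice consistency is computed over triplets answered at least twice:
per triplet, the fraction of unordered response pairs that chose the same
stimulus *identity* (invariant to screen position), averaged over triplets
so that triplets with different repeat counts weigh equally.  Chance level
is 1/3.  A modal-choice variant (`method="modal"`) is exposed because the
pairwise-vs-modal convention is ambiguous in common usage; pairwise is the
default and the documented behavior.

The position rule has a nonzero false-positive rate on honest workers:
a 32-trial set has roughly a 7% chance of one position reaching 16/32 by
luck, so a worker with dozens of sets can accumulate six flagged sets.
At realistic sets-per-worker (≈6–8) this is negligible; simulations use
cohort sizes with that ratio.

## Embedding training

`model.train` initializes an $n \times K_{\text{init}}$ matrix uniformly
in $[0, 1)$ (default $K_{\text{init}} = 100$), splits trials 90/10 into
train/validation at the trial level, and minimizes

$$\mathcal{L}(W) = \frac{1}{B}\sum_{t \in \text{batch}} -\log
p(\text{choice}_t \mid W) + \lambda \, \frac{\lVert W \rVert_1}{n}$$

with Adam (learning rate 0.001, batch size 128), clipping weights at zero
after every update (projected gradient).  Dividing the L1 term by the
number of items keeps $\lambda$ comparable across catalog sizes.  The
gradient is analytic — per trial, $\partial\mathcal{L}/\partial s_m = p_m
- \mathbb{1}[m = \text{odd}]$ scattered onto the two rows of pair $m$ —
and is verified against central finite differences in the tests.  The
scatter is implemented as a one-hot matrix product, which is several times
faster than `np.add.at` at these sizes.

Early stopping: training halts at `max_epochs` (default 500) or once the
validation loss has not improved for `window` (default 50) consecutive
epochs.  The validation loss is the mean cross-entropy on the held-out
trials *without* the penalty term: the penalty is a training-time prior on
$W$, not part of predictive fit, and including it would let $\lambda$
shrink the quantity used to select $\lambda$.  The weights at the stopping
epoch are kept.

After training, columns whose sum is strictly below 0.1 are removed
(a sum of exactly 0.1 survives), survivors are sorted by descending column
sum and relabeled `dim_001…`; the surviving count is the effective
dimensionality $k$.  Holdout accuracy is the fraction of validation trials
whose argmax predicted probability matches the observed choice; exact ties
resolve to the lowest screen position and the tie frequency is recorded.

## Hyperparameter selection and stability

`tuning.lambda_grid` builds an inclusive arithmetic grid (the reference
grid 0.006–0.012 in steps of 0.0005 has 13 values).  `grid_search` trains
one model per (λ, seed) pair — 13 × 10 = 130 runs at full protocol —
averages each run's best validation cross-entropy over seeds per λ and
selects the argmin.  Seeds are `base_seed + 1 … base_seed + n_seeds`.
`seed_stability` refits at the chosen λ across seeds and reports the
distribution of $k$.

## Interpretation and rating validation

Dimension readouts are `top_ranking_items` (descending weight, ties
broken lexicographically) and `dimension_profile` (one item's row — the
data behind a rose plot).  For the rating validation, typicality ratings
on a seven-level scale are mapped with level 1 ("very typical") → 1 and
level $\ell$ → $(8-\ell)/7$, while the off-scale answer "not at all" is
pinned to 0.  This reverse-coding keeps "very untypical" ($1/7$) distinct
from "not at all" (0), preserving the scale's semantics; the exact mapping
is a package decision, as only the endpoints are conventionally fixed.
Ratings are averaged across raters per (item, dimension).

Model weights for the rated items are min–max scaled to $[0,1]$ per
dimension over those items (constant dimensions map to 0 and are flagged).
Both matrices become item × item Pearson similarity matrices; the
representational similarity is the Pearson correlation of their strict
lower triangles.  Significance comes from a label-shuffling randomization
test: rows and columns of one matrix are relabeled by a random permutation
and the correlation recomputed; $p$ is the plain proportion of
permutations reaching the observed value (no +1 correction), so the
smallest nonzero $p$ is $1/n_{\text{perm}}$ and $p = 0$ when no
permutation reaches it.  The null calibration of this $p$ is itself
tested (uniformity under independent matrices).  No confidence interval
is attached to the RSA correlation: the package reports the correlation
and the randomization $p$ only, leaving interval construction (e.g.,
bootstrap over items) to the analyst.

## Stimulus curation

`curation` consumes per-frame classifier softmax vectors from a table.
Per video, the frame with the highest correct-class probability is kept
(ties → lowest frame index); category representatives are the mean of
their videos' best-frame vectors; pairwise cosine dissimilarity ($1 -
\cos$) between representatives feeds agglomerative clustering
(scipy linkage; average linkage by default — no linkage is canonical for
this use, and average is the least extreme of the three offered).  The
flat cut is exposed as either a cluster count or a height, since the
meta-cluster granularity is an analyst's choice.  The naming filter
excludes a category iff its mean exemplar naming accuracy is below 0.7
*and* at least two exemplars are individually below 0.7; the filter is
monotone in each accuracy.

## Parameter recovery (the end-to-end check)

`recovery.run_parameter_recovery` simulates 60 stimuli with 6 planted
dimensions, a pair-coverage design of ≈30,000 trials answered by 150
compliant workers, runs quality control, selects λ on a reduced grid
(five points spanning 0.006–0.012, two seeds, 120-epoch budget), and fits
the final model.  Success is measured by $|k - 6|$ and by the Pearson
correlation between the true and recovered item-pair dot-product vectors.

One numerical choice matters here.  At this data scale an epoch contains
~200 parameter updates (vs. thousands at full scale), and the validation
loss plateaus within a couple of hundred epochs while the L1 penalty is
still draining redundant dimensions: the effective dimensionality keeps
falling from ~20 at the plateau to the planted 6 over the following ~1,500
epochs with no change in validation loss.  The final recovery fit
therefore runs a fixed 2,500-epoch budget with early stopping disabled,
giving sparsification a number of updates comparable to a full-scale run.
The default `TrainingConfig` keeps the standard 500/50 settings; the
larger budget is a property of the recovery experiment, stated in its
docstring.

## Problem sizes and tolerances

Tests and the acceptance script run the recovery at n = 60 items /
30,000 choices, consistency calibration at 10,000 repeated-triplet
responses (±0.01 around 1/3), contaminant detection on a 14-worker cohort
(~3,600 trials), gradient checks at 1e-6 relative tolerance against
central differences with step 1e-6, and null calibration of the
randomization test with 200 replicates of 1,000 permutations
(Kolmogorov–Smirnov test against uniformity).  Clustering is verified
against a brute-force agglomeration oracle at n ≤ 6.

## Known limitations

* The synthetic generator is the model's own data-generating process;
  recovery results say nothing about model misspecification on real data.
* Effective dimensionality depends jointly on λ, the optimization budget
  and the data volume; at small scales the pruning threshold 0.1 (a sum
  over items) is relatively more permissive than at full scale.
* The randomization test permutes one matrix's labels, which assumes
  exchangeability of items under the null; it does not account for
  uncertainty in the rating preprocessing.
* Worker contamination is limited to the two pathologies the filters
  target; adversarial response patterns beyond speeding and position bias
  are out of scope.
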