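# sposekit

Learning interpretable similarity embeddings from triplet odd-one-out
judgments — experiment design, crowdsourcing quality control, sparse
positive embedding training, hyperparameter selection, dimension
interpretation, and stimulus curation, with a synthetic-data generator so
the whole pipeline is testable without collecting behavioral data.

## The problem

In a triplet odd-one-out task, a participant sees three stimuli and picks
the one least similar to the other two.  Millions of such cheap judgments
can reveal the mental similarity space of a stimulus set — *if* one can
(a) decide which triplets to show, (b) filter careless crowd workers,
(c) learn an embedding whose geometry explains the choices, and
(d) check that the learned dimensions mean something to people.
`sposekit` implements each step for anyone running or reanalyzing such
experiments (vision and cognition labs, computational social scientists).

At its core is the sparse positive similarity embedding (SPoSE) model:
each stimulus $i$ gets a non-negative vector $w_i \in \mathbb{R}^K_{\ge 0}$,
similarity is the dot product $s_{ij} = w_i \cdot w_j$, and the
probability that $k$ is judged odd in $\{i,j,k\}$ is

$$p(\text{odd}=k) = \frac{e^{s_{ij}}}{e^{s_{ij}}+e^{s_{ik}}+e^{s_{jk}}}.$$

Training minimizes the choice cross-entropy plus an L1 penalty
$\lambda\,\lVert W\rVert_1 / n$ under a non-negativity projection
(Adam, batch 128, learning rate 0.001); dimensions whose total weight
ends below 0.1 are pruned and the rest sorted by total weight, so the
effective dimensionality is an *output* controlled by $\lambda$.

## Worked example

Simulate an experiment from a known 6-dimensional ground truth, filter
it, tune λ, fit, and score recovery:

```python
from sposekit import run_parameter_recovery

result = run_parameter_recovery(seed=1)   # ~8 min on one core
print(result.k_true, result.k_effective)
print(round(result.similarity_r, 4), result.best_lambda)
```

prints

```
6 6
0.9792 0.012
```

i.e. from 30,000 simulated choices over 60 stimuli the pipeline recovers
exactly the 6 planted dimensions, and the recovered pairwise similarities
correlate at r = 0.98 with the true ones; the grid search picked
λ = 0.012.  The same experiment, split into narrated steps that write
TSV/JSON artifacts under `results/`, lives in `analysis/`:

```bash
python analysis/01_design_experiment.py    # triplet design + arithmetic
python analysis/02_simulate_choices.py     # contaminated simulated cohort
python analysis/03_quality_control.py      # exclusions, retention, consistency
python analysis/04_tune_lambda.py          # validation-loss grid search
python analysis/05_train_embedding.py      # final fit + recovery metrics
python analysis/06_interpret_dimensions.py # top-k items, profiles, rating RSA
python analysis/07_curate_stimuli.py       # clustering + naming filter demo
```

For example, `03_quality_control.py` reports on the simulated cohort of
120 compliant workers, 2 speeders and 2 position-biased workers:

```
workers excluded: [('pb0', 'deterministic'), ('pb1', 'deterministic'), ('sp0', 'fast_sets'), ('sp1', 'fast_sets')]
retained 30,265 / 31,530 trials (96.0%)
choice consistency on repeated triplets: 57.48% (chance 33.3%)
```

— exactly the planted contaminants are caught, and the compliant
workers' agreement on repeated triplets sits far above chance.  The
fitting steps then report (`04_tune_lambda.py`, `05_train_embedding.py`):

```
selected lambda = 0.0105
trained at lambda=0.0105: 8 dimensions (truth: 6)
true-vs-recovered similarity correlation: r = 0.9526
holdout accuracy: 68.2% (chance 33.3%)
```

## Layout

```
src/sposekit/     library: design, synthetic, qc, choice, model,
                  tuning, interpret, curation, recovery, io
analysis/         numbered narrative drivers writing results/
tests/            pytest suite (unit, property and acceptance tests)
scripts/          acceptance.py
docs/methods.md   model, assumptions, parameter choices, limitations
```
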