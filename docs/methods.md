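# Methods

## Problem and model

`velogrn` infers tissue-specific TF→gene regulatory interactions by asking
which transcription factors best predict a gene's *RNA velocity* — the time
derivative of its expression state — rather than its expression level.
Velocity is a better proxy for instantaneous regulatory activity: a gene's
steady-state expression can stay high long after its regulators have
switched off, whereas its velocity responds immediately.

Each gene *i* is a regression task. The input for cell *c* concatenates
three blocks of length *n* (number of TFs):

- `a_sum[·, i]` — summed open-chromatin coverage of each TF's binding sites
  in gene *i*'s promoter,
- `a_mean[·, i]` — the same averaged over the *m* sites,
- `x[c, ·]` — the cell's standardized TF expressions.

The network is small: a *TF aggregation layer* whose neuron *k* computes
`g(w1_k·a_sum_k + w2_k·a_mean_k + w3_k·x_k)` (one neuron per TF, three
learned weights each), followed by fully connected layers of 64, 32 and 16
ReLU units and a linear scalar output. `g` is ReLU by default
(configurable to tanh).

### Activity scores

For TF *i* and gene *j*, each binding site overlapping the gene's promoter
window (strand-aware, 3000 bp upstream to 3000 bp downstream of the TSS,
BED-convention half-open coordinates, clamped at 0) is scored by the
fraction of its basepairs covered by merged open-chromatin peaks — the
function `S ∈ [0, 1]`. Then `a_sum = Σ_k S_k` and `a_mean = a_sum / m`.
Open-chromatin peaks are merged per chromosome before coverage is counted,
which guarantees `S ≤ 1` regardless of how raw peaks overlap. A site
overlapping several promoter windows is credited only to the gene with the
nearest TSS (distance from the site midpoint; lexicographic gene id on
ties); this self-contained rule approximates nearest-gene annotation tools
and is not guaranteed to match any particular one. Pairs with no assigned
site score 0 (so the `m = 0` case never divides by zero). For joint
accessibility+expression assays, peaks are attributed back to individual
cells and a per-cell score replaces the tissue-level one.

Activity matrices are scaled `log2(x + 1)`; expressions are
`log10(RPKM + 1)` (the pseudocount keeps zeros at zero, which matters
because RPKM matrices contain many exact zeros) and column-standardized
with the population standard deviation. Velocities are standardized per
gene over their *observed* entries only; missing entries are never used as
targets. Training and test splits are standardized independently; a
`standardize_with_train_stats` flag offers the conventional alternative
(apply training statistics to the test set), off by default.

### Multi-task loss

Genes are grouped into nearly equal-sized clusters (see below), and within
a cluster the tasks are trained jointly:

    L = Σ_i MSE_i + λ Σ_i Σ_layers ‖W‖₁ + γ Σ_{k ∈ shared} ‖W′^[k]‖_*

`W′^[k]` stacks each task's layer-*k* weights, flattened row-major over
(input, output), as columns; biases are excluded from both penalties. The
nuclear norm `‖·‖_*` (sum of singular values) pushes the stacked matrix
toward low rank, i.e. toward tasks expressing their layer weights as
combinations of a few shared basis matrices — "soft" sharing with no hard
tying. Only FC1 and FC2 are shared; FC3 and the output layer stay
task-specific, on the usual grounds that lower-level features transfer
better. Its (sub)gradient is `U Vᵀ` from the thin SVD, recomputed at every
optimizer step (the stacks are at most a few thousand rows by ~25 columns,
so a thin SVD per step is cheap); tiny singular values are kept, since
`U Vᵀ` is stable regardless. Setting `sharing_enabled=False` removes the
γ term and yields the independent-baseline ablation with an identical
architecture.

The squared-error term is the per-task batch *mean* by default (so λ and γ
scales do not depend on batch size); `normalize_mse=False` restores the
plain sum. Optimization is Adam (β₁=0.9, β₂=0.999) implemented alongside
the network in NumPy; gradients of the full loss are validated against
central finite differences under tanh activation, where the loss is smooth
(under ReLU a finite-difference probe straddles kinks and disagrees
spuriously).

### Batching and epochs

Tasks have unequal sample sizes because velocity is unavailable in many
cells. One *ensemble batch* holds a size-*b* batch from every task; an
epoch has `ceil(C_max / b)` ensemble batches, `C_max` being the largest
task. Smaller tasks cycle through reshuffled permutations of their indices
("bootstrapping" by permutation cycling): unlike with-replacement
resampling, this guarantees every example of every task is used at least
once per epoch, which the protocol requires.

### Gene clustering

Sharing operates within clusters of genes with similar velocity profiles.
The feature vector of a gene is its standardized velocities with missing
entries imputed as 0 — the post-standardization column mean, a neutral
value that adds no distance. Clustering is k-means with the assignment
step replaced by a transportation linear program with per-cluster size
bounds (default 24–25), in the Bradley–Bennett–Demiriz style. The LP's
constraint matrix is totally unimodular, so the HiGHS vertex solution is
integral; the implementation verifies integrality and fails loudly
otherwise. Initialization is k-means++ from the given seed; iteration
stops when assignments no longer change (at most 100 rounds), and the
within-cluster SSE is non-increasing.

### TF ranking by attribution

After training, each input feature of each training example is attributed
relative to a single *reference example*: per-TF means of the standardized
training expressions (≈ 0 after standardization) and exactly zero activity
scores. Attributions use the rescale rule: multipliers propagate backward
through linear layers by the transposed weights and through each
nonlinearity by the secant slope `(g(z) − g(z_ref)) / (z − z_ref)`. Because
every step is exactly linear in the deltas, the attributions satisfy
*completeness* — per row they sum to `f(row) − f(reference)` to machine
precision — which the implementation verifies on every call (tolerance
1e-3 relative, configurable). The reference is computed from training
cells only, avoiding test leakage. A TF's importance for a gene is the sum
over attributed rows of the absolute attributions of its three features;
it is nonnegative, additive over row sets and permutation-equivariant in
TF order.

### Consensus networks

Training + ranking is repeated for `rounds` (default 5) seeds; for each
gene the regulators are the TFs present in the top-k (default 50)
importance list of *every* round, with edge importance the mean across
rounds and ties in top-k membership broken lexicographically for
reproducibility. Rounds differ by seed only by default (`--resample` style
data perturbation is intentionally not implemented; seed-only rounds keep
the consensus attributable to optimization variability). TFs are ranked
globally by out-degree.

### Evaluation

`r_squared` is the standard `1 − SS_res/SS_tot` (the occasionally-seen
per-term summation variant is a typographical reading; the standard score
is what "R²" means here). Recall against a curated truth set is
`TP/(TP+FN)`; precision is deliberately not reported because truth sets
are incomplete. Set-overlap enrichment is the inclusive upper tail
`P(X ≥ x)` of the hypergeometric distribution, evaluated in log space;
Benjamini–Hochberg correction is available when testing many sets.

## Synthetic data

The generator plants a coefficient matrix **B** (exactly `k_per_gene`
regulators per gene, effects uniform on ±[0.5, 2]) and emits every input
format the pipeline consumes. Raw expression is `10**z` with `z` standard
normal; velocity is `B`ᵀ applied to the log-transformed, standardized
expressions plus Gaussian noise (default sd 0.5), with entries missing
independently at the per-gene rate (default 0.3). A toy genome (one
chromosome, genes 20 kb apart, one per-TF slot inside each promoter) gives
every regulator a binding site covered 25–100% by an open peak and every
non-regulator a site with no peak overlap, so activity scores carry real
signal and exercise the same interval code as real data. Drop-out zeroes
raw expression entries independently before the log transform. A `tanh`
link is available as a nonlinearity stress.

What this emulates — and what it does not: linear (or saturating)
regulation with Gaussian noise, realistic missingness and drop-out, and
informative chromatin signal. It does not emulate count noise,
overdispersion, library-size effects, velocity-estimation artifacts, TF–TF
interactions, or annotation ambiguity. Passing benchmarks therefore show
the machinery recovers planted structure under its own assumptions, not
that it matches any particular tissue's biology.

## Benchmark conditions and default sizes

- *Recovery*: 50 TFs, 30 genes, 5 regulators/gene, 2000 cells, noise 0.5,
  30% missing; 2 clusters, 30 epochs, batch 128, 3 rounds, top-10
  consensus; recall of planted regulators within the ranked top 5,
  median over 3 seeds. One run takes ~20 s on one core.
- *Low-sample sharing comparison*: same but 200 cells and regulators drawn
  from a shared pool of 8 TFs (so the stacked task weights are genuinely
  low-rank). γ is raised to 0.1 — ten times the default — because with
  ~125 training examples the data term is small and the sharing penalty
  must be comparable in scale to have any effect; 300 epochs because one
  epoch is a single ensemble batch here. A development sweep (4 seeds)
  showed γ in 0.03–0.3 non-harmful and γ=1 over-shrinking to zero
  predictions. The comparison is medians over 10 seeds per arm.
- *Drop-out robustness*: recovery conditions with 60% drop-out; the
  reference point is random selection, which recovers 0.5 of 5 regulators
  in expectation (recall 0.1).

## Defaults and numerical choices

| parameter | default | note |
|---|---|---|
| λ (L1) | 0.01 | common framework default for L1 factors |
| γ (trace norm) | 0.01 | 0.1 in the low-sample benchmark (above) |
| learning rate | 1e-3 | Adam default scale |
| batch size b | 128 | |
| epochs | 30 | 300 in the low-sample benchmark |
| repeats | 3 | R² averaged over repeats with derived seeds |
| rounds / top-k | 5 / 50 | consensus construction |
| promoter window | ±3000 bp | strand-aware, clamped at 0 |
| cluster sizes | 24–25 | transportation-LP assignment |
| ChIP QC | q≥25, map≥60%, PBC≥80%, FRiP≥1%, peaks(FC>10)≥500 | inclusive |

Degenerate inputs: zero-variance columns standardize to zeros; genes with
fewer than 2 observed training cells are dropped (reported on the model
object); a gene with fewer than 2 observed test cells trains but gets NaN
R²; constant test targets make R² undefined and surface as NaN; empty site
lists and double scaling raise errors rather than propagate silently.

## Known limitations

- The NN stack (forward, backward, Adam) is NumPy; it is exact and tested
  but not GPU-capable, and very large clusters (thousands of tasks) would
  be slow.
- The nearest-TSS promoter assignment approximates but does not reproduce
  external annotators' nearest-gene rules.
- Whether promoter windows should clamp at chromosome right ends is
  unresolved; no chromosome sizes are required or used.
- The low-sample benefit of trace-norm sharing is real but small at these
  sizes; at single seeds the two arms can tie or cross.
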