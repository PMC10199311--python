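# Methods

## Detection model

All statistics operate on length-normalized counts
`round(1000 · raw / length_bp)` (half-away-from-zero rounding; the ×1000
scale keeps typical values from rounding to zero). After this
normalization, reads on a well-behaved signature gene (SG) set are treated
as uniform, independent draws with replacement over the n genes. The
number of distinct genes D hit by k reads then has pmf

    P(D = d | k, n) = C(n, d) · S(k, d) · d! / n^k,

with S(k, d) the Stirling number of the second kind. `sgabund.ccp`
evaluates log S(k, d) by the standard recurrence
S(k, d) = d·S(k−1, d) + S(k−1, d−1) as a log-sum-exp dynamic programme,
memoized in a growing rectangular table, so the pmf is exact to floating
precision for any k below the large-k cutoff. A Monte-Carlo backend
(`ccp_bootstrap`, `bootstrap_pmf_grid`) exists purely as an independent
cross-check of the analytic path; the test suite verifies a Pearson
correlation ≥ 0.99 between the two over n = 100, k = 1..176.

Degenerate regimes: for k ≥ 3000 the left tail collapses — P(D = n) ≈ 1
and P(D ≤ d) ≈ 0 for every d < n — so `ccp_pvalue` short-circuits there
instead of building enormous tables. Observing d ≥ n_test distinct genes
can never be evidence of depletion and returns p = 1; observing d > k is
impossible and raises. The expected-detection curve is the closed form
E[D | k, n] = n·(1 − ((n−1)/n)^k).

## Selection, ranking and refinement

**Initial set.** Per entity, genes are ranked by Pearson correlation of
their normalized count profile with the entity's per-sample median
profile ("co-abundance"); the top 100 form the initial SG set.
Zero-variance genes have no defined correlation and score −∞; ties break
lexicographically on gene id so selection is deterministic across
platforms. By default the correlation uses all samples; a config switch
(`coabundance_samples="detected"`) restricts it to samples with any
entity signal, since either reading is defensible.

**Replacement pool.** Genes are ordered by detection frequency (fraction
of samples with a positive normalized count). Frequencies outside the
Tukey fences [Q1 − 1.2·IQR, Q3 + 1.2·IQR] are excluded — this is our
concrete reading of a "1.2 interquartile range" screen, applied on both
sides — and the top 700 survivors form the pool (entities with fewer
genes contribute everything that survives).

**Ranking.** Within each detected sample (detection = ≥ 3 SGs with
counts), counts over the SG set are fitted by a negative binomial via
method of moments: μ = mean, σ = μ²/(s² − μ) when s² > μ, else σ = ∞ (the
Poisson limit). Genes are ranked by the raw deficit μ_j − y_ij with
average ranks on ties; rank n = most under-detected. The fitted
dispersion is carried in the fit and refreshed after each removal, but
the ranking statistic itself is the plain residual; a Pearson-residual
option (`residual="pearson"`) is available and is a no-op within a single
sample since the scaling is constant there. We fixed the rank direction
as "high aggregate rank = under-detected, remove above the threshold":
this is the only direction under which the published threshold grids
(35–60 out of 100 for the mean step, 90–98 for the percentile step) act
as coherent upper cut-offs; `remove_rank="low"` flips it if wanted.

**Two-step loop.** Step one sweeps every integer mean-rank threshold
t = 35..60; each run starts from the pristine initial set and repeats
remove → refit → refill → MSE-gate until the relative MSE improvement
drops below `mse_rel_tol` (default 1%; set 0 to demand any strict
decrease). Candidate sets detected in fewer than 10 samples are discarded
as too scarce to rank reliably (the retained, pre-refill set decides
this). Refills come from the pool in frozen co-abundance order, skipping
current members and genes removed in the same step. Step two repeats the
sweep with the 95th-percentile rank (nearest rank at or above the
percentile, so "rank 100 in 1 of 20 samples" aggregates to 100, not to an
interpolated value) over t = 90..98, seeded with step one's best set —
the two stages are sequential, not independent. The overall winner is the
lowest-MSE set across both sweeps; if nothing beats the initial MSE the
initial set is returned unchanged. The MSE is always evaluated against a
complete set (n_eval = 100), never against the shrunken retained set, so
the loop cannot optimize for an incomplete set; detection is evaluated
against the candidate set, so the detected-sample population may change
between iterations (the per-entity log records it). Refinement contains
no randomness.

**QC and abundance.** Every sample is scored per entity by
p = P(D ≤ d | k, 95) and rejected below α = 0.05; samples below the
detection threshold are neither accepted nor rejected. The ≥ 3-gene rule
is the primary detection criterion; a read-based alternative
(`detection="reads"`) is provided because both readings occur in
practice. QC-rejected cells stay in the abundance matrix by default —
rejection flags skewed gene representation rather than absent signal —
with `zero_rejected=True` enforcing literal removal. Relative abundance
divides each entity's summed normalized SG counts by the per-sample total
over entities; entities with fewer than 100 genes are reported as zero.
Entities sharing a user-supplied taxonomic label are collapsed by summing
rows, each entity labelled by the modal label over its refined SGs (ties
lexicographic).

## Synthetic catalogs

The simulator generates what the method assumes plus the failure modes it
corrects. Per-sample read totals (uniform in 20k–100k by default) are
partitioned over entities by a multinomial on log-normal relative
abundances (per-entity log-mean spread 1.0, per-sample log-sd 1.5), then
over genes by a multinomial whose weights are gene length times a
per-gene bias multiplier times a per-sample gamma perturbation with shape
σ_j ~ U(2, 10) — a Dirichlet-multinomial giving negative-binomial-like
marginals while conserving totals exactly. Two planted pathologies are
registered with ground truth: strain-specific genes (default 20% of each
entity's 1000 genes) that are exactly zero in a fraction (default half)
of the entity's samples, and detection-bias genes with log2 multipliers.
Strain absence defaults to the entity's lowest-abundance samples — the
accessory strain dominates only where the species is abundant — which
both mirrors the pathology seen in real catalogs (accessory genes riding
the co-abundance correlation into the initial set while being absent
elsewhere) and guarantees the planted genes actually enter the initial
selection; `strain_absence="random"` is available.

The default scale (5 entities × 1000 genes × 40 samples) matches a
40-sample benchmark catalog while fitting in seconds; tests use smaller
catalogs (2–3 entities × 150–400 genes × 12–30 samples) where the full
scale adds nothing. What the simulator does **not** emulate: cross-entity
read mapping, zero inflation beyond what the sampling model produces,
sequence-level artefacts, and compositional correlations between
entities. Passing tests therefore certify the statistical machinery under
the model's own assumptions, not performance on arbitrary real data.

## Numerical and design notes

* Rounding is half-away-from-zero (`floor(x + 0.5)`), not banker's
  rounding; stated because default numeric stacks differ here and the
  choice changes counts of exactly 0.5.
* Sample variance in the NB moment fit uses ddof = 1.
* All orderings (correlation, frequency, refill) break ties
  lexicographically by gene id; reruns are bit-identical.
* Refinement requires ≥ 3 detected samples at entry (the method needs
  cross-sample power); the separate < 10-sample rule applies to candidate
  retained sets inside the loop.
* On a clean catalog with no planted pathology the strict-decrease MSE
  gate still admits swaps that chase sampling noise, so some churn of the
  gene set is expected even when there is nothing to fix; the test suite
  checks that such churn leaves abundance accuracy intact rather than
  asserting the set stays untouched.
* Known limitation: over-sampled genes (surplus, rank ≈ 1) are never
  removed by either filtering step — the ranking targets deficits. The
  frequency fence on the replacement pool mitigates but does not remove
  this.

## Problem sizes

The acceptance script and test suite use: the full analytic/bootstrap
grid n = 100, k = 1..176 at 10⁵ iterations; 10,000 null QC samples with
k ∈ [50, 500]; 10⁵-draw checks of the expectation curve at
k ∈ {10, 100, 1000}; and one reference planted catalog at the simulator's
default scale. These sizes give Monte-Carlo standard errors well below
the asserted tolerances while keeping a full run in the low minutes on a
single core.
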