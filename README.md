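# sgabund

Signature-gene selection, refinement and relative-abundance estimation for
metagenomic species.

## The problem

Metagenomic binning (MSPminer, VAMB, MetaBAT 2, ...) groups the genes of a
gene catalog into species-level entities — Metagenomic Species Pan-genomes
(MSPs) or Metagenome-Assembled Genomes (MAGs). Quantifying such an entity
across samples by mapping reads to *all* of its genes is fragile: accessory
genes are carried only by some strains, some genomic regions are easier to
sequence than others, and multi-copy genes inflate the signal. A better
estimator uses a small set of **signature genes (SGs)** — genes present in
a single copy in every member of the clade and detected with uniform
sensitivity — and measures abundance from reads on those genes alone.
`sgabund` selects and iteratively refines 100-gene signature sets using
nothing but the gene count matrix itself, and produces QC-filtered relative
abundance profiles.

## The statistics

For a good signature set, length-normalized reads should land on the n
genes as uniform draws with replacement. The number of *distinct* genes D
observed after k reads then follows a coupon-collector law,

    P(D = d | k, n) = C(n, d) · S(k, d) · d! / n^k,

with S(k, d) the Stirling number of the second kind (evaluated here by a
log-space recurrence, exact to floating precision for any k), and

    E[D | k, n] = n · (1 − ((n−1)/n)^k).

Three uses follow:

* **Refinement objective.** An SG set is scored by the MSE between the
  observed d_j and E[D | k_j, 100] across detected samples (a sample is
  detected when ≥ 3 SGs carry counts).
* **Gene ranking.** Within each detected sample, per-gene counts are
  modelled as negative binomial (mean μ_j, dispersion σ_j by method of
  moments; var = μ + μ²/σ) and genes are ranked by their deficit μ_j − y_ij;
  rank n = most under-detected. Step one of the refinement removes genes
  whose *mean* rank across samples exceeds a threshold t (t swept over
  35..60); step two uses the *95th-percentile* rank (t in 90..98) to catch
  genes missing in only a few samples. Removed genes are replaced from a
  frequency-filtered pool (top-700 genes by detection frequency, Tukey
  fences at 1.2×IQR) in co-abundance order, and the edit is kept only if
  the MSE strictly decreases; each threshold run iterates until the
  relative improvement falls below 1%.
* **Per-sample QC.** A sample is rejected for an entity when
  P(D ≤ d | k, n_test = 95) < 0.05 — the observed gene diversity is
  improbably low for the read count, indicating skewed gene representation
  such as strain-level gene absence. Testing against 95 of 100 genes
  tolerates an inconsequential amount of biological variation.

Relative abundance is the per-sample share of length-normalized SG counts
across entities (entities below detection contribute zero).

## Worked example

Everything runs on synthetic catalogs with known ground truth (the
`simulate` module plants strain-specific genes that are absent from half
of each entity's samples — exactly the pathology refinement removes):

```python
import sgabund as sg
from sgabund.simulate import truth_error

catalog = sg.simulate_catalog(sg.SimConfig(seed=42))
model = sg.SignatureGeneModel(catalog.raw_counts, catalog.gene_entities,
                              catalog.gene_lengths)
result = model.fit()
print(result.summary())
```

```
Signature gene refinement summary
========================================================================
entities: 5  (refined: 5, unchanged: 0, skipped: 0)
samples: 40
------------------------------------------------------------------------
            status  mse_initial  mse_refined  genes_retained  ...
entity_id
E01        refined        9.762        7.260              78  ...
E02        refined       96.540        8.454              68  ...
E03        refined      229.970        1.865              14  ...
E04        refined      224.311        1.783              52  ...
E05        refined       29.943        4.801              66  ...
```

Each row is one entity: the MSE of its initial 100-gene set against the
expected-detection curve, the MSE after two-step refinement, and how many
initial genes survived. Here every entity moves markedly closer to the
coupon-collector expectation (e.g. E03: 230.0 → 1.9, with 86 of 100 genes
exchanged). The refined abundance estimates also move closer to the truth:

```python
e0 = truth_error(model.fit(refine=False).abundance, catalog.truth).overall_mean
e1 = truth_error(result.abundance, catalog.truth).overall_mean
print(f"mean |err| initial: {e0:.4f}  refined: {e1:.4f}")
# mean |err| initial: 0.0125  refined: 0.0101
```

`result.abundance` is the entities × samples relative-abundance matrix
(columns sum to 1 where anything is detected), `result.qc` the per-sample
coupon-collector verdicts.

The same pipeline is available from a shell:

```sh
sgabund simulate --out data --seed 42
sgabund run --counts data/counts.tsv --entities data/entities.tsv \
            --lengths data/lengths.tsv --out results
sgabund ccp-pvalue --d 80 --k 500 --n 95
```

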