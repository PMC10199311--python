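"""Synthetic gene-catalog generator with known ground truth.

Emulates the statistical structure the refinement method assumes and the
failure modes it corrects:

* entities (species-level gene bins) with log-normally varying relative
  abundance across samples;
* per-gene expected raw counts proportional to gene length (so that
  length-normalized counts are uniform across a good gene set);
* overdispersed counts: each sample's read total is partitioned over
  entities by a multinomial on the true abundances, then over genes by a
  multinomial whose weights are gamma-perturbed per gene and sample (a
  Dirichlet-multinomial), giving NB-like marginals with a per-sample
  dispersion while conserving read totals exactly;
* planted pathologies, recorded in a registry: *strain-specific* genes
  carried by an accessory strain and therefore exactly absent from a
  fraction of samples, and *detection-bias* genes whose sampling
  probability is multiplied by a per-gene factor (over- or under-sampled).

By default strain-specific genes are absent from the lowest-abundance
samples of their entity: the accessory strain dominates only where the
species is abundant, which is exactly the pattern that lets such genes
ride the co-abundance correlation into the initial signature set while
being undetectable in the rest of the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = ["SimConfig", "SimulatedCatalog", "simulate_catalog", "truth_error", "TruthError"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic catalog.

    The default scale — 5 entities x 1000 genes x 40 samples, 20%
    strain-specific genes per entity absent from half of its samples,
    20k–100k reads per sample — exercises both the detection pathology and
    the refinement machinery while running in seconds.
    """

    n_entities: int = 5
    genes_per_entity: int = 1000
    n_samples: int = 40
    gene_length_range: tuple[int, int] = (300, 3000)
    entity_mean_sigma: float = 1.0  # spread of per-entity log-mean abundance
    abundance_sigma: float = 1.5  # per-sample log-normal abundance spread
    dispersion_range: tuple[float, float] | None = (2.0, 10.0)  # per-sample sigma_j
    bias_fraction: float = 0.0
    bias_log2_range: tuple[float, float] = (-2.0, 2.0)  # log2 sampling multiplier
    strain_fraction: float = 0.2
    strain_absent_fraction: float = 0.5
    strain_absence: str = "low_abundance"  # or "random"
    reads_per_sample: tuple[int, int] = (20_000, 100_000)
    seed: int = 0

    def validate(self) -> None:
        if self.n_entities < 1 or self.genes_per_entity < 1 or self.n_samples < 1:
            raise ValueError("entity, gene and sample counts must be positive")
        for name in ("bias_fraction", "strain_fraction", "strain_absent_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.bias_fraction + self.strain_fraction > 1.0:
            raise ValueError("planted-gene fractions exceed 1")
        if self.gene_length_range[0] < 1 or self.gene_length_range[0] > self.gene_length_range[1]:
            raise ValueError("invalid gene_length_range")
        if self.reads_per_sample[0] < 1 or self.reads_per_sample[0] > self.reads_per_sample[1]:
            raise ValueError("invalid reads_per_sample")
        if self.strain_absence not in ("low_abundance", "random"):
            raise ValueError(f"unknown strain_absence mode {self.strain_absence!r}")
        if self.dispersion_range is not None and self.dispersion_range[0] <= 0:
            raise ValueError("dispersion must be positive (or None for no perturbation)")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


@dataclass
class SimulatedCatalog:
    """A simulated catalog plus its ground truth."""

    raw_counts: pd.DataFrame  # genes x samples, integer reads
    gene_entities: pd.Series  # gene_id -> entity_id
    gene_lengths: pd.Series  # gene_id -> length (bp)
    truth: pd.DataFrame  # entities x samples true relative abundance
    planted: pd.DataFrame  # gene_id, entity_id, kind, detail
    config: SimConfig | None = field(repr=False, default=None)

    @property
    def entity_ids(self) -> list[str]:
        return list(self.truth.index)

    def planted_genes(self, entity_id: str | None = None, kind: str | None = None) -> set[str]:
        sel = self.planted
        if entity_id is not None:
            sel = sel[sel["entity_id"] == entity_id]
        if kind is not None:
            sel = sel[sel["kind"] == kind]
        return set(sel["gene_id"])


def simulate_catalog(config: SimConfig) -> SimulatedCatalog:
    """Generate a catalog; bit-reproducible for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    E, G, S = config.n_entities, config.genes_per_entity, config.n_samples
    entity_ids = [f"E{e + 1:02d}" for e in range(E)]
    sample_ids = [f"S{s + 1:03d}" for s in range(S)]
    gene_ids = [f"{ent}_G{g + 1:04d}" for ent in entity_ids for g in range(G)]

    lengths = rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1,
                           size=E * G)
    offsets = rng.normal(0.0, config.entity_mean_sigma, size=E)
    raw_abund = np.exp(offsets[:, None] + rng.normal(0.0, config.abundance_sigma, size=(E, S)))
    truth = raw_abund / raw_abund.sum(axis=0, keepdims=True)

    totals = rng.integers(config.reads_per_sample[0], config.reads_per_sample[1] + 1, size=S)
    if config.dispersion_range is None:
        dispersions = None
    else:
        dispersions = rng.uniform(*config.dispersion_range, size=S)

    n_strain = int(round(config.strain_fraction * G))
    n_bias = int(round(config.bias_fraction * G))
    n_absent = int(round(config.strain_absent_fraction * S))

    planted_rows = []
    base_weights = np.empty((E, G))
    strain_masks = []  # per entity: boolean (G,) of strain-specific genes
    absent_masks = []  # per entity: boolean (S,) of samples lacking the strain
    for e, ent in enumerate(entity_ids):
        lo = e * G
        flagged = rng.permutation(G)
        strain_idx = flagged[:n_strain]
        bias_idx = flagged[n_strain : n_strain + n_bias]

        weights = lengths[lo : lo + G].astype(float)
        if n_bias:
            mult = 2.0 ** rng.uniform(*config.bias_log2_range, size=n_bias)
            weights[bias_idx] *= mult
            planted_rows.extend(
                (gene_ids[lo + i], ent, "bias", f"multiplier={m:.4f}")
                for i, m in zip(bias_idx, mult)
            )

        strain_mask = np.zeros(G, dtype=bool)
        strain_mask[strain_idx] = True
        absent_mask = np.zeros(S, dtype=bool)
        if n_strain and n_absent:
            if config.strain_absence == "low_abundance":
                absent_mask[np.argsort(truth[e])[:n_absent]] = True
            else:
                absent_mask[rng.choice(S, size=n_absent, replace=False)] = True
        planted_rows.extend(
            (gene_ids[lo + i], ent, "strain_specific", f"n_absent_samples={int(absent_mask.sum())}")
            for i in strain_idx
        )

        base_weights[e] = weights
        strain_masks.append(strain_mask)
        absent_masks.append(absent_mask)

    counts = np.zeros((E * G, S), dtype=np.int64)
    for s in range(S):
        entity_reads = rng.multinomial(totals[s], truth[:, s])
        for e in range(E):
            lo = e * G
            w = base_weights[e].copy()
            if absent_masks[e][s]:
                w[strain_masks[e]] = 0.0
            if dispersions is not None:
                w = w * rng.gamma(dispersions[s], 1.0 / dispersions[s], size=G)
            counts[lo : lo + G, s] = rng.multinomial(entity_reads[e], w / w.sum())

    raw = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)
    return SimulatedCatalog(
        raw_counts=raw,
        gene_entities=pd.Series(
            np.repeat(entity_ids, G), index=raw.index, name="entity_id"
        ),
        gene_lengths=pd.Series(lengths, index=raw.index, name="length_bp"),
        truth=pd.DataFrame(truth, index=pd.Index(entity_ids, name="entity_id"),
                           columns=sample_ids),
        planted=pd.DataFrame(planted_rows,
                             columns=["gene_id", "entity_id", "kind", "detail"]),
        config=config,
    )


class TruthError(NamedTuple):
    """Absolute abundance error per cell, with per-entity means."""

    table: pd.DataFrame  # entities x samples, |predicted - truth|
    entity_mean: pd.Series

    @property
    def overall_mean(self) -> float:
        return float(self.table.to_numpy().mean())


def truth_error(profile: pd.DataFrame, truth: pd.DataFrame) -> TruthError:
    """Absolute difference between a predicted relative-abundance profile
    and the ground truth, per entity x sample."""
    if sorted(profile.index) != sorted(truth.index) or list(profile.columns) != list(
        truth.columns
    ):
        raise ValueError("profile and truth dimensions do not match")
    aligned = profile.reindex(index=truth.index, columns=truth.columns)
    err = (aligned - truth).abs()
    return TruthError(table=err, entity_mean=err.mean(axis=1))
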