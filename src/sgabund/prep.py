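"""Catalog preparation: length normalization, co-abundance ordering, the
initial 100-gene signature set and the frequency-filtered replacement pool.

Counts live in pandas DataFrames with gene ids on the index and sample ids
on the columns.  All downstream statistics (detection, ranking, MSE, QC,
abundance) consume length-normalized counts, defined as
``round(1000 * raw / length_bp)`` with half-away-from-zero rounding; the
factor 1000 keeps the rounded values from collapsing to zero for typical
gene lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SignatureGeneSet",
    "EntityTooSmallError",
    "length_normalize",
    "median_profile",
    "coabundance_scores",
    "initial_sg_set",
    "replacement_pool",
    "sample_stats",
    "detected_samples",
]

DEFAULT_N_GENES = 100
DEFAULT_MIN_DETECTED_GENES = 3
DEFAULT_POOL_SIZE = 700
DEFAULT_IQR_FACTOR = 1.2


class EntityTooSmallError(ValueError):
    """Raised when an entity has fewer genes than the requested set size."""


@dataclass(frozen=True)
class SignatureGeneSet:
    """An ordered set of signature genes for one metagenomic entity.

    ``genes`` preserves selection order (descending co-abundance for an
    initial set).  ``origin`` flags each gene as ``"initial"`` or
    ``"replacement"``; ``scores`` carries the co-abundance score each gene
    had at selection time.
    """

    entity_id: str
    genes: tuple[str, ...]
    scores: dict[str, float] = field(default_factory=dict)
    origin: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"duplicate genes in SG set for {self.entity_id}")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "entity_id": self.entity_id,
                "gene_id": list(self.genes),
                "rank": np.arange(1, len(self.genes) + 1),
                "score": [self.scores.get(g, np.nan) for g in self.genes],
                "origin": [self.origin.get(g, "initial") for g in self.genes],
            }
        )


def length_normalize(raw_counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Length-normalize raw read counts: round(1000 * raw / length_bp).

    Rounding is half-away-from-zero (0.5 -> 1), not banker's rounding.
    Every counted gene must have a positive length; a missing length is a
    hard error naming the gene.
    """
    missing = raw_counts.index.difference(lengths.index)
    if len(missing) > 0:
        raise KeyError(
            f"no gene length for {missing[0]!r}"
            + (f" (and {len(missing) - 1} more)" if len(missing) > 1 else "")
        )
    use = lengths.reindex(raw_counts.index)
    if (use <= 0).any():
        bad = use.index[use <= 0][0]
        raise ValueError(f"non-positive length for gene {bad!r}")
    scaled = raw_counts.astype(float).div(use, axis=0) * 1000.0
    return pd.DataFrame(
        np.floor(scaled.to_numpy() + 0.5).astype(np.int64),
        index=raw_counts.index,
        columns=raw_counts.columns,
    )


def median_profile(norm_counts: pd.DataFrame) -> pd.Series:
    """Per-sample median across the entity's genes."""
    if norm_counts.shape[0] == 0:
        raise ValueError("entity has no genes")
    return norm_counts.median(axis=0)


def coabundance_scores(norm_counts: pd.DataFrame, samples=None) -> pd.Series:
    """Pearson correlation of each gene's profile with the entity median.

    Genes (or a median profile) with zero variance have no defined
    correlation and score ``-inf``, which sorts them last deterministically.
    ``samples`` restricts the computation to a subset of sample ids.
    """
    sub = norm_counts if samples is None else norm_counts.loc[:, samples]
    x = sub.to_numpy(dtype=float)
    med = np.median(x, axis=0)
    xc = x - x.mean(axis=1, keepdims=True)
    mc = med - med.mean()
    gene_ss = (xc**2).sum(axis=1)
    med_ss = float((mc**2).sum())
    if med_ss == 0.0:
        scores = np.full(x.shape[0], -np.inf)
    else:
        denom = np.sqrt(gene_ss * med_ss)
        with np.errstate(invalid="ignore", divide="ignore"):
            scores = np.where(gene_ss > 0, (xc @ mc) / np.where(denom > 0, denom, 1.0), -np.inf)
    return pd.Series(scores, index=sub.index, name="coabundance")


def initial_sg_set(
    entity_id: str,
    norm_counts: pd.DataFrame,
    n_genes: int = DEFAULT_N_GENES,
    samples=None,
) -> SignatureGeneSet:
    """Select the ``n_genes`` genes most correlated with the entity median.

    Order within the set is descending correlation; ties break
    lexicographically on gene id so the selection is reproducible across
    platforms.  Raises :class:`EntityTooSmallError` when the entity has
    fewer than ``n_genes`` genes.
    """
    if norm_counts.shape[0] < n_genes:
        raise EntityTooSmallError(
            f"entity {entity_id!r} has {norm_counts.shape[0]} genes < {n_genes}"
        )
    scores = coabundance_scores(norm_counts, samples=samples)
    order = sorted(scores.index, key=lambda g: (-scores[g], g))
    chosen = tuple(order[:n_genes])
    return SignatureGeneSet(
        entity_id=entity_id,
        genes=chosen,
        scores={g: float(scores[g]) for g in chosen},
        origin={g: "initial" for g in chosen},
    )


def replacement_pool(
    norm_counts: pd.DataFrame,
    pool_size: int = DEFAULT_POOL_SIZE,
    iqr_factor: float = DEFAULT_IQR_FACTOR,
) -> list[str]:
    """Frequency-filtered pool of candidate replacement genes.

    Genes are ordered by detection frequency (fraction of samples with a
    positive normalized count), descending, ties lexicographic.  Genes
    whose frequency falls outside the Tukey fences
    ``[Q1 - f*IQR, Q3 + f*IQR]`` of the entity's frequency distribution are
    excluded, so replacements share a consistently high ease of detection.
    The top ``pool_size`` survivors are returned; entities with fewer genes
    contribute everything that survives the fences.
    """
    freq = (norm_counts > 0).mean(axis=1)
    q1, q3 = freq.quantile([0.25, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - iqr_factor * iqr, q3 + iqr_factor * iqr
    surviving = freq[(freq >= lo) & (freq <= hi)]
    order = sorted(surviving.index, key=lambda g: (-surviving[g], g))
    return order[:pool_size]


def sample_stats(
    genes,
    norm_counts: pd.DataFrame,
    min_detected_genes: int = DEFAULT_MIN_DETECTED_GENES,
) -> pd.DataFrame:
    """Per-sample totals over a gene set.

    Returns a DataFrame indexed by sample id with columns ``k`` (total
    normalized counts on the set), ``d`` (genes with a positive count) and
    ``detected`` (d >= min_detected_genes).
    """
    sub = norm_counts.loc[list(genes)]
    k = sub.sum(axis=0)
    d = (sub > 0).sum(axis=0)
    return pd.DataFrame({"k": k, "d": d, "detected": d >= min_detected_genes})


def detected_samples(
    genes,
    norm_counts: pd.DataFrame,
    min_detected_genes: int = DEFAULT_MIN_DETECTED_GENES,
) -> pd.DataFrame:
    """Samples where the entity is detected (>= min_detected_genes SGs hit),
    with their (k, d) totals."""
    stats = sample_stats(genes, norm_counts, min_detected_genes)
    return stats.loc[stats["detected"], ["k", "d"]]
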