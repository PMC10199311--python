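"""Per-sample negative-binomial ranking of signature genes.

Within a sample, normalized counts over a signature gene set are modelled
as negative binomial with mean mu_j (average count per gene) and
sample-specific dispersion sigma_j, var = mu + mu^2 / sigma; sigma -> inf
recovers the Poisson limit.  Genes are ranked within each sample by their
deficit relative to expectation: rank 1 is the largest surplus, rank n the
largest deficit (the most under-detected gene).  Aggregating ranks across
samples (mean, or the 95th percentile to focus on the worst 5% of samples)
scores how consistently a gene under-performs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["NBFit", "fit_nb", "rank_genes", "rank_matrix", "aggregate_ranks"]


@dataclass(frozen=True)
class NBFit:
    """Method-of-moments NB fit for one sample over a signature gene set."""

    sample_id: str | None
    mu: float
    dispersion: float  # +inf means the Poisson limit

    @property
    def variance(self) -> float:
        if np.isinf(self.dispersion):
            return self.mu
        return self.mu + self.mu**2 / self.dispersion

    def expected_share(self, n: int) -> float:
        """Uniform null: each read has probability 1/n of hitting a gene."""
        return 1.0 / n


def fit_nb(counts, sample_id: str | None = None) -> NBFit:
    """Fit (mu, sigma) by the method of moments.

    mu is the mean count per gene; sigma solves var = mu + mu^2/sigma, i.e.
    sigma = mu^2 / (s^2 - mu) when the sample variance exceeds the mean,
    and +inf (Poisson limit) otherwise.
    """
    y = np.asarray(counts, dtype=float)
    if y.size == 0 or not np.any(y > 0):
        raise ValueError("cannot fit NB model to an all-zero count vector")
    mu = float(y.mean())
    s2 = float(y.var(ddof=1)) if y.size > 1 else 0.0
    if s2 > mu:
        sigma = mu**2 / (s2 - mu)
    else:
        sigma = np.inf
    return NBFit(sample_id=sample_id, mu=mu, dispersion=sigma)


def rank_genes(counts: pd.Series, fit: NBFit, residual: str = "raw") -> pd.Series:
    """Rank genes within one sample by deficit from expectation.

    The deficit score is ``mu - y`` (``residual="raw"``), or the Pearson
    residual ``(mu - y)/sqrt(mu + mu^2/sigma)`` (``residual="pearson"``;
    a per-sample constant under the uniform null, so it changes ranks only
    when combined across heterogeneous fits).  Genes are ranked ascending
    by score with average ranks on ties: rank 1 = largest surplus, rank
    n = largest deficit (most under-detected).
    """
    y = counts.to_numpy(dtype=float)
    score = fit.mu - y
    if residual == "pearson":
        score = score / np.sqrt(max(fit.variance, np.finfo(float).tiny))
    elif residual != "raw":
        raise ValueError(f"unknown residual type {residual!r}")
    return pd.Series(rankdata(score, method="average"), index=counts.index)


def rank_matrix(
    sg_counts: pd.DataFrame,
    sample_ids=None,
    residual: str = "raw",
) -> tuple[pd.DataFrame, dict[str, NBFit]]:
    """Rank matrix (genes x samples) over the given samples.

    Each column is the within-sample ranking of the signature genes; the
    per-sample NB fits are returned alongside.  Callers restrict
    ``sample_ids`` to detected samples.
    """
    cols = list(sg_counts.columns if sample_ids is None else sample_ids)
    ranks = {}
    fits = {}
    for s in cols:
        col = sg_counts[s]
        fit = fit_nb(col.to_numpy(), sample_id=s)
        fits[s] = fit
        ranks[s] = rank_genes(col, fit, residual=residual)
    return pd.DataFrame(ranks, index=sg_counts.index, columns=cols), fits


def aggregate_ranks(rank_df: pd.DataFrame, mode: str = "mean") -> pd.Series:
    """Aggregate per-sample ranks into one score per gene.

    ``mode="mean"``: arithmetic mean across samples.  ``mode="percentile95"``:
    the 95th percentile of the per-sample ranks (nearest rank at or above
    the percentile), so only the worst ~5% of samples drive the score.
    """
    if rank_df.shape[1] == 0:
        raise ValueError("no samples to aggregate over")
    if mode == "mean":
        return rank_df.mean(axis=1)
    if mode == "percentile95":
        agg = np.percentile(rank_df.to_numpy(), 95, axis=1, method="higher")
        return pd.Series(agg, index=rank_df.index)
    raise ValueError(f"unknown aggregation mode {mode!r}")
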