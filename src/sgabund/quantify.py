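"""Per-sample quality control and relative abundance estimation.

QC: a sample detected for an entity is rejected when the coupon-collector
left tail P(D <= d | k, n_test=95) falls below alpha=0.05 — the observed
number of unique signature genes is improbably low for the reads assigned,
indicating a skewed gene representation (e.g. strain-level gene absence).
Testing against 95 rather than all 100 genes tolerates an inconsequential
amount of biological variation.  Samples below the detection threshold are
neither accepted nor rejected.

Relative abundance: per sample, each entity's signal is the sum of
length-normalized counts over its signature genes (0 when below
detection), normalized across entities to sum to one.
"""

from __future__ import annotations

from collections import Counter
from typing import Mapping

import numpy as np
import pandas as pd

from .ccp import ccp_pvalue
from .prep import DEFAULT_MIN_DETECTED_GENES, sample_stats

__all__ = [
    "qc_samples",
    "relative_abundance",
    "collapse_entities",
    "entity_labels_from_genes",
]

DEFAULT_N_TEST = 95
DEFAULT_ALPHA = 0.05


def qc_samples(
    entity_id: str,
    genes,
    norm_counts: pd.DataFrame,
    n_test: int = DEFAULT_N_TEST,
    alpha: float = DEFAULT_ALPHA,
    min_detected_genes: int = DEFAULT_MIN_DETECTED_GENES,
    detection: str = "genes",
) -> pd.DataFrame:
    """CCP quality control of every sample for one entity.

    Returns one row per sample with columns ``entity_id, sample_id, k, d,
    pvalue, verdict``.  ``detection="genes"`` (default) marks a sample
    evaluable when >= min_detected_genes signature genes carry counts;
    ``detection="reads"`` uses k >= min_detected_genes instead.  Samples
    below the threshold get verdict ``not-evaluated`` and a NaN p-value.
    """
    stats = sample_stats(genes, norm_counts, min_detected_genes)
    if detection == "reads":
        evaluable = stats["k"] >= min_detected_genes
    elif detection == "genes":
        evaluable = stats["detected"]
    else:
        raise ValueError(f"unknown detection rule {detection!r}")
    rows = []
    for sample_id, row in stats.iterrows():
        if not evaluable[sample_id]:
            rows.append((entity_id, sample_id, int(row.k), int(row.d), np.nan, "not-evaluated"))
            continue
        p = ccp_pvalue(int(row.d), int(row.k), n_test)
        verdict = "rejected" if p < alpha else "accepted"
        rows.append((entity_id, sample_id, int(row.k), int(row.d), p, verdict))
    return pd.DataFrame(
        rows, columns=["entity_id", "sample_id", "k", "d", "pvalue", "verdict"]
    )


def relative_abundance(
    sg_sets: Mapping[str, tuple],
    norm_counts: pd.DataFrame,
    min_detected_genes: int = DEFAULT_MIN_DETECTED_GENES,
    qc: pd.DataFrame | None = None,
    zero_rejected: bool = False,
    zero_entities=(),
) -> pd.DataFrame:
    """Entities x samples matrix of relative abundances.

    Per sample j, entity e contributes a_ej = sum of length-normalized
    counts over e's signature genes, or 0 when the entity is below the
    detection threshold in that sample; columns are normalized to sum to 1
    (all-zero columns stay zero).  QC-rejected cells are kept by default —
    rejection flags skewed gene representation, it does not erase signal —
    but ``zero_rejected=True`` removes them before normalization (``qc``
    required).  ``zero_entities`` adds all-zero rows for entities that
    could not be quantified (e.g. too few genes).
    """
    signals = {}
    for entity_id, genes in sg_sets.items():
        stats = sample_stats(genes, norm_counts, min_detected_genes)
        signal = stats["k"].where(stats["detected"], 0)
        signals[entity_id] = signal.astype(float)
    for entity_id in zero_entities:
        signals[entity_id] = pd.Series(0.0, index=norm_counts.columns)
    profile = pd.DataFrame(signals).T
    profile = profile.reindex(sorted(profile.index))

    if zero_rejected:
        if qc is None:
            raise ValueError("zero_rejected=True requires the QC table")
        for _, row in qc[qc["verdict"] == "rejected"].iterrows():
            if row.entity_id in profile.index:
                profile.loc[row.entity_id, row.sample_id] = 0.0

    totals = profile.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = profile.div(totals.where(totals > 0, 1.0), axis=1)
    return rel


def entity_labels_from_genes(
    sg_sets: Mapping[str, tuple], gene_labels: Mapping[str, str]
) -> dict[str, str]:
    """Assign each entity the modal label over its (refined) signature genes.

    Ties break lexicographically; entities whose genes carry no labels are
    left out (they pass through :func:`collapse_entities` uncollapsed).
    """
    out = {}
    for entity_id, genes in sg_sets.items():
        labels = [gene_labels[g] for g in genes if g in gene_labels]
        if not labels:
            continue
        counts = Counter(labels)
        top = max(counts.values())
        out[entity_id] = sorted(l for l, c in counts.items() if c == top)[0]
    return out


def collapse_entities(
    profile: pd.DataFrame, entity_labels: Mapping[str, str]
) -> pd.DataFrame:
    """Sum abundance rows that share a taxonomic label.

    Entities without a label keep their own row (identity transform when
    no labels are supplied or all labels are unique).
    """
    labels = {e: entity_labels.get(e, e) for e in profile.index}
    collapsed = profile.groupby(pd.Series(labels)).sum()
    collapsed.index.name = profile.index.name
    return collapsed.sort_index()
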