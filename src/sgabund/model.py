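"""Model/Results interface tying selection, refinement and quantification
together.

:class:`SignatureGeneModel` is built from a gene count matrix, a
gene-to-entity map and gene lengths; :meth:`SignatureGeneModel.fit` runs
initial signature-gene selection, two-step refinement and per-sample QC,
and returns a :class:`SignatureGeneResults` carrying the refined sets,
MSE diagnostics, QC table, relative abundance profile and a ``summary()``
table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as sgio
from .ccp import expected_unique
from .prep import (
    EntityTooSmallError,
    SignatureGeneSet,
    coabundance_scores,
    detected_samples,
    initial_sg_set,
    length_normalize,
    replacement_pool,
)
from .quantify import (
    DEFAULT_ALPHA,

    collapse_entities,
    entity_labels_from_genes,
    qc_samples,
    relative_abundance,
)
from .refine import RefinementConfig, RefinementResult, refine_entity, sg_mse

__all__ = ["RunConfig", "SignatureGeneModel", "SignatureGeneResults"]


@dataclass(frozen=True)
class RunConfig:
    """Pipeline-level configuration: the refinement parameters plus the QC
    significance level, abundance handling and bookkeeping defaults."""

    refinement: RefinementConfig = field(default_factory=RefinementConfig)
    alpha: float = DEFAULT_ALPHA
    bootstrap_iterations: int = 100_000
    seed: int = 20230508
    zero_rejected: bool = False
    detection: str = "genes"  # QC evaluability rule: "genes" or "reads"
    coabundance_samples: str = "all"  # or "detected": restrict correlation

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        data = dict(data)
        ref_fields = {f for f in RefinementConfig.__dataclass_fields__}
        ref_kwargs = {k: data.pop(k) for k in list(data) if k in ref_fields}
        for key in ("mean_thresholds", "percentile_thresholds"):
            if key in ref_kwargs:
                ref_kwargs[key] = tuple(ref_kwargs[key])
        own = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(own)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(refinement=RefinementConfig(**ref_kwargs), **own)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(sgio.read_yaml_config(path))


class SignatureGeneModel:
    """Signature-gene abundance model for a metagenomic gene catalog.

    Parameters
    ----------
    counts : DataFrame, genes x samples, non-negative integer read counts.
    entities : Series mapping gene_id -> entity_id.
    lengths : Series mapping gene_id -> gene length in bp.
    config : RunConfig, optional.
    counts_are_normalized : pass True when ``counts`` are already
        length-normalized (x1000, rounded); otherwise normalization is
        applied at construction.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        entities: pd.Series,
        lengths: pd.Series,
        config: RunConfig | None = None,
        counts_are_normalized: bool = False,
    ) -> None:
        self.config = config or RunConfig()
        missing = counts.index.difference(entities.index)
        if len(missing) > 0:
            raise ValueError(f"gene {missing[0]!r} in counts but absent from entity map")
        missing = counts.index.difference(lengths.index)
        if len(missing) > 0:
            raise ValueError(f"gene {missing[0]!r} in counts but absent from lengths")
        if counts.shape[1] < 3:
            raise ValueError(
                f"refinement requires at least three samples, got {counts.shape[1]}"
            )
        self.raw_counts = None if counts_are_normalized else counts
        self.norm_counts = (
            counts if counts_are_normalized else length_normalize(counts, lengths)
        )
        self.entities = entities.reindex(counts.index)
        self.lengths = lengths.reindex(counts.index)
        self.entity_ids = sorted(self.entities.unique())

    @classmethod
    def from_tsv(cls, counts_path, entities_path, lengths_path,
                 config: RunConfig | None = None) -> "SignatureGeneModel":
        return cls(
            counts=sgio.read_counts(counts_path),
            entities=sgio.read_entity_map(entities_path),
            lengths=sgio.read_lengths(lengths_path),
            config=config,
        )

    def entity_counts(self, entity_id: str) -> pd.DataFrame:
        genes = self.entities.index[self.entities == entity_id]
        return self.norm_counts.loc[genes]

    def select_initial(self) -> tuple[dict[str, SignatureGeneSet], dict[str, pd.Series], list[str]]:
        """Initial SG sets and frozen co-abundance scores for every entity.

        Returns (sets, scores, skipped) where ``skipped`` lists entities
        with fewer genes than the configured set size (their abundance is
        reported as 0).
        """
        cfg = self.config.refinement
        sets, scores, skipped = {}, {}, []
        for entity_id in self.entity_ids:
            sub = self.entity_counts(entity_id)
            samples = None
            if self.config.coabundance_samples == "detected":
                any_signal = sub.sum(axis=0) > 0
                samples = sub.columns[any_signal]
            try:
                sets[entity_id] = initial_sg_set(entity_id, sub, cfg.n_genes, samples=samples)
            except EntityTooSmallError:
                skipped.append(entity_id)
                continue
            scores[entity_id] = coabundance_scores(sub, samples=samples)
        return sets, scores, skipped

    def fit(self, refine: bool = True) -> "SignatureGeneResults":
        """Run selection, refinement and quantification.

        ``refine=False`` stops after initial selection (the refined sets
        equal the initial ones), which is useful for before/after
        comparisons.
        """
        cfg = self.config.refinement
        initial_sets, scores, skipped = self.select_initial()
        refinements: dict[str, RefinementResult] = {}
        refined_sets: dict[str, SignatureGeneSet] = {}
        for entity_id, sg in initial_sets.items():
            sub = self.entity_counts(entity_id)
            if refine:
                pool = replacement_pool(sub, cfg.pool_size, cfg.iqr_factor)
                res = refine_entity(sg, pool, sub, cfg, coabundance=scores[entity_id])
            else:
                n_det = int(detected_samples(sg.genes, sub, cfg.min_detected_genes).shape[0])
                try:
                    mse = sg_mse(sg.genes, sub, cfg.n_eval, cfg.min_detected_genes)
                except Exception:
                    mse = np.nan
                res = RefinementResult(
                    entity_id=entity_id, status="unchanged", initial_set=sg,
                    refined_set=sg, mse_initial=mse, mse_refined=mse,
                    detected_before=n_det, detected_after=n_det,
                )
            refinements[entity_id] = res
            refined_sets[entity_id] = res.refined_set
        for entity_id in skipped:
            refinements[entity_id] = RefinementResult(
                entity_id=entity_id, status="skipped-small-entity"
            )

        qc_frames = []
        for entity_id, sg in refined_sets.items():
            qc_frames.append(
                qc_samples(
                    entity_id, sg.genes, self.entity_counts(entity_id),
                    n_test=cfg.n_test, alpha=self.config.alpha,
                    min_detected_genes=cfg.min_detected_genes,
                    detection=self.config.detection,
                )
            )
        qc = (
            pd.concat(qc_frames, ignore_index=True)
            if qc_frames
            else pd.DataFrame(columns=["entity_id", "sample_id", "k", "d", "pvalue", "verdict"])
        )

        abundance = relative_abundance(
            {e: s.genes for e, s in refined_sets.items()},
            self.norm_counts,
            min_detected_genes=cfg.min_detected_genes,
            qc=qc,
            zero_rejected=self.config.zero_rejected,
            zero_entities=skipped,
        )
        return SignatureGeneResults(
            model=self,
            refinements=refinements,
            initial_sets=initial_sets,
            refined_sets=refined_sets,
            skipped_entities=tuple(skipped),
            qc=qc,
            abundance=abundance,
        )


@dataclass
class SignatureGeneResults:
    """Fitted signature-gene sets plus diagnostics and abundance estimates."""

    model: SignatureGeneModel
    refinements: dict[str, RefinementResult]
    initial_sets: dict[str, SignatureGeneSet]
    refined_sets: dict[str, SignatureGeneSet]
    skipped_entities: tuple[str, ...]
    qc: pd.DataFrame
    abundance: pd.DataFrame

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for entity_id in sorted(self.refinements):
            r = self.refinements[entity_id]
            n_rej = int(
                (
                    (self.qc["entity_id"] == entity_id)
                    & (self.qc["verdict"] == "rejected")
                ).sum()
            )
            rows.append(
                {
                    "entity_id": entity_id,
                    "status": r.status,
                    "mse_initial": r.mse_initial,
                    "mse_refined": r.mse_refined,
                    "genes_retained": r.genes_retained,
                    "detected_before": r.detected_before,
                    "detected_after": r.detected_after,
                    "mean_threshold": r.best_mean_threshold,
                    "pct95_threshold": r.best_percentile_threshold,
                    "qc_rejected": n_rej,
                }
            )
        return pd.DataFrame(rows).set_index("entity_id")

    def summary(self) -> str:
        frame = self.summary_frame()
        lines = [
            "Signature gene refinement summary",
            "=" * 72,
            f"entities: {len(self.refinements)}  "
            f"(refined: {sum(r.status == 'refined' for r in self.refinements.values())}, "
            f"unchanged: {sum(r.status == 'unchanged' for r in self.refinements.values())}, "
            f"skipped: {sum(r.status.startswith('skipped') for r in self.refinements.values())})",
            f"samples: {self.model.norm_counts.shape[1]}",
            "-" * 72,
            frame.to_string(float_format=lambda v: f"{v:.3f}"),
        ]
        return "\n".join(lines)

    def collapse(self, gene_labels: Mapping[str, str]) -> pd.DataFrame:
        """Collapse entities sharing a taxonomic label (modal label over
        each refined SG set) and return the collapsed abundance matrix."""
        labels = entity_labels_from_genes(
            {e: s.genes for e, s in self.refined_sets.items()}, gene_labels
        )
        return collapse_entities(self.abundance, labels)

    def iteration_log(self) -> pd.DataFrame:
        frames = [r.log_frame() for r in self.refinements.values() if r.log]
        if not frames:
            return pd.DataFrame(
                columns=["entity_id", "mode", "threshold", "iteration", "mse_before",
                         "mse_after", "accepted", "n_removed", "n_added", "n_detected",
                         "reason"]
            )
        return pd.concat(frames, ignore_index=True)

    def plot_detection(self, entity_id: str, refined: bool = True, ax=None):
        """Observed unique-gene counts d_j against reads k_j for one entity,
        with the expected-detection curve overlaid."""
        import matplotlib.pyplot as plt

        sg = (self.refined_sets if refined else self.initial_sets)[entity_id]
        cfg = self.model.config.refinement
        det = detected_samples(sg.genes, self.model.entity_counts(entity_id),
                               cfg.min_detected_genes)
        if ax is None:
            _, ax = plt.subplots()
        k = det["k"].to_numpy()
        ax.scatter(k, det["d"], s=12, alpha=0.7, label="samples")
        grid = np.linspace(0, max(k.max(), 1), 200)
        ax.plot(grid, expected_unique(grid, cfg.n_eval), color="k",
                label=f"expected (n={cfg.n_eval})")
        ax.set_xlabel("reads on SG set (k)")
        ax.set_ylabel("unique SGs detected (d)")
        ax.set_title(f"{entity_id} ({'refined' if refined else 'initial'} SGs)")
        ax.legend()
        return ax

    def to_dir(self, out_dir) -> None:
        """Write the standard output files under ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sgio.write_sg_sets(self.refined_sets, out / "refined_sg")
        sgio.write_sg_sets(self.initial_sets, out / "initial_sg")
        self.summary_frame().to_csv(out / "refinement_summary.tsv", sep="\t")
        self.iteration_log().to_csv(out / "iteration_log.tsv", sep="\t", index=False)
        self.qc.to_csv(out / "sample_qc.tsv", sep="\t", index=False)
        self.abundance.to_csv(out / "relative_abundance.tsv", sep="\t")
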