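import numpy as np
import pandas as pd
import pytest

import sgabund as sg
from sgabund import refine
from sgabund.ccp import expected_unique
from sgabund.prep import (
    SignatureGeneSet,
    coabundance_scores,
    initial_sg_set,
    length_normalize,
    replacement_pool,
)


def _entity_norm(catalog, entity_id):
    genes = catalog.gene_entities.index[catalog.gene_entities == entity_id]
    return length_normalize(catalog.raw_counts.loc[genes], catalog.gene_lengths)


@pytest.fixture(scope="module")
def refined_entity(small_catalog):
    """One planted entity refined end to end (shared across tests)."""
    ent = small_catalog.entity_ids[0]
    norm = _entity_norm(small_catalog, ent)
    initial = initial_sg_set(ent, norm, n_genes=100)
    pool = replacement_pool(norm)
    scores = coabundance_scores(norm)
    result = refine.refine_entity(initial, pool, norm, coabundance=scores)
    return small_catalog, ent, norm, initial, pool, scores, result


class TestMse:
    def _set_with(self, k, d, n_genes=100):
        """One sample hitting exactly d of n_genes SGs with k total counts."""
        counts = np.zeros(n_genes, dtype=int)
        counts[: d - 1] = 1
        counts[d - 1] = k - (d - 1)
        return pd.DataFrame({"s1": counts}, index=[f"g{i:03d}" for i in range(n_genes)])

    def test_definition(self):
        df = self._set_with(k=200, d=80)
        expect = expected_unique(200, 100)
        assert refine.sg_mse(df.index, df) == pytest.approx((80 - expect) ** 2)

    def test_mean_over_samples(self):
        a = self._set_with(k=200, d=80)
        b = self._set_with(k=300, d=90)
        df = pd.concat([a, b.rename(columns={"s1": "s2"})], axis=1)
        e1 = (80 - expected_unique(200, 100)) ** 2
        e2 = (90 - expected_unique(300, 100)) ** 2
        assert refine.sg_mse(df.index, df) == pytest.approx((e1 + e2) / 2)

    def test_no_detected_samples_is_an_error(self):
        df = pd.DataFrame({"s1": [0] * 100}, index=[f"g{i}" for i in range(100)])
        with pytest.raises(refine.NoDetectedSamplesError):
            refine.sg_mse(df.index, df)

    def test_planted_bias_raises_mse(self, small_catalog, null_catalog):
        """A planted catalog's initial sets sit farther from the detection
        curve than a clean catalog's."""
        planted = _entity_norm(small_catalog, small_catalog.entity_ids[0])
        clean = _entity_norm(null_catalog, null_catalog.entity_ids[0])
        sg_planted = initial_sg_set("p", planted, 100)
        sg_clean = initial_sg_set("c", clean, 100)
        assert refine.sg_mse(sg_planted.genes, planted) > refine.sg_mse(
            sg_clean.genes, clean
        )


class TestRefineStep:
    def test_no_gene_beyond_threshold(self, refined_entity):
        _, ent, norm, initial, pool, scores, _ = refined_entity
        genes, record = refine.refine_step(
            initial.genes, pool, norm, threshold=100, mode="mean",
            coabundance=scores, config=refine.RefinementConfig(),
        )
        assert genes == initial.genes
        assert not record.accepted
        assert record.reason == "no gene beyond threshold"

    def test_pool_exhaustion_keeps_original(self, refined_entity):
        _, ent, norm, initial, _, scores, _ = refined_entity
        genes, record = refine.refine_step(
            initial.genes, (), norm, threshold=50, mode="mean",
            coabundance=scores, config=refine.RefinementConfig(),
        )
        assert genes == initial.genes
        assert not record.accepted
        assert "pool exhausted" in record.reason

    def test_planted_genes_acquire_high_ranks(self, refined_entity):
        from sgabund.nb import aggregate_ranks, rank_matrix
        from sgabund.prep import detected_samples

        catalog, ent, norm, initial, _, _, _ = refined_entity
        det = detected_samples(initial.genes, norm)
        ranks, _ = rank_matrix(norm.loc[list(initial.genes)], sample_ids=det.index)
        agg = aggregate_ranks(ranks, "mean")
        planted = catalog.planted_genes(ent) & set(initial.genes)
        core = set(initial.genes) - planted
        assert agg[list(planted)].mean() > agg[list(core)].mean() + 10


class TestRefineEntity:
    def test_planted_catalog_improves(self, refined_entity):
        catalog, ent, _, initial, _, _, result = refined_entity
        assert result.status == "refined"
        assert result.mse_refined < result.mse_initial
        planted_in_initial = catalog.planted_genes(ent) & set(initial.genes)
        removed = planted_in_initial - set(result.refined_set.genes)
        assert len(removed) / len(planted_in_initial) > 0.5

    def test_refined_mse_never_exceeds_initial(self, refined_entity):
        *_, result = refined_entity
        assert result.mse_refined <= result.mse_initial

    def test_set_size_preserved(self, refined_entity):
        *_, result = refined_entity
        assert len(result.refined_set) == 100

    def test_replacement_provenance(self, refined_entity):
        """Every refined gene is from the initial set or the pool."""
        _, _, _, initial, pool, _, result = refined_entity
        allowed = set(initial.genes) | set(pool)
        assert set(result.refined_set.genes) <= allowed
        for g in result.refined_set.genes:
            expected = "initial" if g in set(initial.genes) else "replacement"
            assert result.refined_set.origin[g] == expected

    def test_accepted_mse_strictly_decreasing_within_runs(self, refined_entity):
        *_, result = refined_entity
        runs = {}
        for rec in result.log:
            if rec.accepted:
                runs.setdefault((rec.mode, rec.threshold), []).append(rec.mse_after)
        assert runs  # something was accepted
        for seq in runs.values():
            assert all(a > b for a, b in zip(seq, seq[1:])) or len(seq) == 1

    def test_deterministic(self, refined_entity):
        _, ent, norm, initial, pool, scores, result = refined_entity
        again = refine.refine_entity(initial, pool, norm, coabundance=scores)
        assert again.refined_set.genes == result.refined_set.genes
        assert again.mse_refined == result.mse_refined

    def test_null_catalog_refinement_is_harmless(self, null_catalog):
        """With no planted pathology the MSE gate still admits swaps that
        chase sampling noise, but they must not hurt abundance accuracy:
        initial and refined estimates both stay close to the truth."""
        from sgabund.model import SignatureGeneModel
        from sgabund.simulate import truth_error

        m = SignatureGeneModel(
            null_catalog.raw_counts, null_catalog.gene_entities, null_catalog.gene_lengths
        )
        refined = m.fit()
        initial = m.fit(refine=False)
        e0 = truth_error(initial.abundance, null_catalog.truth).overall_mean
        e1 = truth_error(refined.abundance, null_catalog.truth).overall_mean
        assert e0 < 0.02 and e1 < 0.02
        assert e1 - e0 < 0.005
        for res in refined.refinements.values():
            assert res.mse_refined <= res.mse_initial

    def test_too_few_detected_samples_skips(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            0, index=[f"g{i:03d}" for i in range(120)], columns=[f"s{j}" for j in range(5)]
        )
        counts.iloc[:50, 0] = rng.poisson(5, 50)  # detected in one sample only
        initial = SignatureGeneSet("e", tuple(counts.index[:100]))
        result = refine.refine_entity(initial, list(counts.index), counts)
        assert result.status == "skipped-too-few-samples"


class TestConfig:
    def test_threshold_bounds_validated(self):
        with pytest.raises(ValueError):
            refine.RefinementConfig(mean_thresholds=(0,))
        with pytest.raises(ValueError):
            refine.RefinementConfig(n_test=120)

    def test_defaults_match_method(self):
        cfg = refine.RefinementConfig()
        assert cfg.n_genes == 100
        assert cfg.n_eval == 100
        assert cfg.n_test == 95
        assert cfg.mean_thresholds == tuple(range(35, 61))
        assert cfg.percentile_thresholds == tuple(range(90, 99))
        assert cfg.min_samples == 10
        assert cfg.mse_rel_tol == 0.01
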