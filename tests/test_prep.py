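import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sgabund import prep


def _counts(data, samples=None):
    df = pd.DataFrame(data).T
    df.index.name = "gene_id"
    if samples:
        df.columns = samples
    return df


class TestLengthNormalize:
    def test_scaling_and_rounding(self):
        raw = _counts({"a": [50, 0, 1], "b": [1, 0, 0]})
        lengths = pd.Series({"a": 1000, "b": 3000})
        norm = prep.length_normalize(raw, lengths)
        assert norm.loc["a"].tolist() == [50, 0, 1]
        # 1000 * 1/3000 = 0.333 rounds to 0: normalization can erase singletons
        assert norm.loc["b"].tolist() == [0, 0, 0]

    def test_half_away_from_zero(self):
        raw = _counts({"a": [1, 3]})
        lengths = pd.Series({"a": 2000})
        # 0.5 -> 1 and 1.5 -> 2 (banker's rounding would give 0 and 2)
        assert prep.length_normalize(raw, lengths).loc["a"].tolist() == [1, 2]

    def test_missing_length_names_gene(self):
        raw = _counts({"a": [1], "b": [1]})
        with pytest.raises(KeyError, match="b"):
            prep.length_normalize(raw, pd.Series({"a": 100}))

    def test_nonpositive_length_rejected(self):
        raw = _counts({"a": [1]})
        with pytest.raises(ValueError, match="a"):
            prep.length_normalize(raw, pd.Series({"a": 0}))

    @given(st.lists(st.integers(0, 1000), min_size=2, max_size=6), st.integers(100, 5000))
    def test_homogeneous_before_rounding(self, counts, length):
        raw = _counts({"g": counts})
        lengths = pd.Series({"g": length})
        single = 1000.0 * np.array(counts) / length
        doubled = 1000.0 * 2 * np.array(counts) / length
        assert np.allclose(2 * single, doubled)
        # and the rounded values differ by at most the rounding step
        n1 = prep.length_normalize(raw, lengths).loc["g"].to_numpy()
        n2 = prep.length_normalize(2 * raw, lengths).loc["g"].to_numpy()
        assert np.all(np.abs(n2 - 2 * n1) <= 1)


class TestMedianAndScores:
    def test_median_profile(self):
        counts = _counts({"a": [0, 1], "b": [5, 2], "c": [10, 3]})
        assert prep.median_profile(counts).tolist() == [5.0, 2.0]

    def test_single_gene_is_its_own_median(self):
        counts = _counts({"a": [3, 1, 4]})
        assert prep.median_profile(counts).tolist() == [3.0, 1.0, 4.0]

    def test_zero_variance_gene_scores_neg_inf(self):
        counts = _counts({"a": [1, 2, 3], "b": [2, 4, 6], "c": [5, 5, 5]})
        scores = prep.coabundance_scores(counts)
        # a and b are proportional, hence equally correlated with the median
        assert scores["a"] == pytest.approx(scores["b"])
        assert scores["a"] > 0.9
        assert scores["c"] == -np.inf

    def test_all_zero_entity(self):
        counts = _counts({"a": [0, 0], "b": [0, 0]})
        assert prep.median_profile(counts).tolist() == [0.0, 0.0]
        assert (prep.coabundance_scores(counts) == -np.inf).all()


class TestInitialSet:
    def test_ordering(self):
        # a tracks the median exactly, b is anti-proportional, c is noise
        counts = _counts(
            {
                "a": [1, 5, 10, 2],
                "b": [10, 6, 1, 9],
                "c": [3, 3, 4, 3],
                "d": [1, 5, 10, 2],
            }
        )
        sg = prep.initial_sg_set("e", counts, n_genes=3)
        assert list(sg.genes)[:2] == ["a", "d"]  # tie broken lexicographically
        assert "b" not in sg.genes

    def test_too_small_entity(self):
        counts = _counts({"a": [1, 2], "b": [2, 3]})
        with pytest.raises(prep.EntityTooSmallError):
            prep.initial_sg_set("e", counts, n_genes=3)

    def test_invariant_to_orderings(self, small_catalog):
        ent = small_catalog.entity_ids[0]
        genes = small_catalog.gene_entities.index[small_catalog.gene_entities == ent]
        from sgabund.prep import length_normalize

        norm = length_normalize(
            small_catalog.raw_counts.loc[genes], small_catalog.gene_lengths
        )
        base = prep.initial_sg_set(ent, norm, n_genes=50)
        rng = np.random.default_rng(0)
        shuffled = norm.iloc[rng.permutation(norm.shape[0]), rng.permutation(norm.shape[1])]
        assert prep.initial_sg_set(ent, shuffled, n_genes=50).genes == base.genes

    def test_zero_variance_gene_never_enters_when_enough_good_genes(self):
        data = {f"g{i:02d}": [i, 2 * i, 3 * i, 4 * i] for i in range(1, 6)}
        data["flat"] = [7, 7, 7, 7]
        sg = prep.initial_sg_set("e", _counts(data), n_genes=5)
        assert "flat" not in sg.genes


class TestReplacementPool:
    def test_small_entity_uses_all_genes(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(
            rng.integers(0, 5, size=(30, 10)),
            index=[f"g{i:02d}" for i in range(30)],
        )
        pool = prep.replacement_pool(counts, pool_size=700)
        freq = (counts > 0).mean(axis=1)
        q1, q3 = freq.quantile([0.25, 0.75])
        lo, hi = q1 - 1.2 * (q3 - q1), q3 + 1.2 * (q3 - q1)
        expected = ((freq >= lo) & (freq <= hi)).sum()
        assert len(pool) == expected

    def test_high_frequency_outlier_excluded(self):
        # 20 genes detected in 2/10 samples; one gene detected everywhere
        data = {f"g{i:02d}": [1, 1] + [0] * 8 for i in range(20)}
        data["hot"] = [1] * 10
        pool = prep.replacement_pool(_counts(data), pool_size=700)
        assert "hot" not in pool
        assert len(pool) == 20

    def test_identical_frequencies_no_exclusion(self):
        data = {f"g{i}": [1, 0, 1, 0] for i in range(5)}
        pool = prep.replacement_pool(_counts(data), pool_size=3)
        assert len(pool) == 3  # IQR 0 but all freqs inside the fence


class TestDetection:
    def test_three_gene_boundary(self):
        counts = _counts(
            {"a": [1, 9, 0], "b": [1, 9, 0], "c": [1, 0, 0], "d": [0, 0, 0]},
            samples=["s1", "s2", "s3"],
        )
        det = prep.detected_samples(["a", "b", "c", "d"], counts)
        # s1 hits exactly 3 genes -> detected; s2 has many reads on only
        # 2 genes -> not detected; s3 is all-zero -> not detected
        assert list(det.index) == ["s1"]
        assert det.loc["s1", "k"] == 3
        assert det.loc["s1", "d"] == 3

    def test_stats_totals(self, toy_counts):
        stats = prep.sample_stats(["g1", "g2", "g3"], toy_counts)
        assert stats.loc["s1", "k"] == 30
        assert stats.loc["s1", "d"] == 3
        assert bool(stats.loc["s1", "detected"])
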