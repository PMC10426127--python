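"""Association analyses: BH, Spearman invariances, motif space, co-occurrence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scregmotif.data_io import SequenceSet
from scregmotif.downstream import (
    bh_adjust,
    co_occurrence_sets,
    correlate_with_covariate,
    family_activation,
    gene_set_correlation,
    motif_space,
    signature_score,
    tf_correlation,
)


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Textbook step-up: q_(i) = min over j >= i of p_(j) * m / j, capped at 1."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q[order[rank - 1]] = running
    return q


class TestBH:
    def test_hand_worked_example(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = rng.random(rng.integers(1, 40))
            assert np.allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)


class TestSpearmanInvariance:
    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_monotone_transform_invariance(self, seed):
        from scipy import stats

        rng = np.random.default_rng(seed)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        base = stats.spearmanr(x, y)[0]
        assert stats.spearmanr(np.exp(x), y)[0] == pytest.approx(base)
        assert stats.spearmanr(x, 3 * y + 7)[0] == pytest.approx(base)
        assert stats.spearmanr(x ** 3, y)[0] == pytest.approx(base)


class TestTfCorrelation:
    def _inputs(self, tf_values):
        pools = [f"pool_{j}" for j in range(6)]
        influence = pd.DataFrame([[1.0, 2, 3, 4, 5, 6]], index=["FAM"], columns=pools)
        expression = pd.DataFrame([tf_values], index=["TF1"], columns=pools)
        clusters = pd.DataFrame({"id": ["TF1"], "cluster": ["FAM"]})
        return influence, expression, clusters

    def test_monotone_transform_gives_rho_one(self):
        influence, expression, clusters = self._inputs(np.exp([1.0, 2, 3, 4, 5, 6]))
        table = tf_correlation(influence, expression, clusters)
        assert table["rho"].iloc[0] == pytest.approx(1.0)

    def test_anti_monotone_gives_rho_minus_one(self):
        influence, expression, clusters = self._inputs([6.0, 5, 4, 3, 2, 1])
        table = tf_correlation(influence, expression, clusters)
        assert table["rho"].iloc[0] == pytest.approx(-1.0)

    def test_constant_expression_reported_missing(self, caplog):
        influence, expression, clusters = self._inputs([2.0] * 6)
        table = tf_correlation(influence, expression, clusters)
        assert np.isnan(table["rho"].iloc[0])
        assert "undefined" in caplog.text

    def test_bh_applied_across_pairs(self):
        pools = [f"pool_{j}" for j in range(8)]
        rng = np.random.default_rng(0)
        influence = pd.DataFrame(rng.normal(size=(2, 8)), index=["F1", "F2"], columns=pools)
        expression = pd.DataFrame(rng.normal(size=(3, 8)), index=["A", "B", "C"], columns=pools)
        clusters = pd.DataFrame({"id": ["A", "B", "C"], "cluster": ["F1", "F1", "F2"]})
        table = tf_correlation(influence, expression, clusters)
        assert np.allclose(np.sort(table["q"]), np.sort(bh_adjust(table["p"].to_numpy())))


class TestGeneSetCorrelation:
    def test_fifty_gene_set_excluded(self):
        pools = [f"pool_{j}" for j in range(5)]
        genes = [f"g{i}" for i in range(60)]
        pooled = pd.DataFrame(np.random.default_rng(0).random((60, 5)),
                              index=genes, columns=pools)
        influence = pd.DataFrame([[1.0, 2, 3, 4, 5]], index=["FAM"], columns=pools)
        sets = {"too_big": genes[:50], "ok": genes[:10]}
        corr, _ = gene_set_correlation(pooled, sets, influence)
        assert list(corr.index) == ["ok"]

    def test_planted_program_correlates_perfectly(self):
        pools = [f"pool_{j}" for j in range(8)]
        influence_row = np.array([1.0, 3, 2, 5, 4, 7, 6, 8])
        # each member gene's expression is a monotone transform of the influence
        pooled = pd.DataFrame(np.vstack([np.exp(influence_row)] * 5 +
                                        [np.random.default_rng(1).random(8)]),
                              index=[f"g{i}" for i in range(6)], columns=pools)
        influence = pd.DataFrame([influence_row], index=["FAM"], columns=pools)
        corr, groups = gene_set_correlation(pooled, {"program": [f"g{i}" for i in range(5)]},
                                            influence)
        assert corr.loc["program", "FAM"] == pytest.approx(1.0)

    def test_fewer_than_top_n_sets_all_kept(self):
        pools = [f"pool_{j}" for j in range(5)]
        pooled = pd.DataFrame(np.random.default_rng(2).random((20, 5)),
                              index=[f"g{i}" for i in range(20)], columns=pools)
        influence = pd.DataFrame(np.random.default_rng(3).random((2, 5)),
                                 index=["F1", "F2"], columns=pools)
        sets = {f"set{k}": [f"g{3 * k}", f"g{3 * k + 1}"] for k in range(6)}
        corr, groups = gene_set_correlation(pooled, sets, influence, top_n=500)
        assert len(corr) == 6
        assert set(groups.unique()) <= {1, 2, 3}

    def test_set_without_matching_genes_skipped(self, caplog):
        pools = [f"pool_{j}" for j in range(4)]
        pooled = pd.DataFrame(np.ones((2, 4)), index=["g0", "g1"], columns=pools)
        influence = pd.DataFrame(np.ones((1, 4)), index=["F"], columns=pools)
        corr, _ = gene_set_correlation(pooled, {"ghost": ["nope"]}, influence)
        assert corr.empty
        assert "no matching genes" in caplog.text


class TestMotifSpace:
    def test_column_count_and_order(self, flagship):
        ckpts = flagship["ensemble"].checkpoints
        seqs = flagship["dataset"].sequences.subset(np.arange(40))
        space = motif_space(ckpts, seqs)
        d = ckpts[0].params.d
        assert space.shape == (40, len(ckpts) * d)
        assert list(space.columns[:2]) == ["0_0", "0_1"]
        assert space.columns[d] == "1_0"  # run-major ordering

    def test_single_model_equals_forward_activations(self, flagship):
        from scregmotif.network import conv_activations

        ckpt = flagship["ensemble"].checkpoints[0]
        seqs = flagship["dataset"].sequences.subset(np.arange(25))
        space = motif_space([ckpt], seqs)
        assert np.allclose(space.to_numpy(), conv_activations(ckpt.params, seqs.onehot))

    def test_zero_filter_gives_zero_column(self):
        from scregmotif.network import Checkpoint, ModelConfig, ModelParams

        params = ModelParams(np.zeros((2, 4, 4)), np.ones((2, 1)), np.zeros(1))
        ckpt = Checkpoint(params=params, config=ModelConfig(d=2, m=4, p=1, L=20),
                          train_ids=np.arange(3), val_ids=np.arange(3),
                          test_ids=np.arange(3), best_val_mse=0.0)
        seqs = SequenceSet.from_sequences(
            ["a", "b", "c"], ["ACGTACGTACGTACGTACGT"] * 3)
        space = motif_space([ckpt], seqs)
        assert np.allclose(space["0_0"], 0.0)


class TestCoOccurrence:
    def test_threshold_is_three_quarters_of_max(self):
        scores = pd.DataFrame({"FAM": [1.0, 2.0, 4.0]}, index=["g0", "g1", "g2"])
        sets, inter = co_occurrence_sets(scores)
        assert sets["FAM"] == {"g2"}
        assert inter.loc["FAM", "FAM"] == 1

    def test_identical_vectors_identical_sets(self):
        scores = pd.DataFrame({"A": [1.0, 5.0, 4.5], "B": [1.0, 5.0, 4.5]},
                              index=["g0", "g1", "g2"])
        sets, inter = co_occurrence_sets(scores)
        assert sets["A"] == sets["B"] == {"g1", "g2"}
        assert inter.loc["A", "B"] == 2

    def test_non_positive_family_empty_with_warning(self, caplog):
        scores = pd.DataFrame({"DEAD": [-1.0, -2.0, 0.0]}, index=["g0", "g1", "g2"])
        sets, _ = co_occurrence_sets(scores)
        assert sets["DEAD"] == set()
        assert "no positive" in caplog.text

    def test_disjoint_planted_programs_give_disjoint_sets(self):
        rng = np.random.default_rng(0)
        base = rng.random(100) * 0.1
        a = base.copy()
        b = base.copy()
        a[:10] += 5.0   # program A genes
        b[50:60] += 5.0  # program B genes
        scores = pd.DataFrame({"A": a, "B": b}, index=[f"g{i}" for i in range(100)])
        sets, _ = co_occurrence_sets(scores)
        jaccard = len(sets["A"] & sets["B"]) / max(len(sets["A"] | sets["B"]), 1)
        assert jaccard < 0.2


class TestSignatureScore:
    def _pooled(self):
        pools = [f"pool_{j}" for j in range(4)]
        return pd.DataFrame([[1.0, 2, 3, 4], [2.0, 2, 2, 2], [0.0, 1, 0, 1]],
                            index=["MKI67", "PLK1", "other"], columns=pools)

    def test_single_gene_list_is_that_row(self):
        score = signature_score(self._pooled(), ["MKI67"])
        assert np.allclose(score, [1, 2, 3, 4])

    def test_constant_genes_give_constant_score(self):
        score = signature_score(self._pooled(), ["PLK1"])
        assert np.allclose(score, 2.0)

    def test_absent_genes_error(self):
        with pytest.raises(ValueError, match="none"):
            signature_score(self._pooled(), ["GHOST"])

    def test_correlation_with_influence_row(self):
        score = signature_score(self._pooled(), ["MKI67"])
        influence_row = pd.Series([2.0, 4, 6, 8], index=score.index)
        rho, p = correlate_with_covariate(influence_row, score)
        assert rho == pytest.approx(1.0)


def test_family_activation_sums_member_columns(flagship):
    seqs = flagship["dataset"].sequences.subset(np.arange(30))
    space = motif_space(flagship["ensemble"].checkpoints, seqs)
    fam = family_activation(space, flagship["assignment"])
    assignment = flagship["assignment"]
    for cluster in fam.columns:
        members = assignment.index[(assignment["cluster"] == cluster)
                                   & assignment["retained"]]
        assert np.allclose(fam[cluster], space[list(members)].sum(axis=1))
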