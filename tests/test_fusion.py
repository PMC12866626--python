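"""Rocchio interpolation, weighted RRF, and the All-in-One combinations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grflink import (
    Feedback,
    FeedbackTask,
    QueryVector,
    Ranking,
    ValidationError,
    aggregate_synonym_vectors,
    all_in_one_rank,
    all_in_one_vector,
    fuse_ranks,
    fuse_text,
    fuse_vector,
)


def _qv(*values):
    return QueryVector(values=np.array(values, dtype=float))


def _feedback(*texts, kind="definition", n=10):
    task = FeedbackTask(kind=kind, n=n) if kind == "n_synonyms" else FeedbackTask(kind=kind)
    return Feedback(task=task, texts=tuple(texts), provider_id="mock", mention_id="m1")


def _ranking(*cuis, source="mention"):
    n = len(cuis)
    return Ranking(
        items=[(c, f"{c} surface", float(n - i)) for i, c in enumerate(cuis)],
        query_source=source,
    )


class TestTextFusion:
    def test_mention_then_feedback_with_separator(self):
        fb = _feedback("a skeletal disorder of early infancy")
        assert fuse_text("AO1", fb, separator=" [SEP] ") == (
            "AO1 [SEP] a skeletal disorder of early infancy"
        )

    def test_synonyms_joined_in_generation_order(self):
        fb = _feedback(*[f"syn{i}" for i in range(10)], kind="n_synonyms")
        fused = fuse_text("m", fb)
        assert fused == "m " + " ".join(f"syn{i}" for i in range(10))

    def test_blank_feedback_returns_mention_with_warning(self):
        fb = _feedback("placeholder")
        object.__setattr__(fb, "texts", ("  ",))  # simulate degenerate content
        with pytest.warns(UserWarning):
            assert fuse_text("AO1", fb) == "AO1"


class TestVectorFusion:
    def test_alpha_one_is_collinear_with_mention(self):
        q = fuse_vector(_qv(3.0, 4.0), _qv(0.0, 1.0), alpha=1.0)
        assert np.allclose(q.values, [0.6, 0.8], atol=1e-12)

    def test_alpha_zero_is_collinear_with_feedback(self):
        q = fuse_vector(_qv(1.0, 0.0), _qv(0.0, 2.0), alpha=0.0)
        assert np.allclose(q.values, [0.0, 1.0], atol=1e-12)

    def test_half_alpha_arithmetic_pre_normalization(self):
        q = fuse_vector(_qv(1.0, 0.0), _qv(0.0, 1.0), alpha=0.5, normalize=False)
        assert np.array_equal(q.values, [0.5, 0.5])
        assert q.source == "fused"

    def test_dim_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            fuse_vector(_qv(1.0, 0.0), _qv(1.0, 0.0, 0.0), alpha=0.5)

    @pytest.mark.parametrize("alpha", [-0.1, 1.5])
    def test_alpha_out_of_range_rejected(self, alpha):
        with pytest.raises(ValidationError):
            fuse_vector(_qv(1.0), _qv(1.0), alpha=alpha)

    @settings(deadline=None, max_examples=50)
    @given(
        alpha=st.floats(0.0, 1.0),
        values=st.lists(st.floats(-5, 5), min_size=3, max_size=3),
    )
    def test_self_fusion_is_collinear(self, alpha, values):
        if not any(values):
            values = [1.0, 0.0, 0.0]
        q = _qv(*values)
        fused = fuse_vector(q, q, alpha=alpha, normalize=False)
        assert np.allclose(fused.values, alpha * q.values + (1 - alpha) * q.values)
        cross = np.cross(fused.values, q.values)
        assert np.allclose(cross, 0.0, atol=1e-9)


class TestSynonymAggregation:
    def test_single_vector_identity(self):
        v = _qv(0.6, 0.8)
        assert np.allclose(aggregate_synonym_vectors([v]).values, v.values)

    def test_mean_arithmetic(self):
        out = aggregate_synonym_vectors([_qv(1.0, 0.0), _qv(0.0, 1.0)], normalize=False)
        assert np.array_equal(out.values, [0.5, 0.5])

    def test_mean_of_copies_is_idempotent(self):
        v = _qv(0.6, 0.8)
        out = aggregate_synonym_vectors([v] * 5, normalize=False)
        assert np.allclose(out.values, v.values)

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_synonym_vectors([])


def _rrf_oracle(r0, rf, alpha):
    """Brute-force enumeration of the weighted RRF scores."""
    scores = {}
    for c in set(r0.cuis) | set(rf.cuis):
        s = 0.0
        if r0.rank_of(c):
            s += alpha / r0.rank_of(c)
        if rf.rank_of(c):
            s += (1 - alpha) / rf.rank_of(c)
        scores[c] = s
    return sorted(scores, key=lambda c: (-scores[c], c)), scores


class TestRankFusion:
    def test_worked_example_rank1_rank2(self):
        r0 = _ranking("C:1", "C:2")
        rf = _ranking("C:3", "C:1")
        fused = fuse_ranks(r0, rf, alpha=0.5)
        scores = {c: s for c, _, s in fused.items}
        assert scores["C:1"] == pytest.approx(0.5 * 1 + 0.5 * 0.5)  # 0.75
        assert fused.items[0][0] == "C:1"

    def test_alpha_one_preserves_mention_order(self):
        r0 = _ranking("C:2", "C:1", "C:4")
        rf = _ranking("C:9", "C:8")
        fused = fuse_ranks(r0, rf, alpha=1.0)
        order = fused.cuis
        assert order[: len(r0)] == r0.cuis
        assert all(s == 0.0 for c, _, s in fused.items if c in ("C:9", "C:8"))

    def test_alpha_zero_preserves_feedback_order(self):
        r0 = _ranking("C:2", "C:1")
        rf = _ranking("C:9", "C:8", "C:7")
        assert fuse_ranks(r0, rf, alpha=0.0).cuis[: 3] == rf.cuis

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_enumeration_oracle_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        pool = [f"C:{i}" for i in range(10)]
        r0 = _ranking(*rng.permutation(pool)[: rng.integers(1, 9)])
        rf = _ranking(*rng.permutation(pool)[: rng.integers(1, 9)])
        alpha = float(rng.random())
        fused = fuse_ranks(r0, rf, alpha)
        expected_order, expected_scores = _rrf_oracle(r0, rf, alpha)
        assert fused.cuis == expected_order
        for c, _, s in fused.items:
            assert s == pytest.approx(expected_scores[c], abs=1e-12)

    def test_improving_a_rank_never_lowers_fused_score(self):
        r0 = _ranking("C:1", "C:2", "C:3")
        rf_worse = _ranking("C:9", "C:8", "C:2")
        rf_better = _ranking("C:2", "C:9", "C:8")
        worse = {c: s for c, _, s in fuse_ranks(r0, rf_worse, 0.5).items}
        better = {c: s for c, _, s in fuse_ranks(r0, rf_better, 0.5).items}
        assert better["C:2"] >= worse["C:2"]


class TestAllInOne:
    def test_single_feedback_equals_half_alpha_rocchio(self, embedder):
        [q0, qf] = [
            QueryVector(values=row)
            for row in embedder.encode(["conorenal syndrome", "Mainzer-Saldino disease"])
        ]
        via_mean = all_in_one_vector(q0, [qf])
        via_rocchio = fuse_vector(q0, qf, alpha=0.5)
        assert np.array_equal(via_mean.values, via_rocchio.values)  # bitwise

    def test_identical_feedback_vectors_return_mention(self):
        q0 = _qv(0.6, 0.8)
        out = all_in_one_vector(q0, [q0, q0, q0], normalize=False)
        assert np.allclose(out.values, q0.values)

    def test_two_feedback_vectors_equal_direct_mean(self):
        q0, f1, f2 = _qv(1.0, 0.0), _qv(0.0, 1.0), _qv(1.0, 1.0)
        out = all_in_one_vector(q0, [f1, f2], normalize=False)
        assert np.allclose(out.values, (q0.values + f1.values + f2.values) / 3)

    def test_empty_feedback_warns_and_returns_mention(self):
        q0 = _qv(1.0, 0.0)
        with pytest.warns(UserWarning):
            assert all_in_one_vector(q0, []) is q0

    def test_rank_all_in_one_sums_reciprocals(self):
        lists = [_ranking("C:1", "C:2"), _ranking("C:1", "C:3"), _ranking("C:4")]
        fused = all_in_one_rank(lists)
        scores = {c: s for c, _, s in fused.items}
        assert scores["C:1"] == pytest.approx(2.0)
        assert scores["C:2"] == pytest.approx(0.5)
        assert scores["C:4"] == pytest.approx(1.0)

    def test_identical_lists_keep_their_order(self):
        r = _ranking("C:3", "C:1", "C:2")
        assert all_in_one_rank([r, r, r]).cuis == r.cuis

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_on_random_instances(self, seed):
        rng = np.random.default_rng(100 + seed)
        pool = [f"C:{i}" for i in range(8)]
        lists = [
            _ranking(*rng.permutation(pool)[: rng.integers(1, 7)])
            for _ in range(rng.integers(2, 5))
        ]
        fused = all_in_one_rank(lists)
        expected = {}
        for c in {c for r in lists for c in r.cuis}:
            expected[c] = sum(1.0 / r.rank_of(c) for r in lists if r.rank_of(c))
        order = sorted(expected, key=lambda c: (-expected[c], c))
        assert fused.cuis == order
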