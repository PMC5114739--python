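import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from immunedecomp import (
    GeneSignature,
    SignatureCollection,
    SsgseaParams,
    enrichment_score,
    rank_transform,
    score_matrix,
)
from conftest import brute_force_es


class TestRankTransform:
    def test_monotone_column_gets_identity_ranks(self, small_expr):
        ranks = rank_transform(small_expr)
        assert list(ranks["A"]) == [5, 4, 3, 2, 1]

    def test_ties_get_average_rank(self):
        expr = pd.DataFrame({"s": [2.0, 2.0, 1.0]}, index=["a", "b", "c"])
        assert list(rank_transform(expr)["s"]) == [2.5, 2.5, 1.0]

    def test_strictly_increasing_transform_leaves_ranks_unchanged(self, small_expr):
        transformed = np.log1p(small_expr**3)
        pd.testing.assert_frame_equal(
            rank_transform(small_expr), rank_transform(transformed)
        )

    def test_single_gene_rejected(self):
        with pytest.raises(ValueError):
            rank_transform(pd.DataFrame({"s": [1.0]}, index=["g"]))


class TestEnrichmentScore:
    def test_hand_evaluated_running_sum(self, small_expr):
        # p=5, ranks 5..1, set {g1,g2}, alpha=0.25:
        # 5^.25/(5^.25+4^.25) + 1 + 2/3 + 1/3 + 0
        ranks = rank_transform(small_expr)["A"]
        es = enrichment_score(ranks, GeneSignature("t", ("g1", "g2")), alpha=0.25)
        expected = 5**0.25 / (5**0.25 + 4**0.25) + 1 + 2 / 3 + 1 / 3
        assert es == pytest.approx(expected, abs=1e-12)
        assert es == pytest.approx(2.5139, abs=5e-4)

    def test_top_set_scores_higher_than_bottom_set(self, small_expr):
        ranks = rank_transform(small_expr)["A"]
        top = enrichment_score(ranks, GeneSignature("t", ("g1", "g2")))
        bottom = enrichment_score(ranks, GeneSignature("b", ("g4", "g5")))
        assert top > bottom

    def test_alpha_zero_closed_form_p2(self):
        expr = pd.DataFrame({"s": [2.0, 1.0]}, index=["hi", "lo"])
        ranks = rank_transform(expr)["s"]
        assert enrichment_score(ranks, GeneSignature("t", ("hi",)), alpha=0.0) == 1.0

    def test_absent_genes_dropped_with_warning(self, small_expr):
        ranks = rank_transform(small_expr)["A"]
        with pytest.warns(UserWarning, match="absent"):
            es = enrichment_score(ranks, GeneSignature("t", ("g1", "NOPE")))
        assert es == enrichment_score(ranks, GeneSignature("t", ("g1",)))

    def test_empty_and_full_intersections_rejected(self, small_expr):
        ranks = rank_transform(small_expr)["A"]
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="no genes"):
                enrichment_score(ranks, GeneSignature("t", ("X", "Y")))
        with pytest.raises(ValueError, match="undefined"):
            enrichment_score(
                ranks, GeneSignature("t", ("g1", "g2", "g3", "g4", "g5"))
            )

    def test_matches_brute_force_oracle_exhaustively(self):
        """Closed-form engine == direct running sum on all small instances.

        Every matrix size p <= 8 (with and without ties), every gene subset
        of size 1..3, alpha in {0, 0.25, 1}.
        """
        rng = np.random.default_rng(42)
        for p in range(3, 9):
            genes = [f"g{i}" for i in range(p)]
            for tied in (False, True):
                values = rng.permutation(p).astype(float)
                if tied:
                    values[: p // 2] = values[p // 2]  # force a tie block
                expr = pd.DataFrame({"s": values}, index=genes)
                ranks = rank_transform(expr)["s"]
                rank_map = dict(zip(genes, ranks))
                for m in (1, 2, 3):
                    if m >= p:
                        continue
                    for subset in itertools.combinations(genes, m):
                        for alpha in (0.0, 0.25, 1.0):
                            es = enrichment_score(
                                ranks, GeneSignature("t", subset), alpha=alpha
                            )
                            oracle = brute_force_es(rank_map, subset, alpha)
                            assert es == pytest.approx(oracle, abs=1e-9), (
                                p, tied, subset, alpha
                            )

    @settings(derandomize=True, max_examples=60)
    @given(
        values=st.lists(
            st.floats(-50, 50, allow_nan=False), min_size=4, max_size=10
        ),
        alpha=st.sampled_from([0.0, 0.25, 0.75]),
    )
    def test_random_instances_match_oracle(self, values, alpha):
        genes = [f"g{i}" for i in range(len(values))]
        expr = pd.DataFrame({"s": values}, index=genes)
        ranks = rank_transform(expr)["s"]
        subset = tuple(genes[:2])
        es = enrichment_score(ranks, GeneSignature("t", subset), alpha=alpha)
        oracle = brute_force_es(dict(zip(genes, ranks)), subset, alpha)
        assert es == pytest.approx(oracle, abs=1e-9)


class TestScoreMatrix:
    def test_normalized_scores_span_unit_range(self, small_expr, tiny_collection):
        scores = score_matrix(small_expr, tiny_collection, SsgseaParams())
        span = float(scores.to_numpy().max() - scores.to_numpy().min())
        assert span == pytest.approx(1.0, abs=1e-12)

    def test_unnormalized_single_cell_equals_enrichment_score(self, small_expr):
        coll = SignatureCollection((GeneSignature("t", ("g1", "g2")),))
        scores = score_matrix(
            small_expr[["A"]], coll, SsgseaParams(normalize=False)
        )
        ranks = rank_transform(small_expr[["A"]])["A"]
        assert scores.loc["t", "A"] == pytest.approx(
            enrichment_score(ranks, coll["t"]), abs=1e-12
        )

    def test_sample_permutation_permutes_columns(self, small_expr, tiny_collection):
        scores = score_matrix(small_expr, tiny_collection)
        permuted = score_matrix(small_expr[["C", "A", "B"]], tiny_collection)
        pd.testing.assert_frame_equal(scores[["C", "A", "B"]], permuted)

    def test_monotone_per_sample_transform_invariance(self, small_expr, tiny_collection):
        scores = score_matrix(small_expr, tiny_collection)
        transformed = score_matrix(np.exp(small_expr / 2), tiny_collection)
        pd.testing.assert_frame_equal(scores, transformed)

    def test_min_genes_present_enforced(self, small_expr):
        coll = SignatureCollection((GeneSignature("t", ("g1", "MISSING")),))
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="min_genes_present"):
                score_matrix(small_expr, coll, SsgseaParams(min_genes_present=2))

    def test_error_names_offending_signature(self, small_expr):
        coll = SignatureCollection(
            (GeneSignature("all_genes", ("g1", "g2", "g3", "g4", "g5")),)
        )
        with pytest.raises(ValueError, match="all_genes"):
            score_matrix(small_expr, coll)

    def test_equal_size_random_signatures_have_equal_expected_score(self, rng):
        """Exchangeability: no signature of a given size is privileged."""
        p, n_draws = 40, 500
        genes = [f"g{i}" for i in range(p)]
        diffs = []
        sig_a = GeneSignature("a", tuple(genes[:4]))
        sig_b = GeneSignature("b", tuple(genes[-4:]))
        coll = SignatureCollection((sig_a, sig_b))
        for _ in range(n_draws):
            expr = pd.DataFrame({"s": rng.normal(size=p)}, index=genes)
            scores = score_matrix(expr, coll, SsgseaParams(normalize=False))
            diffs.append(scores.loc["a", "s"] - scores.loc["b", "s"])
        diffs = np.asarray(diffs)
        assert abs(diffs.mean()) < 3 * diffs.std() / np.sqrt(n_draws)


class TestExternalCrossCheck:
    def test_agrees_with_gseapy_ssgsea(self, rng):
        """Independent implementation check: raw ES matches gseapy exactly."""
        gseapy = pytest.importorskip("gseapy")
        genes = [f"g{i}" for i in range(300)]
        expr = pd.DataFrame(
            rng.lognormal(3, 1, (300, 8)),
            index=genes,
            columns=[f"s{i}" for i in range(8)],
        )
        sets = {"A": genes[:20], "B": genes[50:85]}
        result = gseapy.ssgsea(
            data=expr, gene_sets=sets, outdir=None,
            sample_norm_method="rank", min_size=1, threads=1, seed=0,
        )
        theirs = (
            result.res2d.pivot(index="Term", columns="Name", values="ES")
            .astype(float)
            .loc[list(sets), expr.columns]
        )
        coll = SignatureCollection(
            tuple(GeneSignature(k, tuple(v)) for k, v in sets.items())
        )
        mine = score_matrix(expr, coll, SsgseaParams(normalize=False))
        assert np.allclose(theirs.to_numpy(), mine.to_numpy(), atol=1e-9)


class TestParams:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SsgseaParams(alpha=-0.1)
        with pytest.raises(ValueError):
            SsgseaParams(min_genes_present=0)
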