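import numpy as np
import pandas as pd
import pytest

from oracles import es_oracle, signal2noise_oracle
from conftest import make_metadata
from channelscreen import enrichment_screen as es
from channelscreen import normalization as norm
from channelscreen.types import ExpressionMatrix, FamilyAnnotation, ValidationError


def series(d):
    return pd.Series(d, dtype=float)


class TestLog2FCScreen:
    def test_forced_arithmetic(self):
        out = es.log2fc_screen(series({"g": 8.0}), series({"g": 2.0}))
        assert out.loc["g", "log2fc"] == 2.0
        assert out.loc["g", "status"] == "tumor_enriched"

    def test_zero_denominator_excluded(self):
        out = es.log2fc_screen(series({"g": 5.0}), series({"g": 0.0}),
                               zero_policy="exclude_zero_denominator")
        assert out.loc["g", "status"] == "excluded_zero_denominator"
        assert np.isnan(out.loc["g", "log2fc"])

    def test_zero_numerator_under_pseudo_policy(self):
        out = es.log2fc_screen(series({"g": 0.0}), series({"g": 1.0}),
                               zero_policy="replace_with_pseudo")
        assert np.isclose(out.loc["g", "log2fc"], np.log2(0.01), atol=1e-12)
        assert out.loc["g", "status"] == "control_enriched"

    def test_policies_agree_on_positive_denominators(self):
        rng = np.random.default_rng(4)
        t = series({f"g{i}": v for i, v in enumerate(rng.lognormal(0, 2, 50))})
        c = series({f"g{i}": v for i, v in enumerate(rng.lognormal(0, 2, 50))})
        a = es.log2fc_screen(t, c, zero_policy="exclude_zero_denominator")
        b = es.log2fc_screen(t, c, zero_policy="replace_with_pseudo")
        pd.testing.assert_frame_equal(a, b)

    def test_negative_mean_rejected(self):
        with pytest.raises(ValidationError):
            es.log2fc_screen(series({"g": -1.0}), series({"g": 1.0}))

    def test_status_thresholds_are_inclusive(self):
        out = es.log2fc_screen(series({"up": 4.0, "down": 0.25, "flat": 1.0}),
                               series({"up": 1.0, "down": 1.0, "flat": 1.0}))
        assert out.loc["up", "status"] == "tumor_enriched"       # log2fc == +2
        assert out.loc["down", "status"] == "control_enriched"   # log2fc == -2
        assert out.loc["flat", "status"] == "unchanged"


def _class_matrix(tumor_cols, control_cols, genes):
    data = np.column_stack(tumor_cols + control_cols).astype(float)
    samples = [f"t{i}" for i in range(len(tumor_cols))] + [
        f"c{i}" for i in range(len(control_cols))
    ]
    m = ExpressionMatrix(pd.DataFrame(data, index=genes, columns=samples), "CPM")
    meta = make_metadata(samples, ["tumor"] * len(tumor_cols) + ["control"] * len(control_cols))
    return m, meta


class TestSignal2Noise:
    def test_equal_class_means_score_zero(self):
        m, meta = _class_matrix([[5.0], [5.0]], [[5.0], [5.0]], ["g"])
        ranked = es.signal2noise_rank(m, meta)
        assert ranked.scores["g"] == 0.0

    def test_label_swap_negates_scores_and_reverses_order(self, small_cohort):
        matrix, meta, _ = small_cohort
        flipped_table = meta.table.copy()
        flipped_table["group"] = flipped_table["group"].map(
            {"tumor": "control", "control": "tumor"}
        )
        flipped = type(meta)(flipped_table)
        cpm = norm.cpm(matrix)
        a = es.signal2noise_rank(cpm, meta)
        b = es.signal2noise_rank(cpm, flipped)
        assert np.allclose(a.scores.sort_index(), -b.scores.sort_index())
        nontrivial = a.scores[a.scores.abs() > 1e-9]
        assert list(nontrivial.index) == list(reversed(
            b.scores[b.scores.abs() > 1e-9].index))

    def test_matches_independent_formula_with_floored_sd(self):
        m, meta = _class_matrix([[3.0], [5.0]], [[1.0], [1.0]], ["g"])
        ranked = es.signal2noise_rank(m, meta)
        expected = signal2noise_oracle([3.0, 5.0], [1.0, 1.0])
        assert np.isclose(ranked.scores["g"], expected, atol=1e-12)

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(17)
        genes = [f"g{i}" for i in range(30)]
        t = [rng.lognormal(1, 1, 30) for _ in range(5)]
        c = [rng.lognormal(1, 1, 30) for _ in range(3)]
        m, meta = _class_matrix(t, c, genes)
        ranked = es.signal2noise_rank(m, meta)
        for i, g in enumerate(genes):
            expected = signal2noise_oracle([col[i] for col in t], [col[i] for col in c])
            assert np.isclose(ranked.scores[g], expected, atol=1e-12)

    def test_single_column_class_is_error(self):
        m, meta = _class_matrix([[1.0], [2.0]], [[3.0]], ["g"])
        with pytest.raises(ValidationError, match="2 columns"):
            es.signal2noise_rank(m, meta)


class TestEnrichmentScore:
    def _ranked(self, scores):
        order = sorted(scores, key=lambda g: (-scores[g], g))
        return es.RankedList(pd.Series({g: scores[g] for g in order}, dtype=float))

    def test_single_gene_set_at_rank_one(self):
        ranked = self._ranked({f"g{i}": 10.0 - i for i in range(10)})
        res = es.gsea_es(ranked, ["g0"])
        assert np.isclose(res.es, 1.0)
        assert res.leading_edge == ["g0"]

    def test_bottom_set_has_negative_es(self):
        ranked = self._ranked({f"g{i}": 10.0 - i for i in range(10)})
        res = es.gsea_es(ranked, ["g8", "g9"])
        assert res.es < 0
        assert set(res.leading_edge) <= {"g8", "g9"}

    def test_matches_walk_oracle_on_random_instances(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            n = int(rng.integers(10, 60))
            scores = {f"g{i}": float(rng.normal()) for i in range(n)}
            ranked = self._ranked(scores)
            k = int(rng.integers(1, n // 2 + 1))
            members = list(rng.choice(ranked.genes, size=k, replace=False))
            res = es.gsea_es(ranked, members)
            hit = [g in set(members) for g in ranked.genes]
            es_expected, walk = es_oracle(list(ranked.scores), hit)
            assert np.isclose(res.es, es_expected, atol=1e-12)
            assert np.allclose(res.running_sum, walk, atol=1e-12)

    def test_weight_zero_invariant_to_monotone_rescaling(self):
        rng = np.random.default_rng(14)
        scores = {f"g{i}": float(v) for i, v in enumerate(np.sort(rng.normal(0, 1, 30))[::-1])}
        ranked = self._ranked(scores)
        members = ["g2", "g7", "g20"]
        a = es.gsea_es(ranked, members, weight_p=0.0)
        rescaled = self._ranked({g: 3.0 * s + 17.0 for g, s in scores.items()})
        b = es.gsea_es(rescaled, members, weight_p=0.0)
        assert np.isclose(a.es, b.es, atol=1e-12)

    def test_empty_intersection_is_error(self):
        ranked = self._ranked({"g0": 1.0, "g1": 0.5})
        with pytest.raises(ValidationError, match="myset"):
            es.gsea_es(ranked, ["absent"], set_name="myset")

    def test_full_universe_set_is_error(self):
        ranked = self._ranked({"g0": 1.0, "g1": 0.5})
        with pytest.raises(ValidationError):
            es.gsea_es(ranked, ["g0", "g1"])


class TestPermutationP:
    def test_planted_top_set_hits_minimum_p(self, small_cohort):
        matrix, meta, truth = small_cohort
        cpm = norm.cpm(matrix, norm.tmm_factors(matrix))
        res = es.gsea_permutation_p(cpm, meta, truth.planted_gene_ids,
                                    n_perm=200, seed=1)
        # more extreme than every same-sign null: p at its attainable floor
        assert res.p_value == 1.0 / (1 + res.n_same_sign_null)
        assert res.nes > 1.0

    def test_fixed_seed_reproducible(self, small_cohort):
        matrix, meta, truth = small_cohort
        cpm = norm.cpm(matrix)
        a = es.gsea_permutation_p(cpm, meta, truth.planted_gene_ids, n_perm=150, seed=9)
        b = es.gsea_permutation_p(cpm, meta, truth.planted_gene_ids, n_perm=150, seed=9)
        assert a.p_value == b.p_value
        assert a.nes == b.nes

    def test_phenotype_scheme_runs_and_detects_planted_signal(self, small_cohort):
        matrix, meta, truth = small_cohort
        cpm = norm.cpm(matrix)
        res = es.gsea_permutation_p(cpm, meta, truth.planted_gene_ids,
                                    n_perm=100, scheme="phenotype", seed=2)
        assert res.p_value <= 0.05

    def test_too_few_permutations_rejected(self, small_cohort):
        matrix, meta, truth = small_cohort
        cpm = norm.cpm(matrix)
        with pytest.raises(ValidationError, match="n_perm"):
            es.gsea_permutation_p(cpm, meta, truth.planted_gene_ids, n_perm=50)


class TestSelection:
    def _ranked(self, n):
        return es.RankedList(pd.Series({f"g{i:03d}": float(n - i) for i in range(n)}))

    def test_all_pass_filter(self):
        ranked = self._ranked(20)
        cpm = pd.Series(10.0, index=ranked.genes)
        sel = es.select_candidates(ranked, cpm, top_k=5)
        assert sel.candidates == ranked.genes[:5]

    def test_infinite_cutoff_empties_selection_with_audit(self):
        ranked = self._ranked(10)
        cpm = pd.Series(10.0, index=ranked.genes)
        sel = es.select_candidates(ranked, cpm, top_k=4, cpm_min=np.inf)
        assert sel.candidates == []
        assert sel.dropped_low_cpm == ranked.genes[:4]
        assert sel.dropped_below_rank == ranked.genes[4:]

    def test_top_k_exceeding_list_is_error(self):
        ranked = self._ranked(5)
        with pytest.raises(ValidationError, match="top_k"):
            es.select_candidates(ranked, pd.Series(1.0, index=ranked.genes), top_k=6)

    def test_cpm_filter_drops_lowly_expressed(self):
        ranked = self._ranked(6)
        cpm = pd.Series([5.0, 0.5, 5.0, 0.5, 5.0, 5.0], index=ranked.genes)
        sel = es.select_candidates(ranked, cpm, top_k=4, cpm_min=1.0)
        assert sel.candidates == [ranked.genes[0], ranked.genes[2]]
        assert sel.dropped_low_cpm == [ranked.genes[1], ranked.genes[3]]


class TestFamilyEnrichment:
    def _fc(self, d, statuses=None):
        df = pd.DataFrame({"log2fc": pd.Series(d, dtype=float)})
        df["status"] = "unchanged" if statuses is None else pd.Series(statuses)
        return df

    def test_one_member_family_omitted(self):
        fams = FamilyAnnotation(pd.Series({"g1": "famA", "g2": "famB", "g3": "famB"}))
        fc = self._fc({"g1": 3.0, "g2": 1.0, "g3": 3.0})
        out = es.family_enrichment(fc, fams, pd.Series(2.0, index=["g1", "g2", "g3"]))
        assert list(out.index) == ["famB"]

    def test_forced_mean_and_proportion(self):
        fams = FamilyAnnotation(pd.Series({"g1": "f", "g2": "f"}))
        fc = self._fc({"g1": 1.0, "g2": 3.0})
        out = es.family_enrichment(fc, fams, pd.Series({"g1": 4.0, "g2": 6.0}))
        assert out.loc["f", "mean_log2fc"] == 2.0
        # fold 8 > 2 counts, fold 2 == 2 does not (strict cut)
        assert out.loc["f", "proportion_above_fold"] == 0.5
        assert out.loc["f", "mean_tumor_cpm"] == 5.0
        assert out.loc["f", "n_members_used"] == 2

    def test_fully_excluded_family_absent(self):
        fams = FamilyAnnotation(pd.Series({"g1": "f", "g2": "f"}))
        fc = pd.DataFrame(
            {"log2fc": [np.nan, np.nan],
             "status": ["excluded_zero_denominator"] * 2},
            index=["g1", "g2"],
        )
        out = es.family_enrichment(fc, fams, pd.Series({"g1": 1.0, "g2": 1.0}))
        assert len(out) == 0

    def test_unannotated_gene_warned_and_skipped(self, caplog):
        fams = FamilyAnnotation(pd.Series({"g1": "f", "g2": "f"}))
        fc = self._fc({"g1": 1.0, "g2": 2.0, "g3": 5.0})
        with caplog.at_level("WARNING"):
            out = es.family_enrichment(fc, fams, pd.Series(1.0, index=["g1", "g2", "g3"]))
        assert list(out.index) == ["f"]
        assert any("family annotation" in r.message for r in caplog.records)
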