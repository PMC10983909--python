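import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from chemoscreen import scoring
from chemoscreen.errors import ValidationError
from conftest import build_counts, residual_frame

SETTINGS = dict(derandomize=True, deadline=None, max_examples=50)


class TestNormalizeDepth:
    def test_direct_example(self, tiny_screen):
        cm = build_counts(
            {"t0": [2, 3, 5]},
            ["GA", "GA", "GB"],
            [("t0", "T0", None, 1, 1)],
        )
        norm = scoring.normalize_depth(cm)
        assert np.allclose(norm.values["t0"], [200000, 300000, 500000])

    def test_identical_columns_identical(self, tiny_screen):
        norm = scoring.normalize_depth(tiny_screen)
        assert np.allclose(norm.values.sum(axis=0), 1e6, rtol=1e-9)

    def test_zero_column_names_sample(self):
        cm = build_counts(
            {"t0": [1, 1, 1], "dead": [0, 0, 0]},
            ["GA", "GA", "GB"],
            [("t0", "T0", None, 1, 1), ("dead", "mock", None, 1, 1)],
        )
        with pytest.raises(ValidationError, match="dead"):
            scoring.normalize_depth(cm)

    @given(factor=st.integers(min_value=1, max_value=1000))
    @settings(**SETTINGS)
    def test_scale_invariant_to_column_multiplication(self, factor):
        cm = build_counts(
            {"t0": [10, 20, 30], "m": [5, 6, 7]},
            ["GA", "GA", "GB"],
            [("t0", "T0", None, 1, 1), ("m", "mock", None, 1, 1)],
        )
        cm2 = build_counts(
            {"t0": [10, 20, 30], "m": [5 * factor, 6 * factor, 7 * factor]},
            ["GA", "GA", "GB"],
            [("t0", "T0", None, 1, 1), ("m", "mock", None, 1, 1)],
        )
        n1 = scoring.normalize_depth(cm).values
        n2 = scoring.normalize_depth(cm2).values
        pd.testing.assert_frame_equal(n1, n2)


class TestGuideLFC:
    def _norm(self, t0, sample):
        cm = build_counts(
            {"t0": t0, "s": sample},
            ["GA"] * len(t0),
            [("t0", "T0", None, 1, 1), ("s", "mock", None, 1, 1)],
        )
        return scoring.normalize_depth(cm)

    def test_fourfold_is_two_without_pseudocount(self):
        # both columns sum to 1000 -> CPM shares are directly comparable
        norm = self._norm([100, 900], [400, 600])
        lfc = scoring.guide_lfc(norm, pseudocount=0.0)
        assert lfc.lfc.loc["g1", "s"] == pytest.approx(2.0)

    def test_sample_identical_to_t0_is_zero(self):
        norm = self._norm([100, 900], [100, 900])
        lfc = scoring.guide_lfc(norm, pseudocount=0.5)
        assert np.allclose(lfc.lfc["s"], 0.0)

    def test_pseudocount_arithmetic(self):
        # guide at CPM 400 vs T0 CPM 100: log2(400.5/100.5)
        cm = build_counts(
            {"t0": [100, 9900], "s": [400, 9600]},
            ["GA", "GA"],
            [("t0", "T0", None, 1, 1), ("s", "mock", None, 1, 1)],
        )
        norm = scoring.normalize_depth(cm, scale=1e4)
        lfc = scoring.guide_lfc(norm, pseudocount=0.5)
        assert lfc.lfc.loc["g1", "s"] == pytest.approx(math.log2(400.5 / 100.5), abs=1e-12)

    def test_antisymmetry_swapping_sample_and_baseline(self):
        norm = self._norm([100, 900], [400, 600])
        fwd = scoring.guide_lfc(norm, pseudocount=0.0).lfc["s"]
        swapped = self._norm([400, 600], [100, 900])
        rev = scoring.guide_lfc(swapped, pseudocount=0.0).lfc["s"]
        assert np.allclose(fwd.to_numpy(), -rev.to_numpy())


class TestFilters:
    def _cm(self, t0_counts):
        n = len(t0_counts)
        return build_counts(
            {"t0": t0_counts},
            ["GA"] * n,
            [("t0", "T0", None, 1, 1)],
        )

    def test_t0_boundary_29_dropped_30_kept(self):
        mask = scoring.filter_guides(self._cm([29, 30, 31]))
        assert list(mask["keep"]) == [False, True, True]
        assert list(mask["reason"]) == ["low_T0", "kept", "kept"]

    def test_all_above_threshold_all_kept(self):
        mask = scoring.filter_guides(self._cm([30, 100, 500]))
        assert mask["keep"].all()

    def test_gene_with_two_surviving_guides_dropped(self):
        cm = build_counts(
            {"t0": [100, 100, 5, 5]},
            ["GA", "GA", "GA", "GA"],
            [("t0", "T0", None, 1, 1)],
        )
        gmask = scoring.filter_guides(cm)
        genes = scoring.filter_genes(gmask, cm.library)
        assert not genes.loc[genes["gene_id"] == "GA", "keep"].item()
        assert genes.loc[genes["gene_id"] == "GA", "reason"].item() == "too_few_guides"

    def test_gene_with_three_of_four_guides_kept(self):
        cm = build_counts(
            {"t0": [100, 100, 100, 5]},
            ["GA", "GA", "GA", "GA"],
            [("t0", "T0", None, 1, 1)],
        )
        genes = scoring.filter_genes(scoring.filter_guides(cm), cm.library)
        assert genes.loc[genes["gene_id"] == "GA", "keep"].item()

    def test_empty_mask_drops_all_genes(self):
        cm = self._cm([5, 5, 5])
        genes = scoring.filter_genes(scoring.filter_guides(cm), cm.library)
        assert not genes["keep"].any()

    def test_controls_never_form_genes(self, tiny_screen):
        genes = scoring.filter_genes(
            scoring.filter_guides(tiny_screen, min_t0=0), tiny_screen.library, min_guides=1
        )
        assert "CTRL1" not in set(genes["gene_id"])

    @given(
        t0=st.lists(st.integers(min_value=0, max_value=200), min_size=4, max_size=12),
        lo=st.integers(min_value=0, max_value=100),
        hi=st.integers(min_value=0, max_value=100),
    )
    @settings(**SETTINGS)
    def test_filters_monotone_in_thresholds(self, t0, lo, hi):
        lo, hi = min(lo, hi), max(lo, hi)
        cm = self._cm(t0)
        keep_lo = scoring.filter_guides(cm, min_t0=lo)["keep"]
        keep_hi = scoring.filter_guides(cm, min_t0=hi)["keep"]
        assert not (keep_hi & ~keep_lo).any()


class TestTechnicalAveraging:
    def test_mean_of_two_tech_reps(self):
        cm = build_counts(
            {"t0": [100, 100], "m1": [200, 100], "m2": [800, 100]},
            ["GA", "GB"],
            [
                ("t0", "T0", None, 1, 1),
                ("m1", "mock", None, 1, 1),
                ("m2", "mock", None, 1, 2),
            ],
        )
        norm = scoring.normalize_depth(cm)
        lfc = scoring.guide_lfc(norm, pseudocount=0.0)
        avg = scoring.average_technical_replicates(lfc)
        mock_col = [c for c in avg.lfc.columns if c.startswith("mock")]
        assert len(mock_col) == 1
        expected = (lfc.lfc["m1"] + lfc.lfc["m2"]) / 2
        assert np.allclose(avg.lfc[mock_col[0]], expected)

    def test_single_tech_rep_passes_through(self, tiny_screen):
        lfc = scoring.guide_lfc(scoring.normalize_depth(tiny_screen))
        avg = scoring.average_technical_replicates(lfc)
        assert avg.lfc.shape[1] == 3
        drug_col = [c for c in avg.lfc.columns if c.startswith("treated")][0]
        assert np.allclose(avg.lfc[drug_col], lfc.lfc["drug_1"])

    def test_three_tech_reps_mean(self):
        cm = build_counts(
            {"t0": [10, 10], "m1": [10, 10], "m2": [20, 10], "m3": [40, 10]},
            ["GA", "GB"],
            [
                ("t0", "T0", None, 1, 1),
                ("m1", "mock", None, 1, 1),
                ("m2", "mock", None, 1, 2),
                ("m3", "mock", None, 1, 3),
            ],
        )
        lfc = scoring.guide_lfc(scoring.normalize_depth(cm), pseudocount=0.0)
        avg = scoring.average_technical_replicates(lfc)
        mock_col = [c for c in avg.lfc.columns if c.startswith("mock")][0]
        vals = lfc.lfc[["m1", "m2", "m3"]].mean(axis=1)
        assert np.allclose(avg.lfc[mock_col], vals)


class TestResidualEffects:
    def _avg_lfc(self, treated, mock):
        n = len(treated)
        lfc = pd.DataFrame(
            {"T0|b|1": np.zeros(n), "mock||1": mock, "treated|d|1": treated},
            index=pd.Index([f"g{i + 1}" for i in range(n)], name="guide_id"),
        )
        samples = pd.DataFrame(
            [
                ("T0|b|1", "T0", None, 1, 1),
                ("mock||1", "mock", None, 1, 1),
                ("treated|d|1", "treated", "d", 1, 1),
            ],
            columns=["sample_id", "arm", "compound", "bio_rep", "tech_rep"],
        )
        library = pd.DataFrame(
            {"guide_id": lfc.index, "gene_id": ["G"] * n, "is_control": [False] * n}
        )
        return scoring.LFCTable(lfc=lfc, samples=samples, library=library)

    def test_m_and_a_arithmetic(self):
        res = scoring.residual_effects(self._avg_lfc([2.0, -1.0], [0.5, -3.0]), "d")
        assert np.allclose(res["M"], [1.5, 2.0])
        assert np.allclose(res["A"], [1.25, -2.0])

    def test_treated_equals_mock_gives_zero_m(self):
        res = scoring.residual_effects(self._avg_lfc([0.7, 0.7], [0.7, 0.7]), "d")
        assert np.allclose(res["M"], 0.0)
        assert np.allclose(res["A"], 0.7)

    def test_missing_mock_partner_errors(self):
        table = self._avg_lfc([1.0], [0.0])
        table.samples.loc[1, "bio_rep"] = 2  # mock now in a different bio rep
        with pytest.raises(ValidationError, match="matching mock"):
            scoring.residual_effects(table, "d")


class TestVariancePrior:
    def test_parameter_recovery(self):
        # scaled-inverse-chi-square mixture with known hyperparameters
        rng = np.random.default_rng(7)
        d0_true, s0_true, d = 4.0, 0.04, 8
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, size=5000)
        s_sq = sigma2 * rng.chisquare(d, size=5000) / d
        prior = scoring.fit_variance_prior(s_sq, np.full(5000, d))
        assert prior.d0 == pytest.approx(d0_true, rel=0.20)
        assert prior.s0_sq == pytest.approx(s0_true, rel=0.10)

    def test_identical_variances_give_infinite_d0(self):
        prior = scoring.fit_variance_prior(np.full(50, 0.25), np.full(50, 5))
        assert math.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(0.25, rel=1e-6)

    def test_two_gene_input_rejected(self):
        with pytest.raises(ValidationError, match=">= 20 genes"):
            scoring.fit_variance_prior([0.1, 0.2], [4, 4])

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValidationError, match="zero"):
            scoring.fit_variance_prior(np.zeros(30), np.full(30, 4))


class TestModeratedT:
    def _res(self, values_per_gene: dict) -> pd.DataFrame:
        rows = []
        for gene, vals in values_per_gene.items():
            for i, v in enumerate(vals):
                rows.append((f"{gene}_sg{i}", gene, "d", 1, v, 0.0, v))
        return pd.DataFrame(rows, columns=["guide_id", "gene_id", "compound", "bio_rep", "M", "A", "M_norm"])

    def test_hand_computed_example(self):
        res = self._res({"G1": [1.0, 1.2, 0.8, 1.0]})
        prior = scoring.VariancePrior(d0=3.0, s0_sq=0.04)
        out = scoring.moderated_t(res, prior)
        row = out.iloc[0]
        assert row["effect"] == pytest.approx(1.0)
        assert row["s_sq"] == pytest.approx(0.0266667, rel=1e-5)
        s_post = (3 * 0.04 + 3 * row["s_sq"]) / 6
        assert s_post == pytest.approx(0.0333333, rel=1e-5)
        assert row["t"] == pytest.approx(10.9545, rel=1e-4)
        assert row["df"] == pytest.approx(6.0)
        assert row["p"] == pytest.approx(2 * stats.t.sf(10.95445, 6), rel=1e-4)

    def test_zero_effect_gives_t_zero_p_one(self):
        res = self._res({"G1": [0.0, 0.0, 0.0]})
        out = scoring.moderated_t(res, scoring.VariancePrior(d0=3.0, s0_sq=0.04))
        assert out.iloc[0]["t"] == 0.0
        assert out.iloc[0]["p"] == 1.0

    def test_d0_zero_collapses_to_ordinary_t(self):
        rng = np.random.default_rng(11)
        data = {f"G{i}": rng.normal(0, 1, 6) for i in range(1000)}
        out = scoring.moderated_t(self._res(data), scoring.VariancePrior(d0=0.0, s0_sq=1.0))
        vals = np.array([data[g] for g in out["gene_id"]])
        t_ref, p_ref = stats.ttest_1samp(vals, 0.0, axis=1)
        assert np.allclose(out["t"], t_ref, atol=1e-12, rtol=1e-12)
        assert np.allclose(out["p"], p_ref, atol=1e-12, rtol=1e-10)

    def test_d0_infinity_is_z_statistic(self):
        res = self._res({"G1": [0.5, 0.7, 0.6, 0.6]})
        out = scoring.moderated_t(res, scoring.VariancePrior(d0=math.inf, s0_sq=0.04))
        z = 0.6 / math.sqrt(0.04 / 4)
        assert out.iloc[0]["t"] == pytest.approx(z)
        assert out.iloc[0]["p"] == pytest.approx(2 * stats.norm.sf(abs(z)))

    def test_monotone_in_effect_at_fixed_variance(self):
        prior = scoring.VariancePrior(d0=4.0, s0_sq=0.1)
        effects = [0.2, 0.5, 1.0, 2.0]
        ts = []
        for e in effects:
            res = self._res({"G1": [e - 0.1, e, e + 0.1]})
            ts.append(scoring.moderated_t(res, prior).iloc[0]["t"])
        assert all(a < b for a, b in zip(ts, ts[1:]))

    def test_single_observation_gene_excluded_with_warning(self):
        res = self._res({"G1": [1.0], "G2": [0.1, 0.2, 0.3]})
        with pytest.warns(UserWarning, match="excluded"):
            out = scoring.moderated_t(res, scoring.VariancePrior(d0=3.0, s0_sq=0.04))
        assert list(out["gene_id"]) == ["G2"]

    def test_unset_m_norm_rejected(self):
        res = self._res({"G1": [0.1, 0.2]})
        res["M_norm"] = np.nan
        with pytest.raises(ValidationError, match="loess"):
            scoring.moderated_t(res, scoring.VariancePrior(d0=3.0, s0_sq=0.04))


class TestBHFDR:
    def test_step_up_example(self):
        q = scoring.bh_fdr([0.005, 0.01, 0.03, 0.04])
        assert np.allclose(q, [0.02, 0.02, 0.04, 0.04])

    def test_single_p_one(self):
        assert scoring.bh_fdr([1.0]) == pytest.approx([1.0])

    def test_all_equal_collapse_to_common_value(self):
        q = scoring.bh_fdr(np.full(10, 0.2))
        assert np.allclose(q, 0.2)

    def test_out_of_range_rejected(self):
        for bad in ([0.0, 0.5], [0.5, 1.5], [np.nan, 0.5]):
            with pytest.raises(ValidationError):
                scoring.bh_fdr(bad)

    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=20))
    @settings(**SETTINGS)
    def test_matches_statsmodels_and_is_order_invariant(self, p):
        from statsmodels.stats.multitest import multipletests

        p = np.asarray(p)
        q = scoring.bh_fdr(p)
        q_ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, q_ref, atol=1e-12)
        perm = np.random.default_rng(0).permutation(len(p))
        assert np.allclose(scoring.bh_fdr(p[perm]), q[perm])
        assert (q <= 1.0).all() and q[np.argmax(p)] >= p.max() - 1e-12


class TestCallHits:
    @pytest.mark.parametrize(
        "effect,q,expected",
        [
            (0.6, 0.39, "resistant"),
            (0.5, 0.10, "none"),  # strictly greater than the cut
            (-0.8, 0.40, "none"),  # strictly below the FDR cut
            (-0.8, 0.39, "sensitive"),
            (0.51, 0.399, "resistant"),
            (0.0, 0.01, "none"),
        ],
    )
    def test_strict_threshold_predicate(self, effect, q, expected):
        table = pd.DataFrame(
            {
                "gene_id": ["G1"],
                "n_guides": [4],
                "effect": [effect],
                "t": [1.0],
                "df": [6.0],
                "p": [0.01],
                "q": [q],
                "hit_class": ["none"],
            }
        )
        out = scoring.call_hits(table)
        assert out.iloc[0]["hit_class"] == expected


class TestSpecificity:
    def _scores(self, hit_classes: dict) -> pd.DataFrame:
        genes = sorted(hit_classes)
        return pd.DataFrame(
            {
                "gene_id": genes,
                "hit_class": [hit_classes[g] for g in genes],
            }
        )

    def test_same_direction_in_all_is_non_specific(self):
        per = {
            c: self._scores({"G1": "sensitive", "G2": "none"})
            for c in ("a", "b", "c")
        }
        spec = scoring.classify_specificity(per)
        row = spec[spec["gene_id"] == "G1"].iloc[0]
        assert row["specificity"] == "non_specific"
        assert row["excluded"]

    def test_single_compound_hit_is_specific(self):
        per = {
            "palbociclib": self._scores({"G1": "resistant"}),
            "colchicine": self._scores({"G1": "none"}),
            "camptothecin": self._scores({"G1": "none"}),
        }
        spec = scoring.classify_specificity(per)
        assert spec.iloc[0]["specificity"] == "compound_specific"

    def test_two_of_three_is_shared_subset(self):
        per = {
            "a": self._scores({"G1": "sensitive"}),
            "b": self._scores({"G1": "sensitive"}),
            "c": self._scores({"G1": "none"}),
        }
        assert scoring.classify_specificity(per).iloc[0]["specificity"] == "shared_subset"

    def test_mixed_directions_in_all_not_non_specific(self):
        per = {
            "a": self._scores({"G1": "sensitive"}),
            "b": self._scores({"G1": "resistant"}),
            "c": self._scores({"G1": "sensitive"}),
        }
        assert scoring.classify_specificity(per).iloc[0]["specificity"] == "shared_subset"

    def test_mismatched_universe_errors(self):
        per = {
            "a": self._scores({"G1": "none"}),
            "b": self._scores({"G2": "none"}),
        }
        with pytest.raises(ValidationError, match="universe"):
            scoring.classify_specificity(per)


class TestScoreScreenComposition:
    def test_duplicated_treated_as_own_mock_gives_zero_hits(self):
        rng = np.random.default_rng(5)
        n = 60
        t0 = rng.integers(200, 1000, n)
        final = rng.integers(200, 1000, n)
        cm = build_counts(
            {"t0": t0, "mock_1": final, "drug_1": final},
            [f"G{i // 3}" for i in range(n)],
            [
                ("t0", "T0", None, 1, 1),
                ("mock_1", "mock", None, 1, 1),
                ("drug_1", "treated", "drug", 1, 1),
            ],
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores = scoring.score_screen(cm, scoring.ScoreParams(min_guides=2))["drug"]
        assert np.allclose(scores["effect"], 0.0)
        assert (scores["hit_class"] == "none").all()

    def test_hit_calls_reproducible_from_saved_table(self, tmp_path):
        from chemoscreen import io, simulate

        cfg = simulate.SimConfig(n_genes=60, n_controls=10, seed=2)
        counts, *_ = simulate.simulate_screen(cfg)
        scores = scoring.score_screen(counts)["drugA"]
        path = tmp_path / "scores.tsv"
        io.write_gene_scores(scores, path)
        back = io.read_gene_scores(path)
        recalled = scoring.call_hits(back)
        assert list(recalled["hit_class"]) == list(back["hit_class"])
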