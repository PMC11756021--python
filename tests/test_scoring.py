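"""The CV heterogeneity score, weight derivation, panel selection, strata."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from meheg import (
    BetaMatrix,
    SampleAnnotation,
    ScoringError,
    ValidationError,
    WeightMatrix,
    classify_dual,
    derive_weights,
    meheg_cohort,
    meheg_score,
    select_model_probes,
    simulate_cohort,
    simulate_reference,
    stratify,
)


def _identity_weights(n=3, regions=("DTS", "CB", "IF")):
    return WeightMatrix(
        pd.DataFrame(np.eye(n), index=[f"cg{i}" for i in range(n)],
                     columns=list(regions))
    )


def _brute_force_score(betas, weights):
    """Literal re-evaluation of the CV formula, probe by probe."""
    regions = weights.regions
    s = []
    for r in regions:
        total = 0.0
        for p in weights.probes:
            total += betas[p] * weights.values.loc[p, r]
        s.append(total)
    s_bar = sum(s) / len(s)
    var = sum((x - s_bar) ** 2 for x in s) / len(s)
    return (var ** 0.5) / s_bar


class TestScoreFormula:
    def test_hand_evaluated_example(self):
        """Regional scores (1, 2, 3): CV = sqrt(2/3)/2 = 0.40825."""
        res = meheg_score(
            pd.Series([1.0, 2.0, 3.0], index=["cg0", "cg1", "cg2"]),
            _identity_weights(),
        )
        assert res.mean_score == pytest.approx(2.0)
        assert res.score == pytest.approx(np.sqrt(2 / 3) / 2, abs=1e-12)

    def test_zero_iff_equal_regional_scores(self):
        res = meheg_score(
            pd.Series([2.0, 2.0, 2.0], index=["cg0", "cg1", "cg2"]),
            _identity_weights(),
        )
        assert res.score == 0.0

    def test_agrees_with_brute_force_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = rng.integers(2, 9)
            probes = [f"cg{i}" for i in range(n)]
            w = WeightMatrix(
                pd.DataFrame(
                    rng.uniform(0.05, 1.0, size=(n, 3)),
                    index=probes, columns=["DTS", "CB", "IF"],
                )
            )
            betas = pd.Series(rng.uniform(0.01, 1.0, n), index=probes)
            res = meheg_score(betas, w)
            assert res.score == pytest.approx(
                _brute_force_score(betas, w), abs=1e-12
            )

    @given(c=st.floats(min_value=0.01, max_value=100.0))
    @settings(deadline=None, max_examples=30)
    def test_scale_invariance_in_weights_and_betas(self, c):
        probes = ["cg0", "cg1", "cg2"]
        w = WeightMatrix(
            pd.DataFrame(
                [[0.4, 0.1, 0.2], [0.2, 0.5, 0.3], [0.1, 0.2, 0.6]],
                index=probes, columns=["DTS", "CB", "IF"],
            )
        )
        betas = pd.Series([0.3, 0.6, 0.9], index=probes)
        base = meheg_score(betas, w).score
        scaled_w = WeightMatrix(w.values * c)
        assert meheg_score(betas, scaled_w).score == pytest.approx(
            base, abs=1e-10
        )
        assert meheg_score(betas * c, w).score == pytest.approx(
            base, abs=1e-10
        )

    def test_mean_preserving_spread_never_decreases_score(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            s = rng.uniform(0.5, 2.0, 3)
            betas = pd.Series(s, index=["cg0", "cg1", "cg2"])
            base = meheg_score(betas, _identity_weights()).score
            spread = pd.Series(
                s.mean() + 1.5 * (s - s.mean()), index=betas.index
            )
            if (spread > 0).all():
                assert meheg_score(spread, _identity_weights()).score >= base

    def test_negative_regional_score_is_error(self):
        w = WeightMatrix(
            pd.DataFrame(
                [[-1.0, 1.0, 1.0]], index=["cg0"], columns=["DTS", "CB", "IF"]
            )
        )
        with pytest.raises(ScoringError, match="negative regional"):
            meheg_score(pd.Series([0.5], index=["cg0"]), w)

    def test_missing_panel_probe_named(self):
        with pytest.raises(ScoringError, match="cg2"):
            meheg_score(
                pd.Series([0.5, 0.5], index=["cg0", "cg1"]),
                _identity_weights(),
            )


class TestWeights:
    @pytest.fixture
    def indicator_design(self):
        """Three near-indicator probes (one per region) plus four nulls."""
        rng = np.random.default_rng(8)
        regions = ["DTS", "CB", "IF"]
        samples = [f"P{p}_{r}" for p in range(6) for r in regions]
        annot = SampleAnnotation(
            pd.DataFrame(
                {
                    "sample": samples,
                    "patient": [s.split("_")[0] for s in samples],
                    "region": [s.split("_")[1] for s in samples],
                }
            ).set_index("sample")
        )
        probes = [f"ind_{r}" for r in regions] + [f"null_{i}" for i in range(4)]
        vals = np.empty((7, len(samples)))
        for j, s in enumerate(samples):
            r = s.split("_")[1]
            for k, rr in enumerate(regions):
                vals[k, j] = (0.8 if r == rr else 0.2) + rng.normal(0, 0.02)
            vals[3:, j] = 0.5 + rng.normal(0, 0.02, 4)
        beta = BetaMatrix(
            pd.DataFrame(np.clip(vals, 0, 1), index=probes, columns=samples)
        )
        return beta, annot, probes, regions

    def test_signature_strategy_equals_region_means(self, tiny_beta, tiny_annot):
        w = derive_weights(
            tiny_beta, tiny_annot, ["cgA", "cgB", "cgC"], strategy="signature"
        )
        assert w.strategy == "signature"
        assert w.values.loc["cgA", "DTS"] == pytest.approx(0.15)
        assert w.values.loc["cgA", "IF"] == pytest.approx(0.85)

    def test_perfect_separator_has_positive_weight(self, indicator_design):
        beta, annot, probes, regions = indicator_design
        vals = beta.values.copy()
        vals.loc["ind_DTS"] = [
            1.0 if s.split("_")[1] == "DTS" else 0.0 for s in beta.samples
        ]
        w = derive_weights(BetaMatrix(vals), annot, probes)
        assert w.values.loc["ind_DTS", "DTS"] > 0

    def test_svr_primal_signs_match_ridge_oracle(self, indicator_design):
        """Dominant weight signs agree with closed-form ridge (lambda=1)."""
        beta, annot, probes, regions = indicator_design
        w = derive_weights(beta, annot, probes)
        x = beta.values.to_numpy().T
        xc = x - x.mean(axis=0)
        for r in regions:
            y = np.array(
                [1.0 if s.split("_")[1] == r else 0.0 for s in beta.samples]
            )
            ridge = np.linalg.solve(
                xc.T @ xc + np.eye(len(probes)), xc.T @ (y - y.mean())
            )
            dominant = np.abs(ridge) > 0.5 * np.abs(ridge).max()
            svr = w.values[r].to_numpy()
            assert (np.sign(ridge[dominant]) == np.sign(svr[dominant])).all()

    def test_region_with_one_sample_fatal(self, tiny_beta, tiny_annot):
        annot = SampleAnnotation(tiny_annot.table.drop(index="P2_IF"))
        with pytest.raises(ValidationError, match="IF"):
            derive_weights(tiny_beta, annot, ["cgA", "cgB", "cgC"])


class TestPanelSelection:
    def test_planted_probes_recovered(self):
        sig, truth = simulate_reference(107, 7, separation=0.1, seed=21)
        conc = {
            r: np.where(np.arange(3) == j, 500.0, 0.01)
            for j, r in enumerate(sig.regions)
        }
        beta, annot, _ = simulate_cohort(
            sig, 4, noise_sd=0.005, concentrations=conc, seed=22
        )
        selected = select_model_probes(beta, annot, list(beta.probes),
                                       panel_size=7)
        assert sorted(selected) == sorted(truth.planted_probes)

    def test_single_elimination_round_boundary(self, small_cohort):
        beta, annot, _, truth_ref = small_cohort
        dmps = truth_ref.planted_probes[:10]
        selected = select_model_probes(beta, annot, dmps, panel_size=9)
        assert len(selected) == 9
        assert set(selected) < set(dmps)

    def test_panel_size_must_be_smaller_than_dmp_set(self, small_cohort):
        beta, annot, _, truth_ref = small_cohort
        dmps = truth_ref.planted_probes[:5]
        with pytest.raises(ValidationError):
            select_model_probes(beta, annot, dmps, panel_size=5)

    def test_deterministic_given_inputs(self, small_cohort):
        beta, annot, _, truth_ref = small_cohort
        dmps = truth_ref.planted_probes[:20]
        a = select_model_probes(beta, annot, dmps, panel_size=7)
        b = select_model_probes(beta, annot, dmps, panel_size=7)
        assert a == b


class TestCohortScoring:
    def test_single_sample_matches_scalar_call(self, small_cohort):
        beta, annot, _, truth_ref = small_cohort
        panel = truth_ref.planted_probes[:7]
        w = derive_weights(beta, annot, panel, strategy="signature")
        one = BetaMatrix(beta.values[[beta.samples[0]]])
        table = meheg_cohort(one, w)
        res = meheg_score(beta.values[beta.samples[0]], w)
        assert len(table) == 1
        assert table["meheg"].iloc[0] == pytest.approx(res.score, abs=1e-12)

    def test_permuting_samples_permutes_rows_only(self, small_cohort):
        beta, annot, _, truth_ref = small_cohort
        panel = truth_ref.planted_probes[:7]
        w = derive_weights(beta, annot, panel, strategy="signature")
        table = meheg_cohort(beta, w)
        perm = list(reversed(beta.samples))
        table2 = meheg_cohort(BetaMatrix(beta.values[perm]), w)
        pd.testing.assert_frame_equal(table.loc[perm], table2)

    def test_invasive_front_scores_highest_on_admixture_gradient(
        self, small_cohort
    ):
        """The most admixed region carries the highest mean score."""
        beta, annot, _, truth_ref = small_cohort
        panel = truth_ref.planted_probes[:7]
        w = derive_weights(beta, annot, panel, strategy="signature")
        table = meheg_cohort(beta, w)
        assert (table["status"] == "ok").all()
        means = {
            r: table.loc[annot.samples_of(r), "meheg"].mean()
            for r in annot.region_set
        }
        assert means["IF"] > means["CB"]
        assert means["IF"] > means["DTS"]

    def test_entropy_correlates_with_score(self, small_cohort):
        from scipy.stats import spearmanr

        beta, annot, _, truth_ref = small_cohort
        _, _, truth, _ = (None, None, small_cohort[2], None)
        panel = truth_ref.planted_probes[:7]
        w = derive_weights(beta, annot, panel, strategy="signature")
        table = meheg_cohort(beta, w)
        rho = spearmanr(
            truth.entropy[table.index], table["meheg"]
        ).statistic
        assert rho > 0


class TestStratification:
    def test_upper_quartile_cut(self):
        scores = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        labels = stratify(scores, 0.75)
        # linear-interpolation quantile: threshold 3.25, strict >
        assert labels.tolist() == ["L", "L", "L", "H"]

    def test_upper_q_zero_labels_everything_above_min(self):
        scores = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        labels = stratify(scores, 0.0)
        assert labels.tolist() == ["L", "H", "H"]

    def test_identical_scores_empty_h_group(self):
        scores = pd.Series([2.0, 2.0, 2.0], index=list("abc"))
        labels = stratify(scores, 0.75)
        assert (labels == "L").all()

    def test_dual_classification_four_types(self):
        idx = [f"s{i}" for i in range(8)]
        meheg_scores = pd.Series([1, 1, 1, 1, 1, 1, 9, 9], index=idx,
                                 dtype=float)
        metil_scores = pd.Series([5, 5, 5, 5, 5, 0, 0, 5], index=idx,
                                 dtype=float)
        types = classify_dual(meheg_scores, metil_scores,
                              upper_q=0.75, lower_q=0.25)
        assert types["s6"] == 1  # high heterogeneity, low MeTIL
        assert types["s7"] == 2  # high heterogeneity, high MeTIL
        assert types["s5"] == 3  # low heterogeneity, low MeTIL
        assert types["s0"] == 4  # low heterogeneity, high MeTIL
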