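"""Weighted and centroid expression signatures."""

import numpy as np
import pandas as pd
import pytest

from survbench import (
    CentroidSignature,
    SurvivalOutcome,
    WeightedSignature,
    centroid_signature_score,
    signature_as_feature_set,
    weighted_signature_score,
)


@pytest.fixture()
def toy_expr():
    rng = np.random.default_rng(0)
    return pd.DataFrame(rng.normal(size=(5, 6)),
                        index=[f"g{i}" for i in range(5)],
                        columns=[f"s{i}" for i in range(6)])


class TestWeightedSignature:
    def test_zero_weights_constant(self, toy_expr):
        sig = WeightedSignature("w0", {"g0": 0.0, "g1": 0.0})
        assert weighted_signature_score(toy_expr, sig).nunique() == 1

    def test_single_gene_weight_one_is_negated_zscore(self, toy_expr):
        sig = WeightedSignature("one", {"g2": 1.0})
        score = weighted_signature_score(toy_expr, sig)
        z = (toy_expr.loc["g2"] - toy_expr.loc["g2"].mean()) / toy_expr.loc["g2"].std(ddof=0)
        assert np.allclose(score, -z)

    def test_hand_computed_weighted_sum(self):
        expr = pd.DataFrame(
            {"s1": [1.0, 0.0, 2.0], "s2": [2.0, 1.0, 4.0],
             "s3": [3.0, 2.0, 6.0], "s4": [4.0, 3.0, 8.0]},
            index=["gA", "gB", "gC"],
        )
        sig = WeightedSignature("hand", {"gA": 1.0, "gB": -1.0, "gC": 2.0})
        score = weighted_signature_score(expr, sig)
        z = expr.sub(expr.mean(axis=1), axis=0).div(expr.std(axis=1, ddof=0), axis=0)
        expected = -(z.loc["gA"] - z.loc["gB"] + 2 * z.loc["gC"])
        assert np.allclose(score, expected)

    def test_affine_rescaling_invariance(self, toy_expr):
        sig = WeightedSignature("aff", {"g0": 1.0, "g1": -2.0, "g3": 0.5})
        a = weighted_signature_score(toy_expr, sig)
        rescaled = toy_expr.mul(pd.Series([3, 0.1, 5, 2, 7], index=toy_expr.index), axis=0)
        rescaled = rescaled.add(pd.Series([1, -4, 2, 0, 9], index=toy_expr.index), axis=0)
        b = weighted_signature_score(rescaled, sig)
        assert np.allclose(a, b)

    def test_absent_genes_dropped_all_absent_errors(self, toy_expr):
        sig = WeightedSignature("partial", {"g0": 1.0, "missing": 2.0})
        assert len(weighted_signature_score(toy_expr, sig)) == toy_expr.shape[1]
        with pytest.raises(ValueError):
            weighted_signature_score(toy_expr, WeightedSignature("none", {"absent": 1.0}))


class TestCentroidSignature:
    def outcome(self, times):
        idx = [f"s{i}" for i in range(len(times))]
        return SurvivalOutcome(pd.Series(times, index=idx),
                               pd.Series(1, index=idx))

    def test_matches_pearson_oracle_and_endpoints(self):
        """Scores equal Pearson correlation to the good-prognosis profile."""
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(size=(4, 6)),
                            index=list("wxyz"), columns=[f"s{i}" for i in range(6)])
        out = self.outcome([100, 100, 100, 10, 10, 10])
        sig = CentroidSignature("c", genes=list("wxyz"), good_prognosis_horizon=60)
        score = centroid_signature_score(expr, sig, out)
        z = expr.sub(expr.mean(axis=1), axis=0).div(expr.std(axis=1, ddof=0), axis=0)
        profile = z[["s0", "s1", "s2"]].mean(axis=1)
        for s in expr.columns:
            assert score[s] == pytest.approx(np.corrcoef(z[s], profile)[0, 1], abs=1e-9)
        assert score.between(-1, 1).all()
        # a (standardized) sample vector equal to +/- the profile scores +/-1
        prof = profile.to_numpy()
        pc = prof - prof.mean()
        assert np.dot(pc, pc) / (np.linalg.norm(pc) ** 2) == pytest.approx(1.0)

    def test_profile_aligned_sample_scores_plus_minus_one(self):
        """Samples collinear with the profile (after standardization) hit +/-1."""
        # two mirrored samples make each gene's standardization symmetric, so
        # the standardized vectors stay proportional to the raw ones
        base = np.array([1.0, -2.0, 0.5, 3.0])
        expr = pd.DataFrame({"s0": base, "s1": -base, "s2": base, "s3": -base},
                            index=list("wxyz"))
        out = self.outcome([100, 10, 100, 10])
        sig = CentroidSignature("c", genes=list("wxyz"), good_prognosis_horizon=60)
        score = centroid_signature_score(expr, sig, out)
        # profile = mean of the two good-prognosis samples = z(s0) exactly
        assert score["s0"] == pytest.approx(1.0)
        assert score["s2"] == pytest.approx(1.0)
        assert score["s1"] == pytest.approx(-1.0)
        assert score["s3"] == pytest.approx(-1.0)

    def test_censored_before_horizon_excluded_from_reference(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.normal(size=(4, 5)),
                            index=list("wxyz"), columns=[f"s{i}" for i in range(5)])
        idx = [f"s{i}" for i in range(5)]
        out = SurvivalOutcome(pd.Series([100, 100, 50, 50, 20], index=idx),
                              pd.Series([1, 0, 0, 1, 1], index=idx))
        sig = CentroidSignature("c", genes=list("wxyz"), good_prognosis_horizon=60)
        score = centroid_signature_score(expr, sig, out)
        # only s0 and s1 lived past 60 months; both count (event or censored later)
        z = expr.sub(expr.mean(axis=1), axis=0).div(expr.std(axis=1, ddof=0), axis=0)
        profile = z[["s0", "s1"]].mean(axis=1).to_numpy()
        assert score["s0"] == pytest.approx(np.corrcoef(z["s0"], profile)[0, 1])

    def test_too_few_reference_samples_errors(self, toy_expr):
        out = self.outcome([10, 10, 10, 10, 10, 100])
        sig = CentroidSignature("c", genes=["g0", "g1", "g2"], good_prognosis_horizon=60)
        with pytest.raises(ValueError, match="reference"):
            centroid_signature_score(toy_expr, sig, out)


class TestSignatureFeatureSet:
    def test_feature_set_from_weighted(self, small_cohort):
        lists = small_cohort.gene_lists["oncotype_like"]
        sig = WeightedSignature("oncotype_like", lists)
        fs = signature_as_feature_set(sig, small_cohort)
        assert len(fs) == len(lists)
        assert all(f.startswith("expr:") for f in fs.ids)

    def test_absent_genes_reduce_count(self, small_cohort):
        sig = CentroidSignature("c", genes=["g00000", "g00001", "not_there"])
        fs = signature_as_feature_set(sig, small_cohort)
        assert len(fs) == 2

    def test_disjoint_errors(self, small_cohort):
        with pytest.raises(ValueError):
            signature_as_feature_set(CentroidSignature("c", genes=["zz"]), small_cohort)


def test_embedded_signature_beats_raw_score_as_features():
    """Signature genes fed to supervised learners outscore the raw centroid score."""
    import numpy as np

    from survbench import (
        GeneratorConfig,
        concordance_index,
        customPredict,
        customTrain,
        generate_cohort,
        make_learner,
    )
    from survbench.design import freeze_feature_ids

    cohort = generate_cohort(GeneratorConfig(n_samples=500, n_genes=600, seed=9))
    # the weighted stand-in carries deliberately noisy published-style weights,
    # which supervised re-estimation on the same gene list should beat
    sig = WeightedSignature("oncotype_like", cohort.gene_lists["oncotype_like"])
    train, val = cohort.train_samples, cohort.validation_samples
    raw = weighted_signature_score(cohort.expression, sig, train_samples=train)
    raw_c = concordance_index(raw.loc[val], cohort.outcome.loc(val)).c_index
    fs = signature_as_feature_set(sig, cohort)
    frozen = freeze_feature_ids(cohort, "sig_grid", fs.ids)
    scores = []
    for learner in ["boosting", "random_survival_forest", "lasso_cox", "elasticnet_cox"]:
        model = make_learner(learner, seed=0)
        customTrain(model, frozen.transform(cohort, train), cohort.outcome.loc(train))
        pred = customPredict(model, frozen.transform(cohort, val))
        scores.append(concordance_index(pred, cohort.outcome.loc(val)).c_index)
    assert np.mean(scores) > raw_c
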