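import math

import numpy as np
import pandas as pd
import pytest

from mrkit.grs import (
    AssocResult,
    WeightEntry,
    assign_quartiles,
    compute_scores,
    first_pc_phenotype,
    quartile_contrasts,
    read_weights,
    score_regression,
    write_weights,
)
from mrkit.summary_io import CohortTable, ValidationError


def _cohort(dosages, pheno=None, counted=None, ids=None):
    dosages = pd.DataFrame(dosages)
    ids = ids or [f"i{k}" for k in range(len(dosages))]
    dosages.index = pd.Index(ids, name="IID")
    if pheno is None:
        pheno = pd.DataFrame(index=dosages.index)
    else:
        pheno = pd.DataFrame(pheno, index=dosages.index)
    counted = counted or {c: "A" for c in dosages.columns}
    return CohortTable(dosages=dosages, counted_alleles=counted, pheno=pheno)


class TestComputeScores:
    def test_worked_example(self):
        """Two risk alleles at OR 1.2 plus one at OR 1.5:
        2 ln 1.2 + 1 ln 1.5 = 0.770108..."""
        cohort = _cohort({"rs1": [2.0], "rs2": [1.0]})
        weights = [WeightEntry("rs1", 1.2, "A"), WeightEntry("rs2", 1.5, "A")]
        (res,) = compute_scores(cohort, weights)
        assert res.score == pytest.approx(2 * math.log(1.2) + math.log(1.5))
        assert res.score == pytest.approx(0.770108, abs=1e-6)

    def test_null_weights_give_zero_scores(self):
        cohort = _cohort({"rs1": [2.0, 1.0], "rs2": [0.0, 2.0]})
        weights = [WeightEntry("rs1", 1.0, "A"), WeightEntry("rs2", 1.0, "A")]
        assert all(r.score == 0.0 for r in compute_scores(cohort, weights))

    def test_missing_dosage_imputed_with_cohort_mean(self):
        cohort = _cohort({"rs1": [0.0, 2.0, np.nan]})
        (a, b, c) = compute_scores(cohort, [WeightEntry("rs1", 1.2, "A")])
        assert c.score == pytest.approx(math.log(1.2) * 1.0)  # mean dosage 1.0
        assert c.n_imputed == 1 and a.n_imputed == 0

    def test_missing_dosage_prefers_weight_file_frequency(self):
        cohort = _cohort({"rs1": [0.0, 2.0, np.nan]})
        (_, _, c) = compute_scores(cohort, [WeightEntry("rs1", 1.2, "A", eaf=0.25)])
        assert c.score == pytest.approx(math.log(1.2) * 0.5)

    def test_opposite_counted_allele_realigned(self):
        cohort = _cohort({"rs1": [2.0, 0.0]}, counted={"rs1": "G"})
        scores = compute_scores(cohort, [WeightEntry("rs1", 1.5, "A")])
        assert scores[0].score == pytest.approx(0.0)
        assert scores[1].score == pytest.approx(2 * math.log(1.5))

    def test_weight_variant_absent_excluded_consistently(self):
        cohort = _cohort({"rs1": [1.0, 2.0]})
        weights = [WeightEntry("rs1", 1.2, "A"), WeightEntry("rs_gone", 2.0, "A")]
        scores = compute_scores(cohort, weights)
        assert scores[0].score == pytest.approx(math.log(1.2))

    def test_additivity_over_disjoint_variant_sets(self, rng):
        g = rng.integers(0, 3, size=(20, 6)).astype(float)
        cohort = _cohort({f"rs{j}": g[:, j] for j in range(6)})
        weights = [WeightEntry(f"rs{j}", float(np.exp(rng.normal(0, 0.1))), "A") for j in range(6)]
        full = compute_scores(cohort, weights)
        part_a = compute_scores(cohort, weights[:3])
        part_b = compute_scores(cohort, weights[3:])
        for f, a, b in zip(full, part_a, part_b):
            assert f.score == pytest.approx(a.score + b.score)

    def test_weights_file_roundtrip(self, tmp_path):
        weights = [WeightEntry("rs1", 1.23, "A", eaf=0.31), WeightEntry("rs2", 0.9, "C")]
        path = tmp_path / "w.tsv"
        write_weights(weights, path)
        assert read_weights(path) == weights


class TestQuartiles:
    def test_eight_distinct_scores_split_evenly(self):
        cohort = _cohort({"rs1": [float(k) / 4 for k in range(8)]})
        scores = compute_scores(cohort, [WeightEntry("rs1", 1.5, "A")])
        counts = pd.Series([s.quartile for s in scores]).value_counts()
        assert sorted(counts.index) == [1, 2, 3, 4]
        assert set(counts.values) == {2}

    def test_tie_goes_to_lower_quartile(self):
        from mrkit.grs import ScoreResult

        scores = [ScoreResult(f"i{k}", s) for k, s in enumerate([0, 0, 1, 1, 2, 2, 3, 3])]
        assign_quartiles(scores)
        # the 25% boundary falls on a tied value: ties stay in the lower quartile
        assert scores[0].quartile == 1
        boundary = np.quantile([s.score for s in scores], 0.25)
        for s in scores:
            if s.score == boundary:
                assert s.quartile <= 2


def _regression_cohort(rng, n=200, score_effect=0.5, noise=0.0):
    g = rng.integers(0, 3, size=(n, 4)).astype(float)
    cohort_cols = {f"rs{j}": g[:, j] for j in range(4)}
    weights = [WeightEntry(f"rs{j}", 1.3, "A") for j in range(4)]
    age = rng.normal(60, 5, n)
    sex = rng.integers(0, 2, n).astype(float)
    score = g.sum(axis=1) * math.log(1.3)
    pheno = {
        "y": score_effect * score + 0.1 * age - 0.3 * sex + noise * rng.standard_normal(n),
        "age": age,
        "sex": sex,
    }
    cohort = _cohort(cohort_cols, pheno=pheno)
    return cohort, weights


class TestScoreRegression:
    def test_noiseless_recovery_is_exact(self, rng):
        cohort, weights = _regression_cohort(rng)
        scores = compute_scores(cohort, weights)
        res = score_regression(scores, cohort, "y", ["age", "sex"])
        assert res.beta == pytest.approx(0.5, abs=1e-8)

    def test_affine_covariate_shift_leaves_coefficient_unchanged(self, rng):
        cohort, weights = _regression_cohort(rng, noise=1.0)
        scores = compute_scores(cohort, weights)
        a = score_regression(scores, cohort, "y", ["age", "sex"])
        cohort.pheno["age"] = cohort.pheno["age"] + 1000.0
        b = score_regression(scores, cohort, "y", ["age", "sex"])
        assert b.beta == pytest.approx(a.beta)
        assert b.se == pytest.approx(a.se)

    def test_collinear_design_names_columns(self, rng):
        cohort, weights = _regression_cohort(rng, noise=1.0)
        cohort.pheno["age_copy"] = cohort.pheno["age"]
        scores = compute_scores(cohort, weights)
        with pytest.raises(ValidationError, match="age"):
            score_regression(scores, cohort, "y", ["age", "age_copy"])

    def test_confounded_batch_adjustment_removes_bias(self, rng):
        """A batch covariate correlated with the score and driving the
        phenotype biases the unadjusted fit; adjustment removes it."""
        n = 2000
        g = rng.integers(0, 3, size=(n, 4)).astype(float)
        score = g.sum(axis=1) * math.log(1.3)
        batch = (score + rng.standard_normal(n) > np.median(score)).astype(float)
        y = 2.0 * batch + 0.3 * rng.standard_normal(n)  # no direct score effect
        cohort = _cohort(
            {f"rs{j}": g[:, j] for j in range(4)}, pheno={"y": y, "batch": batch}
        )
        weights = [WeightEntry(f"rs{j}", 1.3, "A") for j in range(4)]
        scores = compute_scores(cohort, weights)
        unadjusted = score_regression(scores, cohort, "y", [])
        adjusted = score_regression(scores, cohort, "y", ["batch"])
        assert abs(unadjusted.beta) > 4 * abs(unadjusted.se)
        assert abs(adjusted.beta) < 3 * adjusted.se

    def test_type_i_error_calibrated(self, rng):
        """Phenotype independent of the score: the score coefficient is
        significant at alpha=0.05 in about 5% of simulated cohorts."""
        hits, reps = 0, 400
        for _ in range(reps):
            n = 60
            g = rng.integers(0, 3, size=(n, 3)).astype(float)
            cohort = _cohort(
                {f"rs{j}": g[:, j] for j in range(3)},
                pheno={"y": rng.standard_normal(n)},
            )
            weights = [WeightEntry(f"rs{j}", 1.3, "A") for j in range(3)]
            res = score_regression(compute_scores(cohort, weights), cohort, "y", [])
            hits += res.pvalue < 0.05
        assert 0.02 <= hits / reps <= 0.08


class TestQuartileContrasts:
    def test_monotone_contrasts_for_linear_phenotype(self, rng):
        cohort, weights = _regression_cohort(rng, n=400, noise=0.05)
        scores = compute_scores(cohort, weights)
        q2, q3, q4 = quartile_contrasts(scores, cohort, "y", ["age", "sex"])
        assert q2.term == "Q2_vs_Q1" and q4.term == "Q4_vs_Q1"
        assert q2.beta < q3.beta < q4.beta

    def test_all_identical_scores_degenerate(self):
        cohort = _cohort({"rs1": [1.0] * 10}, pheno={"y": list(range(10))})
        scores = compute_scores(cohort, [WeightEntry("rs1", 1.5, "A")])
        with pytest.raises(ValidationError, match="degenerate"):
            quartile_contrasts(scores, cohort, "y")

    def test_too_few_individuals_rejected(self):
        cohort = _cohort({"rs1": [0, 1, 2, 0, 1]}, pheno={"y": [1, 2, 3, 4, 5]})
        scores = compute_scores(cohort, [WeightEntry("rs1", 1.5, "A")])
        with pytest.raises(ValidationError):
            quartile_contrasts(scores, cohort, "y")

    def test_null_contrasts_cover_zero(self, rng):
        """With no score effect, each of the three contrast CIs covers 0
        in about 95% of replicates."""
        covered, total = 0, 0
        for _ in range(150):
            n, m = 80, 10
            g = rng.integers(0, 3, size=(n, m)).astype(float)
            cohort = _cohort(
                {f"rs{j}": g[:, j] for j in range(m)},
                pheno={"y": rng.standard_normal(n)},
            )
            # distinct weights keep the score distribution effectively tie-free
            weights = [WeightEntry(f"rs{j}", 1.1 + 0.07 * j, "A") for j in range(m)]
            scores = compute_scores(cohort, weights)
            for c in quartile_contrasts(scores, cohort, "y"):
                covered += c.ci_low <= 0.0 <= c.ci_high
                total += 1
        assert 0.92 <= covered / total <= 0.98


class TestFirstPcPhenotype:
    def test_rank_one_matrix_recovers_common_column(self, rng):
        col = rng.standard_normal(60)
        X = np.tile(col[:, None], (1, 48)) * rng.uniform(0.5, 2.0, 48)
        res = first_pc_phenotype(X)
        z = (col - col.mean()) / col.std(ddof=1)
        assert res.explained_variance_ratio == pytest.approx(1.0)
        assert abs(np.corrcoef(res.scores, z)[0, 1]) == pytest.approx(1.0)

    def test_matches_sklearn_pca_oracle(self, rng):
        from sklearn.decomposition import PCA

        X = rng.standard_normal((40, 10)) @ rng.standard_normal((10, 10))
        res = first_pc_phenotype(X)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        pc1 = PCA(n_components=1).fit_transform(Z)[:, 0]
        assert abs(np.corrcoef(res.scores, pc1)[0, 1]) == pytest.approx(1.0)
        # unit-variance convention
        assert res.scores.std(ddof=1) == pytest.approx(1.0)

    def test_sign_convention_positive_loading_sum(self, rng):
        X = rng.standard_normal((30, 6)) + 2.0 * rng.standard_normal((30, 1))
        a = first_pc_phenotype(X)
        b = first_pc_phenotype(-X)
        assert a.loadings.sum() > 0 and b.loadings.sum() > 0
        np.testing.assert_allclose(a.scores, -b.scores, atol=1e-10)

    def test_invariant_to_column_scaling_and_row_order(self, rng):
        X = rng.standard_normal((30, 6)) + rng.standard_normal((30, 1))
        base = first_pc_phenotype(X)
        scaled = first_pc_phenotype(X * rng.uniform(0.1, 10.0, 6))
        np.testing.assert_allclose(scaled.scores, base.scores, atol=1e-8)
        perm = rng.permutation(30)
        reordered = first_pc_phenotype(X[perm])
        np.testing.assert_allclose(reordered.scores, base.scores[perm], atol=1e-8)

    def test_zero_variance_column_dropped(self, rng):
        X = rng.standard_normal((20, 4))
        X[:, 2] = 7.0
        res = first_pc_phenotype(X)
        assert res.kept_columns == [0, 1, 3]

    def test_degenerate_inputs_rejected(self, rng):
        with pytest.raises(ValidationError):
            first_pc_phenotype(np.ones((1, 5)))
        X = rng.standard_normal((10, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValidationError):
            first_pc_phenotype(X)
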