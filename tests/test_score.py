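"""Coding selection, weight derivation, scoring and score summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nafldscore import (
    PAPER_CODINGS,
    SCORE_SNP_IDS,
    GeneticRiskScore,
    categorize_score,
    compute_scores,
    derive_weights,
    group_score_summary,
    select_coding,
)
from nafldscore.errors import DegenerateInputError
from nafldscore.score import CodingSelection, WeightSet
from nafldscore.simulate import LiabilitySpec, simulate_cohort_liability
from tests.conftest import make_cohort

UNIT_WEIGHTS = WeightSet(
    raw={}, standardized={}, points={sid: 1 for sid in SCORE_SNP_IDS}, dropped={}
)
PAPER_SELECTION = CodingSelection.fixed(PAPER_CODINGS)


class TestDeriveWeights:
    def test_published_coefficients_give_unit_points(self):
        ws = derive_weights({"rs738409": 0.43, "rs58542926": 0.39, "rs3750861": 0.46})
        assert ws.points == {"rs738409": 1, "rs58542926": 1, "rs3750861": 1}
        assert ws.standardized["rs738409"] == pytest.approx(0.43 / 0.4266667, abs=1e-4)
        assert ws.standardized["rs58542926"] == pytest.approx(0.914, abs=1e-3)
        assert not ws.dropped
        assert ws.max_score(PAPER_SELECTION) == 4

    @given(st.floats(0.01, 10))
    def test_equal_coefficients_always_unit(self, c):
        ws = derive_weights({"a": c, "b": c, "c": c})
        assert ws.points == {"a": 1, "b": 1, "c": 1}

    def test_unequal_coefficients_arithmetic(self):
        ws = derive_weights({"a": 0.9, "b": 0.3, "c": 0.3})
        assert ws.points == {"a": 2, "b": 1, "c": 1}

    def test_scale_invariance(self):
        raw = {"a": 0.43, "b": 0.39, "c": 0.46}
        ws1 = derive_weights(raw)
        ws2 = derive_weights({k: 7.3 * v for k, v in raw.items()})
        assert ws1.points == ws2.points

    def test_zero_rounding_snp_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="dropped"):
            ws = derive_weights({"a": 1.0, "b": 1.0, "c": 0.1})
        assert "c" in ws.dropped
        assert ws.points == {"a": 1, "b": 1}

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(DegenerateInputError):
            derive_weights({"a": -0.5, "b": 0.2})

    def test_empty_rejected(self):
        with pytest.raises(DegenerateInputError):
            derive_weights({})


class TestCategorize:
    @pytest.mark.parametrize(
        "score, mode, label",
        [
            (0, "abstract", "0"),
            (1, "abstract", "1-2"),
            (2, "abstract", "1-2"),
            (3, "abstract", "3-4"),
            (4, "abstract", "3-4"),
            (0, "table", "0"),
            (2, "table", "2"),
            (3, "table", "3+"),
            (4, "table", "3+"),
        ],
    )
    def test_bands(self, score, mode, label):
        assert categorize_score(score, mode) == label

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            categorize_score(5, "abstract")
        with pytest.raises(ValueError):
            categorize_score(-1, "table")


class TestComputeScores:
    def test_printed_coding_examples(self):
        cohort = make_cohort(
            [
                {"rs738409": "GG", "rs58542926": "CT", "rs3750861": "CC"},  # 2+1+0
                {"rs738409": "CC", "rs58542926": "CC", "rs3750861": "CC"},  # 0
                {"rs738409": "GG", "rs58542926": "TT", "rs3750861": "TT"},  # max
            ]
        )
        scores = compute_scores(cohort, PAPER_SELECTION, UNIT_WEIGHTS)
        assert list(scores["score"]) == [3, 0, 4]
        assert list(scores["category_abstract"]) == ["3-4", "0", "3-4"]
        assert list(scores["category_table"]) == ["3+", "0", "3+"]

    def test_missing_genotype_excludes_subject(self):
        cohort = make_cohort(
            [
                {"rs738409": "NA"},
                {"rs738409": "CG"},
            ]
        )
        scores = compute_scores(cohort, PAPER_SELECTION, UNIT_WEIGHTS)
        assert scores["score"].isna().tolist() == [True, False]
        assert scores.attrs["excluded"] == ["s000"]


class TestSelectCoding:
    def test_identical_encodings_tie_to_additive(self):
        # no TT at TM6SF2: dominant and additive encodings coincide on {0,1}
        rows = []
        for grp, geno, k in [
            ("nafld", "CC", 30), ("nafld", "CT", 10),
            ("cirrhosis", "CC", 20), ("cirrhosis", "CT", 20),
        ]:
            rows += [{"group": grp, "rs58542926": geno}] * k
        entry = select_coding(make_cohort(rows), "rs58542926", ("cirrhosis", "nafld"))
        assert entry.chosen == "additive"
        assert entry.tied
        assert entry.aic["additive"] == pytest.approx(entry.aic["dominant"], abs=1e-6)

    def test_recessive_unavailable_without_minor_homozygotes(self):
        rows = (
            [{"group": "nafld", "rs3750861": "CC"}] * 25
            + [{"group": "nafld", "rs3750861": "CT"}] * 5
            + [{"group": "cirrhosis", "rs3750861": "CC"}] * 20
            + [{"group": "cirrhosis", "rs3750861": "CT"}] * 10
        )
        entry = select_coding(make_cohort(rows), "rs3750861", ("cirrhosis", "nafld"))
        assert "recessive" in entry.unavailable
        assert entry.chosen in ("additive", "dominant")

    def test_empty_contrast_group_rejected(self):
        cohort = make_cohort([{"group": "nafld"}] * 4)
        with pytest.raises(DegenerateInputError):
            select_coding(cohort, "rs738409", ("cirrhosis", "nafld"))

    def test_additive_truth_recovered(self):
        spec = LiabilitySpec(
            n=5000,
            maf={"rs738409": 0.3},
            effects={"rs738409": ("additive", 0.5)},
            intercept=-0.3,
        )
        cohort = simulate_cohort_liability(spec, seed=5)
        entry = select_coding(cohort, "rs738409", ("cirrhosis", "nafld"))
        assert entry.chosen == "additive"


class TestGroupSummary:
    def test_group_means_from_published_margins(self, study_cohort):
        scores = compute_scores(study_cohort, PAPER_SELECTION, UNIT_WEIGHTS)
        summary = group_score_summary(scores).set_index("group")
        assert summary.loc["nafld", "mean"] == pytest.approx(90 / 93 + 19 / 93 + 13 / 93)
        assert summary.loc["cirrhosis", "mean"] == pytest.approx(
            130 / 107 + 28 / 107 + 24 / 107
        )
        # distribution columns are per-group fractions summing to one
        pcols = [c for c in summary.columns if c.startswith("p")]
        np.testing.assert_allclose(summary[pcols].sum(axis=1), 1.0)

    def test_single_subject(self):
        cohort = make_cohort([{"rs738409": "GG"}])
        scores = compute_scores(cohort, PAPER_SELECTION, UNIT_WEIGHTS)
        summary = group_score_summary(scores)
        assert summary.loc[0, "mean"] == 2.0
        assert summary.loc[0, "sd"] == 0.0

    def test_linearity_of_group_mean(self, study_cohort):
        """Group mean score == sum of points x group mean encoded genotype."""
        scores = compute_scores(study_cohort, PAPER_SELECTION, UNIT_WEIGHTS)
        summary = group_score_summary(scores).set_index("group")
        for grp in ("healthy", "nafld", "cirrhosis"):
            mask = study_cohort.data["group"] == grp
            expected = sum(
                study_cohort.encoded(sid, PAPER_CODINGS[sid])[mask].mean()
                for sid in SCORE_SNP_IDS
            )
            assert summary.loc[grp, "mean"] == pytest.approx(expected, abs=1e-12)


class TestGeneticRiskScoreEstimator:
    @pytest.fixture()
    def fitted(self, study_cohort):
        mask = study_cohort.data["group"].isin(["cirrhosis", "nafld"])
        X = study_cohort.data.loc[mask, SCORE_SNP_IDS]
        y = (study_cohort.data.loc[mask, "group"] == "cirrhosis").astype(float)
        return GeneticRiskScore().fit(X, y), X

    def test_selects_reasonable_codings_and_unit_points(self, fitted):
        model, _ = fitted
        assert model.coding_selection_.scheme("rs738409") == "additive"
        assert set(model.weights_.points.values()) <= {1, 2}
        assert model.max_score_ >= 4

    def test_transform_matches_compute_scores(self, fitted, study_cohort):
        model, X = fitted
        transformed = model.transform(study_cohort.data[SCORE_SNP_IDS])
        frame = model.score_frame(study_cohort)
        np.testing.assert_allclose(
            transformed[:, 0], frame["score"].astype(float).to_numpy()
        )

    def test_deterministic_refit(self, fitted, study_cohort):
        model, X = fitted
        mask = study_cohort.data["group"].isin(["cirrhosis", "nafld"])
        y = (study_cohort.data.loc[mask, "group"] == "cirrhosis").astype(float)
        refit = GeneticRiskScore().fit(X, y)
        assert refit.weights_.points == model.weights_.points
        assert {
            k: e.chosen for k, e in refit.coding_selection_.entries.items()
        } == {k: e.chosen for k, e in model.coding_selection_.entries.items()}

    def test_sklearn_pipeline_compatible(self, study_cohort):
        from sklearn.pipeline import Pipeline

        mask = study_cohort.data["group"].isin(["cirrhosis", "nafld"])
        X = study_cohort.data.loc[mask, SCORE_SNP_IDS]
        y = (study_cohort.data.loc[mask, "group"] == "cirrhosis").astype(int)
        pipe = Pipeline(
            [
                ("grs", GeneticRiskScore(coding=PAPER_CODINGS)),
                ("clf", __import__("nafldscore").LogisticIRLS()),
            ]
        )
        pipe.fit(X, y)
        proba = pipe.predict_proba(X)
        assert proba.shape == (len(X), 2)

    def test_imposed_codings_skip_aic(self, study_cohort):
        mask = study_cohort.data["group"].isin(["cirrhosis", "nafld"])
        X = study_cohort.data.loc[mask, SCORE_SNP_IDS]
        y = (study_cohort.data.loc[mask, "group"] == "cirrhosis").astype(float)
        model = GeneticRiskScore(coding=PAPER_CODINGS).fit(X, y)
        assert model.coding_selection_.scheme("rs58542926") == "dominant"
        assert model.max_score_ == 4
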