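"""Patient aggregation, WB selection, classifier, CV, ROC and prevalence."""

import numpy as np
import pandas as pd
import pytest

from biodyn.chemosensitivity import (
    CVResult,
    TrialTable,
    aggregate_patient_biomarkers,
    bilinear_biomarkers,
    bilinear_columns,
    biomarker_prevalence,
    double_holdout_cv,
    roc_auc,
    select_biomarkers,
    train_classifier,
    wb_ratio,
)


def _table(X, outcomes=None, precond=None, holdouts=()):
    patients = X.index
    if outcomes is None:
        half = len(patients) // 2
        outcomes = pd.Series(
            ["resistant"] * half + ["sensitive"] * (len(patients) - half), index=patients
        )
    if precond is None:
        rng = np.random.default_rng(0)
        precond = pd.DataFrame(
            rng.standard_normal((len(patients), 3)), index=patients, columns=["NSD", "DR", "HW"]
        )
    return TrialTable(X=X, precond=precond, outcomes=outcomes, permanent_holdouts=holdouts)


def _noise_table(seed=0, n=28, n_cols=50):
    rng = np.random.default_rng(seed)
    patients = [f"pt{i:02d}" for i in range(n)]
    X = pd.DataFrame(
        rng.standard_normal((n, n_cols)),
        index=patients,
        columns=[f"drug{j % 4}:ALLF{j}" if False else f"drug{j % 4}:BM{j}" for j in range(n_cols)],
    )
    return _table(X)


class TestWBRatio:
    def test_identical_means_give_zero(self):
        assert wb_ratio([1.0, 2.0, 1.0, 2.0], ["a", "a", "b", "b"]) == 0.0

    def test_zero_within_spread_hits_cap(self):
        assert wb_ratio([0.0, 0.0, 1.0, 1.0], ["a", "a", "b", "b"]) == 100.0

    def test_hand_computed_value(self):
        # cohorts {0,1} vs {2,3}: between-sd |0.5-2.5|/2 = 1,
        # pooled within-sd sqrt(0.5) -> ratio sqrt(2)
        got = wb_ratio([0.0, 1.0, 2.0, 3.0], ["a", "a", "b", "b"])
        assert got == pytest.approx(np.sqrt(2.0), rel=1e-12)

    def test_single_cohort_rejected(self):
        with pytest.raises(ValueError):
            wb_ratio([1.0, 2.0], ["a", "a"])


class TestBilinear:
    def test_aligned_centered_signs(self):
        patients = list("abcd")
        X = pd.DataFrame({"drug:ALLF": [1.0, -1.0, 1.0, -1.0]}, index=patients)
        precond = pd.DataFrame(
            {"NSD": [1.0, -1.0, 1.0, -1.0], "DR": [0.0] * 4, "HW": [0.0] * 4}, index=patients
        )
        t = _table(X, precond=precond)
        aug = bilinear_biomarkers(t)
        assert np.allclose(aug.X["drug:ALLFxNSD"], 1.0)
        assert np.allclose(aug.X["drug:ALLFxDR"], 0.0)  # constant precondition

    def test_interaction_only_signal_found_by_bilinear(self):
        """Response sign depends on the NSD level: no linear column
        separates the cohorts, but the bilinear product does."""
        rng = np.random.default_rng(3)
        n = 28
        patients = [f"p{i:02d}" for i in range(n)]
        y = np.array([0] * 14 + [1] * 14)
        nsd = np.where(rng.random(n) < 0.5, -1.0, 1.0) + 0.05 * rng.standard_normal(n)
        resp = nsd * (2 * y - 1) + 0.3 * rng.standard_normal(n)  # sign flips with NSD
        X = pd.DataFrame({"drug:ALLF": resp}, index=patients)
        for j in range(20):
            X[f"drug:BM{j}"] = rng.standard_normal(n)
        precond = pd.DataFrame({"NSD": nsd, "DR": rng.standard_normal(n), "HW": rng.standard_normal(n)}, index=patients)
        outcomes = pd.Series(np.where(y == 0, "resistant", "sensitive"), index=patients)
        t = _table(X, outcomes=outcomes, precond=precond)
        aug = bilinear_biomarkers(t)
        sel = select_biomarkers(aug.X, y, top_n=3)
        linear_wb = dict(sel.ranking)["drug:ALLF"]
        assert sel.ranking[0][0] == "drug:ALLFxNSD"
        assert sel.ranking[0][1] > 3 * linear_wb

    def test_missing_preconditions_rejected(self):
        X = pd.DataFrame({"d:ALLF": np.arange(4.0)}, index=list("abcd"))
        t = _table(X, precond=pd.DataFrame({"NSD": np.ones(4)}, index=list("abcd")))
        with pytest.raises(ValueError):
            bilinear_biomarkers(t)


class TestSelection:
    def test_planted_columns_dominate(self):
        rng = np.random.default_rng(5)
        t = _noise_table(seed=5)
        y = (t.outcomes == "sensitive").astype(int)
        X = t.X.copy()
        for c in ("drug0:BM0", "drug1:BM1", "drug2:BM2"):
            X[c] = rng.standard_normal(len(X)) + 2.0 * y.to_numpy()
        sel = select_biomarkers(X, y, top_n=5)
        assert {"drug0:BM0", "drug1:BM1", "drug2:BM2"} <= set(sel.columns)

    def test_full_ranking_when_top_n_is_all(self):
        t = _noise_table(seed=1)
        y = (t.outcomes == "sensitive").astype(int)
        sel = select_biomarkers(t.X, y, top_n=t.X.shape[1])
        assert len(sel.columns) == t.X.shape[1]
        wbs = [v for _, v in sel.ranking]
        assert all(a >= b for a, b in zip(wbs, wbs[1:]))

    def test_permuted_labels_remove_the_signal(self):
        rng = np.random.default_rng(7)
        t = _noise_table(seed=7)
        y = (t.outcomes == "sensitive").astype(int).to_numpy()
        X = t.X.copy()
        informative = ["drug0:BM0", "drug1:BM1", "drug2:BM2"]
        for c in informative:
            X[c] = rng.standard_normal(len(X)) + 2.0 * y
        y_perm = rng.permutation(y)
        sel = select_biomarkers(X, y_perm, top_n=X.shape[1])
        ranking = pd.Series(dict(sel.ranking))
        noise_wb = ranking.drop(informative)
        # informative columns' WB under permuted labels is noise-like
        assert ranking[informative].mean() < noise_wb.mean() + 3 * noise_wb.std()


class TestClassifierAndROC:
    def test_separable_toy_reaches_perfect_training_accuracy(self):
        X = np.concatenate([np.random.default_rng(0).normal(-2, 0.3, 5), np.random.default_rng(1).normal(2, 0.3, 5)])[:, None]
        y = np.array([0] * 5 + [1] * 5)
        model = train_classifier(X, y, seed=0)
        assert (model.predict(X) == y).all()

    def test_same_seed_same_predictions(self):
        rng = np.random.default_rng(2)
        X, y = rng.standard_normal((12, 3)), rng.integers(0, 2, 12)
        y[:2], y[-2:] = 0, 1
        p1 = train_classifier(X, y, seed=9).predict_proba(X)
        p2 = train_classifier(X, y, seed=9).predict_proba(X)
        assert np.array_equal(p1, p2)

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            train_classifier(np.zeros((3, 2)), np.array([0, 1, 0]), seed=0)

    def test_roc_extremes(self):
        outcomes = pd.Series(
            ["sensitive", "sensitive", "resistant", "resistant", "resistant"],
            index=list("abcde"),
        )
        perfect = pd.Series({"a": 0.9, "b": 0.8, "c": 0.7, "d": 0.6, "e": 0.1})
        _, auc = roc_auc(perfect, outcomes)
        assert auc == 1.0
        _, auc_rev = roc_auc(1 - perfect, outcomes)
        assert auc_rev == 0.0

    def test_one_swap_matches_rank_sum_count(self):
        # sensitive {0.9, 0.65} vs resistant {0.7, 0.6, 0.1}:
        # winning pairs 5 of 6 -> AUC 5/6 (Mann-Whitney hand count)
        outcomes = pd.Series(
            ["sensitive", "sensitive", "resistant", "resistant", "resistant"],
            index=list("abcde"),
        )
        scores = pd.Series({"a": 0.9, "b": 0.65, "c": 0.7, "d": 0.6, "e": 0.1})
        _, auc = roc_auc(scores, outcomes)
        assert auc == pytest.approx(5 / 6)


class TestAggregation:
    def test_identical_replicates_average_to_themselves(self, small_trial):
        meta = small_trial["meta"]
        bm = small_trial["biomarkers"]
        table = aggregate_patient_biomarkers(meta, bm, small_trial["dataset"].outcomes)
        # single patient / drug sanity: mean of that patient's wells
        p, d = meta.iloc[0]["patient"], meta.iloc[0]["drug"]
        wells = meta.index[(meta["patient"] == p) & (meta["drug"] == d)]
        expected = bm.loc[wells, "ALLF"].mean()
        assert table.X.loc[p, f"{d}:ALLF"] == pytest.approx(expected)
        assert not table.imputed

    def test_censoring_creates_flagged_imputed_cells(self, small_trial):
        meta = small_trial["meta"]
        # drop every well of one (patient, drug) cell by hand
        p, d = meta.iloc[0]["patient"], meta.iloc[0]["drug"]
        keep = meta.index[~((meta["patient"] == p) & (meta["drug"] == d))]
        table = aggregate_patient_biomarkers(meta.loc[keep], small_trial["biomarkers"], small_trial["dataset"].outcomes)
        assert any(pp == p and cc.startswith(f"{d}:") for pp, cc in table.imputed)
        assert np.isfinite(table.X.to_numpy()).all()


class TestCrossValidation:
    def test_deterministic_under_seed(self):
        t = _noise_table(seed=9)
        cv1 = double_holdout_cv(t, n_runs=8, seed=3)
        cv2 = double_holdout_cv(t, n_runs=8, seed=3)
        assert cv1.scores.equals(cv2.scores)
        assert cv1.holdout_pairs == cv2.holdout_pairs
        assert cv1.selections == cv2.selections
        assert cv1.n_runs == 8

    def test_holdout_pairs_are_one_per_cohort(self):
        t = _noise_table(seed=4)
        cv = double_holdout_cv(t, n_runs=10, seed=1)
        for r, s in cv.holdout_pairs:
            assert t.outcomes[r] == "resistant"
            assert t.outcomes[s] == "sensitive"

    def test_permanent_holdouts_scored_but_never_trained(self):
        t = _noise_table(seed=2)
        perm = (t.outcomes.index[0], t.outcomes.index[-1])
        t2 = TrialTable(X=t.X, precond=t.precond, outcomes=t.outcomes, permanent_holdouts=perm)
        cv = double_holdout_cv(t2, n_runs=6, seed=0)
        for p in perm:
            assert p in cv.scores.index
            assert all(p not in pair for pair in cv.holdout_pairs)

    def test_selection_independent_of_held_out_pair_values(self):
        """Mutation test: arbitrary changes to the held-out pair leave the
        fold's biomarker selection (and training matrix) unchanged."""
        t = _noise_table(seed=6)
        cv = double_holdout_cv(t, n_runs=4, seed=11)
        for run in range(4):
            pair = cv.holdout_pairs[run]
            mutated = t.X.copy()
            mutated.loc[list(pair)] = 1e3
            t_mut = TrialTable(
                X=mutated, precond=t.precond, outcomes=t.outcomes,
            )
            # rebuild the same fold by hand: training rows identical
            train = [p for p in t.outcomes.index if p not in pair]
            y = (t.outcomes == "sensitive").astype(int)
            X1 = pd.concat([t.X, bilinear_columns(t.X, t.precond, train)], axis=1)
            X2 = pd.concat([mutated, bilinear_columns(mutated, t.precond, train)], axis=1)
            assert X1.loc[train].equals(X2.loc[train])
            s1 = select_biomarkers(X1.loc[train], y.loc[train], top_n=10)
            s2 = select_biomarkers(X2.loc[train], y.loc[train], top_n=10)
            assert s1.ranking == s2.ranking
            assert s1.columns == cv.selections[run]

    def test_cohort_too_small_rejected(self):
        rng = np.random.default_rng(0)
        patients = list("abcdef")
        X = pd.DataFrame(rng.standard_normal((6, 4)), index=patients, columns=[f"d:BM{i}" for i in range(4)])
        outcomes = pd.Series(["resistant"] * 2 + ["sensitive"] * 4, index=patients)
        t = _table(X, outcomes=outcomes)
        with pytest.raises(ValueError):
            double_holdout_cv(t, n_runs=4, seed=0)


class TestPrevalence:
    def test_identical_selections_have_unit_prevalence(self):
        cv = CVResult(
            scores=pd.Series(dtype=float),
            holdout_pairs=[],
            selections=[["cisplatin:ALLFT", "cisplatin:CDIPxNSD"]] * 5,
            n_runs=5,
            seed=0,
        )
        prev = biomarker_prevalence(cv)
        assert prev["by_column"]["cisplatin:ALLFT"] == 1.0
        assert prev["by_drug"]["cisplatin"] == 1.0
        # bilinear column counts both its response biomarker and precondition
        assert prev["by_feature"]["CDIP"] == 1.0
        assert prev["by_feature"]["NSD"] == 1.0
        assert prev["by_feature"]["ALLFT"] == 1.0

    def test_empty_selections_rejected(self):
        cv = CVResult(pd.Series(dtype=float), [], [], 0, 0)
        with pytest.raises(ValueError):
            biomarker_prevalence(cv)
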