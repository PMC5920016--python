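"""PC-regression training, cohort scoring, percentiles, and combination."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from coxenpipe import (
    BiomarkerSet,
    CombinationModel,
    DrugActivityProfile,
    ExpressionPanel,
    SimulationConfig,
    fit_combination,
    fit_drug_model,
    generate_cell_line_panel,
    generate_patient_cohort,
    predict_combination,
    score_cohort,
    select_coxen_genes,
    to_rank_percentile,
)
from coxenpipe.discovery import rank_candidates
from coxenpipe.exceptions import (
    ConfigValidationError,
    FitError,
    PredictionError,
    ScoringError,
)


def _panel(values, name="p"):
    g, s = values.shape
    return ExpressionPanel(
        pd.DataFrame(
            values,
            index=[f"G{i:03d}" for i in range(g)],
            columns=[f"S{i:03d}" for i in range(s)],
        ),
        name=name,
    )


def _profile(values, panel, drug="T"):
    return DrugActivityProfile(
        drug=drug, activity=pd.Series(values, index=panel.sample_ids)
    )


class TestFitDrugModel:
    def test_single_gene_noiseless_fit_is_exact(self, rng):
        x = rng.normal(size=20)
        panel = _panel(x[None, :])
        z = (x - x.mean()) / x.std(ddof=1)
        profile = _profile(3 * z, panel)
        model = fit_drug_model(
            panel, profile, BiomarkerSet(drug="T", genes=["G000"]), n_components_rule=1
        )
        fitted = score_cohort(model, panel)
        np.testing.assert_allclose(fitted, profile.activity, atol=1e-10)

    def test_full_components_equal_ols(self, rng):
        """With all components kept and fewer genes than samples, PC
        regression reproduces OLS on the standardized genes."""
        g, n = 6, 30
        X = rng.normal(size=(g, n))
        panel = _panel(X)
        y = rng.normal(size=n)
        profile = _profile(y, panel)
        model = fit_drug_model(
            panel,
            profile,
            BiomarkerSet(drug="T", genes=panel.gene_ids),
            n_components_rule=g,
        )
        fitted = score_cohort(model, panel)
        Z = (X.T - X.mean(axis=1)) / X.std(axis=1, ddof=1)
        design = np.column_stack([np.ones(n), Z])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        ols_fitted = design @ beta
        np.testing.assert_allclose(fitted.to_numpy(), ols_fitted, atol=1e-8)

    def test_training_r2_matches_brute_force_projection(self, small_study):
        """Model-reported fit equals an independent reimplementation of
        standardize -> project -> regress."""
        panel, profiles, _, truth, _ = small_study
        genes = truth.signature_genes["T"]
        model = fit_drug_model(
            panel, profiles["T"], BiomarkerSet(drug="T", genes=list(genes))
        )
        fitted = score_cohort(model, panel)
        # brute force with numpy only
        X = panel.subset_genes(genes).values.T
        Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        k = model.n_components
        _, _, Vt = np.linalg.svd(Z, full_matrices=False)
        scores = Z @ Vt[:k].T
        D = np.column_stack([np.ones(Z.shape[0]), scores])
        y = profiles["T"].aligned_to(panel).to_numpy()
        beta, *_ = np.linalg.lstsq(D, y, rcond=None)
        brute = D @ beta
        ss = lambda v: ((v - v.mean()) ** 2).sum()
        r2_model = 1 - ss(y - fitted.to_numpy()) / ss(y)
        r2_brute = 1 - ss(y - brute) / ss(y)
        assert r2_model == pytest.approx(r2_brute, rel=1e-10)

    def test_loadings_orthonormal(self, small_study):
        panel, profiles, _, truth, _ = small_study
        model = fit_drug_model(
            panel, profiles["T"], BiomarkerSet(drug="T", genes=truth.signature_genes["T"])
        )
        gram = model.loadings.T @ model.loadings
        np.testing.assert_allclose(gram, np.eye(model.n_components), atol=1e-10)

    def test_missing_biomarker_gene_fails(self, small_study):
        panel, profiles, _, _, _ = small_study
        with pytest.raises(FitError, match="GHOST"):
            fit_drug_model(
                panel, profiles["T"], BiomarkerSet(drug="T", genes=["GHOST"])
            )

    def test_excess_components_reduced_with_warning(self, rng, caplog):
        panel = _panel(rng.normal(size=(3, 10)))
        profile = _profile(rng.normal(size=10), panel)
        model = fit_drug_model(
            panel, profile, BiomarkerSet(drug="T", genes=panel.gene_ids),
            n_components_rule=50,
        )
        assert model.n_components == 3


class TestScoreCohort:
    def test_training_round_trip(self, small_study):
        panel, profiles, _, truth, _ = small_study
        model = fit_drug_model(
            panel, profiles["T"], BiomarkerSet(drug="T", genes=truth.signature_genes["T"])
        )
        raw = score_cohort(model, panel)
        Z = panel.subset_genes(model.genes).values.T
        Z = (Z - Z.mean(axis=0)) / Z.std(axis=0, ddof=1)
        expected = model.intercept + Z @ model.loadings @ model.coefficients
        np.testing.assert_allclose(raw.to_numpy(), expected, atol=1e-10)

    def test_shift_invariance_of_cohort_standardization(self, small_study, rng):
        panel, profiles, _, truth, reference = small_study
        model = fit_drug_model(
            panel, profiles["T"], BiomarkerSet(drug="T", genes=truth.signature_genes["T"])
        )
        base = score_cohort(model, reference.panel)
        shifted = ExpressionPanel(reference.panel.data + 5.0, name="shifted")
        np.testing.assert_allclose(
            base.to_numpy(), score_cohort(model, shifted).to_numpy(), atol=1e-10
        )

    def test_scoring_is_linear_in_standardized_expression(self, small_study):
        panel, profiles, _, truth, reference = small_study
        model = fit_drug_model(
            panel, profiles["T"], BiomarkerSet(drug="T", genes=truth.signature_genes["T"])
        )
        raw = score_cohort(model, reference.panel).to_numpy()
        # cohort standardization absorbs per-gene scaling of the input, so
        # linearity is checked through the coefficients: doubling them
        # doubles the centered scores
        model2 = fit_drug_model(
            panel, profiles["T"], BiomarkerSet(drug="T", genes=truth.signature_genes["T"])
        )
        model2.coefficients = model.coefficients * 2
        raw2 = score_cohort(model2, reference.panel).to_numpy()
        np.testing.assert_allclose(
            raw2 - raw2.mean(), 2 * (raw - raw.mean()), atol=1e-10
        )

    def test_heldout_scores_track_true_score(self):
        rs = []
        for seed in range(3):
            cfg = SimulationConfig(n_drugs=1, seed=seed)
            panel, profiles, tissue, truth = generate_cell_line_panel(cfg)
            ref = generate_patient_cohort(cfg, truth, cohort_id=0, tag="ref")
            heldout = generate_patient_cohort(cfg, truth, cohort_id=1, tag="val")
            cands = rank_candidates(panel, profiles["T"], "pearson", top_k=500)
            bset = select_coxen_genes(cands, panel, ref.panel, 33, drug="T")
            model = fit_drug_model(panel, profiles["T"], bset)
            raw = score_cohort(model, heldout.panel)
            ts = truth.patient_truth["val"]["true_score"]
            rs.append(np.corrcoef(raw.loc[ts.index], ts)[0, 1])
        assert all(r > 0.5 for r in rs)

    def test_too_many_missing_genes_fails(self, small_study):
        panel, profiles, _, truth, reference = small_study
        genes = truth.signature_genes["T"]
        model = fit_drug_model(
            panel, profiles["T"], BiomarkerSet(drug="T", genes=genes)
        )
        reduced = ExpressionPanel(
            reference.panel.data.drop(index=genes[:3]), name="reduced"
        )
        with pytest.raises(ScoringError):
            score_cohort(model, reduced)

    def test_few_missing_genes_mean_imputed(self, small_study):
        panel, profiles, _, truth, reference = small_study
        genes = truth.signature_genes["T"]
        model = fit_drug_model(panel, profiles["T"], BiomarkerSet(drug="T", genes=genes))
        reduced = ExpressionPanel(
            reference.panel.data.drop(index=genes[:1]), name="reduced"
        )
        raw = score_cohort(model, reduced)
        assert np.isfinite(raw).all()


class TestRankPercentile:
    def test_forced_examples(self):
        np.testing.assert_allclose(
            to_rank_percentile(pd.Series([5.0, 1.0, 3.0])), [1.0, 0.0, 0.5]
        )
        np.testing.assert_allclose(
            to_rank_percentile(pd.Series([2.0, 2.0, 4.0])), [0.25, 0.25, 1.0]
        )

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=25)
        a = to_rank_percentile(pd.Series(x))
        b = to_rank_percentile(pd.Series(np.exp(3 * x)))
        np.testing.assert_allclose(a, b)

    def test_distinct_scores_give_exact_grid(self, rng):
        n = 17
        x = rng.permutation(np.arange(n, dtype=float))
        pct = np.sort(to_rank_percentile(pd.Series(x)).to_numpy())
        np.testing.assert_allclose(pct, np.arange(n) / (n - 1))

    def test_all_tied_warns_and_returns_half(self):
        with pytest.warns(UserWarning, match="tied"):
            out = to_rank_percentile(pd.Series([1.0, 1.0, 1.0]))
        assert (out == 0.5).all()


class TestCombination:
    def _pct(self, rng, n=60, drugs=("T", "A")):
        idx = [f"P{i:02d}" for i in range(n)]
        return {
            d: pd.Series(np.round(rng.random(n), 3), index=idx) for d in drugs
        }

    def test_single_drug_logistic_preserves_ranking(self, rng):
        pct = self._pct(rng, drugs=("T",))
        score = pct["T"]
        labels = pd.Series(
            np.where(rng.random(60) < 0.2 + 0.6 * score, "pCR", "RD"), index=score.index
        )
        model = fit_combination(pct, labels, mode="logistic")
        combined = predict_combination(model, pct)
        order_a = score.sort_values().index
        order_b = combined.sort_values().index
        assert list(order_a) == list(order_b) or list(order_a) == list(order_b[::-1])

    def test_equal_weight_is_mean(self):
        pct = {
            "T": pd.Series([0.2], index=["p"]),
            "A": pd.Series([0.8], index=["p"]),
        }
        model = fit_combination(pct, None, mode="equal_weight")
        assert predict_combination(model, pct)["p"] == pytest.approx(0.5)

    def test_null_logistic_model_predicts_half(self):
        model = CombinationModel(
            drugs=["T", "A"], mode="logistic", intercept=0.0,
            coefficients={"T": 0.0, "A": 0.0},
        )
        pct = {
            "T": pd.Series([0.1, 0.9]),
            "A": pd.Series([0.4, 0.6]),
        }
        np.testing.assert_allclose(predict_combination(model, pct), 0.5)

    def test_matches_logistic_formula_at_random_coefficients(self, rng):
        pct = self._pct(rng)
        for _ in range(5):
            b0 = rng.normal()
            bT, bA = rng.normal(size=2)
            model = CombinationModel(
                drugs=["T", "A"], mode="logistic", intercept=b0,
                coefficients={"T": bT, "A": bA},
            )
            out = predict_combination(model, pct)
            expected = expit(b0 + bT * pct["T"] + bA * pct["A"])
            np.testing.assert_allclose(out.to_numpy(), expected.to_numpy(), atol=1e-12)

    def test_output_invariant_to_key_order(self, rng):
        pct = self._pct(rng)
        model = CombinationModel(
            drugs=["T", "A"], mode="logistic", intercept=0.3,
            coefficients={"T": 1.0, "A": -0.5},
        )
        a = predict_combination(model, pct)
        b = predict_combination(model, dict(reversed(list(pct.items()))))
        np.testing.assert_allclose(a, b)

    def test_missing_drug_named_in_error(self, rng):
        pct = self._pct(rng, drugs=("T",))
        model = CombinationModel(
            drugs=["T", "A"], mode="logistic", intercept=0.0,
            coefficients={"T": 1.0, "A": 1.0},
        )
        with pytest.raises(PredictionError, match="A"):
            predict_combination(model, pct)

    def test_separation_falls_back_to_equal_weight(self):
        pct = {"T": pd.Series([0.1, 0.2, 0.8, 0.9])}
        labels = pd.Series(["RD", "RD", "pCR", "pCR"])
        model = fit_combination(pct, labels, mode="logistic")
        assert model.mode == "equal_weight"

    def test_single_class_labels_rejected(self):
        pct = {"T": pd.Series([0.1, 0.2, 0.8])}
        with pytest.raises(FitError):
            fit_combination(pct, pd.Series(["RD", "RD", "RD"]), mode="logistic")

    def test_combining_two_informative_drugs_not_worse_than_best_single(self):
        """Fusion of two independent informative drugs keeps (nearly) the
        best single-drug AUC on held-out patients."""
        from coxenpipe.evaluation import auc

        deltas = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 400
            sT, sA = rng.normal(size=n), rng.normal(size=n)
            prob = expit(-0.5 + 1.2 * sT + 1.2 * sA)
            y = (rng.random(n) < prob).astype(int)
            idx = [f"P{i}" for i in range(n)]
            pct = {
                "T": to_rank_percentile(pd.Series(sT + rng.normal(size=n), index=idx)),
                "A": to_rank_percentile(pd.Series(sA + rng.normal(size=n), index=idx)),
            }
            labels = pd.Series(np.where(y == 1, "pCR", "RD"), index=idx)
            half = n // 2
            fit_idx, val_idx = idx[:half], idx[half:]
            model = fit_combination(
                {d: p.loc[fit_idx] for d, p in pct.items()}, labels.loc[fit_idx]
            )
            combined = predict_combination(
                model, {d: p.loc[val_idx] for d, p in pct.items()}
            )
            yv = labels.loc[val_idx]
            auc_comb = auc(combined, yv)
            auc_single = max(auc(pct[d].loc[val_idx], yv) for d in ("T", "A"))
            deltas.append(auc_comb - auc_single)
        assert np.mean(deltas) >= -0.02
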