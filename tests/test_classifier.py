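import itertools

import numpy as np
import pandas as pd
import pytest

from methpred import classifier as clf
from methpred import simcohort
from methpred.classifier import (
    NO_CALL,
    ClassifierModel,
    dlda_train,
    evaluate,
    loocv,
    probe_auc,
    published_array_model,
    recalibrate_threshold,
    score,
    select_features,
)
from methpred.formats_io import BetaMatrix


def _bm(values, probes=None, samples=None, scale="array"):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"cg{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{i}" for i in range(values.shape[1])]
    return BetaMatrix(pd.DataFrame(values, index=probes, columns=samples), scale)


def _labels(n_pos, n_neg, samples=None):
    lab = ["pCR"] * n_pos + ["pIR"] * n_neg
    samples = samples or [f"S{i}" for i in range(len(lab))]
    return pd.Series(lab, index=samples)


class TestProbeAUC:
    def test_perfect_separation(self):
        assert probe_auc([0.9, 0.8, 0.1, 0.2], ["pCR", "pCR", "pIR", "pIR"]) == 1.0

    def test_identical_tied_values(self):
        assert probe_auc([0.5] * 6, ["pCR"] * 3 + ["pIR"] * 3) == 0.5

    def test_three_of_four_concordant_pairs(self):
        v = [0.1, 0.2, 0.15, 0.3]
        assert probe_auc(v, ["pCR", "pCR", "pIR", "pIR"]) == pytest.approx(0.75)

    def test_one_empty_class_rejected(self):
        with pytest.raises(ValueError):
            probe_auc([0.1, 0.2], ["pCR", "pCR"])


class TestSelectFeatures:
    def test_duplicated_informative_probe_kept_once(self):
        rng = np.random.default_rng(0)
        n = 20
        lab = _labels(10, 10)
        signal = np.clip(np.where(np.arange(n) < 10, 0.7, 0.3) + rng.normal(0, 0.05, n), 0.01, 0.99)
        noise = np.clip(rng.uniform(0.2, 0.8, size=(4, n)), 0.01, 0.99)
        bm = _bm(np.vstack([signal, signal, noise]), probes=["dupA", "dupB", "n0", "n1", "n2", "n3"])
        kept = select_features(bm.probe_ids, bm, lab)
        assert sum(k in ("dupA", "dupB") for k in kept) == 1

    def test_pure_noise_yields_empty_list(self):
        rng = np.random.default_rng(1)
        lab = _labels(8, 8)
        bm = _bm(rng.uniform(0.4, 0.6, size=(6, 16)))
        assert select_features(bm.probe_ids, bm, lab, p_enter=1e-6) == []

    def test_agrees_with_all_subsets_bic_oracle_in_majority(self):
        """Stepwise choice vs brute-force best-BIC over all 2^10 subsets.

        Three strong independent probes among ten; the oracle fits every
        subset by least squares and ranks by BIC. Agreement on a majority of
        seeds (the criteria differ, so occasional divergence is expected).
        """
        agree = 0
        n_seeds = 30
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n = 30
            y = np.array([1.0] * 15 + [0.0] * 15)
            x = rng.uniform(0.3, 0.7, size=(10, n))
            for j in range(3):  # strong probes 0..2
                x[j] = np.clip(0.45 + 0.2 * (y - 0.5) * 2 + rng.normal(0, 0.07, n), 0.01, 0.99)
            bm = _bm(np.clip(x, 0.01, 0.99))
            lab = _labels(15, 15)
            kept = set(select_features(bm.probe_ids, bm, lab))
            best, best_bic = None, np.inf
            cols = list(bm.probe_ids)
            xt = bm.values.T.to_numpy()
            for r in range(1, 11):
                for comb in itertools.combinations(range(10), r):
                    design = np.column_stack([np.ones(n), xt[:, comb]])
                    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
                    rss = float(((y - design @ beta) ** 2).sum())
                    bic = n * np.log(rss / n) + (r + 1) * np.log(n)
                    if bic < best_bic:
                        best, best_bic = {cols[j] for j in comb}, bic
            agree += kept == best
        assert agree > n_seeds / 2


class TestDLDA:
    def test_one_marker_threshold_at_midpoint(self):
        rng = np.random.default_rng(2)
        pos = 0.5 + rng.normal(0, 0.05, 10)
        neg = 0.3 + rng.normal(0, 0.05, 10)
        bm = _bm(np.concatenate([pos, neg])[None, :], probes=["cgM"])
        lab = _labels(10, 10)
        model = dlda_train(bm, lab, ["cgM"])
        mu_p, mu_n = pos.mean(), neg.mean()
        s2 = (pos.var(ddof=1) * 9 + neg.var(ddof=1) * 9) / 18
        w = (mu_p - mu_n) / s2
        assert model.weights[0] == pytest.approx(w)
        assert model.threshold == pytest.approx(w * (mu_p + mu_n) / 2)
        assert model.orientation == "pCR_high"

    def test_matches_diagonal_gaussian_bayes_oracle(self):
        """Trained rule's labels equal the shared-diagonal-covariance Bayes rule."""
        rng = np.random.default_rng(3)
        mu_p = np.array([0.6, 0.4, 0.55])
        mu_n = np.array([0.45, 0.55, 0.35])
        sd = np.array([0.06, 0.08, 0.1])
        train_p = np.clip(rng.normal(mu_p[:, None], sd[:, None], (3, 30)), 0.01, 0.99)
        train_n = np.clip(rng.normal(mu_n[:, None], sd[:, None], (3, 30)), 0.01, 0.99)
        bm = _bm(np.hstack([train_p, train_n]))
        lab = _labels(30, 30)
        model = dlda_train(bm, lab)
        # oracle uses the same plug-in estimates but the raw Gaussian densities
        xp = bm.values.iloc[:, :30].to_numpy()
        xn = bm.values.iloc[:, 30:].to_numpy()
        m_p, m_n = xp.mean(1), xn.mean(1)
        s2 = (29 * xp.var(1, ddof=1) + 29 * xn.var(1, ddof=1)) / 58
        test_x = np.clip(rng.uniform(0.2, 0.8, size=(3, 200)), 0.01, 0.99)
        for i in range(200):
            x = test_x[:, i]
            loglik_p = -0.5 * np.sum((x - m_p) ** 2 / s2)
            loglik_n = -0.5 * np.sum((x - m_n) ** 2 / s2)
            bayes = "pCR" if loglik_p > loglik_n else "pIR"
            assert score(model, x)[1] == bayes

    def test_equal_class_means_degenerate(self, caplog):
        v = np.tile([0.2, 0.5, 0.8], 2)[None, :].repeat(2, axis=0)
        bm = _bm(v)
        with caplog.at_level("WARNING"):
            model = dlda_train(bm, _labels(3, 3))
        assert all(w == 0 for w in model.weights)
        assert any("degenerate" in r.message for r in caplog.records)

    def test_zero_variance_marker_rejected(self):
        v = np.array([[0.5] * 6, [0.2, 0.3, 0.4, 0.6, 0.7, 0.8]])
        bm = _bm(v)
        with pytest.raises(ValueError, match="cg0"):
            dlda_train(bm, _labels(3, 3))


class TestScore:
    def test_published_model_arithmetic(self):
        model = published_array_model()
        assert model.weights == (-19.3, -11.2, -24.6)
        assert score(model, [0, 0, 0])[0] == 0.0
        assert score(model, [1, 1, 1])[0] == pytest.approx(-55.1)

    def test_classification_flips_at_threshold_for_both_orientations(self):
        for orientation in ("pCR_high", "pCR_low"):
            model = published_array_model(orientation)
            x_at = model.threshold / model.weights[0]
            below = score(model, [x_at + 1e-9, 0, 0])[1]  # weight negative: score < tau
            above = score(model, [x_at - 1e-9, 0, 0])[1]
            assert {below, above} == {"pCR", "pIR"}
            if orientation == "pCR_high":
                assert above == "pCR"
            else:
                assert above == "pIR"

    def test_missing_marker_gives_no_call(self):
        model = published_array_model()
        s, lab = score(model, [0.5, np.nan, 0.5])
        assert lab == NO_CALL and np.isnan(s)

    def test_linearity(self):
        rng = np.random.default_rng(4)
        model = ClassifierModel(("a", "b", "c"), tuple(rng.normal(size=3)), 0.0)
        for _ in range(20):
            x, y = rng.normal(size=3), rng.normal(size=3)
            a, b = rng.normal(size=2)
            lhs = score(model, a * x + b * y)[0]
            rhs = a * score(model, x)[0] + b * score(model, y)[0]
            assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9)

    def test_model_json_round_trip(self, tmp_path):
        model = published_array_model("pCR_low")
        p = tmp_path / "m.json"
        model.to_json(p)
        assert ClassifierModel.from_json(p) == model


class TestLOOCV:
    def _cohort(self, seed=0, n_pos=11, n_neg=21, delta=0.3, sd=0.05):
        rng = np.random.default_rng(seed)
        markers = np.vstack(
            [
                np.concatenate(
                    [rng.normal(0.3 + delta, sd, n_pos), rng.normal(0.3, sd, n_neg)]
                )
                for _ in range(3)
            ]
        )
        noise = rng.uniform(0.2, 0.8, size=(5, n_pos + n_neg))
        bm = _bm(np.clip(np.vstack([markers, noise]), 0.01, 0.99))
        return bm, _labels(n_pos, n_neg)

    def test_separated_cohort_gives_full_sensitivity(self):
        bm, lab = self._cohort()
        res = loocv(bm, lab, markers=["cg0", "cg1", "cg2"])
        assert res.sensitivity == 1.0

    def test_equals_per_fold_rebuild_oracle(self):
        """LOOCV labels equal a from-scratch numpy rebuild of each fold."""
        bm, lab = self._cohort(seed=9, delta=0.08, sd=0.08)  # imperfect problem
        markers = ["cg0", "cg1", "cg2"]
        res = loocv(bm, lab, markers=markers)
        x = bm.values.loc[markers]
        for held in bm.sample_ids:
            train = [s for s in bm.sample_ids if s != held]
            xp = x[[s for s in train if lab[s] == "pCR"]].to_numpy()
            xn = x[[s for s in train if lab[s] == "pIR"]].to_numpy()
            mp, mn = xp.mean(1), xn.mean(1)
            s2 = (
                (xp.shape[1] - 1) * xp.var(1, ddof=1) + (xn.shape[1] - 1) * xn.var(1, ddof=1)
            ) / (xp.shape[1] + xn.shape[1] - 2)
            w = (mp - mn) / s2
            tau = float(w @ ((mp + mn) / 2))
            s = float(w @ x[held].to_numpy())
            pcr_high = float(w @ mp) >= tau
            expect = ("pCR" if s > tau else "pIR") if pcr_high else ("pCR" if s < tau else "pIR")
            assert res.predicted[held] == expect

    def test_shuffled_labels_give_chance_auc(self):
        """Permutation null: mean LOOCV AUC ~ 0.5 over 100 label shuffles."""
        rng = np.random.default_rng(11)
        base = rng.uniform(0.2, 0.8, size=(3, 20))
        bm = _bm(np.clip(base, 0.01, 0.99))
        aucs = []
        for _ in range(100):
            lab = pd.Series(
                rng.permutation(["pCR"] * 8 + ["pIR"] * 12), index=bm.sample_ids
            )
            res = loocv(bm, lab, markers=list(bm.probe_ids))
            aucs.append(res.auc)
        mc_se = np.std(aucs, ddof=1) / np.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) <= 2 * mc_se + 1e-9

    def test_nested_mode_never_sees_held_out_sample(self):
        bm, lab = self._cohort(seed=5)
        seen: list[list] = []
        res = loocv(
            bm,
            lab,
            mode="nested",
            candidates=list(bm.probe_ids),
            usage_hook=seen.append,
        )
        held_order = [s for s in bm.sample_ids]
        assert len(seen) == len(held_order)
        for held, train_ids in zip(held_order, seen):
            assert held not in train_ids

    def test_sensitivity_specificity_envelope_at_validation_sizes(self):
        """LOOCV on 16/52 cohorts with marker AUCs ~0.70-0.75: mean sensitivity
        >= 60% and specificity >= 50% — a plausibility envelope, not an exact
        reproduction of any printed figure."""
        sens, spec = [], []
        for seed in range(30):
            cfg = simcohort.SimConfig(seed=seed, n_probes=10, n_pCR=16, n_pIR=52)
            bm, _, sheet, _ = simcohort.generate_cohort(cfg)
            lab = sheet.table["group"]
            tum = bm.subset_samples(lab.index[lab != "NT"])
            res = loocv(tum, lab, markers=list(simcohort.MARKER_IDS))
            sens.append(res.sensitivity)
            spec.append(res.specificity)
        assert np.mean(sens) >= 0.60
        assert np.mean(spec) >= 0.50


class TestRecalibration:
    def _model_and_data(self, seed=0):
        rng = np.random.default_rng(seed)
        bm, lab = TestLOOCV()._cohort(seed=seed, delta=0.15, sd=0.08)
        markers = ["cg0", "cg1", "cg2"]
        model = dlda_train(bm, lab, markers)
        return model, bm.subset_probes(markers), lab

    def test_scale_equivariance_under_pure_rescale(self):
        model, bm, lab = self._model_and_data()
        pyro = BetaMatrix(bm.values * 100.0, "pyro")
        new = recalibrate_threshold(model, pyro, lab)
        scores = np.asarray(model.weights) @ (100.0 * bm.values.to_numpy())
        gaps = np.diff(np.sort(np.unique(scores)))
        assert abs(new.threshold - 100.0 * model.threshold) <= gaps.max()
        assert new.scale == "pyro"

    def test_beats_or_matches_naively_scaled_threshold(self):
        model, bm, lab = self._model_and_data(seed=3)
        rng = np.random.default_rng(30)
        noisy = np.clip(bm.values * 100.0 + rng.normal(0, 4, bm.values.shape), 0, 100)
        pyro = BetaMatrix(noisy, "pyro")
        new = recalibrate_threshold(model, pyro, lab)

        def acc(tau):
            s = np.asarray(model.weights) @ pyro.values.to_numpy()
            pred = s > tau if model.orientation == "pCR_high" else s < tau
            return np.mean(pred == (lab.to_numpy() == "pCR"))

        assert acc(new.threshold) >= acc(100.0 * model.threshold)

    def test_matches_exhaustive_midpoint_scan(self):
        model, bm, lab = self._model_and_data(seed=7)
        pyro = BetaMatrix(bm.values * 100.0, "pyro")
        new = recalibrate_threshold(model, pyro, lab)
        s = np.asarray(model.weights) @ pyro.values.to_numpy()
        y = lab.to_numpy() == "pCR"
        sign = 1.0 if model.orientation == "pCR_high" else -1.0
        uniq = np.sort(np.unique(s))
        best = None
        for tau in (uniq[:-1] + uniq[1:]) / 2:
            pred = (sign * s) > (sign * tau)
            key = (np.mean(pred == y), np.mean(pred[y]), -tau)
            if best is None or key > best[0]:
                best = (key, tau)
        assert new.threshold == pytest.approx(best[1])

    def test_constant_scores_rejected(self):
        model, bm, lab = self._model_and_data()
        flat = BetaMatrix(bm.values * 0 + 50.0, "pyro")
        with pytest.raises(ValueError, match="identical"):
            recalibrate_threshold(model, flat, lab)


class TestEvaluate:
    def test_validation_sensitivity_printout(self):
        """15 of 16 pCR correct reports as 93.8% sensitivity."""
        true = pd.Series(["pCR"] * 16 + ["pIR"] * 4)
        pred = pd.Series(["pCR"] * 15 + ["pIR"] + ["pIR"] * 4)
        scores = pd.Series(np.linspace(1, 0, 20))
        res = evaluate(pred, true, scores)
        assert round(100 * res.sensitivity, 1) == 93.8

    def test_validation_specificity_printout(self):
        """35 of 52 pIR correct reports as 67.3% specificity."""
        true = pd.Series(["pIR"] * 52 + ["pCR"] * 3)
        pred = pd.Series(["pIR"] * 35 + ["pCR"] * 17 + ["pCR"] * 3)
        scores = pd.Series(np.zeros(55))
        res = evaluate(pred, true, scores)
        assert round(100 * res.specificity, 1) == 67.3

    def test_all_correct(self):
        true = pd.Series(["pCR", "pCR", "pIR", "pIR"])
        scores = pd.Series([0.9, 0.8, 0.1, 0.2])
        res = evaluate(true.copy(), true, scores)
        assert res.sensitivity == 1.0 and res.specificity == 1.0 and res.auc == 1.0

    def test_no_calls_counted_separately(self):
        true = pd.Series(["pCR", "pIR", "pIR"])
        pred = pd.Series(["pCR", NO_CALL, "pIR"])
        res = evaluate(pred, true, pd.Series([1.0, np.nan, 0.0]))
        assert res.n_no_call == 1
        assert res.tp + res.fp + res.tn + res.fn == 2

    def test_missing_class_metric_undefined(self):
        true = pd.Series(["pCR", "pCR"])
        res = evaluate(true.copy(), true, pd.Series([1.0, 0.9]))
        assert res.specificity is None and res.auc is None
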