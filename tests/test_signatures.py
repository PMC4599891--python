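"""Zero-transformation, fold filtering, signature creation/projection,
and signature regression."""

import numpy as np
import pandas as pd
import pytest

from poolscreen import (
    create_signature,
    fold_filter,
    make_expression_truth,
    project_signature,
    signature_regression,
    simulate_expression,
    zero_transform,
)


def _matrix(seed=0, n_genes=30, samples=("c1", "c2", "s1", "s2")):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(7, 1, size=(n_genes, len(samples))),
        index=[f"g{i}" for i in range(n_genes)],
        columns=list(samples),
    )


class TestZeroTransform:
    def test_control_means_become_zero(self):
        mat = _matrix()
        zt = zero_transform(mat, ["c1", "c2"])
        np.testing.assert_allclose(zt.values[["c1", "c2"]].mean(axis=1), 0.0, atol=1e-12)

    def test_single_control_column_exactly_zero(self):
        mat = _matrix()
        zt = zero_transform(mat, ["c1"])
        np.testing.assert_allclose(zt.values["c1"], 0.0, atol=1e-12)

    def test_matches_rowwise_subtraction_oracle(self):
        mat = _matrix(3)
        zt = zero_transform(mat, ["c1", "c2"])
        for g in mat.index:
            ctrl_mean = (mat.loc[g, "c1"] + mat.loc[g, "c2"]) / 2
            np.testing.assert_allclose(zt.values.loc[g], mat.loc[g] - ctrl_mean)

    def test_idempotent_given_same_controls(self):
        zt = zero_transform(_matrix(4), ["c1", "c2"])
        again = zero_transform(zt.values, ["c1", "c2"])
        np.testing.assert_allclose(again.values, zt.values, atol=1e-12)

    def test_absent_control_id_rejected(self):
        with pytest.raises(ValueError):
            zero_transform(_matrix(), ["nope"])


class TestFoldFilter:
    def test_boundary_inclusive_on_fold_scale(self):
        thr = np.log2(1.7)
        row = np.r_[np.full(6, thr), np.zeros(12)]
        zt = _as_zt(pd.DataFrame([row], index=["g0"]))
        assert len(fold_filter(zt, fold=1.7, min_arrays=6)) == 1
        assert len(fold_filter(zt, fold=1.7, min_arrays=6, strict=True)) == 0

    def test_all_zero_row_dropped(self):
        zt = _as_zt(pd.DataFrame(np.zeros((3, 8))))
        assert len(fold_filter(zt, fold=1.7, min_arrays=1)) == 0

    def test_matches_counting_loop_oracle(self):
        rng = np.random.default_rng(5)
        zt = _as_zt(pd.DataFrame(rng.normal(0, 1, size=(200, 12))))
        out = fold_filter(zt, fold=1.7, min_arrays=6)
        thr = np.log2(1.7)
        expect = [
            f"g{i}" for i in range(200)
            if sum(abs(x) >= thr for x in zt.values.iloc[i]) >= 6
        ]
        assert list(out.index) == expect

    def test_survivors_monotone_in_fold_and_min_arrays(self):
        rng = np.random.default_rng(6)
        zt = _as_zt(pd.DataFrame(rng.normal(0, 1, size=(300, 10))))
        n = [len(fold_filter(zt, fold=f, min_arrays=4)) for f in (1.3, 1.7, 2.5)]
        assert n == sorted(n, reverse=True)
        m = [len(fold_filter(zt, fold=1.7, min_arrays=k)) for k in (2, 5, 8)]
        assert m == sorted(m, reverse=True)

    def test_log2_scale_switch(self):
        zt = _as_zt(pd.DataFrame([[1.0, 1.0, 0.0]]))
        assert len(fold_filter(zt, fold=1.0, min_arrays=2, scale="log2")) == 1
        assert len(fold_filter(zt, fold=1.7, min_arrays=2, scale="log2")) == 0

    def test_min_arrays_exceeding_samples_rejected(self):
        zt = _as_zt(pd.DataFrame(np.ones((2, 4))))
        with pytest.raises(ValueError):
            fold_filter(zt, min_arrays=5)


def _as_zt(df):
    from poolscreen.signatures import ZeroTransformedMatrix

    df = df.copy()
    df.index = [f"g{i}" for i in range(len(df))]
    return ZeroTransformedMatrix(values=df, control_ids=[])


def _two_class(seed, effect, noise, n_per_class=6, n_genes=300, n_de=40):
    truth = make_expression_truth(n_genes=n_genes, n_de=n_de, overlap=0.6, seed=seed)
    mat, lab = simulate_expression(
        truth, samples_per_class=n_per_class, effect_size=effect,
        noise_sd=noise, seed=seed + 1,
    )
    ctrl = list(lab.index[lab == 0])
    kd = list(lab.index[lab == 1])
    return zero_transform(mat, ctrl), ctrl, kd


class TestSignatureModel:
    def test_perfect_separation_classifies_training_samples(self):
        zt, ctrl, kd = _two_class(seed=0, effect=2.0, noise=0.0)
        model = create_signature(zt, ctrl, kd, n_sig=50, k_factors=2)
        p = project_signature(model, zt.values)
        assert (p[ctrl] < 0.5).all() and (p[kd] > 0.5).all()

    def test_null_classes_give_probabilities_near_half(self):
        # no planted effect: mean training probability ~0.5 over repeats
        means = []
        for seed in range(20):
            zt, ctrl, kd = _two_class(seed=seed, effect=0.0, noise=0.5)
            model = create_signature(zt, ctrl, kd, n_sig=50)
            means.append(project_signature(model, zt.values).mean())
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - 0.5) < 3 * se

    def test_projection_ignores_genes_outside_signature(self):
        zt, ctrl, kd = _two_class(seed=2, effect=1.0, noise=0.5)
        model = create_signature(zt, ctrl, kd, n_sig=50)
        p1 = project_signature(model, zt.values)
        perturbed = zt.values.copy()
        outside = [g for g in perturbed.index if g not in set(model.genes)]
        perturbed.loc[outside] += 100.0
        p2 = project_signature(model, perturbed)
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_missing_signature_genes_rejected_with_ids(self):
        zt, ctrl, kd = _two_class(seed=3, effect=1.0, noise=0.5)
        model = create_signature(zt, ctrl, kd, n_sig=50)
        test = zt.values.drop(index=model.genes[:3])
        with pytest.raises(ValueError, match=model.genes[0]):
            project_signature(model, test)

    def test_heldout_recovery(self):
        # simulated two-class data: held-out samples on the correct side
        correct = total = 0
        for seed in range(20):
            truth = make_expression_truth(n_genes=500, n_de=50, overlap=0.6, seed=seed)
            mat, lab = simulate_expression(truth, samples_per_class=9,
                                           effect_size=1.0, noise_sd=0.5, seed=seed + 100)
            ctrl = list(lab.index[lab == 0])
            kd = list(lab.index[lab == 1])
            zt = zero_transform(mat, ctrl[:6])
            model = create_signature(zt, ctrl[:6], kd[:6], n_sig=100)
            p = project_signature(model, zt.values[ctrl[6:] + kd[6:]])
            correct += (p[ctrl[6:]] < 0.5).sum() + (p[kd[6:]] > 0.5).sum()
            total += 6
        assert correct / total >= 0.9

    def test_serialization_round_trip(self, tmp_path):
        from poolscreen.signatures import SignatureModel

        zt, ctrl, kd = _two_class(seed=4, effect=1.0, noise=0.5)
        model = create_signature(zt, ctrl, kd, n_sig=30)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = SignatureModel.from_json(path)
        np.testing.assert_allclose(
            project_signature(back, zt.values), project_signature(model, zt.values)
        )

    def test_ridge_probit_close_to_statsmodels_on_separable_free_fit(self):
        # independent oracle: with a tiny ridge and a non-separable design,
        # coefficients approach the unpenalized ML probit fit
        import statsmodels.api as sm
        from poolscreen.signatures import _ridge_probit

        rng = np.random.default_rng(11)
        F = rng.normal(size=(200, 2))
        eta = 0.3 + 0.8 * F[:, 0] - 0.5 * F[:, 1]
        y = (eta + rng.normal(size=200) > 0).astype(float)
        ours = _ridge_probit(F, y, ridge=1e-8)
        ref = sm.Probit(y, sm.add_constant(F)).fit(disp=0).params
        np.testing.assert_allclose(ours, ref, atol=1e-4)


class TestSignatureRegression:
    def test_identity_and_negation(self):
        x = pd.Series(np.linspace(0.1, 0.9, 20), index=[f"s{i}" for i in range(20)])
        r = signature_regression(x, x)
        assert r.slope == pytest.approx(1.0) and r.r_squared == pytest.approx(1.0)
        r2 = signature_regression(x, 1 - x)
        assert r2.slope == pytest.approx(-1.0) and r2.r_squared == pytest.approx(1.0)

    def test_zero_variance_predictor_undefined(self):
        idx = [f"s{i}" for i in range(10)]
        x = pd.Series(0.5, index=idx)
        y = pd.Series(np.linspace(0, 1, 10), index=idx)
        r = signature_regression(x, y)
        assert np.isnan(r.slope)

    def test_matches_statsmodels_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        idx = [f"s{i}" for i in range(50)]
        x = pd.Series(rng.uniform(size=50), index=idx)
        y = pd.Series(0.3 * x + rng.normal(0, 0.1, 50), index=idx)
        r = signature_regression(x, y)
        fit = sm.OLS(y.to_numpy(), sm.add_constant(x.to_numpy())).fit()
        assert r.slope == pytest.approx(fit.params[1])
        assert r.p_value == pytest.approx(fit.pvalues[1])
        assert r.r_squared == pytest.approx(fit.rsquared)

    def test_null_probabilities_rarely_significant(self):
        # Monte-Carlo null oracle: independent uniforms, n=130
        rng = np.random.default_rng(1)
        n_sig = 0
        reps = 200
        slopes = []
        for _ in range(reps):
            idx = [f"s{i}" for i in range(130)]
            x = pd.Series(rng.uniform(size=130), index=idx)
            y = pd.Series(rng.uniform(size=130), index=idx)
            r = signature_regression(x, y)
            slopes.append(r.slope)
            n_sig += r.p_value < 0.05
        assert abs(np.mean(slopes)) < 0.05
        # rejection rate ~5%: allow 3x binomial SE
        assert n_sig / reps < 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)
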