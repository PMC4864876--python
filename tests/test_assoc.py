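"""Pedigree kinship, REML mixed model, Wald inference, association models."""

import numpy as np
import pandas as pd
import pytest

from polycog.assoc import (
    RelationshipMatrix,
    KinshipMixedModel,
    kinship_from_pedigree,
    linear_assoc,
    ols_fit,
    reml_fit,
    single_snp_scan,
    wald_p,
    wald_test,
)
from polycog.errors import ConfigError, DegenerateDataError

from conftest import make_panel
from helpers import direct_reml, sibship_matrix


def ped_frame(rows):
    return pd.DataFrame(rows, columns=["id", "father", "mother", "sex"])


NUCLEAR = ped_frame([
    ("F", "0", "0", "M"), ("M", "0", "0", "F"),
    ("C1", "F", "M", "M"), ("C2", "F", "M", "F"),
])


class TestKinship:
    def test_textbook_coefficients(self):
        K = kinship_from_pedigree(NUCLEAR)
        i = {s: j for j, s in enumerate(K.ids)}
        assert K.A[i["F"], i["C1"]] == 0.5        # parent-offspring
        assert K.A[i["C1"], i["C2"]] == 0.5       # full siblings
        assert K.A[i["F"], i["M"]] == 0.0
        assert np.allclose(np.diag(K.A), 1.0)

    def test_half_siblings(self):
        ped = ped_frame([
            ("F", "0", "0", "M"), ("M1", "0", "0", "F"), ("M2", "0", "0", "F"),
            ("H1", "F", "M1", "M"), ("H2", "F", "M2", "F"),
        ])
        K = kinship_from_pedigree(ped)
        i = {s: j for j, s in enumerate(K.ids)}
        assert K.A[i["H1"], i["H2"]] == 0.25

    def test_inbred_diagonal(self):
        ped = pd.concat([NUCLEAR, ped_frame([("D", "C1", "C2", "M")])],
                        ignore_index=True)
        K = kinship_from_pedigree(ped)
        i = {s: j for j, s in enumerate(K.ids)}
        assert K.A[i["D"], i["D"]] == 1.25

    def test_row_order_invariance(self):
        K1 = kinship_from_pedigree(NUCLEAR)
        shuffled = NUCLEAR.sample(frac=1, random_state=0).reset_index(drop=True)
        K2 = kinship_from_pedigree(shuffled)
        pos = {s: j for j, s in enumerate(K2.ids)}
        perm = [pos[s] for s in K1.ids]
        assert np.array_equal(K1.A, K2.A[np.ix_(perm, perm)])

    def test_cycle_detected(self):
        ped = ped_frame([("A", "B", "0", "M"), ("B", "A", "0", "M")])
        with pytest.raises(ConfigError, match="cycle"):
            kinship_from_pedigree(ped)

    def test_unknown_parent_is_founder_with_warning(self):
        ped = ped_frame([("A", "ghost", "0", "M")])
        with pytest.warns(UserWarning, match="founder"):
            K = kinship_from_pedigree(ped)
        assert K.A[0, 0] == 1.0


class TestReml:
    def test_identity_kinship_degenerates_to_ols(self):
        rng = np.random.default_rng(0)
        n = 150
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = X @ [1.0, 0.4, -0.2] + rng.normal(size=n)
        fit = reml_fit(y, X, A=np.eye(n))
        ols = ols_fit(y, X)
        assert np.allclose(fit.params, ols.params, atol=1e-8)
        assert np.allclose(fit.bse, ols.bse, atol=1e-6)
        assert fit.varcomp.boundary  # variance split unidentifiable

    def test_matches_direct_likelihood_maximization(self):
        rng = np.random.default_rng(1)
        A = sibship_matrix(12, 10)
        n = A.shape[0]
        d, U = np.linalg.eigh(A)
        Ah = (U * np.sqrt(np.clip(d, 0, None))) @ U.T
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [1.0, 0.3] + Ah @ rng.normal(size=n) * np.sqrt(0.6) \
            + rng.normal(size=n) * np.sqrt(0.4)
        fit = reml_fit(y, X, A=A)
        sg, se = direct_reml(y, X, A)
        assert fit.varcomp.sigma2_g == pytest.approx(sg, rel=1e-4, abs=1e-6)
        assert fit.varcomp.sigma2_e == pytest.approx(se, rel=1e-4)

    def test_profile_likelihood_unimodal_on_sibships(self):
        rng = np.random.default_rng(2)
        A = sibship_matrix(20, 10)
        n = A.shape[0]
        d, U = np.linalg.eigh(A)
        dc = np.clip(d, 0, None)
        Ah = (U * np.sqrt(dc)) @ U.T
        y = Ah @ rng.normal(size=n) * np.sqrt(0.5) + rng.normal(size=n) * np.sqrt(0.5)
        X = np.ones((n, 1))
        ys, Xs = U.T @ y, U.T @ X
        p = 1

        def nll(lam):
            w = 1.0 / (lam * dc + 1.0)
            Xw = Xs * w[:, None]
            XtWX = Xs.T @ Xw
            beta = np.linalg.solve(XtWX, Xw.T @ ys)
            r = ys - Xs @ beta
            s2 = float(r @ (w * r)) / (n - p)
            return ((n - p) * np.log(s2) + np.sum(np.log(lam * dc + 1.0))
                    + np.linalg.slogdet(XtWX)[1])

        grid = np.array([nll(lam) for lam in np.logspace(-3, 3, 50)])
        sign_changes = np.sum(np.diff(np.sign(np.diff(grid))) != 0)
        assert sign_changes <= 1  # single interior minimum

    def test_null_variance_often_at_boundary(self):
        # with a true zero genetic variance the REML estimate collapses to
        # the boundary in about half of replicates (boundary mixture)
        rng = np.random.default_rng(3)
        A = sibship_matrix(60, 8)
        n = A.shape[0]
        d, U = np.linalg.eigh(A)
        eig = (np.clip(d, 0, None), U)
        X = np.ones((n, 1))
        at_boundary = 0
        h2 = []
        for _ in range(30):
            y = rng.standard_normal(n)
            fit = reml_fit(y, X, eig=eig)
            h2.append(fit.varcomp.heritability)
            if fit.varcomp.boundary and fit.varcomp.lam < 1e-4:
                at_boundary += 1
        assert at_boundary >= 0.35 * 30
        assert np.median(h2) < 0.05

    def test_rank_deficient_design_reports_columns(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=50)
        X = np.column_stack([np.ones(50), x, 2 * x])
        with pytest.raises(DegenerateDataError, match="collinear"):
            reml_fit(rng.normal(size=50), X, A=np.eye(50), names=["c", "x", "2x"])


class TestWald:
    def test_z_to_p_identity(self):
        assert wald_p(0.0) == pytest.approx(1.0)
        z, p = 1.96, wald_p(1.96)
        assert p == pytest.approx(0.05, abs=2e-4)

    def test_monotone_in_abs_z(self):
        grid = np.linspace(0, 8, 100)
        ps = [wald_p(z) for z in grid]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        assert wald_p(-2.5) == wald_p(2.5)

    def test_zero_se_errors(self):
        from polycog.assoc import FitResult

        fit = FitResult(
            params=pd.Series({"x": 1.0}), bse=pd.Series({"x": 0.0}),
            cov=pd.DataFrame([[0.0]], index=["x"], columns=["x"]),
            varcomp=None, n=10, method="ols",
        )
        with pytest.raises(DegenerateDataError):
            wald_test(fit, "x")
        with pytest.raises(ConfigError):
            wald_test(fit, "absent")


class TestLinearAssoc:
    def test_self_association(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=100)
        res = linear_assoc(y, y)
        assert res.beta == pytest.approx(1.0)
        assert res.p < 1e-100

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(7)
        rej = 0
        reps = 500
        for _ in range(reps):
            y = rng.standard_normal(1000)
            x = rng.standard_normal(1000)
            rej += linear_assoc(y, x).p < 0.05
        assert 0.03 <= rej / reps <= 0.08

    def test_duplicated_covariate_errors(self):
        rng = np.random.default_rng(8)
        y, x = rng.normal(size=60), rng.normal(size=60)
        c = rng.normal(size=60)
        cov = pd.DataFrame({"c1": c, "c2": c})
        with pytest.raises(DegenerateDataError, match="collinear"):
            linear_assoc(y, x, cov)

    def test_binary_outcome_linear_probability(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=400)
        y = (rng.random(400) < 0.3 + 0.1 * (x > 0)).astype(float)
        res = linear_assoc(y, x)
        assert res.beta > 0
        # outcome left on the 0/1 scale
        assert res.trait == "y"

    def test_interaction_term_tested(self):
        rng = np.random.default_rng(10)
        n = 500
        x = rng.normal(size=n)
        a = rng.normal(size=n)
        y = 0.5 * x * a + rng.normal(size=n)
        res = linear_assoc(y, x, pd.DataFrame({"age": a}), interaction="age")
        assert res.coefficient == "predictor:age"
        assert res.p < 1e-6

    def test_mixed_model_fixes_family_inflation(self):
        # familial clustering in both outcome and predictor inflates the
        # naive OLS test; the kinship REML model restores calibration
        nfam, fs = 120, 5
        A = sibship_matrix(nfam, fs)
        n = nfam * fs
        d, U = np.linalg.eigh(A)
        dc = np.clip(d, 0, None)
        Ah = (U * np.sqrt(dc)) @ U.T
        K = RelationshipMatrix([f"s{i}" for i in range(n)], A)
        fam_id = np.repeat(np.arange(nfam), fs)
        rng = np.random.default_rng(13)
        rej_ols = rej_lmm = 0
        reps = 200
        for _ in range(reps):
            x = (rng.standard_normal(nfam)[fam_id] * np.sqrt(0.5)
                 + rng.standard_normal(n) * np.sqrt(0.5))
            y = Ah @ rng.standard_normal(n) * np.sqrt(0.5) \
                + rng.standard_normal(n) * np.sqrt(0.5)
            rej_ols += linear_assoc(y, x).p < 0.05
            rej_lmm += linear_assoc(y, x, kinship=K, sample_ids=K.ids).p < 0.05
        assert rej_ols / reps > 0.08
        assert 0.03 <= rej_lmm / reps <= 0.08


class TestSingleSnpScan:
    def test_matches_direct_call_and_skips(self, small_world):
        panel = small_world["panel"]
        ph = small_world["phenotypes"]
        y = ph["digit_symbol"].to_numpy()
        ids = panel.variants["id"].tolist()[:5] + ["absent"]
        log = []
        out = single_snp_scan(panel, ids, y, log=log)
        assert len(out) == 5
        assert any("absent" in line for line in log)
        direct = linear_assoc(y, panel.dosages[:, 0], trait=ids[0])
        assert out.loc[0, "beta"] == pytest.approx(direct.beta)
        assert out.loc[0, "p"] == pytest.approx(direct.p)

    def test_monomorphic_skipped(self):
        panel = make_panel(np.column_stack([np.ones(40), np.arange(40) % 3]))
        rng = np.random.default_rng(11)
        log = []
        out = single_snp_scan(panel, ["v1", "v2"], rng.normal(size=40), log=log)
        assert out["snp"].tolist() == ["v2"]
        assert any("monomorphic" in line for line in log)

    def test_null_scan_rejection_rate(self):
        rng = np.random.default_rng(12)
        hits, total = 0, 0
        for _ in range(8):
            D = rng.integers(0, 3, size=(300, 25)).astype(float)
            panel = make_panel(D)
            y = rng.normal(size=300)
            out = single_snp_scan(panel, panel.variants["id"].tolist(), y)
            hits += (out["p"] < 0.05).sum()
            total += len(out)
        rate = hits / total
        assert 0.02 <= rate <= 0.09


class TestEstimator:
    def test_fit_predict_and_params(self):
        rng = np.random.default_rng(14)
        A = sibship_matrix(30, 5)
        n = A.shape[0]
        d, U = np.linalg.eigh(A)
        Ah = (U * np.sqrt(np.clip(d, 0, None))) @ U.T
        X = rng.normal(size=(n, 2))
        y = 1.0 + X @ [0.5, -0.3] + Ah @ rng.normal(size=n) * 0.7 \
            + rng.normal(size=n) * 0.7
        model = KinshipMixedModel(kinship=A).fit(X, y)
        assert model.coef_.shape == (2,)
        assert abs(model.coef_[0] - 0.5) < 0.15
        assert 0 <= model.heritability_ <= 1
        pred = model.predict(X)
        assert np.corrcoef(pred, y)[0, 1] > 0.3
        clone_params = model.get_params()
        m2 = KinshipMixedModel(**clone_params)
        assert m2.get_params().keys() == clone_params.keys()
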