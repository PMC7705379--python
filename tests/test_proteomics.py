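import numpy as np
import pandas as pd
import pytest

from njoracle import random_additive_matrix as _random_additive_matrix
from njoracle import tree_path_lengths as _tree_path_lengths

from perivesiq.proteomics import (
    fit_plsda,
    group_ellipses,
    log2_ratio_matrix,
    nj_cluster,
    nj_from_profiles,
    predict_groups,
    smc,
    vip,
    volcano,
    volcano_frame,
)


def _lfq_from_dict(d, groups):
    lfq = pd.DataFrame(d).T
    lfq.index.name = "protein_id"
    labels = pd.Series(groups, name="group")
    return lfq, labels


GROUPS6 = {
    "c1": "CNT", "c2": "CNT", "c3": "CNT",
    "s1": "SAD", "s2": "SAD", "s3": "SAD",
}


class TestHeatmap:
    def test_reference_equal_means_give_zero_row(self):
        lfq, labels = _lfq_from_dict(
            {"P1": {"c1": 100.0, "c2": 100.0, "c3": 100.0, "s1": 200.0, "s2": 200.0, "s3": 200.0}},
            GROUPS6,
        )
        mat, kept = log2_ratio_matrix(lfq, labels, fc_filter=1.2)
        assert kept == ["P1"]
        np.testing.assert_allclose(mat.loc["P1", ["c1", "c2", "c3"]], 0.0)
        np.testing.assert_allclose(mat.loc["P1", ["s1", "s2", "s3"]], 1.0)

    def test_fold_change_filter_boundary(self):
        lfq, labels = _lfq_from_dict(
            {
                "weak": {"c1": 100.0, "c2": 100.0, "c3": 100.0, "s1": 115.0, "s2": 115.0, "s3": 115.0},
                "strong": {"c1": 100.0, "c2": 100.0, "c3": 100.0, "s1": 125.0, "s2": 125.0, "s3": 125.0},
            },
            GROUPS6,
        )
        _, kept = log2_ratio_matrix(lfq, labels, fc_filter=1.2)
        assert kept == ["strong"]

    def test_downregulation_also_retained(self):
        lfq, labels = _lfq_from_dict(
            {"down": {"c1": 120.0, "c2": 120.0, "c3": 120.0, "s1": 90.0, "s2": 90.0, "s3": 90.0}},
            GROUPS6,
        )
        _, kept = log2_ratio_matrix(lfq, labels, fc_filter=1.2)
        assert kept == ["down"]

    def test_all_missing_reference_dropped(self):
        lfq, labels = _lfq_from_dict(
            {"gone": {"c1": 0.0, "c2": 0.0, "c3": 0.0, "s1": 200.0, "s2": 200.0, "s3": 200.0}},
            GROUPS6,
        )
        mat, kept = log2_ratio_matrix(lfq, labels)
        assert kept == [] and mat.empty

    def test_unknown_reference_rejected(self):
        lfq, labels = _lfq_from_dict(
            {"P1": {"c1": 1.0, "c2": 1.0, "c3": 1.0, "s1": 1.0, "s2": 1.0, "s3": 1.0}}, GROUPS6
        )
        with pytest.raises(ValueError):
            log2_ratio_matrix(lfq, labels, reference="XXX")


class TestVolcano:
    def test_null_protein(self):
        lfq, labels = _lfq_from_dict(
            {"P1": {"c1": 100.0, "c2": 100.0, "c3": 100.0, "s1": 100.0, "s2": 100.0, "s3": 100.0}},
            GROUPS6,
        )
        (rec,) = volcano(lfq, labels, "SAD", "CNT")
        assert rec.log2_fc == 0.0 and rec.p_value == 1.0 and not rec.significant

    def test_exact_twofold_shift_noiseless(self):
        lfq, labels = _lfq_from_dict(
            {"P1": {"c1": 100.0, "c2": 100.001, "c3": 99.999, "s1": 200.0, "s2": 200.002, "s3": 199.998}},
            GROUPS6,
        )
        (rec,) = volcano(lfq, labels, "SAD", "CNT")
        assert rec.log2_fc == pytest.approx(1.0, abs=1e-4)
        assert rec.p_value < 0.05 and rec.significant

    def test_missing_group_yields_na_record(self):
        lfq, labels = _lfq_from_dict(
            {"P1": {"c1": 0.0, "c2": 0.0, "c3": 100.0, "s1": 200.0, "s2": 210.0, "s3": 190.0}},
            GROUPS6,
        )
        (rec,) = volcano(lfq, labels, "SAD", "CNT")
        assert rec.is_na and not rec.significant

    def test_planted_signature_recovery(self, lfq_with_signature):
        lfq, labels, truth = lfq_with_signature
        recs = volcano(lfq, labels, "SAD", "CNT")
        frame = volcano_frame(recs)
        flagged = set(frame[frame.significant].protein_id)
        planted = set(truth.protein_id)
        assert len(planted & flagged) >= 0.95 * len(planted)
        assert len(flagged - planted) <= 0.05 * len(planted)


class TestPLSDA:
    def test_separable_groups_separate_on_lv1(self):
        rng = np.random.default_rng(0)
        n = 8
        data = {}
        for j in range(5):
            if j == 0:
                vals = np.concatenate([rng.normal(10, 0.1, n), rng.normal(20, 0.1, n)])
            else:
                vals = rng.normal(15, 1.0, 2 * n)
            data[f"P{j}"] = dict(zip([f"x{i}" for i in range(2 * n)], vals))
        groups = {f"x{i}": ("A" if i < n else "B") for i in range(2 * n)}
        lfq, labels = _lfq_from_dict(data, groups)
        model = fit_plsda(lfq, labels, n_components=2)
        t1 = model.T[:, 0]
        assert max(t1[:n]) < min(t1[n:]) or min(t1[:n]) > max(t1[n:])

    def test_duplicated_sample_has_identical_scores(self):
        rng = np.random.default_rng(1)
        data = rng.lognormal(5, 1, (10, 6))
        data[:, 5] = data[:, 4]  # duplicate
        lfq = pd.DataFrame(data, index=[f"P{i}" for i in range(10)],
                           columns=[f"x{i}" for i in range(6)])
        labels = pd.Series({"x0": "A", "x1": "A", "x2": "A", "x3": "B", "x4": "B", "x5": "B"})
        model = fit_plsda(lfq, labels, n_components=2)
        np.testing.assert_allclose(model.T[4], model.T[5], atol=1e-10)

    def test_planted_structure_cross_validated_accuracy(self):
        """Two well-separated groups encoded in 2 of 20 variables: leave-one-
        out group prediction must be nearly perfect despite the noise block."""
        rng = np.random.default_rng(7)
        n, p_noise = 30, 18
        y = np.array(["A"] * 15 + ["B"] * 15)
        informative = np.zeros((2, n))
        informative[0] = np.where(y == "A", 5.0, -5.0) + rng.normal(0, 0.5, n)
        informative[1] = np.where(y == "A", -5.0, 5.0) + rng.normal(0, 0.5, n)
        noise = rng.normal(0, 1, (p_noise, n))
        X = np.vstack([informative, noise]) + 20.0
        cols = [f"x{i}" for i in range(n)]
        lfq = pd.DataFrame(X, index=[f"P{i}" for i in range(p_noise + 2)], columns=cols)
        labels = pd.Series(dict(zip(cols, y)))
        correct = 0
        for i in range(n):  # leave-one-out
            train = [c for c in cols if c != cols[i]]
            model = fit_plsda(lfq[train], labels[train], n_components=3)
            pred = predict_groups(model, lfq[[cols[i]]])
            correct += pred[0] == y[i]
        assert correct / n >= 0.9

    def test_matches_sklearn_pls_scores_subspace(self):
        """Cross-check NIPALS against scikit-learn's PLSRegression."""
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (12, 8))
        y = np.array(["A"] * 6 + ["B"] * 6)
        cols = [f"x{i}" for i in range(12)]
        lfq = pd.DataFrame(X.T + 50, index=[f"P{i}" for i in range(8)], columns=cols)
        labels = pd.Series(dict(zip(cols, y)))
        model = fit_plsda(lfq, labels, n_components=2, scale=True)
        Y = np.where(y == "A", 1.0, 0.0).reshape(-1, 1)
        skl = PLSRegression(n_components=2, scale=True).fit(lfq.T.to_numpy(), Y)
        # single-response PLS2 == PLS1: scores agree up to per-component sign
        for a in range(2):
            c = np.corrcoef(model.T[:, a], skl.x_scores_[:, a])[0, 1]
            assert abs(c) > 0.999

    def test_too_few_samples_rejected(self):
        lfq = pd.DataFrame(np.ones((3, 2)), columns=["a", "b"])
        labels = pd.Series({"a": "A", "b": "B"})
        with pytest.raises(ValueError):
            fit_plsda(lfq, labels)


class TestVIP:
    def test_closed_form_single_component(self):
        """Two variables, weights (1,0): VIP = (sqrt(2), 0)."""
        rng = np.random.default_rng(0)
        t = rng.normal(0, 1, 20)
        x1 = t.copy()
        x2 = rng.normal(0, 1, 20)  # orthogonal-ish noise, no Y relation
        y = np.where(t > 0, "A", "B")
        cols = [f"x{i}" for i in range(20)]
        lfq = pd.DataFrame([x1 + 10, x2 + 10], index=["P0", "P1"], columns=cols)
        labels = pd.Series(dict(zip(cols, y)))
        model = fit_plsda(lfq, labels, n_components=1)
        v = vip(model)
        # weight mass concentrates on P0; exact (sqrt2, 0) in the noiseless limit
        assert v[0] > 1.3 and v[1] < 0.4

    def test_equal_weights_give_unit_vip(self):
        n = 16
        t = np.linspace(-1, 1, n)
        cols = [f"x{i}" for i in range(n)]
        lfq = pd.DataFrame([t + 5, t + 9, t + 2], index=["P0", "P1", "P2"], columns=cols)
        labels = pd.Series(dict(zip(cols, np.where(t > 0, "A", "B"))))
        model = fit_plsda(lfq, labels, n_components=1)
        np.testing.assert_allclose(vip(model), 1.0, atol=1e-8)

    def test_mean_square_vip_is_one(self, lfq_with_signature):
        lfq, labels, _ = lfq_with_signature
        for ncomp in (1, 2, 3):
            model = fit_plsda(lfq, labels, n_components=ncomp)
            v = vip(model)
            assert np.mean(v**2) == pytest.approx(1.0, abs=1e-8)


class TestSMC:
    def test_variable_proportional_to_target_projection_is_infinite(self):
        # two collinear variables: after autoscaling both equal the target
        # projection direction exactly, so their residual is zero
        n = 12
        t = np.linspace(-2, 2, n)
        cols = [f"x{i}" for i in range(n)]
        lfq = pd.DataFrame([t + 10, 2 * t + 30], index=["P0", "P1"], columns=cols)
        labels = pd.Series(dict(zip(cols, np.where(t > 0, "A", "B"))))
        model = fit_plsda(lfq, labels, n_components=1)
        s = smc(model, response=0)
        assert np.isinf(s).all()

    def test_matches_univariate_regression_f_ratio(self, lfq_with_signature):
        lfq, labels, _ = lfq_with_signature
        model = fit_plsda(lfq, labels, n_components=2)
        s = smc(model, response=0)
        # oracle: regress each scaled variable on the target-projection
        # score by the explicit slope formula, F with df (1, n-2)
        X = model.X_scaled
        beta = model.beta[:, 0]
        t_tp = X @ (beta / np.linalg.norm(beta))
        n = X.shape[0]
        for j in range(0, X.shape[1], 25):
            slope = X[:, j] @ t_tp / (t_tp @ t_tp)
            fit = slope * t_tp
            res = X[:, j] - fit
            f_oracle = (fit @ fit) / ((res @ res) / (n - 2))
            assert s[j] == pytest.approx(f_oracle, rel=1e-9)

    def test_smc_nonnegative(self, lfq_with_signature):
        lfq, labels, _ = lfq_with_signature
        model = fit_plsda(lfq, labels, n_components=3)
        s = smc(model)
        assert np.all(s >= 0)


class TestEllipses:
    def test_ellipse_centres_match_group_score_means(self, lfq_with_signature):
        lfq, labels, _ = lfq_with_signature
        model = fit_plsda(lfq, labels, n_components=2)
        ell = group_ellipses(model)
        labs = np.array(model.y_labels)
        for g, e in ell.items():
            np.testing.assert_allclose(
                e["center"], model.T[labs == g, :2].mean(axis=0), atol=1e-12
            )
            assert e["semi_axes"][0] >= e["semi_axes"][1] >= 0


class TestNeighborJoining:
    def test_identical_samples_join_as_cherry(self):
        d = np.array(
            [
                [0.0, 0.0, 5.0, 6.0],
                [0.0, 0.0, 5.0, 6.0],
                [5.0, 5.0, 0.0, 3.0],
                [6.0, 6.0, 3.0, 0.0],
            ]
        )
        nwk = nj_cluster(d, ["a", "b", "c", "d"])
        assert "(a:0,b:0)" in nwk.replace(" ", "")

    @pytest.mark.parametrize("n_leaves", [4, 5, 6, 8])
    def test_exact_on_additive_matrices(self, rng, n_leaves):
        for _ in range(5):
            d = _random_additive_matrix(rng, n_leaves)
            names = [f"L{i}" for i in range(n_leaves)]
            nwk = nj_cluster(d, names)
            paths = _tree_path_lengths(nwk, names)
            for (a, b), got in paths.items():
                want = d[names.index(a), names.index(b)]
                assert got == pytest.approx(want, abs=1e-8)

    def test_agrees_with_scikit_bio(self, rng):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        d = _random_additive_matrix(rng, 6)
        names = [f"L{i}" for i in range(6)]
        ours = _tree_path_lengths(nj_cluster(d, names), names)
        ref_tree = skbio_nj(DistanceMatrix(d, names))
        for (a, b), got in ours.items():
            ref = ref_tree.find(a).distance(ref_tree.find(b))
            assert got == pytest.approx(ref, abs=1e-8)

    def test_leaf_set_conserved(self, rng):
        d = _random_additive_matrix(rng, 5)
        names = ["s1", "s2", "s3", "s4", "s5"]
        nwk = nj_cluster(d, names)
        for nm in names:
            assert nm in nwk

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError):
            nj_cluster(np.zeros((2, 2)), ["a", "b"])

    def test_profiles_tree_over_samples(self, lfq_with_signature):
        lfq, labels, _ = lfq_with_signature
        mat, _ = log2_ratio_matrix(lfq, labels)
        nwk = nj_from_profiles(mat)
        for s in lfq.columns:
            assert s in nwk
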