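"""Auto-covariance features, SVM training and sigmoid calibration."""

import numpy as np
import pytest

from gofuse.io_formats import AMINO_ACIDS, PssmProfile
from gofuse.pssm import (
    AccVector, PssmTrainConfig, SigmoidParams, acc_transform, fit_sigmoid,
    score_pssm, train_term_classifier,
)


def make_profile(matrix, domain="dx"):
    matrix = np.asarray(matrix, dtype=float)
    seq = "".join(AMINO_ACIDS[i % 20] for i in range(matrix.shape[0]))
    return PssmProfile(domain, matrix.tolist(), seq)


def naive_ac(X, lag):
    """Literal double-loop transcription of the auto-covariance formula."""
    X = np.asarray(X, dtype=float)
    DL = X.shape[0]
    out = []
    for j in range(20):
        xbar = X[:, j].mean()
        for k in range(1, lag + 1):
            s = 0.0
            for i in range(DL - k):
                s += (X[i, j] - xbar) * (X[i + k, j] - xbar)
            out.append(s / (DL - k))
    return np.array(out)


class TestAccTransform:
    def test_constant_column_gives_zero(self):
        prof = make_profile(np.full((30, 20), 3.0))
        assert np.all(acc_transform(prof, 5).values == 0.0)

    def test_hand_case_column_1234_lag1(self):
        M = np.zeros((4, 20))
        M[:, 0] = [1, 2, 3, 4]
        v = acc_transform(make_profile(M), lag=1).values
        # (0.75 - 0.25 + 0.75) / 3
        assert v[0] == pytest.approx(0.4166666666666667, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        M = rng.normal(0, 4, size=(60, 20))
        got = acc_transform(make_profile(M), lag=10).values
        np.testing.assert_allclose(got, naive_ac(M, 10), atol=1e-12)

    def test_invariant_to_column_wise_constant_shift(self):
        rng = np.random.default_rng(2)
        M = rng.normal(size=(50, 20))
        shifted = M + rng.normal(size=(1, 20))  # constant per column
        a = acc_transform(make_profile(M), 10).values
        b = acc_transform(make_profile(shifted), 10).values
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_sequence_shorter_than_lag_rejected(self):
        prof = make_profile(np.zeros((5, 20)))
        with pytest.raises(ValueError, match="exceed"):
            acc_transform(prof, lag=10)

    def test_cross_covariance_extension_length(self):
        rng = np.random.default_rng(3)
        prof = make_profile(rng.normal(size=(40, 20)))
        v = acc_transform(prof, lag=4, cross=True).values
        assert v.shape == (20 * 4 + 20 * 19 * 4,)


class TestSigmoidCalibration:
    def test_recovers_generating_parameters(self):
        rng = np.random.default_rng(0)
        m = rng.normal(0.0, 2.0, size=2000)
        p = 1.0 / (1.0 + np.exp(-2.0 * m + 0.5))
        y = (rng.uniform(size=2000) < p).astype(int)
        A, B = fit_sigmoid(m, y)
        assert A == pytest.approx(-2.0, abs=0.15)
        assert B == pytest.approx(0.5, abs=0.15)

    def test_convergence_improves_with_n(self):
        errs = []
        for n in (200, 20000):
            rng = np.random.default_rng(1)
            m = rng.normal(0.0, 2.0, size=n)
            p = 1.0 / (1.0 + np.exp(-2.0 * m + 0.5))
            y = (rng.uniform(size=n) < p).astype(int)
            A, B = fit_sigmoid(m, y)
            errs.append(abs(A + 2.0) + abs(B - 0.5))
        assert errs[1] < errs[0]

    def test_midpoint_gives_half(self):
        sp = SigmoidParams("g", A=-1.7, B=0.3)
        assert sp.probability(-sp.B / sp.A) == pytest.approx(0.5, abs=1e-12)

    def test_limit_toward_one(self):
        sp = SigmoidParams("g", A=-2.0, B=0.0)
        assert sp.probability(400.0) == pytest.approx(1.0)
        assert sp.probability(-400.0) == pytest.approx(0.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_sigmoid([1.0, 2.0], [1, 1])


class TestTermClassifier:
    def _cluster_data(self, rng, n=60, sep=6.0):
        vecs, labels = [], []
        for i in range(n):
            y = i % 2
            base = np.zeros(200)
            base[:5] = sep * y
            vecs.append(AccVector(f"d{i}", base + rng.normal(0, 1, 200), 10))
            labels.append(y)
        return vecs, labels

    def test_separable_clusters_perfect_training_accuracy(self):
        rng = np.random.default_rng(5)
        vecs, labels = self._cluster_data(rng)
        clf = train_term_classifier(vecs, labels, "GO:0000002")
        margins = clf.margin(vecs)
        assert np.all((margins > 0) == np.array(labels, dtype=bool))
        probs = clf.probability(vecs)
        assert np.all((probs > 0.5) == np.array(labels, dtype=bool))

    def test_class_floor_unmet_skips(self):
        rng = np.random.default_rng(6)
        vecs, _ = self._cluster_data(rng, n=20)
        labels = [1, 1, 1] + [0] * 17
        assert train_term_classifier(vecs, labels, "g", PssmTrainConfig()) is None

    def test_probability_monotone_in_margin(self):
        rng = np.random.default_rng(7)
        vecs, labels = self._cluster_data(rng)
        clf = train_term_classifier(vecs, labels, "g")
        assert clf.sigmoid.A < 0
        m = np.linspace(-5, 5, 100)
        p = clf.sigmoid.probability(m)
        assert np.all(np.diff(p) > 0)

    def test_score_pssm_matches_direct_formula(self):
        rng = np.random.default_rng(8)
        vecs, labels = self._cluster_data(rng)
        clf = train_term_classifier(vecs, labels, "g")
        triples = score_pssm(vecs, {"g": clf})
        margins = clf.margin(vecs)
        for (d, t, p3), f in zip(triples, margins):
            expected = 1.0 / (1.0 + np.exp(clf.sigmoid.A * f + clf.sigmoid.B))
            assert p3 == pytest.approx(expected, abs=1e-12)

    def test_feature_length_mismatch_rejected(self):
        rng = np.random.default_rng(9)
        vecs, labels = self._cluster_data(rng)
        clf = train_term_classifier(vecs, labels, "g")
        with pytest.raises(ValueError, match="length"):
            clf.margin([AccVector("dz", np.zeros(40), 2)])

    def test_model_store_round_trip(self, tmp_path):
        import io

        from gofuse.pssm import load_models, save_models

        rng = np.random.default_rng(10)
        vecs, labels = self._cluster_data(rng)
        clf = train_term_classifier(vecs, labels, "g")
        buf = io.StringIO()
        save_models({"g": clf}, buf)
        buf.seek(0)
        back = load_models(buf)
        np.testing.assert_allclose(back["g"].probability(vecs),
                                   clf.probability(vecs), atol=1e-9)
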