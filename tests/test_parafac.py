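"""CP decomposition: recovery oracles, diagnostics, alignment, congruence."""

import numpy as np
import pytest

from emomediate import (
    BipolarScale,
    RatingsTensor,
    StimulusSet,
    ValidationError,
    align_factors,
    corcondia,
    fit_cp,
    scree,
    split_joint_scores,
    standardize_tensor,
    tucker_congruence,
)
from emomediate.parafac import FitError, JointStimulusIndex


def rank2_tensor(seed=0, shape=(8, 5, 6), orthogonal=True):
    """Noiseless rank-2 tensor with known (optionally orthogonal) factors."""
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(shape[0], 2))
    B = rng.normal(size=(shape[1], 2))
    C = rng.normal(size=(shape[2], 2))
    if orthogonal:
        A, _ = np.linalg.qr(A)
        B, _ = np.linalg.qr(B)
        C, _ = np.linalg.qr(C)
        A, B, C = A[:, :2] * 3, B[:, :2], C[:, :2]
    Z = np.einsum("ir,jr,kr->ijk", A, B, C)
    return Z, (A, B, C)


def corcondia_oracle(Z, model):
    """Independent core solve via explicit Kronecker normal equations."""
    K = np.kron(np.kron(model.A, model.B), model.C)
    g, *_ = np.linalg.lstsq(K, Z.reshape(-1), rcond=None)
    R = model.R
    G = g.reshape(R, R, R)
    T = np.zeros((R, R, R))
    T[np.arange(R), np.arange(R), np.arange(R)] = 1.0
    return 100 * (1 - np.sum((G - T) ** 2) / R)


class TestStandardize:
    def make_tensor(self, values):
        values = np.asarray(values, dtype=float)
        n_i, n_j, n_k = values.shape
        return RatingsTensor(
            values=values,
            stimuli=StimulusSet(
                ids=tuple(f"x{i}" for i in range(n_i)), modality="music"
            ),
            scales=tuple(BipolarScale(f"p{j}/n{j}") for j in range(n_j)),
            subjects=tuple(f"s{k}" for k in range(n_k)),
        )

    def test_hand_fiber(self):
        t = self.make_tensor(np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1))
        z = standardize_tensor(t)
        np.testing.assert_allclose(z.values[:, 0, 0], [-1, 0, 1])

    def test_idempotent_on_standard_fibers(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(50, 2, 2))
        v = (v - v.mean(axis=0)) / v.std(axis=0, ddof=1)
        t = self.make_tensor(v * 0.5)  # keep within bounds pre-flagging
        z = standardize_tensor(t)
        np.testing.assert_allclose(z.values, v, atol=1e-10)

    def test_constant_fiber_rejected(self):
        t = self.make_tensor(np.ones((4, 1, 1)))
        with pytest.raises(ValidationError, match="zero-variance"):
            standardize_tensor(t)

    def test_double_standardization_rejected(self):
        t = self.make_tensor(np.arange(8.0).reshape(4, 1, 2))
        with pytest.raises(ValidationError, match="already"):
            standardize_tensor(standardize_tensor(t))


class TestFitCp:
    def test_exact_rank1_identity(self):
        rng = np.random.default_rng(1)
        a, b, c = rng.normal(size=6), rng.normal(size=4), rng.normal(size=5)
        Z = np.einsum("i,j,k->ijk", a, b, c)
        m = fit_cp(Z, R=1, n_starts=3, seed=0)
        assert m.sse / m.total_ss <= 1e-8
        assert tucker_congruence(m.A, a[:, None]).min() >= 0.999

    def test_exact_rank2_recovery(self):
        Z, (A, B, C) = rank2_tensor(seed=2)
        m = fit_cp(Z, R=2, n_starts=5, seed=0)
        assert m.sse / m.total_ss <= 1e-8
        for est, true in ((m.A, A), (m.B, B), (m.C, C)):
            assert tucker_congruence(est, true).min() >= 0.999

    def test_determinism(self):
        Z, _ = rank2_tensor(seed=3)
        m1 = fit_cp(Z, R=2, n_starts=4, seed=42)
        m2 = fit_cp(Z, R=2, n_starts=4, seed=42)
        np.testing.assert_array_equal(m1.A, m2.A)
        np.testing.assert_array_equal(m1.B, m2.B)
        np.testing.assert_array_equal(m1.C, m2.C)
        assert m1.sse == m2.sse

    def test_sse_monotone_within_start(self):
        rng = np.random.default_rng(4)
        Z = rng.normal(size=(10, 6, 7))
        m = fit_cp(Z, R=3, n_starts=2, seed=1, max_iter=100)
        h = np.array(m.sse_history)
        assert np.all(np.diff(h) <= 1e-9 * np.maximum(h[:-1], 1.0))

    def test_reconstruction_normalization_convention(self):
        Z, _ = rank2_tensor(seed=5)
        m = fit_cp(Z, R=2, n_starts=3, seed=0)
        np.testing.assert_allclose(
            np.linalg.norm(m.B, axis=0), np.ones(2), atol=1e-9
        )
        np.testing.assert_allclose(
            np.linalg.norm(m.C, axis=0), np.ones(2), atol=1e-9
        )
        np.testing.assert_allclose(m.reconstruct(), Z, atol=1e-6)

    def test_r_exceeding_mode_rejected(self):
        Z, _ = rank2_tensor()
        with pytest.raises(FitError, match="exceeds"):
            fit_cp(Z, R=6, n_starts=1)

    def test_nonfinite_rejected(self):
        Z, _ = rank2_tensor()
        Z[0, 0, 0] = np.nan
        with pytest.raises(FitError):
            fit_cp(Z, R=1)

    def test_nonnegative_subject_mode_option(self):
        Z, (A, B, C) = rank2_tensor(seed=6)
        Zp = np.einsum("ir,jr,kr->ijk", A, B, np.abs(C) + 0.2)
        m = fit_cp(Zp, R=2, n_starts=4, seed=0, nonnegative_subjects=True)
        assert np.all(m.C >= 0)
        assert m.variance_explained >= 0.99


class TestCorcondia:
    def test_exact_rank_fit_scores_100(self):
        Z, _ = rank2_tensor(seed=7)
        m = fit_cp(Z, R=2, n_starts=4, seed=0)
        assert corcondia(Z, m) == pytest.approx(100.0, abs=1e-6)

    def test_rank1_fit_on_any_tensor_scores_100(self):
        rng = np.random.default_rng(8)
        Z = rng.normal(size=(6, 5, 4))
        m = fit_cp(Z, R=1, n_starts=2, seed=0)
        assert corcondia(Z, m) == pytest.approx(100.0, abs=1e-6)
        assert corcondia(Z, m) == pytest.approx(corcondia_oracle(Z, m), abs=1e-6)

    def test_overfactored_fit_matches_normal_equations_oracle(self):
        """Fitting two factors to a noiseless rank-1 tensor leaves a core
        far from superdiagonal; the value must match the independent
        Kronecker least-squares solve."""
        rng = np.random.default_rng(1)
        a, b, c = rng.normal(size=8), rng.normal(size=5), rng.normal(size=6)
        Z = np.einsum("i,j,k->ijk", a, b, c)
        m = fit_cp(Z, R=2, n_starts=6, seed=0)
        val = corcondia(Z, m)
        assert val == pytest.approx(corcondia_oracle(Z, m), abs=1e-5)
        assert val < 50.0  # substantially below 100 for an over-factored model


class TestScree:
    def test_variance_explained_nondecreasing(self):
        rng = np.random.default_rng(10)
        Z = rng.normal(size=(9, 6, 5))
        table = scree(Z, R_range=range(1, 5), n_starts=2, seed=0, max_iter=200)
        ve = table["variance_explained"].to_numpy()
        assert np.all(np.diff(ve) >= -1e-6)

    def test_planted_rank_shows_elbow_and_corcondia_drop(self):
        Z, _ = rank2_tensor(seed=11, shape=(10, 6, 7))
        table = scree(Z, R_range=range(1, 4), n_starts=4, seed=0)
        ve = dict(zip(table["R"], table["variance_explained"]))
        cc = dict(zip(table["R"], table["corcondia"]))
        assert ve[2] == pytest.approx(1.0, abs=1e-8)
        assert cc[2] == pytest.approx(100.0, abs=1e-4)
        assert cc[3] < 50.0

    def test_empty_range_gives_empty_table(self):
        Z, _ = rank2_tensor()
        assert len(scree(Z, R_range=[], n_starts=1)) == 0


class TestAlignment:
    def fitted(self):
        Z, _ = rank2_tensor(seed=12)
        m = fit_cp(Z, R=2, n_starts=4, seed=0)
        m.scale_labels = ("agitated/calm", "happy/sad", "warm/cool", "x/y", "p/q")
        return Z, m

    def test_idempotent_when_aligned(self):
        Z, m = self.fitted()
        anchors = {"agitated/calm": 0, "happy/sad": 1}
        m1 = align_factors(m, anchors)
        m2 = align_factors(m1, anchors)
        np.testing.assert_allclose(m1.A, m2.A)
        np.testing.assert_allclose(m1.B, m2.B)

    def test_sign_flip_preserves_reconstruction(self):
        Z, m = self.fitted()
        import dataclasses

        flipped = dataclasses.replace(
            m, A=m.A * np.array([-1, 1]), B=m.B * np.array([-1, 1])
        )
        j = flipped.scale_labels.index("agitated/calm")
        aligned = align_factors(flipped, {"agitated/calm": 0})
        assert aligned.B[j, 0] > 0
        np.testing.assert_allclose(aligned.reconstruct(), m.reconstruct(), atol=1e-8)

    def test_column_swap_is_undone(self):
        Z, m = self.fitted()
        import dataclasses

        swapped = dataclasses.replace(
            m, A=m.A[:, ::-1], B=m.B[:, ::-1], C=m.C[:, ::-1]
        )
        aligned = align_factors(
            swapped,
            {"agitated/calm": int(np.argmax(np.abs(m.B[0]))),
             },
        )
        # after re-anchoring, congruence with the original fit is exact
        assert tucker_congruence(aligned.A, m.A).min() == pytest.approx(1.0)

    def test_contradictory_anchor_rejected(self):
        _, m = self.fitted()
        with pytest.raises(FitError, match="contradictory|claimed"):
            align_factors(m, {"agitated/calm": 0, "happy/sad": 0})


class TestSplitJoint:
    def test_study_sized_split(self):
        rng = np.random.default_rng(13)
        A = rng.normal(size=(71, 2))
        from emomediate import CpModel

        m = CpModel(
            A=A, B=np.eye(2), C=np.eye(2), R=2, sse=0.0, total_ss=1.0,
            n_iter=1, converged=True, start_seed=0,
        )
        idx = JointStimulusIndex(range(0, 37), range(37, 71))
        colors, music = split_joint_scores(m, idx)
        assert colors.shape == (37, 2) and music.shape == (34, 2)
        np.testing.assert_array_equal(np.vstack([colors, music]), A)

    def test_degenerate_all_color_index(self):
        from emomediate import CpModel

        m = CpModel(
            A=np.ones((4, 1)), B=np.ones((2, 1)), C=np.ones((2, 1)), R=1,
            sse=0.0, total_ss=1.0, n_iter=1, converged=True, start_seed=0,
        )
        colors, music = split_joint_scores(m, JointStimulusIndex(range(4), range(4, 4)))
        assert music.shape[0] == 0

    def test_mismatched_index_rejected(self):
        with pytest.raises(FitError):
            JointStimulusIndex(range(0, 3), range(4, 6))


class TestTuckerCongruence:
    def test_self_congruence(self):
        rng = np.random.default_rng(14)
        M = rng.normal(size=(12, 3))
        np.testing.assert_allclose(tucker_congruence(M, M), np.ones(3), atol=1e-12)

    def test_sign_flips_ignored(self):
        rng = np.random.default_rng(15)
        M = rng.normal(size=(12, 3))
        np.testing.assert_allclose(tucker_congruence(M, -M), np.ones(3), atol=1e-12)

    def test_permutation_plus_noise(self):
        rng = np.random.default_rng(16)
        M = rng.normal(size=(30, 3))
        noisy = M[:, [2, 0, 1]] + 0.01 * rng.normal(size=(30, 3))
        assert tucker_congruence(M, noisy).min() >= 0.99

    def test_zero_column_rejected(self):
        M = np.ones((4, 2))
        M[:, 1] = 0
        with pytest.raises(FitError):
            tucker_congruence(M, M)
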