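"""Parafac (CANDECOMP/CP) decomposition of three-mode rating tensors.

The trilinear model

    z_ijk ~= sum_r  a_ir * b_jr * c_kr

decomposes a stimulus x scale x subject rating array into R latent
factors with stimulus weights A, scale weights B, and subject weights C
(the subject mode captures individual differences in factor salience).
Fitting is by alternating least squares (ALS) from multiple random
starts, keeping the best-fitting start; the scale of each factor is
absorbed into A, with B and C columns normalized to unit length.

Model selection support: residual variance across a range of R (scree)
and the core consistency diagnostic (CORCONDIA), which measures how
close the least-squares Tucker core implied by a CP fit is to a
superdiagonal identity — values far below 100 flag over-factoring.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import RatingsTensor, ValidationError


class FitError(ValueError):
    """Raised on invalid factorization input or a degenerate fit."""


@dataclass
class JointStimulusIndex:
    """Row partition of the stimulus mode of a joint (colors + music) tensor."""

    color_rows: range
    music_rows: range

    def __post_init__(self) -> None:
        rows = list(self.color_rows) + list(self.music_rows)
        if sorted(rows) != list(range(len(rows))):
            raise FitError("color_rows and music_rows must partition 0..n-1")


@dataclass
class CpModel:
    """Fitted CP factors with bookkeeping.

    ``A`` (stimuli x R) carries the factor scales; ``B`` (scales x R) and
    ``C`` (subjects x R) have unit-norm columns.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    R: int
    sse: float
    total_ss: float
    n_iter: int
    converged: bool
    start_seed: int
    sse_history: list[float] = field(default_factory=list)
    stimulus_labels: tuple[str, ...] = ()
    scale_labels: tuple[str, ...] = ()
    subject_labels: tuple[str, ...] = ()

    @property
    def variance_explained(self) -> float:
        return float(1.0 - self.sse / self.total_ss)

    def reconstruct(self) -> np.ndarray:
        return np.einsum("ir,jr,kr->ijk", self.A, self.B, self.C)


def _unfold(T: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(T, mode, 0).reshape(T.shape[mode], -1)


def _khatri_rao(U: np.ndarray, V: np.ndarray) -> np.ndarray:
    # columnwise Kronecker product; rows ordered to match _unfold's reshape
    r = U.shape[1]
    return (U[:, None, :] * V[None, :, :]).reshape(-1, r)


def standardize_tensor(raw: RatingsTensor, scheme: str = "fiber") -> RatingsTensor:
    """Z-score the tensor prior to factorization.

    ``scheme='fiber'`` (default) centers and scales each (scale, subject)
    fiber across stimuli to mean 0, sample SD 1, removing differences in
    how individual subjects use individual scales.  ``'scale'`` z-scores
    each scale globally; ``'none'`` returns a flagged copy unchanged.
    """
    if raw.standardized:
        raise ValidationError("tensor is already standardized")
    Z = raw.values.astype(float).copy()
    if scheme == "none":
        pass
    elif scheme == "scale":
        for j in range(Z.shape[1]):
            sl = Z[:, j, :]
            sd = sl.std(ddof=1)
            if sd == 0:
                raise ValidationError(
                    f"zero variance on scale {raw.scales[j].name}"
                )
            Z[:, j, :] = (sl - sl.mean()) / sd
    elif scheme == "fiber":
        mean = Z.mean(axis=0, keepdims=True)
        sd = Z.std(axis=0, ddof=1, keepdims=True)
        bad = np.argwhere(sd[0] == 0)
        if bad.size:
            j, k = bad[0]
            raise ValidationError(
                "zero-variance fiber at "
                f"(scale={raw.scales[j].name}, subject={raw.subjects[k]})"
            )
        Z = (Z - mean) / sd
    else:
        raise ValidationError(f"unknown standardization scheme {scheme!r}")
    return raw.copy_with(values=Z, standardized=True)


def _als_single_start(
    Z: np.ndarray, R: int, tol: float, max_iter: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, int, bool, list[float]]:
    I, J, K = Z.shape
    A = rng.uniform(-1, 1, size=(I, R))
    B = rng.uniform(-1, 1, size=(J, R))
    C = rng.uniform(-1, 1, size=(K, R))
    Z0 = _unfold(Z, 0)
    Z1 = _unfold(Z, 1)
    Z2 = _unfold(Z, 2)

    sse_prev = np.inf
    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        A = _solve_mode(Z0, B, C)
        B = _solve_mode(Z1, A, C)
        C = _solve_mode(Z2, A, B)
        resid = Z0 - A @ _khatri_rao(B, C).T
        sse = float(np.sum(resid * resid))
        history.append(sse)
        if sse_prev - sse < tol * max(sse_prev, 1e-300):
            converged = True
            break
        sse_prev = sse
    return A, B, C, history[-1], it, converged, history


def _solve_mode(unfolded: np.ndarray, U: np.ndarray, V: np.ndarray) -> np.ndarray:
    # X(n) ~= F (U ⊙ V)^T  =>  F = X(n) (U ⊙ V) (U^T U * V^T V)^+
    kr = _khatri_rao(U, V)
    gram = (U.T @ U) * (V.T @ V)
    return unfolded @ kr @ np.linalg.pinv(gram)


def _normalize_model(A, B, C):
    """Absorb column scales into A; fix B/C column signs to positive sums."""
    bn = np.linalg.norm(B, axis=0)
    cn = np.linalg.norm(C, axis=0)
    bn[bn == 0] = 1.0
    cn[cn == 0] = 1.0
    B = B / bn
    C = C / cn
    A = A * (bn * cn)
    # deterministic sign convention: largest-|loading| entry of B positive,
    # compensated in A; C sign likewise compensated in A
    for r in range(B.shape[1]):
        jb = np.argmax(np.abs(B[:, r]))
        if B[jb, r] < 0:
            B[:, r] *= -1
            A[:, r] *= -1
        kc = np.argmax(np.abs(C[:, r]))
        if C[kc, r] < 0:
            C[:, r] *= -1
            A[:, r] *= -1
    return A, B, C


def fit_cp(
    tensor: RatingsTensor | np.ndarray,
    R: int,
    n_starts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int = 0,
    nonnegative_subjects: bool = False,
) -> CpModel:
    """Multi-start ALS fit of an R-factor CP model.

    The best start by residual sum of squares is kept.  Deterministic
    given ``seed``: start *s* uses a child generator derived from
    (seed, s).  With ``nonnegative_subjects`` the subject mode is clipped
    to be nonnegative after each update (projected ALS).
    """
    if isinstance(tensor, RatingsTensor):
        Z = tensor.values
        labels = (tensor.stimuli.ids, tensor.scale_names, tensor.subjects)
    else:
        Z = np.asarray(tensor, dtype=float)
        labels = ((), (), ())
    if Z.ndim != 3:
        raise FitError("a three-mode array is required")
    if not np.all(np.isfinite(Z)):
        raise FitError("tensor contains non-finite values")
    if R < 1:
        raise FitError("R must be >= 1")
    if R > min(Z.shape):
        raise FitError(f"R={R} exceeds the smallest mode length {min(Z.shape)}")

    total_ss = float(np.sum(Z * Z))
    best: CpModel | None = None
    for s in range(n_starts):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), s]))
        if nonnegative_subjects:
            A, B, C, sse, it, conv, hist = _als_nonneg_c(Z, R, tol, max_iter, rng)
        else:
            A, B, C, sse, it, conv, hist = _als_single_start(Z, R, tol, max_iter, rng)
        if best is None or sse < best.sse:
            A, B, C = _normalize_model(A, B, C)
            best = CpModel(
                A=A,
                B=B,
                C=C,
                R=R,
                sse=sse,
                total_ss=total_ss,
                n_iter=it,
                converged=conv,
                start_seed=s,
                sse_history=hist,
                stimulus_labels=tuple(labels[0]),
                scale_labels=tuple(labels[1]),
                subject_labels=tuple(labels[2]),
            )
    assert best is not None
    return best


def _als_nonneg_c(Z, R, tol, max_iter, rng):
    """ALS with the subject mode projected to the nonnegative orthant."""
    I, J, K = Z.shape
    A = rng.uniform(-1, 1, size=(I, R))
    B = rng.uniform(-1, 1, size=(J, R))
    C = rng.uniform(0, 1, size=(K, R))
    Z0, Z1, Z2 = (_unfold(Z, m) for m in range(3))

    sse_prev = np.inf
    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        A = _solve_mode(Z0, B, C)
        B = _solve_mode(Z1, A, C)
        C = np.maximum(_solve_mode(Z2, A, B), 0.0)
        resid = Z0 - A @ _khatri_rao(B, C).T
        sse = float(np.sum(resid * resid))
        history.append(sse)
        if abs(sse_prev - sse) < tol * max(sse_prev, 1e-300):
            converged = True
            break
        sse_prev = sse
    return A, B, C, history[-1], it, converged, history


def corcondia(tensor: RatingsTensor | np.ndarray, model: CpModel) -> float:
    """Core consistency diagnostic, in percent (may be negative).

    Solves the least-squares Tucker core G given the fitted A, B, C and
    compares it with the superdiagonal identity target T:
    ``100 * (1 - sum((g - t)^2) / sum(t^2))``.
    """
    Z = tensor.values if isinstance(tensor, RatingsTensor) else np.asarray(tensor, float)
    for M, name in ((model.A, "A"), (model.B, "B"), (model.C, "C")):
        norms = np.linalg.norm(M, axis=0)
        if np.any(norms <= 1e-12 * max(norms.max(), 1.0)):
            raise FitError(f"factor matrix {name} has a null column")
    # G = Z x1 A+ x2 B+ x3 C+  (pinv of a Kronecker product factors per mode)
    G = np.einsum(
        "ri,sj,tk,ijk->rst",
        np.linalg.pinv(model.A),
        np.linalg.pinv(model.B),
        np.linalg.pinv(model.C),
        Z,
    )
    R = model.R
    T = np.zeros((R, R, R))
    T[np.arange(R), np.arange(R), np.arange(R)] = 1.0
    return float(100.0 * (1.0 - np.sum((G - T) ** 2) / R))


def scree(
    tensor: RatingsTensor | np.ndarray,
    R_range: Sequence[int] = range(2, 11),
    n_starts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit summaries over a range of factor counts for model selection."""
    rows = []
    for R in R_range:
        m = fit_cp(tensor, R, n_starts=n_starts, tol=tol, max_iter=max_iter, seed=seed)
        rows.append(
            {
                "R": R,
                "sse": m.sse,
                "variance_explained": m.variance_explained,
                "corcondia": corcondia(tensor, m),
            }
        )
    return pd.DataFrame(rows, columns=["R", "sse", "variance_explained", "corcondia"])


def align_factors(model: CpModel, anchor: Mapping[str, int]) -> CpModel:
    """Resolve CP sign/permutation indeterminacy against anchor scales.

    ``anchor`` maps a scale label to the factor index (0-based) it should
    define; each anchored scale ends up loading positively on its
    assigned factor.  Signs are flipped jointly on A and B columns, so the
    reconstruction (and SSE) is unchanged.
    """
    if not model.scale_labels:
        raise FitError("model carries no scale labels to anchor against")
    targets = list(anchor.values())
    if len(set(targets)) != len(targets):
        raise FitError("contradictory anchor: one factor claimed by two scales")
    for t in targets:
        if not 0 <= t < model.R:
            raise FitError(f"anchor factor index {t} out of range")

    A = model.A.copy()
    B = model.B.copy()
    C = model.C.copy()
    perm = list(range(model.R))
    assigned: set[int] = set()
    # greedily permute: each anchored scale pulls the column it loads
    # most heavily on (in absolute value) into its assigned position
    for scale_name, target in anchor.items():
        if scale_name not in model.scale_labels:
            raise FitError(f"anchor scale {scale_name!r} not in model")
        j = model.scale_labels.index(scale_name)
        order = np.argsort(-np.abs(B[j, :]))
        src = next(int(r) for r in order if int(r) not in assigned)
        assigned.add(src)
        perm[target] = src
    # complete the permutation with the unassigned columns
    leftover = [r for r in range(model.R) if r not in assigned]
    for pos in range(model.R):
        if pos not in anchor.values():
            perm[pos] = leftover.pop(0)

    A = A[:, perm]
    B = B[:, perm]
    C = C[:, perm]
    for scale_name, target in anchor.items():
        j = model.scale_labels.index(scale_name)
        if B[j, target] < 0:
            B[:, target] *= -1
            A[:, target] *= -1
    return replace(model, A=A, B=B, C=C)


def split_joint_scores(
    model: CpModel, index: JointStimulusIndex
) -> tuple[np.ndarray, np.ndarray]:
    """Split the stimulus-weight matrix of a joint colors+music fit."""
    n = model.A.shape[0]
    if len(index.color_rows) + len(index.music_rows) != n:
        raise FitError(
            f"index covers {len(index.color_rows) + len(index.music_rows)} rows, "
            f"model has {n}"
        )
    return model.A[list(index.color_rows), :], model.A[list(index.music_rows), :]


def tucker_congruence(M1: np.ndarray, M2: np.ndarray) -> np.ndarray:
    """Per-factor Tucker congruence after optimal column permutation and sign.

    Returns the |cosine| between each matched pair of columns, in the
    column order of ``M1``.  Matching is exhaustive over the R!
    permutations (R is small here).
    """
    X = np.asarray(M1, dtype=float)
    Y = np.asarray(M2, dtype=float)
    if X.shape != Y.shape:
        raise FitError("factor matrices must have equal shape")
    norms_x = np.linalg.norm(X, axis=0)
    norms_y = np.linalg.norm(Y, axis=0)
    if np.any(norms_x == 0) or np.any(norms_y == 0):
        raise FitError("zero-norm factor column")
    Cmat = (X / norms_x).T @ (Y / norms_y)  # R x R cosines
    R = Cmat.shape[0]
    best_perm = None
    best_score = -np.inf
    for perm in itertools.permutations(range(R)):
        score = sum(abs(Cmat[r, perm[r]]) for r in range(R))
        if score > best_score:
            best_score = score
            best_perm = perm
    assert best_perm is not None
    return np.array([abs(Cmat[r, best_perm[r]]) for r in range(R)])
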