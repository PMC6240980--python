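"""Rank-based correlation, mediation partialling, and reliability statistics.

All correlations are Spearman's rho (mid-ranks for ties), with p-values
from the t approximation on n-2 degrees of freedom — appropriate at the
study's sample sizes (34 excerpts, 37 colors).  Partial correlations are
computed by rank-transforming every variable, residualizing the ranked x
and y on the ranked covariates by least squares, and correlating the
residuals; this scales to the ten simultaneous covariates used in the
mediation analysis, where recursion formulas would not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


class StatError(ValueError):
    """Raised on degenerate statistical input (constant vector, collinear covariates)."""


def _as_vector(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(v)):
        raise StatError(f"{name} contains non-finite values")
    return v


def _t_pvalue(rho: float, df: int, tail: str) -> float:
    if df <= 0:
        raise StatError("not enough observations for a p-value")
    r = min(max(rho, -1.0), 1.0)
    if abs(r) >= 1.0:
        t = np.inf * np.sign(r)
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
    if tail == "two":
        return float(2.0 * sps.t.sf(abs(t), df))
    if tail == "one":
        # one-tailed in the direction of positive association
        return float(sps.t.sf(t, df))
    raise StatError(f"unknown tail {tail!r}")


def spearman(x, y, tail: str = "two") -> tuple[float, float]:
    """Spearman rank correlation with a t-approximation p-value.

    Ties receive mid-ranks.  ``tail='one'`` tests for positive
    association; ``tail='two'`` is symmetric.
    """
    xv = _as_vector(x, "x")
    yv = _as_vector(y, "y")
    if xv.size != yv.size:
        raise StatError("x and y must have equal length")
    n = xv.size
    if n < 3:
        raise StatError("need at least 3 observations")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise StatError("Spearman correlation undefined for a constant vector")
    rx = sps.rankdata(xv)
    ry = sps.rankdata(yv)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    return rho, _t_pvalue(rho, n - 2, tail)


def partial_spearman(x, y, Z, tail: str = "two") -> tuple[float, float]:
    """Spearman correlation of x and y after removing ranked covariates Z.

    Z is a sequence of covariate vectors (or an (n, q) array).  With Z
    empty this reduces exactly to :func:`spearman`.  The p-value uses
    n - q - 2 degrees of freedom.
    """
    xv = _as_vector(x, "x")
    yv = _as_vector(y, "y")
    Zm = np.asarray(Z, dtype=float)
    if Zm.size == 0:
        return spearman(xv, yv, tail)
    if Zm.ndim == 1:
        Zm = Zm[:, None]
    elif Zm.shape[0] != xv.size and Zm.shape[1] == xv.size:
        Zm = Zm.T
    if Zm.shape[0] != xv.size:
        raise StatError("covariate length does not match x")
    n, q = Zm.shape
    if n <= q + 2:
        raise StatError(f"need n > q + 2 (n={n}, q={q})")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise StatError("constant input vector")

    rx = sps.rankdata(xv)
    ry = sps.rankdata(yv)
    RZ = np.column_stack([sps.rankdata(Zm[:, j]) for j in range(q)])
    D = np.column_stack([np.ones(n), RZ])
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        raise StatError("collinear covariates in Z")
    beta_x, *_ = np.linalg.lstsq(D, rx, rcond=None)
    beta_y, *_ = np.linalg.lstsq(D, ry, rcond=None)
    ex = rx - D @ beta_x
    ey = ry - D @ beta_y
    if np.allclose(ex, 0) or np.allclose(ey, 0):
        raise StatError("a variable is perfectly explained by the covariates")
    rho = float(np.corrcoef(ex, ey)[0, 1])
    return rho, _t_pvalue(rho, n - q - 2, tail)


def adjust_pvalues(p, method: str = "holm") -> np.ndarray:
    """Family-wise adjusted p-values (Holm step-down or Bonferroni)."""
    pv = _as_vector(p, "p")
    if pv.size == 0:
        return pv
    if np.any((pv < 0) | (pv > 1)):
        raise StatError("p-values must lie in [0, 1]")
    m = pv.size
    if method == "bonferroni":
        return np.minimum(1.0, m * pv)
    if method == "holm":
        order = np.argsort(pv, kind="stable")
        scaled = pv[order] * (m - np.arange(m))
        adj_sorted = np.minimum(1.0, np.maximum.accumulate(scaled))
        out = np.empty(m)
        out[order] = adj_sorted
        return out
    if method == "none":
        return pv.copy()
    raise StatError(f"unknown correction method {method!r}")


def cronbach_alpha(matrix) -> float:
    """Cronbach's alpha for a stimulus x rater matrix (sample variances)."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise StatError("need at least 2 stimuli and 2 raters")
    k = X.shape[1]
    item_vars = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise StatError("zero variance of rater sums")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


@dataclass
class CorrelationEntry:
    x_label: str
    y_label: str
    rho: float
    n: int
    p_raw: float
    p_adjusted: float
    tail: str
    covariates: tuple[str, ...] = ()


@dataclass
class CorrelationReport:
    """Labeled family of (partial) Spearman correlations with corrected p-values."""

    entries: list[CorrelationEntry]
    method: str  # {spearman, partial_spearman}
    correction: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (
                    e.x_label,
                    e.y_label,
                    e.rho,
                    e.n,
                    e.p_raw,
                    e.p_adjusted,
                    e.tail,
                    ";".join(e.covariates),
                )
                for e in self.entries
            ],
            columns=[
                "x",
                "y",
                "rho",
                "n",
                "p_raw",
                "p_adjusted",
                "tail",
                "covariates",
            ],
        )

    def n_significant(self, alpha: float = 0.05) -> int:
        return int(sum(e.p_adjusted < alpha for e in self.entries))

    def matrix(self, value: str = "rho") -> pd.DataFrame:
        df = self.to_frame()
        return df.pivot(index="x", columns="y", values=value)


def correlation_matrix(
    X: Mapping[str, Sequence[float]] | pd.DataFrame,
    Y: Mapping[str, Sequence[float]] | pd.DataFrame,
    correction: str = "holm",
    tail: str = "two",
    Z: Mapping[str, Sequence[float]] | pd.DataFrame | None = None,
) -> CorrelationReport:
    """All pairwise (partial) Spearman correlations, corrected as one family.

    The family over which the correction is applied is the full |X| x |Y|
    grid — each figure-style matrix in the analysis is its own family.
    Passing ``Z`` computes partial correlations with the same covariate
    set for every pair.
    """
    Xd = pd.DataFrame(X)
    Yd = pd.DataFrame(Y)
    if len(Xd) != len(Yd):
        raise StatError("X and Y must share observations")
    Zd = pd.DataFrame(Z) if Z is not None else None
    covariates = tuple(map(str, Zd.columns)) if Zd is not None else ()

    entries: list[CorrelationEntry] = []
    for xl in Xd.columns:
        for yl in Yd.columns:
            if Zd is None:
                rho, p = spearman(Xd[xl], Yd[yl], tail=tail)
            else:
                rho, p = partial_spearman(Xd[xl], Yd[yl], Zd.to_numpy(), tail=tail)
            entries.append(
                CorrelationEntry(
                    str(xl), str(yl), rho, len(Xd), p, np.nan, tail, covariates
                )
            )
    adjusted = adjust_pvalues([e.p_raw for e in entries], correction)
    for e, a in zip(entries, adjusted):
        e.p_adjusted = float(a)
    return CorrelationReport(
        entries,
        method="partial_spearman" if Zd is not None else "spearman",
        correction=correction,
    )


@dataclass
class VariancePartition:
    """Hierarchical OLS variance decomposition for one response."""

    response_label: str
    first_entered: str
    r2_first: float
    r2_total: float
    coefficient_signs: dict[str, int] = field(default_factory=dict)

    @property
    def r2_increment(self) -> float:
        return self.r2_total - self.r2_first


def _ols_r2(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    n = y.size
    D = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise StatError("collinear predictors")
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    tss = np.sum((y - y.mean()) ** 2)
    if tss == 0:
        raise StatError("constant response")
    return float(1.0 - resid @ resid / tss), beta[1:]


def hierarchical_r2(
    factors: Mapping[str, Sequence[float]] | pd.DataFrame,
    response: Sequence[float],
    response_label: str = "response",
    first: str | None = None,
) -> VariancePartition:
    """OLS with the named factor entered first; reports R² of the
    single-predictor and the full two-predictor model."""
    F = pd.DataFrame(factors)
    if F.shape[1] != 2:
        raise StatError("exactly two factor score vectors are required")
    y = _as_vector(response, "response")
    if len(F) != y.size:
        raise StatError("response length mismatch")
    if y.size <= 3:
        raise StatError("need more than 3 observations")
    first = str(first) if first is not None else str(F.columns[0])
    if first not in map(str, F.columns):
        raise StatError(f"unknown first factor {first!r}")
    other = [c for c in map(str, F.columns) if c != first][0]

    r2_first, _ = _ols_r2(F[first].to_numpy()[:, None], y)
    r2_total, betas = _ols_r2(F[[first, other]].to_numpy(), y)
    signs = {
        first: int(np.sign(betas[0])),
        other: int(np.sign(betas[1])),
    }
    return VariancePartition(
        response_label=response_label,
        first_entered=first,
        r2_first=r2_first,
        r2_total=r2_total,
        coefficient_signs=signs,
    )
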