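"""Multivariate general linear model per region.

For one region's data matrix Y (subjects x modalities) and a design matrix
X (intercept, diagnostic group, confounds), the model is

    Y = X B + U,        rows of U ~ N_p(0, Sigma)

fit by ordinary least squares.  The group effect is tested through the
hypothesis and error SSCP matrices

    E = (Y - X B)' (Y - X B)
    H = (C B)' [C (X'X)^- C']^{-1} (C B)

whose generalized eigenstructure H v = lambda E v yields the canonical
vectors (the modality combinations that best separate the groups) and
Wilks' lambda

    Lambda = det(E) / det(E + H) = prod_i 1 / (1 + lambda_i).

Significance is assessed with Bartlett's chi-square approximation

    chi2 = -(n - r - (p - q + 1)/2) ln Lambda,   df = p q,

and with Rao's F transformation of Lambda (exact when min(p, q) <= 2).
Here n = subjects, r = rank of X, p = modalities, q = hypothesis df.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats

__all__ = [
    "DesignMatrix",
    "HypothesisContrast",
    "MglmFit",
    "RegionTestResult",
    "build_design",
    "fit_mglm",
    "hypothesis_sscp",
    "wilks_lambda",
    "bartlett_chi2",
    "chi2_upper_tail",
    "rao_f",
    "canonical_vectors",
    "region_test",
]

_RANK_RTOL = 1e-10  # relative singular-value cutoff for numerical rank


@dataclass
class DesignMatrix:
    """Design with tagged columns: exactly one intercept, >= 1 group column."""

    matrix: np.ndarray
    column_roles: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("design matrix must be 2-D")
        if len(self.column_roles) != self.matrix.shape[1]:
            raise ValueError("one role per design column required")
        bad = set(self.column_roles) - {"intercept", "group", "confound"}
        if bad:
            raise ValueError(f"unknown column roles: {sorted(bad)}")
        if self.column_roles.count("intercept") != 1:
            raise ValueError("exactly one intercept column required")
        if "group" not in self.column_roles:
            raise ValueError("at least one group column required")
        if self.n <= self.rank:
            raise ValueError("no error degrees of freedom (n <= rank of X)")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def rank(self) -> int:
        s = np.linalg.svd(self.matrix, compute_uv=False)
        if s.size == 0 or s[0] == 0:
            return 0
        return int(np.sum(s > _RANK_RTOL * s[0]))

    @property
    def group_columns(self) -> list[int]:
        return [j for j, r in enumerate(self.column_roles) if r == "group"]

    @property
    def confound_columns(self) -> list[int]:
        return [j for j, r in enumerate(self.column_roles) if r == "confound"]


@dataclass
class HypothesisContrast:
    """Full-row-rank contrast C over design columns; q = rows of C."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if np.linalg.matrix_rank(self.matrix) != self.matrix.shape[0]:
            raise ValueError("contrast matrix must have full row rank")

    @property
    def q(self) -> int:
        return self.matrix.shape[0]


@dataclass
class MglmFit:
    B: np.ndarray            # columns x modalities coefficients
    E: np.ndarray            # residual SSCP, modalities x modalities
    error_df: int            # n - rank(X)

    def __post_init__(self) -> None:
        if not np.allclose(self.E, self.E.T, atol=1e-10):
            raise ValueError("residual SSCP must be symmetric")
        if self.error_df <= 0:
            raise ValueError("error_df must be positive")


@dataclass
class RegionTestResult:
    region_id: int
    region_name: str
    wilks_lambda: float
    chi_square: float
    df: int
    p_value: float
    f_stat: float
    f_df1: float
    f_df2: float
    f_p_value: float
    canonical_vector: np.ndarray
    canonical_eigenvalues: np.ndarray
    canonical_matrix: np.ndarray = field(repr=False, default=None)
    p_corrected: float | None = None


def build_design(
    cohort: pd.DataFrame,
    group_column: str = "diagnosis",
    confounds: tuple[str, ...] = ("age", "sex", "tiv"),
    group_order: tuple[str, str] | None = None,
) -> tuple[DesignMatrix, HypothesisContrast]:
    """Intercept + two-level group indicator + confound columns.

    The group is coded as a single 0/1 indicator (q = 1); the returned
    contrast selects that column, testing equality of the two group means
    adjusted for confounds.
    """
    levels = list(pd.unique(cohort[group_column]))
    if len(levels) != 2:
        raise ValueError(
            f"group column {group_column!r} must have exactly 2 levels, got {levels}"
        )
    if group_order is not None:
        if set(group_order) != set(levels):
            raise ValueError(f"group_order {group_order} does not match levels {levels}")
        levels = list(group_order)
    indicator = (cohort[group_column] == levels[1]).to_numpy(dtype=float)
    cols = [np.ones(len(cohort)), indicator]
    roles = ["intercept", "group"]
    for c in confounds:
        if c not in cohort.columns:
            raise ValueError(f"confound column {c!r} not in cohort table")
        cols.append(cohort[c].to_numpy(dtype=float))
        roles.append("confound")
    X = DesignMatrix(np.column_stack(cols), roles)
    C = np.zeros((1, X.matrix.shape[1]))
    C[0, 1] = 1.0
    return X, HypothesisContrast(C)


def fit_mglm(Y, X: DesignMatrix) -> MglmFit:
    """OLS fit of the multivariate linear model (min-norm if X is rank-deficient)."""
    values = Y.values if hasattr(Y, "values") else np.asarray(Y, dtype=float)
    values = np.atleast_2d(values.astype(float))
    if values.shape[0] != X.n:
        raise ValueError(
            f"Y has {values.shape[0]} rows but design has {X.n} subjects"
        )
    B, *_ = np.linalg.lstsq(X.matrix, values, rcond=_RANK_RTOL)
    resid = values - X.matrix @ B
    E = resid.T @ resid
    E = (E + E.T) / 2.0
    return MglmFit(B=B, E=E, error_df=X.n - X.rank)


def hypothesis_sscp(fit: MglmFit, X: DesignMatrix, C: HypothesisContrast) -> np.ndarray:
    """H = (C B)' [C (X'X)^- C']^{-1} (C B) for the contrast C."""
    Cm = C.matrix
    if Cm.shape[1] != X.matrix.shape[1]:
        raise ValueError(
            f"contrast has {Cm.shape[1]} columns, design has {X.matrix.shape[1]}"
        )
    XtX = X.matrix.T @ X.matrix
    XtX_pinv = np.linalg.pinv(XtX, rcond=_RANK_RTOL)
    # estimability: C must lie in the row space of X
    if not np.allclose(Cm @ XtX_pinv @ XtX, Cm, atol=1e-8):
        raise ValueError("contrast is not estimable under this design")
    M = Cm @ XtX_pinv @ Cm.T
    CB = Cm @ fit.B
    H = CB.T @ np.linalg.solve(M, CB)
    return (H + H.T) / 2.0


def _check_e_nonsingular(E: np.ndarray) -> np.ndarray:
    E = np.atleast_2d(np.asarray(E, dtype=float))
    try:
        return np.linalg.cholesky(E)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "error SSCP is singular; collect more subjects or use fewer modalities"
        ) from None


def wilks_lambda(H, E) -> float:
    """Lambda = det(E) / det(E + H), clamped to (0, 1]."""
    H = np.atleast_2d(np.asarray(H, dtype=float))
    L = _check_e_nonsingular(E)
    E = np.atleast_2d(np.asarray(E, dtype=float))
    ld_e = 2.0 * np.sum(np.log(np.diag(L)))
    sign, ld_eh = np.linalg.slogdet(E + H)
    if sign <= 0:
        raise np.linalg.LinAlgError("E + H is not positive definite")
    lam = float(np.exp(ld_e - ld_eh))
    return min(1.0, max(lam, np.finfo(float).tiny))


def bartlett_chi2(lam: float, n: int, r: int, p: int, q: int) -> tuple[float, int]:
    """Bartlett's chi-square approximation of Wilks' lambda."""
    if not 0.0 < lam <= 1.0:
        raise ValueError(f"lambda must be in (0, 1], got {lam}")
    scale = n - r - (p - q + 1) / 2.0
    if scale <= 0:
        raise ValueError(
            f"nonpositive Bartlett scale {scale}: sample too small for p={p}, q={q}"
        )
    return float(-scale * np.log(lam)), p * q


def chi2_upper_tail(x: float, df: int) -> float:
    if x < 0:
        raise ValueError("chi-square statistic must be >= 0")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.sf(x, df))


def rao_f(lam: float, n: int, r: int, p: int, q: int) -> tuple[float, float, float]:
    """Rao's F approximation of Wilks' lambda (exact when min(p, q) <= 2)."""
    if not 0.0 < lam <= 1.0:
        raise ValueError(f"lambda must be in (0, 1], got {lam}")
    pq = p * q
    denom = p * p + q * q - 5
    s = np.sqrt((p * p * q * q - 4.0) / denom) if denom > 0 else 1.0
    m = (n - r) - (p - q + 1) / 2.0
    df2 = m * s - pq / 2.0 + 1.0
    if df2 <= 0:
        raise ValueError(f"nonpositive F denominator df {df2}: sample too small")
    ls = lam ** (1.0 / s)
    F = ((1.0 - ls) / ls) * (df2 / pq)
    return float(F), float(pq), float(df2)


def canonical_vectors(H, E) -> tuple[np.ndarray, np.ndarray]:
    """Solve H v = lambda E v; unit-norm columns, eigenvalues nonincreasing.

    Sign convention: the largest-magnitude component of each vector is
    positive (signs are otherwise arbitrary).  Ties in eigenvalues (within
    1e-12) are broken by ascending lexicographic comparison of the vectors.
    """
    H = np.atleast_2d(np.asarray(H, dtype=float))
    _check_e_nonsingular(E)
    E = np.atleast_2d(np.asarray(E, dtype=float))
    eigvals, eigvecs = scipy.linalg.eigh(H, E)
    eigvals = np.clip(eigvals[::-1], 0.0, None)
    eigvecs = eigvecs[:, ::-1]
    # unit Euclidean norm and sign fix
    eigvecs = eigvecs / np.linalg.norm(eigvecs, axis=0, keepdims=True)
    for j in range(eigvecs.shape[1]):
        k = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[k, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    # deterministic order within eigenvalue ties
    order = list(range(len(eigvals)))
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and abs(eigvals[order[j + 1]] - eigvals[order[i]]) <= 1e-12:
            j += 1
        if j > i:
            tied = sorted(order[i : j + 1], key=lambda k: tuple(eigvecs[:, k]))
            order[i : j + 1] = tied
        i = j + 1
    return eigvecs[:, order], eigvals[order]


def region_test(
    Y,
    X: DesignMatrix,
    C: HypothesisContrast,
    region_id: int | None = None,
    region_name: str | None = None,
) -> RegionTestResult:
    """Full per-region test chain: fit, SSCP, Wilks, chi-square, F, canonical vectors."""
    rid = region_id if region_id is not None else getattr(Y, "region_id", 0)
    rname = region_name if region_name is not None else getattr(Y, "region_name", str(rid))
    try:
        fit = fit_mglm(Y, X)
        H = hypothesis_sscp(fit, X, C)
        lam = wilks_lambda(H, fit.E)
        p = fit.E.shape[0]
        q = C.q
        n, r = X.n, X.rank
        chi2, df = bartlett_chi2(lam, n, r, p, q)
        pval = chi2_upper_tail(chi2, df)
        F, df1, df2 = rao_f(lam, n, r, p, q)
        f_p = float(stats.f.sf(F, df1, df2))
        vecs, vals = canonical_vectors(H, fit.E)
    except (ValueError, np.linalg.LinAlgError) as exc:
        raise type(exc)(f"region {rname!r}: {exc}") from exc
    lam_from_eigs = float(np.prod(1.0 / (1.0 + vals)))
    if abs(lam_from_eigs - lam) > 1e-8:
        raise ArithmeticError(
            f"region {rname!r}: Wilks lambda {lam} inconsistent with "
            f"canonical eigenvalues (prod 1/(1+l) = {lam_from_eigs})"
        )
    return RegionTestResult(
        region_id=rid,
        region_name=rname,
        wilks_lambda=lam,
        chi_square=chi2,
        df=df,
        p_value=pval,
        f_stat=F,
        f_df1=df1,
        f_df2=df2,
        f_p_value=f_p,
        canonical_vector=vecs[:, 0].copy(),
        canonical_eigenvalues=vals,
        canonical_matrix=vecs,
    )
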