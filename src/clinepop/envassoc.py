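"""Genotype-environment association: VIF pruning, RDA, and Mantel tests.

Redundancy analysis (RDA) regresses a population x clinal-locus frequency
matrix Y on environmental predictors X (optionally after residualizing both
on conditioning covariates such as latitude/longitude — partial RDA), and
partitions variance into the constrained projection and the residual.
Significance is by permutation of (residualized) response rows: a global
pseudo-F test and marginal (type-III) per-term tests under the reduced
model, following the standard constrained-ordination convention.

The partial Mantel statistic is the Pearson correlation of the off-diagonal
residuals of two distance matrices after matrix regression on a control
matrix, with significance from joint row/column permutations of the first
matrix (two-sided).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VifReport",
    "RdaResult",
    "MantelResult",
    "vif_prune",
    "rda",
    "mantel",
    "partial_mantel",
]


# ---------------------------------------------------------------------------
# VIF pruning
# ---------------------------------------------------------------------------

@dataclass
class VifReport:
    vif_initial: dict[str, float]
    vif_final: dict[str, float]
    dropped: list[str]          # in drop order
    retained: list[str]
    threshold: float


def _vifs(X: np.ndarray) -> np.ndarray:
    """VIF_k = 1/(1 - R^2_k) of column k regressed on the others (+intercept)."""
    n, p = X.shape
    out = np.empty(p)
    for k in range(p):
        y = X[:, k]
        others = np.column_stack([np.ones(n), np.delete(X, k, axis=1)])
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        ss_tot = ((y - y.mean()) ** 2).sum()
        if ss_tot <= 0:
            out[k] = np.inf
            continue
        r2 = 1 - (resid ** 2).sum() / ss_tot
        out[k] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_prune(X: pd.DataFrame, threshold: float = 5.0) -> VifReport:
    """Iteratively drop the largest-VIF predictor until all VIFs < threshold.

    Exact collinearity shows up as infinite VIF and is dropped first; ties
    are broken by column order (the earlier column is kept).  Terminates in
    at most #predictors iterations.
    """
    if X.shape[1] < 2:
        raise ValueError("need at least two predictors")
    if X.shape[0] < X.shape[1] + 2:
        raise ValueError("need at least #predictors + 2 rows")
    cols = list(X.columns)
    initial = dict(zip(cols, _vifs(X[cols].to_numpy(float))))
    dropped: list[str] = []
    while len(cols) >= 2:
        v = _vifs(X[cols].to_numpy(float))
        worst = int(np.argmax(v))  # argmax keeps the FIRST max -> drops later duplicate?
        # tie-break by column order: among maximal VIFs keep the earliest column,
        # i.e. drop the LAST of the tied columns
        tied = np.flatnonzero(v == v[worst])
        worst = int(tied[-1])
        if v[worst] < threshold:
            break
        dropped.append(cols.pop(worst))
    final = dict(zip(cols, _vifs(X[cols].to_numpy(float)))) if len(cols) >= 2 else {
        c: 1.0 for c in cols
    }
    return VifReport(initial, final, dropped, cols, threshold)


# ---------------------------------------------------------------------------
# RDA
# ---------------------------------------------------------------------------

@dataclass
class RdaResult:
    total_variance: float
    constrained_variance: float
    proportion_explained: float
    axes: np.ndarray                 # canonical axes (columns)
    eigenvalues: np.ndarray
    pseudo_f: float
    p_global: float | None
    marginal: pd.DataFrame | None    # per-term type-III F and p
    rank: int
    n_perm: int


def _residualize(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of M on [1, C] by least squares."""
    Z = np.column_stack([np.ones(len(M)), C])
    coef, *_ = np.linalg.lstsq(Z, M, rcond=None)
    return M - Z @ coef


def _fit_rda(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float, float, int]:
    """Returns (Yhat, constrained SS, residual SS, rank of X)."""
    Xc = X - X.mean(axis=0)
    coef, _, rank, _ = np.linalg.lstsq(Xc, Y, rcond=None)
    Yhat = Xc @ coef
    ss_c = float((Yhat ** 2).sum())
    ss_r = float(((Y - Yhat) ** 2).sum())
    return Yhat, ss_c, ss_r, int(rank)


def rda(
    Y: pd.DataFrame,
    X: pd.DataFrame,
    condition: pd.DataFrame | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    standardize: bool = True,
) -> RdaResult:
    """Redundancy analysis of Y (populations x loci) on predictors X.

    Y is centered; when ``condition`` is given both Y and X are first
    residualized on it (partial RDA).  Predictors are z-scored by default.
    Global significance permutes rows of the (residualized) Y; marginal
    type-III tests refit each predictor given all the others, permuting
    reduced-model residuals.  p = (exceedances + 1)/(n_perm + 1).
    """
    if not (len(Y) == len(X) and (condition is None or len(condition) == len(Y))):
        raise ValueError("Y, X and condition must have aligned rows")
    n = len(Y)
    q = 0 if condition is None else condition.shape[1]
    if n <= X.shape[1] + q + 1:
        raise ValueError("need more rows than predictors + conditions + 1")
    Ym = Y.to_numpy(float)
    Ym = Ym - Ym.mean(axis=0)
    Xm = X.to_numpy(float).copy()
    if standardize:
        sd = Xm.std(axis=0)
        if np.any(sd == 0):
            bad = [X.columns[i] for i in np.flatnonzero(sd == 0)]
            raise ValueError(f"constant predictor columns: {bad}")
        Xm = (Xm - Xm.mean(axis=0)) / sd
    if condition is not None:
        C = condition.to_numpy(float)
        Ym = _residualize(Ym, C)
        Xm = _residualize(Xm, C)

    Yhat, ss_c, ss_r, rank = _fit_rda(Ym, Xm)
    if rank < Xm.shape[1]:
        # name the deficient columns: those whose VIF is infinite
        v = _vifs(Xm) if Xm.shape[1] > 1 else np.array([1.0])
        bad = [X.columns[i] for i in np.flatnonzero(~np.isfinite(v))]
        raise ValueError(f"rank-deficient predictors after conditioning: {bad or 'unknown'}")
    ss_tot = float((Ym ** 2).sum())
    total_var = ss_tot / (n - 1)
    constrained_var = ss_c / (n - 1)
    prop = ss_c / ss_tot if ss_tot > 0 else 0.0

    # canonical axes: eigen-decomposition of Yhat' Yhat
    _, s, vt = np.linalg.svd(Yhat, full_matrices=False)
    eig = (s ** 2) / (n - 1)
    axes = vt.T[:, : rank]

    df_resid = n - rank - 1 - q
    pseudo_f = (ss_c / rank) / (ss_r / df_resid) if ss_r > 0 else np.inf

    rng = np.random.default_rng(seed)
    p_global = None
    if n_perm > 0:
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            _, ss_cp, ss_rp, _ = _fit_rda(Ym[perm], Xm)
            f_p = (ss_cp / rank) / (ss_rp / df_resid) if ss_rp > 0 else np.inf
            if f_p >= pseudo_f:
                exceed += 1
        p_global = (exceed + 1) / (n_perm + 1)

    marginal = None
    if n_perm > 0 and Xm.shape[1] > 1:
        rows = []
        for j, name in enumerate(X.columns):
            X_red = np.delete(Xm, j, axis=1)
            Yhat_red, ss_red, _, rank_red = _fit_rda(Ym, X_red)
            df_j = rank - rank_red
            if df_j <= 0:
                rows.append(dict(term=name, pseudo_f=np.nan, p=np.nan))
                continue
            f_obs = ((ss_c - ss_red) / df_j) / (ss_r / df_resid)
            resid_red = Ym - Yhat_red
            exceed = 0
            for _ in range(n_perm):
                perm = rng.permutation(n)
                Y_p = Yhat_red + resid_red[perm]
                Y_p = Y_p - Y_p.mean(axis=0)
                _, ss_cp, ss_rp, _ = _fit_rda(Y_p, Xm)
                _, ss_redp, _, _ = _fit_rda(Y_p, X_red)
                f_p = ((ss_cp - ss_redp) / df_j) / (ss_rp / df_resid)
                if f_p >= f_obs:
                    exceed += 1
            rows.append(dict(term=name, pseudo_f=f_obs, p=(exceed + 1) / (n_perm + 1)))
        marginal = pd.DataFrame(rows)

    return RdaResult(
        total_variance=total_var,
        constrained_variance=constrained_var,
        proportion_explained=prop,
        axes=axes,
        eigenvalues=eig[: rank],
        pseudo_f=pseudo_f,
        p_global=p_global,
        marginal=marginal,
        rank=rank,
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# Mantel tests
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    n_perm: int
    p_value: float
    partial: bool
    control: str | None


def _offdiag(M: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(len(M), 1)
    return M[iu]


def _check_dist(M: np.ndarray, name: str) -> None:
    if not np.allclose(M, M.T):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(M), 0):
        raise ValueError(f"{name} must have a zero diagonal")


def mantel(A: pd.DataFrame, B: pd.DataFrame, n_perm: int = 999, seed: int = 0) -> MantelResult:
    """Simple Mantel test: Pearson correlation of off-diagonals, two-sided
    permutation p from joint row/column permutations of A."""
    return partial_mantel(A, B, None, n_perm=n_perm, seed=seed)


def partial_mantel(
    A: pd.DataFrame,
    B: pd.DataFrame,
    C: pd.DataFrame | None,
    n_perm: int = 999,
    seed: int = 0,
) -> MantelResult:
    """Partial Mantel correlation of A and B controlling for C.

    r is the Pearson correlation of the off-diagonal residuals of A|C and
    B|C; with C = None this reduces to the simple Mantel r.  The null
    distribution jointly permutes rows/columns of A; two-sided
    p = (#{|r_perm| >= |r_obs|} + 1)/(n_perm + 1).
    """
    Am = A.to_numpy(float)
    Bm = B.to_numpy(float)
    _check_dist(Am, "A")
    _check_dist(Bm, "B")
    n = len(Am)
    if Bm.shape != (n, n):
        raise ValueError("matrices must share a common population order")
    if C is not None:
        Cm = C.to_numpy(float)
        _check_dist(Cm, "C")
        c_off = _offdiag(Cm)
    else:
        c_off = None

    b_off = _offdiag(Bm)
    if np.ptp(b_off) == 0:
        raise ValueError("constant off-diagonal in B: correlation undefined")

    def _stat(a_off: np.ndarray) -> float:
        if np.ptp(a_off) == 0:
            raise ValueError("constant off-diagonal in A: correlation undefined")
        if c_off is None:
            return float(np.corrcoef(a_off, b_off)[0, 1])
        Z = np.column_stack([np.ones_like(c_off), c_off])
        ra = a_off - Z @ np.linalg.lstsq(Z, a_off, rcond=None)[0]
        rb = b_off - Z @ np.linalg.lstsq(Z, b_off, rcond=None)[0]
        if np.ptp(ra) == 0 or np.ptp(rb) == 0:
            raise ValueError("residuals constant after controlling: undefined")
        return float(np.corrcoef(ra, rb)[0, 1])

    r_obs = _stat(_offdiag(Am))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = _stat(_offdiag(Am[np.ix_(perm, perm)]))
        if abs(r_p) >= abs(r_obs):
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return MantelResult(
        r=r_obs, n_perm=n_perm, p_value=p, partial=C is not None,
        control=None if C is None else "C",
    )
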