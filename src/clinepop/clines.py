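"""Per-locus binomial logistic clines in latitude and the steep-change rule.

For each locus and lineage, counted-allele counts k_j of m_j alleles in
population j at latitude x_j are modelled as Binomial(m_j, p(x_j)) with
p(x) = 1/(1 + exp(-(a + b x))), fitted by iteratively reweighted least
squares.  The classifier statistic is the fitted range
dp = |p(x_max) - p(x_min)| evaluated on the fitted curve at the lineage's
observed latitude extremes; a locus is clinal when dp strictly exceeds the
threshold (default 0.40).  A threshold scan over a grid, with a knee
estimate from the discrete second difference of the retained-locus count,
serves as the diagnostic that motivates the default threshold.

Binomial counts, not bare frequencies, are the response, so small samples
carry proportionally less weight.  Perfect separation is capped at
|b| <= SEPARATION_CAP per degree and flagged rather than diverging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit

from .genio import FreqTable

__all__ = [
    "ClineFit",
    "ClinalSet",
    "SEPARATION_CAP",
    "fit_locus_cline",
    "fit_all_clines",
    "classify_clinal",
    "threshold_scan",
]

SEPARATION_CAP = 50.0  # |slope| bound, logit units per degree latitude
_TOL = 1e-8
_MAX_ITER = 100


@dataclass
class ClineFit:
    locus: str
    intercept: float
    slope: float
    p_at_min: float     # fitted frequency at the observed minimum latitude
    p_at_max: float
    dp: float           # |p_at_max - p_at_min| on the fitted curve
    converged: bool
    capped: bool        # separation cap engaged
    degenerate: bool    # monomorphic / undefined fit
    wald_p: float       # two-sided Wald p for the slope (NaN if unavailable)


@dataclass
class ClinalSet:
    threshold: float
    loci: list[str]
    fits: dict[str, ClineFit]


def _irls_binomial(x: np.ndarray, k: np.ndarray, m: np.ndarray):
    """IRLS for logit(p) = a + b x with binomial response (k of m).

    Returns (a, b, converged, capped, cov).  The slope is clamped to
    +/- SEPARATION_CAP each step; if the clamp is active at exit the fit is
    flagged capped (separation) and the intercept is re-profiled with the
    slope held at the cap.
    """
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    p0 = np.clip(k.sum() / m.sum(), 1e-9, 1 - 1e-9)
    beta[0] = np.log(p0 / (1 - p0))
    converged = False
    capped = False
    for _ in range(_MAX_ITER):
        eta = X @ beta
        p = expit(eta)
        w = m * p * (1 - p)
        if w.sum() < 1e-12:
            break
        grad = X.T @ (k - m * p)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        new = beta + step
        if abs(new[1]) > SEPARATION_CAP:
            new[1] = np.sign(new[1]) * SEPARATION_CAP
            capped = True
        else:
            capped = False
        if np.max(np.abs(new - beta)) < _TOL:
            beta = new
            converged = not capped
            break
        beta = new
    if not converged and not capped:
        # complete separation: the fit is perfect but the slope drifts to
        # infinity without ever tripping the cap; detect via zero residuals
        p = expit(X @ beta)
        if np.max(np.abs(k - m * p)) < 1e-3 and beta[1] != 0:
            beta[1] = np.sign(beta[1]) * SEPARATION_CAP
            capped = True
    if capped:
        # profile intercept at the capped slope; when the data are fully
        # separated every interior intercept fits perfectly, so place the
        # transition at the midpoint of the gap between the low- and
        # high-frequency populations (deterministic tie-break)
        b = beta[1]
        freq = k / np.maximum(m, 1)
        lo_side = freq < 0.5
        if lo_side.any() and (~lo_side).any():
            if b > 0:
                x_mid = (x[lo_side].max() + x[~lo_side].min()) / 2
            else:
                x_mid = (x[lo_side].min() + x[~lo_side].max()) / 2
            a = -b * x_mid
        else:
            a = beta[0]
        for _ in range(_MAX_ITER):
            p = expit(a + b * x)
            w = (m * p * (1 - p)).sum()
            if w < 1e-12:
                break
            da = (k - m * p).sum() / w
            a += da
            if abs(da) < _TOL:
                break
        beta = np.array([a, b])
    eta = X @ beta
    p = expit(eta)
    w = m * p * (1 - p)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.nan)
    return beta[0], beta[1], converged, capped, cov


def fit_locus_cline(
    freqs: np.ndarray,
    latitudes: np.ndarray,
    *,
    counts: np.ndarray | None = None,
    sizes: np.ndarray | None = None,
    locus: str = "",
) -> ClineFit:
    """Fit the binomial logistic cline for one locus in one lineage.

    Parameters
    ----------
    freqs, latitudes
        Per-population counted-allele frequencies (NaN = undefined) and
        latitudes; populations with undefined frequency are dropped.
    counts, sizes
        Allele counts k_j and sample sizes m_j.  When omitted, m_j defaults
        to a constant weight (unweighted fit on the frequencies).

    Requires >= 3 populations with defined frequency and non-constant
    latitudes.  Monomorphic loci give a degenerate intercept-only fit with
    dp = 0.
    """
    p_obs = np.asarray(freqs, dtype=float)
    x = np.asarray(latitudes, dtype=float)
    ok = np.isfinite(p_obs)
    if ok.sum() == 0:
        raise ValueError(f"locus {locus}: all frequencies undefined")
    if ok.sum() < 3:
        raise ValueError(f"locus {locus}: need >= 3 populations with data")
    p_obs, x = p_obs[ok], x[ok]
    if np.ptp(x) == 0:
        raise ValueError(f"locus {locus}: latitudes all equal")
    if sizes is not None:
        m = np.asarray(sizes, dtype=float)[ok]
        k = (
            np.asarray(counts, dtype=float)[ok]
            if counts is not None
            else p_obs * m
        )
    else:
        m = np.full(len(x), 100.0)
        k = p_obs * m
    x_min, x_max = x.min(), x.max()

    if np.all(k == 0) or np.all(k == m):
        p_fix = 1.0 if np.all(k == m) else 0.0
        a = 50.0 if p_fix == 1.0 else -50.0
        return ClineFit(locus, a, 0.0, p_fix, p_fix, 0.0, True, False, True, np.nan)

    a, b, converged, capped, cov = _irls_binomial(x, k, m)
    p_lo = float(expit(a + b * x_min))
    p_hi = float(expit(a + b * x_max))
    dp = abs(p_hi - p_lo)
    se_b = np.sqrt(cov[1, 1]) if np.isfinite(cov[1, 1]) and cov[1, 1] > 0 else np.nan
    wald_p = (
        2 * stats.norm.sf(abs(b) / se_b) if np.isfinite(se_b) and se_b > 0 else np.nan
    )
    return ClineFit(locus, float(a), float(b), p_lo, p_hi, float(dp),
                    bool(converged), bool(capped), False, float(wald_p))


def fit_all_clines(freq_table: FreqTable, latitudes: np.ndarray | dict) -> list[ClineFit]:
    """Fit every locus in a (single-lineage) frequency table.

    ``latitudes`` is an array aligned with ``freq_table.populations`` or a
    mapping population -> latitude.
    """
    if isinstance(latitudes, dict):
        lats = np.array([latitudes[p] for p in freq_table.populations], float)
    else:
        lats = np.asarray(latitudes, float)
    fits = []
    for j, locus in enumerate(freq_table.loci):
        fits.append(
            fit_locus_cline(
                freq_table.p[:, j],
                lats,
                counts=freq_table.counts[:, j],
                sizes=freq_table.m[:, j],
                locus=locus,
            )
        )
    return fits


def classify_clinal(
    fits: list[ClineFit],
    threshold: float = 0.40,
    wald_alpha: float | None = None,
) -> ClinalSet:
    """Loci whose fitted range strictly exceeds ``threshold``.

    The inequality is strict (dp = 0.40 exactly is NOT clinal).  Degenerate
    fits are excluded; separation-capped fits count (they are extreme
    clines).  ``wald_alpha``, off by default, additionally requires the
    slope's Wald p below it.
    """
    members: dict[str, ClineFit] = {}
    for f in fits:
        if f.degenerate:
            continue
        if not (f.converged or f.capped):
            continue
        if f.dp <= threshold:
            continue
        if wald_alpha is not None and not (np.isfinite(f.wald_p) and f.wald_p < wald_alpha):
            continue
        members[f.locus] = f
    return ClinalSet(threshold, list(members), members)


def threshold_scan(
    fits: list[ClineFit], thresholds: np.ndarray | list[float]
) -> tuple[np.ndarray, float | None]:
    """Retained-locus count over a threshold grid, plus a knee estimate.

    Returns ``(table, knee)`` where ``table`` has columns (threshold, count)
    with count(t) = #{loci : dp > t}, and ``knee`` is the elbow of the
    decline: the interior grid point whose (normalized) count falls furthest
    below the chord joining the grid endpoints.  For the sharply-declining-
    then-flat curves this diagnostic produces, that is the point where the
    neutral bulk has been exhausted and the plateau of genuine clines
    begins.  Grids shorter than 3 give knee None.
    """
    t = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("threshold grid must be strictly increasing")
    dps = np.array([f.dp for f in fits if not f.degenerate])
    counts = np.array([(dps > ti).sum() for ti in t])
    table = np.column_stack([t, counts])
    if len(t) < 3:
        return table, None
    tn = (t - t[0]) / (t[-1] - t[0])
    span = counts[0] - counts[-1]
    cn = (counts - counts[-1]) / span if span else np.zeros_like(tn)
    chord = cn[0] + tn * (cn[-1] - cn[0])
    below = chord - cn
    knee = float(t[int(np.argmax(below[1:-1])) + 1])
    return table, knee
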