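"""Summary statistics: observed heterozygosity, Weir-Cockerham F_ST,
two-level AMOVA, and isolation-by-distance regression.

F_ST uses the Weir & Cockerham (1984) variance-component estimator theta-hat:
per-locus among-population (a), among-individual-within-population (b) and
within-individual (c) components from genotype counts with the heterozygosity
correction, theta = a/(a+b+c), and the multilocus estimate as a ratio of sums
(sum a over sum a+b+c), the standard convention.  Negative per-locus values
are retained so multilocus sums stay unbiased.

The AMOVA partitions allele-count squared-Euclidean sums of squares into
among-group / among-population-within-group / within-population strata with
unequal-size nested-ANOVA coefficients, giving F_CT, F_SC and F_ST with
permutation p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genio import MISSING, GenotypeDataset

__all__ = [
    "FstResult",
    "AmovaResult",
    "IbdResult",
    "observed_heterozygosity",
    "wc_fst",
    "pairwise_fst",
    "amova_two_level",
    "ibd_regression",
]


@dataclass
class FstResult:
    loci: list[str]
    per_locus: np.ndarray       # theta-hat per locus, NaN where undefined
    multilocus: float           # ratio of sums
    components: np.ndarray      # (n_loci, 3) of a, b, c


@dataclass
class AmovaResult:
    sigma_among_groups: float
    sigma_among_pops: float
    sigma_within: float
    f_ct: float
    f_sc: float
    f_st: float
    ss: dict[str, float]        # sums of squares per stratum + total
    df: dict[str, int]
    p_fct: float | None
    p_fsc: float | None


@dataclass
class IbdResult:
    slope: float
    intercept: float
    r_squared: float
    mantel_r: float
    p_value: float
    n_pairs: int


def observed_heterozygosity(ds: GenotypeDataset) -> pd.DataFrame:
    """Per-locus Ho = heterozygotes / non-missing individuals.

    Returns a DataFrame ``locus,ho``; loci with no genotyped individuals get
    NaN.  Lineage-level means are taken by subsetting the dataset first.
    """
    g = ds.genotypes
    miss = g == MISSING
    n = (~miss).sum(axis=0)
    het = (g == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n > 0, het / np.maximum(n, 1), np.nan)
    return pd.DataFrame({"locus": ds.loci, "ho": ho})


def _wc_components(n: np.ndarray, p: np.ndarray, h: np.ndarray) -> tuple[float, float, float]:
    """Weir-Cockerham (1984) a, b, c for one biallelic locus.

    n: individuals genotyped per population, p: counted-allele frequency per
    population, h: observed heterozygote proportion per population.  Only
    populations with n > 0 contribute.
    """
    ok = n > 0
    n, p, h = n[ok].astype(float), p[ok], h[ok]
    r = len(n)
    if r < 2:
        return (np.nan, np.nan, np.nan)
    nbar = n.mean()
    nc = (r * nbar - (n ** 2).sum() / (r * nbar)) / (r - 1)
    pbar = (n * p).sum() / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n * h).sum() / (r * nbar)
    if nbar <= 1 or nc <= 0:
        return (np.nan, np.nan, np.nan)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    return (a, b, c)


def wc_fst(ds: GenotypeDataset, grouping: pd.Series | None = None) -> FstResult:
    """Per-locus and multilocus Weir-Cockerham theta-hat.

    ``grouping`` maps individuals to population labels; defaults to the
    dataset's population membership.  Loci monomorphic across all groups are
    flagged NaN (0/0) and excluded from the multilocus sums.
    """
    labels = (
        grouping.to_numpy()
        if grouping is not None
        else ds.individuals["population"].to_numpy()
    )
    pops = list(dict.fromkeys(labels))
    if len(pops) < 2:
        raise ValueError("need at least two populations for F_ST")
    g = ds.genotypes
    miss = g == MISSING
    comps = np.full((ds.n_loci, 3), np.nan)
    masks = [labels == pop for pop in pops]
    n = np.array([(~miss[mask]).sum(axis=0) for mask in masks])  # pops x loci
    k = np.array([np.where(miss[mask], 0, g[mask]).sum(axis=0) for mask in masks])
    het = np.array([(g[mask] == 1).sum(axis=0) for mask in masks])
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, k / np.maximum(2 * n, 1), np.nan)
        h = np.where(n > 0, het / np.maximum(n, 1), np.nan)
    for j in range(ds.n_loci):
        comps[j] = _wc_components(n[:, j], p[:, j], h[:, j])
    a, b, c = comps[:, 0], comps[:, 1], comps[:, 2]
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = np.where(np.abs(denom) > 1e-300, a / denom, np.nan)
    per_locus = np.where(denom == 0, np.nan, per_locus)  # monomorphic: 0/0
    ok = np.isfinite(per_locus) & np.isfinite(denom) & (denom != 0)
    multilocus = float(a[ok].sum() / denom[ok].sum()) if ok.any() else np.nan
    return FstResult(list(ds.loci), per_locus, multilocus, comps)


def pairwise_fst(ds: GenotypeDataset) -> pd.DataFrame:
    """Multilocus WC theta-hat for every population pair (square DataFrame)."""
    pops = ds.population_ids
    labels = ds.individuals["population"].to_numpy()
    out = pd.DataFrame(0.0, index=pops, columns=pops)
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            mask = (labels == pops[i]) | (labels == pops[j])
            sub = GenotypeDataset(
                ds.individuals[mask].reset_index(drop=True),
                ds.loci,
                ds.genotypes[mask],
                ds.populations.loc[[pops[i], pops[j]]],
                ds.allele_codes,
            )
            val = wc_fst(sub).multilocus
            out.iloc[i, j] = out.iloc[j, i] = val
    return out


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

def _impute_matrix(ds: GenotypeDataset) -> np.ndarray:
    """Genotype matrix with missing entries replaced by the pooled locus mean."""
    x = ds.genotypes.astype(float)
    x[x == MISSING] = np.nan
    mean = np.nanmean(x, axis=0)
    mean = np.where(np.isnan(mean), 0.0, mean)
    idx = np.where(np.isnan(x))
    x[idx] = mean[idx[1]]
    return x


def _amova_ss(x: np.ndarray, pop_of: np.ndarray, group_of_pop: dict) -> tuple[dict, dict, dict]:
    """Sums of squares and nested-ANOVA size coefficients."""
    pops = list(dict.fromkeys(pop_of))
    groups = list(dict.fromkeys(group_of_pop[p] for p in pops))
    n_tot = len(x)
    grand = x.mean(axis=0)

    pop_mean = {p: x[pop_of == p].mean(axis=0) for p in pops}
    n_p = {p: int((pop_of == p).sum()) for p in pops}
    grp_members = {g: [p for p in pops if group_of_pop[p] == g] for g in groups}
    n_g = {g: sum(n_p[p] for p in grp_members[g]) for g in groups}
    grp_mean = {
        g: sum(n_p[p] * pop_mean[p] for p in grp_members[g]) / n_g[g] for g in groups
    }

    ss_wp = sum(((x[pop_of == p] - pop_mean[p]) ** 2).sum() for p in pops)
    ss_ap = sum(
        n_p[p] * ((pop_mean[p] - grp_mean[group_of_pop[p]]) ** 2).sum() for p in pops
    )
    ss_ag = sum(n_g[g] * ((grp_mean[g] - grand) ** 2).sum() for g in groups)
    ss_tot = ((x - grand) ** 2).sum()

    G, P = len(groups), len(pops)
    df = {"among_groups": G - 1, "among_pops": P - G, "within": n_tot - P}
    ss = {"among_groups": ss_ag, "among_pops": ss_ap, "within": ss_wp, "total": ss_tot}

    sum_np2_over_ng = sum(sum(n_p[p] ** 2 for p in grp_members[g]) / n_g[g] for g in groups)
    sum_np2 = sum(n_p[p] ** 2 for p in pops)
    sum_ng2 = sum(n_g[g] ** 2 for g in groups)
    coef = {
        "n_prime": (n_tot - sum_np2_over_ng) / max(P - G, 1),
        "n_dprime": (sum_np2_over_ng - sum_np2 / n_tot) / max(G - 1, 1),
        "n_tprime": (n_tot - sum_ng2 / n_tot) / max(G - 1, 1),
    }
    return ss, df, coef


def _amova_components(ss: dict, df: dict, coef: dict) -> tuple[float, float, float]:
    ms_wp = ss["within"] / df["within"] if df["within"] > 0 else 0.0
    ms_ap = ss["among_pops"] / df["among_pops"] if df["among_pops"] > 0 else 0.0
    ms_ag = ss["among_groups"] / df["among_groups"] if df["among_groups"] > 0 else 0.0
    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / coef["n_prime"] if df["among_pops"] > 0 else 0.0
    sigma_a = (ms_ag - sigma_c - coef["n_dprime"] * sigma_b) / coef["n_tprime"]
    return sigma_a, sigma_b, sigma_c


def amova_two_level(
    ds: GenotypeDataset,
    groups: dict[str, str] | pd.Series | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> AmovaResult:
    """Two-level AMOVA (groups / populations within groups / individuals).

    ``groups`` maps population id to group label; defaults to the dataset's
    lineage labels.  Distances are squared Euclidean on the allele-count
    genotype vectors (missing mean-imputed).  F_CT significance permutes
    whole populations among groups; F_SC permutes individuals among
    populations within their group.  p = (exceedances + 1) / (n_perm + 1).
    """
    if groups is None:
        groups = ds.populations["lineage"].to_dict()
    elif isinstance(groups, pd.Series):
        groups = groups.to_dict()
    pops = ds.population_ids
    group_labels = list(dict.fromkeys(groups[p] for p in pops))
    if len(group_labels) < 2:
        raise ValueError("AMOVA needs at least two groups")
    if len(pops) <= len(group_labels):
        raise ValueError("AMOVA needs more populations than groups")

    x = _impute_matrix(ds)
    pop_of = ds.individuals["population"].to_numpy()
    ss, df, coef = _amova_ss(x, pop_of, groups)
    sigma_a, sigma_b, sigma_c = _amova_components(ss, df, coef)
    total = sigma_a + sigma_b + sigma_c
    f_ct = sigma_a / total if total != 0 else 0.0
    f_sc = sigma_b / (sigma_b + sigma_c) if sigma_b + sigma_c != 0 else 0.0
    f_st = (sigma_a + sigma_b) / total if total != 0 else 0.0

    p_fct = p_fsc = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        # F_CT: permute population labels among groups
        grp_of = [groups[p] for p in pops]
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(grp_of)
            g_map = dict(zip(pops, perm))
            ss_p, df_p, coef_p = _amova_ss(x, pop_of, g_map)
            sa, sb, sc = _amova_components(ss_p, df_p, coef_p)
            if sa / (sa + sb + sc) >= f_ct:
                exceed += 1
        p_fct = (exceed + 1) / (n_perm + 1)
        # F_SC: permute individuals among populations within groups
        exceed = 0
        grp_of_ind = np.array([groups[p] for p in pop_of])
        for _ in range(n_perm):
            perm_pop = pop_of.copy()
            for g in group_labels:
                mask = grp_of_ind == g
                perm_pop[mask] = rng.permutation(pop_of[mask])
            ss_p, df_p, coef_p = _amova_ss(x, perm_pop, groups)
            sa, sb, sc = _amova_components(ss_p, df_p, coef_p)
            if sb / (sb + sc) >= f_sc:
                exceed += 1
        p_fsc = (exceed + 1) / (n_perm + 1)

    return AmovaResult(sigma_a, sigma_b, sigma_c, f_ct, f_sc, f_st, ss, df, p_fct, p_fsc)


# ---------------------------------------------------------------------------
# Isolation by distance
# ---------------------------------------------------------------------------

def ibd_regression(
    fst_matrix: pd.DataFrame,
    dist_matrix: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> IbdResult:
    """Regress linearized F_ST, F/(1-F), on pairwise distance; Mantel p-value.

    Uses unordered off-diagonal pairs; OLS slope and r-squared; the p-value
    is a one-sided Mantel test (larger-than-observed correlation) permuting
    population labels of the F_ST matrix, p = (exceedances+1)/(n_perm+1).
    Pairs with F_ST = 1 (infinite linearization) are excluded with a warning.
    """
    if list(fst_matrix.index) != list(dist_matrix.index):
        raise ValueError("matrices must share population order")
    F = fst_matrix.to_numpy(float)
    D = dist_matrix.to_numpy(float)
    if not (np.allclose(F, F.T) and np.allclose(D, D.T)):
        raise ValueError("matrices must be symmetric")
    n = len(F)
    iu = np.triu_indices(n, 1)
    with np.errstate(divide="ignore"):
        L = F / (1 - F)
    finite = np.isfinite(L[iu])
    if not finite.all():
        import warnings

        warnings.warn("excluding pairs with F_ST = 1 (infinite linearization)")
    y, d = L[iu][finite], D[iu][finite]
    res = stats.linregress(d, y)
    r_obs = res.rvalue

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Lp = L[np.ix_(perm, perm)]
        yp = Lp[iu][finite]
        ok = np.isfinite(yp)
        r_p = np.corrcoef(d[ok], yp[ok])[0, 1]
        if r_p >= r_obs:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return IbdResult(res.slope, res.intercept, res.rvalue ** 2, r_obs, p, int(finite.sum()))
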