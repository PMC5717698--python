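"""Heterozygosity, Weir-Cockerham F_ST (vs an independent oracle), AMOVA, IBD."""

import numpy as np
import pandas as pd
import pytest

from clinepop import popstats
from clinepop.genio import MISSING

from conftest import make_dataset


# ---------------------------------------------------------------------------
# Independent Weir-Cockerham oracle: direct transcription of the 1984
# variance-component formulas for one biallelic locus, written with explicit
# per-population loops and no shared code with the implementation.
# ---------------------------------------------------------------------------

def wc_theta_oracle(pop_counts):
    """pop_counts: list of (n_AA, n_Aa, n_aa) per population; returns theta.

    Computes a (among populations), b (between individuals within
    populations), c (within individuals) for the allele A, then a/(a+b+c).
    """
    r = len(pop_counts)
    n = [sum(c) for c in pop_counts]
    p = [(2 * c[0] + c[1]) / (2 * nn) for c, nn in zip(pop_counts, n)]
    h = [c[1] / nn for c, nn in zip(pop_counts, n)]
    nbar = sum(n) / r
    nc = (r * nbar - sum(x * x for x in n) / (r * nbar)) / (r - 1)
    pbar = sum(nn * pp for nn, pp in zip(n, p)) / (r * nbar)
    s2 = sum(nn * (pp - pbar) ** 2 for nn, pp in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(nn * hh for nn, hh in zip(n, h)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a / (a + b + c)


def _counts_to_dataset(pop_counts):
    codes, pops = [], []
    for i, (n_aa2, n_het, n_aa0) in enumerate(pop_counts):
        codes += [2] * n_aa2 + [1] * n_het + [0] * n_aa0
        pops += [f"p{i}"] * (n_aa2 + n_het + n_aa0)
    return make_dataset(np.array(codes).reshape(-1, 1), pops=pops)


class TestObservedHeterozygosity:
    @pytest.mark.parametrize(
        "codes, expected",
        [([1, 1, 1, 1], 1.0), ([2, 2, 0, 0], 0.0), ([1, 1, 2, 0], 0.5)],
    )
    def test_hand_counts(self, codes, expected):
        ds = make_dataset(np.array(codes).reshape(-1, 1))
        ho = popstats.observed_heterozygosity(ds)
        assert ho["ho"].iloc[0] == expected

    def test_missing_excluded(self):
        ds = make_dataset(np.array([1, MISSING, 0]).reshape(-1, 1))
        ho = popstats.observed_heterozygosity(ds)
        assert ho["ho"].iloc[0] == 0.5

    def test_all_missing_flagged(self):
        ds = make_dataset(np.array([MISSING, MISSING]).reshape(-1, 1))
        assert np.isnan(popstats.observed_heterozygosity(ds)["ho"].iloc[0])


class TestWcFst:
    def test_toy_counts_match_independent_oracle(self):
        """Implementation equals the brute-force WC84 transcription to 1e-10."""
        pop_counts = [(10, 5, 5), (2, 6, 12)]
        ds = _counts_to_dataset(pop_counts)
        res = popstats.wc_fst(ds)
        assert res.per_locus[0] == pytest.approx(wc_theta_oracle(pop_counts), abs=1e-10)

    @pytest.mark.parametrize("pop_counts", [
        [(8, 10, 2), (5, 5, 10), (1, 3, 16)],
        [(30, 0, 0), (0, 0, 30)],
        [(4, 4, 4), (4, 4, 4)],
    ])
    def test_oracle_agreement_across_configurations(self, pop_counts):
        ds = _counts_to_dataset(pop_counts)
        res = popstats.wc_fst(ds)
        assert res.per_locus[0] == pytest.approx(wc_theta_oracle(pop_counts), abs=1e-10)

    def test_complete_differentiation(self):
        ds = _counts_to_dataset([(30, 0, 0), (0, 0, 30)])
        assert popstats.wc_fst(ds).per_locus[0] == pytest.approx(1.0)

    def test_no_differentiation_small_magnitude(self):
        # identical genotype count vectors: finite-sample theta <= 0, small
        ds = _counts_to_dataset([(20, 20, 10), (20, 20, 10)])
        theta = popstats.wc_fst(ds).per_locus[0]
        assert theta <= 0
        assert abs(theta) < 0.05

    def test_monomorphic_locus_undefined_and_excluded(self):
        g = np.hstack([
            np.full((20, 1), 2),                                  # monomorphic
            np.random.default_rng(0).binomial(2, 0.5, (20, 1)),   # polymorphic
        ])
        ds = make_dataset(g, pops=["a"] * 10 + ["b"] * 10)
        res = popstats.wc_fst(ds)
        assert np.isnan(res.per_locus[0])
        assert np.isfinite(res.multilocus)

    def test_multilocus_is_ratio_of_sums(self, small_panel):
        ds, _ = small_panel
        sub = ds.subset_lineage("north_america")
        res = popstats.wc_fst(sub)
        comps = res.components
        ok = np.isfinite(res.per_locus)
        expected = comps[ok, 0].sum() / comps[ok].sum(axis=1).sum()
        assert res.multilocus == pytest.approx(expected, abs=1e-12)

    def test_single_population_rejected(self):
        ds = make_dataset(np.array([[1], [2]]))
        with pytest.raises(ValueError):
            popstats.wc_fst(ds)


class TestAmova:
    def _nested(self, seed=0, n_groups=2, pops_per_group=3, n_ind=8, n_loci=12,
                group_sep=0.0):
        rng = np.random.default_rng(seed)
        codes, pops, lats, lineages = [], [], {}, {}
        for g in range(n_groups):
            base = rng.uniform(0.2, 0.8, n_loci)
            if group_sep:
                base = np.clip(base + (g - 0.5) * 2 * group_sep, 0.02, 0.98)
            for p in range(pops_per_group):
                pid = f"g{g}p{p}"
                freq = np.clip(base + rng.normal(0, 0.02, n_loci), 0.01, 0.99)
                codes.append(rng.binomial(2, freq, size=(n_ind, n_loci)))
                pops += [pid] * n_ind
                lats[pid] = 50.0 + p
                lineages[pid] = f"group{g}"
        return make_dataset(np.vstack(codes), pops=pops, lats=lats, lineages=lineages)

    def test_ss_partition_identity(self):
        """among-groups + among-pops + within SS equals total SS exactly."""
        ds = self._nested(seed=1, group_sep=0.2)
        res = popstats.amova_two_level(ds, n_perm=0)
        total = res.ss["among_groups"] + res.ss["among_pops"] + res.ss["within"]
        assert total == pytest.approx(res.ss["total"], abs=1e-10)

    def test_indices_consistent_with_components(self):
        ds = self._nested(seed=2, group_sep=0.2)
        res = popstats.amova_two_level(ds, n_perm=0)
        tot = res.sigma_among_groups + res.sigma_among_pops + res.sigma_within
        assert res.f_ct == pytest.approx(res.sigma_among_groups / tot)
        assert res.f_sc == pytest.approx(
            res.sigma_among_pops / (res.sigma_among_pops + res.sigma_within)
        )
        assert res.f_st == pytest.approx(
            (res.sigma_among_groups + res.sigma_among_pops) / tot
        )

    def test_saturated_case(self):
        """Groups fixed for alternative alleles, identical pops within groups."""
        n_ind, n_loci = 10, 8
        blocks, pops, lats, lineages = [], [], {}, {}
        for g, code in enumerate([2, 0]):
            for p in range(2):
                pid = f"g{g}p{p}"
                blocks.append(np.full((n_ind, n_loci), code))
                pops += [pid] * n_ind
                lats[pid] = 50.0 + p
                lineages[pid] = f"group{g}"
        ds = make_dataset(np.vstack(blocks), pops=pops, lats=lats, lineages=lineages)
        res = popstats.amova_two_level(ds, n_perm=0)
        assert res.f_ct == pytest.approx(1.0, abs=1e-10)
        assert abs(res.f_sc) < 1e-10

    def test_null_fct_near_zero(self):
        """Panmictic groups: F_CT ~ 0 and p > 0.05 in most seeds."""
        ok = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            freq = rng.uniform(0.3, 0.7, 30)
            codes, pops, lats, lineages = [], [], {}, {}
            for g in range(2):
                for p in range(4):
                    pid = f"g{g}p{p}"
                    codes.append(rng.binomial(2, freq, size=(10, 30)))
                    pops += [pid] * 10
                    lats[pid] = 50.0
                    lineages[pid] = f"group{g}"
            ds = make_dataset(np.vstack(codes), pops=pops, lats=lats, lineages=lineages)
            res = popstats.amova_two_level(ds, n_perm=99, seed=seed)
            if abs(res.f_ct) < 0.03 and res.p_fct > 0.05:
                ok += 1
        assert ok / n_seeds >= 0.90

    def test_lineage_divergence_orders_indices(self, small_panel):
        """Synthetic two-lineage panel: F_CT dominates F_SC."""
        ds, _ = small_panel
        res = popstats.amova_two_level(ds, n_perm=0)
        assert res.f_ct > res.f_sc

    def test_argument_validation(self):
        ds = self._nested()
        with pytest.raises(ValueError, match="two groups"):
            popstats.amova_two_level(ds, groups={p: "same" for p in ds.population_ids})


class TestIbdRegression:
    def _matrices(self, n=6, slope=0.001, seed=0):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 1000, size=(n, 2))
        D = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        L = slope * D  # linearized F_ST exactly proportional to distance
        F = L / (1 + L)
        pops = [f"p{i}" for i in range(n)]
        return (pd.DataFrame(F, index=pops, columns=pops),
                pd.DataFrame(D, index=pops, columns=pops))

    def test_exact_linear_construction(self):
        F, D = self._matrices()
        res = popstats.ibd_regression(F, D, n_perm=199, seed=1)
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)
        assert res.slope == pytest.approx(0.001, abs=1e-12)
        assert res.p_value == pytest.approx(1 / 200)

    def test_three_population_closed_form(self):
        pops = ["a", "b", "c"]
        D = pd.DataFrame([[0, 10, 20], [10, 0, 30], [20, 30, 0]], index=pops, columns=pops, dtype=float)
        L = np.array([0.02, 0.05, 0.055])  # pairs (a,b), (a,c), (b,c)
        F = L / (1 + L)
        Fm = pd.DataFrame(0.0, index=pops, columns=pops)
        Fm.iloc[0, 1] = Fm.iloc[1, 0] = F[0]
        Fm.iloc[0, 2] = Fm.iloc[2, 0] = F[1]
        Fm.iloc[1, 2] = Fm.iloc[2, 1] = F[2]
        res = popstats.ibd_regression(Fm, D, n_perm=0, seed=0)
        d = np.array([10.0, 20.0, 30.0])
        slope = np.cov(d, L, ddof=1)[0, 1] / np.var(d, ddof=1)
        assert res.slope == pytest.approx(slope, abs=1e-12)

    def test_mantel_null_uniform(self):
        """p-values approximately uniform when distance is unrelated to F_ST."""
        n_perm = 49
        rej, n_seeds = 0, 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n = 8
            pops = [f"p{i}" for i in range(n)]
            A = rng.uniform(0.01, 0.2, (n, n))
            F = pd.DataFrame((A + A.T) / 2 * (1 - np.eye(n)), index=pops, columns=pops)
            B = rng.uniform(1, 100, (n, n))
            D = pd.DataFrame((B + B.T) / 2 * (1 - np.eye(n)), index=pops, columns=pops)
            res = popstats.ibd_regression(F, D, n_perm=n_perm, seed=seed + 1)
            if res.p_value <= 0.05:
                rej += 1
        # nominal 0.05 -> binomial(100, ~0.04-0.06); generous 99% band
        assert rej <= 15
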