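#!/usr/bin/env python
"""Marine distances, isolation by distance, and genotype-environment association.

Builds a synthetic coastline raster around each lineage's river mouths,
computes least-cost over-water distances and their NMDS planar projection,
regresses linearized pairwise F_ST on distance (isolation by distance with a
Mantel test), then runs an RDA of clinal-locus frequencies on the climate
covariates (with and without conditioning on geography) and a partial
Mantel test of environmental vs genetic distance controlling for marine
distance.  Population subsets keep the pairwise-F_ST stage quick.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from clinepop import genio, popstats
from clinepop.envassoc import partial_mantel, rda, vif_prune
from clinepop.spatial import least_cost_distances, make_coast_raster, nmds_project

ROOT = Path(__file__).resolve().parents[1] / "results"
N_POPS_IBD = 20  # pairwise-F_ST population subsample per lineage


def main() -> None:
    pops = genio.read_populations_csv(ROOT / "panel" / "populations.csv")
    ds = genio.read_genotype_csv(ROOT / "panel" / "genotypes.csv", pops)
    ds, _ = genio.filter_loci(ds)
    env = pd.read_csv(ROOT / "panel" / "environment.csv", index_col=0)
    out = {}

    for lineage in ds.lineages():
        sub = ds.subset_lineage(lineage)
        meta = sub.populations
        raster = make_coast_raster(
            (meta["latitude"].min() - 1, meta["latitude"].max() + 1),
            (meta["longitude"].min() - 1, meta["longitude"].max() + 1),
            cellsize=0.25,
        )
        dist = least_cost_distances(meta, raster)
        dist.to_csv(ROOT / f"least_cost_{lineage}.csv")
        emb = nmds_project(dist, seed=4)
        emb.frame().to_csv(ROOT / f"nmds_{lineage}.csv")
        print(f"{lineage}: least-cost distances for {len(meta)} river mouths; "
              f"NMDS stress {emb.stress:.4f}")

        rng = np.random.default_rng(5)
        keep = sorted(rng.choice(meta.index, size=min(N_POPS_IBD, len(meta)),
                                 replace=False))
        mask = sub.individuals["population"].isin(keep).to_numpy()
        ibd_ds = genio.GenotypeDataset(
            sub.individuals[mask].reset_index(drop=True), sub.loci,
            sub.genotypes[mask], meta.loc[keep], sub.allele_codes,
        )
        fst_mat = popstats.pairwise_fst(ibd_ds)
        ibd = popstats.ibd_regression(fst_mat, dist.loc[keep, keep], n_perm=199, seed=6)
        print(f"  isolation by distance: r2 = {ibd.r_squared:.3f}, "
              f"Mantel p = {ibd.p_value:.4f} ({ibd.n_pairs} pairs)")

        clines = pd.read_csv(ROOT / f"clines_{lineage}.csv")
        clinal_loci = list(clines.loc[clines["clinal"], "locus"])
        freqs = genio.allele_frequencies(sub.subset_loci(clinal_loci))
        Y = pd.DataFrame(freqs.p, index=freqs.populations, columns=freqs.loci)
        Y = Y.fillna(Y.mean())
        X = env.loc[Y.index]
        X = X[vif_prune(X).retained]
        geo = meta.loc[Y.index, ["latitude", "longitude"]]

        plain = rda(Y, X, n_perm=999, seed=7)
        cond = rda(Y, X, condition=geo, n_perm=999, seed=8)
        print(f"  RDA: {plain.proportion_explained:.2f} of clinal-frequency variance "
              f"explained by climate (p = {plain.p_global}); "
              f"{cond.proportion_explained:.2f} after conditioning on lat/lon "
              f"(p = {cond.p_global})")

        env_z = (X - X.mean()) / X.std()
        env_dist = pd.DataFrame(
            np.sqrt(((env_z.loc[keep].to_numpy()[:, None] -
                      env_z.loc[keep].to_numpy()[None, :]) ** 2).sum(-1)),
            index=keep, columns=keep,
        )
        pm = partial_mantel(fst_mat, env_dist, dist.loc[keep, keep],
                            n_perm=999, seed=9)
        print(f"  partial Mantel (F_ST ~ environment | marine distance): "
              f"r = {pm.r:.3f}, p = {pm.p_value:.4f}")

        out[lineage] = {
            "nmds_stress": emb.stress,
            "ibd_r2": ibd.r_squared, "ibd_p": ibd.p_value,
            "rda_prop": plain.proportion_explained, "rda_p": plain.p_global,
            "rda_prop_conditioned": cond.proportion_explained,
            "rda_p_conditioned": cond.p_global,
            "partial_mantel_r": pm.r, "partial_mantel_p": pm.p_value,
        }

    (ROOT / "spatial_envassoc.json").write_text(json.dumps(out, indent=1))


if __name__ == "__main__":
    main()
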