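#!/usr/bin/env python
"""North-south clustering coefficients and their environmental correlates.

For each lineage: DAPC-style K=2 membership on the clinal loci, coefficients
standardized 0-1 south to north, then one generalized logistic model per
predictor (latitude plus each climate covariate, after VIF pruning), ranked
by AIC with McFadden pseudo-r2 and the fitted inflection latitude — the
estimated position of the north-south divide.
"""

import json
from pathlib import Path

import pandas as pd

from clinepop import genio
from clinepop.clustering import dapc_membership
from clinepop.envassoc import vif_prune
from clinepop.geomodel import compare_predictors

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    pops = genio.read_populations_csv(ROOT / "panel" / "populations.csv")
    ds = genio.read_genotype_csv(ROOT / "panel" / "genotypes.csv", pops)
    ds, _ = genio.filter_loci(ds)
    env = pd.read_csv(ROOT / "panel" / "environment.csv", index_col=0)

    inflections = {}
    for lineage in ds.lineages():
        clines = pd.read_csv(ROOT / f"clines_{lineage}.csv")
        clinal_loci = list(clines.loc[clines["clinal"], "locus"])
        sub = ds.subset_lineage(lineage).subset_loci(clinal_loci)
        coefs = dapc_membership(sub, seed=3)
        coefs.frame().to_csv(ROOT / f"coefficients_{lineage}.csv", index=False)

        lat = sub.populations["latitude"]
        predictors = env.loc[coefs.populations].copy()
        predictors = predictors[vif_prune(predictors).retained]
        predictors.insert(0, "latitude", lat.loc[coefs.populations].to_numpy())
        table = compare_predictors(coefs.standardized, predictors)
        table.to_csv(ROOT / f"models_{lineage}.csv", index=False)

        lat_row = table[table["predictor"] == "latitude"].iloc[0]
        best = table.iloc[0]
        inflections[lineage] = float(lat_row["inflection"])
        print(f"{lineage}: {len(clinal_loci)} clinal loci -> DAPC coefficients on "
              f"{len(coefs.populations)} populations")
        print(f"  latitude model: inflection {lat_row['inflection']:.1f} degN, "
              f"pseudo-r2 {lat_row['mcfadden_r2']:.2f}")
        print(f"  best predictor by AIC: {best['predictor']} "
              f"(AIC {best['AIC']:.1f}, pseudo-r2 {best['mcfadden_r2']:.2f})")

    (ROOT / "inflections.json").write_text(json.dumps(inflections, indent=1))


if __name__ == "__main__":
    main()
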