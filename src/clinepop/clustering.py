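"""North-south membership coefficients from clinal loci.

`dapc_membership` reproduces the DAPC recipe at K = 2: genotypes (missing
mean-imputed) are centered and reduced by PCA, groups are found by K-means
on the retained components, and a linear discriminant on those groups yields
per-individual posterior membership probabilities, averaged to population
level.  `standardize_south_north` rescales ANY per-population coefficient
source (DAPC here; STRUCTURE Q columns or SPCA lagged scores via the CSV
contract) to [0, 1] oriented south to north, so coefficient sources are
directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .genio import GenotypeDataset
from .popstats import _impute_matrix

__all__ = ["ClusterCoefficients", "dapc_membership", "standardize_south_north"]


@dataclass
class ClusterCoefficients:
    populations: list[str]
    raw: np.ndarray            # per-population coefficient, source scale
    standardized: np.ndarray   # [0, 1], south-to-north oriented
    method: str                # dapc | structure | spca | other
    orientation: int           # +1 kept, -1 flipped

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"population": self.populations, "coefficient": self.raw,
             "standardized": self.standardized, "method": self.method,
             "orientation": self.orientation}
        )


def _choose_n_pcs(explained_ratio: np.ndarray, n_individuals: int) -> int:
    """Components reaching 80% variance, capped at n/3 (DAPC overfitting guard)."""
    cum = np.cumsum(explained_ratio)
    n80 = int(np.searchsorted(cum, 0.80) + 1)
    return max(1, min(n80, n_individuals // 3))


def dapc_membership(
    ds: GenotypeDataset,
    n_pcs: int | None = None,
    seed: int = 0,
) -> ClusterCoefficients:
    """Per-population membership coefficients at K = 2 from clinal loci.

    Subset the dataset to the clinal loci before calling.  The membership
    group is oriented so the coefficient correlates positively with
    latitude; K-means label switching therefore cannot change the output.
    """
    if ds.n_loci == 0:
        raise ValueError("clinal locus set is empty")
    if len(ds.population_ids) < 2:
        raise ValueError("need at least K = 2 populations")
    x = _impute_matrix(ds)
    x = x - x.mean(axis=0)
    if n_pcs is not None and n_pcs >= ds.n_individuals:
        raise ValueError("n_pcs must be smaller than the number of individuals")
    max_rank = min(ds.n_individuals - 1, ds.n_loci)
    pca = PCA(n_components=min(max_rank, ds.n_individuals - 1), random_state=seed)
    scores = pca.fit_transform(x)
    if n_pcs is None:
        n_pcs = _choose_n_pcs(pca.explained_variance_ratio_, ds.n_individuals)
    scores = scores[:, :n_pcs]

    km = KMeans(n_clusters=2, n_init=20, random_state=seed)
    labels = km.fit_predict(scores)
    if len(np.unique(labels)) < 2:
        raise ValueError("K-means collapsed to a single group")
    lda = LinearDiscriminantAnalysis()
    lda.fit(scores, labels)
    prob = lda.predict_proba(scores)[:, 1]  # membership in group "1"

    pops = ds.population_ids
    pop_of = ds.individuals["population"].to_numpy()
    raw = np.array([prob[pop_of == p].mean() for p in pops])
    lats = ds.populations.loc[pops, "latitude"].to_numpy(float)
    return standardize_south_north(raw, lats, populations=pops, method="dapc")


def standardize_south_north(
    raw: np.ndarray | pd.Series,
    latitudes: np.ndarray,
    populations: list[str] | None = None,
    method: str = "other",
) -> ClusterCoefficients:
    """Orient a coefficient to increase with latitude and min-max scale to [0, 1].

    The sign is flipped when the Pearson correlation with latitude is
    negative.  A zero correlation (non-constant input) is a genuine tie: the
    orientation is then chosen so the northernmost population ends up on the
    high side of the scale.  Constant input has no defined orientation and
    is an error.
    """
    raw = np.asarray(raw, dtype=float)
    lats = np.asarray(latitudes, dtype=float)
    if len(raw) < 2:
        raise ValueError("need at least two populations")
    if np.ptp(raw) == 0:
        raise ValueError("constant coefficients: orientation undefined")
    if populations is None:
        populations = [f"pop_{i}" for i in range(len(raw))]

    if np.ptp(lats) == 0:
        corr = 0.0
    else:
        corr = float(np.corrcoef(raw, lats)[0, 1])
    if corr < 0:
        orientation = -1
    elif corr > 0:
        orientation = 1
    else:
        north = int(np.argmax(lats))
        midrange = (raw.min() + raw.max()) / 2
        orientation = 1 if raw[north] >= midrange else -1
    oriented = orientation * raw
    std = (oriented - oriented.min()) / np.ptp(oriented)
    return ClusterCoefficients(list(populations), raw, std, method, orientation)
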