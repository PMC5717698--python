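import numpy as np
import pandas as pd
import pytest

from clinepop import genio, synthdata


@pytest.fixture
def toy_genepop(tmp_path):
    """Two populations, two loci; hand-decodable genotypes.

    Locus lA: north_a has 0102 (1 copy of counted allele 01) and 0202 (0
    copies); south pops homozygous 0101 (2 copies).  Locus lB is fixed 0101
    everywhere.
    """
    text = (
        "toy panel\n"
        "lA\n"
        "lB\n"
        "POP\n"
        "south_01, 0101 0101\n"
        "south_02, 0101 0101\n"
        "POP\n"
        "north_01, 0102 0101\n"
        "north_02, 0202 0101\n"
    )
    path = tmp_path / "toy.gen"
    path.write_text(text)
    sidecar = tmp_path / "pops.csv"
    sidecar.write_text(
        "population,latitude,longitude,lineage\n"
        "south,45.0,-60.0,west\n"
        "north,58.0,-61.0,west\n"
    )
    return path, sidecar


def make_dataset(genotypes, pops=None, lats=None, lineages=None, loci=None):
    """Small in-memory dataset builder: genotypes is (n_ind, n_loci) with -1 missing."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_ind, n_loci = g.shape
    if pops is None:
        pops = ["p1"] * n_ind
    pop_ids = list(dict.fromkeys(pops))
    if lats is None:
        lats = {p: 50.0 + i for i, p in enumerate(pop_ids)}
    if lineages is None:
        lineages = {p: "west" for p in pop_ids}
    if loci is None:
        loci = [f"L{j}" for j in range(n_loci)]
    individuals = pd.DataFrame(
        {"individual": [f"{p}_{i}" for i, p in enumerate(pops)], "population": pops}
    )
    populations = pd.DataFrame(
        {
            "latitude": [lats[p] for p in pop_ids],
            "longitude": [0.0] * len(pop_ids),
            "lineage": [lineages[p] for p in pop_ids],
        },
        index=pd.Index(pop_ids, name="population"),
    )
    return genio.GenotypeDataset(individuals, loci, g, populations)


@pytest.fixture
def small_panel():
    """Seeded two-lineage synthetic panel at test scale, with truth."""
    cfg = synthdata.SynthConfig(
        n_pops=(15, 15), n_individuals=20, n_loci=120, n_shared_clinal=4,
        clinal_fraction=(0.08, 0.08), missing_rate=0.03, seed=7,
    )
    return synthdata.simulate_dataset(cfg)
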