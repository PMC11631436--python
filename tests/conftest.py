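import io

import numpy as np
import pandas as pd
import pytest

import molaric as m

FIVE_TAXON_NEWICK = "((A:1.0,B:1.0):0.5,((C:0.6,D:0.6):0.5,E:1.1):0.4):0.0;"


@pytest.fixture
def five_taxon_tree() -> m.PhyloTree:
    """Fixed 5-taxon tree used for cross-validated comparative oracles."""
    return m.PhyloTree.from_newick(FIVE_TAXON_NEWICK)


@pytest.fixture
def five_taxon_trait() -> pd.Series:
    return pd.Series({"A": 1.2, "B": 0.9, "C": 2.3, "D": 2.6, "E": 2.1})


@pytest.fixture
def balanced_tree() -> m.PhyloTree:
    return m.PhyloTree.from_newick("((A:1,B:1):1,C:2);")


def star_tree(n: int, depth: float = 1.0) -> m.PhyloTree:
    labels = [f"s{i}" for i in range(n)]
    newick = "(" + ",".join(f"{l}:{depth}" for l in labels) + ");"
    return m.PhyloTree.from_newick(newick)


@pytest.fixture
def measurement_csv() -> io.StringIO:
    return io.StringIO(
        "group_id,jaw,tooth,md,bl\n"
        "Homo_sapiens,lower,M1,11.0,10.5\n"
        "Homo_sapiens,lower,M2,10.7,10.2\n"
        "Homo_sapiens,lower,M3,10.1,9.8\n"
    )


@pytest.fixture
def exact_ic_triples() -> pd.DataFrame:
    """Noise-free cascade triples across a spread of activator/inhibitor
    ratios; every (r2, r3) point lies exactly on r3 = 2 r2 - 1."""
    cfg = m.SyntheticConfig(seed=7, n_groups=12, noise_sd=0.0, ic_ratio_range=(0.8, 1.4))
    triples, _ = m.gen_ic_dataset(cfg)
    return triples


def grid_locations(n: int) -> pd.DataFrame:
    """Deterministic, well-spread coordinates for spatial tests."""
    rng = np.random.default_rng(12345)
    lat = np.degrees(np.arcsin(rng.uniform(-0.9, 0.9, size=n)))
    lon = rng.uniform(-179, 179, size=n)
    return pd.DataFrame(
        {"group_id": [f"p{i:02d}" for i in range(n)], "lat": lat, "lon": lon}
    )
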