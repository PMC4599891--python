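import numpy as np
import pandas as pd
import pytest

from poolscreen import ShrnaLibrary, make_library
from poolscreen.preprocess import RGMatrix


@pytest.fixture
def small_library() -> ShrnaLibrary:
    """10 genes x 4 hairpins in 2 pools, efficacy fixed at 1 for exactness."""
    return make_library(
        n_genes=10,
        hairpins_per_gene_range=(4, 4),
        n_pools=2,
        seed=11,
        efficacy_range=(1.0, 1.0),
    )


@pytest.fixture
def random_raw_table() -> pd.DataFrame:
    """1,000 random probe rows spanning the background-filter boundary."""
    rng = np.random.default_rng(42)
    n = 1000
    df = pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(n)],
            "hairpin_id": [f"h{i % 200}" for i in range(n)],
            "gene_id": [f"g{(i % 200) // 4}" for i in range(n)],
            "pool": (np.arange(n) % 3) + 1,
            "replicate": (np.arange(n) // 200) % 5 + 1,
            "cy3_fg": rng.uniform(0, 400, n),
            "cy3_bg": rng.uniform(0, 150, n),
            "cy5_fg": rng.uniform(0, 400, n),
            "cy5_bg": rng.uniform(0, 150, n),
        }
    )
    df.attrs["condition"] = "hypoxia"
    return df


def rg_from_values(values: np.ndarray, n_pools: int = 1) -> RGMatrix:
    """Build an RGMatrix directly from a hairpins x replicates array."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    idx = pd.Index([f"h{i:04d}" for i in range(n)], name="hairpin_id")
    return RGMatrix(
        values=pd.DataFrame(
            values, index=idx, columns=[f"rep{j + 1}" for j in range(values.shape[1])]
        ),
        gene_of=pd.Series([f"g{i // 4}" for i in range(n)], index=idx),
        pool_of=pd.Series((np.arange(n) % n_pools) + 1, index=idx),
        condition="test",
    )
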