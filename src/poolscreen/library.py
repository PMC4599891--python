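"""shRNA library construction.

A pooled screen library maps genes to several independent hairpins, each
with its own (unobserved) knockdown efficacy, and partitions hairpins into
sub-pools that are hybridized on separate physical arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ShrnaLibrary", "make_library"]


@dataclass(frozen=True)
class ShrnaLibrary:
    """Gene ↔ hairpin ↔ pool mapping with per-hairpin knockdown efficacy.

    Attributes
    ----------
    entries
        One row per hairpin with columns ``hairpin_id``, ``gene_id``,
        ``pool_id`` (1-based), ``efficacy`` (fraction of full knockdown
        achieved, in [0, 1]).
    n_pools
        Number of sub-pools the library is divided into.
    """

    entries: pd.DataFrame
    n_pools: int = 6
    _by_gene: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        req = {"hairpin_id", "gene_id", "pool_id", "efficacy"}
        missing = req - set(self.entries.columns)
        if missing:
            raise ValueError(f"library entries missing columns: {sorted(missing)}")
        if self.entries["hairpin_id"].duplicated().any():
            raise ValueError("hairpin_id values must be unique")
        eff = self.entries["efficacy"].to_numpy()
        if ((eff < 0) | (eff > 1)).any():
            raise ValueError("efficacy must lie in [0, 1]")
        pools = self.entries["pool_id"].to_numpy()
        if ((pools < 1) | (pools > self.n_pools)).any():
            raise ValueError(f"pool_id must lie in [1, {self.n_pools}]")

    @property
    def n_hairpins(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> list[str]:
        return sorted(self.entries["gene_id"].unique())

    def hairpins_of(self, gene_id: str) -> list[str]:
        sub = self.entries.loc[self.entries["gene_id"] == gene_id, "hairpin_id"]
        if sub.empty:
            raise KeyError(gene_id)
        return list(sub)

    def gene_of(self) -> pd.Series:
        """hairpin_id → gene_id mapping as a Series."""
        return self.entries.set_index("hairpin_id")["gene_id"]

    def pool_of(self) -> pd.Series:
        return self.entries.set_index("hairpin_id")["pool_id"]

    def to_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, n_pools: int | None = None) -> "ShrnaLibrary":
        df = pd.read_csv(path, sep="\t")
        if n_pools is None:
            n_pools = int(df["pool_id"].max())
        return cls(entries=df, n_pools=n_pools)


def make_library(
    n_genes: int,
    hairpins_per_gene_range: tuple[int, int] = (4, 6),
    n_pools: int = 6,
    seed: int = 0,
    efficacy_range: tuple[float, float] = (0.5, 1.0),
    pool_assignment: str = "round_robin",
) -> ShrnaLibrary:
    """Build a synthetic genome-wide hairpin library.

    Hairpin counts per gene are drawn uniformly from
    ``hairpins_per_gene_range`` (inclusive); per-hairpin efficacy is drawn
    Uniform over ``efficacy_range``, modelling variable knockdown so that
    multi-hairpin concordance is a meaningful property downstream. Pools are
    assigned round-robin over the hairpin list by default, or uniformly at
    random with ``pool_assignment="random"``.

    Deterministic for a fixed ``seed``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = hairpins_per_gene_range
    if lo < 1 or hi < lo:
        raise ValueError("hairpins_per_gene_range bounds must satisfy 1 <= lo <= hi")
    if n_pools < 1:
        raise ValueError("n_pools must be >= 1")
    if pool_assignment not in ("round_robin", "random"):
        raise ValueError("pool_assignment must be 'round_robin' or 'random'")

    rng = np.random.default_rng(seed)
    counts = rng.integers(lo, hi + 1, size=n_genes)
    width = len(str(n_genes))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(n_genes)]

    rows = []
    for gid, c in zip(gene_ids, counts):
        for j in range(c):
            rows.append((f"sh_{gid}_{j + 1}", gid))
    n_hp = len(rows)
    if pool_assignment == "round_robin":
        pools = (np.arange(n_hp) % n_pools) + 1
    else:
        pools = rng.integers(1, n_pools + 1, size=n_hp)
    eff = rng.uniform(efficacy_range[0], efficacy_range[1], size=n_hp)

    entries = pd.DataFrame(
        {
            "hairpin_id": [r[0] for r in rows],
            "gene_id": [r[1] for r in rows],
            "pool_id": pools,
            "efficacy": eff,
        }
    )
    return ShrnaLibrary(entries=entries, n_pools=n_pools)
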