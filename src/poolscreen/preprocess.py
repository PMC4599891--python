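"""Two-color array preprocessing: background filtering, R/G log-ratios,
quantile normalization, and replicate QC.

The screen readout compares stress (Cy5, "red") against control (Cy3,
"green") channel intensities per probe. Probes dim in either channel are
unreliable and discarded; the remaining probes are summarized as
log2(Cy5net/Cy3net) — the "R/G" ratio — then quantile normalized across
the replicate arrays of each sub-pool.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RGMatrix",
    "QCReport",
    "filter_background",
    "compute_log_ratios",
    "quantile_normalize",
    "replicate_qc",
]


@dataclass
class RGMatrix:
    """Hairpins × replicates matrix of log2 stress/control ratios.

    ``values`` is indexed by hairpin_id with columns ``rep1..repR``; NaN
    marks entries discarded by the background filter or with non-positive
    net intensity. ``gene_of``/``pool_of`` map hairpins to annotation.
    """

    values: pd.DataFrame
    gene_of: pd.Series
    pool_of: pd.Series
    condition: str = ""

    @property
    def replicate_columns(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        out = pd.DataFrame(
            {
                "hairpin_id": self.values.index,
                "gene_id": self.gene_of.reindex(self.values.index).to_numpy(),
                "pool": self.pool_of.reindex(self.values.index).to_numpy(),
            }
        )
        out = pd.concat([out.set_index("hairpin_id"), self.values], axis=1)
        out.to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def from_tsv(cls, path, condition: str = "") -> "RGMatrix":
        df = pd.read_csv(path, sep="\t", index_col="hairpin_id", na_values=["NA"])
        rep_cols = [c for c in df.columns if c.startswith("rep")]
        return cls(
            values=df[rep_cols].astype(float),
            gene_of=df["gene_id"],
            pool_of=df["pool"],
            condition=condition,
        )


@dataclass
class QCReport:
    """Replicate-reproducibility and signal-range QC summary."""

    pair_correlations: dict
    discarded_fraction: float
    missing_fraction: float
    rg_range: tuple
    histogram: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "pair_correlations": {
                "|".join(k): (None if v is None or np.isnan(v) else float(v))
                for k, v in self.pair_correlations.items()
            },
            "discarded_fraction": float(self.discarded_fraction),
            "missing_fraction": float(self.missing_fraction),
            "rg_range": [float(x) for x in self.rg_range],
            "histogram": self.histogram,
            "warnings": list(self.warnings),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def filter_background(
    raw: pd.DataFrame, fold: float = 2.0, channels: str = "both"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Discard probe rows whose foreground is less than ``fold`` × background.

    A row is removed when the tested channel's foreground is *strictly*
    below ``fold`` times that channel's background (a foreground exactly at
    the threshold survives). ``channels`` selects which channels are
    tested: ``"both"`` (default; failing either discards), ``"cy3"`` or
    ``"cy5"``.

    Returns ``(kept_rows, removal_log)``; kept rows are unchanged.
    """
    if fold <= 0:
        raise ValueError("fold must be > 0")
    if channels not in ("both", "cy3", "cy5"):
        raise ValueError("channels must be 'both', 'cy3' or 'cy5'")
    inten = raw[["cy3_fg", "cy3_bg", "cy5_fg", "cy5_bg"]].to_numpy(float)
    if (inten < 0).any():
        raise ValueError("negative intensities in raw table")

    fail3 = raw["cy3_fg"].to_numpy() < fold * raw["cy3_bg"].to_numpy()
    fail5 = raw["cy5_fg"].to_numpy() < fold * raw["cy5_bg"].to_numpy()
    if channels == "both":
        bad = fail3 | fail5
    elif channels == "cy3":
        bad = fail3
    else:
        bad = fail5
    removal_log = raw.loc[bad, ["probe_id", "hairpin_id", "replicate"]].copy()
    removal_log["reason"] = np.where(
        fail3[bad] & fail5[bad], "both", np.where(fail3[bad], "cy3", "cy5")
    )
    kept = raw.loc[~bad].copy()
    kept.attrs.update(raw.attrs)
    return kept, removal_log


def compute_log_ratios(
    filtered: pd.DataFrame, subtract_background: bool = True
) -> RGMatrix:
    """Collapse a filtered probe table into the hairpins × replicates R/G matrix.

    Entry = log2((cy5 − cy5_bg)/(cy3 − cy3_bg)) with background optionally
    subtracted first. A non-positive net intensity in either channel makes
    that entry missing (NaN) rather than raising; the count is available to
    QC via the NaN pattern. Probes absent from a replicate (discarded by
    the background filter) are likewise missing.
    """
    df = filtered.copy()
    if subtract_background:
        net5 = df["cy5_fg"] - df["cy5_bg"]
        net3 = df["cy3_fg"] - df["cy3_bg"]
    else:
        net5 = df["cy5_fg"].astype(float)
        net3 = df["cy3_fg"].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where((net5 > 0) & (net3 > 0), net5 / net3, np.nan)
        df["log_ratio"] = np.log2(ratio)

    wide = df.pivot(index="hairpin_id", columns="replicate", values="log_ratio")
    wide.columns = [f"rep{int(c)}" for c in wide.columns]
    wide = wide.sort_index()
    ann = df.drop_duplicates("hairpin_id").set_index("hairpin_id")
    return RGMatrix(
        values=wide,
        gene_of=ann["gene_id"].reindex(wide.index),
        pool_of=ann["pool"].reindex(wide.index),
        condition=filtered.attrs.get("condition", ""),
    )


def _qn_group(values: np.ndarray, warn_sink: list, label) -> np.ndarray:
    """Quantile-normalize one group of columns in place-safe fashion.

    Each column's k-th order statistic is replaced by the reference
    quantile function (mean of the columns' empirical quantile functions)
    evaluated at that order statistic's plotting position rank/(n−1);
    ranks are ordinal with stable tie order, so within-column ranks are
    preserved and, for complete data, the post-normalization multisets of
    all columns are identical. Missing values are left missing and ignored
    for ranks.
    """
    out = values.copy()
    counts = (~np.isnan(values)).sum(axis=0)
    usable = counts >= 2
    if not usable.all():
        warn_sink.append(
            f"group {label}: {int((~usable).sum())} column(s) with <2 values passed through unnormalized"
        )
    if usable.sum() < 2:
        warn_sink.append(f"group {label}: fewer than 2 usable columns, left unnormalized")
        return out
    m = int(counts[usable].max())
    grid = np.linspace(0.0, 1.0, m)
    ref = np.zeros(m)
    for j in np.flatnonzero(usable):
        col = values[:, j]
        obs = np.sort(col[~np.isnan(col)])
        ref += np.quantile(obs, grid)
    ref /= usable.sum()
    for j in np.flatnonzero(usable):
        col = values[:, j]
        mask = ~np.isnan(col)
        n = mask.sum()
        order = np.argsort(col[mask], kind="stable")
        ranks = np.empty(n, dtype=float)
        ranks[order] = np.arange(n)
        p = ranks / (n - 1)
        newvals = np.interp(p, grid, ref)
        out[mask, j] = newvals
    return out


def quantile_normalize(rg: RGMatrix, group_by_pool: bool = True) -> RGMatrix:
    """Quantile normalize replicate columns, by default within each sub-pool.

    Each sub-pool was hybridized on its own physical array, so its probes
    form one normalization group across the replicate columns
    (``group_by_pool=True``); with the flag off all hairpins form a single
    group. Missing entries stay missing and do not enter rank computation.
    """
    vals = rg.values.to_numpy(float)
    out = vals.copy()
    warn_sink: list = []
    if group_by_pool:
        pools = rg.pool_of.reindex(rg.values.index).to_numpy()
        for p in pd.unique(pools):
            sel = pools == p
            out[sel] = _qn_group(vals[sel], warn_sink, f"pool {p}")
    else:
        out = _qn_group(vals, warn_sink, "all")
    for w in warn_sink:
        warnings.warn(w, stacklevel=2)
    norm = pd.DataFrame(out, index=rg.values.index, columns=rg.values.columns)
    res = RGMatrix(
        values=norm, gene_of=rg.gene_of, pool_of=rg.pool_of, condition=rg.condition
    )
    res.values.attrs["qn_warnings"] = warn_sink
    return res


def replicate_qc(
    rg: RGMatrix, discarded_fraction: float = 0.0, n_bins: int = 40
) -> QCReport:
    """Reproducibility QC: pairwise replicate correlations, R/G range, histogram.

    Pearson correlations use jointly non-missing entries; a pair with
    fewer than 3 such entries is reported as undefined (None).
    """
    cols = rg.replicate_columns
    if len(cols) < 2:
        raise ValueError("need at least 2 replicate columns for QC")
    corrs: dict = {}
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            a = rg.values[cols[i]].to_numpy(float)
            b = rg.values[cols[j]].to_numpy(float)
            mask = ~(np.isnan(a) | np.isnan(b))
            if mask.sum() < 3:
                corrs[(cols[i], cols[j])] = None
            else:
                corrs[(cols[i], cols[j])] = float(np.corrcoef(a[mask], b[mask])[0, 1])
    flat = rg.values.to_numpy(float).ravel()
    finite = flat[~np.isnan(flat)]
    if finite.size:
        lo, hi = float(finite.min()), float(finite.max())
        counts, edges = np.histogram(finite, bins=n_bins)
        hist = {"bin_edges": [float(e) for e in edges], "counts": [int(c) for c in counts]}
    else:
        lo = hi = float("nan")
        hist = {}
    return QCReport(
        pair_correlations=corrs,
        discarded_fraction=float(discarded_fraction),
        missing_fraction=float(np.isnan(flat).mean()),
        rg_range=(lo, hi),
        histogram=hist,
        warnings=list(rg.values.attrs.get("qn_warnings", [])),
    )
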