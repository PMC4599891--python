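"""Protein-normalized metabolite summaries.

Metabolite raw signals scale with the amount of harvested material, so
every sample is first normalized by its total protein content. Summaries
are per (cell line, metabolite) hypoxia fold or percent change and per
(cell line, condition) substrate/product ratios, each with a standard
error of the mean over biological replicates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "protein_normalize",
    "hypoxia_change",
    "substrate_product_ratio",
    "metabolite_columns",
]

_META_COLS = ("cell_line", "condition", "replicate", "protein_ug")


def metabolite_columns(panel: pd.DataFrame) -> list[str]:
    return [c for c in panel.columns if c not in _META_COLS]


def protein_normalize(panel: pd.DataFrame) -> pd.DataFrame:
    """Divide every metabolite column by the sample's protein content."""
    if "protein_ug" not in panel.columns:
        raise ValueError("panel lacks a protein_ug column")
    protein = panel["protein_ug"].to_numpy(float)
    if (protein <= 0).any():
        raise ValueError("protein_ug must be positive for every sample")
    out = panel.copy()
    for m in metabolite_columns(panel):
        out[m] = panel[m].to_numpy(float) / protein
    return out


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size >= 2 else 0.0


def hypoxia_change(panel: pd.DataFrame, mode: str = "fold") -> pd.DataFrame:
    """Per (cell line, metabolite) hypoxia/normoxia change with SEM.

    ``fold`` is the ratio of replicate means (hypoxia over normoxia);
    ``percent`` is ``(fold − 1) × 100``. The SEM is propagated from the
    two replicate SEMs by the delta method:
    ``sem_fold ≈ fold · sqrt((sem_H/mean_H)² + (sem_N/mean_N)²)``. Input
    must already be protein normalized. A zero normoxia mean leaves the
    statistic undefined (NaN).
    """
    if mode not in ("fold", "percent"):
        raise ValueError("mode must be 'fold' or 'percent'")
    rows = []
    for line, sub in panel.groupby("cell_line", sort=True):
        norm = sub[sub["condition"] == "normoxia"]
        hyp = sub[sub["condition"] == "hypoxia"]
        if norm.empty or hyp.empty:
            raise ValueError(f"cell line {line!r} lacks one of the conditions")
        for m in metabolite_columns(panel):
            vn = norm[m].to_numpy(float)
            vh = hyp[m].to_numpy(float)
            mn, mh = vn.mean(), vh.mean()
            if mn == 0:
                fold = sem_fold = float("nan")
            else:
                fold = mh / mn
                rel_h = _sem(vh) / mh if mh != 0 else 0.0
                rel_n = _sem(vn) / mn
                sem_fold = abs(fold) * float(np.sqrt(rel_h**2 + rel_n**2))
            if mode == "fold":
                value, sem = fold, sem_fold
            else:
                value, sem = (fold - 1.0) * 100.0, sem_fold * 100.0
            rows.append(
                {
                    "cell_line": line,
                    "metabolite": m,
                    "mode": mode,
                    "value": value,
                    "sem": sem,
                    "n_normoxia": vn.size,
                    "n_hypoxia": vh.size,
                }
            )
    return pd.DataFrame(rows)


def substrate_product_ratio(
    panel: pd.DataFrame,
    numerator: str = "alpha-ketoglutarate",
    denominator: str = "succinate",
    ratio_of_means: bool = False,
) -> pd.DataFrame:
    """Per (cell line, condition) substrate/product ratio with SEM.

    By default the ratio is computed per replicate and then summarized as
    mean ± SEM, matching per-replicate error bars; ``ratio_of_means``
    instead divides the replicate means (SEM then by the delta method).
    Replicates with a zero denominator are excluded and counted in
    ``n_excluded``.
    """
    for m in (numerator, denominator):
        if m not in panel.columns:
            raise ValueError(f"metabolite {m!r} not in panel")
    rows = []
    for (line, cond), sub in panel.groupby(["cell_line", "condition"], sort=True):
        num = sub[numerator].to_numpy(float)
        den = sub[denominator].to_numpy(float)
        ok = den != 0
        n_excluded = int((~ok).sum())
        if ratio_of_means:
            if den[ok].size == 0 or den[ok].mean() == 0:
                value, sem = float("nan"), float("nan")
            else:
                mn, md = num[ok].mean(), den[ok].mean()
                value = mn / md
                rel_n = _sem(num[ok]) / mn if mn != 0 else 0.0
                rel_d = _sem(den[ok]) / md
                sem = abs(value) * float(np.sqrt(rel_n**2 + rel_d**2))
        else:
            ratios = num[ok] / den[ok]
            if ratios.size == 0:
                value, sem = float("nan"), float("nan")
            else:
                value, sem = float(ratios.mean()), _sem(ratios)
        rows.append(
            {
                "cell_line": line,
                "condition": cond,
                "numerator": numerator,
                "denominator": denominator,
                "ratio": value,
                "sem": sem,
                "n": int(ok.sum()),
                "n_excluded": n_excluded,
            }
        )
    return pd.DataFrame(rows)
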