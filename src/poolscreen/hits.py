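"""Multiple-hairpin hit calling.

The screen's deterministic hit rule: a hairpin shows an event when its
absolute normalized log2 R/G exceeds a threshold in at least ``min_reps``
of the biological replicates and the replicate coefficient of variation
(sample stdev over |mean|) stays below ``cv_max``. A gene is a hit when at
least ``min_hairpins`` distinct hairpins agree in direction — enrichment
under stress marks a synthetic survival/protective gene, depletion a
synthetic sick/lethal one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .library import ShrnaLibrary
from .preprocess import RGMatrix

__all__ = [
    "HairpinCall",
    "GeneHitTable",
    "OverlapSummary",
    "call_hairpin_events",
    "call_gene_hits",
    "cross_condition_overlap",
]


@dataclass(frozen=True)
class HairpinCall:
    hairpin_id: str
    gene_id: str
    direction: str  # "enriched" | "depleted" | "none"
    n_passing_reps: int
    cv: float  # NaN when undefined (mean 0 or <2 values)
    mean_rg: float
    insufficient_data: bool = False


@dataclass
class GeneHitTable:
    """Per-gene classification with supporting hairpins.

    ``table`` has one row per gene: ``gene_class`` in
    {protective, lethal, none}, ``supporting_hairpins`` (comma-joined ids),
    ``n_support``, ``n_hairpins_total``, ``ambiguous`` (True when distinct
    hairpin subsets satisfied both directions).
    """

    table: pd.DataFrame
    condition: str = ""

    def genes_in_class(self, gene_class: str) -> set:
        return set(self.table.index[self.table["gene_class"] == gene_class])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")


@dataclass
class OverlapSummary:
    """Per-class hit overlap between two conditions (two Venn diagrams)."""

    condition_a: str
    condition_b: str
    counts: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "condition_a": self.condition_a,
                    "condition_b": self.condition_b,
                    "counts": {
                        k: {kk: sorted(vv) if isinstance(vv, set) else vv for kk, vv in d.items()}
                        for k, d in self.counts.items()
                    },
                },
                fh,
                indent=2,
                default=list,
            )


def call_hairpin_events(
    rg: RGMatrix, tau: float = 0.7, min_reps: int = 2, cv_max: float = 0.5
) -> list[HairpinCall]:
    """Classify every hairpin as enriched, depleted or no event.

    An event requires |R/G| > ``tau`` (strict) in at least ``min_reps``
    non-missing replicates AND sample stdev / |mean| < ``cv_max`` (strict)
    over the non-missing replicate values; the direction is the sign of
    the replicate mean. The CV denominator is the absolute mean of the
    log2 ratios; a zero mean leaves the CV undefined and produces no
    event. Hairpins with fewer than ``min_reps`` non-missing values are
    flagged insufficient-data.
    """
    if tau <= 0 or cv_max <= 0:
        raise ValueError("thresholds must be positive")
    if min_reps < 1:
        raise ValueError("min_reps must be >= 1")
    if len(rg.replicate_columns) < min_reps:
        raise ValueError("fewer replicate columns than min_reps")

    calls: list[HairpinCall] = []
    genes = rg.gene_of.reindex(rg.values.index)
    for hp, row in zip(rg.values.index, rg.values.to_numpy(float)):
        v = row[~np.isnan(row)]
        gene = genes.loc[hp]
        if v.size < min_reps:
            calls.append(
                HairpinCall(hp, gene, "none", 0, float("nan"), float(np.mean(v)) if v.size else float("nan"), True)
            )
            continue
        n_pass = int((np.abs(v) > tau).sum())
        mean = float(np.mean(v))
        sd = float(np.std(v, ddof=1)) if v.size >= 2 else float("nan")
        cv = sd / abs(mean) if mean != 0 and not np.isnan(sd) else float("nan")
        event = n_pass >= min_reps and not np.isnan(cv) and cv < cv_max
        if event:
            direction = "enriched" if mean > 0 else "depleted"
        else:
            direction = "none"
        calls.append(HairpinCall(hp, gene, direction, n_pass, cv, mean))
    return calls


def call_gene_hits(
    calls: list[HairpinCall],
    library: ShrnaLibrary,
    min_hairpins: int = 2,
    allow_mixed_direction: bool = False,
) -> GeneHitTable:
    """Aggregate hairpin events to gene-level hits.

    A gene is protective when ≥ ``min_hairpins`` of its hairpins are
    enriched, lethal when ≥ ``min_hairpins`` are depleted. When distinct
    hairpin subsets satisfy both directions the gene is flagged ambiguous
    and classed none (``allow_mixed_direction=True`` instead counts any
    ≥ ``min_hairpins`` events regardless of direction and classes by the
    majority direction, majority ties → none).
    """
    known = set(library.entries["gene_id"])
    by_gene: dict[str, list[HairpinCall]] = {}
    for c in calls:
        if c.gene_id not in known:
            raise ValueError(f"call references gene {c.gene_id!r} absent from library")
        by_gene.setdefault(c.gene_id, []).append(c)
    totals = library.entries.groupby("gene_id")["hairpin_id"].count()

    rows = []
    for gene in sorted(by_gene):
        gcalls = by_gene[gene]
        enr = [c.hairpin_id for c in gcalls if c.direction == "enriched"]
        dep = [c.hairpin_id for c in gcalls if c.direction == "depleted"]
        ambiguous = False
        if allow_mixed_direction:
            if len(enr) + len(dep) >= min_hairpins and len(enr) != len(dep):
                cls = "protective" if len(enr) > len(dep) else "lethal"
                support = enr if len(enr) > len(dep) else dep
            else:
                cls, support = "none", []
        else:
            p = len(enr) >= min_hairpins
            l = len(dep) >= min_hairpins
            if p and l:
                cls, support, ambiguous = "none", [], True
            elif p:
                cls, support = "protective", enr
            elif l:
                cls, support = "lethal", dep
            else:
                cls, support = "none", []
        rows.append(
            {
                "gene_id": gene,
                "gene_class": cls,
                "supporting_hairpins": ",".join(support),
                "n_support": len(support),
                "n_enriched": len(enr),
                "n_depleted": len(dep),
                "n_hairpins_total": int(totals.get(gene, 0)),
                "ambiguous": ambiguous,
            }
        )
    table = pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame(
        columns=[
            "gene_class",
            "supporting_hairpins",
            "n_support",
            "n_enriched",
            "n_depleted",
            "n_hairpins_total",
            "ambiguous",
        ]
    )
    return GeneHitTable(table=table)


def cross_condition_overlap(hits_a: GeneHitTable, hits_b: GeneHitTable) -> OverlapSummary:
    """Per-class overlap of hit genes between two stress conditions.

    Protective (enriched) and lethal (depleted) hits are intersected
    separately, matching the two Venn diagrams of a cross-stress
    comparison.
    """
    counts = {}
    for cls in ("protective", "lethal"):
        a = hits_a.genes_in_class(cls)
        b = hits_b.genes_in_class(cls)
        counts[cls] = {
            "only_a": len(a - b),
            "only_b": len(b - a),
            "shared": len(a & b),
            "total_a": len(a),
            "total_b": len(b),
            "shared_genes": sorted(a & b),
        }
    return OverlapSummary(
        condition_a=hits_a.condition, condition_b=hits_b.condition, counts=counts
    )
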