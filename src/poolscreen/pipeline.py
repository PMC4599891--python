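"""End-to-end pipeline orchestration.

Each ``run_*`` function executes one arm of the analysis (screen,
expression signatures, metabolites) from a :class:`PipelineConfig`,
writing every intermediate artifact plus a structured record-count log and
the resolved configuration to the output directory. All randomness is
derived from the single config seed, so identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .gct import write_cls, write_gct
from .hits import call_gene_hits, call_hairpin_events, cross_condition_overlap
from .library import ShrnaLibrary, make_library
from .metabolites import hypoxia_change, protein_normalize, substrate_product_ratio
from .preprocess import compute_log_ratios, filter_background, quantile_normalize, replicate_qc
from .ranking import hairpin_scores, permutation_nes, second_best_gene_score
from .signatures import create_signature, fold_filter, signature_regression, zero_transform
from .simulate import (
    ScreenTruth,
    default_metabolite_panel,
    make_expression_truth,
    simulate_cohort,
    simulate_expression,
    simulate_metabolites,
    simulate_screen,
)

__all__ = [
    "child_seeds",
    "plant_screen_truths",
    "run_screen_pipeline",
    "run_signature_pipeline",
    "run_metabolite_pipeline",
    "run_all",
]


def child_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit child seeds from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def plant_screen_truths(cfg: PipelineConfig) -> tuple[ShrnaLibrary, dict]:
    """Build the library and one ScreenTruth per stress condition.

    Protective genes get +effect_size, lethal genes −effect_size; a
    ``shared_hit_fraction`` of each condition's true genes is common to
    both stresses (stresses mostly engage distinct survival programs).
    """
    sc = cfg.screen
    lib_seed, pick_seed = child_seeds(cfg.seed, 2)
    library = make_library(
        n_genes=sc.n_genes,
        hairpins_per_gene_range=tuple(sc.hairpins_per_gene),
        n_pools=sc.n_pools,
        seed=lib_seed,
        efficacy_range=tuple(sc.efficacy_range),
    )
    rng = np.random.default_rng(pick_seed)
    genes = library.genes
    n_true = sc.n_protective + sc.n_lethal
    n_shared = int(round(sc.shared_hit_fraction * n_true))
    truths = {}
    shared = rng.choice(genes, size=n_shared, replace=False) if n_shared else []
    taken = set(shared)
    for cond in sc.conditions:
        avail = [g for g in genes if g not in taken]
        own = rng.choice(avail, size=n_true - n_shared, replace=False)
        taken.update(own)
        cond_genes = [str(g) for g in shared] + [str(g) for g in own]
        effects = {}
        for i, g in enumerate(cond_genes):
            effects[g] = float(sc.effect_size if i < sc.n_protective else -sc.effect_size)
        truths[cond] = ScreenTruth(
            gene_effects=effects,
            baseline_stress_survival=sc.baseline_stress_survival,
            representation=sc.representation,
            noise_sd=sc.noise_sd,
        )
    return library, truths


def run_screen_pipeline(cfg: PipelineConfig) -> dict:
    """simulate → preprocess → call hits → rank, for every stress condition."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "resolved_config.yaml")
    sc, pp, hc, rc = cfg.screen, cfg.preprocess, cfg.hits, cfg.ranking

    library, truths = plant_screen_truths(cfg)
    library.to_tsv(out / "library.tsv")
    sim_seeds = child_seeds(cfg.seed + 1, len(sc.conditions))

    counts: dict = {}
    results: dict = {"library": library, "conditions": {}}
    hit_tables = {}
    for cond, sim_seed in zip(sc.conditions, sim_seeds):
        truth = truths[cond]
        truth.to_yaml(out / f"truth_{cond}.yaml")
        raw = simulate_screen(
            library,
            truth,
            n_replicates=sc.n_replicates,
            seed=sim_seed,
            condition=cond,
            background_median=sc.background_median,
            background_log_sd=sc.background_log_sd,
            pcr_log2_sd=sc.pcr_log2_sd,
            equalize_channel_mass=sc.equalize_channel_mass,
        )
        raw.to_csv(out / f"raw_{cond}.tsv", sep="\t", index=False)
        kept, removed = filter_background(
            raw, fold=pp.background_fold, channels=pp.background_channels
        )
        rg = compute_log_ratios(kept, subtract_background=pp.subtract_background)
        rg = quantile_normalize(rg, group_by_pool=pp.group_by_pool)
        rg.to_tsv(out / f"rg_{cond}.tsv")
        qc = replicate_qc(rg, discarded_fraction=len(removed) / max(len(raw), 1))
        qc.to_json(out / f"qc_{cond}.json")

        calls = call_hairpin_events(rg, tau=hc.tau, min_reps=hc.min_reps, cv_max=hc.cv_max)
        pd.DataFrame(calls).to_csv(out / f"hairpin_calls_{cond}.tsv", sep="\t", index=False)
        hits = call_gene_hits(
            calls, library, min_hairpins=hc.min_hairpins,
            allow_mixed_direction=hc.allow_mixed_direction,
        )
        hits.condition = cond
        hits.to_tsv(out / f"gene_hits_{cond}.tsv")
        hit_tables[cond] = hits

        scores = hairpin_scores(rg)
        rankings = {}
        for direction in ("enrichment", "depletion"):
            gs = second_best_gene_score(scores, library, direction)
            rk = permutation_nes(gs, library, B=rc.n_permutations, seed=child_seeds(sim_seed + 7, 1)[0])
            rk.to_tsv(out / f"ranking_{cond}_{direction}.tsv")
            rankings[direction] = rk

        counts[cond] = {
            "raw_rows": int(len(raw)),
            "background_discarded": int(len(removed)),
            "rg_hairpins": int(len(rg.values)),
            "missing_entries": int(rg.values.isna().to_numpy().sum()),
            "gene_hits": int((hits.table["gene_class"] != "none").sum()),
        }
        results["conditions"][cond] = {
            "truth": truth,
            "rg": rg,
            "qc": qc,
            "hits": hits,
            "rankings": rankings,
        }

    if len(sc.conditions) >= 2:
        a, b = sc.conditions[0], sc.conditions[1]
        overlap = cross_condition_overlap(hit_tables[a], hit_tables[b])
        overlap.to_json(out / "overlap.json")
        results["overlap"] = overlap
    with open(out / "screen_counts.json", "w") as fh:
        json.dump(counts, fh, indent=2)
    results["counts"] = counts
    return results


def run_signature_pipeline(cfg: PipelineConfig) -> dict:
    """Simulate two knockdown programs, build both signatures, project a cohort."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "resolved_config.yaml")
    sg = cfg.signature
    truth_seed, seed_a, seed_b, cohort_seed = child_seeds(cfg.seed + 2, 4)
    truth = make_expression_truth(
        n_genes=sg.n_genes, n_de=sg.n_de, overlap=sg.overlap, seed=truth_seed
    )
    truth.to_yaml(out / "expression_truth.yaml")

    mats, labels, models, probs = {}, {}, {}, {}
    for program, seed in (("A", seed_a), ("B", seed_b)):
        mat, lab = simulate_expression(
            truth,
            samples_per_class=sg.samples_per_class,
            effect_size=sg.effect_size,
            noise_sd=sg.noise_sd,
            seed=seed,
            program=program,
        )
        write_gct(mat, out / f"expr_{program}.gct")
        write_cls(lab, out / f"expr_{program}.cls")
        ctrl = list(lab.index[lab == 0])
        kd = list(lab.index[lab == 1])
        zt = zero_transform(mat, ctrl)
        models[program] = create_signature(
            zt, ctrl, kd, n_sig=sg.n_sig, k_factors=sg.k_factors, ridge=sg.ridge
        )
        models[program].to_json(out / f"signature_{program}.json")
        mats[program], labels[program] = mat, lab

    # occurrence/fold filter on the knockdown arrays of both programs
    combined = pd.concat(
        [
            zero_transform(mats[p], list(labels[p].index[labels[p] == 0])).values[
                list(labels[p].index[labels[p] == 1])
            ].rename(columns=lambda c: f"{p}_{c}")
            for p in ("A", "B")
        ],
        axis=1,
    )
    filtered = fold_filter(
        _as_zt(combined),
        fold=sg.fold,
        min_arrays=min(sg.min_arrays, combined.shape[1]),
        scale=sg.filter_scale,
    )
    write_gct(filtered, out / "filtered_matrix.gct")

    cohort, activation = simulate_cohort(
        truth, n_samples=sg.cohort_samples, effect_size=sg.effect_size,
        noise_sd=sg.noise_sd, seed=cohort_seed,
    )
    write_gct(cohort, out / "cohort.gct")
    for program in ("A", "B"):
        probs[program] = models[program].project(cohort, center="test")
    pd.DataFrame(probs).to_csv(out / "cohort_probabilities.tsv", sep="\t")
    regression = signature_regression(probs["A"], probs["B"])
    regression.to_json(out / "signature_regression.json")

    counts = {
        "n_genes": sg.n_genes,
        "filtered_genes": int(len(filtered)),
        "cohort_samples": sg.cohort_samples,
    }
    with open(out / "signature_counts.json", "w") as fh:
        json.dump(counts, fh, indent=2)
    return {
        "truth": truth,
        "models": models,
        "filtered": filtered,
        "probs": probs,
        "activation": activation,
        "regression": regression,
        "counts": counts,
    }


def _as_zt(df: pd.DataFrame):
    from .signatures import ZeroTransformedMatrix

    return ZeroTransformedMatrix(values=df, control_ids=[])


def run_metabolite_pipeline(cfg: PipelineConfig) -> dict:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    mc = cfg.metabolites
    (panel_seed,) = child_seeds(cfg.seed + 3, 1)
    spec = default_metabolite_panel(noise_sd=mc.noise_sd)
    panel = simulate_metabolites(spec, seed=panel_seed)
    panel.to_csv(out / "metabolite_panel.csv", index=False)
    normalized = protein_normalize(panel)
    fold = hypoxia_change(normalized, mode="fold")
    percent = hypoxia_change(normalized, mode="percent")
    ratio = substrate_product_ratio(
        normalized, numerator=mc.numerator, denominator=mc.denominator,
        ratio_of_means=mc.ratio_of_means,
    )
    fold.to_csv(out / "hypoxia_fold.tsv", sep="\t", index=False)
    percent.to_csv(out / "hypoxia_percent.tsv", sep="\t", index=False)
    ratio.to_csv(out / "substrate_product_ratio.tsv", sep="\t", index=False)
    return {"spec": spec, "panel": panel, "fold": fold, "percent": percent, "ratio": ratio}


def run_all(cfg: PipelineConfig) -> dict:
    return {
        "screen": run_screen_pipeline(cfg),
        "signature": run_signature_pipeline(cfg),
        "metabolites": run_metabolite_pipeline(cfg),
    }
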