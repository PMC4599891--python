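"""Synthetic data generation with known ground truth.

Three generators emulate the three data modalities of a pooled-shRNA
stress-survival study:

* :func:`simulate_screen` — endpoint abundances of a pooled fitness screen
  read out by competitive two-color hybridization (Cy3 = control channel,
  Cy5 = stress channel) on per-sub-pool arrays.
* :func:`simulate_expression` / :func:`simulate_cohort` — two-class log2
  expression matrices (scramble control vs knockdown) and a tumor-cohort
  matrix whose samples vary continuously in the planted program.
* :func:`simulate_metabolites` — metabolite panels across cell line ×
  oxygen condition × replicate with per-sample protein content.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .library import ShrnaLibrary

__all__ = [
    "ScreenTruth",
    "simulate_screen",
    "ExpressionTruth",
    "make_expression_truth",
    "simulate_expression",
    "simulate_cohort",
    "MetabolitePanelSpec",
    "default_metabolite_panel",
    "simulate_metabolites",
    "RAW_TABLE_COLUMNS",
]

RAW_TABLE_COLUMNS = [
    "probe_id",
    "hairpin_id",
    "gene_id",
    "pool",
    "replicate",
    "cy3_fg",
    "cy3_bg",
    "cy5_fg",
    "cy5_bg",
]


@dataclass
class ScreenTruth:
    """Ground truth of a simulated screen condition.

    ``gene_effects`` maps gene_id to the signed log2 fitness effect of full
    knockdown under stress (delta); neutral genes are exactly 0 and may be
    omitted. ``baseline_stress_survival`` is the fraction of cells
    surviving the stress treatment irrespective of genotype (the stress
    dose is titrated to roughly halve cell number, hence the 0.5 default).
    ``representation`` is the expected number of cells carrying each
    hairpin at infection. ``noise_sd`` is the biological replicate noise of
    the stress/control abundance ratio, in log2 units.
    """

    gene_effects: dict = field(default_factory=dict)
    baseline_stress_survival: float = 0.5
    representation: int = 1000
    noise_sd: float = 0.25

    def __post_init__(self) -> None:
        if not (0.0 < self.baseline_stress_survival <= 1.0):
            raise ValueError("baseline_stress_survival must be in (0, 1]")
        if self.representation < 1:
            raise ValueError("representation must be a positive integer")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    def effect_of(self, gene_id: str) -> float:
        return float(self.gene_effects.get(gene_id, 0.0))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScreenTruth":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def simulate_screen(
    library: ShrnaLibrary,
    truth: ScreenTruth,
    n_replicates: int = 3,
    seed: int = 0,
    condition: str = "hypoxia",
    background_median: float = 50.0,
    background_log_sd: float = 0.5,
    pcr_log2_sd: float = 0.25,
    gain: float = 1.0,
    equalize_channel_mass: bool = True,
) -> pd.DataFrame:
    """Simulate endpoint two-color array intensities for one stress condition.

    The abundance model collapses the multi-day treatment to a single
    endpoint factor: each hairpin h in replicate r seeds ``N0 ~
    Poisson(representation)`` cells (shared by both arms of the replicate,
    which are split after selection). The control arm ends at ``N0`` cells;
    the stress arm at ``N0 * survival * 2**(delta_g * efficacy_h)`` with
    multiplicative lognormal replicate noise of sd ``noise_sd`` (log2).

    PCR amplification bias is a shared lognormal per-probe factor applied
    to both channels, so it cancels in the ratio. Channel foreground is
    ``gain * abundance + background`` with lognormal additive background of
    the given median (0 disables background).

    ``equalize_channel_mass`` models competitive hybridization: equal
    amounts of labeled product are hybridized per channel, so each
    channel's abundances are rescaled to a common total per replicate.
    Neutral genes then center at log-ratio ~0. With the flag off the raw
    ratio carries ``log2(survival)`` for neutral genes.
    """
    if library.n_hairpins == 0:
        raise ValueError("library is empty")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")

    rng = np.random.default_rng(seed)
    ent = library.entries
    n_hp = len(ent)
    delta = ent["gene_id"].map(lambda g: truth.effect_of(g)).to_numpy(float)
    eff = ent["efficacy"].to_numpy(float)

    frames = []
    for rep in range(1, n_replicates + 1):
        n0 = rng.poisson(truth.representation, size=n_hp).astype(float)
        eps = rng.normal(0.0, truth.noise_sd, size=n_hp) if truth.noise_sd > 0 else 0.0
        control = n0
        stress = n0 * truth.baseline_stress_survival * 2.0 ** (delta * eff + eps)
        if equalize_channel_mass:
            target = n_hp * truth.representation
            control = control * (target / control.sum())
            stress = stress * (target / stress.sum())
        pcr = 2.0 ** rng.normal(0.0, pcr_log2_sd, size=n_hp) if pcr_log2_sd > 0 else 1.0
        if background_median > 0:
            bg3 = background_median * np.exp(rng.normal(0.0, background_log_sd, size=n_hp))
            bg5 = background_median * np.exp(rng.normal(0.0, background_log_sd, size=n_hp))
        else:
            bg3 = np.zeros(n_hp)
            bg5 = np.zeros(n_hp)
        frames.append(
            pd.DataFrame(
                {
                    "probe_id": ent["hairpin_id"].to_numpy() + "_p",
                    "hairpin_id": ent["hairpin_id"].to_numpy(),
                    "gene_id": ent["gene_id"].to_numpy(),
                    "pool": ent["pool_id"].to_numpy(),
                    "replicate": rep,
                    "cy3_fg": gain * control * pcr + bg3,
                    "cy3_bg": bg3,
                    "cy5_fg": gain * stress * pcr + bg5,
                    "cy5_bg": bg5,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    table.attrs["condition"] = condition
    return table


# ---------------------------------------------------------------------------
# Expression


@dataclass
class ExpressionTruth:
    """Planted structure of a two-class knockdown expression experiment.

    ``programs`` maps a program name (one per knockdown construct) to a
    dict gene_id → signed unit effect (±1); the actual log2 shift is
    ``sign * effect_size`` at simulation time. Two programs share a
    fraction ``shared_program_overlap`` of their differentially expressed
    (DE) genes, with identical signs on shared genes — emulating knockdowns
    that converge on a common downstream response. ``baseline`` holds
    per-gene log2 baseline expression shared by every simulated sample.
    """

    gene_ids: list
    programs: dict
    shared_program_overlap: float
    baseline: np.ndarray

    def __post_init__(self) -> None:
        if not (0.0 <= self.shared_program_overlap <= 1.0):
            raise ValueError("shared_program_overlap must be in [0, 1]")
        genes = set(self.gene_ids)
        for name, prog in self.programs.items():
            unknown = set(prog) - genes
            if unknown:
                raise ValueError(f"program {name!r} references unmeasured genes")

    def de_genes(self, program: str) -> set:
        return set(self.programs[program])

    def to_yaml(self, path) -> None:
        payload = {
            "gene_ids": list(self.gene_ids),
            "programs": {k: dict(v) for k, v in self.programs.items()},
            "shared_program_overlap": float(self.shared_program_overlap),
            "baseline": [float(x) for x in self.baseline],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def make_expression_truth(
    n_genes: int = 2000,
    n_de: int = 50,
    overlap: float = 0.6,
    seed: int = 0,
    baseline_mean: float = 7.0,
    baseline_sd: float = 1.5,
) -> ExpressionTruth:
    """Plant two knockdown programs of ``n_de`` DE genes sharing ``overlap``.

    Shared genes carry identical signs in both programs; the remaining DE
    genes of each program are disjoint. Signs are Rademacher (half up, half
    down in expectation).
    """
    if n_de * 2 > n_genes:
        raise ValueError("n_de too large for n_genes")
    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    gene_ids = [f"EG{i + 1:0{width}d}" for i in range(n_genes)]
    n_shared = int(round(overlap * n_de))
    n_spec = n_de - n_shared
    picked = rng.choice(n_genes, size=n_shared + 2 * n_spec, replace=False)
    shared = picked[:n_shared]
    spec_a = picked[n_shared : n_shared + n_spec]
    spec_b = picked[n_shared + n_spec :]
    signs = rng.choice([-1.0, 1.0], size=n_shared + 2 * n_spec)
    prog_a = {gene_ids[g]: float(s) for g, s in zip(shared, signs[:n_shared])}
    prog_b = dict(prog_a)
    for g, s in zip(spec_a, signs[n_shared : n_shared + n_spec]):
        prog_a[gene_ids[g]] = float(s)
    for g, s in zip(spec_b, signs[n_shared + n_spec :]):
        prog_b[gene_ids[g]] = float(s)
    baseline = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    return ExpressionTruth(
        gene_ids=gene_ids,
        programs={"A": prog_a, "B": prog_b},
        shared_program_overlap=overlap,
        baseline=baseline,
    )


def _effect_vector(truth: ExpressionTruth, program: str) -> np.ndarray:
    idx = {g: i for i, g in enumerate(truth.gene_ids)}
    v = np.zeros(len(truth.gene_ids))
    for g, s in truth.programs[program].items():
        v[idx[g]] = s
    return v


def simulate_expression(
    truth: ExpressionTruth,
    samples_per_class: int = 3,
    effect_size: float = 1.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    program: str = "A",
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a two-class (scramble vs knockdown) log2 expression matrix.

    Returns ``(matrix, labels)`` where the matrix is genes × samples and
    labels are 0 (control/scramble, train0) or 1 (knockdown, train1).
    Planted DE genes differ in class means by ``sign * effect_size`` log2
    units; all genes carry i.i.d. Gaussian noise of sd ``noise_sd``.
    """
    if samples_per_class < 2:
        raise ValueError("samples_per_class must be >= 2")
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0 (direction lives in truth)")
    rng = np.random.default_rng(seed)
    n_genes = len(truth.gene_ids)
    v = _effect_vector(truth, program) * effect_size
    n = 2 * samples_per_class
    noise = rng.normal(0.0, noise_sd, size=(n_genes, n)) if noise_sd > 0 else 0.0
    means = truth.baseline[:, None] + np.outer(
        v, np.r_[np.zeros(samples_per_class), np.ones(samples_per_class)]
    )
    mat = means + noise
    cols = [f"ctrl_{i + 1}" for i in range(samples_per_class)] + [
        f"kd{program}_{i + 1}" for i in range(samples_per_class)
    ]
    labels = pd.Series(
        np.r_[np.zeros(samples_per_class, int), np.ones(samples_per_class, int)],
        index=cols,
        name="class",
    )
    return pd.DataFrame(mat, index=truth.gene_ids, columns=cols), labels


def simulate_cohort(
    truth: ExpressionTruth,
    n_samples: int = 130,
    effect_size: float = 1.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate a tumor cohort varying continuously in the planted programs.

    Each sample draws a latent activation ``a ~ Uniform(0, 1)`` applied to
    the union of both programs' effect vectors (shared genes once), so the
    two program signatures should co-vary across the cohort. Returns
    ``(matrix, activations)``.
    """
    rng = np.random.default_rng(seed)
    union = np.zeros(len(truth.gene_ids))
    for name in truth.programs:
        v = _effect_vector(truth, name)
        nz = v != 0
        union[nz] = v[nz]
    union = union * effect_size
    a = rng.uniform(0.0, 1.0, size=n_samples)
    noise = (
        rng.normal(0.0, noise_sd, size=(len(truth.gene_ids), n_samples))
        if noise_sd > 0
        else 0.0
    )
    mat = truth.baseline[:, None] + np.outer(union, a) + noise
    cols = [f"tumor_{i + 1:03d}" for i in range(n_samples)]
    return pd.DataFrame(mat, index=truth.gene_ids, columns=cols), a


# ---------------------------------------------------------------------------
# Metabolites

REQUIRED_METABOLITES = ("alpha-ketoglutarate", "succinate")


@dataclass
class MetabolitePanelSpec:
    """Specification of a simulated metabolite panel.

    ``baseline`` gives each metabolite's protein-normalized level in the
    reference state (first cell line, normoxia). ``fold_effects`` maps
    ``(cell_line, condition, metabolite)`` to a multiplicative planted fold
    versus that baseline (unlisted combinations default to 1.0).
    ``noise_sd`` is lognormal measurement noise in log2 units.
    """

    metabolites: list
    cell_lines: list
    baseline: dict
    fold_effects: dict = field(default_factory=dict)
    conditions: tuple = ("normoxia", "hypoxia")
    n_replicates: int = 3
    noise_sd: float = 0.1
    protein_ug_mean: float = 100.0
    protein_ug_cv: float = 0.1

    def __post_init__(self) -> None:
        missing = [m for m in REQUIRED_METABOLITES if m not in self.metabolites]
        if missing:
            raise ValueError(f"panel must include required metabolites: {missing}")
        for m in self.metabolites:
            if m not in self.baseline:
                raise ValueError(f"no baseline level for metabolite {m!r}")

    def planted_fold(self, line: str, condition: str, metabolite: str) -> float:
        return float(self.fold_effects.get((line, condition, metabolite), 1.0))


def default_metabolite_panel(noise_sd: float = 0.1) -> MetabolitePanelSpec:
    """Panel emulating the lipogenesis-knockdown hypoxia experiment.

    In the control (scramble) line alpha-ketoglutarate drops under hypoxia
    while in the knockdown line it paradoxically rises; succinate falls
    under hypoxia in both lines, as do the other TCA intermediates.
    """
    mets = ["alpha-ketoglutarate", "succinate", "fumarate", "malate", "citrate"]
    baseline = {m: b for m, b in zip(mets, [2.0, 4.0, 1.5, 3.0, 5.0])}
    folds = {
        ("shScramble", "hypoxia", "alpha-ketoglutarate"): 0.7,
        ("shKD", "hypoxia", "alpha-ketoglutarate"): 1.5,
        ("shKD", "normoxia", "alpha-ketoglutarate"): 1.1,
        ("shScramble", "hypoxia", "succinate"): 0.8,
        ("shKD", "hypoxia", "succinate"): 0.8,
        ("shScramble", "hypoxia", "fumarate"): 0.8,
        ("shKD", "hypoxia", "fumarate"): 0.8,
        ("shScramble", "hypoxia", "malate"): 0.85,
        ("shKD", "hypoxia", "malate"): 0.85,
        ("shScramble", "hypoxia", "citrate"): 0.9,
        ("shKD", "hypoxia", "citrate"): 0.9,
    }
    return MetabolitePanelSpec(
        metabolites=mets,
        cell_lines=["shScramble", "shKD"],
        baseline=baseline,
        fold_effects=folds,
        noise_sd=noise_sd,
    )


def simulate_metabolites(panel_spec: MetabolitePanelSpec, seed: int = 0) -> pd.DataFrame:
    """Simulate a metabolite panel as a tidy table.

    One row per (cell_line, condition, replicate) with a ``protein_ug``
    column and one raw-value column per metabolite. Raw values are the
    planted protein-normalized level times the sample's protein content
    times lognormal noise, so protein normalization exactly recovers the
    planted levels at zero noise.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for line in panel_spec.cell_lines:
        for cond in panel_spec.conditions:
            for rep in range(1, panel_spec.n_replicates + 1):
                protein = panel_spec.protein_ug_mean * (
                    1.0 + panel_spec.protein_ug_cv * rng.standard_normal()
                )
                protein = max(protein, 1e-6)
                row = {
                    "cell_line": line,
                    "condition": cond,
                    "replicate": rep,
                    "protein_ug": protein,
                }
                for m in panel_spec.metabolites:
                    level = panel_spec.baseline[m] * panel_spec.planted_fold(line, cond, m)
                    noise = (
                        2.0 ** rng.normal(0.0, panel_spec.noise_sd)
                        if panel_spec.noise_sd > 0
                        else 1.0
                    )
                    row[m] = level * protein * noise
                rows.append(row)
    return pd.DataFrame(rows)
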