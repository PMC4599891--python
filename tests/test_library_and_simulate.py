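"""Library construction and the screen/expression/metabolite simulators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from poolscreen import (
    ScreenTruth,
    default_metabolite_panel,
    make_expression_truth,
    make_library,
    protein_normalize,
    simulate_expression,
    simulate_metabolites,
    simulate_screen,
)
from poolscreen.metabolites import hypoxia_change


class TestMakeLibrary:
    def test_forced_bounds_single_gene(self):
        lib = make_library(1, (3, 3), n_pools=1, seed=0)
        assert lib.n_hairpins == 3
        assert (lib.entries["pool_id"] == 1).all()

    def test_seed_determinism(self):
        a = make_library(100, (2, 6), n_pools=6, seed=1)
        b = make_library(100, (2, 6), n_pools=6, seed=1)
        pd.testing.assert_frame_equal(a.entries, b.entries)

    def test_pool_balance(self):
        # brute-force count of pool assignments: each pool within 20% of N*4/6
        lib = make_library(500, (4, 4), n_pools=6, seed=3)
        counts = lib.entries.groupby("pool_id")["hairpin_id"].count()
        expected = 500 * 4 / 6
        assert ((counts >= 0.8 * expected) & (counts <= 1.2 * expected)).all()
        # random assignment obeys the same bound at this size
        lib_r = make_library(500, (4, 4), n_pools=6, seed=3, pool_assignment="random")
        counts_r = lib_r.entries.groupby("pool_id")["hairpin_id"].count()
        assert ((counts_r >= 0.8 * expected) & (counts_r <= 1.2 * expected)).all()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_genes": 0},
            {"n_genes": 5, "hairpins_per_gene_range": (0, 3)},
            {"n_genes": 5, "n_pools": 0},
        ],
    )
    def test_invalid_arguments(self, kwargs):
        defaults = {"n_genes": 5, "hairpins_per_gene_range": (2, 3), "n_pools": 2}
        defaults.update(kwargs)
        with pytest.raises(ValueError):
            make_library(**defaults)


class TestSimulateScreen:
    def test_identity_case_channels_equal(self, small_library):
        truth = ScreenTruth(baseline_stress_survival=1.0, noise_sd=0.0)
        raw = simulate_screen(
            small_library, truth, n_replicates=2, seed=0,
            background_median=0.0, equalize_channel_mass=False,
        )
        np.testing.assert_allclose(raw["cy5_fg"], raw["cy3_fg"])

    def test_planted_effect_exact_ratio(self, small_library):
        gene = small_library.genes[0]
        truth = ScreenTruth(
            gene_effects={gene: 2.0}, baseline_stress_survival=1.0, noise_sd=0.0
        )
        raw = simulate_screen(
            small_library, truth, n_replicates=1, seed=0,
            background_median=0.0, equalize_channel_mass=False,
        )
        hp = set(small_library.hairpins_of(gene))
        sub = raw[raw["hairpin_id"].isin(hp)]
        net = (sub["cy5_fg"] - sub["cy5_bg"]) / (sub["cy3_fg"] - sub["cy3_bg"])
        np.testing.assert_allclose(net, 4.0)  # efficacy fixed at 1 in fixture

    def test_neutral_mean_matches_survival(self):
        # Monte-Carlo oracle: mean neutral log-ratio ~ log2(survival) +/- 3 SE
        lib = make_library(500, (1, 1), n_pools=1, seed=5)
        truth = ScreenTruth(baseline_stress_survival=0.5, noise_sd=0.25)
        raw = simulate_screen(
            lib, truth, n_replicates=3, seed=9,
            background_median=0.0, equalize_channel_mass=False,
        )
        lr = np.log2(
            (raw["cy5_fg"] - raw["cy5_bg"]) / (raw["cy3_fg"] - raw["cy3_bg"])
        )
        se = 0.25 / np.sqrt(len(lr))
        assert abs(lr.mean() - np.log2(0.5)) < 3 * se

    def test_determinism_and_row_conservation(self, small_library):
        truth = ScreenTruth()
        a = simulate_screen(small_library, truth, n_replicates=3, seed=4)
        b = simulate_screen(small_library, truth, n_replicates=3, seed=4)
        pd.testing.assert_frame_equal(a, b)
        assert len(a) == small_library.n_hairpins * 3
        assert not a.duplicated(["hairpin_id", "replicate"]).any()

    def test_planted_signal_monotone_in_delta_times_efficacy(self):
        # noiseless: hairpin log-ratio strictly increasing in delta*efficacy
        lib = make_library(9, (1, 1), n_pools=1, seed=2, efficacy_range=(1.0, 1.0))
        effects = {g: d for g, d in zip(lib.genes, np.linspace(-2, 2, 9))}
        truth = ScreenTruth(gene_effects=effects, noise_sd=0.0)
        raw = simulate_screen(
            lib, truth, n_replicates=1, seed=0,
            background_median=0.0, equalize_channel_mass=False,
        )
        raw = raw.merge(lib.entries, on="hairpin_id")
        raw["lr"] = np.log2(
            (raw["cy5_fg"] - raw["cy5_bg"]) / (raw["cy3_fg"] - raw["cy3_bg"])
        )
        raw["de"] = raw["gene_id_x"].map(effects) * raw["efficacy"]
        ordered = raw.sort_values("de")["lr"].to_numpy()
        assert (np.diff(ordered) > 0).all()

    def test_empty_library_rejected(self, small_library):
        empty = small_library.entries.iloc[:0]
        import poolscreen.library as pl

        with pytest.raises(ValueError):
            simulate_screen(
                pl.ShrnaLibrary(entries=empty, n_pools=1), ScreenTruth(), seed=0
            )


class TestSimulateExpression:
    def test_exact_class_difference_noiseless(self):
        truth = make_expression_truth(n_genes=200, n_de=20, overlap=0.5, seed=0)
        mat, lab = simulate_expression(truth, samples_per_class=3, effect_size=1.0,
                                       noise_sd=0.0, seed=1, program="A")
        diff = mat.loc[:, lab == 1].mean(axis=1) - mat.loc[:, lab == 0].mean(axis=1)
        for g in truth.de_genes("A"):
            assert diff[g] == pytest.approx(truth.programs["A"][g] * 1.0)
        non_de = diff.drop(list(truth.de_genes("A")))
        np.testing.assert_allclose(non_de, 0.0, atol=1e-12)

    def test_de_genes_carry_larger_t_statistics(self):
        truth = make_expression_truth(n_genes=500, n_de=50, overlap=0.6, seed=2)
        mat, lab = simulate_expression(truth, samples_per_class=6, effect_size=1.0,
                                       noise_sd=0.5, seed=3, program="A")
        t, _ = stats.ttest_ind(mat.loc[:, lab == 1], mat.loc[:, lab == 0], axis=1)
        t = pd.Series(np.abs(t), index=mat.index)
        de = list(truth.de_genes("A"))
        assert t[de].mean() > t.drop(de).mean() + 1.0

    def test_program_overlap_fraction(self):
        truth = make_expression_truth(n_genes=1000, n_de=50, overlap=0.6, seed=4)
        a, b = truth.de_genes("A"), truth.de_genes("B")
        assert len(a) == len(b) == 50
        assert len(a & b) == 30
        for g in a & b:  # shared genes agree in sign
            assert truth.programs["A"][g] == truth.programs["B"][g]

    def test_negative_effect_size_rejected(self):
        truth = make_expression_truth(n_genes=100, n_de=10, seed=0)
        with pytest.raises(ValueError):
            simulate_expression(truth, samples_per_class=3, effect_size=-1.0, seed=0)


class TestSimulateMetabolites:
    def test_noiseless_fold_recovery(self):
        spec = default_metabolite_panel(noise_sd=0.0)
        panel = protein_normalize(simulate_metabolites(spec, seed=0))
        fold = hypoxia_change(panel, mode="fold").set_index(["cell_line", "metabolite"])
        assert fold.loc[("shKD", "alpha-ketoglutarate"), "value"] == pytest.approx(
            1.5 / 1.1
        )
        assert fold.loc[("shScramble", "alpha-ketoglutarate"), "value"] == pytest.approx(0.7)
        assert fold.loc[("shScramble", "succinate"), "value"] == pytest.approx(0.8)

    def test_identical_conditions_zero_percent_change(self):
        spec = default_metabolite_panel(noise_sd=0.0)
        spec.fold_effects = {}
        panel = protein_normalize(simulate_metabolites(spec, seed=0))
        pct = hypoxia_change(panel, mode="percent")
        np.testing.assert_allclose(pct["value"], 0.0, atol=1e-9)

    def test_noisy_fold_within_monte_carlo_error(self):
        # repeat-simulation oracle: recovered fold within 3 SE of planted
        spec = default_metabolite_panel(noise_sd=0.1)
        folds = []
        for seed in range(30):
            panel = protein_normalize(simulate_metabolites(spec, seed=seed))
            f = hypoxia_change(panel, mode="fold").set_index(["cell_line", "metabolite"])
            folds.append(f.loc[("shScramble", "alpha-ketoglutarate"), "value"])
        folds = np.asarray(folds)
        se = folds.std(ddof=1) / np.sqrt(len(folds))
        assert abs(folds.mean() - 0.7) < 3 * se

    def test_missing_required_metabolite_rejected(self):
        spec = default_metabolite_panel()
        with pytest.raises(ValueError):
            type(spec)(
                metabolites=["succinate"],
                cell_lines=["x"],
                baseline={"succinate": 1.0},
            )
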