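"""Synthetic screen generator: design arithmetic, determinism, null structure."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ldlrscreen import (
    PipelineConfig,
    SimulationConfig,
    normalize_screen,
    simulate_deconvolution,
    simulate_expression,
    simulate_screen,
)
from ldlrscreen.io import ConfigError
from ldlrscreen.simulate import simulate_truth


class TestDesign:
    def test_plate_count_and_single_placement(self):
        sim = SimulationConfig(n_genes=700, n_ns_per_plate=16,
                               n_pos_per_plate=4, n_neg_per_plate=4,
                               n_cytotox_per_plate=4, seed=1)
        design, wells, truth = simulate_screen(sim)
        capacity = 384 - 28
        n_plates = math.ceil(700 / capacity)
        assert design.groupby("replicate")["plate"].nunique().eq(n_plates).all()
        # every gene placed exactly once per replicate
        samples = design[design["role"] == "sample"]
        counts = samples.groupby(["gene", "replicate"]).size()
        assert (counts == 1).all()
        assert samples["gene"].nunique() == 700

    def test_roles_partition_wells(self, small_sim):
        design, _, _ = simulate_screen(small_sim)
        per_plate = design.groupby("plate")["role"].value_counts().unstack(
            fill_value=0
        )
        assert (per_plate["ns_control"] == small_sim.n_ns_per_plate).all()
        assert (per_plate["pos_control_npc1"] == small_sim.n_pos_per_plate).all()
        assert (per_plate.sum(axis=1) == small_sim.wells_per_plate).all()

    def test_control_overflow_rejected(self):
        with pytest.raises(ConfigError, match="capacity"):
            SimulationConfig(n_genes=10, wells_per_plate=96,
                             n_ns_per_plate=90, n_pos_per_plate=4,
                             n_neg_per_plate=4, n_cytotox_per_plate=4)

    def test_control_positions_randomized_across_plates(self, small_sim):
        design, _, _ = simulate_screen(small_sim)
        ns = design[design["role"] == "ns_control"]
        layouts = {
            tuple(sorted(grp["well"])) for _, grp in ns.groupby("plate")
        }
        assert len(layouts) > 1  # not a fixed column of control wells


class TestDeterminism:
    def test_same_seed_identical_tables(self, small_sim):
        _, w1, t1 = simulate_screen(small_sim)
        _, w2, t2 = simulate_screen(small_sim)
        pd.testing.assert_frame_equal(w1, w2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_seed_changes_measurements(self, small_sim):
        import dataclasses

        _, w1, _ = simulate_screen(small_sim)
        _, w2, _ = simulate_screen(dataclasses.replace(small_sim, seed=43))
        assert not np.allclose(w1["mean_intensity"], w2["mean_intensity"])

    def test_deconvolution_deterministic(self, small_sim):
        _, _, truth = simulate_screen(small_sim)
        genes = truth["gene"].head(10).tolist()
        d1 = simulate_deconvolution(small_sim, truth, genes)
        d2 = simulate_deconvolution(small_sim, truth, genes)
        pd.testing.assert_frame_equal(d1, d2)


class TestScreenStructure:
    def test_ns_median_z_near_zero_despite_plate_effects(self):
        """With no true effects but strong multiplicative plate effects, the
        plate-median normalization recenters NS wells at z ~ 0."""
        sim = SimulationConfig(
            n_genes=50 * 368, frac_true_up=0.0, frac_true_down=0.0,
            cytotox_fraction=0.0, plate_effect_sd=0.3, n_replicates=1, seed=7,
        )
        _, wells, _ = simulate_screen(sim)
        raw_medians = wells[wells["role"] != "empty"].groupby("plate")[
            "mean_intensity"
        ].median()
        assert raw_medians.std() / raw_medians.mean() > 0.1  # plates do differ
        wellz, _, _ = normalize_screen(wells, PipelineConfig())
        ns_median = wellz.loc[wellz["role"] == "ns_control", "z"].median()
        assert abs(ns_median) < 0.1

    def test_positive_control_thirty_percent_above_ns(self, small_sim):
        """NPC1 wells average ~1.30x the NS level within sampling error."""
        import dataclasses

        sim = dataclasses.replace(small_sim, n_genes=3000,
                                  wells_per_plate=384, n_ns_per_plate=16,
                                  n_pos_per_plate=8, plate_effect_sd=0.0)
        _, wells, _ = simulate_screen(sim)
        pos = wells.loc[wells["role"] == "pos_control_npc1", "mean_intensity"]
        ns = wells.loc[wells["role"] == "ns_control", "mean_intensity"]
        ratio = pos.mean() / ns.mean()
        se = ratio * sim.well_noise_cv * math.sqrt(1 / len(pos) + 1 / len(ns))
        assert abs(ratio - 1.30) < 4 * se

    def test_cytotoxic_genes_get_low_cell_counts(self, small_sim):
        import dataclasses

        sim = dataclasses.replace(small_sim, cytotox_fraction=0.2)
        _, wells, truth = simulate_screen(sim)
        toxic = set(truth.loc[truth["cytotoxic"], "gene"])
        assert toxic
        sample = wells[wells["role"] == "sample"]
        toxic_counts = sample.loc[sample["gene"].isin(toxic),
                                  "valid_object_count"]
        ok_counts = sample.loc[~sample["gene"].isin(toxic),
                               "valid_object_count"]
        assert toxic_counts.max() < 500 <= ok_counts.min()

    def test_null_z_plate_exchangeable(self):
        """Zero-effect z distributions are indistinguishable across plates."""
        sim = SimulationConfig(
            n_genes=2 * 368, frac_true_up=0.0, frac_true_down=0.0,
            cytotox_fraction=0.0, plate_effect_sd=0.3, n_replicates=1, seed=3,
        )
        _, wells, _ = simulate_screen(sim)
        wellz, _, _ = normalize_screen(wells, PipelineConfig())
        plates = wellz["plate"].unique()
        z0 = wellz.loc[wellz["plate"] == plates[0], "z"]
        z1 = wellz.loc[wellz["plate"] == plates[1], "z"]
        assert sps.ks_2samp(z0, z1).pvalue > 0.01


class TestDeconvolution:
    def test_arity(self, small_sim):
        _, _, truth = simulate_screen(small_sim)
        genes = truth["gene"].head(10).tolist()
        wells = simulate_deconvolution(small_sim, truth, genes)
        samples = wells[wells["role"] == "sample"]
        assert len(samples) == 10 * 3 * small_sim.n_replicates
        assert samples.groupby(["gene", "sirna", "replicate"]).size().eq(1).all()

    def test_empty_candidates_empty_output(self, small_sim):
        _, _, truth = simulate_screen(small_sim)
        assert len(simulate_deconvolution(small_sim, truth, [])) == 0

    def test_unknown_candidate_rejected(self, small_sim):
        _, _, truth = simulate_screen(small_sim)
        with pytest.raises(ValueError, match="ghost"):
            simulate_deconvolution(small_sim, truth, ["ghost"])

    def test_null_gene_sirnas_stay_null(self, small_sim):
        """A gene with zero true effect yields siRNA wells at baseline level
        regardless of the drawn efficacies."""
        import dataclasses

        sim = dataclasses.replace(small_sim, plate_effect_sd=0.0,
                                  well_noise_cv=1e-6)
        _, _, truth = simulate_screen(sim)
        null_gene = truth.loc[truth["true_screen_effect"] == 0, "gene"].iloc[0]
        wells = simulate_deconvolution(sim, truth, [null_gene])
        vals = wells.loc[wells["gene"] == null_gene, "mean_intensity"]
        assert np.allclose(vals, sim.baseline_intensity, rtol=1e-4)


class TestExpression:
    def test_arity(self):
        sim = SimulationConfig(n_genes=100, seed=2)
        rng = np.random.default_rng(sim.seed)
        truth = simulate_truth(sim, rng)
        expr = simulate_expression(sim, truth)
        assert len(expr) == 100 * 3 * sim.expr_n_replicates

    def test_noise_free_limit_recovers_exact_ratio(self):
        import dataclasses

        sim = dataclasses.replace(SimulationConfig(n_genes=50, seed=2),
                                  expr_noise_sd=0.0, frac_modulated=1.0,
                                  modulated_log2fc_range=(
                                      math.log2(1.2), math.log2(1.2)))
        rng = np.random.default_rng(sim.seed)
        truth = simulate_truth(sim, rng)
        expr = simulate_expression(sim, truth)
        g = truth["gene"].iloc[0]
        sub = expr[expr["gene"] == g]
        statin = sub.loc[sub["condition"] == "statin", "expression"].mean()
        ctrl = sub.loc[sub["condition"] == "control", "expression"].mean()
        assert statin / ctrl == pytest.approx(1.2, abs=1e-12)

    def test_unmodulated_geometric_mean_fc_is_one(self):
        """Under the null the statin/control ratio centres on 1: the mean
        log2 ratio over genes is 0 within sampling error (the log scale is
        where the generator's noise is additive and unbiased)."""
        sim = SimulationConfig(n_genes=2000, frac_modulated=0.0, seed=9)
        rng = np.random.default_rng(sim.seed)
        truth = simulate_truth(sim, rng)
        expr = simulate_expression(sim, truth)
        wide = expr.pivot_table(index="gene", columns="condition",
                                values="expression", aggfunc="mean")
        log_ratios = np.log2(wide["statin"] / wide["control"])
        se = log_ratios.std() / math.sqrt(len(log_ratios))
        assert abs(log_ratios.mean()) < 3 * se
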