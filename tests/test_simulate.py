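"""Generator determinism, planted-truth consistency and null calibration."""

import math

import numpy as np
import pandas as pd
import pytest

from eposcreen import (
    MANELLA_CONTRASTS, STUDY_THRESHOLDS, ScreenConfig, SimConfig, cohens_d,
    filter_table, gen_alias_table, gen_annotations, gen_deg_tables,
    gen_expression, screen_panel,
)


class TestConfigValidation:
    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            SimConfig(zero_variance_fraction=1.5)
        with pytest.raises(ValueError):
            SimConfig(alias_noise={"synonym": -0.1})

    def test_group_size_below_two_needs_zero_variance_intent(self):
        with pytest.raises(ValueError, match="group size"):
            SimConfig(group_sizes=1)
        SimConfig(group_sizes=1, zero_variance_fraction=1.0)  # allowed

    def test_unknown_dialect_rejected(self):
        with pytest.raises(ValueError, match="dialect"):
            SimConfig(deg_fractions={"nonexistent": 0.1})

    def test_control_must_be_a_condition(self):
        with pytest.raises(ValueError):
            SimConfig(condition_labels=("a", "b"), control_label="z")


class TestDeterminism:
    def test_identical_config_identical_outputs(self):
        cfg_a = SimConfig(seed=21, n_genes=40, group_sizes=5,
                          planted_effects={"G0001": ("acute_aerobic", 1.0)},
                          zero_variance_fraction=0.1)
        cfg_b = SimConfig(seed=21, n_genes=40, group_sizes=5,
                          planted_effects={"G0001": ("acute_aerobic", 1.0)},
                          zero_variance_fraction=0.1)
        sa, suma, ta = gen_expression(cfg_a)
        sb, sumb, tb = gen_expression(cfg_b)
        assert sa.to_csv() == sb.to_csv()  # byte-identical serialisation
        assert suma.to_csv() == sumb.to_csv()
        assert ta.responsive_genes == tb.responsive_genes

    def test_streams_are_independent(self):
        """Changing annotation parameters must not perturb expression output."""
        base = SimConfig(seed=13, n_genes=30, group_sizes=4)
        other = SimConfig(seed=13, n_genes=30, group_sizes=4, n_terms=200,
                          term_size_range=(2, 10))
        _, sum_a, _ = gen_expression(base)
        _, sum_b, _ = gen_expression(other)
        pd.testing.assert_frame_equal(sum_a, sum_b)

    def test_seed_changes_output(self):
        _, a, _ = gen_expression(SimConfig(seed=1, n_genes=10, group_sizes=4))
        _, b, _ = gen_expression(SimConfig(seed=2, n_genes=10, group_sizes=4))
        assert not a.equals(b)


class TestExpression:
    def test_null_gene_not_in_truth_and_small_effect(self):
        cfg = SimConfig(seed=5, n_genes=20, group_sizes=50)
        _, summary, truth = gen_expression(cfg)
        assert truth.responsive_genes == set()
        d = cohens_d(summary.loc["G0000", "acute_aerobic_mean"],
                     summary.loc["G0000", "acute_aerobic_sd"],
                     summary.loc["G0000", "inactivity_mean"],
                     summary.loc["G0000", "inactivity_sd"])
        assert abs(d) < 0.8  # null effect, sampling error only

    def test_planted_effect_recovered_within_sampling_error(self):
        """Monte-Carlo over 200 replicate seeds: empirical d within +/-0.3."""
        errs = []
        for seed in range(200):
            cfg = SimConfig(seed=seed, n_genes=3, group_sizes=30,
                            planted_effects={"G0000": ("acute_aerobic", 1.0)})
            _, summary, truth = gen_expression(cfg)
            assert truth.responsive_genes == {"G0000"}
            d = cohens_d(summary.loc["G0000", "acute_aerobic_mean"],
                         summary.loc["G0000", "acute_aerobic_sd"],
                         summary.loc["G0000", "inactivity_mean"],
                         summary.loc["G0000", "inactivity_sd"])
            errs.append(d - 1.0)
        assert np.mean(np.abs(errs)) < 0.3
        assert abs(np.mean(errs)) < 0.1  # unbiased

    def test_all_zero_variance_forces_nan_p_everywhere(self):
        cfg = SimConfig(seed=2, n_genes=15, group_sizes=4,
                        zero_variance_fraction=1.0)
        samples, summary, truth = gen_expression(cfg)
        assert summary["p"].isna().all()
        assert (summary.filter(like="_sd") == 0).all().all()
        assert truth.zero_variance_genes == set(summary.index)

    def test_sub_threshold_planted_effect_not_responsive_truth(self):
        cfg = SimConfig(seed=4, n_genes=5, group_sizes=10,
                        planted_effects={"G0002": ("other", 0.3)})
        _, _, truth = gen_expression(cfg)
        assert truth.responsive_genes == set()

    def test_unknown_planted_gene_rejected(self):
        with pytest.raises(ValueError):
            gen_expression(SimConfig(n_genes=5, planted_effects={
                "G9999": ("other", 1.0)}))

    def test_null_screen_calibration(self):
        """With no planted effects the screen flags at most alpha + 2*SE."""
        flagged, total = 0, 0
        for seed in (31, 32, 33):
            cfg = SimConfig(seed=seed, n_genes=150, group_sizes=10)
            _, summary, _ = gen_expression(cfg)
            res = screen_panel(list(summary.index), summary, ScreenConfig())
            flagged += len(res.responsive_genes)
            total += cfg.n_genes
        alpha = 0.05
        se = math.sqrt(alpha * (1 - alpha) / total)
        assert flagged / total <= alpha + 2 * se


class TestDEGTables:
    def test_zero_fraction_empty_everywhere(self):
        cfg = SimConfig(seed=1, n_genes=50,
                        deg_fractions={k: 0.0 for k in STUDY_THRESHOLDS})
        tables, truth = gen_deg_tables(cfg)
        for dialect, rows in tables.items():
            assert truth.deg_sets[dialect] == set()
            assert filter_table(rows, STUDY_THRESHOLDS[dialect]).genes == set()

    def test_manella_contrast_labels_from_known_intervals(self):
        tables, _ = gen_deg_tables(SimConfig(seed=7, n_genes=60))
        labels = {r.contrast for r in tables["manella"]}
        assert labels <= set(MANELLA_CONTRASTS)
        assert {r.contrast for r in tables["pham"]} <= {"HA1", "HA3"}

    def test_non_degs_fail_at_least_one_criterion(self):
        cfg = SimConfig(seed=8, n_genes=200)
        tables, truth = gen_deg_tables(cfg)
        for dialect, rows in tables.items():
            thr = STUDY_THRESHOLDS[dialect]
            from eposcreen import row_passes
            for row in rows:
                assert row_passes(row, thr) == (row.gene in truth.deg_sets[dialect])


class TestAliasGenerator:
    def test_no_noise_identity(self):
        _, _, corrupted, truth = gen_alias_table(SimConfig(seed=1, panel_size=30))
        assert corrupted == [f"GENE{i}" for i in range(30)]
        assert all(truth.alias_map[r] == r for r in corrupted)

    def test_truth_structure(self):
        cfg = SimConfig(seed=2, panel_size=100,
                        alias_noise={"synonym": 0.2, "case": 0.1, "loc": 0.2,
                                     "loc_unresolvable": 0.5})
        primary, secondary, corrupted, truth = gen_alias_table(cfg)
        assert len(corrupted) == 100
        routes = list(truth.alias_routes.values())
        assert routes.count("synonym") == 20
        assert routes.count("second_pass") == 10
        assert routes.count("unmapped") == 10
        # every truth target exists in the primary table
        for target in truth.alias_map.values():
            if target is not None:
                assert primary.approved(target) is not None


class TestAnnotationGenerator:
    def test_planted_term_too_large_rejected(self):
        cfg = SimConfig(planted_terms=1, planted_term_size=50,
                        planted_term_input_fraction=1.0)
        with pytest.raises(ValueError, match="planted term"):
            gen_annotations(cfg, [f"g{i}" for i in range(100)],
                            input_genes=["g0", "g1"])

    def test_term_sizes_respect_range_and_universe(self):
        cfg = SimConfig(seed=3, n_terms=20, term_size_range=(5, 15))
        annotation, _ = gen_annotations(cfg, [f"g{i}" for i in range(50)])
        for _, (_, genes) in annotation.terms.items():
            assert 5 <= len(genes) <= 15

    def test_oversized_terms_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            gen_annotations(SimConfig(term_size_range=(10, 50)),
                            [f"g{i}" for i in range(20)])
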