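"""Synthetic experiment generators: design structure, effects, validation, I/O."""

import math

import numpy as np
import pandas as pd
import pytest

from wienerfit.ddm import DDMParams, choice_probability
from wienerfit.generate import (
    DesignConfig,
    GroundTruth,
    exp1_design,
    exp2_design,
    generate_experiment1,
    generate_experiment2,
    read_trials,
    validate_trials,
    write_trials,
)

#: near-degenerate group spread: isolates fixed effects from subject noise
TIGHT = dict(sd_v=1e-3, sd_log_a=1e-3, sd_log_t=1e-3, sd_logit_z=1e-3)


class TestDesignConfig:
    def test_default_shapes_match_study_designs(self):
        d1, d2 = exp1_design(), exp2_design()
        assert (d1.n_subjects, d1.trials_per_block) == (27, 100)
        assert (d2.n_subjects, d2.trials_per_block) == (30, 96)
        assert d2.cue_schedule == ("none", "none", "cued", "cued")

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_subjects": 0, "trials_per_block": 10},
            {"n_subjects": 2, "trials_per_block": 9},
            {"n_subjects": 2, "trials_per_block": 10, "switch_position": 1.5},
            {"n_subjects": 2, "trials_per_block": 10, "cue_schedule": ("none",)},
            {"n_subjects": 2, "trials_per_block": 10, "modality_order": "random"},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DesignConfig(**kwargs)

    def test_truth_with_out_of_domain_starting_point_rejected(self):
        with pytest.raises(ValueError):
            GroundTruth(z0=0.98, dz_cue=0.05)


class TestExperiment1:
    def test_default_design_yields_10800_rows(self):
        df = generate_experiment1(exp1_design(seed=0), GroundTruth(**TIGHT), dt=1e-3)
        assert len(df) == 27 * 4 * 100
        assert set(df["cue"]) == {"none"}
        assert set(df["congruency"]) == {"baseline"}

    def test_modality_alternates_and_orders_are_counterbalanced(self, exp1_small):
        per_block = exp1_small.groupby(["subject", "block"])["modality"].agg(lambda s: s.iloc[0]).unstack()
        # alternation within subject
        assert (per_block[1] != per_block[2]).all()
        assert (per_block[1] == per_block[3]).all()
        # half the subjects start with each modality (+/- 1)
        n_point_first = (per_block[1] == "point").sum()
        assert abs(n_point_first - len(per_block) / 2) <= 0.5

    def test_nondecision_shift_passes_through_to_mean_rt(self):
        truth = GroundTruth(t_point=0.55, t_swipe=0.45, **TIGHT)
        cfg = exp1_design(n_subjects=25, trials_per_block=100, seed=5)
        df = generate_experiment1(cfg, truth, dt=2e-4)
        g = df.groupby("modality")["rt"]
        diff = g.mean()["point"] - g.mean()["swipe"]
        se = math.sqrt(sum(g.var()[m] / g.count()[m] for m in ("point", "swipe")))
        assert abs(diff - 0.1) < 3 * se

    def test_same_seed_gives_byte_identical_tables(self, tmp_path):
        cfg = exp1_design(n_subjects=3, trials_per_block=10, seed=9)
        paths = []
        for i in range(2):
            df = generate_experiment1(cfg, dt=1e-3)
            path = tmp_path / f"t{i}.csv"
            write_trials(df, path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    def test_choice_frequencies_match_closed_form_prediction(self):
        truth = GroundTruth(**TIGHT)
        cfg = exp1_design(n_subjects=20, trials_per_block=50, seed=13)
        df = generate_experiment1(cfg, truth, dt=1e-4)
        right = df[df["stimulus"] == "right"]
        p_exact = choice_probability(DDMParams(v=truth.v, a=truth.a, z=truth.z0, t=0.5))
        n = len(right)
        phat = (right["response"] == "right").mean()
        assert abs(phat - p_exact) < 3 * math.sqrt(p_exact * (1 - p_exact) / n)


class TestExperiment2:
    def test_default_design_yields_11520_rows(self):
        df = generate_experiment2(exp2_design(seed=0), GroundTruth(**TIGHT), dt=1e-3)
        assert len(df) == 30 * 4 * 96

    def test_cued_blocks_structure(self, exp2_small):
        uncued = exp2_small[exp2_small["block"] <= 2]
        cued = exp2_small[exp2_small["block"] >= 3]
        assert set(uncued["cue"]) == {"none"}
        assert set(cued["cue"]) == {"75/25", "25/75"}
        # mid-block switch: each cue fills exactly half of each cued block
        counts = cued.groupby(["subject", "block", "cue"]).size()
        assert (counts == exp2_small.attrs["meta"]["design"]["trials_per_block"] // 2).all()

    def test_balanced_stimuli_force_equal_congruency_counts(self, exp2_small):
        cued = exp2_small[exp2_small["cue"] != "none"]
        counts = cued.groupby(["subject", "congruency"]).size().unstack()
        assert (counts["congruent"] == counts["incongruent"]).all()

    def test_null_truth_shows_no_cue_effect_on_choice(self):
        truth = GroundTruth(dz_cue=0.0, dv_congruency=0.0, z0=0.5, **TIGHT)
        cfg = exp2_design(n_subjects=10, trials_per_block=96, seed=21)
        df = generate_experiment2(cfg, truth, dt=2e-4)
        cued = df[df["cue"] != "none"]
        p = cued.groupby("cue")["response"].apply(lambda s: (s == "right").mean())
        n = cued.groupby("cue").size()
        se = math.sqrt(sum(p[c] * (1 - p[c]) / n[c] for c in p.index))
        assert abs(p["75/25"] - p["25/75"]) < 3 * se

    def test_cue_shifts_choice_toward_majority_side(self):
        df = generate_experiment2(exp2_design(n_subjects=10, trials_per_block=96, seed=22),
                                  GroundTruth(**TIGHT), dt=2e-4)
        cued = df[df["cue"] != "none"]
        p = cued.groupby("cue")["response"].apply(lambda s: (s == "right").mean())
        assert p["25/75"] > p["75/25"]

    def test_match_cue_frequencies_flag(self):
        cfg = exp2_design(n_subjects=4, trials_per_block=96, seed=3, match_cue_frequencies=True)
        df = generate_experiment2(cfg, GroundTruth(**TIGHT), dt=1e-3)
        cued = df[df["cue"] == "75/25"]
        frac_left = (cued["stimulus"] == "left").mean()
        assert frac_left == 0.75


class TestValidationAndIO:
    def test_round_trip_preserves_table(self, exp2_small, tmp_path):
        path = tmp_path / "trials.csv"
        write_trials(exp2_small, path)
        back = read_trials(path)
        pd.testing.assert_frame_equal(back, exp2_small.reset_index(drop=True))
        assert back.attrs["meta"]["rt_unit"] == "s"

    def test_millisecond_tables_are_converted_on_read(self, exp2_small, tmp_path):
        ms = exp2_small.copy()
        ms["rt"] = ms["rt"] * 1000.0
        ms.attrs["meta"] = {"rt_unit": "ms"}
        path = tmp_path / "ms.csv"
        write_trials(ms, path)
        back = read_trials(path)
        np.testing.assert_allclose(back["rt"], exp2_small["rt"])

    def test_negative_rt_rejected(self, exp2_small):
        bad = exp2_small.copy()
        bad.loc[bad.index[0], "rt"] = -0.1
        with pytest.raises(ValueError, match="rt"):
            validate_trials(bad)

    def test_baseline_cue_with_congruency_label_rejected(self, exp2_small):
        bad = exp2_small.copy()
        idx = bad.index[bad["cue"] == "none"][0]
        bad.loc[idx, "congruency"] = "congruent"
        with pytest.raises(ValueError, match="congruency"):
            validate_trials(bad)

    def test_missing_column_rejected(self, exp2_small):
        with pytest.raises(ValueError, match="missing columns"):
            validate_trials(exp2_small.drop(columns=["response"]))

    def test_mirrored_truth_mirrors_choice_behaviour(self):
        # relabelling left/right (z -> 1 - z) flips the lateral bias exactly
        cfg = exp2_design(n_subjects=8, trials_per_block=48, seed=17)
        df_r = generate_experiment2(cfg, GroundTruth(z0=0.55, **TIGHT), dt=1e-3)
        df_l = generate_experiment2(cfg, GroundTruth(z0=0.45, **TIGHT), dt=1e-3)
        p_right = (df_r[df_r["cue"] == "none"]["response"] == "right").mean()
        p_left = (df_l[df_l["cue"] == "none"]["response"] == "left").mean()
        # same seed drives the same noise stream; mirrored bias => close rates
        assert abs(p_right - p_left) < 0.03
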