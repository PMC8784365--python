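import numpy as np
import pandas as pd
import pytest

from suturespm.efficiency import efficiency_table
from suturespm.noise import (
    NoiseError,
    inject_target_noise,
    noise_sweep,
    reduced_vocabulary_analysis,
)
from suturespm.similarity import similarity_table
from suturespm.synthetic import (
    SyntheticConfig,
    action_signal_profiles,
    generate_dataset,
    target_signal_profiles,
)
from suturespm.vectorization import get_vocabulary

from conftest import make_dataset


def _interval_pairs(a, b):
    for (_, _, seg_a), (_, _, seg_b) in zip(a.iter_segments(), b.iter_segments()):
        for hand in ("left", "right"):
            yield from zip(seg_a.intervals(hand), seg_b.intervals(hand))


class TestInjectTargetNoise:
    def test_zero_probability_is_identity(self, small_cohort):
        assert inject_target_noise(small_cohort, 0.0, seed=1) == small_cohort

    def test_full_probability_changes_every_target(self, paper_cohort):
        corrupted = inject_target_noise(paper_cohort, 1.0, seed=2)
        for orig, new in _interval_pairs(paper_cohort, corrupted):
            assert (orig.start_s, orig.end_s) == (new.start_s, new.end_s)
            if orig.label.is_productive:
                assert new.label.action == orig.label.action
                assert new.label.target != orig.label.target
            else:
                assert new.label == orig.label

    def test_half_probability_changes_half_the_targets(self):
        config = SyntheticConfig(seed=9, sutures_per_participant=16)
        dataset = generate_dataset(config)
        corrupted = inject_target_noise(dataset, 0.5, seed=10)
        changed = total = 0
        for orig, new in _interval_pairs(dataset, corrupted):
            if orig.label.is_productive:
                total += 1
                changed += orig.label.target != new.label.target
        assert total >= 10_000
        assert changed / total == pytest.approx(0.5, abs=0.02)

    def test_deterministic_given_seed(self, small_cohort):
        a = inject_target_noise(small_cohort, 0.3, seed=5)
        b = inject_target_noise(small_cohort, 0.3, seed=5)
        c = inject_target_noise(small_cohort, 0.3, seed=6)
        assert a == b
        assert a != c

    def test_efficiency_exactly_invariant_under_target_switching(self, small_cohort):
        corrupted = inject_target_noise(small_cohort, 0.7, seed=3)
        for level in ("suture", "segment"):
            pd.testing.assert_frame_equal(
                efficiency_table(small_cohort, level),
                efficiency_table(corrupted, level),
                check_exact=True,
            )

    def test_to_idle_mode_degrades_efficiency(self, small_cohort):
        corrupted = inject_target_noise(small_cohort, 0.5, seed=4, mode="to_idle")
        base = efficiency_table(small_cohort, "suture")["s_eff_left"].mean()
        after = efficiency_table(corrupted, "suture")["s_eff_left"].mean()
        assert after < base - 0.1

    def test_invalid_probability_rejected(self, small_cohort):
        with pytest.raises(NoiseError):
            inject_target_noise(small_cohort, 1.5, seed=0)


class TestNoiseSweep:
    def test_zero_grid_matches_uncorrupted_run(self, small_cohort):
        result = noise_sweep(
            small_cohort, p_grid=(0.0,), replicates=3, analyses=("s_eff",), seed=1
        )
        from suturespm.stats import suture_level_lmm

        eff = efficiency_table(small_cohort, "suture")
        direct = suture_level_lmm(eff, "s_eff_left")
        row = result.table[result.table["hand"] == "left"].iloc[0]
        assert row["estimate"] == pytest.approx(direct.fixed_effect_estimate, abs=1e-9)
        assert row["p_value"] == pytest.approx(direct.p_value, rel=1e-6)

    def test_sweep_is_deterministic(self, small_cohort):
        kwargs = dict(p_grid=(0.0, 0.5), replicates=2, analyses=("similarity_suture",), seed=3)
        t1 = noise_sweep(small_cohort, **kwargs).table
        t2 = noise_sweep(small_cohort, **kwargs).table
        pd.testing.assert_frame_equal(t1, t2, check_exact=True)

    def test_unknown_analysis_rejected(self, small_cohort):
        with pytest.raises(NoiseError, match="unknown"):
            noise_sweep(small_cohort, analyses=("roc",), seed=0)

    def test_target_only_signal_is_destroyed_at_full_noise(self):
        profiles = target_signal_profiles()
        config = SyntheticConfig(
            seed=31, expert_profile=profiles["expert"], novice_profile=profiles["novice"],
        )
        dataset = generate_dataset(config)
        result = noise_sweep(
            dataset, p_grid=(0.0, 1.0), replicates=3,
            analyses=("similarity_suture",), seed=7,
        )
        tab = result.table[result.table["hand"] == "left"]
        sep = tab.groupby("noise_p").apply(
            lambda g: (g["expert_mean"] - g["novice_mean"]).mean(),
            include_groups=False,
        )
        assert sep[0.0] > 0.2
        assert abs(sep[1.0]) < 0.1

    def test_action_signal_survives_full_noise(self):
        profiles = action_signal_profiles()
        config = SyntheticConfig(
            seed=37, expert_profile=profiles["expert"], novice_profile=profiles["novice"],
        )
        dataset = generate_dataset(config)
        result = noise_sweep(
            dataset, p_grid=(1.0,), replicates=3, analyses=("similarity_suture",), seed=8
        )
        tab = result.table[result.table["hand"] == "left"]
        separation = (tab["expert_mean"] - tab["novice_mean"]).mean()
        assert separation > 0.1
        assert (tab["p_value"] < 0.05).all()

    def test_surviving_noise_level_summary(self, small_cohort):
        result = noise_sweep(
            small_cohort, p_grid=(0.0, 0.5), replicates=2, analyses=("b_eff",), seed=2
        )
        level = result.surviving_noise_level("b_eff")
        # efficiency is invariant under target switching: if significant at 0 it
        # survives the whole grid, otherwise it never is
        assert level in (-1.0, 0.5)


class TestReducedVocabulary:
    def test_uniform_targets_make_full18_equal_actions6(self):
        # every productive label targets the needle, so targets carry no signal
        suture_a = [[("needle_transport",
                      [(4.0, "move;needle"), (2.0, "idle"), (3.0, "hold_still;needle")],
                      [(5.0, "transport;needle"), (4.0, "grasp;needle")])]]
        suture_b = [[("needle_transport",
                      [(1.0, "move;needle"), (6.0, "idle"), (2.0, "not_visible")],
                      [(3.0, "transport;needle"), (6.0, "idle")])]]
        ds = make_dataset(
            {
                "e1": ("expert", suture_a), "e2": ("expert", suture_a),
                "n1": ("novice", suture_b), "n2": ("novice", suture_b),
            }
        )
        t18 = similarity_table(ds, "suture", "left", get_vocabulary("full18"))
        t6 = similarity_table(ds, "suture", "left", get_vocabulary("actions_special6"))
        assert np.allclose(t18["difference"], t6["difference"], atol=1e-12)

    def test_identical_groups_score_zero_in_every_variant(self):
        suture = [[("needle_transport",
                    [(4.0, "move;needle"), (2.0, "idle")], [(6.0, "transport;thread")])]]
        ds = make_dataset(
            {
                "e1": ("expert", suture), "e2": ("expert", suture),
                "n1": ("novice", suture), "n2": ("novice", suture),
            }
        )
        for variant in ("actions_special6", "actions_only4"):
            res = reduced_vocabulary_analysis(ds, variant)
            for hand in ("left", "right"):
                assert res.similarity_tables[hand]["difference"].abs().max() < 1e-12

    def test_action_separated_groups_keep_sign_under_actions_only4(self):
        profiles = action_signal_profiles()
        config = SyntheticConfig(
            seed=41, expert_profile=profiles["expert"], novice_profile=profiles["novice"],
        )
        dataset = generate_dataset(config)
        res = reduced_vocabulary_analysis(dataset, "actions_only4")
        agree = total = 0
        for hand in ("left", "right"):
            tab = res.similarity_tables[hand]
            expected = np.where(tab["group"] == "expert", 1.0, -1.0)
            agree += int((np.sign(tab["difference"]) == expected).sum())
            total += len(tab)
        assert agree / total >= 0.9
        assert res.n_skipped == 0

    def test_mostly_nonproductive_dataset_aborts(self):
        # each participant: one scoreable suture, two with no productive time
        valid = [("needle_transport", [(5.0, "move;needle")], [(5.0, "transport;needle")])]
        idle = [("needle_transport", [(5.0, "idle")], [(5.0, "not_visible")])]
        sutures = [valid, idle, idle]
        ds = make_dataset(
            {
                "e1": ("expert", sutures), "e2": ("expert", sutures),
                "n1": ("novice", sutures), "n2": ("novice", sutures),
            }
        )
        with pytest.raises(NoiseError, match="not meaningful"):
            reduced_vocabulary_analysis(ds, "actions_only4")

    def test_unknown_variant_rejected(self, small_cohort):
        with pytest.raises(NoiseError):
            reduced_vocabulary_analysis(small_cohort, "full18")
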