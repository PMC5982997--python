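"""Generator: schedule geometry, trait battery, and clip-level invariants."""

import numpy as np
import pandas as pd
import pytest

from earlife import (
    BehaviorTruth,
    ProtocolConfig,
    TruthParams,
    default_truth,
    generate_schedule,
    make_trait_scores,
    simulate_clips,
    simulate_study,
)
from earlife.errors import ConfigurationError, DataError
from earlife.synthetic import cronbach_alpha


class TestSchedule:
    def test_daily_slot_count_and_total(self):
        sched = generate_schedule(ProtocolConfig(), 3, seed=0)
        per_day = sched.groupby(
            [sched["participant_id"], sched["timestamp"].dt.normalize()]
        ).size()
        # 18 recording hours at one clip per 12.5 min, timer restarting
        # at 06:00: 87 slots every day, 261 over the three days
        assert set(per_day) == {87}
        assert all(sched.groupby("participant_id").size() == 261)

    def test_all_slots_outside_blackout(self):
        sched = generate_schedule(ProtocolConfig(), 5, seed=1)
        hours = sched["timestamp"].dt.hour
        assert ((hours >= 6) & (hours < 24)).all()

    def test_monday_start_has_no_weekend_slots(self):
        sched = generate_schedule(ProtocolConfig(), 2, seed=0, start_weekday=0)
        assert not sched["is_weekend"].any()

    def test_friday_start_is_mostly_weekend(self):
        sched = generate_schedule(ProtocolConfig(), 1, seed=0, start_weekday=4)
        # Friday 17:00 onwards plus all of Saturday and Sunday
        assert sched["is_weekend"].mean() == pytest.approx(208 / 261)

    def test_zero_study_days_gives_empty_schedule(self):
        sched = generate_schedule(ProtocolConfig(study_days=0), 3, seed=0)
        assert len(sched) == 0

    def test_weekend_fraction_over_uniform_weekday_starts(self):
        # enumerating the five start days gives 363/1305 = .278 exactly
        fractions = [
            generate_schedule(ProtocolConfig(), 1, seed=0, start_weekday=d)[
                "is_weekend"
            ].mean()
            for d in range(5)
        ]
        assert np.mean(fractions) == pytest.approx(363 / 1305)

    def test_deterministic_given_seed(self):
        a = generate_schedule(ProtocolConfig(), 4, seed=7)
        b = generate_schedule(ProtocolConfig(), 4, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_interval_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_schedule(
                ProtocolConfig(clip_interval_minutes=0), 1, seed=0
            )


class TestTraitScores:
    def test_output_is_standardized(self):
        scores = make_trait_scores(200, seed=0)
        assert scores.mean() == pytest.approx(0.0, abs=1e-12)
        assert scores.std(ddof=0) == pytest.approx(1.0, abs=1e-12)

    def test_single_scale_is_plain_normal_sample(self):
        scores, scales = make_trait_scores(500, n_scales=1, seed=1, return_scales=True)
        assert scales.shape == (500, 1)
        np.testing.assert_allclose(
            np.corrcoef(scores, scales[:, 0])[0, 1], 1.0, atol=1e-12
        )

    def test_default_correlation_yields_target_reliability(self):
        _, scales = make_trait_scores(4000, seed=2, return_scales=True)
        assert cronbach_alpha(scales) == pytest.approx(0.68, abs=0.04)

    def test_invalid_scale_count_rejected(self):
        with pytest.raises(ConfigurationError):
            make_trait_scores(10, n_scales=0, seed=0)


def _tiny_truth(n=6, seed=0, **overrides):
    base = dict(default_truth(n, seed=seed).behaviors)
    base.update(overrides)
    return TruthParams(
        behaviors=base,
        trait_scores=make_trait_scores(n, seed=seed),
        sex=np.arange(n) % 2,
    )


class TestSimulateClips:
    def test_impossible_behavior_never_occurs(self):
        truth = _tiny_truth(
            amusement_venue=BehaviorTruth(alpha=-np.inf, sigma_participant=0.0)
        )
        protocol = ProtocolConfig()
        sched = generate_schedule(protocol, truth.n_participants, seed=3)
        clips = simulate_clips(sched, truth, protocol, seed=4)
        assert (clips["beh_amusement_venue"] == 1).sum() == 0

    def test_neutral_behavior_has_half_occurrence(self):
        truth = _tiny_truth(
            n=30,
            tv_watching=BehaviorTruth(alpha=0.0, sigma_participant=0.0),
        )
        protocol = ProtocolConfig()
        sched = generate_schedule(protocol, truth.n_participants, seed=5)
        clips = simulate_clips(sched, truth, protocol, seed=6)
        code = clips["beh_tv_watching"]
        prop = (code == 1).sum() / code.isin([0, 1]).sum()
        assert prop == pytest.approx(0.5, abs=0.03)

    def test_occurrences_respect_denominators(self, study):
        clips, _, _ = study
        social = clips["beh_multi_interlocutor"].notna()
        assert (clips.loc[social, "in_social_interaction"] == True).all()  # noqa: E712
        awake = clips["beh_amusement_venue"].notna()
        assert (clips.loc[awake, "asleep"] == False).all()  # noqa: E712
        speaking = clips["beh_arguing"].notna()
        assert (clips.loc[speaking, "speaking"] == True).all()  # noqa: E712
        klass = clips["beh_class_attendance"].notna()
        ts = clips.loc[klass, "timestamp"]
        assert (ts.dt.dayofweek < 5).all()
        assert ((ts.dt.hour >= 8) & (ts.dt.hour < 17)).all()

    def test_asleep_clips_have_no_social_or_speaking(self, study):
        clips, _, _ = study
        asleep = clips["asleep"] == True  # noqa: E712
        assert not clips.loc[asleep, "in_social_interaction"].any()
        assert not clips.loc[asleep, "speaking"].any()

    def test_flags_undefined_when_noncompliant(self, study):
        clips, _, _ = study
        bad = ~clips["compliant"]
        assert clips.loc[bad, "asleep"].isna().all()
        beh_cols = [c for c in clips.columns if c.startswith("beh_")]
        assert clips.loc[bad, beh_cols].isna().all().all()

    def test_uncodable_fraction_bounded(self, study):
        clips, _, protocol_max = study
        for col in ("beh_tv_watching", "beh_amusement_venue", "beh_arguing"):
            per = clips.groupby("participant_id")[col].agg(
                uncod=lambda s: (s == -1).sum(),
                elig=lambda s: s.notna().sum(),
            )
            per = per[per["elig"] > 0]
            assert (per["uncod"] / per["elig"] <= 0.066).all()

    def test_deterministic_given_seed(self):
        truth = _tiny_truth()
        protocol = ProtocolConfig()
        sched = generate_schedule(protocol, truth.n_participants, seed=8)
        a = simulate_clips(sched, truth, protocol, seed=9)
        b = simulate_clips(sched, truth, protocol, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_schedule_rejected(self):
        truth = _tiny_truth()
        with pytest.raises(DataError):
            simulate_clips(
                pd.DataFrame(columns=["participant_id", "timestamp", "is_weekend"]),
                truth,
                ProtocolConfig(),
                seed=0,
            )

    def test_unknown_behavior_rejected(self):
        truth = _tiny_truth()
        truth.behaviors["sighing"] = BehaviorTruth(alpha=-1.0)
        protocol = ProtocolConfig()
        sched = generate_schedule(protocol, truth.n_participants, seed=0)
        with pytest.raises(ConfigurationError):
            simulate_clips(sched, truth, protocol, seed=0)


class TestStudyLevel:
    def test_compliance_and_weekend_rates(self, study):
        clips, _, _ = study
        per = clips.groupby("participant_id")["compliant"].sum()
        assert per.mean() == pytest.approx(232, abs=6)
        weekend_pct = clips.loc[clips["compliant"], "is_weekend"].mean()
        assert weekend_pct == pytest.approx(0.278, abs=0.10)

    def test_cohort_flags_mirror_study(self, study):
        _, participants, _ = study
        assert (~participants["enrolled_in_classes"]).sum() == 4
        assert (~participants["sleep_data_available"]).sum() == 1

    def test_reproducible(self):
        a = simulate_study(n_participants=5, seed=21)[0]
        b = simulate_study(n_participants=5, seed=21)[0]
        pd.testing.assert_frame_equal(a, b)
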