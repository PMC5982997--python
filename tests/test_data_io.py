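"""Aggregation against a brute-force oracle, merging, filters, and I/O."""

import numpy as np
import pandas as pd
import pytest

from earlife import (
    aggregate_counts,
    analyzed_behaviors,
    apply_cohort_filters,
    merge_religious_volunteer,
    pool_strata,
    read_count_table,
    simulate_study,
    write_count_table,
)
from earlife.behaviors import behavior_map
from earlife.data_io import read_clips, write_clips
from earlife.errors import AggregationError, SchemaError, ValidationError


@pytest.fixture(scope="module")
def small_study():
    return simulate_study(n_participants=5, seed=33)


def _oracle_counts(clips, spec):
    """Independent filter-and-count over plain clip dictionaries."""
    out = {}
    for rec in clips.to_dict("records"):
        if not rec["compliant"]:
            continue
        ts = rec["timestamp"]
        hour = ts.hour + ts.minute / 60.0
        rule = spec.denominator_rule.value
        def flag(name, value):
            v = rec[name]
            return (not pd.isna(v)) and bool(v) == value

        if rule == "clips_0600_1800":
            ok = 6 <= hour < 18
        elif rule == "clips_awake":
            ok = flag("asleep", False)
        elif rule == "clips_in_social_interaction":
            ok = flag("in_social_interaction", True)
        elif rule == "clips_speaking":
            ok = flag("speaking", True)
        else:  # weekday_0800_1700
            ok = ts.weekday() < 5 and 8 <= hour < 17
        code = rec[f"beh_{spec.name}"]
        if not ok or pd.isna(code) or code == -1:
            continue
        stratum = (
            "pooled"
            if spec.weekday_only
            else ("weekend" if rec["is_weekend"] else "weekday")
        )
        key = (rec["participant_id"], stratum)
        k, n = out.get(key, (0, 0))
        out[key] = (k + int(code == 1), n + 1)
    return out


@pytest.mark.parametrize(
    "behavior",
    ["daytime_sleeping", "multi_interlocutor", "arguing", "class_attendance",
     "amusement_venue"],
)
def test_aggregation_matches_bruteforce_oracle(small_study, behavior):
    clips, _, _ = small_study
    spec = behavior_map()[behavior]
    rows = aggregate_counts(clips, [spec])
    oracle = _oracle_counts(clips, spec)
    for rec in rows.to_dict("records"):
        k, n = oracle.get((rec["participant_id"], rec["stratum"]), (0, 0))
        assert (rec["k"], rec["n"]) == (k, n)


def test_counting_direct_example():
    ts = pd.Timestamp("2014-01-07 10:00")
    clips = pd.DataFrame(
        {
            "participant_id": 0,
            "timestamp": [ts] * 10,
            "is_weekend": False,
            "compliant": True,
            "asleep": pd.array([False] * 10, dtype="boolean"),
            "in_social_interaction": pd.array(
                [True] * 3 + [False] * 7, dtype="boolean"
            ),
            "speaking": pd.array([False] * 10, dtype="boolean"),
            "beh_social_interaction": pd.array(
                [1] * 3 + [0] * 7, dtype="Int8"
            ),
        }
    )
    rows = aggregate_counts(
        clips, [behavior_map()["social_interaction"]], stratify_by_weekend=False
    )
    assert rows.iloc[0][["k", "n"]].tolist() == [3, 10]


def test_aggregation_invariant_to_clip_order(small_study):
    clips, _, _ = small_study
    specs = [behavior_map()["social_interaction"]]
    shuffled = clips.sample(frac=1.0, random_state=5)
    a = aggregate_counts(clips, specs).sort_values(
        ["participant_id", "stratum"]).reset_index(drop=True)
    b = aggregate_counts(shuffled, specs).sort_values(
        ["participant_id", "stratum"]).reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b)


def test_strata_sum_to_pooled(small_study):
    clips, _, _ = small_study
    specs = list(analyzed_behaviors())
    strat = aggregate_counts(clips, specs, stratify_by_weekend=True)
    pooled = aggregate_counts(clips, specs, stratify_by_weekend=False)
    collapsed = pool_strata(strat)
    merged = collapsed.merge(
        pooled, on=["participant_id", "behavior"], suffixes=("_s", "_p")
    )
    assert (merged["k_s"] == merged["k_p"]).all()
    assert (merged["n_s"] == merged["n_p"]).all()


def test_denominator_never_exceeds_compliant_clips(small_study):
    clips, _, _ = small_study
    rows = pool_strata(aggregate_counts(clips, list(analyzed_behaviors())))
    compliant = clips.groupby("participant_id")["compliant"].sum()
    for rec in rows.to_dict("records"):
        assert rec["n"] <= compliant[rec["participant_id"]]

def test_missing_flag_names_behavior_and_rule(small_study):
    clips, _, _ = small_study
    spec = behavior_map()["social_interaction"]
    with pytest.raises(SchemaError, match="social_interaction"):
        aggregate_counts(clips.drop(columns=["asleep"]), [spec])


class TestMergeReligiousVolunteer:
    @staticmethod
    def _rows(k1, k2, n):
        return pd.DataFrame(
            {
                "participant_id": [0, 0],
                "behavior": ["religious_service", "volunteering"],
                "stratum": ["pooled", "pooled"],
                "k": [k1, k2],
                "n": [n, n],
            }
        )

    def test_count_level_sum(self):
        merged = merge_religious_volunteer(self._rows(2, 1, 200))
        row = merged[merged["behavior"] == "religious_or_volunteer"].iloc[0]
        assert (row["k"], row["n"]) == (3, 200)

    def test_sum_capped_at_denominator(self):
        merged = merge_religious_volunteer(self._rows(3, 2, 4))
        assert merged[merged["behavior"] == "religious_or_volunteer"]["k"].iloc[0] == 4

    def test_degenerate_zero_rows_kept_with_warning(self):
        with pytest.warns(UserWarning, match="zero denominators"):
            merged = merge_religious_volunteer(self._rows(0, 0, 0))
        row = merged[merged["behavior"] == "religious_or_volunteer"].iloc[0]
        assert (row["k"], row["n"]) == (0, 0)

    def test_mismatched_denominators_rejected(self):
        rows = self._rows(1, 1, 10)
        rows.loc[1, "n"] = 9
        with pytest.raises(AggregationError):
            merge_religious_volunteer(rows)

    def test_clip_level_union_counts_joint_clip_once(self):
        # five awake clips; clip 0 contains both behaviors
        ts = pd.Timestamp("2014-01-07 10:00")
        clips = pd.DataFrame(
            {
                "participant_id": 0,
                "timestamp": [ts] * 5,
                "is_weekend": False,
                "compliant": True,
                "asleep": pd.array([False] * 5, dtype="boolean"),
                "in_social_interaction": pd.array([False] * 5, dtype="boolean"),
                "speaking": pd.array([False] * 5, dtype="boolean"),
                "beh_religious_service": pd.array([1, 1, 0, 0, 0], dtype="Int8"),
                "beh_volunteering": pd.array([1, 0, 1, 0, 0], dtype="Int8"),
            }
        )
        rows = aggregate_counts(
            clips,
            [behavior_map()["religious_service"], behavior_map()["volunteering"]],
            stratify_by_weekend=False,
        )
        merged = merge_religious_volunteer(rows, clips=clips)
        row = merged[merged["behavior"] == "religious_or_volunteer"].iloc[0]
        # union is 3 clips (the joint clip counts once), not 2+2
        assert (row["k"], row["n"]) == (3, 5)


class TestCohortFilters:
    @staticmethod
    def _setup(n=91, not_enrolled=4, no_sleep=1):
        participants = pd.DataFrame(
            {
                "participant_id": range(n),
                "alhb": 0.0,
                "sex": 0,
                "enrolled_in_classes": [False] * not_enrolled
                + [True] * (n - not_enrolled),
                "sleep_data_available": [False] * no_sleep + [True] * (n - no_sleep),
            }
        )
        rows = pd.DataFrame(
            {
                "participant_id": list(range(n)) * 2,
                "behavior": ["class_attendance"] * n + ["daytime_sleeping"] * n,
                "stratum": "pooled",
                "k": 1,
                "n": 10,
            }
        )
        return rows, participants

    def test_enrollment_and_sleep_filters(self):
        rows, participants = self._setup()
        out = apply_cohort_filters(rows, participants)
        assert (out["behavior"] == "class_attendance").sum() == 87
        assert (out["behavior"] == "daytime_sleeping").sum() == 90

    def test_identity_when_all_flags_true(self):
        rows, participants = self._setup(not_enrolled=0, no_sleep=0)
        out = apply_cohort_filters(rows, participants)
        pd.testing.assert_frame_equal(out, rows)

    def test_other_behaviors_untouched(self):
        rows, participants = self._setup()
        rows.loc[rows["behavior"] == "daytime_sleeping", "behavior"] = "tv_watching"
        out = apply_cohort_filters(rows, participants)
        assert (out["behavior"] == "tv_watching").sum() == 91


class TestCountTableIO:
    def test_round_trip_csv_and_tsv(self, small_study, tmp_path):
        clips, participants, _ = small_study
        rows = aggregate_counts(clips, list(analyzed_behaviors()))
        for name in ("table.csv", "table.tsv"):
            path = tmp_path / name
            write_count_table(path, rows, participants)
            p2, r2 = read_count_table(path)
            merged = rows.merge(
                r2, on=["participant_id", "behavior", "stratum"], suffixes=("", "_r")
            )
            assert len(merged) == len(rows)
            assert (merged["k"] == merged["k_r"]).all()
            assert (merged["n"] == merged["n_r"]).all()
            np.testing.assert_allclose(
                p2.sort_values("participant_id")["alhb"].to_numpy(),
                participants.sort_values("participant_id")["alhb"].to_numpy(),
            )

    def test_pooled_layout_accepted(self, tmp_path):
        path = tmp_path / "pooled.csv"
        path.write_text(
            "participant_id,alhb,sex,arguing_k,arguing_n\n0,0.5,1,2,10\n1,-0.5,0,0,8\n"
        )
        participants, rows = read_count_table(path)
        assert set(rows["stratum"]) == {"pooled"}
        assert rows["k"].tolist() == [2, 0]

    def test_unknown_columns_preserved(self, tmp_path):
        path = tmp_path / "extra.csv"
        path.write_text(
            "participant_id,alhb,sex,cohort_wave,arguing_k,arguing_n\n"
            "0,0.5,1,w2,2,10\n"
        )
        participants, _ = read_count_table(path)
        assert participants["cohort_wave"].tolist() == ["w2"]

    def test_k_greater_than_n_rejected_with_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("participant_id,alhb,sex,arguing_k,arguing_n\n0,0,0,5,4\n")
        with pytest.raises(ValidationError, match="index 0"):
            read_count_table(path)

    def test_clip_round_trip(self, small_study, tmp_path):
        clips, _, _ = small_study
        path = tmp_path / "clips.csv"
        write_clips(path, clips)
        back = read_clips(path)
        assert len(back) == len(clips)
        pd.testing.assert_series_equal(
            back["beh_social_interaction"], clips["beh_social_interaction"]
        )
        pd.testing.assert_series_equal(back["asleep"], clips["asleep"])
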