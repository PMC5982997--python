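"""Reading, writing, and aggregation of EAR count tables.

The participant-level count table has one row per participant (or
participant x weekend stratum) with the trait composite, sex, cohort
flags, and per-behavior occurrence counts ``<behavior>_k`` and
eligible-clip counts ``<behavior>_n``.  Clip-level tables are long:
one row per 30-s sampling occasion with state flags and per-behavior
codes (see :mod:`earlife.synthetic`).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .behaviors import (
    BehaviorSpec,
    Denominator,
    MERGE_SOURCES,
    RELIGIOUS_OR_VOLUNTEER,
)
from .errors import AggregationError, SchemaError, ValidationError

PARTICIPANT_COLUMNS = (
    "participant_id",
    "alhb",
    "sex",
    "enrolled_in_classes",
    "sleep_data_available",
)

_RULE_REQUIRES = {
    Denominator.CLIPS_0600_1800: ("timestamp",),
    Denominator.CLIPS_AWAKE: ("asleep",),
    Denominator.CLIPS_IN_SOCIAL_INTERACTION: ("in_social_interaction",),
    Denominator.CLIPS_SPEAKING: ("speaking",),
    Denominator.WEEKDAY_0800_1700: ("timestamp",),
}


def _clip_denominator_mask(clips: pd.DataFrame, rule: Denominator) -> np.ndarray:
    ts = pd.to_datetime(clips["timestamp"]) if "timestamp" in clips else None
    if rule is Denominator.CLIPS_0600_1800:
        hour = ts.dt.hour + ts.dt.minute / 60.0
        return ((hour >= 6.0) & (hour < 18.0)).to_numpy()
    if rule is Denominator.CLIPS_AWAKE:
        return (clips["asleep"] == False).to_numpy()  # noqa: E712 (NA-safe)
    if rule is Denominator.CLIPS_IN_SOCIAL_INTERACTION:
        return (clips["in_social_interaction"] == True).to_numpy()  # noqa: E712
    if rule is Denominator.CLIPS_SPEAKING:
        return (clips["speaking"] == True).to_numpy()  # noqa: E712
    if rule is Denominator.WEEKDAY_0800_1700:
        hour = ts.dt.hour + ts.dt.minute / 60.0
        return ((ts.dt.dayofweek < 5) & (hour >= 8.0) & (hour < 17.0)).to_numpy()
    raise SchemaError(f"unknown denominator rule {rule!r}")


def aggregate_counts(
    clips: pd.DataFrame,
    behaviors: list[BehaviorSpec],
    stratify_by_weekend: bool = True,
) -> pd.DataFrame:
    """Aggregate clip records into per-participant (k, n) count rows.

    For each participant x behavior (x weekend stratum when stratified):
    ``n`` counts compliant clips that satisfy the behavior's denominator
    rule and were codable for it; ``k`` counts those in which the
    behavior occurred.  Uncodable clips (code -1) are excluded from both.
    Weekday-only behaviors are never stratified (their denominator
    excludes weekends by construction).  Participants with no eligible
    clips in a stratum get an explicit (k=0, n=0) row.
    """
    records = []
    participants = np.sort(clips["participant_id"].unique())
    for spec in behaviors:
        if spec.denominator_rule is None:
            raise SchemaError(
                f"behavior {spec.name!r} has no denominator rule; "
                "apply the reliability gate first"
            )
        for col in _RULE_REQUIRES[spec.denominator_rule] + ("compliant",):
            if col not in clips.columns:
                raise SchemaError(
                    f"behavior {spec.name!r} (rule {spec.denominator_rule.value}) "
                    f"requires clip column {col!r}"
                )
        code_col = f"beh_{spec.name}"
        if code_col not in clips.columns:
            raise SchemaError(f"missing clip column {code_col!r}")
        denom = _clip_denominator_mask(clips, spec.denominator_rule)
        code = clips[code_col]
        eligible = (
            clips["compliant"].to_numpy(dtype=bool)
            & denom
            & code.notna().to_numpy()
            & (code != -1).fillna(False).to_numpy()
        )
        occurred = eligible & (code == 1).fillna(False).to_numpy()
        stratified = stratify_by_weekend and not spec.weekday_only
        if stratified:
            if "is_weekend" not in clips.columns:
                raise SchemaError(
                    f"behavior {spec.name!r} stratification requires 'is_weekend'"
                )
            strata = np.where(
                clips["is_weekend"].to_numpy(dtype=bool), "weekend", "weekday"
            )
            levels = ("weekday", "weekend")
        else:
            strata = np.full(len(clips), "pooled")
            levels = ("pooled",)
        pid = clips["participant_id"].to_numpy()
        for p in participants:
            psel = pid == p
            for level in levels:
                ssel = psel & (strata == level)
                records.append(
                    {
                        "participant_id": p,
                        "behavior": spec.name,
                        "stratum": level,
                        "k": int(occurred[ssel].sum()),
                        "n": int(eligible[ssel].sum()),
                    }
                )
    return pd.DataFrame(
        records, columns=["participant_id", "behavior", "stratum", "k", "n"]
    )


def pool_strata(rows: pd.DataFrame) -> pd.DataFrame:
    """Collapse weekend strata to pooled per-participant counts."""
    pooled = (
        rows.groupby(["participant_id", "behavior"], as_index=False)[["k", "n"]]
        .sum()
    )
    pooled.insert(2, "stratum", "pooled")
    return pooled


def merge_religious_volunteer(
    rows: pd.DataFrame,
    clips: pd.DataFrame | None = None,
    sources: tuple[str, str] = MERGE_SOURCES,
    merged_name: str = RELIGIOUS_OR_VOLUNTEER.name,
    drop_sources: bool = True,
) -> pd.DataFrame:
    """Combine the two rare prosocial behaviors into one count variable.

    With clip-level data the union is taken per clip, so a clip
    containing both behaviors contributes one occurrence.  Without it,
    counts are summed and capped at the (shared) denominator.  Both
    source behaviors must use the awake-clips denominator.
    """
    a, b = sources
    have = set(rows["behavior"])
    if a not in have or b not in have:
        raise AggregationError(f"rows must contain both {a!r} and {b!r}")
    if clips is not None:
        ca, cb = f"beh_{a}", f"beh_{b}"
        if ca not in clips.columns or cb not in clips.columns:
            raise SchemaError(f"clip table lacks {ca!r}/{cb!r}")
        union = clips[[c for c in clips.columns if not c.startswith("beh_")]].copy()
        xa, xb = clips[ca], clips[cb]
        merged = pd.array(np.zeros(len(clips), dtype=np.int8), dtype="Int8")
        merged[(xa == 1).fillna(False) | (xb == 1).fillna(False)] = 1
        uncod = ((xa == -1) | (xb == -1)).fillna(False) & ~(
            (xa == 1) | (xb == 1)
        ).fillna(False)
        merged[uncod.to_numpy(dtype=bool)] = -1
        merged[(xa.isna() & xb.isna()).to_numpy()] = pd.NA
        union[f"beh_{merged_name}"] = merged
        stratified = set(rows.loc[rows["behavior"] == a, "stratum"]) != {"pooled"}
        merged_rows = aggregate_counts(
            union,
            [RELIGIOUS_OR_VOLUNTEER],
            stratify_by_weekend=stratified,
        )
        merged_rows["behavior"] = merged_name
    else:
        ra = rows[rows["behavior"] == a].set_index(["participant_id", "stratum"])
        rb = rows[rows["behavior"] == b].set_index(["participant_id", "stratum"])
        if not ra.index.equals(rb.index):
            raise AggregationError(
                f"{a!r} and {b!r} rows are not aligned on participant/stratum"
            )
        if not (ra["n"].to_numpy() == rb["n"].to_numpy()).all():
            raise AggregationError(
                f"{a!r} and {b!r} have mismatched denominators; cannot merge"
            )
        merged_rows = ra.reset_index()[["participant_id", "stratum", "n"]]
        merged_rows["behavior"] = merged_name
        merged_rows["k"] = np.minimum(
            ra["k"].to_numpy() + rb["k"].to_numpy(), ra["n"].to_numpy()
        )
        merged_rows = merged_rows[
            ["participant_id", "behavior", "stratum", "k", "n"]
        ]
    if (merged_rows["n"] == 0).any():
        warnings.warn(
            f"{merged_name}: some merged rows have zero denominators",
            stacklevel=2,
        )
    out = rows
    if drop_sources:
        out = out[~out["behavior"].isin(sources)]
    return pd.concat([out, merged_rows], ignore_index=True)


def apply_cohort_filters(
    rows: pd.DataFrame,
    participants: pd.DataFrame,
    class_behavior: str = "class_attendance",
    sleep_behavior: str = "daytime_sleeping",
) -> pd.DataFrame:
    """Drop rows the cohort flags make uninterpretable.

    Class-attendance rows are removed for participants not enrolled in
    classes; daytime-sleeping rows for participants without early-
    morning data.  All other rows pass through unchanged.
    """
    p = participants.set_index("participant_id")
    keep = np.ones(len(rows), dtype=bool)
    pid = rows["participant_id"]
    if "enrolled_in_classes" in p.columns:
        enrolled = p["enrolled_in_classes"].reindex(pid).fillna(True).to_numpy(bool)
        keep &= ~((rows["behavior"] == class_behavior).to_numpy() & ~enrolled)
    if "sleep_data_available" in p.columns:
        ok = p["sleep_data_available"].reindex(pid).fillna(True).to_numpy(bool)
        keep &= ~((rows["behavior"] == sleep_behavior).to_numpy() & ~ok)
    return rows[keep].reset_index(drop=True)


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def write_count_table(path, rows: pd.DataFrame, participants: pd.DataFrame) -> None:
    """Write a wide count table (one row per participant[/stratum])."""
    _validate_rows(rows)
    wide = rows.pivot_table(
        index=["participant_id", "stratum"],
        columns="behavior",
        values=["k", "n"],
        aggfunc="first",
    )
    wide.columns = [f"{behavior}_{kn}" for kn, behavior in wide.columns]
    wide = wide.sort_index(axis=1).reset_index()
    stratified = set(rows["stratum"]) != {"pooled"}
    if not stratified:
        wide = wide.drop(columns="stratum")
    merged = participants.merge(wide, on="participant_id", how="right")
    merged.to_csv(path, sep=_sep_for(path), index=False)


def read_count_table(path):
    """Read a wide count table back into (participants, rows).

    Accepts pooled (no ``stratum`` column) and weekend-stratified
    layouts; unknown columns are preserved on the participant table.
    Count invariants (integer, 0 <= k <= n) are enforced on read.
    """
    df = pd.read_csv(path, sep=_sep_for(path))
    if "participant_id" not in df.columns:
        raise SchemaError("count table lacks 'participant_id'")
    count_cols = [c for c in df.columns if c.endswith(("_k", "_n"))]
    behaviors = sorted({c[:-2] for c in count_cols})
    for b in behaviors:
        for suffix in ("_k", "_n"):
            if b + suffix not in df.columns:
                raise SchemaError(f"behavior {b!r} lacks column {b + suffix!r}")
    has_stratum = "stratum" in df.columns
    id_cols = ["participant_id"] + (["stratum"] if has_stratum else [])
    part_cols = [c for c in df.columns if c not in count_cols and c != "stratum"]
    participants = (
        df[part_cols].drop_duplicates("participant_id").reset_index(drop=True)
    )
    long = df.melt(
        id_vars=id_cols,
        value_vars=count_cols,
        var_name="measure",
        value_name="value",
    )
    long["behavior"] = long["measure"].str[:-2]
    long["kn"] = long["measure"].str[-1]
    rows = long.pivot_table(
        index=id_cols + ["behavior"], columns="kn", values="value", aggfunc="first"
    ).reset_index()
    if not has_stratum:
        rows.insert(1, "stratum", "pooled")
    rows = rows.rename(columns={"k": "k", "n": "n"})
    rows = rows[["participant_id", "behavior", "stratum", "k", "n"]]
    rows = rows.dropna(subset=["k", "n"]).reset_index(drop=True)
    _validate_rows(rows)
    rows[["k", "n"]] = rows[["k", "n"]].astype(int)
    return participants, rows


def _validate_rows(rows: pd.DataFrame) -> None:
    for col in ("participant_id", "behavior", "stratum", "k", "n"):
        if col not in rows.columns:
            raise SchemaError(f"count rows lack column {col!r}")
    k = np.asarray(rows["k"], dtype=float)
    n = np.asarray(rows["n"], dtype=float)
    bad = ~np.isfinite(k) | ~np.isfinite(n) | (k < 0) | (n < 0) | (k > n)
    bad |= (k != np.round(k)) | (n != np.round(n))
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise ValidationError(
            f"invalid count row at index {idx}: k={rows['k'].iloc[idx]}, "
            f"n={rows['n'].iloc[idx]}"
        )


def write_clips(path, clips: pd.DataFrame) -> None:
    clips.to_csv(path, sep=_sep_for(path), index=False)


def read_clips(path) -> pd.DataFrame:
    clips = pd.read_csv(path, sep=_sep_for(path))
    if "timestamp" in clips.columns:
        clips["timestamp"] = pd.to_datetime(clips["timestamp"])
    for col in ("asleep", "in_social_interaction", "speaking"):
        if col in clips.columns:
            clips[col] = clips[col].map(
                {True: True, False: False, "True": True, "False": False}
            ).astype("boolean")
    for col in clips.columns:
        if col.startswith("beh_"):
            clips[col] = clips[col].astype("Int8")
    return clips
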