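"""Behavior roster for the EAR study design.

Each coded behavior carries its predicted direction of association with
slow life-history strategy, the inter-rater agreement (Cohen's kappa)
measured on the jointly coded test set, and the denominator rule that
defines in which clips the behavior could possibly have been observed
(the ``n_i`` of the aggregated binomial likelihood).  Behaviors whose
kappa fell below the preregistered 0.41 cut-off have no denominator and
are excluded by the reliability gate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional


class Denominator(str, Enum):
    """Which clips count as 'possible' for a behavior."""

    CLIPS_0600_1800 = "clips_0600_1800"
    CLIPS_AWAKE = "clips_awake"
    CLIPS_IN_SOCIAL_INTERACTION = "clips_in_social_interaction"
    WEEKDAY_0800_1700 = "weekday_0800_1700"
    CLIPS_SPEAKING = "clips_speaking"


@dataclass(frozen=True)
class BehaviorSpec:
    """Metadata for one coded behavior.

    Parameters
    ----------
    name
        Snake-case identifier used in clip and count tables.
    predicted_direction
        ``"positive"`` or ``"negative"``: the direction of the
        hypothesized association with a slower life-history strategy.
    kappa
        Inter-rater Cohen's kappa on the coder test set; ``None`` if
        never measured.
    denominator_rule
        Rule selecting the eligible clips; ``None`` for behaviors that
        failed the reliability screen and were never analyzed.
    weekday_only
        True for behaviors assumed possible only on weekdays (class
        attendance); such behaviors are never weekend-stratified and
        their models carry no weekend covariate.
    """

    name: str
    predicted_direction: str
    kappa: Optional[float]
    denominator_rule: Optional[Denominator]
    weekday_only: bool = False

    def with_kappa(self, kappa: float) -> "BehaviorSpec":
        return replace(self, kappa=kappa)


#: The 18 study-relevant coded behaviors with their measured kappas.
#: Six fall below the 0.41 gate and carry no denominator rule.
CODED_BEHAVIORS: tuple[BehaviorSpec, ...] = (
    BehaviorSpec("daytime_sleeping", "negative", 0.76, Denominator.CLIPS_0600_1800),
    BehaviorSpec("social_interaction", "positive", 0.85, Denominator.CLIPS_AWAKE),
    BehaviorSpec("multi_interlocutor", "positive", 0.76, Denominator.CLIPS_IN_SOCIAL_INTERACTION),
    BehaviorSpec("class_attendance", "positive", 0.88, Denominator.WEEKDAY_0800_1700, weekday_only=True),
    BehaviorSpec("tv_watching", "negative", 0.73, Denominator.CLIPS_AWAKE),
    BehaviorSpec("videogame_playing", "negative", 0.52, Denominator.CLIPS_AWAKE),
    BehaviorSpec("amusement_venue", "negative", 0.84, Denominator.CLIPS_AWAKE),
    BehaviorSpec("religious_service", "positive", 0.65, Denominator.CLIPS_AWAKE),
    BehaviorSpec("volunteering", "positive", 0.61, Denominator.CLIPS_AWAKE),
    BehaviorSpec("arguing", "negative", 0.49, Denominator.CLIPS_SPEAKING),
    BehaviorSpec("future_plans_talk", "positive", 0.80, Denominator.CLIPS_SPEAKING),
    BehaviorSpec("past_experiences_talk", "positive", 0.30, None),
    BehaviorSpec("alcohol_drug_talk", "negative", 0.60, Denominator.CLIPS_SPEAKING),
    BehaviorSpec("talk_about_kin", "positive", 0.39, None),
    BehaviorSpec("talk_to_kin", "positive", 0.17, None),
    BehaviorSpec("complaining", "negative", 0.39, None),
    BehaviorSpec("anti_authority_talk", "negative", 0.11, None),
    BehaviorSpec("sighing", "negative", 0.26, None),
)

#: Aggregate of the two rare prosocial behaviors, modeled as one variable.
RELIGIOUS_OR_VOLUNTEER = BehaviorSpec(
    "religious_or_volunteer", "positive", None, Denominator.CLIPS_AWAKE
)

#: Source behaviors merged into :data:`RELIGIOUS_OR_VOLUNTEER`.
MERGE_SOURCES = ("religious_service", "volunteering")


def behavior_map(behaviors=CODED_BEHAVIORS) -> dict[str, BehaviorSpec]:
    return {b.name: b for b in behaviors}


def analyzed_behaviors() -> tuple[BehaviorSpec, ...]:
    """Behaviors passing the reliability screen (denominator defined)."""
    return tuple(b for b in CODED_BEHAVIORS if b.denominator_rule is not None)
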