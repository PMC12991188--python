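"""Symptom acuity rating and automated triage disposition.

A completed session's asserted-symptom set is evaluated against a
declarative rule table; each satisfied rule contributes an acuity level,
and the disposition takes the *maximum* level (safety-first aggregation)
together with a service drawn from the maximal rule's hint or the urgency
band's default.  A history of potentially severe trauma (chemical, blunt
or high-velocity) bypasses rating entirely: the fast-path emits a same-day
emergency disposition with a first-aid notice.

Urgency bands (most to least acute): same-day emergency, within 24 h,
within 48 h, within a week / routine, pharmacist self-care.  Emergency and
urgent dispositions always route to hospital (ED/EEC) or MECS/CUES, since
urgent appointments are typically only available through those services.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml

from .errors import DefinitionError, SessionError
from .questionnaire import QuestionGraph, TriageSession

logger = logging.getLogger(__name__)

FIRST_AID_NOTICE = (
    "Eye first aid: irrigate chemical splashes immediately with copious "
    "water for at least 15 minutes, do not patch penetrating injuries, and "
    "attend emergency eye services without delay."
)


class AcuityLevel(enum.IntEnum):
    """Ordinal urgency, larger = more acute."""

    SELF_CARE = 0
    ROUTINE_WEEK = 1
    SOON_48H = 2
    URGENT_24H = 3
    EMERGENCY_SAME_DAY = 4

    @property
    def is_urgent_24h(self) -> bool:
        """True for the two most acute bands (the study's dichotomization)."""
        return self >= AcuityLevel.URGENT_24H


class Service(enum.Enum):
    ED_EEC = "ED_EEC"
    MECS_CUES = "MECS_CUES"
    COMMUNITY_OPTOMETRY = "COMMUNITY_OPTOMETRY"
    PHARMACIST = "PHARMACIST"


# fixed tie-break precedence for conflicting service hints at equal level
SERVICE_PRECEDENCE = (
    Service.ED_EEC,
    Service.MECS_CUES,
    Service.COMMUNITY_OPTOMETRY,
    Service.PHARMACIST,
)

# default service per urgency band when the maximal rule has no hint
_BAND_DEFAULT_SERVICE = {
    AcuityLevel.EMERGENCY_SAME_DAY: Service.ED_EEC,
    AcuityLevel.URGENT_24H: Service.MECS_CUES,
    AcuityLevel.SOON_48H: Service.COMMUNITY_OPTOMETRY,
    AcuityLevel.ROUTINE_WEEK: Service.COMMUNITY_OPTOMETRY,
    AcuityLevel.SELF_CARE: Service.PHARMACIST,
}


@dataclass(frozen=True)
class AcuityRule:
    """One row of the acuity table.

    The trigger is a monotone predicate over the asserted-symptom set:
    ``all_of`` codes must all be present, and at least one ``any_of`` code
    must be present when ``any_of`` is non-empty.
    """

    rule_id: str
    all_of: frozenset[str] = frozenset()
    any_of: frozenset[str] = frozenset()
    level: AcuityLevel = AcuityLevel.SELF_CARE
    service_hint: Optional[Service] = None
    emergency_class: bool = False

    def triggered_by(self, symptoms: frozenset[str]) -> bool:
        if not self.all_of <= symptoms:
            return False
        if self.any_of and not self.any_of & symptoms:
            return False
        return True

    @property
    def codes(self) -> frozenset[str]:
        return self.all_of | self.any_of


@dataclass(frozen=True)
class AcuityTable:
    version: str
    vocabulary: frozenset[str]
    rules: tuple[AcuityRule, ...]

    def rule(self, rule_id: str) -> AcuityRule:
        for r in self.rules:
            if r.rule_id == rule_id:
                return r
        raise KeyError(rule_id)


@dataclass(frozen=True)
class Disposition:
    """The automated triage output: a (service, urgency) recommendation."""

    service: Service
    urgency: AcuityLevel
    triggered_rules: tuple[str, ...] = ()
    fast_path: bool = False
    patient_notice: Optional[str] = None
    order_reference: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "order_reference": self.order_reference,
            "service": self.service.value,
            "urgency": self.urgency.name,
            "triggered_rules": list(self.triggered_rules),
            "fast_path": self.fast_path,
            "patient_notice": self.patient_notice,
        }


def load_acuity_table(source: str | Path | Mapping) -> AcuityTable:
    """Load and validate an acuity rule table (YAML/JSON file or dict).

    Enforces: known combinators only; rule codes drawn from the declared
    vocabulary; every vocabulary code covered by at least one rule; every
    emergency-class rule pinned at same-day emergency level with ED/EEC
    service.  Violations raise :class:`DefinitionError` naming the element.
    """
    if isinstance(source, (str, Path)):
        doc = yaml.safe_load(Path(source).read_text())
    else:
        doc = dict(source)

    for key in ("version", "vocabulary", "rules"):
        if key not in doc:
            raise DefinitionError(f"acuity table missing top-level key {key!r}")
    vocabulary = frozenset(doc["vocabulary"])

    rules: list[AcuityRule] = []
    seen: set[str] = set()
    for rdoc in doc["rules"]:
        rid = str(rdoc["id"])
        if rid in seen:
            raise DefinitionError(f"duplicate rule id {rid!r}")
        seen.add(rid)
        trigger = rdoc.get("trigger", {})
        unknown_comb = set(trigger) - {"all_of", "any_of"}
        if unknown_comb:
            raise DefinitionError(
                f"rule {rid!r}: unknown trigger combinator(s) "
                f"{sorted(unknown_comb)}"
            )
        all_of = frozenset(trigger.get("all_of", []))
        any_of = frozenset(trigger.get("any_of", []))
        if not (all_of or any_of):
            raise DefinitionError(f"rule {rid!r}: empty trigger")
        bad = (all_of | any_of) - vocabulary
        if bad:
            raise DefinitionError(
                f"rule {rid!r}: unknown symptom code(s) {sorted(bad)}"
            )
        try:
            level = AcuityLevel[str(rdoc["level"])]
        except KeyError:
            raise DefinitionError(
                f"rule {rid!r}: unknown acuity level {rdoc.get('level')!r}"
            ) from None
        hint = rdoc.get("service_hint")
        service_hint = Service[str(hint)] if hint is not None else None
        emergency = bool(rdoc.get("emergency_class", False))
        if emergency and (
            level is not AcuityLevel.EMERGENCY_SAME_DAY
            or service_hint is not Service.ED_EEC
        ):
            raise DefinitionError(
                f"rule {rid!r}: emergency-class rules must carry "
                "EMERGENCY_SAME_DAY level and ED_EEC service"
            )
        rules.append(
            AcuityRule(
                rule_id=rid, all_of=all_of, any_of=any_of, level=level,
                service_hint=service_hint, emergency_class=emergency,
            )
        )

    covered = frozenset().union(*(r.codes for r in rules)) if rules else frozenset()
    uncovered = vocabulary - covered
    if uncovered:
        raise DefinitionError(
            f"vocabulary code(s) covered by no rule: {sorted(uncovered)}"
        )

    return AcuityTable(
        version=str(doc["version"]), vocabulary=vocabulary, rules=tuple(rules)
    )


def check_vocabulary_alignment(graph: QuestionGraph, table: AcuityTable) -> None:
    """Every symptom code the questionnaire can assert must be rateable."""
    asserted = frozenset().union(
        *(opt.symptom_codes
          for q in graph.questions.values() for opt in q.options),
        frozenset(),
    )
    missing = asserted - table.vocabulary
    if missing:
        raise DefinitionError(
            f"questionnaire asserts code(s) absent from the acuity table "
            f"vocabulary: {sorted(missing)}"
        )


def trauma_fast_path(
    session: TriageSession, graph: QuestionGraph
) -> Optional[Disposition]:
    """Same-day emergency routing on any potentially severe trauma history.

    Returns the fast-path disposition (with a first-aid patient notice) if
    any chosen option carries a chemical, blunt or high-velocity trauma
    flag; otherwise ``None``.
    """
    for option in session.chosen_options(graph):
        if option.is_trauma:
            return Disposition(
                service=Service.ED_EEC,
                urgency=AcuityLevel.EMERGENCY_SAME_DAY,
                triggered_rules=(),
                fast_path=True,
                patient_notice=FIRST_AID_NOTICE,
                order_reference=session.order_reference,
            )
    return None


def rate_acuity(
    session: TriageSession, graph: QuestionGraph, table: AcuityTable
) -> list[tuple[str, AcuityLevel]]:
    """Every rule satisfied by the session's asserted symptoms, once each."""
    if not session.at_terminal:
        raise SessionError("cannot rate acuity: session not at TERMINAL")
    symptoms = session.asserted_symptoms(graph)
    return [
        (rule.rule_id, rule.level)
        for rule in table.rules
        if rule.triggered_by(symptoms)
    ]


def assign_disposition(
    ratings: Sequence[tuple[str, AcuityLevel]],
    session: TriageSession,
    graph: QuestionGraph,
    table: AcuityTable,
) -> Disposition:
    """Aggregate ratings into the automated (service, urgency) disposition.

    Trauma fast-path takes precedence.  Otherwise urgency is the maximum
    triggered level (SELF_CARE when nothing fires); the service comes from
    the maximal rule's hint, ties broken by the fixed precedence
    ED/EEC > MECS/CUES > community optometry > pharmacist (logged), and
    hint-less bands fall back to the band default.
    """
    fast = trauma_fast_path(session, graph)
    if fast is not None:
        return fast

    if not ratings:
        return Disposition(
            service=Service.PHARMACIST,
            urgency=AcuityLevel.SELF_CARE,
            order_reference=session.order_reference,
        )

    urgency = max(level for _, level in ratings)
    maximal = [rid for rid, level in ratings if level == urgency]
    hints = {
        table.rule(rid).service_hint
        for rid in maximal
        if table.rule(rid).service_hint is not None
    }
    if not hints:
        service = _BAND_DEFAULT_SERVICE[urgency]
    elif len(hints) == 1:
        service = next(iter(hints))
    else:
        service = min(hints, key=SERVICE_PRECEDENCE.index)
        logger.info(
            "conflicting service hints %s at level %s resolved to %s by "
            "fixed precedence",
            sorted(h.value for h in hints), urgency.name, service.value,
        )
    # urgent bands only route to services that can deliver urgent slots
    if urgency.is_urgent_24h and service not in (Service.ED_EEC, Service.MECS_CUES):
        service = _BAND_DEFAULT_SERVICE[urgency]

    return Disposition(
        service=service,
        urgency=urgency,
        triggered_rules=tuple(rid for rid, _ in ratings),
        fast_path=False,
        order_reference=session.order_reference,
    )


def triage(
    session: TriageSession, graph: QuestionGraph, table: AcuityTable
) -> Disposition:
    """Convenience: rate a completed session and assign its disposition."""
    ratings = rate_acuity(session, graph, table)
    return assign_disposition(ratings, session, graph, table)


def default_table_path() -> Path:
    return Path(__file__).parent / "data" / "default_acuity_table.yaml"


def load_default_table() -> AcuityTable:
    return load_acuity_table(default_table_path())
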