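"""Symptom report generation and study-table I/O.

The symptom report is the clinician-facing artifact of a completed triage
session: the transcript grouped by topic, the asserted symptom codes and
triggered rules, and — unless masked — the automated (service, urgency)
disposition.  Masking removes exactly the disposition fields and nothing
else, so reviewers establishing a gold standard are not biased by the
tool's suggestion while still seeing every symptom.

Study tables are plain CSV: one row per patient linking the date, a
pseudonym, the unique order reference and the optometry triage outcome.
Rows failing validation are collected into an exclusion report rather than
silently dropped, mirroring how incomplete outcome records are excluded
from analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .acuity import AcuityLevel, Disposition, Service
from .errors import TableIOError, TriageError
from .questionnaire import (
    QuestionGraph,
    TriageSession,
    session_duration,
)

STUDY_TABLE_COLUMNS = (
    "date", "pseudonym", "order_reference",
    "optometry_service", "optometry_urgency",
)

_URGENCY_WORDS = {level.name for level in AcuityLevel}
_SERVICE_WORDS = {service.value for service in Service}


@dataclass(frozen=True)
class FeedbackRecord:
    """A voluntary 5-point pictorial Likert rating (1 least, 5 most favorable)."""

    order_reference: str
    likert: Optional[int] = None

    def __post_init__(self) -> None:
        if self.likert is not None and not 1 <= self.likert <= 5:
            raise TriageError(
                f"likert rating must be in 1..5, got {self.likert}"
            )


@dataclass(frozen=True)
class StudyRow:
    date: date
    pseudonym: str
    order_reference: str
    optometry_service: Service
    optometry_urgency: AcuityLevel


def generate_report(
    session: TriageSession,
    disposition: Disposition,
    graph: QuestionGraph,
    mask: bool = False,
) -> dict:
    """Build the canonical JSON-able symptom report.

    A pure function of (session, disposition, mask): the same inputs always
    produce an identical report, and ``mask=True`` removes only the
    disposition block.
    """
    if (
        disposition.order_reference is not None
        and disposition.order_reference != session.order_reference
    ):
        raise TriageError(
            f"order reference mismatch: session "
            f"{session.order_reference!r} vs disposition "
            f"{disposition.order_reference!r}"
        )
    transcript = []
    for qid in session.answer_order:
        question = graph.question(qid)
        chosen = session.answers[qid]
        transcript.append({
            "question": qid,
            "text": question.text,
            "answers": [question.option(o).label for o in chosen],
        })
    report = {
        "order_reference": session.order_reference,
        "age": session.age,
        "complaint_category": (
            session.answers.get(graph.entry, ("",))[0]
        ),
        "laterality": session.laterality,
        "mode": session.mode,
        "duration_seconds": session_duration(session),
        "transcript": transcript,
        "asserted_symptoms": sorted(session.asserted_symptoms(graph)),
        "triggered_rules": list(disposition.triggered_rules),
        "free_text": session.free_text,
        "masked": mask,
    }
    if not mask:
        report["disposition"] = {
            "service": disposition.service.value,
            "urgency": disposition.urgency.name,
            "fast_path": disposition.fast_path,
            "patient_notice": disposition.patient_notice,
        }
    return report


def render_report(report: Mapping) -> str:
    """Stable plain-text rendering with a fixed section order."""
    lines = [
        "SYMPTOM REPORT",
        "==============",
        f"Order reference : {report['order_reference']}",
        f"Age             : {report['age']}",
        f"Complaint       : {report['complaint_category']}",
        f"Laterality      : {report['laterality']}",
        f"Completion mode : {report['mode']}",
        f"Duration        : {report['duration_seconds']:.0f} s",
        "",
        "Answers",
        "-------",
    ]
    for item in report["transcript"]:
        lines.append(f"Q: {item['text']}")
        for answer in item["answers"]:
            lines.append(f"   - {answer}")
    lines += ["", "Symptoms asserted", "-----------------"]
    if report["asserted_symptoms"]:
        lines += [f"   - {code}" for code in report["asserted_symptoms"]]
    else:
        lines.append("   No red-flag symptoms asserted.")
    if report.get("free_text"):
        lines += ["", "Patient comments", "----------------",
                  f"   {report['free_text']}"]
    if not report["masked"]:
        dispo = report["disposition"]
        lines += [
            "",
            "Automated triage disposition",
            "----------------------------",
            f"Service : {dispo['service']}",
            f"Urgency : {dispo['urgency']}",
        ]
        if dispo.get("patient_notice"):
            lines.append(f"Notice  : {dispo['patient_notice']}")
    else:
        lines += ["", "[Automated disposition withheld for masked review]"]
    return "\n".join(lines) + "\n"


def write_report(report: Mapping, out_dir: str | Path) -> Path:
    """Deliver a report to an outbox directory (JSON + rendered text)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = report["order_reference"]
    (out / f"{stem}.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (out / f"{stem}.txt").write_text(render_report(report))
    return out / f"{stem}.json"


# ---------------------------------------------------------------------------
# study table CSV

def write_study_table(rows: Sequence[StudyRow], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "date": row.date.isoformat(),
                "pseudonym": row.pseudonym,
                "order_reference": row.order_reference,
                "optometry_service": row.optometry_service.value,
                "optometry_urgency": row.optometry_urgency.name,
            }
            for row in rows
        ],
        columns=list(STUDY_TABLE_COLUMNS),
    )
    frame.to_csv(path, index=False)


def read_study_table(
    path: str | Path, *, strict: bool = True
) -> tuple[list[StudyRow], list[dict]]:
    """Parse a study CSV into rows plus an exclusion report.

    Rows with malformed dates, unknown outcome vocabulary, blank fields or
    duplicate order references are listed (with 1-based row numbers and a
    reason) in the exclusion report.  With ``strict=True`` any exclusion
    raises :class:`TableIOError` carrying the same detail.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(STUDY_TABLE_COLUMNS) - set(frame.columns)
    if missing:
        raise TableIOError(
            f"study table missing column(s): {sorted(missing)}"
        )
    rows: list[StudyRow] = []
    excluded: list[dict] = []
    seen_refs: set[str] = set()
    for idx, rec in frame.iterrows():
        row_no = int(idx) + 2  # 1-based, counting the header line
        problems: list[str] = []
        try:
            row_date = date.fromisoformat(rec["date"])
        except ValueError:
            problems.append(f"malformed date {rec['date']!r}")
            row_date = None
        ref = rec["order_reference"].strip()
        if not ref:
            problems.append("blank order_reference")
        elif ref in seen_refs:
            problems.append(f"duplicate order_reference {ref!r}")
        service = urgency = None
        if rec["optometry_service"] in _SERVICE_WORDS:
            service = Service(rec["optometry_service"])
        else:
            problems.append(
                f"unknown optometry_service {rec['optometry_service']!r}"
            )
        if rec["optometry_urgency"] in _URGENCY_WORDS:
            urgency = AcuityLevel[rec["optometry_urgency"]]
        else:
            problems.append(
                f"unknown optometry_urgency {rec['optometry_urgency']!r}"
            )
        if problems:
            excluded.append({"row": row_no, "reasons": problems,
                             "order_reference": ref or None})
            continue
        seen_refs.add(ref)
        rows.append(StudyRow(
            date=row_date, pseudonym=rec["pseudonym"],
            order_reference=ref,
            optometry_service=service, optometry_urgency=urgency,
        ))
    if excluded and strict:
        detail = "; ".join(
            f"row {e['row']}: {', '.join(e['reasons'])}" for e in excluded
        )
        raise TableIOError(f"study table rejected {len(excluded)} row(s): {detail}")
    return rows, excluded


def write_feedback_table(records: Sequence[FeedbackRecord],
                         path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {"order_reference": r.order_reference,
             "likert": "" if r.likert is None else r.likert}
            for r in records
        ],
        columns=["order_reference", "likert"],
    )
    frame.to_csv(path, index=False)


def read_feedback_table(path: str | Path) -> list[FeedbackRecord]:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    records = []
    for _, rec in frame.iterrows():
        raw = rec["likert"].strip()
        records.append(FeedbackRecord(
            order_reference=rec["order_reference"],
            likert=int(raw) if raw else None,
        ))
    return records
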