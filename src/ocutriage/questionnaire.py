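"""Conditional-logic questionnaire engine.

A questionnaire is a directed acyclic graph of multiple-choice questions.
Each answer option may assert controlled-vocabulary symptom codes and/or a
trauma mechanism flag; routing between questions is decided by ordered
conditional edges evaluated against the answers recorded so far.  A patient
session walks the graph from the entry complaint-filter question to a
TERMINAL state in at most ``MAX_PATH_QUESTIONS`` steps, accumulating an
asserted-symptom set that the acuity module later rates.

The engine is content-agnostic: question wording, branching and symptom
vocabulary all live in a YAML/JSON definition document loaded by
:func:`load_graph`.  A representative default questionnaire is shipped in
``ocutriage/data/default_questionnaire.yaml``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence

import yaml

from .errors import (
    ConsentError,
    DefinitionError,
    EligibilityError,
    SessionError,
)

TERMINAL = "TERMINAL"
MAX_PATH_QUESTIONS = 25
MIN_AGE_YEARS = 13

TRAUMA_FLAGS = ("chemical", "blunt", "high_velocity", "none")


@dataclass(frozen=True)
class AnswerOption:
    """One selectable answer: display label plus the symptom codes it asserts."""

    option_id: str
    label: str
    symptom_codes: frozenset[str] = frozenset()
    trauma_flag: str = "none"

    def __post_init__(self) -> None:
        if self.trauma_flag not in TRAUMA_FLAGS:
            raise DefinitionError(
                f"option {self.option_id!r}: unknown trauma_flag {self.trauma_flag!r}"
            )

    @property
    def is_trauma(self) -> bool:
        return self.trauma_flag != "none"


@dataclass(frozen=True)
class Question:
    question_id: str
    text: str
    options: tuple[AnswerOption, ...]
    select_mode: str = "single"  # single | multiple

    def __post_init__(self) -> None:
        if self.select_mode not in ("single", "multiple"):
            raise DefinitionError(
                f"question {self.question_id!r}: select_mode must be "
                f"'single' or 'multiple', got {self.select_mode!r}"
            )
        if len(self.options) < 2:
            raise DefinitionError(
                f"question {self.question_id!r}: needs at least 2 options, "
                f"has {len(self.options)}"
            )
        seen: set[str] = set()
        for opt in self.options:
            if opt.option_id in seen:
                raise DefinitionError(
                    f"question {self.question_id!r}: duplicate option id "
                    f"{opt.option_id!r}"
                )
            seen.add(opt.option_id)

    def option(self, option_id: str) -> AnswerOption:
        for opt in self.options:
            if opt.option_id == option_id:
                return opt
        raise SessionError(
            f"question {self.question_id!r} has no option {option_id!r}"
        )


@dataclass(frozen=True)
class ConditionalEdge:
    """Routing rule: if the predicate holds on the transcript, go to ``to``.

    The predicate, when present, is (question_id, any_of option ids): true
    iff that already-answered question's chosen options intersect ``any_of``.
    An edge without a predicate is a default edge and always matches.
    Edges from a question are tried in declaration order; first match wins.
    """

    from_question: str
    to: str  # question_id or TERMINAL
    when_question: Optional[str] = None
    when_any_of: frozenset[str] = frozenset()

    @property
    def is_default(self) -> bool:
        return self.when_question is None

    def matches(self, answers: Mapping[str, tuple[str, ...]]) -> bool:
        if self.is_default:
            return True
        chosen = answers.get(self.when_question, ())
        return bool(self.when_any_of.intersection(chosen))


@dataclass(frozen=True)
class QuestionGraph:
    """A validated conditional-logic questionnaire."""

    version: str
    vocabulary: frozenset[str]
    entry: str
    questions: Mapping[str, Question]
    edges: Mapping[str, tuple[ConditionalEdge, ...]]

    def question(self, question_id: str) -> Question:
        try:
            return self.questions[question_id]
        except KeyError:
            raise SessionError(f"unknown question {question_id!r}") from None

    def successor(self, question_id: str,
                  answers: Mapping[str, tuple[str, ...]]) -> str:
        """First edge (declaration order) whose predicate holds decides."""
        for edge in self.edges.get(question_id, ()):
            if edge.matches(answers):
                return edge.to
        raise DefinitionError(
            f"question {question_id!r}: no edge matches and no default edge "
            "declared"
        )

    def longest_path_questions(self) -> int:
        """Number of questions on the longest entry→TERMINAL path.

        Computed over the edge structure (predicates ignored), so it upper-
        bounds the number of questions any traversal can ask.
        """
        memo: dict[str, int] = {}

        def depth(node: str) -> int:
            if node == TERMINAL:
                return 0
            if node in memo:
                return memo[node]
            memo[node] = 1 + max(
                (depth(e.to) for e in self.edges.get(node, ())), default=0
            )
            return memo[node]

        return depth(self.entry)


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise DefinitionError(message)


def load_graph(source: str | Path | Mapping) -> QuestionGraph:
    """Load and validate a questionnaire definition (YAML/JSON file or dict).

    Validation enforces: schema shape; vocabulary-closed symptom codes;
    ≥2 options per question; acyclicity; every question reachable from the
    entry; every path reaching TERMINAL within 25 questions; a default edge
    on every question.  Violations raise :class:`DefinitionError` naming the
    offending element.
    """
    if isinstance(source, (str, Path)):
        doc = yaml.safe_load(Path(source).read_text())
    else:
        doc = dict(source)

    _require(isinstance(doc, Mapping), "definition document must be a mapping")
    for key in ("version", "vocabulary", "questions", "edges"):
        _require(key in doc, f"definition missing top-level key {key!r}")

    vocabulary = frozenset(doc["vocabulary"])
    _require(bool(vocabulary), "vocabulary must be non-empty")

    questions: dict[str, Question] = {}
    order: list[str] = []
    for qdoc in doc["questions"]:
        _require(
            isinstance(qdoc, Mapping) and "id" in qdoc,
            "each question needs an 'id'",
        )
        qid = str(qdoc["id"])
        _require(qid not in questions, f"duplicate question id {qid!r}")
        options = []
        for odoc in qdoc.get("options", []):
            codes = frozenset(odoc.get("symptom_codes", []))
            unknown = codes - vocabulary
            _require(
                not unknown,
                f"question {qid!r} option {odoc.get('id')!r}: unknown symptom "
                f"code(s) {sorted(unknown)}",
            )
            options.append(
                AnswerOption(
                    option_id=str(odoc["id"]),
                    label=str(odoc.get("label", odoc["id"])),
                    symptom_codes=codes,
                    trauma_flag=str(odoc.get("trauma_flag", "none")),
                )
            )
        questions[qid] = Question(
            question_id=qid,
            text=str(qdoc.get("text", qid)),
            options=tuple(options),
            select_mode=str(qdoc.get("select_mode", "single")),
        )
        order.append(qid)

    entry = str(doc.get("entry", order[0] if order else ""))
    _require(entry in questions, f"entry question {entry!r} not defined")

    edges: dict[str, list[ConditionalEdge]] = {qid: [] for qid in questions}
    for edoc in doc["edges"]:
        frm = str(edoc["from"])
        _require(frm in questions, f"edge from unknown question {frm!r}")
        to = str(edoc["to"])
        _require(
            to == TERMINAL or to in questions,
            f"edge from {frm!r} to unknown question {to!r}",
        )
        when = edoc.get("when")
        if when is None:
            edge = ConditionalEdge(from_question=frm, to=to)
        else:
            wq = str(when["question"])
            _require(
                wq in questions,
                f"edge from {frm!r}: predicate references unknown question {wq!r}",
            )
            edge = ConditionalEdge(
                from_question=frm,
                to=to,
                when_question=wq,
                when_any_of=frozenset(str(o) for o in when["any_of"]),
            )
        edges[frm].append(edge)

    for qid in questions:
        _require(
            edges[qid] and edges[qid][-1].is_default,
            f"question {qid!r}: a default (unconditional) edge must be "
            "declared last",
        )

    graph = QuestionGraph(
        version=str(doc["version"]),
        vocabulary=vocabulary,
        entry=entry,
        questions=questions,
        edges={qid: tuple(es) for qid, es in edges.items()},
    )
    _validate_structure(graph)
    return graph


def _validate_structure(graph: QuestionGraph) -> None:
    # Cycle check + longest-path cap via DFS with an explicit path stack,
    # and reachability from the entry — all over the raw edge structure.
    # Predicates only restrict which edges fire, so this bounds every
    # possible traversal.
    reachable: set[str] = set()
    on_stack: list[str] = []

    def visit(node: str) -> int:
        """Return longest question-count from node to TERMINAL."""
        if node == TERMINAL:
            return 0
        if node in on_stack:
            cycle = on_stack[on_stack.index(node):] + [node]
            raise DefinitionError(f"cycle detected: {' -> '.join(cycle)}")
        reachable.add(node)
        on_stack.append(node)
        try:
            best = 0
            for edge in graph.edges.get(node, ()):
                best = max(best, visit(edge.to))
            return 1 + best
        finally:
            on_stack.pop()

    longest = visit(graph.entry)
    if longest > MAX_PATH_QUESTIONS:
        raise DefinitionError(
            f"longest path from entry asks {longest} questions, exceeding the "
            f"cap of {MAX_PATH_QUESTIONS} (path reachable from "
            f"{graph.entry!r})"
        )
    unreachable = set(graph.questions) - reachable
    if unreachable:
        raise DefinitionError(
            f"unreachable question(s): {sorted(unreachable)}"
        )

    # predicates must only reference questions, and terminal-reachability is
    # implied by the mandatory default edges + acyclicity (every maximal
    # path ends at TERMINAL because every question has an out-edge).


@dataclass
class TriageSession:
    """One patient's passage through the questionnaire.

    The transcript is append-only and ordered; ``record_answer`` enforces
    that answers follow graph traversal order.  Timestamps are supplied by
    the caller (clock injection) so duration arithmetic is testable.
    """

    order_reference: str
    age: int
    consent: bool
    mode: str  # online | telephone
    graph_version: str
    started_at: datetime
    finished_at: Optional[datetime] = None
    answers: dict[str, tuple[str, ...]] = field(default_factory=dict)
    answer_order: list[str] = field(default_factory=list)
    laterality: str = "unknown"  # left | right | both | unknown
    free_text: Optional[str] = None
    _position: str = ""  # pending question id, or TERMINAL

    @property
    def finished(self) -> bool:
        return self.finished_at is not None

    @property
    def at_terminal(self) -> bool:
        return self._position == TERMINAL

    def asserted_symptoms(self, graph: QuestionGraph) -> frozenset[str]:
        """Union of symptom codes across all chosen options."""
        codes: set[str] = set()
        for qid, chosen in self.answers.items():
            question = graph.question(qid)
            for oid in chosen:
                codes |= question.option(oid).symptom_codes
        return frozenset(codes)

    def chosen_options(self, graph: QuestionGraph) -> list[AnswerOption]:
        return [
            graph.question(qid).option(oid)
            for qid in self.answer_order
            for oid in self.answers[qid]
        ]


_session_counter = 0


def _default_order_reference() -> str:
    global _session_counter
    _session_counter += 1
    return f"OCU-{_session_counter:06d}"


def start_session(
    graph: QuestionGraph,
    age: int,
    consent: bool,
    mode: str = "online",
    *,
    order_reference: Optional[str] = None,
    started_at: Optional[datetime] = None,
    laterality: str = "unknown",
) -> TriageSession:
    """Open a session positioned at the entry filter question.

    Raises :class:`EligibilityError` below the age floor of 13 years and
    :class:`ConsentError` when consent is declined — in both cases no
    session object is created.
    """
    if age < MIN_AGE_YEARS:
        raise EligibilityError(
            f"age {age} below eligibility floor of {MIN_AGE_YEARS} years"
        )
    if not consent:
        raise ConsentError("data-use consent declined; session not created")
    if mode not in ("online", "telephone"):
        raise SessionError(f"unknown completion mode {mode!r}")
    if laterality not in ("left", "right", "both", "unknown"):
        raise SessionError(f"unknown laterality {laterality!r}")
    return TriageSession(
        order_reference=order_reference or _default_order_reference(),
        age=age,
        consent=consent,
        mode=mode,
        graph_version=graph.version,
        started_at=started_at or datetime.now(timezone.utc),
        _position=graph.entry,
    )


def next_question(session: TriageSession, graph: QuestionGraph):
    """Return the pending :class:`Question`, or ``TERMINAL`` when done.

    Deterministic: routing is fixed by the transcript and the graph version.
    """
    if session.graph_version != graph.version:
        raise SessionError(
            f"session was opened on graph version {session.graph_version!r}, "
            f"not {graph.version!r}"
        )
    if session._position == TERMINAL:
        return TERMINAL
    return graph.question(session._position)


def record_answer(
    session: TriageSession,
    graph: QuestionGraph,
    question_id: str,
    option_ids: Sequence[str],
) -> TriageSession:
    """Append an answer for the currently pending question and advance.

    Enforces in-order answering (transcripts are append-only), option
    validity and select-mode cardinality.
    """
    pending = next_question(session, graph)
    if pending == TERMINAL:
        raise SessionError("session already at TERMINAL; no question pending")
    if question_id != pending.question_id:
        raise SessionError(
            f"out-of-order answer: pending question is "
            f"{pending.question_id!r}, got {question_id!r}"
        )
    chosen = tuple(dict.fromkeys(str(o) for o in option_ids))
    if not chosen:
        raise SessionError(f"question {question_id!r}: no option chosen")
    if pending.select_mode == "single" and len(chosen) > 1:
        raise SessionError(
            f"question {question_id!r} is single-select; got "
            f"{len(chosen)} options"
        )
    for oid in chosen:
        pending.option(oid)  # raises on unknown option
    session.answers[question_id] = chosen
    session.answer_order.append(question_id)
    session._position = graph.successor(question_id, session.answers)
    return session


def finish_session(
    session: TriageSession,
    graph: QuestionGraph,
    finished_at: Optional[datetime] = None,
) -> TriageSession:
    """Close a session that has reached TERMINAL."""
    if not session.at_terminal:
        raise SessionError("cannot finish: session has not reached TERMINAL")
    ts = finished_at or datetime.now(timezone.utc)
    if ts < session.started_at:
        raise SessionError("finished_at precedes started_at")
    session.finished_at = ts
    return session


def session_duration(session: TriageSession) -> float:
    """Completion time in seconds (finished − started)."""
    if not session.finished:
        raise SessionError("session not finished; duration undefined")
    return (session.finished_at - session.started_at).total_seconds()


def run_script(
    graph: QuestionGraph,
    script: Sequence[tuple[str, Sequence[str]]],
    *,
    age: int = 40,
    consent: bool = True,
    mode: str = "online",
    order_reference: Optional[str] = None,
    started_at: Optional[datetime] = None,
    finished_at: Optional[datetime] = None,
) -> TriageSession:
    """Execute a (question_id, option_ids) answer script to TERMINAL."""
    session = start_session(
        graph, age, consent, mode,
        order_reference=order_reference, started_at=started_at,
    )
    for question_id, option_ids in script:
        record_answer(session, graph, question_id, option_ids)
    if not session.at_terminal:
        raise SessionError("answer script ended before TERMINAL")
    return finish_session(session, graph, finished_at or session.started_at)


# ---------------------------------------------------------------------------
# transcript serialization (lossless JSON round-trip)

def session_to_dict(session: TriageSession) -> dict:
    return {
        "order_reference": session.order_reference,
        "age": session.age,
        "consent": session.consent,
        "mode": session.mode,
        "graph_version": session.graph_version,
        "started_at": session.started_at.isoformat(),
        "finished_at": session.finished_at.isoformat()
        if session.finished_at else None,
        "answers": [
            {"question": qid, "options": list(session.answers[qid])}
            for qid in session.answer_order
        ],
        "laterality": session.laterality,
        "free_text": session.free_text,
        "position": session._position,
    }


def session_from_dict(doc: Mapping) -> TriageSession:
    answers = {a["question"]: tuple(a["options"]) for a in doc["answers"]}
    return TriageSession(
        order_reference=doc["order_reference"],
        age=int(doc["age"]),
        consent=bool(doc["consent"]),
        mode=doc["mode"],
        graph_version=doc["graph_version"],
        started_at=datetime.fromisoformat(doc["started_at"]),
        finished_at=datetime.fromisoformat(doc["finished_at"])
        if doc.get("finished_at") else None,
        answers=answers,
        answer_order=[a["question"] for a in doc["answers"]],
        laterality=doc.get("laterality", "unknown"),
        free_text=doc.get("free_text"),
        _position=doc.get("position", TERMINAL),
    )


def save_session(session: TriageSession, path: str | Path) -> None:
    Path(path).write_text(json.dumps(session_to_dict(session), indent=2))


def load_session(path: str | Path) -> TriageSession:
    return session_from_dict(json.loads(Path(path).read_text()))


def default_graph_path() -> Path:
    return Path(__file__).parent / "data" / "default_questionnaire.yaml"


def load_default_graph() -> QuestionGraph:
    return load_graph(default_graph_path())
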