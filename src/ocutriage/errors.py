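"""Exception hierarchy for the triage engine and its evaluation layer."""


class TriageError(Exception):
    """Base class for all errors raised by this package."""


class DefinitionError(TriageError):
    """A questionnaire or acuity-table definition document is invalid.

    The message always names the offending element (question id, rule id,
    symptom code or path) so a configuration author can fix it.
    """


class SessionError(TriageError):
    """A session operation violated the traversal protocol."""


class EligibilityError(SessionError):
    """Patient does not meet the age-eligibility floor (13 years)."""


class ConsentError(SessionError):
    """Patient declined the data-use consent gate; no session is created."""


class EvaluationError(TriageError):
    """An accuracy/agreement computation received inadmissible input."""


class UndefinedMetricError(EvaluationError):
    """A rate's denominator class is empty (e.g. no gold-positive cases)."""


class TableIOError(TriageError):
    """A study table or record file failed validation on read/write."""
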