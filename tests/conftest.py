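import pytest

from ocutriage import (
    load_archetypes,
    load_default_graph,
    load_default_table,
)


@pytest.fixture(scope="session")
def graph():
    return load_default_graph()


@pytest.fixture(scope="session")
def table():
    return load_default_table()


@pytest.fixture(scope="session")
def pool(graph, table):
    return load_archetypes(graph, table)


def minimal_graph_doc():
    """A tiny two-question questionnaire definition for loader tests."""
    return {
        "version": "t1",
        "vocabulary": ["code_a", "code_b"],
        "entry": "q1",
        "questions": [
            {
                "id": "q1",
                "text": "first",
                "options": [
                    {"id": "a", "symptom_codes": ["code_a"]},
                    {"id": "b"},
                ],
            },
            {
                "id": "q2",
                "text": "second",
                "options": [
                    {"id": "x", "symptom_codes": ["code_b"]},
                    {"id": "y"},
                ],
            },
        ],
        "edges": [
            {"from": "q1", "to": "q2",
             "when": {"question": "q1", "any_of": ["a"]}},
            {"from": "q1", "to": "TERMINAL"},
            {"from": "q2", "to": "TERMINAL"},
        ],
    }
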