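import pytest

from geccolink import (
    annotate_response,
    generate_responses,
    mini_gecco,
    render_questionnaire,
)

CORPUS_SEED = 1234
CORPUS_SIZE = 200  # 100 subjects x 2 responses


@pytest.fixture(scope="session")
def model():
    return mini_gecco()


@pytest.fixture(scope="session")
def questionnaire(model):
    return render_questionnaire(model)


@pytest.fixture(scope="session")
def corpus(questionnaire):
    """200 seeded random responses (not annotated)."""
    return generate_responses(questionnaire, 100, 2, CORPUS_SEED)


@pytest.fixture(scope="session")
def annotated_corpus(corpus, questionnaire):
    return [annotate_response(r, questionnaire) for r in corpus]
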