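import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from promptgauge import (
    EvalItem,
    FewShotExample,
    HashedNgramEmbedder,
    MockGenerator,
    UnigramCorpusScorer,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def generator():
    return MockGenerator()


@pytest.fixture(scope="session")
def scorer():
    return UnigramCorpusScorer()


@pytest.fixture(scope="session")
def embedder():
    return HashedNgramEmbedder()


@pytest.fixture(scope="session")
def eval_items():
    return [
        EvalItem(
            item_id="i1",
            user_message="Is my lab result normal?",
            ground_truth_response="Your results are within the normal range, no action needed.",
            ehr_context={"name": "Pat", "age": "44"},
        ),
        EvalItem(
            item_id="i2",
            user_message="Can I get a refill?",
            ground_truth_response="Your refill was sent to the pharmacy and is ready today.",
            ehr_context={"name": "Sam", "age": "57"},
        ),
    ]


@pytest.fixture(scope="session")
def few_shot():
    return [
        FewShotExample("Do I need a follow up visit?", "Yes, please schedule a visit next week."),
        FewShotExample("Is this medication safe?", "Yes, at the prescribed dose it is safe for you."),
        FewShotExample("Can you send my form?", "The form will appear in your portal in three days."),
    ]


@pytest.fixture(scope="session")
def seed_prompt():
    # a template-shaped seed instruction with placeholder and two EHR slots
    return (
        "You are a helpful, respectful and honest primary care provider "
        "answering patient questions submitted electronically. Address "
        "<User Message> with a formal greeting and use the patient details "
        "[name] [age] from the record. The ‖ examples offer guidance."
    )


class StaticGenerator:
    """Returns a fixed text for every sample; ignores the prompt."""

    name = "static"

    def __init__(self, text: str):
        self.text = text

    def generate(self, request):
        return [self.text] * request.n_samples


class PerPromptGenerator:
    """Returns texts[i % len] per sample, cycling; useful for stubbing
    distinct outputs."""

    name = "cycle"

    def __init__(self, texts):
        self.texts = list(texts)

    def generate(self, request):
        return [self.texts[i % len(self.texts)] for i in range(request.n_samples)]


@pytest.fixture
def static_generator_factory():
    return StaticGenerator


@pytest.fixture
def cycle_generator_factory():
    return PerPromptGenerator


def random_text(rng: np.random.Generator, alphabet: str = "abc", max_len: int = 6) -> str:
    n = int(rng.integers(0, max_len + 1))
    return "".join(alphabet[int(i)] for i in rng.integers(0, len(alphabet), size=n))
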