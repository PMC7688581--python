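import pandas as pd
import pytest

from morphcomp.models import SmoothingConfig, train_all_models
from morphcomp.scoring import score_all
from morphcomp.stimuli import (
    PRODUCTIVE_PREFIXES,
    PRODUCTIVE_SUFFIXES,
    extract_templates,
    generate_stimuli,
    stimuli_to_frame,
)
from morphcomp.synth import default_grammar, sample_lexicon


@pytest.fixture(scope="session")
def demo_grammar():
    return default_grammar()


@pytest.fixture(scope="session")
def demo_lexicon(demo_grammar):
    """A mid-sized synthetic lexicon shared across the suite."""
    return sample_lexicon(demo_grammar, 3000, seed=11)


@pytest.fixture(scope="session")
def demo_templates(demo_lexicon):
    lin = extract_templates(demo_lexicon, "linear", 5, PRODUCTIVE_SUFFIXES)
    nst = extract_templates(demo_lexicon, "nested", 2, PRODUCTIVE_PREFIXES)
    assert lin and nst
    return lin, nst


@pytest.fixture(scope="session")
def demo_stimuli(demo_lexicon, demo_templates):
    lin, nst = demo_templates
    return generate_stimuli(demo_lexicon, lin, nst, n_per_kind=60, seed=11)


@pytest.fixture(scope="session")
def demo_stim_frame(demo_stimuli):
    return stimuli_to_frame(demo_stimuli)


@pytest.fixture(scope="session")
def demo_models(demo_lexicon):
    return train_all_models(demo_lexicon, SmoothingConfig(0.1))


@pytest.fixture(scope="session")
def demo_scores(demo_models, demo_stimuli):
    models, unigram = demo_models
    return score_all(models, unigram, demo_stimuli)


def make_clean_metadata(participants):
    """Metadata that excludes nobody."""
    return pd.DataFrame(
        {
            "participant": sorted(set(participants)),
            "native_language": "English",
            "birthplace": "USA",
        }
    )


@pytest.fixture
def clean_metadata():
    return make_clean_metadata
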