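"""Shared fixtures: a held-out reference bank and a small synthetic corpus.

Everything is generated programmatically and seeded; session scope keeps
the DTW-heavy fixtures to one construction per run.
"""

import numpy as np
import pytest

from repseg.reference_bank import build_bank
from repseg.synth import SynthSpec, make_emulated_corpus, synth_recording

#: Seed of the designated held-out reference "speaker".
REFERENCE_SEED = 999


@pytest.fixture(scope="session")
def reference_source():
    """A parsed 10-repetition recording from the held-out speaker."""
    return synth_recording(SynthSpec(n_repetitions=10, seed=REFERENCE_SEED))


@pytest.fixture(scope="session")
def bank(reference_source):
    audio, parse = reference_source
    return build_bank(audio, parse, max_count=13)


@pytest.fixture(scope="session")
def corpus():
    """5 synthetic speakers x 4 elicitation conditions = 20 recordings."""
    return make_emulated_corpus(n_speakers=5, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
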