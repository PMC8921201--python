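import hypothesis
import numpy as np
import pytest

from rivaldyn.records import CleanTrial, PerceptResponse, PerceptState, Trial

hypothesis.settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=50
)
hypothesis.settings.load_profile("suite")

STATES = list(PerceptState)

_DESIGN = dict(
    participant_id="p1", group="control", paradigm="CBR",
    condition="0.78v0.78", orientation="A", trial_index=1,
)


def make_trial(stream, **overrides) -> Trial:
    """Build a contiguous trial from (state, duration) pairs."""
    design = {**_DESIGN, **overrides}
    responses = []
    t = 0.0
    for s, d in stream:
        responses.append(PerceptResponse(state=s, onset=t, duration=d))
        t += d
    return Trial(**design, responses=responses)


def make_clean(phases, **overrides) -> CleanTrial:
    design = {**_DESIGN, **overrides}
    return CleanTrial(**design, phases=list(phases))


def random_clean_sequence(rng: np.random.Generator, min_len=2, max_len=30):
    """A random phase sequence with no adjacent duplicate states."""
    n = int(rng.integers(min_len, max_len + 1))
    seq = []
    prev = None
    for _ in range(n):
        choices = [s for s in STATES if s is not prev]
        s = choices[int(rng.integers(len(choices)))]
        seq.append((s, float(rng.uniform(0.2, 8.0))))
        prev = s
    return seq


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
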