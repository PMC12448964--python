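import numpy as np
import pytest


@pytest.fixture
def rng():
    """Factory for independent, reproducible generators."""

    def make(*key):
        return np.random.default_rng(np.random.SeedSequence(list(key) or [0]))

    return make


class ScriptedRng:
    """Deterministic stand-in for a Generator: replays scripted uniforms."""

    def __init__(self, values):
        self.values = list(values)
        self.i = 0

    def random(self, size=None):
        if size is not None:
            raise NotImplementedError
        v = self.values[self.i]
        self.i += 1
        return v


@pytest.fixture
def scripted_rng():
    return ScriptedRng
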