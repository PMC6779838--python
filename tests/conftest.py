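import pytest

from tkdseq import ActionCode, Alphabet, Corpus, EventSequence, TKDOT


@pytest.fixture(scope="session")
def ab_alphabet():
    """Minimal two-code alphabet for hand-enumerable transition examples."""
    return Alphabet(
        [ActionCode("A", "alpha", "attack"), ActionCode("B", "beta", "defense")]
    )


def make_corpus(sequences, alphabet=TKDOT, sex=None):
    """Build a corpus from lists of code symbols, auto-numbering bouts."""
    return Corpus(
        tuple(
            EventSequence(str(i + 1), tuple(events), sex)
            for i, events in enumerate(sequences)
        ),
        alphabet,
    )


@pytest.fixture
def tiny_corpus():
    return make_corpus([["OPE", "DIA", "OPE", "DIA"], ["DOD", "SCA", "DIA"]],
                       sex="male")
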