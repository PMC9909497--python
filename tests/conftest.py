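import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from cxrcaption.labeler import load_negation_lexicon
from cxrcaption.rulegen import load_rule_table
from cxrcaption.textproc import load_location_lexicon
from cxrcaption.vocab import AbnormalSign, SignVocabulary, load_vocabulary


@pytest.fixture(scope="session")
def vocab():
    return load_vocabulary()


@pytest.fixture(scope="session")
def rules(vocab):
    return load_rule_table(None, vocab)


@pytest.fixture(scope="session")
def locations():
    return load_location_lexicon()


@pytest.fixture(scope="session")
def negation():
    return load_negation_lexicon()


@pytest.fixture(scope="session")
def small_vocab():
    """An 8-sign vocabulary for exhaustive-enumeration tests."""
    names = [
        ("consolidation", "lung_parenchyma"),
        ("nodule", "lung_parenchyma"),
        ("mass", "lung_parenchyma"),
        ("cavity", "lung_parenchyma"),
        ("cardiomegaly", "mediastinum"),
        ("pneumothorax", "pleura"),
        ("pleural effusion", "pleura"),
        ("scoliosis", "thorax"),
    ]
    return SignVocabulary(
        tuple(
            AbnormalSign(i, name, group, (name,))
            for i, (name, group) in enumerate(names)
        )
    )
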