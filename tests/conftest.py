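import pytest

from epiedu import synthcorpus as sc
from epiedu import textprep as tp


@pytest.fixture(scope="session")
def small_corpus():
    cfg = sc.CorpusConfig(n_bulletins=60, seed=42)
    return sc.generate_corpus(cfg)


@pytest.fixture(scope="session")
def truth_lexicon(small_corpus):
    return tp.lexicon_from_corpus_truth(small_corpus, min_freq=1)
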