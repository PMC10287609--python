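import numpy as np
import pytest

from radconcept import corpus_io
from radconcept.lexicon import default_lexicon
from radconcept.ner_rules import compile_patterns
from radconcept.synthgen import SyntheticCorpusSpec, generate_corpus

#: Literal expansion of the generative concept-1 templates, used by oracle
#: tests to keep the brute-force scanner regex-free.
GENERATIVE_EXPANSIONS = tuple(
    f"{prefix}{adeno}{stem} lung"
    for prefix in ("", "squamous cell ", "sqaumous cell ")
    for adeno in ("", "adeno")
    for stem in ("ca", "ca.", "carcinoma")
) + tuple(
    f"lung {adeno}{stem}"
    for adeno in ("", "adeno")
    for stem in ("ca", "ca.", "carcinoma")
)


@pytest.fixture(scope="session")
def lex():
    return default_lexicon()


@pytest.fixture(scope="session")
def pats(lex):
    return compile_patterns(lex, enable_generative=True)


@pytest.fixture(scope="session")
def strict_pats(lex):
    return compile_patterns(lex, enable_generative=False)


def make_corpus(n=100, seed=0, **kwargs):
    spec = SyntheticCorpusSpec(n_reports=n, seed=seed, **kwargs)
    return spec, generate_corpus(spec)


def prepared_records(records, doctor_names):
    """clean + select: the standard path from raw records to NER-ready ones."""
    cleaned = corpus_io.clean_records(records, doctor_names)
    return corpus_io.select_reports(cleaned).records


def preprocessed_texts(records, doctor_names):
    recs = prepared_records(records, doctor_names)
    return [corpus_io.preprocess(r.unified_text)[1] for r in recs], recs


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
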