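import pytest

from sbelkit import (
    GeneratorConfig,
    build_fd_instances,
    build_re_instances,
    convert_corpus,
    generate_corpus,
    worked_examples,
    worked_sentences,
)


@pytest.fixture(scope="session")
def worked():
    return worked_examples()


@pytest.fixture(scope="session")
def worked_sent():
    return worked_sentences()


@pytest.fixture(scope="session")
def small_corpus():
    """A mixed-complexity corpus small enough for exhaustive checks."""
    return generate_corpus(GeneratorConfig(n_sentences=60, seed=42))


def sbel_by_sentence(corpus):
    qs = convert_corpus(corpus)
    by = {s.sentence_id: [] for s in corpus}
    for q in qs:
        by[q.sentence_id].append(q)
    return qs, by


def gold_instances(corpus):
    """RE and FD instances for a corpus, labeled from the gold conversion."""
    _, by = sbel_by_sentence(corpus)
    re_instances, fd_instances = [], []
    for s in corpus:
        re_instances.extend(build_re_instances(s, by[s.sentence_id])[0])
        fd_instances.extend(build_fd_instances(s, by[s.sentence_id])[0])
    return re_instances, fd_instances
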