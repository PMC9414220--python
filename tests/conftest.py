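import numpy as np
import pytest

import mirepr as m


@pytest.fixture(scope="session")
def tiny_spec():
    """Two subjects, one run, six 4 s intervals (3 rest)."""
    return m.SyntheticSpec(n_subjects=2, runs_per_subject=1,
                           intervals_per_run=6, rest_intervals_per_run=3,
                           seed=11)


@pytest.fixture(scope="session")
def tiny_corpus(tiny_spec):
    return m.generate_corpus(tiny_spec)


@pytest.fixture(scope="session")
def tiny_epochs(tiny_corpus):
    epochs = []
    for rec in tiny_corpus:
        epochs.extend(m.extract_epochs(rec).epochs)
    return epochs


@pytest.fixture(scope="session")
def edf_dir(tiny_spec, tiny_corpus, tmp_path_factory):
    d = tmp_path_factory.mktemp("edf_corpus")
    m.write_corpus(tiny_spec, str(d), tiny_corpus)
    return d
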