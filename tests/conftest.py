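import numpy as np
import pytest

from conceptdrift.events import EdgeEvent, TemporalGraph
from conceptdrift.synthetic import DriftConfig, generate_dynamic_graph, generate_embeddings

TOY_ANNOTATIONS = """\
# article_id\tyear\tconcept_id\tconcept_type\tconcept_name
A1\t2001\tD001\tMeSH\talpha
A1\t2001\tD002\tMeSH\tbeta
A1\t2001\tD003\tMeSH\tgamma
A2\t2001\tD001\tMeSH\talpha
A2\t2001\tD002\tMeSH\tbeta
A3\t2002\tD002\tMeSH\tbeta
A3\t2002\tD004\tMeSH\tdelta
A4\t2002\t\tMeSH\tnameless
A5\t2002\tG001\tGene\tsome gene
A6\t2003\tD001\tMeSH\talpha
A6\t2003\tD004\tMeSH\tdelta
A7\t2003\tD005\tMeSH\tepsilon
A8\t2001\tD003\tMeSH\tgamma
A8\t2001\tD004\tMeSH\tdelta
A9\t2003\tD001\tMeSH\talpha
A9\t2003\tD002\tMeSH\tbeta
A10\t2002\tD005\tMeSH\tepsilon
"""


@pytest.fixture
def toy_annotation_file(tmp_path):
    path = tmp_path / "annotations.tsv"
    path.write_text(TOY_ANNOTATIONS)
    return path


@pytest.fixture
def toy_graph():
    """5 concepts, horizon 4; hand-checkable event list."""
    events = [
        EdgeEvent(1, 0, 1),
        EdgeEvent(1, 0, 2),
        EdgeEvent(2, 0, 3),
        EdgeEvent(2, 1, 2),
        EdgeEvent(3, 0, 1),
        EdgeEvent(3, 2, 3),
        EdgeEvent(4, 3, 4),
    ]
    return TemporalGraph([f"D{k}" for k in range(5)], 4, events)


@pytest.fixture(scope="session")
def small_drift_cfg():
    """Down-scaled generator config for fast training tests."""
    return DriftConfig(n_concepts=100, horizon=8, converge_pairs=10, seed=3)


@pytest.fixture(scope="session")
def small_synth(small_drift_cfg):
    synth = generate_dynamic_graph(small_drift_cfg)
    emb = generate_embeddings(synth, small_drift_cfg)
    return synth, emb


@pytest.fixture(scope="session")
def default_synth():
    """The packaged default fixture (300 concepts, T=12)."""
    cfg = DriftConfig(seed=1)
    synth = generate_dynamic_graph(cfg)
    emb = generate_embeddings(synth, cfg)
    return cfg, synth, emb
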