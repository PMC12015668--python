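import pytest

from scai.kg import Concept, KnowledgeGraph, SemanticTriple
from scai.synthetic import WorldConfig, make_world


@pytest.fixture
def fig_graph():
    """Two-triple demo graph: an antibiotic treating a pneumonia whose
    causal organism is linked by a relation outside the default registry."""
    g = KnowledgeGraph()
    g.add_concept(Concept("C323", "penicillin", "substance"))
    g.add_concept(Concept("C233604007", "pneumococcal pneumonia", "disorder"))
    g.add_concept(Concept("C9861002", "streptococcus pneumoniae", "organism"))
    g.add_triple(SemanticTriple("C323", "treats", "C233604007"))
    g.add_triple(SemanticTriple("C233604007", "causal agent", "C9861002"))
    return g


@pytest.fixture(scope="session")
def small_world():
    """Desk-size synthetic world shared by retrieval/backend/pipeline tests."""
    return make_world(WorldConfig(n_concepts=80, n_triples=240, n_questions=20), seed=11)
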