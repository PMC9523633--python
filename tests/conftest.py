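import numpy as np
import pytest

from litkg import core, models, synthetic


@pytest.fixture
def small_corpus() -> list[core.Predication]:
    """Ten hand-written predications: 3 mentions of one triple, assorted others."""
    P = core.Predication
    return [
        P("C001", "TREATS", "C100", "drug a", "phsu", "disease x", "dsyn", "PMID1", 2010, "a treats x ."),
        P("C001", "TREATS", "C100", "drug a", "phsu", "disease x", "dsyn", "PMID2", 2018, "a treats x again ."),
        P("C001", "TREATS", "C100", "drug a", "phsu", "disease x", "dsyn", "PMID3", None, "undated mention ."),
        P("C001", "PREVENTS", "C100", "drug a", "phsu", "disease x", "dsyn", "PMID4", 2015, "a prevents x ."),
        P("C002", "TREATS", "C100", "drug b", "orch", "disease x", "dsyn", "PMID5", 2019, "b treats x ."),
        P("C002", "AFFECTS", "C101", "drug b", "orch", "pathway y", "phsf", "PMID6", 2021, "b affects y ."),
        P("C003", "AFFECTS", "C101", "idea c", "idcn", "pathway y", "phsf", "PMID7", 2020, "c affects y ."),
        P("C004", "TREATS", "C102", "drug d", "phsu", "disease z", "mobd", "PMID8", 2022, "d treats z ."),
        P("C001", "AFFECTS", "C102", "drug a", "phsu", "disease z", "mobd", "PMID9", 2009, "a affects z ."),
        P("C100", "AFFECTS", "C001", "disease x", "dsyn", "drug a", "phsu", "PMID10", 2012, "x affects a ."),
    ]


@pytest.fixture(scope="session")
def synth_corpus():
    """Default-condition synthetic corpus, shared across tests (read-only)."""
    cfg = synthetic.SyntheticConfig(seed=0)
    preds, truth = synthetic.generate_kg(cfg)
    return cfg, preds, truth


@pytest.fixture(scope="session")
def trained_transe(synth_corpus):
    """TransE trained on the full synthetic corpus (dim 32, 200 epochs)."""
    _, preds, truth = synth_corpus
    graph = core.build_graph(core.deduplicate(preds))
    model, trace = models.train(
        graph.triple_ids(), "TransE", graph.n_entities, graph.n_relations,
        models.TrainConfig(dim=32, learning_rate=0.01, epochs=200, batch_size=512, seed=1),
    )
    return graph, model, trace


@pytest.fixture
def tiny_model():
    """A 5-entity, 2-relation random DistMult model for ranking oracles."""
    rng = np.random.default_rng(42)
    return models.EmbeddingModel(
        "DistMult", rng.standard_normal((5, 4)), rng.standard_normal((2, 4))
    )
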