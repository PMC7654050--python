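import numpy as np
import pytest

import ppiam_triage as pt


@pytest.fixture(scope="session")
def tiny_corpus() -> pt.Corpus:
    return pt.Corpus([
        pt.Document(doc_id="d1", title="Binding study",
                    body="GeneAp binds GeneBp , but the R117H variant fails .",
                    label=1),
        pt.Document(doc_id="d2", title="Field survey",
                    body="The meadow was green in spring .", label=0),
        pt.Document(doc_id="d3", title="Mutant report",
                    body="GeneCp interacts GeneAp , but the K55E variant fails .",
                    label=1),
    ])


@pytest.fixture(scope="session")
def gen_small() -> pt.GeneratedCorpus:
    return pt.generate_corpus(pt.GeneratorConfig(n_docs=60, prevalence=0.42,
                                                 seed=7))


@pytest.fixture(scope="session")
def fitted_featurizer(gen_small):
    feat = pt.TriageFeaturizer(protein_terms=gen_small.protein_terms,
                               interaction_terms=gen_small.interaction_terms,
                               mutation_terms=gen_small.mutation_terms)
    X = feat.fit_transform(gen_small.corpus)
    return feat, X


@pytest.fixture
def planted_analysis():
    """Analysis of a single document holding the documented
    protein/mutation path example (interior [binds, PROT2, fails])."""
    doc = pt.Document(
        doc_id="fig", title="",
        body="GeneAp binds GeneBp , but the R117H variant fails .")
    feat = pt.TriageFeaturizer(protein_terms=["GeneAp", "GeneBp"],
                               interaction_terms=["binds"],
                               mutation_terms=["variant"])
    feat._prepare([doc])
    return feat._analyze(doc)


def small_grid() -> dict:
    """One-point hyperparameter grid for fast classifier fits in tests."""
    return {"max_depth": [3], "n_estimators": [60], "learning_rate": [0.2],
            "reg_lambda": [1]}
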