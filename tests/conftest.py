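import datetime as dt

import numpy as np
import pytest

from mendelsim.fixtures import FixtureSpec, gen_knowledge_base
from mendelsim.kg import DiseaseRecord, KnowledgeGraph
from mendelsim.ontology import Ontology


@pytest.fixture(scope="session")
def default_kg():
    """The default synthetic knowledge base (30 diseases, 260 genes)."""
    return gen_knowledge_base(FixtureSpec())


@pytest.fixture(scope="session")
def small_kg():
    """A smaller knowledge base for fast per-module checks."""
    spec = FixtureSpec(
        n_terms=200,
        n_diseases=6,
        n_genes=120,
        fraction_nondisease=0.4,
        novelty_quotas={
            "known_disease_new_gene_link": 1,
            "novel_disease_undiscovered_gene": 1,
        },
    )
    return gen_knowledge_base(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def flat_ontology(leaf_terms, n_mid=3):
    """Root -> mid-level nodes -> the given leaf terms (round-robin).

    Depth 2 everywhere so obfuscation has non-root parents to climb to.
    """
    root = "PT:ROOT"
    mids = [f"PT:MID{i}" for i in range(n_mid)]
    parents = {root: set(), **{m: {root} for m in mids}}
    for i, t in enumerate(leaf_terms):
        parents[t] = {mids[i % n_mid]}
    return Ontology(parents)


def build_kg(
    diseases,
    gene_phenotypes=None,
    nondisease_genes=(),
    flags=None,
    expression=None,
    claims=None,
    gene_gene=None,
    extra_terms=(),
    timestamp=dt.date(2015, 2, 1),
):
    """Hand-built KnowledgeGraph over a flat ontology.

    ``diseases`` maps disease id -> dict with keys ``genes``, ``phenotypes``
    (term -> prevalence), and optional ``date``, ``ages``, ``classification``,
    ``parent``.  Ontology terms are collected automatically.
    """
    from mendelsim.kg import AgeCategory, Classification

    terms = set(extra_terms)
    for d in diseases.values():
        terms |= set(d["phenotypes"])
    for ts in (gene_phenotypes or {}).values():
        terms |= set(ts)
    if claims is not None:
        terms |= set(claims["term_id"])
    onto = flat_ontology(sorted(terms))
    records = {}
    dates = {}
    for did, d in diseases.items():
        date = d.get("date", dt.date(2010, 1, 1))
        records[did] = DiseaseRecord(
            id=did,
            causal_genes=frozenset(d.get("genes", ())),
            phenotypes=d["phenotypes"],
            age_ranges=frozenset(d.get("ages", {AgeCategory.ADULT})),
            classification=d.get("classification", Classification.DISORDER),
            parent_id=d.get("parent"),
            discovery_date=date,
        )
        for g in d.get("genes", ()):
            dates[(g, did)] = d.get("edge_date", date)
    return KnowledgeGraph(
        ontology=onto,
        diseases=records,
        gene_disease_dates=dates,
        gene_phenotypes=gene_phenotypes or {},
        gene_gene=gene_gene,
        nondisease_genes=nondisease_genes,
        flags=flags,
        expression=expression,
        claims=claims,
        timestamp=timestamp,
    )
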