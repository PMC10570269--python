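"""Phenotype-similarity gene rankers.

Two ranker families are implemented over an ancestor-propagated annotation
corpus with per-term information content:

* Phrank-style scoring: the similarity of two term sets is the summed
  information content of the shared ancestor closure.  In gene mode the
  patient's positives are compared to each candidate gene's phenotype
  annotations; in disease mode to each disease associated with the gene,
  taking the best disease.
* Phenomizer-style scoring: a patient-disease score is the mean, over
  patient terms, of the information content of the most informative common
  ancestor with the best-matching disease term; an empirical p-value is
  obtained by rescoring random term sets of the same cardinality.

All scorers see only knowledge dated on or before the graph's timestamp:
gene-disease links discovered later are invisible, as are diseases not yet
described.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import rankdata

from .kg import KnowledgeGraph
from .ontology import Ontology
from .patient import SimulatedPatient

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationCorpus",
    "information_content",
    "phrank_similarity",
    "RankingResult",
    "PhrankScorer",
    "PhenomizerScorer",
    "rank_genes_phrank",
    "build_gene_corpus",
    "build_disease_corpus",
]


class AnnotationCorpus:
    """Entity -> term-set annotations with ancestor closure and IC in bits.

    IC(t) = -log2(fraction of entities annotated, directly or through a
    descendant, to t).  The root covers every entity, so IC(root) = 0, and
    IC never increases walking from a term to an ancestor.  Terms covering
    no entity have undefined IC and are excluded from scoring.  Entities
    with empty term sets are dropped.
    """

    def __init__(self, ontology: Ontology, annotations: Mapping[str, Iterable[str]], propagate: bool = True):
        self.ontology = ontology
        self.annotations: Dict[str, FrozenSet[str]] = {}
        self.closures: Dict[str, FrozenSet[str]] = {}
        for entity, terms in annotations.items():
            terms = frozenset(t for t in terms if t in ontology)
            if not terms:
                continue
            self.annotations[entity] = terms
            self.closures[entity] = ontology.closure_of_set(terms) if propagate else terms
        self.n_entities = len(self.annotations)
        counts: Dict[str, int] = {}
        for closure in self.closures.values():
            for t in closure:
                counts[t] = counts.get(t, 0) + 1
        self.counts = counts
        self.ic: Dict[str, float] = {
            t: -math.log2(c / self.n_entities) for t, c in counts.items()
        } if self.n_entities else {}

    @property
    def entities(self) -> FrozenSet[str]:
        return frozenset(self.annotations)

    @property
    def vocabulary(self) -> List[str]:
        """Terms directly annotated to at least one entity, sorted."""
        out = set()
        for terms in self.annotations.values():
            out |= terms
        return sorted(out)


def information_content(corpus: AnnotationCorpus) -> Dict[str, float]:
    """Per-term IC in bits over the corpus's ancestor-propagated closure."""
    return dict(corpus.ic)


def phrank_similarity(set_a: Iterable[str], set_b: Iterable[str], corpus: AnnotationCorpus) -> float:
    """Summed IC over the intersection of the two sets' ancestor closures.

    Terms absent from the ontology are filtered first; an empty filtered
    set scores 0 with a warning.
    """
    onto = corpus.ontology
    a = frozenset(t for t in set_a if t in onto)
    b = frozenset(t for t in set_b if t in onto)
    if not a or not b:
        logger.warning("phrank_similarity: empty term set after ontology filtering")
        return 0.0
    shared = onto.closure_of_set(a) & onto.closure_of_set(b)
    # summation over sorted terms keeps scores bit-reproducible
    return float(sum(corpus.ic.get(t, 0.0) for t in sorted(shared)))


@dataclass
class RankingResult:
    """A scorer's ordering of one patient's candidate genes."""

    patient_id: str
    genes: List[str]
    scores: List[float]
    causal_rank: float
    scorer: str


def _causal_rank(genes: Sequence[str], scores: Sequence[float], causal: str) -> float:
    """Rank of the causal gene, ties resolved to the mean tied position."""
    ranks = rankdata([-s for s in scores], method="average")
    return float(ranks[list(genes).index(causal)])


def build_gene_corpus(kg: KnowledgeGraph, propagate: bool = True) -> AnnotationCorpus:
    return AnnotationCorpus(kg.ontology, kg.gene_phenotypes, propagate=propagate)


def build_disease_corpus(kg: KnowledgeGraph, propagate: bool = True) -> AnnotationCorpus:
    """Disease -> phenotype corpus over diseases known at the KG timestamp.

    Only terms with positive prevalence count as a disease's phenotypes
    (excluded terms are evidence against the disease, not for it).
    """
    known = kg.known_diseases_as_of()
    ann = {
        did: {t for t, p in kg.diseases[did].phenotypes.items() if p > 0}
        for did in known
    }
    return AnnotationCorpus(kg.ontology, ann, propagate=propagate)


class PhrankScorer:
    """Phrank-style candidate-gene ranking against a time-stamped KG.

    ``mode='gene'`` scores the patient's positives against each gene's own
    phenotype annotations; ``mode='disease'`` scores them against every
    disease linked to the gene by an edge dated on or before the KG
    timestamp and keeps the best disease.  Unannotated genes score 0.
    """

    def __init__(self, kg: KnowledgeGraph, mode: str = "disease", propagate: bool = True):
        if mode not in ("gene", "disease"):
            raise ValueError(f"mode must be 'gene' or 'disease', got {mode!r}")
        self.kg = kg
        self.mode = mode
        self.name = f"phrank-{mode}"
        if mode == "gene":
            self.corpus = build_gene_corpus(kg, propagate)
        else:
            self.corpus = build_disease_corpus(kg, propagate)
            known = self.corpus.entities
            self._gene_diseases: Dict[str, List[str]] = {}
            for (g, d), date in kg.gene_disease_dates.items():
                if date <= kg.timestamp and d in known:
                    self._gene_diseases.setdefault(g, []).append(d)

    def _score_closure(self, patient_closure: FrozenSet[str], entity: str) -> float:
        shared = patient_closure & self.corpus.closures[entity]
        return float(sum(self.corpus.ic.get(t, 0.0) for t in sorted(shared)))

    def score_gene(self, patient_terms: Iterable[str], gene: str) -> float:
        terms = [t for t in patient_terms if t in self.kg.ontology]
        if not terms:
            return 0.0
        closure = self.kg.ontology.closure_of_set(terms)
        return self._score_gene_closure(closure, gene)

    def _score_gene_closure(self, patient_closure: FrozenSet[str], gene: str) -> float:
        if self.mode == "gene":
            if gene not in self.corpus.closures:
                return 0.0
            return self._score_closure(patient_closure, gene)
        return max(
            (self._score_closure(patient_closure, d) for d in self._gene_diseases.get(gene, ())),
            default=0.0,
        )

    def rank(self, patient: SimulatedPatient) -> RankingResult:
        genes = patient.candidate_genes()
        terms = [t for t in patient.positives if t in self.kg.ontology]
        closure = self.kg.ontology.closure_of_set(terms) if terms else frozenset()
        scores = [self._score_gene_closure(closure, g) if terms else 0.0 for g in genes]
        return RankingResult(
            patient_id=patient.id,
            genes=genes,
            scores=scores,
            causal_rank=_causal_rank(genes, scores, patient.true_gene),
            scorer=self.name,
        )

    __call__ = rank


class PhenomizerScorer:
    """Best-match semantic similarity of patient terms to diseases, with
    permutation p-values.

    The patient-disease score is the mean over patient terms of the IC of
    the most informative common ancestor (MICA) with the best-matching
    disease term (one-sided, patient -> disease).  The empirical p-value
    rescores ``n_samples`` random term sets of the same cardinality drawn
    from the annotated vocabulary and uses the add-one convention
    (b + 1) / (n + 1), so p is lower-bounded by 1/(n+1).  A candidate
    gene's score is the best score over its (time-stamped) diseases.
    """

    def __init__(self, kg: KnowledgeGraph, n_samples: int = 10_000):
        self.kg = kg
        self.n_samples = n_samples
        self.name = "phenomizer"
        self.corpus = build_disease_corpus(kg)
        known = self.corpus.entities
        self._gene_diseases: Dict[str, List[str]] = {}
        for (g, d), date in kg.gene_disease_dates.items():
            if date <= kg.timestamp and d in known:
                self._gene_diseases.setdefault(g, []).append(d)
        self.vocabulary = self.corpus.vocabulary
        self._vocab_index = {t: i for i, t in enumerate(self.vocabulary)}
        self._best_ic_cache: Dict[str, np.ndarray] = {}
        self._mica_cache: Dict[Tuple[str, str], float] = {}

    def _mica_ic(self, t1: str, t2: str) -> float:
        key = (t1, t2) if t1 <= t2 else (t2, t1)
        cached = self._mica_cache.get(key)
        if cached is None:
            onto = self.kg.ontology
            common = onto.ancestors(t1) & onto.ancestors(t2)
            cached = max((self.corpus.ic.get(t, 0.0) for t in common), default=0.0)
            self._mica_cache[key] = cached
        return cached

    def _best_ic_vector(self, disease: str) -> np.ndarray:
        """For each vocabulary term, the best MICA IC against the disease."""
        cached = self._best_ic_cache.get(disease)
        if cached is None:
            d_terms = self.corpus.annotations[disease]
            cached = np.array(
                [max(self._mica_ic(t, td) for td in d_terms) for t in self.vocabulary]
            )
            self._best_ic_cache[disease] = cached
        return cached

    def score_disease(self, patient_terms: Iterable[str], disease: str) -> float:
        terms = [t for t in patient_terms if t in self.kg.ontology]
        if not terms or disease not in self.corpus.annotations:
            return 0.0
        d_terms = self.corpus.annotations[disease]
        return float(np.mean([max(self._mica_ic(t, td) for td in d_terms) for t in terms]))

    def score_and_p(
        self, patient_terms: Iterable[str], disease: str, rng: np.random.Generator
    ) -> Tuple[float, float]:
        """Observed score plus the add-one empirical p-value under random
        same-size term sets from the annotated vocabulary."""
        terms = [t for t in patient_terms if t in self.kg.ontology]
        score = self.score_disease(terms, disease)
        k = len(terms)
        if k == 0:
            return score, 1.0
        best = self._best_ic_vector(disease)
        draws = rng.integers(len(self.vocabulary), size=(self.n_samples, k))
        null_scores = best[draws].mean(axis=1)
        b = int(np.sum(null_scores >= score))
        return score, (b + 1) / (self.n_samples + 1)

    def score_gene(self, patient_terms: Iterable[str], gene: str) -> float:
        return max(
            (self.score_disease(patient_terms, d) for d in self._gene_diseases.get(gene, ())),
            default=0.0,
        )

    def rank(self, patient: SimulatedPatient) -> RankingResult:
        genes = patient.candidate_genes()
        scores = [self.score_gene(patient.positives, g) for g in genes]
        return RankingResult(
            patient_id=patient.id,
            genes=genes,
            scores=scores,
            causal_rank=_causal_rank(genes, scores, patient.true_gene),
            scorer=self.name,
        )

    __call__ = rank


def rank_genes_phrank(patient: SimulatedPatient, kg: KnowledgeGraph, mode: str = "disease") -> RankingResult:
    """One-shot Phrank ranking (builds the corpus each call; prefer
    :class:`PhrankScorer` for cohorts)."""
    return PhrankScorer(kg, mode=mode).rank(patient)
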