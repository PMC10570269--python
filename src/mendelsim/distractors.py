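"""Distractor candidate-gene generation.

Six modules each emulate a class of plausible-but-noncausal genes a
clinical team would shortlist during a real diagnostic workup:

1. genes causing a phenotypically similar (overlapping) disease;
2. genes causing a phenotypically distinct (zero-overlap) disease;
3. non-disease genes explaining only a strict subset of the true disease's
   low-prevalence phenotypes;
4. non-disease genes annotated only to phenotypes unrelated to the disease;
5. genes with tissue-expression profiles similar to the causal gene;
6. frequently-mutated genes that recur as false positives in pipelines.

Modules 1, 3 and 4 also perturb the patient's phenotype sets; modules 2, 5
and 6 never touch phenotypes.  A patient receives 1 + Poisson(λ_G)
noncausal genes, each slot's module drawn from a categorical over the
module weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np

from .kg import DiseaseRecord, KnowledgeGraph, PrevalenceBucket
from .patient import Provenance, SimulatedPatient

logger = logging.getLogger(__name__)

__all__ = [
    "DistractorParams",
    "DistractorResult",
    "NoCandidate",
    "DistractorEngine",
    "sample_budgets",
    "attach_distractors",
]

MODULE_LABELS = Provenance.MODULES


class NoCandidate(Exception):
    """Raised when a module has no eligible gene for this patient."""


@dataclass(frozen=True)
class DistractorParams:
    """Weights, budgets and toggles for distractor generation.

    ``module_weights`` are the categorical probabilities of the six modules
    (must sum to 1); ``lambda_genes`` parameterises the 1 + Poisson(λ_G)
    noncausal gene budget and ``lambda_phenotypes`` the 1 + Poisson(λ_P)
    phenotype additions inside modules 1, 3 and 4.  ``gene_only`` suppresses
    all phenotype side-effects (ablation mode).
    """

    module_weights: Tuple[float, ...] = (0.33, 0.42, 0.05, 0.09, 0.08, 0.03)
    lambda_genes: float = 12.0
    lambda_phenotypes: float = 1.0
    top_k_expression: int = 100
    gene_only: bool = False
    max_resamples: int = 10

    def __post_init__(self):
        if len(self.module_weights) != 6:
            raise ValueError("module_weights must have six entries")
        if abs(sum(self.module_weights) - 1.0) > 1e-9:
            raise ValueError(f"module_weights must sum to 1, got {sum(self.module_weights)}")
        if any(w < 0 for w in self.module_weights):
            raise ValueError("module_weights must be nonnegative")
        if self.lambda_genes < 0 or self.lambda_phenotypes < 0:
            raise ValueError("Poisson rates must be >= 0")
        if self.top_k_expression < 1:
            raise ValueError("top_k_expression must be >= 1")


@dataclass
class DistractorResult:
    """One noncausal gene plus the phenotype terms its module contributes."""

    gene: str
    module: str
    pos_added: Set[str] = field(default_factory=set)
    neg_added: Set[str] = field(default_factory=set)


def sample_budgets(
    params: DistractorParams, rng: np.random.Generator, n_modules: int = 6
) -> Tuple[int, List[int]]:
    """Draw the noncausal gene budget and a module index (0-5) per slot."""
    n_noncausal = 1 + int(rng.poisson(params.lambda_genes))
    weights = np.asarray(params.module_weights, dtype=float)
    slots = [int(m) for m in rng.choice(n_modules, size=n_noncausal, p=weights)]
    return n_noncausal, slots


def _sample_some(
    pool: Sequence[str], lam: float, rng: np.random.Generator, exclude: Set[str] = frozenset()
) -> Set[str]:
    """Draw 1 + Poisson(lam) items without replacement, truncated to availability."""
    avail = sorted(set(pool) - set(exclude))
    if not avail:
        return set()
    k = min(1 + int(rng.poisson(lam)), len(avail))
    idx = rng.choice(len(avail), size=k, replace=False)
    return {avail[int(i)] for i in idx}


class DistractorEngine:
    """Per-knowledge-graph distractor sampler with cached eligibility sets.

    Eligibility for modules 1-4 depends only on the true disease, and the
    module-5 expression neighbourhood only on the causal gene, so both are
    computed once per disease/gene and reused across patients.
    """

    def __init__(self, kg: KnowledgeGraph, params: Optional[DistractorParams] = None):
        self.kg = kg
        self.params = params or DistractorParams()
        self._m1_cache: Dict[str, List[Tuple[str, str]]] = {}
        self._m2_cache: Dict[str, List[str]] = {}
        self._m3_cache: Dict[str, List[str]] = {}
        self._m4_cache: Dict[str, List[str]] = {}
        self._m5_cache: Dict[Tuple[str, str], Tuple[List[str], np.ndarray]] = {}
        self._disease_gene_map: Dict[str, FrozenSet[str]] = {
            d.id: d.causal_genes for d in kg.diseases.values()
        }
        # genes -> diseases they cause (full, undated knowledge base)
        self._gene_diseases: Dict[str, Set[str]] = {}
        for d in kg.diseases.values():
            for g in d.causal_genes:
                self._gene_diseases.setdefault(g, set()).add(d.id)
        self._all_disease_genes: FrozenSet[str] = frozenset(self._gene_diseases)
        self._gene_universe: List[str] = sorted(kg.genes)
        self._flags_genes: List[str] = sorted(g for g, c in kg.flags.items())
        self._flags_weights: np.ndarray = np.array(
            [kg.flags[g] for g in self._flags_genes], dtype=float
        )

    # ----- module 1: phenotypically similar disease genes ---------------
    def _eligible_similar(self, disease: DiseaseRecord) -> List[Tuple[str, str]]:
        cached = self._m1_cache.get(disease.id)
        if cached is not None:
            return cached
        pairs: List[Tuple[str, str]] = []
        true_terms = disease.term_set
        for other_id in sorted(self.kg.diseases):
            if other_id == disease.id:
                continue
            other = self.kg.diseases[other_id]
            if not other.causal_genes:
                continue
            overlap = true_terms & other.term_set
            if not overlap:
                continue
            has_obligate = bool(other.terms_in_bucket(PrevalenceBucket.OBLIGATE))
            has_excluded = bool(other.terms_in_bucket(PrevalenceBucket.EXCLUDED))
            weak_overlap = overlap & other.terms_in_bucket(PrevalenceBucket.WEAK)
            if not (has_obligate or has_excluded or weak_overlap):
                continue
            for g in sorted(other.causal_genes - disease.causal_genes):
                pairs.append((other_id, g))
        self._m1_cache[disease.id] = pairs
        return pairs

    def phenotypically_similar_distractor(
        self,
        patient: SimulatedPatient,
        disease: DiseaseRecord,
        rng: np.random.Generator,
        exclude: frozenset = frozenset(),
    ) -> DistractorResult:
        """Gene causing an overlapping distractor disease, made definitively
        noncausal by planting contradicting evidence.

        Overlapping terms go to the patient's positives.  If the distractor
        disease has excluded (0%) terms some are added to positives, and if
        it has obligate (100%) terms some are added to negatives — either
        contradicts the distractor disease.  If it has neither and only weak
        terms overlap, some of its strong non-overlapping terms are added to
        negatives instead.
        """
        pairs = [(d, g) for d, g in self._eligible_similar(disease) if g not in exclude]
        if not pairs:
            raise NoCandidate("no phenotypically similar distractor disease")
        other_id, gene = pairs[int(rng.integers(len(pairs)))]
        other = self.kg.diseases[other_id]
        lam = self.params.lambda_phenotypes

        overlap = disease.term_set & other.term_set
        has_obligate = bool(other.terms_in_bucket(PrevalenceBucket.OBLIGATE))
        has_excluded = bool(other.terms_in_bucket(PrevalenceBucket.EXCLUDED))
        all_weak_path = not (has_obligate or has_excluded)
        if all_weak_path:
            # only the weak overlapping terms may be transferred to the patient
            overlap = overlap & other.terms_in_bucket(PrevalenceBucket.WEAK)

        pos: Set[str] = _sample_some(overlap, lam, rng)
        neg: Set[str] = set()
        if has_excluded:
            pos |= _sample_some(other.terms_in_bucket(PrevalenceBucket.EXCLUDED), lam, rng, exclude=pos)
        if has_obligate:
            neg |= _sample_some(other.terms_in_bucket(PrevalenceBucket.OBLIGATE), lam, rng, exclude=pos)
        if all_weak_path:
            strong_nonoverlap = other.terms_in_bucket(PrevalenceBucket.STRONG) - disease.term_set
            neg |= _sample_some(strong_nonoverlap, lam, rng, exclude=pos)
        return DistractorResult(gene, Provenance.PHENOTYPICALLY_SIMILAR, pos, neg)

    # ----- module 2: phenotypically distinct disease genes --------------
    def _eligible_distinct(self, disease: DiseaseRecord) -> List[str]:
        cached = self._m2_cache.get(disease.id)
        if cached is not None:
            return cached
        true_terms = disease.term_set
        genes = []
        for g in sorted(self._all_disease_genes - disease.causal_genes):
            others = self._gene_diseases[g]
            if all(not (true_terms & self.kg.diseases[d].term_set) for d in others):
                genes.append(g)
        self._m2_cache[disease.id] = genes
        return genes

    def phenotypically_distinct_distractor(
        self,
        patient: SimulatedPatient,
        disease: DiseaseRecord,
        rng: np.random.Generator,
        exclude: frozenset = frozenset(),
    ) -> DistractorResult:
        """Gene whose diseases share no phenotype term with the true disease.

        Overlap is computed on raw annotated term sets, not ancestor
        closures, so sibling terms count as non-overlapping.  No phenotype
        side-effects.
        """
        genes = [g for g in self._eligible_distinct(disease) if g not in exclude]
        if not genes:
            raise NoCandidate("no phenotypically distinct disease gene")
        return DistractorResult(
            genes[int(rng.integers(len(genes)))], Provenance.PHENOTYPICALLY_DISTINCT
        )

    # ----- module 3: insufficiently explanatory non-disease genes -------
    def _eligible_insufficient(self, disease: DiseaseRecord) -> List[str]:
        cached = self._m3_cache.get(disease.id)
        if cached is not None:
            return cached
        weak = disease.terms_in_bucket(PrevalenceBucket.WEAK)
        genes = []
        for g in sorted(self.kg.nondisease_genes):
            terms = self.kg.gene_phenotypes.get(g, frozenset())
            if terms and terms < weak:  # nonempty strict subset
                genes.append(g)
        self._m3_cache[disease.id] = genes
        return genes

    def insufficiently_explanatory_distractor(
        self,
        patient: SimulatedPatient,
        disease: DiseaseRecord,
        rng: np.random.Generator,
        exclude: frozenset = frozenset(),
    ) -> DistractorResult:
        """Non-disease gene explaining a strict subset of the disease's weak
        (low-prevalence) terms; its terms join the positives only when none
        of them is already positive."""
        genes = [g for g in self._eligible_insufficient(disease) if g not in exclude]
        if not genes:
            raise NoCandidate("no insufficiently explanatory non-disease gene")
        gene = genes[int(rng.integers(len(genes)))]
        terms = self.kg.gene_phenotypes[gene]
        pos: Set[str] = set()
        if not (terms & patient.positives):
            pos = _sample_some(terms, self.params.lambda_phenotypes, rng)
        return DistractorResult(gene, Provenance.INSUFFICIENTLY_EXPLANATORY, pos)

    # ----- module 4: incidental-phenotype non-disease genes -------------
    def _eligible_incidental(self, disease: DiseaseRecord) -> List[str]:
        cached = self._m4_cache.get(disease.id)
        if cached is not None:
            return cached
        true_terms = disease.term_set
        genes = []
        for g in sorted(self.kg.nondisease_genes):
            terms = self.kg.gene_phenotypes.get(g, frozenset())
            if terms and not (terms & true_terms):
                genes.append(g)
        self._m4_cache[disease.id] = genes
        return genes

    def incidental_phenotype_distractor(
        self,
        patient: SimulatedPatient,
        disease: DiseaseRecord,
        rng: np.random.Generator,
        exclude: frozenset = frozenset(),
    ) -> DistractorResult:
        """Non-disease gene annotated only to terms unrelated to the true
        disease; a few of its terms join the positives."""
        genes = [g for g in self._eligible_incidental(disease) if g not in exclude]
        if not genes:
            raise NoCandidate("no incidental-phenotype non-disease gene")
        gene = genes[int(rng.integers(len(genes)))]
        pos = _sample_some(self.kg.gene_phenotypes[gene], self.params.lambda_phenotypes, rng)
        return DistractorResult(gene, Provenance.INCIDENTAL_PHENOTYPE, pos)

    # ----- module 5: similarly expressed genes --------------------------
    def _expression_neighbours(
        self, causal_gene: str, disease: DiseaseRecord
    ) -> Tuple[List[str], np.ndarray]:
        key = (causal_gene, disease.id)
        cached = self._m5_cache.get(key)
        if cached is not None:
            return cached
        expr = self.kg.normalized_expression()
        if expr.empty or causal_gene not in expr.index:
            self._m5_cache[key] = ([], np.array([]))
            return self._m5_cache[key]
        mat = expr.to_numpy(float)
        genes = list(expr.index)
        target = expr.loc[causal_gene].to_numpy(float)
        tnorm = np.linalg.norm(target)
        norms = np.linalg.norm(mat, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            sims = mat @ target / np.where(norms * tnorm > 0, norms * tnorm, np.inf)
        sims = np.nan_to_num(sims, nan=0.0)
        # exclude the causal gene and genes causing overlapping diseases
        true_terms = disease.term_set
        keep = []
        for i, g in enumerate(genes):
            if g == causal_gene:
                continue
            overlapping = any(
                true_terms & self.kg.diseases[d].term_set for d in self._gene_diseases.get(g, ())
            )
            if overlapping:
                continue
            keep.append(i)
        keep = sorted(keep, key=lambda i: (-sims[i], genes[i]))[: self.params.top_k_expression]
        result = ([genes[i] for i in keep], sims[keep].astype(float))
        self._m5_cache[key] = result
        return result

    def similarly_expressed_distractor(
        self,
        patient: SimulatedPatient,
        disease: DiseaseRecord,
        rng: np.random.Generator,
        exclude: frozenset = frozenset(),
    ) -> DistractorResult:
        """Gene drawn from the causal gene's top-K cosine-similarity
        expression neighbourhood with probability proportional to similarity.

        Expression values are min-max normalised per tissue over all genes
        before computing cosine similarity.  No phenotype side-effects.
        """
        all_genes, all_sims = self._expression_neighbours(patient.true_gene, disease)
        keep = [i for i, g in enumerate(all_genes) if g not in exclude]
        genes = [all_genes[i] for i in keep]
        sims = all_sims[keep] if len(keep) else np.array([])
        if not genes:
            raise NoCandidate("causal gene missing from expression matrix or no neighbours")
        total = sims.sum()
        if total <= 0:
            idx = int(rng.integers(len(genes)))
        else:
            idx = int(rng.choice(len(genes), p=sims / total))
        return DistractorResult(genes[idx], Provenance.SIMILARLY_EXPRESSED)

    # ----- module 6: common false positive genes ------------------------
    def false_positive_distractor(
        self, rng: np.random.Generator, exclude: frozenset = frozenset()
    ) -> DistractorResult:
        """Frequently-mutated gene drawn with probability proportional to
        its rare functional variant count."""
        if not self._flags_genes:
            raise NoCandidate("flags table is empty")
        keep = [i for i, g in enumerate(self._flags_genes) if g not in exclude]
        weights = self._flags_weights[keep]
        total = weights.sum()
        if not keep or total <= 0:
            raise NoCandidate("no flags gene with positive variant count available")
        idx = keep[int(rng.choice(len(keep), p=weights / total))]
        return DistractorResult(self._flags_genes[idx], Provenance.FALSE_POSITIVE)

    # ----- orchestration -------------------------------------------------
    def _draw_module(
        self,
        module_idx: int,
        patient: SimulatedPatient,
        disease: DiseaseRecord,
        rng: np.random.Generator,
        exclude: frozenset = frozenset(),
    ) -> DistractorResult:
        if module_idx == 0:
            return self.phenotypically_similar_distractor(patient, disease, rng, exclude)
        if module_idx == 1:
            return self.phenotypically_distinct_distractor(patient, disease, rng, exclude)
        if module_idx == 2:
            return self.insufficiently_explanatory_distractor(patient, disease, rng, exclude)
        if module_idx == 3:
            return self.incidental_phenotype_distractor(patient, disease, rng, exclude)
        if module_idx == 4:
            return self.similarly_expressed_distractor(patient, disease, rng, exclude)
        if module_idx == 5:
            return self.false_positive_distractor(rng, exclude)
        raise ValueError(f"invalid module index {module_idx}")

    def _random_backfill(
        self, existing: Set[str], rng: np.random.Generator
    ) -> Optional[DistractorResult]:
        pool = [g for g in self._gene_universe if g not in existing]
        if not pool:
            return None
        return DistractorResult(pool[int(rng.integers(len(pool)))], Provenance.RANDOM_BACKFILL)

    def attach_distractors(
        self,
        patient: SimulatedPatient,
        rng: np.random.Generator,
        enabled_modules: Sequence[bool] = (True,) * 6,
    ) -> SimulatedPatient:
        """Fill the patient's candidate list with 1 + Poisson(λ_G) noncausal
        genes and apply module phenotype side-effects.

        A slot whose module yields no candidate (or a duplicate gene) is
        redrawn from the renormalised weights of the enabled modules up to
        ``max_resamples`` times, then backfilled with a uniform random gene
        labelled ``random_backfill``; slots of disabled modules are
        backfilled directly, keeping the candidate count unchanged.  In
        ``gene_only`` mode phenotype side-effects are suppressed.  The final
        candidate list is shuffled with provenance retained.
        """
        disease = self.kg.diseases[patient.disease_id]
        n_noncausal, slots = sample_budgets(self.params, rng)
        existing: Set[str] = set(patient.candidate_genes())
        weights = np.asarray(self.params.module_weights, dtype=float)
        enabled = np.asarray(enabled_modules, dtype=bool)
        redraw_w = np.where(enabled, weights, 0.0)

        for module_idx in slots:
            result: Optional[DistractorResult] = None
            if enabled[module_idx]:
                tries, idx = 0, module_idx
                while tries <= self.params.max_resamples:
                    try:
                        cand = self._draw_module(idx, patient, disease, rng, frozenset(existing))
                    except NoCandidate:
                        cand = None
                    if cand is not None and cand.gene not in existing:
                        result = cand
                        break
                    tries += 1
                    if redraw_w.sum() > 0:
                        idx = int(rng.choice(6, p=redraw_w / redraw_w.sum()))
            if result is None:
                result = self._random_backfill(existing, rng)
                if result is None:
                    logger.warning("gene universe exhausted; candidate list truncated")
                    break
            existing.add(result.gene)
            patient.candidates.append((result.gene, result.module))
            if not self.params.gene_only:
                self._apply_side_effects(patient, result)

        order = rng.permutation(len(patient.candidates))
        patient.candidates = [patient.candidates[int(i)] for i in order]
        return patient

    @staticmethod
    def _apply_side_effects(patient: SimulatedPatient, result: DistractorResult) -> None:
        # a term destined for one set but already in the other is skipped
        # (never moved): recorded absences/presences are not overwritten
        for t in sorted(result.pos_added):
            if t not in patient.negatives:
                patient.positives.add(t)
        for t in sorted(result.neg_added):
            if t not in patient.positives:
                patient.negatives.add(t)


# -- thin functional wrappers -------------------------------------------

def attach_distractors(
    patient: SimulatedPatient,
    kg: KnowledgeGraph,
    params: DistractorParams,
    rng: np.random.Generator,
    enabled_modules: Sequence[bool] = (True,) * 6,
) -> SimulatedPatient:
    return DistractorEngine(kg, params).attach_distractors(patient, rng, enabled_modules)
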