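"""Simulated patient container and initialization from a disease record.

A patient starts as a direct transcript of the disease: one causal gene
drawn uniformly from the disease's known causal genes, an onset age drawn
uniformly from the disease's age ranges, and every annotated phenotype term
assigned to the positive set with probability P(term|disease) or to the
negative set otherwise.  Diagnostic imprecision and distractor genes are
layered on afterwards by the other pipeline stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Set, Tuple

import numpy as np

from .kg import AgeCategory, DiseaseRecord, KnowledgeGraph, NoveltyCategory

__all__ = ["Provenance", "SimulatedPatient", "init_patient"]


class Provenance:
    """Labels recording where each candidate gene came from."""

    CAUSAL = "causal"
    PHENOTYPICALLY_SIMILAR = "module1_phenotypically_similar"
    PHENOTYPICALLY_DISTINCT = "module2_phenotypically_distinct"
    INSUFFICIENTLY_EXPLANATORY = "module3_insufficiently_explanatory"
    INCIDENTAL_PHENOTYPE = "module4_incidental_phenotype"
    SIMILARLY_EXPRESSED = "module5_similarly_expressed"
    FALSE_POSITIVE = "module6_false_positive"
    RANDOM_BACKFILL = "random_backfill"

    MODULES = (
        PHENOTYPICALLY_SIMILAR,
        PHENOTYPICALLY_DISTINCT,
        INSUFFICIENTLY_EXPLANATORY,
        INCIDENTAL_PHENOTYPE,
        SIMILARLY_EXPRESSED,
        FALSE_POSITIVE,
    )

    ALL = (CAUSAL,) + MODULES + (RANDOM_BACKFILL,)


@dataclass
class SimulatedPatient:
    """One simulated rare-disease patient.

    ``candidates`` is an ordered list of ``(gene, provenance)`` pairs; the
    true causal gene appears exactly once with provenance ``causal``.
    Positive and negative phenotype sets are disjoint and every term exists
    in the ontology the patient was simulated against.
    """

    id: str
    disease_id: str
    true_gene: str
    age: AgeCategory
    positives: Set[str] = field(default_factory=set)
    negatives: Set[str] = field(default_factory=set)
    candidates: List[Tuple[str, str]] = field(default_factory=list)
    novelty: Optional[NoveltyCategory] = None

    def candidate_genes(self) -> List[str]:
        return [g for g, _ in self.candidates]

    def check_invariants(self) -> None:
        if self.positives & self.negatives:
            raise AssertionError("positives and negatives overlap")
        genes = self.candidate_genes()
        if len(genes) != len(set(genes)):
            raise AssertionError("duplicate candidate genes")
        causal = [g for g, lab in self.candidates if lab == Provenance.CAUSAL]
        if causal != [self.true_gene]:
            raise AssertionError("causal gene missing or mislabelled in candidates")


def init_patient(
    disease: DiseaseRecord,
    kg: KnowledgeGraph,
    rng: np.random.Generator,
    patient_id: str = "patient-0",
) -> SimulatedPatient:
    """Initialize a patient from a simulatable disease record.

    Each annotated term lands in the positive set with probability
    P(term|disease), otherwise in the negative set; at this stage the two
    sets partition the disease's annotated terms exactly.
    """
    if not disease.phenotypes:
        raise ValueError(f"disease {disease.id} has no phenotype annotations")
    if not disease.causal_genes:
        raise ValueError(f"disease {disease.id} has no causal genes")
    if not disease.age_ranges:
        raise ValueError(f"disease {disease.id} has no age ranges")

    gene = str(rng.choice(sorted(disease.causal_genes)))
    age = AgeCategory(str(rng.choice(sorted(a.value for a in disease.age_ranges))))
    positives: Set[str] = set()
    negatives: Set[str] = set()
    for term in sorted(disease.phenotypes):
        p = disease.phenotypes[term]
        (positives if rng.random() < p else negatives).add(term)
    return SimulatedPatient(
        id=patient_id,
        disease_id=disease.id,
        true_gene=gene,
        age=age,
        positives=positives,
        negatives=negatives,
        candidates=[(gene, Provenance.CAUSAL)],
    )
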