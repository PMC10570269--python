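"""Diagnostic-process imprecision operators: dropout, obfuscation, noise.

Real clinical phenotyping is partial (terms go unrecorded), imprecise
(specific terms are recorded as less precise ancestors) and contaminated
(unrelated comorbid symptoms are recorded).  The three operators here model
those effects and are applied in that order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Set

import numpy as np

from .kg import AgeCategory, KnowledgeGraph
from .ontology import Ontology
from .patient import SimulatedPatient

logger = logging.getLogger(__name__)

__all__ = [
    "ImprecisionParams",
    "apply_dropout",
    "apply_obfuscation",
    "apply_noise",
    "age_stratum",
]


@dataclass(frozen=True)
class ImprecisionParams:
    """Probabilities and rates for the three imprecision operators.

    Dropout removes each positive term with probability 0.7 and each
    negative with 0.2 by default; obfuscation replaces each surviving term
    with a parent with probability 0.15 per set.  Noise adds 1 + Poisson(λ)
    terms to each set (λ configurable; the +1 floor guarantees at least one
    noise term per set).
    """

    p_pos_dropout: float = 0.7
    p_neg_dropout: float = 0.2
    p_pos_obfuscate: float = 0.15
    p_neg_obfuscate: float = 0.15
    lambda_noise_pos: float = 2.0
    lambda_noise_neg: float = 2.0

    def __post_init__(self):
        for name in ("p_pos_dropout", "p_neg_dropout", "p_pos_obfuscate", "p_neg_obfuscate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("lambda_noise_pos", "lambda_noise_neg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _drop(terms: Set[str], p: float, rng: np.random.Generator) -> Set[str]:
    return {t for t in sorted(terms) if not rng.random() < p}


def apply_dropout(
    patient: SimulatedPatient, params: ImprecisionParams, rng: np.random.Generator
) -> SimulatedPatient:
    """Remove each phenotype term independently with its set's dropout rate.

    Removal is unconditional: a patient may lose every initial disease
    phenotype; no re-draw is performed.
    """
    patient.positives = _drop(patient.positives, params.p_pos_dropout, rng)
    patient.negatives = _drop(patient.negatives, params.p_neg_dropout, rng)
    return patient


def _obfuscate_set(
    terms: Set[str],
    other: Set[str],
    ontology: Ontology,
    p: float,
    rng: np.random.Generator,
) -> Set[str]:
    out: Set[str] = set()
    replaced = []
    for t in sorted(terms):
        if rng.random() < p:
            parents = sorted(ontology.parents(t) - {ontology.root})
            if not parents:  # only parent is the root: leave unchanged
                out.add(t)
                continue
            replaced.append(str(rng.choice(parents)))
        else:
            out.add(t)
    for parent in replaced:
        # collision with an existing term in either set deduplicates
        if parent not in out and parent not in other:
            out.add(parent)
    return out


def apply_obfuscation(
    patient: SimulatedPatient,
    ontology: Ontology,
    params: ImprecisionParams,
    rng: np.random.Generator,
) -> SimulatedPatient:
    """Replace terms with a uniformly chosen parent, per-set probability.

    Terms whose only parent is the root are never coarsened to the root
    (that would erase all information).  A replacement already present in
    either phenotype set is deduplicated: term sets are sets, not multisets.
    """
    new_pos = _obfuscate_set(patient.positives, patient.negatives, ontology, params.p_pos_obfuscate, rng)
    new_neg = _obfuscate_set(patient.negatives, new_pos, ontology, params.p_neg_obfuscate, rng)
    patient.positives = new_pos
    patient.negatives = new_neg
    return patient


def age_stratum(age: AgeCategory) -> str:
    """Claims-table stratum key for an age category (identity mapping)."""
    if not isinstance(age, AgeCategory):
        raise ValueError(f"unknown age category: {age!r}")
    return age.value


def _weighted_sample_without_replacement(
    items, weights: np.ndarray, k: int, rng: np.random.Generator
):
    """Sequential draws with renormalisation; k is truncated to availability."""
    items = list(items)
    w = np.asarray(weights, dtype=float).copy()
    chosen = []
    for _ in range(min(k, len(items))):
        total = w.sum()
        if total <= 0:
            idx = int(rng.integers(len(items)))
        else:
            idx = int(rng.choice(len(items), p=w / total))
        chosen.append(items.pop(idx))
        w = np.delete(w, idx)
    return chosen


def apply_noise(
    patient: SimulatedPatient,
    kg: KnowledgeGraph,
    params: ImprecisionParams,
    rng: np.random.Generator,
) -> SimulatedPatient:
    """Add claims-derived noise terms to both phenotype sets.

    Draws 1 + Poisson(λ_pos) new positive terms without replacement with
    probability proportional to their prevalence in the patient's age
    stratum, and 1 + Poisson(λ_neg) negative terms uniformly from the same
    stratum's vocabulary; terms already present in either set are excluded.
    If the stratum vocabulary is smaller than a requested draw, all
    available terms are taken and a warning is logged.
    """
    stratum = age_stratum(patient.age)
    vocab, prev = kg.claims_for_stratum(stratum)

    n_pos = 1 + int(rng.poisson(params.lambda_noise_pos))
    present = patient.positives | patient.negatives
    avail = [(t, p) for t, p in zip(vocab, prev) if t not in present]
    if len(avail) < n_pos:
        logger.warning(
            "stratum %s vocabulary (%d available) smaller than requested %d positive noise draws",
            stratum, len(avail), n_pos,
        )
    drawn = _weighted_sample_without_replacement(
        [t for t, _ in avail], np.array([p for _, p in avail]), n_pos, rng
    )
    patient.positives |= set(drawn)

    n_neg = 1 + int(rng.poisson(params.lambda_noise_neg))
    present = patient.positives | patient.negatives
    avail_neg = [t for t in vocab if t not in present]
    if len(avail_neg) < n_neg:
        logger.warning(
            "stratum %s vocabulary (%d available) smaller than requested %d negative noise draws",
            stratum, len(avail_neg), n_neg,
        )
    n_take = min(n_neg, len(avail_neg))
    if n_take:
        idx = rng.choice(len(avail_neg), size=n_take, replace=False)
        patient.negatives |= {avail_neg[int(i)] for i in idx}
    return patient
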