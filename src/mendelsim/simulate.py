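"""Cohort simulation orchestration and JSONL serialisation.

The per-patient pipeline is: initialize from the disease record, then
dropout -> obfuscation -> noise (each toggleable), then distractor gene
attachment, then novelty classification against the KG timestamp.  Each
patient gets its own random substream derived from (master seed, disease
id, replicate index) so cohorts are reproducible and independent of
iteration order.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .distractors import DistractorEngine, DistractorParams
from .imprecision import ImprecisionParams, apply_dropout, apply_noise, apply_obfuscation
from .kg import AgeCategory, DiseaseRecord, KnowledgeGraph, NoveltyCategory, classify_novelty
from .patient import SimulatedPatient

__all__ = [
    "SimulationConfig",
    "simulate_patient",
    "simulate_cohort",
    "write_patients",
    "read_patients",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Everything that controls a cohort simulation run.

    Component toggles switch individual pipeline stages off for ablation
    studies; ``uniform_module_weights`` replaces the calibrated module mix
    with a uniform one and ``module_enabled`` disables single distractor
    modules (their slots are backfilled with random genes so candidate
    counts are unchanged).
    """

    patients_per_disease: int = 20
    imprecision: ImprecisionParams = field(default_factory=ImprecisionParams)
    distractor: DistractorParams = field(default_factory=DistractorParams)
    dropout: bool = True
    obfuscation: bool = True
    noise: bool = True
    distractor_phenotypes: bool = True
    module_enabled: Tuple[bool, ...] = (True,) * 6
    uniform_module_weights: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.patients_per_disease < 1:
            raise ValueError("patients_per_disease must be >= 1")
        if len(self.module_enabled) != 6:
            raise ValueError("module_enabled must have six entries")

    def effective_distractor_params(self) -> DistractorParams:
        params = self.distractor
        if self.uniform_module_weights:
            params = replace(params, module_weights=(1.0 / 6,) * 6)
        if not self.distractor_phenotypes:
            params = replace(params, gene_only=True)
        return params

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["imprecision"] = dataclasses.asdict(self.imprecision)
        d["distractor"] = dataclasses.asdict(self.distractor)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "imprecision" in d:
            d["imprecision"] = ImprecisionParams(**d["imprecision"])
        if "distractor" in d:
            dp = dict(d["distractor"])
            if "module_weights" in dp:
                dp["module_weights"] = tuple(dp["module_weights"])
            d["distractor"] = DistractorParams(**dp)
        if "module_enabled" in d:
            d["module_enabled"] = tuple(d["module_enabled"])
        return cls(**d)


def patient_rng(master_seed: int, disease_id: str, replicate: int) -> np.random.Generator:
    """Deterministic substream for one patient, independent of iteration order."""
    key = zlib.crc32(disease_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([master_seed & 0x7FFFFFFF, key, replicate]))


def simulate_patient(
    disease: DiseaseRecord,
    kg: KnowledgeGraph,
    config: SimulationConfig,
    rng: np.random.Generator,
    patient_id: str = "patient-0",
    engine: Optional[DistractorEngine] = None,
) -> SimulatedPatient:
    """Run the full per-patient pipeline for one disease."""
    from .patient import init_patient

    if engine is None:
        engine = DistractorEngine(kg, config.effective_distractor_params())
    patient = init_patient(disease, kg, rng, patient_id)
    if config.dropout:
        apply_dropout(patient, config.imprecision, rng)
    if config.obfuscation:
        apply_obfuscation(patient, kg.ontology, config.imprecision, rng)
    if config.noise:
        apply_noise(patient, kg, config.imprecision, rng)
    engine.attach_distractors(patient, rng, config.module_enabled)
    patient.novelty = classify_novelty(kg, patient.true_gene, disease.id)
    return patient


def simulate_cohort(
    kg: KnowledgeGraph,
    config: SimulationConfig,
    diseases: Optional[Sequence[DiseaseRecord]] = None,
) -> Iterator[SimulatedPatient]:
    """Simulate ``patients_per_disease`` patients for every simulatable disease.

    Patients are yielded disease-by-disease in sorted disease-id order; each
    patient's randomness comes from its own seed-derived substream, so the
    produced multiset of patients does not depend on disease ordering.
    """
    from .kg import select_simulatable_diseases

    if diseases is None:
        diseases = select_simulatable_diseases(kg)
    engine = DistractorEngine(kg, config.effective_distractor_params())
    for disease in sorted(diseases, key=lambda d: d.id):
        for rep in range(config.patients_per_disease):
            rng = patient_rng(config.seed, disease.id, rep)
            yield simulate_patient(
                disease, kg, config, rng, patient_id=f"{disease.id}-{rep}", engine=engine
            )


# -- JSONL serialisation -------------------------------------------------

_SCHEMA_FIELDS = {
    "id": str,
    "disease_id": str,
    "true_gene": str,
    "age": str,
    "positives": list,
    "negatives": list,
    "candidates": list,
    "novelty": (str, type(None)),
}


def patient_to_dict(patient: SimulatedPatient) -> dict:
    return {
        "id": patient.id,
        "disease_id": patient.disease_id,
        "true_gene": patient.true_gene,
        "age": patient.age.value,
        "positives": sorted(patient.positives),
        "negatives": sorted(patient.negatives),
        "candidates": [[g, label] for g, label in patient.candidates],
        "novelty": patient.novelty.value if patient.novelty else None,
    }


def patient_from_dict(d: dict) -> SimulatedPatient:
    return SimulatedPatient(
        id=d["id"],
        disease_id=d["disease_id"],
        true_gene=d["true_gene"],
        age=AgeCategory(d["age"]),
        positives=set(d["positives"]),
        negatives=set(d["negatives"]),
        candidates=[(g, label) for g, label in d["candidates"]],
        novelty=NoveltyCategory(d["novelty"]) if d.get("novelty") else None,
    )


def write_patients(patients: Iterable[SimulatedPatient], path: str | Path) -> int:
    """Write patients as JSONL (one patient per line); returns the count."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for p in patients:
            fh.write(json.dumps(patient_to_dict(p), sort_keys=True) + "\n")
            n += 1
    return n


def read_patients(path: str | Path) -> List[SimulatedPatient]:
    """Read a JSONL patient file, validating the schema per line."""
    patients = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                d = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{lineno}: invalid JSON ({exc})") from None
            for key, typ in _SCHEMA_FIELDS.items():
                if key not in d:
                    raise ValueError(f"{path}:{lineno}: missing field {key!r}")
                if not isinstance(d[key], typ):
                    raise ValueError(f"{path}:{lineno}: field {key!r} has wrong type")
            for pair in d["candidates"]:
                if not (isinstance(pair, list) and len(pair) == 2):
                    raise ValueError(f"{path}:{lineno}: malformed candidate entry {pair!r}")
            try:
                patients.append(patient_from_dict(d))
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return patients
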