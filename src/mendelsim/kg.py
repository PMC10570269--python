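"""Time-stamped disease knowledge graph.

Holds the Orphanet-like disease records (causal genes, phenotype annotations
with prevalence, onset age ranges, classification/subtype links), the
gene-level annotation layers (gene-phenotype, gene-gene interactions,
non-disease genes, frequently-mutated "FLAGS"-like genes, a gene x tissue
expression matrix) and a claims-derived age-stratified phenotype prevalence
table.  Gene-disease associations and disease discoveries carry calendar
dates so that the graph can be viewed "as of" a timestamp and causal
gene-disease pairs can be classified by their novelty relative to it.
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .ontology import Ontology, load_ontology

logger = logging.getLogger(__name__)

__all__ = [
    "AgeCategory",
    "PrevalenceBucket",
    "Classification",
    "NoveltyCategory",
    "DiseaseRecord",
    "KnowledgeGraph",
    "bucket_prevalence",
    "prevalence_from_frequency_class",
    "impute_subtype_annotations",
    "select_simulatable_diseases",
    "classify_novelty",
    "load_knowledge_graph",
]


class AgeCategory(str, Enum):
    """Patient age bands used for onset sampling and claims stratification."""

    INFANT = "infant"  # 0-1 years
    CHILD = "child"  # 2-11 years
    ADOLESCENT = "adolescent"  # 12-18 years
    ADULT = "adult"  # 19-64 years
    SENIOR = "senior"  # 65+ years

    @property
    def years(self) -> Tuple[int, Optional[int]]:
        return _AGE_YEARS[self]


_AGE_YEARS = {
    AgeCategory.INFANT: (0, 1),
    AgeCategory.CHILD: (2, 11),
    AgeCategory.ADOLESCENT: (12, 18),
    AgeCategory.ADULT: (19, 64),
    AgeCategory.SENIOR: (65, None),
}


class PrevalenceBucket(str, Enum):
    """Discretisation of P(term|disease) used by the distractor logic."""

    OBLIGATE = "obligate"  # 100%
    STRONG = "strong"  # 80-99%
    MODERATE = "moderate"  # 30-79% (band left unnamed by the source ranges)
    WEAK = "weak"  # 1-29%
    EXCLUDED = "excluded"  # 0%


class Classification(str, Enum):
    DISORDER = "disorder"
    CATEGORY = "category"
    CLINICAL_SUBTYPE = "clinical_subtype"
    ETIOLOGICAL_SUBTYPE = "etiological_subtype"
    HISTOPATHOLOGICAL_SUBTYPE = "histopathological_subtype"

    @property
    def is_subtype(self) -> bool:
        return self in (
            Classification.CLINICAL_SUBTYPE,
            Classification.ETIOLOGICAL_SUBTYPE,
            Classification.HISTOPATHOLOGICAL_SUBTYPE,
        )


class NoveltyCategory(str, Enum):
    """How much of a causal gene-disease pair a dated KG view already knows."""

    KNOWN_DISEASE_KNOWN_GENE = "known_disease_known_gene"
    KNOWN_DISEASE_NEW_GENE_LINK = "known_disease_new_gene_link"
    KNOWN_DISEASE_UNDISCOVERED_GENE = "known_disease_undiscovered_gene"
    NOVEL_DISEASE_KNOWN_GENE = "novel_disease_known_gene"
    NOVEL_DISEASE_UNDISCOVERED_GENE = "novel_disease_undiscovered_gene"


#: Representative point prevalences for Orphanet-style frequency classes,
#: used when a disease-phenotype table carries class labels instead of
#: numeric fractions (Bernoulli sampling needs point probabilities).
FREQUENCY_CLASS_PREVALENCE: Dict[str, float] = {
    "obligate": 1.0,
    "very frequent": 0.895,
    "frequent": 0.545,
    "occasional": 0.17,
    "very rare": 0.025,
    "excluded": 0.0,
}


def prevalence_from_frequency_class(label: str) -> float:
    try:
        return FREQUENCY_CLASS_PREVALENCE[label.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown frequency class: {label!r}") from None


def bucket_prevalence(p: float) -> PrevalenceBucket:
    """Discretise a prevalence fraction into the five-bucket scheme.

    1.0 is obligate, [0.80, 0.99] strong, [0.01, 0.29] weak, 0.0 excluded;
    everything else (the unnamed 0.30-0.79 band plus the tiny gaps at the
    boundaries) is moderate.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"prevalence must be in [0, 1], got {p}")
    if p == 1.0:
        return PrevalenceBucket.OBLIGATE
    if p == 0.0:
        return PrevalenceBucket.EXCLUDED
    if 0.80 <= p <= 0.99:
        return PrevalenceBucket.STRONG
    if 0.01 <= p <= 0.29:
        return PrevalenceBucket.WEAK
    return PrevalenceBucket.MODERATE


@dataclass(frozen=True)
class DiseaseRecord:
    """One rare-disease entry with its annotations.

    ``phenotypes`` maps term id -> P(term | disease) in [0, 1].
    """

    id: str
    name: str = ""
    causal_genes: FrozenSet[str] = frozenset()
    phenotypes: Mapping[str, float] = field(default_factory=dict)
    age_ranges: FrozenSet[AgeCategory] = frozenset()
    classification: Classification = Classification.DISORDER
    parent_id: Optional[str] = None
    discovery_date: Optional[dt.date] = None

    def __post_init__(self):
        for t, p in self.phenotypes.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"disease {self.id}: prevalence of {t} out of [0,1]: {p}")

    def terms_in_bucket(self, bucket: PrevalenceBucket) -> FrozenSet[str]:
        return frozenset(t for t, p in self.phenotypes.items() if bucket_prevalence(p) is bucket)

    @property
    def term_set(self) -> FrozenSet[str]:
        return frozenset(self.phenotypes)


class KnowledgeGraph:
    """The full knowledge base plus a timestamp defining "existing knowledge".

    Parameters
    ----------
    ontology
        Phenotype ontology all term references must resolve against.
    diseases
        Map of disease id to :class:`DiseaseRecord`.
    gene_disease_dates
        ``(gene, disease) -> date`` for every causal association; the date is
        when the association was first reported.
    gene_phenotypes
        Direct gene-to-phenotype annotations (undated snapshot).
    gene_gene
        Undirected interaction edge list.
    nondisease_genes
        Genes with phenotype annotations but no causal disease association.
    flags
        Frequently-mutated gene -> rare functional variant count.
    expression
        Gene x tissue median-expression matrix (TPM-like).
    claims
        Age-stratified phenotype prevalence: columns stratum, term_id,
        prevalence.
    timestamp
        The "knowledge as of" date used for novelty classification and for
        restricting rankers.
    """

    def __init__(
        self,
        ontology: Ontology,
        diseases: Mapping[str, DiseaseRecord],
        gene_disease_dates: Mapping[Tuple[str, str], dt.date],
        gene_phenotypes: Mapping[str, Iterable[str]],
        gene_gene: Optional[Iterable[Tuple[str, str]]] = None,
        nondisease_genes: Iterable[str] = (),
        flags: Optional[Mapping[str, int]] = None,
        expression: Optional[pd.DataFrame] = None,
        claims: Optional[pd.DataFrame] = None,
        timestamp: dt.date = dt.date(2015, 2, 1),
    ):
        self.ontology = ontology
        self.diseases: Dict[str, DiseaseRecord] = dict(diseases)
        self.gene_disease_dates: Dict[Tuple[str, str], dt.date] = dict(gene_disease_dates)
        self.gene_phenotypes: Dict[str, FrozenSet[str]] = {
            g: frozenset(ts) for g, ts in gene_phenotypes.items()
        }
        graph = nx.Graph()
        for a, b in gene_gene or ():
            if a == b:
                raise ValueError(f"gene-gene self-loop on {a}")
            graph.add_edge(a, b)
        self.gene_gene: nx.Graph = graph
        self.nondisease_genes: FrozenSet[str] = frozenset(nondisease_genes)
        self.flags: Dict[str, int] = dict(flags or {})
        self.expression: pd.DataFrame = (
            expression if expression is not None else pd.DataFrame(dtype=float)
        )
        self.claims: pd.DataFrame = (
            claims if claims is not None else pd.DataFrame(columns=["stratum", "term_id", "prevalence"])
        )
        self.timestamp = timestamp
        self._normalized_expression: Optional[pd.DataFrame] = None
        self._claims_by_stratum: Optional[Dict[str, Tuple[List[str], np.ndarray]]] = None
        self._validate()

    # -- validation ------------------------------------------------------
    def _validate(self) -> None:
        onto = self.ontology
        for d in self.diseases.values():
            for t in d.phenotypes:
                if t not in onto:
                    raise ValueError(f"disease {d.id}: phenotype term {t} not in ontology")
        for g, ts in self.gene_phenotypes.items():
            for t in ts:
                if t not in onto:
                    raise ValueError(f"gene {g}: phenotype term {t} not in ontology")
        if not self.claims.empty:
            bad = self.claims[(self.claims["prevalence"] < 0) | (self.claims["prevalence"] > 1)]
            if len(bad):
                raise ValueError("claims prevalences outside [0, 1]")
            for t in self.claims["term_id"]:
                if t not in onto:
                    raise ValueError(f"claims term {t} not in ontology")

    # -- gene universe ---------------------------------------------------
    @property
    def genes(self) -> FrozenSet[str]:
        universe = set(self.gene_phenotypes) | self.nondisease_genes | set(self.flags)
        universe.update(g for g, _ in self.gene_disease_dates)
        universe.update(self.gene_gene.nodes)
        if not self.expression.empty:
            universe.update(self.expression.index)
        return frozenset(universe)

    # -- dated views -----------------------------------------------------
    def gene_disease_edges_as_of(self, when: Optional[dt.date] = None) -> FrozenSet[Tuple[str, str]]:
        when = when or self.timestamp
        return frozenset(e for e, d in self.gene_disease_dates.items() if d <= when)

    def known_diseases_as_of(self, when: Optional[dt.date] = None) -> FrozenSet[str]:
        when = when or self.timestamp
        out = set()
        for d in self.diseases.values():
            if d.discovery_date is None:
                raise ValueError(f"disease {d.id} has no discovery date")
            if d.discovery_date <= when:
                out.add(d.id)
        return frozenset(out)

    def diseases_of_gene_as_of(self, gene: str, when: Optional[dt.date] = None) -> FrozenSet[str]:
        when = when or self.timestamp
        return frozenset(
            d for (g, d), date in self.gene_disease_dates.items() if g == gene and date <= when
        )

    # -- expression ------------------------------------------------------
    def normalized_expression(self) -> pd.DataFrame:
        """Per-tissue min-max normalisation of the expression matrix to [0, 1]."""
        if self._normalized_expression is None:
            e = self.expression.astype(float)
            lo, hi = e.min(axis=0), e.max(axis=0)
            span = (hi - lo).replace(0.0, 1.0)
            self._normalized_expression = (e - lo) / span
        return self._normalized_expression

    # -- claims ----------------------------------------------------------
    def claims_for_stratum(self, stratum: str) -> Tuple[List[str], np.ndarray]:
        """Vocabulary and prevalence vector for one age stratum."""
        if self._claims_by_stratum is None:
            by: Dict[str, Tuple[List[str], np.ndarray]] = {}
            for s, grp in self.claims.groupby("stratum"):
                by[str(s)] = (list(grp["term_id"]), grp["prevalence"].to_numpy(float))
            self._claims_by_stratum = by
        try:
            return self._claims_by_stratum[stratum]
        except KeyError:
            raise KeyError(f"no claims data for age stratum {stratum!r}") from None

    def copy_with(self, **changes) -> "KnowledgeGraph":
        state = dict(
            ontology=self.ontology,
            diseases=self.diseases,
            gene_disease_dates=self.gene_disease_dates,
            gene_phenotypes=self.gene_phenotypes,
            gene_gene=self.gene_gene.edges,
            nondisease_genes=self.nondisease_genes,
            flags=self.flags,
            expression=self.expression,
            claims=self.claims,
            timestamp=self.timestamp,
        )
        state.update(changes)
        return KnowledgeGraph(**state)


# -- subtype imputation and disease filtering ----------------------------

def impute_subtype_annotations(kg: KnowledgeGraph) -> KnowledgeGraph:
    """Fill subtype records missing exactly one of {causal genes, phenotypes}.

    A clinical/etiological/histopathological subtype that lacks causal genes
    but has phenotypes (or vice versa) inherits the missing element from its
    parent disease.  Records missing both are left unfilled (they fall out in
    :func:`select_simulatable_diseases`).  Imputed causal genes carry over the
    parent's association dates.  Idempotent.
    """
    diseases = dict(kg.diseases)
    dates = dict(kg.gene_disease_dates)
    for did in sorted(diseases):
        rec = diseases[did]
        if not rec.classification.is_subtype or rec.parent_id is None:
            continue
        missing_genes = not rec.causal_genes
        missing_phens = not rec.phenotypes
        if missing_genes == missing_phens:  # both present (no-op) or both absent (flagged)
            if missing_genes and missing_phens:
                logger.warning("subtype %s missing both causal genes and phenotypes; left unfilled", did)
            continue
        parent = diseases.get(rec.parent_id)
        if parent is None:
            logger.warning("subtype %s references unknown parent %s", did, rec.parent_id)
            continue
        if missing_genes:
            if not parent.causal_genes:
                logger.warning("subtype %s: parent %s also lacks causal genes", did, parent.id)
                continue
            diseases[did] = replace(rec, causal_genes=parent.causal_genes)
            for g in parent.causal_genes:
                parent_date = dates.get((g, parent.id))
                if parent_date is not None and (g, did) not in dates:
                    dates[(g, did)] = parent_date
        else:
            if not parent.phenotypes:
                logger.warning("subtype %s: parent %s also lacks phenotypes", did, parent.id)
                continue
            diseases[did] = replace(rec, phenotypes=dict(parent.phenotypes))
    return kg.copy_with(diseases=diseases, gene_disease_dates=dates)


def select_simulatable_diseases(kg: KnowledgeGraph) -> List[DiseaseRecord]:
    """Diseases eligible for patient simulation, sorted by id.

    Excludes records classified as heterogeneous disease groups ("category")
    and records lacking phenotype annotations or causal genes.
    """
    out = [
        d
        for d in kg.diseases.values()
        if d.classification is not Classification.CATEGORY and d.phenotypes and d.causal_genes
    ]
    return sorted(out, key=lambda d: d.id)


def classify_novelty(
    kg: KnowledgeGraph, gene: str, disease: str, when: Optional[dt.date] = None
) -> NoveltyCategory:
    """Classify a causal (gene, disease) pair against the dated KG view.

    Using only edges and discoveries dated on or before the timestamp: the
    pair is fully known if the exact association is present; otherwise the
    category records whether the disease itself and/or the gene's role as a
    disease gene (for any disease) were already known.
    """
    when = when or kg.timestamp
    rec = kg.diseases.get(disease)
    if rec is None:
        raise KeyError(f"unknown disease: {disease}")
    if rec.discovery_date is None:
        raise ValueError(f"disease {disease} has no discovery date; novelty undefined")
    disease_known = rec.discovery_date <= when
    edge_date = kg.gene_disease_dates.get((gene, disease))
    edge_known = edge_date is not None and edge_date <= when
    gene_known = bool(kg.diseases_of_gene_as_of(gene, when))
    if disease_known and edge_known:
        return NoveltyCategory.KNOWN_DISEASE_KNOWN_GENE
    if disease_known and gene_known:
        return NoveltyCategory.KNOWN_DISEASE_NEW_GENE_LINK
    if disease_known:
        return NoveltyCategory.KNOWN_DISEASE_UNDISCOVERED_GENE
    if gene_known:
        return NoveltyCategory.NOVEL_DISEASE_KNOWN_GENE
    return NoveltyCategory.NOVEL_DISEASE_UNDISCOVERED_GENE


# -- loaders -------------------------------------------------------------

def _parse_date(value: str, context: str) -> dt.date:
    value = str(value).strip()
    if not value or value.lower() == "nan":
        raise ValueError(f"{context}: missing discovery date")
    return dt.date.fromisoformat(value)


def _parse_prevalence(value) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        return prevalence_from_frequency_class(str(value))


def _read_tsv(path: Path, required: Iterable[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path.name}: missing required columns {sorted(missing)}")
    return df


def load_knowledge_graph(
    directory: str | Path,
    timestamp: dt.date = dt.date(2015, 2, 1),
    gene_id_map: Optional[Mapping[str, str]] = None,
) -> KnowledgeGraph:
    """Load a knowledge-base directory of TSV tables plus an OBO ontology.

    Expected files: ``ontology.obo``, ``diseases.tsv`` (disease_id, name,
    classification, parent_id, date, age_ranges), ``gene_disease.tsv``
    (gene_id, disease_id, date), ``disease_phenotype.tsv`` (disease_id,
    term_id, prevalence — numeric fraction or frequency-class label),
    ``gene_phenotype.tsv``, ``gene_gene.tsv``, ``nondisease_genes.tsv``,
    ``flags.tsv`` (gene_id, rare_variant_count), ``expression.tsv``
    (gene_id plus one column per tissue), ``claims.tsv`` (stratum, term_id,
    prevalence).  All TSVs are UTF-8 with a header row.

    ``gene_id_map`` optionally normalises gene symbols into a single
    (Ensembl-style) namespace; rows whose gene cannot be mapped are dropped
    with a logged warning.
    """
    directory = Path(directory)
    onto = load_ontology(str(directory / "ontology.obo"))

    def norm_gene(g: str) -> Optional[str]:
        g = g.strip()
        if gene_id_map is None:
            return g
        mapped = gene_id_map.get(g)
        if mapped is None:
            logger.warning("dropping unmappable gene symbol %r", g)
        return mapped

    gd = _read_tsv(directory / "gene_disease.tsv", ["gene_id", "disease_id", "date"])
    gene_disease_dates: Dict[Tuple[str, str], dt.date] = {}
    for row in gd.itertuples(index=False):
        g = norm_gene(row.gene_id)
        if g is None:
            continue
        gene_disease_dates[(g, row.disease_id)] = _parse_date(
            row.date, f"gene_disease {row.gene_id}-{row.disease_id}"
        )

    dp = _read_tsv(directory / "disease_phenotype.tsv", ["disease_id", "term_id", "prevalence"])
    phen_by_disease: Dict[str, Dict[str, float]] = {}
    for row in dp.itertuples(index=False):
        phen_by_disease.setdefault(row.disease_id, {})[row.term_id] = _parse_prevalence(row.prevalence)

    genes_by_disease: Dict[str, set] = {}
    for (g, d) in gene_disease_dates:
        genes_by_disease.setdefault(d, set()).add(g)

    dd = _read_tsv(
        directory / "diseases.tsv",
        ["disease_id", "name", "classification", "parent_id", "date", "age_ranges"],
    )
    diseases: Dict[str, DiseaseRecord] = {}
    for row in dd.itertuples(index=False):
        did = row.disease_id
        ages = frozenset(
            AgeCategory(a.strip()) for a in str(row.age_ranges).split(";") if a.strip() and a != "nan"
        )
        parent = None if pd.isna(row.parent_id) or not str(row.parent_id).strip() else str(row.parent_id)
        diseases[did] = DiseaseRecord(
            id=did,
            name="" if pd.isna(row.name) else str(row.name),
            causal_genes=frozenset(genes_by_disease.get(did, ())),
            phenotypes=phen_by_disease.get(did, {}),
            age_ranges=ages,
            classification=Classification(row.classification),
            parent_id=parent,
            discovery_date=_parse_date(row.date, f"disease {did}"),
        )

    gp = _read_tsv(directory / "gene_phenotype.tsv", ["gene_id", "term_id"])
    gene_phenotypes: Dict[str, set] = {}
    for row in gp.itertuples(index=False):
        g = norm_gene(row.gene_id)
        if g is not None:
            gene_phenotypes.setdefault(g, set()).add(row.term_id)

    gg = _read_tsv(directory / "gene_gene.tsv", ["gene1", "gene2"])
    edges = []
    for row in gg.itertuples(index=False):
        a, b = norm_gene(row.gene1), norm_gene(row.gene2)
        if a is not None and b is not None:
            edges.append((a, b))

    nd = _read_tsv(directory / "nondisease_genes.tsv", ["gene_id"])
    nondisease = {g for g in (norm_gene(x) for x in nd["gene_id"]) if g is not None}

    fl = _read_tsv(directory / "flags.tsv", ["gene_id", "rare_variant_count"])
    flags = {}
    for row in fl.itertuples(index=False):
        g = norm_gene(row.gene_id)
        if g is not None:
            flags[g] = int(row.rare_variant_count)

    expr = pd.read_csv(directory / "expression.tsv", sep="\t", index_col="gene_id").astype(float)
    if gene_id_map is not None:
        keep = [g for g in expr.index if g in gene_id_map]
        expr = expr.loc[keep].rename(index=gene_id_map)

    claims = _read_tsv(directory / "claims.tsv", ["stratum", "term_id", "prevalence"])
    claims = claims.assign(prevalence=claims["prevalence"].astype(float))

    return KnowledgeGraph(
        ontology=onto,
        diseases=diseases,
        gene_disease_dates=gene_disease_dates,
        gene_phenotypes=gene_phenotypes,
        gene_gene=edges,
        nondisease_genes=nondisease,
        flags=flags,
        expression=expr,
        claims=claims,
        timestamp=timestamp,
    )
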