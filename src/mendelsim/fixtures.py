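"""Self-contained synthetic knowledge bases with planted structure.

Generates an ontology plus every knowledge-graph table the loaders read,
constructed so that all six distractor modules are viable for every
simulatable disease and so that novelty categories appear with exact,
planted counts.  The layout:

* diseases are split into two groups drawing phenotype terms from disjoint
  leaf blocks, so every disease has zero-overlap disease genes (module 2);
* within a group, consecutive diseases share a weak term, giving every
  disease an overlapping distractor disease (module 1), and every disease
  carries obligate, strong, moderate, weak and excluded terms so all five
  prevalence buckets occur;
* one dedicated non-disease gene per disease is annotated to a strict
  subset of its weak terms (module 3), and a pool of non-disease genes is
  annotated only to "incidental" terms no disease uses (module 4);
* every gene has a tissue-expression vector drawn from a small number of
  latent tissue programs (module 5) and a few genes get FLAGS-like rare
  variant counts (module 6);
* claims prevalence tables are generated per age stratum with Zipf-like
  decay, mirroring heavy-tailed billing-code frequencies.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Set, Tuple

import numpy as np
import pandas as pd

from .kg import (
    AgeCategory,
    Classification,
    DiseaseRecord,
    KnowledgeGraph,
    NoveltyCategory,
)
from .ontology import Ontology

__all__ = ["FixtureSpec", "gen_ontology", "gen_knowledge_base", "write_knowledge_base", "audit_viability"]

KNOWN_DATE = dt.date(2010, 1, 1)
ANCHOR_DATE = dt.date(2008, 1, 1)
NOVEL_DATE = dt.date(2018, 1, 1)
TIMESTAMP = dt.date(2015, 2, 1)

_TERMS_PER_DISEASE = 6  # obligate, strong, moderate, 2 weak, excluded


@dataclass(frozen=True)
class FixtureSpec:
    """Size and composition knobs for a synthetic knowledge base."""

    n_terms: Optional[int] = 400
    depth: int = 4
    branching: int = 3
    double_parent_fraction: float = 0.1
    n_diseases: int = 30
    n_genes: int = 260
    fraction_nondisease: float = 0.45
    n_tissues: int = 8
    n_incidental_terms: int = 10
    claims_vocab_size: int = 40
    novelty_quotas: Mapping[str, int] = field(
        default_factory=lambda: {
            NoveltyCategory.KNOWN_DISEASE_NEW_GENE_LINK.value: 3,
            NoveltyCategory.KNOWN_DISEASE_UNDISCOVERED_GENE.value: 3,
            NoveltyCategory.NOVEL_DISEASE_KNOWN_GENE.value: 3,
            NoveltyCategory.NOVEL_DISEASE_UNDISCOVERED_GENE.value: 2,
        }
    )
    seed: int = 0

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.n_diseases < 4:
            raise ValueError("need at least 4 diseases (two groups of two)")
        quota_total = sum(self.novelty_quotas.values())
        if quota_total > self.n_diseases:
            raise ValueError("novelty quotas exceed n_diseases")
        needs_anchor = any(
            self.novelty_quotas.get(c.value, 0) > 0
            for c in (NoveltyCategory.KNOWN_DISEASE_NEW_GENE_LINK, NoveltyCategory.NOVEL_DISEASE_KNOWN_GENE)
        )
        if needs_anchor and quota_total >= self.n_diseases:
            raise ValueError("known-gene quotas need at least one fully-known anchor disease")
        n_nondisease = int(self.fraction_nondisease * self.n_genes)
        if self.n_genes < self.n_diseases + n_nondisease + 5:
            raise ValueError(
                f"n_genes={self.n_genes} too small for {self.n_diseases} disease genes, "
                f"{n_nondisease} non-disease genes and 5 flags genes"
            )
        if n_nondisease < 3 * self.n_diseases + 5:
            raise ValueError(
                "too few non-disease genes: need 3 per disease (module 3) plus an "
                "incidental pool (module 4); raise n_genes or fraction_nondisease"
            )


def gen_ontology(spec: FixtureSpec, rng: np.random.Generator) -> Ontology:
    """Rooted leveled DAG; a fraction of terms get a second parent.

    With ``n_terms=None`` a complete tree of the given depth and branching
    factor is produced; otherwise level sizes follow a geometric profile.
    """
    root = "PT:0000000"
    if spec.n_terms is None:
        sizes = [spec.branching ** (k + 1) for k in range(spec.depth)]
    else:
        raw = np.array([float(spec.branching) ** k for k in range(spec.depth)])
        sizes = np.maximum(1, np.floor(raw / raw.sum() * (spec.n_terms - 1))).astype(int)
        sizes[-1] += (spec.n_terms - 1) - sizes.sum()
        sizes = list(sizes)
    parents: Dict[str, Set[str]] = {root: set()}
    names = {root: "phenotypic abnormality (root)"}
    levels: List[List[str]] = [[root]]
    counter = 1
    for depth, size in enumerate(sizes, start=1):
        level = []
        for _ in range(int(size)):
            tid = f"PT:{counter:07d}"
            counter += 1
            parent = levels[-1][int(rng.integers(len(levels[-1])))]
            parents[tid] = {parent}
            names[tid] = f"synthetic phenotype {counter - 1} (depth {depth})"
            level.append(tid)
        levels.append(level)
    # second parents: any strictly shallower non-root term
    candidates = [t for lvl in levels[1:] for t in lvl]
    term_depth = {t: d for d, lvl in enumerate(levels) for t in lvl}
    for t in candidates:
        if term_depth[t] >= 2 and rng.random() < spec.double_parent_fraction:
            pool = [
                u
                for lvl in levels[1 : term_depth[t]]
                for u in lvl
                if u not in parents[t]
            ]
            if pool:
                parents[t].add(pool[int(rng.integers(len(pool)))])
    onto = Ontology(parents, names)
    onto._levels = levels  # type: ignore[attr-defined]  # reused by gen_knowledge_base
    return onto


def _zipf_prevalences(n: int, top: float = 0.3, decay: float = 0.8) -> np.ndarray:
    ranks = np.arange(1, n + 1, dtype=float)
    return top / ranks**decay


def gen_knowledge_base(spec: FixtureSpec, rng: Optional[np.random.Generator] = None) -> KnowledgeGraph:
    """Generate a complete knowledge graph with planted structure.

    Raises ``ValueError`` if the spec is infeasible (counts too small for
    the requested quotas or module-viability guarantees).
    """
    rng = rng or np.random.default_rng(spec.seed)
    onto = gen_ontology(spec, rng)
    levels: List[List[str]] = onto._levels  # type: ignore[attr-defined]
    leaves = list(levels[-1])

    n_groups = 2
    group_of = [i % n_groups for i in range(spec.n_diseases)]
    groups = [[i for i in range(spec.n_diseases) if group_of[i] == g] for g in range(n_groups)]

    need_block = spec.n_diseases * _TERMS_PER_DISEASE
    need = need_block + n_groups + spec.n_incidental_terms
    if len(leaves) < need:
        raise ValueError(
            f"ontology has {len(leaves)} leaf terms but the disease layout needs {need}; "
            "increase n_terms or reduce n_diseases"
        )
    blocks = [leaves[i * _TERMS_PER_DISEASE : (i + 1) * _TERMS_PER_DISEASE] for i in range(spec.n_diseases)]
    # one "hub" weak term per group, annotated to every disease in the group,
    # so each disease has many overlapping distractor diseases
    hub_terms = leaves[need_block : need_block + n_groups]
    incidental_pool = leaves[need_block + n_groups : need]

    # -- genes ------------------------------------------------------------
    all_genes = [f"ENSG{j:08d}" for j in range(spec.n_genes)]
    disease_genes = all_genes[: spec.n_diseases]
    n_nondisease = int(spec.fraction_nondisease * spec.n_genes)
    nondisease_genes = all_genes[spec.n_diseases : spec.n_diseases + n_nondisease]
    other_genes = all_genes[spec.n_diseases + n_nondisease :]
    flags_genes = other_genes[:5]

    # -- novelty planting --------------------------------------------------
    quotas = {NoveltyCategory(k): v for k, v in spec.novelty_quotas.items()}
    order: List[NoveltyCategory] = []
    for cat, count in sorted(quotas.items(), key=lambda kv: kv[0].value):
        order.extend([cat] * count)
    categories = [NoveltyCategory.KNOWN_DISEASE_KNOWN_GENE] * (spec.n_diseases - len(order)) + order
    anchors = [i for i, c in enumerate(categories) if c is NoveltyCategory.KNOWN_DISEASE_KNOWN_GENE]

    # -- disease records ---------------------------------------------------
    diseases: Dict[str, DiseaseRecord] = {}
    gene_disease_dates: Dict[Tuple[str, str], dt.date] = {}
    age_choices = list(AgeCategory)
    extra_causal: Dict[int, List[str]] = {}

    for i in range(spec.n_diseases):
        did = f"ORPHA:{i + 1:05d}"
        block = blocks[i]
        phen = {
            block[0]: 1.0,  # obligate
            block[1]: 0.895,  # strong
            block[2]: 0.545,  # moderate
            block[3]: 0.17,  # weak
            block[4]: 0.17,  # weak
            block[5]: 0.0,  # excluded
            hub_terms[group_of[i]]: 0.17,  # weak, shared group-wide
        }
        n_ages = 1 + int(rng.integers(3))
        ages = frozenset(
            AgeCategory(str(a)) for a in rng.choice([c.value for c in age_choices], size=n_ages, replace=False)
        )
        cat = categories[i]
        disease_date = (
            NOVEL_DATE
            if cat in (NoveltyCategory.NOVEL_DISEASE_KNOWN_GENE, NoveltyCategory.NOVEL_DISEASE_UNDISCOVERED_GENE)
            else KNOWN_DATE
        )
        edge_date = KNOWN_DATE if cat is NoveltyCategory.KNOWN_DISEASE_KNOWN_GENE else NOVEL_DATE
        gene = disease_genes[i]
        gene_disease_dates[(gene, did)] = edge_date
        diseases[did] = DiseaseRecord(
            id=did,
            name=f"synthetic disorder {i + 1}",
            causal_genes=frozenset({gene}),
            phenotypes=phen,
            age_ranges=ages,
            classification=Classification.DISORDER,
            discovery_date=disease_date,
        )
        if cat in (NoveltyCategory.KNOWN_DISEASE_NEW_GENE_LINK, NoveltyCategory.NOVEL_DISEASE_KNOWN_GENE):
            # make this disease's gene a pre-timestamp causal gene of an anchor
            anchor = anchors[i % len(anchors)]
            extra_causal.setdefault(anchor, []).append(gene)

    for anchor, genes in extra_causal.items():
        did = f"ORPHA:{anchor + 1:05d}"
        rec = diseases[did]
        diseases[did] = DiseaseRecord(
            id=rec.id,
            name=rec.name,
            causal_genes=rec.causal_genes | frozenset(genes),
            phenotypes=dict(rec.phenotypes),
            age_ranges=rec.age_ranges,
            classification=rec.classification,
            discovery_date=rec.discovery_date,
        )
        for g in genes:
            gene_disease_dates[(g, did)] = ANCHOR_DATE

    # -- gene-phenotype annotations ---------------------------------------
    gene_phenotypes: Dict[str, Set[str]] = {}
    for i in range(spec.n_diseases):
        # disease gene annotated to its disease's non-excluded terms
        rec = diseases[f"ORPHA:{i + 1:05d}"]
        gene_phenotypes[disease_genes[i]] = {t for t, p in rec.phenotypes.items() if p > 0}
        # three dedicated module-3 genes per disease, each annotated to a
        # distinct nonempty strict subset of the disease's weak terms
        w1, w2 = blocks[i][3], blocks[i][4]
        for g3, subset in zip(nondisease_genes[3 * i : 3 * i + 3], ({w1}, {w2}, {w1, w2})):
            gene_phenotypes[g3] = set(subset)
    for g in nondisease_genes[3 * spec.n_diseases :]:
        k = 1 + int(rng.integers(2))
        idx = rng.choice(len(incidental_pool), size=min(k, len(incidental_pool)), replace=False)
        gene_phenotypes[g] = {incidental_pool[int(x)] for x in idx}

    # -- expression: latent tissue programs --------------------------------
    n_programs = 4
    programs = rng.gamma(shape=2.0, scale=50.0, size=(n_programs, spec.n_tissues))
    assign = rng.integers(n_programs, size=spec.n_genes)
    noise = rng.gamma(shape=2.0, scale=5.0, size=(spec.n_genes, spec.n_tissues))
    expr_mat = programs[assign] * rng.uniform(0.5, 1.5, size=(spec.n_genes, 1)) + noise
    expression = pd.DataFrame(
        expr_mat, index=pd.Index(all_genes, name="gene_id"),
        columns=[f"tissue_{t}" for t in range(spec.n_tissues)],
    )

    # -- gene-gene network: ring plus random chords ------------------------
    edges = [(all_genes[j], all_genes[(j + 1) % spec.n_genes]) for j in range(spec.n_genes)]
    n_chords = 2 * spec.n_genes
    for _ in range(n_chords):
        a, b = rng.integers(spec.n_genes, size=2)
        if a != b:
            edges.append((all_genes[int(a)], all_genes[int(b)]))

    # -- flags -------------------------------------------------------------
    flags = {g: c for g, c in zip(flags_genes, (300, 150, 100, 60, 30))}

    # -- claims: Zipf decay per age stratum --------------------------------
    claim_pool = leaves[:need]  # all disease-block, hub and incidental terms
    rows = []
    for cat in AgeCategory:
        size = min(spec.claims_vocab_size, len(claim_pool))
        idx = rng.choice(len(claim_pool), size=size, replace=False)
        vocab = sorted(claim_pool[int(x)] for x in idx)
        prevs = _zipf_prevalences(size)
        perm = rng.permutation(size)
        for t, p in zip(vocab, prevs[perm]):
            rows.append({"stratum": cat.value, "term_id": t, "prevalence": float(p)})
    claims = pd.DataFrame(rows, columns=["stratum", "term_id", "prevalence"])

    kg = KnowledgeGraph(
        ontology=onto,
        diseases=diseases,
        gene_disease_dates=gene_disease_dates,
        gene_phenotypes=gene_phenotypes,
        gene_gene=edges,
        nondisease_genes=nondisease_genes,
        flags=flags,
        expression=expression,
        claims=claims,
        timestamp=TIMESTAMP,
    )
    audit_viability(kg)
    return kg


def audit_viability(kg: KnowledgeGraph) -> None:
    """Check that every simulatable disease can feed all six modules.

    Raises ``ValueError`` naming the first disease and module that fail.
    """
    from .distractors import DistractorEngine
    from .kg import select_simulatable_diseases

    engine = DistractorEngine(kg)
    if not kg.flags:
        raise ValueError("viability: flags table is empty (module 6)")
    n_expr = 0 if kg.expression.empty else len(kg.expression)
    if n_expr < 100:
        raise ValueError(f"viability: only {n_expr} genes have expression vectors (module 5 wants >= 100)")
    for d in select_simulatable_diseases(kg):
        checks = {
            "module 1 (phenotypically similar)": engine._eligible_similar(d),
            "module 2 (phenotypically distinct)": engine._eligible_distinct(d),
            "module 3 (insufficiently explanatory)": engine._eligible_insufficient(d),
            "module 4 (incidental phenotype)": engine._eligible_incidental(d),
        }
        for label, pool in checks.items():
            if not pool:
                raise ValueError(f"viability: disease {d.id} has no candidates for {label}")
        for g in d.causal_genes:
            if kg.expression.empty or g not in kg.expression.index:
                raise ValueError(f"viability: causal gene {g} of {d.id} lacks an expression vector")


# -- writers --------------------------------------------------------------

def _write_obo(onto: Ontology, path: Path) -> None:
    lines = ["format-version: 1.2", ""]
    for tid in sorted(onto.terms):
        lines.append("[Term]")
        lines.append(f"id: {tid}")
        name = onto.name(tid)
        if name:
            lines.append(f"name: {name}")
        for p in sorted(onto.parents(tid)):
            lines.append(f"is_a: {p} ! {onto.name(p)}")
        lines.append("")
    path.write_text("\n".join(lines), encoding="utf-8")


def write_knowledge_base(kg: KnowledgeGraph, outdir: str | Path) -> Path:
    """Write the knowledge graph as the TSV/OBO dialects the loaders read.

    Output is deterministic (sorted rows), so identical graphs produce
    byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_obo(kg.ontology, outdir / "ontology.obo")

    disease_rows = []
    dp_rows = []
    for did in sorted(kg.diseases):
        d = kg.diseases[did]
        disease_rows.append(
            {
                "disease_id": d.id,
                "name": d.name,
                "classification": d.classification.value,
                "parent_id": d.parent_id or "",
                "date": d.discovery_date.isoformat() if d.discovery_date else "",
                "age_ranges": ";".join(sorted(a.value for a in d.age_ranges)),
            }
        )
        for t in sorted(d.phenotypes):
            dp_rows.append({"disease_id": d.id, "term_id": t, "prevalence": repr(d.phenotypes[t])})
    pd.DataFrame(disease_rows).to_csv(outdir / "diseases.tsv", sep="\t", index=False)
    pd.DataFrame(dp_rows, columns=["disease_id", "term_id", "prevalence"]).to_csv(
        outdir / "disease_phenotype.tsv", sep="\t", index=False
    )

    gd_rows = [
        {"gene_id": g, "disease_id": d, "date": date.isoformat()}
        for (g, d), date in sorted(kg.gene_disease_dates.items())
    ]
    pd.DataFrame(gd_rows, columns=["gene_id", "disease_id", "date"]).to_csv(
        outdir / "gene_disease.tsv", sep="\t", index=False
    )

    gp_rows = [
        {"gene_id": g, "term_id": t}
        for g in sorted(kg.gene_phenotypes)
        for t in sorted(kg.gene_phenotypes[g])
    ]
    pd.DataFrame(gp_rows, columns=["gene_id", "term_id"]).to_csv(
        outdir / "gene_phenotype.tsv", sep="\t", index=False
    )

    gg_rows = [{"gene1": a, "gene2": b} for a, b in sorted(map(lambda e: tuple(sorted(e)), kg.gene_gene.edges))]
    pd.DataFrame(gg_rows, columns=["gene1", "gene2"]).to_csv(outdir / "gene_gene.tsv", sep="\t", index=False)

    pd.DataFrame({"gene_id": sorted(kg.nondisease_genes)}).to_csv(
        outdir / "nondisease_genes.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [{"gene_id": g, "rare_variant_count": c} for g, c in sorted(kg.flags.items())],
        columns=["gene_id", "rare_variant_count"],
    ).to_csv(outdir / "flags.tsv", sep="\t", index=False)

    kg.expression.sort_index().to_csv(outdir / "expression.tsv", sep="\t", float_format="%.6f")
    kg.claims.sort_values(["stratum", "term_id"]).to_csv(outdir / "claims.tsv", sep="\t", index=False)
    return outdir
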