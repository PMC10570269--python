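"""Cohort-level evaluation: novelty-stratified top-k reports, ablation
grids, phenotype-based patient retrieval and gene-network distance checks.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from pathlib import Path
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .kg import KnowledgeGraph
from .patient import SimulatedPatient
from .ranking import PhenomizerScorer, PhrankScorer, RankingResult, _causal_rank
from .simulate import SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "make_scorer",
    "ExternalScorer",
    "evaluate_cohort",
    "ablation_report",
    "ablation_arms",
    "jaccard_retrieval",
    "network_distance_comparison",
]

Scorer = Callable[[SimulatedPatient], RankingResult]


class ExternalScorer:
    """Ranks candidates from an externally produced per-patient score TSV.

    The TSV has columns ``patient_id``, ``gene``, ``score``; genes missing
    from the file score 0.  This lets rankings from tools that are not
    re-implemented here be ingested and reported identically.
    """

    def __init__(self, path: str | Path, name: Optional[str] = None):
        df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "gene": str})
        required = {"patient_id", "gene", "score"}
        if not required <= set(df.columns):
            raise ValueError(f"external score file must have columns {sorted(required)}")
        self.name = name or f"external:{Path(path).name}"
        self._scores: Dict[Tuple[str, str], float] = {
            (r.patient_id, r.gene): float(r.score) for r in df.itertuples(index=False)
        }

    def rank(self, patient: SimulatedPatient) -> RankingResult:
        genes = patient.candidate_genes()
        scores = [self._scores.get((patient.id, g), 0.0) for g in genes]
        return RankingResult(
            patient_id=patient.id,
            genes=genes,
            scores=scores,
            causal_rank=_causal_rank(genes, scores, patient.true_gene),
            scorer=self.name,
        )

    __call__ = rank


def make_scorer(kg: KnowledgeGraph, name: str, **kwargs) -> Scorer:
    """Scorer factory: ``phrank-disease``, ``phrank-gene``, ``phenomizer``
    or ``external:<path>``."""
    if name == "phrank-disease":
        return PhrankScorer(kg, mode="disease", **kwargs)
    if name == "phrank-gene":
        return PhrankScorer(kg, mode="gene", **kwargs)
    if name == "phenomizer":
        return PhenomizerScorer(kg, **kwargs)
    if name.startswith("external:"):
        return ExternalScorer(name.split(":", 1)[1])
    raise ValueError(f"unknown scorer {name!r}")


def evaluate_cohort(
    patients: Sequence[SimulatedPatient],
    scorer: Scorer,
    k_list: Sequence[int] = (1, 3, 5, 10),
    by_novelty: bool = True,
    n_random_rankings: int = 10,
    baseline_seed: int = 0,
) -> pd.DataFrame:
    """Rank every patient and report top-k fractions and mean causal rank.

    One row per novelty category plus an ``overall`` row.  The random
    baseline is the average fraction of patients whose causal gene lands in
    the top 10 across ``n_random_rankings`` seeded random permutations of
    each patient's candidate list.
    """
    rows = []
    baseline_rng = np.random.default_rng(baseline_seed)
    for p in patients:
        if len(p.candidates) < 2:
            raise ValueError(f"patient {p.id} has fewer than 2 candidates")
        result = scorer(p)
        n = len(p.candidates)
        causal_idx = p.candidate_genes().index(p.true_gene)
        random_top10 = np.mean(
            [int(baseline_rng.permutation(n)[causal_idx] < 10) for _ in range(n_random_rankings)]
        )
        rows.append(
            {
                "patient_id": p.id,
                "category": p.novelty.value if p.novelty else "unclassified",
                "rank": result.causal_rank,
                "n_candidates": n,
                "random_top10": random_top10,
            }
        )
    per_patient = pd.DataFrame(rows)

    def summarise(group: pd.DataFrame, label: str) -> dict:
        out = {
            "category": label,
            "n_patients": len(group),
            "mean_rank": group["rank"].mean(),
            "random_baseline_top10": group["random_top10"].mean(),
        }
        for k in k_list:
            out[f"top_{k}"] = float((group["rank"] <= k).mean())
        return out

    summary = [summarise(per_patient, "overall")]
    if by_novelty:
        for cat, grp in per_patient.groupby("category", sort=True):
            summary.append(summarise(grp, str(cat)))
    report = pd.DataFrame(summary)
    report.attrs["per_patient"] = per_patient
    return report


# -- ablation grid --------------------------------------------------------

def ablation_arms(grid: str = "fig5") -> Dict[str, Dict]:
    """Named configuration overrides for the ablation study.

    Every arm uses uniform module weights.  ``none`` disables all phenotype
    alteration and all distractor modules (their slots are randomly
    backfilled, keeping candidate counts intact); ``phenotype_only`` keeps
    only the phenotype-altering components; ``distractors_only`` keeps only
    the distractor modules (with their phenotype side-effects);
    ``gene_only_distractors`` strips the side-effects; single-component and
    leave-one-module-out arms complete the grid.
    """
    off = dict(dropout=False, obfuscation=False, noise=False, distractor_phenotypes=False)
    no_modules = dict(module_enabled=(False,) * 6)
    arms: Dict[str, Dict] = {
        "none": {**off, **no_modules},
        "phenotype_only": {**no_modules, "distractor_phenotypes": False},
        "distractors_only": {**off, "distractor_phenotypes": True},
        "gene_only_distractors": {**off},
        "full": {},
    }
    if grid == "fig5":
        arms.update(
            {
                "dropout_only": {**off, **no_modules, "dropout": True},
                "obfuscation_only": {**off, **no_modules, "obfuscation": True},
                "noise_only": {**off, **no_modules, "noise": True},
            }
        )
        for i in range(6):
            enabled = tuple(j != i for j in range(6))
            arms[f"without_module_{i + 1}"] = {"module_enabled": enabled}
    elif grid != "basic":
        raise ValueError(f"unknown ablation grid {grid!r}")
    return arms


def ablation_report(
    kg: KnowledgeGraph,
    base_config: SimulationConfig,
    scorer_name: str = "phrank-disease",
    grid: str = "fig5",
    seeds: Sequence[int] = (0,),
    k_list: Sequence[int] = (1, 3, 5, 10),
) -> pd.DataFrame:
    """Simulate matched cohorts under each ablation arm and rank them.

    Arms share per-seed random substreams (same master seed), and all arms
    use uniform module sampling probabilities.  Reports the mean causal
    rank (averaged over seeds) and top-k fractions per arm.
    """
    scorer = make_scorer(kg, scorer_name)
    rows = []
    for arm, overrides in ablation_arms(grid).items():
        ranks: List[float] = []
        topk_acc = {k: [] for k in k_list}
        for seed in seeds:
            config = replace(base_config, seed=seed, uniform_module_weights=True, **overrides)
            patients = list(simulate_cohort(kg, config))
            results = [scorer(p).causal_rank for p in patients]
            ranks.extend(results)
            for k in k_list:
                topk_acc[k].append(float(np.mean([r <= k for r in results])))
        row = {"arm": arm, "mean_rank": float(np.mean(ranks)), "n_patients": len(ranks)}
        for k in k_list:
            row[f"top_{k}"] = float(np.mean(topk_acc[k]))
        rows.append(row)
    return pd.DataFrame(rows)


# -- cohort-comparison statistics -----------------------------------------

def jaccard_retrieval(
    query_patients: Sequence[SimulatedPatient],
    reference_patients: Sequence[SimulatedPatient],
    seed: int = 0,
) -> pd.DataFrame:
    """Same-disease retrieval curves under Jaccard vs random ranking.

    For each query patient the references are ranked by Jaccard similarity
    of positive phenotype sets (and, separately, randomly); the output
    gives, per rank r, the fraction of queries for which a same-disease
    reference appears within the top r.
    """
    rng = np.random.default_rng(seed)
    n_ref = len(reference_patients)
    first_match_jac: List[float] = []
    first_match_rand: List[float] = []
    for q in query_patients:
        sims = []
        for r in reference_patients:
            union = q.positives | r.positives
            sims.append(len(q.positives & r.positives) / len(union) if union else 0.0)
        order = sorted(range(n_ref), key=lambda i: (-sims[i], reference_patients[i].id))
        match_ranks = [
            pos + 1
            for pos, i in enumerate(order)
            if reference_patients[i].disease_id == q.disease_id
        ]
        first_match_jac.append(min(match_ranks) if match_ranks else np.inf)
        rand_order = rng.permutation(n_ref)
        rand_ranks = [
            pos + 1
            for pos, i in enumerate(rand_order)
            if reference_patients[int(i)].disease_id == q.disease_id
        ]
        first_match_rand.append(min(rand_ranks) if rand_ranks else np.inf)
    ranks = np.arange(1, n_ref + 1)
    jac = np.array([(np.array(first_match_jac) <= r).mean() for r in ranks])
    rand = np.array([(np.array(first_match_rand) <= r).mean() for r in ranks])
    return pd.DataFrame({"rank": ranks, "frac_jaccard": jac, "frac_random": rand})


def network_distance_comparison(
    patients_a: Sequence[SimulatedPatient],
    patients_b: Sequence[SimulatedPatient],
    network: nx.Graph,
) -> dict:
    """Compare noncausal-to-causal shortest-path distance distributions.

    For each patient, the BFS distance from every noncausal candidate to
    the causal gene is collected; candidates unreachable from the causal
    gene are tallied as ``disconnected`` and patients whose causal gene is
    absent from the network are skipped (and counted).  The two pooled
    finite-distance samples are compared with a two-sample KS test.
    """

    def pool(patients: Sequence[SimulatedPatient]) -> Tuple[List[int], int, int]:
        distances: List[int] = []
        disconnected = 0
        skipped = 0
        for p in patients:
            if p.true_gene not in network:
                skipped += 1
                continue
            lengths = nx.single_source_shortest_path_length(network, p.true_gene)
            for g in p.candidate_genes():
                if g == p.true_gene:
                    continue
                if g in lengths:
                    distances.append(int(lengths[g]))
                else:
                    disconnected += 1
        return distances, disconnected, skipped

    dist_a, disc_a, skip_a = pool(patients_a)
    dist_b, disc_b, skip_b = pool(patients_b)
    if dist_a and dist_b:
        stat = ks_2samp(dist_a, dist_b)
        ks_statistic, ks_p = float(stat.statistic), float(stat.pvalue)
    else:
        ks_statistic, ks_p = float("nan"), float("nan")
    return {
        "distances_a": dist_a,
        "distances_b": dist_b,
        "disconnected_a": disc_a,
        "disconnected_b": disc_b,
        "skipped_a": skip_a,
        "skipped_b": skip_b,
        "ks_statistic": ks_statistic,
        "ks_pvalue": ks_p,
    }
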