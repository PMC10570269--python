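"""Distractor gene modules: eligibility logic, side-effects, budgets."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from conftest import build_kg
from mendelsim.distractors import (
    DistractorEngine,
    DistractorParams,
    NoCandidate,
    sample_budgets,
)
from mendelsim.kg import AgeCategory, PrevalenceBucket
from mendelsim.patient import Provenance, SimulatedPatient


def make_patient(disease_id, gene, positives=(), negatives=()):
    return SimulatedPatient(
        id="p0",
        disease_id=disease_id,
        true_gene=gene,
        age=AgeCategory.ADULT,
        positives=set(positives),
        negatives=set(negatives),
        candidates=[(gene, Provenance.CAUSAL)],
    )


class TestBudgets:
    def test_lambda_zero_yields_one_noncausal(self, rng):
        n, slots = sample_budgets(DistractorParams(lambda_genes=0), rng)
        assert n == 1 and len(slots) == 1

    def test_poisson_mean(self):
        rng = np.random.default_rng(2)
        params = DistractorParams(lambda_genes=12)
        draws = [sample_budgets(params, rng)[0] for _ in range(10_000)]
        assert abs(np.mean(draws) - 13.0) < 0.2

    def test_degenerate_weights_hit_one_module(self, rng):
        params = DistractorParams(module_weights=(1, 0, 0, 0, 0, 0))
        _, slots = sample_budgets(params, rng)
        assert set(slots) == {0}

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            DistractorParams(module_weights=(0.5, 0.5, 0.5, 0, 0, 0))


def alstrom_wolfram_kg():
    """Target disease with 5 terms overlapping a 38-term distractor disease
    (5 strong + 33 weak, no obligate/excluded); 3 of the 5 overlapping terms
    are weak for the distractor."""
    strong = {f"s{i}": 0.9 for i in range(5)}
    weak = {f"w{i}": 0.1 for i in range(33)}
    distractor_phens = {**strong, **weak}
    # overlap: 3 weak (w0..w2) + 2 strong (s0, s1); plus target-only terms
    target_phens = {"w0": 0.5, "w1": 0.5, "w2": 0.5, "s0": 0.5, "s1": 0.5, "u0": 1.0, "u1": 0.2}
    return build_kg(
        {
            "D:WOLF": {"genes": {"G_WFS"}, "phenotypes": target_phens},
            "D:ALST": {"genes": {"G_ALMS"}, "phenotypes": distractor_phens},
        }
    )


class TestPhenotypicallySimilar:
    def test_all_weak_clause_grants_eligibility(self):
        kg = alstrom_wolfram_kg()
        engine = DistractorEngine(kg)
        pairs = engine._eligible_similar(kg.diseases["D:WOLF"])
        assert ("D:ALST", "G_ALMS") in pairs

    def test_all_weak_path_side_effects(self, rng):
        """Without obligate/excluded terms, only weak overlapping terms join
        the positives and strong non-overlapping terms join the negatives."""
        kg = alstrom_wolfram_kg()
        engine = DistractorEngine(kg)
        dist = kg.diseases["D:ALST"]
        weak_overlap = {"w0", "w1", "w2"}
        strong_nonoverlap = {"s2", "s3", "s4"}
        for _ in range(50):
            p = make_patient("D:WOLF", "G_WFS")
            res = engine.phenotypically_similar_distractor(p, kg.diseases["D:WOLF"], rng)
            assert res.gene == "G_ALMS"
            assert res.pos_added and res.pos_added <= weak_overlap
            assert res.neg_added and res.neg_added <= strong_nonoverlap

    def test_contradiction_terms_have_extreme_prevalence(self, rng):
        """Excluded terms added to positives have distractor prevalence 0;
        obligate terms added to negatives have prevalence 1."""
        kg = build_kg(
            {
                "D:T": {"genes": {"GT"}, "phenotypes": {"shared": 0.5, "t1": 1.0}},
                "D:X": {
                    "genes": {"GX"},
                    "phenotypes": {"shared": 0.5, "ob1": 1.0, "ob2": 1.0, "ex1": 0.0, "ex2": 0.0},
                },
            }
        )
        engine = DistractorEngine(kg)
        dist = kg.diseases["D:X"]
        for _ in range(100):
            p = make_patient("D:T", "GT")
            res = engine.phenotypically_similar_distractor(p, kg.diseases["D:T"], rng)
            for t in res.pos_added - {"shared"}:
                assert dist.phenotypes[t] == 0.0
            for t in res.neg_added:
                assert dist.phenotypes[t] == 1.0
            assert not (res.pos_added & res.neg_added)

    def test_single_eligible_pair_always_selected(self, rng):
        kg = alstrom_wolfram_kg()
        engine = DistractorEngine(kg)
        p = make_patient("D:WOLF", "G_WFS")
        genes = {
            engine.phenotypically_similar_distractor(p, kg.diseases["D:WOLF"], rng).gene
            for _ in range(20)
        }
        assert genes == {"G_ALMS"}

    def test_no_overlap_means_no_candidate(self, rng):
        kg = build_kg(
            {
                "D:A": {"genes": {"GA"}, "phenotypes": {"a": 1.0}},
                "D:B": {"genes": {"GB"}, "phenotypes": {"b": 1.0}},
            }
        )
        engine = DistractorEngine(kg)
        with pytest.raises(NoCandidate):
            engine.phenotypically_similar_distractor(
                make_patient("D:A", "GA"), kg.diseases["D:A"], rng
            )


class TestPhenotypicallyDistinct:
    def kb(self):
        return build_kg(
            {
                "D:A": {"genes": {"GA"}, "phenotypes": {"a1": 1.0, "a2": 0.5}},
                "D:B": {"genes": {"GB"}, "phenotypes": {"a1": 0.5, "b1": 1.0}},  # overlaps A
                "D:C": {"genes": {"GC"}, "phenotypes": {"c1": 1.0}},  # disjoint from A
            }
        )

    def test_only_disjoint_disease_gene_qualifies(self, rng):
        kg = self.kb()
        engine = DistractorEngine(kg)
        res = engine.phenotypically_distinct_distractor(
            make_patient("D:A", "GA"), kg.diseases["D:A"], rng
        )
        assert res.gene == "GC"
        assert not res.pos_added and not res.neg_added

    def test_never_returns_causal_gene(self, rng):
        """The causal gene's own disease overlaps itself, so it never
        qualifies, even without explicit exclusion."""
        kg = self.kb()
        engine = DistractorEngine(kg)
        for d in ("D:A", "D:B", "D:C"):
            genes = engine._eligible_distinct(kg.diseases[d])
            assert not (set(genes) & kg.diseases[d].causal_genes)

    def test_sibling_terms_count_as_non_overlapping(self, rng):
        """Overlap uses raw annotated term sets, not ancestor closures."""
        kg = self.kb()
        # a1 and c1 share mid-level ancestry in the flat ontology, yet D:C
        # still qualifies as disjoint from D:A
        engine = DistractorEngine(kg)
        assert engine._eligible_distinct(kg.diseases["D:A"]) == ["GC"]


class TestInsufficientlyExplanatory:
    def kb(self):
        return build_kg(
            {
                "D:A": {
                    "genes": {"GA"},
                    "phenotypes": {"ob": 1.0, "w1": 0.1, "w2": 0.1, "w3": 0.1},
                }
            },
            gene_phenotypes={
                "N_sub": {"w1"},  # strict subset of weak terms
                "N_all": {"w1", "w2", "w3"},  # not strict
                "N_off": {"ob"},  # not weak terms
            },
            nondisease_genes={"N_sub", "N_all", "N_off"},
        )

    def test_strict_subset_eligibility(self, rng):
        kg = self.kb()
        engine = DistractorEngine(kg)
        assert engine._eligible_insufficient(kg.diseases["D:A"]) == ["N_sub"]

    def test_skips_phenotype_addition_when_any_term_already_positive(self, rng):
        kg = self.kb()
        engine = DistractorEngine(kg)
        p = make_patient("D:A", "GA", positives={"w1"})
        res = engine.insufficiently_explanatory_distractor(p, kg.diseases["D:A"], rng)
        assert res.gene == "N_sub" and not res.pos_added

    def test_adds_gene_terms_when_none_present(self, rng):
        kg = self.kb()
        engine = DistractorEngine(kg)
        p = make_patient("D:A", "GA", positives={"ob"})
        res = engine.insufficiently_explanatory_distractor(p, kg.diseases["D:A"], rng)
        assert res.pos_added == {"w1"}

    def test_chosen_genes_never_causal(self, default_kg, rng):
        engine = DistractorEngine(default_kg)
        causal = {g for d in default_kg.diseases.values() for g in d.causal_genes}
        for d in list(default_kg.diseases.values())[:10]:
            for g in engine._eligible_insufficient(d):
                assert g not in causal


class TestIncidentalPhenotype:
    def kb(self):
        return build_kg(
            {"D:A": {"genes": {"GA"}, "phenotypes": {"a1": 1.0, "a2": 0.5}}},
            gene_phenotypes={
                "N_clean": {"x1", "x2"},  # no overlap with D:A
                "N_dirty": {"a1", "x3"},  # shares a term
            },
            nondisease_genes={"N_clean", "N_dirty"},
        )

    def test_overlapping_gene_ineligible(self, rng):
        kg = self.kb()
        engine = DistractorEngine(kg)
        assert engine._eligible_incidental(kg.diseases["D:A"]) == ["N_clean"]

    def test_lambda_zero_adds_one_term_from_annotations(self):
        kg = self.kb()
        engine = DistractorEngine(kg, DistractorParams(lambda_phenotypes=0))
        rng = np.random.default_rng(0)
        res = engine.incidental_phenotype_distractor(
            make_patient("D:A", "GA"), kg.diseases["D:A"], rng
        )
        assert len(res.pos_added) == 1
        assert res.pos_added <= {"x1", "x2"}


class TestSimilarlyExpressed:
    def kb(self):
        genes = [f"G{i}" for i in range(10)]
        mat = np.abs(np.random.default_rng(1).normal(size=(10, 4))) + 0.1
        mat[1] = mat[0]  # G1 identical to causal G0
        mat[2] = 0.0  # G2 all-zero expression
        expr = pd.DataFrame(mat, index=pd.Index(genes, name="gene_id"),
                            columns=[f"ts{i}" for i in range(4)])
        return build_kg(
            {"D:A": {"genes": {"G0"}, "phenotypes": {"a": 1.0}}},
            expression=expr,
        )

    def test_identical_vector_gets_top_similarity(self):
        kg = self.kb()
        engine = DistractorEngine(kg)
        genes, sims = engine._expression_neighbours("G0", kg.diseases["D:A"])
        assert genes[0] == "G1"
        assert sims[0] == pytest.approx(1.0)

    def test_zero_vector_has_zero_similarity(self):
        kg = self.kb()
        engine = DistractorEngine(kg)
        genes, sims = engine._expression_neighbours("G0", kg.diseases["D:A"])
        assert sims[genes.index("G2")] == pytest.approx(0.0)

    def test_selection_frequencies_proportional_to_similarity(self):
        """Over 10,000 draws, per-gene selection frequencies match the exact
        categorical probabilities within 2 points."""
        kg = self.kb()
        engine = DistractorEngine(kg)
        genes, sims = engine._expression_neighbours("G0", kg.diseases["D:A"])
        expected = sims / sims.sum()
        rng = np.random.default_rng(3)
        p = make_patient("D:A", "G0")
        counts = Counter(
            engine.similarly_expressed_distractor(p, kg.diseases["D:A"], rng).gene
            for _ in range(10_000)
        )
        for g, e in zip(genes, expected):
            assert abs(counts[g] / 10_000 - e) < 0.02

    def test_missing_causal_gene_is_no_candidate(self, rng):
        kg = self.kb()
        engine = DistractorEngine(kg)
        with pytest.raises(NoCandidate):
            engine.similarly_expressed_distractor(
                make_patient("D:A", "G_absent"), kg.diseases["D:A"], rng
            )

    def test_no_phenotype_side_effects(self, rng):
        kg = self.kb()
        engine = DistractorEngine(kg)
        res = engine.similarly_expressed_distractor(
            make_patient("D:A", "G0"), kg.diseases["D:A"], rng
        )
        assert not res.pos_added and not res.neg_added


class TestFalsePositive:
    def test_single_gene_table(self, rng):
        kg = build_kg({"D:A": {"genes": {"GA"}, "phenotypes": {"a": 1.0}}}, flags={"F1": 10})
        assert DistractorEngine(kg).false_positive_distractor(rng).gene == "F1"

    def test_draw_frequency_proportional_to_counts(self):
        kg = build_kg(
            {"D:A": {"genes": {"GA"}, "phenotypes": {"a": 1.0}}}, flags={"F1": 300, "F2": 100}
        )
        engine = DistractorEngine(kg)
        rng = np.random.default_rng(4)
        hits = sum(engine.false_positive_distractor(rng).gene == "F1" for _ in range(10_000))
        assert abs(hits / 10_000 - 0.75) < 0.02

    def test_zero_count_gene_never_chosen(self, rng):
        kg = build_kg(
            {"D:A": {"genes": {"GA"}, "phenotypes": {"a": 1.0}}}, flags={"F1": 50, "F0": 0}
        )
        engine = DistractorEngine(kg)
        assert all(engine.false_positive_distractor(rng).gene == "F1" for _ in range(100))

    def test_empty_table_is_no_candidate(self, rng):
        kg = build_kg({"D:A": {"genes": {"GA"}, "phenotypes": {"a": 1.0}}})
        with pytest.raises(NoCandidate):
            DistractorEngine(kg).false_positive_distractor(rng)


class TestAttachDistractors:
    def fresh_patient(self, kg, disease_id):
        d = kg.diseases[disease_id]
        gene = sorted(d.causal_genes)[0]
        p = make_patient(disease_id, gene)
        p.positives = {t for t, pv in d.phenotypes.items() if pv >= 0.5}
        p.negatives = {t for t, pv in d.phenotypes.items() if pv < 0.5}
        return p

    def test_gene_only_mode_leaves_phenotypes_untouched(self, default_kg):
        engine = DistractorEngine(default_kg, DistractorParams(gene_only=True))
        p = self.fresh_patient(default_kg, "ORPHA:00001")
        pos, neg = set(p.positives), set(p.negatives)
        engine.attach_distractors(p, np.random.default_rng(0))
        assert p.positives == pos and p.negatives == neg

    def test_candidates_unique_and_contain_causal(self, default_kg):
        engine = DistractorEngine(default_kg)
        for seed in range(5):
            p = self.fresh_patient(default_kg, "ORPHA:00003")
            engine.attach_distractors(p, np.random.default_rng(seed))
            p.check_invariants()

    def test_candidate_count_is_two_plus_budget(self, default_kg):
        engine = DistractorEngine(default_kg, DistractorParams(lambda_genes=0))
        p = self.fresh_patient(default_kg, "ORPHA:00002")
        engine.attach_distractors(p, np.random.default_rng(1))
        assert len(p.candidates) == 2

    def test_all_weight_on_flags_module(self, default_kg):
        params = DistractorParams(module_weights=(0, 0, 0, 0, 0, 1), lambda_genes=0)
        engine = DistractorEngine(default_kg, params)
        for seed in range(10):
            p = self.fresh_patient(default_kg, "ORPHA:00001")
            engine.attach_distractors(p, np.random.default_rng(seed))
            labels = {lab for g, lab in p.candidates if lab != Provenance.CAUSAL}
            assert labels == {Provenance.FALSE_POSITIVE}

    def test_disabled_modules_backfilled_keeping_length(self, default_kg):
        """Disabling a module replaces its slots with random genes without
        changing the candidate-list length."""
        for seed in range(5):
            p_full = self.fresh_patient(default_kg, "ORPHA:00004")
            p_ablate = self.fresh_patient(default_kg, "ORPHA:00004")
            DistractorEngine(default_kg).attach_distractors(
                p_full, np.random.default_rng(seed)
            )
            DistractorEngine(default_kg).attach_distractors(
                p_ablate, np.random.default_rng(seed), enabled_modules=(False,) * 6
            )
            assert len(p_full.candidates) == len(p_ablate.candidates)
            labels = {lab for g, lab in p_ablate.candidates if lab != Provenance.CAUSAL}
            assert labels <= {Provenance.RANDOM_BACKFILL}

    def test_only_modules_1_3_4_touch_phenotypes(self, default_kg, rng):
        """Modules 2, 5 and 6 never produce phenotype side-effects."""
        engine = DistractorEngine(default_kg)
        d = default_kg.diseases["ORPHA:00005"]
        p = self.fresh_patient(default_kg, "ORPHA:00005")
        for _ in range(30):
            for method in (
                engine.phenotypically_distinct_distractor,
                engine.similarly_expressed_distractor,
            ):
                res = method(p, d, rng)
                assert not res.pos_added and not res.neg_added
            res = engine.false_positive_distractor(rng)
            assert not res.pos_added and not res.neg_added

    def test_term_in_negatives_never_moved_to_positives(self, default_kg):
        """Side-effect terms already recorded as absent stay absent."""
        engine = DistractorEngine(default_kg)
        for seed in range(10):
            p = self.fresh_patient(default_kg, "ORPHA:00006")
            neg_before = set(p.negatives)
            engine.attach_distractors(p, np.random.default_rng(seed))
            assert neg_before <= p.negatives | set()  # nothing removed
            assert not (p.positives & neg_before)
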