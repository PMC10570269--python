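# Methods

This note documents the simulation model, its parameters and defaults, the
synthetic knowledge-base generator, and the numerical and design choices
made where the procedure left room for judgement.

## Patient model

A simulated patient is a tuple (age band, positive term set, negative term
set, candidate gene list, novelty label). Phenotype terms come from a rooted
DAG ontology; candidate genes carry a provenance label (causal, one of six
distractor modules, or random backfill). Sex and gender are not modelled and
no field is reserved for them. Patients are monogenic: exactly one causal
gene per patient, drawn uniformly when a disease has several known genes.

### Initialization

Each annotated term of the disease enters the positives with probability
P(term | disease) and the negatives otherwise, so at initialization the two
sets exactly partition the disease's annotation set. Frequency-class labels
in input tables are mapped to representative point prevalences at load time
(obligate 1.0, very frequent 0.895, frequent 0.545, occasional 0.17, very
rare 0.025, excluded 0.0) because Bernoulli sampling needs point
probabilities. Prevalence fractions are discretised into five buckets:
obligate (= 1), strong (0.80–0.99), weak (0.01–0.29), excluded (= 0), and a
moderate bucket for the remaining band (0.30–0.79 plus the hairline gaps at
the boundaries). The moderate bucket participates in overlap matching but
never in obligate/excluded contradiction logic.

Subtype records (clinical, etiological, histopathological) missing exactly
one of {causal genes, phenotype annotations} inherit the missing element
from their parent disease, along with the parent's association dates;
records missing both are left unfilled and excluded by the simulatability
filter (no "category" classification, ≥ 1 phenotype, ≥ 1 causal gene).

### Imprecision operators

Applied in the fixed order dropout → obfuscation → noise:

* **Dropout** removes each positive term with probability 0.7 and each
  negative with 0.2. Removal is unconditional and independent; a patient may
  lose all disease phenotypes and no re-draw is performed.
* **Obfuscation** replaces each surviving term, with probability 0.15 per
  set, by a uniformly chosen parent. Terms whose only parent is the root are
  left unchanged (coarsening to the root would erase all signal; when a term
  has several parents the root is likewise never chosen). A replacement
  already present in either set deduplicates — term sets are sets, and a
  term recorded as absent is never flipped to present.
* **Noise** adds 1 + Poisson(λ_pos) positive terms drawn without replacement
  with probability proportional to their prevalence in the patient's age
  stratum of a claims-derived table, and 1 + Poisson(λ_neg) negative terms
  uniformly from the same stratum's vocabulary, excluding terms already
  present. The 1+Poisson form mirrors the gene- and phenotype-budget
  convention used elsewhere in the pipeline; the claims source itself never
  states how many noise terms a real workup accrues, so λ is exposed in the
  configuration with a default of 2.0 per set, chosen so that noise
  contributes a realistic minority (~3 terms) of a patient's final
  annotations at fixture scale. Age strata are infant 0–1, child 2–11,
  adolescent 12–18, adult 19–64, senior 65+ years.

### Distractor modules

Each patient receives 1 + Poisson(λ_G) noncausal candidate genes; each slot
is assigned a module by a categorical draw over the weights
(0.33, 0.42, 0.05, 0.09, 0.08, 0.03). λ_G defaults to 12, putting the mean
candidate-list length at 14, the value reported for real undiagnosed-patient
workups. Phenotype additions inside modules use 1 + Poisson(λ_P) draws
without replacement, truncated to availability, with λ_P = 1.

1. **Phenotypically similar disease genes.** Eligible distractor diseases
   overlap the true disease on raw annotated term sets (no ancestor
   expansion — overlap counts are stated at the term level) and satisfy at
   least one of: ≥ 1 obligate term, ≥ 1 excluded term, or ≥ 1 weak
   overlapping term. The module adds overlapping terms to the positives
   (only the weak overlap in the third, "all-weak" case), then guarantees
   noncausality: excluded terms (prevalence 0) are planted into the
   positives and obligate terms (prevalence 1) into the negatives when they
   exist; otherwise strong non-overlapping terms go to the negatives.
2. **Phenotypically distinct disease genes.** Uniform draw among genes none
   of whose diseases shares a term with the true disease; no side-effects.
3. **Insufficiently explanatory genes.** Non-disease genes whose annotations
   form a nonempty strict subset of the true disease's weak-bucket terms.
   The gene's terms are added to the positives only when none of them is
   already positive — the conservative reading of "if none are already
   present" (skip entirely, rather than add the missing ones).
4. **Incidental-phenotype genes.** Non-disease genes annotated only to terms
   disjoint from the disease; some of their terms join the positives.
5. **Similarly expressed genes.** Expression is min-max normalised per
   tissue over all genes; candidates are the top-100 cosine-similarity
   neighbours of the causal gene, excluding the causal gene and any disease
   gene whose disease overlaps the true one, sampled with probability
   proportional to similarity. No side-effects.
6. **Common false positives.** Frequently-mutated genes drawn with
   probability proportional to their rare-variant counts. No side-effects.

Only modules 1, 3 and 4 may touch phenotype sets; a "gene-only" switch
suppresses all side-effects for ablation. Modules exclude genes already on
the candidate list at draw time, so a list never contains duplicates. A
module with no eligible gene triggers a redraw from the renormalised weights
of the enabled modules (up to 10 times), after which the slot is filled with
a uniform random gene labelled `random_backfill`; disabled modules are
backfilled directly. This keeps the candidate count at exactly 2 + N_G
(causal + 1 + N_G noncausal) regardless of ablation, which is what makes
module-removal comparisons fair. The final list is shuffled.

The per-slot module stream is interpreted as the source of *all* 1 + N_G
noncausal genes (total list length 2 + N_G): the budget definition is taken
as authoritative and the module description as shorthand for it.

## Time-stamping and novelty

Gene–disease associations and disease discoveries carry calendar dates.
Relative to a timestamp (2015-02-01 by default), a causal (gene, disease)
pair is classified as: fully known (the association itself is dated on or
before the timestamp); known disease with a new gene link (disease known,
gene causes some other disease); known disease with an undiscovered gene;
novel disease with a known gene; or novel disease with an undiscovered gene.
Records without discovery dates fail loudly — novelty labels drive the
headline evaluation, so silently defaulting to "known" would be worse than
an error. The categories are mutually exclusive and exhaustive, and moving
the timestamp later never removes a pair from the fully-known category.

Rankers only consume edges within the timestamp: disease corpora contain
only diseases discovered by then, and gene–disease links dated later are
invisible to disease-mode scoring.

## Rankers

The annotation corpus propagates each entity's terms to their full ancestor
closure; IC(t) = −log₂(|entities covered by t or a descendant| / |entities|)
so IC(root) = 0 and IC never increases toward ancestors. Terms covering no
entity have undefined IC and contribute nothing. Propagation can be disabled
behind a flag for sensitivity checks.

* **Phrank** similarity is the summed IC over the intersection of the two
  sets' ancestor closures (summed in sorted term order so scores are
  bit-reproducible). Disease mode takes a gene's best associated disease;
  genes without annotations score 0.
* **Phenomizer** uses one-sided (patient → disease) best-match averaging of
  MICA information content, following the original description of the
  method. p-values rescore 10,000 random term sets of the same cardinality
  drawn from the annotated vocabulary, with the add-one convention
  (b + 1)/(n + 1) so p ≥ 1/(n + 1) and the null is super-uniform.

Tied scores receive the mean of the tied rank positions — unbiased for
average-rank reporting and invariant to candidate-list order. The evaluation
report gives, per novelty category and overall, top-k fractions, mean causal
rank, and a baseline from ten seeded random permutations per patient.
External tools are not re-implemented; their per-patient gene-score TSVs
(`patient_id`, `gene`, `score`) can be ingested and reported identically.

## Determinism

Every patient draws from an independent substream seeded by (master seed,
CRC32 of the disease id, replicate index), so cohorts are byte-reproducible
and independent of disease iteration order. Fixture generation is seeded the
same way; identical specs produce byte-identical TSV/OBO output.

## Synthetic knowledge-base generator

The generator emulates every input table: an OBO ontology (leveled rooted
DAG, geometric level widths, ~10% of deep terms get a second parent),
disease records with all five prevalence buckets, dated gene–disease
associations, gene–phenotype annotations, a gene–gene interaction network
(ring plus random chords), non-disease gene lists, a FLAGS-like table, a
gene × tissue expression matrix, and age-stratified claims prevalences with
Zipf-like decay (mirroring heavy-tailed billing-code frequencies).
Expression vectors are drawn from four latent tissue programs plus gamma
noise so cosine-similarity neighbourhoods are nontrivial.

Structure is planted so that every module is viable for every simulatable
disease: diseases split into two groups with disjoint term blocks (module 2
pools are the other group's genes), a per-group hub weak term shared by all
group members (module 1 pools are the same group's genes), three dedicated
non-disease genes per disease annotated to strict subsets of its weak terms
(module 3), an incidental term pool no disease uses (module 4), expression
vectors for all ≥ 100 genes (module 5) and a five-gene FLAGS table
(module 6). Pool sizes at the default scale (30 diseases, 260 genes) exceed
the per-patient per-module demand at λ_G = 12, so module provenance
frequencies track the configured weights; shrinking the knowledge base below
that makes pool exhaustion, and hence random backfill, more common. Novelty
quotas are planted by assigning post-timestamp dates; "known gene" quotas
additionally anchor the gene to a fully-known disease via a pre-timestamp
association. A viability audit runs after generation and fails with the
offending disease and module named.

What the generator does **not** emulate: real HPO/Orphanet marginal
statistics (term counts per disease are uniform at 7, versus dozens in real
records, so simulated patients here have ~10 positive terms rather than the
~18–24 of real deep-phenotyped cohorts), correlated phenotype co-occurrence,
literature-driven annotation bias, or realistic interactome topology.
Passing tests therefore demonstrate the correctness of the sampling
machinery and the qualitative behaviour of the rankers, not cohort-level
statistics of any real patient population.

## Problem sizes

The test suite and the acceptance script run entirely on generated
knowledge bases: cohorts of 600 patients (30 diseases × 20) for composition
statistics, 10,000 patients for distributional checks, five matched seeds ×
five arms for the ablation grid, and 1,000 random 50-term DAGs for the
oracle-equality checks. These sizes give standard errors well inside the
asserted tolerances while keeping a full run in tens of seconds.

## Known limitations

* Variant-level evidence (consequence, frequency, pathogenicity scores) is
  out of scope; candidate genes abstract over "a compelling variant exists".
* Multigenic patients are not simulated.
* Tie-handling for association dates with multiple supporting publications
  is the caller's responsibility: the loaders take one date per association.
* The Phenomizer reimplementation uses one-sided best-match averaging;
  symmetric averaging would change absolute scores (not ranks, in the cases
  tested).
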