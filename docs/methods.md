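# Methods

This note documents the statistical model behind the package, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that matter for
reproducing results.

## The concordance coefficient

For a set of n biomarker genes measured in two systems (e.g. a cell-line
panel and a patient cohort), let U and V be the within-system n × n
Pearson gene–gene correlation matrices. The co-expression extrapolation
(COXEN) coefficient of gene j is the Pearson correlation between column j
of U and column j of V. Two diagonal conventions are implemented:

- **included** — the sum runs over all n partners, including the (1, 1)
  self-pair. This is the textbook column-correlation formula applied
  verbatim; the constant self-pair pulls rc toward +1.
- **excluded** (default) — the self-pair is dropped (k ≠ j). This
  restores the exact identity rc ≡ −1 when one system's off-diagonal
  correlations are the negation of the other's, and removes the upward
  bias, so it is the mode used throughout the pipeline. The included mode
  is kept for comparison.

A column whose off-diagonal entries are (numerically) constant has no
variance to correlate; its rc is reported as missing (NaN), never
fabricated. Near-constant columns are caught with an absolute variance
tolerance of 1e-10·(n−1) to avoid sign noise from floating-point
cancellation.

## Permutation null

The null hypothesis is "no cross-system correspondence of co-expression".
It is simulated by permuting gene identities in one system — rows and
columns of V jointly — which preserves each system's internal correlation
structure exactly while destroying the gene-to-gene match between
systems. Alternatives (permuting samples, or simulating independent
data) would also destroy the within-system structure and make the null
too easy.

Per-gene two-sided p-values use the null |rc| values pooled across all
genes and permutations (B·n draws), add-one smoothed:
p_j = (1 + #{|null| ≥ |rc_j|}) / (1 + B·n). Pooling gives resolution
~1/(B·n) at the cost of assuming approximate exchangeability of gene
columns under the null; a per-gene mode (each gene against its own B
draws) is available via `pooled=False`. The significance cut-off is the
98th percentile of the pooled |null| distribution, i.e. 2% total mass on
|rc| — the two-sided reading of a "98th percentile" rule; a per-tail
reading (4% total) can be obtained by configuring the percentile.
B defaults to 500 permutations (resolution 1/(1+500·n) in pooled mode);
at least 100 are required.

## Gating candidate cancer types

wCOXEN sets are rc distributions between pairs of cohorts of the original
cancer type; bCOXEN sets are rc distributions between an original-type
cohort and a candidate new-type cohort, both computed on the initial
drug-sensitivity biomarkers. The reference is the wCOXEN set with the
lowest median — the weakest concordance the original type exhibits with
itself. Each candidate is tested one-sided (alternative: its bCOXEN is
stochastically lower than the reference) with the Wilcoxon rank-sum test:
exact enumeration when both groups have ≤ 8 tie-free values, otherwise
the tie-corrected normal approximation. Raw p-values are
Bonferroni-multiplied by the number of candidates tested in the same run,
and a candidate is suitable iff its adjusted p exceeds α = 0.025. Note
the logic is deliberately inverted relative to ordinary testing: a
*small* p (clear inferiority) rejects the candidate.

## Three-way triage

Initial biomarkers are kept only if their permutation-BH q-value is below
0.2 in all three system pairs (cell↔original, cell↔new, original↔new).
The three permutation nulls draw child seeds from one seed via
`numpy.random.SeedSequence.spawn`, so a single integer reproduces the
whole triage. An alternative selection path keeps genes whose |rc|
exceeds the pooled-null percentile cut-off directly
(`selection="percentile_cut"`); the BH path is the default because it
adapts to the actual signal density instead of fixing the flag rate.

## Modeling and threshold

Model genes are standardized by training means/SDs (sample SD, ddof 1);
PCA is computed by SVD of the standardized samples × genes matrix; the
smallest k whose cumulative explained variance reaches 0.8 is retained
(k ≥ 1, clamped to samples − 2), and drug activity is regressed on the k
component scores by OLS. 0.8 is the conventional PCR variance heuristic;
k can be fixed through `variance_frac`.

Patient cohorts are standardized *within the cohort* before projection.
The cell panel and the cohorts come from different platforms; per-dataset
per-gene z-scoring is the minimal harmonization that makes a regression
trained on one applicable to the other, and it is stated here as a design
choice because nothing stronger (probe mapping, quantile normalization)
is in scope. Raw scores are converted to within-cohort percentiles
(average rank / n, so 1 = most sensitive); percentiles are what the
threshold operates on, making the classifier invariant to any monotone
rescaling of raw scores.

Candidate models use nested top-m subsets of the concordant biomarkers
ranked by the absolute initial discovery statistic (m = 4, 8, 12, …, plus
the full set; ties broken lexicographically for reproducibility). On the
evaluation cohort, the selection rule is: among candidates significant at
the one-sided Mann–Whitney level 0.05, take the highest AUC, breaking
ties toward fewer genes; if none is significant, the max-AUC candidate is
taken with a warning. The decision threshold is the midpoint between
consecutive distinct percentile scores that maximizes Youden's J, ties
resolved toward the larger cut (higher specificity). Midpoints make the
classifier stable under infinitesimal score perturbations. The threshold
comparison is inclusive (positive ⇔ percentile ≥ threshold).

## Validation statistics

- AUC by pairwise concordance with ties counted 1/2; SE and 95% CI by the
  DeLong placement-value method; p-value one-sided Mann–Whitney
  (alternative AUC > 0.5), tie-corrected normal approximation.
- PPV enrichment: exact one-sided binomial test of responders among
  predicted positives against the cohort's unselected response rate.
- Survival: Kaplan–Meier curves per predicted group (lifelines) and the
  unstratified two-group log-rank test, hypergeometric variance under
  ties.
- Every report carries an explicit `sidedness` field.
- The suitability re-check computes the validation cohort's bCOXEN on the
  *final model genes* and gates it against the reference wCOXEN; failing
  cohorts are still scored and reported with a flag, since overall
  ranking ability (AUC) can survive a concordance failure that breaks
  threshold transfer.

## Synthetic study conditions

The generator's defaults are the package's reference conditions: 100
genes (30 concordant, 20 pairwise-only, 50 null), 60 cell lines, original
cancer type with a 100-patient co-expression reference cohort and a
100-patient evaluation cohort (binary response), a 100-patient new-type
co-expression cohort, an 80-patient new-type validation cohort (response
and exponential survival), and a 60-patient gene-permuted "unsuitable"
cohort. Sizes sit in the range typical of neoadjuvant microarray cohorts;
the co-expression cohorts share one size so that correlation-estimate
attenuation does not systematically separate wCOXEN from bCOXEN.

Structure: each system draws a latent sensitivity factor f ~ N(0,1) per
sample. Concordant genes load s_i·λ·f plus unit Gaussian noise in every
system (signs s_i fixed across systems, λ = 1 by default, giving
between-gene correlations of ±0.5). Pairwise-only genes load an
*independent* secondary factor g, with the same λ, in the cell panel and
the new cancer type only. The secondary factor matters: if all planted
genes shared the single factor and pairwise-only genes merely sat out the
original type, their correlation columns there would still align with the
factor's sign pattern through finite-sample correlation with f, and the
"discordant" genes would not actually be discordant. Drug activity is
f + 0.7·g + 0.5·ε, so pairwise-only genes are discoverable as initial
biomarkers. Patient response is Bernoulli(logistic(2·(f − c))) with c
calibrated so the realized mean response probability equals the 0.3
baseline rate; survival is exponential with hazard 0.3 for responders and
1.0 for non-responders, independently censored at rate 0.2 (censored
times drawn uniformly below the event time). The unsuitable cohort is a
new-type cohort whose gene identities are randomly permuted after
generation — marginals intact, concordance destroyed — mirroring how a
differently-processed cohort can retain predictive signal yet fail
threshold transfer.

What the generator does **not** emulate: probe-level effects, batch
structure, heavy-tailed or platform-specific noise, correlated survival
beyond the responder/non-responder hazard split, and multi-drug
treatment. Passing tests therefore demonstrate the pipeline's behaviour
under its own model assumptions, not robustness to real microarray
artefacts.

## Pipeline conventions and degenerate inputs

- Cohort roles (co-expression reference, evaluation, candidate,
  validation) are declared in the configuration; the runner only opens
  validation files in the final step, so removing them after training
  provably cannot change the model.
- Constant genes are assigned p = 1 and flagged in discovery (never
  silently dropped); they are rejected with a named error where they make
  an operation undefined (z-scoring, correlation matrices, PCR).
- If discovery or the three-way triage leaves fewer than
  `min_model_genes` (default 4) genes, the pipeline falls back to the
  top-ranked genes of that step and flags the run, so a no-signal or
  no-transferable-type configuration completes with an honest null-ish
  model instead of crashing.
- All randomness flows from a single seed (permutation nulls via spawned
  child seeds); repeated runs with the same configuration and seed are
  bitwise identical, and expression TSVs round-trip at full float
  precision.

## Known limitations

- The pooled permutation null assumes gene columns are roughly
  exchangeable; strongly heterogeneous biomarker sets may prefer the
  per-gene null.
- The gate's "not significantly worse" criterion treats low power as
  evidence of suitability (small candidate cohorts pass more easily);
  this is inherent to the equivalence-by-nonsignificance design.
- Model selection uses a single evaluation cohort, not cross-validation,
  so the reported evaluation AUC is mildly optimistic; the prospective
  validation statistics are the honest numbers.
- Probe-to-gene mapping across platforms is the caller's responsibility;
  inputs must already share identifiers.
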