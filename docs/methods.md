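# Methods

## Scope and model

`phenorules` mines directed phenotype–phenotype association rules from a
three-valued call matrix (abnormal / normal / not-tested; phenotypes ×
mutant strains) and builds the derived objects — ego-modules (PPAPs),
pathway-like configurations, communities, enrichment tables — on top of the
selected rules. The statistical substrate is the complete-case 2×2
cross-table of each phenotype pair: strains not tested in either member of
a pair are removed before any measure is computed, so adding or removing
not-tested strains never changes a pair's measures.

## Phenotypic calls

Quantitative measurements are converted to calls per (parameter, strain)
cell by the unbiased standardized mean difference (Hedges' g):

    d  = (mean_mutant − mean_control) / s_pooled
    J  = 1 − 3 / (4·df − 1),  df = n_m + n_c − 2
    g  = J · d
    se(g)² = (n_m + n_c)/(n_m·n_c) + g² / (2(n_m + n_c))

The variance formula is the common Hedges–Olkin large-sample approximation;
the 95% CI and the p-value for g ≠ 0 use normal quantiles on se(g). A cell
is abnormal at threshold τ iff |g| ≥ τ, p(g) < 0.05, and the accompanying
two-group significance test has p < 0.05. The accompanying test is Welch's
two-sided t by default; an exact-style Wilcoxon rank-sum is available
(`exact_test="wilcoxon"`) since both are standard for continuous screening
parameters and the choice is not determined by the call criteria
themselves. Cells with fewer than two values in a group or zero pooled
variance are not-tested. Parameter-level calls collapse to phenotype level
by OR: abnormal if any constituent parameter is abnormal, normal if tested
and none abnormal, not-tested otherwise. (Combining by best |ES| instead of
OR was considered; OR matches the semantics of "any constituent assay
flagged the phenotype" and keeps phenotype calls monotone in τ.)

Because abnormality is defined on |g|, direction is discarded at the call
stage; the signed effect-size table is retained as a separate artifact.

The threshold grid defaults to 0.8–3.0 in bins of 0.1 (23 values). Call
sets are nested across the grid: the abnormal set at a larger τ is a subset
of the set at any smaller τ.

## Rule measures

For the ordered pair (X, Y) with complete-case table (n11, n10, n01, n00),
N = their sum:

* co-expressions: n11
* support: n11/N
* confidence forward/reverse: n11/(n11+n10), n11/(n11+n01)
* lift: n11·N / ((n11+n10)(n11+n01)) — symmetric, 1 at independence
* rule polarity: −log10 p of the two-tailed Fisher exact test on
  [[n11, n10], [n11, n01]] — the two conditional-probability
  numerators/complements share n11. Large polarity means the premise has
  far fewer abnormal cases than the conclusion. (The alternative reading,
  margins-vs-margins, was rejected: comparing the two confidences is
  literally a comparison of the two success/failure splits.)
* rule significance: two-tailed Fisher exact p of the cross table itself,
  evaluated only when n11 ≥ 2; not-evaluated pairs carry no p and no q.

Two-tailed Fisher p-values are the sum of hypergeometric outcome
probabilities not exceeding the observed outcome's probability (the
standard minimum-likelihood convention), with a 1 + 1e-7 relative slack
when comparing probabilities so that exact ties are kept under floating
point. The implementation is verified against a brute-force
integer-arithmetic enumeration oracle to 1e-9 over every 2×2 table with
N ≤ 30, and spot-checked against `scipy.stats.fisher_exact`.

## q-values and their calibration guards

q-values are π0-scaled Benjamini–Hochberg adjustments. π0 is estimated by
a sliding linear model: straight lines are fitted to the p-value survival
function over sliding windows of a λ grid (0.05–0.95, window of 5 points);
the slope with respect to (1 − λ), averaged over the upper-λ windows,
estimates π0, floored by Storey's survival-ratio estimate S(λ)/(1 − λ) at
λ ∈ {0.5, 0.8}. The Storey floor exists because discrete, super-uniform
exact-test p-values make the survival curve convex, biasing the local
slope downward — and an underestimated π0 deflates *every* q uniformly.
Estimates that are non-finite, at float-noise level, or above 1 fall back
to π0 = 1 (plain BH).

Two structural guards address the n11 ≥ 2 evaluation gate, which in sparse
matrices preselects extreme tables:

1. **Family-size correction.** The BH step-up runs over the full pair
   family, with unevaluated pairs entering as evidence-free (p = 1), and
   the family π0 counts unevaluated pairs as nulls by construction:
   π0 = (m_unevaluated + π0̂·m_evaluated)/m_family. In dense matrices
   (nearly every pair evaluated — the regime the selection thresholds were
   designed for) this is numerically indistinguishable from correcting
   over the evaluated vector alone; in sparse matrices it prevents the
   gated subset from certifying itself.
2. **Sweep-step screening.** Within the end-to-end selection, a sweep step
   whose evaluated p-value family has no mass anywhere near 1 cannot be
   calibrated at all — the q < 0.1 criterion could not fail for any pair —
   and such steps are excluded from the per-phenotype optimum scan and
   reported in `SignificantRuleSet.excluded_thresholds`.

Without these guards, a null 200-phenotype × 500-strain matrix has ~80% of
its evaluated pairs pass the q-filter; with them, ~0.02%.

## Rule selection

Selection criteria: n11 ≥ 2, lift strictly > 2, q < 0.1. A single global
threshold applies to all phenotypes during the sweep; per-phenotype optima
are read off afterwards as the grid value maximizing the phenotype's
incident selected-rule count, ties toward the larger (more stringent)
threshold. Rules incident to each phenotype at its optimum are accumulated;
duplicate unordered pairs keep the occurrence with larger lift, then larger
n11 (the spec of "removed duplicates" does not fix the occurrence; larger
lift retains the stronger version of the rule). Each surviving rule is
stored in the direction of the larger confidence, which — since the two
confidences share n11 — is equivalent to pointing from the phenotype with
fewer complete-case abnormal strains to the one with more. Exact confidence
ties break lexicographically and are flagged (`tie_flag`).

## PPAPs and pathway conversion

A PPAP is the closed one-hop neighborhood of a query phenotype in the
directed rule graph together with all induced edges; neighbor–neighbor
edges carry the indirectly related phenotypes and are what makes multi-edge
paths possible. Reachability closure was rejected: it would collapse most
of the graph into near-identical modules. Reported statistics count related
phenotypes excluding the query; distinct biological systems are counted
over the related phenotypes, and `n_same_system_as_query` counts related
phenotypes sharing at least one system with the query.

Conversion keeps, for every phenotype reachable from the query, the longest
simple path from the query to it, and symmetrically for every phenotype
that reaches the query; kept paths' edges are unioned. Targeting the
reachable set (rather than direct neighbors only — in an ego-module all
reachable nodes *are* direct neighbors, so the two coincide there) makes
the operation idempotent on already-converted graphs. Length ties keep the
lexicographically smallest node sequence. Enumeration of simple paths per
source–target pair is capped (default 1e5); exceeding the cap raises a
too-complex error rather than silently truncating, and the pipeline
records such modules as excluded. Degree deviation per query uses the
two-tailed Fisher test on [[in, out], [out, in]] (the transposed-margins
reading; testing against global margins instead would conflate a node's
imbalance with the network-wide one), signed negative when out > in, with
FDR < 0.05 classes rare/common/neutral.

Gene ranking lists strains abnormal for the query phenotype, scored by the
number and proportion of PPAP phenotypes (query included) abnormal in that
strain, descending, ties by strain symbol. Eligibility by query abnormality
(not "abnormal for ≥ 1 module phenotype") keeps the list anchored to the
module's defining phenotype.

## Communities and enrichment

PPAP similarity is the Simpson (overlap) distance between phenotype node
sets; biological systems are compared by the sets of PPAPs they occur in.
Agglomeration is Ward linkage on the distance matrix, cut at fixed k
(defaults: 7 for PPAP-level, 4 for system-level). No automatic k selection
is attempted. Input order does not affect partitions (items are sorted
before distances are computed). The membership matrix marks never-co-tested
query/phenotype pairs (zero complete cases) separately from non-membership.

Enrichment uses exact hypergeometric tests: two-tailed when both directions
matter (stage/type rule categories, Holm-corrected over the 16 ordered
pairs; between-system rule categories, FDR < 0.01), one-tailed only at
fold ≥ 1 when screening for positive enrichment (measure extremes,
Bonferroni-corrected). For pair-level category analyses each phenotype
contributes its primary (first-listed) biological system, which keeps
per-category rule counts additive. The bootstrap expected-count test draws
the observed number of rules uniformly without replacement from all
possible phenotype pairs B times and reports the mean number of realized
between-system categories and the lower-tail p. Measure-extreme splits
default to quartiles (q = 0.25); the split point is a reporting choice, not
an inference threshold. Spearman correlations among support, confidence,
polarity and significance (−log10 p) are computed for all six pairs.

## Synthetic data generator

The generator emulates the statistical shape of a large knockout screen:

| parameter | default | meaning |
|---|---|---|
| n_phenotypes | 500 | catalog size |
| n_strains | 3000 | mutant strains (one gene each) |
| n_controls_per_parameter | 100 | shared control pool per parameter |
| n_mutants_per_strain | 7 | replicate animals per (phenotype, strain) |
| abnormality_rate | 0.04 | marginal latent abnormality frequency |
| effect_size_abnormal | 3.0 | shift of abnormal cells, units of σ |
| missing_rate | 0.3 | MCAR probability a cell is not tested |
| stage_type_mix | 0.46/0.25/0.17/0.12 | adult_trait/adult_gene/embryo_trait/embryo_gene |
| n_biological_systems | 60 | annotation vocabulary |

Controls are N(0,1); mutant cells are N(δ,1) when latently abnormal with
δ = 3 so that calls at |ES| = 2 recover latent abnormals with ~95%
sensitivity and essentially no false calls — the ~4% called-abnormal
frequency at threshold 2 then mirrors the latent rate. Planted pairs draw
their two statuses per strain jointly from the exact 2×2 law
p11 = min(lift·rate², rate), p10 = p01 = rate − p11, keeping both marginals
at the configured rate; the closed-form joint makes moment-based tests
exact. Each phenotype may join at most one planted pair, so every
non-planted pair is exactly independent. Not-tested masking is
missing-completely-at-random at 30% — substantial missingness without
starving complete-case counts at 3,000 strains; real corpora are
missing-heavier and heterogeneous. All randomness fans out from one seed
via independent named streams, so the measurement path and the direct
call-matrix shortcut share identical latent truth.

What the generator does *not* emulate: center/batch/sex/zygosity structure,
heterogeneous per-phenotype abnormality rates, categorical parameters
(covered by supplying call matrices directly), informative missingness, and
genuine biological correlation beyond the planted pairs. Passing tests
therefore demonstrate correctness of the machinery and calibration under
idealized conditions, not performance on a real corpus. In particular,
accumulated atlases on synthetic corpora show empirical false-discovery
proportions fluctuating roughly between 0.05 and 0.25 around the nominal
per-step q < 0.1, because the union over per-phenotype optima collects
borderline rejections from many correlated sweep steps.

## Validation experiments

The acceptance suite (tests/test_acceptance.py) re-derives, at sizes chosen
to keep the default test run in minutes: pair-pattern counting (532² =
283,024); lift = 1 on the exactly independent table; exact-test equivalence
with the enumeration oracle over all 2×2 tables with N ≤ 30; the Hedges' g
closed form and call monotonicity; null FDR calibration over 20 corpora of
200 × 500; recovery of 50 planted lift-5 pairs at 3,000 strains and 120
phenotypes (recovery ≥ 80%, empirical false discovery ≤ 0.15); pathway
conversion against the brute-force longest-path oracle on 200 random DAG
modules; the premise-has-fewer-abnormal-cases direction invariant; Ward/
Simpson recovery of three planted PPAP communities (ARI ≥ 0.8); and the
bootstrap null (expected 0 with one system; lower-tail p ≈ ½ at the
analytic null mean, with the draw count chosen so the mean falls near a
half-integer of the count lattice).
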