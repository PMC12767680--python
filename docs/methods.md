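# Methods

This note documents the statistical model, the default parameters and
their rationale, the synthetic-market generator, and the numerical
implementation choices in `etscan`.

## 1. Additive lexicon and detection

The bundled lexicon (`etscan/data/ets_lexicon.tsv`) covers 59 additives
in the E400–E499 range (emulsifiers, thickeners, stabilisers). Each
entry carries canonical name, synonyms, common misspellings, optional
extra regex patterns, a lump group, and a fate class
(absorbed / non-absorbed).

Every entry compiles to one regular expression that matches, case
insensitively:

- the E-number in the spellings `e471`, `E 471`, `e-471`, with optional
  letter subclass (`a`–`f`) or roman-numeral subclass (`i`–`iii`),
  guarded by `(?<![a-z0-9]) … (?![a-z0-9])` so `E4071` never matches
  `E407`;
- every synonym and misspelling as a literal token with the same
  boundary guards;
- any extra patterns, e.g. the carrageenan pattern `(c|k)ar*age*nan`
  which covers `karagenan`, `carragenan`, `carrageenan` and similar
  variants.

Detection runs *all* entries over the text and resolves overlaps by
longest match: a hit is discarded when a strictly longer hit of a
different additive covers its span. This disambiguates the cellulose
family (`methyl cellulose` vs `cellulose`) and E471 names contained in
E472 names. Subclass detections fold into the parent code
(`E472a` → `E472`, `E450ii` → `E450`).

For aggregate analyses, codes project onto lump groups: E40x
(E400–E404), E42x (E420–E422), E45x (E450–E452), E47x (E470–E477);
all other codes pass through unchanged.

## 2. Eligibility cascade

Products pass an ordered exclusion cascade; each exclusion is charged
to the **first** applicable reason so tallies partition the input:

1. `non_food` — flagged non-food items;
2. `no_ingredients` — missing/empty ingredient list;
3. `nutrient_gt_100` — any declared nutrient above 100 g per 100 g;
4. `sugar_gt_carb` — sugar exceeding total carbohydrate;
5. `satfat_gt_fat` — saturated fat exceeding total fat;
6. `no_energy` — missing or zero energy;
7. `energy_gt_4200` — energy above 4 200 kJ/100 g (more than pure fat);
8. `bad_kj_kcal_ratio` — kJ/kcal outside [3.984, 4.384] (±5 % around
   4.184), inclusive at both ends; skipped when both declarations are
   near zero (kJ < 10 and kcal < 2), where the ratio is uninformative;
9. `duplicate` — repeated GTIN or case-folded, whitespace-collapsed
   name; the first occurrence after a stable sort by (source, GTIN) is
   kept.

Rules are checked only on fields present in the record; a missing kcal
declaration, for instance, never triggers the ratio rule.

## 3. Hyper-palatability classification

Energy shares are computed from declared macros: fat 37 kJ/g and
carbohydrate 17 kJ/g, as a percentage of declared total energy; sodium
is taken as 40 % of declared salt. Criteria:

- **fat + sodium**: fat > 5 E% and sodium ≥ 0.30 g/100 g;
- **fat + sugar**: fat > 20 E% and sugar > 20 E%;
- **carbohydrate + sodium**: non-sugar carbohydrate > 40 E% and
  sodium ≥ 0.20 g/100 g.

Energy-share cut-offs are strict (>), sodium cut-offs inclusive (≥).
Products meeting two or more criteria are labelled `FitsMoreThanOne`;
beverages are excluded from classification. The fat threshold in the
fat+sodium criterion is configurable (`HPThresholds.fat_sodium_fat_epct`);
the default is 5 E%, and 25 E% — used by part of the source
literature — is available for sensitivity analysis.

## 4. Exact co-occurrence test

For a food group of N products in which additive *i* occurs in k_i
products, the null model draws each additive's product set uniformly
at random without replacement, independently across additives. The
intersection size T of m ≥ 2 such sets then has an exact distribution
obtained by chaining hypergeometric transitions:

- T₂ | (k₁, k₂) ~ Hypergeometric(N, k₁, k₂);
- T_{j+1} | T_j = t ~ Hypergeometric(N, t, k_{j+1}).

The distribution is computed by dynamic programming over these
transitions (exact for any m; cost O(m · min(k)²)). The transition
matrices are evaluated in log space via `scipy.special.gammaln`
rather than repeated `hypergeom.pmf` calls — identical to ~1e-15 and
roughly 50× faster at the problem sizes the scan encounters
(N ≈ 5 000, set sizes in the hundreds).

Two-sided p-values use **Blaker's rule**: with γ(x) = min(P(T ≤ x),
P(T ≥ x)), the p-value at observation t is the null probability of
{x : γ(x) ≤ γ(t)}. Ties in γ are compared with a relative slack of
1e-7 to absorb floating-point noise; the test suite verifies agreement
with a rational-arithmetic oracle to 1e-11 relative error.

**Fold enrichment** is observed / expected with expected =
N · ∏(k_i / N). Enrichment uses *at-least* semantics (a product with
{E412, E415, E471} counts for the pair E412&E415), whereas descriptive
combination counts (`exact_combination_counts`) use exact-set,
UpSet-style semantics. Confidence intervals for log fold enrichment
come from a percentile bootstrap over products (default B = 1000);
replicates in which the observed or any expected count degenerates to
zero are excluded and counted. Benjamini–Hochberg q-values are reported
across each scan.

Scan filters (defaults): additives below 1 % prevalence in the group
are dropped; combinations with expected count < 10 are skipped;
groups below 50 products are skipped with a warning; combination sizes
2–4 are tested. These floors keep the exact test away from
near-degenerate supports where any two-sided rule is dominated by
discreteness.

## 5. Synthetic market with analytic ground truth

Each food group is a mixture of **archetypes**: archetype *a* has
weight w_a and per-additive probabilities p_{ac}; a product drawn from
*a* includes additive *c* independently with probability p_{ac}.
Marginals and combination probabilities are therefore closed-form:

- P(c) = Σ_a w_a · p_{ac}
- P(S ⊆ product) = Σ_a w_a · ∏_{c∈S} p_{ac}
- FE(S) = P(S) / ∏_{c∈S} P(c)

With a single archetype every FE is exactly 1 (independence); mixing
archetypes induces positive dependence. The worked validation case —
two archetypes with w = (0.5, 0.5) and pair probabilities (0.8, 0.8)
and (0.1, 0.1) — gives FE = (0.5·0.64 + 0.5·0.01)/0.45² ≈ 1.6049.

Ingredient texts are rendered per additive in one of four styles
(E-number, canonical name, misspelling, subclass form) mixed with
non-matching filler ingredients; detection ∘ rendering is verified to
be the identity. Nutrition panels are drawn as Beta total solids × a
Dirichlet macro split, with sugar and saturated fat as Beta fractions
of their parents, and energy computed from the macros — so synthetic
products satisfy every eligibility rule by construction. Integer kcal
declarations are chosen to keep the kJ/kcal ratio inside the accepted
band (guaranteed for kJ ≥ 50).

Defects are injected into disjoint product subsets, one defect type
per eligibility rule, with exact expected tallies recorded in the
ground truth; the suite asserts the pipeline's exclusion tallies match
them exactly. The default market mirrors a Norway-like grocery
assortment: 16 food groups, n = 8 164 at scale 1, phosphate-heavy
processed meat, gum-heavy sauces and desserts, and a near-clean infant
category.

## 6. Validation design notes

- **Type-I control** is checked empirically on independent data:
  six additives with prevalences 0.15–0.35 in groups of n = 5 000,
  pooled over 20 seeded replicates (~944 tests), asserting the
  fraction of p < 0.05 lies in [0.03, 0.07]. The prevalence range is a
  design choice made *before* freezing the test: at these prevalences
  the intersection null has fine support, which is the regime the
  scan's expected-count floor (≥ 10) targets; very sparse additives
  would instead probe the heavily discrete regime the filters exclude.
- **Bootstrap coverage**: 95 % percentile intervals for log FE must
  cover the analytic value in ≥ 45 of 50 seeded runs at n = 2 000.
- **Oracles**: the Blaker p-value is checked against an exact
  Fraction-arithmetic implementation; the m = 3 null against full
  enumeration (N = 6) and a 200 000-draw Monte-Carlo sampler
  (total-variation distance < 0.01, observed ≈ 5 × 10⁻⁴).

## 7. Reproducibility

All randomness flows through `numpy.random.default_rng` seeded from a
single integer; derived seeds stay below 2³¹. Re-running the pipeline
with the same inputs and seed reproduces every artifact byte-for-byte
(asserted in the suite). `scripts/acceptance.py --seed S --out F`
writes the headline quantities deterministically.
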