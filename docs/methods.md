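# Methods

This note documents the models, rules and numerical choices behind
`pollennet`, and what its synthetic data can and cannot say about real
pollen metabarcoding studies.

## The analysis being reproduced

The pipeline mirrors a common field design: flower-visiting insects
(here, *Eristalis*-like hoverflies) are netted at several grassland
sites in an early and a late summer period; pollen washed from each
individual is amplified with a plant barcode marker (rbcL-style, ~500 bp
amplicons sequenced as 2×300 bp read pairs), and reads are matched
against a curated reference library. Downstream, per-insect pollen
profiles support three levels of inference: site-level bipartite
networks, species-level exclusivity, and individual-level flower
constancy.

## Sequence processing

Read pairs are quality trimmed with a trailing sliding window (window 4,
threshold Q20; the cut lands on the first sub-threshold base inside the
first failing window), then merged over their best 3' overlap
(minimum 20 bp, mismatch fraction ≤ 0.1; disagreements resolve to the
higher-quality base, ties to the forward read). Only merged sequences
*strictly longer* than 450 bp proceed; the boundary is exclusive and
pinned by test. The trimmer, merger parameters and tie rules are
package conventions, stated in the configuration, not field standards
with a single canonical value.

## Taxonomic assignment

References carry three ranks (species, genus, family-or-tribe) in their
FASTA headers. Candidate references must share at least one k-mer
(k = 8) with the query; candidates are scored with affine-gap local
alignment (match +1, mismatch −2, gap open −5, gap extend −2) and
reported as bit scores (λ·S − ln K)/ln 2 with λ = 1.28, K = 0.46 — the
megablast-style constants. The bit score is a strictly increasing
transform of the raw score, so these constants affect reporting only,
never which hits rank highest (asserted by test).

Like a BLAST search, the hit table only contains significant hits:
anything below 98% of the read's best bit score is not reported. This
reporting cutoff is what makes consensus assignment behave sensibly
against a compact reference library — with a handful of references and
no cutoff, every distant relative would enter the consensus and species
calls would be impossible. Against large multi-accession libraries the
cutoff is nearly inert, because the returned top hits are close
relatives anyway.

The consensus rule over the retained top hits (top 20 bit scores, all
ties at the cut kept) is:

1. all hits one species → that species;
2. else ≥ 60% of hits share one genus → that genus (inclusive);
3. else "various": ≥ 90% of hits share one family/tribe → that family,
   otherwise **unknown**.

The 60% share counts hit records, not distinct species. An allow-list
of regionally recorded taxa can be applied; a species-level call
survives if its genus or family is listed (the mechanical replacement
for expert curation). Finally, per-insect counts become percentages of
identified reads, controlling for amplification-depth differences
between samples; insects with zero identified reads are excluded.

## Networks: H2′ and d′

For each site × period, the interaction matrix counts the number of
individual insects of species *i* carrying plant taxon *j* — presence/
absence per individual, because read abundances are at best
semi-quantitative. With p_ij = a_ij/m, network-level specialisation is

    H2 = −Σ_ij p_ij ln p_ij,     H2′ = (H2max − H2) / (H2max − H2min)

standardised between the entropy extremes attainable with the observed
marginal totals, so H2′ runs from 0 (complete generalisation) to 1
(complete specialisation). H2max uses a near-proportional integer fill
polished by marginal-preserving 2×2 transfers. H2min is computed
*exactly* for small networks (m ≤ 40, up to 6×6) by a memoised search
over transportation-polytope vertices — entropy is concave, so its
minimum sits at a vertex, and every vertex arises from some order of
saturating placements; plain greedy concentration with local polishing
misses the optimum on a small but real fraction of marginals, which is
why the exact search exists. Larger networks fall back to the greedy
heuristic. Both bounds are validated against exhaustive enumeration of
all integer matrices (feasible to m = 12).

Species-level exclusivity is the Kullback–Leibler divergence of a
species' interaction proportions from overall partner availability
q_j = C_j/m:

    d_i = Σ_j (a_ij/A_i) ln((a_ij/A_i)/q_j),    d′ = (d − dmin)/(dmax − dmin)

with dmax = ln(m/A_i) and dmin from the best integer allocation of A_i
interactions across partners (the greedy unit-by-unit allocation is
exact here because the objective is separable and convex). Natural
logarithms throughout. Species absent from a period are omitted rather
than reported as zero.

## Individual specialisation

An insect is a *single-plant visitor* when its dominant pollen taxon
reaches ≥ 90% of identified reads (inclusive; ties broken
lexicographically and flagged). The 90% threshold acknowledges
heterospecific carry-over and windblown pollen: perfectly pure loads
are unrealistic. Summaries report counts and percentages at 90% and
60% per period, plus a decile histogram of top-taxon percentages.

The binary class is modelled as logistic with fixed effects for period
(early = 0, late = 1) and sex (female = 0, male = 1) and crossed
Gaussian random intercepts for site and insect species. The marginal
likelihood is maximised under the Laplace approximation (adaptive
Gauss–Hermite with one node, the default of standard mixed-model
software): an inner Newton iteration finds the conditional mode of the
random effects, the outer optimiser (L-BFGS-B) works on fixed effects
and log-SDs jointly. Wald z and two-sided normal p-values come from
the finite-difference curvature of the Laplace log-likelihood in the
fixed effects. With both variances fixed at zero the model reduces
exactly to ordinary logistic regression, fitted by Newton iteration
(matches the IRLS oracle to < 1e-6). A degenerate all-one-class
response raises a separation error; non-convergence is flagged on the
fit. The fit agrees with lme4's `glmer` to ~3 decimals on test data.

## Synthetic community generator

The generator provides every input the analysis needs, with the
statistical structure the analysis assumes:

* **Reference library** — sequences evolve from a random root along the
  family/genus/species hierarchy by independent substitutions; expected
  pairwise divergences default to 3% within genus, 8% between genera,
  16% between families. Unless within-genus divergence is zero, any
  species pair is kept ≥ 1% of the amplicon apart by deterministic
  re-draws, because a curated barcode library only resolves species the
  marker can distinguish; identical species (for genus-rank behaviour)
  are generated with zero divergence.
* **Insects** — six hoverfly species with capture weights 5:57:2:41:53:17
  (the uneven relative frequencies typical of *Eristalis* catches), four
  sites, two periods. A period-dependent fraction of insects are
  specialists (defaults 0.40 early, 0.24 late, matching the observed
  seasonal decline in single-plant visiting); a specialist's dominant
  share is Beta(20, 1) truncated to ≥ 0.9 — near-pure with a little
  carry-over. Generalists draw 2–6 taxa with Dirichlet proportions
  whose concentration blends availability with a uniform floor, so
  availability skew only rarely produces accidental ≥ 90% dominance
  (~7% of generalists).
* **Availability** — gamma-distributed plant weights per site × period,
  with independent late-season draws at a higher scale and ~25% of taxa
  not flowering, emulating seasonal turnover; the flower-unit survey
  integerises the same weights into Poisson quadrat counts whose totals
  span tens to several hundred units.
* **Reads** — per-read source taxa are multinomial in the true
  proportions; forward/reverse reads cover the amplicon ends;
  substitution errors are i.i.d. (default 0.5%/base), with **no indels**,
  so merged lengths are deterministic and the >450 bp filter behaves
  predictably. Depths are lognormal (median ~245) or fixed. Every read
  id appears exactly once in the ground-truth table.

What passing tests on these data do *not* show: robustness to PCR and
extraction bias, chimeras, index hopping, indel errors, reference
misannotation, or the taxonomic richness of a real flora (65 taxa in a
typical study vs 16 here). The generator's role is to verify the
*computation*, end to end, under controlled truth.

## Problem sizes

Unit and property tests run at small sizes (tens of insects, depths
10–200). The recovery checks use a 4×2×2 library, 50 insects at depth
200 (10,000 read pairs) for assignment, and 50 replicate studies of
n = 400 insects for the mixed model — sizes at which multinomial and
sampling error are small relative to the tolerances being asserted.
The acceptance script runs the full pipeline at 5 early + 11 late
insects per site (64 insects, depth 60), a deliberate scale-down of the
study design that preserves its structure: all four sites, both
periods, uneven species weights and seasonal specialist decline.

## Known limitations

* The exact H2min vertex search grows combinatorially; beyond m = 40 the
  greedy fallback can, in principle, overestimate H2min slightly
  (making H2′ conservative, i.e. biased toward 0).
* The aligner is a full Smith–Waterman over k-mer-prefiltered
  candidates; it is exact but not seeded/banded, so very large reference
  libraries would need a faster search backend.
* The GLMM supports exactly the crossed two-intercept structure used
  here; it is not a general mixed-model engine.
* Tie handling (lexicographic top taxon, forward-base merge ties) is
  deterministic by design but arbitrary; flagged in outputs where it
  occurs.
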