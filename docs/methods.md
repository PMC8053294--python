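# Methods

## Scope and model

diaflux implements the downstream-interpretation chain that follows a
differential-expression (DE) fit: the DE statistics table is an *input*
(any edgeR/DESeq2-style fit produces one); read alignment, count
normalization and the negative-binomial test itself are out of scope.
Four analyses are chained:

1. **DEG selection.** A gene is differentially expressed when its
   FDR-adjusted P-value is at or below the cutoff (inclusive boundary).
   The working cutoff is 0.10; a stricter 0.05 count is always reported
   alongside, split into up- (log2FC > 0) and downregulated (log2FC < 0)
   genes, with exact zeros counted in neither and reported separately.
2. **Impact/flux scoring** of gene sets (pathways or TF regulons).
3. **Regulon enrichment and state calls.**
4. **Pathway network expansion and tri-partite assembly.**

## Impact and flux

For a set with background B = members ∩ universe and DEG subset D:
π = |D|/|B|, m = mean |log2FC| over D, s = mean −log₁₀P over D,
I = 100·π·m·s, d = Σlog2FC/Σ|log2FC| (0 when the denominator is 0),
F = I·d. Empty B or D yields an all-zero result.

Choices behind this definition:

- **The ×100 multiplicative form.** Impact is defined as the product of
  the three ingredients on a percentage-proportion scale. This puts
  typical scores for strongly perturbed sets in the low hundreds — the
  0–300 display range conventional for this kind of analysis — while
  remaining a pure definition of this package: no equality with any other
  implementation's arithmetic is claimed.
- **Raw P in the significance term**, log base 10; a flag
  (`use_adjusted_p`) switches to the adjusted value.
- **Magnitude-weighted direction.** d = Σlog2FC/Σ|log2FC| guarantees
  |F| ≤ I with equality exactly for single-signed DEG, which matches how
  published impact/flux tables behave (|flux| < impact whenever a set has
  genes moving both ways). The alternative count-based direction
  (n_up − n_down)/n_DEG is available via `direction_method="count"` but
  does not carry the bound.
- **Universe-conditioned background.** π's denominator is members ∩
  analyzed genes, never the whole genome: genes the experiment could not
  have detected do not dilute the score.
- Display clamping to [0, 300] is never applied to stored values;
  formatting (6 significant digits in TSV output) is presentation only.

Hierarchy aggregation takes the arithmetic mean of impacts and of signed
fluxes over a subcategory's (or category's) pathways, excluding pathways
with empty background; whether to average signed fluxes or rescale them by
impact is genuinely open, and the unweighted mean was chosen as the least
structured option. |flux| ≤ impact is therefore *not* guaranteed after
averaging and is not asserted there. Top-N ranking filters by flux sign
first, then orders by impact; all ranking ties break lexicographically by
set id for reproducibility.

## Regulon enrichment and state

Each regulon is tested for DEG over-representation with the one-sided
hypergeometric tail P(X ≥ k) (equivalent to one-sided Fisher exact),
with N = universe size, n = |DEG|, K = regulon background, k = overlap,
computed by log-space summation of the probability mass. The BH family is
*all* tested regulons, not only reported ones (standard step-up practice);
regulons with empty background are reported with p = 1. The published
tool-chain this mirrors integrates ranks across several ChIP-seq
libraries; single-library exact testing is the implemented analog, and no
attempt is made to match any specific tool's adjustment procedure.

Regulons at FDR ≤ 0.05 are scored with the pathway impact/flux machinery
over their target sets, and the flux sign gives the predicted state:
positive → Activated, negative → Inhibited, exactly zero → Indeterminate
(the zero label is this package's choice; exact zeros essentially never
occur on real data).

## Pathway networks

Pathway links are undirected (up- and downstream expansion is symmetric).
Levels are breadth-first distances from the seed set, seeds at level 0;
expansion retains every pathway within the requested number of levels and
every link among retained pathways. Genes shown are restricted to DEG
belonging to ≥ 1 retained pathway (level = 1 + the smallest level of their
pathways, log2FC carried as an attribute); TFs attach only through
regulation edges to genes in their enrichment overlap and are pruned when
no target is in view (level = 1 + smallest target level). Isolated pathway
nodes are retained. A TF id colliding with a node already in view (which
happens when one library serves as both pathway catalog and regulon
library) gets a `tf:` prefix so node ids stay unique. The tri-partite
constraint — no gene–gene, tf–tf or tf–pathway edges — holds by
construction and is property-tested.

## Synthetic cohorts

The generator emulates the *shape* of an edgeR output table, not the
count-level data-generating process: no negative-binomial counts, library
sizes or dispersion estimation, and one contrast only. Null genes draw
log2FC ~ Normal(0, se); each planted set has a fraction of responding
members drawing log2FC ~ direction·Normal(effect_mu, effect_sd); P-values
are the two-sided normal tail of z = log2FC/se (the simplest mechanism
giving jointly consistent log2FC/P/FDR triples) and FDR is BH over all
genes. Defaults — 10,000 genes, 50 sets of 40, 5 activated + 5 inhibited
planted sets, effect_mu 1.5, effect_sd 0.3, se 0.3, frac_responding 0.8 —
put ~3–4% of genes past FDR ≤ 0.10, i.e. a few hundred DEG among ~10⁴
analyzed genes, the regime this kind of study operates in; with
effect_mu/se = 5 the planted sets are strongly but not trivially
detectable.

Planted sets are sampled disjointly from one permutation so planted
directions never conflict; null sets are sampled independently (overlap
allowed), which gives the shared-gene pathway-link graph its edges. The
hierarchy assigns sets round-robin to five synthetic subcategories across
two categories. All randomness flows from one integer seed through numpy's
PCG64 with three spawned streams (gene effects / set memberships / planted
effects), so output is reproducible across platforms.

What passing tests on these cohorts shows — and does not: recovery and
calibration results demonstrate the chain's statistical behavior under a
clean two-group normal model with independent genes; they do not speak to
count-level artifacts, correlated genes, annotation bias, or library
version effects in real data.

A hand-built miniature fixture (10-gene universe plus 2 off-universe set
members; 12 distinct ids, 3 sets) embeds two exactly known results used
throughout the tests: one set scoring π = 0.4, m = 1.5, s = 3, I = 180,
d = 1/3, F = 60, and one set whose enrichment p is exactly 5/210
(N=10, K=5, n=4, k=4).

## Numerical and I/O choices

- P-values of exactly 0 are rejected at parse time (−log₁₀P must stay
  finite); simulated P-values are floored at the smallest positive double.
- Duplicate gene ids in a DE table collapse to the record with the
  smallest raw P (ties: smallest |log2FC|, then first occurrence); how a
  real pipeline resolved its duplicates is unknowable downstream, so the
  rule favors the strongest evidence and is deterministic.
- Gene-id matching is exact and case-sensitive; `uppercase_ids=True`
  normalizes symbols when regulon libraries and DE tables disagree on
  case (regulon libraries are typically human-symbol upper case while DE
  tables may carry native-species symbols or numeric ids — which id space
  a given study used cannot be assumed, so it is a flag, not a default).
- BH adjustment is delegated to statsmodels behind `bh_adjust` (with
  domain validation); the hypergeometric tail to scipy. Independent naive
  re-implementations of both serve as test oracles only.
- The pipeline writes no timestamps, sorts all outputs deterministically,
  and records input SHA-256 checksums, configuration and package version
  in `manifest.json`; rerunning with identical inputs is byte-identical.
  A stage failure removes partial outputs and raises a stage-tagged error.

## Problem sizes used in verification

The test-suite and acceptance script run at desk scale by design: the
hypergeometric oracle enumerates all configurations with N ≤ 12; flux
bounds are checked on 10,000 random ≤ 8-gene instances; recovery uses
50–100 seeded default cohorts and null calibration 25–50 null cohorts.
These sizes are the package's verification conditions, chosen to make the
checks exhaustive where enumeration is possible and statistically stable
where they are sampled.

## Known limitations

- Single two-group contrast; no time-course/multi-contrast mode.
- Enrichment assumes exchangeable genes within the universe; correlated
  regulons inflate neither the test nor the FDR family beyond standard BH
  assumptions, but no inter-set dependence correction is attempted.
- The impact scale is a package definition, comparable within a run,
  not across tools.
- No network fetching; KEGG-like catalogs, regulon GMTs, hierarchies and
  link tables are user-supplied files.
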