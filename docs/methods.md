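# Methods

This note documents the models, conventions, numerical choices and known
limitations of `cismap`. It describes what the code computes; every
empirical number cited here is produced by the test suite or by
`scripts/acceptance.py`, not asserted from elsewhere.

## Coordinates and distances

All intervals are 0-based half-open (BED convention); a TSS position is
a single 0-based base. The reference point of a CRM for all distance
computations is its floor midpoint `(start + end) // 2`. The signed
relative position of a CRM to a TSS is `midpoint − position`,
sign-flipped for '−'-strand TSSs, so negative always means upstream in
transcription orientation. Chromosome names are compared by exact string
equality; `diagnose_chromosome_mismatch` surfaces naming mismatches
(`chr1` vs `1`) instead of silently pairing nothing.

## Map building

1. **Non-overlapping CRM selection.** CRMs predicted in different
   tissues may overlap. Rather than amalgamating overlapping predictions
   into tissue-nonspecific regions, one representative per overlapping
   cluster is kept: greedy selection by descending prediction score,
   ties broken by leftmost start and then lexicographic id. The rule is
   deterministic and favours confident predictions; every discarded CRM
   overlaps a kept CRM of equal-or-higher priority.
2. **Candidate enumeration.** All same-chromosome CRM–TSS pairs with
   |relative position| ≤ `window_bp` (default 1 Mbp — the longest range
   at which cis-regulation is commonly sought).
3. **Correlation and threshold.** Rows of the histone and expression
   matrices are centred and L2-normalised once over the reference panel
   (test-tissue column removed first when a hold-out is named), so each
   pair's Pearson r is a dot product. The p-value is the exact two-sided
   t-test with n − 2 degrees of freedom — the standard test for a
   Pearson correlation under bivariate normality. Pairs with p ≤ θ
   become links. No multiple-testing correction is applied: θ is a raw
   p-value threshold exposed as the map's stringency parameter, and maps
   are typically built at several stringencies to show the
   accuracy/coverage trade-off.

Degenerate pairs whose histone or expression vector is constant over the
reference panel have undefined correlation; they are skipped, never
linked, and counted in `diagnostics["skipped_constant"]`. |r| = 1 maps
to the smallest positive double and is counted in diagnostics.
`min_tissues` (default 6) refuses configurations whose panel is too
small for the correlation to mean anything; real applications use 11–15
reference tissues or many hundreds. Matrices must be complete: the
per-pair n is the panel size, recorded once per map.

## Sampled control maps

A control map preserves five properties of the real map exactly or
closely: (a) the TSS universe and linked-TSS set, (b) the total link
count, (c) the per-TSS link counts (preserved *exactly*, which is the
simplest sufficient condition for "similar connectivity"), (d) the
distribution of link positions relative to the TSS, and (e) the CRM
universe. Only the identity of the linked CRMs changes.

Position matching uses binned importance sampling: link positions of the
real map are histogrammed in 50 kb signed bins over ±window; each TSS
then draws its (real) number of links without replacement from its own
in-window candidates with probability proportional to the bin weight of
each candidate's position. If a TSS has fewer positive-weight candidates
than its degree, its weights relax to uniform over the remaining
candidates and the event is logged (`diagnostics["relaxed_tss"]`); the
`max_retries` knob is retained for interface stability but the
feasibility check makes retry loops unnecessary. A TSS whose degree
exceeds its candidate count is an infeasibility error naming the TSS.

Reproducibility: replicate r of an ensemble uses the RNG stream
`default_rng([seed, r])`, so ensembles are stable under parallel
generation and fully determined by `(seed, replicate_index)`.

**Limitation.** Binned matching reproduces the position distribution at
bin resolution only. If the real map concentrates mass inside a fraction
of a bin (e.g. a nearest-CRM spike within ±10 kb), control positions
spread over the whole 50 kb bin and the two-sample KS distance saturates
around the within-bin mass. The distribution-similarity tests therefore
use maps whose position profile is smooth at the bin scale; the exact
matched properties (a)–(c), (e) hold for any input.

## Expression models

Features for a TSS are per-TF binding signals **summed** over its linked
CRMs (aggregation configurable: sum/mean/max; sum is the default because
regulatory input from multiple enhancers is at least additive in the
simplest model), then transformed by log(1 + x). The response is
log(1 + expression) in the test tissue. The log transform stabilises the
heavy right tails of both binding and expression signal and is standard
in TF-binding expression modelling. The promoter model uses binding
quantified over the strand-oriented −500..+200 bp window around the TSS,
same transform, same protocol.

Fitting is nested cross-validation: an outer seeded, shuffled K-fold
(default 10) gives the reported per-fold held-out R²; within each outer
training fold, features are standardised (training statistics only) and
the LASSO penalty is chosen by inner 5-fold CV over a 100-point penalty
path (`sklearn.linear_model.LassoCV`). Held-out R² is 1 − SS_res/SS_tot
with SS_tot about the held-out fold's own mean; negative values are
reported as-is. Nothing from a held-out fold influences scaling or
penalty choice, so permuted-response fits centre near zero (verified by
test). Feature selection is the LASSO's own sparsity; an optional
`max_features` cap keeps the top coefficients at the chosen penalty and
refits on them (inactive by default). A fold with zero response variance
is skipped with a warning.

`validate_map` fits the map model, the promoter model and each control
replicate **on the map's linked TSS set** — identical for every control
by construction — so differences in R² reflect only which CRMs each map
ties to each TSS. Nearest-neighbor map variants and their set algebra
(union, intersection, differences keyed by (crm_id, tss_id)) are each
fit on their own linked TSS set.

## Nearest-neighbor maps

Each TSS links to its k closest CRMs by |midpoint distance| within the
same ±1 Mbp window (so comparisons with correlation maps are
like-for-like); ties break by smaller genomic start, then lexicographic
id. CRMs overlapping the TSS are eligible (distance 0). A TSS with no
in-window CRM gets no link.

## Promoter characterisation

GC content is computed over the 500 bp upstream of each TSS in
transcription orientation; ambiguous bases are excluded from numerator
and denominator, fully ambiguous promoters are dropped with a warning,
and the histogram is normalised to sum to 1. The TATA scan reports, for
each offset d, the fraction of promoters whose upstream 40 bp contain
the literal tetramer TATA with its 3'-most base exactly d bases 5' of
the TSS; d runs from 1 to 37 so the whole motif fits in the window.
Matching is exact and case-insensitive; each promoter counts once per
offset regardless of multiplicity. Region overlap requires strict
containment: a link is inside a region only when the full CRM interval
and the TSS position fall within that single region.

## Synthetic panels

The generator emulates the statistical structure the method assumes — a
shared latent regulatory activity read out by both the histone mark at a
CRM and the expression at its target — without simulating read-level
data or peak calling.

* Elements live on one synthetic chromosome: CRMs (300–1200 bp) on a
  jittered grid with 20 kb mean spacing (≈100 candidates per ±1 Mbp
  window, a realistic enhancer density), TSSs uniform.
* Each linked TSS and its parent CRMs share a latent activity
  `a ~ LogNormal(0, 0.5)` per reference tissue. Histone at a parent CRM
  is `a + noise` and expression at the TSS is `a + noise`, each noise
  term a mean-centred gamma variate with sd `sd(a)·√((1−ρ)/ρ)` so the
  pairwise correlation is the configured `link_correlation` (default
  0.95, a strong planted effect); values are clipped at 0 as physical
  signal.
* Unlinked CRMs and TSSs carry independent gamma(shape 4) signal. The
  shape matters: the correlation t-test assumes normality, and strongly
  log-normal marginals inflate its extreme tails several-fold, while
  gamma(4) (skewness 1) keeps the null link rate within binomial error
  of θ down to 10⁻³ for panels of 15–50 tissues. The activity σ of 0.5
  keeps cross-regulon pairs similarly calibrated.
* In the held-out test tissue each CRM is independently active with
  probability 0.5; active CRMs get a LogNormal(0, 1) activity, inactive
  ones 0. TF binding at a CRM is a per-TF loading × activity for a
  random half of TFs plus noise; test expression at a TSS is the sum of
  its parent CRM activities plus noise. Binding therefore predicts
  expression only through true links — the property the validation is
  designed to detect.
* Half of planted links (configurable `frac_distal`) attach the TSS's
  globally nearest CRM; the rest draw uniformly from non-nearest
  in-window CRMs, so roughly half of distal links exceed 500 kb and
  long-range recovery can be compared with proximal recovery.
* The optional genome is random sequence at GC 0.45; map-target
  promoters can be rewritten at a depleted GC and given a TATA tetramer
  ending 30 bp upstream, for characterisation tests.
* Defaults: 15 reference tissues and a 53-TF panel (ENCODE-like regime:
  the lymphoblastoid test tissue has 53 TFs assayed); a
  `fantom5_like_config` preset gives 50 tissues, 1000 CRMs, 100 TSSs and
  200 planted links for the many-tissue regime in which extreme
  stringencies are reachable.

What passing tests on these panels show: the pipeline recovers planted
correlation structure at the advertised error rates and the validation
separates real from control links when binding truly drives expression.
What they do not show: robustness to quantification artefacts, batch
effects, correlated noise across tissues, overlapping regulatory
domains, or CRM predictions that are themselves wrong — none of which
the generator emulates.

## Problem sizes in tests and the acceptance script

Test and acceptance runs use compact instances chosen to make the
statistical checks sharp at desk scale: toy oracle instances (20 CRM ×
5 TSS × 8 tissues), null panels pooling ≈4700 candidate pairs over three
seeds, recovery on five 50-tissue panels (1000 quantities), validation
with 10 control replicates and 10 outer folds on 100-TSS maps, KS checks
on ≥1000-link maps, and the NN comparison on degree-1 truth with a 22-TF
panel (the smallest real TF panel) at θ = 10⁻⁶, averaged over three
seeds. Stringency monotonicity is assessed on fold R² pooled over two
seeds, comparing consecutive θ with one combined standard error of the
difference.

## Known limitations

* The artifact consumes pre-quantified signal matrices; signal
  extraction from coverage tracks (bigWig/BAM) is out of scope.
* Raw p-value thresholding means loose stringencies admit a predictable
  false-link fraction (θ × candidate pairs); map quality at θ ≥ 10⁻²
  degrades accordingly, which the stringency sweep makes visible.
* Pearson correlation assumes a collinear histone–expression
  relationship; rank-based or information-theoretic alternatives are not
  implemented.
* The control sampler matches positions at bin resolution (see above).
* Promoter models and CRM models share one protocol by design; no
  attempt is made to tune either separately.
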