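# Methods

## Data model

The atomic record is an *occurrence*: the unique combination of a taxon, a
fossil locality, and one of three analysis time intervals (Tortonian,
pre-evaporitic Messinian, Zanclean). Within an organism group, duplicate
(taxon, locality, interval) rows are collapsed to one occurrence at load;
when duplicates disagree on the reworked flag the non-reworked copy wins,
since a genuine in-place record of that occurrence exists. Region is a
property of the locality, not part of occurrence identity. Records dated to
the salinity-crisis interval itself are rejected at load: that record is too
sparse for occurrence-based standardisation, and mixing it in would
contaminate the pre/post comparison.

Reworked occurrences (fossils redeposited into younger sediment) are
excluded before any statistic is computed. Genus-level analyses replace the
taxon name by the genus and re-deduplicate; indeterminate-rank records
without a genus are dropped with a logged count (conservative: they can
support neither a species nor a genus tally), while species-rank records
without a genus are a validation error.

Coral records carry an ecology attribution (zooxanthellate `z`,
azooxanthellate `az`, or `unresolved` where the genus contains both and the
record has no per-record resolution). "All corals" analyses include all
three; `z`/`az` analyses include only the matching attribution, so
unresolved records never leak into an ecology-specific run.

## Evaluability

A stratum enters a statistical comparison only with at least 15
occurrences; the boundary is inclusive (15 passes, 14 fails). Below that,
an 80% quota leaves ~12 records and replicate richness is dominated by
noise. The floor is applied per interval within whatever scope (basin or
region) is being compared; failing strata are reported with a status flag,
never dropped silently, and `make_plan(..., floor=None)` is the explicit
override.

## Rarefaction

Sampling effort differs by orders of magnitude between groups, intervals
and regions, so all richness comparisons are made at a shared quota:
`quota = floor(fraction × min stratum size)` with `fraction = 0.80` by
default, subsampling occurrences **without replacement** (classical
rarefaction; the occurrence — not the locality or taxon — is the sampling
unit), 10,000 replicates by default. Replicate richness is summarised by
the median, the linearly interpolated quartiles, and Tukey whiskers
(quartiles ± 1.5 × IQR, clipped to observed values). Percent change between
strata is the change of medians relative to the baseline (oldest) interval.

Numerical/validation details:

- Quota uses floor (integer sample size, conservative); quota 0 or an empty
  stratum is a hard error.
- The replicate stream for stratum *s*, replicate *r* is derived from
  (plan seed, *s*, *r*) via `numpy` `SeedSequence` spawn keys, so any single
  replicate can be recomputed in isolation and runs are exactly reproducible.
- The Monte-Carlo engine is checked against the closed-form hypergeometric
  expectation `E[S] = Σ_i [1 − C(N−n_i, q)/C(N, q)]`, which is exposed as
  `expected_richness` and recomputed independently in the tests (for the
  {5, 3, 2} fixture at quota 4 it equals 2.476190…).
- The quartile estimator (linear interpolation between order statistics) is
  the common default; it is a documented choice, not a claim about how any
  particular published figure was drawn.

For three-interval richness panels the default quota is shared by all three
intervals ("three_way"); pairwise quotas (each pair rarefied to its own
minimum) are available via `comparison="pairwise"`. Beta partitions and
rank tests always use the pair's own quota.

## Beta-diversity partition

With `a` shared taxa and `b`, `c` unique to either side:
`β_sor = (b+c)/(2a+b+c)`, `β_sim = min(b,c)/(a+min(b,c))`,
`β_nes = β_sor − β_sim`. These are the standard incidence-based pairwise
definitions for which turnover is independent of richness differences and
the nestedness-resultant component is the remainder of the Sørensen total.
Exact mode computes them on full assemblages (additivity holds to machine
precision; symmetric in the arguments; empty assemblages are an error).
Rarefied mode computes the partition per replicate on the subsampled
assemblages and reports per-index medians; the median triplet need not
satisfy additivity exactly, which is recorded in the result metadata.
Percentages in reports are index × 100.

## Rank tests

Two constructions over a pair's shared-quota replicates: a two-sample
Wilcoxon rank-sum (Mann–Whitney) test between the two replicate richness
lists, and a one-sample Wilcoxon signed-rank test on per-replicate
differences. The tail is chosen by the sign of the median difference and
reported. Exact enumeration is used for tie-free samples with n1+n2 ≤ 12
(rank-sum) or n ≤ 25 (signed-rank); otherwise the normal approximation with
midrank tie correction and continuity correction. Zero differences are
dropped before ranking; an all-zero difference vector is a degenerate-input
error. Both paths are scipy-backed and verified against brute-force
enumeration oracles in the tests.

Two caveats are deliberately built in. First, every result carries a text
caveat that rarefaction replicates are pseudo-replicates of a single
dataset: p-values shrink without bound as the replicate count grows and
must not be read as independent-sample evidence. Reported p-values are
floored at machine epsilon rather than printed as zero. Second, no
multiple-testing correction is applied across groups; adding one silently
would misrepresent the procedure this pipeline implements, so the absence
is stated instead.

## Synthetic scenarios and what they do (not) show

`ScenarioSpec` programs, per group: a Tortonian species pool; per-step
`turnover_frac` (taxa replaced by novel taxa) and `nested_loss_frac` (taxa
lost outright), applied Tortonian→Messinian and again Messinian→Zanclean;
sampling effort per (group, interval) split multinomially over the three
regions; uniform or geometric-series abundances (`geometric_s = 0.8`
default for dominance structure; uniform for analytic checks); localities
allocated to regions; a Bernoulli reworked fraction; and, for corals, a z/az
attribution with optional z-extirpation after the Messinian. Ground truth
(pools, richness, pairwise beta) is computed exactly from the realised
pools and stored with the dataset, so recovery tests compare pipeline
estimates against closed-form answers. The same seed reproduces the dataset
byte for byte. `degrade()` thins one stratum's records with keep-probability
1/factor to emulate facies/sampling bias.

`study_default()` is the study-scale scenario: 13 groups (including sharks
and marine mammals, which load and validate but are excluded from
statistics by default), pool sizes and efforts chosen so the compilation
lands near a realistic regional scale (~23,000 unique occurrences, ~4,800
observed species, strongly uneven effort between groups), turnover 0.35 and
nested loss 0.05 per step, 5% reworked records, geometric abundances with a
gentle gradient (s = 0.999, appropriate to pools of hundreds of taxa), 200
localities.

What the generator does **not** emulate: spatial autocorrelation of
localities, facies-selective preservation, taxonomic revision error,
stratigraphic dating uncertainty, or correlated sampling between groups.
Passing recovery tests therefore show the estimators are correct under
known sampling models of this structure — not that any particular empirical
compilation is unbiased.

## Problem sizes used by tests and the acceptance script

The unit/property suite runs small fixtures and 50–1,000-replicate plans;
the end-to-end study-scale check in the suite uses 1,000 replicates. The
acceptance script repeats the study-scale run and the truth-recovery
scenarios at the full 10,000 replicates (deep even sampling: one group,
100-taxon pool, ~4,600 occurrences per interval). These sizes were chosen
so each stage is exercised at the scale its defaults target while keeping
the whole run reproducible on a single CPU in minutes.

## Known limitations

- Pairwise beta only; multi-site (more than two assemblages) partitions and
  abundance-based (e.g. Bray–Curtis) decompositions are out of scope.
- No coverage-based (Chao-style) standardisation or extrapolation;
  rarefaction interpolates only.
- Occurrence tables are read wholesale into memory; compilations in the
  10⁵–10⁶ row range are fine, but the package is not an out-of-core tool.
- The reworked flag, region placement and coral-ecology attribution are
  taken as given in the input; the package validates form, not science.
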