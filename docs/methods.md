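# Methods

This note documents the statistical models implemented in
`phyloassembly`, the conventions and defaults chosen where the
literature admits more than one reading, and what the synthetic-data
generators do and do not emulate.

## Phylogenetic null models

**MNTD / NTI (per sample).** MNTD is the mean, over taxa present in a
sample, of the patristic distance to the nearest other present taxon
(presence-based; an abundance-weighted variant exists for βMNTD, below).
The null shuffles tip labels across the full analyzed taxon pool — all
taxa in the aligned table, not only those in the focal sample — which is
equivalent to drawing uniform random subsets of the same richness
("taxa.labels", richness preserved). NTI is the *negated* z-score,
NTI = −(MNTD_obs − μ_null)/σ_null, so positive values mean phylogenetic
clustering and NTI > +2 is read as environmental filtering. Default
1000 randomizations.

**βMNTD / βNTI (per sample pair).** βMNTD between samples k and l
averages, in both directions, each taxon's distance to its nearest
taxon in the partner sample; the abundance-weighted form (default)
weights each taxon by its relative abundance, and a presence-based form
sits behind `weighted=False` (both appear in common tooling; the flag is
recorded in output provenance). βNTI = (βMNTD_obs − μ_null)/σ_null with
999 tip-shuffle replicates by default. One label shuffle per replicate
is shared by all sample pairs: the pairwise values then share a coherent
null and the computation vectorizes to a matrix product per replicate.
Pairs with σ_null = 0 (e.g. equidistant star trees) are flagged NaN and
counted, never silently reported as 0.

Exhaustive-enumeration twins (`nti_exhaustive`,
`beta_nti_exhaustive`) compute the exact null over all T! tip
permutations for pools of ≤ 8 taxa; they are the brute-force oracles the
sampled implementations are tested against (agreement within |Δ| < 0.15
at 10⁴ replicates).

## Raup–Crick on Bray–Curtis

For each pair and replicate both communities are re-assembled from the
regional pool: a community draws its observed richness without
replacement with probability ∝ occupancy (number of samples containing
the taxon), each drawn taxon is seeded with one read, and the remaining
reads are allocated multinomially ∝ metacommunity mean relative
abundance — so null communities preserve the sample's richness and read
total. The single-read seeding guarantees drawn taxa are actually
present; total reads are conserved. RC_raw is the fraction of null
Bray–Curtis values below the observed one, ties counted at half weight
(mid-P), and RC_bray = 2(RC_raw − ½) ∈ [−1, 1]. Within a replicate each
sample's null assembly is shared across the pairs it participates in,
mirroring the shared-shuffle convention of βNTI. Default 999 replicates.

## Five-process partition

Per pair: βNTI > 2 → variable selection; βNTI < −2 → homogeneous
selection; otherwise RC > 0.95 → dispersal limitation; RC < −0.95 →
homogenizing dispersal; |RC| ≤ 0.95 → undominated (drift). Thresholds
are strict exceedances, so boundary values fall to the stochastic /
undominated side. "Stochastic %" is the share of classified pairs with
|βNTI| ≤ 2. Group summaries count within-group pairs only (or all pairs
pooled); flagged pairs are excluded with a reported count, and
percentages are over classified pairs, summing to 100.

## Sloan's neutral community model

At stationarity the local relative abundance of OTU i is
Beta(N·m·p_i, N·m·(1−p_i)): N is the local community size (taken as the
mean reads per sample), p_i the metacommunity relative abundance (mean
of per-sample relative abundances), and m the migration rate — the
probability that a death is replaced by an immigrant. The predicted
detection frequency uses one of two conventions:

- `detection="exact"` (default): the probability that at least one of N
  multinomially drawn reads hits the OTU,
  f̂ = 1 − B(a, b+N)/B(a, b). This is the exact marginal detection
  probability for sequencing-style (Dirichlet-multinomial) data; fitting
  it recovers a known m essentially unbiased (median relative error ≈ 2%
  at N = 1000, 60 samples, 800 taxa).
- `detection="threshold"`: the classic sharp-cutoff approximation
  f̂ = 1 − BetaCDF(1/N; a, b) with detection threshold d = 1/N, the
  convention of the widely used R implementations. Against
  Dirichlet-multinomial data this form overestimates m by roughly 45%
  under the same conditions, because reads detect taxa below 1/N with
  appreciable probability; it is retained for comparability with
  published fits.

m is fit by bounded scalar least squares on (10⁻⁶, 1]; goodness of fit
is the generalized R² = 1 − SS_res/SS_tot (negative for terrible fits,
never > 1; > 0.2 is conventionally read as a neutral-assembly signal).
The 95% band uses Wilson score intervals around f̂ at n = number of
samples (Clopper–Pearson behind `ci_method="binom"`); OTUs are
partitioned above/within/below the band. Occurrence means count ≥ 1; no
relative-abundance floor beyond the model's own d. Per-group fits
require ≥ 3 samples; smaller groups are skipped with a warning. No
rarefaction is applied anywhere by default.

## Species-abundance distribution

Pooled per-taxon abundances are binned into Preston doubling octaves
(octave R spans (2^(R−1), 2^R]; abundances exactly on a power-of-two
boundary contribute half a species to each adjacent octave). The
log-normal form S(R) = S₀·e^(−a²R²) — R the signed offset from the
modal octave, S₀ the modal-octave species count, 1/a the distribution
width — is fit by nonlinear least squares, alongside a geometric-series
comparator S(octave) = c·θ^octave on the same histogram. Both models
report the Gaussian-residual AIC, n·ln(SS_res/n) + 2k with k = 2 and n
the number of octaves; the comparison contract is relative (lower wins
among models fit the same way), not an absolute AIC scale.

## Diversity indices and distances

Chao1 = SR + F1²/(2F2), switching to the bias-corrected
SR + F1(F1−1)/(2(F2+1)) when F2 = 0; ACE uses rare threshold 10 and
falls back to bias-corrected Chao1 when coverage is 0 (all rare taxa
singletons). Shannon is in natural log; "Simpson" is reported as
Gini–Simpson 1 − Σp². Faith PD (scikit-bio) includes the stem to the
root. Bray–Curtis and weighted UniFrac operate on per-sample relative
abundances, removing library-size artifacts; UniFrac is normalized to
[0, 1] by default (raw variant behind a flag), and identical
compositions return exactly 0 rather than a 0/0 normalization.

## Mantel and partial Mantel

The Mantel statistic correlates upper triangles (Pearson, or Spearman
via rank transform); significance jointly permutes rows/columns of the
second matrix, p = (1 + #{r_perm ≥ r_obs})/(1 + n_perm) — one-sided
"greater" by default (the distance-decay convention; a two-sided
alternative exists) and never 0 by the add-one rule. The partial
variant residualizes both triangles on the control matrix's triangle
and re-residualizes under each permutation; if the controlled residual
vanishes (dy collinear with dz) the partial r is 0 by convention.
Defaults: 9999 permutations (plain), 999 (partial). Environmental
distances are Euclidean on z-scored variables (sample sd, so distances
are invariant to affine rescaling; zero-variance variables dropped with
a warning); geographic distances default to haversine on a 6371-km
sphere, with a Euclidean-on-degrees mode for comparability with analyses
that used raw coordinates. Both matrices' sample sets must match;
permutation cores run on a seeded generator, with scikit-bio's `mantel`
kept as an independent cross-check in the test suite.

## Synthetic data: what it emulates, and what it does not

The generators emulate the statistical structure of an altitudinal
soil-survey design: 7 elevations × 3 soil layers (surface/middle/deep)
× 3 replicates = 63 samples by default, a few hundred taxa with
log-normal metacommunity abundances, and per-sample read depth as a
multinomial draw. Read depth defaults to 2000 — a deliberately
scaled-down library size (real ITS runs are ~6.6×10⁴ reads/sample) so a
full pipeline run takes seconds; richness per sample stays in the
hundreds and every statistic remains well defined. Validation problem
sizes follow the same logic (e.g. null models at 199 replicates and
10-seed scenario batteries), chosen so each battery completes in well
under a minute of CPU while keeping Monte-Carlo error far below the
decision thresholds.

Regimes:

- **Neutral** — Dirichlet(Nm·p) compositions then multinomial reads:
  the stationary distribution of Sloan's model, chosen over explicit
  birth–death–immigration time-stepping precisely so that fitting the
  NCM to the output is a clean parameter-recovery experiment
  (true m = Nm/reads).
- **Selection** — a trait evolves on the tree by Brownian motion
  (tip values standardized), and sample j weights taxon i by
  p_i·exp(−(trait_i − env_j)²/(2σ_w²)). Brownian traits make the
  filtering phylogenetically autocorrelated — necessary for a
  *phylogenetic* statistic (βNTI) to register selection. Contrasting
  env values produce variable selection between groups; a single
  extreme env value produces homogeneous selection, which is only
  detectable when the analyzed pool is broader than the realized niche
  (keep unobserved taxa in the table, or use a pool-spanning tree).
- **Dispersal-limited** — taxa assigned at random (no phylogenetic
  structure) to patch pools sharing a fraction `overlap` of taxa;
  samples draw only from their patch. Between-patch pairs show
  |βNTI| < 2 with RC → +1: dispersal limitation. Within-patch pairs are
  *more* similar than the regional null and classify as homogenizing
  dispersal — a faithful property of the regime, not an artifact.

Not emulated: raw reads, PCR/chimera artifacts, OTU clustering noise,
taxonomy, spatially explicit landscapes, temporal dynamics, and
environment–abundance feedbacks beyond the Gaussian niche. Passing
tests therefore demonstrate the *statistical machinery* is correct and
calibrated on data satisfying each model's assumptions; they do not
certify behavior under real-data pathologies (compositional artifacts,
uneven sequencing depth, tree misestimation).

## Numerical and design notes

- **Determinism.** Every stochastic routine takes a seed; the pipeline
  splits one global seed into per-stage substreams keyed by stable stage
  names (CRC-32 of the name into a `SeedSequence`), so toggling one
  stage never changes another's draws. TSV floats use a fixed `%.10g`
  format and JSON keys are sorted: identical config + seed reproduces
  outputs byte for byte.
- **Alignment.** Taxa are restricted to table ∩ tree tips (tables
  routinely exceed the tree; dropped counts are logged), samples to
  table ∩ metadata; all orderings lexicographic; `align_inputs` is
  idempotent.
- **Degenerate inputs.** All-zero samples, single-taxon tables,
  single-octave SADs, σ_null = 0 nulls and zero-variance environmental
  variables are rejected or flagged explicitly — never coerced to 0.
- **Table orientation** defaults to taxa-as-rows with a transpose flag.
- **Null replicate counts** follow the stated conventions (1000 for
  NTI, 999 for βNTI/RC) and are configurable; Raup–Crick's replicate
  count has no canonical value and simply reuses 999.
- **Thresholds** (±2, ±0.95) are fixed constants of the framework, not
  tunables.
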