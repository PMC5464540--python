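# Methods

## The estimation problem

Dilution-style virus production assays follow bulk prokaryotic (P) and
viral (V) abundance in sealed incubations of natural water, typically in
duplicate, across several treatments: whole water with and without
mitomycin C, virus-reduced ("dilution") water with and without mitomycin C,
and a cell-free decay control. Because the community contains many host
taxa in different stages of infection, V(t) is non-monotonic: each cohort
of infected cells that completes its latent period produces a discrete
burst of free viruses, while decay pulls the curve down between bursts.
The package estimates gross rates from this structure rather than from a
single fitted slope.

## Piece-wise rates

A series is segmented at its local extrema. Interior extrema are sign
changes of the first differences; runs of equal consecutive values are
merged into a single extremum placed at the last point of the run (a
deterministic tie-break); the first and last samples are always boundary
extrema, typed by the direction of the adjacent segment. No smoothing or
noise thresholding is applied — every local maximum is treated as a lysis
signal. This is a deliberate modelling commitment: with multiplicative
counting noise of CV σ, spurious rises of order σ·V enter the gross rates,
so VP and VD are upper-biased net-of-nothing estimates whose bias grows
with standing stock. That bias is inherent to the method, not to this
implementation; the duplicate range is the only uncertainty measure
carried.

A replicate's production rate is the sum of rising-segment amplitudes
divided by the total incubation span (not the mean of per-segment slopes).
This choice makes VP × duration equal the accumulated viral rise that also
feeds the infected-cell computation, and it makes production − loss
telescope exactly to (final − initial)/duration, which the tests verify as
an invariant. Turnover times divide in situ standing stocks by the
production rates and convert hours to days.

Rates from dilution replicates are multiplied by c = P_insitu / P(t₀) to
undo the variable recovery of the tangential-flow filtration; undiluted
replicates use c = 1. The same factor scales the viral-rise numerator of
FIC, so dilution-approach FIC is referenced to in situ conditions while
its denominator remains the measured t₀ prokaryotic abundance of the
replicate.

## Infection metrics

FIC converts accumulated rises to a percentage of the standing stock via a
burst size (default 28 viruses per cell, a literature TEM value for
brackish suboxic water). FIC is inversely proportional to the burst size;
when an empirical burst size (VP / mortality, dilution replicates only) is
available, the rescale factor assumed/empirical quantifies how much FIC
shifts. FLC is the difference between induced and control mean FIC and is
reported only when the duplicate ranges of the two treatments are disjoint
(closed intervals — touching ranges count as overlapping) and the induced
mean is larger; it is computed per approach, never pooled across
approaches. Duplicates are summarised as the midpoint average and min–max
range, replicates being processed independently first.

Intrinsic decay is the OLS slope of ln V on time. The detection rule —
p ≤ 0.05, R² ≥ 0.50, slope < 0 — makes the rate a censored quantity: a
fit failing any clause is reported as "below detection", never as zero. A
positive slope is reported but can never be flagged as detected.

## Comparative statistics

Spearman correlations use average ranks for ties; below-detection values
are carried as missing-with-flag through parsing and substituted (default:
zero) only at analysis time, so "n.d." markers survive round-trips. For
n ≤ 9 an exact two-sided p by full enumeration of rank permutations is
available. Mann–Whitney returns the classical U, the tie-corrected normal
z, and the two-sided p; Kruskal–Wallis is tie-corrected with pairwise U
tests as post-hoc. The "relevant difference" rule between single
experiments is disjointness of the duplicate ranges.

Redundancy analysis is the multivariate least-squares projection of the
column-centered response matrix; the partial variant residualises response
and explanatory matrices on the conditional matrix. Variance fractions are
raw R² by default (Ezekiel-adjusted fractions optional, and then
individual components may be negative): unique explanatory
R²(X+Z) − R²(Z), conditional R²(X+Z) − R²(X), shared
R²(X) + R²(Z) − R²(X+Z), residual 1 − R²(X+Z); the four sum to one. The
permutation test permutes rows of the residualised response without
replacement (a bootstrap mode resampling with replacement is available but
is not the default, since with-replacement resampling is nonstandard for
ordination significance); p = (exceedances + 1)/(n_perm + 1), seeded, with
10 000 permutations by default. The partition is cross-checked in the test
suite against values computed with vegan::rda / RsquareAdj on a frozen
seeded fixture. Rank-deficient designs fall back to the pseudo-inverse
projection and are flagged.

## The synthetic generator

`simulate_experiment` integrates a deterministic cohort-lysis model with an
Euler step of 0.1 h (halving the step changes observed series by < 0.1%,
verified in the tests): uninfected cells grow exponentially; each infected
cohort lyses uniformly over [latency, latency + spread], releasing its
burst; free viruses decay exponentially; when the adsorption coefficient is
positive, new infections arise at rate k·V·P and join a delayed cohort
(one virion consumed per infection). Mitomycin C induction is an extra
cohort. Duplicates share the dynamics (same water) and differ only by
mean-one lognormal observation noise. Uniform within-cohort lysis is the
simplest mechanism that yields discrete abundance maxima at 5 h sampling.

Default parameters encode the emulated study conditions: ~7.3×10⁵
prokaryotes mL⁻¹ and 1.5×10⁷ viruses mL⁻¹ in situ; two staggered cohorts
(latencies 8 h and 22 h, burst 10, ~8% of cells infected); prokaryotic
growth 0.006 h⁻¹; in-incubation viral decay 0.004 h⁻¹ but zero intrinsic
decay (the decay control uses the intrinsic rate only — the distinction
reflects that enzymatic and particle-mediated decay are removed by
ultra-filtration); dilution recovery 132% for prokaryotes and 30% virus
carry-over; adsorption 4×10⁻¹⁰ mL h⁻¹ in whole water and zero in dilution
treatments; noise CV 0.05 (flow-cytometric triplicate counting implies
small measurement error); sampling 0–40 h every 5 h in duplicate. With
these defaults the pipeline lands inside the emulated study's reported
ranges (dilution VP ~1.9×10⁴ mL⁻¹ h⁻¹, dilution FIC ~3%, viral turnover
~40 d, empirical burst ~9, no intrinsic-decay detections), which is a
consistency property of the generator, not an empirical result.

What the generator does not emulate: taxon-resolved host dynamics, grazing,
nutrient feedback on growth, inter-duplicate biological variability, and
any chemistry of the redox gradient. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated noise model,
not field accuracy. `simulate_env_table` provides depth-ordered
physicochemistry with monotone O₂/H₂S/NH₄ gradients and below-detection
censoring for exercising the correlation machinery only.

## Numerical and design choices

- Segmentation needs ≥ 3 points; an all-constant series yields a degenerate
  segmentation with zero segments and zero rates, while turnover at zero
  production raises an undefined-result signal rather than returning
  infinity.
- The ln-linear decay fit refuses zero abundances (log undefined) instead
  of imputing.
- The packaged nine-sample environmental table keeps the printed
  virus-to-prokaryote ratio column as printed (rounded) rather than
  recomputing it, so rank statistics match the published table layout;
  abundance columns are expanded from their printed 10⁵/10⁷ scales via a
  sidecar schema.
- Cross-study compilations are validated on load by recomputing
  VPR = VA/PA, VTT = VA/VP (converted to days), VT = 1/VTT and requiring
  agreement within 5% (printed rounding tolerance); missing entries are
  filled from the identities. The packaged compilation is synthetic — it
  exercises the loader and carries no empirical content.
- Mann–Whitney reports both U and z because small-sample software often
  prints the normal approximation; no downstream logic depends on which
  one is read.
- All randomness (simulation noise, permutation tests) flows from explicit
  integer seeds; reports are byte-identical across runs with equal inputs
  and seeds.

## Known limitations

Gross rates are biased upward by observation noise (see above); FLC
detectability depends strongly on duplicate spread, so weak induction is
usually censored; the RDA permutation test with n near the number of
predictors has little power and its raw-R² fractions are optimistic for
small n; the empirical burst size inherits the biases of both VP and
mortality and is undefined when no prokaryotic decline is observed.
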