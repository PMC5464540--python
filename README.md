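# viroprod

Estimation of virus-mediated prokaryotic mortality from incubation
experiments: piece-wise virus production and decay rates, the frequency of
lytically (FIC) and lysogenically (FLC) infected cells, burst size, turnover
times, intrinsic viral decay with a statistical detection rule, and the
comparative statistics used alongside them. The package is aimed at aquatic
microbial ecologists who run dilution-style virus production assays — bulk
prokaryotic and viral abundance counted every few hours over a one- to
two-day incubation — and need reproducible rate estimates from the strongly
non-monotonic time series such assays produce.

## The method

Bulk viral abundance V(t) in an incubation of a natural community rarely
changes linearly: host cells in different stages of infection lyse in
staggered cohorts, so V(t) alternates between local minima (V_min) and
maxima (V_max). A least-squares slope through such data underestimates the
gross rate and is usually unsupported statistically. The piece-wise method
segments each series at its local extrema and accumulates amplitudes:

    VP = Σ_rising (V_max,n − V_min,n) / (t_last − t_first)
    VD = Σ_falling (V_max,n − V_min,n) / (t_last − t_first)

and identically PG (growth) and mortality for the prokaryote series. Net
rates are VP − VD and PG − mortality; by construction the net rate times the
duration telescopes to the end-to-start abundance difference. Rates from the
virus-dilution treatment are multiplied by the recovery correction
c = P_in situ / P(t₀). Derived quantities:

    FIC  = 100 · c · Σ_rising ΔV / (BS · P(t₀))        [% of standing stock]
    FLC  = FIC_mitC − FIC_control   (only if duplicate ranges are disjoint
                                     and the induced mean is higher)
    BS_empirical = VP / mortality   (dilution replicates)
    turnover [d] = standing stock / production / 24

Intrinsic viral decay is the slope of an ordinary least-squares fit of
ln V(t) against time in a cell- and particle-free decay incubation, reported
as *detected* only when p ≤ 0.05, R² ≥ 0.50 and the slope is negative.

The `stats` module provides the surrounding comparative statistics
(tie-corrected Spearman with below-detection→0 substitution and an exact
permutation option, Mann–Whitney U with tie-corrected z, Kruskal–Wallis with
pairwise post-hoc tests, the duplicate-range "relevant difference" rule) and
partial redundancy analysis with variation partitioning and a seeded
permutation test, cross-checked against `vegan::rda`.

The `simulate` module generates truth-known experiments: staggered infected
cohorts with per-cohort latency, lysis window and burst size; exponential
growth of uninfected hosts; free-virus decay; optional abundance-dependent
reinfection (suppressed in dilution treatments); mitomycin C induction as an
extra cohort; and mean-one lognormal counting noise. It emits the same CSV
schema the readers consume, plus a ground-truth record.

## Worked example

```python
from viroprod import (IncubationSeries, detect_extrema, production_rate,
                      loss_rate, fic)

virus = IncubationSeries(
    station="GD", zone="anoxic", treatment="dilution", replicate=1,
    population="virus",
    times=(0, 5, 10, 15, 20, 25, 30, 35, 40),
    abundances=(4.54e6, 4.06e6, 4.28e6, 4.90e6, 4.75e6,
                4.56e6, 4.75e6, 4.76e6, 4.67e6),
)
seg = detect_extrema(virus)
print([(p.time, p.kind) for p in seg.points])
print(f"VP  = {production_rate(virus):.3g}  VD = {loss_rate(virus):.3g}")
print(f"FIC = {fic(virus, p0=9.6e5, burst=28):.2f} %")
```

prints

```
[(0.0, 'max'), (5.0, 'min'), (15.0, 'max'), (25.0, 'min'), (35.0, 'max'), (40.0, 'min')]
VP  = 2.6e+04  VD = 2.28e+04
FIC = 3.87 %
```

i.e. the series rises in two phases (5→15 h and 25→35 h, two lysis events),
gross production 2.6×10⁴ viruses mL⁻¹ h⁻¹ against 2.3×10⁴ lost to decay,
and the accumulated rises correspond to 3.87 % of the prokaryotic standing
stock having been lytically infected at a burst size of 28.

The same analysis runs from the shell:

```
viroprod simulate --seed 1 --out sim.csv      # synthetic 5-treatment study
viroprod rates   --input sim.csv              # piece-wise rates per replicate
viroprod run-all --input sim.csv --out report # full report (JSON + CSV)
```

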