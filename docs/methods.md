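# Methods

This note documents the statistical model and procedure the package
implements, the choices made where the design was genuinely open, and what
the synthetic generator does and does not emulate.

## The quantification model

Detector response per compound is linear over a validated range,
`A = m·C + b`, fitted by **unweighted OLS** (no weighting scheme is part of
the method; the reported `r` is the Pearson correlation of the calibration
points). Inversion `C = (A − b)/m` is total: out-of-range and negative
results are returned flagged (`below_range`, `above_range`, `negative`)
rather than raised, because sample quantification must proceed near range
edges.

The single-marker route replaces per-compound curves by relative correction
factors `f_is = (C_i·A_s)/(C_s·A_i)`, a ratio of response factors that is
invariant under any common rescaling of the areas in a run (detector gain)
and equals `m_s/m_i` exactly when both intercepts vanish. Quantification
uses the **mean** `f_is` per compound (the factor is treated as a constant
of proportionality; per-run factors are aggregated, never used
individually). Note the gain invariance holds for the concentration ratio
`C_i/C_s`; the absolute contents still pass once through the reference
curve.

An algebraic consequence used as a test oracle throughout: with zero
intercepts and `f_is = m_s/m_i`, QAMS and the external standard method are
identical for any areas. Conversely, every systematic ESM-vs-QAMS offset
must come from nonzero intercepts (QAMS ignores the target compound's
intercept) or from a correction factor that differs from the current
system's slope ratio. Both mechanisms are real: in the packaged 31-sample
comparison the single-marker values sit ~10% above ESM for gallic acid and
~8% below for 7β-O-methylmorroniside — the latter is reproduced by the
simulator as intercept-extrapolation error of ESM for a compound whose
sample levels graze the bottom of its calibrated range.

## Peak location

Only the reference substance has a confirmable peak, so compounds are
identified by relative retention time (RRT = `t_i/t_s`):

1. **Anchor**: largest-area peak within ±5 % (configurable) of the expected
   absolute reference retention time; exact area ties fall back to
   proximity. No anchor ⇒ a hard error (QAMS is impossible for that run).
2. **Assignment**: candidate (compound, peak) pairs are those with relative
   RRT deviation within tolerance (default 5 %, per-compound overrides
   allowed); they are granted greedily in order of increasing deviation,
   each peak to at most one compound. The order makes assignment
   independent of compound enumeration and resolves a merged (co-eluting)
   peak in favour of the compound whose expected RRT it sits nearest —
   mirroring the co-elution failure of cornin/sweroside at 35 °C, where the
   merged apex lies by the much larger sweroside peak and cornin comes back
   *not-detected* and *contested*. Exact deviation ties raise rather than
   guess.

Assignment is invariant under uniform time rescaling (RRT is a ratio), and
is provably error-free when RRT noise stays below half the smallest
expected-RRT gap of the panel (0.01 absolute at the
7α/7β-O-methylmorroniside pair, i.e. ~0.4 % relative).

## Dispersion and validation statistics

All RSDs use the sample standard deviation (n−1): that form reproduces the
transcribed six-solution RCF RSDs to ≲0.1 % where the printed cells carry
three decimals. Ruggedness panels aggregate one mean RCF per condition and
report the across-condition RSD against a 5 % threshold; missing cells
(unseparated peak pairs) are excluded from mean and SD, never imputed.
Spike recovery is the marginal form `100·(detected − original)/added`,
which reproduces the printed loganin (104.27 %) and morroniside (102.07 %)
recoveries from the printed masses to ~0.15 percentage points; the
alternative `detected/(original+added)` form does not.

The method-agreement report pairs ESM and QAMS contents per (sample,
compound), drops not-detected pairs, and gives per-compound mean and
maximum relative difference plus a paired two-sided t-test (Wilcoxon
signed-rank optional). A caution documented here deliberately: because both
estimates derive from the same raw areas, the paired test is hyper-powered
and flags even sub-percent systematic offsets; the CLI pipeline therefore
gates on offsets that are *both* significant and practically large
(default 13 %, the envelope the packaged 31-sample comparison itself
satisfies), while the library reports the raw p-values.

## The synthetic generator

`GeneratorConfig` defines a phenomenological chromatographic system;
defaults are the study conditions used throughout the tests:

| parameter | default | meaning |
| --- | --- | --- |
| response slopes | packaged calibration slopes | area per µg/mL |
| response intercepts | 0 | through-origin detector response |
| `anchor_rt` | 31.0 min | loganin apex (inside the 50-min gradient; absolute times are configuration, not data) |
| `base_rt` | mean-RRT × 31.0 | elution pattern of the panel |
| `area_cv` | 0.02 | lognormal multiplicative area noise (matches ~1–3 % replicate-injection RSDs) |
| `rt_jitter_cv` | 0.01 | common per-run retention drift (whole chromatogram) |
| `rt_selectivity_cv` | 0.0005 | independent per-peak jitter; kept ≪ half the smallest RRT gap so location is error-free by construction |
| `condition_response_cv` | 0.015 | per-(condition, compound) response spread; sized so recomputed ruggedness RSDs stay under 5 % |
| `condition_rt_cv`, `condition_selectivity_cv` | 0.01, 0.002 | per-condition retention shifts (flow rate additionally scales retention as 1/flow) |
| `rcf_perturbation_pct` | 0 | optional offset of sample-run RCFs from slope ratios, for emulating factors carried across systems |
| content ranges | span of the packaged 31-sample survey | true contents drawn uniformly per compound |
| prep | 2 g / 50 mL, dilution 1 | fixed sample preparation |

Standard series default to the published six-level twofold dilution design
(stock … stock/32 — exactly the printed linearity ranges); a shallower
series leaves the minor components below the calibrated range and inflates
ESM extrapolation error. Crude samples omit 5-HMF and both
O-ethylmorronisides; processed samples contain them. At ≥35 °C the
cornin/sweroside peaks are emitted as one merged peak (summed area,
area-weighted apex). All randomness flows from one integer seed through
named sub-streams; identical seeds reproduce identical outputs.

What the generator does **not** emulate: physical retention modelling from
the gradient program, peak shapes/widths and integration error, baseline
drift, carryover, and between-day calibration drift. Passing tests
therefore demonstrate the correctness of the computational pipeline under
a faithful noise/structure model, not the analytical performance of any
real instrument.

Two retention-noise choices deserve justification. Run-to-run drift is
modelled as *common* to all peaks (the physical reason RRT location works);
per-peak selectivity jitter within a run is an order of magnitude smaller
than across-condition selectivity differences, consistent with the
2-decimal stability of the transcribed per-condition RRT cells. An
independent per-peak jitter as large as the run drift would scramble the
7α/7β-O-methylmorroniside pair and contradict the error-free-location
regime stated above.

## Numerical choices

- OLS via `scipy.stats.linregress`; fits require ≥3 distinct
  concentrations (warning below 6, the recommended design).
- Lognormal noise uses σ = √ln(1+cv²) (median-one multiplier).
- Assignment tie tolerance 1e-12 relative; round-trip identities asserted
  at 1e-9 relative.
- RSD of fewer than two values is undefined (error), not zero.
- Not-detected is an explicit state (absent peak / "—" cell), never 0.

## Known limitations and red test cases

Several printed summary cells of the transcribed source tables cannot be
recomputed from the printed per-observation cells at any tolerance: the
7β-O-ethylmorroniside column of the six-solution RCF table is internally
inconsistent (recomputed mean 1.140 vs printed 1.150, RSD 6.6 vs 4.9), the
instrument/column morroniside mean prints 1.04 where the eight 2-dp cells
average to 1.02, and most temperature/flow-rate RSDs were evidently
computed from unrounded triplicate values that were never published (one
column prints RSD 0.19 over three identical 2-dp cells). The acceptance
suite asserts every printed cell anyway, one parametrized case each, and
those cases fail; the non-acceptance suite is unaffected. Reproducible
cells reproduce exactly at printed rounding.
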