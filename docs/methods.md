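# Methods

This note records the models implemented in `nitrokit`, their assumptions,
the defaults and why they were chosen, and what the synthetic-data tests
do and do not demonstrate about real data.

## Two-endmember oxygen-isotope mixing

### Model and assumptions

An observed nitrate pool is treated as a linear mixture of exactly two
sources on one tracer at a time:

    obs = f_atm · em_atm + (1 − f_atm) · em_bio ,

solved as `f_atm = (obs − em_bio)/(em_atm − em_bio)`. Assumptions: the two
endmembers are isotopically stationary over the integration time of the
pool; no post-depositional kinetic fractionation of the tracer (a good
assumption for Δ¹⁷O, which is conserved through mass-dependent chemistry,
and an approximation for δ¹⁸O); no third source. Three-endmember and
Bayesian mixing are deliberately out of scope.

### Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| atmospheric δ¹⁸O | 92 | ‰ | annual-mean snow/atmosphere nitrate at the coastal Antarctic station relevant to the shipped configuration |
| atmospheric Δ¹⁷O | 32 | ‰ | same source; Antarctic atmospheric nitrate can reach ≥ 35‰ |
| biological δ¹⁸O | 0.6 | ‰ | published constant for this system (see note below) |
| biological Δ¹⁷O | 0 | ‰ | O₂ and water both carry zero anomaly; mixing preserves it |
| λ (mass-dependent slope) | 0.52 | – | community-standard linear anomaly definition; configurable; measured Δ¹⁷O values bypass the formula |
| σ(δ¹⁸O), σ(Δ¹⁷O), σ(δ¹⁵N) | 0.3, 0.8, 0.6 | ‰ | pooled 1σ precisions of the bacterial denitrifier method |
| n_draws | 10 000 | – | percentile-interval Monte-Carlo resolution |

**The 0.6‰ vs −0.5‰ biological endmember.** The 1:2 O₂:H₂O mixing
arithmetic with the measured inputs (O₂ at 23.9‰, lake water at
−12.7 ± 1.5‰) gives −0.5‰, while the constant in circulation for this
system is ~0.6‰ — the two differ by ~1.1‰, possibly from an unstated
fractionation term. The package ships 0.6‰ as the default endmember and
exposes the arithmetic separately (`biological_endmember_d18O`); it never
silently substitutes one for the other. At 91.4‰ endmember separation the
choice moves `f_bio` by ~0.01.

### Uncertainty propagation

The observation and both endmembers are drawn from independent Gaussians
(no covariance information exists for these quantities); each draw's
fraction is clipped to [0, 1] — noise can legitimately push a draw past an
endmember, so clipping is flagged, never an error. The point estimate is
the closed form on the means, the interval the [2.5, 97.5] percentile
range. When a group of n samples is apportioned mean-first, the
observation σ is the standard error of the mean, σ/√n. Draws where the
resampled endmembers come within 1e-9‰ of each other fall back to the
mean separation instead of dividing by ~0 (irrelevant at the shipped
σ = 0 endmember defaults).

Aggregation default is mean-first (mix once on the group mean); because
the model is affine in the observation, per-sample mixing followed by
averaging gives the identical fraction whenever nothing clips, and the
option exists for datasets where clipping or unequal per-sample σ matter.

## Marker-gene inventory

Gene columns are matched case-insensitively against the panel with an
explicit alias table only (no fuzzy matching: *amoA* ≠ *amoB*). Process
abundance is the **sum** over the process's genes (genes jointly evidence
a process; `max` is available), and presence is abundance > threshold with
threshold 0 by default — any positive signal counts as potential. A
qPCR-mode preset of 10 copies ng⁻¹ DNA reflects the scale at which
single-digit copy numbers are treated as background. *nirS*/*nirK* sit
under denitrification only in the default panel; they also occur in
nitrifiers, and a dual-attribution map is a supported configuration.
Unmapped columns are retained and listed, never dropped silently. The
energy/carbon screening panel covers only markers that are explicitly
named for this system (CO dehydrogenase *coxL*, uptake [NiFe]-hydrogenase
groups, CBB via *rbcL*, 3-hydroxypropionate via *accC*/*pccB*, terminal
oxidases) and is user-extensible; an "all"-rule feature whose markers are
not all present in the table scores absent.

## SIP density-shift statistic

Gradient plots demonstrate labeling visually as a peak shift; this package
defines the primary statistic as the difference in abundance-weighted mean
buoyant density, ΔWMD = WMD(¹³C) − WMD(¹²C), with the modal-fraction shift
as a secondary readout. WMD was chosen over the peak because it is robust
to fraction granularity: a peak can only move in grid steps (~0.006 g/mL
here), while WMD moves continuously. This statistic is this package's
formalization, not a community standard. Replicate microcosms are averaged
after per-profile normalization so each contributes equally regardless of
DNA yield. The labeling threshold defaults to 0.005 g mL⁻¹ — an order of
magnitude below the ~0.036 g mL⁻¹ full-labeling shift of DNA, and far
above the ΔWMD noise floor of the simulated experiments (≈ 4 × 10⁻⁴
g mL⁻¹). No atom-fraction-excess (qSIP) conversion is attempted because
gradient calibration parameters are not part of the inputs. Shift
statistics require ≥ 3 fractions per profile.

## Synthetic-data generator

The generator emulates the three input families under the study
conditions: isotope tables at instrument noise (Gaussian, 0.3/0.8/0.6‰)
with per-sample-type true atmospheric fractions (defaults 5% sediment, 4%
soil); annotation tables with log-uniform abundances over 10²–10⁴ copies
ng⁻¹ DNA for present processes and exact zeros for absent ones (default
preset: anammox absent); SIP profiles as Gaussian bands (width 0.012 g/mL,
center 1.725 g/mL) over a conventional CsCl grid of 14 fractions spanning
1.69–1.77 g/mL, with the ¹³C band rigidly translated by the true shift
and 20% multiplicative lognormal noise per fraction, 3 replicates.

All randomness derives from one spec seed through fixed `SeedSequence`
spawn keys per generator (isotopes = 0, annotation = 1, sip = 2), so each
generator reproduces identically whether called alone or alongside the
others. Ground truth goes to a sidecar JSON only.

**What passing tests show — and don't.** Parameter recovery on this
generator demonstrates correctness of the estimators under the model's own
assumptions (independent Gaussian noise, exactly two sources, rigid band
translation, no covariance). Real data can violate each: a third nitrate
source, correlated measurement errors, GC-content-dependent buoyant
density, or asymmetric partial labeling would not be caught by these
tests. The generator also makes no attempt at sequencing realism (no
reads, assembly, or community structure).

## Numerical choices

- Fractions satisfy `f_atm + f_bio = 1` exactly by construction; the
  inversion property holds to ≤ 1e-12 for endmember separations ≥ 1‰ at
  per-mil magnitudes (float64 cancellation makes tighter separations at
  large magnitudes unverifiable at that tolerance).
- Coincident endmembers raise a degenerate-endmember error; an
  observation outside the endmember hull without clipping is returned
  as-is with an `out_of_hull` flag.
- Modal-fraction ties take the first (lightest) fraction.
- One CSV dialect everywhere (comma, UTF-8, header, "." decimal, empty =
  missing) so repeated runs are byte-identical; malformed cells raise with
  file and row context rather than being coerced.
- Statistical checks in the test suite use replicate counts of 100–200
  and Monte-Carlo sizes of 4 000–100 000 draws, sized to keep the full
  suite around a few seconds while leaving comfortable margins on the
  bounds being asserted.

## Known limitations

- Two sources, one tracer at a time; the δ¹⁸O and Δ¹⁷O balances are
  reported side by side and never combined into a single estimate (how
  such a combination should be weighted is left open deliberately).
- The δ¹⁸O balance ignores post-formation fractionation of nitrate
  oxygen; interpret it as a consistency check on the Δ¹⁷O balance where
  both exist.
- The inventory starts from annotation counts; it performs no sequence
  homology search and no taxonomy assignment.
- The SIP module quantifies density shifts only; substrate assimilation
  rates (qSIP) and gradient physics are out of scope.
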