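# nitrokit

Source apportionment of nitrate, nitrogen-cycle marker-gene inventories,
and DNA stable-isotope-probing (SIP) density-shift analysis for polar lake
sediments and soils.

## The problem

In cold oligotrophic landscapes such as the ice-free coastal oases of East
Antarctica, the nitrate (NO₃⁻) in lake sediments and soils can come from
two very different sources: photochemically produced atmospheric nitrate
deposited with snow, or in-situ microbial nitrification. The two sources
carry distinct oxygen-isotope fingerprints, which makes the question
quantitatively answerable from measurements alone. `nitrokit` is aimed at
biogeochemists and environmental microbiologists who have (a) nitrate
δ¹⁸O/Δ¹⁷O tables, (b) marker-gene annotation or qPCR tables, and/or (c)
DNA-SIP gradient-fraction tables, and want a reproducible, seeded pipeline
from those tables to apportioned fractions, process-potential matrices,
and labeling calls.

## The model

**Isotope mass balance.** Nitrification builds nitrate with one O atom
from dissolved O₂ and two from ambient water, so its δ¹⁸O is low
(δ¹⁸O_bio = ⅔·δ¹⁸O_H₂O + ⅓·δ¹⁸O_O₂ ≈ 0.6‰ in this system) and it carries
no mass-independent anomaly (Δ¹⁷O = δ¹⁷O − λ·δ¹⁸O = 0, λ = 0.52).
Atmospheric nitrate formed through ozone chemistry is heavily enriched
(δ¹⁸O ≈ 92‰) with a large anomaly (Δ¹⁷O ≈ 32‰). For an observed value
`obs` on either tracer,

    f_atm = (obs − em_bio) / (em_atm − em_bio),    f_bio = 1 − f_atm .

Uncertainty is propagated by Monte-Carlo resampling of the observation and
both endmembers from independent Gaussians at their stated 1σ (instrument
precisions 0.3‰ for δ¹⁸O, 0.8‰ for Δ¹⁷O), reporting the median and the
[2.5, 97.5] percentile interval of the clipped draws.

**Gene inventories.** Annotation tables (samples/genomes × gene symbols)
are folded onto processes through an explicit panel: N₂ fixation (*nifH*),
nitrification (*amoA*, *hao*, *nxrB*), denitrification (*napA*, *narG*,
*nirS*, *nirK*, *norB*, *nosZ*), DNRA (*nrfA*), assimilatory nitrite
reduction (*nasA*, *nirA*), anammox (*hzo*, *hzs*). A process is "present"
where its aggregated abundance exceeds a threshold (default 0); processes
absent in every sample are reported globally absent.

**SIP shifts.** ¹³C-assimilating organisms build denser DNA. Labeling is
quantified as the difference in abundance-weighted mean buoyant density
(WMD, g mL⁻¹) between the ¹³C- and ¹²C-treatment distributions of a target
gene, ΔWMD = WMD₁₃ − WMD₁₂, with a labeling call at ΔWMD > 0.005 g mL⁻¹ by
default.

A seeded synthetic-data module generates all three table families with
known ground truth, so the full pipeline is testable without any external
downloads.

## Worked example

Apportion the observed sediment mean (δ¹⁸O = 4.6‰) between the shipped
endmembers:

```python
>>> import nitrokit as nk
>>> nk.two_endmember_fraction(4.6, em_bio=0.6, em_atm=92.0).f_bio
0.9562363238512035
>>> mc = nk.monte_carlo_fraction(4.6, 0.3, nk.BIOLOGICAL, nk.ATMOSPHERIC,
...                              n_draws=100_000, seed=42)
>>> round(mc.f_atm, 4), (round(mc.ci_low, 4), round(mc.ci_high, 4))
(0.0438, (0.0373, 0.0502))
```

So ~95.6% of the sediment nitrate is of biological (nitrification) origin;
the atmospheric share is 4.4% with a 95% interval of [3.7%, 5.0%] at
instrument-level noise.

The same end to end from the shell, on synthetic data with known truth
(5% atmospheric in sediments, 4% in soils):

```bash
nitrokit simulate --seed 11 --out-dir demo
nitrokit mix --input demo/isotopes.csv --seed 11 --out-dir demo
```

`demo/mixing_results.csv` then contains one row per sample-type group and
tracer (values from this exact run):

```
   group tracer  point_obs  f_bio  ci_low  ci_high
sediment   d18O     5.0017 0.9518  0.0456   0.0508
sediment   D17O     2.0049 0.9373  0.0427   0.0832
    soil   d18O     4.3032 0.9595  0.0380   0.0432
    soil   D17O     1.5848 0.9505  0.0291   0.0698
```

Both tracers recover the simulated truth within noise, and the δ¹⁸O and
Δ¹⁷O balances are reported side by side, never averaged. The companion
subcommands `nitrokit inventory` (process abundance/presence matrices plus
a JSON absence report) and `nitrokit sip` (ΔWMD shift table plus labeling
summary) work the same way; `--help` lists their options.

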