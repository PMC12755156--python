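# pedkit

Pedigree-based demography, inbreeding, and genetic-diversity analysis for
livestock registries.

Breed associations curate multi-decade herd books: one row per animal with
its sire, dam, sex, and birth date, often with large and time-varying gaps
in recorded parentage. From that single table a conservation geneticist
wants to know how complete the pedigree actually is, how fast inbreeding is
accumulating, how large the population effectively is, and how much founder
diversity has already been lost to unequal founder use, bottlenecks, and
drift. `pedkit` computes that whole battery of statistics from a plain
delimited pedigree file, and ships a registry simulator with known ground
truth so every estimator can be validated end to end.

## What it computes

* **Completeness** — pedigree completeness index (PCI) per ancestral depth
  (harmonic-mean combination of the paternal and maternal line scores), and
  the generation counts GMax, GCom, and GEqu = Σ(1/2)ⁿ over known ancestors.
* **Demography** — generation intervals over the four gametic pathways
  (sire→son, sire→daughter, dam→son, dam→daughter; only offspring that
  themselves reproduce count), progeny statistics, and parity distributions.
* **Inbreeding and relatedness** — F from the Meuwissen–Luo algorithm
  (diagonal of the numerator relationship matrix **A** minus one); a
  recursive variant in which unknown-parent animals carry the mean F of
  their birth-year contemporaries instead of zero; average relatedness
  AR = (1/n)·**1**′**A** and mean coancestry C via Colleau's indirect
  **A**·x method (no dense matrix); non-random mating α from Wright's
  identity (1−F) = (1−C)(1−α); and the genetic conservation index
  GCI = 1/Σp², with p the founder gene proportions of an individual.
* **Effective population size** — Ne = 1/(2ΔF) by three routes:
  individual rates ΔFᵢ = 1 − (1−Fᵢ)^(1/(Ecgᵢ−1)); the regression of
  ln(1−F̄) on birth year scaled by the generation interval; and mean-kinship
  differences between parent and offspring cohorts.
* **Gene origin** — founder contributions q and fe = 1/Σq²; Boichard's
  greedy marginal ancestor decomposition and fa = 1/Σp²; founder genome
  equivalents fg = 1/(2f̄) from mean kinship; the effective number of
  non-founders; and the split of diversity loss GD = 1 − 1/(2fg),
  GD\* = 1 − 1/(2fe) into unequal-founder and drift components.
* **Simulation** — an overlapping-generation registry generator
  (growth-then-contraction birth schedule, lognormal sire-usage skew,
  parity-limited dams, decade-specific missing-parent masking) and a
  Wright–Fisher pedigree generator used as the oracle for Ne estimators.

## Worked example

```python
import pedkit as pk
from pedkit.simulate import SimulationConfig, simulate_registry

ped, truth = simulate_registry(SimulationConfig(seed=7))
last = pk.slice_by_birth_years(ped, 2015, 2024, "2015-2024")
ref = pk.reference_slice(last)

f = pk.kinship.inbreeding_array(ped)
idx = last.member_indices
members = [ped.ids[i] for i in idx]
C = pk.mean_coancestry(ped, members, f=f)
print(f"mean F        = {100*f[idx].mean():.2f}%")
print(f"mean C        = {100*C:.2f}%")
print(f"alpha         = {pk.non_random_mating_alpha(float(f[idx].mean()), C):+.4f}")
origin = pk.gene_origin_report(ped, ref)
print(f"fe / fa / fg  = {origin.fe:.2f} / {origin.fa_int} / {origin.fg:.2f}")
print(f"GD loss       = {origin.loss.loss_total:.2f}% "
      f"(founders {origin.loss.loss_unequal_founders:.2f}%, drift {origin.loss.loss_drift:.2f}%)")
```

prints

```
mean F        = 1.42%
mean C        = 1.95%
alpha         = -0.0054
fe / fa / fg  = 54.04 / 25 / 17.52
GD loss       = 2.85% (founders 0.93%, drift 1.93%)
```

Mean inbreeding in the simulated 2015–2024 cohort is 1.42% while mean
coancestry is 1.95%, so α < 0: matings are slightly less related than
random pairs. The 2,758 reference animals trace back to the genetic
equivalent of 54 equally contributing founders, but only 25 effective
ancestors (a bottleneck) and 17.5 founder genomes (drift); 2.85% of founder
heterozygosity is gone, about two thirds of it through drift and
bottlenecks rather than unequal founder use.

The same pipeline runs on a real pedigree file, and a CLI mirrors the
library (`pedkit analyze herd.csv --out results/`, plus `validate`,
`census`, `completeness`, `gi`, `inbreeding`, `ne`, `origin`, `simulate`).

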