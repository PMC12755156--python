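# Methods

This note documents the statistical definitions implemented in `pedkit`,
the conventions chosen where the literature is ambiguous, what the
synthetic-data generator does and does not emulate, and the numerical
choices that affect results.

## Pedigree model

A pedigree is a directed acyclic graph over animals with sire/dam links,
a sex, and a birth year (full dates are degraded to years; registry dates
are too often partial for sub-year precision to be dependable). Missing
parents are first-class: the tokens `""`, `0`, and `NA` all map to
MISSING on input. Parents referenced but never defined as rows are
synthesised as founders (sex inferred from the slot, year unset). A
parent recorded as born at or after its offspring is registry noise and
is warned about, not rejected. All algorithms run on the topologically
ordered pedigree (parents before offspring), with a deterministic
(birth-year, id) tie-break so identical inputs yield identical files.

Population slices (the historical window, 10-year cohorts, the
both-parents-known *reference* population) restrict only the member set;
every statistic recurses through the full pedigree, so ancestors born
outside a window still count as known.

## Completeness

Per parental line, the line score at depth *d* is
C = (1/d)·Σᵢ aᵢ with aᵢ the fraction of known ancestors in generation
*i* of that line (generation 1 is the parent itself, generation *i* has
2^(i−1) slots counted along pedigree paths). PCI combines the two lines
as the harmonic mean 2·C_pat·C_mat/(C_pat+C_mat) — the MacCluer-style
index used by ENDOG — and is 0 whenever either line is wholly unknown,
because inbreeding detection needs both sides. PCI means are taken over
*all* slice members, founders included; pass a pre-filtered member set to
average over non-founders instead.

GMax is the longest known ancestor chain (founder = 0), GCom the deepest
generation at which every one of the 2^g ancestors is known, and GEqu
(= Ecg) the sum of (1/2)ⁿ over all known ancestors at generation n,
computed by the equivalent recursion gequ(x) = Σ_known parents
(1 + gequ(parent))/2. A slice's "number of generations" is reported as
max GMax + 1, i.e. whole generations including the animal's own.

## Generation intervals

James's definition: the parent's age at the birth of offspring that are
themselves parents somewhere in the full pedigree ("selected"
offspring). Ages are split by gametic pathway (parent slot × offspring
sex); unknown-sex offspring enter no pathway; non-positive ages (noise)
are dropped. The pooled mean over all contributing pairs is the
generation interval L used by the Ne-Ln estimator.

## Inbreeding and relationships

**Classical F** is the diagonal of the numerator relationship matrix
minus one, computed with the Meuwissen–Luo L·D algorithm: the pedigree
defines A = T·D·T′ with T the gene-flow triangle and D the Mendelian
sampling variances (d = 0.5 − 0.25(F_s + F_d) with both parents known,
0.75 − 0.25·F_known with one, 1 + F for a founder block). Unknown
parents are unrelated and non-inbred.

**Recursive F** drops that last assumption. Following the
VanRaden/Aguilar–Misztal convention, an animal with *both* parents
unknown is treated as a founder block carrying the mean F of
both-parents-known animals born in the same year — equivalently, its two
phantom parents are assumed to mate like an average pair of that cohort.
The assignment uses the previous iteration's coefficients and is
iterated to a fixed point (max |ΔF| < 1e-8, cap 50 iterations; in
practice 3–6 suffice). Year cohorts with no known-parent animals inherit
the nearest earlier cohort's mean; cohorts *before* the first
known-parent cohort get 0 (the base population predates measurable
inbreeding) — this is what makes the method collapse exactly to the
classical coefficients on a fully recorded pedigree; animals without a
birth year get the global known-parent mean. A design note: a phantom
parent given only an inflated self-relationship 1 + f̄ but no
relationships provably changes no real animal's F (the Mendelian d-term
compensates exactly), so the per-cohort founder-block formulation above
is the minimal construction that actually encodes "unknown parents are
not outbred". Animals with exactly one known parent keep the classical
treatment of the missing slot.

**Population relationship sums** never materialise A. Colleau's indirect
method evaluates A·x as two triangular passes plus a diagonal scale;
average relatedness is the member-restricted (1/n)·1′A, and mean
coancestry f̄ = a_ij/2 averaged either over unordered distinct pairs
(the default — the coancestry of two animals is the inbreeding of their
prospective offspring) or over the full matrix including self-kinships
(`include_self=True`). A dense tabular-method builder exists for small
pedigrees and is the oracle the tests compare against (≤1e-12 on F,
≤1e-10 on AR/coancestry).

**α** comes from Wright's identity (1−F) = (1−C)(1−α): positive when
mates are more related than random pairs from the population.

**GCI** is 1/Σp² over an individual's founder gene proportions, with
each unknown parent slot a distinct anonymous founder.

## Effective population size

All three estimators are Ne = 1/(2ΔF) and differ in the rate:

* **Ecg route** — individual rates ΔFᵢ = 1 − (1−Fᵢ)^(1/(Ecgᵢ−1)),
  averaged over members with Ecg > 1 (shallower pedigrees carry no rate
  information and are excluded with a log note).
* **Ln route** — unweighted OLS of ln(1−F̄_year) on birth year over the
  yearly cohort means; the per-generation rate is ΔF = 1 − exp(b·L).
  The frequently quoted −b·L is the first-order approximation of the
  same quantity; the exponential form is exact and is what is
  implemented.
* **Coancestry route** — ΔF_g = (f_t − f_{t−1})/(1 − f_{t−1}) on the
  mean kinships of the window members (offspring cohort) versus the
  animals with at least one offspring born inside the window (parent
  cohort).

A flat or declining trend yields an explicit "undefined" estimate rather
than a negative Ne. This is not hypothetical: in the simulated registry
the within-decade cohort noise can exceed the within-decade accumulation,
in which case the per-decade Ln estimate is honestly undefined while the
40-year historical window gives a well-determined slope.

## Gene origin

Founders are animals with both parents unrecorded, assumed unrelated and
non-inbred; a missing slot of a one-known-parent animal is a distinct
anonymous founder (so such an animal counts as half a founder in the
adjusted base count). Founder contributions q_k are expected gene-pool
shares obtained by pushing each member's 1/n weight up the pedigree;
fe = 1/Σq².

Effective ancestors follow Boichard's greedy decomposition. Each round
scores every candidate by its *marginal* contribution: the member weight
flowing through it with propagation blocked at already-selected animals
(genes explained by a selected descendant on the path), multiplied by
the unexplained fraction of its own genome (1 − g, with g the
probability a random gene of the candidate derives from the selected
set, computed top-down with selected animals pinned at 1). The two
factors concern disjoint path segments, so their product is the exact
marginal. The largest marginal is selected; ties break by earlier birth
year then lexicographic id, making runs deterministic. Run to
exhaustion the marginals sum to 1; fa = 1/Σp², and the "ancestors
explaining 25/50/75/100% of the pool" counts are prefixes of the
selection-ordered cumulative sum. The propagation is vectorised over
GMax strata, so each round costs a handful of array operations.

fg = 1/(2f̄) uses the **self-inclusive** mean kinship by default. Under
that convention A − QQ′ (Q the founder-contribution matrix) is positive
semi-definite, which guarantees fg ≤ fe — drift can only lose diversity
relative to founder balance; the strictly-between-animals mean is
available behind the same flag as elsewhere but can violate the
inequality on small or fragmented member sets. The effective number of
non-founders is Nenf = (1/fg − 1/fe)⁻¹, the form that makes
1/fg = 1/fe + 1/Nenf an exact partition of diversity loss; the variant
with the additional factor two (1/(2·(1/fg − 1/fe))) is available via
`caballero_toro=True`. Diversity retention is GD = 1 − 1/(2fg) and
GD\* = 1 − 1/(2fe); the loss identity
(100 − GD) = (100 − GD\*) + (GD\* − GD) holds to machine precision by
construction.

Animal identifiers beginning with `@` are reserved for anonymous
founder keys and should not appear in input files.

## Synthetic registry

`simulate_registry` emulates a 40-year dairy herd book at roughly
quarter scale of a large association registry:

* **Census**: yearly births follow a growth-then-contraction schedule
  (decade totals 1,700 / 3,140 / 7,000 / 4,270 by default, ~19k animals
  including 3,000 founders born in the pre-window decade).
* **Mating**: overlapping generations; dams are parity-limited (≤12)
  females aged 2–12 sampled without replacement within a year, sires are
  males aged 2–12 sampled with replacement proportional to a per-bull
  lognormal usage weight exp(σ·z). σ (default 2.0) is the concentration
  dial: 0 gives uniform usage; the default lets single bulls reach
  several hundred offspring at this scale, the scaled counterpart of the
  hundreds-to-a-thousand seen in AI-driven registries. Parent ages are
  drawn from a bounded 2–12 law peaked at 4–6 years, which yields a
  generation interval near 5.5–6 years.
* **Sex ratio**: 5% of registered animals are male, reflecting that
  herd books register nearly all females but few bulls.
* **Missing parentage**: after simulation, sire/dam identifiers are
  masked independently per decade (defaults 6–16% for sires, 26–40% for
  dams, mirroring the observed pattern that dams of early cohorts are
  the least recorded). Masking happens post hoc so the truth object
  retains the complete pedigree for oracle comparisons.

What it does **not** emulate: culling and death (eligibility is purely
age/parity), correlated missingness (sire and dam are masked
independently, so fully unknown-parent rates are the product of the
marginals), imported animals or herd substructure, twinning, and any
phenotype or selection response. Passing tests on these simulations
therefore validates the estimators' arithmetic and their response to
census shape, usage skew, and missingness — not robustness to herd
structure or non-random data loss.

`simulate_wright_fisher_pedigree` is the idealised oracle: constant size
n, discrete generations, monoecious random mating with replacement
(selfing allowed), so ΔF = 1/(2n) per generation exactly and mean F at
generation g is 1 − (1 − 1/2n)^(g−1).

## Numerical choices and degenerate inputs

* Recursive-F fixed point: tol 1e-8 on max |ΔF|, cap 50 iterations.
* Boichard rounds stop when the residual pool is < 1e-9 or no candidate
  exceeds 1e-13; tie-break (birth year, id) as above.
* Mean coancestry over distinct pairs requires ≥2 members; f̄ ≤ 0 makes
  fg infinite (flagged), fe = fg makes Nenf infinite (flagged); C = 1
  makes α undefined (error).
* Empty birth-year windows are warnings, not errors; empty slices abort
  summary statistics with a clear message.
* The "highly inbred" threshold in period reports defaults to F > 0.125
  (closer than half-sib mating); it is a parameter because published
  reports rarely state their cut-off.
* Reported tables round percentages to 2 decimals and α to 4, so the
  printed loss partition can differ from exact by one unit in the last
  place.

## Acceptance problem sizes

`scripts/acceptance.py` runs the registry at its default ~19k-animal
scale and the Wright–Fisher recovery at n = 100, 10 generations, 5
replicates, reporting medians; the whole script completes in seconds on
one CPU, and the test-suite's oracle comparisons (50 random pedigrees up
to 500 animals against the dense tabular A) run in well under a minute.
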