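# Methods

## The model

`polledsim` is a stochastic, individual-based, forward-in-time simulator of
a two-tier (nucleus/multiplier) beef breeding program with overlapping
generations and an annual cycle. Each simulated year runs, per tier:
service-pool construction under the active mating scheme → assignment of a
unique sire portfolio to every herd → random mating of cows to portfolio
bulls under a 35-matings-per-bull cap → calf creation → fetal gene editing
(in editing scenarios) → calf mortality → steering of commercial bull
calves → ranking, retention (top 5%) and transfer of seedstock yearling
bulls → culling by age and to the population caps → statistics capture.

### Genetics

One autosomal biallelic locus controls horns; the *POLLED* allele (P) is
dominant, *HORNED* (p) recessive, so only pp animals grow horns. Genotypes
are stored as POLLED-allele counts (0/1/2). A calf receives one allele
drawn uniformly from each parent; calves homozygous for the major allele
are converted to heterozygous with probability 1e-5 (one-way mutation, a
guard against losing the minor allele to drift; no back-mutation). Scurs
and other horn-modifying loci are outside the model.

Quantitative merit is one economic index (the $JapOx index, AUD) treated as
a purely additive trait with true breeding values assumed known without
error — selection accuracy is 1 and there is no genomic or phenotypic
evaluation layer. Calf TBV is the parent average plus a Mendelian sampling
deviate with variance ½[1 − ½(f_S + f_D)]σ_a², σ_a = $34. The base
population draws TBVs from normal distributions: seedstock cows mean $34,
commercial cows $0, bulls one SD above their tier's cows, and homozygous
polled base bulls penalised $5.44 (0.16 SD), reflecting the observed merit
gap of polled sires. The additive variance is held constant (no Bulmer
effect), matching the calf-TBV recipe above.

### Pedigree and inbreeding

Every animal is registered in an append-only pedigree with ids in birth
order; base animals are unrelated founders (f = 0). Inbreeding is Wright's
coefficient computed exactly from the whole recorded pedigree with the
Meuwissen–Luo recursive (tabular kinship) algorithm, implemented as an
incremental numba kernel so each birth cohort's coefficients are available
at creation (they feed the Mendelian sampling variance). The kernel is
verified against a brute-force numerator-relationship-matrix oracle to
1e-12 on random pedigrees.

### Demography

Cows enter the mating pool in the year of their first calf (age 3; the
annual cycle books mating and calving in the same year) and are culled at
age 10; bulls serve from age 2 and are culled at age 5 (three service
years). Calves die pre-weaning with tier-specific probability (8%
seedstock, 13% commercial) and horned survivors additionally die with 2%
probability (dehorning mortality under extensive tropical management) —
the only fitness differential between genotypes. Sex is assigned 50:50.
Females never change herds; calves are born in their dam's herd. Female
caps (3,000 seedstock / 100,000 commercial, all ages) are enforced by
random involuntary culls; bull caps (60 / 2,000, mating-age) by the
scheme's culling order.

### Mating schemes

Yearling ranking (retention) uses descending TBV under scheme A and
genotype class (PP > Pp > pp) then TBV under B/C/D; bull capacity culling
mirrors it in reverse (horned culled first under B/C/D, lowest TBV within
class; TBV alone under A). Service pools:

- **A**: all bulls of the tier, by TBV.
- **B**: polled bulls (PP and Pp) as a first tier used to full mating
  capacity, horned bulls only for remaining cows; TBV within tier.
- **C**: PP bulls first, then all remaining bulls by TBV alone (the
  overflow tier makes no Pp-over-pp distinction).
- **D**: PP bulls only, in both tiers; seedstock herds use their retained
  PP bulls first with commercial-born PP bulls filling the deficit, and
  commercial herds use the PP bulls standing in the commercial tier.
  Uncovered cows stay open. Scheme D selects on genotype alone, so its
  pools carry no merit ordering.

Two design choices deserve emphasis because they are what make the
obligatory-polled scheme costly in merit, as observed in this production
system:

1. **The multiplier tier records no merit.** Commercial-born bulls carry
   no usable TBV: wherever a ranking is required they are ordered randomly
   within their group, and commercial-tier capacity culls are random
   within genotype class (involuntary culls). Only the nucleus
   performance-records its animals.
2. **Scheme D's commercial "keeps" are deficit-sized.** Hornless
   commercial bull calves are separated at the first muster,
   genotype-confirmed (testing assumed error-free) and kept entire — but
   only up to the tier's serviceable-bull shortfall (bull cap minus the
   standing mating-age PP inventory, or the year's realised deficit in
   bull-equivalents). Kept calves are chosen at random. Without the limit
   the unranked keeps swamp the PP pool and commercial genetic gain
   collapses; without any keeps the deficit never closes.

### Gene editing

In editing scenarios the top 1% or 10% (by TBV) of the year's seedstock
bull calves are gene edited to PP before birth: eligibility is restricted
to non-PP calves (when fewer eligible calves exist than the quota, all are
edited; at least one is edited whenever the fraction is positive and a
candidate exists). Each editing/ET cycle succeeds with probability
0.61 × 0.21 and cycles repeat until success, so the cycle count is
geometric (mean ≈ 7.8) and every selected calf is born PP in the same year
— no time lag or cost is modelled. Editing changes only the genotype and
the edited flag; TBV, sex, pedigree links and herd are untouched (the
SCNT clone carries the selected genome and replaces the candidate
one-for-one).

### Burn-in

Base animals (ages drawn uniformly: cows 0–10, bulls 0–5) are mated at
random within their tier for 10 years with the standard calf, mortality,
aging and cap rules but no preference of any kind: random service order,
random capacity culls, no yearling transfer (the tiers stay closed, which
is why scheme year 1 finds only commercial-descended bulls in the
commercial tier). Surplus male weanlings are steered down to the
replacement rate (bull cap over a three-year service life) per tier, so
the schemes inherit a steady-state bull inventory rather than a backlog of
entire young males. The end state of the burn-in is scheme year 0.

## Statistics

Yearly, per tier: HORNED allele frequency by allele counting over all
animals alive at year end; birth-cohort mean TBV and mean pedigree
inbreeding (the year's surviving calves); sires used by genotype, origin
tier and edited status; mean sire TBV; open cows; deaths by cause; animals
sold (steers, age-culled males and females, capacity-culled females).
Replicates are the experimental unit: summaries report means, SEM and
t-based 95% CIs (replicates − 1 df, appropriate for ~10 replicates);
genetic trends are per-replicate OLS slopes of cohort mean TBV on birth
year (years with no surviving births are dropped), then averaged; scenario
contrasts use all-pairs Tukey HSD on replicate-level values at α = 0.05.
Hardy–Weinberg proportions project final genotype shares from a final
allele frequency.

## Scaling for desk-size runs

`ScenarioConfig.scaled(s)` multiplies every population size, cap and herd
count by `s`, leaving rates, ages, the mating cap and variances untouched.
This preserves cows-per-herd, bulls-per-cow and every selection fraction,
so selection intensities and the deterministic dynamics are
scale-invariant; what grows as `s` shrinks is drift (allele-frequency
variance between replicates) and pedigree inbreeding, which accumulates in
proportion to 1/N_e. Empirically, year-20 seedstock cohort inbreeding
times `s` is constant across s ∈ {0.1, 0.2, 0.4} (≈1.1%), supporting the
linear rescaling the acceptance script applies when reporting a
full-scale-equivalent inbreeding level. The test suite runs the
ten-scenario grid at 1/5 scale with 3 replicates; the acceptance script
uses 1/5 scale with 5 replicates.

## Numerical and implementation notes

- All randomness flows through one `numpy` Generator per replicate, seeded
  `default_rng([master_seed, replicate])`; a fixed master seed makes every
  scenario bit-reproducible and any single replicate independently
  re-runnable.
- Ties in every ranking break by ascending animal id, so orderings are
  deterministic given the draw.
- The mating cap is enforced structurally (each bull contributes exactly 35
  shuffled slots), so it cannot be exceeded; portfolio needs use ceiling
  division so small herds still receive a bull when any are available.
- Mortality order: pre-weaning loss first, then dehorning mortality on
  horned survivors (independent risks, joint survival 0.87 × 0.98
  commercially).
- Degenerate inputs: empty populations raise on allele counting; trends
  need ≥3 distinct years; summaries need ≥2 replicates; a mating plan with
  zero capacity simply leaves all cows open.

## What the simulator does and does not show

The generator *is* the study system: no external data are read, and all
parameters are the configured population description. Passing tests
therefore demonstrate internal consistency and agreement with the
published simulation outcomes, not field validity. Known limitations, all
deliberate: selection on true (not estimated) breeding values; no genomic
selection; a single abstract locus with no linkage; no AI or ET
amplification of elite sires (natural service only, which is precisely why
editing's population-level impact is modest here); no female selection; no
economics; base animals assumed unrelated, so absolute inbreeding levels
are lower bounds — and this implementation's nucleus accumulates roughly
1.6× the inbreeding reported for the original program at year 20 (~1.1%
full-scale-equivalent vs 0.70%), an exact-pedigree result that likely
reflects unspecified differences in sire-pool turnover rather than a
computational artefact. Scheme-D trajectories at small scale show deeper
early sire deficits than at full scale, leaving the year-20 commercial
HORNED frequency ~2 percentage points above the published value.
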