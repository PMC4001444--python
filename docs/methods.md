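# Methods

`pdgsim` is an individual-based, spatially explicit simulator that couples
three layers for every tree in a stand on an elevational gradient:

1. **Physiology** — a daily thermal-time budburst model and a surrogate
   carbon/water balance that turn weather into a budburst date (TBB),
   growing-season length (LGS), annual gross primary production (GPP),
   a water stress index (WSI), wood growth, and two carbon-starvation
   indicators;
2. **Demography** — survival thresholds on those indicators, reserve-driven
   seed production, spatially explicit pollen and seed dispersal, selfing,
   size-dependent male fertility, and density-dependent recruitment;
3. **Quantitative genetics** — a ten-locus purely additive architecture for
   the one heritable parameter, the budburst forcing requirement
   F_critBB (degree-days above a base temperature needed to flush leaves).

The stand occupies a 200 x 1000 m rectangle mapped linearly onto a
700-1700 m elevational gradient and divided into 500 cells of 20 x 20 m.
Scenarios A-Hb toggle heritability (h² = 0 / 0.6 / 1), the mortality
channels, differential reproduction, and a frost effect on leaf area.

## Phenology

From the rest-onset day (day of year 78) the daily forcing rate
`max(T - T_base, 0)` (T_base = 0 °C) accumulates; budburst falls on the
first day the sum reaches the tree's F_critBB. Accumulation includes the
rest-onset day, and a tie at exact equality counts as budburst — the
underlying model leaves this convention open, so it is fixed here and
tested against a day-by-day oracle. Chilling/dormancy is deliberately held
constant: only the forcing phase is modelled. A non-positive requirement
degenerates to budburst on the rest-onset day.

After budburst initiation, each day whose minimum temperature falls below
the frost threshold (0 °C) multiplies the canopy LAI by
`max(0, 1 - frost_k (T_thr - T_min))`; `frost_k` is 0, 0.1 or 0.2 depending
on the scenario. Frost damage compounds multiplicatively across days.

## Surrogate carbon/water balance

A full process-based canopy model is out of scope; the surrogate keeps only
the couplings the demography needs, per m² of crown-projected ground:

* **Assimilation** (leaf period only):
  `a_max (1 - e^{-k LAI}) · min(T/T_opt, 1) · f_water`, with `a_max` =
  10 gC m⁻² d⁻¹, Beer-Lambert extinction k = 0.5, T_opt = 20 °C.
  `f_water` = 1 while relative soil water ≥ 0.4, declining linearly to 0
  below that; the daily shortfall `1 - f_water` accumulates into the annual
  WSI.
* **Maintenance respiration**: `r_m · B^0.75 · Q10^{(T-15)/10}` with
  `r_m` = 0.0046 d⁻¹ and Q10 = 2. The sublinear exponent stands in for the
  fact that only a sapwood-like fraction of a growing stem respires; with
  respiration linear in accumulated biomass the 30-year adult stage has no
  viable regime (either universal starvation near age 60 or no mortality at
  all, depending on allocation).
* **Canopy construction**: at budburst the full canopy (LAI_max = 5,
  LMA = 93 g m⁻², carbon fraction 0.5) is built from reserves at a 50%
  growth-respiration overhead (348.75 gC m⁻² in total).
* **Allocation**: positive daily net carbon is split 15% to wood, 85% to
  reserves; deficits are paid from reserves. Reserve storage is capped at
  700 gC m⁻² (non-structural carbon capacity); the overflow, and a 2% yr⁻¹
  structural turnover, are shed as litter.
* **Soil**: a single bucket of 60 mm extractable water, recharged by rain
  and drained by evapotranspiration `0.03 · LAI · max(T, 0)` mm d⁻¹.
* **Senescence**: leaves drop on a fixed day (doy 285); LGS = 285 - TBB.

Pools never go negative: respiration and leaf construction are paid only as
far as reserves allow, and the amounts actually paid enter the annual
books, so every simulated tree-year satisfies
`ΔB_tree + ΔB_res = GPP - respiration - leaf cost - litter` to round-off
(audited in the test suite).

Two starvation indicators feed mortality: `CumCR`, the reserves on the last
day of the year (Type I death below 45 gC m⁻²), and `bb_deficit`, the
canopy construction cost minus the reserves available at budburst (Type II
death above 160 gC m⁻²). CumCR is evaluated before the year's seed-carbon
debit. When both thresholds are breached in the same year the recorded
cause is Type I (the model gives no tie-break; one cause per death is
enforced).

The defaults were calibrated once so that annual GPP is of order
10³ gC m⁻² across the gradient (peaking low/mid-slope), the lowest band
suffers pre-reproductive Type II mortality and collapses, mid-slope bands
see late-adult mortality, and the top of the gradient is safest. An
emergent and intentional behaviour: under drought, moderate frost damage
can *increase* annual GPP (a smaller canopy transpires less), so the frost
scenarios are only monotonically harmful in wet years.

## Demography

* **Seed production**: if end-of-year reserves exceed 100 gC m⁻², the tree
  makes `floor(R_SP · B_res · C_P / c)` seeds (R_SP = 0.05, seed cost
  c = 0.45 gC, C_P the crown projection); the corresponding carbon is
  debited from reserves. Effective fecundity multiplies by
  `(1 - r_ES) r_SS r_SG` = 0.67 · 0.15 · 0.485 (empty-seed, survival and
  germination rates).
* **Dispersal kernels**: the exponential-power family
  `p(r) = b/(2π a² Γ(2/b)) e^{-(r/a)^b}` parameterised by its mean distance
  `δ = a Γ(3/b)/Γ(2/b)`; pollen δ = 37.9 m with b = 0.97, seed δ = 18.13 m
  with b = 0.31. At b = 1 the kernel is the pure exponential with δ = 2a.
  Distances are sampled as `a G^{1/b}` with G ~ Gamma(2/b). The domain has
  reflecting borders, implemented as first-order mirror images of the
  source across the four edges.
* **Mating**: a seed is selfed with fixed probability s = 0.025; otherwise
  its father is drawn with probability ∝ `p_P(r) · DBH^0.82` over all other
  living adults (no pollen limitation).
* **Seed rain and recruitment**: mother j deposits intensity
  `τ_ij = F_j p_S(r_ij)` on the centre of each cell i; the number of
  recruits per (mother, cell) is Poisson(τ_ij · S) with S = 400 m², the
  natural point-process discretisation of a seed-rain intensity.
  Recruits enter at age 40 with
  Gaussian height (9 ± 0.34 m) and DBH (13.8 ± 0.9 cm), placed uniformly in
  their cell, or by an isotropic Gaussian (sd 5 m, clipped to the domain)
  around the mother when she stands in the same cell.
* **Thinning**: crowns are discs of the tree's crown-projection area; all
  pairs overlapping by more than 30% of the smaller crown are found, visited
  in random order, and one member of each still-intact violating pair is
  removed uniformly at random. Removal cannot create new overlap, so a
  single pass yields an audit-clean stand. The 30% is measured against the
  smaller crown of the pair, the conservative convention.
* **Allometry and growth**: the year's wood carbon is converted to a DBH
  increment by inverting a cylindrical stem (form factor 0.5, dry-wood
  density 550 kg m⁻³, carbon fraction 0.5) at fixed height; height
  (1.86 · DBH^0.6 m) and crown projection (0.6 · DBH^1.2 m²) are power laws
  of DBH (cm) calibrated to the recruit dimensions above. These are
  deliberately plain, configurable stand-ins for species-specific
  allometries.

## Genetics

Ten independent biallelic loci contribute `m_l + α_l`, `m_l`, `m_l - α_l`
for the A1A1, A1A2, A2A2 genotypes; all midpoints equal μ/10 = 19 °C so
the all-heterozygote value is μ = 190 °C. Effects follow an L-shaped QTL
distribution: `α_l ~ Normal(μ/20, μ/80)`, redrawn until inside [0, 19]
(the bound keeps all genotypic values in [0, 2μ]). Effects are drawn once
per scenario and shared by all repetitions; founder allele frequencies are
Uniform(0, 1) per locus with Hardy-Weinberg genotypes. Gametes segregate
independently per locus (free recombination); mutation and immigration are
ignored. The within-population additive variance is the standard closed
form for purely additive biallelic loci, `Σ 2 p_l q_l α_l²`, validated in
the test suite against a Monte-Carlo genotype-variance oracle.

Heritability modes: h² = 1 (phenotype = genotypic value), h² = 0 (control:
phenotype ~ Normal(190, 22), genotype ignored) and 0 < h² < 1, where a
lifetime environmental deviation Normal(0, V_E) is added with
V_E = V_A (1-h²)/h² and V_A the reference variance 22 (so h² = 0.6 gives
V_E ≈ 14.67). The deviation is drawn once per tree and fixed for life; the
underlying trait is defined as constant over a tree's lifetime. The
environmental deviate is consumed by the random stream in every mode so
that heritability settings do not perturb downstream stochastic dynamics
under a shared seed.

## Climate

The simulator ships a synthetic weather generator emulating a temperate
mountain climate (observed station series can be plugged in through the CSV
interchange format instead): a sinusoidal seasonal cycle (annual mean 7.5 °C at the 1200 m reference elevation, half-amplitude
8.5 °C) with AR(1) daily noise (φ = 0.65, σ = 2.2 °C), a diurnal range
giving `t_min`, stochastic spring frost snaps (days 90-150), gamma-rain wet
days (~900 mm yr⁻¹), a radiation proxy, and one anomalously hot and dry
year per 5-year block (+2.5 °C and 40% summer rain, emulating an extreme
drought summer). Years are 365 days; the phenology uses day-of-year only.

Elevational adjustment is linear: -0.6 °C / 100 m for mean and minimum
temperature (the standard environmental lapse rate; all slopes are
configuration entries so site-fitted regressions can be substituted), with
no adjustment of precipitation or radiation by default. The 5-year block is
repeated in six loops to drive the 30-year adult stage of every generation;
all repetitions of a scenario share one climate draw.

## Schedule and regulation

Each generation lasts 70 years: the seedling stage (ages 0-39) is not
simulated — seeds jump from dormancy to age-40 recruits — and the adult
stage runs 30 years of daily physiology with annual mortality and growth;
reproduction occurs only in adult years 21-30. After year 30 all survivors
are removed and the dormant seed pool founds the next generation.

Before the six selected generations, five neutral generations (equal
fecundity, no mortality, physiology bypassed; mating and dispersal operate
normally) build spatial genetic structure and among-band differentiation by
drift and gene flow alone; recruits are uniformly subsampled back to the
founder count, a selectively neutral population regulation.

Two regulation devices stand in for unmodelled competition and juvenile
mortality: the dormant seed pool is uniformly subsampled to three times the
population cap before recruitment, and the post-thinning cohort is
uniformly subsampled to the cap (default 2000 trees). Both are uniform, so
they are selectively neutral. Desk-scale runs in the test suite use 40-120
founders, 1-3 generations and caps of 100-300 trees; the neutral-null
response test uses 20 repetitions of a 100-founder, 3-generation control
scenario.

## Randomness and reproducibility

One master seed spawns named independent streams (allelic effects, climate,
and per-repetition founders / pre-evolution / simulation) via numpy
`SeedSequence` spawn keys, so components are testable in isolation and a
run is bit-reproducible from its manifest (config + master seed) alone.
Repetitions differ only in founder genotypes and positions.

## Statistics

Trees are binned at recruitment into five 200-m elevational bands
(Alt1-Alt5, half-open intervals, the 1700 m edge closed). `Cb`, the
response to selection, is the change in a band's mean trait between the
first adult year of the first and last generations, averaged over
repetitions (per climatic year for TBB, matched across the repeated
weather block); repetitions with an empty band are excluded and the count
reported. `Cw`, the selection differential, is the survivors' mean at the
final adult year minus the cohort mean at entry. The phenotypic variance is
the sample variance among survivors in the last year of the final
generation. Every statistic is computed over all repetitions present and
returns the repetition count it actually used.

## Known limitations

* The surrogate physiology reproduces couplings and orders of magnitude,
  not site-specific field estimates: selection responses measured on a real
  gradient depend on the observed weather series and a full process-based
  canopy model, both of which this package intentionally replaces with
  simpler, configurable components.
* Mortality in the surrogate is dominated by the pre-budburst reserve
  deficit (Type II); end-of-year starvation (Type I) is rare under the
  default calibration, so the two mortality-channel scenarios are less
  contrasted than in the original system.
* No competition among adults, no pollen limitation, no mutation or
  immigration, non-overlapping generations, fixed senescence date, no
  chilling model — all by design.
* Selection on the forcing requirement through smooth physiology is weak;
  most trait response is driven by threshold (mortality) events, so
  desk-scale runs mainly exercise drift, plasticity and the machinery of
  selection rather than strong directional change.
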