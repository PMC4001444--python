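# pdgsim

An individual-based, spatially explicit **physio-demo-genetic** simulator
for studying how a forest tree population adapts to a local climate
gradient within a handful of generations. It couples

* a **physiological layer**: a thermal-time budburst model plus a surrogate
  daily carbon/water balance per tree (assimilation, respiration, reserves,
  soil drought, late-frost damage to the canopy);
* a **demographic layer**: carbon-starvation mortality, reserve-driven seed
  production, spatial mating with an exponential-power pollen kernel,
  selfing and size-dependent male fertility, seed rain onto a cell grid,
  and density-dependent recruitment with crown-overlap thinning;
* a **quantitative-genetic layer**: the budburst forcing requirement
  F_critBB (the temperature sum, in degree-days above a 0 °C base, a bud
  needs to break) is controlled by ten unlinked biallelic loci with purely
  additive effects, under configurable narrow-sense heritability h².

The stand lives on a 200 × 1000 m grid of 500 cells mapped onto a
700–1700 m elevational gradient; a synthetic 5-year daily weather block,
lapse-adjusted by elevation and looped six times per 30-year adult stage,
drives everything. It is written for evolutionary ecologists who want to
ask, mechanistically, how much of a phenological cline is plastic and how
much is genetic: the budburst date of every tree responds to temperature
(plasticity), while selection acts on F_critBB through survival and
reproduction (evolution). Scenarios A–Hb switch heritability (0, 0.6, 1),
mortality channels, differential reproduction and frost severity.

The model and its default parameters are documented in
[docs/methods.md](docs/methods.md).

## Worked example

Run a small adaptive-evolution scenario (h² = 1) and summarise it:

```sh
pdg run --scenario B --reps 2 --seed 42 --out demo --founders 100 --generations 3
pdg analyze demo
```

which prints (this exact output, seed 42):

```
scenario B: 2 repetition(s), seed 42
            n_start   n_end
generation
0             100.0    43.0
1            2000.0  1366.0
2            2000.0  1614.5
wrote 8 files to demo

band   Cb_Fcrit  n_rep_Cb  Cw_G0  V_P_final    Cb_TBB
Alt1 -14.243146         2    NaN        NaN -0.847263
Alt2  -9.493471         2    NaN 380.365210 -0.544785
Alt3  -0.012014         2    0.0 352.281135  0.093342
Alt4   0.141616         2    0.0 366.165220  0.082616
Alt5   0.810509         2    0.0 268.616480  0.041584
```

Reading it: the population grows from 100 founders to the 2000-tree cap and
loses roughly a quarter of each cohort to carbon starvation within a
generation (`n_start` vs `n_end`). Per 200-m elevational band, `Cb_Fcrit`
is the response to selection — the change (°C of forcing requirement)
in the band mean between the first and last generation; `Cb_TBB` is the
same change expressed in days of budburst date per matched climatic year
(fractions of a day here: plastic variation dwarfs the genetic shift).
`Cw_G0` is the selection differential inside the first generation —
survivors minus entrants — which is exactly 0 where nobody died and
missing (NaN) where no tree survived to age 70: in this run the lowest band
is a mortality sink, and the large negative `Cb` there reflects which
immigrant genotypes its short-lived occupants inherit rather than in-place
adaptation. `V_P_final` is the phenotypic variance of F_critBB among
survivors at the end of the last generation; under h² = 1 it equals the
realized additive variance of the L-shaped allelic-effect draw (hundreds of
(°C)², see docs/methods.md), while under the non-heritable control
(`--scenario A`) it sits at the configured environmental variance of 22.

The run directory holds tidy CSVs (`trees.csv`, `band_stats.csv`,
`pop_stats.csv`, `tbb_stats.csv`, `fecundity.csv`, `pedigree.csv`) and a
`manifest.json` from which the whole run can be regenerated byte for byte.
The same machinery is available as a library:

```python
from pdgsim import ScenarioConfig, run_scenario
out = run_scenario(ScenarioConfig.for_scenario("A", n_repetitions=5), master_seed=1)
out.band_stats.head()
```

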