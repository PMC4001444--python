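"""Initialization, neutral pre-evolution, generation clock and scenarios."""
import numpy as np
import pandas as pd
import pytest

from pdgsim import analysis, climate, genetics as gen
from pdgsim._rng import stream
from pdgsim.demography import MortalityMode
from pdgsim.engine import (
    FOUNDER_BANDS,
    SCENARIO_TABLE,
    ScenarioConfig,
    initialize,
    neutral_preevolution,
    run_generation,
    run_scenario,
)


@pytest.fixture(scope="module")
def effects():
    return gen.draw_allelic_effects(10, 190.0, seed=2)


class TestScenarioTable:
    def test_switches(self):
        assert ScenarioConfig.for_scenario("A").h2 == 0.0
        assert ScenarioConfig.for_scenario("B").h2 == 1.0
        assert ScenarioConfig.for_scenario("C").mortality_mode == MortalityMode.NONE
        assert not ScenarioConfig.for_scenario("D").differential_reproduction
        assert ScenarioConfig.for_scenario("E").mortality_mode == MortalityMode.TYPE_I_ONLY
        assert ScenarioConfig.for_scenario("F").mortality_mode == MortalityMode.TYPE_II_ONLY
        assert ScenarioConfig.for_scenario("G").h2 == 0.6
        assert ScenarioConfig.for_scenario("Ha").frost_k == 0.1
        assert ScenarioConfig.for_scenario("Hb").frost_k == 0.2
        assert len(SCENARIO_TABLE) == 9

    def test_unknown_scenario(self):
        with pytest.raises(ValueError):
            ScenarioConfig(scenario_id="Z")


class TestInitialize:
    def test_founder_layout(self, effects):
        config = ScenarioConfig.for_scenario("B")
        pop = initialize(config, effects, stream(3, "founders"))
        assert pop.n == 500
        assert pop.age == 40
        elev = pop.elevation(config.domain())
        for lo, hi in FOUNDER_BANDS:
            assert ((elev >= lo) & (elev <= hi)).sum() == 100
        assert np.all(config.domain().contains(pop.x, pop.y))
        assert pop.dbh.mean() == pytest.approx(13.8, abs=0.2)
        assert pop.height.mean() == pytest.approx(9.0, abs=0.1)

    def test_same_seed_same_founders(self, effects):
        config = ScenarioConfig.for_scenario("B")
        a = initialize(config, effects, stream(3, "founders"))
        b = initialize(config, effects, stream(3, "founders"))
        np.testing.assert_array_equal(a.genotypes, b.genotypes)
        np.testing.assert_array_equal(a.x, b.x)


class TestNeutralPreevolution:
    def test_differentiation_builds_up(self, effects):
        """Drift plus limited dispersal creates among-band allele-frequency
        variance that is absent in the founders."""
        config = ScenarioConfig.for_scenario("B", n_founders=150, max_population=300)
        rng = stream(11, "preevo")
        pop = initialize(config, effects, stream(11, "founders"))
        bands0 = analysis.assign_bands(pop.elevation(config.domain()))

        def among_band_var(p, bands):
            freqs = np.array([
                gen.allele_frequencies(p.genotypes[bands == b]) for b in np.unique(bands)
            ])
            return freqs.var(axis=0).mean()

        v0 = among_band_var(pop, bands0)
        pop2, _ = neutral_preevolution(pop, config, effects, rng, n_gen=3)
        bands2 = analysis.assign_bands(pop2.elevation(config.domain()))
        v2 = among_band_var(pop2, bands2)
        assert pop2.n <= config.n_founders
        assert v2 > v0

    def test_population_rescaled(self, effects):
        config = ScenarioConfig.for_scenario("B", n_founders=100, max_population=300)
        pop = initialize(config, effects, stream(4, "founders"))
        pop2, _ = neutral_preevolution(pop, config, effects, stream(4, "pre"), n_gen=2)
        assert pop2.n <= 100
        assert pop2.age == 40

    def test_heritability_irrelevant_without_selection(self, effects):
        """h2 = 0 and h2 = 1 give identical genotype dynamics when neither
        mortality nor fecundity depends on the trait."""
        pops = {}
        for h2 in (0.0, 1.0):
            config = ScenarioConfig.for_scenario("B", h2=h2, n_founders=60, max_population=200)
            pop = initialize(config, effects, stream(9, "founders"))
            pop2, _ = neutral_preevolution(pop, config, effects, stream(9, "pre"), n_gen=2)
            pops[h2] = pop2
        np.testing.assert_array_equal(pops[0.0].genotypes, pops[1.0].genotypes)
        np.testing.assert_array_equal(pops[0.0].x, pops[1.0].x)


class TestRunGeneration:
    def test_no_mortality_scenario_keeps_everyone(self, effects, base_series):
        config = ScenarioConfig.for_scenario("C", n_founders=60, max_population=150)
        pop = initialize(config, effects, stream(6, "founders"))
        n0 = pop.n
        run_generation(pop, config, effects, base_series, stream(6, "sim"))
        assert pop.alive.sum() == n0

    def test_reproduction_only_in_final_decade(self, effects, base_series):
        """The generation clock confines seed production to adult years 21-30."""
        from pdgsim.engine import Records

        config = ScenarioConfig.for_scenario("C", n_founders=40, max_population=100)
        rec = Records()
        run_generation(pop := initialize(config, effects, stream(8, "founders")),
                       config, effects, base_series, stream(8, "sim"), collector=rec)
        fec = pd.DataFrame(rec.fecundity_rows)
        assert len(fec) > 0
        assert fec["year"].min() >= config.repro_start_year
        assert fec["year"].max() <= config.adult_years

    def test_equal_fecundity_scenario(self, effects, base_series):
        from pdgsim.engine import Records

        config = ScenarioConfig.for_scenario("D", n_founders=40, max_population=100)
        rec = Records()
        run_generation(initialize(config, effects, stream(8, "founders")),
                       config, effects, base_series, stream(8, "sim"), collector=rec)
        fec = pd.DataFrame(rec.fecundity_rows)
        assert len(fec) > 0
        np.testing.assert_allclose(fec["f_min"], fec["f_max"])

    def test_recruits_have_valid_pedigree(self, effects, base_series):
        config = ScenarioConfig.for_scenario("C", n_founders=50, max_population=120)
        pop = initialize(config, effects, stream(12, "founders"))
        new, _ = run_generation(pop, config, effects, base_series, stream(12, "sim"))
        assert new is not None and new.n > 0
        assert np.all(np.isin(new.mother, pop.ids))
        assert np.all(np.isin(new.father, pop.ids))
        assert np.all(new.genotypes >= 0) and np.all(new.genotypes <= 2)
        assert np.all(config.domain().contains(new.x, new.y))

    def test_extinction_is_graceful(self, effects, base_series):
        config = ScenarioConfig.for_scenario(
            "B", n_founders=30, max_population=60, cum_cr_crit=1e9
        )
        pop = initialize(config, effects, stream(13, "founders"))
        new, _ = run_generation(pop, config, effects, base_series, stream(13, "sim"))
        assert new is None


class TestRunScenario:
    def test_bit_reproducibility(self):
        kw = dict(n_founders=50, n_generations=1, n_preevolution=1,
                  n_repetitions=2, max_population=120)
        a = run_scenario(ScenarioConfig.for_scenario("B", **kw), 5)
        b = run_scenario(ScenarioConfig.for_scenario("B", **kw), 5)
        pd.testing.assert_frame_equal(a.trees, b.trees)
        pd.testing.assert_frame_equal(a.band_stats, b.band_stats)

    def test_repetitions_share_effects_but_not_founders(self):
        kw = dict(n_founders=40, n_generations=1, n_preevolution=0,
                  n_repetitions=2, max_population=100)
        out = run_scenario(ScenarioConfig.for_scenario("C", **kw), 5)
        g0 = out.trees[(out.trees.generation == 0)]
        r0 = g0[g0.rep == 0]["f_crit"].to_numpy()
        r1 = g0[g0.rep == 1]["f_crit"].to_numpy()
        assert not np.array_equal(r0, r1)

    def test_forced_directional_selection_gives_negative_response(self, base_series):
        """Killing the highest forcing requirements before reproduction must
        drag the mean requirement down across generations (h2 = 1)."""

        def cull_top_half(pop, year):
            if year != 20:
                return np.zeros(pop.n, bool)
            thresh = np.quantile(pop.f_crit[pop.alive], 0.5)
            return pop.alive & (pop.f_crit > thresh)

        config = ScenarioConfig.for_scenario(
            "C", n_founders=120, n_generations=3, n_preevolution=0,
            n_repetitions=1, max_population=250,
        )
        config.selection_hook = cull_top_half
        out = run_scenario(config, 17)
        trees = out.trees
        m0 = trees[trees.generation == 0]["f_crit"].mean()
        m2 = trees[trees.generation == trees.generation.max()]["f_crit"].mean()
        assert m2 < m0 - 1.0
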