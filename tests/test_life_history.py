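import numpy as np
import pytest

from stoatsim import calendar as cal
from stoatsim import life_history as lh
from stoatsim.config import ConfigError, SimConfig


class TestSurvivalConversion:
    @pytest.mark.parametrize("annual,daily", [(0.45, 0.9978), (0.61, 0.9986),
                                              (1.0, 1.0)])
    def test_annual_to_daily(self, annual, daily):
        assert lh.daily_survival_from_annual(annual) == pytest.approx(
            daily, abs=5e-5)

    @pytest.mark.parametrize("bad", [0.0, -0.2, 1.5])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ConfigError):
            lh.daily_survival_from_annual(bad)


class TestInitialisation:
    def test_initial_counts_distribution(self, rng):
        ns, fs = [], []
        for _ in range(10_000):
            n, f, m = lh.draw_initial_counts(rng)
            assert 6 <= n <= 12
            assert f >= 1 and f + m == n
            ns.append(n)
            fs.append(f)
        assert np.mean(ns) == pytest.approx(9.0, abs=0.1)

    def test_population_placed_inside_island(self, rng, study_island):
        cfg = SimConfig(initial_n=(6, 12))
        pop = lh.init_population(rng, cfg, study_island)
        assert 6 <= pop.n <= 12
        assert study_island.contains_xy(pop.x[:pop.n], pop.y[:pop.n]).all()
        assert (~pop.male[:pop.n]).sum() >= 1

    def test_initial_females_carry_pregnancy(self, rng, study_island):
        pop = lh.init_population(rng, SimConfig(initial_n=12), study_island)
        females = ~pop.male[:pop.n]
        assert pop.pregnant[:pop.n][females].all()
        assert (pop.due_year[:pop.n][females] == 0).all()
        assert not pop.pregnant[:pop.n][~females].any()


class TestImplantation:
    def test_autumn_mating_births_next_year(self):
        # mated 20 Sep of year 1 -> birth 30 Oct of year 2
        assert lh.implantation_due_date(1, 263) == (2, cal.BIRTH_DAY)

    def test_january_mating_same_season(self):
        # mated 10 Jan of year 2 (season started Sep year 1) -> 30 Oct year 2
        assert lh.implantation_due_date(2, 10) == (2, cal.BIRTH_DAY)

    def test_initial_pregnancy_due_first_october(self, rng, study_island):
        pop = lh.init_population(rng, SimConfig(initial_n=8), study_island,
                                 start_year=0)
        females = np.flatnonzero(~pop.male[:pop.n])
        assert (pop.due_year[females] == 0).all()


class TestStates:
    def _one_stoat(self, male, **flags):
        pop = lh.Population()
        i = pop.add(male=male, hx=0.0, hy=0.0)
        for k, v in flags.items():
            getattr(pop, k)[i] = v
        return pop, i

    def test_male_in_window_searches(self):
        pop, i = self._one_stoat(True)
        lh.update_states(pop, cal.OESTRUS_START)
        assert pop.ms[i] and pop.attractive[i]

    def test_pregnant_female_stays_home(self):
        pop, i = self._one_stoat(False, pregnant=True)
        lh.update_states(pop, cal.OESTRUS_START)
        assert not pop.ms[i] and not pop.attractive[i]

    def test_outside_window_all_home_range(self):
        pop, i = self._one_stoat(True, ms=True, attractive=True)
        lh.update_states(pop, 60)  # 1 March
        assert not pop.ms[i] and not pop.attractive[i]

    def test_nursing_dam_attractive_ten_days_after_birth(self):
        pop, i = self._one_stoat(False, nursing=True)
        lh.update_states(pop, cal.DAM_OESTRUS_DAY)
        assert pop.attractive[i] and not pop.ms[i]


class TestMating:
    def _pair(self):
        pop = lh.Population()
        m = pop.add(male=True, hx=0.0, hy=0.0)
        f = pop.add(male=False, hx=10.0, hy=0.0)
        pop.ms[m] = pop.ms[f] = True
        pop.attractive[m] = pop.attractive[f] = True
        return pop, m, f

    def test_conception_frequency(self, rng):
        cfg = SimConfig()
        hits = 0
        for _ in range(10_000):
            pop, m, f = self._pair()
            hits += lh.attempt_mating(pop, m, f, 0, cal.OESTRUS_START, rng, cfg)
        assert hits / 10_000 == pytest.approx(0.9, abs=0.01)

    def test_fertilised_female_goes_home_but_stays_receptive(self, rng):
        cfg = SimConfig(p_pregnancy=1.0)
        pop, m, f = self._pair()
        lh.attempt_mating(pop, m, f, 0, 300, rng, cfg)
        assert pop.pregnant[f] and not pop.ms[f]
        assert pop.attractive[f]  # males may still mate her
        assert pop.due_year[f] == 1  # delayed implantation: next 30 Oct

    def test_male_habituates_to_mated_female(self, rng):
        cfg = SimConfig(habituation_days=10)
        pop, m, f = self._pair()
        day = cal.to_day_index(0, cal.OESTRUS_START)
        lh.attempt_mating(pop, m, f, 0, cal.OESTRUS_START, rng, cfg,
                          day_index=day)
        assert lh.is_habituated(pop, m, lh.STOAT_CODE_BASE + f, day + 3)
        assert not lh.is_habituated(pop, m, lh.STOAT_CODE_BASE + f, day + 10)

    def test_mating_outside_window_rejected(self, rng):
        pop, m, f = self._pair()
        with pytest.raises(ValueError):
            lh.attempt_mating(pop, m, f, 0, 100, rng, SimConfig())


class TestBirthsAndNests:
    def test_litter_size_distribution(self, rng):
        cfg = SimConfig()
        sizes = []
        for _ in range(10_000):
            pop = lh.Population()
            dam = pop.add(male=False, hx=0, hy=0, pregnant=True, due_year=0)
            nests = lh.NestLedger()
            j = lh.give_birth(pop, nests, dam, rng, cfg)
            sizes.append(nests.fem[j] + nests.male[j])
            assert not pop.pregnant[dam] and pop.nursing[dam]
        assert np.mean(sizes) == pytest.approx(9.0, abs=0.1)

    def test_dispersal_count_conservation(self, rng, small_island):
        c = small_island.polygon.centroid
        pop = lh.Population()
        dam = pop.add(male=False, hx=c.x, hy=c.y)
        pop.nursing[dam] = True
        nests = lh.NestLedger()
        j = nests.add(dam, c.x, c.y, 4, 5)
        nests.fem_pregnant[j] = 2
        n = lh.disperse_nests(pop, nests, small_island, rng, year=1)
        assert n == 9 and pop.n == 10
        assert small_island.contains_xy(pop.x[:pop.n], pop.y[:pop.n]).all()
        newly_pregnant = pop.pregnant[1:]
        assert newly_pregnant.sum() == 2
        assert (pop.due_year[1:][newly_pregnant] == 1).all()
        assert len(nests) == 0 and not pop.nursing[dam]

    def test_dead_dam_produces_no_dispersers(self, rng, small_island):
        pop = lh.Population()
        dam = pop.add(male=False, hx=100, hy=100)
        pop.nursing[dam] = True
        nests = lh.NestLedger()
        nests.add(dam, 100, 100, 4, 5)
        lh.kill(pop, dam, lh.TRAP_DEATH, nests)
        assert lh.disperse_nests(pop, nests, small_island, rng, 1) == 0

    def test_nest_mating_fertilises_kits(self, rng):
        cfg = SimConfig(p_pregnancy=0.9)
        pop = lh.Population()
        male = pop.add(male=True, hx=0, hy=0)
        nests = lh.NestLedger()
        j = nests.add(0, 0, 0, 10, 0)
        got = lh.mate_nest(pop, nests, male, j, rng, cfg, day_index=50)
        assert nests.mated[j] and 0 <= got <= 10
        # second visit mates nothing new
        assert lh.mate_nest(pop, nests, male, j, rng, cfg, day_index=51) == 0


class TestMortality:
    def test_certain_survival_no_deaths(self, rng):
        pop = lh.Population()
        for _ in range(50):
            pop.add(male=True, hx=0, hy=0)
        deaths, _ = lh.apply_natural_mortality(pop, lh.NestLedger(), 1.0, rng)
        assert deaths == 0

    def test_death_rate_matches_probability(self, rng):
        p = 0.9981
        deaths = 0
        n_days = 2000
        pop = lh.Population()
        for _ in range(50):
            pop.add(male=True, hx=0, hy=0)
        for _ in range(n_days):
            pop.alive[:pop.n] = True
            d, _ = lh.apply_natural_mortality(pop, lh.NestLedger(), p, rng)
            deaths += d
        rate = deaths / (50 * n_days)
        assert rate == pytest.approx(1 - p, abs=2e-4)

    def test_dam_death_removes_litter(self, rng):
        pop = lh.Population()
        dam = pop.add(male=False, hx=0, hy=0)
        pop.nursing[dam] = True
        nests = lh.NestLedger()
        nests.add(dam, 0, 0, 5, 4)
        kit_losses = lh.kill(pop, dam, lh.NATURAL_DEATH, nests)
        assert kit_losses == 9 and not nests.alive[0]


class TestHabituationLedger:
    def test_entry_expires_exactly_after_duration(self):
        pop = lh.Population()
        i = pop.add(male=True, hx=0, hy=0)
        lh.add_habituation(pop, i, 7, expiry_day=110)
        assert lh.is_habituated(pop, i, 7, 100)
        assert lh.is_habituated(pop, i, 7, 109)
        assert not lh.is_habituated(pop, i, 7, 110)

    def test_capacity_overflow_recycles_stalest(self):
        pop = lh.Population()
        i = pop.add(male=True, hx=0, hy=0)
        for code in range(lh.HAB_CAPACITY + 5):
            lh.add_habituation(pop, i, code, expiry_day=code + 100)
        # oldest entries were overwritten, newest survive
        assert lh.is_habituated(pop, i, lh.HAB_CAPACITY + 4, 100)
        assert not lh.is_habituated(pop, i, 0, 100)
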