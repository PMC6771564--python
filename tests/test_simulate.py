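"""Agent-based label-inheritance simulation."""

import numpy as np
import pandas as pd
import pytest

from trypocycle.ergodic import age_cdf
from trypocycle.simulate import (
    CellAgent,
    Inheritance,
    Label,
    LabellingSimulation,
    Population,
    SimScenario,
    classify_stage,
    divide,
    init_population,
    plateau_fraction,
    run,
    step,
)


def one_agent_population(progress, old=Label.FULL, new=Label.NONE,
                         inh=Inheritance.OFD) -> Population:
    return Population(
        np.array([progress], dtype=float),
        np.array([int(old)], dtype=np.int8),
        np.array([int(new)], dtype=np.int8),
        np.array([int(inh)], dtype=np.int8),
    )


class TestClassifyStage:
    @pytest.mark.parametrize(
        "p,stage",
        [(0.50, "1F1K1N"), (0.70, "2F1K1N"), (0.90, "2F2K1N"), (0.99, "2F2K2N"),
         (0.0, "1F1K1N")],
    )
    def test_examples(self, cmap, p, stage):
        assert classify_stage(p, cmap) == stage

    @pytest.mark.parametrize("p", [-0.01, 1.0, 1.5])
    def test_rejects_out_of_range(self, cmap, p):
        with pytest.raises(ValueError):
            classify_stage(p, cmap)


class TestInitPopulation:
    def test_age_structure_matches_ergodic_cdf(self, cmap):
        from scipy import stats

        scenario = SimScenario(n_agents=10_000, seed=5)
        pop = init_population(scenario, cmap)
        assert stats.kstest(pop.progress, age_cdf).statistic < 0.02

    def test_initial_labels(self, cmap):
        pop = init_population(SimScenario(n_agents=500, seed=3), cmap)
        assert np.all(pop.old_label == int(Label.FULL))
        below = pop.progress < cmap.b_2f
        assert np.all(pop.new_label[below] == int(Label.NONE))
        assert np.all(pop.new_label[~below] == int(Label.FULL))

    def test_single_agent(self, cmap):
        pop = init_population(SimScenario(n_agents=1, seed=0), cmap)
        assert pop.size == 1
        assert pop.agent(0).old_label == Label.FULL

    def test_same_seed_reproducible(self, cmap):
        a = init_population(SimScenario(n_agents=100, seed=9), cmap)
        b = init_population(SimScenario(n_agents=100, seed=9), cmap)
        assert np.array_equal(a.progress, b.progress)
        assert np.array_equal(a.inheritance, b.inheritance)

    def test_alternating_flags(self, cmap):
        pop = init_population(
            SimScenario(n_agents=10, seed=0, init_flags="alternating"), cmap
        )
        assert list(pop.inheritance[:4]) == [0, 1, 0, 1]


class TestStep:
    """New-flagellum labelling rules around the induction step."""

    def test_crossing_before_induction_is_full(self, cmap):
        pop = one_agent_population(0.59)
        out = step(pop, SimScenario(), cmap, t_now=0.10)
        assert Label(int(out.new_label[0])) == Label.FULL

    def test_present_at_induction_becomes_partial(self, cmap):
        pop = one_agent_population(0.70, new=Label.FULL)
        out = step(pop, SimScenario(), cmap, t_now=0.29)  # step containing 0.3
        assert Label(int(out.new_label[0])) == Label.PARTIAL

    def test_crossing_at_induction_step_becomes_partial(self, cmap):
        pop = one_agent_population(0.59)
        out = step(pop, SimScenario(), cmap, t_now=0.29)
        assert Label(int(out.new_label[0])) == Label.PARTIAL

    def test_crossing_after_induction_is_unlabelled(self, cmap):
        pop = one_agent_population(0.59)
        out = step(pop, SimScenario(), cmap, t_now=0.50)
        assert Label(int(out.new_label[0])) == Label.UNLABELLED

    def test_increment_follows_inheritance_flag(self, cmap):
        scenario = SimScenario.nfd_slow()
        ofd = step(one_agent_population(0.2, inh=Inheritance.OFD), scenario, cmap, 0.0)
        nfd = step(one_agent_population(0.2, inh=Inheritance.NFD), scenario, cmap, 0.0)
        assert ofd.progress[0] == pytest.approx(0.21)
        assert nfd.progress[0] == pytest.approx(0.209)

    def test_division_resets_and_appends_nfd(self, cmap):
        pop = one_agent_population(0.995, new=Label.PARTIAL)
        out = step(pop, SimScenario(), cmap, t_now=0.50)
        assert out.size == 2
        ofd, nfd = out.agent(0), out.agent(1)
        assert ofd.progress == 0.0 and nfd.progress == 0.0
        assert ofd.old_label == Label.FULL and ofd.new_label == Label.NONE
        assert nfd.old_label == Label.PARTIAL and nfd.new_label == Label.NONE
        assert ofd.inheritance == Inheritance.OFD
        assert nfd.inheritance == Inheritance.NFD


class TestDivide:
    @pytest.mark.parametrize(
        "old,new",
        [
            (Label.FULL, Label.PARTIAL),
            (Label.FULL, Label.FULL),
            (Label.PARTIAL, Label.UNLABELLED),
        ],
    )
    def test_label_propagation(self, old, new):
        ofd, nfd = divide(CellAgent(1.0, old, new, Inheritance.OFD))
        assert ofd.old_label == old and nfd.old_label == new
        assert ofd.new_label == Label.NONE and nfd.new_label == Label.NONE
        assert (ofd.inheritance, nfd.inheritance) == (Inheritance.OFD, Inheritance.NFD)
        assert ofd.progress == 0.0 and nfd.progress == 0.0

    def test_rejects_undivided_agent(self):
        with pytest.raises(ValueError):
            divide(CellAgent(0.5, Label.FULL, Label.FULL))

    def test_rejects_agent_without_new_flagellum(self):
        with pytest.raises(ValueError):
            divide(CellAgent(1.0, Label.FULL, Label.NONE))


class TestRun:
    def test_all_full_before_induction(self, cmap):
        report = run(SimScenario(n_agents=1000, seed=2), cmap)
        early = report.counts[report.counts["time_u"] < 0.3]
        affected = early[early["old_label_class"] == "affected"]
        assert (affected["count"] == 0).all()

    def test_counts_conserved_and_growing(self, cmap):
        report = run(SimScenario(n_agents=1000, seed=2), cmap)
        sizes = report.population_size()
        assert sizes.iloc[0] == 1000
        assert (np.diff(sizes.values) >= 0).all()

    def test_population_doubles_per_unit_cycle(self, cmap):
        report = run(SimScenario.equal_rates(n_agents=5000, seed=4), cmap)
        sizes = report.population_size()
        assert sizes.loc[1.0] / sizes.loc[0.0] == pytest.approx(2.0, rel=0.02)
        assert sizes.loc[1.8] / sizes.loc[0.8] == pytest.approx(2.0, rel=0.02)

    def test_report_times(self, cmap):
        report = run(SimScenario(n_agents=100, seed=1), cmap)
        assert report.times == pytest.approx(np.arange(0, 1.8 + 1e-9, 0.05))

    def test_same_seed_bit_identical(self, cmap):
        a = run(SimScenario(n_agents=2000, seed=7), cmap)
        b = run(SimScenario(n_agents=2000, seed=7), cmap)
        assert a.counts.equals(b.counts)

    def test_full_old_flagella_non_increasing_after_induction(self, cmap):
        report = run(SimScenario(n_agents=2000, seed=8), cmap)
        full = (
            report.counts[report.counts["old_label_class"] == "full"]
            .groupby("time_u")["count"]
            .sum()
        )
        post = full[full.index > 0.4]
        assert (np.diff(post.values) <= 0).all()


class TestPlateau:
    def test_equal_rates_is_exactly_half_by_pairing(self, cmap):
        """Once every 1K1N lineage has divided exactly once post-induction,
        each division contributed one fully-labelled and one affected cell at
        identical progress, so the pooled counts are exactly equal."""
        report = run(SimScenario.equal_rates(n_agents=2000, seed=6), cmap)
        counts = report.counts
        for t in (1.20, 1.25):  # 0.90 and 0.95 u post-induction
            at = counts[np.isclose(counts["time_u"], t)]
            k1n1 = at[at["stage"].isin(["1F1K1N", "2F1K1N"])]
            full = k1n1[k1n1["old_label_class"] == "full"]["count"].sum()
            affected = k1n1[k1n1["old_label_class"] == "affected"]["count"].sum()
            assert full == affected

    def test_window_before_induction_is_all_full(self, cmap):
        report = run(SimScenario(n_agents=1000, seed=2), cmap)
        est = plateau_fraction(report, window=(-0.3, -0.1))
        assert est.fraction == 1.0

    def test_empty_window_rejected(self, cmap):
        report = run(SimScenario(n_agents=500, seed=2), cmap)
        with pytest.raises(ValueError):
            plateau_fraction(report, window=(0.5, 0.5))
        with pytest.raises(ValueError):
            plateau_fraction(report, window=(7.0, 8.0))

    def test_slow_scenarios_mirror_each_other(self, cmap):
        nfd = run(SimScenario.nfd_slow(n_agents=4000, seed=11), cmap).plateau()
        ofd = run(SimScenario.ofd_slow(n_agents=4000, seed=11), cmap).plateau()
        assert nfd.fraction + ofd.fraction == pytest.approx(1.0, abs=0.015)
        assert ofd.fraction > 0.5 > nfd.fraction

    def test_detected_plateau_matches_explicit_flat_window(self, cmap):
        report = run(SimScenario.equal_rates(n_agents=4000, seed=12), cmap)
        detected = report.plateau()
        explicit = plateau_fraction(report, window=(0.85, 1.0))
        assert detected.fraction == pytest.approx(explicit.fraction, abs=0.01)


class TestScenarioValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(n_agents=0),
            dict(dt=0.0),
            dict(increment_ofd=0.02),  # exceeds dt
            dict(increment_nfd=0.0),
            dict(report_interval=0.013),  # not a multiple of dt
            dict(duration=1.0),  # cannot cover the plateau
            dict(init_flags="sorted"),
        ],
    )
    def test_invalid_scenarios(self, kw):
        with pytest.raises(ValueError):
            SimScenario(**kw)

    def test_named_scenarios(self):
        assert SimScenario.nfd_slow().increment_nfd == 0.009
        assert SimScenario.ofd_slow().increment_ofd == 0.009
        eq = SimScenario.equal_rates()
        assert eq.increment_ofd == eq.increment_nfd == 0.01
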