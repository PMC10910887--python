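"""Forward lifeline simulation and the benchmark generator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import idmincidence as idm
from idmincidence.mrr import MRRScenario
from idmincidence.simulate import (
    BenchmarkConfig,
    RateModel,
    SimulationGrid,
    lifeline_prevalence,
)


def constant_model(i0=0.02, m0=0.0, r=1.0):
    # scalar returns broadcast fine inside the vectorised integrator
    return RateModel(
        incidence=lambda t, a: float(i0),
        mortality=lambda t, a: float(m0),
        mrr=MRRScenario(id="c", r50=r, r95=r),
    )


class TestSplitMortality:
    def test_unit_mrr_leaves_rates_equal(self):
        m0, m1 = idm.split_mortality(0.05, 0.3, 1.0)
        assert m0 == m1 == 0.05

    def test_hand_values_and_mixture_identity(self):
        m0, m1 = idm.split_mortality(0.05, 0.2, 3.2)
        assert m0 == pytest.approx(0.05 / 1.44, rel=1e-12)
        assert m1 == pytest.approx(3.2 * 0.05 / 1.44, rel=1e-12)
        assert 0.2 * m1 + 0.8 * m0 == pytest.approx(0.05, rel=1e-12)

    def test_zero_prevalence(self):
        m0, m1 = idm.split_mortality(0.05, 0.0, 3.2)
        assert m0 == 0.05 and m1 == pytest.approx(3.2 * 0.05)

    @settings(max_examples=200, deadline=None)
    @given(
        m=st.floats(0.0, 1.0),
        p=st.floats(0.0, 1.0),
        r=st.floats(1.0, 10.0),
    )
    def test_mixture_identity_everywhere(self, m, p, r):
        m0, m1 = idm.split_mortality(m, p, r)
        assert p * m1 + (1 - p) * m0 == pytest.approx(m, rel=1e-12, abs=1e-15)
        assert m1 >= m0 >= 0


class TestSimulatePrevalence:
    def test_nothing_enters_stays_empty(self):
        model = constant_model(i0=0.0)
        grid = SimulationGrid.regular(2011, 2021, 2, 50, 99, 1,
                                      entry_prevalence=0.0)
        p = idm.simulate_prevalence(model, grid)
        assert np.all(p.values == 0.0)

    def test_closed_form_constant_incidence(self):
        """R=1, i constant: p(u) = 1 - exp(-i0 u) along a lifeline."""
        model = constant_model(i0=0.02)
        for u in (5.0, 20.0, 45.0):
            got = lifeline_prevalence(model, 2011.0, 50.0, 0.0, u, substep=0.25)
            assert got == pytest.approx(1 - np.exp(-0.02 * u), abs=1e-8)

    def test_surface_matches_closed_form(self):
        model = constant_model(i0=0.02)
        grid = SimulationGrid.regular(2011, 2021, 2, 50, 99, 1,
                                      entry_prevalence=0.0)
        p = idm.simulate_prevalence(model, grid)
        A = np.broadcast_to(p.ages, p.values.shape)
        expected = 1 - np.exp(-0.02 * (A - 50.0))
        assert np.max(np.abs(p.values - expected)) < 1e-8

    def test_excess_mortality_depletes_without_incidence(self):
        model = constant_model(i0=0.0, m0=0.3, r=3.0)
        vals = [lifeline_prevalence(model, 2011, 50, 0.4, u) for u in
                (0.0, 5.0, 10.0, 20.0)]
        assert np.all(np.diff(vals) < 0)

    def test_bounded_state(self):
        model = constant_model(i0=0.5, m0=0.2, r=3.0)
        grid = SimulationGrid.regular(2011, 2021, 1, 50, 99, 1,
                                      entry_prevalence=0.9)
        p = idm.simulate_prevalence(model, grid)
        assert np.all((p.values >= 0) & (p.values <= 1))

    def test_explicit_initial_condition_used(self):
        model = constant_model(i0=0.0)
        grid = SimulationGrid.regular(2011, 2021, 2, 50, 99, 1,
                                      entry_prevalence=0.0,
                                      initial_prevalence=lambda a: np.full_like(
                                          np.asarray(a, float), 0.25))
        p = idm.simulate_prevalence(model, grid)
        # i=0, m=0: prevalence is conserved along lifelines
        assert p(2011.0, 80.0) == pytest.approx(0.25)
        assert p(2021.0, 60.0 + 10.0) == pytest.approx(0.25)

    def test_invalid_entry_prevalence_rejected(self):
        model = constant_model()
        grid = SimulationGrid.regular(2011, 2021, 2, 50, 99, 1,
                                      entry_prevalence=1.5)
        with pytest.raises(ValueError, match=r"\[0, 1\)"):
            idm.simulate_prevalence(model, grid)


class TestBenchmarkDataset:
    def test_deterministic_given_seed(self):
        a = idm.make_benchmark_dataset(7)
        b = idm.make_benchmark_dataset(7)
        for sex in ("male", "female"):
            np.testing.assert_array_equal(a.prevalence[sex].values,
                                          b.prevalence[sex].values)

    def test_biennial_window_has_six_year_levels(self, benchmark):
        for sex in ("male", "female"):
            assert benchmark.prevalence[sex].years.size == 6
            assert benchmark.mortality[sex].ages.size == 50

    def test_plausible_magnitudes(self, benchmark):
        p = benchmark.prevalence["male"]
        assert p(2011.0, 55.0) < 0.05          # rare in the 50s
        assert p(2021.0, 90.0) > 0.2           # tens of percent above 90
        assert np.all(np.diff(p.values, axis=1) > -1e-9)  # rises with age
        pf = benchmark.prevalence["female"]
        assert not np.allclose(pf.values, p.values)

    def test_noise_moves_surfaces_but_not_truth(self):
        noisy = idm.make_benchmark_dataset(3, BenchmarkConfig(noise_sigma=0.02))
        clean = idm.make_benchmark_dataset(3)
        assert not np.allclose(noisy.prevalence["male"].values,
                               clean.prevalence["male"].values)
        t, a = 2015.0, 80.0
        assert noisy.models["male"].incidence(t, a) == pytest.approx(
            clean.models["male"].incidence(t, a))

    def test_incidence_recovery_closes_the_loop(self, benchmark):
        """Invert the simulated surface with the true m and R: the
        estimated incidence matches the generating incidence at interior
        points of the biennial registry-style grid."""
        sc = benchmark.models["male"].mrr
        est = idm.estimate_incidence_grid(
            benchmark.prevalence["male"], benchmark.mortality["male"], sc,
            [2013.0, 2015.0, 2017.0, 2019.0], [55.0, 65.0, 75.0, 85.0, 95.0],
            h=1.0,
        )
        rel = [abs(e.incidence - float(benchmark.models["male"].incidence(
            e.year, e.age))) / float(benchmark.models["male"].incidence(
            e.year, e.age)) for e in est]
        assert max(rel) < 0.01

    def test_negative_config_rejected(self):
        with pytest.raises(ValueError):
            BenchmarkConfig(params={"male": dict(i50=-0.1, incidence_age_slope=0.09,
                                                 gompertz_intercept=0.003,
                                                 gompertz_slope=0.1)})
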