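"""Inversion of the illness-death equation: stencils, terms, identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import idmincidence as idm
from idmincidence.estimator import SingularPrevalenceError
from idmincidence.mrr import MRRScenario
from idmincidence.surfaces import SurfaceDomainError, SurfaceQuery

from conftest import make_affine_prevalence

R1 = MRRScenario(id="unit", r50=1.0, r95=1.0)


class TestDirectionalDerivative:
    def test_constant_surface_is_zero(self, flat_prevalence):
        d, flags = idm.directional_derivative(
            flat_prevalence, SurfaceQuery(2013.0, 61.0), h=1.0
        )
        assert d == pytest.approx(0.0, abs=1e-15)
        assert flags == ()

    def test_pure_age_gradient(self):
        p = make_affine_prevalence(age_slope=0.001, year_slope=0.0)
        d, _ = idm.directional_derivative(p, SurfaceQuery(2015.0, 70.0), h=1.0)
        assert d == pytest.approx(0.001, rel=1e-10)

    def test_affine_surface_sums_partials(self):
        p = make_affine_prevalence(age_slope=0.0005, year_slope=0.002)
        d, _ = idm.directional_derivative(p, SurfaceQuery(2015.0, 70.0), h=1.0)
        assert d == pytest.approx(0.0025, rel=1e-10)

    def test_one_sided_at_window_edges(self):
        p = make_affine_prevalence(age_slope=0.0005, year_slope=0.002)
        d, flags = idm.directional_derivative(p, SurfaceQuery(2011.0, 70.0), h=1.0)
        assert flags == ("one_sided_forward",)
        assert d == pytest.approx(0.0025, rel=1e-10)  # exact on affine data
        d, flags = idm.directional_derivative(p, SurfaceQuery(2021.0, 70.0), h=1.0)
        assert flags == ("one_sided_backward",)

    def test_no_stencil_fits_raises(self):
        p = make_affine_prevalence(0.0005, 0.0, years=[2011.0])
        with pytest.raises(SurfaceDomainError):
            idm.directional_derivative(p, SurfaceQuery(2011.0, 70.0), h=2.0)

    def test_nonpositive_step_rejected(self, flat_prevalence):
        with pytest.raises(ValueError):
            idm.directional_derivative(flat_prevalence, SurfaceQuery(2013, 61), h=0)


def surface_pair(p_value, m_value, years=None, ages=None):
    years = years if years is not None else np.arange(2011.0, 2022.0, 2.0)
    ages = ages if ages is not None else np.arange(50.0, 100.0, 1.0)
    p = idm.PrevalenceSurface("male", years, ages,
                              np.full((len(years), len(ages)), p_value))
    m = idm.MortalitySurface("male", years, ages,
                             np.full((len(years), len(ages)), m_value))
    return p, m


class TestEstimateIncidence:
    def test_mortality_free_inversion_at_unit_mrr(self):
        # steady p = 0.1 with R = 1: i = D/(1-p); build D = 0.009 via a pure
        # lifeline gradient of 0.009 per year
        years = np.arange(2011.0, 2022.0, 2.0)
        ages = np.arange(50.0, 100.0, 1.0)
        T, A = np.meshgrid(years, ages, indexing="ij")
        vals = 0.12 + 0.0045 * (A - 70.0) + 0.0045 * (T - 2015.0)
        p = idm.PrevalenceSurface("male", years, ages, vals)
        m = idm.MortalitySurface("male", years, ages, np.full_like(vals, 0.3))
        est = idm.estimate_incidence(p, m, R1, SurfaceQuery(2015.0, 70.0), h=1.0)
        assert est.excess_term == 0.0
        assert est.incidence == pytest.approx(0.009 / (1 - 0.12), rel=1e-9)

    def test_steady_state_excess_term_hand_value(self):
        p, m = surface_pair(0.2, 0.05)
        sc = MRRScenario(id="flat", r50=3.2, r95=3.2)
        est = idm.estimate_incidence(p, m, sc, SurfaceQuery(2015.0, 70.0), h=1.0)
        assert est.derivative_term == pytest.approx(0.0, abs=1e-12)
        assert est.incidence == pytest.approx(0.05 * 0.2 * 2.2 / (0.2 * 2.2 + 1),
                                              rel=1e-9)

    def test_zero_prevalence_gives_zero_incidence(self):
        p, m = surface_pair(0.0, 0.05)
        sc = idm.standard_scenarios()[0]
        est = idm.estimate_incidence(p, m, sc, SurfaceQuery(2015.0, 70.0), h=1.0)
        assert est.incidence == 0.0

    def test_decomposition_identity(self, benchmark):
        sc = idm.standard_scenarios()[4]
        est = idm.estimate_incidence(
            benchmark.prevalence["female"], benchmark.mortality["female"],
            sc, SurfaceQuery(2015.0, 80.0), h=1.0,
        )
        assert est.incidence == est.derivative_term + est.excess_term

    def test_singularity_near_full_prevalence(self):
        p, m = surface_pair(1.0 - 1e-9, 0.05)
        with pytest.raises(SingularPrevalenceError):
            idm.estimate_incidence(p, m, R1, SurfaceQuery(2015.0, 70.0), h=1.0)

    def test_negative_incidence_flagged_not_clipped(self):
        # prevalence falling along lifelines with R = 1 forces i < 0
        years = np.arange(2011.0, 2022.0, 2.0)
        ages = np.arange(50.0, 100.0, 1.0)
        T, A = np.meshgrid(years, ages, indexing="ij")
        vals = 0.2 - 0.001 * (A - 50.0)
        p = idm.PrevalenceSurface("male", years, ages, vals)
        m = idm.MortalitySurface("male", years, ages, np.full_like(vals, 0.05))
        est = idm.estimate_incidence(p, m, R1, SurfaceQuery(2015.0, 70.0), h=1.0)
        assert est.incidence < 0
        assert "negative_incidence" in est.flags

    @settings(max_examples=100, deadline=None)
    @given(
        pv=st.floats(0.01, 0.95),
        mv=st.floats(0.001, 0.5),
        r_lo=st.floats(1.0, 5.0),
        dr=st.floats(0.01, 5.0),
    )
    def test_excess_term_increasing_in_R_and_below_m(self, pv, mv, r_lo, dr):
        def excess(r):
            return mv * pv * (r - 1.0) / (pv * (r - 1.0) + 1.0)

        assert excess(r_lo + dr) > excess(r_lo)
        assert excess(r_lo + dr) < mv


class TestEstimateIncidenceGrid:
    def test_cardinality_and_order(self, benchmark):
        sc = idm.standard_scenarios()[0]
        est = idm.estimate_incidence_grid(
            benchmark.prevalence["male"], benchmark.mortality["male"], sc,
            [2013.0, 2015.0], [55.0, 65.0, 75.0, 85.0, 95.0], h=1.0,
        )
        assert len(est) == 10
        assert [(e.year, e.age) for e in est[:3]] == [
            (2013.0, 55.0), (2013.0, 65.0), (2013.0, 75.0)]

    def test_constant_surface_unit_mrr_all_zero(self, flat_prevalence):
        m = idm.MortalitySurface("male", flat_prevalence.years,
                                 flat_prevalence.ages,
                                 np.full((3, 3), 0.1))
        est = idm.estimate_incidence_grid(flat_prevalence, m, R1,
                                          [2013.0], [61.0], h=1.0)
        assert all(abs(e.incidence) < 1e-14 for e in est)

    def test_all_points_failing_aggregates(self, flat_prevalence):
        m = idm.MortalitySurface("male", flat_prevalence.years,
                                 flat_prevalence.ages, np.full((3, 3), 0.1))
        with pytest.raises(SurfaceDomainError, match="all"):
            idm.estimate_incidence_grid(flat_prevalence, m, R1,
                                        [2030.0], [61.0], h=1.0)

    def test_partial_failure_reported_per_point(self, flat_prevalence):
        m = idm.MortalitySurface("male", flat_prevalence.years,
                                 flat_prevalence.ages, np.full((3, 3), 0.1))
        est = idm.estimate_incidence_grid(flat_prevalence, m, R1,
                                          [2013.0], [61.0, 75.0], h=1.0)
        ok = [e for e in est if not e.flags]
        failed = [e for e in est if e.flags and e.flags[0].startswith("failed:")]
        assert len(ok) == 1 and len(failed) == 1
        assert np.isnan(failed[0].incidence)
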