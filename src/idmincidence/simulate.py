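"""Forward illness-death simulation along lifelines.

The prevalence transport equation

    (d/da + d/dt) p = (1 - p) * (i - m * p (R - 1) / (p (R - 1) + 1))

reduces to an ordinary differential equation along characteristics
(lifelines) a - t = const, which this module integrates with a classical
4th-order Runge-Kutta one-step scheme and samples onto a rectangular
(year, age) grid.  Because the generating rates i, m, R are known exactly,
the resulting prevalence surfaces serve as ground-truthed stand-ins for
registry data: running the inversion on them and comparing against the true
incidence is the package's end-to-end correctness check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .mrr import MRRScenario, mrr_at, standard_scenarios
from .surfaces import MortalitySurface, PrevalenceSurface, Surface


class NumericalInstabilityError(RuntimeError):
    """Integration produced prevalence outside [0, 1] beyond tolerance."""


def split_mortality(m, p, R):
    """Split general mortality into disease-free (m0) and diseased (m1) rates.

    The general rate is the prevalence-weighted mixture
    ``m = p*m1 + (1-p)*m0`` with ``m1 = R*m0``, hence
    ``m0 = m / (1 + p(R-1))`` and ``m1 = R*m0``.  Vectorised.
    """
    m = np.asarray(m, dtype=float)
    p = np.asarray(p, dtype=float)
    R = np.asarray(R, dtype=float)
    m0 = m / (1.0 + p * (R - 1.0))
    m1 = R * m0
    if m0.ndim == 0:
        return float(m0), float(m1)
    return m0, m1


@dataclass(frozen=True)
class RateModel:
    """The generating transition intensities of the illness-death model.

    ``incidence`` and ``mortality`` are vectorised callables (t, a) -> rate
    per person-year; ``mrr`` is an :class:`~idmincidence.mrr.MRRScenario`
    (or any callable (t, a) -> R >= 1).
    """

    incidence: Callable
    mortality: Callable
    mrr: Callable

    def rhs(self, t, a, p):
        """Right-hand side of the lifeline ODE dp/du = (1-p)(i - excess)."""
        i = self.incidence(t, a)
        m = self.mortality(t, a)
        R = self.mrr(t, a) if not isinstance(self.mrr, MRRScenario) else mrr_at(self.mrr, t, a)
        excess = m * p * (R - 1.0) / (p * (R - 1.0) + 1.0)
        return (1.0 - p) * (i - excess)

    @staticmethod
    def parametric(
        i50: float,
        incidence_age_slope: float,
        incidence_apc_percent: float,
        gompertz_intercept: float,
        gompertz_slope: float,
        mortality_apc_percent: float = 0.0,
        mrr: MRRScenario | None = None,
        reference_year: float = 2011.0,
    ) -> "RateModel":
        """Build the standard parametric model.

        Incidence: ``i50 * exp(slope*(a-50)) * (1+apc_i/100)**(t-ref)`` —
        exponential in age with a constant annual percent change, so the
        true APC of incidence is known exactly.  Mortality: Gompertz
        ``kappa * exp(lambda*(a-50))`` with an optional annual trend.  MRR:
        a scenario (default: log-affine 3.2 at age 50 down to 1.2 at 95, no
        time trend).
        """
        if mrr is None:
            mrr = standard_scenarios(reference_year)[0]

        def incidence(t, a):
            t = np.asarray(t, dtype=float)
            a = np.asarray(a, dtype=float)
            return (
                i50
                * np.exp(incidence_age_slope * (a - 50.0))
                * (1.0 + incidence_apc_percent / 100.0) ** (t - reference_year)
            )

        def mortality(t, a):
            t = np.asarray(t, dtype=float)
            a = np.asarray(a, dtype=float)
            return (
                gompertz_intercept
                * np.exp(gompertz_slope * (a - 50.0))
                * (1.0 + mortality_apc_percent / 100.0) ** (t - reference_year)
            )

        return RateModel(incidence=incidence, mortality=mortality, mrr=mrr)


@dataclass
class SimulationGrid:
    """Output grid and entry conditions for the forward simulation.

    ``years`` and ``ages`` are the rectangular sampling grid.
    ``entry_prevalence`` is p at the minimum-age edge (scalar or callable of
    the entry year); real populations have a small positive prevalence at
    age 50, so the default is 0.005 rather than 0.  ``initial_prevalence``
    optionally fixes p(t_min, a) over ages (scalar or callable of age); when
    None, lifelines are instead continued backwards in time to the
    minimum-age edge ("spin-up"), which yields an initial cross-section that
    is itself consistent with the rate model.  ``substep`` caps the
    Runge-Kutta step in years.
    """

    years: np.ndarray
    ages: np.ndarray
    entry_prevalence: float | Callable = 0.005
    initial_prevalence: float | Callable | None = None
    substep: float = 0.25

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=float)
        self.ages = np.asarray(self.ages, dtype=float)
        if self.years.ndim != 1 or np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be 1-d strictly increasing")
        if self.ages.ndim != 1 or np.any(np.diff(self.ages) <= 0):
            raise ValueError("ages must be 1-d strictly increasing")
        if self.substep <= 0:
            raise ValueError("substep must be positive")

    @staticmethod
    def regular(
        year_start: float, year_stop: float, year_step: float,
        age_start: float, age_stop: float, age_step: float,
        **kwargs,
    ) -> "SimulationGrid":
        years = np.arange(year_start, year_stop + 0.5 * year_step, year_step)
        ages = np.arange(age_start, age_stop + 0.5 * age_step, age_step)
        return SimulationGrid(years=years, ages=ages, **kwargs)


def _as_callable(x):
    return x if callable(x) else (lambda arg, _v=float(x): np.full_like(
        np.asarray(arg, dtype=float), _v))


def simulate_prevalence(
    model: RateModel,
    grid: SimulationGrid,
    sex: str = "unspecified",
    margin: float = 1.0,
    _tol: float = 1e-9,
) -> Surface:
    """Integrate the lifeline ODE to every grid node and return the surface.

    Each node (t, a) is reached by integrating dp/du along its lifeline from
    the point where the lifeline enters the domain: the minimum-age edge, the
    initial-time edge if ``initial_prevalence`` is given, or the backward
    continuation to the minimum-age edge otherwise.  Integration is classical
    RK4 with a per-node uniform step <= ``grid.substep``; all nodes advance
    in lockstep as vectorised array operations.
    """
    years, ages = grid.years, grid.ages
    T, A = np.meshgrid(years, ages, indexing="ij")
    t = T.ravel()
    a = A.ravel()

    entry_p = _as_callable(grid.entry_prevalence)
    if grid.initial_prevalence is None:
        # spin-up: every lifeline starts at the minimum-age edge, possibly
        # before the first grid year
        dist = a - ages[0]
        p0 = np.asarray(entry_p(t - dist), dtype=float) + np.zeros_like(t)
    else:
        init_p = _as_callable(grid.initial_prevalence)
        from_time_edge = (t - years[0]) <= (a - ages[0])
        dist = np.where(from_time_edge, t - years[0], a - ages[0])
        p0 = np.where(
            from_time_edge,
            np.asarray(init_p(a - (t - years[0])), dtype=float) + np.zeros_like(a),
            np.asarray(entry_p(t - (a - ages[0])), dtype=float) + np.zeros_like(t),
        )
    if np.any((p0 < 0) | (p0 >= 1)):
        raise ValueError("entry/initial prevalence must lie in [0, 1)")

    n_steps = np.maximum(np.ceil(dist / grid.substep - 1e-12).astype(int), 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(n_steps > 0, dist / np.maximum(n_steps, 1), 0.0)

    p = p0.copy()
    t_entry = t - dist
    a_entry = a - dist
    for s in range(int(n_steps.max()) if n_steps.size else 0):
        active = s < n_steps
        hs = np.where(active, h, 0.0)
        u = s * h
        tc = t_entry + u
        ac = a_entry + u
        k1 = model.rhs(tc, ac, p)
        k2 = model.rhs(tc + hs / 2, ac + hs / 2, p + hs / 2 * k1)
        k3 = model.rhs(tc + hs / 2, ac + hs / 2, p + hs / 2 * k2)
        k4 = model.rhs(tc + hs, ac + hs, p + hs * k3)
        p = p + hs / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)

    if np.any(p < -_tol) or np.any(p > 1.0 + _tol):
        worst = p[np.argmax(np.maximum(-p, p - 1.0))]
        raise NumericalInstabilityError(
            f"simulated prevalence left [0, 1] (worst value {worst}); "
            f"reduce the substep (currently {grid.substep})"
        )
    p = np.clip(p, 0.0, 1.0)
    return PrevalenceSurface(
        sex=sex, years=years, ages=ages,
        values=p.reshape(len(years), len(ages)), margin=margin,
    )


def lifeline_prevalence(model: RateModel, t0: float, a0: float, p0: float,
                        u: float, substep: float = 0.25) -> float:
    """Prevalence after following one lifeline for ``u`` years from
    (t0, a0, p0); same RK4 scheme as :func:`simulate_prevalence`."""
    n = max(int(np.ceil(u / substep - 1e-12)), 0)
    if n == 0:
        return float(p0)
    h = u / n
    p = float(p0)
    for s in range(n):
        tc, ac = t0 + s * h, a0 + s * h
        k1 = model.rhs(tc, ac, p)
        k2 = model.rhs(tc + h / 2, ac + h / 2, p + h / 2 * k1)
        k3 = model.rhs(tc + h / 2, ac + h / 2, p + h / 2 * k2)
        k4 = model.rhs(tc + h, ac + h, p + h * k3)
        p = p + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return float(p)


# -- benchmark dataset ----------------------------------------------------

#: per-sex generating parameters of the benchmark: incidence at age 50 of a
#: few per thousand person-years rising exponentially to ~0.1/yr above 90,
#: Gompertz all-cause mortality declining ~1 %/yr, female mortality below
#: male; magnitudes chosen to resemble German registry surfaces.
BENCHMARK_PARAMS = {
    "male": dict(i50=0.002, incidence_age_slope=0.09,
                 gompertz_intercept=0.0030, gompertz_slope=0.100,
                 mortality_apc_percent=-1.0),
    "female": dict(i50=0.0025, incidence_age_slope=0.088,
                   gompertz_intercept=0.0016, gompertz_slope=0.106,
                   mortality_apc_percent=-1.0),
}


@dataclass
class BenchmarkConfig:
    """Study conditions emulated by the benchmark generator: biennial
    prevalence reporting 2011-2021, single-year ages 50-99, a default
    incidence trend of +5 %/yr, no observation noise (full-population
    registry counts), base-case excess mortality."""

    year_start: float = 2011.0
    year_stop: float = 2021.0
    year_step: float = 2.0
    age_start: float = 50.0
    age_stop: float = 99.0
    age_step: float = 1.0
    incidence_apc_percent: float = 5.0
    mrr: MRRScenario | None = None
    noise_sigma: float = 0.0
    entry_prevalence: float = 0.005
    substep: float = 0.25
    params: dict = field(default_factory=lambda: BENCHMARK_PARAMS)

    def __post_init__(self) -> None:
        for sex, kw in self.params.items():
            for key, val in kw.items():
                if key != "mortality_apc_percent" and val < 0:
                    raise ValueError(f"{sex}.{key} must be non-negative, got {val}")


@dataclass
class BenchmarkDataset:
    """Per-sex surfaces plus the generating truth for recovery testing."""

    prevalence: dict[str, Surface]
    mortality: dict[str, Surface]
    models: dict[str, RateModel]
    config: BenchmarkConfig
    seed: int


def make_benchmark_dataset(seed: int, config: BenchmarkConfig | None = None) -> BenchmarkDataset:
    """Generate the two-sex synthetic registry stand-in.

    Deterministic given ``seed``; the seed only matters when
    ``config.noise_sigma > 0``, in which case multiplicative log-normal
    observation noise is applied to the prevalence surfaces (truth and
    mortality stay exact).
    """
    config = config or BenchmarkConfig()
    rng = np.random.default_rng(seed)
    prevalence, mortality, models = {}, {}, {}
    for sex, kw in config.params.items():
        model = RateModel.parametric(
            incidence_apc_percent=config.incidence_apc_percent,
            mrr=config.mrr,
            reference_year=config.year_start,
            **kw,
        )
        grid = SimulationGrid.regular(
            config.year_start, config.year_stop, config.year_step,
            config.age_start, config.age_stop, config.age_step,
            entry_prevalence=config.entry_prevalence,
            substep=config.substep,
        )
        p = simulate_prevalence(model, grid, sex=sex)
        if config.noise_sigma > 0:
            noise = np.exp(rng.normal(0.0, config.noise_sigma, size=p.values.shape))
            p = PrevalenceSurface(sex=sex, years=p.years, ages=p.ages,
                                  values=np.clip(p.values * noise, 0.0, 1.0))
        T, A = np.meshgrid(grid.years, grid.ages, indexing="ij")
        m_values = np.asarray(model.mortality(T, A), dtype=float)
        prevalence[sex] = p
        mortality[sex] = MortalitySurface(sex=sex, years=grid.years,
                                          ages=grid.ages, values=m_values)
        models[sex] = model
    return BenchmarkDataset(prevalence=prevalence, mortality=mortality,
                            models=models, config=config, seed=seed)


def write_truth_sidecar(model: RateModel, years, ages, path) -> None:
    """Write the generating rates on a grid: year, age, true_i, true_m, true_R."""
    years = np.asarray(years, dtype=float)
    ages = np.asarray(ages, dtype=float)
    T, A = np.meshgrid(years, ages, indexing="ij")
    R = (mrr_at(model.mrr, T, A) if isinstance(model.mrr, MRRScenario)
         else model.mrr(T, A))
    pd.DataFrame(
        {
            "year": T.ravel(),
            "age": A.ravel(),
            "true_i": np.asarray(model.incidence(T, A)).ravel(),
            "true_m": np.asarray(model.mortality(T, A)).ravel(),
            "true_R": np.broadcast_to(np.asarray(R), T.shape).ravel(),
        }
    ).to_csv(path, index=False, float_format="%.17g")
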