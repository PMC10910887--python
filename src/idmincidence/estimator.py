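"""Inversion of the illness-death transport equation.

For an irreversible condition with zero remission, the prevalence p(t, a)
satisfies

    (d/da + d/dt) p = (1 - p) * (i - m * p (R - 1) / (p (R - 1) + 1)),

where i is the incidence rate among the condition-free, m the general
(all-cause) mortality of the whole population and R the mortality rate
ratio of diseased vs disease-free.  Solving for i,

    i = (d/da + d/dt) p / (1 - p)  +  m * p (R - 1) / (p (R - 1) + 1),

which this module evaluates pointwise: the lifeline (directional) derivative
of prevalence by finite differences on the interpolated surface, the excess
mortality term from m, p and the scenario R.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mrr import MRRScenario, mrr_at
from .surfaces import Surface, SurfaceDomainError, SurfaceQuery

#: prevalence this close to 1 makes 1/(1-p) meaningless
SINGULARITY_EPS = 1e-6


class SingularPrevalenceError(ValueError):
    """Prevalence at the query point is too close to 1 for Eq. inversion."""


@dataclass
class IncidenceEstimate:
    """Incidence at one (sex, year, age) point with its exact decomposition.

    ``incidence == derivative_term + excess_term`` by construction:
    the first term is D/(1-p) with D the lifeline derivative of prevalence,
    the second m*p(R-1)/(p(R-1)+1).  ``flags`` records departures from the
    default scheme ("one_sided_forward"/"one_sided_backward" at the first or
    last grid year) and diagnostics ("negative_incidence"); negative
    estimates are never clipped — they signal inputs incompatible with the
    assumed R.
    """

    sex: str
    year: float
    age: float
    incidence: float
    derivative_term: float
    excess_term: float
    p: float
    m: float
    R: float
    flags: tuple[str, ...] = field(default_factory=tuple)


def directional_derivative(
    p: Surface, q: SurfaceQuery, h: float = 1.0
) -> tuple[float, tuple[str, ...]]:
    """Lifeline derivative (d/da + d/dt) p at ``q`` by finite differences.

    Central difference [p(t+h, a+h) - p(t-h, a-h)] / (2h) along the
    characteristic direction, with bilinear interpolation for off-grid
    points.  At the first/last grid year the stencil would leave the
    surface, so a one-sided difference with the same h is used and flagged
    (``one_sided_forward`` / ``one_sided_backward``).

    Returns the derivative and the tuple of flags.
    """
    if h <= 0:
        raise ValueError("step h must be positive")
    t, a = q.year, q.age
    can_back = t - h >= p.years[0]
    can_fwd = t + h <= p.years[-1]
    if can_back and can_fwd:
        d = (p(t + h, a + h) - p(t - h, a - h)) / (2.0 * h)
        return float(d), ()
    if can_fwd:
        d = (p(t + h, a + h) - p(t, a)) / h
        return float(d), ("one_sided_forward",)
    if can_back:
        d = (p(t, a) - p(t - h, a - h)) / h
        return float(d), ("one_sided_backward",)
    raise SurfaceDomainError(
        f"no difference stencil with h={h} fits the year range "
        f"[{p.years[0]}, {p.years[-1]}] at t={t}"
    )


def estimate_incidence(
    p: Surface,
    m: Surface,
    scenario: MRRScenario,
    q: SurfaceQuery,
    h: float = 1.0,
) -> IncidenceEstimate:
    """Evaluate the inverted illness-death equation at one point.

    The estimate decomposes exactly into the derivative term D/(1-p) and the
    excess-mortality term m*p(R-1)/(p(R-1)+1); both are recorded together
    with the p, m, R values used.  Negative incidence is flagged, not
    clipped.
    """
    pv = p.at(q)
    if pv >= 1.0 - SINGULARITY_EPS:
        raise SingularPrevalenceError(
            f"prevalence {pv} at (year={q.year}, age={q.age}) is too close to 1"
        )
    d, flags = directional_derivative(p, q, h)
    mv = m.at(q)
    rv = mrr_at(scenario, q.year, q.age)
    derivative_term = d / (1.0 - pv)
    excess_term = mv * pv * (rv - 1.0) / (pv * (rv - 1.0) + 1.0)
    incidence = derivative_term + excess_term
    if incidence < 0:
        flags = flags + ("negative_incidence",)
    return IncidenceEstimate(
        sex=p.sex,
        year=q.year,
        age=q.age,
        incidence=incidence,
        derivative_term=derivative_term,
        excess_term=excess_term,
        p=pv,
        m=mv,
        R=rv,
        flags=flags,
    )


def estimate_incidence_grid(
    p: Surface,
    m: Surface,
    scenario: MRRScenario,
    years,
    ages,
    h: float = 1.0,
) -> list[IncidenceEstimate]:
    """Apply :func:`estimate_incidence` over the product of years x ages.

    One estimate per (year, age) in year-major order.  Per-point failures
    (domain or singularity errors) are collected; if every point fails an
    aggregate error is raised, otherwise failed points are reported as
    estimates with ``incidence = nan`` and a flag naming the error.
    """
    out: list[IncidenceEstimate] = []
    n_failed = 0
    for year in years:
        for age in ages:
            q = SurfaceQuery(year=float(year), age=float(age))
            try:
                out.append(estimate_incidence(p, m, scenario, q, h))
            except (SurfaceDomainError, SingularPrevalenceError) as exc:
                n_failed += 1
                out.append(
                    IncidenceEstimate(
                        sex=p.sex, year=float(year), age=float(age),
                        incidence=float("nan"), derivative_term=float("nan"),
                        excess_term=float("nan"), p=float("nan"),
                        m=float("nan"), R=float("nan"),
                        flags=("failed:" + type(exc).__name__,),
                    )
                )
    if out and n_failed == len(out):
        raise SurfaceDomainError(
            f"all {n_failed} grid points failed incidence estimation"
        )
    return out


def estimates_to_frame(estimates: list[IncidenceEstimate]):
    """Tabulate estimates (sex, year, age, incidence, terms, inputs, flags)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "sex": [e.sex for e in estimates],
            "year": [e.year for e in estimates],
            "age": [e.age for e in estimates],
            "incidence": [e.incidence for e in estimates],
            "derivative_term": [e.derivative_term for e in estimates],
            "excess_term": [e.excess_term for e in estimates],
            "p": [e.p for e in estimates],
            "m": [e.m for e in estimates],
            "R": [e.R for e in estimates],
            "flags": [";".join(e.flags) for e in estimates],
        }
    )
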