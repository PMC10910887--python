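"""Mortality-rate-ratio (MRR) scenarios.

The MRR ``R = m1 / m0`` is the excess mortality of people in the disease
state relative to the disease-free.  No population-wide estimate of R exists
for need-for-long-term-care in Germany, so the pipeline works with scenarios:
log(R) is affine-linear in age between anchors at ages 50 and 95 (an
empirical regularity of chronic conditions), an optional multiplicative
annual time trend scales R over calendar time, and the result is floored at
1 (the condition is never assumed protective against death).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

ANCHOR_AGE_LO = 50.0
ANCHOR_AGE_HI = 95.0


@dataclass(frozen=True)
class MRRScenario:
    """One excess-mortality scenario.

    Parameters
    ----------
    id : int | str
        Scenario label.
    r50, r95 : float
        MRR anchors at ages 50 and 95 (dimensionless, >= 1).
    apc_mrr_percent : float
        Annual percent change of the MRR over calendar time; <= 0 in the
        standard set (treatment progress lowers excess mortality).
    reference_year : float
        Calendar year at which the anchors apply; the time factor is
        ``(1 + apc/100) ** (year - reference_year)``.
    """

    id: int | str
    r50: float
    r95: float
    apc_mrr_percent: float = 0.0
    reference_year: float = 2011.0

    def __post_init__(self) -> None:
        if self.r50 < 1.0 or self.r95 < 1.0:
            raise ValueError(
                f"scenario {self.id}: MRR anchors must be >= 1 "
                f"(got r50={self.r50}, r95={self.r95})"
            )

    def __call__(self, year, age):
        return mrr_at(self, year, age)


def mrr_at(scenario: MRRScenario, year, age):
    """Evaluate R(t, a): log-linear age interpolation, time trend, floor at 1.

    The age profile interpolates log R between (50, log r50) and
    (95, log r95); ages outside [50, 95] clamp to the nearest anchor.  The
    annual trend then multiplies by ``(1 + apc/100) ** (year - ref_year)``,
    and finally the floor ``max(1, .)`` is applied, so R >= 1 everywhere even
    after a long negative trend.  Vectorised over ``year`` and ``age``.
    """
    year = np.asarray(year, dtype=float)
    age = np.asarray(age, dtype=float)
    frac = (np.clip(age, ANCHOR_AGE_LO, ANCHOR_AGE_HI) - ANCHOR_AGE_LO) / (
        ANCHOR_AGE_HI - ANCHOR_AGE_LO
    )
    log_r = (1.0 - frac) * np.log(scenario.r50) + frac * np.log(scenario.r95)
    trend = (1.0 + scenario.apc_mrr_percent / 100.0) ** (year - scenario.reference_year)
    r = np.maximum(1.0, np.exp(log_r) * trend)
    return float(r) if r.ndim == 0 else r


def mrr_halving_time(apc_mrr_percent: float) -> float:
    """Years until an MRR with the given negative APC halves.

    ``log(0.5) / log(1 + apc/100)``; e.g. an APC of -10 %/yr halves the MRR
    every 6.58 years.  Raises for apc >= 0 (no halving).
    """
    if apc_mrr_percent >= 0:
        raise ValueError("halving time is defined only for a negative APC")
    return float(np.log(0.5) / np.log1p(apc_mrr_percent / 100.0))


def standard_scenarios(reference_year: float = 2011.0) -> list[MRRScenario]:
    """The built-in ``standard8`` scenario set.

    Eight scenarios spanning the literature range of the age-specific MRR
    (1.2 to 3.2): a base case declining log-linearly from 3.2 at age 50 to
    1.2 at age 95 with no time trend, the same profile with annual MRR
    declines of 2.5 %, 5 % and 10 %, and age-constant profiles at 3.2 and
    1.2 with and without a 5 % annual decline.
    """
    rows = [
        (1, 3.2, 1.2, 0.0),
        (2, 3.2, 1.2, -2.5),
        (3, 3.2, 1.2, -5.0),
        (4, 3.2, 1.2, -10.0),
        (5, 3.2, 3.2, 0.0),
        (6, 3.2, 3.2, -5.0),
        (7, 1.2, 1.2, 0.0),
        (8, 1.2, 1.2, -5.0),
    ]
    return [
        MRRScenario(id=i, r50=r50, r95=r95, apc_mrr_percent=apc,
                    reference_year=reference_year)
        for i, r50, r95, apc in rows
    ]


def load_scenarios(path) -> list[MRRScenario]:
    """Load scenarios from a YAML file: a list of mappings with keys
    ``id, r50, r95, apc_mrr_percent[, reference_year]``."""
    with open(Path(path)) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list) or not raw:
        raise ValueError(f"{path}: expected a non-empty list of scenario mappings")
    return [MRRScenario(**entry) for entry in raw]


def resolve_scenarios(spec: str | Path) -> list[MRRScenario]:
    """Resolve ``"standard8"`` to the built-in set, anything else to a file path."""
    if str(spec) == "standard8":
        return standard_scenarios()
    return load_scenarios(spec)
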