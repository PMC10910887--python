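"""Annual percent change (APC) of the incidence rate.

The trend summary is the constant annual growth rate that carries the
incidence from its start-window value to its end-window value:

    APC = 100 * ((i_end / i_start) ** (1 / (end_year - start_year)) - 1),

evaluated per (scenario, sex, age).  Only the two endpoint years enter; no
regression over intermediate years is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimator import estimate_incidence_grid
from .mrr import MRRScenario
from .surfaces import Surface, write_apc_table


def compute_apc(i_start: float, i_end: float, start_year: float, end_year: float) -> float:
    """APC in percent per year between two positive rates.

    Scale-invariant in (i_start, i_end) jointly and exactly inverts
    compounding: if i_end = i_start * (1+x)^n over n years, the result is
    100x.
    """
    if end_year <= start_year:
        raise ValueError("end_year must exceed start_year")
    if not i_start > 0:
        raise ValueError(f"start incidence must be positive (got {i_start})")
    if not i_end > 0:
        raise ValueError(f"end incidence must be positive (got {i_end})")
    n = end_year - start_year
    return float(100.0 * ((i_end / i_start) ** (1.0 / n) - 1.0))


@dataclass
class APCTable:
    """Long-format APC results: one row per (scenario, sex, age).

    ``data`` has columns scenario, sex, age, apc_percent; ``window`` records
    the (start_year, end_year) the APCs refer to.
    """

    data: pd.DataFrame
    window: tuple[float, float] | None = None
    failures: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return self.data

    def __len__(self) -> int:
        return len(self.data)

    def lookup(self, scenario, sex, age) -> float:
        d = self.data
        row = d[(d["scenario"] == scenario) & (d["sex"] == sex) & (d["age"] == age)]
        if len(row) != 1:
            raise KeyError(f"no unique row for ({scenario}, {sex}, {age})")
        return float(row["apc_percent"].iloc[0])

    def report_layout(self) -> pd.DataFrame:
        """Wide layout: one row per (scenario, sex), one column per age,
        APCs rounded to one decimal place."""
        wide = self.data.pivot(index=["scenario", "sex"], columns="age",
                               values="apc_percent").round(1)
        wide.columns = [f"age_{g:g}" for g in wide.columns]
        return wide.reset_index()

    def write(self, path, mode: str = "machine") -> None:
        write_apc_table(self, path, mode=mode)


def apc_table(
    p_by_sex: dict[str, Surface],
    m_by_sex: dict[str, Surface],
    scenarios: list[MRRScenario],
    ages,
    start_year: float,
    end_year: float,
    h: float = 1.0,
) -> APCTable:
    """Assemble the APC of incidence per (scenario, sex, age).

    For each combination the incidence is estimated at both window endpoint
    years via the illness-death inversion, then summarised with
    :func:`compute_apc`.  Rows come out scenario-major, then sex, then age.
    A misspecified scenario (assumed R differing from the truth) is a valid
    analysis, not an error — the table records which scenario produced each
    row.  Per-cell failures (non-positive or non-finite incidence) are
    recorded in ``failures`` and omitted from the table; if everything
    fails, an error is raised.
    """
    if set(p_by_sex) != set(m_by_sex):
        raise ValueError("prevalence and mortality must cover the same sexes")
    ages = [float(g) for g in ages]
    rows = []
    failures: list[dict] = []
    for scenario in scenarios:
        for sex in p_by_sex:
            est_start = estimate_incidence_grid(
                p_by_sex[sex], m_by_sex[sex], scenario, [start_year], ages, h
            )
            est_end = estimate_incidence_grid(
                p_by_sex[sex], m_by_sex[sex], scenario, [end_year], ages, h
            )
            for e0, e1 in zip(est_start, est_end):
                try:
                    apc = compute_apc(e0.incidence, e1.incidence, start_year, end_year)
                except ValueError as exc:
                    failures.append(
                        {"scenario": scenario.id, "sex": sex, "age": e0.age,
                         "reason": str(exc)}
                    )
                    continue
                rows.append(
                    {"scenario": scenario.id, "sex": sex, "age": e0.age,
                     "apc_percent": apc}
                )
    if not rows:
        raise ValueError(f"APC failed at every cell; first: {failures[:3]}")
    df = pd.DataFrame(rows)
    if np.allclose(df["age"], np.round(df["age"])):
        df["age"] = df["age"].astype(int)
    return APCTable(data=df, window=(start_year, end_year), failures=failures)
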