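"""Config-driven pipeline runs: estimate, simulate, recovery.

Each run function takes a plain configuration mapping (typically loaded from
YAML), performs one workflow end to end and writes its outputs under the
configured directory.  The command-line layer in :mod:`idmincidence.cli` is a
thin wrapper around these functions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .estimator import estimate_incidence_grid, estimates_to_frame
from .mrr import MRRScenario, resolve_scenarios, standard_scenarios
from .simulate import (
    BenchmarkConfig,
    RateModel,
    SimulationGrid,
    make_benchmark_dataset,
    simulate_prevalence,
    write_truth_sidecar,
)
from .surfaces import read_surface, write_surface
from .trends import APCTable, apc_table, compute_apc

log = logging.getLogger("idmincidence")

EVALUATION_AGES = (55.0, 65.0, 75.0, 85.0, 95.0)


class ConfigError(ValueError):
    """The run configuration is invalid; raised before any computation."""


@dataclass
class RunConfig:
    """Validated configuration of an estimation run."""

    prevalence_paths: dict[str, Path]
    mortality_paths: dict[str, Path]
    scenarios: list[MRRScenario]
    ages: tuple[float, ...] = EVALUATION_AGES
    window: tuple[float, float] = (2011.0, 2021.0)
    h: float = 1.0
    out: Path = Path("results")

    @staticmethod
    def from_mapping(cfg: dict) -> "RunConfig":
        try:
            prevalence = {s: Path(p) for s, p in cfg["prevalence"].items()}
            mortality = {s: Path(p) for s, p in cfg["mortality"].items()}
        except (KeyError, AttributeError) as exc:
            raise ConfigError(
                "config must map 'prevalence' and 'mortality' to {sex: path}"
            ) from exc
        if set(prevalence) != set(mortality):
            raise ConfigError("prevalence and mortality must list the same sexes")
        for path in [*prevalence.values(), *mortality.values()]:
            if not path.exists():
                raise ConfigError(f"input file not found: {path}")
        scenarios = resolve_scenarios(cfg.get("scenarios", "standard8"))
        window = tuple(float(v) for v in cfg.get("window", (2011, 2021)))
        if len(window) != 2 or window[1] <= window[0]:
            raise ConfigError(f"window must be (start, end) with end > start, got {window}")
        return RunConfig(
            prevalence_paths=prevalence,
            mortality_paths=mortality,
            scenarios=scenarios,
            ages=tuple(float(a) for a in cfg.get("ages", EVALUATION_AGES)),
            window=window,  # type: ignore[arg-type]
            h=float(cfg.get("h", 1.0)),
            out=Path(cfg.get("out", "results")),
        )


def run_estimate(config: RunConfig) -> APCTable:
    """Load surfaces, estimate incidence at both window endpoints for every
    scenario and sex, and write incidence grids plus the APC table (machine
    and report layouts) under ``config.out``."""
    log.info("defaults in effect: h=%s, one-sided differences at boundary "
             "years, no pre-smoothing", config.h)
    p_by_sex = {s: read_surface(path, "prevalence", s)
                for s, path in config.prevalence_paths.items()}
    m_by_sex = {s: read_surface(path, "mortality", s)
                for s, path in config.mortality_paths.items()}
    start, end = config.window
    config.out.mkdir(parents=True, exist_ok=True)

    for scenario in config.scenarios:
        frames = []
        for sex in p_by_sex:
            est = estimate_incidence_grid(
                p_by_sex[sex], m_by_sex[sex], scenario,
                [start, end], config.ages, config.h,
            )
            frames.append(estimates_to_frame(est))
        import pandas as pd

        inc = pd.concat(frames, ignore_index=True)
        inc.to_csv(config.out / f"incidence_scenario{scenario.id}.csv",
                   index=False, float_format="%.17g")

    table = apc_table(p_by_sex, m_by_sex, config.scenarios, config.ages,
                      start, end, config.h)
    table.write(config.out / "apc_table.csv", mode="machine")
    table.write(config.out / "apc_table_report.csv", mode="report")
    table.report_layout().to_csv(config.out / "apc_report_wide.csv", index=False)
    if table.failures:
        log.warning("%d APC cell(s) failed: %s", len(table.failures),
                    table.failures[:5])
    return table


def run_simulate(cfg: dict) -> dict[str, Path]:
    """Generate the benchmark fixture files: per-sex prevalence and mortality
    surfaces plus the ground-truth rate sidecars."""
    seed = int(cfg.get("seed", 0))
    bench_cfg = BenchmarkConfig(
        **{k: cfg[k] for k in (
            "year_start", "year_stop", "year_step", "age_start", "age_stop",
            "age_step", "incidence_apc_percent", "noise_sigma",
            "entry_prevalence", "substep",
        ) if k in cfg}
    )
    out = Path(cfg.get("out", "results/benchmark"))
    out.mkdir(parents=True, exist_ok=True)
    data = make_benchmark_dataset(seed, bench_cfg)
    written: dict[str, Path] = {}
    for sex in data.prevalence:
        for kind, surf in (("prevalence", data.prevalence[sex]),
                           ("mortality", data.mortality[sex])):
            path = out / f"{kind}_{sex}.csv"
            write_surface(surf, path)
            written[f"{kind}_{sex}"] = path
        truth_path = out / f"truth_{sex}.csv"
        write_truth_sidecar(data.models[sex], data.prevalence[sex].years,
                            data.prevalence[sex].ages, truth_path)
        written[f"truth_{sex}"] = truth_path
    log.info("simulated %d sexes on %d years x %d ages (seed %d)",
             len(data.prevalence), len(bench_cfg_years(bench_cfg)),
             data.prevalence[next(iter(data.prevalence))].ages.size, seed)
    return written


def bench_cfg_years(cfg: BenchmarkConfig) -> np.ndarray:
    return np.arange(cfg.year_start, cfg.year_stop + 0.5 * cfg.year_step,
                     cfg.year_step)


@dataclass
class RecoveryReport:
    """Parameter-recovery diagnostics of the simulate -> invert round trip."""

    max_rel_incidence_error: float
    mean_rel_incidence_error: float
    per_age_max_rel_error: dict[float, float]
    apc_true: float
    apc_errors_pp: dict[float, float]  # age -> |recovered - true| in pp
    max_apc_error_pp: float = field(init=False)

    def __post_init__(self) -> None:
        self.max_apc_error_pp = max(self.apc_errors_pp.values())

    def passed(self, tol_incidence_pct: float = 1.0, tol_apc_pp: float = 0.3) -> bool:
        return (self.max_rel_incidence_error * 100.0 < tol_incidence_pct
                and self.max_apc_error_pp < tol_apc_pp)


def run_recovery(
    incidence_apc_percent: float = 10.0,
    mrr: MRRScenario | None = None,
    window: tuple[float, float] = (2011.0, 2021.0),
    ages: tuple[float, ...] = EVALUATION_AGES,
    grid_step: float = 0.25,
    h: float = 0.5,
    substep: float = 0.25,
    sex_params: dict | None = None,
) -> RecoveryReport:
    """Simulate with known rates, invert with the true MRR, compare.

    The simulation grid extends one year beyond the analysis window so the
    same central-difference stencil applies at the window endpoints as in
    the interior; the inversion uses the true mortality surface and the true
    MRR scenario.  Incidence errors are taken over the evaluation ages and
    the interior integer years of the window; APC errors compare the
    pipeline APC against the known generating APC at each evaluation age.
    """
    from .simulate import BENCHMARK_PARAMS

    params = dict(sex_params or BENCHMARK_PARAMS["male"])
    mrr = mrr or standard_scenarios(window[0])[0]
    model = RateModel.parametric(
        incidence_apc_percent=incidence_apc_percent, mrr=mrr,
        reference_year=window[0], **params,
    )
    grid = SimulationGrid.regular(
        window[0] - 1.0, window[1] + 1.0, grid_step,
        50.0, 99.0, grid_step, substep=substep,
    )
    p = simulate_prevalence(model, grid, sex="synthetic")
    T, A = np.meshgrid(grid.years, grid.ages, indexing="ij")
    from .surfaces import MortalitySurface

    m_surface = MortalitySurface(
        sex="synthetic", years=grid.years, ages=grid.ages,
        values=np.asarray(model.mortality(T, A), dtype=float),
    )

    interior_years = [y for y in np.arange(window[0] + 1, window[1], 1.0)]
    est = estimate_incidence_grid(p, m_surface, mrr, interior_years, ages, h)
    rel_errors: dict[float, list[float]] = {a: [] for a in ages}
    for e in est:
        truth = float(model.incidence(e.year, e.age))
        rel_errors[e.age].append(abs(e.incidence - truth) / truth)
    per_age_max = {a: max(v) for a, v in rel_errors.items()}
    all_errors = [x for v in rel_errors.values() for x in v]

    est_start = estimate_incidence_grid(p, m_surface, mrr, [window[0]], ages, h)
    est_end = estimate_incidence_grid(p, m_surface, mrr, [window[1]], ages, h)
    apc_errors = {}
    for e0, e1 in zip(est_start, est_end):
        apc = compute_apc(e0.incidence, e1.incidence, window[0], window[1])
        apc_errors[e0.age] = abs(apc - incidence_apc_percent)

    return RecoveryReport(
        max_rel_incidence_error=float(np.max(all_errors)),
        mean_rel_incidence_error=float(np.mean(all_errors)),
        per_age_max_rel_error=per_age_max,
        apc_true=incidence_apc_percent,
        apc_errors_pp=apc_errors,
    )
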