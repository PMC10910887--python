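"""Age-period surfaces: containers, validation, I/O and bilinear interpolation.

Prevalence and mortality enter the pipeline as rectangular Lexis surfaces:
a value per (calendar year, age) cell on a complete grid.  Calendar time and
age are treated as continuous coordinates (decimal years); published age
bands must be converted to midpoints by the data preparer before loading.

Files are long-format delimited text (UTF-8, comma-separated, ``.`` decimal
separator) with a ``year,age,value`` header, one file per (quantity, sex).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator


class SurfaceFormatError(ValueError):
    """Input file does not have the expected columns/layout."""


class SurfaceValidationError(ValueError):
    """Values or grid violate the surface invariants."""


class SurfaceDomainError(ValueError):
    """Query outside the surface hull plus the extrapolation margin."""


@dataclass(frozen=True)
class SurfaceQuery:
    """A single evaluation point (decimal calendar year, decimal age)."""

    year: float
    age: float


@dataclass
class Surface:
    """A gridded quantity on a complete (year, age) rectangle.

    Parameters
    ----------
    sex : str
        Population label, conventionally ``"male"`` or ``"female"``.
    years, ages : array-like
        Strictly increasing grid coordinates in (decimal) years.
    values : ndarray, shape (n_years, n_ages)
        One value per grid cell; ``values[j, k]`` belongs to
        ``(years[j], ages[k])``.
    kind : {"prevalence", "mortality"}
        Selects the range check: prevalence must lie in [0, 1],
        mortality rates must be >= 0.
    margin : float
        Extrapolation margin in years.  Queries up to ``margin`` outside the
        grid hull are answered by clamped (constant) extrapolation; anything
        farther raises :class:`SurfaceDomainError`.  The margin exists because
        the lifeline derivative needs ``p`` at ``(t +/- h, a +/- h)``, which
        can step just outside a biennial reporting grid.
    """

    sex: str
    years: np.ndarray
    ages: np.ndarray
    values: np.ndarray
    kind: Literal["prevalence", "mortality"] = "prevalence"
    margin: float = 1.0
    _interp: RegularGridInterpolator = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=float)
        self.ages = np.asarray(self.ages, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.ndim != 1 or self.ages.ndim != 1:
            raise SurfaceValidationError("years and ages must be 1-dimensional")
        if np.any(np.diff(self.years) <= 0):
            raise SurfaceValidationError("years must be strictly increasing")
        if np.any(np.diff(self.ages) <= 0):
            raise SurfaceValidationError("ages must be strictly increasing")
        if self.values.shape != (self.years.size, self.ages.size):
            raise SurfaceValidationError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.years.size} years x {self.ages.size} ages)"
            )
        if np.any(~np.isfinite(self.values)):
            j, k = np.argwhere(~np.isfinite(self.values))[0]
            raise SurfaceValidationError(
                f"non-finite value at (year={self.years[j]}, age={self.ages[k]})"
            )
        self._check_range()
        self._interp = RegularGridInterpolator(
            (self.years, self.ages),
            self.values,
            method="linear",
            bounds_error=False,
            fill_value=None,  # we clamp queries ourselves
        )

    def _check_range(self) -> None:
        if self.kind == "prevalence":
            bad = (self.values < 0.0) | (self.values > 1.0)
            what = "prevalence outside [0, 1]"
        elif self.kind == "mortality":
            bad = self.values < 0.0
            what = "negative mortality rate"
        else:
            raise SurfaceValidationError(f"unknown surface kind {self.kind!r}")
        if np.any(bad):
            j, k = np.argwhere(bad)[0]
            raise SurfaceValidationError(
                f"{what}: value {self.values[j, k]} at "
                f"(year={self.years[j]}, age={self.ages[k]})"
            )

    # -- queries ---------------------------------------------------------

    def __call__(self, year, age):
        """Bilinear interpolation at (year, age); vectorised over inputs.

        Exact at grid nodes; clamped constant extrapolation within
        ``margin``; :class:`SurfaceDomainError` beyond it.
        """
        year = np.asarray(year, dtype=float)
        age = np.asarray(age, dtype=float)
        if np.any(year < self.years[0] - self.margin) or np.any(
            year > self.years[-1] + self.margin
        ):
            raise SurfaceDomainError(
                f"year query outside [{self.years[0]}, {self.years[-1]}] "
                f"+/- margin {self.margin}"
            )
        if np.any(age < self.ages[0] - self.margin) or np.any(
            age > self.ages[-1] + self.margin
        ):
            raise SurfaceDomainError(
                f"age query outside [{self.ages[0]}, {self.ages[-1]}] "
                f"+/- margin {self.margin}"
            )
        yq = np.clip(year, self.years[0], self.years[-1])
        aq = np.clip(age, self.ages[0], self.ages[-1])
        pts = np.stack(np.broadcast_arrays(yq, aq), axis=-1)
        out = self._interp(pts)
        if year.ndim == 0 and age.ndim == 0:
            return float(out.reshape(()))
        return out

    def at(self, q: SurfaceQuery) -> float:
        return float(self(q.year, q.age))

    # -- serialisation ---------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        jj, kk = np.meshgrid(
            np.arange(self.years.size), np.arange(self.ages.size), indexing="ij"
        )
        return pd.DataFrame(
            {
                "year": self.years[jj.ravel()],
                "age": self.ages[kk.ravel()],
                "value": self.values[jj.ravel(), kk.ravel()],
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def PrevalenceSurface(sex, years, ages, values, margin: float = 1.0) -> Surface:
    """Construct a validated prevalence surface (values in [0, 1])."""
    return Surface(sex, years, ages, values, kind="prevalence", margin=margin)


def MortalitySurface(sex, years, ages, values, margin: float = 1.0) -> Surface:
    """Construct a validated general-mortality surface (rates >= 0)."""
    return Surface(sex, years, ages, values, kind="mortality", margin=margin)


def read_surface(
    path,
    kind: Literal["prevalence", "mortality"],
    sex: str,
    margin: float = 1.0,
) -> Surface:
    """Read a long-format ``year,age,value`` file into a validated surface.

    Raises
    ------
    SurfaceFormatError
        Missing columns or duplicated (year, age) rows.
    SurfaceValidationError
        Out-of-range values or an incomplete grid (missing cells are listed).
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"year", "age", "value"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise SurfaceFormatError(
            f"{path}: missing column(s) {sorted(missing_cols)}; "
            f"expected header year,age,value"
        )
    if df.duplicated(subset=["year", "age"]).any():
        dup = df[df.duplicated(subset=["year", "age"])].iloc[0]
        raise SurfaceFormatError(
            f"{path}: duplicate row for (year={dup['year']}, age={dup['age']})"
        )
    years = np.unique(df["year"].to_numpy(dtype=float))
    ages = np.unique(df["age"].to_numpy(dtype=float))
    if len(df) != years.size * ages.size:
        have = set(zip(df["year"].astype(float), df["age"].astype(float)))
        missing = [
            (y, a) for y in years for a in ages if (y, a) not in have
        ]
        raise SurfaceValidationError(
            f"{path}: incomplete grid, {len(missing)} missing cell(s), "
            f"first few: {missing[:5]}"
        )
    values = (
        df.pivot(index="year", columns="age", values="value")
        .reindex(index=years, columns=ages)
        .to_numpy(dtype=float)
    )
    return Surface(sex=sex, years=years, ages=ages, values=values, kind=kind, margin=margin)


def write_surface(surface: Surface, path) -> None:
    """Write a surface in the long-format layout read by :func:`read_surface`."""
    surface.write(path)


def interpolate(surface: Surface, q: SurfaceQuery) -> float:
    """Bilinear interpolation of a surface at a query point (module-level alias)."""
    return surface.at(q)


def smooth_ages(surface: Surface, window: int) -> Surface:
    """Optional pre-smoothing hook: centred moving average over the age axis.

    Off by default everywhere in the pipeline — smoothing changes the
    estimates and must be an explicit, logged choice.  ``window`` is the
    odd number of age points averaged; edges use the available points.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if window == 1:
        return surface
    kernel = np.ones(window) / window
    sm = np.empty_like(surface.values)
    half = window // 2
    padded = np.pad(surface.values, ((0, 0), (half, half)), mode="edge")
    for j in range(surface.values.shape[0]):
        sm[j] = np.convolve(padded[j], kernel, mode="valid")
    return Surface(sex=surface.sex, years=surface.years, ages=surface.ages,
                   values=sm, kind=surface.kind, margin=surface.margin)


# -- APC result tables ---------------------------------------------------

APC_COLUMNS = ["scenario", "sex", "age", "apc_percent"]


def write_apc_table(table, path, mode: Literal["machine", "report"] = "machine") -> None:
    """Write an APC table as ``scenario,sex,age,apc_percent`` delimited text.

    ``mode="machine"`` keeps full precision; ``mode="report"`` rounds the APC
    to one decimal place, the resolution at which such tables are published.
    """
    df = table.to_frame() if hasattr(table, "to_frame") else pd.DataFrame(table)
    if df.empty:
        raise ValueError("refusing to write an empty APC table")
    missing = set(APC_COLUMNS) - set(df.columns)
    if missing:
        raise SurfaceFormatError(f"APC table missing column(s) {sorted(missing)}")
    out = df[APC_COLUMNS].copy()
    if mode == "report":
        out["apc_percent"] = out["apc_percent"].map(lambda v: f"{float(v):.1f}")
        out.to_csv(path, index=False)
    else:
        out.to_csv(path, index=False, float_format="%.17g")


def read_apc_table(path):
    """Read an APC table written by :func:`write_apc_table` (machine mode)."""
    from .trends import APCTable

    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(APC_COLUMNS) - set(df.columns)
    if missing:
        raise SurfaceFormatError(f"{path}: APC table missing column(s) {sorted(missing)}")
    return APCTable(df)
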