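"""Panel data types for provincial healthcare-services efficiency analysis.

The unit of observation is a province-year.  Inputs are the (logged) number of
health technicians and hospital beds per 1,000 population; outputs are the
(logged) counts of outpatient/emergency visits, hospital discharges and
surgical procedures, aggregated into a single log output index by principal
component analysis so that a single-output production frontier can be
estimated.

The module also ships two small reference datasets:

* a 31-province x 11-year technical-efficiency panel (the published
  provincial HSE results, transcribed at 3 decimals), used as a fixture by
  the distribution-dynamics and spatial stages; and
* a queen-contiguity adjacency list for the 31 provinces with a
  Hainan-Guangdong bridge so the island province is not an isolate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import DegeneratePCAError, LogDomainError, PanelError, UnknownUnitError

__all__ = [
    "EASTERN",
    "CENTRAL",
    "WESTERN",
    "REGION_MAP",
    "ProvincePanel",
    "EfficiencyPanel",
    "assign_region",
    "build_output_index",
    "descriptive_stats",
    "load_efficiency_fixture",
    "load_china_adjacency",
    "read_panel",
    "write_panel",
]

# Fixed three-region partition of mainland China's 31 provincial units.
EASTERN = (
    "Beijing", "Tianjin", "Hebei", "Liaoning", "Shanghai", "Jiangsu",
    "Zhejiang", "Fujian", "Shandong", "Guangdong", "Hainan",
)
CENTRAL = (
    "Shanxi", "Jilin", "Heilongjiang", "Anhui", "Jiangxi", "Henan",
    "Hubei", "Hunan",
)
WESTERN = (
    "Inner Mongolia", "Chongqing", "Guangxi", "Sichuan", "Guizhou", "Yunnan",
    "Tibet", "Shaanxi", "Gansu", "Qinghai", "Ningxia", "Xinjiang",
)

REGION_MAP: dict[str, str] = {
    **{p: "eastern" for p in EASTERN},
    **{p: "central" for p in CENTRAL},
    **{p: "western" for p in WESTERN},
}

LOG_COLUMNS = (
    "ln_labor",
    "ln_capital",
    "ln_out_visits",
    "ln_out_discharge",
    "ln_out_surgery",
)


def assign_region(unit_id: str, region_map: dict[str, str] | None = None) -> str:
    """Return the region label ('eastern' / 'central' / 'western') for a unit."""
    rmap = REGION_MAP if region_map is None else region_map
    try:
        return rmap[unit_id]
    except KeyError:
        raise UnknownUnitError(f"unknown unit {unit_id!r}; not in region map") from None


def _check_balanced(df: pd.DataFrame) -> tuple[list, list]:
    units = sorted(df["unit_id"].unique())
    years = sorted(df["year"].unique())
    if len(df) != len(units) * len(years):
        have = set(zip(df["unit_id"], df["year"]))
        missing = [(u, int(y)) for u in units for y in years if (u, y) not in have]
        raise PanelError(f"unbalanced panel; missing unit-years: {missing[:10]}")
    if any(b - a != 1 for a, b in zip(years, years[1:])):
        raise PanelError(f"years are not consecutive: {years}")
    dup = df.duplicated(subset=["unit_id", "year"])
    if dup.any():
        raise PanelError("duplicate unit-year rows present")
    return units, years


@dataclass
class ProvincePanel:
    """Balanced unit x year panel of log inputs and log outputs.

    ``data`` columns: unit_id, region, year, ln_labor, ln_capital,
    ln_out_visits, ln_out_discharge, ln_out_surgery and (after
    :func:`build_output_index`) ln_output_index.
    """

    data: pd.DataFrame
    output_weights: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        df = self.data
        required = {"unit_id", "year", "ln_labor", "ln_capital"}
        missing = required - set(df.columns)
        if missing:
            raise PanelError(f"panel missing columns: {sorted(missing)}")
        _check_balanced(df)
        num = df.select_dtypes(include=[np.number])
        if not np.isfinite(num.to_numpy(dtype=float)).all():
            raise PanelError("panel contains non-finite values")
        self.data = df.sort_values(["unit_id", "year"], kind="stable").reset_index(drop=True)

    @property
    def units(self) -> list:
        return sorted(self.data["unit_id"].unique())

    @property
    def years(self) -> list:
        return sorted(self.data["year"].unique())

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def n_periods(self) -> int:
        return len(self.years)

    def wide(self, column: str) -> pd.DataFrame:
        """Pivot one column to a units x years matrix (rows sorted by unit)."""
        return self.data.pivot(index="unit_id", columns="year", values=column).sort_index()


@dataclass
class EfficiencyPanel:
    """Balanced unit x year panel of technical-efficiency scores in (0, 1]."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        required = {"unit_id", "year", "te"}
        if required - set(df.columns):
            raise PanelError(f"efficiency panel needs columns {sorted(required)}")
        _check_balanced(df)
        te = df["te"].to_numpy(dtype=float)
        if not np.isfinite(te).all() or (te <= 0).any() or (te > 1).any():
            raise PanelError("technical efficiency must lie in (0, 1]")
        self.data = df.sort_values(["unit_id", "year"], kind="stable").reset_index(drop=True)

    @property
    def units(self) -> list:
        return sorted(self.data["unit_id"].unique())

    @property
    def years(self) -> list:
        return sorted(self.data["year"].unique())

    def wide(self) -> pd.DataFrame:
        return self.data.pivot(index="unit_id", columns="year", values="te").sort_index()

    def lookup(self, unit_id, year) -> float:
        sel = self.data[(self.data["unit_id"] == unit_id) & (self.data["year"] == year)]
        if sel.empty:
            raise UnknownUnitError(f"no observation for ({unit_id!r}, {year})")
        return float(sel["te"].iloc[0])


def read_panel(path, schema: dict[str, str] | None = None,
               log_transform: bool = False,
               region_map: dict[str, str] | None = None) -> ProvincePanel:
    """Read a panel CSV, optionally applying log transforms and renaming columns.

    ``schema`` maps canonical column names (unit_id, year, ln_labor, ...) to
    the names used in the file.  With ``log_transform=True`` the input/output
    columns are taken as raw positive levels and logged; a non-positive cell
    raises :class:`LogDomainError` naming the offending unit-year and column.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if schema:
        rename = {v: k for k, v in schema.items()}
        df = df.rename(columns=rename)
    value_cols = [c for c in LOG_COLUMNS + ("ln_output_index",) if c in df.columns]
    if log_transform:
        for col in value_cols:
            vals = df[col].to_numpy(dtype=float)
            bad = np.nonzero(vals <= 0)[0]
            if bad.size:
                i = int(bad[0])
                raise LogDomainError(
                    f"column {col!r} has non-positive value {vals[i]} at "
                    f"unit {df['unit_id'].iloc[i]!r}, year {df['year'].iloc[i]}"
                )
            df[col] = np.log(vals)
    if "region" not in df.columns:
        rmap = REGION_MAP if region_map is None else region_map
        df["region"] = [rmap.get(u, "unknown") for u in df["unit_id"]]
    return ProvincePanel(df)


def write_panel(panel: ProvincePanel, path) -> None:
    """Write a panel to CSV at full precision (round-trips with read_panel).

    Floats use the shortest round-trip representation, so numeric fields
    survive a write/read cycle bit-for-bit.
    """
    panel.data.to_csv(path, index=False)


def build_output_index(ln_outputs, *, standardize: bool = False,
                       use_correlation: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate three log output columns into a single log output index.

    The weights are the loadings of the first principal component of the
    correlation matrix (default) of the log outputs, rescaled to sum to one,
    applied to the unstandardized log columns so the index stays on the same
    log scale as its components.  The sign of the component is fixed by
    forcing its largest-magnitude loading positive.

    Returns ``(index, weights)``.
    """
    X = np.asarray(ln_outputs, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("ln_outputs must be a 2-D matrix with >=2 columns")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 observations for PCA weights")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise DegeneratePCAError("constant output column; PCA weights undefined")
    C = np.corrcoef(X, rowvar=False) if use_correlation else np.cov(X, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(C)
    pc1 = eigvecs[:, -1]
    pc1 = pc1 * np.sign(pc1[np.argmax(np.abs(pc1))])
    weights = pc1 / pc1.sum()
    cols = (X - X.mean(axis=0)) / sd if standardize else X
    return cols @ weights, weights


def descriptive_stats(panel: ProvincePanel, by_year: bool = False,
                      columns: list[str] | None = None) -> pd.DataFrame:
    """Summary table (mean, median, SD, min, max) per variable.

    SD uses the sample (n-1) convention; a single observation reports SD 0
    together with a ``degenerate`` flag column.
    """
    if columns is None:
        columns = [c for c in LOG_COLUMNS + ("ln_output_index",) if c in panel.data.columns]
    if not columns:
        raise PanelError("no numeric variables to summarise")

    def _summ(g: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for col in columns:
            v = g[col].to_numpy(dtype=float)
            rows.append({
                "variable": col,
                "mean": v.mean(),
                "median": float(np.median(v)),
                "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
                "min": v.min(),
                "max": v.max(),
                "n": v.size,
                "degenerate": v.size < 2,
            })
        return pd.DataFrame(rows)

    if by_year:
        parts = []
        for year, g in panel.data.groupby("year"):
            t = _summ(g)
            t.insert(0, "year", year)
            parts.append(t)
        return pd.concat(parts, ignore_index=True)
    return _summ(panel.data)


def load_efficiency_fixture() -> EfficiencyPanel:
    """Load the embedded 31-province x 11-year (2010-2020) efficiency panel."""
    with resources.files("hsekit.data").joinpath("china_hse_2010_2020.csv").open() as f:
        df = pd.read_csv(f)
    return EfficiencyPanel(df)


def load_china_adjacency() -> list[tuple[str, str]]:
    """Queen-contiguity neighbour pairs for the 31 provinces (with a
    Hainan-Guangdong bridge)."""
    with resources.files("hsekit.data").joinpath("china_adjacency.csv").open() as f:
        df = pd.read_csv(f)
    return list(df.itertuples(index=False, name=None))
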