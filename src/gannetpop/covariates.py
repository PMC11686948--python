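"""Colony-specific climate covariates from gridded monthly fields.

Monthly gridded covariates (SST, sea-surface salinity, near-surface air
temperature, near-surface wind speed, precipitation) are reduced to one
value per colony and year by (1) averaging the February–September
breeding-season months, (2) weighting grid cells by the colony's at-sea
density surface, and (3) pooled z-scoring over the model-fitting window
so the regression coefficients shared across colonies act on one common
scale.

Density surfaces stand in for mechanistic colony home-range models: an
exponential distance kernel over sea cells whose range grows with the
square root of colony size, with overlapping colonies splitting each
cell in proportion to their kernel values (a competitive-exclusion
proxy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import COVARIATES

EPOCHS: tuple[int, ...] = (1900, 1920, 1940, 1960, 1980, 2000, 2016)
SEASON_MONTHS: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8, 9)  # Feb-Sep attendance
SCENARIOS: tuple[str, ...] = ("hindcast", "SSP1", "SSP5")

#: kernel range (km) per sqrt(AOS); lambda = KERNEL_KM_PER_SQRT_AOS * sqrt(size)
KERNEL_KM_PER_SQRT_AOS = 1.0
_KM_PER_DEG = 111.32


class ClimateSeries:
    """Per-colony, per-year covariate values for hindcast and scenarios.

    Stored as a long DataFrame with columns (scenario, colony, year,
    covariate, value) plus the z-scoring constants when standardized.
    """

    def __init__(self, table: pd.DataFrame, constants: dict | None = None):
        required = {"scenario", "colony", "year", "covariate", "value"}
        if not required <= set(table.columns):
            raise ValueError(f"climate table must have columns {sorted(required)}")
        self.table = table.reset_index(drop=True)
        self.constants = constants  # covariate -> (mean, sd), None if raw

    @property
    def standardized(self) -> bool:
        return self.constants is not None

    def colonies(self) -> list:
        return sorted(self.table["colony"].unique())

    def years(self, scenario: str) -> np.ndarray:
        return np.sort(self.table.loc[self.table.scenario == scenario, "year"].unique())

    def to_array(self, scenario: str, colonies, years) -> np.ndarray:
        """Dense (n_years, n_colonies, 5) array in canonical covariate order."""
        sub = self.table[self.table.scenario == scenario]
        piv = sub.pivot_table(index=["year", "colony"], columns="covariate",
                              values="value")
        out = np.empty((len(years), len(colonies), len(COVARIATES)))
        for iy, y in enumerate(years):
            for ic, c in enumerate(colonies):
                try:
                    row = piv.loc[(y, c)]
                except KeyError:
                    raise ValueError(f"missing climate for colony {c!r}, year {y}, "
                                     f"scenario {scenario!r}") from None
                for k, cov in enumerate(COVARIATES):
                    out[iy, ic, k] = row[cov]
        if not np.all(np.isfinite(out)):
            raise ValueError("non-finite covariate values")
        return out

    def row(self, scenario: str, colonies, year: int) -> dict:
        """Covariate-name -> per-colony array for one year (demography input)."""
        arr = self.to_array(scenario, colonies, [year])[0]
        return {cov: arr[:, k] for k, cov in enumerate(COVARIATES)}


@dataclass
class DensitySurface:
    """At-sea density weights of one colony over a regular grid."""

    colony: str
    epoch: int
    cell_id: np.ndarray
    lon: np.ndarray
    lat: np.ndarray
    w: np.ndarray

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        if np.any(self.w < 0):
            raise ValueError("weights must be non-negative")
        if not np.any(self.w > 0):
            raise ValueError("surface has no positive weight")
        if self.epoch not in EPOCHS:
            raise ValueError(f"epoch {self.epoch} not in {EPOCHS}")

    def normalized(self) -> np.ndarray:
        return self.w / self.w.sum()


class ClimateGrid:
    """Monthly gridded covariate fields over a flat cell list.

    ``values[cov]`` has shape (n_years, 12, n_cells); cell centroid
    coordinates in decimal degrees.
    """

    def __init__(self, years, cell_id, lon, lat, values: dict):
        self.years = np.asarray(years, dtype=int)
        self.cell_id = np.asarray(cell_id)
        self.lon = np.asarray(lon, dtype=float)
        self.lat = np.asarray(lat, dtype=float)
        self.values = values
        for cov, arr in values.items():
            if arr.shape != (len(self.years), 12, len(self.cell_id)):
                raise ValueError(f"{cov}: expected shape "
                                 f"{(len(self.years), 12, len(self.cell_id))}, "
                                 f"got {arr.shape}")

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "ClimateGrid":
        """Build from long CSV records (cell_id, lon, lat, year, month, covariate, value)."""
        required = {"cell_id", "lon", "lat", "year", "month", "covariate", "value"}
        if not required <= set(df.columns):
            raise ValueError(f"long climate table needs columns {sorted(required)}")
        cells = df[["cell_id", "lon", "lat"]].drop_duplicates().sort_values("cell_id")
        years = np.sort(df["year"].unique())
        cell_pos = {c: i for i, c in enumerate(cells.cell_id)}
        year_pos = {y: i for i, y in enumerate(years)}
        values = {}
        for cov, g in df.groupby("covariate"):
            arr = np.full((len(years), 12, len(cells)), np.nan)
            arr[g.year.map(year_pos), g.month - 1, g.cell_id.map(cell_pos)] = g.value
            values[cov] = arr
        return cls(years, cells.cell_id.to_numpy(), cells.lon.to_numpy(),
                   cells.lat.to_numpy(), values)

    @classmethod
    def from_netcdf(cls, path) -> "ClimateGrid":
        """Read a CF-style (lon, lat, time) NetCDF file, one variable per covariate."""
        import xarray as xr

        ds = xr.open_dataset(path)
        t = pd.DatetimeIndex(ds["time"].values)
        stacked = ds.stack(cell=("lat", "lon"))
        lon = stacked["lon"].values
        lat = stacked["lat"].values
        years = np.sort(np.unique(t.year))
        year_pos = {y: i for i, y in enumerate(years)}
        values = {}
        for cov in ds.data_vars:
            raw = stacked[cov].values  # (time, cell)
            arr = np.full((len(years), 12, lon.size), np.nan)
            for k, ts in enumerate(t):
                arr[year_pos[ts.year], ts.month - 1, :] = raw[k]
            values[str(cov)] = arr
        return cls(years, np.arange(lon.size), lon, lat, values)


def _distance_km(lon0, lat0, lon, lat):
    """Equirectangular small-area distance (km)."""
    dx = (np.asarray(lon) - lon0) * _KM_PER_DEG * np.cos(np.deg2rad(lat0))
    dy = (np.asarray(lat) - lat0) * _KM_PER_DEG
    return np.hypot(dx, dy)


def make_surface(colony: str, lon: float, lat: float, size: float, epoch: int,
                 cell_id, cell_lon, cell_lat, sea_mask,
                 neighbours=(), kernel_km_per_sqrt_aos: float = KERNEL_KM_PER_SQRT_AOS,
                 ) -> DensitySurface:
    """Exponential-kernel density surface for one colony.

    ``w ~ exp(-d / lambda)`` over sea cells with ``lambda`` proportional
    to sqrt(colony size), so larger colonies range further.  Cells also
    used by ``neighbours`` (tuples ``(lon, lat, size)``) are split in
    proportion to each colony's kernel value.  Weights sum to 1.
    """
    if size <= 0:
        raise ValueError("colony size must be positive")
    sea = np.asarray(sea_mask, dtype=bool)
    lam = kernel_km_per_sqrt_aos * np.sqrt(size)
    k_own = np.exp(-_distance_km(lon, lat, cell_lon, cell_lat) / lam) * sea
    total = k_own.copy()
    for nb_lon, nb_lat, nb_size in neighbours:
        lam_nb = kernel_km_per_sqrt_aos * np.sqrt(nb_size)
        total = total + np.exp(-_distance_km(nb_lon, nb_lat, cell_lon, cell_lat) / lam_nb) * sea
    share = np.divide(k_own, total, out=np.zeros_like(k_own), where=total > 0)
    w = k_own * share
    if w.sum() <= 0:
        raise ValueError(f"colony {colony!r} is landlocked on this grid")
    return DensitySurface(colony, epoch, np.asarray(cell_id), np.asarray(cell_lon),
                          np.asarray(cell_lat), w / w.sum())


def extract_covariate(surface: DensitySurface, grid: ClimateGrid, covariate: str,
                      year: int, months=SEASON_MONTHS) -> float:
    """Density-weighted breeding-season mean of one covariate for one year."""
    if surface.cell_id.shape != grid.cell_id.shape or np.any(surface.cell_id != grid.cell_id):
        raise ValueError("surface and climate grid are on different cells")
    iy = np.flatnonzero(grid.years == year)
    if iy.size == 0:
        raise ValueError(f"year {year} not in climate grid")
    midx = np.asarray(months) - 1
    season = np.nanmean(grid.values[covariate][iy[0], midx, :], axis=0)
    return float(np.sum(surface.normalized() * season))


def epoch_for_year(year: int) -> int:
    """Which 20-year density-surface epoch a calendar year falls in."""
    eligible = [e for e in EPOCHS if e <= year]
    if not eligible:
        raise ValueError(f"year {year} predates the first epoch {EPOCHS[0]}")
    return max(eligible)


def assemble_series(surfaces: dict, grids: dict, colonies, fit_years,
                    forecast_years=(), covariates=COVARIATES) -> ClimateSeries:
    """Assemble the full per-colony annual covariate table.

    ``surfaces`` maps (colony, epoch) -> DensitySurface, ``grids`` maps
    scenario -> ClimateGrid.  Fitting years up to 2014 use the hindcast
    grid; 2015–2016 use the mean of the two scenarios (hindcast fields
    end in 2014); forecast years use each scenario's grid with the last
    (2016) surface.
    """
    records = []

    def surf(colony, epoch):
        try:
            return surfaces[(colony, epoch)]
        except KeyError:
            raise ValueError(f"no density surface for colony {colony!r}, epoch {epoch}") from None

    for colony in colonies:
        for year in fit_years:
            s = surf(colony, epoch_for_year(year))
            for cov in covariates:
                if year <= 2014:
                    val = extract_covariate(s, grids["hindcast"], cov, year)
                else:
                    val = 0.5 * (extract_covariate(s, grids["SSP1"], cov, year)
                                 + extract_covariate(s, grids["SSP5"], cov, year))
                records.append(("hindcast", colony, year, cov, val))
        for year in forecast_years:
            s = surf(colony, EPOCHS[-1])
            for scen in ("SSP1", "SSP5"):
                for cov in covariates:
                    val = extract_covariate(s, grids[scen], cov, year)
                    records.append((scen, colony, year, cov, val))
    return ClimateSeries(pd.DataFrame(records, columns=["scenario", "colony", "year",
                                                        "covariate", "value"]))


def standardize(series: ClimateSeries, window=(1900, 2016)) -> ClimateSeries:
    """Z-score all covariates with constants pooled over the fitting window.

    The same constants are applied to every scenario and year, so
    forecast z-scores may legitimately leave the fitting range.
    """
    if series.standardized:
        raise ValueError("series is already standardized")
    tab = series.table.copy()
    fit = tab[(tab.scenario == "hindcast")
              & tab.year.between(window[0], window[1])]
    if fit.empty:
        raise ValueError("no hindcast rows in the standardization window")
    constants = {}
    for cov, g in fit.groupby("covariate"):
        mu, sd = g.value.mean(), g.value.std(ddof=0)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"covariate {cov!r} has zero variance in the window")
        constants[cov] = (float(mu), float(sd))
    for cov, (mu, sd) in constants.items():
        sel = tab.covariate == cov
        tab.loc[sel, "value"] = (tab.loc[sel, "value"] - mu) / sd
    return ClimateSeries(tab, constants)


def unstandardize(series: ClimateSeries) -> ClimateSeries:
    """Invert :func:`standardize` using the stored constants."""
    if not series.standardized:
        raise ValueError("series is not standardized")
    tab = series.table.copy()
    for cov, (mu, sd) in series.constants.items():
        sel = tab.covariate == cov
        tab.loc[sel, "value"] = tab.loc[sel, "value"] * sd + mu
    return ClimateSeries(tab, None)


def surfaces_to_frame(surfaces: dict) -> pd.DataFrame:
    """Serialize surfaces as tidy (colony, epoch, cell_id, weight) rows."""
    rows = []
    for (colony, epoch), s in surfaces.items():
        for cid, w in zip(s.cell_id, s.w):
            rows.append((colony, epoch, cid, w))
    return pd.DataFrame(rows, columns=["colony", "epoch", "cell_id", "weight"])
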