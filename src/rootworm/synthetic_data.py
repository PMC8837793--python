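"""Synthetic trap networks, weather, latent parameters, counts and blanks.

The generator reproduces the statistical structure the hierarchical model
assumes — a monitoring network of pheromone traps read weekly for 19
weeks (early June to early October), weekly Poisson counts whose
intensity follows the Gompertz-derivative curve in cumulative growing
degree days, trap-year Gompertz parameters drawn from log-normal
hierarchies with covariate-driven means, and raw sheets in which blanks
and zeroes are interchangeable — so that every downstream stage can be
exercised and scored against retained ground truth without any real data.

Weather is a deterministic annual sinusoid plus Gaussian noise with
station and year offsets: the simplest process that yields realistic
degree-day accumulation and between-station/between-year covariate
variation.  No attempt is made to match real geography or climate
normals.  Default true coefficients follow the posterior means of the
fitted Austrian analysis, standing in for the unknown truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
import yaml

from . import phenology
from .model import ModelSpec, build_design
from .recode import N_WEEKS, TrapSeries

__all__ = [
    "TrueCoefficients",
    "WeatherConfig",
    "MissingnessConfig",
    "SyntheticConfig",
    "SyntheticDataset",
    "gen_trap_network",
    "gen_station_network",
    "gen_weather",
    "gen_params",
    "gen_counts",
    "inject_missingness",
    "week_dates",
    "simulate_dataset",
    "to_model_data",
    "load_config",
]


@dataclass(frozen=True)
class TrueCoefficients:
    """Generative constants of the hierarchy (log-scale regressions)."""

    a0: float = 2.03
    w: dict = field(
        default_factory=lambda: {
            "winter_temp": 0.143,
            "winter_precip": -3.72e-6,
            "year_index": 0.106,
            "maize": 0.00014,
            "x": 0.069,
            "y": 0.175,
            "xy": -0.082,
            "x2": 0.058,
            "y2": -0.097,
        }
    )
    # intercepts anchored so the median inflection falls mid-season under
    # this package's z convention (z = cumulative GDD / mean season-end GDD,
    # so the 19 readings span roughly z in [0.17, 1]): median gamma ~ 9 and
    # beta = exp(4.5) put peak emergence near week 8 with near-zero counts
    # in the first and last weeks, as observed monitoring data show
    b0: float = 4.5
    g0: float = 1.55
    u: dict = field(default_factory=lambda: {"spring_temp": 0.0454})
    tau_alpha: float = 0.149
    tau_beta: float = 0.672
    tau_gamma: float = 2.890

    def __post_init__(self) -> None:
        if min(self.tau_alpha, self.tau_beta, self.tau_gamma) <= 0:
            raise ValueError("precisions must be strictly positive")


@dataclass(frozen=True)
class WeatherConfig:
    """Annual sinusoid plus noise; °C and mm, coldest day mid-January."""

    mean_temp: float = 9.5
    amplitude: float = 10.5
    coldest_doy: float = 15.0
    diurnal_range: float = 8.0
    diurnal_sd: float = 2.0
    noise_sd: float = 3.0
    station_offset_sd: float = 1.0
    year_offset_sd: float = 1.0
    wet_prob: float = 0.45
    wet_mean_mm: float = 5.0


@dataclass(frozen=True)
class MissingnessConfig:
    """Blank-injection probabilities for the raw sheets."""

    blank_given_zero: float = 0.5  # a true zero written as an empty cell
    blank_given_positive: float = 0.05  # a genuinely lost positive record

    def __post_init__(self) -> None:
        for p in (self.blank_given_zero, self.blank_given_positive):
            if not 0.0 <= p <= 1.0:
                raise ValueError("missingness probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticConfig:
    n_traps: int = 100
    years: tuple = (2004, 2005, 2006)
    region_extent: tuple = (0.0, 200.0, 0.0, 200.0)  # xmin, xmax, ymin, ymax in km
    n_stations: int = 6
    true_coefficients: TrueCoefficients = field(default_factory=TrueCoefficients)
    weather: WeatherConfig = field(default_factory=WeatherConfig)
    missingness: MissingnessConfig = field(default_factory=MissingnessConfig)
    maize_beta: tuple = (2.0, 5.0)  # Beta shape for maize share / 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_traps < 1 or self.n_stations < 1:
            raise ValueError("n_traps and n_stations must be >= 1")
        xmin, xmax, ymin, ymax = self.region_extent
        if xmax < xmin or ymax < ymin:
            raise ValueError("region_extent must be an (xmin, xmax, ymin, ymax) rectangle")
        if not self.years:
            raise ValueError("at least one study year required")


def _from_mapping(cls, data):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in fields:
            raise ValueError(f"unknown {cls.__name__} field {key!r}")
        ftype = fields[key].type
        if key in ("true_coefficients", "weather", "missingness") and isinstance(value, dict):
            sub = {"true_coefficients": TrueCoefficients, "weather": WeatherConfig,
                   "missingness": MissingnessConfig}[key]
            value = _from_mapping(sub, value)
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path) -> SyntheticConfig:
    """Read a SyntheticConfig from YAML (or JSON, a YAML subset)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _from_mapping(SyntheticConfig, raw or {})


def week_dates(year: int) -> list[date]:
    """The 19 weekly reading dates: 1 June plus 0..18 weeks (last: early October)."""
    start = date(year, 6, 1)
    return [start + timedelta(weeks=k) for k in range(N_WEEKS)]


def gen_trap_network(config: SyntheticConfig, rng=None) -> pd.DataFrame:
    """Trap locations uniform over the region with bounded maize shares.

    Columns: trap_id, x_raw, y_raw (km), x, y (mean-centred km), maize (%).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    xmin, xmax, ymin, ymax = config.region_extent
    x = rng.uniform(xmin, xmax, config.n_traps)
    y = rng.uniform(ymin, ymax, config.n_traps)
    maize = 100.0 * rng.beta(*config.maize_beta, config.n_traps)
    return pd.DataFrame(
        {
            "trap_id": [f"T{i:04d}" for i in range(config.n_traps)],
            "x_raw": x,
            "y_raw": y,
            "x": x - x.mean(),
            "y": y - y.mean(),
            "maize": maize,
        }
    )


def gen_station_network(config: SyntheticConfig, rng=None) -> pd.DataFrame:
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    xmin, xmax, ymin, ymax = config.region_extent
    return pd.DataFrame(
        {
            "station_id": [f"S{i:02d}" for i in range(config.n_stations)],
            "x": rng.uniform(xmin, xmax, config.n_stations),
            "y": rng.uniform(ymin, ymax, config.n_stations),
        }
    )


def gen_weather(config: SyntheticConfig, stations: pd.DataFrame, rng=None) -> pd.DataFrame:
    """Daily weather per station per study year, 1 Jan-31 Oct.

    Daily mean temperature = annual sinusoid + station offset + year offset
    + N(0, noise_sd); tmin/tmax are the mean -/+ half a (non-negative)
    diurnal range, so tmin <= tmax holds by construction.  Precipitation is
    a wet-day Bernoulli times an exponential amount.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    w = config.weather
    st_offsets = rng.normal(0.0, w.station_offset_sd, len(stations))
    yr_offsets = rng.normal(0.0, w.year_offset_sd, len(config.years))
    frames = []
    for si, station_id in enumerate(stations["station_id"]):
        for yi, year in enumerate(config.years):
            dates = pd.date_range(date(year, 1, 1), date(year, 10, 31), freq="D")
            doy = dates.dayofyear.to_numpy(dtype=float)
            tmean = (
                w.mean_temp
                - w.amplitude * np.cos(2 * np.pi * (doy - w.coldest_doy) / 365.25)
                + st_offsets[si]
                + yr_offsets[yi]
                + rng.normal(0.0, w.noise_sd, len(dates))
            )
            half_range = np.abs(rng.normal(w.diurnal_range, w.diurnal_sd, len(dates))) / 2.0
            precip = rng.exponential(w.wet_mean_mm, len(dates)) * (
                rng.random(len(dates)) < w.wet_prob
            )
            frames.append(
                pd.DataFrame(
                    {
                        "station_id": station_id,
                        "date": dates,
                        "tmin": tmean - half_range,
                        "tmax": tmean + half_range,
                        "precip": precip,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def gen_params(
    config: SyntheticConfig, covariates: pd.DataFrame, rng=None, spec: ModelSpec | None = None
) -> pd.DataFrame:
    """Latent Gompertz parameters per trap-year from the log-scale hierarchy.

    Means follow the covariate regressions; spreads are the configured
    precisions.  Returns one row per trap-year with the log draws and the
    exponentiated (strictly positive) alpha, beta, gamma.
    """
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    spec = spec or ModelSpec()
    coef = config.true_coefficients
    X_alpha, X_gamma, alpha_names, gamma_names = build_design(covariates, spec)
    wa = np.array([coef.a0] + [coef.w[name] for name in alpha_names[1:]])
    wg = np.array([coef.g0] + [coef.u[name] for name in gamma_names[1:]])
    n = len(covariates)
    la = X_alpha @ wa + rng.normal(0.0, coef.tau_alpha**-0.5, n)
    lb = coef.b0 + rng.normal(0.0, coef.tau_beta**-0.5, n)
    lg = X_gamma @ wg + rng.normal(0.0, coef.tau_gamma**-0.5, n)
    out = covariates[["trap_id", "year"]].copy()
    out["log_alpha"], out["log_beta"], out["log_gamma"] = la, lb, lg
    out["alpha"], out["beta"], out["gamma"] = np.exp(la), np.exp(lb), np.exp(lg)
    return out


def gen_counts(params: pd.DataFrame, z_matrix: np.ndarray, rng=None, seed: int = 0) -> np.ndarray:
    """Weekly Poisson counts with intensity exp(log f'(z)) per trap-year.

    ``z_matrix`` holds the scaled cumulative GDD at the 19 reading dates,
    row-aligned with ``params``; rows must be non-negative and non-decreasing.
    """
    from .gompertz import GompertzParams, log_intensity

    rng = np.random.default_rng(seed) if rng is None else rng
    z = np.asarray(z_matrix, dtype=float)
    if z.shape != (len(params), N_WEEKS):
        raise ValueError(f"z_matrix must be ({len(params)}, {N_WEEKS})")
    if np.any(z < 0) or np.any(np.diff(z, axis=1) < -1e-9):
        raise ValueError("z rows must be non-negative and non-decreasing")
    gp = GompertzParams(
        params["alpha"].to_numpy()[:, None],
        params["beta"].to_numpy()[:, None],
        params["gamma"].to_numpy()[:, None],
    )
    mu = np.exp(log_intensity(z, gp))
    return rng.poisson(mu).astype(np.int64)


def inject_missingness(
    counts: np.ndarray, config: SyntheticConfig, rng=None
) -> np.ndarray:
    """Render a raw sheet from true counts: some cells become blanks.

    True zeroes are written as empty cells with probability
    ``blank_given_zero`` (blank/zero interchangeability); positive counts
    are lost with probability ``blank_given_positive``.  Returns an object
    array with None for blanks; the input is the retained ground truth.
    """
    rng = np.random.default_rng(config.seed + 4) if rng is None else rng
    counts = np.asarray(counts)
    m = config.missingness
    u = rng.random(counts.shape)
    blank = np.where(counts == 0, u < m.blank_given_zero, u < m.blank_given_positive)
    raw = counts.astype(object)
    raw[blank] = None
    return raw


@dataclass
class SyntheticDataset:
    """Everything one simulated study produces, ground truth included."""

    config: SyntheticConfig
    traps: pd.DataFrame
    stations: pd.DataFrame
    weather: pd.DataFrame
    covariates: pd.DataFrame  # one row per trap-year, incl. x, y, maize
    z_raw: np.ndarray  # (n_ty, 19) raw cumulative GDD at reading dates
    z_scale: float
    params: pd.DataFrame  # true latent Gompertz parameters
    counts: np.ndarray  # (n_ty, 19) true counts
    raw: np.ndarray  # (n_ty, 19) object; None = blank

    @property
    def index(self) -> pd.DataFrame:
        return self.covariates[["trap_id", "year"]]

    def raw_series(self) -> list[TrapSeries]:
        out = []
        for row, (_, ix) in zip(self.raw, self.index.iterrows()):
            records = tuple(None if v is None else int(v) for v in row)
            out.append(TrapSeries(ix["trap_id"], int(ix["year"]), records))
        return out

    def counts_frame(self, which: str = "raw") -> pd.DataFrame:
        """Long-format counts table; 'raw' renders blanks as empty strings."""
        matrix = self.raw if which == "raw" else self.counts
        rows = []
        for r, (_, ix) in zip(matrix, self.index.iterrows()):
            for wk, v in enumerate(r, start=1):
                value = "" if v is None else int(v)
                rows.append(
                    {"trap_id": ix["trap_id"], "year": int(ix["year"]), "week": wk, "count": value}
                )
        return pd.DataFrame(rows)

    def z_frame(self) -> pd.DataFrame:
        rows = []
        for r, (_, ix) in zip(self.z_raw, self.index.iterrows()):
            for wk, v in enumerate(r, start=1):
                rows.append(
                    {"trap_id": ix["trap_id"], "year": int(ix["year"]), "week": wk, "z": float(v)}
                )
        return pd.DataFrame(rows)


def to_model_data(
    ds: SyntheticDataset,
    spec: ModelSpec | None = None,
    apply_retention_filter: bool = True,
):
    """Recode the raw sheets and assemble fit-ready model arrays.

    With ``apply_retention_filter`` (the monitoring-data convention) traps
    with no positive count are dropped, which truncates the latent
    hierarchy and slightly biases covariate slopes on the growth rate —
    the selection effect a hurdle extension would absorb.  Recovery
    experiments that probe the estimation machinery itself should pass
    ``False``: all-zero trap-years are then kept, their blanks coded zero
    (rule 1 applies for the whole season when no positive entry exists).
    """
    from .model import prepare_model_data
    from .recode import BLANK, N_WEEKS, RecodedSeries, recode_series, recoded_to_frame, retain_trap

    recoded = []
    for s in ds.raw_series():
        if retain_trap(s):
            recoded.append(recode_series(s))
        elif not apply_retention_filter:
            records = tuple(0 if v is BLANK else int(v) for v in s.records)
            recoded.append(
                RecodedSeries(s.trap_id, s.year, records, ("rule1_zero",) * N_WEEKS)
            )
    return prepare_model_data(
        recoded_to_frame(recoded), ds.covariates, ds.z_frame(), spec or ModelSpec()
    )


def simulate_dataset(config: SyntheticConfig, spec: ModelSpec | None = None) -> SyntheticDataset:
    """Full generative pass: network, weather, covariates, z, params, counts, blanks.

    A single seed in ``config`` drives every stage through independent
    substreams, so the whole dataset is a pure function of the config.
    """
    spec = spec or ModelSpec()
    rng = np.random.default_rng(config.seed)
    streams = rng.spawn(6)
    traps = gen_trap_network(config, streams[0])
    stations = gen_station_network(config, streams[1])
    weather = gen_weather(config, stations, streams[2])

    station_of = phenology.nearest_station(
        traps[["x_raw", "y_raw"]].to_numpy(),
        stations[["x", "y"]].to_numpy(),
        stations["station_id"],
    )
    first_year = min(config.years)

    # seasonal stats and weekly z depend only on (station, year): compute once
    per_station_year: dict = {}
    for sid, series in weather.groupby("station_id"):
        years_col = pd.to_datetime(series["date"]).dt.year
        for year in config.years:
            series_y = series[years_col == year]
            sc = phenology.season_covariates(series_y, year, sid, 0.0, first_year)
            gdd = phenology.cumulative_gdd(series_y)
            z = phenology.weekly_z(gdd, week_dates(year))
            per_station_year[(sid, year)] = (sc, z)

    cov_rows = []
    z_rows = []
    for trap_idx, trap in traps.iterrows():
        sid = station_of[trap_idx]
        for year in config.years:
            sc, z = per_station_year[(sid, year)]
            cov_rows.append(
                {
                    "trap_id": trap["trap_id"],
                    "year": year,
                    "winter_temp": sc.winter_temp,
                    "spring_temp": sc.spring_temp,
                    "winter_precip": sc.winter_precip,
                    "maize": trap["maize"],
                    "year_index": sc.year_index,
                    "x": trap["x_raw"],
                    "y": trap["y_raw"],
                }
            )
            z_rows.append(z)
    covariates = pd.DataFrame(cov_rows)
    z_raw = np.vstack(z_rows)
    z_scale = spec.z_scale if spec.z_scale is not None else 1.0 / float(z_raw[:, -1].mean())

    params = gen_params(config, covariates, streams[3], spec)
    counts = gen_counts(params, z_raw * z_scale, streams[4])
    raw = inject_missingness(counts, config, streams[5])
    return SyntheticDataset(
        config=config,
        traps=traps,
        stations=stations,
        weather=weather,
        covariates=covariates,
        z_raw=z_raw,
        z_scale=z_scale,
        params=params,
        counts=counts,
        raw=raw,
    )
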