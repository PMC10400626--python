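"""Synthetic monthly migration-flow scenarios with known ground truth.

Real monthly series of sea arrivals, pushbacks and migrant deaths (and the
wide panels of economic, weather and conflict covariates used to predict
them) are compiled from proprietary sources and cannot be redistributed.
This module generates stand-in data with the same statistical structure —
a count target driven by a local linear trend, a 12-month seasonal pattern,
a sparse subset of a wide covariate panel, and multiplicative intervention
effects at known dates — so the whole counterfactual pipeline can be
exercised and validated against a known truth.

The generator returns the truth (latent states, active covariates, effect
paths) in a separate :class:`GroundTruth` record that is never written into
the data files, so downstream code cannot accidentally condition on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, GenerationError, ValidationError

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "generate_covariates",
    "generate_flow",
    "generate_scenario",
    "apply_underreporting",
    "write_scenario",
]

#: covariate families cycled through when building a panel
_FAMILIES = ("econ", "weather", "shock")


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic scenario.

    All standard deviations are on the natural-log scale of the monthly
    count of crossing attempts.  ``interventions`` is a list of
    ``(month_index, multiplicative_effect)`` pairs: from ``month_index``
    onward the expected count is multiplied by ``multiplicative_effect``
    (1.0 = no effect, 1.5 = 50% increase, 0.6 = suppression).

    Parameters
    ----------
    n_months : int
        Length of the observation window (default 120 = ten years).
    start_month : str
        First calendar month, ISO format ``YYYY-MM``.
    n_covariates : int
        Number of candidate covariate columns.
    n_active : int
        Number of covariates that truly drive the target.
    beta_active : tuple of float
        Log-scale effect sizes of the active covariates (per standard
        deviation of the covariate); recycled to length ``n_active``.
    base_level : float
        Log-scale intercept of the latent intensity; the default
        ``log(1000)`` puts monthly totals near 1,000 crossings.
    death_share, pushback_share : float
        Expected fractions of the total allocated to deaths and pushbacks;
        deaths default to 4% of the total, matching the observed share of
        recorded deaths in Central-Mediterranean crossing counts.
    underreport_rate : float
        Probability that a recorded death is deleted (0 disables; 0.10
        emulates the estimated share of deaths missing from the registries).
    count_noise : {"poisson", "negbin", "none"}
        Marginal count distribution around ``exp(lambda_t)``; ``negbin``
        uses ``nb_dispersion`` (Poisson is the large-dispersion limit),
        ``none`` returns the rounded mean (useful for exact fixtures).
    """

    n_months: int = 120
    start_month: str = "2011-01"
    n_covariates: int = 30
    n_active: int = 3
    beta_active: tuple[float, ...] = (0.30, -0.25, 0.20)
    base_level: float = float(np.log(1000.0))
    trend_level_sd: float = 0.01
    trend_slope_sd: float = 0.001
    seasonal_sd: float = 0.15
    obs_sd: float = 0.05
    season_period: int = 12
    interventions: tuple[tuple[int, float], ...] = ()
    death_share: float = 0.04
    pushback_share: float = 0.06
    underreport_rate: float = 0.0
    count_noise: str = "poisson"
    nb_dispersion: float = 20.0
    ar_coef: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.n_months < 1:
            raise ConfigError("n_months must be >= 1")
        if not 0 <= self.n_active <= self.n_covariates:
            raise ConfigError(
                f"n_active={self.n_active} must lie in [0, n_covariates="
                f"{self.n_covariates}]"
            )
        for name in ("death_share", "pushback_share", "underreport_rate"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ConfigError(f"{name}={val} must lie in [0, 1]")
        if self.death_share + self.pushback_share > 1.0:
            raise ConfigError("death_share + pushback_share must be <= 1")
        if self.season_period < 2:
            raise ConfigError("season_period must be >= 2")
        if self.n_months < 2 * self.season_period:
            raise ConfigError(
                "n_months must span at least two full seasonal cycles"
            )
        if self.count_noise not in ("poisson", "negbin", "none"):
            raise ConfigError(f"unknown count_noise {self.count_noise!r}")
        if not 0 < abs(self.ar_coef) < 1:
            raise ConfigError("ar_coef must lie in (-1, 1) and be nonzero")

    def month_index(self) -> pd.DatetimeIndex:
        return pd.date_range(
            pd.Timestamp(self.start_month + "-01"),
            periods=self.n_months,
            freq="MS",
        )


@dataclass
class GroundTruth:
    """Latent truth of a generated scenario, kept apart from the data."""

    level: np.ndarray          # trend (level) path, log scale
    slope: np.ndarray
    seasonal: np.ndarray       # sum-to-zero 12-pattern tiled over the window
    regression: np.ndarray     # covariate contribution per month, log scale
    effect_log: np.ndarray     # cumulative log intervention effect per month
    log_intensity: np.ndarray  # lambda_t = level + seasonal + regression + effect
    beta: dict[str, float]     # active column -> log-scale coefficient
    active: tuple[str, ...]
    config: ScenarioConfig

    def to_frame(self) -> pd.DataFrame:
        idx = self.config.month_index()
        return pd.DataFrame(
            {
                "level": self.level,
                "slope": self.slope,
                "seasonal": self.seasonal,
                "regression": self.regression,
                "effect_log": self.effect_log,
                "log_intensity": self.log_intensity,
            },
            index=idx,
        ).rename_axis("month")


def _family_of(j: int) -> str:
    return _FAMILIES[j % len(_FAMILIES)]


def generate_covariates(config: ScenarioConfig, rng: np.random.Generator):
    """Generate a covariate panel with three structural families.

    Columns cycle through three families mirroring the covariate classes
    used to predict migration flows: smooth AR(1) series (economic proxies
    such as exchange rates and commodity prices), annual sinusoids plus
    noise (weather proxies), and sparse non-negative spike series
    (conflict/disaster proxies).

    Returns a :class:`~flowimpact.assembly.CovariatePanel`.
    """
    from .assembly import CovariatePanel

    config.validate()
    idx = config.month_index()
    n = config.n_months
    cols: dict[str, np.ndarray] = {}
    t = np.arange(n)
    for j in range(config.n_covariates):
        fam = _family_of(j)
        name = f"{fam}_{j:02d}"
        if fam == "econ":
            phi = config.ar_coef
            x = np.empty(n)
            # stationary start so the marginal variance is constant
            x[0] = rng.normal(0.0, 1.0 / np.sqrt(1 - phi**2))
            innov = rng.normal(0.0, 1.0, size=n - 1)
            for i in range(1, n):
                x[i] = phi * x[i - 1] + innov[i - 1]
        elif fam == "weather":
            phase = rng.uniform(0, 2 * np.pi)
            amp = rng.uniform(0.8, 1.5)
            x = amp * np.sin(2 * np.pi * t / config.season_period + phase)
            x = x + rng.normal(0.0, 0.3, size=n)
        else:  # shock: sparse non-negative spikes
            active = rng.random(n) < 0.15
            x = np.where(active, rng.exponential(2.0, size=n), 0.0)
        cols[name] = x
    data = pd.DataFrame(cols, index=idx).rename_axis("month")
    return CovariatePanel(data)


def _latent_path(config: ScenarioConfig, panel, rng: np.random.Generator):
    """Build the latent log-intensity and its components."""
    n = config.n_months
    # local linear trend: level random walk with drifting slope
    level = np.empty(n)
    slope = np.empty(n)
    level[0] = config.base_level
    slope[0] = 0.0
    for tt in range(1, n):
        slope[tt] = slope[tt - 1] + rng.normal(0.0, config.trend_slope_sd)
        level[tt] = level[tt - 1] + slope[tt - 1] + rng.normal(
            0.0, config.trend_level_sd
        )

    # fixed sum-to-zero seasonal pattern (identifiable against the trend)
    s = config.season_period
    pattern = rng.normal(0.0, config.seasonal_sd, size=s)
    pattern -= pattern.mean()
    seasonal = np.tile(pattern, n // s + 1)[:n]

    # sparse regression: the first n_active columns (panel order) are active,
    # standardized so beta is an effect per covariate standard deviation
    regression = np.zeros(n)
    beta_map: dict[str, float] = {}
    active_cols: list[str] = []
    if config.n_active > 0:
        betas = np.resize(np.asarray(config.beta_active, float), config.n_active)
        names = list(panel.data.columns[: config.n_active])
        for b, name in zip(betas, names):
            x = panel.data[name].to_numpy(float)
            sd = x.std()
            z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
            regression += b * z
            beta_map[name] = float(b)
            active_cols.append(name)

    effect_log = np.zeros(n)
    for tau, eff in config.interventions:
        if not 0 <= tau < n:
            raise ConfigError(f"intervention month index {tau} out of range")
        if eff <= 0:
            raise ConfigError("multiplicative effects must be positive")
        effect_log[tau:] += np.log(eff)

    lam = level + seasonal + regression + effect_log
    return level, slope, seasonal, regression, effect_log, lam, beta_map, active_cols


def generate_flow(config: ScenarioConfig, panel, rng: np.random.Generator):
    """Draw a flow series from the latent intensity implied by ``panel``.

    The monthly total of crossing attempts ``Y_t`` is drawn from the
    configured count distribution with mean ``exp(lambda_t)`` where
    ``lambda_t`` adds trend, seasonality, the sparse covariate signal, the
    intervention effects and a log-scale observation noise.  ``Y_t`` is then
    split multinomially into arrivals, pushbacks and deaths so that the
    additive identity ``Y = A + P + D`` holds exactly.

    Returns ``(FlowSeries, GroundTruth)``.
    """
    from .assembly import FlowSeries

    config.validate()
    if len(panel.data) != config.n_months:
        raise ConfigError(
            f"panel has {len(panel.data)} rows, expected {config.n_months}"
        )
    (level, slope, seasonal, regression, effect_log, lam,
     beta_map, active_cols) = _latent_path(config, panel, rng)

    lam_obs = lam + rng.normal(0.0, config.obs_sd, size=config.n_months)
    if np.any(lam_obs > 700):
        raise GenerationError(
            "log-intensity exceeds 700 (exp overflow); reduce base_level, "
            "effect sizes or the trend/seasonal standard deviations"
        )
    mean = np.exp(lam_obs)
    if config.count_noise == "poisson":
        y = rng.poisson(mean)
    elif config.count_noise == "negbin":
        r = config.nb_dispersion
        # NB(mean m, dispersion r): gamma-poisson mixture, var = m + m^2/r
        y = rng.poisson(rng.gamma(shape=r, scale=mean / r))
    else:
        y = np.round(mean).astype(np.int64)

    shares = [config.death_share, config.pushback_share,
              1.0 - config.death_share - config.pushback_share]
    split = np.array([rng.multinomial(int(yt), shares) for yt in y])
    deaths, pushbacks, arrivals = split[:, 0], split[:, 1], split[:, 2]

    idx = config.month_index()
    flow = FlowSeries.from_components(
        arrivals=pd.Series(arrivals, index=idx),
        pushbacks=pd.Series(pushbacks, index=idx),
        deaths=pd.Series(deaths, index=idx),
    )
    truth = GroundTruth(
        level=level, slope=slope, seasonal=seasonal, regression=regression,
        effect_log=effect_log, log_intensity=lam,
        beta=beta_map, active=tuple(active_cols), config=config,
    )
    if config.underreport_rate > 0:
        flow = apply_underreporting(flow, config.underreport_rate, rng)
    return flow, truth


def generate_scenario(config: ScenarioConfig, rng=None):
    """Convenience wrapper: panel + flow + truth from one config/seed."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    panel = generate_covariates(config, rng)
    flow, truth = generate_flow(config, panel, rng)
    return flow, panel, truth


def apply_underreporting(flow, rate: float, rng: np.random.Generator):
    """Thin recorded deaths: each death independently deleted with ``rate``.

    Arrivals and pushbacks are unchanged; the total is recomputed from the
    thinned deaths so the additive identity still holds.
    """
    from .assembly import FlowSeries

    if not 0.0 <= rate < 1.0:
        raise ValidationError(f"underreporting rate {rate} must lie in [0, 1)")
    if rate == 0.0:
        return flow
    d = flow.deaths.to_numpy()
    kept = rng.binomial(d, 1.0 - rate)
    return FlowSeries.from_components(
        arrivals=flow.arrivals.copy(),
        pushbacks=flow.pushbacks.copy(),
        deaths=pd.Series(kept, index=flow.index),
    )


def write_scenario(flow, panel, truth: GroundTruth, out_dir) -> list[str]:
    """Write flow/panel CSVs and the ground truth (YAML + CSV) to a directory.

    The truth files are separate from the data files on purpose: pipeline
    code reads only the CSVs, tests may read the truth.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = []
    p = os.path.join(out_dir, "flow.csv")
    flow.to_csv(p)
    paths.append(p)
    p = os.path.join(out_dir, "covariates.csv")
    panel.to_csv(p)
    paths.append(p)
    p = os.path.join(out_dir, "ground_truth.csv")
    truth.to_frame().to_csv(p, date_format="%Y-%m-%d")
    paths.append(p)
    p = os.path.join(out_dir, "ground_truth.yaml")
    cfg = asdict(truth.config)
    cfg["beta_active"] = list(map(float, cfg["beta_active"]))
    cfg["interventions"] = [list(map(float, iv)) for iv in cfg["interventions"]]
    with open(p, "w") as fh:
        yaml.safe_dump(
            {
                "config": cfg,
                "active_covariates": list(truth.active),
                "beta": {k: float(v) for k, v in truth.beta.items()},
            },
            fh,
            sort_keys=False,
        )
    paths.append(p)
    return paths
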