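"""Per-fish-group methylmercury concentration models.

Within each of the five raw-fish groups of the national nutrition survey,
methylmercury concentration (mg/kg wet weight) is modelled as log-normal.
The model carries both parameterizations — the arithmetic mean/SD a monitoring
report prints, and the log-scale (mu, sigma) the sampler uses — and keeps them
mutually consistent.  Three truncation scenarios cap the sampled concentrations
at +inf, twice the observed group maximum, or the observed maximum itself;
truncation is a renormalized (rejection-resampled) log-normal, never a clip,
so no point mass appears at the cap.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    InvalidParameterError,
    NumericDomainError,
    PathologicalTruncationError,
)

__all__ = [
    "FishGroup",
    "GROUP_ORDER",
    "TruncationScenario",
    "ConcentrationDataset",
    "LogNormalParams",
    "moments_to_logparams",
    "fit_lognormal",
    "ks_statistic",
    "ad_statistic",
    "ks_statistic_cdf",
    "ad_statistic_cdf",
    "truncation_limit",
    "sample_concentrations",
    "truncated_mean",
    "load_concentration_csv",
    "fit_report",
]

_REL_TOL = 1e-9
# Below this acceptance probability, rejection sampling against the cap is
# declared pathological rather than looping (virtually) forever.
MIN_ACCEPTANCE_PROBABILITY = 1e-6

CONCENTRATION_CSV_COLUMNS = ("group", "species", "concentration_mg_per_kg")


class FishGroup(str, enum.Enum):
    """The five raw-fish categories used by the consumption survey."""

    HORSE_MACKEREL_SARDINE = "horse_mackerel_sardine"
    SALMON_TROUT = "salmon_trout"
    RED_SNAPPER_FLOUNDER = "red_snapper_flounder"
    TUNA_SWORDFISH = "tuna_swordfish"
    OTHER_RAW_FISH = "other_raw_fish"


#: Canonical group order; random substreams are keyed to this order so the
#: draws for one group never depend on which other groups are configured.
GROUP_ORDER: tuple[FishGroup, ...] = tuple(FishGroup)


class TruncationScenario(enum.Enum):
    """Rule for capping sampled concentrations.

    NONE       — no upper limit (scenario 1),
    TWICE_MAX  — cap at twice the observed group maximum (scenario 2),
    AT_MAX     — cap at the observed group maximum (scenario 3).
    """

    NONE = "none"
    TWICE_MAX = "twice_max"
    AT_MAX = "at_max"


@dataclass(frozen=True)
class ConcentrationDataset:
    """Observed methylmercury concentrations (mg/kg) for one fish group."""

    group: FishGroup
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise InvalidParameterError("concentration dataset needs >= 1 value")
        if not np.all(np.isfinite(values)):
            raise InvalidParameterError("concentrations must be finite")
        if np.any(values <= 0):
            raise InvalidParameterError(
                "concentrations must be strictly positive (log-normal support)"
            )
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def max_observed(self) -> float:
        """Group maximum (mg/kg); the anchor for the truncation scenarios."""
        return float(self.values.max())


@dataclass(frozen=True)
class LogNormalParams:
    """A log-normal concentration distribution in both parameterizations.

    ``arithmetic_mean`` / ``arithmetic_sd`` are on the mg/kg scale;
    ``log_mu`` / ``log_sigma`` are the mean and SD of ln(concentration).
    The two are required to agree to 1e-9 relative at construction.
    """

    arithmetic_mean: float
    arithmetic_sd: float
    log_mu: float
    log_sigma: float

    def __post_init__(self) -> None:
        if not (self.arithmetic_mean > 0 and self.arithmetic_sd > 0):
            raise InvalidParameterError("arithmetic mean and sd must be positive")
        if not self.log_sigma > 0:
            raise InvalidParameterError("log_sigma must be positive")
        s2 = self.log_sigma**2
        mean = math.exp(self.log_mu + s2 / 2.0)
        var = (math.expm1(s2)) * math.exp(2.0 * self.log_mu + s2)
        sd = math.sqrt(var)
        if (
            abs(mean - self.arithmetic_mean) > _REL_TOL * self.arithmetic_mean
            or abs(sd - self.arithmetic_sd) > _REL_TOL * self.arithmetic_sd
        ):
            raise InvalidParameterError(
                "inconsistent dual parameterization: "
                f"moments ({self.arithmetic_mean}, {self.arithmetic_sd}) vs "
                f"log-scale implied ({mean}, {sd})"
            )

    @classmethod
    def from_moments(cls, mean: float, sd: float) -> "LogNormalParams":
        if not (mean > 0 and sd > 0):
            raise InvalidParameterError("mean and sd must be positive")
        s2 = math.log1p((sd / mean) ** 2)
        log_mu = math.log(mean) - s2 / 2.0
        log_sigma = math.sqrt(s2)
        # Store the exact moments implied by (log_mu, log_sigma) so the
        # consistency invariant holds to machine precision.
        mean_back = math.exp(log_mu + s2 / 2.0)
        sd_back = math.sqrt((math.expm1(s2)) * math.exp(2.0 * log_mu + s2))
        return cls(mean_back, sd_back, log_mu, log_sigma)

    @classmethod
    def from_log_params(cls, log_mu: float, log_sigma: float) -> "LogNormalParams":
        if not log_sigma > 0:
            raise InvalidParameterError("log_sigma must be positive")
        s2 = log_sigma**2
        mean = math.exp(log_mu + s2 / 2.0)
        sd = math.sqrt((math.expm1(s2)) * math.exp(2.0 * log_mu + s2))
        return cls(mean, sd, log_mu, log_sigma)

    @property
    def median(self) -> float:
        return math.exp(self.log_mu)

    def frozen(self) -> stats.rv_continuous:
        """The matching scipy frozen distribution (for CDF/quantile work)."""
        return stats.lognorm(s=self.log_sigma, scale=math.exp(self.log_mu))

    def cdf(self, x) -> np.ndarray:
        return self.frozen().cdf(x)


def moments_to_logparams(mean: float, sd: float) -> LogNormalParams:
    """Convert an arithmetic mean/SD (mg/kg) into log-normal parameters.

    Uses the closed-form inversion
    ``log_sigma^2 = ln(1 + (sd/mean)^2)``, ``log_mu = ln(mean) - log_sigma^2/2``,
    which round-trips exactly back to the arithmetic moments.
    """
    return LogNormalParams.from_moments(mean, sd)


def fit_lognormal(
    dataset: ConcentrationDataset, method: str = "moments"
) -> LogNormalParams:
    """Fit a log-normal distribution to one group's concentrations.

    method="moments"
        Matches the sample arithmetic mean and sample SD (ddof=1) exactly —
        the default, so a printed mean/SD table reproduces the simulation.
    method="mle"
        Maximum likelihood: ``log_mu`` = mean of log-values, ``log_sigma`` =
        population SD (ddof=0) of log-values.
    """
    values = dataset.values
    if values.size < 2:
        raise InsufficientDataError("need at least 2 observations to fit")
    if np.ptp(values) == 0.0:
        raise DegenerateDataError(
            "all observations identical; zero variance is not a valid log-normal"
        )
    if method == "moments":
        return LogNormalParams.from_moments(
            float(values.mean()), float(values.std(ddof=1))
        )
    if method == "mle":
        logs = np.log(values)
        return LogNormalParams.from_log_params(
            float(logs.mean()), float(logs.std(ddof=0))
        )
    raise InvalidParameterError(f"unknown fit method: {method!r}")


def ks_statistic_cdf(values: Iterable[float], cdf: Callable) -> float:
    """Kolmogorov–Smirnov statistic of a sample against an arbitrary CDF.

    D_n = sup_i max(|i/n - F(x_(i))|, |(i-1)/n - F(x_(i))|).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 1:
        raise InvalidParameterError("need at least one observation")
    f = np.asarray(cdf(x), dtype=float)
    i = np.arange(1, n + 1, dtype=float)
    return float(np.max(np.maximum(np.abs(i / n - f), np.abs((i - 1) / n - f))))


def ad_statistic_cdf(values: Iterable[float], cdf: Callable) -> float:
    """Anderson–Darling A^2 of a sample against an arbitrary CDF.

    A^2 = -n - (1/n) * sum_i (2i-1) [ln F(x_(i)) + ln(1 - F(x_(n+1-i)))].
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 1:
        raise InvalidParameterError("need at least one observation")
    f = np.asarray(cdf(x), dtype=float)
    if np.any(f <= 0.0) or np.any(f >= 1.0):
        raise NumericDomainError(
            "CDF value hit 0 or 1 at machine precision; A^2 undefined"
        )
    i = np.arange(1, n + 1, dtype=float)
    terms = (2.0 * i - 1.0) * (np.log(f) + np.log1p(-f[::-1]))
    return float(-n - terms.sum() / n)


def ks_statistic(dataset: ConcentrationDataset, params: LogNormalParams) -> float:
    """KS distance between a group's data and its fitted log-normal."""
    return ks_statistic_cdf(dataset.values, params.cdf)


def ad_statistic(dataset: ConcentrationDataset, params: LogNormalParams) -> float:
    """Anderson–Darling A^2 between a group's data and its fitted log-normal."""
    return ad_statistic_cdf(dataset.values, params.cdf)


def truncation_limit(
    dataset: ConcentrationDataset, scenario: TruncationScenario
) -> float:
    """Concentration cap (mg/kg) implied by a truncation scenario."""
    if scenario is TruncationScenario.NONE:
        return math.inf
    if scenario is TruncationScenario.TWICE_MAX:
        return 2.0 * dataset.max_observed
    if scenario is TruncationScenario.AT_MAX:
        return dataset.max_observed
    raise InvalidParameterError(f"unknown scenario: {scenario!r}")


def sample_concentrations(
    params: LogNormalParams, limit: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` concentrations from the (possibly truncated) log-normal.

    Truncation is rejection-with-redraw: draws above ``limit`` are replaced by
    fresh draws from the same stream until all are accepted, which realizes the
    renormalized distribution on (0, limit].  With ``limit=inf`` this is plain
    log-normal sampling, so matched seeds give common random numbers across
    scenarios (only the rejected tail draws differ).
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    if not limit > 0:
        raise InvalidParameterError("limit must be positive")
    draws = rng.lognormal(mean=params.log_mu, sigma=params.log_sigma, size=n)
    if math.isinf(limit):
        return draws
    accept_p = float(params.cdf(limit))
    if accept_p < MIN_ACCEPTANCE_PROBABILITY:
        raise PathologicalTruncationError(
            f"acceptance probability {accept_p:.3g} below "
            f"{MIN_ACCEPTANCE_PROBABILITY}; limit {limit} is pathologically low"
        )
    reject = draws > limit
    while reject.any():
        draws[reject] = rng.lognormal(
            mean=params.log_mu, sigma=params.log_sigma, size=int(reject.sum())
        )
        reject = draws > limit
    return draws


def truncated_mean(params: LogNormalParams, limit: float) -> float:
    """Closed-form mean of the log-normal truncated to (0, limit].

    E[X | X <= L] = exp(mu + sigma^2/2) * Phi((ln L - mu - sigma^2)/sigma)
                    / Phi((ln L - mu)/sigma),
    which tends to the arithmetic mean as L -> inf and increases in L.
    """
    if not limit > 0:
        raise InvalidParameterError("limit must be positive")
    if math.isinf(limit):
        return params.arithmetic_mean
    z = (math.log(limit) - params.log_mu) / params.log_sigma
    numer = stats.norm.cdf(z - params.log_sigma)
    denom = stats.norm.cdf(z)
    if denom == 0.0:
        raise PathologicalTruncationError(
            f"truncation limit {limit} has zero mass below it"
        )
    return float(params.arithmetic_mean * numer / denom)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def load_concentration_csv(path: str | Path) -> dict[FishGroup, ConcentrationDataset]:
    """Read per-sample concentrations from CSV.

    Expected header: ``group,species,concentration_mg_per_kg`` (UTF-8, decimal
    point).  ``group`` must be one of the five FishGroup labels.
    """
    frame = pd.read_csv(path)
    missing = set(CONCENTRATION_CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise InvalidParameterError(
            f"concentration CSV missing columns: {sorted(missing)}"
        )
    datasets: dict[FishGroup, ConcentrationDataset] = {}
    for label, sub in frame.groupby("group", sort=False):
        try:
            group = FishGroup(str(label))
        except ValueError as exc:
            raise InvalidParameterError(
                f"unknown fish group label {label!r}; expected one of "
                f"{[g.value for g in GROUP_ORDER]}"
            ) from exc
        datasets[group] = ConcentrationDataset(
            group, sub["concentration_mg_per_kg"].to_numpy(dtype=float)
        )
    return datasets


def write_concentration_csv(
    datasets: Mapping[FishGroup, ConcentrationDataset],
    path: str | Path,
    species_label: str = "synthetic",
) -> None:
    """Write datasets in the same CSV dialect :func:`load_concentration_csv` reads."""
    rows = []
    for group in GROUP_ORDER:
        if group not in datasets:
            continue
        for value in datasets[group].values:
            rows.append((group.value, species_label, value))
    pd.DataFrame(rows, columns=list(CONCENTRATION_CSV_COLUMNS)).to_csv(
        path, index=False
    )


def fit_report(
    datasets: Mapping[FishGroup, ConcentrationDataset], method: str = "moments"
) -> dict[str, dict[str, float]]:
    """Fitted-parameter summary, JSON-ready: group -> moments, log params, n, max."""
    report: dict[str, dict[str, float]] = {}
    for group in GROUP_ORDER:
        if group not in datasets:
            continue
        dataset = datasets[group]
        params = fit_lognormal(dataset, method=method)
        report[group.value] = {
            "arithmetic_mean": params.arithmetic_mean,
            "arithmetic_sd": params.arithmetic_sd,
            "log_mu": params.log_mu,
            "log_sigma": params.log_sigma,
            "n": dataset.n,
            "max_observed": dataset.max_observed,
        }
    return report
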