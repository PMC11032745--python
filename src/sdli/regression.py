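"""Square-root-scale linear regression of annual overdose deaths on SALI.

The model is ordinary least squares of √(annual unintentional overdose
deaths) on the Summed Annual Lethality Index:

    √(deaths_y) = a + b · SALI_y + ε_y

The square-root transform stabilises the right-skew of annual death counts;
predictions are back-transformed by squaring the (zero-clamped) linear
predictor, with no retransformation bias correction.  Residual independence
is screened with the Durbin–Watson statistic; normality and homoscedasticity
are assessed visually via the diagnostic plots, with no automated pass/fail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.stats
import statsmodels.api as sm

from .errors import (
    DegenerateDesignError,
    InsufficientDataError,
    UndefinedStatisticError,
)
from .index import SALISeries
from .records import DeathRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnualDeaths:
    """Annual unintentional overdose death totals (all drugs by default)."""

    values: dict[int, int]

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted(self.values))

    @classmethod
    def from_death_records(
        cls,
        deaths: Iterable[DeathRecord],
        scope: str = "all_unintentional",
        drugs: Sequence[str] | None = None,
    ) -> "AnnualDeaths":
        """Tally filtered death records per calendar year.

        ``scope="indexed_drugs_only"`` restricts the total to deaths whose
        toxicology involves at least one of ``drugs``.
        """
        if scope not in ("all_unintentional", "indexed_drugs_only"):
            raise ValueError(f"unknown deaths scope {scope!r}")
        drug_set = set(drugs or ())
        totals: dict[int, int] = {}
        for d in deaths:
            if scope == "indexed_drugs_only" and not (d.tox_substances & drug_set):
                continue
            totals[d.year] = totals.get(d.year, 0) + 1
        return cls(totals)


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of √deaths on SALI, with slope inference and DW diagnostic.

    ``residuals`` (and the parallel arrays) are stored in ascending calendar
    year order, as the Durbin–Watson statistic requires.
    """

    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    t_stat: float
    df: int
    p_value: float
    r_squared: float
    residuals: tuple[float, ...]
    durbin_watson: float
    ci_level: float
    years: tuple[int, ...]
    sali: tuple[float, ...]
    sqrt_deaths: tuple[float, ...]
    fitted_sqrt: tuple[float, ...]
    observed_deaths: tuple[int, ...]


def durbin_watson(residuals: Sequence[float]) -> float:
    """Σ(e_t − e_{t−1})² / Σe_t² over year-ordered residuals; range [0, 4].

    ≈2 under independence; 0 iff all successive differences vanish.
    """
    e = np.asarray(residuals, dtype=float)
    if e.size < 2:
        raise UndefinedStatisticError("Durbin-Watson needs at least 2 residuals")
    denom = float(np.sum(e**2))
    if denom == 0.0:
        raise UndefinedStatisticError("Durbin-Watson undefined for all-zero residuals")
    return float(np.sum(np.diff(e) ** 2) / denom)


def fit_sali_regression(
    sali: SALISeries,
    deaths: AnnualDeaths,
    ci_level: float = 0.95,
) -> RegressionResult:
    """Fit √(deaths) = a + b·SALI by OLS with two-sided t inference on b.

    Years are matched between the two series; at least 3 matched points are
    required, and the predictor must have nonzero variance.
    """
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must be in (0, 1)")
    years = sorted(set(sali.values) & set(deaths.values))
    if len(years) < 3:
        raise InsufficientDataError(
            f"need at least 3 matched (year, SALI, deaths) points; got {len(years)}"
        )
    x = np.array([sali.values[y] for y in years], dtype=float)
    d = np.array([deaths.values[y] for y in years], dtype=int)
    if np.any(d < 0):
        raise ValueError("death counts must be non-negative")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("SALI has zero variance across the fitted years")
    y = np.sqrt(d.astype(float))

    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=1 - ci_level)
    resid = model.resid
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
        t_stat=float(model.tvalues[1]),
        df=int(model.df_resid),
        p_value=float(model.pvalues[1]),
        r_squared=float(model.rsquared),
        residuals=tuple(float(e) for e in resid),
        durbin_watson=durbin_watson(resid) if np.any(resid != 0) else 0.0,
        ci_level=ci_level,
        years=tuple(years),
        sali=tuple(x),
        sqrt_deaths=tuple(y),
        fitted_sqrt=tuple(float(v) for v in model.fittedvalues),
        observed_deaths=tuple(int(v) for v in d),
    )


def predict_deaths(result: RegressionResult, sali_value: float) -> float:
    """Back-transformed prediction: max(0, a + b·SALI)².

    The linear predictor is clamped at zero before squaring (squaring a
    negative predictor would otherwise fabricate deaths under extreme
    downward extrapolation); no smearing/bias correction is applied.
    """
    lin = result.intercept + result.slope * sali_value
    if lin < 0:
        logger.warning(
            "negative linear predictor %.4f at SALI=%.4f clamped to 0", lin, sali_value
        )
        lin = 0.0
    return lin * lin


@dataclass(frozen=True)
class ResidualDiagnostics:
    """Descriptive residual diagnostics; interpretation is left to the analyst."""

    skewness: float
    standardized_residuals: tuple[float, ...]
    histogram_path: Path | None
    qq_path: Path | None
    residual_vs_fitted_path: Path | None


def residual_diagnostics(
    result: RegressionResult,
    output_dir: str | Path | None = None,
) -> ResidualDiagnostics:
    """Residual skewness, standardized residuals, and diagnostic plots.

    Skewness is the third standardized moment m3 / m2^1.5.  When
    ``output_dir`` is given, a histogram, normal Q-Q plot, and
    residual-vs-fitted scatter are written there.
    """
    e = np.asarray(result.residuals, dtype=float)
    skew = float(scipy.stats.skew(e, bias=True)) if np.ptp(e) > 0 else 0.0
    sd = float(np.std(e, ddof=1)) if e.size > 1 else 0.0
    std_resid = tuple((e / sd).tolist()) if sd > 0 else tuple(np.zeros_like(e).tolist())

    hist_path = qq_path = rvf_path = None
    if output_dir is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)

        hist_path = out / "residual_histogram.png"
        fig, ax = plt.subplots()
        ax.hist(e, bins="auto", edgecolor="black")
        ax.set_xlabel("residual (sqrt-death scale)")
        ax.set_ylabel("frequency")
        ax.set_title("Residual histogram")
        fig.savefig(hist_path, dpi=120)
        plt.close(fig)

        qq_path = out / "residual_qq.png"
        fig, ax = plt.subplots()
        scipy.stats.probplot(e, dist="norm", plot=ax)
        ax.set_title("Residual normal Q-Q plot")
        fig.savefig(qq_path, dpi=120)
        plt.close(fig)

        rvf_path = out / "residual_vs_fitted.png"
        fig, ax = plt.subplots()
        ax.scatter(result.fitted_sqrt, std_resid)
        ax.axhline(0.0, linestyle="--", linewidth=1)
        ax.set_xlabel("fitted sqrt(deaths)")
        ax.set_ylabel("standardized residual")
        ax.set_title("Standardized residuals vs fitted values")
        fig.savefig(rvf_path, dpi=120)
        plt.close(fig)

    return ResidualDiagnostics(skew, std_resid, hist_path, qq_path, rvf_path)
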