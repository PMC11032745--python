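"""End-to-end pipeline: read → filter → index → SALI → regression → report.

Given one configuration the pipeline reads the case-level CSVs, applies the
ICD-10 unintentional filter, builds the reference-year lethality table,
computes the SALI series, fits the sqrt-scale regression, and writes every
intermediate as CSV alongside the figures, so each number in the report is
traceable to a persisted table.  The pipeline is a pure function of
(config, input files): identical inputs produce identical tabular outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import records as _records
from . import index as _index
from . import regression as _regression
from .errors import AlignmentError, ConfigurationError, PipelineStageError, SDLIError
from .index import round_half_up
from .records import ANALYTIC_CATEGORIES
from .regression import AnnualDeaths, RegressionResult, predict_deaths

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; round-trips losslessly via YAML."""

    seizures_path: str
    deaths_path: str
    output_dir: str
    mapping_path: str | None = None
    reference_year: int = 2017
    years: list[int] = field(default_factory=lambda: list(range(2009, 2019)))
    drugs: list[str] = field(default_factory=lambda: list(ANALYTIC_CATEGORIES))
    ci_level: float = 0.95
    unmapped_policy: str = "keep_as_other"
    ignore_other_substances: bool = False
    deaths_scope: str = "all_unintentional"

    def __post_init__(self) -> None:
        if self.deaths_scope not in ("all_unintentional", "indexed_drugs_only"):
            raise ConfigurationError(f"unknown deaths_scope {self.deaths_scope!r}")
        if not 0 < self.ci_level < 1:
            raise ConfigurationError("ci_level must be in (0, 1)")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _load_mapping(config: PipelineConfig) -> _records.SubstanceMapping:
    if config.mapping_path is None:
        return _records.SubstanceMapping.default(config.unmapped_policy)
    return _records.SubstanceMapping.from_csv(config.mapping_path, config.unmapped_policy)


def render_prediction_figure(
    observed: AnnualDeaths,
    predicted: Mapping[int, float],
    path: str | Path,
) -> Path:
    """Paired observed/predicted deaths per year, with a CSV data sidecar.

    The sidecar (same stem, ``.csv``) carries the plotted numbers so tests
    and downstream checks never need to read pixels.
    """
    if set(observed.values) != set(predicted):
        raise AlignmentError(
            f"observed years {sorted(observed.values)} != predicted years {sorted(predicted)}"
        )
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    years = sorted(observed.values)
    obs = [observed.values[y] for y in years]
    pred = [predicted[y] for y in years]

    sidecar = path.with_suffix(".csv")
    pd.DataFrame(
        {"year": years, "observed_deaths": obs, "predicted_deaths": pred}
    ).to_csv(sidecar, index=False)

    fig, ax = plt.subplots(figsize=(8, 5))
    ax.bar(years, obs, color="#9ecae1", label="Observed")
    ax.plot(years, pred, "o-", color="#de2d26", label="Predicted (SALI model)")
    ax.set_xlabel("Year")
    ax.set_ylabel("Unintentional overdose deaths")
    ax.set_title("Predicted vs observed unintentional overdose deaths")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def _fit_summary_frame(result: RegressionResult) -> pd.DataFrame:
    return pd.DataFrame(
        [
            ("slope", result.slope, result.slope_ci[0], result.slope_ci[1],
             result.t_stat, result.df, result.p_value),
            ("intercept", result.intercept, float("nan"), float("nan"),
             float("nan"), result.df, float("nan")),
        ],
        columns=["term", "estimate", "ci_low", "ci_high", "t", "df", "p"],
    )


def run_pipeline(config: PipelineConfig, stages: str = "report") -> dict[str, Path]:
    """Execute the pipeline and return the bundle of written file paths.

    ``stages`` limits how far the run goes: ``"index"`` stops after the
    lethality table and SALI series, ``"fit"`` adds the regression summary,
    ``"report"`` (default) adds diagnostics and figures.  Stage failures are
    wrapped with the stage name and a remediation hint; outputs written
    before the failure are retained.
    """
    if stages not in ("index", "fit", "report"):
        raise ConfigurationError(f"unknown stages {stages!r}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Path] = {}

    def _stage(name, fn, hint):
        try:
            return fn()
        except SDLIError as exc:
            raise PipelineStageError(name, exc, hint) from exc

    mapping = _stage(
        "load_mapping", lambda: _load_mapping(config),
        "check mapping_path and unmapped_policy in the config",
    )
    seizures = _stage(
        "read_seizures", lambda: _records.read_seizures(config.seizures_path, mapping),
        "check the seizure CSV path and its columns (seizure_id,date,county,substances)",
    )
    all_deaths = _stage(
        "read_deaths", lambda: _records.read_deaths(config.deaths_path, mapping),
        "check the death CSV path and its columns",
    )
    deaths = _records.filter_unintentional(all_deaths)
    logger.info(
        "records: %d seizures; %d deaths, %d unintentional (X40-X44)",
        len(seizures), len(all_deaths), len(deaths),
    )

    table = _stage(
        "build_lethality_table",
        lambda: _index.build_lethality_table(
            deaths, seizures, config.reference_year, config.drugs,
            config.ignore_other_substances,
        ),
        "reference year may have no single-drug seizures for the configured drugs",
    )
    bundle["lethality_table"] = out / "lethality_table.csv"
    table.to_csv(bundle["lethality_table"])
    for e in table.entries:
        logger.info(
            "LR[%s] = %d/%d = %.3f",
            e.drug, e.single_deaths, e.single_seizures, round_half_up(e.lr, 3),
        )

    sali = _stage(
        "compute_sali_series",
        lambda: _index.compute_sali_series(
            table, seizures, config.years, config.ignore_other_substances
        ),
        "check the analysis year list",
    )
    bundle["sdli"] = out / "sdli.csv"
    sali.entries_frame().to_csv(bundle["sdli"], index=False)
    bundle["sali"] = out / "sali.csv"
    sali.to_frame().to_csv(bundle["sali"], index=False)

    if stages == "index":
        return bundle

    observed = AnnualDeaths.from_death_records(
        deaths, scope=config.deaths_scope, drugs=config.drugs
    )
    observed = AnnualDeaths({y: observed.values.get(y, 0) for y in config.years})
    result = _stage(
        "fit_sali_regression",
        lambda: _regression.fit_sali_regression(sali, observed, config.ci_level),
        "need >=3 years with both SALI and death totals, with varying SALI",
    )
    logger.info(
        "fit: sqrt(deaths) = %.6f + %.6f*SALI, r^2=%.3f, DW=%.3f",
        result.intercept, result.slope, result.r_squared, result.durbin_watson,
    )
    bundle["fit_summary"] = out / "fit_summary.csv"
    _fit_summary_frame(result).to_csv(bundle["fit_summary"], index=False)

    predicted = {y: predict_deaths(result, s) for y, s in zip(result.years, result.sali)}
    diag_df = pd.DataFrame({
        "year": result.years,
        "sali": result.sali,
        "observed_deaths": result.observed_deaths,
        "sqrt_observed": result.sqrt_deaths,
        "fitted_sqrt": result.fitted_sqrt,
        "residual": result.residuals,
        "predicted_deaths": [predicted[y] for y in result.years],
    })
    bundle["diagnostics"] = out / "diagnostics.csv"
    diag_df.to_csv(bundle["diagnostics"], index=False)

    if stages == "fit":
        return bundle

    diag = _stage(
        "residual_diagnostics",
        lambda: _regression.residual_diagnostics(result, out),
        "",
    )
    bundle["residual_histogram"] = diag.histogram_path
    bundle["residual_qq"] = diag.qq_path
    bundle["residual_vs_fitted"] = diag.residual_vs_fitted_path

    fig_observed = AnnualDeaths({y: observed.values[y] for y in result.years})
    bundle["prediction_figure"] = _stage(
        "render_prediction_figure",
        lambda: render_prediction_figure(fig_observed, predicted, out / "predicted_vs_observed.png"),
        "",
    )
    bundle["prediction_data"] = out / "predicted_vs_observed.csv"
    return bundle
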