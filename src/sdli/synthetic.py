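"""Synthetic drug-market generator with known ground truth.

Real seizure databases and death registries are restricted administrative
data, so the pipeline is exercised against a simulator with known parameters:

* per-(drug, year) seizure volumes drawn Poisson around a supply-trend mean
  (seizure frequency standing proxy for street availability);
* each seizure is single-drug with probability 1 − ``p_mixed``; mixed
  seizures add one (occasionally two) partner drugs drawn by normalized
  co-occurrence weights;
* single-drug deaths per (drug, year) are Binomial(single seizures, θ_d),
  so the pipeline's estimated lethality ratio should recover θ_d;
* under ``deaths_model="linear_sqrt"`` additional multi-drug deaths are
  appended so annual totals follow deaths_y = round((a + b·SALI(y) + ε)²)
  with ε ~ N(0, noise_sd), SALI computed from the *true* θ and realized
  seizure tallies.  Appended deaths always carry ≥2 toxicology substances so
  they never contaminate the single-drug death counts.

Identical parameters and seed reproduce output bit-for-bit; per-(drug, year)
RNG substreams are derived deterministically from the root seed.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ParameterError
from .index import SALISeries
from .records import (
    ANALYTIC_CATEGORIES,
    UNINTENTIONAL_ICD10,
    DeathRecord,
    SeizureRecord,
    other_category,
    write_deaths,
    write_seizures,
)

#: filler co-intoxicant used when a multi-drug death needs a second substance
#: but the market has only one drug
_CO_INTOXICANT = other_category("co-intoxicant")


@dataclass(frozen=True)
class MarketParams:
    """Full parameterization of one synthetic market run.

    ``seizure_intensity`` maps (drug, year) to the expected number of seizure
    events whose *primary* drug is that drug; mixed seizures add the partner
    drugs on top, so a drug's all-seizure count exceeds its primary count.
    ``true_lethality`` is θ_d, the per-single-seizure probability that scales
    single-drug deaths.  ``linear_sqrt`` is the (a, b, noise_sd) triple of the
    sqrt-scale death-total model.
    """

    drugs: tuple[str, ...]
    years: tuple[int, ...]
    seizure_intensity: Mapping[tuple[str, int], float]
    true_lethality: Mapping[str, float]
    p_mixed: float = 0.25
    p_third: float = 0.2
    mix_weights: Mapping[str, float] | None = None
    deaths_model: str = "mechanistic"
    linear_sqrt: tuple[float, float, float] = (12.0, 0.0095, 0.3)
    rng_seed: int = 0

    def validate(self) -> None:
        if not self.drugs:
            raise ParameterError("drugs list is empty")
        if len(set(self.drugs)) != len(self.drugs):
            raise ParameterError("duplicate drug in params")
        if not self.years:
            raise ParameterError("years list is empty")
        if not 0.0 <= self.p_mixed <= 1.0:
            raise ParameterError("p_mixed must be in [0, 1]")
        if not 0.0 <= self.p_third <= 1.0:
            raise ParameterError("p_third must be in [0, 1]")
        for d in self.drugs:
            theta = self.true_lethality.get(d)
            if theta is None or not 0.0 <= theta <= 1.0:
                raise ParameterError(f"true_lethality[{d!r}] must be in [0, 1]")
        for (d, y), lam in self.seizure_intensity.items():
            if lam < 0:
                raise ParameterError(f"seizure_intensity[{d!r}, {y}] is negative")
        if self.deaths_model not in ("mechanistic", "linear_sqrt"):
            raise ParameterError(f"unknown deaths_model {self.deaths_model!r}")
        if self.mix_weights is not None:
            for d, w in self.mix_weights.items():
                if w < 0:
                    raise ParameterError(f"mix_weights[{d!r}] is negative")

    def intensity(self, drug: str, year: int) -> float:
        return float(self.seizure_intensity.get((drug, year), 0.0))

    def weight(self, drug: str) -> float:
        if self.mix_weights is None:
            return 1.0
        return float(self.mix_weights.get(drug, 0.0))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["seizure_intensity"] = {f"{k[0]}:{k[1]}": v for k, v in self.seizure_intensity.items()}
        return d


@dataclass
class GeneratorLog:
    """Ground-truth bookkeeping emitted alongside the records.

    Tallies are exhaustive counts over the emitted records (and are asserted
    as such in the test suite), so the log can serve as an independent oracle
    for the reading and counting stages.
    """

    single_seizures: dict[tuple[str, int], int] = field(default_factory=dict)
    mixed_seizures: dict[tuple[str, int], int] = field(default_factory=dict)
    all_seizures: dict[tuple[str, int], int] = field(default_factory=dict)
    single_deaths: dict[tuple[str, int], int] = field(default_factory=dict)
    true_sali: dict[int, float] = field(default_factory=dict)
    total_deaths: dict[int, int] = field(default_factory=dict)

    def is_empty(self) -> bool:
        return not any(self.all_seizures.values()) and not any(self.total_deaths.values())


def _random_date(rng: np.random.Generator, year: int) -> _dt.date:
    start = _dt.date(year, 1, 1)
    n_days = (_dt.date(year + 1, 1, 1) - start).days
    return start + _dt.timedelta(days=int(rng.integers(n_days)))


def _partner_probs(
    params: MarketParams, year: int, exclude: set[str]
) -> tuple[list[str], np.ndarray] | None:
    """Partner-drug distribution for mixed exhibits in one year.

    Probability ∝ co-occurrence weight × that year's seizure intensity, so a
    drug scarcely present in a given year rarely shows up as a partner.
    """
    pairs = [
        (d, params.weight(d) * params.intensity(d, year))
        for d in params.drugs
        if d not in exclude
    ]
    pairs = [(d, w) for d, w in pairs if w > 0]
    if not pairs:
        return None
    w = np.array([w for _, w in pairs], dtype=float)
    return [d for d, _ in pairs], w / w.sum()


def generate_market(params: MarketParams) -> tuple[list[SeizureRecord], list[DeathRecord], GeneratorLog]:
    """Generate one market realization: seizure records, death records, log."""
    params.validate()
    root = np.random.SeedSequence(params.rng_seed)
    # one substream per (drug, year) plus one for the death-total top-up;
    # spawn order is fixed by the params' drug/year ordering
    children = root.spawn(len(params.drugs) * len(params.years) + 1)
    log = GeneratorLog()
    seizures: list[SeizureRecord] = []
    deaths: list[DeathRecord] = []
    all_count: dict[tuple[str, int], int] = {
        (d, y): 0 for d in params.drugs for y in params.years
    }

    idx = 0
    for drug in params.drugs:
        for year in params.years:
            rng = np.random.default_rng(children[idx])
            idx += 1
            lam = params.intensity(drug, year)
            n = int(rng.poisson(lam)) if lam > 0 else 0
            n_mixed = int(rng.binomial(n, params.p_mixed)) if n else 0
            n_single = n - n_mixed
            log.single_seizures[(drug, year)] = n_single
            log.mixed_seizures[(drug, year)] = n_mixed

            for k in range(n_single):
                seizures.append(SeizureRecord(
                    f"S-{drug}-{year}-{k}", _random_date(rng, year), frozenset({drug})
                ))
                all_count[(drug, year)] += 1
            pp = _partner_probs(params, year, {drug})
            for k in range(n_mixed):
                subs = {drug}
                if pp is None:
                    subs.add(_CO_INTOXICANT)
                else:
                    cands, probs = pp
                    subs.add(cands[int(rng.choice(len(cands), p=probs))])
                    if len(cands) > 1 and rng.random() < params.p_third:
                        remaining = [c for c in cands if c not in subs]
                        if remaining:
                            subs.add(remaining[int(rng.integers(len(remaining)))])
                seizures.append(SeizureRecord(
                    f"S-{drug}-{year}-m{k}", _random_date(rng, year), frozenset(subs)
                ))
                for s in subs:
                    if (s, year) in all_count:
                        all_count[(s, year)] += 1

            theta = float(params.true_lethality[drug])
            n_deaths = int(rng.binomial(n_single, theta)) if n_single else 0
            log.single_deaths[(drug, year)] = n_deaths
            for k in range(n_deaths):
                deaths.append(DeathRecord(
                    f"D-{drug}-{year}-{k}",
                    _random_date(rng, year),
                    str(rng.choice(UNINTENTIONAL_ICD10)),
                    frozenset({drug}),
                ))

    log.all_seizures = all_count
    for year in params.years:
        log.true_sali[year] = sum(
            params.true_lethality[d] * all_count[(d, year)] for d in params.drugs
        )
        log.total_deaths[year] = sum(
            log.single_deaths[(d, year)] for d in params.drugs
        )

    if params.deaths_model == "linear_sqrt":
        a, b, noise_sd = params.linear_sqrt
        rng = np.random.default_rng(children[-1])
        for year in params.years:
            pp_all = _partner_probs(params, year, set())
            lin = a + b * log.true_sali[year] + float(rng.normal(0.0, noise_sd))
            target = int(round(max(0.0, lin) ** 2))
            mech = log.total_deaths[year]
            if target < mech:
                raise ParameterError(
                    f"linear_sqrt total {target} in {year} is below the {mech} "
                    f"mechanistic single-drug deaths; increase the intercept a"
                )
            for k in range(target - mech):
                if pp_all is None or len(pp_all[0]) < 2:
                    subs = {params.drugs[0], _CO_INTOXICANT}
                else:
                    cands, probs = pp_all
                    i, j = rng.choice(len(cands), size=2, replace=False, p=probs)
                    subs = {cands[int(i)], cands[int(j)]}
                deaths.append(DeathRecord(
                    f"D-multi-{year}-{k}",
                    _random_date(rng, year),
                    str(rng.choice(UNINTENTIONAL_ICD10)),
                    frozenset(subs),
                ))
            log.total_deaths[year] = target

    return seizures, deaths, log


def true_sali(params: MarketParams, log: GeneratorLog) -> SALISeries:
    """Ground-truth SALI from θ and realized all-seizure tallies.

    This is the series the pipeline would produce if it knew the lethality
    ratios exactly; it is the reference in parameter-recovery tests.
    """
    return SALISeries(dict(log.true_sali), frozenset(params.drugs))


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

#: reference-year lethality used by the ohio2017-like preset (deaths per
#: single-drug seizure, at the magnitudes of the published 2017 ratios)
_OHIO_THETA = {
    "fentanyl": 0.393,
    "cocaine": 0.044,
    "prescription_opioids": 0.059,
    "heroin": 0.044,
    "amphetamines": 0.009,
    "benzodiazepines": 0.005,
}

#: expected primary-seizure volume in the 2017 reference year
_OHIO_BASE_INTENSITY = {
    "fentanyl": 9000.0,
    "cocaine": 13000.0,
    "prescription_opioids": 5000.0,
    "heroin": 6000.0,
    "amphetamines": 13000.0,
    "benzodiazepines": 8000.0,
}

#: per-drug availability trend multipliers, 2009→2018: fentanyl emerges late
#: and sharply, heroin rises then recedes, prescription opioids decline,
#: stimulants climb, benzodiazepines stay flat
_OHIO_TREND = {
    "fentanyl": (0.01, 0.02, 0.03, 0.05, 0.08, 0.18, 0.40, 0.70, 1.00, 1.05),
    "cocaine": (0.70, 0.68, 0.65, 0.65, 0.70, 0.75, 0.80, 0.90, 1.00, 1.02),
    "prescription_opioids": (1.30, 1.35, 1.30, 1.25, 1.20, 1.10, 1.05, 1.00, 1.00, 0.90),
    "heroin": (0.50, 0.60, 0.75, 0.90, 1.05, 1.15, 1.20, 1.10, 1.00, 0.85),
    "amphetamines": (0.25, 0.28, 0.32, 0.38, 0.45, 0.55, 0.65, 0.80, 1.00, 1.10),
    "benzodiazepines": (1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 0.95),
}

#: co-occurrence weights: opioids dominate mixed exhibits
_OHIO_MIX_WEIGHTS = {
    "fentanyl": 4.0,
    "cocaine": 2.0,
    "prescription_opioids": 1.0,
    "heroin": 2.0,
    "amphetamines": 1.5,
    "benzodiazepines": 1.0,
}

OHIO_YEARS = tuple(range(2009, 2019))
OHIO_REFERENCE_YEAR = 2017


def ohio2017_like(seed: int = 0, scale: float = 1.0) -> MarketParams:
    """Market preset at the magnitudes of the 2017 Ohio application.

    Six analytic drugs over 2009–2018, reference-year single-seizure volumes
    in the thousands, lethality at the published ratio magnitudes, half of
    all exhibits mixed, and death totals following the sqrt-scale linear
    model (a=12, b=0.0095, noise_sd=0.3).

    ``scale`` shrinks the whole market proportionally for reduced-size runs:
    seizure intensities are multiplied by ``scale`` and the sqrt-model
    coefficients become (a·√scale, b/√scale) so that annual death totals
    also shrink by ``scale`` and stay above the mechanistic single-drug
    deaths at every scale.
    """
    intensity = {
        (d, y): _OHIO_BASE_INTENSITY[d] * _OHIO_TREND[d][i] * scale
        for d in ANALYTIC_CATEGORIES
        for i, y in enumerate(OHIO_YEARS)
    }
    root_s = float(np.sqrt(scale))
    return MarketParams(
        drugs=ANALYTIC_CATEGORIES,
        years=OHIO_YEARS,
        seizure_intensity=intensity,
        true_lethality=dict(_OHIO_THETA),
        p_mixed=0.5,
        p_third=0.2,
        mix_weights=dict(_OHIO_MIX_WEIGHTS),
        deaths_model="linear_sqrt",
        linear_sqrt=(12.0 * root_s, 0.0095 / root_s, 0.3),
        rng_seed=seed,
    )


PRESETS = {"ohio2017-like": ohio2017_like}


def write_market(
    seizures: Sequence[SeizureRecord],
    deaths: Sequence[DeathRecord],
    log: GeneratorLog,
    params: MarketParams,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the generated market in the CSV dialects the readers consume.

    Emits ``seizures.csv``, ``deaths.csv``, a ``generator_log.csv`` of the
    ground-truth tallies, and a ``params.json`` echo for provenance.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "seizures": out / "seizures.csv",
        "deaths": out / "deaths.csv",
        "generator_log": out / "generator_log.csv",
        "params": out / "params.json",
    }
    write_seizures(seizures, paths["seizures"])
    write_deaths(deaths, paths["deaths"])
    with open(paths["generator_log"], "w") as fh:
        fh.write("drug,year,single_seizures,mixed_seizures,all_seizures,single_deaths\n")
        for drug in params.drugs:
            for year in params.years:
                fh.write(
                    f"{drug},{year},{log.single_seizures.get((drug, year), 0)},"
                    f"{log.mixed_seizures.get((drug, year), 0)},"
                    f"{log.all_seizures.get((drug, year), 0)},"
                    f"{log.single_deaths.get((drug, year), 0)}\n"
                )
    with open(paths["params"], "w") as fh:
        json.dump(params.to_dict(), fh, indent=2, sort_keys=True)
    return paths
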