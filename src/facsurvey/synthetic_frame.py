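"""Synthetic census frame and response generator for an HIV-care facility survey.

Emulates an establishment survey of ~1022 HIV care facilities: a census frame
with administrative ("minimal dataset") covariates, a contact-information
completeness status, a logistic response-propensity mechanism for the full
survey, an abbreviated nonresponse follow-up (NRFU) instrument covering a
subset of the analytic items, and item-level missingness.  Every downstream
stage (status coding, rates, bias contrasts, weighting, imputation) runs on
the tables produced here.

The response mechanism is missing-at-random given the Ryan White funding
covariates by construction: the full-survey completion probability is a
logistic function of the configured covariates, so weighting classes built
from those covariates can correct the nonresponse exactly in expectation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy.optimize import brentq
from scipy.special import expit, logit

from .errors import ConfigurationError

# --------------------------------------------------------------------------
# Constants: covariates, weighting classes, default instrument
# --------------------------------------------------------------------------

#: Minimal-dataset covariates usable in propensity models and item effects.
COVARIATES = (
    "rw_any", "rw_a", "rw_b", "rw_c", "rw_d", "rw_f",
    "hpsa", "mua", "rucc", "n_abstractions",
)

#: Ryan White cross-class label -> (rw_any, rw_a, rw_f) cell.
CLASS_DEFS: dict[str, tuple[int, int, int]] = {
    "rw_af": (1, 1, 1),     # funded overall, Part A and Part F
    "rw_a_only": (1, 1, 0),
    "rw_f_only": (1, 0, 1),
    "no_rw": (0, 0, 0),
}

#: Default class populations, N_c = r_c x w_c from the published final-weight
#: distribution (94x1.0000, 96x1.8229, 67x2.5522, 198x2.9394); sum = 1022.
DEFAULT_CLASS_SIZES: dict[str, int] = {
    "rw_af": 94, "rw_a_only": 175, "rw_f_only": 171, "no_rw": 582,
}

#: Class response probabilities implied by the final-weight distribution
#: (r_c / N_c); the all-respondent class is smoothed to 0.97 because a
#: logistic mechanism cannot produce probability 1.
_CLASS_RESPONSE_TARGETS = {
    "rw_af": 0.97,
    "rw_a_only": 96 / 175,
    "rw_f_only": 67 / 171,
    "no_rw": 198 / 582,
}

CONTINUOUS_ITEM = "patient_load"  # annual HIV patient load

_PROJECT_AREAS = [
    "CA", "LAC", "SF", "DE", "FL", "GA", "IL", "CHI", "IN", "MI", "MS",
    "NJ", "NY", "NYC", "NC", "OR", "PA", "PHL", "PR", "TX", "HOU", "VA", "WA",
]

_DEFAULT_CONTACT_MARGINALS = {"complete": 960, "partial": 58, "missing": 4}


def _solve_propensity_defaults() -> dict[str, float]:
    """Exactly identify the saturated 4-cell logistic from the class targets."""
    b0 = logit(_CLASS_RESPONSE_TARGETS["no_rw"])
    # rw_a_only cell: b0 + b_any + b_a ; rw_f_only: b0 + b_any + b_f ;
    # rw_af: b0 + b_any + b_a + b_f.
    l_af = logit(_CLASS_RESPONSE_TARGETS["rw_af"])
    l_a = logit(_CLASS_RESPONSE_TARGETS["rw_a_only"])
    l_f = logit(_CLASS_RESPONSE_TARGETS["rw_f_only"])
    b_f = l_af - l_a
    b_any = l_f - b0 - b_f
    b_a = l_a - b0 - b_any
    return {"intercept": float(b0), "rw_any": float(b_any),
            "rw_a": float(b_a), "rw_f": float(b_f)}


def _default_items() -> tuple[dict[str, float], dict[str, dict[str, float]], list[str]]:
    """Default analytic instrument: 34 shared binary items + the continuous
    patient-load item on the NRFU (35 items), plus 5 full-only binary items.

    Prevalences for four items are pinned to the full-survey estimates the
    weighting/bias stages are calibrated against; the rest default to 0.5.
    Every item carries a Ryan White covariate effect so that nonresponse is
    informative for every item (the condition the weighting stage corrects).
    """
    prevalences: dict[str, float] = {}
    pinned = {"q01": 0.7703, "q02": 0.3154, "q03": 0.0265, "q04": 0.0244}
    for i in range(1, 35):
        item = f"q{i:02d}"
        prevalences[item] = pinned.get(item, 0.5)
    for i in range(36, 41):  # full-only items
        prevalences[f"q{i:02d}"] = 0.5
    cycle = ("rw_a", "rw_f", "rw_any")
    effects = {item: {cycle[k % 3]: 1.0}
               for k, item in enumerate(sorted(prevalences))}
    nrfu_items = [f"q{i:02d}" for i in range(1, 35)] + [CONTINUOUS_ITEM]
    return prevalences, effects, nrfu_items


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

class SimulationConfig(BaseModel):
    """Validated parameter set for one synthetic survey draw.

    All probabilities are in [0, 1]; ``class_sizes`` must sum to
    ``n_facilities``; propensity coefficients are on the log-odds scale and
    may reference only known covariates (plus ``intercept``).
    """

    n_facilities: int = Field(default=1022, ge=0)
    class_sizes: dict[str, int] = Field(default_factory=lambda: dict(DEFAULT_CLASS_SIZES))
    contact_marginals: dict[str, int] = Field(
        default_factory=lambda: dict(_DEFAULT_CONTACT_MARGINALS))
    propensity_coefficients: dict[str, float] = Field(
        default_factory=_solve_propensity_defaults)
    item_prevalences: dict[str, float] = Field(
        default_factory=lambda: _default_items()[0])
    item_effects: dict[str, dict[str, float]] = Field(
        default_factory=lambda: _default_items()[1])
    nrfu_items: list[str] = Field(default_factory=lambda: _default_items()[2])
    nrfu_takeup: float = Field(default=0.1048, ge=0.0, le=1.0)
    access_only_rate: float = Field(default=0.067, ge=0.0, le=1.0)
    partial_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    item_missing_rate: float = Field(default=0.05, ge=0.0, le=1.0)
    patient_load_meanlog: float = 4.3
    patient_load_sdlog: float = Field(default=0.9, gt=0.0)
    patient_load_effects: dict[str, float] = Field(
        default_factory=lambda: {"rw_a": 0.5, "rw_any": 0.4})
    seed: int = 1

    @field_validator("item_prevalences")
    @classmethod
    def _check_prevalences(cls, v: dict[str, float]) -> dict[str, float]:
        for item, p in v.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"item_prevalences[{item!r}]={p} outside [0, 1]")
        return v

    @field_validator("class_sizes")
    @classmethod
    def _check_classes(cls, v: dict[str, int]) -> dict[str, int]:
        for label, n in v.items():
            if label not in CLASS_DEFS:
                raise ValueError(f"class_sizes: unknown class label {label!r}")
            if n < 0:
                raise ValueError(f"class_sizes[{label!r}]={n} is negative")
        return v

    @model_validator(mode="after")
    def _check_consistency(self) -> "SimulationConfig":
        total = sum(self.class_sizes.values())
        if total != self.n_facilities:
            raise ValueError(
                f"class_sizes sum to {total}, expected n_facilities={self.n_facilities}")
        for name in self.propensity_coefficients:
            if name != "intercept" and name not in COVARIATES:
                raise ValueError(
                    f"propensity_coefficients: unknown covariate {name!r}")
        for item, eff in self.item_effects.items():
            for name in eff:
                if name not in COVARIATES:
                    raise ValueError(
                        f"item_effects[{item!r}]: unknown covariate {name!r}")
        if sum(self.contact_marginals.get(k, 0) for k in ("complete", "partial", "missing")) \
                != sum(self.contact_marginals.values()):
            raise ValueError("contact_marginals: keys must be complete/partial/missing")
        return self


def default_config(**overrides) -> SimulationConfig:
    """Return the default study configuration, optionally overridden.

    ``n_facilities`` overrides rescale the class sizes proportionally
    (largest-remainder rounding) unless ``class_sizes`` is also given.
    """
    if "n_facilities" in overrides and "class_sizes" not in overrides:
        n = overrides["n_facilities"]
        overrides["class_sizes"] = _scale_counts(DEFAULT_CLASS_SIZES, n)
    try:
        return SimulationConfig(**overrides)
    except ValueError as exc:  # pydantic ValidationError subclasses ValueError
        raise ConfigurationError(str(exc)) from exc


def load_config(path) -> SimulationConfig:
    """Load and validate a YAML or JSON configuration document."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)  # YAML is a superset of JSON
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigurationError(f"config document {path} is not a mapping")
    return default_config(**doc)


def config_json_schema() -> dict:
    """JSON schema the configuration documents are validated against."""
    return SimulationConfig.model_json_schema()


def _scale_counts(counts: Mapping[str, int], n: int) -> dict[str, int]:
    """Scale integer marginals to total n by largest remainder."""
    total = sum(counts.values())
    if total == 0 or n == 0:
        return {k: 0 for k in counts}
    keys = list(counts)
    exact = np.array([counts[k] * n / total for k in keys])
    base = np.floor(exact).astype(int)
    short = n - int(base.sum())
    order = np.argsort(-(exact - base), kind="stable")
    for i in order[:short]:
        base[i] += 1
    return {k: int(b) for k, b in zip(keys, base)}


# --------------------------------------------------------------------------
# Frame generation
# --------------------------------------------------------------------------

def generate_frame(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate the synthetic census frame.

    One row per facility with columns: facility_id, project_area,
    contact_status (complete/partial/missing), the Ryan White funding
    indicators rw_any/rw_a/rw_b/rw_c/rw_d/rw_f, hpsa, mua, rucc (ordinal
    1-3 metro, 4 = collapsed nonmetro), and n_abstractions.

    Contact-status counts follow the configured marginals (defaults
    960/58/4, scaled proportionally for other frame sizes); Ryan White
    cross-class counts match ``class_sizes`` exactly.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_facilities
    rows = []
    for label, size in config.class_sizes.items():
        any_, a, f = CLASS_DEFS[label]
        rows.append(pd.DataFrame({
            "rw_class": label, "rw_any": any_, "rw_a": a, "rw_f": f,
        }, index=range(size)))
    frame = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["rw_class", "rw_any", "rw_a", "rw_f"])
    if len(frame) != n:  # defensive; config validation enforces this
        raise ConfigurationError("class_sizes do not sum to n_facilities")
    if n == 0:
        return pd.DataFrame(columns=[
            "facility_id", "project_area", "contact_status", "rw_any", "rw_a",
            "rw_b", "rw_c", "rw_d", "rw_f", "hpsa", "mua", "rucc",
            "n_abstractions"])

    frame = frame.iloc[rng.permutation(n)].reset_index(drop=True)
    frame.insert(0, "facility_id", [f"F{i:04d}" for i in range(1, n + 1)])
    frame.insert(1, "project_area", rng.choice(_PROJECT_AREAS, size=n))

    contact_counts = _scale_counts(config.contact_marginals, n)
    status = np.repeat(
        ["complete", "partial", "missing"],
        [contact_counts.get("complete", 0), contact_counts.get("partial", 0),
         contact_counts.get("missing", 0)])
    frame.insert(2, "contact_status", status[rng.permutation(n)])

    # Parts B/C/D only arise for facilities with any Ryan White funding.
    for part, p in (("rw_b", 0.30), ("rw_c", 0.35), ("rw_d", 0.15)):
        frame[part] = (rng.random(n) < p).astype(int) * frame["rw_any"]
    frame["hpsa"] = (rng.random(n) < 0.35).astype(int)
    frame["mua"] = (rng.random(n) < 0.40).astype(int)
    # rucc: metro codes 1-3 kept distinct, nonmetro 4-9 collapsed to 4.
    frame["rucc"] = rng.choice([1, 2, 3, 4], size=n, p=[0.60, 0.15, 0.10, 0.15])
    frame["n_abstractions"] = 1 + rng.poisson(4.0, size=n)
    cols = ["facility_id", "project_area", "contact_status", "rw_any", "rw_a",
            "rw_b", "rw_c", "rw_d", "rw_f", "hpsa", "mua", "rucc",
            "n_abstractions"]
    return frame[cols]


def covariate_matrix(frame: pd.DataFrame, names) -> np.ndarray:
    """Numeric design matrix (no intercept) for the named covariates."""
    for name in names:
        if name not in COVARIATES:
            raise ConfigurationError(f"unknown covariate {name!r}")
    return frame[list(names)].to_numpy(dtype=float)


def data_dictionary(config: SimulationConfig) -> pd.DataFrame:
    """Analytic-item dictionary: item_id, type (binary/continuous), on_nrfu.

    Row order defines the canonical item processing order for imputation.
    """
    items = sorted(config.item_prevalences) + [CONTINUOUS_ITEM]
    return pd.DataFrame({
        "item_id": items,
        "type": ["binary"] * (len(items) - 1) + ["continuous"],
        "on_nrfu": [it in config.nrfu_items for it in items],
    })


# --------------------------------------------------------------------------
# Latent item truth
# --------------------------------------------------------------------------

def _calibrated_intercept(offsets: np.ndarray, target: float) -> float:
    """Intercept b0 with mean(expit(b0 + offsets)) == target (population-
    calibrated prevalence despite covariate effects)."""
    if target <= 0.0:
        return -np.inf
    if target >= 1.0:
        return np.inf
    lo, hi = logit(target) - np.max(offsets) - 1, logit(target) - np.min(offsets) + 1
    return brentq(lambda b: expit(b + offsets).mean() - target, lo, hi)


def draw_item_truth(frame: pd.DataFrame, config: SimulationConfig,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Latent item values for every frame facility (response-independent).

    Binary items follow a logistic model in the configured covariates with
    the intercept calibrated so the population prevalence equals the
    configured target; patient load is log-normal with log-scale covariate
    shifts.
    """
    n = len(frame)
    truth = pd.DataFrame(index=frame.index)
    for item in sorted(config.item_prevalences):
        target = config.item_prevalences[item]
        eff = config.item_effects.get(item, {})
        if eff and 0.0 < target < 1.0:
            offsets = covariate_matrix(frame, list(eff)) @ np.array(list(eff.values()))
            b0 = _calibrated_intercept(offsets, target)
            p = expit(b0 + offsets)
        else:
            p = np.full(n, target)
        truth[item] = (rng.random(n) < p).astype(float)
    eff = config.patient_load_effects
    mu = np.full(n, config.patient_load_meanlog)
    if eff:
        mu = mu + covariate_matrix(frame, list(eff)) @ np.array(list(eff.values()))
    truth[CONTINUOUS_ITEM] = np.exp(rng.normal(mu, config.patient_load_sdlog))
    return truth


# --------------------------------------------------------------------------
# Response simulation
# --------------------------------------------------------------------------

def full_response_probability(frame: pd.DataFrame, config: SimulationConfig) -> np.ndarray:
    """Per-facility full-survey completion probability under the configured
    logistic propensity; facilities with no contact information get 0."""
    coefs = dict(config.propensity_coefficients)
    b0 = coefs.pop("intercept", 0.0)
    eta = np.full(len(frame), float(b0))
    if coefs:
        eta = eta + covariate_matrix(frame, list(coefs)) @ np.array(list(coefs.values()))
    p = expit(eta)
    p[frame["contact_status"].to_numpy() == "missing"] = 0.0
    return p


@dataclass
class SurveyData:
    """One complete synthetic draw: frame, latent truth, responses, dictionary."""
    config: SimulationConfig
    frame: pd.DataFrame
    truth: pd.DataFrame
    responses: pd.DataFrame
    dictionary: pd.DataFrame


def simulate_responses(frame: pd.DataFrame, config: SimulationConfig,
                       rng: np.random.Generator | None = None,
                       truth: pd.DataFrame | None = None) -> pd.DataFrame:
    """Simulate instrument outcomes and item answers for every frame facility.

    Mechanism: full-survey completion ~ Bernoulli(logistic propensity);
    remaining contactable facilities complete the NRFU with probability
    ``nrfu_takeup``; of the rest, a fraction ``access_only_rate`` access a
    survey but give no valid responses (address verification only); everyone
    else is a noncontact.  Facilities missing all contact information never
    respond.  Item answers are the latent truth with independent item-level
    missingness at ``item_missing_rate``; NRFU records carry only the NRFU
    item subset.
    """
    if frame["facility_id"].duplicated().any():
        from .errors import DataError
        raise DataError("duplicate facility_id in frame")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = len(frame)
    if truth is None:
        truth = draw_item_truth(frame, config, rng)
    dictionary = data_dictionary(config)
    items = dictionary["item_id"].tolist()
    nrfu_set = set(config.nrfu_items)

    p_full = full_response_probability(frame, config)
    u = rng.random(n)
    full = u < p_full
    contactable = frame["contact_status"].to_numpy() != "missing"
    nrfu = (~full) & contactable & (rng.random(n) < config.nrfu_takeup)
    access_only = (~full) & (~nrfu) & contactable & (rng.random(n) < config.access_only_rate)
    # Optional break-offs: demote a fraction of full completes to partials
    # (accessed, >=1 valid response, no complete flag).
    partial = full & (rng.random(n) < config.partial_rate)
    full = full & ~partial

    resp = pd.DataFrame({"facility_id": frame["facility_id"].to_numpy()})
    instrument = np.where(full | partial, "full", np.where(nrfu, "nrfu", "none"))
    instrument = np.where(access_only, "full", instrument)  # accessed full survey
    resp["instrument"] = np.where(full | partial | nrfu | access_only, instrument, "none")
    mode = np.full(n, "none", dtype=object)
    mode[full | partial | access_only] = rng.choice(
        ["web", "mail", "phone"], size=int((full | partial | access_only).sum()),
        p=[253 / 455, 201 / 455, 1 / 455])
    mode[nrfu] = "web"
    resp["mode"] = mode
    resp["completed"] = full | nrfu
    resp["accessed"] = full | partial | nrfu | access_only
    resp["address_verified_only"] = access_only

    values = np.full((n, len(items)), np.nan)
    observed = rng.random((n, len(items))) >= config.item_missing_rate
    for j, item in enumerate(items):
        col = truth[item].to_numpy(dtype=float)
        take_full = (full | partial) & observed[:, j]
        take_nrfu = nrfu & observed[:, j] & (item in nrfu_set)
        take = take_full | take_nrfu
        values[take, j] = col[take]
    # a "complete" with zero valid responses is incoherent; force one answer
    ncols = np.sum(~np.isnan(values), axis=1)
    fix = (full | nrfu) & (ncols == 0)
    if fix.any():
        for i in np.flatnonzero(fix):
            j = items.index(sorted(nrfu_set)[0]) if nrfu[i] else 0
            values[i, j] = truth[items[j]].iloc[i]
    # partials keep at most a random prefix of answers, never a complete flag
    if partial.any():
        for i in np.flatnonzero(partial):
            keep = rng.integers(1, max(2, len(items) // 3))
            idx = np.flatnonzero(~np.isnan(values[i]))
            values[i, idx[keep:]] = np.nan
    for j, item in enumerate(items):
        resp[item] = values[:, j]
    resp["valid_response_count"] = np.sum(~np.isnan(values), axis=1).astype(int)
    return resp


def simulate_survey(config: SimulationConfig | None = None, seed: int | None = None) -> SurveyData:
    """Draw one full synthetic survey (frame, truth, responses, dictionary).

    A single generator seeded from ``seed`` (default: config.seed) drives
    every stochastic step, so identical seed + config give byte-identical
    tables.
    """
    if config is None:
        config = default_config()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    frame = generate_frame(config, rng)
    truth = draw_item_truth(frame, config, rng)
    responses = simulate_responses(frame, config, rng, truth=truth)
    return SurveyData(config, frame, truth, responses, data_dictionary(config))


# --------------------------------------------------------------------------
# CSV output
# --------------------------------------------------------------------------

def write_tables(data: SurveyData, out_dir) -> dict[str, str]:
    """Write frame, responses and data dictionary as CSV (missing = empty
    field). Returns {name: path}."""
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (("frame", data.frame), ("responses", data.responses),
                     ("data_dictionary", data.dictionary)):
        path = out / f"{name}.csv"
        df.to_csv(path, index=False, na_rep="")
        paths[name] = str(path)
    (out / "config.json").write_text(
        json.dumps(data.config.model_dump(), indent=2, sort_keys=True))
    paths["config"] = str(out / "config.json")
    return paths
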