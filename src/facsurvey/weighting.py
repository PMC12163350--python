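"""Nonresponse weighting: covariate screening, class adjustment, diagnostics.

The frame is a census, so every facility starts with base weight 1.  A
logistic response-propensity model screens the candidate minimal-dataset
covariates by backward elimination (drop the largest Wald p > alpha until
all survivors are at or below alpha).  The surviving covariates are
cross-classified into weighting cells; within cell c every respondent's
weight is inflated by N_c / r_c, nonrespondents get final weight 0, so the
final weights sum back to the frame size.  The unequal weighting effect
UWE = n * sum(w^2) / (sum w)^2 over the n positive weights measures the
variance inflation from weight variability, and n / UWE is the effective
sample size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DataError

logger = logging.getLogger(__name__)


def backward_eliminate(response_indicator, candidates: pd.DataFrame,
                       alpha: float = 0.05) -> list[str]:
    """Backward elimination on a logistic response-propensity model.

    Repeatedly fits response ~ candidates and removes the single covariate
    with the largest Wald p-value above ``alpha``; stops when every
    remaining covariate has p <= alpha.  Covariates on which the fit fails
    (separation, non-convergence) are dropped with a warning.  Returns the
    survivors in their original column order.
    """
    if candidates.shape[1] == 0:
        raise DataError("backward_eliminate needs at least one candidate covariate")
    y = np.asarray(response_indicator, dtype=float)
    remaining = list(candidates.columns)
    while remaining:
        X = sm.add_constant(candidates[remaining].astype(float), has_constant="add")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            pvals = fit.pvalues.drop("const")
            if not np.all(np.isfinite(pvals)):
                raise ValueError("non-finite Wald p-values")
        except Exception as exc:  # separation / convergence failure
            # drop the most recently added (last) covariate and keep going
            dropped = remaining.pop()
            logger.warning("propensity fit failed (%s); dropping %r", exc, dropped)
            continue
        worst = pvals.idxmax()
        if pvals[worst] > alpha:
            remaining.remove(worst)
        else:
            break
    return [c for c in candidates.columns if c in remaining]


def class_adjust(frame: pd.DataFrame, respondent_ids,
                 class_variables: list[str]) -> pd.DataFrame:
    """Weighting-class nonresponse adjustment over the cross-classification.

    Returns one WeightRecord row per frame facility: facility_id,
    base_weight (1.0, census), adjustment (N_c / r_c for respondents, 0
    otherwise) and final_weight.  Cells that contain facilities but no
    respondents are collapsed by dropping class variables from the end of
    ``class_variables`` for the affected cells (merging them with every cell
    sharing the shorter prefix) until each populated cell has a respondent;
    if collapsing exhausts all levels with still no respondent anywhere, a
    DataError lists the class.
    """
    respondent_ids = set(respondent_ids)
    if not respondent_ids:
        raise DataError("class_adjust: empty respondent set")
    unknown = respondent_ids - set(frame["facility_id"])
    if unknown:
        raise DataError(f"class_adjust: respondent ids not on frame: {sorted(unknown)[:5]}")
    is_resp = frame["facility_id"].isin(respondent_ids).to_numpy()

    # per-record class key; collapsing truncates the key for affected records
    if class_variables:
        keys = [tuple(row) for row in frame[class_variables].itertuples(index=False)]
    else:  # no class variables: the whole frame is one adjustment cell
        keys = [() for _ in range(len(frame))]
    level = len(class_variables)
    while True:
        resp_keys = {k for k, r in zip(keys, is_resp) if r}
        bad = sorted({k for k in keys if k not in resp_keys}, key=repr)
        if not bad:
            break
        if level == 0:
            raise DataError(f"class with facilities but no respondents: {bad[0]!r}")
        level -= 1
        bad_prefixes = {k[:level] for k in bad}
        keys = [k[:level] if k[:level] in bad_prefixes else k for k in keys]
        logger.info("collapsed %d donor-free weighting cell(s) to prefix length %d",
                    len(bad_prefixes), level)

    key_series = pd.Series(keys, index=frame.index)
    n_c = key_series.map(key_series.value_counts())
    r_c = key_series.map(key_series[is_resp].value_counts())
    adjustment = np.where(is_resp, n_c / r_c, 0.0)
    return pd.DataFrame({
        "facility_id": frame["facility_id"].to_numpy(),
        "base_weight": 1.0,
        "adjustment": adjustment,
        "final_weight": 1.0 * adjustment,
    })


@dataclass(frozen=True)
class WeightDiagnostics:
    """Unequal weighting effect and effective sample size."""
    n_respondents: int
    uwe: float          # n * sum(w^2) / (sum w)^2, >= 1 by Cauchy-Schwarz
    effective_n: float  # n / uwe


def weight_diagnostics(weights) -> WeightDiagnostics:
    """UWE and effective n over the positive weights."""
    w = np.asarray(weights, dtype=float)
    w = w[w > 0]
    if len(w) == 0:
        raise DataError("weight_diagnostics: no positive weights")
    n = len(w)
    uwe = n * np.sum(w ** 2) / np.sum(w) ** 2
    return WeightDiagnostics(n, float(uwe), float(n / uwe))
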