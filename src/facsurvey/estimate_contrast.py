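"""Weighted (respondent-only) vs imputed (all-facility) estimates.

The weighted route estimates each item from the full-survey respondents with
their nonresponse-adjusted final weights (Hajek ratio mean, Taylor-linearized
SE treating the weights as fixed).  The imputed route treats the fully
imputed frame as observed respondent data: simple-random-sampling formulas
with weight 1 per facility.  The contrast (imputed - weighted) uses a
conservative independent-samples Wald SE; because the imputed dataset
contains the respondents, the true contrast variance is smaller, so the
resulting p-values overstate differences' uncertainty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

logger = logging.getLogger(__name__)

_Z95 = 1.959963984540054


def weighted_estimate(item_values, weights, item_type: str = "binary"
                      ) -> tuple[float, float]:
    """Hajek weighted mean and linearized SE for one item.

    Binary items are reported on the percent scale.  Records with missing
    values are dropped along with their weights (complete-case per item).
    The SE is the with-replacement Taylor linearization of the ratio mean,
    sqrt(n/(n-1) * sum(w_i^2 (y_i - ybar_w)^2) / (sum w)^2), with the
    weights treated as fixed.
    """
    y = np.asarray(item_values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if len(y) != len(w):
        raise DataError("weighted_estimate: values and weights misaligned")
    keep = ~np.isnan(y) & (w > 0)
    y, w = y[keep], w[keep]
    if len(y) == 0 or w.sum() <= 0:
        raise DataError("weighted_estimate: no positive-weight observations")
    est = np.sum(w * y) / np.sum(w)
    n = len(y)
    if n > 1:
        resid = w * (y - est)
        var = (n / (n - 1)) * np.sum(resid ** 2) / np.sum(w) ** 2
    else:
        var = 0.0
    scale = 100.0 if item_type == "binary" else 1.0
    return float(scale * est), float(scale * np.sqrt(var))


def srs_estimate(item_values, item_type: str = "binary") -> tuple[float, float]:
    """Unweighted mean and simple-random-sampling SE (the imputed route)."""
    y = np.asarray(item_values, dtype=float)
    y = y[~np.isnan(y)]
    if len(y) == 0:
        raise DataError("srs_estimate: no observations")
    n = len(y)
    est = y.mean()
    if item_type == "binary":
        var = est * (1 - est) / n
        return float(100 * est), float(100 * np.sqrt(var))
    var = y.var(ddof=1) / n if n > 1 else 0.0
    return float(est), float(np.sqrt(var))


@dataclass(frozen=True)
class EstimatePair:
    """Weighted vs imputed estimate for one item, with their contrast."""
    item_id: str
    item_type: str
    weighted_est: float
    weighted_se: float
    imputed_est: float
    imputed_se: float
    contrast: float      # imputed_est - weighted_est
    contrast_se: float
    ci_low: float
    ci_high: float
    p_value: float
    se_ratio: float      # imputed_se / weighted_se


def compare_estimates(imputed_data: pd.DataFrame, respondent_data: pd.DataFrame,
                      respondent_weights, dictionary: pd.DataFrame
                      ) -> list[EstimatePair]:
    """Compare weighted-respondent and imputed-frame estimates per item.

    ``respondent_data`` holds the (possibly item-missing) full-survey
    respondent rows aligned with ``respondent_weights``; ``imputed_data``
    the fully imputed frame.  Items absent from either side are skipped
    with a log entry.
    """
    w = np.asarray(respondent_weights, dtype=float)
    pairs: list[EstimatePair] = []
    for spec in dictionary.to_dict("records"):
        item, item_type = spec["item_id"], spec["type"]
        if item not in imputed_data.columns or item not in respondent_data.columns:
            logger.warning("item %s missing on one side; skipped", item)
            continue
        w_est, w_se = weighted_estimate(respondent_data[item], w, item_type)
        i_est, i_se = srs_estimate(imputed_data[item], item_type)
        diff = i_est - w_est
        se = float(np.sqrt(w_se ** 2 + i_se ** 2))
        if se > 0:
            p = 2 * stats.norm.sf(abs(diff) / se)
        else:
            p = 1.0 if diff == 0 else 0.0
        pairs.append(EstimatePair(
            item, item_type, w_est, w_se, i_est, i_se, float(diff), se,
            float(diff - _Z95 * se), float(diff + _Z95 * se), float(p),
            float(i_se / w_se) if w_se > 0 else float("inf")))
    return pairs


def comparison_table(pairs: list[EstimatePair]) -> pd.DataFrame:
    cols = ["item_id", "item_type", "weighted_est", "weighted_se",
            "imputed_est", "imputed_se", "contrast", "contrast_se",
            "ci_low", "ci_high", "p_value", "se_ratio"]
    if not pairs:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([{k: getattr(p, k) for k in cols} for p in pairs])


def comparison_summary(pairs: list[EstimatePair]) -> dict:
    """Counts of significant contrasts and the SE-ratio distribution."""
    if not pairs:
        return {"n_items": 0, "n_significant_05": 0, "mean_se_ratio": float("nan"),
                "median_se_ratio": float("nan")}
    ratios = np.array([p.se_ratio for p in pairs])
    return {
        "n_items": len(pairs),
        "n_significant_05": int(sum(p.p_value < 0.05 for p in pairs)),
        "mean_se_ratio": float(ratios.mean()),
        "median_se_ratio": float(np.median(ratios)),
    }
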