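"""Full-survey vs NRFU nonresponse-bias contrasts with familywise control.

For each analytic item shared by the full and NRFU instruments, the two
respondent groups are compared on the proportion answering 1 (binary items)
or the mean (the continuous patient-load item).  Contrasts use the unpooled
(Wald) variance with a normal approximation; items are analysed complete-case
(pairwise deletion), so the combined n varies by item.  The family of tests
is controlled at familywise level alpha by Bonferroni (p < alpha/m, with m
the family size, which may exceed the number of tests actually run) and by
the step-down Holm procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError

logger = logging.getLogger(__name__)


@dataclass
class ContrastResult:
    """Two-group difference for one analytic item, on the percent scale for
    binary items and the raw scale for continuous items."""
    item_id: str
    item_type: str
    est_a: float
    est_b: float
    contrast: float            # est_b - est_a
    n_combined: int            # non-missing responses pooled over both groups
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    significant_bonferroni: bool = field(default=False)
    significant_holm: bool = field(default=False)


@dataclass(frozen=True)
class FamilywiseConfig:
    """Familywise-error control settings: level alpha over a family of m tests."""
    alpha: float = 0.05
    m: int = 35
    method: str = "bonferroni"

    @property
    def bonferroni_threshold(self) -> float:
        return self.alpha / self.m


def contrast_item(group_a_values, group_b_values, item_type: str = "binary",
                  item_id: str = "") -> ContrastResult | None:
    """Contrast (group B - group A) for one item after dropping missing values.

    Binary items: difference of proportions x100 with unpooled variance
    p_a(1-p_a)/n_a + p_b(1-p_b)/n_b; continuous items: difference of means
    with Welch (unpooled) variance.  Two-sided normal p and 95% CI.
    Returns None (with a logged reason) if either group is empty after
    dropping missing values.
    """
    a = np.asarray(group_a_values, dtype=float)
    b = np.asarray(group_b_values, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        logger.warning("item %s skipped: a group is empty after dropping missing",
                       item_id or "<unnamed>")
        return None
    if item_type == "binary":
        pa, pb = a.mean(), b.mean()
        var = pa * (1 - pa) / len(a) + pb * (1 - pb) / len(b)
        est_a, est_b = 100 * pa, 100 * pb
        se = 100 * np.sqrt(var)
    elif item_type == "continuous":
        est_a, est_b = a.mean(), b.mean()
        va = a.var(ddof=1) / len(a) if len(a) > 1 else 0.0
        vb = b.var(ddof=1) / len(b) if len(b) > 1 else 0.0
        se = np.sqrt(va + vb)
    else:
        raise ConfigurationError(f"unknown item_type {item_type!r}")
    diff = est_b - est_a
    if se > 0:
        z = diff / se
        p = 2 * stats.norm.sf(abs(z))
    else:
        p = 1.0 if diff == 0 else 0.0
    half = 1.959963984540054 * se
    return ContrastResult(item_id, item_type, float(est_a), float(est_b),
                          float(diff), len(a) + len(b), float(se),
                          float(diff - half), float(diff + half), float(p))


def adjust_familywise(p_values, config: FamilywiseConfig | None = None
                      ) -> tuple[np.ndarray, np.ndarray, float]:
    """Bonferroni and Holm significance flags for a family of tests.

    Returns (bonferroni_flags, holm_flags, bonferroni_threshold).  The family
    size m may exceed the number of p-values supplied (items dropped for
    missingness still count toward the family); both procedures then use m in
    their denominators, which is conservative.
    """
    if config is None:
        config = FamilywiseConfig()
    if config.m <= 0:
        raise ConfigurationError("FamilywiseConfig.m must be a positive integer")
    p = np.asarray(list(p_values), dtype=float)
    if len(p) > config.m:
        raise ConfigurationError(
            f"family size m={config.m} smaller than number of tests {len(p)}")
    if np.any((p < 0) | (p > 1)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    threshold = config.bonferroni_threshold
    bonf = p < threshold

    holm = np.zeros(len(p), dtype=bool)
    order = np.argsort(p, kind="stable")
    for rank, idx in enumerate(order):
        if p[idx] < config.alpha / (config.m - rank):
            holm[idx] = True
        else:
            break  # step-down: first failure retains all larger p-values
    return bonf, holm, threshold


def bias_report(contrasts: list[ContrastResult],
                config: FamilywiseConfig | None = None) -> pd.DataFrame:
    """Flag every contrast and return the Bonferroni-significant rows.

    Mutates each ContrastResult's significance flags in place; the returned
    table keeps the original item order.
    """
    if config is None:
        config = FamilywiseConfig()
    if not contrasts:
        return _as_frame([])
    bonf, holm, _ = adjust_familywise([c.p_value for c in contrasts], config)
    for c, fb, fh in zip(contrasts, bonf, holm):
        c.significant_bonferroni = bool(fb)
        c.significant_holm = bool(fh)
    return _as_frame([c for c in contrasts if c.significant_bonferroni])


def contrast_table(contrasts: list[ContrastResult]) -> pd.DataFrame:
    """All contrasts as a table (same column layout as the bias report)."""
    return _as_frame(contrasts)


def _as_frame(contrasts: list[ContrastResult]) -> pd.DataFrame:
    cols = ["item_id", "item_type", "est_a", "est_b", "n_combined", "contrast",
            "se", "ci_low", "ci_high", "p_value", "significant_bonferroni",
            "significant_holm"]
    if not contrasts:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([{k: getattr(c, k) for k in cols} for c in contrasts])
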