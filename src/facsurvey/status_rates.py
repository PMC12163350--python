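"""Final status coding and contact / cooperation / response rates.

Every frame facility receives exactly one of four final status groups:

* ``noncontact`` — never accessed either instrument;
* ``noncooperation`` — accessed a survey but produced no valid response
  beyond address verification (break-offs with some valid responses but no
  complete flag are also grouped here, with a ``*_partial`` detail code);
* ``full_respondent`` — at least one valid response and a full-survey
  complete flag;
* ``nrfu_respondent`` — at least one valid response and an NRFU complete flag.

The contact rate is attempters / frame size, the cooperation rate is
completes / attempters (the attempter denominator is shared across groups),
and the response rate is their product.  Rates are kept unrounded; rounding
to display precision is a rendering concern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

STATUSES = ("noncontact", "noncooperation", "full_respondent", "nrfu_respondent")
GROUPS = ("combined", "full_only", "nrfu_only")


def assign_status(responses: pd.DataFrame) -> pd.DataFrame:
    """Assign the final four-group status and six-code detail per facility.

    Expects one response record per facility.  All facilities are eligible;
    there is no ineligible status.
    """
    if responses["facility_id"].duplicated().any():
        dup = responses.loc[responses["facility_id"].duplicated(), "facility_id"].iloc[0]
        raise DataError(f"duplicate facility_id {dup!r} in responses")
    accessed = responses["accessed"].to_numpy(dtype=bool)
    completed = responses["completed"].to_numpy(dtype=bool)
    valid = responses["valid_response_count"].to_numpy(dtype=int)
    instrument = responses["instrument"].to_numpy()

    status = np.full(len(responses), "noncontact", dtype=object)
    detail = np.full(len(responses), "none", dtype=object)

    has_valid = valid >= 1
    full_complete = completed & (instrument == "full") & has_valid
    nrfu_complete = completed & (instrument == "nrfu") & has_valid
    status[accessed] = "noncooperation"
    status[full_complete] = "full_respondent"
    detail[full_complete] = "full_complete"
    status[nrfu_complete] = "nrfu_respondent"
    detail[nrfu_complete] = "nrfu_complete"
    partial = accessed & has_valid & ~completed
    detail[partial & (instrument == "full")] = "full_partial"
    detail[partial & (instrument == "nrfu")] = "nrfu_partial"

    return pd.DataFrame({
        "facility_id": responses["facility_id"].to_numpy(),
        "status": status,
        "detail": detail,
    })


def status_table(statuses: pd.DataFrame) -> pd.DataFrame:
    """Count / percent / cumulative summary by status group."""
    order = pd.CategoricalDtype(STATUSES, ordered=True)
    counts = statuses["status"].astype(order).value_counts().sort_index()
    n = len(statuses)
    out = pd.DataFrame({
        "status": counts.index.astype(str),
        "n": counts.to_numpy(),
        "percent": 100 * counts.to_numpy() / n if n else 0.0,
    })
    out["cumulative_n"] = out["n"].cumsum()
    out["cumulative_percent"] = out["percent"].cumsum()
    return out


@dataclass(frozen=True)
class RateTable:
    """Contact/cooperation/response rates for one respondent group."""
    group: str
    frame_size: int
    n_contact: int          # attempters: accessed either instrument
    contact_rate: float
    n_cooperate: int        # completes in the group's numerator
    cooperation_rate: float
    response_rate: float
    degenerate: bool = False  # True when there were no attempters


def compute_rates(statuses: pd.DataFrame, frame_size: int) -> dict[str, RateTable]:
    """Compute the three rates for combined, full-only and NRFU-only groups.

    Attempters are every facility that accessed either instrument (all
    non-noncontacts, break-offs included); the attempter denominator is
    shared across the three groups.
    """
    if frame_size <= 0:
        raise DataError("frame_size must be positive to define rates")
    counts = statuses["status"].value_counts()
    attempters = int(len(statuses) - counts.get("noncontact", 0))
    n_full = int(counts.get("full_respondent", 0))
    n_nrfu = int(counts.get("nrfu_respondent", 0))
    numerators = {"combined": n_full + n_nrfu, "full_only": n_full, "nrfu_only": n_nrfu}

    out: dict[str, RateTable] = {}
    for group in GROUPS:
        completes = numerators[group]
        if attempters == 0:
            out[group] = RateTable(group, frame_size, 0, 0.0, completes, 0.0, 0.0,
                                   degenerate=True)
            continue
        contact = attempters / frame_size
        cooperation = completes / attempters
        out[group] = RateTable(group, frame_size, attempters, contact,
                               completes, cooperation, contact * cooperation)
    return out


def rates_table(rates: dict[str, RateTable]) -> pd.DataFrame:
    """Flatten the per-group rates into a display table (percent scale)."""
    rows = []
    for group in GROUPS:
        r = rates[group]
        rows.append({
            "group": group,
            "frame_size": r.frame_size,
            "n_contact": r.n_contact,
            "contact_rate_pct": 100 * r.contact_rate,
            "n_cooperate": r.n_cooperate,
            "cooperation_rate_pct": 100 * r.cooperation_rate,
            "response_rate_pct": 100 * r.response_rate,
        })
    return pd.DataFrame(rows)
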