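"""Tree-partitioned weighted sequential hot-deck (WSHD) imputation.

For each analytic item, a CART prediction tree is grown on the donors
(records with the item observed) from the complete administrative
covariates; its terminal nodes, crossed with the Ryan White funding
indicator, form the imputation classes.  Recipients are routed down the same
tree.  If any recipient lands in a class without donors, the minimum node
size is doubled and the tree regrown until every recipient-bearing class has
at least one donor (terminating, in the worst case, at the single-node
tree).  Within each class a deterministic weighted sequential hot deck
allocates donors to recipients: both sides are sorted (Part A funding,
Part F funding, annual patient load; ties by facility id), donor weights are
rescaled so their total matches the recipients' total, and each recipient is
served by the donor whose cumulative-weight interval contains the
recipient's cumulative start point.  With unit recipient weights each
donor's usage count therefore lies within the floor/ceiling of its rescaled
weight.

The three-step cascade imputes (1) item missingness among full-survey
respondents from full-survey donors, (2) NRFU respondents' shared items from
the pooled full+NRFU donors and their full-only items from full-survey
donors, and (3) every item for total nonrespondents from the now-complete
respondent pool.  Full-survey donors carry their final nonresponse-adjusted
weight; all other donors and all recipients carry weight 1.  Observed values
are never overwritten.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .errors import DataError
from .synthetic_frame import CONTINUOUS_ITEM

logger = logging.getLogger(__name__)

#: Predictors for the imputation trees: complete for every frame facility.
DEFAULT_TREE_PREDICTORS = ["rw_any", "rw_a", "rw_b", "rw_c", "rw_d", "rw_f",
                           "hpsa", "mua", "rucc", "n_abstractions"]
#: Auxiliary stratifier crossed with the tree node to form imputation classes.
DEFAULT_CLASS_STRATA = ["rw_any"]
#: WSHD sort order inside a class.
DEFAULT_SORT_VARIABLES = ["rw_a", "rw_f", CONTINUOUS_ITEM]

DEFAULT_MIN_NODE_SIZE = 25
#: Minimum impurity improvement to split, as a fraction of root impurity;
#: keeps no-signal targets in a single node at realistic sample sizes.
MIN_IMPROVEMENT_FRAC = 0.02


# --------------------------------------------------------------------------
# Prediction trees
# --------------------------------------------------------------------------

@dataclass
class ImputationTree:
    """A fitted CART tree whose terminal nodes are imputation classes."""
    target_item: str
    predictors: list[str]
    min_node_size: int
    model: object = field(repr=False)

    def assign(self, X: pd.DataFrame) -> np.ndarray:
        """Terminal-node id for each record."""
        return self.model.apply(X[self.predictors].to_numpy(dtype=float))

    @property
    def n_leaves(self) -> int:
        return int(self.model.get_n_leaves())

    def to_dict(self) -> dict:
        """JSON-serializable structure (split variables, thresholds, children)."""
        t = self.model.tree_
        return {
            "target_item": self.target_item,
            "predictors": self.predictors,
            "min_node_size": self.min_node_size,
            "n_nodes": int(t.node_count),
            "children_left": t.children_left.tolist(),
            "children_right": t.children_right.tolist(),
            "split_variable": [self.predictors[f] if f >= 0 else None
                               for f in t.feature],
            "threshold": [float(x) if f >= 0 else None
                          for f, x in zip(t.feature, t.threshold)],
            "node_size": t.n_node_samples.tolist(),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def build_tree(donors: pd.DataFrame, target_item: str, predictors: list[str],
               min_node_size: int = DEFAULT_MIN_NODE_SIZE,
               target_type: str = "binary") -> ImputationTree:
    """Grow a CART tree on the donors (records with ``target_item`` observed).

    Gini impurity for binary targets, variance reduction for the continuous
    target; splits must improve impurity by at least a fixed fraction of the
    root impurity and leave ``min_node_size`` donors in each terminal node.
    Deterministic given the data (fixed random state breaks exact ties).
    When no admissible split exists, the single-node tree (one class)
    results.
    """
    y = donors[target_item].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise DataError(f"build_tree: donors have missing {target_item!r}")
    X = donors[predictors].to_numpy(dtype=float)
    if target_type == "binary":
        yb = y.astype(int)
        p = yb.mean() if len(yb) else 0.0
        root_impurity = p * (1 - p) * 2 if 0 < p < 1 else 0.0  # gini of root
        cls = DecisionTreeClassifier
        kwargs = {"criterion": "gini"}
        y_fit = yb
    else:
        root_impurity = float(np.var(y)) if len(y) > 1 else 0.0
        cls = DecisionTreeRegressor
        kwargs = {"criterion": "squared_error"}
        y_fit = y
    model = cls(min_samples_leaf=max(1, min_node_size),
                min_impurity_decrease=MIN_IMPROVEMENT_FRAC * root_impurity,
                random_state=0, **kwargs)
    if len(donors) < 2 * min_node_size or root_impurity == 0.0:
        model.set_params(max_depth=1, min_samples_split=max(2, 2 * len(donors)))
    model.fit(X, y_fit)
    return ImputationTree(target_item, list(predictors), min_node_size, model)


def _class_ids(strata: pd.DataFrame, leaves: np.ndarray) -> pd.Series:
    parts = [strata[c].astype(str) for c in strata.columns]
    key = parts[0] if parts else pd.Series("", index=strata.index)
    for p in parts[1:]:
        key = key + "|" + p
    return key + "|node" + pd.Series(leaves.astype(str), index=strata.index)


def ensure_donors(donors: pd.DataFrame, recipients: pd.DataFrame,
                  target_item: str, predictors: list[str],
                  strata: list[str] = DEFAULT_CLASS_STRATA,
                  min_node_size: int = DEFAULT_MIN_NODE_SIZE,
                  target_type: str = "binary"
                  ) -> tuple[ImputationTree, pd.Series, pd.Series]:
    """Build the imputation classes, escalating node size until covered.

    Classes are the cross of ``strata`` and the tree's terminal nodes.  If
    some class contains recipients but no donors, the minimum node size is
    doubled and the tree rebuilt; the escalation terminates at the
    single-node tree, whose classes are the strata alone and always contain
    donors as long as each recipient stratum does.  Returns the final tree
    and the per-record class ids for donors and recipients.
    """
    if len(donors) == 0:
        raise DataError(f"ensure_donors: no donors at all for {target_item!r}")
    size = min_node_size
    while True:
        tree = build_tree(donors, target_item, predictors, size, target_type)
        donor_classes = _class_ids(donors[strata], tree.assign(donors))
        recip_classes = _class_ids(recipients[strata], tree.assign(recipients))
        uncovered = set(recip_classes) - set(donor_classes)
        if not uncovered:
            return tree, donor_classes, recip_classes
        if tree.n_leaves == 1:
            # strata themselves leave a recipient without donors
            raise DataError(
                f"no donors for class(es) {sorted(uncovered)} of {target_item!r}")
        logger.info("item %s: %d donor-free class(es); min node size %d -> %d",
                    target_item, len(uncovered), size, 2 * size)
        size *= 2


# --------------------------------------------------------------------------
# Weighted sequential hot deck
# --------------------------------------------------------------------------

def weighted_sequential_hotdeck(donors: pd.DataFrame, recipients: pd.DataFrame,
                                donor_weights, recipient_weights,
                                sort_variables: list[str],
                                id_col: str = "facility_id") -> pd.DataFrame:
    """Deterministic weighted sequential hot deck within one imputation class.

    Donors and recipients are each sorted by ``sort_variables`` (missing sort
    values last, ties by ``id_col``).  Donor weights are rescaled so their
    total equals the recipients' total; on the cumulative recipient-weight
    axis each donor owns a half-open interval of length equal to its rescaled
    weight, and each recipient is assigned the donor whose interval contains
    the recipient's cumulative start point.  Each donor's usage count
    therefore lies in {floor(e_d), ceil(e_d)} when recipient weights are
    constant, where e_d is the rescaled weight in recipient-weight units.

    Returns a DataFrame (recipient_id, donor_id) in recipient sort order.
    """
    if len(donors) == 0:
        raise DataError("weighted_sequential_hotdeck: no donors")
    dw = np.asarray(donor_weights, dtype=float)
    rw = np.asarray(recipient_weights, dtype=float)
    if len(dw) != len(donors) or len(rw) != len(recipients):
        raise DataError("weights misaligned with donor/recipient tables")
    if np.any(dw <= 0) or np.any(rw <= 0):
        raise DataError("weighted_sequential_hotdeck: nonpositive weight")
    if len(recipients) == 0:
        return pd.DataFrame(columns=["recipient_id", "donor_id"])

    def _order(df: pd.DataFrame) -> np.ndarray:
        cols = [c for c in sort_variables if c in df.columns] + [id_col]
        return df[cols].sort_values(cols, na_position="last",
                                    kind="mergesort").index.to_numpy()

    d_idx = _order(donors)
    r_idx = _order(recipients)
    dw_sorted = pd.Series(dw, index=donors.index).loc[d_idx].to_numpy()
    rw_sorted = pd.Series(rw, index=recipients.index).loc[r_idx].to_numpy()

    total_r = rw_sorted.sum()
    e = dw_sorted * (total_r / dw_sorted.sum())   # rescaled donor allocations
    bounds = np.cumsum(e)                          # donor interval upper bounds
    starts = np.concatenate([[0.0], np.cumsum(rw_sorted)[:-1]])
    assigned = np.searchsorted(bounds, starts, side="right")
    assigned = np.minimum(assigned, len(e) - 1)    # guard float round-off at the end

    donor_ids = donors.loc[d_idx, id_col].to_numpy()
    recip_ids = recipients.loc[r_idx, id_col].to_numpy()
    return pd.DataFrame({"recipient_id": recip_ids,
                         "donor_id": donor_ids[assigned]})


# --------------------------------------------------------------------------
# The three-step cascade
# --------------------------------------------------------------------------

@dataclass
class CascadeResult:
    """Fully imputed dataset plus audit trail."""
    data: pd.DataFrame                      # one row per facility, items complete
    flags: pd.DataFrame                     # observed / imputed_step{1,2,3} per item
    assignments: pd.DataFrame               # recipient_id, donor_id, item_id, step, class_id
    trees: dict[str, list[dict]]            # per item, per step, serialized trees


def _impute_items(data: pd.DataFrame, flags: pd.DataFrame, items: list[dict],
                  donor_mask: np.ndarray, recip_mask: np.ndarray,
                  weights: pd.Series, step: int, predictors: list[str],
                  strata: list[str], sort_variables: list[str],
                  min_node_size: int, records: list, trees: dict,
                  item_groups: list[list[str]] | None = None,
                  observed_only: bool = True) -> None:
    """Impute one batch of items for one cascade step, in dictionary order.

    ``items`` is a list of {item_id, type}; ``item_groups`` optionally lists
    blocks donated jointly from a single donor (skip-pattern families): the
    tree is built on the block's first item and donors must have the whole
    block observed, which keeps intra-block patterns consistent.  With
    ``observed_only`` donors must carry genuinely observed (never previously
    imputed) values; step 3 relaxes this to the imputed respondent pool.
    """
    grouped: dict[str, list[str]] = {}
    if item_groups:
        for block in item_groups:
            for it in block:
                grouped[it] = block
    batch = {s["item_id"] for s in items}
    done: set[str] = set()
    for spec in items:
        item, item_type = spec["item_id"], spec["type"]
        if item in done:
            continue
        block = [b for b in grouped.get(item, [item]) if b in batch]
        done.update(block)
        need = recip_mask & data[block].isna().any(axis=1).to_numpy()
        if not need.any():
            continue
        have = donor_mask & data[block].notna().all(axis=1).to_numpy()
        if observed_only:
            have &= (flags[block] == "observed").all(axis=1).to_numpy()
        if not have.any():
            raise DataError(f"no potential donor has {block!r} observed")
        donors = data.loc[have]
        recips = data.loc[need]
        tree, d_cls, r_cls = ensure_donors(
            donors, recips, item, predictors, strata, min_node_size, item_type)
        trees.setdefault(item, []).append({"step": step, **tree.to_dict()})
        rid_to_idx = pd.Series(recips.index, index=recips["facility_id"])
        for cls in sorted(set(r_cls)):
            d_in = donors.loc[d_cls[d_cls == cls].index]
            r_in = recips.loc[r_cls[r_cls == cls].index]
            pairs = weighted_sequential_hotdeck(
                d_in, r_in, weights.loc[d_in.index].to_numpy(),
                np.ones(len(r_in)), sort_variables)
            donor_lookup = d_in.set_index("facility_id")
            r_idx = rid_to_idx.loc[pairs["recipient_id"]].to_numpy()
            for it in block:
                vals = donor_lookup[it].loc[pairs["donor_id"]].to_numpy()
                fill = data.loc[r_idx, it].isna().to_numpy()  # never overwrite
                data.loc[r_idx[fill], it] = vals[fill]
                flags.loc[r_idx[fill], it] = f"imputed_step{step}"
            records.extend(
                {"recipient_id": rid, "donor_id": did,
                 "item_id": "+".join(block), "step": step, "class_id": cls}
                for rid, did in zip(pairs["recipient_id"], pairs["donor_id"]))


def impute_cascade(data: pd.DataFrame, statuses: pd.DataFrame,
                   weights: pd.DataFrame, dictionary: pd.DataFrame,
                   predictors: list[str] = DEFAULT_TREE_PREDICTORS,
                   strata: list[str] = DEFAULT_CLASS_STRATA,
                   sort_variables: list[str] = DEFAULT_SORT_VARIABLES,
                   min_node_size: int = DEFAULT_MIN_NODE_SIZE,
                   item_groups: list[list[str]] | None = None) -> CascadeResult:
    """Run the three-step imputation cascade to a fully observed dataset.

    ``data`` carries one row per frame facility with the administrative
    predictors (complete) and the analytic item columns (missing where
    unobserved); ``statuses`` the four-group final status; ``weights`` the
    final nonresponse-adjusted weights; ``dictionary`` the item dictionary
    with the NRFU subset flagged.  The cascade is seed-free: identical
    inputs give identical imputations.
    """
    data = data.copy()
    status = statuses.set_index("facility_id")["status"]
    data = data.reset_index(drop=True)
    st = data["facility_id"].map(status).to_numpy()
    full_resp = st == "full_respondent"
    nrfu_resp = st == "nrfu_respondent"
    nonresp = ~(full_resp | nrfu_resp)

    w = weights.set_index("facility_id")["final_weight"]
    donor_w = data["facility_id"].map(w).fillna(0.0)
    donor_w = donor_w.where(donor_w > 0, 1.0)  # weight 1 for non-full-survey donors
    donor_w.index = data.index

    items = dictionary.to_dict("records")
    shared = [s for s in items if s["on_nrfu"]]
    full_only = [s for s in items if not s["on_nrfu"]]
    item_cols = [s["item_id"] for s in items]

    flags = pd.DataFrame("observed", index=data.index, columns=item_cols)
    flags = flags.where(data[item_cols].notna(), "missing")
    records: list[dict] = []
    trees: dict[str, list[dict]] = {}
    common = dict(predictors=predictors, strata=strata,
                  sort_variables=sort_variables, min_node_size=min_node_size,
                  records=records, trees=trees, item_groups=item_groups)

    # Step 1: full respondents' item missingness, full-respondent donors only.
    _impute_items(data, flags, items, donor_mask=full_resp, recip_mask=full_resp,
                  weights=donor_w, step=1, **common)
    # Step 2: NRFU respondents -- shared items from the pooled full+NRFU
    # observed donors, full-only items from full-survey donors.
    _impute_items(data, flags, shared, donor_mask=full_resp | nrfu_resp,
                  recip_mask=nrfu_resp, weights=donor_w, step=2, **common)
    _impute_items(data, flags, full_only, donor_mask=full_resp,
                  recip_mask=nrfu_resp, weights=donor_w, step=2, **common)
    # Step 3: total nonrespondents, donors = the imputed respondent pool.
    _impute_items(data, flags, items, donor_mask=full_resp | nrfu_resp,
                  recip_mask=nonresp, weights=donor_w, step=3,
                  observed_only=False, **common)

    flags = flags.where(flags != "missing", "observed")  # nothing left missing
    assignments = pd.DataFrame(records, columns=["recipient_id", "donor_id",
                                                 "item_id", "step", "class_id"])
    return CascadeResult(data, flags, assignments, trees)
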