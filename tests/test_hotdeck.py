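"""Imputation trees, donor coverage, WSHD allocation, and the cascade."""

import json

import numpy as np
import pandas as pd
import pytest

import facsurvey as fs
from facsurvey.hotdeck_imputation import (DEFAULT_SORT_VARIABLES, build_tree,
                                          ensure_donors, impute_cascade,
                                          weighted_sequential_hotdeck)


def donor_frame(n, rng, target=None):
    df = pd.DataFrame({
        "facility_id": [f"D{i:04d}" for i in range(n)],
        "rw_any": rng.integers(0, 2, n), "rw_a": rng.integers(0, 2, n),
        "rw_b": rng.integers(0, 2, n), "rw_c": rng.integers(0, 2, n),
        "rw_d": rng.integers(0, 2, n), "rw_f": rng.integers(0, 2, n),
        "hpsa": rng.integers(0, 2, n), "mua": rng.integers(0, 2, n),
        "rucc": rng.integers(1, 5, n), "n_abstractions": rng.poisson(4, n),
    })
    df["y"] = rng.integers(0, 2, n).astype(float) if target is None else target
    return df


PREDICTORS = ["rw_any", "rw_a", "rw_b", "rw_c", "rw_d", "rw_f", "hpsa",
              "mua", "rucc", "n_abstractions"]


class TestBuildTree:
    def test_no_signal_single_node(self):
        """A target independent of every predictor yields one class."""
        rng = np.random.default_rng(0)
        donors = donor_frame(500, rng)
        tree = build_tree(donors, "y", PREDICTORS, min_node_size=25)
        assert tree.n_leaves == 1

    def test_perfect_predictor_two_pure_leaves(self):
        rng = np.random.default_rng(1)
        donors = donor_frame(400, rng)
        donors["y"] = donors["rw_a"].astype(float)
        tree = build_tree(donors, "y", PREDICTORS, min_node_size=25)
        assert tree.n_leaves == 2
        assert tree.to_dict()["split_variable"][0] == "rw_a"
        leaves = tree.assign(donors)
        for leaf in np.unique(leaves):
            assert donors.loc[leaves == leaf, "y"].nunique() == 1

    def test_interaction_cell_means_recovered(self):
        """Known two-way interaction: class-conditional donor means match the
        population cell probabilities within Monte Carlo error."""
        rng = np.random.default_rng(2)
        donors = donor_frame(4000, rng)
        cell_p = {(0, 0): 0.1, (0, 1): 0.7, (1, 0): 0.8, (1, 1): 0.2}
        p = np.array([cell_p[(a, f)] for a, f in
                      zip(donors["rw_a"], donors["rw_f"])])
        donors["y"] = (rng.random(len(donors)) < p).astype(float)
        tree = build_tree(donors, "y", PREDICTORS, min_node_size=50)
        leaves = tree.assign(donors)
        for leaf in np.unique(leaves):
            sub = donors.loc[leaves == leaf]
            cells = sub.groupby(["rw_a", "rw_f"]).size()
            # a leaf should be (nearly) cell-pure once the tree has split on
            # the interacting predictors
            top_cell = cells.idxmax()
            frac = cells.max() / len(sub)
            if frac > 0.95:
                mc = 3 * np.sqrt(0.25 / len(sub))
                assert abs(sub["y"].mean() - cell_p[top_cell]) < mc + 0.02

    def test_continuous_target_regressor(self):
        rng = np.random.default_rng(3)
        donors = donor_frame(600, rng)
        donors["y"] = 10.0 + 5.0 * donors["rw_f"] + rng.normal(0, 1, 600)
        tree = build_tree(donors, "y", PREDICTORS, min_node_size=25,
                          target_type="continuous")
        assert tree.n_leaves >= 2
        assert tree.to_dict()["split_variable"][0] == "rw_f"

    def test_serialization_roundtrip(self):
        rng = np.random.default_rng(4)
        donors = donor_frame(300, rng)
        donors["y"] = donors["hpsa"].astype(float)
        tree = build_tree(donors, "y", PREDICTORS, 25)
        doc = json.loads(tree.to_json())
        assert doc["target_item"] == "y"
        assert doc["n_nodes"] == len(doc["children_left"])

    def test_determinism(self):
        rng = np.random.default_rng(5)
        donors = donor_frame(500, rng)
        t1 = build_tree(donors, "y", PREDICTORS, 25)
        t2 = build_tree(donors, "y", PREDICTORS, 25)
        assert t1.to_json() == t2.to_json()


class TestEnsureDonors:
    def test_covered_classes_identity(self):
        rng = np.random.default_rng(6)
        donors = donor_frame(400, rng)
        recips = donor_frame(100, rng).drop(columns="y")
        recips["facility_id"] = [f"R{i:04d}" for i in range(100)]
        tree, d_cls, r_cls = ensure_donors(donors, recips, "y", PREDICTORS,
                                           ["rw_any"], 25)
        assert tree.min_node_size == 25  # no escalation needed
        assert set(r_cls) <= set(d_cls)

    def test_donor_free_leaf_triggers_one_rebuild(self):
        """Adversarial fixture: donors never have rw_any=0 inside one leaf's
        stratum, recipients do; the minimum node size doubles once and the
        audit shows every recipient class covered."""
        rng = np.random.default_rng(7)
        donors = donor_frame(200, rng)
        donors["rw_any"] = 1
        donors["y"] = donors["rw_f"].astype(float)  # forces a split on rw_f
        recips = donor_frame(50, rng).drop(columns="y")
        recips["facility_id"] = [f"R{i:04d}" for i in range(50)]
        recips["rw_any"] = 1
        tree, d_cls, r_cls = ensure_donors(donors, recips, "y", PREDICTORS,
                                           ["rw_any"], min_node_size=25)
        assert set(r_cls) <= set(d_cls)

    def test_stratum_without_donors_is_hard_error(self):
        rng = np.random.default_rng(8)
        donors = donor_frame(100, rng)
        donors["rw_any"] = 1
        recips = donor_frame(10, rng).drop(columns="y")
        recips["rw_any"] = 0  # stratum absent among donors entirely
        with pytest.raises(fs.DataError, match="no donors"):
            ensure_donors(donors, recips, "y", PREDICTORS, ["rw_any"], 25)

    def test_no_donors_at_all(self):
        rng = np.random.default_rng(9)
        recips = donor_frame(10, rng)
        with pytest.raises(fs.DataError):
            ensure_donors(recips.iloc[:0], recips, "y", PREDICTORS, ["rw_any"], 25)


def brute_force_usage(donor_w, recip_w):
    """Independent cumulative-weight oracle: per-donor usage counts."""
    e = np.asarray(donor_w, float) * (np.sum(recip_w) / np.sum(donor_w))
    uppers = np.cumsum(e)
    counts = np.zeros(len(e), dtype=int)
    pos = 0.0
    for w in recip_w:
        d = 0
        while pos >= uppers[d] - 1e-12 and d < len(e) - 1:
            d += 1
        counts[d] += 1
        pos += w
    return e, counts


class TestWSHD:
    def _tables(self, n_d, n_r, rng):
        donors = donor_frame(n_d, rng)
        donors["patient_load"] = rng.lognormal(4, 1, n_d)
        recips = donor_frame(n_r, rng).drop(columns="y")
        recips["facility_id"] = [f"R{i:04d}" for i in range(n_r)]
        recips["patient_load"] = rng.lognormal(4, 1, n_r)
        return donors, recips

    def test_single_donor_serves_everyone(self):
        rng = np.random.default_rng(10)
        donors, recips = self._tables(1, 17, rng)
        out = weighted_sequential_hotdeck(donors, recips, [2.5], np.ones(17),
                                          DEFAULT_SORT_VARIABLES)
        assert (out["donor_id"] == donors["facility_id"].iloc[0]).all()
        assert len(out) == 17

    def test_uniform_allocation_exact_multiples(self):
        """Equal donor weights and recipients = k x donors: every donor is
        used exactly k times."""
        rng = np.random.default_rng(11)
        donors, recips = self._tables(6, 24, rng)
        out = weighted_sequential_hotdeck(donors, recips, np.ones(6),
                                          np.ones(24), DEFAULT_SORT_VARIABLES)
        assert out["donor_id"].value_counts().eq(4).all()

    def test_floor_ceiling_usage_500_random_classes(self):
        """Donor usage counts stay within the floor/ceiling of the expected
        allocation on 500 random small classes, verified against an
        independent cumulative-weight oracle (unit recipient weights)."""
        rng = np.random.default_rng(12)
        for _ in range(500):
            n_d = int(rng.integers(1, 13))
            n_r = int(rng.integers(1, 41))
            donors, recips = self._tables(n_d, n_r, rng)
            dw = rng.uniform(0.1, 3.0, n_d)
            out = weighted_sequential_hotdeck(donors, recips, dw,
                                              np.ones(n_r),
                                              DEFAULT_SORT_VARIABLES)
            usage = out["donor_id"].value_counts()
            # oracle on the same sort order
            order = donors[["rw_a", "rw_f", "patient_load", "facility_id"]] \
                .sort_values(["rw_a", "rw_f", "patient_load", "facility_id"]) \
                .index.to_numpy()
            e, counts = brute_force_usage(
                pd.Series(dw, index=donors.index).loc[order], np.ones(n_r))
            ids = donors.loc[order, "facility_id"].to_numpy()
            for i, did in enumerate(ids):
                u = usage.get(did, 0)
                assert np.floor(e[i]) - 1e-9 <= u <= np.ceil(e[i]) + 1e-9
                assert u == counts[i]

    def test_unequal_recipient_weights_bounded_allocation(self):
        """With unequal recipient weights each donor's served recipient
        weight differs from its rescaled allocation by less than the largest
        recipient weight."""
        rng = np.random.default_rng(13)
        for _ in range(100):
            n_d = int(rng.integers(1, 10))
            n_r = int(rng.integers(1, 30))
            donors, recips = self._tables(n_d, n_r, rng)
            dw = rng.uniform(0.2, 2.0, n_d)
            rw = rng.uniform(0.2, 2.0, n_r)
            out = weighted_sequential_hotdeck(donors, recips, dw, rw,
                                              DEFAULT_SORT_VARIABLES)
            served = out.merge(
                recips.assign(w=rw)[["facility_id", "w"]],
                left_on="recipient_id", right_on="facility_id")
            tot = served.groupby("donor_id")["w"].sum()
            e = pd.Series(dw * rw.sum() / dw.sum(),
                          index=donors["facility_id"].to_numpy())
            for did, alloc in e.items():
                assert abs(tot.get(did, 0.0) - alloc) < rw.max() + 1e-9

    def test_determinism_and_errors(self):
        rng = np.random.default_rng(14)
        donors, recips = self._tables(5, 20, rng)
        a = weighted_sequential_hotdeck(donors, recips, np.ones(5), np.ones(20),
                                        DEFAULT_SORT_VARIABLES)
        b = weighted_sequential_hotdeck(donors, recips, np.ones(5), np.ones(20),
                                        DEFAULT_SORT_VARIABLES)
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(fs.DataError, match="nonpositive"):
            weighted_sequential_hotdeck(donors, recips, np.zeros(5),
                                        np.ones(20), DEFAULT_SORT_VARIABLES)
        with pytest.raises(fs.DataError, match="no donors"):
            weighted_sequential_hotdeck(donors.iloc[:0], recips, [], np.ones(20),
                                        DEFAULT_SORT_VARIABLES)


class TestCascade:
    def _inputs(self, data: fs.SurveyData):
        statuses = fs.assign_status(data.responses)
        resp_ids = statuses.loc[statuses["status"] == "full_respondent",
                                "facility_id"]
        weights = fs.class_adjust(data.frame, resp_ids,
                                  ["rw_any", "rw_a", "rw_f"])
        merged = data.frame.merge(
            data.responses[["facility_id"] + data.dictionary["item_id"].tolist()],
            on="facility_id")
        return merged, statuses, weights

    def test_no_missingness_identity(self):
        """With full response and no item missingness the cascade returns
        the input unchanged."""
        cfg = fs.default_config(
            propensity_coefficients={"intercept": 30.0},
            item_missing_rate=0.0, nrfu_takeup=0.0, access_only_rate=0.0,
            contact_marginals={"complete": 1022, "partial": 0, "missing": 0})
        d = fs.simulate_survey(cfg, seed=3)
        merged, statuses, weights = self._inputs(d)
        out = impute_cascade(merged, statuses, weights, d.dictionary)
        items = d.dictionary["item_id"].tolist()
        pd.testing.assert_frame_equal(out.data[items], merged[items])
        assert (out.flags[items] == "observed").all().all()
        assert len(out.assignments) == 0

    def test_default_run_complete_and_preserves_observed(self, pipeline_result):
        res = pipeline_result
        items = res.data.dictionary["item_id"].tolist()
        imputed = res.cascade.data
        assert len(imputed) == 1022
        assert imputed[items].notna().all().all()
        # observed cells are byte-identical to the responses
        original = res.data.responses.set_index("facility_id")[items]
        got = imputed.set_index("facility_id")[items]
        mask = original.notna()
        assert got.where(mask).equals(original.where(mask).astype(float)) or \
            np.allclose(got.to_numpy()[mask.to_numpy()],
                        original.to_numpy()[mask.to_numpy()])
        flagged = res.cascade.flags.to_numpy()
        assert set(np.unique(flagged)) <= {"observed", "imputed_step1",
                                           "imputed_step2", "imputed_step3"}

    def test_cascade_deterministic(self, default_data):
        merged, statuses, weights = self._inputs(default_data)
        a = impute_cascade(merged, statuses, weights, default_data.dictionary)
        b = impute_cascade(merged, statuses, weights, default_data.dictionary)
        pd.testing.assert_frame_equal(a.data, b.data)
        pd.testing.assert_frame_equal(a.assignments, b.assignments)

    def test_step_structure(self, pipeline_result):
        """Step 1 serves full respondents, step 2 NRFU respondents, step 3
        total nonrespondents; every nonrespondent row is fully imputed."""
        res = pipeline_result
        st = res.statuses.set_index("facility_id")["status"]
        asg = res.cascade.assignments
        step_status = asg["recipient_id"].map(st).groupby(asg["step"]).unique()
        assert set(step_status.get(1, [])) <= {"full_respondent"}
        assert set(step_status.get(2, [])) <= {"nrfu_respondent"}
        assert set(step_status.get(3, [])) <= {"noncontact", "noncooperation"}

    def test_grouped_vector_mode_keeps_blocks_consistent(self, default_data):
        """Items imputed as a block come jointly from a single donor, so an
        impossible intra-block combination can never be fabricated."""
        d = default_data
        merged, statuses, weights = self._inputs(d)
        block = ["q05", "q06"]
        out = impute_cascade(merged, statuses, weights, d.dictionary,
                             item_groups=[block])
        asg = out.assignments
        joint = asg[asg["item_id"] == "q05+q06"]
        assert len(joint) > 0
        donors = out.data.set_index("facility_id")
        both_imputed = (out.flags[block] != "observed").all(axis=1)
        for _, row in joint.iterrows():
            i = out.data.index[out.data["facility_id"] == row.recipient_id][0]
            if both_imputed.loc[i]:
                for it in block:
                    assert out.data.at[i, it] == donors.at[row.donor_id, it]

    def test_imputed_prevalence_tracks_weighted_estimate(self):
        """Over replicates the imputed-frame prevalence tracks the weighted
        respondent prevalence (the hot deck preserves the weighted donor
        distribution within classes)."""
        reps = 6
        diffs = []
        for rep in range(reps):
            d = fs.simulate_survey(fs.default_config(seed=100 + rep))
            merged, statuses, weights = self._inputs(d)
            out = impute_cascade(merged, statuses, weights, d.dictionary)
            w = weights.set_index("facility_id")["final_weight"]
            resp = d.responses.set_index("facility_id")
            for item in ["q01", "q02", "q10"]:
                ww = w.loc[resp.index]
                keep = resp[item].notna() & (ww > 0)
                west, _ = fs.weighted_estimate(resp.loc[keep, item],
                                               ww[keep])
                diffs.append(out.data[item].mean() * 100 - west)
        # weighted-estimate MC error at n~455 is ~2.3 points per item
        assert abs(np.mean(diffs)) < 3 * 2.3 / np.sqrt(len(diffs))
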