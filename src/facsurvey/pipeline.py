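"""End-to-end orchestration: simulate -> status -> rates -> bias -> weight ->
impute -> compare, with a reproducibility manifest.

Each stage consumes only the declared upstream tables; all outputs are plain
CSV/JSON.  A run manifest records the configuration hash, the seed, the
package version and a SHA-256 digest of every file written, so two runs with
identical inputs can be verified byte-identical.  Timestamps live only in
the manifest, never inside data outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import ConfigurationError
from .estimate_contrast import (compare_estimates, comparison_summary,
                                comparison_table)
from .hotdeck_imputation import impute_cascade
from .nonresponse_bias import (FamilywiseConfig, bias_report, contrast_item,
                               contrast_table)
from .status_rates import assign_status, compute_rates, rates_table, status_table
from .synthetic_frame import (COVARIATES, SimulationConfig, SurveyData,
                              default_config, simulate_survey, write_tables)
from .weighting import backward_eliminate, class_adjust, weight_diagnostics

logger = logging.getLogger(__name__)

STAGES = ("simulate", "status", "rates", "bias", "weight", "impute", "compare")

#: Candidate covariates for the propensity screen: the minimal-dataset
#: variables, abstraction count excluded by default (no clear association
#: with reported patient load).
DEFAULT_CANDIDATES = [c for c in COVARIATES if c != "n_abstractions"]


@dataclass
class RunManifest:
    """Audit record for one pipeline run."""
    config_hash: str
    seed: int
    package_version: str
    stages: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"config_hash": self.config_hash, "seed": self.seed,
                "package_version": self.package_version, "stages": self.stages}


@dataclass
class PipelineResult:
    """In-memory results of a run (stages beyond those requested may be
    populated when later requested stages needed them)."""
    manifest: RunManifest
    data: SurveyData
    statuses: pd.DataFrame | None = None
    rates: dict | None = None
    contrasts: list | None = None
    selected_covariates: list[str] | None = None
    weights: pd.DataFrame | None = None
    diagnostics: object = None
    cascade: object = None
    comparison: list | None = None


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: SimulationConfig | None = None, seed: int | None = None,
                 out_dir=None, stages=None, data: SurveyData | None = None,
                 include_abstractions: bool = False,
                 bias_family: FamilywiseConfig | None = None) -> PipelineResult:
    """Execute the pipeline and (optionally) write stage outputs.

    Stages not requested are still computed in memory when a requested stage
    depends on them, but only requested stages write files.  Pass ``data``
    to run on user-supplied tables instead of simulating.
    """
    if config is None:
        config = default_config()
    if seed is None:
        seed = config.seed
    if stages is None:
        stages = list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigurationError(f"unknown stage(s): {sorted(unknown)}")
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    cfg_json = json.dumps(config.model_dump(), sort_keys=True)
    manifest = RunManifest(hashlib.sha256(cfg_json.encode()).hexdigest(),
                           seed, __version__)
    report_lines: list[str] = []

    def _record(stage: str, paths: dict[str, Path]) -> None:
        manifest.stages.append({
            "stage": stage,
            "outputs": {name: {"path": str(p), "sha256": _digest(p)}
                        for name, p in paths.items()},
            "completed_unix": time.time(),
        })

    def _write(stage: str, tables: dict[str, pd.DataFrame],
               blobs: dict[str, dict] | None = None) -> None:
        if out is None or stage not in stages:
            return
        paths = {}
        for name, df in tables.items():
            p = out / f"{name}.csv"
            df.to_csv(p, index=False, na_rep="")
            paths[name] = p
        for name, obj in (blobs or {}).items():
            p = out / f"{name}.json"
            p.write_text(json.dumps(obj, indent=2, sort_keys=True))
            paths[name] = p
        _record(stage, paths)

    # ---- simulate -------------------------------------------------------
    if data is None:
        t0 = time.time()
        data = simulate_survey(config, seed=seed)
        logger.info("simulate: %d facilities in %.2fs", len(data.frame),
                    time.time() - t0)
    if out is not None and "simulate" in stages:
        paths = write_tables(data, out)
        _record("simulate", {k: Path(v) for k, v in paths.items()})
    res = PipelineResult(manifest, data)
    need = {s: (s in stages) for s in STAGES}
    run_status = need["status"] or need["rates"] or need["bias"] or \
        need["weight"] or need["impute"] or need["compare"]

    # ---- status ---------------------------------------------------------
    if run_status:
        res.statuses = assign_status(data.responses)
        tab = status_table(res.statuses)
        report_lines += ["Final status groups", tab.to_string(index=False), ""]
        _write("status", {"status": res.statuses, "status_table": tab})

    # ---- rates ----------------------------------------------------------
    if need["rates"]:
        res.rates = compute_rates(res.statuses, len(data.frame))
        tab = rates_table(res.rates)
        report_lines += ["Contact / cooperation / response rates",
                         tab.to_string(index=False), ""]
        _write("rates", {"rates": tab})

    # ---- bias -----------------------------------------------------------
    if need["bias"]:
        fam = bias_family or FamilywiseConfig()
        full_ids = set(res.statuses.loc[res.statuses["status"] == "full_respondent",
                                        "facility_id"])
        nrfu_ids = set(res.statuses.loc[res.statuses["status"] == "nrfu_respondent",
                                        "facility_id"])
        resp = data.responses
        shared = data.dictionary[data.dictionary["on_nrfu"]]
        contrasts = []
        for spec in shared.to_dict("records"):
            c = contrast_item(
                resp.loc[resp["facility_id"].isin(full_ids), spec["item_id"]],
                resp.loc[resp["facility_id"].isin(nrfu_ids), spec["item_id"]],
                spec["type"], spec["item_id"])
            if c is not None:
                contrasts.append(c)
        res.contrasts = contrasts
        sig = bias_report(contrasts, fam)
        report_lines += [
            f"Nonresponse bias: {len(sig)} of {len(contrasts)} shared items "
            f"significant at Bonferroni alpha/m = {fam.bonferroni_threshold:.4f}",
            sig.to_string(index=False) if len(sig) else "(none)", ""]
        _write("bias", {"bias_contrasts": contrast_table(contrasts),
                        "bias_significant": sig})

    # ---- weight ---------------------------------------------------------
    if need["weight"] or need["impute"] or need["compare"]:
        responded = data.frame["facility_id"].isin(
            res.statuses.loc[res.statuses["status"] == "full_respondent",
                             "facility_id"]).astype(int)
        candidates = list(DEFAULT_CANDIDATES)
        if include_abstractions:
            candidates.append("n_abstractions")
        res.selected_covariates = backward_eliminate(
            responded, data.frame[candidates])
        if not res.selected_covariates:
            logger.warning("no covariate survived elimination; single class")
        res.weights = class_adjust(
            data.frame,
            data.frame.loc[responded.astype(bool), "facility_id"],
            res.selected_covariates)
        res.diagnostics = weight_diagnostics(res.weights["final_weight"])
        diag = {"selected_covariates": res.selected_covariates,
                "n_respondents": res.diagnostics.n_respondents,
                "uwe": res.diagnostics.uwe,
                "effective_n": res.diagnostics.effective_n}
        dist = (res.weights["final_weight"].round(4).value_counts().sort_index()
                .rename_axis("final_weight").reset_index(name="n"))
        report_lines += [
            "Weighting: covariates " + ", ".join(res.selected_covariates),
            dist.to_string(index=False),
            f"UWE {res.diagnostics.uwe:.4f}, effective n "
            f"{res.diagnostics.effective_n:.1f} of {res.diagnostics.n_respondents}",
            ""]
        _write("weight", {"weights": res.weights, "weight_distribution": dist},
               {"weight_diagnostics": diag})

    # ---- impute ---------------------------------------------------------
    if need["impute"] or need["compare"]:
        merged = data.frame.merge(
            data.responses[["facility_id"] + data.dictionary["item_id"].tolist()],
            on="facility_id", validate="one_to_one")
        res.cascade = impute_cascade(merged, res.statuses, res.weights,
                                     data.dictionary)
        n_missing = int(res.cascade.data[data.dictionary["item_id"]].isna().sum().sum())
        report_lines += [f"Imputation cascade: {len(res.cascade.data)} rows, "
                         f"{n_missing} missing analytic cells remain", ""]
        _write("impute",
               {"imputed": res.cascade.data, "imputation_flags": res.cascade.flags,
                "donor_assignments": res.cascade.assignments},
               {"imputation_trees": res.cascade.trees})

    # ---- compare --------------------------------------------------------
    if need["compare"]:
        resp_mask = res.weights["final_weight"] > 0
        resp_ids = res.weights.loc[resp_mask, "facility_id"]
        resp_rows = data.responses.set_index("facility_id").loc[resp_ids]
        res.comparison = compare_estimates(
            res.cascade.data, resp_rows,
            res.weights.loc[resp_mask, "final_weight"].to_numpy(),
            data.dictionary)
        summary = comparison_summary(res.comparison)
        report_lines += [
            "Weighted vs imputed estimates: "
            f"{summary['n_significant_05']} of {summary['n_items']} items with "
            f"p < .05; mean imputed/weighted SE ratio {summary['mean_se_ratio']:.3f}",
            ""]
        _write("compare", {"estimate_comparison": comparison_table(res.comparison)},
               {"comparison_summary": summary})

    if out is not None:
        (out / "report.txt").write_text("\n".join(report_lines))
        (out / "manifest.json").write_text(
            json.dumps(manifest.to_dict(), indent=2))
    return res
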