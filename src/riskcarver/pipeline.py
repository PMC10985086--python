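"""End-to-end orchestration of the risk-subgrouping analysis on a synthetic
cohort pair: generate discovery and holdout populations, train the
cross-validated risk model, explain it, cluster the explanation space,
induce per-cluster rules, validate the rules on the holdout population, and
test per-cluster molecular markers.

All artefacts are plain text (TSV/JSON) and byte-reproducible for a fixed
configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import explain, holdout, markers, rules, subgroup, synthetic
from ._util import child_seed
from .risk_model import run_nested_cv


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n")


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def run_all(config: dict, seed: int, outdir) -> dict:
    """Run the full pipeline from a configuration mapping; writes artefacts
    under outdir and returns the headline quantities."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    base = dict(config["cohort"])
    base.setdefault("assessment_to_index_years", (0.0, 5.0))
    disc_cfg = synthetic.config_from_dict({**base, "seed": child_seed(seed, "discovery")})
    hold_over = dict(config.get("holdout", {}))
    hold_cfg = synthetic.config_from_dict(
        {
            **base,
            "n_cases": hold_over.get("n_cases", base["n_cases"]),
            "n_controls": hold_over.get("n_controls", base["n_controls"]),
            "assessment_to_index_years": hold_over.get("assessment_to_index_years", (5.0, 11.0)),
            "seed": child_seed(seed, "holdout"),
        }
    )
    discovery = synthetic.generate_subjects(disc_cfg)
    holdout_pop = synthetic.generate_subjects(hold_cfg)
    synthetic.write_cohort(discovery, outdir / "cohort_discovery.tsv")
    synthetic.write_cohort(holdout_pop, outdir / "cohort_holdout.tsv")

    model_cfg = config.get("model", {})
    table = discovery.features.copy()
    bundle, probs, metrics = run_nested_cv(
        table,
        discovery.labels,
        seed=child_seed(seed, "model"),
        eta_grid=tuple(model_cfg.get("eta_grid", (0.1, 0.3))),
        nrounds_grid=tuple(model_cfg.get("nrounds_grid", (50, 100))),
    )
    metrics_out = {
        "mean": metrics.mean,
        "ci_lo": metrics.ci_lo,
        "ci_hi": metrics.ci_hi,
        "counts": metrics.counts,
        "chosen_params": [dataclasses.asdict(m.params) for m in bundle.models],
    }
    _dump_json(metrics_out, outdir / "metrics.json")

    shap = explain.shap_values(bundle, table)
    explain.check_additivity(shap, probs)
    ranking = explain.global_ranking(shap)
    ranking.to_csv(outdir / "shap_ranking.tsv", sep="\t", index=False)

    # fold-pooled attributions for clustering (out-of-fold attribution would
    # superimpose per-fold offsets that cluster by fold, not by biology)
    shap_pooled = explain.shap_values(bundle, table, mode="pooled")
    cl_cfg = config.get("cluster", {})
    emb = subgroup.embed_pca(shap_pooled.values.to_numpy(), d=cl_cfg.get("dims", 10))
    solutions = subgroup.scan_resolutions(
        emb,
        probs,
        discovery.labels,
        resolutions=tuple(cl_cfg.get("resolutions", subgroup.DEFAULT_RESOLUTIONS)),
        k_neighbors=cl_cfg.get("k_neighbors", 20),
        n_subsamples=cl_cfg.get("n_subsamples", 30),
        seed=child_seed(seed, "cluster"),
    )
    best = subgroup.select_resolution(solutions)
    _dump_json(
        {
            "selected_resolution": best.resolution,
            "n_clusters": best.n_clusters,
            "solutions": [
                {
                    "resolution": s.resolution,
                    "n_clusters": s.n_clusters,
                    "score": None if not np.isfinite(s.score) else s.score,
                    "valid": s.valid,
                }
                for s in solutions
            ],
        },
        outdir / "cluster_solutions.json",
    )
    labels_frame = pd.DataFrame(
        {"subject_id": discovery.frame["subject_id"], "cluster": best.labels}
    )
    labels_frame.to_csv(outdir / "cluster_labels.tsv", sep="\t", index=False)
    best.per_cluster.to_csv(outdir / "cluster_metrics.tsv", sep="\t")
    profile = subgroup.characterize(best, shap.inputs, ranking, oof_probs=probs)
    profile.to_csv(outdir / "cluster_profiles.tsv", sep="\t")

    rule_cfg = config.get("rules", {})
    ruleset = rules.rules_for_clusters(
        shap.inputs,
        best.labels,
        n_estimators=rule_cfg.get("n_estimators", 10),
        max_depth=rule_cfg.get("max_depth", 5),
        recall_min=rule_cfg.get("recall_min", 0.2),
        max_depth_duplication=rule_cfg.get("max_depth_duplication", 7),
        seed=child_seed(seed, "rules"),
    )
    _dump_json(ruleset.to_records(), outdir / "rules.json")
    (outdir / "rules.txt").write_text(
        "".join(
            f"cluster {c}: {ruleset.selected[c] or '<no rule>'}\n" for c in ruleset.clusters()
        )
    )

    hold_feats = holdout_pop.features.copy()
    hold_feats.index = holdout_pop.frame["subject_id"]
    case_pct = (best.per_cluster["case_frac"] * 100).to_dict()
    sizes = best.per_cluster["size"].to_dict()
    assignment = holdout.assign_clusters(ruleset, hold_feats, case_pct, sizes)
    assignment.table.assign(
        matched=assignment.table["matched"].map(lambda m: ",".join(map(str, m)))
    ).to_csv(outdir / "assignments.tsv", sep="\t", index=False)
    hold_labels = pd.Series(
        holdout_pop.labels, index=holdout_pop.frame["subject_id"]
    )
    concordance = holdout.compare_populations(best.per_cluster, assignment, hold_labels)
    fractions = assignment.category_fractions()
    _dump_json(
        {
            "category_fractions": fractions,
            "n_excluded_missing": assignment.n_excluded_missing,
            "r2_case_fraction": concordance.r2_case_fraction,
            "r2_size_fraction": concordance.r2_size_fraction,
            "dropped_clusters": concordance.dropped_clusters,
        },
        outdir / "concordance.json",
    )

    marker_summary = None
    mk_cfg = config.get("markers")
    if mk_cfg is not None:
        omics = synthetic.simulate_omics(
            discovery,
            n_features=mk_cfg.get("n_features", 50),
            shifts=[tuple(s) for s in mk_cfg.get("shifts", ())],
            seed=child_seed(seed, "omics"),
        )
        subset = discovery.labels == 1 if mk_cfg.get("subset", "cases_only") == "cases_only" else None
        sex_col = mk_cfg.get("sex_feature")
        cov = None
        if sex_col and sex_col in discovery.feature_names:
            cov = pd.DataFrame({"sex": discovery.features[sex_col].fillna(0).to_numpy()},
                               index=omics.index)
        res = markers.de_markers(omics, best.labels, covariates=cov, subset_mask=subset)
        markers.results_frame(res).to_csv(outdir / "markers.tsv", sep="\t", index=False)
        marker_summary = markers.top_markers(res)
        _dump_json(marker_summary, outdir / "marker_panel.json")

    return {
        "auc": metrics.mean["auc"],
        "n_clusters": best.n_clusters,
        "resolution": best.resolution,
        "unique_fraction": fractions["unique"],
        "r2_case_fraction": concordance.r2_case_fraction,
        "r2_size_fraction": concordance.r2_size_fraction,
    }
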