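"""Rule-based assignment of holdout subjects to discovered clusters and
discovery/holdout concordance.

Holdout subjects are matched against every cluster's rule.  A subject firing
exactly one rule is uniquely assigned; one firing several is assigned to the
matching cluster with the highest discovery case percentage (ties broken by
larger discovery cluster, then lowest cluster id); one firing none stays
unassigned.  Subjects with missing values in any rule variable are, by
default, excluded before assignment (non-imputed data are used for
validation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .rules import RuleSet, apply_rule


@dataclass
class AssignmentResult:
    table: pd.DataFrame          # subject_id, matched (list), category, final
    n_excluded_missing: int

    def category_fractions(self) -> dict[str, float]:
        n = len(self.table)
        frac = self.table["category"].value_counts(normalize=True)
        return {c: float(frac.get(c, 0.0)) for c in ("unique", "ambiguous", "unassigned")}


def _rule_features(ruleset: RuleSet) -> list[str]:
    feats: set[str] = set()
    for r in ruleset.selected.values():
        if r is not None:
            feats.update(c.feature for c in r.conditions)
    return sorted(feats)


def exclude_missing(holdout: pd.DataFrame, ruleset: RuleSet) -> tuple[pd.DataFrame, int]:
    """Drop subjects with a missing value in any variable used by a rule."""
    feats = [f for f in _rule_features(ruleset) if f in holdout.columns]
    keep = holdout[feats].notna().all(axis=1) if feats else pd.Series(True, index=holdout.index)
    return holdout.loc[keep], int((~keep).sum())


def assign_clusters(ruleset: RuleSet, holdout: pd.DataFrame,
                    discovery_case_pct: dict[int, float],
                    discovery_sizes: dict[int, int] | None = None,
                    handle_missing: str = "exclude") -> AssignmentResult:
    """Assign each holdout subject to a cluster via the rule set.

    handle_missing: "exclude" drops subjects with missing rule variables
    before assignment (default); "non_firing" keeps them, with missing
    values failing the condition.
    """
    missing_feats = [f for f in _rule_features(ruleset) if f not in holdout.columns]
    if missing_feats:
        raise KeyError(f"holdout table lacks rule features: {missing_feats}")
    n_excluded = 0
    if handle_missing == "exclude":
        holdout, n_excluded = exclude_missing(holdout, ruleset)
    elif handle_missing != "non_firing":
        raise ValueError("handle_missing must be 'exclude' or 'non_firing'")
    clusters = [c for c in ruleset.clusters() if ruleset.selected[c] is not None]
    fired = {c: apply_rule(ruleset.selected[c], holdout) for c in clusters}
    sizes = discovery_sizes or {}
    rows = []
    for i in range(len(holdout)):
        matched = [c for c in clusters if fired[c][i]]
        if len(matched) == 0:
            cat, final = "unassigned", None
        elif len(matched) == 1:
            cat, final = "unique", matched[0]
        else:
            cat = "ambiguous"
            final = min(
                matched,
                key=lambda c: (-discovery_case_pct[c], -sizes.get(c, 0), c),
            )
        rows.append(
            {
                "subject_id": holdout.index[i],
                "matched": matched,
                "category": cat,
                "final": final,
            }
        )
    return AssignmentResult(pd.DataFrame(rows), n_excluded)


@dataclass
class ConcordanceReport:
    per_cluster: pd.DataFrame    # discovery/holdout case and size fractions
    r2_case_fraction: float
    r2_size_fraction: float
    dropped_clusters: list[int]


def compare_populations(discovery_per_cluster: pd.DataFrame, assignment: AssignmentResult,
                        holdout_case_labels: pd.Series) -> ConcordanceReport:
    """Squared Pearson correlation of per-cluster case fractions and size
    fractions between the discovery solution and the rule-assigned holdout.
    Clusters with no assigned holdout member are excluded and reported."""
    assigned = assignment.table.dropna(subset=["final"]).copy()
    assigned["final"] = assigned["final"].astype(int)
    assigned["is_case"] = holdout_case_labels.loc[assigned["subject_id"]].to_numpy()
    hold = assigned.groupby("final").agg(h_size=("is_case", "size"), h_case_frac=("is_case", "mean"))
    hold["h_size_frac"] = hold["h_size"] / hold["h_size"].sum()
    merged = discovery_per_cluster[["case_frac", "size_frac"]].join(hold, how="left")
    dropped = merged.index[merged["h_size"].isna()].tolist()
    merged = merged.dropna(subset=["h_size"])
    if len(merged) < 3:
        raise ValueError("need at least 3 clusters with assigned holdout subjects")
    def _r2(a, b):
        if np.std(a) == 0 or np.std(b) == 0:
            return float("nan")  # correlation undefined for a constant vector
        return float(pearsonr(a, b).statistic ** 2)

    r2_case = _r2(merged["case_frac"], merged["h_case_frac"])
    r2_size = _r2(merged["size_frac"], merged["h_size_frac"])
    return ConcordanceReport(merged, r2_case, r2_size, dropped)
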