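"""Interpretable per-cluster rule induction in the SkopeRules style.

For each cluster (one-vs-rest) a small ensemble of bootstrap-bagged shallow
decision trees is fitted on the original (imputed) input values.  Every
root-to-node path ending in a majority-positive node becomes a candidate
conjunctive rule; conditions on the same feature are intersected; each rule
is scored on its source tree's out-of-bag samples and dropped when the
out-of-bag recall falls below recall_min or the precision is not above 0.5.
Semantically identical rules from different trees are merged, and the
per-cluster rule is the one produced by the most trees, with out-of-bag
precision then recall breaking ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from ._util import child_seed


@dataclass(frozen=True)
class Condition:
    feature: str
    op: str           # "<=" or ">"
    threshold: float

    def __post_init__(self):
        if self.op not in ("<=", ">"):
            raise ValueError(f"operator must be '<=' or '>', got {self.op!r}")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    def __str__(self) -> str:
        return f"{self.feature} {self.op} {self.threshold:.6g}"


@dataclass
class Rule:
    conditions: tuple[Condition, ...]
    oob_precision: float = np.nan
    oob_recall: float = np.nan
    tree_count: int = 1
    source_trees: frozenset = field(default_factory=frozenset)

    def __str__(self) -> str:
        return " and ".join(str(c) for c in self.conditions)


def normalize_conditions(conditions) -> tuple[Condition, ...] | None:
    """Intersect conditions per feature: keep the tightest upper (<=) and
    lower (>) bound. Returns None when the intersection is empty. The result
    is sorted by (feature, op) and has at most one bound of each kind per
    feature."""
    upper: dict[str, float] = {}
    lower: dict[str, float] = {}
    for c in conditions:
        if c.op == "<=":
            upper[c.feature] = min(upper.get(c.feature, np.inf), c.threshold)
        else:
            lower[c.feature] = max(lower.get(c.feature, -np.inf), c.threshold)
    out = []
    for f in sorted(set(upper) | set(lower)):
        if f in upper and f in lower and lower[f] >= upper[f]:
            return None
        if f in lower:
            out.append(Condition(f, ">", lower[f]))
        if f in upper:
            out.append(Condition(f, "<=", upper[f]))
    return tuple(out)


def apply_rule(rule: Rule, table: pd.DataFrame):
    """Row-wise conjunction. A missing value in any condition feature makes
    the rule not fire for that row."""
    mask = np.ones(len(table), dtype=bool)
    for c in rule.conditions:
        if c.feature not in table.columns:
            raise KeyError(f"rule feature {c.feature!r} not in table")
        col = table[c.feature].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            fired = col > c.threshold if c.op == ">" else col <= c.threshold
        mask &= np.where(np.isnan(col), False, fired)
    return mask


def rule_precision_recall(rule: Rule, table: pd.DataFrame, target) -> tuple[float, float]:
    y = np.asarray(target, dtype=int)
    fired = apply_rule(rule, table)
    precision = float(y[fired].mean()) if fired.any() else np.nan
    recall = float(fired[y == 1].mean()) if (y == 1).any() else np.nan
    return precision, recall


def _paths_from_tree(tree: DecisionTreeClassifier, feature_names) -> list[tuple[Condition, ...]]:
    """All root-to-node paths whose end node is majority-positive."""
    t = tree.tree_
    out = []

    def walk(node: int, conds: list[Condition]):
        value = t.value[node][0]
        if conds and value[1] > value[0]:
            out.append(tuple(conds))
        if t.children_left[node] == -1:
            return
        f = feature_names[t.feature[node]]
        thr = float(t.threshold[node])
        walk(t.children_left[node], conds + [Condition(f, "<=", thr)])
        walk(t.children_right[node], conds + [Condition(f, ">", thr)])

    walk(0, [])
    return out


def induce_rules(table: pd.DataFrame, target, n_estimators: int = 10, max_depth: int = 5,
                 recall_min: float = 0.2, max_samples: float = 1.0, seed: int = 0) -> list[Rule]:
    """Candidate rules for a binary cluster indicator from bagged shallow
    trees, scored and filtered on out-of-bag samples."""
    y = np.asarray(target, dtype=int)
    if y.min() == y.max():
        raise ValueError("target must contain both classes")
    if table.isna().any().any():
        raise ValueError("rule induction expects a fully imputed table")
    n = len(table)
    X = table.to_numpy(dtype=float)
    feature_names = list(table.columns)
    rules: list[Rule] = []
    for b in range(n_estimators):
        rng = np.random.default_rng(child_seed(seed, "bag", b))
        bag = rng.integers(0, n, size=int(round(max_samples * n)))
        oob = np.setdiff1d(np.arange(n), np.unique(bag))
        if oob.size == 0 or len(np.unique(y[bag])) < 2:
            continue
        tree = DecisionTreeClassifier(
            max_depth=max_depth, random_state=child_seed(seed, "tree", b)
        ).fit(X[bag], y[bag])
        oob_table = table.iloc[oob]
        for conds in _paths_from_tree(tree, feature_names):
            norm = normalize_conditions(conds)
            if not norm:
                continue
            rule = Rule(norm, source_trees=frozenset([b]))
            prec, rec = rule_precision_recall(rule, oob_table, y[oob])
            if np.isnan(prec) or np.isnan(rec) or rec < recall_min or prec <= 0.5:
                continue
            rule.oob_precision, rule.oob_recall = prec, rec
            rules.append(rule)
    return rules


def _rule_key(rule: Rule, max_terms: int) -> tuple:
    """Semantic identity of a rule up to max_terms conditions, thresholds
    rounded to 6 significant digits."""
    terms = tuple(
        (c.feature, c.op, float(f"{c.threshold:.6g}")) for c in rule.conditions[:max_terms]
    )
    return terms


def deduplicate(rules: list[Rule], max_depth_duplication: int = 7) -> list[Rule]:
    """Merge semantically identical rules; the keeper has the highest
    (oob_precision, oob_recall) and a tree_count equal to the number of
    distinct source trees in its group."""
    groups: dict[tuple, list[Rule]] = {}
    for r in rules:
        groups.setdefault(_rule_key(r, max_depth_duplication), []).append(r)
    out = []
    for grp in groups.values():
        keeper = max(grp, key=lambda r: (r.oob_precision, r.oob_recall))
        trees = frozenset().union(*(r.source_trees for r in grp))
        out.append(
            Rule(keeper.conditions, keeper.oob_precision, keeper.oob_recall, len(trees), trees)
        )
    return out


def select_cluster_rule(candidates: list[Rule]) -> Rule | None:
    """Total-order selection: most source trees, then highest out-of-bag
    precision, then recall, then fewest conditions, then rule text."""
    if not candidates:
        return None
    return min(
        candidates,
        key=lambda r: (-r.tree_count, -r.oob_precision, -r.oob_recall, len(r.conditions), str(r)),
    )


@dataclass
class RuleSet:
    """cluster id -> selected rule (None when no candidate survived), with
    the retained candidate lists for audit."""

    selected: dict[int, Rule | None]
    candidates: dict[int, list[Rule]]

    def clusters(self) -> list[int]:
        return sorted(self.selected)

    def to_records(self) -> list[dict]:
        recs = []
        for c in self.clusters():
            r = self.selected[c]
            recs.append(
                {
                    "cluster": c,
                    "rule": str(r) if r else None,
                    "conditions": [
                        {"feature": q.feature, "op": q.op, "threshold": q.threshold}
                        for q in (r.conditions if r else ())
                    ],
                    "oob_precision": None if r is None else r.oob_precision,
                    "oob_recall": None if r is None else r.oob_recall,
                    "tree_count": None if r is None else r.tree_count,
                }
            )
        return recs


def rules_for_clusters(table: pd.DataFrame, cluster_labels, n_estimators: int = 10,
                       max_depth: int = 5, recall_min: float = 0.2,
                       max_depth_duplication: int = 7, seed: int = 0) -> RuleSet:
    """One-vs-rest rule induction for every cluster label."""
    labels = np.asarray(cluster_labels)
    selected, cand = {}, {}
    for c in np.unique(labels):
        rules = induce_rules(
            table, (labels == c).astype(int), n_estimators=n_estimators,
            max_depth=max_depth, recall_min=recall_min, seed=child_seed(seed, "cluster", int(c)),
        )
        rules = deduplicate(rules, max_depth_duplication)
        cand[int(c)] = rules
        selected[int(c)] = select_cluster_rule(rules)
    return RuleSet(selected, cand)
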