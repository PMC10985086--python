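"""Feature-table construction: winsorization, yearly longitudinal binning,
missingness / near-zero-variance filters, fold-internal median imputation
and omics normalization.

All quantiles use linear interpolation (numpy default, R type 7). Anything
learned from data (filter decisions, imputation medians) is fitted on an
explicit set of training rows so it can live inside a cross-validation fold
without leaking information from held-out subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import DAYS_PER_MONTH, DAYS_PER_YEAR, CohortTable


def winsorize(values, lo_pct: float = 1.0, hi_pct: float = 99.0) -> np.ndarray:
    """Clip to the [lo_pct, hi_pct] percentiles of the non-missing values;
    missing entries pass through unchanged."""
    x = np.asarray(values, dtype=float)
    finite = ~np.isnan(x)
    if finite.sum() == 0:
        raise ValueError("cannot winsorize an all-missing vector")
    q_lo, q_hi = np.percentile(x[finite], [lo_pct, hi_pct])
    out = x.copy()
    out[finite] = np.clip(x[finite], q_lo, q_hi)
    return out


def bin_yearly(records: pd.DataFrame, index_dates: pd.Series,
               continuous_codes=(), medication_codes=(),
               n_years: int = 5, window_months: int = 11) -> pd.DataFrame:
    """Collapse long-format records into per-subject yearly snapshot features.

    Year k (k = 1..n_years) covers index_date - k*365 < date <= index_date -
    (k-1)*365.  For continuous codes the feature is the median over the
    window_months 30-day months of the bin farthest from the index date;
    the leftover 365 - window_months*30 days adjacent to the index-date
    side of the bin are excluded, leaving a time gap between the snapshot
    and the diagnosis/index date.
    Medication codes become a binary any-prescription flag over the whole
    year bin.  Empty bins are missing (NaN for continuous, 0 for drugs only
    when the subject has records; subjects absent from `records` get NaN
    everywhere).

    Returns a frame indexed like index_dates with columns
    "<code>_pre{k}y".
    """
    subjects = index_dates.index
    cols: dict[str, np.ndarray] = {}
    rec = records.merge(
        index_dates.rename("index_date"), left_on="subject_id", right_index=True, how="inner"
    )
    delta = rec["index_date"] - rec["date"]  # days before index, > 0
    gap_days = DAYS_PER_YEAR - window_months * DAYS_PER_MONTH
    for k in range(1, n_years + 1):
        lo, hi = (k - 1) * DAYS_PER_YEAR, k * DAYS_PER_YEAR
        in_bin = (delta > lo) & (delta <= hi)
        in_window = in_bin & (delta > lo + gap_days)
        for code in continuous_codes:
            sel = rec[in_window & (rec["code"] == code)]
            med = sel.groupby("subject_id")["value"].median()
            cols[f"{code}_pre{k}y"] = med.reindex(subjects).to_numpy()
        for code in medication_codes:
            sel = rec[in_bin & (rec["code"] == code)]
            flag = sel.groupby("subject_id").size().gt(0).astype(float)
            present = rec.loc[rec["code"] == code, "subject_id"].unique()
            out = flag.reindex(subjects)
            out[out.index.isin(present) & out.isna()] = 0.0
            cols[f"{code}_pre{k}y"] = out.to_numpy()
    return pd.DataFrame(cols, index=subjects)


@dataclass
class FilterReport:
    excluded: list[dict] = field(default_factory=list)

    def add(self, feature: str, reason: str, statistic: float) -> None:
        self.excluded.append({"feature": feature, "reason": reason, "statistic": float(statistic)})

    @property
    def features(self) -> list[str]:
        return [e["feature"] for e in self.excluded]


def filter_features(table: pd.DataFrame, train_rows, max_missing: float = 0.5,
                    freq_ratio: float = 95 / 5, unique_pct: float = 10.0):
    """Drop features with > max_missing missing fraction, or near-zero
    variance (ratio of the two most common values > freq_ratio AND percent
    unique values < unique_pct), both judged on the training rows only.

    Returns (filtered table, FilterReport).
    """
    train = table.loc[train_rows]
    if len(train) == 0:
        raise ValueError("empty training partition")
    report = FilterReport()
    for col in table.columns:
        vals = train[col]
        miss = vals.isna().mean()
        if miss > max_missing:
            report.add(col, "missingness", miss)
            continue
        nonmiss = vals.dropna()
        counts = nonmiss.value_counts()
        if len(counts) <= 1:
            report.add(col, "near_zero_variance", np.inf)
            continue
        ratio = counts.iloc[0] / counts.iloc[1]
        uniq = 100.0 * len(counts) / len(nonmiss)
        if ratio > freq_ratio and uniq < unique_pct:
            report.add(col, "near_zero_variance", ratio)
    keep = [c for c in table.columns if c not in report.features]
    if not keep:
        raise ValueError("all features excluded by filters")
    return table[keep], report


@dataclass
class ImputationModel:
    """Per-feature medians learned on a training partition."""

    medians: pd.Series

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in table.columns if c not in self.medians.index]
        if missing:
            raise ValueError(f"no learned median for features {missing}")
        return table.fillna(self.medians)


def fit_impute(table: pd.DataFrame, train_rows) -> ImputationModel:
    train = table.loc[train_rows]
    medians = train.median(axis=0, skipna=True)
    dead = medians.index[medians.isna()].tolist()
    if dead:
        raise ValueError(f"features with no non-missing training values: {dead}")
    return ImputationModel(medians)


def apply_impute(model: ImputationModel, table: pd.DataFrame) -> pd.DataFrame:
    return model.apply(table)


def normalize_metabolites(table: pd.DataFrame, ratio_features=()) -> pd.DataFrame:
    """Square-root transform absolute-concentration metabolite features;
    features named in ratio_features (ratios / percentages) pass through."""
    out = table.copy()
    absolute = [c for c in table.columns if c not in set(ratio_features)]
    if (out[absolute] < 0).any().any():
        raise ValueError("negative metabolite concentration")
    out[absolute] = np.sqrt(out[absolute])
    return out


def filter_protein_outliers(table: pd.DataFrame, lo_pct: float = 0.2,
                            hi_pct: float = 99.8) -> tuple[pd.DataFrame, list]:
    """Drop subjects whose mean protein expression falls outside the
    [lo_pct, hi_pct] percentiles of the cohort's per-subject means.
    Returns (filtered table, dropped subject index list)."""
    means = table.mean(axis=1, skipna=True)
    q_lo, q_hi = np.percentile(means.dropna(), [lo_pct, hi_pct])
    keep = (means >= q_lo) & (means <= q_hi)
    return table.loc[keep], table.index[~keep].tolist()


def assemble_features(cohort: CohortTable, records: pd.DataFrame | None = None,
                      continuous_codes=(), medication_codes=()) -> pd.DataFrame:
    """Join assessment-centre features with yearly-binned longitudinal
    features into one model-ready table indexed by subject_id."""
    feats = cohort.features.copy()
    feats.index = cohort.frame["subject_id"]
    if records is not None and len(records) and (len(continuous_codes) or len(medication_codes)):
        index_dates = pd.Series(
            cohort.frame["index_date"].to_numpy(), index=cohort.frame["subject_id"]
        )
        binned = bin_yearly(records, index_dates, continuous_codes, medication_codes)
        feats = feats.join(binned)
    return feats
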