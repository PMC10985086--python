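"""Synthetic case-control cohort generator with planted subgroup structure.

Emulates a retrospective case-control study: a fixed number of cases and
controls, an assessment date at which baseline features are measured, an
index date (diagnosis date for cases, matched stand-in for controls), a
mixed continuous/binary/ordinal feature panel linked to case status through
a logistic risk model, latent "archetypes" (subgroups defined by small
conjunctive threshold rules that carry an extra log-odds risk shift), and
longitudinal monthly biomarker / prescription records in the five years
before the index date.

Sampling is class-conditional: labels are drawn first at the exact
case/control counts, and features are drawn from the class-conditional
distributions implied by the logistic model (for a continuous feature with
control distribution N(mu, sd), cases are shifted by effect*sd**2; for a
binary feature, the case probability is tilted by `effect` on the logit
scale).  The induced posterior P(case | x) is then exactly
sigmoid(beta0 + sum_f effect_f * x_f + risk_shift), and for a single
Gaussian feature the population ROC-AUC has the closed form
Phi(effect * sd / sqrt(2)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from ._util import logit, rng_for, sigmoid

DAYS_PER_YEAR = 365
DAYS_PER_MONTH = 30

#: reserved (non-feature) columns of a cohort frame
COHORT_META_COLS = [
    "subject_id",
    "is_case",
    "assessment_date",
    "index_date",
    "obs_start_date",
    "obs_end_date",
    "death_date",
    "true_archetype",
    "true_risk",
]


@dataclass(frozen=True)
class FeatureSpec:
    """One baseline feature: its control-class distribution and risk effect.

    kind:
        continuous -> Normal(mean, sd)
        binary     -> Bernoulli(p), encoded {0, 1}
        ordinal    -> integer levels 0..len(probs)-1 with the given probabilities
    effect: log-odds of case status per unit of the feature.
    missing_rate: probability each value is masked, completely at random.
    """

    name: str
    kind: str = "continuous"
    mean: float = 0.0
    sd: float = 1.0
    p: float = 0.5
    probs: tuple[float, ...] = ()
    effect: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self):
        if self.kind not in ("continuous", "binary", "ordinal"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError(f"missing_rate out of [0,1] for {self.name!r}")
        if not np.isfinite(self.effect):
            raise ValueError(f"non-finite effect for {self.name!r}")
        if self.kind == "ordinal" and (len(self.probs) < 2 or abs(sum(self.probs) - 1) > 1e-9):
            raise ValueError(f"ordinal feature {self.name!r} needs probabilities summing to 1")


@dataclass(frozen=True)
class ArchetypeSpec:
    """A planted subgroup: a conjunctive threshold rule plus a risk shift.

    rule: list of (feature_name, op, threshold) with op in {"<=", ">"};
    members are generated to satisfy every condition.
    risk_shift: log-odds added to the linear predictor for members.
    prevalence: population fraction belonging to the archetype.
    """

    id: int
    rule: tuple[tuple[str, str, float], ...]
    risk_shift: float
    prevalence: float

    def __post_init__(self):
        if not np.isfinite(self.risk_shift):
            raise ValueError("risk_shift must be finite")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0,1)")
        for _, op, _ in self.rule:
            if op not in ("<=", ">"):
                raise ValueError(f"rule operator must be '<=' or '>', got {op!r}")


@dataclass(frozen=True)
class CohortConfig:
    n_cases: int
    n_controls: int
    features: tuple[FeatureSpec, ...]
    archetypes: tuple[ArchetypeSpec, ...] = ()
    assessment_to_index_years: tuple[float, float] = (0.0, 5.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("case and control counts must be positive")
        lo, hi = self.assessment_to_index_years
        if not 0 <= lo < hi:
            raise ValueError("assessment-to-index interval needs 0 <= lo < hi")
        declared = {f.name for f in self.features}
        if len(declared) != len(self.features):
            raise ValueError("duplicate feature names")
        total_prev = sum(a.prevalence for a in self.archetypes)
        if total_prev > 1.0 + 1e-12:
            raise ValueError("archetype prevalences sum to > 1")
        for a in self.archetypes:
            for fname, _, _ in a.rule:
                if fname not in declared:
                    raise ValueError(f"archetype {a.id} rule references undeclared feature {fname!r}")

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.features]


@dataclass
class CohortTable:
    """Subjects x (metadata + features). One row per subject.

    frame holds the reserved columns in COHORT_META_COLS followed by the
    feature columns; missing feature entries are NaN. true_archetype /
    true_risk are simulation ground truth and absent from real data.
    """

    frame: pd.DataFrame
    feature_names: list[str]

    def __post_init__(self):
        if self.frame["subject_id"].duplicated().any():
            raise ValueError("duplicate subject_id")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def features(self) -> pd.DataFrame:
        return self.frame[self.feature_names]

    @property
    def labels(self) -> np.ndarray:
        return self.frame["is_case"].to_numpy(dtype=int)

    def subset(self, mask) -> "CohortTable":
        return CohortTable(self.frame.loc[mask].reset_index(drop=True), list(self.feature_names))


def _calibrate_background_prob(target: float, archetypes: Sequence[ArchetypeSpec],
                               tol_frac: float = 0.01, max_iter: int = 100) -> float:
    """Bisection on the background case probability so that the population
    case fraction (mixing archetype risk shifts at their prevalences) hits
    the target within tol_frac of the target."""
    if not 0.0 < target < 1.0:
        raise ValueError("target case fraction must be in (0,1)")
    rho_bg = 1.0 - sum(a.prevalence for a in archetypes)

    def realized(p_bg: float) -> float:
        b0 = logit(p_bg)
        return rho_bg * p_bg + sum(a.prevalence * float(sigmoid(b0 + a.risk_shift)) for a in archetypes)

    lo, hi = 1e-12, 1.0 - 1e-12
    if not realized(lo) <= target <= realized(hi):
        raise ValueError("infeasible calibration: archetype risk shifts push prevalence outside (0,1)")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if realized(mid) < target:
            lo = mid
        else:
            hi = mid
        mid = 0.5 * (lo + hi)
        if abs(realized(mid) - target) <= tol_frac * target:
            return mid
    raise ValueError("intercept calibration did not converge within 100 bisection steps")


def _case_tilted_probs(probs: np.ndarray, levels: np.ndarray, effect: float) -> np.ndarray:
    w = probs * np.exp(effect * levels)
    return w / w.sum()


def _draw_feature(rng, spec: FeatureSpec, is_case: np.ndarray) -> np.ndarray:
    n = is_case.size
    if spec.kind == "continuous":
        mu = np.where(is_case == 1, spec.mean + spec.effect * spec.sd**2, spec.mean)
        return rng.normal(mu, spec.sd)
    if spec.kind == "binary":
        p1 = float(sigmoid(logit(spec.p) + spec.effect))
        p = np.where(is_case == 1, p1, spec.p)
        return (rng.random(n) < p).astype(float)
    levels = np.arange(len(spec.probs), dtype=float)
    p0 = np.asarray(spec.probs, dtype=float)
    p1 = _case_tilted_probs(p0, levels, spec.effect)
    out = np.empty(n)
    for label, pr in ((0, p0), (1, p1)):
        m = is_case == label
        out[m] = rng.choice(levels, size=int(m.sum()), p=pr)
    return out


def _force_condition(rng, spec: FeatureSpec, values: np.ndarray, rows: np.ndarray,
                     op: str, threshold: float, is_case: np.ndarray) -> None:
    """Redraw `values[rows]` from the class-conditional distribution truncated
    to the side of the threshold that satisfies the condition."""
    if rows.size == 0:
        return
    if spec.kind == "continuous":
        mu = np.where(is_case[rows] == 1, spec.mean + spec.effect * spec.sd**2, spec.mean)
        if op == ">":
            a, b = (threshold - mu) / spec.sd, np.inf
        else:
            a, b = -np.inf, (threshold - mu) / spec.sd
        values[rows] = truncnorm.rvs(a, b, loc=mu, scale=spec.sd, random_state=rng)
        return
    levels = np.arange(2.0) if spec.kind == "binary" else np.arange(len(spec.probs), dtype=float)
    ok = levels > threshold if op == ">" else levels <= threshold
    if not ok.any():
        raise ValueError(f"no level of {spec.name!r} satisfies {op} {threshold}")
    base0 = np.array([1 - spec.p, spec.p]) if spec.kind == "binary" else np.asarray(spec.probs, float)
    base1 = _case_tilted_probs(base0, levels, spec.effect)
    for label, base in ((0, base0), (1, base1)):
        m = rows[is_case[rows] == label]
        pr = np.where(ok, base, 0.0)
        if pr.sum() == 0:
            pr = ok.astype(float)
        pr = pr / pr.sum()
        values[m] = rng.choice(levels, size=m.size, p=pr)


def _rule_mask(frame: pd.DataFrame, rule) -> np.ndarray:
    mask = np.ones(len(frame), dtype=bool)
    for fname, op, thr in rule:
        col = frame[fname].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            cond = col > thr if op == ">" else col <= thr
        mask &= np.where(np.isnan(col), False, cond)
    return mask


def _feature_llr(spec: FeatureSpec, x: np.ndarray) -> np.ndarray:
    """Exact log-likelihood ratio log f(x|case)/f(x|control) for one feature."""
    if spec.effect == 0.0:
        return np.zeros_like(x, dtype=float)
    if spec.kind == "continuous":
        return spec.effect * (x - spec.mean) - 0.5 * spec.effect**2 * spec.sd**2
    if spec.kind == "binary":
        p1 = float(sigmoid(logit(spec.p) + spec.effect))
        return np.where(x == 1, np.log(p1 / spec.p), np.log((1 - p1) / (1 - spec.p)))
    levels = np.arange(len(spec.probs), dtype=float)
    p0 = np.asarray(spec.probs, float)
    p1 = _case_tilted_probs(p0, levels, spec.effect)
    lut = np.log(p1 / p0)
    return lut[x.astype(int)]


def generate_subjects(config: CohortConfig) -> CohortTable:
    """Generate a cohort of exactly n_cases + n_controls subjects.

    Returns a CohortTable whose feature columns follow the class-conditional
    sampling scheme described in the module docstring, with ground-truth
    archetype membership (first matching rule, in declaration order) and the
    posterior case probability recorded per subject.
    """
    rng = rng_for(config.seed, "subjects")
    n = config.n_cases + config.n_controls
    target = config.n_cases / n
    p_bg = _calibrate_background_prob(target, config.archetypes)
    b0 = float(logit(p_bg))

    is_case = np.zeros(n, dtype=int)
    is_case[: config.n_cases] = 1
    rng.shuffle(is_case)

    # retrospective archetype assignment: P(A=k | class) via Bayes at the
    # calibrated background probability
    arch_assign = np.full(n, -1)
    if config.archetypes:
        q = np.array([float(sigmoid(b0 + a.risk_shift)) for a in config.archetypes])
        rho = np.array([a.prevalence for a in config.archetypes])
        pi = float(np.sum(rho * q) + (1 - rho.sum()) * p_bg)
        for label, class_p in ((1, rho * q / pi), (0, rho * (1 - q) / (1 - pi))):
            m = np.flatnonzero(is_case == label)
            pr = np.append(class_p, 1 - class_p.sum())
            draws = rng.choice(len(pr), size=m.size, p=pr)
            arch_assign[m] = np.where(draws == len(config.archetypes), -1, draws)

    feats = {}
    spec_by_name = {f.name: f for f in config.features}
    for spec in config.features:
        feats[spec.name] = _draw_feature(rng, spec, is_case)
    for k, arch in enumerate(config.archetypes):
        rows = np.flatnonzero(arch_assign == k)
        for fname, op, thr in arch.rule:
            _force_condition(rng, spec_by_name[fname], feats[fname], rows, op, thr, is_case)

    frame = pd.DataFrame(feats)

    # ground truth: first matching archetype rule, evaluated on the final features
    true_arch = np.full(n, -1)
    for k, arch in enumerate(config.archetypes):
        hit = _rule_mask(frame, arch.rule) & (true_arch == -1)
        true_arch[hit] = arch.id if arch.id >= 0 else k

    eta = np.full(n, b0)
    for spec in config.features:
        eta += _feature_llr(spec, frame[spec.name].to_numpy())
    shift_by_id = {a.id: a.risk_shift for a in config.archetypes}
    eta += np.array([shift_by_id.get(a, 0.0) for a in true_arch])
    true_risk = sigmoid(eta)

    # MCAR missingness, inserted after ground truth is recorded
    for spec in config.features:
        if spec.missing_rate > 0:
            mask = rng.random(n) < spec.missing_rate
            frame.loc[mask, spec.name] = np.nan

    lo, hi = config.assessment_to_index_years
    assessment = rng.integers(0, 3 * DAYS_PER_YEAR + 1, size=n)
    gap = rng.integers(int(lo * DAYS_PER_YEAR) + 1, int(hi * DAYS_PER_YEAR) + 1, size=n)
    index_date = assessment + gap

    meta = pd.DataFrame(
        {
            "subject_id": [f"S{i:06d}" for i in range(n)],
            "is_case": is_case,
            "assessment_date": assessment,
            "index_date": index_date,
            "obs_start_date": index_date - 10 * DAYS_PER_YEAR,
            "obs_end_date": index_date + DAYS_PER_YEAR,
            "death_date": np.nan,
            "true_archetype": true_arch,
            "true_risk": true_risk,
        }
    )
    out = pd.concat([meta, frame], axis=1)
    return CohortTable(out, config.feature_names)


@dataclass(frozen=True)
class BiomarkerSpec:
    """Monthly longitudinal biomarker: subject-level mean plus AR(1) noise."""

    code: str
    mean: float = 0.0
    between_sd: float = 0.0
    rho: float = 0.0
    sigma: float = 0.0
    case_shift: float = 0.0


@dataclass(frozen=True)
class MedicationSpec:
    """Prescription events with per-year probabilities (year -1 .. -5)."""

    code: str
    yearly_prob_case: tuple[float, ...] = (0.0,) * 5
    yearly_prob_control: tuple[float, ...] = (0.0,) * 5


def simulate_longitudinal(cohort: CohortTable, biomarker_specs: Sequence[BiomarkerSpec],
                          med_specs: Sequence[MedicationSpec], seed: int) -> pd.DataFrame:
    """Monthly biomarker values and yearly prescription events for the five
    years before each subject's index date. Returns a long-format frame
    (subject_id, code, value, date); all dates strictly precede index_date."""
    rng = rng_for(seed, "longitudinal")
    n = len(cohort)
    index = cohort.frame["index_date"].to_numpy()
    is_case = cohort.labels
    months = np.arange(1, 5 * 12 + 1)
    chunks = []
    for spec in biomarker_specs:
        subj_mean = spec.mean + spec.case_shift * is_case + rng.normal(0, 1, n) * spec.between_sd
        # stationary AR(1): e_t = rho*e_{t-1} + innovation, marginal sd sigma/sqrt(1-rho^2)
        innov = rng.normal(0, 1, (n, months.size))
        e = np.zeros((n, months.size))
        stat_sd = spec.sigma / np.sqrt(1 - spec.rho**2) if abs(spec.rho) < 1 else spec.sigma
        e[:, 0] = innov[:, 0] * stat_sd
        for t in range(1, months.size):
            e[:, t] = spec.rho * e[:, t - 1] + spec.sigma * innov[:, t]
        values = subj_mean[:, None] + e
        dates = index[:, None] - DAYS_PER_MONTH * months[None, :]
        chunks.append(
            pd.DataFrame(
                {
                    "subject_id": np.repeat(cohort.frame["subject_id"].to_numpy(), months.size),
                    "code": spec.code,
                    "value": values.ravel(),
                    "date": dates.ravel(),
                }
            )
        )
    for spec in med_specs:
        for year in range(1, 6):
            p = np.where(
                is_case == 1,
                spec.yearly_prob_case[year - 1],
                spec.yearly_prob_control[year - 1],
            )
            hit = np.flatnonzero(rng.random(n) < p)
            if hit.size == 0:
                continue
            offset = rng.integers((year - 1) * DAYS_PER_YEAR + 1, year * DAYS_PER_YEAR + 1, hit.size)
            chunks.append(
                pd.DataFrame(
                    {
                        "subject_id": cohort.frame["subject_id"].to_numpy()[hit],
                        "code": spec.code,
                        "value": 1.0,
                        "date": index[hit] - offset,
                    }
                )
            )
    if not chunks:
        return pd.DataFrame(columns=["subject_id", "code", "value", "date"])
    out = pd.concat(chunks, ignore_index=True)
    return out.sort_values(["subject_id", "code", "date"], kind="mergesort").reset_index(drop=True)


def simulate_omics(cohort: CohortTable, n_features: int = 50,
                   shifts: Sequence[tuple[int, int, float]] = (), seed: int = 0,
                   prefix: str = "prot") -> pd.DataFrame:
    """Synthetic normalized protein-expression panel (arbitrary log-scale
    units): independent standard normals per subject and feature, with
    optional planted mean shifts given as (archetype_id, feature_index,
    delta) applied to that archetype's members.  Indexed by subject_id."""
    rng = rng_for(seed, "omics")
    X = rng.normal(size=(len(cohort), n_features))
    arch = cohort.frame["true_archetype"].to_numpy()
    for arch_id, j, delta in shifts:
        X[arch == arch_id, j] += delta
    return pd.DataFrame(
        X, index=pd.Index(cohort.frame["subject_id"], name="subject_id"),
        columns=[f"{prefix}{j:03d}" for j in range(n_features)],
    )


def match_controls(cases: CohortTable, control_pool: CohortTable, seed: int) -> CohortTable:
    """Date-match controls to cases without replacement.

    Each selected control inherits the index date of its case and must have
    observational coverage of the five years before that date and no death
    registered in that window.
    """
    rng = rng_for(seed, "matching")
    pool = control_pool.frame
    used = np.zeros(len(pool), dtype=bool)
    obs_start = pool["obs_start_date"].to_numpy(dtype=float)
    obs_end = pool["obs_end_date"].to_numpy(dtype=float)
    death = pool["death_date"].to_numpy(dtype=float)
    picked_rows, picked_dates = [], []
    for _, case in cases.frame.iterrows():
        idx_date = case["index_date"]
        window_start = idx_date - 5 * DAYS_PER_YEAR
        covered = (obs_start <= window_start) & (obs_end >= idx_date)
        no_death = np.isnan(death) | (death < window_start) | (death > idx_date)
        eligible = np.flatnonzero(covered & no_death & ~used)
        if eligible.size == 0:
            raise ValueError(f"no eligible control for case {case['subject_id']!r}")
        pick = int(rng.choice(eligible))
        used[pick] = True
        picked_rows.append(pick)
        picked_dates.append(idx_date)
    matched = pool.iloc[picked_rows].copy().reset_index(drop=True)
    matched["index_date"] = picked_dates
    return CohortTable(matched, list(control_pool.feature_names))


def split_populations(cohort: CohortTable,
                      discovery_years: tuple[float, float] = (0.0, 5.0),
                      holdout_years: tuple[float, float] = (5.0, 11.0)) -> tuple[CohortTable, CohortTable]:
    """Partition by the assessment-to-index gap: (0, 5] years -> discovery,
    (5, 11] years -> holdout, anything else dropped. Windows are half-open on
    the lower bound and closed on the upper, measured in 365-day years."""
    gap = (cohort.frame["index_date"] - cohort.frame["assessment_date"]).to_numpy()
    d_lo, d_hi = (int(y * DAYS_PER_YEAR) for y in discovery_years)
    h_lo, h_hi = (int(y * DAYS_PER_YEAR) for y in holdout_years)
    disc = cohort.subset((gap > d_lo) & (gap <= d_hi))
    hold = cohort.subset((gap > h_lo) & (gap <= h_hi))
    return disc, hold


def write_cohort(cohort: CohortTable, path) -> None:
    cohort.frame.to_csv(path, sep="\t", index=False)


def read_cohort(path) -> CohortTable:
    frame = pd.read_csv(path, sep="\t")
    feature_names = [c for c in frame.columns if c not in COHORT_META_COLS]
    return CohortTable(frame, feature_names)


def write_records(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False)


def read_records(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def config_from_dict(d: dict) -> CohortConfig:
    """Build a CohortConfig from a plain (YAML-loaded) mapping."""
    feats = tuple(
        FeatureSpec(
            name=f["name"],
            kind=f.get("kind", "continuous"),
            mean=f.get("mean", 0.0),
            sd=f.get("sd", 1.0),
            p=f.get("p", 0.5),
            probs=tuple(f.get("probs", ())),
            effect=f.get("effect", 0.0),
            missing_rate=f.get("missing_rate", 0.0),
        )
        for f in d["features"]
    )
    archs = tuple(
        ArchetypeSpec(
            id=a["id"],
            rule=tuple((c["feature"], c["op"], float(c["threshold"])) for c in a["rule"]),
            risk_shift=float(a["risk_shift"]),
            prevalence=float(a["prevalence"]),
        )
        for a in d.get("archetypes", ())
    )
    return CohortConfig(
        n_cases=int(d["n_cases"]),
        n_controls=int(d["n_controls"]),
        features=feats,
        archetypes=archs,
        assessment_to_index_years=tuple(d.get("assessment_to_index_years", (0.0, 5.0))),
        seed=int(d.get("seed", 0)),
    )
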