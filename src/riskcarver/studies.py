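"""Reference synthetic study configurations.

These are the canonical cohort designs the examples, tests and validation
scripts run on; they fix the study conditions (sample sizes, effect sizes,
archetype structure) in one place.
"""

from __future__ import annotations

from .synthetic import ArchetypeSpec, CohortConfig, FeatureSpec


def single_gaussian_config(effect: float = 1.19, n_cases: int = 2500, n_controls: int = 2500,
                           seed: int = 0, window: tuple[float, float] = (0.0, 5.0)) -> CohortConfig:
    """One standard-normal feature with a log-odds effect per unit; the
    population ROC-AUC of the feature is Phi(effect / sqrt(2))."""
    return CohortConfig(
        n_cases, n_controls,
        features=(FeatureSpec("x", effect=effect),),
        assessment_to_index_years=window,
        seed=seed,
    )


def four_archetype_config(n_cases: int = 2000, n_controls: int = 2000, seed: int = 0,
                          risk_shift: float = 2.0, prevalence: float = 0.12,
                          window: tuple[float, float] = (0.0, 5.0)) -> CohortConfig:
    """Four planted archetypes, each defined by a rare binary flag (think: a
    specific diagnosis or prescription code) carrying a 2 log-odds risk
    shift. Background subjects carry a flag only rarely (0.2%), so archetype
    membership is essentially the flag itself and the explanation space has
    five well-separated populations (four archetypes + background)."""
    flags = tuple(FeatureSpec(f"flag{k}", kind="binary", p=0.002) for k in range(1, 5))
    archetypes = tuple(
        ArchetypeSpec(k, ((f"flag{k + 1}", ">", 0.5),), risk_shift, prevalence) for k in range(4)
    )
    return CohortConfig(
        n_cases, n_controls,
        features=flags,
        archetypes=archetypes,
        assessment_to_index_years=window,
        seed=seed,
    )


#: planted conjunctive threshold rules for the rule-recovery study
FIVE_RULES = (
    (("x1", ">", 1.17), ("x2", "<=", -1.17)),
    (("x3", ">", 1.17), ("x4", ">", 1.17)),
    (("x5", ">", 2.4),),
    (("x6", ">", 2.5),),
    (("x7", "<=", -2.5),),
)


def five_rule_config(n_cases: int = 2000, n_controls: int = 2000, seed: int = 0,
                     risk_shift: float = 1.5) -> CohortConfig:
    """Five planted conjunctive rules over continuous features with disjoint
    feature sets. Ground-truth membership is the rule itself (noiseless), so
    an induced rule can be compared threshold-by-threshold."""
    feats = tuple(FeatureSpec(f"x{j}") for j in range(1, 9))
    # conjunction conditions each fire naturally for ~12% of subjects, so no
    # single condition is by itself a majority-positive split and only the
    # full conjunction survives induction; the single-condition archetypes
    # sit in the far tails, where membership is rare and sharp
    prevalences = (0.06, 0.06, 0.10, 0.10, 0.10)
    archetypes = tuple(
        ArchetypeSpec(k, rule, risk_shift, prev)
        for k, (rule, prev) in enumerate(zip(FIVE_RULES, prevalences))
    )
    return CohortConfig(n_cases, n_controls, features=feats, archetypes=archetypes, seed=seed)


def pipeline_config(n_cases: int = 2000, n_controls: int = 2000) -> dict:
    """Full-pipeline configuration (dict form, as the YAML front end takes)
    built around the four-archetype cohort, with a small synthetic protein
    panel carrying one planted marker."""
    base = four_archetype_config(n_cases, n_controls)
    return {
        "cohort": {
            "n_cases": n_cases,
            "n_controls": n_controls,
            "features": [
                {
                    "name": f.name, "kind": f.kind, "mean": f.mean, "sd": f.sd,
                    "p": f.p, "effect": f.effect, "missing_rate": f.missing_rate,
                }
                for f in base.features
            ],
            "archetypes": [
                {
                    "id": a.id,
                    "rule": [
                        {"feature": fn, "op": op, "threshold": thr} for fn, op, thr in a.rule
                    ],
                    "risk_shift": a.risk_shift,
                    "prevalence": a.prevalence,
                }
                for a in base.archetypes
            ],
        },
        "holdout": {"assessment_to_index_years": [5.0, 11.0]},
        "model": {"eta_grid": [0.1, 0.3], "nrounds_grid": [50, 100]},
        "cluster": {"resolutions": [0.3, 0.4, 0.5, 0.6, 0.8, 1.0], "n_subsamples": 30},
        "markers": {"n_features": 40, "shifts": [[0, 0, 2.0]], "subset": "cases_only"},
    }
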