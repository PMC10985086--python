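"""Shared fixtures: small trained bundles and the planted-archetype
pipeline chain reused across test modules. Everything is generated
programmatically and seeded."""

from __future__ import annotations

import numpy as np
import pytest

from riskcarver import explain, studies, synthetic
from riskcarver.risk_model import run_nested_cv

SMALL_GRID = {"eta_grid": (0.1, 0.3), "nrounds_grid": (50, 100)}


@pytest.fixture(scope="session")
def gauss_run():
    """Single-Gaussian-feature cohort (d = 1.19, n = 5000) through the
    nested five-by-five cross-validated model."""
    cohort = synthetic.generate_subjects(studies.single_gaussian_config(seed=101))
    bundle, probs, metrics = run_nested_cv(
        cohort.features, cohort.labels, seed=7, **SMALL_GRID
    )
    return {"cohort": cohort, "bundle": bundle, "probs": probs, "metrics": metrics}


@pytest.fixture(scope="session")
def archetype_run():
    """Four-archetype cohort (n = 4000) through model, explanation,
    clustering and resolution selection."""
    from riskcarver import subgroup

    cohort = synthetic.generate_subjects(studies.four_archetype_config(seed=202))
    bundle, probs, metrics = run_nested_cv(
        cohort.features, cohort.labels, seed=7, **SMALL_GRID
    )
    shap_oof = explain.shap_values(bundle, cohort.features)
    shap_pooled = explain.shap_values(bundle, cohort.features, mode="pooled")
    embedding = subgroup.embed_pca(shap_pooled.values.to_numpy(), d=10)
    solutions = subgroup.scan_resolutions(embedding, probs, cohort.labels, seed=9)
    best = subgroup.select_resolution(solutions)
    return {
        "cohort": cohort,
        "bundle": bundle,
        "probs": probs,
        "metrics": metrics,
        "shap": shap_oof,
        "shap_pooled": shap_pooled,
        "embedding": embedding,
        "solutions": solutions,
        "best": best,
    }


@pytest.fixture(scope="session")
def tiny_bundle():
    """Small three-feature cohort and trained bundle for explanation tests."""
    rng = np.random.default_rng(5)
    import pandas as pd

    n = 600
    table = pd.DataFrame(
        {
            "a": rng.normal(size=n),
            "b": rng.normal(size=n),
            "c": rng.integers(0, 2, n).astype(float),
        }
    )
    logits = 1.2 * table["a"].to_numpy() - 0.8 * table["c"].to_numpy()
    y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
    bundle, probs, metrics = run_nested_cv(
        table, y, seed=3, eta_grid=(0.3,), nrounds_grid=(30,)
    )
    return {"table": table, "labels": y, "bundle": bundle, "probs": probs}
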