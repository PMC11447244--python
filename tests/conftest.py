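"""Shared fixtures: the reference synthetic panel/cohort and tiny toy tables.

The expensive artifacts (full panel screen, the five null-panel screens, the
reference cohort) are session-scoped so the recovery, null-calibration and
survival tests share one computation.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from rxsig.io import DrugResponseTable, ExpressionMatrix, SampleAnnotation
from rxsig.score import fit_weights
from rxsig.screen import screen_all
from rxsig.simulate import CohortConfig, PanelConfig, simulate_cohort, simulate_panel

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def panel_seed1():
    """Reference cell-line panel at the default study conditions, seed 1."""
    return simulate_panel(PanelConfig(seed=1))


@pytest.fixture(scope="session")
def screens_seed1(panel_seed1):
    expr, resp, _, _ = panel_seed1
    return screen_all(expr, resp)


@pytest.fixture(scope="session")
def null_panel_screens():
    """Five pure-noise panels (loading 0) at 300 samples, screened."""
    out = []
    for seed in range(1, 6):
        cfg = PanelConfig(seed=seed, loading=0.0, n_samples=300)
        expr, resp, _, _ = simulate_panel(cfg)
        out.append(screen_all(expr, resp))
    return out


@pytest.fixture(scope="session")
def weights_seed1(panel_seed1):
    """SCC weights for the planted resistance genes in one (drug, lineage)
    context of the reference panel."""
    expr, resp, annot, truth = panel_seed1
    return fit_weights(expr, resp, truth.resistance_genes, "DRUG000", "LINEAGE0", annot)


@pytest.fixture(scope="session")
def cohort_seed1(weights_seed1):
    """Reference patient cohort driven by the fitted weights, seed 1."""
    return simulate_cohort(CohortConfig(seed=1), weights_seed1)


@pytest.fixture
def tiny_expr():
    """4 genes x 6 samples with one flat gene; not z-scored."""
    rng = np.random.default_rng(42)
    data = pd.DataFrame(
        rng.normal(size=(4, 6)),
        index=["GA", "GB", "GC", "GD"],
        columns=[f"S{i}" for i in range(6)],
    )
    data.loc["GD"] = 5.0
    return ExpressionMatrix(data)


@pytest.fixture
def tiny_response():
    rows = []
    rng = np.random.default_rng(7)
    for d in ("DR1", "DR2"):
        for i in range(6):
            rows.append({"drug_id": d, "sample_id": f"S{i}", "value": rng.normal()})
    return DrugResponseTable(pd.DataFrame(rows))


@pytest.fixture
def tiny_annotation():
    return SampleAnnotation(
        pd.DataFrame({"lineage": ["BREAST"] * 6}, index=[f"S{i}" for i in range(6)])
    )
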