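"""Synthetic cell-line panels and patient cohorts with known ground truth.

The panel generator emulates the statistical structure of the public
pharmacogenomic panels the pipeline targets: a genes x samples matrix of
per-gene z-scores, a long drug-response table in which a subset of "planted"
genes shares a monotone association with response across many drugs, and a
lineage annotation with at least 9 samples per lineage.

Generative model (panel)
------------------------
Per sample s there is a global resistance factor g_s ~ N(0,1).  Drugs are
grouped into classes; class c's latent factor is

    u_{s,c} = sqrt(class_cor) * g_s + sqrt(1 - class_cor) * v_{s,c}

so any two class factors correlate at ``class_cor``.  A planted resistance
gene assigned to class c has raw expression lambda*u_{s,c} + sigma*eps, a
planted sensitivity gene -lambda*u_{s,c} + sigma*eps, and background genes
are independent standard normal.  The response of drug d (class c(d)) is
response_scale*u_{s,c(d)} + tau*eta.  Expression is then z-scored per gene.
Under this model the Pearson correlation of a planted gene with a drug of
its own class is rho_P = lambda / (sqrt(lambda^2+sigma^2) *
sqrt(response_scale^2+tau^2)) and its population Spearman is
(6/pi)*asin(rho_P/2); cross-class correlations are attenuated by
``class_cor``, which is what lets a planted gene reach the "top-K for >= M
drugs" selection rule across the whole panel.

Generative model (cohort)
-------------------------
Patient expression of signature (and background) genes is i.i.d. standard
normal; the true score is the supplied weight map applied to the z-scored
matrix, standardized.  Survival times are Weibull proportional-hazards with
log-hazard beta * true_score + covariate terms (age, stage, grade), and
censoring is independent uniform, calibrated by bisection to the target
rate.  Times are rounded to 0.1 months so tie handling is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import DrugResponseTable, ExpressionMatrix, SampleAnnotation, zscore_rows

# sub-stream keys so adding one artifact never perturbs another
_PANEL_KEY, _COHORT_KEY = 11, 101


@dataclass
class PanelConfig:
    """Cell-line panel simulation parameters (defaults are the reference
    study conditions used throughout the test-suite)."""

    n_genes: int = 2000
    n_planted_resistance: int = 40
    n_planted_sensitivity: int = 5
    n_samples: int = 400
    n_lineages: int = 4
    n_drugs: int = 60
    n_drug_classes: int = 4
    loading: float = 0.5          # lambda: planted-gene loading on its class factor
    noise_sd: float = 1.0         # sigma
    response_scale: float = 1.0
    response_noise_sd: float = 0.5  # tau
    class_cor: float = 0.6        # correlation between class latent factors
    metric: str = "LN_IC50"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_samples", "n_lineages", "n_drugs", "n_drug_classes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_planted_resistance + self.n_planted_sensitivity > self.n_genes:
            raise ValueError("planted genes exceed total genes")
        if self.n_samples // self.n_lineages < 9:
            raise ValueError(
                "each lineage needs at least 9 samples "
                f"({self.n_samples} samples / {self.n_lineages} lineages)"
            )
        if not (0.0 <= self.class_cor <= 1.0):
            raise ValueError("class_cor must lie in [0, 1]")


@dataclass
class CohortConfig:
    """Patient-cohort simulation parameters.

    Covariate effect defaults follow typical adjusted estimates for an
    ER+ breast-cancer cohort: ~6%/year hazard increase for age, moderate
    stage and grade effects.
    """

    n_patients: int = 1000
    beta: float = 0.3             # log-hazard per SD of true score
    baseline_shape: float = 1.2   # Weibull shape
    baseline_scale: float = 120.0 # months
    censoring_rate: float = 0.3
    age_effect: float = 0.058     # per year (centered)
    stage_effect: float = 0.33    # per ordinal step
    grade_effect: float = 0.11
    n_background_genes: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 50:
            raise ValueError("cohort needs at least 50 patients")
        if not (0.0 <= self.censoring_rate <= 0.9):
            raise ValueError("censoring rate must lie in [0, 0.9]")
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")


@dataclass
class GroundTruth:
    """Everything a recovery test needs about a simulated artifact."""

    resistance_genes: list[str] = field(default_factory=list)
    sensitivity_genes: list[str] = field(default_factory=list)
    gene_class: dict = field(default_factory=dict)    # planted gene -> class index
    drug_class: dict = field(default_factory=dict)    # drug -> class index
    loadings: dict = field(default_factory=dict)      # planted gene -> signed lambda
    true_score: pd.Series | None = None               # cohorts: standardized score
    beta: float | None = None
    censoring_threshold: float | None = None
    config: dict = field(default_factory=dict)


def simulate_panel(
    config: PanelConfig,
) -> tuple[ExpressionMatrix, DrugResponseTable, SampleAnnotation, GroundTruth]:
    """Generate one cell-line panel; deterministic given ``config.seed``."""
    rng = np.random.default_rng([_PANEL_KEY, config.seed])
    n_res, n_sen = config.n_planted_resistance, config.n_planted_sensitivity
    n_bg = config.n_genes - n_res - n_sen
    genes = (
        [f"RES{i:03d}" for i in range(n_res)]
        + [f"SNS{i:03d}" for i in range(n_sen)]
        + [f"BGD{i:04d}" for i in range(n_bg)]
    )
    samples = [f"CL{i:04d}" for i in range(config.n_samples)]
    drugs = [f"DRUG{i:03d}" for i in range(config.n_drugs)]

    C = config.n_drug_classes
    a = config.class_cor
    g = rng.standard_normal(config.n_samples)
    v = rng.standard_normal((config.n_samples, C))
    u = np.sqrt(a) * g[:, None] + np.sqrt(1.0 - a) * v  # samples x classes

    lam, sigma = config.loading, config.noise_sd
    expr = np.empty((config.n_genes, config.n_samples))
    gene_class, loadings = {}, {}
    for i in range(n_res):
        c = i % C
        expr[i] = lam * u[:, c] + sigma * rng.standard_normal(config.n_samples)
        gene_class[genes[i]] = c
        loadings[genes[i]] = lam
    # sensitivity genes emulate markers of sensitivity to one drug family,
    # so they all load on class 0 (the class screened in single-drug analyses)
    for j in range(n_sen):
        i = n_res + j
        expr[i] = -lam * u[:, 0] + sigma * rng.standard_normal(config.n_samples)
        gene_class[genes[i]] = 0
        loadings[genes[i]] = -lam
    expr[n_res + n_sen:] = rng.standard_normal((n_bg, config.n_samples))

    drug_class = {d: k % C for k, d in enumerate(drugs)}
    records = []
    for d in drugs:
        resp = (config.response_scale * u[:, drug_class[d]]
                + config.response_noise_sd * rng.standard_normal(config.n_samples))
        records.append(pd.DataFrame({"drug_id": d, "sample_id": samples, "value": resp}))
    resp_table = DrugResponseTable(pd.concat(records, ignore_index=True),
                                   metric=config.metric)

    matrix = ExpressionMatrix(
        zscore_rows(pd.DataFrame(expr, index=genes, columns=samples)), zscored=True
    )
    lineage = [f"LINEAGE{i % config.n_lineages}" for i in range(config.n_samples)]
    annotation = SampleAnnotation(pd.DataFrame({"lineage": lineage}, index=samples))
    truth = GroundTruth(
        resistance_genes=genes[:n_res],
        sensitivity_genes=genes[n_res:n_res + n_sen],
        gene_class=gene_class,
        drug_class=drug_class,
        loadings=loadings,
        config=asdict(config),
    )
    return matrix, resp_table, annotation, truth


def _calibrate_censoring(event_times: np.ndarray, uniforms: np.ndarray,
                         target: float) -> float:
    """Bisect the uniform-censoring upper bound c so that the realized
    fraction of subjects with C_i = c*U_i < T_i matches the target rate."""
    if target <= 0:
        return float("inf")
    lo, hi = 1e-6, float(event_times.max()) * 1e3
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        censored = np.mean(mid * uniforms < event_times)
        if censored > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohort(
    config: CohortConfig, weights
) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Generate a patient cohort whose log-hazard tracks a known score.

    ``weights`` may be a :class:`~rxsig.score.SignatureWeights`, a mapping,
    or a pandas Series of gene -> weight; these define the *true* score
    driving survival.  Returns the z-scored cohort expression matrix (weight
    genes plus background noise genes), the clinical table (time in months,
    event, age, stage, grade), and the ground truth.
    """
    w = pd.Series(weights.weights if hasattr(weights, "weights") else weights,
                  dtype=float)
    if w.empty:
        raise ValueError("need at least one score gene")
    rng = np.random.default_rng([_COHORT_KEY, config.seed])
    n = config.n_patients
    patients = [f"PT{i:04d}" for i in range(n)]
    bg = [f"CBG{i:04d}" for i in range(config.n_background_genes)]
    genes = list(w.index) + bg

    raw = pd.DataFrame(rng.standard_normal((len(genes), n)), index=genes, columns=patients)
    matrix = ExpressionMatrix(zscore_rows(raw), zscored=True)

    score = matrix.data.loc[w.index].mul(w, axis=0).sum(axis=0)
    score_std = (score - score.mean()) / score.std(ddof=1)

    age = np.clip(rng.normal(61.0, 12.0, n), 25.0, 90.0)
    stage = rng.choice([1, 2, 3], size=n, p=[0.45, 0.40, 0.15]).astype(float)
    grade = rng.choice([1, 2, 3], size=n, p=[0.20, 0.45, 0.35]).astype(float)

    eta = (config.beta * score_std.to_numpy()
           + config.age_effect * (age - age.mean())
           + config.stage_effect * (stage - 2.0)
           + config.grade_effect * (grade - 2.0))
    # Weibull PH: S(t) = exp(-(t/scale)^shape * exp(eta))
    uu = rng.uniform(size=n)
    times = config.baseline_scale * (-np.log(uu) / np.exp(eta)) ** (1.0 / config.baseline_shape)

    cens_u = rng.uniform(size=n)
    cmax = _calibrate_censoring(times, cens_u, config.censoring_rate)
    cens_times = cmax * cens_u
    event = (times <= cens_times).astype(int)
    observed = np.minimum(times, cens_times)
    observed = np.maximum(np.round(observed, 1), 0.1)  # 0.1-month grid -> ties

    clinical = pd.DataFrame(
        {"time": observed, "event": event, "age": age, "stage": stage, "grade": grade},
        index=pd.Index(patients, name="sample_id"),
    )
    truth = GroundTruth(
        loadings=dict(w),
        true_score=score_std,
        beta=config.beta,
        censoring_threshold=float(cmax) if np.isfinite(cmax) else None,
        config=asdict(config),
    )
    return matrix, clinical, truth
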