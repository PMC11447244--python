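"""The SCC-weighted polygenic resistance score and its Fisher-Z machinery.

For a fixed context — one drug, one lineage — each signature gene's weight is
its Spearman correlation (SCC) with the drug response across the lineage's
cell lines.  A sample's score is then the linear combination

    score_c = sum_g SCC_g * exp_cg

over the signature genes, where exp_cg is the z-scored expression of gene g
in sample c.  Genes missing from a cohort's platform are dropped without
re-normalizing the remaining weights, so a 35-gene application of a 36-gene
signature is the same formula minus one term.

Correlations are variance-stabilized for cross-context comparison with
Fisher's transformation F(r) = arctanh(r) scaled by sqrt((N-3)/1.06), the
Fieller correction appropriate for Spearman coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import DrugResponseTable, ExpressionMatrix, SampleAnnotation
from .screen import spearman

logger = logging.getLogger(__name__)

#: Fieller variance correction for Fisher-transformed Spearman coefficients
FIELLER_CONSTANT = 1.06


def fisher_transform(r):
    """F(r) = 0.5*log((1+r)/(1-r)) = arctanh(r); defined for |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("fisher_transform requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out

def fisher_zscore(r, n):
    """Z = sqrt((N-3)/1.06) * F(r); requires N >= 4."""
    n_arr = np.asarray(n, dtype=float)
    if np.any(n_arr < 4):
        raise ValueError("fisher_zscore requires sample size N >= 4")
    out = np.sqrt((n_arr - 3.0) / FIELLER_CONSTANT) * fisher_transform(r)
    return float(out) if np.ndim(out) == 0 else out


class PolygenicScorer(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer fitting SCC weights and scoring samples.

    ``fit(X, y)`` takes a samples x genes frame of z-scored expression and a
    response vector (ln IC50 or AUC; larger = more resistant) and stores one
    Spearman weight per testable gene in ``weights_``.  ``transform(X)``
    returns the polygenic score of each sample, dropping (and recording)
    genes absent from ``X``.

    Parameters
    ----------
    min_samples : minimum pairwise-complete samples for a gene to receive a
        weight (the panel inclusion rule; default 9).
    """

    def __init__(self, min_samples: int = 9):
        self.min_samples = min_samples

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        if X.shape[0] != y.size:
            raise ValueError("X and y disagree on the number of samples")
        if X.shape[0] < self.min_samples:
            raise ValueError(
                f"need at least {self.min_samples} samples to fit weights, got {X.shape[0]}"
            )
        weights, n_used, omitted = {}, {}, []
        for gene in X.columns:
            x = X[gene].to_numpy(dtype=float)
            m = np.isfinite(x) & np.isfinite(y)
            if m.sum() < self.min_samples:
                omitted.append(gene)
                continue
            rho, _ = spearman(x[m], y[m])
            if not np.isfinite(rho):
                omitted.append(gene)
                continue
            weights[gene] = rho
            n_used[gene] = int(m.sum())
        if not weights:
            raise ValueError("no testable gene: all candidates constant or too sparse")
        if omitted:
            logger.warning("fit: omitted %d untestable gene(s): %s", len(omitted), omitted[:10])
        self.weights_ = pd.Series(weights, dtype=float)
        self.n_samples_ = pd.Series(n_used, dtype=int)
        self.omitted_genes_ = omitted
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns)
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "weights_")
        X = pd.DataFrame(X)
        present = [g for g in self.weights_.index if g in X.columns]
        if not present:
            raise ValueError("no signature gene present in the expression frame")
        missing = [g for g in self.weights_.index if g not in X.columns]
        if missing:
            logger.warning("transform: %d signature gene(s) missing, dropped: %s",
                           len(missing), missing[:10])
        w = self.weights_[present]
        vals = X[present].to_numpy(dtype=float)
        scores = np.nansum(vals * w.to_numpy()[None, :], axis=1)
        self.genes_missing_ = missing
        return scores.reshape(-1, 1)


@dataclass
class SignatureWeights:
    """Context-tagged gene -> SCC weight map defining one polygenic score."""

    drug_id: str
    lineage: str
    weights: pd.Series          # gene -> SCC
    n_samples: pd.Series = None # gene -> complete pairs used in fitting

    def __post_init__(self) -> None:
        self.weights = pd.Series(self.weights, dtype=float)
        if self.weights.empty:
            raise ValueError("a signature needs at least one weighted gene")
        if not np.isfinite(self.weights.to_numpy()).all():
            raise ValueError("non-finite weight")
        if self.n_samples is None:
            self.n_samples = pd.Series(0, index=self.weights.index, dtype=int)

    @property
    def n_genes(self) -> int:
        return len(self.weights)

    def drop(self, genes) -> "SignatureWeights":
        """New weights with the given genes' terms deleted (no refit)."""
        genes = set([genes] if isinstance(genes, str) else genes)
        unknown = genes - set(self.weights.index)
        if unknown:
            raise KeyError(f"not in signature: {sorted(unknown)}")
        keep = [g for g in self.weights.index if g not in genes]
        if not keep:
            raise ValueError("cannot remove every gene from the signature")
        return SignatureWeights(self.drug_id, self.lineage,
                                self.weights[keep], self.n_samples.reindex(keep))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": list(self.weights.index),
             "weight": self.weights.to_numpy(),
             "n_samples": self.n_samples.reindex(self.weights.index).to_numpy(),
             "drug_id": self.drug_id,
             "lineage": self.lineage}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SignatureWeights":
        return cls(
            drug_id=str(df["drug_id"].iloc[0]),
            lineage=str(df["lineage"].iloc[0]),
            weights=pd.Series(df["weight"].to_numpy(), index=df["gene_id"]),
            n_samples=pd.Series(df["n_samples"].to_numpy(), index=df["gene_id"]),
        )


@dataclass
class ScoreVector:
    """Per-sample polygenic scores plus bookkeeping about dropped genes."""

    scores: pd.Series
    genes_used: int
    genes_missing: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": list(self.scores.index),
                             "score": self.scores.to_numpy()})


def fit_weights(
    expr: ExpressionMatrix,
    resp: DrugResponseTable,
    genes,
    drug_id: str,
    lineage: str,
    annotation: SampleAnnotation,
    min_samples: int = 9,
) -> SignatureWeights:
    """Fit per-gene SCC weights within one (drug, lineage) context."""
    lineage_samples = annotation.samples_in_lineage(lineage)
    y = resp.response_vector(drug_id)
    shared = [s for s in lineage_samples if s in expr.data.columns and s in y.index]
    if len(shared) < min_samples:
        raise ValueError(
            f"lineage {lineage!r} has {len(shared)} usable sample(s) for {drug_id!r}; "
            f"the inclusion rule requires at least {min_samples}"
        )
    genes = [g for g in genes]
    absent = [g for g in genes if g not in expr.data.index]
    if absent:
        logger.warning("fit_weights: %d gene(s) absent from panel, omitted: %s",
                       len(absent), absent[:10])
    present = [g for g in genes if g in expr.data.index]
    X = expr.data.loc[present, shared].T  # samples x genes
    scorer = PolygenicScorer(min_samples=min_samples).fit(X, y.loc[shared].to_numpy())
    return SignatureWeights(drug_id, lineage, scorer.weights_, scorer.n_samples_)


def compute_score(weights: SignatureWeights, expr: ExpressionMatrix) -> ScoreVector:
    """Apply Eq.-style weights to a (z-scored) cohort matrix.

    Genes absent from the matrix are dropped without re-normalization and
    reported in ``genes_missing``; missing individual entries contribute 0.
    """
    if not expr.zscored:
        logger.warning("compute_score: expression matrix is not flagged as z-scored")
    scorer = PolygenicScorer()
    scorer.weights_ = weights.weights
    X = expr.data.T  # samples x genes
    values = scorer.transform(X)[:, 0]
    return ScoreVector(
        scores=pd.Series(values, index=expr.data.columns),
        genes_used=weights.n_genes - len(scorer.genes_missing_),
        genes_missing=list(scorer.genes_missing_),
    )


@dataclass
class ScoreGeneComparison:
    """Per-drug score-vs-baseline correlations and their rank-sum contrast."""

    table: pd.DataFrame            # drug_id, n, rho_score, rho_gene, z_score, z_gene
    p_value: float                 # two-sided Wilcoxon rank-sum on the Z columns
    low_power: bool


def compare_score_vs_gene(
    expr: ExpressionMatrix,
    resp: DrugResponseTable,
    weights: SignatureWeights,
    baseline_gene: str,
    drug_ids=None,
    min_samples: int = 9,
) -> ScoreGeneComparison:
    """Contrast the polygenic score against a single-gene baseline across
    drugs, on the Fisher-Z scale.

    For each drug the Spearman correlation of (a) the score and (b) the
    baseline gene's expression with response is computed, Fisher-Z scaled
    with that drug's sample count, and the two Z distributions compared with
    a two-sided Wilcoxon rank-sum test.
    """
    if baseline_gene not in expr.data.index:
        raise ValueError(f"baseline gene {baseline_gene!r} absent from the panel")
    if drug_ids is None:
        drug_ids = resp.drug_ids
    score = compute_score(weights, expr).scores
    rows = []
    for drug_id in sorted(drug_ids):
        y = resp.response_vector(drug_id)
        shared = [s for s in expr.data.columns if s in y.index]
        if len(shared) < max(min_samples, 4):
            continue
        yv = y.loc[shared].to_numpy(dtype=float)
        rho_s, _ = spearman(score.loc[shared].to_numpy(), yv)
        rho_g, _ = spearman(expr.data.loc[baseline_gene, shared].to_numpy(), yv)
        if not (np.isfinite(rho_s) and np.isfinite(rho_g)):
            continue
        n = len(shared)
        rows.append(
            {"drug_id": drug_id, "n": n,
             "rho_score": rho_s, "rho_gene": rho_g,
             "z_score": fisher_zscore(min(max(rho_s, -0.999999), 0.999999), n),
             "z_gene": fisher_zscore(min(max(rho_g, -0.999999), 0.999999), n)}
        )
    if len(rows) < 2:
        raise ValueError("need at least 2 evaluable drugs for the comparison")
    table = pd.DataFrame(rows)
    stat = stats.ranksums(table["z_score"], table["z_gene"])
    low_power = len(rows) < 5
    if low_power:
        logger.warning("compare_score_vs_gene: only %d drugs — low power", len(rows))
    return ScoreGeneComparison(table=table, p_value=float(stat.pvalue), low_power=low_power)
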