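"""Genome-wide Spearman screening of expression against drug response.

For one drug, every gene's z-scored expression is correlated (Spearman, SCC)
with the response values of the samples shared between the expression panel
and that drug's records.  P-values use the large-sample t approximation and
are BH-adjusted across the genes tested for that drug; genes are ranked by
descending rho (1 = most resistance-associated), ties broken by gene id so
rankings are reproducible.

Pairwise-complete handling: samples missing either the expression value or
the response are dropped per gene; a gene is testable only if at least
``min_samples`` complete pairs remain and both vectors are non-constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import DrugResponseTable, ExpressionMatrix

logger = logging.getLogger(__name__)

#: columns of a per-drug correlation table
RECORD_COLUMNS = ["gene_id", "drug_id", "rho", "n_samples", "p_value", "p_adjusted", "rank"]

_TINY = np.finfo(float).tiny


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho and two-sided p for a single vector pair.

    Pairwise-complete; returns ``(nan, nan)`` (an undefined-result marker,
    not an exception) when fewer than 3 complete pairs remain or either
    vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m = np.isfinite(x) & np.isfinite(y)
    x, y = x[m], y[m]
    if x.size < 3 or np.unique(x).size < 2 or np.unique(y).size < 2:
        return (np.nan, np.nan)
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(min(max(p, _TINY), 1.0))


def _rho_pvalues(rho: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p from the t approximation t = rho*sqrt((n-2)/(1-rho^2))."""
    rho = np.asarray(rho, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2.0) / ((1.0 - rho) * (1.0 + rho)))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2.0)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    return np.clip(p, _TINY, 1.0)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p-values, input order preserved, capped at 1.

    adj_(i) = min_{j >= i} ( p_(j) * m / j ), computed in this exact form so
    the adjustment is reproducible to the bit against the textbook step-up
    definition (statsmodels' fdr_bh is the cross-check in the test-suite).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def screen_drug(
    expr: ExpressionMatrix,
    resp: DrugResponseTable,
    drug_id: str,
    min_samples: int = 9,
) -> pd.DataFrame:
    """Correlate every gene with one drug's response.

    Returns a table with columns ``gene_id, drug_id, rho, n_samples, p_value,
    p_adjusted, rank`` sorted by rank. Untestable genes (too few complete
    pairs, or constant within the complete pairs) are excluded and counted in
    the log.
    """
    y_all = resp.response_vector(drug_id)
    shared = expr.data.columns.intersection(y_all.index)
    if len(shared) == 0:
        raise ValueError(f"drug {drug_id!r}: no samples shared with the expression panel")
    if len(shared) < max(min_samples, 3):
        raise ValueError(
            f"drug {drug_id!r}: only {len(shared)} shared sample(s), "
            f"need at least {max(min_samples, 3)}"
        )
    X = expr.data[shared].to_numpy(dtype=float)
    y = y_all.loc[shared].to_numpy(dtype=float)
    ok_y = np.isfinite(y)
    X, y = X[:, ok_y], y[ok_y]
    genes = np.asarray(expr.data.index)

    n_total = y.size
    rho = np.full(genes.size, np.nan)
    nvec = np.zeros(genes.size, dtype=int)
    finite = np.isfinite(X)
    complete = finite.all(axis=1)

    if n_total >= max(min_samples, 3) and complete.any() and np.unique(y).size > 1:
        # fast path: rank once, correlate all complete rows as a matrix product
        Xr = stats.rankdata(X[complete], axis=1)
        yr = stats.rankdata(y)
        Xc = Xr - Xr.mean(axis=1, keepdims=True)
        yc = yr - yr.mean()
        xnorm = np.sqrt((Xc**2).sum(axis=1))
        ynorm = np.sqrt((yc**2).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (Xc @ yc) / (xnorm * ynorm)
        r[xnorm == 0] = np.nan
        rho[complete] = r
        nvec[complete] = n_total

    for i in np.flatnonzero(~complete):
        m = finite[i]
        n_i = int(m.sum())
        if n_i < max(min_samples, 3):
            continue
        r_i, _ = spearman(X[i, m], y[m])
        rho[i] = r_i
        nvec[i] = n_i

    tested = np.isfinite(rho) & (nvec >= min_samples)
    n_excluded = int((~tested).sum())
    if n_excluded:
        logger.info("screen_drug(%s): %d untestable gene(s) excluded", drug_id, n_excluded)
    if not tested.any():
        return pd.DataFrame(columns=RECORD_COLUMNS)

    out = pd.DataFrame(
        {
            "gene_id": genes[tested],
            "drug_id": drug_id,
            "rho": rho[tested],
            "n_samples": nvec[tested],
            "p_value": _rho_pvalues(rho[tested], nvec[tested]),
        }
    )
    out["p_adjusted"] = benjamini_hochberg(out["p_value"].to_numpy())
    out = out.sort_values(["rho", "gene_id"], ascending=[False, True], kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)[RECORD_COLUMNS]


@dataclass
class ScreenSet:
    """Per-drug correlation tables plus drugs that failed to screen."""

    results: dict[str, pd.DataFrame] = field(default_factory=dict)
    failed: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, drug_id: str) -> pd.DataFrame:
        return self.results[drug_id]

    def __contains__(self, drug_id: str) -> bool:
        return drug_id in self.results

    def __len__(self) -> int:
        return len(self.results)

    def items(self):
        return self.results.items()

    def keys(self):
        return self.results.keys()


def screen_all(
    expr: ExpressionMatrix,
    resp: DrugResponseTable,
    drug_ids=None,
    min_samples: int = 9,
) -> ScreenSet:
    """Screen several drugs; failures are recorded, the rest proceed.

    Drugs are processed in sorted order so output is deterministic.
    """
    if drug_ids is None:
        drug_ids = resp.drug_ids
    out = ScreenSet()
    for drug_id in sorted(drug_ids):
        try:
            out.results[drug_id] = screen_drug(expr, resp, drug_id, min_samples=min_samples)
        except (ValueError, KeyError) as exc:
            logger.warning("screen_all: drug %s failed: %s", drug_id, exc)
            out.failed[drug_id] = str(exc)
    return out
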