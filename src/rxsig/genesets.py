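"""Score vs gene-set association and annotation enrichment.

Two complementary analyses: (1) correlate the polygenic score with each gene
of an external set in a patient cohort (the surrogate test for resistance
programs: how many set genes are significantly positively correlated with
the score?), with a top-k cross-cohort overlap; (2) Fisher's exact test for
enrichment of an annotation (e.g. tumor-suppressor genes) within the
signature against a gene universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix
from .screen import benjamini_hochberg, spearman

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCorrelation:
    """Per-gene correlation of a set with the score in one cohort."""

    table: pd.DataFrame           # gene_id, rho, p_value, p_adjusted, significant_positive
    n_significant_positive: int
    excluded_genes: list[str]     # set genes absent from the cohort matrix
    alpha: float
    cohort: str = ""

    @property
    def set_size_tested(self) -> int:
        return len(self.table)


def score_geneset_correlation(
    scores, expr: ExpressionMatrix, gene_set, alpha: float = 0.05, cohort: str = ""
) -> GeneSetCorrelation:
    """Spearman-correlate each set gene's expression with the score; BH
    within the set; count significant positive genes."""
    if hasattr(scores, "scores"):
        scores = scores.scores
    s = pd.Series(scores, dtype=float)
    gene_set = list(dict.fromkeys(gene_set))
    if not gene_set:
        raise ValueError("empty gene set")
    shared = [c for c in expr.data.columns if c in s.index]
    if len(shared) < 10:
        raise ValueError(f"need >= 10 samples with both score and expression, got {len(shared)}")
    present = [g for g in gene_set if g in expr.data.index]
    excluded = [g for g in gene_set if g not in expr.data.index]
    if not present:
        raise ValueError("no gene of the set is present in the expression matrix")
    if excluded:
        logger.info("score_geneset_correlation: %d set gene(s) absent from cohort", len(excluded))
    sv = s.loc[shared].to_numpy()
    rows = []
    for g in present:
        rho, p = spearman(expr.data.loc[g, shared].to_numpy(), sv)
        if np.isfinite(rho):
            rows.append({"gene_id": g, "rho": rho, "p_value": p})
        else:
            excluded.append(g)
    table = pd.DataFrame(rows)
    table["p_adjusted"] = benjamini_hochberg(table["p_value"].to_numpy())
    table["significant_positive"] = (table["rho"] > 0) & (table["p_adjusted"] < alpha)
    return GeneSetCorrelation(
        table=table.reset_index(drop=True),
        n_significant_positive=int(table["significant_positive"].sum()),
        excluded_genes=excluded,
        alpha=alpha,
        cohort=cohort,
    )


def top_k_overlap(result_a: GeneSetCorrelation, result_b: GeneSetCorrelation,
                  k: int = 50) -> list[str]:
    """Genes in both cohorts' top-k significant-positive lists (by rho),
    sorted by descending mean rho."""
    def top(res: GeneSetCorrelation) -> pd.DataFrame:
        sig = res.table[res.table["significant_positive"]]
        if len(sig) < k:
            logger.warning("top_k_overlap: only %d significant genes available (k=%d)",
                           len(sig), k)
        return sig.sort_values(["rho", "gene_id"], ascending=[False, True],
                               kind="mergesort").head(k)

    ta, tb = top(result_a), top(result_b)
    common = set(ta["gene_id"]) & set(tb["gene_id"])
    if not common:
        return []
    mean_rho = (ta.set_index("gene_id")["rho"].loc[sorted(common)]
                + tb.set_index("gene_id")["rho"].loc[sorted(common)]) / 2.0
    return list(mean_rho.sort_values(ascending=False, kind="mergesort").index)


def fisher_exact_enrichment(signature_genes, annotation_genes, universe_genes):
    """Two-sided Fisher's exact test on the 2x2 (in/out signature) x (in/out
    annotation) table over a gene universe.

    Returns ``(odds_ratio, p_value)`` where the odds ratio is the sample
    (unconditional) cross-product ratio; ``inf`` marks a degenerate margin.
    """
    universe = set(universe_genes)
    if not universe:
        raise ValueError("empty gene universe")
    sig = set(signature_genes)
    ann = set(annotation_genes)
    if not sig <= universe:
        raise ValueError("signature genes must be a subset of the universe")
    if not ann <= universe:
        raise ValueError("annotation genes must be a subset of the universe")
    a = len(sig & ann)
    b = len(sig - ann)
    c = len(ann - sig)
    d = len(universe - sig - ann)
    odds_ratio, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds_ratio), float(p)


def read_gmt(path) -> dict[str, list[str]]:
    """Read GMT gene sets: one set per line (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = [p.strip() for p in line.rstrip("\n").split("\t")]
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g.upper() for g in parts[2:] if g]
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


def read_gene_list(path) -> list[str]:
    """One gene symbol per line; upper-cased, de-duplicated, order kept."""
    with open(path, encoding="utf-8") as fh:
        genes = [line.strip().upper() for line in fh if line.strip()]
    return list(dict.fromkeys(genes))
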