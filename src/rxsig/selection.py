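"""Multi-drug resistance gene selection and cross-panel validation.

A gene counts toward selection for a drug when it is significantly
(BH-adjusted p < alpha) *positively* correlated with response and ranks in
the drug's top-K genes by rho.  Genes counted for at least ``min_drugs``
drugs form the signature ("top 50 genes for 20 or more drugs" in the default
parameterization).  Validation in an independent panel uses a top-fraction
cutoff (top 2% of tested genes by default) instead of a fixed K.  The
mirror-image procedure selects sensitivity genes: significantly negatively
correlated in both of two panels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class SignatureSelection:
    """Selected genes, the per-gene drug counts behind them, and parameters."""

    selected_genes: list[str]
    per_gene_drug_count: pd.Series  # every gene counted for >=1 drug
    top_k: int
    min_drugs: int
    alpha: float
    n_drugs_screened: int = 0

    def to_frame(self) -> pd.DataFrame:
        counts = self.per_gene_drug_count
        return pd.DataFrame(
            {
                "gene_id": list(counts.index),
                "drug_count": counts.to_numpy(),
                "selected": [g in set(self.selected_genes) for g in counts.index],
            }
        )


def _as_results(screens) -> dict[str, pd.DataFrame]:
    return screens.results if hasattr(screens, "results") else dict(screens)


def select_resistance_genes(
    screens, top_k: int = 50, min_drugs: int = 20, alpha: float = 0.05
) -> SignatureSelection:
    """Select genes in the top-``top_k`` (by rho), significant and positive,
    for at least ``min_drugs`` drugs.

    Output order: descending drug count, then gene id.
    """
    if top_k < 1 or min_drugs < 1:
        raise ValueError("top_k and min_drugs must be positive")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    results = _as_results(screens)
    if not results:
        raise ValueError("no screened drugs provided")
    counts: dict[str, int] = {}
    for drug_id in sorted(results):
        rec = results[drug_id]
        if rec.empty:
            continue
        hits = rec[(rec["p_adjusted"] < alpha) & (rec["rank"] <= top_k) & (rec["rho"] > 0)]
        for gene in hits["gene_id"]:
            counts[gene] = counts.get(gene, 0) + 1
    count_series = pd.Series(counts, dtype=int).sort_index()
    if not count_series.empty:
        count_series = count_series.sort_values(ascending=False, kind="mergesort")
    selected = [g for g, c in count_series.items() if c >= min_drugs]
    return SignatureSelection(
        selected_genes=selected,
        per_gene_drug_count=count_series,
        top_k=top_k,
        min_drugs=min_drugs,
        alpha=alpha,
        n_drugs_screened=len(results),
    )


def validate_in_second_panel(
    genes, screens2, top_fraction: float = 0.02, alpha: float = 0.05
) -> pd.DataFrame:
    """Count, per gene, the drugs of an independent panel for which the gene
    is significant, positive, and within the top ``top_fraction`` of tested
    genes (ceiling cutoff).

    Genes entirely absent from the second panel get count 0 and
    ``present=False`` (the situation the pipeline hits when a platform did
    not measure a signature gene).
    """
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must be in (0, 1]")
    results = _as_results(screens2)
    genes = list(genes)
    counts = {g: 0 for g in genes}
    seen = {g: False for g in genes}
    for drug_id in sorted(results):
        rec = results[drug_id]
        if rec.empty:
            continue
        cutoff = math.ceil(top_fraction * len(rec))
        hits = rec[(rec["p_adjusted"] < alpha) & (rec["rho"] > 0) & (rec["rank"] <= cutoff)]
        hit_genes = set(hits["gene_id"])
        present_genes = set(rec["gene_id"])
        for g in genes:
            if g in present_genes:
                seen[g] = True
            if g in hit_genes:
                counts[g] += 1
    absent = [g for g in genes if not seen[g]]
    if absent:
        logger.warning("validate_in_second_panel: %d gene(s) absent from panel: %s",
                       len(absent), absent[:10])
    return pd.DataFrame(
        {"gene_id": genes,
         "validated_drugs": [counts[g] for g in genes],
         "present": [seen[g] for g in genes]}
    )


def _single_drug_table(screens, which: str) -> pd.DataFrame:
    if isinstance(screens, pd.DataFrame):
        return screens
    results = _as_results(screens)
    if len(results) != 1:
        raise ValueError(
            f"panel {which}: sensitivity selection needs screens restricted to one drug, "
            f"got {len(results)}"
        )
    return next(iter(results.values()))


def select_sensitivity_genes(screens_a, screens_b, alpha: float = 0.05) -> list[str]:
    """Genes significantly *negatively* correlated with response in both of
    two single-drug screens; sorted by gene id."""
    rec_a = _single_drug_table(screens_a, "A")
    rec_b = _single_drug_table(screens_b, "B")
    if rec_a.empty or rec_b.empty:
        raise ValueError("sensitivity selection: a panel has no screened records for the drug")
    neg_a = set(rec_a.loc[(rec_a["rho"] < 0) & (rec_a["p_adjusted"] < alpha), "gene_id"])
    neg_b = set(rec_b.loc[(rec_b["rho"] < 0) & (rec_b["p_adjusted"] < alpha), "gene_id"])
    return sorted(neg_a & neg_b)
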