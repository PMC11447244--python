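"""Signature-minus-k ablation: is every gene of the signature required?

Each candidate gene subset is deleted from the score (pure term deletion —
remaining weights are NOT refitted), the cohort is re-scored and re-split at
the median, and the multivariate Cox hazard ratio of the HIGH-vs-LOW
indicator is refit with the same clinical covariates.  The change in HR
against the full signature says whether the removed genes were carrying
predictive signal (HR drops) or diluting it (HR rises).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .io import ExpressionMatrix
from .score import SignatureWeights, compute_score
from .survival import score_group_cox

logger = logging.getLogger(__name__)

INCREASED, DECREASED, UNCHANGED = "INCREASED", "DECREASED", "UNCHANGED"

#: |delta HR| below this is called UNCHANGED (zero-weight removals land here)
_DELTA_TOL = 1e-9


@dataclass
class AblationReport:
    signature_genes: tuple
    full_hazard_ratio: float
    full_p_value: float
    results: pd.DataFrame  # removed_genes, hazard_ratio, p_value, delta_hr, direction

    def increased(self) -> list[tuple]:
        sel = self.results[self.results["direction"] == INCREASED]
        return [tuple(g.split("|")) for g in sel["removed_genes"]]


def _candidate_sets(weights: SignatureWeights, subset_sizes, candidate_sets, exhaustive):
    genes = list(weights.weights.index)
    if candidate_sets is not None:
        sets = [tuple(sorted({g} if isinstance(g, str) else g)) for g in candidate_sets]
    else:
        sets = []
        for size in subset_sizes:
            if size < 1:
                raise ValueError("subset sizes must be >= 1")
            if size == 1:
                sets.extend((g,) for g in genes)
            elif exhaustive:
                sets.extend(tuple(sorted(c)) for c in combinations(genes, size))
            else:
                raise ValueError(
                    f"subset size {size} > 1 requires explicit candidate_sets "
                    "or exhaustive=True"
                )
    for s in sets:
        unknown = set(s) - set(genes)
        if unknown:
            raise KeyError(f"removal set {s} not a subset of the signature: {sorted(unknown)}")
        if len(s) >= len(genes):
            raise ValueError(f"removal set {s} would leave an empty signature")
    return sets


def ablate(
    weights: SignatureWeights,
    cohort_expr: ExpressionMatrix,
    clinical: pd.DataFrame,
    covariates=(),
    subset_sizes=(1,),
    candidate_sets=None,
    exhaustive: bool = False,
) -> AblationReport:
    """Delete gene subsets from the score and record the resulting HR shift.

    Results are sorted by descending ``delta_hr`` (removals that *increase*
    the hazard ratio first), with the full-signature HR recorded once.
    """
    covariates = list(covariates)
    full = score_group_cox(clinical, compute_score(weights, cohort_expr).scores,
                           covariates=covariates, stratify="MEDIAN")
    full_hr = full.hazard_ratio("score_high")
    full_p = full.p_value("score_high")

    rows = []
    for removal in _candidate_sets(weights, subset_sizes, candidate_sets, exhaustive):
        reduced = weights.drop(removal)
        res = score_group_cox(clinical, compute_score(reduced, cohort_expr).scores,
                              covariates=covariates, stratify="MEDIAN")
        hr = res.hazard_ratio("score_high")
        delta = hr - full_hr
        if abs(delta) <= _DELTA_TOL:
            direction = UNCHANGED
        else:
            direction = INCREASED if delta > 0 else DECREASED
        rows.append({"removed_genes": "|".join(removal),
                     "n_removed": len(removal),
                     "hazard_ratio": hr,
                     "p_value": res.p_value("score_high"),
                     "delta_hr": delta,
                     "direction": direction})
    results = (pd.DataFrame(rows)
               .sort_values(["delta_hr", "removed_genes"], ascending=[False, True],
                            kind="mergesort")
               .reset_index(drop=True))
    return AblationReport(
        signature_genes=tuple(weights.weights.index),
        full_hazard_ratio=full_hr,
        full_p_value=full_p,
        results=results,
    )


def consistent_removals(report_a: AblationReport, report_b: AblationReport) -> list[tuple]:
    """Removal sets whose deletion INCREASED the HR in both cohorts."""
    if set(report_a.signature_genes) != set(report_b.signature_genes):
        raise ValueError("ablation reports come from different signatures")
    inc_a = {tuple(sorted(s)) for s in report_a.increased()}
    inc_b = {tuple(sorted(s)) for s in report_b.increased()}
    return sorted(inc_a & inc_b)
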