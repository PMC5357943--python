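"""Kaplan-Meier / log-rank prioritization of switch genes.

For each candidate gene, patients are stratified into a low cohort
(tumor expression strictly below the 25th percentile) and a high cohort
(strictly above the 75th); the separation of their survival curves is
scored by the unweighted two-group log-rank test and genes are ranked by
increasing p-value.  Estimation and testing go through lifelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from statsmodels.stats.multitest import multipletests

from .io import ClinicalTable, ExpressionMatrix

__all__ = [
    "KMCurve",
    "stratify_by_expression",
    "km_estimate",
    "logrank_test",
    "rank_switch_genes_by_survival",
]


@dataclass
class KMCurve:
    """Product-limit survival curve: step times, survival values, at-risk counts."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.survival, dtype=float)
        if s.size and (np.any(np.diff(s) > 1e-12) or s.min() < -1e-12 or s.max() > 1 + 1e-12):
            raise ValueError("survival curve must be non-increasing within [0, 1]")


def _cohort_frame(records) -> pd.DataFrame:
    df = pd.DataFrame(records)
    required = {"time_days", "event"}
    if not required <= set(df.columns):
        raise ValueError(f"cohort needs columns {sorted(required)}")
    return df


def stratify_by_expression(
    em: ExpressionMatrix,
    clinical: ClinicalTable,
    gene: str,
    low_q: float = 0.25,
    high_q: float = 0.75,
    max_followup_days: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame] | None:
    """Split patients into low (< Q1) / high (> Q3) tumor-expression cohorts.

    Inequalities are strict, so patients tied at a quartile fall into the
    excluded middle.  Returns ``None`` (with a warning) when either cohort
    is empty, e.g. for a constant gene.  ``max_followup_days`` optionally
    right-censors follow-up at a horizon.
    """
    if gene not in em.gene_ids:
        raise KeyError(f"gene {gene!r} not in expression matrix")
    expr = em.patient_expression(gene, "tumor")
    expr = expr[expr.index.isin(clinical.patient_ids)]
    if expr.empty:
        warnings.warn(f"{gene}: no tumor patients with clinical records")
        return None
    q_low, q_high = np.quantile(expr, [low_q, high_q])
    cohorts = []
    for name, mask in (("low", expr < q_low), ("high", expr > q_high)):
        patients = expr.index[mask]
        if len(patients) == 0:
            warnings.warn(f"{gene}: empty {name}-expression cohort; gene skipped")
            return None
        rec = clinical.data.loc[patients, ["time_days", "event"]].copy()
        if max_followup_days is not None:
            over = rec["time_days"] > max_followup_days
            rec.loc[over, "event"] = False
            rec.loc[over, "time_days"] = max_followup_days
        rec["group"] = name
        rec.index.name = "patient_id"
        cohorts.append(rec.reset_index())
    return cohorts[0], cohorts[1]


def km_estimate(cohort) -> KMCurve:
    """Kaplan-Meier product-limit estimate S(t) = prod (1 - d_i / n_i)."""
    df = _cohort_frame(cohort)
    if df.empty:
        raise ValueError("empty cohort")
    kmf = KaplanMeierFitter()
    kmf.fit(df["time_days"], event_observed=df["event"].astype(bool))
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(times).to_numpy(dtype=float)
    return KMCurve(times=times, survival=surv, at_risk=at_risk)


def logrank_test(a, b) -> tuple[float, float]:
    """Unweighted two-group log-rank test; returns (chi_square, p_value).

    With zero events overall the statistic is undefined; 0 and p = 1 are
    returned with a warning.
    """
    a, b = _cohort_frame(a), _cohort_frame(b)
    if a.empty or b.empty:
        raise ValueError("both cohorts must be non-empty")
    if int(a["event"].sum() + b["event"].sum()) == 0:
        warnings.warn("no events in either cohort; log-rank undefined, p = 1")
        return 0.0, 1.0
    res = _ll_logrank(
        a["time_days"], b["time_days"],
        event_observed_A=a["event"].astype(bool),
        event_observed_B=b["event"].astype(bool),
    )
    return float(res.test_statistic), float(res.p_value)


def rank_switch_genes_by_survival(
    em: ExpressionMatrix,
    clinical: ClinicalTable,
    switch_genes,
    low_q: float = 0.25,
    high_q: float = 0.75,
    max_followup_days: float | None = None,
) -> tuple[pd.DataFrame, list]:
    """Rank genes by the prognostic separation of their expression cohorts.

    Returns the table (gene, chi_square, p, q_bh, n_low, n_high) sorted by
    ascending p — the ranking uses raw p-values; the BH column is reported
    for convenience only — plus the list of skipped (unevaluable) genes.
    """
    switch_genes = list(switch_genes)
    if not switch_genes:
        raise ValueError("switch gene list is empty")
    rows, skipped = [], []
    for gene in switch_genes:
        split = stratify_by_expression(
            em, clinical, gene, low_q, high_q, max_followup_days
        )
        if split is None:
            skipped.append(gene)
            continue
        low, high = split
        chi2, p = logrank_test(low, high)
        rows.append(
            {"gene": gene, "chi_square": chi2, "p": p,
             "n_low": len(low), "n_high": len(high)}
        )
    table = pd.DataFrame(rows, columns=["gene", "chi_square", "p", "n_low", "n_high"])
    if not table.empty:
        table["q_bh"] = multipletests(table["p"], method="fdr_bh")[1]
        table = table.sort_values(["p", "gene"], kind="mergesort").reset_index(drop=True)
    return table, skipped
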