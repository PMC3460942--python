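"""The Correlation step: cluster identity vs relapse status, gene by gene.

For every gene the two-cluster mixture model assigns each sample an unsupervised
cluster label from its expression and cell-type composition. A 2x2 contingency
table of cluster identity against observed biochemical relapse status is tested
with a Pearson chi-square (1 df, no continuity correction); genes with p below
the selection threshold (default 0.005) are kept. Each selected gene is then
attributed to tumor or stroma by refitting the two restricted models (only the
tumor, resp. stroma, coefficient cluster-varying) and taking the smaller BIC; a
BIC difference of 2 or more is flagged as strong evidence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ClinicalTable, CompositionTable, ExpressionMatrix
from .mixture import MixtureSpec, fit_gene_batch

logger = logging.getLogger("ccprog")

STRONG_EVIDENCE_DELTA = 2.0


@dataclass
class ContingencyResult:
    table: np.ndarray  # 2x2, rows = cluster identity, cols = relapse status
    statistic: float
    df: int
    p_value: float
    low_expected: bool  # any expected count < 5 (approximation warning)


def contingency_table(cluster_labels, relapse_labels) -> np.ndarray:
    """2x2 counts of cluster identity (rows) vs relapse status (columns).

    Samples with missing relapse status are excluded; each remaining label
    vector must have exactly two levels.
    """
    cluster = np.asarray(cluster_labels, dtype=float)
    relapse = np.asarray(relapse_labels, dtype=float)
    if cluster.shape != relapse.shape:
        raise ValueError("label vectors must be aligned")
    keep = ~np.isnan(relapse) & ~np.isnan(cluster)
    cluster, relapse = cluster[keep], relapse[keep]
    clevels = np.unique(cluster)
    rlevels = np.unique(relapse)
    if len(clevels) != 2:
        raise ValueError(f"cluster labels have {len(clevels)} level(s); need exactly 2")
    if len(rlevels) != 2:
        raise ValueError(f"relapse labels have {len(rlevels)} level(s); need exactly 2")
    table = np.zeros((2, 2), dtype=int)
    for i, c in enumerate(clevels):
        for j, r in enumerate(rlevels):
            table[i, j] = int(np.sum((cluster == c) & (relapse == r)))
    return table


def chi_square_test(table) -> ContingencyResult:
    """Pearson chi-square on a 2x2 table, 1 df, no continuity correction."""
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    stat, p, df, expected = stats.chi2_contingency(table, correction=False)
    return ContingencyResult(
        table=table,
        statistic=float(stat),
        df=int(df),
        p_value=float(p),
        low_expected=bool(np.any(expected < 5)),
    )


def screen_genes(
    expr: ExpressionMatrix,
    comp: CompositionTable,
    clinical: ClinicalTable,
    spec: MixtureSpec | None = None,
    alpha: float = 0.005,
    include_unknown_in_clustering: bool = False,
) -> pd.DataFrame:
    """Run the full per-gene cluster-correlation screen.

    Returns one row per gene with columns: gene_id, statistic, p_value,
    selected, attribution, bic_tumor, bic_stroma, delta_bic, strong_evidence,
    low_expected, failure, fdr_bh (informational only; selection uses the raw
    p-value threshold). ``delta_bic`` is bic_stroma - bic_tumor, so positive
    values favor the tumor-restricted model. Per-gene failures (degenerate
    clusterings, EM breakdowns) are recorded, never raised.
    """
    if spec is None:
        spec = MixtureSpec()
    comp = comp.align(expr.sample_ids)
    clinical = clinical.align(expr.sample_ids)
    known = ~np.isnan(clinical.relapse)
    if include_unknown_in_clustering:
        cluster_samples = np.ones(expr.n_samples, dtype=bool)
    else:
        cluster_samples = known
    Y = expr.values[:, cluster_samples]
    P = comp.fractions[cluster_samples]
    relapse = clinical.relapse[cluster_samples]
    n = int(cluster_samples.sum())

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = fit_gene_batch(Y, P, spec, cell_types=comp.cell_types)
    G = expr.n_genes
    stat = np.full(G, np.nan)
    pval = np.full(G, np.nan)
    low_exp = np.zeros(G, dtype=bool)
    failure = np.array([""] * G, dtype=object)
    for g in range(G):
        if not np.isfinite(full["loglik"][g]):
            failure[g] = "em_failed"
            continue
        try:
            res = chi_square_test(contingency_table(full["hard_labels"][g], relapse))
        except ValueError as e:
            failure[g] = f"contingency: {e}"
            continue
        stat[g], pval[g], low_exp[g] = res.statistic, res.p_value, res.low_expected

    selected = (pval < alpha) & (failure == "")

    bic_tumor = np.full(G, np.nan)
    bic_stroma = np.full(G, np.nan)
    attribution = np.array([""] * G, dtype=object)
    sel_idx = np.flatnonzero(selected)
    if sel_idx.size:
        for cell_type, store in (("tumor", bic_tumor), ("stroma", bic_stroma)):
            rspec = spec.restricted(cell_type)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rfit = fit_gene_batch(Y[sel_idx], P, rspec, cell_types=comp.cell_types)
            store[sel_idx] = -2.0 * rfit["loglik"] + rspec.n_params * np.log(n)
        # smaller BIC wins; exact tie attributed to tumor (documented)
        attribution[sel_idx] = np.where(
            bic_tumor[sel_idx] <= bic_stroma[sel_idx], "tumor", "stroma"
        )
    delta_bic = bic_stroma - bic_tumor
    strong = np.abs(delta_bic) >= STRONG_EVIDENCE_DELTA

    ok = ~np.isnan(pval)
    fdr = np.full(G, np.nan)
    if ok.any():
        fdr[ok] = stats.false_discovery_control(pval[ok], method="bh")

    n_failed = int((failure != "").sum())
    if n_failed:
        logger.info("screen_genes: %d gene(s) recorded as failed", n_failed)
    return pd.DataFrame(
        {
            "gene_id": expr.gene_ids,
            "statistic": stat,
            "p_value": pval,
            "selected": selected,
            "attribution": attribution,
            "bic_tumor": bic_tumor,
            "bic_stroma": bic_stroma,
            "delta_bic": delta_bic,
            "strong_evidence": np.where(selected, strong, False),
            "low_expected": low_exp,
            "failure": failure,
            "fdr_bh": fdr,
        }
    )
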