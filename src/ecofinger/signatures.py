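"""Downstream surrogate signatures of an interaction fingerprint.

Cells (or samples) with the fingerprint pairs are compared against those
without by per-gene two-sided Wilcoxon rank-sum tests with
Benjamini-Hochberg adjustment; genes passing strict log-fold-change and
adjusted-p thresholds form two disjoint surrogate sets (up in the
with-pair group, up in the without-pair group), whose bulk-expression
ratio is then associated with the geometric-mean fingerprint score.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "differential_expression",
    "extract_surrogates",
    "surrogate_association",
]

EPS = 1e-8


def differential_expression(
    norm,
    group_labels,
    group_a=None,
    group_b=None,
) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum DE between two cell groups.

    ``norm`` is an AnnData (normalized log expression) or a cells x
    genes DataFrame; ``group_labels`` assigns each cell to one of two
    groups (``group_a`` is the "with-pair" reference; defaults to the
    first label in sorted order).  The log fold-change is
    ``log(mean(expm1 x_a) + 1) - log(mean(expm1 x_b) + 1)``; p-values
    are two-sided Wilcoxon rank-sum with BH adjustment.  Genes constant
    across both groups get p = 1 and logFC = 0.
    """
    if hasattr(norm, "var_names"):
        X = pd.DataFrame(
            np.asarray(norm.X, dtype=np.float64),
            index=norm.obs_names,
            columns=norm.var_names,
        )
    else:
        X = norm.astype(np.float64)
    labels = pd.Series(group_labels, index=X.index)
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {uniq}")
    group_a = group_a if group_a is not None else uniq[0]
    group_b = group_b if group_b is not None else next(
        u for u in uniq if u != group_a
    )
    A = X[labels == group_a].to_numpy()
    B = X[labels == group_b].to_numpy()
    if A.shape[0] < 3 or B.shape[0] < 3:
        raise ValueError("both groups need >= 3 cells")

    lfc = np.log(np.expm1(A).mean(axis=0) + 1.0) - np.log(
        np.expm1(B).mean(axis=0) + 1.0
    )
    pvals = np.ones(X.shape[1])
    for j in range(X.shape[1]):
        a, b = A[:, j], B[:, j]
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            lfc[j] = 0.0
            continue
        pvals[j] = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    adj = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {"log_fc": lfc, "p_value": pvals, "adj_p_value": adj},
        index=X.columns,
    )


def extract_surrogates(
    de: pd.DataFrame,
    lfc_min: float = 1.0,
    adj_p_max: float = 0.05,
) -> dict:
    """Strict-threshold surrogate gene sets from a DE table.

    ``set1`` holds genes with log fold-change strictly above ``lfc_min``
    (up in the with-pair group), ``set2`` those strictly below
    ``-lfc_min``; both additionally need adjusted p strictly below
    ``adj_p_max``.  The sets are disjoint by construction; empty sets
    are allowed and flagged with a warning.
    """
    if len(de) == 0:
        raise ValueError("empty DE table")
    sig = de["adj_p_value"] < adj_p_max
    set1 = de.index[sig & (de["log_fc"] > lfc_min)].tolist()
    set2 = de.index[sig & (de["log_fc"] < -lfc_min)].tolist()
    for name, genes in (("set1", set1), ("set2", set2)):
        if not genes:
            logger.warning("surrogate %s is empty", name)
    return {"set1": set1, "set2": set2}


def surrogate_association(
    bulk: pd.DataFrame,
    fingerprint_genes,
    set1,
    set2,
    eps: float = EPS,
) -> dict:
    """Correlation of the fingerprint score with the surrogate ratio.

    ``bulk`` is genes x samples.  The fingerprint score per sample is
    the geometric mean of the four fingerprint genes (epsilon pseudocount
    for zeros); the surrogate ratio is mean(set1)/(mean(set2) + eps).
    Returns the per-sample scores and the Pearson r with two-sided p.
    """
    genes = list(fingerprint_genes)
    missing = [g for g in genes if g not in bulk.index]
    if missing:
        raise ValueError(f"fingerprint gene(s) missing from bulk: {missing}")
    if bulk.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    set1 = [g for g in set1 if g in bulk.index]
    set2 = [g for g in set2 if g in bulk.index]
    if not set1 or not set2:
        raise ValueError("surrogate sets must be nonempty and measurable")
    fingerprint = np.exp(np.log(bulk.loc[genes] + eps).mean(axis=0))
    ratio = bulk.loc[set1].mean(axis=0) / (bulk.loc[set2].mean(axis=0) + eps)
    r, p = stats.pearsonr(fingerprint, ratio)
    return {
        "fingerprint_score": fingerprint,
        "surrogate_ratio": ratio,
        "r": float(r),
        "p_value": float(p),
    }
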