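"""Transcriptomic heterogeneity at three levels.

Intraregional heterogeneity is the distribution of pairwise Pearson
correlations of malignant cells within one tumor region; interregional,
across regions of one patient; intertumoral, across patients.  Region
dendrograms use correlation distance with Ward agglomeration on squared
dissimilarities (the ward.D2 variant).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy.cluster.hierarchy import linkage
from scipy.stats import pearsonr

logger = logging.getLogger(__name__)

__all__ = [
    "select_variable_genes",
    "correlation_distributions",
    "region_dendrogram",
    "covariate_association",
    "immune_scores",
    "celltype_region_correlation",
]

EPS = 1e-8


def select_variable_genes(norm: AnnData, top_k: int = 2000) -> pd.DataFrame:
    """Rank genes by variance standardized against the mean-variance trend.

    Per-gene variances are standardized by an expected variance from a
    degree-2 polynomial trend fit in log10(mean)/log10(variance) space;
    standardized values are clipped at sqrt(n_cells) before the final
    variance is taken as the score.  Returns a DataFrame indexed by gene
    with a ``score`` column, sorted descending, truncated to ``top_k``.
    """
    if norm.n_obs < 2:
        raise ValueError("need at least 2 cells")
    X = np.asarray(norm.X, dtype=np.float64)
    n = X.shape[0]
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1)

    expected = np.full_like(var, np.nan)
    ok = (mean > 0) & (var > 0)
    if ok.sum() >= 3:
        coef = np.polyfit(np.log10(mean[ok]), np.log10(var[ok]), deg=2)
        expected[ok] = 10 ** np.polyval(coef, np.log10(mean[ok]))
    scores = np.zeros_like(var)
    if ok.any():
        sd = np.sqrt(expected[ok])
        z = (X[:, ok] - mean[ok]) / sd
        clip = np.sqrt(n)
        np.clip(z, -clip, clip, out=z)
        scores[ok] = z.var(axis=0, ddof=1)

    out = pd.DataFrame({"score": scores}, index=norm.var_names)
    out = out.sort_values("score", ascending=False, kind="stable")
    if top_k > norm.n_vars:
        logger.warning(
            "top_k=%d exceeds gene count %d; returning all genes",
            top_k, norm.n_vars,
        )
        top_k = norm.n_vars
    return out.iloc[:top_k]


def _pairwise_corr(X: np.ndarray) -> np.ndarray:
    """Cell-cell Pearson correlation matrix over gene vectors."""
    sd = X.std(axis=1, keepdims=True)
    dead = (sd == 0).ravel()
    if dead.any():
        logger.warning("%d constant cell vectors excluded", dead.sum())
    Z = (X - X.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, np.nan)
    return (Z @ Z.T) / X.shape[1]


def correlation_distributions(
    norm: AnnData,
    meta: pd.DataFrame,
    genes,
    patient_col: str = "patient",
    region_col: str = "region",
) -> dict:
    """Pairwise malignant-cell correlations at three levels.

    Returns ``{"pairs": DataFrame, "not_detectable": list}`` where the
    DataFrame has one row per unordered cell pair with columns ``level``
    (intraregion/interregion/intertumor), the two (patient, region)
    groups, and ``r``; regions with fewer than 2 malignant cells are
    listed as not detectable.
    """
    genes = [g for g in genes if g in norm.var_names]
    mal = meta["is_malignant"].astype(bool).to_numpy()
    sub = norm[mal, genes]
    m = meta.loc[mal]
    pats = m[patient_col].to_numpy()
    regs = m[region_col].to_numpy()

    nd = [
        key
        for key, grp in m.groupby([patient_col, region_col], observed=True)
        if len(grp) < 2
    ]

    R = _pairwise_corr(np.asarray(sub.X, dtype=np.float64))
    iu, ju = np.triu_indices(R.shape[0], k=1)
    r = R[iu, ju]
    same_pat = pats[iu] == pats[ju]
    same_reg = same_pat & (regs[iu] == regs[ju])
    level = np.where(
        same_reg, "intraregion", np.where(same_pat, "interregion", "intertumor")
    )
    pairs = pd.DataFrame(
        {
            "level": level,
            "patient_a": pats[iu],
            "region_a": regs[iu],
            "patient_b": pats[ju],
            "region_b": regs[ju],
            "r": r,
        }
    ).dropna(subset=["r"])
    return {"pairs": pairs, "not_detectable": nd}


def region_dendrogram(
    norm: AnnData,
    meta: pd.DataFrame,
    genes,
    patient_col: str = "patient",
    region_col: str = "region",
    malignant_only: bool = True,
):
    """Ward (D2) tree over (patient, region) mean expression profiles.

    Distance between samples is ``1 - Pearson r`` of their mean
    variable-gene profiles; samples are ordered lexicographically before
    linkage so the tree is invariant to input order.  Returns
    ``(linkage_matrix, sample_labels)``.
    """
    genes = [g for g in genes if g in norm.var_names]
    mask = (
        meta["is_malignant"].astype(bool).to_numpy()
        if malignant_only and "is_malignant" in meta.columns
        else np.ones(len(meta), dtype=bool)
    )
    sub = norm[mask, genes]
    m = meta.loc[mask]
    prof = (
        pd.DataFrame(np.asarray(sub.X), index=sub.obs_names)
        .groupby(
            [m[patient_col].to_numpy(), m[region_col].to_numpy()]
        )
        .mean()
    )
    prof = prof.sort_index()
    labels = [f"{p}_{r}" for p, r in prof.index]
    if len(labels) < 2:
        return None, labels
    R = np.corrcoef(prof.to_numpy())
    D = 1.0 - R
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, None)
    iu = np.triu_indices(len(labels), k=1)
    Z = linkage(D[iu], method="ward")
    return Z, labels


def covariate_association(statistic, covariate):
    """Pearson association between a per-patient summary and a covariate."""
    statistic = np.asarray(statistic, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if statistic.size != covariate.size:
        raise ValueError("statistic and covariate lengths differ")
    if statistic.size < 3:
        raise ValueError("need at least 3 patients")
    if np.std(covariate) == 0 or np.std(statistic) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    r, p = pearsonr(statistic, covariate)
    return float(r), float(p)


def immune_scores(
    norm: AnnData,
    meta: pd.DataFrame,
    signatures: dict,
    patient_col: str = "patient",
    eps: float = EPS,
) -> pd.DataFrame:
    """Per-patient pseudo-bulk immune / cytotoxic / exhaustion scores.

    Pseudo-bulk is the arithmetic mean of normalized log expression over
    all cells of a patient; each score is the mean over the signature's
    genes present in the matrix.  The cytotoxic/exhaustion ratio uses an
    epsilon-protected denominator.  Signatures with no genes in the
    matrix yield NaN and an ``undefined`` flag.
    """
    for name in ("immune", "cytotoxic", "exhaustion"):
        if name not in signatures:
            raise ValueError(f"signature {name!r} required")
    X = np.asarray(norm.X, dtype=np.float64)
    bulk = (
        pd.DataFrame(X, index=norm.obs_names, columns=norm.var_names)
        .groupby(meta[patient_col].to_numpy())
        .mean()
    )
    rows = {}
    flags = {}
    for name, genes in signatures.items():
        present = [g for g in genes if g in bulk.columns]
        if not present:
            logger.warning("signature %r has no genes in the matrix", name)
            rows[name] = pd.Series(np.nan, index=bulk.index)
            flags[name] = True
        else:
            rows[name] = bulk[present].mean(axis=1)
            flags[name] = False
    out = pd.DataFrame(rows)
    out["cytotoxic_exhaustion_ratio"] = out["cytotoxic"] / (
        out["exhaustion"] + eps
    )
    out["undefined"] = any(flags[n] for n in ("cytotoxic", "exhaustion"))
    return out


def celltype_region_correlation(
    norm: AnnData,
    meta: pd.DataFrame,
    genes_per_type: dict,
    patient_col: str = "patient",
    region_col: str = "region",
    border_region: str = "B",
    core_regions=("T1", "T2", "T3"),
) -> dict:
    """Per-cell-type region correlations and border/core ratios.

    For each cell type and patient: pairwise Pearson correlations of
    region-mean profiles over that type's variable genes
    (``region_pairs``), the mean pairwise cell-cell correlation within
    each region (``intraregion``), and the ratio of the border region's
    value to the mean over core regions (``border_core_ratio``).
    """
    region_rows, intra_rows, ratio_rows = [], [], []
    for ct, genes in genes_per_type.items():
        genes = [g for g in genes if g in norm.var_names]
        mask = (meta["cell_type"] == ct).to_numpy()
        if mask.sum() == 0 or not genes:
            logger.info("cell type %r absent or without genes; skipped", ct)
            continue
        sub = norm[mask, genes]
        m = meta.loc[mask]
        X = np.asarray(sub.X, dtype=np.float64)
        for patient, pidx in m.groupby(patient_col, observed=True).groups.items():
            sel = m.index.isin(pidx)
            Xp = X[sel]
            regs = m.loc[sel, region_col].to_numpy()
            uniq = sorted(set(regs))
            profs = {rg: Xp[regs == rg].mean(axis=0) for rg in uniq}
            for i, ra in enumerate(uniq):
                for rb in uniq[i + 1:]:
                    sa, sb = profs[ra], profs[rb]
                    if sa.std() == 0 or sb.std() == 0:
                        continue
                    region_rows.append(
                        (ct, patient, ra, rb, float(np.corrcoef(sa, sb)[0, 1]))
                    )
            intra = {}
            for rg in uniq:
                cells = Xp[regs == rg]
                if cells.shape[0] < 2:
                    continue
                R = _pairwise_corr(cells)
                iu = np.triu_indices(R.shape[0], k=1)
                intra[rg] = float(np.nanmean(R[iu]))
                intra_rows.append((ct, patient, rg, intra[rg]))
            cores = [intra[rg] for rg in core_regions if rg in intra]
            if border_region in intra and cores:
                ratio_rows.append(
                    (ct, patient, intra[border_region] / np.mean(cores))
                )
    return {
        "region_pairs": pd.DataFrame(
            region_rows,
            columns=["cell_type", "patient", "region_a", "region_b", "r"],
        ),
        "intraregion": pd.DataFrame(
            intra_rows, columns=["cell_type", "patient", "region", "mean_r"]
        ),
        "border_core_ratio": pd.DataFrame(
            ratio_rows, columns=["cell_type", "patient", "ratio"]
        ),
    }
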