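"""QC, normalization, inferred CNV and cell identity.

The malignant/non-malignant separation follows the expression-based CNV
inference idea: average normalized expression over windows of genomically
adjacent genes along each chromosome, centered on cells from adjacent
normal tissue, so that aneuploid malignant cells stand out as coherent
window-level deviations while diploid cells stay near zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scanpy as sc
from anndata import AnnData

from .config import CD3_GENES, NORMAL_REGION

logger = logging.getLogger(__name__)

__all__ = [
    "qc_and_normalize",
    "infer_cnv",
    "call_malignant",
    "assign_cell_types",
    "select_samples",
    "CNVProfile",
]


class EmptyResultError(RuntimeError):
    """All cells (or genes) were removed by a filter."""


# ---------------------------------------------------------------------------
# QC + normalization
# ---------------------------------------------------------------------------

def qc_and_normalize(
    raw: AnnData,
    min_cells_per_gene: int = 3,
    min_genes_per_cell: int = 500,
    scale_factor: float = 10_000.0,
) -> AnnData:
    """Filter genes/cells and depth-normalize to log space.

    Genes expressed in fewer than ``min_cells_per_gene`` cells and cells
    detecting fewer than ``min_genes_per_cell`` genes are dropped; each
    remaining cell is scaled to ``scale_factor`` total counts and
    log(1 + x) transformed.  Raw counts are kept in ``layers['counts']``.
    """
    if raw.n_obs == 0:
        raise EmptyResultError("input matrix has no cells")
    adata = raw.copy()
    if min_cells_per_gene > 0:
        sc.pp.filter_genes(adata, min_cells=min_cells_per_gene)
    if min_genes_per_cell > 0:
        sc.pp.filter_cells(adata, min_genes=min_genes_per_cell)
    if adata.n_obs == 0:
        raise EmptyResultError("all cells removed by QC filters")
    if adata.n_vars == 0:
        raise EmptyResultError("all genes removed by QC filters")
    adata.layers["counts"] = adata.X.copy()
    sc.pp.normalize_total(adata, target_sum=scale_factor)
    sc.pp.log1p(adata)
    adata.X = np.asarray(adata.X, dtype=np.float64)
    adata.uns["scale_factor"] = float(scale_factor)
    return adata


# ---------------------------------------------------------------------------
# CNV inference
# ---------------------------------------------------------------------------

@dataclass
class CNVProfile:
    """Cells x windows inferred copy-number matrix.

    ``values[i, j]`` is the reference-centered sliding-window mean for
    cell i in window j; ``windows`` maps each window to its chromosome
    and gene span.  Windows are ordered by chromosome then position.
    """

    values: np.ndarray
    windows: pd.DataFrame  # columns: chromosome, start_gene, end_gene
    cell_ids: pd.Index
    reference: np.ndarray = field(repr=False)  # boolean mask over cells
    # reference-centered per-gene matrix (same cells, CNV gene subset);
    # retained because gene resolution carries more degrees of freedom
    # for the malignant-call correlation feature than smoothed windows
    gene_values: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]

    def aberration_score(self) -> np.ndarray:
        """Mean squared window deviation per cell."""
        return np.mean(self.values**2, axis=1)


def infer_cnv(
    norm: AnnData,
    reference_cells,
    window_genes: int = 100,
    clip_sd: float = 3.0,
    min_mean_counts: float = 0.1,
    gene_order: pd.DataFrame | None = None,
) -> CNVProfile:
    """Infer CNVs from genomically ordered, window-averaged expression.

    Parameters
    ----------
    norm
        Normalized (log) expression; gene order is taken from
        ``norm.var[['chromosome', 'position']]`` unless ``gene_order`` is
        given (indexed by gene id).
    reference_cells
        Boolean mask or list of cell ids defining the diploid reference
        (adjacent-normal cells).
    window_genes
        Sliding-window length in genes (step 1) within each chromosome;
        chromosomes with fewer genes collapse to one window.
    clip_sd
        Values are clipped at ``clip_sd`` standard deviations of the
        reference-cell window values; nonpositive disables clipping.
    min_mean_counts
        Genes with mean raw counts per cell below this cutoff are
        excluded before windowing (the usual expression cutoff of
        expression-based CNV inference for droplet data); set to 0 to
        keep every gene.  Counts come from ``layers['counts']`` when
        present, otherwise from expm1 of the normalized values.
    """
    order = gene_order if gene_order is not None else norm.var
    if not {"chromosome", "position"} <= set(order.columns):
        raise ValueError("gene order needs 'chromosome' and 'position'")

    if min_mean_counts > 0:
        counts = (
            norm.layers["counts"]
            if "counts" in norm.layers
            else np.expm1(np.asarray(norm.X))
        )
        expressed = np.asarray(counts).mean(axis=0) >= min_mean_counts
        norm = norm[:, expressed]

    known = norm.var_names.intersection(order.index)
    missing = norm.var_names.difference(order.index)
    if len(missing):
        logger.warning(
            "%d genes absent from the gene order were excluded from CNV "
            "inference", len(missing)
        )
    if len(known) == 0:
        raise ValueError("no genes overlap the gene order")

    ref = np.asarray(
        norm.obs_names.isin(reference_cells)
        if not isinstance(reference_cells, np.ndarray)
        or reference_cells.dtype != bool
        else reference_cells
    )
    if ref.sum() == 0:
        raise ValueError("reference cell set is empty")

    sub = order.loc[known].sort_values(["chromosome", "position"])
    X = np.asarray(norm[:, sub.index].X, dtype=np.float64)
    # center genes on the reference mean
    X = X - X[ref].mean(axis=0, keepdims=True)

    values_parts = []
    win_rows = []
    chroms = sub["chromosome"]
    for chrom in chroms.unique():
        idx = np.flatnonzero((chroms == chrom).to_numpy())
        w = min(window_genes, idx.size)
        block = X[:, idx]
        cs = np.cumsum(
            np.concatenate([np.zeros((X.shape[0], 1)), block], axis=1), axis=1
        )
        n_win = idx.size - w + 1
        means = (cs[:, w:] - cs[:, :-w])[:, :n_win] / w
        values_parts.append(means)
        for s in range(n_win):
            win_rows.append(
                (
                    chrom,
                    sub.index[idx[s]],
                    sub.index[idx[s + w - 1]],
                )
            )
    values = np.concatenate(values_parts, axis=1)
    # subtract the per-window reference mean (exact re-centering)
    values -= values[ref].mean(axis=0, keepdims=True)
    ref_sd = values[ref].std()
    if clip_sd > 0 and ref_sd > 0 and np.isfinite(ref_sd):
        bound = clip_sd * ref_sd
        np.clip(values, -bound, bound, out=values)
    windows = pd.DataFrame(
        win_rows, columns=["chromosome", "start_gene", "end_gene"]
    )
    return CNVProfile(
        values=values,
        windows=windows,
        cell_ids=norm.obs_names.copy(),
        reference=ref,
        gene_values=X,
    )


# ---------------------------------------------------------------------------
# malignant calling
# ---------------------------------------------------------------------------

def _two_means_1d(x: np.ndarray) -> np.ndarray:
    """Exact 1-D 2-means: boolean mask of the upper cluster.

    Minimizes within-cluster sum of squares over all sorted split
    points; deterministic and invariant to input order.
    """
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = len(xs)
    cs = np.cumsum(xs)
    css = np.cumsum(xs**2)
    k = np.arange(1, n)  # lower-cluster size
    sse_lo = css[:-1] - cs[:-1] ** 2 / k
    sse_hi = (css[-1] - css[:-1]) - (cs[-1] - cs[:-1]) ** 2 / (n - k)
    split = int(np.argmin(sse_lo + sse_hi)) + 1
    mask = np.zeros(n, dtype=bool)
    mask[order[split:]] = True
    return mask


def _centroid_correlation(values: np.ndarray, centroid: np.ndarray):
    c = centroid - centroid.mean()
    c_sd = c.std()
    v_sd = values.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (values - values.mean(axis=1, keepdims=True)) @ c / (
            values.shape[1]
            * np.where(v_sd > 0, v_sd, np.nan)
            * (c_sd if c_sd > 0 else np.nan)
        )
    return np.nan_to_num(corr)


def call_malignant(
    cnv: CNVProfile,
    meta: pd.DataFrame,
    min_coherence_z: float = 3.0,
    n_refinements: int = 2,
) -> pd.DataFrame:
    """Partition cells into malignant / non-malignant from CNV aberration.

    Each cell gets an aberration score (mean squared window deviation,
    reported as ``cnv_score``) and a correlation with the centroid
    profile of the top-decile cells, computed at gene resolution when
    available (gene resolution carries far more degrees of freedom than
    the smoothed windows, which are strongly autocorrelated).  Exact
    1-D 2-means on the correlation axis (optimal sorted split, hence
    deterministic and invariant to cell order) separates the two
    groups; the centroid is then refined from the called group and the
    clustering repeated (``n_refinements`` passes).  The higher-correlation group
    is accepted as malignant only when its mean centroid correlation
    exceeds ``min_coherence_z`` times the reference cells' correlation
    spread: genuinely aneuploid cells share a coherent deviation
    pattern, whereas in cohorts without CNVs the top-scoring cells are
    uncorrelated noise and nobody is called.  Reference cells are always
    forced non-malignant.

    Returns a copy of ``meta`` with ``is_malignant`` (bool) and
    ``cnv_score`` columns; malignant cells get ``cell_type='malignant'``.
    """
    meta = meta.copy()
    scores = cnv.aberration_score()
    ref = cnv.reference

    meta["cnv_score"] = scores
    meta["is_malignant"] = False
    if "cell_type" not in meta.columns:
        meta["cell_type"] = "unassigned"

    if np.allclose(scores, scores[0]):
        logger.warning("degenerate CNV scores: all cells non-malignant")
        return meta

    profile = cnv.gene_values if cnv.gene_values is not None else cnv.values
    top = scores >= np.quantile(scores, 0.9)
    centroid = profile[top].mean(axis=0)

    corr = np.zeros(len(scores))
    group = top
    for _ in range(max(n_refinements, 0) + 1):
        corr = _centroid_correlation(profile, centroid)
        group = _two_means_1d(corr)
        centroid = profile[group].mean(axis=0)

    ref_spread = corr[ref].std()
    if corr[group].mean() <= min_coherence_z * ref_spread:
        logger.warning(
            "high-aberration cluster shows no coherent CNV pattern; "
            "no malignant calls made"
        )
        return meta

    malignant = group & ~ref
    meta.loc[malignant, "is_malignant"] = True
    meta.loc[malignant, "cell_type"] = "malignant"
    return meta


# ---------------------------------------------------------------------------
# cell typing
# ---------------------------------------------------------------------------

def assign_cell_types(
    norm: AnnData,
    meta: pd.DataFrame,
    markers: dict,
    cd3_genes=CD3_GENES,
    purity_threshold: float = 0.80,
    n_pcs: int = 20,
    n_neighbors: int = 20,
    resolution: float = 1.0,
    random_state: int = 0,
) -> pd.DataFrame:
    """Cluster non-malignant cells and label clusters by marker score.

    Clustering is Leiden community detection on a k-nearest-neighbor
    graph over the top principal components.  Each cluster is labeled by
    the arg-max mean marker-signature score; within T-labeled clusters
    the fraction of cells with summed CD3D+CD3E+CD3G expression > 0 is
    computed and clusters strictly below ``purity_threshold`` are
    reassigned to ``unassigned``.  Marker genes absent from the matrix
    count as zero expression.
    """
    meta = meta.copy()
    if "cell_type" not in meta.columns:
        meta["cell_type"] = "unassigned"
    nonmal = ~meta.get("is_malignant", pd.Series(False, index=meta.index))
    nonmal = nonmal.astype(bool).to_numpy()
    if nonmal.sum() == 0:
        raise ValueError("no non-malignant cells to type")

    sub = norm[nonmal].copy()
    sc.pp.pca(sub, n_comps=min(n_pcs, sub.n_obs - 1, sub.n_vars - 1))
    sc.pp.neighbors(
        sub, n_neighbors=min(n_neighbors, sub.n_obs - 1), random_state=random_state
    )
    sc.tl.leiden(
        sub,
        resolution=resolution,
        random_state=random_state,
        flavor="igraph",
        n_iterations=2,
        directed=False,
    )
    clusters = sub.obs["leiden"]

    X = np.asarray(sub.X)
    var_index = sub.var_names

    def signature_score(genes):
        present = [g for g in genes if g in var_index]
        if not present:
            return np.zeros(sub.n_obs)
        cols = var_index.get_indexer(present)
        score = X[:, cols].sum(axis=1)
        return score / len(genes)  # absent genes count as zeros

    type_scores = {}
    for ct, genes in markers.items():
        if not genes:
            logger.warning("empty marker set for %r; type never assigned", ct)
            continue
        type_scores[ct] = signature_score(genes)
    if not type_scores:
        raise ValueError("no usable marker sets")
    score_df = pd.DataFrame(type_scores, index=sub.obs_names)

    cd3_cols = [g for g in cd3_genes if g in var_index]
    cd3_sum = (
        X[:, var_index.get_indexer(cd3_cols)].sum(axis=1)
        if cd3_cols
        else np.zeros(sub.n_obs)
    )

    labels = pd.Series("unassigned", index=sub.obs_names, dtype=object)
    for cl in clusters.cat.categories:
        mask = (clusters == cl).to_numpy()
        best = score_df.loc[mask].mean(axis=0).idxmax()
        if best == "T":
            positive = float(np.mean(cd3_sum[mask] > 0))
            if positive < purity_threshold:
                logger.info(
                    "T cluster %s removed (CD3+ fraction %.2f < %.2f)",
                    cl, positive, purity_threshold,
                )
                best = "unassigned"
        labels[mask] = best

    meta.loc[labels.index, "cell_type"] = labels
    return meta


# ---------------------------------------------------------------------------
# sample selection
# ---------------------------------------------------------------------------

def select_samples(
    meta: pd.DataFrame,
    min_malignant: int = 10,
    patient_col: str = "patient",
    region_col: str = "region",
) -> list:
    """(patient, region) samples with strictly more than ``min_malignant``
    malignant cells."""
    if "is_malignant" not in meta.columns:
        raise ValueError("malignancy calls missing from metadata")
    counts = (
        meta[meta["is_malignant"].astype(bool)]
        .groupby([patient_col, region_col], observed=True)
        .size()
    )
    return sorted(counts[counts > min_malignant].index.tolist())
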