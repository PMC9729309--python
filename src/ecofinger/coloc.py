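"""Tile-based spatial colocalization of a two-gene fingerprint.

A spot table (cell_id, x_px, y_px, gene, copies) is partitioned into
square tiles (default 500 px) anchored at the field's minimum corner
with half-open intervals.  Per gene, the copy-weighted probability of
each tile yields a distribution p over tiles, and the overlap of two
genes is the Bhattacharyya coefficient

    BC(p1, p2) = sum_i sqrt(p1_i * p2_i),

which is 1 for identical distributions and 0 for disjoint ones.  The
spatial concentration of a pair is measured as the proportion of filled
tiles relative to a per-cell gene-label shuffle null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "TileDistribution",
    "tile_probabilities",
    "bhattacharyya",
    "filled_tile_proportion",
    "include_sample",
    "expression_groups",
]


@dataclass(frozen=True)
class TileDistribution:
    """Per-gene probability vector over a shared tile grid."""

    probabilities: np.ndarray
    grid_shape: tuple          # (n_tiles_x, n_tiles_y)
    tile_size_px: float
    origin: tuple              # (x_min, y_min)
    gene: str = ""

    @property
    def n_tiles(self) -> int:
        return int(np.prod(self.grid_shape))

    def same_grid(self, other: "TileDistribution") -> bool:
        return (
            self.grid_shape == other.grid_shape
            and self.tile_size_px == other.tile_size_px
            and np.allclose(self.origin, other.origin)
        )


def _tile_index(spots: pd.DataFrame, origin, tile_size, grid_shape):
    ix = np.floor((spots["x_px"].to_numpy() - origin[0]) / tile_size)
    iy = np.floor((spots["y_px"].to_numpy() - origin[1]) / tile_size)
    ix = ix.astype(int)
    iy = iy.astype(int)
    return ix * grid_shape[1] + iy


def tile_probabilities(
    sample: pd.DataFrame,
    tile_size_px: float = 500.0,
    copy_weighted: bool = True,
    bounds=None,
) -> dict:
    """Per-gene tile probability vectors for a spot table.

    Tiles are half-open squares ``[x0, x0+tile) x [y0, y0+tile)``
    anchored at the field's minimum coordinate (or at ``bounds =
    (x_min, y_min, x_max, y_max)`` when given); partial edge tiles are
    kept.  Probabilities weight spots by copy number unless
    ``copy_weighted=False``.  Genes with zero total copies are flagged
    with a warning and omitted.
    """
    if len(sample) == 0:
        raise ValueError("empty spot table")
    if bounds is None:
        x0, y0 = sample["x_px"].min(), sample["y_px"].min()
        x1, y1 = sample["x_px"].max(), sample["y_px"].max()
    else:
        x0, y0, x1, y1 = bounds
    nx = max(int(np.floor((x1 - x0) / tile_size_px)) + 1, 1)
    ny = max(int(np.floor((y1 - y0) / tile_size_px)) + 1, 1)
    grid_shape = (nx, ny)
    out = {}
    for gene, grp in sample.groupby("gene"):
        w = grp["copies"].to_numpy(dtype=float) if copy_weighted else np.ones(
            len(grp)
        )
        total = w.sum()
        if total <= 0:
            logger.warning("gene %s has zero copies; distribution undefined",
                           gene)
            continue
        idx = _tile_index(grp, (x0, y0), tile_size_px, grid_shape)
        p = np.bincount(idx, weights=w, minlength=nx * ny) / total
        out[gene] = TileDistribution(
            probabilities=p,
            grid_shape=grid_shape,
            tile_size_px=float(tile_size_px),
            origin=(float(x0), float(y0)),
            gene=str(gene),
        )
    return out


def bhattacharyya(p1: TileDistribution, p2: TileDistribution) -> float:
    """Bhattacharyya coefficient of two tile distributions (same grid)."""
    if not p1.same_grid(p2):
        raise ValueError("tile grids do not match")
    return float(np.sum(np.sqrt(p1.probabilities * p2.probabilities)))


def filled_tile_proportion(
    sample: pd.DataFrame,
    pair_genes,
    tile_size_px: float = 500.0,
    n_shuffles: int = 10,
    seed: int = 0,
    fill_rule: str = "either",
) -> dict:
    """Observed filled tiles relative to a gene-label shuffle null.

    A tile is *filled* when it contains at least one copy of either pair
    gene (``fill_rule='either'``, default) or of both (``'both'``).  The
    null permutes the per-cell gene payloads across cells while keeping
    every coordinate fixed; each shuffle's filled-tile count is the
    denominator for one observed/null ratio.  Returns the observed
    count, the mean ratio, all ratios, and a two-sided one-sample t test
    of the null counts against the observed count.
    """
    if n_shuffles < 2:
        raise ValueError("need >= 2 shuffles for a variance estimate")
    if fill_rule not in ("either", "both"):
        raise ValueError(f"unknown fill_rule {fill_rule!r}")
    pair_genes = list(pair_genes)
    sub = sample[sample["gene"].isin(pair_genes)].reset_index(drop=True)
    if len(sub) == 0:
        raise ValueError("no spots for the pair genes")

    x0, y0 = sample["x_px"].min(), sample["y_px"].min()
    x1, y1 = sample["x_px"].max(), sample["y_px"].max()
    nx = max(int(np.floor((x1 - x0) / tile_size_px)) + 1, 1)
    ny = max(int(np.floor((y1 - y0) / tile_size_px)) + 1, 1)
    grid_shape = (nx, ny)

    # one position per cell; the shuffle permutes payloads across cells
    cells = sample.groupby("cell_id", sort=True)
    pos = cells[["x_px", "y_px"]].first()
    tile_of_cell = _tile_index(pos, (x0, y0), tile_size_px, grid_shape)
    payload_genes = cells["gene"].apply(list)

    def filled_count(cell_tiles):
        tiles_by_gene = []
        for g in pair_genes:
            has = np.array(
                [g in genes for genes in payload_genes], dtype=bool
            )
            tiles_by_gene.append(set(cell_tiles[has]))
        if fill_rule == "either":
            return len(set().union(*tiles_by_gene))
        return len(set.intersection(*tiles_by_gene))

    observed = filled_count(tile_of_cell)
    rng = np.random.default_rng(seed)
    null_counts = []
    for _ in range(n_shuffles):
        perm = rng.permutation(len(pos))
        # cell i's position now carries cell perm[i]'s payload; equivalently
        # permute positions against fixed payloads
        null_counts.append(filled_count(tile_of_cell[perm]))
    null_counts = np.array(null_counts, dtype=float)
    ratios = observed / np.where(null_counts > 0, null_counts, np.nan)
    t, p = stats.ttest_1samp(null_counts, popmean=observed)
    return {
        "observed_filled": int(observed),
        "null_filled": null_counts,
        "ratios": ratios,
        "mean_ratio": float(np.nanmean(ratios)),
        "t": float(t),
        "p_value": float(p),
    }


def include_sample(
    sample: pd.DataFrame,
    pair_genes,
    min_positive_fraction: float = 0.01,
) -> bool:
    """True iff strictly more than ``min_positive_fraction`` of cells are
    positive (>= 1 copy) for each pair gene."""
    cell_ids = sample["cell_id"].unique()
    if len(cell_ids) == 0:
        logger.warning("sample has no cells; excluded")
        return False
    for gene in pair_genes:
        pos = sample.loc[
            (sample["gene"] == gene) & (sample["copies"] >= 1), "cell_id"
        ].nunique()
        if pos / len(cell_ids) <= min_positive_fraction:
            return False
    return True


def expression_groups(
    expression: pd.DataFrame,
    fingerprint_genes,
    lower_q: float = 1 / 3,
    upper_q: float = 2 / 3,
) -> pd.Series:
    """High/low/others grouping on four fingerprint genes.

    ``expression`` is samples x genes (per-sample summary expression,
    e.g. mean copies per cell).  A sample is ``high`` when all four
    genes exceed their cohort upper quantile (default upper tertile),
    ``low`` when all four fall below their lower quantile, otherwise
    ``others``.  Degenerate cohorts (a gene constant across samples)
    yield all ``others``.
    """
    genes = list(fingerprint_genes)
    missing = [g for g in genes if g not in expression.columns]
    if missing:
        raise ValueError(f"fingerprint genes missing: {missing}")
    sub = expression[genes]
    lo = sub.quantile(lower_q)
    hi = sub.quantile(upper_q)
    high = (sub.gt(hi)).all(axis=1)
    low = (sub.lt(lo)).all(axis=1)
    out = pd.Series("others", index=expression.index, name="group")
    out[high] = "high"
    out[low] = "low"
    return out
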