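"""Synthetic data with the statistical structure the pipeline assumes.

Four generators cover the input shapes of the analysis:

* :func:`generate_cohort` — a multi-patient, multi-region single-cell
  count matrix (negative-binomial counts, log-normal gene means and
  library sizes) with patient-specific malignant programs, contiguous
  chromosomal gains, shared non-malignant cell-type programs and planted
  ligand-receptor pairs.  Ground truth travels in ``obs``.
* :func:`generate_bulk_cohort` — a bulk expression matrix whose samples
  fall into survival clusters; cluster-1 samples over-express a planted
  interaction-pair set and die with a higher exponential hazard.
* :func:`generate_spatial_sample` — 2-D transcript-spot tables for two
  genes whose spatial densities share a tunable mixture weight
  (``overlap``), for tile-based colocalization.
* :func:`generate_lr_database` — a ligand-receptor pair table, optionally
  anchored on the LGALS9-SLC1A5 / SPP1-PTGER4 fingerprint.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy.optimize import brentq

from .config import (
    CD3_GENES,
    ConfigurationError,
    FINGERPRINT_PAIRS,
    NONMALIGNANT_TYPES,
    NORMAL_REGION,
    SimulationConfig,
)

__all__ = [
    "generate_cohort",
    "generate_bulk_cohort",
    "generate_spatial_sample",
    "generate_lr_database",
]


# ---------------------------------------------------------------------------
# single-cell cohort
# ---------------------------------------------------------------------------

def _gene_order(cfg: SimulationConfig) -> pd.DataFrame:
    """Genes laid out contiguously on equal-size chromosomes."""
    chroms = cfg.chromosome_names()
    per = int(np.ceil(cfg.n_genes / cfg.n_chromosomes))
    chrom = np.repeat(chroms, per)[: cfg.n_genes]
    pos = np.concatenate(
        [np.arange(1, np.sum(chrom == c) + 1) * 1000 for c in chroms]
    )
    ids = [f"G{i:04d}" for i in range(cfg.n_genes)]
    return pd.DataFrame(
        {"chromosome": chrom, "position": pos.astype(np.int64)}, index=ids
    )


def _nb_sample(rng, mean, dispersion):
    """NB draw with variance mean + dispersion * mean**2."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p).astype(np.int32)


def generate_cohort(cfg: SimulationConfig | None = None) -> AnnData:
    """Simulate a multiregional single-cell cohort.

    Returns an :class:`~anndata.AnnData` with raw integer counts in ``X``,
    cell metadata (``patient``, ``region``, ``true_type``,
    ``true_malignant``) in ``obs``, genomic gene order (``chromosome``,
    ``position``) in ``var``, and ground-truth bookkeeping (marker sets,
    program genes, gain genes, planted pairs) in ``uns``.

    Malignant cells exist only in tumor regions (never in N), carry a
    patient-specific multiplicative expression program and the configured
    copy-number gains; non-malignant cells share cell-type marker
    programs across patients.
    """
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)

    var = _gene_order(cfg)
    gene_ids = list(var.index)
    n_genes = cfg.n_genes

    # baseline per-gene means (log-normal, sparse scRNA-seq-like)
    base_mean = rng.lognormal(
        mean=np.log(cfg.base_mean_log_median),
        sigma=cfg.base_mean_log_sigma,
        size=n_genes,
    )

    # reserve genes for planted-pair genes and markers so the roles never
    # collide; gain-region genes are excluded from special roles
    gain_mask = np.zeros(n_genes, dtype=bool)
    chrom_arr = var["chromosome"].to_numpy()
    for gain in cfg.gain_regions:
        on = np.flatnonzero(chrom_arr == gain.chromosome)
        if on.size == 0:
            raise ConfigurationError(
                f"gain names unknown chromosome {gain.chromosome!r}"
            )
        lo = on[0] + int(np.floor(gain.start * on.size))
        hi = on[0] + int(np.ceil(gain.end * on.size))
        gain_mask[lo:hi] = True

    free = list(np.flatnonzero(~gain_mask))
    rng.shuffle(free)
    n_special = len(
        {g for p in cfg.planted_pairs for g in (p.ligand, p.receptor)}
    ) + cfg.n_markers_per_type * len(NONMALIGNANT_TYPES)
    if n_special > len(free):
        raise ConfigurationError(
            f"{n_special} marker/pair genes requested but only {len(free)} "
            f"genes lie outside the gain regions; increase n_genes or "
            f"reduce n_markers_per_type"
        )
    free_iter = iter(free)

    def take(k):
        return [next(free_iter) for _ in range(k)]

    # planted-pair genes get dedicated, renamed genes with a solid baseline
    pair_gene_idx: dict[str, int] = {}
    for pair in cfg.planted_pairs:
        for g in (pair.ligand, pair.receptor):
            if g not in pair_gene_idx:
                idx = take(1)[0]
                pair_gene_idx[g] = idx
                gene_ids[idx] = g
                base_mean[idx] = cfg.pair_base_mean

    # cell-type marker programs (shared across patients); T markers start
    # with the CD3 complex so the purity filter is exercised
    markers: dict[str, list] = {}
    for ct in NONMALIGNANT_TYPES:
        idx = take(cfg.n_markers_per_type)
        if ct == "T":
            for j, name in enumerate(CD3_GENES):
                gene_ids[idx[j]] = name
                base_mean[idx[j]] = max(base_mean[idx[j]], 0.5)
        markers[ct] = idx

    # patient-specific malignant programs
    patients = cfg.patient_ids()
    program: dict[str, np.ndarray] = {}
    program_genes: dict[str, list] = {}
    for p in patients:
        idx = rng.choice(np.flatnonzero(~gain_mask), cfg.n_program_genes, replace=False)
        fac = np.ones(n_genes)
        fac[idx] = np.exp(rng.normal(0.0, cfg.program_sigma, idx.size)) * 2.0
        program[p] = fac
        program_genes[p] = idx.tolist()

    gain_factor = np.ones(n_genes)
    for gain in cfg.gain_regions:
        on = np.flatnonzero(chrom_arr == gain.chromosome)
        lo = on[0] + int(np.floor(gain.start * on.size))
        hi = on[0] + int(np.ceil(gain.end * on.size))
        gain_factor[lo:hi] *= gain.fold_change

    marker_factor: dict[str, np.ndarray] = {}
    for ct in NONMALIGNANT_TYPES:
        fac = np.ones(n_genes)
        fac[markers[ct]] = cfg.marker_strength
        marker_factor[ct] = fac

    # optional tumor-border program shift per cell type
    border_shift: dict[str, np.ndarray] = {}
    if cfg.border_shift_sigma > 0:
        for ct in NONMALIGNANT_TYPES:
            border_shift[ct] = np.exp(
                rng.normal(0.0, cfg.border_shift_sigma, n_genes)
            )

    # planted-pair expression effects per (patient, cell role)
    def pair_effect(patient, is_malignant, cell_type):
        fac = np.ones(n_genes)
        for pair in cfg.planted_pairs:
            if pair.direction == "tumor_to_tme":
                tumor_gene, partner_gene = pair.ligand, pair.receptor
            else:
                tumor_gene, partner_gene = pair.receptor, pair.ligand
            partner_gate = (
                pair.partner_patients
                if pair.partner_patients is not None
                else pair.patients
            )
            if is_malignant:
                if pair.patients is None or patient in pair.patients:
                    fac[pair_gene_idx[tumor_gene]] *= pair.effect
            elif cell_type == pair.partner_celltype:
                if partner_gate is None or patient in partner_gate:
                    fac[pair_gene_idx[partner_gene]] *= pair.effect
        return fac

    # assemble cells
    rows_mean = []
    obs_rows = []
    for p in patients:
        for region in cfg.regions_per_patient:
            if region != NORMAL_REGION and cfg.n_malignant_per_region > 0:
                mean = (
                    base_mean
                    * program[p]
                    * gain_factor
                    * pair_effect(p, True, None)
                )
                rows_mean.append(
                    np.repeat(
                        mean[None, :], cfg.n_malignant_per_region, axis=0
                    )
                )
                obs_rows += [
                    (p, region, "malignant", True)
                ] * cfg.n_malignant_per_region
            for ct in NONMALIGNANT_TYPES:
                mean = base_mean * marker_factor[ct] * pair_effect(p, False, ct)
                if region == "B" and ct in border_shift:
                    mean = mean * border_shift[ct]
                rows_mean.append(
                    np.repeat(mean[None, :], cfg.n_per_celltype, axis=0)
                )
                obs_rows += [(p, region, ct, False)] * cfg.n_per_celltype

    mean_matrix = np.vstack(rows_mean)
    n_cells = mean_matrix.shape[0]
    libsize = rng.lognormal(0.0, cfg.library_size_sigma, n_cells)
    mean_matrix *= libsize[:, None]
    counts = _nb_sample(rng, mean_matrix, cfg.baseline_dispersion)

    obs = pd.DataFrame(
        obs_rows, columns=["patient", "region", "true_type", "true_malignant"]
    )
    obs.index = [f"cell_{i:05d}" for i in range(n_cells)]
    var.index = gene_ids

    adata = AnnData(X=counts, obs=obs, var=var)
    adata.uns["celltype_markers"] = {
        ct: [gene_ids[i] for i in idx] for ct, idx in markers.items()
    }
    adata.uns["patient_program_genes"] = {
        p: [gene_ids[i] for i in idx] for p, idx in program_genes.items()
    }
    adata.uns["gain_genes"] = [gene_ids[i] for i in np.flatnonzero(gain_mask)]
    adata.uns["planted_pairs"] = [
        {
            "ligand": pr.ligand,
            "receptor": pr.receptor,
            "partner_celltype": pr.partner_celltype,
            "direction": (
                "tumor->TME" if pr.direction == "tumor_to_tme" else "TME->tumor"
            ),
            "patients": list(pr.patients) if pr.patients else patients,
            "effect": pr.effect,
        }
        for pr in cfg.planted_pairs
    ]
    return adata


# ---------------------------------------------------------------------------
# bulk cohort with survival
# ---------------------------------------------------------------------------

def _uniform_censor_bound(hazard: float, rate: float) -> float:
    """Upper bound u of Uniform(0, u) censoring achieving P(C < T) = rate
    for T ~ Exp(hazard)."""
    if rate <= 0:
        return np.inf

    def f(u):
        return (1.0 - np.exp(-hazard * u)) / (hazard * u) - rate

    # f(u) -> 1 - rate as u -> 0+, -> -rate as u -> inf
    lo, hi = 1e-9, 1.0
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e9:  # pragma: no cover - numerically unreachable
            return hi
    return brentq(f, lo, hi)


def generate_bulk_cohort(
    cfg: SimulationConfig | None = None,
    pair_list: list | None = None,
    cluster_pairs: dict | None = None,
    n_extra_genes: int = 200,
):
    """Simulate a bulk cohort whose survival depends on a planted
    interaction cluster.

    By default every pair in ``pair_list`` is elevated (ligand and
    receptor, by ``cfg.bulk_effect`` on the linear scale) in cluster-1
    samples.  ``cluster_pairs`` — a mapping from cluster label to a pair
    list — instead plants a polarized network in which each cluster
    over-expresses its own pair program, the structure published
    interaction maps show.  Survival is exponential with the cluster's
    hazard; censoring is uniform at the configured rate.

    Returns ``(expr, survival, labels)`` where ``expr`` is a genes x
    samples DataFrame (log2 intensities), ``survival`` has columns
    ``sample_id, time_months, event`` and ``labels`` maps samples to the
    true cluster.
    """
    cfg = cfg or SimulationConfig()
    if len(cfg.survival_hazards) < 2:
        raise ConfigurationError("need >= 2 clusters in survival_hazards")
    rng = np.random.default_rng(cfg.seed + 1)

    clusters = sorted(cfg.survival_hazards)
    if cluster_pairs is None:
        if pair_list is None:
            pair_list = [(p.ligand, p.receptor) for p in cfg.planted_pairs]
        cluster_pairs = {clusters[0]: list(pair_list)}
    unknown = set(cluster_pairs) - set(clusters)
    if unknown:
        raise ConfigurationError(f"cluster_pairs names unknown clusters {unknown}")
    all_pairs = [pr for prs in cluster_pairs.values() for pr in prs]
    pair_genes = sorted({g for pr in all_pairs for g in pr})
    genes = pair_genes + [f"BG{i:04d}" for i in range(n_extra_genes)]
    n_genes = len(genes)

    n = cfg.n_bulk_samples
    labels = np.array([clusters[i % len(clusters)] for i in range(n)])
    sample_ids = [f"S{i:03d}" for i in range(n)]

    base = rng.normal(7.0, 1.0, n_genes)  # per-gene log2 baseline
    expr = rng.normal(0.0, 1.0, (n_genes, n)) + base[:, None]
    lift = np.log2(cfg.bulk_effect)
    for cluster, prs in cluster_pairs.items():
        members = labels == cluster
        for lig, rec in prs:
            for g in (lig, rec):
                expr[genes.index(g), members] += lift

    hazards = np.array([cfg.survival_hazards[c] for c in labels])
    t_event = rng.exponential(1.0 / hazards)
    event = np.ones(n, dtype=int)
    time = t_event.copy()
    if cfg.censoring_rate > 0:
        for c in clusters:
            m = labels == c
            u = _uniform_censor_bound(cfg.survival_hazards[c], cfg.censoring_rate)
            cens = rng.uniform(0.0, u, m.sum())
            tt = time[m]
            ee = event[m]
            censored = cens < tt
            tt[censored] = cens[censored]
            ee[censored] = 0
            time[m] = tt
            event[m] = ee
    time = np.maximum(time, 1e-6)

    expr_df = pd.DataFrame(expr, index=genes, columns=sample_ids)
    survival = pd.DataFrame(
        {"sample_id": sample_ids, "time_months": time, "event": event}
    )
    label_s = pd.Series(labels, index=sample_ids, name="true_cluster")
    return expr_df, survival, label_s


# ---------------------------------------------------------------------------
# spatial spot tables
# ---------------------------------------------------------------------------

def generate_spatial_sample(
    n_cells: int = 2000,
    field_size_px: float = 4000.0,
    overlap: float = 0.5,
    seed: int = 0,
    genes: tuple = ("LGALS9", "SLC1A5"),
    n_blobs: int = 3,
    blob_sigma_frac: float = 0.08,
    mean_extra_copies: float = 1.0,
) -> pd.DataFrame:
    """Simulate transcript spots for two genes with tunable spatial overlap.

    Each gene's spot density is a mixture ``overlap * shared +
    (1 - overlap) * own`` where the shared component is a set of Gaussian
    blobs over the whole field and the gene-own components are blobs
    confined to the left (gene 1) and right (gene 2) half-fields.  At
    ``overlap=1`` both genes share one density; at ``overlap=0`` their
    supports are disjoint halves of the field.

    Returns a spot table with columns ``cell_id, x_px, y_px, gene, copies``.
    """
    if not (0.0 <= overlap <= 1.0):
        raise ValueError(f"overlap must be in [0, 1], got {overlap}")
    if len(genes) != 2:
        raise ValueError("exactly two genes expected")
    rng = np.random.default_rng(seed)
    W = float(field_size_px)
    sigma = blob_sigma_frac * W

    shared = rng.uniform(0.15 * W, 0.85 * W, (n_blobs, 2))
    own = {
        genes[0]: np.column_stack(
            [rng.uniform(0.05 * W, 0.40 * W, n_blobs),
             rng.uniform(0.05 * W, 0.95 * W, n_blobs)]
        ),
        genes[1]: np.column_stack(
            [rng.uniform(0.60 * W, 0.95 * W, n_blobs),
             rng.uniform(0.05 * W, 0.95 * W, n_blobs)]
        ),
    }
    half = {genes[0]: (0.0, W / 2.0), genes[1]: (W / 2.0, W)}

    rows = []
    per_gene = n_cells // 2
    cell = 0
    for gene in genes:
        use_shared = rng.random(per_gene) < overlap
        blob = rng.integers(0, n_blobs, per_gene)
        centers = np.where(
            use_shared[:, None], shared[blob], own[gene][blob]
        )
        pts = centers + rng.normal(0.0, sigma, (per_gene, 2))
        pts = np.clip(pts, 0.0, np.nextafter(W, 0.0))
        # gene-own points stay strictly within their half-field so that
        # overlap=0 yields disjoint supports
        lo, hi = half[gene]
        x = pts[:, 0]
        x[~use_shared] = np.clip(
            x[~use_shared], lo, np.nextafter(hi, lo)
        )
        copies = 1 + rng.poisson(mean_extra_copies, per_gene)
        for i in range(per_gene):
            rows.append((f"c{cell:05d}", x[i], pts[i, 1], gene, copies[i]))
            cell += 1
    return pd.DataFrame(
        rows, columns=["cell_id", "x_px", "y_px", "gene", "copies"]
    )


# ---------------------------------------------------------------------------
# ligand-receptor database
# ---------------------------------------------------------------------------

def generate_lr_database(
    n_pairs: int,
    gene_pool: list,
    include_fingerprint: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Build a ligand-receptor pair table from a gene pool.

    With ``include_fingerprint=True`` the first two pairs are the
    LGALS9-SLC1A5 and SPP1-PTGER4 tumor-TAM fingerprint pairs.  Pair ids
    are unique and ligand != receptor within every pair.
    """
    rng = np.random.default_rng(seed)
    pool = [g for g in gene_pool]
    pairs = []
    if include_fingerprint:
        for lig, rec in FINGERPRINT_PAIRS[:n_pairs]:
            pairs.append((lig, rec))
        pool = [g for g in pool if g not in set(sum(FINGERPRINT_PAIRS, ()))]
    need = n_pairs - len(pairs)
    if need > 0:
        if len(pool) < 2 * need:
            raise ValueError(
                f"gene pool of {len(pool)} too small for {need} more pairs"
            )
        chosen = rng.choice(len(pool), 2 * need, replace=False)
        for k in range(need):
            pairs.append((pool[chosen[2 * k]], pool[chosen[2 * k + 1]]))
    seen = set()
    for lig, rec in pairs:
        if (lig, rec) in seen:
            raise ValueError(f"duplicate pair {lig}-{rec}")
        seen.add((lig, rec))
    return pd.DataFrame(
        {
            "pair_id": [f"{lig}_{rec}" for lig, rec in pairs],
            "ligand": [p[0] for p in pairs],
            "receptor": [p[1] for p in pairs],
        }
    )
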