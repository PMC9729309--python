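"""Permutation-based ligand-receptor enrichment between tumor and TME.

For a candidate pair, the observed statistic is the arithmetic mean of
the ligand's mean expression in the source cell type and the receptor's
mean expression in the target type; the null distribution comes from
random shuffles of the cell-type labels, and

    p = (1 + #{null >= observed}) / (1 + n_permutations)

(ties count as >=, the add-one rule keeps the minimum attainable p at
1/(n_permutations+1)).  A pair is evaluated only when both genes are
expressed in at least ``min_expr_frac`` of their type's cells.  Both
directions are tested: tumor->TME (ligand measured in malignant cells,
receptor in the partner type) and TME->tumor (the reverse).

The module also implements the downstream experiments built on this
test: stringent filtering, per-case regional stability, Jaccard overlap
of interaction sets, the tumor/TME switching experiment, and the
malignant-cell subsampling robustness check.
"""

from __future__ import annotations

import itertools
import logging
from math import factorial

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "lr_permutation_test",
    "lr_tests_by",
    "filter_pairs",
    "significant_keys",
    "regional_stability",
    "interaction_overlap",
    "switching_experiment",
    "subsample_accuracy",
]

TUMOR_TO_TME = "tumor->TME"
TME_TO_TUMOR = "TME->tumor"

RECORD_COLUMNS = [
    "sample_id",
    "pair_id",
    "ligand",
    "receptor",
    "direction",
    "partner_celltype",
    "p_value",
    "pair_mean",
]


def _empty_records() -> pd.DataFrame:
    return pd.DataFrame(columns=RECORD_COLUMNS)


def _multiset_label_permutations(codes: np.ndarray, cap: int):
    """All distinct arrangements of a label vector (exact null)."""
    n = len(codes)
    counts = np.bincount(codes)
    total = factorial(n)
    for c in counts:
        total //= factorial(int(c))
    if total > cap:
        raise ValueError(
            f"{total} distinct labelings exceed the exact-mode cap of {cap}"
        )
    # enumerate by choosing positions for each label in turn
    def rec(positions, remaining_counts, assign):
        if not positions:
            yield assign.copy()
            return
        label = next(
            i for i, c in enumerate(remaining_counts) if c > 0
        )
        for combo in itertools.combinations(positions, remaining_counts[label]):
            for pos in combo:
                assign[pos] = label
            rest = [p for p in positions if p not in set(combo)]
            rc = list(remaining_counts)
            rc[label] = 0
            yield from rec(rest, rc, assign)

    assign = np.empty(n, dtype=int)
    yield from rec(list(range(n)), list(counts), assign)


def lr_permutation_test(
    adata: AnnData,
    db: pd.DataFrame,
    sample_id: str = "sample",
    source_type: str = "malignant",
    partner_types=None,
    celltype_col: str = "cell_type",
    n_permutations: int = 1000,
    seed: int = 0,
    min_cells: int = 10,
    min_expr_frac: float = 0.10,
    method: str = "sampled",
    exact_cap: int = 200_000,
) -> pd.DataFrame:
    """Test every database pair between ``source_type`` and each partner.

    ``adata`` holds one sample's normalized log expression with cell
    types in ``obs[celltype_col]``.  ``db`` needs columns ``pair_id,
    ligand, receptor``.  With ``method='exact'`` the null enumerates all
    distinct cell-type label assignments (p = #{null >= obs} / N, the
    observed labeling included); the default samples ``n_permutations``
    label shuffles and applies the add-one estimator.

    Returns one record per (pair, direction, partner) that passes the
    expression gate, with columns :data:`RECORD_COLUMNS`.
    """
    if len(db) == 0:
        return _empty_records()
    if n_permutations < 100 and method == "sampled":
        logger.warning(
            "n_permutations=%d is very low; p-values will be coarse",
            n_permutations,
        )
    labels = adata.obs[celltype_col].astype(str)
    type_counts = labels.value_counts()
    if type_counts.get(source_type, 0) < min_cells:
        logger.info(
            "sample %s: fewer than %d %s cells; no records",
            sample_id, min_cells, source_type,
        )
        return _empty_records()
    if partner_types is None:
        partner_types = sorted(
            t for t in type_counts.index
            if t != source_type and type_counts[t] >= min_cells
            and t != "unassigned"
        )
    else:
        partner_types = [
            t for t in partner_types if type_counts.get(t, 0) >= min_cells
        ]
    if not partner_types:
        return _empty_records()

    # genes touched by the database
    db_genes = sorted(
        set(db["ligand"]).union(db["receptor"]) & set(adata.var_names)
    )
    skipped = set(db["ligand"]).union(db["receptor"]) - set(adata.var_names)
    if skipped:
        logger.warning(
            "%d database genes absent from the matrix; their pairs are "
            "skipped", len(skipped)
        )
    if not db_genes:
        return _empty_records()
    gindex = {g: i for i, g in enumerate(db_genes)}
    Xg = np.asarray(adata[:, db_genes].X, dtype=np.float64)
    n = Xg.shape[0]

    used_types = [source_type] + partner_types
    tindex = {t: i for i, t in enumerate(used_types)}
    codes = np.full(n, -1, dtype=int)
    for t, i in tindex.items():
        codes[(labels == t).to_numpy()] = i
    keep = codes >= 0
    Xg, codes = Xg[keep], codes[keep]
    n = len(codes)
    n_types = len(used_types)
    counts = np.bincount(codes, minlength=n_types).astype(float)

    order = np.argsort(codes, kind="stable")
    Xs = Xg[order]
    starts = np.searchsorted(codes[order], np.arange(n_types))

    obs_means = np.add.reduceat(Xs, starts, axis=0) / counts[:, None]
    expr_frac = (
        np.add.reduceat((Xs > 0).astype(float), starts, axis=0)
        / counts[:, None]
    )

    if method == "exact":
        null_means = []
        for labs in _multiset_label_permutations(codes, exact_cap):
            M = np.zeros((n_types, len(db_genes)))
            for t in range(n_types):
                M[t] = Xg[labs == t].mean(axis=0)
            null_means.append(M)
        null_means = np.stack(null_means)  # (N, n_types, g)
        denom = null_means.shape[0]
        add_one = 0
        # recompute the observed means along the same floating-point path
        # as the null so that the identity labeling ties exactly
        for t in range(n_types):
            obs_means[t] = Xg[codes == t].mean(axis=0)
    elif method == "sampled":
        rng = np.random.default_rng(seed)
        null_means = np.empty((n_permutations, n_types, len(db_genes)))
        for b in range(n_permutations):
            perm = rng.permutation(n)
            null_means[b] = (
                np.add.reduceat(Xg[perm], starts, axis=0) / counts[:, None]
            )
        denom = n_permutations
        add_one = 1
    else:
        raise ValueError(f"unknown method {method!r}")

    rows = []
    for _, pair in db.iterrows():
        lig, rec = pair["ligand"], pair["receptor"]
        if lig not in gindex or rec not in gindex:
            continue
        li, ri = gindex[lig], gindex[rec]
        for partner in partner_types:
            pi = tindex[partner]
            for direction in (TUMOR_TO_TME, TME_TO_TUMOR):
                if direction == TUMOR_TO_TME:
                    lt, rt = 0, pi  # ligand in malignant, receptor in partner
                else:
                    lt, rt = pi, 0
                if (
                    expr_frac[lt, li] < min_expr_frac
                    or expr_frac[rt, ri] < min_expr_frac
                ):
                    continue
                obs = 0.5 * (obs_means[lt, li] + obs_means[rt, ri])
                null = 0.5 * (null_means[:, lt, li] + null_means[:, rt, ri])
                p = (add_one + np.sum(null >= obs)) / (add_one + denom)
                rows.append(
                    (
                        sample_id,
                        pair["pair_id"],
                        lig,
                        rec,
                        direction,
                        partner,
                        float(p),
                        float(obs),
                    )
                )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def lr_tests_by(
    adata: AnnData,
    db: pd.DataFrame,
    by,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Run :func:`lr_permutation_test` per group of ``obs`` columns.

    ``by`` is one obs column or a list; the joined group key becomes the
    record's ``sample_id`` and extra columns with the group values are
    attached.  Each group gets a distinct sub-seed derived from ``seed``.
    """
    by = [by] if isinstance(by, str) else list(by)
    frames = []
    groups = adata.obs.groupby(by, observed=True).groups
    for gi, (key, idx) in enumerate(sorted(groups.items())):
        key_t = key if isinstance(key, tuple) else (key,)
        sid = "_".join(map(str, key_t))
        rec = lr_permutation_test(
            adata[adata.obs_names.isin(idx)],
            db,
            sample_id=sid,
            seed=(seed + gi) % (2**31 - 1),
            **kwargs,
        )
        for col, val in zip(by, key_t):
            rec[col] = val
        frames.append(rec)
    if not frames:
        return _empty_records()
    return pd.concat(frames, ignore_index=True)


def filter_pairs(
    records: pd.DataFrame,
    p_max: float = 0.01,
    mean_min: float = 0.5,
    cases=None,
    case_col: str = "sample_id",
    drop_ubiquitous: bool = True,
) -> pd.DataFrame:
    """Stringent filter: p < p_max (strict) and pair_mean > mean_min
    (strict); keys significant in every case are dropped as common,
    patient-unspecific features.

    ``cases`` fixes the case universe for the ubiquity rule; by default
    it is the set of cases present in ``records``.
    """
    if len(records) == 0:
        return records.copy()
    out = records[
        (records["p_value"] < p_max) & (records["pair_mean"] > mean_min)
    ].copy()
    if drop_ubiquitous and len(out):
        universe = (
            set(cases) if cases is not None else set(records[case_col])
        )
        key_cols = ["pair_id", "direction", "partner_celltype"]
        per_key = out.groupby(key_cols, observed=True)[case_col].nunique()
        everywhere = set(per_key[per_key >= len(universe)].index)
        if everywhere:
            keys = out[key_cols].apply(tuple, axis=1)
            out = out[~keys.isin(everywhere)]
    return out.reset_index(drop=True)


def significant_keys(records: pd.DataFrame) -> set:
    """Set of (pair_id, direction, partner_celltype) keys in a record set."""
    if len(records) == 0:
        return set()
    return set(
        map(
            tuple,
            records[["pair_id", "direction", "partner_celltype"]]
            .drop_duplicates()
            .itertuples(index=False),
        )
    )


def regional_stability(
    filtered_records: pd.DataFrame,
    regions=None,
    region_col: str = "region",
) -> pd.DataFrame:
    """Proportion of evaluable tumor regions identifying each key.

    ``filtered_records`` are one case's post-filter records carrying a
    region column; ``regions`` fixes the evaluable-region universe
    (default: regions present in the records).  1 means the key occurs
    in every region, 0 in none.
    """
    if regions is None:
        regions = sorted(set(filtered_records[region_col]))
    if len(regions) == 0:
        raise ValueError("no evaluable regions")
    key_cols = ["pair_id", "direction", "partner_celltype"]
    if len(filtered_records) == 0:
        return pd.DataFrame(columns=key_cols + ["n_regions", "proportion"])
    counts = (
        filtered_records[filtered_records[region_col].isin(regions)]
        .groupby(key_cols, observed=True)[region_col]
        .nunique()
    )
    out = counts.rename("n_regions").reset_index()
    out["proportion"] = out["n_regions"] / len(regions)
    return out


def interaction_overlap(keys_a: set, keys_b: set) -> float:
    """Jaccard similarity of two interaction key sets (0 = disjoint,
    1 = identical); two empty sets are defined as 0."""
    keys_a, keys_b = set(keys_a), set(keys_b)
    union = keys_a | keys_b
    if not union:
        logger.warning("both key sets empty; overlap defined as 0")
        return 0.0
    return len(keys_a & keys_b) / len(union)


def _derangement(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform random permutation of range(n) with no fixed point."""
    if n < 2:
        raise ValueError("derangement needs n >= 2")
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def switching_experiment(
    adata: AnnData,
    db: pd.DataFrame,
    n_shuffles: int = 20,
    seed: int = 0,
    case_col: str = "patient",
    celltype_col: str = "cell_type",
    p_max: float = 0.01,
    mean_min: float = 0.5,
    **test_kwargs,
):
    """Tumor/TME switching: how fast do interaction fingerprints decay?

    Each shuffle deranges the malignant compartments across cases,
    producing chimeric ecosystems (tumor from case a, TME from case b,
    a != b).  The chimera's significant keys are compared with the
    original keys of the case that kept its compartment: against the TME
    owner (``switch_tumor`` mode — the tumor moved) and against the
    tumor owner (``switch_tme`` mode — the TME moved).  The matched
    proportion is |chimera keys ∩ original keys| / |original keys|.

    Returns ``(per_chimera DataFrame, summary dict)`` where the summary
    holds per-mode means, the two-sided t statistic/p and the one-sided
    p for switch_tumor decaying faster than switch_tme.
    """
    mal = adata.obs[celltype_col] == "malignant"
    cases = sorted(
        c
        for c in adata.obs[case_col].unique()
        if (mal & (adata.obs[case_col] == c)).sum() > 0
        and (~mal & (adata.obs[case_col] == c)).sum() > 0
    )
    if len(cases) < 3:
        raise ValueError("switching needs >= 3 cases with both compartments")

    def case_keys(tumor_case, tme_case, sub_seed):
        take = (mal & (adata.obs[case_col] == tumor_case)).to_numpy() | (
            ~mal & (adata.obs[case_col] == tme_case)
        ).to_numpy()
        rec = lr_permutation_test(
            adata[take],
            db,
            sample_id=f"{tumor_case}|{tme_case}",
            celltype_col=celltype_col,
            seed=sub_seed,
            **test_kwargs,
        )
        return significant_keys(
            filter_pairs(rec, p_max, mean_min, drop_ubiquitous=False)
        )

    original = {
        c: case_keys(c, c, seed + 10_000 + i) for i, c in enumerate(cases)
    }
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_shuffles):
        perm = _derangement(rng, len(cases))
        for i, c in enumerate(cases):
            tumor_case = cases[perm[i]]  # tumor moved onto case c's TME
            chim = case_keys(
                tumor_case, c, seed + 20_000 + s * len(cases) + i
            )
            for mode, ref_case in (
                ("switch_tumor", c),
                ("switch_tme", tumor_case),
            ):
                ref = original[ref_case]
                if not ref:
                    continue
                rows.append(
                    (
                        mode,
                        s,
                        tumor_case,
                        c,
                        len(chim & ref) / len(ref),
                    )
                )
    result = pd.DataFrame(
        rows,
        columns=["mode", "shuffle", "tumor_case", "tme_case",
                 "matched_proportion"],
    )
    a = result.loc[result["mode"] == "switch_tumor", "matched_proportion"]
    b = result.loc[result["mode"] == "switch_tme", "matched_proportion"]
    t, p_two = stats.ttest_ind(a, b, equal_var=False)
    t_one, p_one = stats.ttest_ind(a, b, equal_var=False, alternative="less")
    summary = {
        "mean_switch_tumor": float(a.mean()),
        "mean_switch_tme": float(b.mean()),
        "t": float(t),
        "p_two_sided": float(p_two),
        "p_tumor_decays_faster": float(p_one),
    }
    return result, summary


def subsample_accuracy(
    adata: AnnData,
    db: pd.DataFrame,
    cell_counts=(200, 100, 50, 20, 10),
    n_reps: int = 5,
    seed: int = 0,
    celltype_col: str = "cell_type",
    p_max: float = 0.01,
    mean_min: float = 0.5,
    **test_kwargs,
):
    """Robustness of pair identification to malignant-cell subsampling.

    For one case: subsample the malignant compartment to each count
    (all non-malignant cells kept), rerun test + filters, and score the
    matched fraction against the full-data reference key set.  Counts
    exceeding the available malignant cells are skipped with a warning.

    Returns ``(per_replicate DataFrame, mean accuracy per count Series)``.
    """
    mal_idx = np.flatnonzero(
        (adata.obs[celltype_col] == "malignant").to_numpy()
    )
    other_idx = np.flatnonzero(
        (adata.obs[celltype_col] != "malignant").to_numpy()
    )
    ref_rec = lr_permutation_test(
        adata, db, sample_id="full", celltype_col=celltype_col,
        seed=seed, **test_kwargs,
    )
    ref = significant_keys(
        filter_pairs(ref_rec, p_max, mean_min, drop_ubiquitous=False)
    )
    if not ref:
        raise ValueError("no reference interactions identified on full data")

    rng = np.random.default_rng(seed)
    rows = []
    for count in cell_counts:
        if count > mal_idx.size:
            logger.warning(
                "requested %d malignant cells but only %d available; "
                "count skipped", count, mal_idx.size,
            )
            continue
        for rep in range(n_reps):
            take = rng.choice(mal_idx, size=count, replace=False)
            sub = adata[np.sort(np.concatenate([take, other_idx]))]
            rec = lr_permutation_test(
                sub, db, sample_id=f"n{count}_r{rep}",
                celltype_col=celltype_col,
                seed=(seed + 1000 * count + rep) % (2**31 - 1),
                **test_kwargs,
            )
            keys = significant_keys(
                filter_pairs(rec, p_max, mean_min, drop_ubiquitous=False)
            )
            rows.append((count, rep, len(keys & ref) / len(ref)))
    result = pd.DataFrame(rows, columns=["n_cells", "rep", "accuracy"])
    return result, result.groupby("n_cells")["accuracy"].mean()
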