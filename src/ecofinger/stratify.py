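"""Patient stratification by interaction-occurrence networks.

Single-cell interaction records become a binary sample x key occurrence
map; bulk cohorts get an analogous map via the median rule (a pair
"occurs" in a sample when the mean of its ligand and receptor expression
strictly exceeds the cohort median of that pair's scores).  Samples are
clustered with Ward (D2) on correlation distance, and survival
separation between clusters is assessed with the log-rank test (with an
ordered-groups trend variant).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "build_sc_interaction_map",
    "bulk_pair_occurrence",
    "cluster_patients",
    "logrank",
    "cluster_concordance",
]


def build_sc_interaction_map(
    records: pd.DataFrame,
    min_cases: int = 3,
    max_cases: int = 10,
    case_col: str = "sample_id",
) -> pd.DataFrame:
    """Binary sample x (pair, direction, partner) occurrence matrix.

    Keys occurring in fewer than ``min_cases`` or more than ``max_cases``
    cases are dropped (bounds inclusive: the exclusion wording is
    "less than"/"more than").
    """
    if len(records) == 0:
        raise ValueError("no interaction records")
    key = (
        records["pair_id"].astype(str)
        + "|" + records["direction"].astype(str)
        + "|" + records["partner_celltype"].astype(str)
    )
    occ = (
        pd.crosstab(records[case_col], key).astype(bool).astype(int)
    )
    per_key = occ.sum(axis=0)
    keep = per_key[(per_key >= min_cases) & (per_key <= max_cases)].index
    occ = occ[sorted(keep)]
    if occ.shape[1] == 0:
        raise ValueError(
            f"no keys occur in [{min_cases}, {max_cases}] cases"
        )
    return occ


def bulk_pair_occurrence(
    bulk: pd.DataFrame,
    db: pd.DataFrame,
) -> pd.DataFrame:
    """Median-rule occurrence map for a bulk cohort.

    ``bulk`` is genes x samples.  Per sample and pair, the score is the
    mean of ligand and receptor expression; occurrence is 1 iff the score
    strictly exceeds the cohort median of that pair's scores (ties are
    absent, so occurrence is at most 50% of samples).  Keys in bulk are
    pair-only: directions cannot be resolved without cell types.
    """
    if bulk.shape[1] < 2:
        raise ValueError("median rule needs a cohort of >= 2 samples")
    rows = {}
    for _, pair in db.drop_duplicates(["ligand", "receptor"]).iterrows():
        lig, rec = pair["ligand"], pair["receptor"]
        if lig not in bulk.index or rec not in bulk.index:
            logger.warning("pair %s-%s missing from bulk matrix; skipped",
                           lig, rec)
            continue
        score = (bulk.loc[lig] + bulk.loc[rec]) / 2.0
        rows[f"{lig}_{rec}"] = (score > score.median()).astype(int)
    if not rows:
        raise ValueError("no database pair is measurable in the bulk matrix")
    return pd.DataFrame(rows, index=bulk.columns).sort_index(axis=1)


def _occurrence_distance(occ: np.ndarray) -> np.ndarray:
    """1 - Pearson r between occurrence vectors; Jaccard fallback for
    constant vectors (correlation undefined)."""
    n = occ.shape[0]
    sd = occ.std(axis=1)
    D = np.zeros((n, n))
    const = sd == 0
    if const.any():
        logger.warning(
            "%d samples have constant occurrence vectors; Jaccard distance "
            "used for their comparisons", const.sum(),
        )
    with np.errstate(invalid="ignore"):
        R = np.corrcoef(occ)
    for i in range(n):
        for j in range(i + 1, n):
            if const[i] or const[j]:
                a, b = occ[i] > 0, occ[j] > 0
                union = (a | b).sum()
                d = 1.0 - ((a & b).sum() / union if union else 1.0)
            else:
                d = 1.0 - R[i, j]
            D[i, j] = D[j, i] = max(d, 0.0)
    return D


def cluster_patients(
    occurrence: pd.DataFrame,
    k: int = 2,
    survival: pd.DataFrame | None = None,
) -> pd.Series:
    """Cut a Ward (D2) tree over occurrence vectors into ``k`` clusters.

    Samples are ordered lexicographically before linkage so labels are
    invariant to input order.  When ``survival`` (columns ``sample_id,
    time_months, event``) is given, clusters are renamed so that cluster
    1 is the one with the worse (shorter) mean survival time; otherwise
    cluster ids follow dendrogram order.
    """
    if occurrence.shape[0] < k:
        raise ValueError("fewer samples than requested clusters")
    if occurrence.shape[1] < 2:
        raise ValueError("need >= 2 interaction keys")
    occ = occurrence.sort_index()
    D = _occurrence_distance(occ.to_numpy(dtype=float))
    if k == 1:
        return pd.Series(1, index=occ.index, name="cluster")
    Z = linkage(squareform(D, checks=False), method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(raw, index=occ.index, name="cluster")
    if survival is not None:
        surv = survival.set_index("sample_id").reindex(occ.index)
        order = (
            surv.assign(cluster=labels)
            .groupby("cluster")["time_months"]
            .mean()
            .sort_values()  # shortest mean survival first -> cluster 1
            .index
        )
        remap = {old: new + 1 for new, old in enumerate(order)}
        labels = labels.map(remap).rename("cluster")
    return labels


def logrank(
    survival: pd.DataFrame,
    groups: pd.Series,
    trend_scores: dict | None = None,
) -> dict:
    """k-group log-rank test (observed minus expected events, with
    hypergeometric variance) and an optional ordered-groups trend test.

    ``survival`` needs columns ``sample_id, time_months, event``;
    ``groups`` maps sample_id to a group label.  ``trend_scores`` maps
    group label to a numeric score; when given, the trend z statistic
    z = s'(O-E) / sqrt(s'Vs) and its two-sided p are added.
    """
    df = survival.set_index("sample_id")
    groups = pd.Series(groups)
    common = df.index.intersection(groups.index)
    df = df.loc[common]
    g = groups.loc[common]
    labels = sorted(g.unique())
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    if (df["event"] == 1).sum() == 0:
        raise ValueError("all observations censored: log-rank undefined")
    for lab in labels:
        if (g == lab).sum() == 0:  # pragma: no cover - labels from data
            raise ValueError(f"group {lab!r} is empty")

    time = df["time_months"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=int)
    gi = g.map({lab: i for i, lab in enumerate(labels)}).to_numpy()
    k = len(labels)

    event_times = np.unique(time[event == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in event_times:
        at_risk = time >= t
        n = at_risk.sum()
        d = ((time == t) & (event == 1)).sum()
        n_j = np.array([(at_risk & (gi == j)).sum() for j in range(k)],
                       dtype=float)
        d_j = np.array(
            [((time == t) & (event == 1) & (gi == j)).sum() for j in range(k)],
            dtype=float,
        )
        O += d_j
        E += n_j * d / n
        if n > 1:
            c = d * (n - d) / (n - 1) / n**2
            V += c * (np.diag(n_j * n) - np.outer(n_j, n_j))

    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    chi2 = float(diff @ np.linalg.pinv(Vsub) @ diff)
    p = float(stats.chi2.sf(chi2, df=k - 1))
    native = [
        lab.item() if hasattr(lab, "item") else lab for lab in labels
    ]
    out = {
        "statistic": chi2,
        "p_value": p,
        "df": k - 1,
        "observed": dict(zip(native, O.tolist())),
        "expected": dict(zip(native, E.tolist())),
    }
    if trend_scores is not None:
        s = np.array([trend_scores[lab] for lab in labels], dtype=float)
        denom = float(s @ V @ s)
        if denom <= 0:
            raise ValueError("degenerate variance for trend test")
        z = float(s @ (O - E) / np.sqrt(denom))
        out["trend_z"] = z
        out["trend_p"] = float(2.0 * stats.norm.sf(abs(z)))
    return out


def cluster_concordance(
    maps: dict,
    labels: dict,
    cluster: int = 1,
) -> tuple:
    """Cross-cohort agreement of per-key cluster-1 occurrence fractions.

    ``maps`` maps cohort name to an occurrence DataFrame (samples x
    keys) and ``labels`` to a cluster Series over the same samples.  For
    each cohort and key the fraction of cluster-``cluster`` samples with
    occurrence 1 is computed over the shared key universe; agreement is
    the Pearson correlation of these fractions for each cohort pair.

    Returns ``(fractions DataFrame keys x cohorts, agreement DataFrame)``.
    """
    shared = None
    for occ in maps.values():
        cols = set(occ.columns)
        shared = cols if shared is None else shared & cols
    shared = sorted(shared or [])
    if not shared:
        raise ValueError("no shared key universe across cohorts")
    frac = {}
    for name, occ in maps.items():
        lab = pd.Series(labels[name])
        members = lab[lab == cluster].index.intersection(occ.index)
        if len(members) == 0:
            logger.warning("cluster %d empty in cohort %s", cluster, name)
            frac[name] = pd.Series(np.nan, index=shared)
        else:
            frac[name] = occ.loc[members, shared].mean(axis=0)
    frac = pd.DataFrame(frac)
    cohorts = list(frac.columns)
    agree = pd.DataFrame(np.eye(len(cohorts)), index=cohorts, columns=cohorts)
    for i, a in enumerate(cohorts):
        for b in cohorts[i + 1:]:
            ok = frac[[a, b]].dropna()
            if len(ok) < 3 or ok[a].std() == 0 or ok[b].std() == 0:
                r = np.nan
            else:
                r = float(stats.pearsonr(ok[a], ok[b])[0])
            agree.loc[a, b] = agree.loc[b, a] = r
    return frac, agree
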