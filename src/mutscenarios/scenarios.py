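"""Mutational-scenario stratification and cohort statistics.

The per-sample feature table combines relative signature exposures across
variant classes with per-class complex-event counts; features are z-scaled
and clustered by the hybrid hierarchical/k-means procedure (Ward linkage
cut at k initializes Lloyd's k-means).  Defining features of a cluster are
the scaled centroid components exceeding 0.3 in magnitude; concordance maps
each cluster to its majority clinical label.  Co-occurrence uses Spearman
correlation with Benjamini-Hochberg control; group contrasts use
Kruskal-Wallis and pairwise Wilcoxon rank-sum tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .rearrangement_topography import EVENT_CLASSES, ComplexEvent

log = logging.getLogger(__name__)

_EXCLUDED_METADATA = {"risk_group", "sex", "age_group", "os_time", "os_event",
                      "purity", "ploidy", "sample_id"}


@dataclass
class FeatureTable:
    raw: pd.DataFrame     # samples x features
    scaled: pd.DataFrame  # z-scored copy, constant features dropped

    @property
    def samples(self) -> list[str]:
        return list(self.raw.index)


@dataclass
class ScenarioResult:
    k: int
    assignment: pd.Series              # sample -> cluster label (1..k)
    centroids: pd.DataFrame            # cluster x feature, scaled space
    defining_features: dict[int, list[tuple[str, str]]] = field(default_factory=dict)
    concordance: float | None = None
    label_crosstab: pd.DataFrame | None = None


def assemble_features(exposure_tables: Mapping[str, pd.DataFrame],
                      complex_events: Sequence[ComplexEvent] = (),
                      cx_exposures: pd.DataFrame | None = None,
                      event_encoding: str = "count") -> FeatureTable:
    """Join relative exposure tables (one per scheme, samples x signatures)
    with per-class complex-event counts (and optional externally computed
    copy-number signature exposures) into one feature table.

    Sample sets are inner-joined (drops logged); metadata columns never
    enter; a z-scaled copy is produced with constant features dropped.
    """
    blocks: list[pd.DataFrame] = []
    for scheme, table in sorted(exposure_tables.items()):
        tab = table.drop(columns=[c for c in table.columns if c in _EXCLUDED_METADATA],
                         errors="ignore")
        tab = tab.add_prefix(f"{scheme}:")
        blocks.append(tab)
    if cx_exposures is not None:
        blocks.append(cx_exposures.add_prefix("CX:"))
    if not blocks:
        raise ValueError("no exposure tables supplied")
    common = blocks[0].index
    for b in blocks[1:]:
        common = common.intersection(b.index)
    dropped = set().union(*(set(b.index) for b in blocks)) - set(common)
    if dropped:
        log.info("assemble_features: dropped samples absent from some table: %s",
                 sorted(dropped))
    joined = pd.concat([b.loc[common] for b in blocks], axis=1)
    if joined.columns.duplicated().any():
        dups = joined.columns[joined.columns.duplicated()].tolist()
        raise ValueError(f"duplicate feature names: {dups}")

    ev_counts = pd.DataFrame(0.0, index=common,
                             columns=[f"event:{c}" for c in EVENT_CLASSES])
    for ev in complex_events:
        if ev.sample_id in ev_counts.index:
            ev_counts.loc[ev.sample_id, f"event:{ev.event_class}"] += 1
    if event_encoding == "presence":
        ev_counts = (ev_counts > 0).astype(float)
    raw = pd.concat([joined.astype(float), ev_counts], axis=1)
    raw = raw.fillna(0.0)

    sd = raw.std(axis=0, ddof=0)
    constant = sd[sd == 0].index.tolist()
    if constant:
        log.info("assemble_features: dropping constant features %s", constant)
    keep = raw.drop(columns=constant)
    scaled = (keep - keep.mean(axis=0)) / keep.std(axis=0, ddof=0)
    return FeatureTable(raw=raw, scaled=scaled)


def hkmeans(X: pd.DataFrame, k: int, seed: int = 0) -> ScenarioResult:
    """Hybrid hierarchical/k-means: Ward-linkage tree cut at ``k`` supplies
    the initial cluster means for a Lloyd refinement (tol 1e-6, <= 300
    iterations).  Deterministic given the input row order."""
    if k > len(X):
        raise ValueError(f"k={k} exceeds sample count {len(X)}")
    arr = X.to_numpy(dtype=float)
    Z = linkage(arr, method="ward")
    init_labels = fcluster(Z, t=k, criterion="maxclust")
    centers = np.vstack([arr[init_labels == c].mean(axis=0)
                         for c in range(1, k + 1)])
    km = KMeans(n_clusters=k, init=centers, n_init=1, max_iter=300, tol=1e-6,
                random_state=seed).fit(arr)
    assignment = pd.Series(km.labels_ + 1, index=X.index, name="cluster")
    centroids = pd.DataFrame(km.cluster_centers_, index=range(1, k + 1),
                             columns=X.columns)
    return ScenarioResult(k=k, assignment=assignment, centroids=centroids)


def _within_dispersion(X: np.ndarray, labels: np.ndarray) -> float:
    w = 0.0
    for c in np.unique(labels):
        pts = X[labels == c]
        w += ((pts - pts.mean(axis=0)) ** 2).sum()
    return w


def select_k(X: pd.DataFrame, k_range: Sequence[int] = range(1, 11),
             B: int = 50, seed: int = 0,
             reference: str = "scaled_pca") -> tuple[pd.DataFrame, int]:
    """Gap statistic over ``k_range``; suggested k is the smallest k with
    gap(k) >= gap(k+1) - s(k+1).

    ``reference="scaled_pca"`` draws the B uniform reference data sets in
    the PCA-rotated bounding box of the data (the R ``clusGap`` default),
    which keeps the reference's rank structure comparable to features with
    compositional constraints; ``reference="original"`` uses the plain
    per-feature bounding box.
    """
    rng = np.random.default_rng(seed)
    arr = X.to_numpy(dtype=float)
    ks = [k for k in k_range if 1 <= k <= len(X)]

    def labels_for(data: np.ndarray, k: int) -> np.ndarray:
        if k == 1:
            return np.zeros(len(data), dtype=int)
        Z = linkage(data, method="ward")
        init = fcluster(Z, t=k, criterion="maxclust")
        centers = np.vstack([data[init == c].mean(axis=0) for c in range(1, k + 1)])
        return KMeans(n_clusters=k, init=centers, n_init=1, max_iter=300,
                      tol=1e-6, random_state=0).fit(data).labels_

    if reference == "scaled_pca":
        mu = arr.mean(axis=0)
        centered = arr - mu
        _u, _s, vt = np.linalg.svd(centered, full_matrices=False)
        scores = centered @ vt.T
        lo, hi = scores.min(axis=0), scores.max(axis=0)
        refs = [rng.uniform(lo, hi, size=scores.shape) @ vt + mu for _ in range(B)]
    elif reference == "original":
        lo, hi = arr.min(axis=0), arr.max(axis=0)
        refs = [rng.uniform(lo, hi, size=arr.shape) for _ in range(B)]
    else:
        raise ValueError(f"unknown reference scheme {reference!r}")
    rows = []
    for k in ks:
        logw = np.log(_within_dispersion(arr, labels_for(arr, k)) + 1e-300)
        ref_logw = np.array([np.log(_within_dispersion(r, labels_for(r, k)) + 1e-300)
                             for r in refs])
        gap = ref_logw.mean() - logw
        s = ref_logw.std(ddof=0) * np.sqrt(1.0 + 1.0 / B)
        rows.append({"k": k, "gap": gap, "s": s, "log_wk": logw})
    report = pd.DataFrame(rows).set_index("k")
    suggested = ks[-1]
    for i, k in enumerate(ks[:-1]):
        if report.loc[k, "gap"] >= report.loc[ks[i + 1], "gap"] - report.loc[ks[i + 1], "s"]:
            suggested = k
            break
    return report, int(suggested)


def defining_features(centroids: pd.DataFrame,
                      threshold: float = 0.3) -> dict[int, list[tuple[str, str]]]:
    """Per cluster, features whose scaled centroid magnitude is >= threshold,
    signed as enriched/depleted, ordered by descending magnitude."""
    out: dict[int, list[tuple[str, str]]] = {}
    for cluster, row in centroids.iterrows():
        hits = [(feat, "enriched" if val >= 0 else "depleted", abs(val))
                for feat, val in row.items() if abs(val) >= threshold]
        hits.sort(key=lambda t: -t[2])
        out[int(cluster)] = [(f, sign) for f, sign, _ in hits]
    return out


def concordance(assignment: pd.Series, labels: pd.Series,
                ) -> tuple[float, pd.DataFrame]:
    """Majority-label concordance: each cluster maps to its most frequent
    label; returns (fraction of labelled samples matching their cluster's
    majority label, cluster x label crosstab)."""
    common = assignment.index.intersection(labels.dropna().index)
    if len(common) == 0:
        raise ValueError("no labelled samples")
    a = assignment.loc[common]
    l = labels.loc[common]
    crosstab = pd.crosstab(a, l)
    matched = int(crosstab.max(axis=1).sum())
    return matched / len(common), crosstab


def spearman_cooccurrence(X: pd.DataFrame, Y: pd.DataFrame | None = None,
                          alpha: float = 0.05,
                          ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman correlation with BH-adjusted significance mask.

    Returns (rho, adjusted p, mask) frames; constant columns yield NaN and
    are never significant.
    """
    Y = X if Y is None else Y
    rho = pd.DataFrame(np.nan, index=X.columns, columns=Y.columns)
    pval = pd.DataFrame(np.nan, index=X.columns, columns=Y.columns)
    for cx in X.columns:
        for cy in Y.columns:
            x, y = X[cx].to_numpy(float), Y[cy].to_numpy(float)
            if len(x) < 3 or np.all(x == x[0]) or np.all(y == y[0]):
                continue
            r, p = stats.spearmanr(x, y)
            rho.loc[cx, cy] = r
            pval.loc[cx, cy] = p
    flat = pval.to_numpy().ravel()
    finite = np.isfinite(flat)
    adj = np.full_like(flat, np.nan)
    if finite.any():
        adj[finite] = multipletests(flat[finite], method="fdr_bh")[1]
    padj = pd.DataFrame(adj.reshape(pval.shape), index=pval.index, columns=pval.columns)
    mask = padj < alpha
    return rho, padj, mask


def group_tests(values: pd.Series, groups: pd.Series, alpha: float = 0.05,
                exact_max_n: int = 25) -> dict:
    """Kruskal-Wallis omnibus plus BH-adjusted pairwise Wilcoxon rank-sum
    tests; exact Wilcoxon when both groups have <= ``exact_max_n``
    observations and no ties, normal approximation with tie correction
    otherwise.  Groups with < 2 members are dropped (logged)."""
    common = values.index.intersection(groups.dropna().index)
    v, g = values.loc[common], groups.loc[common]
    by_group = {name: v[g == name].to_numpy(float) for name in sorted(g.unique())}
    for name in [n for n, arr in by_group.items() if len(arr) < 2]:
        log.info("group_tests: dropping group %r with < 2 members", name)
        del by_group[name]
    if len(by_group) < 2:
        raise ValueError("need at least two groups with >= 2 members")
    kw_p = float(stats.kruskal(*by_group.values()).pvalue)
    pairs, raw_p = [], []
    for a, b in combinations(sorted(by_group), 2):
        xa, xb = by_group[a], by_group[b]
        pooled = np.concatenate([xa, xb])
        has_ties = len(np.unique(pooled)) < len(pooled)
        method = ("exact" if (len(xa) <= exact_max_n and len(xb) <= exact_max_n
                              and not has_ties) else "asymptotic")
        res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
        pairs.append((a, b))
        raw_p.append(float(res.pvalue))
    adj = multipletests(raw_p, method="fdr_bh")[1] if raw_p else []
    pairwise = pd.DataFrame({
        "group_a": [p[0] for p in pairs], "group_b": [p[1] for p in pairs],
        "p": raw_p, "p_adj": list(adj)})
    return {"kruskal_p": kw_p, "pairwise": pairwise,
            "significant": pairwise[pairwise["p_adj"] < alpha] if len(pairwise) else pairwise}
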