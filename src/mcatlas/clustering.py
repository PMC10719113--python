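"""Iterative consensus clustering of binned single-cell methylomes.

The clustering round mirrors the atlas recipe: beta-shrunken (posterior)
bin fractions normalized by each cell's global level, highly variable
feature selection, PCA, many-seed Leiden consensus, and supervised merging
of confusable clusters until a held-out prediction accuracy target is met.
Rounds recurse into large, well-predicted clusters; final labels are split
by dissection region into cell groups.
"""

from __future__ import annotations

import warnings

import igraph
import leidenalg
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, mutual_info_score
from sklearn.model_selection import cross_val_predict
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .containers import CellBasecallTable

__all__ = [
    "posterior_fractions", "select_features", "cluster_enriched_features",
    "consensus_cluster", "iterate_clustering", "mutual_information_rank",
    "knn_graph", "leiden_once",
]


# ---------------------------------------------------------------- posterior

def posterior_fractions(table: CellBasecallTable, context: str = "CG",
                        prior: tuple | None = None, normalize: bool = True,
                        cap: float = 10.0) -> np.ndarray:
    """Beta-shrunken per-cell bin fractions.

    For each cell a Beta(alpha, beta) prior is fitted by method of moments to
    that cell's raw bin fractions; the posterior mean ``(mc+a)/(cov+a+b)`` is
    returned, optionally divided by the cell's global level and capped.
    Zero-coverage bins get the prior mean.  ``prior`` forces one (a, b) for
    every cell (used for closed-form checks).
    """
    mc, cov = table.counts[context]
    n, b = mc.shape
    out = np.empty((n, b))
    glob = table.global_levels["mCG" if context == "CG" else "mCH"].to_numpy()
    for i in range(n):
        ci, mi = cov[i], mc[i]
        has = ci > 0
        if prior is not None:
            a, be = prior
        else:
            raw = mi[has] / ci[has]
            m, v = raw.mean(), raw.var()
            if v <= 1e-12 or not (0 < m < 1):
                warnings.warn(f"degenerate beta prior for cell {i}; using raw "
                              "fractions")
                row = np.where(has, np.divide(mi, ci, where=has,
                                              out=np.full(b, m, float)), m)
                out[i] = row
                continue
            common = m * (1 - m) / v - 1
            if common <= 0:
                warnings.warn(f"degenerate beta prior for cell {i}; using raw "
                              "fractions")
                out[i] = np.where(has, np.divide(mi, ci, where=has,
                                                 out=np.full(b, m, float)), m)
                continue
            a, be = m * common, (1 - m) * common
        out[i] = (mi + a) / (ci + a + be)
    if normalize:
        out = out / np.maximum(glob, 1e-6)[:, None]
        out = np.minimum(out, cap)
    return out


# ------------------------------------------------------------ feature sets

def _overlaps(bin_starts, bin_size, intervals) -> np.ndarray:
    """Mask of bins overlapping any 0-based half-open interval."""
    mask = np.zeros(len(bin_starts), dtype=bool)
    ends = bin_starts + bin_size
    for _, s, e in intervals:
        mask |= (bin_starts < e) & (ends > s)
    return mask


def select_features(matrix: np.ndarray, cov: np.ndarray,
                    bin_starts: np.ndarray, bin_size: int,
                    blacklist=None, n_top: int = 100,
                    cov_bounds: tuple = (0.05, 20.0),
                    n_dispersion_bins: int = 1) -> np.ndarray:
    """Highly variable feature (bin) indices.

    Removes blacklist-overlapping bins and bins whose mean coverage falls
    outside ``cov_bounds`` x the median bin coverage, ranks the rest by
    Z-normalized dispersion (variance/mean) of the posterior fractions and
    returns the top ``n_top`` indices.  ``n_dispersion_bins > 1`` normalizes
    within mean-quantile bins instead (useful when dispersion is strongly
    mean-coupled, as in count data; fraction matrices default to global).
    """
    keep = np.ones(matrix.shape[1], dtype=bool)
    if blacklist is not None and len(blacklist):
        ivals = [(c, s, e) for c, s, e in
                 (blacklist[["chrom", "start", "end"]].itertuples(index=False)
                  if isinstance(blacklist, pd.DataFrame) else blacklist)]
        keep &= ~_overlaps(bin_starts, bin_size, ivals)
    mean_cov = cov.mean(axis=0)
    med = np.median(mean_cov[keep]) if keep.any() else 0.0
    keep &= (mean_cov > cov_bounds[0] * med) & (mean_cov < cov_bounds[1] * med)
    if not keep.any():
        raise ValueError("all bins removed by blacklist/coverage filters")

    idx = np.where(keep)[0]
    sub = matrix[:, idx]
    mean = sub.mean(axis=0)
    var = sub.var(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    # normalize dispersion within mean-quantile bins (scanpy-style)
    order = np.argsort(mean)
    nbin = max(min(n_dispersion_bins, len(idx) // 50), 1)
    bins = np.array_split(order, nbin)
    norm = np.empty_like(disp)
    for bidx in bins:
        d = disp[bidx]
        sd = d.std()
        norm[bidx] = (d - d.mean()) / sd if sd > 0 else 0.0
    top = idx[np.argsort(norm)[::-1][:n_top]]
    return np.sort(top)


def _auroc_low(ranks: np.ndarray, member: np.ndarray) -> np.ndarray:
    """Per-feature AUROC that member cells have LOWER values (hypomethylated).

    ``ranks``: cells x features rank matrix (1-based, average ties)."""
    n1 = member.sum()
    n2 = len(member) - n1
    rank_sum = ranks[member].sum(axis=0)
    u_greater = rank_sum - n1 * (n1 + 1) / 2.0
    return 1.0 - u_greater / (n1 * n2)


def cluster_enriched_features(matrix: np.ndarray, labels: np.ndarray,
                              n_top: int = 200, n_perm: int = 2000,
                              fdr_cut: float = 0.01, seed: int = 0,
                              min_cluster_size: int = 3):
    """Per-cluster hypomethylation-enriched features (CEFs).

    Features are ranked per cluster by one-vs-rest AUROC of *low* fraction;
    significance from a label-permutation null (cluster membership resampled
    ``n_perm`` times), BH-corrected.  Returns (union indices, per-cluster dict
    of DataFrames with auroc/p/fdr for its selected features).
    """
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")
    rng = np.random.default_rng(seed)
    ranks = stats.rankdata(matrix, axis=0)
    n = matrix.shape[0]

    per_cluster, union = {}, set()
    for c in clusters:
        member = labels == c
        n1 = int(member.sum())
        if n1 < min_cluster_size:
            warnings.warn(f"cluster {c} has <{min_cluster_size} cells; skipped")
            continue
        obs = _auroc_low(ranks, member)
        null = np.empty((n_perm, matrix.shape[1]))
        for p in range(n_perm):
            fake = np.zeros(n, dtype=bool)
            fake[rng.choice(n, n1, replace=False)] = True
            null[p] = _auroc_low(ranks, fake)
        pvals = (1 + (null >= obs).sum(axis=0)) / (1 + n_perm)
        fdr = multipletests(pvals, method="fdr_bh")[1]
        sig = np.where(fdr < fdr_cut)[0]
        chosen = sig[np.argsort(obs[sig])[::-1][:n_top]]
        per_cluster[c] = pd.DataFrame({"feature": chosen, "auroc": obs[chosen],
                                       "p": pvals[chosen], "fdr": fdr[chosen]})
        union.update(chosen.tolist())
    return np.array(sorted(union), dtype=int), per_cluster


# -------------------------------------------------------------- clustering

def knn_graph(embedding: np.ndarray, k: int = 15) -> igraph.Graph:
    nn = NearestNeighbors(n_neighbors=min(k + 1, len(embedding))).fit(embedding)
    _, ind = nn.kneighbors(embedding)
    edges = {(min(i, j), max(i, j)) for i, row in enumerate(ind) for j in row[1:]}
    g = igraph.Graph(n=len(embedding), edges=sorted(edges))
    return g


def leiden_once(graph: igraph.Graph, resolution: float, seed: int) -> np.ndarray:
    part = leidenalg.find_partition(
        graph, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=int(seed))
    return np.asarray(part.membership)


def _merge_score(cm: np.ndarray) -> np.ndarray:
    """Symmetric pairwise confusability from a confusion matrix via row (R1)
    and column (R2) normalization (SCCAF-lineage)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        r1 = cm / np.maximum(cm.sum(axis=1, keepdims=True), 1)
        r2 = cm / np.maximum(cm.sum(axis=0, keepdims=True), 1)
    s = (r1 + r1.T + r2 + r2.T) / 4.0
    np.fill_diagonal(s, 0.0)
    return s


def consensus_cluster(embedding: np.ndarray, n_runs: int = 200,
                      resolution: float = 0.25, accuracy_target: float = 0.95,
                      k: int = 15, seed: int = 0, min_cluster_size: int = 10,
                      cv: int = 5):
    """Many-seed Leiden consensus with supervised cluster merging.

    Leiden runs ``n_runs`` times with distinct seeds; cells with identical
    label vectors form preliminary clusters (tiny ones are reassigned by the
    classifier).  A multinomial logistic-regression model on the embedding
    predicts labels under cross-validation; the most confusable cluster pair
    (R1/R2-normalized confusion) is merged until held-out accuracy reaches
    ``accuracy_target``.  Returns (labels, overall accuracy, per-cluster
    accuracy array).
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    n = len(embedding)
    graph = knn_graph(embedding, k=k)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_runs)
    runs = np.stack([leiden_once(graph, resolution, s) for s in seeds], axis=1)

    _, labels = np.unique(runs, axis=0, return_inverse=True)
    # drop tiny preliminary clusters; reassign by nearest big-cluster centroid
    sizes = np.bincount(labels)
    big = np.where(sizes >= min_cluster_size)[0]
    if len(big) == 0:
        big = np.array([np.argmax(sizes)])
    centroids = np.stack([embedding[labels == c].mean(axis=0) for c in big])
    small_mask = ~np.isin(labels, big)
    if small_mask.any():
        d = ((embedding[small_mask][:, None, :] - centroids[None]) ** 2).sum(-1)
        labels[small_mask] = big[np.argmin(d, axis=1)]
    _, labels = np.unique(labels, return_inverse=True)

    def evaluate(lab):
        n_cl = lab.max() + 1
        if n_cl == 1:
            return 1.0, np.ones(1), np.ones((1, 1))
        clf = LogisticRegression(max_iter=500, random_state=int(seed))
        folds = min(cv, np.bincount(lab).min())
        if folds < 2:
            pred = clf.fit(embedding, lab).predict(embedding)
        else:
            pred = cross_val_predict(clf, embedding, lab, cv=folds)
        cm = confusion_matrix(lab, pred)
        acc = (pred == lab).mean()
        per = np.diag(cm) / np.maximum(cm.sum(axis=1), 1)
        return acc, per, cm

    while True:
        acc, per_cluster, cm = evaluate(labels)
        if acc >= accuracy_target or labels.max() == 0:
            break
        score = _merge_score(cm)
        i, j = np.unravel_index(np.argmax(score), score.shape)
        labels[labels == max(i, j)] = min(i, j)
        _, labels = np.unique(labels, return_inverse=True)
    return labels, acc, per_cluster


def _round(matrix_cg, matrix_ch, cov_cg, bin_starts, bin_size, blacklist,
           n_hvf, n_pcs, resolution, accuracy_target, n_runs, seed):
    hvf_cg = select_features(matrix_cg, cov_cg, bin_starts, bin_size,
                             blacklist=blacklist, n_top=n_hvf)
    feats = [matrix_cg[:, hvf_cg]]
    if matrix_ch is not None:
        feats.append(matrix_ch[:, hvf_cg])
    X = np.column_stack(feats)
    X = (X - X.mean(axis=0)) / np.maximum(X.std(axis=0), 1e-9)
    n_pcs = min(n_pcs, min(X.shape) - 1)
    pcs = PCA(n_components=n_pcs, random_state=seed).fit_transform(X)
    labels, acc, per = consensus_cluster(pcs, n_runs=n_runs,
                                         resolution=resolution,
                                         accuracy_target=accuracy_target,
                                         seed=seed)
    return labels, acc, per, pcs


def iterate_clustering(table: CellBasecallTable, max_rounds: int = 4,
                       n_hvf: int = 100, n_pcs: int = 20, n_runs: int = 50,
                       resolution_first: float = 0.25,
                       resolution_later: float = 0.5,
                       blacklist=None, seed: int = 0,
                       min_split_size: int = 20,
                       split_accuracy: float = 0.9):
    """Full iterative clustering: rounds of consensus clustering that recurse
    into accurate (>{split_accuracy}), large (>{min_split_size}) clusters,
    then a final split of clusters by dissection region into cell groups
    (regions with <{min_split_size} cells merge into the nearest region by
    mean Euclidean distance in PC space).

    Returns (labels, cell_groups, info dict with pcs / per-round history).
    """
    frac_cg = posterior_fractions(table, "CG")
    frac_ch = posterior_fractions(table, "CH") if "CH" in table.counts else None
    _, cov_cg = table.counts["CG"]

    n = table.n_cells
    labels = np.zeros(n, dtype=int)
    history = []
    pcs_final = np.zeros((n, n_pcs))
    active = [(np.arange(n), 0)]
    for rnd in range(max_rounds):
        res = resolution_first if rnd == 0 else resolution_later
        target = 0.95 if rnd == 0 else 0.9
        next_active, changed = [], False
        for cells, _ in active:
            if len(cells) <= min_split_size:
                continue
            sub_labels, acc, per, pcs = _round(
                frac_cg[cells], None if frac_ch is None else frac_ch[cells],
                cov_cg[cells], table.bin_starts, table.bin_size, blacklist,
                n_hvf, n_pcs, res, target, n_runs, seed + rnd)
            pcs_final[cells, :pcs.shape[1]] = pcs
            if sub_labels.max() == 0:
                continue
            changed = True
            base = labels.max() + 1
            labels[cells] = base + sub_labels
            for c in range(sub_labels.max() + 1):
                members = cells[sub_labels == c]
                if len(members) > min_split_size and per[c] > split_accuracy:
                    next_active.append((members, rnd + 1))
            history.append({"round": rnd, "n_cells": len(cells),
                            "n_clusters": int(sub_labels.max() + 1),
                            "accuracy": acc})
        _, labels = np.unique(labels, return_inverse=True)
        if not next_active or not changed:
            break
        active = next_active

    cell_groups = _split_by_region(labels, table, pcs_final, min_split_size)
    return labels, cell_groups, {"pcs": pcs_final, "history": history}


def _split_by_region(labels, table, pcs, min_size):
    regions = table.cell_meta["region"].to_numpy()
    groups = np.empty(len(labels), dtype=object)
    for c in np.unique(labels):
        members = np.where(labels == c)[0]
        regs, counts = np.unique(regions[members], return_counts=True)
        big = regs[counts >= min_size]
        if len(big) == 0:
            groups[members] = f"c{c}:{regs[np.argmax(counts)]}"
            continue
        cent = {r: pcs[members[regions[members] == r]].mean(axis=0) for r in big}
        for r, cnt in zip(regs, counts):
            cells = members[regions[members] == r]
            if r in cent and cnt >= min_size:
                groups[cells] = f"c{c}:{r}"
            else:
                mean_pc = pcs[cells].mean(axis=0)
                nearest = min(cent, key=lambda rr: np.sum((cent[rr] - mean_pc) ** 2))
                groups[cells] = f"c{c}:{nearest}"
    return pd.Series(groups, index=table.cells, name="cell_group")


# ------------------------------------------------------- mutual information

def mutual_information_rank(matrix: np.ndarray, labels, n_bins: int = 20
                            ) -> pd.DataFrame:
    """Rank features by mutual information between the quantile-discretized
    fraction and categorical labels (descending)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        return pd.DataFrame({"feature": np.arange(matrix.shape[1]),
                             "mi": np.zeros(matrix.shape[1])})
    mis = np.empty(matrix.shape[1])
    for j in range(matrix.shape[1]):
        col = matrix[:, j]
        qs = np.unique(np.quantile(col, np.linspace(0, 1, n_bins + 1)[1:-1]))
        disc = np.searchsorted(qs, col)
        mis[j] = mutual_info_score(labels, disc)
    order = np.argsort(mis)[::-1]
    return pd.DataFrame({"feature": order, "mi": mis[order]})
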