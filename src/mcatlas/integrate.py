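"""Cross-modality integration: downsampled CCA, mutual-nearest-neighbour
anchors, bias-vector embedding correction, LSI with hypomethylation scores,
overlap-score cluster matching, iterative integration, alignment score, and
spatial-location imputation against imaging data.

The CCA is fitted on a (seeded, optionally stratified) reference subsample of
each dataset and queries are projected algebraically onto the same canonical
space, which makes the procedure identical to full CCA whenever the reference
covers all cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats
from sklearn.neighbors import NearestNeighbors

from .clustering import knn_graph, leiden_once
from .containers import CellBasecallTable, Embedding

__all__ = [
    "downsampled_cca", "find_anchors", "correct_embedding",
    "hypomethylation_score", "lsi_fit_transform", "overlap_score_map",
    "iterate_integration", "alignment_score", "filter_merfish_cells",
    "impute_spatial_location", "AnchorSet", "ClusterMap", "zscore_clip",
]


@dataclass
class AnchorSet:
    pairs: np.ndarray      # (n_anchors, 2): index in A, index in B
    scores: np.ndarray     # in [0, 1]

    def __len__(self):
        return len(self.pairs)


@dataclass
class ClusterMap:
    overlap: pd.DataFrame          # A clusters x B clusters overlap scores
    groups_a: dict                 # A cluster -> integration group
    groups_b: dict


# ----------------------------------------------------------------- scaling

def zscore_clip(X: np.ndarray, clip: float = 10.0) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = np.maximum(X.std(axis=0), 1e-9)
    return np.clip((X - mu) / sd, -clip, clip)


def _l2norm(X: np.ndarray) -> np.ndarray:
    return X / np.maximum(np.linalg.norm(X, axis=1, keepdims=True), 1e-12)


# --------------------------------------------------------------------- CCA

def downsampled_cca(X: np.ndarray, Y: np.ndarray, n_dims: int = 10,
                    n_ref: int = 100_000, seed: int = 0,
                    labels_x=None, labels_y=None):
    """CCA of two scaled cell x shared-feature matrices via a reference
    subsample.

    SVD of ``X_ref @ Y_ref.T = U_ref S V_ref^T`` gives the reference
    canonical vectors; query cells are projected with
    ``U_qry = X_qry (Y_ref^T V_ref) / S`` (and symmetrically for Y).  Rows are
    L2-normalized.  Returns two :class:`Embedding` objects whose ``basis``
    holds the projection operator ``Y_ref^T V_ref`` (resp. ``X_ref^T U_ref``).
    """
    if X.shape[1] != Y.shape[1]:
        raise ValueError("datasets must share feature columns")
    rank = min(X.shape[0], Y.shape[0], X.shape[1])
    if n_dims > rank:
        raise ValueError(f"n_dims={n_dims} exceeds attainable rank {rank}")
    rng = np.random.default_rng(seed)

    def pick(n, labels):
        if n <= n_ref:
            return np.arange(n)
        if labels is None:
            return np.sort(rng.choice(n, n_ref, replace=False))
        # stratified by cluster label
        labels = np.asarray(labels)
        out = []
        for c in np.unique(labels):
            idx = np.where(labels == c)[0]
            take = max(1, int(round(n_ref * len(idx) / n)))
            out.append(rng.choice(idx, min(take, len(idx)), replace=False))
        return np.sort(np.concatenate(out))

    ix = pick(X.shape[0], labels_x)
    iy = pick(Y.shape[0], labels_y)
    Xr, Yr = X[ix], Y[iy]

    cross = Xr @ Yr.T
    Ur, S, Vt = np.linalg.svd(cross, full_matrices=False)
    Ur, S, Vr = Ur[:, :n_dims], S[:n_dims], Vt[:n_dims].T

    proj_x = Yr.T @ Vr      # features x dims
    proj_y = Xr.T @ Ur
    U_all = (X @ proj_x) / S
    V_all = (Y @ proj_y) / S

    emb_x = Embedding(coords=_l2norm(U_all), singular_values=S, basis=proj_x,
                      provenance="CCA")
    emb_y = Embedding(coords=_l2norm(V_all), singular_values=S, basis=proj_y,
                      provenance="CCA")
    return emb_x, emb_y


# ----------------------------------------------------------------- anchors

def find_anchors(emb_a: Embedding, emb_b: Embedding, k: int = 5,
                 k_score: int = 30) -> AnchorSet:
    """Mutual k-nearest-neighbour anchor pairs with shared-neighbour scores.

    A pair (a, b) is an anchor when a is among b's k nearest cross-dataset
    neighbours and vice versa.  The anchor score counts shared cells among
    the two members' ``k_score``-neighbourhoods in the joint space, min-max
    rescaled to [0, 1].
    """
    A, B = emb_a.coords, emb_b.coords
    ka = min(k, len(B)); kb = min(k, len(A))
    nn_ab = NearestNeighbors(n_neighbors=ka).fit(B)
    _, ab = nn_ab.kneighbors(A)             # A -> B
    nn_ba = NearestNeighbors(n_neighbors=kb).fit(A)
    _, ba = nn_ba.kneighbors(B)             # B -> A

    ba_sets = [set(row) for row in ba]
    pairs = [(i, j) for i in range(len(A)) for j in ab[i] if i in ba_sets[j]]
    if not pairs:
        warnings.warn("no mutual nearest neighbours found")
        return AnchorSet(pairs=np.empty((0, 2), dtype=int),
                         scores=np.empty(0))
    pairs = np.array(pairs)

    joint = np.vstack([A, B])
    ks = min(k_score, len(joint) - 1)
    nn_joint = NearestNeighbors(n_neighbors=ks + 1).fit(joint)
    _, jnn = nn_joint.kneighbors(joint)
    neigh = [set(row[1:]) for row in jnn]
    off = len(A)
    raw = np.array([len(neigh[i] & neigh[off + j]) for i, j in pairs],
                   dtype=float)
    lo, hi = raw.min(), raw.max()
    scores = (raw - lo) / (hi - lo) if hi > lo else np.ones_like(raw)
    return AnchorSet(pairs=pairs, scores=scores)


def correct_embedding(query: np.ndarray, reference: np.ndarray,
                      anchors: AnchorSet, n_anchor_nn: int = 100,
                      kernel_sigma: float = 0.3) -> np.ndarray:
    """Move each query cell by a weighted average of its nearest anchors'
    bias vectors ``B_k = reference[k_ref] - query[k_query]``.

    Distances are measured in the query embedding to the anchor's query-side
    cell; weights are a Gaussian kernel on rank-normalized distances (closest
    anchor weighs most).  The reference embedding is never modified.
    """
    if len(anchors) == 0:
        raise ValueError("anchor set is empty")
    a_ref = anchors.pairs[:, 0]
    a_qry = anchors.pairs[:, 1]
    bias = reference[a_ref] - query[a_qry]       # per-anchor bias vectors
    k = min(n_anchor_nn, len(anchors))
    nn = NearestNeighbors(n_neighbors=k).fit(query[a_qry])
    dist, idx = nn.kneighbors(query)
    ranks = np.arange(1, k + 1) / k
    w = np.exp(-(ranks ** 2) / (2 * kernel_sigma ** 2))
    w = w / w.sum()
    corrected = query + np.einsum("k,nkd->nd", w, bias[idx])
    return corrected


# ------------------------------------------------------ LSI / hypo scores

def hypomethylation_score(table: CellBasecallTable, context: str = "CG",
                          threshold: float = 0.95,
                          min_nonzero: int = 5, z_bounds=(-2.0, 2.0)):
    """Binarized per-cell hypomethylation calls on fine bins.

    Score = P(Binomial(cov_ij, p_i) > mc_ij), the binomial tail probability
    that the bin is less methylated than the cell's global level ``p_i``;
    entries with score > ``threshold`` become 1.  Columns must have more than
    ``min_nonzero`` non-zeros and Z-scored log2 column sums inside
    ``z_bounds``.  Returns (binary csr matrix, kept column indices, scores).
    """
    mc, cov = table.counts[context]
    p = table.global_levels["mCG" if context == "CG" else "mCH"].to_numpy()
    # P(X > mc) = sf(mc); cov=0 -> score 0
    score = stats.binom.sf(mc, cov, p[:, None])
    score[cov == 0] = 0.0
    binary = (score > threshold).astype(np.int8)

    colsum = binary.sum(axis=0)
    keep = colsum > min_nonzero
    if keep.any():
        lg = np.log2(colsum[keep])
        z = (lg - lg.mean()) / max(lg.std(), 1e-9)
        ok = (z >= z_bounds[0]) & (z <= z_bounds[1])
        cols = np.where(keep)[0][ok]
    else:
        cols = np.array([], dtype=int)
    return sparse.csr_matrix(binary[:, cols]), cols, score


def lsi_fit_transform(B, fitted: Embedding | None = None, n_dims: int = 10,
                      scale: float = 100_000.0) -> Embedding:
    """Latent semantic indexing with log term frequency.

    Fit mode: ``X = log(TFreq*scale + 1) * IDF`` with
    ``IDF_j = log(1 + n_cells / colsum_j)``; SVD ``X = U S V^T`` returns the
    singular-value-normalized ``U`` and stores (S, V, IDF) for transform mode,
    which projects new data with the stored IDF via ``U_a = X_a V / S``.
    """
    B = sparse.csr_matrix(B).astype(float)
    rowsum = np.asarray(B.sum(axis=1)).ravel()
    if np.any(rowsum == 0):
        bad = int(np.where(rowsum == 0)[0][0])
        raise ValueError(f"cell {bad} has an all-zero row")
    tf = sparse.diags(1.0 / rowsum) @ B
    if fitted is None:
        colsum = np.asarray(B.sum(axis=0)).ravel()
        idf = np.log(1 + B.shape[0] / np.maximum(colsum, 1e-12))
    else:
        idf = fitted.idf
    X = np.log1p(tf.toarray() * scale) * idf
    if fitted is None:
        U, S, Vt = np.linalg.svd(X, full_matrices=False)
        U, S, V = U[:, :n_dims], S[:n_dims], Vt[:n_dims].T
        return Embedding(coords=U, singular_values=S, basis=V,
                         provenance="LSI", idf=idf)
    U = (X @ fitted.basis) / fitted.singular_values
    return Embedding(coords=U, singular_values=fitted.singular_values,
                     basis=fitted.basis, provenance="LSI", idf=idf)


# --------------------------------------------------- cluster correspondence

def overlap_score_map(labels_a, labels_b, co_labels_a, co_labels_b,
                      resolution: float = 1.0, seed: int = 0) -> ClusterMap:
    """Overlap-score confusion matrix between two cluster labelings plus
    Leiden biclustering into integration groups.

    ``OS(a, b) = sum_k min(frac of cluster a in co-cluster k, frac of b in
    k)`` where co-clusters come from joint clustering of the integrated
    embedding.  The OS matrix, used as a weighted bipartite adjacency, is
    Leiden-clustered (resolution 1) to assign each A and B cluster to an
    integration group.
    """
    labels_a = np.asarray(labels_a); labels_b = np.asarray(labels_b)
    co_a = np.asarray(co_labels_a); co_b = np.asarray(co_labels_b)
    cas = np.unique(labels_a); cbs = np.unique(labels_b)
    ks = np.unique(np.concatenate([co_a, co_b]))
    fa = np.zeros((len(cas), len(ks)))
    fb = np.zeros((len(cbs), len(ks)))
    for i, c in enumerate(cas):
        m = labels_a == c
        if m.any():
            cnt = np.array([(co_a[m] == k).sum() for k in ks], float)
            fa[i] = cnt / cnt.sum()
    for i, c in enumerate(cbs):
        m = labels_b == c
        if m.any():
            cnt = np.array([(co_b[m] == k).sum() for k in ks], float)
            fb[i] = cnt / cnt.sum()
    os_mat = np.minimum(fa[:, None, :], fb[None, :, :]).sum(axis=2)
    overlap = pd.DataFrame(os_mat, index=cas, columns=cbs)

    # weighted bipartite graph -> Leiden integration groups
    na, nb = len(cas), len(cbs)
    edges, weights = [], []
    for i in range(na):
        for j in range(nb):
            if os_mat[i, j] > 0:
                edges.append((i, na + j))
                weights.append(os_mat[i, j])
    g = igraph_graph(na + nb, edges, weights)
    import leidenalg as la
    part = la.find_partition(g, la.RBConfigurationVertexPartition,
                             weights="weight" if weights else None,
                             resolution_parameter=resolution, seed=seed)
    member = np.asarray(part.membership)
    groups_a = {c: int(member[i]) for i, c in enumerate(cas)}
    groups_b = {c: int(member[na + j]) for j, c in enumerate(cbs)}
    return ClusterMap(overlap=overlap, groups_a=groups_a, groups_b=groups_b)


def igraph_graph(n, edges, weights):
    import igraph
    g = igraph.Graph(n=n, edges=edges)
    g.es["weight"] = weights if weights else []
    return g


def iterate_integration(X: np.ndarray, Y: np.ndarray, labels_x, labels_y,
                        n_dims: int = 10, seed: int = 0, max_rounds: int = 4,
                        min_x: int = 30, min_y: int = 100,
                        co_cluster_resolution: float = 1.0) -> pd.DataFrame:
    """Recursive integration of two datasets into a final cluster map.

    Each round co-embeds the current group's cells (CCA), co-clusters the
    joint embedding (Leiden), biclusters the overlap-score matrix, and
    recurses into each integration group until a stop criterion: one group
    only, a single cluster on either side, fewer than ``min_x`` X cells or
    ``min_y`` Y cells.  Returns a table mapping each X cluster to matched Y
    clusters with the final group id.
    """
    labels_x = np.asarray(labels_x); labels_y = np.asarray(labels_y)
    result = []
    stack = [(np.arange(len(X)), np.arange(len(Y)), "g")]
    while stack:
        ix, iy, tag = stack.pop()
        cx = np.unique(labels_x[ix]); cy = np.unique(labels_y[iy])
        def emit():
            for a in cx:
                for b in cy:
                    result.append({"group": tag, "cluster_x": a, "cluster_y": b})
        if len(cx) <= 1 or len(cy) <= 1 or len(ix) < min_x or len(iy) < min_y:
            emit()
            continue
        emb_x, emb_y = downsampled_cca(X[ix], Y[iy], n_dims=min(
            n_dims, min(len(ix), len(iy)) - 1), seed=seed)
        anchors = find_anchors(emb_x, emb_y)
        if len(anchors) == 0:
            emit()
            continue
        corrected = correct_embedding(emb_y.coords, emb_x.coords, anchors)
        joint = np.vstack([emb_x.coords, corrected])
        co = leiden_once(knn_graph(joint, k=15), co_cluster_resolution, seed)
        cmap = overlap_score_map(labels_x[ix], labels_y[iy],
                                 co[: len(ix)], co[len(ix):], seed=seed)
        groups = sorted(set(cmap.groups_a.values()) | set(cmap.groups_b.values()))
        if len(groups) <= 1 or tag.count(".") + 1 >= max_rounds:
            for a in cx:
                for b in cy:
                    if cmap.groups_a[a] == cmap.groups_b[b]:
                        result.append({"group": f"{tag}.{cmap.groups_a[a]}",
                                       "cluster_x": a, "cluster_y": b})
            continue
        for gid in groups:
            ga = [c for c in cx if cmap.groups_a.get(c) == gid]
            gb = [c for c in cy if cmap.groups_b.get(c) == gid]
            if not ga or not gb:
                continue
            sx = ix[np.isin(labels_x[ix], ga)]
            sy = iy[np.isin(labels_y[iy], gb)]
            stack.append((sx, sy, f"{tag}.{gid}"))
    return pd.DataFrame(result)


# ------------------------------------------------------------- diagnostics

def alignment_score(embedding: np.ndarray, dataset_labels, regions=None,
                    k_frac: float = 0.01, k_min: int = 20) -> pd.Series:
    """Cross-dataset mixing score per region after integration.

    With ``k = max(k_min, k_frac x region size)``, the mean number of
    same-dataset cells among each cell's k nearest neighbours (x_bar) is
    rescaled as ``1 - (x_bar - k/N) / (k - k/N)`` for N datasets: 1 for
    perfect mixing, 0 for full separation.
    """
    dataset_labels = np.asarray(dataset_labels)
    if regions is None:
        regions = np.zeros(len(embedding), dtype=int)
    regions = np.asarray(regions)
    n_datasets = len(np.unique(dataset_labels))
    out = {}
    for r in np.unique(regions):
        m = regions == r
        emb, ds = embedding[m], dataset_labels[m]
        k = max(k_min, int(round(k_frac * m.sum())))
        k = min(k, m.sum() - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
        _, idx = nn.kneighbors(emb)
        same = (ds[idx[:, 1:]] == ds[:, None]).sum(axis=1)
        xbar = same.mean()
        expected = k / n_datasets
        out[r] = float(1 - (xbar - expected) / (k - expected))
    return pd.Series(out, name="alignment_score")


MERFISH_FILTERS = {"volume": (30.0, 2000.0), "total_count": (10.0, 4000.0),
                   "density": (0.05, 5.0), "min_genes": 3, "max_blanks": 5}


def filter_merfish_cells(cells: pd.DataFrame) -> pd.Series:
    """QC mask for imaging-based cells.

    Rejects cells with volume outside (30, 2000) um^3, total counts outside
    (10, 4000), count/volume density outside (0.05, 5), fewer than 3 genes
    detected, or more than 5 blank (negative-control) probes.
    """
    for col in ("volume", "total_count", "n_genes", "n_blanks"):
        if col not in cells.columns:
            raise ValueError(f"missing column {col!r}")
    f = MERFISH_FILTERS
    density = cells["total_count"] / cells["volume"]
    mask = (
        (cells["volume"] > f["volume"][0]) & (cells["volume"] < f["volume"][1])
        & (cells["total_count"] > f["total_count"][0])
        & (cells["total_count"] < f["total_count"][1])
        & (density > f["density"][0]) & (density < f["density"][1])
        & (cells["n_genes"] >= f["min_genes"])
        & (cells["n_blanks"] <= f["max_blanks"])
    )
    return mask


def impute_spatial_location(query_embedding: np.ndarray,
                            ref_embedding: np.ndarray,
                            ref_xy: np.ndarray, k: int = 10) -> np.ndarray:
    """Assign each query cell the centroid of its k nearest reference
    (imaged) cells' spatial coordinates in the joint embedding."""
    if len(ref_embedding) < k:
        warnings.warn(f"only {len(ref_embedding)} reference cells; using all")
        k = len(ref_embedding)
    nn = NearestNeighbors(n_neighbors=k).fit(ref_embedding)
    _, idx = nn.kneighbors(query_embedding)
    return ref_xy[idx].mean(axis=1)
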