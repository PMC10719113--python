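"""Contact-map imputation and the three chromatin-conformation analyses:
A/B compartments, domain boundaries, and highly variable interactions — each
linked to methylation through a within-sample shuffle permutation null.

Imputation follows the single-cell Hi-C lineage: Gaussian convolution
(pad = 1) then random walk with restart on the row-normalized contact graph.
Compartment scores come from one PCA fitted jointly (incrementally) across
all groups on distance-normalized correlation matrices, signed so CpG-rich
bins are positive (A).  Boundaries are called per cell with the TopDom
window statistic and compared across groups with a chi-square test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from sklearn.decomposition import IncrementalPCA
from statsmodels.stats.multitest import multipletests

__all__ = [
    "gaussian_convolve", "impute_cell_contacts", "compartment_scores",
    "call_boundaries_topdom", "differential_boundaries",
    "highly_variable_interactions", "quantile_normalize",
    "shuffle_null_correlation", "correlate_boundaries_with_mch",
    "correlate_interactions_with_mch", "group_transcripts", "CompartmentTrack",
]


# --------------------------------------------------------------- imputation

def gaussian_convolve(mat: np.ndarray, pad: int = 1) -> np.ndarray:
    """Gaussian convolution with kernel half-width ``pad`` (sigma = 1)."""
    return ndimage.gaussian_filter(mat.astype(float), sigma=1,
                                   truncate=float(pad), mode="constant")


def _row_normalize(mat: np.ndarray) -> np.ndarray:
    rs = mat.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(rs > 0, mat / rs, 0.0)
    return out


def impute_cell_contacts(raw, restart_prob: float = 0.5, pad: int = 1,
                         band_bins: int | None = None, tol: float = 1e-6,
                         max_iter: int = 1000) -> np.ndarray:
    """Impute a single cell's contact matrix.

    Convolve, row-normalize into a walk matrix W, then iterate the random
    walk with restart ``R <- (1 - a) R W + a W`` from ``R0 = W`` until
    convergence (so ``restart_prob = 1`` returns the convolved, row-
    normalized matrix unchanged).  The result is masked to ``band_bins`` off
    the diagonal when given, row-sum-normalized and symmetrized.
    """
    mat = np.asarray(raw.todense() if hasattr(raw, "todense") else raw,
                     dtype=float)
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise ValueError("input contact matrix must be symmetric")
    if mat.sum() == 0:
        warnings.warn("empty contact matrix; returning zeros")
        return np.zeros_like(mat)
    conv = gaussian_convolve(mat, pad=pad)
    W = _row_normalize(conv)
    a = restart_prob
    R = W.copy()
    for _ in range(max_iter):
        R_new = (1 - a) * (R @ W) + a * W
        if np.max(np.abs(R_new - R)) < tol:
            R = R_new
            break
        R = R_new
    if band_bins is not None:
        n = len(R)
        i, j = np.indices((n, n))
        R = np.where(np.abs(i - j) <= band_bins, R, 0.0)
    R = _row_normalize(R)
    R = (R + R.T) / 2.0
    return R


# ------------------------------------------------------------- compartments

@dataclass
class CompartmentTrack:
    scores: pd.DataFrame      # groups x bins (NaN outside retained bins)
    retained: np.ndarray      # bool mask over bins
    component: int            # 1 or 2: which PC became the score
    cpg_corr: float           # correlation of the signed score with CpG density


def _distance_normalize(mat: np.ndarray) -> np.ndarray:
    n = len(mat)
    out = mat.astype(float).copy()
    for d in range(n):
        diag = np.diagonal(mat, d)
        m = diag.mean()
        if m > 0:
            idx = np.arange(n - d)
            out[idx, idx + d] = diag / m
            out[idx + d, idx] = diag / m
    return out


def retained_bins(maps, blacklist_mask=None) -> np.ndarray:
    """Bins kept for compartment analysis: not blacklisted, and per-group
    coverage (row sum R) between ``2*median(R) - q99`` and ``q99``."""
    n = len(maps[0])
    keep = np.ones(n, dtype=bool)
    if blacklist_mask is not None:
        keep &= ~np.asarray(blacklist_mask)
    for m in maps:
        R = np.asarray(m).sum(axis=1)
        q99 = np.quantile(R, 0.99)
        lo = 2 * np.median(R) - q99
        keep &= (R >= lo) & (R <= q99) & (R > 0)
    return keep


def compartment_scores(maps, cpg_density, blacklist_mask=None,
                       min_bins: int = 10) -> CompartmentTrack:
    """Signed compartment score per group per 100-kb bin.

    Each group's map is distance-normalized; its bin-bin Pearson correlation
    matrix feeds one PCA fitted incrementally across all groups, and every
    group is transformed with the shared loadings.  The score is PC1 or PC2,
    whichever correlates more with CpG density, signed so CpG-rich (A
    compartment) bins are positive.
    """
    if len(maps) < 2:
        raise ValueError("need at least two groups")
    cpg = np.asarray(cpg_density, dtype=float)
    keep = retained_bins(maps, blacklist_mask)
    if keep.sum() < min_bins:
        raise ValueError("fewer than min_bins retained bins")
    corr_mats = []
    for m in maps:
        norm = _distance_normalize(np.asarray(m, dtype=float))[np.ix_(keep, keep)]
        with np.errstate(invalid="ignore"):
            c = np.corrcoef(norm)
        corr_mats.append(np.nan_to_num(c))

    ipca = IncrementalPCA(n_components=2)
    for c in corr_mats:
        ipca.partial_fit(c)
    pcs = [ipca.transform(c) for c in corr_mats]      # retained bins x 2

    ck = cpg[keep]
    pooled = np.concatenate([p for p in pcs], axis=0)
    cpg_rep = np.tile(ck, len(pcs))
    corrs = [np.corrcoef(pooled[:, d], cpg_rep)[0, 1] for d in range(2)]
    comp = int(np.argmax(np.abs(corrs)))
    sign = 1.0 if corrs[comp] >= 0 else -1.0

    n = len(maps[0])
    rows = []
    for p in pcs:
        row = np.full(n, np.nan)
        row[keep] = sign * p[:, comp]
        rows.append(row)
    scores = pd.DataFrame(rows, index=[f"group{i}" for i in range(len(maps))])
    return CompartmentTrack(scores=scores, retained=keep, component=comp + 1,
                            cpg_corr=float(sign * corrs[comp]))


# --------------------------------------------------------------- boundaries

def call_boundaries_topdom(mat: np.ndarray, w: int = 5, p_cut: float = 0.05,
                           blacklist_mask=None) -> np.ndarray:
    """TopDom-style domain boundary bins of one (imputed) matrix.

    binSignal_i is the mean contact between the w bins upstream and the w
    bins downstream of the boundary after bin i; local minima that pass a
    one-sided rank-sum test (cross-boundary contacts lower than within-flank
    contacts) are returned.
    """
    mat = np.asarray(mat, dtype=float)
    n = len(mat)
    if n < 2 * w + 1:
        return np.array([], dtype=int)
    signal = np.full(n, np.nan)
    for i in range(w - 1, n - w):
        U = slice(i - w + 1, i + 1)
        D = slice(i + 1, i + w + 1)
        signal[i] = mat[U, D].mean()

    bounds = []
    for i in range(w, n - w - 1):
        if not (signal[i] < signal[i - 1] and signal[i] < signal[i + 1]):
            continue
        U = np.arange(i - w + 1, i + 1)
        D = np.arange(i + 1, i + w + 1)
        across = mat[np.ix_(U, D)].ravel()
        wu = mat[np.ix_(U, U)][np.triu_indices(w, 1)]
        wd = mat[np.ix_(D, D)][np.triu_indices(w, 1)]
        within = np.concatenate([wu, wd])
        if across.std() == 0 and within.std() == 0:
            continue
        p = stats.mannwhitneyu(across, within, alternative="less").pvalue
        if p < p_cut:
            bounds.append(i)
    bounds = np.array(bounds, dtype=int)
    if blacklist_mask is not None and len(bounds):
        bounds = bounds[~np.asarray(blacklist_mask)[bounds]]
    return bounds


def differential_boundaries(calls: np.ndarray, groups,
                            fdr_cut: float = 1e-3) -> pd.DataFrame:
    """Chi-square test of boundary frequency across groups per bin.

    ``calls``: boolean cells x bins matrix of per-cell boundary calls.
    Returns per-bin statistic, p, FDR, differential flag and per-group
    boundary probabilities.
    """
    calls = np.asarray(calls, dtype=bool)
    groups = np.asarray(groups)
    gs = np.unique(groups)
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    n_bins = calls.shape[1]
    yes = np.stack([calls[groups == g].sum(axis=0) for g in gs])
    tot = np.array([(groups == g).sum() for g in gs])[:, None]
    no = tot - yes

    chi2 = np.zeros(n_bins)
    pvals = np.ones(n_bins)
    called = yes.sum(axis=0) > 0
    for j in np.where(called)[0]:
        tbl = np.stack([yes[:, j], no[:, j]], axis=1)
        if (tbl.sum(axis=1) == 0).any() or tbl[:, 0].sum() == 0 or \
                tbl[:, 1].sum() == 0:
            continue
        chi2[j], pvals[j], _, _ = stats.chi2_contingency(tbl, correction=False)
    fdr = multipletests(pvals, method="fdr_bh")[1]
    out = pd.DataFrame({"chi2": chi2, "p": pvals, "fdr": fdr,
                        "differential": fdr < fdr_cut})
    for gi, g in enumerate(gs):
        out[f"prob_{g}"] = yes[gi] / tot[gi, 0]
    return out


# ------------------------------------------------- variable interactions

def highly_variable_interactions(pixel_strengths: np.ndarray, groups,
                                 pixels: np.ndarray, resolution: int,
                                 min_dist: int = 50_000, max_dist: int = 5_000_000,
                                 f_cut: float = 3.0, fdr_cut: float = 1e-3,
                                 blacklist_mask=None, log_scale: bool = False
                                 ) -> pd.DataFrame:
    """One-way ANOVA of per-cell pixel strengths across groups.

    ``pixel_strengths``: cells x pixels (imputed, continuous);
    ``pixels``: (n_pixels, 2) bin indices.  Pixels outside the
    [min_dist, max_dist] anchor-distance window or with a blacklisted anchor
    are dropped; retained (highly variable) pixels satisfy both F > ``f_cut``
    and FDR < ``fdr_cut``.
    """
    X = np.asarray(pixel_strengths, dtype=float)
    if log_scale:
        X = np.log1p(X)
    groups = np.asarray(groups)
    pixels = np.asarray(pixels)
    dist = np.abs(pixels[:, 1] - pixels[:, 0]) * resolution
    keep = (dist >= min_dist) & (dist <= max_dist)
    if blacklist_mask is not None:
        bl = np.asarray(blacklist_mask)
        keep &= ~(bl[pixels[:, 0]] | bl[pixels[:, 1]])
    idx = np.where(keep)[0]

    gs = [g for g in np.unique(groups) if (groups == g).sum() >= 2]
    if len(gs) < 2:
        raise ValueError("need >=2 groups with >=2 cells")
    sub = [X[groups == g][:, idx] for g in gs]
    ns = np.array([s.shape[0] for s in sub])
    grand = np.vstack(sub).mean(axis=0)
    means = np.stack([s.mean(axis=0) for s in sub])
    ss_between = (ns[:, None] * (means - grand) ** 2).sum(axis=0)
    ss_within = np.stack([((s - m) ** 2).sum(axis=0)
                          for s, m in zip(sub, means)]).sum(axis=0)
    df_b = len(gs) - 1
    df_w = ns.sum() - len(gs)
    with np.errstate(invalid="ignore", divide="ignore"):
        F = (ss_between / df_b) / np.maximum(ss_within / df_w, 1e-300)
    pvals = stats.f.sf(F, df_b, df_w)
    fdr = multipletests(pvals, method="fdr_bh")[1]
    out = pd.DataFrame({
        "bin1": pixels[idx, 0], "bin2": pixels[idx, 1],
        "distance": dist[idx], "F": F, "p": pvals, "fdr": fdr,
        "variable": (F > f_cut) & (fdr < fdr_cut),
    })
    # deterministic ordering: F desc then distance asc
    return out.sort_values(["F", "distance"], ascending=[False, True],
                           ignore_index=True)


# --------------------------------------------- shuffle permutation null

def quantile_normalize(M: np.ndarray) -> np.ndarray:
    """Force every sample (row) to the common average distribution."""
    M = np.asarray(M, dtype=float)
    order = np.argsort(M, axis=1)
    ref = np.sort(M, axis=1).mean(axis=0)
    out = np.empty_like(M)
    for i, o in enumerate(order):
        out[i, o] = ref
    return out


def _pair_pcc(A, B, pairs):
    a = A[:, pairs[:, 0]]
    b = B[:, pairs[:, 1]]
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    denom = np.sqrt((ac ** 2).sum(axis=0) * (bc ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, (ac * bc).sum(axis=0) / denom, np.nan)


def shuffle_null_correlation(A: np.ndarray, B: np.ndarray, pairs,
                             n_perm: int = 100_000, seed: int = 0,
                             fdr_cut: float = 1e-3,
                             normalize: bool = True) -> pd.DataFrame:
    """Pearson correlations across samples with a within-sample shuffle null.

    Both matrices (samples x items) are quantile-normalized along samples;
    the null permutes item values independently within each sample —
    preserving sample-level distributions while destroying the item
    correspondence — and the pooled null PCCs (at least ``n_perm`` of them)
    are summarized by a Gaussian for tail P values, then BH-corrected.
    Pairs with a constant vector are flagged and skipped.
    """
    A = np.asarray(A, float); B = np.asarray(B, float)
    pairs = np.asarray(pairs)
    if normalize:       # a single-item matrix cannot be quantile-normalized
        if A.shape[1] > 1:
            A = quantile_normalize(A)
        if B.shape[1] > 1:
            B = quantile_normalize(B)
    obs = _pair_pcc(A, B, pairs)
    valid = np.isfinite(obs)

    rng = np.random.default_rng(seed)
    n_pairs = max(int(valid.sum()), 1)
    n_shuffles = max(int(np.ceil(n_perm / n_pairs)), 1)
    null = []
    for _ in range(n_shuffles):
        As = np.stack([rng.permutation(row) for row in A])
        Bs = np.stack([rng.permutation(row) for row in B])
        null.append(_pair_pcc(As, Bs, pairs))
    null = np.concatenate(null)
    null = null[np.isfinite(null)]
    mu = null.mean() if len(null) else 0.0
    sd = max(null.std(), 1e-12) if len(null) else 1.0
    z = (obs - mu) / sd
    pvals = 2 * stats.norm.sf(np.abs(z))
    fdr = np.full_like(pvals, np.nan)
    if valid.any():
        fdr[valid] = multipletests(pvals[valid], method="fdr_bh")[1]
    return pd.DataFrame({
        "item_a": pairs[:, 0], "item_b": pairs[:, 1], "pcc": obs,
        "p": np.where(valid, pvals, np.nan), "fdr": fdr,
        "significant": np.where(valid, fdr < fdr_cut, False).astype(bool),
        "skipped": ~valid,
    })


# ----------------------------------------------- methylation correlations

def group_transcripts(transcripts: pd.DataFrame, min_overlap: float = 0.9
                      ) -> pd.DataFrame:
    """Collapse transcripts of a gene whose spans reciprocally overlap by
    more than ``min_overlap``; the group takes the longest (union) range."""
    out = []
    for gene, sub in transcripts.groupby("gene_id"):
        sub = sub.sort_values("start").reset_index(drop=True)
        used = np.zeros(len(sub), dtype=bool)
        for i in range(len(sub)):
            if used[i]:
                continue
            members = [i]
            for j in range(i + 1, len(sub)):
                if used[j]:
                    continue
                s = max(sub.start[i], sub.start[j])
                e = min(sub.end[i], sub.end[j])
                ov = max(0, e - s)
                li = sub.end[i] - sub.start[i]
                lj = sub.end[j] - sub.start[j]
                if ov > min_overlap * li and ov > min_overlap * lj:
                    members.append(j)
                    used[j] = True
            used[i] = True
            rows = sub.iloc[members]
            out.append({"gene_id": gene,
                        "transcript_id": rows.transcript_id.iloc[0],
                        "start": int(rows.start.min()),
                        "end": int(rows.end.max()),
                        "strand": rows.strand.iloc[0],
                        "n_members": len(members)})
    df = pd.DataFrame(out)
    df["length"] = df["end"] - df["start"]
    df["length_class"] = np.where(df["length"] < 100_000, "short", "long")
    return df


def correlate_boundaries_with_mch(boundary_prob: np.ndarray,
                                  transcript_mc: np.ndarray,
                                  transcripts: pd.DataFrame,
                                  bin_size: int = 25_000,
                                  window: int = 2_000_000,
                                  n_perm: int = 100_000, seed: int = 0,
                                  fdr_cut: float = 1e-3,
                                  normalize: bool = True):
    """Correlate each transcript's body mC with boundary probabilities of
    bins within transcript +/- ``window``.

    Returns (pair table from :func:`shuffle_null_correlation` with transcript
    and bin columns, per-transcript summary of the most negative / positive
    significant bins relative to TSS and TTS).
    """
    n_bins = boundary_prob.shape[1]
    pairs = []
    for t, row in enumerate(transcripts.itertuples()):
        lo = max(0, (row.start - window) // bin_size)
        hi = min(n_bins, (row.end + window) // bin_size + 1)
        for b in range(lo, hi):
            pairs.append((t, b))
    if not pairs:
        return pd.DataFrame(), pd.DataFrame()
    res = shuffle_null_correlation(transcript_mc, boundary_prob,
                                   np.array(pairs), n_perm=n_perm, seed=seed,
                                   fdr_cut=fdr_cut, normalize=normalize)
    res = res.rename(columns={"item_a": "transcript", "item_b": "bin"})
    summaries = []
    for t, sub in res[res["significant"]].groupby("transcript"):
        row = transcripts.iloc[int(t)]
        tss = row.start if row.strand == "+" else row.end
        tts = row.end if row.strand == "+" else row.start
        neg = sub.loc[sub["pcc"].idxmin()]
        pos = sub.loc[sub["pcc"].idxmax()]
        summaries.append({
            "transcript": int(t), "gene_id": row.gene_id,
            "top_neg_bin": int(neg["bin"]), "top_neg_pcc": neg["pcc"],
            "top_neg_dist_tss": int(neg["bin"]) * bin_size - tss,
            "top_neg_dist_tts": int(neg["bin"]) * bin_size - tts,
            "top_pos_bin": int(pos["bin"]), "top_pos_pcc": pos["pcc"],
            "top_pos_dist_tss": int(pos["bin"]) * bin_size - tss,
        })
    return res, pd.DataFrame(summaries)


INTERACTION_CLASSES = ("intragenic", "upstream", "downstream",
                       "upstream-intragenic", "downstream-intragenic",
                       "upstream-downstream")


def _anchor_side(pos, start, end, strand):
    if start <= pos < end:
        return "I"
    before = pos < start
    if strand == "+":
        return "U" if before else "D"
    return "D" if before else "U"


_CLASS_MAP = {frozenset("I"): "intragenic", frozenset("U"): "upstream",
              frozenset("D"): "downstream",
              frozenset("UI"): "upstream-intragenic",
              frozenset("DI"): "downstream-intragenic",
              frozenset("UD"): "upstream-downstream"}


def correlate_interactions_with_mch(hvi: pd.DataFrame,
                                    pixel_strengths: np.ndarray,
                                    transcript_mc: np.ndarray,
                                    transcripts: pd.DataFrame,
                                    resolution: int,
                                    window: int = 5_000_000,
                                    n_perm: int = 100_000, seed: int = 0,
                                    fdr_cut: float = 1e-3,
                                    require_anchor_overlap: bool = True,
                                    normalize: bool = True) -> pd.DataFrame:
    """Correlate gene body mCH with the strengths of highly variable
    interactions whose anchors overlap the gene, and classify each
    significant interaction by its anchor locations (intragenic / upstream /
    downstream combinations, strand-aware).

    ``pixel_strengths`` is samples x rows-of-``hvi``.
    """
    pairs, meta = [], []
    for t, row in enumerate(transcripts.itertuples()):
        for pi, h in enumerate(hvi.itertuples()):
            a1 = (h.bin1 * resolution, (h.bin1 + 1) * resolution)
            a2 = (h.bin2 * resolution, (h.bin2 + 1) * resolution)
            in1 = a1[0] < row.end and a1[1] > row.start
            in2 = a2[0] < row.end and a2[1] > row.start
            span = abs((h.bin1 + h.bin2) / 2 * resolution -
                       (row.start + row.end) / 2)
            if (in1 or in2 or not require_anchor_overlap) and span <= window:
                pairs.append((t, pi))
                s1 = "I" if in1 else _anchor_side(a1[0], row.start, row.end,
                                                  row.strand)
                s2 = "I" if in2 else _anchor_side(a2[0], row.start, row.end,
                                                  row.strand)
                meta.append(_CLASS_MAP[frozenset(s1 + s2)])
    if not pairs:
        return pd.DataFrame()
    res = shuffle_null_correlation(transcript_mc, pixel_strengths,
                                   np.array(pairs), n_perm=n_perm, seed=seed,
                                   fdr_cut=fdr_cut, normalize=normalize)
    res = res.rename(columns={"item_a": "transcript", "item_b": "interaction"})
    res["location_class"] = meta
    res["gene_id"] = transcripts["gene_id"].to_numpy()[res["transcript"]]
    return res
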