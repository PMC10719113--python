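"""Intragenic prediction of transcript expression and exon inclusion.

Per gene, intragenic methylation features (exon bodies, +/-300-bp exon
flanks, intragenic DMRs) or chromatin-interaction features (intragenic
highly variable loop strengths) predict transcript TPM and exon PSI across
cell groups with cross-validated random forests.  Predictability specific to
the intragenic feature identity is quantified as dPCC = PCC(true features) -
PCC(within-sample-shuffled features).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.feature_selection import f_regression
from sklearn.model_selection import KFold

__all__ = ["compute_psi", "build_features", "select_and_fit",
           "shuffled_control", "PredictionResult",
           "hv_transcripts", "hv_exons"]


# --------------------------------------------------------------------- PSI

def compute_psi(tpm: pd.DataFrame, genes: list) -> pd.DataFrame:
    """Exon percent-spliced-in from transcript TPMs.

    ``PSI(exon) = sum TPM of transcripts containing the exon / sum TPM of all
    the gene's transcripts``; NaN where the denominator is 0.  ``genes`` are
    dicts with ``gene_id`` and ``transcripts`` (tx -> exon interval list);
    exon ids are ``gene.e<i>`` over the gene's sorted unique exons.
    """
    cols = {}
    for g in genes:
        txs = list(g["transcripts"])
        missing = [t for t in txs if t not in tpm.columns]
        if missing:
            raise ValueError(f"transcript {missing[0]} absent from TPM table")
        total = tpm[txs].sum(axis=1)
        exons = sorted({e for tx in g["transcripts"].values() for e in tx})
        for ei, exon in enumerate(exons):
            has = [t for t in txs if exon in g["transcripts"][t]]
            num = tpm[has].sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                psi = np.where(total > 0, num / total, np.nan)
            cols[f"{g['gene_id']}.e{ei}"] = psi
    return pd.DataFrame(cols, index=tpm.index)


# --------------------------------------------------------- target selection

def hv_transcripts(tpm: pd.DataFrame, lengths: dict,
                   min_mean: float = 0.2, min_sd: float = 0.3,
                   min_length: int = 30_000) -> list:
    """Highly variable transcripts: mean TPM > 0.2, s.d. > 0.3, body > 30 kb."""
    keep = []
    for t in tpm.columns:
        if tpm[t].mean() > min_mean and tpm[t].std() > min_sd \
                and lengths.get(t, 0) > min_length:
            keep.append(t)
    return keep


def hv_exons(psi: pd.DataFrame, min_sd: float = 0.02,
             min_q_range: float = 0.05) -> list:
    """Highly variable exons: PSI s.d. > 0.02 and (q90 - q10) > 0.05."""
    keep = []
    for e in psi.columns:
        v = psi[e].dropna()
        if len(v) and v.std() > min_sd and \
                (v.quantile(0.9) - v.quantile(0.1)) > min_q_range:
            keep.append(e)
    return keep


# ----------------------------------------------------------------- features

def build_features(gene_id: str, feature_table: pd.DataFrame,
                   feature_matrix: np.ndarray,
                   var_cut: float = 0.01, overlap_frac: float = 0.9):
    """Assemble one gene's intragenic feature matrix.

    ``feature_table`` rows (gene_id, kind, start, end) index columns of
    ``feature_matrix`` (groups x features).  Features with variance below
    ``var_cut`` are removed; features whose intervals reciprocally overlap by
    more than ``overlap_frac`` are combined by mean.  Returns (matrix,
    metadata DataFrame); raises ``ValueError`` when nothing survives.
    """
    idx = np.where(feature_table["gene_id"].to_numpy() == gene_id)[0]
    if len(idx) == 0:
        raise ValueError(f"gene {gene_id} has no features")
    meta = feature_table.iloc[idx].reset_index(drop=True)
    X = feature_matrix[:, idx]
    keep = X.var(axis=0) >= var_cut
    meta, X = meta[keep].reset_index(drop=True), X[:, keep]
    if X.shape[1] == 0:
        raise ValueError(f"gene {gene_id}: all features removed")

    # combine reciprocally overlapping intervals (union-find by sweep)
    order = np.argsort(meta["start"].to_numpy())
    groups, assigned = [], np.full(X.shape[1], -1)
    for oi in order:
        s, e = meta.loc[oi, "start"], meta.loc[oi, "end"]
        placed = False
        for gi, members in enumerate(groups):
            m0 = members[0]
            s0, e0 = meta.loc[m0, "start"], meta.loc[m0, "end"]
            ov = max(0, min(e, e0) - max(s, s0))
            if ov > overlap_frac * (e - s) and ov > overlap_frac * (e0 - s0):
                members.append(oi)
                assigned[oi] = gi
                placed = True
                break
        if not placed:
            assigned[oi] = len(groups)
            groups.append([oi])
    out_cols, out_meta = [], []
    for members in groups:
        out_cols.append(X[:, members].mean(axis=1))
        row = meta.loc[members[0]].copy()
        row["n_combined"] = len(members)
        out_meta.append(row)
    return np.column_stack(out_cols), pd.DataFrame(out_meta).reset_index(drop=True)


# --------------------------------------------------------------- model fit

@dataclass
class PredictionResult:
    pcc: pd.Series                 # per target
    predictions: pd.DataFrame      # out-of-fold predictions
    selected: dict                 # fold -> feature index array


def _pcc(a, b):
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3 or np.std(a[ok]) == 0 or np.std(b[ok]) == 0:
        return np.nan
    return float(stats.pearsonr(a[ok], b[ok])[0])


def select_and_fit(features: np.ndarray, targets: pd.DataFrame,
                   k_top: int = 100, folds: int = 5, seed: int = 0,
                   n_trees: int = 300, min_groups: int = 20,
                   nested: bool = True) -> PredictionResult:
    """Cross-validated random-forest prediction of the gene's targets.

    Univariate F-regression ranks features per target; the union of top-
    ``k_top`` sets over the gene's targets is used to fit one forest per
    target under ``folds``-fold CV (selection nested inside each training
    fold by default, leak-free).  PCC is between out-of-fold predictions and
    the observed values.
    """
    n = features.shape[0]
    if n < min_groups:
        raise ValueError(f"need >= {min_groups} cell groups, got {n}")
    targets = targets.copy()
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    preds = pd.DataFrame(np.nan, index=targets.index, columns=targets.columns)
    selected = {}

    def select(X, Y):
        union = set()
        for t in Y.columns:
            y = Y[t].to_numpy()
            ok = np.isfinite(y)
            if ok.sum() < 3:
                continue
            F, _ = f_regression(X[ok], y[ok])
            F = np.nan_to_num(F)
            k = min(k_top, X.shape[1])
            union.update(np.argsort(F)[::-1][:k].tolist())
        return np.array(sorted(union), dtype=int)

    if not nested:
        global_sel = select(features, targets)
    for fi, (tr, te) in enumerate(kf.split(features)):
        sel = select(features[tr], targets.iloc[tr]) if nested else global_sel
        selected[fi] = sel
        for t in targets.columns:
            y = targets[t].to_numpy()
            ok_tr = tr[np.isfinite(y[tr])]
            if len(ok_tr) < 3 or len(sel) == 0:
                continue
            rf = RandomForestRegressor(n_estimators=n_trees,
                                       random_state=seed)
            rf.fit(features[np.ix_(ok_tr, sel)], y[ok_tr])
            preds.loc[targets.index[te], t] = rf.predict(features[np.ix_(te, sel)])
    pcc = pd.Series({t: _pcc(preds[t].to_numpy(), targets[t].to_numpy())
                     for t in targets.columns}, name="pcc")
    return PredictionResult(pcc=pcc, predictions=preds, selected=selected)


def shuffled_control(features: np.ndarray, targets: pd.DataFrame,
                     k_top: int = 100, folds: int = 5, seed: int = 0,
                     n_trees: int = 300, nested: bool = True):
    """Within-sample feature shuffle control and dPCC.

    Feature values are permuted within each sample (cell group) —
    destroying which feature carries which value while preserving the
    group-level value distribution — then the identical selection/fit runs.
    Returns (true result, shuffled result, dPCC Series).
    """
    true = select_and_fit(features, targets, k_top=k_top, folds=folds,
                          seed=seed, n_trees=n_trees, nested=nested)
    rng = np.random.default_rng(seed)
    shuffled = np.stack([rng.permutation(row) for row in features])
    sh = select_and_fit(shuffled, targets, k_top=k_top, folds=folds,
                        seed=seed, n_trees=n_trees, nested=nested)
    delta = (true.pcc - sh.pcc).rename("delta_pcc")
    return true, sh, delta
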