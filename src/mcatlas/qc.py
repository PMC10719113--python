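"""Cell-level quality control.

``filter_cells`` applies the primary methylome QC thresholds (bisulfite
non-conversion proxy mCCC, global mCH/mCG, read depth, mapping rate, and for
joint methylome+3C cells the cis-long-range contact count).  ``pncc_test``
screens pre-clusters with the plate-normalized cell coverage statistic
against a composition-stratified permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = ["filter_cells", "pncc_test", "PNCCResult", "QC_THRESHOLDS"]

# strict inequalities throughout
QC_THRESHOLDS = {
    "mccc_max": 0.05,
    "mch_max": 0.2,
    "mcg_min": 0.5,
    "reads_min": 500_000,
    "reads_max": 10_000_000,
    "mapping_rate_min": 0.5,
    "cis_long_min": 50_000,   # m3C modality only
}

_REQUIRED = ["mCCC", "mCH", "mCG", "final_reads", "mapping_rate"]


def filter_cells(records: pd.DataFrame, modality: str = "mC") -> pd.Series:
    """Boolean pass mask for primary QC.

    ``records`` needs columns mCCC, mCH, mCG, final_reads, mapping_rate and,
    for ``modality='m3C'``, cis_long_contacts (contact anchors >2,500 bp
    apart).  All comparisons are strict.
    """
    if modality not in {"mC", "m3C"}:
        raise ValueError(f"unknown modality {modality!r}")
    required = list(_REQUIRED)
    if modality == "m3C":
        required.append("cis_long_contacts")
    for col in required:
        if col not in records.columns:
            raise ValueError(f"missing QC field {col!r}")
        bad = records.index[records[col].isna()]
        if len(bad):
            raise ValueError(f"missing {col!r} for cell {bad[0]!r}")
    t = QC_THRESHOLDS
    mask = (
        (records["mCCC"] < t["mccc_max"])
        & (records["mCH"] < t["mch_max"])
        & (records["mCG"] > t["mcg_min"])
        & (records["final_reads"] > t["reads_min"])
        & (records["final_reads"] < t["reads_max"])
        & (records["mapping_rate"] > t["mapping_rate_min"])
    )
    if modality == "m3C":
        mask &= records["cis_long_contacts"] > t["cis_long_min"]
    return mask


@dataclass
class PNCCResult:
    pncc: pd.Series              # per cell
    table: pd.DataFrame          # per pre-cluster: mean, sd, p_mean, p_sd,
    #                              fdr_mean, fdr_sd, flagged


def _plate_normalize(reads: pd.Series, plates: pd.Series) -> pd.Series:
    plate_mean = reads.groupby(plates).transform("mean")
    singles = plates.map(plates.value_counts()) == 1
    if singles.any():
        warnings.warn(f"{int(singles.sum())} plate(s) with a single cell; "
                      "their PNCC is 1 by construction")
    return reads / plate_mean


def pncc_test(reads: pd.Series, plates: pd.Series, preclusters: pd.Series,
              n_perm: int = 10_000, seed: int = 0,
              log2_cut: float = 0.8, fdr_cut: float = 0.01) -> PNCCResult:
    """Permutation test for pre-clusters with abnormal coverage.

    PNCC = cell final reads / mean final reads of its plate.  For each
    pre-cluster, a null is built by drawing ``n_perm`` random cell sets of the
    same size stratified on the cluster's plate composition; the observed PNCC
    mean is tested two-tailed and the s.d. one-tailed (larger).  A cluster is
    flagged when |log2(mean PNCC)| > ``log2_cut`` and either FDR < ``fdr_cut``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    reads = pd.Series(reads).astype(float)
    plates = pd.Series(plates).reindex(reads.index)
    preclusters = pd.Series(preclusters).reindex(reads.index)
    if plates.isna().any() or preclusters.isna().any():
        raise ValueError("every cell needs a plate and a pre-cluster label")

    pncc = _plate_normalize(reads, plates)
    rng = np.random.default_rng(seed)

    by_plate = {p: pncc[plates == p].to_numpy() for p in plates.unique()}
    rows = {}
    for cl, idx in pncc.groupby(preclusters).groups.items():
        vals = pncc.loc[idx].to_numpy()
        obs_mean, obs_sd = vals.mean(), vals.std(ddof=0)
        comp = plates.loc[idx].value_counts()
        null_mean = np.empty(n_perm)
        null_sd = np.empty(n_perm)
        draws = []
        for p, cnt in comp.items():
            pool = by_plate[p]
            picks = rng.integers(0, len(pool), size=(n_perm, cnt))
            draws.append(pool[picks])
        sample = np.concatenate(draws, axis=1)
        null_mean = sample.mean(axis=1)
        null_sd = sample.std(axis=1, ddof=0)
        p_hi = (1 + np.sum(null_mean >= obs_mean)) / (1 + n_perm)
        p_lo = (1 + np.sum(null_mean <= obs_mean)) / (1 + n_perm)
        p_mean = min(1.0, 2 * min(p_hi, p_lo))
        p_sd = (1 + np.sum(null_sd >= obs_sd)) / (1 + n_perm)
        rows[cl] = (obs_mean, obs_sd, p_mean, p_sd)

    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["mean", "sd", "p_mean", "p_sd"])
    table["fdr_mean"] = multipletests(table["p_mean"], method="fdr_bh")[1]
    table["fdr_sd"] = multipletests(table["p_sd"], method="fdr_bh")[1]
    table["log2_mean"] = np.log2(table["mean"])
    table["flagged"] = (np.abs(table["log2_mean"]) > log2_cut) & (
        (table["fdr_mean"] < fdr_cut) | (table["fdr_sd"] < fdr_cut))
    return PNCCResult(pncc=pncc, table=table)
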