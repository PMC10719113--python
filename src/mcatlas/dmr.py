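"""Differentially methylated site (DMS) and region (DMR) calling across
pseudo-bulk samples.

Coverage is first proportionally downsampled (per-sample and total caps) to
balance samples.  At each CpG unit, homogeneity of the samples x (methylated,
unmethylated) table is tested with a permutation root-mean-square statistic
(null: basecalls reassigned among samples with margins fixed).  Significant
sites chain into DMRs when neighbours are within 250 bp and their per-sample
fractions correlate (PCC > 0.3); DMR sets from multiple runs merge into
non-overlapping intervals with a strongest-value representative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = ["BaseProfile", "downsample_coverage", "rms_statistic", "call_dms",
           "merge_dms_to_dmr", "merge_overlapping_dmrs", "DMRRecord"]


@dataclass
class BaseProfile:
    """Per-sample x per-CpG-unit (mc, cov) counts on one chromosome.

    CpG pairs are assumed already combined into 2-bp units; ``positions``
    strictly increasing, 0-based."""

    chrom: str
    positions: np.ndarray          # (n_sites,)
    mc: np.ndarray                 # (n_samples, n_sites)
    cov: np.ndarray
    samples: list

    def __post_init__(self):
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.mc > self.cov):
            raise ValueError("mc exceeds cov")

    def fractions(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            f = self.mc / self.cov
        return f


@dataclass
class DMRRecord:
    chrom: str
    start: int
    end: int
    sites: np.ndarray              # member DMS positions
    sample_mc: np.ndarray          # (n_samples,) summed over member sites
    sample_cov: np.ndarray
    statistic: float
    fdr: float
    hypo_samples: np.ndarray = field(default=None)
    hyper_samples: np.ndarray = field(default=None)
    provenance: str = ""


def _proportional(mc, cov, cap):
    """Scale (mc, cov) pairs down so cov <= cap, nearest-integer rounding,
    preserving the fraction in expectation; mc <= cov guaranteed."""
    scale = np.minimum(1.0, cap / np.maximum(cov, 1))
    new_cov = np.rint(cov * scale).astype(np.int64)
    new_mc = np.minimum(np.rint(mc * scale).astype(np.int64), new_cov)
    return new_mc, new_cov


def downsample_coverage(profile: BaseProfile, per_sample_cap: int = 50,
                        total_cap: int = 3000) -> BaseProfile:
    """Deterministic proportional downsampling of basecall coverage.

    Each sample's coverage at a site is capped at ``per_sample_cap``; the
    summed coverage across samples is then capped at ``total_cap`` by a second
    proportional pass.  Fractions are preserved up to rounding.
    """
    if per_sample_cap <= 0 or total_cap <= 0:
        raise ValueError("caps must be positive")
    mc, cov = _proportional(profile.mc, profile.cov, per_sample_cap)
    total = cov.sum(axis=0)
    over = total > total_cap
    if over.any():
        factor = np.ones_like(total, dtype=float)
        factor[over] = total_cap / total[over]
        new_cov = np.rint(cov * factor).astype(np.int64)
        new_mc = np.minimum(np.rint(mc * factor).astype(np.int64), new_cov)
        mc, cov = new_mc, new_cov
    return BaseProfile(profile.chrom, profile.positions, mc, cov,
                       list(profile.samples))


def rms_statistic(mc: np.ndarray, cov: np.ndarray) -> float:
    """Root mean square of (observed - expected) over the samples x
    (methylated, unmethylated) table; expected from the pooled fraction."""
    tot = cov.sum()
    if tot == 0:
        return 0.0
    p = mc.sum() / tot
    em = cov * p
    return float(np.sqrt(np.mean(np.concatenate([(mc - em), ((cov - mc) - (cov - em))]) ** 2)))


def call_dms(profile: BaseProfile, n_perm: int = 3000, seed: int = 0,
             fdr_cut: float = 0.01) -> pd.DataFrame:
    """Permutation RMS test for differential methylation per site.

    The null reassigns the pooled methylated basecalls to samples with both
    margins fixed (multivariate hypergeometric).  Returns a DataFrame with
    position, statistic, p, fdr, significant; all-zero-coverage sites and
    sites with <2 covered samples are skipped.
    """
    rng = np.random.default_rng(seed)
    mc, cov = profile.mc, profile.cov
    n_samples, n_sites = mc.shape
    usable = (cov > 0).sum(axis=0) >= 2
    idx = np.where(usable)[0]
    stats_obs = np.array([rms_statistic(mc[:, j], cov[:, j]) for j in idx])

    exceed = np.zeros(len(idx), dtype=np.int64)
    covs = cov[:, idx]
    total_mc = mc[:, idx].sum(axis=0)
    for _ in range(n_perm):
        remaining_mc = total_mc.copy()
        remaining_cov = covs.sum(axis=0)
        perm_stat = np.zeros(len(idx))
        perm_mc = np.empty((n_samples, len(idx)), dtype=np.int64)
        for s in range(n_samples):
            cs = covs[s]
            ngood = np.maximum(remaining_mc, 0)
            nbad = np.maximum(remaining_cov - remaining_mc, 0)
            draw = np.zeros(len(idx), dtype=np.int64)
            nz = cs > 0
            if nz.any():
                draw[nz] = rng.hypergeometric(ngood[nz], nbad[nz], cs[nz])
            perm_mc[s] = draw
            remaining_mc = remaining_mc - draw
            remaining_cov = remaining_cov - cs
        # vectorized RMS over sites
        p = total_mc / np.maximum(covs.sum(axis=0), 1)
        em = covs * p
        dev = perm_mc - em
        perm_stat = np.sqrt(np.mean(np.concatenate([dev, -dev]) ** 2, axis=0))
        exceed += perm_stat >= stats_obs
    pvals = (1 + exceed) / (1 + n_perm)
    fdr = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({
        "position": profile.positions[idx],
        "site_index": idx,
        "statistic": stats_obs,
        "p": pvals,
        "fdr": fdr,
        "significant": fdr < fdr_cut,
    })


def merge_dms_to_dmr(dms: pd.DataFrame, profile: BaseProfile,
                     max_gap: int = 250, min_pcc: float = 0.3,
                     site_size: int = 2, provenance: str = "") -> list:
    """Greedy left-to-right chaining of significant DMSs into DMRs.

    Adjacent DMSs join when their gap is <= ``max_gap`` bp AND the Pearson
    correlation of their per-sample fractions exceeds ``min_pcc``; singletons
    become single-site DMRs.
    """
    sig = dms[dms["significant"]].sort_values("position")
    if sig.empty:
        return []
    frac = profile.fractions()
    records, chain = [], [sig.iloc[0]]

    def flush(chain):
        sidx = np.array([int(r["site_index"]) for r in chain])
        pos = np.array([int(r["position"]) for r in chain])
        mc = profile.mc[:, sidx].sum(axis=1)
        cov = profile.cov[:, sidx].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(cov > 0, mc / np.maximum(cov, 1), np.nan)
        overall = mc.sum() / max(cov.sum(), 1)
        records.append(DMRRecord(
            chrom=profile.chrom, start=int(pos.min()),
            end=int(pos.max()) + site_size, sites=pos,
            sample_mc=mc, sample_cov=cov,
            statistic=float(np.max([r["statistic"] for r in chain])),
            fdr=float(np.min([r["fdr"] for r in chain])),
            hypo_samples=f < overall, hyper_samples=f > overall,
            provenance=provenance))

    for _, row in sig.iloc[1:].iterrows():
        prev = chain[-1]
        gap = row["position"] - prev["position"]
        if gap <= max_gap:
            a = frac[:, int(prev["site_index"])]
            b = frac[:, int(row["site_index"])]
            ok = np.isfinite(a) & np.isfinite(b)
            pcc = np.corrcoef(a[ok], b[ok])[0, 1] if ok.sum() >= 3 else 0.0
            if np.isfinite(pcc) and pcc > min_pcc:
                chain.append(row)
                continue
        flush(chain)
        chain = [row]
    flush(chain)
    return records


def merge_overlapping_dmrs(runs: list, key=lambda r: abs(r.statistic)
                           ) -> pd.DataFrame:
    """Merge DMR lists from multiple runs into non-overlapping intervals.

    Touching or overlapping intervals (distance 0) merge; the source record
    with the largest |key| represents each merged interval.  Returns a
    DataFrame with chrom/start/end/representative columns.
    """
    records = [r for run in runs for r in run]
    if not records:
        return pd.DataFrame(columns=["chrom", "start", "end", "representative",
                                     "provenance", "n_sources"])
    records.sort(key=lambda r: (r.chrom, r.start, r.end))
    merged = []
    cur = [records[0]]
    cur_end = records[0].end
    for r in records[1:]:
        if r.chrom == cur[0].chrom and r.start <= cur_end:
            cur.append(r)
            cur_end = max(cur_end, r.end)
        else:
            merged.append((cur, cur_end))
            cur, cur_end = [r], r.end
    merged.append((cur, cur_end))
    rows = []
    for group, end in merged:
        rep = max(group, key=key)
        rows.append({"chrom": group[0].chrom,
                     "start": min(r.start for r in group),
                     "end": end, "representative": rep,
                     "provenance": rep.provenance, "n_sources": len(group)})
    return pd.DataFrame(rows)
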