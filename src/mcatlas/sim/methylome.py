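"""Simulate per-cell binned methylomes with planted cluster structure.

Each cell carries a global mCG and mCH level; at every bin the basecall count
is Poisson and the methylated count is Binomial around the cell's global level,
shifted down by the planted effect at that cluster's marker bins.  Gene-level
mCH (used by the integration / GRN / isoform fixtures) follows the same rule
on gene intervals laid head-to-tail along the chromosome.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..containers import CellBasecallTable
from .config import ConfigError, GroundTruth, SimulationConfig

__all__ = ["simulate_methylomes"]


def _cluster_labels(config: SimulationConfig, rng) -> np.ndarray:
    # near-balanced random assignment; every cluster non-empty
    base = np.repeat(np.arange(config.n_clusters),
                     int(np.ceil(config.n_cells / config.n_clusters)))
    labels = base[: config.n_cells].copy()
    rng.shuffle(labels)
    return labels


def _sample_counts(rng, p_matrix, mean_cov):
    cov = rng.poisson(mean_cov, size=p_matrix.shape)
    mc = rng.binomial(cov, p_matrix)
    return mc.astype(np.int64), cov.astype(np.int64)


def simulate_methylomes(config: SimulationConfig):
    """Return ``(CellBasecallTable, GroundTruth)`` with planted clusters.

    Marker bins of each cluster are hypomethylated by ``config.hypo_effect``
    in mCG; mCH markers are scaled so the fraction stays positive.  Ground
    truth additionally carries gene intervals and the planted cluster-level
    gene-body mCH/mCG matrices consumed by the expression generator.
    """
    truth = GroundTruth()
    rng = config.rng("methylome")

    n, b, k = config.n_cells, config.n_bins, config.n_clusters
    labels = _cluster_labels(config, rng)
    truth.labels = labels

    # per-cell global levels
    g_cg = np.clip(rng.normal(config.global_mcg_mean, config.global_mcg_sd, n),
                   0.05, 0.99)
    g_ch = np.clip(rng.normal(config.global_mch_mean, config.global_mch_sd, n),
                   0.005, 0.5)

    # disjoint marker bins per cluster
    needed = k * config.n_marker_bins
    if needed > b:
        raise ConfigError("not enough bins for the requested marker layout")
    perm = rng.permutation(b)[:needed]
    marker = {c: np.sort(perm[c * config.n_marker_bins:(c + 1) * config.n_marker_bins])
              for c in range(k)}
    truth.marker_bins = marker

    # bin-level success probabilities
    p_cg = np.repeat(g_cg[:, None], b, axis=1)
    p_ch = np.repeat(g_ch[:, None], b, axis=1)
    ch_effect = config.hypo_effect * (config.global_mch_mean / config.global_mcg_mean)
    for c in range(k):
        cells = labels == c
        cols = marker[c]
        p_cg[np.ix_(cells, cols)] -= config.hypo_effect
        p_ch[np.ix_(cells, cols)] -= ch_effect
    p_cg = np.clip(p_cg, 0.01, 0.99)
    p_ch = np.clip(p_ch, 0.002, 0.99)

    mc_cg, cov_cg = _sample_counts(rng, p_cg, config.mean_coverage)
    mc_ch, cov_ch = _sample_counts(rng, p_ch, config.mean_coverage)

    # gene layout: n_genes disjoint intervals tiled along the chromosome
    gene_len = config.chrom_size // max(config.n_genes, 1)
    genes = [(config.chrom, g * gene_len, (g + 1) * gene_len, f"gene{g}",
              "+" if g % 2 == 0 else "-") for g in range(config.n_genes)]
    truth.gene_intervals = genes

    # planted cluster-level gene methylation: each cluster hypomethylates a
    # disjoint slice of "its" genes (used for expression anti-correlation)
    gene_mch = np.full((k, config.n_genes), config.global_mch_mean)
    gene_mcg = np.full((k, config.n_genes), config.global_mcg_mean)
    per = config.n_genes // k
    for c in range(k):
        sl = slice(c * per, (c + 1) * per)
        gene_mch[c, sl] = max(config.global_mch_mean * (1 - 0.8), 0.002)
        gene_mcg[c, sl] = max(config.global_mcg_mean - config.hypo_effect, 0.02)
    gene_mch += rng.normal(0, 0.002, gene_mch.shape)
    gene_mcg += rng.normal(0, 0.01, gene_mcg.shape)
    truth.gene_mch = np.clip(gene_mch, 1e-4, 1.0)
    truth.gene_mcg = np.clip(gene_mcg, 1e-3, 1.0)

    # planted DMR intervals: one per marker bin, centred in the bin
    for c in range(k):
        for j in marker[c]:
            start = j * config.bin_size + config.bin_size // 2 - 250
            truth.dmr_intervals.append((config.chrom, start, start + 500, c))

    cells = pd.Index([f"cell{i}" for i in range(n)], name="cell")
    global_levels = pd.DataFrame({
        "mCG": (mc_cg.sum(1) / np.maximum(cov_cg.sum(1), 1)),
        "mCH": (mc_ch.sum(1) / np.maximum(cov_ch.sum(1), 1)),
        "mCCC": np.clip(rng.normal(0.01, 0.003, n), 0.0, 0.05),
    }, index=cells)
    meta = pd.DataFrame({
        "plate": [f"plate{i % config.n_plates}" for i in range(n)],
        "region": [f"region{labels[i] % config.n_regions}" for i in range(n)],
        "cluster_true": labels,
    }, index=cells)

    table = CellBasecallTable(
        chrom=config.chrom,
        bin_size=config.bin_size,
        bin_starts=np.arange(b, dtype=np.int64) * config.bin_size,
        counts={"CG": (mc_cg, cov_cg), "CH": (mc_ch, cov_ch)},
        global_levels=global_levels,
        cell_meta=meta,
    )
    truth.validate(config)
    return table, truth
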