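"""Simulate expression / accessibility / isoform profiles coupled to the
planted methylation structure.

RNA: per-cluster log expression decreases linearly with the planted gene-body
mCH of the cluster (anti-correlation strength configurable).  ATAC: binary
cell x 5-kb bin accessibility elevated where the cluster's planted DMRs are
hypomethylated.  Isoforms: per-gene transcript TPM and exon PSI across cell
groups, driven either by a gene-level (shared) factor or by one specific
intragenic feature (the planted, shuffle-sensitive signal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .config import ConfigError, GroundTruth, SimulationConfig

__all__ = ["simulate_expression_profiles", "ExpressionProfiles"]

ATAC_BIN = 5_000


@dataclass
class ExpressionProfiles:
    """Bundle of simulated cross-modality profiles (see module docstring)."""

    rna_counts: pd.DataFrame          # RNA cells x genes (UMI counts)
    rna_labels: np.ndarray            # RNA cell -> planted cluster
    atac_binary: sparse.csr_matrix    # ATAC cells x 5-kb bins
    atac_labels: np.ndarray
    atac_bin_starts: np.ndarray
    cluster_log_expr: np.ndarray      # clusters x genes planted log expression
    # isoform block
    group_ids: list = field(default_factory=list)
    isoform_genes: list = field(default_factory=list)   # gene dicts (see io.write_gtf)
    feature_table: pd.DataFrame | None = None           # feature metadata rows
    feature_matrix: np.ndarray | None = None            # groups x features
    tpm: pd.DataFrame | None = None                     # groups x transcripts
    psi: pd.DataFrame | None = None                     # groups x exons


def _rna_block(config, truth, rng, strength):
    k, g = truth.gene_mch.shape
    rel = (truth.gene_mch - truth.gene_mch.min()) / max(np.ptp(truth.gene_mch), 1e-9)
    noise = rng.normal(0, 1.0, size=(k, g))
    log_expr = 2.0 - 3.0 * strength * rel + (1.0 - strength) * noise \
        + rng.normal(0, 0.05, size=(k, g))
    n_rna = config.n_cells
    labels = np.repeat(np.arange(k), int(np.ceil(n_rna / k)))[:n_rna]
    rng.shuffle(labels)
    lam = np.exp(log_expr)[labels]          # cells x genes
    counts = rng.poisson(lam)
    df = pd.DataFrame(counts, index=[f"rna{i}" for i in range(n_rna)],
                      columns=[gi[3] for gi in truth.gene_intervals])
    return df, labels, log_expr


def _atac_block(config, truth, rng, strength):
    nb = config.chrom_size // ATAC_BIN
    k = truth.gene_mch.shape[0]
    base = 0.02
    prob = np.full((k, nb), base)
    # DMR bins of each cluster are open in that cluster
    for chrom, start, end, c in truth.dmr_intervals:
        j = min(start // ATAC_BIN, nb - 1)
        prob[c, j] = base + 0.6 * strength
    n_atac = config.n_cells
    labels = np.repeat(np.arange(k), int(np.ceil(n_atac / k)))[:n_atac]
    rng.shuffle(labels)
    mat = (rng.random((n_atac, nb)) < prob[labels]).astype(np.int8)
    return sparse.csr_matrix(mat), labels, np.arange(nb) * ATAC_BIN


def _isoform_block(config, truth, rng, strength, n_groups, n_iso_genes):
    """Per-gene transcripts/exons plus group-level features and targets."""
    group_ids = [f"group{i}" for i in range(n_groups)]
    genes, feat_rows, feat_cols = [], [], []
    tpm_cols, tpm_names, psi_cols, psi_names = [], [], [], []
    gene_len = 60_000
    exon_len, n_exons = 500, 8
    for gi in range(n_iso_genes):
        gene_id = f"isog{gi}"
        gstart = gi * (gene_len + 10_000)
        exon_starts = gstart + np.arange(n_exons) * (gene_len // n_exons)
        exons = [(int(s), int(s + exon_len)) for s in exon_starts]
        # two transcripts: tx0 skips the middle (alternative) exon
        alt = n_exons // 2
        tx = {f"{gene_id}.t0": [e for i, e in enumerate(exons) if i != alt],
              f"{gene_id}.t1": exons}
        genes.append({"gene_id": gene_id, "chrom": config.chrom, "strand": "+",
                      "transcripts": tx})

        planted = gi < n_iso_genes // 2   # first half carry intragenic signal
        shared = rng.normal(0, 1, n_groups)           # gene-level factor
        cols, rows = [], []
        driver = None
        for ei, (s, e) in enumerate(exons):
            for kind, (fs, fe) in (("exon", (s, e)),
                                   ("flank_up", (s - 300, s)),
                                   ("flank_down", (e, e + 300))):
                if planted and kind == "exon" and ei == alt:
                    v = rng.normal(0, 1, n_groups)    # independent driver
                    driver = len(cols)
                else:
                    v = 0.8 * shared + 0.2 * rng.normal(0, 1, n_groups)
                rows.append((gene_id, kind, fs, fe))
                cols.append(v)
        # two intragenic DMR features
        for d in range(2):
            ds = gstart + 5_000 + d * 20_000
            rows.append((gene_id, "dmr", ds, ds + 500))
            cols.append(0.8 * shared + 0.2 * rng.normal(0, 1, n_groups))
        if planted and driver is None:
            driver = 0
        fmat = np.column_stack(cols)
        feat_rows.extend(rows)
        feat_cols.append(fmat)

        # targets
        drive = strength * fmat[:, driver] if planted else strength * shared
        noise = rng.normal(0, 0.15, n_groups)
        # PSI of the alternative exon tracks the driver (logistic squash)
        psi_alt = 1.0 / (1.0 + np.exp(2.0 * (drive + noise)))
        total = np.exp(1.0 + 0.3 * shared)
        tpm1 = total * psi_alt
        tpm0 = total * (1 - psi_alt)
        tpm_cols.extend([tpm0, tpm1])
        tpm_names.extend([f"{gene_id}.t0", f"{gene_id}.t1"])
        for ei, (s, e) in enumerate(exons):
            psi_names.append(f"{gene_id}.e{ei}")
            psi_cols.append(psi_alt.copy() if ei == alt else np.ones(n_groups))
        truth.isoform_signal[gene_id] = {
            "planted": planted,
            "driver_feature": (len(feat_rows) - fmat.shape[1] + driver)
            if planted else None,
            "alt_exon": f"{gene_id}.e{alt}",
            "alt_transcripts": (f"{gene_id}.t0", f"{gene_id}.t1"),
        }

    feature_table = pd.DataFrame(feat_rows,
                                 columns=["gene_id", "kind", "start", "end"])
    feature_matrix = np.column_stack(feat_cols) if feat_cols else np.empty((n_groups, 0))
    tpm = pd.DataFrame(np.column_stack(tpm_cols), index=group_ids, columns=tpm_names)
    psi = pd.DataFrame(np.column_stack(psi_cols), index=group_ids, columns=psi_names)
    return group_ids, genes, feature_table, feature_matrix, tpm, psi


def simulate_expression_profiles(config: SimulationConfig, truth: GroundTruth,
                                 anti_corr_strength: float = 1.0,
                                 n_groups: int = 30,
                                 n_iso_genes: int = 12) -> ExpressionProfiles:
    """Simulate RNA/ATAC/isoform profiles coupled to ``truth``.

    ``anti_corr_strength`` in [0, 1] scales how strongly expression and
    accessibility are anti-correlated with the planted methylation (1 = fully
    deterministic coupling up to sampling noise, 0 = independent).
    """
    if truth is None or truth.gene_mch is None or truth.labels is None:
        raise ConfigError("truth must come from simulate_methylomes")
    if not (0.0 <= anti_corr_strength <= 1.0):
        raise ConfigError("anti_corr_strength must be in [0, 1]")
    rng = config.rng("expression")

    rna, rna_labels, log_expr = _rna_block(config, truth, rng, anti_corr_strength)
    atac, atac_labels, atac_starts = _atac_block(config, truth, rng, anti_corr_strength)
    (group_ids, genes, ftab, fmat, tpm, psi) = _isoform_block(
        config, truth, rng, anti_corr_strength, n_groups, n_iso_genes)

    return ExpressionProfiles(
        rna_counts=rna, rna_labels=rna_labels,
        atac_binary=atac, atac_labels=atac_labels, atac_bin_starts=atac_starts,
        cluster_log_expr=log_expr,
        group_ids=group_ids, isoform_genes=genes,
        feature_table=ftab, feature_matrix=fmat, tpm=tpm, psi=psi,
    )
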