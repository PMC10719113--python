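"""End-to-end benchmarks of every pipeline stage on synthetic data with
planted structure.

Each function regenerates its fixture from a seed, runs the relevant stage,
and returns a dict of summary metrics (recovery rates, calibration checks,
closed-form verifications).  They are shared by the test suite and the
reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score

from . import clustering, conformation, dmr, grn, integrate, isoform, qc
from .containers import CellBasecallTable
from .sim import (SimulationConfig, simulate_contacts,
                  simulate_expression_profiles, simulate_methylomes,
                  simulate_motif_dmrs, simulate_subclass_profiles)

__all__ = ["clustering_benchmark", "dmr_benchmark", "integration_benchmark",
           "conformation_benchmark", "grn_benchmark", "isoform_benchmark"]


# --------------------------------------------------------------- criterion 1

def clustering_benchmark(seed: int = 0, n_cells: int = 1000, k: int = 4,
                         delta: float = 0.3) -> dict:
    """Consensus clustering on a planted K-cluster methylome plus PNCC null
    calibration."""
    cfg = SimulationConfig(n_cells=n_cells, n_clusters=k, hypo_effect=delta,
                           chrom_size=20_000_000, seed=seed)
    table, truth = simulate_methylomes(cfg)
    post = clustering.posterior_fractions(table, "CG")
    _, cov = table.counts["CG"]
    hvf = clustering.select_features(post, cov, table.bin_starts,
                                     table.bin_size, n_top=100)
    X = post[:, hvf]
    X = (X - X.mean(0)) / np.maximum(X.std(0), 1e-9)
    pcs = PCA(n_components=20, random_state=seed).fit_transform(X)
    labels, acc, _ = clustering.consensus_cluster(
        pcs, n_runs=50, resolution=0.5, accuracy_target=0.95, seed=seed)
    ari = adjusted_rand_score(truth.labels, labels)

    rng = np.random.default_rng(seed + 1)
    n = 500
    reads = pd.Series(rng.lognormal(13, 0.3, n))
    plates = pd.Series(rng.choice([f"p{i}" for i in range(5)], n))
    pre = pd.Series(rng.choice([f"c{i}" for i in range(25)], n))
    res = qc.pncc_test(reads, plates, pre, n_perm=2000, seed=seed)
    ks_p = stats.kstest(res.table["p_mean"], "uniform").pvalue
    return {"clustering_ari": float(ari),
            "n_clusters_found": int(labels.max() + 1),
            "pncc_null_ks_p": float(ks_p)}


# --------------------------------------------------------------- criterion 2

def dmr_benchmark(seed: int = 0) -> dict:
    """Type-I calibration of the RMS permutation test, planted-DMR recovery
    at Delta = 0.4 / coverage 50, and the exact merge boundary rules."""
    rng = np.random.default_rng(seed)
    # null calibration
    n_sites = 2000
    cov = rng.poisson(40, (4, n_sites)) + 1
    mc = rng.binomial(cov, 0.7)
    prof = dmr.BaseProfile("chr1", np.arange(n_sites) * 2, mc, cov,
                           [f"s{i}" for i in range(4)])
    null = dmr.call_dms(prof, n_perm=2000, seed=seed)
    type1 = float((null["p"] < 0.05).mean() / 0.05)

    # planted recovery (default DMS cut-off FDR < 0.01)
    n_sites = 800
    positions = np.arange(n_sites) * 100
    frac = np.full((5, n_sites), 0.8)
    planted = np.arange(4, n_sites, 8)
    frac[np.ix_([0, 1], planted)] = 0.4
    cov = np.full((5, n_sites), 50)
    mc = rng.binomial(cov, frac)
    prof = dmr.downsample_coverage(dmr.BaseProfile(
        "chr1", positions, mc, cov, [f"s{i}" for i in range(5)]))
    out = dmr.call_dms(prof, n_perm=3000, seed=seed, fdr_cut=0.01)
    called = set(out[out["significant"]]["site_index"])
    sens = len(called & set(planted)) / len(planted)
    fdr = len(called - set(planted)) / max(len(called), 1)

    # merge boundary cases (exact rules)
    def merge_case(gap, mc_pair):
        pos = np.array([0, gap])
        cov2 = np.full((4, 2), 10)
        p2 = dmr.BaseProfile("chr1", pos, np.array(mc_pair), cov2,
                             list("abcd"))
        sig = pd.DataFrame({"position": pos, "site_index": [0, 1],
                            "statistic": 1.0, "p": 1e-4, "fdr": 1e-3,
                            "significant": True})
        return len(dmr.merge_dms_to_dmr(sig, p2))

    corr_pair = [[10, 10], [0, 0], [10, 10], [0, 0]]
    anti_pair = [[10, 0], [0, 10], [10, 0], [0, 10]]
    return {"dms_type1_ratio": type1,
            "dmr_sensitivity": float(sens),
            "dmr_fdr": float(fdr),
            "merge_251bp_splits": int(merge_case(251, corr_pair) == 2),
            "merge_250bp_joins": int(merge_case(250, corr_pair) == 1),
            "merge_anticorrelated_splits": int(merge_case(100, anti_pair) == 2)}


# --------------------------------------------------------------- criterion 3

def integration_benchmark(seed: int = 0) -> dict:
    """Downsampled-vs-full CCA identity, binomial hypomethylation oracle,
    planted cluster-map recovery and alignment-score endpoints."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(80, 50))
    Y = rng.normal(size=(70, 50))
    ea, eb = integrate.downsampled_cca(X, Y, n_dims=8, n_ref=10_000, seed=seed)
    U, _, Vt = np.linalg.svd(X @ Y.T, full_matrices=False)
    U, V = U[:, :8], Vt[:8].T

    def l2(A):
        return A / np.linalg.norm(A, axis=1, keepdims=True)
    sx = np.sign((ea.coords * l2(U)).sum(axis=0))
    sy = np.sign((eb.coords * l2(V)).sum(axis=0))
    cca_err = max(np.abs(ea.coords - l2(U) * sx).max(),
                  np.abs(eb.coords - l2(V) * sy).max())

    # hypomethylation score against the binomial-tail oracle
    n, b = 30, 40
    covm = rng.poisson(15, (n, b))
    p = np.clip(rng.normal(0.8, 0.03, n), 0.5, 0.95)
    mcm = rng.binomial(covm, p[:, None])
    table = CellBasecallTable(
        "chr1", 5000, np.arange(b) * 5000, {"CG": (mcm, covm)},
        pd.DataFrame({"mCG": p, "mCH": np.full(n, 0.02)},
                     index=[f"c{i}" for i in range(n)]))
    _, _, score = integrate.hypomethylation_score(table)
    oracle = stats.binom.sf(mcm, covm, p[:, None])
    oracle[covm == 0] = 0.0
    hypo_err = float(np.abs(score - oracle).max())

    # planted cross-modality map
    cfg = SimulationConfig(n_cells=200, n_clusters=4, chrom_size=10_000_000,
                           seed=seed)
    _, truth = simulate_methylomes(cfg)
    prof = simulate_expression_profiles(cfg, truth)
    mc_feat = truth.gene_mch[truth.labels] + rng.normal(
        0, 0.02, (cfg.n_cells, cfg.n_genes))
    Xm = integrate.zscore_clip(-mc_feat)
    Yr = integrate.zscore_clip(np.log1p(prof.rna_counts.to_numpy()))
    cmap = integrate.iterate_integration(Xm, Yr, truth.labels,
                                         prof.rna_labels, n_dims=8,
                                         seed=seed, min_y=30)
    pairs = cmap[["cluster_x", "cluster_y"]].drop_duplicates()
    map_exact = int(len(pairs) == cfg.n_clusters and
                    (pairs["cluster_x"].to_numpy()
                     == pairs["cluster_y"].to_numpy()).all())

    a = rng.normal(size=(200, 4)); b2 = rng.normal(size=(200, 4))
    ds = np.array([0] * 200 + [1] * 200)
    mixed = float(integrate.alignment_score(np.vstack([a, b2]), ds).iloc[0])
    sep = float(integrate.alignment_score(np.vstack([a, b2 + 100]), ds).iloc[0])
    return {"cca_max_abs_diff": float(cca_err),
            "hypo_score_max_err": hypo_err,
            "cluster_map_exact": map_exact,
            "alignment_mixed": mixed,
            "alignment_separated": sep}


# --------------------------------------------------------------- criterion 4

def conformation_benchmark(seed: int = 0) -> dict:
    """Compartment sign convention, chi-square closed form, ANOVA = t^2
    identity, shuffle-null calibration and planted-coupling recovery."""
    cfg = SimulationConfig(n_cells=24, n_clusters=2, chrom_size=20_000_000,
                           contact_resolution=100_000,
                           contacts_per_cell=30_000, n_compartment_blocks=6,
                           domain_size_bins=100_000, n_loops=0, seed=seed)
    _, truth = simulate_methylomes(cfg)
    cms, truth = simulate_contacts(cfg, truth)
    imputed = [conformation.impute_cell_contacts(cms.dense(i),
                                                 restart_prob=0.5)
               for i in range(len(cms))]
    g0 = np.mean([m for m, l in zip(imputed, truth.labels) if l == 0], axis=0)
    g1 = np.mean([m for m, l in zip(imputed, truth.labels) if l == 1], axis=0)
    rng = np.random.default_rng(seed)
    cpg = np.where(truth.compartment_labels == 1, 0.02, 0.01) \
        + rng.normal(0, 5e-4, cfg.n_contact_bins)
    track = conformation.compartment_scores([g0, g1], cpg)
    s = track.scores.to_numpy()[:, track.retained]
    sign_agree = float(np.mean(
        np.sign(s) == truth.compartment_labels[track.retained][None, :]))

    calls = np.zeros((200, 1), dtype=bool)
    calls[:80, 0] = True; calls[100:120, 0] = True
    chi2 = float(conformation.differential_boundaries(
        calls, np.repeat(["a", "b"], 100))["chi2"].iloc[0])

    x = rng.normal(size=(30, 6))
    g = np.repeat(["a", "b"], 15)
    pix = np.column_stack([np.arange(6), np.arange(6) + 10])
    out = conformation.highly_variable_interactions(
        x, g, pix, resolution=10_000, min_dist=0, max_dist=10**9)
    t = stats.ttest_ind(x[:15], x[15:])
    f_err = float(np.abs(out.sort_values("bin1")["F"].to_numpy()
                         - t.statistic ** 2).max())

    A = rng.normal(size=(20, 300)); B = rng.normal(size=(20, 300))
    prs = np.stack([np.arange(300)] * 2, 1)
    res = conformation.shuffle_null_correlation(A, B, prs, n_perm=100_000,
                                                seed=seed)
    null_sig = float(res["significant"].mean())

    # planted DMR-gene couplings through the same machinery
    _, truth2 = simulate_methylomes(SimulationConfig(
        n_cells=30, n_clusters=3, chrom_size=10_000_000, seed=seed))
    simulate_motif_dmrs(SimulationConfig(n_cells=30, n_clusters=3,
                                         chrom_size=10_000_000, seed=seed),
                        truth2, n_dmrs=150)
    profs = simulate_subclass_profiles(
        SimulationConfig(n_cells=30, n_clusters=3, chrom_size=10_000_000,
                         seed=seed), truth2, n_subclasses=30)
    gm = profs["gene_mch"].to_numpy()
    dm = profs["dmr_mcg"].to_numpy()
    gcols = list(profs["gene_mch"].columns)
    dcols = list(profs["dmr_mcg"].columns)
    planted_pairs = [(gcols.index(g2), dcols.index(d))
                     for r in truth2.regulons
                     for g2 in r["targets"] for d in r["dmrs"]]
    bg_pairs = [(int(a), int(b)) for a, b in zip(
        rng.integers(0, len(gcols), 200), rng.integers(0, len(dcols), 200))]
    pairs2 = np.array(planted_pairs + bg_pairs)
    res2 = conformation.shuffle_null_correlation(gm, dm, pairs2,
                                                 n_perm=50_000, seed=seed)
    coupling_recall = float(
        res2["significant"][: len(planted_pairs)].mean())
    return {"compartment_sign_agreement": sign_agree,
            "chi2_80_20": chi2,
            "anova_t2_max_err": f_err,
            "shuffle_null_sig_frac": null_sig,
            "coupling_recall": coupling_recall}


# --------------------------------------------------------------- criterion 5

def grn_benchmark(seed: int = 0) -> dict:
    """Triple-score arithmetic, NES calibration, planted-regulon recovery and
    PageRank TF ranking."""
    s_all_err = abs(grn.triple_score(0.9, 0.64, 0.81, 0.49)
                    - (0.9 * 0.64 * 0.81 * 0.49) ** 0.25)

    cfg = SimulationConfig(n_cells=60, n_clusters=3, chrom_size=10_000_000,
                           seed=seed)
    _, truth = simulate_methylomes(cfg)
    seqs, pwms = simulate_motif_dmrs(cfg, truth, n_regulons=3, n_dmrs=200)
    scores = grn.scan_motifs(seqs, pwms)
    rng = np.random.default_rng(seed)
    nes_means = [grn.motif_enrichment(
        rng.choice(scores.index, 25, replace=False), scores,
        top_frac=0.15)["nes"].mean() for _ in range(10)]

    profiles = simulate_subclass_profiles(cfg, truth, n_subclasses=30)
    gene_mch = profiles["gene_mch"]; dmr_mcg = profiles["dmr_mcg"]
    tf_mch = gene_mch[profiles["tf_ids"]]
    cand = pd.DataFrame([{"gene_id": g, "dmr_id": d, "interaction": (0, 1)}
                         for r in truth.regulons
                         for g in r["targets"] for d in r["dmrs"]])
    dt = grn.dmr_target_edges(dmr_mcg, gene_mch, cand, n_perm=20_000,
                              seed=seed)
    tt = grn.tf_target_edges(tf_mch, gene_mch, n_perm=20_000, seed=seed)
    td = grn.tf_dmr_edges(tf_mch, dmr_mcg, scores,
                          {r["tf"]: [r["motif"]] for r in truth.regulons},
                          n_perm=20_000, seed=seed, top_frac=0.15)
    triples = grn.assemble_triples(dt, td, tt, profiles["contact"], gene_mch)
    planted = {(r["tf"], d, g) for r in truth.regulons
               for d in r["dmrs"] for g in r["targets"]}
    got = set(zip(triples["tf"], triples["dmr_id"], triples["gene_id"]))
    precision = len(got & planted) / max(len(got), 1)
    recall = len(got & planted) / len(planted)

    pr = grn.pagerank_tfs(triples, gene_mch, dmr_mcg)
    act = profiles["activity"]
    tfs = profiles["tf_ids"]
    top1 = float(np.mean([pr.iloc[i].idxmax() == tfs[act[i].argmax()]
                          for i in range(len(pr))]))
    return {"s_all_example_err": float(s_all_err),
            "nes_null_mean": float(np.mean(nes_means)),
            "regulon_precision": float(precision),
            "regulon_recall": float(recall),
            "pagerank_top1_accuracy": top1}


# --------------------------------------------------------------- criterion 6

def isoform_benchmark(seed: int = 0) -> dict:
    """dPCC calibration (null genes near 0, planted genes > 0.3) and PSI
    closed forms."""
    cfg = SimulationConfig(n_cells=60, n_clusters=3, chrom_size=10_000_000,
                           seed=seed)
    _, truth = simulate_methylomes(cfg)
    prof = simulate_expression_profiles(cfg, truth, n_groups=30,
                                        n_iso_genes=12)
    null_deltas, planted_deltas = [], []
    for g in prof.isoform_genes:
        gid = g["gene_id"]
        X, _ = isoform.build_features(gid, prof.feature_table,
                                      prof.feature_matrix)
        target = prof.psi[[truth.isoform_signal[gid]["alt_exon"]]]
        _, _, d = isoform.shuffled_control(X, target, folds=5, seed=seed,
                                           n_trees=100)
        (planted_deltas if truth.isoform_signal[gid]["planted"]
         else null_deltas).append(abs(float(d.iloc[0]))
                                  if not truth.isoform_signal[gid]["planted"]
                                  else float(d.iloc[0]))

    genes = [{"gene_id": "g", "chrom": "chr1", "strand": "+",
              "transcripts": {"t0": [(0, 100), (200, 300)],
                              "t1": [(0, 100), (200, 300), (400, 500)]}}]
    tpm = pd.DataFrame({"t0": [1.0], "t1": [1.0]}, index=["s0"])
    psi = isoform.compute_psi(tpm, genes)
    return {"delta_pcc_null_frac_below_0p1":
            float(np.mean([d < 0.1 for d in null_deltas])),
            "delta_pcc_planted_min": float(min(planted_deltas)),
            "psi_shared_exon": float(psi["g.e0"].iloc[0]),
            "psi_half_exon": float(psi["g.e2"].iloc[0])}
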