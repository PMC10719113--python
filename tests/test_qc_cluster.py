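"""Cell QC, PNCC pre-cluster screening, and the consensus-clustering stack."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score

from mcatlas.clustering import (cluster_enriched_features, consensus_cluster,
                                iterate_clustering, mutual_information_rank,
                                posterior_fractions, select_features)
from mcatlas.qc import filter_cells, pncc_test


# ------------------------------------------------------------- filter_cells

def _record(**kw):
    base = dict(mCCC=0.04, mCH=0.10, mCG=0.70, final_reads=1e6,
                mapping_rate=0.6, cis_long_contacts=60_000)
    base.update(kw)
    return base


@pytest.mark.parametrize("modality,override,expected", [
    ("mC", {}, True),                                  # canonical pass
    ("mC", {"mCCC": 0.05}, False),                     # strict < 0.05
    ("mC", {"mCH": 0.2}, False),
    ("mC", {"mCG": 0.5}, False),
    ("mC", {"final_reads": 500_000}, False),           # strict > 500k
    ("mC", {"final_reads": 10_000_000}, False),
    ("mC", {"mapping_rate": 0.5}, False),
    ("m3C", {}, True),
    ("m3C", {"cis_long_contacts": 50_000}, False),     # strict > 50k
])
def test_filter_cells_thresholds(modality, override, expected):
    df = pd.DataFrame([_record(**override)], index=["cell"])
    assert filter_cells(df, modality).iloc[0] == expected


def test_filter_cells_missing_field_names_cell():
    df = pd.DataFrame([_record()], index=["cellX"]).drop(columns=["mCG"])
    with pytest.raises(ValueError, match="mCG"):
        filter_cells(df)


def test_filter_cells_idempotent_and_order_independent(rng):
    df = pd.DataFrame([_record(mCCC=rng.uniform(0, 0.1),
                               final_reads=rng.uniform(1e5, 2e7))
                       for _ in range(50)])
    m1 = filter_cells(df)
    m2 = filter_cells(df.iloc[::-1]).iloc[::-1]
    assert m1.equals(filter_cells(df))
    assert np.array_equal(m1.to_numpy(), m2.to_numpy())


# -------------------------------------------------------------------- PNCC

def test_pncc_equal_reads_all_one():
    n = 60
    reads = pd.Series(np.full(n, 1e6))
    plates = pd.Series(np.repeat(["p1", "p2"], n // 2))
    pre = pd.Series(np.tile([f"c{i}" for i in range(6)], n // 6))
    res = pncc_test(reads, plates, pre, n_perm=200, seed=0)
    assert np.allclose(res.pncc, 1.0)
    assert np.allclose(res.table["log2_mean"], 0.0)
    assert not res.table["flagged"].any()


def test_pncc_flags_triple_coverage_cluster(rng):
    n = 400
    reads = pd.Series(rng.lognormal(13, 0.25, n))
    plates = pd.Series(rng.choice([f"p{i}" for i in range(4)], n))
    pre = pd.Series(rng.choice([f"c{i}" for i in range(20)], n))
    reads[pre == "c0"] *= 3
    res = pncc_test(reads, plates, pre, n_perm=10_000, seed=0)
    row = res.table.loc["c0"]
    assert abs(row["log2_mean"]) > 0.8
    assert row["fdr_mean"] < 0.01
    assert bool(row["flagged"])
    assert not res.table.drop("c0")["flagged"].any()


def test_pncc_null_pvalues_uniform(rng):
    n = 500
    reads = pd.Series(rng.lognormal(13, 0.3, n))
    plates = pd.Series(rng.choice([f"p{i}" for i in range(5)], n))
    pre = pd.Series(rng.choice([f"c{i}" for i in range(25)], n))
    res = pncc_test(reads, plates, pre, n_perm=2000, seed=1)
    ks = stats.kstest(res.table["p_mean"], "uniform")
    assert ks.pvalue > 0.01


def test_pncc_single_cell_plate_warns(rng):
    reads = pd.Series([1e6, 2e6, 3e6])
    plates = pd.Series(["a", "b", "b"])
    pre = pd.Series(["c", "c", "c"])
    with pytest.warns(UserWarning, match="single cell"):
        res = pncc_test(reads, plates, pre, n_perm=100)
    assert res.pncc.iloc[0] == 1.0


# ------------------------------------------------------ posterior fractions

def test_posterior_closed_form_uniform_prior(methylome):
    """With a forced Beta(1,1) prior, mc=3/cov=7 shrinks to 4/9."""
    table, _ = methylome
    mc, cov = table.counts["CG"]
    mc = mc.copy(); cov = cov.copy()
    mc[0, 0], cov[0, 0] = 3, 7
    from mcatlas.containers import CellBasecallTable
    t2 = CellBasecallTable(table.chrom, table.bin_size, table.bin_starts,
                           {"CG": (mc, cov)}, table.global_levels,
                           table.cell_meta)
    post = posterior_fractions(t2, "CG", prior=(1.0, 1.0), normalize=False)
    assert post[0, 0] == pytest.approx(4 / 9)


def test_posterior_zero_coverage_gets_prior_mean(methylome):
    table, _ = methylome
    mc, cov = [a.copy() for a in table.counts["CG"]]
    cov[0, 5] = 0; mc[0, 5] = 0
    from mcatlas.containers import CellBasecallTable
    t2 = CellBasecallTable(table.chrom, table.bin_size, table.bin_starts,
                           {"CG": (mc, cov)}, table.global_levels,
                           table.cell_meta)
    a, b = 2.0, 1.0
    post = posterior_fractions(t2, "CG", prior=(a, b), normalize=False)
    assert post[0, 5] == pytest.approx(a / (a + b))


def test_posterior_limit_and_monotonicity(methylome):
    """High coverage converges to the raw fraction; monotone in mc."""
    table, _ = methylome
    mc, cov = [a.copy() for a in table.counts["CG"]]
    cov[0, :3] = 100_000
    mc[0, 0], mc[0, 1], mc[0, 2] = 20_000, 50_000, 80_000
    from mcatlas.containers import CellBasecallTable
    t2 = CellBasecallTable(table.chrom, table.bin_size, table.bin_starts,
                           {"CG": (mc, cov)}, table.global_levels,
                           table.cell_meta)
    post = posterior_fractions(t2, "CG", normalize=False)
    assert post[0, 0] == pytest.approx(0.2, abs=1e-3)
    assert post[0, 0] < post[0, 1] < post[0, 2]
    norm = posterior_fractions(t2, "CG", normalize=True, cap=10.0)
    assert norm.min() >= 0 and norm.max() <= 10.0


# ----------------------------------------------------------------- features

def test_select_features_blacklist_and_constant(k4_methylome):
    table, truth = k4_methylome
    post = posterior_fractions(table, "CG")
    _, cov = table.counts["CG"]
    bl = pd.DataFrame({"chrom": [table.chrom], "start": [0],
                       "end": [table.bin_size]})  # bin 0 fully blacklisted
    const = post.copy()
    const[:, 1] = 0.5   # constant bin -> zero dispersion
    hvf = select_features(const, cov, table.bin_starts, table.bin_size,
                          blacklist=bl, n_top=100)
    assert 0 not in hvf
    assert 1 not in hvf


def test_select_features_recovers_planted_markers(k4_methylome):
    table, truth = k4_methylome
    post = posterior_fractions(table, "CG")
    _, cov = table.counts["CG"]
    planted = np.concatenate(list(truth.marker_bins.values()))
    hvf = select_features(post, cov, table.bin_starts, table.bin_size,
                          n_top=len(planted))
    recall = len(set(hvf) & set(planted)) / len(planted)
    assert recall > 0.8


def test_select_features_all_removed_errors(k4_methylome):
    table, _ = k4_methylome
    post = posterior_fractions(table, "CG")
    _, cov = table.counts["CG"]
    bl = pd.DataFrame({"chrom": [table.chrom], "start": [0],
                       "end": [table.bin_starts[-1] + table.bin_size]})
    with pytest.raises(ValueError, match="removed"):
        select_features(post, cov, table.bin_starts, table.bin_size,
                        blacklist=bl)


def test_cluster_enriched_features(k4_methylome):
    table, truth = k4_methylome
    post = posterior_fractions(table, "CG")
    union, per = cluster_enriched_features(post, truth.labels, n_top=50,
                                           n_perm=2000, seed=0)
    planted = np.concatenate(list(truth.marker_bins.values()))
    recall = len(set(union) & set(planted)) / len(planted)
    assert recall > 0.8
    # planted marker bins reach AUROC > 0.9 in their own cluster
    for c, bins in truth.marker_bins.items():
        tab = per[c].set_index("feature")
        found = [b for b in bins if b in tab.index]
        assert len(found) > 0.8 * len(bins)
        assert (tab.loc[found, "auroc"] > 0.9).all()


def test_cef_constant_feature_not_selected(rng):
    X = rng.normal(0.5, 0.05, (90, 30))
    X[:, 0] = 0.5
    labels = np.repeat([0, 1, 2], 30)
    union, per = cluster_enriched_features(X, labels, n_top=10, n_perm=500)
    assert 0 not in union


def test_cef_small_cluster_skipped(rng):
    X = rng.normal(size=(23, 10))
    labels = np.array([0] * 20 + [1] * 2 + [2] * 1)
    with pytest.warns(UserWarning, match="skipped"):
        cluster_enriched_features(X, labels, n_perm=100)


# ---------------------------------------------------------------- consensus

def test_consensus_two_blobs(rng):
    X = np.vstack([rng.normal(0, 0.3, (60, 4)), rng.normal(4, 0.3, (60, 4))])
    labels, acc, per = consensus_cluster(X, n_runs=20, resolution=0.5,
                                         accuracy_target=0.95, seed=0)
    assert labels.max() + 1 == 2
    assert acc > 0.99


def test_consensus_planted_k4(k4_methylome):
    table, truth = k4_methylome
    post = posterior_fractions(table, "CG")
    _, cov = table.counts["CG"]
    hvf = select_features(post, cov, table.bin_starts, table.bin_size,
                          n_top=80)
    X = post[:, hvf]
    X = (X - X.mean(0)) / np.maximum(X.std(0), 1e-9)
    pcs = PCA(n_components=15, random_state=0).fit_transform(X)
    labels, acc, _ = consensus_cluster(pcs, n_runs=50, resolution=0.5,
                                       accuracy_target=0.95, seed=0)
    assert adjusted_rand_score(truth.labels, labels) > 0.9


def test_consensus_seed_stability(k4_methylome):
    table, truth = k4_methylome
    post = posterior_fractions(table, "CG")
    _, cov = table.counts["CG"]
    hvf = select_features(post, cov, table.bin_starts, table.bin_size, n_top=80)
    X = post[:, hvf]
    X = (X - X.mean(0)) / np.maximum(X.std(0), 1e-9)
    pcs = PCA(n_components=15, random_state=0).fit_transform(X)
    l1, _, _ = consensus_cluster(pcs, n_runs=30, resolution=0.5, seed=1)
    l2, _, _ = consensus_cluster(pcs, n_runs=30, resolution=0.5, seed=99)
    assert adjusted_rand_score(l1, l2) > 0.95


# ------------------------------------------------------- iterative rounds

def test_iterate_clustering_recovers_planted(k4_methylome):
    table, truth = k4_methylome
    labels, groups, info = iterate_clustering(table, max_rounds=2,
                                              n_runs=30, seed=0)
    assert adjusted_rand_score(truth.labels, labels) > 0.9
    # one region per cluster in the fixture layout -> groups refine clusters
    assert groups.nunique() >= labels.max() + 1


def test_iterate_small_cluster_not_resplit():
    from mcatlas.sim import SimulationConfig, simulate_methylomes
    cfg = SimulationConfig(n_cells=15, n_clusters=1, chrom_size=5_000_000,
                           seed=8)
    table, _ = simulate_methylomes(cfg)
    labels, groups, _ = iterate_clustering(table, max_rounds=3, n_runs=10,
                                           seed=0)
    assert labels.max() == 0     # 15 cells <= min_split_size: never split


# ------------------------------------------------------ mutual information

def test_mi_identity_and_independence(rng):
    labels = np.repeat([0, 1, 2, 3], 250)
    X = np.column_stack([
        labels + rng.normal(0, 1e-6, 1000),    # deterministic mapping
        rng.normal(size=1000),                 # independent
    ])
    out = mutual_information_rank(X, labels).set_index("feature")
    ent = stats.entropy(np.bincount(labels) / 1000)
    assert out.loc[0, "mi"] == pytest.approx(ent, rel=0.05)
    assert out.loc[1, "mi"] < 0.1
    assert out.index[0] == 0


def test_mi_single_label_zero(rng):
    X = rng.normal(size=(50, 5))
    out = mutual_information_rank(X, np.zeros(50))
    assert (out["mi"] == 0).all()


def test_mi_planted_markers_rank_top(k4_methylome):
    table, truth = k4_methylome
    post = posterior_fractions(table, "CG")
    planted = set(np.concatenate(list(truth.marker_bins.values())).tolist())
    out = mutual_information_rank(post, truth.labels)
    top = set(out["feature"][: len(planted)].tolist())
    assert len(top & planted) / len(planted) > 0.9
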