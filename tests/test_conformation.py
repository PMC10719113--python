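"""Contact imputation, compartments, boundaries, variable interactions and
the shuffle permutation null."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mcatlas.conformation import (call_boundaries_topdom, compartment_scores,
                                  correlate_boundaries_with_mch,
                                  correlate_interactions_with_mch,
                                  differential_boundaries, gaussian_convolve,
                                  group_transcripts,
                                  highly_variable_interactions,
                                  impute_cell_contacts, quantile_normalize,
                                  shuffle_null_correlation)


# --------------------------------------------------------------- imputation

def test_rwr_against_closed_form(rng):
    """Iterative RWR equals the closed form a W (I - (1-a) W)^(-1)."""
    m = rng.random((5, 5)); m = (m + m.T) / 2
    conv = gaussian_convolve(m)
    W = conv / conv.sum(axis=1, keepdims=True)
    a = 0.5
    R_closed = a * W @ np.linalg.inv(np.eye(5) - (1 - a) * W)
    R_closed = R_closed / R_closed.sum(axis=1, keepdims=True)
    R_closed = (R_closed + R_closed.T) / 2
    R = impute_cell_contacts(m, restart_prob=a, tol=1e-12)
    assert np.abs(R - R_closed).max() < 1e-8


def test_rwr_restart_one_is_convolved_input(rng):
    m = rng.random((20, 20)); m = (m + m.T) / 2
    R = impute_cell_contacts(m, restart_prob=1.0)
    conv = gaussian_convolve(m)
    W = conv / conv.sum(axis=1, keepdims=True)
    W = W / W.sum(axis=1, keepdims=True)
    assert np.abs(R - (W + W.T) / 2).max() < 1e-12


def test_rwr_block_mass_stays_within_block():
    blk = np.kron(np.eye(2), np.ones((10, 10)))
    R = impute_cell_contacts(blk, restart_prob=0.5)
    off = R[:10, 10:].sum() / R.sum()
    assert off < 0.05


def test_imputation_symmetric_nonnegative_deterministic(rng):
    m = rng.poisson(2, (15, 15)).astype(float); m = (m + m.T) / 2
    R1 = impute_cell_contacts(m, restart_prob=0.5)
    R2 = impute_cell_contacts(m, restart_prob=0.5)
    assert np.allclose(R1, R2)
    assert np.abs(R1 - R1.T).max() < 1e-12
    assert R1.min() >= 0


def test_imputation_empty_matrix_warns():
    with pytest.warns(UserWarning, match="empty"):
        R = impute_cell_contacts(np.zeros((5, 5)))
    assert np.all(R == 0)


def test_imputation_rejects_asymmetric(rng):
    m = rng.random((5, 5))
    with pytest.raises(ValueError, match="symmetric"):
        impute_cell_contacts(m)


def test_imputation_band_mask(rng):
    m = rng.random((30, 30)); m = (m + m.T) / 2
    R = impute_cell_contacts(m, restart_prob=0.5, band_bins=3)
    i, j = np.indices(R.shape)
    assert np.all(R[np.abs(i - j) > 3] == 0)


# ------------------------------------------------------------- compartments

@pytest.fixture(scope="module")
def imputed_groups(contact_set):
    cms, truth, cfg = contact_set
    imputed = [impute_cell_contacts(cms.dense(i), restart_prob=0.5)
               for i in range(len(cms))]
    g0 = np.mean([m for m, l in zip(imputed, truth.labels) if l == 0], axis=0)
    g1 = np.mean([m for m, l in zip(imputed, truth.labels) if l == 1], axis=0)
    rng = np.random.default_rng(0)
    cpg = np.where(truth.compartment_labels == 1, 0.02, 0.01) \
        + rng.normal(0, 5e-4, cfg.n_contact_bins)
    return [g0, g1], truth, cpg


def test_compartment_sign_convention(imputed_groups):
    maps, truth, cpg = imputed_groups
    track = compartment_scores(maps, cpg)
    s = track.scores.to_numpy()[:, track.retained]
    lab = truth.compartment_labels[track.retained]
    agreement = np.mean(np.sign(s) == lab[None, :])
    assert agreement > 0.9
    assert track.cpg_corr > 0          # sign convention: CpG-rich positive


def test_compartment_sign_flip_of_cpg_inverts_nothing(imputed_groups):
    """Flipping the raw PC sign (via negated CpG-correlated PCA input) is
    undone by the sign convention: A stays positive."""
    maps, truth, cpg = imputed_groups
    t1 = compartment_scores(maps, cpg)
    t2 = compartment_scores(maps[::-1], cpg)     # group order must not matter
    assert np.allclose(t1.scores.to_numpy()[0, t1.retained],
                       t2.scores.to_numpy()[1, t2.retained], atol=1e-6)


def test_compartment_identical_groups_identical_tracks(imputed_groups):
    maps, truth, cpg = imputed_groups
    track = compartment_scores([maps[0], maps[0].copy()], cpg)
    s = track.scores.to_numpy()
    assert np.allclose(s[0, track.retained], s[1, track.retained])


# --------------------------------------------------------------- boundaries

def test_topdom_planted_boundary_probability(domain_contacts):
    cms, truth, cfg = domain_contacts
    calls = []
    for i in range(len(cms)):
        imp = impute_cell_contacts(cms.dense(i), restart_prob=0.5)
        calls.append(call_boundaries_topdom(imp, w=5))
    # planted domain borders recovered (+-1 bin) in most cells
    recalls = []
    for b in truth.domain_boundaries[1:-1]:
        hit = sum(any(abs(c - b) <= 1 for c in cc) for cc in calls)
        recalls.append(hit / len(calls))
    assert np.mean(recalls) > 0.8


def test_topdom_constant_and_uniform_matrices():
    const = np.ones((40, 40))
    assert len(call_boundaries_topdom(const, w=5)) == 0
    d = np.abs(np.subtract.outer(np.arange(40), np.arange(40)))
    banded = 1.0 / (1 + d)
    assert len(call_boundaries_topdom(banded, w=5)) == 0


def test_topdom_short_chromosome_empty():
    assert len(call_boundaries_topdom(np.ones((8, 8)), w=5)) == 0


def test_differential_boundaries_closed_form():
    calls = np.zeros((200, 2), dtype=bool)
    calls[:80, 0] = True          # group a: 80/100
    calls[100:120, 0] = True      # group b: 20/100
    groups = np.array(["a"] * 100 + ["b"] * 100)
    out = differential_boundaries(calls, groups)
    assert out["chi2"].iloc[0] == pytest.approx(72.0)
    assert out["prob_a"].iloc[0] == pytest.approx(0.8)
    assert out["prob_b"].iloc[0] == pytest.approx(0.2)
    # equal proportions: statistic 0, P 1
    calls2 = np.zeros((200, 1), dtype=bool)
    calls2[:50, 0] = True; calls2[100:150, 0] = True
    out2 = differential_boundaries(calls2, groups)
    assert out2["chi2"].iloc[0] == pytest.approx(0.0)
    assert out2["p"].iloc[0] == pytest.approx(1.0)


def test_differential_boundaries_never_called_bin():
    calls = np.zeros((40, 3), dtype=bool)
    calls[:10, 0] = True
    groups = np.repeat(["a", "b"], 20)
    out = differential_boundaries(calls, groups)
    assert out["chi2"].iloc[2] == 0.0


def test_boundary_chi2_nominal_size_under_permutation(domain_contacts, rng):
    cms, truth, cfg = domain_contacts
    calls = []
    for i in range(len(cms)):
        imp = impute_cell_contacts(cms.dense(i), restart_prob=0.5)
        b = call_boundaries_topdom(imp, w=5)
        row = np.zeros(cms.n_bins, dtype=bool)
        row[b] = True
        calls.append(row)
    calls = np.array(calls)
    labels = rng.permutation(np.repeat(["a", "b"], len(cms) // 2))
    out = differential_boundaries(calls, labels)
    called = out[calls.sum(axis=0) > 0]
    assert (called["p"] < 0.05).mean() < 0.15   # no real signal


# ----------------------------------------------------------------- ANOVA

def test_hvi_two_groups_equals_t_squared(rng):
    x = rng.normal(size=(30, 6))
    g = np.repeat(["a", "b"], 15)
    pix = np.column_stack([np.arange(6), np.arange(6) + 10])
    out = highly_variable_interactions(x, g, pix, resolution=10_000,
                                       min_dist=0, max_dist=10**9)
    t = stats.ttest_ind(x[:15], x[15:])
    merged = out.sort_values("bin1")
    assert np.abs(merged["F"].to_numpy() - t.statistic ** 2).max() < 1e-10


def test_hvi_distance_window_and_blacklist(rng):
    x = rng.normal(size=(10, 3))
    g = np.repeat(["a", "b"], 5)
    pix = np.array([[0, 2], [0, 100], [50, 60]])   # 20kb, 1Mb, 100kb
    out = highly_variable_interactions(x, g, pix, resolution=10_000)
    assert len(out) == 2                            # 20 kb below min_dist
    bl = np.zeros(101, dtype=bool); bl[50] = True
    out2 = highly_variable_interactions(x, g, pix, resolution=10_000,
                                        blacklist_mask=bl)
    assert len(out2) == 1


def test_hvi_planted_loops_recovered(methylome, small_config):
    from mcatlas.sim import SimulationConfig, simulate_contacts, simulate_methylomes
    cfg = SimulationConfig(n_cells=40, n_clusters=2, chrom_size=10_000_000,
                           contact_resolution=100_000, contacts_per_cell=30_000,
                           n_compartment_blocks=1, domain_size_bins=100_000,
                           n_loops=8, loop_coupling=2.0, seed=12)
    _, truth = simulate_methylomes(cfg)
    cms, truth = simulate_contacts(cfg, truth)
    strengths = np.stack([impute_cell_contacts(cms.dense(i), restart_prob=0.5)
                          for i in range(len(cms))])
    iu, ju = np.triu_indices(cms.n_bins, k=1)
    pix = np.column_stack([iu, ju])
    vals = strengths[:, iu, ju]
    out = highly_variable_interactions(vals, truth.labels, pix,
                                       resolution=100_000, min_dist=200_000)
    hv = out[out["variable"]]
    got = set(zip(hv["bin1"], hv["bin2"]))
    loops = {(min(i, j), max(i, j)) for i, j in truth.loop_pixels
             if abs(i - j) >= 2}
    recall = len(got & loops) / len(loops)
    assert recall > 0.9


# ------------------------------------------------------------ shuffle null

def test_quantile_normalize_rows_share_distribution(rng):
    M = rng.normal(loc=[[0], [5], [10]], size=(3, 100))
    Q = quantile_normalize(M)
    for i in range(1, 3):
        assert np.allclose(np.sort(Q[0]), np.sort(Q[i]))


def test_shuffle_null_perfect_anticorrelation(rng):
    A = rng.normal(size=(20, 10))
    res = shuffle_null_correlation(A, -A, np.stack([np.arange(10)] * 2, 1),
                                   n_perm=5000, seed=0, normalize=False)
    assert np.allclose(res["pcc"], -1.0)
    # P at the minimum the Gaussian null can produce for this sample count
    assert (res["p"] < 1e-3).all()
    assert (res["p"] <= res["p"].min() + 1e-15).all()


def test_shuffle_null_independent_noise_calibrated(rng):
    A = rng.normal(size=(20, 300)); B = rng.normal(size=(20, 300))
    pairs = np.stack([np.arange(300)] * 2, 1)
    res = shuffle_null_correlation(A, B, pairs, n_perm=100_000, seed=1)
    assert res["significant"].mean() <= 0.002
    # empirical-null P values approximately uniform
    ks = stats.kstest(res["p"].dropna(), "uniform")
    assert ks.pvalue > 0.01


def test_shuffle_null_constant_vector_skipped(rng):
    A = rng.normal(size=(10, 2)); A[:, 1] = 1.0
    B = rng.normal(size=(10, 2))
    res = shuffle_null_correlation(A, B, np.array([[0, 0], [1, 1]]),
                                   n_perm=500, normalize=False)
    assert bool(res["skipped"].iloc[1])


# --------------------------------------------- methylation correlations

def test_group_transcripts_overlap_rule():
    tx = pd.DataFrame({
        "gene_id": ["g1"] * 3,
        "transcript_id": ["t1", "t2", "t3"],
        "start": [0, 100, 50_000],
        "end": [10_000, 10_100, 200_000],
        "strand": ["+"] * 3,
    })
    out = group_transcripts(tx)
    assert len(out) == 2                       # t1/t2 collapse (>90% overlap)
    assert out["length_class"].tolist() == ["short", "long"]


def test_correlate_boundaries_planted_tss_boundary(rng):
    """A boundary tracking (anti-correlated with) gene mCH lands as the top
    negative bin at the TSS."""
    n_sub, n_bins = 24, 200
    mch = rng.random((n_sub, 1))
    bound = rng.uniform(0.2, 0.4, (n_sub, n_bins))
    tss_bin = 80
    bound[:, tss_bin] = 0.6 - 0.5 * mch[:, 0]   # anti-correlated at TSS
    tx = pd.DataFrame({"gene_id": ["g"], "transcript_id": ["t"],
                       "start": [tss_bin * 25_000], "end": [tss_bin * 25_000
                                                            + 150_000],
                       "strand": ["+"]})
    res, summary = correlate_boundaries_with_mch(bound, mch, tx,
                                                 n_perm=20_000, seed=0)
    assert len(summary) == 1
    assert summary["top_neg_bin"].iloc[0] == tss_bin
    assert summary["top_neg_dist_tss"].iloc[0] == 0


def test_correlate_boundaries_no_variable_bins_empty(rng):
    mch = rng.random((10, 1))
    bound = np.full((10, 50), 0.3)
    tx = pd.DataFrame({"gene_id": ["g"], "transcript_id": ["t"],
                       "start": [0], "end": [100_000], "strand": ["+"]})
    res, summary = correlate_boundaries_with_mch(bound, mch, tx,
                                                 n_perm=2000, seed=0)
    assert summary.empty


def test_interaction_location_classes(rng):
    n_sub = 24
    mch = rng.random((n_sub, 1))
    hvi = pd.DataFrame({"bin1": [12, 2, 30, 2], "bin2": [14, 15, 40, 40]})
    strengths = rng.normal(size=(n_sub, 4))
    strengths[:, 0] = -mch[:, 0] + rng.normal(0, 0.05, n_sub)
    tx = pd.DataFrame({"gene_id": ["g"], "transcript_id": ["t"],
                       "start": [10 * 10_000], "end": [20 * 10_000],
                       "strand": ["+"]})
    res = correlate_interactions_with_mch(hvi, strengths, mch, tx,
                                          resolution=10_000, n_perm=20_000,
                                          seed=0, normalize=False,
                                          require_anchor_overlap=False)
    assert res["location_class"].tolist() == [
        "intragenic", "upstream-intragenic", "downstream",
        "upstream-downstream"]
    # planted anti-correlated intragenic loop recovered with negative sign
    top = res.iloc[0]
    assert top["significant"] and top["pcc"] < 0
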