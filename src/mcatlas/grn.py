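"""Multi-omic gene-regulatory-network construction and TF ranking.

Edges link TFs, DMRs (candidate binding elements) and target genes through
correlations of methylation fractions across cell subclasses: DMR-target
(gated by positively gene-correlated chromatin interactions), TF-target, and
TF-DMR (gated by motif enrichment with leading-edge occurrence).  Triples
score as the geometric mean of four absolute correlations, and per-subclass
TF importance comes from weighted personalized PageRank with methylation-
inverted node and edge weights.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx
from sklearn.preprocessing import RobustScaler

from .conformation import quantile_normalize, shuffle_null_correlation

__all__ = [
    "scan_motifs", "motif_enrichment", "candidate_dmrs",
    "dmr_target_edges", "tf_target_edges", "tf_dmr_edges",
    "assemble_triples", "pagerank_tfs", "triple_score",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


# -------------------------------------------------------------- motif scan

def _revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[c] for c in reversed(seq))


def _scan_one(seq: str, logodds: np.ndarray) -> float:
    w = logodds.shape[0]
    if len(seq) < w:
        return -np.inf
    idx = np.array([_BASE_INDEX.get(c, -1) for c in seq])
    best = -np.inf
    arange = np.arange(w)
    for s in range(len(seq) - w + 1):
        window = idx[s:s + w]
        valid = window >= 0
        score = logodds[arange[valid], window[valid]].sum()  # N -> 0 log-odds
        best = max(best, score)
    return best


def scan_motifs(sequences: dict, pwms: dict, background=None,
                pseudocount: float = 1e-3) -> pd.DataFrame:
    """Max log-odds score of each PWM on each sequence (both strands).

    The log-odds ratio is against a 0-order background (uniform by default);
    ``N`` positions contribute the background odds (0).  Empty sequences get
    ``-inf``.  Returns a sequences x motifs DataFrame.
    """
    bg = np.asarray(background if background is not None else [0.25] * 4)
    out = np.empty((len(sequences), len(pwms)))
    names = list(sequences)
    for mi, (mname, pwm) in enumerate(pwms.items()):
        pwm = np.asarray(pwm, dtype=float)
        lo = np.log2((pwm + pseudocount) / (bg + pseudocount))
        for si, sname in enumerate(names):
            seq = sequences[sname].upper()
            fwd = _scan_one(seq, lo)
            rev = _scan_one(_revcomp(seq), lo)
            out[si, mi] = max(fwd, rev)
    return pd.DataFrame(out, index=names, columns=list(pwms))


# -------------------------------------------------------- motif enrichment

def motif_enrichment(query_ids, scores: pd.DataFrame, top_frac: float = 0.03,
                     nes_cut: float = 3.0, min_set: int = 1) -> pd.DataFrame:
    """Recovery-curve motif enrichment of a query DMR set.

    For each motif, DMRs are ranked by score (descending); the recovery curve
    is the cumulative fraction of the query set recovered along the rank and
    the AUC is taken over the top ``top_frac`` of the ranking (normalized to
    [0, 1]).  NES = (AUC - mean AUC over motifs) / s.d. over motifs; a motif
    is enriched at NES > ``nes_cut``.  Leading-edge query DMRs are those
    ranked above the point where recovery exceeds the uniform expectation the
    most.  Returns a per-motif table with auc, nes, enriched, leading_edge.
    """
    if scores.shape[1] < 2:
        raise ValueError("need at least two motifs in the collection for NES")
    query = [q for q in query_ids if q in scores.index]
    if len(query) < min_set:
        raise ValueError("query set too small")
    qset = set(query)
    n = len(scores)
    n_top = max(int(np.ceil(top_frac * n)), 2)
    is_query = scores.index.isin(qset).astype(float)

    aucs, edges = [], []
    for m in scores.columns:
        order = np.argsort(-scores[m].to_numpy(), kind="stable")
        hits = is_query[order]
        rec = np.cumsum(hits) / len(query)
        aucs.append(rec[:n_top].mean())
        expected = np.arange(1, n + 1) / n
        peak = int(np.argmax(rec[:n_top] - expected[:n_top]))
        lead = [scores.index[order[i]] for i in range(peak + 1)
                if hits[i] > 0]
        edges.append(lead)
    aucs = np.asarray(aucs)
    sd = aucs.std()
    nes = (aucs - aucs.mean()) / sd if sd > 0 else np.zeros_like(aucs)
    return pd.DataFrame({"motif": scores.columns, "auc": aucs, "nes": nes,
                         "enriched": nes > nes_cut,
                         "leading_edge": edges}).set_index("motif")


# -------------------------------------------------------------- edge tables

def candidate_dmrs(interactions: pd.DataFrame, dmr_table: pd.DataFrame,
                   resolution: int) -> pd.DataFrame:
    """Candidate (gene, DMR) pairs: DMRs inside any anchor of the gene's
    positively correlated highly variable interactions.

    ``interactions`` needs gene_id, bin1, bin2, pcc (gene-interaction
    correlation); ``dmr_table`` needs dmr_id, start, end.
    """
    rows = []
    pos = interactions[interactions["pcc"] > 0]
    for h in pos.itertuples():
        for b in (h.bin1, h.bin2):
            a_lo, a_hi = b * resolution, (b + 1) * resolution
            hit = dmr_table[(dmr_table["start"] < a_hi) &
                            (dmr_table["end"] > a_lo)]
            for d in hit.itertuples():
                rows.append({"gene_id": h.gene_id, "dmr_id": d.dmr_id,
                             "interaction": (h.bin1, h.bin2)})
    if not rows:
        return pd.DataFrame(columns=["gene_id", "dmr_id", "interaction"])
    return pd.DataFrame(rows).drop_duplicates(["gene_id", "dmr_id"])


def _corr_edges(A: pd.DataFrame, B: pd.DataFrame, pairs, n_perm, seed,
                fdr_cut):
    res = shuffle_null_correlation(A.to_numpy(), B.to_numpy(),
                                   np.asarray(pairs), n_perm=n_perm,
                                   seed=seed, fdr_cut=fdr_cut)
    return res


def dmr_target_edges(dmr_mcg: pd.DataFrame, gene_mch: pd.DataFrame,
                     candidates: pd.DataFrame,
                     dmr_table: pd.DataFrame | None = None,
                     n_perm: int = 10_000, seed: int = 0,
                     fdr_cut: float = 1e-3) -> pd.DataFrame:
    """DMR-target edges: PCC(DMR mCG, gene mCH) across subclasses for the
    candidate pairs, shuffle-null FDR filtered; among overlapping DMRs of a
    gene the one with max |PCC| represents the group."""
    if candidates.empty:
        return pd.DataFrame(columns=["gene_id", "dmr_id", "pcc", "fdr",
                                     "interaction"])
    gi = {g: i for i, g in enumerate(gene_mch.columns)}
    di = {d: i for i, d in enumerate(dmr_mcg.columns)}
    cand = candidates[candidates["gene_id"].isin(gi)
                      & candidates["dmr_id"].isin(di)].reset_index(drop=True)
    pairs = np.array([[di[d], gi[g]] for d, g in
                      zip(cand["dmr_id"], cand["gene_id"])])
    res = _corr_edges(dmr_mcg, gene_mch, pairs, n_perm, seed, fdr_cut)
    edges = cand.assign(pcc=res["pcc"].to_numpy(), fdr=res["fdr"].to_numpy(),
                        significant=res["significant"].to_numpy())
    edges = edges[edges["significant"]].drop(columns="significant")
    if dmr_table is not None and not edges.empty:
        coords = dmr_table.set_index("dmr_id")
        kept = []
        for gene, sub in edges.groupby("gene_id"):
            sub = sub.assign(start=coords.loc[sub["dmr_id"], "start"].to_numpy(),
                             end=coords.loc[sub["dmr_id"], "end"].to_numpy())
            sub = sub.sort_values("start")
            cur, cur_end = [], -1
            for row in sub.itertuples():
                if row.start < cur_end and cur:
                    cur.append(row)
                    cur_end = max(cur_end, row.end)
                else:
                    if cur:
                        kept.append(max(cur, key=lambda r: abs(r.pcc)))
                    cur, cur_end = [row], row.end
            if cur:
                kept.append(max(cur, key=lambda r: abs(r.pcc)))
        edges = pd.DataFrame([{
            "gene_id": r.gene_id, "dmr_id": r.dmr_id, "pcc": r.pcc,
            "fdr": r.fdr, "interaction": r.interaction} for r in kept])
    return edges.reset_index(drop=True)


def tf_target_edges(tf_mch: pd.DataFrame, gene_mch: pd.DataFrame,
                    n_perm: int = 10_000, seed: int = 0,
                    fdr_cut: float = 1e-3) -> pd.DataFrame:
    """TF-target edges: PCC of TF gene-body mCH vs every (cluster-enriched)
    gene's mCH across subclasses, FDR filtered; self-edges excluded."""
    pairs = [(i, j) for i in range(tf_mch.shape[1])
             for j in range(gene_mch.shape[1])
             if tf_mch.columns[i] != gene_mch.columns[j]]
    res = _corr_edges(tf_mch, gene_mch, pairs, n_perm, seed, fdr_cut)
    out = pd.DataFrame({
        "tf": tf_mch.columns[res["item_a"]],
        "gene_id": gene_mch.columns[res["item_b"]],
        "pcc": res["pcc"], "fdr": res["fdr"],
        "significant": res["significant"]})
    return out[out["significant"]].drop(columns="significant").reset_index(drop=True)


def tf_dmr_edges(tf_mch: pd.DataFrame, dmr_mcg: pd.DataFrame,
                 motif_scores: pd.DataFrame, tf_motifs: dict,
                 n_perm: int = 10_000, seed: int = 0, fdr_cut: float = 1e-3,
                 nes_cut: float = 3.0, top_frac: float = 0.03) -> pd.DataFrame:
    """TF-DMR edges: correlation-significant pairs gated by motif enrichment.

    Per TF, its significantly correlated DMRs are split by PCC sign; an edge
    survives only when one of the TF's motifs (``tf_motifs``: tf -> motif
    ids) is enriched (NES > ``nes_cut``) in that signed set and the specific
    DMR carries a leading-edge occurrence of that motif.
    """
    pairs = [(i, j) for i in range(tf_mch.shape[1])
             for j in range(dmr_mcg.shape[1])]
    res = _corr_edges(tf_mch, dmr_mcg, pairs, n_perm, seed, fdr_cut)
    res = res[res["significant"]]
    rows = []
    for ti, tf in enumerate(tf_mch.columns):
        motifs = tf_motifs.get(tf, [])
        if not motifs:
            continue
        sub = res[res["item_a"] == ti]
        for sign in (1, -1):
            dmrs = dmr_mcg.columns[
                sub[np.sign(sub["pcc"]) == sign]["item_b"]].tolist()
            dmrs = [d for d in dmrs if d in motif_scores.index]
            if not dmrs:
                continue
            try:
                enr = motif_enrichment(dmrs, motif_scores, top_frac=top_frac,
                                       nes_cut=nes_cut)
            except ValueError:
                continue
            for m in motifs:
                if m not in enr.index or not enr.loc[m, "enriched"]:
                    continue
                lead = set(enr.loc[m, "leading_edge"])
                for d in dmrs:
                    if d in lead:
                        pcc = sub[(sub["item_b"] == list(dmr_mcg.columns).index(d))
                                  ]["pcc"].iloc[0]
                        rows.append({"tf": tf, "dmr_id": d, "pcc": pcc,
                                     "motif": m, "sign": sign})
    cols = ["tf", "dmr_id", "pcc", "motif", "sign"]
    return pd.DataFrame(rows, columns=cols).drop_duplicates(["tf", "dmr_id"])


# ------------------------------------------------------------------ triples

def triple_score(s_a: float, s_b: float, s_c: float, s_d: float) -> float:
    """Geometric mean of the absolute values of the four correlations."""
    return float(abs(s_a * s_b * s_c * s_d) ** 0.25)


def assemble_triples(dmr_target: pd.DataFrame, tf_dmr: pd.DataFrame,
                     tf_target: pd.DataFrame, contact: pd.DataFrame,
                     gene_mch: pd.DataFrame) -> pd.DataFrame:
    """Join the three edge tables on shared gene and DMR ids into
    (TF, DMR, target) triples.

    ``contact``: subclasses x (gene, dmr) MultiIndex columns of gene-DMR
    interaction strengths; S_d is the PCC of target mCH with that strength
    (the most negative one when several interactions connect the pair);
    triples without any contact column are dropped.
    """
    rows = []
    tt = tf_target.set_index(["tf", "gene_id"])["pcc"]
    for dt in dmr_target.itertuples():
        linked_tfs = tf_dmr[tf_dmr["dmr_id"] == dt.dmr_id]
        for td in linked_tfs.itertuples():
            key = (td.tf, dt.gene_id)
            if key not in tt.index:
                continue
            if (dt.gene_id, dt.dmr_id) not in contact.columns:
                continue
            strength = contact[(dt.gene_id, dt.dmr_id)]
            target_vec = gene_mch[dt.gene_id]
            if isinstance(strength, pd.DataFrame):   # several interactions
                s_d = min(np.corrcoef(target_vec, strength[c])[0, 1]
                          for c in strength.columns)
            else:
                s_d = np.corrcoef(target_vec, strength)[0, 1]
            s_a, s_b, s_c = dt.pcc, td.pcc, tt.loc[key]
            rows.append({"tf": td.tf, "dmr_id": dt.dmr_id,
                         "gene_id": dt.gene_id, "s_a": s_a, "s_b": s_b,
                         "s_c": s_c, "s_d": s_d,
                         "s_all": triple_score(s_a, s_b, s_c, s_d)})
    return pd.DataFrame(rows, columns=["tf", "dmr_id", "gene_id", "s_a",
                                       "s_b", "s_c", "s_d", "s_all"])


# ----------------------------------------------------------------- PageRank

def _inverted_weights(M: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize, robust-scale (quantile range 0.1-0.9), then invert
    per subclass: W = (max - x) / (max - min), in [0, 1]."""
    qn = quantile_normalize(M.to_numpy())
    scaled = RobustScaler(quantile_range=(10.0, 90.0)).fit_transform(qn)
    hi = scaled.max(axis=1, keepdims=True)
    lo = scaled.min(axis=1, keepdims=True)
    w = (hi - scaled) / np.maximum(hi - lo, 1e-12)
    return pd.DataFrame(w, index=M.index, columns=M.columns)


def pagerank_tfs(triples: pd.DataFrame, gene_mch: pd.DataFrame,
                 dmr_mcg: pd.DataFrame, damping: float = 0.85,
                 tol: float = 1e-8, max_iter: int = 1000) -> pd.DataFrame:
    """Per-subclass TF importance by weighted personalized PageRank.

    The network keeps TF and gene nodes only; in subclass i the gene node
    weight is the inverted scaled mCH ``W_i`` and the TF->target edge weight
    is ``e = (1/n) sum_t S_all,t * V_i,t`` over the n DMRs t connecting the
    pair (``V`` = inverted scaled DMR mCG).  Personalization is proportional
    to node weights.  Returns subclasses x TF scores, each row summing over
    TFs after within-subclass normalization of the full PageRank vector.
    """
    if triples.empty:
        raise ValueError("no triples to rank")
    W = _inverted_weights(gene_mch)
    V = _inverted_weights(dmr_mcg)
    tfs = sorted(triples["tf"].unique())
    genes = sorted(set(triples["gene_id"]) | set(tfs))
    out = {}
    for sub in gene_mch.index:
        g = nx.DiGraph()
        g.add_nodes_from(genes)
        grouped = triples.groupby(["tf", "gene_id"])
        for (tf, target), t in grouped:
            v = V.loc[sub, t["dmr_id"]].to_numpy()
            e = float(np.mean(t["s_all"].to_numpy() * v))
            if e > 0:
                g.add_edge(tf, target, weight=e)
        personalization = {n: max(float(W.loc[sub, n]), 1e-12) if n in W.columns
                           else 1e-12 for n in genes}
        pr = nx.pagerank(g, alpha=damping, personalization=personalization,
                         weight="weight", tol=tol, max_iter=max_iter)
        out[sub] = {tf: pr[tf] for tf in tfs}
    table = pd.DataFrame(out).T        # subclasses x TFs
    return table
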