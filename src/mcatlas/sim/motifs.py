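"""Simulate DMR sequences with planted TF motif occurrences, PWM sets, and
subclass-level methylation/contact profiles for the regulatory-network
fixtures.

Regulons are planted as (TF, DMR set, target-gene set) triples: the TF's PWM
consensus is embedded in its regulon DMR sequences, and subclass-level TF/
target mCH, DMR mCG and gene-DMR contact strength all track a latent per-
subclass regulon activity (methylation inverted, contacts following activity).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ConfigError, GroundTruth, SimulationConfig

__all__ = ["simulate_motif_dmrs", "simulate_subclass_profiles", "random_pwm"]

BASES = np.array(list("ACGT"))


def random_pwm(rng, length: int = 8, sharpness: float = 0.88) -> np.ndarray:
    """A (length, 4) PWM with a random consensus at probability ``sharpness``."""
    pwm = np.full((length, 4), (1 - sharpness) / 3)
    cons = rng.integers(0, 4, length)
    pwm[np.arange(length), cons] = sharpness
    return pwm


def _sample_site(rng, pwm: np.ndarray) -> str:
    idx = [rng.choice(4, p=row / row.sum()) for row in pwm]
    return "".join(BASES[idx])


def simulate_motif_dmrs(config: SimulationConfig, truth: GroundTruth,
                        n_regulons: int = 3, n_dmrs: int = 300,
                        dmr_len: int = 200, motif_len: int = 10,
                        n_decoy_motifs: int = 30):
    """Return ``(sequences, pwms)`` and plant regulons into ``truth``.

    ``sequences``: dict dmr_id -> ACGT string; ``pwms``: dict motif_id -> PWM
    (rows sum to 1).  The first ``n_regulons`` motifs belong to planted
    regulon TFs; each regulon's DMRs carry one exact sampled occurrence.
    """
    if truth is None or not truth.gene_intervals:
        raise ConfigError("truth must come from simulate_methylomes")
    rng = config.rng("motifs")

    pwms = {}
    for r in range(n_regulons + n_decoy_motifs):
        pwm = random_pwm(rng, motif_len)
        if not np.allclose(pwm.sum(axis=1), 1.0):
            raise ConfigError("PWM rows must sum to 1")
        pwms[f"motif{r}"] = pwm

    seqs = {f"dmr{i}": "".join(rng.choice(BASES, dmr_len)) for i in range(n_dmrs)}

    n_genes = len(truth.gene_intervals)
    gene_ids = [g[3] for g in truth.gene_intervals]
    dmrs_per = max(n_dmrs // (3 * n_regulons), 5)
    targets_per = max(n_genes // (2 * n_regulons) - 1, 3)
    truth.regulons = []
    used = 0
    for r in range(n_regulons):
        tf = gene_ids[r]                       # first genes act as TFs
        dmr_ids = [f"dmr{i}" for i in range(used, used + dmrs_per)]
        used += dmrs_per
        tstart = n_regulons + r * targets_per
        targets = gene_ids[tstart: tstart + targets_per]
        motif = f"motif{r}"
        consensus = "".join(BASES[np.argmax(pwms[motif], axis=1)])
        for d in dmr_ids:
            site = consensus
            pos = int(rng.integers(0, dmr_len - len(site)))
            s = seqs[d]
            seqs[d] = s[:pos] + site + s[pos + len(site):]
        truth.regulons.append({"tf": tf, "motif": motif, "dmrs": dmr_ids,
                               "targets": targets, "sign": -1})
    return seqs, pwms


def simulate_subclass_profiles(config: SimulationConfig, truth: GroundTruth,
                               n_subclasses: int = 40, noise: float = 0.05):
    """Subclass-level matrices for the GRN fixtures.

    Returns a dict with ``tf_mch`` / ``gene_mch`` (subclass x gene),
    ``dmr_mcg`` (subclass x DMR), ``contact`` (subclass x (gene, dmr) loop
    strength) as DataFrames, plus the latent per-regulon activity.  Methylation
    is inverted activity (active subclass = hypomethylated TF/target/DMR);
    loop strength follows activity.
    """
    if not truth.regulons:
        raise ConfigError("no regulons planted; run simulate_motif_dmrs first")
    rng = config.rng("subclass-profiles")
    subclasses = [f"sub{i}" for i in range(n_subclasses)]
    gene_ids = [g[3] for g in truth.gene_intervals]
    dmr_ids = sorted({d for reg in truth.regulons for d in reg["dmrs"]},
                     key=lambda x: int(x[3:]))
    # background DMRs too (unlinked)
    n_bg = len(dmr_ids)
    bg_ids = [f"dmr{900 + i}" for i in range(n_bg)]

    # each subclass has one clearly dominant regulon (subclass-specific TF)
    activity = rng.uniform(0.0, 0.4, (n_subclasses, len(truth.regulons)))
    dominant = np.arange(n_subclasses) % len(truth.regulons)
    activity[np.arange(n_subclasses), dominant] = 0.8 + 0.2 * rng.random(n_subclasses)
    gene_mch = pd.DataFrame(rng.normal(0.5, 0.12, (n_subclasses, len(gene_ids))),
                            index=subclasses, columns=gene_ids)
    dmr_mcg = pd.DataFrame(rng.normal(0.7, 0.1, (n_subclasses, len(dmr_ids) + n_bg)),
                           index=subclasses, columns=dmr_ids + bg_ids)
    contact_cols, contact_vals = [], []
    for ri, reg in enumerate(truth.regulons):
        act = activity[:, ri]
        gene_mch[reg["tf"]] = 1 - act + rng.normal(0, noise, n_subclasses)
        for t in reg["targets"]:
            gene_mch[t] = 1 - act + rng.normal(0, noise, n_subclasses)
        for d in reg["dmrs"]:
            dmr_mcg[d] = 1 - act + rng.normal(0, noise, n_subclasses)
        for t in reg["targets"]:
            for d in reg["dmrs"]:
                contact_cols.append((t, d))
                contact_vals.append(act + rng.normal(0, noise, n_subclasses))
    contact = pd.DataFrame(np.column_stack(contact_vals), index=subclasses,
                           columns=pd.MultiIndex.from_tuples(contact_cols))
    gene_mch = gene_mch.clip(lower=0.001)
    dmr_mcg = dmr_mcg.clip(lower=0.001, upper=1.0)
    return {"subclasses": subclasses, "gene_mch": gene_mch, "dmr_mcg": dmr_mcg,
            "contact": contact, "activity": activity,
            "tf_ids": [r["tf"] for r in truth.regulons],
            "background_dmrs": bg_ids}
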