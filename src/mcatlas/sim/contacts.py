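"""Simulate per-cell cis contact maps with planted A/B blocks, domains and
methylation-coupled loop pixels.

Expected contact intensity at pixel (i, j) combines a power-law distance
decay, a within-compartment-block boost (alternating A/B blocks), a
within-domain boost, and planted loop pixels whose strength decreases
linearly with the planted methylation of the coupled gene in the cell's
cluster.  Each cell's contacts are a multinomial draw of
``contacts_per_cell`` pairs from its cluster's intensity surface.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

from ..containers import ContactMatrixSet
from .config import ConfigError, GroundTruth, SimulationConfig

__all__ = ["simulate_contacts", "expected_intensity"]

BLOCK_BOOST = 2.0
DOMAIN_BOOST = 3.0
LOOP_BASE = 8.0


def _plant_layout(config: SimulationConfig, truth: GroundTruth, rng) -> None:
    nb = config.n_contact_bins
    # alternating A/B compartment blocks
    edges = np.linspace(0, nb, config.n_compartment_blocks + 1).astype(int)
    comp = np.empty(nb, dtype=int)
    for bi in range(config.n_compartment_blocks):
        comp[edges[bi]:edges[bi + 1]] = 1 if bi % 2 == 0 else -1
    truth.compartment_labels = comp

    # domain boundaries every domain_size_bins
    bounds = np.arange(config.domain_size_bins, nb, config.domain_size_bins)
    truth.domain_boundaries = bounds

    # loop pixels at mid-range distances, each coupled to a gene
    if config.n_loops > 0:
        max_d = max(min(nb - 2, 50), 2)
        d = rng.integers(2, max_d, size=config.n_loops)
        i = rng.integers(0, nb - d.max() - 1, size=config.n_loops)
        j = i + d
        truth.loop_pixels = np.stack([i, j], axis=1)
        truth.loop_genes = rng.integers(0, config.n_genes, size=config.n_loops)
    else:
        truth.loop_pixels = np.empty((0, 2), dtype=int)
        truth.loop_genes = np.empty(0, dtype=int)


def expected_intensity(config: SimulationConfig, truth: GroundTruth,
                       cluster: int) -> np.ndarray:
    """Dense expected-intensity surface for one cluster (unnormalized)."""
    nb = config.n_contact_bins
    idx = np.arange(nb)
    dist = np.abs(idx[:, None] - idx[None, :])
    with np.errstate(divide="ignore"):
        inten = np.where(dist == 0, 1.5, dist.astype(float) ** (-config.decay_exponent))

    comp = truth.compartment_labels
    if comp is not None:
        same = comp[:, None] == comp[None, :]
        inten *= np.where(same, BLOCK_BOOST, 1.0)

    if truth.domain_boundaries is not None:
        edges = np.concatenate([[0], truth.domain_boundaries, [nb]])
        dom = np.searchsorted(edges, idx, side="right")
        inten *= np.where(dom[:, None] == dom[None, :], DOMAIN_BOOST, 1.0)

    if truth.loop_pixels is not None and len(truth.loop_pixels):
        # loop strength anti-correlated with the coupled gene's planted mCH
        mch = truth.gene_mch[cluster, truth.loop_genes] if truth.gene_mch is not None \
            else np.full(len(truth.loop_pixels), 0.02)
        rel = mch / max(truth.gene_mch.max(), 1e-9) if truth.gene_mch is not None else mch
        strength = LOOP_BASE * (1.0 + config.loop_coupling * (1.0 - rel))
        for (li, lj), s in zip(truth.loop_pixels, strength):
            inten[li, lj] *= s
            inten[lj, li] *= s
    return inten


def simulate_contacts(config: SimulationConfig, truth: GroundTruth | None = None,
                      symmetric: bool = True):
    """Return ``(ContactMatrixSet, GroundTruth)`` of per-cell contact maps.

    ``truth`` from :func:`simulate_methylomes` supplies cluster labels and the
    gene methylation used for loop coupling; if omitted a structure-free truth
    (single cluster) is created.
    """
    if not symmetric:
        raise ConfigError("contact maps are symmetric by construction")
    rng = config.rng("contacts")
    if truth is None:
        truth = GroundTruth()
    if truth.labels is None:
        truth.labels = np.zeros(config.n_cells, dtype=int)
    _plant_layout(config, truth, rng)
    truth.validate(config)

    nb = config.n_contact_bins
    iu, ju = np.triu_indices(nb)
    n_clusters = int(truth.labels.max()) + 1
    probs = []
    for c in range(n_clusters):
        inten = expected_intensity(config, truth, c)
        p = inten[iu, ju].astype(float)
        probs.append(p / p.sum())

    cms = ContactMatrixSet(chrom=config.chrom, resolution=config.contact_resolution,
                           n_bins=nb, cells=[])
    for i in range(config.n_cells):
        p = probs[truth.labels[i]]
        counts = rng.multinomial(config.contacts_per_cell, p)
        nz = counts > 0
        m = sparse.coo_matrix((counts[nz], (iu[nz], ju[nz])), shape=(nb, nb))
        cms.add(f"cell{i}", m)
    return cms, truth
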