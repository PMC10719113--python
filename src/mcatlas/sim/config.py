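"""Configuration and ground-truth containers for the synthetic-data generator.

The generator emulates the statistical structure of a brain-wide single-cell
methylome (+3C) experiment at desk scale: cells drawn from K planted clusters
with cluster-specific hypomethylated bins, chromatin contact maps with planted
A/B blocks, domains and methylation-coupled loops, and expression/accessibility
profiles anti-correlated with methylation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np


class ConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


def _check_fraction(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigError(f"{name} must be a fraction in [0, 1], got {value!r}")


def _check_positive(name: str, value) -> None:
    if value <= 0:
        raise ConfigError(f"{name} must be positive, got {value!r}")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic atlas.

    All coordinates are 0-based, half-open (BED convention).  A single seed
    fully determines every output: the same config + seed produces
    byte-identical tables.

    Parameters
    ----------
    n_cells, n_clusters
        Number of cells and planted cell clusters.
    chrom, chrom_size, bin_size
        Single synthetic chromosome and the primary (methylome) binning.
    global_mcg_mean / sd, global_mch_mean / sd
        Population distribution of per-cell global mCG / mCH levels.  Values
        mimic mammalian neurons (high CpG methylation, low but nonzero mCH).
    mean_coverage
        Mean number of cytosine basecalls per cell per bin (Poisson).
    hypo_effect
        Planted hypomethylation depth (Delta fraction) at cluster marker bins.
    n_marker_bins
        Marker bins planted per cluster (disjoint between clusters).
    n_genes
        Genes laid out head-to-tail along the chromosome (for gene-level mCH,
        expression coupling and the GRN/isoform fixtures).
    contact parameters
        ``contact_resolution`` is the bin size of simulated contact maps;
        ``n_compartment_blocks`` alternating A/B blocks; ``domain_size_bins``
        planted domain width; ``n_loops`` planted loop pixels whose strength is
        (negatively) coupled to the cluster-level methylation of the nearest
        gene with strength ``loop_coupling``; ``decay_exponent`` gives
        P(contact at distance d) ~ (d / bin)**(-decay_exponent);
        ``contacts_per_cell`` total cis contacts sampled per cell.
    seed
        Master seed for all randomness.
    """

    n_cells: int = 300
    n_clusters: int = 3
    chrom: str = "chr1"
    chrom_size: int = 50_000_000
    bin_size: int = 100_000

    global_mcg_mean: float = 0.75
    global_mcg_sd: float = 0.03
    global_mch_mean: float = 0.04
    global_mch_sd: float = 0.01

    mean_coverage: float = 30.0
    hypo_effect: float = 0.3
    n_marker_bins: int = 20
    n_genes: int = 100

    n_plates: int = 4
    n_regions: int = 2

    contact_resolution: int = 100_000
    n_compartment_blocks: int = 10
    domain_size_bins: int = 10
    n_loops: int = 20
    loop_coupling: float = 1.0
    decay_exponent: float = 1.0
    contacts_per_cell: int = 20_000

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cells", "n_clusters", "chrom_size", "bin_size",
                     "n_marker_bins", "n_genes", "n_plates", "n_regions",
                     "contact_resolution", "n_compartment_blocks",
                     "domain_size_bins", "contacts_per_cell"):
            _check_positive(name, getattr(self, name))
        for name in ("global_mcg_mean", "global_mch_mean", "hypo_effect"):
            _check_fraction(name, getattr(self, name))
        if self.global_mcg_sd < 0 or self.global_mch_sd < 0:
            raise ConfigError("global level s.d. must be nonnegative")
        if self.mean_coverage <= 0:
            raise ConfigError("mean_coverage must be positive")
        if self.n_loops < 0:
            raise ConfigError("n_loops must be nonnegative")
        if self.n_clusters > self.n_cells:
            raise ConfigError("more clusters than cells")

    @property
    def n_bins(self) -> int:
        return self.chrom_size // self.bin_size

    @property
    def n_contact_bins(self) -> int:
        return self.chrom_size // self.contact_resolution

    def rng(self, stream: str) -> np.random.Generator:
        """Named independent random stream derived from the master seed."""
        key = zlib.crc32(stream.encode("utf-8"))
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)


@dataclass
class GroundTruth:
    """Planted structure of a simulated dataset.

    Fields are filled progressively by the generator functions; downstream
    tests read whichever part they exercise.
    """

    labels: np.ndarray | None = None                    # cell -> cluster
    marker_bins: dict = field(default_factory=dict)     # cluster -> bin index array
    dmr_intervals: list = field(default_factory=list)   # (chrom, start, end, cluster)
    gene_intervals: list = field(default_factory=list)  # (chrom, start, end, gene_id, strand)
    gene_mch: np.ndarray | None = None                  # cluster x gene planted mCH
    gene_mcg: np.ndarray | None = None                  # cluster x gene planted mCG
    compartment_labels: np.ndarray | None = None        # contact bin -> {1 (A), -1 (B)}
    domain_boundaries: np.ndarray | None = None         # contact bin indices
    loop_pixels: np.ndarray | None = None               # (n_loops, 2) bin pairs
    loop_genes: np.ndarray | None = None                # gene index coupled to each loop
    regulons: list = field(default_factory=list)        # dicts: tf, dmrs, targets, sign
    isoform_signal: dict = field(default_factory=dict)  # gene -> planted feature info

    def validate(self, config: SimulationConfig) -> None:
        if self.labels is not None:
            if len(self.labels) != config.n_cells:
                raise ConfigError("labels do not cover all cells")
            if self.labels.min() < 0 or self.labels.max() >= config.n_clusters:
                raise ConfigError("label out of range")
        for bins in self.marker_bins.values():
            if np.any(bins < 0) or np.any(bins >= config.n_bins):
                raise ConfigError("marker bin out of range")
        if self.loop_pixels is not None and len(self.loop_pixels):
            if self.loop_pixels.max() >= config.n_contact_bins:
                raise ConfigError("loop pixel out of range")
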