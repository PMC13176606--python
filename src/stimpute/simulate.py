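"""Synthetic paired ST/SC datasets with a shared latent program.

Both modalities are driven by the same rank-``latent_rank`` factor model:
per-gene loadings map latent cell states to log-expression through an
exponential link, so expression is positive and right-skewed like count
data. SC cells draw factors independently; ST cells draw them from a
spatially smooth Gaussian-process-like field over random 2-D coordinates
(approximated with random Fourier features to stay linear in cell count).

Observation noise is modality-specific: Poisson counting noise and
multiplicative amplification jitter for both; library-size variation and
dropout for SC; additive optical background and (typically heavier)
dropout-style sparsity for ST. Gene panels overlap only partially — the
regime the translation model is built for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import (
    ExpressionMatrix,
    PairedDataset,
    SpatialCoordinates,
    ValidationError,
    build_shared_map,
)

ST_BACKGROUND_RATE = 0.1  # mean additive background counts per ST entry
N_FOURIER_FEATURES = 64


@dataclass
class SimConfig:
    """Generative settings for one paired dataset."""

    n_st_cells: int = 2000
    n_sc_cells: int = 3000
    n_genes_total: int = 300
    overlap_fraction: float = 0.6
    latent_rank: int = 8
    spatial_smoothness: float = 0.3  # Gaussian-kernel length scale in unit-square coords
    st_dropout: float = 0.2
    sc_dropout: float = 0.3
    noise_sd: float = 0.1  # log-normal amplification noise SD
    library_size_cv: float = 0.3
    st_panel_fraction: float = 0.5  # fraction of all genes on the ST panel
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_st_cells, self.n_sc_cells, self.n_genes_total) < 1:
            raise ValidationError("cell and gene counts must be >= 1")
        for name in ("overlap_fraction", "st_dropout", "sc_dropout", "st_panel_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if not 1 <= self.latent_rank <= self.n_genes_total:
            raise ValidationError("latent_rank must be in [1, n_genes_total]")
        if self.spatial_smoothness <= 0 or self.noise_sd < 0 or self.library_size_cv < 0:
            raise ValidationError("noise parameters out of range")


@dataclass
class SimTruth:
    """The noiseless generative state behind one simulated pair."""

    factors_st: np.ndarray  # (n_st_cells, rank)
    factors_sc: np.ndarray
    loadings: np.ndarray  # (n_genes_total, rank)
    baseline: np.ndarray  # per-gene log-mean offset
    gene_names: list[str]
    st_panel: list[str]
    sc_panel: list[str]
    shared_genes: list[str]
    noiseless_st: np.ndarray  # (n_st_cells, |st_panel|)
    noiseless_sc: np.ndarray
    coords: np.ndarray

    def st_gene_truth(self, genes) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.st_panel)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise KeyError(f"gene(s) not on the simulated ST panel: {missing[:5]}")
        return self.noiseless_st[:, [pos[g] for g in genes]]


def _smooth_spatial_factors(
    coords: np.ndarray, rank: int, length_scale: float, rng: np.random.Generator
) -> np.ndarray:
    """Low-rank Gaussian-process draw via random Fourier features of an RBF kernel."""
    d = N_FOURIER_FEATURES
    omega = rng.normal(0.0, 1.0 / length_scale, size=(2, d))
    phase = rng.uniform(0.0, 2 * np.pi, size=d)
    phi = np.sqrt(2.0 / d) * np.cos(coords @ omega + phase)
    f = phi @ rng.normal(size=(d, rank))
    f -= f.mean(axis=0)
    sd = f.std(axis=0)
    sd[sd == 0] = 1.0
    return f / sd


def _observe(
    noiseless: np.ndarray,
    rng: np.random.Generator,
    dropout: float,
    noise_sd: float,
    library_size_cv: float,
    background: float = 0.0,
) -> np.ndarray:
    """Counts = Poisson(library * amplification * mean) + background, then dropout."""
    n = noiseless.shape[0]
    if library_size_cv > 0:
        sigma = np.sqrt(np.log1p(library_size_cv**2))
        lib = np.exp(rng.normal(-sigma**2 / 2, sigma, size=(n, 1)))
    else:
        lib = np.ones((n, 1))
    if noise_sd > 0:
        amp = np.exp(rng.normal(-noise_sd**2 / 2, noise_sd, size=noiseless.shape))
    else:
        amp = 1.0
    counts = rng.poisson(lib * amp * noiseless).astype(np.float64)
    if background > 0:
        counts += rng.poisson(background, size=counts.shape)
    if dropout > 0:
        counts *= rng.random(counts.shape) >= dropout
    return counts


def simulate_pair(cfg: SimConfig) -> tuple[PairedDataset, SimTruth]:
    """Draw one paired dataset and its generative truth, deterministically from the seed."""
    rng = np.random.default_rng(cfg.seed)
    g_total, rank = cfg.n_genes_total, cfg.latent_rank
    width = len(str(g_total - 1))
    gene_names = [f"gene{str(i).zfill(width)}" for i in range(g_total)]

    loadings = np.clip(rng.normal(size=(g_total, rank)), -2.0, 2.0) / np.sqrt(rank)
    baseline = rng.normal(0.7, 0.4, size=g_total)

    coords = rng.uniform(0.0, 1.0, size=(cfg.n_st_cells, 2))
    factors_st = _smooth_spatial_factors(coords, rank, cfg.spatial_smoothness, rng)
    factors_sc = rng.normal(size=(cfg.n_sc_cells, rank))

    # panel assignment: ST panel is a random subset; its first `n_shared` genes
    # are also on the SC panel, the rest are ST-exclusive
    perm = rng.permutation(g_total)
    n_st_genes = max(1, int(round(cfg.st_panel_fraction * g_total)))
    st_panel_idx = np.sort(perm[:n_st_genes])
    shared_idx = np.sort(perm[: int(round(cfg.overlap_fraction * n_st_genes))])
    st_only = set(st_panel_idx) - set(shared_idx)
    sc_panel_idx = np.array([i for i in range(g_total) if i not in st_only], dtype=int)

    mean_st = np.exp(baseline[st_panel_idx] + factors_st @ loadings[st_panel_idx].T)
    mean_sc = np.exp(baseline[sc_panel_idx] + factors_sc @ loadings[sc_panel_idx].T)

    st_counts = _observe(mean_st, rng, cfg.st_dropout, cfg.noise_sd, 0.0,
                         background=ST_BACKGROUND_RATE)
    sc_counts = _observe(mean_sc, rng, cfg.sc_dropout, cfg.noise_sd, cfg.library_size_cv)

    st = ExpressionMatrix(
        st_counts, [gene_names[i] for i in st_panel_idx],
        [f"st_{i}" for i in range(cfg.n_st_cells)], stage="raw",
    )
    sc = ExpressionMatrix(
        sc_counts, [gene_names[i] for i in sc_panel_idx],
        [f"sc_{i}" for i in range(cfg.n_sc_cells)], stage="raw",
    )
    pair = PairedDataset(
        st=st, sc=sc, shared=build_shared_map(st, sc),
        st_coords=SpatialCoordinates(coords),
    )
    truth = SimTruth(
        factors_st=factors_st, factors_sc=factors_sc, loadings=loadings, baseline=baseline,
        gene_names=gene_names,
        st_panel=[gene_names[i] for i in st_panel_idx],
        sc_panel=[gene_names[i] for i in sc_panel_idx],
        shared_genes=[gene_names[i] for i in shared_idx],
        noiseless_st=mean_st, noiseless_sc=mean_sc, coords=coords,
    )
    return pair, truth


def ground_truth_heldout(sim: SimTruth, fold_genes) -> np.ndarray:
    """Noiseless ST-side expression for the requested genes (oracle-grade reference)."""
    return sim.st_gene_truth(list(fold_genes))


def easy_regime(seed: int = 0) -> SimConfig:
    """High-overlap, mild-noise conditions: 2000 ST / 3000 SC cells, 300 genes,
    60% ST-panel overlap, rank-8 latent."""
    return SimConfig(seed=seed)


def hard_regime(seed: int = 0) -> SimConfig:
    """Degradation conditions: 10% overlap and heavy dropout in both modalities."""
    return SimConfig(
        overlap_fraction=0.1,
        st_dropout=0.7,
        sc_dropout=0.7,
        noise_sd=0.3,
        seed=seed,
    )
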