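"""Four-step preprocessing: detection filters, HVG selection, clipping, sqrt normalization.

The pipeline, applied to a paired ST/SC dataset in order: drop genes detected
in fewer than 5% of cells, drop cells detecting fewer than 10% of genes,
keep the 2,000 most variable SC genes (plus all shared genes), clip each
feature at mean + 2 SD, and replace every value by its square root as a mild
variance-stabilizing transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import (
    ExpressionMatrix,
    PairedDataset,
    SharedGeneMap,
    ValidationError,
    build_shared_map,
)

logger = logging.getLogger("stimpute")


@dataclass
class PreprocessConfig:
    """Thresholds of the preprocessing pipeline.

    gene_min_detection
        Minimum fraction of cells in which a gene must be detected (nonzero).
    cell_min_detection
        Minimum fraction of genes a cell must detect.
    n_hvg
        Number of highly variable genes kept for the SC reference.
    clip_sd
        Per-feature values above mean + clip_sd * SD are clipped to that cap.
    """

    gene_min_detection: float = 0.05
    cell_min_detection: float = 0.1
    n_hvg: int = 2000
    clip_sd: float = 2.0

    def __post_init__(self) -> None:
        for name in ("gene_min_detection", "cell_min_detection"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.n_hvg < 1:
            raise ValidationError("n_hvg must be >= 1")
        if self.clip_sd <= 0:
            raise ValidationError("clip_sd must be > 0")


def filter_genes(m: ExpressionMatrix, threshold: float = 0.05) -> ExpressionMatrix:
    """Drop genes with detection rate strictly below ``threshold``."""
    rate = m.gene_detection_rate()
    keep = np.flatnonzero(rate >= threshold)
    if keep.size == 0:
        raise ValidationError(
            f"all {m.n_genes} genes fall below detection rate {threshold}; relax the threshold"
        )
    return m.subset_genes(keep, stage="filtered")


def filter_cells(m: ExpressionMatrix, threshold: float = 0.1) -> tuple[ExpressionMatrix, np.ndarray]:
    """Drop cells with detection rate strictly below ``threshold``.

    Returns the filtered matrix and the kept row indices so that ST
    coordinates can be subset in lockstep.
    """
    rate = m.cell_detection_rate()
    keep = np.flatnonzero(rate >= threshold)
    if keep.size == 0:
        raise ValidationError(
            f"all {m.n_cells} cells fall below detection rate {threshold}; relax the threshold"
        )
    return m.subset_cells(keep, stage="filtered"), keep


def hvg_dispersion(m: ExpressionMatrix) -> np.ndarray:
    """Dispersion (variance / mean) of log1p-transformed values, per gene."""
    y = np.log1p(m.values)
    mean = y.mean(axis=0)
    var = y.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    return disp


def select_hvg(sc: ExpressionMatrix, n: int, shared: SharedGeneMap) -> ExpressionMatrix:
    """Keep the top-``n`` most dispersed SC genes plus every shared gene.

    Shared genes are force-retained even when they rank below the cutoff:
    the identity loss anchors translation on them, so they must stay in the
    SC feature space. Ties in dispersion break by gene name so the selection
    is deterministic. Surviving genes keep their original column order.
    """
    if n >= sc.n_genes:
        return sc
    disp = hvg_dispersion(sc)
    order = sorted(range(sc.n_genes), key=lambda i: (-disp[i], sc.gene_names[i]))
    chosen = set(order[:n])
    chosen.update(int(j) for j in shared.sc_indices)
    keep = [i for i in range(sc.n_genes) if i in chosen]
    return sc.subset_genes(keep)


def clip_outliers(m: ExpressionMatrix, k: float = 2.0) -> ExpressionMatrix:
    """Clip each feature at mean + k * SD (population SD, computed per gene)."""
    mu = m.values.mean(axis=0)
    sd = m.values.std(axis=0)  # population convention: deterministic at n=1
    cap = mu + k * sd
    clipped = np.minimum(m.values, cap[None, :])
    return ExpressionMatrix(clipped, list(m.gene_names), list(m.cell_ids), stage="clipped")


def sqrt_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Replace every entry by its square root."""
    if np.any(m.values < 0):
        raise ValidationError("sqrt normalization requires non-negative values")
    return ExpressionMatrix(
        np.sqrt(m.values), list(m.gene_names), list(m.cell_ids), stage="normalized"
    )


def preprocess_pair(p: PairedDataset, cfg: PreprocessConfig | None = None) -> PairedDataset:
    """Run the full preprocessing pipeline on a paired dataset.

    Order: gene filter (both) -> cell filter (both) -> HVG (SC only) ->
    clip (both) -> sqrt (both). The shared-gene map is rebuilt after every
    step that changes a gene set. Clipping statistics are computed on the
    pre-sqrt values.
    """
    cfg = cfg or PreprocessConfig()
    st = filter_genes(p.st, cfg.gene_min_detection)
    sc = filter_genes(p.sc, cfg.gene_min_detection)
    st, kept_cells = filter_cells(st, cfg.cell_min_detection)
    coords = p.st_coords.subset(kept_cells) if p.st_coords is not None else None
    sc, _ = filter_cells(sc, cfg.cell_min_detection)
    shared = build_shared_map(st, sc)
    sc = select_hvg(sc, cfg.n_hvg, shared)
    shared = build_shared_map(st, sc)
    st = clip_outliers(st, cfg.clip_sd)
    sc = clip_outliers(sc, cfg.clip_sd)
    st = sqrt_normalize(st)
    sc = sqrt_normalize(sc)
    return PairedDataset(st=st, sc=sc, shared=shared, st_coords=coords)
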