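"""Per-gene imputation metrics, spatial diagnostics, and clustering scores.

All expression metrics compare one gene's measured vector across cells with
its imputed counterpart, on the square-root-normalized scale the model is
supervised on:

* PCC — Pearson correlation (constant vectors score 0).
* SSIM — structural similarity of min–max-normalized vectors with
  stabilizers C1 = 0.01 and C2 = 0.03.
* RMSE — root-mean-square error after independent z-scoring (affine
  invariant).
* Wasserstein — 1-D optimal-transport distance between the two z-scored
  empirical distributions.
* JS — Jensen–Shannon divergence (base-2 logs, so values lie in [0, 1])
  after normalizing each vector to a probability distribution over cells.

Spatial diagnostics: Moran's I on a row-standardized k-nearest-neighbor
graph, its imputed-minus-measured shift per gene, and latent neighborhood
recall under cosine distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon
from scipy.stats import wasserstein_distance
from sklearn.metrics import (
    adjusted_rand_score,
    normalized_mutual_info_score,
    silhouette_samples,
)
from sklearn.neighbors import NearestNeighbors

from .data import MetricReport, SpatialCoordinates, ValidationError
from .networks import LatentEmbedding

logger = logging.getLogger("stimpute")

SSIM_C1 = 0.01
SSIM_C2 = 0.03


@dataclass
class GeneVectorPair:
    """Measured and predicted per-cell expression for one gene, same cell order."""

    measured: np.ndarray
    predicted: np.ndarray

    def __post_init__(self) -> None:
        self.measured = np.asarray(self.measured, dtype=np.float64).ravel()
        self.predicted = np.asarray(self.predicted, dtype=np.float64).ravel()
        if self.measured.shape != self.predicted.shape:
            raise ValidationError("measured and predicted vectors must have equal length")
        if self.measured.size < 2:
            raise ValidationError("metrics need at least 2 cells")


def _pair(measured, predicted) -> tuple[np.ndarray, np.ndarray]:
    p = GeneVectorPair(measured, predicted)
    return p.measured, p.predicted


def pcc(measured, predicted) -> float:
    """Pearson correlation coefficient; 0 if either vector is constant."""
    x, y = _pair(measured, predicted)
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def _minmax(v: np.ndarray) -> np.ndarray:
    rng = v.max() - v.min()
    if rng == 0.0:
        return np.zeros_like(v)  # constant vector maps to all-zeros
    return (v - v.min()) / rng


def ssim(measured, predicted) -> float:
    """Structural similarity of the min–max-normalized vectors (C1=0.01, C2=0.03)."""
    x, y = _pair(measured, predicted)
    xn, yn = _minmax(x), _minmax(y)
    mx, my = xn.mean(), yn.mean()
    vx, vy = xn.var(), yn.var()  # population variance
    cov = ((xn - mx) * (yn - my)).mean()
    return float(
        (2 * mx * my + SSIM_C1) * (2 * cov + SSIM_C2)
        / ((mx**2 + my**2 + SSIM_C1) * (vx + vy + SSIM_C2))
    )


def _zscore(v: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / (sd + eps)


def rmse_z(measured, predicted) -> float:
    """Root-mean-square error after independent z-scoring of both vectors."""
    x, y = _pair(measured, predicted)
    return float(np.sqrt(np.mean((_zscore(x) - _zscore(y)) ** 2)))


def wasserstein_z(measured, predicted) -> float:
    """1-D Wasserstein-1 distance between the z-scored empirical distributions."""
    x, y = _pair(measured, predicted)
    return float(wasserstein_distance(_zscore(x), _zscore(y)))


def js_divergence(measured, predicted) -> float:
    """Jensen–Shannon divergence (base 2) between per-cell probability profiles.

    Each vector is normalized to sum to one over cells. Negative inputs are
    shifted by the global minimum first; a zero-sum vector yields the maximal
    divergence 1 with a warning.
    """
    x, y = _pair(measured, predicted)
    lo = min(x.min(), y.min())
    if lo < 0:
        x, y = x - lo, y - lo
    sx, sy = x.sum(), y.sum()
    if sx <= 0 or sy <= 0:
        logger.warning("zero-sum vector in JS divergence; returning maximal value 1")
        return 1.0
    d = jensenshannon(x / sx, y / sy, base=2)  # scipy returns sqrt(JS)
    return float(0.0 if np.isnan(d) else d * d)


def morans_i(values, coords: SpatialCoordinates, k_neighbors: int = 6) -> float:
    """Moran's I under row-standardized k-nearest-neighbor weights.

    I = (N / sum(W)) * sum_ij w_ij (x_i - mu)(x_j - mu) / sum_i (x_i - mu)^2,
    which simplifies with row-standardized rows summing to 1. A constant
    vector returns 0 by convention.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    xy = coords.xy if isinstance(coords, SpatialCoordinates) else np.asarray(coords)
    n = x.size
    if xy.shape[0] != n:
        raise ValidationError("values and coordinates must align")
    if n < k_neighbors + 1:
        raise ValidationError(f"need at least {k_neighbors + 1} cells for k={k_neighbors}")
    z = x - x.mean()
    denom = (z**2).sum()
    if denom == 0.0:
        return 0.0
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(xy)
    _, idx = nn.kneighbors(xy)
    neigh = idx[:, 1:]  # drop self
    lag = z[neigh].mean(axis=1)  # row-standardized weights: mean over k neighbors
    # with rows summing to 1, sum(W) = N and I reduces to sum(z * lag) / sum(z^2)
    return float((z * lag).sum() / denom)


@dataclass
class MoranShiftSummary:
    """Per-gene imputed-minus-measured Moran's I shifts and their summary."""

    genes: list[str]
    delta: np.ndarray
    median: float
    mean: float
    fraction_within: float
    band: float = 0.10


def moran_shift_summary(
    measured: np.ndarray,
    imputed: np.ndarray,
    coords: SpatialCoordinates,
    genes: Sequence[str],
    k_neighbors: int = 6,
    band: float = 0.10,
) -> MoranShiftSummary:
    """Spatial-autocorrelation inflation check: Delta I = I(imputed) - I(measured)."""
    measured, imputed = np.asarray(measured), np.asarray(imputed)
    if measured.shape != imputed.shape or measured.shape[1] != len(genes):
        raise ValidationError("measured/imputed/genes must align")
    delta = np.array([
        morans_i(imputed[:, j], coords, k_neighbors) - morans_i(measured[:, j], coords, k_neighbors)
        for j in range(len(genes))
    ])
    return MoranShiftSummary(
        genes=list(genes),
        delta=delta,
        median=float(np.median(delta)),
        mean=float(delta.mean()),
        fraction_within=float((np.abs(delta) <= band).mean()),
        band=band,
    )


@dataclass
class NeighborhoodRecallResult:
    per_cell: np.ndarray
    mean: float
    k: int
    m: int
    mode: str = "one_way"


def neighborhood_recall(
    original: LatentEmbedding | np.ndarray,
    mapped: LatentEmbedding | np.ndarray,
    k: int = 15,
    m: int = 45,
    mode: str = "one_way",
) -> NeighborhoodRecallResult:
    """Fraction of each cell's k cosine neighbors retained among the mapped
    embedding's top m neighbors.

    Source neighborhoods are computed in the original space, target
    neighborhoods in the mapped space (the two spaces may differ in
    dimension); self-neighbors are excluded in both.
    """
    a = np.asarray(original.vectors if isinstance(original, LatentEmbedding) else original)
    b = np.asarray(mapped.vectors if isinstance(mapped, LatentEmbedding) else mapped)
    n = a.shape[0]
    if b.shape[0] != n:
        raise ValidationError("embeddings must have equal row counts")
    if not k < m < n:
        raise ValidationError(f"need k < m < n_cells, got k={k}, m={m}, n={n}")
    src = NearestNeighbors(n_neighbors=k + 1, metric="cosine").fit(a)
    dst = NearestNeighbors(n_neighbors=m + 1, metric="cosine").fit(b)
    src_idx = src.kneighbors(a, return_distance=False)[:, 1:]
    dst_idx = dst.kneighbors(b, return_distance=False)[:, 1:]
    recall = np.empty(n)
    for i in range(n):
        recall[i] = len(set(src_idx[i]) & set(dst_idx[i])) / k
    return NeighborhoodRecallResult(recall, float(recall.mean()), k, m, mode)


def clustering_scores(labels_true, labels_pred, embedding: Optional[np.ndarray] = None) -> dict:
    """ARI, NMI, and (if an embedding is given) the macro-averaged silhouette.

    The silhouette follows the cluster-averaged form: per-sample scores are
    first averaged within each identified cluster, then across clusters.
    """
    labels_true = np.asarray(labels_true)
    labels_pred = np.asarray(labels_pred)
    if labels_true.shape != labels_pred.shape:
        raise ValidationError("label vectors must have equal length")
    out = {
        "ari": float(adjusted_rand_score(labels_true, labels_pred)),
        "nmi": float(normalized_mutual_info_score(labels_true, labels_pred)),
    }
    if embedding is not None:
        clusters = np.unique(labels_pred)
        if clusters.size < 2:
            raise ValidationError("silhouette requires at least 2 clusters")
        s = silhouette_samples(np.asarray(embedding), labels_pred)
        out["silhouette"] = float(np.mean([s[labels_pred == c].mean() for c in clusters]))
    return out


def evaluate_imputation(
    measured: np.ndarray, imputed: np.ndarray, genes: Sequence[str]
) -> MetricReport:
    """Per-gene PCC/SSIM/RMSE/Wasserstein/JS plus their averages.

    Genes whose measured vector is identically zero cannot be scored and are
    excluded (listed under diagnostics["excluded_genes"]).
    """
    measured, imputed = np.asarray(measured, dtype=np.float64), np.asarray(imputed, dtype=np.float64)
    if measured.shape != imputed.shape:
        raise ValidationError("measured and imputed must have the same shape")
    if measured.shape[1] != len(genes):
        raise ValidationError("gene list must match column count")
    rows, kept, excluded = [], [], []
    for j, g in enumerate(genes):
        x, y = measured[:, j], imputed[:, j]
        if not np.any(x):
            excluded.append(g)
            continue
        rows.append({
            "pcc": pcc(x, y),
            "ssim": ssim(x, y),
            "rmse": rmse_z(x, y),
            "wasserstein": wasserstein_z(x, y),
            "js": js_divergence(x, y),
        })
        kept.append(g)
    if not rows:
        raise ValidationError("no evaluable genes (all measured vectors are zero)")
    df = pd.DataFrame(rows, index=kept)
    return MetricReport(df, diagnostics={"excluded_genes": excluded})


def svg_recovery_auprc(scores: dict, reference_genes: Sequence[str]) -> float:
    """Area under the precision–recall curve for recovering a reference gene set.

    ``scores`` maps gene name to a spatial-variability score from imputed
    data; ``reference_genes`` is the externally supplied positive set (e.g.,
    significant spatially variable genes called on the measured data).
    """
    from sklearn.metrics import average_precision_score

    genes = list(scores)
    y_true = np.array([g in set(reference_genes) for g in genes], dtype=int)
    if y_true.sum() == 0 or y_true.sum() == len(genes):
        raise ValidationError("reference set must be a proper subset of scored genes")
    y_score = np.array([scores[g] for g in genes], dtype=float)
    return float(average_precision_score(y_true, y_score))
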