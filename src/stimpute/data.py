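"""Core data containers and on-disk readers/writers.

The two inputs of the pipeline are a spatial transcriptomics (ST) matrix with
per-cell 2-D coordinates and a dissociated single-cell (SC) reference matrix.
Both are cells-by-genes tables of non-negative expression values; the only
molecular correspondence between them is the set of gene symbols they share.
"""

from __future__ import annotations

import json
import logging
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("stimpute")

STAGES = ("raw", "filtered", "clipped", "normalized")


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass
class ExpressionMatrix:
    """Dense cells-by-genes matrix of non-negative expression values.

    ``stage`` tracks the preprocessing state: raw counts, after
    detection-rate filtering, after outlier clipping, or after square-root
    normalization.
    """

    values: np.ndarray
    gene_names: list[str]
    cell_ids: list[str]
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_names = [str(g) for g in self.gene_names]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D array")
        if self.values.shape != (len(self.cell_ids), len(self.gene_names)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_names)} genes"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValidationError("expression values must be non-negative")
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ValidationError("duplicate gene names; deduplicate on load")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell ids")
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_detection_rate(self) -> np.ndarray:
        """Fraction of cells with nonzero expression, per gene."""
        return (self.values > 0).mean(axis=0)

    def cell_detection_rate(self) -> np.ndarray:
        """Fraction of genes with nonzero expression, per cell."""
        return (self.values > 0).mean(axis=1)

    def subset_genes(self, idx: Sequence[int], stage: Optional[str] = None) -> "ExpressionMatrix":
        idx = np.asarray(idx, dtype=int)
        return ExpressionMatrix(
            self.values[:, idx],
            [self.gene_names[i] for i in idx],
            list(self.cell_ids),
            stage or self.stage,
        )

    def subset_cells(self, idx: Sequence[int], stage: Optional[str] = None) -> "ExpressionMatrix":
        idx = np.asarray(idx, dtype=int)
        return ExpressionMatrix(
            self.values[idx],
            list(self.gene_names),
            [self.cell_ids[i] for i in idx],
            stage or self.stage,
        )

    def drop_genes(self, names: Sequence[str]) -> "ExpressionMatrix":
        drop = set(names)
        keep = [i for i, g in enumerate(self.gene_names) if g not in drop]
        return self.subset_genes(keep)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), list(self.gene_names), list(self.cell_ids), self.stage
        )


@dataclass
class SpatialCoordinates:
    """2-D spatial positions, row-aligned to the ST matrix's cells."""

    xy: np.ndarray

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=np.float64)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValidationError("coordinates must be an (n_cells, 2) array")
        if not np.all(np.isfinite(self.xy)):
            raise ValidationError("coordinates must be finite")

    @property
    def n_cells(self) -> int:
        return self.xy.shape[0]

    def subset(self, idx: Sequence[int]) -> "SpatialCoordinates":
        return SpatialCoordinates(self.xy[np.asarray(idx, dtype=int)])


@dataclass
class SharedGeneMap:
    """Alignment of the genes measured in both panels.

    ``st_indices[i]`` and ``sc_indices[i]`` are the column positions of
    ``shared_names[i]`` in the ST and SC matrices respectively.
    """

    shared_names: list[str]
    st_indices: np.ndarray
    sc_indices: np.ndarray

    def __post_init__(self) -> None:
        self.shared_names = [str(g) for g in self.shared_names]
        self.st_indices = np.asarray(self.st_indices, dtype=int)
        self.sc_indices = np.asarray(self.sc_indices, dtype=int)
        n = len(self.shared_names)
        if len(self.st_indices) != n or len(self.sc_indices) != n:
            raise ValidationError("shared map fields must have equal length")
        for arr in (self.st_indices, self.sc_indices):
            if len(np.unique(arr)) != n:
                raise ValidationError("shared map indices must be duplicate-free")

    def __len__(self) -> int:
        return len(self.shared_names)

    def restrict(self, names: Sequence[str]) -> "SharedGeneMap":
        """Keep only the listed shared genes, preserving order."""
        keep = set(names)
        sel = [i for i, g in enumerate(self.shared_names) if g in keep]
        return SharedGeneMap(
            [self.shared_names[i] for i in sel],
            self.st_indices[sel],
            self.sc_indices[sel],
        )


def _match_key(name: str, case_insensitive: bool) -> str:
    return name.casefold() if case_insensitive else name


def build_shared_map(
    st: ExpressionMatrix, sc: ExpressionMatrix, case_insensitive: bool = True
) -> SharedGeneMap:
    """Intersect the two gene panels (case-insensitive symbol match by default).

    Shared genes are ordered by their ST column order and named with the ST
    spelling. An empty intersection is legal but logged loudly, since
    translator training requires shared genes for the identity loss.
    """
    sc_pos = {_match_key(g, case_insensitive): j for j, g in enumerate(sc.gene_names)}
    names, st_idx, sc_idx = [], [], []
    for i, g in enumerate(st.gene_names):
        j = sc_pos.get(_match_key(g, case_insensitive))
        if j is not None:
            names.append(g)
            st_idx.append(i)
            sc_idx.append(j)
    if not names:
        logger.warning(
            "ST and SC gene panels share no genes; translator training will fail "
            "at the identity loss"
        )
    return SharedGeneMap(names, np.array(st_idx, dtype=int), np.array(sc_idx, dtype=int))


@dataclass
class PairedDataset:
    """An ST matrix (+ optional coordinates), an SC reference, and their shared-gene map."""

    st: ExpressionMatrix
    sc: ExpressionMatrix
    shared: SharedGeneMap
    st_coords: Optional[SpatialCoordinates] = None

    def __post_init__(self) -> None:
        if self.st_coords is not None and self.st_coords.n_cells != self.st.n_cells:
            raise ValidationError("coordinate rows must match ST cell count")
        for name, i, j in zip(
            self.shared.shared_names, self.shared.st_indices, self.shared.sc_indices
        ):
            if i >= self.st.n_genes or j >= self.sc.n_genes:
                raise ValidationError("shared map index out of range")
            if _match_key(self.st.gene_names[i], True) != _match_key(name, True):
                raise ValidationError(f"shared map mismatch at ST gene {name}")
            if _match_key(self.sc.gene_names[j], True) != _match_key(name, True):
                raise ValidationError(f"shared map mismatch at SC gene {name}")


@dataclass
class MetricReport:
    """Per-gene evaluation metrics, their averages, and optional diagnostics."""

    per_gene: pd.DataFrame  # index = gene name; columns pcc, ssim, rmse, wasserstein, js
    averages: dict[str, float] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    METRICS = ("pcc", "ssim", "rmse", "wasserstein", "js")

    def __post_init__(self) -> None:
        missing = [m for m in self.METRICS if m not in self.per_gene.columns]
        if missing:
            raise ValidationError(f"per-gene table missing columns {missing}")
        if not self.averages:
            self.averages = {m: float(self.per_gene[m].mean()) for m in self.METRICS}


# ---------------------------------------------------------------------------
# Readers / writers


def _dedup_genes(values: np.ndarray, genes: list[str]) -> tuple[np.ndarray, list[str]]:
    """Resolve duplicate gene names: keep the copy with the highest detection rate."""
    if len(set(genes)) == len(genes):
        return values, genes
    det = (values > 0).mean(axis=0)
    best: dict[str, int] = {}
    for i, g in enumerate(genes):
        if g not in best or det[i] > det[best[g]]:
            best[g] = i
    keep = sorted(best.values())
    dropped = len(genes) - len(keep)
    logger.warning("dropped %d duplicate gene column(s), keeping highest detection rate", dropped)
    return values[:, keep], [genes[i] for i in keep]


def read_expression(path, format: str, transposed: bool = False) -> ExpressionMatrix:
    """Load a raw expression matrix from h5ad, dense CSV/TSV, or MatrixMarket MTX.

    CSV/TSV files are cells-as-rows with a header row of gene names; a leading
    unnamed column is treated as cell identifiers. MTX requires ``genes.txt``
    and ``cells.txt`` sidecars next to the matrix file. Set ``transposed`` for
    genes-as-rows tables.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "h5ad":
        import anndata

        ad = anndata.read_h5ad(path)
        x = ad.X
        if not isinstance(x, np.ndarray):
            x = np.asarray(x.todense())
        values = np.asarray(x, dtype=np.float64)
        genes = [str(g) for g in ad.var_names]
        cells = [str(c) for c in ad.obs_names]
    elif format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        import csv as _csv

        with open(path, newline="") as fh:
            header = next(_csv.reader(fh, delimiter=sep))  # pandas mangles duplicate names
        try:
            df = pd.read_csv(path, sep=sep, header=None, skiprows=1)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise ValidationError(f"failed to parse {path}: {exc}") from exc
        if header and header[0].lower() in ("", "cell", "cell_id", "index"):
            cells = [str(c) for c in df.iloc[:, 0]]
            df = df.iloc[:, 1:]
            genes = [str(g) for g in header[1:]]
        else:
            cells = [f"cell{i}" for i in range(len(df))]
            genes = [str(g) for g in header]
        if len(genes) != df.shape[1]:
            raise ValidationError(
                f"{path}: header names {len(genes)} columns but rows have {df.shape[1]}"
            )
        if not all(np.issubdtype(d, np.number) for d in df.dtypes):
            bad = [genes[k] for k, d in enumerate(df.dtypes) if not np.issubdtype(d, np.number)]
            raise ValidationError(f"non-numeric column(s) {bad} in {path}")
        values = df.to_numpy(dtype=np.float64)
    elif format == "mtx":
        from scipy.io import mmread

        try:
            values = np.asarray(mmread(path).todense(), dtype=np.float64)
        except Exception as exc:
            raise ValidationError(f"failed to parse MTX {path}: {exc}") from exc
        gdir = path.parent
        gene_file, cell_file = gdir / "genes.txt", gdir / "cells.txt"
        if not gene_file.exists() or not cell_file.exists():
            raise FileNotFoundError("MTX requires genes.txt and cells.txt sidecars")
        genes = gene_file.read_text().split()
        cells = cell_file.read_text().split()
    else:
        raise ValueError(f"unknown format {format!r}")
    if transposed:
        values = values.T
        genes, cells = cells, genes
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise ValidationError(f"negative expression value at cell {i}, gene {j}")
    values, genes = _dedup_genes(values, genes)
    return ExpressionMatrix(values, genes, cells, stage="raw")


def write_expression(m: ExpressionMatrix, path, format: str,
                     coords: Optional[SpatialCoordinates] = None) -> None:
    """Write an expression matrix (and optional coordinates) in a supported format."""
    path = Path(path)
    if format == "h5ad":
        import anndata

        ad = anndata.AnnData(
            X=m.values.copy(),
            obs=pd.DataFrame(index=m.cell_ids),
            var=pd.DataFrame(index=m.gene_names),
        )
        if coords is not None:
            ad.obsm["spatial"] = coords.xy.copy()
        ad.write_h5ad(path)
    elif format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = pd.DataFrame(m.values, index=m.cell_ids, columns=m.gene_names)
        df.index.name = "cell_id"
        df.to_csv(path, sep=sep)
        if coords is not None:
            cdf = pd.DataFrame(coords.xy, index=m.cell_ids, columns=["x", "y"])
            cdf.index.name = "cell_id"
            cdf.to_csv(path.with_name(path.stem + "_coords" + path.suffix), sep=sep)
    elif format == "mtx":
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        mmwrite(str(path), csr_matrix(m.values))
        (path.parent / "genes.txt").write_text("\n".join(m.gene_names) + "\n")
        (path.parent / "cells.txt").write_text("\n".join(m.cell_ids) + "\n")
        if coords is not None:
            cdf = pd.DataFrame(coords.xy, index=m.cell_ids, columns=["x", "y"])
            cdf.index.name = "cell_id"
            cdf.to_csv(path.parent / "coords.csv")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_coordinates(path) -> SpatialCoordinates:
    """Read a coordinate table: CSV with x,y columns (first column = cell id)."""
    df = pd.read_csv(path, index_col=0)
    cols = [c for c in df.columns if c.lower() in ("x", "y")]
    if len(cols) == 2:
        return SpatialCoordinates(df[sorted(cols, key=str.lower)].to_numpy())
    return SpatialCoordinates(df.to_numpy()[:, :2])


def read_h5ad_coordinates(path) -> Optional[SpatialCoordinates]:
    import anndata

    ad = anndata.read_h5ad(path)
    if "spatial" in ad.obsm:
        return SpatialCoordinates(np.asarray(ad.obsm["spatial"], dtype=np.float64))
    return None


def write_report(report: MetricReport, path) -> None:
    """Serialize a MetricReport to JSON (bit-exact float round trip)."""
    payload = {
        "per_gene": {
            "genes": list(report.per_gene.index),
            "columns": list(report.per_gene.columns),
            "values": report.per_gene.to_numpy().tolist(),
        },
        "averages": report.averages,
        "diagnostics": _jsonable(report.diagnostics),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_report(path) -> MetricReport:
    try:
        payload = json.loads(Path(path).read_text())
        pg = payload["per_gene"]
    except (json.JSONDecodeError, KeyError) as exc:
        raise ValidationError(f"malformed report file {path}: {exc}") from exc
    df = pd.DataFrame(pg["values"], index=pg["genes"], columns=pg["columns"])
    return MetricReport(df, dict(payload["averages"]), payload.get("diagnostics", {}))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_model(bundle, path) -> None:
    """Save a trained ModelBundle as a single .npz archive with a JSON config block."""
    arrays, meta = bundle.state_arrays()
    arrays = dict(arrays)
    arrays["__config__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def read_model(path):
    from .networks import ModelBundle

    try:
        with np.load(path) as archive:
            arrays = {k: archive[k] for k in archive.files}
    except (zipfile.BadZipFile, OSError, ValueError) as exc:
        raise ValidationError(f"malformed model archive {path}: {exc}") from exc
    meta = json.loads(bytes(arrays.pop("__config__")).decode())
    return ModelBundle.from_state_arrays(arrays, meta)
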