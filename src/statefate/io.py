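"""Reading and writing expression matrices, labels and simulation results.

Expression matrices are cells x genes everywhere: rows are cells, columns are
genes, and all identifiers are strings.  Two on-disk layouts are accepted: a
dense TSV/CSV with a header row of gene names and a first column of cell ids,
and a Matrix Market triplet directory (``matrix.mtx`` in genes x cells
orientation with ``genes.tsv`` / ``barcodes.tsv`` sidecars, the 10x
convention).  Simulation snapshots go to a single HDF5 container.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

RESULT_FORMAT_VERSION = 1

#: highest admissible value of log2(g + 1); raw counts therefore cap at 2**16 - 1
LOG2_CAP = 16.0


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


@dataclass
class ExpressionMatrix:
    """A cells x genes non-negative expression matrix with string identifiers.

    ``log_scale`` records whether values are raw counts or log2(g + 1);
    several operations (perturbation, embedding) require a specific scale.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    labels: list[str] | None = None
    log_scale: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise DataError("expression values must be a 2-D array")
        n_cells, n_genes = self.values.shape
        if len(self.cell_ids) != n_cells:
            raise DataError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix rows"
            )
        if len(self.gene_ids) != n_genes:
            raise DataError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise DataError("duplicate gene ids")
        if len(set(self.cell_ids)) != n_cells:
            raise DataError("duplicate cell ids")
        if not np.all(np.isfinite(self.values)):
            raise DataError("expression values must be finite")
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise DataError(
                f"negative expression for cell {self.cell_ids[i]!r}, "
                f"gene {self.gene_ids[j]!r}"
            )
        if self.labels is not None:
            self.labels = [str(x) for x in self.labels]
            if len(self.labels) != n_cells:
                raise DataError("one label per cell required")
        if self.log_scale and float(self.values.max(initial=0.0)) > LOG2_CAP:
            # real data may exceed the cap in principle; warn, do not clip
            warnings.warn(
                f"log-scale values exceed the log2 cap of {LOG2_CAP}",
                stacklevel=2,
            )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, **kw) -> "ExpressionMatrix":
        return replace(self, values=values, **kw)


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Return a copy with every value replaced by log2(g + 1).

    Applying the transform to an already log-scaled matrix is an error.
    """
    if matrix.log_scale:
        raise DataError("matrix is already log-scaled")
    return matrix.with_values(np.log2(matrix.values + 1.0), log_scale=True)


def read_expression(path: str | Path, format: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix from a dense table or an MTX directory.

    ``format`` is one of ``"mtx_dir"`` or ``"dense"``; when omitted it is
    inferred from the path (directory -> MTX triplet, file -> dense table).
    """
    path = Path(path)
    if format is None:
        format = "mtx_dir" if path.is_dir() else "dense"
    if format == "mtx_dir":
        return _read_mtx_dir(path)
    if format == "dense":
        return _read_dense(path)
    raise DataError(f"unknown expression format {format!r}")


def _read_dense(path: Path) -> ExpressionMatrix:
    if not path.exists():
        raise DataError(f"no such file: {path}")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep, index_col=0)
    values = frame.to_numpy(dtype=float)
    cell_ids = [str(c) for c in frame.index]
    gene_ids = [str(g) for g in frame.columns]
    return ExpressionMatrix(values, gene_ids, cell_ids)


def _read_mtx_dir(path: Path) -> ExpressionMatrix:
    matrix_file = path / "matrix.mtx"
    genes_file = path / "genes.tsv"
    barcodes_file = path / "barcodes.tsv"
    for f in (matrix_file, genes_file, barcodes_file):
        if not f.exists():
            raise DataError(f"missing companion file: {f}")
    mat = scipy.io.mmread(matrix_file)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    genes = pd.read_csv(genes_file, sep="\t", header=None)[0].astype(str).tolist()
    cells = pd.read_csv(barcodes_file, sep="\t", header=None)[0].astype(str).tolist()
    # genes x cells on disk -> cells x genes in memory
    return ExpressionMatrix(np.asarray(mat, dtype=float).T, genes, cells)


def write_expression(matrix: ExpressionMatrix, path: str | Path,
                     format: str = "dense") -> None:
    """Write a matrix as a dense TSV/CSV or an MTX triplet directory."""
    path = Path(path)
    if format == "dense":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        frame = pd.DataFrame(matrix.values, index=matrix.cell_ids,
                             columns=matrix.gene_ids)
        frame.to_csv(path, sep=sep)
    elif format == "mtx_dir":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(path / "matrix.mtx",
                         scipy.sparse.coo_matrix(matrix.values.T))
        pd.Series(matrix.gene_ids).to_csv(path / "genes.tsv", sep="\t",
                                          header=False, index=False)
        pd.Series(matrix.cell_ids).to_csv(path / "barcodes.tsv", sep="\t",
                                          header=False, index=False)
    else:
        raise DataError(f"unknown expression format {format!r}")


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (cell_id, label) into a dict."""
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return dict(zip(frame[0], frame[1]))


@dataclass
class SimulationResult:
    """Time-stamped solver output for either geometry.

    For the continuum geometry ``snapshots`` is a list of (M1, M2) density
    arrays and ``grid_x`` / ``grid_y`` hold the grid axes.  For the graph
    geometry ``node_snapshots`` is (S, n_nodes) and ``edge_snapshots`` is one
    (S, n_interior) array per edge; ``edge_meta`` records (a, b, length,
    n_interior) per edge.
    """

    geometry: str
    times: np.ndarray
    mass_times: np.ndarray
    mass: np.ndarray
    s_values: np.ndarray
    snapshots: list[np.ndarray] = field(default_factory=list)
    grid_x: np.ndarray | None = None
    grid_y: np.ndarray | None = None
    node_snapshots: np.ndarray | None = None
    edge_snapshots: list[np.ndarray] = field(default_factory=list)
    edge_meta: list[tuple[str, str, float, int]] = field(default_factory=list)
    node_labels: list[str] = field(default_factory=list)
    type_labels: list[str] = field(default_factory=list)
    type_mass: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size > 1 and np.any(np.diff(self.times) < 0):
            raise DataError("snapshot times must be non-decreasing")


def write_result(result: SimulationResult, path: str | Path) -> None:
    """Store a :class:`SimulationResult` in a single HDF5 file."""
    if result.times.size > 1 and np.any(np.diff(result.times) < 0):
        raise DataError("snapshot times must be non-decreasing")
    with h5py.File(path, "w") as h5:
        h5.attrs["format_version"] = RESULT_FORMAT_VERSION
        h5.attrs["geometry"] = result.geometry
        h5.create_dataset("times", data=result.times)
        h5.create_dataset("mass_times", data=np.asarray(result.mass_times))
        h5.create_dataset("mass", data=np.asarray(result.mass))
        h5.create_dataset("s_values", data=np.asarray(result.s_values))
        if result.grid_x is not None:
            h5.create_dataset("grid_x", data=result.grid_x)
            h5.create_dataset("grid_y", data=result.grid_y)
        if result.snapshots:
            h5.create_dataset("snapshots", data=np.stack(result.snapshots))
        if result.node_snapshots is not None:
            h5.create_dataset("node_snapshots", data=result.node_snapshots)
            h5.attrs["node_labels"] = [s.encode() for s in result.node_labels]
            grp = h5.create_group("edges")
            for k, (arr, meta) in enumerate(
                    zip(result.edge_snapshots, result.edge_meta)):
                ds = grp.create_dataset(f"edge_{k}", data=arr)
                ds.attrs["a"], ds.attrs["b"] = meta[0], meta[1]
                ds.attrs["length"], ds.attrs["n_interior"] = meta[2], meta[3]
        if result.type_mass is not None:
            h5.create_dataset("type_mass", data=result.type_mass)
            h5.attrs["type_labels"] = [s.encode() for s in result.type_labels]


def _as_str(x) -> str:
    return x.decode() if isinstance(x, bytes) else str(x)


def read_result(path: str | Path) -> SimulationResult:
    """Read back a result written by :func:`write_result`."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    with h5py.File(path, "r") as h5:
        version = int(h5.attrs.get("format_version", -1))
        if version != RESULT_FORMAT_VERSION:
            raise DataError(
                f"result format version {version} != {RESULT_FORMAT_VERSION}"
            )
        kw: dict = dict(
            geometry=str(h5.attrs["geometry"]),
            times=h5["times"][()],
            mass_times=h5["mass_times"][()],
            mass=h5["mass"][()],
            s_values=h5["s_values"][()],
        )
        if "grid_x" in h5:
            kw["grid_x"] = h5["grid_x"][()]
            kw["grid_y"] = h5["grid_y"][()]
        if "snapshots" in h5:
            kw["snapshots"] = list(h5["snapshots"][()])
        if "node_snapshots" in h5:
            kw["node_snapshots"] = h5["node_snapshots"][()]
            kw["node_labels"] = [_as_str(b) for b in h5.attrs["node_labels"]]
            edges, meta = [], []
            grp = h5["edges"]
            for k in range(len(grp)):
                ds = grp[f"edge_{k}"]
                edges.append(ds[()])
                meta.append((str(ds.attrs["a"]), str(ds.attrs["b"]),
                             float(ds.attrs["length"]),
                             int(ds.attrs["n_interior"])))
            kw["edge_snapshots"] = edges
            kw["edge_meta"] = meta
        if "type_mass" in h5:
            kw["type_mass"] = h5["type_mass"][()]
            kw["type_labels"] = [_as_str(b) for b in h5.attrs["type_labels"]]
    return SimulationResult(**kw)
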