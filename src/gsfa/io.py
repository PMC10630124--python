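"""Data containers and readers for counts, guide assignments and covariates.

The on-disk 10x convention stores genes in rows; everything in memory is
cells x genes (matching the Y_{N x P} orientation of the model).
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "PerturbationMatrix",
    "CellMetadata",
    "DataError",
    "AlignmentError",
    "read_counts",
    "read_guides",
    "collapse_guide_name",
    "align",
]


class DataError(ValueError):
    """Structural problem in an input matrix (shape, type, ids)."""


class AlignmentError(ValueError):
    """Cell identifiers of two inputs cannot be reconciled."""


def _check_unique(ids, what: str) -> None:
    if len(set(ids)) != len(ids):
        dup = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
        raise DataError(f"duplicate {what}: {dup[:5]}")


@dataclass
class CountMatrix:
    """Cells x genes UMI count matrix with string identifiers.

    Entries must be nonnegative integers; duplicate cell or gene ids are
    rejected rather than merged.
    """

    counts: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise DataError("counts must be 2-dimensional (cells x genes)")
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise DataError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.cell_ids)} cell ids and {len(self.gene_ids)} gene ids"
            )
        if np.any(self.counts < 0):
            raise DataError("counts contain negative entries")
        if not np.allclose(self.counts, np.round(self.counts)):
            raise DataError("counts contain non-integral entries")
        self.counts = np.asarray(np.round(self.counts), dtype=np.int64)
        _check_unique(self.cell_ids, "cell ids")
        _check_unique(self.gene_ids, "gene ids")
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.cell_ids, columns=self.gene_ids)


@dataclass
class PerturbationMatrix:
    """Binary cells x perturbations indicator matrix G.

    Columns are perturbation *types* (one per target gene after guide
    collapsing).  ``negative_control_index`` optionally names the column of
    non-targeting control guides used for nonspecific-effect adjustment.
    """

    G: np.ndarray
    perturbation_names: list[str]
    cell_ids: list[str] | None = None
    negative_control_index: int | None = None

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G)
        if self.G.ndim != 2:
            raise DataError("G must be 2-dimensional (cells x perturbations)")
        if not np.isin(self.G, (0, 1)).all():
            raise DataError("perturbation matrix entries must be 0/1")
        self.G = self.G.astype(np.int8)
        if self.G.shape[1] != len(self.perturbation_names):
            raise DataError("perturbation_names length does not match G columns")
        _check_unique(self.perturbation_names, "perturbation names")
        if self.cell_ids is not None:
            if len(self.cell_ids) != self.G.shape[0]:
                raise DataError("cell_ids length does not match G rows")
            _check_unique(self.cell_ids, "cell ids")
        if self.negative_control_index is not None and not (
            0 <= self.negative_control_index < self.G.shape[1]
        ):
            raise DataError("negative_control_index out of range")

    @property
    def shape(self) -> tuple[int, int]:
        return self.G.shape

    def set_negative_control(self, name: str) -> None:
        """Designate the named perturbation column as the negative control."""
        if name not in self.perturbation_names:
            raise DataError(f"unknown perturbation {name!r}")
        self.negative_control_index = self.perturbation_names.index(name)

    def check_fittable(self) -> None:
        empty = [
            n
            for n, col in zip(self.perturbation_names, self.G.T)
            if int(col.sum()) == 0
        ]
        if empty:
            raise DataError(f"perturbation columns with no carrier cells: {empty}")


@dataclass
class CellMetadata:
    """Per-cell covariates and an optional binary group label."""

    covariates: np.ndarray | None = None
    covariate_names: list[str] = field(default_factory=list)
    group: np.ndarray | None = None
    cell_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if not self.covariate_names:
                self.covariate_names = [
                    f"cov{i}" for i in range(self.covariates.shape[1])
                ]
        if self.group is not None:
            self.group = np.asarray(self.group)
            if not np.isin(self.group, (0, 1)).all():
                raise DataError("group labels must be binary (0/1)")
            self.group = self.group.astype(np.int8)

    @property
    def n_cells(self) -> int | None:
        if self.covariates is not None:
            return self.covariates.shape[0]
        if self.group is not None:
            return self.group.shape[0]
        return None


# ---------------------------------------------------------------------------
# readers


def read_counts(path: str | Path, format: str = "mtx_dir") -> CountMatrix:
    """Read a UMI count matrix.

    Parameters
    ----------
    path
        A 10x-style MTX triplet directory (``matrix.mtx`` + ``barcodes.tsv`` +
        ``features.tsv``/``genes.tsv``), a dense TSV (rows = cells, first
        column cell ids, header gene ids), or an HDF5 container written by
        :func:`write_counts_h5`.
    format
        One of ``mtx_dir``, ``tsv``, ``h5``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "mtx_dir":
        return _read_mtx_dir(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return CountMatrix(df.to_numpy(), list(df.index), list(df.columns))
    if format == "h5":
        import h5py

        with h5py.File(path, "r") as f:
            counts = f["counts"][...]
            cells = [s.decode() for s in f["cell_ids"][...]]
            genes = [s.decode() for s in f["gene_ids"][...]]
        return CountMatrix(counts, cells, genes)
    raise ValueError(f"unknown counts format {format!r}")


def _read_mtx_dir(path: Path) -> CountMatrix:
    mtx = path / "matrix.mtx"
    if not mtx.exists():
        raise FileNotFoundError(mtx)
    try:
        mat = scipy.io.mmread(mtx)
    except ValueError as exc:
        raise DataError(f"malformed MatrixMarket file {mtx}: {exc}") from exc
    features = path / "features.tsv"
    if not features.exists():
        features = path / "genes.tsv"
    genes = pd.read_csv(features, sep="\t", header=None)[0].astype(str).tolist()
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)
    cells = barcodes[0].astype(str).tolist()
    dense = np.asarray(scipy.sparse.coo_matrix(mat).todense())
    # 10x stores genes in rows; transpose to cells x genes
    if dense.shape != (len(genes), len(cells)):
        raise DataError(
            f"matrix shape {dense.shape} does not match {len(genes)} features "
            f"x {len(cells)} barcodes"
        )
    return CountMatrix(dense.T, cells, genes)


def write_counts_h5(counts: CountMatrix, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=counts.counts)
        f.create_dataset("cell_ids", data=np.array(counts.cell_ids, dtype="S"))
        f.create_dataset("gene_ids", data=np.array(counts.gene_ids, dtype="S"))


def write_counts_mtx_dir(counts: CountMatrix, path: str | Path) -> None:
    """Write a 10x-style triplet directory (genes in rows)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        str(path / "matrix.mtx"), scipy.sparse.coo_matrix(counts.counts.T)
    )
    pd.Series(counts.gene_ids).to_csv(
        path / "features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(counts.cell_ids).to_csv(
        path / "barcodes.tsv", sep="\t", header=False, index=False
    )


_GUIDE_SUFFIX = re.compile(r"^(.+?)[_.\-]g?(?:RNA)?\d+$", re.IGNORECASE)


def collapse_guide_name(guide: str) -> str:
    """Collapse a guide name to its target gene (``GENE1_g2`` -> ``GENE1``)."""
    m = _GUIDE_SUFFIX.match(guide)
    return m.group(1) if m else guide


def read_guides(
    path: str | Path,
    counts: CountMatrix | None = None,
    collapse: bool = True,
    negative_control: str | None = None,
) -> PerturbationMatrix:
    """Read gRNA assignments and binarize, collapsing guides per target gene.

    Accepts either a long-format two-column TSV (cell_id, guide) or a
    cells x guides matrix TSV (first column cell ids, header guide names,
    numeric entries).  Guides targeting the same gene are merged by
    logical OR; any nonzero count is binarized to 1.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] == 2 and not pd.api.types.is_numeric_dtype(df.iloc[:, 1]):
        long = df.copy()
        long.columns = ["cell_id", "guide"]
        long["cell_id"] = long["cell_id"].astype(str)
        wide = pd.crosstab(long["cell_id"], long["guide"])
        # crosstab sorts cells; restore first-appearance order
        order = long["cell_id"].drop_duplicates().tolist()
        wide = wide.reindex(order)
    else:
        wide = pd.read_csv(path, sep="\t", index_col=0)
        wide.index = wide.index.astype(str)
    return guides_from_frame(
        wide, counts=counts, collapse=collapse, negative_control=negative_control
    )


def guides_from_frame(
    wide: pd.DataFrame,
    counts: CountMatrix | None = None,
    collapse: bool = True,
    negative_control: str | None = None,
) -> PerturbationMatrix:
    """Build a :class:`PerturbationMatrix` from a cells x guides table."""
    mat = (wide.to_numpy(dtype=float) != 0).astype(np.int8)
    names = [str(c) for c in wide.columns]
    if collapse:
        targets: list[str] = []
        for n in names:
            t = collapse_guide_name(n)
            if t not in targets:
                targets.append(t)
        collapsed = np.zeros((mat.shape[0], len(targets)), dtype=np.int8)
        for j, n in enumerate(names):
            collapsed[:, targets.index(collapse_guide_name(n))] |= mat[:, j]
        mat, names = collapsed, targets
    cell_ids = [str(c) for c in wide.index]
    if counts is not None:
        unknown = set(cell_ids) - set(counts.cell_ids)
        if unknown:
            raise AlignmentError(
                f"{len(unknown)} guide cell ids absent from the count matrix "
                f"(e.g. {sorted(unknown)[:3]})"
            )
    multi = int((mat.sum(axis=1) > 1).sum())
    if multi:
        logger.info("%d cells carry more than one perturbation type (kept)", multi)
    pm = PerturbationMatrix(mat, names, cell_ids=cell_ids)
    if negative_control is not None:
        pm.set_negative_control(negative_control)
    return pm


def align(
    counts: CountMatrix,
    guides: PerturbationMatrix,
    meta: CellMetadata | None = None,
) -> tuple[CountMatrix, PerturbationMatrix, CellMetadata | None]:
    """Restrict all inputs to the common cells, in the counts' order."""
    if guides.cell_ids is None:
        if guides.G.shape[0] != counts.shape[0]:
            raise AlignmentError(
                "guides carry no cell ids and row count differs from counts"
            )
        return counts, guides, meta
    common = [c for c in counts.cell_ids if c in set(guides.cell_ids)]
    if not common:
        raise AlignmentError("no overlapping cell ids between counts and guides")
    dropped = (len(counts.cell_ids) - len(common)) + (
        len(guides.cell_ids) - len(common)
    )
    if dropped:
        logger.info("align: dropped %d cells outside the id intersection", dropped)
    c_idx = [counts.cell_ids.index(c) for c in common]
    g_pos = {c: i for i, c in enumerate(guides.cell_ids)}
    g_idx = [g_pos[c] for c in common]
    counts2 = CountMatrix(counts.counts[c_idx], common, list(counts.gene_ids))
    guides2 = PerturbationMatrix(
        guides.G[g_idx],
        list(guides.perturbation_names),
        cell_ids=common,
        negative_control_index=guides.negative_control_index,
    )
    meta2 = meta
    if meta is not None and meta.cell_ids is not None:
        m_pos = {c: i for i, c in enumerate(meta.cell_ids)}
        missing = [c for c in common if c not in m_pos]
        if missing:
            raise AlignmentError(f"metadata missing {len(missing)} aligned cells")
        m_idx = [m_pos[c] for c in common]
        meta2 = CellMetadata(
            covariates=None if meta.covariates is None else meta.covariates[m_idx],
            covariate_names=list(meta.covariate_names),
            group=None if meta.group is None else meta.group[m_idx],
            cell_ids=common,
        )
    return counts2, guides2, meta2
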