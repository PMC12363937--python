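"""Labeled perturbation count matrices: containers, filtering, and IO.

The central object is :class:`ExpressionDataset`, a cells x genes raw-count
matrix with a per-cell perturbation label. Counts are kept raw (no log/CPM
normalization): the linear-response machinery downstream works on absolute
counts, and all first/second moments are taken on that scale. Optional
normalization hooks exist but default to off.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "ExpressionDataset",
    "FilterConfig",
    "DeltaExpression",
    "EmptyFilterError",
    "NoSharedGenesError",
    "normalize_perturbation_labels",
    "filter_dataset",
    "delta_expression",
    "align_genes",
    "read_expression",
    "write_expression",
]

#: final underscore- or dash-delimited token like ``_g1`` / ``-G12``
_GUIDE_SUFFIX = re.compile(r"[_-][gG]\d+$")


class EmptyFilterError(ValueError):
    """Raised when filtering removes all control cells or all perturbations."""


class NoSharedGenesError(ValueError):
    """Raised when two objects to be aligned share no gene ids."""


def _as_2d(counts) -> np.ndarray | sp.spmatrix:
    if sp.issparse(counts):
        return counts.tocsr()
    arr = np.asarray(counts)
    if arr.ndim != 2:
        raise ValueError(f"counts must be 2-D, got shape {arr.shape}")
    return arr


@dataclass
class ExpressionDataset:
    """A perturbation screen: raw counts with per-cell perturbation labels.

    Parameters
    ----------
    counts
        Non-negative raw counts, cells x genes (dense or CSR sparse).
    gene_ids, cell_ids
        Unique, ordered identifiers for columns / rows.
    perturbation
        Per-cell label; either ``control_label`` or a base perturbation name
        (conventionally the targeted gene id).
    control_label
        Label designating unperturbed cells.
    """

    counts: np.ndarray | sp.spmatrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    perturbation: np.ndarray
    control_label: str = "control"

    def __post_init__(self) -> None:
        self.counts = _as_2d(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.perturbation = np.asarray(self.perturbation, dtype=object)
        n_cells, n_genes = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match counts columns")
        if len(self.cell_ids) != n_cells:
            raise ValueError("cell_ids length does not match counts rows")
        if len(self.perturbation) != n_cells:
            raise ValueError("perturbation length does not match counts rows")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene_ids contain duplicates")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("cell_ids contain duplicates")
        if sp.issparse(self.counts):
            if self.counts.nnz and self.counts.min() < 0:
                raise ValueError("counts contain negative entries")
        else:
            if not np.all(np.isfinite(self.counts)):
                raise ValueError("counts contain non-finite entries")
            if self.counts.size and self.counts.min() < 0:
                raise ValueError("counts contain negative entries")

    # -- basic views ------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def control_mask(self) -> np.ndarray:
        return self.perturbation == self.control_label

    def perturbation_names(self) -> list[str]:
        """Distinct non-control labels, in order of first appearance."""
        seen: dict[str, None] = {}
        for lab in self.perturbation:
            if lab != self.control_label:
                seen.setdefault(lab, None)
        return list(seen)

    def dense_counts(self) -> np.ndarray:
        return self.counts.toarray() if sp.issparse(self.counts) else np.asarray(self.counts, dtype=float)

    def control_counts(self) -> np.ndarray:
        """Dense control-cell submatrix (cells x genes)."""
        sub = self.counts[self.control_mask]
        return sub.toarray() if sp.issparse(sub) else np.asarray(sub, dtype=float)

    def counts_for(self, perturbation: str) -> np.ndarray:
        mask = self.perturbation == perturbation
        if not mask.any():
            raise KeyError(f"unknown perturbation {perturbation!r}")
        sub = self.counts[mask]
        return sub.toarray() if sp.issparse(sub) else np.asarray(sub, dtype=float)

    def gene_means(self, cells: str = "all") -> np.ndarray:
        """Per-gene mean count over ``'all'`` or ``'control'`` cells."""
        if cells == "all":
            m = self.counts
        elif cells == "control":
            m = self.counts[self.control_mask]
        else:
            raise ValueError("cells must be 'all' or 'control'")
        mean = m.mean(axis=0)
        return np.asarray(mean).ravel()

    def subset(self, cell_idx=None, gene_idx=None) -> "ExpressionDataset":
        counts = self.counts
        cell_ids, pert, gene_ids = self.cell_ids, self.perturbation, self.gene_ids
        if cell_idx is not None:
            counts = counts[cell_idx]
            cell_ids = cell_ids[cell_idx]
            pert = pert[cell_idx]
        if gene_idx is not None:
            counts = counts[:, gene_idx]
            gene_ids = gene_ids[gene_idx]
        return ExpressionDataset(counts, gene_ids, cell_ids, pert, self.control_label)

    # -- AnnData bridge ---------------------------------------------------
    def to_anndata(self, label_key: str = "perturbation"):
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.copy() if sp.issparse(self.counts) else np.asarray(self.counts),
            obs=pd.DataFrame({label_key: pd.array(self.perturbation, dtype="str")},
                             index=pd.Index(self.cell_ids.astype(str), name="cell")),
            var=pd.DataFrame(index=pd.Index(self.gene_ids.astype(str), name="gene")),
        )
        adata.uns["control_label"] = self.control_label
        return adata

    @classmethod
    def from_anndata(cls, adata, label_key: str = "perturbation",
                     control_label: str | None = None) -> "ExpressionDataset":
        if label_key not in adata.obs.columns:
            raise KeyError(
                f"perturbation annotation {label_key!r} not found in obs "
                f"(available: {list(adata.obs.columns)})"
            )
        if control_label is None:
            control_label = adata.uns.get("control_label", "control")
        return cls(
            counts=adata.X.copy() if sp.issparse(adata.X) else np.asarray(adata.X),
            gene_ids=adata.var_names.to_numpy(dtype=object),
            cell_ids=adata.obs_names.to_numpy(dtype=object),
            perturbation=adata.obs[label_key].to_numpy(dtype=object),
            control_label=str(control_label),
        )


@dataclass(frozen=True)
class FilterConfig:
    """Pre-processing filter for perturbation screens.

    ``min_mean_expression`` keeps genes whose mean count over all cells is at
    least the threshold (1 count by default; lowered to 0.1 for sparse
    cross-dataset work). Measured perturbation-target genes are always kept
    when ``always_keep_perturbed_genes``. Perturbations with fewer than
    ``min_cells_per_perturbation`` cells are dropped entirely.
    """

    min_mean_expression: float = 1.0
    min_cells_per_perturbation: int = 100
    always_keep_perturbed_genes: bool = True
    #: which cells the gene-mean is computed over ('all' or 'control')
    mean_over: str = "all"

    def __post_init__(self) -> None:
        if self.min_mean_expression < 0:
            raise ValueError("min_mean_expression must be >= 0")
        if self.min_cells_per_perturbation < 1:
            raise ValueError("min_cells_per_perturbation must be >= 1")
        if self.mean_over not in ("all", "control"):
            raise ValueError("mean_over must be 'all' or 'control'")


@dataclass
class DeltaExpression:
    """Mean expression change of a perturbation: dX = <X>_u - <X>_0."""

    values: np.ndarray
    gene_ids: np.ndarray
    perturbation_name: str
    n_control: int
    n_perturbed: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.values.shape != (len(self.gene_ids),):
            raise ValueError("values and gene_ids lengths differ")
        if self.n_control < 1 or self.n_perturbed < 1:
            raise ValueError("need at least one control and one perturbed cell")


def normalize_perturbation_labels(labels: Sequence[str],
                                  control_label: str | None = None) -> list[str]:
    """Strip a trailing guide/replicate suffix (``_g1``, ``-g2``, ...) from labels.

    Only the final underscore- or dash-delimited token matching ``g<digits>``
    (case-insensitive) is removed, so multi-gene labels like
    ``"GENE1_GENE2_g2"`` lose only the guide token. The control label is never
    altered.
    """
    out = []
    for lab in labels:
        if not isinstance(lab, str) or not lab:
            raise ValueError("labels must be non-empty strings")
        if control_label is not None and lab == control_label:
            out.append(lab)
            continue
        stripped = _GUIDE_SUFFIX.sub("", lab)
        # never produce an empty label (e.g. a bare "g1")
        out.append(stripped if stripped else lab)
    return out


def filter_dataset(ds: ExpressionDataset, cfg: FilterConfig = FilterConfig()) -> ExpressionDataset:
    """Apply the gene-mean and cells-per-perturbation filters.

    Genes with mean count >= ``cfg.min_mean_expression`` are retained, plus all
    genes that appear as perturbation targets (matched by label == gene id).
    Perturbations with too few cells are removed with their cells; control
    cells are always retained. Gene and cell order is preserved.
    """
    means = ds.gene_means(cells=cfg.mean_over)
    keep_gene = means >= cfg.min_mean_expression
    if cfg.always_keep_perturbed_genes:
        targets = set(ds.perturbation_names())
        keep_gene |= np.array([g in targets for g in ds.gene_ids])
    if not keep_gene.any():
        raise EmptyFilterError("no genes survive the expression filter")

    labels, counts_per = np.unique(ds.perturbation, return_counts=True)
    big_enough = {
        lab for lab, c in zip(labels, counts_per)
        if lab == ds.control_label or c >= cfg.min_cells_per_perturbation
    }
    keep_cell = np.array([lab in big_enough for lab in ds.perturbation])

    out = ds.subset(cell_idx=np.where(keep_cell)[0], gene_idx=np.where(keep_gene)[0])
    if not out.control_mask.any():
        raise EmptyFilterError("no control cells remain after filtering")
    if not out.perturbation_names():
        raise EmptyFilterError("no perturbation survives the min-cells filter")
    return out


def delta_expression(ds: ExpressionDataset, perturbation: str) -> DeltaExpression:
    """Per-gene mean over perturbed cells minus mean over control cells (raw counts)."""
    pert = ds.counts_for(perturbation)
    ctrl_mask = ds.control_mask
    if not ctrl_mask.any():
        raise ValueError("dataset has no control cells")
    ctrl = ds.control_counts()
    return DeltaExpression(
        values=pert.mean(axis=0) - ctrl.mean(axis=0),
        gene_ids=ds.gene_ids.copy(),
        perturbation_name=perturbation,
        n_control=ctrl.shape[0],
        n_perturbed=pert.shape[0],
    )


def _restrict_to_genes(obj, genes: np.ndarray):
    """Restrict a gene-indexed object to ``genes`` (in that order)."""
    pos = {g: i for i, g in enumerate(obj.gene_ids)}
    idx = np.array([pos[g] for g in genes], dtype=int)
    if isinstance(obj, ExpressionDataset):
        return obj.subset(gene_idx=idx)
    if isinstance(obj, DeltaExpression):
        return DeltaExpression(obj.values[idx], genes.copy(), obj.perturbation_name,
                               obj.n_control, obj.n_perturbed)
    if hasattr(obj, "sigma"):  # CovarianceModel, without importing it here
        return replace(obj, sigma=obj.sigma[np.ix_(idx, idx)], gene_ids=genes.copy())
    raise TypeError(f"cannot align object of type {type(obj).__name__}")


def align_genes(a, b):
    """Restrict two gene-indexed objects to their shared genes.

    Both are returned restricted to the intersection of their ``gene_ids``
    in a single canonical (lexicographic) order, so covariance matrices from
    one dataset can be applied to expression changes from another.
    """
    shared = sorted(set(a.gene_ids) & set(b.gene_ids))
    if not shared:
        raise NoSharedGenesError("gene id intersection is empty")
    genes = np.asarray(shared, dtype=object)
    return _restrict_to_genes(a, genes), _restrict_to_genes(b, genes)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_expression(path, fmt: str | None = None, label_key: str = "perturbation",
                    control_label: str = "control") -> ExpressionDataset:
    """Read a labeled count matrix from ``.h5ad`` or an MTX directory.

    The MTX directory layout is ``matrix.mtx`` plus ``genes.tsv``,
    ``barcodes.tsv`` and ``labels.tsv`` (one entry per line). The matrix may be
    stored either cells x genes or genes x cells; orientation is resolved
    against the id files.
    """
    path = Path(path)
    if fmt is None:
        fmt = "h5ad" if path.suffix == ".h5ad" else "mtx_dir"
    if fmt == "h5ad":
        import anndata as ad

        return ExpressionDataset.from_anndata(ad.read_h5ad(path), label_key=label_key,
                                              control_label=control_label)
    if fmt == "mtx_dir":
        import scipy.io as sio

        mat = sp.csr_matrix(sio.mmread(path / "matrix.mtx"))
        genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0].to_numpy(dtype=object)
        cells = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].to_numpy(dtype=object)
        labels_path = path / "labels.tsv"
        if not labels_path.exists():
            raise KeyError("labels.tsv with per-cell perturbation labels is required")
        labels = pd.read_csv(labels_path, sep="\t", header=None)[0].to_numpy(dtype=object)
        if mat.shape == (len(genes), len(cells)) and mat.shape[0] != mat.shape[1]:
            mat = mat.T.tocsr()
        if mat.shape != (len(cells), len(genes)):
            raise ValueError(
                f"matrix shape {mat.shape} matches neither (cells, genes)="
                f"({len(cells)}, {len(genes)}) nor its transpose"
            )
        return ExpressionDataset(mat, genes, cells, labels, control_label)
    raise ValueError(f"unknown format {fmt!r}")


def write_expression(ds: ExpressionDataset, path, label_key: str = "perturbation") -> None:
    """Write to ``.h5ad`` (anything else raises)."""
    path = Path(path)
    if path.suffix != ".h5ad":
        raise ValueError("only .h5ad output is supported")
    ds.to_anndata(label_key=label_key).write_h5ad(path)
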