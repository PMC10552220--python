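"""Atlas and query data models, container I/O, and the common gene space.

An atlas is a metacell x gene UMI count matrix with gene masks (feature /
noisy / lateral), one type label per metacell, and a short list of
"essential" marker genes per type.  A query is just a metacell x gene UMI
count matrix.  Both are read from h5ad containers (metacells as
observations, genes as variables) or from an MTX + TSV sidecar bundle.
All downstream computation happens on the intersection of the two gene
universes, in atlas gene order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "DataModelError",
    "GeneMasks",
    "AtlasModel",
    "QueryModel",
    "CommonGeneSpace",
    "load_atlas",
    "load_query",
    "save_atlas",
    "save_query",
    "intersect_genes",
]


class DataModelError(ValueError):
    """A container or model violated a structural invariant."""


def _as_dense_counts(matrix, *, field_name: str) -> np.ndarray:
    """Validate and densify a count matrix: finite, non-negative, integral."""
    if sparse.issparse(matrix):
        matrix = matrix.toarray()
    counts = np.asarray(matrix)
    if counts.ndim != 2:
        raise DataModelError(f"{field_name}: expected a 2-D matrix, got shape {counts.shape}")
    if not np.issubdtype(counts.dtype, np.number):
        raise DataModelError(f"{field_name}: non-numeric count matrix")
    counts = counts.astype(np.float64)
    if not np.all(np.isfinite(counts)):
        raise DataModelError(f"{field_name}: non-finite entries in count matrix")
    if (counts < 0).any():
        raise DataModelError(f"{field_name}: negative entries in count matrix")
    if not np.allclose(counts, np.rint(counts)):
        raise DataModelError(f"{field_name}: non-integer entries in count matrix")
    return np.rint(counts).astype(np.int64)


def _check_gene_names(names: Sequence[str], *, field_name: str) -> list[str]:
    names = [str(n) for n in names]
    if len(set(names)) != len(names):
        dups = sorted({n for n in names if names.count(n) > 1})
        raise DataModelError(f"{field_name}: duplicate gene names {dups[:5]} (ambiguous mapping)")
    return names


@dataclass(frozen=True)
class GeneMasks:
    """Feature / noisy / lateral gene sets of an atlas.

    Feature genes drive the fit; noisy and lateral genes are never used as
    negative evidence.  Lateral genes are forbidden from being features.
    """

    feature: frozenset[str] = frozenset()
    noisy: frozenset[str] = frozenset()
    lateral: frozenset[str] = frozenset()

    def validate(self, universe: Sequence[str]) -> None:
        universe_set = set(universe)
        for name, members in (("feature", self.feature), ("noisy", self.noisy), ("lateral", self.lateral)):
            unknown = members - universe_set
            if unknown:
                raise DataModelError(f"masks.{name}: genes outside the atlas universe: {sorted(unknown)[:5]}")
        overlap = self.feature & self.lateral
        if overlap:
            raise DataModelError(f"masks.feature: lateral genes marked as features: {sorted(overlap)[:5]}")


@dataclass
class AtlasModel:
    """Reference atlas: counts, gene masks, type labels, essential genes."""

    umis: np.ndarray  # (metacells, genes) int64
    gene_names: list[str]
    masks: GeneMasks
    types: list[str]  # one label per metacell
    essential: dict[str, frozenset[str]]  # type -> essential genes
    metacell_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.umis = _as_dense_counts(self.umis, field_name="umis")
        self.gene_names = _check_gene_names(self.gene_names, field_name="gene_names")
        if self.umis.shape[1] != len(self.gene_names):
            raise DataModelError("gene_names: length does not match the count matrix")
        if len(self.types) != self.umis.shape[0]:
            raise DataModelError("types: need exactly one type label per metacell")
        self.types = [str(t) for t in self.types]
        if not self.metacell_names:
            self.metacell_names = [f"MC{j}" for j in range(self.umis.shape[0])]
        totals = self.umis.sum(axis=1)
        if (totals <= 0).any():
            bad = int(np.flatnonzero(totals <= 0)[0])
            raise DataModelError(f"umis: metacell {self.metacell_names[bad]!r} has zero total UMIs")
        self.masks.validate(self.gene_names)
        universe = set(self.gene_names)
        self.essential = {str(t): frozenset(map(str, genes)) for t, genes in self.essential.items()}
        for t, genes in self.essential.items():
            unknown = genes - universe
            if unknown:
                raise DataModelError(f"essential[{t!r}]: genes outside the atlas universe: {sorted(unknown)[:5]}")

    @property
    def n_metacells(self) -> int:
        return self.umis.shape[0]

    @property
    def n_genes(self) -> int:
        return self.umis.shape[1]

    @property
    def type_names(self) -> list[str]:
        return sorted(set(self.types))

    def drop_genes(self, genes: Sequence[str]) -> "AtlasModel":
        """Return a copy with the given gene columns removed (pre-exclusion)."""
        drop = set(genes)
        keep = [i for i, g in enumerate(self.gene_names) if g not in drop]
        kept_names = [self.gene_names[i] for i in keep]
        kept = set(kept_names)
        return AtlasModel(
            umis=self.umis[:, keep],
            gene_names=kept_names,
            masks=GeneMasks(
                feature=self.masks.feature & kept,
                noisy=self.masks.noisy & kept,
                lateral=self.masks.lateral & kept,
            ),
            types=list(self.types),
            essential={t: genes & kept for t, genes in self.essential.items()},
            metacell_names=list(self.metacell_names),
        )


@dataclass
class QueryModel:
    """Query dataset: a metacell x gene UMI count matrix."""

    umis: np.ndarray
    gene_names: list[str]
    cell_counts: Optional[np.ndarray] = None  # reporting only
    metacell_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.umis = _as_dense_counts(self.umis, field_name="umis")
        self.gene_names = _check_gene_names(self.gene_names, field_name="gene_names")
        if self.umis.shape[1] != len(self.gene_names):
            raise DataModelError("gene_names: length does not match the count matrix")
        if not self.metacell_names:
            self.metacell_names = [f"Q{j}" for j in range(self.umis.shape[0])]
        totals = self.umis.sum(axis=1)
        if (totals <= 0).any():
            bad = int(np.flatnonzero(totals <= 0)[0])
            raise DataModelError(f"umis: metacell {self.metacell_names[bad]!r} has zero total UMIs")
        if self.cell_counts is not None:
            self.cell_counts = np.asarray(self.cell_counts, dtype=np.int64)
            if self.cell_counts.shape != (self.umis.shape[0],):
                raise DataModelError("cell_counts: one entry per metacell required")

    @property
    def n_metacells(self) -> int:
        return self.umis.shape[0]

    @property
    def n_genes(self) -> int:
        return self.umis.shape[1]


@dataclass(frozen=True)
class CommonGeneSpace:
    """Ordered gene intersection of a query and an atlas, with column maps."""

    genes: tuple[str, ...]
    query_index: np.ndarray  # columns into the query matrix
    atlas_index: np.ndarray  # columns into the atlas matrix

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def position(self, gene: str) -> int:
        return self.genes.index(gene)


def intersect_genes(
    atlas: AtlasModel,
    query: QueryModel,
    *,
    case_fold: bool = False,
    min_feature_genes: int = 2,
) -> CommonGeneSpace:
    """Intersect the atlas and query gene universes, in atlas gene order.

    Matching is by exact identifier equality (optionally case-folded); no
    alias translation is attempted.  Raises if the intersection is empty or
    carries fewer than ``min_feature_genes`` atlas feature genes, in which
    case projection is impossible.
    """
    fold = (lambda g: g.casefold()) if case_fold else (lambda g: g)
    query_pos = {fold(g): i for i, g in enumerate(query.gene_names)}
    genes: list[str] = []
    q_idx: list[int] = []
    a_idx: list[int] = []
    for j, g in enumerate(atlas.gene_names):
        i = query_pos.get(fold(g))
        if i is not None:
            genes.append(g)
            q_idx.append(i)
            a_idx.append(j)
    if not genes:
        raise DataModelError("empty common gene space: query and atlas share no genes")
    n_features = len(set(genes) & atlas.masks.feature)
    if n_features < min_feature_genes:
        raise DataModelError(
            f"common gene space holds only {n_features} atlas feature genes "
            f"(need at least {min_feature_genes}); projection impossible"
        )
    return CommonGeneSpace(
        genes=tuple(genes),
        query_index=np.asarray(q_idx, dtype=np.int64),
        atlas_index=np.asarray(a_idx, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# container I/O
# ---------------------------------------------------------------------------

_MASK_COLUMNS = {"feature": "feature_gene", "noisy": "noisy_gene", "lateral": "lateral_gene"}


def _is_mtx_bundle(path: Path) -> bool:
    return path.is_dir()


def load_atlas(path, *, exclude_genes: Optional[Sequence[str]] = None) -> AtlasModel:
    """Load and validate an atlas from an h5ad container or an MTX bundle.

    ``exclude_genes`` drops the listed gene columns before any computation,
    for users starting from raw matrices that still carry e.g. mitochondrial
    genes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"atlas container not found: {path}")
    if _is_mtx_bundle(path):
        atlas = _load_atlas_mtx(path)
    else:
        atlas = _load_atlas_h5ad(path)
    if exclude_genes:
        atlas = atlas.drop_genes(exclude_genes)
    return atlas


def _load_atlas_h5ad(path: Path) -> AtlasModel:
    import anndata as ad

    adata = ad.read_h5ad(path)
    if "type" not in adata.obs.columns:
        raise DataModelError("types: missing metacell annotation column 'type'")
    masks = {}
    for key, column in _MASK_COLUMNS.items():
        if column in adata.var.columns:
            masks[key] = frozenset(adata.var.index[np.asarray(adata.var[column], dtype=bool)])
        else:
            masks[key] = frozenset()
    essential_raw = adata.uns.get("essential_genes_of_type", {})
    essential = {str(t): frozenset(np.atleast_1d(genes).astype(str)) for t, genes in dict(essential_raw).items()}
    return AtlasModel(
        umis=adata.X,
        gene_names=list(adata.var_names),
        masks=GeneMasks(**masks),
        types=[str(t) for t in adata.obs["type"]],
        essential=essential,
        metacell_names=list(adata.obs_names),
    )


def _load_atlas_mtx(path: Path) -> AtlasModel:
    umis, gene_names, meta = _load_mtx_common(path)
    if "type" not in meta.columns:
        raise DataModelError("types: metacells.tsv is missing the 'type' column")
    masks_path = path / "masks.tsv"
    masks = GeneMasks()
    if masks_path.exists():
        mdf = pd.read_csv(masks_path, sep="\t").set_index("gene")
        kw = {}
        for key, column in _MASK_COLUMNS.items():
            if column in mdf.columns:
                kw[key] = frozenset(mdf.index[mdf[column].astype(bool)].astype(str))
        masks = GeneMasks(**kw)
    essential: dict[str, frozenset[str]] = {}
    essential_path = path / "essential.tsv"
    if essential_path.exists():
        edf = pd.read_csv(essential_path, sep="\t")
        for t, group in edf.groupby("type"):
            essential[str(t)] = frozenset(group["gene"].astype(str))
    return AtlasModel(
        umis=umis,
        gene_names=gene_names,
        masks=masks,
        types=[str(t) for t in meta["type"]],
        essential=essential,
        metacell_names=[str(m) for m in meta["metacell"]],
    )


def load_query(path) -> QueryModel:
    """Load and validate a query from an h5ad container or an MTX bundle."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"query container not found: {path}")
    if _is_mtx_bundle(path):
        umis, gene_names, meta = _load_mtx_common(path)
        cells = meta["cells"].to_numpy() if "cells" in meta.columns else None
        return QueryModel(
            umis=umis,
            gene_names=gene_names,
            cell_counts=cells,
            metacell_names=[str(m) for m in meta["metacell"]],
        )
    import anndata as ad

    adata = ad.read_h5ad(path)
    cells = np.asarray(adata.obs["cells"]) if "cells" in adata.obs.columns else None
    return QueryModel(
        umis=adata.X,
        gene_names=list(adata.var_names),
        cell_counts=cells,
        metacell_names=list(adata.obs_names),
    )


def _load_mtx_common(path: Path) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    matrix_path = path / "matrix.mtx"
    if not matrix_path.exists():
        raise DataModelError(f"umis: missing matrix.mtx in bundle {path}")
    umis = spio.mmread(matrix_path)
    genes = pd.read_csv(path / "genes.tsv", sep="\t")
    meta = pd.read_csv(path / "metacells.tsv", sep="\t")
    gene_names = [str(g) for g in genes["gene"]]
    return umis, gene_names, meta


def _to_anndata(umis: np.ndarray, gene_names: list[str], metacell_names: list[str]):
    import anndata as ad

    return ad.AnnData(
        X=sparse.csr_matrix(umis.astype(np.float32)),
        obs=pd.DataFrame(index=pd.Index(metacell_names, name="metacell")),
        var=pd.DataFrame(index=pd.Index(gene_names, name="gene")),
    )


def save_atlas(atlas: AtlasModel, path) -> None:
    """Write an atlas to an h5ad container (``.h5ad``) or an MTX bundle (dir)."""
    path = Path(path)
    if path.suffix == ".h5ad":
        adata = _to_anndata(atlas.umis, atlas.gene_names, atlas.metacell_names)
        adata.obs["type"] = pd.Categorical(atlas.types)
        for key, column in _MASK_COLUMNS.items():
            members = getattr(atlas.masks, key)
            adata.var[column] = np.asarray([g in members for g in atlas.gene_names], dtype=bool)
        adata.uns["essential_genes_of_type"] = {t: sorted(genes) for t, genes in atlas.essential.items()}
        adata.write_h5ad(path)
        return
    path.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(path / "matrix.mtx"), sparse.coo_matrix(atlas.umis))
    pd.DataFrame({"gene": atlas.gene_names}).to_csv(path / "genes.tsv", sep="\t", index=False)
    pd.DataFrame({"metacell": atlas.metacell_names, "type": atlas.types}).to_csv(
        path / "metacells.tsv", sep="\t", index=False
    )
    masks = pd.DataFrame({"gene": atlas.gene_names})
    for key, column in _MASK_COLUMNS.items():
        members = getattr(atlas.masks, key)
        masks[column] = [int(g in members) for g in atlas.gene_names]
    masks.to_csv(path / "masks.tsv", sep="\t", index=False)
    rows = [(t, g) for t, genes in sorted(atlas.essential.items()) for g in sorted(genes)]
    pd.DataFrame(rows, columns=["type", "gene"]).to_csv(path / "essential.tsv", sep="\t", index=False)


def save_query(query: QueryModel, path) -> None:
    """Write a query to an h5ad container (``.h5ad``) or an MTX bundle (dir)."""
    path = Path(path)
    if path.suffix == ".h5ad":
        adata = _to_anndata(query.umis, query.gene_names, query.metacell_names)
        if query.cell_counts is not None:
            adata.obs["cells"] = query.cell_counts
        adata.write_h5ad(path)
        return
    path.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(path / "matrix.mtx"), sparse.coo_matrix(query.umis))
    pd.DataFrame({"gene": query.gene_names}).to_csv(path / "genes.tsv", sep="\t", index=False)
    meta = pd.DataFrame({"metacell": query.metacell_names})
    if query.cell_counts is not None:
        meta["cells"] = query.cell_counts
    meta.to_csv(path / "metacells.tsv", sep="\t", index=False)
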