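"""Result assembly, per-metacell / per-gene QC, and result container I/O.

The core result is the query-by-atlas weight matrix plus the corrected
query UMIs and the projected UMIs.  On top of that the per-metacell ledger
records the projected (and possibly composite) type, misfit counts,
essential-gene misfit fractions, the similar mask and R2; the per-gene
ledger records correction factors and the fitted masks per type.  The
misfit QC is a pure function of the stored fold deviations, so it can be
recomputed at a different threshold without re-running the projection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .config import ProjectionConfig

logger = logging.getLogger(__name__)

__all__ = [
    "ProjectionResult",
    "compute_r2",
    "recompute_misfits",
    "write_result",
    "load_result",
]


def compute_r2(e_q: np.ndarray, e_p: np.ndarray, fitted_masks: Sequence[np.ndarray]) -> np.ndarray:
    """Squared Pearson correlation between observed and projected expression.

    Computed per metacell over its fitted genes, in log-expression space.
    Metacells with fewer than 2 fitted genes or a zero-variance side get 0.
    """
    n = e_q.shape[0]
    r2 = np.zeros(n)
    for i in range(n):
        mask = np.asarray(fitted_masks[i], dtype=bool)
        if int(mask.sum()) < 2:
            logger.debug("metacell %d has <2 fitted genes; r2 set to 0", i)
            continue
        x = e_q[i, mask]
        y = e_p[i, mask]
        xc = x - x.mean()
        yc = y - y.mean()
        denom = np.linalg.norm(xc) * np.linalg.norm(yc)
        if denom == 0:
            continue
        r = float(xc @ yc / denom)
        r2[i] = min(r * r, 1.0)
    return r2


@dataclass
class ProjectionResult:
    """Everything the projection pipeline emits for one query/atlas pair."""

    # identity
    query_metacells: list[str]
    query_genes: list[str]  # the common genes, atlas order
    atlas_metacells: list[str]
    atlas_types: list[str]  # per atlas metacell
    query_umis: np.ndarray  # original query counts over the common genes
    query_all_gene_names: list[str] = field(default_factory=list)
    common_query_index: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))

    # core matrices (all over the common genes)
    weights: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    corrected_fractions: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    projected_fractions: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    totals: np.ndarray = field(default_factory=lambda: np.zeros(0))
    lfold: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    delta: np.ndarray = field(default_factory=lambda: np.zeros((0, 0), dtype=bool))
    profile_umis: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))

    # masks over the common genes
    feature_mask: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    noisy_mask: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    lateral_mask: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    kept_mask: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    fitted_masks: np.ndarray = field(default_factory=lambda: np.zeros((0, 0), dtype=bool))
    skewed_by_type: Dict[str, np.ndarray] = field(default_factory=dict)
    essential_positions: Dict[str, list[int]] = field(default_factory=dict)

    # per-gene annotations
    correction_factor: np.ndarray = field(default_factory=lambda: np.zeros(0))
    correlated_mask: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    fit_correlation: np.ndarray = field(default_factory=lambda: np.zeros(0))

    # per-metacell annotations
    projected_type: list[str] = field(default_factory=list)
    composite_type: list[str] = field(default_factory=list)
    misfit_count: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    misfit_essential_fraction: np.ndarray = field(default_factory=lambda: np.zeros(0))
    similar: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    r2: np.ndarray = field(default_factory=lambda: np.zeros(0))
    anchors: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))

    config: ProjectionConfig = field(default_factory=ProjectionConfig)

    @property
    def n_query(self) -> int:
        return len(self.query_metacells)

    @property
    def n_genes(self) -> int:
        return len(self.query_genes)

    @property
    def n_query_features(self) -> int:
        return int(self.feature_mask.sum())

    @property
    def corrected_umis(self) -> np.ndarray:
        return self.corrected_fractions * self.totals[:, None]

    @property
    def projected_umis(self) -> np.ndarray:
        return np.rint(self.projected_fractions * self.totals[:, None])

    @property
    def metacell_qc(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "projected_type": self.projected_type,
                "composite_type": self.composite_type,
                "misfit_genes": self.misfit_count,
                "misfit_essential_fraction": self.misfit_essential_fraction,
                "similar": self.similar,
                "r2": self.r2,
                "fitted_genes": self.fitted_masks.sum(axis=1),
                "anchor": [self.atlas_metacells[a] for a in self.anchors],
            },
            index=pd.Index(self.query_metacells, name="metacell"),
        )

    @property
    def gene_qc(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "atlas_gene": np.ones(self.n_genes, dtype=bool),
                "atlas_feature": self.feature_mask,
                "correlated_gene": self.correlated_mask,
                "correction_factor": self.correction_factor,
                "fit_correlation": self.fit_correlation,
                "noisy_gene": self.noisy_mask,
                "lateral_gene": self.lateral_mask,
            },
            index=pd.Index(self.query_genes, name="gene"),
        )
        for t in sorted(set(self.projected_type) | set(self.skewed_by_type)):
            df[f"fitted_of_{t}"] = self.fitted_mask_of_type(t)
        return df

    def fitted_mask_of_type(self, type_name: str) -> np.ndarray:
        skew = self.skewed_by_type.get(type_name, np.zeros(self.n_genes, dtype=bool))
        return self.kept_mask & ~skew

    @property
    def type_skewed_genes(self) -> pd.DataFrame:
        rows = [
            (t, self.query_genes[g])
            for t in sorted(self.skewed_by_type)
            for g in np.flatnonzero(self.skewed_by_type[t])
        ]
        return pd.DataFrame(rows, columns=["type", "gene"])


def _statuses_from_delta(
    result: ProjectionResult,
    delta: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Misfit counts, essential fractions, and the similar mask from a delta matrix."""
    cfg = result.config
    n = result.n_query
    misfit = np.zeros(n, dtype=np.int64)
    ess = np.zeros(n)
    for i in range(n):
        misfit[i] = int(delta[i, result.fitted_masks[i]].sum())
        positions: list[int] = list(result.essential_positions.get(result.projected_type[i], []))
        if result.composite_type[i]:
            positions = sorted(set(positions) | set(result.essential_positions.get(result.composite_type[i], [])))
        ess[i] = float(np.mean(delta[i, positions])) if positions else 0.0
    unassigned = (misfit > cfg.max_misfit) | (ess >= cfg.max_essential_fraction)
    enough_fitted = result.fitted_masks.sum(axis=1) >= cfg.min_fitted_feature_fraction * result.n_query_features
    similar = ~unassigned & enough_fitted
    return misfit, ess, similar


def recompute_misfits(
    result: ProjectionResult,
    new_max_lfold: float,
    *,
    min_umis: Optional[int] = None,
) -> ProjectionResult:
    """Re-threshold the stored fold deviations without re-running projection.

    Returns a new result whose delta, misfit counts, essential fractions and
    similar mask reflect the new threshold; weights, types and R2 are kept.
    Recomputing at the original threshold reproduces the original QC.
    """
    cfg = result.config.with_overrides(max_lfold=new_max_lfold, min_umis=min_umis)
    excluded = result.noisy_mask | result.lateral_mask
    delta = (np.abs(result.lfold) > cfg.max_lfold) & (result.profile_umis >= cfg.min_umis)
    delta &= ~excluded[None, :]
    for i, t in enumerate(result.projected_type):
        for label in filter(None, (t, result.composite_type[i])):
            skew = result.skewed_by_type.get(label)
            if skew is not None and skew.any():
                delta[i, skew] = False
    new = replace(result, config=cfg)
    new.delta = delta
    misfit, ess, similar = _statuses_from_delta(new, delta)
    new.misfit_count = misfit
    new.misfit_essential_fraction = ess
    new.similar = similar
    return new


# ---------------------------------------------------------------------------
# container I/O
# ---------------------------------------------------------------------------


def write_result(result: ProjectionResult, path) -> None:
    """Write the result as an augmented query h5ad plus flat TSV summaries.

    The container holds the original query counts as X (over all query
    genes), layers with the corrected and projected UMIs and the fold
    deviations, the query-by-atlas weight matrix, and all per-metacell and
    per-gene annotation columns.  ``metacell_qc.tsv``, ``gene_qc.tsv`` and
    ``type_skewed_genes.tsv`` are written next to the container.
    """
    import anndata as ad

    path = Path(path)
    try:
        n_all = len(result.query_all_gene_names)
        nq = result.n_query
        qidx = result.common_query_index

        def widen(matrix: np.ndarray, fill: float = 0.0) -> np.ndarray:
            wide = np.full((nq, n_all), fill)
            wide[:, qidx] = matrix
            return wide

        x = np.zeros((nq, n_all))
        x[:, qidx] = result.query_umis
        adata = ad.AnnData(
            X=sparse.csr_matrix(x),
            obs=pd.DataFrame(index=pd.Index(result.query_metacells, name="metacell")),
            var=pd.DataFrame(index=pd.Index(result.query_all_gene_names, name="gene")),
        )
        adata.layers["corrected_umis"] = sparse.csr_matrix(widen(result.corrected_umis))
        adata.layers["projected_umis"] = sparse.csr_matrix(widen(result.projected_umis))
        adata.layers["lfold"] = sparse.csr_matrix(widen(result.lfold))
        adata.layers["profile_umis"] = sparse.csr_matrix(widen(result.profile_umis))
        adata.obsm["atlas_weights"] = sparse.csr_matrix(result.weights)

        qc = result.metacell_qc
        for column in qc.columns:
            adata.obs[column] = qc[column].to_numpy()

        in_common = np.zeros(n_all, dtype=bool)
        in_common[qidx] = True
        adata.var["atlas_gene"] = in_common

        def widen_gene(values: np.ndarray, fill) -> np.ndarray:
            wide = np.full(n_all, fill, dtype=np.asarray(values).dtype)
            wide[qidx] = values
            return wide

        adata.var["atlas_feature"] = widen_gene(result.feature_mask, False)
        adata.var["correlated_gene"] = widen_gene(result.correlated_mask, False)
        adata.var["correction_factor"] = widen_gene(result.correction_factor, 1.0)
        adata.var["fit_correlation"] = widen_gene(result.fit_correlation, 0.0)
        adata.var["noisy_gene"] = widen_gene(result.noisy_mask, False)
        adata.var["lateral_gene"] = widen_gene(result.lateral_mask, False)
        adata.var["kept_gene"] = widen_gene(result.kept_mask, False)

        adata.uns["atlas_metacells"] = list(result.atlas_metacells)
        adata.uns["atlas_metacell_types"] = list(result.atlas_types)
        adata.uns["common_genes"] = list(result.query_genes)
        adata.uns["fitted_masks"] = result.fitted_masks.astype(np.uint8)
        adata.uns["skewed_genes_by_type"] = {
            t: [result.query_genes[g] for g in np.flatnonzero(mask)] for t, mask in result.skewed_by_type.items()
        }
        adata.uns["essential_genes_of_type"] = {
            t: [result.query_genes[p] for p in positions] for t, positions in result.essential_positions.items()
        }
        adata.uns["totals"] = result.totals
        adata.uns["anchors"] = result.anchors
        adata.uns["config"] = {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in result.config.to_dict().items()
        }
        adata.write_h5ad(path)

        result.metacell_qc.to_csv(path.parent / "metacell_qc.tsv", sep="\t")
        result.gene_qc.to_csv(path.parent / "gene_qc.tsv", sep="\t")
        result.type_skewed_genes.to_csv(path.parent / "type_skewed_genes.tsv", sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"failed writing result to {path}: {exc}") from exc


def load_result(path) -> ProjectionResult:
    """Reload a written result container into a ProjectionResult.

    All stored annotations round-trip exactly; matrices derived from the
    stored layers (fractions, delta) are reconstructed.
    """
    import anndata as ad

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"result container not found: {path}")
    adata = ad.read_h5ad(path)
    config = ProjectionConfig.from_mapping(
        {k: (tuple(v) if k == "range_quantiles" else v) for k, v in dict(adata.uns["config"]).items()}
    )
    all_genes = list(adata.var_names)
    common_genes = [str(g) for g in adata.uns["common_genes"]]
    gene_pos = {g: i for i, g in enumerate(all_genes)}
    qidx = np.array([gene_pos[g] for g in common_genes], dtype=np.int64)

    def narrow(layer) -> np.ndarray:
        matrix = layer.toarray() if sparse.issparse(layer) else np.asarray(layer)
        return matrix[:, qidx]

    totals = np.asarray(adata.uns["totals"], dtype=np.float64)
    corrected = narrow(adata.layers["corrected_umis"]) / totals[:, None]
    lfold = narrow(adata.layers["lfold"])
    epsilon = config.epsilon
    projected = (epsilon + corrected) / np.exp2(lfold) - epsilon

    def var_col(name: str, dtype=bool) -> np.ndarray:
        return np.asarray(adata.var[name])[qidx].astype(dtype)

    skewed = {
        str(t): np.isin(np.asarray(common_genes), np.asarray(list(genes), dtype=object))
        for t, genes in dict(adata.uns["skewed_genes_by_type"]).items()
    }
    common_index = {g: i for i, g in enumerate(common_genes)}
    essentials = {
        str(t): [common_index[str(g)] for g in genes]
        for t, genes in dict(adata.uns["essential_genes_of_type"]).items()
    }
    weights = adata.obsm["atlas_weights"]
    if sparse.issparse(weights):
        weights = weights.toarray()

    result = ProjectionResult(
        query_metacells=list(adata.obs_names),
        query_genes=common_genes,
        atlas_metacells=[str(m) for m in adata.uns["atlas_metacells"]],
        atlas_types=[str(t) for t in adata.uns["atlas_metacell_types"]],
        query_umis=narrow(adata.X),
        query_all_gene_names=all_genes,
        common_query_index=qidx,
        weights=np.asarray(weights, dtype=np.float64),
        corrected_fractions=corrected,
        projected_fractions=np.clip(projected, 0.0, None),
        totals=totals,
        lfold=lfold,
        profile_umis=narrow(adata.layers["profile_umis"]),
        feature_mask=var_col("atlas_feature"),
        noisy_mask=var_col("noisy_gene"),
        lateral_mask=var_col("lateral_gene"),
        kept_mask=var_col("kept_gene"),
        fitted_masks=np.asarray(adata.uns["fitted_masks"], dtype=bool),
        skewed_by_type=skewed,
        essential_positions=essentials,
        correction_factor=var_col("correction_factor", np.float64),
        correlated_mask=var_col("correlated_gene"),
        fit_correlation=var_col("fit_correlation", np.float64),
        projected_type=[str(t) for t in adata.obs["projected_type"]],
        composite_type=[str(t) if str(t) != "nan" else "" for t in adata.obs["composite_type"]],
        misfit_count=np.asarray(adata.obs["misfit_genes"], dtype=np.int64),
        misfit_essential_fraction=np.asarray(adata.obs["misfit_essential_fraction"], dtype=np.float64),
        similar=np.asarray(adata.obs["similar"], dtype=bool),
        r2=np.asarray(adata.obs["r2"], dtype=np.float64),
        anchors=np.asarray(adata.uns["anchors"], dtype=np.int64),
        config=config,
    )
    excluded = result.noisy_mask | result.lateral_mask
    delta = (np.abs(lfold) > config.max_lfold) & (result.profile_umis >= config.min_umis) & ~excluded[None, :]
    for i, t in enumerate(result.projected_type):
        for label in filter(None, (t, result.composite_type[i])):
            skew = skewed.get(label)
            if skew is not None and skew.any():
                delta[i, skew] = False
    result.delta = delta
    return result
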