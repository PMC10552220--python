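"""End-to-end projection pipeline.

Order of stages: gene-space intersection -> log expression -> preliminary
mixture projection over the atlas feature genes -> optional multiplicative
gene correction (iterated with re-projection) -> range-based gene filtering
-> per-type skewed-gene filtering (iterated with re-projection) -> tagging
of unassigned metacells and two-region composite refits -> QC assembly.
"""

from __future__ import annotations

import logging
from typing import Dict

import numpy as np

from .adjustment import (
    assign_types,
    compute_deviation,
    correction_loop,
    range_filter,
    type_filter_loop,
)
from .composite import fit_composite, flag_unassigned, residual_candidates
from .config import ProjectionConfig
from .data_model import AtlasModel, CommonGeneSpace, QueryModel, intersect_genes
from .projection import compute_log_expression, project_all
from .qc import ProjectionResult, _statuses_from_delta, compute_r2

logger = logging.getLogger(__name__)

__all__ = ["project_query"]


def _mask_from_names(names, members) -> np.ndarray:
    return np.array([g in members for g in names], dtype=bool)


def project_query(
    atlas: AtlasModel,
    query: QueryModel,
    config: ProjectionConfig = ProjectionConfig(),
) -> ProjectionResult:
    """Project a query metacell dataset onto an annotated atlas."""
    common = intersect_genes(atlas, query, case_fold=config.case_fold_genes)
    genes = list(common.genes)
    n_genes = len(genes)
    epsilon = config.epsilon

    q_umis = query.umis[:, common.query_index].astype(np.float64)
    a_umis = atlas.umis[:, common.atlas_index].astype(np.float64)
    q_prof = compute_log_expression(q_umis, epsilon=epsilon, metacell_names=query.metacell_names)
    a_prof = compute_log_expression(a_umis, epsilon=epsilon, metacell_names=atlas.metacell_names)
    e_a = a_prof.log2e

    feature_mask = _mask_from_names(genes, atlas.masks.feature)
    noisy_mask = _mask_from_names(genes, atlas.masks.noisy)
    lateral_mask = _mask_from_names(genes, atlas.masks.lateral)
    excluded = noisy_mask | lateral_mask
    fitted = feature_mask.copy()

    logger.info(
        "projecting %d query metacells onto %d atlas metacells over %d common genes (%d features)",
        query.n_metacells,
        atlas.n_metacells,
        n_genes,
        int(fitted.sum()),
    )

    # --- seeding and mixture modeling -------------------------------------
    state = project_all(q_prof.log2e, e_a, fitted, min_weight=config.min_weight, epsilon=epsilon)

    # --- multiplicative gene correction -----------------------------------
    if config.correct_genes:
        # every common gene is a correction candidate (technology bias is not
        # limited to feature genes); only noisy/lateral genes are exempt
        loop = correction_loop(
            q_prof.fractions, e_a, state, fitted, ~excluded, config, query_totals=q_prof.totals
        )
        fractions_corr = loop.corrected_fractions
        e_q = loop.e_q_corrected
        factor = loop.accumulated_factor
        fit_correlation = loop.fit
        correlated = loop.correlated_mask
        state = loop.state
        if loop.rounds:
            logger.info("gene correction: %d genes corrected over %d rounds", int((factor != 1).sum()), loop.rounds)
    else:
        fractions_corr = q_prof.fractions
        e_q = q_prof.log2e
        factor = np.ones(n_genes)
        fit_correlation = np.zeros(n_genes)
        correlated = np.zeros(n_genes, dtype=bool)

    essential_positions: Dict[str, list[int]] = {}
    gene_pos = {g: i for i, g in enumerate(genes)}
    for t, ess_genes in atlas.essential.items():
        essential_positions[t] = sorted(gene_pos[g] for g in ess_genes if g in gene_pos)
    protected_by_type: Dict[str, np.ndarray] = {}
    for t, positions in essential_positions.items():
        mask = np.zeros(n_genes, dtype=bool)
        mask[positions] = True
        protected_by_type[t] = mask

    # --- range-based filtering --------------------------------------------
    rf = range_filter(
        e_q,
        state.e_p,
        fitted,
        excluded,
        quantiles=config.range_quantiles,
        min_shared=config.range_min_shared,
    )
    kept = rf.kept_mask
    degenerate_fit = int(kept.sum()) < 2
    if degenerate_fit:
        # almost no gene shows a compatible expression range: the query is
        # essentially unexplainable; keep the preliminary projection so the
        # QC can report the (tiny) fitted fraction
        logger.warning(
            "range filter left %d fitted genes; skipping re-projection and per-type filtering",
            int(kept.sum()),
        )
        types = assign_types(state.weights, atlas.types)
        skewed_by_type: Dict[str, np.ndarray] = {}
        deviation = compute_deviation(
            fractions_corr,
            state.projected_fractions(epsilon),
            q_prof.totals,
            epsilon=epsilon,
            max_lfold=config.max_lfold,
            min_umis=config.min_umis,
            excluded=excluded,
        )
    else:
        if int((fitted & ~kept).sum()):
            logger.info(
                "range filter dropped %d of %d fitted genes", int((fitted & ~kept).sum()), int(fitted.sum())
            )
            state = project_all(e_q, e_a, kept, min_weight=config.min_weight, epsilon=epsilon)

        # --- per-type skewed-gene filtering -------------------------------
        tl = type_filter_loop(
            fractions_corr,
            q_prof.totals,
            e_q,
            e_a,
            atlas.types,
            state,
            kept,
            excluded,
            config,
            protected_by_type=protected_by_type,
        )
        state = tl.state
        types = list(tl.metacell_types)
        skewed_by_type = dict(tl.skewed_by_type)
        deviation = tl.deviation

    def type_mask(t: str) -> np.ndarray:
        return kept & ~skewed_by_type.get(t, np.zeros(n_genes, dtype=bool))

    fitted_masks = np.stack([type_mask(t) for t in types])

    # --- tag unassigned metacells ------------------------------------------
    statuses, delta = flag_unassigned(
        deviation.delta,
        types,
        skewed_by_type,
        fitted_masks,
        essential_positions,
        max_misfit=config.max_misfit,
        max_essential_fraction=config.max_essential_fraction,
    )

    composite_types = [""] * query.n_metacells
    lfold = deviation.lfold.copy()
    profile_umis = deviation.profile_umis.copy()

    # --- composite projection ----------------------------------------------
    if config.composite_enabled:
        n_composite = 0
        for i, status in enumerate(statuses):
            if not status.unassigned:
                continue
            mask_i = fitted_masks[i]
            if int(mask_i.sum()) < 2:
                continue
            secondary = residual_candidates(
                e_q[i],
                state.e_p[i],
                e_a,
                mask_i,
                exclude=state.candidates[i],
            )
            if secondary is None or len(secondary.members) == 0:
                continue
            comp = fit_composite(
                e_q[i],
                state.candidates[i],
                secondary,
                e_a,
                mask_i,
                atlas.types,
                anchor=int(state.anchors[i]),
                min_weight=config.min_weight,
            )
            if not comp.primary_type or not comp.secondary_type:
                continue
            comp_fractions = np.clip(np.exp2(comp.e_p) - epsilon, 0.0, None)
            dev_i = compute_deviation(
                fractions_corr[i : i + 1],
                comp_fractions[None, :],
                q_prof.totals[i : i + 1],
                epsilon=epsilon,
                max_lfold=config.max_lfold,
                min_umis=config.min_umis,
                excluded=excluded,
            )
            delta_i = dev_i.delta[0]
            comp_mask = type_mask(comp.primary_type) & type_mask(comp.secondary_type)
            for label in (comp.primary_type, comp.secondary_type):
                skew = skewed_by_type.get(label)
                if skew is not None and skew.any():
                    delta_i = delta_i & ~skew
            misfit = int(delta_i[comp_mask].sum())
            positions = sorted(
                set(essential_positions.get(comp.primary_type, []))
                | set(essential_positions.get(comp.secondary_type, []))
            )
            ess = float(np.mean(delta_i[positions])) if positions else 0.0
            # composite rescue allows "up to" the essential fraction bound
            # (inclusive), while unassignment triggers at the bound
            accepted = (
                misfit <= config.max_misfit
                and ess <= config.max_essential_fraction
                and misfit <= status.misfit_count
            )
            if not accepted:
                logger.debug(
                    "metacell %s: composite rejected (misfit=%d, essential=%.2f)",
                    query.metacell_names[i],
                    misfit,
                    ess,
                )
                continue
            n_composite += 1
            types[i] = comp.primary_type
            composite_types[i] = comp.secondary_type
            state.weights[i, :] = 0.0
            state.weights[i, comp.members] = comp.weights
            state.e_p[i] = comp.e_p
            state.candidates[i] = comp.members
            fitted_masks[i] = comp_mask
            delta[i] = delta_i
            lfold[i] = dev_i.lfold[0]
            profile_umis[i] = dev_i.profile_umis[0]
        if n_composite:
            logger.info("accepted %d composite metacells", n_composite)

    projected_fractions = state.projected_fractions(epsilon)

    result = ProjectionResult(
        query_metacells=list(query.metacell_names),
        query_genes=genes,
        atlas_metacells=list(atlas.metacell_names),
        atlas_types=list(atlas.types),
        query_umis=q_umis,
        query_all_gene_names=list(query.gene_names),
        common_query_index=common.query_index,
        weights=state.weights,
        corrected_fractions=fractions_corr,
        projected_fractions=projected_fractions,
        totals=q_prof.totals,
        lfold=lfold,
        delta=delta,
        profile_umis=profile_umis,
        feature_mask=feature_mask,
        noisy_mask=noisy_mask,
        lateral_mask=lateral_mask,
        kept_mask=kept,
        fitted_masks=fitted_masks,
        skewed_by_type=skewed_by_type,
        essential_positions=essential_positions,
        correction_factor=factor,
        correlated_mask=correlated,
        fit_correlation=fit_correlation,
        projected_type=types,
        composite_type=composite_types,
        anchors=state.anchors,
        config=config,
    )
    misfit, ess, similar = _statuses_from_delta(result, delta)
    result.misfit_count = misfit
    result.misfit_essential_fraction = ess
    result.similar = similar
    result.r2 = compute_r2(e_q, state.e_p, list(fitted_masks))
    logger.info(
        "projection done: %d/%d similar, %d unassigned, %d composite",
        int(similar.sum()),
        query.n_metacells,
        int((~similar).sum()),
        sum(1 for t in composite_types if t),
    )
    return result
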