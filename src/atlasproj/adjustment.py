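"""Gene-level adjustment: multiplicative correction and misfit filtering.

Technology differences that act independently on single molecules induce a
single multiplicative factor per gene.  Genes whose query expression tracks
the projection tightly (high correlation) but at a shifted magnitude are
corrected by that factor; genes whose expression ranges barely overlap, or
that deviate strongly within an assigned atlas type, are dropped from the
fitted set instead.  Corrections multiply linear expression fractions; log
values are recomputed afterwards, and corrected fractions are deliberately
not renormalized (renormalizing would leak a gene's correction into all
other genes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from .config import ProjectionConfig
from .projection import ProjectionState, log_of_fractions, project_all

logger = logging.getLogger(__name__)

__all__ = [
    "CorrectionState",
    "RangeFilterState",
    "DeviationState",
    "TypeSkewState",
    "estimate_corrections",
    "correction_loop",
    "range_filter",
    "compute_deviation",
    "assign_types",
    "detect_type_skew",
    "type_filter_loop",
]


def _columnwise_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of matching columns; zero-variance columns give 0."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    xn = np.linalg.norm(xc, axis=0)
    yn = np.linalg.norm(yc, axis=0)
    denom = xn * yn
    safe = denom > 0
    fit = np.zeros(x.shape[1])
    fit[safe] = (xc[:, safe] * yc[:, safe]).sum(axis=0) / denom[safe]
    return np.clip(fit, -1.0, 1.0)


@dataclass
class CorrectionState:
    """Per-gene fit correlation and multiplicative correction factors."""

    fit: np.ndarray  # cor(query, projection) per gene, over metacells
    factor: np.ndarray  # multiplier applied to the query (1 = uncorrected)
    corrected_mask: np.ndarray  # genes corrected this round
    correlated_mask: np.ndarray  # genes passing the fit gate (eligible ones)
    corrected_fractions: np.ndarray  # query fractions after applying factor


def estimate_corrections(
    query_fractions: np.ndarray,
    projected_fractions: np.ndarray,
    e_q: np.ndarray,
    e_p: np.ndarray,
    eligible: np.ndarray,
    *,
    min_fit: float = 0.8,
    min_factor: float = 1.15,
    query_totals: Optional[np.ndarray] = None,
    min_umis: int = 0,
) -> CorrectionState:
    """Estimate per-gene multiplicative corrections from one projection round.

    ``fit_g`` is the query/projection correlation of log expression over all
    query metacells; the candidate factor is the ratio of summed projected to
    summed query linear fractions.  A gene is corrected only if it is
    eligible (fitted, neither noisy nor lateral), fit exceeds ``min_fit``,
    and the factor deviates from 1 by more than ``min_factor`` as a fold.
    As for all fold factors, genes whose query plus projected profiles carry
    fewer than ``min_umis`` summed UMIs (when ``query_totals`` is given)
    provide no evidence and are never corrected.
    Corrected query fractions are factor x query fractions.
    """
    eligible = np.asarray(eligible, dtype=bool)
    fit = _columnwise_pearson(e_q, e_p)
    q_sum = query_fractions.sum(axis=0)
    p_sum = projected_fractions.sum(axis=0)
    cf = np.ones_like(q_sum)
    expressed = q_sum > 0
    if (~expressed & eligible).any():
        logger.debug("%d eligible genes with zero query expression: factor forced to 1", int((~expressed & eligible).sum()))
    cf[expressed] = p_sum[expressed] / q_sum[expressed]
    cf[cf <= 0] = 1.0
    correlated = eligible & (fit > min_fit)
    corrected = correlated & (np.abs(np.log(cf)) > np.log(min_factor))
    if query_totals is not None and min_umis > 0:
        profile_umis = ((query_fractions + projected_fractions) * query_totals[:, None]).sum(axis=0)
        corrected &= profile_umis >= min_umis
    factor = np.where(corrected, cf, 1.0)
    return CorrectionState(
        fit=fit,
        factor=factor,
        corrected_mask=corrected,
        correlated_mask=correlated,
        corrected_fractions=query_fractions * factor[None, :],
    )


@dataclass
class CorrectionLoopResult:
    """Outcome of the iterated correction / re-projection procedure."""

    corrected_fractions: np.ndarray
    e_q_corrected: np.ndarray
    accumulated_factor: np.ndarray  # product of per-round factors
    fit: np.ndarray  # fit correlations from the last estimation round
    correlated_mask: np.ndarray
    state: ProjectionState
    rounds: int


def correction_loop(
    query_fractions: np.ndarray,
    e_a: np.ndarray,
    initial_state: ProjectionState,
    gene_mask: np.ndarray,
    eligible: np.ndarray,
    config: ProjectionConfig,
    query_totals: Optional[np.ndarray] = None,
) -> CorrectionLoopResult:
    """Alternate correction estimation and re-projection (at most 3 rounds).

    Stops as soon as a round corrects no genes.  The accumulated factor per
    gene is the product over rounds.  With correction disabled upstream this
    function is simply not called and the initial projection stands.
    """
    epsilon = config.epsilon
    fractions = query_fractions.copy()
    e_q = log_of_fractions(fractions, epsilon)
    accumulated = np.ones(fractions.shape[1])
    state = initial_state
    fit = np.zeros(fractions.shape[1])
    correlated = np.zeros(fractions.shape[1], dtype=bool)
    rounds = 0
    for _ in range(config.correction_max_rounds):
        projected = state.projected_fractions(epsilon)
        est = estimate_corrections(
            fractions,
            projected,
            e_q,
            state.e_p,
            eligible,
            min_fit=config.correction_min_fit,
            min_factor=config.correction_min_factor,
            query_totals=query_totals,
            min_umis=config.min_umis,
        )
        fit = est.fit
        correlated |= est.correlated_mask
        if not est.corrected_mask.any():
            break
        rounds += 1
        n = int(est.corrected_mask.sum())
        logger.info("correction round %d: corrected %d genes", rounds, n)
        accumulated *= est.factor
        fractions = est.corrected_fractions
        e_q = log_of_fractions(fractions, epsilon)
        state = project_all(e_q, e_a, gene_mask, min_weight=config.min_weight, epsilon=epsilon)
    return CorrectionLoopResult(
        corrected_fractions=fractions,
        e_q_corrected=e_q,
        accumulated_factor=accumulated,
        fit=fit,
        correlated_mask=correlated,
        state=state,
        rounds=rounds,
    )


@dataclass
class RangeFilterState:
    """Per-gene query/projection expression ranges and the surviving mask."""

    low_q: np.ndarray
    high_q: np.ndarray
    low_p: np.ndarray
    high_p: np.ndarray
    kept_mask: np.ndarray


def range_filter(
    e_q: np.ndarray,
    e_p: np.ndarray,
    fitted: np.ndarray,
    exempt: np.ndarray,
    *,
    quantiles: tuple[float, float] = (0.02, 0.98),
    min_shared: float = 0.5,
) -> RangeFilterState:
    """Drop fitted genes whose query and projected ranges barely overlap.

    A gene is filtered iff the shared range [max(low), min(high)] is
    strictly shorter than ``min_shared`` of its query range.  Genes with a
    zero query range are kept, as are exempt (noisy/lateral) genes.
    Quantiles use linear interpolation between order statistics.
    """
    fitted = np.asarray(fitted, dtype=bool)
    exempt = np.asarray(exempt, dtype=bool)
    lo, hi = quantiles
    low_q = np.quantile(e_q, lo, axis=0)
    high_q = np.quantile(e_q, hi, axis=0)
    low_p = np.quantile(e_p, lo, axis=0)
    high_p = np.quantile(e_p, hi, axis=0)
    low_s = np.maximum(low_q, low_p)
    high_s = np.minimum(high_q, high_p)
    query_span = high_q - low_q
    shared_span = high_s - low_s  # may be negative: disjoint ranges
    filtered = (query_span > 0) & (shared_span < min_shared * query_span)
    kept = fitted & (~filtered | exempt)
    logger.debug("range filter: %d of %d fitted genes dropped", int((fitted & ~kept).sum()), int(fitted.sum()))
    return RangeFilterState(low_q=low_q, high_q=high_q, low_p=low_p, high_p=high_p, kept_mask=kept)


@dataclass
class DeviationState:
    """Per-gene/per-metacell log2 fold deviations and misfit indicators."""

    lfold: np.ndarray  # log2((eps + query fraction) / (eps + projected fraction))
    delta: np.ndarray  # bool: deviation large AND well-supported AND usable
    umi_ok: np.ndarray  # bool: the two profiles carry enough summed UMIs
    profile_umis: np.ndarray  # summed query + projected UMIs per entry


def compute_deviation(
    query_fractions: np.ndarray,
    projected_fractions: np.ndarray,
    query_totals: np.ndarray,
    *,
    epsilon: float = 1e-5,
    max_lfold: float = 3.0,
    min_umis: int = 40,
    excluded: Optional[np.ndarray] = None,
) -> DeviationState:
    """Threshold query-vs-projection fold deviations into misfit indicators.

    delta is set only where |lfold| exceeds ``max_lfold`` (3 = the 8x
    threshold) AND the query plus projected profiles carry at least
    ``min_umis`` summed UMIs.  ``excluded`` genes (noisy / lateral) never
    provide negative evidence.
    """
    lfold = np.log2((epsilon + query_fractions) / (epsilon + projected_fractions))
    projected_umis = np.rint(projected_fractions * query_totals[:, None])
    query_umis = query_fractions * query_totals[:, None]
    profile_umis = query_umis + projected_umis
    umi_ok = profile_umis >= min_umis
    delta = (np.abs(lfold) > max_lfold) & umi_ok
    if excluded is not None:
        delta = delta & ~np.asarray(excluded, dtype=bool)[None, :]
    return DeviationState(lfold=lfold, delta=delta, umi_ok=umi_ok, profile_umis=profile_umis)


def assign_types(weights: np.ndarray, atlas_types: Sequence[str]) -> list[str]:
    """Assign each query metacell the atlas type with maximal summed weight.

    Ties are broken toward the lexicographically first type label (logged).
    """
    type_labels = sorted(set(atlas_types))
    indicator = np.array([[t == label for label in type_labels] for t in atlas_types], dtype=np.float64)
    type_weights = weights @ indicator  # (n_query, n_types)
    best = np.argmax(type_weights, axis=1)  # first max = lexicographic winner
    sorted_w = np.sort(type_weights, axis=1)
    ties = np.isclose(sorted_w[:, -1], sorted_w[:, -2]) if len(type_labels) > 1 else np.zeros(len(best), dtype=bool)
    if ties.any():
        logger.warning(
            "type assignment ties for %d metacells; lexicographically first type chosen",
            int(ties.sum()),
        )
    return [type_labels[i] for i in best]


@dataclass
class TypeSkewState:
    """Per-type fractions of misfit metacells and the resulting skewed gene sets."""

    metacell_type: list[str]
    skew: Dict[str, np.ndarray]  # type -> per-gene fraction of misfit metacells
    skewed_genes: Dict[str, np.ndarray] = field(default_factory=dict)  # type -> bool mask


def detect_type_skew(
    deviation: DeviationState,
    metacell_types: Sequence[str],
    fitted_by_type: Dict[str, np.ndarray],
    *,
    min_fraction: float = 0.5,
    protected_by_type: Optional[Dict[str, np.ndarray]] = None,
) -> TypeSkewState:
    """Find genes whose deviation is pervasive within an assigned atlas type.

    For each type t and gene g, skew is the mean of delta over the query
    metacells assigned t; genes with skew strictly above ``min_fraction``
    are marked skewed for that type (only currently fitted genes can be).

    A type's essential genes (``protected_by_type``) are never added to its
    own skewed set: they are the designated sentinels of the type, and
    silently filtering them would blind the assignment QC to exactly the
    mismatches it is meant to catch.
    """
    metacell_types = list(metacell_types)
    skew: Dict[str, np.ndarray] = {}
    skewed: Dict[str, np.ndarray] = {}
    for t in sorted(set(metacell_types)):
        rows = [i for i, ti in enumerate(metacell_types) if ti == t]
        if not rows:
            continue
        s = deviation.delta[rows].mean(axis=0)
        skew[t] = s
        mask = (s > min_fraction) & fitted_by_type.get(t, np.ones(s.shape, dtype=bool))
        if protected_by_type is not None:
            protected = protected_by_type.get(t)
            if protected is not None and (mask & protected).any():
                logger.info(
                    "type %s: %d essential genes exceed the skew threshold but stay fitted",
                    t,
                    int((mask & protected).sum()),
                )
                mask = mask & ~protected
        skewed[t] = mask
    return TypeSkewState(metacell_type=metacell_types, skew=skew, skewed_genes=skewed)


@dataclass
class TypeLoopResult:
    state: ProjectionState
    skew_state: TypeSkewState
    deviation: DeviationState
    metacell_types: list[str]
    skewed_by_type: Dict[str, np.ndarray]  # accumulated across rounds
    rounds: int


def type_filter_loop(
    query_fractions: np.ndarray,
    query_totals: np.ndarray,
    e_q: np.ndarray,
    e_a: np.ndarray,
    atlas_types: Sequence[str],
    initial_state: ProjectionState,
    kept_mask: np.ndarray,
    excluded: np.ndarray,
    config: ProjectionConfig,
    protected_by_type: Optional[Dict[str, np.ndarray]] = None,
) -> TypeLoopResult:
    """Per-type skewed-gene filtering, iterated with re-projection.

    Each round removes the accumulated skewed genes of a metacell's assigned
    type from its fitted mask and re-projects; the loop stops when the type
    assignment is stable or after ``type_loop_max_rounds`` rounds.  The
    fitted mask never grows.
    """
    n_genes = e_a.shape[1]
    epsilon = config.epsilon
    state = initial_state
    types = assign_types(state.weights, atlas_types)
    accumulated: Dict[str, np.ndarray] = {}
    deviation = compute_deviation(
        query_fractions,
        state.projected_fractions(epsilon),
        query_totals,
        epsilon=epsilon,
        max_lfold=config.max_lfold,
        min_umis=config.min_umis,
        excluded=excluded,
    )
    rounds = 0
    for _ in range(config.type_loop_max_rounds):
        fitted_by_type = {
            t: kept_mask & ~accumulated.get(t, np.zeros(n_genes, dtype=bool)) for t in sorted(set(types))
        }
        skew_state = detect_type_skew(
            deviation,
            types,
            fitted_by_type,
            min_fraction=config.skew_min_fraction,
            protected_by_type=protected_by_type,
        )
        new_skew = False
        for t, mask in skew_state.skewed_genes.items():
            prior = accumulated.get(t, np.zeros(n_genes, dtype=bool))
            if (mask & ~prior).any():
                new_skew = True
            accumulated[t] = prior | mask
        if not new_skew and rounds > 0:
            break
        if not new_skew and rounds == 0:
            # nothing to filter: the initial projection stands unchanged
            break
        rounds += 1
        masks = []
        for t in types:
            mask = kept_mask & ~accumulated.get(t, np.zeros(n_genes, dtype=bool))
            if int(mask.sum()) < 2:
                logger.warning(
                    "type %s: skew filtering left %d fitted genes; keeping the unfiltered mask",
                    t,
                    int(mask.sum()),
                )
                mask = kept_mask
            masks.append(mask)
        state = project_all(e_q, e_a, masks_per_metacell=masks, min_weight=config.min_weight, epsilon=epsilon)
        deviation = compute_deviation(
            query_fractions,
            state.projected_fractions(epsilon),
            query_totals,
            epsilon=epsilon,
            max_lfold=config.max_lfold,
            min_umis=config.min_umis,
            excluded=excluded,
        )
        new_types = assign_types(state.weights, atlas_types)
        if new_types == types:
            types = new_types
            break
        logger.info("type assignments changed for %d metacells; repeating filtering round", sum(a != b for a, b in zip(types, new_types)))
        types = new_types
    fitted_by_type = {
        t: kept_mask & ~accumulated.get(t, np.zeros(n_genes, dtype=bool)) for t in sorted(set(types))
    }
    skew_state = detect_type_skew(
        deviation,
        types,
        fitted_by_type,
        min_fraction=config.skew_min_fraction,
        protected_by_type=protected_by_type,
    )
    return TypeLoopResult(
        state=state,
        skew_state=skew_state,
        deviation=deviation,
        metacell_types=types,
        skewed_by_type=accumulated,
        rounds=max(rounds, 1),
    )
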