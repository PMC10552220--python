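"""Unassigned metacells and two-region composite (doublet-like) modeling.

A query metacell whose best single-region projection leaves more than a
handful of misfit genes — or skews a quarter of its type's essential
markers — is tagged unassigned.  Before declaring it a novel state, we try
to explain it as a mixture of two distinct atlas regions: the projected
expression is subtracted from both query and atlas, a second candidate set
is found on the residuals, and the query is refit (on the original values)
over the union of the two candidate sets.  Such composites typically arise
from doublet clusters or from mixed cell groups the query's metacell
partition failed to split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np

from .projection import (
    CandidateSet,
    correlate_query_atlas,
    mix_fractions,
    select_candidates,
    solve_mixture_weights,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AssignmentStatus",
    "CompositeFit",
    "flag_unassigned",
    "residual_candidates",
    "fit_composite",
]


@dataclass
class AssignmentStatus:
    """Misfit summary deciding whether a metacell's projection is acceptable."""

    misfit_count: int
    essential_skew_fraction: float
    unassigned: bool


def _essential_fraction(
    delta_row: np.ndarray,
    essential_positions: Sequence[int],
) -> float:
    if not len(essential_positions):
        return 0.0
    return float(np.mean([delta_row[p] for p in essential_positions]))


def flag_unassigned(
    delta: np.ndarray,
    metacell_types: Sequence[str],
    skewed_by_type: Dict[str, np.ndarray],
    fitted_masks: Sequence[np.ndarray],
    essential_positions: Dict[str, list[int]],
    *,
    max_misfit: int = 3,
    max_essential_fraction: float = 0.25,
) -> tuple[list[AssignmentStatus], np.ndarray]:
    """Zero type-skewed deviations, then flag metacells with too many misfits.

    A metacell is unassigned iff its misfit count (delta over its fitted
    genes) exceeds ``max_misfit`` or at least ``max_essential_fraction`` of
    its assigned type's essential genes are misfit.  Types with no essential
    genes defined contribute a fraction of 0 (logged once).

    Returns the per-metacell status and the adjusted delta matrix.
    """
    delta = np.asarray(delta, dtype=bool).copy()
    missing_essentials = set()
    statuses: list[AssignmentStatus] = []
    for i, t in enumerate(metacell_types):
        skew = skewed_by_type.get(t)
        if skew is not None and skew.any():
            delta[i, skew] = False
        positions = essential_positions.get(t, [])
        if not positions:
            missing_essentials.add(t)
        misfit = int(delta[i, np.asarray(fitted_masks[i], dtype=bool)].sum())
        ess = _essential_fraction(delta[i], positions)
        unassigned = misfit > max_misfit or ess >= max_essential_fraction
        statuses.append(
            AssignmentStatus(misfit_count=misfit, essential_skew_fraction=ess, unassigned=unassigned)
        )
    if missing_essentials:
        logger.debug(
            "no essential genes defined for types %s; essential fraction taken as 0",
            sorted(missing_essentials),
        )
    return statuses, delta


def residual_candidates(
    query_vec: np.ndarray,
    projected_vec: np.ndarray,
    e_a: np.ndarray,
    gene_mask: np.ndarray,
    *,
    exclude: Optional[np.ndarray] = None,
) -> Optional[CandidateSet]:
    """Find a second candidate region on projection residuals.

    Subtracts the projected expression from both the query and every atlas
    metacell, then seeds and grows a candidate set on the residual
    correlations with the usual closest-10 plus up-to-40-below-distance-2
    rule.  Returns None (composite attempt abandoned) when the residual has
    no variance.  ``exclude`` marks atlas metacells (the primary candidates)
    that may not re-enter.
    """
    gene_mask = np.asarray(gene_mask, dtype=bool)
    residual_q = (query_vec - projected_vec)[None, :]
    residual_a = e_a - projected_vec[None, :]
    if np.allclose(residual_q[0, gene_mask], residual_q[0, gene_mask].mean()):
        logger.info("query residual has no variance; composite attempt abandoned")
        return None
    c = correlate_query_atlas(residual_q, residual_a, gene_mask)[0]
    if exclude is not None:
        c = c.copy()
        c[np.asarray(exclude, dtype=np.int64)] = -np.inf
    anchor = int(np.argmax(c))
    if not np.isfinite(c[anchor]) or c[anchor] == 0.0:
        logger.info("no informative residual correlation; composite attempt abandoned")
        return None
    cand = select_candidates(anchor, residual_a, gene_mask)
    if exclude is not None:
        excluded_set = set(int(j) for j in exclude)
        keep = np.array([j not in excluded_set for j in cand.members])
        cand = CandidateSet(anchor=cand.anchor, members=cand.members[keep], distances=cand.distances[keep])
    return cand


@dataclass
class CompositeFit:
    """A two-region refit of an unassigned metacell."""

    members: np.ndarray  # union of primary and secondary candidates
    weights: np.ndarray  # aligned with members; simplex
    e_p: np.ndarray  # refit projected log expression, all genes
    primary_members: np.ndarray
    secondary_members: np.ndarray
    primary_type: str
    secondary_type: str
    misfit_count: int = 0
    essential_skew_fraction: float = 0.0
    accepted: bool = False
    objective: float = 0.0


def _dominant_type(weights: np.ndarray, members: np.ndarray, region: np.ndarray, atlas_types: Sequence[str]) -> str:
    region_set = set(int(j) for j in region)
    sums: Dict[str, float] = {}
    for w, j in zip(weights, members):
        if int(j) in region_set:
            t = atlas_types[int(j)]
            sums[t] = sums.get(t, 0.0) + float(w)
    if not sums:
        return ""
    best = max(sums.values())
    return sorted(t for t, s in sums.items() if s == best)[0]


def fit_composite(
    query_vec: np.ndarray,
    primary: np.ndarray,
    secondary: CandidateSet,
    e_a: np.ndarray,
    gene_mask: np.ndarray,
    atlas_types: Sequence[str],
    *,
    anchor: int,
    min_weight: float = 1e-5,
    epsilon: float = 1e-5,
) -> CompositeFit:
    """Refit the query over the union of primary and secondary candidates.

    The fit uses the original expression values (not residuals).  Acceptance
    (misfit / essential bookkeeping) is decided by the caller, which owns
    the deviation machinery.
    """
    gene_mask = np.asarray(gene_mask, dtype=bool)
    members = np.concatenate([np.asarray(primary, dtype=np.int64), secondary.members])
    members = np.unique(members)
    union = CandidateSet(anchor=int(anchor), members=members, distances=np.zeros(len(members)))
    w = solve_mixture_weights(query_vec, union, e_a, gene_mask, min_weight=min_weight)
    fractions_a = np.clip(np.exp2(e_a) - epsilon, 0.0, None)
    e_p = np.log2(epsilon + mix_fractions(w, members, fractions_a))
    objective = float(np.linalg.norm(e_p[gene_mask] - query_vec[gene_mask]))
    return CompositeFit(
        members=members,
        weights=w,
        e_p=e_p,
        primary_members=np.asarray(primary, dtype=np.int64),
        secondary_members=secondary.members,
        primary_type=_dominant_type(w, members, np.asarray(primary), atlas_types),
        secondary_type=_dominant_type(w, members, secondary.members, atlas_types),
        objective=objective,
    )
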