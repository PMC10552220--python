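"""Core projection: log expression, seeding, and convex mixture modeling.

Each query metacell i is modeled as a convex combination of a small set of
atlas metacells: weights w_ik >= 0, sum_k w_ik = 1, chosen to minimize the
L2 distance between the query log2 expression vector and the weighted
average of the candidate atlas log2 expression vectors over the currently
fitted genes.  The candidate set is seeded from the atlas metacell best
correlated with the query (the anchor) and grown by log-expression distance
to the anchor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import nnls

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionProfile",
    "CandidateSet",
    "ProjectionState",
    "compute_log_expression",
    "correlate_query_atlas",
    "select_candidates",
    "solve_mixture_weights",
    "project_expression",
    "mix_fractions",
    "project_all",
]

#: hard ceiling on candidate-set size: the 10 closest plus up to 40 more
CLOSEST_CANDIDATES = 10
EXTRA_CANDIDATES = 40
EXTRA_MAX_DISTANCE = 2.0


@dataclass
class ExpressionProfile:
    """Linear fractions and log2 expression of a count matrix over the common genes.

    ``fractions[i, g] = u[i, g] / N_i`` with ``N_i`` summed over the common
    genes only, and ``log2e = log2(epsilon + fractions)``.
    """

    fractions: np.ndarray  # (metacells, genes)
    log2e: np.ndarray
    totals: np.ndarray  # per-metacell UMIs over the common genes
    epsilon: float


def compute_log_expression(umis: np.ndarray, *, epsilon: float = 1e-5, metacell_names: Optional[Sequence[str]] = None) -> ExpressionProfile:
    """Convert UMI counts (already restricted to the common genes) to log2 expression.

    Raises if any metacell has zero UMIs over the common genes, naming it.
    """
    umis = np.asarray(umis, dtype=np.float64)
    totals = umis.sum(axis=1)
    if (totals <= 0).any():
        bad = int(np.flatnonzero(totals <= 0)[0])
        name = metacell_names[bad] if metacell_names is not None else str(bad)
        raise ValueError(f"metacell {name!r} has zero UMIs over the common genes")
    fractions = umis / totals[:, None]
    return ExpressionProfile(
        fractions=fractions,
        log2e=np.log2(epsilon + fractions),
        totals=totals,
        epsilon=epsilon,
    )


def log_of_fractions(fractions: np.ndarray, epsilon: float) -> np.ndarray:
    return np.log2(epsilon + np.maximum(fractions, 0.0))


def correlate_query_atlas(e_q: np.ndarray, e_a: np.ndarray, gene_mask: np.ndarray) -> np.ndarray:
    """Pearson correlation of every query/atlas metacell pair over the masked genes.

    Zero-variance vectors yield a correlation of 0 (never NaN); such pairs
    are reported at debug level.
    """
    gene_mask = np.asarray(gene_mask, dtype=bool)
    if int(gene_mask.sum()) < 2:
        raise ValueError("correlation requires at least 2 masked genes")
    q = np.asarray(e_q, dtype=np.float64)[:, gene_mask]
    a = np.asarray(e_a, dtype=np.float64)[:, gene_mask]
    q = q - q.mean(axis=1, keepdims=True)
    a = a - a.mean(axis=1, keepdims=True)
    qn = np.linalg.norm(q, axis=1)
    an = np.linalg.norm(a, axis=1)
    zq = qn == 0
    za = an == 0
    if zq.any() or za.any():
        logger.debug(
            "zero-variance expression vectors: %d query, %d atlas (correlation set to 0)",
            int(zq.sum()),
            int(za.sum()),
        )
    qn[zq] = 1.0
    an[za] = 1.0
    c = (q / qn[:, None]) @ (a / an[:, None]).T
    c[zq, :] = 0.0
    c[:, za] = 0.0
    return np.clip(c, -1.0, 1.0)


@dataclass
class CandidateSet:
    """Anchor atlas metacell and its distance-ordered candidate neighborhood."""

    anchor: int
    members: np.ndarray  # atlas metacell indices, increasing anchor distance
    distances: np.ndarray  # d to the anchor, aligned with members
    correlations: Optional[np.ndarray] = None  # full correlation row, if kept


def select_candidates(
    anchor: int,
    e_a: np.ndarray,
    gene_mask: np.ndarray,
    *,
    n_closest: int = CLOSEST_CANDIDATES,
    n_extra: int = EXTRA_CANDIDATES,
    max_extra_distance: float = EXTRA_MAX_DISTANCE,
) -> CandidateSet:
    """Grow the anchor into a candidate set by max-abs log-expression distance.

    Takes the ``n_closest`` atlas metacells nearest the anchor (the anchor
    itself has distance 0), then up to ``n_extra`` additional ones with
    distance below ``max_extra_distance``.  Ties are broken toward the lower
    atlas index.
    """
    gene_mask = np.asarray(gene_mask, dtype=bool)
    d = np.max(np.abs(e_a[:, gene_mask] - e_a[anchor, gene_mask][None, :]), axis=1)
    order = np.lexsort((np.arange(len(d)), d))  # by (distance, index)
    closest = order[:n_closest]
    rest = order[n_closest : n_closest + n_extra]
    rest = rest[d[rest] < max_extra_distance]
    members = np.concatenate([closest, rest])
    return CandidateSet(anchor=int(anchor), members=members, distances=d[members])


def _simplex_lsq(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimize ||a @ w - b||_2 subject to w >= 0, sum(w) = 1.

    Solved by non-negative least squares on a system augmented with a heavy
    sum-to-one penalty row, followed by an exact equality-constrained
    refinement (KKT system) on the active support.  Deterministic.
    """
    n_genes, k = a.shape
    scale = max(1.0, float(np.abs(a).max()), float(np.abs(b).max()))
    lam = 1e4 * scale
    a_aug = np.vstack([a, np.full((1, k), lam)])
    b_aug = np.append(b, lam)
    w, _ = nnls(a_aug, b_aug)
    total = w.sum()
    if total <= 0:
        raise RuntimeError("non-negative least squares returned an all-zero weight vector")
    w = w / total
    # exact refinement on the support of the penalized solution
    support = np.flatnonzero(w > 1e-12)
    if support.size:
        a_s = a[:, support]
        gram = a_s.T @ a_s
        kkt = np.zeros((support.size + 1, support.size + 1))
        kkt[:-1, :-1] = gram
        kkt[:-1, -1] = 1.0
        kkt[-1, :-1] = 1.0
        rhs = np.append(a_s.T @ b, 1.0)
        try:
            sol = np.linalg.lstsq(kkt, rhs, rcond=None)[0]
            w_ref = sol[:-1]
            if w_ref.min() >= -1e-9 and abs(w_ref.sum() - 1.0) <= 1e-6:
                w_ref = np.clip(w_ref, 0.0, None)
                w_ref = w_ref / w_ref.sum()
                if np.linalg.norm(a_s @ w_ref - b) <= np.linalg.norm(a @ w - b) + 1e-12:
                    full = np.zeros(k)
                    full[support] = w_ref
                    return full
        except np.linalg.LinAlgError:  # pragma: no cover - degenerate Gram
            pass
    return w


def solve_mixture_weights(
    query_vec: np.ndarray,
    candidates: CandidateSet,
    e_a: np.ndarray,
    gene_mask: np.ndarray,
    *,
    min_weight: float = 1e-5,
) -> np.ndarray:
    """Solve the simplex-constrained least squares over the candidate set.

    Returns the weight vector aligned with ``candidates.members``.  Weights
    below ``min_weight`` are dropped and the remainder renormalized.  On
    solver failure the anchor alone receives weight 1 (with a warning); the
    achieved objective is also guaranteed never to exceed the anchor-only
    objective.
    """
    gene_mask = np.asarray(gene_mask, dtype=bool)
    members = candidates.members
    b = np.asarray(query_vec, dtype=np.float64)[gene_mask]
    a = e_a[members][:, gene_mask].T  # genes x candidates
    anchor_pos = int(np.flatnonzero(members == candidates.anchor)[0])
    try:
        w = _simplex_lsq(a, b)
    except (RuntimeError, np.linalg.LinAlgError, ValueError) as exc:
        logger.warning("mixture solver failed (%s); falling back to anchor-only weights", exc)
        w = np.zeros(len(members))
        w[anchor_pos] = 1.0
    # the anchor-only solution is always feasible; never do worse than it
    anchor_obj = np.linalg.norm(a[:, anchor_pos] - b)
    if np.linalg.norm(a @ w - b) > anchor_obj + 1e-9:
        w = np.zeros(len(members))
        w[anchor_pos] = 1.0
    w = np.where(np.abs(w) < min_weight, 0.0, np.clip(w, 0.0, None))
    total = w.sum()
    if total <= 0:
        w = np.zeros(len(members))
        w[anchor_pos] = 1.0
        total = 1.0
    return w / total


def project_expression(weights: np.ndarray, members: np.ndarray, e_a: np.ndarray) -> np.ndarray:
    """Weighted average of candidate atlas log-expression rows over all genes.

    This is the quantity the mixture objective is written on.  The emitted
    projected profile, however, mixes candidate *fractions* linearly (see
    :func:`mix_fractions`): a convex mixture of UMI distributions is an
    arithmetic mixture, and averaging in log space would bias every variable
    gene downward (geometric mean < arithmetic mean).
    """
    return np.asarray(weights, dtype=np.float64) @ e_a[members]


def mix_fractions(weights: np.ndarray, members: np.ndarray, fractions: np.ndarray) -> np.ndarray:
    """Linear-scale projected expression: convex mixture of candidate fractions."""
    return np.asarray(weights, dtype=np.float64) @ fractions[members]


@dataclass
class ProjectionState:
    """Per-query-metacell mixture solutions against one atlas."""

    anchors: np.ndarray  # (n_query,) atlas indices
    candidates: list[np.ndarray]  # member indices per metacell
    weights: np.ndarray  # dense (n_query, n_atlas); rows sum to 1
    e_p: np.ndarray  # projected log2 expression (n_query, n_genes)
    fractions_p: np.ndarray  # projected linear fractions (n_query, n_genes)
    objective: np.ndarray  # solver L2 distance over fitted genes per metacell
    fitted_masks: list[np.ndarray]  # per-metacell fitted-gene mask used

    @property
    def n_query(self) -> int:
        return self.weights.shape[0]

    def projected_fractions(self, epsilon: float) -> np.ndarray:  # noqa: ARG002 - epsilon kept for API symmetry
        return self.fractions_p


def project_all(
    e_q: np.ndarray,
    e_a: np.ndarray,
    gene_mask: np.ndarray | None = None,
    *,
    masks_per_metacell: Optional[Sequence[np.ndarray]] = None,
    min_weight: float = 1e-5,
    epsilon: float = 1e-5,
) -> ProjectionState:
    """Project every query metacell onto the atlas.

    Either a single ``gene_mask`` shared by all query metacells or one mask
    per metacell (``masks_per_metacell``, e.g. per assigned type) must be
    given.  Weights are solved on log expression; the emitted projected
    profile is the linear mixture of candidate fractions (re-logged with
    ``epsilon``).  Deterministic: identical inputs yield bit-identical
    weights.
    """
    n_query = e_q.shape[0]
    n_atlas, n_genes = e_a.shape
    fractions_a = np.clip(np.exp2(e_a) - epsilon, 0.0, None)
    if masks_per_metacell is None:
        if gene_mask is None:
            raise ValueError("either gene_mask or masks_per_metacell is required")
        masks_per_metacell = [np.asarray(gene_mask, dtype=bool)] * n_query

    anchors = np.zeros(n_query, dtype=np.int64)
    weights = np.zeros((n_query, n_atlas))
    e_p = np.zeros((n_query, n_genes))
    fractions_p = np.zeros((n_query, n_genes))
    objective = np.zeros(n_query)
    cand_list: list[np.ndarray] = []
    fitted_masks = [np.asarray(m, dtype=bool) for m in masks_per_metacell]

    # group metacells sharing a mask so correlations are computed in blocks
    groups: dict[bytes, list[int]] = {}
    for i, mask in enumerate(fitted_masks):
        groups.setdefault(mask.tobytes(), []).append(i)

    cand_by_index: dict[int, np.ndarray] = {}
    for rows in groups.values():
        mask = fitted_masks[rows[0]]
        c = correlate_query_atlas(e_q[rows], e_a, mask)
        group_anchors = np.argmax(c, axis=1)
        cand_cache: dict[int, CandidateSet] = {}
        for pos, i in enumerate(rows):
            anchor = int(group_anchors[pos])
            cand = cand_cache.get(anchor)
            if cand is None:
                cand = select_candidates(anchor, e_a, mask)
                cand_cache[anchor] = cand
            w = solve_mixture_weights(e_q[i], cand, e_a, mask, min_weight=min_weight)
            anchors[i] = anchor
            weights[i, cand.members] = w
            fractions_p[i] = mix_fractions(w, cand.members, fractions_a)
            e_p[i] = np.log2(epsilon + fractions_p[i])
            objective[i] = np.linalg.norm(project_expression(w, cand.members, e_a)[mask] - e_q[i, mask])
            cand_by_index[i] = cand.members
            logger.debug(
                "metacell %d: anchor=%d candidates=%d objective=%.4g",
                i,
                anchor,
                len(cand.members),
                objective[i],
            )
    cand_list = [cand_by_index[i] for i in range(n_query)]
    return ProjectionState(
        anchors=anchors,
        candidates=cand_list,
        weights=weights,
        e_p=e_p,
        fractions_p=fractions_p,
        objective=objective,
        fitted_masks=fitted_masks,
    )
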