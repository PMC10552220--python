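"""Seeded synthetic atlases and queries with known ground truth.

The generator emulates the structure the projection algorithm assumes:
type-structured expression profiles with within-type gradients and
metacell-level variation, multinomial UMI sampling at a fixed depth,
per-gene multiplicative capture biases, held-out (novel) types, and
doublet-like mixed metacells.  Every draw is threaded through named
substreams of a single seed, so a scenario's seed fully determines its
outputs.

Profiles are built as a shared log-normal baseline, modulated genome-wide
per type (types differ moderately in most genes, as real cell types do) and
boosted strongly on a disjoint block of marker genes per type.  Metacells
of a type interpolate between the base profile and a drifted endpoint and
carry independent multiplicative jitter, so they are linearly independent
and mixture weights are identifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .data_model import AtlasModel, GeneMasks, QueryModel

__all__ = [
    "SyntheticScenario",
    "GroundTruth",
    "generate_atlas",
    "generate_query",
    "split_atlas",
]


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of a synthetic atlas/query pair.

    The defaults describe a desk-scale tissue: 8 types x 12 metacells x
    2,000 genes at 50,000 UMIs per metacell, with 500 feature genes.
    ``type_spread`` is the log2 standard deviation of genome-wide per-type
    expression modulation; ``metacell_noise`` the log2 jitter per metacell;
    marker genes are boosted by 2^U(marker_boost_log2) in their own type.
    """

    n_types: int = 8
    metacells_per_type: int = 12
    n_genes: int = 2000
    n_feature_genes: int = 500
    umis_per_metacell: int = 50_000
    markers_per_type: int = 120
    marker_boost_log2: Tuple[float, float] = (4.0, 5.5)
    type_spread: float = 1.0
    marker_spread: float = 0.5
    gradient_strength: float = 1.0
    metacell_noise: float = 0.25
    base_sigma: float = 1.5
    min_feature_mean_umis: float = 25.0
    n_essential: int = 4
    n_noisy: int = 0
    n_lateral: int = 0
    bias_fraction: float = 0.0
    bias_factor: float = 1.0
    bias_genes: Tuple[str, ...] = ()
    novel_types: Tuple[str, ...] = ()
    doublet_pairs: Tuple[Tuple[str, str, float], ...] = ()
    n_query_metacells: int = 100
    max_components: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_types", "metacells_per_type", "n_genes", "n_feature_genes", "umis_per_metacell"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_types * self.markers_per_type > self.n_genes:
            raise ValueError("not enough genes for disjoint marker blocks: lower markers_per_type")
        if self.n_feature_genes > self.n_genes:
            raise ValueError("n_feature_genes exceeds n_genes")
        for _, _, alpha in self.doublet_pairs:
            if not (0.0 < alpha < 1.0):
                raise ValueError("doublet mixing fraction must be in (0, 1)")

    @property
    def type_names(self) -> list[str]:
        return [f"T{k:02d}" for k in range(self.n_types)]

    @property
    def gene_names(self) -> list[str]:
        return [f"g{i:04d}" for i in range(self.n_genes)]


@dataclass
class GroundTruth:
    """What the generator actually did, for checking recovery."""

    true_weights: np.ndarray  # (n_query, n_atlas_metacells); rows sum to 1 (0 rows for novel)
    true_type: list[str]
    true_bias: np.ndarray  # per-gene multiplicative factor applied to the query
    is_novel: np.ndarray
    is_doublet: np.ndarray
    doublet_pair: list[Optional[Tuple[str, str, float]]] = field(default_factory=list)

    def to_frame(self, metacell_names: Sequence[str]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "true_type": self.true_type,
                "is_novel": self.is_novel,
                "is_doublet": self.is_doublet,
                "n_components": (self.true_weights > 0).sum(axis=1),
            },
            index=pd.Index(metacell_names, name="metacell"),
        )


def _rng(scenario: SyntheticScenario, *stream: int) -> np.random.Generator:
    return np.random.default_rng([scenario.seed, *stream])


def _type_profiles(scenario: SyntheticScenario) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Base and endpoint expression fractions per type, plus marker blocks."""
    rng = _rng(scenario, 0)
    n_genes = scenario.n_genes
    base = np.exp(rng.normal(0.0, scenario.base_sigma, n_genes))
    # markers come from mid-baseline genes (like canonical cell-type markers,
    # which are well expressed but not at the extreme top of the transcriptome)
    eligible = np.flatnonzero((base >= 1.0 / 3.0) & (base <= 3.0))
    needed = scenario.n_types * scenario.markers_per_type
    if len(eligible) < needed:
        raise ValueError("not enough mid-expression genes for marker blocks: increase n_genes")
    marker_blocks = rng.permutation(eligible)[:needed].reshape(scenario.n_types, scenario.markers_per_type)
    starts = np.zeros((scenario.n_types, n_genes))
    ends = np.zeros((scenario.n_types, n_genes))
    lo, hi = scenario.marker_boost_log2
    # marker-block genes get a reduced genome-wide modulation: their
    # between-type separation is carried by the on/off boost itself
    is_marker = np.zeros(n_genes, dtype=bool)
    is_marker[marker_blocks.ravel()] = True
    spread = np.where(is_marker, scenario.marker_spread, scenario.type_spread)
    for k in range(scenario.n_types):
        weights = base * np.exp2(spread * rng.normal(size=n_genes))
        weights[marker_blocks[k]] *= np.exp2(rng.uniform(lo, hi, scenario.markers_per_type))
        drift = np.zeros(n_genes)
        drift[marker_blocks[k]] = scenario.gradient_strength * rng.uniform(-1.0, 1.0, scenario.markers_per_type)
        end_weights = weights * np.exp2(drift)
        starts[k] = weights / weights.sum()
        ends[k] = end_weights / end_weights.sum()
    return starts, ends, marker_blocks


def _type_metacell_fractions(scenario: SyntheticScenario, type_index: int, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Expected expression fractions of the metacells of one type."""
    rng = _rng(scenario, 1, type_index)
    m = scenario.metacells_per_type
    fractions = np.zeros((m, scenario.n_genes))
    for j in range(m):
        t = j / (m - 1) if m > 1 else 0.0
        f = (1.0 - t) * starts[type_index] + t * ends[type_index]
        f = f * np.exp2(scenario.metacell_noise * rng.normal(size=scenario.n_genes))
        fractions[j] = f / f.sum()
    return fractions


def _bias_vector(scenario: SyntheticScenario) -> np.ndarray:
    bias = np.ones(scenario.n_genes)
    if scenario.bias_genes:
        positions = [scenario.gene_names.index(g) for g in scenario.bias_genes]
    elif scenario.bias_fraction > 0:
        rng = _rng(scenario, 4)
        n_biased = int(round(scenario.bias_fraction * scenario.n_genes))
        positions = rng.choice(scenario.n_genes, size=n_biased, replace=False)
    else:
        return bias
    bias[np.asarray(positions, dtype=np.int64)] = scenario.bias_factor
    return bias


def generate_atlas(scenario: SyntheticScenario) -> AtlasModel:
    """Generate a seeded synthetic atlas (novel types are held out of it)."""
    starts, ends, marker_blocks = _type_profiles(scenario)
    type_names = scenario.type_names
    novel = set(scenario.novel_types)
    unknown = novel - set(type_names)
    if unknown:
        raise ValueError(f"novel_types not in the scenario's type universe: {sorted(unknown)}")

    rows: list[np.ndarray] = []
    types: list[str] = []
    names: list[str] = []
    expected: list[np.ndarray] = []
    for k, label in enumerate(type_names):
        if label in novel:
            continue
        fractions = _type_metacell_fractions(scenario, k, starts, ends)
        rng = _rng(scenario, 2, k)
        for j in range(scenario.metacells_per_type):
            rows.append(rng.multinomial(scenario.umis_per_metacell, fractions[j]))
            types.append(label)
            names.append(f"{label}.{j}")
            expected.append(fractions[j])
    umis = np.asarray(rows, dtype=np.int64)

    rng = _rng(scenario, 3)
    log_e = np.log2(1e-5 + umis / umis.sum(axis=1, keepdims=True))
    variance = log_e.var(axis=0)
    # features must be quantifiable above sampling noise in a typical
    # metacell, as in curated atlases; otherwise their "variance" is mostly
    # multinomial noise and they carry no positional information
    expressed = umis.mean(axis=0) >= scenario.min_feature_mean_umis
    candidates = np.argsort(-np.where(expressed, variance, -np.inf), kind="stable")
    candidates = candidates[: int(expressed.sum())]
    lateral = frozenset(
        scenario.gene_names[i] for i in rng.choice(scenario.n_genes, size=scenario.n_lateral, replace=False)
    )
    noisy = frozenset(
        scenario.gene_names[i] for i in rng.choice(scenario.n_genes, size=scenario.n_noisy, replace=False)
    )
    feature: list[str] = []
    for i in candidates:
        g = scenario.gene_names[i]
        if g in lateral:
            continue
        feature.append(g)
        if len(feature) == scenario.n_feature_genes:
            break

    # essential genes: the most type-distinctive markers of each retained type
    essential: dict[str, frozenset[str]] = {}
    types_arr = np.asarray(types)
    mean_fraction = umis / umis.sum(axis=1, keepdims=True)
    for k, label in enumerate(type_names):
        if label in novel:
            continue
        own = mean_fraction[types_arr == label].mean(axis=0)
        other = mean_fraction[types_arr != label].mean(axis=0) if (types_arr != label).any() else np.full(scenario.n_genes, 1e-12)
        fold = (own + 1e-9) / (other + 1e-9)
        block = marker_blocks[k]
        best = block[np.argsort(-fold[block], kind="stable")[: scenario.n_essential]]
        essential[label] = frozenset(scenario.gene_names[i] for i in best)

    return AtlasModel(
        umis=umis,
        gene_names=scenario.gene_names,
        masks=GeneMasks(feature=frozenset(feature), noisy=noisy, lateral=lateral),
        types=types,
        essential=essential,
        metacell_names=names,
    )


def generate_query(scenario: SyntheticScenario, atlas: AtlasModel) -> tuple[QueryModel, GroundTruth]:
    """Generate a query with known mixture weights, biases, novel and doublet metacells.

    Regular query metacells are convex combinations of 1 to
    ``max_components`` atlas metacells of a single type (with multinomial
    resampling); doublets mix two types; novel metacells are drawn from the
    scenario's held-out type profiles, which are absent from the atlas.
    """
    starts, ends, _ = _type_profiles(scenario)
    type_names = scenario.type_names
    atlas_fractions = atlas.umis / atlas.umis.sum(axis=1, keepdims=True)
    types_arr = np.asarray(atlas.types)
    present_types = [t for t in type_names if (types_arr == t).any()]
    bias = _bias_vector(scenario)
    rng = _rng(scenario, 5)

    rows: list[np.ndarray] = []
    names: list[str] = []
    true_weights: list[np.ndarray] = []
    true_type: list[str] = []
    is_novel: list[bool] = []
    is_doublet: list[bool] = []
    doublet_pair: list[Optional[Tuple[str, str, float]]] = []

    def sample(fractions: np.ndarray) -> np.ndarray:
        f = fractions * bias
        f = f / f.sum()
        return rng.multinomial(scenario.umis_per_metacell, f)

    for i in range(scenario.n_query_metacells):
        label = present_types[int(rng.integers(len(present_types)))]
        members = np.flatnonzero(types_arr == label)
        n_comp = int(rng.integers(1, min(scenario.max_components, len(members)) + 1))
        # a query state sits locally on the manifold: its components are
        # mutually adjacent atlas metacells (contiguous along the type's
        # gradient), as for a left-out batch re-projected onto the atlas
        start = int(rng.integers(len(members) - n_comp + 1))
        chosen = members[start : start + n_comp]
        w = rng.dirichlet(np.ones(n_comp))
        fractions = w @ atlas_fractions[chosen]
        rows.append(sample(fractions))
        names.append(f"mix{i}")
        weights = np.zeros(atlas.n_metacells)
        weights[chosen] = w
        true_weights.append(weights)
        true_type.append(label)
        is_novel.append(False)
        is_doublet.append(False)
        doublet_pair.append(None)

    for i, (ta, tb, alpha) in enumerate(scenario.doublet_pairs):
        ma = rng.choice(np.flatnonzero(types_arr == ta))
        mb = rng.choice(np.flatnonzero(types_arr == tb))
        fractions = alpha * atlas_fractions[ma] + (1.0 - alpha) * atlas_fractions[mb]
        rows.append(sample(fractions))
        names.append(f"doublet{i}")
        weights = np.zeros(atlas.n_metacells)
        weights[ma] = alpha
        weights[mb] = 1.0 - alpha
        true_weights.append(weights)
        true_type.append(ta if alpha >= 0.5 else tb)
        is_novel.append(False)
        is_doublet.append(True)
        doublet_pair.append((ta, tb, alpha))

    for label in scenario.novel_types:
        k = type_names.index(label)
        fractions = _type_metacell_fractions(scenario, k, starts, ends)
        for j in range(scenario.metacells_per_type):
            rows.append(sample(fractions[j]))
            names.append(f"novel.{label}.{j}")
            true_weights.append(np.zeros(atlas.n_metacells))
            true_type.append(label)
            is_novel.append(True)
            is_doublet.append(False)
            doublet_pair.append(None)

    query = QueryModel(
        umis=np.asarray(rows, dtype=np.int64),
        gene_names=scenario.gene_names,
        metacell_names=names,
    )
    truth = GroundTruth(
        true_weights=np.asarray(true_weights),
        true_type=true_type,
        true_bias=bias,
        is_novel=np.asarray(is_novel),
        is_doublet=np.asarray(is_doublet),
        doublet_pair=doublet_pair,
    )
    return query, truth


def split_atlas(atlas: AtlasModel, holdout_type: str) -> tuple[AtlasModel, QueryModel]:
    """Hold one type out of an atlas; its metacells become the query.

    The leave-one-type-out design: the returned atlas no longer represents
    the held-out state, so projecting the returned query should tag its
    metacells as dissimilar.
    """
    types_arr = np.asarray(atlas.types)
    held = types_arr == holdout_type
    if not held.any():
        raise ValueError(f"atlas has no metacells of type {holdout_type!r}")
    if held.all():
        raise ValueError("cannot hold out the only type in the atlas")
    keep = ~held
    punctuated = AtlasModel(
        umis=atlas.umis[keep],
        gene_names=list(atlas.gene_names),
        masks=atlas.masks,
        types=[t for t, k in zip(atlas.types, keep) if k],
        essential={t: genes for t, genes in atlas.essential.items() if t != holdout_type},
        metacell_names=[m for m, k in zip(atlas.metacell_names, keep) if k],
    )
    query = QueryModel(
        umis=atlas.umis[held],
        gene_names=list(atlas.gene_names),
        metacell_names=[m for m, k in zip(atlas.metacell_names, held) if k],
    )
    return punctuated, query
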