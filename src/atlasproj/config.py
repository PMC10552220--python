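"""Run configuration for the projection pipeline.

All thresholds of the algorithm are exposed here; the defaults are the
published ones.  Dotted keys (``correction.min_fit``) in YAML config files
map onto the flat attribute names below.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Any, Mapping, Tuple

__all__ = ["ProjectionConfig"]

# dotted config-file key -> attribute
_KEY_ALIASES = {
    "epsilon": "epsilon",
    "correction.enabled": "correct_genes",
    "correction.min_fit": "correction_min_fit",
    "correction.min_factor": "correction_min_factor",
    "correction.max_rounds": "correction_max_rounds",
    "range.quantiles": "range_quantiles",
    "range.min_shared": "range_min_shared",
    "deviation.max_lfold": "max_lfold",
    "deviation.min_umis": "min_umis",
    "skew.min_fraction": "skew_min_fraction",
    "type_loop.max_rounds": "type_loop_max_rounds",
    "unassigned.max_misfit": "max_misfit",
    "unassigned.max_essential_fraction": "max_essential_fraction",
    "composite.enabled": "composite_enabled",
}


@dataclass(frozen=True)
class ProjectionConfig:
    """Tunable parameters of the projection algorithm.

    Attributes
    ----------
    epsilon
        Regularization added to expression fractions before taking log2.
    correct_genes
        Whether the multiplicative gene-correction loop is enabled.
    correction_min_fit
        Minimum query/projection correlation for a gene to be eligible for
        correction.
    correction_min_factor
        Minimum magnitude (as a fold) of the correction factor; factors
        closer to 1 than this are not applied.
    correction_max_rounds
        Maximum correction/re-projection rounds.
    range_quantiles
        Lower/upper quantiles defining a gene's expression range.
    range_min_shared
        Minimum shared-range length as a fraction of the query range.
    max_lfold
        Absolute log2 fold deviation above which a gene is a misfit
        (3 corresponds to the published 8x threshold).
    min_umis
        Minimum summed UMIs of the query and projected profiles for a fold
        deviation to count as evidence.
    skew_min_fraction
        Fraction of a type's metacells that must be misfit for a gene to be
        dropped from that type's fitted set (strictly greater than).
    type_loop_max_rounds
        Maximum per-type filtering / re-projection rounds.
    max_misfit
        Misfit-gene count above which a metacell is unassigned.
    max_essential_fraction
        Fraction of essential genes misfit at which a metacell is unassigned.
    composite_enabled
        Whether unassigned metacells are tested as two-region composites.
    min_weight
        Mixture weights below this are dropped and the rest renormalized.
    min_fitted_feature_fraction
        A metacell is "similar" only if at least this fraction of the query
        feature genes is fitted for it.
    case_fold_genes
        Match gene identifiers case-insensitively when intersecting.
    """

    epsilon: float = 1e-5
    correct_genes: bool = False
    correction_min_fit: float = 0.8
    correction_min_factor: float = 1.15
    correction_max_rounds: int = 3
    range_quantiles: Tuple[float, float] = (0.02, 0.98)
    range_min_shared: float = 0.5
    max_lfold: float = 3.0
    min_umis: int = 40
    skew_min_fraction: float = 0.5
    type_loop_max_rounds: int = 3
    max_misfit: int = 3
    max_essential_fraction: float = 0.25
    composite_enabled: bool = True
    min_weight: float = 1e-5
    min_fitted_feature_fraction: float = 1.0 / 3.0
    case_fold_genes: bool = False

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        lo, hi = self.range_quantiles
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("range_quantiles must satisfy 0 <= low < high <= 1")
        if self.correction_min_factor <= 1.0:
            raise ValueError("correction_min_factor must exceed 1")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "ProjectionConfig":
        """Build a config from a flat mapping with dotted or attribute keys."""
        known = {f.name for f in fields(cls)}
        kwargs: dict[str, Any] = {}
        for key, value in mapping.items():
            name = _KEY_ALIASES.get(key, key)
            if name not in known:
                raise KeyError(f"unknown configuration key: {key!r}")
            if name == "range_quantiles":
                value = tuple(float(v) for v in value)
            kwargs[name] = value
        return cls(**kwargs)

    def with_overrides(self, **kwargs: Any) -> "ProjectionConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        return {f.name: getattr(self, f.name) for f in fields(self)}
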