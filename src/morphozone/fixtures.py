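"""Tiny synthetic datasets for fast, deterministic end-to-end runs.

These are scaled-down study designs — a few landmarks, a dozen specimens —
small enough that the full pipeline finishes in seconds, used throughout the
test suite and as worked examples.
"""

from __future__ import annotations

from .datatypes import SymmetryScheme
from .simulate import SimulationParams, simulate_hybrid_dataset

__all__ = [
    "tiny_object_scheme",
    "tiny_matching_scheme",
    "tiny_object_params",
    "tiny_matching_params",
    "tiny_object_dataset",
    "tiny_matching_dataset",
]

TINY_GROUP_SIZES = (2, 2, 2, 0, 2, 0, 0, 0, 2, 2)  # 12 specimens, 6 groups of 2
TINY_FAMILIES = (1, 1, 1, 0, 1, 0, 0, 0, 1, 1)


def tiny_object_scheme() -> SymmetryScheme:
    """Object symmetry with 3 landmark pairs + 2 midline points (dim 9)."""
    return SymmetryScheme(
        mode="object", paired=((0, 1), (2, 3), (4, 5)), midline=(6, 7)
    )


def tiny_matching_scheme() -> SymmetryScheme:
    """Matching symmetry with 5 landmarks per side (dim 8)."""
    return SymmetryScheme.matching(5)


def tiny_object_params(seed: int = 0, **overrides) -> SimulationParams:
    base = dict(
        scheme=tiny_object_scheme(),
        group_sizes=TINY_GROUP_SIZES,
        families_per_group=TINY_FAMILIES,
        males_per_group=None,
        seed=seed,
    )
    base.update(overrides)
    return SimulationParams(**base)


def tiny_matching_params(seed: int = 0, **overrides) -> SimulationParams:
    base = dict(
        group_sizes=TINY_GROUP_SIZES,
        families_per_group=TINY_FAMILIES,
        males_per_group=None,
        seed=seed,
    )
    base.update(overrides)
    return SimulationParams.mandible_defaults(scheme=tiny_matching_scheme(), **base)


def tiny_object_dataset(seed: int = 0, **overrides):
    """12-specimen object-symmetry dataset: (configs, covariates, truth)."""
    return simulate_hybrid_dataset(tiny_object_params(seed, **overrides))


def tiny_matching_dataset(seed: int = 0, **overrides):
    """12-specimen matching-symmetry dataset: (configs, covariates, truth)."""
    return simulate_hybrid_dataset(tiny_matching_params(seed, **overrides))
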