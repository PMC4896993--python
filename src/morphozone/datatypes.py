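"""Core containers for landmark-based geometric morphometrics.

Coordinates are stored landmark-major: a configuration of ``L`` landmarks is an
``(L, 3)`` array, and a flattened shape vector is the row-major ravel of that
array (``[x0, y0, z0, x1, ...]``), so Euclidean norms of flattened vectors are
Procrustes distances in the common superimposition frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

Side = Literal["whole", "left", "right"]


class DegenerateConfigurationError(ValueError):
    """Raised for landmark configurations with no usable geometry.

    All-coincident or collinear landmarks leave the Procrustes rotation
    underdetermined, so they are rejected rather than silently handled.
    """


@dataclass(frozen=True)
class LandmarkConfig:
    """One digitized landmark configuration (one specimen, one side).

    Parameters
    ----------
    specimen_id : str
        Specimen identifier; shared between the two sides of a paired
        (matching-symmetry) structure.
    coords : ndarray of shape (L, 3)
        Raw landmark coordinates in arbitrary device units. Landmark order is
        fixed and must be identical across a dataset.
    side : {"whole", "left", "right"}
        ``"whole"`` for object-symmetric structures (e.g. a skull), left/right
        for separately digitized paired structures (e.g. hemimandibles).
    """

    specimen_id: str
    coords: np.ndarray
    side: Side = "whole"

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must be (L, 3), got {coords.shape}")
        if coords.shape[0] < 3:
            raise ValueError("a configuration needs at least 3 landmarks")
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"non-finite coordinates in specimen {self.specimen_id!r}")
        if self.side not in ("whole", "left", "right"):
            raise ValueError(f"invalid side {self.side!r}")
        object.__setattr__(self, "coords", coords)

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class SymmetryScheme:
    """Bookkeeping of bilateral landmark pairs and midline landmarks.

    ``mode="object"`` describes a single bilaterally symmetric structure with
    ``k`` (left, right) landmark pairs and ``l`` unpaired midline landmarks.
    ``mode="matching"`` describes separately digitized left/right copies of a
    structure with ``k`` landmarks each; there is no midline and the pairing is
    between the two configurations landmark-by-landmark.

    The reflection used in the symmetry decomposition negates
    ``symmetry_plane_axis`` (by convention the first coordinate axis).
    """

    mode: Literal["object", "matching"]
    paired: tuple[tuple[int, int], ...]
    midline: tuple[int, ...] = ()
    symmetry_plane_axis: int = 0

    def __post_init__(self) -> None:
        paired = tuple((int(a), int(b)) for a, b in self.paired)
        midline = tuple(int(i) for i in self.midline)
        object.__setattr__(self, "paired", paired)
        object.__setattr__(self, "midline", midline)
        if self.mode not in ("object", "matching"):
            raise ValueError(f"invalid mode {self.mode!r}")
        if self.symmetry_plane_axis not in (0, 1, 2):
            raise ValueError("symmetry_plane_axis must be 0, 1 or 2")
        if self.mode == "matching" and self.k < 1:
            raise ValueError("at least one landmark pair is required")
        if self.mode == "object" and self.k == 0 and self.l < 3:
            raise ValueError("an all-midline object scheme needs at least 3 landmarks")
        if self.mode == "matching" and midline:
            raise ValueError("matching symmetry has no midline landmarks")
        if self.mode == "object":
            flat = [i for pair in paired for i in pair] + list(midline)
            if len(set(flat)) != len(flat):
                raise ValueError("paired and midline indices must be disjoint")
            if set(flat) != set(range(self.n_landmarks)):
                raise ValueError(
                    "object symmetry: paired + midline indices must cover "
                    f"0..{self.n_landmarks - 1} exactly"
                )
        else:
            # matching symmetry pairs landmark i of one side with landmark i of
            # the other; the pair list is the identity correspondence
            lefts = [a for a, _ in paired]
            if sorted(lefts) != list(range(len(paired))):
                raise ValueError(
                    "matching symmetry: pair left-indices must cover one side's "
                    "landmarks exactly"
                )

    @classmethod
    def matching(cls, n_landmarks: int, symmetry_plane_axis: int = 0) -> "SymmetryScheme":
        """Matching-symmetry scheme for two sides of ``n_landmarks`` each."""
        return cls(
            mode="matching",
            paired=tuple((i, i) for i in range(n_landmarks)),
            midline=(),
            symmetry_plane_axis=symmetry_plane_axis,
        )

    @property
    def k(self) -> int:
        """Number of landmark pairs."""
        return len(self.paired)

    @property
    def l(self) -> int:
        """Number of midline landmarks (zero for matching symmetry)."""
        return len(self.midline)

    @property
    def n_landmarks(self) -> int:
        """Landmarks per configuration (per side for matching symmetry)."""
        return self.k if self.mode == "matching" else 2 * self.k + self.l

    def relabel_permutation(self) -> np.ndarray:
        """Landmark permutation that swaps left and right labels."""
        perm = np.arange(self.n_landmarks)
        if self.mode == "object":
            for a, b in self.paired:
                perm[a], perm[b] = b, a
        return perm


@dataclass
class AlignedSample:
    """A superimposed cohort: symmetric shape component plus asymmetry.

    Attributes
    ----------
    symmetric_coords : ndarray (N, 3L)
        Per-specimen symmetric shape component (average of the original and
        reflected-relabeled copy, or of the two sides) in the joint Procrustes
        tangent frame.
    asymmetry_coords : ndarray (N, 3L)
        Half the difference between the two copies; zero for perfectly
        symmetric specimens. ``None`` when no symmetry decomposition was done.
    centroid_sizes : ndarray (N,)
        Raw-data centroid size per specimen; for matching symmetry the mean of
        the two sides' centroid sizes.
    mean_shape : ndarray (3L,)
        Consensus (grand mean) shape of the superimposition.
    scheme : SymmetryScheme or None
    specimen_ids : tuple of str
    converged : bool
    n_iterations : int
    """

    symmetric_coords: np.ndarray
    centroid_sizes: np.ndarray
    mean_shape: np.ndarray
    specimen_ids: tuple[str, ...]
    asymmetry_coords: np.ndarray | None = None
    scheme: SymmetryScheme | None = None
    converged: bool = True
    n_iterations: int = 0

    @property
    def n_specimens(self) -> int:
        return self.symmetric_coords.shape[0]

    def replace_coords(self, coords: np.ndarray) -> "AlignedSample":
        """Copy of the sample with new symmetric coordinates (same frame)."""
        return AlignedSample(
            symmetric_coords=np.asarray(coords, float),
            centroid_sizes=self.centroid_sizes,
            mean_shape=coords.mean(axis=0),
            specimen_ids=self.specimen_ids,
            asymmetry_coords=self.asymmetry_coords,
            scheme=self.scheme,
            converged=self.converged,
            n_iterations=self.n_iterations,
        )


@dataclass
class FAScores:
    """Fluctuating-asymmetry scores in Procrustes-distance units.

    ``per_specimen[i]`` is the Procrustes-distance deviation of specimen ``i``'s
    asymmetry component from the cohort mean asymmetry (the directional-
    asymmetry estimate), a standard proxy for developmental instability.
    """

    per_specimen: np.ndarray
    specimen_ids: tuple[str, ...]
    group_means: dict[object, float] = field(default_factory=dict)
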