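"""Generalized Procrustes superimposition and bilateral-symmetry decomposition.

The superimposition is partial Procrustes: configurations are centered, scaled
to unit centroid size and rotated (proper rotations only) to an iteratively
re-estimated consensus, then orthogonally projected to the tangent space at the
consensus so that Euclidean distances between aligned shape vectors are
reproducible Procrustes distances.

Bilateral symmetry is handled in the two standard designs:

* object symmetry — a single structure with an internal midplane; the raw
  configurations and their reflected-relabeled copies are superimposed jointly
  and averaged per specimen;
* matching symmetry — separately digitized left/right structures; one side is
  reflected and all sides are superimposed jointly.

The per-specimen average of the two copies is the symmetric shape component,
and half their difference is the individual asymmetry component.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import (
    AlignedSample,
    DegenerateConfigurationError,
    FAScores,
    LandmarkConfig,
    SymmetryScheme,
)

__all__ = [
    "centroid_size",
    "gpa",
    "GeneralizedProcrustesAnalysis",
    "reflect_and_relabel",
    "decompose_symmetry",
    "shape_space_dim",
    "fa_scores",
    "procrustes_distance",
]


def centroid_size(config: LandmarkConfig | np.ndarray) -> float:
    """Centroid size: sqrt of summed squared landmark distances to the centroid.

    Scale-equivariant: scaling the coordinates by ``c`` scales CS by ``c``.

    Raises
    ------
    DegenerateConfigurationError
        If all landmarks coincide.
    """
    coords = config.coords if isinstance(config, LandmarkConfig) else np.asarray(config, float)
    centered = coords - coords.mean(axis=0)
    cs = float(np.sqrt(np.sum(centered**2)))
    if cs <= 0.0:
        raise DegenerateConfigurationError("all landmarks coincide; centroid size is zero")
    return cs


def _center_and_scale(coords: np.ndarray, check_rank: bool = True) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    cs = np.sqrt(np.sum(centered**2))
    if cs <= 0.0:
        raise DegenerateConfigurationError("degenerate configuration: zero centroid size")
    scaled = centered / cs
    if check_rank and np.linalg.matrix_rank(scaled, tol=1e-10) < 2:
        raise DegenerateConfigurationError(
            "degenerate configuration: landmarks are collinear"
        )
    return scaled


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R (det +1) minimizing ||source @ R - target||_F."""
    h = source.T @ target
    u, _, vt = np.linalg.svd(h)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1.0
        r = u @ vt
    return r


def _tangent_project(flat: np.ndarray, consensus_flat: np.ndarray) -> np.ndarray:
    """Orthogonal projection onto the tangent space at the (unit-norm) consensus."""
    m = consensus_flat / np.linalg.norm(consensus_flat)
    return flat - np.outer(flat @ m - 1.0, m)


class GeneralizedProcrustesAnalysis(BaseEstimator, TransformerMixin):
    """Partial generalized Procrustes superimposition of 3D configurations.

    Fitting iterates: rotate every centered, unit-centroid-size configuration
    onto the current consensus with the closed-form orthogonal Procrustes
    solution (improper rotations forbidden), re-estimate the consensus, and
    repeat until the relative change in summed squared deviations falls below
    ``tol``. ``transform`` aligns configurations to the fitted consensus
    without re-estimating it.

    Parameters
    ----------
    tol : float, default 1e-10
        Relative convergence tolerance on the summed squared deviations.
    max_iter : int, default 100
        Iteration cap; exceeding it raises unless ``allow_nonconvergence``.
    tangent_project : bool, default True
        Project aligned coordinates orthogonally onto the tangent space at the
        consensus, so inter-specimen Euclidean distances are Procrustes
        distances in one flat chart.

    Attributes
    ----------
    mean_shape_ : ndarray (L, 3)
        Consensus configuration, centered with unit centroid size.
    n_iter_ : int
    converged_ : bool
    """

    def __init__(
        self,
        tol: float = 1e-10,
        max_iter: int = 100,
        tangent_project: bool = True,
        allow_nonconvergence: bool = False,
    ) -> None:
        self.tol = tol
        self.max_iter = max_iter
        self.tangent_project = tangent_project
        self.allow_nonconvergence = allow_nonconvergence

    def _validate(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[2] != 3:
            raise ValueError(f"expected an (N, L, 3) array, got {X.shape}")
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite coordinates")
        return X

    def fit(self, X: np.ndarray, y=None) -> "GeneralizedProcrustesAnalysis":
        """Superimpose ``X`` (N, L, 3) and estimate the consensus."""
        X = self._validate(X)
        n = X.shape[0]
        scaled = np.stack([_center_and_scale(c) for c in X])
        consensus = scaled[0].copy()

        prev_ss = np.inf
        converged = False
        n_iter = 0
        aligned = scaled
        for n_iter in range(1, self.max_iter + 1):
            aligned = np.stack([c @ _optimal_rotation(c, consensus) for c in scaled])
            consensus = aligned.mean(axis=0)
            cs = np.sqrt(np.sum(consensus**2))
            if cs <= 0:
                raise DegenerateConfigurationError("consensus collapsed to a point")
            consensus = consensus / cs
            ss = float(np.sum((aligned - consensus) ** 2))
            # the 1e-12 floor keeps the relative criterion meaningful when the
            # fit is exact and ss is pure rounding noise
            if n == 1 or abs(prev_ss - ss) <= self.tol * max(ss, 1e-12):
                converged = True
                break
            prev_ss = ss
        if not converged and not self.allow_nonconvergence:
            raise RuntimeError(
                f"GPA did not converge in {self.max_iter} iterations "
                f"(last change {abs(prev_ss - ss):.3e})"
            )
        self.mean_shape_ = consensus
        self.n_iter_ = n_iter
        self.converged_ = converged
        self._aligned_fit_ = aligned
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Align configurations to the fitted consensus; returns (N, 3L)."""
        X = self._validate(X)
        consensus = self.mean_shape_
        aligned = np.stack(
            [
                (c := _center_and_scale(cfg)) @ _optimal_rotation(c, consensus)
                for cfg in X
            ]
        )
        flat = aligned.reshape(X.shape[0], -1)
        if self.tangent_project:
            flat = _tangent_project(flat, consensus.ravel())
        return flat

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        """Superimpose and return the aligned flattened coordinates (N, 3L)."""
        self.fit(X)
        flat = self._aligned_fit_.reshape(len(self._aligned_fit_), -1)
        if self.tangent_project:
            flat = _tangent_project(flat, self.mean_shape_.ravel())
        return flat


def gpa(
    configs: Sequence[LandmarkConfig],
    tol: float = 1e-10,
    max_iter: int = 100,
    tangent_project: bool = True,
) -> AlignedSample:
    """Generalized Procrustes superimposition of a cohort.

    Thin wrapper over :class:`GeneralizedProcrustesAnalysis`; returns an
    :class:`AlignedSample` without symmetry decomposition (``asymmetry_coords``
    is ``None``).
    """
    configs = list(configs)
    if not configs:
        raise ValueError("no configurations given")
    n_lm = {c.n_landmarks for c in configs}
    if len(n_lm) != 1:
        raise ValueError(f"configurations disagree on landmark count: {sorted(n_lm)}")
    X = np.stack([c.coords for c in configs])
    est = GeneralizedProcrustesAnalysis(
        tol=tol, max_iter=max_iter, tangent_project=tangent_project
    )
    flat = est.fit_transform(X)
    return AlignedSample(
        symmetric_coords=flat,
        centroid_sizes=np.array([centroid_size(c) for c in configs]),
        mean_shape=est.mean_shape_.ravel(),
        specimen_ids=tuple(c.specimen_id for c in configs),
        asymmetry_coords=None,
        scheme=None,
        converged=est.converged_,
        n_iterations=est.n_iter_,
    )


def reflect_coords(coords: np.ndarray, axis: int = 0) -> np.ndarray:
    """Mirror coordinates across the plane normal to ``axis``."""
    out = np.array(coords, dtype=float, copy=True)
    out[:, axis] *= -1.0
    return out


def reflect_and_relabel(
    config: LandmarkConfig | np.ndarray, scheme: SymmetryScheme
) -> LandmarkConfig | np.ndarray:
    """Reflect an object-symmetric configuration and swap left/right labels.

    Negates the symmetry-plane coordinate axis and permutes each bilateral
    landmark pair; midline landmarks keep their labels. The operation is an
    exact involution. Accepts a :class:`LandmarkConfig` or a bare ``(L, 3)``
    array and returns the same type.
    """
    if scheme.mode != "object":
        raise ValueError("reflect_and_relabel applies to object symmetry only")
    coords = config if isinstance(config, np.ndarray) else config.coords
    if coords.shape[0] != scheme.n_landmarks:
        raise ValueError(
            f"scheme expects {scheme.n_landmarks} landmarks, "
            f"configuration has {coords.shape[0]}"
        )
    perm = scheme.relabel_permutation()
    mirrored = reflect_coords(coords, scheme.symmetry_plane_axis)[perm]
    if isinstance(config, np.ndarray):
        return mirrored
    return LandmarkConfig(config.specimen_id, mirrored, config.side)


def decompose_symmetry(
    configs: Sequence[LandmarkConfig],
    scheme: SymmetryScheme,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> AlignedSample:
    """Joint superimposition splitting shape into symmetric + asymmetry parts.

    Object symmetry: each specimen contributes its raw configuration and a
    reflected-relabeled copy to one joint GPA; the per-specimen average of the
    two aligned copies is the symmetric component and half their difference
    (original minus reflected) the asymmetry component.

    Matching symmetry: left configurations are reflected and all sides enter
    one joint GPA; the symmetric component is the per-specimen side average
    and the asymmetry component half of (right − reflected left). Centroid
    size is the average of the two sides' raw centroid sizes.
    """
    configs = list(configs)
    if not configs:
        raise ValueError("no configurations given")

    if scheme.mode == "object":
        ids = [c.specimen_id for c in configs]
        if len(set(ids)) != len(ids):
            raise ValueError("object symmetry expects one configuration per specimen")
        originals = configs
        mirrored = [reflect_and_relabel(c, scheme) for c in configs]
        sizes = np.array([centroid_size(c) for c in originals])
    else:
        by_id: dict[str, dict[str, LandmarkConfig]] = {}
        order: list[str] = []
        for c in configs:
            if c.side not in ("left", "right"):
                raise ValueError(
                    f"matching symmetry needs side left/right, got {c.side!r} "
                    f"for specimen {c.specimen_id!r}"
                )
            if c.specimen_id not in by_id:
                order.append(c.specimen_id)
            by_id.setdefault(c.specimen_id, {})[c.side] = c
        for sid, sides in by_id.items():
            missing = {"left", "right"} - set(sides)
            if missing:
                raise ValueError(f"specimen {sid!r} is missing side(s): {sorted(missing)}")
        originals = [by_id[sid]["right"] for sid in order]
        mirrored = [
            LandmarkConfig(
                sid,
                reflect_coords(by_id[sid]["left"].coords, scheme.symmetry_plane_axis),
                "left",
            )
            for sid in order
        ]
        sizes = np.array(
            [
                0.5
                * (
                    centroid_size(by_id[sid]["right"])
                    + centroid_size(by_id[sid]["left"])
                )
                for sid in order
            ]
        )

    n = len(originals)
    X = np.stack([c.coords for c in originals] + [c.coords for c in mirrored])
    est = GeneralizedProcrustesAnalysis(tol=tol, max_iter=max_iter)
    flat = est.fit_transform(X)
    sym = 0.5 * (flat[:n] + flat[n:])
    asym = 0.5 * (flat[:n] - flat[n:])
    return AlignedSample(
        symmetric_coords=sym,
        centroid_sizes=sizes,
        mean_shape=est.mean_shape_.ravel(),
        specimen_ids=tuple(c.specimen_id for c in originals),
        asymmetry_coords=asym,
        scheme=scheme,
        converged=est.converged_,
        n_iterations=est.n_iter_,
    )


def shape_space_dim(scheme: SymmetryScheme) -> int:
    """Dimensionality of the symmetric shape component's space.

    Object symmetry with ``k`` landmark pairs and ``l`` midline landmarks:
    ``3k + 2l − 4``. Matching symmetry with ``k`` landmarks per side:
    ``3k − 7``.
    """
    if scheme.mode == "object":
        return 3 * scheme.k + 2 * scheme.l - 4
    return 3 * scheme.k - 7


def fa_scores(
    sample: AlignedSample, groups: Sequence[object] | None = None
) -> FAScores:
    """Per-specimen fluctuating-asymmetry scores.

    Each score is the Procrustes-distance norm of the deviation of the
    specimen's asymmetry component from the cohort's mean asymmetry component
    (the directional-asymmetry estimate). Scores are zero for a perfectly
    symmetric cohort, and also when every specimen shares the same (purely
    directional) asymmetry.
    """
    if sample.asymmetry_coords is None:
        raise ValueError("sample has no asymmetry decomposition; run decompose_symmetry")
    dev = sample.asymmetry_coords - sample.asymmetry_coords.mean(axis=0)
    scores = np.linalg.norm(dev, axis=1)
    group_means: dict[object, float] = {}
    if groups is not None:
        groups = np.asarray(groups)
        if groups.shape[0] != scores.shape[0]:
            raise ValueError("groups length must match number of specimens")
        for g in np.unique(groups):
            group_means[g.item() if hasattr(g, "item") else g] = float(
                scores[groups == g].mean()
            )
    return FAScores(
        per_specimen=scores,
        specimen_ids=sample.specimen_ids,
        group_means=group_means,
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two shape vectors in a common frame."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"shape vectors differ in length: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))
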