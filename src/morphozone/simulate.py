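"""Synthetic landmark datasets with a polygenic additive admixture architecture.

The generator emulates a hybrid-zone study design: specimens fall into ten
admixture deciles (hybrid groups 0–9) with configurable per-group sample,
family and sex counts; the expected symmetric shape of a specimen with
admixture proportion ``h`` is ``mus + h·(dom − mus)`` (optionally plus a
dominance-like quadratic term), with added family, sex, allometric and
residual deviations, plus directional and fluctuating asymmetry, all wrapped
in nuisance position/orientation and digitization jitter that a Procrustes
superimposition must remove.

Every shape deviation is drawn in an orthonormal basis of the appropriate
(symmetric or asymmetric) tangent subspace at the template mean, orthogonal to
the similarity modes (translation, rotation, scale). Two consequences: the
symmetric-subspace dimension equals the closed-form shape-space
dimensionality, and variance components are exact in Procrustes units, so
effect magnitudes can be calibrated analytically from target variance
fractions rather than tuned by trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datatypes import LandmarkConfig, SymmetryScheme
from .procrustes import centroid_size, reflect_coords, shape_space_dim

__all__ = [
    "SimulationParams",
    "TruthRecord",
    "skull_scheme",
    "mandible_scheme",
    "landmark_template",
    "symmetric_tangent_basis",
    "asymmetric_tangent_basis",
    "simulate_parental_shapes",
    "simulate_hybrid_dataset",
]

# Study-design defaults: per-decile specimen, family and male counts of the
# 249-mouse hybrid-zone sample (group 7 unobserved).
GROUP_SIZES_DEFAULT = (6, 39, 67, 23, 31, 26, 31, 0, 9, 17)
FAMILIES_PER_GROUP_DEFAULT = (1, 9, 17, 7, 5, 12, 10, 0, 3, 7)
MALES_PER_GROUP_DEFAULT = (2, 30, 67, 23, 17, 26, 25, 0, 3, 11)


def skull_scheme() -> SymmetryScheme:
    """Object-symmetry scheme of a 44-landmark skull: 17 pairs + 10 midline."""
    paired = tuple((2 * i, 2 * i + 1) for i in range(17))
    midline = tuple(range(34, 44))
    return SymmetryScheme(mode="object", paired=paired, midline=midline)


def mandible_scheme(n_landmarks: int = 13) -> SymmetryScheme:
    """Matching-symmetry scheme of paired hemimandibles (13 landmarks/side)."""
    return SymmetryScheme.matching(n_landmarks)


def _smooth_field(t: np.ndarray, rng: np.random.Generator, amplitude: float) -> np.ndarray:
    """Seeded low-frequency trigonometric deformation along a parameter."""
    out = np.zeros_like(t)
    for order in range(1, 4):
        a, b = rng.normal(size=2)
        out += (a * np.sin(2 * np.pi * order * t) + b * np.cos(2 * np.pi * order * t)) / order
    return amplitude * out


def landmark_template(scheme: SymmetryScheme, seed: int = 0) -> np.ndarray:
    """Deterministic non-degenerate template configuration for a scheme.

    Object mode: exactly mirror-symmetric about the symmetry plane (paired
    landmarks mirrored, midline landmarks in-plane). Matching mode: a single
    side's configuration. Centered, unit centroid size.
    """
    rng = np.random.default_rng(seed)
    axis = scheme.symmetry_plane_axis
    if scheme.mode == "object":
        k, l = scheme.k, scheme.l
        t = (np.arange(k) + 1.0) / (k + 1.0)
        right = np.column_stack(
            [
                0.45 + 0.25 * np.sin(2 * np.pi * t + 0.5) + np.abs(_smooth_field(t, rng, 0.1)),
                2.0 * (t - 0.5) + _smooth_field(t, rng, 0.15),
                0.6 * np.cos(np.pi * t) + _smooth_field(t, rng, 0.15),
            ]
        )
        s = (np.arange(l) + 1.0) / (l + 1.0)
        mid = np.column_stack(
            [
                np.zeros(l),
                2.0 * (s - 0.5) + _smooth_field(s, rng, 0.1),
                0.8 * np.sin(np.pi * s + 1.0) + _smooth_field(s, rng, 0.2),
            ]
        )
        coords = np.zeros((scheme.n_landmarks, 3))
        for j, (a, b) in enumerate(scheme.paired):
            coords[a] = right[j]
            coords[b] = right[j]
            coords[b, 0] *= -1.0
        for j, idx in enumerate(scheme.midline):
            coords[idx] = mid[j]
        if axis != 0:  # template is built with the plane normal on axis 0
            coords[:, [0, axis]] = coords[:, [axis, 0]]
    else:
        k = scheme.k
        t = (np.arange(k) + 1.0) / (k + 1.0)
        coords = np.column_stack(
            [
                0.4 + 0.3 * np.sin(2 * np.pi * t) + _smooth_field(t, rng, 0.15),
                2.0 * (t - 0.5) + _smooth_field(t, rng, 0.1),
                0.6 * np.cos(3 * np.pi * t) + _smooth_field(t, rng, 0.2),
            ]
        )
    coords -= coords.mean(axis=0)
    coords /= centroid_size(coords)
    # an all-midline object scheme is inherently planar (every landmark lies
    # on the symmetry plane), so only non-collinearity can be required there
    min_rank = 2 if (scheme.mode == "object" and scheme.k == 0) else 3
    if np.linalg.matrix_rank(coords, tol=1e-8) < min_rank:
        if seed > 1000:
            raise RuntimeError("could not build a non-degenerate template")
        return landmark_template(scheme, seed + 1)
    return coords


def _reflect_flat(v: np.ndarray, scheme: SymmetryScheme) -> np.ndarray:
    """Apply the reflect-and-relabel linear operator to a flattened vector."""
    pts = v.reshape(-1, 3)
    perm = scheme.relabel_permutation()
    return reflect_coords(pts, scheme.symmetry_plane_axis)[perm].ravel()


def _similarity_modes(template: np.ndarray) -> np.ndarray:
    """Translation, rotation and scale modes at a configuration (7 × 3L)."""
    n = template.shape[0]
    modes = []
    for a in range(3):
        t = np.zeros((n, 3))
        t[:, a] = 1.0
        modes.append(t.ravel())
    modes.append(template.ravel())  # scale
    eye = np.eye(3)
    for a in range(3):
        modes.append(np.cross(eye[a], template).ravel())
    return np.stack(modes)


def _subspace_basis(candidates: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Orthonormal basis of span(candidates) minus the similarity modes."""
    sim = _similarity_modes(template)
    q_sim, _ = np.linalg.qr(sim.T)
    residual = candidates - q_sim @ (q_sim.T @ candidates)
    u, s, _ = np.linalg.svd(residual, full_matrices=False)
    return u[:, s > 1e-8 * s[0]]


def symmetric_tangent_basis(template: np.ndarray, scheme: SymmetryScheme) -> np.ndarray:
    """Orthonormal basis (3L × dim) of symmetric tangent shape deviations.

    For object symmetry, the +1 eigenspace of the reflect-relabel operator
    minus the similarity modes; its dimension equals ``shape_space_dim``.
    For matching symmetry (one side's configuration), the whole tangent
    space, of dimension 3k − 7.
    """
    d = template.size
    eye = np.eye(d)
    if scheme.mode == "object":
        refl = np.stack([_reflect_flat(eye[i], scheme) for i in range(d)], axis=1)
        candidates = 0.5 * (eye + refl)
    else:
        candidates = eye
    basis = _subspace_basis(candidates, template)
    expected = shape_space_dim(scheme)
    if basis.shape[1] != expected:
        raise RuntimeError(
            f"symmetric tangent basis has dimension {basis.shape[1]}, "
            f"expected {expected}"
        )
    return basis


def asymmetric_tangent_basis(template: np.ndarray, scheme: SymmetryScheme) -> np.ndarray:
    """Orthonormal basis of asymmetric tangent deviations.

    Object symmetry: the −1 eigenspace of the reflect-relabel operator minus
    similarity modes. Matching symmetry: side differences live in the same
    single-configuration tangent space as symmetric deviations.
    """
    if scheme.mode == "matching":
        return symmetric_tangent_basis(template, scheme)
    d = template.size
    eye = np.eye(d)
    refl = np.stack([_reflect_flat(eye[i], scheme) for i in range(d)], axis=1)
    return _subspace_basis(0.5 * (eye - refl), template)


def simulate_parental_shapes(
    scheme: SymmetryScheme,
    seed: int = 0,
    divergence_vector_scale: float = 0.026,
) -> tuple[np.ndarray, np.ndarray]:
    """Template mean shapes of the two parental taxa.

    ``dom`` differs from ``mus`` by a symmetric tangent-space perturbation of
    Procrustes norm ``divergence_vector_scale``, so the Procrustes distance
    between the aligned means matches the requested scale to first order.
    """
    mus = landmark_template(scheme, seed)
    if divergence_vector_scale == 0:
        return mus, mus.copy()
    basis = symmetric_tangent_basis(mus, scheme)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2101]))
    u = rng.standard_normal(basis.shape[1])
    delta = basis @ (u / np.linalg.norm(u) * divergence_vector_scale)
    return mus, mus + delta.reshape(mus.shape)


@dataclass
class SimulationParams:
    """Study-design parameters of the synthetic hybrid dataset.

    Effect magnitudes are specified as target fractions of the total
    non-allometric symmetric shape variance (admixture, sex, family), as a
    fraction-of-total for allometry, and as Procrustes-unit magnitudes for
    the mean-shape divergence, directional asymmetry and mean fluctuating
    asymmetry; residual noise absorbs the remainder. Defaults reproduce the
    skull arm of the study design (44 landmarks, 249 specimens in 9 observed
    admixture deciles, admixture ≈ 8.4 % of shape variance, sex 1.9 %,
    allometry 5.4 %, divergence 0.026, mean FA 0.01); use
    :meth:`mandible_defaults` for the hemimandible arm.
    """

    scheme: SymmetryScheme = field(default_factory=skull_scheme)
    group_sizes: tuple[int, ...] = GROUP_SIZES_DEFAULT
    families_per_group: tuple[int, ...] = FAMILIES_PER_GROUP_DEFAULT
    males_per_group: tuple[int, ...] | None = MALES_PER_GROUP_DEFAULT
    divergence_vector_scale: float = 0.026
    admixture_var_fraction: float = 0.084
    sex_var_fraction: float = 0.019
    family_var_fraction: float = 0.20
    allometry_var_fraction: float = 0.054
    fa_mean_target: float = 0.01
    da_vector_scale: float = 0.005
    additive: bool = True
    dominance_scale: float = 0.0
    cs_mean: float = 50.0
    cs_sd: float = 1.5
    translation_range: float = 100.0
    rotation_nuisance: bool = True
    device_scale_range: tuple[float, float] = (1.0, 1.0)
    jitter_sd: float = 0.0
    residual_sd: float | None = None
    family_sd: float | None = None
    seed: int = 0

    @classmethod
    def mandible_defaults(cls, **overrides) -> "SimulationParams":
        """Parameters for the matching-symmetry hemimandible design."""
        base = dict(
            scheme=mandible_scheme(),
            divergence_vector_scale=0.042,
            admixture_var_fraction=0.108,
            sex_var_fraction=0.039,
            allometry_var_fraction=0.018,
            fa_mean_target=0.028,
            cs_mean=20.0,
            cs_sd=0.6,
        )
        base.update(overrides)
        return cls(**base)

    def __post_init__(self) -> None:
        if len(self.group_sizes) != 10:
            raise ValueError("group_sizes must have length 10 (deciles 0–9)")
        if any(n < 0 for n in self.group_sizes) or sum(self.group_sizes) == 0:
            raise ValueError("group sizes must be non-negative with at least one specimen")
        for name in (
            "admixture_var_fraction",
            "sex_var_fraction",
            "family_var_fraction",
            "allometry_var_fraction",
        ):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.admixture_var_fraction <= 0:
            raise ValueError("admixture_var_fraction must be positive")
        total = self.admixture_var_fraction + self.sex_var_fraction + self.family_var_fraction
        if total >= 1:
            raise ValueError("variance fractions exceed the total; nothing left for noise")

    @property
    def n_specimens(self) -> int:
        return int(sum(self.group_sizes))

    def admixture_variance(self) -> float:
        """Variance of the admixture proportion h under uniform-within-decile draws."""
        sizes = np.asarray(self.group_sizes, float)
        w = sizes / sizes.sum()
        centers = (np.arange(10) + 0.5) / 10.0
        eh = float(w @ centers)
        eh2 = float(w @ (centers**2 + 0.1**2 / 12.0))
        return eh2 - eh**2


@dataclass
class TruthRecord:
    """Ground truth of a simulated dataset, for parameter-recovery checks."""

    mus_mean: np.ndarray
    dom_mean: np.ndarray
    effect_vectors: dict[str, np.ndarray]
    h: np.ndarray
    family: np.ndarray
    sex: np.ndarray
    cs: np.ndarray
    realized_variance_fractions: dict[str, float]
    derived_scales: dict[str, float]

    def to_jsonable(self) -> dict:
        return {
            "mus_mean": self.mus_mean.tolist(),
            "dom_mean": self.dom_mean.tolist(),
            "effect_vectors": {k: v.tolist() for k, v in self.effect_vectors.items()},
            "h": self.h.tolist(),
            "family": self.family.tolist(),
            "sex": self.sex.tolist(),
            "cs": self.cs.tolist(),
            "realized_variance_fractions": self.realized_variance_fractions,
            "derived_scales": self.derived_scales,
        }


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1.0
    return q


def _male_counts(params: SimulationParams) -> list[int]:
    """Per-group male counts, rescaled if group sizes differ from the defaults."""
    counts = []
    for g, n in enumerate(params.group_sizes):
        if n == 0:
            counts.append(0)
            continue
        if params.males_per_group is None:
            counts.append(int(round(0.5 * n)))
            continue
        ref_n = GROUP_SIZES_DEFAULT[g]
        ref_m = params.males_per_group[g]
        if ref_n == n:
            counts.append(min(ref_m, n))
        else:
            frac = ref_m / ref_n if ref_n > 0 else 0.5
            counts.append(int(round(frac * n)))
    return counts


def simulate_hybrid_dataset(params: SimulationParams):
    """Simulate raw landmark configurations plus covariates and ground truth.

    Returns ``(configs, covariates, truth)``. In object mode there is one
    ``whole`` configuration per specimen; in matching mode a ``right`` and a
    ``left`` configuration. Covariates columns: ``specimen_id, pct_dom,
    family_id, sex, age_weeks``. The same params and seed reproduce the
    output bit-identically.
    """
    import pandas as pd

    scheme = params.scheme
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 7919]))
    mus, dom = simulate_parental_shapes(
        scheme, params.seed, params.divergence_vector_scale
    )
    n_lm = mus.shape[0]
    b_sym = symmetric_tangent_basis(mus, scheme)
    b_asym = asymmetric_tangent_basis(mus, scheme)
    dim_s, dim_a = b_sym.shape[1], b_asym.shape[1]
    d_flat = (dom - mus).ravel()
    n_total = params.n_specimens

    # --- analytic calibration of magnitudes from target variance fractions ---
    var_adm = params.admixture_variance() * params.divergence_vector_scale**2
    total_var = var_adm / params.admixture_var_fraction
    male_counts = _male_counts(params)
    p_male = sum(male_counts) / n_total
    p_male = min(max(p_male, 1e-6), 1 - 1e-6)
    sex_scale = float(np.sqrt(params.sex_var_fraction * total_var / (p_male * (1 - p_male))))
    family_sd = (
        params.family_sd
        if params.family_sd is not None
        else float(np.sqrt(params.family_var_fraction * total_var / dim_s))
    )
    if params.residual_sd is not None:
        residual_sd = params.residual_sd
    else:
        resid_var = total_var * (
            1.0 - params.admixture_var_fraction - params.sex_var_fraction
        )
        resid_var -= family_sd**2 * dim_s
        if resid_var <= 0:
            raise ValueError("variance fractions leave no room for residual noise")
        residual_sd = float(np.sqrt(resid_var / dim_s))
    allo_var = total_var * params.allometry_var_fraction / (1.0 - params.allometry_var_fraction)
    if allo_var == 0.0:
        allometry_slope = 0.0
    elif params.cs_sd <= 0:
        raise ValueError("allometric variance requires cs_sd > 0")
    else:
        allometry_slope = float(np.sqrt(allo_var)) / params.cs_sd
    fa_sd = params.fa_mean_target / np.sqrt(dim_a) if dim_a > 0 else 0.0

    def unit(dim: int) -> np.ndarray:
        u = rng.standard_normal(dim)
        return u / np.linalg.norm(u)

    sex_vec = b_sym @ (unit(dim_s) * sex_scale)
    allo_vec = b_sym @ unit(dim_s)
    dom_vec = b_sym @ (unit(dim_s) * params.dominance_scale)
    da_vec = b_asym @ (unit(dim_a) * params.da_vector_scale)

    # --- per-specimen draws ---
    records = []
    h_all, fam_all, sex_all, cs_all = [], [], [], []
    sym_components: dict[str, list[np.ndarray]] = {
        k: [] for k in ("admixture", "family", "sex", "allometry", "residual")
    }
    family_effects: dict[str, np.ndarray] = {}
    configs: list[LandmarkConfig] = []
    spec_counter = 0
    for g, n_g in enumerate(params.group_sizes):
        if n_g == 0:
            continue
        n_fam = max(1, params.families_per_group[g])
        sexes = np.array(["m"] * male_counts[g] + ["f"] * (n_g - male_counts[g]))
        sexes = rng.permutation(sexes)
        for j in range(n_g):
            sid = f"s{spec_counter:03d}"
            spec_counter += 1
            h = rng.uniform(g / 10.0, (g + 1) / 10.0)
            fam = f"g{g}f{j % n_fam}"
            if fam not in family_effects:
                family_effects[fam] = b_sym @ (family_sd * rng.standard_normal(dim_s))
            sex = sexes[j]
            cs = rng.normal(params.cs_mean, params.cs_sd)

            comp_adm = h * d_flat
            if not params.additive:
                comp_adm = comp_adm + h * (1.0 - h) * dom_vec
            comp_fam = family_effects[fam]
            comp_sex = sex_vec if sex == "m" else np.zeros_like(sex_vec)
            comp_allo = allometry_slope * (cs - params.cs_mean) * allo_vec
            comp_resid = b_sym @ (residual_sd * rng.standard_normal(dim_s))
            sym_dev = comp_adm + comp_fam + comp_sex + comp_allo + comp_resid
            asym_dev = da_vec + b_asym @ (fa_sd * rng.standard_normal(dim_a))

            for key, comp in zip(
                sym_components, (comp_adm, comp_fam, comp_sex, comp_allo, comp_resid)
            ):
                sym_components[key].append(comp)
            h_all.append(h)
            fam_all.append(fam)
            sex_all.append(sex)
            cs_all.append(cs)
            records.append(
                {
                    "specimen_id": sid,
                    "pct_dom": 100.0 * h,
                    "family_id": fam,
                    "sex": sex,
                    "age_weeks": int(rng.integers(9, 14)),
                }
            )

            sym_shape = mus + sym_dev.reshape(n_lm, 3)

            def nuisance(coords: np.ndarray) -> np.ndarray:
                out = coords * cs
                lo, hi = params.device_scale_range
                if (lo, hi) != (1.0, 1.0):
                    out = out * rng.uniform(lo, hi)
                if params.rotation_nuisance:
                    out = out @ _random_rotation(rng).T
                out = out + rng.uniform(
                    -params.translation_range, params.translation_range, 3
                )
                if params.jitter_sd > 0:
                    out = out + rng.normal(0.0, params.jitter_sd, out.shape)
                return out

            if scheme.mode == "object":
                whole = sym_shape + asym_dev.reshape(n_lm, 3)
                configs.append(LandmarkConfig(sid, nuisance(whole), "whole"))
            else:
                right = sym_shape + asym_dev.reshape(n_lm, 3)
                left = reflect_coords(
                    sym_shape - asym_dev.reshape(n_lm, 3), scheme.symmetry_plane_axis
                )
                configs.append(LandmarkConfig(sid, nuisance(right), "right"))
                configs.append(LandmarkConfig(sid, nuisance(left), "left"))

    covariates = pd.DataFrame.from_records(records)

    # realized marginal variance shares of the symmetric deviations
    comp_mats = {k: np.stack(v) for k, v in sym_components.items()}
    total_dev = sum(comp_mats.values())
    total_nonallo = total_dev - comp_mats["allometry"]

    def ss(mat: np.ndarray) -> float:
        return float(np.sum((mat - mat.mean(axis=0)) ** 2))

    ss_total = ss(total_dev)
    ss_nonallo = ss(total_nonallo)
    # zero-variance (fully noiseless) datasets have no defined shares
    realized = {
        f"{k}_of_total": (ss(m) / ss_total if ss_total > 0 else 0.0)
        for k, m in comp_mats.items()
    }
    realized.update(
        {
            f"{k}_of_nonallometric": (ss(m) / ss_nonallo if ss_nonallo > 0 else 0.0)
            for k, m in comp_mats.items()
            if k != "allometry"
        }
    )

    truth = TruthRecord(
        mus_mean=mus,
        dom_mean=dom,
        effect_vectors={
            "admixture": d_flat,
            "sex": sex_vec,
            "allometry": allometry_slope * allo_vec,
            "directional_asymmetry": da_vec,
            "dominance": dom_vec,
        },
        h=np.array(h_all),
        family=np.array(fam_all),
        sex=np.array(sex_all),
        cs=np.array(cs_all),
        realized_variance_fractions=realized,
        derived_scales={
            "sex_effect_scale": sex_scale,
            "family_sd": family_sd,
            "residual_sd": residual_sd,
            "allometry_slope": allometry_slope,
            "fa_sd": float(fa_sd),
            "symmetric_dim": float(dim_s),
            "asymmetric_dim": float(dim_a),
        },
    )
    return configs, covariates, truth
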