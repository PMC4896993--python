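"""End-to-end hybrid-gradient analysis of a landmark cohort.

Orchestrates the full design: symmetry decomposition, allometric correction,
decile hybrid-group assignment, size analyses, extreme-group comparison,
gradient regression and ordination, all pairwise group comparisons, the
shape-distance vs genomic-distance correlation, and shape-change-vector
direction tests, assembled into an :class:`AnalysisReport` of tidy tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import AlignedSample, LandmarkConfig, SymmetryScheme
from .procrustes import (
    decompose_symmetry,
    fa_scores,
    procrustes_distance,
    shape_space_dim,
)
from .stats import (
    AngleResult,
    HotellingResult,
    MantelResult,
    RegressionResult,
    angle_test,
    between_group_pca,
    holm_adjust,
    hotelling_two_sample,
    lda_loocv,
    mantel_test,
    pairwise_rank_test,
    pca_reduce,
    shape_regression_permutation,
)

logger = logging.getLogger("morphozone")

__all__ = [
    "PipelineConfig",
    "AnalysisReport",
    "assign_hybrid_groups",
    "consecutive_group_steps",
    "remove_allometry",
    "pool_extremes",
    "run_full_pipeline",
]


def assign_hybrid_groups(covariates: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bin specimens into admixture deciles (hybrid groups 0–9).

    Group ``g`` holds specimens with ``pct_dom`` in ``[10g, 10(g+1))``
    (left-closed), with group 9 closed at 100. Returns ``(grouping,
    summary)``: the covariate table with a ``group`` column, and a per-group
    summary with count, family count, sex counts and mean admixture, followed
    by the consecutive-group step statistics on the observed group means.
    """
    cov = covariates.copy()
    pct = np.asarray(cov["pct_dom"], float)
    if np.any((pct < 0) | (pct > 100)) or not np.all(np.isfinite(pct)):
        raise ValueError("pct_dom must lie in [0, 100]")
    cov["group"] = np.minimum(np.floor(pct / 10.0).astype(int), 9)

    rows = []
    for g, sub in cov.groupby("group"):
        rows.append(
            {
                "group": int(g),
                "n": len(sub),
                "n_families": sub["family_id"].nunique() if "family_id" in sub else np.nan,
                "n_male": int((sub["sex"] == "m").sum()) if "sex" in sub else np.nan,
                "n_female": int((sub["sex"] == "f").sum()) if "sex" in sub else np.nan,
                "mean_pct_dom": float(sub["pct_dom"].mean()),
            }
        )
    summary = pd.DataFrame(rows).sort_values("group").reset_index(drop=True)
    steps = consecutive_group_steps(summary["mean_pct_dom"].to_numpy())
    summary.attrs["step_statistics"] = steps
    return cov, summary


def consecutive_group_steps(group_means: Sequence[float]) -> dict[str, float]:
    """Mean/min/max of differences between successive observed group means."""
    means = np.asarray(group_means, float)
    if means.size < 2:
        raise ValueError("need at least two group means")
    diffs = np.diff(means)
    return {
        "mean_step": float(diffs.mean()),
        "min_step": float(diffs.min()),
        "max_step": float(diffs.max()),
    }


def remove_allometry(sample: AlignedSample) -> tuple[AlignedSample, float]:
    """Remove size-predictable shape variation by regression residuals.

    Each symmetric shape coordinate is regressed on centroid size; the
    corrected shapes are the residuals with the grand mean added back.
    Returns the corrected sample and the percentage of total shape variance
    attributable to size (allometry).
    """
    cs = np.asarray(sample.centroid_sizes, float)
    if np.ptp(cs) == 0:
        raise ValueError("centroid size is constant; allometric regression undefined")
    X = sample.symmetric_coords
    Xc = X - X.mean(axis=0)
    csc = cs - cs.mean()
    beta = Xc.T @ csc / float(csc @ csc)
    fitted = np.outer(csc, beta)
    pct = 100.0 * float(np.sum(fitted**2)) / float(np.sum(Xc**2))
    corrected = X - fitted
    return sample.replace_coords(corrected), pct


def pool_extremes(grouping: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Pool the gradient extremes: groups 0∪1 → ``mus``, groups 8∪9 → ``dom``.

    Returns ``(labels, summary)`` where ``labels`` maps each specimen to
    ``"mus"``, ``"dom"`` or NA, and ``summary`` gives pooled sizes and mean
    admixture.
    """
    labels = pd.Series(pd.NA, index=grouping.index, dtype="object")
    labels[grouping["group"].isin([0, 1])] = "mus"
    labels[grouping["group"].isin([8, 9])] = "dom"
    rows = []
    for name in ("mus", "dom"):
        sub = grouping[labels == name]
        if len(sub) == 0:
            raise ValueError(f"no specimens in the pooled {name!r} extreme")
        rows.append(
            {
                "pooled_group": name,
                "n": len(sub),
                "mean_pct_dom": float(sub["pct_dom"].mean()),
                "min_pct_dom": float(sub["pct_dom"].min()),
                "max_pct_dom": float(sub["pct_dom"].max()),
            }
        )
    return labels, pd.DataFrame(rows)


@dataclass
class PipelineConfig:
    """Tunable parameters of the full analysis."""

    n_pcs: int = 10
    n_perm: int = 10000
    seed: int = 0
    angle_dim: int | None = None  # None -> full symmetric shape-space dim
    min_group_size: int = 2
    genomic_distance_subset_pct: float = 20.0


@dataclass
class AnalysisReport:
    """All tables produced by one full pipeline run."""

    group_table: pd.DataFrame
    step_statistics: dict[str, float]
    size_results: dict[str, object]
    allometry_pct: float
    sex_pct: float
    age_pct: float | None
    extremes_summary: pd.DataFrame
    extremes_comparison: dict[str, object]
    gradient_regression: RegressionResult
    gradient_scores: pd.DataFrame
    bgpca_group_scores: pd.DataFrame
    bgpca_individual_scores: pd.DataFrame
    group_variance: pd.DataFrame
    pairwise_table: pd.DataFrame
    direction_table: pd.DataFrame
    distance_correlation: MantelResult
    distance_correlation_subset: MantelResult
    procrustes_distance_matrix: pd.DataFrame
    genomic_distance_matrix: pd.DataFrame
    aligned: AlignedSample
    grouping: pd.DataFrame
    config: PipelineConfig


def _variance_pct_on_indicator(X: np.ndarray, indicator: np.ndarray) -> float:
    """Percent of total variance predicted by a 0/1 (or scalar) covariate."""
    z = np.asarray(indicator, float)
    if np.ptp(z) == 0:
        return 0.0
    Xc = X - X.mean(axis=0)
    zc = z - z.mean()
    ss_pred = float(np.sum((Xc.T @ zc) ** 2)) / float(zc @ zc)
    return 100.0 * ss_pred / float(np.sum(Xc**2))


def _subset_pair_correlation(
    shape_d: np.ndarray, genomic_d: np.ndarray, n_perm: int, seed: int
) -> MantelResult:
    """Permutation Pearson correlation over a subset of pairwise entries.

    The near-pairs subset is not a complete distance matrix, so a Mantel
    permutation is unavailable; the pair values themselves are permuted.
    """
    if shape_d.size < 3:
        return MantelResult(r=float("nan"), p_perm=float("nan"), n_perm=0)
    r_obs = float(np.corrcoef(shape_d, genomic_d)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        r = float(np.corrcoef(shape_d, rng.permutation(genomic_d))[0, 1])
        if abs(r) >= abs(r_obs) - 1e-12:
            count += 1
    return MantelResult(r=r_obs, p_perm=(count + 1) / (n_perm + 1), n_perm=n_perm)


def run_full_pipeline(
    configs: Sequence[LandmarkConfig],
    scheme: SymmetryScheme,
    covariates: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> AnalysisReport:
    """Execute the complete hybrid-gradient analysis.

    Stages, in order: symmetry decomposition → allometry removal → hybrid
    group assignment → centroid-size analyses → pooled-extremes comparison
    (per-pair PCA to ``n_pcs``, Hotelling T², Procrustes distance, LDA with
    leave-one-out validation) → gradient analyses (permutation regression of
    shape on admixture, projection scores, between-group PCA, per-group
    variance and FA means) → all pairwise group comparisons with per-pair PCA
    and Holm correction → Procrustes-vs-genomic distance Mantel test (full and
    near-pairs subset) → shape-change-vector direction tests against the
    mus→dom vector with Holm correction.
    """
    cfg = config or PipelineConfig()
    stage = "symmetry decomposition"
    try:
        aligned = decompose_symmetry(configs, scheme)
        logger.info("decomposed %d specimens (%d GPA iterations)",
                    aligned.n_specimens, aligned.n_iterations)

        stage = "group assignment"
        cov = covariates.set_index("specimen_id").loc[list(aligned.specimen_ids)].reset_index()
        grouping, group_table = assign_hybrid_groups(cov)
        steps = group_table.attrs["step_statistics"]

        stage = "covariate variance accounting"
        sex_pct = _variance_pct_on_indicator(
            aligned.symmetric_coords, (grouping["sex"] == "m").to_numpy(float)
        ) if "sex" in grouping else float("nan")
        age_pct = (
            _variance_pct_on_indicator(
                aligned.symmetric_coords, grouping["age_weeks"].to_numpy(float)
            )
            if "age_weeks" in grouping and grouping["age_weeks"].nunique() > 1
            else None
        )

        stage = "allometry removal"
        corrected, allo_pct = remove_allometry(aligned)
        logger.info("allometry: %.2f%% of shape variance removed", allo_pct)
        X = corrected.symmetric_coords
        groups = grouping["group"].to_numpy()
        pct_dom = grouping["pct_dom"].to_numpy(float)

        stage = "centroid size analyses"
        cs = aligned.centroid_sizes
        lin = sps.linregress(pct_dom, cs)
        size_results = {
            "cs_regression_r": float(lin.rvalue),
            "cs_regression_p": float(lin.pvalue),
            "cs_regression_slope": float(lin.slope),
            "pairwise_rank_tests": pd.DataFrame(pairwise_rank_test(cs, groups)),
            "group_mean_cs": {
                int(g): float(cs[groups == g].mean()) for g in np.unique(groups)
            },
        }

        stage = "pooled extremes comparison"
        ext_labels, extremes_summary = pool_extremes(grouping)
        ext_mask = ext_labels.notna().to_numpy()
        # cap retained PCs as in the pairwise stage: keep Hotelling df2 ≥ 1
        # and the LOOCV within-class scatter nonsingular
        n_pc_ext = min(cfg.n_pcs, int(ext_mask.sum()) - 3)
        if n_pc_ext < cfg.n_pcs:
            logger.warning(
                "pooled extremes: retaining %d PCs (n=%d too small for %d)",
                n_pc_ext, int(ext_mask.sum()), cfg.n_pcs,
            )
        ext_scores, _ = pca_reduce(X[ext_mask], n_pc_ext)
        ext_y = ext_labels[ext_mask].to_numpy()
        hot = hotelling_two_sample(ext_scores[ext_y == "mus"], ext_scores[ext_y == "dom"])
        mus_mean = X[ext_mask][ext_y == "mus"].mean(axis=0)
        dom_mean = X[ext_mask][ext_y == "dom"].mean(axis=0)
        extremes_comparison = {
            "hotelling": hot,
            "procrustes_distance": procrustes_distance(mus_mean, dom_mean),
            "misclassification_fraction": lda_loocv(ext_scores, ext_y),
        }

        stage = "gradient regression"
        reg = shape_regression_permutation(X, pct_dom, n_perm=cfg.n_perm, seed=cfg.seed)
        gradient_scores = pd.DataFrame(
            {
                "specimen_id": aligned.specimen_ids,
                "group": groups,
                "pct_dom": pct_dom,
                "sex": grouping["sex"] if "sex" in grouping else pd.NA,
                "projection_score": reg.projection_scores,
            }
        )

        stage = "between-group PCA"
        axes, group_scores, indiv_scores = between_group_pca(X, groups)
        observed = np.unique(groups)
        n_axes = group_scores.shape[1]
        bg_cols = [f"bgPC{i + 1}" for i in range(n_axes)]
        bgpca_groups = pd.DataFrame(group_scores, columns=bg_cols)
        bgpca_groups.insert(0, "group", observed)
        bgpca_indiv = pd.DataFrame(indiv_scores, columns=bg_cols)
        bgpca_indiv.insert(0, "group", groups)
        bgpca_indiv.insert(0, "specimen_id", aligned.specimen_ids)

        stage = "per-group variance and FA"
        fa = fa_scores(aligned, groups)
        var_rows = []
        for g in observed:
            sub = X[groups == g]
            if len(sub) > 1:
                ssd = float(np.sum((sub - sub.mean(axis=0)) ** 2)) / (len(sub) - 1)
            else:
                ssd = float("nan")
            var_rows.append(
                {
                    "group": int(g),
                    "n": int(len(sub)),
                    "phenotypic_variance": ssd,
                    "phenotypic_variance_sqrt": float(np.sqrt(ssd)),
                    "mean_fa": fa.group_means.get(int(g), float("nan")),
                }
            )
        group_variance = pd.DataFrame(var_rows)

        stage = "pairwise group comparisons"
        usable = [
            int(g) for g in observed if (groups == g).sum() >= cfg.min_group_size
        ]
        dropped = sorted(set(observed.tolist()) - set(usable))
        if dropped:
            logger.warning("groups %s dropped from pairwise tests (n < %d)",
                           dropped, cfg.min_group_size)
        pair_rows = []
        group_means = {g: X[groups == g].mean(axis=0) for g in usable}
        for i, ga in enumerate(usable):
            for gb in usable[i + 1 :]:
                mask = np.isin(groups, [ga, gb])
                # keep Hotelling df2 ≥ 1 and the LOOCV within-class scatter
                # nonsingular for the smallest pairs
                n_pc_pair = min(cfg.n_pcs, int(mask.sum()) - 3)
                if n_pc_pair < cfg.n_pcs:
                    logger.warning(
                        "pair (%d, %d): retaining %d PCs (n=%d too small for %d)",
                        ga, gb, n_pc_pair, int(mask.sum()), cfg.n_pcs,
                    )
                scores, var_frac = pca_reduce(X[mask], n_pc_pair)
                y = groups[mask]
                h = hotelling_two_sample(scores[y == ga], scores[y == gb])
                mis = lda_loocv(scores, y)
                pair_rows.append(
                    {
                        "group_a": ga,
                        "group_b": gb,
                        "t2": h.t2,
                        "f_stat": h.f_stat,
                        "df1": h.df1,
                        "df2": h.df2,
                        "p_raw": h.p_raw,
                        "n_pcs": n_pc_pair,
                        "pct_var_pcs": 100.0 * float(var_frac[:n_pc_pair].sum()),
                        "misclassification_pct": 100.0 * mis,
                        "procrustes_distance": procrustes_distance(
                            group_means[ga], group_means[gb]
                        ),
                    }
                )
        pairwise = pd.DataFrame(pair_rows)
        pairwise["p_holm"] = holm_adjust(pairwise["p_raw"].to_numpy())

        stage = "distance correlation"
        mean_pct = {g: float(pct_dom[groups == g].mean()) for g in usable}
        k = len(usable)
        pd_mat = np.zeros((k, k))
        gd_mat = np.zeros((k, k))
        for i, ga in enumerate(usable):
            for j, gb in enumerate(usable):
                if i != j:
                    pd_mat[i, j] = procrustes_distance(group_means[ga], group_means[gb])
                    gd_mat[i, j] = abs(mean_pct[ga] - mean_pct[gb])
        mantel = mantel_test(pd_mat, gd_mat, n_perm=cfg.n_perm, seed=cfg.seed + 1)
        iu = np.triu_indices(k, 1)
        near = gd_mat[iu] < cfg.genomic_distance_subset_pct
        mantel_subset = _subset_pair_correlation(
            pd_mat[iu][near], gd_mat[iu][near], cfg.n_perm, cfg.seed + 2
        )

        stage = "direction analysis"
        ref_vec = dom_mean - mus_mean
        angle_dim = cfg.angle_dim if cfg.angle_dim is not None else shape_space_dim(scheme)
        dir_rows = []
        for i, ga in enumerate(usable):
            for gb in usable[i + 1 :]:
                lo, hi = (ga, gb) if mean_pct[ga] <= mean_pct[gb] else (gb, ga)
                vec = group_means[hi] - group_means[lo]
                ang = angle_test(vec, ref_vec, dim=angle_dim)
                dir_rows.append(
                    {
                        "group_low": lo,
                        "group_high": hi,
                        "angle_deg": ang.angle_deg,
                        "dim": ang.dim,
                        "p_raw": ang.p_raw,
                    }
                )
        direction = pd.DataFrame(dir_rows)
        direction["p_holm"] = holm_adjust(direction["p_raw"].to_numpy())
        direction["consistent"] = direction["p_holm"] < 0.05

        pd_df = pd.DataFrame(pd_mat, index=usable, columns=usable)
        gd_df = pd.DataFrame(gd_mat, index=usable, columns=usable)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage: {stage}") from exc

    return AnalysisReport(
        group_table=group_table,
        step_statistics=steps,
        size_results=size_results,
        allometry_pct=allo_pct,
        sex_pct=sex_pct,
        age_pct=age_pct,
        extremes_summary=extremes_summary,
        extremes_comparison=extremes_comparison,
        gradient_regression=reg,
        gradient_scores=gradient_scores,
        bgpca_group_scores=bgpca_groups,
        bgpca_individual_scores=bgpca_indiv,
        group_variance=group_variance,
        pairwise_table=pairwise,
        direction_table=direction,
        distance_correlation=mantel,
        distance_correlation_subset=mantel_subset,
        procrustes_distance_matrix=pd_df,
        genomic_distance_matrix=gd_df,
        aligned=corrected,
        grouping=grouping,
        config=cfg,
    )
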