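"""Serialization of analysis results: tidy result tables and figure-data CSVs.

Everything here is a pure function of an :class:`AnalysisReport`; identical
reports produce byte-identical files. No plotting dependency is required —
the figure exports are the data layers (scores, distances, variances,
ordinations), one CSV per figure analog.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .pipeline import AnalysisReport

__all__ = ["write_report_tables", "export_figure_data", "report_summary_dict"]


def report_summary_dict(report: AnalysisReport) -> dict:
    """Machine-readable scalar summary of a pipeline run."""
    hot = report.extremes_comparison["hotelling"]
    return {
        "n_specimens": int(report.aligned.n_specimens),
        "n_groups": int(report.group_table.shape[0]),
        "n_pairwise_comparisons": int(report.pairwise_table.shape[0]),
        "allometry_pct": report.allometry_pct,
        "sex_pct": report.sex_pct,
        "age_pct": report.age_pct,
        "step_statistics": report.step_statistics,
        "extremes": {
            "t2": hot.t2,
            "f_stat": hot.f_stat,
            "df1": hot.df1,
            "df2": hot.df2,
            "p_raw": hot.p_raw,
            "procrustes_distance": report.extremes_comparison["procrustes_distance"],
            "misclassification_fraction": report.extremes_comparison[
                "misclassification_fraction"
            ],
        },
        "gradient": {
            "pct_var_explained": report.gradient_regression.pct_var_explained,
            "p_perm": report.gradient_regression.p_perm,
            "n_perm": report.gradient_regression.n_perm,
        },
        "mantel": {
            "r": report.distance_correlation.r,
            "p_perm": report.distance_correlation.p_perm,
        },
        "mantel_subset": {
            "r": report.distance_correlation_subset.r,
            "p_perm": report.distance_correlation_subset.p_perm,
        },
        "n_direction_consistent": int(report.direction_table["consistent"].sum()),
        "size_regression": {
            "r": report.size_results["cs_regression_r"],
            "p": report.size_results["cs_regression_p"],
        },
        "seed": report.config.seed,
        "n_perm": report.config.n_perm,
        "n_pcs": report.config.n_pcs,
    }


def write_report_tables(report: AnalysisReport, outdir: str | Path) -> list[Path]:
    """Write all result tables of a run as tidy CSVs plus a JSON summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def emit(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, index=False)
        written.append(path)

    emit(report.group_table, "group_table.csv")
    emit(report.size_results["pairwise_rank_tests"], "size_pairwise_tests.csv")
    emit(report.pairwise_table, "pairwise_comparisons.csv")
    emit(report.direction_table, "direction_tests.csv")
    emit(report.group_variance, "group_variance_fa.csv")
    emit(report.extremes_summary, "pooled_extremes.csv")
    mat_path = outdir / "procrustes_distance_matrix.csv"
    report.procrustes_distance_matrix.to_csv(mat_path)
    written.append(mat_path)
    gmat_path = outdir / "genomic_distance_matrix.csv"
    report.genomic_distance_matrix.to_csv(gmat_path)
    written.append(gmat_path)

    summary_path = outdir / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(report_summary_dict(report), fh, indent=2, sort_keys=True)
    written.append(summary_path)
    return written


def export_figure_data(report: AnalysisReport, outdir: str | Path) -> dict[str, Path]:
    """Export the four figure-analog data layers as tidy CSVs.

    Returns a mapping of export name to path:

    * ``gradient_scores`` — one row per specimen: admixture %, group and the
      projection of the specimen's shape onto the regression vector.
    * ``distance_scatter`` — one row per group pair: Procrustes vs genomic
      distance, a flag for near pairs (genomic distance below the configured
      subset cutoff) and a marker for pairs whose shape-change direction is
      not consistent with the mus→dom transition.
    * ``group_variance_fa`` — one row per group: phenotypic variance (and its
      square root) and mean fluctuating asymmetry.
    * ``bgpca_ordination`` — group mean scores followed by individual
      projections on the between-group PC axes (G + N rows).
    """
    for attr in ("gradient_scores", "pairwise_table", "direction_table",
                 "group_variance", "bgpca_group_scores"):
        value = getattr(report, attr, None)
        if value is None or (hasattr(value, "empty") and value.empty):
            raise ValueError(f"incomplete report: missing stage output {attr!r}")

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["gradient_scores"] = outdir / "fig_gradient_scores.csv"
    report.gradient_scores.to_csv(paths["gradient_scores"], index=False)

    scatter = report.pairwise_table[
        ["group_a", "group_b", "procrustes_distance"]
    ].copy()
    key = list(zip(scatter["group_a"], scatter["group_b"]))
    gd = {
        (min(a, b), max(a, b)): report.genomic_distance_matrix.loc[a, b]
        for a, b in key
    }
    scatter["genomic_distance"] = [gd[(min(a, b), max(a, b))] for a, b in key]
    cutoff = report.config.genomic_distance_subset_pct
    scatter["near_pair"] = scatter["genomic_distance"] < cutoff
    consistent = {
        (min(r.group_low, r.group_high), max(r.group_low, r.group_high)): bool(
            r.consistent
        )
        for r in report.direction_table.itertuples()
    }
    scatter["direction_consistent"] = [
        consistent[(min(a, b), max(a, b))] for a, b in key
    ]
    paths["distance_scatter"] = outdir / "fig_distance_scatter.csv"
    scatter.to_csv(paths["distance_scatter"], index=False)

    paths["group_variance_fa"] = outdir / "fig_group_variance_fa.csv"
    report.group_variance.to_csv(paths["group_variance_fa"], index=False)

    groups = report.bgpca_group_scores.copy()
    groups.insert(0, "level", "group_mean")
    groups.insert(1, "specimen_id", pd.NA)
    indiv = report.bgpca_individual_scores.copy()
    indiv.insert(0, "level", "individual")
    ordination = pd.concat([groups, indiv], ignore_index=True)
    cols = ["level", "specimen_id", "group"] + [
        c for c in ordination.columns if c.startswith("bgPC")
    ]
    paths["bgpca_ordination"] = outdir / "fig_bgpca_ordination.csv"
    ordination[cols].to_csv(paths["bgpca_ordination"], index=False)
    return paths
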