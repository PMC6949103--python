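"""Run every analysis stage over one or more cohort directories.

Each cohort directory follows the TSV contract written by
:func:`clockscape.simulate.write_cohort` (any subset of assays; stages
whose inputs are missing are skipped with a logged notice).  FDR
correction is applied within each cohort and analysis family, never
pooled across cancer types.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .association import (
    default_signatures,
    drug_correlation,
    drug_to_frame,
    immune_correlation,
    score_immune_signatures,
)
from .clinical import (
    curves_to_frame,
    differential_expression,
    survival_by_median_split,
    survival_to_frame,
)
from .core import AnalysisConfig, OmicsMatrix, records_to_frame, write_matrix
from .epigenomics import (
    cnv_to_frame,
    differential_methylation,
    methylation_expression_effect,
    summarize_cnv,
)
from .pathway import (
    calls_to_frame,
    call_pathway_effects,
    compute_pas,
    default_pathways,
    normalize_rppa,
    pas_diff_wide,
)
from .rhythm import fits_to_frame, rhythm_panel
from .simulate import CohortBundle, read_cohort

logger = logging.getLogger("clockscape")


class StageError(RuntimeError):
    """A stage failed on malformed input; carries the cohort and stage name."""

    def __init__(self, cohort: str, stage: str, cause: Exception):
        super().__init__(f"cohort {cohort!r}, stage {stage!r}: {cause}")
        self.cohort = cohort
        self.stage = stage


def _long_rows(df: pd.DataFrame, cohort: str, stage: str) -> pd.DataFrame:
    out = df.copy()
    out.insert(0, "stage", stage)
    out.insert(0, "cohort", cohort)
    return out


def run_cohort(
    bundle: CohortBundle, config: AnalysisConfig, cohort: str, out_dir: Path
) -> list[pd.DataFrame]:
    """Run all applicable stages for one cohort; returns long-format
    result frames for the combined report."""
    out_dir.mkdir(parents=True, exist_ok=True)
    combined: list[pd.DataFrame] = []

    def stage(name: str, condition: bool, fn) -> None:
        if not condition:
            logger.info("[%s] stage %s skipped: required assay missing", cohort, name)
            return
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - rewrapped with context
            raise StageError(cohort, name, exc) from exc

    # -- epigenomics -----------------------------------------------------
    def _meth_diff() -> None:
        recs = differential_methylation(
            bundle.methylation, bundle.tumor_ids, bundle.normal_ids, config
        )
        df = records_to_frame(recs)
        df.to_csv(out_dir / "methylation_diff.tsv", sep="\t", index=False, na_rep="NA")
        combined.append(_long_rows(df, cohort, "differential_methylation"))
        logger.info("[%s] differential_methylation: %d records", cohort, len(df))

    stage(
        "differential_methylation",
        bundle.methylation is not None and bool(bundle.normal_ids),
        _meth_diff,
    )

    def _meth_expr() -> None:
        recs = methylation_expression_effect(
            bundle.methylation, bundle.expression, bundle.tumor_ids, config
        )
        df = records_to_frame(recs)
        df.to_csv(out_dir / "meth_expr_effect.tsv", sep="\t", index=False, na_rep="NA")
        combined.append(_long_rows(df, cohort, "methylation_expression"))
        logger.info("[%s] methylation_expression: %d records", cohort, len(df))

    stage(
        "methylation_expression",
        bundle.methylation is not None and bundle.expression is not None,
        _meth_expr,
    )

    def _cnv() -> None:
        summaries = summarize_cnv(bundle.cnv, config)
        df = cnv_to_frame(summaries)
        df.to_csv(out_dir / "cnv_summary.tsv", sep="\t", index=False, na_rep="NA")
        logger.info(
            "[%s] cnv_summary: %d genes, %d displayed",
            cohort, len(df), int(df["displayed"].sum()),
        )

    stage("cnv_summary", bundle.cnv is not None, _cnv)

    # -- pathway activity -------------------------------------------------
    def _pathway() -> None:
        normed = normalize_rppa(bundle.rppa)
        pas = compute_pas(normed, default_pathways())
        write_matrix(
            OmicsMatrix(pas.values, kind="rppa", units="PAS"),
            out_dir / "pas_matrix.tsv",
        )
        calls = call_pathway_effects(bundle.expression, pas, config)
        df = calls_to_frame(calls)
        df.to_csv(out_dir / "pathway_calls.tsv", sep="\t", index=False, na_rep="NA")
        pas_diff_wide(calls, config).to_csv(out_dir / "pas_diff_wide.tsv", sep="\t", na_rep="NA")
        combined.append(
            _long_rows(
                df.rename(columns={"pathway": "target", "pas_diff": "effect"})[
                    ["gene", "target", "effect", "p_value", "fdr", "direction"]
                ],
                cohort,
                "pathway_activity",
            )
        )
        logger.info(
            "[%s] pathway_activity: %d calls, %d non-null directions",
            cohort, len(df), int((df["direction"] != "none").sum()),
        )

    stage(
        "pathway_activity",
        bundle.rppa is not None and bundle.expression is not None,
        _pathway,
    )

    # -- clinical ----------------------------------------------------------
    def _survival() -> None:
        tumor_expr = bundle.expression.subset_samples(bundle.tumor_ids)
        results = survival_by_median_split(tumor_expr, bundle.survival, config)
        survival_to_frame(results).to_csv(
            out_dir / "survival_results.tsv", sep="\t", index=False, na_rep="NA"
        )
        curves_to_frame(results).to_csv(
            out_dir / "km_curves.tsv", sep="\t", index=False, na_rep="NA"
        )
        df = survival_to_frame(results)
        combined.append(
            _long_rows(
                df.rename(columns={"logrank_chi2": "statistic"}).assign(
                    target="median_split_survival"
                )[["gene", "target", "statistic", "p_value", "direction"]],
                cohort,
                "survival",
            )
        )
        logger.info("[%s] survival: %d genes tested", cohort, len(df))

    stage(
        "survival",
        bundle.expression is not None and bundle.survival is not None,
        _survival,
    )

    def _de() -> None:
        recs = differential_expression(
            bundle.expression, bundle.tumor_ids, bundle.normal_ids, config
        )
        df = records_to_frame(recs)
        df.to_csv(out_dir / "diff_expr.tsv", sep="\t", index=False, na_rep="NA")
        combined.append(_long_rows(df, cohort, "differential_expression"))
        logger.info("[%s] differential_expression: %d records", cohort, len(df))

    stage(
        "differential_expression",
        bundle.expression is not None and len(bundle.normal_ids) >= 3,
        _de,
    )

    # -- association -------------------------------------------------------
    def _drug() -> None:
        assocs = drug_correlation(bundle.cell_line_expression, bundle.auc, config)
        df = drug_to_frame(assocs)
        df.to_csv(out_dir / "drug_associations.tsv", sep="\t", index=False, na_rep="NA")
        combined.append(
            _long_rows(
                df.rename(columns={"drug": "target", "pearson_r": "effect", "z_score": "statistic"})[
                    ["gene", "target", "statistic", "effect", "p_value", "fdr", "n", "label"]
                ],
                cohort,
                "drug_sensitivity",
            )
        )
        logger.info("[%s] drug_sensitivity: %d pairs", cohort, len(df))

    stage(
        "drug_sensitivity",
        bundle.cell_line_expression is not None and bundle.auc is not None,
        _drug,
    )

    def _immune() -> None:
        tumor_expr = bundle.expression.subset_samples(bundle.tumor_ids)
        scores = bundle.immune_scores
        if scores is None:
            scores = score_immune_signatures(tumor_expr, default_signatures())
        write_matrix(scores, out_dir / "immune_scores.tsv")
        recs = immune_correlation(tumor_expr, scores, config)
        df = records_to_frame(recs)
        df.to_csv(out_dir / "immune_correlations.tsv", sep="\t", index=False, na_rep="NA")
        combined.append(_long_rows(df, cohort, "immune_infiltration"))
        logger.info("[%s] immune_infiltration: %d records", cohort, len(df))

    def _immune_inputs_ok() -> bool:
        if bundle.expression is None:
            return False
        if bundle.immune_scores is not None:
            return True
        observed = set(bundle.expression.feature_ids)
        return any(
            sum(m in observed for m in sig.marker_genes) >= 2
            for sig in default_signatures()
        )

    stage("immune_infiltration", _immune_inputs_ok(), _immune)

    # -- rhythm ------------------------------------------------------------
    def _rhythm() -> None:
        fits = rhythm_panel(bundle.timeseries, bundle.times_hours, config)
        df = fits_to_frame(fits)
        df.to_csv(out_dir / "rhythm_fits.tsv", sep="\t", index=False, na_rep="NA")
        combined.append(
            _long_rows(
                df.rename(columns={"amplitude": "effect"}).assign(target="cosinor_24h")[
                    ["gene", "target", "effect", "acrophase_hours", "p_value", "fdr", "n"]
                ],
                cohort,
                "rhythm",
            )
        )
        logger.info("[%s] rhythm: %d genes fitted", cohort, len(df))

    stage(
        "rhythm",
        bundle.timeseries is not None and bundle.times_hours is not None,
        _rhythm,
    )

    return combined


def config_hash(config: AnalysisConfig) -> str:
    payload = yaml.safe_dump(
        {**dataclasses.asdict(config), "gene_panel": list(config.gene_panel)},
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()


def run_pipeline(
    config: AnalysisConfig,
    cohort_dirs: Sequence[str | Path],
    out_dir: str | Path,
) -> Path:
    """Run every stage for every cohort directory and write the combined
    report, stage TSVs, and a manifest sufficient to re-run bit-identically."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    combined: list[pd.DataFrame] = []
    cohorts = []
    for d in cohort_dirs:
        d = Path(d)
        cohort = d.name
        cohorts.append(cohort)
        bundle = read_cohort(d)
        combined.extend(run_cohort(bundle, config, cohort, out / cohort))

    if combined:
        all_cols = ["cohort", "stage", "gene", "target", "statistic", "effect",
                    "p_value", "fdr", "n", "direction", "label", "acrophase_hours"]
        merged = pd.concat(combined, ignore_index=True)
        cols = [c for c in all_cols if c in merged.columns]
        merged = merged[cols + [c for c in merged.columns if c not in cols]]
        merged = merged.sort_values(["cohort", "stage", "gene", "target"], kind="stable")
    else:
        merged = pd.DataFrame(columns=["cohort", "stage", "gene", "target"])
    merged.to_csv(out / "results.tsv", sep="\t", index=False, na_rep="NA")

    manifest = {
        "config": {**dataclasses.asdict(config), "gene_panel": list(config.gene_panel)},
        "config_sha256": config_hash(config),
        "seed": config.seed,
        "cohorts": sorted(cohorts),
        "versions": {
            "clockscape": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
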