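"""RPPA pathway activity scoring and per-gene activation/inhibition calls.

The pathway activity score (PAS) of a sample is the sum of the
SD-normalized abundances of the pathway's positive-regulator proteins
minus the sum over its negative regulators.  A gene is called an
activator (inhibitor) of a pathway when samples with above-median
expression of the gene show significantly higher (lower) PAS than
below-median samples.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    AnalysisConfig,
    OmicsMatrix,
    PathwayDefinition,
    benjamini_hochberg,
    read_pathways,
)

logger = logging.getLogger("clockscape")


def default_pathways() -> list[PathwayDefinition]:
    """The ten hallmark pathways (TSC/mTOR, RTK, RAS/MAPK, PI3K/AKT,
    Hormone ER, Hormone AR, EMT, DNA Damage Response, Cell Cycle,
    Apoptosis) with signed RPPA memberships.

    Memberships ship as an editable data file modeled on published
    RPPA-based pathway annotations; edit ``data/pathways.tsv`` or pass a
    custom file to use a different annotation.
    """
    ref = importlib.resources.files("clockscape") / "data" / "pathways.tsv"
    with importlib.resources.as_file(ref) as path:
        return read_pathways(path)


@dataclass
class PasMatrix:
    """Pathways x samples activity-score matrix."""

    values: pd.DataFrame

    @property
    def pathway_names(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class PathwayCall:
    """One gene x pathway activation/inhibition call.

    ``pas_diff`` is mean PAS of the high-expression group minus the
    low-expression group; ``pct_influenced`` is the absolute rank-biserial
    effect size of the group comparison clipped to [0, 1] — a stand-in for
    a per-patient influence fraction, not a patient percentage.
    """

    gene: str
    pathway: str
    direction: str  # "activate" | "inhibit" | "none"
    pas_diff: float
    p_value: float
    fdr: float
    pct_influenced: float
    n_high: int
    n_low: int

    def as_dict(self) -> dict:
        return asdict(self)


def normalize_rppa(rppa: OmicsMatrix) -> OmicsMatrix:
    """Center each protein and scale to unit sample standard deviation.

    Proteins with zero variance (or fewer than two non-missing values)
    carry no relative signal and are dropped with a warning.
    """
    if rppa.kind != "rppa":
        raise ValueError(f"expected an rppa matrix, got kind={rppa.kind!r}")
    vals = rppa.values
    mean = vals.mean(axis=1, skipna=True)
    sd = vals.std(axis=1, ddof=1, skipna=True)
    degenerate = sd.isna() | (sd == 0.0)
    if degenerate.any():
        for protein in vals.index[degenerate]:
            logger.warning("dropping zero-variance RPPA protein %s", protein)
    keep = vals.loc[~degenerate]
    normed = keep.sub(mean[~degenerate], axis=0).div(sd[~degenerate], axis=0)
    return OmicsMatrix(normed, kind="rppa", units="sd units")


def compute_pas(rppa_norm: OmicsMatrix, pathways: list[PathwayDefinition]) -> PasMatrix:
    """PAS(pathway, sample) = sum of positive-regulator levels minus sum of
    negative-regulator levels over the pathway members observed in the
    matrix; missing member values are omitted from the sum."""
    vals = rppa_norm.values
    rows = {}
    for pw in pathways:
        pos = [p for p in pw.positive if p in vals.index]
        neg = [p for p in pw.negative if p in vals.index]
        if not pos and not neg:
            logger.warning("pathway %s has no observed member proteins", pw.pathway_name)
            rows[pw.pathway_name] = pd.Series(np.nan, index=vals.columns)
            continue
        score = vals.loc[pos].sum(axis=0, min_count=1).fillna(0.0) - vals.loc[
            neg
        ].sum(axis=0, min_count=1).fillna(0.0)
        # samples where every member is missing stay missing
        observed = vals.loc[pos + neg].notna().any(axis=0)
        rows[pw.pathway_name] = score.where(observed)
    return PasMatrix(pd.DataFrame(rows).T[vals.columns])


def median_split(values: pd.Series) -> tuple[pd.Index, pd.Index]:
    """Split samples at the median; ties go to the low group."""
    med = values.median()
    high = values.index[values > med]
    low = values.index[values <= med]
    return high, low


def call_pathway_effects(
    expression: OmicsMatrix,
    pas: PasMatrix,
    config: AnalysisConfig,
    test: str = "mannwhitney",
) -> list[PathwayCall]:
    """Call activation/inhibition of each pathway by each panel gene.

    Samples are split at the gene's median expression (ties to the low
    group); the two groups' PAS are compared with a two-sided
    Mann-Whitney U test (``test="welch"`` switches to Welch's t);
    Benjamini-Hochberg correction runs across all gene x pathway tests.
    ``direction`` is "activate" when fdr <= threshold and the high group
    has the larger mean PAS, "inhibit" when smaller, "none" otherwise.
    """
    shared = [s for s in expression.sample_ids if s in pas.values.columns]
    if len(shared) < 8:
        raise ValueError(
            f"need >= 8 samples shared between expression and PAS, got {len(shared)}"
        )
    expr = expression.values[shared]
    pasv = pas.values[shared]

    raw: list[dict] = []
    for gene in config.gene_panel:
        if gene not in expr.index:
            logger.warning("panel gene %s absent from expression; skipped", gene)
            continue
        g = expr.loc[gene].dropna()
        high, low = median_split(g)
        for pathway in pasv.index:
            hi = pasv.loc[pathway, high].dropna().to_numpy()
            lo = pasv.loc[pathway, low].dropna().to_numpy()
            rec = {
                "gene": gene,
                "pathway": pathway,
                "n_high": hi.size,
                "n_low": lo.size,
            }
            if hi.size < 4 or lo.size < 4:
                rec.update(pas_diff=np.nan, p_value=np.nan, pct_influenced=np.nan)
            else:
                diff = float(hi.mean() - lo.mean())
                if test == "welch":
                    p = float(stats.ttest_ind(hi, lo, equal_var=False).pvalue)
                    u = stats.mannwhitneyu(hi, lo, alternative="two-sided").statistic
                else:
                    res = stats.mannwhitneyu(hi, lo, alternative="two-sided")
                    u, p = float(res.statistic), float(res.pvalue)
                # rank-biserial r = 2U/(n1*n2) - 1
                rb = 2.0 * u / (hi.size * lo.size) - 1.0
                rec.update(
                    pas_diff=diff,
                    p_value=p,
                    pct_influenced=float(np.clip(abs(rb), 0.0, 1.0)),
                )
            raw.append(rec)

    fdrs = benjamini_hochberg([r["p_value"] for r in raw])
    calls = []
    for rec, fdr in zip(raw, fdrs):
        direction = "none"
        if np.isfinite(fdr) and fdr <= config.fdr_threshold and rec["pas_diff"] != 0:
            direction = "activate" if rec["pas_diff"] > 0 else "inhibit"
        calls.append(
            PathwayCall(
                gene=rec["gene"],
                pathway=rec["pathway"],
                direction=direction,
                pas_diff=rec["pas_diff"],
                p_value=rec["p_value"],
                fdr=float(fdr),
                pct_influenced=rec["pct_influenced"],
                n_high=rec["n_high"],
                n_low=rec["n_low"],
            )
        )
    return calls


def calls_to_frame(calls: list[PathwayCall]) -> pd.DataFrame:
    cols = [
        "gene",
        "pathway",
        "direction",
        "pas_diff",
        "p_value",
        "fdr",
        "pct_influenced",
        "n_high",
        "n_low",
    ]
    if not calls:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([c.as_dict() for c in calls])[cols]


def pas_diff_wide(calls: list[PathwayCall], config: AnalysisConfig) -> pd.DataFrame:
    """Heatmap-ready genes x pathways table of pas_diff, with non-significant
    cells masked to NaN."""
    df = calls_to_frame(calls)
    if df.empty:
        return df
    masked = df.assign(
        pas_diff=df["pas_diff"].where(df["fdr"] <= config.fdr_threshold)
    )
    return masked.pivot(index="gene", columns="pathway", values="pas_diff")
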