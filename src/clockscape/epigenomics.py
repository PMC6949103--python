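"""Differential DNA methylation, methylation-expression coupling, and
copy-number frequency summaries.

Methylation enters as gene-level beta values in [0, 1] (probe-to-gene
aggregation, e.g. promoter means, is an upstream preprocessing contract).
CNV enters as per-gene per-sample integer calls: -1/+1 heterozygous
deletion/amplification, -2/+2 homozygous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    AnalysisConfig,
    AssociationRecord,
    OmicsMatrix,
    benjamini_hochberg,
)

logger = logging.getLogger("clockscape")


def differential_methylation(
    meth: OmicsMatrix,
    tumor_ids: Sequence[str],
    normal_ids: Sequence[str],
    config: AnalysisConfig,
) -> list[AssociationRecord]:
    """Tumor-vs-normal methylation difference per panel gene.

    Effect = mean beta(tumor) - mean beta(normal); p from a two-sided
    Wilcoxon rank-sum test (beta values are bounded and non-normal);
    Benjamini-Hochberg FDR across the panel.  A gene is significantly
    differentially methylated when fdr < the configured threshold.
    """
    if meth.kind != "methylation":
        raise ValueError(f"expected methylation matrix, got {meth.kind!r}")
    tumor = [s for s in tumor_ids if s in meth.values.columns]
    normal = [s for s in normal_ids if s in meth.values.columns]

    raw = []
    for gene in config.gene_panel:
        if gene not in meth.values.index:
            logger.warning("gene %s absent from methylation matrix", gene)
            raw.append((gene, np.nan, np.nan, np.nan, 0))
            continue
        t = meth.values.loc[gene, tumor].dropna().to_numpy()
        n = meth.values.loc[gene, normal].dropna().to_numpy()
        if t.size < 5 or n.size < 5:
            logger.warning(
                "gene %s: fewer than 5 samples per group (%d tumor, %d normal)",
                gene, t.size, n.size,
            )
            raw.append((gene, np.nan, np.nan, np.nan, t.size + n.size))
            continue
        stat, p = stats.ranksums(t, n)
        raw.append((gene, float(stat), float(t.mean() - n.mean()), float(p), t.size + n.size))

    fdrs = benjamini_hochberg([r[3] for r in raw])
    return [
        AssociationRecord(
            gene=g, target="tumor_vs_normal", statistic=s, effect=e,
            p_value=p, fdr=float(q), n=int(n),
        )
        for (g, s, e, p, n), q in zip(raw, fdrs)
    ]


def methylation_expression_effect(
    meth: OmicsMatrix,
    expr: OmicsMatrix,
    tumor_ids: Sequence[str],
    config: AnalysisConfig,
) -> list[AssociationRecord]:
    """Spearman correlation of beta value with expression across tumors.

    A negative rho indicates methylation-driven silencing; Spearman is
    used because the silencing claim is monotone, not linear.
    """
    shared = [
        s for s in tumor_ids
        if s in meth.values.columns and s in expr.values.columns
    ]
    if len(shared) < 10:
        raise ValueError(f"need >= 10 shared tumor samples, got {len(shared)}")

    raw = []
    for gene in config.gene_panel:
        if gene not in meth.values.index or gene not in expr.values.index:
            logger.warning("gene %s missing from methylation or expression", gene)
            raw.append((gene, np.nan, np.nan, 0))
            continue
        pair = pd.DataFrame(
            {"beta": meth.values.loc[gene, shared], "expr": expr.values.loc[gene, shared]}
        ).dropna()
        if len(pair) < 10 or pair["beta"].nunique() < 2 or pair["expr"].nunique() < 2:
            logger.warning("gene %s: degenerate or undersized methylation/expression pair", gene)
            raw.append((gene, np.nan, np.nan, len(pair)))
            continue
        rho, p = stats.spearmanr(pair["beta"], pair["expr"])
        raw.append((gene, float(rho), float(p), len(pair)))

    fdrs = benjamini_hochberg([r[2] for r in raw])
    return [
        AssociationRecord(
            gene=g, target="methylation_vs_expression", statistic=rho, effect=rho,
            p_value=p, fdr=float(q), n=int(n),
        )
        for (g, rho, p, n), q in zip(raw, fdrs)
    ]


@dataclass
class CnvSummary:
    """Per-gene copy-number alteration frequencies.

    ``displayed`` is True when any category frequency exceeds the
    configured display fraction (strictly greater, matching a > 5%
    default display rule).
    """

    gene: str
    het_amp_frac: float
    het_del_frac: float
    hom_amp_frac: float
    hom_del_frac: float
    displayed: bool

    def as_dict(self) -> dict:
        return asdict(self)


def summarize_cnv(cnv: OmicsMatrix, config: AnalysisConfig) -> list[CnvSummary]:
    """Fraction of samples per gene carrying heterozygous (+/-1) or
    homozygous (+/-2) copy-number calls, over non-missing samples."""
    if cnv.kind != "cnv":
        raise ValueError(f"expected cnv matrix, got {cnv.kind!r}")
    out = []
    for gene in cnv.values.index:
        row = cnv.values.loc[gene].dropna()
        n = len(row)
        if n == 0:
            out.append(CnvSummary(gene, np.nan, np.nan, np.nan, np.nan, False))
            continue
        fracs = {
            "het_amp_frac": float((row == 1).sum() / n),
            "het_del_frac": float((row == -1).sum() / n),
            "hom_amp_frac": float((row == 2).sum() / n),
            "hom_del_frac": float((row == -2).sum() / n),
        }
        displayed = max(fracs.values()) > config.cnv_display_fraction
        out.append(CnvSummary(gene=gene, displayed=displayed, **fracs))
    return out


def cnv_to_frame(summaries: list[CnvSummary]) -> pd.DataFrame:
    cols = ["gene", "het_amp_frac", "het_del_frac", "hom_amp_frac", "hom_del_frac", "displayed"]
    if not summaries:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([s.as_dict() for s in summaries])[cols]
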