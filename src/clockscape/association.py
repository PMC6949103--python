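"""Drug-sensitivity and immune-infiltration associations of the gene panel.

Drug sensitivity: Pearson correlation of a gene's transcript level with
each drug's dose-response AUC across cell lines, variance-stabilized with
Fisher's Z (z = atanh(r)); since higher AUC means more resistant, a
significant positive correlation is labelled "resistance" and a negative
one "sensitivity".

Immune infiltration: a marker-gene signature score per immune cell type
(mean of per-gene z-scored log2(expression + 1) over the cell type's
markers), then Spearman correlation of each panel gene with each score.
The signature is a deliberately simple stand-in for full deconvolution;
externally computed infiltration matrices can be supplied through the
same matrix contract instead.
"""

from __future__ import annotations

import importlib.resources
import logging
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    AnalysisConfig,
    AssociationRecord,
    OmicsMatrix,
    benjamini_hochberg,
    fisher_z,
)

logger = logging.getLogger("clockscape")

IMMUNE_CELL_TYPES = (
    "B cells",
    "CD4+ T cells",
    "CD8+ T cells",
    "Neutrophils",
    "Macrophages",
    "Dendritic cells",
)


@dataclass(frozen=True)
class ImmuneSignature:
    """Marker-gene list defining one immune cell type's signature."""

    cell_type: str
    marker_genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.marker_genes:
            raise ValueError(f"signature {self.cell_type!r} has no marker genes")


def default_signatures() -> list[ImmuneSignature]:
    """Six-cell-type marker lists (B, CD4+ T, CD8+ T, neutrophil,
    macrophage, dendritic) shipped as an editable data file."""
    ref = importlib.resources.files("clockscape") / "data" / "immune_markers.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    return [
        ImmuneSignature(str(ct), tuple(grp["gene"].astype(str)))
        for ct, grp in df.groupby("cell_type", sort=False)
    ]


@dataclass
class DrugAssociation:
    gene: str
    drug: str
    pearson_r: float
    fisher_z: float
    z_score: float  # fisher_z * sqrt(n - 3)
    p_value: float
    fdr: float
    n: int
    label: str  # "resistance" | "sensitivity" | "none"

    def as_dict(self) -> dict:
        return asdict(self)


def drug_correlation(
    expr: OmicsMatrix,
    auc: OmicsMatrix,
    config: AnalysisConfig,
    p_method: str = "fisher",
) -> list[DrugAssociation]:
    """Correlate panel-gene expression with drug AUC across cell lines.

    Expression is log2(x + 1)-transformed before correlating, the
    standard scale for transcript-drug response association.
    ``p_method="fisher"`` (default) takes the two-sided p from the normal
    approximation z = atanh(r) * sqrt(n - 3); ``"exact"`` uses the exact
    t-distribution p of the Pearson test.  BH correction runs within each
    panel gene's drug family; labels require fdr <= the configured
    threshold.  A perfect |r| = 1 is reported as a signed-infinity Fisher
    Z with p = 0 and a warning.
    """
    shared = [s for s in expr.sample_ids if s in auc.values.columns]
    raw: list[dict] = []
    for gene in config.gene_panel:
        if gene not in expr.values.index:
            logger.warning("panel gene %s absent from cell-line expression", gene)
            continue
        g = np.log2(expr.values.loc[gene, shared] + 1.0)
        for drug in auc.feature_ids:
            pair = pd.DataFrame({"x": g, "y": auc.values.loc[drug, shared]}).dropna()
            n = len(pair)
            rec = {"gene": gene, "drug": drug, "n": n}
            if n < 10:
                logger.warning("pair (%s, %s): only %d shared cell lines", gene, drug, n)
                rec.update(pearson_r=np.nan, fisher_z=np.nan, z_score=np.nan, p_value=np.nan)
            else:
                r = float(stats.pearsonr(pair["x"], pair["y"]).statistic)
                # rounding keeps an exactly affine pair just below |r| = 1
                if abs(r) >= 1.0 - 1e-12:
                    r = math.copysign(1.0, r)
                z = fisher_z(r)
                if math.isinf(z):
                    logger.warning("pair (%s, %s): |r| = 1 exactly", gene, drug)
                    rec.update(pearson_r=r, fisher_z=z, z_score=z, p_value=0.0)
                else:
                    zs = z * math.sqrt(n - 3)
                    if p_method == "exact":
                        p = float(stats.pearsonr(pair["x"], pair["y"]).pvalue)
                    else:
                        p = float(2.0 * stats.norm.sf(abs(zs)))
                    rec.update(pearson_r=r, fisher_z=z, z_score=zs, p_value=p)
            raw.append(rec)

    # BH within each gene's drug family (one screen per panel gene)
    fdrs = np.full(len(raw), np.nan)
    genes_in = np.array([r["gene"] for r in raw])
    pvals = np.array([r["p_value"] for r in raw], dtype=float)
    for gene in np.unique(genes_in):
        idx = np.flatnonzero(genes_in == gene)
        fdrs[idx] = benjamini_hochberg(pvals[idx])
    out = []
    for rec, q in zip(raw, fdrs):
        label = "none"
        if np.isfinite(rec["pearson_r"]) and np.isfinite(q) and q <= config.fdr_threshold:
            if rec["pearson_r"] > 0:
                label = "resistance"
            elif rec["pearson_r"] < 0:
                label = "sensitivity"
        out.append(DrugAssociation(fdr=float(q), label=label, **rec))
    return out


def drug_to_frame(assocs: list[DrugAssociation]) -> pd.DataFrame:
    cols = ["gene", "drug", "pearson_r", "fisher_z", "z_score", "p_value", "fdr", "n", "label"]
    if not assocs:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([a.as_dict() for a in assocs])[cols]


def score_immune_signatures(
    expr: OmicsMatrix, signatures: list[ImmuneSignature] | None = None
) -> OmicsMatrix:
    """Marker-mean signature score per cell type per sample.

    Each observed marker gene is log2(x + 1)-transformed and z-scored
    across samples; the cell-type score is the mean over its observed
    markers.  Cell types with fewer than the minimum observed markers get
    a missing row with a warning.
    """
    if signatures is None:
        signatures = default_signatures()
    logx = np.log2(expr.values + 1.0)
    sd = logx.std(axis=1, ddof=1)
    z = logx.sub(logx.mean(axis=1), axis=0).div(sd.replace(0.0, np.nan), axis=0)

    rows = {}
    for sig in signatures:
        markers = [m for m in sig.marker_genes if m in z.index]
        if len(markers) < 1 or (len(sig.marker_genes) >= 2 and len(markers) < 2):
            logger.warning(
                "signature %s: %d of %d markers observed; emitting missing row",
                sig.cell_type, len(markers), len(sig.marker_genes),
            )
            rows[sig.cell_type] = pd.Series(np.nan, index=z.columns)
            continue
        rows[sig.cell_type] = z.loc[markers].mean(axis=0)
    scores = pd.DataFrame(rows).T[expr.sample_ids]
    return OmicsMatrix(scores, kind="expression", units="signature z")


def immune_correlation(
    expr: OmicsMatrix,
    immune_scores: OmicsMatrix,
    config: AnalysisConfig,
) -> list[AssociationRecord]:
    """Spearman correlation of each panel gene with each immune cell-type
    score across shared samples; BH FDR across all gene x cell-type pairs."""
    shared = [s for s in expr.sample_ids if s in immune_scores.values.columns]
    if len(shared) < 20:
        raise ValueError(f"need >= 20 shared samples, got {len(shared)}")

    raw = []
    for gene in config.gene_panel:
        if gene not in expr.values.index:
            logger.warning("panel gene %s absent from expression", gene)
            continue
        g = expr.values.loc[gene, shared]
        for cell_type in immune_scores.feature_ids:
            pair = pd.DataFrame(
                {"x": g, "y": immune_scores.values.loc[cell_type, shared]}
            ).dropna()
            if len(pair) < 3 or pair["y"].nunique() < 2 or pair["x"].nunique() < 2:
                logger.warning("pair (%s, %s): degenerate or undersized", gene, cell_type)
                raw.append((gene, cell_type, np.nan, np.nan, len(pair)))
                continue
            rho, p = stats.spearmanr(pair["x"], pair["y"])
            raw.append((gene, cell_type, float(rho), float(p), len(pair)))

    fdrs = benjamini_hochberg([r[3] for r in raw])
    return [
        AssociationRecord(
            gene=g, target=ct, statistic=rho, effect=rho,
            p_value=p, fdr=float(q), n=int(n),
        )
        for (g, ct, rho, p, n), q in zip(raw, fdrs)
    ]
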