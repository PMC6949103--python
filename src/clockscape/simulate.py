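"""Synthetic multi-omics cohort generator with planted, recoverable effects.

Every downstream stage of the pipeline has a parameter-recovery test
against cohorts produced here.  The generator emulates, at desk scale, a
TCGA-style tumor cohort with matched normals plus cell-line drug-response
and time-stamped normal-tissue expression:

* methylation beta values (logit-normal background; planted tumor shifts),
* expression driven down by methylation (Gaussian-copula coupling so a
  target Spearman correlation holds under the log-normal marginal),
* RPPA protein abundances whose pathway positive regulators shift with a
  driver gene's expression group,
* proportional-hazards exponential survival with uniform censoring,
* drug AUC columns correlated with a gene's cell-line expression,
* immune marker genes correlated with chosen driver genes so the derived
  signature scores carry a planted correlation, and
* 24 h sinusoidal rhythms plus Gaussian noise.

All randomness flows from one ``numpy`` Generator seeded by the config,
so the same seed yields a byte-identical serialized cohort.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .association import default_signatures, score_immune_signatures
from .core import (
    AnalysisConfig,
    OmicsMatrix,
    SurvivalTable,
    read_matrix,
    read_survival,
    write_matrix,
    write_survival,
)
from .pathway import default_pathways


def spearman_to_pearson_latent(rho_s: float) -> float:
    """Latent bivariate-normal correlation reproducing a target Spearman
    correlation under a Gaussian copula: r = 2 sin(pi rho_s / 6)."""
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


@dataclass
class PlantedTruth:
    """Ground-truth effects planted into a synthetic cohort.

    activating_pairs: (gene, pathway, effect_sd) — the pathway's positive
        regulators shift by effect_sd (raw SD units) in samples with
        above-median driver expression; negative effect_sd plants
        inhibition.
    silenced_genes: (gene, delta_beta, meth_expr_rho) — tumor betas shift
        up by delta_beta and tumor expression couples to methylation with
        the given (negative) Spearman target.
    prognostic_genes: (gene, hazard_ratio) — hazard multiplier for
        above-median expression.
    drug_pairs: (gene, drug, rho) — target Spearman between cell-line
        expression and that drug's AUC.
    rhythmic_genes: (gene, amplitude, acrophase_hours).
    immune_pairs: (gene, cell_type, rho) — target correlation between the
        gene and the cell type's signature score.
    """

    activating_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    silenced_genes: list[tuple[str, float, float]] = field(default_factory=list)
    prognostic_genes: list[tuple[str, float]] = field(default_factory=list)
    drug_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    rhythmic_genes: list[tuple[str, float, float]] = field(default_factory=list)
    immune_pairs: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for g, d, rho in self.drug_pairs:
            if not -1.0 < rho < 1.0:
                raise ValueError(f"drug pair ({g}, {d}): rho must be in (-1, 1)")
        for g, ct, rho in self.immune_pairs:
            if not -1.0 < rho < 1.0:
                raise ValueError(f"immune pair ({g}, {ct}): rho must be in (-1, 1)")
        for g, _, rho in self.silenced_genes:
            if not -1.0 < rho < 1.0:
                raise ValueError(f"silenced gene {g}: meth_expr_rho must be in (-1, 1)")
        for g, hr in self.prognostic_genes:
            if hr <= 0:
                raise ValueError(f"prognostic gene {g}: hazard ratio must be > 0")
        for g, amp, acro in self.rhythmic_genes:
            if amp < 0:
                raise ValueError(f"rhythmic gene {g}: amplitude must be >= 0")
            if not 0.0 <= acro < 24.0:
                raise ValueError(f"rhythmic gene {g}: acrophase must be in [0, 24)")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: [list(t) for t in v] for k, v in dataclasses.asdict(self).items()},
                fh,
                sort_keys=False,
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PlantedTruth":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**{k: [tuple(t) for t in v] for k, v in raw.items()})


def default_truth() -> PlantedTruth:
    """The default planted scenario: a lung-cohort-like pattern where
    clock genes activate RTK signalling, inhibit apoptosis and cell
    cycle, are methylation-silenced, prognostic, drug-linked, rhythmic,
    and tied to T-cell infiltration."""
    return PlantedTruth(
        activating_pairs=[
            ("RORA", "RTK", 0.8),
            ("CLOCK", "RTK", 0.8),
            ("PER2", "Apoptosis", -0.8),
            ("CRY2", "Cell Cycle", -0.8),
        ],
        silenced_genes=[
            ("PER1", 0.2, -0.5),
            ("PER2", 0.2, -0.5),
            ("PER3", 0.2, -0.5),
            ("CRY2", 0.2, -0.5),
            ("ARNTL", 0.2, -0.5),
        ],
        prognostic_genes=[("RORA", 0.5), ("CRY2", 0.5), ("PER1", 0.5)],
        drug_pairs=[
            ("CLOCK", "drug_01", 0.4),
            ("CRY1", "drug_02", 0.4),
            ("PER2", "drug_03", -0.4),
            ("CRY2", "drug_04", -0.4),
        ],
        rhythmic_genes=[
            ("CLOCK", 1.0, 0.0),
            ("ARNTL", 1.0, 22.0),
            ("NR1D1", 1.0, 6.0),
            ("PER1", 1.0, 8.0),
            ("PER3", 1.0, 9.0),
            ("PER2", 1.0, 10.0),
            ("CRY2", 1.0, 11.0),
            ("CRY1", 1.0, 12.0),
            ("RORA", 1.0, 16.0),
        ],
        immune_pairs=[
            ("CLOCK", "CD8+ T cells", 0.4),
            ("ARNTL", "CD8+ T cells", 0.4),
            ("CRY2", "CD4+ T cells", 0.4),
            ("PER1", "CD4+ T cells", 0.4),
        ],
    )


@dataclass
class CohortBundle:
    """One cancer type's full synthetic (or real) multi-omics set.

    Tumor-sample matrices (expression, methylation, cnv, immune_scores,
    survival) share sample IDs; methylation and expression additionally
    carry matched-normal columns; RPPA samples are a subset of the tumor
    samples; AUC and cell_line_expression share cell-line IDs; the
    timeseries matrix has its own time-stamped samples.
    """

    expression: OmicsMatrix | None = None
    methylation: OmicsMatrix | None = None
    rppa: OmicsMatrix | None = None
    cnv: OmicsMatrix | None = None
    auc: OmicsMatrix | None = None
    cell_line_expression: OmicsMatrix | None = None
    survival: SurvivalTable | None = None
    immune_scores: OmicsMatrix | None = None
    timeseries: OmicsMatrix | None = None
    times_hours: pd.Series | None = None
    tumor_ids: list[str] = field(default_factory=list)
    normal_ids: list[str] = field(default_factory=list)
    truth: PlantedTruth | None = None


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(
    config: AnalysisConfig,
    n_tumor: int = 200,
    n_normal: int = 50,
    n_cell_lines: int = 100,
    n_timepoints: int = 24,
    truth: PlantedTruth | None = None,
    *,
    n_null_genes: int = 20,
    n_drugs: int = 8,
    expr_log_sd: float = 0.6,
    cell_line_log_sd: float = 0.3,
    beta_logit_sd: float = 0.5,
    rhythm_noise_sd: float = 0.5,
    timeseries_span_hours: float = 48.0,
    baseline_median_days: float = 365.0,
    censoring_window_multiplier: float = 4.6,
) -> CohortBundle:
    """Generate a synthetic cohort with the given planted truth.

    Deterministic for a fixed ``config.seed``.  Planted gene, pathway,
    drug and cell-type names must exist in the configured panel, the
    default pathway set, the generated drug list and the default immune
    signature set respectively.
    """
    if n_tumor < 20:
        raise ValueError("n_tumor must be >= 20")
    if truth is None:
        truth = PlantedTruth()
    rng = np.random.default_rng(config.seed)

    panel = list(config.gene_panel)
    pathways = {p.pathway_name: p for p in default_pathways()}
    signatures = {s.cell_type: s for s in default_signatures()}
    drugs = [f"drug_{i + 1:02d}" for i in range(n_drugs)]

    # -- validate planted IDs -------------------------------------------
    for gene, pw, _ in truth.activating_pairs:
        if gene not in panel:
            raise ValueError(f"planted activating gene {gene!r} not in panel")
        if pw not in pathways:
            raise ValueError(f"planted pathway {pw!r} not in pathway set")
    for gene, *_ in truth.silenced_genes:
        if gene not in panel:
            raise ValueError(f"planted silenced gene {gene!r} not in panel")
    for gene, _ in truth.prognostic_genes:
        if gene not in panel:
            raise ValueError(f"planted prognostic gene {gene!r} not in panel")
    for gene, drug, _ in truth.drug_pairs:
        if gene not in panel:
            raise ValueError(f"planted drug-pair gene {gene!r} not in panel")
        if drug not in drugs:
            raise ValueError(f"planted drug {drug!r} not among generated drugs")
    for gene, *_ in truth.rhythmic_genes:
        if gene not in panel:
            raise ValueError(f"planted rhythmic gene {gene!r} not in panel")
    for gene, ct, _ in truth.immune_pairs:
        if gene not in panel:
            raise ValueError(f"planted immune-pair gene {gene!r} not in panel")
        if ct not in signatures:
            raise ValueError(f"planted cell type {ct!r} not in signature set")

    tumor_ids = [f"TUMOR_{i:04d}" for i in range(n_tumor)]
    normal_ids = [f"NORMAL_{i:04d}" for i in range(n_normal)]
    all_ids = tumor_ids + normal_ids
    n_all = len(all_ids)

    marker_genes: list[str] = []
    for sig in signatures.values():
        marker_genes.extend(g for g in sig.marker_genes if g not in marker_genes)
    null_genes = [f"NULL_{i:03d}" for i in range(n_null_genes)]
    genes = panel + marker_genes + null_genes

    silenced = {g: (db, rho) for g, db, rho in truth.silenced_genes}

    # -- methylation: logit-normal background, tumor shift for silenced --
    beta_center = {g: rng.normal(-0.8, 0.4) for g in genes}
    meth_latent = {g: rng.standard_normal(n_all) for g in genes}
    meth_rows = {}
    for g in genes:
        base = _sigmoid(beta_center[g] + beta_logit_sd * meth_latent[g])
        if g in silenced:
            db = silenced[g][0]
            base = base.copy()
            base[:n_tumor] = np.clip(base[:n_tumor] + db, 0.0, 1.0)
        meth_rows[g] = base
    methylation = OmicsMatrix(
        pd.DataFrame(meth_rows, index=all_ids).T, kind="methylation", units="beta"
    )

    # -- expression: log-normal background; copula couplings -------------
    expr_mu = {g: rng.normal(3.0, 1.0) for g in genes}
    expr_latent: dict[str, np.ndarray] = {}
    for g in genes:
        eps = rng.standard_normal(n_all)
        if g in silenced:
            # couple tumor expression to the methylation latent so the
            # target Spearman holds; normals stay independent
            rho_s = silenced[g][1]
            r = spearman_to_pearson_latent(rho_s)
            lat = eps.copy()
            lat[:n_tumor] = (
                r * meth_latent[g][:n_tumor] + np.sqrt(1.0 - r**2) * eps[:n_tumor]
            )
            expr_latent[g] = lat
        else:
            expr_latent[g] = eps

    # Immune marker genes ride on their driver genes' latents, with
    # per-marker weights chosen so the m-marker mean signature score hits
    # each planted target.  For drivers with independent latents and
    # weights w_j = rho_j / sqrt(m (1 - sum rho^2) + sum rho^2), the
    # score-driver correlation comes out at exactly rho_j.
    immune_by_ct: dict[str, list[tuple[str, float]]] = {}
    for gene, ct, rho in truth.immune_pairs:
        immune_by_ct.setdefault(ct, []).append((gene, rho))
    for ct, pairs in immune_by_ct.items():
        markers = list(signatures[ct].marker_genes)
        m = len(markers)
        s = sum(rho**2 for _, rho in pairs)
        if s >= 1.0:
            raise ValueError(f"cell type {ct!r}: sum of squared planted rho >= 1")
        denom = np.sqrt(m * (1.0 - s) + s)
        weights = [(gene, rho / denom) for gene, rho in pairs]
        resid_sd = np.sqrt(1.0 - sum(w**2 for _, w in weights))
        for mk in markers:
            if mk not in expr_latent:
                continue
            eps = rng.standard_normal(n_all)
            expr_latent[mk] = (
                sum(w * expr_latent[g] for g, w in weights) + resid_sd * eps
            )

    expr_rows = {}
    for g in genes:
        log_expr = expr_mu[g] + expr_log_sd * expr_latent[g]
        if g in silenced:
            log_expr = log_expr.copy()
            log_expr[:n_tumor] -= 0.7  # ~2-fold tumor down-regulation
        expr_rows[g] = np.exp(log_expr)
    expression = OmicsMatrix(
        pd.DataFrame(expr_rows, index=all_ids).T, kind="expression", units="RPKM"
    )
    tumor_expr = expression.values[tumor_ids]

    # -- RPPA: standard-normal background + driver-linked shifts ---------
    proteins: list[str] = []
    for pw in pathways.values():
        proteins.extend(p for p, _ in pw.members if p not in proteins)
    rppa_vals = pd.DataFrame(
        rng.standard_normal((len(proteins), n_tumor)),
        index=proteins,
        columns=tumor_ids,
    )
    for gene, pw_name, effect_sd in truth.activating_pairs:
        g = tumor_expr.loc[gene]
        high = (g > g.median()).to_numpy()
        for protein in pathways[pw_name].positive:
            if protein in rppa_vals.index:
                rppa_vals.loc[protein] += effect_sd * high
    rppa = OmicsMatrix(rppa_vals, kind="rppa", units="normalized protein")

    # -- CNV: per-gene category frequencies ------------------------------
    cnv_rows = {}
    for g in genes:
        p_het_amp = rng.uniform(0.0, 0.10)
        p_het_del = rng.uniform(0.0, 0.10)
        p_hom_amp = rng.uniform(0.0, 0.03)
        p_hom_del = rng.uniform(0.0, 0.03)
        p0 = 1.0 - (p_het_amp + p_het_del + p_hom_amp + p_hom_del)
        cnv_rows[g] = rng.choice(
            [0, 1, -1, 2, -2],
            size=n_tumor,
            p=[p0, p_het_amp, p_het_del, p_hom_amp, p_hom_del],
        ).astype(float)
    cnv = OmicsMatrix(pd.DataFrame(cnv_rows, index=tumor_ids).T, kind="cnv", units="call")

    # -- survival: exponential proportional hazards + uniform censoring --
    lam0 = np.log(2.0) / baseline_median_days
    log_hr = np.zeros(n_tumor)
    for gene, hr in truth.prognostic_genes:
        g = tumor_expr.loc[gene]
        log_hr += np.log(hr) * (g > g.median()).to_numpy()
    lam = lam0 * np.exp(log_hr)
    t_event = rng.exponential(1.0 / lam)
    # uniform censoring on [0, k * median event time]; k = 4.6 gives
    # ~30% censoring for exponential event times
    c = rng.uniform(
        0.0, censoring_window_multiplier * np.median(t_event), size=n_tumor
    )
    time = np.minimum(t_event, c)
    event = (t_event <= c).astype(int)
    survival = SurvivalTable(
        pd.DataFrame({"sample": tumor_ids, "time": time, "event": event})
    )

    # -- cell lines: expression + AUC with copula-planted correlations ---
    cl_ids = [f"CL_{i:03d}" for i in range(n_cell_lines)]
    cl_latent = {g: rng.standard_normal(n_cell_lines) for g in panel}
    cl_rows = {
        g: np.exp(expr_mu[g] + cell_line_log_sd * cl_latent[g]) for g in panel
    }
    cell_line_expression = OmicsMatrix(
        pd.DataFrame(cl_rows, index=cl_ids).T, kind="expression", units="RPKM"
    )
    planted_drug = {d: (g, rho) for g, d, rho in truth.drug_pairs}
    if len(planted_drug) != len(truth.drug_pairs):
        raise ValueError("each drug may carry at most one planted pair")
    auc_rows = {}
    for d in drugs:
        eps = rng.standard_normal(n_cell_lines)
        if d in planted_drug:
            g, rho = planted_drug[d]
            r = spearman_to_pearson_latent(rho)
            lat = r * cl_latent[g] + np.sqrt(1.0 - r**2) * eps
        else:
            lat = eps
        auc_rows[d] = 10.0 + 2.0 * lat
    auc = OmicsMatrix(pd.DataFrame(auc_rows, index=cl_ids).T, kind="auc", units="AUC")

    # -- immune scores derived from the marker genes ---------------------
    immune_scores = score_immune_signatures(
        expression.subset_samples(tumor_ids), list(signatures.values())
    )

    # -- time-stamped normal-tissue expression ---------------------------
    tp_ids = [f"TP_{i:03d}" for i in range(n_timepoints)]
    times = np.arange(n_timepoints) * (timeseries_span_hours / n_timepoints)
    rhythmic = {g: (a, acro) for g, a, acro in truth.rhythmic_genes}
    ts_rows = {}
    for g in panel + null_genes:
        mesor = rng.normal(5.0, 1.0)
        signal = np.full(n_timepoints, mesor)
        if g in rhythmic:
            a, acro = rhythmic[g]
            signal = mesor + a * np.cos(
                2.0 * np.pi * (times - acro) / config.rhythm_period_hours
            )
        ts_rows[g] = signal + rhythm_noise_sd * rng.standard_normal(n_timepoints)
    timeseries = OmicsMatrix(
        pd.DataFrame(ts_rows, index=tp_ids).T, kind="expression", units="log2 expression"
    )
    times_hours = pd.Series(times, index=tp_ids, name="hour")

    return CohortBundle(
        expression=expression,
        methylation=methylation,
        rppa=rppa,
        cnv=cnv,
        auc=auc,
        cell_line_expression=cell_line_expression,
        survival=survival,
        immune_scores=immune_scores,
        timeseries=timeseries,
        times_hours=times_hours,
        tumor_ids=tumor_ids,
        normal_ids=normal_ids,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_FILES = {
    "expression": ("expression.tsv", "expression"),
    "methylation": ("methylation.tsv", "methylation"),
    "rppa": ("rppa.tsv", "rppa"),
    "cnv": ("cnv.tsv", "cnv"),
    "auc": ("auc.tsv", "auc"),
    "cell_line_expression": ("cell_line_expression.tsv", "expression"),
    "immune_scores": ("immune_scores.tsv", "expression"),
    "timeseries": ("timeseries.tsv", "expression"),
}


def write_cohort(bundle: CohortBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for attr, (fname, _) in _FILES.items():
        matrix = getattr(bundle, attr)
        if matrix is not None:
            write_matrix(matrix, out / fname)
    if bundle.survival is not None:
        write_survival(bundle.survival, out / "survival.tsv")
    if bundle.times_hours is not None:
        bundle.times_hours.rename("hour").to_frame().rename_axis("sample").to_csv(
            out / "times.tsv", sep="\t"
        )
    pd.DataFrame(
        {
            "sample": bundle.tumor_ids + bundle.normal_ids,
            "group": ["tumor"] * len(bundle.tumor_ids)
            + ["normal"] * len(bundle.normal_ids),
        }
    ).to_csv(out / "samples.tsv", sep="\t", index=False)
    if bundle.truth is not None:
        bundle.truth.to_yaml(out / "truth.yaml")


def read_cohort(in_dir: str | Path) -> CohortBundle:
    src = Path(in_dir)
    matrices = {
        attr: read_matrix(src / fname, kind)
        for attr, (fname, kind) in _FILES.items()
        if (src / fname).exists()
    }
    if (src / "samples.tsv").exists():
        samples = pd.read_csv(src / "samples.tsv", sep="\t", dtype=str)
        tumor_ids = list(samples.loc[samples["group"] == "tumor", "sample"])
        normal_ids = list(samples.loc[samples["group"] == "normal", "sample"])
    elif "expression" in matrices:
        tumor_ids = matrices["expression"].sample_ids
        normal_ids = []
    else:
        tumor_ids, normal_ids = [], []
    times_hours = None
    if (src / "times.tsv").exists():
        times_hours = pd.read_csv(src / "times.tsv", sep="\t", index_col=0)["hour"]
    survival = (
        read_survival(src / "survival.tsv") if (src / "survival.tsv").exists() else None
    )
    truth = None
    if (src / "truth.yaml").exists():
        truth = PlantedTruth.from_yaml(src / "truth.yaml")
    return CohortBundle(
        survival=survival,
        times_hours=times_hours,
        tumor_ids=tumor_ids,
        normal_ids=normal_ids,
        truth=truth,
        **matrices,
    )
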