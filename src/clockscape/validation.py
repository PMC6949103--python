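"""Property-based validation of the pipeline on synthetic cohorts.

Each function here measures, from scratch, how well a pipeline stage
recovers effects planted by :mod:`clockscape.simulate` — recovery rates,
null calibration, and agreement with independent brute-force oracles.
These quantities back both the acceptance test suite and the
``scripts/acceptance.py`` report.
"""

from __future__ import annotations

import itertools
import tempfile
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .association import drug_correlation
from .clinical import (
    differential_expression,
    km_estimate,
    logrank_test,
    significant_de,
    survival_by_median_split,
)
from .core import AnalysisConfig, OmicsMatrix, SurvivalTable
from .epigenomics import differential_methylation, methylation_expression_effect
from .pathway import (
    call_pathway_effects,
    compute_pas,
    default_pathways,
    normalize_rppa,
)
from .rhythm import fit_cosinor
from .pipeline import run_pipeline
from .simulate import PlantedTruth, default_truth, generate_cohort, write_cohort


# ---------------------------------------------------------------------------
# 1. PAS oracle equivalence
# ---------------------------------------------------------------------------

def _loop_pas(values: pd.DataFrame, pathways) -> pd.DataFrame:
    """Brute-force PAS: explicit loops over pathways, samples, members."""
    out = pd.DataFrame(
        np.nan, index=[p.pathway_name for p in pathways], columns=values.columns
    )
    for pw in pathways:
        for sample in values.columns:
            total, seen = 0.0, False
            for protein, sign in pw.members:
                if protein not in values.index:
                    continue
                v = values.loc[protein, sample]
                if np.isnan(v):
                    continue
                total += sign * v
                seen = True
            if seen:
                out.loc[pw.pathway_name, sample] = total
    return out


def pas_oracle_max_abs_diff(seed: int, n_instances: int = 100) -> float:
    """Max |compute_pas - loop oracle| over random RPPA instances
    (<=30 proteins, <=20 samples, random signed pathways, missing cells)."""
    from .core import PathwayDefinition

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n_prot = int(rng.integers(3, 31))
        n_samp = int(rng.integers(2, 21))
        proteins = [f"P{i}" for i in range(n_prot)]
        vals = rng.normal(size=(n_prot, n_samp))
        vals[rng.uniform(size=vals.shape) < 0.15] = np.nan
        m = OmicsMatrix(
            pd.DataFrame(vals, index=proteins, columns=[f"s{j}" for j in range(n_samp)]),
            kind="rppa",
        )
        pathways = []
        for k in range(int(rng.integers(1, 8))):
            size = int(rng.integers(1, min(6, n_prot) + 1))
            members = rng.choice(proteins, size=size, replace=False)
            signs = rng.choice([1, -1], size=size)
            pathways.append(
                PathwayDefinition(f"pw{k}", tuple(zip(members.tolist(), signs.tolist())))
            )
        pas = compute_pas(m, pathways).values.to_numpy()
        ref = _loop_pas(m.values, pathways).to_numpy()
        if not np.array_equal(np.isnan(pas), np.isnan(ref)):
            return float("inf")
        mask = ~np.isnan(pas)
        if mask.any():
            worst = max(worst, float(np.max(np.abs(pas[mask] - ref[mask]))))
    return worst


# ---------------------------------------------------------------------------
# 2. Pathway activation-call recovery and null calibration
# ---------------------------------------------------------------------------

def activation_recovery(seed: int, n_seeds: int = 100, n_tumor: int = 200):
    """Fraction of seeds where a planted (RORA -> RTK, 0.8 SD) effect is
    called "activate" at FDR <= 0.05, plus the fraction of null
    gene x pathway pairs called anything but "none"."""
    truth = PlantedTruth(activating_pairs=[("RORA", "RTK", 0.8)])
    hits = 0
    null_calls = 0
    null_total = 0
    for s in range(n_seeds):
        cfg = AnalysisConfig(seed=seed + s)
        b = generate_cohort(cfg, n_tumor=n_tumor, truth=truth)
        pas = compute_pas(normalize_rppa(b.rppa), default_pathways())
        calls = call_pathway_effects(
            b.expression.subset_samples(b.tumor_ids), pas, cfg
        )
        for c in calls:
            if (c.gene, c.pathway) == ("RORA", "RTK"):
                hits += c.direction == "activate" and c.fdr <= cfg.fdr_threshold
            else:
                null_total += 1
                null_calls += c.direction != "none"
    return hits / n_seeds, null_calls / null_total


# ---------------------------------------------------------------------------
# 3. Methylation calibration and recovery
# ---------------------------------------------------------------------------

def methylation_null_rejection_rate(seed: int, n_genes: int = 2000) -> float:
    """Raw-p rejection rate at alpha = 0.05 for null genes with no
    tumor/normal methylation difference."""
    panel = tuple(f"G{i:04d}" for i in range(n_genes))
    cfg = AnalysisConfig(gene_panel=panel, seed=seed)
    b = generate_cohort(cfg, truth=PlantedTruth(), n_null_genes=0, n_drugs=1)
    recs = differential_methylation(b.methylation, b.tumor_ids, b.normal_ids, cfg)
    p = np.array([r.p_value for r in recs])
    return float(np.mean(p < 0.05))


def methylation_detection_rate(seed: int, n_seeds: int = 100) -> float:
    """Fraction of seeds where a planted tumor beta shift of +0.2 is
    significant at FDR < 0.05."""
    truth = PlantedTruth(silenced_genes=[("PER1", 0.2, -0.5)])
    hits = 0
    for s in range(n_seeds):
        cfg = AnalysisConfig(seed=seed + s)
        b = generate_cohort(cfg, truth=truth, n_drugs=1)
        recs = differential_methylation(b.methylation, b.tumor_ids, b.normal_ids, cfg)
        rec = next(r for r in recs if r.gene == "PER1")
        hits += rec.fdr < cfg.fdr_threshold
    return hits / n_seeds


def meth_expr_rho_mean(seed: int, n_seeds: int = 50) -> float:
    """Mean estimated methylation-expression Spearman rho for a planted
    target of -0.5."""
    truth = PlantedTruth(silenced_genes=[("PER1", 0.2, -0.5)])
    rhos = []
    for s in range(n_seeds):
        cfg = AnalysisConfig(seed=seed + s)
        b = generate_cohort(cfg, truth=truth, n_drugs=1)
        recs = methylation_expression_effect(b.methylation, b.expression, b.tumor_ids, cfg)
        rhos.append(next(r for r in recs if r.gene == "PER1").effect)
    return float(np.mean(rhos))


# ---------------------------------------------------------------------------
# 4. Survival: oracle exactness, power, type-I error
# ---------------------------------------------------------------------------

def _km_oracle(times, events):
    out_t, out_s = [], []
    s = 1.0
    for t in sorted(set(t for t, e in zip(times, events) if e)):
        n = sum(ti >= t for ti in times)
        d = sum((ti == t) and e for ti, e in zip(times, events))
        s *= 1 - d / n
        out_t.append(t)
        out_s.append(s)
    return out_t, out_s


def _logrank_oracle(ta, ea, tb, eb):
    all_t = sorted(set([t for t, e in zip(ta, ea) if e] + [t for t, e in zip(tb, eb) if e]))
    oe, var = 0.0, 0.0
    for t in all_t:
        n1 = sum(ti >= t for ti in ta)
        n2 = sum(ti >= t for ti in tb)
        d1 = sum((ti == t) and e for ti, e in zip(ta, ea))
        d2 = sum((ti == t) and e for ti, e in zip(tb, eb))
        n, d = n1 + n2, d1 + d2
        if n1 == 0 or n2 == 0 or n < 2:
            continue
        oe += d1 - d * n1 / n
        var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return 0.0 if var <= 0 else oe**2 / var


def _table(times, events):
    return SurvivalTable(
        pd.DataFrame(
            {"sample": [f"s{i}" for i in range(len(times))], "time": times, "event": events}
        )
    )


def survival_oracle_max_abs_diff(max_n: int = 6) -> float:
    """Max discrepancy of km_estimate and logrank_test against brute-force
    risk-set enumeration over all subject counts <= max_n, exhaustive
    event/censor patterns, and (for the log-rank) all 2-group splits."""
    worst = 0.0
    for n in range(1, max_n + 1):
        times = list(range(1, n + 1))
        for events in itertools.product([0, 1], repeat=n):
            if sum(events) == 0:
                continue
            curve = km_estimate(_table(times, list(events)))
            ot, os_ = _km_oracle(times, list(events))
            if list(curve.times) != ot:
                return float("inf")
            if ot:
                worst = max(worst, float(np.max(np.abs(np.array(curve.survival) - np.array(os_)))))
            for mask in itertools.product([0, 1], repeat=n):
                if sum(mask) in (0, n):
                    continue
                ta = [t for t, m in zip(times, mask) if m]
                ea = [e for e, m in zip(events, mask) if m]
                tb = [t for t, m in zip(times, mask) if not m]
                eb = [e for e, m in zip(events, mask) if not m]
                chi2, _ = logrank_test(_table(ta, ea), _table(tb, eb))
                worst = max(worst, abs(chi2 - _logrank_oracle(ta, ea, tb, eb)))
    return worst


def _median_split_pvalue(seed: int, hazard_ratio: float) -> float:
    truth = (
        PlantedTruth(prognostic_genes=[("RORA", hazard_ratio)])
        if hazard_ratio != 1.0
        else PlantedTruth()
    )
    cfg = AnalysisConfig(seed=seed)
    b = generate_cohort(cfg, truth=truth, n_null_genes=0, n_drugs=1, n_cell_lines=20,
                        n_normal=20, n_timepoints=4)
    res = survival_by_median_split(
        b.expression.subset_samples(b.tumor_ids), b.survival, cfg
    )
    return next(r for r in res if r.gene == "RORA").p_value


def logrank_power(seed: int, n_seeds: int = 500, hazard_ratio: float = 2.0) -> float:
    """Rejection rate at alpha = 0.05 of the median-split log-rank test
    for a planted hazard ratio, 100 + 100 patients per arm."""
    return float(
        np.mean([_median_split_pvalue(seed + s, hazard_ratio) < 0.05 for s in range(n_seeds)])
    )


def logrank_null_rate(seed: int, n_seeds: int = 2000) -> float:
    """Type-I error of the median-split log-rank test at alpha = 0.05."""
    return float(
        np.mean([_median_split_pvalue(seed + s, 1.0) < 0.05 for s in range(n_seeds)])
    )


# ---------------------------------------------------------------------------
# 5. Cosinor recovery
# ---------------------------------------------------------------------------

def cosinor_noiseless_max_err() -> float:
    """Worst recovery error of (mesor, amplitude, acrophase) for noiseless
    cosines over a grid of amplitudes and acrophases."""
    t = np.arange(24.0)
    worst = 0.0
    for amp in (0.5, 1.0, 2.0):
        for acro in (0.0, 3.0, 8.0, 13.5, 21.0):
            y = 3.0 + amp * np.cos(2 * np.pi * (t - acro) / 24.0)
            fit = fit_cosinor(y, t)
            d_acro = abs(fit.acrophase_hours - acro) % 24.0
            worst = max(
                worst,
                abs(fit.mesor - 3.0),
                abs(fit.amplitude - amp),
                min(d_acro, 24.0 - d_acro),
            )
    return worst


def cosinor_recovery(seed: int, n_seeds: int = 200):
    """Mean amplitude estimate and detection rate for a planted 24 h
    rhythm (A = 1, sigma = 0.5, 24 samples over 48 h), fitted through the
    cohort generator's time-series assay."""
    truth = PlantedTruth(rhythmic_genes=[("CLOCK", 1.0, 8.0)])
    amps, detected = [], 0
    for s in range(n_seeds):
        cfg = AnalysisConfig(seed=seed + s)
        b = generate_cohort(cfg, truth=truth, n_null_genes=0, n_drugs=1,
                            n_cell_lines=20, n_normal=20)
        fit = fit_cosinor(
            b.timeseries.values.loc["CLOCK"].to_numpy(),
            b.times_hours.to_numpy(),
            period_hours=cfg.rhythm_period_hours,
        )
        amps.append(fit.amplitude)
        detected += fit.p_value < 0.05
    return float(np.mean(amps)), detected / n_seeds


def cosinor_shift_equivariance_max_err(seed: int) -> float:
    """Worst-case deviation from acrophase equivariance and amplitude/p
    invariance under time shifts."""
    rng = np.random.default_rng(seed)
    t = np.sort(rng.uniform(0, 48, size=30))
    y = 2.0 + 1.5 * np.cos(2 * np.pi * (t - 14.0) / 24.0) + rng.normal(0, 0.4, 30)
    base = fit_cosinor(y, t)
    worst = 0.0
    for delta in (1.3, 7.9, 24.0, -5.5):
        fit = fit_cosinor(y, t + delta)
        d = abs(fit.acrophase_hours - (base.acrophase_hours + delta) % 24.0) % 24.0
        worst = max(
            worst,
            min(d, 24.0 - d),
            abs(fit.amplitude - base.amplitude),
            abs(fit.p_value - base.p_value),
        )
    return worst


# ---------------------------------------------------------------------------
# 6. Fisher Z and drug-label recovery
# ---------------------------------------------------------------------------

def fisher_z_max_err() -> float:
    """Max |atanh(tanh(z)) - z| over a grid of z values."""
    from .core import fisher_z as fz

    grid = np.linspace(-5, 5, 201)
    return float(np.max(np.abs([fz(np.tanh(z)) - z for z in grid])))


def drug_label_recovery(seed: int, n_seeds: int = 100) -> float:
    """Fraction of seeds where a planted (CLOCK, drug_01, rho = 0.4) pair
    over 100 cell lines is labeled "resistance"."""
    truth = PlantedTruth(drug_pairs=[("CLOCK", "drug_01", 0.4)])
    hits = 0
    for s in range(n_seeds):
        cfg = AnalysisConfig(seed=seed + s)
        b = generate_cohort(cfg, truth=truth, n_null_genes=0, n_normal=20,
                            n_timepoints=4)
        recs = drug_correlation(b.cell_line_expression, b.auc, cfg)
        rec = next(r for r in recs if (r.gene, r.drug) == ("CLOCK", "drug_01"))
        hits += rec.label == "resistance"
    return hits / n_seeds


# ---------------------------------------------------------------------------
# 7. Differential-expression joint filter on the constructed fixture
# ---------------------------------------------------------------------------

def de_fixture_matrix():
    """Ten genes, 6 + 6 samples: exactly three genes carry a clean
    4-fold shift with tiny within-group variation; seven are null."""
    rows = []
    for i in range(3):
        base = 10.0 + i
        rows.append([4 * base + 0.01 * j for j in range(6)] + [base + 0.01 * j for j in range(6)])
    for i in range(7):
        base = 20.0 + i
        rows.append([base + 0.1 * j for j in range(6)] + [base + 0.1 * j for j in range(6)])
    cols = [f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)]
    df = pd.DataFrame(rows, columns=cols, index=[f"g{i}" for i in range(10)])
    return OmicsMatrix(df, kind="expression"), cols[:6], cols[6:]


def de_filter_count() -> int:
    """Number of fixture genes passing |log2FC| > 1 AND FDR <= 0.05."""
    m, a, b = de_fixture_matrix()
    cfg = AnalysisConfig()
    return len(significant_de(differential_expression(m, a, b, cfg), cfg))


# ---------------------------------------------------------------------------
# 8. End-to-end simulate + run
# ---------------------------------------------------------------------------

def end_to_end(seed: int, workdir: str | Path | None = None):
    """Simulate the default three cohorts, run the full pipeline twice,
    and report (wall seconds for one simulate+run, results identical)."""
    ctx = tempfile.TemporaryDirectory() if workdir is None else None
    root = Path(ctx.name) if ctx else Path(workdir)
    try:
        t0 = time.perf_counter()
        dirs = []
        for i, name in enumerate(("LUAD", "LUSC", "ESCA")):
            cfg = AnalysisConfig(seed=seed + i)
            write_cohort(generate_cohort(cfg, truth=default_truth()), root / "sim" / name)
            dirs.append(root / "sim" / name)
        run_pipeline(AnalysisConfig(seed=seed), dirs, root / "rep1")
        elapsed = time.perf_counter() - t0
        run_pipeline(AnalysisConfig(seed=seed), dirs, root / "rep2")
        identical = (
            (root / "rep1" / "results.tsv").read_bytes()
            == (root / "rep2" / "results.tsv").read_bytes()
        )
        return elapsed, identical
    finally:
        if ctx:
            ctx.cleanup()
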